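import numpy as np
import pandas as pd
import pytest

import perturbnet as pn


@pytest.fixture()
def tiny_panel():
    """Four control samples, one tumor sample, two hand-checkable edges."""
    samples = ["c1", "c2", "c3", "c4", "t1"]
    mirna = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 1.0, 4.0, 3.0, 2.0]],
        index=["m1", "m2"],
        columns=samples,
    )
    lncrna = pd.DataFrame(
        [[1.0, 3.0, 2.0, 4.0, 0.0], [5.0, 4.0, 3.0, 2.0, 1.0]],
        index=["l1", "l2"],
        columns=samples,
    )
    phenotype = pd.Series(
        ["non_tumor"] * 4 + ["tumor"], index=samples, name="phenotype"
    )
    return pn.ExpressionPanel(mirna=mirna, lncrna=lncrna, phenotype=phenotype)


@pytest.fixture()
def tiny_catalog(tiny_panel):
    return pn.make_catalog(["m1", "m2"], ["l1", "l2"], panel=tiny_panel)


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded synthetic cohort small enough for exhaustive checks."""
    cfg = pn.SyntheticConfig(n_edges=60, n_planted=6, n_ref=30, n_tumor=20, seed=42)
    panel, catalog, planted = pn.generate(cfg)
    return panel, catalog, planted


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Reference network, ΔPCC matrices, cutoff and scores for the small cohort."""
    panel, catalog, planted = small_cohort
    ref = pn.build_reference(panel, catalog)
    dt = pn.delta_matrix(ref, panel, "tumor")
    dc = pn.delta_matrix(ref, panel, "non_tumor")
    cutoff = pn.fit_cutoff(dt, alpha=0.05)
    scores = pn.scores_from_delta(dt, cutoff, catalog)
    return {
        "panel": panel,
        "catalog": catalog,
        "planted": planted,
        "ref": ref,
        "delta_tumor": dt,
        "delta_control": dc,
        "cutoff": cutoff,
        "scores": scores,
    }


def all_edge_candidates(scores: pd.DataFrame) -> pn.CandidateSet:
    """The full catalog as an (ordered) candidate set, for feature building."""
    edges = scores[["mirna", "lncrna", "score"]].copy()
    edges["catalog_index"] = np.arange(len(scores))
    return pn.CandidateSet(edges=edges, threshold=0.0)
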