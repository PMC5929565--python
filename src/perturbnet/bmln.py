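"""Aggregate per-sample networks into a per-cancer basic network (BMLN).

For each catalog edge the significance score is the fraction of tumor samples
whose individual-specific network contains it:

    score(miRNA_i, lncRNA_j) = N1 / N

where N1 counts the samples with a significant ΔPCC on that edge and N is the
total number of tumor samples.  Edges with high scores form the cancer's
basic network; those above a threshold (default 0.8, strict inequality)
become the candidate edge biomarkers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io import InteractionCatalog
from .network import DeltaPccMatrix, Ismln, SignificanceCutoff, significant_matrix

SCORE_COLUMNS = ["mirna", "lncrna", "n_significant", "n_samples", "score"]


@dataclass
class CandidateSet:
    """Edges above the score threshold, deterministically ordered.

    Order: descending score, then descending |mean tumor ΔPCC|, then catalog
    order.  ``edges`` carries the ordered rows with their catalog indices.
    """

    edges: pd.DataFrame  # columns: mirna, lncrna, score, catalog_index
    threshold: float

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["mirna"], self.edges["lncrna"]))

    @property
    def catalog_indices(self) -> np.ndarray:
        return self.edges["catalog_index"].to_numpy(dtype=int)


@dataclass
class CrossCancerMatrix:
    """Top-K edges per cohort, compared across cohorts.

    ``matrix``: rows = union of the per-cohort top-K edges, columns =
    cohorts, cells = that cohort's significance score (0 where the edge is
    absent from a cohort's catalog).  ``lncrna_degree``: for each lncRNA
    appearing in some cohort's top-K edges, the number of cohorts in which it
    does.
    """

    matrix: pd.DataFrame
    lncrna_degree: pd.DataFrame
    k: int


def significance_scores(
    ismlns: list[Ismln],
    catalog: InteractionCatalog,
    delta: DeltaPccMatrix | None = None,
) -> pd.DataFrame:
    """Per-edge significance scores N1/N over a list of ISMLNs.

    Returns a table covering every catalog edge with columns
    ``(mirna, lncrna, n_significant, n_samples, score)``.  When ``delta`` is
    given, a ``mean_abs_delta`` column (|mean tumor ΔPCC|, the ranking
    tie-break) is appended.
    """
    if not ismlns:
        raise DataError("significance_scores: empty ISMLN list")
    n_edges = len(catalog)
    counts = np.zeros(n_edges, dtype=int)
    for net in ismlns:
        if len(net.edge_indices) and net.edge_indices.max() >= n_edges:
            raise DataError("ISMLN references an edge outside the catalog")
        counts[net.edge_indices] += 1
    n = len(ismlns)
    table = pd.DataFrame(
        {
            "mirna": catalog.mirna_ids,
            "lncrna": catalog.lncrna_ids,
            "n_significant": counts,
            "n_samples": n,
            "score": counts / n,
        }
    )
    if delta is not None:
        table["mean_abs_delta"] = delta.mean_abs_delta()
    return table


def scores_from_delta(
    delta: DeltaPccMatrix, cutoff: SignificanceCutoff, catalog: InteractionCatalog
) -> pd.DataFrame:
    """Significance scores straight from a ΔPCC matrix and fitted cutoff."""
    if delta.n_edges != len(catalog):
        raise DataError("ΔPCC matrix and catalog disagree on the number of edges")
    sig = significant_matrix(delta, cutoff)
    counts = sig.sum(axis=1).astype(int)
    table = pd.DataFrame(
        {
            "mirna": catalog.mirna_ids,
            "lncrna": catalog.lncrna_ids,
            "n_significant": counts,
            "n_samples": delta.n_samples,
            "score": counts / delta.n_samples,
        }
    )
    table["mean_abs_delta"] = delta.mean_abs_delta()
    return table


def _ordering(scores: pd.DataFrame, tie_break=None) -> np.ndarray:
    """Deterministic ranking order: score desc, tie-break desc, catalog order."""
    s = scores["score"].to_numpy(dtype=float)
    if tie_break is None:
        if "mean_abs_delta" in scores.columns:
            tie_break = scores["mean_abs_delta"].to_numpy(dtype=float)
        else:
            tie_break = np.zeros(len(scores))
    tie = np.abs(np.asarray(tie_break, dtype=float))
    # np.lexsort sorts by the last key first
    return np.lexsort((np.arange(len(s)), -tie, -s))


def select_candidates(
    scores: pd.DataFrame, threshold: float = 0.8, tie_break=None
) -> CandidateSet:
    """Edges with score strictly greater than ``threshold``, ranked.

    ``tie_break`` (optional) is a per-edge array in catalog order, typically
    |mean tumor ΔPCC|; it defaults to the ``mean_abs_delta`` column when
    present.  An empty result is a warning, not an error.
    """
    if not (0.0 <= threshold <= 1.0):
        raise DataError(f"threshold must be in [0, 1], got {threshold}")
    order = _ordering(scores, tie_break)
    keep = scores["score"].to_numpy(dtype=float) > threshold
    ordered = [i for i in order if keep[i]]
    if not ordered:
        warnings.warn(f"no edge has significance score > {threshold}", stacklevel=2)
    edges = scores.iloc[ordered][["mirna", "lncrna", "score"]].reset_index(drop=True)
    edges["catalog_index"] = np.asarray(ordered, dtype=int)
    return CandidateSet(edges=edges, threshold=threshold)


def top_k_edges(scores: pd.DataFrame, k: int, tie_break=None) -> pd.DataFrame:
    """The k highest-ranked edges under the candidate ordering."""
    if k < 1:
        raise DataError("k must be >= 1")
    order = _ordering(scores, tie_break)[:k]
    out = scores.iloc[order][["mirna", "lncrna", "score"]].reset_index(drop=True)
    out["catalog_index"] = order
    return out


def cross_cancer(
    tables: dict[str, pd.DataFrame], k: int = 200
) -> CrossCancerMatrix:
    """Compare the top-k edges of several cohorts.

    Rows are the union of each cohort's top-k edges (first-appearance order
    over cohorts); each cell holds that cohort's significance score for the
    edge, 0.0 where the edge is outside the cohort's catalog.  The degree
    table counts, per lncRNA, the cohorts in which it appears among the
    top-k edges.
    """
    if len(tables) < 2:
        raise DataError("cross_cancer needs at least 2 cohorts")
    edge_sets = {
        c: set(zip(t["mirna"], t["lncrna"])) for c, t in tables.items()
    }
    cohorts = list(tables)
    for i, a in enumerate(cohorts):
        for b in cohorts[i + 1 :]:
            if not (edge_sets[a] & edge_sets[b]):
                raise DataError(f"cohorts {a!r} and {b!r} have disjoint catalogs")

    tops = {c: top_k_edges(t, k) for c, t in tables.items()}
    rows: list[tuple[str, str]] = []
    seen = set()
    for c in cohorts:
        for pair in zip(tops[c]["mirna"], tops[c]["lncrna"]):
            if pair not in seen:
                seen.add(pair)
                rows.append(pair)

    lookup = {
        c: dict(zip(zip(t["mirna"], t["lncrna"]), t["score"])) for c, t in tables.items()
    }
    data = {
        c: [float(lookup[c].get(pair, 0.0)) for pair in rows] for c in cohorts
    }
    matrix = pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(rows, names=["mirna", "lncrna"])
    )

    top_lnc = {c: set(tops[c]["lncrna"]) for c in cohorts}
    all_lnc: list[str] = []
    seen_l: set[str] = set()
    for c in cohorts:
        for l in tops[c]["lncrna"]:
            if l not in seen_l:
                seen_l.add(l)
                all_lnc.append(l)
    degree = pd.DataFrame(
        {
            "lncrna": all_lnc,
            "degree": [sum(l in top_lnc[c] for c in cohorts) for l in all_lnc],
        }
    )
    return CrossCancerMatrix(matrix=matrix, lncrna_degree=degree, k=k)
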