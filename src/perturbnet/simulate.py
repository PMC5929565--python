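"""Synthetic cohort generator with planted correlation perturbations.

The perturbation method is sensitive only to the pair-level correlation
structure of the expression matrices, so cohorts are simulated from latent
bivariate normals: each catalog edge's endpoints are drawn with a prescribed
reference correlation in the non-tumor samples, while a chosen ("planted")
subset of edges switches to a different correlation in the tumor samples —
relational dysregulation with untouched marginals.  Latent values are mapped
to expression-like scale by an affine transform (which preserves every
correlation exactly) and shifted to be non-negative.

Defaults mirror a breast-carcinoma-shaped cohort thinned to desk scale:
84 controls, 100 tumors, 500 catalog edges of which 25 are planted with the
reference correlation 0.8 collapsing to 0 in tumors.  The full 84/508
control/tumor shape is available as the ``brca-shape`` preset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError
from .io import ExpressionPanel, InteractionCatalog
from .network import Ismln

PRESETS = {
    # control/tumor counts of the breast-carcinoma cohort shape
    "brca-shape": {"n_ref": 84, "n_tumor": 508},
}


@dataclass
class SyntheticConfig:
    """Parameters of one simulated cohort.

    ``rho_ref`` may be a scalar or per-edge vector in (-1, 1); planted edges
    use ``rho_tumor`` in the tumor samples.  ``mean_shift`` optionally shifts
    tumor means of named features (dict id -> shift) or, as a scalar, of all
    planted-edge endpoints — the knob for node-level (differential
    expression) signal.  ``mode="shared_mirna"`` lets one miRNA serve
    ``edges_per_mirna`` consecutive edges through a common latent factor,
    which is what exercises the C1/C2 bookkeeping of the activity score.
    The seed fully determines the output.
    """

    n_ref: int = 84
    n_tumor: int = 100
    n_edges: int = 500
    n_planted: int = 25
    rho_ref: float | np.ndarray = 0.8
    rho_tumor: float = 0.0
    noise_sd: float = 1.0
    base_mean: float = 10.0
    mean_shift: float | dict[str, float] | None = None
    mode: str = "independent_pair"
    edges_per_mirna: int = 4
    seed: int = 0

    def with_preset(self, name: str) -> "SyntheticConfig":
        if name not in PRESETS:
            raise DataError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        return replace(self, **PRESETS[name])


def _validate_rho(rho: np.ndarray) -> None:
    if not np.all(np.abs(rho) < 1.0):
        raise DataError("correlations must lie strictly inside (-1, 1)")


def _mirna_name(i: int) -> str:
    return f"mir-{i:05d}"


def _lncrna_name(i: int) -> str:
    return f"lnc-{i:05d}"


def generate(config: SyntheticConfig):
    """Simulate a cohort; returns ``(panel, catalog, planted_pairs)``.

    ``planted_pairs`` is the ground-truth list of perturbed (miRNA, lncRNA)
    edges in catalog order.
    """
    cfg = config
    if cfg.n_ref < 3 or cfg.n_tumor < 1:
        raise DataError("need n_ref >= 3 and n_tumor >= 1")
    if not (0 <= cfg.n_planted <= cfg.n_edges):
        raise DataError("n_planted must be between 0 and n_edges")
    rng = np.random.default_rng(cfg.seed)
    E, S = cfg.n_edges, cfg.n_ref + cfg.n_tumor
    rho_ref = np.broadcast_to(np.asarray(cfg.rho_ref, dtype=float), (E,)).copy()
    _validate_rho(rho_ref)
    _validate_rho(np.asarray([cfg.rho_tumor]))

    planted = np.sort(rng.choice(E, size=cfg.n_planted, replace=False))

    # per-edge, per-sample target correlation
    rho = np.tile(rho_ref[:, None], (1, S))
    rho[planted, cfg.n_ref:] = cfg.rho_tumor

    if cfg.mode == "independent_pair":
        zm = rng.standard_normal((E, S))
        eps = rng.standard_normal((E, S))
        zl = rho * zm + np.sqrt(1.0 - rho**2) * eps
        mirna_names = [_mirna_name(e) for e in range(E)]
        lncrna_names = [_lncrna_name(e) for e in range(E)]
        M = zm
        parent = np.arange(E)
    elif cfg.mode == "shared_mirna":
        if cfg.edges_per_mirna < 1:
            raise DataError("edges_per_mirna must be >= 1")
        n_m = math.ceil(E / cfg.edges_per_mirna)
        parent = np.repeat(np.arange(n_m), cfg.edges_per_mirna)[:E]
        latent = rng.standard_normal((n_m, S))
        eps = rng.standard_normal((E, S))
        zl = rho * latent[parent] + np.sqrt(1.0 - rho**2) * eps
        mirna_names = [_mirna_name(p) for p in parent]
        lncrna_names = [_lncrna_name(e) for e in range(E)]
        M = latent
    else:
        raise DataError(f"unknown mode {cfg.mode!r}")

    sample_ids = [f"ctrl-{i:04d}" for i in range(cfg.n_ref)] + [
        f"tum-{i:04d}" for i in range(cfg.n_tumor)
    ]
    mirna_index = (
        [_mirna_name(e) for e in range(E)]
        if cfg.mode == "independent_pair"
        else [_mirna_name(p) for p in range(M.shape[0])]
    )
    mirna = pd.DataFrame(
        cfg.base_mean + cfg.noise_sd * M, index=mirna_index, columns=sample_ids
    )
    lncrna = pd.DataFrame(
        cfg.base_mean + cfg.noise_sd * zl,
        index=[_lncrna_name(e) for e in range(E)],
        columns=sample_ids,
    )

    if cfg.mean_shift is not None:
        tumor_cols = sample_ids[cfg.n_ref:]
        if isinstance(cfg.mean_shift, dict):
            shifts = cfg.mean_shift
        else:
            shifts = {}
            for e in planted:
                shifts[mirna_names[e]] = float(cfg.mean_shift)
                shifts[lncrna_names[e]] = float(cfg.mean_shift)
        for fid, val in shifts.items():
            if fid in mirna.index:
                mirna.loc[fid, tumor_cols] += val
            elif fid in lncrna.index:
                lncrna.loc[fid, tumor_cols] += val
            else:
                raise DataError(f"mean_shift names unknown feature {fid!r}")

    # per-feature affine shift to non-negative values: preserves correlations
    for df in (mirna, lncrna):
        mins = df.min(axis=1)
        neg = mins < 0.0
        if neg.any():
            df.loc[neg] = df.loc[neg].sub(mins[neg], axis=0)

    phenotype = pd.Series(
        ["non_tumor"] * cfg.n_ref + ["tumor"] * cfg.n_tumor,
        index=sample_ids,
        name="phenotype",
    )
    panel = ExpressionPanel(mirna=mirna, lncrna=lncrna, phenotype=phenotype)
    catalog = InteractionCatalog(
        edges=pd.DataFrame({"mirna": mirna_names, "lncrna": lncrna_names})
    )
    planted_pairs = [(mirna_names[e], lncrna_names[e]) for e in planted]
    return panel, catalog, planted_pairs


def worked_example_fixture(n_samples: int = 508):
    """Indicator fixture for the significance-score arithmetic.

    Three edges over ``n_samples`` individual networks: one significant in
    every sample, one in none, one in exactly half.  Returns ``(indicator,
    expected)`` where ``indicator`` is an edges x samples boolean frame and
    ``expected`` the score table the significance score must reproduce.
    """
    if n_samples < 2 or n_samples % 2:
        raise DataError("n_samples must be an even number >= 2")
    edges = [("mir-a", "lnc-x"), ("mir-b", "lnc-y"), ("mir-c", "lnc-z")]
    samples = [f"tum-{i:04d}" for i in range(n_samples)]
    ind = np.zeros((3, n_samples), dtype=bool)
    ind[0, :] = True
    ind[2, : n_samples // 2] = True
    indicator = pd.DataFrame(
        ind, index=pd.MultiIndex.from_tuples(edges, names=["mirna", "lncrna"]),
        columns=samples,
    )
    expected = pd.DataFrame(
        {
            "mirna": [m for m, _ in edges],
            "lncrna": [l for _, l in edges],
            "n_significant": [n_samples, 0, n_samples // 2],
            "n_samples": n_samples,
            "score": [1.0, 0.0, 0.5],
        }
    )
    return indicator, expected


def ismlns_from_indicator(indicator: pd.DataFrame) -> tuple[list[Ismln], InteractionCatalog]:
    """Turn an edges x samples boolean frame into per-sample ISMLN objects."""
    mirnas = [m for m, _ in indicator.index]
    lncrnas = [l for _, l in indicator.index]
    catalog = InteractionCatalog(edges=pd.DataFrame({"mirna": mirnas, "lncrna": lncrnas}))
    vals = indicator.to_numpy(dtype=bool)
    nets = []
    for j, sid in enumerate(indicator.columns):
        idx = np.flatnonzero(vals[:, j])
        nets.append(Ismln(sample_id=str(sid), edge_indices=idx, delta=np.zeros(len(idx))))
    return nets, catalog
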