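"""Reference correlation network, single-sample perturbation and ΔPCC statistics.

The method models each catalog edge (miRNA i, lncRNA j) by the Pearson
correlation r_ij of the two expression profiles over the n non-tumor
(reference) samples.  Appending one case sample to the reference cohort and
recomputing the correlation over the n+1 samples yields the perturbed
correlation; the difference

    ΔPCC = r(n+1 samples) - r(n samples)

measures how strongly that single sample disturbs the edge.  An
individual-specific network (ISMLN) is the set of catalog edges whose ΔPCC is
statistically significant for that sample.

Per-edge sufficient statistics (endpoint means, centered sums of squares and
the cross-deviation sum over the reference samples) are cached so that
perturbing one sample costs O(edges) instead of O(edges x samples), and the
incremental update is algebraically exact: it equals recomputation from
scratch up to floating-point round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, DegenerateDistributionError
from .io import ExpressionPanel, InteractionCatalog

GROUPS = ("tumor", "non_tumor")


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Returns NaN (the "undefined" flag) when either vector has zero variance.
    Sums are accumulated with compensated summation for reproducibility.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise DataError("pearson: vectors must be 1-D and of equal length")
    if x.size < 3:
        raise DataError("pearson: need at least 3 observations")
    mx = math.fsum(x) / x.size
    my = math.fsum(y) / y.size
    dx = x - mx
    dy = y - my
    sxx = math.fsum(dx * dx)
    syy = math.fsum(dy * dy)
    if sxx <= 0.0 or syy <= 0.0:
        return float("nan")
    r = math.fsum(dx * dy) / math.sqrt(sxx * syy)
    return float(min(1.0, max(-1.0, r)))


@dataclass
class ReferenceNetwork:
    """Per-edge correlations over the reference (non-tumor) samples.

    Carries the cached sufficient statistics needed for O(edges) single-sample
    perturbation: per-edge endpoint means (``mean_m``, ``mean_l``), centered
    sums of squares (``sxx``, ``syy``) and the cross-deviation sum (``sxy``),
    all over the ``n_ref`` reference samples, plus the raw endpoint expression
    of those samples (``xm``, ``xl``, edges x n_ref) for leave-one-out work.
    Edges with a zero-variance endpoint are flagged undefined (``defined`` is
    False and ``pcc`` is NaN); they are never silently imputed.
    """

    catalog: InteractionCatalog
    pcc: np.ndarray
    defined: np.ndarray
    n_ref: int
    ref_sample_ids: list[str]
    mean_m: np.ndarray
    mean_l: np.ndarray
    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    xm: np.ndarray
    xl: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.catalog)


@dataclass
class DeltaPccMatrix:
    """Edge x sample ΔPCC values for one phenotype group.

    ``delta = perturbed - ref_pcc`` wherever both are defined; entries for
    undefined edges are NaN with ``defined`` False, never silently zero.
    """

    delta: np.ndarray
    perturbed: np.ndarray
    defined: np.ndarray
    sample_ids: list[str]
    group: str
    n_ref: int
    ref_pcc: np.ndarray
    mirna_ids: np.ndarray
    lncrna_ids: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.delta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.delta.shape[1]

    def mean_abs_delta(self) -> np.ndarray:
        """Per-edge |mean ΔPCC| over defined entries (0 where none defined)."""
        with np.errstate(invalid="ignore"):
            m = np.nanmean(np.where(self.defined, self.delta, np.nan), axis=1)
        return np.abs(np.where(np.isfinite(m), m, 0.0))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.delta, columns=self.sample_ids)
        df.insert(0, "lncrna", self.lncrna_ids)
        df.insert(0, "mirna", self.mirna_ids)
        return df


@dataclass
class SignificanceCutoff:
    """Decision rule for calling a ΔPCC entry significant.

    ``pooled_normal`` fits one normal N(fitted_mean, fitted_sd^2) to every
    defined entry of the ΔPCC matrix and calls an entry significant when
    ``|ΔPCC - fitted_mean| >= cutoff_abs`` with
    ``cutoff_abs = z_{1-alpha/2} * fitted_sd`` — the symmetric two-sided
    cutoff whose tail mass equals alpha exactly.

    ``ssn_z`` uses the per-edge asymptotic statistic
    ``z = ΔPCC * (n_ref - 1) / (1 - r^2)`` referred to the standard normal;
    the implied threshold is then edge-specific (``per_edge_cutoff``).

    Ties (equality with the threshold) are significant.
    """

    alpha: float
    method: str
    cutoff_abs: float = 0.0
    fitted_mean: float = 0.0
    fitted_sd: float = 0.0
    per_edge_cutoff: np.ndarray | None = None
    n_entries: int = 0

    def significant(self, delta: np.ndarray, defined: np.ndarray) -> np.ndarray:
        """Boolean significance mask for a ΔPCC array (edges or edges x samples)."""
        delta = np.asarray(delta, dtype=float)
        defined = np.asarray(defined, dtype=bool)
        with np.errstate(invalid="ignore"):
            if self.method == "pooled_normal":
                hit = np.abs(delta - self.fitted_mean) >= self.cutoff_abs
            elif self.method == "ssn_z":
                thr = self.per_edge_cutoff
                if delta.ndim == 2:
                    thr = thr[:, None]
                hit = np.abs(delta) >= thr
            else:  # pragma: no cover - guarded at fit time
                raise DataError(f"unknown cutoff method {self.method!r}")
        return hit & defined


@dataclass
class Ismln:
    """One sample's individual-specific network: its significant catalog edges."""

    sample_id: str
    edge_indices: np.ndarray
    delta: np.ndarray

    def __len__(self) -> int:
        return len(self.edge_indices)


def build_reference(panel: ExpressionPanel, catalog: InteractionCatalog) -> ReferenceNetwork:
    """Compute one PCC per catalog edge over exactly the non-tumor samples."""
    controls = panel.control_samples
    if len(controls) < 3:
        raise DataError(f"need at least 3 non-tumor samples, found {len(controls)}")
    mi = panel.mirna.index.get_indexer(catalog.mirna_ids)
    li = panel.lncrna.index.get_indexer(catalog.lncrna_ids)
    if (mi < 0).any() or (li < 0).any():
        raise DataError("catalog references feature ids absent from the panel")

    Xm_all = panel.mirna[controls].to_numpy(dtype=float)
    Xl_all = panel.lncrna[controls].to_numpy(dtype=float)
    xm = Xm_all[mi]  # edges x n_ref
    xl = Xl_all[li]
    n = len(controls)
    mean_m = xm.mean(axis=1)
    mean_l = xl.mean(axis=1)
    dm = xm - mean_m[:, None]
    dl = xl - mean_l[:, None]
    sxx = np.einsum("ij,ij->i", dm, dm)
    syy = np.einsum("ij,ij->i", dl, dl)
    sxy = np.einsum("ij,ij->i", dm, dl)
    defined = (sxx > 0.0) & (syy > 0.0)
    pcc = np.full(len(catalog), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc[defined] = np.clip(sxy[defined] / np.sqrt(sxx[defined] * syy[defined]), -1.0, 1.0)
    return ReferenceNetwork(
        catalog=catalog,
        pcc=pcc,
        defined=defined,
        n_ref=n,
        ref_sample_ids=list(controls),
        mean_m=mean_m,
        mean_l=mean_l,
        sxx=sxx,
        syy=syy,
        sxy=sxy,
        xm=xm,
        xl=xl,
    )


def _perturbed_from_stats(ref: ReferenceNetwork, a: np.ndarray, b: np.ndarray):
    """Perturbed PCC over n_ref+1 samples from cached statistics.

    ``a``/``b`` are the appended sample's endpoint values per edge; both may
    be 1-D (one sample) or 2-D (edges x samples).  Returns (perturbed,
    defined) arrays of the same shape.
    """
    n = ref.n_ref
    f = n / (n + 1.0)
    if a.ndim == 1:
        dx = a - ref.mean_m
        dy = b - ref.mean_l
        sxx1 = ref.sxx + f * dx * dx
        syy1 = ref.syy + f * dy * dy
        sxy1 = ref.sxy + f * dx * dy
    else:
        dx = a - ref.mean_m[:, None]
        dy = b - ref.mean_l[:, None]
        sxx1 = ref.sxx[:, None] + f * dx * dx
        syy1 = ref.syy[:, None] + f * dy * dy
        sxy1 = ref.sxy[:, None] + f * dx * dy
    finite = np.isfinite(a) & np.isfinite(b)
    ref_def = ref.defined if a.ndim == 1 else ref.defined[:, None]
    defined = ref_def & finite & (sxx1 > 0.0) & (syy1 > 0.0)
    perturbed = np.full(sxx1.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.clip(sxy1 / np.sqrt(sxx1 * syy1), -1.0, 1.0)
    perturbed[defined] = val[defined]
    return perturbed, defined


def perturb(ref: ReferenceNetwork, sample_mirna, sample_lncrna):
    """ΔPCC column for one appended sample.

    ``sample_mirna`` / ``sample_lncrna`` are pandas Series indexed by feature
    id (or mappings).  A missing or non-finite endpoint value flags that edge
    as missing rather than raising.  Returns ``(delta, perturbed, defined)``.
    """
    import pandas as pd

    sm = pd.Series(sample_mirna, dtype=float)
    sl = pd.Series(sample_lncrna, dtype=float)
    a = sm.reindex(ref.catalog.mirna_ids).to_numpy(dtype=float)
    b = sl.reindex(ref.catalog.lncrna_ids).to_numpy(dtype=float)
    perturbed, defined = _perturbed_from_stats(ref, a, b)
    delta = np.where(defined, perturbed - ref.pcc, np.nan)
    return delta, perturbed, defined


def delta_matrix(
    ref: ReferenceNetwork,
    panel: ExpressionPanel,
    group: str,
    control_mode: str = "loo",
) -> DeltaPccMatrix:
    """ΔPCC matrix (edges x samples) for one phenotype group.

    Tumor samples are appended to the full reference, the method's defining
    construction.  Control samples already sit inside the reference, so by
    default each control column is computed leave-one-out: the sample is
    removed (n_ref - 1 controls form the reference) and then appended back as
    the perturbing sample, giving control columns the same (n+1 vs n)
    structure as tumor columns.  ``control_mode="reappend"`` instead naively
    re-appends the control to the full reference (duplicating it).
    """
    if group not in GROUPS:
        raise DataError(f"group must be one of {GROUPS}")
    samples = panel.tumor_samples if group == "tumor" else panel.control_samples
    if not samples:
        raise DataError(f"no samples in group {group!r}")

    if group == "tumor" or control_mode == "reappend":
        mi = panel.mirna.index.get_indexer(ref.catalog.mirna_ids)
        li = panel.lncrna.index.get_indexer(ref.catalog.lncrna_ids)
        A = panel.mirna[samples].to_numpy(dtype=float)[mi]
        B = panel.lncrna[samples].to_numpy(dtype=float)[li]
        perturbed, defined = _perturbed_from_stats(ref, A, B)
        delta = np.where(defined, perturbed - ref.pcc[:, None], np.nan)
    elif control_mode == "loo":
        if samples != ref.ref_sample_ids:
            raise DataError("leave-one-out requires the reference's own control samples")
        n = ref.n_ref
        if n < 4:
            raise DataError("leave-one-out needs at least 4 reference samples")
        g = n / (n - 1.0)
        dx = ref.xm - ref.mean_m[:, None]  # edges x n_ref
        dy = ref.xl - ref.mean_l[:, None]
        sxx_m = np.maximum(ref.sxx[:, None] - g * dx * dx, 0.0)
        syy_m = np.maximum(ref.syy[:, None] - g * dy * dy, 0.0)
        sxy_m = ref.sxy[:, None] - g * dx * dy
        defined = ref.defined[:, None] & (sxx_m > 0.0) & (syy_m > 0.0)
        pcc_minus = np.full(sxx_m.shape, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.clip(sxy_m / np.sqrt(sxx_m * syy_m), -1.0, 1.0)
        pcc_minus[defined] = val[defined]
        # appending the sample back restores the full n-sample statistics,
        # so the perturbed correlation is exactly the full-reference PCC
        perturbed = np.where(defined, ref.pcc[:, None], np.nan)
        delta = np.where(defined, ref.pcc[:, None] - pcc_minus, np.nan)
    else:
        raise DataError(f"unknown control_mode {control_mode!r}")

    return DeltaPccMatrix(
        delta=delta,
        perturbed=perturbed,
        defined=defined,
        sample_ids=list(samples),
        group=group,
        n_ref=ref.n_ref,
        ref_pcc=ref.pcc.copy(),
        mirna_ids=ref.catalog.mirna_ids.copy(),
        lncrna_ids=ref.catalog.lncrna_ids.copy(),
    )


def fit_cutoff(
    delta: DeltaPccMatrix,
    alpha: float = 0.05,
    method: str = "pooled_normal",
    ref: ReferenceNetwork | None = None,
) -> SignificanceCutoff:
    """Fit the significance cutoff for ΔPCC entries.

    ``pooled_normal`` (default): a single normal is fitted by sample mean and
    standard deviation to all defined entries; the two-sided cutoff is the
    exact alpha-quantile of that fitted normal, i.e. ``z_{1-alpha/2} * sd``.
    ``ssn_z``: the per-edge asymptotic z-statistic; requires ``ref`` for the
    reference correlations and sample count.
    """
    if not (0.0 < alpha < 1.0):
        raise DataError(f"alpha must be in (0, 1), got {alpha}")
    zcrit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    if method == "pooled_normal":
        vals = delta.delta[delta.defined]
        if vals.size < 100:
            raise DataError(
                f"pooled_normal needs >= 100 defined ΔPCC entries, found {vals.size}"
            )
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if sd == 0.0:
            raise DegenerateDistributionError("ΔPCC matrix has zero spread")
        return SignificanceCutoff(
            alpha=alpha,
            method=method,
            cutoff_abs=zcrit * sd,
            fitted_mean=mean,
            fitted_sd=sd,
            n_entries=int(vals.size),
        )
    if method == "ssn_z":
        if ref is None:
            raise DataError("ssn_z requires the reference network")
        with np.errstate(invalid="ignore", divide="ignore"):
            per_edge = zcrit * (1.0 - ref.pcc**2) / (ref.n_ref - 1.0)
        return SignificanceCutoff(
            alpha=alpha,
            method=method,
            per_edge_cutoff=per_edge,
            n_entries=int(delta.defined.sum()),
        )
    raise DataError(f"unknown cutoff method {method!r}")


def significant_matrix(delta: DeltaPccMatrix, cutoff: SignificanceCutoff) -> np.ndarray:
    """Edges x samples boolean mask of significant, defined entries."""
    return cutoff.significant(delta.delta, delta.defined)


def extract_ismln(
    delta: DeltaPccMatrix, cutoff: SignificanceCutoff, sample_id: str
) -> Ismln:
    """The individual-specific network of one sample column."""
    j = delta.sample_ids.index(sample_id)
    col = delta.delta[:, j]
    hit = cutoff.significant(col, delta.defined[:, j])
    idx = np.flatnonzero(hit)
    return Ismln(sample_id=sample_id, edge_indices=idx, delta=col[idx])


def extract_all(delta: DeltaPccMatrix, cutoff: SignificanceCutoff) -> list[Ismln]:
    """One ISMLN per sample column, in column order."""
    sig = significant_matrix(delta, cutoff)
    out = []
    for j, sid in enumerate(delta.sample_ids):
        idx = np.flatnonzero(sig[:, j])
        out.append(Ismln(sample_id=sid, edge_indices=idx, delta=delta.delta[idx, j]))
    return out
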