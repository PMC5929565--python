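"""Edge-biomarker ranking, cross-validated evaluation and activity scores.

Candidate edges are evaluated as classification features: each sample (tumor
and non-tumor alike) contributes its ΔPCC value on every candidate edge, and
a random-forest classifier separates tumor from non-tumor rows.  Impurity
feature importance ranks the candidates; stratified k-fold cross-validation
with pooled out-of-fold probabilities yields one ROC curve and its
trapezoidal AUC (AUC 0.5 is the random-classifier reference).

The per-miRNA activity score aggregates an miRNA's candidate edges:

    activity(miRNA_i) = (sum of its candidate edges' significance scores)
                        * C1 / C2

where C1 is the miRNA's frequency among candidate pairs and C2 its frequency
in the full catalog, down-weighting miRNAs that are promiscuous in the
catalog but rarely perturbed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .bmln import CandidateSet
from .errors import DataError
from .io import ExpressionPanel, InteractionCatalog
from .network import DeltaPccMatrix

logger = logging.getLogger(__name__)


def _edge_label(mirna: str, lncrna: str) -> str:
    return f"{mirna}|{lncrna}"


@dataclass
class FeatureTable:
    """Samples x features design matrix with binary phenotype labels.

    ``X`` rows are samples (tumor then non-tumor, in ΔPCC column order),
    columns are candidate edges labelled ``"miRNA|lncRNA"``; ``y`` is 1 for
    tumor.  ``n_imputed`` counts flagged-missing ΔPCC entries imputed as 0
    (a missing edge reads as "no detectable perturbation").
    """

    X: pd.DataFrame
    y: pd.Series
    n_imputed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.X)


def build_features(
    delta_tumor: DeltaPccMatrix,
    delta_control: DeltaPccMatrix,
    candidates: CandidateSet,
) -> FeatureTable:
    """Assemble the ΔPCC design matrix over all tumor and control samples."""
    if len(candidates) == 0:
        raise DataError("cannot build features from an empty candidate set")
    if delta_tumor.n_edges != delta_control.n_edges:
        raise DataError("tumor and control ΔPCC matrices disagree on edges")
    pair_to_row = {
        (m, l): i
        for i, (m, l) in enumerate(zip(delta_tumor.mirna_ids, delta_tumor.lncrna_ids))
    }
    rows = []
    for m, l in candidates.pairs():
        if (m, l) not in pair_to_row:
            raise DataError(f"candidate edge ({m}, {l}) missing from ΔPCC matrices")
        rows.append(pair_to_row[(m, l)])
    rows = np.asarray(rows, dtype=int)

    blocks = []
    n_imputed = 0
    for dm in (delta_tumor, delta_control):
        vals = dm.delta[rows].T.copy()  # samples x features
        missing = ~dm.defined[rows].T
        n_imputed += int(missing.sum())
        vals[missing] = 0.0
        blocks.append(vals)
    if n_imputed:
        logger.info("build_features: imputed %d missing ΔPCC entries as 0", n_imputed)
    columns = [_edge_label(m, l) for m, l in candidates.pairs()]
    index = list(delta_tumor.sample_ids) + list(delta_control.sample_ids)
    X = pd.DataFrame(np.vstack(blocks), index=index, columns=columns)
    y = pd.Series(
        [1] * delta_tumor.n_samples + [0] * delta_control.n_samples,
        index=index,
        name="label",
    )
    return FeatureTable(X=X, y=y, n_imputed=n_imputed)


def node_feature_table(panel: ExpressionPanel, rnas: list[str]) -> FeatureTable:
    """Expression-value (node biomarker) design matrix for the same samples.

    The node-biomarker baseline: instead of an edge's ΔPCC, each feature is a
    single RNA's expression level.
    """
    cols = {}
    for r in rnas:
        if r in panel.mirna.index:
            cols[r] = panel.mirna.loc[r]
        elif r in panel.lncrna.index:
            cols[r] = panel.lncrna.loc[r]
        else:
            raise DataError(f"RNA id {r!r} absent from panel")
    X = pd.DataFrame(cols)
    y = pd.Series(
        (panel.phenotype.loc[X.index] == "tumor").astype(int), index=X.index, name="label"
    )
    return FeatureTable(X=X, y=y)


def _check_two_classes(y: pd.Series) -> None:
    if y.nunique() < 2:
        raise DataError("labels contain a single class; need tumor and non_tumor rows")


def rank_by_importance(
    features: FeatureTable, seed: int = 17, n_trees: int = 500
) -> pd.DataFrame:
    """Rank features by random-forest impurity importance (descending).

    Deterministic for a fixed seed and input.  Ties break by column order,
    which for candidate features is the BMLN candidate ordering.  Returns a
    table with columns ``(feature, importance, rank)`` sorted by rank.
    """
    _check_two_classes(features.y)
    if min((features.y == 0).sum(), (features.y == 1).sum()) < 2:
        raise DataError("need at least 2 samples per class")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(features.X.to_numpy(), features.y.to_numpy())
    imp = clf.feature_importances_
    order = np.lexsort((np.arange(len(imp)), -imp))
    out = pd.DataFrame(
        {
            "feature": features.X.columns.to_numpy()[order],
            "importance": imp[order],
            "rank": np.arange(1, len(imp) + 1),
        }
    )
    return out


@dataclass
class EvaluationReport:
    """Pooled out-of-fold ROC evaluation of one feature subset."""

    features: list[str]
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    oof_scores: pd.Series
    folds: int
    seed: int


def cv_auc(
    features: FeatureTable,
    subset: list[str] | None = None,
    folds: int = 10,
    seed: int = 17,
    n_trees: int = 500,
    estimator_factory=None,
) -> EvaluationReport:
    """Stratified k-fold cross-validated ROC/AUC for a feature subset.

    Out-of-fold class-1 probabilities from every fold are pooled into a
    single ROC curve; the AUC is its trapezoidal area.  The classifier
    backend defaults to the random forest but is pluggable via
    ``estimator_factory`` (a zero-argument callable returning an unfitted
    scikit-learn classifier).
    """
    _check_two_classes(features.y)
    if folds < 2:
        raise DataError("folds must be >= 2")
    cols = list(features.X.columns) if subset is None else list(subset)
    if not cols:
        raise DataError("empty feature subset")
    missing = [c for c in cols if c not in features.X.columns]
    if missing:
        raise DataError(f"unknown features {missing[:3]}")
    X = features.X[cols].to_numpy()
    y = features.y.to_numpy()
    if min(np.bincount(y)) < folds:
        raise DataError(
            f"a class has fewer samples than folds={folds}; lower the fold count"
        )
    if estimator_factory is None:
        def estimator_factory():
            return RandomForestClassifier(
                n_estimators=n_trees, random_state=seed, n_jobs=1
            )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    for train, test in skf.split(X, y):
        clf = estimator_factory()
        clf.fit(X[train], y[train])
        oof[test] = clf.predict_proba(X[test])[:, 1]
    fpr, tpr, _ = roc_curve(y, oof)
    auc = float(np.trapezoid(tpr, fpr))
    return EvaluationReport(
        features=cols,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        oof_scores=pd.Series(oof, index=features.X.index, name="score"),
        folds=folds,
        seed=seed,
    )


def nested_de_cv_auc(
    panel: ExpressionPanel,
    top_n: int = 5,
    folds: int = 10,
    seed: int = 17,
    n_trees: int = 500,
) -> EvaluationReport:
    """Node-biomarker baseline: cross-validated AUC of top DE expression features.

    For each fold the ``top_n`` RNAs are re-selected by Wilcoxon rank-sum
    p-value on the training rows only, then a random forest fitted on those
    training rows scores the held-out rows; out-of-fold probabilities are
    pooled into one ROC.  Selecting the features inside each training fold is
    essential here: ranking thousands of expression features on the full data
    and then cross-validating the winners measures the selection's winner's
    curse, not the information the features carry.
    """
    X = pd.concat([panel.mirna, panel.lncrna]).T  # samples x features
    y = (panel.phenotype.loc[X.index] == "tumor").astype(int).to_numpy()
    if y.min() == y.max():
        raise DataError("labels contain a single class")
    if min(np.bincount(y)) < folds:
        raise DataError(f"a class has fewer samples than folds={folds}")
    Xv = X.to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    chosen: list[str] = []
    for train, test in skf.split(Xv, y):
        t = Xv[train][y[train] == 1]
        c = Xv[train][y[train] == 0]
        with np.errstate(invalid="ignore"):
            p = stats.mannwhitneyu(t, c, alternative="two-sided", axis=0).pvalue
        p = np.where(np.isfinite(p), p, 1.0)
        top = np.lexsort((np.arange(len(p)), p))[:top_n]
        chosen.extend(X.columns[top])
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        clf.fit(Xv[train][:, top], y[train])
        oof[test] = clf.predict_proba(Xv[test][:, top])[:, 1]
    fpr, tpr, _ = roc_curve(y, oof)
    return EvaluationReport(
        features=sorted(set(chosen)),
        fpr=fpr,
        tpr=tpr,
        auc=float(np.trapezoid(tpr, fpr)),
        oof_scores=pd.Series(oof, index=X.index, name="score"),
        folds=folds,
        seed=seed,
    )


def activity_scores(
    candidates: CandidateSet,
    scores: pd.DataFrame,
    catalog: InteractionCatalog,
) -> pd.DataFrame:
    """Per-miRNA activity scores over the candidate edges.

    Every catalog miRNA gets a row; miRNAs absent from the candidate set have
    activity 0.  Columns: ``(mirna, activity, c1, c2, k_terms)``, sorted by
    descending activity then catalog first-appearance order.
    """
    c2 = pd.Series(catalog.mirna_ids).value_counts()
    score_lookup = dict(zip(zip(scores["mirna"], scores["lncrna"]), scores["score"]))

    sums: dict[str, float] = {}
    c1: dict[str, int] = {}
    for m, l in candidates.pairs():
        if (m, l) not in score_lookup:
            raise DataError(f"candidate edge ({m}, {l}) missing from the score table")
        sums[m] = sums.get(m, 0.0) + float(score_lookup[(m, l)])
        c1[m] = c1.get(m, 0) + 1

    mirnas: list[str] = []
    seen = set()
    for m in catalog.mirna_ids:
        if m not in seen:
            seen.add(m)
            mirnas.append(m)
    rows = []
    for m in mirnas:
        k = c1.get(m, 0)
        n2 = int(c2.get(m, 0))
        if k > 0 and n2 == 0:
            raise DataError(f"miRNA {m!r} has candidate pairs but no catalog pairs")
        activity = sums.get(m, 0.0) * (k / n2) if k > 0 else 0.0
        rows.append((m, activity, k, n2, k))
    out = pd.DataFrame(rows, columns=["mirna", "activity", "c1", "c2", "k_terms"])
    order = np.lexsort((np.arange(len(out)), -out["activity"].to_numpy()))
    return out.iloc[order].reset_index(drop=True)


def de_baseline(
    panel: ExpressionPanel,
    rnas: list[str],
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential-expression baseline for node biomarkers.

    Per RNA: log2 fold change of tumor vs non-tumor group means (pseudocount
    1), two-sided Wilcoxon rank-sum p-value, Benjamini-Hochberg adjustment,
    and a status call — ``up``/``down`` when |lfc| > ``lfc_threshold`` and
    adjusted p < ``p_threshold``, else ``not_de``.
    """
    tumor = panel.tumor_samples
    control = panel.control_samples
    if not tumor or not control:
        raise DataError("both phenotype groups must be nonempty")
    rows = []
    for r in rnas:
        if r in panel.mirna.index:
            vals = panel.mirna.loc[r]
        elif r in panel.lncrna.index:
            vals = panel.lncrna.loc[r]
        else:
            raise DataError(f"RNA id {r!r} absent from panel")
        t = vals[tumor].to_numpy(dtype=float)
        c = vals[control].to_numpy(dtype=float)
        lfc = float(np.log2((t.mean() + 1.0) / (c.mean() + 1.0)))
        both = np.concatenate([t, c])
        if np.ptp(both) == 0.0:  # complete ties: the rank-sum test is vacuous
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(t, c, alternative="two-sided").pvalue)
        rows.append((r, lfc, p))
    out = pd.DataFrame(rows, columns=["rna", "log2fc", "pvalue"])
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    sig = (out["log2fc"].abs() > lfc_threshold) & (out["padj"] < p_threshold)
    out["status"] = np.where(
        sig, np.where(out["log2fc"] > 0, "up", "down"), "not_de"
    )
    return out
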