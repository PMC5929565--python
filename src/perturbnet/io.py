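"""Readers and writers for expression panels, interaction catalogs and result tables.

All inputs are delimited text.  Expression matrices are features x samples with
a header row of sample identifiers and a first column of feature identifiers;
the phenotype table maps sample id to ``tumor`` / ``non_tumor``; the
interaction catalog is a two-column (miRNA id, lncRNA id) edge list with an
optional third provenance column.  The default dialect is tab-separated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

PHENOTYPE_LABELS = ("tumor", "non_tumor")


@dataclass(frozen=True)
class AliasMap:
    """Raw-to-canonical identifier maps, one namespace per RNA class.

    Each map must be a function (no raw id maps to two canonical ids — a dict
    enforces this) and idempotent: a canonical id that itself appears as a key
    must map to itself, so that applying the map twice equals applying it once.
    """

    mirna: Mapping[str, str] = field(default_factory=dict)
    lncrna: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mapping in (("mirna", self.mirna), ("lncrna", self.lncrna)):
            for raw, canonical in mapping.items():
                if mapping.get(canonical, canonical) != canonical:
                    raise DataError(
                        f"alias map ({name}) is not idempotent: "
                        f"{raw!r} -> {canonical!r} -> {mapping[canonical]!r}"
                    )

    def apply_mirna(self, ids: Sequence[str]) -> list[str]:
        return [self.mirna.get(i, i) for i in ids]

    def apply_lncrna(self, ids: Sequence[str]) -> list[str]:
        return [self.lncrna.get(i, i) for i in ids]


@dataclass
class LoadReport:
    """Counts of what was dropped while aligning the inputs."""

    n_samples: int = 0
    n_samples_dropped_mirna: int = 0
    n_samples_dropped_lncrna: int = 0
    n_samples_dropped_phenotype: int = 0
    n_mirnas: int = 0
    n_lncrnas: int = 0


@dataclass
class ExpressionPanel:
    """Paired miRNA / lncRNA expression matrices with phenotype labels.

    Both matrices are features x samples with identical, identically ordered
    sample columns; every sample has a phenotype label in
    ``{"tumor", "non_tumor"}``.
    """

    mirna: pd.DataFrame
    lncrna: pd.DataFrame
    phenotype: pd.Series
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if list(self.mirna.columns) != list(self.lncrna.columns):
            raise DataError("miRNA and lncRNA matrices have different sample columns")
        if self.mirna.index.duplicated().any():
            raise DataError("duplicate miRNA feature id in panel")
        if self.lncrna.index.duplicated().any():
            raise DataError("duplicate lncRNA feature id in panel")
        missing = [s for s in self.mirna.columns if s not in self.phenotype.index]
        if missing:
            raise DataError(f"samples without phenotype label: {missing[:5]}")
        bad = set(self.phenotype.loc[list(self.mirna.columns)]) - set(PHENOTYPE_LABELS)
        if bad:
            raise DataError(f"unknown phenotype labels {sorted(bad)}; expected {PHENOTYPE_LABELS}")
        for name, m in (("miRNA", self.mirna), ("lncRNA", self.lncrna)):
            if not np.isfinite(m.to_numpy(dtype=float)).all():
                raise DataError(f"non-finite values in {name} matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mirna.columns)

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.phenotype[s] == "non_tumor"]

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.phenotype[s] == "tumor"]


@dataclass
class InteractionCatalog:
    """The fixed universe of candidate miRNA-lncRNA edges.

    ``edges`` keeps the stable order of first occurrence in the source file;
    every pair is unique after canonicalization and references feature ids
    present in the panel it was read against.
    """

    edges: pd.DataFrame  # columns: mirna, lncrna [, source]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.edges.duplicated(subset=["mirna", "lncrna"]).any():
            raise DataError("duplicate edge in interaction catalog")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def mirna_ids(self) -> np.ndarray:
        return self.edges["mirna"].to_numpy(dtype=object)

    @property
    def lncrna_ids(self) -> np.ndarray:
        return self.edges["lncrna"].to_numpy(dtype=object)

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["mirna"], self.edges["lncrna"]))


def _read_matrix(path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise DataError(
                f"{path}: non-numeric or missing value at row {row!r}, column {col!r}"
            )
        out[col] = coerced.to_numpy(dtype=float)
    if not np.isfinite(out.to_numpy()).all():
        raise DataError(f"{path}: non-finite expression value")
    return out


def read_panel(
    mirna_path,
    lncrna_path,
    phenotype_path,
    alias: AliasMap | None = None,
    sep: str = "\t",
    log2_transform: bool = False,
) -> ExpressionPanel:
    """Read and align the two expression matrices and the phenotype table.

    Only samples present in *both* matrices and the phenotype table are
    retained (intersection rule), preserving the miRNA matrix column order.
    Row identifiers are canonicalized through ``alias`` when given; a
    collision of two raw ids onto one canonical id is fatal.  Expression
    values are used as provided unless ``log2_transform`` applies
    ``log2(x + 1)``.
    """
    mirna = _read_matrix(mirna_path, sep)
    lncrna = _read_matrix(lncrna_path, sep)
    pheno_df = pd.read_csv(phenotype_path, sep=sep, header=None, dtype=str, comment="#")
    if pheno_df.shape[1] < 2:
        raise DataError(f"{phenotype_path}: expected two columns (sample id, label)")
    # tolerate an optional header line
    if pheno_df.iloc[0, 1] not in PHENOTYPE_LABELS:
        pheno_df = pheno_df.iloc[1:]
    phenotype = pd.Series(
        pheno_df.iloc[:, 1].to_numpy(), index=pheno_df.iloc[:, 0].to_numpy(), dtype=object
    )
    if phenotype.index.duplicated().any():
        raise DataError(f"{phenotype_path}: duplicate sample id")

    if alias is not None:
        for name, df_, fn in (
            ("miRNA", mirna, alias.apply_mirna),
            ("lncRNA", lncrna, alias.apply_lncrna),
        ):
            new_index = pd.Index(fn(list(df_.index)))
            if new_index.duplicated().any():
                dup = new_index[new_index.duplicated()][0]
                raise DataError(f"duplicate {name} feature id after aliasing: {dup!r}")
            df_.index = new_index

    shared = [
        s for s in mirna.columns if s in set(lncrna.columns) and s in set(phenotype.index)
    ]
    if not shared:
        raise DataError("no sample is present in both matrices and the phenotype table")
    report = LoadReport(
        n_samples=len(shared),
        n_samples_dropped_mirna=mirna.shape[1] - len(shared),
        n_samples_dropped_lncrna=lncrna.shape[1] - len(shared),
        n_samples_dropped_phenotype=len(phenotype) - len(shared),
        n_mirnas=mirna.shape[0],
        n_lncrnas=lncrna.shape[0],
    )
    logger.info(
        "panel: %d shared samples (%d/%d/%d dropped from miRNA/lncRNA/phenotype)",
        report.n_samples,
        report.n_samples_dropped_mirna,
        report.n_samples_dropped_lncrna,
        report.n_samples_dropped_phenotype,
    )
    mirna = mirna[shared]
    lncrna = lncrna[shared]
    if log2_transform:
        mirna = np.log2(mirna + 1.0)
        lncrna = np.log2(lncrna + 1.0)
    return ExpressionPanel(
        mirna=mirna,
        lncrna=lncrna,
        phenotype=phenotype.loc[shared],
        load_report=report,
    )


def read_edge_list(path, sep: str = "\t") -> pd.DataFrame:
    """Read a raw 2- or 3-column edge list (miRNA, lncRNA [, source])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise DataError(f"{path}: malformed edge at line {lineno}: {line!r}")
            rows.append((parts[0], parts[1], parts[2] if len(parts) > 2 else ""))
    if rows and rows[0][:2] == ("mirna", "lncrna"):  # optional header
        rows = rows[1:]
    return pd.DataFrame(rows, columns=["mirna", "lncrna", "source"])


def read_catalog(
    path,
    panel: ExpressionPanel,
    alias: AliasMap | None = None,
    sep: str = "\t",
) -> InteractionCatalog:
    """Read the interaction catalog and restrict it to the panel's features.

    Pairs are deduplicated after aliasing, keeping the first occurrence;
    pairs whose miRNA or lncRNA is not measured in the panel are dropped and
    counted rather than treated as errors, because public catalogs routinely
    exceed the measured feature set.  Zero surviving edges is fatal.
    """
    df = read_edge_list(path, sep=sep)
    return make_catalog(
        df["mirna"], df["lncrna"], panel=panel, alias=alias, sources=df["source"]
    )


def make_catalog(
    mirnas: Sequence[str],
    lncrnas: Sequence[str],
    panel: ExpressionPanel | None = None,
    alias: AliasMap | None = None,
    sources: Sequence[str] | None = None,
) -> InteractionCatalog:
    """Build a catalog from parallel id sequences (programmatic entry point)."""
    mirnas = list(mirnas)
    lncrnas = list(lncrnas)
    if alias is not None:
        mirnas = alias.apply_mirna(mirnas)
        lncrnas = alias.apply_lncrna(lncrnas)
    df = pd.DataFrame({"mirna": mirnas, "lncrna": lncrnas})
    if sources is not None:
        df["source"] = list(sources)
    n_raw_unique = (~df.duplicated(subset=["mirna", "lncrna"])).sum()
    df = df.drop_duplicates(subset=["mirna", "lncrna"], keep="first")
    n_dropped = 0
    if panel is not None:
        keep = df["mirna"].isin(panel.mirna.index) & df["lncrna"].isin(panel.lncrna.index)
        n_dropped = int((~keep).sum())
        df = df[keep]
    if df.empty:
        raise DataError("no catalog edge references features present in the panel")
    assert n_dropped + len(df) == n_raw_unique
    logger.info("catalog: %d edges retained, %d dropped (missing features)", len(df), n_dropped)
    return InteractionCatalog(edges=df.reset_index(drop=True), n_dropped=n_dropped)


def write_table(table: pd.DataFrame, path, sep: str = "\t", index: bool = False) -> None:
    """Write a result table as delimited text.

    Floats are rendered with 17 significant digits (full double precision) so that a write/read round
    trip is lossless at the tolerances used throughout the package.  Writing
    an empty table is an error.
    """
    if len(table) == 0:
        raise DataError(f"refusing to write empty table to {path}")
    table.to_csv(path, sep=sep, index=index, float_format="%.17g")


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_panel(panel: ExpressionPanel, outdir, sep: str = "\t") -> dict[str, str]:
    """Write a panel as the three canonical input files; returns the paths."""
    import os

    paths = {
        "mirna": os.path.join(outdir, "mirna.tsv"),
        "lncrna": os.path.join(outdir, "lncrna.tsv"),
        "phenotype": os.path.join(outdir, "phenotype.tsv"),
    }
    panel.mirna.to_csv(paths["mirna"], sep=sep, index=True, float_format="%.17g")
    panel.lncrna.to_csv(paths["lncrna"], sep=sep, index=True, float_format="%.17g")
    panel.phenotype.to_frame().to_csv(paths["phenotype"], sep=sep, header=False)
    return paths


def write_catalog(catalog: InteractionCatalog, path, sep: str = "\t") -> None:
    cols = ["mirna", "lncrna"] + (["source"] if "source" in catalog.edges else [])
    catalog.edges[cols].to_csv(path, sep=sep, index=False, header=False)


def read_alias_map(mirna_path=None, lncrna_path=None, sep: str = "\t") -> AliasMap:
    """Read raw->canonical maps from 2-column files (either may be omitted)."""

    def load(path) -> dict[str, str]:
        if path is None:
            return {}
        df = pd.read_csv(path, sep=sep, header=None, dtype=str)
        if df.shape[1] < 2:
            raise DataError(f"{path}: expected two columns (raw id, canonical id)")
        df = df.drop_duplicates()
        pairs = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if len(pairs) < len(df):
            dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()].iloc[0]
            raise DataError(f"{path}: raw id {dup!r} maps to more than one canonical id")
        return pairs

    return AliasMap(mirna=load(mirna_path), lncrna=load(lncrna_path))
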