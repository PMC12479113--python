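"""Readers and writers for every external table the pipeline touches.

All tables are plain TSV (with header) or BED3+ (tab/whitespace separated, no
header).  Readers validate strictly and never coerce silently: every dropped
row is enumerated in a :class:`LoadReport`, and structural problems (missing
columns, duplicate keys, malformed coordinates) raise :class:`FormatError`.

Coordinate conventions
----------------------
Genomic intervals are stored 0-based half-open throughout.  SNP positions are
published 1-based; on ingest they become the 1-bp interval ``[pos-1, pos)``.
Deposit dates are normalized to ISO 8601 and binned by calendar year.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# canonical column names; a per-source mapping may rename them (ChIP-Atlas,
# GTRD and ReMap metadata headers all differ)
EXPERIMENT_COLUMNS = ("experiment_id", "antigen", "cell_type",
                      "cell_type_class", "deposit_date")


@dataclass(frozen=True)
class ExperimentRecord:
    """One ChIP-seq experiment: the atom whose distribution is audited."""

    experiment_id: str
    antigen: str
    cell_type: str
    cell_type_class: str
    deposit_date: datetime.date


@dataclass
class LoadReport:
    """Accounting of a table load: kept + dropped = input rows."""

    n_input: int = 0
    n_kept: int = 0
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "key", "reason"]))
    conflicts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def to_frame(self) -> pd.DataFrame:
        return self.dropped.copy()

    def write(self, path) -> None:
        self.dropped.to_csv(path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


# ---------------------------------------------------------------------------
# experiment metadata
# ---------------------------------------------------------------------------

def read_experiment_table(path, columns: Mapping[str, str] | None = None,
                          min_year: int = 1990, max_year: int = 2035,
                          ) -> tuple[pd.DataFrame, LoadReport]:
    """Read a ChIP-seq experiment metadata table (experimentList.tab style).

    Parameters
    ----------
    path : str or Path
        TSV with header.
    columns : mapping, optional
        Maps canonical names (``experiment_id``, ``antigen``, ``cell_type``,
        ``cell_type_class``, ``deposit_date``) to the file's column names.
    min_year, max_year : int
        Deposit dates outside this inclusive window are dropped and reported.

    Returns
    -------
    (DataFrame, LoadReport)
        Canonical columns with ``deposit_date`` as datetime64.  Rows with
        unparseable or out-of-range dates, or empty antigen/cell_type, are
        dropped and listed in the report.  Duplicate experiment IDs among the
        kept rows are fatal.
    """
    colmap = {c: c for c in EXPERIMENT_COLUMNS}
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(raw, list(colmap.values()), path)
    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    report = LoadReport(n_input=len(df))

    drops: list[tuple[int, str, str]] = []
    dates = pd.to_datetime(df["deposit_date"], errors="coerce", format="mixed")
    for i in df.index[dates.isna()]:
        drops.append((int(i), df.at[i, "experiment_id"], "unparseable date"))
    year = dates.dt.year
    bad_year = dates.notna() & ((year < min_year) | (year > max_year))
    for i in df.index[bad_year]:
        drops.append((int(i), df.at[i, "experiment_id"],
                      f"year outside [{min_year}, {max_year}]"))
    empty = (df["antigen"].str.strip() == "") | (df["cell_type"].str.strip() == "")
    for i in df.index[empty & dates.notna() & ~bad_year]:
        drops.append((int(i), df.at[i, "experiment_id"],
                      "empty antigen or cell_type"))

    bad_rows = {r for r, _, _ in drops}
    keep = df.index.difference(sorted(bad_rows))
    out = df.loc[keep].copy()
    out["deposit_date"] = dates.loc[keep]

    dup = out["experiment_id"][out["experiment_id"].duplicated(keep=False)]
    if len(dup):
        raise FormatError(
            f"{path}: duplicate experiment_id(s): {sorted(dup.unique())}")

    # conflicting cell_type -> class assignments are surfaced, not resolved
    cls = out.groupby("cell_type")["cell_type_class"].nunique()
    conflicted = cls.index[cls > 1]
    if len(conflicted):
        report.conflicts = (out[out["cell_type"].isin(conflicted)]
                            [["cell_type", "cell_type_class"]]
                            .drop_duplicates().reset_index(drop=True))

    report.n_kept = len(out)
    report.dropped = pd.DataFrame(drops, columns=["row", "key", "reason"])
    return out.reset_index(drop=True), report


def write_experiment_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["deposit_date"] = pd.to_datetime(out["deposit_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep="\t", index=False)


def experiment_records(df: pd.DataFrame) -> list[ExperimentRecord]:
    """Materialize a metadata frame as typed records."""
    return [ExperimentRecord(r.experiment_id, r.antigen, r.cell_type,
                             r.cell_type_class,
                             pd.Timestamp(r.deposit_date).date())
            for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into columns chrom/start/end/name (input order kept).

    Coordinates are 0-based half-open as in the BED standard.  A non-integer
    coordinate or ``start >= end`` is fatal, with the offending line number.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 "
                                  f"columns, got {len(fields)}")
            chrom = fields[0]
            if not chrom:
                raise FormatError(f"{path}: line {lineno}: empty chrom")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer "
                                  f"coordinate in {fields[1:3]}") from None
            if start < 0 or start >= end:
                raise FormatError(f"{path}: line {lineno}: invalid interval "
                                  f"[{start}, {end}) (need 0 <= start < end)")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            names.append(fields[3] if len(fields) > 3 else "")
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends,
                         "name": names})


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"]
    out = df[cols].copy()
    if "name" in df.columns:
        out["name"] = df["name"]
    elif "gene" in df.columns:
        out["name"] = df["gene"]
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(path, layout: str = "wide",
                           gene_col: str = "gene",
                           sample_col: str = "cell_line",
                           value_col: str = "value") -> pd.DataFrame:
    """Read a gene x cell-line expression matrix (nTPM-like, nonnegative).

    ``layout="wide"``: first column is the gene symbol, remaining columns are
    cell lines.  ``layout="long"``: one row per (gene, cell line, value).
    Missing entries stay NaN (absent, not zero).  Any negative or non-finite
    value is fatal.
    """
    if layout == "wide":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.astype(float)
    elif layout == "long":
        long = pd.read_csv(path, sep="\t")
        _require_columns(long, [gene_col, sample_col, value_col], path)
        df = long.pivot(index=gene_col, columns=sample_col, values=value_col)
        df = df.astype(float)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    vals = df.to_numpy()
    finite = vals[np.isfinite(vals)]
    if np.isinf(vals).any():
        raise FormatError(f"{path}: non-finite expression value")
    if (finite < 0).any():
        raise FormatError(f"{path}: negative expression value")
    df.index.name = "gene"
    df.columns.name = "cell_line"
    return df


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# SNPs, DEG counts, markers, ontology map
# ---------------------------------------------------------------------------

def read_snp_table(path, columns: Mapping[str, str] | None = None,
                   ) -> tuple[pd.DataFrame, LoadReport]:
    """Read a GWAS SNP table (rsid, chrom, 1-based pos).

    Duplicate rsIDs are de-duplicated keeping the first occurrence (the
    audit counts *unique* rs numbers); duplicates are listed in the report.
    Adds 0-based half-open columns ``start = pos - 1``, ``end = pos``.
    """
    colmap = {"rsid": "rsid", "chrom": "chrom", "pos": "pos"}
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep="\t", dtype={colmap["rsid"]: str,
                                             colmap["chrom"]: str})
    _require_columns(raw, list(colmap.values()), path)
    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        bad = df.loc[df["pos"] < 1]
        raise FormatError(f"{path}: SNP position < 1 for rsid(s) "
                          f"{list(bad['rsid'].head())}")
    report = LoadReport(n_input=len(df))
    dup_mask = df["rsid"].duplicated(keep="first")
    drops = [(int(i), df.at[i, "rsid"], "duplicate rsid")
             for i in df.index[dup_mask]]
    out = df[~dup_mask].reset_index(drop=True)
    out["start"] = out["pos"] - 1
    out["end"] = out["pos"]
    report.n_kept = len(out)
    report.dropped = pd.DataFrame(drops, columns=["row", "key", "reason"])
    return out, report


def write_snp_table(df: pd.DataFrame, path) -> None:
    df[["rsid", "chrom", "pos"]].to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    """Read a TF-knockout DEG-count table (columns tf, sample, n_deg)."""
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "sample": str})
    _require_columns(df, ["tf", "sample", "n_deg"], path)
    df["n_deg"] = df["n_deg"].astype(int)
    if (df["n_deg"] < 0).any():
        raise FormatError(f"{path}: negative DEG count")
    return df


def write_deg_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_marker_table(path) -> pd.DataFrame:
    """Read a TF-marker annotation table (column ``tf``, extras preserved)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["tf"], path)
    return df


def marker_tf_set(markers: pd.DataFrame) -> frozenset[str]:
    return frozenset(markers["tf"])


def read_class_map(path) -> pd.Series:
    """Read the cell-type -> cell-type-class ontology mapping.

    A cell type mapped to more than one class is fatal: the mapping must be a
    function.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["cell_type", "cell_type_class"], path)
    df = df.drop_duplicates()
    dup = df["cell_type"][df["cell_type"].duplicated(keep=False)]
    if len(dup):
        raise FormatError(f"{path}: cell type(s) mapped to multiple classes: "
                          f"{sorted(dup.unique())}")
    return pd.Series(df["cell_type_class"].to_numpy(),
                     index=df["cell_type"].to_numpy(), name="cell_type_class")


def write_class_map(mapping: pd.Series, path) -> None:
    pd.DataFrame({"cell_type": mapping.index,
                  "cell_type_class": mapping.to_numpy()}
                 ).to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    """Load a YAML pipeline/world configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def dump_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
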