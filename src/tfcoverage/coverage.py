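"""Genomic interval engine and the two coverage statistics.

* **Reg-TF cover ratio** — per cell line and year: the fraction of the cell
  line's expressed genes (top 25% by expression) whose promoter window
  (TSS +/- 500 bp) overlaps at least one ChIP-seq peak deposited for that
  cell line up to the target year.
* **GWAS-SNP cover ratio** — per cell type / class and year: the fraction of
  catalog SNPs overlapping at least one peak deposited for that entity up to
  the target year.

All coordinates are 0-based half-open; 1-based TSS and SNP positions are
converted on ingest.  "Measured until target year" means deposit year <=
target year, inclusive.  Strand is ignored (the flank is symmetric).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


# ---------------------------------------------------------------------------
# promoter windows and interval overlap
# ---------------------------------------------------------------------------

def make_promoter_windows(tss: pd.DataFrame, flank: int = 500) -> pd.DataFrame:
    """Promoter windows around TSS positions.

    ``tss`` carries ``chrom`` plus either a 1-based ``pos`` column or a
    0-based ``start`` column (BED-style single-base intervals).  For a
    1-based position t the window is ``[max(0, t-1-flank), t+flank)``:
    length ``2*flank + 1`` except where clipped at position 0.  A ``gene``
    (or ``name``) column is carried through.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if "pos" in tss.columns:
        p0 = tss["pos"].to_numpy(dtype=int) - 1
    else:
        p0 = tss["start"].to_numpy(dtype=int)
    out = pd.DataFrame({
        "chrom": tss["chrom"].to_numpy(),
        "start": np.maximum(0, p0 - flank),
        "end": p0 + flank + 1,
    })
    for col in ("gene", "name"):
        if col in tss.columns:
            out["gene"] = tss[col].to_numpy()
            break
    return out


def _interval_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int)))
    return trees


def intersect_any(queries: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Boolean per query: does it overlap >= 1 peak by >= 1 bp?

    Half-open semantics: [a, b) and [c, d) overlap iff a < d and c < b on the
    same chromosome (abutting intervals do not overlap).
    """
    trees = _interval_trees(peaks)
    hit = np.zeros(len(queries), dtype=bool)
    for i, (chrom, start, end) in enumerate(zip(queries["chrom"],
                                                queries["start"],
                                                queries["end"])):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(int(start), int(end)):
            hit[i] = True
    return hit


def top_quartile_genes(expression: pd.Series,
                       fraction: float = 0.25) -> list[str]:
    """The "expressed genes" of a cell line: top-``fraction`` by value.

    Genes ranked descending by value with ties broken by ascending symbol;
    the first ``ceil(fraction * n)`` genes are returned.  Deterministic.
    """
    obs = expression.dropna()
    if len(obs) < 4:
        raise ValueError(f"need >= 4 genes with values, got {len(obs)}")
    order = (pd.DataFrame({"gene": obs.index, "value": obs.to_numpy()})
             .sort_values(["value", "gene"], ascending=[False, True],
                          kind="mergesort"))
    k = math.ceil(fraction * len(obs))
    return order["gene"].head(k).tolist()


# ---------------------------------------------------------------------------
# experiment selection and peak pooling
# ---------------------------------------------------------------------------

def experiments_for_entity(metadata: pd.DataFrame, entity: str,
                           level: str = "cell_type",
                           mapping: Mapping[str, str] | None = None,
                           ) -> pd.DataFrame:
    """Metadata rows whose sample (cell type or class) equals ``entity``."""
    if level == "cell_type":
        mask = metadata["cell_type"] == entity
    elif level == "class":
        if mapping is not None:
            sample = metadata["cell_type"].map(pd.Series(mapping))
        else:
            sample = metadata["cell_type_class"]
        mask = sample == entity
    else:
        raise ValueError(f"unknown level {level!r}")
    return metadata[mask]


def pool_peaks(peaks_by_experiment: Mapping[str, pd.DataFrame],
               experiment_ids: Sequence[str]) -> pd.DataFrame:
    frames = [peaks_by_experiment[e] for e in experiment_ids
              if e in peaks_by_experiment and len(peaks_by_experiment[e])]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def _years(metadata: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(metadata["deposit_date"]).dt.year


# ---------------------------------------------------------------------------
# single-year cover ratios
# ---------------------------------------------------------------------------

@dataclass
class CoverRatio:
    ratio: float
    numerator: int
    denominator: int
    covered: pd.Series  # boolean per gene or per SNP rsid


def reg_tf_cover_ratio(expression: pd.DataFrame, tss: pd.DataFrame,
                       peaks_by_experiment: Mapping[str, pd.DataFrame],
                       metadata: pd.DataFrame, cell_line: str, year: int,
                       flank: int = 500, top_fraction: float = 0.25,
                       ) -> CoverRatio:
    """Fraction of the cell line's expressed genes with a peak near the TSS.

    numerator = expressed genes whose promoter window overlaps any peak from
    this cell line's experiments deposited up to ``year``;
    denominator = expressed genes (top 25% by expression).
    """
    if cell_line not in expression.columns:
        raise KeyError(f"cell line {cell_line!r} absent from the expression "
                       f"matrix")
    genes = top_quartile_genes(expression[cell_line], fraction=top_fraction)
    sub = experiments_for_entity(metadata, cell_line, level="cell_type")
    ids = sub["experiment_id"][_years(sub) <= year].tolist()
    peaks = pool_peaks(peaks_by_experiment, ids)
    gene_set = set(genes)
    windows = make_promoter_windows(tss[tss["gene"].isin(gene_set)], flank)
    if len(peaks):
        hit = intersect_any(windows, peaks)
    else:
        hit = np.zeros(len(windows), dtype=bool)
    # a gene may have several TSS; covered iff any window is hit
    per_gene = (pd.Series(hit, index=windows["gene"].to_numpy())
                .groupby(level=0).any().reindex(genes, fill_value=False))
    num = int(per_gene.sum())
    den = len(genes)
    return CoverRatio(num / den, num, den, per_gene)


def gwas_snp_cover_ratio(snps: pd.DataFrame,
                         peaks_by_experiment: Mapping[str, pd.DataFrame],
                         metadata: pd.DataFrame, entity: str,
                         level: str = "class", year: int | None = None,
                         mapping: Mapping[str, str] | None = None,
                         ) -> CoverRatio:
    """Fraction of catalog SNPs inside >= 1 peak of the entity's experiments
    deposited up to ``year``.  Denominator = all (unique) SNPs in the table.
    """
    if not len(snps):
        raise ValueError("empty SNP table")
    sub = experiments_for_entity(metadata, entity, level=level, mapping=mapping)
    if year is not None:
        sub = sub[_years(sub) <= year]
    peaks = pool_peaks(peaks_by_experiment, sub["experiment_id"].tolist())
    if len(peaks):
        hit = intersect_any(snps, peaks)
    else:
        hit = np.zeros(len(snps), dtype=bool)
    num = int(hit.sum())
    den = len(snps)
    return CoverRatio(num / den, num, den,
                      pd.Series(hit, index=snps["rsid"].to_numpy()))


# ---------------------------------------------------------------------------
# annual series
# ---------------------------------------------------------------------------

@dataclass
class CoverRatioSeries:
    """Annual cover-ratio trajectory for one entity.

    With cumulative peak pooling the ratios are nondecreasing in year.
    """

    entity: str
    statistic: str  # "reg_tf" or "gwas_snp"
    years: np.ndarray
    numerators: np.ndarray
    denominators: np.ndarray

    @property
    def ratios(self) -> np.ndarray:
        return self.numerators / self.denominators

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"entity": self.entity,
                             "statistic": self.statistic,
                             "year": self.years,
                             "numerator": self.numerators,
                             "denominator": self.denominators,
                             "ratio": self.ratios})


def earliest_cover_year(queries: pd.DataFrame,
                        peaks_by_experiment: Mapping[str, pd.DataFrame],
                        experiment_years: Mapping[str, int]) -> np.ndarray:
    """For each query interval, the earliest deposit year of any experiment
    whose peaks overlap it (inf if never covered).

    Single pass over experiments in year order; this is the workhorse behind
    every annual series and the order simulation.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in queries.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int),
                grp.index))
    earliest = np.full(len(queries), np.inf)
    pos = {idx: i for i, idx in enumerate(queries.index)}
    for exp_id in sorted(experiment_years,
                         key=lambda e: (experiment_years[e], e)):
        peaks = peaks_by_experiment.get(exp_id)
        if peaks is None or not len(peaks):
            continue
        y = experiment_years[exp_id]
        for chrom, start, end in zip(peaks["chrom"], peaks["start"],
                                     peaks["end"]):
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(int(start), int(end)):
                i = pos[iv.data]
                if y < earliest[i]:
                    earliest[i] = y
    return earliest


def reg_tf_series(expression: pd.DataFrame, tss: pd.DataFrame,
                  peaks_by_experiment: Mapping[str, pd.DataFrame],
                  metadata: pd.DataFrame, cell_line: str,
                  years: Sequence[int], flank: int = 500,
                  top_fraction: float = 0.25) -> CoverRatioSeries:
    """Annual Reg-TF cover-ratio trajectory for one cell line."""
    if cell_line not in expression.columns:
        raise KeyError(f"cell line {cell_line!r} absent from the expression "
                       f"matrix")
    genes = top_quartile_genes(expression[cell_line], fraction=top_fraction)
    windows = make_promoter_windows(tss[tss["gene"].isin(set(genes))], flank)
    windows = windows.reset_index(drop=True)
    sub = experiments_for_entity(metadata, cell_line, level="cell_type")
    exp_years = dict(zip(sub["experiment_id"], _years(sub)))
    earliest = earliest_cover_year(windows, peaks_by_experiment, exp_years)
    per_gene_year = (pd.Series(earliest, index=windows["gene"].to_numpy())
                     .groupby(level=0).min().reindex(genes, fill_value=np.inf))
    yrs = np.asarray(sorted(years), dtype=int)
    nums = np.array([(per_gene_year <= y).sum() for y in yrs])
    dens = np.full(len(yrs), len(genes))
    return CoverRatioSeries(cell_line, "reg_tf", yrs, nums, dens)


def gwas_series(snps: pd.DataFrame,
                peaks_by_experiment: Mapping[str, pd.DataFrame],
                metadata: pd.DataFrame, entity: str,
                years: Sequence[int], level: str = "class",
                mapping: Mapping[str, str] | None = None,
                experiment_years: Mapping[str, int] | None = None,
                ) -> CoverRatioSeries:
    """Annual GWAS-SNP cover-ratio trajectory for one entity.

    ``experiment_years`` overrides the deposit years of the entity's
    experiments (used by the acquisition-order simulation to replay shuffled
    orders without rewriting the metadata).
    """
    if not len(snps):
        raise ValueError("empty SNP table")
    sub = experiments_for_entity(metadata, entity, level=level, mapping=mapping)
    if experiment_years is None:
        exp_years = dict(zip(sub["experiment_id"], _years(sub)))
    else:
        exp_years = {e: int(experiment_years[e])
                     for e in sub["experiment_id"] if e in experiment_years}
    q = snps.reset_index(drop=True)
    earliest = earliest_cover_year(q, peaks_by_experiment, exp_years)
    yrs = np.asarray(sorted(years), dtype=int)
    nums = np.array([(earliest <= y).sum() for y in yrs])
    dens = np.full(len(yrs), len(q))
    return CoverRatioSeries(entity, "gwas_snp", yrs, nums, dens)
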