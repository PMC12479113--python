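"""Coverage inventory of TF-sample pairs and inequality metrics.

The central object is the inventory: for each (TF, sample) pair in a
configured universe, whether the pair is *measured* (>= 1 ChIP-seq
experiment), *unmeasured* (expressed but never measured), or *not_expressed*.
Inequality of experiment counts across TFs or cell types is summarized by
the Gini coefficient and the Lorenz curve; research-attention effects by
Spearman rank correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

STATUS_MEASURED = "measured"
STATUS_UNMEASURED = "unmeasured"
STATUS_NOT_EXPRESSED = "not_expressed"


def measured_pairs(metadata: pd.DataFrame, level: str = "cell_type",
                   mapping: Mapping[str, str] | None = None,
                   ) -> tuple[set[tuple[str, str]], pd.DataFrame]:
    """Pairs (TF, sample) with at least one experiment, plus a count table.

    ``level`` is ``"cell_type"`` (sample = the cell type itself) or
    ``"class"`` (sample = its cell-type class, via ``mapping`` when given,
    else the metadata's own ``cell_type_class`` column).
    """
    if level == "cell_type":
        sample = metadata["cell_type"]
    elif level == "class":
        if mapping is not None:
            mapping = pd.Series(mapping)
            unmapped = sorted(set(metadata["cell_type"]) - set(mapping.index))
            if unmapped:
                raise KeyError(f"cell type(s) missing from the class mapping: "
                               f"{unmapped}")
            sample = metadata["cell_type"].map(mapping)
        else:
            sample = metadata["cell_type_class"]
    else:
        raise ValueError(f"unknown level {level!r}")
    counts = (pd.DataFrame({"tf": metadata["antigen"], "sample": sample})
              .groupby(["tf", "sample"], as_index=False).size()
              .rename(columns={"size": "n_experiments"}))
    pairs = set(zip(counts["tf"], counts["sample"]))
    return pairs, counts


@dataclass
class CoverageInventory:
    """Per-pair status table over the configured pair universe.

    ``extra_measured`` holds measured pairs whose TF or sample falls outside
    the universe (e.g. a TF absent from the expression matrix); they are
    reported separately rather than forced into a status.
    """

    level: str
    table: pd.DataFrame
    extra_measured: set = field(default_factory=set)

    def status_counts(self) -> pd.Series:
        return self.table["status"].value_counts()

    def pairs_with_status(self, status: str) -> set[tuple[str, str]]:
        sub = self.table[self.table["status"] == status]
        return set(zip(sub["tf"], sub["sample"]))


def build_inventory(expressed_pairs: Iterable[tuple[str, str]],
                    measured: Iterable[tuple[str, str]],
                    level: str = "cell_type",
                    tf_universe: Iterable[str] | None = None,
                    sample_universe: Iterable[str] | None = None,
                    ) -> CoverageInventory:
    """Assign measured / unmeasured / not_expressed to every universe pair.

    Status rules: a measured pair is *measured* regardless of its expression
    call; an expressed-but-unmeasured pair is *unmeasured*; the rest are
    *not_expressed*.  Default universe: all TFs and samples seen in either
    input set.
    """
    expressed_pairs = set(expressed_pairs)
    measured = set(measured)
    if tf_universe is None:
        tf_universe = {t for t, _ in expressed_pairs} | {t for t, _ in measured}
    if sample_universe is None:
        sample_universe = ({s for _, s in expressed_pairs}
                           | {s for _, s in measured})
    tfs = sorted(tf_universe)
    samples = sorted(sample_universe)
    tf_set, sample_set = set(tfs), set(samples)
    extra = {(t, s) for t, s in measured
             if t not in tf_set or s not in sample_set}

    rows = []
    for t in tfs:
        for s in samples:
            is_meas = (t, s) in measured
            is_expr = (t, s) in expressed_pairs
            if is_meas:
                status = STATUS_MEASURED
            elif is_expr:
                status = STATUS_UNMEASURED
            else:
                status = STATUS_NOT_EXPRESSED
            rows.append((t, s, is_expr, is_meas, status))
    table = pd.DataFrame(rows, columns=["tf", "sample", "expressed",
                                        "measured", "status"])
    return CoverageInventory(level=level, table=table, extra_measured=extra)


def unmeasured_fraction(inventory: CoverageInventory | pd.DataFrame,
                        by: str | list[str] = "sample") -> pd.DataFrame:
    """Unmeasured / expressed fraction per group (Fig-2c style summary).

    Groups with zero expressed pairs are reported with NaN fraction and
    ``defined = False``, never as 0.
    """
    table = inventory.table if isinstance(inventory, CoverageInventory) \
        else inventory
    if isinstance(by, str):
        by = [by]
    grp = table.groupby(by)
    out = grp.apply(lambda g: pd.Series({
        "n_unmeasured": int((g["status"] == STATUS_UNMEASURED).sum()),
        "n_expressed": int(g["expressed"].sum()),
    }), include_groups=False).reset_index()
    out["fraction"] = np.where(out["n_expressed"] > 0,
                               out["n_unmeasured"] / out["n_expressed"].replace(0, 1),
                               np.nan)
    out["defined"] = out["n_expressed"] > 0
    return out


# ---------------------------------------------------------------------------
# inequality metrics
# ---------------------------------------------------------------------------

def _check_counts(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("need a 1-D vector of length >= 1")
    if not np.all(np.isfinite(x)) or (x < 0).any():
        raise ValueError("counts must be finite and nonnegative")
    if x.sum() == 0:
        raise ValueError("counts must not be all zero")
    return x


def gini(counts) -> float:
    """Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 mean(x)).

    Computed via the sorted-vector identity; bounded by 1 - 1/n.
    """
    x = np.sort(_check_counts(counts))
    n = x.size
    total = x.sum()
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * x) - (n + 1) * total) / (n * total))


def lorenz_curve(counts) -> np.ndarray:
    """Lorenz points: entities ascending by count, cumulative shares on both
    axes, including the (0, 0) origin.  Shape (n+1, 2)."""
    x = np.sort(_check_counts(counts))
    n = x.size
    cum = np.concatenate([[0.0], np.cumsum(x)]) / x.sum()
    frac = np.arange(n + 1) / n
    return np.column_stack([frac, cum])


def gini_from_lorenz(points: np.ndarray) -> float:
    """2 x area between the diagonal and the piecewise-linear Lorenz curve."""
    x, y = points[:, 0], points[:, 1]
    area_under = float(np.trapezoid(y, x))
    return 2.0 * (0.5 - area_under)


def counterfactual_gini(expressed_pairs: Iterable[tuple[str, str]]) -> float:
    """Gini under the counterfactual that every expressed pair had exactly one
    experiment: per-TF count = number of samples in which the TF is expressed.
    """
    expressed_pairs = list(expressed_pairs)
    if not expressed_pairs:
        raise ValueError("expressed set is empty")
    counts = pd.Series(1, index=pd.MultiIndex.from_tuples(expressed_pairs)) \
        .groupby(level=0).size()
    return gini(counts.to_numpy())


def experiment_counts(metadata: pd.DataFrame, by: str = "tf",
                      universe: Iterable[str] | None = None) -> pd.Series:
    """Per-entity experiment counts; entities in ``universe`` with no
    experiments count as zero (the Lorenz curves span all entities)."""
    col = {"tf": "antigen", "cell_type": "cell_type",
           "class": "cell_type_class"}[by]
    counts = metadata.groupby(col).size()
    if universe is not None:
        counts = counts.reindex(sorted(universe), fill_value=0)
    return counts.sort_index()


def attention_correlations(metadata: pd.DataFrame,
                           publications: Mapping[str, int] | pd.Series,
                           split_year: int) -> tuple[float, float]:
    """Spearman correlations quantifying research-attention effects.

    Returns ``(rho_publications, rho_rich_get_richer)``:

    * publications vs total experiment count per TF (over TFs present in
      both tables);
    * experiments dated <= split_year vs >= split_year + 1 per TF (over all
      TFs in the metadata; a TF absent from one period counts 0).

    Average ranks via the Pearson-on-ranks definition (exact under ties).
    """
    publications = pd.Series(publications)
    total = metadata.groupby("antigen").size()
    common = total.index.intersection(publications.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 TFs shared with the publication table")
    rho_pub = float(stats.spearmanr(publications.loc[common],
                                    total.loc[common]).statistic)

    years = pd.to_datetime(metadata["deposit_date"]).dt.year
    lo, hi = int(years.min()), int(years.max())
    if not lo <= split_year < hi:
        raise ValueError(f"split_year {split_year} outside the date range "
                         f"[{lo}, {hi})")
    tfs = sorted(total.index)
    early = metadata[years <= split_year].groupby("antigen").size() \
        .reindex(tfs, fill_value=0)
    late = metadata[years >= split_year + 1].groupby("antigen").size() \
        .reindex(tfs, fill_value=0)
    if len(tfs) < 3:
        raise ValueError("fewer than 3 TFs in the metadata")
    rho_time = float(stats.spearmanr(early, late).statistic)
    return rho_pub, rho_time
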