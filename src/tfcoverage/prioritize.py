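"""DEG-count comparisons and the hidden-gems prioritization filter.

A *hidden gem* is an unmeasured (TF, sample) pair whose TF knockout/knockdown
produces more than ``deg_threshold`` differentially expressed genes (strict
inequality) and whose TF is annotated as a cell-type/tissue marker — a pair
worth prioritizing in future ChIP-seq campaigns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .inventory import (CoverageInventory, STATUS_MEASURED,
                        STATUS_UNMEASURED)
from .stats import RankSumResult, wilcoxon_rank_sum


@dataclass
class GroupComparison:
    grouping: str
    group_names: tuple[str, str]
    sizes: tuple[int, int]
    medians: tuple[float, float]
    test: RankSumResult
    n_unjoined: int = 0


def _inventory_table(inventory) -> pd.DataFrame:
    return inventory.table if isinstance(inventory, CoverageInventory) \
        else inventory


def compare_deg_groups(deg: pd.DataFrame, grouping: str,
                       inventory=None,
                       marker_tfs: Iterable[str] | None = None,
                       alternative: str = "two-sided") -> GroupComparison:
    """Two-sided Wilcoxon comparison of DEG counts between pair categories.

    ``grouping="marker_vs_nonmarker"`` splits DEG rows by TF marker status
    (requires ``marker_tfs``); ``grouping="measured_vs_unmeasured"`` joins
    rows to the inventory on (tf, sample) and splits by status (rows that do
    not join, or join to not_expressed pairs, are dropped and counted).
    No multiple-testing correction is applied (single planned comparison).
    """
    if grouping == "marker_vs_nonmarker":
        if marker_tfs is None:
            raise ValueError("marker_tfs is required for this grouping")
        marker_tfs = set(marker_tfs)
        in_a = deg["tf"].isin(marker_tfs)
        a, b = deg[in_a], deg[~in_a]
        names = ("marker", "nonmarker")
        n_unjoined = 0
    elif grouping == "measured_vs_unmeasured":
        if inventory is None:
            raise ValueError("inventory is required for this grouping")
        table = _inventory_table(inventory)[["tf", "sample", "status"]]
        joined = deg.merge(table, on=["tf", "sample"], how="left")
        n_unjoined = int((~joined["status"].isin(
            [STATUS_MEASURED, STATUS_UNMEASURED])).sum())
        a = joined[joined["status"] == STATUS_MEASURED]
        b = joined[joined["status"] == STATUS_UNMEASURED]
        names = (STATUS_MEASURED, STATUS_UNMEASURED)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    for name, grp in zip(names, (a, b)):
        if len(grp) == 0:
            raise ValueError(f"group {name!r} has no members")
    test = wilcoxon_rank_sum(a["n_deg"], b["n_deg"], alternative=alternative)
    return GroupComparison(grouping, names, (len(a), len(b)),
                           (float(a["n_deg"].median()),
                            float(b["n_deg"].median())),
                           test, n_unjoined)


def hidden_gems(inventory, deg: pd.DataFrame,
                marker_tfs: Iterable[str], deg_threshold: int = 1000,
                agg: str = "max") -> tuple[pd.DataFrame, pd.DataFrame]:
    """The prioritization filter: unmeasured AND n_deg > threshold AND marker.

    Multiple knockout experiments for the same (tf, sample) aggregate by the
    maximum DEG count (``agg="mean"`` for the average).  Returns
    ``(gems, audit)``: the accepted candidates, and the full per-pair flag
    table for every DEG-table pair.
    """
    marker_tfs = set(marker_tfs)
    if agg not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")
    per_pair = (deg.groupby(["tf", "sample"], as_index=False)["n_deg"]
                .agg(agg))
    table = _inventory_table(inventory)[["tf", "sample", "status"]]
    audit = per_pair.merge(table, on=["tf", "sample"], how="left")
    audit["status"] = audit["status"].fillna("not_in_inventory")
    audit["unmeasured"] = audit["status"] == STATUS_UNMEASURED
    audit["marker"] = audit["tf"].isin(marker_tfs)
    audit["above_threshold"] = audit["n_deg"] > deg_threshold
    audit["gem"] = (audit["unmeasured"] & audit["marker"]
                    & audit["above_threshold"])
    audit = audit.sort_values(["tf", "sample"], kind="mergesort",
                              ignore_index=True)
    gems = audit[audit["gem"]].reset_index(drop=True)
    return gems, audit


def gem_pairs(gems: pd.DataFrame) -> set[tuple[str, str]]:
    return set(zip(gems["tf"], gems["sample"]))
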