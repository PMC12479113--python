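"""Acquisition-order simulation.

Would a different historical ordering of the same ChIP-seq experiments have
covered GWAS SNPs faster?  The experiment set and its peaks stay fixed; only
the multiset of deposit dates is permuted over the experiment IDs.  Each
order is scored by the span-normalized trapezoidal area under its annual
GWAS-SNP cover-ratio trajectory (the time-averaged ratio, in [0, 1]); a
higher AUC means earlier coverage gains.  Top and bottom orders are compared
to the real order by subsampled Welch tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import (CoverRatioSeries, earliest_cover_year,
                       experiments_for_entity, gwas_series)
from .stats import WelchResult, welch_t_test


@dataclass
class AcquisitionOrder:
    """An assignment of the original date multiset to experiment IDs."""

    dates: pd.Series          # experiment_id -> Timestamp
    provenance: str           # "real" or "shuffle-<seed>"

    @property
    def years(self) -> pd.Series:
        return pd.to_datetime(self.dates).dt.year


def real_order(metadata: pd.DataFrame) -> AcquisitionOrder:
    return AcquisitionOrder(
        pd.Series(pd.to_datetime(metadata["deposit_date"]).to_numpy(),
                  index=metadata["experiment_id"].to_numpy()),
        "real")


def shuffle_order(metadata: pd.DataFrame, seed: int) -> AcquisitionOrder:
    """Uniform random permutation of deposit dates over experiment IDs."""
    if len(metadata) < 2:
        raise ValueError("need >= 2 experiments to shuffle")
    rng = np.random.default_rng(seed)
    dates = pd.to_datetime(metadata["deposit_date"]).to_numpy()
    return AcquisitionOrder(
        pd.Series(rng.permutation(dates),
                  index=metadata["experiment_id"].to_numpy()),
        f"shuffle-{seed}")


def apply_order(metadata: pd.DataFrame, order: AcquisitionOrder,
                ) -> pd.DataFrame:
    out = metadata.copy()
    out["deposit_date"] = order.dates.loc[out["experiment_id"]].to_numpy()
    return out


def trajectory_auc(years, ratios=None, method: str = "trapezoid") -> float:
    """Span-normalized area under an annual trajectory.

    ``trapezoid``: trapezoidal integral divided by the year span, i.e. the
    time average of the piecewise-linear trend.  ``mean``: plain mean of the
    annual ratios (rectangle variant).
    """
    if isinstance(years, CoverRatioSeries):
        years, ratios = years.years, years.ratios
    years = np.asarray(years, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    if years.size < 2:
        raise ValueError("need >= 2 years")
    if method == "trapezoid":
        return float(np.trapezoid(ratios, years) / (years[-1] - years[0]))
    if method == "mean":
        return float(ratios.mean())
    raise ValueError(f"unknown AUC method {method!r}")


def cumulative_unique_tfs(metadata: pd.DataFrame, years: Sequence[int],
                          order: AcquisitionOrder | None = None) -> np.ndarray:
    """Per-year count of distinct TFs with >= 1 experiment dated <= year."""
    if order is None:
        exp_years = pd.to_datetime(metadata["deposit_date"]).dt.year.to_numpy()
    else:
        exp_years = order.years.loc[metadata["experiment_id"]].to_numpy()
    tfs = metadata["antigen"].to_numpy()
    first_year = pd.Series(exp_years).groupby(tfs).min()
    yrs = np.asarray(sorted(years), dtype=int)
    return np.array([(first_year <= y).sum() for y in yrs])


@dataclass
class OrderSimulationResult:
    provenance: str
    series: CoverRatioSeries
    auc: float
    cumulative_unique_tfs: np.ndarray


class _EntityWorld:
    """Precomputed per-experiment SNP coverage for one entity, so that
    hundreds of shuffled/subsampled trajectories cost almost nothing."""

    def __init__(self, metadata, snps, peaks_by_experiment, entity, level,
                 mapping=None):
        self.metadata = experiments_for_entity(
            metadata, entity, level=level, mapping=mapping).reset_index(drop=True)
        if len(self.metadata) < 2:
            raise ValueError(f"entity {entity!r} has fewer than 2 experiments")
        self.entity = entity
        self.snps = snps.reset_index(drop=True)
        self.n_snps = len(self.snps)
        ids = self.metadata["experiment_id"].tolist()
        # covered SNP indices per experiment, via the earliest-cover engine
        # run one experiment at a time (year 0 marker)
        self.cover: dict[str, np.ndarray] = {}
        for e in ids:
            earliest = earliest_cover_year(
                self.snps, peaks_by_experiment, {e: 0})
            self.cover[e] = np.flatnonzero(np.isfinite(earliest))

    def trajectory(self, years_by_experiment: Mapping[str, int],
                   year_grid: np.ndarray,
                   keep: Sequence[str] | None = None) -> CoverRatioSeries:
        earliest = np.full(self.n_snps, np.inf)
        ids = self.cover.keys() if keep is None else keep
        for e in ids:
            idx = self.cover[e]
            if idx.size:
                np.minimum.at(earliest, idx, years_by_experiment[e])
        nums = np.array([(earliest <= y).sum() for y in year_grid])
        dens = np.full(len(year_grid), self.n_snps)
        return CoverRatioSeries(self.entity, "gwas_snp", year_grid, nums, dens)


def _year_grid(metadata: pd.DataFrame,
               years: Sequence[int] | None) -> np.ndarray:
    if years is not None:
        return np.asarray(sorted(years), dtype=int)
    y = pd.to_datetime(metadata["deposit_date"]).dt.year
    return np.arange(int(y.min()), int(y.max()) + 1)


def run_order_simulation(metadata: pd.DataFrame, snps: pd.DataFrame,
                         peaks_by_experiment: Mapping[str, pd.DataFrame],
                         entity: str, level: str = "class",
                         mapping: Mapping[str, str] | None = None,
                         years: Sequence[int] | None = None,
                         n_reps: int = 100, seed: int = 0,
                         auc_method: str = "trapezoid",
                         ) -> list[OrderSimulationResult]:
    """Real plus ``n_reps`` shuffled acquisition orders for one entity.

    Returns results with the real order first.  Every order ends at the same
    final-year ratio (all experiments are eventually included), an invariant
    the tests rely on.
    """
    world = _EntityWorld(metadata, snps, peaks_by_experiment, entity, level,
                         mapping)
    grid = _year_grid(world.metadata, years)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2 ** 31)
    orders = [real_order(world.metadata)]
    orders += [shuffle_order(world.metadata, int(s)) for s in seeds]
    results = []
    for order in orders:
        ybe = dict(zip(order.dates.index, order.years.to_numpy()))
        series = world.trajectory(ybe, grid)
        results.append(OrderSimulationResult(
            order.provenance, series,
            trajectory_auc(series, method=auc_method),
            cumulative_unique_tfs(world.metadata, grid, order)))
    return results


def simulation_summary(results: Sequence[OrderSimulationResult],
                       early_fraction: float = 1 / 3) -> pd.DataFrame:
    """One row per order: AUC, final ratio, early TF diversity."""
    rows = []
    for r in results:
        grid = r.series.years
        cut = grid[0] + max(0, int(round(early_fraction * (grid[-1] - grid[0]))) - 1)
        early = int(r.cumulative_unique_tfs[np.searchsorted(grid, cut)])
        rows.append((r.provenance, r.auc, float(r.series.ratios[-1]), early))
    return pd.DataFrame(rows, columns=["provenance", "auc", "final_ratio",
                                       "early_unique_tfs"])


def _stable_stream(seed: int, *labels) -> np.random.Generator:
    keys = [zlib.crc32(str(x).encode()) for x in labels]
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF,
                                                         *keys]))


def subsample_aucs(metadata: pd.DataFrame, snps: pd.DataFrame,
                   peaks_by_experiment: Mapping[str, pd.DataFrame],
                   entity: str, order: AcquisitionOrder,
                   fraction: float, n_subsamples: int = 50,
                   level: str = "class",
                   mapping: Mapping[str, str] | None = None,
                   years: Sequence[int] | None = None, seed: int = 0,
                   auc_method: str = "trapezoid",
                   _world: "_EntityWorld | None" = None) -> np.ndarray:
    """AUC distribution over uniform without-replacement subsamples.

    Each subsample retains ``ceil(fraction * N)`` experiments; the RNG stream
    is keyed by (seed, order provenance, fraction) so the real order's
    distribution is reproducible independently of which orders accompany it.
    """
    world = _world or _EntityWorld(metadata, snps, peaks_by_experiment,
                                   entity, level, mapping)
    if n_subsamples < 2:
        raise ValueError("need n_subsamples >= 2")
    grid = _year_grid(world.metadata, years)
    ids = np.asarray(world.metadata["experiment_id"])
    n_keep = int(np.ceil(fraction * len(ids)))
    rng = _stable_stream(seed, order.provenance, f"{fraction:.6f}")
    ybe = dict(zip(order.dates.index, order.years.to_numpy()))
    aucs = np.empty(n_subsamples)
    for i in range(n_subsamples):
        keep = rng.choice(ids, size=n_keep, replace=False)
        series = world.trajectory(ybe, grid, keep=keep)
        aucs[i] = trajectory_auc(series, method=auc_method)
    return aucs


def subsample_compare(metadata: pd.DataFrame, snps: pd.DataFrame,
                      peaks_by_experiment: Mapping[str, pd.DataFrame],
                      entity: str, orders: Sequence[AcquisitionOrder],
                      fractions: Sequence[float] = (0.9, 0.5),
                      n_subsamples: int = 50, level: str = "class",
                      mapping: Mapping[str, str] | None = None,
                      years: Sequence[int] | None = None, seed: int = 0,
                      auc_method: str = "trapezoid") -> pd.DataFrame:
    """Welch comparison of each order's subsampled AUC distribution vs real.

    ``orders`` must include the real order (provenance "real"), which serves
    as the baseline for every comparison.
    """
    real = [o for o in orders if o.provenance == "real"]
    if not real:
        raise ValueError('orders must include the real order '
                         '(provenance "real")')
    world = _EntityWorld(metadata, snps, peaks_by_experiment, entity, level,
                         mapping)
    rows = []
    for fraction in fractions:
        base = subsample_aucs(metadata, snps, peaks_by_experiment, entity,
                              real[0], fraction, n_subsamples, level, mapping,
                              years, seed, auc_method, _world=world)
        for order in orders:
            if order.provenance == "real":
                sample = base
            else:
                sample = subsample_aucs(metadata, snps, peaks_by_experiment,
                                        entity, order, fraction, n_subsamples,
                                        level, mapping, years, seed,
                                        auc_method, _world=world)
            res: WelchResult = welch_t_test(sample, base)
            rows.append((order.provenance, fraction, float(sample.mean()),
                         float(base.mean()), res.t, res.df, res.p_value,
                         res.degenerate))
    return pd.DataFrame(rows, columns=["provenance", "fraction", "mean_auc",
                                       "real_mean_auc", "t", "df", "p_value",
                                       "degenerate"])
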