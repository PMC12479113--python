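"""One-step expression thresholding (StepMiner-style).

A TF is called "expressed" in a cell line by fitting a one-step function to
the TF's expression values sorted ascending across cell lines: every
breakpoint k splits the sorted vector into a low block (first k values) and a
high block, each fitted by its mean; the k minimizing the residual sum of
squares defines the step, and the midpoint between the two block means is the
TF-specific expression threshold.

Conventions (the original description leaves these open; they are fixed here
and documented in the methods note):

* ties in SSE break toward the smallest breakpoint (the most conservative
  "expressed" set);
* a profile whose range is below ``flat_eps`` is degenerate ("flat") and
  yields all not-expressed calls;
* calls use strict inequality ``value > threshold``;
* missing values are excluded from the fit, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StepFit:
    """Result of fitting a one-step function to a sorted value vector.

    ``breakpoint`` is the size k of the low block (1..n-1) over the
    ascending-sorted values; ``threshold = (low_mean + high_mean) / 2``.
    For flat profiles ``flat`` is True and the threshold is NaN.
    """

    breakpoint: int | None
    low_mean: float
    high_mean: float
    threshold: float
    sse: float
    flat: bool

    @property
    def n_low(self) -> int | None:
        return self.breakpoint


def fit_step(values, flat_eps: float | None = None) -> StepFit:
    """Fit a one-step function to ``values`` (n >= 2 finite reals).

    Scans all breakpoints k in 1..n-1 of the ascending-sorted vector and
    returns the one minimizing
    ``SSE = sum_low (v - low_mean)^2 + sum_high (v - high_mean)^2``,
    ties broken by the smallest k.

    ``flat_eps`` defaults to ``1e-9 * max(1, range)``; a vector whose range is
    below it is flagged flat (no step evidence).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"need a 1-D vector of length >= 2, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite value in expression vector")
    s = np.sort(v)
    n = s.size
    vrange = float(s[-1] - s[0])
    eps = flat_eps if flat_eps is not None else 1e-9 * max(1.0, vrange)
    if vrange < eps:
        m = float(s.mean())
        sse = float(((s - m) ** 2).sum())
        return StepFit(None, m, m, math.nan, sse, True)

    csum = np.cumsum(s)
    csq = np.cumsum(s * s)
    k = np.arange(1, n)
    low_sum = csum[k - 1]
    low_sq = csq[k - 1]
    sse = (low_sq - low_sum ** 2 / k) \
        + ((csq[-1] - low_sq) - (csum[-1] - low_sum) ** 2 / (n - k))
    i = int(np.argmin(sse))          # first occurrence -> smallest k on ties
    kbest = i + 1
    low_mean = float(low_sum[i] / kbest)
    high_mean = float((csum[-1] - low_sum[i]) / (n - kbest))
    return StepFit(kbest, low_mean, high_mean,
                   (low_mean + high_mean) / 2.0,
                   float(max(sse[i], 0.0)), False)


@dataclass
class ExpressionCallResult:
    """Boolean expressed calls with per-TF step-fit provenance.

    ``calls`` is a boolean-dtype frame (pd.NA where the input was missing),
    ``fits`` one row per fitted TF, ``skipped`` the TFs with fewer than two
    observed values (excluded, not fatal).
    """

    calls: pd.DataFrame
    fits: pd.DataFrame
    skipped: pd.DataFrame


def call_expression(matrix: pd.DataFrame, flat_eps: float | None = None,
                    strict: bool = True, log_transform: bool = True,
                    ) -> ExpressionCallResult:
    """Call expressed/not-expressed per (TF, cell line) from a value matrix.

    One step fit per row; flat rows give all-False calls.  ``strict``
    controls whether a value exactly at the threshold counts as expressed
    (default: it does not).

    By default the fit runs on ``log1p`` of the values: expression levels
    are heavy-tailed, and a least-squares step on the raw scale is dominated
    by variation within the expressed component rather than by the
    expressed/not-expressed gap.  The transform is monotone, so calls are
    equivalent to comparing raw values against ``expm1`` of the fitted
    threshold; the reported ``threshold`` column is on the raw scale either
    way (fit-scale quantities are ``low_mean``/``high_mean``/``sse``).
    """
    if log_transform:
        matrix = np.log1p(matrix)
    vals = matrix.to_numpy(dtype=float)
    if flat_eps is None:
        finite = vals[np.isfinite(vals)]
        vrange = float(finite.max() - finite.min()) if finite.size else 0.0
        flat_eps = 1e-9 * max(1.0, vrange)

    calls = pd.DataFrame(pd.NA, index=matrix.index, columns=matrix.columns,
                         dtype="boolean")
    fit_rows = []
    skipped = []
    for tf, row in matrix.iterrows():
        obs = row.dropna()
        if len(obs) < 2:
            skipped.append((tf, len(obs), "fewer than 2 observed values"))
            continue
        fit = fit_step(obs.to_numpy(), flat_eps=flat_eps)
        if fit.flat:
            calls.loc[tf, obs.index] = False
        else:
            if strict:
                calls.loc[tf, obs.index] = (obs > fit.threshold).to_numpy()
            else:
                calls.loc[tf, obs.index] = (obs >= fit.threshold).to_numpy()
        thr_raw = float(np.expm1(fit.threshold)) if log_transform \
            else fit.threshold
        fit_rows.append((tf, fit.breakpoint if fit.breakpoint is not None else -1,
                         fit.low_mean, fit.high_mean, thr_raw, fit.sse,
                         fit.flat, log_transform))
    fits = pd.DataFrame(fit_rows, columns=["tf", "breakpoint", "low_mean",
                                           "high_mean", "threshold", "sse",
                                           "flat", "log1p_fit"])
    skip = pd.DataFrame(skipped, columns=["tf", "n_values", "reason"])
    return ExpressionCallResult(calls=calls, fits=fits, skipped=skip)


def expressed_pairs(calls: pd.DataFrame) -> set[tuple[str, str]]:
    """Set of (TF, cell line) pairs called expressed (NA counts as False)."""
    filled = calls.fillna(False).astype(bool)
    tf_idx, cl_idx = np.nonzero(filled.to_numpy())
    return {(filled.index[i], filled.columns[j])
            for i, j in zip(tf_idx, cl_idx)}


def aggregate_to_class(calls: pd.DataFrame, mapping) -> set[tuple[str, str]]:
    """Aggregate cell-line calls to (TF, cell-type-class) pairs.

    A (TF, class) pair is expressed iff at least one member cell line is
    called expressed.  Every called cell line must map to exactly one class.
    """
    mapping = pd.Series(mapping)
    unmapped = [c for c in calls.columns if c not in mapping.index]
    if unmapped:
        raise KeyError(f"cell line(s) missing from the class mapping: "
                       f"{sorted(unmapped)}")
    filled = calls.fillna(False).astype(bool)
    by_class = filled.T.groupby(mapping.loc[filled.columns].to_numpy()).any().T
    tf_idx, cl_idx = np.nonzero(by_class.to_numpy())
    return {(by_class.index[i], by_class.columns[j])
            for i, j in zip(tf_idx, cl_idx)}
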