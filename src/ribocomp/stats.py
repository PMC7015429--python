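"""Single-cell measurement statistics.

Covers the quantities the analysis rests on — Pearson correlation with
percentile-bootstrap confidence intervals, CV^2 (variance over squared
mean, sample variance with denominator n-1 throughout), fluorescence-to-
copy-number quantization for FISH data, Poisson / negative-binomial count
fits, and the grouped (per-condition vs pooled) correlation analysis with
even subsampling that exposes Simpson-style sign reversals.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import UndefinedCorrelationError, UnitEstimationError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None


def pearson_r(x, y, ci: bool = False, B: int = 1000, level: float = 0.95,
              seed=None) -> CorrelationResult:
    """Pearson correlation, optionally with a percentile-bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D with equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    r = float(stats.pearsonr(x, y).statistic)
    if not ci:
        return CorrelationResult(r=r, n=x.size)
    table = pd.DataFrame({"x": x, "y": y})
    lo, hi = bootstrap_ci(
        lambda t: pearson_r(t["x"], t["y"]).r, table, B=B, level=level, seed=seed
    )
    return CorrelationResult(r=r, n=x.size, ci_low=lo, ci_high=hi)


def cv2(x) -> float:
    """Squared coefficient of variation, Var(x)/mean(x)^2 (ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 observations")
    m = float(np.mean(x))
    if m == 0.0:
        raise ValidationError("CV^2 undefined for zero-mean data")
    return float(np.var(x, ddof=1) / m**2)


def bootstrap_ci(statistic, table, B: int = 1000, level: float = 0.95,
                 seed=None) -> tuple[float, float]:
    """Percentile bootstrap interval of ``statistic(table)``.

    Rows of ``table`` (DataFrame or 1/2-D array) are resampled with
    replacement. Resamples on which the statistic is undefined (degenerate
    correlation input) or non-finite are rejected and redrawn, with the
    rejection count logged.
    """
    if B < 100:
        raise ValidationError("B must be >= 100")
    if not 0 < level < 1:
        raise ValidationError("level must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(table)
    is_frame = isinstance(table, pd.DataFrame)
    values = []
    rejected = 0
    max_attempts = 10 * B
    attempts = 0
    while len(values) < B and attempts < max_attempts:
        attempts += 1
        idx = rng.integers(0, n, size=n)
        sample = table.iloc[idx] if is_frame else np.asarray(table)[idx]
        try:
            v = float(statistic(sample))
        except UndefinedCorrelationError:
            rejected += 1
            continue
        if not math.isfinite(v):
            rejected += 1
            continue
        values.append(v)
    if rejected:
        logger.info("bootstrap_ci: rejected %d degenerate resamples", rejected)
    if len(values) < B:
        raise ValidationError(
            f"could not obtain {B} valid bootstrap resamples ({rejected} rejected)"
        )
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# FISH quantization: fluorescence -> integer transcript copies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantizationResult:
    copies: np.ndarray          # integer copies per cell
    unit_intensity: float       # estimated single-transcript density
    threshold: float            # false-positive density threshold
    background: float           # background density subtracted
    n_positive: int


def _round_half_away(x):
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def quantize_mrna(cells: pd.DataFrame, negative_control: pd.DataFrame,
                  channel: str = "channel2", area_col: str = "area",
                  background: float | None = None,
                  threshold_quantile: float = 0.99,
                  low_expression_quantile: float = 0.25) -> QuantizationResult:
    """Convert per-cell fluorescence into integer transcript copies.

    Steps mirror standard smFISH quantification: (1) normalize total
    intensity by cell area; (2) subtract background (estimated as the
    median area-normalized negative-control intensity unless given); (3)
    zero out cells below the false-positive threshold, the
    ``threshold_quantile`` of the background-subtracted negative control;
    (4) estimate the single-transcript unit intensity as the kernel-density
    peak (Silverman bandwidth) among low-expression positive cells — those
    below the ``low_expression_quantile`` of above-threshold densities; (5)
    divide and round to the nearest integer (ties away from zero).
    """
    for df, name in ((cells, "cells"), (negative_control, "negative_control")):
        for col in (channel, area_col):
            if col not in df.columns:
                raise ValidationError(f"{name} table lacks required column {col!r}")
    density = cells[channel].to_numpy(dtype=float) / cells[area_col].to_numpy(dtype=float)
    neg_density = (
        negative_control[channel].to_numpy(dtype=float)
        / negative_control[area_col].to_numpy(dtype=float)
    )
    bg = float(np.median(neg_density)) if background is None else float(background)
    d = density - bg
    threshold = float(np.quantile(neg_density - bg, threshold_quantile))

    positive = d > threshold
    if not np.any(positive):
        raise UnitEstimationError("no cells above the false-positive threshold")
    pos_d = d[positive]
    low_cut = np.quantile(pos_d, low_expression_quantile)
    low = pos_d[pos_d <= low_cut]
    if low.size == 0 or np.std(low) < 1e-12 * max(abs(float(np.mean(low))), 1.0):
        unit = float(np.median(low if low.size else pos_d))
    else:
        kde = stats.gaussian_kde(low, bw_method="silverman")
        grid = np.linspace(low.min(), low.max(), 512)
        unit = float(grid[np.argmax(kde(grid))])
    if unit <= 0:
        raise UnitEstimationError(f"estimated unit intensity is non-positive ({unit})")

    copies = np.zeros(d.size, dtype=int)
    copies[positive] = _round_half_away(pos_d / unit).astype(int)
    return QuantizationResult(
        copies=copies, unit_intensity=unit, threshold=threshold, background=bg,
        n_positive=int(np.sum(positive)),
    )


# ---------------------------------------------------------------------------
# Count-distribution fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountFit:
    family: str                   # "poisson" or "negative_binomial"
    params: dict                  # lam | mean, dispersion
    loglik: float
    dispersion_index: float       # sample variance / mean
    gof_pvalue: float             # chi-square goodness of fit


def _gof_chisquare(counts, pmf, n_params):
    """Chi-square GOF with expected-count bins merged to >= 5."""
    n = counts.size
    kmax = int(np.max(counts))
    support = np.arange(kmax + 1)
    expected = pmf(support) * n
    tail = n - expected.sum()
    observed = np.bincount(counts, minlength=kmax + 1).astype(float)
    exp_bins, obs_bins = [], []
    acc_e = acc_o = 0.0
    for e, o in zip(expected, observed):
        acc_e += e
        acc_o += o
        if acc_e >= 5.0:
            exp_bins.append(acc_e)
            obs_bins.append(acc_o)
            acc_e = acc_o = 0.0
    # fold leftover and the open tail into the last bin
    if exp_bins:
        exp_bins[-1] += acc_e + max(tail, 0.0)
        obs_bins[-1] += acc_o
    else:
        return float("nan")
    exp_arr = np.asarray(exp_bins)
    obs_arr = np.asarray(obs_bins)
    dof = len(exp_bins) - 1 - n_params
    if dof < 1:
        return float("nan")
    chi2 = float(np.sum((obs_arr - exp_arr) ** 2 / exp_arr))
    return float(stats.chi2.sf(chi2, dof))


def fit_counts(counts, family: str = "poisson") -> CountFit:
    """Maximum-likelihood fit of integer count data.

    Poisson: lambda-hat is the sample mean (closed form). Negative binomial
    (NB2, variance = mean + mean^2/dispersion): the mean MLE is the sample
    mean for any fixed dispersion, so the dispersion is profiled by 1-D
    likelihood maximization. Underdispersed data (variance <= mean) have no
    interior NB optimum; the fit falls back to Poisson with a warning.
    """
    counts = np.asarray(counts)
    if counts.size < 20:
        raise ValidationError("need at least 20 observations")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValidationError("counts must be non-negative integers")
    counts = counts.astype(int)
    m = float(np.mean(counts))
    v = float(np.var(counts, ddof=1))
    disp_index = v / m if m > 0 else float("nan")

    if family not in ("poisson", "nb", "negative_binomial"):
        raise ValidationError(f"unknown family {family!r}")

    if family != "poisson" and (m == 0.0 or v <= m):
        warnings.warn(
            "data are not overdispersed; falling back to a Poisson fit",
            stacklevel=2,
        )
        family = "poisson"

    if family == "poisson":
        ll = float(np.sum(stats.poisson.logpmf(counts, m))) if m > 0 else 0.0
        p = _gof_chisquare(counts, lambda k: stats.poisson.pmf(k, m), 1) if m > 0 else float("nan")
        return CountFit(
            family="poisson", params={"lam": m}, loglik=ll,
            dispersion_index=disp_index, gof_pvalue=p,
        )

    def negll(log_k):
        k = np.exp(log_k)
        return -np.sum(stats.nbinom.logpmf(counts, k, k / (k + m)))

    # moment start: v = m + m^2/k
    k0 = m * m / (v - m)
    res = optimize.minimize_scalar(
        negll, bounds=(np.log(k0) - 8.0, np.log(k0) + 8.0), method="bounded"
    )
    k_hat = float(np.exp(res.x))
    ll = float(-res.fun)
    p = _gof_chisquare(counts, lambda kk: stats.nbinom.pmf(kk, k_hat, k_hat / (k_hat + m)), 2)
    return CountFit(
        family="negative_binomial", params={"mean": m, "dispersion": k_hat},
        loglik=ll, dispersion_index=disp_index, gof_pvalue=p,
    )


# ---------------------------------------------------------------------------
# Grouped (per-condition vs pooled) correlation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupedCorrelationReport:
    per_group: dict
    merged: CorrelationResult
    subsample_curve: pd.DataFrame  # columns total_n, mean_r, sd_r


def grouped_correlation_analysis(table: pd.DataFrame, group_key: str = "condition",
                                 x: str = "channel1", y: str = "channel2",
                                 subsample_sizes=None, replicates: int = 100,
                                 seed=None, ci: bool = False) -> GroupedCorrelationReport:
    """Within-group and pooled Pearson correlations, plus an even-subsampling
    stability curve.

    For each requested total sample size n, ``replicates`` random draws take
    n // K cells per group without replacement (K groups) and record the
    merged correlation; the curve reports its mean and SD. Equal per-group
    draws remove group-size confounding from the pooled estimate.
    """
    for col in (group_key, x, y):
        if col not in table.columns:
            raise ValidationError(f"table lacks required column {col!r}")
    groups = list(table.groupby(group_key, sort=False))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    per_group = {
        label: pearson_r(g[x], g[y], ci=ci, seed=rng) for label, g in groups
    }
    merged = pearson_r(table[x], table[y], ci=ci, seed=rng)

    rows = []
    if subsample_sizes is not None:
        k = len(groups)
        for total in subsample_sizes:
            per = int(total) // k
            if per < 3:
                raise ValidationError(f"total size {total} gives < 3 cells per group")
            for label, g in groups:
                if len(g) < per:
                    raise ValidationError(
                        f"group {label!r} has {len(g)} cells, fewer than the {per} requested"
                    )
            rs = np.empty(replicates)
            for rep in range(replicates):
                parts = [
                    g.iloc[rng.choice(len(g), size=per, replace=False)]
                    for _, g in groups
                ]
                sub = pd.concat(parts, ignore_index=True)
                rs[rep] = pearson_r(sub[x], sub[y]).r
            rows.append((int(total), float(np.mean(rs)), float(np.std(rs, ddof=1))))
    curve = pd.DataFrame(rows, columns=["total_n", "mean_r", "sd_r"])
    return GroupedCorrelationReport(per_group=per_group, merged=merged, subsample_curve=curve)
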