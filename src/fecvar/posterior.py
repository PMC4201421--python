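"""Posterior summaries, variance components, CVs and rank correlations.

These are the quantities the analysis reports: posterior means with
2.5/97.5% credible intervals, the among-line versus residual variance
decomposition (intraclass correlation, on two scales), per-line means,
SDs and coefficients of variation pooled over blocks, within-line variance
fold ranges, and Spearman correlations between line-level summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats


class UsageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trace summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    mc_error: float


def batch_means_mc_error(values: np.ndarray, n_batches: int = 50) -> float:
    """Monte Carlo standard error of the mean by the batch-means method.

    The draws are cut into ``n_batches`` equal batches (default 50, the
    WinBUGS-compatible choice; a trailing remainder is dropped) and the MC
    error is the standard error of the batch means.  Falls back to the
    naive iid estimate when there are too few draws to form 2 batches of 2.
    """
    values = np.asarray(values, dtype=float).reshape(-1)
    n = values.size
    if n < 2:
        return 0.0
    batch_size = n // n_batches
    if batch_size < 2:
        n_batches = max(n // 2, 2)
        batch_size = n // n_batches
    if batch_size < 1 or n_batches < 2:
        return float(np.std(values, ddof=1) / math.sqrt(n))
    used = values[: n_batches * batch_size]
    means = used.reshape(n_batches, batch_size).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_batches))


def summarize_trace(values) -> PosteriorSummary:
    """Posterior mean, SD (n−1), empirical 2.5/97.5% CI and MC error."""
    values = np.asarray(values, dtype=float).reshape(-1)
    if values.size == 0:
        raise UsageError("cannot summarize an empty trace")
    lo, hi = np.percentile(values, [2.5, 97.5])
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return PosteriorSummary(
        mean=float(np.mean(values)),
        sd=sd,
        ci_low=float(lo),
        ci_high=float(hi),
        mc_error=batch_means_mc_error(values),
    )


# ---------------------------------------------------------------------------
# Variance components / ICC
# ---------------------------------------------------------------------------

def icc_sd_scale(sd_among: float, sd_resid: float) -> float:
    """Among-line share of dispersion on the SD scale:
    sigma_among / (sigma_among + sigma)."""
    if sd_among < 0 or sd_resid < 0:
        raise UsageError("dispersions must be non-negative")
    total = sd_among + sd_resid
    return 0.0 if total == 0 else sd_among / total


def icc_variance_scale(sd_among: float, sd_resid: float) -> float:
    """Among-line share of variance:
    sigma_among^2 / (sigma_among^2 + sigma^2)."""
    if sd_among < 0 or sd_resid < 0:
        raise UsageError("dispersions must be non-negative")
    total = sd_among**2 + sd_resid**2
    return 0.0 if total == 0 else sd_among**2 / total


@dataclass(frozen=True)
class VarianceComponents:
    """Among-line vs residual dispersion of a common-variance fit.

    Both intraclass-correlation variants are reported because they answer
    the same question on different scales and differ numerically: the
    variance-scale share follows the textbook formula
    ``sigma2_among / (sigma2_among + sigma2)``; the SD-scale share
    ``sigma_among / (sigma_among + sigma)`` is what the published
    percentages (65% and 80%) correspond to.
    """

    sigma_among: PosteriorSummary
    sigma_resid: PosteriorSummary
    icc_variance_scale: float
    icc_sd_scale: float

    @property
    def icc_variance_pct(self) -> int:
        return round(100 * self.icc_variance_scale)

    @property
    def icc_sd_pct(self) -> int:
        return round(100 * self.icc_sd_scale)


def variance_components(fit) -> VarianceComponents:
    """Decompose dispersion from a common-variance hierarchical fit.

    Requires a fit of model 2 (or its block-effect extension, model 5),
    whose trace contains ``sigma2_among`` and ``sigma2_resid``.  ICCs are
    computed from the posterior-mean dispersions on each scale.
    """
    model = getattr(fit, "model", None)
    if model not in (2, 5):
        raise UsageError(
            f"variance components need a common-variance fit (model 2 or 5), got model {model}"
        )
    sd_among_draws = np.sqrt(fit.trace_["sigma2_among"].reshape(-1))
    sd_resid_draws = np.sqrt(fit.trace_["sigma2_resid"].reshape(-1))
    s_among = summarize_trace(sd_among_draws)
    s_resid = summarize_trace(sd_resid_draws)
    return VarianceComponents(
        sigma_among=s_among,
        sigma_resid=s_resid,
        icc_variance_scale=icc_variance_scale(
            float(np.mean(sd_among_draws**2)) ** 0.5,
            float(np.mean(sd_resid_draws**2)) ** 0.5,
        ),
        icc_sd_scale=icc_sd_scale(s_among.mean, s_resid.mean),
    )


# ---------------------------------------------------------------------------
# Per-line summaries
# ---------------------------------------------------------------------------

def line_summaries(data, fit3=None) -> pd.DataFrame:
    """Per-line mean, SD and CV of lifetime fecundity, pooled over blocks.

    ``data`` must be a single-food dataset.  The CV is sample SD (n−1
    denominator) over sample mean; it is undefined (NaN, ``cv_defined``
    False) for lines with fewer than two observations or zero mean.  When a
    line-variance fit (model 3 or 4) on the same data is supplied, its
    posterior within-line variance summaries are attached.
    """
    if len(data.foods) != 1:
        raise UsageError("line summaries require a single-food dataset")
    rows = []
    for line in data.lines:
        vals = data.df.loc[data.df["line_id"] == line, "lifetime_fecundity"].to_numpy()
        n = len(vals)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n >= 2 else float("nan")
        defined = n >= 2 and mean != 0.0
        rows.append(
            {
                "line_id": line,
                "n": n,
                "mean_lf": mean,
                "sd_lf": sd,
                "cv": sd / mean if defined else float("nan"),
                "cv_defined": defined,
            }
        )
    out = pd.DataFrame(rows)
    if fit3 is not None:
        if getattr(fit3, "model", None) not in (3, 4):
            raise UsageError("fit3 must be a line-variance fit (model 3 or 4)")
        if list(fit3.lines_) != list(data.lines):
            raise UsageError("fit3 was fitted on a different set of lines")
        arr = fit3.trace_["sigma2_within"]
        pooled = arr.reshape(-1, arr.shape[2])
        summ = [summarize_trace(pooled[:, j]) for j in range(pooled.shape[1])]
        out["within_var_mean"] = [s.mean for s in summ]
        out["within_var_ci_low"] = [s.ci_low for s in summ]
        out["within_var_ci_high"] = [s.ci_high for s in summ]
    return out


def fold_range(values) -> float:
    """max/min ratio of a collection of positive values (e.g. within-line
    variances across lines)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.any(values <= 0):
        raise UsageError("fold_range requires positive values")
    return float(values.max() / values.min())


# ---------------------------------------------------------------------------
# Rank correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


def spearman_correlation(x, y, *, exact_below: int = 10) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n >= ``exact_below`` the p-value uses
    the usual t approximation; below that, it is computed exactly by full
    enumeration of the n! rank permutations.  If either argument has
    constant ranks the correlation is degenerate and reported as rho=0
    with ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UsageError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 4:
        raise UsageError("need at least 4 pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return CorrelationResult(rho=0.0, p_value=1.0, n=n, degenerate=True)
    if n >= exact_below:
        rho, p = stats.spearmanr(x, y)
        return CorrelationResult(rho=float(rho), p_value=float(p), n=n)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    # exact two-sided permutation p-value on |rho|
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    perms = np.array(list(permutations(ry_c)))
    stats_all = perms @ rx_c / denom
    p = float(np.mean(np.abs(stats_all) >= abs(rho) - 1e-12))
    return CorrelationResult(rho=rho, p_value=p, n=n)


def mean_cv_relationship(summaries: pd.DataFrame) -> CorrelationResult:
    """Spearman correlation between line mean fecundity and line CV."""
    sub = summaries[summaries["cv_defined"]]
    if len(sub) < 4:
        raise UsageError("need at least 4 lines with a defined CV")
    return spearman_correlation(sub["mean_lf"].to_numpy(), sub["cv"].to_numpy())


def cross_environment_cv(
    summaries_env1: pd.DataFrame, summaries_env2: pd.DataFrame
) -> CorrelationResult:
    """Spearman correlation of line CVs across two food environments.

    Lines are matched by ``line_id``; a mismatch in the line sets is a
    usage error naming the offending lines.
    """
    s1 = set(summaries_env1["line_id"])
    s2 = set(summaries_env2["line_id"])
    if s1 != s2:
        raise UsageError(
            f"line sets differ between environments: only in env1 {sorted(s1 - s2)}, "
            f"only in env2 {sorted(s2 - s1)}"
        )
    merged = summaries_env1.merge(
        summaries_env2, on="line_id", suffixes=("_1", "_2")
    )
    merged = merged[merged["cv_defined_1"] & merged["cv_defined_2"]]
    if len(merged) < 4:
        raise UsageError("need at least 4 lines with defined CVs in both environments")
    return spearman_correlation(
        merged["cv_1"].to_numpy(), merged["cv_2"].to_numpy()
    )
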