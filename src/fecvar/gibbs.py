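"""Gibbs samplers for hierarchical normal models of lifetime fecundity.

Five nested Gaussian models of individual lifetime fecundity ``LF_i`` are
supported, indexed by ``model``:

1. ``LF_i ~ N(mu, sigma2)`` — one grand mean and variance.
2. ``LF_i ~ N(mu_j, sigma2)`` — each line j has its own mean,
   ``mu_j ~ N(theta, sigma2_among)``; one residual variance.
3. ``LF_i ~ N(mu_j, sigma2_within_j)`` — each line additionally has its own
   within-line variance; ``mu_j ~ N(theta, sigma2_among)``.
4. Model 3 plus an additive block effect ``alpha_k ~ N(0, 1)``.
5. Model 2 plus the block effect ``alpha_k ~ N(0, 1)``.

Priors follow the diffuse-conjugate convention of the BUGS family: location
parameters get ``N(0, 1e10)`` (parameterized here by *variance*), every
precision ``tau = 1/sigma2`` gets ``Gamma(0.001, 0.001)`` (shape–rate), and
block effects get ``N(0, 1)``.  All full conditionals are then normal or
gamma, so the sampler is a systematic-scan Gibbs sampler with a fixed
update order (line means, hyper-mean, precisions, block effects) and no
Metropolis step.  The deviance ``-2 log p(y | state)`` is recorded at every
kept draw to support DIC computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataio import Dataset
from .posterior import batch_means_mc_error, summarize_trace

_LOG_2PI = float(np.log(2.0 * np.pi))

VALID_MODELS = (1, 2, 3, 4, 5)
#: models with line-specific means / variances / block effects
_LINE_MEAN_MODELS = (2, 3, 4, 5)
_LINE_VAR_MODELS = (3, 4)
_BLOCK_MODELS = (4, 5)


@dataclass(frozen=True)
class PriorSettings:
    """Hyperparameters of the diffuse conjugate priors."""

    normal_hyper_mean: float = 0.0
    normal_hyper_variance: float = 1e10
    gamma_shape: float = 0.001
    gamma_rate: float = 0.001
    block_prior_variance: float = 1.0

    def __post_init__(self) -> None:
        if min(self.normal_hyper_variance, self.block_prior_variance) <= 0:
            raise ValueError("prior variances must be > 0")
        if min(self.gamma_shape, self.gamma_rate) <= 0:
            raise ValueError("gamma shape and rate must be > 0")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain-length settings; defaults follow the study protocol
    (10,000 burn-in iterations followed by 10,000 sampling updates)."""

    burn_in: int = 10000
    draws: int = 10000
    thin: int = 1
    chains: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.draws < 1 or self.thin < 1 or self.chains < 1:
            raise ValueError("invalid MCMC settings")


@dataclass
class ConvergenceReport:
    """Batch-means Monte-Carlo-error diagnostics for one fit."""

    threshold: float
    ratios: dict[str, float]
    flagged: list[str]
    suspect: bool
    rhat: dict[str, float] | None = None
    notes: list[str] = field(default_factory=list)


class UsageError(ValueError):
    """The sampler was called on data it refuses (e.g. mixed foods)."""


class GibbsFecundityModel(BaseEstimator):
    """Hierarchical Bayesian model of lifetime fecundity, fitted by Gibbs.

    Parameters
    ----------
    model : int in {1, 2, 3, 4, 5}
        Which of the nested models to fit (see module docstring).
    burn_in, draws, thin, chains : int
        MCMC protocol; ``draws`` counts post-burn-in updates, of which every
        ``thin``-th is kept.
    seed : int or None
        Seed for the chain(s); identical seed gives an identical fit.
    normal_hyper_mean, normal_hyper_variance, gamma_shape, gamma_rate,
    block_prior_variance : float
        Prior hyperparameters (see :class:`PriorSettings`).

    Attributes
    ----------
    trace_ : dict of str -> ndarray
        Post-burn-in draws, shaped ``(chains, kept)`` for scalars and
        ``(chains, kept, J or K)`` for vector parameters.  Variance
        parameters are stored on the variance scale.
    deviance_ : ndarray of shape (chains, kept)
        ``-2 log p(y | state)`` at each kept draw.
    summaries_ : pandas.DataFrame
        Posterior mean, sd, 2.5/97.5% interval and batch-means MC error per
        scalar parameter component (chains pooled).
    dic_ : DICStats
        Deviance information criterion statistics.
    convergence_ : ConvergenceReport
        MC-error ratios against the 5%-of-posterior-SD criterion.
    """

    def __init__(
        self,
        model: int = 3,
        *,
        burn_in: int = 10000,
        draws: int = 10000,
        thin: int = 1,
        chains: int = 1,
        seed: int | None = None,
        normal_hyper_mean: float = 0.0,
        normal_hyper_variance: float = 1e10,
        gamma_shape: float = 0.001,
        gamma_rate: float = 0.001,
        block_prior_variance: float = 1.0,
    ) -> None:
        self.model = model
        self.burn_in = burn_in
        self.draws = draws
        self.thin = thin
        self.chains = chains
        self.seed = seed
        self.normal_hyper_mean = normal_hyper_mean
        self.normal_hyper_variance = normal_hyper_variance
        self.gamma_shape = gamma_shape
        self.gamma_rate = gamma_rate
        self.block_prior_variance = block_prior_variance

    # ------------------------------------------------------------------
    def _priors(self) -> PriorSettings:
        return PriorSettings(
            normal_hyper_mean=self.normal_hyper_mean,
            normal_hyper_variance=self.normal_hyper_variance,
            gamma_shape=self.gamma_shape,
            gamma_rate=self.gamma_rate,
            block_prior_variance=self.block_prior_variance,
        )

    def _mcmc(self) -> MCMCSettings:
        return MCMCSettings(
            burn_in=self.burn_in,
            draws=self.draws,
            thin=self.thin,
            chains=self.chains,
            seed=self.seed,
        )

    # ------------------------------------------------------------------
    def fit(self, data: Dataset | pd.DataFrame, y=None) -> "GibbsFecundityModel":
        """Run the Gibbs sampler on a single-food dataset."""
        if self.model not in VALID_MODELS:
            raise UsageError(f"model must be one of {VALID_MODELS}, got {self.model}")
        priors = self._priors()
        mcmc = self._mcmc()
        if not isinstance(data, Dataset):
            data = Dataset(pd.DataFrame(data))
        if data.n_obs == 0:
            raise UsageError("cannot fit an empty dataset")
        foods = data.foods
        if len(foods) != 1:
            raise UsageError(
                f"fit requires a single food environment, got {foods}; "
                "use dataio.split_by_food first"
            )
        lines = data.lines
        blocks = data.blocks
        if self.model >= 2 and len(lines) < 2:
            raise UsageError(f"model {self.model} needs at least 2 lines")
        if self.model in _BLOCK_MODELS and len(blocks) < 2:
            raise UsageError(f"model {self.model} needs at least 2 blocks")

        df = data.df
        line_code = {lab: i for i, lab in enumerate(lines)}
        block_code = {lab: i for i, lab in enumerate(blocks)}
        j_idx = df["line_id"].map(line_code).to_numpy(dtype=np.intp)
        k_idx = df["block"].map(block_code).to_numpy(dtype=np.intp)
        y_arr = df["lifetime_fecundity"].to_numpy(dtype=float)
        # canonical internal order makes the fit exactly invariant to the
        # ordering of rows in the input table
        order = np.lexsort((y_arr, k_idx, j_idx))
        y_arr, j_idx, k_idx = y_arr[order], j_idx[order], k_idx[order]

        self.food_ = foods[0]
        self.lines_ = lines
        self.blocks_ = blocks
        self.y_ = y_arr
        self.line_index_ = j_idx
        self.block_index_ = k_idx
        self.n_obs_ = len(y_arr)

        notes: list[str] = []
        n_j = np.bincount(j_idx, minlength=len(lines)).astype(float)
        if self.model in _LINE_VAR_MODELS and np.any(n_j < 2):
            thin_lines = [lines[i] for i in np.flatnonzero(n_j < 2)]
            notes.append(
                "line(s) with fewer than 2 observations under a line-variance "
                f"model: {thin_lines}; their variance posteriors are prior-driven"
            )
        self._notes = notes

        kept = mcmc.draws // mcmc.thin
        if kept < 1:
            raise UsageError("draws // thin must be at least 1")
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
        chain_traces = [
            self._run_chain(np.random.default_rng(s), priors, mcmc, kept)
            for s in seeds
        ]
        self.trace_ = {
            key: np.stack([t[key] for t in chain_traces])
            for key in chain_traces[0]
            if key != "deviance"
        }
        self.deviance_ = np.stack([t["deviance"] for t in chain_traces])

        self.summaries_ = self._summarize()
        from .selection import compute_dic  # local import avoids cycle at import time

        self.dic_ = compute_dic(self)
        self.convergence_ = diagnose_convergence(self)
        return self

    # ------------------------------------------------------------------
    def _run_chain(
        self,
        rng: np.random.Generator,
        priors: PriorSettings,
        mcmc: MCMCSettings,
        kept: int,
    ) -> dict[str, np.ndarray]:
        y, j_idx, k_idx = self.y_, self.line_index_, self.block_index_
        model = self.model
        n = len(y)
        J, K = len(self.lines_), len(self.blocks_)
        a, b = priors.gamma_shape, priors.gamma_rate
        m0, v0 = priors.normal_hyper_mean, priors.normal_hyper_variance
        vb = priors.block_prior_variance

        n_j = np.bincount(j_idx, minlength=J).astype(float)
        n_k = np.bincount(k_idx, minlength=K).astype(float)
        sum_y_j = np.bincount(j_idx, weights=y, minlength=J)

        # deterministic initialization: sample means, 1/sample-variance
        grand_mean = float(np.mean(y))
        grand_var = max(float(np.var(y)), 1e-8)
        mu = grand_mean
        theta = grand_mean
        mu_line = np.where(n_j > 0, sum_y_j / np.maximum(n_j, 1.0), grand_mean)
        tau_resid = 1.0 / grand_var
        line_var = np.full(J, grand_var)
        for j in range(J):
            if n_j[j] >= 2:
                line_var[j] = max(float(np.var(y[j_idx == j], ddof=1)), 1e-8)
        tau_within = 1.0 / line_var
        tau_among = 1.0 / max(float(np.var(mu_line, ddof=1)) if J >= 2 else grand_var, 1e-8)
        alpha = np.zeros(K)

        out: dict[str, np.ndarray] = {"deviance": np.empty(kept)}
        if model == 1:
            out["mu"] = np.empty(kept)
            out["sigma2_resid"] = np.empty(kept)
        else:
            out["mu_line"] = np.empty((kept, J))
            out["theta"] = np.empty(kept)
            out["sigma2_among"] = np.empty(kept)
            if model in _LINE_VAR_MODELS:
                out["sigma2_within"] = np.empty((kept, J))
            else:
                out["sigma2_resid"] = np.empty(kept)
            if model in _BLOCK_MODELS:
                out["alpha_block"] = np.empty((kept, K))

        total = mcmc.burn_in + kept * mcmc.thin
        keep_at = mcmc.burn_in + mcmc.thin - 1  # first kept iteration index
        pos = 0
        for it in range(total):
            if model == 1:
                prec = tau_resid * n + 1.0 / v0
                mean = (tau_resid * y.sum() + m0 / v0) / prec
                mu = mean + rng.standard_normal() / np.sqrt(prec)
                ss = float(np.sum((y - mu) ** 2))
                tau_resid = rng.gamma(a + 0.5 * n, 1.0 / (b + 0.5 * ss))
            else:
                # line means
                if model in _BLOCK_MODELS:
                    resid_sum_j = np.bincount(
                        j_idx, weights=y - alpha[k_idx], minlength=J
                    )
                else:
                    resid_sum_j = sum_y_j
                tau_like = tau_within if model in _LINE_VAR_MODELS else tau_resid
                prec_j = tau_like * n_j + tau_among
                mean_j = (tau_like * resid_sum_j + tau_among * theta) / prec_j
                mu_line = mean_j + rng.standard_normal(J) / np.sqrt(prec_j)
                # hyper-mean
                prec_t = J * tau_among + 1.0 / v0
                mean_t = (tau_among * mu_line.sum() + m0 / v0) / prec_t
                theta = mean_t + rng.standard_normal() / np.sqrt(prec_t)
                # among-line precision
                ss_among = float(np.sum((mu_line - theta) ** 2))
                tau_among = rng.gamma(a + 0.5 * J, 1.0 / (b + 0.5 * ss_among))
                # residual / within-line precision(s)
                e = y - mu_line[j_idx]
                if model in _BLOCK_MODELS:
                    e = e - alpha[k_idx]
                if model in _LINE_VAR_MODELS:
                    ss_j = np.bincount(j_idx, weights=e * e, minlength=J)
                    tau_within = rng.gamma(
                        a + 0.5 * n_j, 1.0 / (b + 0.5 * ss_j)
                    )
                else:
                    tau_resid = rng.gamma(
                        a + 0.5 * n, 1.0 / (b + 0.5 * float(e @ e))
                    )
                # block effects
                if model in _BLOCK_MODELS:
                    r = y - mu_line[j_idx]
                    if model in _LINE_VAR_MODELS:
                        w = tau_within[j_idx]
                        prec_k = np.bincount(k_idx, weights=w, minlength=K) + 1.0 / vb
                        mean_k = (
                            np.bincount(k_idx, weights=w * r, minlength=K) / prec_k
                        )
                    else:
                        prec_k = tau_resid * n_k + 1.0 / vb
                        mean_k = (
                            tau_resid * np.bincount(k_idx, weights=r, minlength=K)
                        ) / prec_k
                    alpha = mean_k + rng.standard_normal(K) / np.sqrt(prec_k)

            if it >= keep_at and (it - keep_at) % mcmc.thin == 0:
                if model == 1:
                    out["mu"][pos] = mu
                    out["sigma2_resid"][pos] = 1.0 / tau_resid
                    dev = n * (_LOG_2PI - np.log(tau_resid)) + tau_resid * float(
                        np.sum((y - mu) ** 2)
                    )
                else:
                    out["mu_line"][pos] = mu_line
                    out["theta"][pos] = theta
                    out["sigma2_among"][pos] = 1.0 / tau_among
                    mean_i = mu_line[j_idx]
                    if model in _BLOCK_MODELS:
                        mean_i = mean_i + alpha[k_idx]
                        out["alpha_block"][pos] = alpha
                    e = y - mean_i
                    if model in _LINE_VAR_MODELS:
                        out["sigma2_within"][pos] = 1.0 / tau_within
                        tau_i = tau_within[j_idx]
                    else:
                        out["sigma2_resid"][pos] = 1.0 / tau_resid
                        tau_i = tau_resid
                    dev = float(
                        np.sum(_LOG_2PI - np.log(tau_i) + tau_i * e * e)
                    )
                out["deviance"][pos] = dev
                pos += 1
        return out

    # ------------------------------------------------------------------
    def scalar_traces(self, include_deviance: bool = False):
        """Yield ``(name, pooled 1-D draws)`` for every scalar component."""
        for key, arr in self.trace_.items():
            if arr.ndim == 2:  # (chains, kept)
                yield key, arr.reshape(-1)
            else:  # (chains, kept, dim)
                labels = self.blocks_ if key == "alpha_block" else self.lines_
                for d in range(arr.shape[2]):
                    yield f"{key}[{labels[d]}]", arr[:, :, d].reshape(-1)
        if include_deviance:
            yield "deviance", self.deviance_.reshape(-1)

    def _summarize(self) -> pd.DataFrame:
        rows = {}
        for name, draws in self.scalar_traces(include_deviance=True):
            s = summarize_trace(draws)
            rows[name] = {
                "mean": s.mean,
                "sd": s.sd,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "mc_error": s.mc_error,
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    # ------------------------------------------------------------------
    def posterior_mean_state(self) -> dict[str, np.ndarray | float]:
        """Plug-in state for DIC's Dhat.

        Location parameters are posterior means on their natural scale;
        variance parameters are plugged in as posterior-mean *precisions*
        (the BUGS convention), i.e. the plug-in variance is
        ``1 / E[1/sigma2]``.
        """
        state: dict[str, np.ndarray | float] = {}
        for key, arr in self.trace_.items():
            pooled = arr.reshape(-1, arr.shape[2]) if arr.ndim == 3 else arr.reshape(-1)
            if key.startswith("sigma2"):
                state[key] = 1.0 / np.mean(1.0 / pooled, axis=0)
            else:
                state[key] = np.mean(pooled, axis=0)
        return state

    def deviance_at(self, state: dict) -> float:
        """Evaluate ``-2 log p(y | state)`` at an explicit parameter state."""
        y, j_idx, k_idx = self.y_, self.line_index_, self.block_index_
        if self.model == 1:
            mean_i = np.full_like(y, float(np.asarray(state["mu"])))
            var_i = np.full_like(y, float(np.asarray(state["sigma2_resid"])))
        else:
            mean_i = np.asarray(state["mu_line"], dtype=float)[j_idx]
            if self.model in _BLOCK_MODELS:
                mean_i = mean_i + np.asarray(state["alpha_block"], dtype=float)[k_idx]
            if self.model in _LINE_VAR_MODELS:
                var_i = np.asarray(state["sigma2_within"], dtype=float)[j_idx]
            else:
                var_i = np.full_like(y, float(np.asarray(state["sigma2_resid"])))
        return float(np.sum(_LOG_2PI + np.log(var_i) + (y - mean_i) ** 2 / var_i))

    # ------------------------------------------------------------------
    def trace_frame(self) -> pd.DataFrame:
        """Kept draws as a tidy table (one column per scalar, plus deviance)."""
        cols = {
            name: draws for name, draws in self.scalar_traces(include_deviance=True)
        }
        return pd.DataFrame(cols)


def fit(
    model: int,
    data: Dataset,
    priors: PriorSettings | None = None,
    mcmc: MCMCSettings | None = None,
) -> GibbsFecundityModel:
    """Thin functional wrapper: fit one model and return the fitted estimator."""
    priors = priors or PriorSettings()
    mcmc = mcmc or MCMCSettings()
    est = GibbsFecundityModel(
        model=model,
        burn_in=mcmc.burn_in,
        draws=mcmc.draws,
        thin=mcmc.thin,
        chains=mcmc.chains,
        seed=mcmc.seed,
        normal_hyper_mean=priors.normal_hyper_mean,
        normal_hyper_variance=priors.normal_hyper_variance,
        gamma_shape=priors.gamma_shape,
        gamma_rate=priors.gamma_rate,
        block_prior_variance=priors.block_prior_variance,
    )
    return est.fit(data)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def _split_rhat(arr: np.ndarray) -> float:
    """Gelman split-chain potential-scale-reduction factor.

    ``arr`` has shape (chains, draws); each chain is split in half, giving
    2·chains sequences.
    """
    c, n = arr.shape
    half = n // 2
    if half < 2:
        return float("nan")
    seqs = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m, n2 = seqs.shape
    means = seqs.mean(axis=1)
    w = seqs.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def diagnose_convergence(
    fit_result: GibbsFecundityModel, threshold: float = 0.05
) -> ConvergenceReport:
    """Check each parameter's MC error against the posterior-SD criterion.

    The Monte Carlo error is estimated by batch means (50 batches).  A
    parameter is flagged when MC error exceeds ``threshold`` times its
    posterior SD — the study's criterion at the default 5% — and the fit is
    marked *suspect* when anything is flagged, the signature of a poorly
    mixing (e.g. non-identifiable) parameterization.  A constant trace has
    zero MC error and zero SD and is not flagged.  With two or more chains
    the split-chain R-hat is reported as well.
    """
    ratios: dict[str, float] = {}
    flagged: list[str] = []
    rhat: dict[str, float] | None = {} if fit_result.deviance_.shape[0] >= 2 else None
    for name, draws in fit_result.scalar_traces():
        sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
        mce = batch_means_mc_error(draws)
        ratio = 0.0 if sd == 0.0 else mce / sd
        ratios[name] = ratio
        if ratio > threshold:
            flagged.append(name)
    if rhat is not None:
        for key, arr in fit_result.trace_.items():
            if arr.ndim == 2:
                rhat[key] = _split_rhat(arr)
            else:
                for d in range(arr.shape[2]):
                    rhat[f"{key}[{d}]"] = _split_rhat(arr[:, :, d])
    return ConvergenceReport(
        threshold=threshold,
        ratios=ratios,
        flagged=flagged,
        suspect=bool(flagged),
        rhat=rhat,
        notes=list(getattr(fit_result, "_notes", [])),
    )
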