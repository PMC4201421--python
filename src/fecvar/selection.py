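"""Deviance information criterion (DIC) computation and model comparison.

DIC = Dbar + pD, where Dbar is the posterior mean of the deviance
(−2 log-likelihood) over the kept draws, Dhat is the deviance at a plug-in
state formed from posterior means of the sampled parameters, and
pD = Dbar − Dhat is the effective number of parameters.  Lower DIC is
better.  Differences between a simpler and a more complex model are read
on the conventional scale: ΔDIC < 2 is substantial support for the simpler
model, 4–7 considerably less, and > 10 essentially none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class UsageError(ValueError):
    pass


@dataclass(frozen=True)
class DICStats:
    """Dbar, Dhat and the derived pD and DIC (pD = Dbar − Dhat,
    DIC = Dbar + pD)."""

    dbar: float
    dhat: float

    @property
    def pd(self) -> float:
        return self.dbar - self.dhat

    @property
    def dic(self) -> float:
        return self.dbar + self.pd


#: ΔDIC (simpler − complex) interpretation bands.  The cited rubric names
#: <2, 4–7 and >10; the gaps 2–4 and 7–10 are labelled "intermediate".
CATEGORY_SUBSTANTIAL = "substantial support for simpler"
CATEGORY_INTERMEDIATE = "intermediate"
CATEGORY_CONSIDERABLY_LESS = "considerably less support for simpler"
CATEGORY_NONE = "essentially no support for simpler"


@dataclass(frozen=True)
class ComparisonResult:
    delta_dic: float
    category: str


def categorize_delta_dic(delta: float) -> str:
    if delta < 2:
        return CATEGORY_SUBSTANTIAL
    if delta < 4:
        return CATEGORY_INTERMEDIATE
    if delta <= 7:
        return CATEGORY_CONSIDERABLY_LESS
    if delta <= 10:
        return CATEGORY_INTERMEDIATE
    return CATEGORY_NONE


def compute_dic(fit, *, variance_plugin: str = "precision") -> DICStats:
    """DIC statistics of a fitted model.

    ``Dbar`` is the mean of the recorded deviance trace.  ``Dhat`` is the
    deviance at the posterior-mean state; by default variance parameters
    are plugged in as posterior-mean precisions (the convention of the BUGS
    family, against which published DIC tables were computed).  Pass
    ``variance_plugin="variance"`` to plug in posterior-mean variances
    instead, as a sensitivity check.
    """
    deviance = np.asarray(fit.deviance_).reshape(-1)
    if deviance.size == 0:
        raise UsageError("fit has an empty deviance trace")
    if variance_plugin not in ("precision", "variance"):
        raise UsageError("variance_plugin must be 'precision' or 'variance'")
    dbar = float(np.mean(deviance))
    if variance_plugin == "precision":
        state = fit.posterior_mean_state()
    else:
        state = {}
        for key, arr in fit.trace_.items():
            pooled = arr.reshape(-1, arr.shape[2]) if arr.ndim == 3 else arr.reshape(-1)
            state[key] = np.mean(pooled, axis=0)
    dhat = fit.deviance_at(state)
    return DICStats(dbar=dbar, dhat=dhat)


def compare_models(fit_simple, fit_complex) -> ComparisonResult:
    """ΔDIC between a simpler and a more complex fit of the same data.

    ΔDIC = DIC(simple) − DIC(complex); the category follows the
    ΔDIC rubric (see :func:`categorize_delta_dic`).
    """
    if not np.array_equal(np.sort(fit_simple.y_), np.sort(fit_complex.y_)):
        raise UsageError("the two fits were not computed on the same dataset")
    dic_s = fit_simple.dic_.dic
    dic_c = fit_complex.dic_.dic
    delta = dic_s - dic_c
    return ComparisonResult(delta_dic=delta, category=categorize_delta_dic(delta))


def dic_table(fits) -> pd.DataFrame:
    """A report table (rows = models; columns Dbar, Dhat, pD, DIC)."""
    rows = {}
    for fit in fits:
        d = fit.dic_
        rows[f"Model {fit.model}"] = {
            "Dbar": d.dbar,
            "Dhat": d.dhat,
            "pD": d.pd,
            "DIC": d.dic,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
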