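"""End-to-end analysis: simulate/load, fit per food, compare, summarize.

``run_full_analysis`` drives the whole workflow the package exists for:
each food environment is analysed separately; the requested models are
fitted by Gibbs sampling; a DIC table and the ΔDIC decisions are computed
(including the block-effect checks, models 2 vs 5 and 3 vs 4, when those
models are requested); variance components come from the common-variance
model, per-line summaries and within-line variances from the line-variance
model; and line-level CV correlations are computed within and, when two
foods are present, across environments.  All artifacts are plain delimited
tables plus a JSON run manifest, and the run is fully determined by
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataio import Dataset, read_fecundity_table, split_by_food, write_fecundity_table
from .gibbs import GibbsFecundityModel, MCMCSettings, PriorSettings, fit as fit_model
from .posterior import (
    cross_environment_cv,
    line_summaries,
    mean_cv_relationship,
    variance_components,
)
from .selection import compare_models, dic_table

#: model pairs compared as (simpler, more complex)
_COMPARISONS = [(1, 2), (2, 3), (2, 5), (3, 4)]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of a full analysis run.

    Exactly one of ``input_path`` (a fecundity table) or
    ``synthetic`` (a :class:`~fecvar.simulate.SyntheticConfig` /
    :class:`~fecvar.simulate.PairedEnvironmentConfig`) must be given.
    Model 4 is excluded from the default model set: with per-line variances
    and free block effects it is the parameterization reported as
    non-identifiable, and requesting it engages the convergence gate rather
    than silent acceptance.
    """

    input_path: str | None = None
    synthetic: object | None = None
    allow_negative: bool = False
    models: tuple[int, ...] = (1, 2, 3, 5)
    priors: PriorSettings = field(default_factory=PriorSettings)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    seed: int | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model must be requested")
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("give exactly one of input_path or synthetic")


@dataclass
class FoodReport:
    food: str
    fits: dict[int, GibbsFecundityModel]
    dic_table: pd.DataFrame
    comparisons: pd.DataFrame
    best_model: int
    variance_components: object | None
    line_summaries: pd.DataFrame
    mean_cv: object | None
    convergence: pd.DataFrame


@dataclass
class AnalysisReport:
    per_food: dict[str, FoodReport]
    cross_food_cv: object | None
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("load")
def _load_data(config: AnalysisConfig) -> Dataset:
    from .simulate import (
        PairedEnvironmentConfig,
        generate_dataset,
        generate_paired_environments,
    )

    if config.input_path is not None:
        return read_fecundity_table(
            config.input_path, allow_negative=config.allow_negative
        )
    seed = np.random.SeedSequence(config.seed).spawn(1)[0]
    if isinstance(config.synthetic, PairedEnvironmentConfig):
        d1, d2 = generate_paired_environments(config.synthetic, seed)
        return Dataset(
            pd.concat([d1.df, d2.df], ignore_index=True),
            allow_negative=d1.allow_negative or d2.allow_negative,
        )
    return generate_dataset(config.synthetic, seed)


def _analyse_food(
    food: str, data: Dataset, config: AnalysisConfig, seed_seq: np.random.SeedSequence
) -> FoodReport:
    fits: dict[int, GibbsFecundityModel] = {}
    child_seeds = seed_seq.spawn(len(config.models))
    for model, child in zip(sorted(config.models), child_seeds):
        mcmc = dataclasses.replace(
            config.mcmc, seed=int(child.generate_state(1)[0] % (2**31))
        )
        fits[model] = fit_model(model, data, config.priors, mcmc)

    table = dic_table([fits[m] for m in sorted(fits)])
    comp_rows = []
    for simple, complex_ in _COMPARISONS:
        if simple in fits and complex_ in fits:
            res = compare_models(fits[simple], fits[complex_])
            comp_rows.append(
                {
                    "simpler": f"Model {simple}",
                    "complex": f"Model {complex_}",
                    "delta_dic": res.delta_dic,
                    "category": res.category,
                }
            )
    comparisons = pd.DataFrame(comp_rows)
    best = min(fits, key=lambda m: fits[m].dic_.dic)

    vc = None
    for m in (2, 5):
        if m in fits:
            vc = variance_components(fits[m])
            break
    fit3 = fits.get(3) or fits.get(4)
    lines = line_summaries(data, fit3)
    mean_cv = None
    if lines["cv_defined"].sum() >= 4:
        mean_cv = mean_cv_relationship(lines)

    conv_rows = []
    for m, f in fits.items():
        conv_rows.append(
            {
                "model": m,
                "max_mc_error_ratio": max(f.convergence_.ratios.values()),
                "n_flagged": len(f.convergence_.flagged),
                "flagged": ";".join(f.convergence_.flagged),
                "suspect": f.convergence_.suspect,
            }
        )
    return FoodReport(
        food=food,
        fits=fits,
        dic_table=table,
        comparisons=comparisons,
        best_model=best,
        variance_components=vc,
        line_summaries=lines,
        mean_cv=mean_cv,
        convergence=pd.DataFrame(conv_rows),
    )


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the complete analysis described in the module docstring."""
    data = _load_data(config)
    by_food = split_by_food(data)
    root = np.random.SeedSequence(config.seed)
    food_seeds = root.spawn(len(by_food) + 1)

    per_food: dict[str, FoodReport] = {}
    for (food, sub), seq in zip(sorted(by_food.items()), food_seeds):
        try:
            per_food[food] = _analyse_food(food, sub, config, seq)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage 'analyse[{food}]' failed: {exc}") from exc

    cross = None
    if len(per_food) == 2:
        r1, r2 = [per_food[f] for f in sorted(per_food)]
        common = set(r1.line_summaries["line_id"]) == set(r2.line_summaries["line_id"])
        if common:
            cross = cross_environment_cv(r1.line_summaries, r2.line_summaries)

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "models": sorted(config.models),
        "mcmc": dataclasses.asdict(config.mcmc),
        "priors": dataclasses.asdict(config.priors),
        "input": config.input_path or repr(config.synthetic),
        "foods": sorted(per_food),
        "n_obs_per_food": {f: per_food[f].line_summaries["n"].sum().item() for f in per_food},
    }
    report = AnalysisReport(per_food=per_food, cross_food_cv=cross, manifest=manifest)
    if config.output_dir is not None:
        write_report(report, config.output_dir, data=data)
    return report


def write_report(report: AnalysisReport, outdir, *, data: Dataset | None = None) -> None:
    """Write all report artifacts as CSV/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        if data is not None:
            write_fecundity_table(data, out / "data.csv")
        for food, rep in report.per_food.items():
            pre = out / food
            pre.mkdir(exist_ok=True)
            rep.dic_table.to_csv(pre / "dic_table.csv")
            rep.comparisons.to_csv(pre / "delta_dic.csv", index=False)
            rep.line_summaries.to_csv(pre / "line_summaries.csv", index=False)
            rep.convergence.to_csv(pre / "convergence.csv", index=False)
            for m, f in rep.fits.items():
                f.summaries_.to_csv(pre / f"model{m}_summary.csv")
                f.trace_frame().to_csv(pre / f"model{m}_trace.csv", index=False)
            extras = {"best_model": rep.best_model}
            if rep.variance_components is not None:
                vc = rep.variance_components
                extras["variance_components"] = {
                    "sigma_among_mean": vc.sigma_among.mean,
                    "sigma_among_ci": [vc.sigma_among.ci_low, vc.sigma_among.ci_high],
                    "sigma_resid_mean": vc.sigma_resid.mean,
                    "sigma_resid_ci": [vc.sigma_resid.ci_low, vc.sigma_resid.ci_high],
                    "icc_sd_pct": vc.icc_sd_pct,
                    "icc_variance_pct": vc.icc_variance_pct,
                }
            if rep.mean_cv is not None:
                extras["mean_cv_spearman"] = {
                    "rho": rep.mean_cv.rho,
                    "p_value": rep.mean_cv.p_value,
                    "n": rep.mean_cv.n,
                }
            (pre / "summary.json").write_text(json.dumps(extras, indent=2))
        if report.cross_food_cv is not None:
            c = report.cross_food_cv
            (out / "cross_food_cv.json").write_text(
                json.dumps({"rho": c.rho, "p_value": c.p_value, "n": c.n}, indent=2)
            )
        (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
    except Exception as exc:  # noqa: BLE001
        (out / "FAILED").write_text(f"report writing failed: {exc}\n")
        raise PipelineError(f"stage 'write_report' failed: {exc}") from exc
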