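"""End-to-end pipeline: cohort -> filters -> estimates -> theory -> report.

``run_pipeline`` simulates (from a preset) or loads (from CSV) a cohort,
applies the parental-survival inclusion filters, builds the per-delivery
analysis table, fits the selected twin-effect regressions, compares the
estimates against the closed-form no-control / full-control expectations,
bounds the controller share, runs the data-quality diagnostics, and writes a
report bundle (CSV + JSON + Markdown).  Outputs are deterministic given the
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import control_theory, data_diagnostics, twin_estimators
from .cohort_model import (
    FilterPolicy,
    apply_filters,
    build_analysis_table,
    cohort_summary,
    read_cohort_csv,
    write_cohort_csv,
)
from .control_theory import TheoryParams
from .synthetic_cohort import scenario_presets, simulate_cohort, SimConfig
from .twin_estimators import TwinEffectEstimate, UnidentifiedError

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_report"]

logger = logging.getLogger("twinstest")

DEFAULT_ESTIMATORS = ("alpha_b", "alpha_c", "alpha_b_nonparametric", "lambda_b", "lambda_c", "omega")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input`` (cohort CSV path) or ``preset`` (simulation
    preset name) must be given.  ``theory='from-data'`` estimates theta_s,
    theta_t and mean births from the cohort itself; pass a TheoryParams to
    override.
    """

    input: Optional[Union[str, Path]] = None
    preset: Optional[str] = None
    n_families: int = 50_000
    seed: Optional[int] = None
    sim_config: Optional[SimConfig] = None
    filters: FilterPolicy = field(default_factory=FilterPolicy)
    estimators: tuple[str, ...] = DEFAULT_ESTIMATORS
    theory: Union[str, TheoryParams] = "from-data"
    output_dir: Optional[Union[str, Path]] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input is None) == (self.preset is None and self.sim_config is None):
            raise ValueError("give exactly one of: an input CSV path, or a preset/sim_config")
        unknown = set(self.estimators) - set(DEFAULT_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimator flags: {sorted(unknown)}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc

        return wrapped

    return deco


@_stage("load")
def _load_cohort(config: RunConfig):
    if config.input is not None:
        logger.info("loading cohort from %s", config.input)
        return read_cohort_csv(config.input)
    sim = config.sim_config or scenario_presets(config.preset, n_families=config.n_families, seed=config.seed)
    if config.sim_config is None and config.seed is not None:
        sim = sim.replace(seed=config.seed)
    logger.info("simulating %d families", sim.n_families)
    return simulate_cohort(sim)


@_stage("filter")
def _filter(families, policy: FilterPolicy):
    kept = apply_filters(families, policy)
    logger.info("filters kept %d of %d families", len(kept), len(families))
    if not any(f.deliveries for f in kept):
        raise ValueError("no families with deliveries remain after the inclusion filters")
    return kept


@_stage("estimate")
def _estimate(table, which: tuple[str, ...]) -> dict[str, Optional[TwinEffectEstimate]]:
    out: dict[str, Optional[TwinEffectEstimate]] = {}

    def run(flag, fn):
        if flag not in which:
            out[flag] = None
            return
        try:
            out[flag] = fn()
        except UnidentifiedError as exc:
            logger.warning("%s unidentified: %s", flag, exc)
            out[flag] = None

    run("alpha_b", lambda: twin_estimators.estimate_twin_effect(table, "births", "parametric"))
    run("alpha_c", lambda: twin_estimators.estimate_twin_effect(table, "survivors", "parametric"))
    run(
        "alpha_b_nonparametric",
        lambda: twin_estimators.estimate_twin_effect(table, "births", "nonparametric"),
    )
    if "lambda_b" in which:
        try:
            _, out["lambda_b"] = twin_estimators.estimate_parity_interaction(table, "births")
        except UnidentifiedError as exc:
            logger.warning("lambda_b unidentified: %s", exc)
            out["lambda_b"] = None
    else:
        out["lambda_b"] = None
    if "lambda_c" in which:
        try:
            _, out["lambda_c"] = twin_estimators.estimate_parity_interaction(table, "survivors")
        except UnidentifiedError as exc:
            logger.warning("lambda_c unidentified: %s", exc)
            out["lambda_c"] = None
    else:
        out["lambda_c"] = None
    run("omega", lambda: twin_estimators.estimate_post_twin_interval(table))
    return out


@_stage("theory")
def _theory_comparison(estimates, params: TheoryParams) -> dict:
    comparison: dict[str, dict] = {
        "params": {
            "theta_s": params.theta_s,
            "theta_t": params.theta_t,
            "phi": params.phi,
            "mean_births": params.mean_births,
        }
    }
    for outcome, flag, expected_fn in (
        ("births", "alpha_b", control_theory.expected_extra_births),
        ("survivors", "alpha_c", control_theory.expected_extra_survivors),
    ):
        nc = expected_fn(params, "no_control")
        fc = expected_fn(params, "full_control")
        entry = {"expected_no_control": nc, "expected_full_control": fc}
        est = estimates.get(flag)
        if est is not None and nc != fc:
            bound = control_theory.controller_share_bound(
                est.coefficient, est.std_error, nc, fc, confidence=0.95, side="one_sided_upper"
            )
            entry.update(
                estimate=est.coefficient,
                se=est.std_error,
                n=est.n_obs,
                controller_share_point=min(
                    1.0, max(0.0, (nc - est.coefficient) / (nc - fc))
                ),
                controller_share_upper_95=bound.upper,
            )
        comparison[outcome] = entry
    return comparison


def _estimate_to_json(est: Optional[TwinEffectEstimate]) -> Optional[dict]:
    if est is None:
        return None
    return {
        "coefficient": est.coefficient,
        "se": est.std_error,
        "n": est.n_obs,
        "variant": est.variant,
        "outcome": est.outcome,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict and, if
    ``config.output_dir`` is set, writes it to disk."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    families = _load_cohort(config)
    kept = _filter(families, config.filters)

    try:
        table = build_analysis_table(kept)
    except Exception as exc:
        raise PipelineError(f"stage 'table': {exc}") from exc

    estimates = _estimate(table, config.estimators)

    summary = cohort_summary(kept)
    if isinstance(config.theory, TheoryParams):
        params = config.theory
    else:
        if config.theory != "from-data":
            raise PipelineError("stage 'theory': theory must be 'from-data' or a TheoryParams")
        params = TheoryParams.from_summary(summary)
    theory = _theory_comparison(estimates, params)

    try:
        diagnostics = {"summary": summary}
        quality = data_diagnostics.same_sex_diagnostic(kept)
        diagnostics["same_sex"] = {
            "R_t": quality.R_t,
            "R_ss_observed": quality.R_ss_observed,
            "R_ss_expected": quality.R_ss_expected,
            "phi_det": quality.phi_det,
            "n_twin_pairs": quality.n_twin_pairs,
        }
    except ValueError as exc:
        logger.warning("diagnostics: %s", exc)
        diagnostics["same_sex"] = None

    profiles = {
        outcome: twin_estimators.parity_profile(table, outcome) for outcome in ("births", "survivors")
    }

    bundle = {
        "estimates": {k: _estimate_to_json(v) for k, v in estimates.items()},
        "theory": theory,
        "diagnostics": diagnostics,
        "report_md": make_report(estimates, theory, diagnostics),
        "table": table,
        "profiles": profiles,
    }

    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "analysis_table.csv", index=False)
        for outcome, prof in profiles.items():
            prof.to_csv(outdir / f"parity_profile_{outcome}.csv", index=False)
        (outdir / "estimates.json").write_text(json.dumps(bundle["estimates"], indent=2))
        (outdir / "theory_comparison.json").write_text(json.dumps(theory, indent=2))
        (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
        (outdir / "report.md").write_text(bundle["report_md"])
        logger.info("report bundle written to %s", outdir)
    return bundle


def _fmt(x, nd=2) -> str:
    return "not computed" if x is None else f"{x:.{nd}f}"


def make_report(estimates: dict, theory: dict, diagnostics: dict) -> str:
    """Render a human-readable Markdown summary with three tables: the twin
    effect on births, on surviving children, and the controller-share bounds."""
    lines = ["# Twin-effect analysis report", ""]

    lines += ["## Twin effect on total births", ""]
    lines += ["| quantity | estimate | SE | N |", "|---|---|---|---|"]
    for flag, label in (
        ("alpha_b", "alpha (parametric)"),
        ("alpha_b_nonparametric", "alpha (nonparametric)"),
        ("lambda_b", "lambda (twin x parity)"),
        ("omega", "omega (post-twin interval, months)"),
    ):
        est = estimates.get(flag)
        if est is None:
            lines.append(f"| {label} | not computed | — | — |")
        else:
            lines.append(f"| {label} | {est.coefficient:.2f} | {est.std_error:.2f} | {est.n_obs} |")
    b = theory.get("births", {})
    lines += [
        "",
        f"Expected alpha: {_fmt(b.get('expected_no_control'))} (no control), "
        f"{_fmt(b.get('expected_full_control'))} (complete control).",
        "",
    ]

    lines += ["## Twin effect on surviving children", ""]
    lines += ["| quantity | estimate | SE | N |", "|---|---|---|---|"]
    for flag, label in (
        ("alpha_c", "alpha (parametric)"),
        ("lambda_c", "lambda (twin x parity)"),
    ):
        est = estimates.get(flag)
        if est is None:
            lines.append(f"| {label} | not computed | — | — |")
        else:
            lines.append(f"| {label} | {est.coefficient:.2f} | {est.std_error:.2f} | {est.n_obs} |")
    s = theory.get("survivors", {})
    lines += [
        "",
        f"Expected alpha: {_fmt(s.get('expected_no_control'))} (no control), "
        f"{_fmt(s.get('expected_full_control'))} (complete control).",
        "",
    ]

    lines += ["## Controller-share bounds (one-sided 95%)", ""]
    lines += ["| outcome | share point | upper bound |", "|---|---|---|"]
    for outcome in ("births", "survivors"):
        entry = theory.get(outcome, {})
        if "controller_share_upper_95" in entry:
            lines.append(
                f"| {outcome} | {entry['controller_share_point']:.2f} "
                f"| {entry['controller_share_upper_95']:.2f} |"
            )
        else:
            lines.append(f"| {outcome} | not computed | not computed |")

    same_sex = diagnostics.get("same_sex")
    lines += ["", "## Data quality", ""]
    if same_sex is None:
        lines.append("Same-sex diagnostic: not computed (no twin deliveries).")
    else:
        lines.append(
            f"Twinning rate R_t = {same_sex['R_t']:.2f} per 100 births; same-sex ratio "
            f"{same_sex['R_ss_observed']:.2f} observed vs {same_sex['R_ss_expected']:.2f} expected; "
            f"implied detection fraction {same_sex['phi_det']:.2f}."
        )
    summary = diagnostics.get("summary", {})
    if summary:
        lines.append(
            f"Mean births per family (with >= 1 birth): {summary['mean_births']:.2f}; "
            f"survival to 14: {summary['theta_s_hat']:.2f} singletons, {summary['theta_t_hat']:.2f} twins."
        )
    lines.append("")
    return "\n".join(lines)
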