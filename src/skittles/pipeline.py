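"""End-to-end analysis pipeline tying the stages together.

grid -> tolerance -> expected results (H1/H2) -> pooled fits -> per-subject
statistics (5x5 likelihood + AIC, ellipses + binomial overlap test,
variability regressions, practice curve), with every artifact written as
delimited text and the fully resolved configuration embedded for
provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as skio
from .execution_space import build_grid, extract_manifold, histogram_on_grid
from .subject_stats import (ModelFitResult, aic, compare_models,
                            confidence_ellipse, discretize_trials,
                            ellipse_overlap_binomial, log_likelihood,
                            practice_curve, predicted_cell_probs,
                            uniform_coverage_probability,
                            variability_regression)
from .synthetic import exp1_cohort_specs, generate_cohort
from .task_model import InvalidInputError, WorkspaceConfig
from .tolerance import (VariabilityProfile, compute_tolerance,
                        expected_result_h1, expected_result_h2, fit_params)

__all__ = ["PipelineConfig", "run_pipeline", "fit_subject"]

_STAGE_ORDER = ("grid", "tolerance", "expect", "fit", "stats")


@dataclass
class PipelineConfig:
    workspace: str = "exp1_calibrated"
    hypotheses: tuple[str, ...] = ("h1", "h2")
    profile: str = "pooled"            # "pooled" | "per-subject"
    n_angle: int = 360
    n_velocity: int = 360
    hist_bins: int = 36
    stages: tuple[str, ...] = _STAGE_ORDER
    drop_first_session: bool = True
    ellipse_convention: str = "chi2-95"
    figures: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        order = [s for s in _STAGE_ORDER if s in self.stages]
        if list(self.stages) != order:
            raise InvalidInputError(
                f"stages must follow the order {_STAGE_ORDER}, got {self.stages}")


def _pooled_profile(trials: pd.DataFrame) -> VariabilityProfile:
    per = trials.groupby("subject")[["angle_deg", "velocity_deg_s"]].std(ddof=1)
    return VariabilityProfile(sd_angle=float(per["angle_deg"].mean()),
                              sd_velocity=float(per["velocity_deg_s"].mean()))


def fit_subject(trials: pd.DataFrame, subject, grid, tmap, hypothesis: str,
                criterion: str = "ml", matrix_profile=None,
                a_grid=None, b_grid=None):
    """Fit the softmax parameters to one subject's 5x5 matrix and score it.

    Searches the log-spaced (a, b) lattice for the parameters that maximize
    the mean per-trial multinomial log likelihood of the subject's observed
    5x5 counts under the cell-integrated prediction (``criterion='lsq'``
    instead minimizes the squared frequency deviation, as used for the
    pooled fits).  The H2 candidate set includes b = inf, i.e. the H1
    restriction, which keeps the fitted models properly nested.
    """
    observed = discretize_trials(trials, subject, profile=matrix_profile)
    if a_grid is None:
        a_grid = np.logspace(0.0, 4.0, 41)
    if b_grid is None:
        b_grid = np.logspace(2.0, 5.0, 21)
    b_grid = np.concatenate([np.asarray(b_grid, float), [np.inf]])
    freq = observed.values / observed.values.sum()
    combos = ([(a, None) for a in a_grid] if hypothesis == "h1"
              else [(a, b) for a in a_grid for b in b_grid])
    best = None
    for a, b in combos:
        er = (expected_result_h1(tmap, a) if b is None
              else expected_result_h2(tmap, grid, a, b))
        p = predicted_cell_probs(er, observed)
        if criterion == "ml":
            score = -log_likelihood(observed, p)
        elif criterion == "lsq":
            score = float(np.sum((freq - p.values) ** 2))
        else:
            raise InvalidInputError(f"unknown fit criterion {criterion!r}")
        if best is None or score < best[0] - 1e-15:
            best = (score, a, b, p)
    _, a, b, pred = best
    LL = log_likelihood(observed, pred)
    return ModelFitResult(hypothesis=hypothesis, a=float(a),
                          b=None if b is None else float(b), LL=LL,
                          n_params=1 if hypothesis == "h1" else 2)


def run_pipeline(config: PipelineConfig, trials: pd.DataFrame | None = None,
                 cohort_specs=None) -> dict:
    """Run the configured stages and return (and optionally write) results."""
    ws = skio.load_workspace(config.workspace)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {"workspace": ws.to_dict(),
                     "pipeline": asdict(config)}

    if trials is None:
        if cohort_specs is None:
            cohort_specs = exp1_cohort_specs(ws, seed=config.seed)
        trials = generate_cohort(cohort_specs, ws)
    analysis = trials
    if config.drop_first_session and trials["session"].nunique() > 1:
        analysis = trials[trials["session"] > 1]

    grid = tmap = None
    ers: dict = {}
    if "grid" in config.stages:
        grid = build_grid(ws, config.n_angle, config.n_velocity)
        manifold = extract_manifold(grid)
        results["grid"] = {"n_angle": config.n_angle,
                           "n_velocity": config.n_velocity,
                           "post_hit_fraction": float(grid.post_hit_mask.mean()),
                           "manifold_points": len(manifold)}
        if out:
            skio.save_matrix(grid.error, out / "grid_error.csv",
                             sidecar=ws.to_dict())
            np.savetxt(out / "post_hit_mask.csv", grid.post_hit_mask.astype(int),
                       delimiter=",", fmt="%d")

    profile = _pooled_profile(analysis)
    results["pooled_profile"] = {"sd_angle": profile.sd_angle,
                                 "sd_velocity": profile.sd_velocity}

    if "tolerance" in config.stages:
        if grid is None:
            raise InvalidInputError("tolerance stage needs the grid stage output")
        tmap = compute_tolerance(grid, profile)
        if out:
            skio.save_matrix(tmap.T, out / "tolerance.csv",
                             sidecar={"sd_angle": profile.sd_angle,
                                      "sd_velocity": profile.sd_velocity})

    hist = histogram_on_grid(analysis["angle_deg"], analysis["velocity_deg_s"],
                             grid, config.hist_bins, config.hist_bins) \
        if grid is not None else None
    if out is not None and hist is not None:
        np.savetxt(out / f"histogram_{config.hist_bins}.csv", hist, delimiter=",")

    if "expect" in config.stages or "fit" in config.stages:
        if tmap is None:
            raise InvalidInputError("expected-result stage needs the tolerance map")
        for hyp in config.hypotheses:
            fp = fit_params(hist, tmap, grid, hypothesis=hyp)
            er = (expected_result_h1(tmap, fp.a) if hyp == "h1"
                  else expected_result_h2(tmap, grid, fp.a, fp.b))
            ers[hyp] = er
            results[f"pooled_fit_{hyp}"] = {
                "a": fp.a, "b": fp.b, "residual": fp.residual,
                "argmax": er.argmax}
            if out:
                skio.save_matrix(er.ER, out / f"expected_result_{hyp}.csv",
                                 sidecar={"hypothesis": hyp, "a": fp.a, "b": fp.b,
                                          "sd_angle": profile.sd_angle,
                                          "sd_velocity": profile.sd_velocity})

    if "stats" in config.stages:
        subjects = sorted(analysis["subject"].unique())
        table = []
        ellipses = {}
        for s in subjects:
            sub = analysis[analysis["subject"] == s]
            if config.profile == "per-subject":
                prof = VariabilityProfile(
                    sd_angle=float(sub["angle_deg"].std(ddof=1)),
                    sd_velocity=float(sub["velocity_deg_s"].std(ddof=1)))
                tm_s = compute_tolerance(grid, prof)
            else:
                tm_s = tmap
            row = {"subject": s, "n_trials": len(sub)}
            fits = {}
            for hyp in config.hypotheses:
                fit = fit_subject(analysis, s, grid, tm_s, hyp)
                fits[hyp] = fit
                row[f"a_{hyp}"] = fit.a
                if fit.b is not None:
                    row[f"b_{hyp}"] = fit.b
                row[f"LL_{hyp}"] = fit.LL
                row[f"AIC_{hyp}"] = fit.AIC
            if set(config.hypotheses) >= {"h1", "h2"}:
                row["winner"] = compare_models(fits["h1"], fits["h2"])["winner"]
            table.append(row)
            ellipses[s] = confidence_ellipse(analysis, s,
                                             convention=config.ellipse_convention)
        summary = pd.DataFrame(table)
        results["subject_table"] = summary

        if "h1" in ers:
            opt = ers["h1"].argmax
            k = sum(e.contains(opt) for e in ellipses.values())
            radius = float(np.mean([e.half_width_angle
                                    for e in ellipses.values()]))
            p_null = uniform_coverage_probability(
                min(radius, abs(np.diff(ws.angle_range)[0]) / 2.0 - 1e-9),
                *ws.angle_range)
            results["overlap_test"] = {
                "k_overlap": k, "n_subjects": len(subjects), "p_null": p_null,
                "p_value": ellipse_overlap_binomial(k, len(subjects), p_null)}

        try:
            reg = variability_regression(analysis)
            results["variability_regression"] = {
                key: asdict(reg[key]) for key in ("sd_angle", "sd_velocity")}
        except InvalidInputError:
            pass
        try:
            pc = practice_curve(trials)
            results["practice_curve"] = {"c": pc.c, "d": pc.d, "lam": pc.lam}
        except InvalidInputError:
            pass
        if out:
            summary.to_csv(out / "subject_table.csv", index=False)

    if out:
        serializable = {k: v for k, v in results.items() if k != "subject_table"}
        (out / "results.json").write_text(json.dumps(serializable, indent=2,
                                                     default=_json_default))
        skio.write_trials(trials, out / "trials.csv")
        if config.figures and grid is not None:
            _write_figures(out, grid, hist, ers, analysis, results)
    return results


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    return str(obj)


def _write_figures(out: Path, grid, hist, ers, analysis, results) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    extent = [grid.velocity_bins[0], grid.velocity_bins[-1],
              grid.angle_bins[0], grid.angle_bins[-1]]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(np.where(grid.post_hit_mask, np.nan, grid.error), origin="lower",
              extent=extent, aspect="auto", cmap="gray_r")
    ax.set_xlabel("release velocity (deg/s)")
    ax.set_ylabel("release angle (deg)")
    ax.set_title("execution space (black: post hit)")
    fig.savefig(out / "execution_space.png", dpi=120)
    plt.close(fig)

    if hist is not None:
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.imshow(hist, origin="lower", extent=extent, aspect="auto")
        ax.set_title("pooled strategy histogram")
        fig.savefig(out / "histogram.png", dpi=120)
        plt.close(fig)

    for hyp, er in ers.items():
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.imshow(er.ER, origin="lower", extent=extent, aspect="auto")
        ax.plot(er.argmax[1], er.argmax[0], "ro", ms=6)
        ax.set_title(f"expected result E(R), {hyp.upper()}")
        fig.savefig(out / f"expected_result_{hyp}.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    for s, sub in analysis.groupby("subject"):
        ax.scatter(sub["velocity_deg_s"], sub["angle_deg"], s=2, alpha=0.3,
                   label=str(s))
    ax.set_xlabel("release velocity (deg/s)")
    ax.set_ylabel("release angle (deg)")
    fig.savefig(out / "cohort_scatter.png", dpi=120)
    plt.close(fig)
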