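"""Virtual subjects and cohorts for the throwing-task analysis pipeline.

No raw subject data are deposited for this task, so every pipeline stage is
exercised on synthetic cohorts whose statistical structure mirrors the
study conditions: per-subject bivariate-Gaussian release distributions
centered on chosen strategies, the experiments' session/block structure
(3x3x60 = 540 throws for the first configuration, 5x3x60 = 900 for the
second), optional practice-dependent drift toward the solution manifold,
and a no-target control with velocity-proportional release noise in five
25-trial blocks.

Default dispersions are the grand-average release SDs printed for the two
experiments (11.70 deg / 40.49 deg/s and 9.44 deg / 70.38 deg/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .execution_space import ExecutionGrid
from .subject_stats import TRIAL_COLUMNS
from .task_model import InvalidInputError, WorkspaceConfig, evaluate_errors
from .tolerance import (EXP1_PROFILE, EXP2_PROFILE, ExpectedResultMap,
                        VariabilityProfile)

__all__ = [
    "PracticeDrift",
    "SubjectSpec",
    "Exp3Spec",
    "generate_subject",
    "generate_cohort",
    "generate_exp3",
    "sample_from_expected_result",
    "manifold_velocity",
    "exp1_cohort_specs",
    "exp3_cohort_specs",
    "exp2_cohort_specs",
]


@dataclass(frozen=True)
class PracticeDrift:
    """Exponential early-practice transient, clearly synthetic.

    The subject starts ``start_offset`` away from their final strategy with
    SDs inflated by ``start_sd_scale``; both relax exponentially with decay
    constant ``tau_trials``.  Emulates the fast first-session improvement
    seen in practice curves without claiming any specific learning model.
    """

    start_offset: tuple[float, float] = (20.0, 80.0)
    start_sd_scale: float = 3.0
    tau_trials: float = 60.0


@dataclass(frozen=True)
class SubjectSpec:
    """One virtual subject: strategy center, dispersion and session structure."""

    subject: str
    center: tuple[float, float]                  # (angle deg, velocity deg/s)
    profile: VariabilityProfile = EXP1_PROFILE
    sessions: int = 3
    blocks: int = 3
    trials_per_block: int = 60
    correlation: float = 0.0                     # angle-velocity correlation
    drift: PracticeDrift | None = None
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.sessions * self.blocks * self.trials_per_block

    def __post_init__(self) -> None:
        if not abs(self.correlation) < 1.0:
            raise InvalidInputError("|correlation| must be < 1")


@dataclass(frozen=True)
class Exp3Spec:
    """No-target control: five instructed-velocity blocks of 25 throws each.

    Release noise follows the signal-dependent laws
    ``SD_v = k_v * v + c_v`` and ``SD_a = k_a * v + c_a``; set the slopes to
    zero for the constant-noise null.
    """

    target_velocities: tuple[float, ...] = (200.0, 350.0, 500.0, 650.0, 800.0)
    trials_per_block: int = 25
    k_velocity: float = 0.10
    c_velocity: float = 10.0
    k_angle: float = 0.015
    c_angle: float = 2.0
    angle_center: float = -60.0
    subject: str = "C1"
    seed: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.target_velocities, float)
        if not (np.all(v > 0) and np.all(np.diff(v) > 0)):
            raise InvalidInputError("target velocities must be positive, increasing")

    def sd_velocity(self, v: float) -> float:
        return self.k_velocity * v + self.c_velocity

    def sd_angle(self, v: float) -> float:
        return self.k_angle * v + self.c_angle


def _draw_correlated(rng: np.random.Generator, n: int,
                     rho: float) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return z1, rho * z1 + np.sqrt(1.0 - rho ** 2) * z2


def generate_subject(spec: SubjectSpec, config: WorkspaceConfig) -> pd.DataFrame:
    """Sample one subject's trial table; byte-identical for a fixed spec.

    Throws are bivariate-Gaussian in (angle, velocity); errors and post-hit
    flags come from the flight model.  Under a drift spec the center and SDs
    relax exponentially over the trial sequence.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials
    z_a, z_v = _draw_correlated(rng, n, spec.correlation)
    t = np.arange(n, dtype=float)
    if spec.drift is not None:
        relax = np.exp(-t / spec.drift.tau_trials)
        sd_scale = 1.0 + (spec.drift.start_sd_scale - 1.0) * relax
        off_a = spec.drift.start_offset[0] * relax
        off_v = spec.drift.start_offset[1] * relax
    else:
        sd_scale = np.ones(n)
        off_a = off_v = 0.0
    ang = spec.center[0] + off_a + spec.profile.sd_angle * sd_scale * z_a
    vel = spec.center[1] + off_v + spec.profile.sd_velocity * sd_scale * z_v
    err, hit = evaluate_errors(ang, vel, config)

    tpb = spec.trials_per_block
    per_sess = spec.blocks * tpb
    return pd.DataFrame({
        "subject": spec.subject,
        "session": (t // per_sess).astype(int) + 1,
        "block": ((t % per_sess) // tpb).astype(int) + 1,
        "trial": (t % tpb).astype(int) + 1,
        "angle_deg": ang,
        "velocity_deg_s": vel,
        "error_cm": err,
        "post_hit": hit.astype(int),
    })[TRIAL_COLUMNS]


def generate_cohort(specs, config: WorkspaceConfig) -> pd.DataFrame:
    """Concatenate per-subject tables; rows depend only on each spec's seed."""
    specs = list(specs)
    if not specs:
        raise InvalidInputError("cohort needs at least one subject spec")
    ids = [s.subject for s in specs]
    if len(set(ids)) != len(ids):
        raise InvalidInputError(f"duplicate subject ids in cohort: {ids}")
    frames = [generate_subject(s, config) for s in specs]
    return pd.concat(frames, ignore_index=True)


def generate_exp3(spec: Exp3Spec, config: WorkspaceConfig) -> pd.DataFrame:
    """No-target control blocks with signal-dependent release noise.

    There is no target, so no distance error is scored (``error_cm`` is the
    penalty for post hits and NaN otherwise); the downstream variability
    regressions only consume the release variables.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for b, v_t in enumerate(spec.target_velocities, start=1):
        sd_v = spec.sd_velocity(v_t)
        sd_a = spec.sd_angle(v_t)
        if sd_v < 0 or sd_a < 0:
            raise InvalidInputError("noise law yields a negative SD")
        vel = v_t + sd_v * rng.standard_normal(spec.trials_per_block)
        ang = spec.angle_center + sd_a * rng.standard_normal(spec.trials_per_block)
        _, hit = evaluate_errors(ang, vel, config)
        rows.append(pd.DataFrame({
            "subject": spec.subject,
            "session": 1,
            "block": b,
            "trial": np.arange(1, spec.trials_per_block + 1),
            "angle_deg": ang,
            "velocity_deg_s": vel,
            "error_cm": np.where(hit, config.penalty_error, np.nan),
            "post_hit": hit.astype(int),
        }))
    return pd.concat(rows, ignore_index=True)[TRIAL_COLUMNS]


def sample_from_expected_result(er: ExpectedResultMap, n: int,
                                seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw (angle, velocity) release states with probability proportional
    to an E(R) surface: inverse-transform sampling over the discretized
    surface with uniform jitter within the chosen cell."""
    rng = np.random.default_rng(seed)
    p = er.ER.ravel()
    cdf = np.cumsum(p / p.sum())
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    i, j = np.unravel_index(np.clip(idx, 0, p.size - 1), er.ER.shape)
    g = er.grid
    ang = g.angle_bins[i] + (rng.random(n) - 0.5) * g.angle_step
    vel = g.velocity_bins[j] + (rng.random(n) - 0.5) * g.velocity_step
    return ang, vel


def manifold_velocity(config: WorkspaceConfig, angle: float,
                      v_bounds: tuple[float, float] | None = None) -> float:
    """Velocity whose throw at ``angle`` minimizes the error (a manifold
    point when the angle admits a zero-error solution)."""
    from .task_model import error_at
    lo, hi = v_bounds if v_bounds is not None else config.velocity_range
    vv = np.linspace(lo + 1e-6, hi, 60)
    errs, _ = evaluate_errors(np.full_like(vv, angle), vv, config)
    k = int(np.argmin(errs))
    res = minimize_scalar(lambda v: error_at(angle, float(v), config),
                          bounds=(vv[max(k - 1, 0)], vv[min(k + 1, len(vv) - 1)]),
                          method="bounded", options={"xatol": 1e-6})
    return float(res.x)


def exp3_cohort_specs(n_subjects: int = 6, seed: int = 0,
                      k_velocity: float = 0.10, k_angle: float = 0.015,
                      subject_sd: float = 0.25) -> list[Exp3Spec]:
    """Six-subject no-target control cohort with heterogeneous noise laws.

    Subjects share the mean signal-dependent slopes but vary around them
    (lognormal, coefficient of variation ``subject_sd``), so pooled
    SD-on-velocity regressions are strong yet imperfect, as in real
    between-subject data.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for k in range(n_subjects):
        mult_v, mult_a = np.exp(subject_sd * rng.standard_normal(2)
                                - subject_sd ** 2 / 2.0)
        specs.append(Exp3Spec(subject=f"C{k + 1}",
                              k_velocity=k_velocity * mult_v,
                              k_angle=k_angle * mult_a,
                              seed=seed * 1021 + k))
    return specs


def exp1_cohort_specs(config: WorkspaceConfig, n_subjects: int = 9,
                      seed: int = 0, drift: PracticeDrift | None = None,
                      correlation: float = 0.5,
                      angles: np.ndarray | None = None,
                      v_bounds: tuple[float, float] = (60.0, 450.0)
                      ) -> list[SubjectSpec]:
    """Nine-subject cohort with strategy centers spread along the low-error
    band of the execution space, three sessions of three 60-trial blocks
    each (540 throws/subject).  Default centers sit on the two low-velocity
    branches of the solution set, far enough from the grid edges that every
    subject's +/-2.5 SD cell matrix stays inside the execution space."""
    if angles is None:
        n_left = (n_subjects + 1) // 2
        angles = np.concatenate([np.linspace(-130.0, -95.0, n_left),
                                 np.linspace(-45.0, -32.0, n_subjects - n_left)])
    specs = []
    for k, a in enumerate(angles):
        v = manifold_velocity(config, float(a), v_bounds=v_bounds)
        specs.append(SubjectSpec(
            subject=f"S{k + 1}", center=(float(a), v), profile=EXP1_PROFILE,
            sessions=3, blocks=3, trials_per_block=60,
            correlation=correlation, drift=drift, seed=seed * 1009 + k))
    return specs


def exp2_cohort_specs(config: WorkspaceConfig, n_subjects: int = 9,
                      seed: int = 0, drift: PracticeDrift | None = None,
                      manifold_angle: float = -82.0,
                      velocity_span: tuple[float, float] = (240.0, 775.0),
                      correlation: float = 0.0) -> list[SubjectSpec]:
    """Nine-subject cohort on the near-vertical manifold, five sessions of
    three 60-trial blocks (900 throws/subject); subject means spread over
    the velocity span observed in the second experiment."""
    velocities = np.linspace(velocity_span[0], velocity_span[1], n_subjects)
    return [SubjectSpec(
        subject=f"S{k + 1}", center=(manifold_angle, float(v)),
        profile=EXP2_PROFILE, sessions=5, blocks=3, trials_per_block=60,
        correlation=correlation, drift=drift, seed=seed * 1013 + k)
        for k, v in enumerate(velocities)]
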