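"""Closed-form ball-flight model for the virtual skittles (tetherball) task.

A ball is thrown by a single-joint lever rotation in the horizontal plane.
At release the ball detaches and, being suspended from a central post, moves
in a centripetal force field: an isotropic harmonic oscillator about the
post center, tracing a closed ellipse (optionally damped).  The two release
variables — lever angle ``alpha`` (deg) and angular velocity ``v`` (deg/s)
— fully determine the trajectory.  Performance error is the minimum distance
between the ball-center path and the target center; trajectories that come
within contact distance of the post are assigned a fixed penalty error.

The workspace geometry (post, target, radii, penalty) is taken from the
experiment configurations; the manipulandum geometry (pivot, lever length,
angle convention) and the oscillator frequency are free constants of the
virtual set-up, exposed in :class:`WorkspaceConfig` and tunable by
:func:`skittles.execution_space.calibrate_geometry`.

Units: lengths cm, angles deg, angular velocities deg/s, time s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "InvalidInputError",
    "WorkspaceConfig",
    "ReleaseState",
    "Trajectory",
    "release_to_state",
    "simulate_trajectory",
    "compute_error",
    "error_at",
    "evaluate_errors",
    "load_preset",
    "preset_names",
]

DEG = math.pi / 180.0


class ConfigError(ValueError):
    """Raised for invalid or degenerate workspace configuration."""


class InvalidInputError(ValueError):
    """Raised for non-finite or out-of-domain operation inputs."""


@dataclass(frozen=True)
class WorkspaceConfig:
    """Geometry and dynamics of one experimental workspace.

    ``angle_zero_direction`` is the unit vector the lever points along at
    ``alpha = 0``; positive ``alpha`` rotates the lever in the sense of
    ``rotation_sign`` (+1 counterclockwise).  ``damping_tau = inf`` gives the
    undamped (closed-ellipse) flight model.  ``horizon = None`` resolves to
    one full oscillator period, which makes the error independent of the
    display duration.
    """

    post_center: tuple[float, float]
    post_radius: float
    target_center: tuple[float, float]
    target_radius: float
    ball_radius: float
    penalty_error: float
    pivot: tuple[float, float] = (0.0, -120.0)
    arm_length: float = 40.0
    angle_zero_direction: tuple[float, float] = (1.0, 0.0)
    rotation_sign: int = 1
    omega: float = 2.0 * math.pi
    damping_tau: float = math.inf
    horizon: float | None = None
    angle_range: tuple[float, float] = (-165.0, 0.0)
    velocity_range: tuple[float, float] = (0.0, 600.0)
    name: str = ""

    def __post_init__(self) -> None:
        for attr in ("post_radius", "target_radius", "ball_radius",
                     "penalty_error", "arm_length", "omega"):
            if not getattr(self, attr) > 0:
                raise ConfigError(f"{attr} must be > 0, got {getattr(self, attr)}")
        if self.rotation_sign not in (-1, 1):
            raise ConfigError("rotation_sign must be +1 or -1")
        if not self.damping_tau > 0:
            raise ConfigError("damping_tau must be > 0 (use inf for undamped)")
        if self.horizon is not None and not self.horizon > 0:
            raise ConfigError("horizon must be > 0 or None")
        d = np.asarray(self.angle_zero_direction, dtype=float)
        norm = float(np.hypot(*d))
        if not norm > 0:
            raise ConfigError("angle_zero_direction must be a nonzero vector")
        object.__setattr__(self, "angle_zero_direction",
                           (float(d[0] / norm), float(d[1] / norm)))
        object.__setattr__(self, "post_center", tuple(map(float, self.post_center)))
        object.__setattr__(self, "target_center", tuple(map(float, self.target_center)))
        object.__setattr__(self, "pivot", tuple(map(float, self.pivot)))

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega

    @property
    def horizon_s(self) -> float:
        """Evaluation duration: the explicit horizon, or one full period."""
        return self.period if self.horizon is None else self.horizon

    @property
    def zero_angle_deg(self) -> float:
        dx, dy = self.angle_zero_direction
        return math.degrees(math.atan2(dy, dx))

    @property
    def post_contact_distance(self) -> float:
        """Ball-center distance at which ball and post disks touch."""
        return self.post_radius + self.ball_radius

    def replace(self, **changes) -> "WorkspaceConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "WorkspaceConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown workspace keys: {sorted(unknown)}")
        kw = dict(d)
        for key in ("post_center", "target_center", "pivot", "angle_zero_direction",
                    "angle_range", "velocity_range"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(float(x) for x in kw[key])
        if kw.get("damping_tau") is None:
            kw["damping_tau"] = math.inf
        return cls(**kw)


@dataclass(frozen=True)
class ReleaseState:
    """One throw's execution variables and the derived Cartesian release."""

    angle: float
    velocity: float
    release_position: tuple[float, float]
    release_velocity: tuple[float, float]


@dataclass(frozen=True)
class Trajectory:
    """Closed-form ball-center path ``p(t) = c + (A cos wt + B sin wt) e^(-t/tau)``.

    ``A`` and ``B`` are conjugate semi-diameter vectors of the (undamped)
    orbital ellipse centered on the post.  ``B`` is chosen so that the t = 0
    position and velocity equal the release state exactly, also when damped.
    """

    center: tuple[float, float]
    cos_amp: tuple[float, float]
    sin_amp: tuple[float, float]
    omega: float
    damping_tau: float
    horizon: float

    def position(self, t) -> np.ndarray:
        """Ball-center position at time(s) ``t``; shape ``t.shape + (2,)``."""
        t = np.asarray(t, dtype=float)
        A = np.asarray(self.cos_amp)
        B = np.asarray(self.sin_amp)
        wt = self.omega * t
        env = np.exp(-t / self.damping_tau) if math.isfinite(self.damping_tau) else 1.0
        osc = (np.multiply.outer(np.cos(wt), A) + np.multiply.outer(np.sin(wt), B))
        return np.asarray(self.center) + np.asarray(env)[..., None] * osc

    def velocity(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        A = np.asarray(self.cos_amp)
        B = np.asarray(self.sin_amp)
        w = self.omega
        wt = w * t
        osc = (np.multiply.outer(np.cos(wt), A) + np.multiply.outer(np.sin(wt), B))
        dosc = w * (np.multiply.outer(-np.sin(wt), A) + np.multiply.outer(np.cos(wt), B))
        if math.isfinite(self.damping_tau):
            env = np.exp(-t / self.damping_tau)
            return env[..., None] * dosc - (env / self.damping_tau)[..., None] * osc
        return dosc

    def semi_axes(self) -> tuple[float, float]:
        """Semi-major and semi-minor axes of the undamped orbital ellipse."""
        A = np.asarray(self.cos_amp)
        B = np.asarray(self.sin_amp)
        M = np.outer(A, A) + np.outer(B, B)
        ev = np.linalg.eigvalsh(M)
        ev = np.clip(ev, 0.0, None)
        return float(math.sqrt(ev[1])), float(math.sqrt(ev[0]))

    def min_max_radius(self) -> tuple[float, float]:
        """Extreme distances from the orbit to its own center (undamped)."""
        major, minor = self.semi_axes()
        return minor, major


def release_to_state(angle: float, velocity: float, config: WorkspaceConfig) -> ReleaseState:
    """Map execution variables (deg, deg/s) to the Cartesian release state.

    The lever tip moves on the circle of radius ``arm_length`` about
    ``pivot``; release velocity is tangent to that circle with sense
    ``rotation_sign`` and magnitude ``|v| * pi/180 * arm_length``.
    """
    if not (math.isfinite(angle) and math.isfinite(velocity)):
        raise InvalidInputError(f"non-finite release variables ({angle}, {velocity})")
    psi = DEG * (config.zero_angle_deg + config.rotation_sign * angle)
    c, s = math.cos(psi), math.sin(psi)
    L = config.arm_length
    px, py = config.pivot
    speed = config.rotation_sign * velocity * DEG * L
    return ReleaseState(
        angle=float(angle),
        velocity=float(velocity),
        release_position=(px + L * c, py + L * s),
        release_velocity=(-speed * s, speed * c),
    )


def simulate_trajectory(state: ReleaseState, config: WorkspaceConfig) -> Trajectory:
    """Closed-form isotropic-oscillator flight about the post center.

    For the damped variant the sine amplitude absorbs the envelope's initial
    slope so that position and velocity at t = 0 match the release state.
    """
    if not config.omega > 0:
        raise ConfigError("omega must be > 0")
    c = np.asarray(config.post_center, dtype=float)
    p0 = np.asarray(state.release_position, dtype=float)
    v0 = np.asarray(state.release_velocity, dtype=float)
    A = p0 - c
    if math.isfinite(config.damping_tau):
        B = (v0 + A / config.damping_tau) / config.omega
    else:
        B = v0 / config.omega
    return Trajectory(
        center=(float(c[0]), float(c[1])),
        cos_amp=(float(A[0]), float(A[1])),
        sin_amp=(float(B[0]), float(B[1])),
        omega=config.omega,
        damping_tau=config.damping_tau,
        horizon=config.horizon_s,
    )


# ---------------------------------------------------------------------------
# Minimum-distance machinery
# ---------------------------------------------------------------------------

def _batch_min_dist(A: np.ndarray, B: np.ndarray, center: np.ndarray,
                    point: np.ndarray, omega: float, tau: float,
                    horizon: float, n_coarse: int = 360,
                    n_newton: int = 30) -> np.ndarray:
    """Minimum of ``|p(t) - point|`` over ``t in [0, horizon]`` for a batch.

    Coarse sampling locates the global basin; safeguarded Newton iterations on
    the squared distance polish the minimizer to machine precision.  ``A`` and
    ``B`` have shape (n, 2).
    """
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    n = A.shape[0]
    d = point - center  # target position relative to orbit center

    periodic = (not math.isfinite(tau)) and horizon >= 2.0 * math.pi / omega - 1e-12
    if periodic:
        t = np.linspace(0.0, 2.0 * math.pi / omega, n_coarse, endpoint=False)
    else:
        t = np.linspace(0.0, horizon, n_coarse)

    cwt = np.cos(omega * t)
    swt = np.sin(omega * t)
    env = np.exp(-t / tau) if math.isfinite(tau) else np.ones_like(t)

    # r(t) = env*(A cos + B sin) - d, squared norm, shape (n, n_coarse)
    rx = env * (np.outer(A[:, 0], cwt) + np.outer(B[:, 0], swt)) - d[0]
    ry = env * (np.outer(A[:, 1], cwt) + np.outer(B[:, 1], swt)) - d[1]
    f = rx * rx + ry * ry
    k = np.argmin(f, axis=1)
    fbest = f[np.arange(n), k]
    tbest = t[k]

    step = t[1] - t[0]
    lo = tbest - step
    hi = tbest + step
    if not periodic:
        lo = np.clip(lo, 0.0, horizon)
        hi = np.clip(hi, 0.0, horizon)

    tc = tbest.copy()
    inv_tau = 0.0 if not math.isfinite(tau) else 1.0 / tau
    for _ in range(n_newton):
        cwt = np.cos(omega * tc)
        swt = np.sin(omega * tc)
        env = np.exp(-tc * inv_tau) if inv_tau else 1.0
        osc_x = A[:, 0] * cwt + B[:, 0] * swt
        osc_y = A[:, 1] * cwt + B[:, 1] * swt
        dosc_x = omega * (-A[:, 0] * swt + B[:, 0] * cwt)
        dosc_y = omega * (-A[:, 1] * swt + B[:, 1] * cwt)
        px = env * osc_x - d[0]
        py = env * osc_y - d[1]
        vx = env * (dosc_x - inv_tau * osc_x)
        vy = env * (dosc_y - inv_tau * osc_y)
        ax = env * (-(omega ** 2) * osc_x - 2.0 * inv_tau * dosc_x + inv_tau ** 2 * osc_x)
        ay = env * (-(omega ** 2) * osc_y - 2.0 * inv_tau * dosc_y + inv_tau ** 2 * osc_y)
        g = 2.0 * (px * vx + py * vy)           # d/dt |r|^2
        h = 2.0 * (vx * vx + vy * vy + px * ax + py * ay)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(h > 0, g / np.where(h > 0, h, 1.0), 0.0)
        tc = np.clip(tc - delta, lo, hi)

    cwt = np.cos(omega * tc)
    swt = np.sin(omega * tc)
    env = np.exp(-tc * inv_tau) if inv_tau else 1.0
    px = env * (A[:, 0] * cwt + B[:, 0] * swt) - d[0]
    py = env * (A[:, 1] * cwt + B[:, 1] * swt) - d[1]
    fref = px * px + py * py
    return np.sqrt(np.minimum(fbest, fref))


def _traj_min_dist(traj: Trajectory, point, n_coarse: int = 720) -> float:
    A = np.asarray(traj.cos_amp)[None, :]
    B = np.asarray(traj.sin_amp)[None, :]
    return float(_batch_min_dist(A, B, np.asarray(traj.center), np.asarray(point, float),
                                 traj.omega, traj.damping_tau, traj.horizon,
                                 n_coarse=n_coarse)[0])


def compute_error(traj: Trajectory, config: WorkspaceConfig) -> tuple[float, bool]:
    """Score one trajectory: (minimum-distance error in cm, post-hit flag).

    The trial is a post hit when the ball disk contacts the post disk, i.e.
    the ball-center path comes within ``post_radius + ball_radius`` of the
    post center; post hits receive the fixed ``penalty_error``.  Otherwise
    the error is the minimum distance between ball center and target center.
    """
    undamped_full = (not math.isfinite(traj.damping_tau)) and \
        traj.horizon >= 2.0 * math.pi / traj.omega - 1e-12
    if undamped_full:
        # orbit is centered on the post: closest approach = semi-minor axis
        d_post = traj.semi_axes()[1]
    else:
        d_post = _traj_min_dist(traj, config.post_center)
    if d_post <= config.post_contact_distance:
        return float(config.penalty_error), True
    return _traj_min_dist(traj, config.target_center), False


def error_at(angle: float, velocity: float, config: WorkspaceConfig) -> float:
    """Convenience scalar path: error (cm) of the throw ``(angle, velocity)``."""
    traj = simulate_trajectory(release_to_state(angle, velocity, config), config)
    return compute_error(traj, config)[0]


def evaluate_errors(angles, velocities, config: WorkspaceConfig,
                    n_coarse: int = 360, chunk: int = 20000):
    """Vectorized errors and post-hit flags for paired (angle, velocity) arrays.

    Returns ``(errors, post_hit)`` with the shape of the inputs.  Uses the
    exact semi-minor-axis criterion for post hits when the flight model is
    undamped and the horizon covers a full period.
    """
    ang = np.asarray(angles, dtype=float)
    vel = np.asarray(velocities, dtype=float)
    if ang.shape != vel.shape:
        raise InvalidInputError("angles and velocities must have the same shape")
    if not (np.all(np.isfinite(ang)) and np.all(np.isfinite(vel))):
        raise InvalidInputError("non-finite release variables")
    shape = ang.shape
    ang = ang.ravel()
    vel = vel.ravel()

    psi = DEG * (config.zero_angle_deg + config.rotation_sign * ang)
    L = config.arm_length
    c = np.asarray(config.post_center, dtype=float)
    p0 = np.stack([config.pivot[0] + L * np.cos(psi),
                   config.pivot[1] + L * np.sin(psi)], axis=1)
    speed = config.rotation_sign * vel * DEG * L
    v0 = np.stack([-speed * np.sin(psi), speed * np.cos(psi)], axis=1)
    A = p0 - c
    if math.isfinite(config.damping_tau):
        B = (v0 + A / config.damping_tau) / config.omega
    else:
        B = v0 / config.omega

    tau = config.damping_tau
    horizon = config.horizon_s
    undamped_full = (not math.isfinite(tau)) and horizon >= config.period - 1e-12

    n = ang.size
    errors = np.empty(n)
    post_hit = np.empty(n, dtype=bool)
    target = np.asarray(config.target_center, dtype=float)
    contact = config.post_contact_distance

    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        Ai, Bi = A[sl], B[sl]
        if undamped_full:
            m11 = Ai[:, 0] ** 2 + Bi[:, 0] ** 2
            m22 = Ai[:, 1] ** 2 + Bi[:, 1] ** 2
            m12 = Ai[:, 0] * Ai[:, 1] + Bi[:, 0] * Bi[:, 1]
            tr = m11 + m22
            disc = np.sqrt(np.clip((m11 - m22) ** 2 + 4.0 * m12 ** 2, 0.0, None))
            lam_min = np.clip(0.5 * (tr - disc), 0.0, None)
            d_post = np.sqrt(lam_min)
        else:
            d_post = _batch_min_dist(Ai, Bi, c, c, config.omega, tau, horizon,
                                     n_coarse=n_coarse)
        hit = d_post <= contact
        err = np.full(sl.stop - sl.start, config.penalty_error)
        if np.any(~hit):
            err[~hit] = _batch_min_dist(Ai[~hit], Bi[~hit], c, target,
                                        config.omega, tau, horizon,
                                        n_coarse=n_coarse)
        errors[sl] = err
        post_hit[sl] = hit

    return errors.reshape(shape), post_hit.reshape(shape)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_names() -> list[str]:
    pkg = resources.files("skittles") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> WorkspaceConfig:
    """Load a shipped workspace preset ('exp1', 'exp2', calibrated variants)."""
    pkg = resources.files("skittles") / "presets" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise ConfigError(f"unknown preset {name!r}; available: {preset_names()}")
    d = yaml.safe_load(text)
    d.setdefault("name", name)
    return WorkspaceConfig.from_dict(d)
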