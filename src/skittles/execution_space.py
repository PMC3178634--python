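"""Execution space: the result function tabulated over the (angle, velocity) plane.

Every throw corresponds to one point of the execution space; the error
surface over a regular lattice of release states exposes the task's
redundancy.  The zero-error set — the solution manifold — is one-dimensional
here because two execution variables map to a single result variable.

The module also provides :func:`calibrate_geometry`, a deterministic
coordinate-descent search that tunes the unprinted constants of the virtual
set-up (pivot height, lever length, angle offset, oscillator frequency) so
that the execution space reproduces known landmarks such as "this strategy
lies on the solution manifold" or "this strategy hits the post".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .task_model import (
    ConfigError,
    WorkspaceConfig,
    compute_error,
    error_at,
    evaluate_errors,
    release_to_state,
    simulate_trajectory,
)

__all__ = [
    "ExecutionGrid",
    "SolutionManifold",
    "Landmark",
    "CalibrationResult",
    "build_grid",
    "extract_manifold",
    "calibrate_geometry",
    "histogram_on_grid",
]


def _bin_centers(lo: float, hi: float, n: int) -> np.ndarray:
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


@dataclass(frozen=True)
class ExecutionGrid:
    """Error surface on a regular lattice of bin centers.

    ``error[i, j]`` is the result of the throw at ``(angle_bins[i],
    velocity_bins[j])``; ``post_hit_mask`` flags penalty cells.
    """

    angle_bins: np.ndarray
    velocity_bins: np.ndarray
    error: np.ndarray
    post_hit_mask: np.ndarray
    config: WorkspaceConfig

    @property
    def angle_step(self) -> float:
        return float(self.angle_bins[1] - self.angle_bins[0])

    @property
    def velocity_step(self) -> float:
        return float(self.velocity_bins[1] - self.velocity_bins[0])

    @property
    def angle_edges(self) -> np.ndarray:
        b, s = self.angle_bins, self.angle_step
        return np.concatenate([b - s / 2.0, [b[-1] + s / 2.0]])

    @property
    def velocity_edges(self) -> np.ndarray:
        b, s = self.velocity_bins, self.velocity_step
        return np.concatenate([b - s / 2.0, [b[-1] + s / 2.0]])


@dataclass(frozen=True)
class SolutionManifold:
    """Near-zero-error strategies, refined along the velocity axis.

    ``points[k] = (angle, velocity)``; ``curvature`` is the second derivative
    of the error surface with respect to velocity at each point (cm per
    (deg/s)^2), a local sensitivity measure.
    """

    points: np.ndarray       # (n, 2)
    errors: np.ndarray       # (n,)
    curvature: np.ndarray    # (n,)
    threshold: float

    def __len__(self) -> int:
        return len(self.points)

    @property
    def angles(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def velocities(self) -> np.ndarray:
        return self.points[:, 1]


def build_grid(config: WorkspaceConfig, n_angle: int = 360,
               n_velocity: int = 360) -> ExecutionGrid:
    """Tabulate the result function at every bin center of a regular lattice.

    Bins are half-open intervals covering ``config.angle_range`` and
    ``config.velocity_range``; cell values are exact pointwise evaluations of
    the error function at bin centers (no interpolation), so the grid is
    deterministic for a fixed config.
    """
    if n_angle < 2 or n_velocity < 2:
        raise ConfigError("grid needs at least 2 bins per axis")
    a_lo, a_hi = config.angle_range
    v_lo, v_hi = config.velocity_range
    if not (a_hi > a_lo and v_hi > v_lo):
        raise ConfigError("degenerate angle or velocity range")
    ab = _bin_centers(a_lo, a_hi, n_angle)
    vb = _bin_centers(v_lo, v_hi, n_velocity)
    A, V = np.meshgrid(ab, vb, indexing="ij")
    err, hit = evaluate_errors(A, V, config)
    return ExecutionGrid(angle_bins=ab, velocity_bins=vb, error=err,
                         post_hit_mask=hit, config=config)


def _refine_velocity(config: WorkspaceConfig, angle: float,
                     v_lo: float, v_hi: float) -> tuple[float, float]:
    res = minimize_scalar(lambda v: error_at(angle, float(v), config),
                          bounds=(v_lo, v_hi), method="bounded",
                          options={"xatol": 1e-7})
    return float(res.x), float(res.fun)


def extract_manifold(grid: ExecutionGrid, threshold: float = 0.01) -> SolutionManifold:
    """Extract the solution manifold from a grid.

    Sub-threshold cells are grouped into contiguous runs per angle column and
    each run is refined by bounded 1-D minimization of the error along the
    velocity axis, yielding one manifold point per run.  An empty manifold is
    returned with a warning, not an error.
    """
    pts, errs, curv = [], [], []
    vb = grid.velocity_bins
    dv = grid.velocity_step
    for i, a in enumerate(grid.angle_bins):
        below = np.flatnonzero(grid.error[i] < threshold)
        if below.size == 0:
            continue
        # contiguous runs of sub-threshold velocity cells
        splits = np.flatnonzero(np.diff(below) > 1) + 1
        for run in np.split(below, splits):
            lo = max(vb[run[0]] - dv, grid.velocity_bins[0] - dv / 2.0)
            hi = min(vb[run[-1]] + dv, grid.velocity_bins[-1] + dv / 2.0)
            v, e = _refine_velocity(grid.config, float(a), lo, hi)
            h = max(dv / 4.0, 1e-3)
            d2 = (error_at(a, v - h, grid.config) - 2.0 * e
                  + error_at(a, v + h, grid.config)) / h ** 2
            pts.append((float(a), v))
            errs.append(e)
            curv.append(d2)
    if not pts:
        warnings.warn("no execution-space cell fell below the zero-error "
                      f"threshold {threshold} cm; manifold is empty")
        return SolutionManifold(np.empty((0, 2)), np.empty(0), np.empty(0), threshold)
    order = np.lexsort((np.array(pts)[:, 1], np.array(pts)[:, 0]))
    pts = np.array(pts)[order]
    return SolutionManifold(pts, np.array(errs)[order], np.array(curv)[order],
                            threshold)


def histogram_on_grid(angles, velocities, grid: ExecutionGrid,
                      n_angle: int = 36, n_velocity: int = 36) -> np.ndarray:
    """2-D histogram of throws on a coarse lattice spanning the grid ranges."""
    H, _, _ = np.histogram2d(
        np.asarray(angles, float), np.asarray(velocities, float),
        bins=[n_angle, n_velocity],
        range=[list(grid.config.angle_range), list(grid.config.velocity_range)])
    return H


# ---------------------------------------------------------------------------
# Geometry calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Landmark:
    """One known property of the execution space used for calibration.

    kinds:
      ``on_manifold``       error at (angle, velocity) should be zero
      ``post_hit``          the throw (angle, velocity) should hit the post
      ``no_post_hit``       the throw should clear the post
      ``manifold_at_angle`` some velocity in range solves the task at ``angle``
    """

    kind: str
    angle: float
    velocity: float | None = None
    weight: float = 1.0


@dataclass(frozen=True)
class CalibrationResult:
    config: WorkspaceConfig
    residual: float
    landmark_residuals: tuple[float, ...]


_DEFAULT_BOUNDS = {
    "pivot_y": (-220.0, -40.0),
    "arm_length": (5.0, 100.0),
    "omega": (0.2, 7.0),
    "angle_offset": (-180.0, 180.0),
}


def _apply_params(base: WorkspaceConfig, params: dict[str, float]) -> WorkspaceConfig:
    cfg = base
    if "pivot_y" in params:
        cfg = cfg.replace(pivot=(cfg.pivot[0], float(params["pivot_y"])))
    if "arm_length" in params:
        cfg = cfg.replace(arm_length=float(params["arm_length"]))
    if "omega" in params:
        cfg = cfg.replace(omega=float(params["omega"]))
    if "angle_offset" in params:
        phi = math.radians(params["angle_offset"])
        cfg = cfg.replace(angle_zero_direction=(math.cos(phi), math.sin(phi)))
    return cfg


def _post_margin(angle: float, velocity: float, cfg: WorkspaceConfig) -> float:
    """Signed clearance of the orbit past the post (negative inside)."""
    traj = simulate_trajectory(release_to_state(angle, velocity, cfg), cfg)
    return traj.semi_axes()[1] - cfg.post_contact_distance


def _landmark_residual(lm: Landmark, cfg: WorkspaceConfig) -> float:
    if lm.kind == "on_manifold":
        return error_at(lm.angle, lm.velocity, cfg)
    if lm.kind == "post_hit":
        return max(0.0, _post_margin(lm.angle, lm.velocity, cfg))
    if lm.kind == "no_post_hit":
        return max(0.0, -_post_margin(lm.angle, lm.velocity, cfg))
    if lm.kind == "manifold_at_angle":
        v_lo, v_hi = cfg.velocity_range
        vv = np.linspace(v_lo + 1e-6, v_hi, 48)
        errs, _ = evaluate_errors(np.full_like(vv, lm.angle), vv, cfg)
        k = int(np.argmin(errs))
        lo = vv[max(k - 1, 0)]
        hi = vv[min(k + 1, len(vv) - 1)]
        _, e = _refine_velocity(cfg, lm.angle, float(lo), float(hi))
        return e
    raise ValueError(f"unknown landmark kind {lm.kind!r}")


def _objective(cfg: WorkspaceConfig, landmarks) -> tuple[float, tuple[float, ...]]:
    res = tuple(_landmark_residual(lm, cfg) for lm in landmarks)
    total = float(sum(lm.weight * r * r for lm, r in zip(landmarks, res)))
    return total, res


def calibrate_geometry(landmarks, free_params=("omega",),
                       base_config: WorkspaceConfig | None = None,
                       bounds: dict | None = None, n_grid: int = 13,
                       n_sweeps: int = 4, shrink: float = 0.35) -> CalibrationResult:
    """Tune unprinted set-up constants against execution-space landmarks.

    Iterated coordinate descent: each free parameter is scanned on a uniform
    grid inside its current bounds, the bounds shrink around the best value,
    and the sweep repeats.  Fully deterministic for a fixed search grid.
    Returns the best configuration together with the total and per-landmark
    residuals (cm-scale violations; 0 means every landmark is satisfied).
    """
    landmarks = list(landmarks)
    if not landmarks:
        raise ValueError("landmark set is empty")
    if base_config is None:
        raise ValueError("base_config is required")
    lims = dict(_DEFAULT_BOUNDS)
    if bounds:
        lims.update(bounds)
    unknown = [p for p in free_params if p not in lims]
    if unknown:
        raise ValueError(f"unknown free parameters: {unknown}")

    current = {
        "pivot_y": base_config.pivot[1],
        "arm_length": base_config.arm_length,
        "omega": base_config.omega,
        "angle_offset": base_config.zero_angle_deg,
    }
    current = {k: v for k, v in current.items() if k in free_params}
    spans = {p: (lims[p][1] - lims[p][0]) for p in free_params}

    best_cfg = _apply_params(base_config, current)
    best_val, best_res = _objective(best_cfg, landmarks)

    for sweep in range(n_sweeps):
        for p in free_params:
            half = spans[p] * (shrink ** sweep) / 2.0
            lo = max(lims[p][0], current[p] - half)
            hi = min(lims[p][1], current[p] + half)
            for x in np.linspace(lo, hi, n_grid):
                trial = dict(current)
                trial[p] = float(x)
                cfg = _apply_params(base_config, trial)
                val, res = _objective(cfg, landmarks)
                if val < best_val - 1e-12:
                    best_val, best_res, best_cfg = val, res, cfg
                    current = trial
    return CalibrationResult(config=best_cfg, residual=best_val,
                             landmark_residuals=best_res)
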