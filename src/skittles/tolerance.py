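"""Tolerance maps and softmax expected-result surfaces.

*Tolerance* T(i, j) is the expected error of the strategy at execution-space
cell (i, j) given the performer's dispersion: a weighted average of the
error surface over a neighborhood, with weights from an independent
bivariate Gaussian whose per-axis standard deviations are the performer's
release-variable SDs.  The kernel is truncated at +/-3 SD and renormalized;
neighborhoods clipped by the grid boundary are renormalized over the
in-range cells.

The expected result E(R) converts Tolerance into a relative preference via
a softmax (negative-exponential) transform scaled to [0, 1]:

    H1 (error tolerance):   E(R) ∝ exp(-T / a)
    H2 (+ velocity cost):   E(R) ∝ exp(-(T / a + v / b))

with temperature ``a`` (cm) and velocity-cost scale ``b`` (deg/s), both
fitted to observed strategy-frequency surfaces by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.optimize import minimize, minimize_scalar

from .execution_space import ExecutionGrid
from .task_model import InvalidInputError

__all__ = [
    "VariabilityProfile",
    "EXP1_PROFILE",
    "EXP2_PROFILE",
    "ToleranceMap",
    "ExpectedResultMap",
    "FitParams",
    "compute_tolerance",
    "expected_result_h1",
    "expected_result_h2",
    "fit_params",
    "aggregate_surface",
]


@dataclass(frozen=True)
class VariabilityProfile:
    """Release-variable dispersion (SD of angle in deg, of velocity in deg/s)."""

    sd_angle: float
    sd_velocity: float

    def __post_init__(self) -> None:
        if not (self.sd_angle > 0 and self.sd_velocity > 0):
            raise InvalidInputError("profile SDs must be > 0")


# Grand-average dispersions printed for the two experiments.
EXP1_PROFILE = VariabilityProfile(sd_angle=11.70, sd_velocity=40.49)
EXP2_PROFILE = VariabilityProfile(sd_angle=9.44, sd_velocity=70.38)


@dataclass(frozen=True)
class ToleranceMap:
    T: np.ndarray
    profile: VariabilityProfile
    grid: ExecutionGrid


@dataclass(frozen=True)
class FitParams:
    a: float
    b: float | None = None
    residual: float | None = None

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise InvalidInputError(f"softmax temperature a must be > 0, got {self.a}")
        if self.b is not None and not self.b > 0:
            raise InvalidInputError(f"velocity-cost scale b must be > 0, got {self.b}")


@dataclass(frozen=True)
class ExpectedResultMap:
    ER: np.ndarray
    hypothesis: str               # "h1" | "h2"
    params: FitParams
    grid: ExecutionGrid

    @property
    def argmax(self) -> tuple[float, float]:
        """(angle, velocity) of the most preferred strategy."""
        i, j = np.unravel_index(int(np.argmax(self.ER)), self.ER.shape)
        return (float(self.grid.angle_bins[i]), float(self.grid.velocity_bins[j]))


def _kernel(sd: float, step: float) -> np.ndarray:
    """Discretized 1-D Gaussian at bin-center offsets, truncated at 3 SD."""
    if sd < step:
        warnings.warn(f"profile SD {sd} is below one bin width {step}; "
                      "the smoothing kernel is nearly a delta")
    k = int(np.floor(3.0 * sd / step))
    off = np.arange(-k, k + 1) * step
    return np.exp(-0.5 * (off / sd) ** 2)


def compute_tolerance(grid: ExecutionGrid, profile: VariabilityProfile) -> ToleranceMap:
    """Gaussian-neighborhood expected error at every execution-space cell.

    Separable normalized convolution: the numerator convolves the error
    surface with the truncated product kernel, the denominator the in-range
    indicator, so boundary neighborhoods average only over existing cells.
    """
    ka = _kernel(profile.sd_angle, grid.angle_step)
    kv = _kernel(profile.sd_velocity, grid.velocity_step)
    num = convolve1d(grid.error, ka, axis=0, mode="constant", cval=0.0)
    num = convolve1d(num, kv, axis=1, mode="constant", cval=0.0)
    wa = convolve1d(np.ones(grid.error.shape[0]), ka, mode="constant", cval=0.0)
    wv = convolve1d(np.ones(grid.error.shape[1]), kv, mode="constant", cval=0.0)
    T = num / np.outer(wa, wv)
    return ToleranceMap(T=T, profile=profile, grid=grid)


def expected_result_h1(tmap: ToleranceMap, a: float) -> ExpectedResultMap:
    """Softmax preference for error-tolerant strategies, scaled to [0, 1]."""
    params = FitParams(a=float(a))
    z = -tmap.T / params.a
    ER = np.exp(z - z.max())
    return ExpectedResultMap(ER=ER, hypothesis="h1", params=params, grid=tmap.grid)


def expected_result_h2(tmap: ToleranceMap, grid: ExecutionGrid | None,
                       a: float, b: float) -> ExpectedResultMap:
    """Softmax preference with an additive velocity cost v/b in the exponent."""
    grid = tmap.grid if grid is None else grid
    params = FitParams(a=float(a), b=float(b))
    v = grid.velocity_bins[None, :]
    z = -(tmap.T / params.a + v / params.b)
    ER = np.exp(z - z.max())
    return ExpectedResultMap(ER=ER, hypothesis="h2", params=params, grid=grid)


def _overlap_weights(n_fine: int, n_coarse: int) -> np.ndarray:
    """Exact index-space overlap of each coarse bin with each fine bin."""
    coarse = np.linspace(0.0, n_fine, n_coarse + 1)
    fine_lo = np.arange(n_fine)
    return np.clip(np.minimum(coarse[1:, None], fine_lo[None, :] + 1.0)
                   - np.maximum(coarse[:-1, None], fine_lo[None, :]), 0.0, None)


def aggregate_surface(surface: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Average a fine lattice surface onto a coarser lattice spanning the
    same ranges (exact piecewise-constant integration per coarse cell)."""
    n0, n1 = surface.shape
    m0, m1 = shape
    if m0 > n0 or m1 > n1:
        raise InvalidInputError(f"cannot aggregate {surface.shape} onto {shape}")
    if n0 % m0 == 0 and n1 % m1 == 0:
        return surface.reshape(m0, n0 // m0, m1, n1 // m1).mean(axis=(1, 3))
    Wa = _overlap_weights(n0, m0)
    Wv = _overlap_weights(n1, m1)
    return (Wa @ surface @ Wv.T) / ((n0 / m0) * (n1 / m1))


def _sse(observed: np.ndarray, ER: np.ndarray) -> float:
    pred = aggregate_surface(ER, observed.shape)
    pred = pred / pred.sum()
    return float(np.sum((observed - pred) ** 2))


def fit_params(observed: np.ndarray, tmap: ToleranceMap,
               grid: ExecutionGrid | None = None, hypothesis: str = "h1",
               a_grid: np.ndarray | None = None,
               b_grid: np.ndarray | None = None) -> FitParams:
    """Least-squares fit of the softmax parameters to an observed surface.

    ``observed`` is a 2-D frequency surface on the full grid lattice or any
    divisor lattice of it (e.g. the 36x36 histogram); it is normalized to
    sum 1 and compared with the identically aggregated, sum-normalized E(R).
    Log-spaced grid search followed by bounded local refinement; the H1 fit
    is the b -> infinity restriction of H2.
    """
    observed = np.asarray(observed, dtype=float)
    tot = observed.sum()
    if not tot > 0:
        raise InvalidInputError("observed surface is all zeros")
    observed = observed / tot
    grid = tmap.grid if grid is None else grid
    if a_grid is None:
        a_grid = np.logspace(0.0, 4.0, 41)
    if b_grid is None:
        b_grid = np.logspace(2.0, 5.0, 31)

    if hypothesis == "h1":
        def obj(log_a: float) -> float:
            return _sse(observed, expected_result_h1(tmap, 10.0 ** log_a).ER)
        vals = [obj(np.log10(a)) for a in a_grid]
        k = int(np.argmin(vals))
        lo = np.log10(a_grid[max(k - 1, 0)])
        hi = np.log10(a_grid[min(k + 1, len(a_grid) - 1)])
        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        return FitParams(a=float(10.0 ** res.x), residual=float(res.fun))

    if hypothesis == "h2":
        def obj2(p) -> float:
            er = expected_result_h2(tmap, grid, 10.0 ** p[0], 10.0 ** p[1])
            return _sse(observed, er.ER)
        best, bval = None, np.inf
        for a in a_grid:
            for b in b_grid:
                v = obj2((np.log10(a), np.log10(b)))
                if v < bval:
                    best, bval = (np.log10(a), np.log10(b)), v
        res = minimize(obj2, x0=np.array(best), method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-14, "maxiter": 400})
        p = res.x if res.fun <= bval else np.array(best)
        return FitParams(a=float(10.0 ** p[0]), b=float(10.0 ** p[1]),
                         residual=float(min(res.fun, bval)))

    raise InvalidInputError(f"unknown hypothesis {hypothesis!r}")
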