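"""Per-subject statistics for throw distributions in execution space.

Covers the full statistical machinery applied to individual subjects:
discretization of a subject's throws into a 5x5 cell matrix centered on
their mean strategy, multinomial log-likelihood of the observed counts under
a softmax-predicted distribution, AIC comparison of the nested hypotheses,
95% confidence ellipses of the release-variable scatter, an exact binomial
test for how many subjects' ellipses cover the predicted optimum, linear
regressions of block-wise variability on mean velocity, and exponential
practice-curve fits to binned median error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .task_model import InvalidInputError
from .tolerance import ExpectedResultMap, VariabilityProfile

__all__ = [
    "TRIAL_COLUMNS",
    "CellMatrix",
    "EllipseParams",
    "ModelFitResult",
    "RegressionReport",
    "PracticeCurve",
    "discretize_trials",
    "predicted_cell_probs",
    "log_likelihood",
    "aic",
    "compare_models",
    "confidence_ellipse",
    "ellipse_overlap_binomial",
    "uniform_coverage_probability",
    "variability_regression",
    "practice_curve",
]

TRIAL_COLUMNS = ["subject", "session", "block", "trial",
                 "angle_deg", "velocity_deg_s", "error_cm", "post_hit"]

#: probability floor applied to predicted cell probabilities before
#: renormalization, keeping the multinomial log-likelihood finite
PROB_FLOOR = 1e-6

CHI2_95_2D = stats.chi2.ppf(0.95, df=2)   # ~5.991


@dataclass(frozen=True)
class CellMatrix:
    """Square cell matrix over execution space (counts or probabilities).

    The matrix is centered on ``center = (mean angle, mean velocity)`` with
    per-axis cell widths ``widths`` (one SD each by default, so a 5x5 matrix
    spans +/-2.5 SD).
    """

    values: np.ndarray
    center: tuple[float, float]
    widths: tuple[float, float]
    kind: str  # "counts" | "probs"

    @property
    def n_cells(self) -> int:
        return self.values.size

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        n0, n1 = self.values.shape
        a = self.center[0] + self.widths[0] * (np.arange(n0 + 1) - n0 / 2.0)
        v = self.center[1] + self.widths[1] * (np.arange(n1 + 1) - n1 / 2.0)
        return a, v


def _subject_trials(trials: pd.DataFrame, subject) -> pd.DataFrame:
    if subject is not None:
        trials = trials[trials["subject"] == subject]
    if trials.empty:
        raise InvalidInputError(f"no trials for subject {subject!r}")
    return trials


def discretize_trials(trials: pd.DataFrame, subject=None,
                      profile: VariabilityProfile | None = None,
                      n: int = 5, span_sd: float = 1.0) -> CellMatrix:
    """Bin a subject's throws into an ``n x n`` matrix centered on their mean.

    Cell widths are ``span_sd`` standard deviations per axis (profile SDs if
    given, else the subject's sample SDs).  Trials outside the span are
    counted in the nearest edge cell, so counts are conserved.
    """
    df = _subject_trials(trials, subject)
    if len(df) < 25:
        raise InvalidInputError(f"need >= 25 trials, got {len(df)}")
    ang = df["angle_deg"].to_numpy(float)
    vel = df["velocity_deg_s"].to_numpy(float)
    center = (float(ang.mean()), float(vel.mean()))
    if profile is None:
        sd_a, sd_v = float(ang.std(ddof=1)), float(vel.std(ddof=1))
    else:
        sd_a, sd_v = profile.sd_angle, profile.sd_velocity
    if not (sd_a > 0 and sd_v > 0):
        raise InvalidInputError("zero dispersion on an axis; cannot discretize")
    widths = (sd_a * span_sd, sd_v * span_sd)
    i = np.clip(np.floor((ang - center[0]) / widths[0] + n / 2.0), 0, n - 1)
    j = np.clip(np.floor((vel - center[1]) / widths[1] + n / 2.0), 0, n - 1)
    counts = np.zeros((n, n))
    np.add.at(counts, (i.astype(int), j.astype(int)), 1.0)
    return CellMatrix(values=counts, center=center, widths=widths, kind="counts")


def _coverage_weights(edges: np.ndarray, cell_edges: np.ndarray) -> np.ndarray:
    """Exact overlap lengths of each coarse cell with each fine grid bin."""
    lo = cell_edges[:-1, None]
    hi = cell_edges[1:, None]
    return np.clip(np.minimum(hi, edges[None, 1:])
                   - np.maximum(lo, edges[None, :-1]), 0.0, None)


def predicted_cell_probs(er: ExpectedResultMap, matrix: CellMatrix,
                         floor: float = PROB_FLOOR) -> CellMatrix:
    """Integrate an E(R) surface over a cell matrix footprint.

    The piecewise-constant E(R) surface is integrated exactly over each cell
    rectangle (per-axis overlap weights), normalized to sum 1, floored at
    ``floor`` and renormalized so the multinomial likelihood stays finite.
    """
    grid = er.grid
    a_edges, v_edges = matrix.edges()
    if (a_edges[0] < grid.angle_edges[0] - 1e-9
            or a_edges[-1] > grid.angle_edges[-1] + 1e-9
            or v_edges[0] < grid.velocity_edges[0] - 1e-9
            or v_edges[-1] > grid.velocity_edges[-1] + 1e-9):
        raise InvalidInputError("cell-matrix footprint extends outside the grid")
    Wa = _coverage_weights(grid.angle_edges, a_edges)
    Wv = _coverage_weights(grid.velocity_edges, v_edges)
    raw = Wa @ er.ER @ Wv.T
    total = raw.sum()
    if not total > 0:
        raise InvalidInputError("E(R) mass over the footprint is zero")
    p = raw / total
    p = np.maximum(p, floor)
    p = p / p.sum()
    return CellMatrix(values=p, center=matrix.center, widths=matrix.widths,
                      kind="probs")


def log_likelihood(observed: CellMatrix, predicted: CellMatrix) -> float:
    """Mean per-trial natural-log multinomial likelihood.

    ``LL = (1/N) * sum_cells count * ln(p)``.  A uniform prediction over 25
    cells gives exactly ``-ln 25 ~ -3.2189`` for any observed counts, the
    lower bracket of realistic fits on a 5x5 matrix.
    """
    if observed.values.shape != predicted.values.shape:
        raise InvalidInputError("observed and predicted matrices differ in shape")
    counts = observed.values
    p = predicted.values
    N = counts.sum()
    if not N > 0:
        raise InvalidInputError("observed matrix holds no trials")
    if np.any(p <= 0):
        raise InvalidInputError("predicted probabilities contain zeros; "
                                "apply the probability floor upstream")
    return float((counts * np.log(p)).sum() / N)


@dataclass(frozen=True)
class ModelFitResult:
    hypothesis: str
    a: float
    b: float | None
    LL: float
    n_params: int

    @property
    def AIC(self) -> float:
        return aic(self.LL, self.n_params)


def aic(LL: float, n_params: int) -> float:
    """Akaike information criterion for a mean per-trial log likelihood."""
    return 2.0 * n_params - 2.0 * LL


def compare_models(fit_h1: ModelFitResult, fit_h2: ModelFitResult) -> dict:
    """Select the lower-AIC hypothesis; H2 can never have the lower LL."""
    if fit_h1.hypothesis != "h1" or fit_h2.hypothesis != "h2":
        raise InvalidInputError("expected an (h1, h2) pair of fits")
    if fit_h2.LL < fit_h1.LL - 1e-9:
        raise InvalidInputError(
            f"nesting violated: LL(H2) = {fit_h2.LL} < LL(H1) = {fit_h1.LL}; "
            "the H2 fit did not reach the H1 optimum")
    winner = "h1" if fit_h1.AIC <= fit_h2.AIC else "h2"
    return {"winner": winner, "h1": fit_h1, "h2": fit_h2,
            "delta_aic": fit_h2.AIC - fit_h1.AIC}


# ---------------------------------------------------------------------------
# Confidence ellipses and the overlap count test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipseParams:
    """Covariance ellipse of a release-variable scatter.

    ``convention='chi2-95'`` scales the eigenvalue square roots by
    sqrt(chi2_0.95(2)) for true 95% Gaussian coverage; ``'raw'`` uses the
    square roots directly (one-sigma ellipse).
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation_deg: float
    convention: str

    @property
    def half_width_angle(self) -> float:
        """Half-extent of the ellipse along the angle axis (deg)."""
        th = math.radians(self.orientation_deg)
        return math.hypot(self.semi_major * math.cos(th),
                          self.semi_minor * math.sin(th))

    def contains(self, point) -> bool:
        th = math.radians(self.orientation_deg)
        R = np.array([[math.cos(th), math.sin(th)],
                      [-math.sin(th), math.cos(th)]])
        u = R @ (np.asarray(point, float) - np.asarray(self.center))
        return bool((u[0] / self.semi_major) ** 2
                    + (u[1] / self.semi_minor) ** 2 <= 1.0)


def confidence_ellipse(trials: pd.DataFrame, subject=None,
                       convention: str = "chi2-95") -> EllipseParams:
    """Covariance ellipse of a subject's (angle, velocity) scatter.

    Eigendecomposition of the 2x2 sample covariance matrix; the square roots
    of the eigenvalues size the semi-axes (scaled per ``convention``) and
    the leading eigenvector sets the orientation.
    """
    df = _subject_trials(trials, subject)
    if len(df) < 3:
        raise InvalidInputError("need >= 3 trials for a covariance ellipse")
    X = df[["angle_deg", "velocity_deg_s"]].to_numpy(float)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[1], 1.0):
        raise InvalidInputError("singular covariance; scatter is degenerate")
    if convention == "chi2-95":
        scale = math.sqrt(CHI2_95_2D)
    elif convention == "raw":
        scale = 1.0
    else:
        raise InvalidInputError(f"unknown ellipse convention {convention!r}")
    lead = evecs[:, 1]
    return EllipseParams(
        center=(float(X[:, 0].mean()), float(X[:, 1].mean())),
        semi_major=float(scale * math.sqrt(evals[1])),
        semi_minor=float(scale * math.sqrt(evals[0])),
        orientation_deg=float(math.degrees(math.atan2(lead[1], lead[0]))),
        convention=convention,
    )


def ellipse_overlap_binomial(k_overlap: int, n_subjects: int,
                             p_null: float) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Bin(n, p).

    Used to test whether the number of subjects whose confidence ellipse
    covers the predicted optimum exceeds chance coverage ``p_null``.
    """
    if not (0 <= k_overlap <= n_subjects):
        raise InvalidInputError("need 0 <= k <= n")
    if not (0.0 < p_null < 1.0):
        raise InvalidInputError("p_null must be in (0, 1)")
    return float(sum(math.comb(n_subjects, i)
                     * p_null ** i * (1.0 - p_null) ** (n_subjects - i)
                     for i in range(k_overlap, n_subjects + 1)))


def uniform_coverage_probability(halfwidth: float, lo: float, hi: float) -> float:
    """Chance that an interval of +/-``halfwidth`` covers a uniform point.

    The null coverage probability for the ellipse-overlap test: an ellipse
    of average angular radius ``halfwidth`` placed uniformly over the
    solution range [lo, hi] covers a fixed point with probability
    ``2*halfwidth / (hi - lo)`` (capped at 1).
    """
    if not hi > lo or not halfwidth > 0:
        raise InvalidInputError("need hi > lo and halfwidth > 0")
    return min(1.0, 2.0 * halfwidth / (hi - lo))


# ---------------------------------------------------------------------------
# Velocity-dependent variability and practice curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionReport:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n_groups: int


def variability_regression(trials: pd.DataFrame,
                           group_cols=("subject", "session", "block")) -> dict:
    """Regress block-wise release SDs on block mean velocity.

    Per (subject, session, block) group: mean velocity, SD(angle),
    SD(velocity).  Each SD is regressed on mean velocity by OLS; returns
    ``{'sd_angle': RegressionReport, 'sd_velocity': ..., 'groups': frame}``.
    A velocity-proportional noise law shows up as a significant positive
    slope; manifold-channeled cohorts show none.
    """
    group_cols = [c for c in group_cols if c in trials.columns]
    g = trials.groupby(group_cols, sort=True)
    summary = pd.DataFrame({
        "mean_velocity": g["velocity_deg_s"].mean(),
        "sd_angle": g["angle_deg"].std(ddof=1),
        "sd_velocity": g["velocity_deg_s"].std(ddof=1),
    }).dropna().reset_index()
    if len(summary) < 3:
        raise InvalidInputError("need >= 3 groups for the regression")
    x = summary["mean_velocity"].to_numpy()
    if np.ptp(x) == 0:
        raise InvalidInputError("identical mean velocities across groups")
    out = {"groups": summary}
    for col in ("sd_angle", "sd_velocity"):
        res = stats.linregress(x, summary[col].to_numpy())
        out[col] = RegressionReport(slope=float(res.slope),
                                    intercept=float(res.intercept),
                                    r2=float(res.rvalue ** 2),
                                    p_value=float(res.pvalue),
                                    n_groups=len(summary))
    return out


@dataclass(frozen=True)
class PracticeCurve:
    bin_centers: np.ndarray     # trial number at bin center
    medians: np.ndarray
    iqr_low: np.ndarray
    iqr_high: np.ndarray
    c: float                    # asymptotic error, cm
    d: float                    # initial excess error, cm
    lam: float                  # decay constant, trials

    def fitted(self, t) -> np.ndarray:
        return self.c + self.d * np.exp(-np.asarray(t, float) / self.lam)


def practice_curve(trials: pd.DataFrame, bin_size: int = 15) -> PracticeCurve:
    """Binned median error over practice with an exponential fit.

    Trials are pooled across subjects in non-overlapping ``bin_size``-trial
    bins by within-subject trial index; medians (with interquartile ranges)
    summarize each bin because the discrete post-hit penalty would skew
    means.  The median series is fitted by ``c + d*exp(-t/lam)`` with
    c, d >= 0 and lam > 0.
    """
    df = trials.dropna(subset=["error_cm"]).copy()
    n_trials = int(df.groupby("subject")["trial"].count().max())
    n_bins = n_trials // bin_size
    if n_bins < 2:
        raise InvalidInputError("need at least 2 practice bins")
    order = df.sort_values(["subject", "session", "block", "trial"])
    order["seq"] = order.groupby("subject").cumcount()
    order = order[order["seq"] < n_bins * bin_size]
    order["bin"] = order["seq"] // bin_size
    med = order.groupby("bin")["error_cm"].median().to_numpy()
    q1 = order.groupby("bin")["error_cm"].quantile(0.25).to_numpy()
    q3 = order.groupby("bin")["error_cm"].quantile(0.75).to_numpy()
    t = (np.arange(n_bins) + 0.5) * bin_size

    c0 = max(float(med[-1]), 1e-6)
    d0 = max(float(med[0] - med[-1]), 1e-6)
    lam0 = max(n_trials / 5.0, bin_size)
    try:
        popt, _ = curve_fit(lambda tt, c, d, lam: c + d * np.exp(-tt / lam),
                            t, med, p0=(c0, d0, lam0),
                            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                            maxfev=20000)
        c, d, lam = map(float, popt)
    except RuntimeError:
        c, d, lam = c0, 0.0, lam0
    return PracticeCurve(bin_centers=t, medians=med, iqr_low=q1, iqr_high=q3,
                         c=c, d=d, lam=lam)
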