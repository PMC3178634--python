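"""Per-subject statistics: discretization, likelihoods, AIC, ellipses,
binomial overlap test, variability regressions, practice curves."""

import math

import numpy as np
import pandas as pd
import pytest

from skittles import (CellMatrix, InvalidInputError, VariabilityProfile, aic,
                      compare_models, compute_tolerance, confidence_ellipse,
                      discretize_trials, ellipse_overlap_binomial,
                      expected_result_h1, expected_result_h2, fit_subject,
                      log_likelihood, practice_curve, predicted_cell_probs,
                      sample_from_expected_result,
                      uniform_coverage_probability, variability_regression)
from skittles.subject_stats import ModelFitResult

from test_tolerance import make_grid


def trials_frame(ang, vel, subject="S1", session=1, block=1, error=None):
    n = len(ang)
    return pd.DataFrame({
        "subject": subject, "session": session, "block": block,
        "trial": np.arange(1, n + 1),
        "angle_deg": np.asarray(ang, float),
        "velocity_deg_s": np.asarray(vel, float),
        "error_cm": np.zeros(n) if error is None else np.asarray(error, float),
        "post_hit": 0,
    })


class TestDiscretize:
    def test_identical_trials_fill_the_center_cell(self):
        tr = trials_frame(np.full(30, -50.0), np.full(30, 200.0))
        m = discretize_trials(tr, "S1", profile=VariabilityProfile(5.0, 20.0))
        assert m.values.sum() == 30
        assert m.values[2, 2] == 30

    def test_counts_conserved_with_out_of_span_clipping(self, rng):
        ang = rng.normal(-50.0, 12.0, 400)
        vel = rng.normal(200.0, 40.0, 400)
        # plant gross outliers that must be clipped into edge cells
        ang[:5] = -160.0
        vel[:5] = 900.0
        m = discretize_trials(trials_frame(ang, vel), "S1")
        assert m.values.sum() == 400
        assert m.values.shape == (5, 5)

    def test_large_isotropic_sample_peaks_in_center(self, rng):
        ang = rng.normal(0.0, 10.0, 20_000)
        vel = rng.normal(0.0, 10.0, 20_000)
        m = discretize_trials(trials_frame(ang, vel), "S1")
        assert m.values.argmax() == 12  # center of the 5x5

    def test_too_few_trials_rejected(self):
        tr = trials_frame(np.zeros(10), np.zeros(10))
        with pytest.raises(InvalidInputError):
            discretize_trials(tr, "S1")

    def test_zero_dispersion_rejected(self):
        tr = trials_frame(np.full(30, 1.0), np.arange(30, dtype=float))
        with pytest.raises(InvalidInputError):
            discretize_trials(tr, "S1")


class TestPredictedCellProbs:
    @pytest.fixture()
    def uniform_er(self):
        g = make_grid(np.full((40, 40), 10.0))
        tm = compute_tolerance(g, VariabilityProfile(2.0, 5.0))
        return expected_result_h1(tm, a=5.0)

    def matrix(self, center=(20.0, 50.0), widths=(4.0, 10.0)):
        return CellMatrix(values=np.zeros((5, 5)), center=center,
                          widths=widths, kind="counts")

    def test_uniform_surface_gives_equal_cell_probabilities(self, uniform_er):
        p = predicted_cell_probs(uniform_er, self.matrix())
        np.testing.assert_allclose(p.values, 1.0 / 25.0, rtol=1e-9)

    def test_concentrated_surface_hits_the_probability_floor(self, uniform_er):
        er = uniform_er
        conc = np.full_like(er.ER, 1e-30)
        conc[20, 20] = 1.0
        er2 = type(er)(ER=conc, hypothesis="h1", params=er.params, grid=er.grid)
        p = predicted_cell_probs(er2, self.matrix())
        eps = 1e-6
        assert p.values.max() == pytest.approx(1.0 - 24.0 * eps, rel=1e-6)
        assert p.values.min() == pytest.approx(eps, rel=1e-3)

    def test_matches_fine_subgrid_integration_oracle(self, rng):
        E = rng.uniform(0.0, 60.0, (40, 40))
        g = make_grid(E)  # angle bins 1 wide, velocity bins 2.5 wide
        tm = compute_tolerance(g, VariabilityProfile(0.51, 1.3))
        er = expected_result_h1(tm, a=10.0)
        # cell edges aligned with grid bins: exact integral = block sums
        m = CellMatrix(values=np.zeros((5, 5)), center=(20.0, 50.0),
                       widths=(4.0, 10.0), kind="counts")
        p = predicted_cell_probs(er, m)
        a_edges, v_edges = m.edges()
        ref = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                ii = (g.angle_bins > a_edges[i]) & (g.angle_bins < a_edges[i + 1])
                jj = (g.velocity_bins > v_edges[j]) & (g.velocity_bins < v_edges[j + 1])
                ref[i, j] = er.ER[np.ix_(ii, jj)].sum() * 1.0 * 2.5
        ref /= ref.sum()
        np.testing.assert_allclose(p.values, ref, atol=1e-6)

    def test_footprint_outside_grid_rejected(self, uniform_er):
        with pytest.raises(InvalidInputError):
            predicted_cell_probs(uniform_er, self.matrix(center=(1.0, 50.0)))


class TestLikelihoodAndAIC:
    def test_uniform_prediction_scores_minus_log_25(self, rng):
        counts = CellMatrix(rng.integers(0, 50, (5, 5)).astype(float),
                            (0, 0), (1, 1), "counts")
        pred = CellMatrix(np.full((5, 5), 1.0 / 25.0), (0, 0), (1, 1), "probs")
        assert log_likelihood(counts, pred) == pytest.approx(-math.log(25.0),
                                                             abs=1e-12)

    def test_point_mass_on_argmax_cell_scores_log_p(self):
        pred_vals = np.full((5, 5), (1.0 - 0.4) / 24.0)
        pred_vals[1, 3] = 0.4
        counts = np.zeros((5, 5))
        counts[1, 3] = 77
        LL = log_likelihood(CellMatrix(counts, (0, 0), (1, 1), "counts"),
                            CellMatrix(pred_vals, (0, 0), (1, 1), "probs"))
        assert LL == pytest.approx(math.log(0.4), abs=1e-12)

    def test_large_sample_ll_approaches_negative_entropy(self, rng):
        p = rng.dirichlet(np.ones(25)).reshape(5, 5)
        counts = rng.multinomial(200_000, p.ravel()).reshape(5, 5).astype(float)
        LL = log_likelihood(CellMatrix(counts, (0, 0), (1, 1), "counts"),
                            CellMatrix(p, (0, 0), (1, 1), "probs"))
        entropy = -(p * np.log(p)).sum()
        assert LL == pytest.approx(-entropy, abs=0.01)

    def test_zero_probability_rejected(self):
        counts = CellMatrix(np.ones((5, 5)), (0, 0), (1, 1), "counts")
        pred = CellMatrix(np.zeros((5, 5)), (0, 0), (1, 1), "probs")
        with pytest.raises(InvalidInputError):
            log_likelihood(counts, pred)

    @pytest.mark.parametrize("LL,k,expected", [
        (-3.08, 1, 8.16),   # printed per-subject H1 row
        (-2.88, 2, 9.76),   # same subject, H2
        (0.0, 1, 2.0),
    ])
    def test_aic_identity(self, LL, k, expected):
        assert aic(LL, k) == pytest.approx(expected, abs=1e-12)

    def test_identical_likelihood_prefers_fewer_parameters(self):
        f1 = ModelFitResult("h1", a=10.0, b=None, LL=-3.0, n_params=1)
        f2 = ModelFitResult("h2", a=10.0, b=1e4, LL=-3.0, n_params=2)
        assert compare_models(f1, f2)["winner"] == "h1"

    def test_nesting_violation_raises(self):
        f1 = ModelFitResult("h1", a=10.0, b=None, LL=-2.5, n_params=1)
        f2 = ModelFitResult("h2", a=10.0, b=1e4, LL=-3.0, n_params=2)
        with pytest.raises(InvalidInputError):
            compare_models(f1, f2)

    def test_strong_velocity_cost_data_let_h2_win_aic(self):
        """Throws sampled from a strong-velocity-cost preference surface on a
        workspace where low tolerance favors high velocity: only H2 can place
        probability where the data are, and its per-trial likelihood gain
        exceeds the AIC parameter penalty."""
        n = 40
        v = (np.arange(n) + 0.5) * 2.5
        a = (np.arange(n) + 0.5) * 1.0
        col = np.where(v < 20.0, 200.0, 50.0 - 0.5 * (v - 20.0))  # drops with v
        E = 2.0 * np.abs(a[:, None] - 20.0) + col[None, :]
        g = make_grid(E)
        tm = compute_tolerance(g, VariabilityProfile(0.6, 1.3))
        gen = expected_result_h2(tm, g, a=5.0, b=2.5)
        ang, vel = sample_from_expected_result(gen, 600, seed=3)
        tr = trials_frame(ang, vel)
        prof = VariabilityProfile(7.5, 10.0)
        b_grid = np.logspace(0.0, 3.0, 16)
        f1 = fit_subject(tr, "S1", g, tm, "h1", matrix_profile=prof)
        f2 = fit_subject(tr, "S1", g, tm, "h2", matrix_profile=prof,
                         b_grid=b_grid)
        verdict = compare_models(f1, f2)
        assert f2.LL >= f1.LL
        assert verdict["winner"] == "h2"


class TestEllipse:
    def test_isotropic_scatter_gives_a_circle(self, rng):
        tr = trials_frame(rng.normal(0, 1, 5000), rng.normal(0, 1, 5000))
        e = confidence_ellipse(tr, "S1")
        assert e.semi_major / e.semi_minor < 1.1

    def test_orientation_follows_a_45_degree_stretch(self, rng):
        z = rng.normal(0, 10, 4000)
        tr = trials_frame(z + rng.normal(0, 1, 4000),
                          z + rng.normal(0, 1, 4000))
        e = confidence_ellipse(tr, "S1")
        assert abs(e.orientation_deg - 45.0) < 3.0

    def test_chi2_convention_covers_95_percent_of_gaussian_mass(self, rng):
        ang = rng.normal(-50, 11.7, 20_000)
        vel = rng.normal(200, 40.5, 20_000)
        e = confidence_ellipse(trials_frame(ang, vel), "S1")
        inside = np.mean([e.contains((a, v)) for a, v in zip(ang, vel)])
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_raw_convention_is_the_one_sigma_ellipse(self, rng):
        tr = trials_frame(rng.normal(0, 2, 3000), rng.normal(0, 6, 3000))
        raw = confidence_ellipse(tr, "S1", convention="raw")
        chi = confidence_ellipse(tr, "S1", convention="chi2-95")
        ratio = chi.semi_major / raw.semi_major
        assert ratio == pytest.approx(math.sqrt(5.991), abs=0.01)

    def test_singular_scatter_rejected(self):
        tr = trials_frame(np.arange(10, dtype=float), np.arange(10, dtype=float))
        with pytest.raises(InvalidInputError):
            confidence_ellipse(tr, "S1")


class TestBinomialOverlap:
    def test_seven_of_nine_at_thirty_percent_null(self):
        assert ellipse_overlap_binomial(7, 9, 0.30) == pytest.approx(0.004,
                                                                     abs=5e-4)

    def test_zero_overlaps_has_probability_one(self):
        assert ellipse_overlap_binomial(0, 9, 0.30) == pytest.approx(1.0,
                                                                     abs=1e-12)

    def test_all_overlaps_is_p_to_the_n(self):
        assert ellipse_overlap_binomial(9, 9, 0.30) == pytest.approx(0.3 ** 9,
                                                                     rel=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(InvalidInputError):
            ellipse_overlap_binomial(10, 9, 0.3)
        with pytest.raises(InvalidInputError):
            ellipse_overlap_binomial(3, 9, 1.5)

    def test_coverage_probability_of_25_deg_radius_over_solution_range(self):
        p = uniform_coverage_probability(25.0, -165.0, 0.0)
        assert p == pytest.approx(50.0 / 165.0)


class TestVariabilityRegression:
    @staticmethod
    def blocks(sds_v, sds_a, means, n=40, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for b, (m, sv, sa) in enumerate(zip(means, sds_v, sds_a), start=1):
            frames.append(trials_frame(rng.normal(-60, sa, n),
                                       rng.normal(m, sv, n), block=b))
        return pd.concat(frames, ignore_index=True)

    def test_sd_proportional_to_velocity_gives_r2_one(self):
        # deterministic scatter: scale one fixed shape per block
        base = np.array([-1.5, -0.5, 0.5, 1.5] * 10)
        frames = []
        for b, m in enumerate([100.0, 300.0, 500.0, 700.0], start=1):
            frames.append(trials_frame(np.tile([-61, -59], 20),
                                       m + 0.1 * m * base, block=b))
        tr = pd.concat(frames, ignore_index=True)
        rep = variability_regression(tr, group_cols=("subject", "block"))
        assert rep["sd_velocity"].r2 == pytest.approx(1.0, abs=1e-9)
        assert rep["sd_velocity"].slope > 0

    def test_constant_noise_shows_no_velocity_dependence(self):
        tr = self.blocks([25.0] * 5, [5.0] * 5,
                         [150.0, 300.0, 450.0, 600.0, 750.0], seed=11)
        rep = variability_regression(tr, group_cols=("subject", "block"))
        assert rep["sd_velocity"].p_value > 0.1
        assert rep["sd_angle"].p_value > 0.1

    def test_identical_mean_velocities_rejected(self):
        base = np.array([-1.0, 1.0] * 20)
        frames = [trials_frame(np.tile([-61, -59], 20), 300.0 + 20 * base,
                               block=b) for b in (1, 2, 3)]
        with pytest.raises(InvalidInputError):
            variability_regression(pd.concat(frames, ignore_index=True),
                                   group_cols=("subject", "block"))


class TestPracticeCurve:
    def test_constant_error_series_fits_a_flat_line(self):
        tr = trials_frame(np.zeros(150), np.zeros(150),
                          error=np.full(150, 8.5))
        pc = practice_curve(tr)
        assert pc.c + pc.d * 0 == pytest.approx(8.5, abs=1e-6) or \
            pc.fitted(pc.bin_centers[0]) == pytest.approx(8.5, abs=1e-6)
        assert np.allclose(pc.medians, 8.5)

    def test_noiseless_exponential_decay_is_recovered(self):
        t = np.arange(540, dtype=float)
        err = 3.0 + 20.0 * np.exp(-t / 90.0)
        tr = trials_frame(np.zeros(540), np.zeros(540), error=err)
        pc = practice_curve(tr)
        assert len(pc.bin_centers) == 36           # 540 / 15 bins
        assert pc.c == pytest.approx(3.0, rel=0.05)
        assert pc.d == pytest.approx(20.0, rel=0.10)
        assert pc.lam == pytest.approx(90.0, rel=0.10)

    def test_too_few_trials_rejected(self):
        tr = trials_frame(np.zeros(10), np.zeros(10), error=np.ones(10))
        with pytest.raises(InvalidInputError):
            practice_curve(tr)
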