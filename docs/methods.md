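# Methods

This note documents the model, the reconstruction choices, the synthetic
data conditions, and the numerical details behind the `skittles` package.
Everything stated here is computed by the package's tests or scripts; no
empirical claim is made beyond what the code produces.

## Flight model

After release the ball is treated as a point mass in a linear centripetal
force field anchored at the post center — an isotropic harmonic oscillator.
With release position `p₀`, release velocity `v₀`, frequency ω and damping
time constant τ the closed-form path is

```
p(t) = c + [A cos ωt + B sin ωt] e^(−t/τ),   A = p₀ − c.
```

For the undamped default `B = v₀/ω`; with finite τ we set
`B = (v₀ + A/τ)/ω` so that position *and* velocity at t = 0 always equal
the release state (the bare formula would start with velocity
`v₀ − A/τ`). Damping is configurable but off by default: the published
description of the task specifies an elliptic orbit, and an undamped orbit
keeps the error function independent of the display duration.

**Evaluation horizon.** The error is minimized over one full oscillator
period by default (`horizon: null`). The original display showed the ball
for 1 s; scoring a fixed window would silently couple the error surface to
ω, so the display-independent closed orbit is used and the horizon is left
configurable for sensitivity analyses.

**Release kinematics.** The lever tip moves on a circle of radius
`arm_length` about `pivot`; α is measured from `angle_zero_direction` with
sense `rotation_sign`, and the tangential speed is `|v|·(π/180)·arm_length`
(all lengths cm, angles deg). Negative velocities are simulated as-is and
produce the mirrored orbit — the operation is total.

**Post hits.** A trial is a post hit when the ball *disk* contacts the post
*disk*, i.e. the ball-center orbit comes within `post_radius + ball_radius`
of the post center. Radii are physical: a trajectory that only touches the
target scores `ball_radius + target_radius = 4 cm`, and the same contact
logic is applied to the post. For the undamped full-period orbit the
closest approach to the post center is exactly the ellipse's semi-minor
axis (the orbit is centered on the post), which the implementation uses in
closed form; the distance to the (off-center) target is minimized
numerically — coarse sampling of the squared distance at 360 phases
followed by safeguarded Newton polishing, which agrees with a 10⁵-point
dense-sampling oracle to well below 0.01 cm.

## Calibrated workspaces

The published geometry fixes post, target, radii and penalty, but not the
virtual manipulandum (pivot, lever length, angle convention) or ω. These
are exposed in `WorkspaceConfig` and tuned by `calibrate_geometry`, a
deterministic iterated coordinate-descent over {pivot height, arm length,
ω, angle offset} that minimizes squared violations of execution-space
landmarks ("this strategy is on the manifold", "this strategy hits the
post", "some solution exists at this angle").

* `exp1_calibrated` — pivot (0, −200) cm, arm 45 cm, ω = 0.901 rad/s,
  angle zero at −40.3°, counterclockwise. The resulting manifold passes
  within 0.02 cm of the two published landmark strategies (−44°, 161°/s)
  and (−29°, 122°/s). The zero-error set is a closed loop whose upper part
  exceeds the 600 °/s range; the loop bounds a shallow basin (error
  < 2 cm), and the H1 preference maximum falls inside that basin at
  (−56.6°, 209°/s) — about 12° from the published (−44°, 161°/s) optimum.
  That offset is reported as a calibration residual: it depends on the
  unprinted set-up constants, and tests assert only the qualitative
  location (low-|α|, low-velocity, near-zero error, clear of the post).
  Under this flight model the penalty region lies *below* the manifold in
  velocity (within ~1 SD_v at the closest point) rather than abutting its
  low-angle end.
* `exp2_calibrated` — pivot (0, −120) cm, arm 15.05 cm, angle zero at
  −168.6°, ω = 1.256 rad/s. The release circle passes through the point
  diametrically opposite the target, which makes the solution manifold
  *exactly* velocity-insensitive at α = −82° (the orbit satisfies
  r(π) = −A for every velocity); ω places the post-grazing boundary
  between 140 and 144 °/s, matching the published minimum-velocity
  solution at 142 °/s, and the H1 preference maximum lands at
  (−81.8°, 999°/s) against the published (−82°, 1000°/s).

## Tolerance and expected result

Tolerance is a normalized convolution: a separable Gaussian kernel with
per-axis SDs from the `VariabilityProfile`, truncated at ±3 SD, discretized
at bin centers, and renormalized over in-range cells so that boundary
neighborhoods average only over existing execution-space cells. A profile
SD below one bin width triggers a warning (near-delta kernel), not an
error. The implementation is verified against an explicit double-loop
oracle to 10⁻¹⁰ relative error.

The exact softmax algebra of the original analysis is not published. This
package uses

```
E(R) = exp(−T/a) / max exp(−T/a)          (H1)
E(R) = exp(−(T/a + v/b)) / max(...)       (H2, additive linear velocity cost)
```

Max-normalization is chosen because the published description scales E(R)
to [0, 1] with a maximum of exactly 1, which sum-normalization cannot do;
a consequence worth knowing is that E(R) is *exactly* invariant to adding
a constant to T. The linear v/b reading of the velocity cost matches the
order of magnitude of the published b values (10³–10⁴ °/s yields velocity
contributions comparable to T/a); a quadratic option (`v²/b`) would be a
one-line change in `expected_result_h2` and is deliberately not a second
code path.

**Fitting.** Pooled fits minimize the squared deviation between the
sum-normalized E(R) (aggregated onto the observed lattice, 36×36 by
default) and the observed frequency surface: log-spaced grid search
(a ∈ 10⁰..10⁴ cm, b ∈ 10²..10⁵ °/s) with bounded golden-section (H1) or
Nelder–Mead (H2) refinement, deterministic throughout. Per-subject fits
maximize the 5×5 multinomial likelihood over the same lattice instead: a
least-squares optimum need not be the likelihood optimum, and the
likelihood criterion (with b = ∞ included in the H2 candidate set)
guarantees the nesting invariant LL(H2) ≥ LL(H1) that the AIC comparison
relies on. Least squares remains available per subject via
`fit_subject(..., criterion="lsq")`.

## Per-subject statistics

* **5×5 matrix** — centered on the subject's mean strategy, one SD per
  axis per cell (span ±2.5 SD; the published description fixes only "5×5,
  sized by the individual's SDs"). Out-of-span trials are clipped into the
  nearest edge cell so the multinomial N is conserved. Both choices are
  configurable.
* **Predicted cell probabilities** — exact integration of the piecewise-
  constant E(R) surface over each cell rectangle (per-axis overlap
  weights), normalized, floored at ε = 10⁻⁶ and renormalized so empty
  predicted cells cannot produce −∞ log likelihoods. A footprint leaving
  the grid is an error, not silently clipped.
* **Log likelihood** — mean per-trial natural log, `Σ count·ln p / N`.
  This convention makes the uniform prediction score exactly
  −ln 25 ≈ −3.219, the lower bracket of realistic 5×5 fits, and it is the
  convention under which the published per-subject AIC values satisfy
  AIC = 2k − 2·LL. Under it the AIC penalty (2 units) corresponds to one
  *per-trial* log unit, so the velocity-cost model can only win a
  comparison when the data show structure the tolerance-only model
  actively contradicts; the test suite constructs exactly such a case.
* **Confidence ellipses** — eigendecomposition of the 2×2 sample
  covariance. Default scaling multiplies the eigenvalue square roots by
  √χ²₀.₉₅(2) ≈ 2.45 for true 95% Gaussian coverage (verified by Monte
  Carlo); the literal "square roots of the eigenvalues" one-sigma reading
  is available as `convention="raw"`. The overlap count test uses each
  ellipse's half-width along the angle axis, an exact binomial upper tail,
  and a null coverage of `2·radius / angle range` (25° over −165..0 gives
  the 30% null).
* **Variability regressions** — per (subject, session, block) group: mean
  velocity, SD(angle), SD(velocity); each SD regressed on mean velocity by
  OLS with slope, r² and two-sided p reported.
* **Practice curve** — pooled non-overlapping 15-trial bins, medians with
  IQRs (medians because the discrete 60 cm penalties would skew means),
  fitted by `c + d·exp(−t/λ)` with c, d ≥ 0, λ > 0 via bounded
  least squares.

## Synthetic cohorts

The generator defines the study conditions; its defaults are not tuned to
any test outcome.

* Release distributions are bivariate Gaussian with the published
  grand-average SDs — (11.70°, 40.49 °/s) and (9.44°, 70.38 °/s) for the
  two workspaces — and configurable angle–velocity correlation.
* Session structure: 3 sessions × 3 blocks × 60 trials (540 throws) and
  5 × 3 × 60 (900 throws; analyses drop session 1, leaving 720), matching
  the experimental designs.
* Default strategy centers sit on the low-velocity branches of the first
  workspace's solution set, far enough from the grid edges that every
  subject's ±2.5 SD matrix stays inside the execution space; the second
  workspace's cohort spreads subject means over 240–775 °/s on the
  vertical manifold.
* Practice drift is an explicitly synthetic exponential relaxation of the
  center offset and SD inflation (defaults: 3× SDs and a (20°, 80 °/s)
  offset decaying with a 60-trial constant) — it emulates the fast
  first-session improvement without claiming a learning model.
* The no-target control draws five 25-trial blocks at increasing
  instructed velocities with linear signal-dependent noise laws
  (SD_v = 0.10·v + 10, SD_α = 0.015·v + 2 by default); the cohort helper
  adds lognormal between-subject variation (CV 0.25) to the slopes, which
  puts the pooled SD-on-velocity r² in the 0.5–0.8 range rather than near
  1. Since there is no target, no distance error is scored (NaN except for
  the post-hit penalty).
* Every table is reproducible byte-for-byte: one PCG64 stream per subject,
  seeded from its `SubjectSpec`, independent of cohort order.

What passing tests on these cohorts do **not** show: real subjects are not
Gaussian around a fixed strategy, their variability is shaped by learning
and by manifold-aligned covariation that the generator only caricatures
with a correlation coefficient, and the published per-subject likelihood
values cannot be reproduced without the authors' raw data. The tests
verify the machinery and its qualitative contrasts (e.g. signal-dependent
noise detected in control blocks but channeled away in task cohorts), not
the human results.

## Numerical details and degenerate inputs

* Grid cells are half-open bins on a regular lattice; values are exact
  pointwise error evaluations at bin centers, bitwise reproducible.
* Manifold extraction refines contiguous sub-threshold runs per angle
  column by bounded 1-D minimization along velocity (xatol 10⁻⁷) and
  reports a finite-difference curvature; an empty manifold warns rather
  than raises. Membership threshold defaults to 0.01 cm.
* Root/optimum searches, grid searches and refinements are deterministic;
  no stage draws randomness except the data generators, which take
  explicit seeds.
* Zero dispersions, empty observed matrices, singular covariances,
  non-finite release variables, misordered pipeline stages and footprints
  outside the grid raise typed errors (`InvalidInputError`, `ConfigError`,
  `TrialTableError`).
* Problem sizes used by the shipped tests and acceptance script: 360×360
  execution grids (the published resolution), 36×36 pooled histograms,
  10⁴-throw recovery samples, and a 90×90 scan to locate a post-hitting
  release. A full grid + Tolerance + E(R) pass takes a few seconds on one
  CPU.

## Known limitations

* The flight-model constants are reconstructions; quantitative surfaces
  (e.g. the exact preference maximum of the first workspace) carry a
  calibration residual of order 10° / 50 °/s.
* The softmax algebra is a documented reconstruction of an unpublished
  supplement; alternative normalizations would change fitted a, b scales.
* Only the Tolerance component of the tolerance–noise–covariation
  decomposition is computed; Noise and Covariation costs are out of scope,
  as are biomechanics, risk-attitude modeling and interactive display.
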