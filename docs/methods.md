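# Methods

## Coordinate conventions

Image coordinates are (x, y) = (column, row), 0-based, origin top-left,
y increasing downward; rotations are positive from +x toward +y. The FAF
frame is a 30° × 30° field sampled at 768 × 768 px (0.0390625 °/px); the
SLO frame defaults to a 36° × 36° field at 1024 × 1024 px. Degrees of
visual angle convert to retinal micrometers at 288 µm/° — the emmetropic
schematic-eye approximation — giving 11.25 µm per FAF pixel. Both constants
are configurable (`UnitConventions`); no axial-length individualization is
applied by default.

## Registration

The SLO→FAF map is an orientation-preserving 2-D similarity (4 DoF) fitted
to manually placed fiducial pairs by closed-form least squares: writing
points as complex numbers, the optimizer of Σ|a·z + b − w|² is
a = cov(w, z̄)/var(z), b = w̄ − a·z̄, with s = |a| and θ = arg(a).
Reflections cannot arise (det = +s²). Two pairs are mathematically
sufficient and accepted; the CLI warns below four. No fiducial outlier
rejection is performed — the fit RMSE is reported so callers can flag poor
registrations. The inverse transform carries RMSE/s as its residual
(forward residuals mapped into the source frame).

Degenerate inputs: fewer than two pairs and all-coincident source points
raise typed errors; target sets that collapse to a point leave the scale
unidentifiable and are also rejected.

## Lesion geometry and the junctional zone

Tracings are polygon components (outer ring plus optional hole rings for
spared islands) in FAF pixels, backed by shapely. Components with area
< 0.05 mm² are removed before any distance is computed — the filter is
inclusive at exactly 0.05 mm², and filtered-out components contribute no
margin (the filter defines what counts as lesion; applied before zone
construction, configurable). Signed distance magnitude is the Euclidean
distance to the nearest margin point over all retained components, outer
and hole rings alike; the sign is negative iff the point lies in the filled
region of any component under the even-odd rule, so points inside holes are
positive. Ties in nearest-component assignment break to the lowest index;
a point exactly on the margin has distance 0 and is in the zone. The
junctional zone is |d| ≤ 250 µm inclusive on both sides of the margin
(half-width and inclusivity configurable).

Binary PNG/array masks are converted to polygons via 0.5-level iso-contours
(scikit-image), with ring nesting resolved by containment depth: even depth
→ component outer ring, odd depth → hole of its immediate parent. The
polygon-path distances agree with a Euclidean distance transform of the
rasterized mask to within one pixel scale (verified in tests).

## Exam model

The 10-2 grid is the odd-integer lattice x, y ∈ {±1, …, ±9}° restricted to
eccentricity ≤ 9.2°, which yields the canonical 68 points (any cutoff in
(9.06°, 9.49°) gives the same set). Sensitivities live on the device's
0–36 dB scale; a stimulus not seen at maximal intensity is the `NOT_SEEN`
sentinel, exported as "<0". Scotomatous defaults to exactly `NOT_SEEN`
(absolute scotoma, the usual device convention); deep-scotoma thresholds
(e.g. < 10 dB) are available as alternative policies. For averaging,
`NOT_SEEN` contributes −1 dB by default (configurable to exclusion); the
substitution used is recorded in every endpoint report.

## Endpoints

Mean zone sensitivity averages over in-zone stimuli only (denominator =
number of in-zone points, not 68). An eye with no in-zone stimuli yields a
missing mean — never 0 — and is dropped pairwise from endpoint agreement
analyses with a reported count. Stimulus pairing across graders is always
by stimulus index (the same exam registered twice), never nearest-neighbor.

## Agreement statistics

- **Bland–Altman**: bias = mean(g1 − g2), LOA = bias ± 1.96·SD (sample SD,
  n−1), plus the percentage of pairs inside the LOA.
- **ICC**: two-way random effects, absolute agreement, single measure —
  ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + k/n·(MSC − MSE)) from the
  two-way ANOVA mean squares. The consistency form ICC(C,1) is exposed for
  comparison. Zero total variance raises an explicit undefined-ICC error,
  which report assembly converts to a null field.
- **Coefficient of repeatability**: two labeled estimators. Default
  `srd_sem` (smallest real difference) = 1.96·√2·SEM with
  SEM = SD_all·√(1 − ICC(A,1)), where SD_all is the sample SD of the pooled
  2n measurements; alternative `ba` = 1.96·SD of the paired differences.
  Both appear in every report because the two published definitions can
  differ materially and a single number would hide the choice.
- **Mixed-model LOA** for stimulus-level differences nested in eyes:
  d_ij = µ + b_i + e_ij with b_i ~ N(0, σ_b²), e_ij ~ N(0, σ_e²), fitted by
  REML (statsmodels MixedLM, default BFGS); LOA = µ̂ ± 1.96·√(σ̂_b² + σ̂_e²).
  A boundary fit (σ_b → 0) is legitimate and reproduces the naive
  Bland–Altman limits. With a single cluster the function falls back to
  Bland–Altman with a warning; constant differences short-circuit to the
  exact degenerate answer rather than invoking the optimizer.

## Synthetic study generator

The generator emulates the structure of a two-grader repeatability study of
30 eyes; every draw derives from `default_rng((seed, eye_index))`, so runs
are reproducible per eye and studies byte-identical per seed.

- **Lesions**: each focus is a radial-Fourier curve
  r(φ) = r₀(1 + Σ_{k=2..6} a_k cos(kφ + φ_k)), a_k ~ N(0, (irregularity/k)²),
  redrawn with damped amplitude if self-intersecting, then rescaled about
  its centroid so the total area is exact. Total areas follow a lognormal
  with geometric mean 8 mm² (a mid-sized GA lesion whose margin crosses the
  central 10°) and log-SD 0.4; eyes take one draw per equal-probability
  stratum of that distribution (strata shuffled), emulating systematically
  stratified case sampling by lesion size. 20% of lesions are bifocal
  (area split 65/35, foci disjoint by construction).
- **Sensitivity field**: S(d) = floor + (healthy − floor)·logistic(d/τ) + ε
  with healthy = 27 dB, floor = −10 dB, τ = 100 µm, ε ~ N(0, 1.5 dB);
  draws below 0 dB become NOT_SEEN, the rest clip at 36 dB. The negative
  floor makes deep-scotoma NOT_SEEN responses near-certain well inside the
  lesion. The real 4-2 staircase and fixation instability are not
  simulated; sensitivity noise is homoscedastic Gaussian.
- **Graders**: the true SLO→FAF transform is the nominal scale ratio of the
  two samplings (0.9) with ~2% calibration wobble, ~2° rotation SD, and a
  small translation. Four vessel-bifurcation-like fiducials per eye sit at
  mid-peripheral radii, angularly stratified. Each grader observes every
  fiducial with iid Gaussian jitter of SD 1.5 px per axis, independently in
  both frames — roughly careful manual clicking. Grader error is modeled at
  the fiducial level because that is the only manual step of the analysis;
  a direct stimulus-coordinate jitter mode (`coordinate_jitter_pair`) is
  provided for closed-form checks (mean coordinate difference = σ√π).

What passing tests on this generator do and do not show: they verify the
pipeline's geometry, statistics and plumbing against ground truth and
closed forms, and that grader-level jitter propagates to endpoint
disagreement with the expected monotone/linear behaviour. They do not
certify agreement magnitudes on clinical images, where the dominant error
is the similarity model's inability to capture true SLO–FAF deformation —
a systematic, spatially structured residual that iid fiducial jitter only
approximates.

## Numerical choices and problem sizes

Distances are computed vectorized over all 68 stimuli against all retained
components; the minimum-size filter runs before distance computation.
Default test and acceptance problem sizes — 30 eyes × 68 stimuli for the
end-to-end study, 50 × 68 for mixed-model recovery, 10⁴ draws for the
jitter closed form, 10⁵ boundary samples for the distance oracle — were
chosen as the smallest sizes at which the statistics are stable against
their Monte-Carlo error.

## Known limitations

- Only baseline (two-grader, single-visit) analysis is modeled; follow-up
  registration and lesion growth are out of scope.
- The similarity model cannot represent non-rigid SLO–FAF deformation; the
  fit RMSE is the only provided diagnostic.
- Tracing variability between graders is not simulated (both graders share
  one tracing, as in the grader-registration repeatability design).
- The 288 µm/° conversion ignores individual axial length; distances in µm
  inherit that approximation.
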