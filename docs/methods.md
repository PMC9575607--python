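# Methods

`tacsloop` is a desk-scale simulation of a closed-loop protocol that couples
dual-site transcranial alternating current stimulation (tACS) with real-time
fMRI: during a scan, a derivative-free optimizer searches the stimulation
frequency (1–150 Hz, integer) and the inter-site phase difference (integer
degrees) to maximize — or, in a control arm, minimize — the windowed
correlation between frontal and parietal ROI BOLD signals.  Every stage of
the loop (field model, schedule, BOLD generation, online scoring,
optimization, protocol orchestration) is implemented and testable without a
scanner.  This note records the models, the defaults and why, and what the
simulation does and does not establish about the real system.

## Electric-field model

Scalp electrodes are modelled as point current sources on the boundary of a
homogeneous conductive half-space (gray-matter conductivity σ = 0.275 S/m by
default).  A source injecting current *I* produces a radial field
E(r) = I / (2π σ r²); montage fields follow by vector superposition over the
ten electrodes (two 4×1 rings: one center at 1 mA peak and four returns at
0.25 mA each per site, zero net current per site).  The antiphase condition
flips the sign of the five parietal-site currents.

The *midpoint shunt field* quantifies the unwanted field between the two
sites.  It is evaluated as the field component along the inter-site axis at
a gray-matter point below the midpoint, using the three electrodes of each
site that lie on that axis: near return at d₁ = 3.5 cm, center at
d₂ = 6.5 cm (site separation 2d₂ = 13 cm), far return at d₃ = 9.5 cm, each
contributing I·d/(2π σ R³) with R = √(d² + depth²).  By mirror symmetry the
two sites cancel exactly in-phase and add in antiphase.  The default
evaluation depth is 1.5 cm, a typical scalp-to-cortex distance; with the
default geometry the antiphase value is 0.039 ≈ 0.04 V/m, well below the
0.1 V/m threshold usually quoted for measurable physiological effects.  The
off-axis returns are excluded from this closed form because the shunt
observable is the axial (site-to-site) component in the sagittal plane; the
full vector field of all ten electrodes is available via `montage_field`.

Focality is summarized as the volume of voxels whose field magnitude is at
least 75% of the peak, with the peak defined as the 99.9th percentile of
voxel values to suppress outliers.  The percentile uses the nearest-rank
convention (rank = ⌈q·n/100⌉) so the metric has exact integer semantics and
is invariant under uniform scaling of the field.  An all-zero grid returns
the total volume with a warning rather than an error.

## Session schedule

A run is 15 blocks of 20 s stimulation + 10 s rest (450 s), sampled at
TR = 2 s (225 volumes), tiled with continuous 4-s cognitive-task trials
(2.5 s stimulus/response + 1.5 s feedback; 112 complete trials per run —
the task keeps frontoparietal engagement, and hence the optimization target,
stable).  A block's connectivity window is the stimulation duration shifted
6 s for the hemodynamic delay: block at onset t is scored over
[t + 6 s, t + 26 s), i.e. 10 samples, extending 6 s into the rest period.
All indexing is 0-based and half-open.

## Synthetic BOLD generator

The generator stands in for the scanner.  A hidden response surface maps a
stimulation setting to a target inter-ROI correlation via a circular
Gaussian bump: r(f, φ) = r_base + (r_max − r_base)·exp(−(Δf/w_f)² −
(Δφ/w_φ)²), with phase distance wrapped on the circle.  Defaults: optimum at
(6 Hz, 0°) — the theta-band prior used to seed the optimizer — r_max = 0.8,
r_base = 0, widths 20 Hz and 60°, i.e. a broad, smooth, unimodal surface.
The surface encodes the protocol's working assumption (some setting couples
the regions more strongly); it is not a fitted physiological model.

Within a block's hemodynamically lagged window the two ROI signals are
drawn by shared-latent mixing — x = √|r|·s + √(1−|r|)·e₁,
y = sign(r)·√|r|·s + √(1−|r|)·e₂ with s, e₁, e₂ independent unit normals —
giving population correlation exactly r and unit variance.  The
hemodynamic delay is a pure 6-s onset lag of the coupling, matching the
6-s window shift; no HRF convolution is applied, because the loop's
observable is the window correlation and the lag is how the delay enters
that observable.  Outside lagged windows the coupling is r_base.

Additive nuisance structure, each scaled in units of the unit-variance
signal: slow random Legendre drift (orders 1–3, amplitude 1.0), linear
leakage of six rigid-body motion channels simulated as slow random walks
(amplitude 0.5), AR(1) white-matter and CSF traces (amplitude 0.5), cardiac
and respiratory sinusoids (amplitude 0.3), and white measurement noise with
sd `noise_sd` (default 1.0).  Note the white noise *attenuates* the
observable window correlation by 1/(1 + noise_sd²): at the surface optimum
the expected observed correlation is 0.4, not 0.8 — deliberate, since a
real-time pipeline never sees the noiseless coupling either.  Physiological
rates default to 1.17 Hz (≈70 bpm) and 0.31 Hz (≈19 breaths/min); they are
chosen so that the first two TR-aliased harmonics of each are distinct,
keeping the RETROICOR design columns linearly independent at TR = 2 s.

All randomness derives from a single seed; each block draws from a
counter-keyed substream, so changing one block's parameters (as the
optimizer does online) never perturbs another block's data, and streaming
block-by-block generation reproduces the batch simulation exactly.

What the generator does **not** emulate: volume-level imaging (slice
timing, motion correction, smoothing are out of the simulated pathway),
scanner artifacts, motion spikes or the z ≈ 2 outlier blocks seen in pilot
recordings, aftereffects of stimulation (the washout rest is a session-log
marker only), and between-subject variability.  Passing tests therefore
establish the correctness of the loop's logic and estimators under the
stated generative model, not performance on real scans.

## Online connectivity engine

Per block, mimicking the causal real-time pipeline: all samples acquired up
to the block's window end form an expanding nuisance design — Legendre
polynomials P₀..P₃ of time rescaled to [−1, 1] (high-pass), six motion
parameters, mean WM and CSF signals, and RETROICOR Fourier pairs
cos(kφ)/sin(kφ), k = 1..2, for cardiac and respiratory phase (20 columns
at the defaults).  The ROI signals are residualized by least squares over
that span, then the window samples are scored with a Pearson correlation
and Fisher's z = atanh(r), clipping |r| at 1 − 10⁻⁷ so degenerate windows
give a finite z.  Zero-variance windows yield an invalid outcome, which the
loop treats as a failed block.

Two numerical guards: rank-deficient designs have dependent columns dropped
(QR with pivoting) with a warning; and early in a run, when the design's
rank approaches the causal sample count, trailing columns (highest-order
RETROICOR terms first) are dropped so the residual space keeps at least
window-length + 2 dimensions — otherwise windowed residuals live in a
low-dimensional space and show spuriously perfect correlation.  Polynomial
order 3 and RETROICOR order 2 are conventional defaults.  Residualize-then-
correlate is the default order of operations; raw-correlation scoring is a
flag.

## Simplex optimizer

Nelder-Mead over the (frequency, phase) plane with both axes treated as
equal units.  The initial triangle is equilateral: center (6, 0),
circumradius 5, vertex angles 90°/210°/330°, giving exact vertices (6, 5),
(1.67, −2.5), (10.33, −2.5).  Because the stimulator takes integers, every
proposed point is rounded half-away-from-zero — mapping the seed triangle
to (6, 5), (2, −3), (10, −3) — with frequency clipped to [1, 150]; the
optimizer works on an unwrapped phase axis and wraps into [0, 359] only at
the device boundary.  (A second preset ships with seed vertices
(6, 5), (1, −3), (2, −3), a variant that appears in some written accounts
of the protocol but is not consistent with the equilateral construction;
it is never selected silently.)  One candidate is evaluated per block, so
the classic iteration is unrolled into an ask/tell state machine with the
standard coefficients α = 1 (reflect), γ = 2 (expand), ρ = 0.5 (contract),
σ = 0.5 (shrink); ranking ties break toward the earlier-evaluated vertex,
and proposals are deterministic functions of the state.

Each evaluated block receives a verdict: success iff its outcome strictly
improves on the *previous block's* outcome under the arm's mode (invalid
outcomes always fail).  The alternative — improvement on the best so far —
is available by configuration, but under realistic outcome noise it fails
almost every block once an early lucky extreme is recorded, which triggers
restarts every ~2 blocks; the previous-block rule yields the ~4 triangles
per 30-block training that pilot recordings of this protocol show.  After
two consecutive failures the triangle is abandoned and a new one is seeded
centered on the best parameters so far.  The new circumradius adapts: it
halves (floor 1) if the abandoned triangle improved the best outcome —
refine around the new best — and doubles (cap 40, twice the frequency
length scale of the default surface) if it never did, escalating the step
size because the current scale is evidently uninformative.  This adaptive
rule is this package's design: pure halving traps the minimize arm on the
coupling bump forever; pure doubling cannot refine on smooth noiseless
surfaces.  A degenerate (zero-area) triangle also triggers a restart.

## Closed-loop protocol and evaluation

One simulated participant: 30 training evaluations across two 15-block runs
(optimizer state carried over the run boundary), a ~7-minute washout rest
marker, then a 15-block test run at the selected parameters — the setting
with the extreme observed training z under the arm's mode.  The
experimental arm maximizes; the control arm minimizes and is tested at its
minimizing setting (the "min-optimization" control, which preserves the
experience of being optimized).  Arm comparison uses the pooled-variance
two-sample t on the arms' test-run z values (df = n₁ + n₂ − 2); on the
pilot's printed summaries (0.70 ± 0.29 vs 0.42 ± 0.33, n = 15 each) the
formula gives t(28) = 2.47 — slightly above the published 2.38, which was
presumably computed from unrounded block values; the formula result is
reported as-is.  Training separation is reported as best z(experimental) −
best z(control).

### Known limitation: selection under noise

With the default generator (noise_sd = 1), the observed z at the surface
optimum is ≈ 0.42 while a single 10-sample window estimate has sd
1/√7 ≈ 0.38.  Selecting the single best observed block — the protocol's
rule — therefore frequently picks a noise-extreme block at weakly-coupled
parameters.  Paired experimental-vs-control protocols separate in about
60–70% of seeds under these conditions, although the search itself visits
the right regions (re-selecting by true coupling over the same visited
points separates in ~95%).  With a noise-free generator the same pipeline
separates in ~80–90% of pairs.  Averaging several blocks at the candidate
setting, or lengthening the window, would make selection consistent, but
both change the protocol and are left out of scope.

## Problem sizes in tests

The test suite uses the protocol's native sizes (15-block runs, 30-block
training) throughout; Monte-Carlo checks use 20–200 seeds and the paired
arm-comparison suite runs 50 full two-arm protocols, all within a few
seconds on one CPU.
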