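# Methods

This note records the models implemented in `zamech`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Signaling network (`zamech.network`)

**Model.** Junction-localized amounts of RhoA, ROCK1, NMIIA, Rnd3 and
p190B are dimensionless state variables; localization at the junctional
cortex is equated with activity. Each node obeys

    dX_i/dt = b_i + Σ_stim w·h(X_j) − X_i·(γ_i + Σ_rep w·h(X_j)),
    h(x) = xⁿ/(Kⁿ + xⁿ),

so stimulation saturates and repression accelerates first-order
removal. SRGAP1 is exogenous: it is never produced by the network but is
imposed as a function of time (constant until `t_start = 200`, then
linear with slope `0.0075` per time unit). This reflects its role as an
orthogonal antagonist whose junctional level is set by upstream
(cortactin-phosphorylation) signaling, not by the RhoA module itself.

**Default parameters.** The pinned set in `build_default_model()` is

| edge | w | K | n |
|---|---|---|---|
| RhoA → ROCK1 | 1.0 | 0.5 | 4 |
| ROCK1 → NMIIA | 1.0 | 0.7 | 4 |
| NMIIA → ROCK1 | 1.0 | 0.7 | 4 |
| ROCK1 ⊣ Rnd3 | 9.0 | 0.7 | 4 |
| Rnd3 → p190B | 2.0 | 0.5 | 4 |
| p190B ⊣ RhoA | 5.0 | 0.5 | 4 |
| SRGAP1 ⊣ RhoA | 3.0 | 1.5 | 2 |

with basal production 1.0 (RhoA, Rnd3), 0.02 (ROCK1, NMIIA), 0.05
(p190B) and unit removal everywhere. The steep (n = 4) feedback edges
make both the myosin–ROCK positive loop and the double-negative
Rnd3/p190B loop switch-like, which is what produces bistability; the
gentler SRGAP1 edge (n = 2, K = 1.5) makes the active branch respond
gradually to small SRGAP1 before the collapse, giving the two-regime
ramp response. The set was designed once against the qualitative
invariants (exactly two stable states at SRGAP1 = 0; all-ones initial
condition in the active basin; monotone RhoA decline then switch under
the default ramp) and is config-overridable (JSON/YAML via
`save_model`/`load_model`); quantitative outputs (state levels, switch
level ≈ 0.86) are properties of this default set, not measurements.

**Numerics.** LSODA with `rtol = 1e-8`, `atol = 1e-10`; integration is
split at the ramp kink so the solver never steps across the non-smooth
point. Equilibration iterates 500-time-unit chunks until
`‖dX/dt‖ < 1e-9` (cap `t = 1e5`). `bistability_scan` starts from the
2⁵ low/high corners of the state box (0.05/2.0 per node), clusters
endpoints within `1e-4`, then verifies each candidate with
`‖RHS‖ < 1e-8` and negative real parts of the finite-difference
Jacobian eigenvalues. Regime classification uses the midpoint threshold
(`switch_fraction = 0.5`) between branch reference levels; a trajectory
that is below threshold at zero forcing reports no SRGAP1 switch level.
Hysteresis: with the default set the inactive state is stable at
SRGAP1 = 0, so the down-sweep never returns to the active branch — the
switch-up level is 0 while the switch-down level is ≈ 0.84.

## Recoil fitting (`zamech.recoil`)

Kelvin-Voigt form `L(t) = L0 + A(1 − e^(−kt))`, fitted by bounded
nonlinear least squares (`A ≥ 0`, `k > 0`) with the initial guess from
the log-linearized residual. `L0` is fixed from the pre-ablation frame
rather than fitted: on 5-point curves a free offset is strongly
correlated with `A`. Time origin: ablation happens inside the 12 s gap
after the pre-ablation frame, so post-ablation frames default to
t = 12, 20, 28, 36, 44 s; the exact sub-interval instant of ablation is
unknowable from the data, and `v0 = A·k` is insensitive to it because
it is defined by the fit, not by the first observed displacement. A
flat curve returns `A = 0, v0 = 0` with `k` flagged unidentifiable.
Condition summaries fit the mean curve per condition (per-junction fits
are also exposed); `v0` values are normalized to the same-experiment
control mean before cross-experiment statistics.

## FRAP fitting (`zamech.frap`)

Normalization uses the mean of the pre-bleach frames as `F(i)` and the
first post-bleach frame as `F(0)`; the normalized curve is exactly 0 at
the bleach frame. The fitted model is the one-phase association
`Mf(1 − e^(−ln2·t/t½))` with the origin pinned at 0 — note the decaying
exponent: a positive exponent (as sometimes typeset) cannot produce the
plateau that defines `Mf`. No acquisition-photofading or reference-ROI
correction is applied by default since none is part of the emulated
protocol. Bleach-depth QC passes at ≥ 70%; the generator's default
depth is 75%. Fits are flagged, never silently replaced, on
non-convergence; `Mf > 1.05` is flagged as over-recovery.

## Junction quantification (`zamech.junction`)

Line scans sample the image by bilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1) at 1 px steps along the
perpendicular through the ROI midpoint, averaging 30 parallel lines
spaced 1 px along the junction. Single-peak markers are quantified as
the amplitude of a fitted Gaussian *with a constant baseline term*; the
reported value is amplitude over baseline, and the windowed background
estimate (mean of the two 5-px windows starting 10 px beyond the
peak/centers, one on each side) is reported alongside rather than
subtracted a second time. Band AUC sums background-subtracted
intensities over ±10 px around the band center(s); two-band centers are
the two highest-prominence maxima within 3 µm of the scan center, with
a single-center fallback. The GFP-AHPH readout is the mean intensity of
a 20 px wide band around the junction polyline (rasterized, distance
transform) divided by the mean of the supplied cytoplasm mask; the mask
must be disjoint from the band. Batch summaries refuse fewer than 25
junctions for immunofluorescence readouts or 60 for the biosensor
unless forced. Apical orientation of stacks comes from explicit
metadata (`apical_first`), never from image content.

## Motility (`zamech.motility`)

MSD is time-averaged within each track over all overlapping pairs at
each frame lag, then ensemble-averaged weighted by pair counts; lags
are capped at 25% of the longest track. The fitted model is a power law
`Γ·τ^α` by least squares on log-log axes — the projection to the 6 h
horizon and the condition/control ratio are taken from this fit; a
purely diffusive `4Dτ` alternative is available (`model="linear"`).
Margin displacement interpolates both margin polylines onto a common
transverse grid and averages the signed advance along the wound axis;
retreat is negative, and non-overlapping transverse ranges are treated
as a wound-axis mismatch error.

## Synthetic data (`zamech.synthetic`)

Noise models: additive Gaussian for distance and intensity traces
(tracking/readout error), Poisson followed by Gaussian read noise for
images (photon + camera noise). Defaults sit in each fitter's
identifiable regime and mirror the acquisition designs: recoil
`L0 = 10 µm, A = 1.2 µm, k = 0.05 s⁻¹, σ = 0.05 µm` on the 5-point
schedule, 12 junctions per condition; FRAP `Mf = 0.7, t½ = 20 s`, 75%
bleach, σ = 0.03 on the normalized scale, 3 + 57 frames at 5 s; images
with band σ = 0.3 µm at 0.1 µm/px on an odd-sized canvas so the
junction center lies on a pixel (noiseless round-trips are then exact
rather than interpolation-limited); tracks `D = 0.5 µm²/min`, 35 nuclei,
6 h at 5 min intervals, optional drift and Ornstein-Uhlenbeck velocity
persistence. Generators are deterministic in their spec (seed included)
and emit ground-truth tables consumed by the tests.

**What the generators do not emulate** — and hence what passing tests
do not show about real data: optical blur (no PSF convolution),
illumination-field inhomogeneity, junction curvature and neighboring
junctions in the scan window, cell-to-cell variability beyond the
per-experiment multiplicative offsets used in normalization tests,
photofading during FRAP acquisition, track loss/merging from imperfect
nuclear segmentation, and margin topology changes (fingering, islands)
in wound healing. Estimator accuracy on real images will be bounded by
these effects, not by the numerics validated here.

## Problem sizes

The test suite and `scripts/acceptance.py` use 200 Monte-Carlo
replicates for the recoil and FRAP recovery studies, 8 replicates per
condition for image measures, and 1000 tracks for MSD calibration —
sizes at which the Monte-Carlo error of each reported median/bias is
comfortably below the tolerances being checked.
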