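# Methods

## Decay-correction model

All times are seconds from scan start, which coincides with the start of
the 20-s infusion; the decay-correction reference defaults to t = 0 and
can be moved for nonzero injection-to-scan offsets. For a frame [t₁, t₂]
of duration Δt the scanner-style correction factor is

f = λΔt · e^(λ(t₁ − t_ref)) / (1 − e^(−λΔt)),

defined so that the frame average of a purely physically decaying source
is mapped to its value at the reference time. Removing the correction
("uncorrecting") divides a frame value by e^(λ·midpoint), i.e. the
within-frame correction is retained — this matches the state the voxel
branch integrates. Both operations are exact involutions. The scanner's
actual convention (frame-start vs scan-start reference) is not public;
scan-start is the default and `reference_time_s` is the dialect knob.

## Biexponential model and TIA

The decay-corrected organ curve is modelled as
c(t) = a₁e^(−μ₁t) + a₂e^(−μ₂t), μᵢ ≥ 0, amplitudes unconstrained in sign.
A forced washout form a(e^(−μ₁t) − e^(−μ₂t)) was rejected because the
measured curves plateau rather than return to zero; the forced form is
the special case a₂ = −a₁. The normalized TIA restores physical decay
analytically inside the integral,

Ã = (V/A_inj)·[a₁/(λ+μ₁) + a₂/(λ+μ₂)] (kBq→MBq, s→h),

so no numerical decay multiplication or numerical integration is
involved; the closed form is verified against adaptive quadrature to
1e−6 relative over randomized parameter sets. Beyond the last frame
(420 s > 5.5 half-lives) the extrapolation is the fitted model times
physical decay and contributes under ~3% of Ã, so fit instability there
is tolerable.

### Fitting procedure

Deterministic multi-start (no RNG): rate pairs from a fixed grid of
eight μ values are ranked by the residual of the amplitude-only linear
solve and the ten best are refined with bounded least squares
(μᵢ ≥ 0, tolerances 1e−14). A refined solution whose curve dips below
−1e−6 of the data scale anywhere on [0, 2 × last midpoint] is re-refined
with a non-negativity penalty and rejected if it still dips; ties are
broken by lower residual, then lower μ₂. If all starts fail the organ
falls back to the trapezoid+tail estimator and is flagged
(`method="trapezoid_fallback"`) in the output provenance. Least squares
is unweighted by default (the reference analysis states no weighting);
1/duration weights are available as a flag.

**Forward model.** Reconstructed frame values are time *averages* over
the frame, not point samples. For the fast early kinetics here, treating
them as midpoint samples biases the fitted TIA by 1–3%, so `tia_table`
fits the model's decay-corrected *frame average* (closed form) to each
frame value, which makes noiseless recovery exact to rounding.
`fit_biexp` on bare (time, value) pairs — the conventional reading —
remains available and is what the point-sample tests exercise. Fitted
parameters always describe the continuous curve, so the TIA closed form
is unchanged.

### Physical bounds

Every organ TIA must satisfy Ã ≤ 1/λ (in hours, 0.030457 for T½ = 76 s)
and the sum over all rows including the remainder must as well: with no
excretion pathway at this half-life, all injected activity decays in the
body. Violations raise with the offending organs named; they indicate
inconsistent units or calibration, not fixable noise.

## Voxel branch

Frames are uncorrected to physical activity at the frame midpoints and
each voxel is integrated as: rectangle from t = 0 to the first midpoint
at the first value, trapezoid across the midpoints, and a
mono-exponential tail A₇/k with k = ln(A₆/A₇)/(t₇ − t₆) from the last
two points. The tail rate is clamped to at least λ and falls back to λ
for rising, flat or empty voxels (a physically decaying source cannot
outlive physical decay); the fallback fraction over active voxels is a
QC output. The rectangle left edge was chosen over a triangle ramp after
checking both on frame-averaged inputs: the first frame's value already
averages over the activity rise, so the rectangle closely matches the
missing early integral (±1.3% per organ on noiseless data), whereas the
triangle underestimates voxels that are active from t = 0 (the blood
background) by ~6%. The triangle remains available via `left_edge`.

Dose maps use local energy deposition by default — appropriate for the
β-dominated self-dose of ⁸²Rb: D = Ã·3.6×10⁹·E·1.602×10⁻¹³/m_voxel, with
E the mean locally deposited energy per decay from the nuclide config.
Kernel mode convolves the energy-release map with a user-supplied
deposited-energy-fraction kernel (FFT, zero-padded); only a
programmatically generated Gaussian toy kernel ships, because no
clinically validated kernel can be bundled without implying false
provenance. A delta kernel reproduces local mode exactly and a
normalized kernel conserves total energy away from the grid boundary.

## S-values, effective dose

The MIRD sum runs over all TIA sources after organ-name normalization
and aliasing ("Heart content" → `heart_contents`, content sources map to
S-rows targeting the wall, the remainder row maps to the table's
`total_body` source — no Olinda-style remainder rescaling is applied
because the remainder here is already organ-subtracted). A missing
remainder source row is a configuration error, never a silent drop.
Reference-phantom S-values are proprietary and not bundled; the package
provides the CSV schema `phantom,source,target,s_mGy_per_MBq_h`, a toy
table for exact tests, and a *synthetic* generator that assigns
(1 − c) of each organ's decay energy locally and spreads the fraction c
(default 2%) uniformly over the body — self-consistent with the voxel
branch's local mode, which is why the two branches agree on the
synthetic study, and explicitly not a clinical surrogate.

Effective dose uses the ICRP-103 tissue weights (bundled CSV; validated
to sum to exactly 1). Weighted tissues absent from a report contribute 0
with a warning (sex-specific organs); colon and gonads average their
available sub-organs; the 13-tissue remainder is averaged over the
tissues present. Effective dose is computed per phantom with no
male/female averaging. The recipe behind the published per-subject
effective doses is not fully specified (remainder composition,
sex-averaging), so those absolute values are carried as fixtures, not
recomputed.

## Synthetic study

The generator produces what the pipeline consumes — a label map and
seven decay-corrected frames — not sinograms: attenuation, scatter,
randoms and reconstruction are out of scope. Geometry is schematic
(axis-aligned ellipsoids/boxes inside a body ellipsoid on a 48×48×72
grid of 4-mm voxels, a deliberately reduced-scale body of ≈5 L), because
the dosimetry math sees only voxel memberships and volumes; the heart
wall is a shell around the ventricular blood pool to exercise adjacent
segmentations. The legend carries the study's eleven source organs.

Ground-truth kinetics are uptake biexponentials c(t) = a(1 − e^(−μ₂t))
(rates 0.01–0.05 s⁻¹, so curves rise within the first minute and
stabilize after about two — the shape seen in the measured TACs), with
plateau activity fractions loosely mirroring the relative source
strengths of the measured TIA (lungs and the unsegmented body dominate).
The remainder is a washout biexponential holding the injected bolus at
t = 0, so whole-body physical activity is non-increasing and the summed
TIA approaches the physical bound from below (~0.95·1/λ here vs ~0.99 in
the measured data). Per-seed lognormal jitter (8% amplitudes, 10% rates)
individualizes examinations; total activity is rescaled if jitter pushes
it above 98% of the injection. Stress examinations scale heart and liver
up and kidneys, spleen and lungs down, the directions seen in the
measured rest/stress TIA.

Noise is per-voxel Poisson on decay-corrected values scaled by frame
duration — a simplification of tomographic noise that is adequate for
estimator testing but does not reproduce spatial correlation, PVE blur
(none is applied by default; a Gaussian switch exists in kernel form) or
scanner saturation. "5% frame noise" is calibrated as the *mean* CV of
the organ-mean value across the seven frames (`noise_scale_for_cv`);
calibrating at the quietest frame alone would make the early frames far
noisier than 5%. Consequently, passing tests show that the estimators
are unbiased and within tolerance under idealized noise; they do not
certify performance on reconstructed clinical images.

## Problem sizes and determinism

The bundled study uses the 48×48×72 phantom per examination; recovery
statistics use 200 seeded single-organ replicates on a 24³ grid
(~640-voxel organ), chosen as the smallest configuration in which the
organ-level noise calibration is meaningful. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); fitting
itself uses no RNG, and reruns of the pipeline are byte-identical.

## Known limitations

* The synthetic S-table and the reduced-scale phantom make the absolute
  synthetic doses (≈2 μSv/MBq effective) incomparable to the published
  per-subject values (0.50–0.76 μSv/MBq); those enter only as fixtures.
* Frame-start vs scan-start decay-correction dialects, and the voxel
  product's sub-frame time assignment, are conventions the reference
  software does not document; ours are flagged in output metadata.
* The injected-activity range quoted in the study's abstract
  (407.0–419.61 MBq) is inconsistent with its subject table
  (398.43–409.19 MBq); the fixtures carry the subject-table values.
* Compartmental kinetic modelling, partial-volume correction, cardiac
  gating and automatic segmentation are out of scope.
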