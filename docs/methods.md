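# Methods

This note documents the models implemented in `perisim`, the defaults and
why they were chosen, the numerical decisions, and what the simulations do
and do not establish about real perimetry.

## Test grid

The 30-2 pattern is generated, not tabulated: all lattice points with
|x|, |y| ∈ {3, 9, 15, 21, 27}° whose eccentricity √(x²+y²) is at most
28.5°. The rule has slack — the farthest retained point is at 28.46°
(±9, ±27) and the nearest excluded one at 29.70° (±21, ±21) — so any
cut-off between those values yields the same canonical 76-point pattern
(rows of 4/6/8/10/10 per hemifield). Canonical order is row-major, top row
first. Laterality matters only for labels: temporal is +x for a right eye
(OD) and −x for a left (OS), putting the OD blind spot beside (+15°, ±3°).

## Bowl geometry and gaze contingency

Field angles (x, y) are tangent-plane direction angles: the stimulus
direction is `normalize(tan x, tan y, 1)`, scaled to the bowl radius
(330 mm). Gaze-contingent placement applies the minimal 3-D rotation
carrying the straight-ahead axis onto the gaze direction to the target
direction (Rodrigues' formula), rather than adding angles component-wise —
additive composition does not preserve angular separations off the
meridians. Two eccentricity notions coexist under this convention: the
*chart* eccentricity √(x²+y²) used for grid inclusion and region labels,
and the *angular* eccentricity atan(√(tan²x + tan²y)) of the 3-D
direction; they differ by ≲ 0.04° inside the 30° field. The rotation
preserves the angular eccentricity exactly (verified to 10⁻⁹ degrees),
which is the retinally relevant invariant. A combined direction leaving
the forward hemisphere raises an out-of-display error; the exam engine
logs it and retries with a fresh gaze sample.

The Goldmann size III figure of 0.43° is the angular diameter of a 4 mm²
disc at the historical 300 mm Goldmann bowl, 2·atan(√(4/π)/300). On the
330 mm virtual bowl the same 4 mm² would subtend ≈ 0.39°; the two printed
specifications are inconsistent at that radius, and the angular size is
taken as normative because it is what the retina sees. The physical extent
on any bowl follows as 2·r·tan(θ/2) (≈ 2.48 mm at 330 mm).

## Photometry

0 dB is fixed at 10,000 asb (the Humphrey convention), which reproduces
the four printed luminance/dB pairs to their printed rounding: 14 dB ↔
395 asb ↔ 125.73 cd/m² and 40 dB ↔ 1 asb ↔ 0.318 cd/m². Conversions use
exact π (1 asb = 1/π cd/m²); note a 10 cd/m² background is 31.42 asb under
exact π, while 31.5 is sometimes quoted from a rounded constant. The exact
device floor implied by the 125.73 cd/m² ceiling is 14.03 dB; the
staircase deliberately uses the nominal integer interval [14, 40] and
`clamp_to_device` governs physical displayability separately.

## Staircase

Pure bisection: *seen* at attenuation a implies sensitivity ≥ a, so the
lower bound rises to a; *not seen* lowers the upper bound. This is the
only bound orientation consistent with dB-as-attenuation. A seed (the
central threshold) sets the first presented intensity only — the search
interval stays [14, 40] — because seeding was specified as a starting
*brightness*, not a starting interval. From the full range an unseeded
staircase halves the width each step (26 → 0.8125 dB in exactly five
presentations), bounding the deterministic-observer error by half the
terminal width, 0.40625 dB. Thresholds that never move a bound off 14 or
40 are reported clamped with `floored`/`ceilinged` flags, since
sensitivities below the device floor are undetectable.

## Exam orchestration

The fixation point (0, 0) — not one of the 76 grid points — is thresholded
first, unseeded, and reported separately; its value seeds the grid
staircases (all of them by default; an optional `neighbour` mode seeds
each point from completed 6°-lattice neighbours as an extension). Grid
order is a seeded permutation. Staircases are completed one location at a
time; interleaving across locations is left as future work. Simulated time
charges each presentation the stimulus duration (200 ms) + response window
(1 s) + inter-stimulus interval (500 ms, a chosen default) = 1.7 s;
early-response truncation is not modelled, so simulated durations slightly
overestimate an eager patient.

## Simulated observers

Truth is a hill of vision s(e) = s₀ − k·e with conventional normative
defaults s₀ = 33 dB, k = 0.3 dB/°, plus 1 dB point-to-point variation,
clipped to [0, 50] dB (truth may exceed the testable range). Scotomas
subtract a depth over a named point set; the `rim_artifact` kind darkens
the ≥ 21° periphery of one side, emulating eyeglass frames displaced by a
headset.

Responses follow p = fp + (1 − fp − fn)·Φ((t_eff − presented)/σ), i.e.
false positives as a floor and false negatives as a ceiling inside one
psychometric equation rather than separate catch trials — appropriate for
an engine that presents no catch trials. σ = 1 dB and fp = fn = 3% are
typical clinical magnitudes. Gaze wander is a discretised
Ornstein–Uhlenbeck (AR(1)) process with stationary per-axis SD `gaze_sd`
(default 1°, bracketing the tracker's stated 0.5°–1.1° accuracy) and a
0.2 s correlation time; the update g ← ρg + N(0, sd²(1−ρ²)), ρ = e^(−dt/τ),
makes the stationary SD independent of the stepping rate.

With tracking off, a stimulus at field position ℓ lands at retinal
position ℓ − g. Truth off the lattice is evaluated by bilinear
interpolation on the uniform 6° lattice (the 24 corners outside the
pattern are filled from the nearest tested point), applied as a
*difference* — t_eff = truth(ℓ) + [interp(ℓ−g) − interp(ℓ)] — so a zero
gaze error reproduces the stored truth exactly and no interpolation bias
enters the tracking-on path.

## Paired cohorts and expected agreement

The cohort generator draws, per eye, a truth field with apex ~
N(33, 2²) dB, then two measurements: truth + shared per-point distortion
(SD 1 dB) + per-device independent error. The independent error is a
per-eye session offset (SD = indep_sd/2) plus per-point noise (SD =
indep_sd); the offset term represents day-to-day and device-calibration
variability and keeps the per-point noise at realistic test–retest
magnitudes. The expected Pearson correlation of the two devices' global
means is then

    r = c / √((c + v_a)(c + v_b)),  c = σ_apex² + (σ_truth² + σ_shared²)/m,
    v_d = indep_d²·(1/4 + 1/m),

with m the number of points in the global mean (74 after blind-spot
exclusion). `nominal_global_r` evaluates this and
`indep_sd_for_target_r` inverts it; the defaults give r ≈ 0.80, and
setting both independent SDs to zero gives r = 1 exactly. Reliability
indices are uniform over configurable ranges whose defaults fail roughly a
fifth of eyes at the FL > 20% / FP > 15% / FN > 30% screen; MD/PSD/VFI are
passthrough metadata drawn from plausible clinical distributions, never
computed from the fields. Left eyes are mirrored into right-eye format
(x → −x) before pooling, the standard convention.

## Comparison statistics

Regional means exclude the two blind-spot points by default (configurable;
the convention in clinical analysis). Quadrant means recombine exactly to
hemifield and global means under a fixed exclusion policy. Correlation
strength classes are strong r ≥ 0.7, moderate 0.4 ≤ r < 0.7, weak r < 0.4;
zero-variance series are flagged undefined, never coerced to a number, and
the paired *t*-test likewise flags zero-variance differences. No
multiple-comparison adjustment is applied across regions or points. The
default GHT sector map is a mirror-symmetric five-pair clustering
(paracentral, nasal, temporal, nasal arcuate, temporal arcuate per
hemifield) of the points inside the 30-2 edge ring, with the edge ring and
blind-spot points unassigned; published GHT cluster boundaries vary across
reproductions, so the map is overridable from a sector-map CSV.

## Numerical and I/O choices

Interior grayscale levels use round-half-up on 1 + 253·(dB − 14)/26, with
14 → 0 and 40 → 255 exact; interpolated rendering snaps values to 10⁻⁹ dB
before mapping so float noise cannot pull an exact endpoint onto the
interior ramp. The tiles renderer is integer-only and its ASCII PGM output
is byte-identical across platforms; PNG is provided for convenience. All
CSV dialects are comma-separated with dot decimals and a mandatory header;
floats are written with `repr` for lossless round-trips. Result documents
are validated structurally on read (76 unique points, log length,
config echo) with descriptive errors naming missing or duplicated
coordinates and line numbers.

## Problem sizes used in the shipped checks

The shipped test suite and acceptance script run entirely from generated
data: single exams (77 staircases, ≈ 460 presentations), 20-replicate
recovery and tracking-contrast experiments, and cohorts of 65–80 eyes with
up to 50 generator seeds — sizes chosen so the full battery completes in
well under a minute while leaving Monte-Carlo margins (e.g. the mean
recovered global r over 50 seeds has standard error ≈ 0.013) comfortably
inside the asserted tolerances.

## Known limitations

* The observer model has no response-time, learning, fatigue, blink or
  headset-slippage dynamics; gaze wander is stationary and Gaussian.
* Truth between grid points is a bilinear surrogate; real scotoma borders
  are steeper than a 6° lattice can represent, so tracking-off errors near
  edges are, if anything, underestimated.
* MD, PSD and VFI require normative databases and are carried as metadata
  only; GHT pass/borderline/fail judgements and Bland–Altman limits of
  agreement are not implemented.
* The cohort generator models measurement agreement, not a clinical case
  mix: it does not reproduce any particular patient population's lesion
  prevalence, and passing its recovery checks shows the statistics
  pipeline is correct, not that any two real devices agree.
* Staircases are not interleaved across locations, and catch trials are
  not presented, so the FL/FP/FN indices attached to synthetic cohort
  records are simulated metadata rather than quantities measured from the
  simulated exams.
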