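# Methods

## Signal model

The instrument records an interferogram stream at frame rate `f_s`
(default 67 kHz, wavelength 852 nm). Moving blood broadens the Doppler
spectrum of the local time series; the analysis quantifies that
broadening through the normalized second-order moment of the in-band
power spectral density,

    M2 = Σ_band f² S(f) / Σ_band S(f)        [Hz²],

computed per pixel in 512-frame short-time windows over the 6–33 kHz
band. The moment is the *raw* (non-centered) second moment: the band
excludes DC, and the arterial–background subtraction cancels common
offsets, so centering would only add an estimation step. Windows are
non-overlapping by default (hop = window); the window is rectangular by
default with Hann available — both conventions are exposed in
`stft_moments`.

The differential broadening between an arterial region and its
background annulus is

    Δf = sign(M2_a − M2_b) · sqrt(|M2_a − M2_b|)      [Hz],

with the sign correcting windows where the neighborhood overestimates
the arterial baseline. RMS velocity follows the linear forward-scattering
model

    v = α λ Δf / NA,

with calibration α = 5, λ = 852 nm and eye numerical aperture
NA = 0.25. α rescales all flows linearly and cancels exactly in RI, PI,
heart rate and diameter; the test suite checks this invariance to 1e-9.
Negative Δf inside arteries is clipped to zero velocity: the sign marks
background mis-estimation, and flow cannot be negative in this model.

## Reconstruction

`angular_spectrum_propagate` applies the standard transfer function
`exp(i2πz√(1/λ² − f_x² − f_y²))` with evanescent components suppressed.
`svd_clutter_filter` subtracts the projection of the Casorati
(pixels × time) matrix onto its `n_remove` leading singular components;
static clutter is temporally rank-1 and is removed exactly by the first
component. The filter is applied globally per acquisition (the number of
removed components and per-window filtering are configuration choices;
nothing in the underlying physics pins them down, so both are exposed).
Note that re-running the truncation removes the residual's next-leading
component — the meaningful idempotence statement, which the tests
assert, is that the output is exactly orthogonal to the removed
subspace.

## Segmentation

Stage 1 builds the arterial map from the moment video alone:

1. time-mean broadening image `sqrt(max(M2̄ − median(M2̄), 0))`;
2. multiscale Frangi vesselness (scales 1–4 px, bright tubes), Otsu
   binarized, giving tubular *seeds*;
3. per-pixel Pearson correlation of the M2 time series with a reference
   arterial pulse (estimated from the top-decile vesselness pixels when
   not supplied), thresholded by Otsu with a floor of 0.25 — far above
   the null |r| for hundreds of windows — because Otsu can split the
   noise mode when arteries occupy few pixels;
4. the final mask is the union of pulse-gated connected components that
   contain a vesselness seed. The Frangi ridge alone is narrower than
   the lumen while the pulse gate covers every pixel carrying pulsatile
   flow, so this geodesic growth recovers the full vessel width; veins
   and static structures fail the gate.

Choroidal-vessel removal is out of scope; an `exclusion_mask` input
stands in for the operator's manual adjustment. The background annulus
spans dilations of the artery mask between 3 and 9 px, minus every
detected vessel pixel, so the tissue baseline is never contaminated.

Branches are connected components outside the optic-disc disk, with
centerlines from skeletonization (BFS main path, ends trimmed — skeleton
end caps are unreliable). Cross-sections sit at fixed arc-length
intervals; their direction comes from the dominant eigenvector of the
local structure tensor of the broadening image (gradients across a tube
point along its normal), falling back to centerline PCA where the
orientation is isotropic. Sections that touch another branch or leave
the field are dropped; a branch shorter than one interval receives a
single mid-branch section.

## Diameters and volume rates

Across a section, Poiseuille flow gives a parabolic velocity profile
`v(x) = v_max(1 − ((x−x₀)/R)²)⁺`, hence an m2 excess
`M2 − bg = (v/coef)²` that is the *square* of that parabola. The
diameter fit runs directly on the cycle-averaged m2-difference profile
with the squared-parabola model: moment noise is zero-mean there,
whereas the square root of a noisy difference carries a positive
pedestal that inflates apparent width at low SNR. For noiseless input
the two parameterizations coincide. Profiles are normalized by their
peak before fitting so the geometry is exactly scale-equivariant. The
velocity-domain fit (`fit_poiseuille`) excludes samples below 12% of the
peak: the image-sampled profile is smeared by about a pixel at the lumen
wall, so the radius is extrapolated from interior curvature rather than
read off the smeared wall. Fits with relative residual above 0.35, flat
or monotone profiles are rejected and their sections excluded.

Per window, the centerline amplitude `v_max(t)` comes from linear
projection of the background-subtracted m2 profile onto the squared
template (interior samples only). The section-mean velocity over a
circular lumen is `v_max/2` (area average of a paraboloid), so

    Q_section(t) = (v_max(t)/2) · π (d/2)²,

converted to µL/min. Branch flow averages its accepted sections; total
flow sums branches. A branch's reported caliber is the mean over its
accepted section fits, time-averaged over an integer number of cycles
(diameter pulsatility in large retinal arteries is ~±2% and is
neglected; a ±2% caliber error moves flow by under ±4%).

Pixel pitch is calibrated from the optic disc: `pixel = disc_mm /
disc_px`, with 1.79 mm as the default anatomical horizontal disc
diameter. The synthetic scenes use a smaller disc (288 µm) because a
desk-scale 64×64 field cannot hold a disc ~18 vessel calibers wide at a
pitch that keeps vessels ≥ 6 px; the calibration formula itself is
unchanged.

## Waveform analysis

The total volume-rate waveform is sampled at the window rate
(`f_s`/hop ≈ 131 Hz). Cycle detection seeds a peak search with the
dominant periodogram frequency (minimum separation 60% of the period, a
height gate at half the pulse amplitude — so the dicrotic notch is never
counted as a systole), then refines the heart rate from median
peak-to-peak intervals with parabolic sub-sample interpolation.
Diastole and the maximum-derivative point are located between
consecutive systoles only; a minimum at the array boundary is not a true
end-diastole. Waveforms are cropped to the span between first and last
systole (an integer cycle count) and low-pass filtered with a zero-phase
4th-order Butterworth at 10× the heart rate — low enough to suppress
window noise, high enough to preserve the systolic peak and dicrotic
notch; the multiple is configurable since nothing fixes it physically.

Biomarkers: QS and QD are means over cycles of the per-cycle systolic
maximum and diastolic minimum (per-cycle averaging is more robust than
the global extremum, which a single noisy window could set); QM is the
time mean; V_AS integrates the volume-rate upstroke from the
maximum-derivative point to the systolic peak (trapezoidal, per cycle,
then averaged), in nL; RI and PI use the Pourcelot and Gosling
definitions on both the velocity and the volume-rate waveform.

## Synthetic scenes

The generator encodes exactly the structure the analysis assumes:

- **Geometry** — straight-to-polyline branches of constant caliber
  (default 96–120 µm) radiating from the disc rim on a 64×64, 12 µm/px
  grid; overlapping branches are rejected. Parabolic cross profiles;
  section-mean = half the centerline peak.
- **Cardiac waveform** — a systolic Gaussian bump plus a smaller
  post-systolic bump (dicrotic notch), periodized and affinely
  normalized so that (max−min)/max equals the requested RI exactly (to
  1e-6 against a dense one-period grid; coarsely sampled series can miss
  the continuous extremum by the sampling curvature error). Default
  75 bpm, RI 0.8, notch depth 0.25.
- **Moments** — inside vessels `M2 = bg + (NA·v/(αλ))²`, the exact
  inversion of the velocity model; outside, the tissue background
  (default 5·10⁷ Hz², i.e. ~7 kHz RMS broadening). `noise_sd` applies
  multiplicative Gaussian perturbation to the moment maps.
- **Frame stacks** — per 512-frame block, each pixel carries a
  stationary circular-Gaussian process whose centered-Gaussian PSD is
  *band-aware shaped*: its width is solved (monotone table inversion on
  the discrete STFT grid) so that the **in-band** second moment equals
  the target M2. A centered Gaussian's raw moment and its in-band moment
  differ by the excluded low-frequency mass, so matching the raw moment
  would make the spectral chain inconsistent with the moment renderer;
  matching in-band makes `stft_moments(render_frame_stack(c))` agree
  with `render_moment_video(c)` to a few percent at 16 windows.
  Static clutter is spatially random, temporally constant (rank-1, the
  SVD filter's exact target); sensor noise is complex white. Targets
  whose in-band moment is unreachable below Nyquist raise an aliasing
  error.
- **Repeat studies** — per-subject and per-measurement multiplicative
  flow factors drawn with the configured between-/within-subject CVs
  (truncated positive). Axial designs scale illumination/noise per
  position, lateral designs shift the disc and tree; neither perturbs
  true flow. Measurements are returned as scene configs plus scalar
  ground truth (rendering on demand), so statistical checks over
  hundreds of seeds stay cheap.

What the generator does **not** emulate: speckle and coherent-imaging
physics, eye motion, choroidal layers, hematocrit or pigmentation
effects, dynamic vessel caliber, or the instrument's actual noise
distribution (the Gaussian line shape and white sensor noise are
generator conventions — only moments matter downstream). Passing tests
therefore demonstrate the *analysis chain's* correctness and internal
consistency on data satisfying its assumptions, not performance on real
holographic recordings.

## Numerical choices and sizes

- Desk-scale defaults: 64×64 px scenes, ~6.5 cardiac cycles (~680
  analysis windows); frame-stack tests use 16×16–32×32 with 8k–16k
  frames. Full acquisitions (512×512 × 187k frames) are deliberately not
  reproduced.
- STFT band edges are inclusive on discrete bins; real-valued stacks use
  the one-sided spectrum. In-band power below 1e-12 of total power
  counts as zero (m2 undefined → NaN, propagated as missing).
- Least-squares fits run to tight tolerances (1e-15) from
  data-derived initializations; the exact-parabola residual is < 1e-9.
- "Several cardiac cycles" for the exclusion rule is read as ≥ 2 full
  cycles (configurable). Sample (n−1) SDs throughout; the intra-day
  repeat unit is the eye, matching a t coefficient at df = n−1.
- The demo pipeline's repeat-study report scales the single measured
  biomarker set by each simulated measurement's flow factor rather than
  re-imaging every measurement — plumbing for a fast demonstration, not
  a claim about measurement noise.

## Known limitations

- Segmentation assumes bright, non-overlapping, roughly tubular
  arteries with pulsatile flow; crossings and anastomoses are out of
  scope (sections touching another branch are simply dropped).
- QD and V_AS inherit low diastolic SNR: with moment noise the
  projection amplitude is clipped at zero, biasing QD downward — the
  same biomarkers that show the poorest repeatability on real data.
- The velocity model is linear in Δf with a fixed global α; no
  per-subject scattering, hematocrit or pigmentation correction is
  attempted.
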