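# retiflow

Quantification of retinal arterial hemodynamics from laser Doppler
holography (LDH), with a fully synthetic test bench.

LDH images the retina interferometrically at tens of kHz; moving red
blood cells broaden the Doppler spectrum of the backscattered light.
`retiflow` implements the offline analysis chain that turns such
recordings into arterial flow biomarkers:

1. **Reconstruction** — angular-spectrum propagation, SVD rejection of
   static clutter on the Casorati (pixels × time) matrix, and short-time
   Fourier moments in 512-frame windows: the in-band power `M0` and the
   normalized second-order moment `M2 = Σ f²S(f) / Σ S(f)` over the
   6–33 kHz band.
2. **Segmentation** — Frangi vesselness of the time-mean broadening
   image, gated by temporal correlation with the arterial pulse (veins
   and static structures fail the gate), Otsu thresholds, a background
   annulus around the arteries, branch labeling and cross-section
   placement.
3. **Hemodynamics** — differential broadening
   `Δf = sign(M2ₐ − M2_b)·√|M2ₐ − M2_b|` between arteries and their
   annulus; velocity `v = αλΔf/NA` (α = 5, λ = 852 nm, NA = 0.25);
   lumen diameters by Poiseuille (parabolic) profile fitting; volume
   rate per section `Q = v̄·π(d/2)²` with `v̄ = v_max/2`, averaged over
   sections, summed over branches; cardiac-cycle detection and
   integer-cycle low-pass filtering; the biomarker set QS/QD/QM, stroke
   volume V_AS, RI = (sys−dia)/sys, PI = (sys−dia)/mean (from both the
   velocity and the volume-rate waveform), heart rate, mean diameter.
4. **Repeatability** — per-subject mean/SD/CoV over repeated
   measurements, group summaries, and Student-t 95% confidence
   intervals `mean ± t₀.₉₇₅(n−1)·SD/√n`; measurements that do not span
   several cardiac cycles (blinks) are excluded first.

Because raw LDH acquisitions are terabyte-scale, the package ships a
**synthetic scene generator** (`retiflow.synthetic`) producing
ground-truth-annotated arterial trees — parabolic velocity profiles,
a cardiac waveform with systolic peak and dicrotic notch, tissue
broadening, clutter, sensor noise, and grouped repeat studies — either
as moment videos or as raw complex frame stacks whose short-time spectra
carry the same moments.

## Worked example

`examples/segment_and_quantify.py` renders a noiseless four-branch
64×64 phantom, segments it, and quantifies flow:

```text
segmented 4 branches, 8 cross-sections
metric           measured     truth
QM (uL/min)         17.65     17.33
QS (uL/min)         40.50     40.38
QD (uL/min)          8.09      8.08
VAS (nL)            50.07     50.22
RI (volume)          0.80      0.80
PI (volume)          1.84      1.86
H (bpm)             75.00     75.00
diameter (um)      105.28    105.00
```

The mean volume rate, resistivity index, heart rate and mean caliber
recover the generator's encoded truth to within a few percent. The other
examples demonstrate scene synthesis, the full frames→moments spectral
chain (including SVD clutter rejection), and a simulated intra-day
repeatability study summarized as a CoV table.

A thin CLI wraps the same library calls:

```bash
retiflow simulate --out scene.h5 --seed 1
retiflow segment --in scene.h5 --out map.h5
retiflow quantify --moments scene.h5 --map map.h5 --out biomarkers.csv
retiflow report --in biomarkers.csv --out table.csv
retiflow run --out bundle/ --seed 1     # full pipeline
```

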