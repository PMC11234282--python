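# Methods

This note documents the models behind each analysis stage, the parameters
that matter, what the synthetic-data generators do and do not emulate, and
the numerical choices made where the design was genuinely open.

## Acoustic exposure

The therapy sequence is a train of `n_pulses` tone bursts of `pulse_length`
seconds at repetition frequency `prf` (defaults 60 × 50 ms at 1 Hz, i.e. a
5% duty cycle, kept low to avoid thermal buildup). The mechanical index is
MI = PNP/√f with PNP in MPa and f in MHz; at the default exposure
(0.6 MPa, 1.5 MHz) MI = 0.49, i.e. 0.5 at one decimal. In-situ pressure is
derated from the free-field calibration as
`PNP · skull_transmission · exp(−α f d)` with brain attenuation
α = 5 Np/m/MHz and depth d in metres. Units are checked at construction;
the PCD sampling rate must exceed twice the 4th harmonic of f₀ so that all
monitored bands are resolvable.

## Intrapulse cavitation dose

**Windowing.** Each burst is segmented after a `head_cut` of 200 µs
(transducer switch-on transients) into contiguous windows of 200 µs; a
400 µs tail is discarded (switch-off distortion). The window count is
`floor((pulse_length − head − tail)/window)` — 247 windows of 3125 samples
for a 50 ms burst at 15.625 MHz. Head and tail samples are never analysed,
and no sample is analysed twice.

**Band power.** Per window a plain (untapered) rFFT is taken; power is
normalised one-sided as `P[k] = 2|X[k]|²/N²` (half that at DC/Nyquist), so a
unit-amplitude sinusoid on a bin contributes 0.5 = A²/2. This convention is
recorded with the outputs. A Hann taper with coherent-gain compensation is
available by flag for signals with strong off-bin leakage. Band integration
covers `[fc − bw/2, fc + bw/2)` on the discrete grid (lower edge included,
upper excluded; default bandwidth 50 kHz). IUD sums the ultra-harmonic bands
(1.5, 2.5, 3.5 × f₀), IHD the harmonic bands (2, 3, 4 × f₀). At the default
geometry the frequency step is 5 kHz and each band covers 10 bins, with all
band centers landing exactly on bins.

**Noise reference.** No pre-injection baseline is required: the default
estimator takes the median of the lowest quartile of all IUD values, which
ignores a minority of cavitation-active windows by construction. For a
dispersed noise distribution this statistic sits below the distribution
mean (it is the 12.5th percentile); since all event decisions are made on
the *ratio* IUD/noise against a configurable multiplier, this bias is
absorbed by the threshold and, critically, the whole decision chain is
invariant to rescaling the recording. An alternative `reference_pulses`
mode averages user-designated quiet bursts.

**Events and classification.** Windows with IUD/noise > `threshold_multiplier`
(default 6) are inertial events. Consecutive events are windows lying in
runs of ≥ `run_min` (default 2) flagged windows within one burst — runs
never span bursts — and both counts are expressed as percentages of all
analysed windows. The verdict is:

* **hard** if any burst's *mean* relative IUD exceeds the threshold (the
  sustained-suprathreshold signature) or the consecutive fraction exceeds
  `hard_consecutive` (default 3%);
* **soft** if the inertial fraction ≤ 1.4% *and* the consecutive fraction
  ≤ 0.3% (the maxima observed in histologically clean sonications);
* **mild** otherwise.

All cutoffs are configuration values echoed into every report. The hard
boundary at 3% sits between the soft maxima and the extremes observed with
erythrocyte extravasation (≈ 6.3%/6%); it is deliberately exposed because
the hard case is ultimately a histological judgement, not a sharp numeric
one. The relation between total and consecutive event fractions across a
cohort is summarised by ordinary least squares with R².

## MRI quantification

All volumes are assumed co-registered; registration, masking and atlas work
are out of scope.

**T1 mapping.** The magnitude inversion-recovery model
`S(TI) = |M0 (1 − 2κ e^{−TI/T1})|` is fitted per voxel by variable
projection: the polarity of pre-null samples is restored (two candidates
around the minimum-magnitude TI), the linear pair (M0, −2κM0) is projected
out in closed form, and T1 is located on a 200-point logarithmic grid over
[0.05, 8] s, refined on a 41-point local grid and a final parabolic step in
log T1. This is orders of magnitude faster than per-voxel curve fitting and
recovers noiseless T1 to better than 10⁻⁴ relative error. Flat, all-zero or
non-finite series and nonpositive fitted M0 are marked non-converged and
NaN-masked.

**Inversion efficiency.** From a phase-corrected (signed) control/label
vessel-slice pair downstream of the labelling plane:
α = mean over the vessel mask of |control − label|/(2|control|), clipped to
(0, 1]; label = −control gives α = 1, label = control raises an error.

**CBF.** Single-compartment pCASL with per-voxel measured T1:
`CBF = 6000 λ ΔM e^{PLD/T1} / (2 α T1 M0 (1 − e^{−τ/T1}))` in mL/100g/min,
with ΔM the mean control−label difference, λ = 0.9 mL/g, label duration
τ = 3 s, post-labelling delay 0.3 s, and T1/M0 resampled from the IR fit.
Negative ΔM voxels are clipped to zero and flagged rather than dropped, so
ROI statistics stay defined everywhere. CBF is linear in ΔM and inversely
proportional to α (verified as perturbation tests).

**BVf.** R2* is fitted pre- and post-USPIO by log-linear least squares over
the echo train (default 8 echoes, TE₁ = 3.5 ms, ΔTE = 5 ms), and
`BVf[%] = 100 · (3/4π) · ΔR2*/(γ Δχ B0)` with γ = 2.675×10⁸ rad/s/T and
B0 = 4.7 T. The blood susceptibility shift Δχ of the contrast dose is not a
universal constant; the default 2.0×10⁻⁷ (SI) puts a healthy-cortex ΔR2* of
≈ 40 s⁻¹ at BVf ≈ 3.9%, and the value used is logged in every map's
provenance. Negative ΔR2* is clipped to zero with a QC flag map. BVf is
linear in ΔR2*; doubling Δχ halves BVf.

**ADC.** Tensor mode fits `ln(S_i/S_0) = −b gᵢᵀ D gᵢ` by least squares over
≥ 6 non-collinear directions and reports trace(D)/3; mean mode averages
`ln(S_0/S_i)/b`. The two agree exactly (to machine precision) on isotropic
data; both are provided because vendor pipelines differ on this point.

**Gd enhancement.** `100 (post − pre)/pre` per voxel. The opened region is
delineated automatically as connected voxels whose pre/post difference
exceeds k·SD (default k = 3) of the difference in a contralateral reference
region — a scale-invariant, documented stand-in for manual outlining; its
volume is voxel count × voxel volume.

## Histology quantification

Marker segmentation uses documented intensity thresholding (Otsu within the
ROI by default, or a fixed level); the downstream quantities — area fraction
(% of ROI pixels) and mean intensity of segmented pixels — do not depend on
a particular classifier. Area fraction is invariant under intensity
rescaling with Otsu; mean intensity scales linearly.

Vessel morphometry skeletonizes the binary mask, splits the skeleton at
branch points (junction pixels close each incident segment for length but
are excluded from diameter sampling), and reports per segment: path length
(sum of centerline step lengths after a 5-pixel moving-average smoothing
that removes staircase quantization, which otherwise inflates curved-path
lengths by several percent), chord (endpoint distance), tortuosity
(path/chord ≥ 1, exactly 1 for straight tubes up to discretization), and
diameter (twice the mean distance-transform value along the centerline with
a half-pixel boundary correction, since the EDT measures to background pixel
centers). Segments shorter than 3 centerline pixels are discarded and
counted.

RBC extravasation sites are single-linkage clusters of RBC centroids at a
linking radius of 50 µm (unstated in the source protocol; config-exposed),
counting clusters with ≥ 5 cells.

## Statistics

Paired ipsi/contra comparisons use the exact two-tailed Wilcoxon signed-rank
test: zero differences are dropped (count reported), ties are mid-ranked,
and for ≤ 25 non-zero pairs the two-tailed p is computed as
`min(1, 2·min(P(W ≤ w), P(W ≥ w)))` from the *full* signed-rank null,
evaluated by a subset-sum dynamic program over doubled ranks (exact also
under ties). Larger samples use the tie-corrected normal approximation. The
n = 6 and n = 7 all-same-sign extremes give p = 2/64 = 0.03125 and
p = 2/128 = 0.015625. Headline changes are reported as
`100 (1 − mean_ipsi/mean_contra)`, rounded to the nearest integer with ties
away from zero; because ratio-of-means and mean-of-ratios differ, the
per-subject-ratio convention is reported alongside.

## Synthetic data: what it emulates and what it does not

The generators are signal-level, not physics-level.

* **PCD**: harmonic and ultra-harmonic content as fixed-phase sinusoids,
  broadband inertial emission as white noise spectrally masked to
  0.3–6 MHz and confined to designated analysis windows, white background
  noise, and the transducer switch-on transient as a decaying chirp inside
  the head-cut interval. No bubble dynamics, propagation, or skull
  aberration: passing tests show the dose engine separates the designed
  spectral content correctly, not that real emissions look like this.
  Amplitudes are in arbitrary units (no pressure calibration is modelled),
  which is consistent with the scale-invariant decision chain.
* **MRI**: a 64×64×8 cortex-like slab (voxel 0.234×0.234×1.5 mm) with
  mirrored hemispheres and a compact opened core (5% of the ipsilateral
  volume by default), uniform per-region ground truth, and forward models
  that are the exact inverses of the quantification formulas, with Rician
  noise (Gaussian on the complex channels, with a Gaussian flag for
  debugging) applied at the magnitude level. Default region truths follow
  the healthy/treated cortex values the pipeline is designed to resolve
  (CBF 93.57/42.24 mL/100g/min, BVf 3.9/3.4%, ADC 10⁻³ mm²/s, T1 1.5 s,
  core enhancement 18.66%). No k-space, partial volume, motion or
  distortion effects: recovery tests validate the inversions and their
  noise behaviour, not robustness to acquisition artifacts.
* **Fluorescence**: cells as disks with radial protrusions, vessels swept
  along explicit polylines with known radius, RBCs as point clusters —
  truth masks and centerlines are returned for oracle comparisons.

## Problem sizes used in the test and acceptance runs

Scaled-down geometries are used where the full study geometry adds nothing
to the property under test, as the package's own choice of desk-scale
conditions: cohort-level cavitation checks run 10 bursts of 10 ms (47
windows per burst, preserving the 200 µs grid and both cuts), and the
100-phantom noise-bias ensemble uses 32×32×4 phantoms. Zero-noise recovery
and the window-count checks run at the full acquisition geometry (50 ms
bursts, 781 250 samples; 64×64×8 phantoms).

## Known limitations

* The soft/mild/hard boundaries are study-derived defaults, not universal
  constants; the hard label in particular should be confirmed by histology.
* The noise-reference estimator assumes a majority of cavitation-quiet
  windows; a recording that is inertial nearly everywhere will inflate the
  reference and undercount events (such a recording is, however, flagged
  hard by the burst-mean rule).
* Δχ for the USPIO dose must be calibrated; BVf values scale inversely
  with it.
* Vessel diameters below ~3 px and segments shorter than 3 skeleton pixels
  are not measured reliably.
* The pipeline assumes co-registered inputs and does not model registration
  error.
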