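# Methods

`pinksfx` models serial still-diffraction data collection with a
polychromatic X-ray beam at the reflection level, merges the simulated
observations by Monte-Carlo averaging, and quantifies how the spectral
bandwidth changes the number of patterns needed for a given data quality.
This note records the model, its assumptions, the default parameters and the
reasoning behind them, and what the synthetic data can and cannot say about
real experiments.

## Diffraction model

**Geometry.** The reciprocal basis is the Busing–Levy upper-triangular B
matrix in the crystallographic convention (no 2π), so `|B·(h,k,l)| = 1/d`.
The laboratory frame is right-handed with the incident beam s₀ along +z; a
flat square detector sits normal to the beam. A reflection with laboratory
reciprocal vector **q** diffracts elastically at its Laue wavelength

    λ* = −2 (q·s₀) / |q|²,

and the scattered ray is s = λ* q + s₀. Reflections with λ* ≤ 0 cannot
diffract in that orientation.

**Finite reciprocal-lattice points.** Each point carries an effective radius

    R_eff = r_p + ½·η·|q|,

with r_p the profile radius from finite crystal size (Å⁻¹) and η the mosaic
full width (radians). The excitation kernel is a top-hat: the point is "on"
the Ewald sphere of wavelength λ whenever its offset e(λ) = ||q + s₀/λ| −
1/λ| is below R_eff. A triangular kernel would smooth the edges but makes
the fine-grid oracle inexact; the top-hat matches still-prediction practice.

**Spectral weight and partiality.** The beam spectrum S(λ) is normalised to
unit integral over a finite support: a Gaussian truncated at ±2.5σ (σ =
FWHM/2.3548), or a top-hat of full fractional width. A reflection's rocking
interval — the wavelength range over which the kernel is on — is found by
linearising e(λ) around λ* (slope |q|²/2, evaluated numerically) and
refining each endpoint with one Newton step on the true offset curve. The
spectral weight w is the integral of S over the rocking interval, computed
on the spectrum's `n_samples` grid (default 50) with exact interval–bin
overlap; the partiality is the fraction of the rocking interval that lies
inside the spectral support. The 50-sample evaluation agrees with a
10⁴-point quadrature to within 2%.

Two consequences drive everything downstream. The number of reflections
excited per still grows with the support width (more of reciprocal space
lies between the limiting Ewald spheres), and the weight of an individual
observation is the spectral density at its λ* times its rocking width — so
at fixed pulse energy a wide spectrum records more spots, each with fewer
photons, with the deficit growing towards the resolution limit where
rocking widths shrink as 1/|q|².

**Recorded intensity.** Expected photon counts of an observation are

    E[N] = k_p · Φ · |F±|² · w,

with Φ the fluence scale, |F±|² the Bijvoet-resolved true intensity and k_p
a per-pattern lognormal crystal scale. The detector records a Poisson draw
over a flat background; the stored intensity is the background-subtracted
net count and σ = sqrt(gross + background + 1). Lorentz/polarisation
factors are omitted (stills, scale-invariant statistics); multi-crystal
hits are not simulated.

## Ground truth

Unique reflections are enumerated to the working resolution, canonicalised
as the lexicographically greatest Laue equivalent, and classified centric or
acentric by whether −m lies in the point-group orbit. Acentric intensities
are exponential (Wilson) and centric ones follow the centric Wilson law,
both with mean ∝ exp(−B/(2d²)); B defaults to 20 Å², a typical
room-temperature protein value. Anomalous differences are zero-mean
Gaussian, scaled so the empirical Bijvoet ratio ⟨|ΔF|⟩/⟨F⟩ over acentrics
equals the target; centrics carry exactly zero difference. The default
target of 2% is the sulfur signal of thaumatin at 6 keV, consistent with
the counting estimate sqrt(2·17/1558)·f″/Z_eff ≈ 0.0198 for f″ = 0.9 e and
Z_eff = 6.7. The amplitude scale is arbitrary (mean intensity 1000 at
d = ∞); every reported statistic is scale-invariant.

## Default parameters

| parameter | default | reason |
|---|---|---|
| SASE mode | 5.99 keV, 0.17% FWHM Gaussian | narrow "self-amplified" lasing mode |
| pink mode | 6.02 keV, 2.2% FWHM Gaussian | chirped large-bandwidth mode; shape beyond the FWHM is not published, Gaussian assumed |
| overlap mode | 4.5 keV, 3.0/3.5% top-hat | large-cell feasibility study settings |
| detector | 373.65 mm square, 75 µm pixels, 95 mm | large flat pixel-array detector geometry |
| profile radius r_p | 1×10⁻⁵ Å⁻¹ | the fixed prediction profile radius used in the study's processing (10⁵ m⁻¹, converted) |
| mosaicity | 0 (merging), 0–0.3° (overlap scans) | well-ordered microcrystals; scan range of the feasibility study |
| fluence scale Φ | 2.0 counts per unit intensity and weight | puts resolution-limit shell I/σ near 1, as in the experiment's outer shells; wide-bandwidth spots at the limit carry a few photons |
| background | 10 counts per spot | viscous-jet background under a spot integration area |
| scale jitter | lognormal σ = 0.3 | ~20×10 µm crystal-size spread (unreported; stand-in) |
| Wilson B | 20 Å² | typical room-temperature protein falloff |
| spectral samples | 50 | mirrors the simulation settings of the study |

With r_p = 10⁻⁵ Å⁻¹ the Bragg spectral width is far below both bandwidths —
the regime the study argues from: every observation is strongly partial,
and the wide-bandwidth arm compensates by recording roughly an order of
magnitude more observations per pattern.

## Merging and metrics

Per-pattern scaling is a two-pass linear fit against the unscaled merged
reference (reflections seen at least twice), with the median scale
normalised to one. Merging is the unweighted Monte-Carlo mean per unique
(ASU triple, Friedel branch), with one 4-standard-deviation outlier pass
for groups of four or more; half datasets split patterns by index parity.
Merged σ is the standard error for n ≥ 2, else the observation's own σ.

Metrics follow their standard serial-crystallography definitions: R_split =
2^(−1/2)·Σ|I_e − I_o| / (½Σ(I_e + I_o)); CC_1/2 is the Pearson correlation
of half-set intensities and CC* its Karplus–Diederichs extrapolation;
CC_ano correlates half-set Bijvoet intensity differences (acentrics with
both mates in both halves); CC_anoref correlates observed |ΔF| (from
positive merged intensities) with the ground truth. Completeness counts
measured uniques against the absence-free enumeration; shells are
equal-volume in 1/d³ (default 10).

Published unique-reflection counts are reproduced exactly only when
systematically absent reflections are *included* (33 976 / 25 539 / 31 565
for the thaumatin ranges): merging tools tabulate the full asymmetric unit
without screw-axis knowledge. `enumerate_unique(..., include_absent=True)`
provides that convention; the default excludes absences, which is what the
simulator and completeness use.

**Recovery against truth.** A still-merged intensity estimates |F|² times
the mean Ewald-sweep weight of its reflection — a smooth function of
resolution (≈ 2R_eff/|q| over the excitation probability). Recovery is
therefore measured after per-shell median scaling, the same relative
scaling half-set comparison tools apply.

## Convergence analysis

Quality-versus-pattern-count curves use nested random subsets (a single
seeded permutation; larger subsets contain smaller ones) so that curve
noise reflects merging statistics, not re-sampling. The minimal pattern
count for a criterion is the smallest grid point meeting it. The
bandwidth comparison simulates both arms on one shared ground truth at
matched fluence and reports, per arm: the convergence table, the minimal
count for the anomalous-signal criterion (CC_ano ≥ 0.3 over d ≥ 3 Å — a
stated proxy for phasability, since phasing pipelines are out of scope) and
for a molecular-replacement-grade criterion (completeness > 80%, CC_1/2 >
0.8, outer-shell SNR > 3), plus two sample-saving summaries:

* the minimal-count ratio where both arms reach the threshold (with a
  conservative lower bound `grid_max / n_min_wide` when only the narrow arm
  falls short), and
* a threshold-free *matched-quality ratio*: for each wide-arm grid point,
  the smallest narrow-arm count reaching the same quality, summarised by
  the median of n_narrow/n_wide. On R_split this estimator is stable at
  desk scale (≈ 4 under the defaults) because precision metrics converge
  smoothly as n^(−1/2).

At desk scale (≤ 3000 patterns/arm, d_min 2.5 Å, ~10⁴ uniques) the CC_ano
estimator itself is noisy: with ~7600 Bijvoet pairs and a 2% signal its
seed-to-seed spread is ~0.1, so minimal-count readings off the CC_ano curve
vary between seeds even though the wide-bandwidth arm is consistently far
ahead. The precision-based ratio is the robust desk-scale statement of the
sample saving; the anomalous criterion's bookkeeping is reported alongside.

## Spot-overlap feasibility

Each excited reflection's footprint is the streak between its detector
projections at the extreme wavelengths of its excited sub-range, with a
transverse half-width of distance × mosaic half-spread plus a one-pixel
point-spread floor. Overlap counting uses dilated axis-aligned pixel
bounding boxes (conservative, brute-force-checkable); the capsule-exact
test — minimum segment–segment distance against the summed half-widths —
refines bbox candidates and is the default for the resolvability statistic,
since radial streaks of neighbouring spots routinely share bounding boxes
without touching. For the 61.5 × 122.2 × 168.5 Å receptor cell at 4.5 keV,
3.5% top-hat bandwidth and 0.2° mosaicity, ~98% of spots keep a positive
separation over the full recordable range (edge resolution ≈ 2.6 Å),
supporting integration feasibility; the overlap fraction grows
monotonically with mosaicity, bandwidth and cell volume.

## Numerical choices

* Spectral density renormalised on its grid so Σ S·Δλ = 1 to 10⁻⁹.
* Offset slope computed by one-sided finite difference at λ* (the analytic
  value is |q|²/2; the numerical route stays faithful near degeneracies).
* Orientations are uniform quaternions from per-pattern seeded substreams
  (`default_rng([seed, index])`), so any pattern can be regenerated alone.
* ASU canonicalisation via a lexicographic scalar key; ties cannot occur.
* Degenerate cells (volume → 0), zero Miller indices, q ⊥ s₀ and zero
  effective radii raise typed errors rather than propagating NaNs.
* Stream files store floats at full precision (`%.17g`); round trips are
  bit-exact.

## What the synthetic data do not show

The generator reproduces the statistical structure that the bandwidth
argument rests on — Ewald-shell coverage, partiality jitter, photon
dilution, Wilson statistics, a controlled Bijvoet ratio — but not:
indexing and prediction errors (orientations and wavelengths are known
exactly, whereas wavelength ambiguity degrades real wide-bandwidth data at
high angle), detector artefacts (gain switching, saturation), per-shot
spectral structure and jitter, multi-crystal hits, or background that
varies with scattering angle. Absolute pattern counts are therefore not
comparable to the experiment's (which needed ~10⁵ indexed images); only
orderings and ratios between the two simulated arms carry over, and they
reproduce the experiment's qualitative findings: ~12× more spots per
pattern, a ~4× pattern saving at matched precision, higher low-resolution
SNR and a terminal-shell SNR deficit for the wide-bandwidth arm at the
2.2 Å analysis limit.

Two documented desk-scale limits: the merged-vs-truth Pearson correlation
reaches only ~0.82 at 2000 patterns under the default photon budget (the
0.99 level would need ~5×10⁴ patterns, echoing the experiment's image
counts), and per-seed CC_ano convergence curves are noisy enough that
threshold crossings shift between seeds. Both are consequences of the
faithfully photon-starved regime, not of the estimator implementations.
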