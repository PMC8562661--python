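# pinksfx

Reflection-level simulation of pink-beam serial femtosecond crystallography
(SFX) and the Monte-Carlo merging statistics that quantify what a larger
X-ray bandwidth buys.

In SFX, every crystal contributes one still snapshot in a random
orientation, and each recorded Bragg spot is *partial*: a still integrates
only the sliver of a reflection's rocking range that the beam's spectrum
covers. Monte-Carlo merging averages these unknown partialities away, at
the price of needing very many patterns. Widening the spectral bandwidth
Δλ/λ from the narrow SASE value (~0.17% FWHM) to a "pink" few percent
thickens the Ewald shell: more reflections are excited per shot and each is
swept more completely, so the merge converges with fewer patterns — while
at the resolution limit the same photons are spread over a wider shell,
diluting the per-spot signal. This package implements that entire argument
as testable code, for crystallographers and instrument scientists who want
to estimate bandwidth/sample trade-offs before a beamtime.

## What it computes

* **Lattice geometry** — Busing–Levy reciprocal basis, P4₁2₁2/P1 symmetry
  with systematic absences, ASU reduction with Bijvoet bookkeeping,
  unique-reflection enumeration, flat-detector projection.
* **Beam and excitation** — truncated-Gaussian and top-hat spectra, Laue
  wavelength λ* = −2(q·s₀)/|q|², rocking widths from mosaicity and crystal
  size, partiality and spectral weight of every reflection in a still.
* **Synthetic ground truth** — Wilson-distributed structure factors with a
  controlled Bijvoet ratio (sulfur-SAD-like, ~2% by default).
* **Pattern simulation** — per-still reflection observations with Poisson
  counting noise, flat background and per-crystal scale jitter, written to
  a versioned text stream format.
* **Merging statistics** — per-pattern scaling, Monte-Carlo merge with
  half-dataset splits, R_split, CC_1/2, CC*, CC_ano, CC_anoref, I/σ,
  completeness, redundancy, per resolution shell:
  R_split = 2^(−1/2) Σ|I_even−I_odd| / (½ Σ(I_even+I_odd)),
  CC* = sqrt(2·CC_1/2 / (1+CC_1/2)).
* **Convergence analysis** — quality versus pattern count on nested
  subsets, minimal pattern counts for quality criteria, and the
  narrow-vs-wide bandwidth comparison at matched fluence.
* **Overlap feasibility** — radial streak footprints and capsule-exact
  spot-separation statistics for large unit cells.

## Worked example

Simulate 600 patterns per beam mode on one thaumatin-like ground truth
(cell 58.52 × 58.52 × 151.30 Å, P4₁2₁2, 2% Bijvoet ratio, d_min 2.5 Å) at
matched fluence, merge, and compare:

```python
from pinksfx import convergence, merging, truth
from pinksfx.config import RunConfig

rc = RunConfig(n_patterns=600, seed=1)
sf = truth.generate_structure_factors(
    rc.cell(), rc.symmetry(), rc.d_min, rc.wilson_b,
    rc.target_bijvoet_ratio, seed=1,
)
for arm in ("sase-6keV", "pink-6keV"):
    ds = convergence.simulate_arm(rc, sf, arm, seed=1)
    mg = merging.merge(merging.scale_patterns(ds.observations()),
                       rc.cell(), "P41212")
    print(arm, ds.summary()["mean_spots_per_pattern"],
          merging.r_split(mg), merging.redundancy(mg))
```

prints (values from this exact run):

```
sase-6keV   82.7 spots/pattern   R_split 56.9%   redundancy  3.1
pink-6keV 1006.3 spots/pattern   R_split 30.9%   redundancy 34.6
```

The 2.2%-bandwidth arm records 12.2× more spots per pattern and, at the
same pattern count, merges to roughly half the R_split — equivalently it
needs about a quarter of the patterns for the same precision (the
matched-precision ratio reported by
`convergence.bandwidth_comparison` is 4.0 under the default preset).

The same comparison from the shell, via the CLI:

```
pinksfx simulate --config run.cfg --spectrum pink-6keV --n-patterns 600 \
        --seed 1 --out pink.stream
pinksfx stats pink.stream --out shells.csv
pinksfx compare-bw --config run.cfg --seed 1 --out report.json
```

The numbered scripts under `analysis/` run the full study: geometry and
bookkeeping cross-checks (`01`), dataset simulation (`02`), shell-resolved
merging quality (`03`), the bandwidth convergence comparison (`04`) and the
large-cell overlap scan (`05`), writing their tables to `results/`. For the
61.5 × 122.2 × 168.5 Å receptor cell at 4.5 keV with 3.5% top-hat bandwidth
and 0.2° mosaicity, 98% of spots keep a positive separation over the full
recordable range (edge resolution 2.63 Å), and the overlap fraction grows
monotonically with mosaicity and bandwidth.

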