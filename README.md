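# filtomo

Subtomogram averaging and morphometry of helical amyloid filaments in
synthetic cryo-electron tomograms.

Cryo-electron tomography of brain tissue shows amyloid pathology as
clusters of thin, helically twisted filaments — tau paired helical
filaments (PHFs) and straight filaments (SFs), and β-amyloid fibrils —
embedded in noise and degraded by the missing wedge of a ±60° tilt series.
Extracting quantitative structure from such volumes takes a chain of
specialised steps: two-point filament picks densified into oriented
subvolume tables, wedge-aware iterative alignment and averaging, gold-
standard FSC resolution estimation, helical-twist measurement, filament
polarity statistics, and fibril morphometry. filtomo implements that chain
as a tested Python library, together with a first-class synthetic-scene
generator that plants filaments, branched fibrils and striated particles
with exact ground truth — so every stage can be validated by parameter
recovery rather than by eye.

The quantities at the package's core, in the field's standard notation:

* **Twist and crossover.** A filament twisting at ω (° nm⁻¹) repeats its
  projected cross-section every *crossover* distance d = 180°/ω; PHF-like
  defaults plant ω = 2.5° nm⁻¹ (d = 72 nm), SF-like ω = 2.2° nm⁻¹.
  Twist is measured from an aligned average by rotational registration of
  cross-section slices against the central slice and a linear fit of the
  unwrapped in-plane angle θ(z).
* **Wedge-constrained correlation.** Alignment scores are normalized
  cross-correlations restricted to the Fourier double-wedge support that a
  ±60° tilt series actually samples, so subvolumes are never aligned to the
  missing wedge; averages are wedge-weighted, and half-maps are built from
  disjoint whole filaments for an honest FSC(0.143) resolution.
* **Polarity statistics.** Each filament's axial orientation is the
  consistency vote of its refined segment directions (80% threshold);
  a cluster with k of n unambiguous filaments pointing the same way is
  scored by the exact one-sided binomial tail P(X ≥ k), p = ½, computed in
  log space (e.g. P(X ≥ 114 | n = 136) = 1.8 × 10⁻¹⁶).
* **Morphometry.** Maximum caliper (Feret) diameters of cross-sections
  (~15 nm tau-like vs ~6 nm amyloid-like populations), branch points as
  degree-≥3 nodes of pruned 3D skeletons (e.g. 17/51 = 33% branched), and
  striation spacing from the dominant interior peak of a detrended 1D power
  spectrum (2.5 / 2.8 nm layers).

## Worked example

`examples/03_align_and_average.py` simulates a 10-filament PHF-like
cluster (7/3 polarity split, 2.5° nm⁻¹ twist, snr 1, missing wedge),
picks it with randomised head/tail so polarity is unknown, aligns 24³
subvolumes against a rendered template reference, and prints:

```
aligned 163 segments from 10 filaments
half-map FSC 0.143 resolution: 19.0 A (curve never drops below 0.143: resolution is sampling-limited at Nyquist)
measured twist: 2.48 deg/nm -> crossover 72.5 nm (planted: 2.5 deg/nm, 72 nm)
```

The FSC line says the two independent half-maps agree at every resolution
the 9.52 Å voxels can represent (Nyquist = 19.0 Å); the twist line shows
the planted helical twist recovered to 0.7% from the average alone.
The other examples cover scene simulation (`01`), pick densification and
STAR export (`02`), polarity statistics (`04` — including the binomial
p-value above), morphometry (`05`) and model-to-map comparison with a
synthetic pseudo-atomic filament model (`06`).

A thin CLI wraps the same library for shell use:

```bash
filtomo run-all --out-dir run1 --seed 7          # simulate -> report
filtomo simulate --config scene.yaml --out tomo.mrc --truth truth.csv
```

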