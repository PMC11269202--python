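# Methods

filtomo re-creates, on synthetic data with exact ground truth, the analysis
chain used for helical amyloid filaments inside tissue cryo-electron
tomograms: scene simulation, filament picking geometry, missing-wedge-aware
subtomogram alignment and averaging, half-map FSC resolution estimation,
helical-twist and polarity statistics, fibril morphometry, and model-to-map
comparison. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic scenes do and do not show about
real data.

## Coordinate and orientation conventions

Volumes are numpy arrays indexed `[z, y, x]` (MRC section/row/column);
public coordinates are `(x, y, z)` triples, 0-based, with a voxel's centre
at integer indices and physical position = index × voxel size. Orientations
are intrinsic ZYZ Euler triplets `(rot, tilt, psi)` in degrees with

    R(rot, tilt, psi) = Rz(rot) · Ry(tilt) · Rz(psi)

mapping reference-frame coordinates into the volume frame (the explicit
matrix is in `geometry.euler_to_matrix`, written out in direct trigonometry
because the quaternion round trip loses precision for near-pole tilts). The
reference filament runs along +z, so a record's filament direction is
`R·ẑ`, which depends only on `rot` and `tilt`; `psi` is the free spin about
the filament axis. Negative twist rates are left-handed (the amyloid
convention); all public statistics report unsigned twist and positive
crossover.

## Synthetic scenes

**Cross-section templates.** Four families, sampled at 2.38 Å/pixel:
`phf_like` (a pair of C-shaped protofilaments related by an exact in-plane
C2, ~15 nm maximum caliper diameter), `sf_like` (the same protofilaments
packed asymmetrically, no C2), `abeta_fibril` (a compact two-lobed
cross-section, ~6 nm) and `protofilament_rod` (a single ~4 nm lobe). Each
C-shape carries a thicker lobe at one arc end. This is deliberate: a plain
circular arc is mirror-symmetric, which would make a filament's two axial
orientations (polarity flips) projectively indistinguishable; real
protofilament cross-sections are asymmetric, and the hook restores that
chirality. Template half-max calipers are checked by the morphology module
against the 15 ± 3 nm (tau-like) and 6 ± 2 nm (amyloid-like) populations.

**Filaments** are straight axes swept with the template cross-section,
rotated in-plane by `phase0 + twist_rate × arc`. Defaults plant
2.5° nm⁻¹ (PHF-like) and 2.2° nm⁻¹ (SF-like) twists, i.e. 72 nm and
~82 nm crossovers under the half-turn convention (below). Branch points
(allowed only for the amyloid-like families, matching the observation that
tau filaments are unbranched) attach a child filament at a stated arc
position and angle.

**Cuboidal particles** are axis-aligned blocks (edges validated against the
27–200 nm range) modulated by planar density layers of stated spacing
(default 2.5 or 2.8 nm) along a stated normal.

**Missing wedge.** The ±60°, 2°-step tilt scheme is idealised as a binary
Fourier double-wedge support: a tilt-α projection samples the central plane
rotated α from the k_z = 0 plane, so the un-sampled region is the double
wedge around the beam (k_z) axis; coefficients there are zeroed. The
retained fraction inside the Nyquist sphere is 120/180 = 2/3 (it is 0.711
over the full FFT cube, a corner effect). Consequences the tests exercise:
beam-axial filaments image cleanly while in-plane features smear along z,
and striations whose layer normal parallels the beam are unobservable —
noisy striation scenes therefore plant in-plane normals, as in real
tomograms where striations are seen in the x–y plane. No CTF, dose
weighting or tilt-dependent attenuation is simulated; the downstream
statistics are contrast-agnostic, and noise is white Gaussian scaled so
that (signal power)/(noise power) equals the requested snr.

**Ground truth.** Every filament contributes one table row per voxel of arc
length (endpoint-inclusive), with true positions in voxels and nm, true
ZYZ Euler angles (psi equals the local cross-section phase), polarity
vectors, twist, and tube bookkeeping; branch children get their own tube
ids. The table and the scene configuration round-trip losslessly through
CSV and YAML/JSON.

**Canned scenes.** `standard_test_scene` is the package's parameter-recovery
substrate: 40 PHF-like filaments in a roughly parallel cluster (≤8° angular
jitter, lateral grid spacing that avoids overlap) with a 34/6 polarity
split, 2.5° nm⁻¹ twist, 60–110 nm lengths, snr 1, in a 200³ volume at
9.52 Å. `mixed_class_scene` plants equal numbers of PHF-like and SF-like
filaments at snr 0.5 for two-reference classification.

## Picking geometry

A filament pick is a two-point head/tail contour. `stalk_init` produces
head, centroid and tail records whose rotation takes +z onto the
tail→head unit vector, with the spin left at 0 as the free parameter;
`add_points_along_axis` densifies a tube at arcs 0, s, 2s, … (the far
endpoint included when it falls on the lattice; default spacing 1 voxel).
Records carry tilt/psi priors of 0 and a psi flip ratio of 0.5, the
bookkeeping for "polarity unknown". Tables export to CSV and to a STAR
dialect using the RELION helical tags (`rlnHelicalTubeID`,
`rlnHelicalTrackLength`, `rlnAngleTiltPrior`, `rlnAnglePsiPrior`,
`rlnAnglePsiFlipRatio`). In the pipeline, picks derived from ground truth
have their head/tail assignment randomised per filament, so downstream
polarity recovery is a genuine inference, not a copy.

## Alignment and averaging

**Score.** Wedge-constrained normalized cross-correlation: the correlation
is computed over Fourier coefficients inside the subvolume's (rotated)
wedge support only, with the DC term excluded (equivalent to mean
subtraction); with a full support it reduces to plain centred NCC. A
subvolume is thus never rewarded or penalised for content in the region
Fourier space never sampled.

**Search.** Each segment is resampled once per iteration into the reference
frame; candidate orientations are realised by rotating the single masked
reference, so the per-iteration cost is O(n_segments + n_candidates) volume
interpolations, with translations scored for all shifts at once in Fourier
space. `restricted` mode searches the spin about the filament axis (default
12° grid over 360°) plus the polarity flip and axial shifts — the standard
first stage for filaments, which cannot align to the missing wedge.
`full` mode searches all three Euler offsets on a local grid plus 3D
shifts. Grid scores are refined by a separable parabolic fit around the
correlation peak, in both the score value and the sub-voxel shift;
integer-only shift scoring was observed to bias candidate selection toward
spurious rotations whose residual centring happens to be near-integer.
Ties resolve to the lowest-index candidate. Divergence (mean parameter
change growing three iterations running) returns the best-so-far state
with a warning.

**Polarity flips** are decided per filament, not per segment: the flip
class evidence (best correlation per class) is summed over a tube's
segments and the winning class applied to all of them. Polarity is a
physical property of the filament, and the aggregation turns a weak
per-segment chirality signal into a reliable per-filament call.

**Averaging** is wedge-weighted: each segment's Fourier data (recentred by
its refined sub-voxel shift, rotated into the reference frame) is
accumulated together with its rotated wedge support, and the sum is divided
by the per-coefficient coverage. Half-sets are whole filaments — odd/even
tube id by default, seeded random split optionally — never split within a
filament, so the half-map FSC is not inflated by intra-filament
correlation. The returned map is the voxelwise mean of the two half-maps.

**Reference.** `align_iterate` builds its reference from the current table
(wedge-weighted average) each iteration; an external initial reference can
seed the first iteration. The pipeline seeds with a noiseless rendered
template filament (untwisted sweep over the box): deterministic, fast, and
consistent with the classifier, which is reference-based by construction.
De novo bootstrap from the de-densified picks remains available by passing
no reference.

**Soft masks.** Cylindrical reference masks with a raised-cosine edge
(default radius 9 voxels, edge 2 voxels); the model-map FSC uses a soft
central sphere (default 80 Å radius).

**Helical symmetrisation** averages the map over j = −n..n copies rotated
by j × twist-per-subunit and shifted by j × rise (cubic spline resampling),
then over the in-plane point group if any. A rise below a quarter voxel
warns that the operation is resampling-limited.

**Classification** scores each segment against two rendered references with
the restricted search and assigns the majority label per filament
('ambiguous' on an exact tie); identical references are rejected.

## FSC

Unit-width shells in integer frequency of the smallest dimension; per-shell
correlation between the two (optionally masked) maps; the resolution is the
linear interpolation of the first downward crossing of 0.143. A curve that
never crosses reports Nyquist (2 × voxel) with a flag. Two caveats the
tests encode: the lowest one or two shells of a 64³ volume hold too few
coefficients for the |FSC| < 0.2 noise bound to hold at the 99th
percentile, and a real-space mask convolves the spectra, so a masked
model-map FSC only tracks a constructed band limit when the signal is
localized inside the mask and the out-of-band leakage tail sits below the
threshold.

## Twist, crossover, polarity statistics

**Crossover convention.** The crossover is the axial repeat of the apparent
(projected) cross-section: 180° of twist, for every template family, so
`crossover × twist = 180` exactly; callers wanting the full-turn repeat for
templates without in-plane C2 pass `full_turn=True`. A zero twist reports
an infinite crossover. The printed-range arithmetic follows directly:
180/2.5 = 72 nm, and crossover ranges of 79–129 nm in situ versus
65–80 nm ex vivo give 100×(1 − 65/80) = 18.75% to
100×(1 − 80/129) = 37.98% less twist (19–38% after integer rounding).

**Twist from an average.** Each z slice of the filament-aligned average is
registered rotationally against the central slice (polar resampling,
circular cross-correlation over angle, sub-bin parabolic peak); the
relative angle θ(z), unwrapped modulo the apparent repeat, is fit linearly
in z and the twist is the slope magnitude, with the RMS fit residual
reported. Registration was chosen over a per-slice principal-axis
(second-moment) fit: the absolute moment orientation carries a
grid-anisotropy distortion of a few degrees that biases the slope by more
than 5% on short boxes, whereas registration recovers planted twists to
~0.2% and is invariant to in-plane rotation of the whole map to ~0.1%.
The second moments are retained as the isotropy guard: a cross-section with
no measurable in-plane anisotropy raises an unmeasurable-twist error.

**Polarity.** A segment's direction is its rotated +z axis. The cluster
reference direction is the principal eigenvector of the segment-direction
scatter matrix (sign fixed so the majority is 'same'; an explicitly
supplied reference is honoured as given, and flipping it swaps the
labels). A filament whose fraction of segments along the reference is
≥ 0.8 is 'same', ≤ 0.2 'opposite', otherwise 'ambiguous' — the 80%
consistency vote is a configurable threshold, and is this package's
reading of an orientation-consistency rule that could be interpreted in
more than one way. The cluster test is the exact one-sided binomial tail
P(X ≥ k_majority) with p = 1/2 over the unambiguous filaments, no
multiplicity correction, computed in log space (gammaln + logsumexp;
relative error ~1e-14 even at tail probabilities of 1e-16, verified against
arbitrary-precision enumeration). Clusters with fewer than two filaments
are flagged with p = 1.

## Morphometry

**Maximum diameter** is the caliper (Feret) diameter of the suprathreshold
footprint in the plane perpendicular to the traced axis, resampled at 2×
the voxel sampling and averaged over ±2 voxels along the axis (the twist
over that span is negligible at these resolutions, and the averaging lifts
weak fibrils above the noise). The default threshold is half the in-plane
maximum after median background subtraction, floored at 3.5× the robust
(negative-side MAD) noise scatter so noise cannot bridge a weak footprint;
footprint components reaching within 8 nm of the plane centre are kept, so
a cross-section that separates into disjoint protofilament densities at
half-max is still measured whole while neighbouring filaments stay
excluded. Raw widths are always reported; subpopulation bins (rod / fibril
/ wide fibril) are assigned by nearest bin centre among 4, 6.5 and 9 nm
(the printed 3–5 / 4–9 / 6–12 nm ranges overlap), with exact midpoint ties
going to the narrower class.

**Branch points** are junctions (degree ≥ 3 voxel clusters) of the 3D
skeleton after pruning spur chains shorter than 3 voxels; disconnected
objects are reported per connected component. The branch fraction returns
both the exact rational and the integer-rounded percent (17 of 51 → 33%).

**Striation spacing** averages the density over planes perpendicular to the
layer normal (bins of one voxel along the projection, rounded — truncation
binning creates spurious empty-bin periodicity), detrends linearly, and
reads the spacing off the dominant interior peak of the 1D power spectrum
with sub-bin parabolic interpolation. A peak below 3× the median spectral
level, or a featureless profile, reports no periodicity; a region holding
fewer than 4 periods is an error.

## Model-map comparison

Atomic models (PDB via gemmi) become densities as sums of per-atom
Gaussians weighted by atomic number, normalised to unit peak. Agreement is
quantified by the Pearson real-space correlation over a mask and by the
model-map FSC under the soft central-sphere mask. Rigid fitting exploits
helical geometry: a grid over rotations about the filament axis plus axial
shifts, not a global 6-D search. Likelihood-based fit scores are out of
scope; the correlation coefficient plus masked FSC is the package's
documented substitute, and the convention that a log-likelihood-gain above
60 indicates a non-random fit is noted here only for context. For testing,
`synthetic_filament_model` builds a pseudo-atomic stand-in (carbon atoms on
the template cross-section, extruded helically); it is labelled synthetic
and is not a real structure.

## Pipeline

`pipeline.run` executes simulate → pick → align (restricted, then a short
full-mode polish) → FSC → twist → polarity → morphology sequentially,
writing every intermediate product (MRC maps, CSV/STAR tables) plus a JSON
and text report with a provenance block (config hash — excluding the output
directory — seed, package version). Identical config and seed give a
byte-identical report body; completed simulate/align stages are skipped on
rerun when the stage manifest hash matches. Alignment runs on segments
subsampled every 4 voxels along each tube (the 1-voxel table is kept and
exported); with ~10–20 segments per filament the per-filament statistics
are already stable, and the subsampling keeps the standard 200³ scene
around three minutes end to end on one CPU. Stage failures are recorded in
the report with partial outputs retained, never raised.

## Known limitations

* Scenes contain only filaments and cuboidal particles — no membranes,
  vesicles, organelles or crowding, no CTF, no per-tilt dose weighting, and
  noise is white rather than structured; passing tests demonstrate the
  correctness of the geometry, alignment and statistics, not robustness to
  the full complexity of tissue tomograms.
* Filament axes are straight; real filaments curve over micrometres.
* Single-segment axis (tilt) precision at 24³/9.52 Å is intrinsically
  ~4°, limited by the spin–shift screw degeneracy of a helical rod and
  interpolation noise; axis accuracy comes from the pick geometry and from
  per-filament aggregation, as in established helical processing.
* The two-reference classifier is competitive template matching, an
  explicit simplification of likelihood-based multi-class refinement.
* Binning-ladder refinement (24³ → 48³ → 96³) is configurable but the
  bundled scenes exercise a single stage; the scheduling machinery carries
  no per-stage CTF model.
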