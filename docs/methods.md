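# Methods

tomogeom converts sparse manual annotations of cryo-electron tomograms into
dense, ordered geometry: oriented particle poses on filaments and membranes,
straightened volumes, and interpolated segmentations. This note records the
models, the numerical choices, and what the synthetic test data does and
does not establish.

## Conventions

Particle positions are voxel coordinates of the source tomogram in `(x, y, z)`
order; image arrays are stored `(z, y, x)` (native index order), and the two
meet only at module boundaries (resampling, file I/O). An orientation matrix
`R` maps reference-frame basis vectors onto particle basis vectors, so the
particle's local z axis in the tomogram is the third column of `R`;
`particle_to_reference` exposes the transposed view. Pixel spacing is Å/voxel
with `0` meaning *unknown*; an unknown spacing is propagated, never guessed,
because silently assumed units are the classic interoperability failure of
particle metadata.

## Splines and arc-length sampling

Curves are parametric B-splines (`scipy.interpolate.splprep`) with
chord-length parametrisation. The requested order `k ∈ [1, 5]` is demoted to
`M − 1` when only `M ≤ k` points are given; smoothing `s` is the standard
least-squares smoothing factor, with `s = 0` interpolating the picks.

Equidistance in Euclidean space — not in parameter — is obtained through a
dense arc-length table: `max(1000, 10·M·(k+1))` uniformly spaced parameters,
cumulative chordal sums, and monotone linear interpolation for the inverse.
`sample_equidistant` places `K = max(2, round(L/spacing) + 1)` samples at arc
lengths `j·L/(K−1)`: exact equidistance is preferred over hitting the nominal
spacing, and both endpoints are always included. On smooth curves, sampled at
spacings well below the curvature radius, the coefficient of variation of
consecutive distances is ~2×10⁻⁴. At coarse spacings an irreducible geometric
term appears — equal *arc* steps produce chords shortened by ≈ κ²s³/24 where
the curvature κ varies — which no sampler can remove; the tests therefore
measure equidistance in the fine-spacing regime.

Frames along a curve are rotation-minimising (twist-free), computed by the
double-reflection parallel-transport method over a dense parameter grid that
always contains the requested parameters. The initial normal at `t = 0` is
deterministic: the coordinate axis with the smallest tangent component,
projected into the normal plane. Local Z is the unit tangent by convention;
on a straight line along +z every frame is the identity.

## Helical filaments

A filament pick is a spline through manually clicked points. Axis samples are
placed equidistantly at the helical **rise**; sample `j` carries the frame
`F_j = RMF_j · Rz(j·twist)`, and with a nonzero **radius** the particle is
shifted off-axis along that frame's local X axis — index-proportional twist
plus radial offset is what produces the helical point pattern. The phase
origin is the filament start (index 0); no user origin is exposed. Cyclic
symmetry Cn replicates each pose by further local rotations `Rz(360°·m/n)`,
rotating offset and orientation together about the axis point, so the output
is `n·K` poses forming a consistent lattice for subtomogram averaging. A rise
longer than the filament degrades gracefully to the 2-endpoint minimum.

## Spline-grid surfaces

Membranes are annotated as ordered point strips on a few z-slices. The
reconstruction: (1) strips ordered by slice, pick order preserved; (2) one
spline per strip; (3) equidistant samples at the requested spacing; (4)
integer index alignment of consecutive strips plus rectangular padding; (5)
a second spline family through matched columns; (6) common equidistant
resampling of the columns; (7) a third family along the rows; (8) tangents of
families 2 and 3 at each node, normal = normalised cross product, frame
completed by Gram–Schmidt (local X from the row tangent, Y = Z × X).

Open choices resolved here:

* **Alignment cost** is the *mean* index-wise distance over the overlap
  (≥ 2 points); a raw sum would favour shifts that shrink the overlap. Ties
  break toward smaller |shift|, then smaller shift.
* **Padding** linearly extrapolates each strip's terminal segment. Padded
  nodes support the splines but are flagged and excluded from pose output by
  default.
* **Common row count** in step 6 is the count the longest column needs
  (`round(L/spacing)+1`, minimum 2), keeping the grid rectangular; shorter
  columns are sampled slightly finer than requested.
* **Mask propagation**: a resampled node is flagged padded when its arc
  position along its column falls outside the arc span of the column's real
  support points (tolerance: half a spacing).
* **Normal sign** is seeded by the raw cross product at the first node and
  made continuous by neighbour propagation across the grid.

On analytic fixtures the grid recovers a tilted plane's normal to well under
1° and a radius-50 cylinder's radial normals to < 0.3°, with inter-node
spacing within 1% of requested away from padding. Strongly irregular
surfaces (invaginations spanning slices) deform the grid; there the
error-contract, not a meaningful grid, is all that is guaranteed.

## Surface-guided resampling ("straightening")

The tomogram is sampled by trilinear interpolation at
`node + (w − (W−1)/2)·step·normal` for `w = 0..W−1`, with
`W = 2·floor(thickness/(2·step)) + 1` forced odd so the annotated surface is
the exact central slice. Output axis order is (normal, u, v), so "average
along Z" is a mean over axis 0. Out-of-volume samples take the volume mean —
a neutral fill that avoids contrast artefacts in projections — and an
optional validity mask records them so `project_mean` can exclude them from
quantification. Output pixel spacing is `step ×` input spacing.

## Label interpolation

Sparse segmentations are densified per label by signed distance fields:
positive Euclidean distance to background inside the mask, negative distance
to the mask outside (scipy's exact EDT), clipped to ±(sum of slice
dimensions) so empty or full slices stay finite. An empty slice is "label
absent" at −cap, which makes a label present on only one bounding slice
shrink toward nothing — a choice, stated here, not a given. For an empty
slice at `x` between annotated slices `a < b` the field is
`((b−x)·SDF_a + (x−a)·SDF_b)/(b−a)` — computed in exactly this
integer-weighted form so the zero crossing is reproducible — and a voxel
joins the label with the largest strictly positive field. Annotated slices
pass through unchanged; nothing is extrapolated beyond the outermost
annotated slices. Thin structures (filament-like labels) are a known weak
spot of distance-field averaging and are out of scope.

## Image operations

`convolve` reproduces on the CPU the weighted-average scheme of a fragment
shader sampling a texture in an N×M window: a centered correlation (no kernel
flip — an impulse reproduces the point-reflected kernel) with clamped
(border-replicated) edges, matching texture-sampling semantics. The Gaussian
filter is separable with auto size `2·ceil(3σ)+1` and agrees with the dense
kernel to float precision because replicate-padding is itself separable. The
bandpass is a radial FFT mask in cycles/image with raised-cosine edges
(default width 2 frequency pixels) against ringing. Power spectra use the
unnormalised forward FFT, pinned down by Parseval
(`ΣP = N·Σ|I|²`), zero frequency centered, with `log(1+P)` exposed as a
separate display transform.

## File formats

STAR (Relion ≥ 3.0) and TBL (Dynamo) conversion goes through the common pose
container, making any-to-any conversion a read plus a write. Relion
positions are `rlnCoordinate − origin` with Å origins (`rlnOriginXAngst`,
3.1 dialect, converted by the optics-group pixel size) preferred over pixel
origins (3.0 dialect); unrecognised columns ride along as features and are
written back. The documented Euler semantics (reference→particle) are
`R = Rz(−rot)·Ry(−tilt)·Rz(−psi)` for Relion ZYZ and, analogously,
`R = Rz(−tdrot)·Rx(−tilt)·Rz(−narot)` for Dynamo ZXZ; at gimbal lock the
in-plane rotation goes to the first angle and the round trip through
matrices stays exact. The Dynamo column map is fixed to the documented
1-indexed layout (1 tag, 4–6 shifts, 7–9 angles, 20 volume, 24–26
coordinates); shorter dialects are zero-padded. Floats are written at 6
decimals in both formats, which bounds round-trip errors at ~10⁻⁶ voxel in
position and ~10⁻⁸ in orientation-matrix entries. MRC2014 I/O is implemented
directly on the 1024-byte header (modes 0/1/2/6 read, mode 2 written with
the voxel size in `cella/m`); `lazy=True` memory-maps voxel data so
larger-than-memory volumes open instantly. EM is read-only; TIFF carries no
spacing. `read_any` dispatches by extension and can stamp a shared
experiment id from a filename regex so images and particles of the same
tomogram associate.

## Synthetic data: what it shows and what it does not

The fixture generators produce a straight helical filament of Gaussian blobs
(default rise 5, twist 30°, radius 8 voxels, 10 subunits in a 64³ volume),
membrane sheets (tilted plane, sphere cap, gentle sinusoid) with per-slice
point strips and analytic normals, and sparse label stacks (concentric disks
of radius 4 and 8 on slices 0 and 10 of an 11-slice stack). Defaults are
chosen to resemble typical sub-tomogram picking geometry at binned pixel
sizes; all randomness (noise, pick jitter) flows from an explicit seed.
Passing tests establish the geometric algorithms against exact ground truth;
they do not establish robustness to missing-wedge anisotropy, CTF, crowding
or picking errors beyond small Gaussian jitter, none of which the fixtures
model.

Problem sizes throughout the suite (≤100³ volumes, tens of strips, a few
thousand poses) were chosen as the smallest at which every property is
meaningfully exercised.

## Known limitations

* No closed/periodic splines, so ring-like filaments close only to within
  one spacing.
* Surfaces must be graphable strip-by-strip; invaginations and branching are
  unsupported.
* Only cyclic (Cn) symmetry; no dihedral or point groups, no helical
  symmetry search.
* Relion-4 tomography tables, EMAN2 `.json`/`.hdf`, and Warp/M XML are not
  read; the Relion 3.x particle table is the supported STAR dialect.
* The exact sign/order semantics of Dynamo's (tdrot, tilt, narot) relative
  to its MATLAB implementation are taken as documented above;
  self-consistency (euler↔matrix, star↔tbl↔star) is what the test suite
  verifies.
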