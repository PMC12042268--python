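# Methods

## Scope and model

`interdigit` quantifies transbilayer chain interdigitation in symmetric,
planar phospholipid bilayers simulated with all-atom force fields (CHARMM
atom naming). The bilayer normal is z; boxes are orthorhombic and periodic in
all three dimensions. The package assumes no lipid flip-flop on the analyzed
timescale: the leaflet map is computed once from the whole trajectory and
held fixed, with an optional per-frame re-check that warns on any anchor
sign change.

### Frame preparation

1. **Unwrap repair.** Molecules split by periodic imaging are rejoined by
   moving each residue's atoms to the minimum-image position relative to the
   residue's first atom. Analyses assume molecule-contiguous coordinates.
2. **Centering.** Each frame is rigidly translated along z so the
   mass-weighted center of the lipid terminal-methyl *carbons* is at z = 0.
   Methyl hydrogens are excluded: carbons dominate the group mass and the
   choice moves the reference by well under 0.05 Å; the selection is
   configurable through the chain-indexing layer. Centering is a pure
   translation, idempotent (a frame already centered within 1e-9 Å is
   returned unchanged), and leaves x, y untouched.
3. **Leaflets.** A lipid belongs to the top leaflet iff its anchor atom
   (headgroup phosphorus "P" by default, configurable) has
   trajectory-averaged z > 0 over the analyzed frames. Lipids whose mean
   anchor z is within 1 Å of the midplane trigger a warning and are assigned
   by sign.

### Chain indexing

Chain carbons are enumerated from CHARMM names: sn-1 = C32, C33, …; sn-2 =
C22, C23, …, ordered toward the terminal methyl and required to be
contiguous. The ester carbonyls (C21/C31) are excluded — they are not acyl
*chain* carbons; the name patterns are overridable for other naming schemes.
Matrix metrics assume one lipid species per system (uniform chain lengths)
and raise otherwise.

## nISA: periodic 3D Voronoi tessellation

All lipid and water atoms of a frame (hydrogens included) are Voronoi
generators. Periodicity is implemented by tessellating the generators
together with their 26 periodic images (Qhull, via `scipy.spatial.Voronoi`)
and mapping ridges back to the primary cells:

- a ridge between two primary-image cells is one physical face;
- a ridge that crosses the box boundary appears twice — once from each
  owning cell — so those ridges carry weight ½ in any area or volume
  bookkeeping, and exactly one copy (the one owned by the top-leaflet atom's
  primary cell) is retained in the interface mesh at its full geometric area.

Cell volumes are convex-hull volumes of each primary cell's vertex set; the
tessellation is validated by the partition identity Σ volumes = Lx·Ly·Lz
(observed relative error ~1e-9, asserted at 1e-6). On small point sets the
neighbor graph and per-pair face areas are additionally checked against an
independent half-space-intersection construction.

The interface mesh keeps exactly the faces whose two owners are lipid atoms
in opposite leaflets; faces involving waters (which belong to no leaflet) or
same-leaflet pairs are excluded. nISA is the mesh area divided by the
frame's instantaneous A_xy, and the trajectory value is the unweighted mean
of per-frame values. The water capping layers included as generators are
essential: they bound the cells at the z extremes and prevent spurious
cross-leaflet faces wrapping through the z boundary.

**Degeneracy handling.** Exactly cocircular/coplanar generators (e.g. ideal
lattices) are perturbed by a deterministic jitter of 1e-6 Å keyed to a fixed
RNG stream over atom indices, applied to all generators. The jitter is far
below atomic resolution; on the flat-lattice reference it changes nISA by
~2e-7. Coincident generators additionally raise a warning.

**Outputs.** Face polygons export to Wavefront OBJ (centroid-fan
triangulation; vertices round-trip to 1e-4 Å). The 2D depth map grids face
centroid |z| over xy (area-weighted per cell; cells finer than the face
spacing are filled from the nearest face centroid). Mesh vertex z is
reported in the centered representation ([−Lz/2, Lz/2)), so midplane faces
form continuous polygons; faces at the box z-edge (never cross-leaflet in a
capped system) would wrap.

**Cost.** The 27-image construction scales Qhull input by 27×; it is exact
and adequate at fixture scale (hundreds of generators per frame, ~0.5 s).
For production bilayers (10⁴–10⁵ atoms/frame) the frame loop is the unit of
parallelism (see block analysis below).

## ccMat: contact counting

A contact is a cross-leaflet pair of chain carbons with minimum-image
distance ≤ cutoff (default 4 Å); each qualifying pair counts once per frame
regardless of distance. Hydrogens are excluded by construction of the chain
index. Counting uses a periodic k-d tree (`scipy.spatial.cKDTree` with
`boxsize`); the O(N²) exhaustive enumeration is kept in the test suite as
the oracle and the two agree exactly. Cutoffs above half the smallest box
length are rejected (minimum image invalid). The matrix is indexed by carbon
position aggregated over lipids (all top-leaflet C216 atoms are one row);
rows/columns are ordered sn-1 C2→terminal then sn-2 C2→terminal, giving the
2×2 quadrant structure. Swapping leaflet labels transposes the matrix
exactly.

## doMat and memIT: density overlaps

Number-density profiles are per-frame z-histograms normalized by (bin width
× that frame's A_xy), averaged over frames on a fixed global grid spanning
the largest box z extent (the box fluctuates under pressure coupling). The
default bin width is 1.0 Å — at this resolution the rectangle-rule overlap
of sampled Gaussians matches the erf closed form to well under 1% at 10⁵
samples, and halving the bin changes overlaps by < 1% on smooth profiles.
Overlaps use Σ min(ρ₁, ρ₂) × Δz on the common grid — consistent with the
histogram estimator — and are computed on the *time-averaged* profiles, not
averaged per-frame overlaps. Each Ωᵢⱼ is symmetric in its arguments and
bounded by the smaller profile integral.

memIT uses whole-leaflet mass-density profiles (all leaflet atoms,
mass-weighted). Two standard dimensionless variants ship:

- `min-ratio`: 2∫min(ρt, ρb)dz / ∫(ρt + ρb)dz;
- `membplugin` (default): ∫ [4 ρt ρb/(ρt + ρb)²] · w(z) dz with
  w(z) = (ρt + ρb)/∫(ρt + ρb)dz.

Both are 1 for coincident and 0 for disjoint profiles. The MEMBPLUGIN-style
form is the default because that is the established tool for this baseline;
both values are always reported so either convention can be matched against
published numbers.

## Time-series layer

- **ACF**: normalized autocovariance with the direct unbiased estimator
  (division by n−k pairs at lag k) by default, exact on short series; an FFT
  path computes the identical quantity for long series (equivalence is
  tested to 1e-10). Default maximum lag n/5.
- **Double-exponential fit**: A·e^(−t/τslow) + (1−A)·e^(−t/τfast) with the
  amplitude sum constrained to ACF(0) = 1 (an unconstrained variant is
  available). The window runs to the first lag below a 0.01 noise floor.
  Several starting points are tried; τslow ≈ τfast is flagged as degenerate
  (effectively single-exponential). Noiseless synthetic ACFs are recovered
  to 1e-6; at 0.01 noise, parameters are recovered within 10%.
- **Block averaging**: block sizes double until the blocked SE changes by
  < 5% across two successive doublings; without a plateau the largest block
  (≥ 4 blocks) is used and flagged. For AR(1) data this reproduces the
  effective-sample-size inflation √((1+φ)/(1−φ)).
- **Correlation**: Pearson r between equal-length per-frame series (e.g.
  interfacial area per lipid vs area per lipid).

## Synthetic bilayer generator

The generator emulates only the statistical structure the metrics consume:
two leaflets of multi-atom "lipids" whose per-carbon z distributions are
Gaussians with means running linearly from `head_depth` (default 12 Å) down
to `−delta`, mirrored about z = 0, with spread `sigma` (default 2 Å — a
realistic carbon z-spread; much smaller values make the two terminal-carbon
distributions nearly coincident at δ = 0, and the summed pairwise overlap is
then non-monotone in small δ even in closed form). `delta` is the
penetration depth: how far the terminal carbon's mean extends past the
midplane. Carbons are re-sorted per chain so depth order is preserved;
water-like generator points cap the system as lattice layers beyond the
headgroups (2–3 layers, enough to bound the tessellation). Atom names follow
the CHARMM convention (P anchor, C2n/C3n chains) so fixtures exercise the
full I/O path via a minimal X-PLOR PSF writer plus MDAnalysis DCD output.

The flat-lattice variant (σ = δ = 0, uniform gap 2×1.5 Å at the midplane,
perfect-square lipid count commensurate with the box) is the analytic
reference: its cross-leaflet Voronoi faces tile the lateral box exactly, so
nISA = 1.

What the fixtures do **not** model: bonded geometry, excluded volume,
realistic area per lipid, undulations, or dynamics (frames are i.i.d.
samples). Passing tests therefore demonstrate correctness of the geometry,
counting and statistics — not force-field-level realism. Fixed seeds make
all fixtures bit-reproducible.

## Block-parallel analysis

The frame range can be split into contiguous blocks analyzed independently.
All accumulators (per-frame rows, contact-matrix sums, density histograms)
merge by addition, so the merged result is identical to a single pass —
block decomposition is a correctness-preserving unit of parallel work, and
is executed sequentially in-process here.

## Problem sizes and defaults

Tests and the acceptance script run on fixtures of 16 lipids/leaflet with
4+4 chain carbons plus ~100 water generators (≈ 500 atoms/frame) and up to
12 frames — large enough that every code path (periodicity, quadrants,
leaflet symmetry, monotone δ response) is exercised, and sized as an
analytic/statistical validation rather than a production simulation.
Defaults: contact cutoff 4 Å; density bin 1 Å; ACF max lag n/5; noise floor
0.01; block-averaging plateau tolerance 5%.

## Known limitations

- nISA is normalized by the projected area and therefore inflates under
  membrane undulation; no curvature correction is applied (per-lipid
  normalization is exposed as an alternative reading of the series output
  but not validated).
- Planar geometry only: leaflet assignment by mean anchor z is wrong for
  vesicles or strongly deformed membranes.
- Single lipid species per system for the matrix metrics.
- The leaflet map is fixed for the trajectory; systems with flip-flop need
  per-frame assignment, which is out of scope.
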