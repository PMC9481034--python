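# Methods

## Scope and model

`asternet` treats an actin aster network as a planar point pattern of
junctions ("vertices") connected by straight bundles. The 2D treatment is
justified by the geometry of the imaged structures: their axial extent is
one to two vertex spacings (≈ 10–25 μm) against a lateral extent of
millimetres, so a single focal plane captures the topology. All analysis
quantities are expressed in micrometres; images carry an explicit
μm-per-pixel calibration that is never guessed from file metadata.
Coordinates follow image convention: x rightward, y downward, origin at
the centre of the top-left pixel.

The network's connectivity proxy is the Delaunay triangulation of the
vertex positions. This is a modelling choice, not a claim that every
Delaunay edge is a physical bundle; on near-hexagonal fields the two
coincide almost everywhere, which is exactly the regime the statistics
(median degree, hexagon correlation) are designed to quantify.

## Synthetic data generator

The generator produces the study conditions the analysis assumes, with
known ground truth:

* **Layout.** Vertices on a triangular lattice of constant `a`
  (default 11 μm, the centre of the observed 9–13 μm range): rows spaced
  (√3/2)·a, alternate rows offset a/2, boundary points included. Each
  vertex is displaced by a uniform draw from a disc of radius
  `jitter_fraction · a` (default 0.1) — isotropic and bounded, so the
  lattice topology survives below fraction 0.5 — and optionally deleted
  with `missing_vertex_prob` (default 0: the generator models the clean,
  settled fields the statistics describe; defects are opt-in).
* **Rendering.** Each Delaunay edge of the true positions is drawn as
  k ∈ [1, 3] parallel strands (bundles frequently run as multi-strand
  connections), offset perpendicular by ≤ 0.9 μm, each 0.8 μm wide, with
  anti-aliased sub-pixel endpoints; the scene is blurred by an isotropic
  Gaussian PSF (σ = 0.45 μm, a typical confocal mid-band value) and scaled
  to `background_level` + `signal_amplitude` (20/160 counts).
* **Noise.** Per-pixel Poisson resampling (shot noise) plus zero-mean
  Gaussian read noise (σ = 3 counts), clipped at zero.
* **Grid.** Default 750 × 750 μm at 2048 × 2048 px → 0.366 μm/px. The
  calibration is a configurable inference, not a measured constant.

Layout, rendering and noise consume independent child streams of the
single spec seed, so every output is a pure function of the spec.

What the generator does **not** emulate: depletion-force physics, bundle
curvature, intensity falloff with depth, pre-aster/partial structures,
uneven illumination beyond a constant background, and detector artefacts
(hot pixels, vignetting). Passing parameter-recovery tests therefore
demonstrates correctness of the analysis chain under the stated geometric
and noise assumptions — not robustness to every pathology of real
micrographs.

## Vertex detection

A junction is a point where several straight bundles cross; a matched
thin-line filter responds there at *many* orientations, but at only one
along a bundle. The chain:

1. **Saturation normalisation.** Intensities are clipped at the 25th
   percentile of the significant pixels (above median + 6·MAD of the
   frame). Multi-strand bundles differ in brightness by integer factors;
   without clipping, bright mid-sections outvote dim junctions and the
   geometric signal is lost. A frame whose significant-pixel fraction is
   below 0.2% is declared structureless and yields zero vertices.
2. **Line-kernel bank.** `n_angles` = 15 anti-aliased line kernels at
   angles iπ/15, length 8 μm, width 1 px, each normalised to zero mean and
   unit norm (a constant image gives exactly zero response). The default
   length suits the default 11 μm spacing; as a guideline the kernel
   should stay below ~0.7 × the expected spacing, so tighter lattices
   call for `line_length_um` ≈ 5–6.
3. **Correlation and elongation.** The locally mean-subtracted image (box
   window of three kernel side lengths, removing the slow background of
   the diffusion gradient) is cross-correlated with every kernel
   (FFT-based, symmetric boundary padding); the per-angle maps are summed.
   A second pass correlates each per-angle map with a line kernel of twice
   the length at the same angle: straight bundles reinforce only their own
   orientation, junction pixels are amplified in every term of the sum.
   Sum (not max) is used to combine angles precisely because junctions
   respond at many angles.
4. **Segmentation.** Gaussian blur (σ = 2 μm) of the combined map,
   binarisation at the 0.6 quantile of its positive values, erosion with a
   2 px disc, connected components ≥ 4 px, response-weighted sub-pixel
   centroids (spacing statistics need better-than-pixel accuracy at
   0.37 μm/px), score = component peak.
5. **Structural vetoes.** A candidate must show at least two distinct
   strong orientation runs (≥ 0.35 of the profile peak) in its per-angle
   profile: free bundle ends and bright mid-sections show one, genuine
   junctions two or more. Candidates within half a line length of the
   frame border are discarded — there the correlation support leaves the
   image and the symmetric padding folds bundles into spurious V-shaped
   pseudo-junctions.
6. **Merging.** Single-linkage clustering with transitive closure merges
   detections at pairwise distance strictly below 3 μm into score-weighted
   centroids, repeated to a fixed point (idempotent); pairs at exactly
   3 μm stay separate.

The 0.6 threshold quantile was set by measuring interior precision/recall
on synthetic fields: the operating plateau spans roughly 0.5–0.8, and the
value sits at its lower edge where recall saturates. Exact 90°-rotation
equivariance of the detector holds only when the angle bank is closed
under that rotation (even `n_angles`); with the default 15 angles the
equivariance is approximate.

## Network statistics

* **Triangulation.** `scipy.spatial.Delaunay` after a deterministic
  symbolic perturbation (per-index hash offsets of ~10⁻⁹ × diameter) so
  cocircular degeneracies resolve reproducibly; edge lengths use the
  unperturbed coordinates. Fewer than three points or collinear input
  raises a degenerate-input error.
* **Edge filter.** Lengths outside [3, 20] μm are discarded; the interval
  is closed at both ends (the merge rule is strictly-less-than 3 μm, so an
  edge of exactly 3 μm is legitimate). Counts of short- and long-rejected
  edges are logged so the filter is auditable.
* **Degrees.** Counted over retained edges (raw Delaunay degrees are
  available via a flag); statistics are taken over vertices farther than
  `boundary_margin_um` (default 20 μm, the long-edge cutoff) from the
  border — a geometric margin is reproducible, whereas dropping low-degree
  vertices post hoc would be circular. The median is reported (on these
  integer counts it lands on an integer); IQR uses linear-interpolation
  quantiles. Multiple strands between the same pair count as one
  neighbour relation: the triangulation is over points, not strands.
* **Density and hexagon model.** Density is the raw count over the full
  frame area scaled to 1 mm², with no edge correction; the border band in
  which junctions cannot be detected biases density low by a factor that
  shrinks with field size (≈ 4% at 750 μm, larger for small crops). The
  hexagon correlation is observed density / N(mean spacing), with
  N(a) = (1000/a)·(1000/((√3/2)a)).
* **Tile bootstrap.** √n × √n equal tiles (n ∈ {16, 64}); vertices are
  partitioned by position (detection is not re-run per tile). A tile needs
  ≥ 4 vertices and ≥ 1 retained edge to contribute; the valid tile means
  are resampled with replacement B ≥ 100 times (default 1000) and a
  Gaussian KDE with Silverman bandwidth summarises the bootstrap
  distribution on a grid spanning ±4 bandwidths (its integral is 1 to
  better than 10⁻³). Zero-spread inputs produce an explicit narrow-spike
  density instead of a singular KDE. Fewer than two valid tiles yields a
  report flagged `insufficient_data`.

## Determinism and degenerate inputs

All randomness (layout, rendering, noise, bootstrap) flows from explicit
seeds; there is no global random state, and identical configuration
reproduces byte-identical statistics. Empty detections propagate as
flagged empty results (CLI exit code 3), distinct from configuration
errors (exit code 2) and crashes.

## Problem sizes

The validation suite runs the full pipeline once per session on the
750 × 750 μm / 2048 px reference field (about twenty seconds of
computation) and uses 100–300 μm fields for unit-level checks; the
acceptance script analyses the reference field, its central 250 μm crop,
and the ground-truth point set. These sizes match the smallest field of
view the statistics are designed for while keeping a full run in the
minutes range on a single CPU.

## Known limitations

* Detection parameters assume a spacing near the 9–13 μm regime; fields
  far outside it need rescaled kernel length and blur.
* The border veto plus merge step make density systematically low on
  small crops; comparisons across magnifications should use fields of
  similar size or interior-restricted counts.
* The generator's bundles are straight; strongly curved or flow-distorted
  ("pre-aster") structures are outside both the generator and the
  detector's design envelope.
* The hexagon correlation conflates packing regularity with detection
  completeness: missed vertices lower it even on a perfect lattice.
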