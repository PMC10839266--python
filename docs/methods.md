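# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the pipeline. Units are μm for lengths and nm only where
stated; intensities are arbitrary units (no photon model is assumed).

## Dendrite surface model and association

A reconstruction is a single-rooted tree of nodes (soma, shaft, spine) with
per-node radii, read from 7-column SWC (type codes 1 = soma, 3 = dendritic
shaft, 5 = spine). The dendrite surface is modelled as a union of tapered
frusta around skeleton segments: the distance from a query point to the
surface is its distance to the nearest segment centerline minus the radius
linearly interpolated at the closest-centerline parameter, floored at zero.
This matches the semantics of filament-based surface reconstructions without
requiring meshes. Two consequences are worth noting:

- The function is not globally 1-Lipschitz on tapered segments (the taper
  slope adds up to √(1+(Δr/L)²) to the Lipschitz constant); on uniform-radius
  cables it is exactly 1-Lipschitz, which is how the property is tested.
- Spine neck segments contribute only their portion *outside* the parent
  shaft surface, as thin frusta of the spine's own radius. If necks instead
  inherited the shaft radius at their proximal end, the neck frustum would
  bulge through the shaft surface and claim nearby shaft-surface points as
  spine-associated (≈6% misclassification on synthetic cells; <1% with the
  clipped model).

A punctum is dendrite-associated when its center is strictly closer than the
association threshold (default 0.5 μm) to the surface; boundary behaviour is
a strict `<` (deterministic; the boundary is a measure-zero event for real
data). Associated puncta are shaft- or spine-associated by the compartment of
the globally nearest segment; exact shaft/spine ties resolve to spine (the
rarer class, deterministic). Distances are computed punctum-center to
surface; spot radii are not subtracted. Spine-associated puncta are
attributed to the branch their spine attaches to for domain binning.

Branches are maximal unbranched shaft paths between the soma, branch points
and tips. A branch is *primary* when its proximal end attaches to the soma and
*terminal* when its distal end is a tip; a branch that is both is labelled
primary (soma attachment is the stronger, explicitly defined criterion).
Branch order starts at 1 for soma-adjacent branches and increments by exactly
one per branch point; spines never split branches or increment order.
Domains (basal / proximal apical / distal apical / apical tuft) come from an
explicit per-branch annotation for real reconstructions (domain assignment on
real data is a judgement made from overview stacks) or, for synthetic trees,
from path-distance thresholds along the apical trunk (defaults 100 and
250 μm) with non-apical branches basal regardless of distance.

Densities are associated-punctum counts per μm of category cable length
(area/volume denominators are deliberately not emitted; length is the one
denominator that is well defined for a skeleton). Normalized density divides
each category's density by the mean over that cell's categories, making the
per-cell mean exactly 1; cells with all-zero densities are flagged and
excluded from summaries. Groups with fewer than 5 associated puncta are
flagged low-n (a reporting aid, not a filter).

## Spot detection

Preprocessing mirrors the standard super-resolution workflow: stacks deeper
than 30 μm are split into the fewest equal sub-stacks each strictly under
30 μm (with recorded z-offsets so coordinates stay global); background at a
1 μm scale is estimated with a wide Gaussian and subtracted with clipping at
zero; per-plane brightness is equalised by matching each plane's 99.5th
percentile to the median of that statistic across planes (a monotone,
per-plane gain). The percentile-matching statistic is a design choice — the
commercial tools' internal rules are unpublished.

Detection is multiscale anisotropic Laplacian-of-Gaussian: σ per axis is the
expected radius/√3 (the scale at which a matched Gaussian blob maximises the
scale-normalised response), at three scale factors (0.75, 1.0, 1.5) when
size-adaptive detection is on. Each scale's response is z-scored by its own
robust statistics (median, 1.4826·MAD) before scales are combined by max;
without per-scale normalisation the small-scale response to white noise is
several-fold broader and floods the combination. Calibration uses only the
top 10 μm of the stack, then applies stack-wide, so depth-dependent intensity
gradients cannot bias the cutoff. The floor default k = 10 robust-σ sits
above the extreme-value range of the preprocessed noise field (zero-clipping
and plane equalisation stretch the robust-z noise tail to ≈7–8 over typical
stack volumes) while matched-scale responses of nominal-size puncta reach
z ≳ 20 even at SNR 5. Candidates are local maxima over a one-expected-radius
footprint; non-maximum suppression removes detections within one expected
radius (anisotropic metric) of a stronger one; centers are intensity-weighted
centroids over a one-radius window, reported in global μm.

## Perisynaptic analysis

Minimum distances are exact: chunked exhaustive Euclidean search over target
centers (the problem sizes here — thousands of puncta — never justify
approximate indexing), with ties going to the lowest target id. The
three-channel analysis treats one channel as reference and reports its
nearest-partner distance in each other channel; a reference punctum passes
the synaptic filter when both partner distances are strictly below the
synaptic radius (default 1 μm). The pairwise triangle is deliberately not
enforced — the filter is per-reference, matching per-marker tabulation.
Scatter output is a seeded uniform subsample without replacement (default
n = 1000) of reference rows; violin summaries (mean, 25%/75% quartiles) are
computed per channel pair on a seeded subsample (default n = 300) of
filter-passing rows. Changing the seed changes only subsample membership,
never the underlying full-population statistics. Overlap fractions are
computed on voxel masks (above per-channel thresholds chosen independently):
for the ordered pair (A, B), 100·|A∧B|/|A|.

Distance summaries support both per-punctum pooling and per-animal averaging;
which unit enters an SEM is stated in every output because published summaries
legitimately mix both.

## Synthetic data

The generators define the study conditions for every test; their defaults
copy the quantitative regimes the analyses are meant to resolve, so recovery
tests are interpretable against figure-scale values:

- **Tree**: soma at the origin; a 300 μm apical trunk with 8 oblique branches
  concentrated on the lower trunk (as in stratum radiatum) and a 6-branch
  terminal tuft; 4 bifurcating basal dendrites; shaft radius 0.4 μm; spines
  as a 1/μm Poisson process along all shaft cable (1 μm necks, 0.15 μm
  heads). Node spacing 2 μm.
- **Puncta**: per-domain Poisson placement along cable (basal and proximal
  apical 0.4/μm, distal apical 0.8/μm, tuft 1.2/μm — a 3× tuft-to-proximal
  ratio); each dendritic punctum relocates to a random spine of its branch
  with probability 0.65; all placements sit exactly on the frustum surface
  before isotropic Gaussian jitter (σ = 0.05 μm, a localization-error scale);
  background false positives at 5·10⁻⁵/μm³ of bounding volume.
- **Triplets**: centers on a 4 μm grid (so nearest-neighbour queries always
  resolve within-triplet), uniformly oriented axes, pre/post separation
  N(0.666, 0.05) μm, perisynaptic marker on the perpendicular bisector at a
  distance N(0.69, 0.05) μm from both, with an optional asymmetry shift
  toward the presynaptic marker (default 0).
- **Rendering**: each punctum is an anisotropic Gaussian (σ = radius/√3) on a
  calibrated voxel grid (default 0.043/0.185 μm), plus Gaussian read noise
  with σ = peak/SNR; a 2 GB guard rejects oversized volumes.
- **smFISH fields**: nuclei by dart-throwing with 7 μm minimum spacing
  (> 2× the 2.5 μm transcript scatter radius, so nearest-nucleus assignment
  is unambiguous by construction); probe-positive cells draw zero-truncated
  Poisson transcript counts (neurons mean 13.2, non-neuronal 2.8);
  probe-positive neuron fractions per stratum range from 63% (deep proximal)
  to 33% (superficial distal); with probability 0.15 a cell's co-located
  transcripts merge into a cluster of up to 6, whose area is the sum of
  single-punctum areas (0.3 ± 0.02 μm²).

All distributional choices (Poisson placements, Gaussian jitter, the truncated
counts) are modelling choices of this generator; no generative model was
measured from tissue. What passing tests show is therefore that the
*measurement machinery* is correct and calibrated — not that real tissue
matches these regimes. Features of real data the generator does not emulate:
optical aberrations and bleed-through, anisotropic and depth-dependent PSFs,
autofluorescence structure, spine-shape diversity, and spatially correlated
cell classes.

## smFISH quantification

Survey rectangles are 600 px wide (132 μm at the default 0.22 μm/px, which is
back-derived from that printed equivalence) and split into deep and
superficial halves at the midline along a configurable depth axis. Transcript
puncta are assigned to the nearest nucleus within a capture radius (default
8 μm, a typical somatic extent — a pipeline parameter, not a measured value);
ties go to the lower cell id. A punctum whose area exceeds 1.5× the mean
isolated punctum is treated as a merged cluster and counted as
round(area/mean single area), floored at 1; the mean single area comes from
config or, by default, the median punctum area (robust to the cluster tail).
Probe positivity is ≥1 assigned punctum (configurable); NeuN positivity is a
per-cell flag in table mode or a mean-signal threshold in image mode.
Percentages are per (region, layer) stratum and sum to 100 by construction;
per-group expression is total probe puncta divided by probe-positive cells in
the group.

## Statistics

Two groups: Mann-Whitney rank-sum, exact null when both n ≤ 8 and no
cross-group ties, otherwise the normal approximation with tie correction;
identical constant groups return p = 1 rather than erroring. Three or more
groups: one-way ANOVA with Tukey HSD pairwise comparisons. Stars are a pure
function of p (*p<0.05, **p<0.01, ***p<0.001). SEM = SD/√n with the n-unit
(cells vs animals) stated explicitly in every output.

The firing-pattern utility classifies a minimal-suprathreshold-step spike
train as early-bursting when more than two spikes occur at step onset —
within a 60 ms window with consecutive inter-spike intervals ≤ 15 ms. The
window and ISI bound are this package's operationalisation of an onset burst;
only the ">2 action potentials" count is a published criterion. Exactly two
onset spikes classify as regular (late-bursting) per that rule.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale sizes chosen to make the
statistical assertions sharp: 500–1500 triplets, ~1500 placed puncta on a
~2000 μm cell, 200 rendered spots at SNR 5, 200 cells per smFISH stratum,
50–100 seeded replicates for recovery rates, 1000 null replicates for ANOVA
calibration. Every stochastic step draws from `numpy.random.default_rng`
seeded explicitly; generators are bit-reproducible given (config, seed), and
every CLI stage writes byte-identical output on re-run (fixed float
formatting, content-hash provenance headers, no timestamps).

## Known limitations

- The surface model is a frustum union; it underestimates distance inside
  concave joints between consecutive segments and has the Lipschitz caveat
  above.
- Detector thresholds assume roughly stationary noise within the calibration
  slab; structured backgrounds (blood vessels, tissue edges) are not modelled.
- Cluster counting assumes area scales linearly with transcript number up to
  k ≈ 6; beyond that, saturation in real images breaks the proportionality.
- The equidistance analysis measures marker *centers*; chromatic offsets
  between channels are not corrected and would add a constant bias to
  cross-channel distances.
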