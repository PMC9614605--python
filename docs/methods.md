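# Methods

## The leaf-counting model

The pipeline rests on a one-to-one hypothesis: every rice leaf blade has
exactly one visible tip in a top-view image, so the number of detected
tips equals the number of leaves (NL). Leaves hidden near the culm
sheath are occluded for any camera and are not attempted; the detector
therefore estimates *visible* leaf count, which is also what the
annotation convention it ingests (small fixed-size square boxes centred
on tips) encodes.

The classical detection chain is

1. **Segmentation.** Excess green, ExG = 2G − R − B, thresholded at 0;
   connected components below `min_area_px` (default 32) are discarded
   as sensor noise. ExG is the standard vegetation index for separating
   green canopy from a non-green background; it needs no training.
2. **Skeletonization.** Morphological thinning to a one-pixel-wide,
   8-connected medial skeleton. Thinning can leave fully set 2×2 blocks
   at staircase turns; a topology-safe post-pass deletes simple pixels
   (single 8-connected neighbour component, at least one background
   4-neighbour, not an endpoint) until the skeleton is irreducible. A
   2×2 block at the crossing of two diagonal strokes is irreducible —
   no pixel in it is simple — and is accepted as correct medial
   structure; the 1-px-wide contract check rejects only reducible
   blocks.
3. **Endpoint extraction.** A tip is a skeleton pixel with exactly one
   8-neighbour. Terminal branches shorter than `prune_len_px` are
   erased first; surviving endpoints within `merge_radius_px` of each
   other *and* geodesically close on the skeleton are merged to their
   centroid; each survivor becomes a square box of edge `box_size_px`
   (default 16 px, matching the annotation convention) with
   confidence 1.0.

### Detector parameters

| parameter | default | units | role |
|---|---|---|---|
| `exg_threshold` | 0 | ExG units | plant/background split |
| `min_area_px` | 32 | px | noise-speck removal |
| `prune_len_px` | 3 | px | spur (thinning-artifact) removal |
| `merge_radius_px` | `box_size_px`/2 = 8 | px | duplicate-endpoint merging |
| `culm_exclusion_px` | 0 (off) | px | drop endpoints near the canopy centroid |
| `box_size_px` | 16 | px | emitted tip-box edge |

Two of these deserve their rationale spelled out.

*Spur pruning at 3 px.* Thinning artifacts on ExG masks are one- to
three-pixel boundary bumps; pruning at that scale removes them while
keeping real blade ends. Longer terminal branches in a crossing canopy
are overwhelmingly *real* leaf tips whose blade crosses another blade
shortly before its end; pruning at, say, 8 px deletes several true tips
per dense plant and produces a systematic undercount out of proportion
to any artifact it removes. The parameter remains exposed for noisier
imagery.

*Geodesic merging.* Duplicate detections of one physical tip (e.g. a
forked thinning artifact) are close both in the plane and along the
skeleton. Two distinct tips of different blades can also land within the
merge radius in a dense canopy, but their skeleton branches connect only
through the culm, many blade-lengths away. Merging therefore requires
both Euclidean proximity (< `merge_radius_px`) and geodesic proximity
(within 3× that radius in 8-connected steps). A plain Euclidean merge
would fuse genuinely distinct tips that any sane non-maximum suppression
would keep apart.

## i-traits

From the tip coordinates of one image: NL (count), the convex hull of
the tip centres and its area CHA (monotone-chain hull, shoelace area;
degenerate one-point/collinear sets give CHA = 0 rather than an error),
the axis-aligned bounding box area BBA with width (x-extent) and length
(y-extent), PAR = width/length, and NLPCHA = NL/CHA. From side-view
masks: plant height (baseline row minus topmost foreground row) and the
plant elongation rate PER, the least-squares slope of height against
time snap. All pixel quantities are scaled by a required scene constant
`cm_per_pixel` (default 0.25 cm/px for the 608 × 608 synthetic scene);
areas scale by its square.

The hull is computed from tip centres, not the mask contour, because the
tip set is what the detection stage guarantees; degenerate hulls flag
NLPCHA as undefined (NaN) instead of dividing by zero. PAR orientation
(width = x, length = y) is a documented convention — for a top view the
two are interchangeable up to the reciprocal.

## The LER stress-tolerance index

Leaf emergence between drought onset (TS1) and peak stress (TS4) is the
drought-responsive signal: Δnl = NL(TS4) − NL(TS1) per treatment, and

    LER = 100 × Δnlᴰ / Δnlᶜ,  clipped into [0, 100].

TS1 is shared between treatments (drought begins at TS1), giving the
deltas a common baseline. A zero control delta leaves the index
undefined (flagged NaN, never a crash); ratios above 100 — drought
out-emerging control, which happens for fully tolerant genotypes plus
integer noise — are clipped, with the raw ratio logged. Clipping, rather
than rescaling the whole distribution, is the simplest reading of
"scaled between 0 and 100%" and keeps per-genotype values comparable
across panels.

Classification bands: sensitive < 60 ≤ moderate < 75 ≤ tolerant. The
band descriptions in the source literature overlap (a tolerant threshold
at 75%, a sensitive bound at 60%, and a separate light-tolerance range
spanning 65–85% that straddles the tolerant threshold), so this package
adopts the non-overlapping three-band partition — every defined LER maps
to exactly one class, and the boundary values 60 and 75 belong to the
upper band.

Biomass accounting: BMW = StW + LW; stem% = 100·StW/BMW and
leaf% = 100·LW/BMW sum to 100 exactly whenever BMW > 0, and are
NaN-flagged at BMW = 0.

## The synthetic phenome

The generator emulates the study conditions the pipeline is meant for: a
diverse genotype panel (round-robin erect/semi-erect/spread/open
architectures; drought-emergence factors sweeping [0.2, 1.0] so all
tolerance classes occur), five imaging time snaps, and two treatments.

**Plants.** Blades radiate from a central culm disk with golden-angle
phyllotaxis (azimuth i·137.5° plus 0.03 rad Gaussian noise — phyllotaxis
is regular; tiller placement perturbs blade azimuths by only a few
degrees). Per-leaf geometry is indexed by leaf number, not time snap, so
leaves persist as the plant grows: tip sets at later snaps extend
earlier ones and NL/BBA trajectories are non-decreasing by construction.
Radial extent is `leaf_len_px × (1 − 0.5·erectness)`, growing 6% per
snap, with ±18% per-leaf length variation; blades are tapered
quadratic-Bézier polygons whose centreline is drawn through to the exact
tip pixel (the ground-truth tip always lies on rendered plant pixels).
Drought multiplies blade width by (1 − rolling_factor) — leaf rolling —
and multiplies the emergence rate by the genotype's
`drought_emergence_factor`, the programmed ground truth the LER index
recovers. Leaf counts follow per-interval arithmetic:
count(TS) = base + (TS − 1)·round(rate·factor), with round-half-up so
trajectories are monotone and platform-stable.

**Colours.** Pre-noise, plant pixels satisfy ExG = +190 and background
ExG = −30, so segmentation has an exact programmed answer (mask-vs-
silhouette IoU ≈ 1); Gaussian pixel noise (sd 2) is added afterwards.

**Regimes.** Sparse = erect/semi-erect plants with ≤ 15 leaves, where
tip separation ≥ `box_size_px`/2 is enforced by azimuth re-jittering;
dense = 60–100 leaves with no separation guarantee, so blades overlap
and tips can be absorbed into crossings — the regime where counting is
genuinely hard.

**Destructive records.** Leaf weight is 0.35 g per counted leaf with
10% multiplicative noise (so NL and LW correlate at r ≈ 0.9 across a
panel, mirroring the strong published leaf-number/leaf-weight
association); stem weight is drawn so the leaf share of above-ground
biomass stays within 30–70%, centred near 45%; root weight and
leaf/stem areas scale with biomass (ratios 1.14, 20 cm²/g, 4.2 cm²/g,
chosen to land at the published panel means for a ~40-leaf plant).

**What the generator does not emulate** — and hence what passing tests
do not show about real imagery: photorealistic texture, specular and
shadow structure, soil/mulch clutter, tillers as distinct organs,
perspective distortion, side views (heights are emitted numerically),
and real rice phyllotaxis across multiple tillers. Detector accuracies
measured here quantify the geometry of overlapping-blade counting, not
robustness to real-world radiometry.

## Evaluation protocol

"Counting accuracy" is 100 × (1 − |NLpred − NLtrue|/NLtrue), undefined
when NLtrue = 0. Because false positives and false negatives can cancel
in a pure count, precision and recall over centre-matched pairs are
reported alongside: greedy matching in ascending centre distance, a pair
matches iff the distance ≤ τ (default the ground-truth box edge, 16 px),
each prediction and each ground-truth tip used at most once. A Hungarian
maximum-cardinality assignment is available (`optimal=True`) for audits;
on τ-separated sets the two agree.

Headline numbers at the package defaults (608×608 scenes, 50 plants per
suite, reproduced by `scripts/acceptance.py` and the acceptance tests):
mean counting accuracy 100% in the sparse regime and ≈ 87–88% in the
dense regime, where the residual error is dominated by tips absorbed
into blade crossings — a genuine property of dense canopies, not of the
detector's post-processing.

## Statistics and clustering

Descriptive statistics use the sample standard deviation (n − 1) and
CV% = 100·σ/μ (NaN at μ = 0); exports round to 2 decimals, internal
values keep full precision. Correlations are Pearson product-moment.
Genotype clustering standardises each trait column (zero mean, unit
variance; constant columns left at zero), computes Euclidean distances
and agglomerates with average linkage by default (complete and single
are options); the dendrogram exports to Newick with branch lengths equal
to merge-height differences. For tolerance grouping, the drought-response
features (LER and the emergence deficit Δnlᶜ − Δnlᴰ) separate programmed
tolerant/sensitive panels exactly at k = 2; absolute leaf counts are
deliberately excluded there because plant size varies within tolerance
classes and swamps the response signal.

## Numerical choices and degenerate inputs

- Round-half-up (`floor(x + 0.5)`) everywhere integers are derived from
  rates, avoiding banker's-rounding platform surprises.
- Undefined quantities (PAR at zero length, NLPCHA at zero hull, LER at
  zero control delta, CV at zero mean, count accuracy with empty truth)
  are NaN-flagged and propagate as "undefined" classes, never raised.
- Hulls of < 3 distinct or collinear points return the extreme
  pair/single point with zero area.
- Tips pushed outside the canvas by long blades are clamped to the
  border, preserving one-tip-per-leaf exactly.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; rendering is bit-identical for identical
  (genotype, treatment, snap, scene, seed), and the pipeline derives
  per-stage seeds from the global seed and stage name.
- Desk-scale problem sizes: 608 × 608 px scenes, 50-plant evaluation
  suites, panels of 4–110 genotypes — chosen so a full run is a
  laptop-scale computation.

## Known limitations

- The detector cannot see tips occluded at the culm or absorbed into
  blade crossings; the dense-regime accuracy ceiling (~90% raw) is
  structural for any endpoint-based method.
- LER needs a non-degenerate control delta; genotypes that emit no new
  leaves under control in the window are flagged undefined.
- The "compactness" canopy descriptor sometimes mentioned alongside
  these traits has no agreed definition and is not computed.
- Newick export encodes the merge history; it is a dendrogram, not a
  phylogeny, and branch lengths are linkage heights in standardised
  trait units.
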