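# Methods

This note records how the extraction pipeline and its evaluation protocol
work, the numerical choices behind them, and what the synthetic
experiments do and do not demonstrate.

## Pipeline model

An extraction pipeline is an ordered sequence of named steps over four
stages — preprocessing, segmentation, graph detection, graph filtering —
with at most one segmentation and one detection step. Everything is
deterministic: the only randomized algorithm (GrabCut's mixture-model
initialization) takes an explicit seed. Coordinates follow one
convention throughout: images are `(row, col)` arrays, vertex positions
are `(x, y) = (col, row)`, foreground is white (bright), with an
`invert` flag on every segmentation method for dark-on-light networks.

### Segmentation

* **Otsu**: global histogram threshold maximizing between-class
  variance; constant images give empty foreground.
* **Adaptive**: a pixel is foreground when it exceeds its local
  block-window mean (reflect-padded) by more than `offset`
  (default block 51, offset 4 at the 1024 px scale). Defined this way,
  a constant image yields an empty mask and any smooth additive
  background ramp leaves the mask unchanged — the property the
  gradient-condition experiment isolates.
* **Guided watershed**: compact watershed on the morphological gradient
  of the 5×5-blurred luma, flooded from marker seeds, with a quadratic
  distance-to-seed penalty (compactness 0.3). The compactness term is
  load-bearing: it makes each basin local to its own seeds, so marker
  strategies that seed every stroke (erosion of the threshold guess;
  adaptive guess) recover essentially all stroke pixels, while the
  distance-transform strategy — whose sure-foreground is only the region
  where the EDT reaches 0.7 of its global maximum, i.e. the widest cores
  — loses every stroke it failed to seed. Plain (non-compact) flooding
  would let the foreground basin travel arbitrarily far through the
  connected network and would hide exactly the marker-quality
  differences the method comparison is about.
* **Marker strategies**: erosion/dilation use a 3×3 structuring element
  with default 1 iteration, chosen so that the thinnest strokes in the
  evaluation (3 px) keep a non-empty sure-foreground core; the
  distance-transform fraction default is 0.7. An empty seed class raises
  a degenerate-marker error naming the offending parameters.
* **GrabCut**: iterative graph-cut segmentation — full-covariance
  Gaussian mixtures (3 components per class, fitted on up to 20 000
  subsampled pixels) for the data term, the standard contrast-sensitive
  8-neighbour smoothness term (γ = 50, β from the mean squared
  neighbour difference), minimum s-t cut via igraph. Sure pixels stay
  pinned; iteration stops early at a fixed point.
* **external_binary** accepts segmentations from third-party tools, so
  the pipeline can start directly at graph detection.

### Thinning

Guo–Hall two-subiteration thinning, fully vectorized over boolean
arrays, iterated to a fixed point (hence idempotent). The image is
implicitly padded with background, so neighbourhood logic at the border
is well defined — a consequence is that background pockets separated
from the outside only across the image border count as outside
background when assessing topology preservation. The deletion conditions
were derived independently from the published two-subiteration rules;
the test suite checks bitwise agreement with scikit-image's LUT-based
implementation of the same algorithm as an independent reference.

### Graph detection

A skeleton pixel becomes a node if its removal leaves exactly one
(endpoint) or at least three (junction) 4-connected white components
among its eight neighbours; since the eight ring cells in cyclic order
are consecutively 4-adjacent, this is a cyclic-run count, precomputed as
a 256-entry lookup table. Node-free components (perfect rings, isolated
pixels) get an anchor node at their lexicographically smallest pixel so
they remain representable.

Edges come from a simultaneous breadth-first search: each branch of each
node — a 4-connected run of its white non-node neighbours — seeds one
uniquely numbered queue; queues are serviced round-robin in ascending
label order (labels assigned in row-major order), one pixel per step.
A dequeued pixel already marked by another label is a collision and
produces the edge joining the two owning nodes, with the path
reconstructed from BFS parent pointers; the colliding labels stop.
Numerical details that the colloquial description leaves open, fixed
here:

* One queue per *branch* rather than per neighbouring pixel: two seeds
  of the same branch would race each other and manufacture spurious
  collisions.
* Stored paths run node pixel to node pixel, so `edge_length(path)`
  equals the stored length, and a straight n-pixel node-to-node path
  measures exactly n−1 units. Junction pixels necessarily belong to
  several paths; every non-node pixel belongs to at most one.
* Self-loop collisions between two branches of the *same* node that
  touch right next to it are 8-adjacency artifacts, not loops; the
  shortest such collision measures 2+√2 ≈ 3.41 units, so self-loops
  under `min_loop_length = 5` units are discarded (and the labels keep
  going). Genuine anchored rings are far longer and survive. Same-label
  collisions are resolved with a budget-bounded lowest-common-ancestor
  test: short cycles are BFS bookkeeping, long ones are real loops.
* Directly 8-adjacent node pixels yield an edge without a BFS.

Lengths count 1 per axial and √2 per diagonal step. The per-pixel
diameter at a path pixel is `2 · max(EDT over its 3×3 neighbourhood)
− 0.25`, summarized per edge by the median and the population variance.
The local maximum compensates the skeleton of digitized oblique strokes
sitting up to one pixel off the true centre line, and the constant
offsets the EDT measuring to background pixel *centres* rather than to
the stroke boundary; both constants were calibrated once on rendered
strokes of known width (3–15 px, several orientations; worst-case error
0.96 px, mean ≈ 0.35 px). A plain `2 · EDT` lookup errs by up to 1.5 px
on diagonal strokes.

`merge_close_nodes` collapses clusters (single-linkage, pairwise
distance ≤ radius) to their rounded centroid, dropping self-edges the
collapse creates when they are no longer than the radius. The default
radius is 0 (off) in the shipped pipeline files; the evaluation
pipelines use 15 px (below).

### Graph filters

Filters operate purely on the graph — the segmentation and skeleton are
never repaired. All are idempotent, and surviving vertices keep their
coordinates. The cycle filter removes exactly the bridges (self-loops
and parallel pairs count as cycles) and then isolated vertices, leaving
a bridge-free graph of minimum degree 2. Degree-2 smoothing contracts
eligible vertices in ascending-id passes to a fixed point, summing
lengths exactly and recomputing width statistics from the concatenated
per-pixel diameters kept on each edge (medians do not compose; when
diameters are unavailable a length-weighted mean is the documented
fallback). Tie-breaks (largest component by vertex count, then edge
count, then smallest lexicographic coordinate) make every filter
deterministic.

## Synthetic evaluation protocol

The protocol quantifies per-segmentation-method extraction quality on
images whose ground truth is known exactly because the images are drawn
from the graphs.

**Generator.** Uniform random points with a minimum-separation
constraint (90 px at 1024², dart throwing), Delaunay triangulation,
deterministic pruning to degree ≤ 4 and ≥ 35° between incident edges,
then random connectivity-preserving thinning (probability 0.3) for
topological diversity, keeping degree ≥ 3 where possible. Integer edge
widths are uniform on 3–11 px. Defaults: 30 vertices on a 1024×1024
canvas with a 60 px margin. Degrees 1–2 are avoided because a drawn
degree-2 vertex produces neither a junction nor an endpoint in the
image — no image-based method could recover it; the wide junction
angles reflect the near-120° junctions of real plasmodial networks.
Truth edge lengths use the chain metric of the digitized segment, the
same metric the tracer measures.

**Distillation.** Ground truths are not the raw generated graphs but
the generated graphs passed four times through render → extract
(Otsu → Guo–Hall → detect with merge radius 15). This expresses the
truth in the extractor's native geometry — junction vertices at
skeleton bifurcations (a junction of wide strokes splits into nearby
low-degree nodes, which the merge step collapses), traced pixel paths,
measured widths — exactly as a truth set obtained by running the
extractor on real images would be. Rendering such a truth along its
pixel paths and re-extracting is then a near fixed point, so the scores
measure what the protocol is after: degradation caused by image
distortions, not the display-limited localisation of ideal junction
points (a junction of strokes at angle θ and width w is drawn as a
merged wedge whose skeleton bifurcation sits up to w/(2·tan(θ/2)) —
tens of pixels — from the ideal crossing; no method can do better from
the image alone). Raw truths remain available
(`distill_iterations=0`).

**Rendering.** Strokes are drawn as the set of pixels within
`(w − 0.2)/2` of the segment (or of the traced pixel path when one is
attached), composed with per-pixel maximum so bright strokes dominate
crossings; vertices are disks of the largest incident width; no
anti-aliasing. Terminal (degree-1) disks are enlarged by 2 px: a cap
drawn flush with the stroke thins to a skeleton that stops up to
6 units short of the endpoint, while the bulb makes the skeleton
terminate at the endpoint, so the drawing preserves edge lengths
(worst-case length error 0.83 units over widths 3–15 at four
orientations). Defaults: foreground 220, background 30.

**Distortions.** `brightness` redraws each edge at a uniform random
intensity in [60, 255] (local contrast varies; vertex disks take their
brightest incident edge). `gradient` replaces background pixels with a
left-to-right linear ramp from 0 to 160, leaving foreground untouched.
`blur` applies a global Gaussian blur, σ = 2 (strokes then measure
wider — a real effect, not an artifact). The distortion magnitudes were
chosen once so that the four conditions qualitatively separate the
methods (adaptive thresholding immune to the gradient; global
thresholding degraded; the distance-transform watershed collapsing) and
are recorded here; they are not fitted quantities.

**Matching and scores.** Vertices of truth A and extraction B are
matched by a minimum-total-distance optimal assignment restricted to
pairs within 10 px (at the 1024 px scale; scale the radius with the
image). Edges correspond when both endpoint pairs match; parallel edges
pair up after sorting by length and width. The similarity score is

    s = ½·S_V + ½·S_E
    S_V = Σ_matched (1 − d/radius) / max(|V_A|, |V_B|)
    S_E = Σ_matched ½·[c(ℓ_A, ℓ_B) + c(w_A, w_B)] / max(|E_A|, |E_B|)

with `c(x, y) = 1 − |x−y|/max(x, y)` and `c(0,0) = 1`; two empty graphs
score 1 by convention. The measure is symmetric, equals 1 exactly at
self-comparison, 0 without any viable correspondence, and decreases
monotonically as positions, lengths, widths or the matched fraction
degrade. The construction is this package's own and version-stamped
(`netextract-s-1`); absolute scores are comparable only within a
measure version. Sensitivity and
precision pool matched/unmatched vertices and edges into single
TP/FN/FP counts (true negatives are undefined in this setting).
Pipeline failures on an image (e.g. degenerate markers) score as an
empty extraction rather than aborting the evaluation.

**Problem sizes.** The shipped acceptance computation uses 50 images per
condition (30-vertex graphs, 1024²) for the headline means, and 15
images for the method-ordering comparison under the gradient condition,
where the huge foreground blobs that global thresholding produces make
thinning substantially slower; the ordering gaps are several tenths, so
15 images resolve them comfortably.

## What passing tests show — and what they do not

The synthetic renders are clean two-level images of straight-edged
planar graphs. They demonstrate that thinning, node detection, tracing
and the weight measurements are essentially exact in the extractor's own
geometry, and they reproduce the relative robustness ordering of the
segmentation methods under brightness variation, background gradients
and blur. They do not contain sensor noise, texture, uneven
illumination beyond a linear ramp, curvilinear vein paths, or
out-of-focus structure; absolute scores on real micrographs will be
lower, and the method ordering — not the absolute numbers — is the
transferable result.

## Known limitations

* The node criterion sees single pixels only, so vertex degree is
  capped at 4 before merging; genuinely higher-degree junctions appear
  as merged clusters.
* A degree-2 bend of the true network is invisible to the criterion by
  construction.
* Two branches of one node that leave in directions 45° apart share one
  4-connected run and are traced as a single branch until they separate.
* Large solid foreground regions produce skeleton artifacts whose shape
  depends on boundary noise; the graph filters, not skeleton repair,
  are the intended cleanup.
* GrabCut's min-cut on megapixel images is slow (minutes); it is
  practical at the few-hundred-pixel scale or on crops.
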