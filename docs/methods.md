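# Methods

`voromorph` maps every object boundary in a segmented image onto a single
generalized Voronoi graph and derives morphometric features from it. This
note records the model, the conventions and tolerances, and the design
choices made where the construction was genuinely open.

## Boundary extraction

Pixel centres sit at integer coordinates `(x=column, y=row)`; the image
domain is `[-0.5, W-0.5] x [-0.5, H-0.5]`.

**Binary masks.** Boundaries are traced along the half-pixel border
between foreground and background pixels rather than through pixel
centres, so a one-pixel-wide line has width exactly 1 and a single pixel
encloses area exactly 1. Foreground is 8-connected, background and holes
4-connected. Where two boundary points coincide (diagonally touching
pixels) the two passes are pulled apart along the off-diagonal by a total
separation of 1/20 px (each point moves 1/40 px), keeping every polyline
simple and every object unambiguously enclosed. The shift changes the
enclosed area by about 0.018 px² per shifted corner (the cut-corner
triangle has base √2 and height 1/40).

**Label images.** Each label is traced around the largest 4-connected
component of its pixels, and every boundary point is displaced half-way
from the half-pixel border towards the owning pixel centre (an inward
offset of the rectilinear loop by 0.25 px). One-pixel-wide objects thin
to width 0.5 and touching labels acquire a half-pixel gap, so the
background graph threads between all cells and encodes their spatial
arrangement. A solid `w x h` label has enclosed area `(w-0.5)(h-0.5)`.

Exterior boundaries carry positive shoelace area in this coordinate
frame, interior (hole) boundaries negative; the sign is the kind test.

## The shape graph

Sites are the decomposition of all boundary polylines into corner points
and open segments between consecutive corners, plus the frame rectangle
(four corner points + four segments). Maximal runs of collinear boundary
vertices are merged into single segment sites: the union of sites is the
same point set, so the diagram is geometrically unchanged, while the
measure-zero degenerate cells of run-interior vertices (and the degree-3
subdivision vertices they would induce on straight bisector chains)
disappear. The frame sits `frame_margin` (default 0.5 px) outside the
pixel-corner domain so that boundary runs of edge-touching objects never
coincide with frame sites.

Distance to a segment site is the perpendicular distance when the foot
falls inside the segment and infinite otherwise; endpoints are their own
point sites, so the minimum over sites equals the true distance to the
geometry. Under this convention the bisector of a segment and its own
endpoint is the perpendicular line at the endpoint — a genuine 1-D
bisector — and the diagram decomposes into straight edges (point/point,
segment/segment, point-on-carrier-line) and parabolic arcs
(point/segment).

**Construction: clearance expansion.** Every boundary corner is a known
vertex of the diagram with clearance 0: its convex-side angle bisector
and the two reflex-side endpoint perpendiculars meet there, giving degree
exactly 3. Starting from these seeds (plus the frame corners), every edge
is walked along its bisector to the next *event* — the first parameter at
which a third site reaches the running clearance. Events are roots of
quadratics solved in closed form, batched over candidate sites pruned
with a KD-tree over dense site samples; a verification bound (arc length
+ maximal radius + sample spacing) guarantees no nearer competitor was
outside the pruned set. Grazing contacts (a point on a pair-segment's
carrier line, or a segment whose carrier passes through a pair point) are
double roots that floating-point discriminants can miss, so they are
solved directly as linear perpendicular-crossing conditions.
Breadth-first expansion saturates the diagram; inside the frame the
1-skeleton is connected (the two sides of every boundary communicate
through the corner contact vertices), so every vertex is reached. The
construction is verified against an exhaustive O(n³) tangent-circle
oracle.

**Numerical policy.** Every discovered vertex is polished by Gauss-Newton
on its full tangency system; a segment tangent at one of its own
endpoints contributes the perpendicular-at-endpoint constraint instead of
the (quadratically flat) distance residual. Refined positions are exact
to ~1e-12 px, which allows tight tolerances: tangency collection at
2e-9 px, emptiness at 1e-9 px, coincident-vertex merging at 1e-6 px.
Grazing tangency membership is decided positionally (foot within 1e-6 px
of the endpoint) because its distance residual cannot separate nearby
vertices. Nearly-coincident vertices with *different* tangency triples (a
collapsed triangle of true vertices) are kept distinct, joined by their
genuine sub-microscopic edges; vertices tangent to four or more cocircular
sites are split into coincident degree-3 vertices chained by zero-length
edges (fan triangulation of the angularly sorted tangencies, anchored at
the lowest site id, with point/own-segment angle ties ordered towards the
segment interior). Edge lengths use exact segment lengths and the
closed-form parabolic arc length.

Every vertex has degree exactly 3, with one documented exception: the
four frame corners keep only their interior diagonal edge, because their
other two edges lie outside the frame and are clipped away.

## Annotation

Vertices and edges are labelled `in` (foreground), `out` (background) or
`frame`. Free vertices are located against the foreground polygons
(shapely); contact (r=0) vertices sit exactly on a boundary and take the
side of their convex wedge, which is the material side exactly when the
boundary turns left there. Edges whose two generating sites are both
frame sites are `frame` and excluded from features; mixed content/frame
bisector edges are genuine out-graph edges (the frame acts as the
outermost boundary).

Roles: a *bridge* is equidistant to exactly two distinct boundaries, a
*hub* to three or more (the frame counts as a boundary); *connectors* are
the vertices promoted while joining disconnected bridge chains of one
subgraph through shortest paths (the hole-within-a-protrusion case);
everything else is a *branch* vertex.

Each boundary owns at most one subgraph per side: an edge belongs to the
side it lies in and to the boundaries generating it. Inter-boundary
(bridge) edges are owned by the lower boundary id for the disjoint
partition but participate in both adjacent subgraphs' root paths. The
*root path* of a subgraph with bridges is the ordered chain of its
multi-boundary vertices along inter-boundary edges (cyclic when closed;
canonically started at the maximal-clearance vertex and traversed with
positive orientation). A bridgeless subgraph is a tree; its root is the
maximal-clearance vertex and the root path is the longest leaf-to-leaf
path through the root restricted to vertices of positive clearance
(contact leaves carry no width information).

## Profiles and the 40 metrics

The *width profile* samples the clearance radius at each root-path vertex
against cumulative arc length: local thickness inside objects, local
sparsity in the background.

The *boundary profile* measures, for every traced boundary point, the
length of the path from the root set to that point along subgraph edges,
normalized by the starting root's clearance:
`h(p) = r_v + min_u [d(u, v) - r_u]`, where `v` is the graph vertex whose
tangency foot is nearest to `p` along the boundary (ties to the smaller
clearance) and `u` ranges over the root set. The `r_v` term is the
attachment gap between the graph vertex and the boundary point on its
circle, so a boundary point touched by a root's own inscribed circle has
height exactly 0, and a protrusion's tip height approximates its geodesic
length. For bridgeless subgraphs the root set is the single
maximal-clearance root (the diameter-shaped root path serves the width
profile only; using it as the source set would swallow the longest
protrusion into the path). Multi-source distances are computed by
Dijkstra with a virtual source whose arc weights are offset by the roots'
clearances.

Twenty metrics per side (in-graph block first), forty per boundary:

1-6. width profile mean, standard deviation, third and fourth central
moments, min, max;
7-9. boundary profile mean, standard deviation, max;
10-17. for the 0/25/50/75% quantiles of the height samples
(linear-interpolation quantiles): the trapezoid area under
`max(h - q, 0)` over boundary arc length (closed cyclically), and the
number of upward crossings of `q` counted cyclically — start-point
independent; for the 0th quantile, the number of contiguous runs at the
minimum (within 1e-9 px);
18-19. enclosed area and perimeter (identical between sides);
20. exterior/interior flag (1 = exterior).

A boundary whose one side has no subgraph (e.g. fully frame-hugging)
gets sentinel zeros for that side's 20 metrics, with a logged warning.

## Boundary types and image analyses

All boundaries of an image set are standardized per feature by median and
interquartile range (zero-IQR features dropped — k-means is
scale-sensitive and the 40 metrics span incommensurate units; robust
scaling resists outlier boundaries), then clustered with seeded k-means
(k-means++ with 10 restarts, best inertia). Counting types per image
gives the bag-of-boundary-types histogram. Downstream: leave-one-out
k-NN (k=3, Euclidean on raw counts, vote ties broken by the nearest
neighbour) for classification; centred PCA for embedding; per-target
ordinary least squares on the histogram counts for regression of
log-transformed generative parameters, scored by leave-one-out MAE and
Pearson correlation. The in-/out-graph ablation flags restrict the
feature block before standardization. The number of types can be selected
by downstream leave-one-out performance (ties to the smallest candidate).

## Well profiling

Per-cell metric vectors (the 40 minus the two flag entries: 19 per side)
are aggregated per well as means then standard deviations (76 values),
normalized by subtracting the per-plate median of control wells, and
classified with a seeded depth-unlimited CART tree (Gini), training on
all plates but one and pooling held-out predictions. Precision, recall
and F1 = 2PR/(P+R) are reported per class with their unweighted mean.
Border-touching cells are included (no exclusion flag is applied by
default). Cells are pooled across fields of view within a well.

## Synthetic data

The generators define the study conditions of the test suite:

* primitives (disk, annulus, bar, spiked disk) rasterized by
  pixel-centre-inside tests, with analytic area/inradius/protrusion
  ground truth;
* the mesh generator scatters `n_seeds` blob centres, takes Delaunay
  neighbour pairs as candidate contacts, joins a seeded random subset of
  exactly `round(connectivity * n_candidates)` pairs with struts of
  half-width `density`, and unions blobs of radius `density + 1`.
  Drawing an exact fraction makes the connectivity parameter the realized
  joined fraction; the stochasticity lies in the layout and in which
  pairs join. The generator is a phenomenological stand-in: it guarantees
  only the monotone structure-parameter relationships (connectivity →
  holes/components, density → thickness) that parameter-recovery
  experiments need, and makes no attempt to model cell mechanics;
* label mosaics are nearest-seed tessellations with a background rim,
  emitting the label adjacency as ground truth.

What passing tests on these fixtures show is that the geometry engine is
exact (oracle equivalence), that the profiles measure what they claim on
shapes with known answers, and that the typing/regression pipeline
recovers designed structural parameters under seeded stochasticity. They
do not certify segmentation quality, intensity effects, or biological
realism of any particular assay; on real images the pipeline is exactly
as good as the upstream segmentation.

## Problem sizes and runtime

Diagram construction costs a few milliseconds per vertex (the fine
structure of a 60 px mesh image has ~1000 vertices and builds in a few
seconds). The test suite uses fixtures of 40-90 px and a 100-image
10x10 parameter sweep at 60 px with 12 seed blobs per image
(connectivity 0.1-1.0, density 1.2-2.0 — higher densities saturate
frames this small); the oracle cross-check runs on instances of up to 50
sites, where the O(n³) enumeration is still fast. These sizes were
chosen so the full suite completes in well under half an hour on one CPU
while every stage is exercised at its native conventions.

## Known limitations

* Degeneracy handling is tolerance-based (documented above), not exact
  arithmetic; configurations engineered to sit exactly at the tolerance
  boundaries (~1e-9 px) can be resolved inconsistently. Pixel-lattice
  inputs sit far from this regime.
* Branched root structures (a material subgraph enclosing several holes)
  are ordered by deterministic DFS rather than a canonical cycle; width
  profiles over such subgraphs depend on that traversal order.
* The root path of a bridgeless subgraph reads "longest path through the
  root" as the leaf-to-leaf diameter over positive-clearance vertices;
  the alternative root-to-leaf reading would halve its length.
* The run-count at the 0th quantile (metric 11) is a degenerate counter
  on continuous data; it is computed as the number of cyclic runs at the
  minimum within 1e-9 px.
* Edge sides are located by chord midpoints; for parabolic edges this is
  safe because edges never cross boundaries, but extremely long parabolic
  edges hugging a concave boundary would be the first place to look if a
  side label ever seems wrong.
* In the mesh stand-in, the out-graph metric block is largely redundant:
  density is by construction a strut half-width (an in-graph quantity)
  and hole boundaries' in-graphs also encode spacing, so dropping the
  out-graph block changes parameter recovery only at the noise level.
  On data where object spacing is encoded solely by the background (for
  example isolated cell clusters), the out-graph block is expected to
  carry independent signal; the suite's ablation check documents this
  divergence between the stand-in and that regime.
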