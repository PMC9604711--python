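# Methods

## Pipeline

For a raw image the pipeline is: green channel (color images carry the
best vessel contrast there) → multiscale Hessian vesselness → linear
rescale of the real-valued response to 8 bits (min→0, max→255; a constant
response maps to all zeros) → binarize at gray level strictly greater than
100 → connectivity filtering (CF or LS-CF) → score threshold strictly
greater than `s_min` → optionally, for the comparison baseline,
morphological closing. Pre-binarized masks can enter the pipeline directly
(`--skip-frangi`). The vesselness stage is prior art and is delegated to
`skimage.filters.frangi`; any callable with the same contract can be
substituted. The 8-bit rescale is the main source of drift between
vesselness implementations, which is why the threshold level remains
configurable; 100 is the reference default for all modalities.

## Connectivity scoring

The connectivity score of a foreground pixel is the cardinality of its
connected component: a pixel's brightness in the score image grows with
the number of pixels it is connected to, and all pixels of one component
share one value. Adjacency comes from the Rodrigues distance
`d = w1·(|Δr|^p + |Δc|^p)^(1/p) + w2·max(|Δr|,|Δc|)` with
`w1 = w2 = p = 1`; neighbor offsets are all nonzero offsets with
`d ≤ radius`. Defaults: `radius = 3` (8-connectivity — vessels run
diagonally; `radius = 2` gives 4-connectivity). The flood fill is an
explicit worklist, so component size is never limited by call-stack depth
(retinal trees run to tens of thousands of pixels). Scores are unbounded
integers; clamping to 8 bits happens only when rendering, because the
score threshold must act on true counts.

Neighbor order is fully deterministic: clockwise from North
(N, NE, E, SE, S, SW, W, NW for radius 3), rotated so that a walker's
previous step comes first ("momentum" — the traversal emulates a brush
stroke). Scores are a per-component property, so the output is invariant
to seed-pixel processing order.

## Local-sensitive bridging

The LS-CF adds a bounded off-vessel search. Design parameters, with
defaults and rationale:

| parameter   | default | meaning |
|-------------|---------|---------|
| `max_dist`  | 4 px    | excursion depth: maximum number of off-vessel pixels in one bridge path. A gap of length `g` is bridgeable iff `g ≤ max_dist`, in any orientation. |
| `max_score` | 350 px  | tolerance: maximum background pixels *visited* (including abandoned search branches) per excursion. At `max_dist = 4` a search can visit at most ~80 pixels, so 350 is a loose outer bound; it becomes the binding stop when `max_dist` is raised. |
| `s_min`     | 1       | final score threshold, strict `>`; 1 deletes exactly the isolated pixels. |

Semantics fixed here (the tunable grain of the tolerance is not uniquely
determined by the filter's informal description): the tolerance counter is
per-excursion — it resets whenever the walk regains vessel. A cumulative
per-component budget would scale with component perimeter and starve late
gaps on any realistic vessel tree, defeating the filter's purpose.
`max_dist` is a step-depth budget rather than a straight-line radius; a
radius in Rodrigues units would make diagonal gaps of the same pixel
length unbridgeable while orthogonal ones bridge, breaking orientation
invariance.

Traversal schedule: components are discovered in raster order and each is
flood-filled *completely* before its excursions launch, so a component can
never bridge to itself through the background — existing vessel bodies are
never dilated, and bridging adds pixels only along successful excursion
paths. Excursions are seeded from every component pixel that still has an
unreached foreground target within reach (cut branch ends first, i.e.
reverse discovery order), and the search expands breadth-first by depth
with momentum-first tie-breaks. The realized bridge is therefore a
shortest admissible background path from the component; on a severed
straight branch it coincides with the punched run of vessel. The momentum
of a departure pixel is estimated as the compass direction from the local
component centroid toward the pixel (the outward continuation of the cut
branch); the raw arrival offset zigzags on vessels wider than one pixel.

Consequences worth knowing: bridges are one pixel thick, so a severed
wide branch is reconnected topologically but the full punched area is not
repainted; any unreached foreground within range is a valid target, so
isolated noise within `~max_dist + 1` pixels of a vessel is linked to it
(a true property of the tolerance heuristic — the specificity cost shows
up in the evaluation); and a bridge may run adjacent to an
already-finished component without merging it, since traversal is
sequential.

With `max_score = 0` or `max_dist < 1` no excursion launches and the
LS-CF output is bit-identical to the CF pipeline.

## Morphological baseline

The comparison baseline is CF → score threshold → closing with the
distance-1 cross `{(0,0),(±1,0),(0,±1)}` (the alternative closing-first
order is exposed as `closing_first`; an `dilations > 1` variant exists for
experimentation). Closing is computed on a padded domain: the dilation's
reach beyond the frame is kept and erosion treats outside the dilated
domain as background — exactly infinite-grid set arithmetic restricted to
the frame, which keeps closing extensive, idempotent and monotone at the
border. Note that cross closing cannot bridge a gap in a thin line — even
a 1-pixel gap: the dilation never covers the gap pixel's off-axis
neighbors, so the erosion reopens it. This is the structural reason the
local-sensitive filter is not equivalent to CF + closing.

## Evaluation

TP rate = sensitivity `100·tp/(tp+fn)`, TN rate = specificity
`100·tn/(tn+fp)`, accuracy `100·(tp+tn)/total`, all in percent. A rate
whose denominator is zero is reported absent, never as 0. Counting may be
restricted to a field-of-view mask; the default is all pixels, and every
report states which convention was used.

## Synthetic fixtures

The generator emulates the defect structure of thresholded vesselness
responses with full knowledge of the ground truth:

- **Vessel trees** — correlated random walks over the 8 compass headings
  (turn probability 0.12 per step), widths 1–2 px stamped as squares,
  sprouting from the existing tree so the truth is one connected
  component. Walks keep a 2-px clearance from previously drawn branches:
  distinct vessel segments do not run alongside each other at sub-clearance
  separation, the mask stays acyclic, and a punched gap therefore genuinely
  disconnects its branch. Reference conditions: 176×176 px, 7 branches of
  length 30–70 px.
- **Punched gaps** — at elongated interior sites (local PCA direction,
  anisotropy ≥ 2), a slab of the requested length (default 10 gaps of
  2–3 px) is removed across the measured local branch width, with an
  explicit check that the slab severs the branch (progressively widened if
  a partial cut would survive). The removed pixels are recorded exactly, so
  bridge placement can be scored against them.
- **Salt noise** — isolated single pixels (no foreground in the
  8-neighborhood at insertion time), default density 2.5·10⁻⁴. The
  gapped-fixture suite is deliberately gap-dominated: it exists to measure
  reconnection, and the CF-vs-LS-CF accuracy ranking genuinely depends on
  the defect mix — the tolerance walk links background speckle within
  reach, so under heavy salt the specificity cost can cancel the
  reconnection gain, mirroring the small margins (and one reversal) the
  method shows on public benchmarks. Heavy-speckle behavior is exercised
  separately by the noise-immunity tests, which inject hundreds of
  isolated pixels and require 100 % removal.

All generator stages are deterministic per seed and fixtures carry their
seeds in metadata. What passing fixture tests do **not** show: performance
on real vesselness responses (soft intensity structure, correlated noise,
vessel crossings, calibre variation) or on dataset-scale images with the
externally tuned vesselness parameter sets; the fixtures verify the
algorithmic contracts, not benchmark numbers.

## Numerical choices and degenerate inputs

Ties in neighbor enumeration are broken by the fixed clockwise canonical
order; equal-length bridge candidates resolve toward the earliest
departure (tips first) and its stroke direction. Empty masks, empty score
maps and zero-budget parameters all pass through every stage. Metrics on
all-zero counts are rejected rather than returning NaN. 16-bit input
images are right-shifted to 8 bits with a logged warning. The pipeline is
purely deterministic: identical configuration and inputs reproduce
hash-identical output files (the CLI writes the resolved configuration
next to its outputs).

## Known limitations

- Bridges are single-pixel paths; reconnection does not restore the
  calibre of wide severed branches.
- The tolerance walk will link any unreached foreground within range,
  including genuine noise; `max_dist` is the only guard.
- Scores of components that merge through bridges are recomputed as the
  merged cardinality, but a bridge passing adjacent to a component
  traversed earlier does not merge with it.
- The vesselness front end is a generic multiscale Hessian filter with one
  default parameter set; per-modality tuning is left to configuration.
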