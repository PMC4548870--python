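# Methods

## Data model

The tracker's input is a time-ordered series of segmented label masks
`I_k`, `k = 1..N` (`N >= 2`), all of one size. Pixel value 0 is
background; positive values are per-frame cell numbers. Within a frame
the numbers are canonical, `1..M_k`; because segmentation numbers each
frame independently, nothing may be inferred from a label's value across
frames. A "cell" is the set of equal-valued pixels — connectivity is not
required and not repaired, since splitting or merging regions is the
segmenter's responsibility. On reading, labels are renumbered to
`1..M_k` in raster (row-major) first-encounter order; the scan order is
this package's choice, as any fixed deterministic order serves.

Coordinates are 0-based `(row, col)` internally; exports use the
conventional image axes x = column, y = row. Centroids are unweighted
means of member pixel coordinates (the standard reading for binary
regions). Output masks are written as 16-bit grayscale TIFF, since track
counts can exceed 255; 8/16-bit TIFF and PNG are accepted on input.
Frame order comes from natural (numeric-aware) filename sort, not image
metadata.

## Cost model and assumptions

The method's operating premise is a high acquisition rate relative to
cell speed: consecutive instances of one cell overlap in pixel space.
Under that premise the dominant evidence for identity is the shared
pixel count, refined by centroid offset and size change:

    d = w_o * O + w_c * delta_c + w_s * delta_s

- `O(s_i, s_j, n_o) = 1 - (n_o/2)(1/s_i + 1/s_j)`: the shared count
  averaged against both cells' reciprocal sizes; 0 iff the two
  footprints coincide exactly, 1 iff disjoint.
- `delta_c`: Euclidean centroid distance divided by the image diagonal
  `sqrt(I_height^2 + I_width^2)`. The diagonal is the only normalizer
  that maps the maximum possible displacement to exactly 1, which is why
  this reading was adopted.
- `delta_s = |s_i - s_j| / max(s_i, s_j)`: 0 for equal sizes, strictly
  below 1 always.

All three metrics lie in [0, 1], so any valid cost is at most
`w_o + w_c + w_s` (3.5 at the defaults).

**Pathological filter.** If a pair shares *no* pixels **and** its raw
centroid distance (pixels, not the normalized metric — the threshold is
meant in image units) exceeds `max_centroid_distance`, the pair gets the
sentinel `MAX_COST` and is invalid. The condition is deliberately
conjunctive: any nonzero overlap keeps a pair valid regardless of
distance, because shared pixels are direct evidence. The threshold is
user-set (default 50 px ≈ several cell diameters per frame, far beyond
plausible motion at the intended acquisition rates). `MAX_COST`
defaults to 1e9; any finite sentinel above the maximum attainable cost
is equivalent, and invalidity is defined as cost equal to the sentinel.

### Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `weight_overlap` (w_o) | 2.0 | – | weight of the overlap metric; raise when frame-to-frame overlap is large |
| `weight_centroid` (w_c) | 1.0 | – | weight of the centroid-offset metric |
| `weight_size` (w_s) | 0.5 | – | weight of the size-change metric; raise for cells of stable area |
| `max_centroid_distance` | 50 | px | pathological-filter distance threshold for zero-overlap pairs |
| `max_cost` | 1e9 | – | invalid-mapping sentinel; must exceed w_o + w_c + w_s |
| frame interval | 15 | min | time between frames, used only to convert path lengths to travel rates |

## Assignment

Per frame pair, the chosen mapping is the global optimum over one-to-one
partial matchings that use only valid pairs, ordered lexicographically
by (most links, least total cost, smallest sorted link list). Maximizing
links first is required for the objective to be well-posed: with
non-negative costs, minimizing cost alone would always pick the empty
matching. The optimum value is obtained with the Hungarian-method solver
(`scipy.optimize.linear_sum_assignment`), with invalid entries replaced
by a finite penalty exceeding the sum of all valid costs (so each
avoided invalid link dominates any cost saving) and penalty-links
stripped from the result. The tie-break is then realized constructively:
sources in ascending label order are fixed to their smallest-labeled
target that preserves the optimal link count and cost (verified by
re-solving the reduced problem), or left unmatched if none does. This
costs O(n·m) extra solver calls per frame pair — negligible at realistic
cell counts — and makes the output fully deterministic. An exhaustive
enumerator with the identical objective (refused above min dimension 8)
serves as an independent oracle in the tests. One-to-one matching is a
modeling choice: splits (mitosis) and merges (collisions) are not
handled, so a dividing cell yields one continued track plus one new one.

## Chaining and relabeling

Mappings are chained through time: every cell of frame 1 seeds a track;
a link extends the source's track onto its target; an unmatched target
starts a new track; an unmatched source's track ends. Track numbers
`1..T` follow first-appearance order (frame, then label). A terminated
track never resumes — there is no gap closing, so a cell that leaves and
re-enters the field (or drops out of the segmentation for one frame)
gets a fresh number. Relabeling replaces each foreground pixel's
per-frame label with its track number and touches nothing else; the
per-frame multiset of region sizes is conserved by construction.

## Trajectories

Per track: the centroid path `(frame, x, y)`, per-step displacement
vectors `(dx, dy, step length)`, and the travel rate = total path length
divided by elapsed time (frame span × frame interval), in px/min. No
micron conversion is applied unless the caller supplies a pixel size.
Plots (2-D quiver of steps, 3-D x–y–frame lines) are conveniences, not
analysis.

## Synthetic sequences

The generator emulates the tracker's intended regime: a sparse culture
of `n_cells` elliptical blobs (radii 8–14 px, mild aspect ratio
0.85–1.18, random orientation) in a 520×696 px frame, whose centers
perform a uniform random walk with per-axis step at most `max_step`
(default 4 px, well under a cell radius), reflecting at the borders,
with per-frame area jitter (default ±5%) and optional permanent
disappearance / new appearance events. Cells never touch: every
placement keeps at least a 1-pixel 8-connected gap, because the tracker
assumes segmentation has separated cells. A move may not touch
already-moved cells nor the previous footprints of cells yet to move
that frame; this slightly restricts motion near contacts but guarantees
the fall-back "stay put" is always collision-free, so generation cannot
deadlock. Per-frame labels are randomly permuted so that no stage can
silently rely on label continuity. Everything is deterministic given the
seed.

Ground truth records each frame's label→identity map. The tracking
score is link-level: a consecutive-frame link is correct iff its two
endpoints carry the same true identity, and the score is correct links
over true persisting pairs (vacuously 1 with no persisting pairs).

What the generator does **not** emulate: touching or overlapping cells,
segmentation errors (split/merged/missing regions), mitosis, intensity
information, or realistic cell shapes. Passing tests on synthetic data
therefore demonstrate correct linking under the stated premise — bounded
motion and clean segmentation — not robustness to segmentation failure.

## Numerical choices and degenerate inputs

- Optimality checks in the tie-break layer compare costs with a 1e-9
  relative/absolute tolerance (sums of the same floats in different
  orders).
- Frames with zero cells are legal throughout: cost matrices may have
  zero rows or columns; an empty matrix maps everything to
  births/deaths.
- A single-point track has no displacements; its travel rate is
  undefined (error in the API, NaN in the CSV export).
- Metric contracts are enforced: sizes >= 1, overlap within
  [0, min(sizes)]; violations raise rather than clamp.
- Test problem sizes (6–10 cells, 5–25 frames, 200×260 to 520×696
  frames) keep the default suite fast while exercising every code path;
  they match the sparse-culture regime the generator models.

## Known limitations

- No mitosis, collision, or shape criterion; morphologically stable
  objects would benefit from a shape term the cost deliberately omits.
- No gap closing; transient segmentation dropouts fragment tracks.
- Tracking quality is bounded by segmentation quality and by the
  acquisition-rate premise; the tests show the score degrading once
  per-frame steps grow far beyond the cell diameter.
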