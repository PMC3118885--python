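# Methods

This note documents the models and procedures implemented in `ecosens`,
the choices made where the design was genuinely open, and what the test
suite does and does not establish.

## Grading model

Every indicator maps raw measurements onto the discrete sensitivity grade
index set {1, 3, 5, 7, 9} (insensitive → extremely sensitive).  Numeric
indicators carry five grade-aligned intervals; open-ended bins use ±∞
edges.  Categorical indicators carry an explicit category → grade map.

Numerical conventions:

- **Boundary ties.** Published grade tables print touching intervals
  (e.g. "15∼25" next to "≥25").  A value on a shared edge is assigned to
  the *more sensitive* class (`tie="higher"`), the conservative choice for
  a protection-oriented assessment; `tie="lower"` is available.
- **Direction is metadata.** Whether a larger raw value means more
  (`benefit`) or less (`cost`) sensitive is an explicit per-indicator
  field, never inferred from bin order: published tables contain
  non-monotone rows (e.g. a rainfall row), so inference would be unsafe.
- **Strictness.** `validate(strict=True)` rejects overlapping or gapped
  interval sets, except for indicators carrying transcription flags: the
  shipped case-study scheme preserves the source's printing defects
  (gapped slope/PM₁₀ rows, an overlapping urbanization row, a
  non-monotone rainfall row) verbatim, flagged.  Values that fall inside
  the domain hull but in a printed gap snap to the nearest bin; values
  outside the hull raise.
- **Missing raw values** propagate as missing with a logged count;
  synthesis treats them per `missing=error|skip` (default error).

## Fuzzy matter-element model

The compound matter-element R_mn collects m objects × n characters of
crisp values x. Normalization to the excellent dependent degree is
u = x / max x per character when larger raw values are closer to the ideal
and u = min x / x otherwise, so every u ∈ [0, 1] and each column attains 1
at its optimum.  The standard element is the columnwise optimum
(identically 1), the difference matrix is Δ = (u₀ − u)², and the approach
degree aggregates Δ with a normalized weight vector:

- `hamming`: PH = 1 − Σ w·Δ
- `euclid` (default): PH = 1 − sqrt(Σ w·Δ)

The source formula for the "Euclid" approach degree is printed without the
square root; standard FME practice includes it.  Both variants are
implemented and every fitted result records which was used.  Because both
are strictly decreasing transforms of the same weighted distance, they
induce identical rankings — a property the suite checks on random
matrices, which is why the default choice is inconsequential for ordering.

Weight vectors must be nonnegative and sum to 1 within 1e-9 (they are
renormalized after the check; the tolerance absorbs 2-d.p. rounding of
published weight tables).

Index conventions in the source swap object/character subscripts between
sections; internally objects are always rows and characters columns, and
all I/O is id-keyed, so the convention never leaks.

## Entropy weighting

Per indicator over m ≥ 2 objects: min-max rank b = (r − r_min)/(r_max −
r_min) (reversed for cost indicators; a constant column maps to all
zeros), corrected frequencies f = (1 + b)/Σ(1 + b), normalized Shannon
entropy H = −Σ f ln f / ln m ∈ (0, 1], and weights w = (1 − H)/(n − ΣH).

- The *corrected* frequency form is always used by default: the
  uncorrected f = b/Σb can be 0, where ln f is undefined.  The
  uncorrected form exists behind `use_correction=False` for comparison.
- A constant column flows to uniform f, H = 1 and weight exactly 0 ("no
  information, no weight").  Entropies within 1e-12 of 1 are snapped to 1
  so this zero is exact despite floating-point log sums.
- If *every* indicator has H = 1 the weights are undefined and a
  degenerate-weights error is raised.
- The chain is verified against an independent loop-based implementation
  to 1e-12 on random matrices (2–10 objects × 2–8 indicators).

## Weight hierarchy

Weights live on an A/B/C/D tree; children of every node sum to 1, and the
global weight of a leaf is the product of relative weights along its path,
which makes level-by-level weighted means algebraically identical to one
flat weighted sum (both modes are implemented; hierarchical is the
default).  Each node records provenance (`fixed` or `entropy`).  Entropy
derivation is bottom-up: an internal child's per-unit value is its own
aggregated weighted mean, and the entropy chain on the child columns gives
that node's weights.

The shipped case-study weight fixture is transcribed as printed.  Several
printed groups do not sum to 1 (a soil-quality group at 1.02, a
water-quality group at 1.12, the water group at 0.88); they are flagged
`non-normalized` and left as printed — `WeightTree.normalized()` returns a
usable renormalized copy, which is what the model facade applies.  One
printed weight row ("quality grade of air", 0.28) is realigned from the
water block to the atmospheric block, where the printed weights then sum
to exactly 1.00; the atmospheric population-intensity factor has no
printed weight and carries 0, flagged.

## Composite index and classification

G at a node is Σ (child weight × child G) with leaves seeded by the grade
indices, i.e. a convex combination: G ∈ [1, 9] always, and raising any
single leaf grade can never lower an ancestor's G nor the final class.
Classification intervals are [1,3), [3,5), [5,7), [7,9), [9,10] —
left-closed right-open with the last interval closed, so every attainable
G has exactly one class.  The source does not state its boundary
convention; this one is the only one in which the interval set partitions
[1, 10], and it is configurable.

Area summaries report per-class totals in hm² (1 hm² = 10⁴ m²) and
proportions of the evaluated total rounded *half-up* to 2 decimals
(matching published table conventions; Python's default banker's rounding
would disagree on .005 cases).  Proportions close to 100% within ±0.02 by
construction of the rounding.

## Vector overlay

Overlay is pairwise-iterated polygon intersection (an STRtree prunes
candidate pairs; an exhaustive all-pairs oracle cross-checks the result in
tests).  Non-polygonal intersection artifacts (lines, points) are
discarded.  Inputs are repaired by zero-width buffering; unrepairable
features are dropped with a logged id list.  Slivers below a configurable
fraction (default 1e-4) of the mean input polygon area are merged into the
neighbor sharing the longest boundary.  "Spatial clustering to merge
units" is implemented as an attribute dissolve of touching same-class
polygons (area-conserving to 1e-6 relative); nothing statistical (e.g.
coordinate k-means) is attempted.

Areas are planar.  Layers declaring degree units (geographic CRS) are
rejected with an instruction to reproject — the package deliberately
ships no reprojection engine; CRS handling is declared metadata on the
layer (`crs`, `crs_units`), and mixed-CRS overlays error out.  Vector I/O
is GeoJSON only, read and written as plain JSON with shapely geometries.

## Synthetic data generator

The generator emulates the *shape* of the study data: polygonal evaluation
units carrying one raw value per leaf indicator.  Units are squares on a
regular grid (default 1 km cells, 100 hm² each) so areas are exact and
overlay arithmetic is assertable; real administrative units are irregular,
so no spatial realism is claimed.  Default mixture is uniform over the
five classes; sigma (within-bin noise, fraction of bin width) and eps
(one-bin leak probability) default to 0.

Raw values are drawn uniformly inside the target class's bin — an explicit
modeling choice; the source makes no distributional statements.  Draws are
rejection-sampled so the noise-free draw always grades back to its target
(necessary where as-printed bins overlap a more sensitive class and the
tie rule would re-grade part of the bin).  Unbounded bins get a finite
sampling surrogate edge: the boundary extended by the width of the nearest
finite bin.  Gaussian noise is clipped to the indicator's domain hull.
Everything is driven by one `numpy` Generator seed; a fixed seed yields
byte-identical CSV/GeoJSON artifacts.

Consequently, passing end-to-end tests show that the pipeline recovers
labels *its own generator planted* under the stated noise; they do not
show that the grade system or weights are ecologically valid for any real
region — that validity rests with the published expert tables.

## Problem sizes

The suite and the reproduction script run the oracle comparisons at 200
random matrices, the noise-free recovery at a 10×10 grid, and the mixture
recovery at 5,000 units (50×100), where the ±2% per-class tolerance is
about 3.5 binomial standard deviations.  All sizes complete in seconds.

## Known limitations

- No Shapefile/GeoPackage I/O and no reprojection; GeoJSON in planar
  meter coordinates is the interchange format.
- No raster support; the evaluation is vector-only, as is the method.
- No interval-valued or linguistic fuzzy numbers; raw values are crisp.
- No subjective weighting (AHP/Delphi) and no weight sensitivity analysis
  beyond reporting provenance.
- The shipped case-study fixtures reproduce their source's printed tables,
  including its internal inconsistencies (flagged); they cannot be
  re-derived from raw data, which was never deposited.
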