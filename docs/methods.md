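# Methods

## Scope and model

`mirprio` operationalizes a two-pass network analysis for prioritizing the
targets of one miRNA. The inputs are consumed as files (prediction scores,
validation labels, association scores and pathway curation are upstream
products, not recomputed here); the package's contribution is the pipeline
that combines them and the quantification formulas implemented alongside.

### Target catalog

Predicted targets are ranked by context score, where lower (more negative)
means more confident; "most confident 15%" is `k = ceil(0.15·n)` genes, so
at least one gene survives any non-empty input. Ties at the cut break by
ascending gene symbol, making builds reproducible. The direction is
configurable (`ascending=False`) for score types where larger is better.
Gene symbols are uppercased and stripped; no species-aware alias resolution
is attempted, but a two-column alias map can be applied at parse time
(strict or pass-through). Duplicate predicted genes keep their best score;
duplicate validated genes merge evidence labels.

### Networks

Edges are undirected, stored canonically (`a < b`), deduplicated to the
maximum score, and filtered at combined score ≥ 900 (inclusive). Two modes:

* **CROSS_GROUP** keeps an edge iff its endpoints can be assigned to
  opposite catalog groups. Genes present in both input sets (label BOTH)
  satisfy either side — the natural reading when the two databases overlap.
* **EXPANDED** additionally keeps within-group edges. By default both
  within-group kinds (predicted–predicted and validated–validated) are
  admitted; `ExpansionKind.PREDICTED_ONLY` restricts expansion to
  predicted–predicted edges for the stricter reading where only the
  predicted side is expanded.

Because EXPANDED's edge set is a superset of CROSS_GROUP's over the same
catalog, every cross-group component nests inside exactly one expanded
component (the coarsening property; asserted on randomized graphs in the
suite). Components below `min_component_size = 2` are reported as isolated
rather than analyzed — a singleton cannot be "connected" by the edge data —
and the cutoff is configurable.

### Over-representation

For a component with `n` genes inside the universe and a pathway with `K`,
overlapping in `k`, the raw p is the hypergeometric upper tail
`P(X ≥ k)`, computed by summing terms in log space (log-gamma binomials +
logsumexp), exact to ~1e-12 against exhaustive enumeration on small grids
and matching an independent survival-function implementation at large sizes.
The Bonferroni family is, per component, the pathways that pass the size
bounds and overlap in ≥ 1 gene — mirroring per-call adjustment in common
enrichment tools; a `global_family` option corrects over all components at
once. The universe defaults to the union of all pathway genes (the
annotation universe); `universe_mode=CATALOG` restricts it to catalog genes,
which is markedly more conservative — at the synthetic fixture's scale it
leaves nothing significant, and the pipeline then terminates cleanly with an
explicit no-candidate marker. No pathway-size bounds are imposed by default
so that small collections remain testable; common tools default to roughly
10–500 and the bounds are exposed.

### Prioritization

"Neuroinflammation-associated" is a keyword-substring classification on
pathway names (case-insensitive). The default vocabulary — toll-like
receptor, tlr, myd88, interleukin, il-1, nf-kb, nfkb, inflammasome, innate
immune, traf — anchors the innate-immune family; a keywords file (one per
line, `#` comments) overrides it. The before/after comparison assigns each
cross-group component to its containing expanded component and counts
distinct enriched neuro pathways on each side; `delta = after − before`.
Note `before ≤ after` is *not* guaranteed in general (merging changes the
overlap structure), only the arithmetic identity is. Candidate ranking —
membership in enriched neuro pathways, then expanded-network degree, then
symbol — is one deliberate operationalization of "best predicted target";
all three scores are emitted so users can re-rank.

## Synthetic fixtures

The generator emulates the analysis inputs with planted ground truth:

* **Targets.** 60 predicted genes (the 15% cut keeps 9) and 12 validated.
  Role genes (hub, two planted predicted partners, two planted validated
  partners, four background predicted, two both-labeled) draw context
  scores from a confident band, fillers from a clearly worse band, so
  selection recovers the planted set for every seed.
* **Edges.** The hub connects at score ≥ 900 cross-group to the two planted
  validated genes and within-group to the two planted predicted genes, so
  the cross-group pass sees a 3-gene hub component that expansion grows to
  5. Four background components are single cross-group edges. All noise
  edges score below 900, so the confidence filter removes exactly them.
* **Pathways.** Eight neuro-named planted pathways all contain the hub.
  Three "core" sets hold the hub + planted validated genes (+1 predicted) —
  over-represented in the hub's component in both passes; five "expansion"
  sets hold the hub + planted predicted genes (+1 validated) — their
  cross-group overlap is too small to survive Bonferroni, but after
  expansion they overlap the component almost entirely. Twelve
  neutral-named decoys partition a shuffled pool of all catalog plus filler
  genes, fixing the universe at 70 genes for every seed. With N = 70 the
  Bonferroni-adjusted outcomes are determined by construction (the planted
  before/after counts are 3 and 8, delta 5, for any seed), which is why
  planted-hub recovery is exact across seeds rather than merely frequent.
* **Images.** Colocalization pairs place a uniform-intensity Arg1 block and
  an Iba1 support covering a requested fraction of it; the noiseless
  thresholded M2 equals that fraction by pixel counting. Truth is computed
  on the noiseless layer; with Gaussian noise of sd 5 on 8-bit-scale levels
  the measured M2 stays within ~0.05.
* **Morphology.** Ameboid cells are octagonal filled blobs (flat and
  45-degree edges keep the pixel union near its own convex hull); ramified
  cells are a small soma with four one-pixel processes. Cells sit on a
  non-touching grid; all geometry is integer-grid and seed-deterministic.

What the fixtures do **not** emulate: realistic STRING degree
distributions, pathway-size distributions, microscopy point-spread or
shot noise, and biological gene identity (symbols are synthetic; the hub is
literally named `MYD88H`). Passing tests therefore demonstrate correctness
of the machinery and recoverability of planted structure, not performance
on real databases — headline counts from any real analysis (numbers of
components or of enriched pathways) depend on database versions and are not
reproduced here.

## Quantification conventions

* **Lesion volume.** `100·(contra − (ipsi − lesion))/contra` — linear in
  the lesion volume with slope `100/contra`; edema (ipsi > contra) deflates
  the naive lesion/contra ratio.
* **2^−ΔΔCt.** `ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target −
  Ct_ref)_control`; swapping sample and control inverts the fold change.
* **Standard curve.** Least-squares `Ct = slope·log10(copies) + intercept`;
  exact doubling chemistry gives slope `−1/log10(2) ≈ −3.3219`. Inversion
  is `10^((Ct − intercept)/slope)`.
* **Colocalization.** Pearson is the plain sample correlation over (masked)
  pixels and errors on constant channels. Manders M2 defaults to the
  thresholded convention: numerator sums Arg1 intensity where both channels
  exceed their thresholds (50 for Arg1, 100 for Iba1, 8-bit assumed),
  denominator where Arg1 does; `require_both=False` switches to the
  unthresholded-partner variant (numerator gated by Iba1 only, denominator
  total Arg1), since reports rarely state which variant a plugin used.
* **Shape descriptors.** Perimeter is the exposed pixel-edge count
  (`4·area − 2·adjacent pairs`) — exact and deterministic, but larger than
  anti-aliased estimators on smooth shapes, so circularity
  (`4π·area/perimeter²`; 10×10 square: exactly π/4) should be compared
  within-convention only. Solidity divides by the exact convex-hull polygon
  area of the pixel-square union. Eccentricity and the major axis come from
  the standard second-moment (inertia-tensor) ellipse; roundness is
  `4·area/(π·major²)` and compactness `equiv_diameter/major`.

## Determinism and numerics

All random generation uses one named NumPy `default_rng` per fixture seeded
explicitly; no global state. Component, enrichment and candidate orderings
are total (size/p-value, then lexicographic), so `report.json` is
byte-identical across reruns. Enrichment p-values are computed in log space
and clipped to [0, 1]; k = 0 returns exactly 1.

## Problem sizes

The shipped defaults (60 predicted genes, 70-gene universe, 20 pathways,
100-seed recovery sweeps, 1,000-graph coarsening checks, N ≤ 12 enumeration
grids) were chosen so the whole suite and the reproduction script each run
in seconds on one CPU while still exercising every code path; all scale
parameters are plain function arguments for larger runs.

## Known limitations

* Keyword classification is lexical; a pathway named without any anchor
  term is invisible to it (no ontology traversal).
* The Bonferroni family covers only pathways with non-zero overlap, which
  is anti-conservative relative to counting all pathways; the global-family
  option is stricter.
* Identifier handling assumes symbols already harmonized or an alias map;
  no web lookups.
* Whether expansion should admit validated–validated edges is ambiguous in
  the workflow this follows; both behaviors are implemented and the default
  admits both within-group kinds.
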