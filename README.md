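# mirprio

Network-based prioritization of microRNA targets, built around the analysis
used to single out MyD88 — the canonical adaptor of toll-like receptor (TLR)
and IL-1 innate-immune signaling — as the top candidate target of a
stroke-responsive miRNA, plus the quantification formulas that surround such
a study (MRI lesion volumetry, qPCR, colocalization, microglial
morphometrics).

## Who this is for

Computational biologists who have, for one miRNA of interest:

* a table of **predicted** targets with a TargetScan-style context score
  (more negative = more confident),
* a table of **experimentally validated** targets (miRTarBase-style),
* a STRING-style table of protein–protein association edges with a combined
  score in [0, 1000],
* a pathway collection in GMT format,

and who want a ranked, reproducible shortlist of candidate genes rather than
two flat target lists.

## The method

1. **Catalog.** Keep the most confident 15% of predicted targets
   (`ceil(0.15·n)` by ascending context score) and all validated targets;
   label every gene PREDICTED, VALIDATED, or BOTH.
2. **Cross-group network.** Keep high-confidence edges (combined score
   ≥ 900) whose endpoints sit in opposite groups, and split the graph into
   connected components.
3. **Per-component over-representation.** For each component of size *n*
   (within a universe of *N* annotated genes) and each pathway of size *K*
   overlapping it in *k* genes, the upper-tail hypergeometric probability

   P(X ≥ k) = Σ_{x≥k} C(K, x)·C(N−K, n−x) / C(N, n)

   is Bonferroni-corrected over the pathways tested for that component and
   thresholded at adjusted p < 0.01.
4. **Expansion.** Rebuild the network keeping within-group edges as well
   (which can merge components), and repeat the enrichment.
5. **Prioritization.** Classify enriched pathways as
   neuroinflammation-associated by keyword match (toll-like receptor, TLR,
   MyD88, interleukin, NF-kB, ...); the expanded component that gains the
   most neuro pathways relative to the cross-group components it absorbed is
   the prioritization target, and its genes are ranked by enriched-neuro-
   pathway membership, then degree, then symbol.

The quantification module implements the study-readout formulas exactly:
edema-corrected lesion volume percent, 2^−ΔΔCt relative expression,
standard-curve absolute copy number, Pearson and thresholded Manders M2
colocalization, and a nine-descriptor cell-shape panel.

## Worked example

Generate a planted synthetic fixture and run the pipeline on it:

```sh
mirprio fixture --seed 7 --out fx
mirprio run --predicted fx/predicted.tsv --validated fx/validated.tsv \
            --edges fx/edges.tsv --pathways fx/pathways.gmt --out out
```

which prints

```
report written to out
prioritized gene: MYD88H
```

`MYD88H` is the fixture's planted hub. `out/report.json` shows why: the
hub's component has `n_neuro_before: 3, n_neuro_after: 8, delta: 5` — after
expansion it gains five enriched neuro-named pathways while every other
component's delta is 0 — and `out/candidates.tsv` ranks the component:

```
rank  gene    component_id  n_enriched_neuro_pathways  degree
1     MYD88H  0             8                          4
2     G0001   0             7                          1
...
```

Standalone quantification, e.g. the lesion-volume formula on hemisphere
volumes (contralateral 100, ipsilateral 110, lesion 30 mm³):

```sh
$ mirprio quant lesion 100 110 30
20.0000
$ mirprio quant ddct 25 20 26 20
2
```

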