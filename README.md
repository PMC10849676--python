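# bmptargets

Genome-wide identification of direct BMP-signaling target genes, as a
reproducible pipeline over synthetic data with planted ground truth.

In anthozoan cnidarians such as the sea anemone *Nematostella vectensis*,
a BMP-signaling gradient read out by nuclear pSMAD1/5 patterns the
secondary ("directive") body axis. Finding the genes that pSMAD1/5 binds
directly requires a chain of bespoke computations around standard ChIP-seq
tooling: per-lane peak calling with cross-lane **quantile normalization of
peak heights**, joining peaks across replicate lanes within **100 bp**,
filtering on **enrichment ≥ 10** and **overall score ≥ 80**, nearest-TSS
gene association, enhancer intersection and BRE-motif flagging; three-way
**reciprocal-best-BLAST-hit** orthology (bit-score metric, e-value ≤ 1e-5,
frog homeolog `.S`/`.L` collapse); spatial quantification of the signaling
gradient (nuclear **arc profiles** with LOESS + 99% confidence bands, and
binned **embryonic-axis profiles**); and ChIP-qPCR **ΔΔCt** fold
enrichment with Welch t-tests. This package implements that chain as a
tested library + CLI, with a seeded synthetic-data generator standing in
for the sequencing and imaging data.

## The statistics at the core

* **Peak score.** For a candidate window that beats a Poisson upper tail
  on the genome-wide midpoint rate, each called peak carries a height
  `H` (fragment midpoints per million within the summit-centred window),
  an enrichment `E = (H + p) / (H_ctrl + p)` over the library-size-scaled
  input control, a distribution score `D = 1 − |L − R| / (L + R)`
  penalising summit asymmetry, and an overall score `S = H·D`. Heights
  are quantile-normalized across lanes (rank *r* in every lane receives
  the across-lane mean of the *r*-th order statistic).
* **Orthology.** `(a, b)` is a reciprocal best hit iff `b` is `a`'s
  highest-bit-score hit and vice versa, after discarding hits with
  e-value > 1e-5; "shared by all three species" is reported both
  triangle-closed and chain-linked.
* **Arc profile.** Nucleus *i* of *N* (ordered from the strongest-signal
  midpoint) sits at `θᵢ = (i/N)·π`; intensities are normalized to the
  upper quartile of the pooled control + experiment values and smoothed
  by local-linear LOESS (tricube weights, span 0.75) with a pointwise
  t-based 99% confidence band.
* **qPCR enrichment.** `fold = 2^−(ΔCt_target − ΔCt_IntA)` with
  `ΔCt = Ct_IP − Ct_input`, referenced to the intergenic *IntA* region;
  conditions are compared by the ratio of mean folds and a two-tailed
  Welch t-test.

## Worked example

Simulate a study (planted qPCR folds: chordin 1.82 in transgenic vs 0.15
in wild-type embryos, gremlin 0.27 vs 0.35; Ct noise 0.05 cycles), then
recompute the enrichments:

```bash
$ bmptargets simulate --out simout --seed 2
$ bmptargets qpcr enrich --ct simout/qpcr_ct.tsv --out simout/enrich.tsv
chordin: transgenic/wildtype ratio=12.68 t=30.440 p=7.26e-05
gremlin: transgenic/wildtype ratio=0.87 t=-4.166 p=8.89e-03
```

The chordin site is strongly enriched in transgenic embryos relative to
wild type (a ~12-fold ratio, highly significant), while the gremlin site
is depleted in both conditions with no meaningful difference — the
signature of a factor binding the repressed target but not the activated
one.

The full pipeline (call → quantile-normalize → join → filter → annotate →
overlap → classify → gradient → qPCR) over the default two-stage
synthetic study:

```bash
$ bmptargets run --seed 1 --out out/
```

prints a JSON report; with seed 1 it contains, per stage, 12 significant
joined peaks mapping to 12 distinct target genes (4 and 7 of them inside
enhancers at the two stages), a stage overlap of 4 shared target genes,
and an orthology section with 6 ortholog groups conserved in ≥ 2 species
of which 4 close a three-species RBH triangle — exactly the planted
truth. `out/manifest.json` records SHA-256 checksums of every
intermediate; reruns with the same seed are bit-identical.

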