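# Methods

This note documents the models, parameter choices and numerical
conventions behind `bmptargets`, and what the synthetic study does and
does not establish about real data.

## Peak calling

Paired-end fragments are reduced to midpoints (`floor((start + end)/2)`,
0-based half-open intervals throughout). A sliding window of `W = 300 bp`
advancing in `W/4` steps counts midpoints per window; a window is a
candidate when its count exceeds the Poisson upper tail (`p < 1e-3`) for
the genome-wide rate `λ = library_size · W / genome_length`. Overlapping
candidate windows merge, and the summit is the midpoint position of
maximal local midpoint density (ties resolved to the middle of the
plateau), refined to the median midpoint within the summit-centred
window. The refinement matters: the raw density argmax wanders by up to
±80 bp between replicate lanes at moderate coverage, which would defeat
the 100 bp cross-lane join distance; the median midpoint has a standard
error of a few bp.

Scores per peak:

* `H` — midpoints in `[summit − W/2, summit + W/2)` per million library
  fragments;
* `E = (H + p)/(H_ctrl + p)` with pseudocount `p = 0.5` and `H_ctrl`
  computed identically from the input control and its own library size.
  Control scaling is per-million only — no local-lambda background — a
  deliberate simplification relative to peakzilla-style local
  backgrounds;
* `D = 1 − |L − R|/(L + R)` from midpoint counts left/right of the
  summit inside the window. `L + R = 0` cannot occur (the summit is a
  midpoint); `D = 0` (fully one-sided mass) drops the peak as not a
  point source;
* `S = H·D`.

A candidate-stage enrichment floor (`E ≥ 2`) removes windows that beat
the Poisson test through chance clustering also present in the control.
The published significance thresholds — enrichment at least 10, overall
score at least 80 — are applied later, inclusively, to cross-lane means.

## Quantile normalization of peak heights

Within each lane, peaks are ranked by `H`; rank *r* receives the
across-lane mean of the *r*-th order statistic. Unequal lane sizes are
handled by linear interpolation of the mean quantile function with nodes
at `p = (r − 0.5)/n`; equal lane sizes reduce exactly to the textbook
mean-of-order-statistics rule. Ties share the mean of their would-be
values. `S` is recomputed from the normalized `H`. Lanes without peaks
pass through unchanged with a warning. Normalization is applied to final
per-lane peak lists, before joining; whether the original analysis
normalized before or after candidate filtering is not determinable from
its description, so the choice is documented here as this package's
convention. For equal lane sizes the procedure preserves the pooled mean
and is idempotent; with ties or unequal sizes idempotence is approximate.

## Joining, filtering, gene association

Joining is single-linkage clustering of summit positions per chromosome:
consecutive sorted summits at most 100 bp apart share a cluster. Summit
(not span) distance is used because peak callers of this family report
summits and 100 bp reads naturally as summit spacing. A joined peak needs
support from ≥ 2 distinct lanes by default (the study used biological
triplicates but states no support rule; configurable). The consensus
summit is the floor of the member-summit mean; `H̄`, `Ē`, `S̄` are member
means, and the filter keeps `Ē ≥ 10` and `S̄ ≥ 80` (inclusive).

Gene association replaces the study's manual curation with a
deterministic rule: a summit inside a gene span is assigned to that gene
(nearest TSS among several); otherwise the nearest TSS within 20 kb wins;
exact ties break to the lexicographically smaller gene id; otherwise
unassigned. Signed distances are negative upstream of the TSS on the
gene's strand. Enhancer overlap means ≥ 1 bp intersection in 0-based
half-open coordinates (bedtools semantics; verified against bedtools in
the test suite).

## Motif scanning

A 4 × L position frequency matrix is converted to log₂ odds against a
uniform background; both strands are scanned at every position; `N`
scores 0 bits; zero-count cells score −∞ (no pseudocount is added by
default — callers wanting soft matrices should pass pre-smoothed
counts). The reverse strand uses the reverse-complemented matrix so
reported positions are forward-strand starts. Motif *discovery* is out of
scope; the scanner only flags peaks given a PFM.

## Orthology

Hit tables are standard 12-column tabular alignment output; only query,
subject, e-value and bit score are consumed. Terminal `.S`/`.L` homeolog
suffixes (allotetraploid frog subgenomes) are stripped first, keeping the
best-bit-score row per collapsed (query, subject) pair. Best hits use bit
score, with ties broken by lower e-value then lexicographic subject id —
deterministic and order-independent. Reciprocal best hits require
mutuality and are one-to-one per species pair.

For three-way target overlaps, a graph connects target genes that are RBH
partners and targets in both species, after restricting to genes with
post-filter hits in both other species (the filter is skipped when raw
hit tables are unavailable, since an absent RBH edge does not imply
absent hits). "Conserved in ≥ 2" counts connected components spanning
≥ 2 species. "Shared by all three" is reported under two rules side by
side — triangle-closed (some gene triple with all three pairwise RBH
edges) and chain-linked (a component touching all three species) —
because published three-way counts can follow either convention.

## Gradient quantification

**Arc profiles.** Nuclei are ordered from the strongest-signal midpoint;
nucleus *i* of *N* sits at `θᵢ = (i/N)·π`, so the first nucleus maps to
`π/N` (not 0) and the last exactly to `π`. Intensities are in arbitrary
units; for a control-experiment pair, all replicates and both conditions
are pooled and divided by the pool's 0.75 quantile (linear-interpolation
definition). "Upper quantile" is ambiguous in common usage; the upper
quartile is the default and the quantile is configurable.

**LOESS.** Local linear regression with tricube weights on the
`ceil(span·n)` nearest points (span 0.75, degree 1 — standard choices),
evaluated on a 100-point grid up to `π`. The bandwidth is the k-th
nearest distance, matching the classical lowess rule, so
`statsmodels.lowess(…, it=0)` reproduces the curve to machine precision
(used as an independent oracle in the tests). The pointwise confidence
band for the mean (level 0.99) uses the smoother weights `l(x)`:
`fit ± t_{ν} · σ̂ · ‖l‖`, with σ̂² the locally weighted residual variance
bias-corrected on the Kish effective sample size and `ν = n_eff − 2`
local degrees of freedom. Constant noise-free input yields a flat fit
with zero band width. Nuclei are pooled across embryos of a condition
rather than averaging per-embryo fits.

**Axis profiles.** A masked 2-D intensity image (ventral at left,
orientation and maximum projection upstream) is reduced to per-column
means over masked pixels, mapped to percent of the masked extent, and
averaged (pixel-count weighted) into 0.5% bins — 200 bins, of which the
first and last 5% are discarded because few pixels make those averages
unreliable, leaving 180. Background subtraction averages the supplied
no-primary-antibody control profiles bin-wise before trimming. Empty mask
columns are skipped and counted.

## qPCR enrichment

`ΔCt = Ct_IP − Ct_input` per region; `fold = 2^−(ΔCt_target − ΔCt_IntA)`
against the intergenic reference region, paired by replicate within a
condition. The enrichment formula is the standard input-normalized ΔΔCt
convention; the original analysis names the reference region but not the
algebra. Conditions are compared by the ratio of mean folds and a
two-tailed Welch t-test (pooled-variance available by flag). Normality is
assumed, not tested — mirroring small-n ChIP-qPCR practice — with a
warning below five replicates; two identical zero-variance groups return
`p = 1` by convention. DE classification is inclusive at `padj ≤ 0.05`
(the source prints both `<` and `≤`; the inclusive reading is used) and
`2xDE` additionally requires `|log₂FC| ≥ 1`. Functional-category
fractions are compared against a seeded uniform draw of 100 background
genes without replacement.

## Synthetic data: what it emulates, and what it does not

All generators derive from one root seed through fixed named substreams,
so adding a generator never perturbs another and identical configurations
give byte-identical files.

* **ChIP fragments** place midpoints Normal(summit, 40 bp) around each
  planted summit and uniformly elsewhere; fragment lengths are
  Normal(200, 40) clipped at 50 bp. Defaults: a 2 Mb genome in 2
  chromosomes, 20 summits of 2000 fragments-per-million, 3 ChIP lanes of
  200k fragments plus matched 200k-fragment inputs. These strengths put
  enrichment comfortably above the E ≥ 10 rule (≈ 13–18 at this
  coverage) without sitting on the boundary. There is no sequence, no
  read-level error, no GC or mappability structure, and no local
  background variation — so passing recovery tests demonstrates the
  correctness of the calling/joining/filtering logic, not robustness to
  the artefacts of real libraries.
* **Annotation** places a gene 1–5 kb from each planted summit with its
  body pointing away (an unambiguous nearest-TSS truth), fills decoy
  genes without overlap, and covers a configurable fraction of summits
  with enhancers.
* **Nuclei** follow `base + amp·(1 + cos θ)/2 + N(0, σ)` with amp 10,
  base 1, σ 0.5, 10 embryos × 60 nuclei; knockdown shapes divide the
  amplitude by 4 (flattened) or widen the plateau via `cos(θ/2)`
  (expanded). Real nucleus segmentation, embryo registration and
  camera effects are upstream and unmodelled.
* **Hit tables** make each planted triple mutual best hits (bit 500,
  e-value 1e-50) and add two adversarial decoys per gene and direction:
  better e-value with lower bit score (bit score must decide) and higher
  bit score with e-value 1e-4 (the ceiling must filter). A leading
  fraction of frog ids is emitted as `.S`/`.L` duplicates.
* **qPCR plates** fix the reference ΔCt at 4 cycles and set target IP
  Cts so ΔΔCt reproduces the planted folds exactly before Normal(0,
  0.05) cycle noise; with quadruplicates this recovers a planted
  12.13-fold condition ratio within 20% in essentially every seed.

## Pipeline and problem sizes

The end-to-end run executes simulate → call → quantile-normalize → join →
filter → annotate → enhancer-intersect → DE-classify → orthology →
gradient → qPCR in fixed order, writes every intermediate with a SHA-256
manifest, and is bit-identical under rerun. Stage-specific fragment sets
reuse the shared annotation; motif flagging in the report requires a
user-supplied FASTA and PFM (the generator emits no sequence) and is
otherwise reported as null. The default study sizes (2 Mb genome, 200k
fragments per lane, 600 nuclei per condition, 50-seed qPCR replication)
keep a full pipeline run and the acceptance script within a few seconds
on one CPU while leaving all recovery margins wide.

## Known limitations

* No FDR control by chip/control swapping, no broad-peak mode, no
  fragment-size estimation — the caller targets point-source binding.
* Quantile normalization assumes lanes measure the same peak population;
  a lane with many extra spurious peaks would distort the shared
  distribution.
* RBH orthology under-counts paralog families by construction; the
  triangle/chain distinction only partially compensates.
* The LOESS confidence band is pointwise, not simultaneous; overlaying
  bands of two conditions is descriptive, not a formal test.
* The DE table is consumed, not computed: no size factors, dispersion
  estimation or shrinkage are reimplemented.
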