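# Methods

## The classification model

A bacterial rRNA operon is modelled as an ordered pair of 16S and 23S
genes on the same replicon and strand.  Within each replicon all complete
16S/23S features are sorted by start coordinate (ties broken by end, then
type, so the ordering is deterministic) and scanned once from left to
right.  A sense 16S immediately followed by a sense 23S forms a unit; an
antisense 23S immediately followed by an antisense 16S forms a unit (the
same operon read on the opposite strand: transcription runs right-to-left,
so the 23S comes first in coordinate order).  "Immediately" is strict — an
intervening rRNA of the wrong type or strand breaks the pair and the
candidate becomes a single copy.  Allowing skips would create ambiguous
many-to-many pairings; a single ordered pass keeps the assignment unique
and order-independent.

The internal transcribed spacer (ITS) is the gap between the two gene
bodies, exclusive of both: `downstream_start − upstream_end − 1`.  On a
circular replicon, an unconsumed trailing/leading pair that is valid
across the origin is joined with the wrapped gap
`(L − upstream_end) + (downstream_start − 1)`.  This wraparound handling is
what distinguishes a genuinely linked operon split by the arbitrary origin
of the deposited sequence from an unlinked one: on a 3,504,252 bp circle
with a plus-strand 16S ending at 3,503,539 and a plus-strand 23S starting
at 437, the naive distance exceeds 3 Mb but the wrapped ITS is 1149 bp —
a linked operon.

A unit with ITS strictly over 1500 bp is an **unlinked** operon (1500
itself is linked).  Genome status: *linked* when every unit is a linked
pair; *unlinked* when no linked pair exists; *mixed* otherwise;
*undetermined* when the genome has no 16S/23S features at all.

**Singles policy.**  Lone 16S or 23S copies count as unlinked evidence.  A
genome whose 16S and 23S sit on opposite strands or on different replicons
is the canonical unlinked arrangement, yet it yields no pair under the
scan; counting singles as linked or neutral would misclassify it.  The
policy is fixed and echoed in the output header
(`singles_policy=unlinked`).  Pairing never crosses replicons.

Annotated features that themselves span the origin (GFF end < start) are
rejected with an explicit error rather than guessed at; negative gaps from
overlapping annotations are clamped to 0 with a warning.

## In silico PCR screening

Annotated counts are cross-validated against primer-based recovery before
classification, to remove genomes whose rRNA annotation is unreliable
(misassembly, dropped predictions, primer-site variation).

* Primers: 16S = 27F `AGRGTTYGATYHTGGCTCAG` / 1492R `TACCTTGTTAYGACTT`;
  23S = 11a `GGAACTGAAACATCTAAGTA` / 2241r `ACCRCCCCAGTHAAACT`.  The 27F
  sequence is the combined degenerate form; its two source variants are
  not searched separately.
* Matching: a primer position matches any base in its IUPAC set; a genome
  base outside {A,C,G,T} always counts as a mismatch.  The mismatch budget
  is an absolute count applied to each primer independently (not a
  percentage, not summed over the pair).
* Products: a forward-orientation forward-primer site paired with a
  downstream reverse-orientation reverse-primer site (and the symmetric
  arrangement for minus-strand products), kept only when strictly inside
  the length window — (1000, 4000) bp for 16S, (1000, 6800) bp for 23S.
* Locus counting: amplicons on one replicon with ≥ 50 % reciprocal overlap
  merge into one locus (transitively).  No published dedup rule exists for
  this step; reciprocal 50 % is conservative and deterministic.
* Escalation: per-type (n16S, n23S) counts are compared component-wise —
  never as totals, since equal totals can hide discordant per-type
  profiles — first at two mismatches, then at four; genomes still
  discordant are excluded from all downstream tables but retained in
  `screening.tsv`.  The same symmetric equality rule applies in both
  directions (more annotation than PCR, or the reverse).

The search runs on the linearized sequence, so no origin-spanning product
is generated; a genome whose only rRNA crossed the origin would fail
concordance and be excluded.  Documented limitation.

## Genomic features

Per genome: total size summed over all replicons in the assembly
(chromosomes and plasmids); whole-genome AT fraction, with ambiguity codes
contributing to the denominator only; 16S copy number; mean 16S/23S gene
lengths from annotation coordinates; mean AT of the 16S gene sequences
(reverse-complemented for antisense copies — a no-op for AT content, kept
for sequence fidelity); and a symbiont label joined from an external
genome→{yes,no} table, `unknown` when absent.

## Statistics

* **Kruskal–Wallis** (tie-corrected) for three-class contrasts, with
  **Dunn's** pairwise z-tests on mean ranks.  No post-hoc adjustment is
  canonical for this design, so Holm is used (conservative, uniformly
  valid) and named in the output column (`p_holm`).
* **Welch's t** (Satterthwaite degrees of freedom) for two-class
  contrasts; **one-way ANOVA + Tukey HSD** where a parametric multi-group
  comparison is wanted.  Degenerate all-equal input reports F = 0 rather
  than erroring.
* **Paired t by category**: functional category counts are compared as
  per-phylum group means, paired across linkage status within phylum —
  phyla are the pairing unit, which controls the dominant taxonomic
  signal.  The pipeline consumes count tables (e.g. eggNOG-mapper COG
  counts, HMMER Pfam RNase counts) as TSV; it does not run the annotators.
* **PCA** on columns standardized to zero mean and unit variance
  (ddof = 1), so explained variances are the correlation-matrix
  eigenvalues; constant columns are dropped with a warning.
* **PGLS** under Brownian motion: V[i,j] is the shared root-to-MRCA path
  length on the supplied Newick tree; b = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y via Cholesky
  whitening; residual variance RSS/(n−2); two-sided t on n−2 df.  The
  model is intercept + a single predictor (linkage coded 0/1); no
  Pagel's-λ or OU extensions.  On a star tree this reduces exactly to OLS,
  and scaling all branch lengths cancels out of the slope and t — both are
  tested, alongside an explicit matrix-algebra oracle and a
  parameter-recovery simulation (known slope recovered within 3 SE in
  ≥ 95 % of 200 Brownian replicates).

## Synthetic data: what it emulates and what it does not

The generator plants rRNA gene templates on pseudo-random background
sequence.  Templates carry exact realizations of the primer sites at their
ends (interior uniform at a configurable AT fraction), so a genome
amplifies cleanly unless a failure is planted: `primer_site_mutations`
substitutes a chosen number of positions inside a named primer's site with
bases outside the IUPAC set (guaranteeing exactly that mismatch count);
`partial_annotations` flags features partial in the GFF only;
`annotation_errors` drops a real feature from, or adds an unsupported
feature to, the GFF.  Units are separated by ≥ 2 kb, which — given the
product-length windows — guarantees cross-unit primer pairings are
filtered out, so each planted gene is exactly one locus.

The background is *sanitized*: any window matching a primer at ≤ 4
mismatches outside a planted site is resampled.  This matters because the
16–17 nt reverse primers match uniform random sequence at budget four at a
rate (~3×10⁻⁵ per window) that would otherwise scatter spurious loci
through a multi-hundred-kb cohort and make screening outcomes depend on
the seed.

Truth manifests are derived from layout intent; the generator additionally
re-derives units with its own compact implementation of the pairing rules
and refuses specs whose layouts would create unintended adjacencies (e.g.
two lone antisense copies that happen to pair).  Round-trip tests
therefore exercise file serialization plus two independent codings of the
rules.

**Cohort study conditions** (`CohortParams`): class AT means 51.4 / 50.1 /
64.9 % for linked / mixed / unlinked genomes; genome-size means 386 / 300
/ 168 kb — the observed class contrast scaled to one tenth so cohorts
generate and screen in seconds (the mixed-class size, unreported anywhere,
is set between the extremes); 2–4 operon copies in linked genomes vs 1–2
in unlinked; 16S gene AT slightly higher and gene lengths slightly shorter
in unlinked genomes; symbiont probability 0.75 for unlinked vs 0.5
otherwise.  Default suite/acceptance runs use 3–10 genomes per class.

What passing synthetic tests do **not** show about real data: the
generator has no rRNA secondary structure, no sequence homology between
gene copies, no tRNAs inside the ITS, no pseudogenes, no assembly gaps,
and uniform base composition — so it validates the *logic* (coordinate
arithmetic, pairing, screening, statistics), not robustness to the full
messiness of public assemblies.  Corpus-scale results (hundreds of
unlinked genomes, exact class means) require the real genome corpus and
are out of desk-scale reach; the synthetic cohort recovers the *direction*
of the class contrasts, and tests assert exactly that.

## Numerical and design choices

* Coordinates are GFF3-native (1-based, inclusive) everywhere.
* rRNA type resolution: case-insensitive "16S"/"23S" in product/Name/gene
  attributes; 5S and non-matching features dropped silently.  Partial
  detection: `partial=true` (any case) or a Note containing "prediction is
  too short".
* Topology default is circular (complete bacterial chromosomes
  predominantly are); the default is logged, and an override map wins over
  the file with a warning on contradiction.
* Length-window bounds are strict inequalities; the ITS threshold is an
  inclusive "≤ 1500 is linked".
* All pipeline outputs are TSV with fixed column order; reruns on the same
  inputs are byte-identical (the run log, which carries timestamps, is the
  only exception).
* Seeds: every stochastic step (generation, simulations) takes an explicit
  seed; child seeds are drawn below 2³¹.

## Known limitations

* No origin-spanning amplicons (see above) and no origin-spanning
  annotated features.
* No thermodynamic primer model (no Tm, no 3′-end weighting) — matching is
  purely combinatorial, as a mismatch-budget search.
* Singles cannot be distinguished from pairs broken by missing annotation;
  screening catches the sequence-level cases, not annotation conventions
  that systematically omit one gene.
* PGLS assumes the supplied tree and Brownian covariance are correct; no
  model selection is attempted.
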