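# Methods

## The allele-ratio model

A strain carrying a recessive lethal mutation over a balancer has a fixed
copy configuration of the balanced region: `m` mutant and `w` wild-type
copies per balanced animal (duplication: m=2, w=1; translocation: m=1, w=1).
When a fraction `c` of the sequenced DNA comes from balancer homozygotes —
which carry two wild-type copies of the region and no mutant copy — linear
pooling of DNA gives the expected variant allele frequency

```
VAF(m, w, c) = m(1 − c) / ((m + w)(1 − c) + 2c)
```

This is the minimal mixture model: it assumes equal ploidy and equal
per-copy sequencing efficiency across genotypes, no reference-mapping bias,
and no somatic mosaicism. At c=0 it reduces to 2/3 and 1/2 for the two
balancer types; for a translocation it simplifies to (1 − c)/2, strictly
decreasing in `c` — which is why homozygote contamination makes
translocation-balanced screens progressively harder (the expected VAF drifts
toward the bottom of the selection window).

The contamination fraction is left a free parameter: screens differ in
whether balancer homozygotes are viable and fertile enough to accumulate
before DNA extraction, and no quantitative estimate of that fraction exists
for the historic strain stocks. `c = 0` is the default.

## Filtration cascade

Four per-call predicates, reported in the order VAF window → MMP →
background → strand support:

| filter | rule | default |
|---|---|---|
| VAF window | low ≤ VAF ≤ high, inclusive at both bounds | 0.40–0.90 (duplication), 0.20–1.00 (translocation) |
| MMP | drop calls whose exact (chrom, pos, ref, alt) is in the population-variant database | allele-exact matching |
| background | drop calls recurring in ≥ `min_recurrence` distinct strains, from all strains | 2 |
| strand support | keep calls with ≥ `min_reads_per_strand` alt reads on each strand | 8 |

Three choices here were genuinely open and are fixed as package conventions:

* **Window bounds are inclusive.** "Between 40 and 90%" has no bracket
  semantics; inclusive bounds are the weaker (more permissive) reading.
* **MMP matching is allele-exact**, not position-only: a different alternate
  allele at a known variable site is new information, not a known variant.
* **Background recurrence is computed on the raw cohort**, before any other
  filter. This makes every predicate a function of the raw input, so the
  final table is the intersection of the four filters and the cascade is
  order-independent (verified by a permutation test over all 24 orders).
  The alternative — recurrence counted after the VAF window — would make
  the output depend on filter order for calls near the window boundary.
* **The strand threshold applies to alt-supporting reads**, not total
  per-strand coverage: it is the *variant* that must be supported in both
  directions.

The strand-support rule is quantitatively the binding constraint at screen
coverage. With site depth Poisson around mean `D` and true VAF `v`, the
forward and reverse alt counts are independent Poisson(`Dv/2`); at D=30,
v=2/3 each strand expects 10 alt reads against a threshold of 8, and at
D=31, v=1/2 each expects 7.75. A substantial minority (duplication) to a
majority (translocation) of true lethal sites therefore fail the ≥8/strand
rule at these depths — a property of the screen design itself, which the
pipeline reports honestly rather than hides. The recovery rates printed by
`analysis/03_identify_genes.py` and measured in the acceptance suite
quantify this.

## Consequence annotation

Each SNV is classified per overlapping transcript by re-translating the
affected codon with the standard nuclear code:

* stop gained → `nonsense`; first codon no longer ATG → `start_loss`
  (ranked as its own class, since ATG→ATA alleles behave differently from
  ordinary missense); reference stop changed → `stop_loss`; amino acid
  preserved → `synonymous`; otherwise `missense`.
* Splice sites are the canonical 2-bp GT donor / AG acceptor dinucleotides
  flanking CDS-containing exons; nothing wider is flagged.
* Severity order for reporting:
  nonsense > splice > start_loss > stop_loss > missense > synonymous > utr
  > intronic.
* `relative_position` = CDS position / CDS length; for a stop gain this is
  the truncation fraction used by the N-terminal statistic.

Correctness is established against a brute-force oracle: an independent
hand-written codon table re-translates random mini-genes on both strands and
must reproduce consequence and amino-acid change exactly.

## Candidate identification

Per gene, five boolean evidence lines: `zone_concordant` (a supporting
strain's genetically mapped zone contains the variant), `second_allele`
(≥2 strains of one complementation group hit the gene), `mmp_consistent`
(missense records present, chain-terminating records absent; genes missing
from the database fail with reason `no_data`), `known_lethal_annotation`,
and `validated_experimentally` (user-supplied). The tier rule is a
transparent conjunction/disjunction:

```
identified_high_confidence  ⇔  zone_concordant AND (second_allele OR
    mmp_consistent OR known_lethal OR validated)
```

The original analyses applied these lines narratively; a formal rule is
needed for a pipeline, and this is the weakest rule that still requires
mapping concordance plus one independent line. Genes hit outside their
strain's mapped zone stay `candidate` — zone assignments can be wrong, so
mismapping is surfaced, not discarded. A multi-strain complementation group
whose alleles hit only disjoint genes is a conflict: its genes are demoted
to `candidate` and logged.

## The synthetic cohort generator

`simulate_reference` builds ACGT chromosomes with non-overlapping,
intron-containing gene models (CDS starts ATG, ends with a stop, no internal
stop, GT/AG introns; 1-based closed coordinates throughout, matching
VCF/GFF3). The first chromosome is the balanced region, subdivided into
mapping zones whose boundaries fall between genes.

`simulate_cohort` draws, per strain, exactly one lethal coding SNV in a
balanced-region target gene (EMS-like transitions), with

* site depth ~ Poisson(mean depth); defaults 25× (duplication screens) and
  31× (translocation screens), the two study designs' mean coverages;
* alt reads ~ Binomial(depth, expected VAF); strand split
  ~ Binomial(alt, 1/2);
* `pair_fraction` of target genes hit in two strains (two independent
  alleles, one complementation group); default 0.5, the two real screens'
  pooled ratio — the analysis drivers use the per-screen values 6/43 and
  40/46;
* `n_background` variants shared by ≥2 strains at identical coordinates
  (the shared starting strain), plus Poisson(3) strain-private neutral
  calls at uniformly drawn true VAFs;
* an MMP-like database giving every gene missense records but withholding
  nonsense/splice records from essential (target) genes, with a
  configurable leak rate (default 0).

Lethal and private sites are globally unique across strains, so the truth
classes {lethal, background, private-neutral} partition the cohort exactly;
this is what makes the background-filter exactness check possible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: mapping and calling artifacts (reads are never
simulated), indels and structural variants, depth overdispersion beyond
Poisson, strand bias, linked-variant haplotypes, mismapped strains, and any
positional bias of lethal alleles within genes. In particular, nonsense
sites are drawn uniformly over the CDS, so the N-terminal nonsense-position
statistic is null-distributed on simulated cohorts; the statistic's
machinery (rank statistic, seeded permutation p, calibration) is what is
validated, not the biological effect.

## Trait analyses

* **Conservation**: clade-presence flags N/I/M/F (nematodes; invertebrates;
  mammals; fungi) collapse to categories N-only, N+I+M, N+I+M+F, other.
  The packaged 60-gene table is a curated transcription of the screen's
  identified-gene catalogue.
* **Duplicability**: a gene is a duplicate iff it has a protein pair with
  PID ≥ 50% and e-value ≤ 1e−20 (both thresholds configurable; the
  classification is monotone in the PID threshold).
* **Fisher's exact test** is implemented directly as the two-sided
  hypergeometric tail sum (probabilities ≤ the observed table's, with a
  1e−9 relative tolerance against floating-point ties) and cross-checked
  against exact integer enumeration and `scipy.stats.fisher_exact`.
* **Connectivity**: interactor counts binned 1 / 2–5 / 6–10 / >10; the >10
  (hub) fraction compared between groups by Fisher. Genes with zero
  recorded interactors are excluded from bins and counted separately.
* **Expression**: log2(RPKM + 1) — pseudocount 1 RPKM, declared since the
  source plots leave it unstated; per-stage, per-group medians/quartiles and
  an OLS trend slope over the stage index (undefined with one stage).
* **Window conservation**: 50 alignment columns upstream + target + 49
  downstream, clipped at the ends; per-column identity is the fraction of
  non-reference rows with the reference residue, gaps excluded from the
  denominator; "conserved" at window mean ≥ 0.7 (a declared default for a
  qualitative call).
* **Nonsense position**: per-class mean relative CDS position and a
  two-sided rank-sum statistic with a seeded permutation null (10,000
  permutations by default); classes with <2 observations skip the
  comparison.

## Problem sizes

Desk-scale defaults keep everything fast and deterministic: 100-gene,
two-chromosome genomes of 180–220 kb; cohorts of 20–86 strains; 10-seed
sweeps for recovery estimates; 1,000 replicates for the binomial retention
check; 10,000 sites for VAF-convergence checks. These sizes give
Monte-Carlo errors well inside the tolerances the checks use while keeping
the whole suite in minutes.

## Known limitations

* The contamination model is a single global fraction; real cohorts mix
  per-strain fractions.
* Multi-transcript genes are supported by the annotator but the simulator
  emits one transcript per gene.
* The zone tables generated for simulations are non-overlapping; the
  pipeline accepts overlapping zones (as deficiency maps have) but the
  generator does not produce them.
* Experimental validation enters only as a boolean flag; no modelling of
  rescue or complementation crosses.
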