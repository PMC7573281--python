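# Methods

This note documents the models, defaults and numerical choices behind
`sibstrain`, and what the simulator-based tests do and do not establish.

## The simulated history

The generator (`sibstrain.synthetic_data`) models the breeding design of a
sibling-derived inbred strain pair:

1. **Founders.** One wild-caught pair, heterozygous at every polymorphic
   site. Sites are planted per contig with count ~ Binomial(L, `founder_het_rate`);
   a fraction `indel_fraction` (default 0.1) are short indels of ≤ 6 bp, the
   rest SNVs, and all are stored left-normalized against the reference. Under
   the default `founder_phase="ancestral"`, each founder carries one
   chromosome from each of two diverged ancestral lineages (haplotype 0 all
   reference alleles, haplotype 1 all alternates). This phase structure is
   what makes fixation status a pure function of descent, so the boundaries of
   fixed-difference blocks coincide exactly with recorded crossover
   breakpoints — an assertable invariant. The alternative
   `founder_phase="random"` scrambles which haplotype carries the alternate
   per site; per-site heterozygosity dynamics are unchanged but the block
   invariant no longer holds.
2. **Recombination.** Each meiosis draws a Poisson(`crossovers_per_meiosis`,
   default 1.0 per contig) crossover count with breakpoints uniform on the
   contig and no interference — no genetic map is assumed.
3. **Line founding and inbreeding.** Two disjoint sibling pairs from the
   founder brood seed the two lines; each subsequent generation one
   brother–sister pair is drawn uniformly from a brood of fixed size
   (`brood_size`, default 6 — the value is immaterial to fixation dynamics
   beyond requiring ≥ 4 for the founding split). `generations=g` samples the
   offspring of the pair reached after g rounds of sib mating; `generations=0`
   samples the founder brood itself. An optional pre-separation flock-mating
   phase (`pre_separation_generations`, default 0) is exposed because the real
   lines were intercrossed for some generations before separation, but no
   fidelity is claimed for it.
4. **Sampling.** The default sampling layout follows the study design this
   pipeline is aimed at: 4 DNA samples per strain, skin RNA cohorts of 25
   (JpA) and 30 (JpB), liver cohorts of 6 and 4. `generations` defaults to
   110 (the real lines are at roughly their 110th inbred generation); tests
   use 20–60 to keep a little residual segregation or none, as each test
   requires.

**Heterozygosity oracle.** With both founders heterozygous, the expected
heterozygosity of the founder brood is 1/2, and — by direct enumeration of
the sib-pair cross (P(IBD) = 1/4, P(unlike alleles | not IBD) = 2/3) — so is
that of the next generation. Thereafter the classic full-sib recurrence
H_t = ½·H_{t−1} + ¼·H_{t−2} applies; `expected_heterozygosity(g)` evaluates
it numerically with h(0) = h(1) = 0.5. Its asymptotic decay ratio is
(1+√5)/4 ≈ 0.809 per generation, so after 110 generations fewer than one
site in 10⁴ still segregates.

**Measurement layer.** Two DNA callers independently miss each true site
with their `caller_fn_rates` (default 5 % each) and corrupt individual
genotype calls with probability `genotype_error_rate` (default 0; the
per-call corruption replaces the dosage with one of the other two uniformly).
These rates stand in for the upstream mapping/caller thresholds of real
pipelines, which are out of scope. RNA callsets contain only sites inside
exons of genes whose mean simulated count in that tissue reaches
`rna_expression_floor` (default 10) — a simple proxy for "supported by RNA
sequencing", since no depth rule is defined for callability.

**Expression.** Counts are negative binomial with gene baseline means
log-uniform on `nb_mean_range` (default 20–500), common dispersion
`nb_dispersion` (default 0.1, a typical bulk-RNA-seq value for inbred lines),
and per-sample library factors uniform on `library_factor_range` (default
0.75–1.25). A fraction `de_fraction` (default 0.1) of genes get their
strain-B skin mean multiplied by 2^(±`de_log2fc`) (default ±2); a fraction
`cis_de_fraction` (default 0.25) of those are chosen among genes that already
have a true fixed variant within `cis_window` (3 kb) of the gene span, giving
the cis-linkage stage a planted signal. When fewer cis-eligible genes exist
than requested, the shortfall is filled from the remaining genes. Liver
counts share the baseline means with no planted effect. All randomness flows
from a single seed; identical seeds give byte-identical outputs.

**What the simulator does not emulate:** read-level artifacts (mapping bias,
allele-specific expression, batch effects), selection or new mutation after
founding, sex chromosomes, crossover interference, and realistic gene density
(genes here are sparse multi-exon CDS-only models). Passing tests therefore
demonstrate the correctness of the analysis logic under the stated model, not
robustness to every artifact of real sequencing data.

## Fixed-difference detection

Variants are left-aligned and parsimony-trimmed with the standard
normalization loop (right-trim shared trailing bases, left-extend with
reference sequence when an allele empties, then left-trim shared leading
bases); the operation is idempotent and leaves SNVs unchanged. Multiallelic
records are decomposed to biallelic ones before filtering, with genotypes
carrying a different alternate treated as missing in the per-allele record.
The two-caller intersection keeps sites matching on (contig, pos, ref, alt
set), taking genotypes from the primary callset.

The fixed-difference rule: some allele x homozygous in ≥ 75 % of strain-A
samples and a different allele y homozygous in ≥ 75 % of strain-B samples.
Fractions are computed over genotyped (non-missing) samples — with only 4
DNA samples per strain, a single missing call would otherwise make 75 %
unreachable — and sites with fewer than 2 genotyped samples in either strain
are skipped. "Homozygous for one allele" includes homozygous-reference, so a
site fixed reference in one strain and fixed alternate in the other
qualifies. The rule is evaluated on the DNA samples by default; RNA samples
enter only through the dual-evidence step, which requires the non-reference
allele to be observed in an RNA callset (in a sample of the strain carrying
it, when per-strain RNA sample lists are supplied) — support is read as
allele-level corroboration, not merely any call at the position.

## Effect annotation

The spliced CDS is assembled in translation order (reverse-complemented on
the minus strand). SNVs are classified by translating the affected codon:
start_lost (first codon no longer ATG), stop_gained, stop_lost, synonymous,
missense. Indels use the left-normalized anchored representation: net length
change not divisible by 3 is a frameshift; in-frame events are *conservative*
when the edited span aligns with codon boundaries (whole codons inserted or
deleted) and *disruptive* otherwise — the common annotator convention — and
any in-frame event that introduces a premature stop is promoted to
stop_gained. Splice region means within 2 bp of intron flanking an exon
(canonical donor/acceptor); variants whose edited span crosses a CDS segment
boundary are conservatively classified splice_region. One effect is produced
per (variant, transcript) pair; gene-level rollups take the most severe by
the documented ordering (frameshift > stop_gained > stop_lost > start_lost >
disruptive in-frame > conservative in-frame > missense > splice_region >
synonymous > utr > intron > intergenic). Protein-altering tallies are
reported both per distinct variant and per variant-transcript pair, since the
two conventions genuinely differ whenever transcripts overlap.

## Blocks and the clustering test

Blocks are maximal runs of consecutive variants with inter-variant gaps
≤ `max_gap` (default 100 kb), discarded below `min_count` (default 5); the
defaults are exposed flags and echoed in output headers, since no canonical
definition exists for such blocks. Per-block density is span/(number of
variants), matching a per-cluster framing; an aggregate density (total
span/total variants) is also reported. The non-randomness test uses the index
of dispersion of inter-variant gaps (variance/mean) with a null of uniform
placement and the add-one permutation p-value (1 + #{null ≥ observed}) /
(1 + N); add-one avoids p = 0 and keeps the type-I rate at the nominal level,
verified by simulation.

## Differential expression

Size factors are median-of-ratios over genes positive in every sample,
rescaled to geometric mean 1, with a total-count fallback (and warning) when
no such gene exists. The test conditions on each gene's total of normalized
counts (rounded to an integer): under equal means and common dispersion φ,
the conditional law of the strain-B sum is a negative-hypergeometric-type
distribution with size parameters n_A/φ and n_B/φ, free of the mean — the
classic conditional exact construction. The two-sided p sums all splits at
most as probable as the observed one. The conditional pmf is computed by
cumulative sums of log((r+i)/(1+i)), which is stable for arbitrarily large
size parameters; as φ → 0 the law converges to Binomial(s, n_B/(n_A+n_B)),
and below φ = 10⁻¹² the binomial form is used directly. Per-gene dispersions
are within-group method-of-moments estimates pooled across the two groups,
shrunk 50/50 toward the common (median positive) dispersion — a deliberately
simple, testable scheme — with non-positive estimates falling back to the
Poisson limit.

log₂FC uses a 0.5 pseudocount on normalized group means so zero-count groups
give finite values. The AUC is the rank-based Mann–Whitney statistic scaled
to [0,1], oriented as P(JpB sample > JpA sample), computed on normalized
counts. The DEG gate applies max(auc, 1−auc) ≥ 0.8 by default so the
criterion is direction-symmetric (the literal one-sided reading is available
via `DEGCriteria(symmetric_auc=False)`); the AUC threshold in the composite
criterion comes with no stated orientation, so the symmetric reading is the
package's own choice, documented rather than claimed canonical. BH FDR is the
step-up procedure with monotonicity enforcement. PCA QC centers and
unit-scales genes (dropping zero-variance genes), takes the top-2 singular
subspace, and fixes each component's sign by forcing its largest-magnitude
loading positive.

## Cis linkage and statistics

A variant links to a gene when its position lies in
[gene_start − window, gene_end + window] with window = 3 kb; the gene body is
included (an interior variant is at least as plausibly cis-acting as a
flanking one; `include_gene_body=False` restricts to flanks). Anchoring is on
the gene span, not the TSS. Adjacency fractions are distinct linked variants
over total variants and distinct linked DEGs over total DEGs, reported to one
decimal percent.

Over-representation is the one-sided hypergeometric tail P(overlap ≥
observed), gated at −log₁₀(p) > 3 with no cross-set multiple-testing
correction (the gate is on raw p < 0.001; a BH option exists in the DE module
for other uses). The universe is caller-supplied; a sensible default is all
expressed genes plus all variant-bearing genes. The goodness-of-fit and
independence chi-squares are uncorrected Pearson statistics (df = 1), the
latter also reported with the Yates correction; both are validated against
closed-form identities. The polygenic expectation for n unlinked heterozygous
loci in a backcross is 0.5ⁿ.

## Problem sizes

Default desk-scale simulations use 3 contigs × 200 kb, 45 genes and ~600
ancestral sites; the test suite and acceptance script use 20–60 generations,
40–60 replicate simulations for Monte-Carlo comparisons, 500-gene DE
recovery at the 25-vs-30 cohort sizes, 1,000-case oracle sweeps and
200-permutation calibration runs. These sizes give Monte-Carlo standard
errors small enough for 3-SE comparisons while keeping any single run in
seconds.

## Known limitations

The DE test assumes a common dispersion within a gene across groups and
ignores uncertainty in the dispersion estimate (no qCML/empirical-Bayes
machinery); p-values are slightly conservative at very small totals. The
annotator handles one transcript at a time, does not model compound variants
phased across a codon, and reports variants spanning CDS/intron junctions as
splice_region rather than attempting a sequence-level re-splice. Blocks from
the gap-merge rule depend on `max_gap` near the block edges; the permutation
test, not the block count, is the calibrated statement about non-randomness.
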