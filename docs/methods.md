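# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `transnp`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data generator

The generator (`transnp.simulate`) emulates a multiplexed cDNA sequencing
experiment on a small ascertainment panel:

- **Panel structure.** 8 diploid individuals from 4 populations (2 per
  population), each tagged with a distinct 10-mer 5′ barcode; barcodes are
  drawn by seeded rejection sampling with pairwise Hamming distance ≥ 3 so
  single-substitution errors cannot flip a read between individuals.
- **Transcripts and truth SNPs.** Random uniform-composition transcripts;
  biallelic substitution SNPs planted at `snp_density` per kb (fractional
  expectations resolved by a Bernoulli draw, so integral expectations are
  exact). Indel variants are never planted. Each SNP's minor-allele
  frequency is drawn from `maf_distribution`; per-individual genotypes are
  binomial(2, f) and phased into haplotypes at read time.
- **MAF sampler default: Uniform(0.05, 0.5).** The conventional choice for
  simulating a genotyping panel, giving the panel-evaluation statistics
  coverage of every frequency bin. A `neutral_maf` sampler (density ∝ 1/x,
  the L-shaped spectrum of an unascertained sample) is provided for
  ascertainment-bias experiments.
- **Reads.** Read count per transcript is `mean_depth · L / read_length_mean`
  (`mean_depth` is *pooled* reads per base across all individuals); lengths
  are normal (mean 205 bp, sd 30) clipped to [50, L]; start positions
  uniform on the valid range; strands equiprobable. Error model:
  independent substitutions at `per_base_error` (default 0.01, also encoded
  in the flat phred qualities), and ±1-unit length errors at homopolymer
  runs ≥ 3 at `homopolymer_indel_rate` (default 5·10⁻⁴) — the dominant
  pyrosequencing error mode, kept to length ±1 so gapless placement
  failures are the only downstream consequence. Barcodes are subject to the
  same substitution process, which is why a realistic fraction of reads
  (~10% at e = 0.01) demultiplexes to no tag.
- **What it does not model.** Flowgram-level noise, 3′ coverage bias,
  expression-level variation between transcripts, chimeric reads,
  paralogous gene families and population differentiation (per-population
  allele frequencies are equal by default). Passing tests on this generator
  therefore demonstrate correctness of the pipeline's logic and statistics,
  not robustness to mis-assembly or paralogy in real libraries.

## Read preparation

Demultiplexing assigns a read iff exactly one barcode matches its 5′
prefix within `max_mismatch` (default 0) substitutions. The contaminant
(mitochondrial) screen removes a read iff some ungapped local alignment to
the reference, on either strand, reaches 94% identity over ≥ 60 bases;
candidate diagonals come from exact 16-mer seeds and every window length is
tested on each diagonal. The low-complexity masker is DUST-style: windows
of 64 bases whose triplet score Σc(c−1)/2 / (n−1) exceeds 2.0 are
soft-masked (case change only, idempotent, masked fraction reported). It
stands in for repeat-library masking, which requires species-specific
external data; the reported masked fraction keeps the stand-in auditable.

## Mapping and pileups

The mapper is gapless by design: reads are transcript-derived, the variant
model excludes indels, and homopolymer-length errors are deliberately
surfaced as unplaced reads rather than absorbed by gapped alignment. A
read is placed at its best full-length location (identity ≥ 90%, both
strands, exact 16-mer seeds nominating diagonals), ties broken by contig
input order, then leftmost coordinate, then plus strand. Pileup columns
store base, phred-derived error probability (clipped to (10⁻⁶, 1−10⁻⁶)),
read and individual; reverse-strand reads are complemented onto the
consensus strand. Internal coordinates are 0-based half-open; every
emitted table is 1-based.

## The Bayesian site model

Priors: (1−θ)/4 per monomorphic base, θ/6 per unordered allele pair, with
θ = 0.003 (per-site prior probability of polymorphism). The allele
fraction is marginalised over the 19-point grid {0.05, …, 0.95} rather
than summed over read permutations: the grid is deterministic,
oracle-checkable and monotone in evidence; its resolution is exposed in
`SiteModelParams.f_grid`. The decision rule is posterior ≥ 0.5 (maximum a
posteriori), exposed as configuration. Hard filters apply in a fixed
order — depth < 4, then minor reads < 2, then posterior — so failure
reasons partition the scanned sites; the single-individual exclusion then
removes candidates whose minor allele was seen in reads of fewer than two
individuals. Only the two most frequent bases become candidate alleles;
third-allele reads count toward depth and are treated as errors.
Likelihoods are computed in log space with log-sum-exp; the posterior
equals a naive linear-scale enumeration to < 10⁻⁹ on all columns of depth
≤ 6 (tested).

### Sensitivity at 20× pooled depth

At 20× pooled coverage over 16 haplotypes, each minor-allele copy carries
~1.25–1.6 expected reads. A site whose minor allele sits in two of the
eight individuals therefore expects ~2.5–3 supporting reads, while with
θ = 0.003 the posterior crosses 0.5 at roughly 3 minor reads out of 20
(the worked example in `examples/posterior_model.py` prints the
transition). Recall of low-carrier-count truth sites is bounded
accordingly: the acceptance benchmark (50 × 1 kb transcripts, seed 1)
measures 78.0% recall over sites with ≥ 2 carrier individuals, rising
above 90% when restricted to sites with ≥ 5 carriers. Claims of > 90%
variant detection at "20 reads per base" in the re-sequencing literature
refer to per-individual coverage; they do not transfer to pooled
ascertainment panels of this size, and the toolkit makes that visible
rather than papering over it.

## Assay selection

- **Window.** 121 bp (SNP ± 60), the region assay oligos are designed on;
  SNPs within 60 bp of a contig end are rejected as `terminal`.
- **Design score.** Consumed as an input column (the production score is
  proprietary): tier `reject` < 0.4 ≤ `acceptable` ≤ 0.7 < `preferred`.
  For synthetic runs `ads_proxy` supplies a crude GC-balance ×
  self-complementarity heuristic in [0, 1], clearly labelled non-Illumina.
- **Boundary screens.** Alignment records follow the tabular BLAST dialect
  (1-based inclusive; subject start > end encodes minus strand); hits are
  significant below e-value 10⁻⁵. The *direct* screen calls `single_exon`
  iff the best genome hit (max query span, then min e-value, then max bit
  score) contains the window, `boundary` if it overlaps without containing
  it, else `no_match` — including when the best hit misses the window
  entirely, since such a hit says nothing about the window. The *projected*
  screen maps the SNP through the best contig↔transcript hit into
  transcript coordinates and tests the window against transcript↔genome
  hit segments treated as exons. The consensus is conservative: any
  boundary evidence from any species or screen rejects the SNP; the
  per-source evidence list is retained so the rule is auditable.
- **Neighbourhood quality (nsq).** Count of non-target window columns whose
  second-most-frequent base has ≥ 2 reads — a countable surrogate for
  visual alignment inspection; high values flag paralog co-assembly.
- **Ranking.** Within each contig: preferred design tier before acceptable,
  then ascending nsq, then descending depth, then ascending position; at
  most two survivors per contig. The stage labels
  (terminal / ads_missing / ads_reject / boundary_reject / not_ranked /
  selected) partition the candidate set, and the funnel report verifies the
  arithmetic.

## Coding effects

The reading frame is projected from the best protein hit (e-value < 10⁻³;
min e-value, tie max bit score) using the translated-search frame
convention: frame +k translates the plus strand from query base k; frame
−k translates the reverse complement from its base k, so minus-strand
phase is computed in reverse-complement coordinates (which requires the
contig length). The codon containing the SNP is translated for both
allele windows under the standard code: equal amino acids → S, different
(including stop gain/loss) → NS, no qualifying hit → NA. The second-pass
confirmation of the 121-bp windows (e-value < 10⁻¹⁰) is an optional
filter: when confirmation records are supplied and neither window hits,
the call degrades to NA. The two alleles are compared by direct
translation, not through separate alignment reports.

## Panel statistics

- **MAF spectrum.** Bins [0, 0.05), …, [0.45, 0.5]; the L-shape flag is
  true iff the lowest bin is modal.
- **Heterozygosity.** H_O is the heterozygote fraction among non-missing
  genotypes; H_E = 2p(1−p), with an optional n/(n−1) small-sample factor
  (off by default).
- **HWE.** Exact Levene enumeration by default — feasible for any panel
  size here and free of Monte-Carlo noise; the two-sided p sums the
  probabilities of all heterozygote configurations no more probable than
  the observed one (tolerance 10⁻¹² on probability comparisons). The
  Monte-Carlo mode (allele shuffling, 10,000 iterations in 20 batches,
  batch spread → standard error) is retained for fidelity with
  permutation-based software. Population-monomorphic loci are skipped, so
  the number of performed tests is data dependent.
- **LD.** G statistic on the genotype contingency table (summed over
  populations), null distribution by permuting one locus's genotypes
  within population. The pair is canonicalized (lexicographic on genotype
  vectors) before drawing the seeded permutation stream so the p-value is
  exactly symmetric in the two loci; p uses the add-one rule
  (count+1)/(N+1), so perfect dependence yields p = 1/(N+1). Missing
  genotypes are dropped test-wise.
- **FDR.** Benjamini–Yekutieli step-up with c(m) = Σ 1/i, valid under
  arbitrary dependence; cross-checked in tests against a brute-force
  implementation and an independent reference implementation.

## Validation model

Binomial logistic regression by IRLS (Newton scoring), converged when the
relative log-likelihood change falls below 10⁻¹⁰ (≤ 100 iterations);
standard errors from the observed information matrix; Wald = (B/SE)² with
χ²(1) p-values; the model χ² is the likelihood-ratio statistic against the
closed-form intercept-only fit. Complete separation raises an explicit
error (perfect-classification check plus coefficient-divergence guards)
instead of silently diverging. Backward elimination drops the largest
Wald p ≥ 0.10 per step (the classic stepwise default; exposed as
configuration) and records a replayable trace. The boundary outcome enters
as two dummies against the `no_match` reference level, each treated as its
own term during elimination. The reduced a priori term set
{depth, minor fraction, nsq, design score, boundary dummies} is provided
as a preset for collinearity-controlled reruns.

## Microsatellites

Perfect tandem repeats of primitive 2–6-mer motifs with ≥ 4 units;
homopolymers excluded; motifs canonicalized to the lexicographically
minimal rotation; phase-shifted and nested calls collapsed to the leftmost
maximal run, so reported loci never overlap. `primer_ready` requires both
flanks ≥ 50 bp (configurable; the sufficiency criterion for primer design
is not standardised) and no other repeat within that distance. The census
bins unit counts as 4–9 / 10–14 / 15–19 / > 19 (the overlapping 14–19
label seen in some printed tables is normalised to 15–19). Motif lengths
of seven, mentioned inconsistently in some sources, are excluded.

## Funnel accounting

Every stage records (in, out, removed-by-reason) and the report enforces
in = out + Σremoved and chain contiguity. Percentages are recomputed from
stored integer counts on demand; truncation toward zero at one decimal is
the default style because it reproduces most published worked examples,
with half-up rounding available — printed percentage styles in the
literature are internally inconsistent (both 993/6331 → "15.6" and
3052/5253 → "58.1" appear), so raw counts are always emitted alongside.

## Problem sizes in the test suite

Property suites run at the sizes their statistics need: the posterior
oracle enumerates all 209 base-composition columns to depth 6; the
HWE enumeration identity is checked for every allele count up to n = 40;
the BY-FDR equivalence runs 200 random vectors plus a derandomised
property test; logistic parameter recovery uses n = 2000 and the null-χ²
distribution check 300 replicates; the microsatellite oracle scans 1,000
random contigs; the caller-recall benchmark uses the full 50-transcript
configuration. The LD type-I-error simulation uses 120 pairs at 400
permutations — enough for a 3-standard-deviation band around the nominal
5% level while keeping the permutation test exact in form.
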