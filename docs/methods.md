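# Methods

`editscan` re-implements, as a tested library, an analysis chain for
SNP-overlapping A-to-I RNA editing sites: identification from RNA-seq
pileups with DNA-genotype gating, site characterisation, dsRNA structure
tests, GWAS-signal enrichment, and a balancing-selection scan.  This note
records the models, the tunable parameters, and the design choices made
where the procedure was genuinely open.

## Editing-site identification

A-to-I editing is read as an A→G mismatch against the genome (T→C on the
genomic minus strand).  The cascade, all thresholds in
`CallerThresholds`:

1. **Variant calls** (`call_variants`): one call per (sample, site, alt
   base) with ≥ 2 supporting reads.  Base quality ≥ 20 and mapping quality
   ≥ 20 are contract preconditions of the pileup tables, not re-checked
   here.  Calls are labelled Alu/non-Alu from repeat intervals.
2. **Sample purity** (`sample_purity_filter`): a sample is kept when
   ≥ 80% of its variant calls are A>G or T>C (strand-unaware, computed
   before strand inference).  The bound is inclusive.  Samples with zero
   variants have an undefined fraction and are dropped.
3. **SNP/non-SNP split** (`split_by_snp`): calls at known SNP positions
   are *SNP-editing candidates* only if every available DNA resource
   (e.g. WGS and array) for that sample reports the same
   homozygous-reference genotype; heterozygous, non-reference, conflicting
   or missing DNA excludes the call.  This is the hard guarantee that RNA
   G reads are not explained by the DNA.  Calls at non-SNP positions pass
   through.
4. **Final filters** (`finalize_sites`): ≥ 3 reads of each allele per
   supporting sample; non-Alu candidates additionally need editing level
   ≥ 0.1, no homopolymer run > 4 nt containing or bordering the site, and
   distance > 4 nt from annotated splice boundaries (the stringency of
   non-Alu calling is configurable; these defaults are this package's
   declared choice).  Strand comes from the overlapping gene: A>G requires
   a + gene, T>C a − gene; contradicting calls are dropped, sites under
   genes on both strands are ambiguous and dropped, sites in no gene keep
   their genomic mismatch with strand ".".

The caller is parameterised by `edit_type`, so a C-to-T/G-to-A negative
control is the same pipeline with one flag.

Editing level is G/(A+G) on the sense strand.  The *representative level*
of a site is the maximum over per-tissue means, each tissue mean taken
over samples with A+G coverage.  Condition comparisons (e.g. ADAR
over-expression vs control) keep sites with depth ≥ 10 in every sample and
level > 0.02 somewhere; SNP-editing sites additionally need DNA depth ≥ 5
with zero G reads.

## Synthetic data

The generator (`simulate.SimConfig` and friends) emulates the statistical
structure the analyses consume, not reads:

- **Reference and annotation**: one chromosome of i.i.d. uniform sequence;
  genes of 6 kb separated by 4 kb of intergenic sequence (~60% genic),
  each with three exons, a CDS leaving both UTRs (80% of genes; the rest
  ncRNA), and one Alu-like interval covering 30% of the gene.
- **Editing sites**: one per gene; the sense base is set to A, and the 5′
  neighbour is drawn with relative weights 0.25 (A, C, T) and
  0.25·`motif_bias` (G), i.e. `motif_bias` = 0.5 gives a 5′ G frequency of
  0.125/0.875 ≈ 0.143 — the ADAR-style depletion.  For `ecs_fraction` of
  sites the exact reverse complement of the 31-nt editing region is
  written into the same gene 400–2400 nt away.
- **Genotype panel**: Hardy–Weinberg sampling per site.  Neutral sites
  draw a derived frequency from the 1/f lattice k/2N (2N = 10,000);
  balanced sites from Beta(20, 20) — intermediate frequencies without
  pinning at 0.5.  Sites are re-drawn until they segregate in the cohort,
  so the emitted panel is polymorphic by construction.  Editing SNPs are
  A/G on the sense strand; the ancestral allele is the editable (A) or
  edited (G) state with equal probability.
- **Pileups**: depth ~ Poisson(`coverage_mean`) truncated at ≥ 1; the
  edited-read fraction at an editing site is the per-sample true level
  (Beta(α, β), optionally clamped at `level_min`) for genotype AA, 0.5
  for AG, 1 for GG; heterozygous pure SNPs are Binomial(depth, 0.5).  A
  per-read error channel moves each read to a uniformly chosen other base
  with probability `seq_error_rate`.  Only genic SNPs receive RNA
  coverage (intergenic SNPs are untranscribed), which is what keeps
  per-sample purity realistic.
- **GWAS**: control SNPs draw p ~ U(0,1); with enrichment factor F > 1,
  each editing SNP independently hits p < 0.001 with probability 0.001·F
  (hits ~ U(0, 0.001), misses ~ U(0.001, 1)).  F = 1 leaves everything on
  the plain uniform, so downstream test p-values stay calibrated.
- **Haplotype-level simulators** for the selection statistics: fixed-S
  neutral windows (each site i.i.d. from the 1/f lattice, conditioned to
  segregate); balanced windows in which the focal site draws
  Beta(20, 20) and half the flanking sites (by default) ride on the two
  balanced haplotype backgrounds with a 5% per-haplotype flip rate — the
  minimal emulation of old allelic classes accumulating linked variation;
  and a founder-mosaic block model (per-bp switch probability) for LD
  decay.

What the generator does **not** emulate — read-level artefacts (mapping
bias, splicing errors, strand-specific library chemistry), linkage between
panel sites outside the dedicated LD mode, population structure, and
realistic GWAS LD clumping.  Passing tests therefore demonstrate that the
statistics and filters behave as designed under their own assumptions, not
that the pipeline is robust to alignment artefacts in real data.

All randomness derives from `SimConfig.seed` through per-stage
`default_rng([seed, stage])` streams; a fixed seed reproduces outputs
byte-for-byte.

## dsRNA structure tests

Two detectors, both calibrated by shuffling the editing region
(mononucleotide Fisher–Yates, preserving composition) and re-scoring
against the unchanged surround:

- **ECS search** (`best_hybridization`): the editing region (site ± 15 nt,
  sense strand) is scanned against every antiparallel placement within the
  surrounding ± 2500 nt, clipped to the enclosing gene.  The default
  scorer sums nearest-neighbour stacking free energies over consecutive
  Watson–Crick and G:U pairs (standard RNA ΔG°37 values for Watson–Crick
  stacks; G:U stacks approximate); unpaired positions break the helix and
  contribute nothing.  The scorer is gapless: bulged duplex alignment was
  deliberately left out because the empirical p is rank-based against
  shuffles scored by the same function, so calibration is invariant to the
  scorer family, and the gapless scan is two orders of magnitude cheaper.
  The scorer is pluggable for anyone wanting a thermodynamic duplex model.
  Energies live on a 0.01 kcal/mol lattice, so the integer kernel is
  exact; the region's own locus is masked, so the trivial self-alignment
  can never win.
- **Local duplex alignment** (`local_duplex_score`): Smith–Waterman of the
  region (site ± 25 nt) against the reverse complement of the surrounding
  ± 2000 nt (match +2, mismatch −3, gap open −5, extend −2, no
  low-complexity filtering), via Biopython's `PairwiseAligner`.  A gap of
  length L costs 5 + 2(L−1).

The empirical p-value uses the add-one rank formula
(#{shuffles at least as extreme} + 1)/(n + 1); the *significant* flag
reproduces the top-rank rule (observed beats all but < 1% of shuffles).
The cohort summary reports the significant fraction and a paired Wilcoxon
signed-rank test of observed statistics against per-site null means.

## GWAS enrichment

For one dataset: a = editing SNPs with GWAS p < 0.001 (strict), b = the
rest; c, d likewise for controls.  Score = (a/(a+b))/(c/(c+d)), tested
with two-sided Fisher's exact.  The control universe is all GWAS-covered
panel SNPs minus the editing SNPs (exclusion avoids self-contamination).
When c = 0 the score is undefined and only p is reported.  A disease with
several datasets is represented by the median-score dataset (lower median
on even counts).  Note that Fisher's exact p on discrete counts is
conservative under the null; "calibrated" here means P(p ≤ α) ≤ α, not
exact uniformity.

## Balancing-selection statistics

- **DAF**: derived allele frequency = frequency of the non-ancestral
  allele (ancestral from INFO/AA, or from an outgroup base when it matches
  ref or alt; otherwise unknown and excluded).  Strict MAF > 0.001 floor.
  Spectra are reported in ten 0.1-wide bins; class comparisons use the
  two-sample Kolmogorov–Smirnov test (exact when both n ≤ 30, asymptotic
  otherwise).
- **Tajima's D** (`window_stats`): with j derived copies among n
  haplotypes, per-site heterozygosity is 2j(n−j)/(n(n−1)); pi is its sum
  over the window, θ_W = S/a₁ with a₁ = Σ 1/i, and D = (pi − θ_W)/√(e₁S +
  e₂S(S−1)) with the standard constants.  D is undefined at S = 0; n ≥ 4
  is required.  Missing alleles use site-wise complete-case n for pi.
  SNP-centred windows are the focal position ± 150 bp (300 bp total);
  windows whose flanking SNPs leave the focal functional class are
  discarded by default (a keep-and-clip mode exists).
- **pi windows**: fixed intervals or sliding 200-bp windows at 100-bp
  steps; `pi_per_bp` divides by window length.
- **LD decay**: haplotype r² = (p_AB − p_A p_B)²/(p_A(1−p_A)p_B(1−p_B)),
  focal-vs-flanking pairs binned into 20 equal-width bins over
  [500, 10000) bp (475 bp per bin); a genotype-correlation fallback exists
  for unphased input and is labelled as such.

## Problem sizes and numerical checks

The test suite and `scripts/acceptance.py` run the whole chain at desk
scale, chosen so each stage finishes in seconds to a couple of minutes:
400–500 planted editing sites at 30× coverage across 20 samples for caller
recovery; 500 windows (n = 50 haplotypes, S = 20) for the neutral
calibration of D and pi; 100 seeds of 200-balanced-vs-5000-neutral DAF
comparisons; 300–500 sites × 1000 shuffles for structure-test calibration
and recovery of a planted 44% ECS fraction; 10,000 editing / 100,000
control SNPs for GWAS enrichment.  Exact-test switches: Mann–Whitney uses
exact enumeration when both groups have n ≤ 8 and no ties (midranks and
tie-corrected normal approximation otherwise); KS is exact for n ≤ 30.
All five statistics are verified against brute-force oracles (exhaustive
pairwise differences, full enumeration of label arrangements and
hypergeometric tables) to 10⁻¹⁰ on small inputs.

## Known limitations

- The ECS scorer ranks duplexes; its absolute energies are not calibrated
  against a thermodynamic folding model and should not be quoted in
  kcal/mol terms beyond "lower is more stable".
- The GWAS enrichment-score estimate at a planted factor F has relative
  sampling spread ≈ √(1/a + 1/c); at the default sizes (≈ 30 expected
  editing hits) a single dataset estimates F = 3 only to ± ~40% at 2σ.
  The estimator is unbiased (its median across seeds sits at the planted
  factor); tight recovery needs more hits, not a different estimator.
- Gene models are single-transcript; overlapping isoforms of one gene are
  represented as separate models, and the genic-location precedence
  (CDS > 3′UTR > 5′UTR > ncRNA > intronic > antisense > intergenic) is
  applied across all overlapping features regardless of gene identity.
- Ancestral-state error (mispolarised SNPs) is not modelled.
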