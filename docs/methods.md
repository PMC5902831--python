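# Methods

`layervar` implements two complementary routes to deleterious variation in
commercial layer-chicken populations and a synthetic-data generator that
reproduces the statistical structure each route assumes.

## Missing-homozygosity scan

A recessive embryonic lethal removes its homozygotes before chicks are
genotyped, so a haplotype linked to one shows a *deficit of homozygotes*
relative to Mendelian expectation in a large pedigreed population.

**Windows and haplotypes.** Phased chip genotypes are cut into overlapping
sliding windows of 0.25, 0.5 and 1 Mb, stepping by half the window size; a
final window is anchored at the chromosome end. Haplotypes are distinct
allele strings within a window; strings with frequency above 0.5% are
retained. Individuals with any missing allele inside a window are excluded
from that window only. Internally coordinates are 0-based half-open;
reported tables are 1-based inclusive.

**Expectation.** For a mating in which the sire carries `h_s` and the dam
`h_d` copies of a haplotype, each offspring is homozygous with probability
`(h_s/2)(h_d/2)`. Summing `n_offspring x p` over matings with phased,
genotyped parents gives the expected homozygote count `E` among `n` at-risk
progeny (offspring of matings with `p > 0`). In the canonical
carrier-by-carrier (C x C) case this is 25% of offspring. Matings with
ungenotyped or unphased parents are excluded rather than imputed.

**Test.** The observed homozygote count is compared with
`X ~ Binomial(n, E/n)` by a one-sided lower-tail exact test; haplotypes with
`p < 0.005` are flagged, with no multiple-testing correction (the raw
cut-off is deliberate: the test is discrete and conservative, and the flag
threshold is part of the method definition). For `observed = 0` the p-value
is computed by the closed form `(1 - E/n)^n`. Mixing matings with different
`p` into a single binomial is an approximation; the exact reference is the
Poisson-binomial, whose lower tail is bounded above by the binomial tail at
the same mean (arithmetic-geometric mean inequality), so the approximation
only loses, never gains, significance. The heterozygous fraction of C x C
progeny is reported as a cross-check: surviving progeny of a fully
penetrant lethal are 2:1 het : non-carrier (~66.7%), against 50% under
neutrality. Overlapping significant windows on a chromosome are merged into
unique loci for the summary table.

**Panel QC.** Before phasing-based analyses, a chip matrix is filtered in
this order: unmapped and sex-chromosome SNPs, animals with call rate below
0.7, then SNPs with MAF not above 0.01 or call rate not above 0.85 (strict
thresholds). No Hardy-Weinberg filter is applied, because the deficit
signal *is* an HWE deviation.

## Variant catalogue

Sequence-level records carry site QC (`qual`, `call_rate`, distance to the
nearest indel), functional annotation (consequence, gene, SIFT, PROVEAN,
protein coordinates, 1:1-orthology flag, RNA-seq coverage) and per-line
allele counts.

- **Site filters:** SNVs within 3 bp of an indel (inclusive: distance <= 3
  removed), sites with quality below 20 or call rate below 0.7. The filter
  is idempotent and reports stage-wise counts.
- **Genotype filter:** per-sample depth outside [4, mean depth x 2.5]
  (both bounds inclusive) sets the call missing; call rate is then
  recomputed. The implemented order is site filters, then depth filter,
  then call-rate recomputation for reporting.
- **Classification:** LoF = splice acceptor/donor, frameshift, in-frame
  insertion/deletion, stop gain/loss, start loss. Missense splits at
  SIFT <= 0.05 (deleterious) vs > 0.05 (tolerated); missense without a SIFT
  score is labelled unscored and excluded from spectrum comparisons. The
  *final deleterious set* additionally requires a 1:1-orthologous gene and
  combined RNA-seq coverage >= 200, which guards against paralog-collapse
  mapping artefacts and broken gene models. Two SIFT thresholds coexist by
  design: <= 0.05 defines the class, < 0.01 defines the per-individual
  mutation-load numerator; both are exposed in configuration.
- **Mutation load:** per individual, carried deleterious (SIFT < 0.01)
  variant count over carried synonymous count.
- **TS/TV** is reported over biallelic SNVs as a calling-quality heuristic.

## Selection signatures

- **Allele-frequency spectra:** 20 bins of width 0.05; bins are half-open
  with the last closed so AF = 1.0 lands in the top bin and the bins
  partition each class. Pooled-across-line frequencies are the default;
  per-line mode is available.
- **Pooled heterozygosity:** for a 20-kb window,
  `Hp = 2 * S_maj * S_min / (S_maj + S_min)^2` with `S_maj`, `S_min` the
  summed per-SNP major/minor allele counts in the line. Windows tile the
  genome without overlap from position 0 (the minimal reading absent a
  stated step) and need >= 20 variants to be scored. `zHp` standardises Hp
  over all scored windows per line; windows at `zHp <= -2.7` are sweep
  candidates.
- **Intolerant sets:** deleterious variants at AF > 0.9 in at least one
  line are "fixed or nearly fixed" (fixed when AF = 1.0 in every line);
  line-specific high-frequency variants have AF > 0.7 in exactly one line
  and zero alt alleles elsewhere. Their overlap with flagged sweep windows
  distinguishes selection candidates from drift.

## Purging and positional signatures

- **Recombination bins:** ~750-kb bins on macrochromosomes 1-5; bin cM from
  linear interpolation of the linkage map at bin edges, held constant beyond
  terminal markers (such bins get rate 0 and a flag); terminal bins shorter
  than half a bin are dropped. Rate = cM / Mb.
- **Purging correlation:** Pearson correlation between bin rate and the
  ratio deleterious missense / (synonymous + tolerated missense). Both the
  t-distribution p-value and a label-permutation p-value are reported —
  bins are spatially autocorrelated, so the permutation p is the safer
  reference. A two-class summary contrasts bins at rate <= 2 vs > 2 cM/Mb.
- **Protein position:** relative position `aa_pos / aa_len` in (0, 1],
  binned by `ceil(10 x relpos)` (deciles; scale-invariant). Terminal
  enrichment of a class is its first+last-decile proportion over the same
  proportion in synonymous variants, with a permutation p-value.
- **Indel lengths:** |length| histograms (1-15) for coding vs non-coding
  indels; the in-frame fraction (|length| % 3 == 0) is compared by a
  two-proportion z-test.

## Embryonic-lethal candidates

A candidate is a LoF or deleterious-missense variant (in-frame indels only
when PROVEAN <= -2.5, the tool's conventional deleteriousness cut-off) with
zero hom-alt genotypes across all samples and a gene whose null-mutant
mouse phenotype is early lethality (supplied as a TSV). Visual curation of
alignments is replaced by a machine-readable exclusion list. Each candidate
carries an ordered reason trail that replays its accept decision, and the
filter is monotone in the gene set. The zero-homozygote criterion is
evaluated on post-QC genotypes, so a spurious hom call at depth 2 cannot
disqualify a candidate.

Carrier-concordance matching looks for protein-altering variants inside a
deficit window (plus a configurable flank) whose sequenced alt-carriers
coincide with the sequenced haplotype carriers. Strict mode demands set
equality (hence symmetry); relaxed mode reports the Jaccard concordance,
because genotyping error tolerance is a judgement call.

Hatchability of C x C vs C x non-carrier matings is compared with an
equal-variance two-sample t-test on per-mating hatch fractions, two-sided
(the original analysis does not state sidedness; two-sided is the
conservative choice).

## Synthetic-data generator

The generator emulates the study's data sources without reproducing any
real population:

- **Pedigree and genotypes.** Discrete generations; random sire/dam pairing
  within line; founder haplotypes drawn site-wise from per-SNP allele
  frequencies uniform on [0.1, 0.9] (chip ascertainment favours
  intermediate frequencies at ~20 markers/Mb). Meioses follow the Haldane
  model: Poisson crossover counts with mean equal to the chromosome map
  length in Morgans, positions uniform, no interference. Phase is emitted
  as truth; a switch-error injection hook exists but is off by default.
  `offspring_per_mating` counts *genotyped surviving* chicks: hatcheries
  genotype a planned number of hatched chicks, and egg-level death is
  modelled separately by the hatchability generator
  (C x C matings hatch at `base x (1 - penetrance/4)`).
- **The embedded lethal** is a point mutation at the midpoint SNP of the
  configured window, carried by founder chromosomes tagged with probability
  `lethal_target_freq`. Tagged chromosomes share one window allele string;
  any founder draw or conceptus homozygous for the tag is removed before
  genotyping with probability `penetrance` (default 1), so surviving C x C
  progeny are 2:1 het : non-carrier. The shared string is rejection-sampled
  until its identical-by-state background probability is at most
  `lethal_max_ibs_fraction` (default 0.02) of the target frequency: a real
  lethal arises once and its carriers are identical by descent, and a
  lethal residing on a common haplotype is the method's documented blind
  spot, not a detectable case. Recombination inside the window can decouple
  tag and string; the tag follows the mutation's position.
- **The catalogue** draws per-class allele frequencies from Beta
  distributions (defaults: synonymous Beta(0.8, 0.8), tolerated missense
  Beta(0.5, 1.0), deleterious missense Beta(0.2, 2.0), stop-gained
  Beta(0.15, 2.5)), genotypes under Hardy-Weinberg per line, SIFT/PROVEAN
  scores consistent with class, transitions at ts:tv = 2.5, in-frame-biased
  coding indel lengths, optionally terminal-inflated frameshift/stop
  positions, line-private variants, and EL-truth variants whose hom-alt
  draws are resampled to het/ref (approximately preserving the marginal
  frequency while guaranteeing the zero-homozygote criterion). The
  deleterious/tolerated gradient is enforced per 750-kb bin: deleterious
  missense variants choose genes with weights proportional to
  `base_ratio + slope x (bin rate - mean rate)`; a slope that would demand
  a negative ratio raises an error.
- **The linkage map** places markers every 250 kb with log-normally varying
  interval rates around 3 cM/Mb (sigma 0.4).

What the generator does **not** model: linkage-disequilibrium decay
calibrated to real chicken data, coalescent ancestry, sequencing reads,
genotyping error on the chip, or the proprietary mating design of a
breeding program (the scheme here is a stand-in). Passing tests therefore
demonstrate the statistical machinery, not properties of any real
population.

## Numerical choices and problem sizes

- All randomness flows from one root seed through
  `numpy.random.default_rng`; derived streams use spawn-style seed lists.
  Identical config + seed reproduces byte-identical outputs.
- Exact binomial p-values use the closed form at `observed = 0` and
  `scipy.stats.binom.cdf` otherwise.
- zHp uses the sample standard deviation (ddof = 1) over scored windows and
  refuses to standardise fewer than 2 scored windows or a zero-variance set.
- Test suites run the scan on a single 4-Mb chromosome at chip density with
  3,000 trios and 20 replicates, the spectra on 100 catalogues of ~840
  coding variants, and the purging recovery on 100 catalogues of ~18,000
  variants over five 15-Mb chromosomes — sizes chosen so per-bin and
  per-window counts match the regimes the statistics assume while the whole
  suite stays interactive.

## Known limitations

- Haplotype frequency is computed in the analysed population as given;
  within-line vs pooled frequency in crossbreds is a user decision.
- The binomial aggregation of heterogeneous mating probabilities is
  conservative (never anti-conservative), but its p-values are not exact
  Poisson-binomial tails.
- The permutation p-value for the purging correlation permutes bins, which
  breaks spatial autocorrelation in the null; adjacent-bin dependence is
  not otherwise modelled.
- Fixed/line-specific thresholds are hard cut-offs; sampling noise near
  AF = 0.9 / 0.7 is not propagated.
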