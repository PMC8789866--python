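# Methods

## The experimental readout being modelled

A somatic nucleus from an F1 hybrid of two inbred strains (labelled A and B)
is transferred into an enucleated MII oocyte; after fertilization with
single-strain sperm the somatic diploid set (2n/2c, one chromatid per
homolog) can segregate so that one homolog of each pair is extruded to a
pseudo-polar body (PPB) and the other stays in the embryo. Because every
homolog carries a strain signature at strain-discriminating SNPs, genotyping
the PPB and the embryo at those sites reveals, chromosome by chromosome,
whether the pair segregated reciprocally or nondisjoined — and, via read
depth, what the resulting copy numbers are.

`haplotrace` covers the dry half of such an experiment: catalog construction
from strain VCFs, zygosity calling from allele read counts, pair
classification, copy-number profiling, the analytic probability layer, and a
generator of synthetic experiments with known truth.

## Informative-site catalog and amplicon selection

A position enters the catalog iff both strains carry a confident homozygous
SNP call there and the two alleles differ. "Confident" is operationalized as
`min_depth = 10` reads and `min_quality = 30` (QUAL); both are exposed because
upstream callers differ. Records that are multiallelic, indels, heterozygous
or missing in either strain are excluded. Calls with missing depth/quality
fields (sites-only VCFs) pass those filters rather than being discarded.

Amplicon selection maximizes the number of catalog sites inside one window of
1100–1500 bp per chromosome, the length range a long-amplicon MiSeq design
uses. Candidate windows are anchored at site positions — a maximal-count
window can always be slid left until its start touches a site, so the search
is exact. Ties break to the smallest start, then the smallest length (the
window is trimmed to the last contained site, never below the minimum
length). A chromosome without sites yields an explicit no-amplicon result
(`None`), not an exception.

## Zygosity calling

Site level: with `a`/`b` reads for the two strain alleles, depth `< 10` is
`NO_COVER`; fraction of A `>= 0.9` is `HOM_A`, `<= 0.1` is `HOM_B`, otherwise
`HET`.

Chromosome level: fewer than `min_sites_covered = 3` covered sites is
`NO_AMP` — a statement about the assay, not the biology. Otherwise the
chromosome is `HET` when the HET-site proportion is `>= 0.3` **or** when both
homozygous labels each exceed 10% of covered sites (`discordance_floor`):
WGA allelic dropout turns a heterozygous chromosome into a mosaic of
discordant homozygous site calls, and a plain site majority would flip it to
HOM. A homozygous label is called only when it reaches `majority_fraction =
0.8` of covered sites; anything else falls back to `HET`. No published
thresholds exist for this assay, so all five parameters are config-exposed
and the defaults above are the package's own choices; reproducing any
specific external call set may require tuning them.

## Pair classification

Inputs per chromosome: the embryo call, the PPB call, the donor's site-level
zygosity and the sperm strain. The embryo genotype is always interpreted
*net of the sperm allele*: with B-strain sperm, embryo `HET` means "somatic A
present"; embryo `HOM_B` means "somatic contribution not detected" (masked or
absent), never somatic homozygosity.

Decision order (first match wins), with `O` the non-sperm strain:

1. Donor not informative on the chromosome (HET fraction < 0.3) → `AMBIGUOUS`.
2. Chromosome missing from either sample → `AMBIGUOUS` (never dropped).
3. PPB `HET` → `NDJ_PPB` (both homologs extruded).
4. PPB `HOM_P`:
   - embryo shows somatic `O` and `P` is the sperm strain → `PROPER`,
     retained origin `O` (the canonical reciprocal pattern);
   - embryo shows somatic `O` and `P = O` (same strain both sides) →
     `PROPER` only if the donor carries homozygous-`O` sites on that
     chromosome (the donor-LOH relaxation), else `AMBIGUOUS`;
   - embryo `HOM_sperm` and `P = O` → `PROPER` with the sperm-strain homolog
     inferred behind the sperm allele;
   - embryo `HOM_sperm` and `P = sperm` → `PROPER` only under donor
     homozygosity for the sperm strain, else `AMBIGUOUS`;
   - embryo `NO_AMP` → `AMBIGUOUS` (no evidence about the embryo side).
5. PPB `NO_AMP`: somatic signal in the embryo → `NDJ_EMBRYO` (an empty PPB
   with somatic material retained); no somatic signal → `AMBIGUOUS`.

The precedence — complementary homozygosity first, donor-LOH relaxation
second, nondisjunction patterns third, `AMBIGUOUS` last — is a design choice
of this module. Treating PPB non-amplification plus embryo somatic signal as
`NDJ_EMBRYO` conflates true retention with technical PPB failure; that
ambiguity is inherent to the assay (a chromosome-level amplification failure
of the PPB is indistinguishable from an empty PPB) and is why the generator
models the two separately.

The X chromosome of a male embryo (Y marker present, so the sperm gave Y) is
classified without sperm subtraction: its X signal is purely somatic. Sex
itself comes from the Y-marker flag (the PCR sex assay abstracted to
presence/absence); a female X that is heterozygous carries both the somatic
and the sperm X.

Cohort aggregation is direct counting. Fractions with empty denominators
(e.g. the nondisjunction-location fraction in an all-proper cohort) are
reported as absent (`None`), never as 0. The per-embryo "percent properly
segregated" uses the full assayed chromosome count (20) as denominator, so
ambiguous chromosomes count against it — the same convention as counting
9–20 proper chromosomes out of 20.

Before calling embryo/PPB chromosomes the pipeline restricts allele counts
to *donor-heterozygous* catalog sites. Sites inside donor LOH tracts show the
tract strain on both homologs; keeping them would make a single homolog that
crosses an opposite-strain tract look like discordant homozygous signal and
inflate false `NDJ_PPB` calls. Only donor-HET sites are informative about
which homolog went where.

## Copy-number profiling

For each sample, `r(c) = count(c) / mean(autosomal counts)` — the autosomal
mean excludes X, so the autosomal r values average exactly 1 — and
`R(c) = r_sample(c) / r_reference(c)` against a single reference male sample.
Estimated copies are `R × reference ploidy` (autosomes 2, X 1 for a male
reference). A call is confident within ±0.25 of an integer (no published
threshold; ±0.25 separates integer copy states at the Poisson noise levels of
whole-chromosome counting at λ ≥ 5000), clipped to 0–3. Euploid means every
autosome confidently calls 2 and the X calls 1 or 2. `R` is undefined (and no
call is made) where the reference count is 0; a zero autosomal mean is a hard
error. Both r and R are invariant to global depth rescaling of either sample.

## Analytic layer

- `semicloning_probability(n, p_proper)` = `(p_proper/2)^n`: the chance that
  all n pairs segregate properly *and* the embryo retains the homolog of one
  pre-specified parental origin every time; `2^-20 ≈ 9.54e-7` for the mouse's
  20 pairs, strictly smaller when `p_proper < 1`. The "either parent" variant
  (twice the value for n ≥ 1) is exposed as an option because the phrase "one
  parental origin" is ambiguous between the two readings.
- `proper_count_distribution(n, p_ndj)`: Binomial(n, 1 − p_ndj) — the
  per-embryo count of properly segregated chromosomes under independence.
- `estimate_ndj_rate`: `1 − proper/classified` over the cohort with an exact
  Clopper–Pearson interval; `AMBIGUOUS` chromosomes are excluded from the
  denominator (configurable by passing different totals).

## The synthetic generator

What it emulates, per `SimConfig` (defaults in parentheses):

- 19 autosomes + X (20 chromosomes), `sites_per_chromosome` (20) informative
  sites each — the SNP count of a dense 1100–1500 bp amplicon.
- An F1 donor heterozygous everywhere except contiguous LOH tracts covering
  `donor_loh_fraction` (0.1) of each chromosome's sites, one strain per
  tract. Tracts, not dispersed sites, were chosen to mimic clonal
  recombination blocks; pooled-cell heterogeneity (different cells carrying
  different blocks) is *not* modelled.
- Per chromosome pair: proper segregation with probability
  `1 − p_nondisjunction` (0.24) and uniform retained homolog; nondisjunction
  extruded to the PPB with `p_ndj_to_ppb` (0.74). Somatic copies in embryo +
  PPB always sum to 2. The 0.24/0.74 defaults are the cohort regime the
  classifier is designed around.
- Sperm of one pure strain (B), transmitting X or Y with equal probability;
  Y is represented only as a boolean marker, not as sites.
- Assay noise: each present allele class dropped per site with
  `p_site_dropout` (0.05, a WGA allelic-dropout scale), whole-chromosome
  amplification failure with `p_chrom_amp_failure` (0.02), per-site depth
  Poisson(`mean_depth` = 100), reads split binomially. The bulk donor sample
  is sequenced without WGA artifacts.
- Chromosome-level read counts Poisson with mean proportional to copy number
  against a diploid-male reference profile (10 000 reads per autosome).

Cohort size defaults to 15 pairs, the scale of a real PPB–embryo series; the
test suite and acceptance script raise it (up to 2000) where Monte-Carlo
precision is needed.

What passing tests on this generator show — and what they do not: the
classifier is exact when its assumptions hold (noiseless recovery is 100%)
and degrades gracefully under the modelled noise; they do not certify
performance under real-data features the generator omits (mapping artifacts,
PCR chimeras, index hopping, cell-to-cell donor heterogeneity, segmental
aneuploidy, recombination within a chromosome — classification is
whole-chromosome throughout).

## Numerical and degenerate-input choices

- All randomness flows from `SimConfig.seed` through per-operation
  substreams, so separately invoked generator stages compose
  deterministically and re-runs are byte-identical.
- A fully homozygous donor chromosome (LOH fraction 1) makes the donor
  uninformative there; classification abstains rather than guessing.
- Site fractions at exactly the homozygosity threshold call HOM (`>=`);
  window-selection ties break deterministically (smallest start, then
  length); ploidy estimates exactly halfway between integers round to even
  via IEEE rounding and are flagged low-confidence regardless.
- Empty variant inputs give an empty catalog with a warning; mismatched
  contig universes between the two strain VCFs are a hard error.

## Known limitations

- The zygosity thresholds are not calibrated against any external call set;
  exact concordance with a specific upstream caller may require tuning.
- `NDJ_EMBRYO` is partially confounded with PPB amplification failure (see
  above); the measured nondisjunction-location fraction is accordingly biased
  by the chromosome-failure rate.
- A chromosome with embryo `NO_AMP` but PPB homozygous is classed
  `AMBIGUOUS`, a conservative choice where a proper-segregation reading is
  also defensible.
- The copy-number layer is whole-chromosome only: no bins, no GC correction,
  no segmental events, single male reference (no multi-reference averaging).
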