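# haplotrace

Genetic-evidence analysis for **somatic-chromosome haploidization** experiments.

When a somatic nucleus is transferred into an enucleated MII oocyte and the
reconstructed oocyte is fertilized, the diploid somatic chromosome set (2n/2c)
can partition like a meiotic division: one homolog of each pair is extruded
into a **pseudo-polar body (PPB)** and the other remains in the zygote next to
the sperm genome, producing a *somatic-haploid (SH) embryo*. `haplotrace`
implements the genetic readout of that process for an F1-hybrid donor (two
inbred strains, labelled **A** and **B**, e.g. FVB and B6):

- **snp_catalog** — build a catalog of strain-discriminating homozygous SNPs
  from two strain VCFs, and pick one maximal-SNP-density amplicon window
  (1100–1500 bp) per chromosome for amplicon sequencing.
- **zygosity** — call per-chromosome zygosity (`HOM_A / HOM_B / HET / NO_AMP`)
  per sample from allele read counts at catalog sites, robustly to
  whole-genome-amplification allelic dropout.
- **segregation** — classify each chromosome of each PPB–embryo pair as
  `PROPER` (reciprocal), `NDJ_PPB` / `NDJ_EMBRYO` (nondisjunction with
  destination) or `AMBIGUOUS`; correct for donor LOH tracts; infer sex and
  X origin from a Y-marker assay; aggregate cohort statistics.
- **cnv** — chromosome-level copy-number profiles: each chromosome's read
  count divided by the sample's mean autosomal count (r), normalized by a
  reference male sample (R), then integer ploidy and euploidy calls.
- **model** — analytic layer: the semi-cloning probability
  `(p_proper / 2)^n` (`2^-20 ≈ 9.54e-7` for the mouse's 20 pairs at
  `p_proper = 1`), the binomial distribution of properly-segregated counts,
  and a nondisjunction-rate estimator with exact Clopper–Pearson intervals.
- **synthetic_data** — a ground-truthed generator of the whole experiment
  (catalog, LOH-bearing donor, segregation events, WGA dropout, Poisson
  depth, chromosome read counts), used by the test suite and the acceptance
  script.

## Worked example

```python
from haplotrace import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(sim=SimConfig(n_pairs=15, p_nondisjunction=0.24,
                              p_ndj_to_ppb=0.74, seed=0))
report = run_pipeline(cfg, out_dir="out")
s = report["segregation_summary"]
print(s["n_proper_per_pair"]["pair000"])   # 12
print(round(s["percent_proper_mean"], 1)) # 69.7
print(report["ndj_rate_estimate"]["p_hat"])  # 0.2666...
print(report["semicloning_probability_20_pairs"])  # 9.5367431640625e-07
```

This simulates 15 PPB–embryo pairs at a 24% per-chromosome nondisjunction
rate (74% of nondisjoined pairs extruded to the PPB), genotypes every sample
at donor-informative catalog sites, classifies each pair's 20 chromosomes and
summarizes the cohort: `pair000` has 12 of 20 chromosomes properly segregated;
on average 69.7% of chromosomes per embryo are classified as reciprocally
segregated (the truth rate is 76%; the gap is assay noise — dropout,
amplification failure — deliberately included in the generator); the
estimator recovers a nondisjunction rate near the configured 0.24. The same
pipeline is exposed as a CLI:

```bash
haplotrace simulate --seed 0 --out sim/
haplotrace catalog strainA.vcf strainB.vcf --out catalog/
haplotrace genotype sim/allele_counts.tsv --catalog sim/catalog.tsv --out calls.tsv
haplotrace segregate calls.tsv --manifest sim/manifest.tsv --counts sim/allele_counts.tsv --out seg/
haplotrace cnv chrom_counts.tsv --reference ref_male --out cnv/
haplotrace model --n 20 --proper 55 --classified 60
haplotrace run --seed 0 --out run/
```

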