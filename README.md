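# beanpop

Population genomics of wild-to-crop introgression during domestication,
built around the scarlet runner bean (*Phaseolus coccineus*), an
open-pollinated legume whose traditional varieties grow in sympatry with
their wild relatives in the Mexican highlands. The package is for
population geneticists who want a desk-scale, fully simulated testbed for
the complete analysis chain applied to GBS SNV panels of crops and their
wild relatives:

* **Synthetic data** — coalescent simulation (msprime) of wild +
  cultivated panels under domestication scenarios (bottleneck, expansion,
  epoch-limited wild-to-crop migration), with phased haplotypes, known
  ancestral states, true donor-tract bookkeeping, and a GBS artifact
  layer (overdispersed depth, structured missingness, collapsed
  paralogs, related samples).
* **Variant QC** — the two-stage filter chain: mean depth ≥ 6×, site
  missingness ≤ 0.05, sample missingness ≤ 0.30/0.15, exact
  Hardy-Weinberg exclusion (p < 0.01 in any wild population), HDplot
  paralog detection (heterozygote proportion *H* vs read-ratio deviation
  *D*), and KING-robust kinship pruning (φ > 0.05).
* **Diversity** — H_O, H_E, F_IS (1000 site bootstraps), Weir-Cockerham
  pairwise F_ST, private-allele classification, ADZE-style rarefied
  (private) allelic richness, and the diversity-vs-distance test.
* **Introgression** — Patterson's D
  (`D = (ABBA − BABA)/(ABBA + BABA)` from derived-allele frequencies)
  with weighted block-jackknife Z tests and Bonferroni correction, and
  the f_d scan in 25-SNV / 10-SNV sliding windows with top-5% window
  calling per chromosome.
* **Selection** — EHH and iHS (MAF 0.05, |iHS| ≥ 1.5, p < 0.05) in
  25-kb / 12.5-kb windows, intersected with introgressed windows to
  nominate adaptive-introgression candidates.
* **Demography** — site-frequency spectra per SNV category, Watterson's
  θ_W = S/a_n with expectation ξ_i = θ_W/i, runs of homozygosity
  (≥ 500 kb), and fastsimcoal2-style composite-likelihood fitting of
  migration-epoch scenarios (recent / ancient / constant) with AIC
  weights and parametric bootstrap.

## Layout

The repository is organised as an analysis project: every computation
lives in the library (`src/beanpop/`), and the numbered scripts under
`analysis/` are thin narrative drivers that run one stage each and write
tables under `results/`:

```
analysis/01_simulate_cohort.py   # simulate the GBS-like study cohort -> VCF
analysis/02_variant_qc.py        # two-stage QC chain + filter report
analysis/03_diversity.py         # H_E/F_IS/F_ST, private alleles, rarefaction
analysis/04_introgression.py     # ABBA-BABA trios + f_d windows
analysis/05_selection.py         # iHS scan + adaptive-introgression overlap
analysis/06_demography.py        # SFS, ROH, scenario fitting + AIC + bootstrap
```

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_variant_qc.py
```

prints (seed 1):

```
cohort: 25 samples x 7600 SNVs on 11 chromosomes
injected: 400 collapsed paralogs, 2 parent-offspring pairs, 1 duplicates; ...
HDplot: 95.2% of injected paralogs flagged, 0.76% false positives
                 filter    axis  before  removed  after
              biallelic   sites    7600        0   7600
      chromosome_mapped   sites    7600      154   7446
         min_mean_depth   sites    7446        1   7445
       site_missingness   sites    7445      625   6820
sample_missingness_0.30 samples      25        0     25
               hwe_wild   sites    6820       75   6745
        hdplot_paralogs   sites    6745      323   6422
        kinship_pruning samples      25        5     20
sample_missingness_0.15 samples      20        0     20
kept 20 samples and 6422 SNVs
```

Each row telescopes (before − removed = after, chaining into the next
row). 95% of the injected collapsed paralogs are caught at a 0.8% false
positive rate, and kinship pruning removes one member of every injected
relative pair. Continuing with `analysis/06_demography.py` fits the
three migration-timing scenarios to a spectrum simulated under ancient
migration and prints the AIC table — the ancient template wins with
weight 1.0 and the migration rate is re-estimated within a factor of two.

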