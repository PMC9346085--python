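# Methods

This note documents the models, estimators and design choices behind the
package, in the spirit of a methods supplement: what is computed, under
which assumptions, with which defaults, and what the synthetic-data
experiments do and do not demonstrate.

## Demographic models

All scenarios are two-population (wild + cultivated) coalescent models
with time in generations and diploid effective sizes.

* **Domestication-centre templates (`tmvb_*`)** — the cultivated
  population diverges from the wild one at TDOM (the domestication
  onset), is founded at the bottleneck size NAC, and grows exponentially
  from TEXP to its current size NCC (growth rate `ln(NCC/NAC)/TEXP`).
  The wild size NWILD is constant. An early-domestication bidirectional
  exchange operates for the first 2000 generations after divergence.
* **Sympatric-relative templates (`smocc_*`, `surch_*`)** — divergence
  at TDIV predates domestication; the bottleneck NAC represents
  traditional-variety spreading.
* **Migration epochs** — the defining feature of each template:
  *recent* = 3000 generations ago to the present, *ancient* = 6000 to
  3000, *constant* = 6000 (or TDOM) to the present. Rates are forward-
  time per-generation replacement fractions of the recipient; MIGWC =
  NMWC/NWILD when expressed as migrant counts, and the model validates
  that identity.
* **`bottleneck_only`** — a single cultivated population with ancestral
  size NANC, bottleneck NBOT from TBOT, and expansion to NCUR from TEXP;
  used for cultivars without detectable wild gene flow and, with all
  sizes equal, as a constant-size control.
* **`trio`** — a four-taxon tree (((h1, h2), h3), out) with an optional
  donor epoch h3 → h2, used by the gene-flow test experiments.

Simulation is backward-in-time coalescent with recombination (msprime)
on 11 chromosomes (configurable lengths, desk-scale default 5 Mb, or
2–3 Mb in the standard fixtures). Mutation and recombination rates
default to 1e-8 per bp per generation; neither is asserted to be the
species' true rate — all inference is reported in the same units used
for simulation, so the experiments are internally consistent. Site
categories (nongenic 14% / intronic 45% / CDS 41%, with CDS effects
41.84 / 56.01 / 1.65 / 0.75% synonymous / nonsynonymous / frameshift /
nonsense) are assigned independently of the genealogy: no selection is
simulated, and adaptive-introgression truth is represented by tract
bookkeeping, not fitness.

**Donor tracts.** With migration recorded, a lineage's passage through
the donor population at a time younger than the split marks all sample
material below it, over the record's genomic span, as donor-origin.
Tracts are reported per diploid sample (union of its two haplotypes),
1-based inclusive.

## GBS artifact layer

Depth is negative-binomial (mean 30×, size 5) around a lognormal
per-site scale; missingness is the product of exponentially distributed
per-site and per-sample rates (so a minority of sites/samples are much
worse than average); collapsed paralogs are built by merging a site with
a randomly chosen *polymorphic* partner (MAF ≥ 0.05) — the apparent
genotype reflects all four haploid alleles, doubling depth and skewing
heterozygote read ratios, which is exactly the signature the paralog
filter targets. A collapse with an invariant second copy would neither
distort genotypes nor be detectable, so it is not simulated. Related
samples are appended by per-site Mendelian sampling from two distinct
parents (distinct across pairs, so the injected relatives form no
triangles among themselves and the truth table stays identifiable).

## QC chain

Stage 1 applies, in order: biallelic-only, chromosome-mapped-only, mean
depth ≥ 6×, site missingness ≤ 0.05, sample missingness ≤ 0.30, exact
Hardy-Weinberg exclusion (full Levene-Haldane enumeration, two-sided by
summing configurations no more probable than the observed one; p < 0.01
in at least one wild population), and HDplot paralog removal
(H > 0.6 or |D| > 5; the cutoffs are not canonical and are exposed in
config). Stage 2 prunes one member of each within-population pair with
KING-robust φ > 0.05 — pairs are resolved in descending φ, and within a
pair the member with more missing data (ties: the lexicographically
later id) is dropped — then removes samples with missingness > 0.15.
The filter report telescopes exactly and is asserted to.

The standard QC cohort deliberately uses a mild bottleneck (NAC =
15,000) and a 22-Mb genome with 8000 SNVs: in a severely bottlenecked
population, pairs of samples are *genuinely* related above φ = 0.05, and
with fewer/linked sites the φ sampling noise alone crosses the
threshold; both would make "exactly one member of each injected pair is
removed" unverifiable even though the pruning is correct. The QC
experiment therefore demonstrates artifact detection, not pruning
behaviour under pervasive true relatedness.

## Diversity statistics

H_E uses the small-sample correction 2p(1−p)·2n/(2n−1) (configurable
off); F_IS is aggregated as 1 − mean(H_O)/mean(H_E) over sites (ratio of
sums — stable for low-diversity sites) with a 1000-replicate site
bootstrap percentile CI. Pairwise F_ST is the Weir-Cockerham (1984)
ratio-of-sums θ from per-site variance components, NaN-skipping sites
monomorphic across the pair or with < 2 genotyped individuals in either
population. Private alleles are classified per unit (one population /
the wilds / the cultivars / the ferals) from pairwise-complete allele
frequencies. Rarefied allelic richness at g gene copies is the
hypergeometric expectation `sum_a [1 − C(N−N_a, g)/C(N, g)]`; private
richness multiplies the probability of presence in the focal subsample
by the probability of absence from every other population's subsample;
loci with > 0.2 missingness in any population are excluded. Geographic
distance is haversine on the sphere; the reference centroid is the mean
of the reference populations' coordinates on the lat/lon plane (spans
are small).

## Gene-flow tests

Patterson's D is computed from population derived-allele frequencies
(ABBA = Σ(1−p1)p2p3(1−p4), BABA symmetric). Polarization uses the
recorded ancestral state where available; for plain VCFs the outgroup
major allele polarizes and sites with outgroup frequency in (0.2, 0.8)
are dropped. Significance uses the weighted delete-one block jackknife
(Busing's formulation; block weights ∝ informative-site sums) over
contiguous blocks, default 1 Mb, requiring ≥ 20 non-empty blocks; the
experiments use 25 independent 150-kb loci as natural blocks. f_d
follows the dynamic-donor normalization with non-positive numerators
clamped to 0, in windows of 25 informative SNVs advancing by 10, never
spanning chromosomes; top-5% windows are flagged per chromosome with
ties at the threshold included.

The tract-enrichment check compares f_d between windows where a
majority of recipient samples carry a true donor tract and the rest,
with a one-sided rank-sum test on every third window (sliding windows
share SNVs; thinning removes the overlap, though residual linkage still
makes the nominal level approximate — the null experiment tolerates up
to 3/10 nominally significant replicates for this reason).

## Selection scan

EHH is the probability that two random carriers of a core allele are
identical from the core out to x, evaluated at successive SNVs until it
falls below 0.05; iHH is the trapezoid integral over physical distance,
both directions; the unstandardized score ln(iHH_A/iHH_D) is z-scored
within 20 equal-width derived-frequency bins (bins under 10 SNVs merged
with their nearest occupied neighbour) and p is two-sided normal.
Edge-censored SNVs (chromosome end reached before decay) are excluded
by default. The scan runs on phased haplotypes — the simulator provides
truth phase; an unphased mode is not implemented. Sweep windows are
25 kb / 12.5 kb tiles flagged when they contain a SNV with |iHS| ≥ 1.5
and p < 0.05; adaptive-introgression candidates are genes (or windows)
overlapping both a sweep candidate and a top-5% f_d window on ≥ 1 bp.

## SFS inference

Observed spectra are derived-allele-count histograms per population and
SNV category, complete-cases by default with optional hypergeometric
projection. The expected spectrum under a scenario is a Monte Carlo
over independent non-recombining loci using branch-length frequency
spectra — the conditional expectation of the mutation count per entry
given each simulated genealogy — which removes mutation-placement noise
and lets desk-scale replicate counts (hundreds to thousands of loci)
stand in for very large mutational simulation budgets. Zero entries are
floored at 1/(10 · n_sims · entries) before the multinomial composite
log-likelihood ln L = Σ ξ_i ln p̂_i (monomorphic classes excluded); the
likelihood at the empirical proportions is asserted to upper-bound every
fit. Optimization is bounded scalar minimization (one free parameter)
or multi-start Nelder-Mead (several), on log10 scale, with a fixed seed
per fit so common random numbers keep the surface smooth. Models are
compared by AIC = 2k − 2 ln L and Akaike weights; parameter uncertainty
by a parametric bootstrap (re-simulate at the fit, re-fit, percentile
CI).

ROH detection is a run-based scan — maximal runs of consecutive
genotyped sites containing at most `max_het` heterozygous calls
(default 1), emitted at ≥ 500 kb and ≥ 25 SNVs — deliberately simpler
than PLINK's windowed heuristic.

## Validation experiments and their frozen conditions

The experiments in `beanpop.experiments` (run by the test suite at full
scale and by `scripts/acceptance.py` at reduced replicate counts) fix
their study conditions once (`configs/scenarios.yaml`):

* **TMVB recovery** — ground truth NAC = 2500, TDOM = 9700,
  TEXP = 1500, NCC = 759,000, the best-fit constant-introgression
  domestication history; NWILD = 25,000 and MIGWC = 1e-4 complete the
  model (chosen once as realistic values). Observed data are 11,000
  nongenic SNVs (the size of a realistic GBS nongenic panel) drawn as
  exact multinomials from a high-precision truth spectrum — the
  generative model for independent sites. Each parameter is re-fit
  one-at-a-time with the others fixed at truth. NAC, TDOM and TEXP use
  the joint wild (10 diploids) + cultivated (20) spectrum with 300
  simulated loci per likelihood evaluation. NCC — the weakly identified
  parameter, visible only through the recent-expansion excess of rare
  cultivated variants — uses the marginal spectrum of the full
  30-diploid cultivated panel with all entries above count 8 pooled
  (the tail carries almost no NCC signal but most of the Monte-Carlo
  noise) and a shared 17-point profile-likelihood grid at 20,000 loci
  per grid value, refined by quadratic interpolation. Even at the
  data-noise limit, NCC recovery within a factor of 2 sits near 90%:
  this experiment documents the resolution of SFS-based inference at
  this panel size, not a property of the optimizer.
* **Migration-rate recovery** — MIGWC = 1.93e-5 under the ancient
  (6000–3000) epoch with NAC = 8500, NCC = 742,000; TDIV = 20,000,
  TEXP = 1000, NWILD = 25,000 complete the model. Rates are weakly
  identified; the factor-3 criterion documents this.
* **Scenario discrimination** — the recent/ancient/constant templates
  are simulated and cross-fit at MIGWC = 3e-4: at 1.93e-5 the recent
  and constant epochs are nearly indistinguishable from SFS data at
  this scale, so the discrimination experiment uses a rate at which
  timing leaves a usable signature.
* **Four-taxon experiments** — Ne = 10,000 everywhere, splits at
  4000/10,000/30,000 generations; the gene-flow condition is a recent
  sympatric epoch (rate 5e-4 over the last 500 generations). Null
  calibration uses 200 replicates of 25 loci; the expected |Z| > 1.96
  rate band [0.01, 0.10] reflects the jackknife's finite-block
  behaviour at this scale.

### What the synthetic data do and do not show

The generator reproduces the statistical structure the estimators
assume: neutral coalescent genealogies, epoch-limited migration, known
polarization, and the GBS artifacts the QC chain removes. It does not
simulate selection (so iHS calibration is purely neutral), restriction-
site ascertainment, genotyping error beyond depth/missingness, or
population structure within labelled populations. Passing tests
demonstrate internal consistency of the estimators at these conditions —
not that the real organism's history is recovered from real data.

## Known limitations

* Frequency-based D is one coherent estimator; genotype-likelihood and
  tool-specific variants are out of scope.
* The composite likelihood ignores linkage among sites (as does the
  method it mirrors); bootstrap CIs inherit that approximation.
* ROH and HWE filters assume diploid autosomes.
* The iHS scan requires phase; unphased GBS data would need external
  phasing first.
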