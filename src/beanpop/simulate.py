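"""Synthetic GBS-like genotype panels under the demographic scenarios.

The generator produces exactly the statistical structure the analysis
assumes: phased coalescent genotypes on 11 chromosomes under a
:class:`~beanpop.demography.DemographicModel`, with a known ancestral
state per site, donor-origin tract truth for introgression-scan
validation, and a configurable layer of GBS artifacts (overdispersed
depth, structured missingness, collapsed paralogs, related samples) that
the QC chain is designed to remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np

from .datatypes import MISSING, GenotypeDataset, PopulationMap, SiteAnnotation
from .demography import DemographicModel

N_CHROMOSOMES = 11
DEFAULT_CHROM_LENGTH = 5_000_000  # bp, desk scale
#: default site-category mixture (nongenic, intronic, CDS)
CATEGORY_PROBS = {"nongenic": 0.14, "intronic": 0.45, "CDS": 0.41}
#: default coding-effect mixture within CDS
EFFECT_PROBS = {
    "synonymous": 0.4184,
    "nonsynonymous": 0.5601,
    "frameshift": 0.0165,
    "nonsense": 0.0075,
}

_BASES = np.array(["A", "C", "G", "T"])


def default_chrom_lengths(length: int = DEFAULT_CHROM_LENGTH) -> dict[str, int]:
    return {f"Chr{i:02d}": int(length) for i in range(1, N_CHROMOSOMES + 1)}


@dataclass
class ArtifactConfig:
    """GBS-artifact layer parameters.

    mean_depth:
        target mean read depth per genotype (reads); the study-like default
        is 30x with moderate overdispersion.
    depth_dispersion:
        negative-binomial size parameter (smaller = more overdispersed).
    site_missing_rate / sample_missing_rate:
        mean per-site and per-sample missingness; actual rates are drawn
        from an exponential around the mean so a minority of sites/samples
        are much worse than average, as in real GBS panels.
    paralog_fraction:
        fraction of sites rebuilt by collapsing two independent loci into
        one apparent site (excess heterozygosity, skewed read ratios).
    related_pairs:
        number of parent-offspring samples to append by Mendelian sampling.
    duplicate_pairs:
        number of exact-duplicate samples to append (re-genotyped clones).
    scaffold_fraction:
        fraction of sites flagged as mapped only to unplaced scaffolds.
    """

    mean_depth: float = 30.0
    depth_dispersion: float = 5.0
    site_missing_rate: float = 0.01
    sample_missing_rate: float = 0.01
    paralog_fraction: float = 0.05
    related_pairs: int = 2
    duplicate_pairs: int = 0
    scaffold_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("site_missing_rate", "sample_missing_rate",
                     "paralog_fraction", "scaffold_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.paralog_fraction >= 0.2:
            raise ValueError("paralog_fraction must be < 0.2")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass
class ArtifactTruth:
    """Ground truth for every injected artifact."""

    paralog_sites: list[tuple[str, int]] = field(default_factory=list)
    related_pairs: list[tuple[str, str]] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    scaffold_sites: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# coalescent simulation
# ---------------------------------------------------------------------------

def _extract_tracts(
    ts, donor_id: int, split_time: float, sample_nodes: np.ndarray
) -> list[tuple[int, int, int]]:
    """Donor-origin intervals per sample node from migration records.

    A lineage record with (backward-time) destination equal to the donor
    population at a time younger than the split means the material it
    carries passed through the donor; every sample below that node over
    the record's span inherits the tract. Returns (node, left, right)
    half-open bp intervals.
    """
    sample_set = set(int(s) for s in sample_nodes)
    out: list[tuple[int, int, int]] = []
    mig = ts.tables.migrations
    for k in range(len(mig)):
        if int(mig.dest[k]) != donor_id or mig.time[k] >= split_time:
            continue
        node = int(mig.node[k])
        left, right = float(mig.left[k]), float(mig.right[k])
        tree = ts.at(left)
        while tree.interval.left < right:
            lo = max(left, tree.interval.left)
            hi = min(right, tree.interval.right)
            if hi > lo:
                if node in sample_set:
                    out.append((node, int(lo), int(hi)))
                else:
                    for s in tree.samples(node):
                        if int(s) in sample_set:
                            out.append((int(s), int(lo), int(hi)))
            if tree.interval.right >= right or not tree.next():
                break
    return out


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    merged = [list(iv[0])]
    for lo, hi in iv[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def simulate_genotypes(
    model: DemographicModel,
    n_samples: dict[str, int],
    n_sites: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
    mutation_rate: float = 1e-8,
    recombination_rate: float = 1e-8,
    seed: int | None = None,
    category_probs: dict[str, float] | None = None,
    effect_probs: dict[str, float] | None = None,
    ancestral_is_ref_prob: float = 0.8,
    record_tracts: bool = True,
) -> tuple[GenotypeDataset, SiteAnnotation, list[tuple[str, str, int, int]]]:
    """Simulate phased diploid genotypes under a demographic scenario.

    Returns the dataset, a site annotation with exact ancestral states and
    randomly assigned category/effect labels, and the list of true
    donor-origin tracts ``(sample_id, chrom, start, end)`` (1-based
    inclusive) carried by cultivated samples when the model includes
    wild-to-crop migration.

    Category and effect labels are assigned independently of the
    genealogy (no selection is simulated); the defaults mirror the
    observed nongenic/intronic/CDS mixture of a typical GBS panel.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible simulation")
    if mutation_rate <= 0 or recombination_rate < 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or default_chrom_lengths()
    category_probs = category_probs or CATEGORY_PROBS
    effect_probs = effect_probs or EFFECT_PROBS

    pop_labels = [lbl for lbl, _ in model.populations]
    samples = {lbl: n_samples.get(lbl, 0) for lbl in pop_labels}
    sample_ids: list[str] = []
    for lbl in pop_labels:
        sample_ids += [f"{lbl}_{i:03d}" for i in range(samples[lbl])]
    n_dip = len(sample_ids)

    demography = model.to_msprime()
    donor_recipient = [
        (d, r) for (_, _, d, r, rate) in model.migration_epochs
        if rate > 0 and dict(model.populations).get(d) == "wild"
    ]
    want_tracts = record_tracts and bool(donor_recipient) and model.split_time is not None

    all_chrom, all_pos, all_gt, all_hap = [], [], [], []
    tracts: list[tuple[str, str, int, int]] = []
    for chrom_name, length in chrom_lengths.items():
        sim_seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples={lbl: n for lbl, n in samples.items() if n > 0},
            demography=demography,
            sequence_length=length,
            recombination_rate=recombination_rate,
            record_migrations=want_tracts,
            random_seed=sim_seed,
        )
        mut_seed = int(rng.integers(1, 2**31 - 1))
        mts = msprime.sim_mutations(
            ts,
            rate=mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=mut_seed,
            discrete_genome=True,
        )
        hap = mts.genotype_matrix().T  # (haplotypes, sites), derived dosage
        positions = np.array(
            [int(s.position) + 1 for s in mts.sites()], dtype=np.int64
        )
        seg = (hap.sum(axis=0) > 0) & (hap.sum(axis=0) < hap.shape[0])
        # discrete genome can stack mutations; keep unique biallelic positions
        uniq = np.concatenate([[True], np.diff(positions) > 0])
        keep = seg & uniq
        hap = hap[:, keep]
        positions = positions[keep]
        all_chrom.append(np.full(len(positions), chrom_name, dtype=object))
        all_pos.append(positions)
        all_hap.append(hap.astype(np.int8))
        if want_tracts:
            recipients = {r for _, r in donor_recipient}
            for donor in {d for d, _ in donor_recipient}:
                donor_id = [
                    p.id for p in demography.populations if p.name == donor
                ][0]
                node_tracts = _extract_tracts(
                    ts, donor_id, float(model.split_time), ts.samples()
                )
                node_to_sample = {}
                for ind in ts.individuals():
                    for node in ind.nodes:
                        node_to_sample[int(node)] = int(ind.id)
                by_sample: dict[int, list[tuple[int, int]]] = {}
                for node, lo, hi in node_tracts:
                    by_sample.setdefault(node_to_sample[node], []).append((lo, hi))
                for ind_id, ivs in sorted(by_sample.items()):
                    sid = sample_ids[ind_id]
                    if sid.rsplit("_", 1)[0] not in recipients:
                        continue
                    for lo, hi in _merge_intervals(ivs):
                        tracts.append((sid, chrom_name, lo + 1, hi))

    chrom = np.concatenate(all_chrom)
    pos = np.concatenate(all_pos)
    hap = np.concatenate(all_hap, axis=1)

    if n_sites is not None and hap.shape[1] > n_sites:
        pick = np.sort(rng.choice(hap.shape[1], size=n_sites, replace=False))
        chrom, pos, hap = chrom[pick], pos[pick], hap[:, pick]
    elif n_sites is not None and hap.shape[1] < n_sites:
        warnings.warn(
            f"requested {n_sites} sites but only {hap.shape[1]} segregating "
            "sites were produced at the given rates"
        )
    n_sites_out = hap.shape[1]

    # map the binary derived state onto ref/alt bases with known polarity
    ref = np.empty(n_sites_out, dtype=object)
    alt = np.empty(n_sites_out, dtype=object)
    anc_state = np.empty(n_sites_out, dtype=object)
    base_idx = rng.integers(0, 4, size=n_sites_out)
    shift = rng.integers(1, 4, size=n_sites_out)
    anc_base = _BASES[base_idx]
    der_base = _BASES[(base_idx + shift) % 4]
    anc_is_ref = rng.random(n_sites_out) < ancestral_is_ref_prob
    genotypes = (hap[0::2] + hap[1::2]).astype(np.int8)  # derived dosage
    hap_out = hap.copy()
    for j in range(n_sites_out):
        if anc_is_ref[j]:
            ref[j], alt[j] = anc_base[j], der_base[j]
            anc_state[j] = "ref"
        else:
            ref[j], alt[j] = der_base[j], anc_base[j]
            anc_state[j] = "alt"
            genotypes[:, j] = 2 - genotypes[:, j]
            hap_out[:, j] = 1 - hap_out[:, j]

    category = rng.choice(
        list(category_probs), size=n_sites_out, p=list(category_probs.values())
    ).astype(object)
    effect = np.full(n_sites_out, "none", dtype=object)
    cds = category == "CDS"
    effect[cds] = rng.choice(
        list(effect_probs),
        size=int(cds.sum()),
        p=np.array(list(effect_probs.values())) / sum(effect_probs.values()),
    )

    dataset = GenotypeDataset(
        sample_ids=sample_ids,
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        genotypes=genotypes,
        phased_haplotypes=hap_out,
    )
    annotation = SiteAnnotation(
        category=category,
        effect=effect,
        ancestral_allele=anc_state,
    )
    assert n_dip == dataset.n_samples
    return dataset, annotation, tracts


# ---------------------------------------------------------------------------
# GBS artifact layer
# ---------------------------------------------------------------------------

def apply_gbs_artifacts(
    dataset: GenotypeDataset,
    annotation: SiteAnnotation,
    config: ArtifactConfig,
) -> tuple[GenotypeDataset, SiteAnnotation, ArtifactTruth]:
    """Overlay depth, missingness, collapsed paralogs and related samples.

    Paralog sites are built by collapsing a site with a randomly chosen
    partner site: the apparent genotype reflects all four haploid alleles
    (heterozygous whenever both alleles are present), read depth doubles
    and the ref read fraction follows the 4-allele dosage, producing the
    excess heterozygosity and skewed read ratios the paralog filter
    targets. Partner sites are consumed (removed). Related samples are
    appended by per-site Mendelian sampling from two existing parents.
    """
    if dataset.phased_haplotypes is None:
        raise ValueError("artifact layer requires phased haplotypes")
    rng = np.random.default_rng(config.seed)
    truth = ArtifactTruth()

    hap = dataset.phased_haplotypes.copy()
    geno = dataset.genotypes.copy()
    sample_ids = list(dataset.sample_ids)
    n_sites = dataset.n_sites

    # --- related samples (parent-offspring) ----------------------------
    # distinct parents across pairs so injected relatives do not form
    # triangles among themselves (keeps the truth table identifiable)
    n_parents = 2 * config.related_pairs + config.duplicate_pairs
    if n_parents > len(sample_ids):
        raise ValueError("not enough samples to host the requested relatives")
    parent_pool = list(rng.choice(len(sample_ids), size=n_parents, replace=False))
    for k in range(config.related_pairs):
        p1, p2 = parent_pool.pop(), parent_pool.pop()
        child_id = f"{sample_ids[p1]}_off{k}"
        g1 = hap[2 * p1 + rng.integers(0, 2, size=n_sites), np.arange(n_sites)]
        g2 = hap[2 * p2 + rng.integers(0, 2, size=n_sites), np.arange(n_sites)]
        hap = np.vstack([hap, g1[None, :], g2[None, :]])
        geno = np.vstack([geno, (g1 + g2)[None, :]])
        truth.related_pairs.append((sample_ids[p1], child_id))
        sample_ids.append(child_id)
    for k in range(config.duplicate_pairs):
        p = int(parent_pool.pop())
        dup_id = f"{sample_ids[p]}_dup{k}"
        hap = np.vstack([hap, hap[2 * p : 2 * p + 2]])
        geno = np.vstack([geno, geno[p][None, :]])
        truth.duplicate_pairs.append((sample_ids[p], dup_id))
        sample_ids.append(dup_id)
    n_samp = len(sample_ids)

    # --- collapsed paralogs --------------------------------------------
    n_par = int(round(config.paralog_fraction * n_sites))
    ref_frac = np.full((n_samp, n_sites), np.nan)
    drop = np.zeros(n_sites, dtype=bool)
    if n_par > 0:
        # collapse only polymorphic loci: a duplicate whose second copy is
        # invariant neither distorts genotypes nor is detectable, so it is
        # not the artifact the paralog filter exists to remove
        freq = geno.mean(axis=0) / 2.0
        eligible = np.flatnonzero((freq >= 0.05) & (freq <= 0.95))
        if 2 * n_par > len(eligible):
            raise ValueError("paralog_fraction incompatible with site count")
        chosen = rng.choice(eligible, size=2 * n_par, replace=False)
        targets, partners = chosen[:n_par], chosen[n_par:]
        for t, q in zip(targets, partners):
            alt4 = geno[:, t].astype(np.int16) + geno[:, q].astype(np.int16)
            collapsed = np.where(
                (alt4 > 0) & (alt4 < 4), 1, np.where(alt4 == 0, 0, 2)
            ).astype(np.int8)
            geno[:, t] = collapsed
            # keep phase representation consistent with the apparent call
            hap[0::2, t] = np.where(collapsed >= 1, 1, 0)
            hap[1::2, t] = np.where(collapsed == 2, 1, 0)
            ref_frac[:, t] = 1.0 - alt4 / 4.0
            truth.paralog_sites.append(
                (str(dataset.chrom[t]), int(dataset.pos[t]))
            )
        drop[partners] = True

    # --- depth and allelic depths --------------------------------------
    site_scale = rng.lognormal(mean=0.0, sigma=0.4, size=n_sites)
    mu = config.mean_depth * site_scale
    par_mask = ~np.isnan(ref_frac[0]) if n_par > 0 else np.zeros(n_sites, bool)
    mu = np.where(par_mask, 2.0 * mu, mu)
    r = config.depth_dispersion
    p_nb = r / (r + mu)
    depth = rng.negative_binomial(r, p_nb[None, :], size=(n_samp, n_sites))
    depth = np.maximum(depth, 1).astype(np.int32)

    het = geno == 1
    pref = np.where(np.isnan(ref_frac), 0.5, ref_frac)
    ad_ref = np.zeros_like(depth)
    ad_ref[het] = rng.binomial(depth[het], pref[het])
    hom_ref = geno == 0
    ad_ref[hom_ref] = depth[hom_ref]
    ad_alt = depth - ad_ref

    # --- missingness ----------------------------------------------------
    if config.site_missing_rate > 0 or config.sample_missing_rate > 0:
        site_rate = np.minimum(
            rng.exponential(config.site_missing_rate, size=n_sites), 0.9
        )
        samp_rate = np.minimum(
            rng.exponential(config.sample_missing_rate, size=n_samp), 0.9
        )
        p_miss = 1.0 - (1.0 - site_rate[None, :]) * (1.0 - samp_rate[:, None])
        miss = rng.random((n_samp, n_sites)) < p_miss
        geno = np.where(miss, MISSING, geno).astype(np.int8)
        depth[miss] = 0
        ad_ref[miss] = 0
        ad_alt[miss] = 0

    # --- scaffold flags --------------------------------------------------
    on_chrom = annotation.on_chromosome.copy()
    n_scaf = int(round(config.scaffold_fraction * n_sites))
    if n_scaf > 0:
        scaf = rng.choice(n_sites, size=n_scaf, replace=False)
        on_chrom[scaf] = False
        truth.scaffold_sites = [
            (str(dataset.chrom[j]), int(dataset.pos[j])) for j in scaf
        ]

    keep = ~drop
    out = GenotypeDataset(
        sample_ids=sample_ids,
        chrom=dataset.chrom[keep],
        pos=dataset.pos[keep],
        ref_allele=dataset.ref_allele[keep],
        alt_allele=dataset.alt_allele[keep],
        genotypes=geno[:, keep],
        depth=depth[:, keep],
        ad_ref=ad_ref[:, keep],
        ad_alt=ad_alt[:, keep],
        phased_haplotypes=None if np.any(geno == MISSING) else hap[:, keep],
    )
    ann_out = SiteAnnotation(
        category=annotation.category[keep],
        effect=annotation.effect[keep],
        ancestral_allele=annotation.ancestral_allele[keep],
        gene_id=None if annotation.gene_id is None else annotation.gene_id[keep],
        on_chromosome=on_chrom[keep],
    )
    return out, ann_out, truth


def make_population_map(
    dataset: GenotypeDataset,
    model: DemographicModel,
    truth: ArtifactTruth | None = None,
    coordinates: dict[str, tuple[float, float]] | None = None,
) -> PopulationMap:
    """Population map for a simulated cohort (artifact offspring follow
    their first parent's population)."""
    cls = dict(model.populations)
    population: dict[str, str] = {}
    sample_class: dict[str, str] = {}
    parent_of = {}
    if truth is not None:
        parent_of.update({c: p for p, c in truth.related_pairs})
        parent_of.update({c: p for p, c in truth.duplicate_pairs})
    for s in dataset.sample_ids:
        base = parent_of.get(s, s)
        label = base.rsplit("_", 1)[0]
        population[s] = label
        sample_class[s] = cls.get(label, "wild")
    lat, lon = {}, {}
    if coordinates:
        for s, p in population.items():
            if p in coordinates:
                lat[s], lon[s] = coordinates[p]
    return PopulationMap(
        population=population, sample_class=sample_class,
        latitude=lat, longitude=lon,
    )
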