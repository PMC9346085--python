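"""SNV and sample quality control for GBS panels.

Implements the two-stage filtering chain used on the runner-bean panel:

stage 1 (site/sample hard filters)
    biallelic-only, chromosome-mapped-only, minimum mean depth (6x),
    per-site missingness (<= 0.05), per-sample missingness (<= 0.30),
    Hardy-Weinberg exclusion (exact test p < 0.01 in at least one wild
    population), and collapsed-paralog removal by the HDplot statistic
    (heterozygote proportion H vs read-ratio deviation D).

stage 2 (relatedness subsetting)
    within-population pairs with KING-robust kinship > 0.05 lose one
    member; samples with missingness > 0.15 are removed.

Every filter step appends a telescoping row to the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import (
    MISSING,
    GenotypeDataset,
    PopulationMap,
    SiteAnnotation,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for the two-stage QC chain (study defaults)."""

    min_mean_depth: float = 6.0
    max_site_missing: float = 0.05
    max_sample_missing_stage1: float = 0.30
    max_sample_missing_stage2: float = 0.15
    hwe_alpha: float = 0.01
    kinship_threshold: float = 0.05
    hdplot_h_max: float = 0.6
    hdplot_d_max: float = 5.0
    kinship_min_sites: int = 50

    def __post_init__(self) -> None:
        if self.max_sample_missing_stage2 > self.max_sample_missing_stage1:
            raise ValueError("stage-2 sample threshold must be <= stage-1")
        for name in ("max_site_missing", "max_sample_missing_stage1",
                     "max_sample_missing_stage2", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class FilterReport:
    """Ordered telescoping record of each filter step."""

    rows: list[dict] = field(default_factory=list)

    def add(self, name: str, axis: str, before: int, after: int) -> None:
        self.rows.append(
            {
                "filter": name,
                "axis": axis,
                "before": before,
                "removed": before - after,
                "after": after,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def telescopes(self) -> bool:
        """True when counts chain exactly within each axis."""
        for axis in ("sites", "samples"):
            rows = [r for r in self.rows if r["axis"] == axis]
            for prev, nxt in zip(rows, rows[1:]):
                if prev["after"] != nxt["before"]:
                    return False
            if any(r["before"] - r["removed"] != r["after"] for r in rows):
                return False
        return True


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test for one biallelic site.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the probabilities of all configurations no
    more probable than the observed one. Monomorphic input returns 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa  # minor-allele copies (either allele works)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # het counts share parity with the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # P(n_Aa = h | allele counts) under HWE:
    #   C(n, h) C(n-h, (rare-h)/2) 2^h / C(2n, rare) * ... via log factorials
    def log_prob(h: np.ndarray) -> np.ndarray:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_rare + 1)
            - gammaln(hom_common + 1)
            + h * np.log(2.0)
            + gammaln(rare + 1)
            + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    lp = log_prob(hets)
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# HDplot paralog detection
# ---------------------------------------------------------------------------

def hdplot(
    dataset: GenotypeDataset,
    h_max: float = 0.6,
    d_max: float = 5.0,
) -> pd.DataFrame:
    """Per-site heterozygote proportion H and read-ratio deviation D.

    H is the fraction of non-missing genotypes that are heterozygous; D is
    the z-score ``(A - B) / sqrt(A + B)`` of total ref (A) vs alt (B) reads
    summed over heterozygotes. A site is flagged as a putative collapsed
    paralog when ``H > h_max`` or ``|D| > d_max``. Sites with no
    heterozygotes have undefined D (NaN) and are never flagged.
    """
    if dataset.ad_ref is None or dataset.ad_alt is None:
        raise ValueError("HDplot requires per-genotype allelic depths (AD)")
    g = dataset.genotypes
    called = g != MISSING
    het = g == 1
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(n_called > 0, het.sum(axis=0) / n_called, 0.0)
    A = np.where(het, dataset.ad_ref, 0).sum(axis=0).astype(float)
    B = np.where(het, dataset.ad_alt, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(A + B > 0, (A - B) / np.sqrt(A + B), np.nan)
    flagged = (H > h_max) | (np.abs(np.nan_to_num(D)) > d_max)
    n_noD = int(np.isnan(D).sum())
    if n_noD:
        logger.info("%d sites without heterozygote reads: D undefined", n_noD)
    return pd.DataFrame({"H": H, "D": D, "paralog_flag": flagged})


# ---------------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------------

def king_kinship(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    min_sites: int = 50,
) -> float:
    """Within-pair KING-robust kinship coefficient phi.

    ``phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa,i + N_Aa,j)`` over
    pairwise-complete sites; NaN when fewer than ``min_sites`` sites are
    jointly genotyped or neither sample carries a heterozygote.
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    ok = (gi != MISSING) & (gj != MISSING)
    if int(ok.sum()) < min_sites:
        return float("nan")
    gi, gj = gi[ok], gj[ok]
    both_het = int(np.sum((gi == 1) & (gj == 1)))
    opp_hom = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    het_i = int(np.sum(gi == 1))
    het_j = int(np.sum(gj == 1))
    denom = het_i + het_j
    if denom == 0:
        return float("nan")
    return (both_het - 2.0 * opp_hom) / denom


def kinship_matrix(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    min_sites: int = 50,
) -> pd.DataFrame:
    """phi for every within-population sample pair."""
    rows = []
    for pop in popmap.populations():
        members = [s for s in popmap.members(pop) if s in dataset.sample_ids]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i = dataset.sample_index(members[a])
                j = dataset.sample_index(members[b])
                phi = king_kinship(
                    dataset.genotypes[i], dataset.genotypes[j], min_sites
                )
                rows.append(
                    {
                        "population": pop,
                        "sample_i": members[a],
                        "sample_j": members[b],
                        "phi": phi,
                    }
                )
    return pd.DataFrame(rows, columns=["population", "sample_i", "sample_j", "phi"])


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

def _hwe_fail_mask(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    alpha: float,
) -> np.ndarray:
    """Sites out of HWE (p < alpha) in at least one wild population."""
    fail = np.zeros(dataset.n_sites, dtype=bool)
    for pop in popmap.populations("wild"):
        idx = popmap.indices(dataset, pop)
        if len(idx) < 2:
            continue
        g = dataset.genotypes[idx]
        n_AA = (g == 0).sum(axis=0)
        n_Aa = (g == 1).sum(axis=0)
        n_aa = (g == 2).sum(axis=0)
        for j in range(dataset.n_sites):
            if fail[j]:
                continue
            if hwe_exact_test(int(n_AA[j]), int(n_Aa[j]), int(n_aa[j])) < alpha:
                fail[j] = True
    return fail


def run_filter_chain(
    dataset: GenotypeDataset,
    annotation: SiteAnnotation,
    popmap: PopulationMap,
    config: FilterConfig | None = None,
    stage: int = 1,
) -> tuple[GenotypeDataset, SiteAnnotation, FilterReport]:
    """Apply the staged QC chain; returns filtered data plus report.

    ``stage=1`` applies the site/sample hard filters; ``stage=2`` applies
    stage 1 and then the relatedness/missingness sample subsetting.
    """
    if stage not in (1, 2):
        raise ValueError("stage must be 1 or 2")
    config = config or FilterConfig()
    popmap.check_covers(dataset)
    report = FilterReport()
    ds, ann = dataset, annotation

    def site_step(name: str, keep: np.ndarray) -> None:
        nonlocal ds, ann
        before = ds.n_sites
        ds = ds.take_sites(keep)
        ann = ann.take(keep)
        report.add(name, "sites", before, ds.n_sites)
        if ds.n_sites == 0:
            raise ValueError(f"no sites left after filter step {name!r}")

    # biallelic by construction of the data model; record the no-op
    site_step("biallelic", np.ones(ds.n_sites, dtype=bool))
    site_step("chromosome_mapped", ann.on_chromosome.copy())

    if ds.depth is not None:
        mean_depth = np.where(
            (ds.genotypes != MISSING).sum(axis=0) > 0,
            np.where(ds.genotypes != MISSING, ds.depth, 0).sum(axis=0)
            / np.maximum((ds.genotypes != MISSING).sum(axis=0), 1),
            0.0,
        )
        site_step("min_mean_depth", mean_depth >= config.min_mean_depth)

    site_step("site_missingness", ds.missing_by_site() <= config.max_site_missing)

    before = ds.n_samples
    keep_samples = [
        s
        for s, m in zip(ds.sample_ids, ds.missing_by_sample())
        if m <= config.max_sample_missing_stage1
    ]
    ds = ds.take_samples(keep_samples)
    report.add("sample_missingness_0.30", "samples", before, ds.n_samples)
    if ds.n_samples == 0:
        raise ValueError("no samples left after stage-1 missingness filter")

    site_step("hwe_wild", ~_hwe_fail_mask(ds, popmap, config.hwe_alpha))

    if ds.ad_ref is not None:
        hd = hdplot(ds, config.hdplot_h_max, config.hdplot_d_max)
        site_step("hdplot_paralogs", ~hd["paralog_flag"].to_numpy())

    if stage == 2:
        kin = kinship_matrix(ds, popmap, config.kinship_min_sites)
        n_undef = int(kin["phi"].isna().sum()) if len(kin) else 0
        if n_undef:
            logger.warning(
                "%d sample pairs below %d shared sites: kinship undefined, "
                "excluded from pruning",
                n_undef,
                config.kinship_min_sites,
            )
        miss = dict(zip(ds.sample_ids, ds.missing_by_sample()))
        to_drop: set[str] = set()
        # strongest relationships resolved first (duplicates, then
        # first-degree, then borderline pairs)
        flagged = kin[kin["phi"] > config.kinship_threshold].sort_values(
            "phi", ascending=False
        )
        for _, row in flagged.iterrows():
            a, b = row["sample_i"], row["sample_j"]
            if a in to_drop or b in to_drop:
                continue
            # drop the member with more missing data; ties -> later id
            if miss[a] > miss[b]:
                to_drop.add(a)
            elif miss[b] > miss[a]:
                to_drop.add(b)
            else:
                to_drop.add(max(a, b))
        before = ds.n_samples
        ds = ds.take_samples([s for s in ds.sample_ids if s not in to_drop])
        report.add("kinship_pruning", "samples", before, ds.n_samples)

        before = ds.n_samples
        keep_samples = [
            s
            for s, m in zip(ds.sample_ids, ds.missing_by_sample())
            if m <= config.max_sample_missing_stage2
        ]
        ds = ds.take_samples(keep_samples)
        report.add("sample_missingness_0.15", "samples", before, ds.n_samples)
        if ds.n_samples == 0:
            raise ValueError("no samples left after stage-2 filters")

    return ds, ann, report


def classify_effect_counts(
    annotation: SiteAnnotation,
    site_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Counts and proportions per category and, within CDS, per effect."""
    ann = annotation if site_mask is None else annotation.take(site_mask)
    n = ann.n_sites
    rows = []
    for cat in ("nongenic", "intronic", "CDS"):
        count = int(np.sum(ann.category == cat))
        rows.append(
            {
                "level": "category",
                "name": cat,
                "count": count,
                "proportion": count / n if n else float("nan"),
            }
        )
    cds = ann.category == "CDS"
    n_cds = int(cds.sum())
    for eff in ("synonymous", "nonsynonymous", "frameshift", "nonsense"):
        count = int(np.sum(cds & (ann.effect == eff)))
        rows.append(
            {
                "level": "effect",
                "name": eff,
                "count": count,
                "proportion": count / n_cds if n_cds else float("nan"),
            }
        )
    return pd.DataFrame(rows)
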