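"""Diversity, differentiation, private alleles, rarefaction, and the
diversity-vs-distance test.

Conventions
-----------
* Gene diversity H_E uses the small-sample correction
  ``2p(1-p) * 2n/(2n-1)`` (hierfstat's convention); F_IS is aggregated as
  ``1 - mean(H_O)/mean(H_E)`` (ratio of sums), which is stable for
  low-diversity sites.
* Missing data are handled pairwise-complete within each population; a
  site with fewer than two genotyped individuals in a population is
  skipped for that population.
* Geographic distance is the haversine great-circle distance; the
  reference centroid is the mean of the reference populations' lat/lon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import spearmanr

from .datatypes import (
    MISSING,
    GenotypeDataset,
    PopulationMap,
    SiteAnnotation,
)

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# heterozygosity / F_IS
# ---------------------------------------------------------------------------

def _pop_site_het(
    dataset: GenotypeDataset, idx: list[int], small_sample: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (H_O, H_E, usable-mask) for one population."""
    g = dataset.genotypes[idx]
    called = g != MISSING
    n = called.sum(axis=0)
    usable = n >= 2
    het = ((g == 1) & called).sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(usable, het / np.maximum(n, 1), np.nan)
        p = alt / np.maximum(2 * n, 1)
        he = 2.0 * p * (1.0 - p)
        if small_sample:
            he = he * (2 * n) / np.maximum(2 * n - 1, 1)
        he = np.where(usable, he, np.nan)
    return ho, he, usable


def heterozygosity(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    n_bootstrap: int = 1000,
    seed: int = 0,
    small_sample: bool = True,
) -> pd.DataFrame:
    """Per-population H_O, H_E and F_IS with a site-bootstrap CI.

    F_IS = 1 - mean(H_O)/mean(H_E) over usable polymorphic sites; the CI
    is the percentile interval over ``n_bootstrap`` site resamples.
    Populations with fewer than two samples are skipped with a warning;
    monomorphic populations report F_IS as NaN.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pop in popmap.populations():
        idx = popmap.indices(dataset, pop)
        if len(idx) < 2:
            logger.warning("population %s has < 2 samples; skipped", pop)
            continue
        ho, he, usable = _pop_site_het(dataset, idx, small_sample)
        ok = usable & np.isfinite(he)
        ho_v, he_v = ho[ok], he[ok]
        mean_ho = float(np.nanmean(ho_v)) if ok.any() else float("nan")
        mean_he = float(np.nanmean(he_v)) if ok.any() else float("nan")
        if ok.any() and he_v.sum() > 0:
            fis = 1.0 - ho_v.mean() / he_v.mean()
            boots = np.empty(n_bootstrap)
            m = len(ho_v)
            for b in range(n_bootstrap):
                take = rng.integers(0, m, size=m)
                denom = he_v[take].mean()
                boots[b] = 1.0 - ho_v[take].mean() / denom if denom > 0 else np.nan
            lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        else:
            fis, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append(
            {
                "population": pop,
                "class": popmap.class_of_population(pop),
                "n_samples": len(idx),
                "n_sites": int(ok.sum()),
                "H_O": mean_ho,
                "H_E": mean_he,
                "F_IS": fis,
                "F_IS_ci_low": lo,
                "F_IS_ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham pairwise F_ST
# ---------------------------------------------------------------------------

def wc_fst_components(
    dataset: GenotypeDataset, idx1: list[int], idx2: list[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (1984) variance components a, b, c for two
    populations (among-population, among-individual, within-individual).

    Sites where either population has < 2 genotyped individuals, or that
    are monomorphic across both, contribute NaN components.
    """
    r = 2
    stats = []
    for idx in (idx1, idx2):
        g = dataset.genotypes[idx]
        called = g != MISSING
        n_i = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(called, g, 0).sum(axis=0) / np.maximum(2 * n_i, 1)
            h_i = ((g == 1) & called).sum(axis=0) / np.maximum(n_i, 1)
        stats.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = stats
    usable = (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        nc = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / nc) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    poly = usable & (p_bar > 0) & (p_bar < 1)
    a = np.where(poly, a, np.nan)
    b = np.where(poly, b, np.nan)
    c = np.where(poly, c, np.nan)
    return a, b, c


def pairwise_fst(dataset: GenotypeDataset, popmap: PopulationMap) -> pd.DataFrame:
    """Weir-Cockerham theta for every population pair (ratio of sums)."""
    pops = [p for p in popmap.populations() if len(popmap.indices(dataset, p)) >= 2]
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b, c = wc_fst_components(
                dataset,
                popmap.indices(dataset, pops[i]),
                popmap.indices(dataset, pops[j]),
            )
            num = np.nansum(a)
            den = np.nansum(a + b + c)
            theta = num / den if den > 0 else float("nan")
            rows.append(
                {
                    "pop1": pops[i],
                    "pop2": pops[j],
                    "theta": theta,
                    "n_sites": int(np.isfinite(a).sum()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# private alleles
# ---------------------------------------------------------------------------

def private_alleles(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    annotation: SiteAnnotation | None = None,
) -> pd.DataFrame:
    """Classify each population's segregating sites as private or shared.

    An allele is private to a unit (one population, the wilds, the
    cultivars, the ferals) when it segregates in at least one population
    of the unit and is absent everywhere outside it. The table reports,
    per population, the proportions of its segregating sites in each
    class and nonsynonymous/synonymous ratios for private vs shared
    subsets when an annotation is supplied.
    """
    pops = popmap.populations()
    freqs = {}
    present = {}
    for pop in pops:
        idx = popmap.indices(dataset, pop)
        f = dataset.alt_frequency(idx)
        freqs[pop] = f
        present[pop] = np.nan_to_num(f) > 0  # alt allele present
    class_of = {p: popmap.class_of_population(p) for p in pops}
    units: dict[str, list[str]] = {"wild": [], "cultivated": [], "feral": []}
    for p in pops:
        if class_of[p] in units:
            units[class_of[p]].append(p)

    rows = []
    for pop in pops:
        f = freqs[pop]
        seg = np.isfinite(f) & (f > 0) & (f < 1)
        others = [q for q in pops if q != pop]
        absent_outside = ~np.logical_or.reduce(
            [present[q] for q in others]
        ) if others else np.ones(dataset.n_sites, bool)
        private_pop = seg & absent_outside
        cls = class_of[pop]
        unit_members = units.get(cls, [pop])
        outside_unit = [q for q in pops if q not in unit_members]
        absent_outside_unit = ~np.logical_or.reduce(
            [present[q] for q in outside_unit]
        ) if outside_unit else np.ones(dataset.n_sites, bool)
        private_unit = seg & absent_outside_unit & ~private_pop
        shared = seg & ~private_pop & ~private_unit

        row = {
            "population": pop,
            "class": cls,
            "segregating": int(seg.sum()),
            "private_to_population": int(private_pop.sum()),
            "private_to_class": int(private_unit.sum()),
            "shared": int(shared.sum()),
        }
        denom = max(int(seg.sum()), 1)
        row["prop_private"] = (row["private_to_population"]) / denom
        if annotation is not None:
            for label, mask in (("private", private_pop), ("shared", shared)):
                nonsyn = int(np.sum(mask & (annotation.effect == "nonsynonymous")))
                syn = int(np.sum(mask & (annotation.effect == "synonymous")))
                row[f"nonsyn_syn_{label}"] = (
                    nonsyn / syn if syn > 0 else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rarefaction (allelic richness / private allelic richness)
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    out = np.full(n.shape, -np.inf)
    ok = n >= k
    out[ok] = gammaln(n[ok] + 1) - gammaln(k + 1) - gammaln(n[ok] - k + 1)
    return out


def _prob_absent(count_other: np.ndarray, total: np.ndarray, g: int) -> np.ndarray:
    """P(allele absent from a subsample of g gene copies) = C(N-Na, g)/C(N, g)."""
    with np.errstate(invalid="ignore"):
        return np.exp(_log_comb(total - count_other, g) - _log_comb(total, g))


def rarefied_richness(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    g_max: int,
    missing_rule: float = 0.2,
) -> pd.DataFrame:
    """Rarefaction curves of allelic richness and private allelic richness.

    Loci with missing-data fraction above ``missing_rule`` in any
    population are excluded. For each population and subsample size g
    (gene copies), expected richness at a locus is
    ``sum_alleles [1 - C(N - N_a, g) / C(N, g)]`` and private richness is
    the probability the allele appears in the focal subsample and in no
    other population's subsample of size g; both are averaged over loci.
    Curves are truncated (with a warning) at the smallest population's
    gene-copy count.
    """
    pops = popmap.populations()
    keep = np.ones(dataset.n_sites, dtype=bool)
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for pop in pops:
        idx = popmap.indices(dataset, pop)
        g = dataset.genotypes[idx]
        called = g != MISSING
        if len(idx):
            keep &= (~called).mean(axis=0) <= missing_rule
        total = 2 * called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        counts[pop] = (total.astype(float), alt.astype(float))

    min_copies = int(min(counts[p][0][keep].min() for p in pops)) if keep.any() else 0
    if g_max > min_copies:
        logger.warning(
            "g_max=%d exceeds the smallest gene-copy count %d; truncating",
            g_max,
            min_copies,
        )
        g_max = min_copies

    rows = []
    for pop in pops:
        total, alt = counts[pop]
        total, alt = total[keep], alt[keep]
        ref = total - alt
        other = [q for q in pops if q != pop]
        for g in range(1, g_max + 1):
            miss_alt = _prob_absent(alt, total, g)
            miss_ref = _prob_absent(ref, total, g)
            richness = (1 - miss_alt) + (1 - miss_ref)
            priv = np.zeros(len(total))
            for count_here, which in ((alt, "alt"), (ref, "ref")):
                p_in = 1 - _prob_absent(count_here, total, g)
                p_absent_elsewhere = np.ones(len(total))
                for q in other:
                    tq, aq = counts[q]
                    cq = (aq if which == "alt" else tq - aq)[keep]
                    p_absent_elsewhere *= _prob_absent(cq, tq[keep], g)
                priv += p_in * p_absent_elsewhere
            rows.append(
                {
                    "population": pop,
                    "g": g,
                    "richness": float(np.mean(richness)),
                    "private_richness": float(np.mean(priv)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diversity vs distance from the domestication centre
# ---------------------------------------------------------------------------

def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in kilometres."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


@dataclass
class DistanceTestResult:
    r_s: float
    p_value: float
    table: pd.DataFrame


def diversity_distance_test(
    summary: pd.DataFrame,
    popmap: PopulationMap,
    reference_pops: list[str],
    exclude: list[str] | None = None,
) -> DistanceTestResult:
    """Spearman correlation of cultivated H_E with distance from the
    centroid of the reference (domestication-centre) populations.

    Populations without coordinates are dropped with a warning; the
    reference populations themselves are included at their own distance.
    """
    exclude = set(exclude or [])
    cen_lat = float(np.mean([popmap.coordinates(p)[0] for p in reference_pops]))
    cen_lon = float(np.mean([popmap.coordinates(p)[1] for p in reference_pops]))
    rows = []
    for _, row in summary.iterrows():
        pop = row["population"]
        if row.get("class") != "cultivated" or pop in exclude:
            continue
        try:
            lat, lon = popmap.coordinates(pop)
        except KeyError:
            logger.warning("population %s has no coordinates; dropped", pop)
            continue
        rows.append(
            {
                "population": pop,
                "H_E": row["H_E"],
                "distance_km": haversine_km(cen_lat, cen_lon, lat, lon),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 4:
        raise ValueError("need at least 4 cultivated populations with coordinates")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # constant input handled below
        r_s, p = spearmanr(table["H_E"], table["distance_km"])
    if np.isnan(r_s):  # constant input -> no monotone association
        r_s, p = 0.0, 1.0
    return DistanceTestResult(float(r_s), float(p), table)
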