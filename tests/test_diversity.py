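"""Diversity statistics against independent textbook implementations."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

from beanpop.datatypes import MISSING
from beanpop.diversity import (
    diversity_distance_test,
    haversine_km,
    heterozygosity,
    pairwise_fst,
    private_alleles,
    rarefied_richness,
    wc_fst_components,
)
from beanpop.datatypes import PopulationMap

from conftest import make_annotation, make_dataset, two_pop_map


# ---------------------------------------------------------------------------
# heterozygosity / F_IS
# ---------------------------------------------------------------------------

def test_full_heterozygosity_gives_negative_fis():
    g = np.ones((5, 4), dtype=np.int8)  # every genotype heterozygous
    ds = make_dataset(g)
    pm = PopulationMap(
        population={s: "p" for s in ds.sample_ids},
        sample_class={s: "wild" for s in ds.sample_ids},
    )
    out = heterozygosity(ds, pm, n_bootstrap=50, seed=0)
    assert out.loc[0, "H_O"] == 1.0
    assert out.loc[0, "F_IS"] < 0


def test_monomorphic_population_reports_missing_fis():
    ds = make_dataset(np.zeros((4, 3), dtype=np.int8))
    pm = PopulationMap(
        population={s: "p" for s in ds.sample_ids},
        sample_class={s: "wild" for s in ds.sample_ids},
    )
    out = heterozygosity(ds, pm, n_bootstrap=10, seed=0)
    assert np.isnan(out.loc[0, "F_IS"])


def test_fis_ci_contains_point_estimate(sim_cohort):
    ds, _, pm, _ = sim_cohort
    out = heterozygosity(ds, pm, n_bootstrap=200, seed=1)
    for _, row in out.iterrows():
        assert row["F_IS_ci_low"] <= row["F_IS"] <= row["F_IS_ci_high"]
        assert 0 <= row["H_O"] <= 1 and 0 <= row["H_E"] <= 1


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST: independent per-site implementation (1984 formulas)
# ---------------------------------------------------------------------------

def wc_oracle_site(g1, g2):
    """Literal two-population Weir-Cockerham components for one site."""
    def pop_stats(g):
        g = [x for x in g if x != MISSING]
        n = len(g)
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        return n, p, h

    n1, p1, h1 = pop_stats(g1)
    n2, p2, h2 = pop_stats(g2)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def test_wc_fst_matches_independent_implementation():
    rng = np.random.default_rng(3)
    g = rng.choice([0, 1, 2, MISSING], size=(10, 10), p=[0.35, 0.3, 0.3, 0.05]).astype(np.int8)
    # ensure >= 2 called per population per site
    g[0:2] = np.abs(g[0:2])
    g[5:7] = np.abs(g[5:7])
    ds = make_dataset(g)
    a, b, c = wc_fst_components(ds, list(range(5)), list(range(5, 10)))
    for j in range(10):
        ga, gb = g[:5, j], g[5:, j]
        ea, eb, ec = wc_oracle_site(ga, gb)
        called = [x for x in np.concatenate([ga, gb]) if x != MISSING]
        pbar = sum(called) / (2 * len(called))
        if 0 < pbar < 1:
            assert a[j] == pytest.approx(ea, abs=1e-12)
            assert b[j] == pytest.approx(eb, abs=1e-12)
            assert c[j] == pytest.approx(ec, abs=1e-12)
        else:
            assert np.isnan(a[j])


def test_fst_zero_for_identical_and_one_for_fixed():
    g_same = np.array([[0, 1, 2, 1]] * 8, dtype=np.int8)
    ds = make_dataset(g_same)
    pm = two_pop_map(4, 4)
    out = pairwise_fst(ds, pm)
    assert out.loc[0, "theta"] == pytest.approx(0.0, abs=1e-12)

    g_fixed = np.vstack([np.zeros((4, 5)), np.full((4, 5), 2)]).astype(np.int8)
    ds = make_dataset(g_fixed)
    out = pairwise_fst(ds, pm)
    assert out.loc[0, "theta"] == pytest.approx(1.0)


def test_fst_invariant_to_allele_label_swap(sim_cohort):
    ds, _, pm, _ = sim_cohort
    sub = ds.take_sites(np.arange(300))
    theta1 = pairwise_fst(sub, pm).loc[0, "theta"]
    swapped = sub.take_sites(np.arange(300))
    g = swapped.genotypes
    swapped.genotypes = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
    swapped.phased_haplotypes = None if sub.phased_haplotypes is None else 1 - sub.phased_haplotypes
    theta2 = pairwise_fst(swapped, pm).loc[0, "theta"]
    assert theta1 == pytest.approx(theta2, abs=1e-12)


# ---------------------------------------------------------------------------
# private alleles
# ---------------------------------------------------------------------------

def test_private_allele_classes_on_three_population_toy():
    # popA wild, popB wild, popC cultivated; 4 sites
    g = np.array(
        [
            # site0: alt only in A (segregating); site1: alt in A+B; site2: everywhere; site3: only C
            [1, 1, 2, 0],
            [1, 0, 1, 0],  # popA
            [0, 1, 1, 0],
            [0, 1, 2, 0],  # popB
            [0, 0, 1, 1],
            [0, 0, 1, 1],  # popC
        ],
        dtype=np.int8,
    )
    ds = make_dataset(g)
    pm = PopulationMap(
        population={"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "C", "s5": "C"},
        sample_class={
            "s0": "wild", "s1": "wild", "s2": "wild", "s3": "wild",
            "s4": "cultivated", "s5": "cultivated",
        },
    )
    out = private_alleles(ds, pm).set_index("population")
    assert out.loc["A", "private_to_population"] == 1  # site0
    assert out.loc["A", "private_to_class"] == 1  # site1 shared with wild B only
    assert out.loc["C", "private_to_population"] == 1  # site3
    assert out.loc["A", "shared"] == 1  # site2
    # exhaustive hand classification: site2 segregates everywhere
    assert out.loc["B", "shared"] == 1


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def rarefaction_oracle(allele_counts, g):
    """Expected distinct alleles by exhaustive subsample enumeration."""
    pool = []
    for allele, count in enumerate(allele_counts):
        pool += [allele] * count
    subs = list(itertools.combinations(range(len(pool)), g))
    total = 0
    for s in subs:
        total += len({pool[i] for i in s})
    return total / len(subs)


def test_rarefied_richness_examples_and_oracle():
    # one population; loci with known allele counts
    g = np.array([[2, 0], [1, 0], [0, 0], [0, 0]], dtype=np.int8)
    # locus0: alt copies = 3 of 8 -> counts (5 ref, 3 alt); locus1 monomorphic
    ds = make_dataset(g)
    pm = PopulationMap(
        population={s: "p" for s in ds.sample_ids},
        sample_class={s: "wild" for s in ds.sample_ids},
    )
    out = rarefied_richness(ds, pm, g_max=8)
    byg = out.set_index("g")
    for gg in (2, 4, 8):
        expected = (rarefaction_oracle([5, 3], gg) + rarefaction_oracle([8, 0], gg)) / 2
        assert byg.loc[gg, "richness"] == pytest.approx(expected, abs=1e-10)
    # complete sample recovers the observed allele count
    assert byg.loc[8, "richness"] == pytest.approx((2 + 1) / 2)
    # monotone non-decreasing
    assert (np.diff(out["richness"]) >= -1e-12).all()


def test_rarefaction_documented_example():
    # allele counts (3, 1), N = 4, g = 2 -> 1 + (1 - C(3,2)/C(4,2)) = 1.5
    g = np.array([[1], [0]], dtype=np.int8)
    ds = make_dataset(g)
    pm = PopulationMap(
        population={"s0": "p", "s1": "p"}, sample_class={"s0": "wild", "s1": "wild"}
    )
    out = rarefied_richness(ds, pm, g_max=2).set_index("g")
    assert out.loc[2, "richness"] == pytest.approx(1.5)
    assert rarefaction_oracle([3, 1], 2) == pytest.approx(1.5)


def test_rarefaction_truncates_with_warning_and_applies_missing_rule(caplog):
    g = np.array([[0, 1], [1, MISSING], [1, MISSING], [0, MISSING]], dtype=np.int8)
    ds = make_dataset(g)
    pm = PopulationMap(
        population={s: "p" for s in ds.sample_ids},
        sample_class={s: "wild" for s in ds.sample_ids},
    )
    out = rarefied_richness(ds, pm, g_max=50)
    # site1 has 75% missing -> excluded by the 0.2 rule; curve truncated at 8
    assert out["g"].max() == 8
    assert out.set_index("g").loc[8, "richness"] == pytest.approx(2.0)


def test_private_richness_probability_logic(sim_cohort):
    ds, _, pm, _ = sim_cohort
    sub = ds.take_sites(np.arange(200))
    out = rarefied_richness(sub, pm, g_max=6)
    assert ((out["private_richness"] >= -1e-12) & (out["private_richness"] <= out["richness"] + 1e-12)).all()


# ---------------------------------------------------------------------------
# diversity vs distance
# ---------------------------------------------------------------------------

def _summary(pops, he):
    import pandas as pd

    return pd.DataFrame(
        {"population": pops, "class": ["cultivated"] * len(pops), "H_E": he}
    )


def _map_with_coords(pops, coords):
    population, cls, lat, lon = {}, {}, {}, {}
    for p, (la, lo) in zip(pops, coords):
        s = f"{p}_0"
        population[s] = p
        cls[s] = "cultivated"
        lat[s] = la
        lon[s] = lo
    return PopulationMap(population, cls, lat, lon)


def test_perfectly_decreasing_diversity_gives_minus_one():
    pops = ["c1", "c2", "c3", "c4", "c5"]
    coords = [(19.0, -99.0), (20.0, -99.0), (21.0, -99.0), (22.0, -99.0), (23.0, -99.0)]
    pm = _map_with_coords(pops, coords)
    res = diversity_distance_test(
        _summary(pops, [0.5, 0.4, 0.3, 0.2, 0.1]), pm, reference_pops=["c1"]
    )
    assert res.r_s == pytest.approx(-1.0)


def test_constant_diversity_gives_zero_correlation():
    pops = ["c1", "c2", "c3", "c4"]
    coords = [(19.0, -99.0), (20.0, -99.0), (21.0, -99.0), (22.0, -99.0)]
    pm = _map_with_coords(pops, coords)
    res = diversity_distance_test(
        _summary(pops, [0.3, 0.3, 0.3, 0.3]), pm, reference_pops=["c1"]
    )
    assert res.r_s == 0.0


def test_spearman_matches_rank_arithmetic():
    pops = ["c1", "c2", "c3", "c4", "c5"]
    coords = [(19.0, -99.0), (20.0, -99.0), (21.0, -99.0), (22.0, -99.0), (23.0, -99.0)]
    he = [0.30, 0.35, 0.20, 0.25, 0.10]  # distance ranks 1..5, H_E ranks 4,5,2,3,1
    pm = _map_with_coords(pops, coords)
    res = diversity_distance_test(_summary(pops, he), pm, reference_pops=["c1"])
    d = np.array([1, 2, 3, 4, 5]) - np.array([4, 5, 2, 3, 1])
    expected = 1 - 6 * (d**2).sum() / (5 * 24)
    assert res.r_s == pytest.approx(expected)


def test_haversine_equator_degree():
    # one degree of longitude at the equator ~ 111.19 km
    assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.1)
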