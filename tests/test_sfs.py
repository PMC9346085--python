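"""SFS construction, Watterson closed forms, ROH, and the fitting stack."""

import itertools

import numpy as np
import pytest

from beanpop.datatypes import MISSING, PopulationMap
from beanpop.demography import build_scenario
from beanpop.sfs import (
    SFS,
    FitConfig,
    composite_loglik,
    compute_sfs,
    detect_roh,
    expected_sfs_from_model,
    fit_model,
    loglik_upper_bound,
    model_selection,
    parametric_bootstrap,
    simulate_observed_sfs,
    watterson_expected,
)

from conftest import make_annotation, make_dataset


def one_pop_map(ds, cls="cultivated"):
    return PopulationMap(
        population={s: "p" for s in ds.sample_ids},
        sample_class={s: cls for s in ds.sample_ids},
    )


# ---------------------------------------------------------------------------
# observed SFS
# ---------------------------------------------------------------------------

def test_sfs_counts_derived_alleles():
    # derived counts 1, 1, 2 at n = 4 -> xi = [2, 1, 0]
    g = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
    ds = make_dataset(g)
    sfs = compute_sfs(ds, one_pop_map(ds), make_annotation(3), "p")
    assert sfs.n == 4
    np.testing.assert_array_equal(sfs.counts, [2, 1, 0])
    assert sfs.S == 3


def test_sfs_respects_polarization_flips():
    g = np.array([[0, 2], [0, 2]], dtype=np.int8)
    ann = make_annotation(2)
    ann.ancestral_allele[1] = "alt"  # derived = ref, count = 4 - 4 = 0
    ds = make_dataset(g)
    sfs = compute_sfs(ds, one_pop_map(ds), ann, "p")
    assert sfs.S == 0  # site0 monomorphic ref, site1 derived-fixed? no: flipped to 0


def test_folded_sfs_identity():
    g = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
    ds = make_dataset(g)
    folded = compute_sfs(ds, one_pop_map(ds), make_annotation(3), "p",
                         polarization="folded")
    # unfolded [2, 1, 0] at n=4 -> eta = [2 + 0, 1]
    np.testing.assert_array_equal(folded.counts, [2, 1])
    assert folded.folded


def test_category_restriction():
    g = np.array([[1, 1], [0, 0]], dtype=np.int8)
    ann = make_annotation(2)
    ann.category[0] = "CDS"
    ann.effect[0] = "synonymous"
    ds = make_dataset(g)
    sfs = compute_sfs(ds, one_pop_map(ds), ann, "p", category="nongenic")
    assert sfs.S == 1


def test_projection_equals_exhaustive_subsample_average():
    """Hypergeometric projection must equal averaging over all C(m, n)
    subsamples of gene copies at a site."""
    # one site, 4 diploids (m = 8 copies), derived count 5, project to n = 4
    g = np.array([[2], [2], [1], [0]], dtype=np.int8)
    ds = make_dataset(g)
    sfs = compute_sfs(ds, one_pop_map(ds), make_annotation(1), "p", projection=4)
    copies = [1, 1, 1, 1, 1, 0, 0, 0]  # 5 derived among 8
    hist = np.zeros(5)
    for sub in itertools.combinations(range(8), 4):
        hist[sum(copies[i] for i in sub)] += 1
    hist /= hist.sum()
    np.testing.assert_allclose(sfs.counts, hist[1:4], atol=1e-12)


def test_projection_larger_than_sample_errors():
    ds = make_dataset(np.array([[1]], dtype=np.int8))
    with pytest.raises(ValueError, match="projection"):
        compute_sfs(ds, one_pop_map(ds), make_annotation(1), "p", projection=4)


# ---------------------------------------------------------------------------
# Watterson closed forms
# ---------------------------------------------------------------------------

def test_watterson_base_case_and_hand_arithmetic():
    theta, expected = watterson_expected(SFS("p", "all", 2, np.array([7.0])))
    assert theta == 7.0  # a_2 = 1
    theta, expected = watterson_expected(SFS("p", "all", 4, np.array([5.0, 4.0, 2.0])))
    assert theta == pytest.approx(11 / (11 / 6))  # a_4 = 1 + 1/2 + 1/3
    np.testing.assert_allclose(expected, [6.0, 3.0, 2.0])
    assert expected.sum() == pytest.approx(11.0)  # sums back to S


def test_watterson_requires_variation():
    with pytest.raises(ValueError):
        watterson_expected(SFS("p", "all", 4, np.zeros(3)))


def test_neutral_simulated_sfs_passes_goodness_of_fit():
    """A constant-size coalescent SFS must be consistent with theta_W / i."""
    from scipy.stats import chisquare

    model = build_scenario(
        "bottleneck_only", dict(NANC=10_000, TBOT=2_000, NBOT=10_000, TEXP=200,
                                NCUR=10_000)
    )
    obs = simulate_observed_sfs(model, {"cult": 6}, 3_000, seed=11, joint=False,
                                n_sims=3_000)
    _, expected = watterson_expected(SFS("p", "all", 12, obs))
    stat, p = chisquare(obs, expected * obs.sum() / expected.sum())
    assert p > 0.01


# ---------------------------------------------------------------------------
# runs of homozygosity
# ---------------------------------------------------------------------------

def test_fully_heterozygous_sample_has_no_roh():
    g = np.ones((1, 100), dtype=np.int8)
    ds = make_dataset(g, pos=np.arange(1, 101) * 10_000)
    table, total = detect_roh(ds, "s0")
    assert len(table) == 0 and total == 0


def test_constructed_homozygous_run_detected_exactly_once():
    # 60 homozygous SNVs spanning 590 kb flanked by heterozygotes
    g = np.concatenate([[1], np.zeros(60), [1]]).astype(np.int8)[None, :]
    pos = np.concatenate([[5_000], 10_000 + np.arange(60) * 10_000, [700_000]])
    ds = make_dataset(g, pos=pos)
    table, total = detect_roh(ds, "s0", min_length_bp=500_000, max_het=0,
                              min_snvs=25)
    assert len(table) == 1
    seg = table.iloc[0]
    assert seg["start"] == 10_000 and seg["end"] == 600_000
    assert total == 590_001


def test_roh_allows_configured_heterozygotes():
    g = np.concatenate([np.zeros(30), [1], np.zeros(30)]).astype(np.int8)[None, :]
    pos = np.arange(1, 62) * 10_000
    ds = make_dataset(g, pos=pos)
    _, total_strict = detect_roh(ds, "s0", min_length_bp=500_000, max_het=0,
                                 min_snvs=25)
    _, total_lenient = detect_roh(ds, "s0", min_length_bp=500_000, max_het=1,
                                  min_snvs=25)
    assert total_strict == 0  # each half spans < 500 kb
    assert total_lenient == 600_001  # the het is absorbed into one long run


def test_bottleneck_increases_total_roh():
    """Stochastic contrast: severe recent bottleneck vs constant size."""
    from scipy.stats import mannwhitneyu

    from beanpop.simulate import simulate_genotypes

    chroms = {"Chr01": 5_000_000}
    bott = build_scenario(
        "bottleneck_only", dict(NANC=20_000, TBOT=800, NBOT=120, TEXP=100, NCUR=120)
    )
    const = build_scenario(
        "bottleneck_only", dict(NANC=20_000, TBOT=800, NBOT=20_000, TEXP=100,
                                NCUR=20_000)
    )
    totals = {}
    for name, model in (("bott", bott), ("const", const)):
        ds, _, _ = simulate_genotypes(model, {"cult": 8}, chrom_lengths=chroms,
                                      seed=31)
        totals[name] = [
            detect_roh(ds, s, min_length_bp=250_000, max_het=1, min_snvs=10)[1]
            for s in ds.sample_ids
        ]
    res = mannwhitneyu(totals["bott"], totals["const"], alternative="greater")
    assert res.pvalue < 0.05


# ---------------------------------------------------------------------------
# fitting machinery
# ---------------------------------------------------------------------------

def test_aic_weights_closed_form_and_normalization():
    from beanpop.sfs import ModelFit

    def fit(name, lnl, k):
        return ModelFit(name, {}, [], lnl, 2 * k - 2 * lnl, k)

    tab = model_selection([fit("a", -100.0, 1), fit("b", -101.0, 1)])
    # delta AIC = {0, 2} -> weights {0.731, 0.269}
    assert tab.loc[0, "weight"] == pytest.approx(0.731, abs=5e-4)
    assert tab.loc[1, "weight"] == pytest.approx(0.269, abs=5e-4)
    assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-12)
    tie = model_selection([fit("a", -100.0, 1), fit("b", -100.0, 1)])
    assert np.allclose(tie["weight"], 0.5)


def test_composite_loglik_bounded_by_empirical_maximum():
    rng = np.random.default_rng(9)
    obs = rng.integers(0, 50, size=20).astype(float)
    ub = loglik_upper_bound(obs)
    for _ in range(5):
        p = rng.random(20)
        assert composite_loglik(obs, p / p.sum()) <= ub + 1e-9


def test_fit_recovers_parameter_from_noiseless_expected_input():
    truth = dict(NWILD=20_000, NAC=2_500, NCC=50_000, TDOM=9_700, TEXP=1_500,
                 MIGWC=1e-4)
    model = build_scenario("tmvb_constant", truth)
    n_pp = {"cult": 10, "wild": 6}
    probs = expected_sfs_from_model(model, n_pp, n_sims=1_500, seed=5, joint=True)
    obs = probs * 20_000  # noiseless composite input
    fit = fit_model(
        obs, "tmvb_constant", {"NAC": (250, 25_000)},
        {k: v for k, v in truth.items() if k != "NAC"},
        n_pp, FitConfig(n_sims=800, seed=5, joint=True),
    )
    assert 0.6 * truth["NAC"] <= fit.parameters["NAC"] <= 1.6 * truth["NAC"]
    assert fit.aic == pytest.approx(2 * 1 - 2 * fit.loglik)


def test_bootstrap_single_replicate_warns_and_collapses():
    from beanpop.sfs import ModelFit

    best = ModelFit(
        "bottleneck_only",
        dict(NANC=10_000, TBOT=2_000, NBOT=1_000, TEXP=200, NCUR=10_000),
        ["NBOT"], -10.0, 22.0, 1,
    )
    with pytest.warns(UserWarning, match="n_boot"):
        out = parametric_bootstrap(
            best, {"NBOT": (100, 10_000)}, {"cult": 6}, 500, n_boot=1, seed=3,
            config=FitConfig(n_sims=200, seed=3, joint=False),
        )
    assert out.loc[0, "ci_low"] == pytest.approx(out.loc[0, "ci_high"])
    assert out.loc[0, "n_ok"] == 1


def test_expected_sfs_monte_carlo_consistency():
    model = build_scenario(
        "bottleneck_only", dict(NANC=10_000, TBOT=2_000, NBOT=10_000, TEXP=200,
                                NCUR=10_000)
    )
    ref = expected_sfs_from_model(model, {"cult": 5}, n_sims=6_000, seed=1,
                                  joint=False)
    coarse = expected_sfs_from_model(model, {"cult": 5}, n_sims=300, seed=2,
                                     joint=False)
    fine = expected_sfs_from_model(model, {"cult": 5}, n_sims=2_400, seed=3,
                                   joint=False)
    assert np.abs(fine - ref).max() < np.abs(coarse - ref).max()


def test_expansion_inflates_singleton_share():
    const = build_scenario(
        "bottleneck_only", dict(NANC=5_000, TBOT=2_000, NBOT=5_000, TEXP=200,
                                NCUR=5_000)
    )
    expand = build_scenario(
        "bottleneck_only", dict(NANC=5_000, TBOT=2_000, NBOT=5_000, TEXP=400,
                                NCUR=500_000)
    )
    p_const = expected_sfs_from_model(const, {"cult": 8}, n_sims=2_000, seed=4,
                                      joint=False)
    p_exp = expected_sfs_from_model(expand, {"cult": 8}, n_sims=2_000, seed=4,
                                    joint=False)
    assert p_exp[0] > p_const[0]
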