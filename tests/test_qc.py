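"""QC operations against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from beanpop.datatypes import MISSING
from beanpop.qc import (
    FilterConfig,
    classify_effect_counts,
    hdplot,
    hwe_exact_test,
    king_kinship,
    run_filter_chain,
)

from conftest import make_annotation, make_dataset, two_pop_map


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test: full-enumeration oracle
# ---------------------------------------------------------------------------

def hwe_oracle(n_AA, n_Aa, n_aa):
    """Independent enumeration using exact binomial coefficients."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if rare == 0:
        return 1.0
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        # multinomial count of genotype configurations x 2^h over C(2n, rare)
        probs[h] = (
            comb(n, h, exact=True)
            * comb(n - h, hom_rare, exact=True)
            * 2**h
            / comb(2 * n, rare, exact=True)
        )
    # normalize the Levene-Haldane distribution
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts",
    [(5, 0, 5), (1, 2, 1), (3, 4, 3), (10, 1, 0), (2, 8, 2), (0, 5, 0), (7, 2, 6)],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-10)


def test_hwe_edge_cases():
    assert hwe_exact_test(10, 0, 0) == 1.0  # monomorphic
    assert hwe_exact_test(1, 2, 1) == 1.0  # modal configuration
    assert hwe_exact_test(5, 0, 5) < 0.01  # extreme heterozygote deficit
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.integers(min_value=0, max_value=25),
    st.integers(min_value=0, max_value=25),
    st.integers(min_value=0, max_value=25),
)
def test_hwe_is_a_probability_and_matches_oracle(a, h, b):
    if a + h + b == 0:
        return
    p = hwe_exact_test(a, h, b)
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(hwe_oracle(a, h, b), abs=1e-10)


# ---------------------------------------------------------------------------
# HDplot
# ---------------------------------------------------------------------------

def test_hdplot_symmetric_reads_give_zero_deviation():
    g = np.array([[1, 1], [1, 1], [1, 1], [1, 1]], dtype=np.int8)
    depth = np.full_like(g, 10, dtype=np.int32)
    ds = make_dataset(g, depth=depth, ad_ref=depth // 2, ad_alt=depth // 2)
    out = hdplot(ds)
    assert np.allclose(out["D"], 0.0)
    assert np.allclose(out["H"], 1.0)
    assert out["paralog_flag"].all()  # H = 1 > 0.6


def test_hdplot_monomorphic_site_unflagged():
    g = np.zeros((4, 1), dtype=np.int8)
    depth = np.full_like(g, 10, dtype=np.int32)
    ds = make_dataset(g, depth=depth, ad_ref=depth, ad_alt=np.zeros_like(depth))
    out = hdplot(ds)
    assert out["H"][0] == 0.0
    assert np.isnan(out["D"][0])
    assert not out["paralog_flag"][0]


def test_hdplot_requires_allelic_depths():
    with pytest.raises(ValueError, match="allelic depth"):
        hdplot(make_dataset([[0, 1]]))


# ---------------------------------------------------------------------------
# KING kinship
# ---------------------------------------------------------------------------

def king_oracle(gi, gj):
    both_het = opp = hi = hj = 0
    n_ok = 0
    for a, b in zip(gi, gj):
        if a == MISSING or b == MISSING:
            continue
        n_ok += 1
        both_het += a == 1 and b == 1
        opp += (a == 0 and b == 2) or (a == 2 and b == 0)
        hi += a == 1
        hj += b == 1
    if n_ok < 50 or hi + hj == 0:
        return float("nan")
    return (both_het - 2 * opp) / (hi + hj)


def test_king_identity_and_opposite_homozygotes():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=200).astype(np.int8)
    assert king_kinship(g, g) == pytest.approx(0.5)
    # fixed differences everywhere except a couple of hets
    gi = np.zeros(100, dtype=np.int8)
    gj = np.full(100, 2, dtype=np.int8)
    gi[:2] = 1
    assert king_kinship(gi, gj) < 0


def test_king_matches_brute_force_with_missing_data():
    rng = np.random.default_rng(1)
    for _ in range(10):
        gi = rng.choice([0, 1, 2, MISSING], size=150, p=[0.3, 0.3, 0.3, 0.1])
        gj = rng.choice([0, 1, 2, MISSING], size=150, p=[0.3, 0.3, 0.3, 0.1])
        expected = king_oracle(gi, gj)
        got = king_kinship(gi, gj)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


def test_king_undefined_below_minimum_shared_sites():
    gi = np.array([1] * 30, dtype=np.int8)
    assert np.isnan(king_kinship(gi, gi, min_sites=50))


# ---------------------------------------------------------------------------
# filter chain on a hand-built fixture
# ---------------------------------------------------------------------------

def chain_fixture():
    """10 sites: 2 fail depth, 1 fails site missingness, 1 HDplot-flagged,
    the rest clean; 6 wild + 6 cultivated samples."""
    rng = np.random.default_rng(42)
    n, m = 12, 10
    g = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    g[:, 5] = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1])  # keeps site 5 polymorphic
    depth = np.full((n, m), 20, dtype=np.int32)
    depth[:, 0] = 2  # fails mean depth
    depth[:, 1] = 3
    g[0:7, 2] = MISSING  # fails site missingness (7/12 > 0.05)
    g[:, 3] = 1  # every genotype heterozygous -> HDplot H = 1
    ad_ref = np.where(g == 1, depth // 2, np.where(g == 0, depth, 0))
    ds = make_dataset(g, depth=depth, ad_ref=ad_ref, ad_alt=depth - ad_ref)
    ann = make_annotation(m)
    pm = two_pop_map(6, 6)
    return ds, ann, pm


def test_filter_chain_telescopes_on_known_failures():
    ds, ann, pm = chain_fixture()
    cfg = FilterConfig(hwe_alpha=1e-9)  # isolate the deterministic filters
    out, _, report = run_filter_chain(ds, ann, pm, cfg, stage=1)
    frame = report.to_frame().set_index("filter")
    assert frame.loc["min_mean_depth", "removed"] == 2
    assert frame.loc["site_missingness", "removed"] == 1
    assert frame.loc["hdplot_paralogs", "removed"] == 1
    assert report.telescopes()
    assert out.n_sites == 6


def test_filter_chain_errors_when_everything_removed():
    ds, ann, pm = chain_fixture()
    cfg = FilterConfig(min_mean_depth=1_000)
    with pytest.raises(ValueError, match="min_mean_depth"):
        run_filter_chain(ds, ann, pm, cfg, stage=1)


def test_stage2_threshold_ordering_enforced():
    with pytest.raises(ValueError, match="stage"):
        FilterConfig(max_sample_missing_stage1=0.1, max_sample_missing_stage2=0.3)


# ---------------------------------------------------------------------------
# effect classification
# ---------------------------------------------------------------------------

def test_effect_counts_on_toy_annotation():
    ann = make_annotation(5)
    ann.category[:] = ["CDS", "CDS", "CDS", "CDS", "nongenic"]
    ann.effect[:] = ["synonymous", "synonymous", "nonsynonymous", "nonsynonymous", "none"]
    table = classify_effect_counts(ann).set_index("name")
    assert table.loc["CDS", "proportion"] == pytest.approx(0.8)
    assert table.loc["synonymous", "count"] == 2
    assert table.loc["synonymous", "proportion"] == pytest.approx(0.5)


def test_effect_counts_degenerate_without_cds():
    ann = make_annotation(3)  # all nongenic
    table = classify_effect_counts(ann).set_index("name")
    assert np.isnan(table.loc["synonymous", "proportion"])
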