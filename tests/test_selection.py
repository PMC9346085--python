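"""EHH/iHS behaviour, window flagging, and interval-overlap oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from beanpop.datatypes import PopulationMap
from beanpop.selection import (
    IhsConfig,
    adaptive_candidates,
    ehh,
    ihs_scan,
    standardize_by_frequency,
    sweep_windows,
)

from conftest import make_annotation, make_dataset


def ehh_oracle(hap, positions, core, allele, direction):
    """Pair-counting by literal enumeration of carrier haplotype pairs."""
    carriers = [i for i in range(hap.shape[0]) if hap[i, core] == allele]
    n = len(carriers)
    out = [(0.0, 1.0)]
    j = core + direction
    while 0 <= j < hap.shape[1]:
        lo, hi = (min(core, j), max(core, j))
        same = sum(
            1
            for a, b in itertools.combinations(carriers, 2)
            if np.array_equal(hap[a, lo : hi + 1], hap[b, lo : hi + 1])
        )
        e = same / (n * (n - 1) / 2)
        out.append((abs(positions[j] - positions[core]), e))
        if e < 0.05:
            break
        j += direction
    return out


def test_ehh_is_one_at_core_and_matches_hand_enumeration():
    hap = np.array(
        [
            [0, 1, 0, 1, 0],
            [0, 1, 0, 1, 1],
            [1, 1, 0, 0, 0],
            [1, 1, 1, 0, 0],
            [0, 0, 1, 1, 0],
            [1, 0, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    pos = np.array([100, 200, 300, 400, 500])
    for allele in (0, 1):
        for direction in (1, -1):
            d, v = ehh(hap, pos, 2, allele, direction)
            expected = ehh_oracle(hap, pos, 2, allele, direction)
            assert v[0] == 1.0
            np.testing.assert_allclose(d, [x for x, _ in expected])
            np.testing.assert_allclose(v, [y for _, y in expected])


def test_ehh_non_increasing_along_the_curve():
    rng = np.random.default_rng(2)
    hap = rng.integers(0, 2, size=(12, 40)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 100_000), size=40, replace=False))
    _, v = ehh(hap, pos, 20, 1, +1, truncation=0.0)
    assert (np.diff(v) <= 1e-12).all()


def test_ehh_needs_two_carriers():
    hap = np.array([[1, 0], [0, 0], [0, 1]], dtype=np.int8)
    with pytest.raises(ValueError, match="carried"):
        ehh(hap, np.array([100, 200]), 0, 1, 1)


def test_allele_label_swap_negates_unstandardized_score():
    """Swapping ancestral/derived labels exchanges iHH_A and iHH_D."""
    rng = np.random.default_rng(3)
    n_sites = 60
    hap = rng.integers(0, 2, size=(16, n_sites)).astype(np.int8)
    geno = hap[0::2] + hap[1::2]
    pos = np.arange(1, n_sites + 1) * 500
    ds = make_dataset(geno, pos=pos, phased_haplotypes=hap)
    pm = PopulationMap(
        population={s: "p" for s in ds.sample_ids},
        sample_class={s: "cultivated" for s in ds.sample_ids},
    )
    cfg = IhsConfig(include_edge_censored=True, min_bin_size=1, n_bins=1)
    ann_fwd = make_annotation(n_sites, ancestral="ref")
    ann_rev = make_annotation(n_sites, ancestral="alt")
    fwd = ihs_scan(ds, pm, ann_fwd, "p", cfg).set_index("pos")
    rev = ihs_scan(ds, pm, ann_rev, "p", cfg).set_index("pos")
    common = fwd.index.intersection(rev.index)
    assert len(common) > 10
    np.testing.assert_allclose(
        fwd.loc[common, "score"], -rev.loc[common, "score"], atol=1e-12
    )


def test_neutral_ihs_is_roughly_standard_normal(sim_cohort):
    ds, ann, pm, _ = sim_cohort
    sub = ds.take_sites(np.asarray(ds.chrom == "Chr01"))
    ann_sub = ann.take(np.asarray(ds.chrom == "Chr01"))
    res = ihs_scan(sub, pm, ann_sub, "wild")
    assert len(res) > 100
    assert abs(res["ihs"].mean()) < 0.1
    assert 0.85 < res["ihs"].std() < 1.15
    frac_extreme = (res["ihs"].abs() > 1.96).mean()
    assert 0.005 <= frac_extreme <= 0.15


def test_standardization_centers_each_frequency_bin():
    rng = np.random.default_rng(4)
    freqs = rng.random(500)
    scores = 2.0 * freqs + rng.normal(size=500)  # frequency-dependent mean
    z = standardize_by_frequency(scores, freqs, n_bins=10, min_bin_size=10)
    assert abs(z.mean()) < 0.05
    assert 0.9 < z.std() < 1.1


def test_hard_sweep_core_scores_extreme():
    """A high-frequency derived allele on one long shared haplotype must
    stand out from a scrambled background."""
    rng = np.random.default_rng(5)
    n_hap, n_sites = 20, 81
    hap = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    core = 40
    sweep = hap[:, core] == 1
    hap[:, core] = 0
    hap[:14, core] = 1  # derived frequency 0.7
    hap[:14, 25:56] = hap[0, 25:56]  # carriers share a 31-site haplotype
    geno = hap[0::2] + hap[1::2]
    pos = np.arange(1, n_sites + 1) * 400
    ds = make_dataset(geno, pos=pos, phased_haplotypes=hap)
    pm = PopulationMap(
        population={s: "p" for s in ds.sample_ids},
        sample_class={s: "cultivated" for s in ds.sample_ids},
    )
    cfg = IhsConfig(include_edge_censored=True, n_bins=1, min_bin_size=1)
    res = ihs_scan(ds, pm, make_annotation(n_sites), "p", cfg)
    row = res[res["pos"] == (core + 1) * 400]
    assert len(row) == 1
    background = res[res["pos"] != (core + 1) * 400]["score"].abs()
    assert row["score"].abs().iloc[0] > background.quantile(0.95)


# ---------------------------------------------------------------------------
# windows and overlap
# ---------------------------------------------------------------------------

def ihs_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ihs", "p_value"])


def test_sweep_windows_flag_by_threshold_and_overlap():
    res = ihs_table(
        [
            ("Chr01", 30_000, 2.0, 0.001),
            ("Chr01", 60_000, 0.5, 0.6),
            ("Chr02", 10_000, -1.7, 0.04),
        ]
    )
    w = sweep_windows(res, {"Chr01": 100_000, "Chr02": 50_000})
    qualifying = w[w["candidate"]]
    # 30 kb SNV is covered by the windows starting at 12.5 kb and 25 kb
    chr1 = qualifying[qualifying["chrom"] == "Chr01"]
    assert set(chr1["start"]) == {12_501, 25_001}
    # negative iHS qualifies through |iHS|; 10 kb only falls in window [1, 25k]
    assert (qualifying["chrom"] == "Chr02").sum() == 1


def test_sweep_windows_none_without_extreme_scores():
    res = ihs_table([("Chr01", 30_000, 1.2, 0.2), ("Chr01", 70_000, -0.3, 0.9)])
    w = sweep_windows(res, {"Chr01": 100_000})
    assert not w["candidate"].any()


def test_sweep_windows_match_brute_force_interval_check():
    rng = np.random.default_rng(6)
    rows = [
        ("Chr01", int(p), float(z), float(pv))
        for p, z, pv in zip(
            rng.choice(np.arange(1, 200_000), size=60, replace=False),
            rng.normal(scale=1.2, size=60),
            rng.random(60),
        )
    ]
    res = ihs_table(rows)
    w = sweep_windows(res, {"Chr01": 200_000})
    qual = [
        (p, z, pv) for _, p, z, pv in res.itertuples(index=False)
        if abs(z) >= 1.5 and pv < 0.05
    ]
    for _, row in w.iterrows():
        expected = any(row["start"] <= p <= row["end"] for p, _, _ in qual)
        assert row["candidate"] == expected


def test_adaptive_candidates_window_and_gene_level():
    sweeps = pd.DataFrame(
        {
            "chrom": ["Chr01", "Chr01"],
            "start": [1, 50_001],
            "end": [25_000, 75_000],
            "candidate": [True, True],
        }
    )
    introg = pd.DataFrame(
        {
            "chrom": ["Chr01", "Chr02"],
            "start": [20_000, 1],
            "end": [30_000, 10_000],
            "top": [True, True],
        }
    )
    window_level = adaptive_candidates(sweeps, introg)
    assert len(window_level) == 1
    assert window_level.loc[0, "sweep_end"] == 25_000

    genes = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3"],
            "chrom": ["Chr01", "Chr01", "Chr02"],
            "start": [19_000, 60_000, 5],
            "end": [21_000, 61_000, 50],
        }
    )
    gene_level = adaptive_candidates(sweeps, introg, genes)
    # g1 overlaps both a sweep and a top window; g2 only a sweep; g3 only f_d
    assert gene_level["gene_id"].tolist() == ["g1"]


def test_adaptive_candidates_disjoint_sets_empty():
    sweeps = pd.DataFrame(
        {"chrom": ["Chr01"], "start": [1], "end": [10], "candidate": [True]}
    )
    introg = pd.DataFrame(
        {"chrom": ["Chr01"], "start": [100], "end": [200], "top": [True]}
    )
    assert len(adaptive_candidates(sweeps, introg)) == 0


def test_gene_overlap_matches_exhaustive_pairwise_check():
    rng = np.random.default_rng(8)
    def windows(flag):
        starts = rng.choice(np.arange(1, 100_000, 500), size=6, replace=False)
        return pd.DataFrame(
            {
                "chrom": "Chr01",
                "start": starts,
                "end": starts + 4_000,
                flag: True,
            }
        )
    sweeps, introg = windows("candidate"), windows("top")
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "chrom": "Chr01",
            "start": rng.choice(np.arange(1, 100_000, 300), size=10, replace=False),
        }
    )
    genes["end"] = genes["start"] + 2_500
    got = set(adaptive_candidates(sweeps, introg, genes)["gene_id"])
    expected = set()
    for _, g in genes.iterrows():
        in_sweep = any(
            g.start <= s.end and s.start <= g.end for _, s in sweeps.iterrows()
        )
        in_top = any(
            g.start <= t.end and t.start <= g.end for _, t in introg.iterrows()
        )
        if in_sweep and in_top:
            expected.add(g.gene_id)
    assert got == expected
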