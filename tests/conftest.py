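"""Shared fixtures: small hand-built datasets plus one simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from beanpop.datatypes import GenotypeDataset, PopulationMap, SiteAnnotation
from beanpop.demography import build_scenario
from beanpop.simulate import make_population_map, simulate_genotypes


def make_dataset(
    genotypes,
    chrom=None,
    pos=None,
    sample_ids=None,
    **kwargs,
) -> GenotypeDataset:
    """Small hand-specified dataset; genotypes is (samples, sites)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samp, n_sites = g.shape
    return GenotypeDataset(
        sample_ids=sample_ids or [f"s{i}" for i in range(n_samp)],
        chrom=np.asarray(chrom if chrom is not None else ["Chr01"] * n_sites, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n_sites + 1) * 100),
        ref_allele=np.asarray(["A"] * n_sites, dtype=object),
        alt_allele=np.asarray(["T"] * n_sites, dtype=object),
        genotypes=g,
        **kwargs,
    )


def make_annotation(n_sites, category="nongenic", ancestral="ref") -> SiteAnnotation:
    cat = np.asarray([category] * n_sites, dtype=object)
    eff = np.asarray(
        ["synonymous" if category == "CDS" else "none"] * n_sites, dtype=object
    )
    return SiteAnnotation(
        category=cat,
        effect=eff,
        ancestral_allele=np.asarray([ancestral] * n_sites, dtype=object),
    )


def two_pop_map(n1, n2, ids=None, classes=("wild", "cultivated")) -> PopulationMap:
    ids = ids or [f"s{i}" for i in range(n1 + n2)]
    return PopulationMap(
        population={s: ("popA" if i < n1 else "popB") for i, s in enumerate(ids)},
        sample_class={s: (classes[0] if i < n1 else classes[1]) for i, s in enumerate(ids)},
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """A clean (artifact-free) two-population simulated panel with phased
    haplotypes, tract truth and annotation, reused across test modules."""
    model = build_scenario(
        "tmvb_constant",
        dict(NWILD=20_000, NAC=2_500, NCC=50_000, TDOM=9_700, TEXP=1_500, MIGWC=2e-4),
    )
    dataset, annotation, tracts = simulate_genotypes(
        model,
        {"wild": 10, "cult": 12},
        n_sites=4_000,
        chrom_lengths={f"Chr{i:02d}": 2_000_000 for i in range(1, 5)},
        seed=20_260_921,
    )
    popmap = make_population_map(dataset, model)
    return dataset, annotation, popmap, tracts
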