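"""Diversity, differentiation, private alleles and rarefaction on the
QC-filtered cohort, plus the diversity-vs-distance test on a synthetic
multi-population panel.

The distance test emulates the serial-founder expectation: cultivated
populations founded progressively farther from the domestication centre
are simulated with progressively stronger bottlenecks, and expected
heterozygosity is correlated with great-circle distance from the centre.

Usage: python analysis/03_diversity.py [--seed N] [--outdir results]
"""

import argparse
from pathlib import Path

import numpy as np

from beanpop.demography import build_scenario
from beanpop.datatypes import PopulationMap
from beanpop.diversity import (
    diversity_distance_test,
    heterozygosity,
    pairwise_fst,
    private_alleles,
    rarefied_richness,
)
from beanpop.simulate import simulate_genotypes
from beanpop.vcfio import read_population_map, read_vcf


def distance_panel(seed: int):
    """Five cultivated populations with bottleneck severity increasing
    with distance from the (synthetic) domestication centre."""
    rng = np.random.default_rng(seed)
    centre = (19.4, -99.7)
    offsets = [0.0, 2.0, 4.0, 7.0, 10.0]  # degrees of longitude
    nbots = [15_000, 8_000, 4_000, 2_000, 1_000]
    rows = []
    population, cls, lat, lon = {}, {}, {}, {}
    he = {}
    for k, (off, nbot) in enumerate(zip(offsets, nbots)):
        name = f"cult{k}"
        model = build_scenario(
            "bottleneck_only",
            dict(NANC=20_000, TBOT=2_000, NBOT=nbot, TEXP=200, NCUR=nbot),
        )
        ds, _, _ = simulate_genotypes(
            model, {"cult": 8}, chrom_lengths={"Chr01": 2_000_000},
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        ds.sample_ids = [f"{name}_{i}" for i in range(ds.n_samples)]
        pm_one = PopulationMap(
            population={s: name for s in ds.sample_ids},
            sample_class={s: "cultivated" for s in ds.sample_ids},
        )
        per_site = heterozygosity(ds, pm_one, n_bootstrap=50, seed=seed).loc[0, "H_E"]
        # genome-wide gene diversity: per-SNV H_E times SNV density, so the
        # measure is not ascertained on each population's own polymorphisms
        he[name] = per_site * ds.n_sites / 2_000_000
        for s in ds.sample_ids:
            population[s] = name
            cls[s] = "cultivated"
            lat[s] = centre[0]
            lon[s] = centre[1] + off
    import pandas as pd

    summary = pd.DataFrame(
        {
            "population": list(he),
            "class": ["cultivated"] * len(he),
            "H_E": list(he.values()),
        }
    )
    return summary, PopulationMap(population, cls, lat, lon)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--g-max", type=int, default=12)
    args = ap.parse_args()
    out = Path(args.outdir)

    dataset, annotation = read_vcf(out / "cohort.filtered.vcf")
    popmap = read_population_map(out / "popmap.tsv")

    summary = heterozygosity(dataset, popmap, seed=args.seed)
    summary.to_csv(out / "diversity_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    fst = pairwise_fst(dataset, popmap)
    fst.to_csv(out / "pairwise_fst.tsv", sep="\t", index=False)
    print("\npairwise Weir-Cockerham F_ST:")
    print(fst.to_string(index=False))

    pa = private_alleles(dataset, popmap, annotation)
    pa.to_csv(out / "private_alleles.tsv", sep="\t", index=False)
    rr = rarefied_richness(dataset, popmap, g_max=args.g_max)
    rr.to_csv(out / "rarefaction.tsv", sep="\t", index=False)
    print(
        f"\nprivate-allele proportions: "
        + ", ".join(f"{r.population}={r.prop_private:.2f}" for r in pa.itertuples())
    )

    summary_panel, pm_panel = distance_panel(args.seed)
    res = diversity_distance_test(summary_panel, pm_panel, reference_pops=["cult0"])
    res.table.to_csv(out / "diversity_vs_distance.tsv", sep="\t", index=False)
    print(
        f"\ndiversity vs distance from the domestication centre: "
        f"Spearman r_s = {res.r_s:.2f} (p = {res.p_value:.3f}); a negative "
        "correlation mirrors the serial-founder expectation"
    )


if __name__ == "__main__":
    main()
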