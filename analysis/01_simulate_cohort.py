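"""Generate the standard GBS-like study cohort.

Simulates a wild + cultivated panel under the constant-introgression
domestication scenario, overlays GBS artifacts (depth, missingness,
collapsed paralogs, related samples, scaffold-only loci), and writes the
VCF, population map and truth tables that the QC step consumes.

Usage: python analysis/01_simulate_cohort.py [--seed N] [--outdir results]
"""

import argparse
from pathlib import Path

from beanpop.experiments import make_qc_cohort
from beanpop.vcfio import write_bed, write_population_map, write_vcf


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    dataset, annotation, popmap, truth = make_qc_cohort(seed=args.seed)
    write_vcf(dataset, annotation, out / "cohort.vcf")
    write_population_map(popmap, out / "popmap.tsv")
    with open(out / "truth_paralogs.tsv", "w") as fh:
        fh.write("chrom\tpos\n")
        for c, p in truth.paralog_sites:
            fh.write(f"{c}\t{p}\n")
    with open(out / "truth_relatives.tsv", "w") as fh:
        fh.write("kind\tsample_a\tsample_b\n")
        for a, b in truth.related_pairs:
            fh.write(f"parent_offspring\t{a}\t{b}\n")
        for a, b in truth.duplicate_pairs:
            fh.write(f"duplicate\t{a}\t{b}\n")
    if truth.scaffold_sites:
        write_bed(
            [(c, p, p) for c, p in truth.scaffold_sites],
            out / "truth_scaffold_sites.bed",
        )

    n_missing = (dataset.genotypes == -1).mean()
    print(
        f"cohort: {dataset.n_samples} samples x {dataset.n_sites} SNVs on "
        f"{len(dataset.chromosomes)} chromosomes"
    )
    print(
        f"injected: {len(truth.paralog_sites)} collapsed paralogs, "
        f"{len(truth.related_pairs)} parent-offspring pairs, "
        f"{len(truth.duplicate_pairs)} duplicates; "
        f"missingness {n_missing:.3f}, mean depth {dataset.depth.mean():.1f}x"
    )
    print(f"wrote {out}/cohort.vcf, popmap.tsv and truth tables")


if __name__ == "__main__":
    main()
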