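"""Run the two-stage SNV/sample QC chain on the simulated cohort.

Reads the VCF and population map written by 01_simulate_cohort.py,
applies the hard filters, Hardy-Weinberg exclusion in wild populations,
HDplot paralog removal and kinship-based subsetting, and reports how the
filter chain telescopes and how well it recovered the injected truth.

Usage: python analysis/02_variant_qc.py [--outdir results]
"""

import argparse
from pathlib import Path

import pandas as pd

from beanpop.qc import FilterConfig, classify_effect_counts, hdplot, run_filter_chain
from beanpop.vcfio import read_population_map, read_vcf, write_vcf


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()
    out = Path(args.outdir)

    dataset, annotation = read_vcf(out / "cohort.vcf")
    popmap = read_population_map(out / "popmap.tsv")
    truth_par = pd.read_csv(out / "truth_paralogs.tsv", sep="\t")
    par = set(zip(truth_par["chrom"], truth_par["pos"]))

    hd = hdplot(dataset)
    flagged = {
        (c, int(p))
        for c, p, f in zip(dataset.chrom, dataset.pos, hd["paralog_flag"])
        if f
    }
    power = len(par & flagged) / len(par)
    fpr = len(flagged - par) / (dataset.n_sites - len(par))
    print(f"HDplot: {power:.1%} of injected paralogs flagged, {fpr:.2%} false positives")

    filtered, ann_f, report = run_filter_chain(
        dataset, annotation, popmap, FilterConfig(), stage=2
    )
    frame = report.to_frame()
    frame.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    print(frame.to_string(index=False))
    assert report.telescopes(), "filter report does not telescope"

    write_vcf(filtered, ann_f, out / "cohort.filtered.vcf")
    effects = classify_effect_counts(ann_f)
    effects.to_csv(out / "effect_counts.tsv", sep="\t", index=False)
    print(
        f"kept {filtered.n_samples} samples and {filtered.n_sites} SNVs; "
        "category/effect counts in effect_counts.tsv"
    )


if __name__ == "__main__":
    main()
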