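"""Readers and writers for the formats at the pipeline edge.

VCF 4.2 with ``GT``(:``DP``:``AD``) genotype fields and INFO keys ``AA``
(ancestral allele base), ``CAT`` (site category) and ``EFF`` (coding
effect); TSV population maps; BED (0-based half-open) window tracks.

Reading uses cyvcf2; writing emits plain uncompressed VCF text so that a
write/read round trip is bit-exact on genotypes, positions and INFO keys.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    MISSING,
    SAMPLE_CLASSES,
    GenotypeDataset,
    PopulationMap,
    SiteAnnotation,
)

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    pass


def read_vcf(path: str | Path) -> tuple[GenotypeDataset, SiteAnnotation]:
    """Read a VCF into a :class:`GenotypeDataset` plus annotation.

    Multi-allelic records are skipped (count logged); half-calls and
    non-diploid genotypes are rejected. Sites are returned sorted by
    (chromosome, position). INFO keys AA/CAT/EFF populate the annotation
    where present; otherwise category defaults to nongenic and ancestral
    state to unknown.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad input
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} contains zero samples")

    chrom, pos, ref, alt = [], [], [], []
    genos, depths, adr, ada = [], [], [], []
    cat, eff, anc, scaffold = [], [], [], []
    n_multi = 0
    has_dp = has_ad = False
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        gt = var.genotype.array()
        if gt.shape[1] < 3:
            raise VcfParseError(
                f"non-diploid record at {var.CHROM}:{var.POS}"
            )
        a0, a1 = gt[:, 0], gt[:, 1]
        half = ((a0 < 0) ^ (a1 < 0))
        if np.any(half):
            raise VcfParseError(
                f"half-called genotype at {var.CHROM}:{var.POS}"
            )
        dosage = np.where(a0 < 0, MISSING, a0 + a1).astype(np.int8)
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        genos.append(dosage)
        try:
            dp = var.format("DP")
        except Exception:
            dp = None
        if dp is not None:
            has_dp = True
            depths.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int32))
        else:
            depths.append(np.zeros(len(samples), dtype=np.int32))
        try:
            ad = var.format("AD")
        except Exception:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            has_ad = True
            adr.append(np.where(ad[:, 0] < 0, 0, ad[:, 0]).astype(np.int32))
            ada.append(np.where(ad[:, 1] < 0, 0, ad[:, 1]).astype(np.int32))
        else:
            adr.append(np.zeros(len(samples), dtype=np.int32))
            ada.append(np.zeros(len(samples), dtype=np.int32))
        cat.append(var.INFO.get("CAT", "nongenic"))
        eff.append(var.INFO.get("EFF", "none"))
        aa = var.INFO.get("AA")
        if aa is None:
            anc.append("unknown")
        elif aa == var.REF:
            anc.append("ref")
        elif aa == var.ALT[0]:
            anc.append("alt")
        else:
            anc.append("unknown")
        scaffold.append(bool(int(var.INFO.get("CHRMAP", 1))))
    if n_multi:
        logger.info("skipped %d multi-allelic/indel records", n_multi)
    if not pos:
        dataset = GenotypeDataset(
            sample_ids=samples,
            chrom=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            ref_allele=np.array([], dtype=object),
            alt_allele=np.array([], dtype=object),
            genotypes=np.zeros((len(samples), 0), dtype=np.int8),
        )
        ann = SiteAnnotation(
            category=np.array([], dtype=object),
            effect=np.array([], dtype=object),
            ancestral_allele=np.array([], dtype=object),
        )
        return dataset, ann

    order = np.lexsort((np.array(pos), np.array(chrom, dtype=object)))
    chrom_a = np.array(chrom, dtype=object)[order]
    dataset = GenotypeDataset(
        sample_ids=samples,
        chrom=chrom_a,
        pos=np.array(pos, dtype=np.int64)[order],
        ref_allele=np.array(ref, dtype=object)[order],
        alt_allele=np.array(alt, dtype=object)[order],
        genotypes=np.stack(genos, axis=1)[:, order],
        depth=np.stack(depths, axis=1)[:, order] if has_dp else None,
        ad_ref=np.stack(adr, axis=1)[:, order] if has_ad else None,
        ad_alt=np.stack(ada, axis=1)[:, order] if has_ad else None,
    )
    ann = SiteAnnotation(
        category=np.array(cat, dtype=object)[order],
        effect=np.array(eff, dtype=object)[order],
        ancestral_allele=np.array(anc, dtype=object)[order],
        on_chromosome=np.array(scaffold, dtype=bool)[order],
    )
    return dataset, ann


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
##INFO=<ID=CAT,Number=1,Type=String,Description="Site category: nongenic/intronic/CDS">
##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect">
##INFO=<ID=CHRMAP,Number=1,Type=Integer,Description="1 if mapped to a chromosome, 0 if scaffold-only">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read depths">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    dataset: GenotypeDataset,
    annotation: SiteAnnotation | None,
    path: str | Path,
) -> None:
    """Write dataset (+ annotation) as uncompressed VCF 4.2."""
    if dataset.n_sites == 0:
        warnings.warn("writing header-only VCF: dataset has zero sites")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in dataset.chromosomes:
            length = int(dataset.pos[dataset.chrom == c].max()) + 1 if dataset.n_sites else 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.sample_ids)
            + "\n"
        )
        fmt = "GT"
        if dataset.depth is not None:
            fmt += ":DP"
        if dataset.ad_ref is not None:
            fmt += ":AD"
        for j in range(dataset.n_sites):
            info = []
            if annotation is not None:
                aa = annotation.ancestral_allele[j]
                if aa == "ref":
                    info.append(f"AA={dataset.ref_allele[j]}")
                elif aa == "alt":
                    info.append(f"AA={dataset.alt_allele[j]}")
                info.append(f"CAT={annotation.category[j]}")
                if annotation.effect[j] != "none":
                    info.append(f"EFF={annotation.effect[j]}")
                info.append(f"CHRMAP={int(annotation.on_chromosome[j])}")
            fields = [
                str(dataset.chrom[j]),
                str(int(dataset.pos[j])),
                ".",
                str(dataset.ref_allele[j]),
                str(dataset.alt_allele[j]),
                ".",
                "PASS",
                ";".join(info) if info else ".",
                fmt,
            ]
            col = []
            for i in range(dataset.n_samples):
                parts = [_GT_STR[int(dataset.genotypes[i, j])]]
                if dataset.depth is not None:
                    parts.append(str(int(dataset.depth[i, j])))
                if dataset.ad_ref is not None:
                    parts.append(
                        f"{int(dataset.ad_ref[i, j])},{int(dataset.ad_alt[i, j])}"
                    )
                col.append(":".join(parts))
            fh.write("\t".join(fields + col) + "\n")


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a TSV with columns sample_id, population, class[, lat, lon]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"population map must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample ids in population map: {dups}")
    bad = sorted(set(df["class"]) - set(SAMPLE_CLASSES))
    if bad:
        raise ValueError(
            f"unknown sample classes {bad}; allowed: {list(SAMPLE_CLASSES)}"
        )
    lat, lon = {}, {}
    if "lat" in df.columns and "lon" in df.columns:
        for _, row in df.iterrows():
            if pd.notna(row["lat"]) and pd.notna(row["lon"]):
                lat[row["sample_id"]] = float(row["lat"])
                lon[row["sample_id"]] = float(row["lon"])
    return PopulationMap(
        population=dict(zip(df["sample_id"], df["population"])),
        sample_class=dict(zip(df["sample_id"], df["class"])),
        latitude=lat,
        longitude=lon,
    )


def write_population_map(popmap: PopulationMap, path: str | Path) -> None:
    rows = []
    for s in popmap.samples:
        rows.append(
            {
                "sample_id": s,
                "population": popmap.population[s],
                "class": popmap.sample_class[s],
                "lat": popmap.latitude.get(s, ""),
                "lon": popmap.longitude.get(s, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bed(
    windows: list[tuple[str, int, int]] | pd.DataFrame,
    path: str | Path,
    scores: list[float] | None = None,
) -> None:
    """Write windows as BED (0-based half-open). Input bounds are 1-based
    inclusive and converted on write."""
    with open(path, "w") as fh:
        if isinstance(windows, pd.DataFrame):
            it = windows[["chrom", "start", "end"]].itertuples(index=False)
        else:
            it = iter(windows)
        for k, (c, s, e) in enumerate(it):
            row = [str(c), str(int(s) - 1), str(int(e))]
            if scores is not None:
                row.append(f"{scores[k]:.6g}")
            fh.write("\t".join(row) + "\n")
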