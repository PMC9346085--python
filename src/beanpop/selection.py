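"""EHH / iHS selective-sweep scans and adaptive-introgression overlap.

EHH at distance x from a core SNV is the probability that two randomly
drawn carrier haplotypes of the core allele are identical over the
interval from the core out to x:

    EHH(x) = sum_h C(n_h, 2) / C(n_core, 2)

over the distinct extended haplotypes h among carriers. iHH is the
trapezoid integral of the EHH curve over physical distance (bp), both
directions from the core, truncated where EHH drops below 0.05; the
unstandardized score is ln(iHH_A / iHH_D) and iHS is its z-score within
derived-allele-frequency bins. Scans run on phased haplotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import GenotypeDataset, PopulationMap, SiteAnnotation

logger = logging.getLogger(__name__)

EHH_TRUNCATION = 0.05


def ehh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    core_allele: int,
    direction: int,
    truncation: float = EHH_TRUNCATION,
) -> tuple[np.ndarray, np.ndarray]:
    """EHH decay curve from a core SNV in one direction.

    Parameters
    ----------
    haplotypes:
        (n_haplotypes, n_sites) binary matrix for one chromosome.
    positions:
        per-site bp positions, strictly increasing.
    core_index, core_allele:
        the focal SNV and which allele (0/1) defines the carrier set.
    direction:
        +1 scans right (increasing position), -1 left.

    Returns (distances_bp, ehh_values) starting at distance 0 with
    EHH = 1, evaluated at successive SNVs until EHH < truncation or the
    chromosome end. Requires >= 2 carrier haplotypes.
    """
    carriers = haplotypes[:, core_index] == core_allele
    n = int(carriers.sum())
    if n < 2:
        raise ValueError("core allele carried by fewer than 2 haplotypes")
    denom = n * (n - 1) / 2.0
    hap = haplotypes[carriers]

    dists = [0.0]
    values = [1.0]
    group = np.zeros(n, dtype=np.int64)  # partition id per carrier
    j = core_index + direction
    while 0 <= j < haplotypes.shape[1]:
        group = group * 2 + hap[:, j]
        _, counts = np.unique(group, return_counts=True)
        e = float((counts * (counts - 1) / 2.0).sum() / denom)
        dists.append(abs(float(positions[j]) - float(positions[core_index])))
        values.append(e)
        if e < truncation:
            break
        # re-compress group labels to avoid overflow on long scans
        _, group = np.unique(group, return_inverse=True)
        j += direction
    return np.asarray(dists), np.asarray(values)


def _ihh_one_side(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    core_allele: int,
    direction: int,
    truncation: float,
) -> tuple[float, bool]:
    """Trapezoid-integrated EHH one side of the core; returns (area,
    edge_censored)."""
    dists, values = ehh(
        haplotypes, positions, core_index, core_allele, direction, truncation
    )
    censored = values[-1] >= truncation  # hit the chromosome end first
    area = float(np.trapezoid(values, dists))
    return area, censored


@dataclass
class IhsConfig:
    maf: float = 0.05
    truncation: float = EHH_TRUNCATION
    n_bins: int = 20
    min_bin_size: int = 10
    include_edge_censored: bool = False


def ihs_scan(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    annotation: SiteAnnotation,
    population: str,
    config: IhsConfig | None = None,
) -> pd.DataFrame:
    """Standardized iHS per SNV for one population.

    Requires phased haplotypes and known ancestral states. SNVs failing
    the within-population MAF filter, with an unknown ancestral state,
    with fewer than 2 carriers of either allele, or edge-censored before
    the EHH curve decays are excluded. Standardization is a z-score
    within derived-frequency bins (equal width, small bins merged with
    their neighbour); the two-sided p comes from the standard normal.
    """
    config = config or IhsConfig()
    if dataset.phased_haplotypes is None:
        raise ValueError("iHS scan requires phased haplotypes")
    idx = popmap.indices(dataset, population)
    hap_rows = [r for i in idx for r in (2 * i, 2 * i + 1)]

    rows = []
    for c in dataset.chromosomes:
        on = np.flatnonzero(dataset.chrom == c)
        hap = dataset.phased_haplotypes[np.ix_(hap_rows, on)]
        pos = dataset.pos[on]
        anc = annotation.ancestral_allele[on]
        derived_is_alt = anc == "ref"
        known = anc != "unknown"
        freq_alt = hap.mean(axis=0)
        freq_derived = np.where(derived_is_alt, freq_alt, 1.0 - freq_alt)
        maf_ok = np.minimum(freq_alt, 1 - freq_alt) >= config.maf
        for local_j in np.flatnonzero(known & maf_ok):
            der_allele = 1 if derived_is_alt[local_j] else 0
            anc_allele = 1 - der_allele
            try:
                areas = {}
                censored = False
                for allele in (anc_allele, der_allele):
                    left, cl = _ihh_one_side(
                        hap, pos, local_j, allele, -1, config.truncation
                    )
                    right, cr = _ihh_one_side(
                        hap, pos, local_j, allele, +1, config.truncation
                    )
                    areas[allele] = left + right
                    censored = censored or cl or cr
            except ValueError:
                continue  # < 2 carriers of one allele
            if censored and not config.include_edge_censored:
                continue
            ihh_a = areas[anc_allele]
            ihh_d = areas[der_allele]
            if ihh_a <= 0 or ihh_d <= 0:
                continue
            rows.append(
                {
                    "chrom": c,
                    "pos": int(pos[local_j]),
                    "derived_freq": float(freq_derived[local_j]),
                    "ihh_a": ihh_a,
                    "ihh_d": ihh_d,
                    "score": math.log(ihh_a / ihh_d),
                }
            )
    result = pd.DataFrame(
        rows, columns=["chrom", "pos", "derived_freq", "ihh_a", "ihh_d", "score"]
    )
    if result.empty:
        result["ihs"] = []
        result["p_value"] = []
        return result
    result["ihs"] = standardize_by_frequency(
        result["score"].to_numpy(),
        result["derived_freq"].to_numpy(),
        n_bins=config.n_bins,
        min_bin_size=config.min_bin_size,
    )
    result["p_value"] = 2.0 * norm.sf(np.abs(result["ihs"]))
    return result


def standardize_by_frequency(
    scores: np.ndarray,
    freqs: np.ndarray,
    n_bins: int = 20,
    min_bin_size: int = 10,
) -> np.ndarray:
    """Z-score within equal-width derived-frequency bins; bins below the
    minimum size are merged with their neighbour toward 0.5."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    merged = np.clip(np.digitize(freqs, edges) - 1, 0, n_bins - 1)
    # repeatedly fold the smallest undersized bin into its nearest
    # occupied neighbour until every occupied bin meets the minimum
    while True:
        occupied, sizes = np.unique(merged, return_counts=True)
        small = occupied[sizes < min_bin_size]
        if len(small) == 0 or len(occupied) == 1:
            break
        b = small[0]
        others = occupied[occupied != b]
        nearest = others[np.argmin(np.abs(others - b))]
        merged[merged == b] = nearest
    out = np.empty_like(scores, dtype=float)
    for b in np.unique(merged):
        mask = merged == b
        mu = scores[mask].mean()
        sd = scores[mask].std(ddof=1) if mask.sum() > 1 else 0.0
        out[mask] = (scores[mask] - mu) / sd if sd > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# windows and overlap
# ---------------------------------------------------------------------------

def sweep_windows(
    ihs_results: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 25_000,
    step_bp: int = 12_500,
    threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tile chromosomes with 25-kb windows (12.5-kb step); a window is a
    sweep candidate when it contains a SNV with |iHS| >= threshold and
    p < alpha. Windows are 1-based inclusive internally."""
    if ihs_results.empty:
        raise ValueError("no iHS results to window")
    qual = ihs_results[
        (ihs_results["ihs"].abs() >= threshold)
        & (ihs_results["p_value"] < alpha)
    ]
    rows = []
    for c, length in chrom_lengths.items():
        snvs = ihs_results[ihs_results["chrom"] == c]
        if snvs.empty:
            continue
        qpos = qual.loc[qual["chrom"] == c, "pos"].to_numpy()
        apos = snvs["pos"].to_numpy()
        start = 1
        while start <= length:
            end = min(start + window_bp - 1, length)
            in_w = (apos >= start) & (apos <= end)
            if in_w.any():
                hit = (qpos >= start) & (qpos <= end)
                sub = snvs.loc[in_w, "ihs"]
                rows.append(
                    {
                        "chrom": c,
                        "start": start,
                        "end": end,
                        "n_snvs": int(in_w.sum()),
                        "max_abs_ihs": float(sub.abs().max()),
                        "candidate": bool(hit.any()),
                    }
                )
            start += step_bp
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snvs", "max_abs_ihs", "candidate"]
    )


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """>= 1 bp intersection of 1-based inclusive intervals."""
    return a_start <= b_end and b_start <= a_end


def adaptive_candidates(
    sweeps: pd.DataFrame,
    introgressed: pd.DataFrame,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regions (or genes) that are both sweep candidates and top-f_d
    introgressed windows.

    ``sweeps`` needs columns chrom/start/end/candidate; ``introgressed``
    needs chrom/start/end/top; ``genes`` (optional) needs
    gene_id/chrom/start/end. Without genes the report is window-level:
    each candidate sweep window paired with every overlapping top window.
    """
    sw = sweeps[sweeps["candidate"]] if "candidate" in sweeps else sweeps
    top = introgressed[introgressed["top"]] if "top" in introgressed else introgressed
    rows = []
    if genes is None or len(genes) == 0:
        for _, s in sw.iterrows():
            for _, t in top.iterrows():
                if s["chrom"] == t["chrom"] and _overlaps(
                    s["start"], s["end"], t["start"], t["end"]
                ):
                    rows.append(
                        {
                            "chrom": s["chrom"],
                            "sweep_start": int(s["start"]),
                            "sweep_end": int(s["end"]),
                            "fd_start": int(t["start"]),
                            "fd_end": int(t["end"]),
                        }
                    )
        return pd.DataFrame(
            rows, columns=["chrom", "sweep_start", "sweep_end", "fd_start", "fd_end"]
        )
    for _, g in genes.iterrows():
        hits_sweep = any(
            g["chrom"] == s["chrom"]
            and _overlaps(g["start"], g["end"], s["start"], s["end"])
            for _, s in sw.iterrows()
        )
        hits_top = any(
            g["chrom"] == t["chrom"]
            and _overlaps(g["start"], g["end"], t["start"], t["end"])
            for _, t in top.iterrows()
        )
        if hits_sweep and hits_top:
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "chrom": g["chrom"],
                    "start": int(g["start"]),
                    "end": int(g["end"]),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
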