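"""ABBA-BABA gene-flow tests and windowed f_d introgression scans.

Patterson's D is computed from population derived-allele frequencies,

    ABBA = sum (1-p1) p2 p3 (1-p4),   BABA = sum p1 (1-p2) p3 (1-p4),
    D = (ABBA - BABA) / (ABBA + BABA)

for a four-taxon tree (((H1, H2), H3), H4=outgroup). Significance uses a
weighted delete-one block jackknife over contiguous genomic blocks and a
Bonferroni correction across the tested trios. Windowed f_d follows the
dynamic-donor normalization: the ABBA-BABA numerator divided by its value
with, per site, whichever of P2/P3 has the higher derived frequency
standing in for both; windows with a non-positive numerator are clamped
to f_d = 0.

Polarization: the recorded ancestral state where available, otherwise the
outgroup major allele; sites with outgroup derived frequency in
(0.2, 0.8) are dropped as unpolarizable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import GenotypeDataset, PopulationMap, SiteAnnotation, derived_frequency

logger = logging.getLogger(__name__)


@dataclass
class TrioTest:
    """ABBA-BABA result for one four-taxon configuration."""

    h1: str
    h2: str
    h3: str
    h4: str
    d: float
    se: float
    z: float
    p_value: float
    abba: float
    baba: float
    n_blocks: int
    degenerate: bool = False
    significant_bonferroni: bool | None = None


def trio_frequencies(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    trio: tuple[str, str, str, str],
    annotation: SiteAnnotation | None = None,
    outgroup_polarize_band: tuple[float, float] = (0.2, 0.8),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele frequencies (4 x sites) for a trio + usable mask.

    With an annotation, sites carry their recorded ancestral state and
    unpolarized sites drop out; without one, the derived allele is the
    allele rare in the outgroup, and sites with outgroup alt frequency
    inside ``outgroup_polarize_band`` are dropped as unpolarizable.
    """
    idx = [popmap.indices(dataset, p) for p in trio]
    if annotation is not None:
        freqs = np.vstack([derived_frequency(dataset, annotation, i) for i in idx])
    else:
        raw = np.vstack([dataset.alt_frequency(i) for i in idx])
        p_out = raw[3]
        lo, hi = outgroup_polarize_band
        flip = p_out >= hi  # alt is ancestral-like in the outgroup
        ambiguous = (p_out > lo) & (p_out < hi)
        freqs = np.where(flip[None, :], 1.0 - raw, raw)
        freqs[:, ambiguous] = np.nan
    usable = np.all(np.isfinite(freqs), axis=0)
    return freqs, usable


def patterson_d(freqs: np.ndarray) -> tuple[float, float, float]:
    """D, ABBA sum and BABA sum from a (4, n_sites) frequency array.

    Raises ValueError when no informative sites remain (ABBA+BABA = 0).
    """
    p1, p2, p3, p4 = freqs
    abba = float(np.nansum((1 - p1) * p2 * p3 * (1 - p4)))
    baba = float(np.nansum(p1 * (1 - p2) * p3 * (1 - p4)))
    if abba + baba == 0:
        raise ValueError("no informative sites: ABBA + BABA = 0")
    return (abba - baba) / (abba + baba), abba, baba


def block_jackknife(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    trio: tuple[str, str, str, str],
    annotation: SiteAnnotation | None = None,
    block_size_bp: int = 1_000_000,
    min_blocks: int = 20,
) -> TrioTest:
    """Patterson's D with a weighted delete-one block jackknife SE.

    Contiguous genomic blocks of ``block_size_bp``; block weights are
    proportional to their informative-site sums (ABBA+BABA). Fewer than
    ``min_blocks`` non-empty blocks is an error. When all blocks give an
    identical D the SE is zero and the result is flagged degenerate with
    p = 0 (guarded rather than divided through).
    """
    freqs, usable = trio_frequencies(dataset, popmap, trio, annotation)
    p1, p2, p3, p4 = freqs
    abba_site = np.where(usable, (1 - p1) * p2 * p3 * (1 - p4), 0.0)
    baba_site = np.where(usable, p1 * (1 - p2) * p3 * (1 - p4), 0.0)

    block_id = np.empty(dataset.n_sites, dtype=int)
    next_id = 0
    for c in dataset.chromosomes:
        on = dataset.chrom == c
        b = (dataset.pos[on] - 1) // block_size_bp
        # renumber to global consecutive ids
        uniq, inv = np.unique(b, return_inverse=True)
        block_id[on] = inv + next_id
        next_id += len(uniq)

    abba_b = np.bincount(block_id, weights=abba_site, minlength=next_id)
    baba_b = np.bincount(block_id, weights=baba_site, minlength=next_id)
    info_b = abba_b + baba_b
    nonempty = info_b > 0
    abba_b, baba_b, info_b = abba_b[nonempty], baba_b[nonempty], info_b[nonempty]
    n_blocks = int(nonempty.sum())
    if n_blocks < min_blocks:
        raise ValueError(
            f"only {n_blocks} non-empty blocks (< {min_blocks}); use a larger "
            "dataset or smaller blocks"
        )

    abba, baba = float(abba_b.sum()), float(baba_b.sum())
    d = (abba - baba) / (abba + baba)

    # delete-one estimates and Busing weighted jackknife variance
    d_del = (abba - abba_b - (baba - baba_b)) / (abba + baba - info_b)
    total = abba + baba
    h = total / info_b  # inverse block weights
    pseudo = h * d - (h - 1.0) * d_del
    theta_j = float(n_blocks * d - np.sum((1.0 - info_b / total) * d_del))
    var = float(np.sum((pseudo - theta_j) ** 2 / (h - 1.0)) / n_blocks)
    se = np.sqrt(max(var, 0.0))

    if se < 1e-9:  # all blocks effectively identical
        degenerate = True
        z = np.inf if d != 0 else 0.0
        p = 0.0 if d != 0 else 1.0
    else:
        degenerate = False
        z = d / se
        p = float(2.0 * norm.sf(abs(z)))
    return TrioTest(
        h1=trio[0], h2=trio[1], h3=trio[2], h4=trio[3],
        d=float(d), se=float(se), z=float(z), p_value=p,
        abba=abba, baba=baba, n_blocks=n_blocks, degenerate=degenerate,
    )


def bonferroni(p_values: list[float], alpha: float = 0.05) -> list[bool]:
    """Family-wise flags: significant when p < alpha / k."""
    k = len(p_values)
    if k < 1:
        raise ValueError("need at least one p-value")
    return [p < alpha / k for p in p_values]


# ---------------------------------------------------------------------------
# windowed f_d scan
# ---------------------------------------------------------------------------

def fd_scan(
    dataset: GenotypeDataset,
    popmap: PopulationMap,
    trio: tuple[str, str, str, str],
    annotation: SiteAnnotation | None = None,
    window_snvs: int = 25,
    step_snvs: int = 10,
) -> pd.DataFrame:
    """Sliding-window f_d along each chromosome (25-SNV windows, 10-SNV
    step by default, counted in informative SNVs, never spanning
    chromosomes). Returns one row per window with its physical bounds
    (1-based inclusive), f_d and the window D sign.
    """
    freqs, usable = trio_frequencies(dataset, popmap, trio, annotation)
    p1, p2, p3, p4 = freqs
    num_site = np.where(usable, (1 - p1) * p2 * p3 * (1 - p4)
                        - p1 * (1 - p2) * p3 * (1 - p4), 0.0)
    pd_dyn = np.maximum(p2, p3)
    den_site = np.where(usable, (1 - p1) * pd_dyn * pd_dyn * (1 - p4)
                        - p1 * (1 - pd_dyn) * pd_dyn * (1 - p4), 0.0)

    rows = []
    for c in dataset.chromosomes:
        on = np.flatnonzero((dataset.chrom == c) & usable)
        if len(on) < window_snvs:
            logger.info("chromosome %s has %d usable SNVs (< window); skipped",
                        c, len(on))
            continue
        for start in range(0, len(on) - window_snvs + 1, step_snvs):
            w = on[start : start + window_snvs]
            num = float(num_site[w].sum())
            den = float(den_site[w].sum())
            fd = num / den if (num > 0 and den > 0) else 0.0
            fd = min(fd, 1.0)
            rows.append(
                {
                    "chrom": c,
                    "start": int(dataset.pos[w[0]]),
                    "end": int(dataset.pos[w[-1]]),
                    "n_snvs": len(w),
                    "fd": fd,
                    "d_sign": int(np.sign(num)),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snvs", "fd", "d_sign"]
    )


def top_windows(windows: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Flag the top-``fraction`` windows by f_d per chromosome.

    The threshold is the value of the ``ceil(fraction * n)``-th largest
    window on each chromosome; ties at the threshold are all flagged.
    """
    out = windows.copy()
    out["top"] = False
    for c, grp in out.groupby("chrom"):
        n = len(grp)
        k = int(np.ceil(fraction * n))
        if k < 1:
            continue
        thresh = np.sort(grp["fd"].to_numpy())[::-1][k - 1]
        out.loc[grp.index[grp["fd"] >= thresh], "top"] = True
    return out
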