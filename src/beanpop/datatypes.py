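"""Core in-memory containers for the pipeline.

Everything downstream operates on these types; files are read once at the
edge (:mod:`beanpop.vcfio`) and never re-read by analysis code.

Conventions
-----------
* Genotypes are diploid alt-allele dosages in {0, 1, 2}; missing calls are
  encoded as -1 (``MISSING``).
* Positions are 1-based inclusive (VCF convention) and strictly increasing
  within each chromosome.
* All sites are biallelic by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING: int = -1

SAMPLE_CLASSES = ("wild", "cultivated", "feral", "outgroup")

CATEGORIES = ("nongenic", "intronic", "CDS")
EFFECTS = ("synonymous", "nonsynonymous", "frameshift", "nonsense", "none")


@dataclass
class GenotypeDataset:
    """Samples x sites diploid genotype matrix with per-genotype depth.

    Parameters
    ----------
    sample_ids:
        Ordered sample identifiers.
    chrom, pos:
        Per-site chromosome label and 1-based position.
    ref_allele, alt_allele:
        Per-site single-character alleles.
    genotypes:
        ``(n_samples, n_sites)`` int8 array of alt dosages; -1 = missing.
    depth:
        Optional ``(n_samples, n_sites)`` total read depth per genotype.
    ad_ref, ad_alt:
        Optional per-genotype ref/alt read counts (sum to ``depth`` where
        both are present); required by the paralog-detection statistic.
    phased_haplotypes:
        Optional ``(2 * n_samples, n_sites)`` binary matrix; haplotype rows
        ``2i`` and ``2i + 1`` belong to sample ``i`` and sum to its dosage.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    genotypes: np.ndarray
    depth: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    phased_haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.pos)} sites"
            )
        self.validate_sorted()
        if self.phased_haplotypes is not None:
            hap = np.asarray(self.phased_haplotypes, dtype=np.int8)
            if hap.shape != (2 * self.n_samples, self.n_sites):
                raise ValueError("phased haplotype matrix has wrong shape")
            dosage = hap[0::2] + hap[1::2]
            obs = self.genotypes
            ok = (obs == MISSING) | (dosage == obs)
            if not np.all(ok):
                raise ValueError("phased haplotypes inconsistent with dosages")
            self.phased_haplotypes = hap

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def validate_sorted(self) -> None:
        for c in set(self.chrom.tolist()):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- subsetting ------------------------------------------------------
    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            genotypes=self.genotypes[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            ad_ref=None if self.ad_ref is None else self.ad_ref[:, idx],
            ad_alt=None if self.ad_alt is None else self.ad_alt[:, idx],
            phased_haplotypes=(
                None
                if self.phased_haplotypes is None
                else self.phased_haplotypes[:, idx]
            ),
        )

    def take_samples(self, keep: Sequence[str]) -> "GenotypeDataset":
        order = [self.sample_ids.index(s) for s in keep]
        hap_rows = None
        if self.phased_haplotypes is not None:
            hap_rows = np.array(
                [r for i in order for r in (2 * i, 2 * i + 1)], dtype=int
            )
        return GenotypeDataset(
            sample_ids=list(keep),
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            genotypes=self.genotypes[order],
            depth=None if self.depth is None else self.depth[order],
            ad_ref=None if self.ad_ref is None else self.ad_ref[order],
            ad_alt=None if self.ad_alt is None else self.ad_alt[order],
            phased_haplotypes=(
                None if hap_rows is None else self.phased_haplotypes[hap_rows]
            ),
        )

    # -- derived quantities ----------------------------------------------
    def alt_frequency(self, sample_index: Sequence[int] | None = None) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing genotypes.

        Returns NaN where no genotype is observed.
        """
        g = self.genotypes if sample_index is None else self.genotypes[list(sample_index)]
        called = g != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def missing_by_sample(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def missing_by_site(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)


@dataclass
class PopulationMap:
    """sample -> population label, class, optional coordinates."""

    population: dict[str, str]
    sample_class: dict[str, str]
    latitude: dict[str, float] = field(default_factory=dict)
    longitude: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s, cls in self.sample_class.items():
            if cls not in SAMPLE_CLASSES:
                raise ValueError(
                    f"sample {s!r}: class {cls!r} not in {SAMPLE_CLASSES}"
                )
            if not self.population.get(s):
                raise ValueError(f"sample {s!r} has empty population label")

    @property
    def samples(self) -> list[str]:
        return list(self.population)

    def populations(self, sample_class: str | None = None) -> list[str]:
        """Population labels in order of first appearance, optionally by class."""
        seen: dict[str, None] = {}
        for s, p in self.population.items():
            if sample_class is None or self.sample_class[s] == sample_class:
                seen.setdefault(p, None)
        return list(seen)

    def members(self, population: str) -> list[str]:
        return [s for s, p in self.population.items() if p == population]

    def class_of_population(self, population: str) -> str:
        classes = {self.sample_class[s] for s in self.members(population)}
        if len(classes) != 1:
            raise ValueError(f"population {population!r} mixes classes {classes}")
        return classes.pop()

    def indices(self, dataset: GenotypeDataset, population: str) -> list[int]:
        return [dataset.sample_index(s) for s in self.members(population)
                if s in dataset.sample_ids]

    def check_covers(self, dataset: GenotypeDataset) -> None:
        missing = [s for s in dataset.sample_ids if s not in self.population]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")

    def coordinates(self, population: str) -> tuple[float, float]:
        lat = [self.latitude[s] for s in self.members(population) if s in self.latitude]
        lon = [self.longitude[s] for s in self.members(population) if s in self.longitude]
        if not lat or not lon:
            raise KeyError(f"no coordinates for population {population!r}")
        return float(np.mean(lat)), float(np.mean(lon))


@dataclass
class SiteAnnotation:
    """Per-site functional annotation and ancestral-state polarization.

    ``effect`` is meaningful only for CDS sites (``"none"`` elsewhere);
    ``ancestral_allele`` is one of ``ref``/``alt``/``unknown``;
    ``on_chromosome`` is False for loci mapped only to unplaced scaffolds.
    """

    category: np.ndarray
    effect: np.ndarray
    ancestral_allele: np.ndarray
    gene_id: np.ndarray | None = None
    on_chromosome: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.category = np.asarray(self.category, dtype=object)
        self.effect = np.asarray(self.effect, dtype=object)
        self.ancestral_allele = np.asarray(self.ancestral_allele, dtype=object)
        n = len(self.category)
        if len(self.effect) != n or len(self.ancestral_allele) != n:
            raise ValueError("annotation arrays have unequal lengths")
        bad = (self.category != "CDS") & (self.effect != "none")
        if np.any(bad):
            raise ValueError("non-CDS sites must carry effect 'none'")
        bad = (self.category == "CDS") & (self.effect == "none")
        if np.any(bad):
            raise ValueError("CDS sites must carry a coding effect")
        for a in set(self.ancestral_allele.tolist()):
            if a not in ("ref", "alt", "unknown"):
                raise ValueError(f"bad ancestral_allele value {a!r}")
        if self.on_chromosome is None:
            self.on_chromosome = np.ones(n, dtype=bool)
        else:
            self.on_chromosome = np.asarray(self.on_chromosome, dtype=bool)

    @property
    def n_sites(self) -> int:
        return len(self.category)

    def take(self, mask_or_index: np.ndarray) -> "SiteAnnotation":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SiteAnnotation(
            category=self.category[idx],
            effect=self.effect[idx],
            ancestral_allele=self.ancestral_allele[idx],
            gene_id=None if self.gene_id is None else self.gene_id[idx],
            on_chromosome=self.on_chromosome[idx],
        )

    def derived_dosage(self, dataset: GenotypeDataset) -> np.ndarray:
        """Genotypes re-polarized to derived-allele dosage.

        Sites with unknown ancestral state are returned as all-missing so
        unpolarized sites drop out of derived-allele statistics.
        """
        g = dataset.genotypes.astype(np.int8).copy()
        flip = self.ancestral_allele == "alt"
        gm = g[:, flip]
        g[:, flip] = np.where(gm == MISSING, MISSING, 2 - gm)
        g[:, self.ancestral_allele == "unknown"] = MISSING
        return g


def derived_frequency(
    dataset: GenotypeDataset,
    annotation: SiteAnnotation,
    sample_index: Sequence[int],
) -> np.ndarray:
    """Per-site derived-allele frequency in a set of samples (NaN if no calls
    or unpolarizable)."""
    g = annotation.derived_dosage(dataset)[list(sample_index)]
    called = g != MISSING
    n = called.sum(axis=0)
    der = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, der / (2.0 * n), np.nan)
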