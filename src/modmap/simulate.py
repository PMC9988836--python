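"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators cover the pipeline's inputs: (1) a group-structured inbred
strain panel — strains fall into subspecies-like groups that share ancestral
haplotype blocks, with strain-specific missingness emulating the uneven SNP
coverage of wild-derived strains; (2) a two-locus complementation trait —
a dominant susceptible allele at the primary (receptor) locus, or a
resistant primary allele rescued by a dominant enhancer allele, expressed
with incomplete penetrance and requiring a functional primary locus; (3)
backcross cohorts recombining along one chromosome under the Haldane
(no-interference) map function; and (4) functional networks with planted
gene modules.  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    HET,
    HOM,
    MISSING,
    BackcrossCohort,
    DoseResponseTable,
    FunctionalNetwork,
    GenotypeMatrix,
)

__all__ = [
    "PanelSimConfig",
    "TwoLocusTraitModel",
    "BackcrossSimConfig",
    "NetworkSimConfig",
    "ParentalHaplotypes",
    "AnnotatedPanel",
    "simulate_strain_panel",
    "assign_trait_alleles",
    "susceptibility_probability",
    "simulate_dose_response",
    "simulate_backcross",
    "simulate_network",
    "haldane",
]


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class PanelSimConfig:
    """Group-structured strain panel.

    Defaults mirror a ~50-strain inbred panel genotyped over a ~70 Mb
    chromosomal interval: 7 phylogenetic groups of 7 strains, ancestral
    haplotype blocks of 2 Mb, and strain-level missingness drawn uniformly
    per strain from ``missing_rate_range`` (wild-derived strains have far
    patchier coverage than classical laboratory strains, hence a wide range).
    """

    n_groups: int = 7
    strains_per_group: int = 7
    n_snps: int = 2000
    chrom_length: int = 70_000_000
    block_length: int = 2_000_000
    between_group_divergence: float = 0.3
    within_group_diversity: float = 0.02
    missing_rate_range: tuple[float, float] = (0.0, 0.3)
    chrom: str = "6"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.between_group_divergence, self.within_group_diversity, *self.missing_rate_range):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_snps < 1 or self.block_length <= 0:
            raise ValueError("need n_snps >= 1 and block_length > 0")


@dataclass(frozen=True)
class TwoLocusTraitModel:
    """Dominant complementation rule: affected iff a susceptible primary
    allele is present, or a resistant primary allele coincides with a
    dominant enhancer allele — always requiring a functional primary locus
    (a knockout animal is never affected).  Expressed with ``penetrance``."""

    primary_locus_pos: int = 55_100_000
    enhancer_locus_pos: int = 52_000_000
    penetrance: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.penetrance <= 1:
            raise ValueError("need 0 < penetrance <= 1")


@dataclass(frozen=True)
class ParentalHaplotypes:
    """(primary, enhancer) alleles of the two backcross parents.

    Alleles: primary in {'s', 'r', 'ko'}; enhancer in {'E', 'e'}.  The
    default is the enhancer-discovery design: a wild-derived donor carrying
    (r, E) crossed to a knockout recurrent parent (ko, e).
    """

    donor: tuple[str, str] = ("r", "E")
    recurrent: tuple[str, str] = ("ko", "e")


@dataclass(frozen=True)
class BackcrossSimConfig:
    """BC1 cohort along one chromosome; defaults follow a 114-animal cohort
    with the Haldane map function at 0.5 cM/Mb."""

    n_animals: int = 114
    marker_positions: tuple[int, ...] = tuple(range(5_000_000, 70_000_001, 5_000_000))
    cm_per_mb: float = 0.5
    chrom: str = "6"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("need n_animals >= 1")
        if list(self.marker_positions) != sorted(self.marker_positions):
            raise ValueError("marker positions must be sorted")


@dataclass(frozen=True)
class NetworkSimConfig:
    """Functional network with planted modules; weights are Beta-distributed
    with distinct within- and between-module means."""

    n_genes: int = 300
    module_sizes: tuple[int, ...] = (40, 40)
    within_weight_mean: float = 0.8
    between_weight_mean: float = 0.1
    weight_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed gene count")
        if self.weight_concentration <= 0:
            raise ValueError("weight_concentration must be positive")


# ---------------------------------------------------------------------------
# strain panel


def simulate_strain_panel(config: PanelSimConfig) -> GenotypeMatrix:
    """Simulate group-structured haploid genotypes with per-strain missingness.

    Per haplotype block, each group draws a haplotype differing from a common
    ancestral reference at rate ``between_group_divergence``; each strain then
    mutates its group haplotype at rate ``within_group_diversity``; finally a
    per-strain missing rate drawn uniformly from ``missing_rate_range`` masks
    calls completely at random.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    pos = np.sort(rng.choice(np.arange(1, config.chrom_length + 1), size=m, replace=False))
    block = pos // config.block_length
    n_strains = config.n_groups * config.strains_per_group

    group_hap = np.zeros((config.n_groups, m), dtype=np.int8)
    for b in np.unique(block):
        idx = block == b
        flips = rng.random((config.n_groups, int(idx.sum()))) < config.between_group_divergence
        group_hap[:, idx] = flips.astype(np.int8)

    calls = np.empty((m, n_strains), dtype=np.int8)
    strains = []
    for g in range(config.n_groups):
        for s in range(config.strains_per_group):
            mut = rng.random(m) < config.within_group_diversity
            calls[:, len(strains)] = group_hap[g] ^ mut.astype(np.int8)
            strains.append(f"G{g + 1}S{s + 1}")

    poly = (calls.min(axis=1) != calls.max(axis=1)).sum()
    if poly == 0:
        raise ValueError(
            "simulation produced zero polymorphic SNPs; increase "
            "between_group_divergence or within_group_diversity"
        )

    lo, hi = config.missing_rate_range
    rates = rng.uniform(lo, hi, size=n_strains)
    mask = rng.random((m, n_strains)) < rates[None, :]
    calls[mask] = MISSING

    variants = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(m)],
            "chrom": config.chrom,
            "pos": pos.astype(int),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(variants, strains, calls)


# ---------------------------------------------------------------------------
# trait model


def susceptibility_probability(primary: str, enhancer: str, model: TwoLocusTraitModel) -> float:
    """Expected probability of the affected phenotype for an inbred strain
    with the given alleles."""
    if primary == "ko":
        return 0.0
    if primary == "s" or (primary == "r" and enhancer == "E"):
        return model.penetrance
    return 0.0


@dataclass
class AnnotatedPanel:
    """A strain panel with trait alleles embedded as genotype columns."""

    genotypes: GenotypeMatrix
    labels: pd.DataFrame  # columns: strain, primary, enhancer
    model: TwoLocusTraitModel
    primary_snp_id: str = "primary_locus"
    enhancer_snp_id: str = "enhancer_locus"

    def susceptibility(self) -> pd.Series:
        p = self.labels.apply(
            lambda r: susceptibility_probability(r["primary"], r["enhancer"], self.model), axis=1
        )
        return pd.Series(p.to_numpy(), index=self.labels["strain"], name="p_affected")


def assign_trait_alleles(
    panel: GenotypeMatrix,
    model: TwoLocusTraitModel,
    group_to_allele: dict[str, tuple[str, str]],
) -> AnnotatedPanel:
    """Label each strain with (primary, enhancer) alleles by group prefix and
    embed the alleles as two extra genotype columns at the model's loci
    (susceptible primary allele and dominant enhancer allele coded 1), so an
    association scan can rediscover them."""
    labels = []
    for strain in panel.strains:
        group = strain.split("S")[0]
        if group not in group_to_allele:
            raise KeyError(f"no allele plan for group {group!r} (strain {strain!r})")
        primary, enhancer = group_to_allele[group]
        labels.append((strain, primary, enhancer))
    labels = pd.DataFrame(labels, columns=["strain", "primary", "enhancer"])

    primary_calls = (labels["primary"] == "s").to_numpy(dtype=np.int8)
    enhancer_calls = (labels["enhancer"] == "E").to_numpy(dtype=np.int8)
    chrom = panel.variants["chrom"].iloc[0]
    extra = pd.DataFrame(
        {
            "snp_id": ["primary_locus", "enhancer_locus"],
            "chrom": chrom,
            "pos": [model.primary_locus_pos, model.enhancer_locus_pos],
            "ref": "A",
            "alt": "G",
        }
    )
    variants = pd.concat([panel.variants, extra], ignore_index=True)
    calls = np.vstack([panel.calls, primary_calls[None, :], enhancer_calls[None, :]])
    gm = GenotypeMatrix(variants, list(panel.strains), calls).sort()
    return AnnotatedPanel(genotypes=gm, labels=labels, model=model)


def simulate_dose_response(
    annotated: AnnotatedPanel,
    doses: list[float],
    animals_per_dose: int,
    seed: int,
    background_rate: float = 0.0,
) -> DoseResponseTable:
    """Binomial dose-response counts: susceptible strains respond at the
    model penetrance (dose structure is kept but does not modulate risk,
    matching a death-at-fixed-time binary readout); resistant strains at
    ``background_rate``."""
    rng = np.random.default_rng(seed)
    probs = annotated.susceptibility()
    rows = []
    for strain in annotated.genotypes.strains:
        p = probs[strain] if probs[strain] > 0 else background_rate
        for dose in doses:
            affected = int(rng.binomial(animals_per_dose, p))
            rows.append((strain, dose, affected, animals_per_dose))
    return DoseResponseTable(pd.DataFrame(rows, columns=["strain", "dose", "affected", "tested"]))


# ---------------------------------------------------------------------------
# backcross


def haldane(d_morgans: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a map distance in
    Morgans, r = (1 - exp(-2d)) / 2 (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, dtype=float)))


def simulate_backcross(
    config: BackcrossSimConfig,
    model: TwoLocusTraitModel,
    parents: ParentalHaplotypes = ParentalHaplotypes(),
) -> BackcrossCohort:
    """Simulate a BC1 cohort: each animal carries one recurrent-parent gamete
    and one F1 gamete built by a Markov walk (donor/recurrent origin switches
    between adjacent loci with the Haldane recombination fraction).  The
    phenotype applies the dominant complementation rule to each animal's two
    alleles at the primary and enhancer loci, at the model penetrance."""
    rng = np.random.default_rng(config.seed)
    markers = np.asarray(config.marker_positions, dtype=int)
    loci = np.union1d(markers, [model.primary_locus_pos, model.enhancer_locus_pos])
    n_loci = len(loci)
    d_mb = np.diff(loci) / 1e6
    rec = haldane(config.cm_per_mb * d_mb / 100.0)

    n = config.n_animals
    origin = np.empty((n_loci, n), dtype=np.int8)  # 1 = donor origin in the F1 gamete
    origin[0] = rng.random(n) < 0.5
    for i in range(1, n_loci):
        flip = rng.random(n) < rec[i - 1]
        origin[i] = origin[i - 1] ^ flip

    pi = int(np.searchsorted(loci, model.primary_locus_pos))
    ei = int(np.searchsorted(loci, model.enhancer_locus_pos))

    def animal_phenotype(j: int) -> int:
        primary = {parents.recurrent[0], parents.donor[0] if origin[pi, j] else parents.recurrent[0]}
        enhancer = {parents.recurrent[1], parents.donor[1] if origin[ei, j] else parents.recurrent[1]}
        functional = bool(primary - {"ko"})
        susceptible = functional and ("s" in primary or ("r" in primary and "E" in enhancer))
        return int(susceptible and rng.random() < model.penetrance)

    phenotypes = np.array([animal_phenotype(j) for j in range(config.n_animals)])
    marker_idx = np.searchsorted(loci, markers)
    genotypes = np.where(origin[marker_idx] == 1, HET, HOM).astype(np.int8)

    animals = pd.DataFrame(
        {"animal_id": [f"bc{j + 1:04d}" for j in range(n)], "phenotype": phenotypes}
    )
    marker_map = pd.DataFrame(
        {
            "marker_id": [f"m{k + 1:03d}" for k in range(len(markers))],
            "chrom": config.chrom,
            "pos": markers,
        }
    )
    return BackcrossCohort(animals=animals, marker_map=marker_map, genotypes=genotypes)


# ---------------------------------------------------------------------------
# network


def simulate_network(config: NetworkSimConfig) -> tuple[FunctionalNetwork, dict[str, list[str]]]:
    """Symmetric [0,1]-weighted network with planted modules.

    Within-module edge weights are Beta with mean ``within_weight_mean``,
    all other edges Beta with mean ``between_weight_mean``; the shared
    concentration controls spread (concentration -> inf degenerates to the
    mean).  Returns the network and the planted membership map.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i + 1:04d}" for i in range(n)]

    def beta_sample(mean: float, size) -> np.ndarray:
        c = config.weight_concentration
        if mean <= 0.0 or mean >= 1.0:
            return np.full(size, mean)
        return rng.beta(mean * c, (1 - mean) * c, size=size)

    weights = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    weights[iu] = beta_sample(config.between_weight_mean, size=len(iu[0]))

    modules: dict[str, list[str]] = {}
    start = 0
    membership = np.full(n, -1)
    for mi, size in enumerate(config.module_sizes):
        modules[f"module{mi + 1}"] = genes[start : start + size]
        membership[start : start + size] = mi
        start += size
    same = (membership[iu[0]] == membership[iu[1]]) & (membership[iu[0]] >= 0)
    weights[iu[0][same], iu[1][same]] = beta_sample(config.within_weight_mean, size=int(same.sum()))
    weights = weights + weights.T
    return FunctionalNetwork(gene_ids=genes, weights=weights), modules
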