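"""Core domain types for inbred-strain modifier-locus mapping.

All genotype data are haploid-coded: panel strains are fully inbred and
homozygous, so a biallelic SNP call is 0 (reference), 1 (alternate) or
:data:`MISSING`.  Missingness is a first-class third symbol and is never
silently replaced by a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for an unobserved call; shared by genotype and marker matrices.
MISSING: int = -1

#: Backcross genotype codes: homozygous for the recurrent-parent allele,
#: or heterozygous (one recurrent, one donor allele).
HOM: int = 0
HET: int = 1

VARIANT_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt")


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP.

    Parameters
    ----------
    snp_id : str
        Unique identifier within a genotype matrix.
    chrom : str
        Chromosome name.
    pos : int
        1-based basepair coordinate.
    ref, alt : str
        Single-character nucleotide codes; must differ.
    """

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.snp_id}: ref and alt alleles are identical")


@dataclass
class GenotypeMatrix:
    """Strains x SNPs haploid genotype calls.

    Attributes
    ----------
    variants : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, ref, alt``,
        sorted by (chrom, pos).
    strains : list of str
        Strain names, case-sensitive exact keys.
    calls : ndarray of int8, shape (n_variants, n_strains)
        Entries in {0, 1, MISSING}.
    """

    variants: pd.DataFrame
    strains: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if list(self.variants.columns[:5]) != list(VARIANT_COLUMNS):
            raise ValueError(f"variants table must have columns {VARIANT_COLUMNS}")
        if self.calls.shape != (len(self.variants), len(self.strains)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.variants)} variants x {len(self.strains)} strains"
            )
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError(f"calls contain symbols outside {{0, 1, NA}} at {np.argwhere(bad)[0]}")
        if self.variants["snp_id"].duplicated().any():
            dup = self.variants.loc[self.variants["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain names")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain {strain!r}") from None

    def is_sorted(self) -> bool:
        v = self.variants
        for _, grp in v.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                return False
        return True

    def sort(self) -> "GenotypeMatrix":
        """Return a copy sorted by (chrom, pos), reordering calls to match."""
        order = self.variants.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
        return GenotypeMatrix(
            variants=self.variants.iloc[order].reset_index(drop=True),
            strains=list(self.strains),
            calls=self.calls[order],
        )

    def missing_fraction(self) -> pd.Series:
        """Per-strain fraction of MISSING calls."""
        frac = (self.calls == MISSING).mean(axis=0)
        return pd.Series(frac, index=self.strains, name="missing_fraction")

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.variants.copy(), list(self.strains), self.calls.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.strains == other.strains
            and self.variants.equals(other.variants)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class DoseResponseTable:
    """Per-strain, per-dose affected/tested counts from a challenge screen."""

    rows: pd.DataFrame  # columns: strain, dose, affected, tested

    def __post_init__(self) -> None:
        df = self.rows.reset_index(drop=True)
        required = ["strain", "dose", "affected", "tested"]
        if list(df.columns[:4]) != required:
            raise ValueError(f"dose-response table must have columns {required}")
        if (df["dose"] <= 0).any():
            raise ValueError("doses must be positive")
        if ((df["affected"] < 0) | (df["affected"] > df["tested"])).any():
            raise ValueError("need 0 <= affected <= tested in every row")
        if df.duplicated(["strain", "dose"]).any():
            raise ValueError("duplicate (strain, dose) row")
        self.rows = df

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.rows["strain"]))


@dataclass
class BackcrossCohort:
    """BC1 animals with binary phenotype and Ho/He marker genotypes.

    ``genotypes[i, j]`` is animal *j*'s call at marker *i*: :data:`HOM`
    (homozygous recurrent parent), :data:`HET` (carries the donor allele)
    or :data:`MISSING`.
    """

    animals: pd.DataFrame  # columns: animal_id, phenotype (0/1)
    marker_map: pd.DataFrame  # columns: marker_id, chrom, pos
    genotypes: np.ndarray  # (n_markers, n_animals) int8

    def __post_init__(self) -> None:
        self.animals = self.animals.reset_index(drop=True)
        self.marker_map = self.marker_map.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if not set(self.animals["phenotype"]).issubset({0, 1}):
            raise ValueError("phenotype must be binary 0/1")
        if self.genotypes.shape != (len(self.marker_map), len(self.animals)):
            raise ValueError("genotype matrix shape inconsistent with markers x animals")
        if not np.isin(self.genotypes, (HOM, HET, MISSING)).all():
            raise ValueError("backcross genotypes must be in {Ho, He, NA}")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("marker positions must be strictly increasing per chromosome")

    @property
    def n_animals(self) -> int:
        return len(self.animals)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in 0-based half-open coordinates (BED convention)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass
class GeneSetCollection:
    """Named trait-term gene sets (e.g. Cardiac, Histamine, ...)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class FunctionalNetwork:
    """Weighted gene-gene functional association network.

    Weights are a dense symmetric matrix with entries in [0, 1] and a zero
    diagonal; row/column order follows ``gene_ids``.
    """

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape inconsistent with gene list")
        if (self.weights < 0).any() or (self.weights > 1).any():
            raise ValueError("network weights must lie in [0, 1]")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("network weights must be symmetric")
        np.fill_diagonal(self.weights, 0.0)
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        if len(self._index) != n:
            raise ValueError("duplicate gene ids in network")

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index(self, gene: str) -> int:
        return self._index[gene]

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self._index[a], self._index[b]])

    def connectivity(self, genes: list[str], to_genes: list[str]) -> np.ndarray:
        """Connectivity feature matrix: rows = ``genes``, columns = weights to ``to_genes``."""
        rows = [self._index[g] for g in genes]
        cols = [self._index[g] for g in to_genes]
        return self.weights[np.ix_(rows, cols)]
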