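"""Readers and writers for the plain-text formats the pipeline touches.

Conventions: genotype TSV and VCF positions are 1-based; BED intervals are
0-based half-open.  All writers emit a ``#``-prefixed provenance header and
deterministic column/row order.  TSV readers are gzip-transparent.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    HET,
    HOM,
    MISSING,
    VARIANT_COLUMNS,
    BackcrossCohort,
    DoseResponseTable,
    FunctionalNetwork,
    GeneModel,
    GeneSetCollection,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)

_CALL_MAP = {"0": 0, "1": 1, "NA": MISSING}
_CALL_REV = {0: "0", 1: "1", MISSING: "NA"}


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def provenance_header(seed=None, config_hash: str | None = None) -> str:
    from . import __version__

    parts = [f"modmap={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config={config_hash}")
    return "# " + " ".join(parts)


def config_digest(obj) -> str:
    """Short stable hash of a config's repr, for provenance headers."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# genotype TSV


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read the canonical genotype TSV: header ``chrom pos snp_id ref alt <strain...>``.

    Calls must be 0, 1 or NA.  Unsorted input is sorted with a warning;
    a duplicated snp_id or an out-of-alphabet call is an error naming the line.
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if header[:5] != ["chrom", "pos", "snp_id", "ref", "alt"]:
        raise ValueError(f"{path}: bad header {header[:5]}, expected chrom pos snp_id ref alt")
    strains = header[5:]
    if not strains:
        raise ValueError(f"{path}: no strain columns")
    var_rows, call_rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 5 + len(strains):
            raise ValueError(f"{path}:{lineno}: expected {5 + len(strains)} fields, got {len(fields)}")
        chrom, pos, snp_id, ref, alt = fields[:5]
        row = []
        for strain, tok in zip(strains, fields[5:]):
            try:
                row.append(_CALL_MAP[tok])
            except KeyError:
                raise ValueError(
                    f"{path}:{lineno}: malformed call {tok!r} for strain {strain!r}"
                ) from None
        var_rows.append((snp_id, chrom, int(pos), ref, alt))
        call_rows.append(row)
    variants = pd.DataFrame(var_rows, columns=list(VARIANT_COLUMNS))
    gm = GenotypeMatrix(variants, strains, np.array(call_rows, dtype=np.int8))
    if not gm.is_sorted():
        warnings.warn(f"{path}: variants not sorted by (chrom, pos); sorting", stacklevel=2)
        gm = gm.sort()
    return gm


def write_genotype_tsv(gm: GenotypeMatrix, path, seed=None) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(provenance_header(seed=seed) + "\n")
        fh.write("\t".join(["chrom", "pos", "snp_id", "ref", "alt", *gm.strains]) + "\n")
        v = gm.variants
        for i in range(gm.n_variants):
            calls = [_CALL_REV[int(c)] for c in gm.calls[i]]
            fh.write(
                "\t".join(
                    [
                        str(v.at[i, "chrom"]),
                        str(int(v.at[i, "pos"])),
                        str(v.at[i, "snp_id"]),
                        str(v.at[i, "ref"]),
                        str(v.at[i, "alt"]),
                        *calls,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a haploid genotype matrix.

    Inbred assumption: 0/0 -> 0, 1/1 -> 1, ./. -> NA; a heterozygous GT
    becomes NA with a warning.  Multi-allelic records are skipped with a
    warning.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        strains = list(vcf.header.samples)
        var_rows, call_rows = [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(f"skipping multi-allelic record at {rec.chrom}:{rec.pos}", stacklevel=2)
                continue
            row = []
            for s in strains:
                alleles = [a for a in rec.samples[s]["GT"] if a is not None]
                if not alleles:
                    row.append(MISSING)
                elif len(set(alleles)) > 1:
                    warnings.warn(
                        f"heterozygous call at {rec.chrom}:{rec.pos} for {s}; "
                        "treated as missing under the inbred assumption",
                        stacklevel=2,
                    )
                    row.append(MISSING)
                else:
                    row.append(int(alleles[0] > 0))
            var_rows.append((rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            call_rows.append(row)
    variants = pd.DataFrame(var_rows, columns=list(VARIANT_COLUMNS))
    gm = GenotypeMatrix(variants, strains, np.array(call_rows, dtype=np.int8).reshape(len(var_rows), len(strains)))
    return gm.sort() if not gm.is_sorted() else gm


# ---------------------------------------------------------------------------
# GMT / BED / network edge list


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: one set per line, ``name <tab> description <tab> gene...``."""
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    return GeneSetCollection(sets)


def read_bed(path) -> list[GeneModel]:
    """BED3+name; returns gene models in file order."""
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs chrom, start, end, name")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: BED start >= end ({start} >= {end})")
            genes.append(GeneModel(gene_id=name, chrom=chrom, start=start, end=end))
    return genes


def read_network_tsv(path) -> FunctionalNetwork:
    """Edge list ``gene_a gene_b weight`` with weights in [0, 1].

    A duplicate edge with a conflicting weight is an error; symmetric
    duplicates with equal weight are tolerated.
    """
    edges: dict[tuple[str, str], float] = {}
    genes: dict[str, None] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: edge line needs gene_a, gene_b, weight")
            if fields[:3] == ["gene_a", "gene_b", "weight"]:
                continue
            a, b, w = fields[0], fields[1], float(fields[2])
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            genes.setdefault(a)
            genes.setdefault(b)
            key = (a, b) if a <= b else (b, a)
            if key in edges and edges[key] != w:
                raise ValueError(f"{path}:{lineno}: conflicting weight for edge {a}-{b}")
            edges[key] = w
    gene_ids = list(genes)
    idx = {g: i for i, g in enumerate(gene_ids)}
    weights = np.zeros((len(gene_ids), len(gene_ids)))
    for (a, b), w in edges.items():
        if a == b:
            continue
        weights[idx[a], idx[b]] = weights[idx[b], idx[a]] = w
    return FunctionalNetwork(gene_ids=gene_ids, weights=weights)


def write_network_tsv(net: FunctionalNetwork, path, seed=None) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(provenance_header(seed=seed) + "\n")
        fh.write("gene_a\tgene_b\tweight\n")
        n = len(net.gene_ids)
        for i in range(n):
            for j in range(i + 1, n):
                w = net.weights[i, j]
                if w > 0:
                    fh.write(f"{net.gene_ids[i]}\t{net.gene_ids[j]}\t{w:.6g}\n")


# ---------------------------------------------------------------------------
# result tables


def write_table(df: pd.DataFrame, path, seed=None, extra_header: list[str] | None = None) -> None:
    """Write a result table as TSV with a provenance header line."""
    with _open_text(path, "wt") as fh:
        fh.write(provenance_header(seed=seed) + "\n")
        for line in extra_header or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def read_dose_response_tsv(path) -> DoseResponseTable:
    """TSV with columns strain, dose, affected, tested."""
    df = read_table(path)
    return DoseResponseTable(df[["strain", "dose", "affected", "tested"]])


def write_dose_response_tsv(table: DoseResponseTable, path, seed=None) -> None:
    write_table(table.rows, path, seed=seed)


_BC_MAP = {HOM: "Ho", HET: "He", MISSING: "NA"}
_BC_REV = {v: k for k, v in _BC_MAP.items()}


def read_backcross(cohort_path, map_path) -> BackcrossCohort:
    """Cohort TSV (``animal_id  phenotype  <marker...>`` with Ho/He/NA calls)
    plus a marker map TSV (``marker_id  chrom  pos``)."""
    marker_map = read_table(map_path)[["marker_id", "chrom", "pos"]]
    cohort = read_table(cohort_path)
    markers = list(cohort.columns[2:])
    if markers != list(marker_map["marker_id"]):
        raise ValueError("cohort marker columns do not match the marker map")
    geno = np.empty((len(markers), len(cohort)), dtype=np.int8)
    for i, mk in enumerate(markers):
        try:
            geno[i] = [_BC_REV[v] for v in cohort[mk]]
        except KeyError as e:
            raise ValueError(f"bad backcross genotype symbol {e} at marker {mk}") from None
    animals = cohort[["animal_id", "phenotype"]]
    return BackcrossCohort(animals=animals, marker_map=marker_map, genotypes=geno)


def write_backcross(cohort: BackcrossCohort, cohort_path, map_path, seed=None) -> None:
    write_table(cohort.marker_map, map_path, seed=seed)
    df = cohort.animals.copy()
    for i, mk in enumerate(cohort.marker_map["marker_id"]):
        df[mk] = [_BC_MAP[int(v)] for v in cohort.genotypes[i]]
    write_table(df, cohort_path, seed=seed)


def write_score_table(table: pd.DataFrame, path, seed=None) -> None:
    """Write a gene score table ordered by rank then gene_id."""
    cols = [c for c in ("rank", "gene_id") if c in table.columns]
    out = table.sort_values(cols, kind="stable") if cols else table
    write_table(out, path, seed=seed)
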