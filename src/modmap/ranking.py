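"""Combine per-SNP association with functional enrichment into a gene score.

Each SNP is assigned to the nearest gene within 1 Mb; a gene's association
score is the maximum -log10 p over its assigned SNPs.  The combined gene
score S_cg sums the association and functional (-log10 FPR) components after
scaling each by its maximum over the positional candidates, so S_cg lies in
[0, 2] and a gene attaining both maxima scores exactly 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneModel
from .mixedmodel import AssociationResult
from .prioritize import FunctionalScore

logger = logging.getLogger(__name__)

__all__ = [
    "SnpAssignment",
    "assign_snps_to_genes",
    "gene_assoc_score",
    "combined_score",
]

ASSIGN_WINDOW = 1_000_000  # bp


@dataclass
class SnpAssignment:
    """gene -> assigned SNPs, plus the SNPs no gene claimed."""

    by_gene: dict[str, list[AssociationResult]]
    unassigned: list[AssociationResult]


def _distance(gene: GeneModel, pos: int) -> int:
    """Distance from a 1-based SNP position to a 0-based half-open gene
    interval; 0 if the SNP lies inside."""
    pos0 = pos - 1
    if gene.start <= pos0 < gene.end:
        return 0
    return gene.start - pos0 if pos0 < gene.start else pos0 - (gene.end - 1)


def assign_snps_to_genes(
    results: list[AssociationResult],
    genes: list[GeneModel],
    window: int = ASSIGN_WINDOW,
) -> SnpAssignment:
    """Assign each SNP to the single nearest gene within ``window`` bp
    (inclusive); ties go to the lower-start gene and are logged.  SNPs with
    no gene in range are reported separately, never dropped silently."""
    by_gene: dict[str, list[AssociationResult]] = {g.gene_id: [] for g in genes}
    unassigned: list[AssociationResult] = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for snp in results:
        cands = genes_by_chrom.get(snp.chrom, [])
        best, best_d = None, None
        for g in cands:
            d = _distance(g, snp.pos)
            if best_d is None or d < best_d:
                best, best_d = g, d
            elif d == best_d:
                logger.info(
                    "SNP %s equidistant from %s and %s; keeping lower-start gene",
                    snp.snp_id,
                    best.gene_id,
                    g.gene_id,
                )
        if best is not None and best_d <= window:
            by_gene[best.gene_id].append(snp)
        else:
            unassigned.append(snp)
    return SnpAssignment(by_gene=by_gene, unassigned=unassigned)


def gene_assoc_score(assignment: SnpAssignment) -> dict[str, float]:
    """Per-gene association score: max -log10 p over assigned SNPs, 0 for a
    gene with no SNP."""
    out = {}
    for gene, snps in assignment.by_gene.items():
        if snps:
            out[gene] = float(max(-np.log10(max(s.p_value, 1e-300)) for s in snps))
        else:
            out[gene] = 0.0
    return out


def combined_score(
    assoc_scores: dict[str, float],
    functional_scores: list[FunctionalScore] | dict[str, float],
) -> pd.DataFrame:
    """Combined gene score over the positional-candidate universe.

    S_cg(g) = assoc(g)/max(assoc) + func(g)/max(func), maxima taken over the
    candidates present in both inputs.  An all-zero component contributes 0
    for every gene (with a warning) rather than dividing by zero.  Returns a
    table sorted by S_cg descending, ties broken alphabetically, with a
    1-based ``rank`` column.
    """
    if isinstance(functional_scores, dict):
        func = dict(functional_scores)
    else:
        func = {s.gene_id: s.neglog10_fpr for s in functional_scores}
    universe = sorted(set(assoc_scores) & set(func))
    if not universe:
        raise ValueError("no genes shared between association and functional scores")
    a = np.array([assoc_scores[g] for g in universe])
    f = np.array([func[g] for g in universe])
    if (a < 0).any() or (f < 0).any():
        raise ValueError("component scores must be non-negative")
    a_max, f_max = a.max(), f.max()
    if a_max == 0:
        logger.warning("association component is all-zero; it contributes 0 to every S_cg")
    if f_max == 0:
        logger.warning("functional component is all-zero; it contributes 0 to every S_cg")
    a_norm = a / a_max if a_max > 0 else np.zeros_like(a)
    f_norm = f / f_max if f_max > 0 else np.zeros_like(f)
    table = pd.DataFrame(
        {
            "gene_id": universe,
            "assoc_neglog10p": a,
            "func_neglog10fpr": f,
            "assoc_norm": a_norm,
            "func_norm": f_norm,
            "s_cg": a_norm + f_norm,
        }
    )
    table = table.sort_values(["s_cg", "gene_id"], ascending=[False, True], kind="stable")
    table = table.reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
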