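"""Backcross linkage scan: per-marker chi-square segregation tests.

Each BC1 animal is Ho (homozygous recurrent parent) or He (carries one donor
allele) at every marker; under free recombination genotype is independent of
the binary phenotype.  Each marker is tested with an uncorrected Pearson
chi-square on the 2x2 table of (affected/unaffected) x (Ho/He).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist

from .datatypes import HET, HOM, BackcrossCohort

__all__ = ["LinkageResult", "chi_square_2x2", "scan_markers"]


@dataclass(frozen=True)
class LinkageResult:
    marker_id: str
    chrom: str
    pos: int
    a_ho: int
    a_he: int
    u_ho: int
    u_he: int
    chi2: float
    p_value: float

    @property
    def n_used(self) -> int:
        return self.a_ho + self.a_he + self.u_ho + self.u_he


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square without continuity correction for [[a, b], [c, d]].

    chi2 = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]; p is the upper tail of
    the chi-square distribution with 1 df.  A zero margin gives (0, 1) with
    a warning.
    """
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); chi2 = 0, p = 1", stacklevel=2)
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(stat), float(_chi2_dist.sf(stat, df=1))


def scan_markers(cohort: BackcrossCohort) -> list[LinkageResult]:
    """Test every marker, dropping animals with a missing call at that marker
    only (so per-marker totals may differ).  Results in map order."""
    phen = cohort.animals["phenotype"].to_numpy()
    results = []
    for i, row in cohort.marker_map.iterrows():
        geno = cohort.genotypes[i]
        a_ho = int(((phen == 1) & (geno == HOM)).sum())
        a_he = int(((phen == 1) & (geno == HET)).sum())
        u_ho = int(((phen == 0) & (geno == HOM)).sum())
        u_he = int(((phen == 0) & (geno == HET)).sum())
        stat, p = chi_square_2x2(a_ho, a_he, u_ho, u_he)
        results.append(
            LinkageResult(
                marker_id=row["marker_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                a_ho=a_ho,
                a_he=a_he,
                u_ho=u_ho,
                u_he=u_he,
                chi2=stat,
                p_value=p,
            )
        )
    return results
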