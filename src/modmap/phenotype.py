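"""Strain susceptibility testing from dose-response challenge counts.

Deaths at 30 min post-challenge are binary, so per-strain results are pooled
over doses into affected/tested totals and compared against a resistant
reference strain with a two-sided Fisher exact test.  Two-sided p-values use
the point-probability rule: sum the hypergeometric probabilities of every
table (margins fixed) no more probable than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datatypes import DoseResponseTable

__all__ = [
    "PooledPhenotype",
    "SusceptibilityResult",
    "pool_doses",
    "fisher_exact_two_sided",
    "susceptibility_screen",
    "round_p_display",
]


@dataclass(frozen=True)
class PooledPhenotype:
    strain: str
    affected: int
    tested: int

    @property
    def percent_affected(self) -> int:
        """Percent affected, rounded half-up to an integer."""
        return int(np.floor(100 * self.affected / self.tested + 0.5))


@dataclass(frozen=True)
class SusceptibilityResult:
    strain: str
    reference_strain: str
    affected: int
    tested: int
    ref_affected: int
    ref_tested: int
    p_value: float

    @property
    def percent_affected(self) -> int:
        return PooledPhenotype(self.strain, self.affected, self.tested).percent_affected

    @property
    def p_display(self) -> str:
        return round_p_display(self.p_value)


def pool_doses(table: DoseResponseTable, strain: str) -> PooledPhenotype:
    """Sum affected and tested counts over all dose rows of one strain."""
    rows = table.rows[table.rows["strain"] == strain]
    if rows.empty:
        raise KeyError(f"strain {strain!r} not present in dose-response table")
    return PooledPhenotype(
        strain=strain,
        affected=int(rows["affected"].sum()),
        tested=int(rows["tested"].sum()),
    )


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Enumerates the full hypergeometric support in log space and sums the
    probability of every table whose point probability does not exceed that
    of the observed table (with a 1 + 1e-7 relative slack against ties lost
    to rounding).  A zero row or column margin returns p = 1 with a warning.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    xs = np.arange(lo, hi + 1)
    logp = _log_binom(np.float64(r1), xs) + _log_binom(np.float64(r2), c1 - xs) - _log_binom(
        np.float64(n), np.float64(c1)
    )
    log_obs = logp[a - lo]
    keep = logp <= log_obs + np.log(1 + 1e-7)
    # log-sum-exp over the kept tables
    m = logp[keep].max()
    p = float(np.exp(m) * np.exp(logp[keep] - m).sum())
    return min(p, 1.0)


def round_p_display(p: float) -> str:
    """Render p to one significant figure, the display convention of the
    susceptibility tables; values below 1e-4 print as ``<0.0001``."""
    if p < 1e-4:
        return "<0.0001"
    exponent = int(np.floor(np.log10(p)))
    rounded = round(p, -exponent)
    if rounded >= 1.0:
        return "1.0"
    return np.format_float_positional(rounded, trim="-")


def susceptibility_screen(
    table: DoseResponseTable, reference_strain: str
) -> list[SusceptibilityResult]:
    """Fisher-test every non-reference strain's pooled counts against the
    pooled reference counts; one result per strain in table order."""
    ref = pool_doses(table, reference_strain)
    results = []
    for strain in table.strains:
        if strain == reference_strain:
            continue
        pooled = pool_doses(table, strain)
        p = fisher_exact_two_sided(
            pooled.affected,
            pooled.tested - pooled.affected,
            ref.affected,
            ref.tested - ref.affected,
        )
        results.append(
            SusceptibilityResult(
                strain=strain,
                reference_strain=reference_strain,
                affected=pooled.affected,
                tested=pooled.tested,
                ref_affected=ref.affected,
                ref_tested=ref.tested,
                p_value=p,
            )
        )
    return results
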