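"""HMM genotype imputation for inbred strain panels.

A target strain's chromosome is modelled as a mosaic of reference strains:
the hidden state at each SNP is the reference strain currently being copied,
transitions between adjacent SNPs switch reference with a small probability
tau, and emissions allow a per-SNP error epsilon.  The maximum-probability
state path is found by Viterbi decoding in log space, and missing target
calls are filled from the decoded reference strain.  The reference panel for
each target is the k most similar strains by genotype concordance — a
computable proxy for phylogenetic closeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import MISSING, GenotypeMatrix

__all__ = [
    "HmmParams",
    "ViterbiPath",
    "select_reference_panel",
    "viterbi_decode",
    "impute_strain",
    "impute_panel",
    "HmmImputer",
]


@dataclass(frozen=True)
class HmmParams:
    """epsilon: per-SNP emission error; tau: per-interval state-switch
    probability (constant between adjacent SNPs); k: panel size."""

    epsilon: float = 0.01
    tau: float = 0.002
    k: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.5:
            raise ValueError("need 0 < epsilon < 0.5")
        if not 0 < self.tau < 1:
            raise ValueError("need 0 < tau < 1")
        if self.k < 1:
            raise ValueError("need k >= 1")


@dataclass
class ViterbiPath:
    states: np.ndarray  # per-SNP decoded reference index
    log_score: float


def select_reference_panel(gm: GenotypeMatrix, target_strain: str, k: int) -> list[str]:
    """Rank candidate strains by genotype concordance with the target over
    jointly observed SNPs and return the top k (ties broken by name)."""
    ti = gm.strain_index(target_strain)
    target = gm.calls[:, ti]
    scores = []
    for j, name in enumerate(gm.strains):
        if j == ti:
            continue
        cand = gm.calls[:, j]
        both = (target != MISSING) & (cand != MISSING)
        n_both = int(both.sum())
        if n_both == 0:
            raise ValueError(f"target {target_strain!r} shares no observed SNP with {name!r}")
        conc = float((target[both] == cand[both]).mean())
        scores.append((-conc, name))
    scores.sort()
    if k > len(scores):
        warnings.warn(
            f"requested k={k} but only {len(scores)} candidate strains available", stacklevel=2
        )
        k = len(scores)
    return [name for _, name in scores[:k]]


def _emission_logprobs(target: np.ndarray, panel: np.ndarray, epsilon: float) -> np.ndarray:
    """(m, k) matrix of per-SNP per-state emission log-probabilities.

    Match -> log(1 - eps), mismatch -> log(eps); uninformative (either call
    missing) -> 0, i.e. probability 1.
    """
    m, k = panel.shape
    obs = (target != MISSING)[:, None] & (panel != MISSING)
    match = target[:, None] == panel
    out = np.zeros((m, k))
    out[obs & match] = np.log1p(-epsilon)
    out[obs & ~match] = np.log(epsilon)
    return out


def viterbi_decode(
    target: np.ndarray, panel: np.ndarray, params: HmmParams
) -> ViterbiPath:
    """Decode the max-probability reference-strain path.

    Initial distribution uniform over k states; stay probability 1 - tau,
    switch tau / (k - 1); ties broken toward the lower state index.
    """
    target = np.asarray(target, dtype=np.int8)
    panel = np.atleast_2d(np.asarray(panel, dtype=np.int8))
    if panel.shape[0] != target.shape[0]:
        raise ValueError("panel rows must align with target SNPs")
    m, k = panel.shape
    if m < 1:
        raise ValueError("need at least one SNP")
    if (target == MISSING).all():
        warnings.warn("all-missing target; returning constant path at state 0", stacklevel=2)
    emis = _emission_logprobs(target, panel, params.epsilon)
    if k == 1:
        return ViterbiPath(states=np.zeros(m, dtype=int), log_score=float(emis.sum()))

    log_stay = np.log1p(-params.tau)
    log_switch = np.log(params.tau / (k - 1))
    delta = np.full(k, -np.log(k)) + emis[0]
    back = np.zeros((m, k), dtype=int)
    for t in range(1, m):
        cand = delta[:, None] + np.where(np.eye(k, dtype=bool), log_stay, log_switch)
        prev = np.argmax(cand, axis=0)  # lowest predecessor index wins ties
        delta = cand[prev, np.arange(k)] + emis[t]
        back[t] = prev
    states = np.zeros(m, dtype=int)
    states[-1] = int(np.argmax(delta))
    score = float(delta[states[-1]])
    for t in range(m - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return ViterbiPath(states=states, log_score=score)


def impute_strain(
    gm: GenotypeMatrix, target_strain: str, params: HmmParams = HmmParams()
) -> tuple[np.ndarray, dict]:
    """Impute one strain's missing calls from its decoded reference path.

    Observed calls are never altered; a missing call stays missing when the
    decoded reference is also missing there.  Returns (calls, report) where
    report carries pre/post missing fractions and the panel used.
    """
    ti = gm.strain_index(target_strain)
    target = gm.calls[:, ti].copy()
    pre_missing = float((target == MISSING).mean())
    panel_names = select_reference_panel(gm, target_strain, params.k)
    panel = gm.calls[:, [gm.strain_index(s) for s in panel_names]]
    path = viterbi_decode(target, panel, params)
    fill = panel[np.arange(gm.n_variants), path.states]
    missing_mask = target == MISSING
    target[missing_mask] = fill[missing_mask]
    post_missing = float((target == MISSING).mean())
    report = {
        "strain": target_strain,
        "panel": panel_names,
        "pre_missing": pre_missing,
        "post_missing": post_missing,
        "log_score": path.log_score,
    }
    return target, report


def impute_panel(
    gm: GenotypeMatrix, params: HmmParams = HmmParams()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Impute every strain against the others; returns the imputed matrix and
    a per-strain summary with median/max residual missingness attached as
    ``summary.attrs``."""
    new_calls = gm.calls.copy()
    reports = []
    for strain in gm.strains:
        calls, rep = impute_strain(gm, strain, params)
        new_calls[:, gm.strain_index(strain)] = calls
        reports.append(rep)
    out = GenotypeMatrix(gm.variants.copy(), list(gm.strains), new_calls)
    summary = pd.DataFrame(
        [{k: r[k] for k in ("strain", "pre_missing", "post_missing")} for r in reports]
    )
    summary.attrs["median_post_missing"] = float(summary["post_missing"].median())
    summary.attrs["max_post_missing"] = float(summary["post_missing"].max())
    return out, summary


class HmmImputer(BaseEstimator, TransformerMixin):
    """scikit-learn-style transformer wrapping :func:`impute_panel`.

    ``transform`` takes and returns a :class:`GenotypeMatrix`; the per-strain
    summary of the last call is stored in ``summary_``.
    """

    def __init__(self, epsilon: float = 0.01, tau: float = 0.002, k: int = 8):
        self.epsilon = epsilon
        self.tau = tau
        self.k = k

    def fit(self, X: GenotypeMatrix, y=None):
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        params = HmmParams(epsilon=self.epsilon, tau=self.tau, k=self.k)
        out, summary = impute_panel(X, params)
        self.summary_ = summary
        return out
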