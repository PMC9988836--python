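"""Mixed-model SNP association across inbred strains.

The model is the standard GWAS linear mixed model

    y = X beta + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I),

where K is a strain kinship matrix and delta = sigma_e^2 / sigma_g^2.  Full
maximum likelihood is profiled over delta after rotating y and X by the
eigenvectors of K, so each candidate delta costs O(n) once the spectral
decomposition is in hand.  Each SNP is tested with a likelihood-ratio test
of the SNP fixed effect (chi-square, 1 df), the approach of
maximum-likelihood mixed-model association in structured strain panels.
A binary phenotype is treated as a 0/1 quantitative trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist
from sklearn.base import BaseEstimator

from .datatypes import MISSING, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "MixedModelFit",
    "AssociationResult",
    "ibs_kinship",
    "fit_mixed_model",
    "lrt_scan",
    "significance_thresholds",
    "MixedModelAssociation",
]

#: Default profile grid for delta = sigma_e^2 / sigma_g^2.
DELTA_GRID_SIZE = 100
DELTA_BOUNDS = (1e-5, 1e5)
BISECT_TOL = 1e-6  # on log10(delta)
RIDGE = 1e-6


@dataclass
class KinshipMatrix:
    """Strain-by-strain genetic similarity; entries in [0, 1], unit diagonal."""

    strains: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.strains)
        if self.K.shape != (n, n):
            raise ValueError("kinship shape inconsistent with strain list")
        if not np.allclose(self.K, self.K.T):
            raise ValueError("kinship must be symmetric")
        if not np.allclose(np.diag(self.K), 1.0):
            raise ValueError("kinship diagonal must be 1")


@dataclass
class MixedModelFit:
    sigma_g2: float
    sigma_e2: float
    delta: float
    beta: np.ndarray
    loglik: float
    boundary: bool = False


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    chrom: str
    pos: int
    lrt_stat: float
    p_value: float
    n_strains_used: int
    monomorphic: bool = False


def ibs_kinship(gm: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: K_ij = fraction of SNPs non-missing in both
    strains with identical calls.  A strain pair with no jointly observed SNP
    is an error."""
    if gm.n_strains < 2 or gm.n_variants < 1:
        raise ValueError("need >= 2 strains and >= 1 SNP for kinship")
    calls = gm.calls.astype(float)
    obs = (gm.calls != MISSING).astype(float)  # (m, n)
    calls = np.where(gm.calls == MISSING, 0.0, calls)
    both = obs.T @ obs  # jointly observed counts
    if (both == 0).any():
        i, j = np.argwhere(both == 0)[0]
        raise ValueError(f"strains {gm.strains[i]!r} and {gm.strains[j]!r} share no observed SNP")
    # identical calls among jointly observed = ones-ones + zeros-zeros
    same1 = calls.T @ calls
    zeros = obs - calls  # 1 where observed call == 0
    same0 = zeros.T @ zeros
    K = (same0 + same1) / both
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(strains=list(gm.strains), K=K)


# ---------------------------------------------------------------------------
# ML machinery


def _decompose(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lam, U = np.linalg.eigh(K)
    if lam.min() < -RIDGE:
        raise ValueError(f"kinship not positive semidefinite (min eigenvalue {lam.min():.3g})")
    # clamp tiny negative eigenvalues; delta's lower bound keeps weights positive
    lam = np.maximum(lam, 0.0)
    return lam, U


def _profile_loglik(delta: float, lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    """ML log-likelihood profiled over beta and sigma_g^2 at fixed delta.

    Returns (loglik, beta, sigma_g2, residual weights) in the rotated basis.
    """
    n = yr.shape[0]
    w = lam + delta
    Xw = Xr / w[:, None]
    A = Xr.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yr)
    r = yr - Xr @ beta
    R = float(np.sum(r * r / w))
    sigma_g2 = R / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma_g2) + 1) - 0.5 * float(np.sum(np.log(w)))
    return ll, beta, sigma_g2, r, w


def _dll_dlogdelta(delta: float, lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """Derivative of the profile log-likelihood w.r.t. log(delta); the GLS
    beta is an interior optimum so only the explicit delta terms contribute."""
    n = yr.shape[0]
    _, _, _, r, w = _profile_loglik(delta, lam, yr, Xr)
    s1 = float(np.sum(r * r / w**2))
    s0 = float(np.sum(r * r / w))
    d = 0.5 * n * s1 / s0 - 0.5 * float(np.sum(1.0 / w))
    return d * delta  # chain rule d delta / d log delta


def _grid_derivs(deltas: np.ndarray, lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> np.ndarray:
    """Vectorized profile-likelihood derivative (w.r.t. log delta) over a
    grid of deltas; one batched GLS solve per grid."""
    n = yr.shape[0]
    w = lam[None, :] + deltas[:, None]  # (d, n)
    iw = 1.0 / w
    A = np.einsum("np,dn,nq->dpq", Xr, iw, Xr)
    b = np.einsum("np,dn,n->dp", Xr, iw, yr)
    beta = np.linalg.solve(A, b[..., None])[..., 0]  # (d, p)
    r = yr[None, :] - beta @ Xr.T  # (d, n)
    r2 = r * r
    s0 = np.sum(r2 * iw, axis=1)
    s1 = np.sum(r2 * iw * iw, axis=1)
    return (0.5 * n * s1 / s0 - 0.5 * np.sum(iw, axis=1)) * deltas


def fit_mixed_model(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | KinshipMatrix,
    *,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    grid_size: int = DELTA_GRID_SIZE,
    bounds: tuple[float, float] = DELTA_BOUNDS,
) -> MixedModelFit:
    """Maximum-likelihood fit of the mixed model for fixed-effect design X.

    The profile likelihood over delta is evaluated on a log-spaced grid;
    every sign change of its derivative is refined by bisection in log-delta
    to within ``BISECT_TOL``; the global maximum (including the grid
    endpoints) wins.  An optimum at a grid edge is flagged ``boundary``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix X is rank deficient")
    if eig is None:
        Km = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
        lam, U = _decompose(Km)
    else:
        lam, U = eig
    yr = U.T @ y
    Xr = U.T @ X

    log_lo, log_hi = np.log10(bounds[0]), np.log10(bounds[1])
    grid = np.logspace(log_lo, log_hi, grid_size)
    derivs = _grid_derivs(grid, lam, yr, Xr)

    candidates = [grid[0], grid[-1]]
    for i in range(grid_size - 1):
        if derivs[i] > 0 and derivs[i + 1] < 0:
            lo, hi = np.log10(grid[i]), np.log10(grid[i + 1])
            while hi - lo > BISECT_TOL:
                mid = 0.5 * (lo + hi)
                if _dll_dlogdelta(10**mid, lam, yr, Xr) > 0:
                    lo = mid
                else:
                    hi = mid
            candidates.append(10 ** (0.5 * (lo + hi)))

    best_ll, best_delta, best_beta, best_sg2 = -np.inf, None, None, None
    for d in candidates:
        ll, beta, sg2, _, _ = _profile_loglik(d, lam, yr, Xr)
        if ll > best_ll:
            best_ll, best_delta, best_beta, best_sg2 = ll, d, beta, sg2
    boundary = best_delta in (grid[0], grid[-1])
    return MixedModelFit(
        sigma_g2=best_sg2,
        sigma_e2=best_delta * best_sg2,
        delta=best_delta,
        beta=best_beta,
        loglik=best_ll,
        boundary=boundary,
    )


def significance_thresholds(n_tests: int) -> tuple[float, float]:
    """(stringent, moderate) p-value cut-offs: Bonferroni 0.05/n and a fixed
    moderate 0.05."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 0.05 / n_tests, 0.05


# ---------------------------------------------------------------------------
# scan


class MixedModelAssociation(BaseEstimator):
    """Per-SNP mixed-model likelihood-ratio association scan.

    scikit-learn-style estimator: ``fit(genotypes, phenotype)`` runs the scan
    and stores results in ``results_``.

    Parameters
    ----------
    kinship : KinshipMatrix or None
        Random-effect covariance.  None estimates identity-by-state kinship
        from the scanned genotypes.
    drop_missing : bool
        If True (pre-imputation mode), strains missing a SNP are dropped for
        that SNP only and the null model is refitted on the same subset.
        If False, any missing call is an error (post-imputation mode).
    grid_size, bounds : delta-profile grid settings.
    """

    def __init__(
        self,
        kinship: KinshipMatrix | None = None,
        drop_missing: bool = True,
        grid_size: int = DELTA_GRID_SIZE,
        bounds: tuple[float, float] = DELTA_BOUNDS,
    ):
        self.kinship = kinship
        self.drop_missing = drop_missing
        self.grid_size = grid_size
        self.bounds = bounds

    def fit(self, genotypes: GenotypeMatrix, phenotype: np.ndarray):
        y = np.asarray(phenotype, dtype=float).ravel()
        if y.shape[0] != genotypes.n_strains:
            raise ValueError("phenotype length must equal the number of strains")
        kin = self.kinship if self.kinship is not None else ibs_kinship(genotypes)
        if kin.strains != genotypes.strains:
            raise ValueError("kinship strain order must match the genotype matrix")
        K = kin.K
        n = genotypes.n_strains

        full_eig = _decompose(K)
        null_cache: dict[bytes, tuple[float, tuple]] = {}

        def null_fit(mask: np.ndarray) -> float:
            key = mask.tobytes()
            if key not in null_cache:
                eig = full_eig if mask.all() else _decompose(K[np.ix_(mask, mask)])
                f = fit_mixed_model(
                    y[mask],
                    np.ones((int(mask.sum()), 1)),
                    K=None,
                    eig=eig,
                    grid_size=self.grid_size,
                    bounds=self.bounds,
                )
                null_cache[key] = (f.loglik, eig)
            return null_cache[key]

        records = []
        for i in range(genotypes.n_variants):
            snp = genotypes.calls[i]
            mask = snp != MISSING
            if not mask.all() and not self.drop_missing:
                raise ValueError(
                    f"SNP {genotypes.variants.at[i, 'snp_id']} has missing calls; "
                    "impute first or set drop_missing=True"
                )
            x = snp[mask].astype(float)
            n_used = int(mask.sum())
            v = genotypes.variants.iloc[i]
            if n_used < 3 or len(np.unique(x)) < 2:
                records.append(
                    AssociationResult(v["snp_id"], v["chrom"], int(v["pos"]), 0.0, 1.0, n_used, True)
                )
                continue
            ll0, eig = null_fit(mask)
            X1 = np.column_stack([np.ones(n_used), x])
            f1 = fit_mixed_model(
                y[mask], X1, K=None, eig=eig, grid_size=self.grid_size, bounds=self.bounds
            )
            lrt = max(0.0, 2.0 * (f1.loglik - ll0))
            p = float(_chi2_dist.sf(lrt, df=1))
            records.append(
                AssociationResult(v["snp_id"], v["chrom"], int(v["pos"]), lrt, p, n_used, False)
            )

        self.kinship_ = kin
        self.results_ = records
        stringent, moderate = significance_thresholds(max(1, sum(not r.monomorphic for r in records)))
        self.stringent_threshold_ = stringent
        self.moderate_threshold_ = moderate
        return self

    def results_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "n": r.n_strains_used,
                "lrt": r.lrt_stat,
                "p": r.p_value,
                "neglog10p": -np.log10(max(r.p_value, 1e-300)),
                "monomorphic": r.monomorphic,
            }
            for r in self.results_
        ]
        return pd.DataFrame(rows)


def lrt_scan(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    kinship: KinshipMatrix | None = None,
    **kwargs,
) -> list[AssociationResult]:
    """Functional wrapper over :class:`MixedModelAssociation`."""
    est = MixedModelAssociation(kinship=kinship, **kwargs)
    est.fit(genotypes, phenotype)
    return est.results_
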