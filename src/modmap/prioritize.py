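"""Network-based candidate gene prioritization (guilt by association).

Trait-term gene sets are clustered into modules of bounded size on their
network connectivity profiles.  Each module trains an ensemble of 100 linear
SVMs, each classifying module genes from an independent balanced sample of
genes outside the parent set, using the gene-to-module connectivity weights
as features and 10-fold cross-validation.  Out-of-fold decision scores of
the sampled negatives form an empirical null; a candidate gene's score (the
mean decision value over the ensemble) is converted to a false-positive
rate against that null, and its final FPR is the minimum over all modules
of all trait terms (its maximum functional enrichment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.svm import SVC

from .datatypes import FunctionalNetwork, GeneSetCollection

__all__ = [
    "FunctionalModule",
    "ModuleClassifierEnsemble",
    "FunctionalScore",
    "cluster_gene_set",
    "tune_cost",
    "train_ensemble",
    "score_candidates",
    "FunctionalPrioritizer",
]

MAX_MODULE_SIZE = 400
MIN_MODULE_SIZE = 5
N_SVMS = 100
CV_FOLDS = 10
N_COSTS = 8
COST_ROUNDS = 3
COST_LOG_BOUNDS = (-3.0, 3.0)


@dataclass
class FunctionalModule:
    parent_set: str
    genes: list[str]

    @property
    def name(self) -> str:
        return f"{self.parent_set}"

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class ModuleClassifierEnsemble:
    module: FunctionalModule
    svms: list[SVC]
    costs: list[float]
    null_scores: np.ndarray  # out-of-fold decision scores of all sampled negatives
    cv_auroc: float

    def score_gene_features(self, features: np.ndarray) -> float:
        """Mean decision value of the ensemble for one gene's feature row."""
        x = features.reshape(1, -1)
        return float(np.mean([clf.decision_function(x)[0] for clf in self.svms]))


@dataclass(frozen=True)
class FunctionalScore:
    gene_id: str
    best_module: str
    score: float
    fpr: float

    @property
    def neglog10_fpr(self) -> float:
        return -np.log10(self.fpr)


# ---------------------------------------------------------------------------
# module clustering


def cluster_gene_set(
    genes: list[str],
    network: FunctionalNetwork,
    parent_set: str = "set",
    max_size: int = MAX_MODULE_SIZE,
    min_size: int = MIN_MODULE_SIZE,
) -> list[FunctionalModule]:
    """Cluster a trait-term gene set into modules each smaller than
    ``max_size``.

    Average-linkage hierarchical clustering on the correlation distance
    between the set genes' full network connectivity profiles; the tree is
    cut at the shallowest level (fewest clusters) at which every cluster is
    below ``max_size``, then clusters smaller than ``min_size`` are merged
    into their nearest sibling by mean inter-cluster distance.
    """
    if max_size <= min_size:
        raise ValueError(f"max_size={max_size} incompatible with minimum module size {min_size}")
    present = [g for g in genes if g in network]
    missing = [g for g in genes if g not in network]
    if not present:
        raise ValueError(f"gene set {parent_set!r} entirely absent from network: {missing}")
    if len(present) < max_size:
        return [FunctionalModule(parent_set=parent_set, genes=list(present))]

    profiles = network.connectivity(present, network.gene_ids)
    dist = pdist(profiles, metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)  # constant profiles -> maximal distance
    tree = linkage(dist, method="average")
    for n_clusters in range(1, len(present) + 1):
        assign = fcluster(tree, t=n_clusters, criterion="maxclust")
        sizes = np.bincount(assign)[1:]
        if sizes.max() < max_size:
            break

    # merge undersized clusters into the nearest sibling (mean profile distance)
    from scipy.spatial.distance import squareform

    dmat = squareform(dist)
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(assign):
        clusters.setdefault(int(c), []).append(i)
    while len(clusters) > 1:
        small = [c for c, idx in clusters.items() if len(idx) < min_size]
        if not small:
            break
        c = min(small, key=lambda c: len(clusters[c]))
        others = [o for o in clusters if o != c]
        nearest = min(
            others, key=lambda o: dmat[np.ix_(clusters[c], clusters[o])].mean()
        )
        clusters[nearest].extend(clusters.pop(c))
    return [
        FunctionalModule(parent_set=parent_set, genes=[present[i] for i in sorted(idx)])
        for _, idx in sorted(clusters.items())
    ]


# ---------------------------------------------------------------------------
# SVM training


def _balanced_sample(
    rng: np.random.Generator, pool: list[str], size: int
) -> list[str]:
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in sorted(idx)]


def _cv_accuracy(X: np.ndarray, y: np.ndarray, cost: float) -> float:
    clf = SVC(kernel="linear", C=cost)
    cv = StratifiedKFold(n_splits=min(CV_FOLDS, int(np.bincount(y).min())))
    return float(cross_val_score(clf, X, y, cv=cv, scoring="accuracy").mean())


def tune_cost(
    module: FunctionalModule,
    network: FunctionalNetwork,
    seed: int,
    exclude: list[str] | None = None,
    rounds: int = COST_ROUNDS,
    n_points: int = N_COSTS,
) -> list[float]:
    """Iteratively narrow the SVM cost window.

    Starting from a log-spaced window over [1e-3, 1e3], evaluate 10-fold CV
    accuracy at ``n_points`` costs on one balanced training set, re-center a
    half-width window on the argmax, and repeat for ``rounds`` rounds; the
    final ``n_points`` costs are returned.
    """
    rng = np.random.default_rng(seed)
    pool = [g for g in network.gene_ids if g not in set(module.genes) | set(exclude or [])]
    negatives = _balanced_sample(rng, pool, module.size)
    X = network.connectivity(module.genes + negatives, module.genes)
    y = np.r_[np.ones(module.size, dtype=int), np.zeros(module.size, dtype=int)]

    lo, hi = COST_LOG_BOUNDS
    center, half_width = (lo + hi) / 2.0, (hi - lo) / 2.0
    costs = np.logspace(center - half_width, center + half_width, n_points)
    for _ in range(rounds):
        acc = [_cv_accuracy(X, y, c) for c in costs]
        best = float(np.log10(costs[int(np.argmax(acc))]))
        half_width /= 2.0
        costs = np.logspace(best - half_width, best + half_width, n_points)
    return [float(c) for c in costs]


def train_ensemble(
    module: FunctionalModule,
    network: FunctionalNetwork,
    costs: list[float],
    seed: int,
    exclude: list[str] | None = None,
    n_svms: int = N_SVMS,
) -> ModuleClassifierEnsemble:
    """Train the 100-SVM ensemble for one module.

    Each SVM draws an independent balanced negative sample from outside the
    parent set (``exclude`` = the rest of the parent set), is assigned a cost
    from the tuned series (cycled), and is fitted on the full balanced set
    after its out-of-fold decision scores are recorded via 10-fold CV; the
    negatives' out-of-fold scores accumulate into the null distribution.
    """
    if len(network.gene_ids) < 2 * module.size:
        raise ValueError("network must contain at least twice the module size")
    rng = np.random.default_rng(seed)
    excluded = set(module.genes) | set(exclude or [])
    pool = [g for g in network.gene_ids if g not in excluded]
    X_pos = network.connectivity(module.genes, module.genes)
    y = np.r_[np.ones(module.size, dtype=int), np.zeros(module.size, dtype=int)]

    svms, used_costs, null_scores = [], [], []
    oof_pos, oof_neg = [], []
    for i in range(n_svms):
        negatives = _balanced_sample(rng, pool, module.size)
        X = np.vstack([X_pos, network.connectivity(negatives, module.genes)])
        cost = costs[i % len(costs)]
        clf = SVC(kernel="linear", C=cost)
        cv = StratifiedKFold(n_splits=min(CV_FOLDS, module.size))
        oof = cross_val_predict(clf, X, y, cv=cv, method="decision_function")
        null_scores.append(oof[module.size :])
        oof_pos.append(oof[: module.size])
        oof_neg.append(oof[module.size :])
        clf.fit(X, y)
        svms.append(clf)
        used_costs.append(cost)

    pos, neg = np.concatenate(oof_pos), np.concatenate(oof_neg)
    # held-out AUROC = P(pos score > neg score), computed by rank comparison
    from scipy.stats import mannwhitneyu

    auroc = float(mannwhitneyu(pos, neg, alternative="greater").statistic / (len(pos) * len(neg)))
    return ModuleClassifierEnsemble(
        module=module,
        svms=svms,
        costs=used_costs,
        null_scores=np.concatenate(null_scores),
        cv_auroc=auroc,
    )


# ---------------------------------------------------------------------------
# candidate scoring


def empirical_fpr(score: float, null_scores: np.ndarray) -> float:
    """Fraction of null scores >= score, floored at 1/(n_null + 1)."""
    n = len(null_scores)
    return max(float((null_scores >= score).sum()) / n, 1.0 / (n + 1))


def score_candidates(
    ensembles: list[ModuleClassifierEnsemble],
    network: FunctionalNetwork,
    candidates: list[str],
) -> list[FunctionalScore]:
    """Score positional candidates against every module ensemble and keep,
    per gene, the module giving the smallest FPR (ties to the first module).
    Candidates absent from the network get FPR 1 with a warning."""
    results = []
    for gene in candidates:
        if gene not in network:
            warnings.warn(f"candidate {gene!r} absent from network; FPR = 1", stacklevel=2)
            results.append(FunctionalScore(gene_id=gene, best_module="", score=np.nan, fpr=1.0))
            continue
        best = None
        for ens in ensembles:
            feats = network.connectivity([gene], ens.module.genes)[0]
            s = ens.score_gene_features(feats)
            fpr = empirical_fpr(s, ens.null_scores)
            if best is None or fpr < best.fpr:
                best = FunctionalScore(gene_id=gene, best_module=ens.module.name, score=s, fpr=fpr)
        results.append(best)
    return results


class FunctionalPrioritizer(BaseEstimator):
    """End-to-end prioritizer: cluster trait-term gene sets, tune costs,
    train the per-module SVM ensembles (``fit``), then convert candidate
    genes' ensemble scores to FPRs (``score_candidates``)."""

    def __init__(
        self,
        max_module_size: int = MAX_MODULE_SIZE,
        n_svms: int = N_SVMS,
        cost_rounds: int = COST_ROUNDS,
        seed: int = 0,
    ):
        self.max_module_size = max_module_size
        self.n_svms = n_svms
        self.cost_rounds = cost_rounds
        self.seed = seed

    def fit(self, gene_sets: GeneSetCollection, network: FunctionalNetwork):
        self.network_ = network
        self.modules_ = []
        self.ensembles_ = []
        rng = np.random.default_rng(self.seed)
        for name in gene_sets:
            genes = gene_sets[name]
            modules = cluster_gene_set(
                genes, network, parent_set=name, max_size=self.max_module_size
            )
            for mi, module in enumerate(modules):
                module = FunctionalModule(
                    parent_set=f"{name}/{mi + 1}" if len(modules) > 1 else name,
                    genes=module.genes,
                )
                rest_of_set = [g for g in genes if g not in set(module.genes)]
                sub_seed = int(rng.integers(2**31 - 1))
                costs = tune_cost(
                    module, network, seed=sub_seed, exclude=rest_of_set, rounds=self.cost_rounds
                )
                ens = train_ensemble(
                    module,
                    network,
                    costs,
                    seed=sub_seed + 1,
                    exclude=rest_of_set,
                    n_svms=self.n_svms,
                )
                self.modules_.append(module)
                self.ensembles_.append(ens)
        return self

    def score_candidates(self, candidates: list[str]) -> list[FunctionalScore]:
        return score_candidates(self.ensembles_, self.network_, candidates)
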