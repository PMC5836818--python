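"""Monte Carlo label-permutation significance of a gene set's testing AUC.

Three strategies: permute class labels only in the training cohort (retraining
the classifier each time), only in the testing cohort (the original classifier
is reused), or in both independently.  Permutations shuffle the existing
labels, so class counts are preserved and all permutations are equiprobable.
Each strategy's p-value is the conservative Monte Carlo estimate
``(r + 1) / (n + 1)`` where ``r`` counts permuted testing AUCs at least as
large as the observed one (ties count against the observed value); the
reported p is the largest — most conservative — of the strategy p-values.

Filtration is not reapplied inside permutations: the permuted testing AUC is
computed for every permutation, so the null distribution is that of the fixed
train->test procedure, not of the subset-selection cascade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import solve_svm
from .evaluation import auc_from_scores
from .metaset import MetaSet
from .subsets import SearchConfig, _train_on

__all__ = ["PermutationResult", "estimate_p", "permutation_test", "STRATEGIES"]

STRATEGIES = ("train_only", "test_only", "both")


@dataclass
class PermutationResult:
    n_permutations: int
    strategy_p: dict[str, float]
    reported_p: float
    seed: int
    observed_auc: float
    n_degenerate_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "strategy_p": dict(self.strategy_p),
            "reported_p": self.reported_p,
            "seed": self.seed,
            "observed_auc": self.observed_auc,
            "n_degenerate_redraws": self.n_degenerate_redraws,
        }


def estimate_p(observed: float, permuted: Sequence[float]) -> float:
    """Conservative Monte Carlo p: ``(#{permuted >= observed} + 1) / (n + 1)``."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("permuted values must be non-empty")
    r = int((permuted >= observed).sum())
    return (r + 1) / (permuted.size + 1)


def _permute_labels(rng: np.random.Generator, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Shuffle ±1 labels; redraw (counting) in the degenerate single-class case.

    Shuffling preserves class counts, so a redraw can only trigger if the
    original labels were single-class — guarded upstream — but the check keeps
    the contract explicit.
    """
    redraws = 0
    while True:
        perm = rng.permutation(y)
        if np.unique(perm).size >= 2:
            return perm, redraws
        redraws += 1


def permutation_test(
    genes: Sequence[str],
    meta: MetaSet,
    n: int = 10_000,
    seed: int = 0,
    strategies: Sequence[str] = STRATEGIES,
    config: SearchConfig = SearchConfig(),
) -> PermutationResult:
    """Permutation significance of the observed testing AUC for one gene set.

    Strategies touching the training labels retrain the classifier inside each
    permutation; feature standardization depends only on the training features
    and is therefore shared.  Results are reproducible bit-for-bit from
    ``seed`` regardless of which strategies are requested.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = [s for s in strategies if s not in STRATEGIES]
    if unknown:
        raise ValueError(f"unknown strategies: {unknown}")
    genes = tuple(sorted(genes))

    clf = _train_on(meta, genes, config.cost)
    x_train = meta.features(meta.training, genes)
    y_train = meta.class_labels(meta.training)
    x_test = meta.features(meta.testing, genes)
    y_test = meta.class_labels(meta.testing) > 0
    test_scores = clf.scores_array(x_test)
    observed = auc_from_scores(test_scores, y_test)
    # standardization depends only on training features, so it is shared by
    # every permutation; pre-transform both cohorts once
    z_train = (x_train - clf.center) / clf.scale
    z_test = (x_test - clf.center) / clf.scale

    strategy_p: dict[str, float] = {}
    total_redraws = 0
    for strat in strategies:
        # independent, strategy-keyed stream: results do not depend on which
        # other strategies were requested
        rng = np.random.default_rng([seed, STRATEGIES.index(strat)])
        permuted = np.empty(n)
        for i in range(n):
            if strat == "test_only":
                y_perm, rd = _permute_labels(rng, y_test)
                permuted[i] = auc_from_scores(test_scores, y_perm)
                total_redraws += rd
                continue
            ytr, rd = _permute_labels(rng, y_train)
            total_redraws += rd
            w, b = solve_svm(z_train, ytr, config.cost)
            scores = z_test @ w + b
            if strat == "both":
                yte, rd = _permute_labels(rng, y_test)
                total_redraws += rd
                permuted[i] = auc_from_scores(scores, yte)
            else:  # train_only
                permuted[i] = auc_from_scores(scores, y_test)
        strategy_p[strat] = estimate_p(observed, permuted)

    return PermutationResult(
        n_permutations=n,
        strategy_p=strategy_p,
        reported_p=max(strategy_p.values()),
        seed=seed,
        observed_auc=float(observed),
        n_degenerate_redraws=total_redraws,
    )
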