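"""Simulation studies over the synthetic meta-set generator.

These are the package's built-in verification experiments: oracle agreement
for the AUC estimator, type-I error of the log-rank test, calibration of the
permutation p-values under the null generative model, and recovery of the
planted signature under the strong preset.  The analysis drivers and the
acceptance checks both run them; every study is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cohorts import KmRecord
from .evaluation import auc_from_scores, log_rank
from .permutation import STRATEGIES, permutation_test
from .subsets import SearchConfig, evaluate_subset, run_search
from .synthetic import generate_meta_set, presets

__all__ = [
    "auc_oracle_agreement",
    "logrank_null_rejection",
    "permutation_calibration",
    "signature_recovery",
    "null_survivor_aucs",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def auc_oracle_agreement(n_fixtures: int = 500, seed: int = 0) -> dict:
    """Compare the midrank AUC against exhaustive pair counting.

    Fixtures are small (n <= 30) score/label sets with deliberately many tied
    scores.  Returns the number of exact agreements and the largest absolute
    discrepancy.
    """
    rng = np.random.default_rng(seed)
    n_equal = 0
    max_diff = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(4, 31))
        # coarse grid of score values forces ties
        scores = rng.integers(0, 6, size=n).astype(float) / 2.0
        y = rng.random(n) < rng.uniform(0.2, 0.8)
        if y.all() or not y.any():
            y[0] = True
            y[-1] = False
        auc = auc_from_scores(scores, y)
        pos, neg = scores[y], scores[~y]
        wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
            pos[:, None] == neg[None, :]
        ).sum()
        oracle = wins / (pos.size * neg.size)
        diff = abs(auc - oracle)
        max_diff = max(max_diff, diff)
        n_equal += diff < 1e-12
    return {"n_fixtures": n_fixtures, "n_equal": int(n_equal),
            "max_abs_diff": float(max_diff)}


def logrank_null_rejection(
    n_reps: int = 2000, n_per_group: int = 60, censor_frac: float = 0.3,
    alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Type-I error of the two-sided log-rank test.

    Both groups are drawn from one exponential survival law with independent
    exponential censoring tuned to the requested censoring fraction.
    """
    rng = np.random.default_rng(seed)
    scale = 50.0
    censor_scale = scale * (1 - censor_frac) / censor_frac
    rejections = 0
    for _ in range(n_reps):
        groups = []
        for g in range(2):
            t = rng.exponential(scale, n_per_group)
            c = rng.exponential(censor_scale, n_per_group)
            obs = np.minimum(t, c)
            ev = t <= c
            groups.append(
                [KmRecord(f"g{g}-{j}", bool(ev[j]), float(obs[j]))
                 for j in range(n_per_group)]
            )
        if log_rank(groups[0], groups[1]).p_two_tailed <= alpha:
            rejections += 1
    return {"n_reps": n_reps, "alpha": alpha,
            "rejection_rate": rejections / n_reps}


def permutation_calibration(
    n_reps: int = 500, n_perms: int = 200, genes=("FAM01", "FAM02"),
    seed: int = 0,
) -> dict:
    """Distribution of permutation p-values under the null generative model.

    Each replicate draws a fresh null meta-set, runs the three-strategy
    permutation test on the given gene pair, and records the strategy
    p-values.  Under the null they should be uniform; the summary reports a
    Kolmogorov-Smirnov uniformity p and the fraction at or below 0.05 per
    strategy, plus whether the conservative-maximum rule held on every run.
    """
    null_cfg = presets()["null"]
    meta_seeds = _child_seeds(seed, n_reps)
    perm_seeds = _child_seeds(seed + 1, n_reps)
    pvals: dict[str, list[float]] = {s: [] for s in STRATEGIES}
    max_rule_held = True
    for i in range(n_reps):
        sm = generate_meta_set(null_cfg.replace(seed=int(meta_seeds[i])))
        meta, _ = sm.build_meta_set()
        res = permutation_test(genes, meta, n=n_perms, seed=int(perm_seeds[i]))
        for s, p in res.strategy_p.items():
            pvals[s].append(p)
        max_rule_held &= res.reported_p == max(res.strategy_p.values())
    summary = {
        "n_reps": n_reps,
        "n_perms": n_perms,
        "max_rule_held": bool(max_rule_held),
        "strategies": {},
    }
    for s, ps in pvals.items():
        arr = np.asarray(ps)
        summary["strategies"][s] = {
            "ks_uniform_p": float(stats.kstest(arr, "uniform").pvalue),
            "frac_le_05": float((arr <= 0.05).mean()),
            "mean": float(arr.mean()),
        }
    return summary


def signature_recovery(n_seeds: int = 100, preset: str = "strong",
                       seed: int = 0) -> dict:
    """How often the search recovers the planted two-gene signature.

    For each seeded meta-set from the given preset, runs the pairs-only search
    over the gene family and records whether the planted pair passed
    filtration and ranked first among pairs, and whether the strongest planted
    singleton clears testing AUC 0.6.
    """
    cfg = presets()[preset]
    planted = tuple(sorted(cfg.planted_weights))
    family = tuple(cfg.family_genes())
    sc = SearchConfig(genes=family, sizes=(2,), include_full=False)
    seeds = _child_seeds(seed, n_seeds)
    top = passed = singleton = 0
    for i in range(n_seeds):
        sm = generate_meta_set(cfg.replace(seed=int(seeds[i])))
        meta, _ = sm.build_meta_set()
        evs = run_search(meta, sc)
        survivors = [e for e in evs if e.passed]
        if survivors and survivors[0].gene_set == planted:
            top += 1
        if any(e.gene_set == planted and e.passed for e in evs):
            passed += 1
        best_gene = max(cfg.planted_weights, key=cfg.planted_weights.get)
        e1 = evaluate_subset((best_gene,), meta, sc)
        if e1.passed and e1.auc_test is not None and e1.auc_test > 0.6:
            singleton += 1
    return {
        "n_seeds": n_seeds,
        "planted_pair": list(planted),
        "top_ranked_rate": top / n_seeds,
        "pass_rate": passed / n_seeds,
        "singleton_auc_above_06_rate": singleton / n_seeds,
    }


def null_survivor_aucs(n_seeds: int = 300, seed: int = 0) -> dict:
    """Testing AUCs of subsets that survive filtration on null meta-sets.

    Because the testing cohort is independent of the selection, the survivor
    AUC distribution should center at 0.5 regardless of the selection applied
    upstream.
    """
    cfg = presets()["null"]
    family = tuple(cfg.family_genes())
    sc = SearchConfig(genes=family, sizes=(2,), include_full=False)
    seeds = _child_seeds(seed, n_seeds)
    aucs: list[float] = []
    for i in range(n_seeds):
        sm = generate_meta_set(cfg.replace(seed=int(seeds[i])))
        meta, _ = sm.build_meta_set()
        aucs.extend(e.auc_test for e in run_search(meta, sc) if e.passed)
    arr = np.asarray(aucs)
    return {
        "n_seeds": n_seeds,
        "n_survivors": int(arr.size),
        "mean_test_auc": float(arr.mean()) if arr.size else None,
        "sd_test_auc": float(arr.std()) if arr.size else None,
    }
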