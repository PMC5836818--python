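"""Exhaustive gene-subset search through the train -> filter -> test cascade.

Every requested subset of the gene family is trained on the training cohort,
judged by the AUC filtration cascade on the held-out filtration cohorts, and —
only if it passes — evaluated on the testing cohort (testing AUC plus
Kaplan-Meier log-rank separation of the score-dichotomized groups).  Failed
subsets are reported with their failing stage rather than dropped; the testing
cohort is never read for them.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifier import LinearClassifier, fit_svm_arrays
from .evaluation import (
    FILTER_AUC_THRESHOLD,
    TRAIN_AUC_THRESHOLD,
    FiltrationVerdict,
    apply_filtration,
    auc_from_scores,
    log_rank,
)
from .metaset import MetaSet

__all__ = ["SearchConfig", "SubsetEvaluation", "enumerate_subsets",
           "evaluate_subset", "run_search", "report_frame"]


@dataclass(frozen=True)
class SearchConfig:
    genes: tuple[str, ...] | None = None  # gene family; None = every meta-set gene
    sizes: tuple[int, ...] = (1, 2, 3)
    include_full: bool = True
    cost: float = 1.0
    train_threshold: float = TRAIN_AUC_THRESHOLD
    filter_threshold: float = FILTER_AUC_THRESHOLD
    km_threshold: float = 0.0  # decision-score cut for the two KM groups


@dataclass
class SubsetEvaluation:
    gene_set: tuple[str, ...]
    classifier: LinearClassifier
    verdict: FiltrationVerdict
    auc_test: float | None = None  # present iff verdict.passed
    km_p: float | None = None
    km_statistic: float | None = None

    @property
    def passed(self) -> bool:
        return self.verdict.passed


def enumerate_subsets(
    genes: Sequence[str], sizes: Iterable[int], include_full: bool = False
) -> list[tuple[str, ...]]:
    """All gene combinations of the requested sizes, in deterministic
    lexicographic order, plus optionally the full family."""
    genes = sorted(genes)
    sizes = sorted(set(int(s) for s in sizes))
    for s in sizes:
        if s < 1 or s > len(genes):
            raise ValueError(f"subset size {s} outside 1..{len(genes)}")
    out: list[tuple[str, ...]] = []
    for s in sizes:
        out.extend(itertools.combinations(genes, s))
    if include_full:
        full = tuple(genes)
        if full not in out:
            out.append(full)
    return out


def _train_on(meta: MetaSet, genes: Sequence[str], cost: float) -> LinearClassifier:
    x = meta.features(meta.training, genes)
    y = meta.class_labels(meta.training)
    w, b, center, scale = fit_svm_arrays(x, y, cost=cost)
    return LinearClassifier(
        gene_ids=list(genes), weights=w, bias=b, center=center, scale=scale,
        cost=cost, training_cohort=meta.training,
    )


def _cohort_auc(meta: MetaSet, c: LinearClassifier, cohort: str) -> float:
    scores = c.scores_array(meta.features(cohort, c.gene_ids))
    return auc_from_scores(scores, meta.class_labels(cohort) > 0)


def evaluate_subset(
    genes: Sequence[str], meta: MetaSet, config: SearchConfig = SearchConfig()
) -> SubsetEvaluation:
    """Run one gene set through the full cascade.

    Testing-cohort expression and survival records are read only after the
    filtration verdict passes.
    """
    genes = tuple(sorted(genes))
    try:
        clf = _train_on(meta, genes, config.cost)
        auc_train = _cohort_auc(meta, clf, meta.training)
        auc_filters = {c: _cohort_auc(meta, clf, c) for c in meta.filtration}
    except ValueError as exc:
        raise ValueError(f"subset {genes}: {exc}") from exc
    verdict = apply_filtration(
        auc_train, auc_filters,
        train_threshold=config.train_threshold,
        filter_threshold=config.filter_threshold,
    )
    ev = SubsetEvaluation(gene_set=genes, classifier=clf, verdict=verdict)
    if not verdict.passed:
        return ev
    ev.auc_test = _cohort_auc(meta, clf, meta.testing)
    # KM separation on the complete testing cohort (late events and short
    # follow-up included), dichotomized at the decision boundary.
    km = meta.km_records(meta.testing)
    km_samples = [r.sample_id for r in km]
    scores = clf.scores_array(
        meta.features(meta.testing, genes, samples=km_samples)
    )
    high = [r for r, s in zip(km, scores) if s > config.km_threshold]
    low = [r for r, s in zip(km, scores) if s <= config.km_threshold]
    if high and low:
        lr = log_rank(high, low)
        ev.km_p = lr.p_two_tailed
        ev.km_statistic = lr.statistic
    return ev


def run_search(
    meta: MetaSet, config: SearchConfig = SearchConfig()
) -> list[SubsetEvaluation]:
    """Evaluate every enumerated subset and rank the survivors.

    Survivors come first, sorted by descending testing AUC with ties broken by
    smaller subset then lexicographic gene order; failed subsets follow in
    enumeration order.
    """
    family = list(config.genes) if config.genes is not None else meta.gene_ids
    missing = [g for g in family if g not in set(meta.gene_ids)]
    if missing:
        raise ValueError(f"family genes absent from meta-set (filtered out?): {missing}")
    subsets = enumerate_subsets(family, config.sizes, config.include_full)
    evals = [evaluate_subset(g, meta, config) for g in subsets]
    passed = [e for e in evals if e.passed]
    failed = [e for e in evals if not e.passed]
    passed.sort(key=lambda e: (-e.auc_test, len(e.gene_set), e.gene_set))
    return passed + failed


def report_frame(evals: Sequence[SubsetEvaluation]) -> pd.DataFrame:
    """Flat report with one row per subset (TSV-ready)."""
    filter_cohorts: list[str] = []
    for e in evals:
        for c in e.verdict.auc_filters:
            if c not in filter_cohorts:
                filter_cohorts.append(c)
    rows = []
    for e in evals:
        row: dict[str, object] = {
            "gene_set": ",".join(e.gene_set),
            "n_genes": len(e.gene_set),
            "auc_train": round(e.verdict.auc_train, 6),
        }
        for c in filter_cohorts:
            row[f"auc_filter_{c}"] = round(e.verdict.auc_filters.get(c, np.nan), 6)
        row["passed"] = e.passed
        row["failing_stage"] = e.verdict.failing_stage or ""
        row["auc_test"] = np.nan if e.auc_test is None else round(e.auc_test, 6)
        row["km_p"] = np.nan if e.km_p is None else e.km_p
        row["weights_json"] = json.dumps(
            dict(zip(e.gene_set, np.round(e.classifier.weights, 6).tolist()))
        )
        rows.append(row)
    return pd.DataFrame(rows)
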