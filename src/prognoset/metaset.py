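"""A labeled multi-cohort meta-set with fixed cohort roles.

One cohort trains the classifier, one or more held-out cohorts filter it by
AUC, and a final independent cohort is used only for classifiers that survive
filtration.  All expression/label access by downstream stages goes through the
methods here, which makes the testing-cohort isolation guarantee auditable: a
wrapper that records cohort accesses can verify that failed classifiers never
touch testing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohorts import CohortLabeling, KmRecord, km_population
from .io import ExpressionMatrix

__all__ = ["MetaSet"]


@dataclass
class MetaSet:
    expression: ExpressionMatrix  # joint gene-level matrix over all cohorts
    labelings: dict[str, CohortLabeling]
    training: str
    filtration: list[str]
    testing: str

    def __post_init__(self) -> None:
        roles = [self.training, *self.filtration, self.testing]
        if len(set(roles)) != len(roles):
            raise ValueError("cohort roles must name distinct cohorts")
        if not self.filtration:
            raise ValueError("at least one filtration cohort is required")
        known = set(self.expression.cohorts)
        unknown = [c for c in roles if c not in known]
        if unknown:
            raise ValueError(f"cohorts absent from expression data: {unknown}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.gene_ids)

    def classified_samples(self, cohort: str) -> list[str]:
        lab = self.labelings[cohort]
        return sorted(lab.positives) + sorted(lab.negatives)

    def class_labels(self, cohort: str) -> np.ndarray:
        """±1 labels aligned with :meth:`classified_samples` order."""
        lab = self.labelings[cohort]
        return np.array([1] * len(lab.positives) + [-1] * len(lab.negatives))

    def features(
        self, cohort: str, genes: Sequence[str], samples: Sequence[str] | None = None
    ) -> np.ndarray:
        """Samples × genes raw expression for a cohort.

        Defaults to the classified samples in deterministic order.  This is the
        single expression access point for pipeline stages.
        """
        if samples is None:
            samples = self.classified_samples(cohort)
        else:
            allowed = set(self.expression.samples_of_cohort(cohort))
            bad = [s for s in samples if s not in allowed]
            if bad:
                raise ValueError(f"samples not in cohort {cohort}: {bad[:5]}")
        missing = [g for g in genes if g not in set(self.expression.gene_ids)]
        if missing:
            raise ValueError(f"genes absent from meta-set: {missing}")
        return self.expression.values.loc[list(genes), list(samples)].to_numpy(
            dtype=float
        ).T

    def km_records(self, cohort: str) -> list[KmRecord]:
        return km_population(self.labelings[cohort])
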