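"""Clinical-record labeling for recurrence-free survival cohorts.

Classification labels follow fixed inclusion windows, all in months:

* positive (event class): diagnosed recurrence at most 36 months after baseline;
* negative (event-free class): no recurrence and follow-up of at least 48 months;
* excluded from classification, with a reason code, everything else —
  unknown recurrence status, recurrence within the first month (likely residual
  disease rather than recurrence), recurrence after 36 months, or event-free
  follow-up shorter than 48 months.

Samples excluded only because of timing (late recurrence, short follow-up) keep
a usable survival record and re-enter the Kaplan-Meier population; first-month
and unknown-status exclusions apply everywhere.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import pandas as pd

__all__ = [
    "ClinicalRecord",
    "CohortLabeling",
    "KmRecord",
    "label_cohort",
    "km_population",
    "read_clinical",
    "write_clinical",
    "cohort_summary",
]

POSITIVE_WINDOW_MONTHS = 36.0
NEGATIVE_FOLLOWUP_MONTHS = 48.0
FIRST_MONTH = 1.0

Status = Literal["yes", "no", "unknown"]


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    recurrence_status: Status
    time_to_recurrence: float | None  # months; present iff status == "yes"
    followup_time: float  # months

    def __post_init__(self) -> None:
        if self.recurrence_status not in ("yes", "no", "unknown"):
            raise ValueError(f"{self.sample_id}: bad status {self.recurrence_status!r}")
        if self.followup_time < 0:
            raise ValueError(f"{self.sample_id}: negative follow-up time")
        if self.recurrence_status == "yes":
            if self.time_to_recurrence is None:
                raise ValueError(f"{self.sample_id}: recurrence without a time")
            if self.time_to_recurrence < 0:
                raise ValueError(f"{self.sample_id}: negative time to recurrence")
            if self.time_to_recurrence > self.followup_time:
                raise ValueError(
                    f"{self.sample_id}: time_to_recurrence exceeds followup_time"
                )


class KmRecord(NamedTuple):
    sample_id: str
    event: bool
    time: float  # months


@dataclass
class CohortLabeling:
    """Partition of a cohort into classification classes plus survival records.

    ``positives``, ``negatives`` and the keys of ``excluded`` partition the
    input samples.  ``km_records`` holds every sample with a usable survival
    time (classification-included plus late events and early-censored).
    """

    positives: list[str] = field(default_factory=list)
    negatives: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)  # sample -> reason code
    km_records: list[KmRecord] = field(default_factory=list)

    @property
    def classified(self) -> list[str]:
        return self.positives + self.negatives

    def class_of(self, sample_id: str) -> int:
        """+1 recurrence, -1 event-free; KeyError for unclassified samples."""
        if sample_id in set(self.positives):
            return 1
        if sample_id in set(self.negatives):
            return -1
        raise KeyError(sample_id)


def label_cohort(
    records: Iterable[ClinicalRecord],
    positive_window: float = POSITIVE_WINDOW_MONTHS,
    negative_followup: float = NEGATIVE_FOLLOWUP_MONTHS,
    first_month: float = FIRST_MONTH,
) -> CohortLabeling:
    """Apply the inclusion windows to one cohort's clinical records.

    Boundary semantics are closed in the patient-friendly direction:
    recurrence at exactly ``positive_window`` is a positive, follow-up of
    exactly ``negative_followup`` is a negative, and an event or censoring at
    exactly ``first_month`` is excluded.
    """
    records = list(records)
    ids = [r.sample_id for r in records]
    dup = [s for s, n in collections.Counter(ids).items() if n > 1]
    if dup:
        raise ValueError(f"duplicate sample_id(s): {sorted(dup)[:5]}")

    out = CohortLabeling()
    for r in records:
        if r.recurrence_status == "unknown":
            out.excluded[r.sample_id] = "unknown_status"
            continue
        if r.recurrence_status == "yes":
            t = float(r.time_to_recurrence)  # type: ignore[arg-type]
            if t <= first_month:
                out.excluded[r.sample_id] = "first_month"
                continue
            if t <= positive_window:
                out.positives.append(r.sample_id)
            else:
                out.excluded[r.sample_id] = "late_recurrence"
            out.km_records.append(KmRecord(r.sample_id, True, t))
        else:  # no recurrence
            f = float(r.followup_time)
            if f <= first_month:
                out.excluded[r.sample_id] = "first_month"
                continue
            if f >= negative_followup:
                out.negatives.append(r.sample_id)
            else:
                out.excluded[r.sample_id] = "short_followup"
            out.km_records.append(KmRecord(r.sample_id, False, f))
    return out


def km_population(labeling: CohortLabeling) -> list[KmRecord]:
    """All samples with a usable survival time.

    The event flag is true iff a recurrence was ever diagnosed; the time is the
    recurrence time for events and the follow-up time for censored samples.
    First-month and unknown-status exclusions never reappear here.
    """
    return list(labeling.km_records)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical TSV schema: sample_id, recurrence_status,
    time_to_recurrence_months, followup_months (empty recurrence time for
    non-events)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "recurrence_status": str})
    out = []
    for row in df.itertuples(index=False):
        t = getattr(row, "time_to_recurrence_months")
        out.append(
            ClinicalRecord(
                sample_id=str(row.sample_id),
                recurrence_status=str(row.recurrence_status),  # type: ignore[arg-type]
                time_to_recurrence=None if pd.isna(t) else float(t),
                followup_time=float(row.followup_months),
            )
        )
    return out


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    lines = ["sample_id\trecurrence_status\ttime_to_recurrence_months\tfollowup_months"]
    for r in records:
        t = "" if r.time_to_recurrence is None else f"{r.time_to_recurrence:.3f}"
        lines.append(f"{r.sample_id}\t{r.recurrence_status}\t{t}\t{r.followup_time:.3f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def cohort_summary(labelings: dict[str, CohortLabeling]) -> pd.DataFrame:
    """Per-cohort patient counts: total, event-free with long follow-up
    (negatives), recurrence within the positive window (positives), and the
    per-reason exclusion counts."""
    rows = []
    for cohort, lab in labelings.items():
        n_total = len(lab.positives) + len(lab.negatives) + len(lab.excluded)
        reasons = collections.Counter(lab.excluded.values())
        rows.append(
            {
                "cohort": cohort,
                "total": n_total,
                "no_recurrence_followup_ge_4y": len(lab.negatives),
                "recurrence_within_3y": len(lab.positives),
                "excluded_unknown_status": reasons.get("unknown_status", 0),
                "excluded_first_month": reasons.get("first_month", 0),
                "excluded_late_recurrence": reasons.get("late_recurrence", 0),
                "excluded_short_followup": reasons.get("short_followup", 0),
            }
        )
    return pd.DataFrame(rows).set_index("cohort")
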