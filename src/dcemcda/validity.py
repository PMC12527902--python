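"""Questionnaire validity screening.

Three rules decide whether a completed questionnaire enters estimation:

1. completion time of at least ``min_minutes`` (default 8);
2. the internal consistency test — the repeated choice task must receive
   the same answer as its original;
3. a respondent who meets (1) but fails (2) is still valid when the
   direct-rating (SMART) importance rankings are logically aligned with
   the importance scores (no strictly higher score carries a strictly
   worse rank).

The filter emits an auditable verdict per respondent with reason codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Questionnaire
from .synthetic_data import RespondentRecord, SurveyDataset

__all__ = [
    "ValidityRules",
    "ValidityVerdict",
    "check_consistency",
    "check_smart_alignment",
    "filter_survey",
]

TIME_FAIL = "TIME_FAIL"
CONSISTENCY_FAIL = "CONSISTENCY_FAIL"
SMART_ALIGN_PASS = "SMART_ALIGN_PASS"
SMART_ALIGN_FAIL = "SMART_ALIGN_FAIL"


@dataclass(frozen=True)
class ValidityRules:
    min_minutes: float = 8.0
    consistency_required: bool = True
    smart_alignment_fallback: bool = True

    def __post_init__(self) -> None:
        if self.min_minutes <= 0:
            raise ValueError("min_minutes must be positive")


@dataclass(frozen=True)
class ValidityVerdict:
    respondent_id: int
    valid: bool
    reasons: tuple[str, ...]
    completion_minutes: float


def check_consistency(record: RespondentRecord, questionnaire: Questionnaire) -> bool:
    """True iff the repeated task received the same answer as its original."""
    if questionnaire.consistency_pair is None:
        raise ValueError("questionnaire has no consistency pair")
    orig, dup = questionnaire.consistency_pair
    return record.choices[orig] == record.choices[dup]


def check_smart_alignment(record: RespondentRecord) -> bool:
    """True iff SMART ranks are weakly concordant with SMART scores.

    Concordance: for every attribute pair, a strictly higher score implies a
    strictly better (numerically smaller) rank; ties in score impose no
    constraint.
    """
    ranks = np.asarray(record.smart_ranks)
    scores = np.asarray(record.smart_scores, dtype=float)
    n = ranks.size
    if sorted(ranks.tolist()) != list(range(1, n + 1)):
        raise ValueError(
            f"respondent {record.respondent_id}: ranks {record.smart_ranks} are not a permutation of 1..{n}"
        )
    for i in range(n):
        for j in range(n):
            if scores[i] > scores[j] and ranks[i] >= ranks[j]:
                return False
    return True


def _verdict(record: RespondentRecord, questionnaire: Questionnaire, rules: ValidityRules) -> ValidityVerdict:
    reasons: list[str] = []
    time_ok = record.completion_time_minutes >= rules.min_minutes
    if not time_ok:
        reasons.append(TIME_FAIL)
    consistent = check_consistency(record, questionnaire) if rules.consistency_required else True
    if not consistent:
        reasons.append(CONSISTENCY_FAIL)
    passes = consistent
    if not consistent and rules.smart_alignment_fallback:
        aligned = check_smart_alignment(record)
        reasons.append(SMART_ALIGN_PASS if aligned else SMART_ALIGN_FAIL)
        passes = aligned
    valid = time_ok and passes
    return ValidityVerdict(
        respondent_id=record.respondent_id,
        valid=valid,
        reasons=tuple(reasons),
        completion_minutes=record.completion_time_minutes,
    )


def filter_survey(
    dataset: SurveyDataset, rules: ValidityRules | None = None
) -> tuple[SurveyDataset, pd.DataFrame]:
    """Apply the three validity rules; return the valid subset and an audit table.

    The audit table has one row per respondent (respondent_id, valid,
    reasons as a ';'-joined string, completion_minutes).  Verdicts depend
    only on the individual record, so the filter is idempotent.
    """
    rules = rules or ValidityRules()
    verdicts = [_verdict(r, dataset.questionnaire_for(r), rules) for r in dataset.records]
    audit = pd.DataFrame(
        {
            "respondent_id": [v.respondent_id for v in verdicts],
            "valid": [v.valid for v in verdicts],
            "reasons": [";".join(v.reasons) for v in verdicts],
            "completion_minutes": [v.completion_minutes for v in verdicts],
        }
    )
    valid_ids = {v.respondent_id for v in verdicts if v.valid}
    return dataset.subset(valid_ids), audit


def write_audit_csv(audit: pd.DataFrame, path: str | Path) -> None:
    audit.to_csv(path, index=False)
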