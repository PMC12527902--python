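"""Synthetic respondent simulation for the orphan-drug DCE.

The study's raw survey responses are not publicly deposited, so every
downstream stage is exercised on simulated surveys whose data-generating
process matches the assumed random-utility model: each respondent draws a
coefficient vector from an independent-normal mixing distribution centred
on the published part-worths, chooses among drug 1 / drug 2 / opt-out by
multinomial logit, and fills in the direct-rating (SMART) block with
scores proportional to the part-worth ranges of their own coefficients
plus rating noise.  A configurable fraction of "careless" respondents
answer uniformly at random and finish faster than the validity time
threshold, which lets the validity filter be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .design import ChoiceSet, Questionnaire
from .schema import AttributeSchema, default_orphan_drug_schema, encode_profile

__all__ = [
    "OPT_OUT",
    "PreferencePopulation",
    "RespondentRecord",
    "SurveyDataset",
    "draw_individual_coefficients",
    "choice_probabilities",
    "simulate_responses",
]

#: choice code for the opt-out alternative (drug alternatives are 1 and 2)
OPT_OUT = 0


@dataclass(frozen=True)
class PreferencePopulation:
    """Parameters of the simulated respondent population.

    Defaults centre the coefficient means on the published all-respondents
    mixed-logit estimates, with between-respondent SDs of half the absolute
    means (moderate preference heterogeneity).  Completion times are
    lognormal with a median of 12 minutes for attentive respondents and 5
    minutes (truncated below the 8-minute validity threshold) for careless
    ones.
    """

    mean_coefficients: np.ndarray = field(
        default_factory=lambda: reference.published_means("all").to_numpy()
    )
    sd_coefficients: np.ndarray = field(
        default_factory=lambda: 0.5 * np.abs(reference.published_means("all").to_numpy())
    )
    asc_opt_out: float = field(default_factory=lambda: reference.published_asc("all"))
    asc_on_opt_out: bool = True  # attach the ASC to the opt-out utility
    careless_fraction: float = 15 / 84
    lapse: float = 0.0  # probability an attentive respondent flips the repeat answer
    time_median_attentive: float = 12.0
    time_median_careless: float = 5.0
    time_sigma: float = 0.25
    smart_noise_sd: float = 8.0
    group_labels: tuple[str, str] = ("health-economics", "medical-insurance")

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sd_coefficients) < 0):
            raise ValueError("sd_coefficients must be non-negative")
        if not 0.0 <= self.careless_fraction <= 1.0:
            raise ValueError("careless_fraction must lie in [0, 1]")


@dataclass
class RespondentRecord:
    respondent_id: int
    block_id: int
    choices: list[int]  # per task position: 1, 2 or OPT_OUT
    completion_time_minutes: float
    smart_ranks: list[int]  # permutation of 1..n_attributes, 1 = most important
    smart_scores: list[float]  # importance scores in [0, 100]
    demographics: dict[str, str] = field(default_factory=dict)


@dataclass
class SurveyDataset:
    """Questionnaires plus respondent records, with generation provenance."""

    questionnaires: list[Questionnaire]
    records: list[RespondentRecord]
    schema: AttributeSchema
    seed: int | None = None
    population: PreferencePopulation | None = None

    @property
    def n_respondents(self) -> int:
        return len(self.records)

    def questionnaire_for(self, record: RespondentRecord) -> Questionnaire:
        for q in self.questionnaires:
            if q.block_id == record.block_id:
                return q
        raise KeyError(f"respondent {record.respondent_id} references unknown block {record.block_id}")

    def subset(self, respondent_ids: set[int]) -> "SurveyDataset":
        return SurveyDataset(
            questionnaires=self.questionnaires,
            records=[r for r in self.records if r.respondent_id in respondent_ids],
            schema=self.schema,
            seed=self.seed,
            population=self.population,
        )

    # -- CSV round trip ----------------------------------------------------
    def choices_frame(self) -> pd.DataFrame:
        """Long-format choice table with both alternatives' level ordinals."""
        names = self.schema.attribute_names
        short = [self.schema.attribute(nm).short_name for nm in names]
        rows = []
        for rec in self.records:
            q = self.questionnaire_for(rec)
            for pos, task in enumerate(q.tasks):
                row: dict = {
                    "respondent_id": rec.respondent_id,
                    "block_id": rec.block_id,
                    "task_position": pos,
                    "set_id": task.set_id,
                    "is_consistency_repeat": int(pos == q.consistency_pair[1]),
                    "choice": rec.choices[pos],
                }
                for alt_no, alt in enumerate(task.alternatives, start=1):
                    for nm, sh in zip(names, short):
                        row[f"alt{alt_no}_{sh}"] = alt[nm]
                rows.append(row)
        return pd.DataFrame(rows)

    def metadata_frame(self) -> pd.DataFrame:
        n_attr = len(self.schema.attributes)
        rows = []
        for rec in self.records:
            row: dict = {
                "respondent_id": rec.respondent_id,
                "block": rec.block_id,
                "completion_minutes": rec.completion_time_minutes,
            }
            for i in range(n_attr):
                row[f"rank_{i + 1}"] = rec.smart_ranks[i]
            for i in range(n_attr):
                row[f"score_{i + 1}"] = rec.smart_scores[i]
            row.update(rec.demographics)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csvs(self, choices_path: str | Path, metadata_path: str | Path) -> None:
        self.choices_frame().to_csv(choices_path, index=False)
        self.metadata_frame().to_csv(metadata_path, index=False)


def draw_individual_coefficients(
    pop: PreferencePopulation, n: int, seed: int
) -> np.ndarray:
    """Draw n respondent-level coefficient vectors, entry k ~ N(mean_k, sd_k)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mean = np.asarray(pop.mean_coefficients, dtype=float)
    sd = np.asarray(pop.sd_coefficients, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd_coefficients must be non-negative")
    rng = np.random.default_rng(seed)
    return mean + sd * rng.standard_normal((n, mean.size))


def choice_probabilities(
    task: ChoiceSet,
    coefficients: np.ndarray,
    asc_opt_out: float,
    schema: AttributeSchema,
    asc_on_opt_out: bool = True,
) -> np.ndarray:
    """MNL probabilities of (drug 1, drug 2, opt-out) for one task.

    Deterministic utilities are beta'x for the drug profiles and the ASC for
    the opt-out (or, with ``asc_on_opt_out=False``, the ASC attaches to both
    drug alternatives and the opt-out utility is zero — the two conventions
    give identical probabilities up to the ASC's sign).
    """
    beta = np.asarray(coefficients, dtype=float)
    v1 = float(beta @ encode_profile(task.alternatives[0], schema))
    v2 = float(beta @ encode_profile(task.alternatives[1], schema))
    if asc_on_opt_out:
        v = np.array([v1, v2, asc_opt_out])
    else:
        v = np.array([v1 + asc_opt_out, v2 + asc_opt_out, 0.0])
    v -= v.max()
    p = np.exp(v)
    return p / p.sum()


def _part_worth_ranges(beta: np.ndarray, schema: AttributeSchema) -> np.ndarray:
    """Per-attribute utility ranges implied by one coefficient vector.

    Categorical range: max - min over {0 (reference)} and the level
    coefficients; continuous range: |coefficient| times the numeric level
    span.  This mirrors the relative-importance computation on the
    estimated model, applied to an individual's own coefficients.
    """
    cols = schema.design_columns
    ranges = []
    for a in schema.attributes:
        if a.kind == "continuous":
            idx = cols.index(a.short_name)
            ranges.append(abs(beta[idx]) * a.numeric_span)
        else:
            vals = [0.0] + [
                beta[i] for i, c in enumerate(cols) if c.startswith(a.short_name + "_")
            ]
            ranges.append(max(vals) - min(vals))
    return np.asarray(ranges)


def simulate_responses(
    questionnaires: list[Questionnaire],
    pop: PreferencePopulation,
    n_respondents: int,
    seed: int,
    schema: AttributeSchema | None = None,
) -> SurveyDataset:
    """Simulate a full survey under the random-utility population model.

    Respondents are assigned to questionnaire blocks round-robin.  The
    number of careless respondents is round(careless_fraction * n); their
    identities are a seeded random subset.  Attentive respondents repeat
    their original answer on the consistency task with probability
    1 - lapse and receive SMART scores proportional to their own part-worth
    ranges (top attribute scaled to 100) plus truncation-free normal noise
    clipped to [0, 100]; careless respondents choose uniformly, finish
    below the time threshold, and produce random SMART blocks.
    """
    if not questionnaires:
        raise ValueError("no questionnaires supplied")
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    schema = schema or default_orphan_drug_schema()
    rng = np.random.default_rng(seed)
    betas = draw_individual_coefficients(pop, n_respondents, seed=int(rng.integers(2**31)))
    n_careless = int(round(pop.careless_fraction * n_respondents))
    careless = np.zeros(n_respondents, dtype=bool)
    careless[rng.permutation(n_respondents)[:n_careless]] = True
    n_attr = len(schema.attributes)

    records: list[RespondentRecord] = []
    for i in range(n_respondents):
        q = questionnaires[i % len(questionnaires)]
        orig_pos, dup_pos = q.consistency_pair
        choices: list[int] = []
        for pos, task in enumerate(q.tasks):
            if careless[i]:
                choices.append(int(rng.choice([1, 2, OPT_OUT])))
                continue
            if pos == dup_pos and rng.random() >= pop.lapse:
                choices.append(choices[orig_pos])
                continue
            p = choice_probabilities(task, betas[i], pop.asc_opt_out, schema, pop.asc_on_opt_out)
            choices.append(int(rng.choice([1, 2, OPT_OUT], p=p)))

        if careless[i]:
            t = float(pop.time_median_careless * np.exp(pop.time_sigma * rng.standard_normal()))
            t = min(t, 7.9)  # careless respondents finish below the validity threshold
            scores = rng.uniform(0, 100, n_attr)
            ranks = list(rng.permutation(n_attr) + 1)
        else:
            t = float(pop.time_median_attentive * np.exp(pop.time_sigma * rng.standard_normal()))
            t = max(t, 8.0)  # attentive respondents always meet the time rule
            ranges = _part_worth_ranges(betas[i], schema)
            top = ranges.max()
            base = 100.0 * ranges / top if top > 0 else np.full(n_attr, 50.0)
            scores = np.clip(base + pop.smart_noise_sd * rng.standard_normal(n_attr), 0.0, 100.0)
            # rank 1 = highest score; ties broken by attribute position
            order = np.lexsort((np.arange(n_attr), -scores))
            ranks_arr = np.empty(n_attr, dtype=int)
            ranks_arr[order] = np.arange(1, n_attr + 1)
            ranks = list(ranks_arr)
        group = pop.group_labels[i % len(pop.group_labels)]
        records.append(
            RespondentRecord(
                respondent_id=i,
                block_id=q.block_id,
                choices=choices,
                completion_time_minutes=t,
                smart_ranks=[int(r) for r in ranks],
                smart_scores=[float(s) for s in scores],
                demographics={"group": group},
            )
        )
    return SurveyDataset(
        questionnaires=list(questionnaires),
        records=records,
        schema=schema,
        seed=seed,
        population=pop,
    )
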