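"""End-to-end orchestration: design -> survey -> filter -> estimate -> weights.

A :class:`PipelineConfig` fully determines a run: every stage draws its
randomness from seeds recorded in the config, so rerunning an identical
config reproduces every output byte.  Surveys are either simulated from
the synthetic population or ingested from the documented CSV pair.
Estimation runs on all valid respondents and, when a grouping variable
is configured, independently on each subgroup.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ChoiceDesign, ChoiceSet, Questionnaire, block_design, build_questionnaire, generate_defficient_design
from .estimation import EstimationResult, ModelSpec, build_long_format, fit_conditional_logit, fit_mixed_logit
from .schema import AttributeSchema, default_orphan_drug_schema
from .synthetic_data import (
    PreferencePopulation,
    RespondentRecord,
    SurveyDataset,
    simulate_responses,
)
from .validity import ValidityRules, filter_survey
from .weights import RIWeights, SMARTWeights, compare_weighting_methods, relative_importance, smart_weights, write_weight_report, wtp_table

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "ingest_survey"]

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Malformed survey input (with row context where possible)."""


@dataclass
class PipelineConfig:
    schema_path: str | None = None
    # design stage
    n_sets: int = 30
    n_blocks: int = 3
    design_restarts: int = 2
    # survey stage: simulate unless both CSV paths are given
    choices_csv: str | None = None
    metadata_csv: str | None = None
    n_respondents: int = 84
    population: PreferencePopulation = field(default_factory=PreferencePopulation)
    # validity stage
    rules: ValidityRules = field(default_factory=ValidityRules)
    # estimation stage
    models: tuple[str, ...] = ("clogit", "mixlogit")
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    n_draws: int = 500
    group_column: str | None = "group"
    # master seed; per-stage seeds are derived deterministically from it
    seed: int = 0
    out_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        stages = ["design", "block", "questionnaire", "simulate", "estimate"]
        return int(np.random.default_rng(self.seed + 7919 * stages.index(stage)).integers(2**31))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        pop = PreferencePopulation(**{
            k: (np.asarray(v, dtype=float) if k.endswith("coefficients") else v)
            for k, v in raw.pop("population", {}).items()
        })
        rules = ValidityRules(**raw.pop("rules", {}))
        spec = ModelSpec(**raw.pop("model_spec", {}))
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(population=pop, rules=rules, model_spec=spec, **raw)


@dataclass
class ReportBundle:
    config: PipelineConfig
    schema: AttributeSchema
    design: ChoiceDesign
    questionnaires: list[Questionnaire]
    survey: SurveyDataset
    valid_survey: SurveyDataset
    audit: pd.DataFrame
    estimations: dict[str, dict[str, EstimationResult]]  # group -> model -> result
    ri: dict[str, RIWeights]
    wtp: dict[str, list]
    smart: SMARTWeights
    concordance: dict


def _load_schema(config: PipelineConfig) -> AttributeSchema:
    if config.schema_path:
        return AttributeSchema.from_json(Path(config.schema_path))
    return default_orphan_drug_schema()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage of a configured run and (optionally) write artifacts."""
    schema = _load_schema(config)
    design = generate_defficient_design(
        schema, n_sets=config.n_sets, seed=config.stage_seed("design"), n_restarts=config.design_restarts
    )
    logger.info("design: %d sets, D-error %.5f", design.n_sets, design.d_error)
    blocks = block_design(design, n_blocks=config.n_blocks, seed=config.stage_seed("block"))
    qrng = np.random.default_rng(config.stage_seed("questionnaire"))
    questionnaires = []
    for bid, block in enumerate(blocks):
        repeat_index = int(qrng.integers(max(1, len(block) - 2)))
        questionnaires.append(
            build_questionnaire(block, repeat_index, seed=int(qrng.integers(2**31)), block_id=bid)
        )

    if config.choices_csv and config.metadata_csv:
        survey = ingest_survey(config.choices_csv, config.metadata_csv, schema)
    else:
        survey = simulate_responses(
            questionnaires, config.population, config.n_respondents,
            seed=config.stage_seed("simulate"), schema=schema,
        )

    valid, audit = filter_survey(survey, config.rules)
    logger.info("validity: %d of %d respondents valid", valid.n_respondents, survey.n_respondents)

    groups: dict[str, SurveyDataset] = {"all": valid}
    if config.group_column:
        values = sorted({r.demographics.get(config.group_column, "") for r in valid.records})
        for v in values:
            if v:
                ids = {r.respondent_id for r in valid.records
                       if r.demographics.get(config.group_column) == v}
                groups[v] = valid.subset(ids)

    estimations: dict[str, dict[str, EstimationResult]] = {}
    ri: dict[str, RIWeights] = {}
    wtp: dict[str, list] = {}
    est_seed = config.stage_seed("estimate")
    for gname, gdata in groups.items():
        estimations[gname] = {}
        try:
            long = build_long_format(gdata, schema)
            if "clogit" in config.models:
                estimations[gname]["clogit"] = fit_conditional_logit(long)
            if "mixlogit" in config.models:
                estimations[gname]["mixlogit"] = fit_mixed_logit(
                    long, config.model_spec, n_draws=config.n_draws, seed=est_seed
                )
            preferred = estimations[gname].get("mixlogit") or estimations[gname]["clogit"]
            ri[gname] = relative_importance(preferred, schema)
            wtp[gname] = wtp_table(preferred, schema)
        except Exception:
            logger.exception("estimation failed for group %r; downstream stages skipped", gname)
            if gname == "all":
                raise

    smart = smart_weights(valid)
    concordance = compare_weighting_methods(ri["all"], smart)

    bundle = ReportBundle(
        config=config,
        schema=schema,
        design=design,
        questionnaires=questionnaires,
        survey=survey,
        valid_survey=valid,
        audit=audit,
        estimations=estimations,
        ri=ri,
        wtp=wtp,
        smart=smart,
        concordance=concordance,
    )
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.design.to_json(out / "design.json")
    bundle.audit.to_csv(out / "validity_audit.csv", index=False)
    bundle.survey.write_csvs(out / "choices.csv", out / "metadata.csv")
    for gname, models in bundle.estimations.items():
        safe = gname.replace("/", "_")
        for mname, result in models.items():
            result.to_json(out / f"estimation_{safe}_{mname}.json")
        if gname in bundle.ri:
            write_weight_report(
                bundle.ri[gname], bundle.wtp[gname],
                bundle.smart if gname == "all" else None,
                out, prefix=f"{safe}_",
            )
    log = {
        "seed": bundle.config.seed,
        "d_error": bundle.design.d_error,
        "n_respondents": bundle.survey.n_respondents,
        "n_valid": bundle.valid_survey.n_respondents,
        "concordance": bundle.concordance,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------


def ingest_survey(
    choices_csv: str | Path, metadata_csv: str | Path, schema: AttributeSchema
) -> SurveyDataset:
    """Read the documented CSV pair back into a :class:`SurveyDataset`.

    The choices CSV is self-contained: it carries both alternatives' level
    ordinals per task, so questionnaires are reconstructed from it.
    Malformed rows raise :class:`DataError` naming the offending
    respondent/task.
    """
    choices = pd.read_csv(choices_csv)
    meta = pd.read_csv(metadata_csv)
    names = schema.attribute_names
    short = [schema.attribute(nm).short_name for nm in names]

    dup = choices.duplicated(subset=["respondent_id", "task_position"])
    if dup.any():
        row = choices[dup].iloc[0]
        raise DataError(
            f"duplicate row for respondent {row['respondent_id']} task {row['task_position']}"
        )

    missing = set(choices["respondent_id"]) - set(meta["respondent_id"])
    if missing:
        raise DataError(f"metadata missing respondents {sorted(missing)[:5]}")

    # rebuild one questionnaire per block from any respondent of that block
    questionnaires: list[Questionnaire] = []
    for bid, bdf in choices.groupby("block_id"):
        rid = bdf["respondent_id"].iloc[0]
        rows = bdf[bdf["respondent_id"] == rid].sort_values("task_position")
        tasks = []
        for _, row in rows.iterrows():
            alts = []
            for alt_no in (1, 2):
                alts.append({nm: int(row[f"alt{alt_no}_{sh}"]) for nm, sh in zip(names, short)})
            tasks.append(ChoiceSet(alternatives=(alts[0], alts[1]), set_id=int(row["set_id"])))
        reps = rows[rows["is_consistency_repeat"] == 1]
        if len(reps) != 1:
            raise DataError(f"block {bid}: expected exactly one consistency repeat, got {len(reps)}")
        dup_pos = int(reps["task_position"].iloc[0])
        dup_set = int(reps["set_id"].iloc[0])
        originals = rows[(rows["set_id"] == dup_set) & (rows["task_position"] != dup_pos)]
        if originals.empty:
            raise DataError(f"block {bid}: consistency repeat has no original task")
        orig_pos = int(originals["task_position"].iloc[0])
        questionnaires.append(
            Questionnaire(block_id=int(bid), tasks=tasks, consistency_pair=(orig_pos, dup_pos))
        )

    n_attr = len(names)
    records = []
    meta_by_id = meta.set_index("respondent_id")
    for rid, rdf in choices.groupby("respondent_id"):
        rdf = rdf.sort_values("task_position")
        m = meta_by_id.loc[rid]
        ranks = [int(m[f"rank_{i + 1}"]) for i in range(n_attr)]
        if sorted(ranks) != list(range(1, n_attr + 1)):
            raise DataError(f"respondent {rid}: ranks {ranks} are not a permutation of 1..{n_attr}")
        demo_cols = [
            c for c in meta.columns
            if c not in {"respondent_id", "block", "completion_minutes"}
            and not c.startswith(("rank_", "score_"))
        ]
        records.append(
            RespondentRecord(
                respondent_id=int(rid),
                block_id=int(rdf["block_id"].iloc[0]),
                choices=[int(c) for c in rdf["choice"]],
                completion_time_minutes=float(m["completion_minutes"]),
                smart_ranks=ranks,
                smart_scores=[float(m[f"score_{i + 1}"]) for i in range(n_attr)],
                demographics={c: str(m[c]) for c in demo_cols},
            )
        )
    return SurveyDataset(questionnaires=questionnaires, records=records, schema=schema)
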