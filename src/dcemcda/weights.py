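"""MCDA criterion weights from choice-model coefficients and SMART ratings.

Three weighting routes are implemented:

* relative importance (RI): each attribute's share of the total
  part-worth range, RI_a = range_a / sum_c range_c, where a categorical
  attribute's range is max - min over {0 (reference)} and its level
  coefficients, and a continuous attribute's range is |coefficient| times
  its observed level span (42 in 10,000 RMB/year for the default cost
  levels 50/20/8);
* willingness to pay (WTP): the money value of moving a level off its
  reference, -beta_level / beta_cost, in 10,000 RMB/year;
* SMART: per-respondent normalized 0-100 importance scores averaged
  across respondents, reported both by mean score and by mean rank.

A concordance report (Spearman, Kendall, top-3 overlap) quantifies how
far the stated (SMART) and revealed (DCE) orderings agree.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import EstimationResult
from .schema import AttributeSchema, SchemaMismatchError
from .synthetic_data import SurveyDataset

__all__ = [
    "WTPEntry",
    "RIWeights",
    "SMARTWeights",
    "wtp_table",
    "relative_importance",
    "smart_weights",
    "compare_weighting_methods",
]

logger = logging.getLogger(__name__)


class CostCoefficientError(ZeroDivisionError):
    """WTP undefined: the cost coefficient is (numerically) zero."""


@dataclass(frozen=True)
class WTPEntry:
    attribute: str
    level: str
    wtp: float  # 10,000 RMB/year
    se: float | None = None  # delta-method, when a covariance is available


@dataclass
class RIWeights:
    """Per-attribute relative-importance weights (fractions summing to 1)."""

    weights: pd.Series  # index: attribute name; values: fractions
    ranking: list[str]  # attribute names, most important first

    @property
    def percentages(self) -> pd.Series:
        return 100.0 * self.weights


@dataclass
class SMARTWeights:
    mean_weights: pd.Series  # mean normalized score per attribute (fractions)
    mean_ranks: pd.Series  # mean stated rank (1 = most important)
    ranking_by_score: list[str]
    ranking_by_rank: list[str]

    @property
    def percentages(self) -> pd.Series:
        return 100.0 * self.mean_weights


def _attribute_ranges(means: pd.Series, schema: AttributeSchema) -> pd.Series:
    cols = list(means.index)
    ranges = {}
    for a in schema.attributes:
        if a.kind == "continuous":
            if a.short_name not in cols:
                raise SchemaMismatchError(f"missing coefficient for {a.name}")
            ranges[a.name] = abs(float(means[a.short_name])) * a.numeric_span
        else:
            level_cols = [c for c in cols if c.startswith(a.short_name + "_")]
            if len(level_cols) != a.n_levels - 1:
                raise SchemaMismatchError(f"missing level coefficients for {a.name}")
            vals = [0.0] + [float(means[c]) for c in level_cols]
            ranges[a.name] = max(vals) - min(vals)
    return pd.Series(ranges)


def relative_importance(result: EstimationResult, schema: AttributeSchema) -> RIWeights:
    """Attribute weights as shares of the total part-worth range.

    The reference level enters each categorical range as 0, so an
    attribute whose largest coefficient belongs to a middle level (or
    whose levels are all negative) still contributes its full span.
    Weights are invariant to a common rescaling of all coefficients.
    """
    ranges = _attribute_ranges(result.means, schema)
    total = float(ranges.sum())
    if total <= 0:
        raise ValueError("all attribute ranges are zero; weights undefined")
    weights = ranges / total
    ranking = list(weights.sort_values(ascending=False).index)
    return RIWeights(weights=weights, ranking=ranking)


def wtp_table(result: EstimationResult, schema: AttributeSchema) -> list[WTPEntry]:
    """Willingness to pay, -beta / beta_cost, per non-reference level.

    Units follow the cost attribute's numeric levels (10,000 RMB/year in
    the default schema).  Delta-method standard errors are attached when
    the result carries a coefficient covariance.
    """
    cost_attr = next((a for a in schema.attributes if a.kind == "continuous"), None)
    if cost_attr is None:
        raise SchemaMismatchError("schema has no continuous cost attribute")
    cost_col = cost_attr.short_name
    beta_cost = float(result.means[cost_col])
    if abs(beta_cost) < 1e-8:
        raise CostCoefficientError("cost coefficient is numerically zero; WTP undefined")

    cov = result.cov
    names = result.param_names or []
    entries: list[WTPEntry] = []
    for a in schema.attributes:
        if a.kind == "continuous":
            continue
        for lv in a.levels:
            if lv.ordinal == a.reference_ordinal:
                continue
            col = f"{a.short_name}_{lv.ordinal}"
            beta = float(result.means[col])
            wtp = -beta / beta_cost
            se = None
            if cov is not None and col in names and cost_col in names:
                bi, ci = names.index(col), names.index(cost_col)
                var = (
                    cov[bi, bi] / beta_cost**2
                    + beta**2 * cov[ci, ci] / beta_cost**4
                    - 2 * beta * cov[bi, ci] / beta_cost**3
                )
                se = float(np.sqrt(var)) if var > 0 else None
            entries.append(WTPEntry(attribute=a.name, level=lv.label, wtp=wtp, se=se))
    return entries


def smart_weights(dataset: SurveyDataset) -> SMARTWeights:
    """Average normalized SMART scores and average stated ranks.

    Each respondent's scores are normalized to sum to one before
    averaging; respondents with an all-zero score vector are excluded from
    the score average (but still count toward mean ranks).
    """
    if not dataset.records:
        raise ValueError("no respondents with a SMART block")
    names = dataset.schema.attribute_names
    score_rows, rank_rows = [], []
    for rec in dataset.records:
        scores = np.asarray(rec.smart_scores, dtype=float)
        total = scores.sum()
        if total <= 0:
            logger.info("respondent %s has an all-zero SMART score vector; excluded from score averaging",
                        rec.respondent_id)
        else:
            score_rows.append(scores / total)
        rank_rows.append(rec.smart_ranks)
    if not score_rows:
        raise ValueError("every respondent has an all-zero SMART score vector")
    mean_weights = pd.Series(np.mean(score_rows, axis=0), index=names)
    mean_ranks = pd.Series(np.mean(rank_rows, axis=0), index=names)
    return SMARTWeights(
        mean_weights=mean_weights,
        mean_ranks=mean_ranks,
        ranking_by_score=list(mean_weights.sort_values(ascending=False).index),
        ranking_by_rank=list(mean_ranks.sort_values(ascending=True).index),
    )


def compare_weighting_methods(ri: RIWeights, smart: SMARTWeights) -> dict:
    """Rank concordance between the DCE (RI) and SMART orderings.

    Returns Spearman and Kendall correlations of the two attribute
    rankings (SMART ranked by mean score) and the size of the top-3
    overlap.
    """
    attrs = list(ri.weights.index)
    if set(attrs) != set(smart.mean_weights.index):
        raise ValueError("RI and SMART cover different attribute sets")
    ri_rank = pd.Series({a: ri.ranking.index(a) + 1 for a in attrs})
    smart_rank = pd.Series({a: smart.ranking_by_score.index(a) + 1 for a in attrs})
    rho = float(stats.spearmanr(ri_rank[attrs], smart_rank[attrs]).statistic)
    tau = float(stats.kendalltau(ri_rank[attrs], smart_rank[attrs]).statistic)
    top3 = len(set(ri.ranking[:3]) & set(smart.ranking_by_score[:3]))
    return {"spearman": rho, "kendall": tau, "top3_overlap": top3}


def write_weight_report(
    ri: RIWeights,
    wtp: list[WTPEntry],
    smart: SMARTWeights | None,
    out_dir: str | Path,
    prefix: str = "",
) -> None:
    """Emit the weight tables as CSV + a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ri_df = pd.DataFrame(
        {
            "attribute": ri.weights.index,
            "ri_percent": ri.percentages.values,
            "rank": [ri.ranking.index(a) + 1 for a in ri.weights.index],
        }
    )
    ri_df.to_csv(out / f"{prefix}relative_importance.csv", index=False)
    wtp_df = pd.DataFrame(
        [{"attribute": e.attribute, "level": e.level, "wtp_10k_rmb_year": e.wtp, "se": e.se} for e in wtp]
    )
    wtp_df.to_csv(out / f"{prefix}wtp.csv", index=False)
    summary: dict = {
        "relative_importance_percent": ri.percentages.to_dict(),
        "wtp_10k_rmb_year": {f"{e.attribute} | {e.level}": e.wtp for e in wtp},
    }
    if smart is not None:
        smart_df = pd.DataFrame(
            {
                "attribute": smart.mean_weights.index,
                "mean_score_percent": smart.percentages.values,
                "mean_rank": smart.mean_ranks.values,
            }
        )
        smart_df.to_csv(out / f"{prefix}smart.csv", index=False)
        summary["smart_percent"] = smart.percentages.to_dict()
        summary["smart_mean_rank"] = smart.mean_ranks.to_dict()
        summary["method_concordance"] = compare_weighting_methods(ri, smart)
    (out / f"{prefix}weights.json").write_text(json.dumps(summary, indent=2))
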