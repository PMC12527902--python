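import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcemcda.reference import DESIGN_COLUMNS, published_estimation_result
from dcemcda.schema import Attribute, AttributeLevel, AttributeSchema, default_orphan_drug_schema
from dcemcda.synthetic_data import RespondentRecord, SurveyDataset
from dcemcda.weights import (
    CostCoefficientError,
    RIWeights,
    compare_weighting_methods,
    relative_importance,
    smart_weights,
    wtp_table,
)

SCHEMA = default_orphan_drug_schema()

# published relative-importance table (percent), one column per group
PUBLISHED_RI = {
    "all": {
        "Improvement in health-related quality of life": 23.44,
        "Disease severity": 18.65,
        "Annual treatment cost per patient reimbursed by basic medical insurance": 17.34,
        "Drug safety": 13.10,
        "Drug efficacy": 11.92,
        "Quality of drug evidence": 10.94,
        "Unmet needs": 4.61,
    },
    "health-economics": {
        "Improvement in health-related quality of life": 23.26,
        "Disease severity": 22.57,
        "Annual treatment cost per patient reimbursed by basic medical insurance": 16.27,
        "Drug safety": 6.86,
        "Drug efficacy": 13.71,
        "Quality of drug evidence": 6.18,
        "Unmet needs": 11.16,
    },
    "medical-insurance": {
        "Improvement in health-related quality of life": 20.12,
        "Disease severity": 11.81,
        "Annual treatment cost per patient reimbursed by basic medical insurance": 18.27,
        "Drug safety": 19.48,
        "Drug efficacy": 8.72,
        "Quality of drug evidence": 13.18,
        "Unmet needs": 8.41,
    },
}


def result_with_means(means: pd.Series):
    res = published_estimation_result("all")
    res.means = means
    res.cov = None
    return res


class TestRelativeImportance:
    @pytest.mark.parametrize("group", list(PUBLISHED_RI))
    def test_reproduces_published_weights(self, group):
        ri = relative_importance(published_estimation_result(group), SCHEMA)
        for attr, expected in PUBLISHED_RI[group].items():
            assert ri.percentages[attr] == pytest.approx(expected, abs=0.15)

    def test_weights_sum_to_one(self):
        ri = relative_importance(published_estimation_result("all"), SCHEMA)
        assert ri.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        base = published_estimation_result("all").means
        ri1 = relative_importance(result_with_means(base), SCHEMA)
        ri2 = relative_importance(result_with_means(2.0 * base), SCHEMA)
        pd.testing.assert_series_equal(ri1.weights, ri2.weights)

    def test_single_attribute_schema_gets_full_weight(self):
        attr = SCHEMA.attributes[0]
        mini = AttributeSchema(attributes=(attr,))
        means = pd.Series({"severity_1": 0.4, "severity_2": 1.1})
        ri = relative_importance(result_with_means(means), mini)
        assert ri.weights.iloc[0] == pytest.approx(1.0)

    def test_reference_zero_enters_the_range(self):
        """An attribute whose coefficients are all negative still spans
        from its minimum up to the reference at 0."""
        means = published_estimation_result("medical-insurance").means
        ri = relative_importance(result_with_means(means), SCHEMA)
        # unmet needs: levels -0.577 and -1.017, range = 0 - (-1.017)
        total = ri.weights.sum()
        assert ri.percentages["Unmet needs"] == pytest.approx(8.41, abs=0.15)

    @settings(derandomize=True, max_examples=30)
    @given(
        coeffs=st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=13, max_size=13
        )
    )
    def test_normalization_for_arbitrary_coefficients(self, coeffs):
        means = pd.Series(coeffs, index=DESIGN_COLUMNS)
        ranges_nonzero = np.any(np.asarray(coeffs) != 0)
        if not ranges_nonzero:
            return
        ri = relative_importance(result_with_means(means), SCHEMA)
        assert ri.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (ri.weights >= 0).all()


class TestWTP:
    def test_published_headline_value(self):
        wtp = wtp_table(published_estimation_result("all"), SCHEMA)
        hrqol = next(
            e for e in wtp if e.level == "Significant improvement in usual activity"
        )
        assert hrqol.wtp == pytest.approx(2.204 / 0.039, rel=1e-9)
        assert hrqol.wtp == pytest.approx(56.79, rel=0.01)  # printed value

    def test_zero_level_coefficient_gives_zero_wtp(self):
        means = pd.Series(0.0, index=DESIGN_COLUMNS)
        means["cost_10k"] = -0.04
        wtp = wtp_table(result_with_means(means), SCHEMA)
        assert all(e.wtp == 0 for e in wtp)

    def test_zero_cost_coefficient_raises(self):
        means = published_estimation_result("all").means.copy()
        means["cost_10k"] = 0.0
        with pytest.raises(CostCoefficientError):
            wtp_table(result_with_means(means), SCHEMA)

    def test_currency_unit_round_trip(self):
        """Re-expressing cost in RMB (levels x 1e4, coefficient / 1e4)
        rescales every WTP by exactly 1e4."""
        cost = SCHEMA.attributes[-1]
        rmb_cost = Attribute(
            name=cost.name,
            domain_tag=cost.domain_tag,
            kind="continuous",
            levels=tuple(
                AttributeLevel(lv.label, lv.ordinal, lv.numeric_value * 1e4) for lv in cost.levels
            ),
        )
        schema_rmb = AttributeSchema(attributes=SCHEMA.attributes[:-1] + (rmb_cost,))
        means = published_estimation_result("all").means.copy()
        means_rmb = means.copy()
        means_rmb["cost_10k"] = means["cost_10k"] / 1e4
        w1 = wtp_table(result_with_means(means), SCHEMA)
        w2 = wtp_table(result_with_means(means_rmb), schema_rmb)
        for a, b in zip(w1, w2):
            assert b.wtp == pytest.approx(a.wtp * 1e4, rel=1e-12)

    def test_delta_method_se_present_with_covariance(self, long_valid):
        from dcemcda.estimation import fit_conditional_logit

        fit = fit_conditional_logit(long_valid)
        wtp = wtp_table(fit, SCHEMA)
        assert all(e.se is not None and e.se > 0 for e in wtp)


def smart_dataset(score_rows, rank_rows=None):
    records = []
    for i, scores in enumerate(score_rows):
        scores = list(map(float, scores))
        if rank_rows is not None:
            ranks = list(rank_rows[i])
        else:
            order = np.lexsort((np.arange(7), -np.asarray(scores)))
            ranks = np.empty(7, dtype=int)
            ranks[order] = np.arange(1, 8)
            ranks = list(ranks)
        records.append(
            RespondentRecord(
                respondent_id=i,
                block_id=0,
                choices=[],
                completion_time_minutes=10.0,
                smart_ranks=[int(r) for r in ranks],
                smart_scores=scores,
            )
        )
    return SurveyDataset(questionnaires=[], records=records, schema=SCHEMA)


class TestSMART:
    def test_uniform_population_recovers_shared_weights(self):
        """Every respondent scoring proportional to the published average
        profile yields exactly that profile (it sums to 100)."""
        profile = [15.18, 13.29, 16.22, 15.94, 13.79, 12.40, 13.18]
        # attribute order in the schema: severity, unmet, efficacy, hrqol,
        # safety, evidence, cost -- matches the profile order
        ds = smart_dataset([profile] * 10)
        sw = smart_weights(ds)
        np.testing.assert_allclose(sw.percentages.to_numpy(), profile, atol=1e-9)

    def test_single_respondent_concentrated_scores(self):
        ds = smart_dataset([[100, 0, 0, 0, 0, 0, 0]])
        sw = smart_weights(ds)
        np.testing.assert_allclose(sw.mean_weights.to_numpy(), [1, 0, 0, 0, 0, 0, 0])

    def test_mean_ranks_match_hand_arithmetic(self):
        ranks = [
            [1, 2, 3, 4, 5, 6, 7],
            [2, 1, 3, 4, 5, 6, 7],
            [3, 2, 1, 4, 5, 6, 7],
        ]
        scores = [[70, 60, 50, 40, 30, 20, 10]] * 3
        ds = smart_dataset(scores, rank_rows=ranks)
        sw = smart_weights(ds)
        np.testing.assert_allclose(sw.mean_ranks.to_numpy(), [2.0, 5 / 3, 7 / 3, 4, 5, 6, 7])
        assert sw.ranking_by_rank[0] == SCHEMA.attribute_names[1]

    def test_all_zero_respondent_excluded_from_score_average(self):
        ds = smart_dataset([[0] * 7, [100, 0, 0, 0, 0, 0, 0]])
        sw = smart_weights(ds)
        np.testing.assert_allclose(sw.mean_weights.to_numpy(), [1, 0, 0, 0, 0, 0, 0])


class TestMethodConcordance:
    def ri_with_ranking(self, ordering):
        weights = pd.Series(
            np.linspace(0.3, 0.05, 7) / np.linspace(0.3, 0.05, 7).sum(), index=ordering
        )
        return RIWeights(weights=weights, ranking=list(ordering))

    def test_identical_rankings(self):
        names = SCHEMA.attribute_names
        ri = self.ri_with_ranking(names)
        profile = list(np.linspace(30, 10, 7))
        ds = smart_dataset([profile])
        sw = smart_weights(ds)
        report = compare_weighting_methods(ri, sw)
        assert report["spearman"] == pytest.approx(1.0)
        assert report["top3_overlap"] == 3

    def test_reversed_rankings(self):
        names = SCHEMA.attribute_names
        ri = self.ri_with_ranking(list(reversed(names)))
        profile = list(np.linspace(30, 10, 7))
        ds = smart_dataset([profile])
        sw = smart_weights(ds)
        report = compare_weighting_methods(ri, sw)
        assert report["spearman"] == pytest.approx(-1.0)

    def test_top3_overlap_on_disagreeing_orders(self):
        names = SCHEMA.attribute_names
        # DCE order: hrqol, severity, cost first; SMART: efficacy, hrqol, severity
        dce_order = [names[3], names[0], names[6], names[2], names[4], names[5], names[1]]
        smart_first = [names[2], names[3], names[0], names[6], names[4], names[5], names[1]]
        ri = self.ri_with_ranking(dce_order)
        profile = np.linspace(30, 10, 7)
        scores = np.empty(7)
        for pos, nm in enumerate(smart_first):
            scores[names.index(nm)] = profile[pos]
        sw = smart_weights(smart_dataset([list(scores)]))
        report = compare_weighting_methods(ri, sw)
        assert report["top3_overlap"] == 2
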