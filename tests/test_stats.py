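"""Group summaries, hypothesis-test selection, and the EU limit check."""

import math

import numpy as np
import pandas as pd
import pytest

from pcbrisk.congeners import CONGENERS, Congener
from pcbrisk.distributions import MomentSpec
from pcbrisk.errors import DataError, SchemaError
from pcbrisk.stats import (
    GroupSummary,
    check_regulatory_limit,
    compare_groups,
    summarize,
    summary_frame,
    total_ndl,
)

NAMES = [c.value for c in CONGENERS]


def _record(values, product="yogurt", brand="A", sid="s1"):
    return {"sample_id": sid, "product": product, "brand": brand,
            **dict(zip(NAMES, values))}


def _frame(rows):
    return pd.DataFrame(rows)


class TestTotal:
    def test_all_zero(self):
        rec = pd.Series(_record([0.0] * 6))
        assert total_ndl(rec) == 0.0

    def test_overall_survey_means_sum(self):
        # pooled per-congener survey means add up to the printed 15.17 total
        rec = pd.Series(_record([0.09, 0.19, 0.10, 0.48, 4.33, 9.98]))
        assert total_ndl(rec) == pytest.approx(15.17, abs=1e-9)

    def test_doogh_means_sum_within_rounding(self):
        rec = pd.Series(_record([0.06, 0.25, 0.08, 0.34, 3.33, 8.14]))
        assert total_ndl(rec) == pytest.approx(12.21, abs=0.011)

    def test_missing_congener_raises(self):
        rec = pd.Series({"PCB28": 1.0})
        with pytest.raises(SchemaError):
            total_ndl(rec)


class TestSummarize:
    def test_identical_records_collapse(self):
        df = _frame([_record([1, 1, 1, 1, 1, 1], sid=f"s{i}") for i in range(4)])
        (summary,) = summarize(df, level="overall")
        for c in CONGENERS:
            ms = summary.per_congener[c]
            assert ms.sd == 0.0 and ms.minimum == ms.maximum == ms.mean == 1.0

    def test_two_record_hand_arithmetic(self):
        df = _frame([
            _record([1, 1, 1, 1, 1, 1], sid="a"),
            _record([3, 1, 1, 1, 1, 1], sid="b"),
        ])
        (summary,) = summarize(df, level="overall")
        ms = summary.per_congener[Congener.PCB28]
        assert ms.mean == pytest.approx(2.0)
        assert ms.sd == pytest.approx(math.sqrt(2.0))

    def test_total_additivity(self, survey):
        (summary,) = summarize(survey, level="overall")
        assert summary.total.mean == pytest.approx(
            float(total_ndl(survey).mean()), rel=1e-12
        )
        per_cong_sum = sum(summary.per_congener[c].mean for c in CONGENERS)
        assert summary.total.mean == pytest.approx(per_cong_sum, rel=1e-9)

    def test_balanced_groups_aggregate_to_overall(self, survey):
        # equal group sizes: overall mean is the unweighted mean of group means
        (overall,) = summarize(survey, level="overall")
        products = summarize(survey, level="product")
        for c in CONGENERS:
            grand = np.mean([g.per_congener[c].mean for g in products])
            assert overall.per_congener[c].mean == pytest.approx(grand, rel=1e-12)

    def test_adding_larger_total_raises_max(self, survey):
        (before,) = summarize(survey, level="overall")
        spike = _record([10, 10, 10, 10, 10, 10], sid="spike")
        bigger = pd.concat([survey, _frame([spike])], ignore_index=True)
        (after,) = summarize(bigger, level="overall")
        assert after.total.maximum > before.total.maximum

    def test_small_group_skipped_with_warning(self):
        rows = [_record([1, 1, 1, 1, 1, 1], product="yogurt", sid=f"y{i}") for i in range(3)]
        rows.append(_record([2, 2, 2, 2, 2, 2], product="kashk", sid="k1"))
        with pytest.warns(UserWarning, match="kashk"):
            out = summarize(_frame(rows), level="product")
        assert [s.value for s in out] == ["yogurt"]

    def test_summary_frame_layout(self, survey):
        frame = summary_frame(summarize(survey, level="product"))
        assert list(frame.index) == NAMES + ["Total"]
        assert set(frame.columns.get_level_values("stat")) == {"min", "max", "mean", "sd"}


class TestCompareGroups:
    def test_overwhelming_shift_detected(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            rows.append(_record([rng.normal(10, 1)] * 6, product="yogurt", sid=f"y{i}"))
        for i in range(40):
            rows.append(_record([rng.normal(15, 1)] * 6, product="doogh", sid=f"d{i}"))
        res = compare_groups(_frame(rows), factor="product", congener=Congener.PCB28)
        assert res.p_value < 0.05 and res.significant
        assert res.test_name in ("t_test", "mann_whitney")

    def test_three_product_groups_return_valid_p(self, survey):
        for target in [Congener.PCB180, "total"]:
            res = compare_groups(survey, factor="product", congener=target)
            assert 0.0 <= res.p_value <= 1.0
            assert res.test_name in ("anova", "kruskal_wallis")
            assert set(res.normality_p) == {"yogurt", "doogh", "kashk"}

    def test_constant_data_rejected(self):
        rows = [_record([1, 1, 1, 1, 1, 1], product=p, sid=f"{p}{i}")
                for p in ("yogurt", "doogh") for i in range(5)]
        with pytest.raises(DataError, match="constant"):
            compare_groups(_frame(rows), factor="product", congener=Congener.PCB28)

    def test_small_groups_rejected(self):
        rows = [_record([1, 2, 3, 4, 5, 6], product=p, sid=f"{p}{i}")
                for p in ("yogurt", "doogh") for i in range(2)]
        with pytest.raises(DataError, match="< 3"):
            compare_groups(_frame(rows), factor="product")


class TestRegulatoryLimit:
    def _summary(self, total_mean):
        ms = MomentSpec(mean=1.0, sd=0.0)
        return GroupSummary(
            level="overall", value="all", n=10,
            per_congener={c: ms for c in CONGENERS},
            total=MomentSpec(mean=total_mean, sd=0.0, minimum=total_mean, maximum=total_mean),
        )

    def test_survey_mean_compliant(self):
        ok, margin = check_regulatory_limit(self._summary(15.17))
        assert ok and margin == pytest.approx(24.83)

    def test_boundary_is_non_compliant(self):
        ok, margin = check_regulatory_limit(self._summary(40.0))
        assert not ok and margin == 0.0

    def test_exceedance(self):
        ok, margin = check_regulatory_limit(self._summary(45.0))
        assert not ok and margin == pytest.approx(-5.0)
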