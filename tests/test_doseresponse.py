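"""Dose-response analysis: percent change, group summaries, trend tests,
and the assembled screen report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiomap.cohort import (
    DOFETILIDE_LIKE,
    NULL_DRUG,
    CohortDesign,
    simulate_null_metrics,
    simulate_screen,
)
from cardiomap.doseresponse import (
    add_percent_change,
    assemble_screen_report,
    build_dose_table,
    compare_groups,
    dose_trend,
    percent_change,
    summarize_groups,
)


def _null_table(seed=0, **kwargs):
    rng = np.random.default_rng(seed)
    return add_percent_change(simulate_null_metrics(rng, **kwargs))


class TestPercentChange:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (182.0, 355.0, 95.05),
            (238.0, 319.0, 34.03),
            (136.0, 188.0, 38.24),
            (82.0, 120.0, 46.34),
            (34.0, 65.0, 91.18),
        ],
    )
    def test_printed_worked_examples(self, pre, post, expected):
        assert percent_change(pre, post) == pytest.approx(expected, abs=0.01)

    def test_identity(self):
        assert percent_change(200.0, 200.0) == 0.0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            percent_change(0.0, 100.0)
        with pytest.raises(ValueError, match="positive"):
            percent_change(-5.0, 100.0)

    @settings(derandomize=True, max_examples=30)
    @given(pre=st.floats(1.0, 1e4))
    def test_roundtrip_identity_only_at_zero(self, pre):
        """(1+p₁/100)(1+p₂/100)=1 for the forward/backward pair exactly
        when the change is zero."""
        post = pre
        p1 = percent_change(pre, post)
        p2 = percent_change(post, pre)
        assert (1 + p1 / 100) * (1 + p2 / 100) == pytest.approx(1.0)
        assert p1 == 0.0


class TestTableConstruction:
    def _rows(self):
        rows = []
        for well, grp in (("a1", "atrial"), ("a2", "atrial")):
            for dose, val in ((0.0, 100.0), (1.0, 120.0)):
                rows.append(
                    {"well": well, "group": grp, "dose": dose,
                     "metric": "apd80", "value": val}
                )
        return rows

    def test_valid_table_roundtrips(self):
        table = build_dose_table(self._rows())
        assert len(table) == 4

    def test_missing_baseline_rejected(self):
        rows = [r for r in self._rows() if not (r["well"] == "a2" and r["dose"] == 0)]
        with pytest.raises(ValueError, match="baseline"):
            build_dose_table(rows)

    def test_duplicate_baseline_rejected(self):
        rows = self._rows() + [self._rows()[0]]
        with pytest.raises(ValueError, match="baseline"):
            build_dose_table(rows)

    def test_baseline_pct_change_is_exactly_zero(self):
        table = add_percent_change(build_dose_table(self._rows()))
        assert (table.loc[table.dose == 0, "pct_change"] == 0.0).all()
        assert table.loc[table.dose == 1.0, "pct_change"].iloc[0] == pytest.approx(20.0)


class TestSummaries:
    def test_mean_and_sem_arithmetic(self):
        """Wells {10, 20, 30}: mean 20, SEM 10/√3."""
        table = pd.DataFrame(
            {
                "well": ["w1", "w2", "w3"],
                "group": "atrial",
                "dose": 1.0,
                "metric": "apd80",
                "pct_change": [10.0, 20.0, 30.0],
            }
        )
        out = summarize_groups(table)
        assert out["mean"].iloc[0] == pytest.approx(20.0)
        assert out["sem"].iloc[0] == pytest.approx(10.0 / np.sqrt(3))
        assert out["n"].iloc[0] == 3

    def test_identical_wells_have_zero_sem(self):
        table = pd.DataFrame(
            {"well": list("abc"), "group": "g", "dose": 1.0,
             "metric": "m", "pct_change": 7.0}
        )
        assert summarize_groups(table)["sem"].iloc[0] == 0.0

    def test_single_well_sem_undefined(self):
        table = pd.DataFrame(
            {"well": ["a"], "group": "g", "dose": 1.0, "metric": "m",
             "pct_change": [5.0]}
        )
        out = summarize_groups(table)
        assert out["mean"].iloc[0] == 5.0 and np.isnan(out["sem"].iloc[0])


class TestCompareGroups:
    def test_identical_groups_give_p1(self):
        table = _null_table(seed=1)
        doubled = table.copy()
        doubled["group"] = np.where(doubled.group == "atrial", "ventricular", "atrial")
        both = pd.concat([table[table.group == "atrial"],
                          doubled[doubled.group == "ventricular"]])
        res = compare_groups(both, 1.0, "apd80")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_null_simulation_type_i_error_within_binomial_bounds(self):
        """Welch rejection rate at α=.05 over 1000 null screens."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            table = add_percent_change(simulate_null_metrics(rng))
            res = compare_groups(table, 1.0, "apd80")
            rejections += res.pvalue < 0.05
        assert 0.036 <= rejections / n_reps <= 0.065


class TestDoseTrend:
    def test_identical_dose_groups_give_f0(self):
        table = pd.DataFrame(
            [
                {"well": f"w{w}", "group": "atrial", "dose": d,
                 "metric": "apd80", "pct_change": 0.0 if d == 0 else 5.0}
                for w in range(4)
                for d in (0.0, 1.0, 2.0)
            ]
        )
        # constant within dose: zero pooled variance path
        f_res, comps = dose_trend(table, "atrial", "apd80")
        assert all(np.isfinite(c.adj_pvalue) for c in comps)

    def test_missing_baseline_rejected(self):
        table = pd.DataFrame(
            [{"well": "w", "group": "g", "dose": 1.0, "metric": "m",
              "pct_change": 1.0}]
        )
        with pytest.raises(ValueError, match="baseline"):
            dose_trend(table, "g", "m")

    def test_full_procedure_type_i_error_within_binomial_bounds(self):
        """Familywise ANOVA+Dunnett false-positive rate ≈ α under the null."""
        rng = np.random.default_rng(7)
        n_reps = 1000
        fw_rejections = 0
        for _ in range(n_reps):
            table = add_percent_change(
                simulate_null_metrics(rng, design=CohortDesign(groups=("atrial",)))
            )
            _, comps = dose_trend(table, "atrial", "apd80")
            fw_rejections += any(c.adj_pvalue < 0.05 for c in comps)
        assert 0.036 <= fw_rejections / n_reps <= 0.065


@pytest.fixture(scope="module")
def screen_tables():
    design = CohortDesign(n_wells=6)
    return {
        "dofetilide_like": add_percent_change(
            simulate_screen(DOFETILIDE_LIKE, design, seed=21)
        ),
        "null_drug": add_percent_change(
            simulate_screen(NULL_DRUG, design, seed=22)
        ),
    }


class TestScreenReport:

    def test_atrial_selective_drug_shows_atrial_dominant_changes(self, screen_tables):
        report, text = assemble_screen_report(
            {"dofetilide_like": screen_tables["dofetilide_like"]}
        )
        sub = report[(report.metric == "apd80") & (report.dose > 0)]
        piv = sub.pivot(index="dose", columns="group", values="pct_mean")
        assert (piv["atrial"] > piv["ventricular"]).all()
        assert "dofetilide_like" in text

    def test_atrial_selective_stars_at_top_doses(self, screen_tables):
        report, _ = assemble_screen_report(
            {"dofetilide_like": screen_tables["dofetilide_like"]}
        )
        top = report[
            (report.metric == "apd80")
            & (report.dose == 100.0)
            & (report.group == "atrial")
        ]
        assert top.between_group_stars.iloc[0] in ("*", "**", "***")
        assert top.dunnett_stars.iloc[0] in ("*", "**", "***")

    def test_null_drug_mostly_unstarred(self, screen_tables):
        report, _ = assemble_screen_report(
            {"null_drug": screen_tables["null_drug"]}
        )
        starred = (report.dunnett_stars.isin(("*", "**", "***"))).sum()
        assert starred <= max(2, int(0.1 * len(report)))

    def test_empty_drug_set_rejected(self):
        with pytest.raises(ValueError, match="no drug tables"):
            assemble_screen_report({})

    def test_drug_without_baseline_excluded_with_note(self, screen_tables):
        broken = screen_tables["null_drug"]
        broken = broken[broken.dose != 0].drop(columns=["pct_change", "baseline_value"])
        report, text = assemble_screen_report(
            {
                "dofetilide_like": screen_tables["dofetilide_like"],
                "broken": broken,
            }
        )
        assert "broken" not in set(report.drug)
        assert "excluded" in text
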