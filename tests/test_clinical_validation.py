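"""Comorbidity rules, blanking, incidence rates, adjusted Cox contrasts."""

import numpy as np
import pandas as pd
import pytest

from cpetphen.clinical_validation import (
    blank_early_events,
    build_covariate_frame,
    cox_hr,
    define_diabetes,
    define_hypertension,
    group_compare,
    km_incidence,
)
from cpetphen.records import Participant, SurvivalRecord


def _p(**kw):
    base = dict(id="p1", sex="male", age=55.0)
    base.update(kw)
    return Participant(**base)


class TestComorbidityDefinitions:
    @pytest.mark.parametrize(
        "sbp, dbp, meds, expected",
        [
            (145, 80, False, True),
            (120, 80, False, False),
            (120, 80, True, True),
            (120, 95, False, True),
            (140, 90, False, False),  # strict inequalities
        ],
    )
    def test_hypertension_rule(self, sbp, dbp, meds, expected):
        p = _p(sbp_rest=sbp, dbp_rest=dbp, antihypertensive_meds=meds)
        assert define_hypertension(p) is expected

    @pytest.mark.parametrize(
        "glucose, meds, self_report, expected",
        [
            (7.5, False, False, True),
            (6.0, False, False, False),
            (6.0, True, False, True),
            (None, False, True, True),
            (7.0, False, False, False),  # strict threshold
        ],
    )
    def test_diabetes_rule(self, glucose, meds, self_report, expected):
        p = _p(
            fasting_glucose=glucose,
            antidiabetic_meds=meds,
            self_report_dm=self_report,
        )
        assert define_diabetes(p) is expected


class TestBlanking:
    def test_early_event_skipped_next_counted(self):
        r = SurvivalRecord(
            id="a", time_years=30 / 365.25, event=True,
            event_offsets_days=[30.0, 400.0], censor_days=2000.0,
        )
        out = blank_early_events([r])[0]
        assert out.event
        assert out.time_years == pytest.approx(400 / 365.25)
        assert out.blanked

    def test_event_after_window_counted_unchanged(self):
        r = SurvivalRecord(
            id="a", time_years=120 / 365.25, event=True,
            event_offsets_days=[120.0], censor_days=2000.0,
        )
        out = blank_early_events([r])[0]
        assert out.event
        assert out.time_years == pytest.approx(120 / 365.25)
        assert not out.blanked

    def test_only_early_events_become_censoring(self):
        r = SurvivalRecord(
            id="a", time_years=30 / 365.25, event=True,
            event_offsets_days=[30.0], censor_days=1461.0,
        )
        out = blank_early_events([r])[0]
        assert not out.event
        assert out.time_years == pytest.approx(4.0)

    def test_no_events_unchanged(self):
        r = SurvivalRecord(
            id="a", time_years=5.0, event=False, censor_days=5 * 365.25
        )
        out = blank_early_events([r])[0]
        assert not out.event
        assert out.time_years == pytest.approx(5.0)

    def test_blanking_never_increases_events(self, rng):
        records = []
        for i in range(200):
            offs = sorted(rng.uniform(0, 2000, rng.integers(0, 3)).tolist())
            records.append(
                SurvivalRecord(
                    id=str(i),
                    time_years=(offs[0] / 365.25) if offs else 5.0,
                    event=bool(offs),
                    event_offsets_days=offs,
                    censor_days=2000.0,
                )
            )
        before = sum(r.event for r in records)
        after = sum(r.event for r in blank_early_events(records))
        assert after <= before


class TestKmIncidence:
    def test_rate_arithmetic(self):
        recs = [
            SurvivalRecord(id="a", time_years=20.0, event=True),
            SurvivalRecord(id="b", time_years=20.0, event=True),
        ]
        out = km_incidence(recs, {"a": 1, "b": 1})
        assert out[1]["events"] == 2
        assert out[1]["person_years"] == pytest.approx(40.0)
        assert out[1]["rate_per_1000py"] == pytest.approx(50.0)

    def test_no_events_flat_curve(self):
        recs = [SurvivalRecord(id="a", time_years=3.0, event=False)]
        out = km_incidence(recs, {"a": 1})
        assert out[1]["rate_per_1000py"] == 0.0
        assert np.allclose(out[1]["km_survival"], 1.0)

    def test_pooled_rate_is_event_weighted_mean(self, rng):
        recs = []
        labels = {}
        for i in range(120):
            recs.append(
                SurvivalRecord(
                    id=str(i),
                    time_years=float(rng.uniform(1, 10)),
                    event=bool(rng.random() < 0.3),
                )
            )
            labels[str(i)] = int(i % 3) + 1
        by_group = km_incidence(recs, labels)
        pooled = km_incidence(recs, {k: 1 for k in labels})
        total_events = sum(v["events"] for v in by_group.values())
        total_py = sum(v["person_years"] for v in by_group.values())
        assert pooled[1]["events"] == total_events
        assert pooled[1]["person_years"] == pytest.approx(total_py)
        assert pooled[1]["rate_per_1000py"] == pytest.approx(
            1000 * total_events / total_py
        )


class TestGroupCompare:
    def test_identical_groups_unmarked(self, rng):
        x = rng.normal(size=200)
        table = pd.DataFrame(
            {"metric": np.r_[x, x]}, index=[str(i) for i in range(400)]
        )
        labels = {str(i): 1 if i < 200 else 2 for i in range(400)}
        out = group_compare(table, labels)
        assert (out["markers"] == "").all()

    def test_large_mean_shift_marked(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(3, 1, 100)  # 3 SD shift: power ~ 1
        table = pd.DataFrame(
            {"metric": np.r_[a, b]}, index=[str(i) for i in range(200)]
        )
        labels = {str(i): 1 if i < 100 else 2 for i in range(200)}
        out = group_compare(table, labels)
        row = out[(out.phenogroup == 2)].iloc[0]
        assert "*" in row["markers"]

    def test_categorical_proportion_gap_marked(self, rng):
        a = (rng.random(100) < 0.5).astype(float)
        b = (rng.random(100) < 0.1).astype(float)
        table = pd.DataFrame(
            {"flag": np.r_[a, b]}, index=[str(i) for i in range(200)]
        )
        labels = {str(i): 1 if i < 100 else 2 for i in range(200)}
        out = group_compare(table, labels)
        row = out[(out.phenogroup == 2)].iloc[0]
        assert "*" in row["markers"]
        assert row["count"] == b.sum()


def simulate_survival(
    n, hr_by_group, seed, h0=0.05, cens_lo=1.0, cens_hi=8.0, weights=None
):
    """Exponential survival with per-group hazard ratios vs baseline h0.

    ``weights`` allocates subjects across groups (default equal); a
    design weighting the contrast arms raises the event count and the
    precision of the hazard-ratio estimate.
    """
    rng = np.random.default_rng(seed)
    recs, labels = [], {}
    groups = sorted(hr_by_group)
    if weights is None:
        alloc = [groups[i % len(groups)] for i in range(n)]
    else:
        w = np.array([weights[g] for g in groups], dtype=float)
        counts = np.floor(w / w.sum() * n).astype(int)
        counts[0] += n - counts.sum()
        alloc = [g for g, c in zip(groups, counts) for _ in range(c)]
    for i, g in enumerate(alloc):
        h = h0 * hr_by_group[g]
        t = rng.exponential(1 / h)
        c = rng.uniform(cens_lo, cens_hi)
        recs.append(
            SurvivalRecord(id=str(i), time_years=min(t, c), event=bool(t < c))
        )
        labels[str(i)] = g
    return recs, labels


class TestCoxHr:
    def test_planted_hazard_recovered(self):
        recs, labels = simulate_survival(
            1000, {1: 1, 2: 1, 3: 1, 4: 1, 5: 2.0}, seed=10,
            h0=0.25, cens_lo=6.0, cens_hi=10.0,
            weights={1: 2, 2: 2, 3: 0.5, 4: 0.5, 5: 5},
        )
        out = cox_hr(recs, labels)
        assert 1.7 <= out.loc["pheno_5", "HR"] <= 2.3
        assert out.loc["pheno_5", "p"] < 0.05

    def test_null_ci_covers_one(self):
        cover = 0
        for rep in range(30):
            recs, labels = simulate_survival(
                300, {1: 1, 2: 1, 3: 1, 4: 1, 5: 1}, seed=200 + rep
            )
            out = cox_hr(recs, labels)
            lo, hi = out.loc["pheno_5", ["ci_low", "ci_high"]]
            cover += lo <= 1.0 <= hi
        assert cover >= 26  # ~95% nominal

    def test_reference_groups_have_no_indicator(self):
        recs, labels = simulate_survival(200, {g: 1 for g in range(1, 6)}, 3)
        out = cox_hr(recs, labels)
        assert set(out.index) == {"pheno_3", "pheno_4", "pheno_5"}

    def test_no_events_raises(self):
        recs = [
            SurvivalRecord(id=str(i), time_years=1.0, event=False)
            for i in range(20)
        ]
        labels = {str(i): (i % 5) + 1 for i in range(20)}
        with pytest.raises(ValueError):
            cox_hr(recs, labels)


class TestCovariateFrame:
    def test_sex_excluded_in_stratified_runs(self):
        parts = [
            _p(id="a", sbp_rest=120.0, dbp_rest=80.0, hr_rest=70.0, bmi=25.0),
            _p(id="b", sbp_rest=150.0, dbp_rest=95.0, hr_rest=80.0, bmi=30.0),
        ]
        pooled = build_covariate_frame(parts, include_sex=True)
        stratified = build_covariate_frame(parts, include_sex=False)
        assert "sex_male" in pooled.columns
        assert "sex_male" not in stratified.columns

    def test_covers_adjustment_set(self):
        parts = [_p(id="a", sbp_rest=120.0, hr_rest=70.0, bmi=25.0)]
        cov = build_covariate_frame(parts, peak_vo2={"a": 2000.0})
        for col in (
            "age", "bmi", "hypertension", "dm_or_cvd",
            "antihypertensive_meds", "sbp_rest", "hr_rest", "peak_VO2",
        ):
            assert col in cov.columns
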