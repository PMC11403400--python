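"""Clinical characterization and outcome validation of the phenogroups.

Derived comorbidity flags follow the usual clinical cutoffs
(hypertension: SBP > 140 mmHg, DBP > 90 mmHg or antihypertensive
medication; diabetes: self-report, fasting glucose > 7 mmol/L or
antidiabetic medication).  Outcome analysis counts only the first
cardiovascular event per participant after a 90-day blanking window
(early events are attributed to residual therapy), reports Kaplan–Meier
cumulative incidence and crude rates per 1,000 person-years per
phenogroup, and fits a covariate-adjusted Cox model contrasting
phenogroups 3, 4 and 5 against the merged 1+2 reference.

Survival machinery is delegated to lifelines; the bespoke content here
is the blanking rule, the merged-reference contrast design and the
rate bookkeeping.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .records import Participant, SurvivalRecord

#: marker symbols per reference group, mirroring clinical-table style
_MARKERS = ["*", "†", "‡", "&", "§"]


def define_hypertension(p: Participant) -> bool:
    """SBP > 140 and/or DBP > 90 mmHg and/or antihypertensive drugs."""
    if p.sbp_rest is None and p.dbp_rest is None and not p.antihypertensive_meds:
        raise ValueError("no blood pressure or medication information")
    return bool(
        (p.sbp_rest is not None and p.sbp_rest > 140)
        or (p.dbp_rest is not None and p.dbp_rest > 90)
        or p.antihypertensive_meds
    )


def define_diabetes(p: Participant) -> bool:
    """Self-report, fasting glucose > 7 mmol/L and/or antidiabetic drugs."""
    return bool(
        p.self_report_dm
        or (p.fasting_glucose is not None and p.fasting_glucose > 7)
        or p.antidiabetic_meds
    )


def blank_early_events(
    records: list[SurvivalRecord], blanking_days: float = 90.0
) -> list[SurvivalRecord]:
    """Discard events inside the blanking window after the CPET.

    The first event at or beyond ``blanking_days`` becomes the counted
    first event; participants whose only events fall inside the window
    are censored at their administrative censoring date.  Blanking never
    increases the event count.
    """
    out: list[SurvivalRecord] = []
    for r in records:
        qualifying = [o for o in r.event_offsets_days if o >= blanking_days]
        had_blanked = any(o < blanking_days for o in r.event_offsets_days)
        if qualifying:
            out.append(
                replace(
                    r,
                    time_years=qualifying[0] / 365.25,
                    event=True,
                    blanked=had_blanked,
                )
            )
        else:
            censor = (
                r.censor_days / 365.25
                if r.censor_days is not None
                else r.time_years
            )
            out.append(
                replace(
                    r, time_years=censor, event=False, blanked=had_blanked
                )
            )
    return out


def group_compare(
    table: pd.DataFrame, labels: dict[str, int], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-phenogroup summary of clinical metrics with significance markers.

    Continuous columns get group mean ± SD and a two-sample Z test
    against every lower-numbered group; boolean columns get counts,
    percentages and a chi-square test.  A marker symbol is appended for
    each lower group the difference is significant against (p < alpha),
    in the ``* † ‡ &`` convention (``*`` = vs group 1, and so on).
    """
    lab = pd.Series(labels, name="phenogroup")
    df = table.join(lab, how="inner")
    groups = sorted(df["phenogroup"].unique())
    rows = []
    for col in table.columns:
        is_bool = table[col].dropna().isin([0, 1, True, False]).all()
        by_group = {g: df.loc[df.phenogroup == g, col].dropna() for g in groups}
        for gi, g in enumerate(groups):
            x = by_group[g]
            if len(x) == 0:
                continue
            marks = ""
            for hi in range(gi):
                h = groups[hi]
                y = by_group[h]
                if len(y) == 0:
                    continue
                p = (
                    _chi2_p(x, y) if is_bool else _ztest_p(x, y)
                )
                if p is not None and p < alpha:
                    marks += _MARKERS[hi % len(_MARKERS)]
            if is_bool:
                n_pos = int(x.sum())
                rows.append(
                    {
                        "metric": col,
                        "phenogroup": g,
                        "n": len(x),
                        "count": n_pos,
                        "percent": 100.0 * n_pos / len(x),
                        "mean": np.nan,
                        "sd": np.nan,
                        "markers": marks,
                    }
                )
            else:
                rows.append(
                    {
                        "metric": col,
                        "phenogroup": g,
                        "n": len(x),
                        "count": np.nan,
                        "percent": np.nan,
                        "mean": float(x.mean()),
                        "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                        "markers": marks,
                    }
                )
    return pd.DataFrame(rows)


def _ztest_p(x: pd.Series, y: pd.Series) -> float | None:
    if len(x) < 2 or len(y) < 2:
        return None
    se = np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
    if se == 0:
        return None
    z = (x.mean() - y.mean()) / se
    return float(2 * stats.norm.sf(abs(z)))


def _chi2_p(x: pd.Series, y: pd.Series) -> float | None:
    tab = np.array(
        [
            [int(x.sum()), len(x) - int(x.sum())],
            [int(y.sum()), len(y) - int(y.sum())],
        ]
    )
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        return None
    return float(stats.chi2_contingency(tab).pvalue)


def km_incidence(
    records: list[SurvivalRecord], labels: dict[str, int]
) -> dict[int, dict]:
    """Events, person-years, rate per 1,000 py and KM curve per phenogroup."""
    out: dict[int, dict] = {}
    by_group: dict[int, list[SurvivalRecord]] = {}
    for r in records:
        if r.id in labels:
            by_group.setdefault(labels[r.id], []).append(r)
    for g in sorted(by_group):
        recs = by_group[g]
        times = np.array([max(r.time_years, 1e-6) for r in recs])
        events = np.array([r.event for r in recs], dtype=bool)
        py = float(times.sum())
        n_events = int(events.sum())
        kmf = KaplanMeierFitter()
        kmf.fit(times, events)
        out[g] = {
            "n": len(recs),
            "events": n_events,
            "person_years": py,
            "rate_per_1000py": 1000.0 * n_events / py if py > 0 else 0.0,
            "km_times": kmf.survival_function_.index.to_numpy(),
            "km_survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        }
    return out


def build_covariate_frame(
    participants: list[Participant],
    peak_vo2: dict[str, float] | None = None,
    include_sex: bool = True,
) -> pd.DataFrame:
    """Adjustment covariates of the Cox model, one row per participant.

    Covers age, sex (pooled model only), BMI, hypertension, history of
    diabetes and/or CV disease, antihypertensive medication, resting SBP
    and HR, and peak VO2 when summary metrics are supplied.
    """
    rows = {}
    for p in participants:
        row = {
            "age": p.age,
            "bmi": p.bmi,
            "hypertension": float(define_hypertension(p)),
            "dm_or_cvd": float(define_diabetes(p) or p.cv_disease_history),
            "antihypertensive_meds": float(p.antihypertensive_meds),
            "sbp_rest": p.sbp_rest,
            "hr_rest": p.hr_rest,
        }
        if include_sex:
            row["sex_male"] = float(p.sex == "male")
        if peak_vo2 is not None:
            row["peak_VO2"] = peak_vo2.get(p.id)
        rows[p.id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def cox_hr(
    records: list[SurvivalRecord],
    labels: dict[str, int],
    covariates: pd.DataFrame | None = None,
    reference: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Adjusted hazard ratios of each phenogroup versus the reference.

    Fits one proportional-hazards model with an indicator per
    non-reference phenogroup (reference = merged phenogroups 1+2 by
    default) plus the supplied covariate columns, complete-case.
    Returns a frame indexed by indicator with HR, 95% CI and p; raises
    a fit failure as ``ValueError`` rather than crashing deeper down.
    """
    data = {}
    groups = sorted(set(labels.values()) - set(reference))
    for r in records:
        if r.id not in labels:
            continue
        g = labels[r.id]
        row = {"duration": max(r.time_years, 1e-6), "event": float(r.event)}
        for other in groups:
            row[f"pheno_{other}"] = float(g == other)
        data[r.id] = row
    df = pd.DataFrame.from_dict(data, orient="index")
    if covariates is not None:
        df = df.join(covariates, how="inner")
    df = df.dropna()
    if df.empty or df["event"].sum() == 0:
        raise ValueError("no usable events for the Cox fit")
    # drop constant covariate columns (degenerate in a partial likelihood)
    keep = [
        c
        for c in df.columns
        if c in ("duration", "event") or df[c].nunique() > 1
    ]
    df = df[keep]
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="duration", event_col="event")
    except Exception as exc:  # convergence/separation failures
        raise ValueError(f"Cox fit failed: {exc}") from exc
    summary = cph.summary
    rows = []
    for g in groups:
        name = f"pheno_{g}"
        if name not in summary.index:
            continue
        s = summary.loc[name]
        rows.append(
            {
                "indicator": name,
                "phenogroup": g,
                "HR": float(np.exp(s["coef"])),
                "ci_low": float(np.exp(s["coef lower 95%"])),
                "ci_high": float(np.exp(s["coef upper 95%"])),
                "p": float(s["p"]),
            }
        )
    return pd.DataFrame(rows).set_index("indicator")
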