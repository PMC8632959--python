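"""Clinical scale scoring and two-group outcome analysis.

Implements the instruments and outcome definitions used in the
psychological-intervention arm of the study: Zung self-rating anxiety and
depression scales (SAS/SDS) and the Hamilton depression scale (HAMD) with
their severity bands; the HAMD reduction rate with its four-level
efficacy banding (cured / markedly effective / effective / ineffective);
treatment-compliance aggregation; and the group-comparison tests
(Pearson chi-square for count data, Welch two-sample t for scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EFFICACY_CATEGORIES",
    "COMPLIANCE_CATEGORIES",
    "classify_severity",
    "hamd_reduction_rate",
    "classify_efficacy",
    "aggregate_outcomes",
    "chi_square_2x2",
    "two_sample_t",
    "cohort_outcome_analysis",
]

EFFICACY_CATEGORIES = ("cured", "markedly_effective", "effective", "ineffective")
COMPLIANCE_CATEGORIES = ("complete", "basic", "non")

# Categories counted into each derived total.
_TOTAL_MEMBERS = {
    "total_effective": ("cured", "markedly_effective", "effective"),
    "total_compliant": ("complete", "basic"),
}


def _round2(value: float) -> float:
    """Round half-up to 2 decimals, matching clinical reporting style."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classify_severity(instrument: str, score: float) -> str:
    """Severity band of a scale score.

    SAS/SDS: below 50 none, 50-59 mild, 60-69 moderate, 70 and above
    severe. HAMD: below 8 none, 8-20 mild, above 20 up to 34 mild-to-
    moderate, above 35 severe (scores in (34, 35] fall in the published
    band gap and are assigned mild-to-moderate to keep a total partition).
    """
    if score < 0:
        raise ValueError("scale scores cannot be negative")
    instrument = instrument.upper()
    if instrument in ("SAS", "SDS"):
        kind = "anxiety" if instrument == "SAS" else "depression"
        if score < 50:
            return "none"
        if score < 60:
            return f"mild_{kind}"
        if score < 70:
            return f"moderate_{kind}"
        return f"severe_{kind}"
    if instrument == "HAMD":
        if score < 8:
            return "none"
        if score <= 20:
            return "mild"
        if score <= 35:
            return "mild_to_moderate"
        return "severe"
    raise ValueError(f"unknown instrument {instrument!r}")


def hamd_reduction_rate(baseline: float, post: float) -> float:
    """Percent reduction of the HAMD score: 100*(baseline - post)/baseline."""
    if baseline <= 0:
        raise ValueError("baseline score must be positive")
    return 100.0 * (baseline - post) / baseline


def classify_efficacy(reduction_rate_percent: float) -> str:
    """Efficacy band of a HAMD reduction rate.

    Above 75% cured; (50, 75] markedly effective; (25, 50] effective;
    25% and below ineffective (exactly 25% is unassigned by the banding's
    published wording and is placed in 'ineffective' for a total
    partition).
    """
    r = reduction_rate_percent
    if r > 75:
        return "cured"
    if r > 50:
        return "markedly_effective"
    if r > 25:
        return "effective"
    return "ineffective"


def aggregate_outcomes(
    categories: "pd.Series | dict | list",
    group_labels: "pd.Series | list | None" = None,
    category_set: tuple[str, ...] = EFFICACY_CATEGORIES,
) -> pd.DataFrame:
    """Per-group outcome table: counts, percentages, and derived totals.

    ``categories`` may be per-patient category labels (with parallel
    ``group_labels``) or a mapping ``{group: {category: count}}``.
    Percentages are 100*count/n rounded half-up to 2 decimals. The
    derived totals are total_effective = cured + markedly_effective +
    effective for efficacy categories, and total_compliant = complete +
    basic for compliance categories.
    """
    if isinstance(categories, dict):
        counts = pd.DataFrame(categories).T.reindex(columns=category_set).fillna(0)
    else:
        cats = pd.Series(list(categories))
        unknown = set(cats) - set(category_set)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if group_labels is None:
            raise ValueError("group_labels required with per-patient categories")
        groups = pd.Series(list(group_labels))
        counts = (
            pd.crosstab(groups, cats).reindex(columns=category_set).fillna(0)
        )
    unknown = set(counts.columns) - set(category_set)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    counts = counts.astype(int)

    out = counts.copy()
    out["n_total"] = counts.sum(axis=1)
    for total_name, members in _TOTAL_MEMBERS.items():
        if set(members) <= set(category_set):
            out[total_name] = counts[list(members)].sum(axis=1)
    for col in list(counts.columns) + [
        t for t in _TOTAL_MEMBERS if t in out.columns
    ]:
        out[f"{col}_pct"] = [
            _round2(100.0 * c / n) if n else 0.0
            for c, n in zip(out[col], out["n_total"])
        ]
    out.index.name = "group"
    return out


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of a 2x2 count table.

    No continuity correction by default (set ``yates=True`` to apply it).
    Returns (statistic, p) with p from the chi-square(1) survival
    function.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal total")
    expected = row @ col / n
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    return stat, float(stats.chi2.sf(stat, df=1))


def two_sample_t(group_a_values, group_b_values) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t test (two-sided).

    Two constant groups with equal means return (0, 1) by convention.
    """
    a = np.asarray(group_a_values, dtype=float)
    b = np.asarray(group_b_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def cohort_outcome_analysis(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Full outcome analysis of a long-format cohort table.

    Expects columns group, patient_id, instrument, timepoint, score. For
    each instrument: Welch t of post scores between groups; for HAMD
    additionally the per-patient reduction-rate efficacy table and the
    chi-square test of total-effective vs not between groups.
    """
    required = {"group", "patient_id", "instrument", "timepoint", "score"}
    if not required <= set(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    tests = []
    outcome_tables: dict[str, pd.DataFrame] = {}
    for instrument, sub in cohort.groupby("instrument"):
        wide = sub.pivot_table(
            index=["group", "patient_id"], columns="timepoint", values="score"
        )
        post = wide["post"].unstack(0) if "post" in wide else None
        if post is not None:
            groups = list(wide.index.get_level_values("group").unique())
            if len(groups) == 2:
                g0 = wide.loc[groups[0], "post"].dropna()
                g1 = wide.loc[groups[1], "post"].dropna()
                t, p = two_sample_t(g0, g1)
                tests.append(
                    {"comparison": f"{instrument}_post_{groups[0]}_vs_{groups[1]}",
                     "statistic": t, "p_value": p, "test": "welch_t"}
                )
        if instrument == "HAMD" and {"pre", "post"} <= set(wide.columns):
            rr = wide.apply(
                lambda r: hamd_reduction_rate(r["pre"], r["post"]), axis=1
            )
            cats = rr.map(classify_efficacy)
            table = aggregate_outcomes(
                cats.values, wide.index.get_level_values("group"), EFFICACY_CATEGORIES
            )
            outcome_tables["HAMD_efficacy"] = table
            if table.shape[0] == 2 and "total_effective" in table:
                eff = table["total_effective"].to_numpy()
                not_eff = (table["n_total"] - table["total_effective"]).to_numpy()
                stat, p = chi_square_2x2(np.column_stack([eff, not_eff]))
                tests.append(
                    {"comparison": "HAMD_total_effective_2x2", "statistic": stat,
                     "p_value": p, "test": "chi_square"}
                )
    return {"tests": pd.DataFrame(tests), **outcome_tables}
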