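"""Evaluation statistics: ANOVAs, effect sizes, correlation, plausibility.

Three ANOVA flavours mirror the analysis design:

* one-way ANOVA of the response deltas (Δv̄, Δh̄r) across response groups;
* two-way ANOVA (response × marathon group, Type II sums of squares for
  the unbalanced design) of the 16-week training parameters;
* one-factor repeated-measures ANOVA of the intensity-zone shares over
  the four training blocks, run per subject stratum.

All report partial eta squared, partial η² = SS_effect/(SS_effect +
SS_error); for the one-way case this equals plain η².  Effect sizes are
star-coded only when p < 0.05, with bands
* : 0.01 <= η² < 0.05, ** : 0.05 <= η² < 0.12, *** : η² >= 0.12.

The repeated-measures ANOVA additionally carries the Greenhouse–Geisser
corrected p value; the star coding uses the uncorrected one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

ALPHA = 0.05


class DegenerateInputError(ValueError):
    """Statistic undefined (e.g. zero variance or too few groups)."""


@dataclass
class AnovaResult:
    effect: str
    ss_effect: float
    ss_error: float
    df_effect: float
    df_error: float
    f: float
    p: float
    partial_eta2: float
    p_gg: float | None = None  # Greenhouse-Geisser corrected (RM only)

    @property
    def stars(self) -> str:
        return effect_stars(self.partial_eta2, self.p)


def effect_stars(partial_eta2: float, p: float) -> str:
    """Star code for a significant effect size ('' when p >= 0.05 or
    η² < 0.01)."""
    if p >= ALPHA or partial_eta2 < 0.01:
        return ""
    if partial_eta2 >= 0.12:
        return "***"
    if partial_eta2 >= 0.05:
        return "**"
    return "*"


def one_way_anova(values, groups) -> AnovaResult:
    """Classical one-way between-subjects ANOVA with η²."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(groups)})
    if df["g"].nunique() < 2:
        raise DegenerateInputError("need at least 2 groups")
    if np.isclose(df["y"].var(ddof=0), 0.0):
        raise DegenerateInputError("zero total variance")
    table = pg.anova(data=df, dv="y", between="g", detailed=True)
    ss_eff = float(table.loc[0, "SS"])
    ss_err = float(table.loc[1, "SS"])
    return AnovaResult(
        effect="g",
        ss_effect=ss_eff,
        ss_error=ss_err,
        df_effect=float(table.loc[0, "DF"]),
        df_error=float(table.loc[1, "DF"]),
        f=float(table.loc[0, "F"]),
        p=float(_col(table, 0, "p_unc", "p-unc")),
        partial_eta2=ss_eff / (ss_eff + ss_err),
    )


def _col(table, row, *names):
    for n in names:
        if n in table.columns:
            return table.loc[row, n]
    raise KeyError(names)


def two_way_anova(data: pd.DataFrame, dv: str, factor_a: str, factor_b: str) -> dict[str, AnovaResult]:
    """Two-way ANOVA (Type II SS) for a possibly unbalanced design.

    Returns results keyed by factor_a, factor_b and "interaction".
    Raises on empty design cells (every factor combination must occur).
    """
    counts = data.groupby([factor_a, factor_b], observed=True).size().unstack()
    counts = counts.reindex(
        index=data[factor_a].unique(), columns=data[factor_b].unique()
    )
    if counts.isna().any().any() or (counts == 0).any().any():
        empty = [
            (a, b)
            for a in counts.index
            for b in counts.columns
            if pd.isna(counts.loc[a, b]) or counts.loc[a, b] == 0
        ]
        raise DegenerateInputError(f"empty design cell(s): {empty}")
    model = smf.ols(f"{dv} ~ C({factor_a}) * C({factor_b})", data=data).fit()
    if model.df_resid <= 0:
        raise DegenerateInputError("saturated design: no residual degrees of freedom")
    table = anova_lm(model, typ=2)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = float(table.loc["Residual", "df"])
    out = {}
    for key, row_name in [
        (factor_a, f"C({factor_a})"),
        (factor_b, f"C({factor_b})"),
        ("interaction", f"C({factor_a}):C({factor_b})"),
    ]:
        ss = float(table.loc[row_name, "sum_sq"])
        out[key] = AnovaResult(
            effect=key,
            ss_effect=ss,
            ss_error=ss_err,
            df_effect=float(table.loc[row_name, "df"]),
            df_error=df_err,
            f=float(table.loc[row_name, "F"]),
            p=float(table.loc[row_name, "PR(>F)"]),
            partial_eta2=ss / (ss + ss_err),
        )
    return out


def rm_anova(data: pd.DataFrame, dv: str, within: str, subject: str) -> AnovaResult:
    """One-factor repeated-measures ANOVA (subject effects removed).

    Every subject must contribute a value at every level of ``within``.
    Reports the uncorrected p plus the Greenhouse–Geisser corrected p.
    """
    wide = data.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise DegenerateInputError("incomplete repeated-measures design")
    if len(wide) < 2:
        raise DegenerateInputError("need at least 2 subjects")
    table = pg.rm_anova(
        data=data, dv=dv, within=within, subject=subject,
        detailed=True, correction=True, effsize="np2",
    )
    ss_eff = float(table.loc[0, "SS"])
    ss_err = float(table.loc[1, "SS"])
    try:
        p_gg = _col(table, 0, "p_GG_corr", "p-GG-corr")
    except KeyError:
        p_gg = None
    return AnovaResult(
        effect=within,
        ss_effect=ss_eff,
        ss_error=ss_err,
        df_effect=float(table.loc[0, "DF"]),
        df_error=float(table.loc[1, "DF"]),
        f=float(table.loc[0, "F"]),
        p=float(_col(table, 0, "p_unc", "p-unc")),
        partial_eta2=ss_eff / (ss_eff + ss_err),
        p_gg=None if p_gg is None or pd.isna(p_gg) else float(p_gg),
    )


def pearson(x, y) -> tuple[float, float, float]:
    """(Pearson r, least-squares slope, intercept) for paired data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 pairs")
    if np.isclose(x.var(), 0) or np.isclose(y.var(), 0):
        raise DegenerateInputError("zero variance")
    res = scipy.stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


@dataclass
class PlausibilityReport:
    """Sanity-check summaries of a filtered cohort."""

    t_mp_hist: tuple[np.ndarray, np.ndarray]  # (counts, bin edges [s]); 5-min bins
    hr_max_hist: tuple[np.ndarray, np.ndarray]  # (counts, edges [bpm]); 2-bpm bins
    delta_v10_sorted: np.ndarray
    pearson_r: float
    slope: float
    intercept: float
    weekend_share: float  # fraction of marathons started Sat/Sun (UTC)


def weekend_share(start_times: np.ndarray) -> float:
    """Fraction of UTC start timestamps falling on Saturday or Sunday."""
    # epoch day 0 (1970-01-01) was a Thursday; +3 makes Monday = 0
    days = (np.asarray(start_times, dtype=np.int64) // 86_400 + 3) % 7
    return float(np.isin(days, (5, 6)).mean())


def plausibility_report(
    t_mp: np.ndarray,
    hr_max: np.ndarray,
    delta_v10: np.ndarray,
    v10_overall: np.ndarray,
    v_mp: np.ndarray,
    marathon_starts: np.ndarray,
) -> PlausibilityReport:
    """Histograms, sorted response curve, v10–v_mp regression and the
    weekend share of marathon start times."""
    t_mp = np.asarray(t_mp, dtype=float)
    hr_max = np.asarray(hr_max, dtype=float)
    bin5 = 300.0
    edges_t = np.arange(np.floor(t_mp.min() / bin5) * bin5, t_mp.max() + bin5, bin5)
    edges_hr = np.arange(np.floor(hr_max.min() / 2) * 2, hr_max.max() + 2, 2.0)
    r, slope, intercept = pearson(v10_overall, v_mp)
    return PlausibilityReport(
        t_mp_hist=np.histogram(t_mp, bins=edges_t),
        hr_max_hist=np.histogram(hr_max, bins=edges_hr),
        delta_v10_sorted=np.sort(np.asarray(delta_v10, dtype=float)),
        pearson_r=r,
        slope=slope,
        intercept=intercept,
        weekend_share=weekend_share(marathon_starts),
    )
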