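"""Inference layer: mixed-design (repeated-measures) two-way ANOVA and t-tests.

The experimental design is a 2 × 2 mixed layout: treatment (excised vs
attached) varies between plants, time of day (AM vs PM) within plants.  With
a two-level within factor the classical mixed ANOVA decomposes exactly into
two independent strata:

* between stratum — a one-way ANOVA of per-subject means across treatments
  (treatment F, tested against subjects-within-treatment error);
* within stratum — a regression of per-subject PM−AM difference scores on
  effect-coded treatment: the intercept tests the time main effect, the
  slope the treatment × time interaction, both against the pooled residual
  of the difference scores.

For balanced data this reproduces the textbook sums-of-squares table; for
unbalanced data the effect-coded regression yields the marginal
(Type-III-style) tests on unweighted group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectResult",
    "RMAnovaResult",
    "TTestResult",
    "DegenerateDataError",
    "two_way_rm_anova",
    "compare_treatments_t",
    "sampling_date_check",
]


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined (zero residual variance)."""


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class RMAnovaResult:
    treatment: EffectResult
    time: EffectResult
    interaction: EffectResult
    n_subjects: int
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for effect in ("treatment", "time", "interaction"):
            r = getattr(self, effect)
            rows.append({"effect": effect, "F": r.F, "df_num": r.df_num,
                         "df_den": r.df_den, "p": r.p})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_difference: float
    flavor: str   # 'one_sample_on_differences' or 'welch_two_sample'


def two_way_rm_anova(table: pd.DataFrame, value: str = "value",
                     treatment: str = "treatment", time: str = "time",
                     subject: str = "replicate") -> RMAnovaResult:
    """Mixed-design two-way ANOVA on a long trait table.

    The table must have one row per (subject, time); subjects are nested in
    treatment.  Subjects missing either time level are dropped (with a
    warning).  Requires >= 2 subjects per treatment after dropping.
    """
    df = table[[subject, treatment, time, value]].dropna(subset=[value]).copy()
    times = sorted(df[time].unique())
    if len(times) != 2:
        raise ValueError(f"expected exactly 2 time levels, got {times}")

    wide = df.pivot_table(index=[treatment, subject], columns=time,
                          values=value, aggfunc="first")
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} subject(s) missing a time level",
                      RuntimeWarning, stacklevel=2)

    groups = complete.index.get_level_values(0)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 treatment levels, got {list(labels)}")
    sizes = {lab: int((groups == lab).sum()) for lab in labels}
    if min(sizes.values()) < 2:
        raise DegenerateDataError("need >= 2 complete subjects per treatment")

    M = complete.mean(axis=1).to_numpy()                     # subject means
    D = (complete[times[1]] - complete[times[0]]).to_numpy()  # PM − AM
    g = np.where(groups == labels[0], 1.0, -1.0)              # effect coding
    N = len(M)
    df_den = N - 2

    # between stratum: one-way ANOVA on subject means
    grand = M.mean()
    ssb = sum(sizes[lab] * (M[groups == lab].mean() - grand) ** 2 for lab in labels)
    ssw = sum(((M[groups == lab] - M[groups == lab].mean()) ** 2).sum()
              for lab in labels)
    if ssw <= 0:
        raise DegenerateDataError("zero between-subject residual variance")
    F_treat = (ssb / 1.0) / (ssw / df_den)

    # within stratum: D ~ 1 + g, Type-III tests via (X'X)^-1
    X = np.column_stack([np.ones(N), g])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ D)
    resid = D - X @ beta
    sse = float(resid @ resid)
    if sse <= 0:
        raise DegenerateDataError("zero within-subject residual variance")
    mse = sse / df_den
    cov = np.linalg.inv(XtX) * mse
    F_time = beta[0] ** 2 / cov[0, 0]
    F_int = beta[1] ** 2 / cov[1, 1]

    def _effect(F):
        return EffectResult(float(F), 1, df_den,
                            float(stats.f.sf(F, 1, df_den)))

    return RMAnovaResult(treatment=_effect(F_treat), time=_effect(F_time),
                         interaction=_effect(F_int), n_subjects=N,
                         n_dropped=n_dropped)


def compare_treatments_t(values_excised, values_attached,
                         paired: bool = False) -> TTestResult:
    """Excised-vs-attached comparison.

    paired=True runs a one-sample t-test on per-pair differences against 0
    (values must be aligned by replicate); otherwise a Welch two-sample
    t-test (plants are independent).
    """
    x = np.asarray(values_excised, dtype=float)
    y = np.asarray(values_attached, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal-length groups")
        d = x - y
        if np.allclose(d.std(ddof=1), 0):
            if np.allclose(d, 0):
                return TTestResult(0.0, len(d) - 1, 1.0, 0.0,
                                   "one_sample_on_differences")
            raise DegenerateDataError("zero variance in differences")
        res = stats.ttest_1samp(d, 0.0)
        return TTestResult(float(res.statistic), float(len(d) - 1),
                           float(res.pvalue), float(d.mean()),
                           "one_sample_on_differences")
    if np.allclose(x.std(ddof=1), 0) and np.allclose(y.std(ddof=1), 0):
        if np.isclose(x.mean(), y.mean()):
            return TTestResult(0.0, float(len(x) + len(y) - 2), 1.0, 0.0,
                               "welch_two_sample")
        raise DegenerateDataError("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue),
                       float(x.mean() - y.mean()), "welch_two_sample")


def sampling_date_check(table: pd.DataFrame, traits: list[str] | None = None,
                        date: str = "date", alpha: float = 0.05
                        ) -> pd.DataFrame:
    """Per-trait test for a sampling-date effect (two date groups).

    Applies the unpaired treatment-comparison machinery between the two
    dates for each trait column and recommends combining the dates when the
    effect is non-significant at ``alpha``.  Returns a frame with columns
    trait, t, df, p, combine.
    """
    dates = sorted(table[date].unique())
    if len(dates) != 2:
        raise ValueError(f"expected exactly 2 date groups, got {dates}")
    if traits is None:
        traits = [c for c in table.columns
                  if c != date and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for trait in traits:
        a = table.loc[table[date] == dates[0], trait].dropna().to_numpy()
        b = table.loc[table[date] == dates[1], trait].dropna().to_numpy()
        res = compare_treatments_t(a, b, paired=False)
        rows.append({"trait": trait, "t": res.t, "df": res.df, "p": res.p,
                     "combine": res.p >= alpha})
    return pd.DataFrame(rows)
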