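"""Group inference on fold effects: ANOVA and Holm-Sidak stepdown adjustment.

Two-way fixed-effects ANOVA (treatment x dose) is applied to fold-effect data;
when residuals fail a normality check the responses are rank-transformed and
the ANOVA is rerun on ranks, the standard nonparametric fallback for balanced
factorial designs. One-way ANOVA covers single-factor contrasts such as
GSH/GSSG oxidative-stress ratios. Families of pairwise comparisons are
adjusted by the Holm-Sidak stepdown: sort raw p ascending and set
adjusted p_(i) = 1 - (1 - p_(i))^(m - i + 1), enforcing monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols

from .errors import DesignError, ValidationError


@dataclass
class AnovaTerm:
    term: str
    F: float
    df: float
    df_resid: float
    p: float


@dataclass
class AnovaResult:
    terms: list[AnovaTerm]
    transform: str  # "none" or "rank"

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.term,
                    "F": t.F,
                    "df": t.df,
                    "df_resid": t.df_resid,
                    "p": t.p,
                    "transform": self.transform,
                }
                for t in self.terms
            ]
        )


@dataclass
class AdjustedComparisons:
    labels: list[str]
    raw_p: np.ndarray
    adjusted_p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"contrast": self.labels, "p_raw": self.raw_p, "p_adj": self.adjusted_p}
        )


def _check_balanced(df: pd.DataFrame, a: str, b: str) -> int:
    counts = df.groupby([a, b]).size()
    full = df[a].nunique() * df[b].nunique()
    if len(counts) != full or counts.nunique() != 1:
        raise DesignError(
            "two-way ANOVA requires a balanced complete design; "
            f"cell counts: {sorted(counts.unique())}, cells present: {len(counts)}/{full}"
        )
    return int(counts.iloc[0])


def two_way_anova(
    data: pd.DataFrame,
    response: str = "fe",
    factor_a: str = "particle",
    factor_b: str = "dose",
    transform: str = "auto",
    normality_alpha: float = 0.05,
) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA with optional rank transform.

    ``transform="auto"`` runs the untransformed ANOVA first and switches to the
    rank path when a Shapiro-Wilk test of the residuals rejects normality at
    ``normality_alpha``. Unbalanced designs are rejected outright rather than
    silently picking a sums-of-squares convention.
    """
    if transform not in ("auto", "none", "rank"):
        raise ValidationError(f"unknown transform: {transform!r}")
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise ValidationError(f"missing column {col!r}")
    df = data[[factor_a, factor_b, response]].copy()
    if df[factor_a].nunique() < 2 or df[factor_b].nunique() < 2:
        raise DesignError("each factor needs >= 2 levels")
    n_per_cell = _check_balanced(df, factor_a, factor_b)
    if n_per_cell < 2:
        raise DesignError(
            "interaction term needs >= 2 replicates per cell; got 1"
        )

    def run(values: np.ndarray, label: str) -> AnovaResult:
        names_flat = [factor_a, factor_b, f"{factor_a}:{factor_b}"]
        dfs = [
            float(df[factor_a].nunique() - 1),
            float(df[factor_b].nunique() - 1),
            float((df[factor_a].nunique() - 1) * (df[factor_b].nunique() - 1)),
        ]
        df_resid_flat = float(len(df) - df[factor_a].nunique() * df[factor_b].nunique())
        if np.ptp(values) == 0:  # no variance anywhere: every F is exactly 0
            return AnovaResult(
                terms=[
                    AnovaTerm(term=t, F=0.0, df=d, df_resid=df_resid_flat, p=1.0)
                    for t, d in zip(names_flat, dfs)
                ],
                transform=label,
            )
        work = df.assign(_y=values)
        model = ols(f"_y ~ C({factor_a}) * C({factor_b})", data=work).fit()
        table = sm.stats.anova_lm(model, typ=2)
        names = {
            f"C({factor_a})": factor_a,
            f"C({factor_b})": factor_b,
            f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
        }
        df_resid = float(table.loc["Residual", "df"])
        terms = []
        for raw_name, name in names.items():
            row = table.loc[raw_name]
            f_stat = float(row["F"])
            p = float(row["PR(>F)"])
            if not np.isfinite(f_stat):  # zero residual and zero effect SS
                f_stat, p = 0.0, 1.0
            terms.append(
                AnovaTerm(term=name, F=max(f_stat, 0.0), df=float(row["df"]),
                          df_resid=df_resid, p=p)
            )
        return AnovaResult(terms=terms, transform=label)

    y = df[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("responses must be finite")
    if transform == "rank":
        return run(stats.rankdata(y), "rank")
    result = run(y, "none")
    if transform == "none":
        return result
    # auto: inspect residuals of the untransformed fit
    model = ols(f"_y ~ C({factor_a}) * C({factor_b})", data=df.assign(_y=y)).fit()
    resid = np.asarray(model.resid)
    if np.ptp(resid) == 0:
        return result
    if stats.shapiro(resid).pvalue < normality_alpha:
        return run(stats.rankdata(y), "rank")
    return result


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Standard one-way fixed-effects F test across >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DesignError("one-way ANOVA needs >= 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise DesignError(f"group {i} has < 2 observations")
        if not np.all(np.isfinite(g)):
            raise ValidationError(f"group {i} contains non-finite values")
    k = len(arrays)
    n = sum(g.size for g in arrays)
    if np.ptp(np.concatenate(arrays)) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
        if not np.isfinite(f_stat):
            f_stat, p = 0.0, 1.0
    return AnovaResult(
        terms=[AnovaTerm(term="group", F=float(max(f_stat, 0.0)), df=float(k - 1),
                         df_resid=float(n - k), p=float(p))],
        transform="none",
    )


def holm_sidak(raw_p, labels: Optional[Sequence[str]] = None) -> AdjustedComparisons:
    """Holm-Sidak stepdown adjustment of a family of p-values.

    Adjusted values are returned in the input order; internally the family is
    sorted ascending, adjusted as 1 - (1 - p)^(remaining comparisons), and a
    running maximum enforces monotonicity before capping at 1.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("raw_p must be a nonempty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    if labels is None:
        labels = [f"c{i}" for i in range(m)]
    return AdjustedComparisons(labels=list(labels), raw_p=p, adjusted_p=adjusted)


def pairwise_contrasts(
    groups: dict[str, Sequence[float]],
    control: Optional[str] = None,
    family: str = "vs_control",
) -> AdjustedComparisons:
    """Pairwise two-sample t tests with Holm-Sidak adjustment.

    ``family="vs_control"`` (default) compares every treatment against the
    named control group; ``family="all_pairs"`` compares every pair.
    """
    names = list(groups)
    if family == "vs_control":
        if control is None or control not in groups:
            raise ValidationError("vs_control family requires a valid control label")
        pairs = [(t, control) for t in names if t != control]
    elif family == "all_pairs":
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    else:
        raise ValidationError(f"unknown contrast family: {family!r}")
    if not pairs:
        raise DesignError("no contrasts to test")
    labels, raw = [], []
    for a, b in pairs:
        res = stats.ttest_ind(np.asarray(groups[a], float), np.asarray(groups[b], float))
        labels.append(f"{a} vs {b}")
        raw.append(float(res.pvalue))
    return holm_sidak(np.array(raw), labels)
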