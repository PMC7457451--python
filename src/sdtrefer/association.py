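"""Covariate associations, cross-task stability and group comparisons.

Per-responder indices (d', c) are regressed on practice-level referral
performance (PPV and sensitivity of urgent referrals, in percentage
points), responder gender (female = 1) and years of experience by
ordinary least squares; cross-task stability is the Pearson correlation
of an index between two vignette tasks over the responders who completed
both; group means are compared with a pooled-variance Student t-test
(df = n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import Gender
from .errors import RankDeficientError

DEFAULT_TERMS = ["practice_ppv_percent", "practice_sensitivity_percent",
                 "gender", "experience_years"]


@dataclass
class RegressionResult:
    outcome_name: str
    terms: pd.DataFrame  # term, b, ci_low, ci_high, p
    n: int
    r_squared: float

    def term(self, name: str) -> pd.Series:
        return self.terms.set_index("term").loc[name]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float


def _numeric_covariates(profiles: pd.DataFrame, terms: list[str],
                        experience_quartiles: bool) -> pd.DataFrame:
    out = {}
    for t in terms:
        if t == "gender":
            out["gender"] = (profiles["gender"] == Gender.FEMALE.name).astype(float)
        elif t == "experience_years" and experience_quartiles:
            q = pd.qcut(profiles["experience_years"], 4, labels=False)
            for lev in (1, 2, 3):  # least-experienced quartile is the reference
                out[f"experience_q{lev + 1}"] = (q == lev).astype(float)
        else:
            out[t] = profiles[t].astype(float)
    return pd.DataFrame(out, index=profiles.index)


def regress_index(
    indices: pd.DataFrame,
    profiles: pd.DataFrame,
    outcome: str = "criterion",
    terms: list[str] | None = None,
    experience_quartiles: bool = False,
) -> RegressionResult:
    """OLS of a per-responder index on responder/practice covariates.

    Analytic 95% CIs and two-sided p-values; covariates stay on their
    natural scales so a PPV coefficient reads "per percentage point".
    Complete cases only.
    """
    terms = DEFAULT_TERMS if terms is None else terms
    df = indices.merge(profiles, on="responder_id", how="inner")
    X = _numeric_covariates(df, terms, experience_quartiles)
    data = pd.concat([df[[outcome]], X], axis=1).dropna()
    if len(data) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} complete cases, have {len(data)}"
        )
    Xm = sm.add_constant(data[X.columns], prepend=True)
    _check_rank(Xm)
    fit = sm.OLS(data[outcome], Xm).fit()
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "term": Xm.columns,
            "b": fit.params.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    ).replace({"term": {"const": "intercept"}})
    return RegressionResult(
        outcome_name=outcome,
        terms=table.reset_index(drop=True),
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = 0
    for j, col in enumerate(X.columns):
        new_rank = np.linalg.matrix_rank(arr[:, : j + 1])
        if new_rank == rank:
            raise RankDeficientError(
                f"design matrix is rank deficient: column {col!r} is a linear "
                "combination of the preceding columns"
            )
        rank = new_rank


def stability_correlation(
    indices_task_a: pd.DataFrame,
    indices_task_b: pd.DataFrame,
    column: str = "criterion",
) -> CorrelationResult:
    """Pearson correlation of an index across two tasks, paired on the
    responders present in both."""
    merged = indices_task_a[["responder_id", column]].merge(
        indices_task_b[["responder_id", column]],
        on="responder_id",
        suffixes=("_a", "_b"),
    ).dropna()
    if len(merged) < 3:
        raise ValueError(
            f"need >= 3 shared responders for a correlation, have {len(merged)}"
        )
    r, p = stats.pearsonr(merged[f"{column}_a"], merged[f"{column}_b"])
    return CorrelationResult(r=float(r), p=float(p), n=len(merged))


def compare_groups(values, group_labels) -> GroupComparison:
    """Pooled-variance two-sample t-test of a score between two groups."""
    values = np.asarray(values, float)
    labels = np.asarray(group_labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {len(groups)}")
    a, b = values[labels == groups[0]], values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
        len(a) + len(b) - 2
    )
    if sp2 == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    df = len(a) + len(b) - 2
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t),
        df=int(df),
        p=float(2 * stats.t.sf(abs(t), df)),
    )
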