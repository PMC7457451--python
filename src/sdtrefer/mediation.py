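"""Mediation of the gender effect on response bias via stress.

Single-mediator model estimated by three OLS regressions on complete
cases: mediator ~ predictor (a path), outcome ~ predictor + mediator
(b path and direct effect) and outcome ~ predictor (total effect).  The
indirect effect is the product a*b with a nonparametric percentile
bootstrap confidence interval; with OLS on a common complete-case sample
the decomposition total = direct + indirect holds as an identity.  The
proportion mediated is indirect/total, reported as-is (and flagged) when
the paths are sign-inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import Gender
from .errors import UndefinedProportionError


class PathEstimate(NamedTuple):
    b: float
    ci_low: float
    ci_high: float
    p: float | None = None


class ProportionMediated(NamedTuple):
    value: float
    inconsistent: bool


@dataclass
class MediationResult:
    a_path: PathEstimate
    b_path: PathEstimate
    direct: PathEstimate
    indirect: PathEstimate
    total: PathEstimate
    proportion_mediated: ProportionMediated
    n: int
    n_boot: int
    seed: int
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("a_path", "b_path", "direct", "indirect", "total"):
            est: PathEstimate = getattr(self, name)
            rows.append({"path": name, "estimate": est.b, "ci_low": est.ci_low,
                         "ci_high": est.ci_high, "p": est.p})
        rows.append({"path": "proportion_mediated",
                     "estimate": self.proportion_mediated.value,
                     "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


def _ols_path(y, X_cols) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = sm.add_constant(np.column_stack(X_cols))
    fit = sm.OLS(y, X).fit()
    return fit.params[1:], fit.conf_int()[1:], fit.pvalues[1:]


def fit_mediation(
    data: pd.DataFrame,
    predictor: str = "gender",
    mediator: str = "stress_score",
    outcome: str = "criterion",
    n_boot: int = 5000,
    seed: int = 1234,
    ci_level: float = 0.95,
) -> MediationResult:
    """Fit the predictor -> mediator -> outcome model on complete cases.

    ``data`` holds one row per responder with the three analysis columns
    (a ``gender`` predictor is recoded female = 1).  Rows missing the
    mediator, outcome or predictor are dropped (listwise deletion).
    """
    df = data[[predictor, mediator, outcome]].copy()
    if predictor == "gender":
        df["gender"] = (data["gender"] == Gender.FEMALE.name).astype(float)
    df = df.dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete cases for mediation, have {len(df)}")
    x = df[predictor].to_numpy(float)
    m = df[mediator].to_numpy(float)
    y = df[outcome].to_numpy(float)
    for name, v in (("mediator", m), ("outcome", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; mediation model undefined")

    warns = []
    if n_boot < 100:
        warns.append(f"n_boot={n_boot} < 100: bootstrap CI will be unstable")

    (a_b,), (a_ci,), (a_p,) = _ols_path(m, [x])
    params, cis, ps = _ols_path(y, [x, m])
    direct_b, b_b = params
    direct_ci, b_ci = cis
    direct_p, b_p = ps
    (tot_b,), (tot_ci,), (tot_p,) = _ols_path(y, [x])

    lo, hi = _bootstrap_indirect(x, m, y, n_boot, seed, ci_level)
    indirect_b = float(a_b * b_b)
    total = PathEstimate(float(tot_b), float(tot_ci[0]), float(tot_ci[1]), float(tot_p))
    prop = proportion_mediated(indirect_b, total.b)
    return MediationResult(
        a_path=PathEstimate(float(a_b), float(a_ci[0]), float(a_ci[1]), float(a_p)),
        b_path=PathEstimate(float(b_b), float(b_ci[0]), float(b_ci[1]), float(b_p)),
        direct=PathEstimate(float(direct_b), float(direct_ci[0]),
                            float(direct_ci[1]), float(direct_p)),
        indirect=PathEstimate(indirect_b, lo, hi),
        total=total,
        proportion_mediated=prop,
        n=len(df),
        n_boot=n_boot,
        seed=seed,
        warnings=warns,
    )


def _bootstrap_indirect(x, m, y, n_boot, seed, ci_level) -> tuple[float, float]:
    """Percentile bootstrap of a*b, closed-form OLS vectorised over
    resamples (identical estimates to the statsmodels fits)."""
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    X, M, Y = x[idx], m[idx], y[idx]
    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    sxm = np.einsum("ij,ij->i", Xc, Mc)
    smm = np.einsum("ij,ij->i", Mc, Mc)
    smy = np.einsum("ij,ij->i", Mc, Yc)
    sxy = np.einsum("ij,ij->i", Xc, Yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        det = sxx * smm - sxm**2
        b = (sxx * smy - sxm * sxy) / det
    prod = a * b
    prod = prod[np.isfinite(prod)]  # degenerate resamples carry no information
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(prod, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def proportion_mediated(indirect_b: float, total_b: float) -> ProportionMediated:
    """indirect / total, flagged when the two disagree in sign
    (inconsistent mediation, where the ratio loses its "share of the
    effect" reading)."""
    if total_b == 0:
        raise UndefinedProportionError(
            "proportion mediated is undefined: total effect is zero"
        )
    value = indirect_b / total_b
    return ProportionMediated(value=float(value), inconsistent=bool(value < 0))
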