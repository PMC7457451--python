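"""Probit-GLM formulation of signal detection with responder nesting.

Dichotomised decisions are modelled at the trial level as

    P(urgent) = Phi(b0 + b1 * signal + sum_k g_k * x_k + sum_k h_k * x_k * signal)

with the case class coded signal = +0.5 (above-threshold) / -0.5
(below-threshold).  Under this centred coding the parameters map directly
onto the classical indices: b0 = -c and b1 = d' at the covariate
reference, covariate main effects shift -c, and covariate-by-signal
interactions shift d'.  Unlike the count-based indices, the GLM needs no
0.5 correction and can absorb responder-level covariates and nesting
(random intercept = per-responder criterion deviation, random signal
slope = per-responder discrimination deviation) in one model.

The mixed-effects likelihood integrates the two independent Gaussian
random effects by Gauss-Hermite quadrature and is maximised numerically;
standard errors come from the finite-difference observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, logsumexp
from scipy.stats import norm

from .datamodel import Gender, SignalClass, StudyDataset
from .errors import NotConvergedError, SeparationError

SIGNAL_CODING = {"POSITIVE": 0.5, "NEGATIVE": -0.5}


class RandomEffects(Enum):
    NONE = "none"
    INTERCEPT = "intercept"
    INTERCEPT_AND_SIGNAL_SLOPE = "intercept_and_signal_slope"


@dataclass
class GlmSdtSpec:
    """Model specification: responder covariates and nesting structure."""

    covariates: list[str] = field(default_factory=list)
    random_effects: RandomEffects = RandomEffects.INTERCEPT_AND_SIGNAL_SLOPE
    with_interactions: bool = True
    n_quad: int = 31       # Gauss-Hermite nodes per random-effect dimension
    max_iter: int = 200
    gtol: float = 1e-6


@dataclass
class GlmSdtResult:
    """Fitted coefficients with the SDT interpretation attached.

    ``coefficients`` has one row per term: estimate, se, ci_low, ci_high,
    p.  Intercept-side terms read as shifts of -c; ``signal`` and
    signal-interaction terms read as d' and shifts of d'.
    """

    coefficients: pd.DataFrame
    n_obs: int
    converged: bool
    random_effects: RandomEffects
    re_sd: dict[str, float]
    loglike: float

    def to_csv(self, path) -> None:
        self.coefficients.to_csv(path, index=False)


def _design(ds: StudyDataset, spec: GlmSdtSpec):
    m = ds.merged().merge(ds.responders, on="responder_id", how="left")
    m = m.sort_values("responder_id", kind="stable").reset_index(drop=True)
    y = m["urgent"].to_numpy(float)
    s = m["signal_class"].map(SIGNAL_CODING).to_numpy(float)
    cols = {"intercept": np.ones(len(m)), "signal": s}
    for cov in spec.covariates:
        if cov == "gender":
            x = (m["gender"] == Gender.FEMALE.name).to_numpy(float)
        else:
            x = m[cov].to_numpy(float)
        cols[cov] = x
        if spec.with_interactions:
            cols[f"{cov}:signal"] = x * s
    X = np.column_stack(list(cols.values()))
    groups = m["responder_id"].to_numpy()
    return y, s, X, list(cols.keys()), groups


def _check_separation(y: np.ndarray, spec: GlmSdtSpec, m_cols: dict[str, np.ndarray]):
    # Complete separation is only diagnosed for binary covariates, where a
    # level with constant outcome sends its coefficient to +/-inf.
    for name, x in m_cols.items():
        levels = np.unique(x)
        if len(levels) != 2:
            continue
        for lev in levels:
            yy = y[x == lev]
            if len(yy) and (yy.min() == yy.max()):
                raise SeparationError(
                    f"complete separation: covariate {name!r} level {lev} has a "
                    "constant outcome; its probit coefficient is unbounded"
                )


def fit_probit_sdt(ds: StudyDataset, spec: GlmSdtSpec | None = None) -> GlmSdtResult:
    """Fit the trial-level probit SDT model.

    With ``RandomEffects.NONE`` this is an ordinary probit regression
    (suitable for single-responder or small fixtures); otherwise
    per-responder Gaussian deviations on the intercept (criterion) and,
    optionally, the signal slope (discrimination) are integrated out by
    Gauss-Hermite quadrature and their standard deviations estimated.
    """
    spec = spec or GlmSdtSpec()
    y, s, X, names, groups = _design(ds, spec)
    cov_cols = {n: X[:, i] for i, n in enumerate(names) if n not in ("intercept",)}
    _check_separation(y, spec, cov_cols)

    if spec.random_effects is RandomEffects.NONE:
        return _fit_fixed(y, X, names, spec)
    return _fit_mixed(y, s, X, names, groups, spec)


def _fit_fixed(y, X, names, spec) -> GlmSdtResult:
    import statsmodels.api as sm

    model = sm.Probit(y, X)
    res = model.fit(disp=0, maxiter=spec.max_iter, method="newton", tol=1e-10)
    converged = bool(res.mle_retvals.get("converged", True))
    ci = res.conf_int()
    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": res.params,
            "se": res.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": res.pvalues,
        }
    )
    return GlmSdtResult(
        coefficients=coef.reset_index(drop=True),
        n_obs=len(y),
        converged=converged,
        random_effects=RandomEffects.NONE,
        re_sd={},
        loglike=float(res.llf),
    )


def _mixed_nll_grad(theta, y, s, X, w, starts, trial_resp, spec):
    """Negative marginal log-likelihood and its gradient.

    Responder random effects are integrated on a (product) Gauss-Hermite
    grid; the score follows from posterior quadrature weights, so one
    call costs about two likelihood evaluations.
    """
    p = X.shape[1]
    beta = theta[:p]
    two_dims = spec.random_effects is RandomEffects.INTERCEPT_AND_SIGNAL_SLOPE
    sd0 = np.exp(theta[p])
    sd1 = np.exp(theta[p + 1]) if two_dims else 0.0

    nodes, weights = np.polynomial.hermite_e.hermegauss(spec.n_quad)
    logw = np.log(weights) - 0.5 * np.log(2 * np.pi)
    if two_dims:
        u0 = np.repeat(nodes * sd0, spec.n_quad)
        u1 = np.tile(nodes * sd1, spec.n_quad)
        logw_q = np.add.outer(logw, logw).ravel()
    else:
        u0, u1 = nodes * sd0, np.zeros(spec.n_quad)
        logw_q = logw

    sign = 2.0 * y - 1.0
    # (n_quad_total, n_cells): linear predictor at each quadrature point;
    # cells are weighted groups of exchangeable trials
    eta = (X @ beta)[None, :] + u0[:, None] + u1[:, None] * s[None, :]
    z = sign[None, :] * eta
    logp = log_ndtr(z) * w[None, :]
    l_iq = np.add.reduceat(logp, starts, axis=1)  # (n_quad, n_responders)
    tot = l_iq + logw_q[:, None]
    lse = logsumexp(tot, axis=0)
    nll = -float(np.sum(lse))

    post = np.exp(tot - lse[None, :])            # posterior weight per node
    W = post[:, trial_resp]                      # spread to cells
    # d log Phi(z) / d eta = sign * phi(z) / Phi(z)
    g = sign[None, :] * np.exp(
        -0.5 * z * z - 0.5 * np.log(2 * np.pi) - log_ndtr(z)
    )
    A = W * g * w[None, :]
    a_t = A.sum(axis=0)
    grad = np.empty_like(theta)
    grad[:p] = a_t @ X
    grad[p] = float(A.sum(axis=1) @ u0)          # d eta / d log sd0 = u0
    if two_dims:
        grad[p + 1] = float(np.einsum("qt,t,q->", A, s, u1))
    return nll, -grad


def _fit_mixed(y, s, X, names, groups, spec) -> GlmSdtResult:
    import statsmodels.api as sm

    p = X.shape[1]
    two_dims = spec.random_effects is RandomEffects.INTERCEPT_AND_SIGNAL_SLOPE

    # Covariates are responder-level, so all trials of a responder with
    # the same case class and outcome are exchangeable: collapse them to
    # weighted cells (at most 4 per responder), which shrinks the
    # quadrature grid's second axis from trials to cells.
    _, trial_resp = np.unique(groups, return_inverse=True)
    key = np.column_stack([trial_resp.astype(float), s, y])
    uniq, first, w = np.unique(key, axis=0, return_index=True, return_counts=True)
    resp_c = uniq[:, 0].astype(int)
    sc, yc = uniq[:, 1], uniq[:, 2]
    Xc = X[first]
    wc = w.astype(float)
    starts = np.flatnonzero(np.r_[1, np.diff(resp_c)])

    # optimise on standardised covariates (better conditioning), report
    # on natural scales via the linear back-transform T
    Xs, T = _standardize_design(Xc, sc, names, wc)

    glm0 = sm.GLM(
        yc, Xs, family=sm.families.Binomial(sm.families.links.Probit()),
        freq_weights=wc,
    ).fit()
    theta0 = np.concatenate([glm0.params, np.log([0.4, 0.3][: 1 + two_dims])])

    fun = lambda t: _mixed_nll_grad(t, yc, sc, Xs, wc, starts, resp_c, spec)
    res = optimize.minimize(
        fun, theta0, method="L-BFGS-B", jac=True,
        options={"maxiter": spec.max_iter, "ftol": 1e-10, "gtol": spec.gtol},
    )
    theta = res.x
    converged = bool(res.success)

    cov_std = _fd_cov(lambda t: fun(t)[1], theta)
    J = np.eye(len(theta))
    J[:p, :p] = T
    cov_nat = J @ cov_std @ J.T
    est = T @ theta[:p]
    d = np.diag(cov_nat)[:p].copy()
    d[d < 0] = np.nan
    se = np.sqrt(d)
    zq = norm.ppf(0.975)
    pvals = 2 * norm.sf(np.abs(est / se))
    coef = pd.DataFrame(
        {
            "term": names,
            "estimate": est,
            "se": se,
            "ci_low": est - zq * se,
            "ci_high": est + zq * se,
            "p": pvals,
        }
    )
    re_sd = {"intercept": float(np.exp(theta[p]))}
    if two_dims:
        re_sd["signal"] = float(np.exp(theta[p + 1]))
    return GlmSdtResult(
        coefficients=coef,
        n_obs=len(y),
        converged=converged,
        random_effects=spec.random_effects,
        re_sd=re_sd,
        loglike=float(-res.fun),
    )


def _standardize_design(Xc, sc, names, wc):
    """Build a standardised copy of the design and the linear map T with
    beta_natural = T @ beta_standardised.

    Covariate columns are centred and scaled by their (trial-weighted)
    moments; intercept and signal coding are untouched, and interaction
    columns are rebuilt as standardised-covariate x signal.
    """
    p = Xc.shape[1]
    Xs = Xc.copy().astype(float)
    T = np.eye(p)
    i_int = names.index("intercept")
    i_sig = names.index("signal") if "signal" in names else None
    for j, name in enumerate(names):
        if j in (i_int, i_sig) or name.endswith(":signal"):
            continue
        x = Xc[:, j]
        mu = np.average(x, weights=wc)
        sd = np.sqrt(np.average((x - mu) ** 2, weights=wc))
        if sd == 0:
            raise ValueError(f"covariate {name!r} is constant")
        Xs[:, j] = (x - mu) / sd
        T[j, j] = 1.0 / sd
        T[i_int, j] = -mu / sd
        if f"{name}:signal" in names:
            k = names.index(f"{name}:signal")
            Xs[:, k] = Xs[:, j] * sc
            T[k, k] = 1.0 / sd
            if i_sig is not None:
                T[i_sig, k] = -mu / sd
    return Xs, T


def _fd_cov(grad, theta, step=1e-5):
    """Parameter covariance from the observed information, obtained by
    central finite differences of the analytic score."""
    k = len(theta)
    H = np.empty((k, k))
    h = step * (1.0 + np.abs(theta))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        H[:, j] = (grad(tp) - grad(tm)) / (2 * h[j])
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((k, k), np.nan)


def glm_to_sdt(result: GlmSdtResult) -> dict[str, dict[str, float]]:
    """Translate probit coefficients into d' and criterion effects.

    Returns ``{"d_prime": {...}, "criterion": {...}}`` where the
    ``"(reference)"`` entry is the index at the covariate reference level
    and each covariate entry is the shift it induces: criterion shifts
    are the negated intercept-side coefficients, discrimination shifts
    the signal-interaction coefficients.
    """
    if not result.converged:
        raise NotConvergedError(
            "refusing to interpret a non-converged probit fit"
        )
    est = dict(zip(result.coefficients["term"], result.coefficients["estimate"]))
    d_eff = {"(reference)": est.get("signal", 0.0)}
    c_eff = {"(reference)": -est.get("intercept", 0.0)}
    for term, b in est.items():
        if term in ("intercept", "signal"):
            continue
        if term.endswith(":signal"):
            d_eff[term.removesuffix(":signal")] = b
        else:
            c_eff[term] = -b
    return {"d_prime": d_eff, "criterion": c_eff}
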