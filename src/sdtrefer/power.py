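"""Monte Carlo power analysis for indirect (mediated) effects.

Power to detect an indirect effect a*b is estimated by simulation from a
trivariate normal population for (predictor, mediator, outcome): each
replication draws n observations, fits mediator ~ predictor and
outcome ~ predictor + mediator by OLS, then draws many (a*, b*) pairs
from the normal approximations to the two coefficient sampling
distributions; the replication counts as a rejection when the percentile
interval of the products a*b* excludes zero.  Power is the rejection
fraction over replications.

The population covariance is typically not observed directly and is
reconstructed from reported summaries: a binary predictor's correlation
with the mediator from a two-sample t statistic (point-biserial
r = t / sqrt(t^2 + df)), and correlations with the outcome from
regression slopes via r = b * sd_x / sd_y, with the binary predictor's
SD equal to sqrt(p(1-p)).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

VARIABLES = ("predictor", "mediator", "outcome")


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the Monte Carlo power computation.

    correlations: 3x3 matrix over (predictor, mediator, outcome);
    sds: the three standard deviations; n: sample size per replication;
    n_reps: replications; n_draws: Monte Carlo draws per replication for
    the product interval; ci_level: nominal level of that interval.
    """

    correlations: np.ndarray
    sds: tuple[float, float, float]
    n: int = 249
    n_reps: int = 5000
    n_draws: int = 20000
    ci_level: float = 0.95
    seed: int = 1234

    def __post_init__(self):
        R = np.asarray(self.correlations, float)
        if R.shape != (3, 3):
            raise ValueError("correlations must be a 3x3 matrix")
        if not np.allclose(R, R.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must have a unit diagonal")
        _check_psd(R)
        if any(s <= 0 for s in self.sds):
            raise ValueError("standard deviations must be positive")
        if self.n < 10:
            raise ValueError("n must be >= 10")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        object.__setattr__(self, "correlations", R)

    @property
    def covariance(self) -> np.ndarray:
        s = np.asarray(self.sds, float)
        return self.correlations * np.outer(s, s)


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_se: float
    spec: PowerSpec
    n_redrawn: int = 0


def _check_psd(R: np.ndarray) -> None:
    # report the first violating leading principal minor, smallest first
    for k in (2, 3):
        minor = np.linalg.det(R[:k, :k])
        if minor < -1e-12:
            names = VARIABLES[:k]
            raise ValueError(
                "correlation matrix is not positive semidefinite: leading "
                f"minor over {names} has determinant {minor:.4g}"
            )


def derive_correlations_from_summaries(
    t_stat: float,
    df: int,
    group_ns: tuple[int, int],
    slope_mediator_outcome: float,
    slope_predictor_outcome: float,
    sds: tuple[float, float],
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Rebuild the (predictor, mediator, outcome) correlations and SDs
    from reported summaries.

    ``t_stat``/``df``/``group_ns`` describe the two-sample comparison of
    the mediator between predictor groups; the slopes are the simple
    regressions of the outcome on the mediator and on the predictor
    (total effect); ``sds`` = (sd_mediator, sd_outcome).  The binary
    predictor's SD is sqrt(p(1-p)) with p = group_ns[0] / n.

    Returns (correlation matrix, (sd_predictor, sd_mediator, sd_outcome)).
    """
    n1, n2 = group_ns
    if n1 + n2 != df + 2:
        raise ValueError(f"group sizes {group_ns} inconsistent with df={df} (need n-2)")
    sd_m, sd_y = sds
    p = n1 / (n1 + n2)
    sd_x = float(np.sqrt(p * (1.0 - p)))
    r_xm = t_stat / np.sqrt(t_stat**2 + df)
    r_my = slope_mediator_outcome * sd_m / sd_y
    r_xy = slope_predictor_outcome * sd_x / sd_y
    R = np.array(
        [[1.0, r_xm, r_xy], [r_xm, 1.0, r_my], [r_xy, r_my, 1.0]]
    )
    _check_psd(R)
    return R, (sd_x, sd_m, sd_y)


def mc_power_indirect(spec: PowerSpec, _chunk: int = 250) -> PowerResult:
    """Estimate power for the indirect effect at the spec's sample size.

    Deterministic for a fixed seed.  Replications whose OLS fits are
    singular (degenerate resampled predictors) are re-drawn and counted
    in ``n_redrawn``.
    """
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(spec.covariance + 1e-12 * np.eye(3))
    alpha = (1.0 - spec.ci_level) / 2.0
    n, n_draws = spec.n, spec.n_draws
    successes = 0
    redrawn = 0
    done = 0
    while done < spec.n_reps:
        m = min(_chunk, spec.n_reps - done)
        D = rng.standard_normal((m, n, 3)) @ L.T
        a, se_a, b, se_b, bad = _fit_paths(D)
        while bad.any():
            redrawn += int(bad.sum())
            D2 = rng.standard_normal((int(bad.sum()), n, 3)) @ L.T
            a2, se_a2, b2, se_b2, bad2 = _fit_paths(D2)
            a[bad], se_a[bad], b[bad], se_b[bad] = a2, se_a2, b2, se_b2
            idx = np.flatnonzero(bad)
            bad[idx] = bad2
        za = rng.standard_normal((m, n_draws))
        zb = rng.standard_normal((m, n_draws))
        prod = (a[:, None] + se_a[:, None] * za) * (b[:, None] + se_b[:, None] * zb)
        q = np.quantile(prod, [alpha, 1.0 - alpha], axis=1)
        successes += int(np.sum((q[0] > 0) | (q[1] < 0)))
        done += m
    power = successes / spec.n_reps
    return PowerResult(
        power=power,
        mc_se=float(np.sqrt(power * (1.0 - power) / spec.n_reps)),
        spec=spec,
        n_redrawn=redrawn,
    )


def _fit_paths(D: np.ndarray):
    """Vectorised OLS of mediator~predictor and outcome~predictor+mediator
    over a stack of replications; returns a, se_a, b, se_b and a mask of
    singular fits."""
    n = D.shape[1]
    X, M, Y = D[..., 0], D[..., 1], D[..., 2]
    Xc = X - X.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Xc, Xc)
    sxm = np.einsum("ij,ij->i", Xc, Mc)
    smm = np.einsum("ij,ij->i", Mc, Mc)
    sxy = np.einsum("ij,ij->i", Xc, Yc)
    smy = np.einsum("ij,ij->i", Mc, Yc)
    det = sxx * smm - sxm**2
    bad = ~np.isfinite(det) | (det <= 0) | (sxx <= 0)
    safe_sxx = np.where(bad, 1.0, sxx)
    safe_det = np.where(bad, 1.0, det)
    a = sxm / safe_sxx
    resid_a = Mc - a[:, None] * Xc
    se_a = np.sqrt(np.einsum("ij,ij->i", resid_a, resid_a) / (n - 2) / safe_sxx)
    bx = (smm * sxy - sxm * smy) / safe_det
    bm = (sxx * smy - sxm * sxy) / safe_det
    resid = Yc - bx[:, None] * Xc - bm[:, None] * Mc
    s2 = np.einsum("ij,ij->i", resid, resid) / (n - 3)
    se_bm = np.sqrt(s2 * safe_sxx / safe_det)
    return a, se_a, bm, se_bm, bad


def required_n_for_power(
    spec: PowerSpec,
    target_power: float,
    n_grid=None,
) -> int:
    """Smallest grid sample size whose estimated power reaches the target.

    Bisection over a monotone grid; every candidate n is evaluated with
    the same spec (hence the same fixed seed), which keeps the search
    deterministic and the power curve monotone up to Monte Carlo noise.
    """
    if not 0.0 < target_power < 1.0:
        if target_power <= 0.0:
            grid = sorted(n_grid) if n_grid is not None else [10]
            return int(grid[0])
        raise ValueError("target_power must lie in (0, 1)")
    grid = sorted(int(v) for v in (n_grid if n_grid is not None else
                                   range(50, 2001, 10)))
    cache: dict[int, float] = {}

    def power_at(n: int) -> float:
        if n not in cache:
            cache[n] = mc_power_indirect(replace(spec, n=n)).power
        return cache[n]

    hi_power = power_at(grid[-1])
    if hi_power < target_power:
        raise ValueError(
            f"target power {target_power} unreachable on the grid: maximum "
            f"achieved power {hi_power:.3f} at n={grid[-1]}"
        )
    lo, hi = 0, len(grid) - 1  # invariant: power(grid[hi]) >= target
    if power_at(grid[0]) >= target_power:
        return grid[0]
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(grid[mid]) >= target_power:
            hi = mid
        else:
            lo = mid
    return grid[hi]


def power_curve(spec: PowerSpec, ns) -> pd.DataFrame:
    """Estimated power (with Monte Carlo SE) over a range of sample sizes."""
    rows = []
    for n in ns:
        res = mc_power_indirect(replace(spec, n=int(n)))
        rows.append({"n": int(n), "power": res.power, "mc_se": res.mc_se})
    return pd.DataFrame(rows)
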