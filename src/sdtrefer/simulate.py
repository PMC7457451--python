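"""Synthetic vignette-study generator.

Produces complete studies with the statistical structure the analysis
pipeline assumes: a cohort of responders (gender, experience, practice
referral PPV/sensitivity, stress-from-uncertainty scores), a balanced
vignette set (equal numbers above and below the 3% risk threshold), and
trial-level trichotomous decisions driven by an equal-variance Gaussian
signal-detection process.

Each responder carries a true discrimination d' and criterion c; the
probability of an urgent referral is

    P(urgent | above threshold) = Phi(+d'/2 - c)
    P(urgent | below threshold) = Phi(-d'/2 - c)

the unique symmetric placement under which the population hit and
false-alarm rates invert exactly to (d', c) through the closed-form
index formulas.  Non-urgent decisions split into routine referrals and
no-referrals with a fixed conditional share, since the detection model
itself is binary.  True parameters are returned alongside the dataset so
estimator-recovery tests can compare against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .datamodel import StudyDataset, write_study

RISK_THRESHOLD = 3.0


@dataclass
class SimConfig:
    """Generator settings; defaults emulate a 252-responder, 48-vignette
    urgent-referral study for suspected colorectal cancer.

    Criterion model: c = intercept + beta_ppv * ppv + beta_gender * female
    + Normal(0, criterion_noise_sd); with the default covariate
    distributions this gives mean c about -0.29 and SD about 0.50.
    Stress scores follow the 8-item stress-from-uncertainty scale
    (assumed range [8, 48]), higher for women.
    """

    n_responders: int = 252
    n_positive_vignettes: int = 24
    n_negative_vignettes: int = 24
    task_label: str = "colorectal"
    prop_female: float = 0.52
    # experience (years in practice): lognormal matching median 13 and
    # IQR [8, 24], clipped to the observed range [1, 42]; positively skewed
    experience_log_mean: float = float(np.log(13.0))
    experience_log_sd: float = 0.8144
    experience_range: tuple[float, float] = (1.0, 42.0)
    ppv_percent_range: tuple[float, float] = (2.0, 16.0)
    sensitivity_percent_range: tuple[float, float] = (30.0, 70.0)
    d_prime_mean: float = 0.79
    d_prime_sd: float = 0.32
    criterion_intercept: float = -0.6516
    beta_ppv: float = 0.05
    beta_gender: float = -0.17
    criterion_noise_sd: float = 0.449
    routine_share_of_nonurgent: float = 1024 / 4820
    stress_mean_male: float = 26.65
    stress_gender_effect: float = 3.76
    stress_sd: float = 8.45
    stress_range: tuple[float, float] = (8.0, 48.0)
    stress_n_missing: int = 3
    prop_prior_task: float = 165 / 252
    cross_task_criterion_r: float = 0.39
    cross_task_dprime_r: float = 0.0
    cross_task_criterion_shift: float = 0.79
    cross_task_criterion_sd: float = 0.75
    cross_task_dprime_mean: float = 0.77
    cross_task_dprime_sd: float = 0.36
    seed: int = 0

    def validate(self) -> None:
        for name in ("prop_female", "routine_share_of_nonurgent", "prop_prior_task"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("cross_task_criterion_r", "cross_task_dprime_r"):
            if abs(getattr(self, name)) > 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        if self.n_responders < 1:
            raise ValueError("n_responders must be >= 1")
        if self.n_positive_vignettes < 1 or self.n_negative_vignettes < 1:
            raise ValueError("need at least one vignette of each class")
        if self.stress_n_missing > self.n_responders:
            raise ValueError("stress_n_missing exceeds n_responders")


@dataclass
class TrueParameters:
    """Ground truth stored next to every generated dataset."""

    per_responder: pd.DataFrame  # responder_id, true_d_prime, true_criterion
    coefficients: dict = field(default_factory=dict)


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from a YAML (or JSON) mapping of field overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw.items()})
    cfg.validate()
    return cfg


def decision_probability(d_prime, criterion, signal_class) -> float:
    """P(urgent) for a responder with the given true indices on a case of
    the given class (POSITIVE = above the risk threshold)."""
    sign = 1.0 if str(signal_class).upper() == "POSITIVE" else -1.0
    out = norm.cdf(sign * np.asarray(d_prime) / 2.0 - np.asarray(criterion))
    return float(out) if np.isscalar(d_prime) else out


def _log_uniform(rng, low, high, size):
    return np.exp(rng.uniform(np.log(low), np.log(high), size))


def generate_study(config: SimConfig | None = None) -> tuple[StudyDataset, TrueParameters]:
    """Generate a full synthetic study; deterministic for a fixed seed."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, n_pos, n_neg = cfg.n_responders, cfg.n_positive_vignettes, cfg.n_negative_vignettes

    # --- vignettes: risks log-uniform on either side of the 3% threshold
    pos_risk = _log_uniform(rng, RISK_THRESHOLD + 1e-6, 18.04, n_pos)
    neg_risk = _log_uniform(rng, 0.18, RISK_THRESHOLD - 1e-6, n_neg)
    vignettes = pd.DataFrame(
        {
            "vignette_id": [f"v{i + 1:02d}" for i in range(n_pos + n_neg)],
            "cancer_risk_percent": np.round(np.concatenate([pos_risk, neg_risk]), 2),
            "signal_class": ["POSITIVE"] * n_pos + ["NEGATIVE"] * n_neg,
        }
    )
    # rounding must not cross the class threshold
    risk = vignettes["cancer_risk_percent"].to_numpy()
    risk[: n_pos] = np.maximum(risk[: n_pos], 3.01)
    risk[n_pos:] = np.minimum(risk[n_pos:], 2.99)
    vignettes["cancer_risk_percent"] = risk

    # --- responders
    ids = np.array([f"r{i + 1:03d}" for i in range(n)])
    female = rng.random(n) < cfg.prop_female
    experience = np.clip(
        rng.lognormal(cfg.experience_log_mean, cfg.experience_log_sd, n),
        *cfg.experience_range,
    )
    ppv = rng.uniform(*cfg.ppv_percent_range, n)
    sens = rng.uniform(*cfg.sensitivity_percent_range, n)
    stress = np.clip(
        cfg.stress_mean_male
        + cfg.stress_gender_effect * female
        + rng.normal(0.0, cfg.stress_sd, n),
        *cfg.stress_range,
    )
    if cfg.stress_n_missing:
        # non-completion of the stress scale occurred among women
        pool = np.flatnonzero(female) if female.sum() >= cfg.stress_n_missing else np.arange(n)
        miss = rng.choice(pool, size=cfg.stress_n_missing, replace=False)
        stress[miss] = np.nan
    prior = rng.random(n) < cfg.prop_prior_task

    responders = pd.DataFrame(
        {
            "responder_id": ids,
            "gender": np.where(female, "FEMALE", "MALE"),
            "experience_years": np.round(experience, 1),
            "practice_ppv_percent": np.round(ppv, 2),
            "practice_sensitivity_percent": np.round(sens, 2),
            "stress_score": np.round(stress, 1),
            "prior_task": prior,
        }
    )

    # --- true indices
    true_d = rng.normal(cfg.d_prime_mean, cfg.d_prime_sd, n)
    true_c = (
        cfg.criterion_intercept
        + cfg.beta_ppv * ppv
        + cfg.beta_gender * female
        + rng.normal(0.0, cfg.criterion_noise_sd, n)
    )

    # --- trial-level decisions
    n_vig = n_pos + n_neg
    signal = np.array([0.5] * n_pos + [-0.5] * n_neg)
    p_urgent = norm.cdf(true_d[:, None] * signal[None, :] - true_c[:, None])
    u = rng.random((n, n_vig))
    urgent = u < p_urgent
    routine = ~urgent & (rng.random((n, n_vig)) < cfg.routine_share_of_nonurgent)
    decision = np.where(urgent, "URGENT", np.where(routine, "ROUTINE", "NONE"))

    responses = pd.DataFrame(
        {
            "responder_id": np.repeat(ids, n_vig),
            "vignette_id": np.tile(vignettes["vignette_id"].to_numpy(), n),
            "task_label": cfg.task_label,
            "decision": decision.ravel(),
        }
    )
    ds = StudyDataset.from_frames(responses, vignettes, responders, validate=False)
    truth = TrueParameters(
        per_responder=pd.DataFrame(
            {"responder_id": ids, "true_d_prime": true_d, "true_criterion": true_c}
        ),
        coefficients={
            "criterion_intercept": cfg.criterion_intercept,
            "beta_ppv": cfg.beta_ppv,
            "beta_gender": cfg.beta_gender,
            "d_prime_mean": cfg.d_prime_mean,
            "d_prime_sd": cfg.d_prime_sd,
            "seed": cfg.seed,
        },
    )
    return ds, truth


def generate_cross_task(
    params: TrueParameters,
    config: SimConfig,
    responder_ids=None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Second-task indices for the responders who did a prior task.

    Second-task criteria are drawn from a bivariate normal correlated
    with the first-task truth at ``cross_task_criterion_r`` and shifted
    by ``cross_task_criterion_shift`` (a more conservative task); d' is
    drawn with correlation ``cross_task_dprime_r`` (default independent).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    tp = params.per_responder
    if responder_ids is not None:
        tp = tp[tp["responder_id"].isin(responder_ids)]
    m = len(tp)

    def correlated(x, r, target_mean, target_sd):
        x = np.asarray(x, float)
        xsd = x.std(ddof=0)
        z = (x - x.mean()) / (xsd if xsd > 0 else 1.0)
        noise = rng.standard_normal(m)
        y = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise
        return target_mean + target_sd * y

    c2 = correlated(
        tp["true_criterion"],
        config.cross_task_criterion_r,
        tp["true_criterion"].mean() + config.cross_task_criterion_shift,
        config.cross_task_criterion_sd,
    )
    d2 = correlated(
        tp["true_d_prime"],
        config.cross_task_dprime_r,
        config.cross_task_dprime_mean,
        config.cross_task_dprime_sd,
    )
    return pd.DataFrame(
        {"responder_id": tp["responder_id"].to_numpy(), "d_prime": d2, "criterion": c2}
    )


def write_simulated_study(
    ds: StudyDataset, truth: TrueParameters, out_dir: str | Path
) -> dict[str, Path]:
    """Emit the three analysis CSVs plus truth.csv with the generating
    per-responder parameters."""
    paths = write_study(ds, out_dir)
    truth_path = Path(out_dir) / "truth.csv"
    truth.per_responder.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    return paths
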