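"""Shared fixtures: programmatic study builders and an independent
inverse-normal oracle (root-finding on the erf-based CDF, so it shares no
code path with the scipy quantile function the package uses)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from sdtrefer import StudyDataset


def z_oracle(p: float) -> float:
    """Standard-normal quantile via bisection on the erf-based CDF."""
    cdf = lambda x: 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))
    return brentq(lambda x: cdf(x) - p, -12.0, 12.0, xtol=1e-12)


def build_study(
    counts,
    n_positive: int = 24,
    n_negative: int = 24,
    routine_share: float = 0.0,
    task_label: str = "colorectal",
    responders: pd.DataFrame | None = None,
    validate: bool = True,
) -> StudyDataset:
    """Construct a study from per-responder (hits, false_alarms) counts.

    Urgent decisions fill the first `hits` positive and first
    `false_alarms` negative vignettes; a leading fraction of the
    remaining decisions becomes ROUTINE, the rest NONE.
    """
    n_vig = n_positive + n_negative
    vignettes = pd.DataFrame(
        {
            "vignette_id": [f"v{i + 1:02d}" for i in range(n_vig)],
            "cancer_risk_percent": [5.0] * n_positive + [1.0] * n_negative,
            "signal_class": ["POSITIVE"] * n_positive + ["NEGATIVE"] * n_negative,
        }
    )
    rows = []
    for i, (hits, fas) in enumerate(counts):
        rid = f"r{i + 1:03d}"
        decisions = ["URGENT"] * hits + ["_"] * (n_positive - hits)
        decisions += ["URGENT"] * fas + ["_"] * (n_negative - fas)
        non_urgent = [j for j, d in enumerate(decisions) if d == "_"]
        n_routine = int(round(routine_share * len(non_urgent)))
        for k, j in enumerate(non_urgent):
            decisions[j] = "ROUTINE" if k < n_routine else "NONE"
        for vid, dec in zip(vignettes["vignette_id"], decisions):
            rows.append((rid, vid, task_label, dec))
    responses = pd.DataFrame(
        rows, columns=["responder_id", "vignette_id", "task_label", "decision"]
    )
    if responders is None:
        responders = default_responders(len(counts))
    return StudyDataset.from_frames(responses, vignettes, responders, validate=validate)


def default_responders(n: int, seed: int = 99) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "responder_id": [f"r{i + 1:03d}" for i in range(n)],
            "gender": rng.choice(["MALE", "FEMALE"], n),
            "experience_years": rng.uniform(1, 40, n).round(1),
            "practice_ppv_percent": rng.uniform(2, 16, n).round(2),
            "practice_sensitivity_percent": rng.uniform(30, 70, n).round(2),
            "stress_score": rng.uniform(10, 46, n).round(1),
            "prior_task": rng.choice([True, False], n),
        }
    )


@pytest.fixture(scope="session")
def table1_dataset() -> StudyDataset:
    """A 252 x 48 study whose pooled margins reproduce the published
    decision tabulation: 4474/6048 urgent on positive cases, 2802/6048 on
    negative cases, and 1024 routine among the 4820 non-urgent decisions."""
    n_resp, n_pos, n_neg = 252, 24, 24
    pos_urgent = np.zeros((n_resp, n_pos), dtype=bool)
    pos_urgent.ravel()[:4474] = True
    neg_urgent = np.zeros((n_resp, n_neg), dtype=bool)
    neg_urgent.ravel()[:2802] = True
    urgent = np.concatenate([pos_urgent, neg_urgent], axis=1).ravel()
    decisions = np.where(urgent, "URGENT", "NONE").astype(object)
    non_urgent_idx = np.flatnonzero(~urgent)
    decisions[non_urgent_idx[:1024]] = "ROUTINE"

    ids = [f"r{i + 1:03d}" for i in range(n_resp)]
    vids = [f"v{i + 1:02d}" for i in range(n_pos + n_neg)]
    responses = pd.DataFrame(
        {
            "responder_id": np.repeat(ids, n_pos + n_neg),
            "vignette_id": np.tile(vids, n_resp),
            "task_label": "colorectal",
            "decision": decisions,
        }
    )
    vignettes = pd.DataFrame(
        {
            "vignette_id": vids,
            "cancer_risk_percent": [5.0] * n_pos + [1.0] * n_neg,
            "signal_class": ["POSITIVE"] * n_pos + ["NEGATIVE"] * n_neg,
        }
    )
    return StudyDataset.from_frames(
        responses, vignettes, default_responders(n_resp), validate=True
    )


@pytest.fixture
def tiny_study() -> StudyDataset:
    """Two responders x four vignettes, hand-checkable."""
    return build_study([(2, 1), (1, 0)], n_positive=2, n_negative=2)
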