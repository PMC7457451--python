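"""Equal-variance Gaussian signal detection indices.

Each responder's repeated urgent-referral decisions yield a hit rate H
(urgent referrals among cases whose risk exceeds the referral threshold)
and a false-alarm rate FA (urgent referrals among cases below it).  Under
the equal-variance Gaussian model,

    d' = z(H) - z(FA)          (discrimination)
    c  = -[z(H) + z(FA)] / 2   (criterion / response bias)

with z the standard-normal quantile function.  Negative c marks a lenient,
refer-prone decision maker; positive c a conservative one.  Because raw
rates of 0 or 1 put z outside its domain, counts are corrected by adding
0.5 to every cell (so rates become (k + 0.5) / (N + 1)) for every
responder, not only boundary cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import SignalClass, StudyDataset
from .errors import EmptyDatasetError, RateDomainError, UndefinedRatesError

INDEX_COLUMNS = [
    "responder_id", "hits", "false_alarms", "n_positive", "n_negative",
    "hit_rate", "fa_rate", "d_prime", "criterion", "corrected",
]


@dataclass(frozen=True)
class RateTable:
    """Per-responder decision counts by case class."""

    n_positive: int
    n_negative: int
    hits: int
    false_alarms: int

    def __post_init__(self):
        if not (0 <= self.hits <= self.n_positive):
            raise ValueError(f"hits {self.hits} outside [0, {self.n_positive}]")
        if not (0 <= self.false_alarms <= self.n_negative):
            raise ValueError(
                f"false_alarms {self.false_alarms} outside [0, {self.n_negative}]"
            )


@dataclass(frozen=True)
class IndexSummary:
    mean: float
    sd: float
    median: float
    min: float
    max: float
    n: int


def _check_interior(rate, name: str) -> None:
    arr = np.asarray(rate, float)
    if np.any((arr <= 0.0) | (arr >= 1.0)):
        raise RateDomainError(
            f"{name} contains values not strictly inside (0, 1); apply the "
            "0.5 count correction (corrected_rates) before computing indices"
        )


def dprime(hit_rate, fa_rate):
    """Discrimination d' = z(H) - z(FA); rates must lie strictly in (0,1)."""
    _check_interior(hit_rate, "hit_rate")
    _check_interior(fa_rate, "fa_rate")
    out = norm.ppf(hit_rate) - norm.ppf(fa_rate)
    return float(out) if np.isscalar(hit_rate) and np.isscalar(fa_rate) else out


def criterion(hit_rate, fa_rate):
    """Response bias c = -[z(H) + z(FA)] / 2; negative = refer-prone."""
    _check_interior(hit_rate, "hit_rate")
    _check_interior(fa_rate, "fa_rate")
    out = -0.5 * (norm.ppf(hit_rate) + norm.ppf(fa_rate))
    return float(out) if np.isscalar(hit_rate) and np.isscalar(fa_rate) else out


def corrected_rates(rt: RateTable) -> tuple[float, float]:
    """0.5-corrected rates: (k + 0.5) / (N + 1), always interior."""
    return (
        (rt.hits + 0.5) / (rt.n_positive + 1),
        (rt.false_alarms + 0.5) / (rt.n_negative + 1),
    )


def count_rates(ds: StudyDataset, responder_id) -> RateTable:
    """Count urgent decisions by case class for one responder."""
    m = ds.merged()
    m = m[m["responder_id"] == responder_id]
    if m.empty:
        raise UndefinedRatesError(f"responder {responder_id!r} has no responses")
    pos = m["signal_class"] == SignalClass.POSITIVE.name
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRatesError(
            f"responder {responder_id!r} lacks "
            f"{'positive' if n_pos == 0 else 'negative'}-class responses; "
            "hit/false-alarm rates are undefined"
        )
    return RateTable(
        n_positive=n_pos,
        n_negative=n_neg,
        hits=int(m.loc[pos, "urgent"].sum()),
        false_alarms=int(m.loc[~pos, "urgent"].sum()),
    )


def compute_indices(ds: StudyDataset) -> pd.DataFrame:
    """Per-responder corrected rates, d' and criterion.

    Returns one row per responder with columns ``responder_id, hits,
    false_alarms, n_positive, n_negative, hit_rate, fa_rate, d_prime,
    criterion, corrected``.  The 0.5 correction is applied to every
    responder.
    """
    if ds.n_responses == 0:
        raise EmptyDatasetError("cannot compute indices on an empty dataset")
    m = ds.merged()
    pos = (m["signal_class"] == SignalClass.POSITIVE.name).to_numpy()
    g = pd.DataFrame(
        {
            "responder_id": m["responder_id"],
            "pos": pos.astype(int),
            "neg": (~pos).astype(int),
            "hit": m["urgent"].to_numpy() * pos,
            "fa": m["urgent"].to_numpy() * ~pos,
        }
    ).groupby("responder_id", sort=True).sum()
    lacking = g[(g["pos"] == 0) | (g["neg"] == 0)]
    if len(lacking):
        raise UndefinedRatesError(
            "responder(s) lacking positive- or negative-class responses: "
            f"{lacking.index.tolist()[:5]}"
        )
    h = (g["hit"] + 0.5) / (g["pos"] + 1)
    fa = (g["fa"] + 0.5) / (g["neg"] + 1)
    zh, zfa = norm.ppf(h), norm.ppf(fa)
    return pd.DataFrame(
        {
            "responder_id": g.index,
            "hits": g["hit"].astype(int).to_numpy(),
            "false_alarms": g["fa"].astype(int).to_numpy(),
            "n_positive": g["pos"].astype(int).to_numpy(),
            "n_negative": g["neg"].astype(int).to_numpy(),
            "hit_rate": h.to_numpy(),
            "fa_rate": fa.to_numpy(),
            "d_prime": zh - zfa,
            "criterion": -0.5 * (zh + zfa),
            "corrected": True,
        }
    ).reset_index(drop=True)


def pooled_rates(ds: StudyDataset) -> tuple[float, float]:
    """Uncorrected hit and false-alarm rates over the pooled decisions."""
    if ds.n_responses == 0:
        raise EmptyDatasetError("cannot pool an empty dataset")
    m = ds.merged()
    pos = m["signal_class"] == SignalClass.POSITIVE.name
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedRatesError("pool lacks positive- or negative-class responses")
    return (
        float(m.loc[pos, "urgent"].sum()) / n_pos,
        float(m.loc[~pos, "urgent"].sum()) / n_neg,
    )


def _summary(values: np.ndarray) -> IndexSummary:
    return IndexSummary(
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        median=float(np.median(values)),
        min=float(np.min(values)),
        max=float(np.max(values)),
        n=int(len(values)),
    )


def summarize_indices(indices: pd.DataFrame) -> tuple[IndexSummary, IndexSummary]:
    """Distribution summaries (sample SD, midpoint median) of d' and c."""
    if len(indices) < 2:
        raise ValueError("need at least 2 responders to summarise indices")
    return (
        _summary(indices["d_prime"].to_numpy(float)),
        _summary(indices["criterion"].to_numpy(float)),
    )


def theoretical_roc(d_prime: float, n_points: int = 99) -> pd.DataFrame:
    """Iso-sensitivity curve: H = Phi(z(FA) + d') on an even FA grid in (0,1)."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    fa = np.linspace(0.0, 1.0, n_points + 2)[1:-1]
    return pd.DataFrame({"fa_rate": fa, "hit_rate": norm.cdf(norm.ppf(fa) + d_prime)})
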