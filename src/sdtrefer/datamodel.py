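"""Study data model: tables, validation, dichotomisation and tabulation.

A referral vignette study is held as three tables:

``responses``
    one row per responder x vignette decision, the decision being one of
    three options (urgent referral / routine referral / no referral);
``vignettes``
    one row per case description, carrying its estimated cancer risk and
    its class under the 3% national urgent-referral threshold (risk above
    3% means the guideline-appropriate decision is an urgent referral);
``responders``
    one row per participating physician, with gender, experience, the
    referral performance of their practice (positive predictive value and
    sensitivity of its urgent referrals, in percent) and an optional
    stress-from-uncertainty score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateResponseError,
    EmptyDatasetError,
    MissingColumnError,
    OrphanReferenceError,
    SignalClassMismatchError,
    UnknownLabelError,
)

RISK_THRESHOLD_PERCENT = 3.0

RESPONSE_COLUMNS = ["responder_id", "vignette_id", "task_label", "decision"]
VIGNETTE_COLUMNS = ["vignette_id", "cancer_risk_percent", "signal_class"]
RESPONDER_COLUMNS = [
    "responder_id",
    "gender",
    "experience_years",
    "practice_ppv_percent",
    "practice_sensitivity_percent",
    "stress_score",
    "prior_task",
]


class Decision(str, Enum):
    URGENT = "URGENT"
    ROUTINE = "ROUTINE"
    NONE = "NONE"


class SignalClass(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class Gender(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


def dichotomize(decision: Decision | str) -> int:
    """Collapse the three-way decision to binary: 1 = urgent referral.

    Routine referrals and no-referrals form the single "no urgent
    referral" category.
    """
    d = _parse_enum(decision, Decision, "decision")
    return 1 if d is Decision.URGENT else 0


def _parse_enum(value, enum_cls, what: str):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls[str(value).strip().upper()]
    except KeyError:
        raise UnknownLabelError(
            f"unknown {what} label {value!r}; expected one of "
            f"{[e.name for e in enum_cls]}"
        ) from None


def _normalize_enum_column(series: pd.Series, enum_cls, what: str) -> pd.Series:
    out = series.astype(str).str.strip().str.upper()
    valid = {e.name for e in enum_cls}
    bad = set(out.unique()) - valid
    if bad:
        raise UnknownLabelError(
            f"unknown {what} label(s) {sorted(bad)}; expected one of {sorted(valid)}"
        )
    return out


@dataclass
class StudyDataset:
    """Validated in-memory study: responses, vignettes and responders."""

    responses: pd.DataFrame
    vignettes: pd.DataFrame
    responders: pd.DataFrame

    @classmethod
    def from_frames(
        cls,
        responses: pd.DataFrame,
        vignettes: pd.DataFrame,
        responders: pd.DataFrame,
        validate: bool = True,
    ) -> "StudyDataset":
        ds = cls(
            responses.reset_index(drop=True),
            vignettes.reset_index(drop=True),
            responders.reset_index(drop=True),
        )
        if validate:
            ds.validate()
        return ds

    def validate(self) -> None:
        """Check schemas, enumerations and referential integrity.

        Raises a specific :class:`~sdtrefer.errors.ValidationError`
        subclass on the first problem found.  An incomplete response grid
        (a responder answering fewer vignettes than the study presents)
        is reported as a warning, not an error.
        """
        for frame, cols, name in (
            (self.responses, RESPONSE_COLUMNS, "responses"),
            (self.vignettes, VIGNETTE_COLUMNS, "vignettes"),
            (self.responders, RESPONDER_COLUMNS, "responders"),
        ):
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise MissingColumnError(f"{name} table lacks column(s) {missing}")

        self.responses["decision"] = _normalize_enum_column(
            self.responses["decision"], Decision, "decision"
        )
        self.vignettes["signal_class"] = _normalize_enum_column(
            self.vignettes["signal_class"], SignalClass, "signal_class"
        )
        self.responders["gender"] = _normalize_enum_column(
            self.responders["gender"], Gender, "gender"
        )

        risk = self.vignettes["cancer_risk_percent"].astype(float)
        expect = np.where(risk > RISK_THRESHOLD_PERCENT, "POSITIVE", "NEGATIVE")
        mismatch = self.vignettes.loc[self.vignettes["signal_class"] != expect]
        if len(mismatch):
            raise SignalClassMismatchError(
                "signal_class contradicts the "
                f"{RISK_THRESHOLD_PERCENT}% risk threshold for vignette(s) "
                f"{mismatch['vignette_id'].tolist()[:5]}"
            )

        dup = self.responses.duplicated(
            subset=["responder_id", "vignette_id", "task_label"]
        )
        if dup.any():
            first = self.responses.loc[dup].iloc[0]
            raise DuplicateResponseError(
                "duplicate (responder, vignette, task) key: "
                f"({first['responder_id']}, {first['vignette_id']}, "
                f"{first['task_label']})"
            )

        known_responders = set(self.responders["responder_id"])
        known_vignettes = set(self.vignettes["vignette_id"])
        orphan_r = set(self.responses["responder_id"]) - known_responders
        if orphan_r:
            raise OrphanReferenceError(
                f"responses reference unknown responder(s) {sorted(orphan_r)[:5]}"
            )
        orphan_v = set(self.responses["vignette_id"]) - known_vignettes
        if orphan_v:
            raise OrphanReferenceError(
                f"responses reference unknown vignette(s) {sorted(orphan_v)[:5]}"
            )
        silent = known_responders - set(self.responses["responder_id"])
        if silent:
            raise OrphanReferenceError(
                f"responder(s) with no responses: {sorted(silent)[:5]}"
            )

        counts = self.responses.groupby("responder_id").size()
        n_vig = len(self.vignettes)
        if (counts < n_vig).any():
            warnings.warn(
                f"{int((counts < n_vig).sum())} responder(s) answered fewer than "
                f"{n_vig} vignettes; analyses use the responses present",
                stacklevel=2,
            )

    def merged(self) -> pd.DataFrame:
        """Responses joined with vignette class and a binary urgent flag."""
        m = self.responses.merge(
            self.vignettes[["vignette_id", "signal_class"]],
            on="vignette_id",
            how="left",
        )
        m["urgent"] = (m["decision"] == Decision.URGENT.name).astype(int)
        return m

    @property
    def n_responders(self) -> int:
        return len(self.responders)

    @property
    def n_responses(self) -> int:
        return len(self.responses)


def read_study(
    responses_path: str | Path,
    vignettes_path: str | Path,
    responders_path: str | Path,
) -> StudyDataset:
    """Read and validate the three study CSV files.

    Files are comma-separated UTF-8 with a header row; enumerated fields
    (decision, signal class, gender) are parsed case-insensitively.  A
    blank ``stress_score`` means the responder did not complete the
    stress-from-uncertainty scale.
    """
    responses = pd.read_csv(responses_path, dtype={"responder_id": str, "vignette_id": str})
    vignettes = pd.read_csv(vignettes_path, dtype={"vignette_id": str})
    responders = pd.read_csv(responders_path, dtype={"responder_id": str})
    if "prior_task" in responders.columns:
        responders["prior_task"] = (
            responders["prior_task"]
            .astype(str)
            .str.strip()
            .str.lower()
            .map({"true": True, "false": False, "1": True, "0": False})
        )
    return StudyDataset.from_frames(responses, vignettes, responders)


def write_study(ds: StudyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset back to the documented three-file CSV schema."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "responses": out / "responses.csv",
        "vignettes": out / "vignettes.csv",
        "responders": out / "responders.csv",
    }
    ds.responses[RESPONSE_COLUMNS].to_csv(paths["responses"], index=False)
    ds.vignettes[VIGNETTE_COLUMNS].to_csv(paths["vignettes"], index=False)
    ds.responders[RESPONDER_COLUMNS].to_csv(paths["responders"], index=False)
    return paths


@dataclass
class DecisionTable:
    """Decision tabulation: urgent vs not by case class, plus the
    three-way decision breakdown with percentages of all decisions."""

    urgent_positive: int
    urgent_negative: int
    nonurgent_positive: int
    nonurgent_negative: int
    decision_counts: dict[str, int] = field(default_factory=dict)
    decision_percent: dict[str, float] = field(default_factory=dict)

    @property
    def urgent_total(self) -> int:
        return self.urgent_positive + self.urgent_negative

    @property
    def nonurgent_total(self) -> int:
        return self.nonurgent_positive + self.nonurgent_negative

    @property
    def n_positive(self) -> int:
        return self.urgent_positive + self.nonurgent_positive

    @property
    def n_negative(self) -> int:
        return self.urgent_negative + self.nonurgent_negative

    @property
    def grand_total(self) -> int:
        return self.urgent_total + self.nonurgent_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "positive_cases": [self.urgent_positive, self.nonurgent_positive,
                                   self.n_positive],
                "negative_cases": [self.urgent_negative, self.nonurgent_negative,
                                   self.n_negative],
                "total": [self.urgent_total, self.nonurgent_total, self.grand_total],
            },
            index=["urgent", "no_urgent", "total"],
        )


def tabulate_decisions(ds: StudyDataset) -> DecisionTable:
    """Cross-tabulate urgent/non-urgent decisions against case class.

    Percentages in the three-way breakdown are computed on the grand
    total and rounded to 2 decimal places.
    """
    if ds.n_responses == 0:
        raise EmptyDatasetError("cannot tabulate an empty dataset")
    m = ds.merged()
    pos = m["signal_class"] == SignalClass.POSITIVE.name
    urgent = m["urgent"] == 1
    counts = {d.name: int((m["decision"] == d.name).sum()) for d in Decision}
    total = len(m)
    return DecisionTable(
        urgent_positive=int((urgent & pos).sum()),
        urgent_negative=int((urgent & ~pos).sum()),
        nonurgent_positive=int((~urgent & pos).sum()),
        nonurgent_negative=int((~urgent & ~pos).sum()),
        decision_counts=counts,
        decision_percent={k: round(100.0 * v / total, 2) for k, v in counts.items()},
    )
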