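"""Trial-level choice data: domain types, CSV I/O, per-subject choice fractions.

The experimental unit is a T-maze trial: a rat enters one of two decision
arms, each associated with an electric shock and a food reward delivered at
fixed delays after arm entry.  A session consists of forced trials (one arm
open, to sample both contingencies) followed by free trials (the measured
decisions).  Trials on which the animal left the arm before the shock are
omissions and carry no choice.

The single interchange format of the pipeline is :class:`TrialTable`, a thin
validated wrapper around a pandas DataFrame with one row per trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the on-disk CSV schema.
CSV_COLUMNS = [
    "experiment_id",
    "subject_id",
    "session",
    "trial_index",
    "trial_type",
    "offered",
    "chosen",
    "omission",
    "side_of_target",
]

VALID_LABELS = {"EL", "LL", "EE"}


class SchemaError(ValueError):
    """CSV header or column types do not match the documented schema."""


class IntegrityError(ValueError):
    """Rows violate trial-table invariants (duplicates, omission with choice, ...)."""


class DomainError(ValueError):
    """Values outside the task's domain (unknown option labels, bad delays)."""


@dataclass(frozen=True)
class OptionSpec:
    """One T-maze arm: shock and reward timing relative to arm entry.

    Delays are seconds from arm entry.  In every design used here the reward
    follows the shock (``reward_delay > shock_delay``).
    """

    label: str
    shock_delay: float
    reward_delay: float
    reward_magnitude: int = 3
    shock_present: bool = True

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise DomainError(f"unknown option label {self.label!r}")
        if self.reward_delay <= 0:
            raise DomainError("reward_delay must be positive")
        if self.shock_delay < 0:
            raise DomainError("shock_delay must be non-negative")


@dataclass(frozen=True)
class ExperimentDesign:
    """The two options of one experiment and which option's fraction is reported.

    Experiment 1: EL (shock 1 s, reward 21 s) vs LL (shock 20 s, reward 21 s);
    experiment 2: EE (shock 1 s, reward 2 s) vs LL; experiment 3: EE vs EL.
    The reported (target) option is EL in experiment 1 and EE in 2 and 3.
    """

    experiment_id: int
    option_a: OptionSpec
    option_b: OptionSpec
    target_option: str

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2, 3):
            raise DomainError("experiment_id must be 1, 2 or 3")
        if self.target_option not in (self.option_a.label, self.option_b.label):
            raise DomainError("target_option must be one of the design's options")
        a, b = self.option_a, self.option_b
        if a.shock_delay == b.shock_delay and a.reward_delay == b.reward_delay:
            raise DomainError("options must differ in at least one delay")

    @property
    def labels(self) -> tuple[str, str]:
        return (self.option_a.label, self.option_b.label)

    def other_option(self) -> str:
        """Label of the non-target option."""
        a, b = self.labels
        return b if self.target_option == a else a


def _make_option(label: str, shock_delay: float, reward_delay: float) -> OptionSpec:
    return OptionSpec(label=label, shock_delay=shock_delay, reward_delay=reward_delay)

# Canonical timings: early shock 1 s, late shock 20 s; early reward 2 s,
# late reward 21 s after arm entry.
EL = _make_option("EL", shock_delay=1.0, reward_delay=21.0)
LL = _make_option("LL", shock_delay=20.0, reward_delay=21.0)
EE = _make_option("EE", shock_delay=1.0, reward_delay=2.0)

DESIGNS: dict[int, ExperimentDesign] = {
    1: ExperimentDesign(1, EL, LL, target_option="EL"),
    2: ExperimentDesign(2, EE, LL, target_option="EE"),
    3: ExperimentDesign(3, EE, EL, target_option="EE"),
}

#: Group sizes of the three cohorts.
GROUP_SIZES = {1: 25, 2: 20, 3: 21}


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    session: int
    trial_index: int
    trial_type: str  # "forced" | "free"
    offered: str  # "EL|LL" for free trials, single label for forced
    chosen: Optional[str]
    omission: bool
    side_of_target: str  # "left" | "right"
    experiment_id: int = 1


class TrialTable:
    """Validated collection of trials plus the design they were run under."""

    def __init__(self, df: pd.DataFrame, design: ExperimentDesign):
        self.design = design
        self.df = self._validate(df.copy(), design)

    @staticmethod
    def _validate(df: pd.DataFrame, design: ExperimentDesign) -> pd.DataFrame:
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        df = df[CSV_COLUMNS].reset_index(drop=True)
        df["session"] = df["session"].astype(int)
        df["trial_index"] = df["trial_index"].astype(int)
        df["experiment_id"] = df["experiment_id"].astype(int)
        df["subject_id"] = df["subject_id"].astype(str)
        if df["omission"].dtype != bool:
            df["omission"] = (
                df["omission"].astype(str).str.lower().map({"true": True, "false": False})
            )
            if df["omission"].isna().any():
                raise SchemaError("omission column must be true/false")
        # chosen: empty string / NaN means no choice
        df["chosen"] = df["chosen"].where(pd.notna(df["chosen"]), None)
        df["chosen"] = df["chosen"].map(lambda v: None if v in (None, "", "none") else v)

        valid = set(design.labels)
        bad_rows: list[int] = []
        for i, row in df.iterrows():
            offered = set(str(row["offered"]).split("|"))
            if not offered <= valid:
                logger.warning("row %d: unknown option label in offered=%r", i, row["offered"])
                raise DomainError(f"row {i}: unknown option label {row['offered']!r}")
            if row["trial_type"] not in ("forced", "free"):
                raise SchemaError(f"row {i}: bad trial_type {row['trial_type']!r}")
            if row["trial_type"] == "forced" and len(offered) != 1:
                bad_rows.append(i)
            if row["trial_type"] == "free" and len(offered) != 2:
                bad_rows.append(i)
            if row["omission"] and row["chosen"] is not None:
                raise IntegrityError(f"row {i}: omission trial with a recorded choice")
            if row["chosen"] is not None and row["chosen"] not in offered:
                raise IntegrityError(f"row {i}: chosen option not among offered")
            if row["chosen"] is not None and row["chosen"] not in valid:
                raise DomainError(f"row {i}: unknown chosen label {row['chosen']!r}")
            if row["side_of_target"] not in ("left", "right"):
                raise SchemaError(f"row {i}: bad side_of_target {row['side_of_target']!r}")
        if bad_rows:
            raise IntegrityError(f"rows {bad_rows}: offered arity inconsistent with trial_type")

        dup = df.duplicated(subset=["subject_id", "session", "trial_index"])
        if dup.any():
            raise IntegrityError(
                f"duplicate (subject, session, trial) keys at rows {list(df.index[dup])}"
            )
        return df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.design == other.design and self.df.equals(other.df)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject_id"]))

    def free_trials(self) -> pd.DataFrame:
        return self.df[self.df["trial_type"] == "free"]


@dataclass(frozen=True)
class SubjectChoiceSummary:
    """Per-subject reduction: percent of valid free trials on the target option.

    ``fraction_target`` is a percentage in [0, 100], or None when the subject
    has no valid free trials (explicit missing marker, never a silent 0).
    """

    subject_id: str
    n_free_valid: int
    n_omissions: int
    fraction_target: Optional[float]
    n_target: int = 0


def load_trials(path: str | Path, design: ExperimentDesign) -> TrialTable:
    """Read a trial CSV and validate it against the design.

    Raises SchemaError / IntegrityError / DomainError rather than silently
    dropping malformed rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "offered": str, "chosen": str})
    return TrialTable(df, design)


def write_trials(table: TrialTable, path: str | Path) -> None:
    """Serialize a TrialTable to CSV (fixed column order, booleans as true/false).

    ``load_trials(write_trials(t))`` round-trips exactly; repeated writes are
    byte-identical.
    """
    df = table.df.copy()
    df["omission"] = df["omission"].map({True: "true", False: "false"})
    df["chosen"] = df["chosen"].map(lambda v: "" if v is None else v)
    df.to_csv(path, index=False, columns=CSV_COLUMNS, lineterminator="\n")


def choice_fractions(table: TrialTable) -> list[SubjectChoiceSummary]:
    """Per-subject percent choice of the design's target option.

    Only free, non-omission trials count; forced trials never enter the
    fraction.  Subjects with zero valid free trials get fraction None.
    """
    if len(table) == 0:
        raise ValueError("empty trial table")
    target = table.design.target_option
    out: list[SubjectChoiceSummary] = []
    free = table.free_trials()
    for subject in table.subjects:
        sub = free[free["subject_id"] == subject]
        n_om = int(sub["omission"].sum())
        valid = sub[~sub["omission"]]
        n_valid = len(valid)
        if n_valid == 0:
            logger.warning("subject %s has no valid free trials", subject)
            out.append(SubjectChoiceSummary(subject, 0, n_om, None, 0))
            continue
        n_target = int((valid["chosen"] == target).sum())
        out.append(
            SubjectChoiceSummary(
                subject_id=subject,
                n_free_valid=n_valid,
                n_omissions=n_om,
                fraction_target=100.0 * n_target / n_valid,
                n_target=n_target,
            )
        )
    return out


def subject_counts(table: TrialTable) -> pd.DataFrame:
    """Per-subject (successes, trials) over valid free trials, for model fitting."""
    rows = []
    for s in choice_fractions(table):
        rows.append({"subject_id": s.subject_id, "k": s.n_target, "n": s.n_free_valid})
    return pd.DataFrame(rows)
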