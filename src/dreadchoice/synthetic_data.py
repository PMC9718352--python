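"""Synthetic T-maze choice data with the task's generative structure.

Two generation modes:

* **fixed-rate** (:func:`generate_binomial_cohort`) — every free-trial
  choice is an independent Bernoulli draw of the target option at a fixed
  probability.  This is the regime of the simulated theory predictions
  (p = 0.6 toward the preferred alternative, 0.4 toward the non-preferred).
* **agent** (:func:`simulate_experiment`) — per-trial choice probabilities
  come from a value theory via the softmax rule in :mod:`.value_models`.

Both modes emit the full session skeleton: 10 sessions of 6 forced trials
(3 per arm, order shuffled) followed by 16 free trials, a pseudo-random
left/right contingency schedule in which no side persists for more than two
consecutive sessions, and free-trial omissions at a configurable rate.
A single numpy Generator seeded from the spec drives everything, so an
identical spec reproduces a byte-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .choice_data import CSV_COLUMNS, DESIGNS, ExperimentDesign, TrialTable
from .value_models import TheoryParams, choice_probability, option_utility

#: Omission rates observed per experiment (fraction of free trials).
DEFAULT_OMISSION_RATES = {1: 0.0080, 2: 0.0002, 3: 0.0013}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout and choice process for one simulated experiment.

    ``p_choice`` is either a fixed Bernoulli probability of choosing the
    target option (fixed-rate mode), a per-subject sequence of such
    probabilities, or a :class:`~dreadchoice.value_models.TheoryParams`
    (agent mode, used by :func:`simulate_experiment`).
    """

    n_subjects: int = 25
    n_sessions: int = 10
    n_free_per_session: int = 16
    n_forced_per_session: int = 6
    p_choice: Union[float, Sequence[float], TheoryParams] = 0.5
    omission_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.n_sessions < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.omission_rate <= 1.0:
            raise ValueError("omission_rate must be a probability")
        if isinstance(self.p_choice, (int, float)) and not 0.0 <= self.p_choice <= 1.0:
            raise ValueError("p_choice must be a probability")


def contingency_schedule(n_sessions: int, rng: Union[int, np.random.Generator]) -> list[str]:
    """Pseudo-random left/right side of the target option across sessions.

    A side that has been constant for two consecutive sessions is reversed in
    the next one, so no side ever persists more than two sessions in a row.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sides: list[str] = []
    run = 0
    for _ in range(n_sessions):
        if run >= 2:
            side = "right" if sides[-1] == "left" else "left"
        else:
            side = "left" if rng.random() < 0.5 else "right"
        if sides and side == sides[-1]:
            run += 1
        else:
            run = 1
        sides.append(side)
    return sides


def _session_rows(
    rng: np.random.Generator,
    design: ExperimentDesign,
    subject: str,
    session: int,
    side: str,
    p_target: float,
    spec: CohortSpec,
) -> list[dict]:
    """One session: shuffled 3/3 forced split, then Bernoulli free choices."""
    target = design.target_option
    other = design.other_option()
    offered_free = "|".join(sorted(design.labels))
    n_forced = spec.n_forced_per_session
    n_half = n_forced // 2
    forced = [target] * n_half + [other] * (n_forced - n_half)
    rng.shuffle(forced)

    rows = []
    idx = 1
    for arm in forced:
        rows.append(
            dict(
                experiment_id=design.experiment_id,
                subject_id=subject,
                session=session,
                trial_index=idx,
                trial_type="forced",
                offered=arm,
                chosen=arm,
                omission=False,
                side_of_target=side,
            )
        )
        idx += 1
    for _ in range(spec.n_free_per_session):
        omit = bool(rng.random() < spec.omission_rate)
        chosen = None if omit else (target if rng.random() < p_target else other)
        rows.append(
            dict(
                experiment_id=design.experiment_id,
                subject_id=subject,
                session=session,
                trial_index=idx,
                trial_type="free",
                offered=offered_free,
                chosen=chosen,
                omission=omit,
                side_of_target=side,
            )
        )
        idx += 1
    return rows


def _build_table(spec: CohortSpec, design: ExperimentDesign, p_per_subject: np.ndarray) -> TrialTable:
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    for s in range(spec.n_subjects):
        subject = f"rat{s + 1:03d}"
        sides = contingency_schedule(spec.n_sessions, rng) if spec.n_sessions else []
        for sess in range(1, spec.n_sessions + 1):
            rows.extend(
                _session_rows(rng, design, subject, sess, sides[sess - 1], p_per_subject[s], spec)
            )
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return TrialTable(df, design)


def generate_binomial_cohort(spec: CohortSpec, design: ExperimentDesign | None = None) -> TrialTable:
    """Fixed-rate cohort: iid Bernoulli(p_choice) free-trial choices of the target.

    ``spec.p_choice`` may be a scalar (shared rate) or one rate per subject
    (e.g. rates drawn from the hierarchical model for calibration studies).
    """
    design = DESIGNS[1] if design is None else design
    if isinstance(spec.p_choice, TheoryParams):
        raise TypeError("agent-mode spec passed to generate_binomial_cohort; use simulate_experiment")
    p = np.broadcast_to(np.asarray(spec.p_choice, dtype=float), (spec.n_subjects,))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_choice entries must be probabilities")
    return _build_table(spec, design, p)


def simulate_experiment(
    design: ExperimentDesign, params: TheoryParams, spec: CohortSpec
) -> TrialTable:
    """Agent-mode cohort: softmax choices from a value theory over the design.

    The per-trial probability of the target option is
    ``choice_probability(U_target, U_other, temperature)`` with utilities
    evaluated once per design (delays do not change across trials).
    """
    target_opt = design.option_a if design.target_option == design.option_a.label else design.option_b
    other_opt = design.option_b if target_opt is design.option_a else design.option_a
    u_t = option_utility(target_opt, params)
    u_o = option_utility(other_opt, params)
    p = choice_probability(u_t, u_o, params.temperature)
    return _build_table(spec, design, np.full(spec.n_subjects, p))


def hierarchical_rates(
    n_subjects: int, mu: float, kappa: float, rng: Union[int, np.random.Generator]
) -> np.ndarray:
    """Per-subject choice rates drawn from the mode-parameterized beta group model.

    theta_s ~ Beta(mu*(kappa-2)+1, (1-mu)*(kappa-2)+1); used to build
    heterogeneous cohorts whose true group-level mode is ``mu``.
    """
    if kappa < 2:
        raise ValueError("kappa must be >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a = mu * (kappa - 2.0) + 1.0
    b = (1.0 - mu) * (kappa - 2.0) + 1.0
    return rng.beta(a, b, size=n_subjects)
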