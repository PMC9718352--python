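"""Null-hypothesis test battery: one-sample t vs 50% chance, and two-way
repeated-measures ANOVAs on block factors.

Two blockings of the free-trial choice percentages are analyzed per
experiment: trial blocks (free trials 1–8 vs 9–16 of each session, crossed
with session 1..10) and session blocks (sessions 1–5 vs 6–10, crossed with
session order 1..5 within each block).  The ANOVA is the classical fully
within-subject two-way decomposition with each effect tested against its own
subject-by-effect error stratum; partial eta^2 = SS_effect / (SS_effect +
SS_error).  Mauchly's sphericity test (via pingouin) is run for factors with
three or more levels, and Greenhouse–Geisser corrected degrees of freedom
are reported when it rejects at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .choice_data import TrialTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean: float
    sem: float

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p, "mean": self.mean, "sem": self.sem}


@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df_num: float
    df_den: float
    p: float
    eta_sq: float
    ss: float = 0.0
    ss_err: float = 0.0
    gg_epsilon: Optional[float] = None
    df_num_gg: Optional[float] = None
    df_den_gg: Optional[float] = None
    p_gg: Optional[float] = None
    sphericity_violated: bool = False


@dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, EffectResult]
    n_subjects: int
    n_dropped: int
    ss_subjects: float = 0.0
    ss_total: float = 0.0

    def to_dict(self) -> dict:
        return {
            name: {
                "F": e.F,
                "df_num": e.df_num,
                "df_den": e.df_den,
                "p": e.p,
                "eta_sq": e.eta_sq,
                "gg_epsilon": e.gg_epsilon,
                "p_gg": e.p_gg,
            }
            for name, e in self.effects.items()
        }


def one_sample_t(values, chance: float = 50.0) -> TTestResult:
    """Two-tailed one-sample t-test of per-subject percentages against chance."""
    x = np.asarray([v for v in values if v is not None], dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two subjects")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(x, popmean=chance)
    return TTestResult(
        t=float(res.statistic),
        df=len(x) - 1,
        p=float(res.pvalue),
        mean=float(x.mean()),
        sem=float(stats.sem(x)),
    )


def block_aggregate(table: TrialTable, blocking: str) -> pd.DataFrame:
    """Per-subject per-cell percent target choices under the stated blocking.

    ``blocking='trial_block'``: factor A = free-trial block within session
    (trials 1–8 vs 9–16), factor B = session (1..n).  ``'session_block'``:
    factor A = session block (first vs second half of sessions), factor B =
    session order within the block.  Cells with no valid free trials hold NaN
    (explicit missing marker).

    Returns a tidy frame with columns (subject_id, a, b, percent).
    """
    if blocking not in ("trial_block", "session_block"):
        raise ValueError("blocking must be 'trial_block' or 'session_block'")
    free = table.free_trials().copy()
    target = table.design.target_option
    # serial position among free trials within (subject, session)
    free["free_pos"] = free.groupby(["subject_id", "session"]).cumcount() + 1
    n_sessions = int(free["session"].max())

    if blocking == "trial_block":
        free["a"] = np.where(free["free_pos"] <= 8, 1, 2)
        free["b"] = free["session"]
        levels_b = range(1, n_sessions + 1)
    else:
        half = n_sessions // 2
        free["a"] = np.where(free["session"] <= half, 1, 2)
        free["b"] = np.where(
            free["session"] <= half, free["session"], free["session"] - half
        )
        levels_b = range(1, half + 1)

    valid = free[~free["omission"]]
    rows = []
    for subject in table.subjects:
        sub = valid[valid["subject_id"] == subject]
        for a in (1, 2):
            for b in levels_b:
                cell = sub[(sub["a"] == a) & (sub["b"] == b)]
                if len(cell) == 0:
                    logger.warning("empty cell: subject=%s a=%d b=%d", subject, a, b)
                    pct = np.nan
                else:
                    pct = 100.0 * float((cell["chosen"] == target).mean())
                rows.append({"subject_id": subject, "a": a, "b": b, "percent": pct})
    return pd.DataFrame(rows)


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the covariance of within-subject levels."""
    import pingouin as pg

    df = pd.DataFrame(wide)
    return float(pg.epsilon(df, correction="gg"))


def _mauchly_pvalue(wide: np.ndarray) -> float:
    import pingouin as pg

    spher = pg.sphericity(pd.DataFrame(wide), method="mauchly")
    return float(spher.pval)


def rm_anova(cells: pd.DataFrame, alpha: float = 0.05) -> AnovaResult:
    """Two-way fully-within-subject ANOVA on a tidy (subject_id, a, b, percent) frame.

    Subjects with any missing cell are dropped listwise (with a warning, and
    correspondingly reduced error degrees of freedom).  Each within factor and
    the interaction are tested against their own subject-interaction error
    stratum.  Greenhouse–Geisser correction is applied to effects whose
    factor has >= 3 levels iff Mauchly's test rejects at ``alpha``.
    """
    wide = cells.pivot_table(index="subject_id", columns=["a", "b"], values="percent")
    complete = wide.dropna(axis=0)
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.warning("dropping %d subject(s) with missing cells", n_dropped)
    n = len(complete)
    if n < 2:
        raise ValueError("need at least two complete subjects")

    a_levels = sorted({a for a, _ in complete.columns})
    b_levels = sorted({b for _, b in complete.columns})
    p, q = len(a_levels), len(b_levels)
    if p < 2 or q < 2:
        raise ValueError("need at least two levels per factor")
    # data cube: subjects x a x b
    y = np.empty((n, p, q))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            y[:, i, j] = complete[(a, b)].to_numpy()

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * q * float(((m_a - grand) ** 2).sum())
    ss_b = n * p * float(((m_b - grand) ** 2).sum())
    ss_ab = n * float(
        ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    )
    ss_s = p * q * float(((m_s - grand) ** 2).sum())
    ss_sa = q * float(((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum())
    ss_sb = p * float(((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_sab = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_sa - ss_sb

    def effect(name: str, ss_eff: float, df_eff: int, ss_err: float, df_err: int,
               wide_for_sphericity: Optional[np.ndarray]) -> EffectResult:
        # squash float dust: an effect whose SS is numerically null has F = 0
        tol = 1e-12 * max(ss_tot, 1.0)
        ss_eff = 0.0 if ss_eff < tol else ss_eff
        ss_err = 0.0 if ss_err < tol else ss_err
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err > 0:
            F = ms_eff / ms_err
        else:
            F = 0.0 if ms_eff == 0.0 else np.inf
        pval = float(stats.f.sf(F, df_eff, df_err))
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        eps = dfn_gg = dfd_gg = p_gg = None
        violated = False
        if wide_for_sphericity is not None and wide_for_sphericity.shape[1] >= 3:
            eps = _gg_epsilon(wide_for_sphericity)
            violated = _mauchly_pvalue(wide_for_sphericity) < alpha
            dfn_gg, dfd_gg = df_eff * eps, df_err * eps
            p_gg = float(stats.f.sf(F, dfn_gg, dfd_gg))
        return EffectResult(
            name=name, F=float(F), df_num=df_eff, df_den=df_err, p=pval, eta_sq=float(eta),
            ss=float(ss_eff), ss_err=float(ss_err),
            gg_epsilon=eps, df_num_gg=dfn_gg, df_den_gg=dfd_gg, p_gg=p_gg,
            sphericity_violated=violated,
        )

    # sphericity is assessed on the subject x level means of each factor
    effects = {
        "a": effect("a", ss_a, p - 1, ss_sa, (n - 1) * (p - 1), m_sa if p >= 3 else None),
        "b": effect("b", ss_b, q - 1, ss_sb, (n - 1) * (q - 1), m_sb if q >= 3 else None),
        "a*b": effect("a*b", ss_ab, (p - 1) * (q - 1), ss_sab, (n - 1) * (p - 1) * (q - 1), None),
    }
    return AnovaResult(
        effects=effects, n_subjects=n, n_dropped=n_dropped,
        ss_subjects=float(ss_s), ss_total=float(ss_tot),
    )
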