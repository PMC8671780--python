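"""Task payoffs and behavioral statistics of the deception game.

Covers the Sender/Receiver scoring rules of the incentivized stage, the
per-participant behavioral summary (lie rate, successful lying, detection,
reaction times), the cohort-level logistic trend of lying over time with
cluster-robust (sandwich) standard errors, the percentage-bend robust
correlation, and the machine-vs-human detection comparison.

Trial outcome codes combine the Sender's act and the Receiver's judgment:
L-T (lied, believed), L-L (lied, caught), T-T (truthful, believed),
T-L (truthful, disbelieved).  In the incentivized stage the Sender earns
6 points for L-T, 4 for T-L and 2 otherwise; the Receiver earns 4 points
for a correct judgment (T-T, L-L) and 0 otherwise; each point is worth
0.2 NIS.  The non-incentivized stage pays nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import TrialEvents

POINT_VALUE_NIS = 0.2

#: Sender / Receiver points per outcome code, incentivized stage only
SENDER_POINTS = {"LT": 6, "TL": 4, "TT": 2, "LL": 2}
RECEIVER_POINTS = {"TT": 4, "LL": 4, "LT": 0, "TL": 0}


@dataclass(frozen=True)
class TrialOutcome:
    sender_lied: bool
    receiver_said_lie: bool
    stage: int

    @property
    def outcome_code(self) -> str:
        return ("L" if self.sender_lied else "T") + ("L" if self.receiver_said_lie else "T")

    @classmethod
    def from_events(cls, tr: TrialEvents) -> "TrialOutcome":
        return cls(sender_lied=tr.is_lie, receiver_said_lie=tr.receiver_said_lie,
                   stage=tr.stage)


def score_trial(outcome: TrialOutcome) -> tuple[int, int]:
    """(sender_points, receiver_points) for one trial; stage 1 pays (0, 0)."""
    if outcome.stage == 1:
        return (0, 0)
    code = outcome.outcome_code
    return (SENDER_POINTS[code], RECEIVER_POINTS[code])


def points_to_money(points: int | float) -> float:
    """Points to NIS at 0.2 NIS per point."""
    if points < 0:
        raise ValueError("points must be non-negative")
    return POINT_VALUE_NIS * points


@dataclass
class ParticipantBehavior:
    """Behavioral summary of one participant's Sender trials.

    ``successful_lying_rate`` is L-T / all lie trials (the complement of
    the detection rate L-L / all lies); both are NaN-marked when the
    participant never lied.  Reaction times: sender RT = speech onset -
    stimulus onset; receiver RT = response onset - speech onset.
    """

    lie_rate: float
    successful_lying_rate: float
    detection_rate: float
    rt_sender_truth_s: float
    rt_sender_lie_s: float
    rt_receiver_truth_s: float
    rt_receiver_lie_s: float
    n_trials: int
    outcome_counts: dict
    sender_points: int
    sender_earnings_nis: float
    max_classifier_accuracy: float = float("nan")


def summarize_behavior(trials: Sequence[TrialEvents]) -> ParticipantBehavior:
    """Rates, reaction times and earnings from one participant's event log."""
    if not trials:
        raise ValueError("need at least one trial")
    outcomes = [TrialOutcome.from_events(t) for t in trials]
    codes = [o.outcome_code for o in outcomes]
    counts = {c: codes.count(c) for c in ("LT", "LL", "TT", "TL")}
    n = len(trials)
    n_lie = counts["LT"] + counts["LL"]
    lie = np.array([t.is_lie for t in trials])
    rt_snd = np.array([t.t_speech_s - t.t_stimulus_s for t in trials])
    rt_rcv = np.array([t.t_response_s - t.t_speech_s for t in trials])

    def _mean(x):
        return float(np.mean(x)) if x.size else float("nan")

    pts = sum(score_trial(o)[0] for o in outcomes)
    return ParticipantBehavior(
        lie_rate=n_lie / n,
        successful_lying_rate=counts["LT"] / n_lie if n_lie else float("nan"),
        detection_rate=counts["LL"] / n_lie if n_lie else float("nan"),
        rt_sender_truth_s=_mean(rt_snd[~lie]),
        rt_sender_lie_s=_mean(rt_snd[lie]),
        rt_receiver_truth_s=_mean(rt_rcv[~lie]),
        rt_receiver_lie_s=_mean(rt_rcv[lie]),
        n_trials=n,
        outcome_counts=counts,
        sender_points=pts,
        sender_earnings_nis=points_to_money(pts),
    )


def lie_trend_model(trials: pd.DataFrame) -> dict:
    """Logistic regression of lying on trial number and incentives with
    standard errors clustered per participant.

    ``trials`` needs columns lied (0/1), trial_idx, has_incentive (0/1)
    and participant_id.  The sandwich covariance applies the G/(G-1)
    small-sample cluster correction.  Raises on degenerate outcomes.
    """
    import statsmodels.api as sm

    df = trials
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants to cluster errors")
    y = df["lied"].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome does not vary")
    X = sm.add_constant(df[["trial_idx", "has_incentive"]].astype(float))
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(cov_type="cluster",
                    cov_kwds={"groups": df["participant_id"].to_numpy()})
    ci = res.conf_int()
    return {
        "coef": dict(res.params),
        "se": dict(res.bse),
        "p": dict(res.pvalues),
        "conf_int": {k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in ci.index},
        "n_participants": int(df["participant_id"].nunique()),
        "n_trials": int(len(df)),
    }


def bend_correlation(x, y, beta: float = 0.2) -> tuple[float, float]:
    """Percentage-bend correlation (Wilcox) with bend constant ``beta``.

    Marginal observations beyond the (1 - beta) quantile of absolute
    deviation from the median are down-weighted; the p-value uses the
    Student-t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length samples of size >= 4")
    X = np.column_stack([x, y])
    n = x.size
    M = np.median(X, axis=0)
    W = np.sort(np.abs(X - M), axis=0)
    m = int((1 - beta) * n)
    omega = W[m - 1, :]
    if np.any(omega <= 0):
        raise ValueError("zero scale: too many tied values")
    a = np.zeros((2, n))
    for c in (0, 1):
        psi = (X[:, c] - M[c]) / omega[c]
        lo, hi = psi < -1, psi > 1
        s = X[:, c].copy()
        s[lo | hi] = 0.0
        pbos = (s.sum() + omega[c] * (hi.sum() - lo.sum())) / (n - lo.sum() - hi.sum())
        a[c] = np.clip((X[:, c] - pbos) / omega[c], -1.0, 1.0)
    r = float((a[0] * a[1]).sum() / np.sqrt((a[0] ** 2).sum() * (a[1] ** 2).sum()))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    tval = r * math.sqrt((n - 2) / (1 - r**2))
    pval = 2 * stats.t.sf(abs(tval), n - 2)
    return r, float(pval)


def machine_vs_human(
    max_classifier_accuracy,
    human_detection,
    successful_lying_rate=None,
) -> dict:
    """Compare machine and human lie detection across participants.

    Paired two-tailed t-test of the classifier's per-participant maximal
    DDM accuracy against the human detection rate, plus the correlation
    (percentage-bend and Spearman) between classifier accuracy and the
    Sender's successful-lying rate (defaults to 1 - human detection).
    """
    acc = np.asarray(max_classifier_accuracy, dtype=float)
    det = np.asarray(human_detection, dtype=float)
    if acc.size != det.size or acc.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    success = (1.0 - det if successful_lying_rate is None
               else np.asarray(successful_lying_rate, dtype=float))
    t, p = stats.ttest_rel(acc, det)
    if np.isnan(t):  # identical vectors: zero difference everywhere
        t, p = 0.0, 1.0
    r_b, p_b = bend_correlation(acc, success)
    rho, p_s = stats.spearmanr(acc, success)
    return {
        "paired_t": float(t), "paired_p": float(p),
        "bend_r": r_b, "bend_p": p_b,
        "spearman_r": float(rho), "spearman_p": float(p_s),
        "n": int(acc.size),
    }
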