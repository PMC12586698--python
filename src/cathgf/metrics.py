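"""Belief-derived trial regressors: surprise, uncertainties, task indicators.

Four quantities are read out of the filter on every trial and, together with
two task indicators, drive the reaction-time response model:

* **surprise** — Shannon surprise, the negative log predicted probability of
  the observed category under the normalised transition matrix row of the
  previous stimulus (nats);
* **expected uncertainty** — the predicted outcome variance of the observed
  transition's binary node, ``S(mu_hat) * (1 - S(mu_hat))``, scaled by the
  imprecision ``1 / pi_hat`` of the belief tracking that transition;
* **unexpected uncertainty** — expected uncertainty further scaled by the
  anticipated environmental volatility ``exp(omega)``;
* **post_error / post_reversal** — whether the previous trial was answered
  incorrectly (or missed), and whether the probability reversal has
  occurred (session "post").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hgf import BeliefTrajectory, sigmoid, volatility

__all__ = [
    "surprise",
    "expected_uncertainty",
    "unexpected_uncertainty",
    "regressor_table",
    "participant_mean_pe",
    "REGRESSOR_COLUMNS",
]

REGRESSOR_COLUMNS = [
    "surprise",
    "u_expected",
    "u_unexpected",
    "post_error",
    "post_reversal",
]

LN4 = float(np.log(4.0))


def surprise(predicted_row, observed: int) -> float:
    """Shannon surprise of the observed category (nats).

    ``predicted_row`` is the predicted probability distribution over the
    four categories; ``observed`` is the 1-based observed category.
    """
    row = np.asarray(predicted_row, dtype=float)
    if row.shape != (4,):
        raise ValueError(f"predicted_row must have 4 entries; got {row.shape}")
    if not np.isclose(row.sum(), 1.0, atol=1e-6):
        raise ValueError(f"predicted_row must sum to 1; sums to {row.sum()}")
    if observed not in (1, 2, 3, 4):
        raise ValueError(f"observed category must be 1-4; got {observed}")
    p = row[observed - 1]
    if p <= 0:
        raise ValueError("predicted probability of the observed category is 0")
    return float(-np.log(p))


def expected_uncertainty(mu_hat: float, pi: float) -> float:
    """Outcome variance of the predicted transition scaled by imprecision."""
    if not pi > 0:
        raise ValueError(f"precision must be positive; got {pi}")
    s = sigmoid(mu_hat)
    return float(s * (1.0 - s) / pi)


def unexpected_uncertainty(mu_hat: float, pi: float, omega: float) -> float:
    """Expected uncertainty amplified by the anticipated volatility exp(omega)."""
    return expected_uncertainty(mu_hat, pi) * volatility(omega)


def regressor_table(trajectory: BeliefTrajectory, trials: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-trial response-model regressors.

    Surprise comes from the normalised prediction row of the previous
    stimulus; the uncertainties are evaluated at the node of the observed
    transition using its pre-update predicted state (``mu_hat``,
    ``pi_hat``), the only belief available before the outcome. On the first
    trial of each session there is no defined transition: surprise is set to
    ln 4 (the uniform four-way prediction) and both uncertainties to 0, so
    the table has no gaps; ``post_error`` is 0 there as well.

    ``trials`` must align with the trajectory row-for-row and provide
    ``session`` and ``correct`` columns (missing correctness counts as an
    error for the post-error indicator).
    """
    n = trajectory.n_trials
    if len(trials) != n:
        raise ValueError(
            f"trial table ({len(trials)} rows) does not match trajectory "
            f"({n} trials)"
        )
    trials = trials.reset_index(drop=True)
    omega = trajectory.params.omega

    s = np.full(n, LN4)
    ue = np.zeros(n)
    uu = np.zeros(n)
    has_transition = trajectory.observed_from > 0
    for t in np.flatnonzero(has_transition):
        i = trajectory.observed_from[t] - 1
        j = trajectory.observed_to[t] - 1
        s[t] = surprise(trajectory.predicted[t, i], j + 1)
        ue[t] = expected_uncertainty(
            trajectory.mu_hat[t, i, j], trajectory.pi_hat[t, i, j]
        )
        uu[t] = ue[t] * volatility(omega)

    correct = trials["correct"].to_numpy(dtype=object)
    prev_ok = np.array([c is True or c == 1 for c in correct], dtype=bool)
    post_error = np.zeros(n, dtype=np.int64)
    post_error[1:] = ~prev_ok[:-1]
    post_error[~has_transition] = 0  # first trial of each session

    post_reversal = (
        trials["session"].astype(str).str.lower().eq("post").to_numpy(np.int64)
    )

    table = pd.DataFrame(
        {
            "trial": trials["trial"].to_numpy()
            if "trial" in trials
            else np.arange(1, n + 1),
            "surprise": s,
            "u_expected": ue,
            "u_unexpected": uu,
            "post_error": post_error,
            "post_reversal": post_reversal,
        }
    )
    trajectory.regressors = table
    return table


def participant_mean_pe(trajectory: BeliefTrajectory) -> float:
    """Participant-level mean high-level prediction error.

    For each of the 16 transition nodes, |delta| is averaged over the trials
    on which that node was updated; the 16 node means are then averaged.
    The absolute value is used because signed binary prediction errors
    average toward zero by construction, whereas this summary is meant to
    index the magnitude of belief updating.
    """
    if trajectory.n_trials == 0:
        raise ValueError("empty trajectory")
    updated = np.isfinite(trajectory.delta)
    n_updates = updated.sum(axis=0)
    if np.any(n_updates == 0):
        silent = [
            (i + 1, j + 1)
            for i, j in zip(*np.nonzero(n_updates == 0))
        ]
        raise ValueError(f"nodes never updated: {silent}")
    with np.errstate(invalid="ignore"):
        node_means = np.nanmean(np.abs(trajectory.delta), axis=0)
    return float(node_means.mean())
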