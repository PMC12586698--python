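"""Categorical state-transition hierarchical Gaussian filter (HGF).

The filter tracks the probabilities of all 16 transitions between the four
stimulus categories. Each transition (i, j) has a binary occurrence node
(did i -> j happen on this trial?) whose tendency is tracked by a continuous
node holding a Gaussian belief over the transition's log-odds. A single
log-volatility parameter ``omega``, shared by all 16 continuous nodes, sets
how quickly those beliefs are expected to drift, i.e. how fast the filter
forgets.

Per trial, for every node:

    prediction   mu_hat = mu,  pi_hat = 1 / (1/pi + exp(omega))

and, for the four nodes of the active row i = previous stimulus (the binary
outcome is 1 for the observed transition, 0 for its three siblings):

    update       b_hat = logistic(mu_hat)
                 delta = outcome - b_hat
                 pi    = pi_hat + b_hat * (1 - b_hat)
                 mu    = mu_hat + delta / pi

Nodes in inactive rows keep their predicted state as the new posterior.
The 4x4 matrix of expected transition probabilities is obtained by passing
the predicted means through the logistic and normalising each row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "HGFParameters",
    "NodeState",
    "BeliefTrajectory",
    "init_network",
    "predict_step",
    "update_step",
    "normalized_prediction",
    "filter_trials",
]

N_CATEGORIES = 4
N_NODES = N_CATEGORIES * N_CATEGORIES

#: Clamp on exp(omega) so extreme volatilities cannot overflow.
MAX_VOLATILITY = 1e12
#: Floor on precisions.
MIN_PRECISION = 1e-12


def sigmoid(x):
    """Numerically stable logistic function (vectorised)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def volatility(omega: float) -> float:
    """Predicted volatility Omega = exp(omega), clamped against overflow."""
    return float(min(np.exp(min(omega, 700.0)), MAX_VOLATILITY))


@dataclass(frozen=True)
class HGFParameters:
    """Perceptual parameters of the transition filter.

    omega : float
        Log-volatility shared by all 16 continuous nodes. Higher values mean
        faster forgetting and larger belief updates.
    mu0, pi0 : float
        Initial mean and precision of every log-odds belief. The defaults
        (0, 1) start the filter at a uniform transition matrix; they are held
        fixed during fitting, leaving omega as the only free perceptual
        parameter.
    """

    omega: float
    mu0: float = 0.0
    pi0: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.omega):
            raise ValueError(f"omega must be finite; got {self.omega}")
        if not (np.isfinite(self.pi0) and self.pi0 > 0):
            raise ValueError(f"pi0 must be positive; got {self.pi0}")
        if not np.isfinite(self.mu0):
            raise ValueError(f"mu0 must be finite; got {self.mu0}")


@dataclass(frozen=True)
class NodeState:
    """Gaussian belief of one transition node.

    ``mu``/``pi`` are the posterior mean and precision, ``mu_hat``/``pi_hat``
    the prediction for the upcoming trial, and ``delta`` the binary
    prediction error of the last update (NaN when the node was not updated).
    """

    mu: float
    pi: float
    mu_hat: float = np.nan
    pi_hat: float = np.nan
    delta: float = np.nan


def init_network(params: HGFParameters) -> np.ndarray:
    """Instantiate the 4x4 grid of transition nodes at the initial belief."""
    grid = np.empty((N_CATEGORIES, N_CATEGORIES), dtype=object)
    for i in range(N_CATEGORIES):
        for j in range(N_CATEGORIES):
            grid[i, j] = NodeState(mu=params.mu0, pi=params.pi0)
    return grid


def predict_step(state: NodeState, params: HGFParameters) -> NodeState:
    """Propagate one node's belief through elapsed-time volatility.

    The mean is carried forward unchanged (no drift); the predicted precision
    shrinks because the underlying log-odds is assumed to have diffused with
    variance exp(omega) since the last trial.
    """
    if not state.pi > 0:
        raise ValueError(f"precision must be positive; got {state.pi}")
    pi_hat = max(1.0 / (1.0 / state.pi + volatility(params.omega)), MIN_PRECISION)
    return replace(state, mu_hat=state.mu, pi_hat=pi_hat)


def update_step(state: NodeState, observed: int) -> NodeState:
    """Update one node's belief after observing its binary outcome.

    The update is precision-weighted: it is larger when the prediction error
    is large and when the current belief is imprecise.
    """
    if observed not in (0, 1):
        raise ValueError(f"observed must be 0 or 1; got {observed}")
    if not (np.isfinite(state.mu_hat) and state.pi_hat > 0):
        raise ValueError("predict_step must run before update_step")
    b_hat = sigmoid(state.mu_hat)
    delta = observed - b_hat
    pi = state.pi_hat + b_hat * (1.0 - b_hat)
    mu = state.mu_hat + delta / pi
    return NodeState(mu=mu, pi=pi, mu_hat=state.mu_hat, pi_hat=state.pi_hat,
                     delta=delta)


def normalized_prediction(mu_hat: np.ndarray) -> np.ndarray:
    """Map predicted log-odds means to a row-stochastic transition matrix.

    Entry (i, j) is ``logistic(mu_hat[i, j])`` normalised within row i, so
    each row is the model's predicted distribution over the next category
    given previous category i.
    """
    mu_hat = _as_mu_array(mu_hat)
    s = sigmoid(mu_hat)
    return s / s.sum(axis=1, keepdims=True)


def _as_mu_array(grid) -> np.ndarray:
    """Accept either a float array of means or an object grid of NodeState."""
    arr = np.asarray(grid)
    if arr.dtype == object:
        arr = np.array([[node.mu_hat for node in row] for row in grid], dtype=float)
    if arr.shape != (N_CATEGORIES, N_CATEGORIES):
        raise ValueError(f"expected a 4x4 array; got shape {arr.shape}")
    return arr.astype(float)


@dataclass
class BeliefTrajectory:
    """Trial-by-trial record of the filter's beliefs over a stimulus stream.

    All node arrays have shape ``(n_trials, 4, 4)`` with axis 1 the
    from-category and axis 2 the to-category (0-based indices for 1-based
    categories). ``delta`` is NaN for nodes that were not updated on a trial.
    ``observed_from``/``observed_to`` give the 1-based observed transition,
    or -1 on trials with no defined transition (the first trial of each
    session). ``predicted`` holds the normalised transition matrix that was
    in force *before* the trial's outcome was seen.
    """

    stimuli: np.ndarray
    sessions: np.ndarray
    params: HGFParameters
    mu: np.ndarray
    pi: np.ndarray
    mu_hat: np.ndarray
    pi_hat: np.ndarray
    delta: np.ndarray
    predicted: np.ndarray
    observed_from: np.ndarray
    observed_to: np.ndarray
    regressors: pd.DataFrame | None = None

    @property
    def n_trials(self) -> int:
        return len(self.stimuli)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per trial x node."""
        t, i, j = np.meshgrid(
            np.arange(self.n_trials), np.arange(4), np.arange(4), indexing="ij"
        )
        return pd.DataFrame(
            {
                "trial": t.ravel() + 1,
                "from": i.ravel() + 1,
                "to": j.ravel() + 1,
                "mu": self.mu.ravel(),
                "pi": self.pi.ravel(),
                "mu_hat": self.mu_hat.ravel(),
                "pi_hat": self.pi_hat.ravel(),
                "delta": self.delta.ravel(),
            }
        )

    def summary(self) -> dict:
        """Compact JSON-ready summary of the run."""
        from .metrics import participant_mean_pe

        return {
            "n_trials": int(self.n_trials),
            "omega": float(self.params.omega),
            "final_predicted_matrix": self.predicted[-1].round(6).tolist(),
            "mean_abs_delta": float(participant_mean_pe(self)),
        }

    def plot_transition_probabilities(self, ax=None):
        """Plot the 16 predicted transition probabilities over trials."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        trials = np.arange(1, self.n_trials + 1)
        for i in range(4):
            for j in range(4):
                ax.plot(trials, self.predicted[:, i, j], lw=0.8,
                        label=f"{i + 1}→{j + 1}")
        ax.set_xlabel("trial")
        ax.set_ylabel("predicted transition probability")
        ax.set_ylim(0, 1)
        ax.legend(ncol=4, fontsize=6)
        return ax


def filter_trials(
    stimuli,
    params: HGFParameters,
    sessions=None,
) -> BeliefTrajectory:
    """Run the transition HGF over a stimulus stream.

    Per trial t >= 2 all 16 nodes make a volatility prediction, the
    normalised transition matrix is recorded, and the four nodes of the row
    of the previous stimulus are updated (outcome 1 for the observed
    transition, 0 for its siblings); inactive rows adopt their predicted
    state as the posterior. Trial 1 records the initial prediction and makes
    no update. When ``sessions`` is given, the first trial of every session
    is treated like trial 1 — beliefs carry over the break, time passes (the
    prediction still runs), but no between-session transition is scored.

    Parameters
    ----------
    stimuli : sequence of int
        Stimulus categories, 1-based (values in {1, 2, 3, 4}).
    params : HGFParameters
    sessions : sequence of str, optional
        Per-trial session labels; session boundaries are where the label
        changes. Omit for a single uninterrupted stream.
    """
    stim = np.asarray(stimuli, dtype=np.int64)
    if stim.ndim != 1 or len(stim) == 0:
        raise ValueError("stimuli must be a non-empty 1-d sequence")
    bad = np.setdiff1d(np.unique(stim), np.arange(1, 5))
    if bad.size:
        raise ValueError(f"invalid stimulus categories: {bad.tolist()}")
    n = len(stim)
    if sessions is None:
        sess = np.full(n, "all", dtype=object)
    else:
        sess = np.asarray(sessions, dtype=object)
        if len(sess) != n:
            raise ValueError("sessions and stimuli must have equal length")
    new_session = np.zeros(n, dtype=bool)
    new_session[0] = True
    new_session[1:] = sess[1:] != sess[:-1]

    omg = volatility(params.omega)
    mu = np.full((4, 4), float(params.mu0))
    pi = np.full((4, 4), float(params.pi0))

    tr = BeliefTrajectory(
        stimuli=stim,
        sessions=sess,
        params=params,
        mu=np.empty((n, 4, 4)),
        pi=np.empty((n, 4, 4)),
        mu_hat=np.empty((n, 4, 4)),
        pi_hat=np.empty((n, 4, 4)),
        delta=np.full((n, 4, 4), np.nan),
        predicted=np.empty((n, 4, 4)),
        observed_from=np.full(n, -1, dtype=np.int64),
        observed_to=np.full(n, -1, dtype=np.int64),
    )

    for t in range(n):
        if t == 0:
            mu_hat, pi_hat = mu.copy(), pi.copy()
        else:
            mu_hat = mu.copy()
            pi_hat = np.maximum(1.0 / (1.0 / pi + omg), MIN_PRECISION)
        tr.mu_hat[t] = mu_hat
        tr.pi_hat[t] = pi_hat
        tr.predicted[t] = normalized_prediction(mu_hat)

        if new_session[t]:
            mu, pi = mu_hat.copy(), pi_hat.copy()
        else:
            i = stim[t - 1] - 1
            j = stim[t] - 1
            tr.observed_from[t] = i + 1
            tr.observed_to[t] = j + 1
            mu, pi = mu_hat.copy(), pi_hat.copy()
            b_hat = sigmoid(mu_hat[i])
            outcome = np.zeros(4)
            outcome[j] = 1.0
            delta = outcome - b_hat
            pi[i] = pi_hat[i] + b_hat * (1.0 - b_hat)
            mu[i] = mu_hat[i] + delta / pi[i]
            tr.delta[t, i] = delta
        tr.mu[t] = mu
        tr.pi[t] = pi
    return tr
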