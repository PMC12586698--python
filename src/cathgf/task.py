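"""Probabilistic serial reaction time (SRT) task generator and agent simulator.

The task presents a stimulus in one of four locations on every trial. The
location on trial ``t`` is determined by the locations on trials ``t-1`` and
``t-2`` through one of two second-order conditional (SOC) sequences: on each
trial the continuation prescribed by the high-probability sequence is used
with probability ``p_high`` (default 0.85) and the continuation prescribed by
the low-probability sequence otherwise. After one session of 960 trials the
roles of the two sequences are reversed for a second 960-trial session.

Synthetic agents respond to this stimulus stream through the categorical
state-transition HGF (``cathgf.hgf``) coupled to a linear log-reaction-time
response model (``cathgf.response``), which makes fully simulated
stimulus + behaviour tables available for testing and parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEQUENCE_A",
    "SEQUENCE_B",
    "SESSIONS",
    "SequenceSpec",
    "build_pair_map",
    "generate_session",
    "generate_experiment",
    "simulate_agent",
]

#: The two deciding 24-element SOC sequences (each is a 12-element cycle
#: written out twice). Every ordered pair of consecutive locations uniquely
#: determines the next location within a sequence.
SEQUENCE_A: tuple[int, ...] = (1, 2, 1, 4, 3, 2, 4, 1, 3, 4, 2, 3) * 2
SEQUENCE_B: tuple[int, ...] = (1, 3, 2, 3, 4, 1, 2, 4, 3, 1, 4, 2) * 2

#: Session labels, in task order. The reversal happens between them.
SESSIONS: tuple[str, str] = ("pre", "post")

CATEGORIES = (1, 2, 3, 4)

#: Column order of a canonical trial table.
TRIAL_COLUMNS = ["trial", "session", "stimulus", "source", "correct", "rt_ms"]


def build_pair_map(sequence: Sequence[int]) -> dict[tuple[int, int], int]:
    """Build the second-order conditional transition map of a SOC sequence.

    Treats ``sequence`` as cyclic and returns a mapping from every ordered
    pair of consecutive categories ``(c[t-2], c[t-1])`` to the category that
    follows it, ``c[t]``.

    Raises
    ------
    ValueError
        If any element is not in 1-4, if the sequence contains an immediate
        repetition, or if the same ordered pair is followed by two different
        categories (i.e. the sequence is not second-order conditional).
    """
    seq = [int(c) for c in sequence]
    if len(seq) < 3:
        raise ValueError("sequence must contain at least 3 elements")
    bad = sorted({c for c in seq if c not in CATEGORIES})
    if bad:
        raise ValueError(f"sequence contains categories outside 1-4: {bad}")
    pair_map: dict[tuple[int, int], int] = {}
    n = len(seq)
    for t in range(n):
        a, b, c = seq[t - 2], seq[t - 1], seq[t]
        if b == c:
            raise ValueError(
                f"immediate repetition {b}->{c} at cyclic position {t}"
            )
        prev = pair_map.setdefault((a, b), c)
        if prev != c:
            raise ValueError(
                f"pair ({a},{b}) maps to both {prev} and {c}: "
                "not a valid second-order conditional sequence"
            )
    return pair_map


def _as_tuple(seq: Sequence[int]) -> tuple[int, ...]:
    return tuple(int(c) for c in seq)


@dataclass(frozen=True)
class SequenceSpec:
    """Task specification: the two deciding sequences and session layout.

    Parameters
    ----------
    sequence_a, sequence_b
        The two SOC sequences (defaults are the task's printed sequences).
    p_high
        Probability that a trial follows the currently high-probability
        sequence's continuation. Must lie strictly between 0 and 1, except
        that the degenerate value 1.0 is accepted for deterministic streams.
    trials_per_session
        Number of trials per session (default 960).
    n_sessions
        Number of sessions (default 2; the sequence roles swap in session 2).
    """

    sequence_a: tuple[int, ...] = field(default=SEQUENCE_A)
    sequence_b: tuple[int, ...] = field(default=SEQUENCE_B)
    p_high: float = 0.85
    trials_per_session: int = 960
    n_sessions: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence_a", _as_tuple(self.sequence_a))
        object.__setattr__(self, "sequence_b", _as_tuple(self.sequence_b))
        if not (0.0 < self.p_high <= 1.0):
            raise ValueError(f"p_high must be in (0, 1]; got {self.p_high}")
        if self.trials_per_session < 3:
            raise ValueError("trials_per_session must be at least 3")
        if not 1 <= self.n_sessions <= len(SESSIONS):
            raise ValueError(f"n_sessions must be 1 or 2; got {self.n_sessions}")
        map_a = build_pair_map(self.sequence_a)
        map_b = build_pair_map(self.sequence_b)
        if set(map_a) != set(map_b):
            raise ValueError(
                "the two sequences must cover the same set of ordered pairs"
            )

    @property
    def pair_map_a(self) -> dict[tuple[int, int], int]:
        return build_pair_map(self.sequence_a)

    @property
    def pair_map_b(self) -> dict[tuple[int, int], int]:
        return build_pair_map(self.sequence_b)

    def maps_for_session(
        self, session: str
    ) -> tuple[dict[tuple[int, int], int], dict[tuple[int, int], int]]:
        """Return ``(high_map, low_map)`` for a session label."""
        if session not in SESSIONS:
            raise ValueError(f"unknown session {session!r}; expected one of {SESSIONS}")
        if session == "pre":
            return self.pair_map_a, self.pair_map_b
        return self.pair_map_b, self.pair_map_a

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SequenceSpec":
        return cls(**json.loads(text))


def generate_session(
    spec: SequenceSpec,
    session: str,
    seed: int | np.random.SeedSequence,
    trial_offset: int = 0,
) -> pd.DataFrame:
    """Generate the stimulus stream of one session.

    The first two stimuli seed the second-order context: they are a
    uniformly random ordered pair drawn from the high-probability sequence's
    12 pairs. Every subsequent stimulus is the high-probability sequence's
    continuation of the current pair with probability ``spec.p_high`` and the
    low-probability sequence's continuation otherwise; its origin is recorded
    in the ``source`` column (``"high"``/``"low"``, missing for the two
    context trials).

    Returns a trial table with columns ``trial, session, stimulus, source,
    correct, rt_ms``; behaviour columns are left missing (fill them with
    :func:`simulate_agent` or with real data).
    """
    high_map, low_map = spec.maps_for_session(session)
    rng = np.random.default_rng(seed)
    n = spec.trials_per_session

    pairs = sorted(high_map)
    first = pairs[int(rng.integers(len(pairs)))]
    stimuli = [first[0], first[1]]
    source: list[object] = [pd.NA, pd.NA]
    # one uniform draw per generated trial decides high vs low continuation
    u = rng.random(n - 2)
    for t in range(2, n):
        pair = (stimuli[t - 2], stimuli[t - 1])
        if pair not in high_map or pair not in low_map:
            raise ValueError(f"context pair {pair} absent from a sequence map")
        if u[t - 2] < spec.p_high:
            stimuli.append(high_map[pair])
            source.append("high")
        else:
            stimuli.append(low_map[pair])
            source.append("low")

    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1) + trial_offset,
            "session": session,
            "stimulus": np.asarray(stimuli, dtype=np.int64),
            "source": pd.array(source, dtype="string"),
            "correct": pd.array([pd.NA] * n, dtype="boolean"),
            "rt_ms": np.full(n, np.nan),
        }
    )


def generate_experiment(
    spec: SequenceSpec, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Generate the full experiment (all sessions, independent contexts).

    Sessions are generated independently — the second-order context is
    re-seeded after the between-session break — from sub-streams of ``seed``.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = ss.spawn(spec.n_sessions)
    frames = []
    offset = 0
    for session, child in zip(SESSIONS[: spec.n_sessions], children):
        frames.append(generate_session(spec, session, child, trial_offset=offset))
        offset += spec.trials_per_session
    return pd.concat(frames, ignore_index=True)


def simulate_agent(
    trials: pd.DataFrame,
    hgf_params,
    resp_params,
    error_rate: float = 0.08,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Fill a stimulus table with simulated correctness and reaction times.

    The agent's beliefs are filtered trial by trial with the categorical
    state-transition HGF (``hgf_params``), the belief-derived regressors are
    assembled, and each log reaction time is drawn from a Gaussian whose mean
    is the linear response model evaluated at ``resp_params`` and whose SD is
    ``resp_params.sigma``. Correctness is exogenous: independent
    Bernoulli(1 - ``error_rate``) draws, matching the observed accuracy of
    roughly 0.92 at the default rate; the learning model does not produce
    choice errors itself.

    Returns a copy of ``trials`` with ``correct`` and ``rt_ms`` filled.
    """
    from .hgf import filter_trials
    from .metrics import regressor_table
    from .response import mu_rt

    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0, 1); got {error_rate}")
    rng = np.random.default_rng(seed)
    out = trials.reset_index(drop=True).copy()
    n = len(out)

    correct = rng.random(n) >= error_rate
    out["correct"] = pd.array(correct, dtype="boolean")

    traj = filter_trials(
        out["stimulus"].to_numpy(), hgf_params, sessions=out["session"].to_numpy()
    )
    regressors = regressor_table(traj, out)
    mu = mu_rt(regressors, resp_params)
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite response-model regressors or predictor")
    log_rt = mu + resp_params.sigma * rng.standard_normal(n)
    out["rt_ms"] = np.exp(log_rt)
    return out
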