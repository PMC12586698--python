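"""Scalar-loop regressor kernel for the inference hot path.

MCMC re-runs the transition filter once per proposed omega, so the filter ->
regressor computation is written here as a tight scalar loop and compiled
with numba when available (a pure-Python fallback keeps the package
functional without it). The kernel must agree with the readable
implementation in ``cathgf.hgf`` / ``cathgf.metrics`` to double precision;
the test suite asserts this equivalence.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["fast_regressors", "NUMBA_ENABLED"]

_MAX_VOLATILITY = 1e12
_MIN_PRECISION = 1e-12


def _kernel(stim, new_session, omega, mu0, pi0, out_s, out_ue, out_uu):
    n = stim.shape[0]
    omg = math.exp(min(omega, 700.0))
    if omg > _MAX_VOLATILITY:
        omg = _MAX_VOLATILITY
    ln4 = math.log(4.0)

    mu = np.full((4, 4), mu0)
    pi = np.full((4, 4), pi0)

    for t in range(n):
        if t > 0:
            # volatility prediction for all 16 nodes
            for a in range(4):
                for b in range(4):
                    ph = 1.0 / (1.0 / pi[a, b] + omg)
                    if ph < _MIN_PRECISION:
                        ph = _MIN_PRECISION
                    pi[a, b] = ph
        if new_session[t]:
            out_s[t] = ln4
            out_ue[t] = 0.0
            out_uu[t] = 0.0
            continue

        i = stim[t - 1] - 1
        j = stim[t] - 1

        ssum = 0.0
        sij = 0.0
        for b in range(4):
            x = mu[i, b]
            if x >= 0.0:
                sb = 1.0 / (1.0 + math.exp(-x))
            else:
                ex = math.exp(x)
                sb = ex / (1.0 + ex)
            ssum += sb
            if b == j:
                sij = sb
        out_s[t] = -math.log(sij / ssum)
        out_ue[t] = sij * (1.0 - sij) / pi[i, j]
        out_uu[t] = out_ue[t] * omg

        # binary-child update of the active row
        for b in range(4):
            x = mu[i, b]
            if x >= 0.0:
                bh = 1.0 / (1.0 + math.exp(-x))
            else:
                ex = math.exp(x)
                bh = ex / (1.0 + ex)
            outcome = 1.0 if b == j else 0.0
            pnew = pi[i, b] + bh * (1.0 - bh)
            mu[i, b] = mu[i, b] + (outcome - bh) / pnew
            pi[i, b] = pnew


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _kernel = numba.njit(cache=False, fastmath=False)(_kernel)
    NUMBA_ENABLED = True
except ImportError:  # pragma: no cover
    NUMBA_ENABLED = False


def fast_regressors(
    stimuli: np.ndarray,
    new_session: np.ndarray,
    omega: float,
    mu0: float = 0.0,
    pi0: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surprise and uncertainty regressors for a stream, at one omega.

    Parameters
    ----------
    stimuli : int64 array
        1-based stimulus categories.
    new_session : bool array
        True on the first trial of each session (no scored transition there;
        those trials get surprise ln 4 and zero uncertainties).

    Returns ``(surprise, u_expected, u_unexpected)`` arrays.
    """
    n = len(stimuli)
    out_s = np.empty(n)
    out_ue = np.empty(n)
    out_uu = np.empty(n)
    _kernel(
        np.ascontiguousarray(stimuli, dtype=np.int64),
        np.ascontiguousarray(new_session, dtype=np.bool_),
        float(omega),
        float(mu0),
        float(pi0),
        out_s,
        out_ue,
        out_uu,
    )
    return out_s, out_ue, out_uu
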