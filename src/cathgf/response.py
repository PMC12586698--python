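"""Linear log-reaction-time response model and RT preprocessing.

The response model maps the belief-derived and task regressors to the mean
log reaction time

    mu_RT = beta0 + beta1 * surprise + beta2 * U_expected
            + beta3 * U_unexpected + beta4 * post_error
            + beta5 * post_reversal

with observed log RTs Gaussian around mu_RT with standard deviation sigma.
RTs are stored in milliseconds and logs are natural, so an intercept near
5.8 corresponds to a typical RT around 340 ms.

Preprocessing follows the conventional SRT cleaning rules: responses faster
than 200 ms are discarded as anticipations, and, per participant, responses
slower than the mean + 2 SD of their remaining RTs are discarded as lapses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import REGRESSOR_COLUMNS

__all__ = [
    "ResponseParameters",
    "FAST_RT_CUTOFF_MS",
    "SLOW_RT_SD",
    "filter_rt",
    "design_matrix",
    "mu_rt",
    "log_likelihood",
]

#: Anticipation cutoff: responses faster than this are excluded.
FAST_RT_CUTOFF_MS = 200.0
#: Lapse cutoff: responses slower than mean + this many SDs are excluded.
SLOW_RT_SD = 2.0


@dataclass(frozen=True)
class ResponseParameters:
    """Weights of the linear log-RT model plus the regression SD.

    All betas are in log-ms units per unit of their regressor; ``sigma`` is
    the residual SD of log RT and must be positive.
    """

    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    beta4: float = 0.0
    beta5: float = 0.0
    sigma: float = 0.2

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive; got {self.sigma}")

    @property
    def betas(self) -> np.ndarray:
        return np.array(
            [self.beta0, self.beta1, self.beta2, self.beta3, self.beta4, self.beta5]
        )


def filter_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag RT outliers; returns a copy with ``excluded`` and ``exclude_reason``.

    Rules, applied in order:

    1. missing RT (non-response) -> excluded, reason ``"missing"``;
    2. RT < 200 ms -> excluded, reason ``"fast"``;
    3. RT more than 2 SD above the participant's mean RT (mean and SD taken
       over the trials surviving rules 1-2) -> excluded, reason ``"slow"``.

    The slow rule is one-sided: the fast tail is already handled by the
    200 ms floor. Flags are recomputed from the RT values alone, so
    re-filtering an already-flagged table reproduces the same flags.
    """
    out = trials.reset_index(drop=True).copy()
    rt = out["rt_ms"].to_numpy(dtype=float)
    reason = np.full(len(out), "", dtype=object)
    reason[~np.isfinite(rt)] = "missing"
    reason[np.isfinite(rt) & (rt < FAST_RT_CUTOFF_MS)] = "fast"

    valid = reason == ""
    if valid.sum() < 2:
        raise ValueError(
            f"fewer than 2 valid trials remain ({int(valid.sum())}); "
            "slow-outlier SD is undefined"
        )
    mean = rt[valid].mean()
    sd = rt[valid].std(ddof=1)
    slow = valid & (rt > mean + SLOW_RT_SD * sd)
    reason[slow] = "slow"

    out["excluded"] = reason != ""
    out["exclude_reason"] = pd.array(reason, dtype="string")
    return out


def design_matrix(regressors: pd.DataFrame) -> np.ndarray:
    """Stack the intercept and the five regressors into an (n, 6) design."""
    X = np.column_stack(
        [np.ones(len(regressors))]
        + [regressors[c].to_numpy(dtype=float) for c in REGRESSOR_COLUMNS]
    )
    return X


def mu_rt(regressors: pd.DataFrame, params: ResponseParameters) -> np.ndarray:
    """Linear predictor of log RT (log-ms) for each trial."""
    return design_matrix(regressors) @ params.betas


def log_likelihood(
    trials: pd.DataFrame,
    regressors: pd.DataFrame,
    params: ResponseParameters,
    include_error_trials: bool = True,
) -> float:
    """Gaussian log-likelihood of the observed log RTs.

    Only trials not flagged ``excluded`` contribute (run :func:`filter_rt`
    first; a table without the column is treated as all included). Error
    trials are kept by default — their successors carry the post-error
    regressor — but can be dropped with ``include_error_trials=False``.
    """
    if params.sigma <= 0:
        raise ValueError(f"sigma must be positive; got {params.sigma}")
    if len(trials) != len(regressors):
        raise ValueError("trials and regressors must have equal length")
    trials = trials.reset_index(drop=True)
    included = (
        ~trials["excluded"].to_numpy(dtype=bool)
        if "excluded" in trials
        else np.isfinite(trials["rt_ms"].to_numpy(dtype=float))
    )
    if not include_error_trials:
        included &= trials["correct"].fillna(False).to_numpy(dtype=bool)
    log_rt = np.log(trials.loc[included, "rt_ms"].to_numpy(dtype=float))
    mu = mu_rt(regressors, params)[included]
    return float(stats.norm.logpdf(log_rt, loc=mu, scale=params.sigma).sum())
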