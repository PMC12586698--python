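"""Readers, writers, run configuration and the end-to-end pipeline.

All tables are UTF-8 comma-separated text with a header row; parameters and
summaries are JSON. Every file written by the pipeline is stamped (via a
leading ``#`` comment line for tables, or embedded keys for JSON) with the
seed, the configuration hash and the package version that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task import TRIAL_COLUMNS, SequenceSpec, generate_experiment, simulate_agent
from .hgf import HGFParameters, filter_trials
from .metrics import regressor_table
from .response import ResponseParameters
from .model import PriorSpec, TransitionHGFModel, recovery_study

__all__ = [
    "read_trials",
    "write_trials",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("cathgf")

_VALID_SESSIONS = {"pre", "post", "all"}


def read_trials(path) -> pd.DataFrame:
    """Read a canonical trial table from delimited text.

    Expects the documented header (``trial, session, stimulus, source,
    correct, rt_ms``; ``source`` optional); unknown columns are preserved.
    Missing ``rt_ms`` stays missing (NaN), never zero. Raises ``ValueError``
    naming the offending row and column on malformed input.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("trial", "session", "stimulus", "rt_ms") if c not in df]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    stim = pd.to_numeric(df["stimulus"], errors="coerce")
    bad = df.index[~stim.isin([1, 2, 3, 4])]
    if len(bad):
        raise ValueError(
            f"{path}: invalid value {df.loc[bad[0], 'stimulus']!r} in column "
            f"'stimulus' at row {int(bad[0]) + 1}"
        )
    df["stimulus"] = stim.astype(np.int64)

    sess = df["session"].astype(str).str.lower()
    bad = df.index[~sess.isin(_VALID_SESSIONS)]
    if len(bad):
        raise ValueError(
            f"{path}: invalid value {df.loc[bad[0], 'session']!r} in column "
            f"'session' at row {int(bad[0]) + 1}"
        )
    df["session"] = sess

    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    neg = df.index[rt.notna() & (rt <= 0)]
    if len(neg):
        raise ValueError(
            f"{path}: non-positive rt_ms at row {int(neg[0]) + 1}"
        )
    df["rt_ms"] = rt.astype(float)

    if "correct" in df:
        df["correct"] = (
            df["correct"]
            .map(
                {
                    True: True, False: False, 1: True, 0: False,
                    "True": True, "False": False, "1": True, "0": False,
                    "1.0": True, "0.0": False, 1.0: True, 0.0: False,
                }
            )
            .astype("boolean")
        )
    else:
        df["correct"] = pd.array([pd.NA] * len(df), dtype="boolean")
    if "source" in df:
        df["source"] = df["source"].astype("string")
    return df


def _stamp_line(stamp: dict | None) -> str:
    if not stamp:
        return ""
    fields = " ".join(f"{k}={v}" for k, v in stamp.items())
    return f"# {fields}\n"


def write_trials(trials: pd.DataFrame, path, stamp: dict | None = None) -> None:
    """Write a trial table as CSV (optionally stamped with provenance)."""
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS if c in trials] + [
        c for c in trials.columns if c not in TRIAL_COLUMNS
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_stamp_line(stamp))
        trials[cols].to_csv(fh, index=False)


def _write_table(df: pd.DataFrame, path, stamp: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_stamp_line(stamp))
        df.to_csv(fh, index=False)


@dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run (JSON-serialisable)."""

    task: SequenceSpec = field(default_factory=SequenceSpec)
    omega: float = -4.0
    mu0: float = 0.0
    pi0: float = 1.0
    response: ResponseParameters = field(
        default_factory=lambda: ResponseParameters(
            beta0=5.83, beta1=0.05, beta2=-0.02, beta3=-0.15,
            beta4=0.10, beta5=-0.01, sigma=0.2,
        )
    )
    priors: PriorSpec = field(default_factory=PriorSpec)
    error_rate: float = 0.08
    chains: int = 4
    samples_per_chain: int = 2000
    seed: int = 0
    recover_agents: int = 0  # 0 disables the recovery stage
    trials_path: str | None = None  # fit real data instead of simulating

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["priors"] = self.priors.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "task" in d and isinstance(d["task"], dict):
            d["task"] = SequenceSpec(**d["task"])
        if "response" in d and isinstance(d["response"], dict):
            d["response"] = ResponseParameters(**d["response"])
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = PriorSpec.from_dict(d["priors"])
        return cls(**d)

    @classmethod
    def from_json_file(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig, outdir) -> dict[str, Path]:
    """Execute simulate -> filter -> fit (-> recover), writing all artifacts.

    Returns a mapping from stage name to the written file. Fails fast with
    the stage name on error; files written before the failure are retained.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }
    outputs: dict[str, Path] = {}
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs["log"] = log_path

    def _stage(name):
        logger.info("stage=%s status=start", name)
        return time.perf_counter()

    def _done(name, t0):
        logger.info("stage=%s status=done elapsed_s=%.2f", name, time.perf_counter() - t0)

    try:
        stage = "simulate"
        t0 = _stage(stage)
        if config.trials_path:
            trials = read_trials(config.trials_path)
        else:
            ss = np.random.SeedSequence(config.seed)
            task_seed, agent_seed = ss.spawn(2)
            stimuli = generate_experiment(config.task, task_seed)
            trials = simulate_agent(
                stimuli,
                HGFParameters(config.omega, config.mu0, config.pi0),
                config.response,
                error_rate=config.error_rate,
                seed=agent_seed,
            )
        trials_path = outdir / "trials.csv"
        write_trials(trials, trials_path, stamp)
        outputs["trials"] = trials_path
        _done(stage, t0)

        stage = "filter"
        t0 = _stage(stage)
        traj = filter_trials(
            trials["stimulus"].to_numpy(),
            HGFParameters(config.omega, config.mu0, config.pi0),
            sessions=trials["session"].to_numpy(),
        )
        traj_path = outdir / "trajectory.csv"
        _write_table(traj.to_frame(), traj_path, stamp)
        outputs["trajectory"] = traj_path
        regressors = regressor_table(traj, trials)
        reg_path = outdir / "regressors.csv"
        _write_table(regressors, reg_path, stamp)
        outputs["regressors"] = reg_path
        _done(stage, t0)

        stage = "fit"
        t0 = _stage(stage)
        model = TransitionHGFModel(
            trials, priors=config.priors, mu0=config.mu0, pi0=config.pi0
        )
        res = model.fit(
            chains=config.chains,
            samples_per_chain=config.samples_per_chain,
            seed=config.seed,
        )
        summary = {
            **stamp,
            "posterior": res.summary_frame().round(6).to_dict(orient="index"),
            "max_rhat": res.max_rhat,
            "acceptance_fraction": res.acceptance_fraction.round(4).tolist(),
            "n_included_trials": model.n_included,
        }
        post_path = outdir / "posterior.json"
        post_path.write_text(json.dumps(summary, indent=2))
        outputs["posterior"] = post_path
        draws_path = outdir / "draws.csv"
        _write_table(res.draws_frame(), draws_path, stamp)
        outputs["draws"] = draws_path
        logger.info("stage=fit max_rhat=%.4f", res.max_rhat)
        _done(stage, t0)

        if config.recover_agents > 0:
            stage = "recover"
            t0 = _stage(stage)
            rec = recovery_study(
                n_agents=config.recover_agents, seed=config.seed, spec=config.task
            )
            rec_path = outdir / "recovery.json"
            rec_path.write_text(
                json.dumps(
                    {
                        **stamp,
                        "summary": json.loads(
                            rec["summary"].round(6).to_json(orient="index")
                        ),
                        "overall_coverage": rec["overall_coverage"],
                    },
                    indent=2,
                )
            )
            outputs["recovery"] = rec_path
            _done(stage, t0)
    except Exception as err:
        logger.error("stage=%s status=failed error=%r", stage, err)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs
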