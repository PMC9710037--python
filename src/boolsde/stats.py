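"""Ensemble runs and summary statistics.

An ensemble re-runs the simulator under fresh U[0,1] weight draws and
independent noise substreams, all derived deterministically from one
root seed, and aggregates per-node mean / standard deviation / CV
trajectories plus per-run summaries (AUC of the activity profile, peak
time and value, time to decay to a fraction of the peak, optionally time
to full inactivation).

Trajectory-level statistics (:func:`auc`, :func:`peak`,
:func:`decay_time`) operate on a single :class:`~boolsde.engine.Trajectory`
and agree with the streamed per-run summaries the ensemble computes
online.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import (
    SimulationConfig,
    StimulusSchedule,
    Trajectory,
    integrate_batch,
    noise_rng_for_run,
    weight_rng_for_run,
)
from .logic import gate_values
from .network import SignalingNetwork, sample_weights

__all__ = [
    "EnsembleResult",
    "run_ensemble",
    "auc",
    "peak",
    "decay_time",
    "coefficient_of_variation",
    "two_sample_t",
    "pool_times",
]


# -- trajectory-level statistics --------------------------------------


def auc(traj: Trajectory, node: str) -> float:
    """Trapezoidal area under the node's activity curve (activity*time)."""
    return float(np.trapezoid(traj.activity(node), traj.times))


def peak(traj: Trajectory, node: str) -> tuple[float, float]:
    """(time, value) of the highest activity; earliest index on ties."""
    x = traj.activity(node)
    idx = int(np.argmax(x))
    return float(traj.times[idx]), float(x[idx])


def decay_time(
    traj: Trajectory, node: str, fraction: float = 0.1
) -> float | None:
    """First grid time after the peak at which activity falls to
    ``fraction`` of the peak value, or ``None`` if never reached."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    x = traj.activity(node)
    pk = int(np.argmax(x))
    tail = x[pk + 1 :]
    below = np.flatnonzero(tail <= fraction * x[pk])
    if below.size == 0:
        return None
    return float(traj.times[pk + 1 + below[0]])


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV = s / mu with the sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least 2 values")
    mu = v.mean()
    if mu == 0.0:
        raise ValueError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mu)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], variant: str = "student"
) -> tuple[float, float]:
    """Two-sided two-sample t-test.

    ``student`` pools the variances (classic Student t-test); ``welch``
    drops the equal-variance assumption.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "student":
        pooled_ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if pooled_ss == 0.0:
            raise ValueError("degenerate samples: zero pooled variance")
    elif a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValueError("degenerate samples: zero variance in both")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def pool_times(
    summaries: pd.DataFrame,
    column: str,
    nodes: Sequence[str] | None = None,
    censor_at: float | None = None,
) -> np.ndarray:
    """Pool a per-(run, node) time column into one sample.

    Undefined entries (NaN) are right-censored at ``censor_at`` when
    given (typically the horizon), otherwise dropped.
    """
    frame = summaries
    if nodes is not None:
        frame = frame[frame["node"].isin(set(nodes))]
    values = frame[column].to_numpy(dtype=float)
    if censor_at is not None:
        values = np.where(np.isnan(values), censor_at, values)
    else:
        values = values[~np.isnan(values)]
    return values


# -- ensembles ---------------------------------------------------------


@dataclass
class EnsembleResult:
    """Aggregated output of ``n_runs`` weight-resampled simulations."""

    times: np.ndarray
    node_order: list[str]
    mean: np.ndarray  # (n_steps+1, N) mean trajectory over runs
    sd: np.ndarray  # (n_steps+1, N) sample sd over runs
    summaries: pd.DataFrame  # rows (run, node): auc, peak_*, decay_time, ...
    weights: pd.DataFrame  # run x "src->tgt" weight draws
    seed: int
    config: SimulationConfig
    schedule: StimulusSchedule
    inactivation_time: np.ndarray | None = None  # (R,), NaN if never
    restim_events: pd.DataFrame | None = None
    trajectories: np.ndarray | None = None  # (R, n_steps+1, N) if retained

    @property
    def n_runs(self) -> int:
        return len(self.weights)

    @property
    def cv(self) -> np.ndarray:
        """Per-step CV trajectory (sd / mean; NaN where the mean is 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.sd / self.mean
        out[self.mean == 0.0] = np.nan
        return out

    def node_values(self, column: str, node: str) -> np.ndarray:
        """Per-run values of a summary column for one node, in run order."""
        sub = self.summaries[self.summaries["node"] == node]
        return sub.sort_values("run")[column].to_numpy(dtype=float)

    def aggregate_frame(self) -> pd.DataFrame:
        """Per-node mean, sd and CV of the per-run AUCs."""
        rows = []
        for node in self.node_order:
            values = self.node_values("auc", node)
            mu = values.mean()
            s = values.std(ddof=1) if len(values) > 1 else 0.0
            rows.append(
                {
                    "node": node,
                    "mean_auc": mu,
                    "sd_auc": s,
                    "cv_auc": s / mu if mu != 0 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def write_summary_tsv(self, path: str | Path) -> None:
        self.summaries.to_csv(path, sep="\t", index=False)

    def write_aggregate_tsv(self, path: str | Path) -> None:
        self.aggregate_frame().to_csv(path, sep="\t", index=False)

    def write_mean_sd_tsv(self, path: str | Path) -> None:
        """Tidy per-step aggregate: time, node, mean, sd."""
        frames = []
        for i, node in enumerate(self.node_order):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "node": node,
                        "mean": self.mean[:, i],
                        "sd": self.sd[:, i],
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def run_ensemble(
    net_template: SignalingNetwork,
    n_runs: int,
    config: SimulationConfig,
    schedule: StimulusSchedule | None = None,
    *,
    resample_weights: bool | None = None,
    retain_trajectories: bool = False,
    decay_fraction: float = 0.1,
    inactivation_eps: float | None = None,
    window_t: float | None = None,
) -> EnsembleResult:
    """Run ``n_runs`` simulations and aggregate them.

    By default edge weights are resampled U[0,1] per run whenever the
    template has unset weights (and kept fixed otherwise); run ``s``
    uses the weight and noise substreams spawned from ``config.seed``
    for member ``s`` (see :mod:`boolsde.engine`), so results are
    reproducible and independent of ``n_runs``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if resample_weights is None:
        resample_weights = net_template.has_unset_weights()
    if not resample_weights and net_template.has_unset_weights():
        raise ValueError(
            "template has unset weights but resample_weights is False"
        )

    edge_names = [f"{e.source}->{e.target}" for e in net_template.edges]
    gates = np.empty((n_runs, len(net_template.nodes)))
    weight_rows = np.empty((n_runs, len(net_template.edges)))
    for s in range(n_runs):
        if resample_weights:
            net_s = sample_weights(
                net_template, weight_rng_for_run(config.seed, s)
            )
        else:
            net_s = net_template
        weight_rows[s] = [e.weight for e in net_s.edges]
        gates[s] = gate_values(net_s, config.r)

    rngs = [noise_rng_for_run(config.seed, s) for s in range(n_runs)]
    result = integrate_batch(
        net_template,
        config,
        schedule,
        rngs,
        gates=gates,
        retain=retain_trajectories,
        aggregate=True,
        decay_fraction=decay_fraction,
        inactivation_eps=inactivation_eps,
        window_t=window_t,
    )

    records = []
    for s in range(n_runs):
        for i, node in enumerate(result.node_order):
            rec = {
                "run": s,
                "node": node,
                "auc": result.auc[s, i],
                "peak_time": result.peak_time[s, i],
                "peak_value": result.peak_value[s, i],
                "decay_time": result.decay_time[s, i],
            }
            if result.window_auc is not None:
                rec["window_auc"] = result.window_auc[s, i]
            records.append(rec)
    summaries = pd.DataFrame(records)

    restim = pd.DataFrame(
        result.restim_events, columns=["run", "node", "step"]
    )
    if len(restim):
        restim["time"] = restim["step"] * config.dt

    return EnsembleResult(
        times=result.times,
        node_order=result.node_order,
        mean=result.mean,
        sd=result.sd,
        summaries=summaries,
        weights=pd.DataFrame(weight_rows, columns=edge_names),
        seed=config.seed,
        config=config,
        schedule=schedule if schedule is not None else StimulusSchedule(),
        inactivation_time=result.inactivation_time,
        restim_events=restim,
        trajectories=result.activities,
    )
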