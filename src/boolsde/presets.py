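"""End-to-end experiment presets.

Each preset reproduces one of the canned MAPK-cascade experiments:
single-stimulus runs with and without noise, the MEK->ERK weight sweep,
weight-resampled ensembles with decay-time statistics, repeated
threshold-triggered receptor stimulation, rate-constant sweeps, and the
AND/OR (operator parameter r) contrast.  A preset is fully determined by
its name, the overrides and the seed; every run writes a plain-text log
with the resolved configuration.

Full-scale presets use the reference resolution (dt=0.001, 60,000 steps,
1000 runs for stochastic ensembles).  The ``fast`` profile drops to
dt=0.01, 6,000 steps and 100 runs — the same t in [0, 60] horizon at
reduced cost — which is also the scale the test suite exercises.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import stats
from .engine import (
    SimulationConfig,
    StimulusSchedule,
    Trajectory,
    simulate,
    weight_rng_for_run,
)
from .network import (
    MAPK_BACKBONE,
    SignalingNetwork,
    build_mapk_fixture,
    sample_weights,
    set_uniform_weights,
)
from .stats import EnsembleResult, pool_times, run_ensemble, two_sample_t

__all__ = ["PRESET_NAMES", "run_preset", "INACTIVATION_EPS"]

PRESET_NAMES = (
    "single-deterministic",
    "single-stochastic",
    "mek-erk-sweep",
    "ensemble-1000",
    "repeated-stimulation",
    "param-sweep",
    "r-sweep",
)

#: Activity level treated as "inactive" (re-stimulation trigger and the
#: full-inactivation criterion share it).
INACTIVATION_EPS = 0.01

#: Real-time window of the fixed-window overall-activity report.
REPEATED_WINDOW_T = 15.0

CONFIG_FIELDS = set(SimulationConfig().to_dict())


def _resolve(
    overrides: Mapping[str, Any] | None,
    seed: int,
    fast: bool,
    *,
    sigma: float,
    r: float = 0.75,
) -> tuple[SimulationConfig, int]:
    overrides = dict(overrides or {})
    n_runs = overrides.pop("n_runs", 100 if fast else 1000)
    base = dict(
        dt=0.01 if fast else 0.001,
        n_steps=6_000 if fast else 60_000,
        sigma=sigma,
        r=r,
        seed=seed,
    )
    for key, value in overrides.items():
        if key not in CONFIG_FIELDS:
            raise ValueError(f"unknown override {key!r}")
        base[key] = value
    return SimulationConfig(**base), int(n_runs)


def _write_log(
    out: Path,
    preset: str,
    config: SimulationConfig,
    schedule: StimulusSchedule,
    extra: Mapping[str, Any] | None = None,
) -> None:
    doc = {
        "preset": preset,
        "config": config.to_dict(),
        "schedule": schedule.to_dict(),
    }
    if extra:
        doc.update(extra)
    (out / "run_log.txt").write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _traj_summary_frame(traj: Trajectory) -> pd.DataFrame:
    rows = []
    for node in traj.node_order:
        t_pk, v_pk = stats.peak(traj, node)
        dec = stats.decay_time(traj, node, 0.1)
        rows.append(
            {
                "node": node,
                "auc": stats.auc(traj, node),
                "peak_time": t_pk,
                "peak_value": v_pk,
                "decay_time": np.nan if dec is None else dec,
            }
        )
    return pd.DataFrame(rows)


def _single_stimulus(
    name: str, sigma: float, overrides, out: Path, seed: int, fast: bool
) -> dict:
    config, _ = _resolve(overrides, seed, fast, sigma=sigma)
    net = sample_weights(build_mapk_fixture(), weight_rng_for_run(seed, 0))
    schedule = StimulusSchedule(initial=["EGFR"])
    traj = simulate(net, config, schedule)
    traj.write_tsv(out / "trajectory.tsv")
    traj.write_csv(out / "trajectory.csv")
    _traj_summary_frame(traj).to_csv(out / "summary.tsv", sep="\t", index=False)
    _write_log(out, name, config, schedule)
    return {"trajectory": traj, "config": config}


def _paired_decay_ttest(
    ens_noisy: EnsembleResult,
    ens_det: EnsembleResult,
    horizon: float,
    nodes: list[str],
) -> dict:
    """Student t-test of decay-to-10%-of-peak times, stochastic vs
    deterministic, pooled over the given nodes and censored at the
    horizon."""
    noisy = pool_times(ens_noisy.summaries, "decay_time", nodes, censor_at=horizon)
    det = pool_times(ens_det.summaries, "decay_time", nodes, censor_at=horizon)
    t_stat, p = two_sample_t(noisy, det, "student")
    return {
        "t": t_stat,
        "p": p,
        "mean_stochastic": float(noisy.mean()),
        "mean_deterministic": float(det.mean()),
        "n_per_condition": int(noisy.size),
        "nodes": nodes,
    }


def run_preset(
    name: str,
    overrides: Mapping[str, Any] | None = None,
    out_dir: str | Path = ".",
    seed: int = 0,
    fast: bool = False,
) -> dict:
    """Run a named experiment preset and write its report files.

    Returns a dict with the in-memory results (trajectories, ensembles,
    test outcomes) alongside everything written under ``out_dir``.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if name == "single-deterministic":
        return _single_stimulus(name, 0.0, overrides, out, seed, fast)

    if name == "single-stochastic":
        return _single_stimulus(name, 1.0, overrides, out, seed, fast)

    if name == "mek-erk-sweep":
        config, _ = _resolve(overrides, seed, fast, sigma=1.0)
        schedule = StimulusSchedule(initial=["EGFR"])
        trajs = {}
        for w in (0.25, 0.5, 0.75):
            net = set_uniform_weights(
                build_mapk_fixture(), 0.5, {("MEK", "ERK"): w}
            )
            traj = simulate(net, config, schedule)
            traj.write_csv(out / f"trajectory_mek_erk_{w}.csv")
            trajs[w] = traj
        _write_log(out, name, config, schedule, {"mek_erk_weights": [0.25, 0.5, 0.75]})
        return {"trajectories": trajs, "config": config}

    if name == "ensemble-1000":
        config, n_runs = _resolve(overrides, seed, fast, sigma=1.0)
        schedule = StimulusSchedule(initial=["EGFR"])
        fixture = build_mapk_fixture()
        ens = run_ensemble(fixture, n_runs, config, schedule)
        ens_det = run_ensemble(
            fixture, n_runs, config.with_overrides(sigma=0.0), schedule
        )
        ens.write_mean_sd_tsv(out / "mean_sd_trajectories.tsv")
        ens.write_summary_tsv(out / "run_summaries.tsv")
        ens.write_aggregate_tsv(out / "auc_aggregate.tsv")
        decaying = [n for n in fixture.node_ids if fixture.role(n) != "terminal"]
        ttest = _paired_decay_ttest(ens, ens_det, config.horizon, decaying)
        (out / "decay_ttest.json").write_text(json.dumps(ttest, indent=2) + "\n")
        _write_log(out, name, config, schedule, {"n_runs": n_runs})
        return {
            "ensemble": ens,
            "ensemble_deterministic": ens_det,
            "decay_ttest": ttest,
            "config": config,
        }

    if name == "repeated-stimulation":
        config, n_runs = _resolve(overrides, seed, fast, sigma=1.0)
        receptors = ["EGFR", "ERBB2", "MET"]
        schedule = StimulusSchedule(
            initial=receptors,
            restim_threshold=INACTIVATION_EPS,
            restim_nodes=receptors,
        )
        ens = run_ensemble(
            build_mapk_fixture(),
            n_runs,
            config,
            schedule,
            window_t=min(REPEATED_WINDOW_T, config.horizon),
        )
        ens.write_mean_sd_tsv(out / "mean_sd_trajectories.tsv")
        ens.write_summary_tsv(out / "run_summaries.tsv")
        peak_report = (
            ens.summaries[ens.summaries["node"].isin(receptors + ["GRB2"])]
            .groupby("node")["peak_time"]
            .agg(["mean", "std"])
            .reset_index()
        )
        peak_report.to_csv(out / "peak_times.tsv", sep="\t", index=False)
        window_rows = []
        for node in ens.node_order:
            values = ens.node_values("window_auc", node)
            mu = values.mean()
            s = values.std(ddof=1) if len(values) > 1 else 0.0
            window_rows.append(
                {
                    "node": node,
                    "mean_window_auc": mu,
                    "cv_window_auc": s / mu if mu != 0 else np.nan,
                }
            )
        pd.DataFrame(window_rows).to_csv(
            out / "window_auc_aggregate.tsv", sep="\t", index=False
        )
        if ens.restim_events is not None and len(ens.restim_events):
            ens.restim_events.to_csv(
                out / "restimulation_events.tsv", sep="\t", index=False
            )
        _write_log(out, name, config, schedule, {"n_runs": n_runs})
        return {"ensemble": ens, "config": config}

    if name == "param-sweep":
        config, n_runs = _resolve(overrides, seed, fast, sigma=1.0)
        schedule = StimulusSchedule(initial=["EGFR"])
        fixture = build_mapk_fixture()
        rows = []
        results = {}
        for param in ("k_u", "k_d", "sigma"):
            for factor in (1.0, 0.5, 0.1):
                scaled = config.with_overrides(
                    **{param: getattr(config, param) * factor}
                )
                ens = run_ensemble(fixture, n_runs, scaled, schedule)
                results[(param, factor)] = ens
                agg = ens.aggregate_frame()
                agg.insert(0, "param", param)
                agg.insert(1, "factor", factor)
                rows.append(agg)
        pd.concat(rows, ignore_index=True).to_csv(
            out / "param_sweep_auc.tsv", sep="\t", index=False
        )
        _write_log(out, name, config, schedule, {"n_runs": n_runs})
        return {"ensembles": results, "config": config}

    if name == "r-sweep":
        config, n_runs = _resolve(overrides, seed, fast, sigma=1.0)
        schedule = StimulusSchedule(initial=["EGFR"])
        fixture = build_mapk_fixture()
        r_values = (0.0, 0.25, 0.75, 1.0)
        samples = {}
        for r in r_values:
            ens = run_ensemble(
                fixture,
                n_runs,
                config.with_overrides(r=r),
                schedule,
                inactivation_eps=INACTIVATION_EPS,
            )
            t_inact = np.where(
                np.isnan(ens.inactivation_time),
                config.horizon,
                ens.inactivation_time,
            )
            samples[r] = t_inact
        pd.DataFrame(
            {f"r={r}": samples[r] for r in r_values}
        ).to_csv(out / "inactivation_times.tsv", sep="\t", index=False)
        tests = {}
        for r_a, r_b in ((1.0, 0.75), (1.0, 0.0), (0.75, 0.25)):
            t_stat, p = two_sample_t(samples[r_a], samples[r_b], "student")
            tests[f"r={r_a}_vs_r={r_b}"] = {"t": t_stat, "p": p}
        (out / "inactivation_ttests.json").write_text(
            json.dumps(tests, indent=2) + "\n"
        )
        _write_log(out, name, config, schedule, {"n_runs": n_runs})
        return {"samples": samples, "ttests": tests, "config": config}

    raise AssertionError("unreachable")
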