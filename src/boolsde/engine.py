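"""Stochastic activity dynamics and the Euler–Maruyama integrator.

Each protein activity ``x_i(t)`` follows

    dx_i = ( k_u * sum_{k in up(i)} B_k x_k  -  k_d * B_i x_i ) dt
           + sigma * x_i dW_i(t)

where ``B`` are the per-node Waller–Kraft gate values over outgoing
weights (:mod:`boolsde.logic`), ``k_u`` / ``k_d`` are activation and
inactivation rate constants, and the last term is multiplicative
self-activity noise driven by independent Wiener processes.  Receptors
have no upstream term (k_u effectively 0) and terminal readout nodes no
downstream term (k_d effectively 0).

Integration uses the explicit Euler–Maruyama scheme

    X(t+dt) = X(t) + f(X(t)) dt + g(X(t)) dW

with, by default, standard Wiener increments dW ~ N(0, dt) (standard
deviation sqrt(dt)); an alternative ``sd_dt`` convention with standard
deviation dt is available (see :class:`SimulationConfig.noise_scale`).

The integrator is vectorized over an arbitrary number of simultaneous
runs; :func:`simulate` is the single-run entry point and
:mod:`boolsde.stats` builds ensembles on the same core.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .logic import gate_values
from .network import SignalingNetwork

__all__ = [
    "SimulationConfig",
    "StimulusSchedule",
    "Trajectory",
    "SimulationError",
    "drift",
    "diffusion",
    "draw_increments",
    "em_step",
    "apply_stimuli",
    "StimulusState",
    "simulate",
    "noise_rng_for_run",
    "weight_rng_for_run",
]

NOISE_SCALES = ("variance_dt", "sd_dt")


class SimulationError(RuntimeError):
    """Numerical failure during integration (non-finite state)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and model parameters.

    Attributes
    ----------
    dt:
        Time step (default 0.001).
    n_steps:
        Number of Euler–Maruyama steps; the grid has ``n_steps + 1``
        points covering ``[0, n_steps * dt]`` (default 60,000).
    k_u, k_d:
        Upstream (activation) and downstream (inactivation) rate
        constants; zeroed per node for receptors / terminals (default 1.0).
    sigma:
        Stochastic self-activity rate constant (default 1.0; 0 gives the
        deterministic ODE limit).
    r:
        Waller–Kraft operator parameter in [0, 1]; [0.5, 1] is the AND
        regime (default 0.75).
    noise_scale:
        ``"variance_dt"`` — Wiener increments with variance dt (sd
        sqrt(dt), the standard Euler–Maruyama convention, default) —
        or ``"sd_dt"`` — increments with standard deviation dt.
    clamp_floor:
        Clip activities at 0 after each step (default True); there is no
        ceiling, activities may exceed 1.
    seed:
        Root seed for the noise stream.
    """

    dt: float = 0.001
    n_steps: int = 60_000
    k_u: float = 1.0
    k_d: float = 1.0
    sigma: float = 1.0
    r: float = 0.75
    noise_scale: str = "variance_dt"
    clamp_floor: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        for name in ("k_u", "k_d", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"r={self.r} outside [0, 1]")
        if self.noise_scale not in NOISE_SCALES:
            raise ValueError(
                f"noise_scale must be one of {NOISE_SCALES}, "
                f"got {self.noise_scale!r}"
            )

    @property
    def horizon(self) -> float:
        return self.n_steps * self.dt

    @property
    def increment_sd(self) -> float:
        """Standard deviation of one noise increment under this config."""
        return math.sqrt(self.dt) if self.noise_scale == "variance_dt" else self.dt

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        return cls(**data)

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StimulusSchedule:
    """External receptor stimulation plan.

    ``initial`` receptors are set to activity 1 at t=0.  ``events`` are
    explicit (node, time) activations applied at the first grid point at
    or after the event time.  When ``restim_threshold`` is set, every
    node in ``restim_nodes`` is re-stimulated (reset to 1) whenever its
    activity, having first risen above twice the threshold, falls below
    the threshold — a simple refractory rule that yields one reset per
    downward crossing.  Stimulation always overwrites the activity with
    exactly 1.
    """

    initial: frozenset[str] = frozenset()
    events: tuple[tuple[str, float], ...] = ()
    restim_threshold: float | None = None
    restim_nodes: frozenset[str] = frozenset()

    def __init__(
        self,
        initial: Iterable[str] = (),
        events: Iterable[tuple[str, float]] = (),
        restim_threshold: float | None = None,
        restim_nodes: Iterable[str] = (),
    ) -> None:
        object.__setattr__(self, "initial", frozenset(initial))
        object.__setattr__(
            self, "events", tuple((str(n), float(t)) for n, t in events)
        )
        object.__setattr__(self, "restim_threshold", restim_threshold)
        object.__setattr__(self, "restim_nodes", frozenset(restim_nodes))
        if restim_threshold is not None and restim_threshold < 0:
            raise ValueError("restim_threshold must be >= 0")

    def validate(self, net: SignalingNetwork, config: SimulationConfig) -> None:
        receptors = set(net.receptors)
        for node in (
            set(self.initial) | set(self.restim_nodes) | {n for n, _ in self.events}
        ):
            if node not in receptors:
                raise ValueError(
                    f"stimulus names {node!r}, which is not a receptor"
                )
        for node, t in self.events:
            if not 0.0 <= t <= config.horizon:
                raise ValueError(
                    f"event ({node!r}, t={t}) outside [0, {config.horizon}]"
                )

    def to_dict(self) -> dict:
        return {
            "initial": sorted(self.initial),
            "events": [[n, t] for n, t in self.events],
            "restim_threshold": self.restim_threshold,
            "restim_nodes": sorted(self.restim_nodes),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StimulusSchedule":
        return cls(
            initial=data.get("initial", ()),
            events=[tuple(e) for e in data.get("events", ())],
            restim_threshold=data.get("restim_threshold"),
            restim_nodes=data.get("restim_nodes", ()),
        )


@dataclass
class Trajectory:
    """One run: time grid x node activities, with provenance."""

    times: np.ndarray
    activities: np.ndarray  # (n_steps + 1, N)
    node_order: list[str]
    config: SimulationConfig
    schedule: StimulusSchedule
    seed: int

    def activity(self, node: str) -> np.ndarray:
        return self.activities[:, self.node_order.index(node)]

    def to_frame(self):
        """Wide :class:`pandas.DataFrame`: time plus one column per node."""
        import pandas as pd

        frame = pd.DataFrame(self.activities, columns=self.node_order)
        frame.insert(0, "time", self.times)
        return frame

    def _provenance_lines(self) -> list[str]:
        import json

        return [
            "# boolsde trajectory",
            f"# config: {json.dumps(self.config.to_dict())}",
            f"# schedule: {json.dumps(self.schedule.to_dict())}",
            f"# seed: {self.seed}",
        ]

    def write_tsv(self, path: str | Path) -> None:
        """Tidy TSV: ``time<TAB>node<TAB>activity`` with provenance header."""
        path = Path(path)
        lines = self._provenance_lines()
        lines.append("time\tnode\tactivity")
        for ti, t in enumerate(self.times):
            for ni, node in enumerate(self.node_order):
                lines.append(f"{t!r}\t{node}\t{self.activities[ti, ni]!r}")
        path.write_text("\n".join(lines) + "\n")

    def write_csv(self, path: str | Path) -> None:
        """Wide CSV: time plus one column per node, provenance as comments."""
        path = Path(path)
        lines = self._provenance_lines()
        lines.append("time," + ",".join(self.node_order))
        for ti, t in enumerate(self.times):
            row = ",".join(repr(v) for v in self.activities[ti])
            lines.append(f"{t!r},{row}")
        path.write_text("\n".join(lines) + "\n")


# -- RNG substream rule ------------------------------------------------
#
# One root seed; run s draws weights from the child SeedSequence with
# spawn_key (s, 0) and noise from spawn_key (s, 1).  Streams are therefore
# reproducible and independent of how many runs an ensemble contains.


def weight_rng_for_run(root_seed: int, run: int) -> np.random.Generator:
    """Weight-draw generator for ensemble member ``run``."""
    return np.random.default_rng(
        np.random.SeedSequence(root_seed, spawn_key=(run, 0))
    )


def noise_rng_for_run(root_seed: int, run: int) -> np.random.Generator:
    """Noise-increment generator for ensemble member ``run``."""
    return np.random.default_rng(
        np.random.SeedSequence(root_seed, spawn_key=(run, 1))
    )


# -- single-state operations ------------------------------------------


def _rate_masks(
    net: SignalingNetwork, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Effective (k_u, k_d) per node: k_u=0 for receptors, k_d=0 for
    terminals."""
    roles = [net.role(node_id) for node_id in net.node_ids]
    ku_eff = np.array(
        [0.0 if role == "receptor" else config.k_u for role in roles]
    )
    kd_eff = np.array(
        [0.0 if role == "terminal" else config.k_d for role in roles]
    )
    return ku_eff, kd_eff


def drift(
    net: SignalingNetwork,
    activities: Sequence[float] | np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Deterministic drive f(x): upstream activation minus downstream
    inactivation, per node."""
    x = np.asarray(activities, dtype=float)
    b = gate_values(net, config.r)
    adj = net.adjacency_matrix()
    ku_eff, kd_eff = _rate_masks(net, config)
    bx = b * x
    return ku_eff * (bx @ adj) - kd_eff * bx


def diffusion(
    activities: Sequence[float] | np.ndarray, sigma: float
) -> np.ndarray:
    """Multiplicative noise amplitude g(x) = sigma * x."""
    return sigma * np.asarray(activities, dtype=float)


def draw_increments(
    rng: np.random.Generator, config: SimulationConfig, n: int
) -> np.ndarray:
    """``n`` independent Gaussian noise increments, scaled per config."""
    return rng.normal(0.0, config.increment_sd, size=n)


def em_step(
    state: Sequence[float] | np.ndarray,
    net: SignalingNetwork,
    config: SimulationConfig,
    dW: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """One Euler–Maruyama step: x + f(x) dt + g(x) * dW (floored at 0
    when ``clamp_floor``)."""
    x = np.asarray(state, dtype=float)
    dw = np.asarray(dW, dtype=float)
    if dw.shape != x.shape:
        raise ValueError(f"dW shape {dw.shape} != state shape {x.shape}")
    new = x + drift(net, x, config) * config.dt + diffusion(x, config.sigma) * dw
    if config.clamp_floor:
        new = np.maximum(new, 0.0)
    if not np.all(np.isfinite(new)):
        bad = [
            net.node_ids[i] for i in np.flatnonzero(~np.isfinite(new))
        ]
        raise SimulationError(f"non-finite activity for node(s) {bad}")
    return new


class StimulusState:
    """Mutable tracker for a schedule over one or more simultaneous runs.

    Holds the precomputed event grid steps and, for threshold-triggered
    re-stimulation, the per-run/per-node "armed" flags of the refractory
    rule (armed once activity >= 2*threshold; a reset fires when an armed
    node falls below the threshold and disarms it).
    """

    def __init__(
        self,
        net: SignalingNetwork,
        schedule: StimulusSchedule,
        config: SimulationConfig,
        n_runs: int = 1,
    ) -> None:
        self.schedule = schedule
        self.initial_idx = sorted(
            net.node_index(n) for n in schedule.initial
        )
        self.event_steps: dict[int, list[int]] = {}
        for node, t in schedule.events:
            step = int(math.ceil(t / config.dt - 1e-9))
            self.event_steps.setdefault(step, []).append(net.node_index(node))
        self.restim_idx = np.array(
            sorted(net.node_index(n) for n in schedule.restim_nodes), dtype=int
        )
        self.eps = schedule.restim_threshold
        self.armed = np.zeros((n_runs, len(self.restim_idx)), dtype=bool)
        self.node_ids = list(net.node_ids)
        #: applied re-stimulations as (run, node_id, step) records
        self.restim_events: list[tuple[int, str, int]] = []

    def apply(self, x: np.ndarray, step: int) -> None:
        """Apply all stimuli due at grid ``step`` to state ``x`` (R, N),
        in place."""
        if step == 0 and self.initial_idx:
            x[:, self.initial_idx] = 1.0
        for idx in self.event_steps.get(step, ()):
            x[:, idx] = 1.0
        if self.eps is not None and len(self.restim_idx):
            sub = x[:, self.restim_idx]
            self.armed |= sub >= 2.0 * self.eps
            trigger = self.armed & (sub < self.eps)
            if trigger.any():
                runs, cols = np.nonzero(trigger)
                for run, col in zip(runs, cols):
                    node = int(self.restim_idx[col])
                    x[run, node] = 1.0
                    self.restim_events.append(
                        (int(run), self.node_ids[node], step)
                    )
                self.armed[trigger] = False


def apply_stimuli(
    state: Sequence[float] | np.ndarray,
    schedule_state: StimulusState,
    step: int,
) -> np.ndarray:
    """Single-run stimulus application; returns the updated state.

    ``schedule_state`` carries the refractory history between calls
    (create one :class:`StimulusState` per run).
    """
    x = np.asarray(state, dtype=float).reshape(1, -1).copy()
    schedule_state.apply(x, step)
    return x[0]


# -- vectorized integration core --------------------------------------


@dataclass
class BatchResult:
    """Raw output of a (possibly multi-run) integration.

    Per-run/per-node summary arrays use NaN for "undefined" (a decay or
    inactivation time never reached within the horizon).
    """

    times: np.ndarray
    node_order: list[str]
    activities: np.ndarray | None  # (R, n_steps+1, N) when retained
    mean: np.ndarray | None  # (n_steps+1, N)
    sd: np.ndarray | None
    auc: np.ndarray  # (R, N)
    window_auc: np.ndarray | None  # (R, N)
    peak_time: np.ndarray  # (R, N)
    peak_value: np.ndarray  # (R, N)
    decay_time: np.ndarray  # (R, N), NaN if undefined
    inactivation_time: np.ndarray | None  # (R,), NaN if never
    restim_events: list[tuple[int, str, int]]


def integrate_batch(
    net: SignalingNetwork,
    config: SimulationConfig,
    schedule: StimulusSchedule | None,
    rngs: Sequence[np.random.Generator],
    *,
    gates: np.ndarray | None = None,
    retain: bool = False,
    aggregate: bool = False,
    decay_fraction: float = 0.1,
    inactivation_eps: float | None = None,
    window_t: float | None = None,
    block_steps: int = 2000,
) -> BatchResult:
    """Integrate ``len(rngs)`` simultaneous runs of the activity SDE.

    All runs share the topology and schedule; per-run gate vectors (rows
    of ``gates``) allow per-run weight draws.  Summaries (trapezoidal
    AUC, earliest peak, post-peak decay time to ``decay_fraction`` of the
    peak, optional time to full inactivation of all non-receptors below
    ``inactivation_eps``) are accumulated online so full trajectories
    need not be retained.
    """
    if schedule is None:
        schedule = StimulusSchedule()
    schedule.validate(net, config)
    if net.has_unset_weights() and gates is None:
        raise ValueError("network has unset edge weights; assign or sample first")

    n_nodes = len(net.nodes)
    n_runs = len(rngs)
    if gates is None:
        gates = np.tile(gate_values(net, config.r), (n_runs, 1))
    gates = np.asarray(gates, dtype=float)
    if gates.shape != (n_runs, n_nodes):
        raise ValueError(
            f"gates shape {gates.shape} != ({n_runs}, {n_nodes})"
        )

    adj = net.adjacency_matrix()
    ku_eff, kd_eff = _rate_masks(net, config)
    dt = config.dt
    n_steps = config.n_steps
    times = np.arange(n_steps + 1) * dt
    sd_inc = config.increment_sd

    nonreceptor = np.array(
        [net.role(node_id) != "receptor" for node_id in net.node_ids]
    )

    x = np.zeros((n_runs, n_nodes))
    stim = StimulusState(net, schedule, config, n_runs)
    stim.apply(x, 0)

    full = (
        np.empty((n_runs, n_steps + 1, n_nodes)) if retain else None
    )
    mean = np.empty((n_steps + 1, n_nodes)) if aggregate else None
    sd = np.empty((n_steps + 1, n_nodes)) if aggregate else None

    auc = np.zeros((n_runs, n_nodes))
    window_auc = np.zeros((n_runs, n_nodes)) if window_t is not None else None
    w_steps = (
        int(math.floor(window_t / dt + 1e-9)) if window_t is not None else None
    )
    peak_value = x.copy()
    peak_step = np.zeros((n_runs, n_nodes), dtype=np.int64)
    decay_step = np.full((n_runs, n_nodes), np.nan)
    if inactivation_eps is not None:
        fi_step = np.full(n_runs, np.nan)
        fi_armed = np.zeros(n_runs, dtype=bool)
    else:
        fi_step = None
        fi_armed = None

    def record(step: int, xs: np.ndarray, x_prev: np.ndarray) -> None:
        nonlocal auc, window_auc, fi_armed
        if retain:
            full[:, step, :] = xs
        if aggregate:
            mean[step] = xs.mean(axis=0)
            sd[step] = xs.std(axis=0, ddof=1) if n_runs > 1 else 0.0
        if step > 0:
            seg = 0.5 * (x_prev + xs) * dt
            auc += seg
            if window_auc is not None and step <= w_steps:
                window_auc += seg
        newpk = xs > peak_value
        if newpk.any():
            peak_value[newpk] = xs[newpk]
            peak_step[newpk] = step
            decay_step[newpk] = np.nan
        if step > 0:
            hit = (
                np.isnan(decay_step)
                & (xs <= decay_fraction * peak_value)
                & ~newpk
                & (step > peak_step)
            )
            decay_step[hit] = step
        if fi_step is not None:
            sub = xs[:, nonreceptor]
            fi_armed |= (sub >= inactivation_eps).any(axis=1)
            done = (
                np.isnan(fi_step)
                & fi_armed
                & (sub < inactivation_eps).all(axis=1)
            )
            fi_step[done] = step

    record(0, x, x)

    step = 1
    while step <= n_steps:
        k = min(block_steps, n_steps - step + 1)
        if sd_inc > 0:
            dW = np.stack(
                [rng.normal(0.0, sd_inc, size=(k, n_nodes)) for rng in rngs]
            )
        else:
            dW = np.zeros((n_runs, k, n_nodes))
        for j in range(k):
            x_prev = x
            bx = gates * x
            x = (
                x
                + (ku_eff * (bx @ adj) - kd_eff * bx) * dt
                + config.sigma * x * dW[:, j, :]
            )
            if config.clamp_floor:
                np.maximum(x, 0.0, out=x)
            stim.apply(x, step)
            record(step, x, x_prev)
            step += 1
        if not np.isfinite(x).all():
            bad_runs = np.flatnonzero(~np.isfinite(x).all(axis=1))
            raise SimulationError(
                f"non-finite activities by step {step - 1} "
                f"(t={times[step - 1]:g}) in run(s) {bad_runs.tolist()}"
            )

    return BatchResult(
        times=times,
        node_order=list(net.node_ids),
        activities=full,
        mean=mean,
        sd=sd,
        auc=auc,
        window_auc=window_auc,
        peak_time=peak_step * dt,
        peak_value=peak_value,
        decay_time=decay_step * dt,
        inactivation_time=fi_step * dt if fi_step is not None else None,
        restim_events=stim.restim_events,
    )


def simulate(
    net: SignalingNetwork,
    config: SimulationConfig,
    schedule: StimulusSchedule | None = None,
    *,
    rng: np.random.Generator | None = None,
    run_index: int = 0,
) -> Trajectory:
    """Integrate one run and return its full :class:`Trajectory`.

    The noise stream defaults to the substream an ensemble would assign
    to member ``run_index`` under ``config.seed``, so a one-run ensemble
    and a direct call produce bit-identical trajectories.
    """
    if rng is None:
        rng = noise_rng_for_run(config.seed, run_index)
    result = integrate_batch(
        net, config, schedule, [rng], retain=True
    )
    return Trajectory(
        times=result.times,
        activities=result.activities[0],
        node_order=result.node_order,
        config=config,
        schedule=schedule if schedule is not None else StimulusSchedule(),
        seed=config.seed,
    )
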