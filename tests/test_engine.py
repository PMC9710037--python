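import numpy as np
import pytest

from boolsde import (
    MAPK_BACKBONE,
    SimulationConfig,
    StimulusSchedule,
    build_mapk_fixture,
    diffusion,
    draw_increments,
    drift,
    em_step,
    noise_rng_for_run,
    sample_weights,
    set_uniform_weights,
    simulate,
    weight_rng_for_run,
)
from boolsde.engine import StimulusState, apply_stimuli

from conftest import decay_pair


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt": 0.0},
            {"n_steps": 0},
            {"sigma": -1.0},
            {"r": 1.5},
            {"noise_scale": "bogus"},
        ],
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_defaults_match_reference_protocol(self):
        config = SimulationConfig()
        assert (config.dt, config.n_steps) == (0.001, 60_000)
        assert (config.k_u, config.k_d, config.sigma, config.r) == (1, 1, 1, 0.75)

    def test_roundtrip_dict(self):
        config = SimulationConfig(dt=0.01, sigma=0.5, seed=42)
        assert SimulationConfig.from_dict(config.to_dict()) == config


class TestDriftDiffusion:
    def test_receptor_drift_is_pure_decay(self):
        # receptor with outgoing gate 0.5, activity 1: drift = -k_d*0.5
        net = decay_pair(0.5)
        config = SimulationConfig(sigma=0.0)
        f = drift(net, [1.0, 0.0], config)
        assert f[0] == pytest.approx(-0.5)

    def test_terminal_drift_zero_with_inactive_upstream(self, mapk):
        net = set_uniform_weights(mapk, 0.5)
        config = SimulationConfig()
        x = np.zeros(len(net.nodes))
        x[net.node_index("Phenotype")] = 0.7
        assert drift(net, x, config)[net.node_index("Phenotype")] == 0.0

    def test_zero_state_gives_zero_drift(self, mapk):
        net = set_uniform_weights(mapk, 0.5)
        f = drift(net, np.zeros(11), SimulationConfig())
        assert np.all(f == 0.0)

    def test_diffusion_is_multiplicative(self):
        assert np.all(diffusion([0.0, 0.4], 1.0) == [0.0, 0.4])
        assert np.all(diffusion([0.3, 0.4], 0.0) == 0.0)


class TestIncrements:
    def test_variance_dt_scale(self):
        config = SimulationConfig(dt=0.001, noise_scale="variance_dt")
        draws = draw_increments(np.random.default_rng(0), config, 100_000)
        assert abs(draws.mean()) < 3 * np.sqrt(0.001 / 100_000)
        assert draws.var() == pytest.approx(0.001, rel=0.05)

    def test_sd_dt_scale(self):
        config = SimulationConfig(dt=0.001, noise_scale="sd_dt")
        draws = draw_increments(np.random.default_rng(0), config, 100_000)
        assert draws.std() == pytest.approx(0.001, rel=0.05)

    def test_same_seed_same_stream(self):
        config = SimulationConfig()
        a = draw_increments(np.random.default_rng(9), config, 1000)
        b = draw_increments(np.random.default_rng(9), config, 1000)
        assert np.array_equal(a, b)


class TestEMStep:
    def test_decay_arithmetic(self):
        net = decay_pair(0.5)
        config = SimulationConfig(dt=0.001, sigma=0.0)
        new = em_step([1.0, 0.0], net, config, [0.0, 0.0])
        assert new[0] == pytest.approx(0.9995)

    def test_origin_is_absorbing(self):
        net = decay_pair(0.5)
        config = SimulationConfig(sigma=1.0)
        new = em_step([0.0, 0.0], net, config, [0.3, -0.2])
        assert np.all(new == 0.0)

    def test_clamp_floor_prevents_negatives(self):
        net = decay_pair(1.0)
        config = SimulationConfig(dt=0.5, sigma=1.0, clamp_floor=True)
        new = em_step([0.001, 0.0], net, config, [-5.0, 0.0])
        assert new[0] == 0.0

    def test_no_clamp_allows_negative(self):
        net = decay_pair(1.0)
        config = SimulationConfig(dt=0.5, sigma=1.0, clamp_floor=False)
        new = em_step([0.001, 0.0], net, config, [-5.0, 0.0])
        assert new[0] < 0.0


class TestStimuli:
    def test_initial_stimulus(self, mapk):
        net = set_uniform_weights(mapk, 0.5)
        config = SimulationConfig()
        state = StimulusState(net, StimulusSchedule(initial=["EGFR"]), config)
        x = apply_stimuli(np.zeros(11), state, 0)
        assert x[net.node_index("EGFR")] == 1.0
        assert x.sum() == 1.0

    def test_empty_schedule_is_identity(self, mapk):
        net = set_uniform_weights(mapk, 0.5)
        config = SimulationConfig()
        state = StimulusState(net, StimulusSchedule(), config)
        x0 = np.full(11, 0.3)
        assert np.array_equal(apply_stimuli(x0, state, 0), x0)

    def test_non_receptor_stimulus_rejected(self, mapk):
        net = set_uniform_weights(mapk, 0.5)
        schedule = StimulusSchedule(initial=["GRB2"])
        with pytest.raises(ValueError, match="GRB2"):
            schedule.validate(net, SimulationConfig())

    def test_restim_triggers_at_threshold_crossing(self, fast_config):
        # Oracle: run the same seed without re-stimulation; both runs
        # share the noise stream up to the first reset, so the reset must
        # land exactly at the free run's first downward crossing of the
        # threshold.
        eps = 0.01
        net = decay_pair(0.5)
        config = fast_config.with_overrides(sigma=1.0, seed=3)
        free = simulate(net, config, StimulusSchedule(initial=["A"]))
        restim = simulate(
            net,
            config,
            StimulusSchedule(
                initial=["A"], restim_threshold=eps, restim_nodes=["A"]
            ),
        )
        x_free = free.activity("A")
        x_re = restim.activity("A")
        below = np.flatnonzero(x_free < eps)
        assert below.size, "noise never drove the receptor below threshold"
        first_cross = below[0]
        assert np.array_equal(x_free[:first_cross], x_re[:first_cross])
        assert x_re[first_cross] == 1.0
        # one reset per crossing: resets never fire on consecutive steps
        resets = np.flatnonzero(x_re == 1.0)
        resets = resets[resets > 0]
        assert resets.size >= 1
        assert np.all(np.diff(resets) > 1)


class TestSimulate:
    def test_no_stimulus_stays_zero(self, mapk, fast_config):
        net = set_uniform_weights(mapk, 0.5)
        traj = simulate(net, fast_config.with_overrides(n_steps=500))
        assert np.all(traj.activities == 0.0)

    def test_egfr_monotone_decay_without_noise(self, mapk, fast_config):
        net = sample_weights(mapk, weight_rng_for_run(0, 0))
        config = fast_config.with_overrides(sigma=0.0)
        traj = simulate(net, config, StimulusSchedule(initial=["EGFR"]))
        egfr = traj.activity("EGFR")
        assert egfr[0] == 1.0
        assert np.all(np.diff(egfr) <= 1e-12)

    def test_matches_discrete_and_continuous_decay(self):
        # isolated receptor with gate b: x(t_n) = (1 - b*dt)^n exactly,
        # within O(dt) of exp(-b t)
        b = 0.8
        net = decay_pair(b)
        config = SimulationConfig(dt=0.01, n_steps=500, sigma=0.0)
        traj = simulate(net, config, StimulusSchedule(initial=["A"]))
        x = traj.activity("A")
        n = np.arange(len(x))
        assert np.allclose(x, (1 - b * config.dt) ** n, rtol=1e-10)
        assert np.max(np.abs(x - np.exp(-b * traj.times))) < 5 * config.dt

    def test_first_order_dt_convergence(self):
        # halving dt should halve the error against the exponential
        b, t_end = 0.8, 4.0
        errors = []
        for dt in (0.02, 0.01):
            net = decay_pair(b)
            config = SimulationConfig(dt=dt, n_steps=int(t_end / dt), sigma=0.0)
            traj = simulate(net, config, StimulusSchedule(initial=["A"]))
            errors.append(
                np.max(np.abs(traj.activity("A") - np.exp(-b * traj.times)))
            )
        ratio = errors[0] / errors[1]
        assert 1.7 < ratio < 2.3

    def test_seed_determinism(self, mapk, fast_config):
        net = sample_weights(mapk, weight_rng_for_run(7, 0))
        config = fast_config.with_overrides(n_steps=500, seed=7)
        schedule = StimulusSchedule(initial=["EGFR"])
        a = simulate(net, config, schedule)
        b = simulate(net, config, schedule)
        assert np.array_equal(a.activities, b.activities)

    def test_backbone_sequential_activation(self, mapk, fast_config):
        # without noise, small-threshold first-crossing times are ordered
        # along the cascade
        net = sample_weights(mapk, weight_rng_for_run(1, 0))
        config = fast_config.with_overrides(sigma=0.0)
        traj = simulate(net, config, StimulusSchedule(initial=["EGFR"]))
        crossing = []
        for node in MAPK_BACKBONE:
            idx = np.flatnonzero(traj.activity(node) > 1e-3)
            assert idx.size, f"{node} never activated"
            crossing.append(traj.times[idx[0]])
        assert all(t2 >= t1 for t1, t2 in zip(crossing, crossing[1:]))

    def test_activities_never_negative_with_clamp(self, mapk, fast_config):
        net = sample_weights(mapk, weight_rng_for_run(2, 0))
        config = fast_config.with_overrides(sigma=1.0, n_steps=2000, seed=2)
        traj = simulate(net, config, StimulusSchedule(initial=["EGFR"]))
        assert traj.activities.min() >= 0.0

    def test_trajectory_grid_shape(self, mapk, fast_config):
        net = set_uniform_weights(mapk, 0.5)
        config = fast_config.with_overrides(n_steps=100)
        traj = simulate(net, config, StimulusSchedule(initial=["EGFR"]))
        assert traj.activities.shape == (101, 11)
        assert traj.times[-1] == pytest.approx(100 * config.dt)


class TestWriters:
    def test_tsv_and_csv_round_numbers(self, tmp_path, chain3, fast_config):
        config = fast_config.with_overrides(n_steps=20)
        traj = simulate(chain3, config, StimulusSchedule(initial=["A"]))
        traj.write_tsv(tmp_path / "t.tsv")
        traj.write_csv(tmp_path / "t.csv")
        tsv = (tmp_path / "t.tsv").read_text().splitlines()
        data = [line for line in tsv if not line.startswith("#")]
        assert len(data) == 1 + 21 * 3  # header + grid x nodes
        csv = (tmp_path / "t.csv").read_text().splitlines()
        header = [line for line in csv if not line.startswith("#")][0]
        assert header == "time,A,B,C"
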