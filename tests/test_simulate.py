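"""Simulator: Euler integration, impulse handling, presets, relapse detection."""

import numpy as np
import pytest

import tregloop as tl
from tregloop.pulses import PulseTrain, generate_pulse_train
from tregloop.simulate import detect_relapses


def test_presets_match_reference_regimes():
    h, a = tl.healthy_config(), tl.autoimmune_config()
    assert h.params.alpha_E == 2.0 and h.params.alpha_R == 1.0
    assert a.params.alpha_R == 0.25
    # the presets differ only in alpha_R
    assert a.params.with_(alpha_R=1.0) == h.params
    for cfg in (h, a):
        assert cfg.duration == 1825.0 and cfg.dt == 0.05
        assert cfg.params.delta == 1.0
        assert (cfg.params.gamma_E, cfg.params.gamma_R) == (0.2, 0.2)
        init = cfg.initial_tcells
        assert (init.E_r, init.R_r, init.E, init.R) == (0, 0, 1000.0, 200.0)
        assert (cfg.initial_damage.l, cfg.initial_damage.L) == (0.0, 0.0)


def test_determinism_bit_identical():
    cfg = tl.autoimmune_config(master_seed=5, duration=200.0)
    a, b = tl.simulate(cfg), tl.simulate(cfg)
    assert np.array_equal(a.states, b.states)
    assert np.array_equal(a.times, b.times)


def test_trajectory_invariants(short_autoimmune):
    traj = short_autoimmune
    assert traj.times[0] == 0.0
    assert np.all(np.diff(traj.times) > 0)
    assert np.all(traj.states[:, :5] >= 0.0)
    assert np.all(np.diff(traj.L) >= 0.0)  # irreversible damage monotone


def test_impulse_conservation(short_autoimmune):
    """Total injected cells equal amplitude x impulse count per the event log."""
    ev = short_autoimmune.events
    cfg = short_autoimmune.config
    assert ev["cells_injected_E"] == ev["n_impulses_E"] * cfg.pulse_amplitude_E
    assert ev["cells_injected_R"] == ev["n_impulses_R"] * cfg.pulse_amplitude_R
    logged_E = sum(m for _, pop, m in ev["impulses"] if pop == "resting_E")
    assert logged_E == pytest.approx(ev["cells_injected_E"])


def test_expected_impulse_count_on_five_year_run(short_autoimmune):
    assert short_autoimmune.events["n_impulses_E"] == 100  # 365-day run
    full = tl.simulate(tl.autoimmune_config(master_seed=2, duration=1825.0,
                                            record_stride=100))
    assert full.events["n_impulses_E"] == 500


def test_apply_impulse_semantics():
    s = tl.TCellState(E_r=1.0, R_r=2.0, E=3.0, R=4.0)
    assert tl.apply_impulse(s, "active_R", 0.0) == s
    bumped = tl.apply_impulse(s, "active_R", 1e4)
    assert bumped.R == pytest.approx(4.0 + 1e4)
    assert (bumped.E_r, bumped.R_r, bumped.E) == (1.0, 2.0, 3.0)
    with pytest.raises(ValueError):
        tl.apply_impulse(s, "plasma_cells", 1.0)
    with pytest.raises(ValueError):
        tl.apply_impulse(s, "active_E", -1.0)


def test_impulse_equals_restart_from_modified_initial_conditions():
    """A scheduled impulse is the same as restarting from the bumped state."""
    dur = 120.0
    cfg = tl.autoimmune_config(duration=dur)
    ss = np.random.SeedSequence(3)
    se, sr = ss.spawn(2)
    trains = (generate_pulse_train(100, 300.0, dur, se),
              generate_pulse_train(100, 60.0, dur, sr))
    t_imp, mag = 60.0, 5e3
    perturbed = tl.simulate(cfg, pulse_trains=trains,
                            scheduled_impulses=[(t_imp, "active_R", mag)])

    i = int(round(t_imp / cfg.dt))
    pre = tl.simulate(cfg, pulse_trains=trains)
    state = pre.states[i]
    bumped = tl.TCellState(E_r=state[0], R_r=state[1], E=state[2],
                           R=state[3] + mag)
    shift = lambda tr: PulseTrain(
        times=tuple(t - t_imp for t in tr.times if t > t_imp),
        amplitude=tr.amplitude, duration=dur - t_imp)
    restarted = tl.simulate(
        cfg.with_(duration=dur - t_imp, initial_tcells=bumped,
                  initial_damage=tl.DamageState(l=state[4], L=state[5])),
        pulse_trains=(shift(trains[0]), shift(trains[1])))
    np.testing.assert_allclose(restarted.states, perturbed.states[i:], rtol=1e-9)


def test_euler_refinement_adequacy():
    """Halving dt changes log-populations by < 5% over a 100-day run.

    Impulse times are aligned to the coarse grid so both resolutions apply
    them at identical times and the comparison isolates integration error.
    """
    dur, dt = 100.0, 0.05

    def snapped(amp, seed):
        tr = generate_pulse_train(100, amp, dur, seed)
        times = tuple(sorted(min(round(t / dt) * dt, dur - dt) for t in tr.times))
        return PulseTrain(times=times, amplitude=amp, duration=dur)

    trains = (snapped(300.0, 7), snapped(60.0, 8))
    coarse = tl.simulate(tl.autoimmune_config(duration=dur, dt=dt),
                         pulse_trains=trains)
    fine = tl.simulate(tl.autoimmune_config(duration=dur, dt=dt / 2,
                                            record_stride=2),
                       pulse_trains=trains)
    np.testing.assert_allclose(coarse.times, fine.times)
    x = np.log10(coarse.states + 1.0)
    y = np.log10(fine.states + 1.0)
    rel = np.abs(x - y) / np.maximum(np.abs(y), 1.0)
    assert rel.max() < 0.05


def test_convergence_to_reduced_equilibrium_under_constant_inflow():
    """With pulses replaced by their expected constant inflow, the full
    system settles near the reduced model's fixed point."""
    inflow = tl.expected_inflow()
    cfg = tl.autoimmune_config(pulse_rate_per_year=0.0,
                               constant_inflow_E=inflow.lambda_E,
                               constant_inflow_R=inflow.lambda_R,
                               duration=2000.0, record_stride=100)
    traj = tl.simulate(cfg)
    eq = tl.find_equilibrium(cfg.params, inflow)
    # the resting-pool bookkeeping (beta losses, eta recycling) shifts the
    # full-model equilibrium a few percent off the reduced one
    assert traj.E[-1] == pytest.approx(eq.E_star, rel=0.05)
    assert traj.R[-1] == pytest.approx(eq.R_star, rel=0.05)


def test_seed_heterogeneity_of_relapse_onsets():
    """Different noise seeds give different relapse timing (autoimmune)."""
    onsets = []
    for seed in range(4):
        traj = tl.simulate(tl.autoimmune_config(master_seed=seed))
        onsets.append(tuple(e.start for e in detect_relapses(traj)))
    assert len(set(onsets)) > 1


def test_nonfinite_state_raises_integration_error():
    # a state at the float ceiling overflows on the first growth step
    cfg = tl.healthy_config(duration=10.0, dt=1.0, pulse_rate_per_year=0.0)
    cfg = cfg.with_(params=cfg.params.with_(alpha_E=100.0),
                    initial_tcells=tl.TCellState(E_r=0, R_r=0, E=1e308, R=0))
    with pytest.raises(tl.IntegrationError, match="non-finite"):
        tl.simulate(cfg)


class TestDetectRelapses:
    def _rect_trajectory(self, levels):
        cfg = tl.autoimmune_config(duration=float(len(levels) - 1), dt=1.0)
        states = np.zeros((len(levels), 6))
        states[:, 2] = levels
        return tl.Trajectory(times=np.arange(len(levels), dtype=float),
                             states=states, config=cfg, events={})

    def test_constant_below_threshold_is_empty(self):
        traj = self._rect_trajectory([10.0] * 8)
        assert detect_relapses(traj, threshold=100.0) == []

    def test_single_rectangular_pulse(self):
        traj = self._rect_trajectory([0, 0, 150, 200, 150, 0, 0])
        (ep,) = detect_relapses(traj, threshold=100.0)
        assert (ep.start, ep.end) == (2.0, 4.0)
        assert ep.peak_E == 200.0 and ep.peak_time == 3.0

    def test_multiple_disjoint_ordered_episodes(self):
        traj = self._rect_trajectory([0, 150, 0, 0, 300, 400, 0, 120])
        eps = detect_relapses(traj, threshold=100.0)
        assert [(e.start, e.end) for e in eps] == [(1, 1), (4, 5), (7, 7)]
        assert eps[1].peak_E == 400.0

    def test_default_threshold_is_damage_scale(self, short_autoimmune):
        assert (detect_relapses(short_autoimmune)
                == detect_relapses(short_autoimmune, threshold=22800.0))

    def test_invalid_threshold(self, short_autoimmune):
        with pytest.raises(ValueError):
            detect_relapses(short_autoimmune, threshold=0.0)


def test_export_round_trip(tmp_path, short_autoimmune):
    df = short_autoimmune.to_frame()
    assert list(df.columns) == ["time", "E_r", "R_r", "E", "R", "l", "L"]
    path = tmp_path / "traj.tsv"
    short_autoimmune.to_table(path)
    import pandas as pd
    back = pd.read_csv(path, sep="\t")
    np.testing.assert_allclose(back["E"].to_numpy(), short_autoimmune.E)
    manifest = short_autoimmune.manifest()
    assert manifest["config"]["master_seed"] == 1
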