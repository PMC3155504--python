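"""Clinical comparison pipeline: discretization, differencing, sliding correlation."""

import numpy as np
import pandas as pd
import pytest

import tregloop as tl
from tregloop.clinical import (
    MONTH_DAYS,
    PatientSeries,
    best_sliding_correlation,
    correlation_distribution,
    evolution_series,
    monthly_series,
    read_cel_table,
    simulate_evolution_bank,
    write_cel_table,
)


def _table(tmp_path, rows, name="cel.tsv", sep="\t"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    return path


class TestReadCelTable:
    def test_two_patient_fixture(self, tmp_path):
        rows = [{"patient_id": p, "month": m, "cel": (m + i) % 3, "edss": 1.5,
                 "relapse": 0}
                for i, p in enumerate(["P1", "P2"]) for m in range(6)]
        series = read_cel_table(_table(tmp_path, rows))
        assert [s.patient_id for s in series] == ["P1", "P2"]
        assert all(s.n_months == 6 for s in series)
        assert series[0].edss is not None and series[0].relapse_flags is not None

    def test_comma_delimiter_sniffed(self, tmp_path):
        rows = [{"patient_id": "P1", "month": m, "cel": m} for m in range(4)]
        series = read_cel_table(_table(tmp_path, rows, "cel.csv", sep=","))
        assert series[0].n_months == 4

    def test_negative_count_rejected(self, tmp_path):
        rows = [{"patient_id": "P1", "month": m, "cel": c}
                for m, c in enumerate([0, 1, -2, 0])]
        with pytest.raises(ValueError, match="P1"):
            read_cel_table(_table(tmp_path, rows))

    def test_nonconsecutive_months_rejected(self, tmp_path):
        rows = [{"patient_id": "P1", "month": m, "cel": 0} for m in (0, 1, 3)]
        with pytest.raises(ValueError, match="consecutive"):
            read_cel_table(_table(tmp_path, rows))

    def test_missing_column_rejected(self, tmp_path):
        rows = [{"patient_id": "P1", "month": 0}]
        with pytest.raises(ValueError, match="cel"):
            read_cel_table(_table(tmp_path, rows))

    def test_round_trip(self, tmp_path):
        patients = [PatientSeries("A", np.array([0, 2, 1, 5]),
                                  relapse_flags=np.array([0, 1, 0, 1], bool))]
        path = tmp_path / "out.tsv"
        write_cel_table(patients, path)
        (back,) = read_cel_table(path)
        np.testing.assert_array_equal(back.cel, patients[0].cel)
        np.testing.assert_array_equal(back.relapse_flags,
                                      patients[0].relapse_flags)


class TestMonthlySeries:
    def test_ten_year_run_gives_120_months(self):
        traj = tl.simulate(tl.autoimmune_config(duration=3650.0, master_seed=0,
                                                record_stride=10))
        assert len(monthly_series(traj, "l")) == 120

    def test_constant_variable_gives_constant_series(self, short_autoimmune):
        cfg = short_autoimmune.config
        states = np.tile([0, 0, 5.0, 5.0, 3.0, 1.0], (len(short_autoimmune), 1))
        traj = tl.Trajectory(times=short_autoimmune.times, states=states,
                             config=cfg, events={})
        out = monthly_series(traj, "l")
        assert np.all(out == 3.0)

    def test_linear_variable_gives_constant_increments(self, short_autoimmune):
        states = np.zeros((len(short_autoimmune), 6))
        states[:, 4] = 2.0 * short_autoimmune.times  # l = 2t
        traj = tl.Trajectory(times=short_autoimmune.times, states=states,
                             config=short_autoimmune.config, events={})
        inc = evolution_series(monthly_series(traj, "l"))
        # month boundaries snap to the 0.05-day grid, so increments are
        # exact only to one grid step of slope
        np.testing.assert_allclose(inc, 2.0 * MONTH_DAYS, atol=2 * 0.05 * 2.0)

    def test_too_short_trajectory_rejected(self, short_autoimmune):
        with pytest.raises(ValueError, match="months"):
            monthly_series(short_autoimmune, "l", months=48)


class TestEvolutionSeries:
    def test_constant_series_is_all_zero(self):
        np.testing.assert_array_equal(evolution_series([4, 4, 4, 4]), [0, 0, 0])

    def test_worked_example(self):
        np.testing.assert_array_equal(evolution_series([0, 2, 1]), [2, -1])

    def test_telescoping_sum(self):
        rng = np.random.default_rng(0)
        s = rng.integers(0, 10, size=48).astype(float)
        assert evolution_series(s).sum() == pytest.approx(s[-1] - s[0])

    def test_shift_invariance(self):
        s = np.array([1.0, 5.0, 2.0, 8.0])
        np.testing.assert_allclose(evolution_series(s), evolution_series(s + 17.3))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            evolution_series([1.0])


class TestBestSlidingCorrelation:
    def test_self_match_is_perfect(self):
        rng = np.random.default_rng(2)
        long = rng.normal(size=119)
        short = long[30:77]
        r, off = best_sliding_correlation(short, long)
        assert r == pytest.approx(1.0)
        assert off == 30

    def test_negated_embedding(self):
        rng = np.random.default_rng(3)
        long = rng.normal(size=100)
        short = -long[10:40]
        windows = np.lib.stride_tricks.sliding_window_view(long, 30)
        r_at_neg = np.corrcoef(short, windows[10])[0, 1]
        assert r_at_neg == pytest.approx(-1.0)
        r, off = best_sliding_correlation(short, long)
        assert off != 10 and r > -1.0

    def test_alignment_count_48_in_120(self):
        """48-month and 120-month raw series give 73 alignments after
        differencing (47-point window in a 119-point series)."""
        disease = evolution_series(np.arange(48.0) % 5)
        insilico = evolution_series(np.sin(np.arange(120.0)))
        m, n = len(disease), len(insilico)
        assert (m, n) == (47, 119)
        assert n - m + 1 == 73

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        d, s = rng.normal(size=20), rng.normal(size=60)
        r0, off0 = best_sliding_correlation(d, s)
        r1, off1 = best_sliding_correlation(3.0 * d + 7.0, 0.5 * s - 2.0)
        assert r1 == pytest.approx(r0)
        assert off1 == off0

    def test_zero_variance_disease_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            best_sliding_correlation(np.zeros(10), np.random.default_rng(0).normal(size=30))

    def test_zero_variance_simulated_windows_skipped(self):
        d = np.array([1.0, 2.0, 0.5, 3.0])
        s = np.concatenate([np.zeros(6), [1.0, 2.0, 0.5, 3.0], np.zeros(4)])
        r, off = best_sliding_correlation(d, s)
        assert r == pytest.approx(1.0)
        assert off == 6

    def test_white_noise_null_stays_moderate(self):
        """Max-over-alignments of two unrelated series concentrates well
        below the clinical correlation levels (selection-maximum null)."""
        rng = np.random.default_rng(5)
        best = [best_sliding_correlation(rng.normal(size=47),
                                         rng.normal(size=119))[0]
                for _ in range(200)]
        assert np.median(best) < 0.55
        assert np.median(best) > 0.0  # maximum selection biases upward


class TestCorrelationDistribution:
    def test_single_simulation_distribution(self):
        patient = PatientSeries("P1", np.arange(12) % 4)
        dist = correlation_distribution(patient, n_simulations=1, months=24,
                                        master_seed=0)
        assert dist.n_simulations == 1
        assert len(dist.best_r) == 1
        assert -1 <= dist.best_r[0] <= 1

    def test_bank_shared_across_patients(self):
        bank = simulate_evolution_bank(3, months=24, master_seed=1)
        p1 = PatientSeries("P1", (np.arange(12) % 5))
        p2 = PatientSeries("P2", (np.arange(12) % 3))
        d1 = correlation_distribution(p1, bank=bank)
        d2 = correlation_distribution(p2, bank=bank)
        assert d1.n_simulations == d2.n_simulations == 3
        summary = d1.summary()
        assert set(summary) >= {"median", "mode_bin_center", "max"}

    def test_closed_loop_self_detection(self):
        """A patient series that IS a simulated damage series correlates
        essentially perfectly when its generating run is in the bank."""
        months = 48
        cfg = tl.autoimmune_config(master_seed=7)
        patient, traj = tl.plant_signal(sim_config=cfg, months=months,
                                        noise=False)
        gen = evolution_series(monthly_series(traj, "l", months=months))
        other = simulate_evolution_bank(2, months=months, master_seed=99)
        dist = correlation_distribution(patient, bank=[gen] + other)
        assert dist.best_r.max() > 0.99
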