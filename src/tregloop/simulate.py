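"""Fixed-step integration of the stochastic Teff–Treg system.

The six-variable system (four T-cell pools plus reversible/irreversible
damage) is advanced with explicit Euler on the model's reference grid (dt = 0.05
days over 1825 days).  Stochastic resting-cell impulses are applied as
instantaneous state jumps at the first grid point at or after each impulse
time; any component driven below zero by a step is clipped to zero and the
event logged.  Two presets span the model's regimes: *healthy*
(alpha_E = 2, alpha_R = 1, homeostatic fluctuation) and *autoimmune*
(alpha_R = 0.25, recurrent relapse-like Teff bursts).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    DamageParameters,
    DamageState,
    ModelParameters,
    TCellState,
)
from .pulses import (
    DEFAULT_AMPLITUDE_E,
    DEFAULT_AMPLITUDE_R,
    DEFAULT_RATE_PER_YEAR,
    PulseTrain,
    generate_pulse_train,
)

__all__ = [
    "POPULATIONS",
    "SimulationConfig",
    "Trajectory",
    "RelapseEpisode",
    "IntegrationError",
    "simulate",
    "healthy_config",
    "autoimmune_config",
    "apply_impulse",
    "detect_relapses",
]

POPULATIONS = ("resting_E", "resting_R", "active_E", "active_R")

_STATE_COLUMNS = ("E_r", "R_r", "E", "R", "l", "L")


class IntegrationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, reproducible specification of one simulation run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    damage_params: DamageParameters = field(default_factory=DamageParameters)
    initial_tcells: TCellState = field(default_factory=TCellState)
    initial_damage: DamageState = field(default_factory=DamageState)
    duration: float = 1825.0
    dt: float = 0.05
    master_seed: int = 0
    pulse_rate_per_year: float = DEFAULT_RATE_PER_YEAR
    pulse_amplitude_E: float = DEFAULT_AMPLITUDE_E
    pulse_amplitude_R: float = DEFAULT_AMPLITUDE_R
    # deterministic resting-cell influx rates (cells/day), added on top of
    # the pulse trains; set the pulse rate to 0 to force the system with
    # constant inflow only (the reduced model's averaged forcing)
    constant_inflow_E: float = 0.0
    constant_inflow_R: float = 0.0
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one step")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RelapseEpisode:
    """A maximal interval during which activated Teff stays at/above threshold."""

    start: float
    peak_time: float
    peak_E: float
    end: float


@dataclass
class Trajectory:
    """Time-indexed record of one simulation.

    Attributes
    ----------
    times : ndarray
        Recorded times, days; strictly increasing, starting at 0.
    states : ndarray, shape (n, 6)
        Columns (E_r, R_r, E, R, l, L) at each recorded time.
    config : SimulationConfig
        The configuration that produced the run.
    events : dict
        Log of applied impulses (pool, time, magnitude) and of clipped
        negative undershoots.
    """

    times: np.ndarray
    states: np.ndarray
    config: SimulationConfig
    events: dict

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def E_r(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def R_r(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def l(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def L(self) -> np.ndarray:
        return self.states[:, 5]

    def state_at(self, t: float) -> np.ndarray:
        """State at the recorded grid point nearest to time ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        return self.states[i]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns time, E_r, R_r, E, R, l, L."""
        df = pd.DataFrame(self.states, columns=list(_STATE_COLUMNS))
        df.insert(0, "time", self.times)
        return df

    def to_table(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def manifest(self) -> dict:
        """JSON-serializable description sufficient to reproduce the run."""
        from . import __version__

        return {
            "config": self.config.to_dict(),
            "package_version": __version__,
            "n_samples": int(len(self)),
            "events": {k: v for k, v in self.events.items()
                       if k in ("n_impulses_E", "n_impulses_R",
                                "cells_injected_E", "cells_injected_R",
                                "n_clips")},
        }

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def healthy_config(**overrides) -> SimulationConfig:
    """Preset for the healthy regime: alpha_E = 2, alpha_R = 1."""
    cfg = SimulationConfig(params=ModelParameters(alpha_E=2.0, alpha_R=1.0))
    return cfg.with_(**overrides) if overrides else cfg


def autoimmune_config(**overrides) -> SimulationConfig:
    """Preset for the autoimmune regime: identical to healthy except alpha_R = 0.25."""
    cfg = SimulationConfig(params=ModelParameters(alpha_E=2.0, alpha_R=0.25))
    return cfg.with_(**overrides) if overrides else cfg


def apply_impulse(state: TCellState, population: str, magnitude: float) -> TCellState:
    """Instantaneously add ``magnitude`` cells to one named pool.

    ``population`` is one of ``resting_E``, ``resting_R``, ``active_E``,
    ``active_R``; all other components are unchanged.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; expected one of {POPULATIONS}")
    fieldname = {"resting_E": "E_r", "resting_R": "R_r",
                 "active_E": "E", "active_R": "R"}[population]
    return replace(state, **{fieldname: getattr(state, fieldname) + magnitude})


def _grid_index(t: float, dt: float, n_steps: int) -> int:
    """First grid point at or after time t (clamped to the final point)."""
    i = math.ceil(t / dt - 1e-9)
    return min(max(i, 0), n_steps)


def simulate(
    config: SimulationConfig,
    pulse_trains: tuple[PulseTrain, PulseTrain] | None = None,
    scheduled_impulses: Sequence[tuple[float, str, float]] = (),
) -> Trajectory:
    """Integrate the full six-variable system under pulse-train forcing.

    Parameters
    ----------
    config : SimulationConfig
        Parameters, initial state, grid and stochastic-forcing spec.
    pulse_trains : (PulseTrain, PulseTrain), optional
        Explicit (Teff, Treg) resting-cell trains to replay; when omitted,
        trains are drawn from ``config.master_seed`` (two independent
        streams spawned from one master seed).
    scheduled_impulses : sequence of (time, population, magnitude), optional
        Additional deterministic impulses (e.g. a therapy bolus), applied
        at the first grid point at or after each time.

    Returns
    -------
    Trajectory
        Deterministic given the full configuration; irreversible damage is
        non-decreasing along the output.
    """
    p = config.params
    dp = config.damage_params
    dt = config.dt
    n_steps = int(round(config.duration / dt))

    if pulse_trains is None:
        ss = np.random.SeedSequence(config.master_seed)
        ss_e, ss_r = ss.spawn(2)
        train_E = generate_pulse_train(config.pulse_rate_per_year,
                                       config.pulse_amplitude_E,
                                       config.duration, ss_e)
        train_R = generate_pulse_train(config.pulse_rate_per_year,
                                       config.pulse_amplitude_R,
                                       config.duration, ss_r)
    else:
        train_E, train_R = pulse_trains

    # Impulse jumps per grid point, for each of the six state slots.
    inj: list[dict[int, float]] = [dict() for _ in range(4)]
    impulse_log: list[tuple[float, str, float]] = []

    def _schedule(slot: int, t: float, mag: float, label: str) -> None:
        k = _grid_index(t, dt, n_steps)
        inj[slot][k] = inj[slot].get(k, 0.0) + mag
        impulse_log.append((k * dt, label, mag))

    for t in train_E.times:
        _schedule(0, t, train_E.amplitude, "resting_E")
    for t in train_R.times:
        _schedule(1, t, train_R.amplitude, "resting_R")
    slot_of = {"resting_E": 0, "resting_R": 1, "active_E": 2, "active_R": 3}
    for t, pop, mag in scheduled_impulses:
        if pop not in slot_of:
            raise ValueError(f"unknown population {pop!r}")
        if mag < 0:
            raise ValueError("impulse magnitude must be non-negative")
        _schedule(slot_of[pop], t, mag, pop)

    inj_Er, inj_Rr, inj_E, inj_R = inj

    stride = config.record_stride
    rec_idx = list(range(0, n_steps + 1, stride))
    if rec_idx[-1] != n_steps:
        rec_idx.append(n_steps)
    record_at = {k: i for i, k in enumerate(rec_idx)}
    out = np.empty((len(rec_idx), 6), dtype=float)
    out_times = np.array([k * dt for k in rec_idx], dtype=float)

    # Unpack everything into locals: the Euler loop is pure Python for speed.
    delta, beta, eta = p.delta, p.beta, p.eta
    aE, aR, gE, gR = p.alpha_E, p.alpha_R, p.gamma_E, p.gamma_R
    kE, kR, h = p.k_E, p.k_R, p.hill_h
    d1, d2, a, r = dp.d1, dp.d2, dp.a, dp.r
    lr_loss = r + d2
    i_E, i_R = config.constant_inflow_E, config.constant_inflow_R
    if i_E < 0 or i_R < 0:
        raise ValueError("constant inflow rates must be non-negative")

    E_r = config.initial_tcells.E_r
    R_r = config.initial_tcells.R_r
    E = config.initial_tcells.E
    R = config.initial_tcells.R
    l = config.initial_damage.l
    L = config.initial_damage.L

    n_clips = 0
    inf = float("inf")
    hill_sat = 1e250 ** (1.0 / h)  # ratio beyond which (x/k)^h overflows

    for k in range(n_steps + 1):
        if k in inj_Er:
            E_r += inj_Er[k]
        if k in inj_Rr:
            R_r += inj_Rr[k]
        if k in inj_E:
            E += inj_E[k]
        if k in inj_R:
            R += inj_R[k]

        i = record_at.get(k)
        if i is not None:
            out[i, 0] = E_r
            out[i, 1] = R_r
            out[i, 2] = E
            out[i, 3] = R
            out[i, 4] = l
            out[i, 5] = L

        if k == n_steps:
            break

        rR = R / kR
        if rR > hill_sat:
            up_R = 1.0
        else:
            tR = rR ** h
            up_R = tR / (1.0 + tR)
        rE = E / kE
        if rE > hill_sat:
            up_E = 1.0
        else:
            tE = rE ** h
            up_E = tE / (1.0 + tE)

        dE_r = i_E - (delta + beta) * E_r + eta * E
        dR_r = i_R - (delta + beta) * R_r + eta * R
        dE = delta * E_r + aE * E * (1.0 - up_R) - gE * E * (1.0 + up_R) - eta * E
        dR = delta * R_r + aR * R * up_E - gR * R - eta * R
        e_ratio = E / a
        e_prime = e_ratio * e_ratio  # multiplication overflows to inf, not error
        dl = d1 * e_prime - lr_loss * l
        dL = d2 * l

        E_r += dt * dE_r
        R_r += dt * dR_r
        E += dt * dE
        R += dt * dR
        l += dt * dl
        L += dt * dL

        if E_r < 0.0:
            E_r = 0.0
            n_clips += 1
        if R_r < 0.0:
            R_r = 0.0
            n_clips += 1
        if E < 0.0:
            E = 0.0
            n_clips += 1
        if R < 0.0:
            R = 0.0
            n_clips += 1
        if l < 0.0:
            l = 0.0
            n_clips += 1

        if not (E_r < inf and R_r < inf and E < inf and R < inf
                and l < inf and L < inf) or E != E:
            raise IntegrationError(
                f"non-finite state at step {k + 1} (t={(k + 1) * dt:.3f} d): "
                f"E_r={E_r}, R_r={R_r}, E={E}, R={R}, l={l}, L={L}")

    events = {
        "impulses": impulse_log,
        "n_impulses_E": len(train_E.times),
        "n_impulses_R": len(train_R.times),
        "cells_injected_E": train_E.total_cells(),
        "cells_injected_R": train_R.total_cells(),
        "n_clips": n_clips,
    }
    return Trajectory(times=out_times, states=out, config=config, events=events)


def detect_relapses(traj: Trajectory, threshold: float | None = None) -> list[RelapseEpisode]:
    """Find maximal episodes with activated Teff at or above ``threshold``.

    The default threshold is the tissue-damage population scale
    ``a`` (22800 cells), the only population-scale threshold the model
    defines.  Episodes are disjoint, ordered, and reported with their
    start/end times and peak.
    """
    if threshold is None:
        threshold = traj.config.damage_params.a
    if threshold <= 0:
        raise ValueError("threshold must be strictly positive")
    above = traj.E >= threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    ends: list[int] = []
    for i in edges:
        if above[i]:      # True -> False transition, episode ends at i
            ends.append(int(i))
        else:             # False -> True transition, episode starts at i+1
            starts.append(int(i) + 1)
    if above[-1]:
        ends.append(len(above) - 1)
    episodes = []
    for s, e in zip(starts, ends):
        seg = traj.E[s:e + 1]
        ipk = s + int(np.argmax(seg))
        episodes.append(RelapseEpisode(
            start=float(traj.times[s]),
            peak_time=float(traj.times[ipk]),
            peak_E=float(traj.E[ipk]),
            end=float(traj.times[e]),
        ))
    return episodes
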