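"""Stochastic pulse-train forcing of the resting T-cell pools.

Thymic escape of self-reactive T cells is modelled as sparse, drastic
impulses — spike trains — rather than Gaussian white noise: a fixed number
of impulses per year at times drawn independently and uniformly over the
simulated span.  Each impulse instantaneously adds a fixed number of cells
to a resting pool.  The reduced deterministic model replaces each train by
its expected influx rate (amplitude x rate averaged over the year).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DAYS_PER_YEAR",
    "DEFAULT_RATE_PER_YEAR",
    "DEFAULT_AMPLITUDE_E",
    "DEFAULT_AMPLITUDE_R",
    "PulseTrain",
    "ExpectedInflow",
    "generate_pulse_train",
    "expected_inflow",
]

DAYS_PER_YEAR = 365.0

# Reference forcing frequency: 100 randomly distributed impulses per year.
DEFAULT_RATE_PER_YEAR = 100.0
# Impulse amplitudes are free constants.  The defaults keep the 5:1
# Teff:Treg ratio of the half-max constants and initial activated pools,
# at the largest scale for which the healthy preset remains homeostatic
# (bounded Treg) and the phase plane keeps a stable spiral equilibrium
# across the full alpha_R range; see docs/methods.md.
DEFAULT_AMPLITUDE_E = 300.0
DEFAULT_AMPLITUDE_R = 60.0


@dataclass(frozen=True)
class PulseTrain:
    """One realization of a spike train of resting-cell impulses.

    Attributes
    ----------
    times : tuple of float
        Impulse times in days, sorted ascending, each in [0, duration).
    amplitude : float
        Cells added per impulse, > 0.
    duration : float
        Total span covered by the train, days.
    seed : int or None
        Seed of the generator that produced the times (None for trains
        built by hand or loaded from file).
    """

    times: tuple[float, ...]
    amplitude: float
    duration: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be strictly positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        ts = self.times
        if any(t < 0 or t >= self.duration for t in ts):
            raise ValueError("impulse times must lie in [0, duration)")
        if any(ts[i] > ts[i + 1] for i in range(len(ts) - 1)):
            raise ValueError("impulse times must be sorted ascending")

    def __len__(self) -> int:
        return len(self.times)

    def total_cells(self) -> float:
        """Total cells injected over the whole train."""
        return self.amplitude * len(self.times)

    def to_table(self, path: str | Path) -> None:
        """Write the train as a two-column TSV (time_days, amplitude_cells)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["time_days", "amplitude_cells"])
            for t in self.times:
                w.writerow([repr(t), repr(self.amplitude)])

    @classmethod
    def from_table(cls, path: str | Path, duration: float | None = None) -> "PulseTrain":
        """Read a train written by :meth:`to_table`.

        ``duration`` defaults to just past the last impulse time.
        """
        times: list[float] = []
        amps: list[float] = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header[:2] != ["time_days", "amplitude_cells"]:
                raise ValueError(f"unexpected header {header!r}")
            for row in reader:
                times.append(float(row[0]))
                amps.append(float(row[1]))
        if amps and len(set(amps)) != 1:
            raise ValueError("pulse-train tables must have a single amplitude")
        amplitude = amps[0] if amps else 1.0
        if duration is None:
            duration = (max(times) + 1.0) if times else 0.0
        return cls(times=tuple(sorted(times)), amplitude=amplitude,
                   duration=duration, seed=None)


@dataclass(frozen=True)
class ExpectedInflow:
    """Expected (time-averaged) resting-cell influx rates, cells/day."""

    lambda_E: float = field(default=DEFAULT_RATE_PER_YEAR * DEFAULT_AMPLITUDE_E / DAYS_PER_YEAR)
    lambda_R: float = field(default=DEFAULT_RATE_PER_YEAR * DEFAULT_AMPLITUDE_R / DAYS_PER_YEAR)

    def __post_init__(self) -> None:
        if self.lambda_E < 0 or self.lambda_R < 0:
            raise ValueError("expected inflow rates must be non-negative")


def generate_pulse_train(
    rate_per_year: float,
    amplitude: float,
    duration: float,
    seed: int | np.random.SeedSequence,
    *,
    poisson: bool = False,
) -> PulseTrain:
    """Draw one pulse-train realization.

    The impulse count is fixed at ``round(rate_per_year * duration / 365)``
    (the trains have a fixed frequency; changing the seed moves
    the impulse times but keeps the count).  Times are i.i.d. uniform on
    [0, duration).  With ``poisson=True`` the count is instead Poisson with
    the same mean, for robustness studies.

    Parameters
    ----------
    rate_per_year : float
        Nominal impulse frequency, impulses/year, >= 0.
    amplitude : float
        Cells added per impulse, > 0.
    duration : float
        Span of the train, days, >= 0.
    seed : int or numpy.random.SeedSequence
        Seed for the time draws; identical seeds give identical trains.
    poisson : bool, optional
        Draw the count from a Poisson distribution instead of fixing it.

    Returns
    -------
    PulseTrain
    """
    if rate_per_year < 0:
        raise ValueError("rate_per_year must be non-negative")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    mean_count = rate_per_year * duration / DAYS_PER_YEAR
    n = int(rng.poisson(mean_count)) if poisson else int(round(mean_count))
    times = np.sort(rng.uniform(0.0, duration, size=n)) if duration > 0 else np.empty(0)
    seed_repr = seed if isinstance(seed, int) else None
    return PulseTrain(times=tuple(float(t) for t in times), amplitude=amplitude,
                      duration=duration, seed=seed_repr)


def expected_inflow(
    rate_per_year_E: float = DEFAULT_RATE_PER_YEAR,
    amplitude_E: float = DEFAULT_AMPLITUDE_E,
    rate_per_year_R: float = DEFAULT_RATE_PER_YEAR,
    amplitude_R: float = DEFAULT_AMPLITUDE_R,
) -> ExpectedInflow:
    """Expected influx rates implied by a pulse-train specification.

    Each train of ``rate`` impulses/year of ``amplitude`` cells delivers on
    average ``rate * amplitude / 365`` cells/day.
    """
    return ExpectedInflow(
        lambda_E=rate_per_year_E * amplitude_E / DAYS_PER_YEAR,
        lambda_R=rate_per_year_R * amplitude_R / DAYS_PER_YEAR,
    )
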