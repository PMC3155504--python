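"""Synthetic patient cohorts with relapsing-remitting CEL statistics.

Each synthetic patient is backed by one autoimmune-regime simulation: the
monthly reversible-damage series sets the expected lesion count, and the
observed monthly CEL count is drawn from a Poisson (optionally
negative-binomial) distribution around it.  A month is flagged as a
relapse when the underlying activated-Teff count crossed the relapse
threshold during that month.  The resulting 48-month integer series show
the bursty temporal clustering and patient-to-patient heterogeneity the
clinical comparison pipeline assumes, so the pipeline is fully testable
without any real patient table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clinical import MONTH_DAYS, PatientSeries, monthly_series
from .simulate import SimulationConfig, Trajectory, autoimmune_config, simulate

__all__ = [
    "DEFAULT_CEL_SCALE",
    "SyntheticCohortSpec",
    "synthesize_cohort",
    "plant_signal",
]

# Expected CELs per unit reversible damage.  Chosen once so that the
# default cohort's mean monthly CEL count lands in the 1-3 lesion range
# typical of active relapsing-remitting MS (a convention: the damage
# variable has arbitrary units and no identified lesion calibration).
DEFAULT_CEL_SCALE = 0.3


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Specification of a synthetic cohort.

    Attributes
    ----------
    n_patients : int
        Number of subjects (default 9, the size of the reference cohort).
    months : int
        Observation span in months (default 48).
    alpha_R : float or sequence of float
        Per-patient maximum Treg proliferation rate, 1/day — the severity
        knob; a scalar applies to every patient.
    scale : float
        Expected CELs per unit reversible damage, > 0.
    seed : int
        Master seed; per-patient streams are derived from it.
    """

    n_patients: int = 9
    months: int = 48
    alpha_R: float | Sequence[float] = 0.25
    scale: float = DEFAULT_CEL_SCALE
    seed: int = 0
    noise: str = "poisson"
    dispersion: float = 5.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.months < 2:
            raise ValueError("months must be >= 2")
        if self.scale < 0:
            raise ValueError("scale must be non-negative")
        if self.noise not in ("poisson", "negbinom"):
            raise ValueError("noise must be 'poisson' or 'negbinom'")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be strictly positive")

    def alpha_R_for(self, i: int) -> float:
        if np.isscalar(self.alpha_R):
            return float(self.alpha_R)  # type: ignore[arg-type]
        seq = list(self.alpha_R)  # type: ignore[arg-type]
        if len(seq) != self.n_patients:
            raise ValueError("alpha_R sequence length must equal n_patients")
        return float(seq[i])


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 noise: str, dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if noise == "poisson":
        return rng.poisson(mean)
    # Negative binomial with variance mean + mean^2/dispersion.
    counts = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    p = dispersion / (dispersion + mean[pos])
    counts[pos] = rng.negative_binomial(dispersion, p)
    return counts


def _relapse_flags(traj: Trajectory, months: int, month_length: float,
                   threshold: float) -> np.ndarray:
    flags = np.zeros(months, dtype=bool)
    for m in range(1, months + 1):
        sel = ((traj.times > (m - 1) * month_length)
               & (traj.times <= m * month_length))
        flags[m - 1] = bool(np.any(traj.E[sel] >= threshold))
    return flags


def _patient_from_trajectory(
    traj: Trajectory,
    patient_id: str,
    months: int,
    scale: float,
    rng: np.random.Generator | None,
    noise: str = "poisson",
    dispersion: float = 5.0,
    month_length: float = MONTH_DAYS,
) -> PatientSeries:
    l_monthly = monthly_series(traj, "l", months=months, month_length=month_length)
    mean = scale * l_monthly
    if rng is None:  # noise-free variant: deterministic rounding
        cel = np.round(mean).astype(np.int64)
    else:
        cel = _draw_counts(rng, mean, noise, dispersion)
    flags = _relapse_flags(traj, months, month_length,
                           traj.config.damage_params.a)
    return PatientSeries(patient_id=patient_id, cel=cel,
                         relapse_flags=flags, source="synthetic")


def synthesize_cohort(spec: SyntheticCohortSpec) -> list[PatientSeries]:
    """Generate a synthetic cohort of monthly CEL series.

    Each patient runs an independent autoimmune-regime simulation (its own
    alpha_R and noise stream), samples reversible damage monthly, and
    draws ``cel[t]`` from the configured count distribution with mean
    ``scale * l[t]``.  Reproducible given ``spec.seed``.
    """
    patients = []
    for i in range(spec.n_patients):
        ss = np.random.SeedSequence(spec.seed, spawn_key=(i,))
        sim_seed = int(ss.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(ss.spawn(1)[0])
        cfg = autoimmune_config(master_seed=sim_seed)
        cfg = cfg.with_(params=cfg.params.with_(alpha_R=spec.alpha_R_for(i)))
        duration = math.ceil(spec.months * MONTH_DAYS / cfg.dt) * cfg.dt
        traj = simulate(cfg.with_(duration=float(duration)))
        patients.append(_patient_from_trajectory(
            traj, f"synthetic-{i + 1:02d}", spec.months, spec.scale, rng,
            spec.noise, spec.dispersion))
    return patients


def plant_signal(
    sim_config: SimulationConfig | None = None,
    months: int = 48,
    scale: float = DEFAULT_CEL_SCALE,
    seed: int = 0,
    noise: bool = True,
) -> tuple[PatientSeries, Trajectory]:
    """Synthetic patient paired with the trajectory that generated it.

    Because the generating process is known, the clinical pipeline can be
    validated in closed loop: the best sliding correlation against the
    generating trajectory should beat the correlation against an
    independent trajectory.  With ``noise=False`` the CEL series is the
    rounded scaled damage itself, so the self-correlation is essentially
    perfect at offset zero.
    """
    cfg = sim_config if sim_config is not None else autoimmune_config()
    cfg = cfg.with_(master_seed=cfg.master_seed if sim_config is not None else seed)
    duration = math.ceil(months * MONTH_DAYS / cfg.dt) * cfg.dt
    if cfg.duration < duration:
        cfg = cfg.with_(duration=float(duration))
    traj = simulate(cfg)
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1,))) if noise else None
    patient = _patient_from_trajectory(traj, "planted-01", months, scale, rng)
    return patient, traj
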