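"""Comparison of simulated reversible damage with monthly CEL series.

Monthly contrast-enhancing-lesion (CEL) counts from relapsing-remitting MS
patients are compared with simulated reversible-damage trajectories: the
simulation is discretized to one point per month, both series are
first-differenced into "evolution" series (zero = stable disease, positive
= exacerbation, negative = improvement), and each 48-month patient series
is slid along each 120-month simulated series keeping the best Pearson
correlation.  Repeating over a bank of stochastic simulations yields one
best-correlation distribution per patient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SimulationConfig, Trajectory, autoimmune_config, simulate

__all__ = [
    "MONTH_DAYS",
    "PatientSeries",
    "CorrelationDistribution",
    "read_cel_table",
    "write_cel_table",
    "monthly_series",
    "evolution_series",
    "best_sliding_correlation",
    "simulate_evolution_bank",
    "correlation_distribution",
]

logger = logging.getLogger(__name__)

# Calendar month used to discretize simulated time, days.  365/12 keeps
# 120 months equal to 3650 days; a 30-day month is also supported.
MONTH_DAYS = 365.0 / 12.0


@dataclass
class PatientSeries:
    """Monthly observations for one subject, real or synthetic.

    Attributes
    ----------
    patient_id : str
        Subject label.
    cel : ndarray of int
        Monthly CEL counts, non-negative, length >= 2.
    edss : ndarray or None
        Optional monthly disability scores (pass-through only).
    relapse_flags : ndarray of bool or None
        Optional monthly clinical-relapse indicators.
    source : {"real", "synthetic"}
    """

    patient_id: str
    cel: np.ndarray
    edss: np.ndarray | None = None
    relapse_flags: np.ndarray | None = None
    source: str = "real"

    def __post_init__(self) -> None:
        self.cel = np.asarray(self.cel)
        if len(self.cel) < 2:
            raise ValueError("cel series must have length >= 2")
        if np.any(self.cel < 0):
            raise ValueError("cel counts must be non-negative")
        if not np.issubdtype(self.cel.dtype, np.integer):
            if not np.allclose(self.cel, np.round(self.cel)):
                raise ValueError("cel counts must be integers")
            self.cel = self.cel.astype(np.int64)

    @property
    def n_months(self) -> int:
        return len(self.cel)


def read_cel_table(path) -> list[PatientSeries]:
    """Read a delimited patient table into validated series.

    The table must have a header with at least ``patient_id``, ``month``
    and ``cel`` columns (``edss`` and ``relapse`` optional); the delimiter
    is sniffed (tab or comma).  Months must be consecutive within each
    patient and counts non-negative integers; violations raise a
    ``ValueError`` naming the offending patient/row.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"patient_id", "month", "cel"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: list[PatientSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("month")
        months = grp["month"].to_numpy()
        if not np.array_equal(months - months[0], np.arange(len(months))):
            raise ValueError(f"patient {pid!r}: months are not consecutive")
        cel = grp["cel"].to_numpy()
        bad = np.flatnonzero((cel < 0) | (cel != np.round(cel)))
        if len(bad):
            row = grp.index[bad[0]]
            raise ValueError(
                f"patient {pid!r}, row {row}: CEL count {cel[bad[0]]!r} "
                "is not a non-negative integer")
        edss = grp["edss"].to_numpy(dtype=float) if "edss" in grp else None
        flags = (grp["relapse"].to_numpy().astype(bool)
                 if "relapse" in grp else None)
        out.append(PatientSeries(patient_id=str(pid), cel=cel.astype(np.int64),
                                 edss=edss, relapse_flags=flags))
    return out


def write_cel_table(patients: list[PatientSeries], path) -> None:
    """Write patient series in the same format :func:`read_cel_table` reads."""
    rows = []
    for ps in patients:
        for m in range(ps.n_months):
            row = {"patient_id": ps.patient_id, "month": m,
                   "cel": int(ps.cel[m])}
            if ps.edss is not None:
                row["edss"] = float(ps.edss[m])
            if ps.relapse_flags is not None:
                row["relapse"] = int(ps.relapse_flags[m])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def monthly_series(
    traj: Trajectory,
    variable: str = "l",
    months: int | None = None,
    month_length: float = MONTH_DAYS,
    mode: str = "sample",
) -> np.ndarray:
    """Discretize a trajectory variable to one value per month.

    The default takes the instantaneous value at each month boundary
    (month m sampled at ``m * month_length`` days, m = 1..n); with
    ``mode="mean"`` the within-month average is used instead.

    Raises
    ------
    ValueError
        If the trajectory is shorter than the requested number of months.
    """
    n_avail = math.floor(traj.times[-1] / month_length + 1e-9)
    n = n_avail if months is None else months
    if n > n_avail:
        raise ValueError(
            f"trajectory covers only {n_avail} months of {month_length:.3f} d; "
            f"{n} requested")
    series = getattr(traj, variable)
    if mode == "sample":
        idx = np.array([int(np.argmin(np.abs(traj.times - m * month_length)))
                        for m in range(1, n + 1)])
        return series[idx].astype(float)
    if mode == "mean":
        out = np.empty(n)
        for m in range(1, n + 1):
            sel = ((traj.times >= (m - 1) * month_length)
                   & (traj.times < m * month_length))
            out[m - 1] = series[sel].mean()
        return out
    raise ValueError(f"unknown mode {mode!r}")


def evolution_series(s: np.ndarray) -> np.ndarray:
    """First-difference a monthly series: out[t] = s[t] - s[t-1].

    The result has one fewer point than the input; zero means no change in
    disease activity, positive values exacerbation, negative improvement.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1 or len(s) < 2:
        raise ValueError("series must be one-dimensional with length >= 2")
    return np.diff(s)


def best_sliding_correlation(
    disease: np.ndarray,
    insilico: np.ndarray,
) -> tuple[float, int]:
    """Best Pearson correlation over all alignments of a short series in a long one.

    The ``disease`` evolution series (length m) is slid along the
    ``insilico`` evolution series (length n >= m); the Pearson r is
    evaluated at each of the n - m + 1 offsets and the maximum returned
    with its offset (ties broken by the smallest offset).  Simulated
    windows with zero variance are skipped; a zero-variance disease series
    is an error since its correlation is undefined.
    """
    disease = np.asarray(disease, dtype=float)
    insilico = np.asarray(insilico, dtype=float)
    m, n = len(disease), len(insilico)
    if m < 3:
        raise ValueError("disease series must have length >= 3")
    if n < m:
        raise ValueError("in-silico series must be at least as long as the disease series")
    d = disease - disease.mean()
    sd = math.sqrt(float(d @ d))
    if sd == 0.0:
        raise ValueError("disease series has zero variance; correlation undefined")

    windows = np.lib.stride_tricks.sliding_window_view(insilico, m)
    wmean = windows.mean(axis=1, keepdims=True)
    wc = windows - wmean
    wnorm = np.sqrt((wc * wc).sum(axis=1))
    valid = wnorm > 0
    if not valid.any():
        raise ValueError("every simulated window has zero variance")
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug("skipped %d zero-variance simulated windows", n_skipped)
    r = np.full(len(windows), -np.inf)
    r[valid] = (wc[valid] @ d) / (wnorm[valid] * sd)
    offset = int(np.argmax(r))
    return float(r[offset]), offset


@dataclass
class CorrelationDistribution:
    """Per-patient distribution of best correlations over a simulation bank."""

    patient_id: str
    best_r: np.ndarray
    offsets: np.ndarray
    n_simulations: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.best_r = np.asarray(self.best_r, dtype=float)
        if np.any(np.abs(self.best_r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    def summary(self) -> dict:
        """Median, modal histogram bin center (width 0.1) and maximum."""
        counts, edges = np.histogram(self.best_r, bins=20, range=(-1.0, 1.0))
        k = int(np.argmax(counts))
        return {
            "patient_id": self.patient_id,
            "median": float(np.median(self.best_r)),
            "mode_bin_center": float((edges[k] + edges[k + 1]) / 2),
            "max": float(self.best_r.max()),
            "n_simulations": self.n_simulations,
            "n_excluded": self.n_excluded,
        }


def simulate_evolution_bank(
    n_simulations: int,
    months: int = 120,
    config: SimulationConfig | None = None,
    master_seed: int = 0,
    month_length: float = MONTH_DAYS,
) -> list[np.ndarray]:
    """Bank of in-silico evolution series from independent stochastic runs.

    Each entry is the first-differenced monthly reversible-damage series of
    one autoimmune-regime simulation long enough to cover ``months``
    months.  The bank can be shared across patients.
    """
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    base = config if config is not None else autoimmune_config()
    duration = math.ceil(months * month_length / base.dt) * base.dt
    base = base.with_(duration=float(duration))
    bank = []
    for k in range(n_simulations):
        seed = int(np.random.SeedSequence(master_seed, spawn_key=(k,))
                   .generate_state(1)[0] % (2 ** 31))
        traj = simulate(base.with_(master_seed=seed))
        bank.append(evolution_series(
            monthly_series(traj, "l", months=months, month_length=month_length)))
    return bank


def correlation_distribution(
    patient: PatientSeries,
    n_simulations: int = 2000,
    months: int = 120,
    config: SimulationConfig | None = None,
    master_seed: int = 0,
    bank: list[np.ndarray] | None = None,
) -> CorrelationDistribution:
    """Distribution of best sliding correlations for one patient.

    For each simulation in the bank (built on demand when not supplied):
    simulate the autoimmune regime, discretize reversible damage monthly,
    first-difference, and record the best Pearson correlation of the
    patient's evolution series slid along the simulated one.  Failing
    simulations are excluded and counted.
    """
    if bank is None:
        bank = simulate_evolution_bank(n_simulations, months=months,
                                       config=config, master_seed=master_seed)
    disease = evolution_series(patient.cel)
    best, offs = [], []
    n_excluded = 0
    for k, insilico in enumerate(bank):
        try:
            r, off = best_sliding_correlation(disease, insilico)
        except ValueError:
            logger.warning("simulation %d excluded for patient %s",
                           k, patient.patient_id)
            n_excluded += 1
            continue
        best.append(r)
        offs.append(off)
    return CorrelationDistribution(
        patient_id=patient.patient_id,
        best_r=np.array(best),
        offsets=np.array(offs, dtype=int),
        n_simulations=len(bank),
        n_excluded=n_excluded,
    )
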