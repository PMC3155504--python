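"""Quick-look plots: trajectories, phase portraits, correlation histograms."""

from __future__ import annotations

import numpy as np

from .clinical import CorrelationDistribution
from .reduced import ReducedState
from .simulate import Trajectory

__all__ = [
    "plot_trajectory",
    "plot_phase_portrait",
    "plot_correlation_histogram",
]


def plot_trajectory(traj: Trajectory, ax=None, log: bool = True):
    """Activated Teff/Treg counts and damage compartments over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    ax.plot(traj.times, traj.E + 1, color="crimson", lw=0.8, label="activated Teff")
    ax.plot(traj.times, traj.R + 1, color="royalblue", lw=0.8, label="activated Treg")
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("cells + 1")
    ax2 = ax.twinx()
    ax2.plot(traj.times, traj.l, color="orange", lw=0.8, alpha=0.7,
             label="reversible damage")
    ax2.plot(traj.times, traj.L, color="gray", lw=0.8, alpha=0.7,
             label="irreversible damage")
    ax2.set_ylabel("damage (a.u.)")
    ax.legend(loc="upper left", fontsize=8)
    ax2.legend(loc="upper right", fontsize=8)
    return ax


def plot_phase_portrait(paths: list[list[ReducedState]], labels=None, ax=None):
    """(R, E) phase-plane spirals for one or more reduced-model paths."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for i, path in enumerate(paths):
        R = np.array([s.R for s in path])
        E = np.array([s.E for s in path])
        label = labels[i] if labels else None
        ax.plot(R, E, lw=0.9, label=label)
        ax.plot(R[0], E[0], "o", ms=4, color=ax.lines[-1].get_color())
    ax.set_xlabel("activated Treg (cells)")
    ax.set_ylabel("activated Teff (cells)")
    if labels:
        ax.legend(fontsize=8)
    return ax


def plot_correlation_histogram(dists: list[CorrelationDistribution], ax=None):
    """Per-patient histograms of best sliding correlations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(-1, 1, 41)
    for dist in dists:
        ax.hist(dist.best_r, bins=bins, histtype="step",
                label=dist.patient_id)
    ax.set_xlabel("best Pearson r")
    ax.set_ylabel("simulations")
    ax.legend(fontsize=7)
    return ax
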