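"""Core types and right-hand sides of the Teff–Treg cross-regulation model.

The model tracks four antigen-specific T-cell pools — resting and activated
effector T cells (``E_r``, ``E``) and resting and activated regulatory T
cells (``R_r``, ``R``) — coupled through a prey–predator negative feedback:
activated Treg suppress Teff proliferation and raise Teff clearance, while
activated Teff stimulate Treg expansion.  Both interactions are sigmoidal
(Hill) in the counterpart population size.  A one-way-coupled pair of damage
compartments (reversible ``l``, irreversible ``L``) translates bursts of
activated Teff into tissue injury.

All rates are per day and populations are continuous cell counts; the model
is population-level, not agent-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "EQUATION_FORM",
    "ModelParameters",
    "DamageParameters",
    "TCellState",
    "DamageState",
    "InstantaneousInflow",
    "hill_up",
    "hill_down",
    "tcell_derivatives",
    "damage_derivatives",
]

# Which transcription of the governing equations is active.  The structural
# fallback form is the documented one: Treg raise Teff clearance above the
# gamma_E baseline, Treg clearance is constant, and d2/r follow the
# "irreversible damage rate" / "recovery" parameter roles.
EQUATION_FORM = "structural-fallback"


@dataclass(frozen=True)
class ModelParameters:
    """Rate and Hill constants of the T-cell population system.

    Defaults are the model's reference parameterization.

    Attributes
    ----------
    delta : float
        Activation (antigen presentation) rate, 1/day.
    beta : float
        Resting-cell anergy/death rate, 1/day.
    eta : float
        Return-to-resting ("memory") rate, 1/day.
    alpha_E : float
        Maximum Teff proliferation rate, 1/day.
    alpha_R : float
        Maximum Treg proliferation/activation rate, 1/day.
    gamma_E : float
        Teff death/anergy/migration rate, 1/day.
    gamma_R : float
        Treg death/anergy/migration rate, 1/day.
    k_E : float
        Teff population size for half-maximal effect on Treg, cells.
    k_R : float
        Treg population size for half-maximal effect on Teff, cells.
    hill_h : float
        Hill coefficient (response steepness), dimensionless, >= 1.
    """

    delta: float = 1.0
    beta: float = 0.01
    eta: float = 0.01
    alpha_E: float = 2.0
    alpha_R: float = 1.0
    gamma_E: float = 0.2
    gamma_R: float = 0.2
    k_E: float = 1000.0
    k_R: float = 200.0
    hill_h: float = 5.0

    def __post_init__(self) -> None:
        for name in ("delta", "beta", "eta", "alpha_E", "alpha_R",
                     "gamma_E", "gamma_R", "k_E", "k_R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.hill_h < 1:
            raise ValueError("hill_h must be >= 1")

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DamageParameters:
    """Constants of the tissue-damage compartments.

    Attributes
    ----------
    d1 : float
        Reversible damage production rate, 1/day.
    d2 : float
        Irreversible damage (conversion) rate, 1/day.
    a : float
        Threshold population size scaling the Teff damage drive, cells.
    r : float
        Recovery rate of reversible damage, 1/day.
    """

    d1: float = 1.0
    d2: float = 0.02
    a: float = 22800.0
    r: float = 0.1

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "a", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TCellState:
    """The four T-cell pools, in cells; all components must be >= 0."""

    E_r: float = 0.0
    R_r: float = 0.0
    E: float = 1000.0
    R: float = 200.0

    def __post_init__(self) -> None:
        if min(self.E_r, self.R_r, self.E, self.R) < 0:
            raise ValueError("T-cell state components must be non-negative")


@dataclass(frozen=True)
class DamageState:
    """Reversible (l) and irreversible (L) damage, arbitrary damage units."""

    l: float = 0.0
    L: float = 0.0

    def __post_init__(self) -> None:
        if self.l < 0 or self.L < 0:
            raise ValueError("damage components must be non-negative")


@dataclass(frozen=True)
class InstantaneousInflow:
    """Resting-pool influx rates at the current instant, cells/day."""

    i_E: float = 0.0
    i_R: float = 0.0

    def __post_init__(self) -> None:
        if self.i_E < 0 or self.i_R < 0:
            raise ValueError("inflow rates must be non-negative")


def hill_up(x: float, k: float, h: float) -> float:
    """Increasing Hill function ``x^h / (k^h + x^h)``.

    Parameters
    ----------
    x : float
        Population size, >= 0.
    k : float
        Half-maximal population size, > 0.
    h : float
        Hill coefficient, >= 1.

    Returns
    -------
    float
        A fraction in [0, 1), strictly increasing in ``x``, equal to
        0.5 at ``x == k``.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    if k <= 0:
        raise ValueError("k must be strictly positive")
    if h < 1:
        raise ValueError("h must be >= 1")
    ratio = x / k
    if ratio > 1e250 ** (1.0 / h):  # (x/k)^h would overflow; saturated
        return 1.0
    t = ratio ** h
    return t / (1.0 + t)


def hill_down(x: float, k: float, h: float) -> float:
    """Decreasing Hill function ``k^h / (k^h + x^h) = 1 - hill_up``."""
    return 1.0 - hill_up(x, k, h)


def tcell_derivatives(
    state: TCellState,
    p: ModelParameters,
    inflow: InstantaneousInflow = InstantaneousInflow(),
) -> tuple[float, float, float, float]:
    """Time derivatives of (E_r, R_r, E, R), cells/day.

    Resting pools gain external inflow and memory returns (eta * activated)
    and lose cells to activation (delta) and anergy/death (beta).  Activated
    Teff gain delta*E_r plus proliferation alpha_E*E suppressed by Treg
    through a decreasing Hill term in R, and are cleared at gamma_E raised
    by Treg through an increasing Hill term in R.  Activated Treg gain
    delta*R_r plus proliferation alpha_R*R stimulated by Teff through an
    increasing Hill term in E, and are cleared at the constant rate gamma_R.
    Both activated pools return to rest at eta.
    """
    E_r, R_r, E, R = state.E_r, state.R_r, state.E, state.R
    up_R = hill_up(R, p.k_R, p.hill_h)
    up_E = hill_up(E, p.k_E, p.hill_h)
    dE_r = inflow.i_E - (p.delta + p.beta) * E_r + p.eta * E
    dR_r = inflow.i_R - (p.delta + p.beta) * R_r + p.eta * R
    dE = (p.delta * E_r + p.alpha_E * E * (1.0 - up_R)
          - p.gamma_E * E * (1.0 + up_R) - p.eta * E)
    dR = (p.delta * R_r + p.alpha_R * R * up_E
          - p.gamma_R * R - p.eta * R)
    return dE_r, dR_r, dE, dR


def damage_derivatives(
    E: float,
    d: DamageState,
    dp: DamageParameters = DamageParameters(),
) -> tuple[float, float]:
    """Time derivatives of (l, L), damage units/day.

    Reversible damage is produced at ``d1 * (E/a)^2`` — a second-order
    effect of activated Teff on the target tissue — and drains through
    recovery (r) and through irreversible conversion (d2).  Irreversible
    damage accrues as ``d2 * l`` and never decreases.  The damage
    compartments have no feedback on the T-cell dynamics.
    """
    if E < 0:
        raise ValueError("E must be non-negative")
    e_prime = (E / dp.a) ** 2
    dl = dp.d1 * e_prime - (dp.r + dp.d2) * d.l
    dL = dp.d2 * d.l
    return dl, dL
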