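"""Closed-form equilibrium unfolding models.

Two-state (N <-> U) and three-state (N <-> I <-> U) chemical denaturation
under the linear extrapolation method (LEM), plus a van't Hoff two-state
thermal melt. All free energies are in kcal/mol, denaturant concentrations
in mol/L, temperatures in kelvin.

The LEM assumes the unfolding free energy varies linearly with denaturant
concentration:

    dG(c) = dG0 - m * c

so each transition is summarized by its zero-denaturant free energy ``dG0``
and cooperativity ``m``; the midpoint is ``Dm = dG0 / m``. Observed probe
signals are population-weighted averages of per-state baselines that are
themselves linear in the perturbant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_KCAL",
    "Conditions",
    "TwoStateParams",
    "ThreeStateParams",
    "ThermalParams",
    "PopulationProfile",
    "gibbs_at",
    "midpoint",
    "two_state_fractions",
    "two_state_signal",
    "three_state_fractions",
    "three_state_signal",
    "thermal_fraction_unfolded",
    "thermal_signal",
    "population_profile",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987e-3

#: Exponent clip bound; beyond this the Boltzmann factor saturates.
_EXP_CLIP = 700.0


def celsius_to_kelvin(t_c: float) -> float:
    return float(t_c) + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return float(t_k) - 273.15


@dataclass(frozen=True)
class Conditions:
    """Thermodynamic conditions for chemical-denaturation calculations.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin (default 298.15, the 25 degC at
        which denaturation samples are equilibrated).
    gas_constant : float
        Gas constant in kcal/(mol K).
    """

    temperature: float = 298.15
    gas_constant: float = R_KCAL

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive kelvin, got {self.temperature}")

    @classmethod
    def from_celsius(cls, t_c: float) -> "Conditions":
        return cls(temperature=celsius_to_kelvin(t_c))

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the two-state LEM model N <-> U.

    ``a1 + b1*c`` is the native baseline S_N and ``c1 + p1*c`` the unfolded
    baseline S_U, both linear in denaturant concentration c.
    """

    dG0: float  # unfolding free energy in water, kcal/mol
    m: float  # denaturant dependence, kcal/(mol M)
    a1: float = 1.0
    b1: float = 0.0
    c1: float = 0.0
    p1: float = 0.0

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise ValueError(f"m must be > 0 for an unfolding transition, got {self.m}")

    @property
    def Dm(self) -> float:
        """Midpoint denaturant concentration dG0/m (M)."""
        return midpoint(self.dG0, self.m)

    def native_baseline(self, c):
        return self.a1 + self.b1 * np.asarray(c, dtype=float)

    def unfolded_baseline(self, c):
        return self.c1 + self.p1 * np.asarray(c, dtype=float)


@dataclass(frozen=True)
class ThreeStateParams:
    """Parameters of the three-state LEM model N <-> I <-> U.

    Two transitions are parameterized relative to the native state:
    (dG_NI0, m_NI) and (dG_NU0, m_NU); the I <-> U leg follows by
    additivity, dG_IU0 = dG_NU0 - dG_NI0 and m_IU = m_NU - m_NI.
    Baselines: native a1 + b1*c, intermediate c1 + p1*c, unfolded e1 + g1*c.
    """

    dG_NI0: float
    m_NI: float
    dG_NU0: float
    m_NU: float
    a1: float = 1.0
    b1: float = 0.0
    c1: float = 0.5
    p1: float = 0.0
    e1: float = 0.0
    g1: float = 0.0

    def __post_init__(self) -> None:
        if not self.m_NI > 0:
            raise ValueError(f"m_NI must be > 0, got {self.m_NI}")
        if not self.m_NU > 0:
            raise ValueError(f"m_NU must be > 0, got {self.m_NU}")
        if self.dG_NU0 < self.dG_NI0:
            raise ValueError(
                "dG_NU0 must be >= dG_NI0 (N -> I -> U presumes ordered stability); "
                f"got dG_NI0={self.dG_NI0}, dG_NU0={self.dG_NU0}"
            )

    @property
    def dG_IU0(self) -> float:
        return self.dG_NU0 - self.dG_NI0

    @property
    def m_IU(self) -> float:
        return self.m_NU - self.m_NI

    @property
    def Dm_NI(self) -> float:
        return midpoint(self.dG_NI0, self.m_NI)

    @property
    def Dm_NU(self) -> float:
        return midpoint(self.dG_NU0, self.m_NU)

    def native_baseline(self, c):
        return self.a1 + self.b1 * np.asarray(c, dtype=float)

    def intermediate_baseline(self, c):
        return self.c1 + self.p1 * np.asarray(c, dtype=float)

    def unfolded_baseline(self, c):
        return self.e1 + self.g1 * np.asarray(c, dtype=float)


@dataclass(frozen=True)
class ThermalParams:
    """Parameters of the van't Hoff two-state thermal melt.

    dG(T) = dH_vH * (1 - T/Tm), i.e. heat-capacity change neglected
    (unidentifiable from a single melt). Baselines are linear in T:
    native a1 + b1*T, unfolded c1 + p1*T, with T in kelvin.
    """

    Tm: float  # midpoint temperature, kelvin
    dH_vH: float  # van't Hoff enthalpy at Tm, kcal/mol
    a1: float = 1.0
    b1: float = 0.0
    c1: float = 0.0
    p1: float = 0.0

    def __post_init__(self) -> None:
        if not self.Tm > 0:
            raise ValueError(f"Tm must be positive kelvin, got {self.Tm}")
        if not self.dH_vH > 0:
            raise ValueError(f"dH_vH must be > 0, got {self.dH_vH}")

    @property
    def Tm_celsius(self) -> float:
        return kelvin_to_celsius(self.Tm)

    @classmethod
    def from_celsius(cls, tm_c: float, dH_vH: float, **baselines) -> "ThermalParams":
        return cls(Tm=celsius_to_kelvin(tm_c), dH_vH=dH_vH, **baselines)


@dataclass(frozen=True)
class PopulationProfile:
    """Species fractions along a perturbant grid (f_I zero for two-state)."""

    grid: np.ndarray
    f_N: np.ndarray
    f_U: np.ndarray
    f_I: np.ndarray = field(default=None)  # type: ignore[assignment]
    argmax_I: float | None = None

    def __post_init__(self) -> None:
        if self.f_I is None:
            object.__setattr__(self, "f_I", np.zeros_like(np.asarray(self.grid, dtype=float)))

    @property
    def max_f_I(self) -> float:
        return float(np.max(self.f_I))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"c": self.grid, "f_N": self.f_N, "f_I": self.f_I, "f_U": self.f_U}
        )


def gibbs_at(dG0: float, m: float, c) -> float | np.ndarray:
    """LEM free energy at denaturant concentration c: dG0 - m*c (kcal/mol)."""
    c = np.asarray(c, dtype=float)
    out = dG0 - m * c
    return float(out) if out.ndim == 0 else out


def midpoint(dG0: float, m: float):
    """Transition midpoint Dm = dG0/m, the concentration with 50% unfolded."""
    if m == 0:
        raise ZeroDivisionError("midpoint undefined for m = 0")
    return dG0 / m


def _boltzmann(neg_dg_over_rt):
    """exp with the argument clipped so extreme stabilities saturate."""
    return np.exp(np.clip(neg_dg_over_rt, -_EXP_CLIP, _EXP_CLIP))


def two_state_fractions(p: TwoStateParams, c, cond: Conditions = Conditions()):
    """Native and unfolded fractions at denaturant concentration c.

    K = exp(-dG(c)/RT); f_U = K/(1+K). Saturates to (1,0)/(0,1) for
    extreme arguments instead of overflowing.
    """
    k = _boltzmann(-gibbs_at(p.dG0, p.m, c) / cond.rt)
    f_u = k / (1.0 + k)
    return 1.0 - f_u, f_u


def two_state_signal(p: TwoStateParams, c, cond: Conditions = Conditions()):
    """Observed probe signal S_N(c)*f_N + S_U(c)*f_U."""
    f_n, f_u = two_state_fractions(p, c, cond)
    return p.native_baseline(c) * f_n + p.unfolded_baseline(c) * f_u


def three_state_fractions(p: ThreeStateParams, c, cond: Conditions = Conditions()):
    """(f_N, f_I, f_U) at concentration c.

    f_N = 1/(1 + K_NI + K_NU), f_I = K_NI/(...), f_U = K_NU/(...), with
    both equilibrium constants referenced to N through their LEM lines.
    Computed shift-stably (softmax over [0, -dG_NI/RT, -dG_NU/RT]) so the
    fractions always sum to one, even deep in either baseline.
    """
    c = np.asarray(c, dtype=float)
    x = np.stack(
        [
            np.zeros_like(c),
            -gibbs_at(p.dG_NI0, p.m_NI, c) / cond.rt,
            -gibbs_at(p.dG_NU0, p.m_NU, c) / cond.rt,
        ]
    )
    x = np.clip(x, -_EXP_CLIP, _EXP_CLIP)
    x = x - x.max(axis=0, keepdims=True)
    w = np.exp(x)
    w /= w.sum(axis=0, keepdims=True)
    if c.ndim == 0:
        return float(w[0]), float(w[1]), float(w[2])
    return w[0], w[1], w[2]


def three_state_signal(p: ThreeStateParams, c, cond: Conditions = Conditions()):
    """Observed probe signal S_N*f_N + S_I*f_I + S_U*f_U with linear baselines."""
    f_n, f_i, f_u = three_state_fractions(p, c, cond)
    return (
        p.native_baseline(c) * f_n
        + p.intermediate_baseline(c) * f_i
        + p.unfolded_baseline(c) * f_u
    )


def thermal_fraction_unfolded(p: ThermalParams, t_kelvin, gas_constant: float = R_KCAL):
    """Unfolded fraction of a van't Hoff melt: K = exp(-dH(1-T/Tm)/RT)."""
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive kelvin")
    dg = p.dH_vH * (1.0 - t / p.Tm)
    k = _boltzmann(-dg / (gas_constant * t))
    f_u = k / (1.0 + k)
    return float(f_u) if f_u.ndim == 0 else f_u


def thermal_signal(p: ThermalParams, t_kelvin, gas_constant: float = R_KCAL):
    """Observed melt signal with baselines linear in temperature."""
    t = np.asarray(t_kelvin, dtype=float)
    f_u = thermal_fraction_unfolded(p, t, gas_constant)
    s_n = p.a1 + p.b1 * t
    s_u = p.c1 + p.p1 * t
    return s_n * (1.0 - f_u) + s_u * f_u


def population_profile(
    p: TwoStateParams | ThreeStateParams,
    grid,
    cond: Conditions = Conditions(),
) -> PopulationProfile:
    """Species fractions over a perturbant grid.

    For three-state parameters ``argmax_I`` is the grid point maximizing
    the intermediate fraction; two-state input yields f_I identically zero
    and no argmax.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("grid values must be non-negative")
    if isinstance(p, ThreeStateParams):
        f_n, f_i, f_u = three_state_fractions(p, grid, cond)
        argmax = float(grid[int(np.argmax(f_i))])
        return PopulationProfile(grid=grid, f_N=f_n, f_I=f_i, f_U=f_u, argmax_I=argmax)
    f_n, f_u = two_state_fractions(p, grid, cond)
    return PopulationProfile(grid=grid, f_N=f_n, f_U=f_u)
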