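"""Parameters, nondimensionalization and kinetic rate laws for VOC biofiltration.

A biofilter bed is packed with material coated by a thin microbial biofilm
(thickness ``delta``).  Contaminated air flows through the bed in plug flow;
methanol (hydrophilic) and alpha-pinene (hydrophobic) partition into the
biofilm at the air interface and are degraded by distinct microbial
populations following Michaelis-Menten kinetics.  Methanol inhibits pinene
degradation through the multiplicative factor ``alpha``.

The canonical internal representation is dimensionless: the biofilm
reaction-diffusion problem is governed by a Thiele-type modulus ``phi``
(reaction capacity vs. diffusion) and a saturation parameter ``beta``
(interface concentration over the half-saturation constant) per compound,
and the gas-phase column by transfer groups ``A``/``A1``.  Dimensional
inputs are converted once at the boundary by the ``nondimensionalize_*``
functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum

import numpy as np

__all__ = [
    "KineticRegime",
    "DimensionalParameters",
    "DimensionlessBiofilmParams",
    "DimensionlessGasParams",
    "inhibition_factor",
    "nondimensionalize_biofilm",
    "nondimensionalize_gas",
    "reaction_rate",
]


class KineticRegime(str, Enum):
    """Kinetic regime of the biofilm reaction term.

    ``michaelis_menten`` is the full saturable law ``phi*s/(1+beta*s)``;
    ``first_order`` its dilute (unsaturated, ``beta*s << 1``) limit
    ``phi*s``; ``zero_order`` its saturated (``beta*s >> 1``) limit with
    constant volumetric demand ``phi/beta``.
    """

    MICHAELIS_MENTEN = "michaelis_menten"
    FIRST_ORDER = "first_order"
    ZERO_ORDER = "zero_order"

    @classmethod
    def parse(cls, name: "str | KineticRegime") -> "KineticRegime":
        """Accept canonical names and the short CLI aliases mm/first/zero."""
        if isinstance(name, cls):
            return name
        aliases = {
            "mm": cls.MICHAELIS_MENTEN,
            "michaelis_menten": cls.MICHAELIS_MENTEN,
            "michaelis-menten": cls.MICHAELIS_MENTEN,
            "first": cls.FIRST_ORDER,
            "first_order": cls.FIRST_ORDER,
            "first-order": cls.FIRST_ORDER,
            "zero": cls.ZERO_ORDER,
            "zero_order": cls.ZERO_ORDER,
            "zero-order": cls.ZERO_ORDER,
        }
        key = str(name).lower()
        if key not in aliases:
            raise ValueError(f"unknown kinetic regime: {name!r}")
        return aliases[key]


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional physical parameters of the biofilter.

    Units are any consistent set (the model only ever uses the dimensionless
    groups).  All fields must be strictly positive.

    Attributes
    ----------
    D_em, D_ep : effective diffusivities of methanol / pinene in the biofilm
        (area/time).
    X : biomass (dry cell) density in the film (mass/volume).
    Y_m, Y_p : yield coefficients (dimensionless).
    mu_max_m, mu_max_p : maximum specific growth rates (1/time).
    K_m, K_p : half-saturation constants (mass/volume).
    K_i : methanol inhibition constant (mass/volume).
    delta : biofilm thickness (length).
    m_m, m_p : gas-biofilm partition coefficients (dimensionless); the
        interface film concentration is ``C_gas / m``.
    U_g : superficial gas velocity (length/time).
    A_s : specific interfacial area of the packing (1/length).
    H : bed height (length).
    C_mi, C_pi : inlet gas concentrations (mass/volume).
    """

    D_em: float
    D_ep: float
    X: float
    Y_m: float
    Y_p: float
    mu_max_m: float
    mu_max_p: float
    K_m: float
    K_p: float
    K_i: float
    delta: float
    m_m: float
    m_p: float
    U_g: float
    A_s: float
    H: float
    C_mi: float
    C_pi: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"{f.name} must be a finite number, got {v!r}")
            # delta = 0 (no film) is the only admissible zero: it yields
            # phi = 0, the no-reaction limit used in tests.
            if f.name == "delta":
                if v < 0:
                    raise ValueError(f"delta must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v}")

    @property
    def s_im(self) -> float:
        """Interface film concentration of methanol, C_mi / m_m."""
        return self.C_mi / self.m_m

    @property
    def s_ip(self) -> float:
        """Interface film concentration of pinene, C_pi / m_p."""
        return self.C_pi / self.m_p


@dataclass(frozen=True)
class DimensionlessBiofilmParams:
    """Dimensionless groups of the biofilm reaction-diffusion problem.

    ``phi = (X mu_max_m / Y_m) delta^2 / (D_em K_m)`` and
    ``beta = S_im / K_m`` for methanol; ``phi1``/``beta1`` analogously for
    pinene.  ``alpha`` multiplies the pinene modulus (methanol inhibition).
    ``alpha`` may be supplied directly as a constant -- in that case no
    upper bound is enforced (only ``alpha > 0``) -- or computed from a
    methanol concentration via :func:`inhibition_factor`, which always lies
    in (0, 1].  The two entry points are intentionally separate.
    """

    phi: float = 0.0
    beta: float = 0.0
    phi1: float = 0.0
    beta1: float = 0.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in ("phi", "beta", "phi1", "beta1"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not (math.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be finite and > 0, got {self.alpha}")


@dataclass(frozen=True)
class DimensionlessGasParams:
    """Dimensionless groups of the gas-phase (column) mass balance.

    ``A = H A_s D_em S_im / (U_g delta C_mi)`` scales the methanol flux
    absorbed from the gas into the film per unit dimensionless height;
    ``A1`` analogously for pinene.  ``gamma = C_mi / K_i`` is the
    inlet-methanol-to-inhibition ratio, used only when the inhibition
    factor is recomputed dynamically along the column (``gamma = 0`` keeps
    alpha constant).
    """

    A: float = 0.0
    A1: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A", "A1", "gamma"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


def inhibition_factor(c_m, k_i: float):
    """Methanol inhibition factor ``1 / (1 + (c_m / k_i)^2)``.

    Strictly decreasing in ``c_m``, equal to 1 at ``c_m = 0`` and 1/2 at
    ``c_m = k_i``; always in (0, 1].  Vectorized over ``c_m``.
    """
    if not (math.isfinite(k_i) and k_i > 0):
        raise ValueError(f"k_i must be finite and > 0, got {k_i}")
    c = np.asarray(c_m, dtype=float)
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("c_m must be finite and >= 0")
    out = 1.0 / (1.0 + (c / k_i) ** 2)
    return float(out) if np.isscalar(c_m) else out


def nondimensionalize_biofilm(
    p: DimensionalParameters, alpha: float = 1.0
) -> DimensionlessBiofilmParams:
    """Form the biofilm groups (phi, beta, phi1, beta1) from dimensional data.

    ``alpha`` is left to the caller: pass a constant, or compute one with
    :func:`inhibition_factor` (e.g. ``inhibition_factor(p.C_mi, p.K_i)``
    for inlet conditions).
    """
    phi = (p.X * p.mu_max_m / p.Y_m) * p.delta**2 / (p.D_em * p.K_m)
    beta = p.s_im / p.K_m
    phi1 = (p.X * p.mu_max_p / p.Y_p) * p.delta**2 / (p.D_ep * p.K_p)
    beta1 = p.s_ip / p.K_p
    return DimensionlessBiofilmParams(
        phi=phi, beta=beta, phi1=phi1, beta1=beta1, alpha=alpha
    )


def nondimensionalize_gas(p: DimensionalParameters) -> DimensionlessGasParams:
    """Form the column groups (A, A1) and the inhibition ratio gamma."""
    if p.delta == 0:
        raise ValueError("delta must be > 0 to form the gas-phase groups")
    A = p.H * p.A_s * p.D_em * p.s_im / (p.U_g * p.delta * p.C_mi)
    A1 = p.H * p.A_s * p.D_ep * p.s_ip / (p.U_g * p.delta * p.C_pi)
    gamma = p.C_mi / p.K_i
    return DimensionlessGasParams(A=A, A1=A1, gamma=gamma)


def reaction_rate(s, phi: float, beta: float, regime=KineticRegime.MICHAELIS_MENTEN):
    """Pointwise dimensionless reaction rate for a given kinetic regime.

    michaelis_menten: ``phi*s/(1+beta*s)``; first_order: ``phi*s``;
    zero_order: the constant demand ``phi/beta`` (requires ``beta > 0``).
    Vectorized over ``s``; the zero-order demand is stored internally as the
    single ratio ``phi/beta`` so ``phi = beta = 0`` never produces 0/0.
    """
    regime = KineticRegime.parse(regime)
    if not (math.isfinite(phi) and phi >= 0):
        raise ValueError(f"phi must be finite and >= 0, got {phi}")
    if not (math.isfinite(beta) and beta >= 0):
        raise ValueError(f"beta must be finite and >= 0, got {beta}")
    sv = np.asarray(s, dtype=float)
    if np.any(sv < 0):
        raise ValueError("s must be >= 0")
    if regime is KineticRegime.MICHAELIS_MENTEN:
        out = phi * sv / (1.0 + beta * sv)
    elif regime is KineticRegime.FIRST_ORDER:
        out = phi * sv
    else:
        if beta == 0:
            raise ValueError("zero_order regime requires beta > 0")
        out = np.full_like(sv, phi / beta)
    return float(out) if np.isscalar(s) else out
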