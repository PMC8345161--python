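"""PD-1/PD-L1/antibody immune-synapse equilibrium.

When an effector T cell contacts a target cell, PD-1 on the T-cell side of
the synapse binds PD-L1 on the target side; a bivalent anti-PD-1 antibody
competes for PD-1, binding first with one arm and then, with cross-arm
efficiency ``chi``, with the second.  At equilibrium the bound fraction
``x = bonds / T2`` of synaptic PD-L1 satisfies a cubic equation with exactly
one root in (0, 1).  The bond count feeds a Hill modifier ``H`` in [0, 1)
that scales killing and exhaustion probabilities throughout the platform.

Unknowns (per synapse): free PD-1 ``P``, free PD-L1 ``L``, PD-1:PD-L1 bonds
``b``, singly antibody-bound PD-1 ``N1``, doubly bound ``N2``.  Equilibrium
and conservation read::

    b  = k1 * P * L
    N1 = k2 * Nivo * P
    N2 = k3 * N1 * P
    T1 = b + P + N1 + 2*N2          (total synaptic PD-1)
    T2 = b + L                      (total synaptic PD-L1)

Eliminating everything but ``x = b/T2`` gives the cubic solved here.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .registry import ParameterRegistry

__all__ = [
    "SynapseParams",
    "SynapseResult",
    "hill",
    "hill_bond_modifier",
    "synapse_totals",
    "cubic_coefficients",
    "solve_synapse_fraction",
    "derived_binding_constants",
    "solve_synapse",
]


@dataclass(frozen=True)
class SynapseParams:
    """Geometry, expression totals and binding constants of one synapse."""

    Teff_PD1_tot: float  # molecules per T cell
    C1_PDL1_tot: float  # maximal molecules per target cell
    A_syn: float  # um^2
    A_T: float  # um^2
    A_C: float  # um^2
    d_syn: float  # um
    kd_PD1_PDL1: float  # M (2D-scaled)
    kd_nivo: float  # M
    chi_cross_arm: float  # dimensionless
    f_vol_tum: float
    K_hill: float  # bonds at half-maximal inhibition
    n_hill: float
    ifng_ec50: float  # ng/mL
    ifng_hill_n: float
    pdl1_base_frac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Teff_PD1_tot", "C1_PDL1_tot", "A_syn", "A_T", "A_C", "K_hill"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")

    @classmethod
    def from_registry(cls, reg: ParameterRegistry) -> "SynapseParams":
        return cls(
            Teff_PD1_tot=reg["Teff_PD1_tot"],
            C1_PDL1_tot=reg["C1_PDL1_tot"],
            A_syn=reg["A_syn"],
            A_T=reg["A_T"],
            A_C=reg["A_C"],
            d_syn=reg["d_syn"],
            kd_PD1_PDL1=reg["kd_PD1_PDL1"],
            kd_nivo=reg["kd_nivo"],
            chi_cross_arm=reg["chi_cross_arm"],
            f_vol_tum=reg["f_vol_tum"],
            K_hill=reg["K_hill_bonds"],
            n_hill=reg["n_hill_bonds"],
            ifng_ec50=reg["ifng_ec50"],
            ifng_hill_n=reg["ifng_hill_n"],
            pdl1_base_frac=reg["pdl1_base_frac"],
        )


@dataclass(frozen=True)
class SynapseResult:
    x: float  # bound fraction of synaptic PD-L1
    bonds: float  # x * T2
    H: float  # Hill modifier of the bond count


def hill(x: float, ec50: float, n: float) -> float:
    """Standard Hill function x^n / (ec50^n + x^n), zero at x=0."""
    if x < 0:
        raise ValueError("Hill input must be nonnegative")
    if x == 0.0:
        return 0.0
    r = (x / ec50) ** n
    return r / (1.0 + r)


def hill_bond_modifier(X: float, K: float, n: float) -> float:
    """Checkpoint modifier H of the PD-1:PD-L1 bond count X.

    H = (X/K)^n / (1 + (X/K)^n); half-maximal at X = K bonds.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    return hill(X, K, n)


def synapse_totals(params: SynapseParams, c_ifng: float) -> tuple[float, float]:
    """Total synaptic PD-1 (T1) and IFNg-induced synaptic PD-L1 (T2).

    T1 scales the cellwide PD-1 count by the synapse/T-cell area ratio;
    T2 does the same on the target side, modulated by a Hill response of
    PD-L1 expression to the local IFNg concentration (plus an optional
    basal fraction so that unstimulated cells are not entirely dark).
    """
    if c_ifng < 0:
        raise ValueError("c_ifng must be nonnegative")
    T1 = params.Teff_PD1_tot * params.A_syn / params.A_T
    induction = hill(c_ifng, params.ifng_ec50, params.ifng_hill_n)
    frac = params.pdl1_base_frac + (1.0 - params.pdl1_base_frac) * induction
    T2 = params.C1_PDL1_tot * params.A_syn / params.A_C * frac
    return T1, T2


def derived_binding_constants(params: SynapseParams) -> tuple[float, float, float]:
    """Default (k1, k2, k3) from dissociation constants and geometry.

    Membrane binding happens in the thin synaptic volume A_syn * d_syn, so
    the 3D dissociation constant converts to a per-molecule count scale
    through that volume and Avogadro's number (1 um^3 = 1e-15 L):

    k1 = 1/(kd_PD1_PDL1 * Na * A_syn * d_syn * 1e-15)  [1/molecule]
    k2 = 2 * f_vol_tum / kd_nivo                       [1/M, two free arms]
    k3 = chi / (kd_nivo * Na * A_syn * d_syn * 1e-15)  [1/molecule]

    The solver takes (k1, k2, k3) directly, so any other convention can be
    injected without touching this mapping.
    """
    NA = 6.02214076e23
    v_syn_l = params.A_syn * params.d_syn * 1e-15
    k1 = 1.0 / (params.kd_PD1_PDL1 * NA * v_syn_l)
    k2 = 2.0 * params.f_vol_tum / params.kd_nivo
    k3 = params.chi_cross_arm / (params.kd_nivo * NA * v_syn_l)
    return k1, k2, k3


def cubic_coefficients(
    T1: float, T2: float, k1: float, k2: float, k3: float, nivo: float
) -> tuple[float, float, float, float]:
    """Monic cubic in x = bonds/T2; coefficients (1, a2, a1, a0).

    a2 = -(2 + 1/(k1 T2) + T1/T2 + nivo k2/(k1 T2) * (1 - 2 k3/k1))
    a1 =   1 + 1/(k1 T2) + 2 T1/T2 + nivo k2/(k1 T2)
    a0 = -T1/T2
    """
    inv = 1.0 / (k1 * T2)
    ratio = T1 / T2
    drug = nivo * k2 * inv
    a2 = -(2.0 + inv + ratio + drug * (1.0 - 2.0 * k3 / k1))
    a1 = 1.0 + inv + 2.0 * ratio + drug
    a0 = -ratio
    return 1.0, a2, a1, a0


def _cubic(x: float, a2: float, a1: float, a0: float) -> float:
    return ((x + a2) * x + a1) * x + a0


def solve_synapse_fraction(
    T1: float,
    T2: float,
    k1: float,
    k2: float,
    k3: float,
    nivo: float,
    *,
    K_hill: float = 1.0,
    n_hill: float = 1.0,
    tol: float = 1e-12,
) -> SynapseResult:
    """Solve the equilibrium cubic for the bound fraction x in (0, 1).

    Uses safeguarded bracketed root finding on [0, 1] rather than a
    closed-form Cardano evaluation, for numerical robustness.  The physical
    root is unique in (0, 1); a failure to bracket raises with diagnostics.
    """
    if T2 <= 0:
        raise ValueError("T2 must be positive (no synaptic PD-L1)")
    if min(T1, k1, k2, k3, nivo) < 0:
        raise ValueError("T1 and binding constants must be nonnegative")
    if T1 == 0.0:
        return SynapseResult(x=0.0, bonds=0.0, H=hill_bond_modifier(0.0, K_hill, n_hill))
    if nivo * k2 == 0.0:
        # without antibody the cubic factors as (x - 1) * quadratic; the
        # physical root is the smaller quadratic root (the other exceeds 1)
        inv = 1.0 / (k1 * T2)
        ratio = T1 / T2
        b = 1.0 + inv + ratio
        disc = math.sqrt(max(b * b - 4.0 * ratio, 0.0))
        x = 2.0 * ratio / (b + disc)  # stable form of (b - disc)/2
        x = min(max(x, 0.0), 1.0)
        bonds = x * T2
        return SynapseResult(x=x, bonds=bonds, H=hill_bond_modifier(bonds, K_hill, n_hill))
    _, a2, a1, a0 = cubic_coefficients(T1, T2, k1, k2, k3, nivo)
    f0 = _cubic(0.0, a2, a1, a0)  # = -T1/T2 < 0
    hi = 1.0
    f1 = _cubic(hi, a2, a1, a0)
    if f1 <= 0.0:
        # the cubic can graze zero at x = 1; retreat until it brackets
        for delta in (1e-12, 1e-9, 1e-6, 1e-3):
            hi = 1.0 - delta
            f1 = _cubic(hi, a2, a1, a0)
            if f1 > 0.0:
                break
    if not f0 < 0.0 < f1:
        raise ArithmeticError(
            "no synapse root bracketed in (0,1): "
            f"f(0)={f0:.3e}, f({hi})={f1:.3e}, T1={T1}, T2={T2}, "
            f"k1={k1}, k2={k2}, k3={k3}, nivo={nivo}"
        )
    x = brentq(_cubic, 0.0, hi, args=(a2, a1, a0), xtol=tol, rtol=8.9e-16)
    bonds = x * T2
    return SynapseResult(x=x, bonds=bonds, H=hill_bond_modifier(bonds, K_hill, n_hill))


def solve_synapse(
    params: SynapseParams, c_ifng: float, nivo: float, tol: float = 1e-12
) -> SynapseResult:
    """Convenience wrapper: totals from IFNg, constants from params, solve.

    Returns H = 0 when the target expresses no PD-L1 (T2 == 0).
    """
    T1, T2 = synapse_totals(params, c_ifng)
    if T2 <= 0.0:
        return SynapseResult(x=0.0, bonds=0.0, H=0.0)
    k1, k2, k3 = derived_binding_constants(params)
    return solve_synapse_fraction(
        T1, T2, k1, k2, k3, nivo, K_hill=params.K_hill, n_hill=params.n_hill, tol=tol
    )


def equilibrium_ode_oracle(
    T1: float,
    T2: float,
    k1: float,
    k2: float,
    k3: float,
    nivo: float,
    t_end: float = 1e7,
) -> float:
    """Mass-action kinetic relaxation to equilibrium; independent check.

    Integrates the binding network with unit off-rates (on-rates k1, k2, k3
    scaled accordingly) until steady state and returns bonds/T2.  The long
    horizon covers slow cross-arm modes; a residual check guards against
    returning a non-equilibrium state.  Used only as a test oracle for
    :func:`solve_synapse_fraction`.
    """
    from scipy.integrate import solve_ivp

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        b, n1, n2 = y
        p = T1 - b - n1 - 2.0 * n2
        l = T2 - b
        db = k1 * p * l - b
        dn1 = k2 * nivo * p - n1 - (k3 * n1 * p - n2)
        dn2 = k3 * n1 * p - n2
        return np.array([db, dn1, dn2])

    sol = solve_ivp(
        rhs, (0.0, t_end), np.zeros(3), method="Radau", rtol=1e-11, atol=1e-13
    )
    if not sol.success:
        raise ArithmeticError(f"kinetic oracle failed: {sol.message}")
    y = sol.y[:, -1]
    resid = np.max(np.abs(rhs(0.0, y)) / (np.abs(y) + 1e-9))
    if resid > 1e-6:
        raise ArithmeticError(f"kinetic oracle not at steady state (residual {resid:.2e})")
    return float(y[0] / T2)
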