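"""Whole-patient compartmental ODE backbone (reduced QSP module).

Compartments: tumor, tumor-draining lymph node (LN), central (blood) and
peripheral.  The network implements the documented minimal reaction set:

* logistic cancer growth toward a carrying capacity,
* Teff killing of cancer cells gated by the PD-1:PD-L1 checkpoint modifier
  ``(1 - H)`` with a crowding ratio Teff/(C1 + T_all),
* two Teff exhaustion routes (PD-L1 contact with H at Hill exponent 1, and
  Treg-amplified suppression with a (1 + H) factor),
* adhesion-site-limited transmigration of central T cells into the tumor,
* an antigen -> pMHC-loaded-APC -> LN priming/expansion chain feeding
  central Teff/Treg (forms are saturating Michaelis expressions; the chain
  closes the positive feedback between cancer-cell death and T-cell
  supply),
* two-compartment linear-clearance antibody PK with a tumor partition
  read by the checkpoint solver.

The module is self-contained: it can run stand-alone or serve as the ODE
side of the hybrid coupling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .registry import ParameterRegistry, default_registry
from .synapse import SynapseParams, hill_bond_modifier, solve_synapse

__all__ = [
    "SPECIES",
    "QSPParams",
    "QSPState",
    "QSPModel",
    "build_qsp_model",
    "integrate_qsp",
    "apply_infusion",
    "apply_resection",
    "tumor_diameter",
]

#: State-vector layout.  Cells unless noted; Nivo concentrations molar.
SPECIES = (
    "Tum.C1",
    "Tum.Teff",
    "Tum.Treg",
    "Tum.Texh",
    "Cent.Teff",
    "Cent.Treg",
    "LN.APC",
    "LN.Teff",
    "LN.Treg",
    "Antigen",
    "Nivo.cent",
    "Nivo.periph",
    "Nivo.tum",
)
_IDX = {name: i for i, name in enumerate(SPECIES)}
TUMOR_CELL_SPECIES = ("Tum.C1", "Tum.Teff", "Tum.Treg", "Tum.Texh")


@dataclass(frozen=True)
class QSPParams:
    """Rate and volume constants of the reduced network."""

    k_C_growth: float
    K_C_max: float
    k_C_death_by_T: float
    k_C_death: float
    k_Teff_death_by_C: float
    k_Teff_inhibBy_Treg: float
    k_Teff_transmig: float
    S_adhesion_tot: float
    vol_cent: float
    vol_periph: float
    vol_tum_max: float
    f_vol_BV: float
    f_vol_tum: float
    t_lifespan_teff: float
    t_lifespan_treg: float
    t_lifespan_cent: float
    antigen_per_death: float
    k_antigen_clear: float
    k_apc_load: float
    k_apc_decay: float
    K_apc_half: float
    n_naive_cd8: float
    k_prime_max: float
    f_treg_out: float
    k_ln_expand: float
    ln_capacity: float
    k_ln_out: float
    n_clones: float
    antigen_strength: float
    k_cl_nivo: float
    k_nivo_cent_periph: float
    k_nivo_periph_cent: float
    k_nivo_cent_tum: float
    gamma_nivo_tum: float
    nivo_mol_weight: float
    n_hill_bonds: float
    c_ifng_qsp: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite QSP parameter {name}={value}")
        rates = (
            "k_C_growth k_C_death_by_T k_C_death k_Teff_death_by_C "
            "k_Teff_inhibBy_Treg k_Teff_transmig k_antigen_clear k_apc_load "
            "k_apc_decay k_prime_max k_ln_expand k_ln_out k_cl_nivo "
            "k_nivo_cent_periph k_nivo_periph_cent k_nivo_cent_tum"
        ).split()
        for name in rates:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be nonnegative")
        if not 0.0 < self.f_vol_BV < 1.0 or not 0.0 < self.f_vol_tum < 1.0:
            raise ValueError("volume fractions must lie in (0, 1)")
        if self.K_C_max <= 0:
            raise ValueError("K_C_max must be positive")

    @classmethod
    def from_registry(cls, reg: ParameterRegistry) -> "QSPParams":
        return cls(**{f: reg[f] for f in cls.__dataclass_fields__})



@dataclass
class QSPState:
    """Compartmental species vector with simulation time (days)."""

    y: np.ndarray
    time: float = 0.0

    @classmethod
    def zeros(cls, time: float = 0.0) -> "QSPState":
        return cls(y=np.zeros(len(SPECIES)), time=time)

    @classmethod
    def initial(
        cls,
        c1: float,
        cent_teff: float = 0.0,
        cent_treg: float = 0.0,
        time: float = 0.0,
    ) -> "QSPState":
        st = cls.zeros(time=time)
        st["Tum.C1"] = c1
        st["Cent.Teff"] = cent_teff
        st["Cent.Treg"] = cent_treg
        return st

    def __getitem__(self, name: str) -> float:
        return float(self.y[_IDX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.y[_IDX[name]] = value

    def copy(self) -> "QSPState":
        return QSPState(y=self.y.copy(), time=self.time)

    def as_dict(self) -> dict[str, float]:
        return {name: float(self.y[i]) for name, i in _IDX.items()}


class SteppingError(RuntimeError):
    def __init__(self, message: str, time: float, state: np.ndarray) -> None:
        super().__init__(message)
        self.time = time
        self.state = state


class QSPModel:
    """Right-hand-side evaluator plus checkpoint closure."""

    def __init__(self, params: QSPParams, synapse: SynapseParams, w_qsp: float = 1.0) -> None:
        self.params = params
        self.synapse = synapse
        # fraction of the tumor this ODE module represents; its quadratic
        # adhesion x vasculature recruitment flux is rescaled so that it
        # stands for exactly w_qsp of the whole-tumor recruitment
        self.w_qsp = w_qsp
        self._h_cache: dict[float, tuple[float, float]] = {}

    # -- checkpoint ----------------------------------------------------
    def checkpoint_modifiers(self, nivo_tum: float) -> tuple[float, float]:
        """(H_n, H_1): bond-count Hill modifier at exponent n and 1.

        Bonds are solved once from the synapse equilibrium at the tumor
        antibody concentration and the representative IFNg level; results
        are memoized at 4 significant digits of the concentration.
        """
        nivo = max(nivo_tum, 0.0)
        key = float(f"{nivo:.3e}")
        hit = self._h_cache.get(key)
        if hit is not None:
            return hit
        res = solve_synapse(self.synapse, self.params.c_ifng_qsp, key)
        H_n = hill_bond_modifier(res.bonds, self.synapse.K_hill, self.params.n_hill_bonds)
        H_1 = hill_bond_modifier(res.bonds, self.synapse.K_hill, 1.0)
        if len(self._h_cache) < 100_000:
            self._h_cache[key] = (H_n, H_1)
        return H_n, H_1

    # -- fluxes --------------------------------------------------------
    def transmigration_flux(self, c1: float, cent_t: float) -> float:
        """Cells/day entering the tumor from the central compartment.

        Proportional to the product of adhesion sites (scaling with tumor
        burden) and T cells on tumor vasculature.
        """
        p = self.params
        frac = max(c1, 0.0) / p.K_C_max
        sites = p.S_adhesion_tot * p.vol_tum_max * frac
        on_vasculature = cent_t * p.vol_tum_max * p.f_vol_BV * frac / p.vol_cent
        return p.k_Teff_transmig * sites * on_vasculature / self.w_qsp

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        c1, teff, treg, texh = (max(v, 0.0) for v in y[0:4])
        cent_teff, cent_treg = max(y[4], 0.0), max(y[5], 0.0)
        apc, ln_teff, ln_treg, antigen = (max(v, 0.0) for v in y[6:10])
        n_c, n_p, n_t = y[10], y[11], y[12]

        t_all = teff + treg + texh
        total = c1 + t_all
        H_n, H_1 = self.checkpoint_modifiers(n_t)

        # K_C_max is a whole-tumor capacity; this module holds w_qsp of it
        growth = p.k_C_growth * c1 * (1.0 - c1 / (self.w_qsp * p.K_C_max))
        if total > 0.0:
            kill = p.k_C_death_by_T * (teff / total) * (1.0 - H_n) * c1
            exhaust_pdl1 = p.k_Teff_death_by_C * (c1 / total) * H_1 * teff
            exhaust_treg = p.k_Teff_inhibBy_Treg * (treg / total) * (1.0 + H_n) * teff
        else:
            kill = exhaust_pdl1 = exhaust_treg = 0.0
        innate = p.k_C_death * c1
        death_flux = kill + innate

        transmig_teff = self.transmigration_flux(c1, cent_teff)
        transmig_treg = self.transmigration_flux(c1, cent_treg)

        # LN chain
        load = p.k_apc_load * antigen
        sat = apc / (apc + p.K_apc_half) if apc > 0 else 0.0
        clone_gain = p.n_clones / 100.0  # normalized to the default burden
        prime = p.k_prime_max * p.n_naive_cd8 * clone_gain * sat
        # clonal expansion saturates as the LN pool approaches capacity
        cap_teff = max(1.0 - ln_teff / p.ln_capacity, 0.0)
        cap_treg = max(1.0 - ln_treg / p.ln_capacity, 0.0)
        expand_teff = p.k_ln_expand * ln_teff * sat * cap_teff
        expand_treg = p.k_ln_expand * ln_treg * sat * cap_treg

        dy = np.empty_like(y)
        dy[_IDX["Tum.C1"]] = growth - death_flux
        dy[_IDX["Tum.Teff"]] = (
            transmig_teff - exhaust_pdl1 - exhaust_treg - teff / p.t_lifespan_teff
        )
        dy[_IDX["Tum.Treg"]] = transmig_treg - treg / p.t_lifespan_treg
        dy[_IDX["Tum.Texh"]] = exhaust_pdl1 + exhaust_treg - texh / p.t_lifespan_teff
        dy[_IDX["Cent.Teff"]] = (
            p.k_ln_out * ln_teff - transmig_teff - cent_teff / p.t_lifespan_cent
        )
        dy[_IDX["Cent.Treg"]] = (
            p.k_ln_out * ln_treg - transmig_treg - cent_treg / p.t_lifespan_cent
        )
        dy[_IDX["LN.APC"]] = load - p.k_apc_decay * apc
        dy[_IDX["LN.Teff"]] = prime + expand_teff - p.k_ln_out * ln_teff
        dy[_IDX["LN.Treg"]] = (
            p.f_treg_out * prime + expand_treg - p.k_ln_out * ln_treg
        )
        dy[_IDX["Antigen"]] = (
            p.antigen_per_death * p.antigen_strength * death_flux
            - p.k_antigen_clear * antigen
        )
        # two-compartment PK + tumor partition (sampling compartment)
        dy[_IDX["Nivo.cent"]] = (
            -p.k_cl_nivo / p.vol_cent * n_c
            - p.k_nivo_cent_periph * n_c
            + p.k_nivo_periph_cent * n_p * p.vol_periph / p.vol_cent
        )
        dy[_IDX["Nivo.periph"]] = (
            p.k_nivo_cent_periph * n_c * p.vol_cent / p.vol_periph
            - p.k_nivo_periph_cent * n_p
        )
        dy[_IDX["Nivo.tum"]] = p.k_nivo_cent_tum * (p.gamma_nivo_tum * n_c - n_t)
        return dy


def build_qsp_model(
    params: QSPParams | None = None,
    synapse: SynapseParams | None = None,
    registry: ParameterRegistry | None = None,
) -> QSPModel:
    """Assemble the ODE evaluator from explicit params or a registry."""
    reg = registry if registry is not None else default_registry()
    if params is None:
        params = QSPParams.from_registry(reg)
    if synapse is None:
        synapse = SynapseParams.from_registry(reg)
    return QSPModel(params, synapse)


def integrate_qsp(
    model: QSPModel,
    state: QSPState,
    dt: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> QSPState:
    """Advance the state by dt with a stiff-capable adaptive solver.

    Species are clipped to zero within -atol after the step; a deeper
    negative excursion indicates an integration failure and raises.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sol = solve_ivp(
        model.rhs,
        (state.time, state.time + dt),
        state.y,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SteppingError(
            f"QSP integration failed at t={state.time}: {sol.message}",
            time=state.time,
            state=state.y.copy(),
        )
    y = sol.y[:, -1]
    floor = -1e3 * atol
    if (y < floor).any():
        worst = SPECIES[int(np.argmin(y))]
        raise SteppingError(
            f"species {worst} went negative ({y.min():.3e}) at t={state.time + dt}",
            time=state.time + dt,
            state=y,
        )
    np.maximum(y, 0.0, out=y)
    return QSPState(y=y, time=state.time + dt)


def apply_infusion(
    state: QSPState, dose_mg_per_kg: float, body_mass_kg: float, mol_weight: float, vol_cent: float
) -> QSPState:
    """Bolus antibody infusion into the central compartment.

    Increment = dose * body_mass / (mol_weight * vol_cent) in molar, with
    the dose in mg/kg converted to grams.
    """
    if dose_mg_per_kg < 0:
        raise ValueError("dose must be nonnegative")
    if vol_cent <= 0 or mol_weight <= 0:
        raise ValueError("vol_cent and mol_weight must be positive")
    new = state.copy()
    grams = dose_mg_per_kg * 1e-3 * body_mass_kg
    new["Nivo.cent"] = new["Nivo.cent"] + grams / (mol_weight * vol_cent)
    return new


def apply_resection(state: QSPState, fraction_removed: float) -> QSPState:
    """Surgical removal: scale tumor-compartment cell species by 1-f."""
    if not 0.0 <= fraction_removed <= 1.0:
        raise ValueError("fraction_removed must be in [0, 1]")
    new = state.copy()
    keep = 1.0 - fraction_removed
    for name in TUMOR_CELL_SPECIES:
        new[name] = new[name] * keep
    return new


def tumor_diameter(
    counts_by_type: dict[str, float],
    volumes_by_type: dict[str, float],
    f_vol_tum: float,
) -> float:
    """Equivalent-sphere tumor diameter from cell counts and volumes.

    d = (6 * sum_i n_i V_i / (pi * (1 - f_vol_tum)))^(1/3), where
    f_vol_tum is the interstitial (void) fraction.  Units follow V_i
    (um^3 in, um out).
    """
    if not 0.0 <= f_vol_tum < 1.0:
        raise ValueError("f_vol_tum must be in [0, 1)")
    total = 0.0
    for name, n in counts_by_type.items():
        if n < 0:
            raise ValueError(f"negative count for {name}")
        total += n * volumes_by_type[name]
    return (6.0 * total / (np.pi * (1.0 - f_vol_tum))) ** (1.0 / 3.0)


def sphere_volume(diameter: float) -> float:
    return np.pi * diameter**3 / 6.0
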