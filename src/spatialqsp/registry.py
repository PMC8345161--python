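"""Versioned parameter registry.

Every tunable quantity in the platform lives in a flat ``key -> (value,
unit, description)`` table.  Configuration files override values by key;
unknown keys are rejected so that typos fail loudly instead of silently
running the defaults.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Mapping

REGISTRY_VERSION = "1"


@dataclass(frozen=True)
class Entry:
    value: float
    unit: str
    description: str


#: Default parameterization.  Rates are per day, volumes in liters,
#: lengths in micrometers, concentrations molar unless noted.
_DEFAULTS: dict[str, Entry] = {
    # --- tumor growth / whole-patient ODE backbone ---
    "k_C_growth": Entry(0.012, "1/day", "net cancer-cell growth rate r"),
    "K_C_max": Entry(2.4e10, "cells", "tumor carrying capacity"),
    "k_C_death_by_T": Entry(1.0, "1/day", "maximal Teff killing rate of cancer cells"),
    "k_C_death": Entry(0.0, "1/day", "innate background cancer death rate"),
    "k_Teff_death_by_C": Entry(0.2, "1/day", "PD-L1 driven Teff exhaustion rate"),
    "k_Teff_inhibBy_Treg": Entry(0.1, "1/day", "Treg-mediated Teff exhaustion rate"),
    "k_Teff_transmig": Entry(1.0e-7, "1/day/site", "per-adhesion-site transmigration rate"),
    "S_adhesion_tot": Entry(1.0e11, "sites/L", "adhesion site density at max tumor volume"),
    "vol_cent": Entry(5.0, "L", "central (blood) compartment volume"),
    "vol_periph": Entry(60.0, "L", "peripheral compartment volume"),
    "vol_tum_max": Entry(0.2, "L", "maximal tumor volume"),
    "f_vol_BV": Entry(0.02, "-", "blood-vessel volume fraction of tumor"),
    "f_vol_tum": Entry(0.5, "-", "interstitial (void) volume fraction of tumor"),
    "t_lifespan_teff": Entry(3.0, "day", "effector CD8 lifespan in tissue"),
    "t_lifespan_treg": Entry(3.0, "day", "Treg lifespan in tissue"),
    "t_lifespan_cent": Entry(30.0, "day", "central-compartment T-cell lifespan"),
    # --- lymph-node priming chain (reduced; forms documented in docs) ---
    "antigen_per_death": Entry(1.0e-8, "1/cell", "antigen pool gain per cancer-cell death"),
    "k_antigen_clear": Entry(1.0, "1/day", "antigen pool clearance rate"),
    "k_apc_load": Entry(10.0, "1/day", "antigen -> pMHC-loaded APC gain"),
    "k_apc_decay": Entry(0.5, "1/day", "pMHC-loaded APC decay rate"),
    "K_apc_half": Entry(0.2, "APC", "half-saturation of priming vs loaded APC"),
    "n_naive_cd8": Entry(1.0e9, "cells", "naive CD8 pool feeding priming"),
    "n_naive_cd4": Entry(5.0e8, "cells", "naive CD4 pool feeding Treg output"),
    "k_prime_max": Entry(1.0e-4, "1/day", "maximal naive->effector priming rate"),
    "f_treg_out": Entry(0.5, "-", "Treg fraction of LN output relative to Teff"),
    "k_ln_expand": Entry(2.0, "1/day", "LN effector clonal-expansion rate"),
    "ln_capacity": Entry(5.0e8, "cells", "LN primed-pool carrying capacity"),
    "k_ln_out": Entry(0.5, "1/day", "LN -> central egress rate"),
    "n_clones": Entry(100.0, "clones", "tumor mutational burden (antigen clone count)"),
    "antigen_strength": Entry(1.0, "-", "dimensionless antigen strength multiplier"),
    # --- nivolumab PK (two-compartment, linear clearance) ---
    "nivo_mol_weight": Entry(1.436e5, "g/mol", "nivolumab molecular weight"),
    "k_cl_nivo": Entry(0.2, "L/day", "nivolumab linear clearance"),
    "k_nivo_cent_periph": Entry(0.3, "1/day", "central->peripheral transfer rate"),
    "k_nivo_periph_cent": Entry(0.025, "1/day", "peripheral->central transfer rate"),
    "k_nivo_cent_tum": Entry(2.0, "1/day", "central<->tumor equilibration rate"),
    "gamma_nivo_tum": Entry(1.0, "-", "tumor:plasma nivolumab partition coefficient"),
    # --- immune synapse / checkpoint ---
    "Teff_PD1_tot": Entry(9.3e3, "molecules/cell", "total PD-1 per T cell"),
    "C1_PDL1_tot": Entry(8.0e4, "molecules/cell", "maximal PD-L1 per cancer cell"),
    "A_syn": Entry(37.8, "um^2", "immune synapse contact area"),
    "A_T": Entry(314.0, "um^2", "T-cell surface area"),
    "A_C": Entry(1257.0, "um^2", "cancer-cell surface area"),
    "d_syn": Entry(3.0e-3, "um", "synaptic cleft width"),
    "kd_PD1_PDL1": Entry(8.2e-6, "M", "PD-1:PD-L1 dissociation constant (2D-scaled)"),
    "kd_nivo": Entry(2.6e-9, "M", "nivolumab:PD-1 dissociation constant"),
    "chi_cross_arm": Entry(10.0, "-", "cross-arm second-site binding efficiency"),
    "K_hill_bonds": Entry(300.0, "bonds", "PD-1:PD-L1 bond count at half-maximal inhibition"),
    "n_hill_bonds": Entry(2.0, "-", "Hill exponent of the bond-count modifier"),
    "ifng_ec50": Entry(1.0, "ng/mL", "IFNg EC50 for PD-L1 induction"),
    "ifng_hill_n": Entry(2.0, "-", "IFNg Hill exponent for PD-L1 induction"),
    "pdl1_base_frac": Entry(0.05, "-", "basal PD-L1 fraction without IFNg"),
    "c_ifng_qsp": Entry(1.0, "ng/mL", "representative tumor IFNg seen by the ODE module"),
    # --- cancer lineage ---
    "k_asym_div": Entry(0.5, "-", "asymmetric CSC division probability k"),
    "r_p": Entry(0.3, "1/day", "progenitor division rate"),
    "mu_senescent": Entry(0.05, "1/day", "senescent-cell death rate"),
    "d_max": Entry(5.0, "divisions", "max progenitor divisions before senescence"),
    "move_prob_csc": Entry(0.05, "1/step", "CSC movement probability per step"),
    "move_prob_prog": Entry(0.0, "1/step", "progenitor movement probability per step"),
    # --- T-cell agents ---
    "n_r": Entry(10.0, "-", "entry-point recruitment normalization"),
    "il2_threshold": Entry(0.5, "ng*day/mL", "cumulative IL-2 exposure to license division"),
    "il2_max_divisions": Entry(4.0, "divisions", "max IL-2 driven CD8 divisions"),
    "move_prob_t": Entry(0.5, "1/step", "T-cell movement probability per step"),
    "s_IL2_0": Entry(2.0e-6, "ng/day/cell", "IL-2 release per cytotoxic CD8"),
    "s_IFNg_0": Entry(4.0e-6, "ng/day/cell", "IFNg release per cytotoxic CD8"),
    "u_IFNg_0": Entry(0.1, "1/day/cell", "IFNg uptake rate per cell"),
    # --- cytokine fields ---
    "D_IL2": Entry(8.64e4, "um^2/day", "IL-2 diffusivity"),
    "D_IFNg": Entry(8.64e4, "um^2/day", "IFNg diffusivity"),
    "gamma_IL2": Entry(24.0, "1/day", "IL-2 degradation rate"),
    "gamma_IFNg": Entry(12.0, "1/day", "IFNg degradation rate"),
    "n_pde_substeps": Entry(10.0, "-", "molecular substeps per ABM step"),
    # --- lattice ---
    "voxel_size": Entry(20.0, "um", "voxel edge length"),
    "cell_diam_cancer": Entry(20.0, "um", "cancer-cell diameter"),
    "cell_diam_t": Entry(10.0, "um", "lymphocyte diameter"),
    "max_t_per_voxel": Entry(8.0, "cells", "T-cell cap in a cancer-free voxel"),
    "init_fill_prob": Entry(0.7, "-", "initial cancer occupancy probability"),
    "entry_density": Entry(1000.0, "points/mm^3", "T-cell entry point density"),
    # --- coupling / protocol ---
    "w_qsp": Entry(0.9, "-", "fraction of tumor handled by the ODE module"),
    "dt_abm": Entry(0.25, "day", "ABM / synchronization time step"),
    "body_mass": Entry(70.0, "kg", "virtual-patient body mass"),
    "detection_floor": Entry(1.0e5, "cells", "whole-tumor count below which CR is called"),
}


class UnknownParameterError(KeyError):
    pass


@dataclass
class ParameterRegistry:
    """Flat parameter table with defaults and typed overrides."""

    entries: dict[str, Entry] = field(default_factory=lambda: dict(_DEFAULTS))
    version: str = REGISTRY_VERSION

    def __getitem__(self, key: str) -> float:
        try:
            return self.entries[key].value
        except KeyError as exc:
            raise UnknownParameterError(key) from exc

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def unit(self, key: str) -> str:
        return self.entries[key].unit

    def describe(self, key: str) -> str:
        return self.entries[key].description

    def updated(self, overrides: Mapping[str, float]) -> "ParameterRegistry":
        """Return a copy with values replaced; unknown keys raise."""
        new = dict(self.entries)
        for key, value in overrides.items():
            if key not in new:
                raise UnknownParameterError(
                    f"unknown parameter {key!r}; registry version {self.version}"
                )
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"non-finite value for parameter {key!r}: {value}")
            new[key] = replace(new[key], value=value)
        return ParameterRegistry(entries=new, version=self.version)

    def as_dict(self) -> dict[str, float]:
        return {k: e.value for k, e in self.entries.items()}

    def to_table(self) -> list[dict[str, Any]]:
        return [
            {"key": k, "value": e.value, "unit": e.unit, "description": e.description}
            for k, e in sorted(self.entries.items())
        ]


def default_registry() -> ParameterRegistry:
    return ParameterRegistry()
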