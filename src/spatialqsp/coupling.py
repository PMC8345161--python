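"""Coupling of the compartmental ODE module with on-lattice tumor volumes.

A fraction ``w_qsp`` of the tumor-compartment cell species is tracked by
the ODE module; the remaining ``1 - w_qsp`` is represented by one or more
3D agent-based volumes (tumor core, invasive front).  Because a simulated
volume is far smaller than the tumor fraction it stands for, its raw
counts are scaled by

    s_i = k_i * (1 - w_qsp) / w_qsp * C_qsp / sum_j C_ij

where ``k_i`` is the fraction of the whole tumor made of region type i and
``C`` are cancer-cell counts.  Per synchronization interval the volumes
advance first against frozen ODE inputs (central T-cell concentrations,
tumor antibody), then the ODE integrates, then scaled ABM recruitment is
deducted from the central pools and scaled ABM cancer deaths feed the
antigen pool — closing the neoantigen -> priming feedback loop.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cancer_rules import step_cancer_cell
from .cytokines import Field, diffuse_react, update_sources
from .lattice import Grid, init_grid, place_entry_points, populate_tumor, shift_window
from .lineage import LineageRates, rates_from_registry, steady_fractions
from .qsp import QSPModel, QSPState, build_qsp_model, integrate_qsp
from .registry import ParameterRegistry, default_registry
from .synapse import SynapseParams
from .tcells import (
    SynapseCache,
    TcellParams,
    _VoxelIndex,
    expected_recruitment,
    kill_phase,
    recruit_at_entry_points,
    step_tcell,
)

__all__ = [
    "VolumeSpec",
    "CouplingConfig",
    "TumorVolume",
    "scale_factor",
    "sync_step",
    "whole_tumor_counts",
    "HybridModel",
]


@dataclass(frozen=True)
class VolumeSpec:
    region_type: str  # "core" | "front"
    k_i: float  # fraction of the whole tumor of this region type
    dims: tuple[int, int, int] = (20, 20, 20)
    entry_density: float | None = None  # points/mm^3; None -> registry value
    fill_probability: float | None = None


@dataclass
class CouplingConfig:
    w_qsp: float = 0.9
    dt: float = 0.25  # day
    volumes: list[VolumeSpec] = field(default_factory=lambda: [VolumeSpec("core", 1.0)])

    def __post_init__(self) -> None:
        if not 0.0 < self.w_qsp <= 1.0:
            raise ValueError("w_qsp must be in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def scale_factor(k_i: float, w_qsp: float, c_qsp: float, c_i_sum: float) -> float:
    """Per-volume scaling s_i mapping raw ABM counts to whole-tumor numbers."""
    if c_i_sum <= 0:
        raise ValueError("scaling undefined for an empty volume (sum of cancer cells is 0)")
    if not 0.0 < w_qsp < 1.0:
        raise ValueError("scaling requires 0 < w_qsp < 1")
    return k_i * (1.0 - w_qsp) / w_qsp * c_qsp / c_i_sum


class TumorVolume:
    """One agent-based region of interest with its cytokine layer."""

    def __init__(
        self,
        spec: VolumeSpec,
        registry: ParameterRegistry,
        rates: LineageRates,
        tparams: TcellParams,
        synapse: SynapseParams,
        seed: int | None = None,
    ) -> None:
        self.spec = spec
        self.reg = registry
        self.rates = rates
        self.tparams = tparams
        self.synapse = synapse
        self.grid: Grid = init_grid(
            spec.dims,
            voxel_size=registry["voxel_size"],
            region_type=spec.region_type,  # type: ignore[arg-type]
            seed=seed,
        )
        self.grid.max_t_per_voxel = int(registry["max_t_per_voxel"])
        fractions = steady_fractions(rates)
        fill = (
            spec.fill_probability
            if spec.fill_probability is not None
            else registry["init_fill_prob"]
        )
        populate_tumor(self.grid, fractions, fill, half_fill=spec.region_type == "front")
        density = spec.entry_density if spec.entry_density is not None else registry["entry_density"]
        place_entry_points(self.grid, density)
        self.fractions = fractions
        self.fill_probability = fill
        dims = self.grid.dims
        h = self.grid.voxel_size
        self.il2 = Field("IL2", dims, h, D=registry["D_IL2"], gamma=registry["gamma_IL2"])
        self.ifng = Field("IFNg", dims, h, D=registry["D_IFNg"], gamma=registry["gamma_IFNg"])
        self.n_substeps = max(int(registry["n_pde_substeps"]), 1)
        self.enable_tcells = True

    # ------------------------------------------------------------------
    def cancer_count(self) -> int:
        return sum(1 for a in self.grid.agents.values() if a.kind == "cancer")

    def species_counts(self) -> dict[str, int]:
        """Raw agent counts keyed like the ODE tumor species."""
        out = {"Tum.C1": 0, "Tum.Teff": 0, "Tum.Treg": 0, "Tum.Texh": 0}
        for a in self.grid.agents.values():
            if a.kind == "cancer":
                out["Tum.C1"] += 1
            elif a.kind == "Treg":
                out["Tum.Treg"] += 1
            elif a.state == "exhausted":
                out["Tum.Texh"] += 1
            else:
                out["Tum.Teff"] += 1
        return out

    def step(
        self,
        dt: float,
        cent_teff: float,
        tum_c1_qsp: float,
        cent_treg: float,
        nivo_tum: float,
    ) -> dict[str, int]:
        """Advance the volume by dt against frozen ODE inputs.

        Order per step: recruitment at entry points, random-permutation
        agent updates, the aggregated kill phase, cytokine substeps, and
        (for invasive-front volumes) window re-centering.  Returns the
        step ledger used by the synchronization bookkeeping.
        """
        grid = self.grid
        rng = grid.rng
        ledger = {"recruited_teff": 0, "recruited_treg": 0, "cancer_deaths": 0, "kills": 0}
        if self.enable_tcells and len(grid.entry_points):
            n = expected_recruitment(cent_teff, tum_c1_qsp, self.tparams.k_rec)
            n_treg = expected_recruitment(
                cent_treg, tum_c1_qsp, self.tparams.k_rec * self.tparams.treg_rec_ratio
            )
            recruits = recruit_at_entry_points(grid, n, n_treg, rng)
            ledger["recruited_teff"] = sum(1 for a in recruits if a.kind == "CD8")
            ledger["recruited_treg"] = sum(1 for a in recruits if a.kind == "Treg")

        index = _VoxelIndex(grid)
        syn_cache = SynapseCache(self.synapse, nivo_tum)
        agent_ids = np.array(list(grid.agents.keys()))
        rng.shuffle(agent_ids)
        died_before = grid.counts["died"]
        for aid in agent_ids:
            agent = grid.agents.get(int(aid))
            if agent is None:  # removed earlier this step
                continue
            if agent.kind == "cancer":
                step_cancer_cell(agent, grid, self.rates, dt, rng)
            else:
                step_tcell(
                    agent,
                    grid,
                    index,
                    self.il2,
                    self.ifng,
                    self.tparams,
                    syn_cache,
                    dt,
                    rng,
                )
        senescent_deaths = grid.counts["died"] - died_before
        if self.enable_tcells:
            kills = kill_phase(grid, index, self.tparams, syn_cache, self.ifng, dt, rng)
            ledger["kills"] = kills
        ledger["cancer_deaths"] = senescent_deaths + ledger["kills"]

        # molecular layer: sources follow cells; several implicit substeps
        update_sources(self.il2, grid.agents.values(), self.tparams.s_IL2_0)
        update_sources(
            self.ifng,
            grid.agents.values(),
            self.tparams.s_IFNg_0,
            uptake_per_cell=self.tparams.u_IFNg_0,
        )
        sub_dt = dt / self.n_substeps
        for _ in range(self.n_substeps):
            diffuse_react(self.il2, sub_dt)
            diffuse_react(self.ifng, sub_dt)

        if grid.region_type == "front" and self.cancer_count():
            shift_window(
                grid,
                self.fractions,
                fields=(self.il2.conc, self.ifng.conc),
                fill_probability=self.fill_probability,
            )
        return ledger


def whole_tumor_counts(
    qsp_state: QSPState,
    volumes: Sequence[TumorVolume],
    config: CouplingConfig,
) -> dict[str, float]:
    """Whole-tumor species totals: ODE part plus scaled ABM parts."""
    totals = {name: qsp_state[name] for name in ("Tum.C1", "Tum.Teff", "Tum.Treg", "Tum.Texh")}
    if config.w_qsp >= 1.0 or not volumes:
        return totals
    c_qsp = qsp_state["Tum.C1"]
    for vol in volumes:
        c_i = vol.cancer_count()
        if c_i == 0:
            continue
        s_i = scale_factor(vol.spec.k_i, config.w_qsp, c_qsp, c_i)
        for name, count in vol.species_counts().items():
            totals[name] += s_i * count
    return totals


def sync_step(
    qsp_state: QSPState,
    model: QSPModel,
    volumes: Sequence[TumorVolume],
    config: CouplingConfig,
) -> tuple[QSPState, dict[str, float]]:
    """One synchronization interval of the hybrid model.

    (1) every ABM volume advances dt with frozen ODE inputs from t;
    (2) the ODE module integrates dt; (3) scaled ABM recruitment is
    deducted from the central pools and scaled ABM cancer deaths are added
    to the antigen pool.  Returns the new ODE state and the flux audit.
    """
    dt = config.dt
    c_qsp = qsp_state["Tum.C1"]
    cent_teff = qsp_state["Cent.Teff"]
    cent_treg = qsp_state["Cent.Treg"]
    nivo_tum = qsp_state["Nivo.tum"]
    audit: dict[str, float] = {
        "teff_deducted": 0.0,
        "treg_deducted": 0.0,
        "antigen_added": 0.0,
        "scaled_deaths": 0.0,
    }

    scaled: list[tuple[TumorVolume, float, dict[str, int]]] = []
    for vol in volumes:
        c_i_before = vol.cancer_count()
        ledger = vol.step(dt, cent_teff, c_qsp, cent_treg, nivo_tum)
        if c_i_before > 0 and config.w_qsp < 1.0:
            s_i = scale_factor(vol.spec.k_i, config.w_qsp, c_qsp, c_i_before)
        else:
            s_i = 0.0
        scaled.append((vol, s_i, ledger))

    new_state = integrate_qsp(model, qsp_state, dt)

    p = model.params
    for _vol, s_i, ledger in scaled:
        audit["teff_deducted"] += s_i * ledger["recruited_teff"]
        audit["treg_deducted"] += s_i * ledger["recruited_treg"]
        audit["scaled_deaths"] += s_i * ledger["cancer_deaths"]
    antigen_gain = p.antigen_per_death * p.antigen_strength * audit["scaled_deaths"]
    audit["antigen_added"] = antigen_gain
    new_state["Cent.Teff"] = max(new_state["Cent.Teff"] - audit["teff_deducted"], 0.0)
    new_state["Cent.Treg"] = max(new_state["Cent.Treg"] - audit["treg_deducted"], 0.0)
    new_state["Antigen"] = new_state["Antigen"] + antigen_gain
    return new_state, audit


class HybridModel:
    """Convenience wrapper assembling ODE + volumes from a registry."""

    def __init__(
        self,
        registry: ParameterRegistry | None = None,
        config: CouplingConfig | None = None,
        seed: int | None = None,
        rates: LineageRates | None = None,
    ) -> None:
        self.reg = registry if registry is not None else default_registry()
        self.config = config if config is not None else CouplingConfig(
            w_qsp=self.reg["w_qsp"], dt=self.reg["dt_abm"]
        )
        self.model = build_qsp_model(registry=self.reg)
        self.model.w_qsp = self.config.w_qsp
        # lineage rates may be supplied directly (e.g. to decouple the ABM
        # net growth from an ODE gross-growth/innate-death split)
        self.rates = rates if rates is not None else rates_from_registry(self.reg)
        self.synapse = SynapseParams.from_registry(self.reg)
        self.tparams = TcellParams.from_registry(self.reg)
        ss = np.random.SeedSequence(seed)
        child_seeds = ss.spawn(max(len(self.config.volumes), 1))
        self.volumes: list[TumorVolume] = []
        if self.config.w_qsp < 1.0:
            for spec, child in zip(self.config.volumes, child_seeds):
                self.volumes.append(
                    TumorVolume(
                        spec,
                        self.reg,
                        self.rates,
                        self.tparams,
                        self.synapse,
                        seed=int(child.generate_state(1)[0] % (2**31)),
                    )
                )

    def initial_state(
        self, c1_total: float, cent_teff: float = 0.0, cent_treg: float = 0.0
    ) -> QSPState:
        """Initial ODE state with the w_qsp weight applied to tumor species.

        ``c1_total`` is the whole-tumor cancer-cell count; the ODE module
        tracks its w_qsp share and the ABM volumes stand for the rest.
        """
        return QSPState.initial(
            c1=self.config.w_qsp * c1_total, cent_teff=cent_teff, cent_treg=cent_treg
        )

    def run(
        self,
        state: QSPState,
        t_end: float,
        infusion_times: Sequence[float] = (),
        dose_mg_per_kg: float = 0.0,
        resection_time: float | None = None,
        resection_fraction: float = 0.9,
        record_every: float = 1.0,
    ) -> "pd.DataFrame":
        """Run the protocol and return a tidy per-day trajectory table."""
        import pandas as pd

        from .qsp import apply_infusion, apply_resection

        p = self.model.params
        rows = []
        pending_doses = sorted(infusion_times)
        next_record = 0.0
        eps = 1e-9
        while state.time < t_end - eps:
            while pending_doses and pending_doses[0] <= state.time + eps:
                pending_doses.pop(0)
                state = apply_infusion(
                    state, dose_mg_per_kg, self.reg["body_mass"], p.nivo_mol_weight, p.vol_cent
                )
            if resection_time is not None and abs(state.time - resection_time) < self.config.dt / 2:
                state = apply_resection(state, resection_fraction)
                resection_time = None
            if state.time + eps >= next_record:
                rows.append(self._record(state))
                next_record += record_every
            state, _audit = sync_step(state, self.model, self.volumes, self.config)
        rows.append(self._record(state))
        return pd.DataFrame(rows)

    def _record(self, state: QSPState) -> dict[str, float]:
        totals = whole_tumor_counts(state, self.volumes, self.config)
        row = {"time": state.time}
        row.update({f"whole.{k.split('.')[1]}": v for k, v in totals.items()})
        row.update(state.as_dict())
        return row
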