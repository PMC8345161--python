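"""CD8+ and regulatory T-cell agent rules.

All per-step probabilities derive from the compartmental rate constants
via the exponential waiting-time conversion, gated by the PD-1:PD-L1
checkpoint modifier H and by neighborhood composition ratios:

    P_kill          = 1 - B_esc^((1 - H) * q_teff),  B_esc  = e^(-dt*k_kill)
    P_exhaust_PDL1  = 1 - B_PDL1^H                   (q_PDL1 fixed to 1)
    P_exhaust_Treg  = 1 - B_Treg^((1 + H) * q_treg)

where q_teff (q_treg) is the fraction of cytotoxic CD8s (Tregs) among all
cells in the Moore neighborhood of the target (of the effector).
Recruitment happens at vascular entry points with per-point Bernoulli
probability n = Cent.Teff * Tum.C1 * k_rec, the lumped constant
k_rec = n_r * k_Teff_transmig * vol_tum_max * f_vol_BV / (K_C_max * vol_cent);
the normalization n_r keeps the maximal n below 1.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .cytokines import Field, sample_concentration
from .lattice import CellAgent, Grid, neighborhood
from .registry import ParameterRegistry
from .synapse import SynapseParams, solve_synapse

logger = logging.getLogger(__name__)

__all__ = [
    "TcellParams",
    "expected_recruitment",
    "recruit_at_entry_points",
    "prob_kill",
    "prob_exhaust_pdl1",
    "prob_exhaust_treg",
    "step_tcell",
    "kill_phase",
]


@dataclass(frozen=True)
class TcellParams:
    k_C_death_by_T: float  # 1/day
    k_Teff_death_by_C: float  # 1/day
    k_Teff_inhibBy_Treg: float  # 1/day
    k_rec: float  # lumped per-entry-point recruitment constant
    treg_rec_ratio: float  # Treg:Teff recruitment probability ratio
    il2_threshold: float  # ng*day/mL
    il2_max_divisions: int
    lifespan: float  # day
    move_prob: float  # per step
    s_IL2_0: float  # ng/day per cytotoxic cell
    s_IFNg_0: float  # ng/day per cytotoxic cell
    u_IFNg_0: float  # 1/day per cell

    @classmethod
    def from_registry(cls, reg: ParameterRegistry) -> "TcellParams":
        k_rec = (
            reg["n_r"]
            * reg["k_Teff_transmig"]
            * reg["vol_tum_max"]
            * reg["f_vol_BV"]
            / (reg["K_C_max"] * reg["vol_cent"])
        )
        return cls(
            k_C_death_by_T=reg["k_C_death_by_T"],
            k_Teff_death_by_C=reg["k_Teff_death_by_C"],
            k_Teff_inhibBy_Treg=reg["k_Teff_inhibBy_Treg"],
            k_rec=k_rec,
            treg_rec_ratio=1.0,
            il2_threshold=reg["il2_threshold"],
            il2_max_divisions=int(reg["il2_max_divisions"]),
            lifespan=reg["t_lifespan_teff"],
            move_prob=reg["move_prob_t"],
            s_IL2_0=reg["s_IL2_0"],
            s_IFNg_0=reg["s_IFNg_0"],
            u_IFNg_0=reg["u_IFNg_0"],
        )


def expected_recruitment(cent_teff: float, tum_c1: float, k_rec: float) -> float:
    """Expected recruits per entry point per step: Cent.Teff * Tum.C1 * k_rec."""
    if min(cent_teff, tum_c1, k_rec) < 0:
        raise ValueError("inputs must be nonnegative")
    n = cent_teff * tum_c1 * k_rec
    if n >= 1.0:
        logger.warning(
            "per-entry-point recruitment expectation %.3f >= 1; lower n_r", n
        )
    return n


def recruit_at_entry_points(
    grid: Grid,
    n_teff: float,
    n_treg: float,
    rng: np.random.Generator,
) -> list[CellAgent]:
    """Bernoulli recruitment of effector CD8s and Tregs at each entry point.

    Cells land at the entry-point voxel if occupancy permits, otherwise at
    a feasible Moore neighbor; full neighborhoods skip the recruit (logged).
    """
    n_teff = min(max(n_teff, 0.0), 1.0)
    n_treg = min(max(n_treg, 0.0), 1.0)
    recruited: list[CellAgent] = []
    for point in grid.entry_points:
        voxel = (int(point[0]), int(point[1]), int(point[2]))
        for prob, kind, state in ((n_teff, "CD8", "effector"), (n_treg, "Treg", "treg")):
            if prob <= 0.0 or rng.random() >= prob:
                continue
            target = None
            if grid.can_place_tcell(voxel):
                target = voxel
            else:
                options = [
                    v for v in neighborhood(grid, voxel, "Moore") if grid.can_place_tcell(v)
                ]
                if options:
                    target = options[rng.integers(len(options))]
            if target is None:
                grid.counts["blocked"] += 1
                continue
            recruited.append(grid.add_agent(kind, state, target))
    return recruited


def prob_kill(dt: float, k_C_death_by_T: float, H: float, q_teff: float) -> float:
    """Kill probability of a cancer cell exposed to cytotoxic CD8s."""
    _check_unit_interval(H=H, q_teff=q_teff)
    return -math.expm1(-dt * k_C_death_by_T * (1.0 - H) * q_teff)


def prob_exhaust_pdl1(dt: float, k_Teff_death_by_C: float, H: float) -> float:
    """PD-L1 driven exhaustion probability; every cell expresses PD-L1."""
    _check_unit_interval(H=H)
    return -math.expm1(-dt * k_Teff_death_by_C * H)


def prob_exhaust_treg(
    dt: float, k_Teff_inhibBy_Treg: float, H: float, q_treg: float
) -> float:
    """Treg-mediated exhaustion; PD-1 engagement amplifies it via (1 + H)."""
    _check_unit_interval(H=H, q_treg=q_treg)
    return -math.expm1(-dt * k_Teff_inhibBy_Treg * (1.0 + H) * q_treg)


def _check_unit_interval(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")


class SynapseCache:
    """Memoized checkpoint modifier for one (step, nivo) context.

    Within a step the tumor antibody concentration is frozen, so H varies
    only with the local IFNg concentration; concentrations are quantized
    to 1e-4 ng/mL for the cache key (far below any Hill sensitivity).
    """

    def __init__(self, synapse: SynapseParams, nivo_tum: float) -> None:
        self.synapse = synapse
        self.nivo = max(nivo_tum, 0.0)
        self._cache: dict[float, float] = {}

    def H(self, c_ifng: float) -> float:
        key = round(c_ifng, 4)
        hit = self._cache.get(key)
        if hit is None:
            hit = solve_synapse(self.synapse, key, self.nivo).H
            self._cache[key] = hit
        return hit


class _VoxelIndex:
    """Transient per-step index of T cells by voxel for neighborhood scans."""

    def __init__(self, grid: Grid) -> None:
        self.by_voxel: dict[tuple[int, int, int], list[CellAgent]] = {}
        for agent in grid.agents.values():
            if agent.kind != "cancer":
                self.by_voxel.setdefault(agent.position, []).append(agent)

    def move(self, agent: CellAgent, old, new) -> None:
        self.by_voxel[old].remove(agent)
        self.by_voxel.setdefault(new, []).append(agent)

    def remove(self, agent: CellAgent) -> None:
        self.by_voxel[agent.position].remove(agent)

    def composition(self, grid: Grid, voxel) -> tuple[int, int, int]:
        n_cyt = n_treg = n_total = 0
        for v in neighborhood(grid, voxel, "Moore"):
            if grid.cancer_id[v] >= 0:
                n_total += 1
            for agent in self.by_voxel.get(v, ()):
                n_total += 1
                if agent.kind == "Treg":
                    n_treg += 1
                elif agent.state == "cytotoxic":
                    n_cyt += 1
        return n_cyt, n_treg, n_total


def kill_phase(
    grid: Grid,
    index: _VoxelIndex,
    params: TcellParams,
    syn_cache: SynapseCache,
    ifng: Field,
    dt: float,
    rng: np.random.Generator,
) -> int:
    """Aggregated killing draw for every cancer cell facing cytotoxic CD8s.

    Each target is evaluated once per step with q_teff summarizing all
    attackers (a single aggregated draw, matching the compartmental
    reaction form rather than independent per-attacker draws).  The
    synapse is solved per target with its local IFNg-induced PD-L1 and
    the tumor antibody concentration.  Returns the number of kills.
    """
    # candidate targets: cancer cells in the Moore shell of a cytotoxic CD8
    target_ids: set[int] = set()
    for voxel, residents in index.by_voxel.items():
        if not any(a.kind == "CD8" and a.state == "cytotoxic" for a in residents):
            continue
        for v in neighborhood(grid, voxel, "Moore"):
            cid = int(grid.cancer_id[v])
            if cid >= 0:
                target_ids.add(cid)
    kills = 0
    for tid in target_ids:
        target = grid.agents.get(tid)
        if target is None:
            continue
        n_cyt, _n_treg, n_total = index.composition(grid, target.position)
        if n_cyt == 0:
            continue
        q_teff = n_cyt / n_total
        H = syn_cache.H(sample_concentration(ifng, target.position))
        if rng.random() < prob_kill(dt, params.k_C_death_by_T, H, q_teff):
            grid.remove_agent(target, reason="died")
            kills += 1
    return kills


def step_tcell(
    cell: CellAgent,
    grid: Grid,
    index: _VoxelIndex,
    il2: Field,
    ifng: Field,
    params: TcellParams,
    syn_cache: SynapseCache,
    dt: float,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Advance one T-cell agent by dt (movement, state, division, exhaustion).

    Killing is handled separately in :func:`kill_phase` so each cancer
    cell receives one aggregated draw per step.
    """
    events: list[tuple[str, int]] = []
    # natural death
    if rng.random() < -math.expm1(-dt / params.lifespan):
        index.remove(cell)
        grid.remove_agent(cell, reason="died")
        events.append(("die", cell.id))
        return events
    # unbiased random walk on free von Neumann voxels
    if params.move_prob > 0 and rng.random() < params.move_prob:
        options = [
            v for v in neighborhood(grid, cell.position, "vonNeumann") if grid.can_place_tcell(v)
        ]
        if options:
            old = cell.position
            target = options[rng.integers(len(options))]
            if grid.move_agent(cell, target):
                index.move(cell, old, target)

    if cell.kind == "Treg":
        return events

    if cell.state == "effector":
        # contact with any cancer cell licenses the cytotoxic program
        if any(grid.cancer_id[v] >= 0 for v in neighborhood(grid, cell.position, "Moore")):
            cell.state = "cytotoxic"
            events.append(("activate", cell.id))
    if cell.state == "cytotoxic":
        cell.il2_accum += sample_concentration(il2, cell.position) * dt
        if (
            cell.il2_accum >= params.il2_threshold
            and cell.il2_divisions < params.il2_max_divisions
        ):
            options = [
                v
                for v in neighborhood(grid, cell.position, "vonNeumann")
                if grid.can_place_tcell(v)
            ]
            if options:
                target = options[rng.integers(len(options))]
                daughter = grid.add_agent("CD8", "effector", target)
                index.by_voxel.setdefault(target, []).append(daughter)
                cell.il2_accum -= params.il2_threshold
                cell.il2_divisions += 1
                events.append(("divide", daughter.id))

    if cell.state in ("effector", "cytotoxic"):
        H = syn_cache.H(sample_concentration(ifng, cell.position))
        exhausted = False
        if rng.random() < prob_exhaust_pdl1(dt, params.k_Teff_death_by_C, H):
            exhausted = True
            events.append(("exhaust_pdl1", cell.id))
        else:
            _n_cyt, n_treg, n_total = index.composition(grid, cell.position)
            if n_treg and rng.random() < prob_exhaust_treg(
                dt, params.k_Teff_inhibBy_Treg, H, n_treg / n_total
            ):
                exhausted = True
                events.append(("exhaust_treg", cell.id))
        if exhausted:
            cell.state = "exhausted"
    return events
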