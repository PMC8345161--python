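"""Stochastic cancer-cell agent rules on the lattice.

Per-step event probabilities derive from the lineage rates through the
exponential waiting-time conversion P = 1 - exp(-rate * dt).  Division
requires a free von Neumann voxel; crowded cells skip the division (the
blocked attempt is logged), which is what couples lineage composition to
spatial constraints.
"""
from __future__ import annotations

import math

import numpy as np

from .lattice import CellAgent, Grid, neighborhood
from .lineage import LineageRates

__all__ = ["step_cancer_cell"]


def _free_cancer_voxel(grid: Grid, voxel, rng: np.random.Generator):
    """Uniformly chosen free von Neumann neighbor, or None when crowded."""
    options = [v for v in neighborhood(grid, voxel, "vonNeumann") if grid.can_place_cancer(v)]
    if not options:
        return None
    return options[rng.integers(len(options))]


def step_cancer_cell(
    cell: CellAgent,
    grid: Grid,
    rates: LineageRates,
    dt: float,
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Advance one cancer agent by dt; returns (event, agent_id) log entries.

    CSC: may move, then divide at rate r_s (asymmetric with probability k,
    yielding a progenitor daughter that inherits the stem lineage label).
    Progenitors divide at rate r_p; when a division would exceed d_max the
    two daughters are senescent.  Senescent cells die at rate mu.
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    events: list[tuple[str, int]] = []
    if dt == 0.0:
        return events
    state = cell.state

    if state == "csc":
        if rates.move_prob_csc > 0 and rng.random() < rates.move_prob_csc:
            target = _free_cancer_voxel(grid, cell.position, rng)
            if target is not None and grid.move_agent(cell, target):
                events.append(("move", cell.id))
        if rng.random() < -math.expm1(-rates.r_s * dt):
            target = _free_cancer_voxel(grid, cell.position, rng)
            if target is None:
                grid.counts["blocked"] += 1
                events.append(("blocked_division", cell.id))
            elif rng.random() < rates.k:
                daughter = grid.add_agent(
                    "cancer", "progenitor", target, stem_id=cell.stem_id, divisions_done=0
                )
                events.append(("divide_asym", daughter.id))
            else:
                daughter = grid.add_agent("cancer", "csc", target)
                events.append(("divide_sym", daughter.id))

    elif state == "progenitor":
        if rates.move_prob_prog > 0 and rng.random() < rates.move_prob_prog:
            target = _free_cancer_voxel(grid, cell.position, rng)
            if target is not None and grid.move_agent(cell, target):
                events.append(("move", cell.id))
        if rng.random() < -math.expm1(-rates.r_p * dt):
            target = _free_cancer_voxel(grid, cell.position, rng)
            if target is None:
                grid.counts["blocked"] += 1
                events.append(("blocked_division", cell.id))
            else:
                new_div = cell.divisions_done + 1
                if new_div >= rates.d_max:
                    daughter_state = "senescent"
                else:
                    daughter_state = "progenitor"
                daughter = grid.add_agent(
                    "cancer", daughter_state, target, stem_id=cell.stem_id, divisions_done=new_div
                )
                cell.divisions_done = new_div
                cell.state = daughter_state
                events.append(("divide", daughter.id))

    elif state == "senescent":
        if rng.random() < -math.expm1(-rates.mu * dt):
            grid.remove_agent(cell, reason="died")
            events.append(("die", cell.id))
    else:
        raise ValueError(f"unknown cancer state {state!r}")
    return events
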