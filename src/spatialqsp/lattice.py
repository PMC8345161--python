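"""3D voxel lattice hosting cell agents.

The tumor microenvironment is discretized into cubic voxels (20 um edge by
default).  Each voxel can hold at most one cancer cell; the number of
T cells allowed to coexist in a voxel is 8 when no cancer cell is present
and 1 otherwise (cell-size bookkeeping: ~20 um cancer cells vs ~10 um
lymphocytes).  Agents move through von Neumann neighborhoods (6 faces) and
interact through Moore neighborhoods (26 voxels); both truncate at the
domain boundary (no-flux, no wraparound).

Two region types are supported: the tumor *core* (fully populated, static
window) and the *invasive front*, where only the lower-z half is populated
and the whole window translates along z to keep the cancer-cell center of
mass fixed, tracking the moving tumor boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CellAgent",
    "Grid",
    "OccupancyError",
    "init_grid",
    "populate_tumor",
    "place_entry_points",
    "neighborhood",
    "shift_window",
]

CANCER_STATES = ("csc", "progenitor", "senescent")
TCELL_STATES = ("effector", "cytotoxic", "exhausted", "treg")

Voxel = tuple[int, int, int]


class OccupancyError(RuntimeError):
    """Raised when an operation would violate voxel occupancy limits."""


@dataclass(slots=True)
class CellAgent:
    id: int
    kind: Literal["cancer", "CD8", "Treg"]
    state: str
    position: Voxel
    stem_id: int = -1  # lineage label: the founding CSC's agent id
    divisions_done: int = 0
    il2_accum: float = 0.0  # ng*day/mL cumulative exposure (CD8 only)
    il2_divisions: int = 0  # IL-2 licensed divisions used (CD8 only)


class Grid:
    """Voxel lattice with occupancy registers and resident agents."""

    def __init__(
        self,
        dims: Voxel,
        voxel_size: float = 20.0,
        region_type: Literal["core", "front"] = "core",
        seed: int | None = None,
        max_t_per_voxel: int = 8,
    ) -> None:
        if any(d <= 0 for d in dims):
            raise ValueError(f"grid dimensions must be positive, got {dims}")
        self.dims: Voxel = tuple(int(d) for d in dims)  # type: ignore[assignment]
        self.voxel_size = float(voxel_size)
        self.region_type = region_type
        self.rng = np.random.default_rng(seed)
        self.max_t_per_voxel = int(max_t_per_voxel)
        # occupancy registers
        self.cancer_id = np.full(self.dims, -1, dtype=np.int64)
        self.t_count = np.zeros(self.dims, dtype=np.int16)
        self.entry_points: np.ndarray = np.empty((0, 3), dtype=np.int64)
        self.agents: dict[int, CellAgent] = {}
        self._next_id = 0
        self.window_origin_z = 0
        self.target_com_z: float | None = None
        # conservation ledger
        self.counts = {"created": 0, "died": 0, "shifted_off": 0, "blocked": 0}
        # lazily built per-voxel neighbor tables (boundary-truncated)
        self._neighbor_cache: dict[str, dict[Voxel, tuple[Voxel, ...]]] = {
            "vonNeumann": {},
            "Moore": {},
        }

    # ------------------------------------------------------------------ geometry
    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * (self.voxel_size * 1e-3) ** 3

    def in_bounds(self, voxel: Voxel) -> bool:
        return all(0 <= voxel[a] < self.dims[a] for a in range(3))

    # ------------------------------------------------------------------ occupancy
    def t_capacity(self, voxel: Voxel) -> int:
        return 1 if self.cancer_id[voxel] >= 0 else self.max_t_per_voxel

    def can_place_cancer(self, voxel: Voxel) -> bool:
        return (
            self.in_bounds(voxel)
            and self.cancer_id[voxel] < 0
            and self.t_count[voxel] <= 1
        )

    def can_place_tcell(self, voxel: Voxel) -> bool:
        return self.in_bounds(voxel) and self.t_count[voxel] < self.t_capacity(voxel)

    def add_agent(
        self,
        kind: str,
        state: str,
        voxel: Voxel,
        stem_id: int = -1,
        divisions_done: int = 0,
    ) -> CellAgent:
        if kind == "cancer":
            if not self.can_place_cancer(voxel):
                raise OccupancyError(f"cannot place cancer cell at {voxel}")
        else:
            if not self.can_place_tcell(voxel):
                raise OccupancyError(f"cannot place T cell at {voxel}")
        agent = CellAgent(
            id=self._next_id,
            kind=kind,  # type: ignore[arg-type]
            state=state,
            position=voxel,
            stem_id=stem_id,
            divisions_done=divisions_done,
        )
        if kind == "cancer" and state == "csc" and stem_id < 0:
            agent.stem_id = agent.id
        self._next_id += 1
        self.agents[agent.id] = agent
        if kind == "cancer":
            self.cancer_id[voxel] = agent.id
        else:
            self.t_count[voxel] += 1
        self.counts["created"] += 1
        return agent

    def remove_agent(self, agent: CellAgent, reason: str = "died") -> None:
        del self.agents[agent.id]
        if agent.kind == "cancer":
            self.cancer_id[agent.position] = -1
        else:
            self.t_count[agent.position] -= 1
        self.counts[reason] = self.counts.get(reason, 0) + 1

    def move_agent(self, agent: CellAgent, voxel: Voxel) -> bool:
        """Move if target occupancy permits; returns False when blocked."""
        if agent.kind == "cancer":
            if not self.can_place_cancer(voxel):
                return False
            self.cancer_id[agent.position] = -1
            self.cancer_id[voxel] = agent.id
        else:
            if not self.can_place_tcell(voxel):
                return False
            self.t_count[agent.position] -= 1
            self.t_count[voxel] += 1
        agent.position = voxel
        return True

    # ------------------------------------------------------------------ queries
    def cancer_cells(self) -> list[CellAgent]:
        return [a for a in self.agents.values() if a.kind == "cancer"]

    def tcells(self) -> list[CellAgent]:
        return [a for a in self.agents.values() if a.kind != "cancer"]

    def counts_by_state(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.agents.values():
            out[a.state] = out.get(a.state, 0) + 1
        return out

    def cancer_com_z(self) -> float:
        zs = [a.position[2] for a in self.agents.values() if a.kind == "cancer"]
        if not zs:
            raise ValueError("no cancer cells on grid")
        return float(np.mean(zs))

    # ------------------------------------------------------------------ window
    def shift_contents(self, dz: int, fields: Sequence[np.ndarray] = ()) -> int:
        """Translate agents, occupancy, entry points and fields by dz voxels.

        Agents shifted outside the domain are removed (counted in the
        ledger); field rasters are shifted with zero-fill on the opened
        side.  Returns the number of agents removed.
        """
        if dz == 0:
            return 0
        nz = self.dims[2]
        removed = 0
        for agent in list(self.agents.values()):
            z = agent.position[2] + dz
            if 0 <= z < nz:
                agent.position = (agent.position[0], agent.position[1], z)
            else:
                del self.agents[agent.id]
                removed += 1
        self.counts["shifted_off"] += removed
        # rebuild occupancy from surviving agents
        self.cancer_id.fill(-1)
        self.t_count.fill(0)
        for agent in self.agents.values():
            if agent.kind == "cancer":
                self.cancer_id[agent.position] = agent.id
            else:
                self.t_count[agent.position] += 1
        if len(self.entry_points):
            pts = self.entry_points.copy()
            pts[:, 2] += dz
            keep = (pts[:, 2] >= 0) & (pts[:, 2] < nz)
            self.entry_points = pts[keep]
        for f in fields:
            shifted = np.zeros_like(f)
            if dz > 0:
                shifted[:, :, dz:] = f[:, :, :-dz]
            else:
                shifted[:, :, :dz] = f[:, :, -dz:]
            f[...] = shifted
        self.window_origin_z -= dz
        return removed


# ---------------------------------------------------------------------- ops
def init_grid(
    dims: Voxel,
    voxel_size: float = 20.0,
    region_type: Literal["core", "front"] = "core",
    seed: int | None = None,
) -> Grid:
    """Create an empty lattice; deterministic under ``seed``."""
    return Grid(dims, voxel_size=voxel_size, region_type=region_type, seed=seed)


def _draw_state(fractions: np.ndarray, d_max: int, rng: np.random.Generator) -> tuple[str, int]:
    """Sample (state, divisions_done) from the lineage fraction vector."""
    idx = rng.choice(len(fractions), p=fractions)
    if idx == 0:
        return "csc", 0
    if idx == len(fractions) - 1:
        return "senescent", d_max
    return "progenitor", idx - 1  # P_i has completed i-1 divisions

    # note: P_i indexes cells *after* i-1 divisions of their progenitor line


def populate_tumor(
    grid: Grid,
    fractions: np.ndarray | Sequence[float],
    fill_probability: float,
    half_fill: bool = False,
) -> Grid:
    """Seed cancer cells voxel-by-voxel at ``fill_probability``.

    ``half_fill`` restricts seeding to the lower-z half (invasive front
    initialization); subtypes are drawn from the steady lineage fractions
    so the initial composition matches the long-time mix.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-8 or (fractions < 0).any():
        raise ValueError("fractions must be nonnegative and sum to 1")
    if not 0.0 <= fill_probability <= 1.0:
        raise ValueError("fill_probability must be in [0, 1]")
    d_max = len(fractions) - 2
    nx, ny, nz = grid.dims
    z_max = nz // 2 if half_fill else nz
    rng = grid.rng
    fill = rng.random((nx, ny, z_max)) < fill_probability
    for i, j, k in zip(*np.nonzero(fill)):
        state, ndiv = _draw_state(fractions, d_max, rng)
        grid.add_agent("cancer", state, (int(i), int(j), int(k)), divisions_done=ndiv)
    if half_fill or grid.region_type == "front":
        if any(a.kind == "cancer" for a in grid.agents.values()):
            grid.target_com_z = grid.cancer_com_z()
    return grid


def place_entry_points(grid: Grid, density_per_mm3: float, seed: int | None = None) -> Grid:
    """Scatter T-cell entry points (tumor vasculature) uniformly in 3D.

    The number of points is Poisson with mean density x window volume, so
    regional density ratios carry over to realized mean counts.
    """
    if density_per_mm3 < 0:
        raise ValueError("density must be nonnegative")
    rng = np.random.default_rng(seed) if seed is not None else grid.rng
    n = rng.poisson(density_per_mm3 * grid.volume_mm3)
    if n == 0:
        grid.entry_points = np.empty((0, 3), dtype=np.int64)
        return grid
    pts = np.column_stack([rng.integers(0, d, size=n) for d in grid.dims]).astype(np.int64)
    grid.entry_points = pts
    return grid


def place_entry_points_stratified(
    grid: Grid,
    density_low_z: float,
    density_high_z: float,
    seed: int | None = None,
) -> Grid:
    """Entry points with different densities below/above the z midplane.

    Supports scenarios where vascular density differs between the tumor
    side (low z) and stromal side (high z) of an invasive-front window.
    """
    rng = np.random.default_rng(seed) if seed is not None else grid.rng
    nx, ny, nz = grid.dims
    half_vol = grid.volume_mm3 / 2.0
    chunks = []
    for density, z_lo, z_hi in (
        (density_low_z, 0, nz // 2),
        (density_high_z, nz // 2, nz),
    ):
        n = rng.poisson(density * half_vol)
        if n:
            chunks.append(
                np.column_stack(
                    [
                        rng.integers(0, nx, size=n),
                        rng.integers(0, ny, size=n),
                        rng.integers(z_lo, z_hi, size=n),
                    ]
                )
            )
    grid.entry_points = (
        np.vstack(chunks).astype(np.int64) if chunks else np.empty((0, 3), dtype=np.int64)
    )
    return grid


_VN_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)
_MOORE_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


def neighborhood(
    grid: Grid, voxel: Voxel, kind: Literal["vonNeumann", "Moore"] = "vonNeumann"
) -> tuple[Voxel, ...]:
    """Face-adjacent (6) or cubic (26) neighbors, truncated at boundaries.

    Results are memoized per grid; neighbor topology never changes after
    construction.
    """
    cache = grid._neighbor_cache[kind]
    hit = cache.get(voxel)
    if hit is not None:
        return hit
    if not grid.in_bounds(voxel):
        raise ValueError(f"voxel {voxel} outside grid {grid.dims}")
    offsets = _VN_OFFSETS if kind == "vonNeumann" else _MOORE_OFFSETS
    out: list[Voxel] = []
    nx, ny, nz = grid.dims
    x, y, z = voxel
    for dx, dy, dz in offsets:
        p = (x + dx, y + dy, z + dz)
        if 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz:
            out.append(p)
    cache[voxel] = tuple(out)
    return cache[voxel]


def shift_window(
    grid: Grid,
    fractions: np.ndarray | Sequence[float],
    fields: Sequence[np.ndarray] = (),
    fill_probability: float | None = None,
) -> int:
    """Re-center the invasive-front window on the cancer center of mass.

    If the center of mass has drifted >= 1 voxel from its initialization
    target, all contents translate by the (negated) integer drift.  Voxels
    opened on the tumor side (low z) are repopulated from the lineage
    fractions at the grid's fill probability; voxels opened on the stromal
    side stay empty.  Returns the applied shift in voxels (signed, in the
    direction contents moved).
    """
    if grid.region_type != "front":
        raise ValueError("window shifting applies to invasive-front regions only")
    if grid.target_com_z is None:
        raise ValueError("grid has no center-of-mass target; populate it first")
    drift = grid.cancer_com_z() - grid.target_com_z
    shift = -int(round(drift))
    if shift == 0:
        return 0
    grid.shift_contents(shift, fields=fields)
    if shift > 0:
        # contents moved toward high z: tumor shrank, low-z voxels opened on
        # the tumor side -> repopulate
        fractions = np.asarray(fractions, dtype=float)
        d_max = len(fractions) - 2
        p_fill = grid.rng.random((grid.dims[0], grid.dims[1], shift))
        fill_p = 0.7 if fill_probability is None else fill_probability
        for i, j, k in zip(*np.nonzero(p_fill < fill_p)):
            vox = (int(i), int(j), int(k))
            if grid.can_place_cancer(vox):
                state, ndiv = _draw_state(fractions, d_max, grid.rng)
                grid.add_agent("cancer", state, vox, divisions_done=ndiv)
    return shift
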