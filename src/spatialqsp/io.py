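"""Run configuration, snapshots, virtual staining, and synthetic cohorts.

Configs are YAML/JSON mappings validated against the parameter registry
and a small run schema; every run can freeze a copy of its resolved
config next to its outputs.  Cell snapshots are plain CSV in physical
micrometer coordinates; virtual immunohistochemistry projects a slab of
the 3D cell snapshot onto a 2D marker raster.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .coupling import CouplingConfig, VolumeSpec
from .lattice import Grid
from .registry import ParameterRegistry, UnknownParameterError, default_registry
from .synapse import SynapseParams, hill
from .trial import Protocol

SCHEMA_VERSION = "1"

__all__ = [
    "RunConfig",
    "load_config",
    "snapshot_cells",
    "render_slice",
    "fixture_cohort",
    "write_timeseries",
]

_RUN_KEYS = {"parameters", "volumes", "coupling", "protocol", "seed", "record_every", "initial_c1"}


@dataclass
class RunConfig:
    registry: ParameterRegistry
    coupling: CouplingConfig
    protocol: Protocol
    seed: int = 0
    record_every: float = 1.0
    initial_c1: float = 1.0e9

    def frozen_copy(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "parameters": self.registry.as_dict(),
            "coupling": {
                "w_qsp": self.coupling.w_qsp,
                "dt": self.coupling.dt,
            },
            "volumes": [asdict(v) for v in self.coupling.volumes],
            "protocol": asdict(self.protocol),
            "seed": self.seed,
            "record_every": self.record_every,
            "initial_c1": self.initial_c1,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.frozen_copy(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | dict[str, Any]) -> RunConfig:
    """Load and validate a run config; unknown keys are rejected."""
    if isinstance(path, dict):
        raw = path
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _RUN_KEYS - {"schema_version"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        reg = default_registry().updated(raw.get("parameters", {}))
    except UnknownParameterError as exc:
        raise ConfigError(f"unknown parameter key: {exc}") from exc
    volumes = [
        VolumeSpec(
            region_type=v["region_type"],
            k_i=float(v["k_i"]),
            dims=tuple(v.get("dims", (20, 20, 20))),
            entry_density=v.get("entry_density"),
            fill_probability=v.get("fill_probability"),
        )
        for v in raw.get("volumes", [{"region_type": "core", "k_i": 1.0}])
    ]
    coupling_raw = dict(raw.get("coupling", {}))
    coupling = CouplingConfig(
        w_qsp=float(coupling_raw.get("w_qsp", reg["w_qsp"])),
        dt=float(coupling_raw.get("dt", reg["dt_abm"])),
        volumes=volumes,
    )
    protocol = Protocol(**raw.get("protocol", {}))
    return RunConfig(
        registry=reg,
        coupling=coupling,
        protocol=protocol,
        seed=int(raw.get("seed", 0)),
        record_every=float(raw.get("record_every", 1.0)),
        initial_c1=float(raw.get("initial_c1", 1.0e9)),
    )


def snapshot_cells(grid: Grid) -> pd.DataFrame:
    """Cell snapshot in physical um coordinates (voxel centers)."""
    h = grid.voxel_size
    rows = []
    for a in grid.agents.values():
        x, y, z = a.position
        rows.append(
            {
                "id": a.id,
                "kind": a.kind,
                "state": a.state,
                "x_um": (x + 0.5) * h,
                "y_um": (y + 0.5) * h,
                "z_um": (z + 0.5) * h,
                "stem_id": a.stem_id,
                "divisions": a.divisions_done,
            }
        )
    df = pd.DataFrame(
        rows, columns=["id", "kind", "state", "x_um", "y_um", "z_um", "stem_id", "divisions"]
    )
    df.attrs["schema_version"] = SCHEMA_VERSION
    return df


_MARKER_STATES = {
    "CD8": ("effector", "cytotoxic", "exhausted"),
    "FoxP3": ("treg",),
}


def render_slice(
    cells: pd.DataFrame,
    ifng_conc: np.ndarray | None,
    marker: str,
    synapse: SynapseParams,
    z_center_um: float,
    thickness_um: float = 20.0,
    pixel_um: float = 20.0,
    extent_um: tuple[float, float] | None = None,
    voxel_um: float = 20.0,
) -> np.ndarray:
    """Virtual IHC/mIF: project a z slab of the cell snapshot to 2D.

    CD8 and FoxP3 channels count matching cells per pixel; the PD-L1
    channel weights every nucleated cell by its IFNg-induced expression
    (Hill response of the local concentration, between the basal fraction
    and 1); ``mIF`` returns a 3-channel stack (cancer, CD8, Treg).
    Deterministic: no staining noise is simulated.
    """
    half = thickness_um / 2.0
    slab = cells[(cells.z_um >= z_center_um - half) & (cells.z_um < z_center_um + half)]
    if extent_um is None:
        if len(cells):
            extent_um = (float(cells.x_um.max()) + pixel_um, float(cells.y_um.max()) + pixel_um)
        else:
            extent_um = (pixel_um, pixel_um)
    nx = max(int(np.ceil(extent_um[0] / pixel_um)), 1)
    ny = max(int(np.ceil(extent_um[1] / pixel_um)), 1)
    if marker == "mIF":
        img = np.zeros((3, nx, ny))
    else:
        img = np.zeros((nx, ny))
    if not len(slab):
        import logging

        logging.getLogger(__name__).warning("empty slice at z=%s um", z_center_um)
        return img
    ix = np.minimum((slab.x_um.to_numpy() / pixel_um).astype(int), nx - 1)
    iy = np.minimum((slab.y_um.to_numpy() / pixel_um).astype(int), ny - 1)
    if marker in _MARKER_STATES:
        mask = slab.state.isin(_MARKER_STATES[marker]).to_numpy()
        np.add.at(img, (ix[mask], iy[mask]), 1.0)
    elif marker == "PDL1":
        if ifng_conc is None:
            raise ValueError("PDL1 rendering needs the IFNg concentration raster")
        vx = np.minimum((slab.x_um.to_numpy() / voxel_um).astype(int), ifng_conc.shape[0] - 1)
        vy = np.minimum((slab.y_um.to_numpy() / voxel_um).astype(int), ifng_conc.shape[1] - 1)
        vz = np.minimum((slab.z_um.to_numpy() / voxel_um).astype(int), ifng_conc.shape[2] - 1)
        local = ifng_conc[vx, vy, vz]
        base = synapse.pdl1_base_frac
        intensity = base + (1.0 - base) * np.array(
            [hill(c, synapse.ifng_ec50, synapse.ifng_hill_n) for c in local]
        )
        np.add.at(img, (ix, iy), intensity)
    elif marker == "mIF":
        for ch, pred in enumerate(
            (
                slab.kind.eq("cancer").to_numpy(),
                slab.state.isin(_MARKER_STATES["CD8"]).to_numpy(),
                slab.state.eq("treg").to_numpy(),
            )
        ):
            np.add.at(img[ch], (ix[pred], iy[pred]), 1.0)
    else:
        raise ValueError(f"unknown marker {marker!r}")
    return img


def fixture_cohort(
    n: int = 200,
    n_decoys: int = 7,
    effects: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    base_hazard: float = 0.01,
    response_intercept: float = -1.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic cohort with planted biomarker effects; the stats test bed.

    Biomarkers x1..x{k} carry the requested linear effects on a latent
    score; decoys are independent noise.  The table carries all three
    endpoint flavors driven by the same score: a continuous endpoint
    (score + Gaussian noise), a logistic responder flag, and an
    exponential time-to-progression with hazard base_hazard * exp(score),
    censored at its 95th percentile.
    """
    rng = np.random.default_rng(seed)
    effects = {} if effects is None else dict(effects)
    active = list(effects)
    names = active + [f"decoy_{i + 1}" for i in range(n_decoys)]
    X = pd.DataFrame(rng.standard_normal((n, len(names))), columns=names)
    score = sum(beta * X[name] for name, beta in effects.items())
    score = np.zeros(n) + (score if len(active) else 0.0)
    table = X.copy()
    table["diameter"] = score + noise_sd * rng.standard_normal(n)
    p_resp = 1.0 / (1.0 + np.exp(-(response_intercept + score)))
    table["responder"] = rng.uniform(size=n) < p_resp
    hazard = base_hazard * np.exp(score)
    ttp = rng.exponential(1.0 / hazard)
    horizon = float(np.quantile(ttp, 0.95))
    table["ttp"] = np.minimum(ttp, horizon)
    table["ttp_event"] = ttp <= horizon
    return table


def write_timeseries(df: pd.DataFrame, path: str | Path) -> Path:
    """Tidy long-format CSV: one row per (time, variable)."""
    path = Path(path)
    long = df.melt(id_vars=["time"], var_name="variable", value_name="value")
    long.to_csv(path, index=False)
    return path
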