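"""Implant channels, dwell-time plans, voxelized ROIs and calc-point sampling.

Coordinates are right-handed Cartesian in centimeters. Voxel grids are
regular; the grid origin is the *center* of voxel (0, 0, 0), so the
center of voxel index ``(i, j, k)`` is ``origin + index * spacing``.
A voxel belongs to a structure when its center lies inside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "Grid",
    "Channel",
    "Plan",
    "ROIMask",
    "CalcPointSet",
    "sample_calc_points",
    "roi_volume",
    "flatten_times",
    "unflatten_times",
    "save_phantom",
    "load_phantom",
    "write_plan_csv",
    "read_plan_csv",
]

PHANTOM_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: origin = center of voxel (0,0,0), cm."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise InputError("grid spacing must be positive on every axis")
        if any(d <= 0 for d in self.dims):
            raise InputError("grid dims must be positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Centers (cm) of the voxels addressed by an (N, 3) index array."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(
            self.spacing
        )


@dataclass(frozen=True)
class Channel:
    """One applicator tube/needle the source steps through.

    ``positions`` is the ordered (N, 3) array of dwell positions in cm;
    consecutive positions are ``step`` cm apart when generated (0.25 cm
    default), though imported geometries are not re-validated.
    """

    name: str
    positions: np.ndarray
    step: float = 0.25

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3 or positions.shape[0] == 0:
            raise InputError(f"channel {self.name!r} needs a nonempty (N, 3) position array")
        object.__setattr__(self, "positions", positions)

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class Plan:
    """Channels plus per-channel dwell-time vectors t_{m,n} in seconds."""

    channels: tuple[Channel, ...]
    dwell_times: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        channels = tuple(self.channels)
        times = tuple(np.asarray(t, dtype=float) for t in self.dwell_times)
        if len(channels) != len(times):
            raise InputError("one dwell-time vector per channel required")
        for ch, t in zip(channels, times):
            if t.shape != (len(ch),):
                raise InputError(
                    f"channel {ch.name!r} has {len(ch)} dwells but {t.shape} times"
                )
            if np.any(t < 0):
                raise InputError("dwell times must be nonnegative")
        object.__setattr__(self, "channels", channels)
        object.__setattr__(self, "dwell_times", times)

    @classmethod
    def uniform(cls, channels, time: float) -> "Plan":
        channels = tuple(channels)
        return cls(channels, tuple(np.full(len(ch), float(time)) for ch in channels))

    @property
    def dwell_count(self) -> int:
        return sum(len(ch) for ch in self.channels)

    def scaled(self, factor: float) -> "Plan":
        return Plan(self.channels, tuple(t * factor for t in self.dwell_times))


@dataclass(frozen=True)
class ROIMask:
    """Boolean occupancy of one structure on a shared grid."""

    name: str
    role: str  # 'target' or 'oar'
    grid: Grid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ("target", "oar"):
            raise InputError(f"role must be 'target' or 'oar', got {self.role!r}")
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != tuple(self.grid.dims):
            raise InputError(f"occupancy shape {occ.shape} != grid dims {self.grid.dims}")
        if not occ.any():
            raise InputError(f"ROI {self.name!r} has no occupied voxels")
        object.__setattr__(self, "occupancy", occ)


@dataclass(frozen=True)
class CalcPointSet:
    """Calculation points (voxel centers) feeding the dose kernel.

    ``roi_membership`` maps each ROI name to the indices of its points
    in ``points``; ``roi_point_volume`` gives the volume in cm³ each
    sampled point represents for that ROI (the full ROI volume divided
    by its sampled point count, so DVHs built from a subsample still
    integrate to the true structure volume).
    """

    points: np.ndarray
    voxel_volume: float
    roi_membership: dict[str, np.ndarray] = field(default_factory=dict)
    roi_point_volume: dict[str, float] = field(default_factory=dict)


def roi_volume(roi: ROIMask) -> float:
    """Structure volume in cm³: occupied voxels × voxel volume."""
    return int(roi.occupancy.sum()) * roi.grid.voxel_volume


def sample_calc_points(rois, subsample_fraction: float = 1.0, seed: int = 0) -> CalcPointSet:
    """Collect (optionally subsampled) occupied voxel centers per ROI.

    With ``subsample_fraction == 1`` every occupied voxel contributes
    its center, deterministically and independent of ``seed``.  With
    ``f < 1`` each ROI is thinned to ``round(f * count)`` voxels (at
    least one), drawn uniformly without replacement with the given
    seed — the full-grid semantics of the method are unchanged, only
    the sampling density.
    """
    rois = list(rois)
    if not rois:
        raise InputError("need at least one ROI")
    if not (0 < subsample_fraction <= 1):
        raise InputError("subsample_fraction must be in (0, 1]")
    grid = rois[0].grid
    for roi in rois[1:]:
        if roi.grid != grid:
            raise InputError("all ROIs must share one grid")
    rng = np.random.default_rng(seed)
    blocks, membership, per_point_volume = [], {}, {}
    offset = 0
    for roi in rois:
        idx = np.argwhere(roi.occupancy)
        if subsample_fraction < 1.0:
            k = max(1, round(subsample_fraction * idx.shape[0]))
            chosen = np.sort(rng.choice(idx.shape[0], size=k, replace=False))
            idx = idx[chosen]
        blocks.append(grid.voxel_centers(idx))
        membership[roi.name] = np.arange(offset, offset + idx.shape[0])
        per_point_volume[roi.name] = roi_volume(roi) / idx.shape[0]
        offset += idx.shape[0]
    return CalcPointSet(
        points=np.vstack(blocks),
        voxel_volume=grid.voxel_volume,
        roi_membership=membership,
        roi_point_volume=per_point_volume,
    )


def flatten_times(plan: Plan) -> np.ndarray:
    """Concatenate per-channel dwell times in (channel, position) order."""
    return np.concatenate(plan.dwell_times)


def unflatten_times(channels, times: np.ndarray) -> Plan:
    """Inverse of :func:`flatten_times` for the given channel list."""
    channels = tuple(channels)
    times = np.asarray(times, dtype=float)
    sizes = [len(ch) for ch in channels]
    if times.shape != (sum(sizes),):
        raise InputError(f"expected {sum(sizes)} times, got {times.shape}")
    split = np.split(times, np.cumsum(sizes)[:-1])
    return Plan(channels, tuple(split))


# ---------------------------------------------------------------------------
# Phantom JSON interchange: grid + RLE-encoded ROI occupancy + channels.
# ---------------------------------------------------------------------------


def _rle_encode(flat: np.ndarray) -> list[int]:
    """[start, length, start, length, ...] of True runs in a flat bool array."""
    padded = np.concatenate(([False], flat, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    out: list[int] = []
    for s, e in zip(starts, ends):
        out += [int(s), int(e - s)]
    return out


def _rle_decode(runs: list[int], size: int) -> np.ndarray:
    flat = np.zeros(size, dtype=bool)
    for s, n in zip(runs[::2], runs[1::2]):
        flat[s : s + n] = True
    return flat


def save_phantom(path, channels, rois) -> None:
    rois = list(rois)
    grid = rois[0].grid
    doc = {
        "schema_version": PHANTOM_SCHEMA_VERSION,
        "grid": {
            "origin_cm": list(grid.origin),
            "spacing_cm": list(grid.spacing),
            "dims": list(grid.dims),
        },
        "rois": [
            {
                "name": roi.name,
                "role": roi.role,
                "rle": _rle_encode(roi.occupancy.ravel(order="C")),
            }
            for roi in rois
        ],
        "channels": [
            {
                "name": ch.name,
                "step_cm": ch.step,
                "positions_cm": np.asarray(ch.positions).tolist(),
            }
            for ch in channels
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_phantom(path):
    """Read a phantom JSON file; returns (channels, rois)."""
    try:
        doc = json.loads(Path(path).read_text())
    except FileNotFoundError:
        raise InputError(f"phantom file not found: {path}") from None
    if doc.get("schema_version") != PHANTOM_SCHEMA_VERSION:
        raise InputError(
            f"unsupported phantom schema version {doc.get('schema_version')!r}"
        )
    g = doc["grid"]
    grid = Grid(tuple(g["origin_cm"]), tuple(g["spacing_cm"]), tuple(g["dims"]))
    size = int(np.prod(grid.dims))
    rois = [
        ROIMask(
            name=r["name"],
            role=r["role"],
            grid=grid,
            occupancy=_rle_decode(r["rle"], size).reshape(grid.dims),
        )
        for r in doc["rois"]
    ]
    channels = [
        Channel(name=c["name"], positions=np.asarray(c["positions_cm"]), step=c["step_cm"])
        for c in doc["channels"]
    ]
    return channels, rois


# ---------------------------------------------------------------------------
# Plan CSV interchange: channel,dwell_index,x_cm,y_cm,z_cm,time_s
# ---------------------------------------------------------------------------


def write_plan_csv(plan: Plan, path) -> None:
    rows = []
    for ch, times in zip(plan.channels, plan.dwell_times):
        for n, (pos, t) in enumerate(zip(ch.positions, times)):
            rows.append((ch.name, n, pos[0], pos[1], pos[2], t))
    frame = pd.DataFrame(
        rows, columns=["channel", "dwell_index", "x_cm", "y_cm", "z_cm", "time_s"]
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_plan_csv(path) -> Plan:
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise InputError(f"plan file not found: {path}") from None
    required = {"channel", "dwell_index", "x_cm", "y_cm", "z_cm", "time_s"}
    if not required.issubset(frame.columns):
        raise InputError(f"plan CSV missing columns {sorted(required - set(frame.columns))}")
    channels, times = [], []
    for name, block in frame.groupby("channel", sort=False):
        block = block.sort_values("dwell_index")
        channels.append(
            Channel(name=str(name), positions=block[["x_cm", "y_cm", "z_cm"]].to_numpy())
        )
        times.append(block["time_s"].to_numpy())
    return Plan(tuple(channels), tuple(times))
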