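"""TG-43 point-source dose engine and dose-kernel assembly.

Dose rate at distance ``r`` from a single HDR source follows the AAPM
TG-43 one-dimensional (point-source) formalism::

    dD/dt (r) = S_K * Lambda * (r0/r)^2 * g(r) * phi_an(r)

where ``S_K`` is the air-kerma strength (U), ``Lambda`` the dose-rate
constant (Gy h^-1 U^-1), ``g(r)`` the radial dose function and
``phi_an(r)`` the 1D anisotropy factor, both tabulated against the
radial distance in cm, with ``r0 = 1 cm`` the reference radius.
The geometry function of a point source, ``1/r^2``, is used; 2D
line-source corrections are out of scope.

The total dose in voxel ``i`` of a stepping-source plan is the linear
superposition over channels ``m`` and dwell positions ``n``::

    D_i = sum_m sum_n d_{m,n,i} * t_{m,n}

with ``d_{m,n,i}`` the dose rate per unit dwell time (Gy/s) collected
into a :class:`DoseKernel` matrix and ``t_{m,n}`` the dwell times in
seconds — the optimization variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputError

SECONDS_PER_HOUR = 3600.0

__all__ = [
    "SourceModel",
    "DoseKernel",
    "radial_dose",
    "anisotropy",
    "dose_rate_at_point",
    "build_dose_kernel",
    "total_dose",
    "read_source_csv",
    "write_source_csv",
]


@dataclass(frozen=True)
class SourceModel:
    """TG-43 point-source parameters and lookup tables.

    Parameters
    ----------
    dose_rate_constant : float
        Lambda, in Gy h^-1 U^-1.
    air_kerma_strength : float
        S_K, in U (1 U = 1 uGy m^2 h^-1).
    radial_dose_table : ndarray, shape (k, 2)
        Columns (r in cm, g(r)); r strictly increasing; g(r0) = 1.
    anisotropy_table : ndarray, shape (k, 2)
        Columns (r in cm, phi_an(r)); r strictly increasing.
    r_min : float
        Near-source clamp in cm; distances below this are treated as
        ``r_min`` to keep the 1/r^2 kernel finite on the dose grid.
    r_max : float
        Table extent in cm; larger radii clamp to the last table row.
    reference_radius : float
        r0, the TG-43 normalization radius (1.0 cm).
    """

    dose_rate_constant: float
    air_kerma_strength: float
    radial_dose_table: np.ndarray
    anisotropy_table: np.ndarray
    r_min: float = 0.1
    r_max: float = 10.0
    reference_radius: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "radial_dose_table", np.asarray(self.radial_dose_table, dtype=float)
        )
        object.__setattr__(
            self, "anisotropy_table", np.asarray(self.anisotropy_table, dtype=float)
        )
        for label, table in (
            ("radial_dose_table", self.radial_dose_table),
            ("anisotropy_table", self.anisotropy_table),
        ):
            if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] == 0:
                raise ConfigurationError(f"{label} must be a nonempty (k, 2) table")
            if not np.all(np.diff(table[:, 0]) > 0):
                raise ConfigurationError(f"{label} radii must be strictly increasing")
            if not np.all(table[:, 1] > 0):
                raise ConfigurationError(f"{label} values must be positive")
        if self.dose_rate_constant <= 0 or self.air_kerma_strength <= 0:
            raise ConfigurationError("dose_rate_constant and air_kerma_strength must be > 0")
        if not (0 < self.r_min < self.r_max):
            raise ConfigurationError("need 0 < r_min < r_max")
        g0 = float(
            np.interp(
                self.reference_radius,
                self.radial_dose_table[:, 0],
                self.radial_dose_table[:, 1],
            )
        )
        if abs(g0 - 1.0) > 1e-6:
            raise ConfigurationError(
                f"radial dose function must equal 1 at r0={self.reference_radius} cm, got {g0}"
            )


@dataclass(frozen=True)
class DoseKernel:
    """Dose rate per unit dwell time from every dwell to every point.

    ``values[i, j]`` is the dose rate in Gy/s delivered to calculation
    point ``i`` by one second of dwell at the flattened dwell index
    ``j``; ``dwell_index_map[j] = (channel, position)`` recovers the
    (m, n) addressing.
    """

    values: np.ndarray
    dwell_index_map: tuple[tuple[int, int], ...]
    channel_sizes: tuple[int, ...] = field(default=())

    @property
    def point_count(self) -> int:
        return self.values.shape[0]

    @property
    def dwell_count(self) -> int:
        return self.values.shape[1]


def _interp_table(table: np.ndarray, r, r_min: float, r_max: float):
    r = np.clip(np.asarray(r, dtype=float), r_min, r_max)
    return np.interp(r, table[:, 0], table[:, 1])


def radial_dose(source: SourceModel, r):
    """Radial dose function g(r), linearly interpolated with clamping.

    ``r`` is clamped to ``[r_min, r_max]`` before lookup; scalar or
    array input is accepted.
    """
    if np.any(np.asarray(r) <= 0):
        raise InputError("radial distance must be positive")
    return _interp_table(source.radial_dose_table, r, source.r_min, source.r_max)


def anisotropy(source: SourceModel, r):
    """1D anisotropy factor phi_an(r), same lookup contract as g(r)."""
    if np.any(np.asarray(r) <= 0):
        raise InputError("radial distance must be positive")
    return _interp_table(source.anisotropy_table, r, source.r_min, source.r_max)


def _dose_rate_from_distance(source: SourceModel, dist):
    """Gy/s at clamped distance(s) ``dist`` in cm."""
    r = np.maximum(np.asarray(dist, dtype=float), source.r_min)
    g = _interp_table(source.radial_dose_table, r, source.r_min, source.r_max)
    phi = _interp_table(source.anisotropy_table, r, source.r_min, source.r_max)
    rate_per_hour = (
        source.air_kerma_strength
        * source.dose_rate_constant
        * (source.reference_radius / r) ** 2
        * g
        * phi
    )
    return rate_per_hour / SECONDS_PER_HOUR


def dose_rate_at_point(source: SourceModel, dwell_position, calc_point) -> float:
    """Dose rate in Gy per second of dwell at ``calc_point``.

    The source-to-point distance is clamped to ``source.r_min`` so a
    calculation point coincident with a dwell stays finite.
    """
    dwell_position = np.asarray(dwell_position, dtype=float)
    calc_point = np.asarray(calc_point, dtype=float)
    if not (np.all(np.isfinite(dwell_position)) and np.all(np.isfinite(calc_point))):
        raise InputError("coordinates must be finite")
    dist = float(np.linalg.norm(calc_point - dwell_position))
    return float(_dose_rate_from_distance(source, dist))


def build_dose_kernel(source: SourceModel, channels, points) -> DoseKernel:
    """Assemble the (points x dwells) dose-rate matrix.

    Parameters
    ----------
    source : SourceModel
    channels : sequence of Channel
        Ordered implant channels; every channel must hold >= 1 dwell.
    points : ndarray (P, 3) or CalcPointSet
        Calculation points in cm.
    """
    coords = getattr(points, "points", points)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise InputError("need a nonempty (P, 3) array of calculation points")
    if len(channels) == 0:
        raise InputError("need at least one channel")
    index_map: list[tuple[int, int]] = []
    dwell_coords = []
    sizes = []
    for m, channel in enumerate(channels):
        positions = np.asarray(channel.positions, dtype=float)
        if positions.ndim != 2 or positions.shape[0] == 0:
            raise InputError(f"channel {m} has no dwell positions")
        sizes.append(positions.shape[0])
        for n in range(positions.shape[0]):
            index_map.append((m, n))
        dwell_coords.append(positions)
    dwells = np.vstack(dwell_coords)
    # pairwise distances (P, Nd); kept dense — desk-scale problems only
    diff = coords[:, None, :] - dwells[None, :, :]
    dist = np.sqrt(np.einsum("pdk,pdk->pd", diff, diff))
    values = _dose_rate_from_distance(source, dist)
    return DoseKernel(
        values=values,
        dwell_index_map=tuple(index_map),
        channel_sizes=tuple(sizes),
    )


def total_dose(kernel: DoseKernel, times) -> np.ndarray:
    """Superpose dwell contributions: D = kernel @ times, in Gy."""
    times = np.asarray(times, dtype=float)
    if times.shape != (kernel.dwell_count,):
        raise InputError(
            f"times must have shape ({kernel.dwell_count},), got {times.shape}"
        )
    if np.any(times < 0):
        raise InputError("dwell times must be nonnegative")
    return kernel.values @ times


# ---------------------------------------------------------------------------
# Source CSV format: a header block of key,value lines, then two column
# groups introduced by [radial_dose] and [anisotropy] section markers
# with fixed column headers "r_cm,g" and "r_cm,phi_an".
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("dose_rate_constant", "air_kerma_strength", "r_min", "r_max")


def read_source_csv(path) -> SourceModel:
    """Load a :class:`SourceModel` from its CSV interchange format."""
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header: dict[str, float] = {}
    tables: dict[str, list[list[float]]] = {}
    section = None
    expected_cols = {"radial_dose": "r_cm,g", "anisotropy": "r_cm,phi_an"}
    for ln in lines:
        if ln.startswith("[") and ln.endswith("]"):
            section = ln[1:-1]
            if section not in expected_cols:
                raise ConfigurationError(f"unknown source CSV section [{section}]")
            tables[section] = []
            continue
        if section is None:
            key, _, value = ln.partition(",")
            if key not in _HEADER_KEYS:
                raise ConfigurationError(f"unknown source CSV header key {key!r}")
            header[key] = float(value)
        elif ln == expected_cols[section]:
            continue
        else:
            tables[section].append([float(v) for v in ln.split(",")])
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing or "radial_dose" not in tables or "anisotropy" not in tables:
        raise ConfigurationError(f"incomplete source CSV (missing {missing or 'tables'})")
    if not tables["radial_dose"] or not tables["anisotropy"]:
        raise ConfigurationError("source CSV has an empty lookup table")
    return SourceModel(
        dose_rate_constant=header["dose_rate_constant"],
        air_kerma_strength=header["air_kerma_strength"],
        radial_dose_table=np.asarray(tables["radial_dose"]),
        anisotropy_table=np.asarray(tables["anisotropy"]),
        r_min=header["r_min"],
        r_max=header["r_max"],
    )


def write_source_csv(source: SourceModel, path) -> None:
    out = [
        f"dose_rate_constant,{float(source.dose_rate_constant)!r}",
        f"air_kerma_strength,{float(source.air_kerma_strength)!r}",
        f"r_min,{float(source.r_min)!r}",
        f"r_max,{float(source.r_max)!r}",
        "[radial_dose]",
        "r_cm,g",
    ]
    out += [f"{float(r)!r},{float(g)!r}" for r, g in source.radial_dose_table]
    out += ["[anisotropy]", "r_cm,phi_an"]
    out += [f"{float(r)!r},{float(p)!r}" for r, p in source.anisotropy_table]
    Path(path).write_text("\n".join(out) + "\n")
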