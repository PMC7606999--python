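"""Synthetic cervix-implant phantoms for desk-scale testing.

No patient geometry ships with the package; instead this module
generates stylized intracavitary implants — applicator channels with
0.25 cm dwell spacing plus voxelized ROI masks — emulating the scale of
a radical cervix case: an HR-CTV of a few tens of cm³ around the
applicator, with bladder (anterior), rectum (posterior) and sigmoid
(superior) placed close enough that their 4.5 Gy maximum-dose
objectives are active but satisfiable.

The HR-CTV is a randomly perturbed ellipsoid whose radii are iterated
until the voxelized volume is within 5% of the requested volume (exact
volumes are unreachable on a discrete grid).  Applicator shapes are
stylized straight/arc tubes, not vendor-accurate: the optimization
behaviour under study depends only on channel topology and dwell
spacing.  Generation is a pure function of the spec (same seed, same
phantom, bit for bit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .geometry import Channel, Grid, ROIMask, roi_volume
from .objective import DoseGoal, ObjectiveSpec, OptimizerConfig, ROIObjective
from .tg43 import SourceModel, read_source_csv

__all__ = [
    "PhantomSpec",
    "RegressionCase",
    "make_phantom",
    "fixture_source",
    "make_regression_case",
    "APPLICATOR_KINDS",
]

APPLICATOR_KINDS = (
    "fletcher",
    "double_ovoid",
    "tandem_ring",
    "multichannel",
    "tandem_needles",
)

_VOLUME_TOLERANCE = 0.05
DWELL_STEP_CM = 0.25


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic implant."""

    kind: str = "fletcher"
    target_volume: float = 52.65  # cm³, cohort-average HR-CTV scale
    spacing: float = 0.1  # cm, isotropic dose-grid resolution
    margin: float = 0.3  # cm, gap between HR-CTV surface and each OAR
    seed: int = 1

    def __post_init__(self) -> None:
        if self.kind not in APPLICATOR_KINDS:
            raise ConfigurationError(f"kind must be one of {APPLICATOR_KINDS}")
        if self.target_volume <= 0 or self.spacing <= 0:
            raise ConfigurationError("target_volume and spacing must be > 0")


def _line_channel(name: str, start: np.ndarray, direction: np.ndarray, length: float) -> Channel:
    """Straight channel: dwells every 0.25 cm from start along direction."""
    direction = direction / np.linalg.norm(direction)
    n = max(1, int(np.floor(length / DWELL_STEP_CM)) + 1)
    offsets = np.arange(n)[:, None] * DWELL_STEP_CM * direction[None, :]
    return Channel(name=name, positions=start[None, :] + offsets, step=DWELL_STEP_CM)


def _ring_channel(name: str, center: np.ndarray, radius: float) -> Channel:
    """Ring channel: dwells on a circle with 0.25 cm chord spacing."""
    dtheta = 2.0 * np.arcsin(DWELL_STEP_CM / (2.0 * radius))
    n = int(np.floor(2.0 * np.pi / dtheta))
    theta = np.arange(n) * dtheta
    positions = center[None, :] + radius * np.stack(
        [np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1
    )
    return Channel(name=name, positions=positions, step=DWELL_STEP_CM)


def _perturbation(rng: np.random.Generator):
    """Smooth random radial modulation field with ~8% amplitude."""
    amps = rng.uniform(0.03, 0.08, size=3)
    freqs = rng.uniform(0.8, 1.6, size=(3, 3))
    phases = rng.uniform(0, 2 * np.pi, size=3)

    def eps(x, y, z):
        return (
            amps[0] * np.sin(freqs[0, 0] * x + phases[0]) * np.cos(freqs[0, 1] * y)
            + amps[1] * np.sin(freqs[1, 1] * y + phases[1]) * np.cos(freqs[1, 2] * z)
            + amps[2] * np.sin(freqs[2, 2] * z + phases[2]) * np.cos(freqs[2, 0] * x)
        )

    return eps


def _ellipsoid_mask(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _channels_for_kind(kind: str, radii: np.ndarray) -> list[Channel]:
    rx, ry, rz = radii
    up = np.array([0.0, 0.0, 1.0])
    tandem = _line_channel(
        "tandem", np.array([0.0, 0.0, -0.6 * rz]), up, 1.45 * rz
    )
    if kind == "fletcher":
        ovoids = [
            _line_channel(f"ovoid_{side}", np.array([sx * 0.45 * rx, 0.0, -0.85 * rz]), up, 1.0)
            for side, sx in (("left", -1.0), ("right", 1.0))
        ]
        return [tandem] + ovoids
    if kind == "double_ovoid":
        return [
            _line_channel(f"ovoid_{side}", np.array([sx * 0.45 * rx, 0.0, -0.85 * rz]), up, 1.5)
            for side, sx in (("left", -1.0), ("right", 1.0))
        ]
    if kind == "tandem_ring":
        ring = _ring_channel(
            "ring", np.array([0.0, 0.0, -0.55 * rz]), radius=min(1.3, 0.55 * min(rx, ry))
        )
        return [tandem, ring]
    if kind == "multichannel":
        channels = [_line_channel("central", np.array([0.0, 0.0, -0.6 * rz]), up, 1.3 * rz)]
        ring_r = 0.4 * min(rx, ry)
        for k in range(6):
            ang = 2 * np.pi * k / 6
            start = np.array([ring_r * np.cos(ang), ring_r * np.sin(ang), -0.6 * rz])
            channels.append(_line_channel(f"peripheral_{k}", start, up, 1.1 * rz))
        return channels
    if kind == "tandem_needles":
        channels = [tandem]
        for k, (sx, sy) in enumerate([(1, 1), (1, -1), (-1, 1), (-1, -1)]):
            start = np.array([sx * 0.55 * rx, sy * 0.45 * ry, -0.7 * rz])
            channels.append(_line_channel(f"needle_{k}", start, up, 1.1 * rz))
        return channels
    raise ConfigurationError(f"unknown applicator kind {kind!r}")


def make_phantom(spec: PhantomSpec):
    """Generate ``(channels, rois)`` for the given spec.

    The HR-CTV volume is brought within ±5% of ``spec.target_volume``
    by iteratively rescaling the perturbed-ellipsoid radii; OAR masks
    are carved to exclude any HR-CTV voxel.
    """
    rng = np.random.default_rng(spec.seed)
    eps = _perturbation(rng)
    # near-spherical base shape, mildly anisotropic
    aspect = np.array([1.0, 0.95, 1.1])
    # OAR nominal centers/radii drawn before the scaling loop so the
    # stream of random draws is independent of iteration count
    oar_jitter = rng.uniform(-0.1, 0.1, size=(3, 3))

    base = (spec.target_volume / (4.0 / 3.0 * np.pi * np.prod(aspect))) ** (1.0 / 3.0)
    radii = base * aspect
    s = spec.spacing

    oar_semis = {
        "bladder": np.array([2.0, 1.4, 2.0]),
        "rectum": np.array([1.4, 1.2, 2.4]),
        "sigmoid": np.array([1.5, 1.4, 1.3]),
    }

    def oar_centers(radii):
        m = spec.margin
        return {
            "bladder": np.array([0.0, radii[1] + m + oar_semis["bladder"][1], 0.8])
            + oar_jitter[0],
            "rectum": np.array([0.0, -(radii[1] + m + oar_semis["rectum"][1]), -0.3])
            + oar_jitter[1],
            "sigmoid": np.array([0.4, 0.6, radii[2] + m + oar_semis["sigmoid"][2]])
            + oar_jitter[2],
        }

    def build_grid(radii):
        lo = -1.25 * radii
        hi = 1.25 * radii
        centers = oar_centers(radii)
        for name, c in centers.items():
            lo = np.minimum(lo, c - oar_semis[name] - 0.2)
            hi = np.maximum(hi, c + oar_semis[name] + 0.2)
        origin = np.floor(lo / s) * s
        dims = np.ceil((hi - origin) / s).astype(int) + 1
        return Grid(tuple(origin), (s, s, s), tuple(int(d) for d in dims))

    def target_mask(grid, radii):
        ax = [
            grid.origin[a] + np.arange(grid.dims[a]) * s for a in range(3)
        ]
        x, y, z = np.meshgrid(*ax, indexing="ij")
        u = (x / radii[0]) ** 2 + (y / radii[1]) ** 2 + (z / radii[2]) ** 2
        return u <= (1.0 + eps(x, y, z)) ** 2

    # iterate radii until the voxelized volume lands within tolerance
    for _ in range(12):
        grid = build_grid(radii)
        occ = target_mask(grid, radii)
        vol = occ.sum() * grid.voxel_volume
        if vol == 0:
            raise ConfigurationError("target volume unreachable on this grid")
        ratio = spec.target_volume / vol
        if abs(ratio - 1.0) <= 0.01:
            break
        radii = radii * ratio ** (1.0 / 3.0)
    else:
        if abs(vol / spec.target_volume - 1.0) > _VOLUME_TOLERANCE:
            raise ConfigurationError(
                f"could not voxelize target volume {spec.target_volume} cm³ "
                f"on a {s} cm grid (got {vol:.2f} cm³)"
            )

    ax = [grid.origin[a] + np.arange(grid.dims[a]) * s for a in range(3)]
    coords = np.meshgrid(*ax, indexing="ij")
    rois = [ROIMask(name="hrctv", role="target", grid=grid, occupancy=occ)]
    centers = oar_centers(radii)
    for name in ("bladder", "rectum", "sigmoid"):
        mask = _ellipsoid_mask(coords, centers[name], oar_semis[name]) & ~occ
        if not mask.any():
            raise ConfigurationError(f"OAR {name!r} fell outside the grid")
        rois.append(ROIMask(name=name, role="oar", grid=grid, occupancy=mask))

    channels = _channels_for_kind(spec.kind, radii)
    return channels, rois


_FIXTURE_CSV = Path(__file__).parent / "data" / "ir192_synthetic.csv"


def fixture_source() -> SourceModel:
    """The packaged synthetic Ir-192-like source characterization."""
    if not _FIXTURE_CSV.is_file():
        raise ConfigurationError(f"missing packaged source data: {_FIXTURE_CSV}")
    return read_source_csv(_FIXTURE_CSV)


@dataclass(frozen=True)
class RegressionCase:
    """The canonical benchmark bundle: Fletcher implant, standard objectives.

    Objectives are the cervix planning defaults — HR-CTV minimum 6.0 Gy
    (weight 100); bladder maximum 4.5 Gy (weight 50); rectum and
    sigmoid maximum 4.5 Gy (weight 80 each) — with DTMF 10, 100
    iterations and a 6 Gy prescription.
    """

    channels: tuple[Channel, ...]
    rois: tuple[ROIMask, ...]
    objectives: ObjectiveSpec
    config: OptimizerConfig
    prescription: float
    source: SourceModel = field(repr=False, default=None)
    target_roi: str = "hrctv"


def standard_objectives() -> ObjectiveSpec:
    """Cervix HDR planning objectives (dose in Gy, dimensionless weights)."""
    return ObjectiveSpec(
        (
            ROIObjective("hrctv", "target", minimum=DoseGoal(6.0, 100.0)),
            ROIObjective("bladder", "oar", maximum=DoseGoal(4.5, 50.0)),
            ROIObjective("rectum", "oar", maximum=DoseGoal(4.5, 80.0)),
            ROIObjective("sigmoid", "oar", maximum=DoseGoal(4.5, 80.0)),
        )
    )


def make_regression_case() -> RegressionCase:
    """Deterministic benchmark: Fletcher phantom at the cohort-mean volume."""
    spec = PhantomSpec(kind="fletcher", target_volume=52.65, spacing=0.1, seed=1)
    channels, rois = make_phantom(spec)
    return RegressionCase(
        channels=tuple(channels),
        rois=tuple(rois),
        objectives=standard_objectives(),
        config=OptimizerConfig(dtmf=10.0, max_iterations=100),
        prescription=6.0,
        source=fixture_source(),
    )
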