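"""Quadratic one-sided dose objective with dwell-time modulation.

The plan cost minimized by the optimizer is

    F(t) =   sum_{i in TAR}  p_TAR  * H_TAR(D_i - D0_TAR)  * (D_i - D0_TAR)^2
           + sum_{i in OARs} p_OARs * H_OARs(D_i - D0_OARs) * (D_i - D0_OARs)^2
           + p_SOU * sum_m sum_n (1/N_n(m)) * (t_{m,n} - t_{m,min})^2

where H is a one-sided Heaviside switch: a target's minimum-dose
objective penalizes voxels with D_i <= D0 (H = 1 there, 0 above), an
OAR's maximum-dose objective penalizes D_i >= D0.  At exact equality
the switch is on but the squared term vanishes, so the choice is value-
and gradient-neutral.  The last term is the dwell time modulation
penalty: p_SOU is the DTMF, and anchoring at each channel's *minimum*
dwell time t_{m,min} (rather than the channel mean) shrinks long dwells
without forcing short ones up, so positions that should barely dwell
keep their small times.

Each ROI may carry a minimum objective, a maximum objective, or both;
targets must have a minimum and OARs a maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputError
from .geometry import CalcPointSet, Plan, flatten_times
from .tg43 import DoseKernel

__all__ = [
    "DoseGoal",
    "ROIObjective",
    "ObjectiveSpec",
    "OptimizerConfig",
    "roi_penalty",
    "dwell_time_modulation_term",
    "objective_value",
    "objective_gradient",
]


@dataclass(frozen=True)
class DoseGoal:
    """One dose objective: threshold D0 in Gy and penalty weight p."""

    dose: float
    weight: float

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ConfigurationError("objective dose must be > 0 Gy")
        if self.weight < 0:
            raise ConfigurationError("penalty weight must be >= 0")


@dataclass(frozen=True)
class ROIObjective:
    roi: str
    role: str  # 'target' or 'oar'
    minimum: DoseGoal | None = None
    maximum: DoseGoal | None = None

    def __post_init__(self) -> None:
        if self.role == "target" and self.minimum is None:
            raise ConfigurationError(f"target {self.roi!r} needs a minimum-dose objective")
        if self.role == "oar" and self.maximum is None:
            raise ConfigurationError(f"OAR {self.roi!r} needs a maximum-dose objective")
        if self.role not in ("target", "oar"):
            raise ConfigurationError(f"role must be 'target' or 'oar', got {self.role!r}")


@dataclass(frozen=True)
class ObjectiveSpec:
    """Per-ROI dose objectives, the clinical input of inverse planning."""

    rois: tuple[ROIObjective, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(self.rois))
        if not self.rois:
            raise ConfigurationError("objective spec needs at least one ROI")

    def scaled_weights(self, factor: float) -> "ObjectiveSpec":
        """All penalty weights multiplied by ``factor`` (F is linear in them)."""

        def scale(goal):
            return None if goal is None else replace(goal, weight=goal.weight * factor)

        return ObjectiveSpec(
            tuple(
                replace(e, minimum=scale(e.minimum), maximum=scale(e.maximum))
                for e in self.rois
            )
        )

    @classmethod
    def from_json(cls, path) -> "ObjectiveSpec":
        try:
            doc = json.loads(Path(path).read_text())
        except FileNotFoundError:
            raise InputError(f"objective spec file not found: {path}") from None
        entries = []
        for row in doc["rois"]:
            minimum = (
                DoseGoal(row["min_dose_gy"], row["min_weight"])
                if row.get("min_dose_gy") is not None
                else None
            )
            maximum = (
                DoseGoal(row["max_dose_gy"], row["max_weight"])
                if row.get("max_dose_gy") is not None
                else None
            )
            entries.append(
                ROIObjective(roi=row["roi"], role=row["role"], minimum=minimum, maximum=maximum)
            )
        return cls(tuple(entries))

    def to_json(self, path) -> None:
        doc = {
            "rois": [
                {
                    "roi": e.roi,
                    "role": e.role,
                    "min_dose_gy": e.minimum.dose if e.minimum else None,
                    "min_weight": e.minimum.weight if e.minimum else None,
                    "max_dose_gy": e.maximum.dose if e.maximum else None,
                    "max_weight": e.maximum.weight if e.maximum else None,
                }
                for e in self.rois
            ]
        }
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings of the bounded quasi-Newton dwell-time optimization.

    ``dtmf`` is p_SOU, the dwell time modulation factor — any
    nonnegative float, deliberately not normalized to [0, 1] so the
    modulation range can be matched to the clinical site.  The lower
    bound of 1e-6 s keeps dwell times strictly positive during the
    search; every dwell starts at 1 s and at most ``max_iterations``
    outer quasi-Newton iterations are taken.
    """

    dtmf: float = 10.0
    max_iterations: int = 100
    lower_bound: float = 1e-6
    initial_time: float = 1.0

    def __post_init__(self) -> None:
        if self.dtmf < 0:
            raise ConfigurationError("dtmf must be >= 0")
        if self.lower_bound <= 0:
            raise ConfigurationError("lower_bound must be > 0")
        if self.initial_time < self.lower_bound:
            raise ConfigurationError("initial_time must be >= lower_bound")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


def roi_penalty(doses: np.ndarray, entry: ROIObjective) -> float:
    """One ROI's contribution: sum_i p * H * (D_i - D0)^2 over its voxels."""
    doses = np.asarray(doses, dtype=float)
    total = 0.0
    if entry.minimum is not None:
        low = doses <= entry.minimum.dose
        total += entry.minimum.weight * float(
            np.sum((doses[low] - entry.minimum.dose) ** 2)
        )
    if entry.maximum is not None:
        high = doses >= entry.maximum.dose
        total += entry.maximum.weight * float(
            np.sum((doses[high] - entry.maximum.dose) ** 2)
        )
    return total


def _channel_slices(channel_sizes) -> list[slice]:
    bounds = np.concatenate(([0], np.cumsum(channel_sizes)))
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def dwell_time_modulation_term(plan: Plan, p_sou: float) -> float:
    """DTMF penalty of a plan: p_SOU * sum_m mean_n (t_{m,n} - t_{m,min})^2."""
    times = flatten_times(plan)
    sizes = [len(ch) for ch in plan.channels]
    return _modulation_value(times, sizes, p_sou)


def _modulation_value(times: np.ndarray, channel_sizes, p_sou: float) -> float:
    total = 0.0
    for sl in _channel_slices(channel_sizes):
        t = times[sl]
        total += float(np.sum((t - t.min()) ** 2)) / t.size
    return p_sou * total


def _modulation_gradient(times: np.ndarray, channel_sizes, p_sou: float) -> np.ndarray:
    grad = np.zeros_like(times)
    if p_sou == 0:
        return grad
    for sl in _channel_slices(channel_sizes):
        t = times[sl]
        k = int(np.argmin(t))  # first minimizer wins ties
        dev = t - t[k]
        g = (2.0 * p_sou / t.size) * dev
        g[k] = -(2.0 * p_sou / t.size) * float(dev.sum())
        grad[sl] = g
    return grad


def _point_multiplicity(points: CalcPointSet, roi: str) -> float:
    """Grid voxels represented by each sampled point of a ROI.

    Penalties sum over the full dose grid; when calculation points are
    subsampled, each sampled point stands in for ``1/f`` voxels, so its
    penalty is weighted accordingly — the subsampled objective is then
    an unbiased estimate of the full-grid objective and the balance
    against the dwell-time modulation term is preserved.  Exactly 1 for
    exhaustive sampling or hand-built point sets.
    """
    volume = points.roi_point_volume.get(roi)
    if volume is None:
        return 1.0
    return volume / points.voxel_volume


def _dose_residual_weights(
    doses: np.ndarray, points: CalcPointSet, spec: ObjectiveSpec
) -> np.ndarray:
    """Per-point mult * p * H * (D - D0), summed over the objectives covering it."""
    w = np.zeros_like(doses)
    for entry in spec.rois:
        if entry.roi not in points.roi_membership:
            raise InputError(f"objective ROI {entry.roi!r} has no calculation points")
        idx = points.roi_membership[entry.roi]
        mult = _point_multiplicity(points, entry.roi)
        d = doses[idx]
        if entry.minimum is not None:
            np.add.at(w, idx, mult * entry.minimum.weight * (d <= entry.minimum.dose) * (d - entry.minimum.dose))
        if entry.maximum is not None:
            np.add.at(w, idx, mult * entry.maximum.weight * (d >= entry.maximum.dose) * (d - entry.maximum.dose))
    return w


def objective_value(
    times: np.ndarray,
    kernel: DoseKernel,
    points: CalcPointSet,
    spec: ObjectiveSpec,
    config: OptimizerConfig,
) -> float:
    """Evaluate F(t): dose penalties plus the DTMF term.  Always >= 0."""
    times = np.asarray(times, dtype=float)
    if times.shape != (kernel.dwell_count,):
        raise InputError(f"times must have shape ({kernel.dwell_count},)")
    doses = kernel.values @ times
    total = 0.0
    for entry in spec.rois:
        if entry.roi not in points.roi_membership:
            raise InputError(f"objective ROI {entry.roi!r} has no calculation points")
        mult = _point_multiplicity(points, entry.roi)
        total += mult * roi_penalty(doses[points.roi_membership[entry.roi]], entry)
    total += _modulation_value(times, kernel.channel_sizes, config.dtmf)
    return total


def objective_gradient(
    times: np.ndarray,
    kernel: DoseKernel,
    points: CalcPointSet,
    spec: ObjectiveSpec,
    config: OptimizerConfig,
) -> np.ndarray:
    """Analytic gradient dF/dt_{m,n}.

    Dose terms contribute 2 * K^T (p * H * (D - D0)); the modulation
    term is differentiated with the per-channel argmin frozen at the
    evaluation point, including the coupling through the minimizing
    coordinate.  Exact wherever F is differentiable (everywhere except
    Heaviside switching surfaces and within-channel min ties, which are
    measure-zero).
    """
    times = np.asarray(times, dtype=float)
    if times.shape != (kernel.dwell_count,):
        raise InputError(f"times must have shape ({kernel.dwell_count},)")
    doses = kernel.values @ times
    w = _dose_residual_weights(doses, points, spec)
    grad = 2.0 * (kernel.values.T @ w)
    grad += _modulation_gradient(times, kernel.channel_sizes, config.dtmf)
    return grad
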