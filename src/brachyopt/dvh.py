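"""Cumulative DVH metrics, plan normalization and dwell-time statistics.

Metrics follow the clinical conventions of image-guided brachytherapy:

* ``D_x%`` — the dose in Gy received by (at least) x% of the structure
  volume,
* ``V_y%`` — the percentage of the structure volume receiving at least
  y% of the prescription dose,
* ``D_zcc`` — the dose received by the hottest z cm³ of the structure.

All three are read from the empirical descending-sorted dose list with
``>=`` threshold comparisons and no interpolation: ``D_x%`` is the dose
of the point at the smallest cumulative volume >= x%.  On a 0.1 cm dose
grid the sub-voxel differences against interpolated DVHs are
negligible, and the empirical form is exactly checkable against a
brute-force oracle.

Plans are reported after normalization: all dwell times are scaled by
one factor so the target's D90% equals the prescription dose (6 Gy
default), the standard reporting condition in cervix HDR brachytherapy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegeneratePlanError, InputError
from .geometry import Plan, flatten_times
from .objective import OptimizerConfig, ObjectiveSpec
from .tg43 import DoseKernel, SourceModel

_log = logging.getLogger("brachyopt")

__all__ = [
    "DVHCurve",
    "PlanQualityReport",
    "dose_at_volume_percent",
    "volume_percent_at_dose",
    "dose_at_absolute_volume",
    "normalize_to_d90",
    "dtsd",
    "dtmf_sweep",
    "quality_report",
]


@dataclass(frozen=True)
class DVHCurve:
    """Per-point doses of one ROI with the volume each point represents.

    ``point_volume`` is cm³ per calculation point (equal weighting);
    ``prescription`` in Gy anchors the V_y% metrics.
    """

    roi: str
    doses: np.ndarray
    point_volume: float
    prescription: float | None = None

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        if doses.ndim != 1 or doses.size == 0:
            raise InputError("DVH curve needs a nonempty 1D dose vector")
        if np.any(doses < 0) or not np.all(np.isfinite(doses)):
            raise InputError("doses must be finite and nonnegative")
        if self.point_volume <= 0:
            raise InputError("point_volume must be > 0")
        object.__setattr__(self, "doses", doses)

    @property
    def total_volume(self) -> float:
        return self.doses.size * self.point_volume


def dose_at_volume_percent(curve: DVHCurve, x: float) -> float:
    """D_x%: largest dose d with at least x% of the volume receiving >= d."""
    if not (0 < x <= 100):
        raise InputError("x must be in (0, 100]")
    d = np.sort(curve.doses)[::-1]
    # cumulative volume fraction after the k-th hottest point is (k+1)/N
    k = int(np.ceil(x / 100.0 * d.size)) - 1
    return float(d[k])


def volume_percent_at_dose(curve: DVHCurve, y: float) -> float:
    """V_y%: percent of the volume receiving >= y% of the prescription."""
    if y <= 0:
        raise InputError("y must be > 0")
    if curve.prescription is None:
        raise InputError("V_y% requires the curve's prescription dose")
    threshold = y / 100.0 * curve.prescription
    return 100.0 * float(np.count_nonzero(curve.doses >= threshold)) / curve.doses.size


def dose_at_absolute_volume(curve: DVHCurve, z: float) -> float:
    """D_zcc: largest dose d with at least z cm³ receiving >= d."""
    if not (0 < z <= curve.total_volume):
        raise InputError(f"z must be in (0, {curve.total_volume}] cm³")
    d = np.sort(curve.doses)[::-1]
    k = int(np.ceil(z / curve.point_volume)) - 1
    k = min(k, d.size - 1)
    return float(d[k])


def normalize_to_d90(plan: Plan, kernel: DoseKernel, target_curve: DVHCurve):
    """Scale all dwell times so the target's D90% equals the prescription.

    Dose is linear in the dwell times, so one global factor
    prescription / D90% restores the reporting condition exactly.
    Returns ``(scaled_plan, factor)``.
    """
    if target_curve.prescription is None:
        raise InputError("normalization requires the prescription dose")
    d90 = dose_at_volume_percent(target_curve, 90.0)
    if d90 <= 0:
        raise DegeneratePlanError("target D90% is zero; plan delivers no dose")
    factor = target_curve.prescription / d90
    return plan.scaled(factor), factor


def dtsd(plan: Plan) -> float:
    """Dwell time standard deviation: population SD pooled over all dwells."""
    times = flatten_times(plan)
    return float(np.std(times))


def dtmf_sweep(channels, rois, objectives: ObjectiveSpec, dtmf_values,
               source: SourceModel, config: OptimizerConfig | None = None,
               subsample_fraction: float = 1.0, seed: int = 0):
    """Optimize the same implant once per DTMF value; return (dtmf, DTSD) pairs.

    The kernel and calculation points are built once and shared, so the
    sweep isolates the effect of the modulation weight.  DTSD is taken
    on the un-normalized optimized plan.
    """
    from dataclasses import replace as _replace

    from .model import DwellTimeModel

    dtmf_values = list(dtmf_values)
    if len(dtmf_values) < 2:
        raise InputError("need at least two DTMF values")
    if any(v < 0 for v in dtmf_values):
        raise InputError("DTMF values must be nonnegative")
    base = config or OptimizerConfig()
    model = DwellTimeModel.from_phantom(
        channels, rois, objectives, source, config=base,
        subsample_fraction=subsample_fraction, seed=seed,
    )
    out = []
    for value in dtmf_values:
        result = model.fit(config=_replace(base, dtmf=float(value)))
        _log.info("DTMF %g: final objective %.8g, DTSD %.4g s",
                  value, result.fun, dtsd(result.plan))
        out.append((float(value), dtsd(result.plan)))
    return out


@dataclass(frozen=True)
class PlanQualityReport:
    """Per-ROI DVH metrics of a normalized plan plus dwell-time statistics.

    ``metrics`` maps (roi, metric-name) to a value: Gy for D metrics,
    percent for V metrics.  ``dtsd_s`` is computed on the un-normalized
    plan; ``normalization_factor`` is the global dwell-time scale that
    set the target's D90% to the prescription.
    """

    metrics: dict[tuple[str, str], float]
    dtsd_s: float
    normalization_factor: float
    prescription: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"roi": roi, "metric": metric, "value_gy_or_pct": value}
            for (roi, metric), value in self.metrics.items()
        ]
        return pd.DataFrame(rows, columns=["roi", "metric", "value_gy_or_pct"])

    def __str__(self) -> str:
        frame = self.to_frame()
        return (
            frame.to_string(index=False)
            + f"\n\nDTSD: {self.dtsd_s:.4g} s"
            + f"\nnormalization factor: {self.normalization_factor:.6g}"
        )


_TARGET_METRICS = (("D_100%", 100.0), ("D_90%", 90.0))
_OAR_VOLUMES_CC = (("D_0.1cc", 0.1), ("D_1cc", 1.0), ("D_2cc", 2.0))


def quality_report(results, target_roi: str, prescription: float) -> PlanQualityReport:
    """Normalize a fitted plan and tabulate the standard reporting metrics.

    Target: D_100%, D_90% and V_150%; each OAR: D_0.1cc, D_1cc, D_2cc,
    clipped to the structure volume when a structure is smaller than
    the nominal hot-volume.
    """
    spread = dtsd(results.plan)
    normalized, factor = results.normalized(target_roi, prescription)
    metrics: dict[tuple[str, str], float] = {}
    for roi in results.model.points.roi_membership:
        curve = normalized.dvh(roi, prescription)
        if roi == target_roi:
            for name, x in _TARGET_METRICS:
                metrics[(roi, name)] = dose_at_volume_percent(curve, x)
            metrics[(roi, "V_150%")] = volume_percent_at_dose(curve, 150.0)
        else:
            for name, z in _OAR_VOLUMES_CC:
                metrics[(roi, name)] = dose_at_absolute_volume(
                    curve, min(z, curve.total_volume)
                )
    return PlanQualityReport(
        metrics=metrics,
        dtsd_s=spread,
        normalization_factor=factor,
        prescription=prescription,
    )
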