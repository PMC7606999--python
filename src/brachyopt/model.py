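"""Dwell-time optimization model and its fitted results.

:class:`DwellTimeModel` bundles the dose kernel, calculation points and
clinical objectives of one implant; ``fit()`` runs a bound-constrained
limited-memory quasi-Newton (L-BFGS-B) minimization of the quadratic
objective over the dwell times and returns a :class:`DwellTimeResults`
carrying the optimized plan, the objective trace and plan-quality
diagnostics.  The interface follows the model/results convention of
statistical modelling packages: the model is immutable input, the
results object owns everything derived from a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .errors import InputError
from .geometry import CalcPointSet, Plan, sample_calc_points, unflatten_times
from .objective import ObjectiveSpec, OptimizerConfig, objective_gradient, objective_value
from .tg43 import DoseKernel, SourceModel, build_dose_kernel

__all__ = ["DwellTimeModel", "DwellTimeResults"]


class DwellTimeModel:
    """Inverse-planning problem: find dwell times minimizing the objective.

    Parameters
    ----------
    kernel : DoseKernel
        Dose rate per unit dwell time, Gy/s, (points x dwells).
    points : CalcPointSet
        Calculation points with per-ROI membership.
    objectives : ObjectiveSpec
        Min/max dose objectives and penalty weights per ROI.
    channels : sequence of Channel
        The implant geometry the kernel was built from (used to shape
        per-channel dwell-time vectors in results).
    config : OptimizerConfig, optional
        DTMF, iteration budget, bound and initial time.
    """

    def __init__(self, kernel: DoseKernel, points: CalcPointSet, objectives: ObjectiveSpec,
                 channels, config: OptimizerConfig | None = None):
        self.kernel = kernel
        self.points = points
        self.objectives = objectives
        self.channels = tuple(channels)
        self.config = config or OptimizerConfig()
        if sum(len(ch) for ch in self.channels) != kernel.dwell_count:
            raise InputError("channel dwell counts do not match the kernel")

    @classmethod
    def from_phantom(cls, channels, rois, objectives: ObjectiveSpec, source: SourceModel,
                     config: OptimizerConfig | None = None,
                     subsample_fraction: float = 1.0, seed: int = 0) -> "DwellTimeModel":
        """Build kernel and calc points directly from a phantom geometry."""
        points = sample_calc_points(rois, subsample_fraction=subsample_fraction, seed=seed)
        kernel = build_dose_kernel(source, channels, points)
        return cls(kernel, points, objectives, channels, config)

    # -- objective surface -------------------------------------------------

    def objective(self, times: np.ndarray) -> float:
        return objective_value(times, self.kernel, self.points, self.objectives, self.config)

    def gradient(self, times: np.ndarray) -> np.ndarray:
        return objective_gradient(times, self.kernel, self.points, self.objectives, self.config)

    # -- fitting -----------------------------------------------------------

    def fit(self, config: OptimizerConfig | None = None) -> "DwellTimeResults":
        """Minimize the objective over t >= lower_bound.

        Uses L-BFGS-B with the analytic gradient; at most
        ``config.max_iterations`` outer iterations, stopping earlier
        only when the projected gradient norm falls below 1e-8.  The
        recorded objective trace (initial point plus each accepted
        iterate) is non-increasing by the monotone line-search
        contract of the solver.  Deterministic for fixed inputs.
        """
        cfg = config or self.config
        if config is not None and config is not self.config:
            model = DwellTimeModel(self.kernel, self.points, self.objectives,
                                   self.channels, config)
            return model.fit()
        t0 = np.full(self.kernel.dwell_count, cfg.initial_time)
        f0 = self.objective(t0)
        if not np.isfinite(f0):
            raise InputError("objective is non-finite at the initial point")
        trace = [f0]

        def callback(xk):
            trace.append(self.objective(xk))

        res = minimize(
            self.objective,
            t0,
            jac=self.gradient,
            method="L-BFGS-B",
            bounds=[(cfg.lower_bound, None)] * t0.size,
            callback=callback,
            # factr pinned low so the iteration budget / gradient norm govern stopping
            options={"maxiter": cfg.max_iterations, "gtol": 1e-8, "ftol": 1e-16,
                     "maxls": 50},
        )
        times = np.maximum(res.x, cfg.lower_bound)
        plan = unflatten_times(self.channels, times)
        at_bound = np.flatnonzero(times <= cfg.lower_bound)
        return DwellTimeResults(
            model=self,
            plan=plan,
            objective_trace=np.asarray(trace),
            fun=float(self.objective(times)),
            n_iterations=int(res.nit),
            active_bound_indices=at_bound,
            config=cfg,
        )


@dataclass(frozen=True)
class DwellTimeResults:
    """Fitted dwell times plus fit diagnostics.

    Attributes
    ----------
    plan : Plan
        Optimized per-channel dwell times, seconds (un-normalized).
    objective_trace : ndarray
        Objective value at the start and after each accepted iteration.
    fun : float
        Final objective value F.
    n_iterations : int
        Outer quasi-Newton iterations taken.
    active_bound_indices : ndarray
        Flat dwell indices pinned at the lower bound.
    """

    model: DwellTimeModel
    plan: Plan
    objective_trace: np.ndarray
    fun: float
    n_iterations: int
    active_bound_indices: np.ndarray
    config: OptimizerConfig

    @property
    def dwell_times(self) -> np.ndarray:
        from .geometry import flatten_times

        return flatten_times(self.plan)

    def doses(self, roi: str | None = None) -> np.ndarray:
        """Dose in Gy at the model's calculation points (optionally one ROI)."""
        d = self.model.kernel.values @ self.dwell_times
        if roi is None:
            return d
        if roi not in self.model.points.roi_membership:
            raise InputError(f"unknown ROI {roi!r}")
        return d[self.model.points.roi_membership[roi]]

    def dvh(self, roi: str, prescription: float | None = None):
        """Cumulative-DVH curve object for one ROI."""
        from .dvh import DVHCurve

        return DVHCurve(
            roi=roi,
            doses=self.doses(roi),
            point_volume=self.model.points.roi_point_volume[roi],
            prescription=prescription,
        )

    def normalized(self, target_roi: str, prescription: float) -> tuple["DwellTimeResults", float]:
        """Rescale dwell times so the target's D90% equals the prescription.

        Returns the rescaled results and the scalar factor applied.
        """
        from .dvh import normalize_to_d90

        plan, factor = normalize_to_d90(
            self.plan, self.model.kernel, self.dvh(target_roi, prescription)
        )
        return replace(self, plan=plan, fun=float("nan")), factor

    def dtsd(self) -> float:
        """Pooled population SD of all dwell times, seconds."""
        from .dvh import dtsd

        return dtsd(self.plan)

    def quality_report(self, target_roi: str, prescription: float):
        """Normalize to D90% = prescription and tabulate the DVH metrics."""
        from .dvh import quality_report

        return quality_report(self, target_roi, prescription)

    def plot_dvh(self, prescription: float | None = None, ax=None):
        """Cumulative DVH (% volume vs dose in Gy) for every ROI."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for roi in self.model.points.roi_membership:
            d = np.sort(self.doses(roi))[::-1]
            frac = 100.0 * np.arange(1, d.size + 1) / d.size
            ax.plot(d, frac, label=roi)
        if prescription is not None:
            ax.axvline(prescription, ls="--", color="gray", lw=0.8)
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("volume (%)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Dwell-time optimization results",
            "===============================",
            f"channels: {len(self.plan.channels)}   dwells: {self.plan.dwell_count}   "
            f"calc points: {self.model.kernel.point_count}",
            f"iterations: {self.n_iterations}   final objective F: {self.fun:.6g}",
            f"dwell times (s): min {self.dwell_times.min():.4g}, "
            f"max {self.dwell_times.max():.4g}, DTSD {self.dtsd():.4g}",
            f"dwells at lower bound: {self.active_bound_indices.size}",
            f"DTMF (p_SOU): {self.config.dtmf}",
        ]
        return "\n".join(lines)
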