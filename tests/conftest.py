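import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import brachyopt as b

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_source():
    """Pure inverse-square source: g == phi_an == 1, S_K*Lambda = 3600 Gy/h.

    Dose rate is exactly (1/r^2) Gy/s for r in [r_min, r_max].
    """
    r = np.array([0.1, 1.0, 5.0, 10.0])
    ones = np.ones_like(r)
    return b.SourceModel(
        dose_rate_constant=1.0,
        air_kerma_strength=3600.0,
        radial_dose_table=np.column_stack([r, ones]),
        anisotropy_table=np.column_stack([r, ones]),
    )


@pytest.fixture(scope="session")
def toy_source():
    """Small hand-checkable lookup tables; g(1 cm) = 1 by construction."""
    g = np.array([[0.1, 0.90], [0.5, 0.96], [1.0, 1.00], [2.0, 0.92], [3.0, 0.84], [5.0, 0.70]])
    phi = np.array([[0.1, 0.80], [0.5, 0.90], [1.0, 0.95], [2.0, 0.96], [3.0, 0.97], [5.0, 0.98]])
    return b.SourceModel(
        dose_rate_constant=1.0,
        air_kerma_strength=3600.0,
        radial_dose_table=g,
        anisotropy_table=phi,
        r_min=0.1,
        r_max=5.0,
    )


@pytest.fixture(scope="session")
def regression_case():
    return b.make_regression_case()


@pytest.fixture(scope="session")
def regression_fit(regression_case):
    """One optimization of the benchmark Fletcher case at 10% sampling."""
    case = regression_case
    model = b.DwellTimeModel.from_phantom(
        case.channels, case.rois, case.objectives, case.source,
        config=case.config, subsample_fraction=0.1, seed=7,
    )
    return model.fit()


def random_instance(rng, n_channels=None, max_dwells=20, max_points=200):
    """A small random optimization problem away from objective kinks.

    Returns (kernel, points, spec, times) with dwell times separated
    within each channel (no min ties) and objective thresholds at least
    1e-2 Gy from every dose (no Heaviside switching within finite-
    difference reach).
    """
    n_channels = n_channels or rng.integers(1, 4)
    sizes = rng.integers(1, max(2, max_dwells // n_channels + 1), size=n_channels)
    channels = []
    for m, size in enumerate(sizes):
        start = rng.uniform(-1, 1, size=3)
        positions = start + np.arange(size)[:, None] * np.array([0.0, 0.0, 0.25])
        channels.append(b.Channel(name=f"ch{m}", positions=positions))
    n_dwell = int(sizes.sum())
    n_points = int(rng.integers(3, max_points + 1))
    values = rng.uniform(0.01, 0.1, size=(n_points, n_dwell))
    kernel = b.DoseKernel(
        values=values,
        dwell_index_map=tuple(
            (m, n) for m, size in enumerate(sizes) for n in range(size)
        ),
        channel_sizes=tuple(int(s) for s in sizes),
    )
    # dwell times with distinct per-channel values (min is unambiguous)
    while True:
        times = rng.uniform(0.5, 2.0, size=n_dwell)
        bounds = np.concatenate(([0], np.cumsum(sizes)))
        gaps = [
            np.diff(np.sort(times[a:bnd])).min() if bnd - a > 1 else 1.0
            for a, bnd in zip(bounds[:-1], bounds[1:])
        ]
        if min(gaps) > 1e-3:
            break
    doses = values @ times
    # two ROIs splitting the points; thresholds between dose samples
    half = n_points // 2 or 1
    membership = {"tar": np.arange(half), "oar": np.arange(half, n_points)}
    if membership["oar"].size == 0:
        membership["oar"] = membership["tar"]
    entries = []
    for name, role in (("tar", "target"), ("oar", "oar")):
        d = doses[membership[name]]
        threshold = float(np.median(d) + 0.5 * (d.max() - np.median(d)) + 0.0131)
        while np.min(np.abs(d - threshold)) < 1e-2:
            threshold += 3e-2
        goal = b.DoseGoal(dose=threshold, weight=float(rng.uniform(10, 100)))
        entries.append(
            b.ROIObjective(name, role, minimum=goal if role == "target" else None,
                           maximum=goal if role == "oar" else None)
        )
    spec = b.ObjectiveSpec(tuple(entries))
    points = b.CalcPointSet(
        points=np.zeros((n_points, 3)), voxel_volume=1e-3, roi_membership=membership
    )
    return kernel, points, spec, times
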