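"""Error distributions, grid search and method ranking.

Estimation quality is measured against reference time courses (motion-capture
in the laboratory setting, exact ground truth for simulated strides) by
pooling per-sample signed errors over all strides of a dataset, separately
per variable and axis.  The summary metrics are the pooled mean (accuracy)
and standard deviation (precision).

Parameter search is an exhaustive grid evaluation of the range-normalised
RMSE objective

    J(θ) = (1/m) Σ_i rmse(ε(α_i, θ)) / ρ_i

over the m monitored axes, where ρ_i is the range (max - min) the reference
course of axis i attains on the dataset.  Ties are broken by grid order, so
the search is fully deterministic.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from sklearn.base import clone

from .orientation import (
    EustonTracker,
    GyroTracker,
    MadgwickTracker,
    OrientationTrack,
)
from .trajectory import (
    AnalyticIntegrator,
    DirectIntegrator,
    DirectReverseIntegrator,
    VERTICAL,
)

__all__ = [
    "ErrorDistribution",
    "GridSpec",
    "plane_angles",
    "pooled_errors",
    "accuracy_precision",
    "grid_objective",
    "grid_search",
    "build_table1_grids",
    "orientation_error_courses",
    "trajectory_error_courses",
    "rank_methods",
    "time_methods",
    "TRACKERS",
    "INTEGRATORS",
]

#: Euler decomposition convention for per-plane angles: intrinsic Z-X-Y of
#: the sensor-to-world rotation.  Rotation about the transversal axis (z) is
#: sagittal-plane motion, about the anterior-posterior axis (x) frontal-plane
#: motion, about the longitudinal axis (y) transversal-plane motion.
EULER_CONVENTION = "ZXY"
PLANE_NAMES = ("sagittal", "frontal", "transversal")

TRACKERS = {
    "gyro": GyroTracker,
    "madgwick": MadgwickTracker,
    "euston": EustonTracker,
}
INTEGRATORS = {
    "direct": DirectIntegrator,
    "direct_reverse": DirectReverseIntegrator,
    "analytic": AnalyticIntegrator,
}


@dataclass
class ErrorDistribution:
    """Pooled per-sample signed errors for one variable and axis."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("error distribution contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class GridSpec:
    """Named parameter lists defining an exhaustive search grid."""

    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, values in self.params.items():
            if len(values) == 0:
                raise ValueError(f"grid for {name!r} is empty")

    def points(self):
        """All grid points as dicts, in deterministic product order."""
        names = list(self.params)
        for combo in itertools.product(*(self.params[n] for n in names)):
            yield dict(zip(names, combo))

    @property
    def size(self) -> int:
        return int(np.prod([len(v) for v in self.params.values()]))


def plane_angles(track: OrientationTrack) -> dict[str, np.ndarray]:
    """Per-plane angle courses (degrees) of a sensor-to-world track.

    Intrinsic Z-X-Y Euler decomposition; keys ``sagittal`` (about z),
    ``frontal`` (about x) and ``transversal`` (about y).
    """
    q = track.quaternions
    rot = Rotation.from_quat(q[:, [1, 2, 3, 0]])  # to scalar-last
    ang = rot.as_euler(EULER_CONVENTION, degrees=True)
    return {
        "sagittal": ang[:, 0],
        "frontal": ang[:, 1],
        "transversal": ang[:, 2],
    }


def pooled_errors(
    estimates: list[np.ndarray],
    references: list[np.ndarray],
    wrap_degrees: bool = False,
) -> ErrorDistribution:
    """Pooled per-sample signed differences (estimate - reference).

    With ``wrap_degrees`` the differences are wrapped into [-180, 180), as
    appropriate for angle courses.
    """
    if len(estimates) != len(references):
        raise ValueError("need one reference course per estimate")
    chunks = []
    for est, ref in zip(estimates, references):
        est, ref = np.asarray(est, dtype=float), np.asarray(ref, dtype=float)
        if est.shape != ref.shape:
            raise ValueError("estimate/reference shape mismatch")
        d = est - ref
        if wrap_degrees:
            d = (d + 180.0) % 360.0 - 180.0
        chunks.append(d.ravel())
    return ErrorDistribution(np.concatenate(chunks))


def accuracy_precision(d: ErrorDistribution) -> tuple[float, float]:
    """Pooled mean (accuracy) and sample standard deviation (precision)."""
    mean = float(np.mean(d.values))
    sd = float(np.std(d.values, ddof=1)) if d.n > 1 else 0.0
    return mean, sd


def grid_objective(errors: dict[str, ErrorDistribution], ranges: dict[str, float]) -> float:
    """Range-normalised mean RMSE over the monitored axes.

    Zero iff all errors are zero; doubling every range halves the objective.
    """
    if not errors:
        raise ValueError("no error distributions given")
    total = 0.0
    for axis, dist in errors.items():
        rho = ranges[axis]
        if rho <= 0:
            raise ValueError(f"non-positive range for axis {axis!r}")
        total += float(np.sqrt(np.mean(dist.values**2))) / rho
    return total / len(errors)


def reference_ranges(reference_courses: dict[str, list[np.ndarray]]) -> dict[str, float]:
    """Range (max - min) each reference course attains over the dataset."""
    return {
        axis: float(max(np.max(c) for c in courses) - min(np.min(c) for c in courses))
        for axis, courses in reference_courses.items()
    }


def orientation_error_courses(tracker, dataset) -> tuple[dict, dict]:
    """Per-plane angle estimates and references for every stride.

    ``dataset`` is a list of ``(spec, recording, truth)`` triples as produced
    by :func:`stridetraj.simulate.make_dataset`.  Returns
    ``(estimates, references)`` keyed by plane name.
    """
    est: dict[str, list] = {p: [] for p in PLANE_NAMES}
    ref: dict[str, list] = {p: [] for p in PLANE_NAMES}
    for _, rec, truth in dataset:
        track = tracker.track(rec)
        ang_e = plane_angles(track)
        ang_r = plane_angles(truth.orientation)
        for p in PLANE_NAMES:
            est[p].append(ang_e[p])
            ref[p].append(ang_r[p])
    return est, ref


def trajectory_error_courses(tracker, integrator, dataset) -> tuple[dict, dict]:
    """Velocity and clearance estimates/references (cyclic-boundary endpoints).

    Axes: ``vx``, ``vy``, ``vz`` (m/s) and ``clearance`` (m).
    """
    names = ("vx", "vy", "vz", "clearance")
    est: dict[str, list] = {k: [] for k in names}
    ref: dict[str, list] = {k: [] for k in names}
    for _, rec, truth in dataset:
        track = tracker.track(rec)
        traj = integrator.estimate(rec, track)
        for ax, key in enumerate(("vx", "vy", "vz")):
            est[key].append(traj.velocity[:, ax])
            ref[key].append(truth.velocity[:, ax])
        est["clearance"].append(traj.position[:, VERTICAL])
        ref["clearance"].append(truth.position[:, VERTICAL])
    return est, ref


def _pool(est: dict, ref: dict, wrap_degrees: bool) -> tuple[dict, dict]:
    errors = {
        axis: pooled_errors(est[axis], ref[axis], wrap_degrees=wrap_degrees)
        for axis in est
    }
    ranges = reference_ranges(ref)
    return errors, ranges


def grid_search(
    dataset,
    estimator,
    grid: GridSpec,
    kind: str = "orientation",
    tracker=None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search of the range-normalised RMSE objective.

    ``kind="orientation"``: ``estimator`` is an orientation tracker whose
    parameters are searched against the reference angle courses.
    ``kind="integration"``: ``estimator`` is an integrator searched against
    the reference velocity/clearance courses, run behind the fixed
    ``tracker`` (default: Madgwick with its reported optimum).

    Returns the optimal parameter dict (first grid point attaining the
    minimum) and the full objective table for inspection.
    """
    if kind not in ("orientation", "integration"):
        raise ValueError("kind must be 'orientation' or 'integration'")
    if kind == "integration" and tracker is None:
        tracker = MadgwickTracker()
    rows = []
    best, best_obj = None, np.inf
    for point in grid.points():
        candidate = clone(estimator).set_params(**point)
        if kind == "orientation":
            est, ref = orientation_error_courses(candidate, dataset)
            errors, ranges = _pool(est, ref, wrap_degrees=True)
        else:
            est, ref = trajectory_error_courses(tracker, candidate, dataset)
            errors, ranges = _pool(est, ref, wrap_degrees=False)
        obj = grid_objective(errors, ranges)
        rows.append({**point, "objective": obj})
        if obj < best_obj:  # strict: ties keep the earlier grid point
            best, best_obj = point, obj
    return best, pd.DataFrame(rows)


def build_table1_grids() -> dict[str, GridSpec]:
    """The benchmark parameter grids.

    * ``beta`` and ``k_p``: ``10^(-i/3)`` for i = 0..9;
    * ``k_i``: {0, 0.01, 0.10};
    * ``gamma``: ten values chosen so the stance-phase fraction receiving an
      accelerometer update is sampled roughly equidistantly;
    * ``t0``: ``0.05·i`` for i = 0..20;
    * ``eta``: ``10^(κ - i·δ)`` with κ = log10(1/2), δ = (log10(1/2)+2)/9,
      i = 0..9, spanning [0.01, 0.5].
    """
    i10 = np.arange(10)
    log_half = np.log10(0.5)
    delta = (log_half + 2.0) / 9.0
    gamma = [0.04, 0.07, 0.09, 0.14, 0.24, 0.45, 0.77, 1.48, 2.50, 4.00]
    return {
        "madgwick": GridSpec(
            {"gamma": gamma, "beta": list(10.0 ** (-i10 / 3.0))}
        ),
        "euston": GridSpec(
            {
                "gamma": gamma,
                "k_p": list(10.0 ** (-i10 / 3.0)),
                "k_i": [0.0, 0.01, 0.10],
            }
        ),
        "direct_reverse": GridSpec(
            {
                "t0": list(0.05 * np.arange(21)),
                "eta": list(10.0 ** (log_half - i10 * delta)),
            }
        ),
    }


def rank_methods(results: dict[str, dict[str, tuple[float, float]]]) -> pd.DataFrame:
    """Order methods from best to worst.

    ``results`` maps method name → axis → (accuracy, precision).  The
    composite criterion is the mean of ``(|accuracy| + precision) / 2`` over
    all monitored endpoints (stated in the output); smaller is better.
    """
    rows = []
    for name, per_axis in results.items():
        score = float(
            np.mean([(abs(acc) + prec) / 2.0 for acc, prec in per_axis.values()])
        )
        rows.append({"method": name, "score": score})
    df = pd.DataFrame(rows).sort_values("score", kind="stable").reset_index(drop=True)
    df.attrs["criterion"] = "mean over endpoints of (|accuracy| + precision) / 2"
    return df


def time_methods(dataset, methods: dict) -> pd.DataFrame:
    """Mean wall-clock execution time per stride for each pipeline (ms).

    Reported for information only; timings are hardware-dependent.
    """
    rows = []
    for name, (tracker, integrator) in methods.items():
        start = time.perf_counter()
        for _, rec, _ in dataset:
            track = tracker.track(rec)
            if integrator is not None:
                integrator.estimate(rec, track)
        elapsed = time.perf_counter() - start
        rows.append({"method": name, "ms_per_stride": 1e3 * elapsed / len(dataset)})
    return pd.DataFrame(rows)
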