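"""Robustness harness and circular statistics.

Stress tests probe how the hockey-stick DLMO estimate reacts to
controlled deviations from ideal sampling: shape-preserving resampling at
coarser/finer intervals (PCHIP), threshold changes, single- and
multi-point deletions, and timing/assay noise. Every perturbation
replicate is re-estimated and the shift relative to the unperturbed
baseline recorded; replicates that fail validation are kept as failures
in the bookkeeping.

Concordance between two sets of DLMO clock times is evaluated with
circular statistics (times-of-day as angles on the 24-h circle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, stats

from .core import estimate_dlmo
from .errors import DlmokitError, UndefinedCircularMeanError
from .profile import MelatoninProfile
from .synthetic import perturb_profile

RESAMPLE_INTERVALS_MIN = (2, 5, 10, 15, 20, 30, 45, 60, 75, 90)
THRESHOLD_SWEEP_DEFAULT = (2.0, 3.0, 4.0, 5.0, 10.0)
DELETION_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class Replicate:
    replicate_id: str
    dlmo_hours: float | None
    delta_hours: float | None
    failure: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class PerturbationReport:
    """One stress condition: replicate-level deltas plus summaries."""

    condition: str
    baseline_dlmo: float
    replicates: list[Replicate]
    binned: list[dict] | None = None

    @property
    def deltas(self) -> np.ndarray:
        return np.asarray(
            [r.delta_hours for r in self.replicates if r.delta_hours is not None]
        )

    @property
    def n_attempted(self) -> int:
        return len(self.replicates)

    @property
    def n_succeeded(self) -> int:
        return sum(r.failure is None for r in self.replicates)

    @property
    def success_rate(self) -> float:
        return self.n_succeeded / self.n_attempted if self.replicates else float("nan")

    def summary(self) -> dict:
        d = self.deltas
        return {
            "condition": self.condition,
            "baseline_dlmo": self.baseline_dlmo,
            "n_attempted": self.n_attempted,
            "n_succeeded": self.n_succeeded,
            "success_rate": self.success_rate,
            "mean_delta": float(np.mean(d)) if d.size else float("nan"),
            "sd_delta": float(np.std(d, ddof=1)) if d.size > 1 else float("nan"),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "condition": self.condition,
                    "replicate": r.replicate_id,
                    "dlmo_hours": r.dlmo_hours,
                    "delta_hours": r.delta_hours,
                    "failure": r.failure,
                    **r.extra,
                }
                for r in self.replicates
            ]
        )


def resample_pchip(
    profile: MelatoninProfile, interval_min: float, anchor: float | None = None
) -> MelatoninProfile:
    """Shape-preserving (monotone cubic Hermite) resampling on a regular
    grid anchored at the first sample (or ``anchor``). Negative
    interpolants are clipped to zero. The interpolant reproduces its
    knots, so resampling an aligned grid is the identity on values."""
    if interval_min <= 0:
        raise ValueError("interval must be positive")
    if len(profile) < 2:
        raise ValueError("need at least two samples to resample")
    t0 = profile.times[0] if anchor is None else anchor
    step = interval_min / 60.0
    grid = np.arange(t0, profile.times[-1] + 1e-9, step)
    f = interpolate.PchipInterpolator(profile.times, profile.concentrations)
    vals = np.maximum(f(grid), 0.0)
    return MelatoninProfile(
        id=f"{profile.id}-resampled-{interval_min:g}min",
        times=grid,
        concentrations=vals,
    )


def _baseline(profile, params) -> float:
    return estimate_dlmo(profile, **params).dlmo_hours


def _try_estimate(profile, params):
    try:
        return estimate_dlmo(profile, **params).dlmo_hours, None
    except DlmokitError as exc:
        return None, str(exc)


def single_deletion_scan(
    profile: MelatoninProfile,
    bin_minutes: float = 15.0,
    window_minutes: float = 120.0,
    **params,
) -> PerturbationReport:
    """Delete each sample once, re-estimate, and bin the DLMO shifts by
    the deleted sample's timing relative to the baseline DLMO."""
    base = _baseline(profile, params)
    reps: list[Replicate] = []
    for i in range(len(profile)):
        sub = MelatoninProfile(
            id=f"{profile.id}-del{i}",
            times=np.delete(profile.times, i),
            concentrations=np.delete(profile.concentrations, i),
        )
        est, fail = _try_estimate(sub, params)
        reps.append(
            Replicate(
                replicate_id=f"delete_index_{i}",
                dlmo_hours=est,
                delta_hours=None if est is None else est - base,
                failure=fail,
                extra={
                    "deleted_time_h": float(profile.times[i]),
                    "rel_deletion_min": float((profile.times[i] - base) * 60.0),
                },
            )
        )
    # 15-min bins of deletion time relative to baseline DLMO
    binned = []
    half = bin_minutes / 2.0
    centers = np.arange(-window_minutes, window_minutes + half, bin_minutes)
    for c in centers:
        ds = [
            r.delta_hours
            for r in reps
            if r.delta_hours is not None
            and c - half <= r.extra["rel_deletion_min"] < c + half
        ]
        if ds:
            binned.append(
                {
                    "bin_center_min": float(c),
                    "mean_delta": float(np.mean(ds)),
                    "sd_delta": float(np.std(ds, ddof=1)) if len(ds) > 1 else 0.0,
                    "n": len(ds),
                }
            )
    return PerturbationReport(
        condition="single_deletion",
        baseline_dlmo=base,
        replicates=reps,
        binned=binned,
    )


def multi_deletion(
    profile: MelatoninProfile,
    fraction: float,
    n_reps: int = 20,
    seed: int | None = None,
    **params,
) -> PerturbationReport:
    """Randomly delete ``fraction`` of the samples, ``n_reps`` times."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    base = _baseline(profile, params)
    rng = np.random.default_rng(seed)
    n = len(profile)
    k = int(np.floor(fraction * n))
    reps = []
    for r in range(n_reps):
        drop = rng.choice(n, size=k, replace=False)
        keep = np.setdiff1d(np.arange(n), drop)
        sub = MelatoninProfile(
            id=f"{profile.id}-mdel{r}",
            times=profile.times[keep],
            concentrations=profile.concentrations[keep],
        )
        est, fail = _try_estimate(sub, params)
        reps.append(
            Replicate(
                replicate_id=f"rep_{r}",
                dlmo_hours=est,
                delta_hours=None if est is None else est - base,
                failure=fail,
                extra={"n_deleted": k},
            )
        )
    return PerturbationReport(
        condition=f"multi_deletion_{int(fraction * 100)}pct",
        baseline_dlmo=base,
        replicates=reps,
    )


def threshold_sweep(
    profile: MelatoninProfile,
    thresholds=THRESHOLD_SWEEP_DEFAULT,
    **params,
) -> PerturbationReport:
    """Estimate at each threshold; deltas are relative to the estimate at
    the first (lowest) threshold."""
    thresholds = list(thresholds)
    if any(th <= 0 for th in thresholds):
        raise ValueError("thresholds must be positive")
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    p0 = dict(params)
    p0["threshold"] = thresholds[0]
    base = _baseline(profile, p0)
    reps = []
    for th in thresholds:
        p = dict(params)
        p["threshold"] = th
        est, fail = _try_estimate(profile, p)
        reps.append(
            Replicate(
                replicate_id=f"threshold_{th:g}",
                dlmo_hours=est,
                delta_hours=None if est is None else est - base,
                failure=fail,
                extra={"threshold": th},
            )
        )
    return PerturbationReport(
        condition="threshold_sweep", baseline_dlmo=base, replicates=reps
    )


NOISE_CONDITIONS = (
    {"name": "clean", "time_sd_min": 0.0, "conc_cv": 0.0},
    {"name": "jitter_5min", "time_sd_min": 5.0, "conc_cv": 0.0},
    {"name": "jitter_10min", "time_sd_min": 10.0, "conc_cv": 0.0},
    {"name": "jitter_20min", "time_sd_min": 20.0, "conc_cv": 0.0},
    {"name": "conc_cv_7.9pct", "time_sd_min": 0.0, "conc_cv": 0.079},
    {"name": "combined", "time_sd_min": 10.0, "conc_cv": 0.079},
)


def noise_sweep(
    profile: MelatoninProfile,
    conditions=NOISE_CONDITIONS,
    n_reps: int = 20,
    seed: int | None = None,
    **params,
) -> list[PerturbationReport]:
    """Re-estimate under each timing/assay noise condition."""
    base = _baseline(profile, params)
    rng = np.random.default_rng(seed)
    reports = []
    for cond in conditions:
        reps = []
        for r in range(n_reps):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            pert, n_clip = perturb_profile(
                profile,
                time_sd_min=cond["time_sd_min"],
                conc_cv=cond["conc_cv"],
                seed=sub_seed,
            )
            est, fail = _try_estimate(pert, params)
            reps.append(
                Replicate(
                    replicate_id=f"rep_{r}",
                    dlmo_hours=est,
                    delta_hours=None if est is None else est - base,
                    failure=fail,
                    extra={"n_clipped": n_clip},
                )
            )
        reports.append(
            PerturbationReport(
                condition=f"noise_{cond['name']}", baseline_dlmo=base, replicates=reps
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Circular statistics (times-of-day on the 24-h circle)
# ---------------------------------------------------------------------------

_H2R = 2.0 * math.pi / 24.0  # hours → radians


def circ_diff(a, b):
    """Signed circular difference a − b in hours, mapped to (−12, 12]."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = -((-(a - b) + 12.0) % 24.0) + 12.0   # boundary maps to +12
    return d if d.ndim else float(d)


def circ_summary(times) -> tuple[float, float]:
    """Circular mean and SD of hours-of-day, both in hours.

    SD is sqrt(-2 ln R) of the mean resultant length, rescaled to hours.
    Raises when the resultant vanishes (antipodal data)."""
    t = np.asarray(times, dtype=float)
    if t.size < 1:
        raise ValueError("need at least one value")
    ang = t * _H2R
    rbar = float(np.abs(np.mean(np.exp(1j * ang))))
    if rbar < 1e-12:
        raise UndefinedCircularMeanError("zero resultant: circular mean undefined")
    mean = float(stats.circmean(ang, high=2 * math.pi, low=0.0)) / _H2R % 24.0
    sd = float(stats.circstd(ang, high=2 * math.pi, low=0.0)) / _H2R
    return mean, sd


def circ_corr(a, b) -> float:
    """Jammalamadaka–SenGupta circular correlation of paired hours-of-day."""
    a = np.asarray(a, float) * _H2R
    b = np.asarray(b, float) * _H2R
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired series of equal length >= 3")
    am = math.atan2(np.sin(a).sum(), np.cos(a).sum())
    bm = math.atan2(np.sin(b).sum(), np.cos(b).sum())
    sa, sb = np.sin(a - am), np.sin(b - bm)
    denom = math.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        raise ValueError("degenerate (constant) series")
    return float((sa * sb).sum() / denom)


def circ_paired_test(a, b) -> tuple[float, float]:
    """Paired location test on wrapped differences.

    Computes d_i = circ_diff(a_i, b_i) and runs a one-sample t-test of
    mean zero on the linearized differences (valid because paired DLMO
    differences are far below the 12-h wrap). Returns (statistic, p).
    Zero-variance differences short-circuit: p = 1 at zero mean, p ≈ 0
    (machine epsilon bound) otherwise."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired series of equal length >= 3")
    d = np.array([circ_diff(x, y) for x, y in zip(a, b)])
    if np.allclose(d.std(ddof=0), 0.0):
        if abs(d.mean()) < 1e-12:
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), float(np.finfo(float).eps)
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p)
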