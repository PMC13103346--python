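"""Synthetic melatonin profiles with known ground truth.

Profiles follow the hockey-stick shape the estimator assumes: a flat (or
gently sloped) baseline up to a known onset time, then a linear or
linear-plus-quadratic rise. Assay noise is multiplicative Gaussian with a
coefficient of variation defaulting to 7.9% (intra-assay precision of the
melatonin radioimmunoassay the sampling protocols use); sampling-time
jitter is additive Gaussian in minutes. Noiseless generation reproduces
the piecewise model exactly at the sample times, so zero-cost fixtures
exist for both search phases.

The generator emulates one evening of saliva sampling; it does not model
melatonin suppression dynamics or the morning decline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile import DEFAULT_THRESHOLD, MelatoninProfile

DEFAULT_CONC_CV = 0.079      # intra-assay coefficient of variation
DEFAULT_BASELINE = 1.0       # pg/mL
DEFAULT_ONSET = 22.25        # decimal hours
DEFAULT_RATE = 4.0           # pg/mL per hour
DEFAULT_START = 19.0         # first sample, decimal hours
DEFAULT_SPAN = 6.0           # hours of sampling
DEFAULT_INTERVAL = 30.0      # minutes between samples


@dataclass
class SyntheticTruth:
    """A generated profile together with its generating parameters."""

    profile: MelatoninProfile
    true_onset: float
    baseline_level: float
    rise_kind: str
    rise_rate: float
    quad_term: float
    sampling_interval: float
    span: float
    conc_cv: float
    time_jitter_sd: float
    seed: int | None
    baseline_slope: float = 0.0
    n_clipped: int = 0


def hockey_stick_value(
    t,
    onset: float,
    baseline: float,
    rate: float,
    quad: float = 0.0,
    baseline_slope: float = 0.0,
):
    """Evaluate the noiseless piecewise model at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    base = baseline + baseline_slope * (t - onset)
    rise = baseline + rate * (t - onset) + quad * (t - onset) ** 2
    return np.where(t <= onset, base, rise)


def generate_profile(
    onset: float = DEFAULT_ONSET,
    baseline: float = DEFAULT_BASELINE,
    rate: float = DEFAULT_RATE,
    quad: float = 0.0,
    rise_kind: str = "linear",
    baseline_slope: float = 0.0,
    start: float = DEFAULT_START,
    span: float = DEFAULT_SPAN,
    interval_min: float = DEFAULT_INTERVAL,
    conc_cv: float = DEFAULT_CONC_CV,
    time_jitter_sd_min: float = 0.0,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int | None = None,
    id: str | None = None,
) -> SyntheticTruth:
    """Sample the hockey-stick model on a regular grid, optionally noised.

    ``rise_kind`` "parabolic" uses the quadratic term (default 1.0 when
    unset) so the refinement-phase model family contains the truth. The
    rise must cross the threshold within the sampled span. Negative noisy
    concentrations are clipped to zero. Deterministic under ``seed``.
    """
    if rise_kind == "parabolic" and quad == 0.0:
        quad = 1.0
    if rise_kind == "linear":
        quad = 0.0
    if baseline >= threshold:
        raise ValueError("baseline must sit below the threshold")
    t_end = start + span
    if hockey_stick_value(t_end, onset, baseline, rate, quad, baseline_slope) <= threshold:
        raise ValueError("rise never crosses the threshold within the span")
    rng = np.random.default_rng(seed)
    times = np.arange(start, t_end + 1e-9, interval_min / 60.0)
    if time_jitter_sd_min > 0:
        times = np.sort(times + rng.normal(0.0, time_jitter_sd_min / 60.0, len(times)))
        times = _deduplicate(times)
    conc = hockey_stick_value(times, onset, baseline, rate, quad, baseline_slope)
    if conc_cv > 0:
        conc = conc * (1.0 + rng.normal(0.0, conc_cv, len(conc)))
    n_clipped = int(np.sum(conc < 0))
    conc = np.maximum(conc, 0.0)
    prof = MelatoninProfile(
        id=id or f"synthetic-onset-{onset:.2f}",
        times=times,
        concentrations=conc,
    )
    return SyntheticTruth(
        profile=prof,
        true_onset=onset,
        baseline_level=baseline,
        rise_kind=rise_kind,
        rise_rate=rate,
        quad_term=quad,
        sampling_interval=interval_min,
        span=span,
        conc_cv=conc_cv,
        time_jitter_sd=time_jitter_sd_min,
        seed=seed,
        baseline_slope=baseline_slope,
        n_clipped=n_clipped,
    )


def _deduplicate(times: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nudge exact duplicates apart by ``eps`` hours, keeping order."""
    t = times.copy()
    for i in range(1, len(t)):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + eps
    return t


def perturb_profile(
    profile: MelatoninProfile,
    time_sd_min: float = 0.0,
    conc_cv: float = 0.0,
    seed: int | None = None,
) -> tuple[MelatoninProfile, int]:
    """Jitter sampling times and/or apply multiplicative assay noise.

    Jittered times are re-sorted (exact collisions nudged by 1e-6 h);
    negative concentrations are clipped to zero and counted. Returns
    (perturbed profile, number of clipped values). Identity when both
    noise scales are zero.
    """
    rng = np.random.default_rng(seed)
    t = profile.times.copy()
    c = profile.concentrations.copy()
    if time_sd_min > 0:
        t = t + rng.normal(0.0, time_sd_min / 60.0, len(t))
        order = np.argsort(t, kind="stable")
        t, c = t[order], c[order]
        t = _deduplicate(t)
    if conc_cv > 0:
        c = c * (1.0 + rng.normal(0.0, conc_cv, len(c)))
    n_clipped = int(np.sum(c < 0))
    c = np.maximum(c, 0.0)
    return (
        MelatoninProfile(id=profile.id, times=t, concentrations=c),
        n_clipped,
    )


_DEGENERATE_CASES = (
    "all_sub_threshold",
    "all_supra_threshold",
    "two_points",
    "spurious_spike",
    "double_rise",
    "trailing_subthreshold",
)


def degenerate_fixture(case: str) -> MelatoninProfile:
    """Canonical pathological profiles exercising the validation gates.

    - ``all_sub_threshold``: every level below threshold → "no dynamic part".
    - ``all_supra_threshold``: every level above threshold → no upward
      crossing, estimation fails.
    - ``two_points``: → "insufficient number of data points".
    - ``spurious_spike``: one early above-threshold sample, a dip, then a
      steady rise ~1 h later; the estimate locks onto the later steady rise.
    - ``double_rise``: two rises above threshold separated by under 2 h;
      the later rise is used.
    - ``trailing_subthreshold``: rise followed by sub-threshold tail; the
      tail is trimmed at validation.
    """
    thr = DEFAULT_THRESHOLD
    if case == "all_sub_threshold":
        t = np.arange(20.0, 24.0, 0.5)
        c = np.full_like(t, 1.0)
        c[3] = 1.4
    elif case == "all_supra_threshold":
        t = np.arange(20.0, 24.0, 0.5)
        c = np.linspace(5.0, 12.0, len(t))
    elif case == "two_points":
        t = np.array([21.0, 21.5])
        c = np.array([1.0, 5.0])
    elif case == "spurious_spike":
        t = np.array([20.0, 20.5, 21.0, 21.5, 22.0, 22.5, 23.0, 23.5])
        c = np.array([1.0, 3.0, 1.2, 1.1, 1.3, 2.8, 5.5, 9.0])
    elif case == "double_rise":
        t = np.array([20.0, 20.5, 21.0, 21.5, 22.0, 22.5, 23.0])
        c = np.array([1.0, 2.6, 1.8, 1.5, 2.9, 5.0, 8.0])
    elif case == "trailing_subthreshold":
        t = np.array([20.0, 20.5, 21.0, 21.5, 22.0, 22.5])
        c = np.array([1.0, 1.0, 3.0, 5.0, 1.5, 1.0])
    else:
        raise ValueError(
            f"unknown degenerate case {case!r}; choose one of {_DEGENERATE_CASES}"
        )
    return MelatoninProfile(id=f"degenerate-{case}", times=t, concentrations=c)
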