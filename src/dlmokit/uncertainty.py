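"""Bootstrap confidence intervals for the DLMO estimate.

Four resampling schemes, each producing an empirical distribution of DLMO
estimates summarized by its mean and 95% percentile interval:

- ``monte_carlo``: Gaussian jitter on sampling times plus multiplicative
  Gaussian noise on concentrations (protocol delays + assay noise).
- ``residual``: residuals of the fitted piecewise model resampled with
  replacement onto the fitted values.
- ``wild``: residuals multiplied by independent random signs (Rademacher
  by default, Mammen's two-point distribution as an option), preserving
  heteroscedasticity.
- ``hybrid``: time jitter combined with residual resampling.

Replicates that fail validation (e.g. all values driven sub-threshold)
are counted as failures, not dropped silently. Estimates live on the
unwrapped hour axis of the single evening; no circular wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DlmoResult, estimate_dlmo
from .errors import BootstrapFailureError, DlmokitError
from .profile import MelatoninProfile
from .synthetic import _deduplicate

METHODS = ("monte_carlo", "residual", "wild", "hybrid")
DEFAULT_N = 1000
DEFAULT_TIME_SD_MIN = 5.0
DEFAULT_CONC_CV = 0.079


@dataclass
class BootstrapResult:
    method: str
    n_requested: int
    n_succeeded: int
    estimates: np.ndarray                # successful replicate DLMOs, hours
    mean_hours: float
    ci_lo: float
    ci_hi: float
    point_estimate: float
    seed: int | None
    noise_params: dict = field(default_factory=dict)
    failures: list[str] = field(default_factory=list)


def predict_piecewise(result: DlmoResult, times) -> np.ndarray:
    """Evaluate the fitted hockey-stick model: the early line before the
    DLMO, the late fit at/after it; both pass through the breakpoint, so
    the prediction is continuous there. Extrapolation outside the observed
    span is permitted."""
    fit = result.best
    t = np.asarray(times, dtype=float)
    d = t - fit.pt
    early = fit.py + fit.early_slope * d
    if fit.late_kind == "linear":
        late = fit.py + fit.late_coeffs[0] * d
    else:
        a, b = fit.late_coeffs
        late = fit.py + a * d * d + b * d
    return np.where(t < fit.pt, early, late)


def _mammen(rng, size):
    # two-point distribution with mean 0, variance 1, third moment 1
    phi = (1 + np.sqrt(5)) / 2
    p = (phi) / np.sqrt(5)
    draws = rng.random(size) < p
    return np.where(draws, 1 - phi, phi)


def bootstrap_dlmo(
    profile: MelatoninProfile,
    method: str = "monte_carlo",
    n: int = DEFAULT_N,
    seed: int | None = None,
    time_sd_min: float = DEFAULT_TIME_SD_MIN,
    conc_cv: float = DEFAULT_CONC_CV,
    wild_multipliers: str = "rademacher",
    **estimate_params,
) -> BootstrapResult:
    """Resample the profile ``n`` times, re-estimate, and summarize.

    ``estimate_params`` are forwarded to :func:`estimate_dlmo` for both
    the point estimate and every replicate. Deterministic under ``seed``.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    point = estimate_dlmo(profile, **estimate_params)
    fitted = predict_piecewise(point, profile.times)
    residuals = profile.concentrations - fitted
    rng = np.random.default_rng(seed)

    estimates = []
    failures: list[str] = []
    t0, c0 = profile.times, profile.concentrations
    m = len(profile)
    for _ in range(n):
        t = t0.copy()
        if method == "monte_carlo":
            c = c0 * (1.0 + rng.normal(0.0, conc_cv, m)) if conc_cv > 0 else c0.copy()
            if time_sd_min > 0:
                t = t0 + rng.normal(0.0, time_sd_min / 60.0, m)
        elif method == "residual":
            c = fitted + rng.choice(residuals, size=m, replace=True)
        elif method == "wild":
            if wild_multipliers == "mammen":
                v = _mammen(rng, m)
            else:
                v = rng.choice([-1.0, 1.0], size=m)
            c = fitted + residuals * v
        else:  # hybrid
            c = fitted + rng.choice(residuals, size=m, replace=True)
            if time_sd_min > 0:
                t = t0 + rng.normal(0.0, time_sd_min / 60.0, m)
        order = np.argsort(t, kind="stable")
        t, c = t[order], c[order]
        t = _deduplicate(t)
        c = np.maximum(c, 0.0)
        try:
            rep = MelatoninProfile(id=profile.id, times=t, concentrations=c)
            res = estimate_dlmo(rep, **estimate_params)
            estimates.append(res.dlmo_hours)
        except DlmokitError as exc:
            failures.append(str(exc))
    if not estimates:
        raise BootstrapFailureError(
            f"all {n} replicates failed; first reason: {failures[0]}"
        )
    est = np.asarray(estimates)
    mean, ci_lo, ci_hi, _ = summarize_bootstrap(est)
    return BootstrapResult(
        method=method,
        n_requested=n,
        n_succeeded=len(est),
        estimates=est,
        mean_hours=mean,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        point_estimate=point.dlmo_hours,
        seed=seed,
        noise_params={"time_sd_min": time_sd_min, "conc_cv": conc_cv},
        failures=failures,
    )


def summarize_bootstrap(estimates, bin_width: float = 0.05):
    """Mean, empirical 2.5/97.5 percentiles (linear interpolation between
    order statistics) and a histogram table of the replicate estimates."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no bootstrap estimates to summarize")
    mean = float(np.mean(est))
    ci_lo = float(np.percentile(est, 2.5))
    ci_hi = float(np.percentile(est, 97.5))
    lo = np.floor(est.min() / bin_width) * bin_width
    hi = np.ceil(est.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(est, bins=edges)
    hist = {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    return mean, ci_lo, ci_hi, hist
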