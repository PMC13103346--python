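"""Two-phase hockey-stick breakpoint search.

The DLMO is located by scanning candidate breakpoints (POIs) on a grid
over a region of interest (ROI): time bounds derive from the labeled
segments (last half of the final base segment, or just past the last base
node when intermediates exist, up to 95% of the first ascending segment);
concentration bounds run from the lowest profile level up to the
threshold.

At each POI the profile is split at the POI time (a node exactly at the
POI joins both sides). The earlier points get a line through the POI with
slope clamped to +-0.2 pg/mL/h and kept inside the [domain minimum,
threshold] band over the earlier points' span; the later points get a
line through the POI (coarse phase) or a parabola through the POI with a
strictly positive derivative whose slope at the POI is at least half the
linear-fit slope and steeper than the early slope (refinement phase). The
POI cost is the sum of the two Euclidean residual norms; the grid argmin
(earliest time, then lowest concentration, on ties) is the DLMO.

The refinement grid spans the bounding box of the 10% lowest-cost coarse
grid points at 0.01 resolution in both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import segmentation as seg
from .errors import (
    DegenerateRoiError,
    NoLateDataError,
    ProfileValidationError,
)
from .profile import (
    DEFAULT_THRESHOLD,
    MelatoninProfile,
    ValidationReport,
    hours_to_clock,
    validate_and_trim,
)

SLOPE_LIMIT = 0.2            # pg/mL per hour, early-fit clamp
COARSE_T_STEP = 0.1          # hours
COARSE_Y_STEP = 0.2          # pg/mL
REFINE_STEP = 0.01           # hours and pg/mL
TOP_FRACTION = 0.10          # refinement keeps the lowest-cost decile
SLOPE_EPS = 1e-6             # strict-inequality margin for parabola slopes
TIME_EPS = 1e-9              # "immediately after the last base node"


@dataclass
class Roi:
    """Time x concentration rectangle searched for the breakpoint."""

    t_lo: float
    t_hi: float
    y_lo: float
    y_hi: float


@dataclass
class PoiFit:
    """Fit of the piecewise model anchored at one candidate breakpoint."""

    pt: float
    py: float
    early_slope: float
    early_clamped: bool
    late_kind: str                      # "linear" or "parabola"
    late_coeffs: tuple                  # (slope,) or (a, b)
    early_norm: float
    late_norm: float

    @property
    def cost(self) -> float:
        return self.early_norm + self.late_norm


@dataclass
class GridResult:
    """Dense residual surface over one search phase."""

    phase: str                          # "coarse" or "refine"
    t_step: float
    y_step: float
    t: np.ndarray
    y: np.ndarray
    early_norm: np.ndarray
    late_norm: np.ndarray
    cost: np.ndarray
    argmin: PoiFit
    top_fraction_box: Optional[tuple] = None   # (t_lo, t_hi, y_lo, y_hi)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "phase": self.phase,
                "time_h": self.t,
                "conc": self.y,
                "early_norm": self.early_norm,
                "late_norm": self.late_norm,
                "cost": self.cost,
            }
        )


@dataclass
class DlmoResult:
    """Full output of a hockey-stick DLMO estimation."""

    dlmo_hours: float
    dlmo_clock: str
    dlmo_conc: float
    coarse: GridResult
    refine: Optional[GridResult]
    labels: seg.SegmentLabels
    roi: Roi
    validation: ValidationReport
    profile: MelatoninProfile            # trimmed profile used for fitting
    params_echo: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def best(self) -> PoiFit:
        return self.refine.argmin if self.refine is not None else self.coarse.argmin


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------


def compute_roi(
    profile: MelatoninProfile,
    labels: seg.SegmentLabels,
    threshold: float = DEFAULT_THRESHOLD,
) -> Roi:
    """Bounds of the breakpoint search region from the labeled segments."""
    t = profile.times
    asc = labels.ascending_segments
    if not asc:
        raise DegenerateRoiError("no ascending segments")
    first_asc = asc[0]
    t_hi = t[first_asc] + 0.95 * (t[first_asc + 1] - t[first_asc])

    base = labels.base_segments
    inter = [i for i in labels.intermediate_segments if i < first_asc]
    if inter:
        last_base_node = (max(base) + 1) if base else min(inter)
        t_lo = t[last_base_node] + TIME_EPS
    elif base:
        last = max(base)
        t_lo = 0.5 * (t[last] + t[last + 1])
    else:
        t_lo = t[first_asc]  # single base node: the ascending left node

    mask = labels.included_node_mask(len(profile))
    y_lo = float(np.min(profile.concentrations[mask]))
    y_hi = float(threshold)
    if not (t_lo < t_hi):
        raise DegenerateRoiError(f"ROI time bounds degenerate: [{t_lo}, {t_hi}]")
    if not (y_lo < y_hi):
        raise DegenerateRoiError(f"ROI level bounds degenerate: [{y_lo}, {y_hi}]")
    return Roi(t_lo=float(t_lo), t_hi=float(t_hi), y_lo=y_lo, y_hi=y_hi)


# ---------------------------------------------------------------------------
# Vectorized fitting kernel (fixed POI time, vector of POI levels)
# ---------------------------------------------------------------------------


def _early_fit_vec(te, ye, pt, py, slope_limit, threshold):
    """Early through-POI line, vectorized over POI level ``py``.

    Returns (slope, norm2, clamped); all arrays matching ``py``.
    """
    py = np.asarray(py, dtype=float)
    n = len(te)
    if n == 0:
        z = np.zeros_like(py)
        return z, z.copy(), np.zeros_like(py, dtype=bool)
    d = te - pt
    s1, s2 = d.sum(), (d * d).sum()
    sy, sy2, sdy = ye.sum(), (ye * ye).sum(), (d * ye).sum()
    if s2 > 0:
        m_unc = (sdy - py * s1) / s2
    else:
        m_unc = np.zeros_like(py)
    m = np.clip(m_unc, -slope_limit, slope_limit)
    if np.any(d < 0):
        span = pt - te.min()
        y_low = ye.min()
        m_hi = (py - y_low) / span
        m_lo = (py - threshold) / span
        m = np.clip(m, m_lo, m_hi)
    clamped = m != m_unc
    norm2 = sy2 - 2 * py * sy + n * py * py - 2 * m * (sdy - py * s1) + m * m * s2
    return m, np.maximum(norm2, 0.0), clamped


def _late_linear_vec(tl, yl, pt, py):
    """Late through-POI line, vectorized over ``py`` → (slope, norm2)."""
    py = np.asarray(py, dtype=float)
    if len(tl) == 0:
        raise NoLateDataError("no data points at or after the POI")
    d = tl - pt
    s1, s2 = d.sum(), (d * d).sum()
    sy, sy2, sdy = yl.sum(), (yl * yl).sum(), (d * yl).sum()
    n = len(tl)
    if s2 > 0:
        m = (sdy - py * s1) / s2
    else:
        m = np.zeros_like(py)
    norm2 = sy2 - 2 * py * sy + n * py * py - 2 * m * (sdy - py * s1) + m * m * s2
    return m, np.maximum(norm2, 0.0)


def _late_parabola_vec(tl, yl, pt, py, coarse_slope, early_slope):
    """Constrained late parabola y = a d^2 + b d + py, vectorized over py.

    Exact active-set QP: the unconstrained least squares and the three
    constraint-boundary solutions (b at its lower bound, derivative at its
    positivity bound at the far end of the late domain, and their vertex)
    are evaluated and the feasible minimizer selected elementwise.
    Returns (a, b, norm2).
    """
    py = np.asarray(py, dtype=float)
    if len(tl) == 0:
        raise NoLateDataError("no data points at or after the POI")
    d = tl - pt
    dmax = float(d.max())
    n = len(tl)
    sy, sy2 = yl.sum(), (yl * yl).sum()
    s1, d2, d3, d4 = d.sum(), (d * d).sum(), (d ** 3).sum(), (d ** 4).sum()
    sdy, sd2y = (d * yl).sum(), (d * d * yl).sum()

    b_min = np.maximum(0.5 * np.asarray(coarse_slope), np.asarray(early_slope) + SLOPE_EPS)
    eps = SLOPE_EPS

    sr2 = sy2 - 2 * py * sy + n * py * py
    rhs1 = sd2y - py * d2          # sum d^2 r
    rhs2 = sdy - py * s1           # sum d r

    def norm2_of(a, b):
        v = sr2 - 2 * a * rhs1 - 2 * b * rhs2 + a * a * d4 + 2 * a * b * d3 + b * b * d2
        return np.maximum(v, 0.0)

    if dmax <= 0:
        # every late point sits at the POI time; model value is py there
        a = np.zeros_like(py)
        return a, b_min * np.ones_like(py), norm2_of(a, b_min * np.ones_like(py))

    ftol = 1e-9
    cands_a, cands_b = [], []

    det = d4 * d2 - d3 * d3
    scale = max(d4 * d2, 1e-300)
    if det > 1e-12 * scale:
        a_u = (rhs1 * d2 - d3 * rhs2) / det
        b_u = (d4 * rhs2 - d3 * rhs1) / det
        cands_a.append(a_u)
        cands_b.append(b_u)

    if d4 > 0:  # b on its lower bound
        a_2 = (rhs1 - b_min * d3) / d4
        cands_a.append(a_2)
        cands_b.append(b_min * np.ones_like(py))

    su2 = d4 - 4 * dmax * d3 + 4 * dmax * dmax * d2   # u = d^2 - 2 dmax d
    if su2 > 1e-12 * scale:  # derivative bound active at dmax
        sur = rhs1 - 2 * dmax * rhs2
        sud = d3 - 2 * dmax * d2
        a_3 = (sur - eps * sud) / su2
        cands_a.append(a_3)
        cands_b.append(eps - 2 * a_3 * dmax)

    a_4 = (eps - b_min) / (2 * dmax)  # vertex: both constraints active
    cands_a.append(a_4)
    cands_b.append(b_min * np.ones_like(py))

    best_a = best_b = None
    best_n2 = np.full_like(py, np.inf)
    for a_c, b_c in zip(cands_a, cands_b):
        a_c = np.broadcast_to(np.asarray(a_c, float), py.shape)
        b_c = np.broadcast_to(np.asarray(b_c, float), py.shape)
        feas = (b_c >= b_min - ftol) & (2 * a_c * dmax + b_c >= eps - ftol)
        n2 = np.where(feas, norm2_of(a_c, b_c), np.inf)
        take = n2 < best_n2
        if best_a is None:
            best_a, best_b = np.where(take, a_c, 0.0), np.where(take, b_c, 0.0)
        else:
            best_a = np.where(take, a_c, best_a)
            best_b = np.where(take, b_c, best_b)
        best_n2 = np.where(take, n2, best_n2)
    return best_a, best_b, best_n2


def _split(t, y, pt):
    """Early/late point sets; a node exactly at pt joins both."""
    early = t <= pt
    late = t >= pt
    return t[early], y[early], t[late], y[late]


def _poi_cost_vec(t, y, pt, py_vec, phase, slope_limit, threshold):
    """Cost components for one POI time and a vector of POI levels."""
    te, ye, tl, yl = _split(t, y, pt)
    m_e, n2_e, clamped = _early_fit_vec(te, ye, pt, py_vec, slope_limit, threshold)
    s_lin, n2_lin = _late_linear_vec(tl, yl, pt, py_vec)
    if phase == "coarse":
        return np.sqrt(n2_e), np.sqrt(n2_lin), (m_e, clamped, ("linear", s_lin))
    a, b, n2_p = _late_parabola_vec(tl, yl, pt, py_vec, s_lin, m_e)
    return np.sqrt(n2_e), np.sqrt(n2_p), (m_e, clamped, ("parabola", a, b))


# ---------------------------------------------------------------------------
# Spec-level scalar operations
# ---------------------------------------------------------------------------


def fit_linear_early(
    points,
    poi,
    slope_limit: float = SLOPE_LIMIT,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Through-POI line on the earlier points → (slope, norm, clamped)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    pt, py = poi
    m, n2, cl = _early_fit_vec(
        pts[:, 0], pts[:, 1], pt, np.array([py]), slope_limit, threshold
    )
    return float(m[0]), float(np.sqrt(n2[0])), bool(cl[0])


def fit_linear_late(points, poi):
    """Unconstrained through-POI line on the later points → (slope, norm)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    pt, py = poi
    m, n2 = _late_linear_vec(pts[:, 0], pts[:, 1], pt, np.array([py]))
    return float(m[0]), float(np.sqrt(n2[0]))


def fit_parabola_late(points, poi, coarse_late_slope, early_slope):
    """Constrained late parabola → (a, b, norm)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    pt, py = poi
    a, b, n2 = _late_parabola_vec(
        pts[:, 0], pts[:, 1], pt, np.array([py]),
        np.array([coarse_late_slope]), np.array([early_slope]),
    )
    return float(a[0]), float(b[0]), float(np.sqrt(n2[0]))


def included_points(profile: MelatoninProfile, labels: seg.SegmentLabels):
    mask = labels.included_node_mask(len(profile))
    return profile.times[mask], profile.concentrations[mask]


def poi_cost(
    profile: MelatoninProfile,
    labels: seg.SegmentLabels,
    poi,
    phase: str = "coarse",
    slope_limit: float = SLOPE_LIMIT,
    threshold: float = DEFAULT_THRESHOLD,
) -> PoiFit:
    """Full fit bookkeeping for one candidate breakpoint."""
    t, y = included_points(profile, labels)
    pt, py = float(poi[0]), float(poi[1])
    e_norm, l_norm, (m_e, clamped, late) = _poi_cost_vec(
        t, y, pt, np.array([py]), phase, slope_limit, threshold
    )
    if late[0] == "linear":
        kind, coeffs = "linear", (float(late[1][0]),)
    else:
        kind, coeffs = "parabola", (float(late[1][0]), float(late[2][0]))
    return PoiFit(
        pt=pt,
        py=py,
        early_slope=float(m_e[0]),
        early_clamped=bool(clamped[0]),
        late_kind=kind,
        late_coeffs=coeffs,
        early_norm=float(e_norm[0]),
        late_norm=float(l_norm[0]),
    )


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    k = int(np.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(max(k, 0) + 1)


def grid_search(
    profile: MelatoninProfile,
    labels: seg.SegmentLabels,
    roi: Roi,
    phase: str = "coarse",
    t_step: float = COARSE_T_STEP,
    y_step: float = COARSE_Y_STEP,
    slope_limit: float = SLOPE_LIMIT,
    threshold: float = DEFAULT_THRESHOLD,
    top_fraction: float = TOP_FRACTION,
) -> GridResult:
    """Score every grid POI in the ROI; argmin ties break to the earliest
    time then the lowest concentration. The coarse phase also records the
    bounding box of the lowest-cost decile for the refinement grid."""
    if t_step <= 0 or y_step <= 0:
        raise ValueError("grid steps must be positive")
    t_vals = _axis(roi.t_lo, roi.t_hi, t_step)
    y_vals = _axis(roi.y_lo, roi.y_hi, y_step)
    if len(t_vals) == 0 or len(y_vals) == 0:
        raise DegenerateRoiError("empty search grid")

    t, y = included_points(profile, labels)
    n_t, n_y = len(t_vals), len(y_vals)
    T = np.repeat(t_vals, n_y)
    Y = np.tile(y_vals, n_t)
    E = np.empty(n_t * n_y)
    L = np.empty(n_t * n_y)
    best = None  # (cost, flat_index)
    for i, pt in enumerate(t_vals):
        e, l, _ = _poi_cost_vec(t, y, pt, y_vals, phase, slope_limit, threshold)
        c = e + l
        E[i * n_y : (i + 1) * n_y] = e
        L[i * n_y : (i + 1) * n_y] = l
        j = int(np.argmin(c))  # first occurrence = lowest level
        if best is None or c[j] < best[0]:
            best = (float(c[j]), i * n_y + j)
    cost = E + L
    argmin = poi_cost(
        profile, labels, (T[best[1]], Y[best[1]]), phase, slope_limit, threshold
    )

    box = None
    if phase == "coarse":
        k = max(1, int(np.ceil(top_fraction * len(cost))))
        idx = np.argpartition(cost, k - 1)[:k]
        box = (
            float(T[idx].min()),
            float(T[idx].max()),
            float(Y[idx].min()),
            float(Y[idx].max()),
        )
    return GridResult(
        phase=phase,
        t_step=t_step,
        y_step=y_step,
        t=T,
        y=Y,
        early_norm=E,
        late_norm=L,
        cost=cost,
        argmin=argmin,
        top_fraction_box=box,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def estimate_dlmo(
    profile: MelatoninProfile,
    threshold: float = DEFAULT_THRESHOLD,
    multi_rise_interval: float = seg.DEFAULT_MULTI_RISE_INTERVAL,
    coarse_t_step: float = COARSE_T_STEP,
    coarse_y_step: float = COARSE_Y_STEP,
    refine_t_step: float = REFINE_STEP,
    refine_y_step: float = REFINE_STEP,
    slope_limit: float = SLOPE_LIMIT,
    rule2_enabled: bool = True,
    rule3_enabled: bool = True,
    lam: float = seg.DEFAULT_LAMBDA,
    seed: int = seg.DEFAULT_SEED,
    coarse_only: bool = False,
) -> DlmoResult:
    """Run the full pipeline: validate → segment → truncate → ROI →
    coarse grid → refinement grid → DLMO.

    Raises :class:`ProfileValidationError` when the profile has no dynamic
    part or too few points; geometric failures raise their specific
    errors. Batch drivers catch these per profile.
    """
    params = dict(
        threshold=threshold,
        multi_rise_interval=multi_rise_interval,
        coarse_t_step=coarse_t_step,
        coarse_y_step=coarse_y_step,
        refine_t_step=refine_t_step,
        refine_y_step=refine_y_step,
        slope_limit=slope_limit,
        rule2_enabled=rule2_enabled,
        rule3_enabled=rule3_enabled,
        lam=lam,
        seed=seed,
        coarse_only=coarse_only,
    )
    report = validate_and_trim(profile, threshold)
    if not report.ok:
        raise ProfileValidationError(
            report.status, f"profile {profile.id!r}: {report.status}"
        )
    prof = report.trimmed_profile
    labels = seg.label_segments(prof, threshold, multi_rise_interval)
    labels = seg.truncate_ascending(
        prof, labels, threshold, rule2_enabled, rule3_enabled, lam=lam, seed=seed
    )
    prof, labels = seg.add_left_node(prof, labels, threshold)
    roi = compute_roi(prof, labels, threshold)
    coarse = grid_search(
        prof, labels, roi, "coarse", coarse_t_step, coarse_y_step,
        slope_limit, threshold,
    )
    refine = None
    if not coarse_only:
        bt_lo, bt_hi, by_lo, by_hi = coarse.top_fraction_box
        refine_roi = Roi(t_lo=bt_lo, t_hi=bt_hi, y_lo=by_lo, y_hi=by_hi)
        refine = grid_search(
            prof, labels, refine_roi, "refine", refine_t_step, refine_y_step,
            slope_limit, threshold,
        )
    best = refine.argmin if refine is not None else coarse.argmin
    warnings = list(report.warnings) + list(labels.warnings)
    return DlmoResult(
        dlmo_hours=best.pt,
        dlmo_clock=hours_to_clock(best.pt),
        dlmo_conc=best.py,
        coarse=coarse,
        refine=refine,
        labels=labels,
        roi=roi,
        validation=report,
        profile=prof,
        params_echo=params,
        warnings=warnings,
    )
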