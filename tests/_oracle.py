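"""Independent brute-force reference for the two-phase breakpoint search.

This module re-implements the documented search contract from scratch so
the package's vectorized kernels can be checked against it:

- fits are solved with ``numpy.linalg.lstsq`` on explicitly built design
  matrices and scored with ``numpy.linalg.norm`` of actual residual
  vectors (the package instead expands the squared norms algebraically);
- the grid is walked with plain Python loops in time-major order, the
  argmin kept by strict ``<`` comparison (earliest time, then lowest
  concentration on ties);
- the constrained late parabola is solved by enumerating the active sets
  of its two linear inequality constraints and picking the feasible
  candidate with the smallest residual norm.

Only the documented numerical contract is shared (grid construction
``lo + step*k``, clamp order, constraint tolerances); no code is shared
with ``dlmokit.core``.

There is also an exhaustive grid oracle for the minimal-area
parallelogram objective.
"""

from __future__ import annotations

import math

import numpy as np

SLOPE_EPS = 1e-6
FEAS_TOL = 1e-9


def axis(lo: float, hi: float, step: float) -> list[float]:
    k = int(math.floor((hi - lo) / step + 1e-9))
    return [lo + step * i for i in range(max(k, 0) + 1)]


def early_fit(te, ye, pt, py, slope_limit, threshold):
    te = np.asarray(te, dtype=float)
    ye = np.asarray(ye, dtype=float)
    if te.size == 0:
        return 0.0, 0.0
    d = te - pt
    r = ye - py
    if float(np.sum(d * d)) > 0.0:
        sol, *_ = np.linalg.lstsq(d.reshape(-1, 1), r, rcond=None)
        m = float(sol[0])
    else:
        m = 0.0
    m = min(max(m, -slope_limit), slope_limit)
    if np.any(d < 0):
        span = pt - float(np.min(te))
        m_hi = (py - float(np.min(ye))) / span
        m_lo = (py - threshold) / span
        m = min(max(m, m_lo), m_hi)
    return m, float(np.linalg.norm(r - m * d))


def late_linear(tl, yl, pt, py):
    tl = np.asarray(tl, dtype=float)
    yl = np.asarray(yl, dtype=float)
    d = tl - pt
    r = yl - py
    if float(np.sum(d * d)) > 0.0:
        sol, *_ = np.linalg.lstsq(d.reshape(-1, 1), r, rcond=None)
        m = float(sol[0])
    else:
        m = 0.0
    return m, float(np.linalg.norm(r - m * d))


def late_parabola(tl, yl, pt, py, coarse_slope, early_slope):
    """Exact solution of min ||r - a d^2 - b d|| s.t. b >= b_min and
    2 a dmax + b >= eps, by active-set enumeration."""
    tl = np.asarray(tl, dtype=float)
    yl = np.asarray(yl, dtype=float)
    d = tl - pt
    r = yl - py
    dmax = float(np.max(d))
    b_min = max(0.5 * coarse_slope, early_slope + SLOPE_EPS)
    eps = SLOPE_EPS

    def norm_of(a, b):
        return float(np.linalg.norm(r - a * d * d - b * d))

    if dmax <= 0:
        return 0.0, b_min, norm_of(0.0, b_min)

    candidates = []
    # unconstrained 2-parameter least squares
    X = np.column_stack([d * d, d])
    if np.linalg.matrix_rank(X) == 2:
        sol, *_ = np.linalg.lstsq(X, r, rcond=None)
        candidates.append((float(sol[0]), float(sol[1])))
    # b at its lower bound
    if float(np.sum(d ** 4)) > 0.0:
        sol, *_ = np.linalg.lstsq((d * d).reshape(-1, 1), r - b_min * d, rcond=None)
        candidates.append((float(sol[0]), b_min))
    # derivative bound active at dmax: b = eps - 2 a dmax
    u = d * d - 2.0 * dmax * d
    if float(np.sum(u * u)) > 0.0:
        sol, *_ = np.linalg.lstsq(u.reshape(-1, 1), r - eps * d, rcond=None)
        a3 = float(sol[0])
        candidates.append((a3, eps - 2.0 * a3 * dmax))
    # both constraints active
    candidates.append(((eps - b_min) / (2.0 * dmax), b_min))

    best = None
    for a, b in candidates:
        if b < b_min - FEAS_TOL or 2.0 * a * dmax + b < eps - FEAS_TOL:
            continue
        n = norm_of(a, b)
        if best is None or n < best[2]:
            best = (a, b, n)
    return best


def poi_cost(t, y, pt, py, phase, slope_limit, threshold):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    te, ye = t[t <= pt], y[t <= pt]
    tl, yl = t[t >= pt], y[t >= pt]
    m_e, norm_e = early_fit(te, ye, pt, py, slope_limit, threshold)
    s_lin, norm_lin = late_linear(tl, yl, pt, py)
    if phase == "coarse":
        return norm_e + norm_lin
    _, _, norm_p = late_parabola(tl, yl, pt, py, s_lin, m_e)
    return norm_e + norm_p


def two_phase(
    t,
    y,
    roi,
    coarse_t_step=0.1,
    coarse_y_step=0.2,
    refine_step=0.01,
    top_fraction=0.10,
    slope_limit=0.2,
    threshold=2.3,
):
    """Brute-force two-phase search over the ROI. ``roi`` is an object with
    t_lo/t_hi/y_lo/y_hi. Returns ((pt, py, cost) coarse, (pt, py, cost)
    refine)."""

    def scan(t_vals, y_vals, phase):
        pts, costs = [], []
        best = None
        for pt in t_vals:
            for py in y_vals:
                c = poi_cost(t, y, pt, py, phase, slope_limit, threshold)
                pts.append((pt, py))
                costs.append(c)
                if best is None or c < best[2]:
                    best = (pt, py, c)
        return pts, costs, best

    t_vals = axis(roi.t_lo, roi.t_hi, coarse_t_step)
    y_vals = axis(roi.y_lo, roi.y_hi, coarse_y_step)
    pts, costs, coarse_best = scan(t_vals, y_vals, "coarse")

    k = max(1, int(math.ceil(top_fraction * len(costs))))
    order = np.argsort(np.asarray(costs), kind="stable")[:k]
    bt = [pts[i][0] for i in order]
    by = [pts[i][1] for i in order]
    rt = axis(min(bt), max(bt), refine_step)
    ry = axis(min(by), max(by), refine_step)
    _, _, refine_best = scan(rt, ry, "refine")
    return coarse_best, refine_best


# ---------------------------------------------------------------------------
# Parallelogram grid oracle
# ---------------------------------------------------------------------------


def parallelogram_grid_oracle(points, lam=1e3, n_pl=100, n_pr=100, n_ps=50):
    """Exhaustive minimum of area + lam*containment over an n_pl x n_pr x
    n_ps parameter grid. Returns (best objective, (pl, pr, ps))."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    ymin, ymax = float(np.min(y)), float(np.max(y))
    h = ymax - ymin
    span = max(float(np.ptp(x)), 1e-3)
    pl_vals = np.linspace(float(np.min(x)) - 2.0 * span, float(np.max(x)), n_pl)
    pr_vals = np.linspace(float(np.min(x)), float(np.max(x)) + 2.0 * span, n_pr)
    dx = np.subtract.outer(x, x)
    dy = np.subtract.outer(y, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(dx != 0, np.abs(dy / dx), 0.0)
    s_steep = float(np.max(slopes))
    if s_steep <= 0:
        s_steep = h / span
    ps_vals = np.geomspace(1e-2 * s_steep, 50.0 * s_steep, n_ps)

    best = (np.inf, None)
    PL = pl_vals[:, None]
    PR = pr_vals[None, :]
    width = PR - PL  # (n_pl, n_pr)
    for ps in ps_vals:
        xs = x - (y - ymin) / ps  # (n_points,)
        pen = np.maximum(0.0, PL[:, :, None] - xs) + np.maximum(
            0.0, xs - PR[:, :, None]
        )
        obj = width * h + lam * pen.sum(axis=2)
        obj = np.where(width >= 0, obj, np.inf)
        i, j = np.unravel_index(int(np.argmin(obj)), obj.shape)
        if obj[i, j] < best[0]:
            best = (float(obj[i, j]), (float(pl_vals[i]), float(pr_vals[j]), float(ps)))
    return best
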