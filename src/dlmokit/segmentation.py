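"""Segment classification and ascending-region truncation.

A *node* is a melatonin sample; a *segment* is the interval between two
adjacent nodes, containing its right node and excluding its left node.
Segments are classified as ``base`` (pre-rise), ``intermediate``
(transition), ``ascending`` (the melatonin rise used for the late fit) or
``excluded`` (removed from the fit set). The ascending region is then
pruned by three truncation rules so the rise kept for fitting is rapid and
consistent; rule 2 is geometric, based on a minimal-area parallelogram
enclosing the rise points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import (
    DegenerateGeometryError,
    NoAscendingError,
    OptimizationFailureError,
)
from .profile import DEFAULT_THRESHOLD, MelatoninProfile

DEFAULT_MULTI_RISE_INTERVAL = 2.0  # hours
DEFAULT_LAMBDA = 1e3  # containment-penalty weight, >> 1
DEFAULT_SEED = 1234

BASE = "base"
INTERMEDIATE = "intermediate"
ASCENDING = "ascending"
EXCLUDED = "excluded"


@dataclass
class SegmentLabels:
    """Per-segment classification plus consistency bookkeeping.

    ``labels[i]`` describes the segment between node ``i`` and ``i+1``.
    ``excluded_nodes`` holds node indices dropped from every fit set
    (leading above-threshold base nodes; nodes stranded beyond the kept
    ascending region after truncation).
    """

    labels: list[str]
    slopes: np.ndarray
    base_consistent: bool = True
    added_node: bool = False
    base_head_truncated: int = 0
    excluded_nodes: set[int] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def indices(self, label: str) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == label]

    @property
    def ascending_segments(self) -> list[int]:
        return self.indices(ASCENDING)

    @property
    def base_segments(self) -> list[int]:
        return self.indices(BASE)

    @property
    def intermediate_segments(self) -> list[int]:
        return self.indices(INTERMEDIATE)

    def included_node_mask(self, n_nodes: int) -> np.ndarray:
        mask = np.ones(n_nodes, dtype=bool)
        for i in self.excluded_nodes:
            mask[i] = False
        return mask


@dataclass(frozen=True)
class Parallelogram:
    """Minimal-area parallelogram around the rise points.

    Lower and upper edges are horizontal at the lowest/highest enclosed
    melatonin levels; lateral edges share slope ``ps > 0``. ``pl``/``pr``
    are the lower-left and lower-right x-coordinates.
    """

    pl: float
    pr: float
    ps: float
    ymin: float
    ymax: float

    @property
    def area(self) -> float:
        # shear-invariant: width x height
        return (self.pr - self.pl) * (self.ymax - self.ymin)

    @property
    def longest_diagonal_slope(self) -> float:
        h = self.ymax - self.ymin
        return h / ((self.pr - self.pl) + h / self.ps)

    @property
    def vertices(self) -> np.ndarray:
        h = self.ymax - self.ymin
        dx = h / self.ps
        return np.array(
            [
                [self.pl, self.ymin],
                [self.pr, self.ymin],
                [self.pr + dx, self.ymax],
                [self.pl + dx, self.ymax],
            ]
        )


def segment_slopes(profile: MelatoninProfile) -> np.ndarray:
    """tan(theta) of every segment, in pg/mL per hour."""
    return np.diff(profile.concentrations) / np.diff(profile.times)


def _up_crossings(c: np.ndarray, threshold: float) -> list[int]:
    """Segment indices crossing the threshold upward (left <= thr < right)."""
    return [i for i in range(len(c) - 1) if c[i] <= threshold < c[i + 1]]


def label_segments(
    profile: MelatoninProfile,
    threshold: float = DEFAULT_THRESHOLD,
    multi_rise_interval: float = DEFAULT_MULTI_RISE_INTERVAL,
) -> SegmentLabels:
    """Classify every segment as base / intermediate / ascending / excluded.

    Base: every sub-threshold segment with non-positive slope, and every
    downward threshold crossing, plus all segments to its left — spent
    rises followed by a decline are thereby absorbed into base. Ascending:
    the last upward threshold crossing and all subsequent above-threshold
    segments, extended by the steepness rule (segments steeper than half
    the steepest non-base segment, plus gaps between them) and an iterative
    left-extension rule. Leading above-threshold base nodes are excluded.
    Remaining gaps are intermediate.
    """
    t, c = profile.times, profile.concentrations
    n_seg = len(t) - 1
    if n_seg < 2:
        raise NoAscendingError("profile too short to segment")
    slopes = segment_slopes(profile)
    warnings: list[str] = []

    # ---- base region ----------------------------------------------------
    def is_base_seed(i: int) -> bool:
        below = c[i] <= threshold and c[i + 1] <= threshold
        down_cross = c[i] > threshold and c[i + 1] <= threshold
        return (below and slopes[i] <= 0) or down_cross

    seeds = [i for i in range(n_seg) if is_base_seed(i)]
    base_end = seeds[-1] if seeds else -1  # segments 0..base_end are base

    # ---- ascending rule 1: last upward crossing + everything above ------
    ups = _up_crossings(c, threshold)
    candidates = [i for i in ups if i > base_end]
    if not candidates:
        raise NoAscendingError(
            "no upward threshold crossing outside the base region"
        )
    if len(ups) >= 2 and (t[ups[-1]] - t[ups[-2]]) < multi_rise_interval:
        warnings.append(
            "multiple rises above threshold closer than the multi-rise "
            "interval; using the later rise"
        )
    first_asc = candidates[-1]
    ascending = set(range(first_asc, n_seg))

    # ---- ascending rule 2: steepness in the non-base portion ------------
    non_base = list(range(base_end + 1, n_seg))
    if non_base:
        s = slopes[non_base]
        steepest = float(np.max(s))
        if steepest > 0:
            # ties in "steepest" break toward the rightmost segment, but the
            # half-steepness criterion only needs the value
            steep = [i for i in non_base if slopes[i] > 0.5 * steepest]
            if steep:
                lo, hi = min(steep), max(steep)
                ascending.update(range(lo, hi + 1))  # incl. segments between

    # ---- ascending rule 3: iterative left extension ---------------------
    for _ in range(n_seg):  # fixed-point iteration, capped
        first = min(ascending)
        prev = first - 1
        if prev <= base_end or prev < 0:
            break
        if slopes[prev] >= 0.5 * slopes[first]:
            ascending.add(prev)
        else:
            break

    labels = []
    for i in range(n_seg):
        if i in ascending:
            labels.append(ASCENDING)
        elif i <= base_end:
            labels.append(BASE)
        else:
            labels.append(INTERMEDIATE)

    out = SegmentLabels(labels=labels, slopes=slopes, warnings=warnings)

    # ---- base head truncation: leading above-threshold nodes ------------
    base_nodes = list(range(0, base_end + 2)) if base_end >= 0 else []
    head = 0
    while head < len(base_nodes) and c[base_nodes[head]] > threshold:
        head += 1
    if head:
        out.base_head_truncated = head
        out.excluded_nodes.update(range(head))
        for i in range(min(head, n_seg)):
            if labels[i] == BASE:
                labels[i] = EXCLUDED
        out.warnings.append(
            f"{head} leading above-threshold base node(s) excluded"
        )

    # ---- base consistency flag ------------------------------------------
    inconsistent = any(
        c[i] > threshold and c[i + 1] <= threshold
        for i in range(n_seg)
        if labels[i] == BASE or i <= base_end
    )
    kept_base_nodes = [i for i in base_nodes if i >= head]
    for a, b in zip(kept_base_nodes, kept_base_nodes[1:]):
        if abs(c[b] - c[a]) > threshold / 2.0:
            inconsistent = True
            break
    if inconsistent:
        out.base_consistent = False
        out.warnings.append("Profile consistency at base part: no")

    return out


# ---------------------------------------------------------------------------
# Parallelogram fitting (truncation rule 2)
# ---------------------------------------------------------------------------


def _slab_bounds(x: np.ndarray, y: np.ndarray, ymin: float, ps: float):
    """Sheared x-coordinates: x' = x - (y - ymin)/ps. The minimal slab for
    this lateral slope is [min x', max x'] with zero containment penalty."""
    xs = x - (y - ymin) / ps
    return float(np.min(xs)), float(np.max(xs))


def parallelogram_objective(
    p: np.ndarray, x: np.ndarray, y: np.ndarray, ymin: float, ymax: float, lam: float
) -> float:
    """Area + lambda * containment penalty for parameters (pl, pr, ps)."""
    pl, pr, ps = p
    if ps <= 0 or pr < pl:
        return np.inf
    area = (pr - pl) * (ymax - ymin)
    xs = x - (y - ymin) / ps  # horizontal position relative to lower edge
    pen = np.sum(np.maximum(0.0, pl - xs) + np.maximum(0.0, xs - pr))
    return area + lam * pen


def fit_parallelogram(
    points,
    lam: float = DEFAULT_LAMBDA,
    seed: int = DEFAULT_SEED,
    method: str = "shear",
) -> Parallelogram:
    """Fit the minimal-area parallelogram around the rise points.

    Minimizes ``area + lam * C(p, x)`` where C sums the horizontal
    distances of points falling outside the slab between the two lateral
    edges; the horizontal top/bottom edges pass through the highest and
    lowest points by construction.

    For any fixed lateral slope ``ps`` the optimal slab is given in closed
    form by shearing the points, which reduces the problem to a 1-D search
    over ``ps`` (method ``"shear"``, default: deterministic scan plus
    bounded refinement and a Nelder-Mead polish of the full objective).
    Method ``"anneal"`` runs scipy's seeded dual annealing on the raw
    3-parameter objective instead, as a slower cross-check.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise DegenerateGeometryError("need >= 2 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    ymin, ymax = float(np.min(y)), float(np.max(y))
    if ymax <= ymin:
        raise DegenerateGeometryError("all melatonin levels equal; no vertical extent")

    dx = np.subtract.outer(x, x)
    dy = np.subtract.outer(y, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        pair_slopes = np.where(dx != 0, dy / np.abs(dx), 0.0)
    s_steep = float(np.max(np.abs(pair_slopes)))
    if s_steep <= 0:
        s_steep = (ymax - ymin) / max(np.ptp(x), 1e-6)
    ps_hi = 50.0 * s_steep
    ps_lo = max(1e-4 * s_steep, 1e-9)

    def width(ps: float) -> float:
        lo, hi = _slab_bounds(x, y, ymin, ps)
        return hi - lo

    if method == "anneal":
        span = max(np.ptp(x), 1e-3)
        bounds = [
            (np.min(x) - 2 * span, np.max(x)),
            (np.min(x), np.max(x) + 2 * span),
            (ps_lo, ps_hi),
        ]
        res = optimize.dual_annealing(
            parallelogram_objective,
            bounds=bounds,
            args=(x, y, ymin, ymax, lam),
            seed=seed,
            maxiter=200,
            x0=np.array([np.min(x), np.max(x), min(s_steep, ps_hi)]),
        )
        if not np.isfinite(res.fun):
            raise OptimizationFailureError("annealing failed to find a finite optimum")
        pl, pr, ps = res.x
        best_f = float(res.fun)
        # local polish of ps (annealing alone leaves the narrow valley in ps
        # under-resolved), then snap the slab onto the points: removes any
        # residual containment violation without increasing the objective
        res_ps = optimize.minimize_scalar(
            width, bounds=(max(ps_lo, ps / 4), min(ps_hi, ps * 4)), method="bounded"
        )
        for cand_ps in (float(res_ps.x), float(ps)):
            lo, hi = _slab_bounds(x, y, ymin, cand_ps)
            f = parallelogram_objective(
                np.array([lo, hi, cand_ps]), x, y, ymin, ymax, lam
            )
            if f <= best_f:
                pl, pr, ps, best_f = lo, hi, cand_ps, f
        return Parallelogram(pl=float(pl), pr=float(pr), ps=float(ps), ymin=ymin, ymax=ymax)

    # deterministic shear reduction: 1-D in ps
    grid = np.geomspace(ps_lo, ps_hi, 200)
    widths = [width(ps) for ps in grid]
    k = int(np.argmin(widths))
    lo_b = grid[max(k - 1, 0)]
    hi_b = grid[min(k + 1, len(grid) - 1)]
    res1 = optimize.minimize_scalar(width, bounds=(lo_b, hi_b), method="bounded")
    ps_best = float(res1.x) if res1.fun <= widths[k] else float(grid[k])
    lo, hi = _slab_bounds(x, y, ymin, ps_best)
    best = np.array([lo, hi, ps_best])
    best_f = parallelogram_objective(best, x, y, ymin, ymax, lam)

    # polish on the full 3-parameter objective
    res2 = optimize.minimize(
        parallelogram_objective,
        best,
        args=(x, y, ymin, ymax, lam),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400},
    )
    if res2.fun < best_f and res2.x[2] > 0:
        lo2, hi2 = _slab_bounds(x, y, ymin, res2.x[2])
        snapped = np.array([lo2, hi2, res2.x[2]])
        if parallelogram_objective(snapped, x, y, ymin, ymax, lam) <= res2.fun:
            best = snapped
        else:
            best = res2.x
    return Parallelogram(
        pl=float(best[0]), pr=float(best[1]), ps=float(best[2]), ymin=ymin, ymax=ymax
    )


def parallelogram_ratio(p: Parallelogram) -> float:
    """Slope of the longest diagonal divided by the lateral-edge slope."""
    if p.ps <= 0:
        raise DegenerateGeometryError("lateral slope must be positive")
    if p.pr < p.pl:
        raise DegenerateGeometryError("pr must be >= pl")
    return p.longest_diagonal_slope / p.ps


# ---------------------------------------------------------------------------
# Ascending truncation
# ---------------------------------------------------------------------------


def ascending_points(
    profile: MelatoninProfile, labels: SegmentLabels
) -> np.ndarray:
    """Rise points for the parallelogram: all ascending nodes plus the last
    node preceding the ascending region."""
    asc = labels.ascending_segments
    if not asc:
        raise NoAscendingError("no ascending segments")
    nodes = sorted({asc[0]} | {i + 1 for i in asc})
    return np.column_stack([profile.times[nodes], profile.concentrations[nodes]])


def truncate_ascending(
    profile: MelatoninProfile,
    labels: SegmentLabels,
    threshold: float = DEFAULT_THRESHOLD,
    rule2_enabled: bool = True,
    rule3_enabled: bool = True,
    lam: float = DEFAULT_LAMBDA,
    seed: int = DEFAULT_SEED,
) -> SegmentLabels:
    """Apply the three ascending-truncation rules in order.

    1. Drop trailing ascending segments with non-positive slope (applied
       repeatedly until the rightmost kept segment rises).
    2. Parallelogram rule: refit the minimal-area parallelogram around the
       rise; while the longest-diagonal/lateral slope ratio is not > 1/2,
       drop the last ascending segment and refit.
    3. Drop the rightmost segment while it is less than half as steep as
       the steepest remaining ascending segment.

    Truncated segments are relabeled ``excluded`` and their stranded right
    nodes leave the fit set. Rules 2 and 3 can be disabled.
    """
    asc = labels.ascending_segments
    if not asc:
        raise NoAscendingError("no ascending segments to truncate")
    slopes = labels.slopes
    kept = list(asc)

    def drop_last(reason: str):
        seg = kept.pop()
        labels.labels[seg] = EXCLUDED
        labels.excluded_nodes.add(seg + 1)
        labels.warnings.append(f"ascending segment {seg} truncated ({reason})")
        if not kept:
            raise NoAscendingError(
                f"truncation exhausted the ascending region ({reason})"
            )

    # rule 1: non-positive trailing slope
    while kept and slopes[kept[-1]] <= 0:
        drop_last("rule 1: non-positive slope")

    # rule 2: parallelogram ratio
    if rule2_enabled:
        for _ in range(len(asc)):
            if len(kept) < 1:
                break
            pts_nodes = sorted({kept[0]} | {i + 1 for i in kept})
            pts = np.column_stack(
                [profile.times[pts_nodes], profile.concentrations[pts_nodes]]
            )
            if np.ptp(pts[:, 1]) <= 0:
                break  # flat rise is degenerate; leave to rule 3 / errors
            para = fit_parallelogram(pts, lam=lam, seed=seed)
            if parallelogram_ratio(para) > 0.5:
                break
            drop_last("rule 2: parallelogram ratio <= 1/2")
        else:
            labels.warnings.append("rule 2 iteration cap reached")

    # rule 3: rightmost at least half as steep as the steepest remaining
    if rule3_enabled:
        while len(kept) > 1 and slopes[kept[-1]] < 0.5 * float(
            np.max(slopes[kept])
        ):
            drop_last("rule 3: rightmost less than half the steepest")

    return labels


def add_left_node(
    profile: MelatoninProfile,
    labels: SegmentLabels,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[MelatoninProfile, SegmentLabels]:
    """Prepend a synthetic node 30 min left of the profile when the whole
    profile is ascending.

    Applies only when every segment is ascending and the leftmost node is
    the only node below half the threshold; the new node gets level
    ``max(conc[0] / 2, 0)`` and the new segment is intermediate. Otherwise
    the inputs are returned unchanged.
    """
    n_seg = len(profile) - 1
    non_excluded = [lab for lab in labels.labels if lab != EXCLUDED]
    all_ascending = bool(non_excluded) and all(lab == ASCENDING for lab in non_excluded)
    below_half = np.flatnonzero(profile.concentrations < threshold / 2.0)
    if not (all_ascending and len(below_half) == 1 and below_half[0] == 0):
        return profile, labels
    new_t = profile.times[0] - 0.5
    new_c = max(profile.concentrations[0] / 2.0, 0.0)
    new_profile = MelatoninProfile(
        id=profile.id,
        times=np.concatenate([[new_t], profile.times]),
        concentrations=np.concatenate([[new_c], profile.concentrations]),
    )
    new_slopes = segment_slopes(new_profile)
    new_labels = SegmentLabels(
        labels=[INTERMEDIATE] + list(labels.labels),
        slopes=new_slopes,
        base_consistent=labels.base_consistent,
        added_node=True,
        base_head_truncated=labels.base_head_truncated,
        excluded_nodes={i + 1 for i in labels.excluded_nodes},
        warnings=labels.warnings + ["synthetic node added 30 min to the left"],
    )
    return new_profile, new_labels
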