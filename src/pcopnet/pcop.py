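"""Principal curves of oriented points (PCOP) in two dimensions.

A PCOP summarises a 2-D data cloud without assuming which variable depends
on which. It generalises, locally, the principal-component property that
projection variance is minimised orthogonally to the first principal
component: a *principal oriented point* (POP) is the local mean of a data
neighbourhood projected onto the neighbourhood's first principal axis,
together with that axis as a local tangent. Chaining POPs from one extreme
of the cloud to the other (or around it, for closed shapes) yields the
curve.

The fit is fully deterministic: the walk starts at the data point extreme
along the global first principal component and advances by a fixed fraction
of the cloud diameter, re-estimating the local principal direction at every
step and keeping its sign aligned with the direction of travel.

Two derived quantities drive everything downstream:

* the **uncorrelation factor** ``f`` in [0, 1] — orthogonal residual
  variance about the fitted polyline, normalised by the cloud's variance per
  transverse dimension and multiplied by a morphology penalty for curves
  much longer than the cloud. ``f ≈ 0`` means the curve explains the cloud
  (strong, possibly nonlinear, correlation); ``f ≈ 1`` means the cloud is
  structureless.
* **curvature points** — POPs where the curve's direction, measured between
  chords spanning two neighbourhood widths on each side, turns by more than
  an angle threshold. Their presence marks a relationship as nonlinear; a
  straight relationship has none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError, ParameterError

MIN_POINTS = 20

DEFAULT_BANDWIDTH_FRACTION = 0.2
DEFAULT_STEP_FRACTION = 0.05
DEFAULT_MIN_NEIGHBOURHOOD = 10

#: Steps of path length a closed curve must cover before the walk may close.
_MIN_STEPS_BEFORE_CLOSURE = 10


@dataclass
class PcopParams:
    """Tunable parameters of the PCOP fit.

    bandwidth_fraction
        Fraction of all points forming each local neighbourhood.
    step_fraction
        Advance per step, as a fraction of the cloud diameter.
    min_neighbourhood
        Lower bound on the neighbourhood size.
    """

    bandwidth_fraction: float = DEFAULT_BANDWIDTH_FRACTION
    step_fraction: float = DEFAULT_STEP_FRACTION
    min_neighbourhood: int = DEFAULT_MIN_NEIGHBOURHOOD

    def __post_init__(self) -> None:
        if not 0 < self.bandwidth_fraction <= 1:
            raise ParameterError("bandwidth_fraction must lie in (0, 1]")
        if not 0 < self.step_fraction <= 0.5:
            raise ParameterError("step_fraction must lie in (0, 0.5]")
        if self.min_neighbourhood < 3:
            raise ParameterError("min_neighbourhood must be >= 3")

    @property
    def angle_window(self) -> int:
        """POPs per side over which turn angles are measured.

        Each chord spans two local-neighbourhood widths so the angle probes
        the curve's shape; at the step scale angles only measure fit jitter.
        """
        return max(1, round(2.0 * self.bandwidth_fraction / self.step_fraction))


@dataclass
class POP:
    """A principal oriented point: local position, unit tangent, support size."""

    position: np.ndarray
    direction: np.ndarray
    support: int


@dataclass
class PrincipalCurve:
    """Ordered POP chain with its uncorrelation factor.

    ``closed`` is true when the walk returned to its starting POP within one
    step length (e.g. a circle-shaped relationship).
    """

    pops: list[POP]
    f: float = math.nan
    closed: bool = False
    angle_window: int = 4
    diameter: float = math.nan

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.pops])

    def __len__(self) -> int:
        return len(self.pops)


@dataclass
class CurvaturePoint:
    """A POP where the curve's slope changes beyond the threshold in force."""

    pop_index: int
    turn_angle_deg: float


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _principal_direction(points: np.ndarray) -> np.ndarray | None:
    """First principal axis of a 2-D point set (closed form, deterministic)."""
    d = points - points.mean(axis=0)
    sxx = float(np.dot(d[:, 0], d[:, 0]))
    syy = float(np.dot(d[:, 1], d[:, 1]))
    sxy = float(np.dot(d[:, 0], d[:, 1]))
    if sxx + syy <= 0.0:
        return None
    theta = 0.5 * math.atan2(2.0 * sxy, sxx - syy)
    return np.array([math.cos(theta), math.sin(theta)])


def _knn(points: np.ndarray, centre: np.ndarray, k: int) -> np.ndarray:
    d2 = ((points - centre) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")  # ties broken by index: deterministic
    return order[:k]


def _march(points: np.ndarray, start: np.ndarray, direction: np.ndarray,
           k: int, step: float, detect_closure: bool):
    """Walk from ``start`` along ``direction``, emitting POPs until the data ends
    (or, when ``detect_closure``, until the walk returns to its first POP)."""
    positions: list[np.ndarray] = []
    tangents: list[np.ndarray] = []
    max_steps = max(200, int(8.0 * len(points)))
    p = start.astype(float).copy()
    d = direction / np.linalg.norm(direction)
    closed = False
    for it in range(max_steps):
        idx = _knn(points, p, k)
        nb = points[idx]
        u = _principal_direction(nb)
        if u is None:
            break
        if float(u @ d) < 0.0:
            u = -u
        m = nb.mean(axis=0)
        pop = m + float((p - m) @ u) * u
        if positions and float(np.linalg.norm(pop - positions[-1])) < 1e-12:
            break
        if len(positions) >= 2 and float((pop - positions[-1]) @ tangents[-1]) < -step:
            break  # pathological backward jump across a data gap
        positions.append(pop)
        tangents.append(u)
        nxt = pop + step * u
        if (detect_closure and it >= _MIN_STEPS_BEFORE_CLOSURE
                and float(np.linalg.norm(nxt - positions[0])) < step):
            closed = True
            break
        # stop at the hull: no data anywhere ahead of the POP (the local
        # neighbourhood can be narrower than one step in dense regions)
        ahead = float(((points - pop) @ u).max())
        if ahead <= 0.55 * step:
            break
        p = nxt
        d = u
    return positions, tangents, closed


def fit_pcop(points, params: PcopParams | None = None) -> PrincipalCurve:
    """Fit a PCOP to a 2-D cloud; deterministic for fixed input and params.

    Raises :class:`InsufficientDataError` for fewer than 20 points and
    :class:`DegenerateInputError` when all points coincide. The returned
    curve already carries its uncorrelation factor ``f``.
    """
    params = params or PcopParams()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < MIN_POINTS:
        raise InsufficientDataError(f"PCOP needs >= {MIN_POINTS} points, got {n}")
    if not np.isfinite(pts).all():
        raise ParameterError("points must be finite")

    diameter = _cloud_diameter(pts)
    if diameter < 1e-12:
        raise DegenerateInputError("degenerate cloud: all points coincide")
    step = params.step_fraction * diameter
    k = min(n, max(params.min_neighbourhood, round(params.bandwidth_fraction * n)))

    v1 = _principal_direction(pts)
    if v1 is None:  # unreachable given diameter check, kept defensive
        raise DegenerateInputError("degenerate cloud: zero variance")
    # orient PC1 toward increasing first coordinate (tie: increasing second)
    if v1[0] < 0 or (v1[0] == 0 and v1[1] < 0):
        v1 = -v1
    proj = pts @ v1
    start = pts[int(np.argmin(proj))]

    fwd_pos, fwd_dir, closed = _march(pts, start, v1, k, step, detect_closure=True)
    if closed:
        positions, tangents = fwd_pos, fwd_dir
    else:
        back_pos, back_dir, _ = _march(pts, start, -v1, k, step, detect_closure=False)
        positions = [p for p in reversed(back_pos)]
        tangents = [-t for t in reversed(back_dir)]
        if positions and fwd_pos and np.linalg.norm(positions[-1] - fwd_pos[0]) < 1e-9:
            positions = positions[:-1]
            tangents = tangents[:-1]
        positions += fwd_pos
        tangents += fwd_dir

    if len(positions) < 2:
        # walk stalled immediately (local direction orthogonal to the data
        # extent, typical of structureless clouds): degrade to the global
        # principal line between the projection extremes
        t = pts @ v1
        centre = pts.mean(axis=0)
        c0 = float(t.min() - t.mean())
        c1 = float(t.max() - t.mean())
        positions = [centre + c0 * v1, centre + 0.5 * (c0 + c1) * v1,
                     centre + c1 * v1]
        tangents = [v1, v1, v1]
        closed = False

    pops = [POP(p, t, k) for p, t in zip(positions, tangents)]
    curve = PrincipalCurve(pops=pops, closed=closed,
                           angle_window=params.angle_window, diameter=diameter)
    curve.f = uncorrelation_factor(curve, pts)
    return curve


def _cloud_diameter(pts: np.ndarray) -> float:
    """Max pairwise distance; exact O(n^2), fine at expression-sample sizes."""
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# uncorrelation factor
# ---------------------------------------------------------------------------

def _point_polyline_sqdist(pts: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Squared distance from each point to the nearest polyline segment."""
    a = verts[:-1]
    b = verts[1:]
    ab = b - a                                   # (s, 2)
    ab2 = (ab ** 2).sum(axis=1)                  # (s,)
    ab2[ab2 == 0] = 1.0
    ap = pts[:, None, :] - a[None, :, :]         # (n, s, 2)
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / ab2[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d2 = ((pts[:, None, :] - proj) ** 2).sum(axis=2)
    return d2.min(axis=1)


def uncorrelation_factor(curve: PrincipalCurve, points) -> float:
    """Uncorrelation factor ``f`` in [0, 1] of a fitted curve on its cloud.

    f = clip( (mean squared orthogonal distance to the polyline)
              / (cloud variance per transverse dimension)
              × max(1, curve length / (2 × cloud diameter)), 0, 1)

    The normalisation makes a structureless isotropic cloud score ≈ 1 and a
    noiseless functional relationship score ≈ 0; the length factor penalises
    overfitted wiggly curves. Rotation invariant.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ParameterError("empty point set")
    verts = curve.positions
    if len(verts) < 2:
        raise ParameterError("curve must have at least 2 POPs")
    if curve.closed:
        verts = np.vstack([verts, verts[:1]])
    resid = float(_point_polyline_sqdist(pts, verts).mean())
    centred = pts - pts.mean(axis=0)
    total = float((centred ** 2).sum(axis=1).mean())
    if total <= 0:
        raise DegenerateInputError("cloud has zero variance")
    per_dim = total / 2.0
    length = float(np.linalg.norm(np.diff(verts, axis=0), axis=1).sum())
    diameter = curve.diameter if math.isfinite(curve.diameter) else _cloud_diameter(pts)
    penalty = max(1.0, length / (2.0 * diameter)) if diameter > 0 else 1.0
    return float(np.clip(resid / per_dim * penalty, 0.0, 1.0))


# ---------------------------------------------------------------------------
# curvature points
# ---------------------------------------------------------------------------

def _chord_angles(curve: PrincipalCurve) -> tuple[np.ndarray, np.ndarray]:
    """Interior angle (deg) at each POP between chords spanning ``angle_window``
    POPs on either side; NaN where the window does not fit.

    Returns (interior_angles, signed_fine_turns); the latter are the signed
    turn deviations between *consecutive* segments, used for cumulative
    turning.
    """
    pos = curve.positions
    m = len(pos)
    w = max(1, min(curve.angle_window, (m - 1) // 2))
    angles = np.full(m, np.nan)

    def at(i: int) -> np.ndarray:
        return pos[i % m] if curve.closed else pos[i]

    idx_range = range(m) if curve.closed else range(w, m - w)
    for i in idx_range:
        a = at(i) - at(i - w)
        b = at(i + w) - at(i)
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-15 or nb < 1e-15:
            continue
        cosang = float(np.clip((a @ b) / (na * nb), -1.0, 1.0))
        deviation = math.degrees(math.acos(cosang))
        angles[i] = 180.0 - deviation

    fine = signed_turns(curve)
    return angles, fine


def signed_turns(curve: PrincipalCurve) -> np.ndarray:
    """Signed turn (deg, + = counter-clockwise) between consecutive segments.

    Entry ``i`` is the turn at POP ``i``; endpoints (or all POPs, cyclically,
    for closed curves) without two adjacent segments hold NaN/values
    accordingly.
    """
    pos = curve.positions
    m = len(pos)
    turns = np.full(m, np.nan)
    if m < 3:
        return turns
    rng = range(m) if curve.closed else range(1, m - 1)
    for i in rng:
        a = pos[i % m] - pos[(i - 1) % m]
        b = pos[(i + 1) % m] - pos[i % m]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-15 or nb < 1e-15:
            turns[i] = 0.0
            continue
        cross = a[0] * b[1] - a[1] * b[0]
        dot = float(a @ b)
        turns[i] = math.degrees(math.atan2(cross, dot))
    return turns


def detect_curvature_points(curve: PrincipalCurve,
                            angle_threshold_deg: float) -> list[CurvaturePoint]:
    """POPs whose neighbourhood-scale interior angle drops below the threshold.

    Runs of consecutive flagged POPs merge into a single curvature point at
    the sharpest POP. On a closed curve where every POP is flagged (constant
    curvature leaves no run boundaries) the cycle is split into one
    curvature point per ~90 degrees of cumulative turning.
    """
    if not 0.0 < angle_threshold_deg <= 180.0:
        raise ParameterError("angle threshold must lie in (0, 180]")
    m = len(curve)
    if m < 3:
        return []
    angles, fine = _chord_angles(curve)
    flagged = np.zeros(m, dtype=bool)
    valid = ~np.isnan(angles)
    flagged[valid] = angles[valid] < angle_threshold_deg
    if not flagged.any():
        return []

    if curve.closed and flagged.all():
        return _split_closed_run(angles, fine)

    runs: list[list[int]] = []
    current: list[int] = []
    for i in range(m):
        if flagged[i]:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    if curve.closed and len(runs) > 1 and flagged[0] and flagged[m - 1]:
        first, last = runs[0], runs[-1]
        runs = [last + first] + runs[1:-1]

    cps = []
    for run in runs:
        sharpest = min(run, key=lambda i: angles[i])
        cps.append(CurvaturePoint(sharpest, float(angles[sharpest])))
    cps.sort(key=lambda c: c.pop_index)
    return cps


def _split_closed_run(angles: np.ndarray, fine: np.ndarray) -> list[CurvaturePoint]:
    m = len(angles)
    total = float(np.nansum(np.abs(fine)))
    pieces = max(1, int(round(total / 90.0)))
    cum = np.nancumsum(np.abs(fine))
    bounds = [total * j / pieces for j in range(pieces + 1)]
    cps = []
    for j in range(pieces):
        members = [i for i in range(m)
                   if bounds[j] <= cum[i] < bounds[j + 1] and not np.isnan(angles[i])]
        if not members:
            continue
        sharpest = min(members, key=lambda i: angles[i])
        cps.append(CurvaturePoint(sharpest, float(angles[sharpest])))
    cps.sort(key=lambda c: c.pop_index)
    return cps


def curve_to_table(curve: PrincipalCurve):
    """POP coordinates and tangents as a DataFrame (for TSV export/plotting)."""
    import pandas as pd

    pos = curve.positions
    dirs = np.array([p.direction for p in curve.pops])
    return pd.DataFrame({
        "pop_index": np.arange(len(curve)),
        "x": pos[:, 0], "y": pos[:, 1],
        "dir_x": dirs[:, 0], "dir_y": dirs[:, 1],
        "support": [p.support for p in curve.pops],
    })
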