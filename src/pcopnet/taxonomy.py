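"""Shape taxonomy of pairwise expression relationships.

A fitted PCOP is reduced to a *segment signature* — slope and turning signs
of the polyline between its curvature points — and classified into one of
14 curve-type codes modelled on the canonical shapes y = ±x, ±e^x, ±ln x,
±x², sideways parabolas, x³, the circle, plus a COMPLEX catch-all. The
taxonomy is shape-based: no parametric function is ever fitted, so unknown
relationship shapes are handled as reliably as the canonical ones.

Each curve type maps to an activation/deactivation dependence between the
two sets of coexpressed genes it relates (e.g. an e^x-shaped relationship
means the first set must overexpress before the second starts to express;
a −ln x shape means mutual exclusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .pcop import (CurvaturePoint, PcopParams, PrincipalCurve,
                   detect_curvature_points, fit_pcop)

CURVE_TYPES = (
    "LIN_POS", "LIN_NEG",
    "EXP_POS", "EXP_NEG",
    "LOG_POS", "LOG_NEG",
    "QUAD_POS", "QUAD_NEG",
    "CUBIC_POS", "CUBIC_NEG",
    "SIDE_QUAD_POS", "SIDE_QUAD_NEG",
    "CLOSED", "COMPLEX",
)

#: Angle threshold (deg) used when classifying a curve outside a matrix scan;
#: the curvature-threshold formula evaluated at the 1416-gene reference scale.
REFERENCE_ANGLE_THRESHOLD = 160.0 - ((15.0 / 20000 + 14.0 / 18400) / 2.0) * 1416

#: Turns smaller than this (deg) are fit jitter, not shape.
TURN_DEAD_ZONE_DEG = 2.0

# Swapping axes mirrors a curve across y = x. For an increasing shape this
# flips convexity (e^x <-> ln x); for a *decreasing* shape it preserves it,
# since (f^-1)'' = -f''/(f')^3 keeps the sign of f'' when f' < 0 — so the
# decreasing exponential and the negative logarithm are each their own
# transpose (-e^x mirrors to ln(-x), still decreasing concave).
_TRANSPOSE = {
    "LIN_POS": "LIN_POS", "LIN_NEG": "LIN_NEG",
    "EXP_POS": "LOG_POS", "LOG_POS": "EXP_POS",
    "EXP_NEG": "EXP_NEG", "LOG_NEG": "LOG_NEG",
    "QUAD_POS": "SIDE_QUAD_POS", "SIDE_QUAD_POS": "QUAD_POS",
    "QUAD_NEG": "SIDE_QUAD_NEG", "SIDE_QUAD_NEG": "QUAD_NEG",
    "CUBIC_POS": "CUBIC_POS", "CUBIC_NEG": "CUBIC_NEG",
    "CLOSED": "CLOSED", "COMPLEX": "COMPLEX",
}

_DEPENDENCE_LABELS = {
    "LIN_POS": "positive coexpression (both sets express together)",
    "LIN_NEG": "inverse coexpression (one set rises as the other falls)",
    "EXP_POS": "activation (first set must overexpress so the second starts to express)",
    "EXP_NEG": "deactivation (overexpression of the first set shuts the second down)",
    "LOG_POS": "saturating activation (the second set switches on as soon as the first expresses)",
    "LOG_NEG": "mutual exclusion",
    "QUAD_POS": "deactivation of second set at both over- and underexpression of first",
    "QUAD_NEG": "activation of second set at both over- and underexpression of first",
    "SIDE_QUAD_POS": "deactivation of first set at both over- and underexpression of second",
    "SIDE_QUAD_NEG": "activation of first set at both over- and underexpression of second",
    "CUBIC_POS": "switch-like dependence (co-directional with an inert middle range)",
    "CUBIC_NEG": "switch-like dependence (counter-directional with an inert middle range)",
    "CLOSED": "cyclic interdependence (closed expression trajectory)",
    "COMPLEX": "complex dependence of unlisted shape",
}


@dataclass
class SegmentSignature:
    """Canonical shape summary of a polyline split at its curvature points."""

    slope_signs: list[int]          # sign(dy/dx) per inter-curvature segment
    turn_direction_signs: list[int]  # net turning sign per segment (+ = ccw)
    total_turning_deg: float
    closed: bool
    dx_signs: list[int] = field(default_factory=list)
    dy_signs: list[int] = field(default_factory=list)


def _sign(v: float, tol: float = 0.0) -> int:
    if v > tol:
        return 1
    if v < -tol:
        return -1
    return 0


def _reduce_runs(signs) -> list[int]:
    """Drop zeros and collapse repeats: [-,-,0,+,+] -> [-,+]."""
    out: list[int] = []
    for s in signs:
        if s == 0:
            continue
        if not out or out[-1] != s:
            out.append(s)
    return out


def segment_signature(curve: PrincipalCurve,
                      cps: list[CurvaturePoint]) -> SegmentSignature:
    """Compute slope/turning signs per inter-curvature-point segment.

    Open curves are first oriented canonically: traversal in increasing x
    (falling back to increasing y when the net x extent is negligible, as
    for sideways parabolas).
    """
    pos = curve.positions
    if len(pos) < 2:
        raise ParameterError("curve must have at least 2 POPs")
    cut = sorted(c.pop_index for c in cps)

    if not curve.closed:
        net = pos[-1] - pos[0]
        if abs(net[0]) >= 0.1 * abs(net[1]):
            flip = net[0] < 0
        else:
            flip = net[1] < 0
        if flip:
            pos = pos[::-1]
            m = len(pos)
            cut = sorted(m - 1 - i for i in cut)

    # signed turns on the (possibly re-oriented) polyline
    turns = _signed_turns_of(pos, curve.closed)
    total = float(np.nansum(np.abs(turns)))

    bounds = [0] + cut + [len(pos) - 1]
    bounds = sorted(set(b for b in bounds if 0 <= b <= len(pos) - 1))
    if bounds[0] != 0:
        bounds = [0] + bounds
    if bounds[-1] != len(pos) - 1:
        bounds = bounds + [len(pos) - 1]

    scale = float(np.abs(np.diff(pos, axis=0)).sum())
    tol = 1e-9 * max(scale, 1.0)
    slope_signs, turn_signs, dxs, dys = [], [], [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        d = pos[b] - pos[a]
        sx, sy = _sign(float(d[0]), tol), _sign(float(d[1]), tol)
        dxs.append(sx)
        dys.append(sy)
        slope_signs.append(sx * sy)
        inner = [turns[i] for i in range(a + 1, b)
                 if not np.isnan(turns[i]) and abs(turns[i]) >= TURN_DEAD_ZONE_DEG]
        s = float(np.sum(inner)) if inner else 0.0
        turn_signs.append(_sign(s, TURN_DEAD_ZONE_DEG))
    return SegmentSignature(slope_signs, turn_signs, total, bool(curve.closed),
                            dxs, dys)


def _signed_turns_of(pos: np.ndarray, closed: bool) -> np.ndarray:
    m = len(pos)
    turns = np.full(m, np.nan)
    if m < 3:
        return turns
    rng = range(m) if closed else range(1, m - 1)
    for i in rng:
        a = pos[i % m] - pos[(i - 1) % m]
        b = pos[(i + 1) % m] - pos[i % m]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-15 or nb < 1e-15:
            turns[i] = 0.0
            continue
        turns[i] = math.degrees(math.atan2(a[0] * b[1] - a[1] * b[0], float(a @ b)))
    return turns


def classify(sig: SegmentSignature, n_curvature_points: int) -> str:
    """Map a segment signature to one of the 14 curve-type codes.

    Deterministic; COMPLEX is the fallback, never an error.
    """
    return _classify(sig.dx_signs, sig.dy_signs, sig.turn_direction_signs,
                     sig.closed, n_curvature_points, _allow_swap=True)


def _classify(dx_signs, dy_signs, turn_signs, closed: bool,
              n_cp: int, _allow_swap: bool) -> str:
    if closed:
        return "CLOSED"
    dy = _reduce_runs(dy_signs)
    dx = _reduce_runs(dx_signs)
    turn = _reduce_runs(turn_signs)

    if n_cp == 0:
        slope = (dy[0] if dy else 0) * (dx[0] if dx else 0)
        if slope == 0:
            slope = dy[0] if dy else (dx[0] if dx else 1)
        return "LIN_POS" if slope >= 0 else "LIN_NEG"

    y_monotone = len(dy) <= 1
    x_monotone = len(dx) <= 1

    if y_monotone and x_monotone:
        rising = (dy[0] if dy else 1) > 0
        if len(turn) == 1:
            convex = turn[0] > 0
            if rising:
                return "EXP_POS" if convex else "LOG_POS"
            return "LOG_NEG" if convex else "EXP_NEG"
        if len(turn) == 2:
            return "CUBIC_POS" if rising else "CUBIC_NEG"
        return "COMPLEX"

    if not y_monotone and x_monotone:
        if dy == [-1, 1]:
            return "QUAD_POS"
        if dy == [1, -1]:
            return "QUAD_NEG"
        return "COMPLEX"

    if y_monotone and not x_monotone and _allow_swap:
        # analyse with axes swapped, then transpose the resulting code
        swapped = _classify(dy_signs, dx_signs, [-t for t in turn_signs],
                            closed, n_cp, _allow_swap=False)
        return transpose_type(swapped)

    return "COMPLEX"


def transpose_type(t: str) -> str:
    """Curve type after swapping the two axes; an involution."""
    try:
        return _TRANSPOSE[t]
    except KeyError:
        raise ParameterError(f"unknown curve type {t!r}") from None


def canonical_code(t: str) -> str:
    """Orientation-free representative of a curve type: min(t, transpose(t)).

    Useful wherever axis orientation is arbitrary (signatures, clique-type
    multisets).
    """
    return min(t, transpose_type(t))


def dependence_label(t: str) -> str:
    """Human-readable activation/deactivation semantics of a curve type."""
    try:
        return _DEPENDENCE_LABELS[t]
    except KeyError:
        raise ParameterError(f"unknown curve type {t!r}") from None


def classify_curve(curve: PrincipalCurve,
                   angle_threshold_deg: float = REFERENCE_ANGLE_THRESHOLD
                   ) -> tuple[str, list[CurvaturePoint]]:
    """Classify a fitted curve: detect curvature points, then apply the taxonomy."""
    cps = detect_curvature_points(curve, angle_threshold_deg)
    sig = segment_signature(curve, cps)
    return classify(sig, len(cps)), cps


def classify_xy(x, y,
                angle_threshold_deg: float = REFERENCE_ANGLE_THRESHOLD,
                params: PcopParams | None = None) -> str:
    """Convenience: standardize a raw (x, y) cloud, fit a PCOP, classify it."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = (x - x.mean()) / x.std(ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    curve = fit_pcop(np.column_stack([xs, ys]), params)
    code, _ = classify_curve(curve, angle_threshold_deg)
    return code
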