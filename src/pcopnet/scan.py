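"""All-pairs PCOP scan with matrix-size-dependent thresholds.

Every unordered gene pair is fitted with a PCOP on its complete-case,
per-pair standardized samples. A pair is *rejected* when its uncorrelation
factor f exceeds the correlation threshold; an accepted pair is *linear*
(coexpressed) when its curve shows no curvature points at the curvature
threshold and *nonlinear* otherwise, in which case its curve type is
recorded.

Both thresholds depend on the number of genes in the matrix:

    f threshold         = 0.12 * (1600 / num_genes) - (num_genes / 40000)^18
    curvature threshold = 160 - ((15.0/20000 + 14.0/18400) / 2) * num_genes

so small matrices accept higher-entropy relationships but are more
restrictive about calling a relationship linear. Because a formula in
num_genes alone cannot anticipate the nature of the experiments, an online
correction periodically projects how many pairs will finally pass and
nudges the f threshold toward a target band.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (DegenerateInputError, InsufficientDataError,
                     ParameterError, ThresholdError)
from .io import ExpressionMatrix
from .pcop import PcopParams, fit_pcop, detect_curvature_points
from .taxonomy import classify, segment_signature

logger = logging.getLogger(__name__)

#: Gene count of the reference matrix on which the threshold formulas were
#: calibrated (1416 genes x 118 samples); used as fallback scale when the
#: f-threshold formula leaves (0, 1].
REFERENCE_NUM_GENES = 1416

MIN_COMPLETE_SAMPLES = 20

RELATION_CLASSES = ("linear", "nonlinear", "rejected")

TABLE_COLUMNS = ("gene_a", "gene_b", "f", "n_curvature_points",
                 "curve_type", "relation_class", "note")


def f_threshold_value(num_genes: int) -> float:
    """Raw value of the f-threshold formula (may be nonpositive or > 1)."""
    if num_genes < 2:
        raise ParameterError("num_genes must be >= 2")
    return 0.12 * (1600.0 / num_genes) - (num_genes / 40000.0) ** 18


def f_threshold(num_genes: int) -> float:
    """Correlation (uncorrelation-factor) threshold for a matrix size.

    Raises :class:`ThresholdError` when the formula degenerates to a
    nonpositive value (very large matrices); override explicitly there.
    """
    v = f_threshold_value(num_genes)
    if v <= 0.0:
        raise ThresholdError(
            f"f-threshold formula is nonpositive ({v:.6g}) at {num_genes} genes; "
            "set an explicit f_threshold_override"
        )
    return v


def curvature_threshold(num_genes: int) -> float:
    """Curvature angle threshold (degrees) for a matrix size."""
    if num_genes < 2:
        raise ParameterError("num_genes must be >= 2")
    v = 160.0 - ((15.0 / 20000 + 14.0 / 18400) / 2.0) * num_genes
    if not 0.0 < v < 180.0:
        raise ThresholdError(
            f"curvature-threshold formula gives {v:.6g} deg at {num_genes} genes; "
            "set an explicit curvature_threshold_override"
        )
    return v


def effective_f_threshold(num_genes: int, override: float | None = None) -> float:
    """f threshold actually applied by the scan.

    The formula stops filtering (value > 1, every f passes) below ~192
    genes; there the scan pins the threshold to the formula's value at the
    1416-gene reference scale instead.
    """
    if override is not None:
        if not 0.0 < override <= 1.0:
            raise ParameterError("f_threshold_override must lie in (0, 1]")
        return override
    v = f_threshold(num_genes)
    return v if v <= 1.0 else f_threshold(REFERENCE_NUM_GENES)


@dataclass
class ScanConfig:
    """Configuration of an all-pairs scan."""

    f_threshold_override: float | None = None
    curvature_threshold_override: float | None = None
    online_correction: bool = True
    target_pass_band: tuple[int, int] | None = None  # default (2n, 20n)
    pcop: PcopParams = field(default_factory=PcopParams)
    min_complete_samples: int = MIN_COMPLETE_SAMPLES

    def __post_init__(self) -> None:
        if self.curvature_threshold_override is not None and not (
                0.0 < self.curvature_threshold_override <= 180.0):
            raise ParameterError("curvature_threshold_override must lie in (0, 180]")
        if self.f_threshold_override is not None and not (
                0.0 < self.f_threshold_override <= 1.0):
            raise ParameterError("f_threshold_override must lie in (0, 1]")

    def pass_band(self, num_genes: int) -> tuple[int, int]:
        return self.target_pass_band or (2 * num_genes, 20 * num_genes)


@dataclass
class ScanState:
    """Progress of a running scan, including the threshold currently in force."""

    n_pairs_total: int
    n_pairs_done: int = 0
    n_passed: int = 0
    current_f_threshold: float = math.nan
    base_f_threshold: float = math.nan


@dataclass
class PairRelationship:
    """Fitted-curve summary of one gene pair (gene_a < gene_b, gene_a on x)."""

    gene_a: str
    gene_b: str
    f: float
    n_curvature_points: int
    curve_type: str
    relation_class: str
    note: str = ""


def scan_pair(m: ExpressionMatrix, gene_a: str, gene_b: str,
              config: ScanConfig | None = None,
              state: ScanState | None = None) -> PairRelationship:
    """Classify a single gene pair.

    The pair is analysed on its complete-case samples, z-scored per gene on
    that subset; pairs with too few complete samples are reported (not
    raised) as rejected with a note.
    """
    config = config or ScanConfig()
    a, b = sorted((gene_a, gene_b))
    xa = m.row(a)
    xb = m.row(b)
    mask = np.isfinite(xa) & np.isfinite(xb)
    n_ok = int(mask.sum())
    if n_ok < config.min_complete_samples:
        logger.warning("pair (%s, %s) skipped: only %d complete samples", a, b, n_ok)
        return PairRelationship(a, b, math.nan, 0, "COMPLEX", "rejected",
                                f"skipped: {n_ok} complete samples")
    x = xa[mask]
    y = xb[mask]
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        return PairRelationship(a, b, math.nan, 0, "COMPLEX", "rejected",
                                "skipped: zero variance on complete cases")
    pts = np.column_stack([(x - x.mean()) / sx, (y - y.mean()) / sy])

    try:
        curve = fit_pcop(pts, config.pcop)
    except (DegenerateInputError, InsufficientDataError) as exc:
        logger.warning("pair (%s, %s) skipped: %s", a, b, exc)
        return PairRelationship(a, b, math.nan, 0, "COMPLEX", "rejected",
                                f"skipped: {exc}")
    f = curve.f
    if state is not None:
        thr = state.current_f_threshold
    else:
        thr = effective_f_threshold(m.n_genes, config.f_threshold_override)
    if f > thr:
        return PairRelationship(a, b, f, 0, "COMPLEX", "rejected", "")

    ang = (config.curvature_threshold_override
           if config.curvature_threshold_override is not None
           else curvature_threshold(m.n_genes))
    cps = detect_curvature_points(curve, ang)
    sig = segment_signature(curve, cps)
    code = classify(sig, len(cps))
    nonlinear = bool(cps) or curve.closed
    return PairRelationship(a, b, f, len(cps), code,
                            "nonlinear" if nonlinear else "linear", "")


def update_threshold_online(state: ScanState, config: ScanConfig,
                            num_genes: int) -> float:
    """Adjust the f threshold from a projection of the final pass count.

    projected = n_passed / n_pairs_done * n_pairs_total; above the target
    band the threshold tightens by 5%, below it loosens by 5% up to the
    formula ceiling. Returns (and stores) the new threshold.
    """
    if state.n_pairs_done <= 0:
        return state.current_f_threshold
    lo, hi = config.pass_band(num_genes)
    projected = state.n_passed / state.n_pairs_done * state.n_pairs_total
    thr = state.current_f_threshold
    if projected > hi:
        thr = thr * 0.95
    elif projected < lo:
        thr = min(thr * 1.05, state.base_f_threshold)
    state.current_f_threshold = thr
    return thr


def scan_all(m: ExpressionMatrix,
             config: ScanConfig | None = None
             ) -> tuple[list[PairRelationship], ScanState]:
    """Scan every unordered gene pair in lexicographic order.

    Emits one record per pair (rejected pairs included, flagged, for audit).
    With online correction disabled and thresholds overridden the result is
    a pure function of the matrix.
    """
    config = config or ScanConfig()
    genes = sorted(m.gene_ids)
    if len(genes) < 2:
        raise ParameterError("need at least 2 analysable genes")
    pairs = list(itertools.combinations(genes, 2))
    base = effective_f_threshold(m.n_genes, config.f_threshold_override)
    state = ScanState(n_pairs_total=len(pairs),
                      current_f_threshold=base, base_f_threshold=base)
    checkpoint = max(1, len(pairs) // 100)

    table: list[PairRelationship] = []
    for a, b in pairs:
        rel = scan_pair(m, a, b, config, state)
        table.append(rel)
        state.n_pairs_done += 1
        if rel.relation_class != "rejected":
            state.n_passed += 1
        if config.online_correction and state.n_pairs_done % checkpoint == 0:
            update_threshold_online(state, config, m.n_genes)
    return table, state


# ---------------------------------------------------------------------------
# relationship-table I/O
# ---------------------------------------------------------------------------

def table_to_frame(table: list[PairRelationship]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_a": r.gene_a, "gene_b": r.gene_b, "f": r.f,
        "n_curvature_points": r.n_curvature_points,
        "curve_type": r.curve_type, "relation_class": r.relation_class,
        "note": r.note,
    } for r in table], columns=list(TABLE_COLUMNS))


def write_relationships(table: list[PairRelationship], path) -> None:
    table_to_frame(table).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_relationships(path) -> list[PairRelationship]:
    df = pd.read_csv(path, sep="\t", dtype={"note": str}, keep_default_na=True)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"relationships table lacks columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        note = "" if (isinstance(row.note, float) and math.isnan(row.note)) else str(row.note)
        out.append(PairRelationship(
            str(row.gene_a), str(row.gene_b), float(row.f),
            int(row.n_curvature_points), str(row.curve_type),
            str(row.relation_class), note))
    return out


def summarize(table: list[PairRelationship], state: ScanState,
              config: ScanConfig, num_genes: int) -> dict:
    """Machine-readable run summary (thresholds in force, class tallies)."""
    counts = {c: 0 for c in RELATION_CLASSES}
    for r in table:
        counts[r.relation_class] += 1
    ang = (config.curvature_threshold_override
           if config.curvature_threshold_override is not None
           else curvature_threshold(num_genes))
    return {
        "schema_version": 1,
        "num_genes": num_genes,
        "n_pairs": state.n_pairs_total,
        "base_f_threshold": state.base_f_threshold,
        "final_f_threshold": state.current_f_threshold,
        "curvature_threshold_deg": ang,
        "online_correction": config.online_correction,
        "counts": counts,
    }
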