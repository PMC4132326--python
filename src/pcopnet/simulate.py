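"""Synthetic expression matrices with planted coexpressed modules.

Every module's genes are noisy affine copies of one shared latent process
pushed through a shape template (identity, exponential, logarithm,
parabola, cubic, circle arcs, and their negatives). Genes within a module
are therefore mutually coexpressed by construction, while the relationship
between two modules is the composition of their templates — a known,
analytically derived curve type. Background genes are pure independent
noise. This gives every pipeline stage a ground truth without any external
dataset.

The induced inter-module curve types are established by an analytic
oracle (:func:`induced_curve_type`) that samples the noiseless parametric
curve densely and reads off exact monotonicity/convexity patterns; it does
not use the PCOP fitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, SpecError
from .io import ExpressionMatrix
from .taxonomy import _classify, canonical_code  # shared shape decision table

#: Latent values live on [0, 1]: a uniform grid jittered by a zero-mean
#: Gaussian with sd = LATENT_JITTER_FRACTION x grid spacing, clipped to the
#: interval.
LATENT_INTERVAL = (0.0, 1.0)
LATENT_JITTER_FRACTION = 0.3

TEMPLATES = {
    "identity": lambda s: s,
    "neg_identity": lambda s: -s,
    "exp": lambda s: np.exp(3.0 * s),
    "neg_exp": lambda s: -np.exp(3.0 * s),
    "log": lambda s: np.log(s + 0.02),
    "neg_log": lambda s: -np.log(s + 0.02),
    "quad": lambda s: (2.0 * s - 1.0) ** 2,
    "neg_quad": lambda s: -((2.0 * s - 1.0) ** 2),
    "cube": lambda s: (2.0 * s - 1.0) ** 3,
    "cos": lambda s: np.cos(2.0 * np.pi * s),
    "sin": lambda s: np.sin(2.0 * np.pi * s),
}

BACKGROUND_PREFIX = "BG"


@dataclass
class ModuleSpec:
    module_id: str
    n_genes: int
    noise_sd: float = 0.05
    transform: str | None = None   # auto-assigned from the intergroup map if None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SpecError("module must contain at least one gene")
        if self.noise_sd < 0:
            raise SpecError("noise sd must be >= 0")
        if self.transform is not None and self.transform not in TEMPLATES:
            raise SpecError(f"unknown transform {self.transform!r}; "
                            f"choose from {sorted(TEMPLATES)}")


@dataclass
class NetworkSpec:
    """Recipe for a planted network of coexpressed modules (complete graph)."""

    n_samples: int
    modules: list[ModuleSpec]
    intergroup: dict[frozenset, str] | None = None  # module-id pair -> curve type
    background_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [m.module_id for m in self.modules]
        if len(set(ids)) != len(ids):
            raise SpecError("module ids must be unique")
        if any(i.startswith(BACKGROUND_PREFIX) for i in ids):
            raise SpecError(f"module id prefix {BACKGROUND_PREFIX!r} is reserved")
        if self.background_genes < 0:
            raise SpecError("background_genes must be >= 0")


@dataclass
class GroundTruth:
    gene_to_module: dict[str, str]        # module id or "background"
    module_transforms: dict[str, str]
    intergroup_types: dict[frozenset, str]  # lexicographically smaller module on x
    signature: tuple[int, tuple[str, ...]]


def gen_latent(n_samples: int, seed: int) -> np.ndarray:
    """Jittered uniform grid on [0, 1]; deterministic per seed."""
    if n_samples < 20:
        raise ParameterError("latent process needs n_samples >= 20")
    rng = np.random.default_rng(seed)
    lo, hi = LATENT_INTERVAL
    grid = np.linspace(lo, hi, n_samples)
    spacing = (hi - lo) / (n_samples - 1)
    s = grid + rng.normal(0.0, LATENT_JITTER_FRACTION * spacing, n_samples)
    return np.clip(s, lo, hi)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def gen_module(latent: np.ndarray, transform: str, n_genes: int,
               noise_sd: float, seed: int) -> np.ndarray:
    """(n_genes, n_samples) block: affine-rescaled noisy copies of the
    transformed latent; genes are mutually coexpressed by construction."""
    if transform not in TEMPLATES:
        raise SpecError(f"unknown transform {transform!r}")
    rng = np.random.default_rng(seed)
    base = _zscore(TEMPLATES[transform](np.asarray(latent, dtype=float)))
    rows = []
    for _ in range(n_genes):
        scale = rng.uniform(0.5, 2.0)
        offset = rng.normal(0.0, 1.0)
        noise = rng.normal(0.0, noise_sd, base.shape) if noise_sd > 0 else 0.0
        rows.append(scale * (base + noise) + offset)
    return np.array(rows)


# ---------------------------------------------------------------------------
# analytic induced-type oracle
# ---------------------------------------------------------------------------

def _run_pattern(diffs: np.ndarray, min_frac: float = 0.02) -> list[int]:
    """Signs of significant monotone runs of a difference sequence."""
    runs: list[tuple[int, float]] = []
    for v in diffs:
        s = 1 if v > 0 else (-1 if v < 0 else 0)
        if runs and runs[-1][0] == s:
            runs[-1] = (s, runs[-1][1] + abs(v))
        else:
            runs.append((s, abs(v)))
    total = sum(m for _, m in runs) or 1.0
    signs = [s for s, m in runs if s != 0 and m >= min_frac * total]
    out: list[int] = []
    for s in signs:
        if not out or out[-1] != s:
            out.append(s)
    return out


def _turn_pattern(turns_deg: np.ndarray, min_abs: float = 5.0) -> list[int]:
    runs: list[tuple[int, float]] = []
    for t in turns_deg:
        s = 1 if t > 0 else (-1 if t < 0 else 0)
        if runs and runs[-1][0] == s:
            runs[-1] = (s, runs[-1][1] + abs(t))
        else:
            runs.append((s, abs(t)))
    signs = [s for s, m in runs if s != 0 and m >= min_abs]
    out: list[int] = []
    for s in signs:
        if not out or out[-1] != s:
            out.append(s)
    return out


def induced_curve_type(transform_x: str, transform_y: str,
                       n_dense: int = 4001) -> str:
    """Exact curve type of the noiseless relationship y = Ty(s) vs x = Tx(s).

    Dense parametric sampling plus exact difference analysis; independent of
    the PCOP fitter but sharing the same shape decision table.
    """
    for t in (transform_x, transform_y):
        if t not in TEMPLATES:
            raise SpecError(f"unknown transform {t!r}")
    s = np.linspace(*LATENT_INTERVAL, n_dense)
    x = _zscore(TEMPLATES[transform_x](s))
    y = _zscore(TEMPLATES[transform_y](s))
    pts = np.column_stack([x, y])

    diam = math.dist(pts.min(axis=0), pts.max(axis=0))
    closed = math.dist(pts[0], pts[-1]) < 0.05 * diam and len(pts) > 2

    if not closed:
        net = pts[-1] - pts[0]
        flip = (net[0] < 0) if abs(net[0]) >= 0.1 * abs(net[1]) else (net[1] < 0)
        if flip:
            pts = pts[::-1]

    d = np.diff(pts, axis=0)
    dx_runs = _run_pattern(d[:, 0])
    dy_runs = _run_pattern(d[:, 1])

    seg = d / np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-300)
    cross = seg[:-1, 0] * seg[1:, 1] - seg[:-1, 1] * seg[1:, 0]
    dot = (seg[:-1] * seg[1:]).sum(axis=1)
    turns = np.degrees(np.arctan2(cross, dot))
    turn_runs = _turn_pattern(turns)
    total_turn = float(np.abs(turns).sum())

    n_cp = 0 if total_turn < 5.0 else max(1, len(turn_runs))
    return _classify(dx_runs, dy_runs, turn_runs, closed, n_cp, _allow_swap=True)


# ---------------------------------------------------------------------------
# full datasets
# ---------------------------------------------------------------------------

_AUTO_TEMPLATES = ("identity", "neg_identity", "exp", "neg_exp", "log",
                   "neg_log", "quad", "neg_quad", "cube", "cos", "sin")


def _induced_map(transforms: dict[str, str]) -> dict[frozenset, str]:
    out = {}
    for a, b in _module_pairs(sorted(transforms)):
        out[frozenset((a, b))] = induced_curve_type(transforms[a], transforms[b])
    return out


def _module_pairs(ids):
    import itertools

    return itertools.combinations(sorted(ids), 2)


def _resolve_transforms(spec: NetworkSpec) -> dict[str, str]:
    """Per-module transforms consistent with the requested intergroup map."""
    ids = [m.module_id for m in spec.modules]
    given = {m.module_id: m.transform for m in spec.modules if m.transform}
    if len(given) == len(ids):
        transforms = dict(given)
        if spec.intergroup:
            induced = _induced_map(transforms)
            for key, want in spec.intergroup.items():
                key = frozenset(key)
                if induced.get(key) != want:
                    a, b = sorted(key)
                    raise SpecError(
                        f"modules ({a}, {b}): transforms "
                        f"({transforms[a]}, {transforms[b]}) induce "
                        f"{induced.get(key)}, not the requested {want}")
        return transforms
    if spec.intergroup is None:
        raise SpecError("either give every module a transform or an intergroup map")

    want = {frozenset(k): v for k, v in spec.intergroup.items()}
    missing = [k for k in map(frozenset, _module_pairs(ids)) if k not in want]
    if missing:
        a, b = sorted(missing[0])
        raise SpecError(f"intergroup map lacks module pair ({a}, {b}); "
                        "planted networks are complete graphs")

    free = [i for i in ids if i not in given]
    cache: dict[tuple[str, str], str] = {}

    def induced(ta: str, tb: str) -> str:
        if (ta, tb) not in cache:
            cache[(ta, tb)] = induced_curve_type(ta, tb)
        return cache[(ta, tb)]

    assign = dict(given)

    def ok_so_far(mid: str) -> bool:
        for other, t_other in assign.items():
            if other == mid:
                continue
            a, b = sorted((mid, other))
            if induced(assign[a], assign[b]) != want[frozenset((a, b))]:
                return False
        return True

    def search(i: int) -> bool:
        if i == len(free):
            return True
        mid = free[i]
        for t in _AUTO_TEMPLATES:
            assign[mid] = t
            if ok_so_far(mid) and search(i + 1):
                return True
            del assign[mid]
        return False

    if not search(0):
        for key in sorted(want, key=sorted):
            a, b = sorted(key)
            feasible = any(induced(ta, tb) == want[key]
                           for ta in _AUTO_TEMPLATES for tb in _AUTO_TEMPLATES)
            if not feasible:
                raise SpecError(f"no transform pair induces curve type "
                                f"{want[key]} for module pair ({a}, {b})")
        raise SpecError("intergroup map is jointly unsatisfiable by the "
                        "available transform templates")
    return assign


def gen_network_dataset(spec: NetworkSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Expression matrix with planted modules, plus its ground truth.

    Deterministic per spec.seed. Modules share one latent process; the
    induced pairwise curve types (oriented with the lexicographically
    smaller module's genes on x) are recorded in the ground truth together
    with the planted network signature.
    """
    transforms = _resolve_transforms(spec)
    rng = np.random.default_rng(spec.seed)
    latent_seed, *module_seeds = rng.integers(0, 2 ** 31 - 1,
                                              size=len(spec.modules) + 2)
    bg_seed = module_seeds.pop()
    latent = gen_latent(spec.n_samples, int(latent_seed))

    gene_ids: list[str] = []
    blocks = []
    gene_to_module: dict[str, str] = {}
    for m, mseed in zip(spec.modules, module_seeds):
        block = gen_module(latent, transforms[m.module_id], m.n_genes,
                           m.noise_sd, int(mseed))
        blocks.append(block)
        for k in range(m.n_genes):
            gid = f"{m.module_id}_{k:03d}"
            gene_ids.append(gid)
            gene_to_module[gid] = m.module_id
    if spec.background_genes:
        bg = np.random.default_rng(int(bg_seed)).normal(
            0.0, 1.0, (spec.background_genes, spec.n_samples))
        blocks.append(bg)
        for k in range(spec.background_genes):
            gid = f"{BACKGROUND_PREFIX}_{k:03d}"
            gene_ids.append(gid)
            gene_to_module[gid] = "background"

    values = np.vstack(blocks)
    matrix = ExpressionMatrix(gene_ids, [f"S{j:03d}" for j in range(spec.n_samples)],
                              values)
    intergroup = _induced_map(transforms)
    sig = (len(spec.modules),
           tuple(sorted(canonical_code(t) for t in intergroup.values())))
    truth = GroundTruth(gene_to_module, transforms, intergroup, sig)
    return matrix, truth
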