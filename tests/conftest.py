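"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import pcopnet as pn
from pcopnet.simulate import TEMPLATES

# canonical noiseless relationship clouds: template pair per curve type
CANONICAL_PAIRS = {
    "LIN_POS": ("identity", "identity"),
    "LIN_NEG": ("identity", "neg_identity"),
    "EXP_POS": ("identity", "exp"),
    "EXP_NEG": ("identity", "neg_exp"),
    "LOG_POS": ("identity", "log"),
    "LOG_NEG": ("identity", "neg_log"),
    "QUAD_POS": ("identity", "quad"),
    "QUAD_NEG": ("identity", "neg_quad"),
    "CUBIC_POS": ("identity", "cube"),
    "CLOSED": ("cos", "sin"),
}


def zscore(v):
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std(ddof=1)


def canonical_cloud(code: str, n: int = 60, noise_sd: float = 0.0, rng=None):
    """Noiseless (or jittered) 2-D cloud of one canonical relationship shape."""
    tx, ty = CANONICAL_PAIRS[code]
    s = np.linspace(0.0, 1.0, n)
    x = zscore(TEMPLATES[tx](s))
    y = zscore(TEMPLATES[ty](s))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
        y = y + rng.normal(0.0, noise_sd, n)
    return x, y


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_maximal_cliques(G, min_size=1):
    """All maximal cliques by exhaustive subset enumeration (n <= ~14)."""
    nodes = sorted(G.nodes)
    n = len(nodes)
    adj = [set(G.neighbors(u)) for u in nodes]
    out = set()
    for mask in range(1, 1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if len(members) < min_size:
            continue
        if any(nodes[j] not in adj[i] for i, j in itertools.combinations(members, 2)):
            continue
        mset = set(members)
        maximal = not any(
            mset <= {k for k in range(n) if nodes[k] in adj[j]}
            for j in range(n) if j not in mset)
        if maximal:
            out.add(frozenset(nodes[i] for i in members))
    return out


def brute_force_bijections(c1, c2, coexpression):
    """All valid isomorphic-linear bijections by exhaustive permutation."""
    if len(c1) != len(c2) or set(c1.genes) & set(c2.genes):
        return []
    found = []
    for perm in itertools.permutations(c2.genes):
        bij = dict(zip(c1.genes, perm))
        if not all(coexpression.has_edge(a, b) for a, b in bij.items()):
            continue
        ok = all(
            c1.oriented_type(a1, a2) == c2.oriented_type(bij[a1], bij[a2])
            for a1, a2 in itertools.combinations(c1.genes, 2))
        if ok:
            found.append(bij)
    return found


def polyline_residual_f(points, vertices):
    """Brute-force uncorrelation factor: projection onto every segment."""
    pts = np.asarray(points, dtype=float)
    verts = np.asarray(vertices, dtype=float)
    best = np.full(len(pts), np.inf)
    for a, b in zip(verts[:-1], verts[1:]):
        ab = b - a
        denom = float(ab @ ab) or 1.0
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        best = np.minimum(best, ((pts - proj) ** 2).sum(axis=1))
    total = ((pts - pts.mean(axis=0)) ** 2).sum(axis=1).mean()
    return float(best.mean() / (total / 2.0))


# ---------------------------------------------------------------------------
# planted dataset shared by the slower integration tests
# ---------------------------------------------------------------------------

THREE_MODULE_SPEC = dict(
    n_samples=60,
    modules=[("M1", 10, 0.05, "identity"),
             ("M2", 10, 0.05, "exp"),
             ("M3", 10, 0.05, "neg_log")],
    background_genes=20,
    seed=7,
)


def make_three_module_spec(seed=7, noise=0.05):
    return pn.NetworkSpec(
        n_samples=60,
        modules=[pn.ModuleSpec(mid, n, noise, t)
                 for mid, n, _, t in THREE_MODULE_SPEC["modules"]],
        background_genes=THREE_MODULE_SPEC["background_genes"],
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    matrix, truth = pn.gen_network_dataset(make_three_module_spec())
    return matrix, truth


@pytest.fixture(scope="session")
def planted_scan(planted_dataset):
    matrix, truth = planted_dataset
    table, state, summary = pn.run_scan(matrix)
    return matrix, truth, table, state, summary


@pytest.fixture(scope="session")
def planted_networks(planted_scan):
    matrix, truth, table, state, summary = planted_scan
    result = pn.run_networks(table)
    return truth, table, result
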