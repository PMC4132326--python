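"""Gene cliques, isomorphic-clique matching and skeleton networks.

From the relationship table two graphs are built: the *coexpression* graph
(accepted linear pairs) and the *nonlinear* graph (accepted nonlinear pairs,
edges labelled with curve types). Gene cliques of size >= 3 in the nonlinear
graph are the seeds. Two disjoint equal-size cliques form an *isomorphic and
linear* pair when a bijection pairs each gene of one with a coexpressed gene
of the other such that corresponding internal edges carry the same curve
type (after orientation normalisation). Cliques of the clique-level graph —
"cliques of cliques" — then yield skeleton networks: composing the
coexpression bijections across the member cliques groups their genes into
coexpressed *sets* (one gene per member clique in each set), every pair of
sets carrying a single well-defined curve type. The genes drawn from the
cliques form each set's *skeleton*; remaining genes coexpressed with a
skeleton gene form its *halo*, ordered by coexpression strength (f).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import ParameterError, UnknownGeneError
from .scan import PairRelationship
from .taxonomy import canonical_code, transpose_type

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULT_MAX_CLIQUES = 50000
DEFAULT_MAX_FAMILIES = 2000


@dataclass
class GeneClique:
    """>= 3 genes pairwise connected by accepted nonlinear relationships."""

    genes: tuple[str, ...]                      # sorted
    edge_types: dict[frozenset, str]            # canonical orientation (min gene on x)

    def __post_init__(self) -> None:
        self.genes = tuple(sorted(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def oriented_type(self, a: str, b: str) -> str:
        """Curve type of edge (a, b) with a on the x axis."""
        t = self.edge_types[frozenset((a, b))]
        return t if a < b else transpose_type(t)


@dataclass
class IsomorphicPair:
    """Two cliques plus the coexpression bijection that matches them."""

    clique_a: int                # indices into the clique list
    clique_b: int
    bijection: dict[str, str]    # gene of a -> gene of b


@dataclass
class CoexpressedSet:
    skeleton: tuple[str, ...]                        # sorted gene ids
    halo: list[tuple[str, float, str]] = field(default_factory=list)
    # halo entries: (gene, f with anchor, anchor skeleton gene), f ascending

    @property
    def members(self) -> set[str]:
        return set(self.skeleton) | {g for g, _, _ in self.halo}


@dataclass
class SkeletonNetwork:
    """Complete graph over >= 3 coexpressed gene sets with typed edges."""

    sets: list[CoexpressedSet]
    intergroup_types: dict[frozenset, str]   # frozenset({i, j}) -> curve type

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    def signature(self) -> tuple[int, tuple[str, ...]]:
        return network_signature(self)


# ---------------------------------------------------------------------------
# graphs and gene cliques
# ---------------------------------------------------------------------------

def build_graphs(table: list[PairRelationship]) -> tuple[nx.Graph, nx.Graph]:
    """(coexpression graph, nonlinear graph) from a relationship table.

    Coexpression edges carry ``f``; nonlinear edges carry ``f`` and
    ``curve_type`` (canonical orientation). The edge sets are disjoint.
    """
    coexpr = nx.Graph()
    nonlin = nx.Graph()
    for r in sorted(table, key=lambda r: (r.gene_a, r.gene_b)):
        if r.relation_class == "linear":
            coexpr.add_edge(r.gene_a, r.gene_b, f=r.f)
        elif r.relation_class == "nonlinear":
            nonlin.add_edge(r.gene_a, r.gene_b, f=r.f, curve_type=r.curve_type)
    return coexpr, nonlin


def enumerate_gene_cliques(nonlinear: nx.Graph, min_size: int = 3,
                           max_cliques: int = DEFAULT_MAX_CLIQUES
                           ) -> list[GeneClique]:
    """All maximal cliques of size >= min_size, sorted by gene ids.

    Enumeration is capped at ``max_cliques`` (with a logged warning) to stay
    bounded on pathological graphs.
    """
    if min_size < 3:
        raise ParameterError("gene cliques must have at least 3 genes")
    out: list[GeneClique] = []
    n_seen = 0
    for c in nx.find_cliques(nonlinear):
        n_seen += 1
        if len(c) >= min_size:
            genes = tuple(sorted(c))
            edge_types = {
                frozenset((a, b)): nonlinear.edges[a, b]["curve_type"]
                for a, b in itertools.combinations(genes, 2)
            }
            out.append(GeneClique(genes, edge_types))
        if n_seen >= max_cliques:
            logger.warning("clique enumeration truncated at %d maximal cliques",
                           max_cliques)
            break
    out.sort(key=lambda c: c.genes)
    return out


# ---------------------------------------------------------------------------
# isomorphic-and-linear clique pairs
# ---------------------------------------------------------------------------

def match_isomorphic_pair(c1: GeneClique, c2: GeneClique,
                          coexpression: nx.Graph) -> dict[str, str] | None:
    """First valid coexpression bijection between two cliques, or None.

    Conditions: cliques are equal-size and disjoint; each gene of c1 maps to
    a distinct gene of c2 it is coexpressed with; corresponding internal
    edges carry the same curve type once both are oriented along the
    bijection. Candidates are tried in gene-id order, so the result is
    deterministic.
    """
    if len(c1) != len(c2):
        return None
    if set(c1.genes) & set(c2.genes):
        return None
    # cheap necessary condition: orientation-free type multisets must agree
    if (sorted(canonical_code(t) for t in c1.edge_types.values())
            != sorted(canonical_code(t) for t in c2.edge_types.values())):
        return None

    cands = {}
    for a in c1.genes:
        cs = [b for b in c2.genes if coexpression.has_edge(a, b)]
        if not cs:
            return None
        cands[a] = cs

    order = sorted(c1.genes, key=lambda a: (len(cands[a]), a))
    assign: dict[str, str] = {}
    used: set[str] = set()

    def backtrack(i: int) -> bool:
        if i == len(order):
            return True
        a = order[i]
        for b in cands[a]:
            if b in used:
                continue
            ok = True
            for a2, b2 in assign.items():
                if c1.oriented_type(a, a2) != c2.oriented_type(b, b2):
                    ok = False
                    break
            if ok:
                assign[a] = b
                used.add(b)
                if backtrack(i + 1):
                    return True
                del assign[a]
                used.discard(b)
        return False

    return dict(assign) if backtrack(0) else None


def match_all_pairs(cliques: list[GeneClique],
                    coexpression: nx.Graph) -> list[IsomorphicPair]:
    """Isomorphic-and-linear pairs over all clique combinations.

    Cliques are pre-bucketed by (size, curve-type multiset) so only
    plausible combinations reach the backtracking matcher.
    """
    buckets: dict[tuple, list[int]] = {}
    for i, c in enumerate(cliques):
        key = (len(c), tuple(sorted(canonical_code(t)
                                    for t in c.edge_types.values())))
        buckets.setdefault(key, []).append(i)
    pairs: list[IsomorphicPair] = []
    for key, members in sorted(buckets.items()):
        for i, j in itertools.combinations(members, 2):
            bij = match_isomorphic_pair(cliques[i], cliques[j], coexpression)
            if bij is not None:
                pairs.append(IsomorphicPair(i, j, bij))
    return pairs


# ---------------------------------------------------------------------------
# cliques of cliques -> skeleton networks
# ---------------------------------------------------------------------------

class _DSU:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        p = self.parent.setdefault(x, x)
        if p != x:
            p = self.parent[x] = self.find(p)
        return p

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _family_to_network(family: list[int], cliques: list[GeneClique],
                       pair_index: dict[frozenset, dict[str, str]]
                       ) -> SkeletonNetwork | None:
    """Compose the bijections of a clique family into transversal sets.

    Returns None (with a logged warning) when the composition is
    inconsistent: a group must contain exactly one gene of every member
    clique, and every set pair must carry a single curve type.
    """
    size = len(cliques[family[0]])
    dsu = _DSU()
    for g in cliques[family[0]].genes:
        dsu.find(g)
    for i, j in itertools.combinations(family, 2):
        bij = pair_index.get(frozenset((i, j)))
        if bij is None:
            return None
        for a, b in bij.items():
            dsu.union(a, b)

    groups: dict[str, set[str]] = {}
    for ci in family:
        for g in cliques[ci].genes:
            groups.setdefault(dsu.find(g), set()).add(g)
    if len(groups) != size:
        logger.warning("discarding inconsistent clique family %s: %d transversal "
                       "groups for clique size %d", family, len(groups), size)
        return None
    for root, members in groups.items():
        per_clique: set[int] = set()
        for ci in family:
            inter = members & set(cliques[ci].genes)
            if len(inter) != 1:
                logger.warning("discarding inconsistent clique family %s: group %s "
                               "meets clique %d in %d genes", family, root, ci,
                               len(inter))
                return None
            per_clique.add(ci)

    sets = [CoexpressedSet(tuple(sorted(m)))
            for m in sorted(groups.values(), key=lambda s: sorted(s))]
    gene_to_set = {g: k for k, s in enumerate(sets) for g in s.skeleton}

    intergroup: dict[frozenset, str] = {}
    for ci in family:
        c = cliques[ci]
        for a, b in itertools.combinations(c.genes, 2):
            si, sj = gene_to_set[a], gene_to_set[b]
            # orient the type with the lower-indexed set on the x axis
            t = c.oriented_type(a, b) if si < sj else c.oriented_type(b, a)
            key = frozenset((si, sj))
            if key in intergroup and intergroup[key] != t:
                logger.warning("discarding clique family %s: sets %s carry both "
                               "%s and %s", family, sorted(key), intergroup[key], t)
                return None
            intergroup[key] = t
    return SkeletonNetwork(sets, intergroup)


def _try_merge(net: SkeletonNetwork, other: SkeletonNetwork) -> bool:
    """Merge ``other`` into ``net`` when both describe the same structure.

    Requires the same set count and signature, a one-to-one alignment of
    sets by skeleton overlap, and identical intergroup types under that
    alignment. Skeletons are unioned in place.
    """
    if net.n_sets != other.n_sets:
        return False
    if network_signature(net) != network_signature(other):
        return False
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for j, so in enumerate(other.sets):
        overlaps = [(len(set(so.skeleton) & set(sn.skeleton)), -k, k)
                    for k, sn in enumerate(net.sets) if k not in used]
        overlaps.sort(reverse=True)
        if not overlaps or overlaps[0][0] == 0:
            return False
        mapping[j] = overlaps[0][2]
        used.add(overlaps[0][2])
    for key, t in other.intergroup_types.items():
        i, j = sorted(key)
        mi, mj = mapping[i], mapping[j]
        to = t if (mi < mj) == (i < j) else transpose_type(t)
        if net.intergroup_types[frozenset((mi, mj))] != to:
            return False
    for j, so in enumerate(other.sets):
        k = mapping[j]
        net.sets[k] = CoexpressedSet(
            tuple(sorted(set(net.sets[k].skeleton) | set(so.skeleton))))
    return True


def cliques_of_cliques(cliques: list[GeneClique],
                       pairs: list[IsomorphicPair],
                       min_sets: int = 3,
                       min_skeleton_genes: int = 3,
                       max_families: int = DEFAULT_MAX_FAMILIES
                       ) -> list[SkeletonNetwork]:
    """Skeleton networks from maximal cliques of the clique-level graph.

    Each family of pairwise isomorphic-linear cliques yields one candidate
    network whose sets are the transversal coexpression groups; candidates
    describing the same structure (same signature, overlapping aligned
    sets, identical types) are merged. ``min_sets`` bounds the number of
    sets (the member-clique size); ``min_skeleton_genes`` bounds skeleton
    size per set (the number of member cliques).
    """
    if not pairs:
        return []
    H = nx.Graph()
    H.add_nodes_from(range(len(cliques)))
    pair_index: dict[frozenset, dict[str, str]] = {}
    for p in pairs:
        H.add_edge(p.clique_a, p.clique_b)
        pair_index[frozenset((p.clique_a, p.clique_b))] = dict(p.bijection)

    networks: list[SkeletonNetwork] = []
    n_fam = 0
    for family in nx.find_cliques(H):
        n_fam += 1
        if n_fam > max_families:
            logger.warning("clique-of-cliques enumeration truncated at %d families",
                           max_families)
            break
        family = sorted(family)
        if len(family) < min_skeleton_genes:
            continue
        if len(cliques[family[0]]) < min_sets:
            continue
        net = _family_to_network(family, cliques, pair_index)
        if net is None:
            continue
        for existing in networks:
            if _try_merge(existing, net):
                break
        else:
            networks.append(net)

    # a second pass lets families merged into different seeds coalesce
    merged = True
    while merged:
        merged = False
        for i, j in itertools.combinations(range(len(networks)), 2):
            if _try_merge(networks[i], networks[j]):
                del networks[j]
                merged = True
                break
    networks.sort(key=lambda n: [s.skeleton for s in n.sets])
    for net in networks:
        _assert_complete(net)
    return networks


def _assert_complete(net: SkeletonNetwork) -> None:
    for i, j in itertools.combinations(range(net.n_sets), 2):
        if frozenset((i, j)) not in net.intergroup_types:
            raise AssertionError("skeleton network is not a complete graph")


def attach_halo(net: SkeletonNetwork, coexpression: nx.Graph,
                table: list[PairRelationship]) -> SkeletonNetwork:
    """Attach to each set the genes coexpressed with its skeleton.

    A halo gene is any gene linearly linked to at least one skeleton gene of
    the set and absent from every skeleton of the network; it carries its
    best (lowest-f) anchor and halos are sorted by f ascending.
    """
    all_skeleton = {g for s in net.sets for g in s.skeleton}
    for k, s in enumerate(net.sets):
        best: dict[str, tuple[float, str]] = {}
        for anchor in s.skeleton:
            if anchor not in coexpression:
                continue
            for g in coexpression.neighbors(anchor):
                if g in all_skeleton:
                    continue
                fval = float(coexpression.edges[anchor, g]["f"])
                if g not in best or (fval, anchor) < best[g]:
                    best[g] = (fval, anchor)
        halo = sorted(((g, fv, anc) for g, (fv, anc) in best.items()),
                      key=lambda e: (e[1], e[0]))
        net.sets[k] = CoexpressedSet(s.skeleton, halo)
    return net


def network_signature(net: SkeletonNetwork) -> tuple[int, tuple[str, ...]]:
    """(set count, sorted multiset of intergroup curve types) display key.

    Types are canonicalised so a code and its transpose (the same shape seen
    from the other axis) hash identically, making the key invariant to set
    relabelling.
    """
    canon = tuple(sorted(canonical_code(t)
                         for t in net.intergroup_types.values()))
    return (net.n_sets, canon)


# ---------------------------------------------------------------------------
# gene-centric query
# ---------------------------------------------------------------------------

def query_gene(table: list[PairRelationship], gene: str) -> list[dict]:
    """All accepted nonlinear relationships of one gene, with both
    coexpressed-gene lists (the gene's and each partner's), f-ordered.

    Curve types are reported with the query gene on the x axis.
    """
    known = {r.gene_a for r in table} | {r.gene_b for r in table}
    if gene not in known:
        raise UnknownGeneError(gene)
    coexpr: dict[str, list[tuple[float, str]]] = {}
    for r in table:
        if r.relation_class == "linear":
            coexpr.setdefault(r.gene_a, []).append((r.f, r.gene_b))
            coexpr.setdefault(r.gene_b, []).append((r.f, r.gene_a))

    def coexpressed(g: str) -> list[dict]:
        return [{"gene": p, "f": fv} for fv, p in sorted(coexpr.get(g, []))]

    entries = []
    for r in table:
        if r.relation_class != "nonlinear":
            continue
        if r.gene_a == gene:
            partner, t = r.gene_b, r.curve_type
        elif r.gene_b == gene:
            partner, t = r.gene_a, transpose_type(r.curve_type)
        else:
            continue
        entries.append({
            "partner": partner,
            "curve_type": t,
            "f": r.f,
            "gene_coexpressed": coexpressed(gene),
            "partner_coexpressed": coexpressed(partner),
        })
    entries.sort(key=lambda e: (e["f"], e["partner"]))
    return entries


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def networks_to_dict(networks: list[SkeletonNetwork]) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "networks": [{
            "n_sets": n.n_sets,
            "signature": [n.signature()[0], list(n.signature()[1])],
            "sets": [{
                "skeleton": list(s.skeleton),
                "halo": [{"gene": g, "f": fv, "anchor": a} for g, fv, a in s.halo],
            } for s in n.sets],
            "intergroup_types": [
                {"set_a": min(k), "set_b": max(k), "curve_type": t}
                for k, t in sorted(n.intergroup_types.items(), key=lambda kv: sorted(kv[0]))
            ],
        } for n in networks],
    }


def write_networks_json(networks: list[SkeletonNetwork], path) -> None:
    with open(path, "w") as fh:
        json.dump(networks_to_dict(networks), fh, indent=2, sort_keys=True)
        fh.write("\n")


def networks_to_graphml(networks: list[SkeletonNetwork]) -> nx.Graph:
    """Two-level view: gene nodes tagged with (network, set, role); edges are
    skeleton-to-skeleton relations between sets, labelled with the curve type."""
    G = nx.Graph()
    for ni, net in enumerate(networks):
        for si, s in enumerate(net.sets):
            for g in s.skeleton:
                G.add_node(f"{ni}:{g}", gene=g, network=ni, set=si, role="skeleton")
            for g, fv, anchor in s.halo:
                node = f"{ni}:{g}"
                G.add_node(node, gene=g, network=ni, set=si, role="halo")
                G.add_edge(node, f"{ni}:{anchor}", kind="coexpression", f=fv)
        for key, t in sorted(net.intergroup_types.items(), key=lambda kv: sorted(kv[0])):
            i, j = sorted(key)
            for a in net.sets[i].skeleton:
                for b in net.sets[j].skeleton:
                    G.add_edge(f"{ni}:{a}", f"{ni}:{b}", kind="nonlinear",
                               curve_type=t)
    return G


def write_networks_graphml(networks: list[SkeletonNetwork], path) -> None:
    nx.write_graphml(networks_to_graphml(networks), path)
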