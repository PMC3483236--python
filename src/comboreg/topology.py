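"""Topology of the combinatorial regulatory network.

Degree statistics, out-degree power-law fit, betweenness, Krackhardt
hierarchy, coordinating regulator pairs (shared-target Fisher tests), and a
census of the 18 signed triple-vertex circuit types (14 feed-forward loops,
4 feed-back loops) with degree-preserving randomization for empirical
significance.

Vertex kinds are TF, miRNA and (non-TF) gene; legal directed edge kinds are
TF→gene, TF→TF, TF→miRNA, miRNA→gene and miRNA→TF. Every miRNA-outgoing
edge is repressing (negative efficacy) by model construction, while TF
edges may activate or repress — this asymmetry is what limits the signed
triad catalogue to exactly 18 types.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_LEGAL_EDGE_KINDS = {
    ("TF", "gene"), ("TF", "TF"), ("TF", "miR"),
    ("miR", "gene"), ("miR", "TF"),
}


def _as_digraph(net) -> nx.DiGraph:
    """Accept a RegulatoryNetwork or a ready nx.DiGraph."""
    if isinstance(net, nx.DiGraph):
        return net
    return net.to_digraph()


# ---------------------------------------------------------------------------
# degrees / global structure

def degree_statistics(net) -> tuple[pd.DataFrame, float]:
    """Per-vertex in/out degrees and the Pearson correlation between them.

    All edge types count uniformly. The correlation is computed over
    vertices carrying at least one edge; NaN when fewer than 3 such
    vertices or no degree variation.
    """
    g = _as_digraph(net)
    rows = [
        (v, d.get("kind", "gene"), g.in_degree(v), g.out_degree(v))
        for v, d in g.nodes(data=True)
    ]
    table = pd.DataFrame(rows, columns=["vertex", "kind", "in_degree", "out_degree"])
    active = table[(table.in_degree + table.out_degree) > 0]
    corr = float("nan")
    if len(active) >= 3 and active.in_degree.nunique() > 1 \
            and active.out_degree.nunique() > 1:
        corr = float(stats.pearsonr(active.in_degree, active.out_degree).statistic)
    return table, corr


def out_degree_powerlaw_fit(net) -> tuple[float, float]:
    """Least-squares slope of log10(frequency) on log10(out-degree).

    Zero out-degrees are excluded; raw (unbinned) degree frequencies are
    used. Returns (slope, p value of the slope's t test); (NaN, NaN) with
    fewer than 3 distinct nonzero out-degree values.
    """
    g = _as_digraph(net)
    degrees = np.array([d for _v, d in g.out_degree() if d > 0])
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        return float("nan"), float("nan")
    fit = stats.linregress(np.log10(values), np.log10(counts))
    return float(fit.slope), float(fit.pvalue)


def betweenness(net) -> dict[str, float]:
    """Directed, unweighted, unnormalized shortest-path betweenness with
    endpoints excluded (raw counts, fractional over tied shortest paths)."""
    g = _as_digraph(net)
    return nx.betweenness_centrality(g, normalized=False, endpoints=False)


def krackhardt_hierarchy(net) -> float:
    """1 − (mutually reachable ordered pairs) / (reachable ordered pairs).

    Reachability is via directed paths of length ≥ 1. A DAG scores 1, a
    fully reciprocal graph 0; NaN when no ordered pair is reachable.
    """
    g = _as_digraph(net)
    reach = {v: nx.descendants(g, v) for v in g}
    n_reachable = sum(len(s) for s in reach.values())
    if n_reachable == 0:
        return float("nan")
    n_mutual = sum(
        1 for u, s in reach.items() for v in s if u in reach[v]
    )
    return 1.0 - n_mutual / n_reachable


def coordinating_pairs(net, alpha: float = 0.01) -> pd.DataFrame:
    """Regulator pairs sharing significantly many targets.

    For each unordered pair of regulators a one-sided Fisher exact test is
    run on the 2×2 table of target-set membership over the universe of all
    distinct targets in the network. Pairs with p < ``alpha`` are returned,
    labelled TF-TF, miR-miR or TF-miR.
    """
    g = _as_digraph(net)
    targets_of = {
        v: set(g.successors(v)) for v in g if g.out_degree(v) > 0
    }
    universe = set().union(*targets_of.values()) if targets_of else set()
    n_universe = len(universe)
    kind_of = {v: g.nodes[v].get("kind", "gene") for v in g}
    rows = []
    for a, b in itertools.combinations(sorted(targets_of), 2):
        ta, tb = targets_of[a], targets_of[b]
        shared = len(ta & tb)
        if shared == 0:
            continue
        table = [[shared, len(ta) - shared],
                 [len(tb) - shared, n_universe - len(ta) - len(tb) + shared]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        if p < alpha:
            ka, kb = kind_of[a], kind_of[b]
            short = {"TF": "TF", "miRNA": "miR", "gene": "gene"}
            group = "-".join(sorted((short[ka], short[kb])))
            rows.append((a, b, group, shared, p))
    out = pd.DataFrame(
        rows, columns=["regulator_a", "regulator_b", "group",
                       "shared_targets", "p_value"])
    return out.sort_values("p_value", ignore_index=True)


# ---------------------------------------------------------------------------
# signed triple-vertex circuits

@dataclass(frozen=True)
class MotifType:
    """One signed, typed closed triple-vertex circuit.

    ``skeleton`` is 'FFL' (A→B, B→C, A→C) or 'FBL' (A→B, B→C, C→A);
    ``kinds`` the vertex kinds of (A, B, C) with 'miR', 'TF' or 'gene'
    (non-TF gene); ``signs`` the signs of the edges in skeleton order,
    +1 activating / −1 repressing. FBL types are anchored at their unique
    miRNA (A = miR).
    """

    skeleton: str
    kinds: tuple[str, str, str]
    signs: tuple[int, int, int]

    @property
    def label(self) -> str:
        s = {1: "+", -1: "-"}
        a, b, c = self.kinds
        sab, sbc, sac = self.signs
        if self.skeleton == "FFL":
            return f"FFL:{a}-{s[sab]}->{b}-{s[sbc]}->{c}|{a}-{s[sac]}->{c}"
        return f"FBL:{a}-{s[sab]}->{b}-{s[sbc]}->{c}-{s[sac]}->{a}"


def _edge_legal(src_kind: str, dst_kind: str) -> bool:
    return (src_kind, dst_kind) in _LEGAL_EDGE_KINDS


def _signs_for(src_kind: str) -> tuple[int, ...]:
    return (1, -1) if src_kind == "TF" else (-1,)


def enumerate_motif_types() -> list[MotifType]:
    """All signed triad types with ≥1 TF and ≥1 miRNA: 14 FFLs + 4 FBLs.

    FFLs take every kind assignment (A, B, C) with legal edges A→B, B→C and
    A→C; FBLs every assignment with legal cycle A→B→C→A, anchored at the
    miRNA. TF-outgoing edges take both signs, miRNA-outgoing edges are
    always repressing; circuits lacking a TF or a miRNA are excluded.
    """
    kinds = ("TF", "miR", "gene")
    types: list[MotifType] = []
    for a, b, c in itertools.product(kinds, kinds, ("miR", "gene")):
        # the FFL sink is an ultimate target: a miRNA or a non-TF gene
        if "miR" not in (a, b, c) or "TF" not in (a, b, c):
            continue
        if _edge_legal(a, b) and _edge_legal(b, c) and _edge_legal(a, c):
            for signs in itertools.product(_signs_for(a), _signs_for(b),
                                           _signs_for(a)):
                types.append(MotifType("FFL", (a, b, c), signs))
    fbl: set[MotifType] = set()
    for a, b, c in itertools.product(kinds, repeat=3):
        if "miR" not in (a, b, c) or "TF" not in (a, b, c):
            continue
        if not (_edge_legal(a, b) and _edge_legal(b, c) and _edge_legal(c, a)):
            continue
        for signs in itertools.product(_signs_for(a), _signs_for(b),
                                       _signs_for(c)):
            fbl.add(_canonical_fbl((a, b, c), signs))
    types.extend(sorted(fbl, key=lambda t: t.label))
    return types


def _canonical_fbl(kinds: tuple[str, str, str],
                   signs: tuple[int, int, int]) -> MotifType:
    """Rotate a 3-cycle so that its (unique) miRNA is vertex A."""
    rotations = [
        (tuple(kinds[i:] + kinds[:i]), tuple(signs[i:] + signs[:i]))
        for i in range(3)
    ]
    for k, s in rotations:
        if k[0] == "miR":
            return MotifType("FBL", k, s)
    raise ValueError("FBL without miRNA cannot be canonicalized")


def _node_kind(g: nx.DiGraph, v) -> str:
    kind = g.nodes[v].get("kind", "gene")
    return {"miRNA": "miR"}.get(kind, kind)


def _edge_sign(g: nx.DiGraph, u, v) -> int:
    data = g.edges[u, v]
    if "efficacy" in data:
        return 1 if data["efficacy"] > 0 else -1
    sign = data.get("sign", "repressing")
    if isinstance(sign, str):
        return 1 if sign in ("activating", "+") else -1
    return 1 if sign > 0 else -1


def _classify_triple(g: nx.DiGraph, triple) -> MotifType | None:
    """Induced-subgraph match: exactly 3 edges forming an FFL or FBL."""
    edges = [(u, v) for u, v in itertools.permutations(triple, 2)
             if g.has_edge(u, v)]
    if len(edges) != 3:
        return None
    for a, b, c in itertools.permutations(triple):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            return MotifType(
                "FFL",
                (_node_kind(g, a), _node_kind(g, b), _node_kind(g, c)),
                (_edge_sign(g, a, b), _edge_sign(g, b, c), _edge_sign(g, a, c)),
            )
    for a, b, c in itertools.permutations(triple):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(c, a):
            kinds = (_node_kind(g, a), _node_kind(g, b), _node_kind(g, c))
            if "miR" not in kinds:
                return None
            signs = (_edge_sign(g, a, b), _edge_sign(g, b, c),
                     _edge_sign(g, c, a))
            return _canonical_fbl(kinds, signs)
    return None


def motif_census(net) -> pd.DataFrame:
    """Count instances of each of the 18 circuit types.

    A vertex triple is an instance when its induced directed edges are
    exactly the three edges of one type, with matching vertex kinds and
    edge signs. Triples whose kinds/signs fall outside the 18-type catalogue
    (e.g. all-TF triangles) are ignored.
    """
    g = _as_digraph(net)
    catalogue = {t: 0 for t in enumerate_motif_types()}
    und = g.to_undirected(as_view=False)
    seen: set[frozenset] = set()
    for u, v in und.edges():
        for w in set(und.neighbors(u)) & set(und.neighbors(v)):
            triple = frozenset((u, v, w))
            if triple in seen:
                continue
            seen.add(triple)
            t = _classify_triple(g, tuple(sorted(triple)))
            if t is not None and t in catalogue:
                catalogue[t] += 1
    rows = [(t.label, t.skeleton, n) for t, n in catalogue.items()]
    return pd.DataFrame(rows, columns=["motif", "skeleton", "count"])


# ---------------------------------------------------------------------------
# degree-preserving randomization

def randomize_network(
    g: nx.DiGraph, rng: np.random.Generator, n_swaps_per_edge: int = 10
) -> nx.DiGraph:
    """Degree-preserving shuffle by within-edge-type pair swaps.

    Edges are grouped by regulation type — regulator kind (TF or miRNA) ×
    target molecule type (miRNA or mRNA, the latter covering TFs and non-TF
    genes alike); two edges a→b, c→d of the same group are rewired to a→d,
    c→b when that creates neither a self-loop nor a duplicate edge. Edge
    attributes (sign, efficacy) travel with the source endpoint, so every
    vertex keeps its exact per-type in- and out-degree and regulators keep
    their sign multiset.
    """
    out = g.copy()
    groups: dict[tuple[str, str], list[tuple]] = {}
    for u, v, data in out.edges(data=True):
        dst = "miR" if _node_kind(out, v) == "miR" else "mRNA"
        key = (_node_kind(out, u), dst)
        groups.setdefault(key, []).append((u, v))
    for key, edges in groups.items():
        if len(edges) < 2:
            logger.debug("edge type %s has <2 edges; left fixed", key)
            continue
        attempts = n_swaps_per_edge * len(edges)
        for _ in range(attempts):
            i, j = rng.integers(0, len(edges), size=2)
            if i == j:
                continue
            (a, b), (c, d) = edges[i], edges[j]
            if a == d or c == b:
                continue
            if out.has_edge(a, d) or out.has_edge(c, b):
                continue
            attr_ab = dict(out.edges[a, b])
            attr_cd = dict(out.edges[c, d])
            out.remove_edge(a, b)
            out.remove_edge(c, d)
            out.add_edge(a, d, **attr_ab)
            out.add_edge(c, b, **attr_cd)
            edges[i], edges[j] = (a, d), (c, b)
    return out


def motif_significance(
    net, n_rand: int = 1000, seed: int = 0, n_swaps_per_edge: int = 10
) -> pd.DataFrame:
    """Empirical motif enrichment against degree-preserving null networks.

    For each circuit type: p = (1 + #{randomized count ≥ observed count})
    / (n_rand + 1) — the add-one estimator, so p is never 0 and an observed
    count of 0 gives p = 1.
    """
    g = _as_digraph(net)
    observed = motif_census(g).set_index("motif")
    rng = np.random.default_rng(seed)
    exceed = pd.Series(0, index=observed.index)
    for _ in range(n_rand):
        shuffled = randomize_network(g, rng, n_swaps_per_edge)
        counts = motif_census(shuffled).set_index("motif")["count"]
        exceed += (counts >= observed["count"]).astype(int)
    out = observed.reset_index()
    out["p_value"] = ((1 + exceed.to_numpy()) / (n_rand + 1))
    out["n_randomizations"] = n_rand
    return out
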