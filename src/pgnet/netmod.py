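"""Dense-module discovery on a gene-score-weighted PPI network.

A module is a connected subgraph with locally maximal aggregate
association signal, scored Zm = sum(z) / sqrt(k) over its k member
nodes.  The search is greedy from every seed node: candidates within
graph distance d of the current module are considered, and the best
addition is accepted only if it raises Zm by more than the factor
(1 + r).  Module scores are normalized against random node sets of the
same size (Zn), the top fraction is selected, and enrichment of the
selected proteins is assessed by hypergeometric/Fisher and permutation
tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genescore import Z_CLAMP

logger = logging.getLogger(__name__)

Z_MIN = -Z_CLAMP  # weight for nodes without a gene score (most conservative)


@dataclass
class Module:
    seed: str
    nodes: frozenset[str]
    zm: float
    zn: float | None = None
    rank: int | None = None

    @property
    def k(self) -> int:
        return len(self.nodes)


@dataclass
class SearchParams:
    d: int = 2
    r: float = 0.1
    max_size: int = 50
    b_norm: int = 10_000

    def validate(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")


def build_weighted_ppi(
    edges, gene_scores: dict[str, float] | pd.DataFrame, z_min: float = Z_MIN
) -> nx.Graph:
    """Simple undirected graph with node weight attribute ``z``.

    Duplicate and reversed edges are deduplicated; self-loops dropped
    with a count logged; nodes without a score get ``z_min``.
    """
    if isinstance(gene_scores, pd.DataFrame):
        gene_scores = dict(zip(gene_scores["gene"], gene_scores["z"]))
    G = nx.Graph()
    n_loops = 0
    for a, b in edges:
        if a == b:
            n_loops += 1
            continue
        G.add_edge(a, b)
    if n_loops:
        logger.info("build_weighted_ppi: dropped %d self-loops", n_loops)
    if G.number_of_edges() == 0:
        raise ValueError("edge list produced an empty graph")
    for node in G.nodes:
        G.nodes[node]["z"] = float(gene_scores.get(node, z_min))
    return G


def module_score(G: nx.Graph, nodes) -> float:
    """Zm = sum of node z over sqrt(module size)."""
    nodes = list(nodes)
    return sum(G.nodes[v]["z"] for v in nodes) / math.sqrt(len(nodes))


def _bfs_candidates(
    G: nx.Graph, module: set[str], d: int
) -> dict[str, list[str]]:
    """Nodes within distance <= d of the module, with shortest-path interiors.

    Multi-source BFS with deterministic (sorted) neighbor expansion;
    returns {candidate: [interior nodes on a shortest path to the
    module]} — empty list for direct neighbors.
    """
    parents: dict[str, str | None] = {v: None for v in module}
    depth = {v: 0 for v in module}
    frontier = sorted(module)
    out: dict[str, list[str]] = {}
    for dist in range(1, d + 1):
        nxt = []
        for u in frontier:
            for w in sorted(G.neighbors(u)):
                if w not in depth:
                    depth[w] = dist
                    parents[w] = u
                    nxt.append(w)
        frontier = nxt
    for v, dist in depth.items():
        if dist == 0:
            continue
        interior = []
        u = parents[v]
        while u is not None and depth[u] > 0:
            interior.append(u)
            u = parents[u]
        out[v] = interior
    return out


def grow_module(
    G: nx.Graph,
    seed: str,
    params: SearchParams | None = None,
    strict_adjacent: bool = False,
) -> Module:
    """Greedy module growth from one seed node.

    Each step evaluates every candidate within distance d of the module
    (distance 1 if ``strict_adjacent``); adding a distance-d candidate
    also adds its shortest-path interior nodes so the module stays
    connected (interiors count toward k).  The step maximizing the new
    Zm is taken iff Zm_new > Zm_old * (1 + r); ties break on
    lexicographic candidate name.
    """
    if params is None:
        params = SearchParams()
    params.validate()
    d = 1 if strict_adjacent else params.d
    module: set[str] = {seed}
    zm = module_score(G, module)
    while len(module) < params.max_size:
        candidates = _bfs_candidates(G, module, d)
        best: tuple[float, str, set[str]] | None = None
        for v in sorted(candidates):
            addition = {v} | set(candidates[v])
            new_nodes = module | addition
            zm_new = module_score(G, new_nodes)
            if best is None or zm_new > best[0] + 1e-15:
                best = (zm_new, v, new_nodes)
        if best is None or not (best[0] > zm * (1.0 + params.r)):
            break
        zm, module = best[0], best[2]
    return Module(seed=seed, nodes=frozenset(module), zm=zm)


def dense_module_search(
    G: nx.Graph,
    params: SearchParams | None = None,
    seed_nodes=None,
    strict_adjacent: bool = False,
) -> list[Module]:
    """One greedy module per seed node (default: every node)."""
    if params is None:
        params = SearchParams()
    if seed_nodes is None:
        seed_nodes = sorted(G.nodes)
    return [grow_module(G, s, params, strict_adjacent) for s in seed_nodes]


def satisfies_stopping(
    G: nx.Graph, module: Module, params: SearchParams, strict_adjacent: bool = False
) -> bool:
    """Post-hoc check: no admissible addition raises Zm by > (1 + r)."""
    d = 1 if strict_adjacent else params.d
    if module.k >= params.max_size:
        return True
    nodes = set(module.nodes)
    candidates = _bfs_candidates(G, nodes, d)
    for v, interior in candidates.items():
        zm_new = module_score(G, nodes | {v} | set(interior))
        if zm_new > module.zm * (1.0 + params.r):
            return False
    return True


def normalize_modules(
    modules: list[Module],
    G: nx.Graph,
    b_norm: int = 10_000,
    seed: int = 0,
) -> list[Module]:
    """Zn = (Zm - mean_k) / sd_k against random same-size node sets.

    For every module size present, ``b_norm`` uniform k-node subsets of
    the graph are drawn (seeded RNG) and their Zm summarize the null.
    """
    if b_norm < 100:
        raise ValueError("b_norm must be >= 100")
    rng = np.random.default_rng(seed)
    z = np.array([G.nodes[v]["z"] for v in sorted(G.nodes)])
    n = z.size
    sizes = sorted({m.k for m in modules})
    null_stats: dict[int, tuple[float, float]] = {}
    for k in sizes:
        if k >= n:
            samples = np.full(b_norm, z.sum() / math.sqrt(n))
        elif b_norm * n <= 50_000_000:
            idx = np.argpartition(rng.random((b_norm, n)), k - 1, axis=1)[:, :k]
            samples = z[idx].sum(axis=1) / math.sqrt(k)
        else:  # pragma: no cover - large-graph fallback
            samples = np.array(
                [z[rng.choice(n, size=k, replace=False)].sum() for _ in range(b_norm)]
            ) / math.sqrt(k)
        mean, sd = float(samples.mean()), float(samples.std(ddof=1))
        if sd <= 1e-12 * max(1.0, abs(mean)):
            raise ValueError(f"degenerate weights: null sd is 0 at size {k}")
        null_stats[k] = (mean, sd)
    out = []
    for m in modules:
        mean, sd = null_stats[m.k]
        out.append(Module(seed=m.seed, nodes=m.nodes, zm=m.zm, zn=(m.zm - mean) / sd))
    return out


def top_percent_modules(
    modules: list[Module], q: float = 0.01
) -> tuple[list[Module], set[str]]:
    """Top ceil(q * n) modules by Zn (ties: Zm, then seed), plus node union."""
    if not modules:
        return [], set()
    if any(m.zn is None for m in modules):
        raise ValueError("modules must be normalized before selection")
    n_sel = math.ceil(q * len(modules))
    ranked = sorted(modules, key=lambda m: (-m.zn, -m.zm, m.seed))
    selected = []
    for rank, m in enumerate(ranked[:n_sel], start=1):
        selected.append(Module(seed=m.seed, nodes=m.nodes, zm=m.zm, zn=m.zn, rank=rank))
    union: set[str] = set()
    for m in selected:
        union |= m.nodes
    return selected, union


def overlap_test(
    set_a: set[str], set_b: set[str], universe_size: int
) -> tuple[int, float, float]:
    """One-sided Fisher/hypergeometric enrichment of the overlap.

    Returns (overlap, upper-tail p, odds ratio from the 2x2 table).
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    ov = len(a & b)
    p = float(stats.hypergeom.sf(ov - 1, universe_size, len(a), len(b)))
    n11 = ov
    n12 = len(a) - ov
    n21 = len(b) - ov
    n22 = universe_size - len(a) - len(b) + ov
    if n12 * n21 == 0:
        odds = math.inf if n11 * n22 > 0 else math.nan
    else:
        odds = (n11 * n22) / (n12 * n21)
    return ov, p, odds


def first_degree_network(
    G: nx.Graph, risk_loci: set[str], pqtl_proteins: set[str] | None = None
) -> nx.Graph:
    """Induced subgraph on present risk loci and their direct neighbors.

    Node attributes mark risk loci and (optionally) pQTL-associated
    proteins.  Raises if no risk locus is present in the graph.
    """
    present = {v for v in risk_loci if v in G}
    missing = set(risk_loci) - present
    if missing:
        logger.info("first_degree_network: %d loci absent from graph", len(missing))
    if not present:
        raise ValueError("no risk locus present in the PPI graph")
    nodes = set(present)
    for v in present:
        nodes |= set(G.neighbors(v))
    sub = G.subgraph(nodes).copy()
    for v in sub.nodes:
        sub.nodes[v]["risk_locus"] = v in present
        if pqtl_proteins is not None:
            sub.nodes[v]["pqtl_protein"] = v in pqtl_proteins
    return sub


def permutation_enrichment(
    G: nx.Graph | list[str],
    neighbor_set: set[str],
    pqtl_proteins: set[str],
    B: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of pQTL-protein enrichment in a node set.

    The observed statistic is the one-sided Fisher p for the overlap of
    ``neighbor_set`` with ``pqtl_proteins`` in the network universe.
    B same-size uniform node sets give the null; the empirical p uses
    the +1 convention: (1 + #{p_b <= p_obs}) / (B + 1).
    Returns (empirical p, observed Fisher p).
    """
    nodes = sorted(G.nodes) if isinstance(G, nx.Graph) else sorted(G)
    n = len(nodes)
    k = len(neighbor_set)
    if k > n:
        raise ValueError("neighbor_set larger than the node universe")
    member = np.isin(np.array(nodes), np.array(sorted(pqtl_proteins)))
    K = int(member.sum())
    ov_obs = len(set(neighbor_set) & set(pqtl_proteins) & set(nodes))
    p_obs = float(stats.hypergeom.sf(ov_obs - 1, n, K, k))

    rng = np.random.default_rng(seed)
    if B * n <= 50_000_000:
        idx = np.argpartition(rng.random((B, n)), k - 1, axis=1)[:, :k]
        ov = member[idx].sum(axis=1)
    else:  # pragma: no cover - large-graph fallback
        ov = np.array(
            [member[rng.choice(n, size=k, replace=False)].sum() for _ in range(B)]
        )
    # Fisher p is monotone decreasing in the overlap count
    p_perm = stats.hypergeom.sf(ov - 1, n, K, k)
    p_emp = (1 + int((p_perm <= p_obs + 1e-15).sum())) / (B + 1)
    return float(p_emp), p_obs


def modules_to_frame(modules: list[Module]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seed": [m.seed for m in modules],
            "members": [";".join(sorted(m.nodes)) for m in modules],
            "k": [m.k for m in modules],
            "Zm": [m.zm for m in modules],
            "Zn": [m.zn for m in modules],
            "rank": [m.rank for m in modules],
        }
    )
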