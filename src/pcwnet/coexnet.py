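"""Spearman co-expression networks and dense-module extraction per bi-cluster.

Each expanded bi-cluster is turned into a network over its genes: an edge is
drawn between two genes when the Spearman correlation of their *raw*
expression values over the bi-cluster's conditions exceeds 0.7 in absolute
value (sign recorded).  Dense connected sub-networks (modules) are extracted
with a molecular-complex-detection style procedure: vertices are weighted by
the highest k-core of their neighborhood times that core's density, complexes
grow from high-weight seeds, and a haircut plus a strict-density refinement
guarantee every emitted module is connected, disjoint from its siblings and
strictly denser than its parent network.  Only modules containing at least
one seed (known pathway) gene are retained downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .exprio import ExpressionMatrix, SeedSet
from .qbiclust import Bicluster


@dataclass
class CoexpressionNetwork:
    bicluster_id: str
    nodes: tuple[str, ...]
    edges: list[tuple[str, str, float]]  # (gene_a, gene_b, rho), a < b

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b, rho in self.edges:
            g.add_edge(a, b, rho=rho, sign="+" if rho > 0 else "-")
        return g

    @property
    def density(self) -> float:
        return nx.density(self.graph())


@dataclass
class CoexpressionModule:
    module_id: str
    genes: tuple[str, ...]
    edges: list[tuple[str, str, float]]
    density: float
    seed_members: dict[str, str] = field(default_factory=dict)
    recruited_members: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class HotLinkGroup:
    module_id: str
    group_id: int
    edges: list[tuple[str, str, float]]

    @property
    def genes(self) -> tuple[str, ...]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out |= {a, b}
        return tuple(sorted(out))


@dataclass
class McodeParams:
    """Canonical published defaults for the complex-detection step."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    min_size: int = 3


def spearman_rho(x, y) -> float | None:
    """Spearman correlation (Pearson of midranks); None for zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rho = stats.spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


def build_network(b: Bicluster, m: ExpressionMatrix,
                  rho_cut: float = 0.7,
                  bicluster_id: str | None = None) -> CoexpressionNetwork | None:
    """All-pairs Spearman network over a bi-cluster's genes and conditions.

    Edges require |rho| > rho_cut on the raw expression values restricted to
    the bi-cluster's conditions.  Returns None when no gene pair qualifies
    (the bi-cluster is dropped from further consideration).
    """
    genes = [g for g in b.genes if g in set(m.gene_ids)]
    conds = [c for c in b.conditions if c in set(m.condition_ids)]
    if len(genes) < 2 or len(conds) < 3:
        return None
    sub = m.data.loc[genes, conds].to_numpy(dtype=float)
    rho = stats.spearmanr(sub, axis=1).statistic
    if np.isscalar(rho):  # two genes
        rho = np.array([[1.0, rho], [rho, 1.0]])
    edges: list[tuple[str, str, float]] = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = rho[i, j]
            if np.isnan(r) or abs(r) <= rho_cut:
                continue
            a, b2 = sorted((genes[i], genes[j]))
            edges.append((a, b2, float(r)))
    if not edges:
        return None
    nodes = tuple(sorted({g for e in edges for g in e[:2]}))
    return CoexpressionNetwork(
        bicluster_id=bicluster_id or "net", nodes=nodes, edges=edges)


def _vertex_weights(g: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph(list(g.neighbors(v)) + [v])
        core = nx.core_number(nbhd)
        kmax = max(core.values())
        core_nodes = [u for u, k in core.items() if k >= kmax]
        core_sub = nbhd.subgraph(core_nodes)
        weights[v] = kmax * nx.density(core_sub)
    return weights


def _haircut(sub: nx.Graph) -> nx.Graph:
    sub = sub.copy()
    while True:
        trim = [v for v in sub.nodes if sub.degree(v) < 2]
        if not trim:
            return sub
        sub.remove_nodes_from(trim)


def find_modules(net: CoexpressionNetwork,
                 params: McodeParams | None = None) -> list[CoexpressionModule]:
    """Non-overlapping dense modules of one co-expression network.

    Complexes grow from the highest-weight unassigned vertex, admitting
    unassigned neighbors whose weight is >= (1 - node_score_cutoff) times the
    seed weight within the depth limit; a haircut removes singly connected
    periphery; modules must contain a k-core, meet the minimum size and be
    strictly denser than the parent network (the sparsest member is removed
    until the density condition holds).  Assignments are partial: genes can
    remain outside every module.  Modules are ordered by score
    (density x size) and numbered ``<network>_<ordinal>``.
    """
    params = params or McodeParams()
    g = net.graph()
    if g.number_of_edges() == 0:
        return []
    net_density = nx.density(g)
    weights = _vertex_weights(g, params.degree_cutoff)
    assigned: set[str] = set()
    raw_modules: list[set[str]] = []
    for seed in sorted(g.nodes, key=lambda v: (-weights[v], v)):
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = (1 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            v, depth = frontier.pop(0)
            if depth >= params.max_depth:
                continue
            for u in sorted(g.neighbors(v)):
                if u in members or u in assigned:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    frontier.append((u, depth + 1))
        sub = g.subgraph(members)
        if params.haircut:
            sub = _haircut(sub)
        if sub.number_of_nodes() == 0:
            assigned |= members
            continue
        core = nx.core_number(sub)
        if max(core.values(), default=0) < params.k_core:
            assigned |= members
            continue
        # Strict-density refinement against the parent network.
        sub = nx.Graph(sub)
        while (sub.number_of_nodes() >= params.min_size
               and nx.density(sub) <= net_density):
            drop = min(sub.nodes, key=lambda v: (sub.degree(v), weights[v], v))
            sub.remove_node(drop)
            if params.haircut:
                sub = _haircut(nx.Graph(sub))
        if (sub.number_of_nodes() >= params.min_size
                and nx.is_connected(sub)
                and nx.density(sub) > net_density):
            raw_modules.append(set(sub.nodes))
        assigned |= members
    raw_modules.sort(key=lambda s: (-nx.density(g.subgraph(s)) * len(s),
                                    tuple(sorted(s))))
    modules = []
    for i, mem in enumerate(raw_modules, start=1):
        sub = g.subgraph(mem)
        edges = sorted((min(a, b), max(a, b), d["rho"])
                       for a, b, d in sub.edges(data=True))
        modules.append(CoexpressionModule(
            module_id=f"{net.bicluster_id}_{i}",
            genes=tuple(sorted(mem)),
            edges=edges,
            density=nx.density(sub),
        ))
    return modules


def retain_seeded_modules(mods: list[CoexpressionModule],
                          seeds: SeedSet) -> list[CoexpressionModule]:
    """Keep modules with >= 1 seed gene; fill seed/recruited partitions."""
    kept = []
    for mod in mods:
        seed_members = {g: seeds.members[g] for g in mod.genes if g in seeds}
        if not seed_members:
            continue
        mod.seed_members = seed_members
        mod.recruited_members = tuple(g for g in mod.genes
                                      if g not in seed_members)
        kept.append(mod)
    return kept


def find_hot_links(mod: CoexpressionModule, percentile: float = 0.90,
                   floor: float = 0.95) -> list[HotLinkGroup]:
    """Connected groups of the module's highest-|rho| ('hot') edges.

    Hot edges satisfy |rho| >= max(floor, the given percentile of the module's
    |rho| values) and lie strictly above the module's median |rho|.
    """
    if not mod.edges:
        raise ValueError("module has no edges")
    abs_rho = np.array([abs(r) for _, _, r in mod.edges])
    threshold = max(floor, float(np.quantile(abs_rho, percentile)))
    median = float(np.median(abs_rho))
    hot = [(a, b, r) for a, b, r in mod.edges
           if abs(r) >= threshold and abs(r) > median]
    if not hot:
        return []
    g = nx.Graph()
    for a, b, r in hot:
        g.add_edge(a, b, rho=r)
    groups = []
    comps = sorted(nx.connected_components(g), key=lambda s: tuple(sorted(s)))
    for i, comp in enumerate(comps, start=1):
        edges = sorted((min(a, b), max(a, b), d["rho"])
                       for a, b, d in g.subgraph(comp).edges(data=True))
        groups.append(HotLinkGroup(module_id=mod.module_id, group_id=i,
                                   edges=edges))
    return groups


def write_network_tsv(net: CoexpressionNetwork, path) -> None:
    import pandas as pd

    pd.DataFrame(net.edges, columns=["gene_a", "gene_b", "rho"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def write_modules_json(mods, path) -> None:
    import json

    payload = [
        {"module_id": m.module_id, "genes": list(m.genes),
         "seed_members": dict(m.seed_members),
         "recruited": list(m.recruited_members), "density": m.density,
         "edges": [[a, b, r] for a, b, r in m.edges]}
        for m in mods
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_hot_links_tsv(groups, path) -> None:
    import pandas as pd

    rows = [(g.module_id, g.group_id, a, b, r)
            for g in groups for a, b, r in g.edges]
    pd.DataFrame(rows, columns=["module_id", "group_id", "gene_a", "gene_b",
                                "rho"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
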