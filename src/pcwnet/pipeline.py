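"""End-to-end glue: expression matrix + seed list -> retained co-expression
modules, plus evaluation helpers against planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

from .coexnet import (CoexpressionModule, CoexpressionNetwork, McodeParams,
                      build_network, find_modules, retain_seeded_modules)
from .exprio import (DiscreteMatrix, ExpressionMatrix, SeedSet, discretize,
                     extract_seed_matrix)
from .qbiclust import Bicluster, expand_bicluster, seed_biclusters


@dataclass
class PipelineResult:
    biclusters: list[Bicluster] = field(default_factory=list)
    networks: list[CoexpressionNetwork] = field(default_factory=list)
    modules: list[CoexpressionModule] = field(default_factory=list)


def run_pipeline(expr: ExpressionMatrix, seeds: SeedSet, q: float = 0.15,
                 c1: float = 0.85, c2: float = 0.80,
                 min_genes: int = 3, min_conditions: int = 3,
                 rho_cut: float = 0.7,
                 mcode_params: McodeParams | None = None) -> PipelineResult:
    """Discretize, bi-cluster around the seeds, expand, and extract modules.

    The default (c1, c2) sit inside the grid-searched consistency range; call
    :func:`pcwnet.qbiclust.grid_search` to tune them for a new compendium.
    """
    d_full = discretize(expr, q=q)
    seed_expr = extract_seed_matrix(expr, seeds)
    d_seed = DiscreteMatrix(d_full.data.loc[seed_expr.gene_ids], q=q)
    result = PipelineResult()
    result.biclusters = [
        expand_bicluster(b, d_full, c2)
        for b in seed_biclusters(d_seed, c1, min_genes, min_conditions)
    ]
    for i, b in enumerate(result.biclusters, start=1):
        net = build_network(b, expr, rho_cut=rho_cut, bicluster_id=str(i))
        if net is None:
            continue
        result.networks.append(net)
        result.modules.extend(find_modules(net, mcode_params))
    result.modules = retain_seeded_modules(result.modules, seeds)
    return result


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def match_planted_blocks(truth_blocks, modules):
    """Best module per planted block by gene-set Jaccard.

    Returns a list of (block, best module or None, jaccard) triples.
    """
    out = []
    for block in truth_blocks:
        best, best_j = None, 0.0
        for mod in modules:
            j = jaccard(block.genes, mod.genes)
            if j > best_j:
                best, best_j = mod, j
        out.append((block, best, best_j))
    return out


def recruited_precision_recall(truth_blocks, seeds: SeedSet, modules):
    """Precision/recall of recruited (non-seed) genes against planted truth.

    The candidate set is the union of recruited members over retained
    modules; the target set is the union of planted non-seed genes.
    """
    planted = set()
    for block in truth_blocks:
        planted |= {g for g in block.genes if g not in seeds}
    recruited = set()
    for mod in modules:
        recruited |= set(mod.recruited_members)
    if not recruited:
        return 0.0, 0.0
    tp = len(recruited & planted)
    return tp / len(recruited), tp / len(planted)
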