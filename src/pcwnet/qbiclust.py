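"""Two-step seeded bi-clustering of a discretized expression compendium.

A bi-cluster is a gene set x condition set whose discretized sub-matrix is
column-wise coherent: on every member condition, at least a fraction ``c`` of
the member genes share the same nonzero regulation symbol (the *consistency
level*).  The procedure follows the graph formulation of qualitative
bi-clustering:

1. *Seed phase* (on the seed-gene sub-matrix): gene pairs are weighted by the
   number of conditions on which they share a nonzero symbol; each edge, in
   decreasing weight order, seeds a candidate from the pair's shared
   conditions.  The candidate grows gene by gene — each addition keeps only
   the conditions still meeting consistency ``c1``, and the largest-area
   snapshot along the growth chain is retained, then closed by alternating
   condition/gene additions.  Emitted bi-clusters are non-redundant: a gene
   pair appears in at most one seed-phase bi-cluster.
2. *Expansion phase* (against the full matrix): each seed bi-cluster recruits
   every outside gene whose symbols agree with the bi-cluster's dominant
   per-condition symbol on at least a fraction ``c2`` of its conditions.

The (c1, c2) pair is chosen by a grid search maximizing the AUC of a
seed-holdout ROC analysis: held-out seed genes are the positives, an
equal-size random draw of non-seed genes the negatives, and each gene is
scored by its best match fraction to any expanded bi-cluster's dominant
profile (zero when below ``c2``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exprio import DiscreteMatrix, SeedSet

_EPS = 1e-12


@dataclass(frozen=True)
class Bicluster:
    """A coherent gene set x condition set with its consistency level."""

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    dominant_symbol: dict[str, int]
    consistency: float
    source: str  # "seed_phase" or "expanded"
    recruited: tuple[str, ...] = ()

    @property
    def area(self) -> int:
        return len(self.genes) * len(self.conditions)

    @property
    def seed_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if g not in set(self.recruited))


@dataclass
class GridSearchResult:
    entries: list[tuple[float, float, float]] = field(default_factory=list)
    best: tuple[float, float] = (0.0, 0.0)

    @property
    def best_auc(self) -> float:
        lookup = {(c1, c2): a for c1, c2, a in self.entries}
        return lookup[self.best]


#: Consistency grid: 0.05 increments over [0.70, 0.95] plus the 0.98 endpoint.
DEFAULT_GRID: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.98)


def build_gene_graph(d: DiscreteMatrix) -> dict[tuple[str, str], int]:
    """Weighted gene graph: weight = #conditions with identical nonzero symbols.

    Zero-weight pairs are omitted.  Keys are lexicographically sorted id pairs.
    """
    A = d.data.to_numpy(dtype=np.int8)
    if A.size == 0:
        return {}
    up = (A == 1).astype(np.int32)
    dn = (A == -1).astype(np.int32)
    W = up @ up.T + dn @ dn.T
    genes = d.gene_ids
    edges: dict[tuple[str, str], int] = {}
    n = len(genes)
    ii, jj = np.triu_indices(n, k=1)
    weights = W[ii, jj]
    for i, j, w in zip(ii, jj, weights):
        if w > 0:
            a, b = sorted((genes[i], genes[j]))
            edges[(a, b)] = int(w)
    return edges


def _counts(A: np.ndarray, rows: list[int], cols: np.ndarray):
    sub = A[np.ix_(rows, cols)]
    return (sub == 1).sum(axis=0), (sub == -1).sum(axis=0)


def bicluster_consistency(genes, conditions, d: DiscreteMatrix) -> float:
    """Min over conditions of the dominant nonzero symbol's gene fraction.

    A condition whose column is all-zero over the member genes scores 0.
    """
    if not len(genes) or not len(conditions):
        raise ValueError("empty gene or condition set")
    gi = [d.gene_ids.index(g) if isinstance(g, str) else g for g in genes]
    ci = np.array([d.condition_ids.index(c) if isinstance(c, str) else c
                   for c in conditions])
    A = d.data.to_numpy(dtype=np.int8)
    pos, neg = _counts(A, gi, ci)
    dom = np.maximum(pos, neg) / len(gi)
    return float(dom.min())


def _grow(A: np.ndarray, g: int, h: int, c1: float,
          min_genes: int, min_conditions: int):
    """Grow one candidate from a seed gene pair; return (genes, conds) or None."""
    n_genes = A.shape[0]
    shared = np.nonzero((A[g] == A[h]) & (A[g] != 0))[0]
    if shared.size < min_conditions:
        return None
    genes = [g, h]
    conds = shared
    snapshots = [(list(genes), conds.copy())]
    remaining = np.array([x for x in range(n_genes) if x not in (g, h)])

    pos, neg = _counts(A, genes, conds)
    while remaining.size and conds.size >= min_conditions:
        cand = A[remaining][:, conds]
        new_pos = pos[None, :] + (cand == 1)
        new_neg = neg[None, :] + (cand == -1)
        dom = np.maximum(new_pos, new_neg) / (len(genes) + 1)
        keep = dom + _EPS >= c1
        n_kept = keep.sum(axis=1)
        # a candidate must itself match the dominant symbol on >= c1 of the
        # retained conditions (dilution alone cannot admit an unrelated gene)
        dom_sym = np.where(new_pos >= new_neg, 1, -1).astype(np.int8)
        agree = ((cand == dom_sym) & keep).sum(axis=1)
        ok = (n_kept >= min_conditions) & (agree + _EPS >= c1 * n_kept)
        if not ok.any():
            break
        ranked = np.lexsort((remaining, -agree, -n_kept))
        best = next(int(i) for i in ranked if ok[i])
        x = int(remaining[best])
        kept_cols = keep[best]
        conds = conds[kept_cols]
        pos = new_pos[best][kept_cols]
        neg = new_neg[best][kept_cols]
        genes.append(x)
        remaining = np.delete(remaining, best)
        snapshots.append((list(genes), conds.copy()))

    # Largest-area snapshot meeting the size thresholds (ties -> more genes).
    best_snap = None
    best_area = -1
    for gs, cs in snapshots:
        if len(gs) >= min_genes and cs.size >= min_conditions:
            area = len(gs) * cs.size
            if area >= best_area:
                best_area = area
                best_snap = (gs, cs)
    if best_snap is None:
        return None
    genes, conds = list(best_snap[0]), np.array(best_snap[1])

    # Closure: alternately add qualifying conditions, then qualifying genes.
    n_cond = A.shape[1]
    for _ in range(20):
        changed = False
        pos, neg = _counts(A, genes, np.arange(n_cond))
        dom_all = np.maximum(pos, neg) / len(genes)
        in_conds = np.zeros(n_cond, dtype=bool)
        in_conds[conds] = True
        addable = np.nonzero(~in_conds & (dom_all + _EPS >= c1) &
                             (np.maximum(pos, neg) > 0))[0]
        if addable.size:
            conds = np.sort(np.concatenate([conds, addable]))
            changed = True
        pos, neg = _counts(A, genes, conds)
        members = set(genes)
        while True:
            outside = [x for x in range(n_genes) if x not in members]
            if not outside:
                break
            cand = A[outside][:, conds]
            new_pos = pos[None, :] + (cand == 1)
            new_neg = neg[None, :] + (cand == -1)
            dom = np.maximum(new_pos, new_neg) / (len(members) + 1)
            dom_sym = np.where(new_pos >= new_neg, 1, -1).astype(np.int8)
            match = (cand == dom_sym).mean(axis=1)
            ok = np.nonzero((dom + _EPS >= c1).all(axis=1)
                            & (match + _EPS >= c1))[0]
            if not ok.size:
                break
            mins = dom[ok].min(axis=1)
            pick = ok[np.lexsort((np.array(outside)[ok], -mins))[0]]
            x = outside[int(pick)]
            members.add(x)
            genes.append(x)
            pos = pos + (A[x][conds] == 1)
            neg = neg + (A[x][conds] == -1)
            changed = True
        if not changed:
            break
    return sorted(genes), conds


def seed_biclusters(d_seed: DiscreteMatrix, c1: float,
                    min_genes: int = 3, min_conditions: int = 3) -> list[Bicluster]:
    """Seed-phase bi-clusters of the (seed-gene) discrete matrix at level c1.

    Every gene-pair edge grows a candidate; candidates are then emitted in
    decreasing area (ties by consistency, then ids) subject to the overlap
    rule that no gene pair appears in two emitted bi-clusters.
    """
    if not 0 < c1 <= 1:
        raise ValueError(f"c1 must lie in (0, 1], got {c1}")
    A = d_seed.data.to_numpy(dtype=np.int8)
    genes = d_seed.gene_ids
    conds = d_seed.condition_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    edges = build_gene_graph(d_seed)
    ordered = sorted(edges.items(), key=lambda kv: (-kv[1], kv[0]))

    seen: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    candidates = []
    for (a, b), _w in ordered:
        grown = _grow(A, gene_index[a], gene_index[b], c1, min_genes, min_conditions)
        if grown is None:
            continue
        gs, cs = grown
        key = (tuple(gs), tuple(int(c) for c in cs))
        if key in seen:
            continue
        seen.add(key)
        pos, neg = _counts(A, gs, cs)
        dom = np.maximum(pos, neg) / len(gs)
        consistency = float(dom.min())
        candidates.append((gs, cs, consistency))

    candidates.sort(key=lambda t: (-len(t[0]) * len(t[1]), -t[2],
                                   tuple(t[0]), tuple(int(c) for c in t[1])))
    emitted: list[Bicluster] = []
    used_pairs: set[tuple[int, int]] = set()
    for gs, cs, consistency in candidates:
        pairs = set(itertools.combinations(gs, 2))
        if pairs & used_pairs:
            continue
        used_pairs |= pairs
        pos, neg = _counts(A, gs, cs)
        dominant = {conds[int(c)]: (1 if p >= n else -1)
                    for c, p, n in zip(cs, pos, neg)}
        emitted.append(Bicluster(
            genes=tuple(genes[i] for i in gs),
            conditions=tuple(conds[int(c)] for c in cs),
            dominant_symbol=dominant,
            consistency=consistency,
            source="seed_phase",
        ))
    return emitted


def expand_bicluster(b: Bicluster, d_full: DiscreteMatrix, c2: float) -> Bicluster:
    """Recruit full-matrix genes matching the dominant profile on >= c2 of conds.

    Conditions are unchanged; recruited genes are recorded separately from the
    seed-phase members.
    """
    if not 0 < c2 <= 1:
        raise ValueError(f"c2 must lie in (0, 1], got {c2}")
    missing = [c for c in b.conditions if c not in set(d_full.condition_ids)]
    if missing:
        raise ValueError(f"conditions absent from the full matrix: {missing}")
    cols = d_full.data.loc[:, list(b.conditions)].to_numpy(dtype=np.int8)
    target = np.array([b.dominant_symbol[c] for c in b.conditions], dtype=np.int8)
    frac = (cols == target).mean(axis=1)
    members = set(b.genes)
    all_genes = d_full.gene_ids
    recruited = tuple(g for g, f in zip(all_genes, frac)
                      if g not in members and f + _EPS >= c2)
    genes = tuple(sorted(set(b.genes) | set(recruited)))
    gi = [all_genes.index(g) for g in genes]
    ci = np.array([d_full.condition_ids.index(c) for c in b.conditions])
    A = d_full.data.to_numpy(dtype=np.int8)
    pos, neg = _counts(A, gi, ci)
    consistency = float((np.maximum(pos, neg) / len(gi)).min())
    return Bicluster(
        genes=genes,
        conditions=b.conditions,
        dominant_symbol=dict(b.dominant_symbol),
        consistency=consistency,
        source="expanded",
        recruited=recruited,
    )


def _score_genes(d_full: DiscreteMatrix, biclusters, c2: float) -> np.ndarray:
    """Best per-bicluster dominant-profile match fraction per gene (0 below c2)."""
    n = len(d_full.gene_ids)
    scores = np.zeros(n)
    A = d_full.data.to_numpy(dtype=np.int8)
    cond_index = {c: i for i, c in enumerate(d_full.condition_ids)}
    for b in biclusters:
        ci = np.array([cond_index[c] for c in b.conditions])
        target = np.array([b.dominant_symbol[c] for c in b.conditions],
                          dtype=np.int8)
        frac = (A[:, ci] == target).mean(axis=1)
        frac = np.where(frac + _EPS >= c2, frac, 0.0)
        scores = np.maximum(scores, frac)
    return scores


def _rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    ranks = rankdata(np.concatenate([pos_scores, neg_scores]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def grid_search(d_seed: DiscreteMatrix, d_full: DiscreteMatrix, seeds: SeedSet,
                grid=DEFAULT_GRID, holdout_fraction: float = 0.3,
                rng_seed: int = 0, n_repeats: int = 3,
                min_genes: int = 3, min_conditions: int = 3) -> GridSearchResult:
    """Choose (c1, c2) by seed-holdout ROC AUC over the consistency grid.

    Per repeat, ``holdout_fraction`` of the seed genes are removed from the
    seed matrix before bi-clustering; held-out seeds are the ROC positives and
    an equal-size random non-seed draw the negatives.  AUC values are averaged
    over repeats; ties on the best AUC go to the smaller c1, then smaller c2.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    if any(not 0 < c <= 1 for c in grid):
        raise ValueError("grid values must lie in (0, 1]")
    seed_genes = [g for g in d_seed.gene_ids if g in seeds]
    non_seed = [g for g in d_full.gene_ids if g not in seeds]
    n_hold = max(1, round(holdout_fraction * len(seed_genes)))
    if n_hold >= len(seed_genes) or not non_seed:
        raise ValueError("not enough seed or non-seed genes for the holdout split")

    rng = np.random.default_rng(rng_seed)
    splits = []
    for _ in range(n_repeats):
        held = set(rng.choice(seed_genes, size=n_hold, replace=False))
        negs = list(rng.choice(non_seed, size=n_hold, replace=False))
        splits.append((held, negs))

    gene_pos = {g: i for i, g in enumerate(d_full.gene_ids)}
    entries: list[tuple[float, float, float]] = []
    for c1 in grid:
        # Seed-phase result depends on (c1, split) only; share across c2.
        per_split_bics = []
        for held, _negs in splits:
            train = [g for g in seed_genes if g not in held]
            d_train = DiscreteMatrix(d_seed.data.loc[train], q=d_seed.q)
            per_split_bics.append(
                seed_biclusters(d_train, c1, min_genes, min_conditions))
        for c2 in grid:
            aucs = []
            for (held, negs), bics in zip(splits, per_split_bics):
                expanded = [expand_bicluster(b, d_full, c2) for b in bics]
                scores = _score_genes(d_full, expanded, c2)
                pos = np.array([scores[gene_pos[g]] for g in sorted(held)])
                neg = np.array([scores[gene_pos[g]] for g in negs])
                aucs.append(_rank_auc(pos, neg))
            entries.append((c1, c2, float(np.mean(aucs))))
    best = max(entries, key=lambda e: (e[2], -e[0], -e[1]))
    return GridSearchResult(entries=entries, best=(best[0], best[1]))


def write_biclusters_json(biclusters, path) -> None:
    import json

    payload = [
        {"id": i, "genes": list(b.genes), "conditions": list(b.conditions),
         "dominant": {c: int(s) for c, s in b.dominant_symbol.items()},
         "consistency": b.consistency, "source": b.source,
         "recruited": list(b.recruited)}
        for i, b in enumerate(biclusters, start=1)
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_grid_tsv(result: GridSearchResult, path) -> None:
    import pandas as pd

    pd.DataFrame(result.entries, columns=["c1", "c2", "auc"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
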