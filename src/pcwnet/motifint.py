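"""Cross-finder / cross-module motif integration and database annotation.

Predicted motifs are compared pairwise by a gapless offset alignment: the
similarity of two IUPAC consensi is the number of matched positions (aligned
columns whose base sets intersect) at the best ungapped offset over both
orientations; the matched *percentage* is taken against the maximum alignable
span, ``min(w1, w2)``, so that partial-overlap coincidences between unrelated
words do not count as strong matches.  The similarity graph is clustered with
Markov clustering (inflation 4), each cluster is collapsed to a gapless
consensus representative, and representatives are matched against a database
of named known motifs (matched positions > 4 and matched percentage >= 0.8
declare two motifs "essentially the same"), which propagates functional tags
(MYB, AC-I, AC-II, lignin, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import iupac
from .coexnet import CoexpressionModule
from .motiffind import Motif

#: Edges enter the clustering graph only when the pair would already count as
#: essentially the same motif (keeps unrelated words from chaining together).
EDGE_PCT_MIN = 0.8
EDGE_MATCHED_MIN = 5


@dataclass(frozen=True)
class MotifSimilarity:
    id_a: str
    id_b: str
    matched: int
    overlap: int
    min_width: int
    offset: int
    orientation: str  # "+" (as given) or "-" (b reverse-complemented)

    @property
    def ratio(self) -> float:
        """Matched fraction of the overlap at the best offset."""
        return self.matched / self.overlap if self.overlap else 0.0

    @property
    def pct(self) -> float:
        """Matched fraction of the maximum alignable span min(w1, w2)."""
        return self.matched / self.min_width if self.min_width else 0.0


@dataclass
class MotifCluster:
    cluster_id: str
    members: list[str]
    representative: str = ""
    offsets: dict[str, tuple[int, str]] = field(default_factory=dict)


@dataclass(frozen=True)
class DBMotif:
    name: str
    consensus: str
    tag: str = ""


@dataclass
class MotifDB:
    entries: list[DBMotif]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate motif names in database")
        for e in self.entries:
            if not iupac.is_valid(e.consensus):
                raise ValueError(f"invalid consensus for {e.name}: {e.consensus}")

    def __len__(self) -> int:
        return len(self.entries)


def read_motif_db(path) -> MotifDB:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    return MotifDB([DBMotif(r["name"], r["iupac"], r.get("tag", ""))
                    for _, r in df.iterrows()])


def write_motif_db(db: MotifDB, path) -> None:
    pd.DataFrame(
        [(e.name, e.consensus, e.tag) for e in db.entries],
        columns=["name", "iupac", "tag"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _consensus_of(m) -> str:
    return getattr(m, "consensus", None) or str(m)


def _id_of(m) -> str:
    return getattr(m, "id", None) or getattr(m, "name", None) or str(m)


def motif_similarity(a, b, min_overlap: int = 4) -> MotifSimilarity:
    """Best ungapped alignment of two IUPAC consensi over offsets and strands.

    ``matched`` counts aligned columns whose IUPAC base sets intersect;
    ``overlap`` is the alignment length at the best offset.  The best offset
    maximizes matched, breaking ties by larger overlap, then smaller |offset|,
    preferring the forward orientation.  The (matched, overlap, ratio) triple
    is symmetric in the two arguments.
    """
    ca, cb = _consensus_of(a).upper(), _consensus_of(b).upper()
    wa, wb = len(ca), len(cb)
    if wa < min_overlap or wb < min_overlap:
        raise ValueError(f"motif width < {min_overlap}")
    sets_a = [iupac.bases_of(ch) for ch in ca]
    best = None
    for orientation, cb_o in (("+", cb), ("-", iupac.revcomp(cb))):
        sets_b = [iupac.bases_of(ch) for ch in cb_o]
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo = max(0, offset)
            hi = min(wa, offset + wb)
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            matched = sum(
                1 for i in range(lo, hi) if sets_a[i] & sets_b[i - offset])
            key = (matched, overlap, -abs(offset), orientation == "+")
            if best is None or key > best[0]:
                best = (key, matched, overlap, offset, orientation)
    assert best is not None
    _, matched, overlap, offset, orientation = best
    return MotifSimilarity(_id_of(a), _id_of(b), matched, overlap,
                           min(wa, wb), offset, orientation)


def mcl_cluster(motifs, sim_edges=None, inflation: float = 4.0,
                edge_pct_min: float = EDGE_PCT_MIN,
                edge_matched_min: int = EDGE_MATCHED_MIN,
                tol: float = 1e-6, max_iter: int = 100) -> list[MotifCluster]:
    """Markov clustering of the motif similarity graph (granularity 4).

    Edges are weighted by the matched percentage and kept only when the pair
    counts as essentially the same motif (matched >= 5 positions covering >=
    80% of the shorter consensus); self-loops are added; the column-stochastic
    matrix is alternately expanded (squared) and inflated (elementwise power,
    columns renormalized) until the maximum elementwise change falls below
    ``tol``.  Clusters are the connected systems of the converged matrix and
    partition the motif set (singletons allowed).
    """
    ids = [_id_of(m) for m in motifs]
    consensi = {_id_of(m): _consensus_of(m) for m in motifs}
    n = len(ids)
    if n == 0:
        return []
    index = {mid: i for i, mid in enumerate(ids)}
    M = np.zeros((n, n))
    if sim_edges is None:
        sim_edges = []
        for i in range(n):
            for j in range(i + 1, n):
                sim_edges.append(motif_similarity(motifs[i], motifs[j]))
    for s in sim_edges:
        if s.pct >= edge_pct_min and s.matched >= edge_matched_min:
            i, j = index[s.id_a], index[s.id_b]
            M[i, j] = M[j, i] = s.pct
    np.fill_diagonal(M, 1.0)
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded ** inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - M).max() < tol:
            M = inflated
            break
        M = inflated
    # Connected attractor systems of the converged matrix.
    adj = (M > 1e-8) | (M.T > 1e-8)
    seen = np.zeros(n, dtype=bool)
    groups: list[list[str]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for u in np.nonzero(adj[v])[0]:
                if not seen[u]:
                    seen[u] = True
                    stack.append(int(u))
        groups.append(sorted(ids[i] for i in comp))
    groups.sort(key=lambda g: (-len(g), g[0]))
    clusters = []
    for k, members in enumerate(groups, start=1):
        cl = MotifCluster(cluster_id=f"cluster_{k}", members=members)
        cl.representative = consensus_motif(cl, consensi)
        clusters.append(cl)
    return clusters


def consensus_motif(cl: MotifCluster, consensi: dict[str, str] | None = None) -> str:
    """Gapless consensus of a motif cluster.

    Members are stacked against the cluster's longest member at their
    pairwise-best offsets (no gaps); columns covered by >= 50% of members are
    retained; per column, the consensus is the minimal IUPAC code covering all
    bases whose (set-weighted) frequency reaches 0.5, falling back to the
    plurality bases when none does.
    """
    if not cl.members:
        raise ValueError("empty cluster")
    if consensi is None:
        consensi = {m: m for m in cl.members}
    seqs = {m: consensi[m].upper() for m in cl.members}
    ref = max(cl.members, key=lambda m: (len(seqs[m]), m))
    placements: list[tuple[str, int]] = []
    offsets: dict[str, tuple[int, str]] = {}
    for m in cl.members:
        if m == ref:
            placements.append((seqs[m], 0))
            offsets[m] = (0, "+")
            continue
        sim = motif_similarity(seqs[ref], seqs[m])
        word = seqs[m] if sim.orientation == "+" else iupac.revcomp(seqs[m])
        placements.append((word, sim.offset))
        offsets[m] = (sim.offset, sim.orientation)
    cl.offsets = offsets
    # columns are anchored on the reference span (gapless, so the consensus
    # can never outgrow the longest member)
    lo, hi = 0, len(seqs[ref])
    n_cols = hi - lo
    n = len(placements)
    columns: list[list[frozenset]] = [[] for _ in range(n_cols)]
    for word, off in placements:
        for i, ch in enumerate(word):
            col = off + i
            if lo <= col < hi:
                columns[col - lo].append(iupac.bases_of(ch))
    letters = []
    for col in columns:
        if len(col) < 0.5 * n:
            continue
        weights = {b: 0.0 for b in "ACGT"}
        for s in col:
            for b in s:
                weights[b] += 1.0 / len(s)
        total = sum(weights.values())
        frac = {b: v / total for b, v in weights.items()}
        chosen = {b for b, f in frac.items() if f >= 0.5}
        if not chosen:
            top = max(frac.values())
            chosen = {b for b, f in frac.items() if f >= top - 1e-12}
        letters.append(iupac.code_for(chosen))
    return "".join(letters)


def annotate_vs_db(motifs, db: MotifDB, integrate_db: bool = True,
                   matched_min: int = 4, ratio_min: float = 0.8) -> dict[str, dict]:
    """Match predicted motifs against the known-motif database.

    A (predicted, known) pair matches when matched positions > ``matched_min``
    and the matched percentage (against the shorter consensus width) reaches
    ``ratio_min``.  When ``integrate_db`` is set, the
    database consensi are first collapsed by the same clustering/consensus
    procedure and matching runs against the cluster representatives (tags and
    names of all cluster members propagate).  Returns, per matched motif id,
    a dict with the best match's name, tag, matched count and ratio.
    """
    if not len(db):
        raise ValueError("empty motif database")
    if integrate_db:
        clusters = mcl_cluster(db.entries)
        targets = []
        for cl in clusters:
            members = [e for e in db.entries if e.name in set(cl.members)]
            name = ";".join(sorted(m.name for m in members))
            tags = ";".join(sorted({m.tag for m in members if m.tag}))
            targets.append(DBMotif(name, cl.representative, tags))
    else:
        targets = list(db.entries)
    results: dict[str, dict] = {}
    for m in motifs:
        best = None
        for t in targets:
            sim = motif_similarity(m, t)
            if sim.matched > matched_min and sim.pct >= ratio_min:
                key = (sim.matched, sim.pct, t.name)
                if best is None or key > best[0]:
                    best = (key, t, sim)
        if best is not None:
            _, t, sim = best
            results[_id_of(m)] = {
                "name": t.name, "tag": t.tag,
                "matched": sim.matched, "overlap": sim.overlap,
                "ratio": sim.ratio, "pct": sim.pct,
            }
    return results


def is_palindrome(m) -> bool:
    """True when the consensus equals its own IUPAC reverse complement."""
    consensus = _consensus_of(m).upper()
    return iupac.revcomp(consensus) == consensus


def module_motif_support(mod: CoexpressionModule, motifs,
                         flag_fraction: float = 0.8):
    """Per-motif fraction of module genes carrying >= 1 instance, plus flag.

    The module is flagged co-regulated when any motif covers at least 80% of
    its genes.
    """
    if not mod.genes:
        raise ValueError("empty module")
    module_genes = set(mod.genes)
    fractions: dict[str, float] = {}
    for m in motifs:
        covered = {g for g, *_ in m.instances} & module_genes
        fractions[m.id] = len(covered) / len(module_genes)
    flag = any(f + 1e-12 >= flag_fraction for f in fractions.values())
    return fractions, flag


def select_reliable_motifs(mod: CoexpressionModule, motifs,
                           conserved_ids=()) -> list[Motif]:
    """Up to three motifs ranked by conservation, then module coverage, then id."""
    conserved = set(conserved_ids)
    module_genes = set(mod.genes)

    def coverage(m) -> int:
        return len({g for g, *_ in m.instances} & module_genes)

    ranked = sorted(motifs,
                    key=lambda m: (m.id not in conserved, -coverage(m), m.id))
    return list(ranked[:3])


def write_motif_table(clusters, annotations, conserved_ids, path) -> None:
    """Non-redundant motif table TSV."""
    rows = []
    for cl in clusters:
        ann = annotations.get(cl.cluster_id, {})
        rows.append((
            cl.cluster_id, cl.representative, len(cl.members),
            ";".join(cl.members), is_palindrome(cl.representative),
            ann.get("name", ""), ann.get("tag", ""),
            cl.cluster_id in set(conserved_ids),
        ))
    pd.DataFrame(rows, columns=[
        "cluster_id", "consensus", "n_members", "member_ids",
        "palindrome", "db_match_name", "db_tag", "conserved",
    ]).to_csv(path, sep="\t", index=False, lineterminator="\n")
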