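"""Promoter extraction and per-module motif discovery.

Promoters are fixed-length windows (2,000 bp by default; 4,000 bp for rice)
immediately upstream of the *translation* start site, truncated at contig
edges and reverse-complemented for minus-strand genes so they read 5'->3'
toward the start codon.

Three complementary finder strategies are provided:

* :func:`enumerate_motifs` — an exhaustive oligo enumerator over widths
  6/8/10/12 with per-width mismatch budgets (1/2/3/4).  A candidate word must
  occur, within its budget, in *every* promoter; it is scored by the summed
  log-likelihood ratio of its best match per sequence against an order-0
  background estimated from the input.  The 15 highest-scoring motifs per
  width are reported, with all instances (multiple per sequence allowed).
* :func:`gibbs_motifs` — a Gibbs site-sampler over motif start positions with
  a per-sequence copy count in {0, 1, 2} governed by a copy prior, a
  position-weight matrix with 0.25/base pseudocounts, and an IUPAC consensus
  that becomes degenerate where the runner-up base reaches half the top count.
* :func:`phylo_motifs` — the enumerator filtered by cross-species promoter
  conservation through an ortholog map (phylogenetic footprinting analog).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import iupac

#: Per-width mismatch budgets of the exhaustive enumerator.
MISMATCH_BUDGET: dict[int, int] = {6: 1, 8: 2, 10: 3, 12: 4}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PromoterSet:
    """gene_id -> promoter sequence, with declared length and provenance."""

    sequences: dict[str, str]
    species: str = "focal"
    length: int = 2000
    provenance: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            if len(seq) > self.length:
                raise ValueError(
                    f"promoter of {gene} longer than declared length "
                    f"({len(seq)} > {self.length})")
            if not set(seq.upper()) <= set("ACGTN"):
                raise ValueError(f"promoter of {gene} has non-ACGTN characters")

    @property
    def genes(self) -> list[str]:
        return sorted(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class Motif:
    id: str
    consensus: str
    width: int
    instances: list[tuple[str, int, str, str]]  # (gene, offset, strand, word)
    score: float
    finder: str

    def __post_init__(self) -> None:
        if self.width != len(self.consensus):
            raise ValueError("width must equal the consensus length")

    @property
    def carriers(self) -> tuple[str, ...]:
        return tuple(sorted({g for g, *_ in self.instances}))


def write_promoters_fasta(p: PromoterSet, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(p.sequences[g]), id=g, description="")
               for g in p.genes]
    SeqIO.write(records, str(path), "fasta")


def read_promoters_fasta(path, species: str = "focal",
                         length: int | None = None) -> PromoterSet:
    from Bio import SeqIO

    with open(path) as fh:
        seqs = {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(fh, "fasta")}
    if length is None:
        length = max((len(s) for s in seqs.values()), default=0)
    return PromoterSet(seqs, species=species, length=length)


def _cds_anchors(annotation) -> dict[str, tuple[str, str, int, int]]:
    """gene -> (contig, strand, min CDS start, max CDS end), 1-based closed."""
    import pandas as pd

    if isinstance(annotation, pd.DataFrame):
        df = annotation
        anchors: dict[str, tuple[str, str, int, int]] = {}
        for gene, grp in df[df["type"] == "CDS"].groupby("gene_id"):
            contig = str(grp["seqid"].iloc[0])
            strand = str(grp["strand"].iloc[0])
            anchors[gene] = (contig, strand,
                             int(grp["start"].min()), int(grp["end"].max()))
        return anchors
    import gffutils

    db = gffutils.create_db(str(annotation), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    anchors = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID")
        gene = parents[0] if parents else cds.id
        contig, strand = cds.seqid, cds.strand
        if gene in anchors:
            _, _, s, e = anchors[gene]
            anchors[gene] = (contig, strand, min(s, cds.start), max(e, cds.end))
        else:
            anchors[gene] = (contig, strand, cds.start, cds.end)
    return anchors


def extract_promoters(genome, annotation, L: int = 2000,
                      species: str = "focal") -> PromoterSet:
    """Strand-aware upstream windows of length L ending before the start codon.

    ``genome`` is a contig -> sequence mapping or a FASTA path; ``annotation``
    a GFF3 path or a DataFrame with columns (seqid, type, start, end, strand,
    gene_id), 1-based closed intervals whose CDS features define translation
    starts.  Windows are truncated (never padded) at contig boundaries;
    minus-strand promoters are reverse-complemented.  Genes without a CDS
    record are skipped.
    """
    if not isinstance(genome, dict):
        from Bio import SeqIO
        with open(genome) as fh:
            genome = {rec.id: str(rec.seq).upper()
                      for rec in SeqIO.parse(fh, "fasta")}
    genome = {k: v.upper() for k, v in genome.items()}
    anchors = _cds_anchors(annotation)
    seqs: dict[str, str] = {}
    provenance: dict[str, tuple] = {}
    for gene in sorted(anchors):
        contig, strand, start, end = anchors[gene]
        if contig not in genome:
            continue
        seq = genome[contig]
        if strand == "+":
            hi = start - 1           # 0-based exclusive end of the window
            lo = max(0, hi - L)
            prom = seq[lo:hi]
        else:
            lo = end                 # 0-based inclusive start of the window
            hi = min(len(seq), lo + L)
            prom = iupac.revcomp(seq[lo:hi])
        if prom:
            seqs[gene] = prom
            provenance[gene] = (contig, strand, lo + 1, hi)
    return PromoterSet(seqs, species=species, length=L, provenance=provenance)


def _windows(enc: np.ndarray, w: int) -> np.ndarray:
    """All length-w windows of an encoded sequence as an (n, w) array."""
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty((0, w), dtype=np.int8)
    return np.lib.stride_tricks.sliding_window_view(enc, w).astype(np.int8)


def _encode_acgt(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(ch, 4) for ch in seq.upper()],
                    dtype=np.int8)


def _background(p: PromoterSet, background=None) -> np.ndarray:
    if background is not None:
        return np.array([background[b] for b in _BASES], dtype=float)
    counts = np.ones(4)  # pseudocount
    for seq in p.sequences.values():
        enc = _encode_acgt(seq)
        counts += np.bincount(enc[enc < 4], minlength=4)[:4]
    return counts / counts.sum()


def enumerate_motifs(p: PromoterSet, widths=(6, 8, 10, 12), top_k: int = 15,
                     background=None, both_strands: bool = True,
                     match_prob: float = 0.9) -> list[Motif]:
    """Exhaustive oligo enumeration over the observed words of each width.

    A candidate word (any exact w-mer present in the promoters) is kept when
    it occurs within the per-width mismatch budget in every promoter, and
    scored by the sum over sequences of
    ``log(best-match likelihood / order-0 background likelihood)``, where the
    best match is the window with fewest mismatches (leftmost, forward strand
    first on ties) and positions contribute ``match_prob`` on a match and
    ``(1 - match_prob)/3`` otherwise.  The ``top_k`` motifs per width are
    returned with all their instances.
    """
    if len(p) < 2:
        raise ValueError("need at least 2 promoters")
    bad = set(widths) - set(MISMATCH_BUDGET)
    if bad:
        raise ValueError(f"unsupported widths: {sorted(bad)}")
    bg = _background(p, background)
    log_bg = np.log(bg)
    genes = p.genes
    encoded = {g: _encode_acgt(p.sequences[g]) for g in genes}
    out: list[Motif] = []
    p_mis = (1 - match_prob) / 3
    for w in sorted(widths):
        e = MISMATCH_BUDGET[w]
        # Stack all scannable windows (both strands) with bookkeeping arrays.
        win_blocks, seq_idx_blocks, off_blocks, strand_blocks = [], [], [], []
        fwd_words = []
        for si, g in enumerate(genes):
            enc = encoded[g]
            fwd = _windows(enc, w)
            valid = (fwd < 4).all(axis=1)
            fwd_words.append(fwd[valid])
            offs = np.nonzero(valid)[0]
            win_blocks.append(fwd[valid])
            seq_idx_blocks.append(np.full(valid.sum(), si))
            off_blocks.append(offs)
            strand_blocks.append(np.zeros(valid.sum(), dtype=np.int8))
            if both_strands:
                rc = (3 - enc)[::-1]
                rcw = _windows(rc, w)
                rvalid = (rcw < 4).all(axis=1)
                # a revcomp window starting at i corresponds to forward offset
                # len(seq) - w - i
                roffs = len(enc) - w - np.nonzero(rvalid)[0]
                win_blocks.append(rcw[rvalid])
                seq_idx_blocks.append(np.full(rvalid.sum(), si))
                off_blocks.append(roffs)
                strand_blocks.append(np.ones(rvalid.sum(), dtype=np.int8))
        if not win_blocks or sum(len(b) for b in win_blocks) == 0:
            continue
        W = np.concatenate(win_blocks)
        seq_idx = np.concatenate(seq_idx_blocks)
        offsets = np.concatenate(off_blocks)
        strands = np.concatenate(strand_blocks)
        logbg_win = log_bg[W].sum(axis=1)

        all_fwd = np.concatenate([b for b in fwd_words if len(b)])
        candidates = np.unique(all_fwd, axis=0)
        if candidates.size == 0:
            continue

        eye = np.eye(4, dtype=np.float32)
        n_seq = len(genes)
        # Row order within a sequence: forward windows (left to right) first,
        # then reverse; argmax of matches therefore prefers the leftmost
        # forward best window.
        order = np.lexsort((offsets, strands, seq_idx))
        W = W[order]
        seq_idx_o = seq_idx[order]
        offsets_o = offsets[order]
        strands_o = strands[order]
        logbg_o = logbg_win[order]
        bounds = np.searchsorted(seq_idx_o, np.arange(n_seq + 1))
        pos_oh_t = [np.ascontiguousarray(
            eye[W[bounds[si]:bounds[si + 1]]].reshape(-1, 4 * w).T)
            for si in range(n_seq)]

        scores = np.full(len(candidates), -np.inf)
        chunk = 2048
        for lo in range(0, len(candidates), chunk):
            cand = candidates[lo:lo + chunk]
            cand_oh = eye[cand].reshape(len(cand), 4 * w)
            contrib = np.zeros(len(cand))
            covered = np.ones(len(cand), dtype=bool)
            for si in range(n_seq):
                if pos_oh_t[si].shape[1] == 0:
                    covered[:] = False
                    break
                seg = cand_oh @ pos_oh_t[si]  # (candidates, positions)
                arg = seg.argmax(axis=1)
                best = seg[np.arange(len(cand)), arg]
                mm = w - best
                covered &= mm <= e
                lik = (w - mm) * math.log(match_prob) + mm * math.log(p_mis)
                contrib += lik - logbg_o[bounds[si]:bounds[si + 1]][arg]
            scores[lo:lo + len(cand)] = np.where(covered, contrib, -np.inf)

        keep = np.nonzero(np.isfinite(scores))[0]
        if keep.size == 0:
            continue
        words = ["".join(_BASES[b] for b in candidates[i]) for i in keep]
        ranked = sorted(zip(keep, words), key=lambda t: (-scores[t[0]], t[1]))
        for rank, (ci, word) in enumerate(ranked[:top_k], start=1):
            cand_oh = eye[candidates[ci]].reshape(1, 4 * w)
            matches = np.concatenate(
                [(cand_oh @ pos_oh_t[si]).ravel() for si in range(n_seq)])
            mm_all = w - matches
            hits = np.nonzero(mm_all <= e)[0]
            instances = []
            for h in hits:
                si = int(seq_idx_o[h])
                off = int(offsets_o[h])
                strand = "-" if strands_o[h] else "+"
                gene = genes[si]
                matched = p.sequences[gene][off:off + w]
                instances.append((gene, off, strand, matched))
            instances.sort()
            out.append(Motif(
                id=f"enum_w{w}_{rank}", consensus=word, width=w,
                instances=instances, score=float(scores[ci]),
                finder="enumerative"))
    return out


def _consensus_from_counts(counts: np.ndarray) -> str:
    """IUPAC consensus: per column, top base plus any base >= half its count."""
    letters = []
    for col in counts.T:
        top = col.max()
        bases = {b for b, c in zip(_BASES, col) if c >= 0.5 * top}
        letters.append(iupac.code_for(bases))
    return "".join(letters)


def gibbs_motifs(p: PromoterSet, w: int = 8, copy_prior: float = 0.5,
                 n_iter: int = 150, rng_seed: int = 0, n_restarts: int = 20,
                 pseudocount: float = 0.25) -> list[Motif]:
    """Gibbs site-sampler for one motif of width ``w`` (default 8).

    Per sweep and sequence, the sequence's sites are removed from the count
    matrix, positions are scored by the PWM/background log ratio, and up to
    two sites are re-sampled; each of the two slots chooses among all start
    positions (weight ``copy_prior * likelihood-ratio``) and an "absent"
    option (weight ``(1 - copy_prior) * n_positions``), so the per-sequence
    copy number lives in {0, 1, 2}.  A greedy phase-shift move after every
    sweep realigns all sites by up to two positions when that improves the
    total likelihood (site samplers otherwise converge to shifted optima).
    After the sweeps a deterministic maximum-likelihood pass fixes the final
    sites; the best of ``n_restarts`` restarts (by total log-likelihood
    ratio) is returned.
    """
    if w < 4:
        raise ValueError("motif width must be >= 4")
    if len(p) < 3:
        raise ValueError("need at least 3 promoters")
    genes = p.genes
    for g in genes:
        if len(p.sequences[g]) < w:
            raise ValueError(f"promoter of {g} shorter than the motif width")
    enc = {g: _encode_acgt(p.sequences[g]) for g in genes}
    wins = {g: _windows(enc[g], w) for g in genes}
    valid = {g: np.nonzero((wins[g] < 4).all(axis=1))[0] for g in genes}
    eye = np.eye(4, dtype=np.float32)
    onehot = {g: eye[wins[g][valid[g]]].reshape(len(valid[g]), 4 * w)
              for g in genes}
    bg = _background(p)
    log_bg = np.log(bg)
    rng = np.random.default_rng(rng_seed)

    def pwm_logratio(counts: np.ndarray) -> np.ndarray:
        freq = counts / counts.sum(axis=0, keepdims=True)
        return np.log(freq) - log_bg[:, None]

    def window_scores(g: str, logratio: np.ndarray) -> np.ndarray:
        # one matvec over the precomputed one-hot windows (j-major layout)
        return (onehot[g] @ logratio.T.ravel().astype(np.float32)).astype(float)

    def counts_from(sites: dict[str, list[int]]) -> np.ndarray:
        counts = np.full((4, w), pseudocount)
        for g, starts in sites.items():
            for s in starts:
                win = wins[g][s]
                counts[win, np.arange(w)] += 1
        return counts

    def total_score(sites: dict[str, list[int]]) -> float:
        logratio = pwm_logratio(counts_from(sites))
        total = 0.0
        for g, starts in sites.items():
            for s in starts:
                total += float(logratio[wins[g][s], np.arange(w)].sum())
        return total

    def phase_shift(sites: dict[str, list[int]]) -> dict[str, list[int]]:
        best_sites, best = sites, total_score(sites)
        for delta in (-2, -1, 1, 2):
            shifted = {
                g: [s + delta for s in starts
                    if 0 <= s + delta < len(p.sequences[g]) - w + 1
                    and (wins[g][s + delta] < 4).all()]
                for g, starts in sites.items()
            }
            if sum(map(len, shifted.values())) < sum(map(len, sites.values())):
                continue
            score = total_score(shifted)
            if score > best:
                best, best_sites = score, shifted
        return best_sites

    cols = np.arange(w)

    def site_counts(g: str, starts: list[int]) -> np.ndarray:
        out = np.zeros((4, w))
        for s in starts:
            out[wins[g][s], cols] += 1
        return out

    best_sites, best_total = None, -np.inf
    for _ in range(n_restarts):
        sites = {g: [int(rng.choice(valid[g]))] for g in genes if len(valid[g])}
        gene_counts = {g: site_counts(g, sites.get(g, [])) for g in genes}
        counts_total = np.full((4, w), pseudocount)
        for g in genes:
            counts_total += gene_counts[g]
        for sweep in range(n_iter):
            for g in genes:
                if not len(valid[g]):
                    continue
                counts = counts_total - gene_counts[g]
                logratio = pwm_logratio(counts)
                scores = window_scores(g, logratio)
                shifted = scores - scores.max()
                r = np.exp(shifted)
                new_sites: list[int] = []
                for _slot in range(2):
                    weights = copy_prior * r
                    # absent option on the same (max-shifted) scale
                    absent = ((1 - copy_prior) * len(valid[g])
                              * math.exp(-scores.max()))
                    total = weights.sum() + absent
                    u = rng.random() * total
                    if u >= weights.sum():
                        continue
                    idx = int(np.searchsorted(np.cumsum(weights), u))
                    pos = int(valid[g][min(idx, len(valid[g]) - 1)])
                    if pos not in new_sites:
                        new_sites.append(pos)
                counts_total -= gene_counts[g]
                sites[g] = new_sites
                gene_counts[g] = site_counts(g, new_sites)
                counts_total += gene_counts[g]
            if sweep % 10 == 9 or sweep == n_iter - 1:
                shifted_sites = phase_shift(sites)
                if shifted_sites is not sites:
                    sites = shifted_sites
                    gene_counts = {g: site_counts(g, sites.get(g, []))
                                   for g in genes}
                    counts_total = np.full((4, w), pseudocount)
                    for g in genes:
                        counts_total += gene_counts[g]
        # Deterministic maximum-likelihood pass.
        counts = counts_from(sites)
        logratio = pwm_logratio(counts)
        total = 0.0
        final: dict[str, list[int]] = {}
        log_absent = math.log(max(1e-300, 1 - copy_prior))
        log_present = math.log(max(1e-300, copy_prior))
        for g in genes:
            if not len(valid[g]):
                final[g] = []
                continue
            scores = window_scores(g, logratio)
            order = np.argsort(-scores)
            chosen = []
            for idx in order[:2]:
                gain = scores[idx] + log_present - log_absent - math.log(len(valid[g]))
                if gain > 0:
                    chosen.append(int(valid[g][idx]))
                    total += scores[idx]
            final[g] = chosen
        if total > best_total:
            best_total, best_sites = total, final
    if best_sites is None:
        return []
    counts = counts_from(best_sites) - pseudocount + 1e-9
    consensus = _consensus_from_counts(counts)
    instances = []
    for g, starts in best_sites.items():
        for s in sorted(starts):
            instances.append((g, int(s), "+", p.sequences[g][s:s + w]))
    instances.sort()
    return [Motif(id=f"gibbs_w{w}_1", consensus=consensus, width=w,
                  instances=instances, score=float(best_total),
                  finder="gibbs")]


def phylo_motifs(p: PromoterSet, orthologs: dict[str, str],
                 ortho_promoters: dict[str, PromoterSet],
                 widths=(6, 8), ortho_min_fraction: float = 0.5,
                 **enum_kwargs) -> list[Motif]:
    """Enumerated motifs retained only when conserved in ortholog promoters.

    A motif survives when, in at least one other species, its consensus occurs
    (exact IUPAC scan, both strands) in the ortholog promoter of at least
    ``ortho_min_fraction`` of its carrier genes.
    """
    if not orthologs:
        raise ValueError("empty ortholog map")
    found = enumerate_motifs(p, widths=widths, **enum_kwargs)
    kept = []
    for motif in found:
        carriers = motif.carriers
        if not carriers:
            continue
        retained = False
        for _species, oset in ortho_promoters.items():
            n_hit = 0
            for g in carriers:
                og = orthologs.get(g)
                if og is None or og not in oset.sequences:
                    continue
                if iupac.scan(oset.sequences[og], motif.consensus):
                    n_hit += 1
            if n_hit / len(carriers) >= ortho_min_fraction:
                retained = True
                break
        if retained:
            kept.append(Motif(id=motif.id.replace("enum", "phylo"),
                              consensus=motif.consensus, width=motif.width,
                              instances=motif.instances, score=motif.score,
                              finder="phylo"))
    return kept
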