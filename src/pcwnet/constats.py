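"""Cross-species motif conservation, the random-group null test, AC-element
positional analysis, and the stage / function annotation layers.

Conservation: a predicted motif is *conserved* when its consensus occurs (exact
IUPAC scan) in the promoter of at least one ortholog of one of its carrier
genes; orthologs come from a reciprocal-best-hit map or are supplied directly.

Specificity: motifs predicted from co-expression modules should match more
known database motifs than motifs predicted from equally sized random gene
groups; a Pearson chi-square test on the 2x2 matched/unmatched table
quantifies this.

Annotation: a module whose seed genes all share one synthesis stage and whose
seed fraction strictly exceeds 10% transfers that stage to every recruited
gene; module function labels come from intersecting the seed members with
curated gene groups (cellulose, lignin, NDP-sugar, GT families), and the
consistency check compares those labels against the functional tags of the
module's three most reliable motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import iupac
from .coexnet import CoexpressionModule
from .exprio import SeedSet
from .motiffind import PromoterSet, enumerate_motifs
from .motifint import MotifDB, annotate_vs_db


@dataclass
class OrthologMap:
    pairs: dict[str, str]
    provenance: str = "given"  # "given" or "rbh"

    def __post_init__(self) -> None:
        targets = list(self.pairs.values())
        if len(set(targets)) != len(targets):
            raise ValueError("ortholog map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, gene: str):
        return self.pairs.get(gene)


@dataclass
class NullMatchResult:
    n_groups: int
    group_size: int
    matched_module: int
    matched_null: int
    total_known: int
    chi2: float | None = None
    p: float | None = None


@dataclass
class StageAnnotation:
    module_stage: dict[str, str] = field(default_factory=dict)
    gene_stages: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


def read_ortholog_map(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return OrthologMap(dict(zip(df["src_id"], df["dst_id"])))


def write_ortholog_map(omap: OrthologMap, path) -> None:
    pd.DataFrame(sorted(omap.pairs.items()),
                 columns=["src_id", "dst_id"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def rbh_orthologs(scores: pd.DataFrame) -> OrthologMap:
    """Reciprocal unique best hits from an all-vs-all similarity table.

    ``scores`` has columns (gene_a, gene_b, score), higher = more similar.
    A pair is kept iff each gene is the other's *unique* best hit; ties on the
    best score discard the gene's candidates entirely.
    """
    if scores.empty:
        raise ValueError("empty score table")

    def unique_best(df, key, other):
        best: dict[str, str | None] = {}
        for g, grp in df.groupby(key):
            top = grp["score"].max()
            hits = grp.loc[grp["score"] == top, other].unique()
            best[g] = hits[0] if len(hits) == 1 else None
        return best

    best_a = unique_best(scores, "gene_a", "gene_b")
    best_b = unique_best(scores, "gene_b", "gene_a")
    pairs = {a: b for a, b in best_a.items()
             if b is not None and best_b.get(b) == a}
    return OrthologMap(pairs, provenance="rbh")


def scan_motif(promoter: str, consensus: str,
               both_strands: bool = True) -> list[tuple[int, str]]:
    """Exact IUPAC occurrences of a consensus in one promoter sequence."""
    if len(consensus) > len(promoter):
        raise ValueError("consensus longer than the promoter")
    return iupac.scan(promoter, consensus, both_strands=both_strands)


@dataclass
class ConservationResult:
    status: str  # "conserved", "not_conserved", "unevaluable"
    support_pairs: list[tuple[str, str]] = field(default_factory=list)


def conservation_filter(motifs, omap: OrthologMap,
                        ortho_promoters: PromoterSet,
                        min_support: int = 1) -> dict[str, ConservationResult]:
    """Flag motifs whose consensus recurs in carrier-gene ortholog promoters.

    A motif with no carrier in the ortholog map is *unevaluable* (distinct
    from not conserved).
    """
    if not len(omap):
        raise ValueError("empty ortholog map")
    out: dict[str, ConservationResult] = {}
    for m in motifs:
        carriers = m.carriers
        mapped = [(g, omap.get(g)) for g in carriers if omap.get(g) is not None]
        mapped = [(g, og) for g, og in mapped if og in ortho_promoters.sequences]
        if not mapped:
            out[m.id] = ConservationResult("unevaluable")
            continue
        support = [(g, og) for g, og in mapped
                   if iupac.scan(ortho_promoters.sequences[og], m.consensus)]
        status = "conserved" if len(support) >= min_support else "not_conserved"
        out[m.id] = ConservationResult(status, support)
    return out


def chi_square_test(matched_a: int, total_a: int,
                    matched_b: int, total_b: int) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 matched/unmatched table (1 df, no
    continuity correction); p from the chi-square survival function."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= matched_a <= total_a and 0 <= matched_b <= total_b):
        raise ValueError("matched counts must lie in [0, total]")
    a, b = matched_a, total_a - matched_a
    c, d = matched_b, total_b - matched_b
    n = a + b + c + d
    for marginal in (a + b, c + d, a + c, b + d):
        if marginal == 0:
            raise ValueError("zero marginal in the 2x2 table")
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def random_group_null(all_genes, promoters: PromoterSet, db: MotifDB,
                      modules, n_groups: int = 1000,
                      group_size: int | None = None,
                      finder_cfg: dict | None = None,
                      rng_seed: int = 0) -> NullMatchResult:
    """Module-vs-random-group comparison of known-motif matches.

    ``n_groups`` random gene groups (default size = the rounded mean module
    size) each undergo motif prediction with the enumerative finder only; the
    pooled predictions are matched against the database, as are the pooled
    module-based predictions (enumerative finder only, for comparability).
    The chi-square test compares the two matched/unmatched proportions over
    the database (skipped when a marginal is zero).
    """
    if n_groups <= 0:
        raise ValueError("n_groups must be positive")
    finder_cfg = dict(finder_cfg or {})
    finder_cfg.setdefault("widths", (6, 8, 10, 12))
    all_genes = [g for g in all_genes if g in promoters.sequences]
    sizes = [len(m.genes) if isinstance(m, CoexpressionModule) else len(m)
             for m in modules]
    if group_size is None:
        group_size = int(round(float(np.mean(sizes))))
    if group_size > len(all_genes):
        raise ValueError("group_size exceeds the available gene universe")

    def predict(genes, prefix):
        sub = PromoterSet({g: promoters.sequences[g] for g in genes},
                          species=promoters.species, length=promoters.length)
        try:
            found = enumerate_motifs(sub, **finder_cfg)
        except ValueError:
            return []
        for m in found:  # ids unique across groups
            m.id = f"{prefix}_{m.id}"
        return found

    def matched_names(motifs):
        if not motifs:
            return set()
        ann = annotate_vs_db(motifs, db)
        return {info["name"] for info in ann.values()}

    module_motifs = []
    for k, m in enumerate(modules):
        genes = [g for g in (m.genes if isinstance(m, CoexpressionModule) else m)
                 if g in promoters.sequences]
        if len(genes) >= 2:
            module_motifs.extend(predict(genes, f"mod{k}"))
    matched_module = len(matched_names(module_motifs))

    rng = np.random.default_rng(rng_seed)
    null_motifs = []
    for k in range(n_groups):
        group = list(rng.choice(all_genes, size=group_size, replace=False))
        null_motifs.extend(predict(group, f"null{k}"))
    matched_null = len(matched_names(null_motifs))

    result = NullMatchResult(
        n_groups=n_groups, group_size=group_size,
        matched_module=matched_module, matched_null=matched_null,
        total_known=len(db))
    try:
        result.chi2, result.p = chi_square_test(
            matched_module, len(db), matched_null, len(db))
    except ValueError:
        pass
    return result


def ac_element_positions(ac_motifs: dict[str, list], promoter_L: int,
                         bin_width: int = 250) -> pd.DataFrame:
    """Distance distribution of AC-element occurrences upstream of the ATG.

    ``ac_motifs`` maps an element name (e.g. "AC-I", "AC-II") to motif objects
    whose instances carry 0-based offsets on promoters anchored at the
    translation start.  The distance of an occurrence is measured from its 3'
    end to the ATG, i.e. ``L - (offset + width)``; distances are binned over
    [0, L] and normalized to fractions per element.
    """
    edges = np.arange(0, promoter_L + bin_width, bin_width)
    rows = []
    for element, motifs in sorted(ac_motifs.items()):
        distances = []
        for m in motifs:
            for _gene, offset, _strand, *_ in m.instances:
                dist = promoter_L - (offset + m.width)
                if not 0 <= dist < promoter_L + bin_width:
                    raise ValueError(
                        f"occurrence outside the promoter: offset {offset}")
                distances.append(dist)
        counts, _ = np.histogram(distances, bins=edges)
        fractions = counts / counts.sum() if counts.sum() else counts.astype(float)
        for lo, hi, frac in zip(edges[:-1], edges[1:], fractions):
            rows.append((element, int(lo), int(hi), float(frac)))
    return pd.DataFrame(rows, columns=["element", "bin_start", "bin_end",
                                       "fraction"])


def annotate_stage(mods, seeds: SeedSet,
                   min_seed_fraction: float = 0.10) -> StageAnnotation:
    """Stage transfer from single-stage seed modules to their recruited genes.

    A module qualifies when all its seed members share one stage *and* its
    seed fraction strictly exceeds ``min_seed_fraction`` of the module's
    genes.  Every recruited gene of a qualifying module inherits the stage;
    genes in several qualifying modules accumulate all labels.
    """
    ann = StageAnnotation()
    for mod in mods:
        seed_stages = {seeds.members[g] for g in mod.genes if g in seeds}
        n_seeds = sum(1 for g in mod.genes if g in seeds)
        if len(seed_stages) != 1:
            continue
        if n_seeds / len(mod.genes) <= min_seed_fraction + 1e-12:
            continue
        stage = next(iter(seed_stages))
        ann.module_stage[mod.module_id] = stage
        for g in mod.genes:
            if g not in seeds:
                ann.gene_stages.setdefault(g, []).append((stage, mod.module_id))
    return ann


def infer_module_function(mods, seed_groups: dict[str, set]) -> dict[str, list[str]]:
    """Label each module with every gene group intersecting its seed members."""
    out: dict[str, list[str]] = {}
    for mod in mods:
        members = set(mod.genes)
        labels = sorted(label for label, genes in seed_groups.items()
                        if members & set(genes))
        out[mod.module_id] = labels
    return out


#: Module function label -> database tags counted as consistent evidence.
DEFAULT_TAG_MAP: dict[str, set] = {
    "lignin": {"AC-I", "AC-II", "lignin", "MYB"},
    "cellulose": {"MYB"},
    "NDP-sugar": {"MYB"},
    "GT-families": {"MYB"},
}


def consistency_check(module_labels: dict[str, list[str]],
                      top3_tags: dict[str, list[str]],
                      tag_map: dict[str, set] | None = None) -> dict:
    """Compare module function labels with the tags of their top-3 motifs.

    A module is *consistent* when any of its top-3 motif tags is accepted for
    any of its labels, *unannotated* when all three motifs lack database tags
    (excluded from the adjusted rate), and *inconsistent* otherwise.
    Returns per-module statuses plus the consistency rate including and
    excluding unannotated modules.
    """
    tag_map = tag_map or DEFAULT_TAG_MAP
    statuses: dict[str, str] = {}
    for module_id, labels in module_labels.items():
        tags = [t for t in top3_tags.get(module_id, []) if t]
        if not tags:
            statuses[module_id] = "unannotated"
            continue
        accepted = set()
        for label in labels:
            accepted |= tag_map.get(label, set())
        flat = set()
        for t in tags:
            flat |= set(t.split(";"))
        statuses[module_id] = ("consistent" if flat & accepted
                               else "inconsistent")
    n = len(statuses)
    n_cons = sum(1 for s in statuses.values() if s == "consistent")
    n_unann = sum(1 for s in statuses.values() if s == "unannotated")
    rate_all = n_cons / n if n else 0.0
    rate_adj = n_cons / (n - n_unann) if n > n_unann else 0.0
    return {"statuses": statuses, "rate_including_unannotated": rate_all,
            "rate_excluding_unannotated": rate_adj}


def write_conservation_tsv(results: dict[str, ConservationResult], path) -> None:
    rows = [(mid, r.status, len(r.support_pairs))
            for mid, r in sorted(results.items())]
    pd.DataFrame(rows, columns=["motif_id", "conserved", "n_support_pairs"]
                 ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_null_test_json(result: NullMatchResult, path) -> None:
    import json
    from dataclasses import asdict

    with open(path, "w") as fh:
        json.dump(asdict(result), fh, indent=1, sort_keys=True)


def write_stage_tsv(ann: StageAnnotation, path) -> None:
    rows = [(g, stage, module) for g, pairs in sorted(ann.gene_stages.items())
            for stage, module in pairs]
    pd.DataFrame(rows, columns=["gene", "stage", "module_id"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def write_ac_distribution_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
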