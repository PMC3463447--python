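"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the structure of a co-expression study at desk scale:

* an expression matrix with planted bi-clusters — gene subsets that share a
  per-condition expression profile over a condition subset.  Background cells
  are standard normal; a planted cell is the block's per-condition effect
  plus ``Normal(0, noise_sd)`` measurement noise.  The effects are additive
  shifts with a controlled dynamic range: ``shift`` times evenly spaced
  multipliers over ``effect_range``, assigned to the block's conditions in a
  random order and signed per the pattern type.  The shared condition profile
  is what makes planted genes rank-correlated, as real co-regulated genes
  are; the multipliers average 1, so the mean planted elevation is ``shift``;
* seed (known-gene) labels covering part of each planted block, drawn from
  the six cell-wall synthesis stages;
* promoters with planted IUPAC motifs at controlled copy numbers over an
  i.i.d. GC-parameterized background;
* ortholog promoter sets with controlled motif conservation; and
* a known-motif database containing planted motifs plus random decoys.

All generators are deterministic under ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constats import OrthologMap
from .exprio import STAGES, ExpressionMatrix, SeedSet
from .motiffind import PromoterSet
from .motifint import DBMotif, MotifDB

_BASES = "ACGT"


class ConfigurationError(ValueError):
    pass


@dataclass
class SynthConfig:
    n_genes: int = 500
    n_conditions: int = 60
    n_biclusters: int = 3
    bicluster_shape: tuple[int, int] = (30, 15)  # genes x conditions
    shift: float = 2.5
    effect_range: tuple[float, float] = (0.3, 1.7)
    noise_sd: float = 0.25
    promoter_length: int = 2000
    gc_content: float = 0.5
    copies_range: tuple[int, int] = (1, 2)
    conservation_fraction: float = 0.75
    mutation_rate: float = 0.0
    plant_on_both_strands: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        bg, bc = self.bicluster_shape
        if min(self.n_genes, self.n_conditions, self.n_biclusters, bg, bc) <= 0:
            raise ConfigurationError("all counts must be positive")
        if not 0 <= self.gc_content <= 1:
            raise ConfigurationError("gc_content must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.conservation_fraction <= 1:
            raise ConfigurationError("conservation_fraction must lie in [0, 1]")
        if self.n_biclusters * bg > self.n_genes:
            raise ConfigurationError("planted gene blocks exceed n_genes")
        if self.n_biclusters * bc > self.n_conditions:
            raise ConfigurationError("planted condition blocks exceed n_conditions")


@dataclass
class PlantedBicluster:
    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    pattern: str  # "up", "down" or "mixed"
    condition_effects: dict[str, float] = field(default_factory=dict)


@dataclass
class MotifPlant:
    motif: str
    carriers: tuple[str, ...]
    copies: int
    conserved: bool
    offsets: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    ortholog_offsets: dict[str, list[tuple[int, str]]] = field(default_factory=dict)


@dataclass
class PlantedTruth:
    biclusters: list[PlantedBicluster] = field(default_factory=list)
    motif_plants: list[MotifPlant] = field(default_factory=list)
    seed_assignment: dict[str, str] = field(default_factory=dict)


def generate_expression(cfg: SynthConfig,
                        patterns=None) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Expression matrix with planted bi-clusters and exact membership truth.

    Gene blocks and condition blocks are disjoint.  ``patterns`` optionally
    fixes the per-block pattern type (default: all "up").
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    n_bg, n_bc = cfg.bicluster_shape
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    cond_ids = [f"C{i:03d}" for i in range(cfg.n_conditions)]
    X = rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_conditions))

    gene_perm = rng.permutation(cfg.n_genes)
    cond_perm = rng.permutation(cfg.n_conditions)
    patterns = list(patterns or ["up"] * cfg.n_biclusters)
    truth = PlantedTruth()
    for b in range(cfg.n_biclusters):
        gi = np.sort(gene_perm[b * n_bg:(b + 1) * n_bg])
        ci = np.sort(cond_perm[b * n_bc:(b + 1) * n_bc])
        pattern = patterns[b % len(patterns)]
        lo, hi = cfg.effect_range
        multipliers = rng.permutation(np.linspace(lo, hi, n_bc))
        magnitude = cfg.shift * multipliers
        if pattern == "up":
            effects = magnitude
        elif pattern == "down":
            effects = -magnitude
        elif pattern == "mixed":
            effects = magnitude * rng.choice([-1.0, 1.0], size=n_bc)
        else:
            raise ConfigurationError(f"unknown pattern: {pattern!r}")
        noise = rng.normal(0.0, cfg.noise_sd, size=(n_bg, n_bc))
        X[np.ix_(gi, ci)] = effects[None, :] + noise
        truth.biclusters.append(PlantedBicluster(
            genes=tuple(gene_ids[i] for i in gi),
            conditions=tuple(cond_ids[i] for i in ci),
            pattern=pattern,
            condition_effects={cond_ids[i]: float(e)
                               for i, e in zip(ci, effects)},
        ))
    df = pd.DataFrame(X, index=gene_ids, columns=cond_ids)
    df.index.name = "gene_id"
    return ExpressionMatrix(df), truth


def generate_seed_labels(truth: PlantedTruth, seeds_per_bicluster: int,
                         stage_scheme: dict[int, str] | None = None,
                         n_decoys: int = 0, decoy_pool=(),
                         rng_seed: int = 0) -> SeedSet:
    """Seed labels covering part of each planted block.

    Each block contributes exactly ``seeds_per_bicluster`` genes; the stage
    per block comes from ``stage_scheme`` (block index -> stage, default:
    cycle through the six stages).  Optional decoy seeds are drawn from
    ``decoy_pool`` (non-planted genes) with stages cycling likewise.
    """
    rng = np.random.default_rng(rng_seed)
    members: dict[str, str] = {}
    for b, planted in enumerate(truth.biclusters):
        if seeds_per_bicluster > len(planted.genes):
            raise ValueError(
                f"requested {seeds_per_bicluster} seeds from a block of "
                f"{len(planted.genes)} genes")
        stage = (stage_scheme or {}).get(b, STAGES[b % len(STAGES)])
        if seeds_per_bicluster:
            chosen = rng.choice(planted.genes, size=seeds_per_bicluster,
                                replace=False)
            for g in chosen:
                members[str(g)] = stage
    if n_decoys:
        pool = [g for g in decoy_pool if g not in members]
        chosen = rng.choice(pool, size=n_decoys, replace=False)
        for i, g in enumerate(chosen):
            members[str(g)] = STAGES[i % len(STAGES)]
    truth.seed_assignment.update(members)
    return SeedSet(members)


def _random_sequence(rng, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=probs))


def _mutate(rng, word: str, rate: float) -> str:
    if rate <= 0:
        return word
    out = []
    for ch in word:
        if rng.random() < rate:
            out.append(rng.choice([b for b in _BASES if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


def _plant(rng, seq: str, word: str, copies: int, both_strands: bool,
           mutation_rate: float,
           taken: list[tuple[int, int]] | None = None
           ) -> tuple[str, list[tuple[int, str]]]:
    """Insert non-overlapping copies of ``word`` at uniform random offsets.

    ``taken`` carries intervals already occupied by earlier plants in the
    same promoter, so that co-planted motifs never overwrite each other.
    """
    L, w = len(seq), len(word)
    if copies * w > L:
        raise ConfigurationError("planted copies do not fit in the promoter")
    chars = list(seq)
    if taken is None:
        taken = []
    placed: list[tuple[int, str]] = []
    for _ in range(copies):
        for _attempt in range(1000):
            off = int(rng.integers(0, L - w + 1))
            if all(off + w <= lo or off >= hi for lo, hi in taken):
                break
        else:
            raise ConfigurationError("could not place non-overlapping copies")
        strand = "-" if (both_strands and rng.random() < 0.5) else "+"
        from . import iupac
        inserted = word if strand == "+" else iupac.revcomp(word)
        inserted = _mutate(rng, inserted, mutation_rate)
        chars[off:off + w] = inserted
        taken.append((off, off + w))
        placed.append((off, strand))
    placed.sort()
    return "".join(chars), placed


def generate_promoters(genes, cfg: SynthConfig,
                       plants: list[MotifPlant] | None = None,
                       species: str = "focal",
                       rng_seed: int | None = None
                       ) -> tuple[PromoterSet, list[MotifPlant]]:
    """Background promoters with planted motif copies at recorded offsets."""
    cfg.validate()
    plants = plants or []
    for plant in plants:
        if len(plant.motif) >= cfg.promoter_length:
            raise ConfigurationError("planted motif as long as the promoter")
    rng = np.random.default_rng(
        cfg.rng_seed if rng_seed is None else rng_seed)
    seqs: dict[str, str] = {}
    carriers = {g: [pl for pl in plants if g in set(pl.carriers)]
                for g in genes}
    for g in genes:
        seq = _random_sequence(rng, cfg.promoter_length, cfg.gc_content)
        taken: list[tuple[int, int]] = []
        for plant in carriers[g]:
            seq, placed = _plant(rng, seq, plant.motif, plant.copies,
                                 cfg.plant_on_both_strands, cfg.mutation_rate,
                                 taken=taken)
            plant.offsets[g] = placed
        seqs[g] = seq
    return PromoterSet(seqs, species=species, length=cfg.promoter_length), plants


def generate_ortholog_set(promoters: PromoterSet, cfg: SynthConfig,
                          plants: list[MotifPlant] | None = None,
                          conservation_fraction: float | None = None,
                          species: str = "ortholog",
                          rng_seed: int | None = None
                          ) -> tuple[OrthologMap, PromoterSet]:
    """One ortholog promoter per source gene; conserved motifs re-planted.

    For every plant flagged conserved, each carrier's ortholog promoter
    receives one copy with probability ``conservation_fraction``.  The map is
    a bijection on the input gene list.
    """
    cf = (cfg.conservation_fraction if conservation_fraction is None
          else conservation_fraction)
    if not 0 <= cf <= 1:
        raise ConfigurationError("conservation_fraction must lie in [0, 1]")
    plants = plants or []
    rng = np.random.default_rng(
        cfg.rng_seed + 1 if rng_seed is None else rng_seed)
    pairs = {g: f"{g}_ort" for g in promoters.genes}
    seqs: dict[str, str] = {}
    for g in promoters.genes:
        og = pairs[g]
        seq = _random_sequence(rng, cfg.promoter_length, cfg.gc_content)
        for plant in plants:
            if not plant.conserved or g not in set(plant.carriers):
                continue
            if rng.random() < cf:
                seq, placed = _plant(rng, seq, plant.motif, 1,
                                     cfg.plant_on_both_strands,
                                     cfg.mutation_rate)
                plant.ortholog_offsets[og] = placed
        seqs[og] = seq
    ortho = PromoterSet(seqs, species=species, length=cfg.promoter_length)
    return OrthologMap(pairs, provenance="given"), ortho


_DB_TAGS = ("MYB", "AC-I", "AC-II", "lignin")


def generate_motif_db(planted: list[MotifPlant] | list[str], n_decoys: int,
                      cfg: SynthConfig, decoy_width: int = 8,
                      tags=_DB_TAGS, rng_seed: int | None = None) -> MotifDB:
    """Known-motif database = named planted motifs + random decoy consensi.

    Decoys are rejection-sampled so they never byte-equal a planted motif;
    names carry cycling functional tags for the planted entries.
    """
    if n_decoys < 0:
        raise ConfigurationError("n_decoys must be >= 0")
    rng = np.random.default_rng(
        cfg.rng_seed + 2 if rng_seed is None else rng_seed)
    words = [pl.motif if isinstance(pl, MotifPlant) else str(pl)
             for pl in planted]
    entries = [DBMotif(name=f"KNOWN_{tags[i % len(tags)]}_{i + 1}",
                       consensus=w, tag=tags[i % len(tags)])
               for i, w in enumerate(words)]
    forbidden = set(words)
    k = 0
    while k < n_decoys:
        w = "".join(rng.choice(list(_BASES), size=decoy_width))
        if w in forbidden:
            continue
        forbidden.add(w)
        entries.append(DBMotif(name=f"DECOY_{k + 1}", consensus=w, tag=""))
        k += 1
    return MotifDB(entries)


def write_truth_json(truth: PlantedTruth, path) -> None:
    payload = {
        "biclusters": [asdict(b) for b in truth.biclusters],
        "motif_plants": [asdict(p) for p in truth.motif_plants],
        "seed_assignment": truth.seed_assignment,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth_json(path) -> PlantedTruth:
    with open(path) as fh:
        payload = json.load(fh)
    truth = PlantedTruth()
    for b in payload["biclusters"]:
        truth.biclusters.append(PlantedBicluster(
            genes=tuple(b["genes"]), conditions=tuple(b["conditions"]),
            pattern=b["pattern"],
            condition_effects=dict(b["condition_effects"])))
    for p in payload["motif_plants"]:
        truth.motif_plants.append(MotifPlant(
            motif=p["motif"], carriers=tuple(p["carriers"]),
            copies=p["copies"], conserved=p["conserved"],
            offsets={g: [tuple(o) for o in v]
                     for g, v in p["offsets"].items()},
            ortholog_offsets={g: [tuple(o) for o in v]
                              for g, v in p["ortholog_offsets"].items()}))
    truth.seed_assignment = dict(payload["seed_assignment"])
    return truth
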