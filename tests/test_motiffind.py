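import numpy as np
import pandas as pd
import pytest

from pcwnet import iupac
from pcwnet.motiffind import (MISMATCH_BUDGET, PromoterSet, enumerate_motifs,
                              extract_promoters, gibbs_motifs, phylo_motifs,
                              read_promoters_fasta, write_promoters_fasta)
from pcwnet.synthdata import MotifPlant, SynthConfig, generate_ortholog_set, \
    generate_promoters


@pytest.fixture(scope="module")
def planted_promoters():
    genes = [f"G{i:02d}" for i in range(12)]
    cfg = SynthConfig(rng_seed=21, promoter_length=300)
    plant = MotifPlant("GTCACGTA", tuple(genes), copies=1, conserved=True)
    proms, plants = generate_promoters(genes, cfg, [plant], rng_seed=21)
    return proms, plants


class TestExtractPromoters:
    contig = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(6000))

    def gff(self, tmp_path):
        rows = [
            ("chr1", "t", "CDS", 3001, 3600, ".", "+", ".", "ID=c1;Parent=gA"),
            ("chr1", "t", "CDS", 501, 900, ".", "+", ".", "ID=c2;Parent=gB"),
            ("chr1", "t", "CDS", 1001, 1500, ".", "-", ".", "ID=c3;Parent=gC"),
        ]
        path = tmp_path / "ann.gff3"
        path.write_text("##gff-version 3\n" + "\n".join(
            "\t".join(map(str, r)) for r in rows) + "\n")
        return path

    def test_plus_strand_window_and_truncation(self, tmp_path):
        ps = extract_promoters({"chr1": self.contig}, self.gff(tmp_path), L=2000)
        assert ps.sequences["gA"] == self.contig[1000:3000]
        assert len(ps.sequences["gB"]) == 500  # truncated at the contig edge

    def test_minus_strand_is_reverse_complemented(self, tmp_path):
        ps = extract_promoters({"chr1": self.contig}, self.gff(tmp_path), L=2000)
        assert ps.sequences["gC"] == iupac.revcomp(self.contig[1500:3500])

    def test_round_trip_through_a_synthetic_genome(self):
        # promoters embedded in a genome and re-extracted come back verbatim
        rng = np.random.default_rng(5)
        prom = "".join(rng.choice(list("ACGT"), size=500))
        genome = {"c": "".join(rng.choice(list("ACGT"), size=1000))
                       + prom + "ATGCCC" * 100}
        ann = pd.DataFrame(dict(seqid=["c"], type=["CDS"], start=[1501],
                                end=[1800], strand=["+"], gene_id=["g"]))
        ps = extract_promoters(genome, ann, L=500)
        assert ps.sequences["g"] == prom

    def test_fasta_round_trip(self, tmp_path, planted_promoters):
        proms, _ = planted_promoters
        path = tmp_path / "p.fasta"
        write_promoters_fasta(proms, path)
        back = read_promoters_fasta(path, length=proms.length)
        assert back.sequences == proms.sequences


class TestEnumerate:
    def test_planted_word_ranks_first(self, planted_promoters):
        proms, _ = planted_promoters
        motifs = enumerate_motifs(proms, widths=(8,))
        assert motifs[0].consensus == "GTCACGTA"

    def test_at_most_top_k_per_width(self, planted_promoters):
        proms, _ = planted_promoters
        motifs = enumerate_motifs(proms, widths=(6, 8))
        for w in (6, 8):
            assert 0 < sum(m.width == w for m in motifs) <= 15

    def test_reported_motifs_cover_every_promoter(self):
        # a word absent (within the budget) from any promoter is never
        # reported: every reported motif has instances in all promoters
        seqs = {f"g{i}": "ATCGTTGACA" * 6 for i in range(3)}
        seqs["g3"] = "CCGGTTGGCC" * 6  # composition unlike the others
        proms = PromoterSet(seqs, length=60)
        motifs = enumerate_motifs(proms, widths=(6,))
        assert motifs  # repeats of the shared sequence survive
        for m in motifs:
            assert {g for g, *_ in m.instances} == set(proms.genes)

    def test_instances_rescan_within_mismatch_budget(self, planted_promoters):
        proms, _ = planted_promoters
        for m in enumerate_motifs(proms, widths=(8,))[:5]:
            e = MISMATCH_BUDGET[8]
            for gene, off, strand, word in m.instances:
                window = proms.sequences[gene][off:off + 8]
                assert window == word
                target = m.consensus if strand == "+" else iupac.revcomp(
                    m.consensus)
                mm = sum(a != b for a, b in zip(window, target))
                assert mm <= e

    def test_unsupported_width_is_an_error(self, planted_promoters):
        proms, _ = planted_promoters
        with pytest.raises(ValueError):
            enumerate_motifs(proms, widths=(7,))

    def test_background_false_positive_control(self):
        # on pure background, the top score does not exceed the 95th
        # percentile of scores from shuffled-promoter runs
        rng = np.random.default_rng(31)
        genes = [f"G{i}" for i in range(8)]
        cfg = SynthConfig(rng_seed=31, promoter_length=150)
        proms, _ = generate_promoters(genes, cfg, rng_seed=31)
        top = enumerate_motifs(proms, widths=(6,), top_k=1)[0].score
        null_scores = []
        for _ in range(100):
            shuffled = {g: "".join(rng.permutation(list(s)))
                        for g, s in proms.sequences.items()}
            null = enumerate_motifs(PromoterSet(shuffled, length=150),
                                    widths=(6,), top_k=1)
            null_scores.append(null[0].score)
        assert top <= np.quantile(null_scores, 0.95)


class TestGibbs:
    def test_same_seed_is_deterministic(self, planted_promoters):
        proms, _ = planted_promoters
        m1 = gibbs_motifs(proms, rng_seed=4, n_restarts=2, n_iter=40)
        m2 = gibbs_motifs(proms, rng_seed=4, n_restarts=2, n_iter=40)
        assert m1[0].consensus == m2[0].consensus
        assert m1[0].instances == m2[0].instances

    def test_default_width_is_eight(self, planted_promoters):
        proms, _ = planted_promoters
        (m,) = gibbs_motifs(proms, rng_seed=0, n_restarts=2, n_iter=40)
        assert m.width == 8

    def test_too_short_promoters_are_an_error(self):
        proms = PromoterSet({"a": "ACGTA", "b": "ACGTA", "c": "ACGTA"},
                            length=5)
        with pytest.raises(ValueError):
            gibbs_motifs(proms, w=8)


class TestPhylo:
    def test_conserved_kept_focal_only_dropped(self):
        genes = [f"G{i:02d}" for i in range(8)]
        cfg = SynthConfig(rng_seed=2, promoter_length=400)
        conserved = MotifPlant("GTCACGTA", tuple(genes), 1, conserved=True)
        focal = MotifPlant("TTGACCGA", tuple(genes), 1, conserved=False)
        proms, plants = generate_promoters(genes, cfg, [conserved, focal],
                                           rng_seed=2)
        omap, ortho = generate_ortholog_set(proms, cfg, plants,
                                            conservation_fraction=1.0,
                                            rng_seed=3)
        out = phylo_motifs(proms, omap.pairs, {"poplar": ortho}, widths=(8,))
        consensi = {m.consensus for m in out}
        assert "GTCACGTA" in consensi
        assert "TTGACCGA" not in consensi
        assert all(m.finder == "phylo" for m in out)

    def test_empty_ortholog_map_is_an_error(self, planted_promoters):
        proms, _ = planted_promoters
        with pytest.raises(ValueError):
            phylo_motifs(proms, {}, {}, widths=(8,))
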