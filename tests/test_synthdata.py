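import numpy as np
import pytest

from pcwnet import iupac
from pcwnet.exprio import STAGES
from pcwnet.synthdata import (ConfigurationError, MotifPlant, SynthConfig,
                              generate_expression, generate_motif_db,
                              generate_ortholog_set, generate_promoters,
                              generate_seed_labels, read_truth_json,
                              write_truth_json)


def test_same_seed_gives_byte_identical_matrices():
    cfg = SynthConfig(rng_seed=7)
    m1, _ = generate_expression(cfg)
    m2, _ = generate_expression(SynthConfig(rng_seed=7))
    assert m1.data.equals(m2.data)


def test_zero_noise_block_cells_dominate_their_rows():
    cfg = SynthConfig(n_genes=10, n_conditions=10, n_biclusters=1,
                      bicluster_shape=(4, 4), noise_sd=0.0, shift=8.0,
                      rng_seed=1)
    m, truth = generate_expression(cfg)
    block = truth.biclusters[0]
    for g in block.genes:
        row = m.data.loc[g]
        inside = row[list(block.conditions)]
        outside = row.drop(list(block.conditions))
        assert inside.min() > outside.max()


def test_block_mean_elevation_is_the_configured_shift():
    # effect multipliers average 1 exactly, so per-block mean minus the
    # background mean equals the shift within the CLT bound of the noise
    cfg = SynthConfig(rng_seed=2)  # 500x60, three 30x15 blocks, sd 0.25
    m, truth = generate_expression(cfg)
    values = m.data.to_numpy()
    mask = np.zeros(values.shape, dtype=bool)
    gidx = {g: i for i, g in enumerate(m.gene_ids)}
    cidx = {c: j for j, c in enumerate(m.condition_ids)}
    for block in truth.biclusters:
        mask[np.ix_([gidx[g] for g in block.genes],
                    [cidx[c] for c in block.conditions])] = True
    bg = values[~mask]
    for block in truth.biclusters:
        cells = m.data.loc[list(block.genes), list(block.conditions)].to_numpy()
        n = cells.size
        tol = 3 * cfg.noise_sd / np.sqrt(n) + 3 * bg.std() / np.sqrt(bg.size)
        assert abs(cells.mean() - bg.mean() - cfg.shift) < tol


def test_shape_overflow_is_a_configuration_error():
    with pytest.raises(ConfigurationError):
        generate_expression(SynthConfig(n_genes=10, bicluster_shape=(5, 15),
                                        n_biclusters=3))


class TestSeedLabels:
    def test_counts_and_single_stage_per_block(self):
        _, truth = generate_expression(SynthConfig(rng_seed=3))
        seeds = generate_seed_labels(truth, 5, rng_seed=3)
        assert len(seeds) == 15
        for block in truth.biclusters:
            stages = {seeds.members[g] for g in block.genes if g in seeds}
            assert len(stages) == 1
            assert stages <= set(STAGES)

    def test_zero_seeds_gives_empty_set(self):
        _, truth = generate_expression(SynthConfig(rng_seed=3))
        assert len(generate_seed_labels(truth, 0, rng_seed=0)) == 0

    def test_oversized_request_is_an_error(self):
        _, truth = generate_expression(SynthConfig(rng_seed=3))
        with pytest.raises(ValueError):
            generate_seed_labels(truth, 31, rng_seed=0)


class TestPromoters:
    def test_every_carrier_has_a_plant_and_truth_records_it(self):
        genes = [f"G{i}" for i in range(10)]
        cfg = SynthConfig(rng_seed=4, promoter_length=400)
        plant = MotifPlant("CCACC", tuple(genes), copies=1, conserved=False)
        proms, plants = generate_promoters(genes, cfg, [plant], rng_seed=4)
        for g in genes:
            assert iupac.scan(proms.sequences[g], "CCACC")
            (off, strand), = plants[0].offsets[g]
            assert proms.sequences[g][off:off + 5] == "CCACC"

    def test_same_seed_gives_identical_promoters(self):
        genes = ["a", "b"]
        cfg = SynthConfig(rng_seed=5, promoter_length=200)
        p1, _ = generate_promoters(genes, cfg, rng_seed=5)
        p2, _ = generate_promoters(genes, cfg, rng_seed=5)
        assert p1.sequences == p2.sequences

    def test_background_word_rate_matches_gc_model(self):
        # >= 1e5 positions; base composition and the frequency of a word with
        # no self-overlap (binomial variance applies) within 3 standard errors
        cfg = SynthConfig(rng_seed=6, promoter_length=2000, gc_content=0.6)
        genes = [f"G{i}" for i in range(60)]
        proms, _ = generate_promoters(genes, cfg, rng_seed=6)
        joined = "".join(proms.sequences.values())
        n = len(joined)
        assert n >= 1e5
        for base, p in zip("ACGT", (0.2, 0.3, 0.3, 0.2)):
            se = np.sqrt(n * p * (1 - p))
            assert abs(joined.count(base) - n * p) < 3 * se
        word, p_word = "ACGTC", 0.2 * 0.3 * 0.3 * 0.2 * 0.3
        n_pos = sum(len(s) - 4 for s in proms.sequences.values())
        hits = sum(len(iupac.scan(s, word, both_strands=False))
                   for s in proms.sequences.values())
        se = np.sqrt(n_pos * p_word * (1 - p_word))
        assert abs(hits - n_pos * p_word) < 3 * se

    def test_copies_that_do_not_fit_raise(self):
        cfg = SynthConfig(rng_seed=0, promoter_length=20)
        plant = MotifPlant("ACGTACGTACGT", ("g",), copies=2, conserved=False)
        with pytest.raises(ConfigurationError):
            generate_promoters(["g"], cfg, [plant], rng_seed=0)

    def test_co_planted_motifs_do_not_overwrite_each_other(self):
        genes = [f"G{i}" for i in range(5)]
        cfg = SynthConfig(rng_seed=8, promoter_length=300)
        words = ["GTCACGTAGCAA", "TTGACCGATTGG", "CACGTGGATACC"]
        plants = [MotifPlant(w, tuple(genes), copies=2, conserved=False)
                  for w in words]
        proms, _ = generate_promoters(genes, cfg, plants, rng_seed=8)
        for g in genes:
            for w in words:
                assert len(iupac.scan(proms.sequences[g], w,
                                      both_strands=False)) >= 2


class TestOrthologs:
    def test_map_is_a_bijection(self):
        genes = [f"G{i}" for i in range(8)]
        cfg = SynthConfig(rng_seed=9, promoter_length=200)
        proms, _ = generate_promoters(genes, cfg, rng_seed=9)
        omap, ortho = generate_ortholog_set(proms, cfg, rng_seed=10)
        assert len(set(omap.pairs.values())) == len(omap.pairs) == len(genes)
        assert set(omap.pairs.values()) == set(ortho.sequences)

    def test_full_conservation_replants_in_every_ortholog(self):
        genes = [f"G{i}" for i in range(8)]
        cfg = SynthConfig(rng_seed=11, promoter_length=300)
        plant = MotifPlant("GTCACGTA", tuple(genes), copies=1, conserved=True)
        proms, plants = generate_promoters(genes, cfg, [plant], rng_seed=11)
        omap, ortho = generate_ortholog_set(
            proms, cfg, plants, conservation_fraction=1.0, rng_seed=12)
        for g in genes:
            assert iupac.scan(ortho.sequences[omap.pairs[g]], "GTCACGTA")


class TestMotifDB:
    def test_size_and_decoy_distinctness(self):
        cfg = SynthConfig(rng_seed=13)
        db = generate_motif_db(["CCACC", "GTAC", "ACCTACC"], n_decoys=0, cfg=cfg)
        assert len(db) == 3
        db2 = generate_motif_db(["ACGTACGT"], n_decoys=50, cfg=cfg)
        planted = {"ACGTACGT"}
        decoys = {e.consensus for e in db2.entries if e.name.startswith("DECOY")}
        assert not decoys & planted
        assert len(db2) == 51

    def test_tags_round_trip_through_tsv(self, tmp_path):
        from pcwnet.motifint import read_motif_db, write_motif_db
        cfg = SynthConfig(rng_seed=14)
        db = generate_motif_db(["CCACC", "ACCTACC"], n_decoys=3, cfg=cfg)
        path = tmp_path / "db.tsv"
        write_motif_db(db, path)
        back = read_motif_db(path)
        assert [(e.name, e.consensus, e.tag) for e in back.entries] == \
               [(e.name, e.consensus, e.tag) for e in db.entries]


def test_truth_json_round_trip(tmp_path):
    cfg = SynthConfig(rng_seed=15, n_genes=50, n_conditions=20,
                      bicluster_shape=(5, 4))
    _, truth = generate_expression(cfg)
    generate_seed_labels(truth, 2, rng_seed=15)
    path = tmp_path / "truth.json"
    write_truth_json(truth, path)
    back = read_truth_json(path)
    assert [b.genes for b in back.biclusters] == [b.genes for b in truth.biclusters]
    assert back.seed_assignment == truth.seed_assignment
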