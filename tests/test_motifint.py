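import itertools

import numpy as np
import pytest

from pcwnet import iupac
from pcwnet.coexnet import CoexpressionModule
from pcwnet.motifint import (DBMotif, MotifCluster, MotifDB, MotifSimilarity,
                             annotate_vs_db, consensus_motif, is_palindrome,
                             mcl_cluster, module_motif_support,
                             motif_similarity, select_reliable_motifs)
from pcwnet.motiffind import Motif


class TestSimilarity:
    def test_identity(self):
        s = motif_similarity("CCACC", "CCACC")
        assert (s.matched, s.overlap, s.ratio, s.pct) == (5, 5, 1.0, 1.0)

    def test_prefix_alignment(self):
        s = motif_similarity("CCACC", "CCACCT")
        assert (s.matched, s.overlap, s.offset) == (5, 5, 0)
        assert s.pct == 1.0  # relative to the shorter width

    def test_reverse_complement_orientation_is_found(self):
        s = motif_similarity("GTCACGTA", iupac.revcomp("GTCACGTA"))
        assert s.matched == 8 and s.orientation in "+-"

    def test_symmetry_on_random_degenerate_pairs(self):
        rng = np.random.default_rng(7)
        codes = list(iupac.IUPAC)
        for _ in range(100):
            a = "".join(rng.choice(codes, size=rng.integers(4, 11)))
            b = "".join(rng.choice(codes, size=rng.integers(4, 11)))
            sa, sb = motif_similarity(a, b), motif_similarity(b, a)
            assert (sa.matched, sa.overlap, sa.min_width) == \
                   (sb.matched, sb.overlap, sb.min_width)

    def test_short_motifs_rejected(self):
        with pytest.raises(ValueError):
            motif_similarity("ACG", "ACGT")


class TestMCL:
    def test_disjoint_components_stay_separate(self):
        motifs = ["AAAAAAA", "AAAAAAT", "GGGGGGG", "GGGGGGC"]
        clusters = mcl_cluster(motifs)
        groups = sorted(tuple(c.members) for c in clusters)
        assert groups == [("AAAAAAA", "AAAAAAT"), ("GGGGGGC", "GGGGGGG")]

    def test_clusters_partition_the_input(self):
        rng = np.random.default_rng(8)
        words = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(20)]
        clusters = mcl_cluster(words)
        flat = sorted(m for c in clusters for m in c.members)
        assert flat == sorted(set(words))

    def test_weakly_bridged_triangles_split_at_inflation_four(self):
        ids = [f"m{i}" for i in range(6)]
        edges = []
        for tri in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(tri, 2):
                edges.append(MotifSimilarity(ids[i], ids[j], 6, 7, 7, 0, "+"))
        edges.append(MotifSimilarity("m2", "m3", 5, 6, 6, 0, "+"))  # bridge
        motifs = [type("M", (), {"id": i, "consensus": "ACGTAAC"})()
                  for i in ids]
        clusters = mcl_cluster(motifs, sim_edges=edges)
        groups = sorted(tuple(c.members) for c in clusters)
        assert groups == [("m0", "m1", "m2"), ("m3", "m4", "m5")]


class TestConsensus:
    def test_identical_members_give_the_motif_verbatim(self):
        cl = MotifCluster("c", ["GTCACG", "GTCACG"])
        assert consensus_motif(cl) in ("GTCACG",)

    def test_half_split_column_becomes_degenerate(self):
        assert consensus_motif(MotifCluster("c", ["CCACC", "CCACG"])) == "CCACS"

    def test_consensus_no_longer_than_longest_member(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            members = ["".join(rng.choice(list("ACGT"), size=rng.integers(5, 9)))
                       for _ in range(rng.integers(1, 4))]
            cl = MotifCluster("c", members)
            assert len(consensus_motif(cl)) <= max(len(m) for m in members)


class TestAnnotate:
    db = MotifDB([DBMotif("FIVE", "CCACC", "MYB"),
                  DBMotif("FOUR", "GTAC", "AC-I"),
                  DBMotif("EIGHT", "GTCACGTA", "lignin")])

    @staticmethod
    def motif(consensus, mid="m"):
        return type("M", (), {"id": mid, "consensus": consensus})()

    def test_identical_eight_and_five_mers_match(self):
        ann = annotate_vs_db([self.motif("GTCACGTA", "a"),
                              self.motif("CCACC", "b")], self.db,
                             integrate_db=False)
        assert ann["a"]["name"] == "EIGHT" and ann["a"]["tag"] == "lignin"
        assert ann["b"]["name"] == "FIVE"

    def test_identical_four_mers_do_not_match(self):
        ann = annotate_vs_db([self.motif("GTAC", "a")], self.db,
                             integrate_db=False)
        assert "a" not in ann  # 4 matched positions is not > 4

    def test_integrated_db_collapses_duplicates_but_keeps_matches(self):
        db = MotifDB([DBMotif("A1", "GTCACGTA", "MYB"),
                      DBMotif("A2", "GTCACGTA", "MYB"),
                      DBMotif("B", "TTTTGGGG", "")])
        ann = annotate_vs_db([self.motif("GTCACGTA", "x")], db)
        assert "A1" in ann["x"]["name"] and "A2" in ann["x"]["name"]

    def test_empty_db_is_an_error(self):
        with pytest.raises(ValueError):
            annotate_vs_db([self.motif("CCACC")], MotifDB([]))

    def test_cluster_representatives_are_mutually_non_matching(self):
        rng = np.random.default_rng(10)
        words = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(25)]
        clusters = mcl_cluster(sorted(set(words)))
        reps = [c.representative for c in clusters]
        from pcwnet.motifint import EDGE_MATCHED_MIN, EDGE_PCT_MIN
        for a, b in itertools.combinations(reps, 2):
            s = motif_similarity(a, b)
            assert not (s.matched >= EDGE_MATCHED_MIN and s.pct >= EDGE_PCT_MIN)


class TestPalindromes:
    def test_classic_cases(self):
        assert is_palindrome("GAATTC")
        assert not is_palindrome("GTACAG")

    @pytest.mark.parametrize("k,expected", [(4, 16), (6, 64)])
    def test_brute_force_count_matches_analytic(self, k, expected):
        count = 0
        for word in itertools.product("ACGT", repeat=k):
            w = "".join(word)
            brute = w == "".join(
                {"A": "T", "T": "A", "C": "G", "G": "C"}[c]
                for c in reversed(w))
            assert is_palindrome(w) == brute
            count += brute
        assert count == expected == 4 ** (k // 2)


def _module(genes):
    return CoexpressionModule("m_1", tuple(genes), [], 1.0)


def _motif(mid, carriers, width=8):
    return Motif(id=mid, consensus="A" * width, width=width,
                 instances=[(g, 0, "+", "A" * width) for g in carriers],
                 score=1.0, finder="enumerative")


class TestSupportAndSelection:
    def test_full_coverage_flags_the_module(self):
        mod = _module(["a", "b", "c", "d", "e"])
        fractions, flag = module_motif_support(
            mod, [_motif("m1", ["a", "b", "c", "d", "e"])])
        assert fractions["m1"] == 1.0 and flag

    def test_seventy_nine_percent_does_not_flag(self):
        genes = [f"g{i}" for i in range(100)]
        mod = _module(genes)
        fractions, flag = module_motif_support(
            mod, [_motif("m1", genes[:79])])
        assert fractions["m1"] == pytest.approx(0.79)
        assert not flag

    def test_no_instances_means_no_flag(self):
        _, flag = module_motif_support(_module(["a", "b"]), [])
        assert not flag

    def test_conservation_outranks_coverage(self):
        mod = _module([f"g{i}" for i in range(10)])
        wide = _motif("wide", [f"g{i}" for i in range(9)])
        narrow = _motif("narrow", [f"g{i}" for i in range(5)])
        picked = select_reliable_motifs(mod, [wide, narrow],
                                        conserved_ids={"narrow"})
        assert [m.id for m in picked] == ["narrow", "wide"]

    def test_at_most_three_returned(self):
        mod = _module(["a"])
        motifs = [_motif(f"m{i}", ["a"]) for i in range(6)]
        assert len(select_reliable_motifs(mod, motifs)) == 3
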