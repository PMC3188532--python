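"""Small-RNA cleaning, cascade annotation, miRNA matching and summaries."""
import numpy as np
import pytest

import tarscribe as ts
from tarscribe.smallrna import (
    CASCADE_ORDER,
    SmallRnaTag,
    tag_distance,
)

from oracles import mirna_match_oracle

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestCleanTags:
    def test_adapter_trimmed_and_retained(self):
        insert = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        tags = ts.clean_tags([(insert + ADAPTER, 3)], ADAPTER)
        assert [(t.sequence, t.count) for t in tags] == [(insert, 3)]

    def test_partial_adapter_at_read_end(self):
        insert = "ACGTACGTACGTACGTACGTAC"
        raw = insert + ADAPTER[:6]  # adapter runs off the read
        tags = ts.clean_tags([(raw, 1)], ADAPTER)
        assert tags[0].sequence == insert

    def test_short_insert_dropped(self):
        tags = ts.clean_tags([("ACGTACGTACGTAC" + ADAPTER, 5)], ADAPTER)  # 14 nt
        assert tags == []

    def test_duplicates_collapsed(self):
        s = "ACGTACGTACGTACGTACGTAC"
        tags = ts.clean_tags([(s, 3), (s, 2)], None)
        assert [(t.sequence, t.count) for t in tags] == [(s, 5)]

    def test_u_normalized_to_t(self):
        tags = ts.clean_tags([("ACGUACGUACGUACGUACGUAC", 1)], None)
        assert "U" not in tags[0].sequence and len(tags[0].sequence) == 22


class TestLengthDistribution:
    def test_single_length(self):
        tags = [SmallRnaTag("A" * 22, 5)]
        d = ts.length_distribution(tags)
        assert d["mode"] == 22 and d["fraction_20_23"] == 1.0

    def test_uniform_lengths(self):
        tags = [SmallRnaTag("A" * n, 1) for n in range(18, 31)]
        d = ts.length_distribution(tags)
        assert d["fraction_20_23"] == pytest.approx(4 / 13)


class TestCascade:
    def test_priority_rrna_over_exon(self):
        tag = SmallRnaTag("ACGTACGTACGTACGTAC", 1)
        refs = {"rRNA": ["TT" + tag.sequence + "GG"], "exon": [tag.sequence + "AAAA"]}
        out = ts.annotate_cascade([tag], refs)
        assert out[0].category == "rRNA"

    def test_unmatched_retained_as_unannotated(self):
        tag = SmallRnaTag("ACGTACGTACGTACGTAC", 1)
        out = ts.annotate_cascade([tag], {"rRNA": ["GGGGGGGG"]})
        assert out[0].category == "unannotated"
        assert ts.retained_for_mirna(out) == out

    def test_partition_property_random_fixture(self):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        refs = {
            cat: ["".join(bases[rng.integers(0, 4, 300)])] for cat in CASCADE_ORDER
        }
        tags = []
        for cat in CASCADE_ORDER:
            ref = refs[cat][0]
            s = int(rng.integers(0, 270))
            tags.append(SmallRnaTag(ref[s:s + 22], 1))
        out = ts.annotate_cascade(tags, refs)
        # every tag gets exactly one category, never later in the cascade
        # than the category it was drawn from
        for tag, src in zip(out, CASCADE_ORDER):
            assert CASCADE_ORDER.index(tag.category) <= CASCADE_ORDER.index(src)


class TestMatching:
    DB = {
        "mir-a": "ACGTACGTACGTACGTACGTAC",
        "mir-b": "TTTTCCCCGGGGAAAATTTTCC",
    }

    def test_exact_and_mismatch_boundaries(self):
        exact = self.DB["mir-a"]
        two = "TTGTACGTACGTACGTACGTAC"  # 2 subs vs mir-a
        three = "TTTTACGTACGTACGTACGTAC"  # 3 subs
        quants, unmatched = ts.match_known(
            [SmallRnaTag(exact, 5), SmallRnaTag(two, 2), SmallRnaTag(three, 1)],
            self.DB, clean_total=100,
        )
        by_id = {q.mirna_id: q for q in quants}
        assert by_id["mir-a"].count == 7
        assert [t.sequence for t in unmatched] == [three]

    def test_end_shift_tolerance(self):
        trimmed = self.DB["mir-a"][2:]  # 20 nt, offset 2
        quants, unmatched = ts.match_known([SmallRnaTag(trimmed, 4)], self.DB, 10)
        assert quants[0].mirna_id == "mir-a" and quants[0].count == 4

    def test_tie_split_and_flagged(self):
        db = {"mir-x": "ACGTACGTACGTACGTACGTAC", "mir-y": "ACGTACGTACGTACGTACGTAG"}
        tag = "ACGTACGTACGTACGTACGTAT"  # 1 sub from each
        quants, _ = ts.match_known([SmallRnaTag(tag, 4)], db, 10)
        assert all(q.count == 2 and q.ambiguous for q in quants)

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        db = {
            f"m{i}": "".join(bases[rng.integers(0, 4, int(rng.integers(20, 25)))])
            for i in range(20)
        }
        for _ in range(300):
            if rng.random() < 0.5:
                seq = "".join(bases[rng.integers(0, 4, int(rng.integers(18, 31)))])
            else:
                base = db[f"m{int(rng.integers(0, 20))}"]
                seq = list(base)
                for pos in rng.choice(len(seq), size=int(rng.integers(0, 4)), replace=False):
                    seq[pos] = str(bases[int(rng.integers(0, 4))])
                seq = "".join(seq)
            oracle_d, oracle_hits = mirna_match_oracle(seq, db)
            quants, unmatched = ts.match_known([SmallRnaTag(seq, 1)], db, 1)
            if oracle_d is None:
                assert quants == [] and len(unmatched) == 1
            else:
                assert sorted(q.mirna_id for q in quants) == oracle_hits

    def test_tag_distance_basics(self):
        assert tag_distance("ACGT" * 5, "ACGT" * 5) == 0
        assert tag_distance("ACGT" * 5, "ACGT" * 8) is None  # length gap > 2


class TestSummaries:
    def test_tpm_linear_in_count(self):
        q1, _ = ts.match_known([SmallRnaTag(TestMatching.DB["mir-a"], 10)], TestMatching.DB, 1000)
        q2, _ = ts.match_known([SmallRnaTag(TestMatching.DB["mir-a"], 20)], TestMatching.DB, 1000)
        assert q2[0].tpm == pytest.approx(2 * q1[0].tpm)

    def test_top_expressed_single(self):
        quants, _ = ts.match_known([SmallRnaTag(TestMatching.DB["mir-a"], 10)], TestMatching.DB, 40)
        top = ts.top_expressed(quants, clean_total=40, k=1)
        assert top["cumulative_fraction"] == pytest.approx(0.25)

    def test_top_k_exceeding_n(self):
        tags = [SmallRnaTag(s, 5) for s in TestMatching.DB.values()]
        quants, _ = ts.match_known(tags, TestMatching.DB, 100)
        top = ts.top_expressed(quants, clean_total=100, k=20)
        assert top["cumulative_fraction"] == pytest.approx(0.10)

    def test_planted_ranking_recovered(self, config):
        tags_raw, refs, mature, truth = ts.simulate_small_rna(config)
        tags = ts.clean_tags(tags_raw)
        annotated = ts.annotate_cascade(tags, refs)
        retained = ts.retained_for_mirna(annotated)
        total = sum(t.count for t in tags)
        quants, _ = ts.match_known(retained, mature, total)
        planted = truth["mature_read_counts"]
        top_called = [q.mirna_id for q in quants[:5]]
        top_planted = sorted(planted, key=lambda m: -planted[m])[:5]
        assert top_called == top_planted
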