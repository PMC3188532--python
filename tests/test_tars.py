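"""TAR calling, unit linking, intergenic filtering and clustering."""
import numpy as np
import pytest

import tarscribe as ts
from tarscribe.model import AlignmentRecord, CoverageTrack, GeneModel, GenomicInterval
from tarscribe.tars import Tar, TranscriptUnit, filter_novel_units

from oracles import coverage_runs


def _read(rid, mate, chrom, spans, unique=True):
    return AlignmentRecord(rid, mate, [GenomicInterval(chrom, s, e) for s, e in spans], unique)


def _gene(gid, chrom, start, end, strand="+"):
    iv = GenomicInterval(chrom, start, end, strand)
    return GeneModel(gid, iv, [iv])


class TestComputeCoverage:
    def test_stacked_reads(self):
        reads = [_read("a", 1, "chr1", [(100, 190)]), _read("b", 1, "chr1", [(100, 190)])]
        cov = ts.compute_coverage(reads, {"chr1": 1000})["chr1"]
        assert (cov.depth[100:190] == 2).all()
        assert cov.depth.sum() == 180

    def test_spliced_read_gap_uncovered(self):
        reads = [_read("a", 1, "chr1", [(0, 40), (240, 290)])]
        cov = ts.compute_coverage(reads, {"chr1": 400})["chr1"]
        assert cov.depth[0:40].sum() == 40
        assert cov.depth[40:240].sum() == 0

    def test_multimapper_excluded(self):
        reads = [_read("a", 1, "chr1", [(0, 90)], unique=False)]
        cov = ts.compute_coverage(reads, {"chr1": 100})["chr1"]
        assert cov.depth.sum() == 0

    def test_conservation_random_reads(self):
        rng = np.random.default_rng(0)
        reads = []
        for i in range(1000):
            s = int(rng.integers(0, 900))
            reads.append(_read(f"r{i}", 1, "chr1", [(s, s + 90)]))
        cov = ts.compute_coverage(reads, {"chr1": 1000})["chr1"]
        assert cov.depth.sum() == sum(r.aligned_length for r in reads)

    def test_block_beyond_chrom_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            ts.compute_coverage([_read("a", 1, "chr1", [(50, 200)])], {"chr1": 100})


class TestCallTars:
    def test_linear_scan_example(self):
        cov = CoverageTrack("chr1", np.array([0, 0, 3, 3, 1, 2, 2, 0]))
        tars = ts.call_tars(cov, 2)
        assert [(t.interval.start, t.interval.end) for t in tars] == [(2, 4), (5, 7)]
        assert tars[0].mean_depth == 3.0

    def test_all_zero_and_uniform(self):
        assert ts.call_tars(CoverageTrack("chr1", np.zeros(50)), 2) == []
        tars = ts.call_tars(CoverageTrack("chr1", np.full(50, 5)), 2)
        assert len(tars) == 1 and len(tars[0].interval) == 50

    def test_matches_per_base_scan_on_random_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            depth = rng.poisson(1.2, size=int(rng.integers(10, 400)))
            tars = ts.call_tars(CoverageTrack("chr1", depth), 2)
            assert [(t.interval.start, t.interval.end) for t in tars] == coverage_runs(depth, 2)
            for t in tars:
                assert t.mean_depth == pytest.approx(
                    depth[t.interval.start:t.interval.end].mean()
                )


class TestLinkTars:
    def _tars(self, spans):
        return [Tar(GenomicInterval("chr1", s, e), 3.0) for s, e in spans]

    def test_pair_links_two_tars(self):
        tars = self._tars([(0, 200), (500, 700)])
        reads = [
            _read("p1", 1, "chr1", [(10, 100)]),
            _read("p1", 2, "chr1", [(550, 640)]),
        ]
        units = ts.link_tars(tars, reads)
        assert len(units) == 1 and units[0].n_exons == 2
        assert units[0].n_linking_pairs == 1

    def test_unlinked_tars_stay_separate(self):
        tars = self._tars([(0, 200), (500, 700)])
        units = ts.link_tars(tars, [_read("a", 1, "chr1", [(10, 100)])])
        assert [u.n_exons for u in units] == [1, 1]

    def test_chain_links_transitively(self):
        tars = self._tars([(0, 200), (500, 700), (1000, 1200)])
        reads = [
            _read("p1", 1, "chr1", [(10, 100)]), _read("p1", 2, "chr1", [(550, 640)]),
            _read("p2", 1, "chr1", [(600, 690)]), _read("p2", 2, "chr1", [(1010, 1100)]),
        ]
        units = ts.link_tars(tars, reads)
        assert len(units) == 1 and units[0].n_exons == 3

    def test_multimapping_pair_does_not_link(self):
        tars = self._tars([(0, 200), (500, 700)])
        reads = [
            _read("p1", 1, "chr1", [(10, 100)], unique=False),
            _read("p1", 2, "chr1", [(550, 640)], unique=False),
        ]
        assert [u.n_exons for u in ts.link_tars(tars, reads)] == [1, 1]


class TestDefineIntergenic:
    def test_complement_example(self):
        ann = [_gene("a", "chr1", 1000, 2000), _gene("b", "chr1", 5000, 6000)]
        out = ts.define_intergenic(ann, {"chr1": 10_000}, 200)
        assert [(i.start, i.end) for i in out] == [(0, 800), (2200, 4800), (6200, 10_000)]

    def test_no_genes_whole_chrom(self):
        out = ts.define_intergenic([], {"chr1": 500}, 200)
        assert [(i.start, i.end) for i in out] == [(0, 500)]

    def test_close_genes_leave_no_gap(self):
        ann = [_gene("a", "chr1", 1000, 2000), _gene("b", "chr1", 2300, 3000)]
        out = ts.define_intergenic(ann, {"chr1": 5000}, 200)
        assert [(i.start, i.end) for i in out] == [(0, 800), (3200, 5000)]


class TestFilterNovelUnits:
    def _unit(self, spans, depth=3.0):
        return TranscriptUnit([Tar(GenomicInterval("chr1", s, e), depth) for s, e in spans])

    def test_gene_overlap_rejected(self):
        intergenic = [GenomicInterval("chr1", 0, 1000)]
        unit = self._unit([(800, 1001)])  # 1 bp outside
        assert filter_novel_units([unit], intergenic) == []

    def test_min_run_boundary(self):
        intergenic = [GenomicInterval("chr1", 0, 1000)]
        short = self._unit([(100, 249)])  # run 149
        exact = self._unit([(400, 550)])  # run 150
        kept = filter_novel_units([short, exact], intergenic)
        assert kept == [exact]

    def test_low_average_coverage_rejected(self):
        intergenic = [GenomicInterval("chr1", 0, 1000)]
        unit = self._unit([(100, 300)], depth=1.9)
        assert filter_novel_units([unit], intergenic) == []


class TestClusterUnits:
    def _unit(self, s, e):
        return TranscriptUnit([Tar(GenomicInterval("chr1", s, e), 3.0)])

    def test_pairwise_merge_example(self):
        units = [self._unit(0, 200), self._unit(2000, 2300), self._unit(6000, 6100)]
        regions = ts.cluster_units(units, 3000)
        assert [(r.span.start, r.span.end) for r in regions] == [(0, 2300), (6000, 6100)]
        assert sum(len(r.units) for r in regions) == 3

    def test_single_unit(self):
        assert len(ts.cluster_units([self._unit(0, 100)])) == 1

    def test_gap_exactly_3000_merges(self):
        units = [self._unit(0, 100), self._unit(3100, 3200)]
        assert len(ts.cluster_units(units, 3000)) == 1
        units = [self._unit(0, 100), self._unit(3101, 3200)]
        assert len(ts.cluster_units(units, 3000)) == 2


class TestPlantedRecovery:
    def test_novel_units_never_touch_padded_genes(self, dataset):
        cfg = dataset["config"]
        _, novel, _ = ts.discover_novel_units(
            dataset["alignments"], dataset["annotation"], cfg.chrom_sizes
        )
        for u in novel:
            for g in dataset["annotation"]:
                padded = GenomicInterval(
                    g.chrom, max(0, g.interval.start - 200), g.interval.end + 200
                )
                assert not u.span.overlaps(padded)

    def test_tar_depth_invariant(self, dataset):
        cov = dataset["coverage"]["chr1"].depth
        for t in dataset["tars"][:200]:
            assert (cov[t.interval.start:t.interval.end] >= 2).all()
            if t.interval.start > 0:
                assert cov[t.interval.start - 1] < 2
            if t.interval.end < len(cov):
                assert cov[t.interval.end] < 2
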