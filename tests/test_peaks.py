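"""Peak calling, joint peaks, downsampling, replicate correlation."""

import numpy as np
import pytest

from clipmap.io_formats import RunConfig
from clipmap.models import AlignedRead, Peak
from clipmap.peaks import (
    biological_complexity,
    call_peaks,
    define_joint_peaks,
    downsample_reads,
    normalize_heights,
    replicate_group_correlation,
)
from conftest import make_gene


def read_at(start, end, strand="+", condition="MN", rep=1, rid=None, chrom="chr1"):
    rid = rid or f"r{start}_{end}_{rep}"
    return AlignedRead(chrom, start, end, strand, condition, rep, rid)


class TestCallPeaks:
    def test_stacked_reads_give_one_peak(self):
        # 20 length-50 reads stacked at one locus of a 1 kb unit: lambda = 1,
        # and the adjusted Poisson tail at height 20 is astronomically small
        gene = make_gene(start=0, end=1000)
        reads = [read_at(200, 250, rid=f"s{i}", rep=1 + i % 4) for i in range(20)]
        peaks = call_peaks(reads, gene, alpha=0.01)
        assert len(peaks) == 1
        (p,) = peaks
        assert p.read_count == 20 and p.summit_height == 20
        assert (p.start, p.end) == (200, 250)
        assert p.p_value < 1e-15

    def test_tiled_reads_give_no_peaks(self):
        gene = make_gene(start=0, end=1000)
        reads = [read_at(i * 50, (i + 1) * 50, rid=f"t{i}") for i in range(20)]
        assert call_peaks(reads, gene, alpha=0.01) == []

    def test_empty_gene_no_peaks(self):
        gene = make_gene(start=0, end=1000)
        assert call_peaks([], gene) == []

    def test_coordinate_shift_equivariance(self):
        # shifting every genomic feature by +k shifts peaks by exactly +k
        k = 1237
        gene = make_gene(start=0, end=2000)
        gene_k = make_gene(start=k, end=2000 + k)
        reads = [read_at(700, 760, rid=f"s{i}") for i in range(25)]
        reads += [read_at(40 * i, 40 * i + 35, rid=f"b{i}") for i in range(30)]
        base = call_peaks(reads, gene, alpha=0.01)
        shifted = call_peaks([r.shifted(k) for r in reads], gene_k, alpha=0.01)
        assert [(p.start + k, p.end + k) for p in base] == [
            (p.start, p.end) for p in shifted
        ]


class TestBiologicalComplexity:
    def _peak(self, start=100, end=200):
        return Peak("g1", "chr1", "+", start, end, 5, 5, 0.001)

    def test_counts_distinct_replicates(self):
        reads = [read_at(120, 170, rep=r) for r in (1, 1, 3)]
        assert biological_complexity(self._peak(), reads) == 2

    def test_zero_when_nothing_overlaps(self):
        assert biological_complexity(self._peak(), [read_at(500, 560)]) == 0

    def test_all_eight_replicates(self):
        reads = [read_at(120, 170, rep=r) for r in range(1, 9)]
        assert biological_complexity(self._peak(), reads) == 8


class TestJointPeaks:
    def _setup(self):
        cfg = RunConfig()
        gene = make_gene(start=0, end=3000, tu_end=13_000, exons=[(0, 400)])
        return cfg, gene

    def test_or_rule_retains_mn_only_peak(self):
        cfg, gene = self._setup()
        mn = [read_at(1000, 1060, condition="MN", rep=1 + i % 4, rid=f"m{i}") for i in range(24)]
        jps = define_joint_peaks(mn, [], [gene], cfg)
        assert len(jps) == 1
        (jp,) = jps
        assert jp.m == 24 and jp.n == 0 and jp.bc_mn == 4
        assert jp.region_class == "intron"

    def test_low_complexity_peak_dropped(self):
        cfg, gene = self._setup()
        mn = [read_at(1000, 1060, condition="MN", rep=1, rid=f"m{i}") for i in range(20)]
        wsc = [read_at(1000, 1060, condition="WSC", rep=1, rid=f"w{i}") for i in range(20)]
        assert define_joint_peaks(mn, wsc, [gene], cfg) == []

    def test_family_totals_shared_within_gene(self):
        cfg, gene = self._setup()
        mn = [read_at(1000, 1060, condition="MN", rep=1 + i % 8, rid=f"a{i}") for i in range(30)]
        mn += [read_at(2000, 2060, condition="MN", rep=1 + i % 8, rid=f"b{i}") for i in range(10)]
        jps = define_joint_peaks(mn, [], [gene], cfg)
        assert sorted(jp.m for jp in jps) == [10, 30]
        assert all(jp.M == 40 for jp in jps)

    def test_condition_labels_are_validated(self):
        cfg, gene = self._setup()
        with pytest.raises(ValueError):
            define_joint_peaks([read_at(0, 50, condition="WSC")], [], [gene], cfg)

    def test_every_jp_satisfies_bc_rule(self, demo_dataset, demo_results, cfg):
        for jp in demo_results.binding.joint_peaks:
            assert jp.bc_mn >= cfg.bc_mn or jp.bc_wsc >= cfg.bc_wsc
            assert 0 <= jp.m <= jp.M and 0 <= jp.n <= jp.N


class TestDownsample:
    def test_identity_when_target_is_size(self):
        reads = [read_at(i, i + 30, rid=str(i)) for i in range(10)]
        assert downsample_reads(reads, 10, seed=1) == reads

    def test_empty_when_target_zero(self):
        reads = [read_at(i, i + 30, rid=str(i)) for i in range(10)]
        assert downsample_reads(reads, 0, seed=1) == []

    def test_seeded_and_order_stable(self):
        reads = [read_at(i, i + 30, rid=str(i)) for i in range(100)]
        s1 = downsample_reads(reads, 40, seed=7)
        s2 = downsample_reads(reads, 40, seed=7)
        assert s1 == s2
        positions = [r.start for r in s1]
        assert positions == sorted(positions)

    def test_target_above_size_errors(self):
        with pytest.raises(ValueError):
            downsample_reads([read_at(0, 30)], 2, seed=1)


class TestReplicateCorrelation:
    def _peaks(self, heights, scale=1.0):
        out = []
        for i, h in enumerate(heights):
            p = Peak("g", "chr1", "+", i * 100, i * 100 + 50, int(h), int(h), 0.001)
            p.normalized_height = h * scale
            out.append(p)
        return out

    def test_identical_groups_give_unity(self):
        h = [3, 10, 30, 100, 8]
        assert replicate_group_correlation(self._peaks(h), self._peaks(h)) == pytest.approx(1.0)

    def test_scaling_is_nearly_invariant_in_log_space(self):
        h = np.geomspace(2, 500, 40)
        r2 = replicate_group_correlation(self._peaks(h), self._peaks(h, scale=3.0))
        assert r2 > 0.999

    def test_independent_heights_near_zero(self):
        rng = np.random.default_rng(5)
        a = self._peaks(rng.poisson(20, size=1000) + 1)
        b = self._peaks(rng.poisson(20, size=1000) + 1)
        assert replicate_group_correlation(a, b) < 0.05

    def test_too_few_matches_error(self):
        with pytest.raises(ValueError):
            replicate_group_correlation(self._peaks([1, 2]), self._peaks([1, 2]))


def test_normalized_height_is_reads_per_million():
    p = Peak("g", "chr1", "+", 0, 50, 5, 50, 0.001)
    normalize_heights([p], library_size=2_000_000)
    assert p.normalized_height == pytest.approx(25.0)
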