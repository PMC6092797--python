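"""RNA-map direction predictions, overlap/gene-set enrichment, concordance."""

import numpy as np
import pandas as pd
import pytest

from clipmap.differential import DifferentialSite
from clipmap.integration import (
    category_concordance,
    evaluate_concordance,
    gene_set_enrichment,
    overlap_enrichment,
    predict_direction,
    signed_offset,
)
from clipmap.models import JointPeakCounts
from conftest import make_gene


def site(call, start, end, gene="g1", fdr=0.01, region="intron"):
    jp = JointPeakCounts(
        jp_id=f"jp_{start}", gene_id=gene, chrom="chr1", strand="+",
        start=start, end=end, region_class=region, m=40, n=20, M=80, N=160,
    )
    return DifferentialSite(jp, 50.0, 12.5, 4.0, 20, 1e-4, fdr, call)


class TestSignedOffset:
    @pytest.mark.parametrize(
        "pos,strand,expected",
        [
            (891, "+", -109),   # upstream on plus strand
            (1000, "+", 0),     # inside the exon
            (1320, "+", 121),   # downstream on plus strand
            (1320, "-", -121),  # same genomic side is upstream on minus
            (891, "-", 109),
        ],
    )
    def test_strand_aware_offsets(self, pos, strand, expected):
        assert signed_offset(pos, (1000, 1200), strand) == expected


class TestPredictDirection:
    def _gene(self):
        return make_gene(start=0, end=5000, tu_end=15_000, exons=[(1000, 1200)])

    def test_over_upstream_predicts_repression(self, cfg):
        # mirrors the Mtss1-style exemplar: stronger binding ~109 nt
        # upstream of the exon predicts lower inclusion
        s = site("over", 870, 912)  # center 891, offset -109
        pred = predict_direction(s, (1000, 1200), self._gene(), cfg)
        assert pred.predicted == "dI<0" and pred.offset == -109

    def test_over_downstream_predicts_activation(self, cfg):
        # Kcnc3-style: stronger binding ~121 nt downstream predicts inclusion
        s = site("over", 1300, 1341)
        pred = predict_direction(s, (1000, 1200), self._gene(), cfg)
        assert pred.predicted == "dI>0" and pred.offset == 121

    def test_under_flips_sign(self, cfg):
        s = site("under", 870, 912)
        assert predict_direction(s, (1000, 1200), self._gene(), cfg).predicted == "dI>0"

    def test_outside_hotspot_gives_none(self, cfg):
        s = site("over", 480, 520)  # center 500, offset -500
        assert predict_direction(s, (1000, 1200), self._gene(), cfg).predicted == "none"

    def test_gene_mismatch_errors(self, cfg):
        s = site("over", 870, 912, gene="other")
        with pytest.raises(ValueError):
            predict_direction(s, (1000, 1200), self._gene(), cfg)


class TestEvaluateConcordance:
    def _events(self, dis, fdrs):
        return pd.DataFrame(
            {"event_id": [f"e{i}" for i in range(len(dis))],
             "dI": dis, "fdr": fdrs}
        )

    def test_eight_of_nine(self, cfg):
        from clipmap.integration import RnaMapPrediction

        preds = [
            RnaMapPrediction(f"e{i}", f"jp{i}", "g", -100, "dI<0", 0.01)
            for i in range(9)
        ]
        dis = [-0.5] * 8 + [0.4]
        n, c, frac = evaluate_concordance(preds, self._events(dis, [0.01] * 9), cfg)
        assert (n, c) == (9, 8)
        assert frac == pytest.approx(8 / 9, abs=1e-9)

    def test_nonsignificant_events_excluded(self, cfg):
        from clipmap.integration import RnaMapPrediction

        preds = [RnaMapPrediction("e0", "jp", "g", -50, "dI<0", 0.01)]
        n, c, frac = evaluate_concordance(preds, self._events([-0.5], [0.5]), cfg)
        assert n == 0 and np.isnan(frac)


class TestOverlapEnrichment:
    def test_study_scale_counts(self):
        universe = [f"x{i}" for i in range(5418)]
        b = set(universe[:1620])
        a = set(universe[:281]) | set(universe[1620 : 1620 + 345])
        overlap, expected, p = overlap_enrichment(a, b, universe)
        assert overlap == 281
        assert expected == pytest.approx(626 * 1620 / 5418, rel=1e-12)
        assert expected == pytest.approx(187.2, abs=0.1)
        assert p < 2.2e-16

    def test_disjoint_sets_certain(self):
        u = set("abcdefgh")
        overlap, _, p = overlap_enrichment({"a", "b"}, {"c", "d"}, u)
        assert overlap == 0 and p == 1.0

    def test_monotone_in_overlap_at_fixed_margins(self):
        universe = [f"g{i}" for i in range(60)]
        b = set(universe[:20])
        prev = 1.1
        for k in range(0, 16):
            a = set(universe[:k]) | set(universe[20 : 20 + 15 - k])
            _, _, p = overlap_enrichment(a, b, universe)
            assert p <= prev + 1e-12
            prev = p

    def test_subset_validation(self):
        with pytest.raises(ValueError):
            overlap_enrichment({"z"}, {"a"}, {"a", "b"})


class TestGeneSetEnrichment:
    def test_target_set_itself_is_most_enriched(self):
        bg = {f"g{i}" for i in range(100)}
        targets = {f"g{i}" for i in range(10)}
        sets = {"self": set(targets), "random": {f"g{i}" for i in range(40, 80)}}
        table = gene_set_enrichment(targets, bg, sets)
        assert table.iloc[0]["set"] == "self"
        assert table.iloc[0]["fdr"] < 0.05

    def test_planted_overrepresentation_ranks_first(self):
        rng = np.random.default_rng(21)
        bg = [f"g{i}" for i in range(500)]
        planted = set(bg[:60])
        targets = set(bg[:30]) | set(rng.choice(bg[60:], size=30, replace=False))
        sets = {"planted": planted}
        for j in range(10):
            sets[f"rand{j}"] = set(rng.choice(bg, size=60, replace=False))
        table = gene_set_enrichment(targets, set(bg), sets)
        assert table.iloc[0]["set"] == "planted"

    def test_disjoint_set_skipped_and_empty_background_errors(self):
        table = gene_set_enrichment({"a"}, {"a", "b"}, {"off": {"z"}, "on": {"a"}})
        assert table["set"].tolist() == ["on"]
        with pytest.raises(ValueError):
            gene_set_enrichment(set(), set(), {"s": {"a"}})


class TestCategoryConcordance:
    def _enrichment(self, directions):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(directions))],
             "direction": directions}
        )

    def test_category_matching_global_split_is_null(self):
        directions = ["enriched"] * 30 + ["depleted"] * 30
        cats = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(60)],
             "category": ["A" if i % 2 else "B" for i in range(60)]}
        )
        # both categories carry exactly the global 50/50 split
        cats["category"] = ["A"] * 15 + ["B"] * 15 + ["A"] * 15 + ["B"] * 15
        table = category_concordance(cats, self._enrichment(directions))
        assert np.allclose(table["p_value"], 1.0)

    def test_marker_category_deviates(self):
        directions = ["enriched"] * 20 + ["depleted"] * 80
        cats = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(100)],
             "category": ["marker"] * 20 + ["rest"] * 80}
        )
        table = category_concordance(cats, self._enrichment(directions)).set_index("category")
        assert table.loc["marker", "fraction_enriched"] == 1.0
        assert table.loc["marker", "p_value"] < 1e-6

    def test_laminae_style_fraction(self):
        directions = ["enriched"] * 42 + ["depleted"] * 13
        cats = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(55)], "category": ["lamina_ix"] * 55}
        )
        table = category_concordance(cats, self._enrichment(directions))
        assert table["fraction_enriched"].iloc[0] == pytest.approx(42 / 55, abs=1e-12)
        assert table["fraction_enriched"].iloc[0] == pytest.approx(0.764, abs=0.001)

    def test_empty_category_gets_na(self):
        cats = pd.DataFrame({"gene_id": ["gX"], "category": ["empty"]})
        table = category_concordance(cats, self._enrichment(["enriched", "depleted"]))
        assert np.isnan(table.set_index("category").loc["empty", "p_value"])
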