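"""Cassette-exon and ALE quantification, Fisher tests, BH over expressed events."""

import numpy as np
import pandas as pd
import pytest

from clipmap.splicing import (
    multiple_testing_and_filters,
    quantify_ale,
    quantify_cassette,
    quantify_events,
)
from oracle_utils import fisher_two_sided_enumeration


def counts(event_id, kind, rows):
    """rows: (condition, replicate, inc1, inc2, skip)"""
    return pd.DataFrame(
        [
            {"event_id": event_id, "gene_id": "g1", "kind": kind,
             "condition": c, "replicate": r, "inc1": i1, "inc2": i2, "skip": e}
            for c, r, i1, i2, e in rows
        ]
    )


class TestCassette:
    def test_reference_event(self, cfg):
        df = counts("ev1", "cassette", [
            ("MN", 1, 30, 30, 10), ("WSC", 1, 10, 10, 30),
        ])
        ev = quantify_cassette(df, cfg)
        assert ev["psi_mn"] == pytest.approx(0.75)
        assert ev["psi_wsc"] == pytest.approx(0.25)
        assert ev["dI"] == pytest.approx(0.5)
        assert ev["p_value"] == pytest.approx(
            fisher_two_sided_enumeration(30, 10, 10, 30), rel=1e-9
        )
        assert ev["expressed"]

    def test_identical_counts_are_null(self, cfg):
        df = counts("ev1", "cassette", [
            ("MN", 1, 20, 20, 20), ("WSC", 1, 20, 20, 20),
        ])
        ev = quantify_cassette(df, cfg)
        assert ev["dI"] == 0.0 and ev["p_value"] == 1.0

    def test_coverage_exactly_ten_is_not_expressed(self, cfg):
        # "over 10" is strict: pooled coverage of exactly 10 fails
        df = counts("ev1", "cassette", [
            ("MN", 1, 5, 5, 5), ("WSC", 1, 40, 40, 40),
        ])
        ev = quantify_cassette(df, cfg)
        assert ev["coverage_mn"] == 10.0
        assert not ev["expressed"]

    def test_zero_coverage_condition_is_unexpressed(self, cfg):
        df = counts("ev1", "cassette", [
            ("MN", 1, 0, 0, 0), ("WSC", 1, 40, 40, 40),
        ])
        ev = quantify_cassette(df, cfg)
        assert not ev["expressed"] and np.isnan(ev["p_value"])

    def test_bc_consistency_is_replicate_sign_agreement(self, cfg):
        consistent = counts("ev1", "cassette", [
            ("MN", 1, 30, 30, 10), ("MN", 2, 28, 30, 12),
            ("WSC", 1, 10, 12, 30), ("WSC", 2, 9, 10, 31),
        ])
        assert quantify_cassette(consistent, cfg)["bc_consistent"]
        flipped = counts("ev2", "cassette", [
            ("MN", 1, 30, 30, 10), ("MN", 2, 5, 5, 30),
            ("WSC", 1, 10, 12, 30), ("WSC", 2, 30, 30, 10),
        ])
        assert not quantify_cassette(flipped, cfg)["bc_consistent"]


class TestAle:
    def test_usage_shift_like_terminal_exon_choice(self, cfg):
        # 65% vs 22% usage at coverage ~200 per condition
        df = counts("ale1", "ALE", [
            ("MN", 1, 130, 0, 70), ("WSC", 1, 44, 0, 156),
        ])
        ev = quantify_ale(df, cfg)
        assert ev["dI"] == pytest.approx(0.43, abs=1e-9)
        assert ev["p_value"] == pytest.approx(
            fisher_two_sided_enumeration(130, 70, 44, 156), rel=1e-9
        )
        assert ev["p_value"] < 1e-10

    def test_equal_usage_is_null(self, cfg):
        df = counts("ale1", "ALE", [
            ("MN", 1, 50, 0, 50), ("WSC", 1, 50, 0, 50),
        ])
        ev = quantify_ale(df, cfg)
        assert ev["dI"] == 0.0 and ev["p_value"] == 1.0

    def test_zero_counts_unexpressed(self, cfg):
        df = counts("ale1", "ALE", [("MN", 1, 0, 0, 0), ("WSC", 1, 30, 0, 40)])
        assert not quantify_ale(df, cfg)["expressed"]


class TestMultipleTesting:
    def test_single_expressed_event_fdr_equals_p(self, cfg):
        df = counts("ev1", "cassette", [("MN", 1, 30, 30, 10), ("WSC", 1, 10, 10, 30)])
        ev = multiple_testing_and_filters(quantify_events(df, cfg), cfg)
        assert ev["fdr"].iloc[0] == pytest.approx(ev["p_value"].iloc[0])

    def test_unexpressed_events_outside_bh_family(self, cfg):
        expressed = counts("a", "cassette", [("MN", 1, 30, 30, 10), ("WSC", 1, 10, 10, 30)])
        silent = counts("b", "cassette", [("MN", 1, 2, 2, 2), ("WSC", 1, 2, 2, 2)])
        ev = multiple_testing_and_filters(
            quantify_events(pd.concat([expressed, silent]), cfg), cfg
        )
        by_id = ev.set_index("event_id")
        assert np.isnan(by_id.loc["b", "fdr"])
        assert not by_id.loc["b", "significant"]

    def test_ale_needs_effect_size(self, cfg):
        # strong p but |dI| < 0.2 must not be called for ALE events
        df = counts("ale1", "ALE", [
            ("MN", 1, 5500, 0, 4500), ("WSC", 1, 4500, 0, 5500),
        ])
        ev = multiple_testing_and_filters(quantify_events(df, cfg), cfg)
        assert ev["p_value"].iloc[0] < 1e-6
        assert abs(ev["dI"].iloc[0]) < 0.2
        assert not ev["significant"].iloc[0]

    def test_null_events_rarely_called(self, cfg):
        rng = np.random.default_rng(12)
        frames = []
        for i in range(400):
            psi = rng.uniform(0.2, 0.8)
            rows = []
            for cond in ("MN", "WSC"):
                for rep in (1, 2):
                    cov = rng.poisson(50)
                    rows.append((cond, rep, rng.binomial(cov, psi),
                                 rng.binomial(cov, psi), rng.binomial(cov, 1 - psi)))
            frames.append(counts(f"ev{i}", "cassette", rows))
        ev = multiple_testing_and_filters(
            quantify_events(pd.concat(frames, ignore_index=True), cfg), cfg
        )
        assert ev["significant"].mean() <= cfg.splicing_fdr

    def test_condition_swap_negates_di_and_keeps_p(self, cfg):
        df = counts("ev1", "cassette", [
            ("MN", 1, 30, 28, 12), ("WSC", 1, 12, 14, 28),
        ])
        swapped = df.copy()
        swapped["condition"] = swapped["condition"].map({"MN": "WSC", "WSC": "MN"})
        a = quantify_cassette(df, cfg)
        b = quantify_cassette(swapped, cfg)
        assert a["dI"] == pytest.approx(-b["dI"])
        assert a["p_value"] == pytest.approx(b["p_value"], rel=1e-12)


class TestEstimatorProperties:
    def test_di_estimator_unbiased_at_coverage_100(self, cfg):
        from clipmap.synthetic import SimulationParams, SyntheticTruth, simulate_junction_counts

        rng = np.random.default_rng(5)
        n = 500
        psi_w = rng.uniform(0.2, 0.7, size=n)
        psi_m = np.clip(psi_w + rng.uniform(-0.3, 0.3, size=n), 0.05, 0.95)
        events = pd.DataFrame({
            "event_id": [f"e{i}" for i in range(n)],
            "gene_id": [f"g{i}" for i in range(n)],
            "kind": "cassette",
            "exon_start": 0, "exon_end": 100,
            "psi_wsc": psi_w, "psi_mn": psi_m, "coupled_site_id": "",
        })
        truth = SyntheticTruth(planted_sites=[], events=events,
                               artifact_anchors={}, gene_weights={})
        params = SimulationParams(seed=17, splicing_depth=50.0, n_rnaseq_reps=2)
        jc = simulate_junction_counts(truth, params)
        ev = quantify_events(jc, cfg).merge(
            events[["event_id", "psi_wsc", "psi_mn"]],
            on="event_id", suffixes=("", "_true"),
        )
        bias = ((ev["psi_mn"] - ev["psi_wsc"])
                - (ev["psi_mn_true"] - ev["psi_wsc_true"])).mean()
        assert abs(bias) <= 0.02

    def test_median_p_decreases_with_coverage(self, cfg):
        rng = np.random.default_rng(8)
        medians = []
        for depth in (15, 60, 240):
            ps = []
            for i in range(120):
                rows = []
                for cond, psi in (("MN", 0.6), ("WSC", 0.4)):
                    cov = rng.poisson(depth)
                    rows.append((cond, 1, rng.binomial(cov, psi),
                                 rng.binomial(cov, psi), rng.binomial(cov, 1 - psi)))
                ev = quantify_cassette(counts("e", "cassette", rows), cfg)
                if not np.isnan(ev["p_value"]):
                    ps.append(ev["p_value"])
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]
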