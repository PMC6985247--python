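"""Contingency-table enrichment statistics against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from _oracles import fisher_two_sided_exact, hypergeom_upper_tail_exact

from g4utr.enrichment_stats import (
    clinvar_density,
    clip_density,
    eqtl_direction_bias,
    eqtl_enrichment,
    fisher_result,
    knockdown_de_odds,
    merge_peaks,
    odds_ratio_ci,
    rbp_pg4_enrichment,
    rbp_target_overlap,
    select_lead_eqtls,
)
from g4utr.intervals import GenomeIntervals
from g4utr.synthetic_data import (
    SimulationConfig,
    simulate_direction_effects,
    simulate_knockdown_tables,
)


class TestFisherMachinery:
    def test_known_table(self):
        res = fisher_result([[30, 70], [10, 90]], "t")
        assert res.odds_ratio == pytest.approx(30 * 90 / (70 * 10), rel=1e-12)
        assert res.p_value == pytest.approx(fisher_two_sided_exact([[30, 70], [10, 90]]), rel=1e-9)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            t = rng.integers(0, 50, size=(2, 2))
            if t.sum() == 0:
                continue
            res = fisher_result(t, "t")
            assert res.p_value == pytest.approx(fisher_two_sided_exact(t.tolist()), rel=1e-9, abs=1e-12)

    def test_or_invariant_to_double_swap(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            t = rng.integers(1, 60, size=(2, 2))
            a = fisher_result(t, "t")
            swapped = t[::-1, ::-1]
            b = fisher_result(swapped, "t")
            assert a.odds_ratio == pytest.approx(b.odds_ratio)
            assert a.p_value == pytest.approx(b.p_value)

    def test_zero_cell_haldane(self):
        odds, lo, hi, flag = odds_ratio_ci([[0, 10], [5, 5]])
        assert flag and 0 < lo < odds < hi

    def test_ci_brackets_or(self):
        res = fisher_result([[20, 80], [10, 90]], "t")
        assert res.ci95[0] < res.odds_ratio < res.ci95[1]


class TestEqtlEnrichment:
    def _fixture(self):
        # pG4 = chr1 [0, 100); UTR = [0, 1000)
        pg4 = GenomeIntervals([("chr1", 0, 100)])
        utr = GenomeIntervals([("chr1", 0, 1000)])
        rows = []
        # 30 significant + 70 non in pG4; 10 + 90 in the rest
        pos = iter(range(2000))
        for n_sig, n_non, lo in ((30, 70, 0), (10, 90, 100)):
            for i in range(n_sig):
                rows.append({"chrom": "chr1", "pos": lo + i % (100 if lo == 0 else 900), "significant": True})
            for i in range(n_non):
                rows.append({"chrom": "chr1", "pos": lo + i % (100 if lo == 0 else 900), "significant": False})
        df = pd.DataFrame(rows)
        df["pos"] = np.arange(len(df)) % 100 + np.where(df.index < 100, 0, 100 + (np.arange(len(df)) % 900))
        # simpler deterministic positions: first 100 rows in [0,100), rest in [100,1000)
        df.loc[: 99, "pos"] = np.arange(100)
        df.loc[100:, "pos"] = 100 + np.arange(100)
        df["gene_id"] = "G0"
        df["tissue"] = "t0"
        df["p_value"] = np.where(df["significant"], 1e-8, 0.5)
        df["causal_candidate"] = False
        return df, pg4, utr

    def test_counts_and_or(self):
        df, pg4, utr = self._fixture()
        res = eqtl_enrichment(df, pg4, utr, "nominal")
        assert res.table.tolist() == [[30, 70], [10, 90]]
        assert res.odds_ratio == pytest.approx(3.857, abs=0.001)
        assert res.p_value == pytest.approx(fisher_two_sided_exact([[30, 70], [10, 90]]), rel=1e-9)

    def test_lead_selection_ties_by_coordinate(self):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [50, 10, 30],
                "gene_id": "G0",
                "tissue": "t0",
                "p_value": [1e-8, 1e-8, 1e-3],
                "significant": True,
            }
        )
        lead = select_lead_eqtls(df)
        assert lead["pos"].tolist() == [10]

    def test_direction_bias_null_and_planted(self):
        cfg = SimulationConfig()
        null = simulate_direction_effects(20000, 0.5, SimulationConfig(tract_pos_prob=0.5), seed=1)
        res0 = eqtl_direction_bias(null)
        assert res0.ci95[0] < 1.0 < res0.ci95[1]
        planted = simulate_direction_effects(20000, 0.5, cfg, seed=2)
        res1 = eqtl_direction_bias(planted)
        truth = (0.64 / 0.36) / 1.0
        assert res1.ci95[0] < truth < res1.ci95[1]
        assert res1.p_value < 1e-10


class TestClipDensity:
    def test_sixfold_arithmetic_fixture(self):
        pg4 = GenomeIntervals([("chr1", 0, 1000)])
        utr = GenomeIntervals([("chr1", 0, 2000)])
        peaks = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [0, 100, 200, 300, 400, 500, 1500],
                "end": [10, 110, 210, 310, 410, 510, 1510],
                "rbp_name": "X",
            }
        )
        res = clip_density(peaks, pg4, utr)
        assert res["n_peaks_pg4"] == 6 and res["n_peaks_non_pg4"] == 1
        assert res["fold"] == pytest.approx(6.0)

    def test_overlapping_peaks_merged(self):
        peaks = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 5, 100], "end": [10, 15, 110], "rbp_name": ["A", "B", "A"]}
        )
        merged = merge_peaks(peaks)
        assert merged[["start", "end"]].values.tolist() == [[0, 15], [100, 110]]

    def test_zero_length_class_rejected(self):
        pg4 = GenomeIntervals([("chr1", 0, 1000)])
        utr = GenomeIntervals([("chr1", 0, 1000)])  # non-pG4 class empty
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "rbp_name": ["X"]})
        with pytest.raises(ValueError):
            clip_density(peaks, pg4, utr)


class TestRbpEnrichment:
    def test_tail_sum_oracle(self):
        # population 1000 peaks / 100 pG4; RBP has 50 peaks, 20 pG4
        pg4 = GenomeIntervals([("chr1", 0, 1000)])
        rows = []
        # pG4-overlapping peaks live in [0,1000); others beyond
        k = 0
        for i in range(100):
            rows.append({"chrom": "chr1", "start": i * 10, "end": i * 10 + 5, "rbp_name": "RBP_A" if i < 20 else "other"})
        for i in range(900):
            rows.append({"chrom": "chr1", "start": 2000 + i * 10, "end": 2000 + i * 10 + 5, "rbp_name": "RBP_A" if i < 30 else "other"})
        peaks = pd.DataFrame(rows)
        out = rbp_pg4_enrichment(peaks, pg4)
        row = out[out["rbp_name"] == "RBP_A"].iloc[0]
        assert (row["n_peaks"], row["n_pg4_peaks"]) == (50, 20)
        assert row["p_value"] == pytest.approx(hypergeom_upper_tail_exact(20, 1000, 100, 50), rel=1e-9)

    def test_null_rbp_not_flagged(self):
        rng = np.random.default_rng(6)
        pg4 = GenomeIntervals([("chr1", 0, 1000)])
        rows = []
        for i in range(400):
            inside = rng.random() < 0.1
            s = int(rng.integers(0, 990)) if inside else int(rng.integers(2000, 5000))
            rows.append({"chrom": "chr1", "start": s, "end": s + 5, "rbp_name": str(rng.choice(["A", "B", "C", "D"]))})
        out = rbp_pg4_enrichment(pd.DataFrame(rows), pg4)
        assert not out["significant"].any()

    def test_target_overlap_extremes(self):
        universe = {f"g{i}" for i in range(200)}
        disjoint = {"A": {f"g{i}" for i in range(10)}, "B": {f"g{i}" for i in range(10, 20)}}
        mat = rbp_target_overlap(disjoint, universe)
        assert mat.loc["A", "B"] < 0.5  # p near 1 -> -log10 near 0
        same = {"A": {f"g{i}" for i in range(10)}, "B": {f"g{i}" for i in range(10)}}
        mat2 = rbp_target_overlap(same, universe)
        expect = -np.log10(hypergeom_upper_tail_exact(10, 200, 10, 10))
        assert mat2.loc["A", "B"] == pytest.approx(expect, rel=1e-9)
        assert mat2.loc["A", "B"] == mat2.loc["B", "A"]


class TestKnockdown:
    def test_planted_odds_and_direction(self):
        cfg = SimulationConfig(kd_multiplier=4.0)
        genes = [f"g{i}" for i in range(4000)]
        pg4 = {g for i, g in enumerate(genes) if i < 1500}
        tables = simulate_knockdown_tables(genes, pg4, cfg, seed=3, rbps=("UPF1", "DDX6"))
        out = knockdown_de_odds(tables, pg4, fdr_across=0.05)
        assert (out["odds_ratio"] > 2).all()
        assert out["significant"].all()
        assert (out["direction"] == -1).all()

    def test_null_or_near_one(self):
        cfg = SimulationConfig(kd_multiplier=1.0)
        genes = [f"g{i}" for i in range(3000)]
        pg4 = {g for i, g in enumerate(genes) if i < 1000}
        tables = simulate_knockdown_tables(genes, pg4, cfg, seed=4, rbps=("A",))
        out = knockdown_de_odds(tables, pg4)
        assert out["ci95_lo"].iloc[0] < 1.0 < out["ci95_hi"].iloc[0]


class TestClinvar:
    def test_filters_and_or(self):
        pg4 = GenomeIntervals([("chr1", 0, 100)])
        utr = GenomeIntervals([("chr1", 0, 1100)])
        variants = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [10, 20, 500, 600, 30, 40, 700],
                "span": [1, 1, 1, 1, 50, 1, 1],
                "gene_id": ["G0"] * 6 + ["G_not_disease"],
                "clnsig": [
                    "Uncertain_significance",
                    "Pathogenic",
                    "Uncertain_significance",
                    "Uncertain_significance",
                    "Uncertain_significance",  # span 50: excluded
                    "Benign",  # excluded
                    "Uncertain_significance",  # not a disease gene: excluded
                ],
            }
        )
        res = clinvar_density(variants, {"G0"}, pg4, utr)
        # 2 variants over 100 pG4 bases vs 2 over 1000 non-pG4 bases
        assert res.table.tolist() == [[2, 100], [2, 1000]]
        assert res.odds_ratio == pytest.approx(10.0)
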