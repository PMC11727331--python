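"""DE testing, thresholding, interaction/refinement rules, consensus."""

import numpy as np
import pandas as pd
import pytest

from rrqpop import gene_selection as gs
from rrqpop import synthetic


def de_frame(rows):
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])
    df["pvalue"] = df["padj"]
    df["direction"] = np.where(df["log2fc"] >= 0, "up", "down")
    return df


class TestSizeFactors:
    def test_equal_depth_near_one(self, rng):
        mu = np.exp(rng.normal(4, 1, 500))
        counts = pd.DataFrame(
            rng.poisson(mu[:, None], (500, 6)),
            columns=[f"s{i}" for i in range(6)])
        sf = gs.size_factors(counts)
        assert np.abs(sf - 1).max() < 0.1

    def test_depth_ratio_recovered(self, rng):
        mu = np.exp(rng.normal(5, 1, 800))
        c1 = rng.poisson(mu[:, None], (800, 3))
        c2 = rng.poisson(3 * mu[:, None], (800, 3))
        counts = pd.DataFrame(np.hstack([c1, c2]),
                              columns=[f"s{i}" for i in range(6)])
        sf = gs.size_factors(counts)
        ratio = sf.iloc[3:].mean() / sf.iloc[:3].mean()
        assert ratio == pytest.approx(3.0, rel=0.05)


class TestThreshold:
    def test_boundary_rules_strict(self):
        recs = de_frame([
            ("kept", 0.6, 0.05),
            ("lfc_at_boundary", 0.5, 0.05),
            ("padj_at_boundary", 0.6, 0.1),
            ("neg_kept", -0.7, 0.01),
        ])
        out = gs.threshold_de(recs)
        assert set(out["gene"]) == {"kept", "neg_kept"}

    def test_summary_bookkeeping(self):
        recs = de_frame([(f"u{i}", 1.0, 0.01) for i in range(362)]
                        + [(f"d{i}", -1.0, 0.01) for i in range(783)])
        up, down, total = gs.de_summary(recs)
        assert (up, down, total) == (362, 783, 1145)


class TestInteraction:
    def test_opposite_direction_rule(self):
        rr = de_frame([("a", 1.0, 0.01), ("b", 1.0, 0.01),
                       ("c", -1.0, 0.01)])
        kd = de_frame([("a", -1.0, 0.01), ("b", 1.0, 0.01),
                       ("c", 1.0, 0.01), ("d", -2.0, 0.01)])
        out = gs.interaction_genes(rr, kd)
        assert out == {"a", "c"}  # opposite in both; "b" same direction


class TestRefine:
    @staticmethod
    def _toy_counts(delta_wt, delta_rr, base=100.0):
        samples = pd.DataFrame({
            "sample": [f"s{i}" for i in range(8)],
            "cell_line": "L1",
            "phenotype": ["WT"] * 4 + ["RR"] * 4,
            "knockdown": ["siNC", "siNC", "siHDAC6", "siHDAC6"] * 2,
            "replicate": [1, 2] * 4,
        }).set_index("sample")
        vals = np.array([base, base, base * delta_wt, base * delta_wt,
                         base, base, base * delta_rr, base * delta_rr])
        # steady housekeeping genes so median-of-ratios size factors are ~1
        hk = np.tile(np.linspace(200, 2000, 10)[:, None], (1, 8))
        counts = pd.DataFrame(
            np.vstack([vals, hk]).astype(int),
            index=["g"] + [f"hk{i}" for i in range(10)],
            columns=samples.index)
        return counts, samples

    def test_fourfold_stronger_rr_response_retained(self):
        counts, samples = self._toy_counts(delta_wt=1.0, delta_rr=4.0)
        kept, trace = gs.refine_by_magnitude(
            counts, samples, {"g"}, "L1", {"g": "up"})
        assert kept == {"g"}
        # pseudocount shifts the ratio slightly below log2(4) = 2
        assert trace.loc[0, "log2_ratio"] == pytest.approx(2.0, abs=0.05)

    def test_equal_response_dropped(self):
        counts, samples = self._toy_counts(delta_wt=3.0, delta_rr=3.0)
        kept, trace = gs.refine_by_magnitude(
            counts, samples, {"g"}, "L1", {"g": "up"})
        assert kept == set()
        assert trace.loc[0, "log2_ratio"] == pytest.approx(0.0, abs=0.05)

    def test_wt_only_response_dropped(self):
        counts, samples = self._toy_counts(delta_wt=4.0, delta_rr=1.0)
        kept, trace = gs.refine_by_magnitude(
            counts, samples, {"g"}, "L1", {"g": "up"})
        assert kept == set()
        assert trace.loc[0, "log2_ratio"] < 0

    def test_missing_group_rejected(self):
        counts, samples = self._toy_counts(1.0, 4.0)
        with pytest.raises(ValueError, match="missing group"):
            gs.refine_by_magnitude(counts[samples.index[:6]],
                                   samples.iloc[:6], {"g"}, "L1",
                                   {"g": "up"})


class TestConsensus:
    def test_study_percentages(self):
        """238 candidates -> 100 (42.0%) / 54 (22.7%) / 24 (10.1%) shared."""
        universe = [f"g{i}" for i in range(238)]
        shared = set(universe[:24])
        fadu = shared | set(universe[24:100])
        hk1 = shared | set(universe[100:130])
        panel, summary = gs.consensus({"FaDu": fadu, "HK1": hk1}, 238)
        assert panel == shared
        tab = summary.set_index("stage")
        assert tab.loc["retained_FaDu", "pct"] == 42.0
        assert tab.loc["retained_HK1", "pct"] == 22.7
        assert tab.loc["consensus", "pct"] == 10.1

    def test_disjoint_and_identical(self):
        p1, _ = gs.consensus({"a": {"x"}, "b": {"y"}}, 10)
        assert p1 == set()
        p2, _ = gs.consensus({"a": {"x", "y"}, "b": {"x", "y"}}, 10)
        assert p2 == {"x", "y"}


class TestDifferentialExpression:
    def test_null_type_one_error_calibrated(self):
        """Raw p < 0.05 rate within [0.03, 0.07] for null NB genes."""
        truth = synthetic.CountTruth(
            seed=11, genes=[f"G{i}" for i in range(5000)],
            cell_lines=("FaDu", "HK1"),
            baseline=np.exp(np.random.default_rng(11).normal(np.log(100),
                                                             1.5, 5000)),
            dispersion=np.exp(np.random.default_rng(12).normal(np.log(0.05),
                                                               0.3, 5000)),
            rr_lfc={"FaDu": np.zeros(5000), "HK1": np.zeros(5000)},
            kd_lfc={"FaDu": np.zeros(5000), "HK1": np.zeros(5000)},
        )
        counts, samples = synthetic.gen_counts(truth)
        de = gs.differential_expression(counts, samples, "RRvsWT")
        rate = (de["pvalue"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_on_planted_effects(self):
        """Planted |log2FC|=2 genes at dispersion 0.05 detected >= 90%."""
        n = 2000
        rng = np.random.default_rng(5)
        rr = np.zeros(n)
        rr[:100] = 2.0 * np.where(np.arange(100) % 2 == 0, 1, -1)
        truth = synthetic.CountTruth(
            seed=5, genes=[f"G{i}" for i in range(n)],
            cell_lines=("FaDu", "HK1"),
            baseline=np.exp(rng.normal(np.log(200), 1.0, n)),
            dispersion=np.full(n, 0.05),
            rr_lfc={"FaDu": rr, "HK1": rr},
            kd_lfc={"FaDu": np.zeros(n), "HK1": np.zeros(n)},
            rr_up={f"G{i}" for i in range(100) if i % 2 == 0},
            rr_down={f"G{i}" for i in range(100) if i % 2 == 1},
        )
        counts, samples = synthetic.gen_counts(truth)
        de = gs.differential_expression(counts, samples, "RRvsWT")
        hits = gs.threshold_de(de, lfc_min=0.5, alpha=0.1)
        power = len(set(hits["gene"]) & {f"G{i}" for i in range(100)}) / 100
        assert power >= 0.9

    def test_unknown_contrast(self):
        truth = synthetic.default_count_truth(seed=0, n_genes=50,
                                              n_consensus=2,
                                              n_line_specific=(2, 2),
                                              n_rr_only=2,
                                              n_same_direction=2)
        counts, samples = synthetic.gen_counts(truth)
        with pytest.raises(ValueError, match="unknown contrast"):
            gs.differential_expression(counts, samples, "bogus")


class TestCascade:
    def test_recovery_and_trace_chain(self):
        truth = synthetic.default_count_truth(seed=1)
        counts, samples = synthetic.gen_counts(truth)
        res = gs.run_cascade(counts, samples)
        panel = res["panel"]
        sens = len(panel & truth.consensus) / len(truth.consensus)
        assert sens >= 0.9
        assert len(panel - truth.consensus) <= 3
        tr = res["trace"]
        lines = sorted(truth.cell_lines)
        refined_both = tr[[f"refined_{ln}" for ln in lines]].all(axis=1)
        assert (tr["consensus"] <= refined_both).all()
        for ln in lines:
            assert (tr[f"refined_{ln}"] <= tr["opposite_direction"]).all()
        assert (tr["opposite_direction"]
                <= (tr["de_rr"] & tr["de_sihdac6"])).all()

    def test_external_de_tables_bypass(self):
        truth = synthetic.default_count_truth(seed=2, n_genes=300,
                                              n_consensus=4,
                                              n_line_specific=(4, 4),
                                              n_rr_only=4,
                                              n_same_direction=4)
        counts, samples = synthetic.gen_counts(truth)
        auto = gs.run_cascade(counts, samples)
        manual = gs.run_cascade(counts, samples, de_rr=auto["de_rr"],
                                de_sihdac6=auto["de_sihdac6"])
        assert manual["panel"] == auto["panel"]
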