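"""Generator contracts: determinism, planted truth, distributional sanity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rrqpop import qpop, synthetic
from rrqpop.design import build_oacd


class TestDeterminism:
    def test_all_generators_reproducible(self, truth):
        d = build_oacd(12)
        ct = synthetic.default_count_truth(seed=3, n_genes=400,
                                           n_consensus=4,
                                           n_line_specific=(4, 4),
                                           n_rr_only=4, n_same_direction=4)
        st = synthetic.default_survival_truth(seed=3)
        pairs = [
            (synthetic.gen_dose_response(truth),
             synthetic.gen_dose_response(truth)),
            (synthetic.gen_screen_viability(truth, d),
             synthetic.gen_screen_viability(truth, d)),
            (synthetic.gen_counts(ct)[0], synthetic.gen_counts(ct)[0]),
            (synthetic.gen_survival(st), synthetic.gen_survival(st)),
        ]
        for a, b in pairs:
            pd.testing.assert_frame_equal(a, b)
        np.testing.assert_array_equal(
            synthetic.gen_bliss_matrix("planted", seed=5),
            synthetic.gen_bliss_matrix("planted", seed=5))
        pd.testing.assert_frame_equal(
            synthetic.gen_clonogenic(seed=5), synthetic.gen_clonogenic(seed=5))


class TestDoseResponse:
    def test_default_ladder_span(self):
        d = synthetic.DEFAULT_DOSE_LADDER
        assert d[0] == pytest.approx(1e-4)
        assert d[-1] == pytest.approx(100.0)
        assert np.allclose(np.diff(np.log10(d)), np.diff(np.log10(d))[0])

    def test_noiseless_on_curve_midpoint(self):
        spec = synthetic.default_truth(seed=0, noise_sd=0.0)
        spec.dr_params.loc["drug01", ["hill", "ic50_uM"]] = [1.0, 1.0]
        tab = synthetic.gen_dose_response(spec, doses=np.array([1.0]),
                                          replicates=1)
        v = tab.loc[tab["drug"] == "drug01", "viability"].iloc[0]
        assert v == pytest.approx(0.5)

    def test_empty_doses_rejected(self, truth):
        with pytest.raises(ValueError, match="empty"):
            synthetic.gen_dose_response(truth, doses=np.array([]))


class TestScreen:
    def test_noiseless_equals_truth_predictions(self, noiseless_truth):
        d = build_oacd(12)
        tab = synthetic.gen_screen_viability(noiseless_truth, d, replicates=1)
        pred = qpop.build_model_matrix(d.levels) @ \
            noiseless_truth.surface_truth.coef
        np.testing.assert_allclose(tab["viability"].values, pred, atol=1e-12)

    def test_replicate_structure(self, truth):
        d = build_oacd(12)
        tab = synthetic.gen_screen_viability(truth, d, replicates=2)
        assert len(tab) == 2 * 155
        assert set(tab["replicate"]) == {1, 2}

    def test_antagonistic_pair_raises_joint_viability(self):
        spec = synthetic.default_truth(seed=4, noise_sd=0.0, planted_sign=+1)
        m = spec.surface_truth
        p, q, sign = spec.planted_pairs[0]
        assert sign == +1
        x_pair = np.full(12, -1.0)
        x_pair[[p, q]] = 1.0
        x_p = np.full(12, -1.0)
        x_p[p] = 1.0
        x_q = np.full(12, -1.0)
        x_q[q] = 1.0
        x_0 = np.full(12, -1.0)
        joint = qpop.predict_viability(m, x_pair)
        additive = (qpop.predict_viability(m, x_p)
                    + qpop.predict_viability(m, x_q)
                    - qpop.predict_viability(m, x_0))
        assert joint > additive


class TestClonogenic:
    def test_dose_zero_expectation(self):
        tabs = [synthetic.gen_clonogenic(plated=500, pe0=0.5, seed=s,
                                         replicates=1)
                for s in range(200)]
        zero = np.mean([t.loc[t["dose_Gy"] == 0, "colonies"].iloc[0]
                        for t in tabs])
        assert zero == pytest.approx(250, rel=0.05)

    def test_lq_truth_at_two_gray(self):
        sf = np.exp(-(0.3 * 2 + 0.03 * 4))
        assert sf == pytest.approx(np.exp(-0.72))
        tabs = [synthetic.gen_clonogenic(b1=0.3, b2=0.03, plated=2000,
                                         pe0=0.5, seed=s, replicates=1)
                for s in range(100)]
        two = np.mean([t.loc[t["dose_Gy"] == 2, "colonies"].iloc[0]
                       for t in tabs])
        assert two == pytest.approx(2000 * 0.5 * sf, rel=0.05)

    def test_default_ladder(self):
        tab = synthetic.gen_clonogenic(seed=0, replicates=1)
        assert tab["dose_Gy"].tolist() == [0, 1, 2, 4]


class TestCounts:
    def test_design_shape(self):
        ct = synthetic.default_count_truth(seed=0, n_genes=200,
                                           n_consensus=4,
                                           n_line_specific=(4, 4),
                                           n_rr_only=4, n_same_direction=4)
        counts, samples = synthetic.gen_counts(ct, n_per_group=3)
        assert counts.shape == (200, 24)
        groups = samples.groupby(["cell_line", "phenotype",
                                  "knockdown"]).size()
        assert len(groups) == 8 and (groups == 3).all()

    def test_planted_fold_change_recovered(self):
        n = 50
        rr = np.zeros(n)
        rr[0] = 2.0  # 4x in RR-siNC vs WT-siNC
        ct = synthetic.CountTruth(
            seed=8, genes=[f"G{i}" for i in range(n)],
            cell_lines=("FaDu", "HK1"),
            baseline=np.full(n, 500.0), dispersion=np.full(n, 0.05),
            rr_lfc={"FaDu": rr, "HK1": rr},
            kd_lfc={"FaDu": np.zeros(n), "HK1": np.zeros(n)},
            rr_up={"G0"},
        )
        counts, samples = synthetic.gen_counts(ct, n_per_group=40)
        sel_rr = samples.index[(samples.phenotype == "RR")
                               & (samples.knockdown == "siNC")]
        sel_wt = samples.index[(samples.phenotype == "WT")
                               & (samples.knockdown == "siNC")]
        ratio = counts.loc["G0", sel_rr].mean() / counts.loc["G0",
                                                             sel_wt].mean()
        assert ratio == pytest.approx(4.0, rel=0.15)
        null_ratio = counts.loc["G1", sel_rr].mean() / counts.loc[
            "G1", sel_wt].mean()
        assert null_ratio == pytest.approx(1.0, rel=0.15)

    def test_nb_moments_consistent(self):
        """Sample mean/variance at n=1000 match NB(mean, dispersion)."""
        n = 5
        ct = synthetic.CountTruth(
            seed=9, genes=[f"G{i}" for i in range(n)],
            cell_lines=("A", "B"),
            baseline=np.full(n, 200.0), dispersion=np.full(n, 0.1),
            rr_lfc={"A": np.zeros(n), "B": np.zeros(n)},
            kd_lfc={"A": np.zeros(n), "B": np.zeros(n)},
        )
        rng = np.random.default_rng(9)
        # library-size factors add log-normal(0, 0.2) spread; emulate the
        # generator's marginal distribution directly at large n
        nbn = 1 / 0.1
        draws = np.array([
            rng.negative_binomial(nbn, nbn / (nbn + 200.0 * np.exp(
                rng.normal(0, 0.2)))) for _ in range(1000)])
        counts, samples = synthetic.gen_counts(ct, n_per_group=250)
        sel = samples.index[(samples.cell_line == "A")
                            & (samples.phenotype == "WT")
                            & (samples.knockdown == "siNC")]
        obs = counts.loc["G0", sel].to_numpy(dtype=float)
        res = stats.ks_2samp(obs, draws)
        assert res.pvalue > 0.01

    def test_truth_label_bookkeeping(self):
        ct = synthetic.default_count_truth(seed=0)
        assert len(ct.consensus) == 24
        assert ct.consensus <= ct.sihdac6_responsive
        assert ct.rr_up.isdisjoint(ct.rr_down)
        assert ct.sihdac6_responsive <= (ct.rr_up | ct.rr_down)
        sets = ct.truth_sets()
        assert sorted(ct.consensus) == sets["consensus"]

    def test_single_replicate_refused(self):
        ct = synthetic.default_count_truth(seed=0, n_genes=100,
                                           n_consensus=2,
                                           n_line_specific=(2, 2),
                                           n_rr_only=2, n_same_direction=2)
        with pytest.raises(ValueError, match="2 replicates"):
            synthetic.gen_counts(ct, n_per_group=1)


class TestSurvival:
    def test_cohort_sizes(self):
        for n in (261, 158):
            st = synthetic.default_survival_truth(seed=0, n_patients=n)
            assert len(synthetic.gen_survival(st)) == n

    def test_null_logrank_p_uniform(self):
        """beta=0 -> median-split groups indistinguishable."""
        from rrqpop import prognostic as prog
        ps = []
        for seed in range(40):
            st = synthetic.default_survival_truth(seed=seed, hr=1.0)
            coh = synthetic.gen_survival(st)
            model = prog.SignatureModel(
                genes=[c for c in coh.columns if c.startswith(("T", "S",
                                                               "H"))])
            _, groups = prog.signature_score(
                coh[model.genes], model)
            out = prog.km_logrank(coh["time"], coh["event"], groups)
            ps.append(out["logrank_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_bliss_matrix_contract(self):
        M = synthetic.gen_bliss_matrix("null", noise_sd=0.0, seed=0)
        assert M.shape == (5, 5)
        assert M[0, 0] == 0.0
        with pytest.raises(ValueError, match="2x2"):
            synthetic.gen_bliss_matrix("null", shape=(1, 5))
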