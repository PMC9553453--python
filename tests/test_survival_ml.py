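import numpy as np
import pandas as pd
import pytest

from lrxtalk.errors import ConfigError
from lrxtalk import survival_ml as sml
from lrxtalk import synthetic_data as sd


class TestKMCurve:
    def test_all_censored_survival_one(self):
        c = sml.km_curve([1, 2, 3], [0, 0, 0])
        assert c.times.size == 0
        assert c.survival_at(10) == 1.0

    def test_two_events_by_hand(self):
        c = sml.km_curve([1, 2], [1, 1])
        np.testing.assert_allclose(c.survival, [0.5, 0.0])
        np.testing.assert_array_equal(c.at_risk, [2, 1])

    def test_time_scale_equivariance(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        c1 = sml.km_curve(t, e)
        c2 = sml.km_curve(2 * t, e)
        np.testing.assert_allclose(c1.survival, c2.survival)
        np.testing.assert_allclose(2 * c1.times, c2.times)

    def test_empty_errors(self):
        with pytest.raises(ConfigError):
            sml.km_curve([], [])

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        if e.sum() == 0:
            e[0] = 1
        c = sml.km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(c.times, c.survival):
            ref = float(kmf.survival_function_at_times(ti).iloc[0])
            assert si == pytest.approx(ref, abs=1e-9)

    def test_pooled_curve_conserves_events(self, rng):
        # pooled risk counts and event counts equal the subgroup sums
        t = rng.exponential(10, 60)
        e = np.ones(60, dtype=int)
        half = 30
        pooled = sml.km_curve(t, e)
        a = sml.km_curve(t[:half], e[:half])
        b = sml.km_curve(t[half:], e[half:])
        assert pooled.n_events.sum() == a.n_events.sum() + b.n_events.sum()
        t0 = pooled.times[0]
        assert pooled.at_risk[0] == (t >= t0).sum()


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 0]
        chi2, p = sml.logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_four_events(self):
        chi2, p = sml.logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(2.8824, abs=5e-5)
        assert p == pytest.approx(0.0896, abs=5e-4)

    def test_label_swap_symmetry(self, rng):
        ta, tb = rng.exponential(5, 30), rng.exponential(8, 25)
        ea, eb = rng.integers(0, 2, 30), rng.integers(0, 2, 25)
        s1 = sml.logrank_test(ta, ea, tb, eb)
        s2 = sml.logrank_test(tb, eb, ta, ea)
        assert s1[0] == pytest.approx(s2[0], abs=1e-10)

    def test_no_events_warning_path(self):
        chi2, p = sml.logrank_test([1, 2], [0, 0], [3], [0])
        assert (chi2, p) == (0.0, 1.0)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta, tb = rng.exponential(5, 40), rng.exponential(8, 35)
        ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 35)
        chi2, p = sml.logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)


def _cohort(beta, n=400, n_genes=30, n_prog=5, seed=0):
    cfg = sd.SimConfig(
        n_genes=n_genes, n_bulk_samples=n,
        n_de_lr_pairs_up=1, n_de_lr_pairs_down=1, n_marker_genes_per_type=1,
        n_prognostic_genes=n_prog, prognostic_beta=beta, seed=seed,
    )
    _, _, truth = sd.generate_sc_cohort(cfg)
    bulk, surv = sd.generate_bulk_cohort(cfg, truth)
    return truth, bulk, surv


class TestPrognosticScreen:
    def test_constant_gene_degenerate(self):
        truth, bulk, surv = _cohort(beta=0.5, seed=1)
        bulk = bulk.copy()
        bulk["FLAT"] = 1.0
        out = sml.prognostic_screen(bulk, surv, ["FLAT"])
        assert np.isnan(out.iloc[0]["logrank_p"])
        assert not out.iloc[0]["prognostic"]

    def test_planted_beta1_power(self):
        hits = trials = 0
        for seed in range(10):
            truth, bulk, surv = _cohort(beta=1.0, n=400, seed=40 + seed)
            genes = list(truth.prognostic_genes["gene"])
            out = sml.prognostic_screen(bulk, surv, genes)
            hits += int(out["prognostic"].sum())
            trials += len(genes)
        assert hits / trials >= 0.9

    def test_null_beta_type_I(self):
        flags = trials = 0
        for seed in range(8):
            truth, bulk, surv = _cohort(beta=0.0, n=300, n_genes=80, n_prog=20,
                                        seed=60 + seed)
            genes = list(truth.prognostic_genes["gene"])
            out = sml.prognostic_screen(bulk, surv, genes)
            flags += int(out["prognostic"].sum())
            trials += len(genes)
        rate = flags / trials
        assert rate == pytest.approx(0.05, abs=0.04)

    def test_alpha_zero_returns_nothing(self):
        truth, bulk, surv = _cohort(beta=1.0, seed=2)
        out = sml.prognostic_screen(bulk, surv, list(truth.prognostic_genes["gene"]),
                                    alpha=0.0)
        assert not out["prognostic"].any()

    def test_fdr_mode_subset_of_raw(self):
        truth, bulk, surv = _cohort(beta=0.7, n_genes=60, n_prog=15, seed=3)
        genes = list(truth.prognostic_genes["gene"])
        raw = sml.prognostic_screen(bulk, surv, genes, fdr=False)
        adj = sml.prognostic_screen(bulk, surv, genes, fdr=True)
        assert set(adj.loc[adj["prognostic"], "gene"]) <= set(
            raw.loc[raw["prognostic"], "gene"]
        )


class TestRiskModel:
    def test_strong_signal_metrics(self):
        truth, bulk, surv = _cohort(beta=1.5, n=450, n_genes=60, n_prog=20, seed=8)
        genes = list(truth.prognostic_genes["gene"])
        model = sml.train_risk_model(bulk, surv, genes, seed=0)
        assert model.precision >= 0.8 and model.recall >= 0.8

    def test_chance_baseline(self):
        truth, bulk, surv = _cohort(beta=0.0, n=450, n_genes=60, n_prog=20, seed=9)
        genes = list(truth.prognostic_genes["gene"])
        model = sml.train_risk_model(bulk, surv, genes, seed=0)
        prevalence = surv["stage"].isin(["III", "IV"]).mean()
        assert model.precision == pytest.approx(prevalence, abs=0.25)

    def test_seed_determinism(self):
        truth, bulk, surv = _cohort(beta=1.0, n=300, n_genes=40, n_prog=10, seed=10)
        genes = list(truth.prognostic_genes["gene"])
        m1 = sml.train_risk_model(bulk, surv, genes, seed=4)
        m2 = sml.train_risk_model(bulk, surv, genes, seed=4)
        assert (m1.precision, m1.recall) == (m2.precision, m2.recall)

    def test_split_ratio_recorded(self):
        truth, bulk, surv = _cohort(beta=1.0, n=300, n_genes=40, n_prog=10, seed=11)
        genes = list(truth.prognostic_genes["gene"])
        model = sml.train_risk_model(bulk, surv, genes, seed=0)
        assert model.realized_ratio == pytest.approx(2.0, abs=0.2)

    def test_missing_feature_gene_errors(self):
        truth, bulk, surv = _cohort(beta=1.0, seed=12)
        with pytest.raises(ConfigError):
            sml.train_risk_model(bulk, surv, ["NOPE"], seed=0)


class TestValidation:
    def test_transfer_to_matched_cohort(self):
        truth, bulk, surv = _cohort(beta=1.5, n=450, n_genes=60, n_prog=20, seed=13)
        genes = list(truth.prognostic_genes["gene"])
        model = sml.train_risk_model(bulk, surv, genes, seed=0)
        # external cohort with the same planted effects
        cfg_ext = sd.SimConfig(
            n_genes=60, n_bulk_samples=400,
            n_de_lr_pairs_up=1, n_de_lr_pairs_down=1, n_marker_genes_per_type=1,
            n_prognostic_genes=20, prognostic_beta=1.5, seed=14,
        )
        _, _, truth_ext = sd.generate_sc_cohort(cfg_ext)
        # reuse the training truth so the same genes carry the signal
        bulk_ext, surv_ext = sd.generate_bulk_cohort(cfg_ext, truth)
        curves, p = sml.validate_risk_model(model, bulk_ext, surv_ext)
        assert set(curves) == {"high", "low"}
        assert p is not None and p < 0.05

    def test_permuted_labels_null(self, rng):
        truth, bulk, surv = _cohort(beta=0.0, n=300, n_genes=40, n_prog=10, seed=15)
        genes = list(truth.prognostic_genes["gene"])
        model = sml.train_risk_model(bulk, surv, genes, seed=0)
        _, p = sml.validate_risk_model(model, bulk, surv)
        if p is not None:
            assert p > 0.001  # no real signal; should almost never be tiny

    def test_missing_genes_imputed(self):
        truth, bulk, surv = _cohort(beta=1.5, n=450, n_genes=60, n_prog=20, seed=16)
        genes = list(truth.prognostic_genes["gene"])
        model = sml.train_risk_model(bulk, surv, genes, seed=0)
        bulk_missing = bulk.drop(columns=genes[:2])
        pred = model.predict_high_risk(bulk_missing)
        assert pred.isin([0, 1]).all()
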