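import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opncircuit.errors import UndefinedR2Error
from opncircuit.severity import (MSSSReference, apply_model_to_group_b,
                                 classify_patient_group, cohort_statistics,
                                 compute_msss, evaluate_feature_sets,
                                 fit_severity_glm, make_folds,
                                 severity_indices, simulate_cohort_patients,
                                 simulate_patient)
from opncircuit.synthetic import (GeneratorConfig, generate_severity)

from .conftest import cohort_in_nm
from .oracles import msss_brute_force


def ref_from_values(values, year=5):
    return MSSSReference(pd.DataFrame({"duration_years": year,
                                       "edss": values}))


class TestMSSS:
    def test_full_tie_bin_gives_five(self):
        assert compute_msss(ref_from_values([2.0, 2.0, 2.0]), 5.0, 2.0) == 5.0

    def test_mixed_bin_examples(self):
        ref = ref_from_values([1.0, 2.0, 2.0, 4.0])
        assert compute_msss(ref, 5.0, 2.0) == pytest.approx(5.0)
        assert compute_msss(ref, 5.0, 4.0) == pytest.approx(7.5)

    def test_query_below_all_corner(self):
        for n in (1, 4, 9):
            ref = ref_from_values([5.0] * n)
            assert compute_msss(ref, 5.0, 0.0) == pytest.approx(10.0 / (n + 2))

    def test_agrees_with_rank_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            n = int(rng.integers(1, 40))
            bin_vals = np.round(rng.uniform(0, 20, n)) / 2.0
            edss = float(np.round(rng.uniform(0, 20)) / 2.0)
            ref = ref_from_values(list(bin_vals))
            assert compute_msss(ref, 5.0, edss) == pytest.approx(
                msss_brute_force(bin_vals, edss))

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=25),
           st.integers(0, 19))
    def test_monotone_in_edss_and_strictly_inside_range(self, raw, q):
        bin_vals = [v / 2.0 for v in raw]
        ref = ref_from_values(bin_vals)
        lo = compute_msss(ref, 5.0, q / 2.0)
        hi = compute_msss(ref, 5.0, (q + 1) / 2.0)
        assert 0.0 < lo <= hi < 10.0


class TestSeverityIndices:
    def test_examples(self):
        assert severity_indices(5.0, 5.0) == (0.0, 0.0)
        assert severity_indices(5.0, 3.0) == (2.0, 10.0)
        assert severity_indices(3.0, 5.0) == (-2.0, -6.0)

    @settings(deadline=None, max_examples=40)
    @given(st.floats(0, 10), st.floats(0, 10))
    def test_delta_antisymmetric_under_phase_swap(self, a, b):
        d1, _ = severity_indices(a, b)
        d2, _ = severity_indices(b, a)
        assert d1 == -d2


class TestClassification:
    @staticmethod
    def records(opn_rem, opn_rel, prot_rem, prot_rel):
        return pd.DataFrame({
            "patient_id": "P", "phase": ["remission", "relapse"],
            "opn_nm": [opn_rem, opn_rel], "prot_nm": [prot_rem, prot_rel]})

    def test_expected_pattern_is_group_a(self):
        assert classify_patient_group(self.records(40, 120, 100, 50)) == "A"

    def test_decreasing_opn_is_group_b(self):
        assert classify_patient_group(self.records(120, 40, 50, 100)) == "B"

    def test_ties_are_group_b(self):
        assert classify_patient_group(self.records(40, 40, 100, 50)) == "B"

    def test_missing_phase_rejected(self):
        rec = self.records(40, 120, 100, 50).iloc[:1]
        with pytest.raises(ValueError):
            classify_patient_group(rec)


class TestSimulatePatient:
    def test_remission_features_equal_measurements(self, gen_config,
                                                   true_kinetics):
        coh = cohort_in_nm(gen_config)
        pid = coh[coh.patient_id == "P010"]
        feats = simulate_patient(pid, true_kinetics)
        means = pid.groupby("phase")[["opn_nm", "prot_nm"]].mean()
        opn_tot_rem = (feats["opn_f_rem"] + feats["opn_n_rem"]
                       + feats["opn_c_rem"])
        assert opn_tot_rem == pytest.approx(
            means.loc["remission", "opn_nm"], rel=1e-6)
        assert feats["prot_rem"] == pytest.approx(
            means.loc["remission", "prot_nm"], rel=1e-6)

    def test_group_a_relapse_opn_exceeds_remission(self, gen_config,
                                                   true_kinetics):
        feats = simulate_cohort_patients(cohort_in_nm(gen_config),
                                         true_kinetics)
        a = feats[feats.group == "A"]
        assert len(a) > 0
        for ph in ("opn_f", "opn_n", "opn_c"):
            assert (a[f"{ph}_rel"] >= a[f"{ph}_rem"] - 1e-12).all()

    def test_group_b_flagged_with_raw_features(self, gen_config,
                                               true_kinetics):
        feats = simulate_cohort_patients(cohort_in_nm(gen_config),
                                         true_kinetics)
        b = feats[feats.group == "B"]
        assert len(b) > 0
        assert (~b.derivable).all()
        assert np.isfinite(b[["prot_rem", "frag_i_rel"]].to_numpy(float)).all()


class TestSeverityGLM:
    @staticmethod
    def planted(n=50, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = pd.Series(X.to_numpy() @ np.array([1, -2, 0.5, 0, 1, 3.0])
                      + noise * rng.normal(size=n))
        return X, y

    def test_noiseless_recovery(self):
        X, y = self.planted()
        assert fit_severity_glm(X, y, seed=1).cv_r2 > 0.99

    def test_permuted_outcome_has_no_skill(self):
        X, y = self.planted()
        for seed in range(20):
            yp = pd.Series(np.random.default_rng(seed).permutation(y))
            assert fit_severity_glm(X, yp, seed=seed).cv_r2 < 0.2

    def test_fold_clamping_equals_leave_one_out(self):
        X, y = self.planted(n=6)
        a = fit_severity_glm(X, y, k_folds=10, seed=3)
        b = fit_severity_glm(X, y, k_folds=6, seed=3)
        assert len(a.folds) == 6
        assert a.cv_r2 == pytest.approx(b.cv_r2)

    def test_duplicated_features_do_not_change_r2(self):
        X, y = self.planted(noise=0.3)
        X2 = X.copy()
        X2["f0_dup"] = X2["f0"]
        r1 = fit_severity_glm(X, y, seed=2).cv_r2
        r2 = fit_severity_glm(X2, y, seed=2).cv_r2
        assert r2 == pytest.approx(r1, abs=1e-6)

    def test_single_feature_equals_simple_regression(self):
        X, y = self.planted(noise=0.5)
        fit = fit_severity_glm(X, y, feature_names=["f0"], seed=4)
        folds = fit.folds
        y_oof = np.empty(len(y))
        for tr, te in folds:
            x_tr = X["f0"].to_numpy()[tr]
            slope, icept = np.polyfit(x_tr, y.to_numpy()[tr], 1)
            y_oof[te] = slope * X["f0"].to_numpy()[te] + icept
        ref = 1 - np.sum((y - y_oof) ** 2) / np.sum((y - y.mean()) ** 2)
        assert fit.cv_r2 == pytest.approx(ref)

    def test_constant_outcome_rejected(self):
        X, _ = self.planted()
        with pytest.raises(UndefinedR2Error):
            fit_severity_glm(X, pd.Series(np.ones(len(X))), seed=0)


class TestFeatureSets:
    def test_planted_prot_frag_signal_ordering(self, true_kinetics):
        cfg = GeneratorConfig(seed=7, n_patients=50, group_b_fraction=0.0,
                              severity_noise_sd=0.0)
        feats = simulate_cohort_patients(cohort_in_nm(cfg), true_kinetics)
        sev, _ = generate_severity(feats, cfg)
        sev = sev.set_index("patient_id")
        r2 = evaluate_feature_sets(
            feats, sev[["msss_relapse", "delta_msss", "msss_prime"]], seed=3)
        piv = r2.pivot(index="feature_set", columns="outcome", values="cv_r2")
        for outcome in piv.columns:
            assert piv.loc["prot_frag", outcome] >= piv[outcome].max() - 1e-9
            assert piv.loc["opn_only", outcome] == piv[outcome].min()
            assert piv.loc["prot_frag", outcome] > 0.9


class TestGroupB:
    def test_empty_group_b_gives_empty_table(self):
        X, y = TestSeverityGLM.planted()
        fit = fit_severity_glm(X, y, seed=0)
        out = apply_model_to_group_b(fit, X.iloc[:0])
        assert out.empty

    def test_planted_discrepancy_detected(self, true_kinetics):
        """Group-B patients with inverted dynamics predict far off the
        group-A model: median |residual| exceeds the group-A CV residual."""
        cfg = GeneratorConfig(seed=19, n_patients=40, group_b_fraction=0.25,
                              severity_noise_sd=0.05)
        feats = simulate_cohort_patients(cohort_in_nm(cfg), true_kinetics)
        sev, _ = generate_severity(feats, cfg)
        sev = sev.set_index("patient_id").loc[feats.index]
        a = feats[feats.group == "A"]
        b = feats[feats.group == "B"]
        cols = ["prot_rem", "prot_rel", "frag_s_rem", "frag_s_rel",
                "frag_i_rem", "frag_i_rel"]
        fit = fit_severity_glm(a, sev.loc[a.index, "msss_prime"],
                               feature_names=cols, seed=1)
        y_oof = np.empty(len(a))
        X = a[cols].to_numpy(float)
        from sklearn.linear_model import LinearRegression
        for tr, te in fit.folds:
            y_oof[te] = LinearRegression().fit(
                X[tr], sev.loc[a.index, "msss_prime"].to_numpy()[tr]
            ).predict(X[te])
        cv_resid = np.median(np.abs(
            sev.loc[a.index, "msss_prime"].to_numpy() - y_oof))
        pred_b = apply_model_to_group_b(fit, b,
                                        sev.loc[b.index, "msss_prime"])
        assert np.median(np.abs(pred_b["residual"])) > cv_resid


class TestCohortStatistics:
    def test_no_phase_difference_gives_null_statistic(self):
        rows = []
        rng = np.random.default_rng(0)
        for k in range(6):
            opn = rng.uniform(0.5, 2.0)
            prot = rng.uniform(0.5, 2.0)
            for ph in ("remission", "relapse"):
                rows.append({"patient_id": f"P{k}", "phase": ph,
                             "opn_nm": opn + 0.1 * (ph == "relapse"),
                             "prot_nm": prot})
        cs = cohort_statistics(pd.DataFrame(rows), n_boot=50, seed=0)
        assert cs.wilcoxon_statistic == 0.0
        assert cs.wilcoxon_p == 1.0

    def test_exact_inverse_relation(self):
        rng = np.random.default_rng(1)
        opn = rng.uniform(0.5, 3.0, 24)
        prot = 1.0 / (0.3 + 0.8 * opn)
        df = pd.DataFrame({"patient_id": [f"P{i // 2}" for i in range(24)],
                           "phase": ["remission", "relapse"] * 12,
                           "opn_nm": opn, "prot_nm": prot})
        cs = cohort_statistics(df, n_boot=200, seed=2)
        assert cs.correlation == pytest.approx(1.0)
        assert cs.boot_ci_low == pytest.approx(1.0)
        assert cs.boot_ci_high == pytest.approx(1.0)

    def test_bootstrap_ci_is_deterministic(self, default_cohort):
        a = cohort_statistics(default_cohort, seed=5)
        b = cohort_statistics(default_cohort, seed=5)
        assert (a.boot_ci_low, a.boot_ci_high) == (b.boot_ci_low,
                                                   b.boot_ci_high)


def test_make_folds_deterministic():
    assert [(list(a), list(b)) for a, b in make_folds(20, 5, seed=3)] == \
           [(list(a), list(b)) for a, b in make_folds(20, 5, seed=3)]
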