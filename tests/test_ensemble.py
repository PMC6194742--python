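import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidens.ensemble import (
    StabilityProfile,
    bootstrap_lasso,
    choose_freq_cut,
    fit_case_control_lm,
    intersect_criteria,
    rf_importance,
    selection_loop,
)
from lipidens.preprocess import normalize
from lipidens.synthetic import CohortDesign, NoiseModel, PlantedEffect, generate_cohort

from conftest import paired_samples


class TestCaseControlLm:
    def test_matches_two_sample_t_test(self):
        # caco-only reduction equals the classical equal-variance t-test
        rng = np.random.default_rng(7)
        samples = paired_samples(15)
        vals = rng.normal(size=30) + 0.8 * (samples["caco"] == "case").to_numpy()
        logm = pd.DataFrame([vals], index=["f1"], columns=samples.index)
        fit = fit_case_control_lm(logm, samples, covariates=())
        a = vals[(samples["caco"] == "case").to_numpy()]
        b = vals[(samples["caco"] == "control").to_numpy()]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert fit.table.loc["f1", "p_value"] == pytest.approx(p, abs=1e-10)
        assert fit.table.loc["f1", "t"] == pytest.approx(t, abs=1e-10)

    def test_identical_case_control_gives_zero_beta(self):
        samples = paired_samples(6)
        base = np.arange(6, dtype=float) + 4.0
        vals = np.repeat(base, 2)  # case == control per pair
        logm = pd.DataFrame([vals], index=["f1"], columns=samples.index)
        fit = fit_case_control_lm(logm, samples, covariates=("age", "gender"))
        assert fit.table.loc["f1", "beta_caco"] == pytest.approx(0.0, abs=1e-12)
        assert fit.table.loc["f1", "fold_change"] == pytest.approx(1.0, abs=1e-12)

    def test_planted_causal_ranks_top_percent(self):
        # beta0=1.0, sd=0.3: the planted feature lands in the top 1% of 2000
        hits = 0
        for seed in range(20):
            design = CohortDesign(n_pairs=66, p_features=2000, seed=seed)
            table, samples, truth = generate_cohort(
                design,
                [PlantedEffect(0, "causal", beta0=1.0)],
                NoiseModel(residual_sd=0.3),
            )
            study = samples[samples["role"] == "study"]
            logm = np.log(table.intensities[study.index])
            fit = fit_case_control_lm(logm, samples)
            planted = truth.index[truth.effect_type == "causal"][0]
            if fit.table.loc[planted, "p_rank"] <= np.ceil(0.01 * 2000):
                hits += 1
        assert hits >= 19

    def test_constant_covariate_dropped_with_warning(self):
        samples = paired_samples(6)  # single batch, no gel
        rng = np.random.default_rng(0)
        logm = pd.DataFrame([rng.normal(size=12)], index=["f1"], columns=samples.index)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_case_control_lm(logm, samples)
        assert "gel" not in fit.covariates and "batch" not in fit.covariates

    def test_too_few_samples_raises(self):
        samples = paired_samples(2)
        logm = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["f1"], columns=samples.index)
        with pytest.raises(ValueError, match="too few samples"):
            fit_case_control_lm(logm, samples, covariates=("age", "gender"))


class TestBootstrapLasso:
    def _cohort_matrix(self, n_pairs=20, p=8, signal=None, seed=0):
        rng = np.random.default_rng(seed)
        samples = paired_samples(n_pairs, seed=seed)
        X = rng.normal(size=(p, 2 * n_pairs))
        if signal is not None:
            caco = (samples["caco"] == "case").to_numpy()
            X[0] = np.where(caco, signal, -signal) + 0.05 * rng.normal(size=2 * n_pairs)
        return pd.DataFrame(X, index=[f"f{i}" for i in range(p)], columns=samples.index), samples

    def test_separating_feature_frequency_near_one(self):
        norm, samples = self._cohort_matrix(signal=2.0)
        prof = bootstrap_lasso(norm, samples, B=40, grid_size=12, seed=1)
        assert prof.summary.loc["f0"] >= 0.95

    def test_all_zero_at_huge_penalty(self):
        norm, samples = self._cohort_matrix(signal=2.0)
        grid = np.array([1e3, 9e2])  # far above any data-derived lambda max
        prof = bootstrap_lasso(norm, samples, B=10, grid=grid, seed=1, window_trim=0.0)
        assert (prof.frequencies.to_numpy() == 0).all()

    def test_reproducible_given_seed(self):
        norm, samples = self._cohort_matrix(signal=1.0, seed=3)
        a = bootstrap_lasso(norm, samples, B=15, grid_size=10, seed=9)
        b = bootstrap_lasso(norm, samples, B=15, grid_size=10, seed=9)
        pd.testing.assert_frame_equal(a.frequencies, b.frequencies)

    def test_sample_order_invariance(self):
        norm, samples = self._cohort_matrix(signal=1.5, seed=4)
        perm = np.random.default_rng(0).permutation(norm.columns)
        a = bootstrap_lasso(norm, samples, B=20, grid_size=10, seed=2)
        b = bootstrap_lasso(norm[perm], samples, B=20, grid_size=10, seed=2)
        pd.testing.assert_series_equal(a.summary, b.summary)

    def test_bad_grid_rejected(self):
        norm, samples = self._cohort_matrix()
        with pytest.raises(ValueError):
            bootstrap_lasso(norm, samples, B=5, grid=np.array([0.1, 0.5]), seed=0)
        with pytest.raises(ValueError):
            bootstrap_lasso(norm, samples, B=0, seed=0)

    def test_age_gender_are_candidates(self):
        norm, samples = self._cohort_matrix()
        prof = bootstrap_lasso(norm, samples, B=5, grid_size=8, seed=0)
        assert "age" in prof.summary.index and "gender" in prof.summary.index
        assert "age" not in prof.retained.index  # retained covers features only


class TestChooseFreqCut:
    def _profile(self, freqs):
        s = pd.Series(freqs)
        return StabilityProfile(
            penalties=np.array([1.0]),
            frequencies=pd.DataFrame({0: s}),
            summary=s,
            retained=s >= 0.1,
            freq_cut=0.1,
            window=(0, 1),
            n_boot=10,
        )

    def test_single_dominant_gap(self):
        cut = choose_freq_cut(self._profile({"a": 0.9, "b": 0.85, "c": 0.8, "d": 0.02, "e": 0.01}))
        assert 0.02 < cut <= 0.8

    def test_no_gap_falls_back(self):
        cut = choose_freq_cut(self._profile({"a": 0.5, "b": 0.5, "c": 0.5}))
        assert cut == 0.10

    def test_separates_planted_signals(self):
        design = CohortDesign(n_pairs=66, p_features=200, seed=6)
        effects = [PlantedEffect(i, "causal", beta0=1.5 if i % 2 else -1.5) for i in range(5)]
        table, samples, truth = generate_cohort(design, effects, NoiseModel(residual_sd=0.4))
        _, norm, _ = normalize(table, samples)
        prof = bootstrap_lasso(norm, samples, B=60, grid_size=25, seed=6)
        cut = choose_freq_cut(prof)
        planted = truth.index[truth.effect_type != "null"]
        nulls = truth.index[truth.effect_type == "null"]
        assert (prof.feature_summary.loc[planted] >= cut).all()
        assert (prof.feature_summary.loc[nulls] < cut).mean() >= 0.99


class TestRfImportance:
    def test_separating_feature_ranks_first(self):
        rng = np.random.default_rng(2)
        samples = paired_samples(20, seed=2)
        caco = (samples["caco"] == "case").to_numpy()
        rows = {f"f{i}": rng.normal(size=40) for i in range(10)}
        rows["f0"] = np.where(caco, 1.5, -1.5) + 0.1 * rng.normal(size=40)
        norm = pd.DataFrame(rows).T.set_axis(samples.index, axis=1)
        imp = rf_importance(norm, samples, n_trees=100, seed=0)
        feature_imp = imp.drop(index=["age", "gender"])
        assert feature_imp.idxmax() == "f0"

    def test_pure_noise_importances_small(self):
        rng = np.random.default_rng(3)
        samples = paired_samples(15, seed=3)
        norm = pd.DataFrame(
            rng.normal(size=(30, 30)),
            index=[f"f{i}" for i in range(30)],
            columns=samples.index,
        )
        imp = rf_importance(norm, samples, n_trees=150, seed=1).drop(index=["age", "gender"])
        # no feature dominates: all importances stay within a narrow null band
        assert imp.abs().max() < 0.05

    def test_impurity_variant(self):
        rng = np.random.default_rng(4)
        samples = paired_samples(10, seed=4)
        norm = pd.DataFrame(
            rng.normal(size=(5, 20)), index=[f"f{i}" for i in range(5)], columns=samples.index
        )
        imp = rf_importance(norm, samples, n_trees=20, seed=0, importance="impurity")
        assert (imp >= 0).all()

    def test_bad_args(self):
        samples = paired_samples(5)
        norm = pd.DataFrame(np.ones((2, 10)), index=["a", "b"], columns=samples.index)
        with pytest.raises(ValueError):
            rf_importance(norm, samples, n_trees=0)
        with pytest.raises(ValueError):
            rf_importance(norm, samples, importance="magic")


class TestIntersectCriteria:
    def _inputs(self, p_values, freqs, imps):
        ids = list(p_values)
        fit_table = pd.DataFrame(
            {
                "p_value": pd.Series(p_values),
                "beta_caco": 0.0,
                "se": 1.0,
                "t": 0.0,
                "q_value": 1.0,
                "fold_change": 1.0,
            }
        )
        fit_table["p_rank"] = fit_table["p_value"].rank(method="min").astype(int)
        from lipidens.ensemble import CaseControlModelFit

        fit = CaseControlModelFit(table=fit_table, n_samples=10, dof=8, covariates=())
        s = pd.Series(freqs)
        prof = StabilityProfile(
            penalties=np.array([1.0]),
            frequencies=pd.DataFrame({0: s}),
            summary=s,
            retained=s >= 0.1,
            freq_cut=0.1,
            window=(0, 1),
            n_boot=10,
        )
        return fit, prof, pd.Series(imps)

    def test_set_intersection(self):
        # lm passes {a,b,c}, lasso {b,c,d}, rf {c} -> selected {c}
        fit, prof, imp = self._inputs(
            {"a": 0.001, "b": 0.002, "c": 0.003, "d": 0.9, "e": 0.91, "f": 0.92},
            {"a": 0.0, "b": 0.5, "c": 0.5, "d": 0.5, "e": 0.0, "f": 0.0},
            {"a": 0.01, "b": 0.02, "c": 1.0, "d": 0.03, "e": 0.5, "f": 0.4},
        )
        prof.retained = prof.summary >= 0.1
        sel = intersect_criteria(fit, prof, imp, top_frac=0.5)
        assert sel.selected_features == ["c"]

    def test_exclusion_dominates(self):
        fit, prof, imp = self._inputs(
            {"a": 0.001, "b": 0.9}, {"a": 0.5, "b": 0.0}, {"a": 1.0, "b": 0.0}
        )
        sel = intersect_criteria(fit, prof, imp, top_frac=0.5, exclusions={"a"})
        assert sel.selected_features == []
        assert bool(sel.table.loc["a", "excluded"])

    def test_mismatched_feature_sets_raise(self):
        fit, prof, imp = self._inputs({"a": 0.5}, {"a": 0.5}, {"a": 0.5})
        imp = pd.Series({"zz": 1.0})
        with pytest.raises(ValueError, match="feature sets"):
            intersect_criteria(fit, prof, imp)

    def test_monotone_in_top_frac(self):
        rng = np.random.default_rng(0)
        ids = [f"f{i}" for i in range(40)]
        fit, prof, imp = self._inputs(
            dict(zip(ids, rng.random(40))),
            dict(zip(ids, rng.random(40))),
            dict(zip(ids, rng.random(40))),
        )
        wide = set(intersect_criteria(fit, prof, imp, top_frac=0.5).selected_features)
        narrow = set(intersect_criteria(fit, prof, imp, top_frac=0.1).selected_features)
        assert narrow <= wide


class TestSelectionLoop:
    def _runner(self, candidates):
        def run(exclusions):
            table = pd.DataFrame(index=pd.Index(candidates, name="feature_id"))
            table["selected"] = [f not in exclusions for f in candidates]
            from lipidens.ensemble import SelectionProfile

            return SelectionProfile(table=table, top_frac=0.01, n_top=1)

        return run

    def test_no_flags_single_iteration(self):
        prof = selection_loop(self._runner(["a", "b"]), [])
        assert prof.iterations == 1
        assert prof.selected_features == ["a", "b"]

    def test_flagged_feature_removed(self):
        prof = selection_loop(self._runner(["a", "b"]), ["a"])
        assert prof.selected_features == ["b"]
        assert prof.iterations == 2

    def test_all_flagged_terminates_empty(self):
        prof = selection_loop(self._runner(["a", "b"]), ["a", "b"])
        assert prof.selected_features == []


class TestRecovery:
    def test_strong_planted_effects_recovered(self):
        # end-to-end criteria intersection on a scaled-down cohort with
        # strong planted effects: high sensitivity, high precision
        sens_list, prec_list = [], []
        for seed in range(3):
            design = CohortDesign(n_pairs=40, p_features=400, seed=seed)
            effects = [
                PlantedEffect(i * 80 + 3, "causal", beta0=1.2 if i % 2 else -1.2)
                for i in range(4)
            ]
            table, samples, truth = generate_cohort(design, effects, NoiseModel(residual_sd=0.4))
            _, norm, _ = normalize(table, samples)
            study = samples[samples["role"] == "study"]
            raw = np.log(table.intensities[study.index])
            lm = fit_case_control_lm(raw, samples)
            stab = bootstrap_lasso(norm, samples, B=40, grid_size=20, seed=seed)
            imp = rf_importance(norm, samples, n_trees=150, seed=seed)
            prof = intersect_criteria(lm, stab, imp)
            sel = set(prof.selected_features)
            planted = set(truth.index[truth.effect_type != "null"])
            sens_list.append(len(sel & planted) / len(planted))
            prec_list.append(len(sel & planted) / max(1, len(sel)))
        assert np.mean(sens_list) >= 0.75
        assert np.mean(prec_list) >= 0.75
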