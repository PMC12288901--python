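import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from neosep import (
    BiomarkerTable,
    FeatureSpec,
    SampleTable,
    SyntheticConfig,
    ValidationError,
    classify_presumed,
    delivery_sum_score,
    exclude_outliers,
    fit_logistic,
    flag_biomarker_outliers,
    generate_cohort,
    pca_embed,
    permutation_variable_importance,
    prune_correlated,
    rf_protocol,
)
from neosep.modeling import build_feature_frame, logistic_comparison

from conftest import tiny_sample_df

SMALL_GRID = {"n_estimators": [50], "criterion": ["gini"],
              "max_depth": [4], "min_samples_leaf": [2]}


def _biomarkers_for(samples, rng=None, separation=4.0):
    rng = rng or np.random.default_rng(0)
    rows = []
    for r in samples.infants().itertuples():
        shift = separation if r.group in ("EOS",) else 0.0
        rows.append(dict(infant_id=r.infant_id, group=r.group,
                         crp=10 ** (rng.normal(-3 + shift / 4, 0.3)),
                         saa=10 ** (rng.normal(-2.7 + shift / 2, 0.3)),
                         lbp=10 ** (rng.normal(-2.3 + shift / 4, 0.3))))
    return BiomarkerTable(pd.DataFrame(rows))


class TestDeliverySumScore:
    @pytest.mark.parametrize("route,labor,expected", [
        ("cesarean", False, 0), ("cesarean", True, 1),
        ("vaginal", False, 1), ("vaginal", True, 2)])
    def test_score(self, route, labor, expected):
        assert delivery_sum_score([route], [labor])[0] == expected


class TestLogistic:
    def _cohort(self, n_eos=2, n_ctl=2):
        rows = ([dict(sample_id=f"E{i}", group="EOS", gestational_age=30.0)
                 for i in range(n_eos)]
                + [dict(sample_id=f"C{i}") for i in range(n_ctl)])
        return SampleTable(tiny_sample_df(rows))

    def test_intercept_only_null_likelihood(self):
        # constant covariate reduces to intercept-only: lnL = 4 ln(0.5),
        # AIC = 2k - 2 lnL = 2 + 8 ln 2 with k = 1
        samples = self._cohort()
        biomarkers = _biomarkers_for(samples, separation=0.0)
        res = fit_logistic(FeatureSpec(biomarkers=(), clinical=("prom",)),
                           samples, biomarkers)
        assert res.llf == pytest.approx(4 * np.log(0.5))
        assert res.aic == pytest.approx(2 + 8 * np.log(2))

    def test_single_class_outcome_rejected(self):
        rows = [dict(sample_id=f"C{i}") for i in range(4)]
        samples = SampleTable(tiny_sample_df(rows))
        with pytest.raises(ValidationError):
            fit_logistic(FeatureSpec(biomarkers=(), clinical=("prom",)),
                         samples, _biomarkers_for(samples))

    def test_perfect_separation_flagged(self):
        samples = self._cohort(n_eos=6, n_ctl=6)
        biomarkers = _biomarkers_for(samples, separation=12.0)
        res = fit_logistic(FeatureSpec(biomarkers=("saa",), clinical=()),
                           samples, biomarkers)
        assert res.separation
        assert np.isnan(res.aic)

    def test_comparison_table_ranks_biomarkers_first(self, default_cohort):
        _, samples, biomarkers, _ = default_cohort
        table = logistic_comparison(samples, biomarkers)
        table = table[~table["separation"]]
        best_bio = table.loc[table["model"].str.contains("saa|crp|lbp"),
                             "aic"].min()
        base = table.loc[table["model"] == "base (sex + GA)", "aic"].iloc[0]
        assert best_bio < base


class TestPruneCorrelated:
    def _samples(self, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        rows = []
        for i in range(60):
            eos = i < 15
            a = bool(rng.random() < (0.7 if eos else 0.2))
            rows.append(dict(sample_id=f"S{i}", group="EOS" if eos else "control",
                             gestational_age=30.0 if eos else 34.0,
                             chorioamnionitis=a, prom=a, preeclampsia=a,
                             multiple_gestation=bool(rng.random() < 0.1)))
        return SampleTable(tiny_sample_df(rows))

    def test_identical_variables_collapse_to_one(self):
        samples = self._samples()
        spec = FeatureSpec(biomarkers=(),
                           clinical=("chorioamnionitis", "prom"))
        pruned = prune_correlated(spec, samples, _biomarkers_for(samples))
        assert len(pruned.clinical) == 1

    def test_uncorrelated_variables_untouched(self):
        samples = self._samples()
        spec = FeatureSpec(biomarkers=(),
                           clinical=("chorioamnionitis", "multiple_gestation"))
        pruned = prune_correlated(spec, samples, _biomarkers_for(samples))
        assert set(pruned.clinical) == set(spec.clinical)

    def test_chain_of_three_leaves_one_survivor(self):
        samples = self._samples()
        spec = FeatureSpec(biomarkers=(),
                           clinical=("chorioamnionitis", "prom", "preeclampsia"))
        pruned = prune_correlated(spec, samples, _biomarkers_for(samples))
        assert len(pruned.clinical) == 1


class TestRFProtocol:
    def test_separable_features_score_highly(self):
        cfg = SyntheticConfig(n_eos=14, n_control=60, n_ps=2, n_proteins=10,
                              seed=31)
        _, samples, _, _ = generate_cohort(cfg)
        # constructed, cleanly separable marker concentrations
        biomarkers = _biomarkers_for(samples, np.random.default_rng(31),
                                     separation=6.0)
        ev = rf_protocol(FeatureSpec(), samples, biomarkers, grid=SMALL_GRID,
                         seed=1)
        mm = ev.mean_metrics()
        assert mm["recall"] >= 0.95
        assert mm["precision"] >= 0.95
        assert len(ev.runs) == 10
        assert ((ev.runs[["precision", "recall", "roc_auc", "f1"]] >= 0)
                & (ev.runs[["precision", "recall", "roc_auc", "f1"]] <= 1)
                ).all().all()

    def test_label_shuffled_features_are_uninformative(self):
        aucs = []
        for seed in range(3):
            cfg = SyntheticConfig(n_eos=14, n_control=60, n_ps=2, n_proteins=10,
                                  seed=100 + seed)
            _, samples, biomarkers, _ = generate_cohort(cfg)
            # break the label-feature link: shuffle biomarker rows
            rng = np.random.default_rng(seed)
            df = biomarkers.df.copy()
            df[["crp", "saa", "lbp"]] = df[["crp", "saa", "lbp"]].sample(
                frac=1.0, random_state=seed).to_numpy()
            shuffled = BiomarkerTable(df)
            ev = rf_protocol(FeatureSpec(clinical=()), samples, shuffled,
                             grid=SMALL_GRID, seed=seed)
            aucs.append(ev.mean_metrics()["roc_auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_same_seed_reproduces_evaluation(self):
        cfg = SyntheticConfig(n_eos=10, n_control=40, n_ps=2, n_proteins=10,
                              seed=17)
        _, samples, biomarkers, _ = generate_cohort(cfg)
        a = rf_protocol(FeatureSpec(), samples, biomarkers, grid=SMALL_GRID,
                        n_runs=4, seed=3)
        b = rf_protocol(FeatureSpec(), samples, biomarkers, grid=SMALL_GRID,
                        n_runs=4, seed=3)
        pd.testing.assert_frame_equal(a.runs, b.runs)
        pd.testing.assert_frame_equal(a.importances, b.importances)


class TestPermutationImportance:
    def _fitted(self, rng):
        X = pd.DataFrame({"signal": np.r_[rng.normal(2, 1, 40),
                                          rng.normal(-2, 1, 40)],
                          "noise": rng.normal(size=80),
                          "constant": np.ones(80)})
        y = np.r_[np.ones(40), np.zeros(40)]
        model = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        return model, X, y

    def test_constant_feature_importance_exactly_zero(self):
        model, X, y = self._fitted(np.random.default_rng(2))
        imp = permutation_variable_importance(model, X, y, seed=1)
        assert imp.set_index("variable").loc["constant", "importance_mean"] == 0.0

    def test_noise_feature_importance_near_zero(self):
        model, X, y = self._fitted(np.random.default_rng(3))
        imp = permutation_variable_importance(model, X, y, seed=2)
        byvar = imp.set_index("variable")["importance_mean"]
        assert abs(byvar["noise"]) < 0.05
        assert byvar["signal"] > byvar["noise"]


class TestOutliers:
    def test_exclusion_reduces_eos_count(self, default_cohort):
        _, samples, _, _ = default_cohort
        eos_ids = samples.infants().query("group == 'EOS'")["infant_id"].tolist()
        out = exclude_outliers(samples, eos_ids[:3])
        assert (out.infants()["group"] == "EOS").sum() == 11

    def test_empty_list_is_identity(self, default_cohort):
        _, samples, _, _ = default_cohort
        out = exclude_outliers(samples, [])
        assert len(out.df) == len(samples.df)

    def test_unknown_id_rejected(self, default_cohort):
        _, samples, _, _ = default_cohort
        with pytest.raises(ValidationError):
            exclude_outliers(samples, ["NOPE"])

    def test_center_of_reference_flagged_extremes_not(self):
        rng = np.random.default_rng(5)
        rows = [dict(infant_id=f"C{i}", group="control",
                     crp=10 ** rng.normal(-3, 0.4),
                     saa=10 ** rng.normal(-2.7, 0.4),
                     lbp=10 ** rng.normal(-2.3, 0.4)) for i in range(100)]
        rows.append(dict(infant_id="E_mid", group="EOS",
                         crp=10 ** -3.0, saa=10 ** -2.7, lbp=10 ** -2.3))
        rows.append(dict(infant_id="E_far", group="EOS",
                         crp=10 ** 1.0, saa=10 ** 1.3, lbp=10 ** 1.7))
        flagged, _ = flag_biomarker_outliers(BiomarkerTable(pd.DataFrame(rows)))
        assert flagged == ["E_mid"]

    def test_planted_outliers_recovered(self):
        hits = 0
        for seed in range(4):
            cfg = SyntheticConfig(n_outlier_eos=3, n_proteins=10, n_ps=2,
                                  seed=200 + seed)
            _, _, biomarkers, truth = generate_cohort(cfg)
            flagged, _ = flag_biomarker_outliers(biomarkers)
            hits += flagged == sorted(truth.outlier_infants)
        assert hits >= 3


class TestPCA:
    def test_collinear_points_have_rank_one_spectrum(self):
        t = np.linspace(0, 1, 30)
        X = np.c_[t, 2 * t]
        scores, evr = pca_embed(X)
        assert evr[0] == pytest.approx(1.0)
        assert evr.sum() <= 1.0 + 1e-12

    def test_rotation_invariance_of_spectrum(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        _, evr_a = pca_embed(X, n_components=4)
        _, evr_b = pca_embed(X @ q, n_components=4)
        np.testing.assert_allclose(evr_a, evr_b, atol=1e-10)

    def test_missing_entries_rejected(self):
        with pytest.raises(ValidationError):
            pca_embed(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestClassifyPresumed:
    def test_memorized_ps_infant_predicted_eos(self):
        cfg = SyntheticConfig(n_eos=10, n_control=40, n_ps=5, n_proteins=10,
                              seed=41)
        _, samples, biomarkers, _ = generate_cohort(cfg)
        # make one PS infant an exact copy of an EOS training infant
        df = biomarkers.df.copy()
        sdf = samples.df.copy()
        eos_row = df[df.group == "EOS"].iloc[0]
        ps_id = df.loc[df.group == "PS", "infant_id"].iloc[0]
        df.loc[df.infant_id == ps_id, ["crp", "saa", "lbp"]] = \
            eos_row[["crp", "saa", "lbp"]].to_numpy()
        eos_meta = sdf[sdf.infant_id == eos_row["infant_id"]].iloc[0]
        for col in ("gestational_age", "sex", "chorioamnionitis", "prom",
                    "preeclampsia", "multiple_gestation", "delivery_route",
                    "labor", "plasma_protein_conc"):
            sdf.loc[sdf.infant_id == ps_id, col] = eos_meta[col]
        result = classify_presumed(
            SampleTable(sdf), BiomarkerTable(df), FeatureSpec(),
            hyperparameters=dict(n_estimators=100, max_depth=5,
                                 min_samples_leaf=2, criterion="gini"),
            seed=3)
        pred = result.predictions.set_index("infant_id")
        assert pred.loc[ps_id, "predicted_group"] == "EOS"
        assert set(result.pca_scores["label"]) <= {
            "EOS", "control", "PS-pEOS", "PS-pControl"}

    def test_feature_frame_mismatch_rejected(self, default_cohort):
        _, samples, biomarkers, _ = default_cohort
        missing = BiomarkerTable(
            biomarkers.df[biomarkers.df.group != "PS"].reset_index(drop=True))
        with pytest.raises(ValidationError):
            classify_presumed(samples, missing, FeatureSpec(),
                              hyperparameters=dict(n_estimators=10), seed=0)


def test_feature_frame_encodings(default_cohort):
    _, samples, biomarkers, _ = default_cohort
    frame = build_feature_frame(samples, biomarkers, FeatureSpec())
    assert set(frame["group"]) == {"EOS", "control", "PS"}
    assert frame["sex_male"].isin([0, 1]).all()
    assert frame["delivery_sum_score"].isin([0, 1, 2]).all()
    assert frame[["crp", "saa", "lbp"]].notna().all().all()
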