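import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st_h

from replomics.associations import (
    DualAssociation,
    GaussianAssociation,
    ModelSpec,
    NegativeBinomialAssociation,
    adjust_fdr,
    baseline_group_tests,
    classify_features,
    correlate_tstats,
    paired_difference_tests,
    richness_models,
    srm_change_model,
)
from replomics.simulate import CohortSimConfig, simulate_cohort

from conftest import make_meta


class TestModelSpec:
    def test_weight_loss_requires_bmi_adjustment(self):
        with pytest.raises(ValueError, match="baseline_bmi"):
            ModelSpec("weight_loss", ("age", "sex"))

    def test_valid_specs(self):
        ModelSpec("weight_loss", ("baseline_bmi", "age", "sex"))
        ModelSpec("baseline_bmi", ("age", "sex"))


class TestGaussian:
    def test_constant_feature_flagged(self, meta24):
        X = pd.DataFrame(
            [[3.0] * 24], index=["flat"], columns=meta24["subject_id"]
        )
        res = GaussianAssociation("weight_loss").fit(X, meta24).results_
        assert res.loc["flat", "coef"] == 0.0
        assert res.loc["flat", "p"] == 1.0
        assert res.loc["flat", "flag"] == "zero_variance"

    def test_group_effect_recovered(self):
        meta = make_meta(100, seed=4)
        rng = np.random.default_rng(4)
        g = (meta["group"] == "weight_loss").to_numpy(float)
        y = 2.0 * g + rng.normal(0, 0.1, 100)
        X = pd.DataFrame([y], index=["f"], columns=meta["subject_id"])
        res = GaussianAssociation("weight_loss").fit(X, meta).results_
        assert 1.9 < res.loc["f", "coef"] < 2.1
        assert res.loc["f", "p"] < 1e-10

    def test_simple_regression_matches_closed_form(self):
        """Single-covariate model on a 6-point fixture reproduces the
        textbook least-squares slope, standard error and t."""
        meta = pd.DataFrame(
            {
                "subject_id": list("abcdef"),
                "sex": ["female"] * 6,
                "age": [50.0] * 6,
                "baseline_bmi": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "group": ["no_weight_loss"] * 6,
            }
        )
        y = [2.1, 3.9, 6.2, 7.8, 10.1, 11.9]
        X = pd.DataFrame([y], index=["f"], columns=meta["subject_id"])
        res = GaussianAssociation("baseline_bmi", covariates=()).fit(X, meta).results_
        assert res.loc["f", "coef"] == pytest.approx(1.9771428571428569, rel=1e-12)
        assert res.loc["f", "se"] == pytest.approx(0.03979539507766895, rel=1e-10)
        assert res.loc["f", "t"] == pytest.approx(49.68270457634742, rel=1e-10)

    def test_t_equals_coef_over_se(self, meta24, rng):
        X = pd.DataFrame(
            rng.normal(0, 1, (5, 24)),
            index=[f"f{i}" for i in range(5)],
            columns=meta24["subject_id"],
        )
        res = GaussianAssociation("weight_loss").fit(X, meta24).results_
        np.testing.assert_allclose(res["t"], res["coef"] / res["se"], rtol=1e-12)

    def test_affine_covariate_rescaling_leaves_t_unchanged(self, rng):
        meta = make_meta(40, seed=8)
        X = pd.DataFrame(
            rng.normal(0, 1, (3, 40)),
            index=["a", "b", "c"],
            columns=meta["subject_id"],
        )
        res1 = GaussianAssociation("weight_loss").fit(X, meta).results_
        meta2 = meta.copy()
        meta2["age"] = meta2["age"] * 12.0 + 7.0  # months, shifted
        meta2["baseline_bmi"] = meta2["baseline_bmi"] / 10.0
        res2 = GaussianAssociation("weight_loss").fit(X, meta2).results_
        np.testing.assert_allclose(res1["t"], res2["t"], rtol=1e-9)
        np.testing.assert_allclose(res1["p"], res2["p"], rtol=1e-9)

    def test_rank_deficient_design_names_columns(self, rng):
        meta = make_meta(20, seed=1)
        meta["age"] = meta["baseline_bmi"]  # perfectly collinear
        X = pd.DataFrame(
            rng.normal(0, 1, (2, 20)), index=["x", "y"], columns=meta["subject_id"]
        )
        with pytest.raises(ValueError, match="collinear"):
            GaussianAssociation("weight_loss").fit(X, meta)

    def test_missing_values_rejected(self, meta24):
        X = pd.DataFrame(
            [[np.nan] + [1.0] * 23], index=["f"], columns=meta24["subject_id"]
        )
        with pytest.raises(ValueError, match="missing"):
            GaussianAssociation("weight_loss").fit(X, meta24)


class TestNegativeBinomial:
    def test_poisson_limit(self):
        """On Poisson-generated counts the estimated dispersion collapses and
        NB coefficients agree with a direct Poisson GLM to 1e-3."""
        meta = make_meta(40, seed=2)
        rng = np.random.default_rng(2)
        g = (meta["group"] == "weight_loss").to_numpy(float)
        mu = np.exp(3.0 + 0.5 * g)
        counts = pd.DataFrame(
            rng.poisson(np.tile(mu, (4, 1))),
            index=[f"f{i}" for i in range(4)],
            columns=meta["subject_id"],
        )
        sf = pd.Series(1.0, index=meta["subject_id"])
        est = NegativeBinomialAssociation(
            "weight_loss", size_factors=sf, dispersion=1e-8
        )
        res = est.fit(counts, meta).results_
        # reference: plain Poisson regression feature by feature
        X = np.column_stack(
            [
                np.ones(40),
                g,
                meta["baseline_bmi"],
                meta["age"],
                (meta["sex"] == "male").astype(float),
            ]
        )
        for i, fid in enumerate(counts.index):
            pois = sm.GLM(
                counts.loc[fid].to_numpy(float), X, family=sm.families.Poisson()
            ).fit()
            assert res.loc[fid, "coef"] == pytest.approx(pois.params[1], abs=1e-3)

    def test_all_zero_feature_flagged(self, meta24):
        counts = pd.DataFrame(
            np.vstack([np.zeros(24, dtype=int), np.full(24, 5)]),
            index=["dead", "ok"],
            columns=meta24["subject_id"],
        )
        sf = pd.Series(1.0, index=meta24["subject_id"])
        res = (
            NegativeBinomialAssociation("weight_loss", size_factors=sf)
            .fit(counts, meta24)
            .results_
        )
        assert res.loc["dead", "flag"] == "all_zero"
        assert np.isnan(res.loc["dead", "p"])
        assert res.loc["ok", "flag"] == ""

    def test_wald_t_equals_coef_over_se(self, meta24, rng):
        counts = pd.DataFrame(
            rng.poisson(20, (3, 24)),
            index=["a", "b", "c"],
            columns=meta24["subject_id"],
        )
        res = NegativeBinomialAssociation("weight_loss").fit(counts, meta24).results_
        np.testing.assert_allclose(res["t"], res["coef"] / res["se"], rtol=1e-12)


class TestFdr:
    def test_hand_evaluated_bh(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_fdr([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @given(
        ps=st_h.lists(st_h.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_bh_dominates_raw_p_and_is_monotone(self, ps):
        adj = adjust_fdr(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestClassification:
    @pytest.mark.parametrize(
        "fb,fw,expected",
        [
            (0.01, 0.50, "bmi_only"),
            (0.50, 0.01, "wl_only"),
            (0.01, 0.01, "both"),
            (0.50, 0.50, "neither"),
            (0.05, 0.04, "wl_only"),  # threshold is strict
        ],
    )
    def test_four_way_labels(self, fb, fw, expected):
        assert classify_features([fb], [fw])[0] == expected


class TestCorrelateTstats:
    def test_identity_and_negation(self, rng):
        t = rng.normal(0, 2, 20)
        assert correlate_tstats(t, t)[0] == pytest.approx(1.0)
        assert correlate_tstats(t, -t)[0] == pytest.approx(-1.0)

    def test_ten_point_fixture_matches_textbook_formula(self):
        a = np.array([0.5, -1.2, 2.0, 0.3, -0.7, 1.5, -2.2, 0.9, 1.1, -0.4])
        b = np.array([1.0, -0.8, 1.7, 0.0, -1.0, 2.1, -1.5, 0.4, 0.8, 0.1])
        num = ((a - a.mean()) * (b - b.mean())).sum()
        den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        rho, p = correlate_tstats(a, b)
        assert rho == pytest.approx(num / den, rel=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            rho, p = correlate_tstats([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        assert np.isnan(rho)


class TestSrmChangeModel:
    def _deltas(self, meta, rng, shifted=(), shift=np.log(2), sd=0.3):
        g = (meta["group"] == "weight_loss").to_numpy(float)
        rows = {}
        for i in range(22):
            y = rng.normal(0, sd, len(meta))
            if i in shifted:
                y = y + shift * g
            rows[f"p{i}"] = y
        return pd.DataFrame.from_dict(rows, orient="index", columns=meta["subject_id"])

    def test_null_deltas_not_significant(self, rng):
        meta = make_meta(25, n_wl=15, seed=3)
        res = srm_change_model(self._deltas(meta, rng), meta)
        assert res["significant"].sum() <= 1

    def test_shifted_proteins_recovered(self):
        meta = make_meta(25, n_wl=15, seed=3)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            res = srm_change_model(self._deltas(meta, rng, shifted=range(7)), meta)
            hits += res["significant"].iloc[:7].all()
        assert hits >= 8

    def test_permuting_groups_destroys_significance(self):
        meta = make_meta(25, n_wl=15, seed=3)
        rng = np.random.default_rng(0)
        deltas = self._deltas(rng=rng, meta=meta, shifted=range(7))
        counts = []
        for seed in range(10):
            perm = meta.copy()
            perm["group"] = np.random.default_rng(seed).permutation(
                perm["group"].to_numpy()
            )
            counts.append(srm_change_model(deltas, perm)["significant"].sum())
        assert np.median(counts) <= 1


class TestRichnessModels:
    def test_bmi_slope_recovered(self):
        meta = make_meta(105, n_wl=48, seed=6)
        rng = np.random.default_rng(6)
        rich = pd.Series(
            3000.0 - 19.0 * meta["baseline_bmi"].to_numpy() + rng.normal(0, 100, 105),
            index=meta["subject_id"],
        )
        rep = richness_models(rich, meta)
        bmi_row = rep[rep["model"] == "baseline_bmi"].iloc[0]
        assert -25 < bmi_row["coef"] < -13

    def test_group_independent_richness_null(self):
        meta = make_meta(105, n_wl=48, seed=6)
        pvals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            rich = pd.Series(
                3000.0 + rng.normal(0, 100, 105), index=meta["subject_id"]
            )
            rep = richness_models(rich, meta)
            pvals.append(rep[rep["model"] == "weight_loss"]["p"].iloc[0])
        # roughly uniform: no excess of small p values
        assert 0.05 < np.mean(pvals) < 0.95
        assert np.mean(np.array(pvals) < 0.05) <= 0.2

    def test_constant_richness_flagged(self):
        meta = make_meta(20, seed=1)
        rich = pd.Series(2500, index=meta["subject_id"], dtype=float)
        rep = richness_models(rich, meta)
        assert (rep["coef"] == 0).all()
        assert (rep["flag"] == "zero_variance").all()


class TestBaselineGroupTests:
    def test_welch_matches_hand_computation(self):
        meta = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "sex": ["female"] * 4,
                "age": [50.0] * 4,
                "baseline_bmi": [30.0] * 4,
                "group": ["weight_loss", "weight_loss", "no_weight_loss", "no_weight_loss"],
            }
        )
        markers = pd.DataFrame(
            [[1.0, 2.0, 3.0, 5.0]], index=["m"], columns=meta["subject_id"]
        )
        welch, rho, rho_p = baseline_group_tests(markers, meta)
        assert welch.loc["m", "t"] == pytest.approx(-2.23606797749979, rel=1e-12)
        assert welch.loc["m", "p"] == pytest.approx(0.19872738893452602, rel=1e-10)

    def test_null_p_roughly_uniform_and_self_correlation_one(self):
        meta = make_meta(60, seed=10)
        rng = np.random.default_rng(10)
        markers = pd.DataFrame(
            rng.normal(0, 1, (20, 60)),
            index=[f"m{i}" for i in range(20)],
            columns=meta["subject_id"],
        )
        welch, rho, _ = baseline_group_tests(markers, meta)
        assert 0.2 < welch["p"].mean() < 0.8
        np.testing.assert_allclose(np.diag(rho), 1.0)
        np.testing.assert_allclose(rho, rho.T)

    def test_paired_difference(self):
        base = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=["m"], columns=list("abcd")
        )
        follow = base + np.array([[0.5, 0.4, 0.6, 0.5]])
        rep = paired_difference_tests(base, follow)
        assert rep.loc["m", "mean_diff"] == pytest.approx(0.5)
        assert rep.loc["m", "p"] < 0.01


class TestDualAssociation:
    def test_orthogonal_effects_classified(self):
        """BMI-only features land in bmi_only with t_wl near 0; group-only
        features symmetric."""
        n_feat = 30
        specs = pd.DataFrame(
            {
                "feature_id": [f"b{i}" for i in range(n_feat)]
                + [f"w{i}" for i in range(n_feat)],
                "kind": "continuous_log",
                "beta_bmi": [0.15] * n_feat + [0.0] * n_feat,
                "beta_wl": [0.0] * n_feat + [1.5] * n_feat,
                "noise_sd": 1.0,
            }
        )
        sim = simulate_cohort(CohortSimConfig(feature_specs=specs, seed=21))
        est = DualAssociation(kind="continuous_log").fit(
            sim["continuous_log"], sim["metadata"]
        )
        res = est.results_
        bmi_rows = res.loc[[f"b{i}" for i in range(n_feat)]]
        wl_rows = res.loc[[f"w{i}" for i in range(n_feat)]]
        assert abs(bmi_rows["t_wl"].mean()) < 0.5
        assert (bmi_rows["class"] == "bmi_only").mean() >= 0.85
        assert (wl_rows["class"] == "wl_only").mean() >= 0.85
        assert abs(wl_rows["t_bmi"].mean()) < 0.5

    def test_fdr_never_below_p_and_reported_t_consistent(self, rng):
        meta = make_meta(40, seed=13)
        X = pd.DataFrame(
            rng.normal(0, 1, (25, 40)),
            index=[f"f{i}" for i in range(25)],
            columns=meta["subject_id"],
        )
        res = DualAssociation(kind="continuous_log").fit(X, meta).results_
        for tag in ("wl", "bmi"):
            assert (res[f"fdr_{tag}"] >= res[f"p_{tag}"] - 1e-15).all()
            np.testing.assert_allclose(
                res[f"t_{tag}"], res[f"coef_{tag}"] / res[f"se_{tag}"], rtol=1e-12
            )
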