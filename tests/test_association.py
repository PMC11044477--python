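import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from calsa.association import (
    LobarAssociationModel,
    adjusted_alpha,
    bland_altman,
    fit_lobar_model,
    fit_spirometry_model,
    icc_average_measures,
    map_location_to_zone,
    subscore_interdependency,
    transform_features,
)
from calsa.io_audio import ChestLocation
from calsa.synthetic import simulate_lobar_dataset


class TestLocationMap:
    @pytest.mark.parametrize(
        "location,zone",
        [
            ("anterior_left", "LUL"),
            ("anterior_right", "RUL"),
            ("posterior_left", "LLL"),
            ("posterior_right", "RLL"),
            ("lateral_right", "RML"),
            ("lateral_left", None),  # no left middle lobe
        ],
    )
    def test_mapping(self, location, zone):
        assert map_location_to_zone(location) == zone
        assert map_location_to_zone(ChestLocation(location)) == zone

    def test_unknown_location_rejected(self):
        with pytest.raises(ValueError):
            map_location_to_zone("sternal")


class TestTransforms:
    def test_log_and_sqrt_columns(self):
        t = pd.DataFrame(
            {
                "ei_100_200": [1.0, 0.5],
                "ei_200_400": [0.17, 2.0],
                "crackles_full": [6.0, 0.0],
                "iRaw": [0.2, 0.5],
                "MEF25_75": [80.0, 40.0],
            }
        )
        out = transform_features(t)
        assert out["log_ei_100_200"].iloc[0] == pytest.approx(0.0)
        assert out["sqrt_crackles_full"].iloc[0] == pytest.approx(2.449489742783178)
        assert out["log_iRaw"].iloc[0] == pytest.approx(np.log(0.2))
        assert out["log_MEF25_75"].iloc[1] == pytest.approx(np.log(40.0))

    def test_zero_ei_floored_and_flagged(self):
        t = pd.DataFrame({"ei_200_400": [0.0, 0.2]})
        out = transform_features(t, epsilon=1e-3)
        assert out["log_ei_200_400"].iloc[0] == pytest.approx(np.log(1e-3))
        assert "ei_200_400_floored" in out["transform_flags"].iloc[0]
        assert out["transform_flags"].iloc[1] == ""

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            transform_features(pd.DataFrame({"crackles_full": [-1.0]}))
        with pytest.raises(ValueError):
            transform_features(pd.DataFrame({"iRaw": [0.0]}))


class TestAdjustedAlpha:
    def test_family_defaults_follow_endpoint_counts(self):
        assert adjusted_alpha("cfct") == pytest.approx(0.05 / 6)
        assert adjusted_alpha("fri") == pytest.approx(0.05 / 3)
        assert adjusted_alpha("spirometry") == pytest.approx(0.05 / 5)

    def test_single_endpoint_is_unadjusted(self):
        assert adjusted_alpha("custom", 1) == 0.05

    def test_invalid(self):
        with pytest.raises(ValueError):
            adjusted_alpha("unknown_family")
        with pytest.raises(ValueError):
            adjusted_alpha("cfct", 0)


class TestICC:
    def test_perfect_agreement(self):
        a = np.array([1.0, 2.0, 5.0, 7.0, 9.0, 12.0])
        assert icc_average_measures(a, a) == pytest.approx(1.0)

    def test_independent_scores_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 400)
        b = rng.permutation(a)
        assert abs(icc_average_measures(a, b)) < 0.15

    def test_matches_brute_force_anova(self):
        # independent mean-squares oracle computed from first principles
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.normal(10, 3, 9)
            b = a + rng.normal(0, 1.5, 9) + rng.normal(0, 0.5)
            y = np.column_stack([a, b])
            n, k = y.shape
            grand = y.mean()
            ms_rows = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
            ms_cols = n * ((y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
            ss_err = ((y - grand) ** 2).sum() - ms_rows * (n - 1) - ms_cols * (k - 1)
            ms_err = ss_err / ((n - 1) * (k - 1))
            expected = (ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n)
            assert icc_average_measures(a, b) == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_two_way_average_absolute(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        a = rng.normal(10, 3, 12)
        b = a + rng.normal(0, 1, 12) + 0.5
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "score": np.column_stack([a, b]).ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref = table.loc[table["Type"] == "ICC(A,k)", "ICC"].iloc[0]
        assert icc_average_measures(a, b) == pytest.approx(ref, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_average_measures(np.ones(8), np.ones(8))
        with pytest.raises(ValueError):
            icc_average_measures(np.arange(3.0), np.arange(3.0))


class TestBlandAltman:
    def test_identical_vectors(self):
        a = np.array([1.0, 4.0, 9.0])
        assert bland_altman(a, a) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        a = np.array([1.0, 4.0, 9.0, 2.0])
        bias, lo, hi = bland_altman(a + 2, a)
        assert (bias, lo, hi) == pytest.approx((2.0, 2.0, 2.0))

    @given(
        d=arrays(np.float64, st.integers(3, 30),
                 elements=st.floats(-50, 50, allow_nan=False)),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_formula_and_symmetry(self, d):
        a = np.linspace(0, 10, d.size)
        bias, lo, hi = bland_altman(a + d, a)
        assert bias == pytest.approx(d.mean(), abs=1e-10)
        sd = d.std(ddof=1)
        assert hi - bias == pytest.approx(1.96 * sd, abs=1e-9)
        assert bias - lo == pytest.approx(1.96 * sd, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.arange(2.0), np.arange(2.0))


class TestSpearmanInterdependency:
    def test_monotone_and_reversed_pairs(self):
        df = pd.DataFrame(
            {
                "bronchiectasis": [1, 2, 3, 4, 5.0],
                "mucus": [2, 4, 9, 16, 25.0],
                "air_trapping": [5, 4, 3, 2, 1.0],
            }
        )
        out = subscore_interdependency(df)
        rho = {(r.score_a, r.score_b): r.rho for r in out.itertuples()}
        assert rho[("bronchiectasis", "mucus")] == pytest.approx(1.0)
        assert rho[("bronchiectasis", "air_trapping")] == pytest.approx(-1.0)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1, 1, 1, 1.0], "b": [1, 2, 3, 4.0]})
        out = subscore_interdependency(df)
        assert out.loc[0, "flag"] == "constant_column"
        assert np.isnan(out.loc[0, "rho"])

    def test_independent_scores_nominal_false_positive_rate(self):
        rng = np.random.default_rng(2)
        sig = []
        for _ in range(20):
            df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
            out = subscore_interdependency(df)
            sig.append((out["p_value"] < 0.05).mean())
            assert out["rho"].abs().max() < 0.6
        assert np.mean(sig) <= 0.12  # ~5% nominal, Monte-Carlo slack


class TestMixedModels:
    def test_noiseless_exact_recovery_both_variants(self):
        df = simulate_lobar_dataset(
            n_subjects=12, effect_size=0.4,
            variances={"subject": 0.0, "zone": 0.0, "residual": 0.0}, seed=11,
        )
        lob = fit_lobar_model(df, "log_ei_200_400", "cfct_total")
        assert lob.slope == pytest.approx(0.4, abs=1e-8)
        spiro = fit_spirometry_model(df, "log_ei_200_400", "cfct_total")
        assert spiro.slope == pytest.approx(0.4, abs=1e-8)

    def test_direction_semantics(self):
        df = simulate_lobar_dataset(n_subjects=25, effect_size=1.5, seed=3)
        r = fit_lobar_model(df, "log_ei_200_400", "cfct_total")
        assert r.direction == "positive" and r.p_value < 0.05
        dfn = simulate_lobar_dataset(n_subjects=25, effect_size=-1.5, seed=3)
        rn = fit_lobar_model(dfn, "log_ei_200_400", "cfct_total")
        assert rn.direction == "negative"

    def test_nested_variant_runs(self):
        df = simulate_lobar_dataset(n_subjects=20, effect_size=0.8, seed=4)
        r = fit_lobar_model(df, "log_ei_200_400", "cfct_total", random="nested")
        assert np.isfinite(r.slope)

    def test_summary_and_dict(self):
        df = simulate_lobar_dataset(n_subjects=20, effect_size=0.8, seed=4)
        r = LobarAssociationModel(
            df, "log_ei_200_400", "cfct_total", adjusted_alpha=0.05 / 6
        ).fit()
        text = r.summary()
        assert "slope" in text and "p-value" in text
        d = r.to_dict()
        assert d["outcome"] == "log_ei_200_400" and 0 <= d["p_value"] <= 1

    def test_too_few_subjects_rejected(self):
        df = simulate_lobar_dataset(n_subjects=5, seed=1)
        with pytest.raises(ValueError, match="10 subjects"):
            fit_lobar_model(df, "log_ei_200_400", "cfct_total")
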