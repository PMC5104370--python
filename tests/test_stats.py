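"""Regional statistics: normalization, group tests, BDI correlation, demographics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import metabnet as m
from metabnet.stats import _bh_adjust

from conftest import make_cohort


def _basic_covariates(n_nc, n_ca, rng, bdi=None):
    n = n_nc + n_ca
    groups = ["NC"] * n_nc + ["cancer"] * n_ca
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": groups,
            "age": rng.normal(50, 8, n).clip(18),
            "gender": rng.choice(["male", "female"], n),
            "bdi": np.concatenate(
                [np.full(n_nc, np.nan), bdi if bdi is not None else rng.uniform(0, 40, n_ca)]
            ),
        }
    )


class TestNormalizeAndAdjust:
    def test_identical_profiles_give_constant_output(self):
        rng = np.random.default_rng(0)
        cov = _basic_covariates(5, 5, rng)
        profile = np.array([10.0, 20.0, 30.0])
        x = np.tile(profile, (10, 1))
        norm = m.normalize_and_adjust(make_cohort(cov, x, ["a", "b", "c"]))
        out = norm.values.to_numpy()
        assert np.allclose(out, out[0])  # constant across subjects

    def test_output_orthogonal_to_covariates(self, default_norm):
        age = default_norm.covariates["age"].to_numpy()
        female = (default_norm.covariates["gender"] == "female").to_numpy(float)
        vals = default_norm.values.to_numpy()
        for covar in (age, female):
            r = np.corrcoef(vals.T, covar)[:-1, -1]
            assert np.max(np.abs(r)) < 1e-10

    def test_age_coefficient_recovered(self, regions20):
        spec = m.SimulationSpec(
            n_nc=250, n_cancer=250, base_cov=np.eye(20), age_effect=0.5, seed=9
        )
        cohort = m.generate_cohort(spec, regions20)
        norm = m.normalize_and_adjust(cohort, mode="none")
        # closed-form OLS oracle for the same design
        d = np.column_stack(
            [
                np.ones(500),
                cohort.covariates["age"],
                (cohort.covariates["gender"] == "female").astype(float),
            ]
        )
        beta = np.linalg.solve(d.T @ d, d.T @ cohort.metabolism.to_numpy())
        np.testing.assert_allclose(
            norm.coefficients["age"].to_numpy(), beta[1], rtol=1e-10
        )
        resid_var = norm.values.to_numpy().var(axis=0).mean()
        se = np.sqrt(resid_var * np.linalg.inv(d.T @ d)[1, 1])
        assert np.all(np.abs(norm.coefficients["age"] - 0.5) < 3 * se + 1e-12)

    def test_regression_step_idempotent(self, default_cohort):
        once = m.normalize_and_adjust(default_cohort, mode="none")
        again = m.normalize_and_adjust(
            make_cohort(once.covariates, once.values.to_numpy(), once.region_names),
            mode="none",
        )
        np.testing.assert_allclose(
            once.values.to_numpy(), again.values.to_numpy(), atol=1e-10
        )

    def test_constant_gender_dropped_with_warning(self, regions20, caplog):
        rng = np.random.default_rng(1)
        cov = _basic_covariates(6, 6, rng)
        cov["gender"] = "female"
        cohort = make_cohort(cov, rng.normal(100, 1, (12, 20)), regions20.names)
        with caplog.at_level("WARNING"):
            norm = m.normalize_and_adjust(cohort)
        assert norm.dropped_covariates == ("gender",)
        assert "gender" in caplog.text

    def test_unknown_mode_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            m.normalize_and_adjust(default_cohort, mode="zscore")


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        # step-up rule by hand: sorted p * N / rank, cumulative minimum from top
        adjusted = _bh_adjust(np.array([0.001, 0.02, 0.03, 0.9]))
        np.testing.assert_allclose(adjusted, [0.004, 0.04, 0.04, 0.9])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2, max_size=40)
    )
    def test_monotone_and_bounded(self, pvals):
        p = np.array(pvals)
        adj = _bh_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestGroupRegionTest:
    def test_large_shift_flagged(self, regions20):
        spec = m.SimulationSpec(n_nc=80, n_cancer=78, base_cov=np.eye(20), seed=2)
        cohort = m.generate_cohort(spec, regions20)
        shifted = cohort.metabolism.copy()
        target = regions20.names[5]
        mask = cohort.group_mask("cancer")
        pooled_sd = shifted[target].std()
        shifted.loc[mask, target] += 3 * pooled_sd
        res = m.group_region_test(
            m.normalize_and_adjust(make_cohort(cohort.covariates, shifted.to_numpy(),
                                               regions20.names), mode="none"),
            alpha=0.01,
        )
        assert target in res.flagged

    def test_scale_invariance_under_global_mean(self, default_cohort):
        res1 = m.group_region_test(m.normalize_and_adjust(default_cohort))
        scaled = make_cohort(
            default_cohort.covariates,
            default_cohort.metabolism.to_numpy() * 7.3,
            default_cohort.region_names,
        )
        res2 = m.group_region_test(m.normalize_and_adjust(scaled))
        np.testing.assert_allclose(
            res1.table["statistic"], res2.table["statistic"], rtol=1e-9
        )
        np.testing.assert_allclose(res1.table["p"], res2.table["p"], rtol=1e-9)

    def test_degenerate_region_excluded(self):
        rng = np.random.default_rng(3)
        cov = _basic_covariates(6, 6, rng)
        x = rng.normal(10, 1, (12, 3))
        x[:, 1] = 5.0  # constant in both groups
        norm = m.NormalizedMatrix(
            pd.DataFrame(x, columns=["a", "b", "c"]), cov, "none",
            pd.DataFrame(index=["a", "b", "c"]),
        )
        with pytest.warns(UserWarning, match="zero variance"):
            res = m.group_region_test(norm)
        assert res.excluded == ("b",)
        assert np.isnan(res.table.set_index("region").loc["b", "p_adj"])


class TestBdiCorrelation:
    def test_exact_linear_function_flagged_with_sign(self):
        rng = np.random.default_rng(4)
        bdi = rng.uniform(0, 40, 30)
        cov = _basic_covariates(6, 30, rng, bdi=bdi)
        x = rng.normal(10, 1, (36, 3))
        x[6:, 0] = 2.0 + 0.5 * bdi          # exact positive linear function
        x[6:, 2] = 9.0 - 0.25 * bdi         # exact negative linear function
        norm = m.NormalizedMatrix(
            pd.DataFrame(x, columns=["pos", "mid", "neg"]), cov, "none",
            pd.DataFrame(index=["pos", "mid", "neg"]),
        )
        res = m.bdi_correlation(norm, alpha=0.01)
        t = res.table.set_index("region")
        assert t.loc["pos", "r"] == pytest.approx(1.0)
        assert t.loc["neg", "r"] == pytest.approx(-1.0)
        assert t.loc["pos", "sign"] == 1 and t.loc["neg", "sign"] == -1
        assert not t.loc["mid", "flag"]

    def test_negative_coupling_recovered_on_named_region(self, regions90):
        spec = m.SimulationSpec(
            base_cov=np.eye(90),
            bdi_coupling=[("IFGtriang.L", "-", m.simulate.DEFAULT_COUPLING_STRENGTH)],
            seed=21,
        )
        cohort = m.generate_cohort(spec, regions90)
        res = m.bdi_correlation(m.normalize_and_adjust(cohort), alpha=0.01)
        row = res.table.set_index("region").loc["IFGtriang.L"]
        assert row["flag"] and row["sign"] == -1

    def test_constant_bdi_rejected(self):
        rng = np.random.default_rng(5)
        cov = _basic_covariates(6, 6, rng, bdi=np.full(6, 10.0))
        norm = m.NormalizedMatrix(
            pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"]), cov, "none",
            pd.DataFrame(index=["a", "b"]),
        )
        with pytest.raises(ValueError, match="constant"):
            m.bdi_correlation(norm)


class TestDemographics:
    @staticmethod
    def _cohort_with_counts(nc_mf, ca_mf, rng):
        rows = []
        for group, (males, females) in (("NC", nc_mf), ("cancer", ca_mf)):
            rows += [(group, "male")] * males + [(group, "female")] * females
        cov = pd.DataFrame(rows, columns=["group", "gender"])
        cov.insert(0, "subject_id", [f"s{i}" for i in range(len(cov))])
        cov["age"] = rng.normal(50, 8, len(cov)).clip(18)
        cov["bdi"] = np.where(cov["group"] == "cancer", rng.uniform(0, 40, len(cov)), np.nan)
        x = rng.normal(100, 1, (len(cov), 2))
        return make_cohort(cov, x, ["a", "b"])

    def test_printed_gender_table_pvalue(self):
        rng = np.random.default_rng(6)
        report = m.demographics_table(self._cohort_with_counts((45, 35), (43, 35), rng))
        assert f"{report.gender_p:.3f}" == "0.887"

    def test_identical_counts_give_unit_p(self):
        rng = np.random.default_rng(7)
        report = m.demographics_table(self._cohort_with_counts((10, 10), (10, 10), rng))
        assert report.gender_chi2 == pytest.approx(0.0)
        assert report.gender_p == pytest.approx(1.0)

    def test_perfect_separation_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        report = m.demographics_table(self._cohort_with_counts((10, 0), (0, 10), rng))
        # direct sum((O-E)^2/E) on the 2x2 table: every cell contributes 5
        assert report.gender_chi2 == pytest.approx(20.0)
        assert report.gender_p == pytest.approx(sps.chi2.sf(20.0, 1), rel=1e-6)
        assert report.gender_p == pytest.approx(7.7e-6, rel=0.01)

    def test_empty_margin_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="margin"):
            m.demographics_table(self._cohort_with_counts((10, 0), (10, 0), rng))

    def test_markdown_render_contains_counts(self, default_cohort):
        report = m.demographics_table(default_cohort)
        md = report.to_markdown()
        assert "45/35" in md and "43/35" in md
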