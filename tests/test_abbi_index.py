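import numpy as np
import pandas as pd
import pytest

from abbi.abbi_index import (area_average, associated_ratio, relative_index,
                             sensitivity_run, stratum_abbi, uncertainty)
from abbi.behaviour import SensitivityGrid


def inputs_frame(rows):
    """rows: (region, year, quarter, m, f, p, crt, cat) per stratum."""
    recs = []
    for region, year, quarter, m, f, p, crt, cat in rows:
        recs.append(dict(region_id=region, lat_min=-10.0, lon_min=50.0,
                         year=year, quarter=quarter, species="SKJ",
                         m_hat=m, f_i=f, p_hat=p, crt=crt, cat=cat))
    return pd.DataFrame(recs)


class TestStratumAbbi:
    def test_equal_time_scales_split_population_in_half(self):
        est = stratum_abbi(inputs_frame([("R1", 2013, 1, 10, 0.5, 100, 5, 5)]))
        assert est["x_a"].iloc[0] == pytest.approx(500.0)
        assert est["x_u"].iloc[0] == pytest.approx(500.0)
        assert est["n_total"].iloc[0] == pytest.approx(1000.0)

    def test_zero_absence_time_means_fully_associated(self):
        est = stratum_abbi(inputs_frame([("R1", 2013, 1, 10, 0.5, 100, 5, 0)]))
        assert est["n_total"].iloc[0] == est["x_a"].iloc[0]
        assert est["x_u"].iloc[0] == 0.0

    def test_direct_formula_evaluation(self):
        m, f, p, crt, cat = 12.0, 0.3, 1666.67, 4.6, 10.0
        est = stratum_abbi(inputs_frame([("R1", 2013, 1, m, f, p, crt, cat)]))
        x_a = m * f * p
        assert est["x_a"].iloc[0] == pytest.approx(x_a)
        assert est["n_total"].iloc[0] == pytest.approx(x_a * (1 + cat / crt))
        assert est["n_total"].iloc[0] == pytest.approx(19043.52, abs=0.01)

    def test_conservation_and_ratio_identities(self, rng):
        n = 500
        df = inputs_frame([("R1", 2013, 1, 1, 1, 1, 1, 1)] * n)
        df["m_hat"] = rng.uniform(0.1, 50, n)
        df["f_i"] = rng.uniform(0, 1, n)
        df["p_hat"] = rng.uniform(1, 5000, n)
        df["crt"] = rng.uniform(0.5, 20, n)
        df["cat"] = rng.uniform(0.0, 60, n)
        est = stratum_abbi(df)
        assert (est["n_total"] == est["x_a"] + est["x_u"]).all()
        ratio = est["x_a"] / est["n_total"]
        want = est["crt"] / (est["crt"] + est["cat"])
        assert np.max(np.abs(ratio - want)) < 1e-12

    def test_monotonicity_in_each_input(self):
        base = inputs_frame([("R1", 2013, 1, 10, 0.4, 100, 5, 8)])
        n0 = stratum_abbi(base)["n_total"].iloc[0]
        for col, up in [("m_hat", True), ("f_i", True), ("p_hat", True),
                        ("cat", True), ("crt", False)]:
            bumped = base.copy()
            bumped[col] *= 1.5
            n1 = stratum_abbi(bumped)["n_total"].iloc[0]
            assert (n1 > n0) == up

    def test_non_positive_crt_rejected(self):
        with pytest.raises(ValueError):
            stratum_abbi(inputs_frame([("R1", 2013, 1, 10, 0.5, 100, 0, 5)]))


class TestAreaAverage:
    def test_mean_of_two_strata(self):
        est = stratum_abbi(inputs_frame([
            ("R1", 2013, 1, 10, 0.5, 20, 5, 5),    # N = 200
            ("R2", 2013, 1, 10, 0.5, 60, 5, 5),    # N = 600
        ]))
        out = area_average(est)
        assert out["n_total"].iloc[0] == pytest.approx(400.0)
        assert out["n_strata"].iloc[0] == 2

    def test_single_stratum_is_itself_with_missing_se(self):
        est = stratum_abbi(inputs_frame([("R1", 2013, 1, 10, 0.5, 20, 5, 5)]))
        out = area_average(est)
        assert out["n_total"].iloc[0] == pytest.approx(200.0)
        assert np.isnan(out["se"].iloc[0])

    def test_matches_mean_oracle(self, rng):
        rows = [("R%d" % i, 2013 + i % 2, 1 + i % 4, rng.uniform(1, 20),
                 rng.uniform(0, 1), rng.uniform(10, 100), 4.6,
                 rng.uniform(0, 30)) for i in range(40)]
        est = stratum_abbi(inputs_frame(rows))
        out = area_average(est)
        for _, r in out.iterrows():
            sel = est[(est["year"] == r["year"]) & (est["quarter"] == r["quarter"])]
            assert r["n_total"] == pytest.approx(sel["n_total"].mean())


class TestRelativeIndex:
    def _series(self, totals, year0=2013):
        rows = []
        for i, n in enumerate(totals):
            rows.append(dict(species="SKJ", year=year0 + i // 4,
                             quarter=1 + i % 4, n_total=n, x_a=n / 2,
                             x_u=n / 2, n_strata=1, se=np.nan))
        return pd.DataFrame(rows)

    def test_first_quarter_becomes_one(self):
        out = relative_index(self._series([50.0, 100.0, 75.0]))
        assert out["relative"].tolist() == pytest.approx([1.0, 2.0, 1.5])

    def test_constant_series_all_ones(self):
        out = relative_index(self._series([7.0] * 6))
        assert out["relative"].tolist() == pytest.approx([1.0] * 6)

    def test_explicit_baseline(self):
        out = relative_index(self._series([50.0, 100.0]), baseline=(2013, 2))
        assert out["relative"].tolist() == pytest.approx([0.5, 1.0])

    def test_missing_or_zero_baseline_raises(self):
        with pytest.raises(ValueError):
            relative_index(self._series([50.0]), baseline=(1999, 1))
        with pytest.raises(ValueError):
            relative_index(self._series([0.0, 50.0]))


class TestAssociatedRatio:
    def test_equal_time_scales_give_half(self):
        est = stratum_abbi(inputs_frame([
            ("R1", 2013, 1, 10, 0.5, 20, 5, 5),
            ("R2", 2013, 1, 30, 0.5, 20, 5, 5),
        ]))
        out = associated_ratio(est)
        assert out["ratio"].iloc[0] == pytest.approx(0.5)

    def test_zero_absence_time_gives_one(self):
        est = stratum_abbi(inputs_frame([("R1", 2013, 1, 10, 0.5, 20, 5, 0)]))
        assert associated_ratio(est)["ratio"].iloc[0] == pytest.approx(1.0)

    def test_single_stratum_equals_renewal_ratio_exactly(self):
        crt, cat = 4.6, 17.3
        est = stratum_abbi(inputs_frame([("R1", 2013, 1, 10, 0.5, 20, crt, cat)]))
        out = associated_ratio(est)
        assert out["ratio"].iloc[0] == pytest.approx(crt / (crt + cat), rel=1e-12)


class TestUncertainty:
    def _est(self, totals):
        rows = [(f"R{i}", 2013, 1, 1.0, 1.0, n, 5, 5)
                for i, n in enumerate(totals)]
        df = inputs_frame(rows)
        est = stratum_abbi(df)
        # n_total = 2 * p_hat with these inputs; rescale to the wanted totals
        est["n_total"] = totals
        return est

    def test_two_strata_sem(self):
        out = uncertainty(self._est([100.0, 300.0]))
        assert out["se"].iloc[0] == pytest.approx(100.0)

    def test_identical_strata_zero_se(self):
        out = uncertainty(self._est([250.0] * 4))
        assert out["se"].iloc[0] == 0.0

    def test_single_stratum_reports_missing(self):
        out = uncertainty(self._est([100.0]))
        assert np.isnan(out["se"].iloc[0])

    def test_bootstrap_close_to_analytic_sem(self, rng):
        totals = list(rng.uniform(50, 400, 5))
        est = self._est(totals)
        sem = uncertainty(est, method="sem")["se"].iloc[0]
        boot = uncertainty(est, method="bootstrap", n_boot=5000, seed=42)["se"].iloc[0]
        # bootstrap sd of the mean uses the 1/n variance convention
        assert boot == pytest.approx(sem * np.sqrt(4 / 5), rel=0.15)


class TestSensitivity:
    def _inputs(self, p_values):
        rows = [("R%d" % i, 2013 + i // 4, 1 + i % 4, 10 + i, 0.4, p, 4.6, 0)
                for i, p in enumerate(p_values)]
        df = inputs_frame(rows)
        return df.drop(columns="cat")

    def test_single_point_grid_equals_plain_run(self):
        from abbi.behaviour import cat_from_phi

        inputs = self._inputs([100.0, 120.0, 90.0, 110.0])
        grid = SensitivityGrid(phi_values=(3e-5,))
        out = sensitivity_run(inputs, grid)
        work = inputs.copy()
        work["cat"] = cat_from_phi(3e-5, work["p_hat"].to_numpy())
        plain = area_average(stratum_abbi(work))
        got = out["absolute"].drop(columns=["phi", "crt_override"])
        pd.testing.assert_frame_equal(got, plain)

    def test_constant_fob_count_cancels_phi_in_relative_series(self):
        inputs = self._inputs([100.0] * 8)
        out = sensitivity_run(inputs, SensitivityGrid(phi_values=(2e-5, 4e-5, 6e-5)))
        assert (out["summary"]["max_relative_divergence_across_phi"] < 1e-12).all()

    def test_smaller_phi_gives_pointwise_larger_absolute_series(self, rng):
        inputs = self._inputs(list(rng.uniform(50, 200, 8)))
        out = sensitivity_run(inputs, SensitivityGrid(phi_values=(2e-5, 6e-5)))
        absolute = out["absolute"].pivot_table(
            index=["species", "year", "quarter"], columns="phi", values="n_total")
        assert (absolute[2e-5] >= absolute[6e-5]).all()
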