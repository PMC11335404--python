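import numpy as np
import pandas as pd
import pytest

from abbi.assoc_biomass import (estimate_m, impute_composition_emm,
                                level1_correct, stratum_composition)
from abbi.strata import STRATUM_COLS

from conftest import make_samples, make_sets


class TestLevel1:
    def test_proportional_scaling(self):
        sets = make_sets(2, ["T1", "T1"], [10.0, 30.0], [False, False])
        landings = pd.DataFrame({"trip_id": ["T1"], "landed_total": [48.0]})
        out = level1_correct(sets, landings)
        assert out["corrected_catch"].tolist() == pytest.approx([12.0, 36.0])
        assert out["level1_applied"].all()

    def test_identity_when_declared_matches_landed(self):
        sets = make_sets(3, ["T1"] * 3, [5.0, 7.0, 8.0], [False] * 3)
        landings = pd.DataFrame({"trip_id": ["T1"], "landed_total": [20.0]})
        out = level1_correct(sets, landings)
        assert out["corrected_catch"].tolist() == pytest.approx([5.0, 7.0, 8.0])

    def test_trip_sums_match_landings_on_random_fixture(self, rng):
        frames, landings = [], []
        for t in range(20):
            n = int(rng.integers(2, 8))
            declared = rng.uniform(1, 40, n)
            frames.append(make_sets(n, [f"T{t}"] * n, declared,
                                    [False] * n, start_id=100 * t))
            landings.append((f"T{t}", float(declared.sum() * rng.uniform(0.7, 1.3))))
        sets = pd.concat(frames, ignore_index=True)
        landed = pd.DataFrame(landings, columns=["trip_id", "landed_total"])
        out = level1_correct(sets, landed)
        sums = out.groupby("trip_id")["corrected_catch"].sum()
        for trip, want in landings:
            assert abs(sums[trip] - want) < 1e-9

    def test_missing_landing_leaves_trip_uncorrected(self, caplog):
        sets = make_sets(2, ["T1", "T2"], [10.0, 10.0], [False, False])
        landings = pd.DataFrame({"trip_id": ["T1"], "landed_total": [20.0]})
        with caplog.at_level("WARNING"):
            out = level1_correct(sets, landings)
        t2 = out[out["trip_id"] == "T2"]
        assert t2["corrected_catch"].iloc[0] == 10.0
        assert not t2["level1_applied"].iloc[0]
        assert "no landing record" in caplog.text

    def test_zero_declared_with_positive_landing_flagged(self, caplog):
        sets = make_sets(1, ["T1"], [0.0], [False])
        landings = pd.DataFrame({"trip_id": ["T1"], "landed_total": [5.0]})
        with caplog.at_level("WARNING"):
            out = level1_correct(sets, landings)
        assert out["corrected_catch"].iloc[0] == 0.0
        assert not out["level1_applied"].iloc[0]


def sampled_sets_with_composition(n, skj_prop, one_region=None, start_id=0):
    sets = make_sets(n, [f"T{i}" for i in range(n)], [10.0] * n, [True] * n,
                     start_id=start_id)
    sets["corrected_catch"] = sets["declared_catch"]
    samples = make_samples(sets["set_id"], ["SKJ"] * n, skj_prop)
    return sets, samples


class TestStratumComposition:
    def test_constant_proportion_recovered(self, one_region):
        sets, samples = sampled_sets_with_composition(25, [0.6] * 25)
        out = stratum_composition(sets, samples, one_region)
        assert len(out) == 1
        assert out["mean_proportion"].iloc[0] == pytest.approx(0.6)
        assert not out["imputed"].iloc[0]
        assert out["n_sampled_sets"].iloc[0] == 25

    def test_under_threshold_emits_missing(self, one_region):
        sets, samples = sampled_sets_with_composition(19, [0.6] * 19)
        out = stratum_composition(sets, samples, one_region)
        assert out["mean_proportion"].isna().all()

    def test_heterogeneous_mix_matches_mean_oracle(self, one_region, rng):
        props = rng.uniform(0, 1, 30)
        sets, samples = sampled_sets_with_composition(30, props)
        out = stratum_composition(sets, samples, one_region)
        assert out["mean_proportion"].iloc[0] == pytest.approx(props.mean())

    def test_unsampled_sets_do_not_enter_composition(self, one_region):
        sets, samples = sampled_sets_with_composition(25, [0.4] * 25)
        extra = make_sets(10, [f"U{i}" for i in range(10)], [99.0] * 10,
                          [False] * 10, start_id=900)
        extra["corrected_catch"] = extra["declared_catch"]
        out = stratum_composition(pd.concat([sets, extra], ignore_index=True),
                                  samples, one_region)
        assert out["mean_proportion"].iloc[0] == pytest.approx(0.4)
        assert out["n_sampled_sets"].iloc[0] == 25


def balanced_table(values, missing_cells=()):
    """Composition table over years x quarters for one region/species."""
    rows = []
    for (y, q), v in values.items():
        rows.append(dict(region_id="R1", lat_min=-10.0, lon_min=50.0,
                         year=y, quarter=q, n_sampled_sets=25,
                         species="SKJ",
                         mean_proportion=np.nan if (y, q) in missing_cells else v,
                         imputed=False))
    return pd.DataFrame(rows)


class TestEmmImputation:
    def test_constant_observed_gives_constant_imputed(self):
        values = {(y, q): 0.5 for y in (2013, 2014) for q in (1, 2, 3, 4)}
        table = balanced_table(values, missing_cells={(2014, 4)})
        out = impute_composition_emm(table)
        cell = out[(out["year"] == 2014) & (out["quarter"] == 4)]
        assert cell["mean_proportion"].iloc[0] == pytest.approx(0.5)
        assert cell["imputed"].iloc[0]

    def test_additive_truth_reconstructed_exactly(self):
        year_eff = {2013: 0.0, 2014: 0.1, 2015: -0.05}
        q_eff = {1: 0.0, 2: 0.08, 3: -0.04, 4: 0.02}
        values = {(y, q): 0.4 + year_eff[y] + q_eff[q]
                  for y in year_eff for q in q_eff}
        table = balanced_table(values, missing_cells={(2015, 3)})
        out = impute_composition_emm(table)
        cell = out[(out["year"] == 2015) & (out["quarter"] == 3)]
        assert cell["mean_proportion"].iloc[0] == pytest.approx(
            0.4 - 0.05 - 0.04, abs=1e-9)

    def test_imputed_values_clipped_to_unit_interval(self):
        year_eff = {2013: 0.0, 2014: 0.6, 2015: -0.5}
        q_eff = {1: 0.0, 2: 0.5, 3: -0.4, 4: 0.0}
        values = {(y, q): min(1.0, max(0.0, 0.5 + year_eff[y] + q_eff[q]))
                  for y in year_eff for q in q_eff}
        table = balanced_table(values, missing_cells={(2014, 2), (2015, 3)})
        out = impute_composition_emm(table)
        assert out["mean_proportion"].between(0, 1).all()

    def test_species_with_no_observations_raises(self):
        table = balanced_table({(2013, 1): np.nan}, missing_cells={(2013, 1)})
        with pytest.raises(ValueError, match="SKJ"):
            impute_composition_emm(table)


class TestEstimateM:
    def _composition(self, prop):
        return balanced_table({(2013, 1): prop})

    def test_product_of_means(self, one_region):
        sets = make_sets(25, [f"T{i}" for i in range(25)], [20.0] * 25,
                         [True] * 25)
        sets["corrected_catch"] = sets["declared_catch"]
        out = estimate_m(sets, self._composition(0.6), one_region)
        assert out["m_hat"].iloc[0] == pytest.approx(12.0)
        assert out["n_sets"].iloc[0] == 25

    def test_under_twenty_sets_excluded(self, one_region):
        sets = make_sets(19, [f"T{i}" for i in range(19)], [20.0] * 19,
                         [True] * 19)
        sets["corrected_catch"] = sets["declared_catch"]
        out = estimate_m(sets, self._composition(0.6), one_region)
        assert len(out) == 0

    def test_matches_independent_recomputation_and_order_invariance(
            self, one_region, rng):
        catches = rng.uniform(5, 50, 40)
        sets = make_sets(40, [f"T{i}" for i in range(40)], catches, [True] * 40)
        sets["corrected_catch"] = sets["declared_catch"]
        comp = self._composition(0.37)
        out = estimate_m(sets, comp, one_region)
        assert out["m_hat"].iloc[0] == pytest.approx(catches.mean() * 0.37)
        shuffled = estimate_m(sets.sample(frac=1, random_state=3), comp, one_region)
        assert shuffled["m_hat"].iloc[0] == out["m_hat"].iloc[0]

    def test_missing_composition_stratum_raises(self, one_region):
        sets = make_sets(25, [f"T{i}" for i in range(25)], [20.0] * 25,
                         [True] * 25)
        sets["corrected_catch"] = sets["declared_catch"]
        comp = self._composition(0.6)
        comp["year"] = 1999  # wrong stratum
        with pytest.raises(ValueError, match="absent from the composition"):
            estimate_m(sets, comp, one_region)

    def test_species_sum_bounded_by_mean_catch(self, one_region, rng):
        n = 30
        sets = make_sets(n, [f"T{i}" for i in range(n)],
                         rng.uniform(5, 50, n), [True] * n)
        sets["corrected_catch"] = sets["declared_catch"]
        comp = pd.concat([
            balanced_table({(2013, 1): 0.55}),
            balanced_table({(2013, 1): 0.35}).assign(species="YFT<10kg"),
        ], ignore_index=True)
        out = estimate_m(sets, comp, one_region)
        assert out["m_hat"].sum() <= sets["corrected_catch"].mean() + 1e-12

    def test_law_of_large_numbers_convergence(self, one_region, rng):
        """With constant true proportions, m-hat -> mean set size x proportion."""
        n = 10_000
        true_mean, prop = 25.0, 0.6
        catches = rng.gamma(4.0, true_mean / 4.0, n)
        sets = make_sets(n, [f"T{i // 10}" for i in range(n)], catches, [True] * n)
        sets["corrected_catch"] = sets["declared_catch"]
        out = estimate_m(sets, self._composition(prop), one_region)
        assert out["m_hat"].iloc[0] == pytest.approx(true_mean * prop, rel=0.02)
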