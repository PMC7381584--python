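import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollinet.preference_null import (MarginalError, SiteWeekMatrix,
                                      aggregate_species_preference,
                                      build_site_week_matrix,
                                      compute_preferences, null_ensemble,
                                      preference_indices, preference_model,
                                      proportional_abundance,
                                      round_preserving_sum,
                                      sample_decimal_table,
                                      sample_decimal_tables,
                                      sample_integer_table,
                                      sample_integer_tables, sample_one_dim,
                                      table_pmf)


class TestProportionalAbundance:
    def test_shares(self):
        assert proportional_abundance({"A": 60, "B": 20, "C": 20}) == \
            {"A": 0.6, "B": 0.2, "C": 0.2}

    def test_single_plant(self):
        assert proportional_abundance({"A": 7.5}) == {"A": 1.0}

    def test_zero_entry(self):
        assert proportional_abundance({"A": 0, "B": 10}) == {"A": 0.0,
                                                             "B": 1.0}

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            proportional_abundance({"A": 0.0, "B": 0.0})


def rates_frame(entries):
    return pd.DataFrame(
        [{"site": "S1", "week": 1, "pollinator_type": t, "plant_id": p,
          "rate": r} for (t, p), r in entries.items()])


class TestBuildSiteWeekMatrix:
    def test_multiply_arithmetic(self):
        m = build_site_week_matrix(
            rates_frame({("honey_bee", "A"): 0.1, ("honey_bee", "B"): 0.0,
                         ("wild", "A"): 0.2, ("wild", "B"): 0.1}),
            {"A": 0.5, "B": 0.5})
        expect = np.array([[0.05, 0.0], [0.1, 0.05]])
        np.testing.assert_allclose(m.values, expect)
        assert m.row_labels == ("honey_bee", "wild")
        assert not m.one_dimensional

    def test_none_is_identity(self):
        m = build_site_week_matrix(
            rates_frame({("honey_bee", "A"): 0.1, ("wild", "A"): 0.2}),
            {"A": 1.0}, scaling_mode="none")
        np.testing.assert_allclose(m.values, [[0.1], [0.2]])

    def test_divide_mode(self):
        m = build_site_week_matrix(
            rates_frame({("honey_bee", "A"): 0.1, ("wild", "A"): 0.2}),
            {"A": 0.5}, scaling_mode="divide")
        np.testing.assert_allclose(m.values, [[0.2], [0.4]])

    def test_divide_drops_zero_share_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            m = build_site_week_matrix(
                rates_frame({("wild", "A"): 0.2, ("wild", "B"): 0.1,
                             ("honey_bee", "A"): 0.1,
                             ("honey_bee", "B"): 0.0}),
                {"A": 1.0, "B": 0.0}, scaling_mode="divide")
        assert m.col_labels == ("A",)

    def test_honey_bee_row_omitted_when_all_zero(self):
        m = build_site_week_matrix(
            rates_frame({("honey_bee", "A"): 0.0, ("honey_bee", "B"): 0.0,
                         ("wild", "A"): 0.2, ("wild", "B"): 0.1}),
            {"A": 0.5, "B": 0.5})
        assert m.one_dimensional
        assert m.row_labels == ("wild",)
        assert m.values.shape == (1, 2)


class TestIntegerSampler:
    def test_two_permutation_matrices_equiprobable(self, rng):
        draws = sample_integer_tables([1, 1], [1, 1], 4000, rng)
        n_diag = int((draws[:, 0, 0] == 1).sum())
        # exact pmf gives 1/2 each; 4000 draws, 4 sigma band
        assert abs(n_diag / 4000 - 0.5) < 4 * 0.5 / np.sqrt(4000)

    def test_2x2_pmf_enumeration(self, rng):
        # oracle: brute-force pmf (prod r_i!)(prod c_j!)/(N! prod n_ij!)
        pmf = table_pmf([2, 1], [2, 1])
        probs = {np.frombuffer(k, dtype=np.int64)[0]: v
                 for k, v in pmf.items()}
        assert probs[2] == pytest.approx(1 / 3)
        assert probs[1] == pytest.approx(2 / 3)
        draws = sample_integer_tables([2, 1], [2, 1], 30000, rng)
        n11 = draws[:, 0, 0]
        assert np.mean(n11 == 2) == pytest.approx(1 / 3, abs=0.02)
        # E[n11] = r1 c1 / N = 4/3
        assert n11.mean() == pytest.approx(4 / 3, abs=0.03)

    def test_degenerate_row_forced(self, rng):
        t = sample_integer_table([5, 0], [2, 3], rng)
        np.testing.assert_array_equal(t, [[2, 3], [0, 0]])

    def test_marginal_mismatch_raises(self, rng):
        with pytest.raises(MarginalError, match="mismatch"):
            sample_integer_table([2, 1], [1, 1], rng)

    def test_negative_marginal_raises(self, rng):
        with pytest.raises(MarginalError):
            sample_integer_table([-1, 2], [1, 0], rng)

    @given(r=st.lists(st.integers(0, 12), min_size=1, max_size=4),
           c_split=st.integers(1, 4), seed=st.integers(0, 2**31))
    @settings(max_examples=40, deadline=None)
    def test_marginals_conserved_exactly(self, r, c_split, seed):
        total = sum(r)
        gen = np.random.default_rng(seed)
        # random column composition of the same grand total
        cuts = np.sort(gen.integers(0, total + 1, size=c_split - 1)) \
            if c_split > 1 else np.array([], dtype=int)
        c = np.diff(np.concatenate([[0], cuts, [total]]))
        draws = sample_integer_tables(r, c, 50, gen)
        np.testing.assert_array_equal(draws.sum(axis=2),
                                      np.tile(r, (50, 1)))
        np.testing.assert_array_equal(draws.sum(axis=1),
                                      np.tile(c, (50, 1)))


class TestDecimalSampler:
    def test_construction_example(self, rng):
        t = sample_decimal_table([0.12, 0.08], [0.15, 0.05], rng, g=1000)
        np.testing.assert_allclose(t.sum(axis=1), [0.12, 0.08], atol=1e-3)
        np.testing.assert_allclose(t.sum(axis=0), [0.15, 0.05], atol=1e-3)
        # marginals are exact multiples of 1/g here
        np.testing.assert_allclose(t.sum(axis=1), [0.12, 0.08], atol=1e-12)

    def test_cell_expectation_matches_closed_form(self, rng):
        r = np.array([0.3, 0.7])
        c = np.array([0.45, 0.4, 0.15])
        n = 20000
        draws = sample_decimal_tables(r, c, n, rng, g=10_000)
        expect = np.outer(r, c) / r.sum()
        se = draws.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - expect) <= 3 * se + 1e-12)

    def test_zero_column_stays_zero(self, rng):
        draws = sample_decimal_tables([0.5, 0.5], [1.0, 0.0], 200, rng)
        assert np.all(draws[:, :, 1] == 0)

    def test_granularity_escalation(self, rng):
        # 1e-5 * 100 rounds to zero; g must escalate until it does not
        t = sample_decimal_table([1e-5, 1.0 - 1e-5], [0.5, 0.5], rng, g=100)
        assert t.sum() == pytest.approx(1.0, abs=1e-4)
        assert t[0].sum() > 0

    def test_escalation_cap_raises(self, rng):
        with pytest.raises(MarginalError, match="granularity"):
            sample_decimal_table([1e-12, 1.0], [0.5, 0.5 + 1e-12], rng,
                                 g=100)

    def test_marginal_mismatch_raises(self, rng):
        with pytest.raises(MarginalError):
            sample_decimal_table([0.5, 0.5], [0.8, 0.3], rng)

    def test_low_granularity_rejected(self, rng):
        with pytest.raises(ValueError, match="granularity"):
            sample_decimal_table([0.5], [0.5], rng, g=10)


class TestRoundPreservingSum:
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1,
                    max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_sum_exact_and_entries_close(self, values):
        target = int(round(sum(values)))
        out = round_preserving_sum(values, target)
        assert out.sum() == target
        assert np.all(np.abs(out - np.asarray(values)) <= 1.0 + 1e-9)


class TestOneDim:
    def test_zero_total(self, rng):
        np.testing.assert_array_equal(sample_one_dim(0.0, 4, rng)[0],
                                      np.zeros(4))

    def test_single_cell_identity(self, rng):
        np.testing.assert_allclose(sample_one_dim(0.37, 1, rng)[0], [0.37])

    def test_multinomial_expectation(self, rng):
        draws = sample_one_dim(1.0, 4, rng, g=10_000, size=10_000)
        se = draws.std(axis=0, ddof=1) / np.sqrt(10_000)
        assert np.all(np.abs(draws.mean(axis=0) - 0.25) <= 3 * se)

    def test_sums_conserved(self, rng):
        draws = sample_one_dim(0.731, 5, rng, g=10_000, size=100)
        np.testing.assert_allclose(draws.sum(axis=1), 0.731, atol=1e-4)

    def test_no_cells_raises(self, rng):
        with pytest.raises(ValueError):
            sample_one_dim(1.0, 0, rng)


def fixed_matrix(values, one_dimensional=False):
    values = np.asarray(values, dtype=float)
    rows = ("wild",) if values.shape[0] == 1 else ("honey_bee", "wild")
    return SiteWeekMatrix(site="S1", week=1, row_labels=rows,
                          col_labels=tuple(f"P{j}" for j in
                                           range(values.shape[1])),
                          values=values, one_dimensional=one_dimensional)


class TestPreferenceIndices:
    def test_observed_minus_expected(self, rng):
        m = fixed_matrix([[0.10, 0.02], [0.04, 0.08]])
        out = preference_indices(m, n_replicates=2000, rng=rng)
        cell = out[(out.pollinator_type == "honey_bee")
                   & (out.plant_id == "P0")].iloc[0]
        assert cell["preference"] == pytest.approx(
            cell["observed"] - cell["expected"])
        # E[null cell] = r c / N
        assert cell["expected"] == pytest.approx(
            0.12 * 0.14 / 0.24, abs=4 * cell["mc_se"] + 1e-4)

    def test_single_plant_forced_null(self, rng):
        m = fixed_matrix([[0.10], [0.04]])
        out = preference_indices(m, n_replicates=50, rng=rng)
        assert np.allclose(out["preference"], 0.0, atol=1e-12)

    def test_one_dimensional_path(self, rng):
        m = fixed_matrix([[0.3, 0.1]], one_dimensional=True)
        out = preference_indices(m, n_replicates=3000, rng=rng)
        assert set(out["pollinator_type"]) == {"wild"}
        # 1-D null allocates the total uniformly: expected 0.2 per cell
        np.testing.assert_allclose(out["expected"], 0.2, atol=0.01)

    def test_zero_sum_within_site_week(self, rng):
        m = fixed_matrix([[0.11, 0.02, 0.05], [0.04, 0.08, 0.01]])
        g = 10_000
        out = preference_indices(m, n_replicates=500, rng=rng, g=g)
        assert abs(out["preference"].sum()) <= m.values.size / g


class TestComputePreferences:
    def _inputs(self):
        rates = pd.DataFrame([
            {"site": "S1", "week": w, "plant_id": p, "pollinator_type": t,
             "rate": r}
            for w, cells in [(1, {("honey_bee", "A"): 0.1,
                                  ("wild", "A"): 0.2,
                                  ("honey_bee", "B"): 0.05,
                                  ("wild", "B"): 0.0}),
                             (2, {("honey_bee", "A"): 0.0,
                                  ("wild", "A"): 0.3,
                                  ("honey_bee", "B"): 0.0,
                                  ("wild", "B"): 0.1})]
            for (t, p), r in cells.items()])
        abund = pd.DataFrame({"site": "S1", "plant_id": ["A", "B"],
                              "abundance": [60.0, 20.0]})
        return rates, abund

    def test_determinism(self):
        rates, abund = self._inputs()
        a = compute_preferences(rates, abund, n_replicates=200, seed=42)
        b = compute_preferences(rates, abund, n_replicates=200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_changes_results(self):
        rates, abund = self._inputs()
        a = compute_preferences(rates, abund, n_replicates=200, seed=1)
        b = compute_preferences(rates, abund, n_replicates=200, seed=2)
        assert not np.allclose(a["expected"], b["expected"])

    def test_honey_bee_absent_week_uses_one_dim(self):
        rates, abund = self._inputs()
        out = compute_preferences(rates, abund, n_replicates=100, seed=0)
        wk2 = out[out["week"] == 2]
        assert wk2["one_dimensional"].all()
        assert set(wk2["pollinator_type"]) == {"wild"}

    def test_missing_abundance_raises(self):
        rates, abund = self._inputs()
        with pytest.raises(KeyError, match="abundance"):
            compute_preferences(rates, abund[abund.plant_id != "B"],
                                n_replicates=10, seed=0)


class TestAggregateSpeciesPreference:
    def test_mean(self):
        df = pd.DataFrame({
            "pollinator_type": ["wild"] * 2, "plant_id": ["A"] * 2,
            "preference": [0.1, 0.12]})
        out = aggregate_species_preference(df)
        assert out.loc[0, "mean_preference"] == pytest.approx(0.11)
        assert out.loc[0, "n_site_weeks"] == 2

    def test_single_value_identity(self):
        df = pd.DataFrame({"pollinator_type": ["wild"], "plant_id": ["A"],
                           "preference": [0.07]})
        assert aggregate_species_preference(df).loc[0, "mean_preference"] \
            == pytest.approx(0.07)

    def test_ranking_descending(self):
        df = pd.DataFrame({
            "pollinator_type": ["wild"] * 3,
            "plant_id": ["A", "B", "C"],
            "preference": [0.05, 0.2, -0.1]})
        out = aggregate_species_preference(df)
        assert list(out["plant_id"]) == ["B", "A", "C"]
        assert list(out["rank"]) == [1, 2, 3]


class TestPreferenceModel:
    def test_single_pollinator_type_raises(self, plants_df):
        df = pd.DataFrame({
            "site": "S1", "week": 1, "plant_id": ["A", "B"],
            "pollinator_type": "wild", "preference": [0.1, -0.1]})
        with pytest.raises(ValueError, match="pollinator_type"):
            preference_model(df, plants_df)

    def test_fits_and_reports_lrts(self, small_dataset):
        from pollinet.io_schema import filter_visits
        from pollinet.visitation_models import long_rates_table

        t = long_rates_table(filter_visits(small_dataset.observations))
        rates = t[["site", "week", "plant_id", "pollinator_type", "rate"]]
        prefs = compute_preferences(rates, small_dataset.abundance,
                                    n_replicates=100, seed=7)
        fit, lrts, means = preference_model(prefs, small_dataset.plants)
        assert set(lrts["term"]) == {"native_status:pollinator_type",
                                     "native_status", "pollinator_type"}
        assert ((lrts["p"] >= 0) & (lrts["p"] <= 1)).all()
        assert (lrts["chi2"] >= 0).all()
        assert len(means) == 4


def test_null_ensemble_marginal_conservation(rng):
    m = fixed_matrix([[0.11, 0.02, 0.05], [0.04, 0.08, 0.01]])
    g = 10_000
    reps = sample_decimal_tables(m.row_sums, m.col_sums, 500, rng, g=g)
    assert np.all(np.abs(reps.sum(axis=2) - m.row_sums) <= 1 / g + 1e-12)
    assert np.all(np.abs(reps.sum(axis=1) - m.col_sums) <= 1 / g + 1e-12)


def test_self_consistency_null_generated_data(rng):
    # observed matrices drawn from the null itself: mean preference ~ 0
    r = np.array([0.2, 0.5])
    c = np.array([0.25, 0.3, 0.15])
    prefs = []
    for _ in range(60):
        m = fixed_matrix(sample_decimal_table(r, c, rng))
        out = preference_indices(m, n_replicates=300, rng=rng)
        prefs.extend(out["preference"])
    prefs = np.array(prefs)
    se = prefs.std(ddof=1) / np.sqrt(len(prefs))
    assert abs(prefs.mean()) <= 3 * se + 1e-9
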