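import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genoscape import (
    AlleleFreqTable,
    CumulativeImportanceFunction,
    GradientForestParams,
    cumulative_importance,
    filter_snps_by_maf,
    fit_gradient_forest,
    overall_importance,
    select_significant_snps,
)


def make_table(freqs: np.ndarray, snp_ids=None) -> AlleleFreqTable:
    n_sites, n_snps = freqs.shape
    return AlleleFreqTable(
        site_ids=[f"s{i}" for i in range(n_sites)],
        coordinates=np.column_stack([np.linspace(9, 10, n_sites), np.linspace(6, 7, n_sites)]),
        snp_ids=snp_ids or [f"snp{j}" for j in range(n_snps)],
        frequencies=freqs,
    )


class TestAlleleFreqTable:
    def test_rejects_out_of_range_frequencies(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            make_table(np.array([[0.5, 1.2], [0.5, 0.5]]))

    def test_rejects_missing_coordinates(self):
        t = make_table(np.full((3, 2), 0.5))
        t.coordinates[0, 0] = np.nan
        with pytest.raises(ValueError):
            AlleleFreqTable(t.site_ids, t.coordinates, t.snp_ids, t.frequencies)

    def test_frame_round_trip(self):
        t = make_table(np.random.default_rng(0).uniform(size=(4, 3)))
        back = AlleleFreqTable.from_frame(t.to_frame())
        assert np.array_equal(back.frequencies, t.frequencies)
        assert back.snp_ids == t.snp_ids


class TestMafFilter:
    def test_threshold_arithmetic_on_known_means(self):
        # per-SNP means 0.01, 0.50, 0.985 -> MAFs 0.01, 0.50, 0.015
        freqs = np.tile([0.01, 0.50, 0.985], (4, 1))
        kept = filter_snps_by_maf(make_table(freqs), threshold=0.02)
        assert kept.snp_ids == ["snp1"]

    def test_vanishing_threshold_keeps_all_polymorphic(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.05, 0.95, size=(5, 20))
        kept = filter_snps_by_maf(make_table(freqs), threshold=1e-12)
        assert kept.n_snps == 20

    def test_column_order_preserved(self):
        freqs = np.tile([0.4, 0.01, 0.6, 0.99, 0.5], (4, 1))
        kept = filter_snps_by_maf(make_table(freqs), threshold=0.02)
        assert kept.snp_ids == ["snp0", "snp2", "snp4"]

    def test_empty_result_warns_not_raises(self):
        freqs = np.tile([0.001, 0.999], (4, 1))
        with pytest.warns(UserWarning, match="removed every SNP"):
            kept = filter_snps_by_maf(make_table(freqs), threshold=0.02)
        assert kept.n_snps == 0

    def test_threshold_bounds(self):
        t = make_table(np.full((3, 2), 0.5))
        for bad in (0.0, 0.5, -0.1):
            with pytest.raises(ValueError):
                filter_snps_by_maf(t, threshold=bad)


class TestCumulativeImportanceFunction:
    def test_single_split_step_evaluation(self):
        f = CumulativeImportanceFunction.from_splits("E", [(5.0, 0.4)], start=0.0)
        assert f(4.0) == 0.0
        assert f(6.0) == pytest.approx(0.4)
        assert f(5.0) == pytest.approx(0.4)  # jump at the threshold
        assert f.total_rise == pytest.approx(0.4)

    def test_clamped_extrapolation(self):
        f = CumulativeImportanceFunction.from_splits("E", [(2.0, 0.1), (4.0, 0.3)], start=1.0)
        assert f(-100.0) == 0.0
        assert f(100.0) == pytest.approx(0.4)

    def test_duplicate_thresholds_merge(self):
        f = CumulativeImportanceFunction.from_splits("E", [(3.0, 0.1), (3.0, 0.2)], start=0.0)
        assert f(3.5) == pytest.approx(0.3)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            CumulativeImportanceFunction("E", [0.0, 0.0], [0.0, 1.0])  # non-increasing bp
        with pytest.raises(ValueError):
            CumulativeImportanceFunction("E", [0.0, 1.0], [0.5, 1.0])  # starts off 0
        with pytest.raises(ValueError):
            CumulativeImportanceFunction("E", [0.0, 1.0, 2.0], [0.0, 0.5, 0.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=2))
    def test_monotone_on_random_pairs(self, pair):
        f = CumulativeImportanceFunction.from_splits(
            "E", [(-10.0, 0.1), (0.0, 0.25), (10.0, 0.05)], start=-20.0
        )
        x1, x2 = sorted(pair)
        assert f(x1) <= f(x2) + 1e-15


@pytest.fixture(scope="module")
def step_snp_model():
    """One SNP that is an exact step in E1, two noise predictors."""
    rng = np.random.default_rng(21)
    n = 16
    E1 = np.linspace(0.0, 1.0, n)
    env = pd.DataFrame(
        {"E1": E1, "N1": rng.normal(size=n), "N2": rng.normal(size=n)}
    )
    y = np.where(E1 > np.median(E1), 0.9, 0.1)
    table = make_table(y[:, None])
    models = [
        fit_gradient_forest(table, env, GradientForestParams(n_trees=200), seed=s)
        for s in range(5)
    ]
    return env, table, models


class TestFitGradientForest:
    def test_step_snp_ranks_its_predictor_first(self, step_snp_model):
        """Rank oracle: pooled per-predictor improvement, 5 refit seeds."""
        _, _, models = step_snp_model
        for m in models:
            assert overall_importance(m)[0][0] == "E1"
            # oracle: raw pooled improvements dominate on E1 too
            rec = m.fits[0]
            raw = {p: a[:, 1].sum() if a.size else 0.0 for p, a in rec.per_predictor_importance.items()}
            assert max(raw, key=raw.get) == "E1"

    def test_overall_importance_equals_total_rise(self, step_snp_model):
        _, _, models = step_snp_model
        m = models[0]
        for p in m.predictor_names:
            assert m.overall[p] == pytest.approx(m.cif[p].total_rise, abs=1e-9)

    def test_nonpositive_r2_snps_contribute_nothing(self):
        rng = np.random.default_rng(5)
        env = pd.DataFrame({"E1": np.linspace(0, 1, 12), "E2": rng.normal(size=12)})
        freqs = rng.uniform(0.3, 0.7, size=(12, 30))
        model = fit_gradient_forest(make_table(freqs), env, GradientForestParams(n_trees=80), seed=9)
        noise_total = sum(
            m.cif[p].total_rise
            for m, p in [(model, p) for p in model.predictor_names]
        )
        r2 = model.oob_r2()
        pos_weight = np.maximum(r2.to_numpy(), 0).sum() / len(r2)
        assert noise_total <= pos_weight + 1e-9  # only positive-R² SNPs feed F

    def test_all_negative_r2_gives_zero_functions(self):
        env = pd.DataFrame({"E1": np.linspace(0, 1, 10)})
        # two anti-patterned SNPs the forest cannot generalize: alternating
        freqs = np.column_stack([np.tile([0.1, 0.9], 5), np.tile([0.9, 0.1], 5)])
        model = fit_gradient_forest(make_table(freqs), env, GradientForestParams(n_trees=60), seed=3)
        if (model.oob_r2() <= 0).all():
            for p in model.predictor_names:
                assert model.cif[p].total_rise == 0.0

    def test_constant_predictor_warns_and_gets_zero_function(self):
        env = pd.DataFrame({"E1": np.linspace(0, 1, 10), "flat": np.full(10, 3.0)})
        freqs = np.linspace(0.1, 0.9, 10)[:, None]
        with pytest.warns(UserWarning, match="flat"):
            model = fit_gradient_forest(make_table(freqs), env, GradientForestParams(n_trees=50), seed=0)
        assert model.cif["flat"].total_rise == 0.0

    def test_constant_snp_recorded_with_zero_r2_and_no_splits(self):
        env = pd.DataFrame({"E1": np.linspace(0, 1, 10)})
        freqs = np.column_stack([np.full(10, 0.5), np.linspace(0.1, 0.9, 10)])
        model = fit_gradient_forest(make_table(freqs), env, GradientForestParams(n_trees=50), seed=0)
        rec = model.fits[0]
        assert rec.oob_r2 == 0.0
        assert all(a.size == 0 for a in rec.per_predictor_importance.values())

    def test_missing_cells_drop_sites_and_sparse_snps_skipped(self):
        env = pd.DataFrame({"E1": np.linspace(0, 1, 10)})
        freqs = np.random.default_rng(2).uniform(0.2, 0.8, size=(10, 3))
        freqs[3, 0] = np.nan  # one missing cell: SNP still fit on 9 sites
        freqs[:7, 1] = np.nan  # only 3 informative sites: skipped
        model = fit_gradient_forest(make_table(freqs), env, GradientForestParams(n_trees=50), seed=1)
        assert [f.snp_id for f in model.fits] == ["snp0", "snp2"]
        assert model.snp_site_mask["snp0"].sum() == 9

    def test_determinism_breakpoint_by_breakpoint(self, small_bundle):
        filt = filter_snps_by_maf(small_bundle.freqs)
        sub = filt.subset_snps(np.arange(30))
        env = small_bundle.env_at_sites()
        params = GradientForestParams(n_trees=120)
        a = fit_gradient_forest(sub, env, params, seed=5)
        b = fit_gradient_forest(sub, env, params, seed=5)
        for p in a.predictor_names:
            assert np.array_equal(a.cif[p].breakpoints, b.cif[p].breakpoints)
            assert np.array_equal(a.cif[p].cumulative, b.cif[p].cumulative)

    def test_too_few_sites_rejected(self):
        env = pd.DataFrame({"E1": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="5 sites"):
            fit_gradient_forest(make_table(np.full((3, 1), 0.5)), env)


class TestSelection:
    def test_selected_set_is_stored_and_subset_of_panel(self, small_model, small_bundle):
        assert small_model.significant_snps is not None
        assert small_model.significant_snps <= set(small_model.snp_ids)

    def test_empirical_null_nested_in_r2_positive(self, small_model):
        strict = set(small_model.significant_snps)
        loose = select_significant_snps(small_model, criterion="r2_positive")
        assert strict <= loose

    def test_all_nonpositive_r2_selects_nothing(self):
        env = pd.DataFrame({"E1": np.linspace(0, 1, 10)})
        freqs = np.column_stack([np.tile([0.1, 0.9], 5), np.tile([0.85, 0.15], 5)])
        model = fit_gradient_forest(make_table(freqs), env, GradientForestParams(n_trees=60), seed=4)
        if (model.oob_r2() <= 0).all():
            assert select_significant_snps(model, criterion="r2_positive") == set()
            assert select_significant_snps(model, criterion="empirical_null") == set()

    def test_unknown_criterion_rejected(self, small_model):
        with pytest.raises(ValueError, match="criterion"):
            select_significant_snps(small_model, criterion="magic")


class TestAccessors:
    def test_unknown_predictor_error_lists_known(self, small_model):
        with pytest.raises(KeyError, match="tmin"):
            cumulative_importance(small_model, "bathymetry")

    def test_ranking_is_descending_with_lexicographic_ties(self):
        from genoscape.gea import GradientForestModel

        cif = {
            "b": CumulativeImportanceFunction.from_splits("b", [(0.0, 0.2)], start=-1),
            "a": CumulativeImportanceFunction.from_splits("a", [(0.0, 0.2)], start=-1),
            "c": CumulativeImportanceFunction.from_splits("c", [(0.0, 0.7)], start=-1),
        }
        m = GradientForestModel(
            predictor_names=list(cif),
            fits=[],
            cif=cif,
            overall={p: f.total_rise for p, f in cif.items()},
            params=GradientForestParams(),
            seed=0,
            env_at_sites=pd.DataFrame(columns=list(cif)),
        )
        ranked = overall_importance(m)
        assert [p for p, _ in ranked] == ["c", "a", "b"]
        assert ranked[0][1] == pytest.approx(0.7)

    def test_singleton_predictor_ranked_first_with_its_rise(self, step_snp_model):
        env, table, _ = step_snp_model
        model = fit_gradient_forest(
            table, env[["E1"]], GradientForestParams(n_trees=100), seed=1
        )
        ((name, imp),) = overall_importance(model)
        assert name == "E1"
        assert imp == pytest.approx(model.cif["E1"].total_rise)
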