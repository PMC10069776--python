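"""Candidate imputers: oracles on toy tables, invariants, determinism."""

import numpy as np
import pandas as pd
import pytest

import phyloimpute as pi
from phyloimpute.imputers import (
    ImputationConfig,
    gower_distances,
    impute_knn,
    impute_mean_mode,
    impute_mice,
    impute_missforest,
    select_auxiliary_traits,
    tune_parameters,
)
from phyloimpute.traits import TraitSpec, TraitTable, TraitTableError

nan = np.nan


def _tab(columns, specs, index=None):
    index = index or [f"s{i}" for i in range(len(next(iter(columns.values()))))]
    return TraitTable(data=pd.DataFrame(columns, index=index), specs=tuple(specs))


class TestScreening:
    def test_strong_linear_association_retained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = 2 * x + rng.normal(size=200)
        t = _tab({"y": y, "x": x, "noise": rng.normal(size=200)},
                 [TraitSpec("y", "continuous"), TraitSpec("x", "continuous"),
                  TraitSpec("noise", "continuous")])
        assert "x" in select_auxiliary_traits(t, "y")

    def test_independent_auxiliary_retained_at_alpha_rate(self):
        hits = 0
        runs = 200
        for s in range(runs):
            rng = np.random.default_rng(s)
            t = _tab({"y": rng.normal(size=60), "x": rng.normal(size=60)},
                     [TraitSpec("y", "continuous"), TraitSpec("x", "continuous")])
            hits += "x" in select_auxiliary_traits(t, "y")
        # binomial(200, 0.05): mean 10, sd ~3
        assert hits / runs < 0.12

    def test_target_never_its_own_auxiliary(self):
        rng = np.random.default_rng(1)
        t = _tab({"y": np.round(rng.poisson(3.0, 100)).astype(float),
                  "x": rng.normal(size=100)},
                 [TraitSpec("y", "count"), TraitSpec("x", "continuous")])
        assert "y" not in select_auxiliary_traits(t, "y")


class TestMeanMode:
    def test_mean_fill(self):
        t = _tab({"x": [1.0, 2.0, nan]}, [TraitSpec("x", "continuous")])
        out = impute_mean_mode(t)
        assert out.table.data.at["s2", "x"] == pytest.approx(1.5)
        assert out.imputed_cells == {("s2", "x")}

    def test_mode_fill(self):
        t = _tab({"c": ["a", "a", "b", None]}, [TraitSpec("c", "binary", categories=("a", "b"))])
        out = impute_mean_mode(t)
        assert out.table.data.at["s3", "c"] == "a"

    def test_complete_table_unchanged(self):
        t = _tab({"x": [1.0, 2.0]}, [TraitSpec("x", "continuous")])
        out = impute_mean_mode(t)
        assert out.imputed_cells == frozenset()
        pd.testing.assert_frame_equal(out.table.data, t.data)


class TestKNN:
    def test_identical_donor_k1_copies_value(self):
        t = _tab(
            {"y": [10.0, 20.0, nan], "a": [1.0, 5.0, 1.0], "b": [2.0, 9.0, 2.0]},
            [TraitSpec("y", "continuous"), TraitSpec("a", "continuous"), TraitSpec("b", "continuous")],
        )
        out = impute_knn(t, {"y": ["a", "b"]}, k_neighbors=1)
        assert out.table.data.at["s2", "y"] == 10.0

    def test_gower_matches_brute_force_on_toy(self):
        t = _tab(
            {
                "y": [1.0, 2.0, 3.0, nan],
                "a": [0.0, 5.0, 10.0, 2.0],
                "c": ["u", "v", "u", "v"],
            },
            [TraitSpec("y", "continuous"), TraitSpec("a", "continuous"),
             TraitSpec("c", "binary", categories=("u", "v"))],
        )
        d = gower_distances(t, ["a", "c"], pd.Index(["s3"]), pd.Index(["s0", "s1", "s2"]))
        # ranges: a in [0,10]; hand Gower = mean(|da|/10, mismatch)
        expect = {
            "s0": (2 / 10 + 1) / 2,
            "s1": (3 / 10 + 0) / 2,
            "s2": (8 / 10 + 1) / 2,
        }
        for sp, e in expect.items():
            assert d.loc["s3", sp] == pytest.approx(e)

    def test_k_all_donors_equals_median_of_all(self):
        t = _tab(
            {"y": [1.0, 2.0, 9.0, nan], "a": [0.0, 1.0, 2.0, 3.0]},
            [TraitSpec("y", "continuous"), TraitSpec("a", "continuous")],
        )
        out = impute_knn(t, {"y": ["a"]}, k_neighbors=3)
        assert out.table.data.at["s3", "y"] == pytest.approx(2.0)

    def test_k_exceeding_donors_rejected(self):
        t = _tab({"y": [1.0, nan], "a": [0.0, 1.0]},
                 [TraitSpec("y", "continuous"), TraitSpec("a", "continuous")])
        with pytest.raises(TraitTableError, match="exceeds"):
            impute_knn(t, {"y": ["a"]}, k_neighbors=2)


class TestMissForest:
    def test_recovers_copied_trait(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        y = x.copy()
        y[:30] = nan
        t = _tab({"y": y, "x": x}, [TraitSpec("y", "continuous"), TraitSpec("x", "continuous")])
        out = impute_missforest(t, {"y": ["x"]}, n_trees=50, seed=0)
        truth = x[:30]
        imputed = out.table.data["y"].values[:30]
        rmse = float(np.sqrt(np.mean((truth - imputed) ** 2)))
        assert rmse < 0.1

    def test_no_missing_is_identity(self):
        t = _tab({"y": [1.0, 2.0], "x": [0.0, 1.0]},
                 [TraitSpec("y", "continuous"), TraitSpec("x", "continuous")])
        out = impute_missforest(t, seed=0)
        pd.testing.assert_frame_equal(out.table.data, t.data)

    def test_no_better_than_mean_mode_on_pure_noise(self):
        """Leakage guard: with uninformative predictors RF ~ mean imputation."""
        ratios = []
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            y = rng.normal(size=80)
            mask = rng.choice(80, 16, replace=False)
            y_missing = y.copy()
            y_missing[mask] = nan
            t = _tab({"y": y_missing, "x": rng.normal(size=80)},
                     [TraitSpec("y", "continuous"), TraitSpec("x", "continuous")])
            rf = impute_missforest(t, {"y": ["x"]}, n_trees=30, seed=s)
            mm = impute_mean_mode(t)
            mse_rf = np.mean((rf.table.data["y"].values[mask] - y[mask]) ** 2)
            mse_mm = np.mean((mm.table.data["y"].values[mask] - y[mask]) ** 2)
            ratios.append(mse_rf / mse_mm)
        # RF must not beat the mean on noise (that would mean truth leakage);
        # being worse is expected, since fitting noise adds variance
        assert np.mean(ratios) > 0.85


class TestMICE:
    def test_m1_pooling_identity(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = x + rng.normal(scale=0.1, size=50)
        y[:5] = nan
        t = _tab({"y": y, "x": x}, [TraitSpec("y", "continuous"), TraitSpec("x", "continuous")])
        out = impute_mice(t, {"y": ["x"]}, m_imputations=1, seed=3)
        for cell, vals in out.per_imputation_values.items():
            assert out.table.data.at[cell] == pytest.approx(vals[0])

    def test_pmm_donor_k1_exact_linear(self):
        # y = x exactly; nearest fitted mean is the nearest donor x
        t = _tab(
            {"y": [1.0, 2.0, 3.0, 4.0, nan], "x": [1.0, 2.0, 3.0, 4.0, 2.2]},
            [TraitSpec("y", "continuous"), TraitSpec("x", "continuous")],
        )
        out = impute_mice(t, {"y": ["x"]}, m_imputations=1, donor_pool_k=1,
                          chain_iterations=2, seed=0)
        assert out.table.data.at["s4", "y"] == 2.0

    def test_pmm_values_are_observed_donors(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        y = 2 * x + rng.normal(size=60)
        y[:12] = nan
        t = _tab({"y": y, "x": x}, [TraitSpec("y", "continuous"), TraitSpec("x", "continuous")])
        out = impute_mice(t, {"y": ["x"]}, m_imputations=3, seed=1)
        observed = set(y[12:])
        for cell, vals in out.per_imputation_values.items():
            assert all(v in observed for v in vals)
        # pooled means stay within the observed range
        imp = out.table.data["y"].values[:12]
        assert imp.min() >= min(observed) and imp.max() <= max(observed)

    def test_categorical_draws_valid_labels(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        c = np.where(x > 0, "yes", "no").astype(object)
        c[:10] = None
        t = _tab({"c": c, "x": x},
                 [TraitSpec("c", "binary", categories=("no", "yes")), TraitSpec("x", "continuous")])
        out = impute_mice(t, {"c": ["x"]}, m_imputations=3, seed=2)
        assert set(out.table.data["c"].unique()) <= {"no", "yes"}


class TestInvariants:
    @pytest.mark.parametrize("method", ["mean_mode", "knn", "rf", "mice"])
    def test_observed_cells_never_altered_and_complete_output(self, method, near80, predictors80):
        _, near = near80
        plan = pi.mask_mcar(near, [0.2], replicate_seed=13)[0]
        masked = pi.apply_mask(near, plan)
        cfg = ImputationConfig(method=method, seed=5, n_trees=20, m_imputations=2)
        out = pi.impute(masked, cfg, predictors80)
        assert not out.table.missing_mask().values.any()
        obs = ~masked.missing_mask()
        for tr in masked.trait_names:
            keep = obs[tr]
            left = masked.data.loc[keep[keep].index, tr]
            right = out.table.data.loc[keep[keep].index, tr]
            assert (left.fillna("~") == right.fillna("~")).all()

    @pytest.mark.parametrize("method", ["knn", "rf", "mice"])
    def test_determinism_same_seed(self, method, near80, predictors80):
        _, near = near80
        plan = pi.mask_mcar(near, [0.1], replicate_seed=17)[0]
        masked = pi.apply_mask(near, plan)
        cfg = ImputationConfig(method=method, seed=21, n_trees=20, m_imputations=2)
        a = pi.impute(masked, cfg, predictors80)
        b = pi.impute(masked, cfg, predictors80)
        pd.testing.assert_frame_equal(a.table.data, b.table.data)

    def test_mean_mode_rejects_phylogeny_source(self):
        with pytest.raises(TraitTableError):
            ImputationConfig(method="mean_mode", phylogeny_source="COI")

    def test_eigenvector_columns_never_imputed(self, near80, predictors80):
        tree, near = near80
        ev = pi.extract_eigenvectors(tree, near.species)
        aug = pi.augment_with_eigenvectors(near, ev)
        plan = pi.mask_mcar(aug, [0.2], replicate_seed=19)[0]
        masked = pi.apply_mask(aug, plan)
        out = pi.impute(masked, ImputationConfig(method="knn", seed=1), predictors80)
        assert all(tr not in aug.aux_columns for _, tr in out.imputed_cells)


class TestAugment:
    def test_appends_exactly_k_columns(self, near80):
        tree, near = near80
        ev = pi.extract_eigenvectors(tree, near.species)
        aug = pi.augment_with_eigenvectors(near, ev)
        assert len(aug.data.columns) == len(near.data.columns) + ev.k
        pd.testing.assert_frame_equal(
            aug.missing_mask(), near.missing_mask().loc[aug.species]
        )

    def test_species_mismatch_excluded_with_warning(self, near80):
        tree, near = near80
        ev = pi.extract_eigenvectors(tree, near.species[:-1])
        with pytest.warns(UserWarning, match="excluded"):
            aug = pi.augment_with_eigenvectors(near, ev)
        assert near.species[-1] not in aug.species

    def test_duplicate_columns_rejected(self, near80):
        tree, near = near80
        ev = pi.extract_eigenvectors(tree, near.species)
        aug = pi.augment_with_eigenvectors(near, ev)
        with pytest.raises(TraitTableError, match="duplicate"):
            pi.augment_with_eigenvectors(aug, ev)


class TestTuning:
    def test_single_point_returned(self):
        cfg = ImputationConfig(method="knn", k_neighbors=3)
        assert tune_parameters([cfg], lambda c: 1.0) == cfg

    def test_selects_small_k_under_nearest_neighbour_structure(self, near80, predictors80):
        _, near = near80
        plan = pi.mask_mcar(near, [0.2], replicate_seed=23)[0]
        masked = pi.apply_mask(near, plan)

        def evaluate(cfg):
            out = impute_knn(masked, predictors80, config=cfg)
            return pi.score_numeric(out, near, plan, "svl_female")

        grid = [ImputationConfig(method="knn", k_neighbors=k) for k in (3, 25)]
        best = tune_parameters(grid, evaluate)
        assert best.k_neighbors == 3

    def test_tie_breaks_deterministically(self):
        grid = [
            ImputationConfig(method="knn", k_neighbors=7),
            ImputationConfig(method="knn", k_neighbors=2),
        ]
        best = tune_parameters(grid, lambda c: 0.5)
        assert best.k_neighbors == 2

    def test_empty_grid_rejected(self):
        with pytest.raises(TraitTableError, match="empty"):
            tune_parameters([], lambda c: 0.0)
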