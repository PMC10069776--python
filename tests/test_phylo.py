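"""Trees, patristic distances, eigenvector extraction and signal metrics."""

import numpy as np
import pandas as pd
import pytest

import phyloimpute as pi
from phyloimpute.phylo import PhyloError, parse_newick


class TestNewick:
    def test_three_leaf_parse(self):
        t = pi.parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(t.leaf_labels) == ["A", "B", "C"]

    def test_duplicate_labels_rejected(self):
        with pytest.raises(PhyloError, match="duplicate"):
            pi.parse_newick("((A:1,A:1):1,C:2);")

    def test_garbage_rejected(self):
        with pytest.raises(PhyloError):
            pi.parse_newick("this is not a tree")

    def test_round_trip_preserves_distances(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            spec = pi.SimulationSpec(n_taxa=int(rng.integers(4, 15)), seed=int(rng.integers(1e6)))
            tree = pi.simulate_tree(spec)
            back = pi.parse_newick(tree.as_newick())
            d1 = pi.patristic_distances(tree)
            d2 = pi.patristic_distances(back, list(d1.index))
            np.testing.assert_allclose(d1.values, d2.values, atol=1e-9)


class TestPatristic:
    def test_hand_path_sums(self):
        t = pi.parse_newick("((A:1,B:1):1,C:2);")
        D = pi.patristic_distances(t)
        assert D.loc["A", "B"] == pytest.approx(2.0)
        assert D.loc["A", "C"] == pytest.approx(4.0)
        assert np.allclose(np.diag(D.values), 0.0)

    def test_two_leaf_pair(self):
        t = pi.parse_newick("(A:3,B:4);")
        assert pi.patristic_distances(t).loc["A", "B"] == pytest.approx(7.0)

    def test_unknown_species_error(self):
        t = pi.parse_newick("(A:3,B:4);")
        with pytest.raises(PhyloError, match="not in tree"):
            pi.patristic_distances(t, ["A", "Z"])

    def test_four_point_condition_on_additive_trees(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=8, seed=int(rng.integers(1e6))))
            D = pi.patristic_distances(tree).values
            n = D.shape[0]
            for _ in range(50):
                i, j, k, l = rng.choice(n, 4, replace=False)
                sums = sorted([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]])
                assert sums[2] - sums[1] <= 1e-8 * max(1.0, sums[2])

    def test_ultrametric_root_to_tip_depths_equal(self):
        tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=30, seed=4))
        depths = tree._leaf_depths()
        vals = np.array(list(depths.values()))
        assert vals.max() - vals.min() <= 1e-6 * vals.max()


class TestEigenvectors:
    def test_star_tree_closed_form(self):
        # 4-leaf star, unit branches: centered matrix is 2 * centering
        # projector -> eigenvalues (2, 2, 2), each explaining 1/3
        star = pi.parse_newick("(A:1,B:1,C:1,D:1);")
        ev = pi.extract_eigenvectors(star, threshold=0.65)
        assert ev.k == 2
        np.testing.assert_allclose(ev.eigenvalues, [2.0, 2.0], atol=1e-10)
        np.testing.assert_allclose(ev.variance_fractions, [1 / 3, 1 / 3], atol=1e-12)

    def test_threshold_one_retains_all_positive_axes(self):
        star = pi.parse_newick("(A:1,B:1,C:1,D:1);")
        ev = pi.extract_eigenvectors(star, threshold=1.0)
        assert ev.k == 3
        assert ev.cumulative_fraction == pytest.approx(1.0)

    def test_coordinates_reproduce_patristic_distances(self):
        tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=20, seed=8))
        ev = pi.extract_eigenvectors(tree, threshold=1.0)
        D = pi.patristic_distances(tree).loc[ev.species, ev.species].values
        X = ev.coordinates.values
        G = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
        np.testing.assert_allclose(G, D**2, atol=1e-6 * (D.max() ** 2))

    def test_minimality_of_retained_set(self, near80):
        tree, near = near80
        ev = pi.extract_eigenvectors(tree, near.species, threshold=0.65)
        below = ev.cumulative_fraction - ev.variance_fractions[-1]
        assert ev.cumulative_fraction >= 0.65
        assert below < 0.65

    def test_orthogonality_after_centering(self, near80):
        tree, near = near80
        ev = pi.extract_eigenvectors(tree, near.species)
        X = ev.coordinates.values
        Xc = X - X.mean(axis=0)
        G = Xc.T @ Xc
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()


class TestPagelsLambda:
    def _bm_trait(self, tree, lam, seed):
        spec = pi.SimulationSpec(
            n_taxa=tree.n_leaves,
            traits=(pi.SimTrait("x", "continuous", signal_lambda=lam),),
            correlation=np.eye(1),
            pre_missing_fraction=0.0,
            seed=seed,
        )
        return pi.simulate_traits(tree, spec).data["x"]

    def test_recovers_brownian_motion(self):
        tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=100, seed=21))
        ests = [
            pi.pagels_lambda(tree, self._bm_trait(tree, 1.0, s)).value
            for s in range(40)
        ]
        assert abs(np.mean(ests) - 1.0) < 0.05

    def test_recovers_no_signal(self):
        tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=100, seed=22))
        ests = [
            pi.pagels_lambda(tree, self._bm_trait(tree, 0.0, s)).value
            for s in range(40)
        ]
        assert abs(np.mean(ests)) < 0.05

    def test_location_scale_invariance(self):
        tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=50, seed=23))
        y = self._bm_trait(tree, 0.7, 3)
        base = pi.pagels_lambda(tree, y).value
        shifted = pi.pagels_lambda(tree, y + 100.0).value
        scaled = pi.pagels_lambda(tree, y * 3.5).value
        assert shifted == pytest.approx(base, abs=1e-5)
        assert scaled == pytest.approx(base, abs=1e-5)

    def test_star_tree_unidentifiable(self):
        star = pi.parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("ABCDE"))
        est = pi.pagels_lambda(star, y)
        assert est.unidentifiable

    def test_constant_trait_rejected(self):
        tree = pi.parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(PhyloError, match="constant"):
            pi.pagels_lambda(tree, pd.Series([1.0, 1.0, 1.0], index=list("ABC")))

    def test_matches_r_phytools_oracle(self, near80):
        """Cross-check the ML estimate against an independent implementation."""
        import shutil
        import subprocess
        import tempfile

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        tree, near = near80
        y = near.data["svl_female"].dropna()
        ours = pi.pagels_lambda(tree, y).value
        with tempfile.TemporaryDirectory() as td:
            open(f"{td}/tree.nwk", "w").write(tree.as_newick() + "\n")
            y.to_csv(f"{td}/y.csv", header=["y"])
            script = (
                'suppressMessages(library(phytools));'
                f'tr <- read.tree("{td}/tree.nwk");'
                f'd <- read.csv("{td}/y.csv", row.names=1);'
                'y <- setNames(d$y, rownames(d));'
                'tr <- keep.tip(tr, names(y));'
                'cat(phylosig(tr, y, method="lambda")$lambda)'
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
            if out.returncode != 0:
                pytest.skip(f"R oracle failed: {out.stderr[:200]}")
            theirs = float(out.stdout.strip().split()[-1])
        assert ours == pytest.approx(theirs, abs=0.01)


class TestFritzPurvisD:
    def _binary(self, tree, lam, seed, q=0.6):
        spec = pi.SimulationSpec(
            n_taxa=tree.n_leaves,
            traits=(pi.SimTrait("b", "binary", signal_lambda=lam, link="threshold",
                                categories=("no", "yes"), thresholds=(q,)),),
            correlation=np.eye(1),
            pre_missing_fraction=0.0,
            seed=seed,
        )
        return pi.simulate_traits(tree, spec).data["b"]

    def test_shuffled_trait_near_one(self):
        tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=100, seed=31))
        rng = np.random.default_rng(0)
        vals = []
        for s in range(12):
            y = self._binary(tree, 1.0, s)
            y = pd.Series(rng.permutation(y.values), index=y.index)
            vals.append(pi.fritz_purvis_D(tree, y, n_random=300, n_brownian=300, seed=s).value)
        assert abs(np.mean(vals) - 1.0) < 0.1

    def test_threshold_brownian_near_zero(self):
        tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=100, seed=32))
        vals = [
            pi.fritz_purvis_D(tree, self._binary(tree, 1.0, s), n_random=300, n_brownian=300, seed=s).value
            for s in range(12)
        ]
        assert abs(np.mean(vals)) < 0.1

    def test_label_swap_invariance(self):
        tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=60, seed=33))
        y = self._binary(tree, 0.8, 5)
        d1 = pi.fritz_purvis_D(tree, y, n_random=200, n_brownian=200, seed=9).value
        swapped = y.map({"no": "yes", "yes": "no"})
        d2 = pi.fritz_purvis_D(tree, swapped, n_random=200, n_brownian=200, seed=9).value
        assert d2 == pytest.approx(d1, abs=0.15)

    def test_one_category_absent_rejected(self):
        tree = pi.parse_newick("((A:1,B:1):1,C:2);")
        y = pd.Series(["yes", "yes", "yes"], index=list("ABC"))
        with pytest.raises(PhyloError, match="both categories"):
            pi.fritz_purvis_D(tree, y, seed=0)

    def test_null_size_stability(self):
        tree = pi.simulate_tree(pi.SimulationSpec(n_taxa=80, seed=34))
        y = self._binary(tree, 0.5, 7)
        d1 = pi.fritz_purvis_D(tree, y, n_random=1000, n_brownian=1000, seed=1).value
        d2 = pi.fritz_purvis_D(tree, y, n_random=2000, n_brownian=2000, seed=2).value
        assert abs(d1 - d2) <= 0.05 * max(1.0, abs(d1))
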