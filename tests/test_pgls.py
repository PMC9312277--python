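import numpy as np
import pytest

from allomet.allometry import fit_ols
from allomet.io import read_tree
from allomet.pgls import (
    PGLSModel,
    PhyloCovariance,
    apply_lambda,
    estimate_lambda_ml,
    pgls_fit,
    phylo_signal_mass_independent,
    tree_covariance,
)
from allomet.simulate import CladeSimSpec, simulate_clade_data, simulate_clade_tree


def covariance_oracle(tree):
    """Brute force: C[i, j] = sum of lengths of edges on both root-to-tip paths."""
    tree.calc_node_root_distances()
    leaves = list(tree.leaf_node_iter())
    paths = []
    for lf in leaves:
        edges = set()
        node = lf
        while node.parent_node is not None:
            edges.add(id(node.edge))
            node = node.parent_node
        paths.append(edges)
    lengths = {
        id(e): e.length for e in tree.preorder_edge_iter() if e.length is not None
    }
    n = len(leaves)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = paths[i] & paths[j]
            C[i, j] = sum(lengths.get(k, 0.0) for k in shared)
    return [lf.taxon.label for lf in leaves], C


class TestTreeCovariance:
    def test_three_tip_hand_sums(self):
        cov = tree_covariance(read_tree("((A:1,B:1):1,C:2);"))
        i = {l: k for k, l in enumerate(cov.labels)}
        assert cov.C[i["A"], i["A"]] == pytest.approx(2.0)
        assert cov.C[i["A"], i["B"]] == pytest.approx(1.0)
        assert cov.C[i["A"], i["C"]] == pytest.approx(0.0)
        assert cov.C[i["C"], i["C"]] == pytest.approx(2.0)

    def test_star_tree_is_diagonal(self):
        cov = tree_covariance(read_tree("(A:1,B:1,C:1,D:1);"))
        assert np.allclose(cov.C, np.eye(4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_path_enumeration_oracle(self, seed):
        tree = simulate_clade_tree(15, seed=seed)
        cov = tree_covariance(tree)
        labels, C_oracle = covariance_oracle(tree)
        order = [labels.index(l) for l in cov.labels]
        assert np.allclose(cov.C, C_oracle[np.ix_(order, order)], atol=1e-12)


class TestApplyLambda:
    def setup_method(self):
        self.C = tree_covariance(read_tree("((A:1,B:1):1,C:2);")).C

    def test_lambda_one_identity(self):
        assert np.allclose(apply_lambda(self.C, 1.0), self.C)

    def test_lambda_zero_diagonal(self):
        out = apply_lambda(self.C, 0.0)
        assert np.allclose(out, np.diag(np.diag(self.C)))

    def test_half_lambda(self):
        out = apply_lambda(self.C, 0.5)
        assert np.allclose(np.diag(out), np.diag(self.C))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(out[off], 0.5 * self.C[off])

    @pytest.mark.parametrize("lam", [-0.1, 1.1])
    def test_out_of_range_rejected(self, lam):
        with pytest.raises(ValueError):
            apply_lambda(self.C, lam)


class TestPGLSFit:
    def test_identity_covariance_equals_ols(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = 0.5 + 0.7 * x + rng.normal(size=n) * 0.2
            cov = PhyloCovariance(tuple(f"t{i}" for i in range(n)), np.eye(n))
            p = pgls_fit(x, y, cov)
            o = fit_ols(x, y)
            assert abs(p.log10_a - o.log10_a) < 1e-8
            assert abs(p.b - o.b) < 1e-8

    def test_lambda_zero_on_unit_depth_tree_equals_ols(self, rng):
        tree = simulate_clade_tree(25, seed=2)
        cov = tree_covariance(tree)
        x = rng.normal(size=25)
        y = 0.2 + 0.8 * x + rng.normal(size=25) * 0.1
        p = pgls_fit(x, y, cov, lam=0.0)
        o = fit_ols(x, y)
        assert p.log10_a == pytest.approx(o.log10_a, abs=1e-10)
        assert p.b == pytest.approx(o.b, abs=1e-10)

    def test_four_tip_matrix_inversion_oracle(self):
        tree = read_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        cov = tree_covariance(tree)
        x = np.array([0.1, 0.9, 1.4, 2.2])
        y = np.array([0.3, 1.0, 1.1, 2.0])
        fit = pgls_fit(x, y, cov)
        Vi = np.linalg.inv(cov.C)
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert fit.log10_a == pytest.approx(beta[0], abs=1e-10)
        assert fit.b == pytest.approx(beta[1], abs=1e-10)

    def test_singular_covariance_reports_condition(self):
        C = np.ones((4, 4))
        cov = PhyloCovariance(("a", "b", "c", "d"), C)
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            pgls_fit(np.arange(4.0), np.arange(4.0), cov)


class TestLambdaML:
    def _sim(self, lam_true, n, seed):
        tree = simulate_clade_tree(n, seed=seed)
        spec = CladeSimSpec("X", n, 1.5, 0.8, 0.5, 0.7, 0.146, lam_true)
        df = simulate_clade_data(spec, tree, seed=seed + 10_000)
        cov = tree_covariance(tree)
        d = df.set_index("species").loc[list(cov.labels)]
        x = np.log10(d["mass_g"].to_numpy())
        y = np.log10(d["bmr"].to_numpy())
        return x, y, cov

    def test_estimate_within_bounds(self):
        x, y, cov = self._sim(0.5, 60, seed=4)
        lam, ll = estimate_lambda_ml(x, y, cov)
        assert 0.0 <= lam <= 1.0
        assert np.isfinite(ll)

    def test_profile_optimality(self):
        x, y, cov = self._sim(0.6, 80, seed=9)
        model = PGLSModel(x, y, cov)
        lam, ll = model.profile_lambda()
        for grid in (0.0, 0.25, 0.5, 0.75, 1.0):
            assert ll >= model._loglik(grid) - 1e-6

    def test_branch_rescaling_invariance(self):
        x, y, cov = self._sim(0.7, 40, seed=12)
        lam1, _ = estimate_lambda_ml(x, y, cov)
        fit1 = PGLSModel(x, y, cov).fit()
        scaled = PhyloCovariance(cov.labels, 13.7 * cov.C)
        lam2, _ = estimate_lambda_ml(x, y, scaled)
        fit2 = PGLSModel(x, y, scaled).fit()
        assert lam1 == pytest.approx(lam2, abs=1e-4)
        assert fit1.b == pytest.approx(fit2.b, abs=1e-8)

    def test_needs_four_observations(self):
        cov = PhyloCovariance(("a", "b", "c"), np.eye(3))
        with pytest.raises(ValueError):
            estimate_lambda_ml(np.arange(3.0), np.arange(3.0), cov)


class TestMassIndependentSignal:
    def _study(self, lam_true, n, seed):
        from allomet.io import CladeTable

        tree = simulate_clade_tree(n, seed=seed)
        spec = CladeSimSpec("X", n, 1.5, 0.8, 0.5, 0.7, 0.146, lam_true)
        df = simulate_clade_data(spec, tree, seed=seed + 5_000)
        return CladeTable(df, ("X",)), tree

    def test_no_signal_detected_when_absent(self):
        ests = []
        for seed in range(10):
            table, tree = self._study(0.0, 150, seed)
            ests.append(phylo_signal_mass_independent(table, tree))
        assert np.median(ests) <= 0.2

    def test_strong_signal_recovered(self):
        """Generating lambda 0.87 (eutherian-like) is recovered on average."""
        ests = []
        for seed in range(10):
            table, tree = self._study(0.87, 300, seed)
            ests.append(phylo_signal_mass_independent(table, tree))
        assert abs(np.mean(ests) - 0.87) < 0.1

    def test_permutation_destroys_signal(self):
        table, tree = self._study(1.0, 120, seed=21)
        before = phylo_signal_mass_independent(table, tree)
        shuffled = table.data.copy()
        rng = np.random.default_rng(0)
        shuffled["species"] = rng.permutation(shuffled["species"].to_numpy())
        from allomet.io import CladeTable

        after = phylo_signal_mass_independent(CladeTable(shuffled, ("X",)), tree)
        assert after < before
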