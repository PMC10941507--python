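import numpy as np
import pytest
from scipy import stats as sps

from neurograd.connectomes import (
    ConnectivityMatrix,
    DiscreteDensity,
    ParcellatedTimeSeries,
    VertexAreaTable,
    common_grid,
    estimate_density,
    functional_connectome,
    kl_divergence,
    regress_confounds,
    structural_connectome,
    symmetric_kl,
)
from oracles import kl_direct, symmetric_kl_direct


def _ts(data, roi_ids=None):
    data = np.asarray(data, float)
    roi_ids = roi_ids or [f"R{i}" for i in range(data.shape[1])]
    return ParcellatedTimeSeries("s1", "control", data, roi_ids)


class TestFunctionalConnectome:
    def test_hand_computed_pearson(self):
        # r(x, y) = 0.6 by direct computation from the definition
        ts = _ts(np.array([[1, 2], [2, 1], [3, 4], [4, 3]], float))
        cm = functional_connectome(ts)
        assert cm.values[0, 1] == pytest.approx(np.arctanh(0.6), abs=1e-12)
        assert cm.values[0, 0] == 0.0

    def test_identical_columns_clip_finite(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ts = _ts(np.column_stack([x, x]))
        cm = functional_connectome(ts)
        assert np.isfinite(cm.values[0, 1])
        assert cm.values[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_orthogonal_zero_mean_columns(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        cm = functional_connectome(_ts(np.column_stack([x, y])))
        assert cm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_column_names_roi(self):
        data = np.column_stack([np.arange(4.0), np.full(4, 2.0)])
        with pytest.raises(ValueError, match="R1"):
            functional_connectome(_ts(data))

    def test_affine_rescaling_invariance(self, rng):
        data = rng.standard_normal((50, 8))
        base = functional_connectome(_ts(data))
        scaled = data * rng.uniform(0.5, 3.0, 8) + rng.normal(0, 5, 8)
        again = functional_connectome(_ts(scaled))
        np.testing.assert_allclose(base.values, again.values, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        data = rng.standard_normal((40, 6))
        cm = functional_connectome(_ts(data))
        perm = rng.permutation(6)
        cm_p = functional_connectome(
            _ts(data[:, perm], roi_ids=[f"R{i}" for i in perm])
        )
        np.testing.assert_allclose(cm_p.values, cm.values[np.ix_(perm, perm)], atol=1e-10)


class TestRegressConfounds:
    @staticmethod
    def _matrices(edges, n_roi=4):
        mats = []
        for s, e in enumerate(edges):
            v = np.zeros((n_roi, n_roi))
            v[0, 1] = v[1, 0] = e
            mats.append(ConnectivityMatrix(v, "functional", [f"R{i}" for i in range(n_roi)], f"s{s}"))
        return mats

    def test_orthogonal_covariates_leave_input(self, rng):
        n = 30
        age = rng.uniform(40, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), age, sex])
        raw = rng.standard_normal(n)
        # orthogonalize exactly against the design so true OLS coefficients are 0
        Q, _ = np.linalg.qr(X)
        edges = raw - Q[:, 1:] @ (Q[:, 1:].T @ raw)
        out = regress_confounds(self._matrices(edges), age, sex)
        got = np.array([m.values[0, 1] for m in out])
        np.testing.assert_allclose(got, edges, atol=1e-8)

    def test_planted_age_effect_removed(self, rng):
        n = 200
        age = rng.uniform(40, 80, n)
        sex = rng.integers(0, 2, n).astype(float)
        edges = 0.01 * age + rng.normal(0, 0.05, n)
        out = regress_confounds(self._matrices(edges), age, sex)
        got = np.array([m.values[0, 1] for m in out])
        r = np.corrcoef(got, age)[0, 1]
        assert abs(r) < 0.05

    def test_constant_edge_unchanged(self):
        age = np.array([50.0, 60.0, 70.0, 55.0])
        sex = np.array([0.0, 1.0, 0.0, 1.0])
        out = regress_confounds(self._matrices(np.full(4, 0.7)), age, sex)
        for m in out:
            assert m.values[0, 1] == pytest.approx(0.7, abs=1e-10)

    def test_rank_deficient_design_raises(self):
        age = np.full(5, 60.0)  # constant age: collinear with intercept
        sex = np.array([0.0, 1.0, 0.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="rank"):
            regress_confounds(self._matrices(np.arange(5.0)), age, sex)


class TestDensity:
    def test_mass_normalized(self, rng):
        vals = rng.lognormal(0, 0.3, 100)
        grid = common_grid({"a": vals})
        d = estimate_density(vals, grid)
        assert abs(d.mass.sum() - 1.0) <= 1e-12
        assert np.all(d.mass > 0)

    def test_symmetric_values_symmetric_density(self):
        m = 5.0
        vals = m + np.array([-2.0, -1.0, 1.0, 2.0])
        grid = np.linspace(m - 6, m + 6, 257)  # odd: symmetric about m
        d = estimate_density(vals, grid)
        np.testing.assert_allclose(d.mass, d.mass[::-1], atol=1e-8)

    def test_kde_matches_histogram_oracle(self, rng):
        # total-variation agreement with a plain histogram at large n
        vals = rng.lognormal(-0.6, 0.3, 100_000)
        grid = common_grid({"a": vals}, n_points=256)
        d = estimate_density(vals, grid)
        edges = np.concatenate(
            [[grid[0] - 1], (grid[:-1] + grid[1:]) / 2, [grid[-1] + 1]]
        )
        hist, _ = np.histogram(vals, bins=edges)
        hist = hist / hist.sum()
        tv = 0.5 * np.abs(hist - d.mass).sum()
        assert tv < 0.02

    def test_identical_values_fallback_warns(self):
        vals = np.full(10, 2.0)
        grid = np.linspace(1.0, 3.0, 64)
        with pytest.warns(RuntimeWarning, match="bandwidth"):
            d = estimate_density(vals, grid)
        assert np.isfinite(d.mass).all()


def _density(mass):
    mass = np.asarray(mass, float)
    return DiscreteDensity(grid=np.arange(mass.size, dtype=float), mass=mass)


class TestKL:
    def test_self_divergence_zero(self, rng):
        m = rng.dirichlet(np.ones(16))
        f = _density(m)
        assert kl_divergence(f, f) == pytest.approx(0.0, abs=1e-12)
        assert symmetric_kl(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        f1 = _density([0.5, 0.25, 0.25])
        f2 = _density([0.25, 0.5, 0.25])
        expected = 0.5 * np.log(2) + 0.25 * np.log(0.5)  # = 0.173286...
        assert kl_divergence(f1, f2) == pytest.approx(expected, abs=1e-12)
        assert symmetric_kl(f1, f2) == pytest.approx(expected, abs=1e-12)

    def test_asymmetry_witness(self):
        f1 = _density([0.9, 0.1])
        f2 = _density([0.5, 0.5])
        assert kl_divergence(f1, f2) != pytest.approx(kl_divergence(f2, f1), abs=1e-3)
        assert kl_divergence(f1, f2) == pytest.approx(kl_direct(f1.mass, f2.mass), abs=1e-14)

    def test_symmetry_and_nonnegativity_random(self, rng):
        for _ in range(50):
            m1 = rng.dirichlet(np.ones(12)) + 1e-9
            m2 = rng.dirichlet(np.ones(12)) + 1e-9
            f1 = _density(m1 / m1.sum())
            f2 = _density(m2 / m2.sum())
            s12 = symmetric_kl(f1, f2)
            assert s12 == pytest.approx(symmetric_kl(f2, f1), abs=1e-14)
            assert s12 >= -1e-12
            assert s12 == pytest.approx(symmetric_kl_direct(f1.mass, f2.mass), abs=1e-12)

    def test_mismatched_grids_raise(self):
        f1 = _density([0.5, 0.5])
        f2 = DiscreteDensity(grid=np.array([5.0, 9.0]), mass=np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="grid"):
            kl_divergence(f1, f2)


class TestStructuralConnectome:
    def test_identical_rois_give_zero_matrix(self, rng):
        vals = rng.lognormal(0, 0.3, 40)
        vt = VertexAreaTable("s", "pre", {f"R{i}": vals for i in range(3)})
        cm = structural_connectome(vt)
        np.testing.assert_allclose(cm.values, 0.0, atol=1e-10)

    def test_contract_symmetry_nonneg(self, rng):
        vt = VertexAreaTable(
            "s", "pre", {f"R{i}": rng.lognormal(0, 0.3, 30) for i in range(6)}
        )
        cm = structural_connectome(vt)
        np.testing.assert_allclose(cm.values, cm.values.T, atol=1e-12)
        assert np.all(cm.values >= 0)
        assert np.all(np.diag(cm.values) == 0)

    def test_three_roi_brute_force_oracle(self, rng):
        areas = {
            "A": np.array([0.4, 0.5, 0.55, 0.6, 0.7]),
            "B": np.array([0.5, 0.6, 0.65, 0.8, 0.9]),
            "C": np.array([0.3, 0.35, 0.4, 0.45, 0.5]),
        }
        vt = VertexAreaTable("s", "pre", areas)
        cm = structural_connectome(vt)
        grid = common_grid(areas)
        dens = {k: estimate_density(v, grid) for k, v in areas.items()}
        for i, a in enumerate("ABC"):
            for j, b in enumerate("ABC"):
                expect = 0.0 if i == j else symmetric_kl_direct(dens[a].mass, dens[b].mass)
                assert cm.values[i, j] == pytest.approx(expect, abs=1e-10)

    def test_missing_roi_named(self, rng):
        vt = VertexAreaTable("s", "pre", {"A": rng.lognormal(0, 0.3, 10)})
        with pytest.raises(ValueError, match="B"):
            structural_connectome(vt, roi_ids=["A", "B"])

    def test_global_area_scaling_near_invariant(self, rng):
        areas = {f"R{i}": rng.lognormal(-0.6 + 0.05 * i, 0.3, 200) for i in range(5)}
        cm1 = structural_connectome(VertexAreaTable("s", "pre", areas))
        cm2 = structural_connectome(
            VertexAreaTable("s", "pre", {k: 2.0 * v for k, v in areas.items()})
        )
        assert np.max(np.abs(cm1.values - cm2.values)) < 5e-2

    def test_permutation_equivariance(self, rng):
        areas = {f"R{i}": rng.lognormal(0.05 * i, 0.3, 25) for i in range(5)}
        vt = VertexAreaTable("s", "pre", areas)
        ids = list(areas)
        cm = structural_connectome(vt, roi_ids=ids)
        perm = rng.permutation(5)
        cm_p = structural_connectome(vt, roi_ids=[ids[i] for i in perm])
        np.testing.assert_allclose(cm_p.values, cm.values[np.ix_(perm, perm)], atol=1e-12)
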