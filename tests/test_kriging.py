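import numpy as np
import pytest

from krigfuse.kriging import (
    cokrige_grid,
    cokrige_point,
    cokrige_points,
    krige_grid,
    krige_lognormal,
    krige_point,
    krige_points,
)
from krigfuse.synthetic import simulate_gaussian_points
from krigfuse.types import Analyte, GridSpec, Instrument, SampleSet, ValidationError
from krigfuse.variography import CrossVariogramModel, VariogramModel

from conftest import make_samples, random_samples
from oracles import ck_oracle, ok_oracle

GAUSS = VariogramModel("gaussian", 0.3, 2.0, 40.0)
SPH = VariogramModel("spherical", 0.1, 1.5, 55.0)


def _lmc(ps_cross=0.8, nug_cross=0.0, rng_major=45.0):
    mk = lambda nug, ps: VariogramModel("gaussian", nug, ps, rng_major)
    return CrossVariogramModel(mk(0.4, 1.2), mk(0.3, 1.0), mk(nug_cross, ps_cross))


class TestOrdinaryKriging:
    def test_single_datum_weight_one(self):
        ss = make_samples([(10, 10)], [7.5])
        sol = krige_point(ss, GAUSS, (40, 40))
        assert sol.estimate == pytest.approx(7.5)
        np.testing.assert_allclose(sol.weights_primary, [1.0])

    def test_symmetric_pair_half_weights(self):
        ss = make_samples([(0, 0), (20, 0)], [2.0, 6.0])
        sol = krige_point(ss, GAUSS, (10, 0))
        np.testing.assert_allclose(sol.weights_primary, [0.5, 0.5], atol=1e-10)
        assert sol.estimate == pytest.approx(4.0)

    def test_pure_nugget_gives_mean(self, rng):
        ss = random_samples(rng, 8)
        nug = VariogramModel("gaussian", 1.0, 0.0, 40.0)
        sol = krige_point(ss, nug, (33.0, 71.0))
        assert sol.estimate == pytest.approx(ss.values.mean(), abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_weights_match_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        ss = random_samples(rng, n)
        model = GAUSS if seed % 2 else SPH
        target = tuple(rng.uniform(0, 100, 2))
        sol = krige_point(ss, model, target)
        lam, mu, est, var = ok_oracle(ss.coords.tolist(), ss.values.tolist(),
                                      model, target)
        np.testing.assert_allclose(sol.weights_primary, lam, atol=1e-8)
        assert sol.estimate == pytest.approx(est, abs=1e-8)
        assert sol.kriging_variance == pytest.approx(var, abs=1e-8)
        assert sol.lagrange_multipliers[0] == pytest.approx(mu, abs=1e-8)

    def test_exact_interpolation_at_datum(self, rng):
        ss = random_samples(rng, 10)
        p = ss.points[4]
        sol = krige_point(ss, GAUSS, p.coords)
        assert sol.estimate == p.value
        assert sol.kriging_variance == 0.0

    def test_weight_sum_constraint(self, rng):
        for _ in range(5):
            ss = random_samples(rng, 12)
            sol = krige_point(ss, SPH, tuple(rng.uniform(0, 100, 2)))
            assert abs(sol.weights_primary.sum() - 1.0) < 1e-8

    def test_duplicate_coordinates_error(self):
        ss = SampleSet.__new__(SampleSet)  # bypass set-level dedup to hit solver check
        a = make_samples([(0, 0), (10, 10)], [1.0, 2.0])
        b = make_samples([(10, 10)], [3.0], prefix="q")
        ss.points = a.points + b.points
        ss.analyte = Analyte.CU
        ss.log_transformed = False
        with pytest.raises(ValidationError, match="duplicate coordinates"):
            krige_points(ss, GAUSS, np.array([[5.0, 5.0]]))

    def test_permutation_invariance(self, rng):
        ss = random_samples(rng, 15)
        perm = rng.permutation(15)
        shuffled = SampleSet([ss.points[i] for i in perm], ss.analyte)
        t = np.array([[47.0, 52.0]])
        e1, _, _ = krige_points(ss, GAUSS, t)
        e2, _, _ = krige_points(shuffled, GAUSS, t)
        assert abs(e1[0] - e2[0]) < 1e-10

    def test_neighborhood_limits_points(self, rng):
        ss = random_samples(rng, 30)
        sol = krige_point(ss, GAUSS, (50, 50), max_points=8)
        assert np.count_nonzero(sol.weights_primary) <= 8
        assert abs(sol.weights_primary.sum() - 1.0) < 1e-8


class TestKrigeGrid:
    def test_1x1_equals_point(self, rng):
        ss = random_samples(rng, 9)
        grid = GridSpec(40, 40, 10.0, 1, 1)
        pg = krige_grid(ss, GAUSS, grid)
        sol = krige_point(ss, GAUSS, (45.0, 45.0))
        assert pg.estimates[0, 0] == pytest.approx(sol.estimate, abs=1e-12)
        assert pg.variances[0, 0] == pytest.approx(sol.kriging_variance, abs=1e-12)

    def test_constant_samples_constant_grid(self, rng):
        ss = random_samples(rng, 6).with_values(np.full(6, 4.2))
        pg = krige_grid(ss, GAUSS, GridSpec(0, 0, 25.0, 3, 3))
        np.testing.assert_allclose(pg.estimates, 4.2, atol=1e-9)

    def test_3x3_cell_ordering_vs_oracle(self, rng):
        ss = random_samples(rng, 7)
        grid = GridSpec(0, 0, 30.0, 3, 3)
        pg = krige_grid(ss, GAUSS, grid)
        X, Y = grid.cell_centers()
        for r in range(3):
            for c in range(3):
                _, _, est, _ = ok_oracle(ss.coords.tolist(), ss.values.tolist(),
                                         GAUSS, (X[r, c], Y[r, c]))
                assert pg.estimates[r, c] == pytest.approx(est, abs=1e-8)


class TestLognormalKriging:
    def test_constant_field_either_back_transform(self, rng):
        # a constant field has a zero-variance variogram; with it both
        # back-transforms must return the datum value everywhere
        ss = random_samples(rng, 6).with_values(np.full(6, 5.0))
        flat = VariogramModel("gaussian", 0.0, 0.0, 40.0)
        grid = GridSpec(0, 0, 30.0, 2, 2)
        for bt in ("naive_exp", "unbiased"):
            pg = krige_lognormal(ss, flat, grid, bt)
            np.testing.assert_allclose(pg.estimates, 5.0, rtol=1e-9)

    def test_constant_field_naive_any_model(self, rng):
        # naive exp is exactness-preserving regardless of the model
        ss = random_samples(rng, 6).with_values(np.full(6, 5.0))
        pg = krige_lognormal(ss, GAUSS, GridSpec(0, 0, 30.0, 2, 2), "naive_exp")
        np.testing.assert_allclose(pg.estimates, 5.0, rtol=1e-9)

    def test_naive_exact_at_datum(self, rng):
        ss = random_samples(rng, 8, lo=5.0, hi=500.0)
        p = ss.points[2]
        est, _ = krige_lognormal(ss, GAUSS, np.array([p.coords]), "naive_exp")
        assert est[0] == pytest.approx(p.value, rel=1e-12)

    def test_outputs_positive(self, rng):
        ss = random_samples(rng, 12, lo=1.0, hi=2000.0)
        pg = krige_lognormal(ss, GAUSS, GridSpec(0, 0, 20, 5, 5), "unbiased")
        assert np.all(pg.estimates > 0)
        assert pg.variance_scale == "log"

    def test_rejects_log_input(self, rng):
        ss = random_samples(rng, 5, log_transformed=True)
        with pytest.raises(ValidationError):
            krige_lognormal(ss, GAUSS, GridSpec(0, 0, 10, 2, 2))

    def test_unknown_back_transform(self, rng):
        ss = random_samples(rng, 5)
        with pytest.raises(ValidationError, match="back_transform"):
            krige_lognormal(ss, GAUSS, GridSpec(0, 0, 10, 2, 2), "median")

    def test_unbiased_less_mean_bias_on_lognormal_field(self):
        """On simulated lognormal fields the Lagrange-corrected
        back-transform has smaller absolute mean bias than naive exp."""
        model = VariogramModel("gaussian", 0.1, 0.8, 35.0)
        bias_naive, bias_unb = [], []
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            coords = rng.uniform(0, 100, size=(24, 2))
            zlog = simulate_gaussian_points(coords, model, rng, mean=2.0)
            truth = np.exp(zlog)
            ss = make_samples(coords[:16], truth[:16])
            targets = coords[16:]
            naive, _ = krige_lognormal(ss, model, targets, "naive_exp")
            unb, _ = krige_lognormal(ss, model, targets, "unbiased")
            bias_naive.append(np.mean(naive - truth[16:]))
            bias_unb.append(np.mean(unb - truth[16:]))
        assert abs(np.mean(bias_unb)) < abs(np.mean(bias_naive))


class TestCoKriging:
    def test_zero_cross_sill_decouples(self, rng):
        pri = random_samples(rng, 6)
        sec = random_samples(rng, 15, prefix="s", instrument=Instrument.SECONDARY)
        lmc = _lmc(ps_cross=0.0)
        target = (42.0, 58.0)
        ck = cokrige_point(pri, sec, lmc, target)
        ok = krige_point(pri, lmc.direct_primary, target)
        assert ck.estimate == pytest.approx(ok.estimate, abs=1e-8)
        np.testing.assert_allclose(ck.weights_secondary, 0.0, atol=1e-8)

    def test_secondary_clone_of_primary_matches_ok(self, rng):
        pri = random_samples(rng, 7)
        sec = make_samples(pri.coords, pri.values, prefix="s",
                           instrument=Instrument.SECONDARY)
        m = VariogramModel("gaussian", 0.4, 1.2, 45.0)
        lmc = CrossVariogramModel(m, m, m)
        target = (30.0, 66.0)
        ck = cokrige_point(pri, sec, lmc, target)
        ok = krige_point(pri, m, target)
        assert ck.estimate == pytest.approx(ok.estimate, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_weights_match_dense_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n, m = int(rng.integers(3, 6)), int(rng.integers(8, 21))
        pri = random_samples(rng, n)
        sec = random_samples(rng, m, prefix="s", instrument=Instrument.SECONDARY)
        lmc = _lmc()
        target = tuple(rng.uniform(0, 100, 2))
        sol = cokrige_point(pri, sec, lmc, target)
        lam, k, est, var = ck_oracle(
            pri.coords.tolist(), pri.values.tolist(),
            sec.coords.tolist(), sec.values.tolist(), lmc, target,
        )
        np.testing.assert_allclose(sol.weights_primary, lam, atol=1e-8)
        np.testing.assert_allclose(sol.weights_secondary, k, atol=1e-8)
        assert sol.estimate == pytest.approx(est, abs=1e-8)
        assert sol.kriging_variance == pytest.approx(var, abs=1e-8)

    def test_constraints_hold(self, rng):
        pri = random_samples(rng, 5)
        sec = random_samples(rng, 12, prefix="s", instrument=Instrument.SECONDARY)
        sol = cokrige_point(pri, sec, _lmc(), (50.0, 50.0))
        assert abs(sol.weights_primary.sum() - 1.0) < 1e-8
        assert abs(sol.weights_secondary.sum()) < 1e-8

    def test_invalid_lmc_rejected_without_override(self, rng):
        pri = random_samples(rng, 5)
        sec = random_samples(rng, 8, prefix="s", instrument=Instrument.SECONDARY)
        bad = _lmc(ps_cross=5.0)  # violates Cauchy-Schwarz
        with pytest.raises(ValidationError, match="sill screen"):
            cokrige_point(pri, sec, bad, (10.0, 10.0))
        sol = cokrige_points(pri, sec, bad, np.array([[10.0, 10.0]]),
                             allow_invalid_lmc=True)
        assert np.isfinite(sol[0][0])

    @pytest.mark.parametrize("seed", range(10))
    def test_information_inequality(self, seed):
        """Adding a correlated secondary never increases the kriging
        variance under a valid coregionalization."""
        rng = np.random.default_rng(7000 + seed)
        pri = random_samples(rng, 6)
        sec = random_samples(rng, 15, prefix="s", instrument=Instrument.SECONDARY)
        lmc = _lmc(ps_cross=float(rng.uniform(0.1, 1.0)))
        for _ in range(5):
            t = tuple(rng.uniform(0, 100, 2))
            ck = cokrige_point(pri, sec, lmc, t)
            ok = krige_point(pri, lmc.direct_primary, t)
            assert ck.kriging_variance <= ok.kriging_variance + 1e-9

    def test_grid_matches_point(self, rng):
        pri = random_samples(rng, 5)
        sec = random_samples(rng, 10, prefix="s", instrument=Instrument.SECONDARY)
        grid = GridSpec(20, 20, 20.0, 2, 2)
        pg = cokrige_grid(pri, sec, _lmc(), grid)
        X, Y = grid.cell_centers()
        sol = cokrige_point(pri, sec, _lmc(), (X[1, 0], Y[1, 0]))
        assert pg.estimates[1, 0] == pytest.approx(sol.estimate, abs=1e-10)

    def test_exactness_at_primary_datum(self, rng):
        pri = random_samples(rng, 6)
        sec = random_samples(rng, 10, prefix="s", instrument=Instrument.SECONDARY)
        p = pri.points[1]
        sol = cokrige_point(pri, sec, _lmc(), p.coords)
        assert sol.estimate == p.value
        assert sol.kriging_variance == 0.0
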