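"""Weighted least-squares estimation: oracles, recovery, uncertainty."""

import numpy as np
import pytest

import allokin as ak
from allokin.fitting import InteractingSites, MichaelisMenten, weighted_ssr


class TestWeightedSSR:
    def test_hand_arithmetic(self):
        # residuals (-1, +1/3, +1) with weights (1, 1, 4)
        ds = ak.VelocityDataset.from_arrays(
            [1.0, 2.0, 4.0], [4.0, 7.0, 9.0], sd=[1.0, 1.0, 0.5]
        )
        w = weighted_ssr("MM", ak.MMParams(1.0, 10.0), ds, weighting="sd")
        assert w == pytest.approx(1 + 1 / 9 + 4, rel=1e-12)

    def test_zero_on_exact_data(self, noiseless_mm_dataset):
        assert weighted_ssr(
            "MM", ak.MMParams(1.0, 10.0), noiseless_mm_dataset, weighting="uniform"
        ) == pytest.approx(0.0, abs=1e-20)

    def test_unit_sd_equals_unweighted(self):
        rng = np.random.default_rng(0)
        c = np.logspace(-1, 1, 8)
        v = rng.uniform(1, 5, 8)
        ds = ak.VelocityDataset.from_arrays(c, v, sd=np.ones(8))
        p = ak.MMParams(1.0, 4.0)
        ssr = np.sum((v - ak.eval_mm(p, np.sort(c))) ** 2)
        assert weighted_ssr("MM", p, ds, "sd") == pytest.approx(ssr)

    def test_zero_sd_names_offending_point(self):
        ds = ak.VelocityDataset.from_arrays([1.0, 2.0], [1.0, 2.0], sd=[0.1, 0.0])
        with pytest.raises(ValueError, match="c0=2"):
            ds.weights("sd")


class TestFitRecovery:
    def test_noiseless_mm_recovery(self, noiseless_mm_dataset):
        res = MichaelisMenten(noiseless_mm_dataset, weighting="uniform").fit(seed=0)
        assert res.params.Km == pytest.approx(1.0, rel=1e-6)
        assert res.params.Vmax == pytest.approx(10.0, rel=1e-6)

    def test_noiseless_is_recovery(self, wt_truth, noiseless_is_dataset):
        res = InteractingSites(noiseless_is_dataset, weighting="uniform").fit(seed=0)
        for name in ("Km1", "Vmax1", "a", "b"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(wt_truth, name), rel=1e-4
            )

    def test_brute_force_grid_oracle(self):
        """The optimizer lands in the same basin as an exhaustive 4-D scan."""
        truth = ak.ISParams(Km1=0.2, Vmax1=4.0, a=30.0, b=1.2)
        grid_c = ak.make_concentration_grid(truth.Km1, truth.Km2, 10)
        ds = ak.simulate_velocity_dataset(
            "IS", truth, grid_c, ak.NoiseSpec(mode="relative", cv=0.02, n_rep=3, seed=3)
        )
        model = InteractingSites(ds, weighting="uniform")
        res = model.fit(seed=0)

        axes = [
            np.log(getattr(truth, n)) + np.linspace(-1, 1, 20) * np.log(10)
            for n in ("Km1", "Vmax1", "a", "b")
        ]
        best_w, best_x = np.inf, None
        K1, V1, A, B = np.meshgrid(*[np.exp(ax) for ax in axes], indexing="ij")
        c = ds.c0[:, None]
        num = 2 * V1.ravel() * c / K1.ravel() + 2 * B.ravel() * V1.ravel() * c**2 / (
            A.ravel() * K1.ravel() ** 2
        )
        den = 1 + 2 * c / K1.ravel() + c**2 / (A.ravel() * K1.ravel() ** 2)
        wssr = np.sum((ds.v0[:, None] - num / den) ** 2, axis=0)
        i = int(np.argmin(wssr))
        best_x = np.array([K1.ravel()[i], V1.ravel()[i], A.ravel()[i], B.ravel()[i]])
        # optimizer beats the coarse scan ...
        assert res.wssr <= wssr[i] + 1e-12
        # ... and a local refinement seeded at the scan's argmin lands in the
        # same basin: identical minimum wssr and an indistinguishable curve
        from scipy.optimize import least_squares

        w = np.ones(len(ds))
        refined = least_squares(
            lambda t: ds.v0 - model._predict_array(np.exp(t), ds.c0),
            np.log(best_x),
            method="trf",
            ftol=1e-12, xtol=1e-12,
        )
        assert 2 * refined.cost == pytest.approx(res.wssr, rel=1e-6)
        assert np.allclose(
            model._predict_array(np.exp(refined.x), ds.c0), res.predict(), rtol=1e-4
        )

    def test_row_permutation_invariance(self, wt_truth, wt_grid):
        ds = ak.simulate_velocity_dataset(
            "IS", wt_truth, wt_grid, ak.NoiseSpec(mode="relative", cv=0.05, n_rep=3, seed=7)
        )
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ds))
        ds_perm = ak.VelocityDataset.from_arrays(
            ds.c0[perm], ds.v0[perm], sd=ds.sd[perm], n_rep=ds.n_rep[perm]
        )
        r1 = InteractingSites(ds, weighting="sd").fit(n_starts=8, seed=0)
        r2 = InteractingSites(ds_perm, weighting="sd").fit(n_starts=8, seed=0)
        assert np.allclose(r1.params_array, r2.params_array, rtol=1e-10)

    def test_log_and_natural_space_agree(self, noiseless_mm_dataset):
        m = MichaelisMenten(noiseless_mm_dataset, weighting="uniform")
        r_log = m.fit(seed=0, transform="log")
        r_nat = m.fit(seed=0, transform="natural")
        assert np.allclose(r_log.params_array, r_nat.params_array, rtol=1e-4)

    def test_nesting_inequality(self, wt_truth, wt_grid):
        for seed in range(5):
            ds = ak.simulate_velocity_dataset(
                "IS", wt_truth, wt_grid,
                ak.NoiseSpec(mode="relative", cv=0.08, n_rep=3, seed=seed),
            )
            r_mm = MichaelisMenten(ds, weighting="sd").fit(n_starts=6, seed=0)
            r_is = InteractingSites(ds, weighting="sd", mm_results=r_mm).fit(
                n_starts=6, seed=0
            )
            assert r_is.wssr <= r_mm.wssr * (1 + 1e-8)

    def test_too_few_points_rejected(self):
        ds = ak.VelocityDataset.from_arrays([1.0, 2.0, 3.0], [1.0, 2.0, 2.5])
        with pytest.raises(ValueError, match="at least 5 points"):
            InteractingSites(ds, weighting="uniform")


class TestStandardErrors:
    def test_noiseless_data_gives_vanishing_stderr(self, noiseless_mm_dataset):
        res = MichaelisMenten(noiseless_mm_dataset, weighting="uniform").fit(seed=0)
        assert np.all(res.bse <= 1e-6 * res.params_array)

    def test_duplication_shrinks_stderr(self):
        truth = ak.MMParams(Km=1.0, Vmax=10.0)
        grid = np.logspace(-1, 2, 30)
        ds = ak.simulate_velocity_dataset(
            "MM", truth, grid, ak.NoiseSpec(mode="relative", cv=0.05, n_rep=3, seed=5)
        )
        dup = ak.VelocityDataset.from_arrays(
            np.concatenate([ds.c0, ds.c0]),
            np.concatenate([ds.v0, ds.v0]),
            sd=np.concatenate([ds.sd, ds.sd]),
        )
        r1 = MichaelisMenten(ds, weighting="sd").fit(n_starts=4, seed=0)
        r2 = MichaelisMenten(dup, weighting="sd").fit(n_starts=4, seed=0)
        n, p = len(ds), 2
        expected = np.sqrt((n - p) / (2 * n - p))  # -> 1/sqrt(2) for large n
        assert np.allclose(r2.bse / r1.bse, expected, rtol=0.02)

    def test_stderr_calibration_monte_carlo(self):
        """Reported asymptotic errors track the true sampling spread."""
        truth = ak.MMParams(Km=1.0, Vmax=10.0)
        grid = np.logspace(-1, 2, 12)
        est, se = [], []
        for seed in range(100):
            ds = ak.simulate_velocity_dataset(
                "MM", truth, grid,
                ak.NoiseSpec(mode="relative", cv=0.05, n_rep=3, seed=seed),
            )
            r = MichaelisMenten(ds, weighting="relative", cv=0.05).fit(
                n_starts=3, seed=0
            )
            est.append(r.params_array)
            se.append(r.bse)
        emp_sd = np.std(np.asarray(est), axis=0, ddof=1)
        mean_se = np.mean(np.asarray(se), axis=0)
        assert np.all(mean_se / emp_sd > 0.5)
        assert np.all(mean_se / emp_sd < 2.0)


class TestResultsObject:
    def test_summary_and_report(self, noiseless_is_dataset):
        res = InteractingSites(noiseless_is_dataset, weighting="uniform").fit(seed=0)
        text = res.summary()
        assert "Km1" in text and "derived" in text
        d = res.to_dict()
        assert d["model"] == "IS"
        assert d["derived"]["Km2"] == pytest.approx(res.params.Km2)
        assert d["dof"] == len(noiseless_is_dataset) - 4

    def test_functional_wrapper_matches_oo(self, noiseless_mm_dataset):
        r1 = ak.fit_model(noiseless_mm_dataset, "MM", weighting="uniform", seed=0)
        r2 = MichaelisMenten(noiseless_mm_dataset, weighting="uniform").fit(seed=0)
        assert np.allclose(r1.params_array, r2.params_array)
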