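"""Likelihood, fitting, and AIC comparison tests."""

import numpy as np
import pytest

from h4zip.estimation import (
    FamilySpec,
    FitResult,
    LikelihoodSpec,
    TimeCourseDataset,
    aic,
    compare,
    fit,
    negative_log_likelihood,
)
from h4zip.kinetics import IntegrationError
from h4zip.motifs import build_network

LOG_2PI = np.log(2 * np.pi)


def _one_site_dataset(y_obs, times=(0.0, 10.0, 20.0), mask=None):
    """2-motif dataset on a single-site lattice; y_obs shape (2, T, R)."""
    return TimeCourseDataset(
        times=np.asarray(times), motifs=["unmod", "K16ac"],
        y=np.asarray(y_obs), mask=mask,
    )


@pytest.fixture(scope="module")
def one_site_spec():
    return FamilySpec(family="mass_action", network=build_network(("K16",)))


class TestNegativeLogLikelihood:
    def test_zero_residuals_unit_sigma(self, one_site_spec):
        """Perfect fit at sigma=1 leaves only the N/2 log(2 pi) constant."""
        times = np.array([0.0, 10.0])
        k = 0.05
        y = np.stack([np.exp(-k * times), 1 - np.exp(-k * times)])[:, :, None]
        data = _one_site_dataset(y, times)
        nll = negative_log_likelihood(
            one_site_spec, np.array([k]), data, LikelihoodSpec(sigma=1.0)
        )
        assert nll == pytest.approx(data.n_points * 0.5 * LOG_2PI, rel=1e-6)

    def test_doubling_sigma_adds_n_log_two(self, one_site_spec):
        times = np.array([0.0, 10.0])
        k = 0.05
        y = np.stack([np.exp(-k * times), 1 - np.exp(-k * times)])[:, :, None]
        data = _one_site_dataset(y, times)
        theta = np.array([k])
        nll1 = negative_log_likelihood(one_site_spec, theta, data, LikelihoodSpec(sigma=1.0))
        nll2 = negative_log_likelihood(one_site_spec, theta, data, LikelihoodSpec(sigma=2.0))
        assert nll2 - nll1 == pytest.approx(data.n_points * np.log(2.0), rel=1e-9)

    def test_hand_computed_three_point_sum(self, one_site_spec):
        """Residuals (0.1, -0.1, 0.2) at sigma=0.05 against direct arithmetic."""
        times = np.array([0.0, 10.0])
        k = 0.0  # model stays at unmod=1, K16ac=0
        y = np.ones((2, 2, 1))
        y[0, 0, 0] = 1 - 0.1
        y[0, 1, 0] = 1 + 0.0  # clipped later via mask
        y[1, 0, 0] = 0.1
        y[1, 1, 0] = 0.2
        mask = np.zeros((2, 2, 1), bool)
        mask[0, 1, 0] = True  # keep exactly three residuals
        data = _one_site_dataset(y, times, mask)
        sigma = 0.05
        expected = (0.1**2 + 0.1**2 + 0.2**2) / (2 * sigma**2) + 3 * (
            np.log(sigma) + 0.5 * LOG_2PI
        )
        nll = negative_log_likelihood(
            one_site_spec, np.array([k]), data, LikelihoodSpec(sigma=sigma)
        )
        assert nll == pytest.approx(expected, rel=1e-9)

    def test_integration_failure_returns_finite_penalty(self, one_site_spec, monkeypatch):
        import h4zip.estimation as est

        def boom(*a, **k):
            raise IntegrationError("forced failure", t_fail=1.0)

        monkeypatch.setattr(est, "_simulated_y", boom)
        data = _one_site_dataset(np.ones((2, 3, 1)) * 0.5)
        nll = est.negative_log_likelihood(
            one_site_spec, np.array([0.1]), data, LikelihoodSpec()
        )
        assert np.isfinite(nll) and nll >= est.PENALTY_NLL


class TestAic:
    def test_arithmetic(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-10.0, 3) == 26.0
        assert aic(-10.0, 4) - aic(-10.0, 3) == 2.0

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            aic(np.inf, 2)


def _fake_fit(family, aic_value, n_params=3):
    logL = (2 * n_params - aic_value) / 2
    return FitResult(
        family=family, theta_hat=np.ones(n_params), param_names=[f"p{i}" for i in range(n_params)],
        logL=logL, n_params=n_params, aic=aic_value, n_starts=1, n_converged=1, seed=0,
    )


class TestCompare:
    def test_rejection_rule(self):
        comp = compare([_fake_fit("a", 100.0), _fake_fit("b", 115.0), _fake_fit("c", 130.0)])
        t = comp.table.set_index("family")
        assert comp.best_family == "a"
        assert not t.loc["a", "rejected"]
        assert t.loc["b", "rejected"] and t.loc["c", "rejected"]
        assert t["delta_aic"].min() == 0.0

    def test_close_models_not_rejected(self):
        comp = compare([_fake_fit("a", 100.0), _fake_fit("b", 105.0)])
        assert not comp.table["rejected"].any()

    def test_permutation_invariance(self):
        fits = [_fake_fit("a", 100.0), _fake_fit("b", 115.0), _fake_fit("c", 130.0)]
        t1 = compare(fits).table
        t2 = compare(fits[::-1]).table
        assert t1.to_dict() == t2.to_dict()

    def test_tie_broken_toward_fewer_parameters(self):
        comp = compare([_fake_fit("big", 100.0, n_params=6), _fake_fit("small", 100.0, n_params=3)])
        assert comp.best_family == "small"

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            compare([_fake_fit("a", 1.0)])


class TestFit:
    def test_one_site_rate_recovery(self, one_site_spec):
        """Noise-free data from k=0.05/min is recovered within 1%."""
        times = np.array([0.0, 5.0, 15.0, 30.0, 60.0])
        k = 0.05
        y = np.stack([np.exp(-k * times), 1 - np.exp(-k * times)])[:, :, None]
        data = _one_site_dataset(y, times)
        res = fit(one_site_spec, data, LikelihoodSpec(sigma=0.01), n_starts=3, seed=0)
        assert res.theta_hat[0] == pytest.approx(k, rel=1e-2)

    def test_seed_determinism_bit_for_bit(self, one_site_spec):
        times = np.array([0.0, 5.0, 15.0])
        k = 0.08
        y = np.stack([np.exp(-k * times), 1 - np.exp(-k * times)])[:, :, None]
        data = _one_site_dataset(y, times)
        r1 = fit(one_site_spec, data, LikelihoodSpec(sigma=0.01), n_starts=2, seed=42)
        r2 = fit(one_site_spec, data, LikelihoodSpec(sigma=0.01), n_starts=2, seed=42)
        assert np.array_equal(r1.theta_hat, r2.theta_hat)
        assert r1.logL == r2.logL

    def test_best_of_starts_weakly_improves(self, one_site_spec):
        times = np.array([0.0, 5.0, 15.0])
        k = 0.08
        y = np.stack([np.exp(-k * times), 1 - np.exp(-k * times)])[:, :, None]
        data = _one_site_dataset(y, times)
        lik = LikelihoodSpec(sigma=0.01)
        nlls = [-fit(one_site_spec, data, lik, n_starts=n, seed=7).logL for n in (1, 2, 4)]
        assert nlls[0] >= nlls[1] - 1e-6 and nlls[1] >= nlls[2] - 1e-6

    def test_aic_counts_profiled_noise_parameters(self, one_site_spec):
        times = np.array([0.0, 5.0, 15.0])
        k = 0.08
        rng = np.random.default_rng(0)
        y_clean = np.stack([np.exp(-k * times), 1 - np.exp(-k * times)])[:, :, None]
        y = np.clip(y_clean + rng.normal(0, 0.01, (2, 3, 1)), 0, 1)
        data = _one_site_dataset(y, times)
        fixed = fit(one_site_spec, data, LikelihoodSpec(sigma=0.01), n_starts=2, seed=1)
        single = fit(one_site_spec, data, LikelihoodSpec(), n_starts=2, seed=1)
        per_motif = fit(one_site_spec, data, LikelihoodSpec(sigma_mode="per_motif"), n_starts=2, seed=1)
        assert fixed.n_params == 1
        assert single.n_params == 2
        assert per_motif.n_params == 3  # one scale per measured motif

    def test_invalid_inputs(self, one_site_spec):
        data = _one_site_dataset(np.full((2, 3, 1), 0.5))
        with pytest.raises(ValueError):
            fit(one_site_spec, data, n_starts=0)
        with pytest.raises(ValueError):
            LikelihoodSpec(sigma=-1.0)
        with pytest.raises(ValueError):
            LikelihoodSpec(bounds=(1.0, 0.1))
        with pytest.raises(ValueError):
            TimeCourseDataset(times=[0.0], motifs=["unmod"], y=np.array([[[1.5]]]))


def test_dataset_csv_roundtrip(tmp_path, wt_bundle):
    path = tmp_path / "ds.csv"
    wt_bundle.dataset.to_csv(path)
    back = TimeCourseDataset.from_csv(path, motifs=wt_bundle.dataset.motifs)
    np.testing.assert_allclose(back.y, wt_bundle.dataset.y, atol=1e-12)
    np.testing.assert_array_equal(back.times, wt_bundle.dataset.times)
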