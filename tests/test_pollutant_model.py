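"""Factor-model data structures, weekly averaging, and likelihood."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmfactors.gp_core import GPHyper, InvalidParameterError, SpatialSites
from pmfactors.pollutant_model import (
    ErrorVariances,
    FactorState,
    MeanStructure,
    PollutantPanel,
    PropagationField,
    conditional_factor_path,
    constrain_loadings,
    factor_step,
    free_loading_indices,
    mean_matrix,
    n_structural_zeros,
    observation_mean,
    pollutant_loglik,
    standardize_field,
    weekly_average,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["site_id", "lon", "lat", "network",
                                       "date", "pollutant", "value"])


class TestWeeklyAverage:
    def test_means_of_logs(self):
        rows = [
            ("a", -120.0, 36.0, "STN", "2003-01-06", "Nitrate", np.exp(2.0)),
            ("a", -120.0, 36.0, "STN", "2003-01-13", "Nitrate", np.exp(1.0)),
            ("a", -120.0, 36.0, "STN", "2003-01-15", "Nitrate", np.exp(3.0)),
        ]
        panel = weekly_average(_records(rows))
        # single record week -> its log; two records in one week -> mean of logs
        assert np.isclose(panel.Y[0, 0, 0], 2.0)
        assert np.isclose(panel.Y[1, 0, 0], 2.0)

    def test_empty_week_is_missing(self):
        rows = [
            ("a", -120.0, 36.0, "STN", "2003-01-06", "Nitrate", 1.0),
            ("a", -120.0, 36.0, "STN", "2003-01-20", "Nitrate", 1.0),
        ]
        panel = weekly_average(_records(rows))
        assert panel.T == 3
        assert np.isnan(panel.Y[1, 0, 0])

    def test_nonpositive_values_dropped(self, caplog):
        rows = [
            ("a", -120.0, 36.0, "STN", "2003-01-06", "Nitrate", 1.0),
            ("a", -120.0, 36.0, "STN", "2003-01-07", "Nitrate", -3.0),
            ("a", -120.0, 36.0, "STN", "2003-01-08", "Nitrate", 0.0),
        ]
        panel = weekly_average(_records(rows))
        assert np.isclose(panel.Y[0, 0, 0], 0.0)  # only the value-1 record kept

    def test_week_anchor_is_monday(self):
        rows = [("a", -120.0, 36.0, "STN", "2003-01-09", "Nitrate", 1.0)]
        panel = weekly_average(_records(rows))  # Jan 9 2003 is a Thursday
        assert panel.week_anchor.isoformat() == "2003-01-06"

    def test_conflicting_network_rejected(self):
        rows = [
            ("a", -120.0, 36.0, "STN", "2003-01-06", "Nitrate", 1.0),
            ("a", -120.0, 36.0, "IMPROVE", "2003-01-07", "Nitrate", 1.0),
        ]
        with pytest.raises(InvalidParameterError):
            weekly_average(_records(rows))


class TestMeanStructure:
    def test_network_means(self):
        ms = MeanStructure(mu0=np.array([1.2]), mu1=np.array([0.3]))
        assert observation_mean(ms, "IMPROVE", 0) == pytest.approx(1.2)
        assert observation_mean(ms, "STN", 0) == pytest.approx(1.5)
        assert observation_mean(ms, "stn", 0) == pytest.approx(1.5)

    def test_zero_offset_networks_equal(self):
        ms = MeanStructure(mu0=np.array([0.7]), mu1=np.array([0.0]))
        assert observation_mean(ms, "STN", 0) == observation_mean(ms, "IMPROVE", 0)

    def test_unknown_network_rejected(self):
        ms = MeanStructure(mu0=np.array([1.0]), mu1=np.array([0.0]))
        with pytest.raises(InvalidParameterError):
            observation_mean(ms, "CSN", 0)


class TestLoadings:
    def test_identity_when_free_fields_zero(self):
        free = {k: np.zeros(2) for k in free_loading_indices(3, 2)}
        lf = constrain_loadings(3, np.zeros((2, 2)), free)
        for s in range(2):
            assert np.array_equal(lf.lam[s], np.array([[1.0, 0.0],
                                                       [0.0, 1.0],
                                                       [0.0, 0.0]]))

    def test_single_factor_all_pollutants_load(self, rng):
        # M=1: positive lambda_11 plus 8 free entries, no structural zeros
        P, n = 9, 3
        free = {k: rng.normal(size=n) for k in free_loading_indices(P, 1)}
        lf = constrain_loadings(P, rng.normal(size=(n, 1)), free)
        assert len(free) == 8
        assert (lf.lam[:, 0, 0] > 0).all()
        assert n_structural_zeros(P, 1) == 0

    @pytest.mark.parametrize("P,M", [(3, 2), (4, 3), (9, 1), (5, 5)])
    def test_structural_zero_count(self, rng, P, M):
        n = 2
        free = {k: rng.normal(size=n) for k in free_loading_indices(P, M)}
        lf = constrain_loadings(P, rng.normal(size=(n, M)), free)
        per_site_zeros = [(lf.lam[s] == 0).sum() for s in range(n)]
        assert all(z == M * (M - 1) // 2 for z in per_site_zeros)

    def test_too_many_factors_rejected(self):
        with pytest.raises(InvalidParameterError):
            constrain_loadings(2, np.zeros((1, 3)), {})


class TestFactorStep:
    def test_zero_gamma_returns_innovation(self, rng):
        innov = rng.normal(size=(3, 2))
        out = factor_step(rng.normal(size=(3, 2)), np.zeros((3, 2)), innov)
        assert np.array_equal(out, innov)

    def test_deterministic_decay(self):
        gamma = np.full((1, 1), 0.5)
        x = np.ones((1, 1))
        for _ in range(4):
            x = factor_step(x, gamma, np.zeros((1, 1)))
        assert np.isclose(x[0, 0], 0.5 ** 4)

    def test_ar1_stationary_variance(self):
        # gamma=0.8, s_w^2=1 -> long-run variance 1/(1-0.64) = 2.778
        rng = np.random.default_rng(0)
        gamma = np.full((1, 1), 0.8)
        x = np.zeros((1, 1))
        n = 100_000
        path = np.empty(n)
        for t in range(n):
            x = factor_step(x, gamma, rng.normal(size=(1, 1)))
            path[t] = x[0, 0]
        target = 1.0 / (1.0 - 0.64)
        se = target * np.sqrt(2.0 / n) * np.sqrt((1 + 0.64) / (1 - 0.64))
        assert abs(path[1000:].var() - target) < 3.0 * se * 3


class TestLoglik:
    def _toy(self, rng, T=2, n=2, P=2, M=1):
        sites = SpatialSites(ids=tuple(f"s{i}" for i in range(n)),
                             coords=rng.uniform(0, 50, (n, 2)))
        network = np.array(["STN", "IMPROVE"] * n)[:n]
        Y = rng.normal(size=(T, n, P))
        panel = PollutantPanel(Y=Y, sites=sites, network=network,
                               pollutant_names=tuple(f"p{j}" for j in range(P)))
        ms = MeanStructure(mu0=rng.normal(size=P), mu1=rng.normal(size=P))
        ev = ErrorVariances(sigma2_stn=rng.uniform(0.5, 2, P),
                            sigma2_imp=rng.uniform(0.5, 2, P))
        free = {k: rng.normal(size=n) for k in free_loading_indices(P, M)}
        lf = constrain_loadings(P, rng.normal(size=(n, M)), free)
        fs = FactorState(delta=rng.normal(size=(T, n, M)),
                         delta0=rng.normal(size=(n, M)))
        return panel, ms, ev, lf, fs

    def test_single_cell_standard_normal(self, rng):
        panel, ms, ev, lf, fs = self._toy(rng, T=1, n=1, P=1)
        panel.Y[0, 0, 0] = observation_mean(ms, panel.network[0], 0)
        ev.sigma2_stn[:] = 1.0
        ev.sigma2_imp[:] = 1.0
        fs.delta[:] = 0.0
        assert pollutant_loglik(panel, ms, ev, lf, fs) == pytest.approx(
            -0.5 * np.log(2 * np.pi))

    def test_missing_cells_contribute_zero(self, rng):
        panel, ms, ev, lf, fs = self._toy(rng)
        full = pollutant_loglik(panel, ms, ev, lf, fs)
        withheld = panel.Y.copy()
        panel.Y[0, 0, 0] = np.nan
        reduced = pollutant_loglik(panel, ms, ev, lf, fs)
        mu = mean_matrix(ms, panel.network)[0, 0] + lf.lam[0, 0] @ fs.delta[0, 0]
        var = ev.sigma2_stn[0]
        cell = -0.5 * (np.log(2 * np.pi * var) + (withheld[0, 0, 0] - mu) ** 2 / var)
        assert reduced == pytest.approx(full - cell)

    def test_matches_naive_loop(self, rng):
        panel, ms, ev, lf, fs = self._toy(rng, T=2, n=2, P=2)
        panel.Y[1, 1, 0] = np.nan
        total = 0.0
        for t in range(2):
            for s in range(2):
                for p in range(2):
                    y = panel.Y[t, s, p]
                    if np.isnan(y):
                        continue
                    mu = observation_mean(ms, panel.network[s], p) \
                        + lf.lam[s, p] @ fs.delta[t, s]
                    var = (ev.sigma2_stn if panel.network[s] == "STN"
                           else ev.sigma2_imp)[p]
                    total += -0.5 * (np.log(2 * np.pi * var) + (y - mu) ** 2 / var)
        assert pollutant_loglik(panel, ms, ev, lf, fs) == pytest.approx(total, abs=1e-12)

    def test_site_permutation_invariance(self, rng):
        panel, ms, ev, lf, fs = self._toy(rng, n=3)
        base = pollutant_loglik(panel, ms, ev, lf, fs)
        perm = np.array([2, 0, 1])
        panel2 = PollutantPanel(Y=panel.Y[:, perm], sites=SpatialSites(
            ids=tuple(np.array(panel.sites.ids)[perm]), coords=panel.sites.coords[perm]),
            network=panel.network[perm], pollutant_names=panel.pollutant_names)
        from pmfactors.pollutant_model import LoadingField
        lf2 = LoadingField(lam=lf.lam[perm], log_diag=lf.log_diag[perm],
                           free={k: v[perm] for k, v in lf.free.items()})
        fs2 = FactorState(delta=fs.delta[:, perm], delta0=fs.delta0[perm])
        assert pollutant_loglik(panel2, ms, ev, lf2, fs2) == pytest.approx(base)

    def test_implied_cross_pollutant_covariance(self):
        # Lambda Var(delta) Lambda' + diag(sigma2) vs simulated covariance
        rng = np.random.default_rng(3)
        lam = np.array([[1.0], [0.8]])
        var_delta = 2.0
        sig2 = np.array([0.3, 0.4])
        n_draws = 50_000
        delta = rng.normal(0, np.sqrt(var_delta), n_draws)
        y = delta[:, None] * lam[:, 0][None, :] \
            + rng.normal(size=(n_draws, 2)) * np.sqrt(sig2)[None, :]
        implied = lam @ lam.T * var_delta + np.diag(sig2)
        emp = np.cov(y.T)
        assert np.abs(emp - implied).max() < 0.05


class TestStandardize:
    def test_population_sd_convention(self):
        out = standardize_field(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(out, [-1.224744871391589, 0.0, 1.224744871391589])

    def test_idempotent(self, rng):
        x = standardize_field(rng.normal(size=50))
        assert np.allclose(standardize_field(x), x, atol=1e-12)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(8)
        y = rng.normal(size=30)
        assert np.allclose(standardize_field(a * y + b), standardize_field(y),
                           atol=1e-9)

    def test_constant_field_rejected(self):
        with pytest.raises(InvalidParameterError):
            standardize_field(np.ones(5))

    def test_nan_aware(self):
        x = np.array([1.0, np.nan, 3.0])
        out = standardize_field(x)
        assert np.isnan(out[1]) and np.isclose(out[0], -1.0)


class TestConditionalFactorPath:
    def test_station_location_reproduces_path(self, rng):
        n, T, M = 3, 5, 1
        sites = SpatialSites(ids=tuple("abc"), coords=rng.uniform(0, 200, (n, 2)))
        pf = PropagationField(gamma=rng.uniform(-0.7, 0.7, (n, M)),
                              hyper=[GPHyper(0.25, 150.0)])
        hypers = {"innovation": GPHyper(1.0, 100.0), "delta0": [GPHyper(2.0, 120.0)]}
        fs = FactorState(delta=rng.normal(size=(T, n, M)),
                         delta0=rng.normal(size=(n, M)))
        path, _, _ = conditional_factor_path(fs, pf, hypers, sites,
                                             sites.coords[[1]], mode="mean")
        assert np.abs(path[:, 0, 0] - fs.delta[:, 1, 0]).max() < 1e-5

    def test_far_site_reverts_to_zero_mean(self, rng):
        n, T, M = 3, 5, 1
        sites = SpatialSites(ids=tuple("abc"), coords=rng.uniform(0, 50, (n, 2)))
        pf = PropagationField(gamma=rng.uniform(-0.7, 0.7, (n, M)),
                              hyper=[GPHyper(0.25, 30.0)])
        hypers = {"innovation": GPHyper(1.0, 30.0), "delta0": [GPHyper(2.0, 30.0)]}
        fs = FactorState(delta=rng.normal(size=(T, n, M)),
                         delta0=rng.normal(size=(n, M)))
        path, _, _ = conditional_factor_path(fs, pf, hypers, sites,
                                             np.array([[5000.0, 5000.0]]),
                                             mode="mean")
        assert np.abs(path).max() < 1e-6
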