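"""Shared oracles for the inference tests: brute-force joint-Gaussian
conditioning of the stacked factor-state path, and a small random system."""

import numpy as np

from pmfactors.gp_core import GPHyper, SpatialSites
from pmfactors.inference import ModelHypers, _state_matrices
from pmfactors.pollutant_model import (
    ErrorVariances,
    MeanStructure,
    PollutantPanel,
    PropagationField,
    constrain_loadings,
    free_loading_indices,
    mean_matrix,
)


def toy_system(rng, n=2, T=4, P=2, M=1, missing=()):
    sites = SpatialSites(ids=tuple(f"s{i}" for i in range(n)),
                         coords=rng.uniform(0, 100, (n, 2)))
    network = np.array(["STN", "IMPROVE"] * n)[:n]
    Y = rng.normal(size=(T, n, P))
    for cell in missing:
        Y[cell] = np.nan
    panel = PollutantPanel(Y=Y, sites=sites, network=network,
                           pollutant_names=tuple(f"p{j}" for j in range(P)))
    ms = MeanStructure(mu0=rng.normal(size=P), mu1=rng.normal(size=P))
    ev = ErrorVariances(sigma2_stn=rng.uniform(0.4, 1.0, P),
                        sigma2_imp=rng.uniform(0.4, 1.0, P))
    free = {k: rng.normal(0, 0.5, n) for k in free_loading_indices(P, M)}
    lf = constrain_loadings(P, rng.normal(0, 0.3, (n, M)), free)
    prop_hyper = [GPHyper(0.25, 80.0) for _ in range(M)]
    pf = PropagationField(gamma=rng.uniform(-0.8, 0.8, (n, M)), hyper=prop_hyper)
    hypers = ModelHypers(
        innovation=GPHyper(1.0, 60.0),
        delta0=[GPHyper(2.0, 70.0) for _ in range(M)],
        propagation=prop_hyper,
        loading={k: GPHyper(1.0, 80.0)
                 for k in list(free) + [(f, f) for f in range(M)]},
    )
    return panel, ms, ev, lf, pf, hypers


def brute_force_smoother(panel, ms, ev, lf, pf, hypers):
    """Exact posterior of the state path by conditioning one big Gaussian."""
    T, n, P = panel.Y.shape
    M = pf.gamma.shape[1]
    W, P0, g, F = _state_matrices(panel, lf, pf, hypers, "exponential")
    K = n * M
    dim = (T + 1) * K
    C = np.zeros((dim, dim))
    C[:K, :K] = P0
    for t in range(1, T + 1):
        for u in range(t):
            blk = g[:, None] * C[(t - 1) * K:t * K, u * K:(u + 1) * K]
            C[t * K:(t + 1) * K, u * K:(u + 1) * K] = blk
            C[u * K:(u + 1) * K, t * K:(t + 1) * K] = blk.T
        C[t * K:(t + 1) * K, t * K:(t + 1) * K] = \
            (g[:, None] * C[(t - 1) * K:t * K, (t - 1) * K:t * K]) * g[None, :] + W
    mu_flat = mean_matrix(ms, panel.network).reshape(-1)
    var_flat = ev.per_site(panel.network).reshape(-1)
    rows, yv, vv = [], [], []
    for t in range(1, T + 1):
        obs = np.nonzero(~np.isnan(panel.Y[t - 1].reshape(-1)))[0]
        for o in obs:
            row = np.zeros(dim)
            row[t * K:(t + 1) * K] = F[o]
            rows.append(row)
            yv.append(panel.Y[t - 1].reshape(-1)[o] - mu_flat[o])
            vv.append(var_flat[o])
    if not rows:
        return np.zeros((T + 1, K)), np.stack(
            [C[t * K:(t + 1) * K, t * K:(t + 1) * K] for t in range(T + 1)])
    H = np.array(rows)
    S = H @ C @ H.T + np.diag(vv)
    gain = C @ H.T @ np.linalg.inv(S)
    mean = (gain @ np.array(yv)).reshape(T + 1, K)
    cov = C - gain @ H @ C
    margs = np.stack([cov[t * K:(t + 1) * K, t * K:(t + 1) * K]
                      for t in range(T + 1)])
    return mean, margs
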