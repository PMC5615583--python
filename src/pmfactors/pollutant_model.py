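"""Multivariate dynamic spatial factor model for speciated PM2.5.

Observation and evolution equations (a dynamic linear model per site):

    Y_t(s)   = mu_t(s) + Lambda(s) delta_t(s) + eps_t(s)
    delta_t(s) = Gamma(s) delta_{t-1}(s) + w_t(s)

with P observed log-concentrations, M <= P latent factors, spatially smooth
factor loadings Lambda(s) (lower-triangular identification: lambda_pf = 0 for
f > p, lambda_pp = exp(GP) > 0, free GP entries below the diagonal), diagonal
propagation Gamma(s) with entries in (-1, 1), spatially correlated
innovations w_t, and network-specific means and error variances (STN vs
IMPROVE monitors).

Concentrations are modeled on the log scale; weekly cell values are means of
log-concentrations within ISO-style weeks anchored to the first Monday at or
before the first observation.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .gp_core import GPHyper, InvalidParameterError, SpatialSites

log = logging.getLogger(__name__)

NETWORKS = ("STN", "IMPROVE")

# pollutant list of the speciated PM2.5 panel this model targets
STUDY_SCALE_POLLUTANTS = (
    "Ammonium", "Nitrate", "Sulfate", "Total Carbon Mass", "Calcium",
    "Iron", "Potassium", "Silicon", "Sulfur",
)


def normalize_network(label):
    lab = str(label).strip().upper()
    if lab in ("STN",):
        return "STN"
    if lab in ("IMPROVE", "IMP"):
        return "IMPROVE"
    raise InvalidParameterError(f"unknown network label {label!r}")


@dataclass
class PollutantPanel:
    """Station x week x pollutant array of weekly mean log-concentrations.

    ``Y`` has shape (T, n, P) with NaN marking missing cells (a week with no
    measurement at that site, or a pollutant a network does not collect).
    """

    Y: np.ndarray
    sites: SpatialSites
    network: np.ndarray
    pollutant_names: tuple
    week_anchor: _dt.date = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.network = np.asarray([normalize_network(x) for x in np.asarray(self.network)])
        self.pollutant_names = tuple(self.pollutant_names)
        t, n, p = self.Y.shape
        if n != self.sites.n or n != self.network.shape[0] or p != len(self.pollutant_names):
            raise InvalidParameterError("panel dimensions inconsistent")
        if t < 1 or n < 1 or p < 1:
            raise InvalidParameterError("T, n, P must all be >= 1")

    @property
    def T(self):
        return self.Y.shape[0]

    @property
    def n(self):
        return self.Y.shape[1]

    @property
    def P(self):
        return self.Y.shape[2]

    @property
    def mask(self):
        """Boolean (T, n, P), True where the cell is observed."""
        return ~np.isnan(self.Y)

    def is_stn(self):
        return self.network == "STN"

    def week_of_date(self, date):
        if self.week_anchor is None:
            raise InvalidParameterError("panel has no calendar anchor")
        d = pd.Timestamp(date).date()
        return (d - self.week_anchor).days // 7


@dataclass
class MeanStructure:
    """Network intercepts: mu0_p at IMPROVE sites, mu0_p + mu1_p at STN sites.

    An optional annual harmonic pair per pollutant captures seasonality; it is
    off (zero amplitude) by default.
    """

    mu0: np.ndarray
    mu1: np.ndarray
    harmonic_cos: np.ndarray = None
    harmonic_sin: np.ndarray = None

    def __post_init__(self):
        self.mu0 = np.asarray(self.mu0, dtype=float)
        self.mu1 = np.asarray(self.mu1, dtype=float)
        if self.mu0.shape != self.mu1.shape or self.mu0.ndim != 1:
            raise InvalidParameterError("mu0/mu1 must be equal-length vectors")
        if not (np.all(np.isfinite(self.mu0)) and np.all(np.isfinite(self.mu1))):
            raise InvalidParameterError("mean structure must be finite")
        for name in ("harmonic_cos", "harmonic_sin"):
            v = getattr(self, name)
            setattr(self, name, np.zeros_like(self.mu0) if v is None
                    else np.asarray(v, dtype=float))


@dataclass
class ErrorVariances:
    """Network-specific observation-error variances per pollutant."""

    sigma2_stn: np.ndarray
    sigma2_imp: np.ndarray

    def __post_init__(self):
        self.sigma2_stn = np.asarray(self.sigma2_stn, dtype=float)
        self.sigma2_imp = np.asarray(self.sigma2_imp, dtype=float)
        if np.any(self.sigma2_stn <= 0) or np.any(self.sigma2_imp <= 0):
            raise InvalidParameterError("error variances must be positive")

    def per_site(self, network):
        """(n, P) variance array given per-site network labels."""
        stn = np.asarray(network) == "STN"
        return np.where(stn[:, None], self.sigma2_stn[None, :], self.sigma2_imp[None, :])


def free_loading_indices(P, M):
    """(p, f) pairs of unconstrained loading entries, row-major.

    Rows p < M have free entries f < p; rows p >= M are entirely free.
    """
    if M > P:
        raise InvalidParameterError("M must be <= P")
    return [(p, f) for p in range(P) for f in range(M) if f < p or p >= M]


def diag_loading_indices(P, M):
    return [(p, p) for p in range(min(P, M))]


def n_structural_zeros(P, M):
    return M * (M - 1) // 2


@dataclass
class LoadingField:
    """Per-site P x M loading matrices with the identification structure.

    ``log_diag[s, f]`` holds log(lambda_ff(s)); ``free[(p, f)]`` are the
    unconstrained site-vectors.  ``lam`` is the assembled (n, P, P->M) array.
    """

    lam: np.ndarray
    log_diag: np.ndarray
    free: dict
    hyper: dict = field(default_factory=dict)

    @property
    def n(self):
        return self.lam.shape[0]

    @property
    def P(self):
        return self.lam.shape[1]

    @property
    def M(self):
        return self.lam.shape[2]


def constrain_loadings(P, log_diag, free, hyper=None):
    """Assemble a :class:`LoadingField` from free GP site-vectors.

    Structural zeros (f > p) are exact; diagonal entries exp(log_diag) are
    strictly positive; entries below the diagonal and all rows p >= M are
    free.  For M = 1 every pollutant loads on the single factor.
    """
    log_diag = np.atleast_2d(np.asarray(log_diag, dtype=float))
    n, M = log_diag.shape
    if M > P:
        raise InvalidParameterError(f"M={M} factors exceed P={P} pollutants")
    lam = np.zeros((n, P, M))
    for f in range(M):
        lam[:, f, f] = np.exp(log_diag[:, f])
    expected = set(free_loading_indices(P, M))
    got = set(free.keys())
    if got != expected:
        raise InvalidParameterError(
            f"free entries {sorted(got)} do not match required {sorted(expected)}")
    for (p, f), v in free.items():
        v = np.asarray(v, dtype=float)
        if v.shape != (n,):
            raise InvalidParameterError(f"free entry {(p, f)} must be an n-vector")
        lam[:, p, f] = v
    return LoadingField(lam=lam, log_diag=log_diag, free=dict(free),
                        hyper=dict(hyper or {}))


@dataclass
class PropagationField:
    """Diagonal factor-propagation coefficients gamma_f(s), all in (-1, 1)."""

    gamma: np.ndarray
    hyper: list = field(default_factory=list)

    def __post_init__(self):
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if np.any(np.abs(self.gamma) >= 1.0):
            raise InvalidParameterError("propagation coefficients must lie in (-1, 1)")


@dataclass
class FactorState:
    """Latent factor paths delta_t(s) plus initial values delta_0(s)."""

    delta: np.ndarray
    delta0: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.delta0 = np.asarray(self.delta0, dtype=float)
        if self.delta.ndim != 3 or self.delta0.shape != self.delta.shape[1:]:
            raise InvalidParameterError("delta must be (T, n, M) with matching delta0")
        if not (np.all(np.isfinite(self.delta)) and np.all(np.isfinite(self.delta0))):
            raise InvalidParameterError("factor state must be finite")


STATION_COLUMNS = ("site_id", "lon", "lat", "network", "date", "pollutant", "value")


def week_anchor_for(dates):
    """First Monday at or before the earliest date."""
    d0 = min(pd.Timestamp(d).date() for d in dates)
    return d0 - _dt.timedelta(days=d0.weekday())


def weekly_average(records, pollutant_names=None, week_anchor=None,
                   projection_ref=None, n_weeks=None):
    """Collapse raw station records to a weekly (T, n, P) log-scale panel.

    ``records`` is a DataFrame with columns ``site_id, lon, lat, network,
    date, pollutant, value`` (concentrations in ug/m^3).  Non-positive
    concentrations cannot be log-transformed and are dropped with a logged
    count.  A cell with no measurement in a week stays missing (NaN) and is
    excluded from every likelihood.
    """
    df = pd.DataFrame(records).copy()
    missing_cols = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise InvalidParameterError(f"station records missing columns {missing_cols}")
    df["date"] = pd.to_datetime(df["date"])
    df["network"] = [normalize_network(x) for x in df["network"]]

    bad = ~(pd.to_numeric(df["value"], errors="coerce") > 0)
    if bad.any():
        log.info("dropping %d non-positive/unparseable concentration records", int(bad.sum()))
        df = df.loc[~bad]
    if df.empty:
        raise InvalidParameterError("no usable station records")
    df["logval"] = np.log(df["value"].astype(float))

    anchor = week_anchor if week_anchor is not None else week_anchor_for(df["date"])
    df["week"] = (df["date"].dt.date - anchor).apply(lambda d: d.days // 7)
    if (df["week"] < 0).any():
        raise InvalidParameterError("records precede the week anchor")

    site_info = df.groupby("site_id").agg(
        lon=("lon", "first"), lat=("lat", "first"), network=("network", "first"))
    nets = df.groupby("site_id")["network"].nunique()
    if (nets > 1).any():
        raise InvalidParameterError(
            f"sites with conflicting network labels: {list(nets[nets > 1].index)}")
    site_ids = tuple(site_info.index)
    sites = SpatialSites.from_lonlat(site_ids, site_info["lon"].to_numpy(),
                                     site_info["lat"].to_numpy(), ref=projection_ref)

    if pollutant_names is None:
        pollutant_names = tuple(sorted(df["pollutant"].unique()))
    p_index = {p: j for j, p in enumerate(pollutant_names)}
    unknown = set(df["pollutant"]) - set(pollutant_names)
    if unknown:
        raise InvalidParameterError(f"unknown pollutants {sorted(unknown)}")

    T = int(df["week"].max()) + 1 if n_weeks is None else int(n_weeks)
    s_index = {s: i for i, s in enumerate(site_ids)}
    Y = np.full((T, sites.n, len(pollutant_names)), np.nan)
    grouped = df.groupby(["week", "site_id", "pollutant"])["logval"].mean()
    for (wk, sid, pol), v in grouped.items():
        if wk < T:
            Y[int(wk), s_index[sid], p_index[pol]] = v
    return PollutantPanel(Y=Y, sites=sites,
                          network=site_info["network"].to_numpy(),
                          pollutant_names=pollutant_names, week_anchor=anchor)


def observation_mean(ms, network_label, p, week=None, period=52.18):
    """Mean of pollutant p at a site of the given network (optional seasonality)."""
    net = normalize_network(network_label)
    base = ms.mu0[p] + (ms.mu1[p] if net == "STN" else 0.0)
    if week is not None:
        ang = 2.0 * np.pi * week / period
        base = base + ms.harmonic_cos[p] * np.cos(ang) + ms.harmonic_sin[p] * np.sin(ang)
    return float(base)


def mean_matrix(ms, network, T=None, period=52.18):
    """(n, P) network mean matrix, or (T, n, P) when seasonality is requested."""
    stn = np.asarray(network) == "STN"
    base = ms.mu0[None, :] + np.where(stn[:, None], ms.mu1[None, :], 0.0)
    if T is None:
        return base
    ang = 2.0 * np.pi * np.arange(T)[:, None, None] / period
    seas = ms.harmonic_cos[None, None, :] * np.cos(ang) + ms.harmonic_sin[None, None, :] * np.sin(ang)
    return base[None, :, :] + seas


def factor_step(delta_prev, gamma, innovation):
    """One evolution step delta_t = gamma * delta_{t-1} + w_t (elementwise)."""
    return np.asarray(gamma) * np.asarray(delta_prev) + np.asarray(innovation)


def pollutant_loglik(panel, ms, ev, lf, fs, seasonal=False):
    """Gaussian log-likelihood of the panel under the factor model.

    Sums over non-missing cells only; each cell uses its network-specific
    mean and error variance.
    """
    mu = mean_matrix(ms, panel.network, T=panel.T if seasonal else None)
    fitted = mu + np.einsum("npm,tnm->tnp", lf.lam, fs.delta)
    var = ev.per_site(panel.network)[None, :, :]
    mask = panel.mask
    resid = np.where(mask, panel.Y - fitted, 0.0)
    ll_cells = -0.5 * (np.log(2.0 * np.pi * var) + resid ** 2 / var)
    return float(np.sum(ll_cells[mask]))


def standardize_field(values):
    """Center/scale to mean 0, population SD 1 over non-missing entries."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise InvalidParameterError("no finite entries to standardize")
    mu = v[finite].mean()
    sd = v[finite].std(ddof=0)
    if sd == 0:
        raise InvalidParameterError("cannot standardize a constant field")
    return (v - mu) / sd


def conditional_factor_path(fs, pf, hypers, sites, new_coords, rng=None,
                            mode="sample", kernel="exponential",
                            krige_ops=None):
    """Factor path at new locations given the station path (composition sampling).

    The conditional law kriges the initial values delta_0 and each week's
    innovation w_t = delta_t - gamma * delta_{t-1} from the stations to the
    new sites (exact GP conditionals, shared across weeks), takes the
    propagation coefficients at the new sites as the kriged conditional mean
    of gamma clipped into (-1, 1), and runs the evolution recursion.

    Parameters
    ----------
    hypers : mapping with keys ``innovation`` (GPHyper), ``delta0`` (list of
        GPHyper per factor) and ``propagation`` (list of GPHyper per factor).
    mode : "sample" draws from the conditional law; "mean" returns the
        conditional mean path (deterministic kriging).

    Returns
    -------
    (delta_new, delta0_new, gamma_new) with shapes (T, m, M), (m, M), (m, M).
    """
    from .gp_core import KrigeOps

    rng = np.random.default_rng(rng)
    new_coords = np.atleast_2d(np.asarray(new_coords, dtype=float))
    T, n, M = fs.delta.shape
    m = new_coords.shape[0]
    ops = krige_ops if krige_ops is not None else KrigeOps(sites, new_coords, kernel)

    gamma_new = np.empty((m, M))
    for f in range(M):
        a_g, _ = ops.weights(pf.hyper[f].range)
        gamma_new[:, f] = np.clip(a_g @ pf.gamma[:, f], -1.0 + 1e-6, 1.0 - 1e-6)

    delta0_new = np.empty((m, M))
    for f in range(M):
        hyp = hypers["delta0"][f]
        a0, _ = ops.weights(hyp.range)
        mean0 = a0 @ fs.delta0[:, f]
        if mode == "sample" and hyp.variance > 0:
            L0 = np.sqrt(hyp.variance) * ops.chol_cond(hyp.range)
            delta0_new[:, f] = mean0 + L0 @ rng.standard_normal(m)
        else:
            delta0_new[:, f] = mean0

    hyp_w = hypers["innovation"]
    a_w, _ = ops.weights(hyp_w.range)
    prev = np.concatenate([fs.delta0[None], fs.delta[:-1]], axis=0)
    w_obs = fs.delta - pf.gamma[None, :, :] * prev                     # (T, n, M)
    w_mean = np.einsum("ij,tjm->tim", a_w, w_obs)
    if mode == "sample" and hyp_w.variance > 0:
        L_w = np.sqrt(hyp_w.variance) * ops.chol_cond(hyp_w.range)
        w_new = w_mean + np.einsum("ij,tjm->tim", L_w, rng.standard_normal((T, m, M)))
    else:
        w_new = w_mean

    delta_new = np.empty((T, m, M))
    x = delta0_new
    for t in range(T):
        x = factor_step(x, gamma_new, w_new[t])
        delta_new[t] = x
    return delta_new, delta0_new, gamma_new


def draw_exposures_from_moments(mean, cov, rng):
    """Batched draw d_i ~ N(mean_i, cov_i) of per-mother exposure vectors."""
    rng = np.random.default_rng(rng)
    N, L, M = mean.shape
    d = L * M
    jit = 1e-10 * (1.0 + cov.reshape(N, -1).max(axis=1))
    Lc = np.linalg.cholesky(cov + jit[:, None, None] * np.eye(d)[None])
    out = mean.reshape(N, d) + np.einsum("nij,nj->ni", Lc,
                                         rng.standard_normal((N, d)))
    return out.reshape(N, L, M)


def mother_exposure_moments(fs, pf, hypers, sites, uniq_coords, site_of,
                            week_idx, krige_ops=None, kernel="exponential"):
    """Per-mother Gaussian law of the 6-week exposure vector given the
    station-level factor field.

    Each subject's exposures are modeled as conditionally independent across
    subjects given the station path: the mean comes from kriging the initial
    values and weekly innovations to her residence(s) and propagating with
    the kriged (clipped) propagation coefficient; the covariance accumulates
    the kriging-residual variance through the same AR recursion, so a mother
    at a station has (numerically) zero exposure uncertainty and one far
    from every monitor reverts to the stationary prior.  Movers carry the
    cross-site conditional correlation between their two addresses.

    Parameters
    ----------
    uniq_coords : (m, 2) unique residence coordinates
    site_of : (N, 6) int, index into ``uniq_coords`` per gestational week
    week_idx : (N, 6) int, 0-based panel week per gestational week

    Returns
    -------
    (mean, cov): mean (N, 6, M); cov (N, 6M, 6M) block-diagonal per factor
    with the (l, m) C-order flattening.
    """
    from .gp_core import KrigeOps

    ops = krige_ops if krige_ops is not None else KrigeOps(sites, uniq_coords, kernel)
    T, n, M = fs.delta.shape
    N = site_of.shape[0]
    L = site_of.shape[1]
    path, _, gamma_new = conditional_factor_path(
        fs, pf, hypers, sites, uniq_coords, mode="mean", kernel=kernel,
        krige_ops=ops)
    mean = path[week_idx, site_of, :]                              # (N, L, M)

    _, cc_w = ops.weights(hypers["innovation"].range)
    s2_w = hypers["innovation"].variance
    cov = np.zeros((N, L * M, L * M))
    tmax = int(week_idx.max()) + 1
    is_mover = ~np.all(site_of == site_of[:, [0]], axis=1)
    # recursion index r = panel week + 1 (r = 0 is the initial state)
    rsel = week_idx + 1
    dmat = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    minidx = np.minimum(np.arange(L)[:, None], np.arange(L)[None, :])

    for f in range(M):
        _, cc_0 = ops.weights(hypers["delta0"][f].range)
        s2_0 = hypers["delta0"][f].variance
        a = gamma_new[:, f]                                        # (m,)
        # single-site residual-variance table V[r, j]
        V = np.empty((tmax + 1, len(uniq_coords)))
        V[0] = s2_0 * np.clip(np.diag(cc_0), 0.0, None)
        qw = s2_w * np.clip(np.diag(cc_w), 0.0, None)
        for r in range(1, tmax + 1):
            V[r] = a ** 2 * V[r - 1] + qw
        rows = (np.arange(L * M).reshape(L, M)[:, f])
        home = site_of[:, 0]
        a_i = a[home]                                              # (N,)
        vsel = V[rsel, site_of]                                    # (N, L)
        vmin = vsel[np.arange(N)[:, None, None], minidx[None]]     # (N, L, L)
        block = (a_i[:, None, None] ** dmat[None]) * vmin
        cov[np.ix_(np.arange(N), rows, rows)] = block

        movers = np.nonzero(is_mover)[0]
        if movers.size:
            # batched joint 2-site residual recursion across movers:
            # same-time blocks V_r per mover, cross-time cov(r, u) =
            # diag(a)^(r-u) V_u for r >= u (weeks are consecutive, so the
            # lag equals |p - q| in window positions)
            jA = site_of[movers, 0]
            jB = site_of[movers, L - 1]
            pair = np.stack([jA, jB], axis=1)                      # (k, 2)
            aa = a[pair]                                           # (k, 2)
            cc2_w = s2_w * cc_w[pair[:, :, None], pair[:, None, :]]
            cc2_0 = s2_0 * cc_0[pair[:, :, None], pair[:, None, :]]
            rmax = int(rsel[movers].max())
            vjoint = np.empty((rmax + 1, movers.size, 2, 2))
            vjoint[0] = cc2_0
            for r in range(1, rmax + 1):
                vjoint[r] = (aa[:, :, None] * vjoint[r - 1]) * aa[:, None, :] + cc2_w
            which = (site_of[movers] != jA[:, None]).astype(int)   # (k, L)
            ri = rsel[movers]                                      # (k, L)
            kk = np.arange(movers.size)[:, None, None]
            rp = np.maximum(ri[:, :, None], ri[:, None, :])
            rq = np.minimum(ri[:, :, None], ri[:, None, :])
            later = (ri[:, :, None] >= ri[:, None, :])
            wp = np.where(later, which[:, :, None], which[:, None, :])
            wq = np.where(later, which[:, None, :], which[:, :, None])
            blk = aa[kk, wp] ** (rp - rq) * vjoint[rq, kk, wp, wq]
            cov[np.ix_(movers, rows, rows)] = blk
    return mean, cov
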