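"""Gaussian-process building blocks shared by every spatial prior in the model.

All spatial computations happen on a planar projection in kilometres:
longitude/latitude are mapped to (x, y) km by an equirectangular projection
about a reference point, and correlation is an isotropic function of
Euclidean distance.  The default family is the exponential kernel
``R(d, phi) = exp(-d / phi)``; a Matern-3/2 alternative is available.

The module also provides interval-truncated multivariate-normal sampling by
coordinate-wise Gibbs over univariate truncated-normal full conditionals,
which is how the (-1, 1) constraint on the factor propagation field is
realized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from scipy.special import ndtr, ndtri

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
#: relative jitter added to covariance diagonals before factorization
JITTER_FRAC = 1e-8

KERNELS = ("exponential", "matern32")


class InvalidParameterError(ValueError):
    """A hyperparameter violates its positivity/ordering constraint."""


class IllConditionedError(np.linalg.LinAlgError):
    """A covariance system is singular in a way jitter must not paper over."""


def project_lonlat(lon, lat, ref):
    """Project degrees lon/lat to planar (x, y) km, equirectangular about ref.

    ``ref`` is the (lon0, lat0) tuple of the projection centre.  Adequate for
    a California-sized extent (<1% distortion).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = ref
    x = np.radians(lon - lon0) * np.cos(np.radians(lat0)) * EARTH_RADIUS_KM
    y = np.radians(lat - lat0) * EARTH_RADIUS_KM
    return np.stack([x, y], axis=-1)


def unproject_xy(coords_km, ref):
    """Inverse of :func:`project_lonlat`; returns (lon, lat) arrays."""
    coords_km = np.asarray(coords_km, dtype=float)
    lon0, lat0 = ref
    lon = lon0 + np.degrees(coords_km[..., 0] / (np.cos(np.radians(lat0)) * EARTH_RADIUS_KM))
    lat = lat0 + np.degrees(coords_km[..., 1] / EARTH_RADIUS_KM)
    return lon, lat


@dataclass(frozen=True)
class GPHyper:
    """Variance and range of an isotropic GP, e.g. (s_w^2, phi_w).

    ``variance`` may be zero (degenerate, mean-reverting draw); ``range`` must
    be strictly positive.
    """

    variance: float
    range: float

    def __post_init__(self):
        if not np.isfinite(self.variance) or self.variance < 0:
            raise InvalidParameterError(f"variance must be >= 0, got {self.variance}")
        if not np.isfinite(self.range) or self.range <= 0:
            raise InvalidParameterError(f"range must be > 0, got {self.range}")


@dataclass(frozen=True)
class SpatialSites:
    """A fixed set of monitoring / residence locations on the km plane.

    Attributes
    ----------
    ids : tuple of str
        Site identifiers, one per row of ``coords``.
    coords : (n, 2) ndarray
        Projected planar coordinates in km.
    ref_lonlat : tuple or None
        Projection reference, kept so cohort residences can be projected
        consistently; None when coordinates were supplied directly in km.
    """

    ids: tuple
    coords: np.ndarray
    ref_lonlat: tuple = None

    def __post_init__(self):
        coords = np.ascontiguousarray(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise InvalidParameterError("coords must be (n, 2)")
        if not np.all(np.isfinite(coords)):
            raise InvalidParameterError("coords must be finite")
        if len(self.ids) != coords.shape[0]:
            raise InvalidParameterError("ids and coords length mismatch")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "_distances", cdist(coords, coords))

    @property
    def n(self):
        return self.coords.shape[0]

    @property
    def distances(self):
        """Symmetric (n, n) Euclidean distance matrix in km."""
        return self._distances

    @classmethod
    def from_lonlat(cls, ids, lon, lat, ref=None):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if ref is None:
            ref = (float(np.mean(lon)), float(np.mean(lat)))
        return cls(ids=tuple(ids), coords=project_lonlat(lon, lat, ref), ref_lonlat=ref)


def _kernel(dist, range_, kernel):
    if kernel == "exponential":
        return np.exp(-dist / range_)
    if kernel == "matern32":
        a = np.sqrt(3.0) * dist / range_
        return (1.0 + a) * np.exp(-a)
    raise InvalidParameterError(f"unknown kernel {kernel!r}; choose from {KERNELS}")


def correlation_matrix(sites, range_, kernel="exponential"):
    """Spatial correlation matrix R(||s-s'||, phi) for a site set.

    ``sites`` may be a :class:`SpatialSites` or a precomputed distance matrix.
    """
    if not np.isfinite(range_) or range_ <= 0:
        raise InvalidParameterError(f"range must be > 0, got {range_}")
    dist = sites.distances if isinstance(sites, SpatialSites) else np.asarray(sites, dtype=float)
    return _kernel(dist, range_, kernel)


def chol_with_jitter(cov, jitter_frac=JITTER_FRAC):
    """Lower Cholesky of a covariance, escalating diagonal jitter on failure."""
    cov = np.asarray(cov, dtype=float)
    scale = max(float(np.mean(np.diag(cov))), 1e-300)
    jitter = jitter_frac * scale
    for _ in range(6):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    log.warning("covariance numerically stabilized with large jitter %.3g", jitter)
    # final attempt with eigenvalue clipping
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    w = np.clip(w, jitter, None)
    return np.linalg.cholesky((v * w) @ v.T)


def gp_sample(sites, hyper, mean=None, rng=None, kernel="exponential"):
    """One draw from GP(mean, variance * R(phi)) at the given sites.

    A zero-variance hyper returns ``mean`` exactly.  Reproducible for a fixed
    ``rng`` state.
    """
    rng = np.random.default_rng(rng)
    n = sites.n if isinstance(sites, SpatialSites) else np.asarray(sites).shape[0]
    mu = np.zeros(n) if mean is None else np.asarray(mean, dtype=float)
    if hyper.variance == 0.0:
        return mu.copy()
    cov = hyper.variance * correlation_matrix(sites, hyper.range, kernel)
    L = chol_with_jitter(cov)
    return mu + L @ rng.standard_normal(n)


def _coords_of(sites):
    return sites.coords if isinstance(sites, SpatialSites) else np.atleast_2d(np.asarray(sites, dtype=float))


def krige_conditional(obs_sites, obs_values, new_sites, hyper, nugget=0.0,
                      kernel="exponential"):
    """Exact GP conditional (kriging) mean and covariance at new sites.

    The prior is a zero-mean GP with ``hyper`` = (variance, range); the
    observations carry iid Gaussian noise of variance ``nugget`` (0 = exact
    interpolation).  ``obs_values`` may be (n,) or (n, k) — the k columns are
    kriged with one shared linear solve and share the returned covariance.

    Returns ``(mean, cov)`` with ``mean`` of shape (m,) or (m, k) and ``cov``
    of shape (m, m).
    """
    if nugget < 0:
        raise InvalidParameterError("nugget must be >= 0")
    obs_coords = _coords_of(obs_sites)
    new_coords = _coords_of(new_sites)
    y = np.asarray(obs_values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise InvalidParameterError("obs_values must be finite")
    n, m = obs_coords.shape[0], new_coords.shape[0]
    if n == 0 or m == 0:
        raise InvalidParameterError("site sets must be non-empty")

    squeeze = y.ndim == 1
    y2 = y[:, None] if squeeze else y

    if hyper.variance == 0.0:
        mean = np.zeros((m, y2.shape[1]))
        return (mean[:, 0] if squeeze else mean), np.zeros((m, m))

    d_oo = cdist(obs_coords, obs_coords)
    if nugget == 0.0:
        # duplicate sites with conflicting values make the system genuinely
        # inconsistent; refuse rather than let jitter fabricate an answer
        dup = (d_oo < 1e-9) & ~np.eye(n, dtype=bool)
        if np.any(dup):
            ii, jj = np.nonzero(dup)
            if np.any(np.abs(y2[ii] - y2[jj]) > 1e-10):
                raise IllConditionedError(
                    "duplicate observation sites with conflicting values and zero nugget")
    r_oo = _kernel(d_oo, hyper.range, kernel)
    r_no = _kernel(cdist(new_coords, obs_coords), hyper.range, kernel)
    r_nn = _kernel(cdist(new_coords, new_coords), hyper.range, kernel)

    k_oo = hyper.variance * r_oo + (nugget + JITTER_FRAC * hyper.variance) * np.eye(n)
    c, lower = cho_factor(k_oo, lower=True)
    k_no = hyper.variance * r_no
    alpha = cho_solve((c, lower), y2)
    mean = k_no @ alpha
    half = cho_solve((c, lower), k_no.T)
    cov = hyper.variance * r_nn - k_no @ half
    cov = (cov + cov.T) / 2.0
    # predictive variance can only shrink relative to the prior
    np.fill_diagonal(cov, np.clip(np.diag(cov), 0.0, hyper.variance + nugget))
    return (mean[:, 0] if squeeze else mean), cov


def kriging_weights(obs_sites, new_sites, range_, kernel="exponential",
                    jitter_frac=JITTER_FRAC):
    """Simple-kriging weight matrix A (m, n) and conditional correlation.

    ``A @ values`` gives conditional means; the conditional covariance of the
    field at the new sites is ``variance * corr_cond``.  Weights depend only
    on the range, not on the GP variance.
    """
    obs_coords = _coords_of(obs_sites)
    new_coords = _coords_of(new_sites)
    n = obs_coords.shape[0]
    r_oo = _kernel(cdist(obs_coords, obs_coords), range_, kernel) + jitter_frac * np.eye(n)
    r_no = _kernel(cdist(new_coords, obs_coords), range_, kernel)
    r_nn = _kernel(cdist(new_coords, new_coords), range_, kernel)
    c, lower = cho_factor(r_oo, lower=True)
    a = cho_solve((c, lower), r_no.T).T
    corr_cond = r_nn - a @ r_no.T
    corr_cond = (corr_cond + corr_cond.T) / 2.0
    return a, corr_cond


class KrigeOps:
    """Cached station-to-target kriging operators, keyed by range.

    The MCMC revisits the same handful of grid ranges thousands of times;
    the weight matrix, the conditional correlation, and its Cholesky factor
    are range-only quantities worth memoizing.
    """

    def __init__(self, obs_sites, new_coords, kernel="exponential"):
        self.obs = _coords_of(obs_sites)
        self.new = np.atleast_2d(np.asarray(new_coords, dtype=float))
        self.kernel = kernel
        self._memo = {}

    def weights(self, range_):
        key = float(range_)
        if key not in self._memo:
            a, cc = kriging_weights(self.obs, self.new, key, self.kernel)
            self._memo[key] = (a, cc, None)
        a, cc, _ = self._memo[key]
        return a, cc

    def chol_cond(self, range_):
        key = float(range_)
        a, cc = self.weights(key)
        if self._memo[key][2] is None:
            L = chol_with_jitter(cc + 1e-12 * np.eye(cc.shape[0]))
            self._memo[key] = (a, cc, L)
        return self._memo[key][2]


class SpatialOps:
    """Cached per-range correlation algebra for one fixed site set."""

    def __init__(self, dists, kernel="exponential", jitter=1e-8):
        self.dists = np.asarray(dists, dtype=float)
        self.kernel = kernel
        self.jitter = jitter
        self._memo = {}

    def _entry(self, range_):
        key = float(range_)
        if key not in self._memo:
            n = self.dists.shape[0]
            R = _kernel(self.dists, key, self.kernel) + self.jitter * np.eye(n)
            L = np.linalg.cholesky(R)
            self._memo[key] = {"R": R, "L": L,
                               "logdet": 2.0 * np.log(np.diag(L)).sum(),
                               "Rinv": None}
        return self._memo[key]

    def corr(self, range_):
        return self._entry(range_)["R"]

    def chol(self, range_):
        return self._entry(range_)["L"]

    def logdet(self, range_):
        return self._entry(range_)["logdet"]

    def inv(self, range_):
        e = self._entry(range_)
        if e["Rinv"] is None:
            inv = cho_solve((e["L"], True), np.eye(self.dists.shape[0]))
            e["Rinv"] = (inv + inv.T) / 2.0
        return e["Rinv"]

    def quad_sum(self, range_, vectors):
        """sum_k v_k' R^{-1} v_k for (k, n) stacked field realizations."""
        half = np.linalg.solve(self._entry(range_)["L"], np.atleast_2d(vectors).T)
        return float((half * half).sum())


_PEPS = 1e-15


def truncnorm_rvs(mean, sd, lower, upper, rng):
    """Vectorized truncated-normal draws by inverse-CDF; open interval output."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    a = ndtr((lower - mean) / np.maximum(sd, 1e-300))
    b = ndtr((upper - mean) / np.maximum(sd, 1e-300))
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    u = rng.uniform(size=np.broadcast(mean, sd, lower, upper).shape)
    p = np.clip(a + u * (b - a), _PEPS, 1.0 - _PEPS)
    x = mean + sd * ndtri(p)
    fin = np.where(np.isfinite(lower), np.abs(lower), 0.0) \
        + np.where(np.isfinite(upper), np.abs(upper), 0.0)
    eps = 1e-12 * (1.0 + fin)
    lo = np.where(np.isfinite(lower), lower + eps, lower)
    hi = np.where(np.isfinite(upper), upper - eps, upper)
    return np.clip(x, lo, hi)


def sample_truncated_mvn(mean, prec, lower, upper, rng, sweeps=10, start=None):
    """Gibbs draw from N(mean, prec^-1) restricted to the box (lower, upper).

    Coordinate-wise sweeps over univariate truncated-normal full conditionals;
    ``start`` (default: box-clipped mean) seeds the chain, ``sweeps`` controls
    mixing per returned draw.
    """
    mean = np.asarray(mean, dtype=float)
    prec = np.asarray(prec, dtype=float)
    n = mean.shape[0]
    if not lower < upper:
        raise InvalidParameterError("lower must be < upper")
    pad = 1e-6 * (upper - lower)
    x = np.clip(mean if start is None else np.asarray(start, dtype=float),
                lower + pad, upper - pad).copy()
    diag = np.diag(prec)
    if np.any(diag <= 0):
        raise InvalidParameterError("precision diagonal must be positive")
    sd = 1.0 / np.sqrt(diag)
    for _ in range(sweeps):
        for i in range(n):
            r = prec[i] @ (x - mean)
            cond_mean = mean[i] - (r - prec[i, i] * (x[i] - mean[i])) / diag[i]
            a = ndtr((lower - cond_mean) / sd[i])
            b = ndtr((upper - cond_mean) / sd[i])
            p = min(max(a + rng.uniform() * (b - a), _PEPS), 1.0 - _PEPS)
            xi = cond_mean + sd[i] * ndtri(p)
            x[i] = min(max(xi, lower + pad * 1e-3), upper - pad * 1e-3)
    return x


def truncated_gp_sample(sites, hyper, lower=-1.0, upper=1.0, rng=None,
                        sweeps=10, kernel="exponential", start=None):
    """Draw a GP realization conditioned on every entry lying in (lower, upper).

    Used for the factor-propagation field, which must stay inside (-1, 1) for
    temporal stationarity.  Implemented by coordinate-wise Gibbs over
    truncated-normal full conditionals of the box-constrained Gaussian.
    """
    rng = np.random.default_rng(rng)
    n = sites.n if isinstance(sites, SpatialSites) else np.asarray(sites).shape[0]
    if hyper.variance == 0.0:
        mid = 0.0 if lower < 0.0 < upper else (lower + upper) / 2.0
        return np.full(n, mid)
    cov = hyper.variance * correlation_matrix(sites, hyper.range, kernel)
    cov = cov + JITTER_FRAC * hyper.variance * np.eye(n)
    c, lowflag = cho_factor(cov, lower=True)
    prec = cho_solve((c, lowflag), np.eye(n))
    prec = (prec + prec.T) / 2.0
    return sample_truncated_mvn(np.zeros(n), prec, lower, upper, rng,
                                sweeps=sweeps, start=start)
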