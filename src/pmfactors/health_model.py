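"""Bivariate probit model for cleft palate and cleft lip with weekly exposures.

Latent utilities Z_i = (Z_i1, Z_i2) follow

    Z_i = beta^T x_i + sum_m sum_{l=3}^{8} w_{lm} delta_{ilm} + eps_i,
    eps_i ~ N(0, Omega),   Y_ij = I(Z_ij > 0),

where delta_{ilm} is the value of latent pollution factor m at mother i's
residence during gestational week l (weeks 3-8, the embryonic window of lip
and palate formation; movers contribute the week-specific address).  The
weekly coefficients w_{lm} are smoothed across weeks by a GP over |l - l'|.

A probit with a free error covariance Omega is identified only up to a
per-outcome scale; draws are kept on the raw scale and reporting helpers
rescale by 1/sqrt(Omega_jj) so probabilities use the standard-normal CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import ndtr
from scipy.stats import norm

from .gp_core import InvalidParameterError, project_lonlat
from .pollutant_model import conditional_factor_path

log = logging.getLogger(__name__)

OUTCOME_NAMES = ("cleft_palate", "cleft_lip")
GESTATION_WEEKS = (3, 4, 5, 6, 7, 8)
N_EXPO_WEEKS = len(GESTATION_WEEKS)

AGE_LEVELS = ("19_and_under", "20_24", "25_29", "30_34", "35_plus")
EDU_LEVELS = ("less_than_high_school", "high_school", "some_college",
              "college_graduate")
SEX_LEVELS = ("male", "female")
BINARY_VARS = ("hbp", "prediabetes", "smoke", "alcohol")

#: design-column labels, reference levels: age 19 and under, less than high
#: school, male fetus, and "no" for every binary indicator
DESIGN_LABELS = (
    "Maternal age 20-24 vs. 19 and under",
    "Maternal age 25-29 vs. 19 and under",
    "Maternal age 30-34 vs. 19 and under",
    "Maternal age 35+ vs. 19 and under",
    "Fetus Sex-Female",
    "High school diploma vs. Less than high school",
    "Some college vs. Less than high school",
    "College graduate vs. Less than high school",
    "High Blood Pressure",
    "Maternal Prediabetes",
    "Maternal Smoking",
    "Maternal Alcohol Use",
)
N_COVARIATES = len(DESIGN_LABELS)


@dataclass
class CohortTable:
    """Per-subject outcomes, covariate design, and weekly residence history.

    ``y`` columns are (cleft palate, cleft lip); ``x`` is the 0/1 dummy
    design; ``residences`` holds one (x, y) coordinate pair per gestational
    week 3..8 (already on the km plane when ``residences_are_km``, otherwise
    lon/lat awaiting projection); ``conception_week`` indexes the panel week
    of conception (0-based) once aligned to a panel calendar.
    """

    ids: tuple
    y: np.ndarray
    x: np.ndarray
    residences: np.ndarray
    conception_week: np.ndarray = None
    conception_date: np.ndarray = None
    residences_are_km: bool = True

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.residences = np.asarray(self.residences, dtype=float)
        n = len(self.ids)
        if self.y.shape != (n, 2) or not np.isin(self.y, (0, 1)).all():
            raise InvalidParameterError("y must be (N, 2) binary")
        if self.x.shape[0] != n:
            raise InvalidParameterError("x row count mismatch")
        if self.residences.shape != (n, N_EXPO_WEEKS, 2):
            raise InvalidParameterError("residences must be (N, 6, 2)")
        if self.conception_week is not None:
            self.conception_week = np.asarray(self.conception_week, dtype=int)

    @property
    def N(self):
        return len(self.ids)

    @property
    def q(self):
        return self.x.shape[1]


@dataclass
class ExposureMatrix:
    """delta_{ilm}: factor values at each mother's weekly residence, (N, 6, M)."""

    delta: np.ndarray

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim != 3 or self.delta.shape[1] != N_EXPO_WEEKS:
            raise InvalidParameterError("exposures must be (N, 6, M)")
        if not np.all(np.isfinite(self.delta)):
            raise InvalidParameterError("exposures must be finite")


@dataclass
class HealthParams:
    """Probit parameters: beta (q, 2), weekly effects w (6, M, 2), Omega (2, 2)."""

    beta: np.ndarray
    w: np.ndarray
    omega: np.ndarray
    weekly_range: float = 2.0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != (2, 2):
            raise InvalidParameterError("omega must be 2x2")
        if not np.allclose(self.omega, self.omega.T):
            raise InvalidParameterError("omega must be symmetric")
        if np.any(np.linalg.eigvalsh(self.omega) <= 0):
            raise InvalidParameterError("omega must be positive definite")
        if self.w.ndim != 3 or self.w.shape[0] != N_EXPO_WEEKS or self.w.shape[2] != 2:
            raise InvalidParameterError("w must be (6, M, 2)")

    @property
    def correlation(self):
        return float(self.omega[0, 1] / np.sqrt(self.omega[0, 0] * self.omega[1, 1]))


@dataclass
class LatentUtilities:
    """Gaussian utilities Z with sign(Z_ij) matching the observed outcomes."""

    z: np.ndarray

    def check_signs(self, y):
        ok = (self.z > 0) == (np.asarray(y) == 1)
        return bool(ok.all())


def latent_mean(hp, x, delta):
    """Linear predictors eta (N, 2) = x beta + sum_{l,m} w_{lm} delta_{ilm}.

    ``x`` may be (q,) or (N, q); ``delta`` (6, M) or (N, 6, M).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    delta = np.asarray(delta, dtype=float)
    if delta.ndim == 2:
        delta = delta[None]
    eta = x @ hp.beta + np.einsum("lmj,nlm->nj", hp.w, delta)
    return eta[0] if eta.shape[0] == 1 and x.shape[0] == 1 else eta


def defect_probability(eta):
    """P(defect) = Phi(eta) on the unit-variance (rescaled) probit scale."""
    return ndtr(np.asarray(eta, dtype=float))


def bvn_cdf(h, k, rho, n_nodes=96):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Gauss-Legendre quadrature of the Drezner identity
    Phi2(h, k, rho) = Phi(h) Phi(k) + (2 pi)^-1 int_0^rho
    exp(-(h^2 - 2 t h k + k^2) / (2 (1 - t^2))) / sqrt(1 - t^2) dt,
    vectorized over (h, k); adaptive quadrature for |rho| near 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if abs(rho) >= 1.0 - 1e-12:
        raise InvalidParameterError("|correlation| must be < 1")
    base = ndtr(h) * ndtr(k)
    if rho == 0.0:
        return base
    if abs(rho) > 0.95:
        scalar_h, scalar_k = np.broadcast_arrays(h, k)
        out = np.empty(scalar_h.shape)
        it = np.nditer([scalar_h, scalar_k], flags=["multi_index"])
        for hh, kk in it:
            val = quad(lambda t: np.exp(-((hh - t * kk) ** 2 / (1 - t * t) + kk * kk) / 2.0)
                       / np.sqrt(1 - t * t), 0.0, rho, epsabs=1e-13, limit=200)[0]
            out[it.multi_index] = val / (2.0 * np.pi)
        return base + out
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    t = 0.5 * rho * (nodes + 1.0)
    wts = 0.5 * rho * weights
    hh = h[..., None]
    kk = k[..., None]
    integrand = np.exp(-(hh * hh - 2.0 * t * hh * kk + kk * kk) / (2.0 * (1.0 - t * t))) \
        / np.sqrt(1.0 - t * t)
    return base + (integrand * wts).sum(axis=-1) / (2.0 * np.pi)


def joint_outcome_logprob(eta, omega, y):
    """log P(sign pattern of Z matches y) for Z ~ N(eta, Omega).

    ``eta`` and ``y`` may be (2,) or (N, 2); a bivariate-normal rectangle
    probability computed as Phi2(s1 a1, s2 a2, s1 s2 rho) with s_j = 2 y_j - 1
    and a_j = eta_j / sqrt(Omega_jj).
    """
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=int)
    omega = np.asarray(omega, dtype=float)
    sd = np.sqrt(np.diag(omega))
    rho = float(omega[0, 1] / (sd[0] * sd[1]))
    if abs(rho) >= 1.0:
        raise InvalidParameterError("|correlation| must be < 1")
    single = eta.ndim == 1
    eta2 = np.atleast_2d(eta)
    y2 = np.atleast_2d(y)
    s = 2.0 * y2 - 1.0
    a = s * eta2 / sd[None, :]
    out = np.empty(eta2.shape[0])
    srho = s[:, 0] * s[:, 1] * rho
    for sign in np.unique(srho):
        mask = srho == sign
        out[mask] = np.log(np.clip(bvn_cdf(a[mask, 0], a[mask, 1], float(sign)),
                                   1e-300, 1.0))
    return float(out[0]) if single else out


def build_design(rows):
    """Dummy-code raw cohort rows into a :class:`CohortTable`.

    Expects a DataFrame with columns ``id, cleft_palate, cleft_lip, age_cat,
    edu_cat, fetal_sex, hbp, prediabetes, smoke, alcohol, conception_date,
    lon_w3, lat_w3, ..., lon_w8, lat_w8``.  Reference levels: age 19 and
    under, less than high school, male fetus, and "no" for each binary
    indicator — a reference-level subject has an all-zero covariate row.
    """
    df = pd.DataFrame(rows).reset_index(drop=True)
    n = len(df)
    ids = tuple(df["id"].astype(str))
    if len(set(ids)) != n:
        raise InvalidParameterError("duplicate subject ids in cohort")
    x = np.zeros((n, N_COVARIATES))

    def _code(series, levels, what):
        vals = series.astype(str).str.strip().str.lower()
        idx = np.full(n, -1)
        for j, lev in enumerate(levels):
            idx[vals == lev] = j
        bad = np.nonzero(idx < 0)[0]
        if bad.size:
            raise InvalidParameterError(
                f"unknown {what} value {series.iloc[bad[0]]!r} for subject {ids[bad[0]]}")
        return idx

    age = _code(df["age_cat"], AGE_LEVELS, "age category")
    for j in range(1, len(AGE_LEVELS)):
        x[:, j - 1] = age == j
    sex = _code(df["fetal_sex"], SEX_LEVELS, "fetal sex")
    x[:, 4] = sex == 1
    edu = _code(df["edu_cat"], EDU_LEVELS, "education category")
    for j in range(1, len(EDU_LEVELS)):
        x[:, 4 + j] = edu == j
    for j, var in enumerate(BINARY_VARS):
        vals = df[var].astype(str).str.strip().str.lower()
        ok = vals.isin(("0", "1", "yes", "no", "true", "false"))
        if not ok.all():
            bad = np.nonzero(~ok.to_numpy())[0][0]
            raise InvalidParameterError(
                f"unknown {var} value {df[var].iloc[bad]!r} for subject {ids[bad]}")
        x[:, 8 + j] = vals.isin(("1", "yes", "true")).to_numpy()

    y = df[["cleft_palate", "cleft_lip"]].to_numpy(dtype=int)
    res = np.empty((n, N_EXPO_WEEKS, 2))
    for li, week in enumerate(GESTATION_WEEKS):
        res[:, li, 0] = df[f"lon_w{week}"].to_numpy(dtype=float)
        res[:, li, 1] = df[f"lat_w{week}"].to_numpy(dtype=float)
    conception = pd.to_datetime(df["conception_date"]).to_numpy() \
        if "conception_date" in df.columns else None
    return CohortTable(ids=ids, y=y, x=x, residences=res,
                       conception_date=conception, residences_are_km=False)


def align_conception_weeks(cohort, panel):
    """Set 0-based panel week of conception from conception dates."""
    if cohort.conception_week is not None:
        return cohort
    if cohort.conception_date is None:
        raise InvalidParameterError("cohort has neither conception weeks nor dates")
    weeks = np.array([panel.week_of_date(d) for d in cohort.conception_date])
    cohort.conception_week = weeks
    return cohort


def _residences_km(cohort, panel):
    if cohort.residences_are_km:
        return cohort.residences
    ref = panel.sites.ref_lonlat
    if ref is None:
        raise InvalidParameterError("panel sites carry no projection reference")
    return project_lonlat(cohort.residences[..., 0], cohort.residences[..., 1], ref)


def exposure_week_indices(cohort, T):
    """Panel week index of each (subject, gestational week 3..8) pair.

    Gestational week l occupies panel week conception_week + l - 1 (week 1 is
    the conception week itself).  Raises listing offending subjects if any
    window falls outside the panel span.
    """
    if cohort.conception_week is None:
        raise InvalidParameterError("cohort conception weeks not aligned to panel")
    idx = cohort.conception_week[:, None] + np.array(GESTATION_WEEKS)[None, :] - 1
    bad = (idx < 0) | (idx >= T)
    if bad.any():
        offenders = [cohort.ids[i] for i in np.unique(np.nonzero(bad)[0])]
        raise InvalidParameterError(
            f"gestational weeks outside panel span for subjects {offenders}")
    return idx


def extract_exposures(cohort, panel, fs, pf, hypers, rng=None, mode="sample",
                      kernel="exponential"):
    """Interpolate latent factors to each mother's weekly residence.

    Kriges the factor field from the stations to the set of unique residence
    coordinates via :func:`conditional_factor_path` (movers contribute the
    address they occupied in each specific week) and gathers the values at
    each subject's gestational weeks 3-8.
    """
    res_km = _residences_km(cohort, panel)
    week_idx = exposure_week_indices(cohort, panel.T)
    flat = np.round(res_km.reshape(-1, 2), 6)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    path, _, _ = conditional_factor_path(fs, pf, hypers, panel.sites, uniq,
                                         rng=rng, mode=mode, kernel=kernel)
    site_of = inv.reshape(cohort.N, N_EXPO_WEEKS)
    delta_i = path[week_idx, site_of, :]
    return ExposureMatrix(delta=delta_i)


def rescale_health_params(beta, w, omega):
    """Rescale (beta, w) per outcome by 1/sqrt(Omega_jj); returns correlation too.

    The bivariate probit likelihood is invariant to this joint rescaling, so
    rescaled draws put Phi directly on the unit-variance scale.
    """
    sd = np.sqrt(np.diag(omega))
    beta_r = beta / sd[None, :]
    w_r = w / sd[None, None, :]
    rho = float(omega[0, 1] / (sd[0] * sd[1]))
    return beta_r, w_r, rho


def weekly_correlation(weekly_range, kernel="exponential"):
    """Correlation of the weekly-effect GP over |l - l'| in weeks."""
    weeks = np.array(GESTATION_WEEKS, dtype=float)
    dist = np.abs(weeks[:, None] - weeks[None, :])
    if kernel == "exponential":
        return np.exp(-dist / weekly_range)
    a = np.sqrt(3.0) * dist / weekly_range
    return (1.0 + a) * np.exp(-a)
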