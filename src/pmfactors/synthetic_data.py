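"""Synthetic monitoring-network and cohort data with the structure the
analysis assumes.

The spatial domain is an abstract 800 x 900 km rectangle (a California-like
extent) with a denser central study subregion; two monitoring networks (STN
urban-biased, IMPROVE elsewhere) observe speciated PM2.5 every 3-6 days over
multiple years with seasonality, cross-pollutant correlations induced by
shared latent factors (including near-duplicate loading rows emulating the
ammonium/nitrate and sulfur/sulfate pairs), and one pollutant withheld from
the IMPROVE network.  The case-control cohort has correlated binary cleft
outcomes, Table-1-like covariate frequencies, and ~15% residential movers
who relocate once mid-window to a distant subregion.

Every generated dataset is accompanied by a :class:`TruthBundle` holding the
generative parameters and latent paths, the reference for parameter-recovery
tests.  Mother exposures are drawn from the same conditional interpolation
law the sampler uses (kriged initial values and innovations given the
station field), so generator and fitted model share one exposure model.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gp_core import GPHyper, InvalidParameterError, SpatialSites, chol_with_jitter, correlation_matrix
from .health_model import (
    CohortTable,
    ExposureMatrix,
    GESTATION_WEEKS,
    N_COVARIATES,
    N_EXPO_WEEKS,
    latent_mean,
    HealthParams,
)
from .inference import ModelHypers
from .pollutant_model import (
    ErrorVariances,
    FactorState,
    LoadingField,
    MeanStructure,
    STUDY_SCALE_POLLUTANTS,
    PollutantPanel,
    PropagationField,
    constrain_loadings,
    draw_exposures_from_moments,
    mother_exposure_moments,
    diag_loading_indices,
    free_loading_indices,
    mean_matrix,
)

log = logging.getLogger(__name__)

TRUTH_SCHEMA_VERSION = "1"

DOMAIN = ((0.0, 800.0), (0.0, 900.0))
STUDY_BOX = ((250.0, 550.0), (300.0, 600.0))
MOVER_BOX = ((40.0, 200.0), (620.0, 860.0))
#: lon/lat reference used when emitting station/cohort text files
CENTER_LONLAT = (-119.5, 37.0)

TOY_POLLUTANTS = ("Ammonium", "Nitrate", "Sulfate", "Total Carbon Mass")

#: Table-1-like covariate frequencies for the simulated cohort
COVARIATE_FREQS = {
    "age": (0.10, 0.25, 0.28, 0.22, 0.15),
    "edu": (0.25, 0.30, 0.25, 0.20),
    "female": 0.49,
    "hbp": 0.12,
    "prediabetes": 0.05,
    "smoke": 0.15,
    "alcohol": 0.25,
}

#: default regression truth (palate, lip columns), Table-3-scale effects
DEFAULT_BETA = np.array([
    # palate   lip
    [0.345, 0.540],
    [0.439, 0.556],
    [0.440, 0.605],
    [0.385, 0.232],
    [-0.247, -0.405],
    [0.023, -0.021],
    [-0.109, 0.032],
    [-0.430, -0.480],
    [0.050, 0.332],
    [1.214, 1.175],
    [0.183, 0.089],
    [0.106, 0.049],
])

#: weekly exposure-effect truth per defect (palate peaks at week 6)
DEFAULT_W = np.array([
    # palate   lip
    [0.15, 0.10],
    [-0.10, -0.05],
    [-0.10, -0.05],
    [0.30, 0.20],
    [-0.10, -0.08],
    [-0.05, -0.04],
])

DEFAULT_OMEGA = np.array([[1.0, 0.51], [0.51, 1.0]])


def _in_box(coords, box):
    (x0, x1), (y0, y1) = box
    return (coords[:, 0] >= x0) & (coords[:, 0] <= x1) & \
           (coords[:, 1] >= y0) & (coords[:, 1] <= y1)


def _uniform_in(box, size, rng):
    (x0, x1), (y0, y1) = box
    return np.column_stack([rng.uniform(x0, x1, size), rng.uniform(y0, y1, size)])


def generate_stations(n_total=40, n_study=20, rng=None):
    """Random station layout: ``n_study`` monitors in the dense study box,
    the rest spread over the full domain, STN labels biased urban (toward
    the study subregion)."""
    rng = np.random.default_rng(rng)
    if n_study > n_total:
        raise InvalidParameterError("n_study must be <= n_total")
    inside = _uniform_in(STUDY_BOX, n_study, rng)
    outside = np.empty((0, 2))
    need = n_total - n_study
    while outside.shape[0] < need:
        cand = _uniform_in(DOMAIN, max(4 * need, 8), rng)
        cand = cand[~_in_box(cand, STUDY_BOX)]
        outside = np.vstack([outside, cand])[:need]
    coords = np.vstack([inside, outside])
    ids = tuple(f"S{i:03d}" for i in range(n_total))
    in_study = _in_box(coords, STUDY_BOX)
    p_stn = np.where(in_study, 0.75, 0.30)
    network = np.where(rng.uniform(size=n_total) < p_stn, "STN", "IMPROVE")
    if n_total >= 2:
        # both networks must exist for the mean/variance structure to matter
        if (network == "STN").all():
            network[-1] = "IMPROVE"
        if (network == "IMPROVE").all():
            network[0] = "STN"
    return SpatialSites(ids=ids, coords=coords), network


@dataclass
class TruthBundle:
    """All generative parameters plus the latent paths actually used."""

    pollutant_names: tuple
    ms: MeanStructure
    ev: ErrorVariances
    lf: LoadingField
    pf: PropagationField
    hypers: ModelHypers
    beta: np.ndarray
    w: np.ndarray
    omega: np.ndarray
    weekly_range: float = 2.0
    fs: FactorState = None
    exposures: ExposureMatrix = None
    meta: dict = field(default_factory=dict)

    def health_params(self):
        return HealthParams(beta=self.beta, w=self.w, omega=self.omega,
                            weekly_range=self.weekly_range)


def default_truth(sites, network, preset="toy", M=1, rng=None,
                  seasonal=None):
    """Generative truth at the given stations.

    ``preset='toy'`` uses P=4 pollutants (fast tests); ``'study-scale'``
    uses the full 9-pollutant speciated PM2.5 list with near-duplicate
    loading rows for (Ammonium, Nitrate) and (Sulfate, Sulfur) and annual
    seasonality on.
    """
    rng = np.random.default_rng(rng)
    n = sites.n
    names = TOY_POLLUTANTS if preset == "toy" else STUDY_SCALE_POLLUTANTS
    P = len(names)
    if seasonal is None:
        seasonal = preset == "study-scale"

    hyp_inn = GPHyper(1.0, 150.0)
    hyp_d0 = [GPHyper(2.0, 150.0) for _ in range(M)]
    hyp_prop = [GPHyper(0.25, 200.0) for _ in range(M)]
    hyp_load = {k: GPHyper(0.25, 250.0)
                for k in free_loading_indices(P, M) + diag_loading_indices(P, M)}
    hypers = ModelHypers(innovation=hyp_inn, delta0=hyp_d0,
                         propagation=hyp_prop, loading=hyp_load)

    def gp(var, rng_km):
        cov = var * correlation_matrix(sites, rng_km)
        return chol_with_jitter(cov) @ rng.standard_normal(n)

    log_diag = np.column_stack([0.05 * gp(1.0, 250.0) for _ in range(M)])
    free = {}
    for (p, f) in free_loading_indices(P, M):
        free[(p, f)] = 0.6 * gp(1.0, 250.0) + (0.6 if f == 0 else 0.0)
    lf = constrain_loadings(P, log_diag, free, hyper=hyp_load)
    # near-duplicate loading rows: pollutant 1 mirrors pollutant 0's loadings,
    # and (study-scale) Sulfur mirrors Sulfate, driving correlations > 0.9
    lam0 = lf.lam[:, 0, :].copy()
    for f in range(M):
        tweak = 0.02 * gp(1.0, 250.0)
        target = lam0[:, f] + tweak
        if (1, f) in lf.free:
            lf.free[(1, f)] = target
            lf.lam[:, 1, f] = target
    if preset == "study-scale":
        i_sulfate, i_sulfur = names.index("Sulfate"), names.index("Sulfur")
        for f in range(M):
            if (i_sulfur, f) in lf.free and (i_sulfate, f) in lf.free:
                target = lf.lam[:, i_sulfate, f] + 0.02 * gp(1.0, 250.0)
                lf.free[(i_sulfur, f)] = target
                lf.lam[:, i_sulfur, f] = target

    gamma = np.clip(0.6 + np.column_stack([0.15 * gp(1.0, 200.0) for _ in range(M)]),
                    -0.9, 0.9)
    pf = PropagationField(gamma=gamma, hyper=hyp_prop)

    mu0 = rng.normal(0.3, 0.5, P)
    mu1 = np.full(P, 0.3)
    amp_c = np.full(P, 0.4) if seasonal else np.zeros(P)
    amp_s = np.full(P, 0.2) if seasonal else np.zeros(P)
    ms = MeanStructure(mu0=mu0, mu1=mu1, harmonic_cos=amp_c, harmonic_sin=amp_s)

    s2_stn = np.full(P, 0.15)
    s2_imp = np.full(P, 0.20)
    s2_stn[:2] = 0.06   # tight pair -> correlation near the 0.96 regime
    s2_imp[:2] = 0.08
    if preset == "study-scale":
        s2_stn[[i_sulfate, i_sulfur]] = 0.06
        s2_imp[[i_sulfate, i_sulfur]] = 0.08
    ev = ErrorVariances(sigma2_stn=s2_stn, sigma2_imp=s2_imp)

    w = np.zeros((N_EXPO_WEEKS, M, 2))
    w[:, 0, :] = DEFAULT_W
    return TruthBundle(pollutant_names=names, ms=ms, ev=ev, lf=lf, pf=pf,
                       hypers=hypers, beta=DEFAULT_BETA.copy(), w=w,
                       omega=DEFAULT_OMEGA.copy(),
                       meta={"preset": preset, "seasonal": bool(seasonal)})


def simulate_factor_path(truth, sites, T_weeks, rng):
    """Simulate the latent factor field at the stations from the model."""
    rng = np.random.default_rng(rng)
    n = sites.n
    M = truth.pf.gamma.shape[1]

    def gp(hyp):
        cov = hyp.variance * correlation_matrix(sites, hyp.range)
        return chol_with_jitter(cov) @ rng.standard_normal(n)

    delta0 = np.column_stack([gp(truth.hypers.delta0[f]) for f in range(M)])
    delta = np.empty((T_weeks, n, M))
    x = delta0
    for t in range(T_weeks):
        innov = np.column_stack([gp(truth.hypers.innovation) for _ in range(M)])
        x = truth.pf.gamma * x + innov
        delta[t] = x
    return FactorState(delta=delta, delta0=delta0)


def generate_pollution(sites, network, truth, T_weeks, rng=None,
                       start_date=_dt.date(2003, 1, 6), sampling_days=(3, 6),
                       withhold_from_improve=0, fs=None):
    """Simulate the weekly panel and the raw 3-6-day measurement records.

    Weekly log-concentrations follow the factor model (with the truth's
    seasonal harmonics); raw records repeat each week's value on that site's
    sampling days, so weekly averaging of the records reproduces the panel
    exactly.  Pollutant index ``withhold_from_improve`` (Ammonium by
    default) is dropped at IMPROVE sites, as in the STN-only collection rule.
    """
    rng = np.random.default_rng(rng)
    n = sites.n
    P = len(truth.pollutant_names)
    if fs is None:
        fs = simulate_factor_path(truth, sites, T_weeks, rng)
    mu = mean_matrix(truth.ms, network, T=T_weeks)
    fitted = mu + np.einsum("npm,tnm->tnp", truth.lf.lam, fs.delta)
    sd = np.sqrt(truth.ev.per_site(network))[None, :, :]
    Y = fitted + sd * rng.standard_normal(fitted.shape)
    if withhold_from_improve is not None:
        Y[:, np.asarray(network) == "IMPROVE", withhold_from_improve] = np.nan

    # per-site sampling schedule: one sampling day every 3-6 days
    rows = []
    lon, lat = None, None
    from .gp_core import unproject_xy
    lon, lat = unproject_xy(sites.coords, CENTER_LONLAT)
    anchor = start_date - _dt.timedelta(days=start_date.weekday())
    horizon = 7 * T_weeks
    sampled_weeks = np.zeros((T_weeks, n), dtype=bool)
    for s in range(n):
        day = int(rng.integers(0, 4))
        while day < horizon:
            wk = day // 7
            date = anchor + _dt.timedelta(days=day)
            for p in range(P):
                v = Y[wk, s, p]
                if np.isfinite(v):
                    rows.append((sites.ids[s], lon[s], lat[s], network[s],
                                 date.isoformat(), truth.pollutant_names[p],
                                 float(np.exp(v))))
            sampled_weeks[wk, s] = True
            day += int(rng.integers(sampling_days[0], sampling_days[1] + 1))
    Y = np.where(sampled_weeks[:, :, None], Y, np.nan)
    records = pd.DataFrame(rows, columns=["site_id", "lon", "lat", "network",
                                          "date", "pollutant", "value"])
    panel = PollutantPanel(Y=Y, sites=sites, network=np.asarray(network),
                           pollutant_names=truth.pollutant_names,
                           week_anchor=anchor)
    return records, panel, fs


def _sample_covariates(n, rng):
    x = np.zeros((n, N_COVARIATES))
    age = rng.choice(5, size=n, p=COVARIATE_FREQS["age"])
    for j in range(1, 5):
        x[:, j - 1] = age == j
    x[:, 4] = rng.uniform(size=n) < COVARIATE_FREQS["female"]
    edu = rng.choice(4, size=n, p=COVARIATE_FREQS["edu"])
    for j in range(1, 4):
        x[:, 4 + j] = edu == j
    for j, key in enumerate(("hbp", "prediabetes", "smoke", "alcohol")):
        x[:, 8 + j] = rng.uniform(size=n) < COVARIATE_FREQS[key]
    return x


def generate_cohort(truth, fs, sites, T_weeks, n_cases=208, n_controls=358,
                    mover_fraction=0.15, rng=None, max_batches=40,
                    exposure_mode="sample", n_subjects=None):
    """Simulate a cohort tied to the latent factor field.

    Residences sit in the study subregion; a ``mover_fraction`` share
    relocates once, mid exposure window, to the distant mover box and
    contributes week-specific addresses.  True exposures are drawn from the
    conditional factor-field law given the station path; outcomes come from
    the bivariate probit with the truth's (beta, w, Omega).  Case/control
    counts are achieved by oversampling from the prospective model (capped):
    retention then depends on the outcome, which mirrors a case-control
    design but — as in any outcome-selected sample fit prospectively —
    distorts the probit coefficients.  Passing ``n_subjects`` instead keeps
    the first N subjects regardless of outcome (a prospective cohort, the
    right design for calibration studies).
    """
    rng = np.random.default_rng(rng)
    if T_weeks < 8:
        raise InvalidParameterError("need at least 8 panel weeks for the window")
    M = truth.pf.gamma.shape[1]
    hp = truth.health_params()
    kept_cases, kept_controls = [], []
    if n_subjects is not None:
        n_cases, n_controls = n_subjects, 0
    batch = max(2 * (n_cases + n_controls), 200) if n_subjects is None \
        else max(n_subjects, 200)
    for _ in range(max_batches):
        if n_subjects is not None:
            if len(kept_cases) >= n_subjects:
                break
        elif len(kept_cases) >= n_cases and len(kept_controls) >= n_controls:
            break
        x = _sample_covariates(batch, rng)
        conception = rng.integers(0, T_weeks - 7, size=batch)
        home = _uniform_in(STUDY_BOX, batch, rng)
        res = np.repeat(home[:, None, :], N_EXPO_WEEKS, axis=1)
        movers = rng.uniform(size=batch) < mover_fraction
        move_week = rng.integers(1, N_EXPO_WEEKS, size=batch)  # index into weeks 3..8
        far = _uniform_in(MOVER_BOX, batch, rng)
        for i in np.nonzero(movers)[0]:
            res[i, move_week[i]:, :] = far[i]

        flat = np.round(res.reshape(-1, 2), 6)
        uniq, inv = np.unique(flat, axis=0, return_inverse=True)
        site_of = inv.reshape(batch, N_EXPO_WEEKS)
        week_idx = conception[:, None] + np.array(GESTATION_WEEKS)[None, :] - 1
        e_mean, e_cov = mother_exposure_moments(
            fs, truth.pf, truth.hypers.path_dict(), sites, uniq, site_of,
            week_idx)
        if exposure_mode == "mean":
            delta_i = e_mean
        else:
            delta_i = draw_exposures_from_moments(e_mean, e_cov, rng)

        eta = latent_mean(hp, x, delta_i)
        L = np.linalg.cholesky(truth.omega)
        z = eta + rng.standard_normal((batch, 2)) @ L.T
        y = (z > 0).astype(int)
        is_case = y.any(axis=1)
        for i in range(batch):
            rec = (x[i], conception[i], res[i], y[i], delta_i[i])
            if n_subjects is not None:
                if len(kept_cases) < n_subjects:
                    kept_cases.append(rec)
            elif is_case[i] and len(kept_cases) < n_cases:
                kept_cases.append(rec)
            elif not is_case[i] and len(kept_controls) < n_controls:
                kept_controls.append(rec)
    if len(kept_cases) < n_cases or len(kept_controls) < n_controls:
        log.warning("oversampling cap hit: %d/%d cases, %d/%d controls",
                    len(kept_cases), n_cases, len(kept_controls), n_controls)
    rows = kept_cases + kept_controls
    N = len(rows)
    x = np.stack([r[0] for r in rows])
    conception = np.array([r[1] for r in rows], dtype=int)
    res = np.stack([r[2] for r in rows])
    y = np.stack([r[3] for r in rows])
    delta_i = np.stack([r[4] for r in rows])
    cohort = CohortTable(ids=tuple(f"C{i:05d}" for i in range(N)), y=y, x=x,
                         residences=res, conception_week=conception,
                         residences_are_km=True)
    return cohort, ExposureMatrix(delta=delta_i)


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def _hyper_to_obj(h):
    return {"variance": h.variance, "range": h.range}


def _truth_to_obj(truth):
    lf = truth.lf
    return {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "pollutant_names": list(truth.pollutant_names),
        "mu0": truth.ms.mu0.tolist(),
        "mu1": truth.ms.mu1.tolist(),
        "harmonic_cos": truth.ms.harmonic_cos.tolist(),
        "harmonic_sin": truth.ms.harmonic_sin.tolist(),
        "sigma2_stn": truth.ev.sigma2_stn.tolist(),
        "sigma2_imp": truth.ev.sigma2_imp.tolist(),
        "log_diag": lf.log_diag.tolist(),
        "free": {f"{p},{f}": v.tolist() for (p, f), v in lf.free.items()},
        "gamma": truth.pf.gamma.tolist(),
        "hyper_innovation": _hyper_to_obj(truth.hypers.innovation),
        "hyper_delta0": [_hyper_to_obj(h) for h in truth.hypers.delta0],
        "hyper_propagation": [_hyper_to_obj(h) for h in truth.hypers.propagation],
        "hyper_loading": {f"{p},{f}": _hyper_to_obj(h)
                          for (p, f), h in truth.hypers.loading.items()},
        "beta": truth.beta.tolist(),
        "w": truth.w.tolist(),
        "omega": truth.omega.tolist(),
        "weekly_range": truth.weekly_range,
        "delta": None if truth.fs is None else truth.fs.delta.tolist(),
        "delta0": None if truth.fs is None else truth.fs.delta0.tolist(),
        "exposures": None if truth.exposures is None else truth.exposures.delta.tolist(),
        "meta": truth.meta,
    }


def save_truth(truth, path):
    """Serialize a TruthBundle to JSON (lossless round-trip)."""
    with open(path, "w") as fh:
        json.dump(_truth_to_obj(truth), fh)


def load_truth(path):
    """Load a TruthBundle; raises on schema-version mismatch or missing file."""
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except FileNotFoundError:
        raise FileNotFoundError(f"truth bundle not found: {path}") from None
    if obj.get("schema_version") != TRUTH_SCHEMA_VERSION:
        raise InvalidParameterError(
            f"truth schema version {obj.get('schema_version')!r} != {TRUTH_SCHEMA_VERSION!r}")

    def key(s):
        p, f = s.split(",")
        return (int(p), int(f))

    names = tuple(obj["pollutant_names"])
    P = len(names)
    ms = MeanStructure(mu0=np.array(obj["mu0"]), mu1=np.array(obj["mu1"]),
                       harmonic_cos=np.array(obj["harmonic_cos"]),
                       harmonic_sin=np.array(obj["harmonic_sin"]))
    ev = ErrorVariances(sigma2_stn=np.array(obj["sigma2_stn"]),
                        sigma2_imp=np.array(obj["sigma2_imp"]))
    free = {key(k): np.array(v) for k, v in obj["free"].items()}
    lf = constrain_loadings(P, np.array(obj["log_diag"]), free)
    hyp = ModelHypers(
        innovation=GPHyper(**obj["hyper_innovation"]),
        delta0=[GPHyper(**h) for h in obj["hyper_delta0"]],
        propagation=[GPHyper(**h) for h in obj["hyper_propagation"]],
        loading={key(k): GPHyper(**h) for k, h in obj["hyper_loading"].items()},
    )
    pf = PropagationField(gamma=np.array(obj["gamma"]), hyper=hyp.propagation)
    fs = None
    if obj["delta"] is not None:
        fs = FactorState(delta=np.array(obj["delta"]), delta0=np.array(obj["delta0"]))
    exposures = None
    if obj["exposures"] is not None:
        exposures = ExposureMatrix(delta=np.array(obj["exposures"]))
    return TruthBundle(pollutant_names=names, ms=ms, ev=ev, lf=lf, pf=pf,
                       hypers=hyp, beta=np.array(obj["beta"]),
                       w=np.array(obj["w"]), omega=np.array(obj["omega"]),
                       weekly_range=obj["weekly_range"], fs=fs,
                       exposures=exposures, meta=obj.get("meta", {}))


PRESETS = {
    "toy": dict(n_total=15, n_study=10, T_weeks=40, n_cases=60, n_controls=100),
    "study-scale": dict(n_total=40, n_study=20, T_weeks=208, n_cases=208,
                        n_controls=358),
}


def simulate_study(preset="toy", seed=0, M=1, mover_fraction=0.15, **overrides):
    """One-call study simulation: stations, truth, panel, records, cohort.

    Returns a dict with keys ``sites, network, truth, records, panel,
    cohort``; the truth bundle carries the latent path and true exposures.
    """
    if preset not in PRESETS:
        raise InvalidParameterError(f"unknown preset {preset!r}")
    cfg = {**PRESETS[preset], **overrides}
    rng = np.random.default_rng(seed)
    sites, network = generate_stations(cfg["n_total"], cfg["n_study"], rng)
    truth = default_truth(sites, network, preset=preset, M=M, rng=rng)
    records, panel, fs = generate_pollution(sites, network, truth,
                                            cfg["T_weeks"], rng)
    cohort, exposures = generate_cohort(truth, fs, sites, cfg["T_weeks"],
                                        n_cases=cfg["n_cases"],
                                        n_controls=cfg["n_controls"],
                                        mover_fraction=mover_fraction, rng=rng)
    truth.fs = fs
    truth.exposures = exposures
    return {"sites": sites, "network": network, "truth": truth,
            "records": records, "panel": panel, "cohort": cohort}
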