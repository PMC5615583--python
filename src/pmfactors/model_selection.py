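"""Model comparison by DIC and posterior-predictive classification.

DIC = Dbar + pD with pD = Dbar - D(theta_bar), computed by default on the
birth-defect (bivariate probit) likelihood: the factor count M is compared by
how well the latent-exposure mixture explains the outcomes.  A flag adds the
pollutant-panel likelihood for a total-model DIC.

theta_bar averages the health parameters on the identified scale: each draw
is rescaled per outcome by 1/sqrt(Omega_jj) (the probit likelihood is
invariant to that rescaling), the outcome covariance is averaged as a
correlation, and exposures are averaged draw-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gp_core import InvalidParameterError
from .health_model import joint_outcome_logprob, rescale_health_params


@dataclass
class DICResult:
    """Deviance summaries; dic = dbar + pD and pD = dbar - d_at_mean by construction."""

    dbar: float
    d_at_mean: float
    pd: float
    dic: float


def deviance(cohort, eta, omega):
    """D(theta) = -2 log p(y | theta) for the bivariate probit outcomes."""
    lp = joint_outcome_logprob(eta, omega, cohort.y)
    return float(-2.0 * np.sum(lp))


def dic(deviances, d_at_mean):
    """Assemble a :class:`DICResult` from draw-wise deviances and D(theta_bar)."""
    deviances = np.asarray(deviances, dtype=float)
    if deviances.size < 2:
        raise InvalidParameterError("need at least 2 deviance draws")
    dbar = float(deviances.mean())
    pd_ = dbar - float(d_at_mean)
    return DICResult(dbar=dbar, d_at_mean=float(d_at_mean), pd=pd_, dic=dbar + pd_)


def _rescaled_etas(cohort, draws):
    """Per-draw rescaled linear predictors (K, N, 2) and correlations (K,)."""
    betas = draws.draws["beta"]
    ws = draws.draws["w"]
    omegas = draws.draws["omega"]
    exps = draws.draws["exposures"]
    K = betas.shape[0]
    etas = np.empty((K, cohort.N, 2))
    rhos = np.empty(K)
    for k in range(K):
        b_r, w_r, rho = rescale_health_params(betas[k], ws[k], omegas[k])
        etas[k] = cohort.x @ b_r + np.einsum("lmj,nlm->nj", w_r, exps[k])
        rhos[k] = rho
    return etas, rhos, exps


def health_dic(cohort, draws, include_pollutant=False, panel=None,
               pollutant_states=None):
    """DIC of the fitted model from stored posterior draws.

    ``include_pollutant`` adds -2 log p(Y_panel | theta) per draw (requires
    the panel and a callable reconstructing the pollutant likelihood per
    draw) for a total-model criterion; by default the health likelihood
    defines p(y | theta).
    """
    etas, rhos, _ = _rescaled_etas(cohort, draws)
    K = etas.shape[0]
    devs = np.empty(K)
    for k in range(K):
        om = np.array([[1.0, rhos[k]], [rhos[k], 1.0]])
        devs[k] = deviance(cohort, etas[k], om)
    if include_pollutant:
        if panel is None or pollutant_states is None:
            raise InvalidParameterError("panel and pollutant_states required")
        for k in range(K):
            devs[k] += -2.0 * pollutant_states(k)
    eta_bar = etas.mean(axis=0)
    rho_bar = float(np.clip(rhos.mean(), -0.999, 0.999))
    om_bar = np.array([[1.0, rho_bar], [rho_bar, 1.0]])
    d_at_mean = deviance(cohort, eta_bar, om_bar)
    if include_pollutant:
        d_at_mean += float(np.mean([-2.0 * pollutant_states(k) for k in range(K)]))
    return dic(devs, d_at_mean)


def posterior_defect_probabilities(cohort, draws):
    """Posterior-predictive marginal P(y_ij = 1), averaged over draws."""
    from scipy.special import ndtr

    etas, _, _ = _rescaled_etas(cohort, draws)
    return ndtr(etas).mean(axis=0)


def classification_sensitivity(cohort, draws, threshold=0.5):
    """P(y_hat = 1 | y = 1): share of observed defects whose posterior
    predictive probability exceeds the threshold, pooled over both outcomes."""
    probs = posterior_defect_probabilities(cohort, draws)
    cases = cohort.y == 1
    if not cases.any():
        raise InvalidParameterError("no observed defects; sensitivity undefined")
    return float((probs[cases] > threshold).mean())
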