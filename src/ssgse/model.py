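"""Probability kernel of the spike-and-slab enrichment model.

Observed data are per-gene z-scores ``z_j = beta_hat_j / se_j``. The model is a
two-component mixture

    z_j ~ pi_j * N(0, sigma_beta^2 + 1) + (1 - pi_j) * N(0, 1),

where the DE probability ``pi_j`` follows a logistic model in the gene-set
membership indicator ``a_j``:

    logit(pi_j) = tau0 + a_j * tau1.

The slab scaling factor ``sigma_beta^2`` carries an inverse-gamma prior
``InvGamma(a_beta=3, b_beta=20)`` (prior mean ``b_beta/(a_beta-1) = 10``).
Everything here is pure, vectorised computation; sampling and optimisation
live in :mod:`ssgse.inference`.

Because the slab variance on the effect-size scale is ``se_j^2 sigma_beta^2``,
likelihoods and responsibilities depend on the data only through the
z-scores, making the analysis invariant to the scale the effect size is
measured on. The z-score formulation is therefore the canonical internal
representation; ``(beta_hat, se)`` inputs are converted on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

# hyperparameters of the inverse-gamma prior on the slab scale
A_BETA = 3.0
B_BETA = 20.0

# numerical guards
_PI_EPS = 1e-8        # pi clamped to [eps, 1-eps] inside likelihoods
_LOG_FLOOR = 1e-12    # floor for log arguments in the M-step objective
TAU_MAX = 25.0        # |tau| clamp for numerical stability


@dataclass(frozen=True)
class LogisticPriorParams:
    """Logistic gene-set prior: ``logit(pi_j) = tau0 + a_j * tau1``.

    tau0 is the baseline log-odds of DE outside the set; tau1 the log odds
    ratio of DE inside versus outside. Both are clamped to ``[-TAU_MAX,
    TAU_MAX]`` on construction.
    """

    tau0: float
    tau1: float

    def __post_init__(self):
        if not (np.isfinite(self.tau0) and np.isfinite(self.tau1)):
            raise ValueError("tau parameters must be finite")
        object.__setattr__(self, "tau0", float(np.clip(self.tau0, -TAU_MAX, TAU_MAX)))
        object.__setattr__(self, "tau1", float(np.clip(self.tau1, -TAU_MAX, TAU_MAX)))

    def as_array(self) -> np.ndarray:
        return np.array([self.tau0, self.tau1])


@dataclass(frozen=True)
class SlabScale:
    """Slab variance scaling factor with its inverse-gamma hyperprior."""

    sigma_beta2: float
    a_beta: float = A_BETA
    b_beta: float = B_BETA

    def __post_init__(self):
        if self.sigma_beta2 <= 0:
            raise ValueError("sigma_beta2 must be positive")
        if self.a_beta <= 2:
            raise ValueError("a_beta must exceed 2 (prior variance must exist)")

    @property
    def prior_mean(self) -> float:
        return self.b_beta / (self.a_beta - 1.0)


def prior_pi(params: LogisticPriorParams, a) -> np.ndarray | float:
    """DE prior probability ``pi_j = sigmoid(tau0 + a_j * tau1)``.

    `a` may be a scalar in {0, 1} or a binary vector; output matches shape.
    Computed with :func:`scipy.special.expit`, which is overflow-safe.
    """
    a = np.asarray(a)
    out = special.expit(params.tau0 + a * params.tau1)
    return float(out) if out.ndim == 0 else out


def _log_norm_pdf(z: np.ndarray, var: float | np.ndarray) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + z * z / var)


def zscore_mixture_loglik(
    z: np.ndarray,
    params: LogisticPriorParams,
    sigma_beta2: float,
    a: np.ndarray,
    slab_var: np.ndarray | None = None,
) -> float:
    """Marginal (observed-data) log-likelihood of the z-score mixture.

    Returns ``sum_j log[pi_j N(z_j; 0, v_j) + (1-pi_j) N(z_j; 0, 1)]`` with
    ``v_j = sigma_beta2 + 1`` by default; ``slab_var`` overrides the per-gene
    slab variance on the z scale (used by the sample-size-independent model
    variant). Evaluated in log space via logaddexp.
    """
    if sigma_beta2 <= 0:
        raise ValueError("sigma_beta2 must be positive")
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    pi = np.clip(prior_pi(params, np.asarray(a)), _PI_EPS, 1.0 - _PI_EPS)
    v = (sigma_beta2 + 1.0) if slab_var is None else np.asarray(slab_var, dtype=float)
    log_slab = np.log(pi) + _log_norm_pdf(z, v)
    log_spike = np.log1p(-pi) + _log_norm_pdf(z, 1.0)
    return float(np.sum(np.logaddexp(log_slab, log_spike)))


def spike_slab_responsibility(
    z, pi, sigma_beta2: float, slab_var=None
) -> np.ndarray | float:
    """Posterior DE probability with the effect size integrated out.

    ``P(gamma_j = 1 | z_j) = pi_j N(z_j;0,v_j) / [pi_j N(z_j;0,v_j) +
    (1-pi_j) N(z_j;0,1)]`` with ``v_j = sigma_beta2 + 1`` unless ``slab_var``
    is given. Computed through the log-odds for stability; exact at the
    ``pi in {0, 1}`` boundaries.
    """
    z = np.asarray(z, dtype=float)
    pi_arr = np.asarray(pi, dtype=float)
    v = (sigma_beta2 + 1.0) if slab_var is None else np.asarray(slab_var, dtype=float)
    with np.errstate(divide="ignore"):
        log_odds_prior = np.log(pi_arr) - np.log1p(-pi_arr)
    log_lr = _log_norm_pdf(z, v) - _log_norm_pdf(z, 1.0)
    out = special.expit(log_odds_prior + log_lr)
    out = np.where(pi_arr == 0.0, 0.0, np.where(pi_arr == 1.0, 1.0, out))
    return float(out) if out.ndim == 0 else out


def slab_loglik_ratio(z: np.ndarray, sigma_beta2: float, slab_var=None) -> np.ndarray:
    """log N(z; 0, v) - log N(z; 0, 1), the per-gene slab/spike Bayes factor."""
    v = (sigma_beta2 + 1.0) if slab_var is None else np.asarray(slab_var, dtype=float)
    return _log_norm_pdf(np.asarray(z, dtype=float), v) - _log_norm_pdf(
        np.asarray(z, dtype=float), 1.0
    )


def expected_complete_loglik(
    pip: np.ndarray, params: LogisticPriorParams, a: np.ndarray
) -> float:
    """M-step objective: expected complete-data log-likelihood in tau.

    ``sum_j [pip_j log pi_j + (1 - pip_j) log(1 - pi_j)]`` — the weighted
    Bernoulli log-likelihood of a logistic regression with the posterior
    inclusion probabilities as outcomes. Log arguments floored at 1e-12.
    """
    pip = np.asarray(pip, dtype=float)
    pi = prior_pi(params, np.asarray(a))
    pi = np.clip(pi, _LOG_FLOOR, 1.0 - _LOG_FLOOR)
    return float(np.sum(pip * np.log(pi) + (1.0 - pip) * np.log1p(-pi)))
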