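"""EM-MCMC fitting of the spike-and-slab enrichment model for one gene set.

The latent data are the per-gene DE indicators ``gamma_j``, the standardised
effects ``u_j = beta_j / se_j`` and the slab scale ``sigma_beta^2``. The
E-step is a systematic-scan Gibbs sampler over these latents with the
enrichment parameters ``tau = (tau0, tau1)`` held fixed; posterior inclusion
probabilities (PIPs) are post-burn-in averages of ``gamma``. The M-step
maximises the expected complete-data log-likelihood over ``tau``, a weighted
logistic regression with the PIPs as outcomes — with a single binary
covariate the maximiser is available in closed form (stratum means of the
PIPs on the logit scale).

Because the gamma-posterior at a *fixed* slab scale is itself closed form,
the fit solves the tau-subproblem by exact deterministic EM and reserves the
Gibbs sampler for what genuinely needs it: the sigma_beta^2 posterior and
the Louis score covariance (see :func:`fit_gene_set`). Truncating a fully
Monte-Carlo EM instead would leave tau shrunk toward its initialisation,
because the large missing-information fraction makes EM contract slowly.

Standard errors for ``tau`` come from the Louis decomposition of the observed
information: ``I_obs = I_com - I_mis`` where ``I_com`` is the complete-data
(logistic) information at ``tau_hat`` and ``I_mis`` is the covariance of the
complete-data score over the posterior, estimated from the per-sweep Gibbs
score samples. Enrichment is tested by a Wald chi-square on ``tau1``.
Uncorrected (complete-data) standard errors ignore the uncertainty in the
latent indicators and give overly liberal tests; the Louis correction
restores calibration.

Gibbs conditionals (derived from the model by conjugacy; ``r_j`` is the slab
to spike variance ratio, ``sigma_beta^2`` for the scale-invariant variant and
``sigma_beta^2 / se_j^2`` for the sample-size-independent one):

* ``gamma_j | rest ~ Bernoulli`` with log-odds
  ``logit(pi_j) + 0.5 * [z_j^2 r_j / (r_j + 1) - log(r_j + 1)]``
  (effect size integrated out);
* ``u_j | gamma_j = 1, rest ~ N(z_j r_j / (r_j+1), r_j / (r_j+1))``,
  and ``u_j = 0`` when ``gamma_j = 0``;
* ``sigma_beta^2 | rest ~ InvGamma(a_beta + k/2, b_beta + ssq/2)`` with
  ``k = sum(gamma)`` and ``ssq`` the sum of squared slab effects on the
  scale of the prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .model import (
    A_BETA,
    B_BETA,
    TAU_MAX,
    LogisticPriorParams,
    prior_pi,
    zscore_mixture_loglik,
)

_EPS = 1e-12


@dataclass(frozen=True)
class MCMCConfig:
    """Knobs of the EM-MCMC fit.

    n_sweeps / burn_in control the Gibbs chain length per E-step; em_tol is
    the relative convergence tolerance on the slab scale between outer
    iterations (the tau-subproblem itself is solved exactly, see
    :func:`fit_gene_set`).
    """

    n_sweeps: int = 1000
    burn_in: int = 500
    seed: int = 0
    em_max_iter: int = 50
    em_tol: float = 1e-3
    em_n_sweeps: int | None = None  # shorter chains for intermediate E-steps

    def __post_init__(self):
        if self.n_sweeps <= 0 or self.burn_in <= 0:
            raise ValueError("n_sweeps and burn_in must be positive")
        if self.burn_in >= self.n_sweeps:
            raise ValueError("burn_in must be smaller than n_sweeps")

    def intermediate(self) -> "MCMCConfig":
        """Config for intermediate E-steps (only PIP means are needed there)."""
        if self.em_n_sweeps is None or self.em_n_sweeps >= self.n_sweeps:
            return self
        return MCMCConfig(self.em_n_sweeps, self.em_n_sweeps // 2, self.seed,
                          self.em_max_iter, self.em_tol)


@dataclass
class EnrichmentResult:
    """Fit of one gene set: enrichment estimate, corrected test, PIPs."""

    tau_hat: tuple[float, float]
    cov_tau: np.ndarray
    p_value: float
    sigma_beta2_hat: float
    pip: np.ndarray
    converged: bool
    n_em_iter: int
    set_size: int = 0
    coverage: float = 0.0
    loglik: float = np.nan
    m_step_flagged: bool = False
    louis_ridged: bool = False

    @property
    def se_tau1(self) -> float:
        return float(np.sqrt(self.cov_tau[1, 1]))


@dataclass
class GibbsState:
    """Current latent state of the sampler."""

    gamma: np.ndarray            # int8 DE indicators
    u: np.ndarray                # standardised effects beta/se (0 where gamma=0)
    sigma_beta2: float


def _variance_ratio(sigma_beta2: float, w) -> np.ndarray | float:
    """Slab/spike variance ratio r = sigma_beta2 / w (w=1 scaled variant)."""
    return sigma_beta2 / w


def gibbs_sweep(
    state: GibbsState,
    z: np.ndarray,
    logit_pi: np.ndarray,
    rng: np.random.Generator,
    *,
    w=1.0,
    sample_sigma: bool = True,
    a_beta: float = A_BETA,
    b_beta: float = B_BETA,
) -> GibbsState:
    """One full systematic-scan Gibbs update of (gamma, u, sigma_beta2).

    ``logit_pi`` is the vector of prior log-odds (fixed during an E-step);
    ``w`` is 1 for the scale-invariant variant or ``se**2`` for the
    sample-size-independent one. Mutates and returns ``state``.
    """
    r = _variance_ratio(state.sigma_beta2, w)
    v = 1.0 + r
    shrink = r / v
    log_odds = logit_pi + 0.5 * (z * z * shrink - np.log(v))
    gamma = rng.random(z.shape[0]) < special.expit(log_odds)
    k = int(gamma.sum())

    u = np.zeros_like(z)
    if k:
        shrink_g = shrink[gamma] if np.ndim(shrink) else shrink
        u[gamma] = z[gamma] * shrink_g + np.sqrt(shrink_g) * rng.standard_normal(k)
        if not np.all(np.isfinite(u)):
            raise FloatingPointError("non-finite effect draw in Gibbs sweep")

    if sample_sigma:
        w_g = w[gamma] if np.ndim(w) else w
        ssq = float(np.sum(u[gamma] ** 2 * w_g)) if k else 0.0
        shape = a_beta + 0.5 * k
        rate = b_beta + 0.5 * ssq
        state.sigma_beta2 = rate / rng.gamma(shape)
    state.gamma = gamma
    state.u = u
    return state


@dataclass
class EStepResult:
    pip: np.ndarray
    sigma_beta2: float
    score_samples: np.ndarray  # (n_kept, 2) complete-data scores per sweep
    state: GibbsState = field(repr=False, default=None)
    tau_mc_se: tuple[float, float] = (np.inf, np.inf)


def _tau_mc_se(scores, pi_sum_all, pi_sum_in, n_in, n_out, n_batches=10):
    """Monte-Carlo s.e. of the M-step tau update, by batch means.

    The M-step maps stratum PIP means through the logit; batch means of the
    per-sweep gamma stratum fractions give the chain's s.e. of those means
    (robust to autocorrelation), and the delta method carries it to tau.
    """
    n_kept = scores.shape[0]
    if n_kept < 2 * n_batches:
        return (np.inf, np.inf)
    bs = n_kept // n_batches
    cut = n_batches * bs
    sum_all = scores[:cut, 0] + pi_sum_all
    sum_in = scores[:cut, 1] + pi_sum_in

    def logit_se(tot, n):
        fr = tot.reshape(n_batches, bs).mean(axis=1) / n
        m = float(np.clip(fr.mean(), 1e-6, 1 - 1e-6))
        se = float(fr.std(ddof=1) / np.sqrt(n_batches))
        return se / (m * (1 - m))

    if n_in == 0:
        se0 = logit_se(sum_all, n_out)
        return (se0, 0.0)
    se0 = logit_se(sum_all - sum_in, n_out)
    se1_in = logit_se(sum_in, n_in)
    return (se0, float(np.hypot(se0, se1_in)))


def e_step(
    z: np.ndarray,
    se: np.ndarray | None,
    a: np.ndarray | None,
    params: LogisticPriorParams,
    cfg: MCMCConfig,
    rng: np.random.Generator,
    *,
    state: GibbsState | None = None,
    variant: str = "scaled",
    sample_sigma: bool = True,
    sigma_beta2: float | None = None,
    a_beta: float = A_BETA,
    b_beta: float = B_BETA,
) -> EStepResult:
    """Monte-Carlo E-step: PIPs, sigma_beta^2 posterior mean, score samples.

    PIPs are post-burn-in averages of ``gamma``; score samples are the
    per-sweep complete-data scores ``S(tau) = sum_j x_j (gamma_j - pi_j)``
    with ``x_j = (1, a_j)``, retained for the Louis correction.
    """
    p = z.shape[0]
    a_vec = np.zeros(p, dtype=np.int8) if a is None else np.asarray(a, dtype=np.int8)
    w = 1.0 if variant == "scaled" else np.asarray(se, dtype=float) ** 2
    pi = np.asarray(prior_pi(params, a_vec), dtype=float)
    logit_pi = params.tau0 + a_vec * params.tau1

    if state is None:
        sig0 = sigma_beta2 if sigma_beta2 is not None else b_beta / (a_beta - 1.0)
        state = GibbsState(np.zeros(p, dtype=bool), np.zeros(p), sig0)
    if sigma_beta2 is not None:
        state.sigma_beta2 = sigma_beta2
        sample_sigma = False

    in_set = np.flatnonzero(a_vec == 1)
    pi_sum_all = float(pi.sum())
    pi_sum_in = float(pi[in_set].sum())

    n_kept = cfg.n_sweeps - cfg.burn_in
    pip_acc = np.zeros(p)
    scores = np.empty((n_kept, 2))
    sigma_acc = 0.0
    for t in range(cfg.n_sweeps):
        gibbs_sweep(
            state, z, logit_pi, rng,
            w=w, sample_sigma=sample_sigma, a_beta=a_beta, b_beta=b_beta,
        )
        if t >= cfg.burn_in:
            i = t - cfg.burn_in
            pip_acc += state.gamma
            scores[i, 0] = state.gamma.sum() - pi_sum_all
            scores[i, 1] = state.gamma[in_set].sum() - pi_sum_in
            sigma_acc += state.sigma_beta2
    mc_se = _tau_mc_se(scores, pi_sum_all, pi_sum_in, len(in_set),
                       p - len(in_set))
    return EStepResult(pip_acc / n_kept, sigma_acc / n_kept, scores, state, mc_se)


def m_step(pip: np.ndarray, a: np.ndarray, tau_max: float = TAU_MAX):
    """Maximise the expected complete-data log-likelihood over (tau0, tau1).

    With a single binary covariate the weighted-logistic MLE is the pair of
    stratum means of the PIPs on the logit scale: ``tau0 = logit(mean pip
    outside)``, ``tau1 = logit(mean pip inside) - tau0``. Values are clamped
    at ``+-tau_max`` (perfect-separation guard); returns (params, flagged).
    """
    pip = np.asarray(pip, dtype=float)
    a = np.asarray(a)
    out, inside = pip[a == 0], pip[a == 1]
    if len(out) == 0 or len(inside) == 0:
        raise ValueError("both membership strata must be nonempty")
    m0, m1 = float(np.mean(out)), float(np.mean(inside))
    eps = special.expit(-tau_max)
    flagged = not (eps < m0 < 1 - eps and eps < m1 < 1 - eps)
    l0 = special.logit(np.clip(m0, eps, 1 - eps))
    l1 = special.logit(np.clip(m1, eps, 1 - eps))
    return LogisticPriorParams(l0, l1 - l0), flagged


def m_step_intercept(pip: np.ndarray, tau_max: float = TAU_MAX):
    """Intercept-only M-step for the annotation-free model."""
    m = float(np.mean(pip))
    eps = special.expit(-tau_max)
    flagged = not (eps < m < 1 - eps)
    return LogisticPriorParams(special.logit(np.clip(m, eps, 1 - eps)), 0.0), flagged


def louis_wald_test(
    pip: np.ndarray,
    score_samples: np.ndarray,
    a: np.ndarray,
    params: LogisticPriorParams,
):
    """Louis-corrected covariance of tau_hat and Wald p-value for tau1 = 0.

    ``I_com = sum_j x_j x_j' pi_j (1 - pi_j)`` at tau_hat; ``I_mis`` is the
    sample covariance of the per-sweep complete-data score vectors. If
    ``I_obs = I_com - I_mis`` is not positive definite a ridge of
    ``1e-6 * trace(I_com)`` is added (flagged). Returns
    (cov_tau, p_value, ridged).
    """
    if score_samples.shape[0] < 2:
        raise ValueError("need at least two post-burn-in score samples")
    a = np.asarray(a)
    pi = np.asarray(prior_pi(params, a), dtype=float)
    wgt = pi * (1.0 - pi)
    s_all = float(wgt.sum())
    s_in = float(wgt[a == 1].sum())
    i_com = np.array([[s_all, s_in], [s_in, s_in]])
    i_mis = np.cov(score_samples, rowvar=False, ddof=1)
    i_obs = i_com - i_mis

    ridged = False
    eig = np.linalg.eigvalsh(i_obs)
    if eig.min() <= 0:
        i_obs = i_obs + 1e-6 * np.trace(i_com) * np.eye(2)
        ridged = True
        if np.linalg.eigvalsh(i_obs).min() <= 0:
            # hopeless geometry: fall back to the complete-data information
            i_obs = i_com
    cov_tau = np.linalg.inv(i_obs)
    var1 = max(cov_tau[1, 1], _EPS)
    wald = params.tau1 ** 2 / var1
    p_value = float(stats.chi2.sf(wald, df=1))
    return cov_tau, p_value, ridged


def _deterministic_em_tau(
    z: np.ndarray,
    a: np.ndarray | None,
    sigma_beta2: float,
    params: LogisticPriorParams,
    slab_var=None,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> tuple[LogisticPriorParams, bool, bool]:
    """Solve the tau-subproblem exactly at a fixed slab scale.

    With sigma_beta2 held fixed the E-step posterior is available in closed
    form (the spike-slab responsibilities), so EM over tau needs no sampling
    and can run to machine precision. This matters because the fraction of
    missing information is large here, making EM contract slowly: a
    noise-floor stop on a Monte-Carlo EM leaves tau multiplicatively shrunk
    toward its initialisation and the Wald test conservative.

    Returns (params, converged, m_step_flagged).
    """
    from .model import spike_slab_responsibility

    a_vec = None if a is None else np.asarray(a)
    flagged = False
    converged = False
    for _ in range(max_iter):
        pi = prior_pi(params, a_vec if a_vec is not None else 0)
        pip = spike_slab_responsibility(z, pi, sigma_beta2, slab_var=slab_var)
        if a_vec is None:
            new, flagged = m_step_intercept(np.atleast_1d(pip))
        else:
            new, flagged = m_step(pip, a_vec)
        delta = float(np.max(np.abs(new.as_array() - params.as_array())))
        params = new
        if delta < tol:
            converged = True
            break
    return params, converged, flagged


def _initial_params(z: np.ndarray) -> LogisticPriorParams:
    # start the DE log-odds at the naive p<0.05 fraction, kept in a sane band
    p_two = 2.0 * stats.norm.sf(np.abs(z))
    frac = max(float(np.mean(p_two < 0.05)), 1.0 / len(z))
    tau0 = float(np.clip(special.logit(frac), -5.0, -0.5))
    return LogisticPriorParams(tau0, 0.0)


def fit_gene_set(
    z: np.ndarray,
    se: np.ndarray | None,
    a: np.ndarray | None,
    cfg: MCMCConfig = MCMCConfig(),
    *,
    variant: str = "scaled",
    sigma_beta2: float | None = None,
    a_beta: float = A_BETA,
    b_beta: float = B_BETA,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Fit the enrichment model for one gene set by EM-MCMC.

    Parameters
    ----------
    z, se
        Per-gene z-scores and standard errors (``se`` may be None for the
        scale-invariant variant, which depends on the data only through z).
    a
        Binary membership vector, or None for the annotation-free
        (intercept-only) model.
    cfg
        Chain/EM configuration; ``cfg.seed`` makes the fit reproducible.
    variant
        "scaled" (slab variance ``se^2 sigma_beta^2``, canonical) or
        "unscaled" (slab variance ``sigma_beta^2``, independent of the
        sample size through se).
    sigma_beta2
        If given, the slab scale is fixed instead of sampled.
    a_beta, b_beta
        Inverse-gamma hyperparameters of the slab-scale prior.

    Non-convergence is reported through ``converged=False``, never raised.
    """
    z = np.asarray(z, dtype=float)
    p = z.shape[0]
    if p < 2:
        raise ValueError("need at least two genes")
    if variant not in ("scaled", "unscaled"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "unscaled" and se is None:
        raise ValueError("the unscaled variant requires standard errors")
    with_annotation = a is not None
    if with_annotation:
        a = np.asarray(a, dtype=np.int8)
        if a.sum() == 0:
            raise ValueError("gene set is empty after intersection")
        if a.sum() == p:
            raise ValueError("gene set covers the whole universe (no contrast)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    params = _initial_params(z)
    sigma_cur = sigma_beta2 if sigma_beta2 is not None else b_beta / (a_beta - 1.0)
    state = None
    converged = False
    m_flagged = False
    n_iter = 0
    mid_cfg = cfg.intermediate()
    a_fit = a if with_annotation else None
    se_arr = None if se is None else np.asarray(se, dtype=float)

    def slab_var_at(s2):
        return None if variant == "scaled" else 1.0 + s2 / se_arr ** 2

    # Alternate: (i) exact EM over tau at the current slab scale (the
    # gamma-posterior is closed-form when sigma_beta2 is fixed, so this
    # subproblem needs no sampling and runs to machine precision); (ii) a
    # Gibbs E-step at the new tau to refresh the sigma_beta2 posterior mean.
    # Iterate until the slab scale stabilises.
    for n_iter in range(1, cfg.em_max_iter + 1):
        params, em_ok, m_flagged = _deterministic_em_tau(
            z, a_fit, sigma_cur, params, slab_var=slab_var_at(sigma_cur))
        if sigma_beta2 is not None:
            converged = em_ok
            break
        es = e_step(
            z, se, a_fit, params, mid_cfg, rng,
            state=state, variant=variant, a_beta=a_beta, b_beta=b_beta,
        )
        state = es.state
        rel = abs(es.sigma_beta2 - sigma_cur) / max(sigma_cur, 1e-12)
        sigma_cur = es.sigma_beta2
        if em_ok and rel < max(cfg.em_tol, 5e-3):
            converged = True
            break
    if converged or sigma_beta2 is not None:
        # re-solve tau at the settled slab scale
        params, _, m_flagged = _deterministic_em_tau(
            z, a_fit, sigma_cur, params, slab_var=slab_var_at(sigma_cur))

    # final E-step at tau_hat: PIPs, sigma posterior mean, Louis score samples
    es = e_step(
        z, se, a if with_annotation else None, params, cfg, rng,
        state=state, variant=variant,
        sigma_beta2=sigma_beta2, a_beta=a_beta, b_beta=b_beta,
    )
    sigma_cur = es.sigma_beta2 if sigma_beta2 is None else sigma_beta2

    if with_annotation:
        cov_tau, p_value, ridged = louis_wald_test(es.pip, es.score_samples, a, params)
        size = int(a.sum())
    else:
        cov_tau = np.full((2, 2), np.nan)
        p_value, ridged, size = np.nan, False, 0

    slab_var = None if variant == "scaled" else 1.0 + sigma_cur / np.asarray(se) ** 2
    ll = zscore_mixture_loglik(
        z, params, sigma_cur, a if with_annotation else np.zeros(p, dtype=np.int8),
        slab_var=slab_var,
    )
    return EnrichmentResult(
        tau_hat=(params.tau0, params.tau1),
        cov_tau=cov_tau,
        p_value=p_value,
        sigma_beta2_hat=sigma_cur,
        pip=es.pip,
        converged=converged,
        n_em_iter=n_iter,
        set_size=size,
        coverage=size / p,
        loglik=ll,
        m_step_flagged=m_flagged,
        louis_ridged=ridged,
    )
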