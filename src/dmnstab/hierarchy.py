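"""Hierarchical Gaussian (parametric empirical Bayes) averaging and
Bayesian model reduction.

Session posteriors are carried up to subject level, and subject posteriors
to group level, under the Gaussian random-effects model

    y_i ~ N(X_i beta, Sigma_i + Gamma),    beta ~ N(m0, C0),

where ``y_i`` and ``Sigma_i`` are a lower-level unit's posterior mean and
covariance and ``Gamma`` is a diagonal per-parameter between-unit
covariance (each parameter has its own precision component).  The
level-above mean ``beta`` carries the same shrinkage prior as a single
unit's connectivity; the *random effects* are anchored to a prior
covariance of ``prior_ratio * C0`` (default 1/16) — the expected
between-unit variability is a fixed fraction of the within-level prior
variance.  Estimation is by EM over ``Gamma`` with
closed-form E-steps — deterministic and exactly testable; the free-energy
surrogate is the Gaussian marginal likelihood of the hierarchy.

Bayesian model reduction (BMR) recomputes a Gaussian posterior and the
change in log evidence under a new prior in closed form, without touching
the data; the empirical-prior pass uses it to shrink session estimates
toward their subject mean (and subjects toward the group mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    N_PARAMS,
    ConnectivityPosterior,
    GaussianPrior,
    default_session_prior,
)

__all__ = [
    "PEBModel",
    "PEBResult",
    "peb_average",
    "bmr_reduce",
    "empirical_prior_pass",
]


@dataclass
class PEBModel:
    """Specification of one level of the Gaussian hierarchy.

    ``design`` is the between-unit design matrix (default a single column of
    ones, modelling the average); ``prior_ratio`` anchors the random-effects
    variance prior at that fraction of the within-level prior variance;
    ``re_prior_strength`` is the weight of that anchor in pseudo-units (a
    weak scaled-inverse-chi-square regularizer keeping the EM variance
    updates away from degenerate optima); ``flat_prior`` replaces the
    level-above prior on the mean with an improper flat one (used mainly in
    degenerate single-unit situations).
    """

    design: np.ndarray | None = None
    prior_ratio: float = 1.0 / 16.0
    prior: GaussianPrior = field(default_factory=default_session_prior)
    re_prior_strength: float = 1.0
    flat_prior: bool = False
    tol: float = 1e-8
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.prior_ratio <= 0:
            raise ValueError("prior_ratio must be > 0")

    def design_for(self, n_units: int) -> np.ndarray:
        X = np.ones((n_units, 1)) if self.design is None else np.asarray(self.design, float)
        if X.ndim != 2 or X.shape[0] != n_units:
            raise ValueError(f"design must be (n_units, k); got {X.shape} for {n_units} units")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return X


@dataclass
class PEBResult:
    """Empirical-Bayes estimate of the level-above mean and random effects."""

    group_posterior: ConnectivityPosterior
    random_effects_variance: np.ndarray  # per-parameter diagonal of Gamma
    free_energy_surrogate: float
    beta_mean: np.ndarray  # full (k*p,) regression coefficients
    beta_covariance: np.ndarray
    n_iterations: int
    converged: bool


def peb_average(
    posteriors: list[ConnectivityPosterior],
    model: PEBModel | None = None,
    level: str = "subject",
) -> PEBResult:
    """Empirical-Bayes average of lower-level posteriors.

    EM alternates a closed-form Gaussian E-step for the level-above mean and
    the unit-level random effects with an M-step update of the diagonal
    random-effects variances.
    """
    if not posteriors:
        raise ValueError("at least one posterior is required")
    model = model or PEBModel()
    p = N_PARAMS
    y = np.stack([po.mean for po in posteriors])  # (n, p)
    Sigmas = np.stack([po.covariance for po in posteriors])
    n = len(posteriors)
    X = model.design_for(n)
    k = X.shape[1]

    if model.flat_prior:
        prec_b = np.zeros(k * p)
        m_b = np.zeros(k * p)
    else:
        prec_block = 1.0 / model.prior.variance
        prec_b = np.tile(prec_block, k)
        m_b = np.concatenate([model.prior.mean] + [np.zeros(p)] * (k - 1))

    gamma_anchor = model.prior_ratio * model.prior.variance
    nu = model.re_prior_strength
    gamma = gamma_anchor.copy()  # initial between-unit variance
    beta = m_b.copy()
    P_beta = np.diag(prec_b) if np.any(prec_b) else np.zeros((k * p, k * p))
    cov_beta = np.zeros((k * p, k * p))
    n_iter = 0
    converged = False
    for n_iter in range(1, model.max_iter + 1):
        V_inv = np.linalg.inv(Sigmas + np.diag(gamma)[None])  # (n, p, p)
        # posterior over beta given gamma
        P = np.diag(prec_b).astype(float)
        h = prec_b * m_b
        for i in range(n):
            P += np.kron(np.outer(X[i], X[i]), V_inv[i])
            h += np.kron(X[i], V_inv[i] @ y[i])
        cov_beta = np.linalg.inv(P)
        cov_beta = 0.5 * (cov_beta + cov_beta.T)
        beta = cov_beta @ h
        # E-step for random effects, M-step for gamma
        G = np.diag(gamma)
        new_gamma = np.zeros(p)
        for i in range(n):
            Xi = np.kron(X[i][None, :], np.eye(p))  # (p, k*p)
            resid = y[i] - Xi @ beta
            GV = G @ V_inv[i]
            mu_u = GV @ resid
            cov_u = G - GV @ G + GV @ Xi @ cov_beta @ Xi.T @ GV.T
            new_gamma += mu_u**2 + np.diag(cov_u)
        new_gamma = np.clip((new_gamma + nu * gamma_anchor) / (n + nu), 0.0, None)
        delta = np.max(np.abs(new_gamma - gamma))
        gamma = new_gamma
        if delta < model.tol:
            converged = True
            break

    fe = _hierarchy_log_evidence(y, Sigmas, X, gamma, m_b, prec_b)

    group_mean = beta[:p]
    group_cov = cov_beta[:p, :p]
    result_post = ConnectivityPosterior(
        mean=group_mean, covariance=group_cov, level=level,
        subject_id=posteriors[0].subject_id if level == "subject" else None,
    )
    return PEBResult(
        group_posterior=result_post,
        random_effects_variance=gamma,
        free_energy_surrogate=fe,
        beta_mean=beta,
        beta_covariance=cov_beta,
        n_iterations=n_iter,
        converged=converged,
    )


def _hierarchy_log_evidence(
    y: np.ndarray,
    Sigmas: np.ndarray,
    X: np.ndarray,
    gamma: np.ndarray,
    m_b: np.ndarray,
    prec_b: np.ndarray,
) -> float:
    """Gaussian marginal log-likelihood of the stacked hierarchy.

    With a proper prior on beta the coefficients are integrated out exactly;
    with a flat prior the beta-dependent terms are profiled at the GLS
    optimum (a surrogate used only for relative comparisons).
    """
    n, p = y.shape
    k = X.shape[1]
    V = Sigmas + np.diag(gamma)[None]
    Vi_inv = np.linalg.inv(V)
    M = np.zeros((k * p, k * p))  # sum of (X_i X_i') kron V_i^{-1}
    h = np.zeros(k * p)
    for i in range(n):
        M += np.kron(np.outer(X[i], X[i]), Vi_inv[i])
        h += np.kron(X[i], Vi_inv[i] @ y[i])

    if not np.any(prec_b):
        # flat prior: profile beta at the GLS optimum
        beta = np.linalg.solve(M, h)
        ll = 0.0
        for i in range(n):
            r = y[i] - np.kron(X[i][None, :], np.eye(p)) @ beta
            _, logdet = np.linalg.slogdet(V[i])
            ll += -0.5 * (p * np.log(2 * np.pi) + logdet + r @ Vi_inv[i] @ r)
        return float(ll)

    # proper prior: integrate beta out via block-wise Woodbury identities
    resid = y - (X @ m_b.reshape(k, p))  # (n, p), residual about the prior mean
    C_b = np.diag(1.0 / prec_b)
    logdet = float(np.sum([np.linalg.slogdet(V[i])[1] for i in range(n)]))
    middle = np.eye(k * p) + C_b @ M
    logdet += np.linalg.slogdet(middle)[1]
    # r' bigV^{-1} r  -  r' bigV^{-1} U (C^{-1} + U' bigV^{-1} U)^{-1} U' bigV^{-1} r
    hr = np.zeros(k * p)
    quad = 0.0
    for i in range(n):
        vr = Vi_inv[i] @ resid[i]
        quad += float(resid[i] @ vr)
        hr += np.kron(X[i], vr)
    inner = np.diag(prec_b) + M
    quad -= float(hr @ np.linalg.solve(inner, hr))
    return float(-0.5 * (n * p * np.log(2 * np.pi) + logdet + quad))


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------


def bmr_reduce(
    posterior: ConnectivityPosterior,
    prior_full: GaussianPrior | None,
    prior_reduced: GaussianPrior,
) -> tuple[ConnectivityPosterior, float]:
    """Closed-form Gaussian Bayesian model reduction.

    Given a posterior obtained under ``prior_full``, returns the posterior
    that the same data would have produced under ``prior_reduced``, and the
    change in log model evidence.  Exact for Gaussian likelihoods; no
    iteration.  ``prior_full=None`` treats the posterior as embodying no
    prior (a pure measurement density), so the reduced prior is simply
    multiplied in.  Zero-variance coordinates of the reduced prior clamp
    the posterior at the reduced-prior mean (infinite precision limit).
    """
    mu = posterior.mean
    P = np.linalg.inv(posterior.covariance)
    p = len(mu)

    clamp = prior_reduced.variance == 0
    if prior_full is None:
        P0 = np.zeros((p, p))
        m0 = np.zeros(p)
        logdet_P0_neg = 0.0
    else:
        if np.any(prior_full.variance == 0):
            raise ValueError("full prior must have strictly positive variances")
        P0 = np.diag(1.0 / prior_full.variance)
        m0 = prior_full.mean
        logdet_P0_neg = float(-np.sum(np.log(prior_full.variance)))
    mr = prior_reduced.mean

    freei = ~clamp
    Pr_free = np.diag(1.0 / prior_reduced.variance[freei])

    if np.all(freei):
        Pq = P + Pr_free - P0
        eig = np.linalg.eigvalsh(0.5 * (Pq + Pq.T))
        if np.min(eig) <= 0:
            raise ValueError("incompatible prior pair: reduced precision is not positive definite")
        cov_q = np.linalg.inv(Pq)
        mu_q = cov_q @ (P @ mu + Pr_free @ mr - P0 @ m0)
    else:
        # condition on the clamped coordinates at their reduced-prior mean
        hq = P @ mu - P0 @ m0
        hq[freei] += (1.0 / prior_reduced.variance[freei]) * mr[freei]
        Pq_full = P - P0
        Pq_full[np.ix_(freei, freei)] += Pr_free
        A = Pq_full[np.ix_(freei, freei)]
        B = Pq_full[np.ix_(freei, ~freei)]
        eig = np.linalg.eigvalsh(0.5 * (A + A.T))
        if np.min(eig) <= 0:
            raise ValueError("incompatible prior pair: reduced precision is not positive definite")
        mu_q = np.array(mr, dtype=float)
        cov_q = np.zeros((p, p))
        rhs = hq[freei] - B @ mr[~freei]
        A_inv = np.linalg.inv(A)
        mu_q[freei] = A_inv @ rhs
        cov_q[np.ix_(freei, freei)] = A_inv
        Pq = None  # evidence below handled in the free subspace

    if Pq is not None:
        sign_q, logdet_Pq = np.linalg.slogdet(Pq)
        sign_p, logdet_P = np.linalg.slogdet(P)
        logdet_Pr = float(-np.sum(np.log(prior_reduced.variance)))
        logdet_P0 = logdet_P0_neg
        quad = (
            mu_q @ Pq @ mu_q
            - mu @ P @ mu
            - mr @ np.diag(1.0 / prior_reduced.variance) @ mr
            + m0 @ P0 @ m0
        )
        delta_f = 0.5 * (logdet_P + logdet_Pr - logdet_P0 - logdet_Pq) + 0.5 * quad
    else:
        delta_f = -np.inf  # evidence of a measure-zero (clamped) model

    cov_q = 0.5 * (cov_q + cov_q.T)
    reduced = ConnectivityPosterior(
        mean=mu_q,
        covariance=cov_q,
        level=posterior.level,
        subject_id=posterior.subject_id,
        session_id=posterior.session_id,
    )
    return reduced, float(delta_f)


def empirical_prior_pass(
    sessions_by_subject: dict[str, list[ConnectivityPosterior]],
    subject_results: dict[str, PEBResult],
    group_result: PEBResult | None = None,
    session_prior: GaussianPrior | None = None,
    subject_prior: GaussianPrior | None = None,
    cap_at_full_prior: bool = True,
) -> tuple[dict[str, list[ConnectivityPosterior]], dict[str, ConnectivityPosterior]]:
    """Re-estimate sessions (and subjects) under empirical priors via BMR.

    Each session posterior is reduced to an empirical prior centred on its
    subject's mean, with variance equal to the estimated between-session
    variance plus the subject-mean uncertainty; subjects are likewise
    reduced toward the group mean.  ``session_prior`` is the prior the
    session posteriors embody: None (default) for the synthetic-cohort
    stand-in posteriors, which are pure measurement densities, or the
    session-level shrinkage prior for posteriors from model inversion.
    With ``cap_at_full_prior`` an explicit prior's replacement is never less
    informative than the prior it replaces, so posterior variances can only
    shrink.
    """
    updated_sessions: dict[str, list[ConnectivityPosterior]] = {}
    for subj, sessions in sessions_by_subject.items():
        sub_res = subject_results[subj]
        var = sub_res.random_effects_variance + np.diag(sub_res.group_posterior.covariance)
        if cap_at_full_prior and session_prior is not None:
            var = np.minimum(var, session_prior.variance)
        emp_prior = GaussianPrior(mean=sub_res.group_posterior.mean, variance=var)
        updated_sessions[subj] = [
            bmr_reduce(post, session_prior, emp_prior)[0] for post in sessions
        ]

    updated_subjects: dict[str, ConnectivityPosterior] = {}
    if group_result is not None:
        if subject_prior is None:
            # subject-level means from peb_average embody the session-level
            # shrinkage prior, whatever the sessions themselves embodied
            subject_prior = default_session_prior()
        var = group_result.random_effects_variance + np.diag(
            group_result.group_posterior.covariance
        )
        if cap_at_full_prior:
            var = np.minimum(var, subject_prior.variance)
        emp_prior = GaussianPrior(mean=group_result.group_posterior.mean, variance=var)
        for subj, sub_res in subject_results.items():
            updated_subjects[subj] = bmr_reduce(
                sub_res.group_posterior, subject_prior, emp_prior
            )[0]
    return updated_sessions, updated_subjects
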