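"""Generative model of BOLD cross spectra for a linear 4-region network.

A desk-scale model of the frequency-domain route to directed connectivity:
neuronal activity follows a linear stochastic differential equation
``dx/dt = A_eff x + v`` driven by stationary fluctuations with power-law
spectra; each region's activity passes through a linearized hemodynamic
(Balloon-type) transfer function; observation noise is added in the spectral
domain.  The predicted cross-spectral density at frequency f (Hz), with
``w = 2*pi*f``, is

    S(f) = T(w) G_v(w) T(w)^H + G_e(w) I,
    T(w) = H(w) (i w I - A_eff)^{-1},

with ``G_v(w) = alpha_v * w^{-beta_v}`` the (two-sided, per-Hz) neuronal
fluctuation density and ``G_e`` the observation-noise density.  Inversion is
maximum-a-posteriori estimation of the connectivity (and spectral nuisance)
parameters from observed cross spectra, with a Laplace (curvature-based)
Gaussian posterior.  This is deliberately a simplified scheme: downstream
stages consume only Gaussian posteriors, so any inversion backend with that
output contract fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from scipy.optimize import least_squares

from . import network
from .network import (
    N_PARAMS,
    N_REGIONS,
    ConnectivityPosterior,
    GaussianPrior,
    default_session_prior,
    effective_matrix,
)

__all__ = [
    "FluctuationSpec",
    "HemoParams",
    "CrossSpectra",
    "SessionFit",
    "OptimizerConfig",
    "default_frequency_grid",
    "predict_csd",
    "simulate_timeseries",
    "estimate_csd",
    "map_invert",
    "check_stability",
    "default_inversion_prior",
]

#: Default analysis band (Hz): the low-frequency range of resting-state BOLD.
FREQ_BAND = (0.0078, 0.1)


@dataclass
class FluctuationSpec:
    """Power-law spectra of neuronal fluctuations and observation noise.

    ``g(w) = alpha * w**(-beta)`` evaluated at angular frequency ``w``, as a
    two-sided spectral density per Hz.  Shared across regions.  Defaults give
    pink-ish neuronal fluctuations and weaker, flatter observation noise —
    an in-band spectral signal-to-noise ratio of roughly 5-20, typical of
    clean resting-state ROI time-series.
    """

    alpha_v: float = 1.0
    beta_v: float = 1.0
    alpha_e: float = 0.05
    beta_e: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_v < 0 or self.alpha_e < 0:
            raise ValueError("spectral amplitudes must be >= 0")
        if self.beta_v < 0 or self.beta_e < 0:
            raise ValueError("spectral exponents must be >= 0")

    def neuronal(self, w: np.ndarray) -> np.ndarray:
        return self.alpha_v * np.asarray(w, dtype=float) ** (-self.beta_v)

    def noise(self, w: np.ndarray) -> np.ndarray:
        return self.alpha_e * np.asarray(w, dtype=float) ** (-self.beta_e)


@dataclass
class HemoParams:
    """Linearized hemodynamic transfer function (canonical Balloon model).

    First-order linearization around the resting fixed point, yielding a
    per-region rational transfer from neuronal activity to BOLD.  Parameter
    defaults are the canonical values used throughout the hemodynamic
    modelling literature: signal decay ``kappa`` (1/s), flow feedback
    ``gamma`` (1/s), mean transit time ``tau`` (s), vessel stiffness
    ``alpha``, resting oxygen extraction ``E0``, resting blood volume
    fraction ``V0`` and field/echo-time surrogates via the classic
    (k1, k2, k3) BOLD coefficients.  ``identity=True`` bypasses hemodynamics
    (H == 1), for analytic tests on the neuronal level.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    E0: float = 0.4
    V0: float = 0.04
    identity: bool = False

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must be in (0, 1)")

    def transfer(self, w: np.ndarray) -> np.ndarray:
        """Complex transfer H(w) at angular frequencies ``w`` (rad/s)."""
        w = np.asarray(w, dtype=float)
        if self.identity:
            return np.ones_like(w, dtype=complex)
        iw = 1j * w
        # neurovascular signal -> blood flow
        F = 1.0 / (iw**2 + self.kappa * iw + self.gamma)
        # flow -> volume and deoxyhemoglobin (linearized Balloon model)
        V = F / (self.tau * iw + 1.0 / self.alpha)
        phi = 1.0 + (1.0 - self.E0) * np.log(1.0 - self.E0) / self.E0
        Q = (phi * F - (1.0 / self.alpha - 1.0) * V) / (self.tau * iw + 1.0)
        k1 = 7.0 * self.E0
        k2 = 2.0
        k3 = 2.0 * self.E0 - 0.2
        return self.V0 * (-(k1 + k2) * Q + (k2 - k3) * V)


@dataclass
class CrossSpectra:
    """Complex cross-spectral density matrices on a frequency grid (Hz)."""

    frequencies: np.ndarray
    csd: np.ndarray  # (n_freq, 4, 4) complex

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.csd = np.asarray(self.csd, dtype=complex)
        if self.frequencies.ndim != 1 or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.csd.shape != (len(self.frequencies), N_REGIONS, N_REGIONS):
            raise ValueError(f"csd must be (n_freq, 4, 4), got {self.csd.shape}")

    def hermitian_error(self) -> float:
        return float(np.max(np.abs(self.csd - self.csd.conj().transpose(0, 2, 1))))

    def features(self) -> np.ndarray:
        """Stacked real and imaginary parts, the inversion data vector."""
        return np.concatenate([self.csd.real.ravel(), self.csd.imag.ravel()])


@dataclass
class SessionFit:
    """Result of inverting one session's cross spectra."""

    posterior: ConnectivityPosterior
    fluctuations: FluctuationSpec
    explained_variance: float
    free_energy_surrogate: float
    converged: bool
    n_scans: int | None = None
    TR: float | None = None
    diagnostics: dict = field(default_factory=dict)


def default_frequency_grid(n: int = 24, band: tuple[float, float] = FREQ_BAND) -> np.ndarray:
    """Evenly spaced frequencies (Hz) spanning the analysis band."""
    return np.linspace(band[0], band[1], n)


def check_stability(params: np.ndarray) -> bool:
    """True iff the effective matrix has all eigenvalue real parts < 0."""
    A_eff = effective_matrix(np.asarray(params, dtype=float))
    return bool(np.all(np.linalg.eigvals(A_eff).real < 0))


def _transfer_matrices(
    A: np.ndarray, hemo: HemoParams, w: np.ndarray
) -> np.ndarray:
    """T(w) = H(w) (i w I - A_eff)^{-1}, stacked over frequencies."""
    A_eff = effective_matrix(A)
    iw = 1j * w[:, None, None] * np.eye(N_REGIONS)[None]
    resolvent = np.linalg.inv(iw - A_eff[None])
    H = hemo.transfer(w)
    return H[:, None, None] * resolvent


def predict_csd(
    params: np.ndarray,
    fluct: FluctuationSpec,
    hemo: HemoParams | None = None,
    frequencies: np.ndarray | None = None,
) -> CrossSpectra:
    """Predicted cross-spectral density of the linear network.

    ``params`` is the 4x4 parameter matrix (off-diagonal Hz, diagonal
    log-scale).  Hermitian by construction.
    """
    params = np.asarray(params, dtype=float)
    if not check_stability(params):
        raise ValueError("parameters are dynamically unstable (eigenvalue with Re >= 0)")
    hemo = hemo or HemoParams()
    f = default_frequency_grid() if frequencies is None else np.asarray(frequencies, float)
    w = 2.0 * np.pi * f
    T = _transfer_matrices(params, hemo, w)
    gv = fluct.neuronal(w)
    S = gv[:, None, None] * (T @ T.conj().transpose(0, 2, 1))
    S = S + fluct.noise(w)[:, None, None] * np.eye(N_REGIONS)[None]
    # symmetrize away floating-point asymmetry
    S = 0.5 * (S + S.conj().transpose(0, 2, 1))
    return CrossSpectra(frequencies=f, csd=S)


def simulate_timeseries(
    params: np.ndarray,
    fluct: FluctuationSpec,
    hemo: HemoParams | None = None,
    n_scans: int = 256,
    TR: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Stationary multivariate BOLD series with the model's cross spectra.

    Spectral synthesis: complex Gaussian Fourier coefficients are drawn with
    the model covariance at each DFT frequency and inverse-transformed, so
    Welch estimates of the output converge to :func:`predict_csd` as the
    series grows.  Returns an (n_scans, 4) array.
    """
    if n_scans < 64:
        raise ValueError("n_scans must be >= 64")
    hemo = hemo or HemoParams()
    rng = np.random.default_rng(seed)
    f = np.fft.rfftfreq(n_scans, d=TR)
    X = np.zeros((len(f), N_REGIONS), dtype=complex)
    k = np.arange(1, len(f) - (1 if n_scans % 2 == 0 else 0))
    w = 2.0 * np.pi * f[k]
    T = _transfer_matrices(params, hemo, w)
    amp_v = np.sqrt(fluct.neuronal(w))
    amp_e = np.sqrt(fluct.noise(w))
    scale = np.sqrt(n_scans / TR)
    wv = (rng.standard_normal((len(k), N_REGIONS)) + 1j * rng.standard_normal((len(k), N_REGIONS))) / np.sqrt(2.0)
    we = (rng.standard_normal((len(k), N_REGIONS)) + 1j * rng.standard_normal((len(k), N_REGIONS))) / np.sqrt(2.0)
    X[k] = scale * (
        np.einsum("fij,fj->fi", T, amp_v[:, None] * wv) + amp_e[:, None] * we
    )
    return np.fft.irfft(X, n=n_scans, axis=0)


def estimate_csd(
    series: np.ndarray,
    TR: float,
    band: tuple[float, float] = FREQ_BAND,
    nperseg: int | None = None,
) -> CrossSpectra:
    """Welch averaged-periodogram cross spectra, restricted to ``band``.

    Returns a two-sided density per Hz (one half of scipy's one-sided
    estimate), matching the convention of :func:`predict_csd`.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be (n_scans, n_regions)")
    n, d = series.shape
    nyquist = 0.5 / TR
    if band[1] > nyquist + 1e-12:
        raise ValueError(f"band upper edge {band[1]} Hz exceeds Nyquist {nyquist} Hz")
    if nperseg is None:
        nperseg = min(n // 2, max(64, n // 4))
    nperseg = min(nperseg, n)
    if n < (3 * nperseg) // 2:  # need at least 2 half-overlapping windows
        raise ValueError("series too short for Welch averaging")
    freqs = None
    S = None
    for i in range(d):
        for j in range(i, d):
            f, Pij = scipy.signal.csd(
                series[:, i], series[:, j], fs=1.0 / TR, nperseg=nperseg,
                return_onesided=True,
            )
            if S is None:
                freqs = f
                S = np.zeros((len(f), d, d), dtype=complex)
            # scipy returns E[conj(X_i) X_j]; our convention is E[X_i conj(X_j)].
            S[:, i, j] = np.conj(Pij) / 2.0  # one-sided -> two-sided
            if j != i:
                S[:, j, i] = Pij / 2.0
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise ValueError("no Welch frequencies fall inside the requested band")
    return CrossSpectra(frequencies=freqs[mask], csd=S[mask])


# ---------------------------------------------------------------------------
# MAP inversion with a Laplace posterior
# ---------------------------------------------------------------------------

#: Nuisance spectral parameters appended to the 16 connectivity parameters:
#: log-amplitudes and exponents of the fluctuation and noise spectra.
N_NUISANCE = 4
HYPER_NAMES = ("log_alpha_v", "beta_v", "log_alpha_e", "beta_e")


def default_inversion_prior(fluct_init: FluctuationSpec | None = None) -> GaussianPrior:
    """Joint prior over 16 connectivity + 4 spectral nuisance parameters."""
    base = default_session_prior()
    f0 = fluct_init or FluctuationSpec()
    mean = np.concatenate(
        [base.mean, [np.log(f0.alpha_v), f0.beta_v, np.log(f0.alpha_e), f0.beta_e]]
    )
    variance = np.concatenate([base.variance, np.full(N_NUISANCE, 1.0 / 4.0)])
    return GaussianPrior(mean=mean, variance=variance)


@dataclass
class OptimizerConfig:
    n_starts: int = 4
    start_scale: float = 0.5  # start spread, in prior-sd units
    maxiter: int = 300
    seed: int = 0
    lambda_rounds: int = 3
    lambda_cap: float = 1e12


def _theta_to_model(theta: np.ndarray) -> tuple[np.ndarray, FluctuationSpec]:
    A = network.vec_to_matrix(theta[:N_PARAMS])
    fluct = FluctuationSpec(
        alpha_v=float(np.exp(theta[N_PARAMS])),
        beta_v=float(max(theta[N_PARAMS + 1], 0.0)),
        alpha_e=float(np.exp(theta[N_PARAMS + 2])),
        beta_e=float(max(theta[N_PARAMS + 3], 0.0)),
    )
    return A, fluct


def _feature_weights(observed: CrossSpectra) -> np.ndarray:
    """Amplitude-normalizing feature weights, ``1/sqrt(S_ii S_jj)`` per entry.

    Puts every cross-spectral entry on a coherence-like O(1) scale, so steep
    low-frequency autospectra do not dominate the fit.
    """
    diag = np.abs(np.einsum("fii->fi", observed.csd).real)
    floor = 1e-12 * max(diag.max(), 1.0)
    W = 1.0 / np.sqrt(
        np.clip(diag[:, :, None] * diag[:, None, :], floor, None)
    )
    return np.concatenate([W.ravel(), W.ravel()])


def _residual(
    theta: np.ndarray,
    observed: np.ndarray,
    f: np.ndarray,
    hemo: HemoParams,
    weights: np.ndarray,
) -> np.ndarray:
    A, fluct = _theta_to_model(theta)
    if not check_stability(A):
        return None
    pred = predict_csd(A, fluct, hemo, f)
    return weights * (pred.features() - observed)


def map_invert(
    observed: CrossSpectra,
    priors: GaussianPrior | None = None,
    hemo: HemoParams | None = None,
    init: np.ndarray | None = None,
    optimizer_config: OptimizerConfig | None = None,
    n_scans: int | None = None,
    TR: float | None = None,
) -> SessionFit:
    """MAP + Laplace inversion of observed cross spectra.

    Minimizes ``0.5 * lam * ||r(theta)||^2 + 0.5 * (theta - m0)' P0 (theta - m0)``
    over the 20-dimensional parameter vector (16 connectivity + 4 spectral
    nuisance), where ``r`` stacks real and imaginary parts of the predicted
    minus observed cross spectra.  The feature precision ``lam`` is updated
    empirically from the residual between optimizer rounds.  The posterior
    covariance is the Gauss-Newton Laplace approximation at the optimum,
    marginalized to the 16 connectivity parameters.  Parameters with zero
    prior variance are clamped at their prior mean.
    """
    priors = priors or default_inversion_prior()
    hemo = hemo or HemoParams()
    cfg = optimizer_config or OptimizerConfig()
    if priors.mean.shape != (N_PARAMS + N_NUISANCE,):
        raise ValueError("inversion prior must cover 20 parameters (16 + 4 nuisance)")

    wts = _feature_weights(observed)
    y = observed.features()
    f = observed.frequencies
    free = priors.variance > 0
    m0 = priors.mean
    prec0 = np.zeros_like(m0)
    prec0[free] = 1.0 / priors.variance[free]

    def full_theta(theta_free: np.ndarray) -> np.ndarray:
        theta = m0.copy()
        theta[free] = theta_free
        return theta

    n_free = int(free.sum())
    sqrt_prec0 = np.sqrt(prec0[free])

    def augmented(theta_free: np.ndarray, lam: float) -> np.ndarray:
        """Stacked weighted-data and prior residuals; 0.5*||.||^2 is the MAP objective."""
        theta = full_theta(theta_free)
        r = _residual(theta, y, f, hemo, wts)
        if r is None:  # over the stability boundary: a large, growing penalty
            return np.concatenate(
                [np.full(len(y), 1e3), sqrt_prec0 * (theta_free - m0[free])]
            )
        return np.concatenate(
            [np.sqrt(lam) * r, sqrt_prec0 * (theta_free - m0[free])]
        )

    rng = np.random.default_rng(cfg.seed)
    sd0 = np.sqrt(priors.variance[free])
    starts = [m0[free].copy() if init is None else np.asarray(init, float)[free]]
    for _ in range(cfg.n_starts - 1):
        starts.append(starts[0] + cfg.start_scale * sd0 * rng.standard_normal(n_free))

    # initial feature precision from the best start's residual
    def residual_norm(theta_free: np.ndarray) -> float:
        r = _residual(full_theta(theta_free), y, f, hemo, wts)
        return np.inf if r is None else float(r @ r)

    lam = min(cfg.lambda_cap, len(y) / max(min(residual_norm(s) for s in starts), 1e-12))

    best = None
    converged = False
    for round_idx in range(cfg.lambda_rounds):
        results = []
        for s in starts:
            res = least_squares(
                augmented, s, args=(lam,), method="trf",
                max_nfev=cfg.maxiter, xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
            results.append(res)
        best = min(results, key=lambda r: r.cost)
        converged = bool(best.status > 0)
        rss = residual_norm(best.x)
        new_lam = min(cfg.lambda_cap, len(y) / max(rss, 1e-12))
        starts = [best.x]
        if np.isclose(new_lam, lam, rtol=0.05):
            lam = new_lam
            break
        lam = new_lam

    theta_hat = full_theta(best.x)
    r_hat = _residual(theta_hat, y, f, hemo, wts)
    rss = float(r_hat @ r_hat)

    # Gauss-Newton Laplace curvature from the converged Jacobian of the
    # augmented residual: J_aug' J_aug = lam * J' J + diag(prior precision).
    H = best.jac.T @ best.jac
    cov_free = np.linalg.inv(H)
    cov = np.zeros((len(m0), len(m0)))
    ix = np.ix_(free, free)
    cov[ix] = 0.5 * (cov_free + cov_free.T)

    yw = wts * y
    total = float(yw @ yw)
    ev = 100.0 * (1.0 - rss / total) if total > 0 else 0.0
    ev = float(np.clip(ev, 0.0, 100.0))

    # Gaussian log-evidence surrogate at the Laplace optimum
    d = theta_hat - m0
    sign, logdet_H = np.linalg.slogdet(H)
    log_prior_det = float(np.sum(np.log(priors.variance[free])))
    fe = (
        0.5 * len(y) * np.log(lam / (2 * np.pi))
        - 0.5 * lam * rss
        - 0.5 * float(d * prec0 @ d)
        - 0.5 * log_prior_det
        - 0.5 * logdet_H
    )

    _, fluct_hat = _theta_to_model(theta_hat)
    posterior = ConnectivityPosterior(
        mean=theta_hat[:N_PARAMS],
        covariance=cov[:N_PARAMS, :N_PARAMS],
        level="session",
    )
    return SessionFit(
        posterior=posterior,
        fluctuations=fluct_hat,
        explained_variance=ev,
        free_energy_surrogate=float(fe),
        converged=converged,
        n_scans=n_scans,
        TR=TR,
        diagnostics={"lambda": lam, "rss": rss, "optimizer_message": str(best.message)},
    )
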