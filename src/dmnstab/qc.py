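"""Session-level quality gates and small signal-processing utilities.

A session enters the analysis only if it passes five diagnostic criteria:
explained variance of the model fit above 60%, at least one estimated
connection stronger than 1/8 Hz, at least one effectively estimated
parameter (posterior-vs-prior Kullback-Leibler divergence above a
threshold), maximum framewise displacement under 1.5 mm, and low-frequency
voxels detectable in every region at an alpha threshold of at most 0.05.
The helpers here — framewise displacement, principal eigenvariate, the
stepwise alpha rule — operate on plain arrays, independent of any imaging
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    N_EXTRINSIC,
    N_PARAMS,
    ConnectivityPosterior,
    GaussianPrior,
    default_session_prior,
)
from .spectral import SessionFit

__all__ = [
    "MotionTrace",
    "SessionDiagnostics",
    "framewise_displacement",
    "kl_gaussian",
    "count_effective_params",
    "principal_eigenvariate",
    "stepwise_alpha",
    "session_gate",
]

ALPHA_LADDER = (0.001, 0.01, 0.05)
MIN_SCANS_FOR_LADDER = 200

EV_THRESHOLD_PCT = 60.0
STRENGTH_THRESHOLD_HZ = 1.0 / 8.0
FD_THRESHOLD_MM = 1.5
KL_THRESHOLD_NATS = 0.5
DEFAULT_HEAD_RADIUS_MM = 50.0


@dataclass
class MotionTrace:
    """Per-scan rigid-body motion: 3 translations (mm), 3 rotations (rad)."""

    translations: np.ndarray  # (n_scans, 3)
    rotations: np.ndarray  # (n_scans, 3)

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.translations.ndim != 2 or self.translations.shape[1] != 3:
            raise ValueError("translations must be (n_scans, 3)")
        if self.rotations.shape != self.translations.shape:
            raise ValueError("rotations must match translations in shape")
        if len(self.translations) < 2:
            raise ValueError("at least 2 scans are required")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations).all()):
            raise ValueError("motion trace contains non-finite values")


@dataclass
class SessionDiagnostics:
    explained_variance_pct: float
    max_abs_connection_hz: float
    n_effective_params: int
    max_fd_mm: float
    alpha_used: float | None
    passed: bool
    failure_reasons: list[str] = field(default_factory=list)


def framewise_displacement(
    trace: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-scan framewise displacement (mm).

    Sum of absolute backward differences of the translations plus the
    rotations converted to arc length on a sphere of ``head_radius`` mm
    (small-angle approximation).  The first scan has FD 0.
    """
    dt = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + head_radius * dr])
    return fd


def kl_gaussian(
    mu_post: float, var_post: float, mu_prior: float, var_prior: float
) -> float:
    """KL(posterior || prior) between univariate Gaussians, in nats."""
    if var_post <= 0 or var_prior <= 0:
        raise ValueError("variances must be > 0")
    ratio = var_post / var_prior
    return float(0.5 * (ratio + (mu_post - mu_prior) ** 2 / var_prior - 1.0 - np.log(ratio)))


def count_effective_params(
    posterior: ConnectivityPosterior,
    priors: GaussianPrior | None = None,
    kl_threshold: float = KL_THRESHOLD_NATS,
) -> int:
    """Number of parameters whose marginal posterior moved appreciably.

    A parameter counts as effectively estimated when the KL divergence of
    its marginal posterior from its prior exceeds ``kl_threshold`` nats.
    """
    priors = priors or default_session_prior()
    if len(priors.mean) != N_PARAMS:
        raise ValueError("prior must cover the 16 connectivity parameters")
    var_post = np.diag(posterior.covariance)
    count = 0
    for i in range(N_PARAMS):
        kl = kl_gaussian(posterior.mean[i], var_post[i], priors.mean[i], priors.variance[i])
        if kl > kl_threshold:
            count += 1
    return count


def principal_eigenvariate(voxels_by_time: np.ndarray) -> np.ndarray:
    """Representative time-series of a voxel set: the scaled first right
    singular vector of the (voxels x time) data matrix.

    The sign is fixed so the mean correlation with the voxel series is
    positive, and the amplitude is scaled to the root-mean-square voxel
    loading (``s1 / sqrt(n_voxels)``), so a set of identical voxels returns
    (approximately) that voxel's series.
    """
    Y = np.asarray(voxels_by_time, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 1 or Y.shape[1] < 2:
        raise ValueError("expected a (n_voxels, n_time) matrix with >= 2 time points")
    if np.allclose(Y, 0):
        raise ValueError("all-zero input has no principal eigenvariate")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    ts = Vt[0] * (s[0] / np.sqrt(Y.shape[0]))
    if U[:, 0].sum() < 0:
        ts = -ts
    return ts


def stepwise_alpha(
    voxel_pvalues: dict[str, np.ndarray] | list[np.ndarray],
    n_scans: int,
) -> float | None:
    """Stepwise alpha rule for detecting low-frequency voxels in every region.

    Sessions with fewer than 200 scans use a fixed uncorrected alpha of
    0.05.  Longer sessions step alpha up through 0.001, 0.01, 0.05 until at
    least one voxel in every region survives; if even 0.05 fails in some
    region the session fails this criterion (returns None).
    """
    if isinstance(voxel_pvalues, dict):
        region_ps = list(voxel_pvalues.values())
    else:
        region_ps = list(voxel_pvalues)
    mins = []
    for ps in region_ps:
        ps = np.asarray(ps, dtype=float)
        if ps.size == 0:
            raise ValueError("a region has no voxel p-values")
        if np.any((ps < 0) | (ps > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        mins.append(ps.min())
    if n_scans < MIN_SCANS_FOR_LADDER:
        return ALPHA_LADDER[-1]
    for alpha in ALPHA_LADDER:
        if all(m < alpha for m in mins):
            return alpha
    return None


def session_gate(
    fit: SessionFit,
    trace: MotionTrace,
    alpha_result: float | None,
    kl_threshold: float = KL_THRESHOLD_NATS,
    priors: GaussianPrior | None = None,
) -> SessionDiagnostics:
    """Evaluate the five session-inclusion criteria (all strict inequalities).

    Connection strength is assessed on the absolute extrinsic estimates and
    on the deviation of the effective self-connections (-0.5 * exp(a)) from
    their prior value of -0.5 Hz.
    """
    reasons: list[str] = []

    ev = fit.explained_variance
    if not ev > EV_THRESHOLD_PCT:
        reasons.append("explained_variance")

    mean = fit.posterior.mean
    extrinsic = np.abs(mean[:N_EXTRINSIC])
    self_dev = np.abs(-0.5 * np.exp(mean[N_EXTRINSIC:]) + 0.5)
    max_conn = float(max(extrinsic.max(), self_dev.max()))
    if not max_conn > STRENGTH_THRESHOLD_HZ:
        reasons.append("connection_strength")

    n_eff = count_effective_params(fit.posterior, priors=priors, kl_threshold=kl_threshold)
    if not n_eff >= 1:
        reasons.append("effective_parameters")

    max_fd = float(framewise_displacement(trace).max())
    if not max_fd < FD_THRESHOLD_MM:
        reasons.append("framewise_displacement")

    if alpha_result is None:
        reasons.append("voxel_detection")

    return SessionDiagnostics(
        explained_variance_pct=ev,
        max_abs_connection_hz=max_conn,
        n_effective_params=n_eff,
        max_fd_mm=max_fd,
        alpha_used=alpha_result,
        passed=not reasons,
        failure_reasons=reasons,
    )
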