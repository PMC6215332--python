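"""Shared parameterization of the 4-region default-mode network.

The network comprises the precuneus (PRC), medial prefrontal cortex (mPFC)
and the left/right inferior parietal cortices (lIPC, rIPC).  Directed
(effective) connectivity is held in a 4x4 ``A`` matrix with the column-to-row
convention: ``A[target, source]`` is the influence of ``source`` on the rate
of change of ``target``, in Hz.  Off-diagonal entries are extrinsic
connections; diagonal entries are unitless log-scale self-connection
parameters ``a`` with effective self-connection ``-0.5 * exp(a)`` Hz, so that
self-influence is always inhibitory and the prior mean ``a = 0`` corresponds
to -0.5 Hz.

All modules share a fixed flattening of the 16 parameters into a vector:
the 12 extrinsic entries in row-major (target-major) order of the
off-diagonal positions, followed by the 4 diagonal log-scale parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "REGIONS",
    "REGION_COORDS",
    "N_REGIONS",
    "N_PARAMS",
    "EXTRINSIC_PAIRS",
    "PRC",
    "MPFC",
    "LIPC",
    "RIPC",
    "RegionSet",
    "ConnectivityPosterior",
    "GaussianPrior",
    "matrix_to_vec",
    "vec_to_matrix",
    "effective_matrix",
    "efferent_indices",
    "extrinsic_index",
    "self_index",
    "lr_swap_permutation",
    "default_session_prior",
]

#: Canonical region ordering, shared by every matrix in a run.
REGIONS: tuple[str, ...] = ("PRC", "mPFC", "lIPC", "rIPC")

#: MNI centre coordinates (mm) of the template ROIs; metadata only.
REGION_COORDS: dict[str, tuple[int, int, int]] = {
    "PRC": (2, -58, 30),
    "mPFC": (2, 56, -4),
    "lIPC": (-44, -60, 24),
    "rIPC": (54, -62, 28),
}

PRC, MPFC, LIPC, RIPC = 0, 1, 2, 3
N_REGIONS = 4

#: Off-diagonal (target, source) positions in fixed vectorization order.
EXTRINSIC_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (t, s) for t in range(N_REGIONS) for s in range(N_REGIONS) if t != s
)
N_EXTRINSIC = len(EXTRINSIC_PAIRS)
N_PARAMS = N_EXTRINSIC + N_REGIONS  # 16

_PAIR_TO_INDEX = {pair: i for i, pair in enumerate(EXTRINSIC_PAIRS)}


@dataclass(frozen=True)
class RegionSet:
    """The ordered 4-region set, with lIPC/rIPC marked as the homotopic pair."""

    labels: tuple[str, ...] = REGIONS
    coordinates: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(REGION_COORDS)
    )
    homotopic_pair: tuple[int, int] = (LIPC, RIPC)

    def __post_init__(self) -> None:
        if len(self.labels) != N_REGIONS:
            raise ValueError("exactly 4 regions are required")
        if len(set(self.labels)) != N_REGIONS:
            raise ValueError("region labels must be distinct")


def extrinsic_index(target: int, source: int) -> int:
    """Vector index of the extrinsic connection source -> target."""
    return _PAIR_TO_INDEX[(target, source)]


def self_index(region: int) -> int:
    """Vector index of a region's log-scale self parameter."""
    return N_EXTRINSIC + region


def efferent_indices(region: int) -> list[int]:
    """Vector indices of the 3 extrinsic connections leaving ``region``."""
    return [_PAIR_TO_INDEX[(t, region)] for t in range(N_REGIONS) if t != region]


def matrix_to_vec(A: np.ndarray) -> np.ndarray:
    """Flatten a 4x4 parameter matrix to the fixed 16-vector ordering."""
    A = np.asarray(A, dtype=float)
    if A.shape != (N_REGIONS, N_REGIONS):
        raise ValueError(f"expected a 4x4 matrix, got shape {A.shape}")
    vec = np.empty(N_PARAMS)
    for i, (t, s) in enumerate(EXTRINSIC_PAIRS):
        vec[i] = A[t, s]
    vec[N_EXTRINSIC:] = np.diag(A)
    return vec


def vec_to_matrix(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`matrix_to_vec`."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_PARAMS,):
        raise ValueError(f"expected a 16-vector, got shape {vec.shape}")
    A = np.zeros((N_REGIONS, N_REGIONS))
    for i, (t, s) in enumerate(EXTRINSIC_PAIRS):
        A[t, s] = vec[i]
    A[np.diag_indices(N_REGIONS)] = vec[N_EXTRINSIC:]
    return A


def effective_matrix(A: np.ndarray) -> np.ndarray:
    """Dynamical generator: off-diagonals in Hz, diagonal -0.5*exp(a) Hz."""
    A = np.asarray(A, dtype=float)
    A_eff = A.copy()
    A_eff[np.diag_indices(N_REGIONS)] = -0.5 * np.exp(np.diag(A))
    return A_eff


def lr_swap_permutation() -> np.ndarray:
    """Permutation of the 16-vector induced by exchanging lIPC and rIPC.

    Relabelling regions by ``pi = (PRC, mPFC, rIPC, lIPC)`` maps matrix entry
    ``(t, s)`` to ``(pi(t), pi(s))``; this returns the index array ``perm``
    such that ``vec_swapped = vec[perm]``.
    """
    pi = np.array([PRC, MPFC, RIPC, LIPC])
    perm = np.empty(N_PARAMS, dtype=int)
    for i, (t, s) in enumerate(EXTRINSIC_PAIRS):
        perm[i] = _PAIR_TO_INDEX[(pi[t], pi[s])]
    for r in range(N_REGIONS):
        perm[self_index(r)] = self_index(pi[r])
    return perm


@dataclass
class ConnectivityPosterior:
    """Gaussian posterior over the 16 connectivity parameters.

    Parameters follow the fixed vectorization of :func:`matrix_to_vec`:
    12 extrinsic connections (Hz) then 4 log-scale self parameters.
    """

    mean: np.ndarray
    covariance: np.ndarray
    level: str = "session"  # {"session", "subject", "group"}
    subject_id: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (N_PARAMS,):
            raise ValueError(f"posterior mean must be a 16-vector, got {self.mean.shape}")
        if self.covariance.shape != (N_PARAMS, N_PARAMS):
            raise ValueError(
                f"posterior covariance must be 16x16, got {self.covariance.shape}"
            )
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("posterior covariance must be symmetric")

    @property
    def matrix(self) -> np.ndarray:
        """The posterior mean as a 4x4 parameter matrix."""
        return vec_to_matrix(self.mean)

    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def copy(self) -> "ConnectivityPosterior":
        return replace(self, mean=self.mean.copy(), covariance=self.covariance.copy())


@dataclass
class GaussianPrior:
    """Independent Gaussian prior per parameter (diagonal covariance)."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.variance = np.atleast_1d(np.asarray(self.variance, dtype=float))
        if self.mean.shape != self.variance.shape:
            raise ValueError("prior mean and variance must have the same shape")
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be nonnegative")

    @property
    def covariance(self) -> np.ndarray:
        return np.diag(self.variance)


#: Shrinkage-prior variances: extrinsic connections are minimally informative
#: about sign but preclude extreme values; self parameters are tighter to
#: reflect gain control and guaranteed dynamical stability.
EXTRINSIC_PRIOR_VAR = 1.0 / 64.0
SELF_PRIOR_VAR = 1.0 / 256.0


def default_session_prior() -> GaussianPrior:
    """Session-level shrinkage prior over the 16 connectivity parameters."""
    variance = np.concatenate(
        [np.full(N_EXTRINSIC, EXTRINSIC_PRIOR_VAR), np.full(N_REGIONS, SELF_PRIOR_VAR)]
    )
    return GaussianPrior(mean=np.zeros(N_PARAMS), variance=variance)
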