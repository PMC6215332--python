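"""Stability criteria for directed DMN connectivity.

Three complementary summaries of how consistent connectivity estimates are
across sessions or subjects, plus a PCA characterization of variability:

* hemispheric asymmetry — the mean efferent (outgoing extrinsic)
  connectivity of the left IPC minus that of the right IPC, with the
  posterior probability that the difference has a definite sign;
* pairwise consistency — correlations between vectorised connectivity
  matrices over all unit pairs;
* sign stability — per connection, the fraction of units classified
  excitatory / inhibitory / non-significant at a posterior criterion;
* PCA of the unit-by-parameter matrix, with a rule flagging components
  dominated by opposite loadings on the two IPCs' efferents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

from .network import (
    LIPC,
    RIPC,
    N_EXTRINSIC,
    N_PARAMS,
    REGIONS,
    ConnectivityPosterior,
    EXTRINSIC_PAIRS,
    efferent_indices,
    lr_swap_permutation,
)

__all__ = [
    "AsymmetryResult",
    "SignStabilityTable",
    "PCAReport",
    "asymmetry",
    "asymmetry_contrast",
    "dominance_reorder",
    "pairwise_consistency",
    "sign_stability",
    "pca_characterize",
]

DEFAULT_CRITERION = 0.90


@dataclass
class AsymmetryResult:
    """Hemispheric asymmetry of one unit's connectivity posterior."""

    index: float  # Hz; positive = left-dominant
    posterior_probability: float  # in [0.5, 1]
    dominance: str  # {"left", "right", "none"}
    level: str = "session"
    subject_id: str | None = None
    session_id: str | None = None


@dataclass
class SignStabilityTable:
    """Per-connection fractions of positive / negative / non-significant units."""

    table: pd.DataFrame  # index: "src->tgt"; columns: positive, negative, nonsignificant
    criterion: float

    def stable_connections(self, min_fraction: float = 0.75) -> pd.DataFrame:
        """Connections with the same sign in at least ``min_fraction`` of units."""
        frac = self.table[["positive", "negative"]].max(axis=1)
        return self.table[frac >= min_fraction]


@dataclass
class PCAReport:
    loadings: np.ndarray  # unit-norm first principal component
    explained_variance_pct: float
    asymmetric_flag: bool


def asymmetry_contrast(n_params: int = N_PARAMS) -> np.ndarray:
    """Linear contrast: mean lIPC efferent minus mean rIPC efferent."""
    c = np.zeros(n_params)
    c[efferent_indices(LIPC)] = 1.0 / 3.0
    c[efferent_indices(RIPC)] = -1.0 / 3.0
    return c


def asymmetry(
    posterior: ConnectivityPosterior,
    criterion: float = DEFAULT_CRITERION,
) -> AsymmetryResult:
    """Asymmetry index and its posterior support under the Gaussian posterior.

    The posterior probability is the larger of P(contrast > 0) and
    P(contrast < 0); dominance is declared only when it reaches the
    criterion, with direction read from the sign of the index.
    """
    if posterior.covariance is None:
        raise ValueError("a posterior covariance is required")
    c = asymmetry_contrast()
    index = float(c @ posterior.mean)
    var = float(c @ posterior.covariance @ c)
    if var <= 0:
        pp = 1.0 if index != 0 else 0.5
    else:
        p_pos = float(norm.sf(0.0, loc=index, scale=np.sqrt(var)))
        pp = max(p_pos, 1.0 - p_pos)
    if pp < criterion or index == 0.0:
        dominance = "none"
    else:
        dominance = "left" if index > 0 else "right"
    return AsymmetryResult(
        index=index,
        posterior_probability=pp,
        dominance=dominance,
        level=posterior.level,
        subject_id=posterior.subject_id,
        session_id=posterior.session_id,
    )


def dominance_reorder(
    posterior: ConnectivityPosterior, dominance: str
) -> ConnectivityPosterior:
    """Exchange lIPC/rIPC slots so the dominant IPC occupies the lIPC slot.

    For ``dominance == "right"`` the rows and columns of the two IPCs are
    swapped jointly in the mean and covariance (a symmetric permutation of
    the 16-parameter vector); for ``"left"`` the posterior is returned
    unchanged.  A unit without dominance cannot be reordered and must be
    excluded upstream.
    """
    if dominance == "left":
        return posterior.copy()
    if dominance != "right":
        raise ValueError(
            f"cannot reorder a unit with dominance {dominance!r}; exclude it instead"
        )
    perm = lr_swap_permutation()
    return ConnectivityPosterior(
        mean=posterior.mean[perm],
        covariance=posterior.covariance[np.ix_(perm, perm)],
        level=posterior.level,
        subject_id=posterior.subject_id,
        session_id=posterior.session_id,
    )


def _vectors(
    posteriors: list[ConnectivityPosterior] | np.ndarray, extrinsic_only: bool
) -> np.ndarray:
    if isinstance(posteriors, np.ndarray):
        V = np.asarray(posteriors, dtype=float)
    else:
        V = np.stack([po.mean for po in posteriors])
    if extrinsic_only:
        V = V[:, :N_EXTRINSIC]
    return V


def pairwise_consistency(
    posteriors: list[ConnectivityPosterior] | np.ndarray,
    extrinsic_only: bool = False,
    method: str = "pearson",
) -> tuple[np.ndarray, float]:
    """Correlations between vectorised connectivity for every unordered pair.

    Accepts posteriors or a pre-stacked (n_units, n_params) array of mean
    vectors.  Returns the full correlation matrix and the mean of its
    off-diagonal entries.
    """
    V = _vectors(posteriors, extrinsic_only)
    if len(V) < 2:
        raise ValueError("at least 2 units are required")
    sd = V.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance vector: pairwise correlation undefined")
    if method == "pearson":
        R = np.corrcoef(V)
    elif method == "spearman":
        R = spearmanr(V.T)[0]
        R = np.atleast_2d(R)
    else:
        raise ValueError(f"unknown method {method!r}")
    off = R[np.triu_indices(len(V), k=1)]
    return R, float(off.mean())


def sign_stability(
    posteriors: list[ConnectivityPosterior],
    criterion: float = DEFAULT_CRITERION,
) -> SignStabilityTable:
    """Classify each extrinsic connection per unit and tabulate fractions.

    A unit counts as positive (negative) for a connection when the marginal
    posterior probability of that sign is at least the criterion; otherwise
    it is non-significant.  The three fractions sum to 1 per connection.
    """
    if not posteriors:
        raise ValueError("at least one posterior is required")
    n = len(posteriors)
    counts = np.zeros((N_EXTRINSIC, 3))
    for po in posteriors:
        mu = po.mean[:N_EXTRINSIC]
        sd = po.marginal_sd()[:N_EXTRINSIC]
        with np.errstate(divide="ignore"):
            p_pos = norm.sf(0.0, loc=mu, scale=np.where(sd > 0, sd, np.inf))
        p_pos = np.where((sd == 0), (mu > 0).astype(float), p_pos)
        pos = p_pos >= criterion
        neg = (1.0 - p_pos) >= criterion
        counts[pos, 0] += 1
        counts[neg, 1] += 1
        counts[~pos & ~neg, 2] += 1
    labels = [f"{REGIONS[s]}->{REGIONS[t]}" for (t, s) in EXTRINSIC_PAIRS]
    table = pd.DataFrame(
        counts / n, index=labels, columns=["positive", "negative", "nonsignificant"]
    )
    return SignStabilityTable(table=table, criterion=criterion)


def pca_characterize(
    mean_vectors: np.ndarray | list[np.ndarray],
    extrinsic_only: bool = False,
) -> PCAReport:
    """First principal component of centered connectivity vectors.

    Covariance PCA (no standardization; the parameters share comparable
    scales).  The component sign is fixed so the largest-magnitude loading
    is positive.  ``asymmetric_flag`` is true when at least two of the three
    highest loadings fall on one IPC's efferent connections while at least
    two of the three lowest fall on the contralateral IPC's efferents.
    """
    V = np.stack([np.asarray(v, dtype=float) for v in mean_vectors])
    if extrinsic_only:
        V = V[:, :N_EXTRINSIC]
    if len(V) < 3:
        raise ValueError("at least 3 vectors are required for PCA")
    X = V - V.mean(axis=0)
    if np.allclose(X, 0):
        raise ValueError("rank-deficient input: all vectors identical")
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    loadings = Vt[0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    explained = 100.0 * float(s[0] ** 2 / np.sum(s**2))

    left = set(efferent_indices(LIPC))
    right = set(efferent_indices(RIPC))
    order = np.argsort(loadings)
    top3, bottom3 = set(order[-3:].tolist()), set(order[:3].tolist())
    flag = (len(top3 & left) >= 2 and len(bottom3 & right) >= 2) or (
        len(top3 & right) >= 2 and len(bottom3 & left) >= 2
    )
    return PCAReport(
        loadings=loadings, explained_variance_pct=explained, asymmetric_flag=bool(flag)
    )
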