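"""Synthetic longitudinal cohorts of directed DMN connectivity.

Emulates the hierarchical structure of a multi-dataset longitudinal resting
state study: a group-level connectivity pattern, per-subject deviations that
include a lateralized (hemispheric-dominance) component, and per-session
fluctuations around each subject.  Session-level measurement uncertainty is
emulated by Gaussian "posterior" distributions around the session matrices,
standing in for full model inversion when downstream stages are tested in
isolation.

Conventions follow :mod:`dmnstab.network`: matrices are column-to-source /
row-to-target, diagonals are log-scale self parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .network import (
    LIPC,
    RIPC,
    N_PARAMS,
    N_REGIONS,
    REGIONS,
    ConnectivityPosterior,
    matrix_to_vec,
    vec_to_matrix,
)
from .spectral import check_stability

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "default_group_matrix",
    "sample_cohort",
    "emit_session_posteriors",
    "write_cohort",
    "read_cohort",
]


def default_group_matrix() -> np.ndarray:
    """A left/right-symmetric DMN-like baseline pattern (Hz; diag log-scale).

    Bilateral IPC drives the medial regions and each other; the medial
    prefrontal cortex mildly inhibits both IPCs.  The baseline is symmetric
    under the lIPC/rIPC exchange so that any hemispheric asymmetry in a
    cohort is exactly the injected dominance effect.
    """
    A = np.zeros((N_REGIONS, N_REGIONS))
    # columns are sources:        PRC    mPFC   lIPC   rIPC
    A[0] = [0.00, 0.05, 0.25, 0.25]  # -> PRC
    A[1] = [0.10, 0.00, 0.20, 0.20]  # -> mPFC
    A[2] = [0.05, -0.10, 0.00, 0.25]  # -> lIPC
    A[3] = [0.05, -0.10, 0.25, 0.00]  # -> rIPC
    return A


@dataclass
class CohortSpec:
    """Generative description of a synthetic longitudinal cohort.

    Random effects are i.i.d. Gaussian per parameter; their standard
    deviations apply to extrinsic connections in Hz and are halved for the
    log-scale self parameters, mirroring the 4x tighter self priors.  The
    default between-subject dispersion is calibrated so that the dominance
    component explains roughly 60% of between-subject parameter variance in
    a 16-subject cohort, the regime reported for real longitudinal DMN
    cohorts (where the first principal component across subjects is the
    hemispheric-asymmetry pattern).

    A subject's hemispheric dominance has three components, all configurable:
    ``asymmetry_magnitude`` (Hz) is added to the 3 efferent connections of
    the dominant IPC; ``self_offset`` (log-scale, typically negative) is
    added to its self parameter — the dominant IPC is disinhibited; and
    ``afferent_offset`` (Hz) is subtracted from the non-dominant IPC's
    inputs from the two medial regions — the non-dominant IPC is inhibited
    by medial regions.  ``flip_probability`` lets individual sessions
    express the opposite dominance (the mechanism behind session-level
    flips is not asserted; this is an explicit knob).
    """

    n_subjects: int = 16
    sessions_per_subject: int | list[int] = 10
    group_matrix: np.ndarray = field(default_factory=default_group_matrix)
    asymmetry_magnitude: float = 0.3
    self_offset: float = -0.3
    afferent_offset: float = 0.15
    dominance_probability: float = 0.625
    symmetric_probability: float = 0.0
    between_subject_sd: float = 0.10
    between_session_sd: float = 0.1
    session_posterior_sd: float = 0.05
    flip_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_matrix = np.asarray(self.group_matrix, dtype=float)
        if self.group_matrix.shape != (N_REGIONS, N_REGIONS):
            raise ValueError("group_matrix must be 4x4")
        for name in ("between_subject_sd", "between_session_sd", "session_posterior_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dominance_probability <= 1.0:
            raise ValueError("dominance_probability must be in [0, 1]")
        if not 0.0 <= self.symmetric_probability <= 1.0:
            raise ValueError("symmetric_probability must be in [0, 1]")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def session_counts(self) -> list[int]:
        if isinstance(self.sessions_per_subject, int):
            return [self.sessions_per_subject] * self.n_subjects
        counts = list(self.sessions_per_subject)
        if len(counts) != self.n_subjects:
            raise ValueError("sessions_per_subject list must have n_subjects entries")
        return counts


@dataclass
class GroundTruth:
    """A sampled cohort: group, subject and session matrices plus labels."""

    spec: CohortSpec
    group_matrix: np.ndarray
    subject_matrices: list[np.ndarray]
    session_matrices: list[list[np.ndarray]]
    dominance_labels: list[str]  # per subject, in {"left", "right", "none"}

    @property
    def n_subjects(self) -> int:
        return len(self.subject_matrices)

    def subject_vectors(self) -> np.ndarray:
        return np.stack([matrix_to_vec(A) for A in self.subject_matrices])

    def session_vectors(self, subject: int) -> np.ndarray:
        return np.stack([matrix_to_vec(A) for A in self.session_matrices[subject]])


_STABILITY_RETRY_CAP = 1000


def _dominance_offset(
    dominant: int, magnitude: float, self_offset: float, afferent_offset: float = 0.0
) -> np.ndarray:
    """Additive matrix expressing dominance of one IPC (in parameter space).

    The dominant IPC gains efferent strength and is disinhibited; the
    non-dominant IPC loses input from the two medial regions.
    """
    off = np.zeros((N_REGIONS, N_REGIONS))
    for t in range(N_REGIONS):
        if t != dominant:
            off[t, dominant] += magnitude
    off[dominant, dominant] += self_offset
    nondominant = LIPC + RIPC - dominant
    for s in (0, 1):  # PRC, mPFC
        off[nondominant, s] -= afferent_offset
    return off


def _param_sd_vector(sd: float) -> np.ndarray:
    sd_vec = np.full(N_PARAMS, sd)
    sd_vec[-N_REGIONS:] = sd / 2.0  # log-scale self parameters vary less
    return sd_vec


def _sample_stable(base: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian parameter noise, rejecting dynamically unstable draws."""
    if sd == 0.0:
        if not check_stability(base):
            raise RuntimeError("base matrix is dynamically unstable")
        return base.copy()
    sd_vec = _param_sd_vector(sd)
    base_vec = matrix_to_vec(base)
    for _ in range(_STABILITY_RETRY_CAP):
        draw = vec_to_matrix(base_vec + rng.normal(0.0, sd_vec))
        if check_stability(draw):
            return draw
    raise RuntimeError(
        "stability rejection cap exceeded: the cohort spec is over-dispersed "
        f"(sd={sd}) around an unstable neighbourhood"
    )


def sample_cohort(spec: CohortSpec) -> GroundTruth:
    """Draw a full cohort: dominance labels, subject and session matrices.

    Subject matrix = group + dominance offset + Gaussian subject effect;
    session matrix = subject + Gaussian session effect (with the dominance
    offset optionally flipped to the contralateral IPC, see
    ``flip_probability``).  Every matrix is dynamically stable by rejection
    sampling.  Identical seeds give bit-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    counts = spec.session_counts()
    labels: list[str] = []
    subject_matrices: list[np.ndarray] = []
    session_matrices: list[list[np.ndarray]] = []

    for subj in range(spec.n_subjects):
        u = rng.uniform()
        if u < spec.symmetric_probability:
            label = "none"
        elif rng.uniform() < spec.dominance_probability:
            label = "left"
        else:
            label = "right"
        labels.append(label)

        dominant = {"left": LIPC, "right": RIPC}.get(label)
        if dominant is None:
            offset = np.zeros((N_REGIONS, N_REGIONS))
        else:
            offset = _dominance_offset(
                dominant, spec.asymmetry_magnitude, spec.self_offset, spec.afferent_offset
            )
        subject = _sample_stable(spec.group_matrix + offset, spec.between_subject_sd, rng)
        subject_matrices.append(subject)

        sessions = []
        for _ in range(counts[subj]):
            base = subject
            if dominant is not None and spec.flip_probability > 0.0:
                if rng.uniform() < spec.flip_probability:
                    flipped = _dominance_offset(
                        LIPC + RIPC - dominant, spec.asymmetry_magnitude,
                        spec.self_offset, spec.afferent_offset,
                    )
                    base = subject - offset + flipped
            sessions.append(_sample_stable(base, spec.between_session_sd, rng))
        session_matrices.append(sessions)

    return GroundTruth(
        spec=spec,
        group_matrix=spec.group_matrix.copy(),
        subject_matrices=subject_matrices,
        session_matrices=session_matrices,
        dominance_labels=labels,
    )


def emit_session_posteriors(
    truth: GroundTruth,
    session_posterior_sd: float | None = None,
    seed: int | None = None,
) -> list[ConnectivityPosterior]:
    """Gaussian session posteriors around the ground-truth session matrices.

    A stand-in for per-session model inversion: posterior mean = session
    matrix + N(0, sd^2) estimation noise, covariance = sd^2 * I.  ``seed``
    defaults to a fixed offset of the cohort seed, so repeated calls on the
    same cohort are reproducible.
    """
    sd = truth.spec.session_posterior_sd if session_posterior_sd is None else session_posterior_sd
    if sd <= 0:
        raise ValueError("session_posterior_sd must be > 0")
    rng = np.random.default_rng(truth.spec.seed + 1_000_003 if seed is None else seed)
    cov = sd**2 * np.eye(N_PARAMS)
    posteriors = []
    for subj, sessions in enumerate(truth.session_matrices):
        for sess, A in enumerate(sessions):
            mean = matrix_to_vec(A) + rng.normal(0.0, sd, size=N_PARAMS)
            posteriors.append(
                ConnectivityPosterior(
                    mean=mean,
                    covariance=cov.copy(),
                    level="session",
                    subject_id=f"S{subj + 1}",
                    session_id=f"ses-{sess + 1:03d}",
                )
            )
    return posteriors


# ---------------------------------------------------------------------------
# On-disk format: a JSON manifest plus TSV tables (diffable, text-only).
# ---------------------------------------------------------------------------

_MANIFEST = "cohort.json"
_SESSIONS = "sessions.tsv"


def _matrix_records(A: np.ndarray) -> list[dict]:
    recs = []
    for t in range(N_REGIONS):
        for s in range(N_REGIONS):
            recs.append(
                {"source_region": REGIONS[s], "target_region": REGIONS[t], "value": A[t, s]}
            )
    return recs


def _records_to_matrix(df: pd.DataFrame, context: str) -> np.ndarray:
    if len(df) != N_REGIONS * N_REGIONS:
        raise ValueError(
            f"schema error in {context}: expected {N_REGIONS * N_REGIONS} matrix "
            f"entries, found {len(df)}"
        )
    A = np.full((N_REGIONS, N_REGIONS), np.nan)
    idx = {name: i for i, name in enumerate(REGIONS)}
    for row in df.itertuples(index=False):
        try:
            t, s = idx[row.target_region], idx[row.source_region]
        except KeyError as exc:
            raise ValueError(f"schema error in {context}: unknown region {exc}") from exc
        A[t, s] = row.value
    if np.isnan(A).any():
        raise ValueError(f"schema error in {context}: missing matrix entries")
    return A


def write_cohort(
    truth: GroundTruth,
    posteriors: list[ConnectivityPosterior] | None,
    path: str | Path,
) -> None:
    """Write a cohort (and optional session posteriors) to ``path``.

    ``cohort.json`` holds the spec, dominance labels and all ground-truth
    matrices; ``sessions.tsv`` holds long-format session posterior means and
    marginal sds with columns subject_id, session_id, source_region,
    target_region, mean, sd.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    spec_dict = asdict(truth.spec)
    spec_dict["group_matrix"] = truth.spec.group_matrix.tolist()
    manifest = {
        "format_version": 1,
        "regions": list(REGIONS),
        "spec": spec_dict,
        "dominance_labels": truth.dominance_labels,
        "group_matrix": truth.group_matrix.tolist(),
        "subject_matrices": [A.tolist() for A in truth.subject_matrices],
        "session_matrices": [
            [A.tolist() for A in sessions] for sessions in truth.session_matrices
        ],
    }
    (path / _MANIFEST).write_text(json.dumps(manifest, indent=1))

    rows = []
    for post in posteriors or []:
        sd = post.marginal_sd()
        A_mean = vec_to_matrix(post.mean)
        A_sd = vec_to_matrix(sd)
        for t in range(N_REGIONS):
            for s in range(N_REGIONS):
                rows.append(
                    {
                        "subject_id": post.subject_id,
                        "session_id": post.session_id,
                        "source_region": REGIONS[s],
                        "target_region": REGIONS[t],
                        "mean": A_mean[t, s],
                        "sd": A_sd[t, s],
                    }
                )
    pd.DataFrame(
        rows, columns=["subject_id", "session_id", "source_region", "target_region", "mean", "sd"]
    ).to_csv(path / _SESSIONS, sep="\t", index=False)


def read_cohort(path: str | Path) -> tuple[GroundTruth, list[ConnectivityPosterior]]:
    """Round-trip counterpart of :func:`write_cohort`."""
    path = Path(path)
    manifest = json.loads((path / _MANIFEST).read_text())
    spec_dict = dict(manifest["spec"])
    spec_dict["group_matrix"] = np.asarray(spec_dict["group_matrix"], dtype=float)
    spec = CohortSpec(**spec_dict)
    truth = GroundTruth(
        spec=spec,
        group_matrix=np.asarray(manifest["group_matrix"], dtype=float),
        subject_matrices=[np.asarray(A, dtype=float) for A in manifest["subject_matrices"]],
        session_matrices=[
            [np.asarray(A, dtype=float) for A in sessions]
            for sessions in manifest["session_matrices"]
        ],
        dominance_labels=list(manifest["dominance_labels"]),
    )
    for i, A in enumerate(truth.subject_matrices):
        if A.shape != (N_REGIONS, N_REGIONS):
            raise ValueError(f"schema error in subject matrix {i}: shape {A.shape}")
    for i, sessions in enumerate(truth.session_matrices):
        for j, A in enumerate(sessions):
            if A.shape != (N_REGIONS, N_REGIONS):
                raise ValueError(
                    f"schema error in session matrix (subject {i}, session {j}): "
                    f"shape {A.shape}"
                )

    df = pd.read_csv(path / _SESSIONS, sep="\t")
    posteriors: list[ConnectivityPosterior] = []
    if len(df):
        for (subj, sess), grp in df.groupby(["subject_id", "session_id"], sort=False):
            A_mean = _records_to_matrix(
                grp.rename(columns={"mean": "value"}), f"session {subj}/{sess}"
            )
            A_sd = _records_to_matrix(
                grp.rename(columns={"sd": "value"}), f"session {subj}/{sess}"
            )
            posteriors.append(
                ConnectivityPosterior(
                    mean=matrix_to_vec(A_mean),
                    covariance=np.diag(matrix_to_vec(A_sd) ** 2),
                    level="session",
                    subject_id=str(subj),
                    session_id=str(sess),
                )
            )
    return truth, posteriors
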