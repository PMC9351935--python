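"""Shared response model: functional alignment via orthonormal transforms.

Subjects watching the same stimulus produce responses X_i (V_i x T) that
share temporal structure but live in idiosyncratic voxel spaces.  The model
factorizes X_i ~= W_i S with W_i a V_i x k matrix with orthonormal columns
(a topographic basis specific to subject i) and S a k x T response shared by
everyone.  Fitting alternates exact coordinate minimizations of
sum_i ||X_i - W_i S||_F^2: S <- mean_i W_i^T X_i, then each W_i by
orthogonal Procrustes (SVD of X_i S^T), so the recorded objective is
non-increasing by construction.  The deterministic formulation is used
throughout; probabilistic and accelerated variants are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import svd

from .core import (
    MultiSubjectDataset,
    SubjectTimeSeries,
    ValidationError,
    zscore_time,
)

__all__ = [
    "SRMModel",
    "TimeSegmentReport",
    "srm_fit",
    "srm_transform",
    "srm_reconstruct",
    "time_segment_classify",
    "make_srm_dataset",
]


@dataclass
class SRMModel:
    k: int
    transforms: list[np.ndarray]  # W_i, each V_i x k, orthonormal columns
    shared_response: np.ndarray  # S, k x T
    objective_trace: list[float]
    n_iter: int
    seed: int


@dataclass
class TimeSegmentReport:
    segment_len_tr: int
    accuracy: float
    chance_level: float
    n_segments: int
    per_subject_accuracy: np.ndarray


def _orthonormal_init(v: int, k: int, rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((v, k)))
    return q[:, :k]


def _objective(xs: list[np.ndarray], ws: list[np.ndarray], s: np.ndarray) -> float:
    return float(sum(np.linalg.norm(x - w @ s, "fro") ** 2 for x, w in zip(xs, ws)))


def srm_fit(
    dataset: MultiSubjectDataset,
    k: int,
    n_iter: int = 10,
    seed: int = 0,
    standardize: bool = True,
    init_transforms: list[np.ndarray] | None = None,
) -> SRMModel:
    """Fit the shared response model by alternating minimization.

    Data are z-scored per unit by default (the shared space should not
    depend on per-unit gain); pass ``standardize=False`` for data that is
    already on a common scale. W_i are initialized from seeded Gaussian
    matrices orthonormalized by QR unless explicit ``init_transforms`` are
    supplied (warm restarts, equivariance studies); exactly ``n_iter``
    iterations are run and the objective sum_i ||X_i - W_i S||_F^2 is
    recorded after each.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    t = dataset.n_timepoints
    xs = []
    for sub in dataset.subjects:
        if not sub.data.any():
            raise ValidationError(f"subject {sub.subject_id!r} is all zeros")
        data = zscore_time(sub).data if standardize else sub.data
        xs.append(data.T)  # V_i x T
    v_min = min(x.shape[0] for x in xs)
    if k > v_min or k > t:
        raise ValidationError(
            f"k={k} exceeds min(V_i)={v_min} or T={t}"
        )
    rng = np.random.default_rng(seed)
    if init_transforms is not None:
        if len(init_transforms) != len(xs):
            raise ValidationError("need one init transform per subject")
        ws = [np.asarray(w, float).copy() for w in init_transforms]
    else:
        ws = [_orthonormal_init(x.shape[0], k, rng) for x in xs]
    trace: list[float] = []
    s = None
    for _ in range(n_iter):
        s = np.mean([w.T @ x for w, x in zip(ws, xs)], axis=0)
        for i, x in enumerate(xs):
            u, _, vt = svd(x @ s.T, full_matrices=False)
            ws[i] = u @ vt
        trace.append(_objective(xs, ws, s))
    # final S consistent with the final transforms
    s = np.mean([w.T @ x for w, x in zip(ws, xs)], axis=0)
    return SRMModel(k, ws, s, trace, n_iter, seed)


def srm_transform(
    model: SRMModel, new_data: SubjectTimeSeries, subject_index: int
) -> np.ndarray:
    """Project unseen data from one subject's voxel space into the shared
    space: returns W_i^T X_new, shape (k, T')."""
    w = model.transforms[subject_index]
    if new_data.n_units != w.shape[0]:
        raise ValidationError(
            f"subject {subject_index} expects V={w.shape[0]}, got {new_data.n_units}"
        )
    return w.T @ new_data.data.T


def srm_reconstruct(
    model: SRMModel, shared: np.ndarray, subject_index: int
) -> SubjectTimeSeries:
    """Map a shared-space response back into a subject's voxel space
    (W_i @ shared); composing with ``srm_transform`` gives the rank-k
    orthogonal projection onto span(W_i)."""
    shared = np.asarray(shared, float)
    if shared.ndim != 2 or shared.shape[0] != model.k:
        raise ValidationError(
            f"shared must be (k={model.k}, T'), got {shared.shape}"
        )
    w = model.transforms[subject_index]
    return SubjectTimeSeries((w @ shared).T, 1.0, f"reconstructed_{subject_index}")


def time_segment_classify(
    spaces: list[np.ndarray],
    segment_len_tr: int,
) -> TimeSegmentReport:
    """Between-subject time-segment classification in a common space.

    The time axis is cut into non-overlapping segments of
    ``segment_len_tr`` TRs. For each held-out subject, each of their
    segments (flattened feature x time block) is matched by Pearson
    correlation against the other-subject-average of every candidate
    segment; prediction is the argmax, ties broken toward the earliest
    segment. Chance level is 1 / n_segments.
    """
    if segment_len_tr < 2:
        raise ValidationError("segment_len_tr must be >= 2")
    if len(spaces) < 2:
        raise ValidationError("need >= 2 subjects")
    arr = np.stack([np.asarray(s, float) for s in spaces])  # (N, k, T)
    n, k, t = arr.shape
    if t < 2 * segment_len_tr:
        raise ValidationError("need T >= 2 * segment_len_tr")
    n_seg = t // segment_len_tr
    # (N, n_seg, k * L) flattened segments
    segs = (
        arr[:, :, : n_seg * segment_len_tr]
        .reshape(n, k, n_seg, segment_len_tr)
        .transpose(0, 2, 1, 3)
        .reshape(n, n_seg, k * segment_len_tr)
    )
    per_subject = np.empty(n)
    for s in range(n):
        others = (segs.sum(axis=0) - segs[s]) / (n - 1)  # (n_seg, kL)
        a = segs[s] - segs[s].mean(axis=1, keepdims=True)
        b = others - others.mean(axis=1, keepdims=True)
        denom = np.outer(
            np.linalg.norm(a, axis=1), np.linalg.norm(b, axis=1)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (a @ b.T) / denom  # (n_seg true, n_seg candidate)
        corr = np.nan_to_num(corr, nan=-np.inf)
        pred = corr.argmax(axis=1)  # argmax returns the earliest tie
        per_subject[s] = float(np.mean(pred == np.arange(n_seg)))
    return TimeSegmentReport(
        segment_len_tr=segment_len_tr,
        accuracy=float(per_subject.mean()),
        chance_level=1.0 / n_seg,
        n_segments=n_seg,
        per_subject_accuracy=per_subject,
    )


# ---------------------------------------------------------------------------
# Synthetic data


def _equal_row_norm_basis(v: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """V x k matrix with orthonormal columns and equal row norms sqrt(k/V).

    Built from k columns of a sign- and permutation-randomized Hadamard
    matrix (requires V a power of two). Equal row energy means per-unit
    standardization of W @ S rescales every unit identically, so noise-free
    data stays exactly of model form after z-scoring.
    """
    from scipy.linalg import hadamard

    if v & (v - 1) != 0:
        raise ValidationError("equal-row-norm basis requires V a power of two")
    h = hadamard(v) / np.sqrt(v)
    cols = rng.choice(v, size=k, replace=False)
    w = h[:, cols] * rng.choice([-1.0, 1.0], size=v)[:, None]
    return w[rng.permutation(v)]


def make_srm_dataset(
    n_subjects: int = 10,
    v: int = 64,
    k: int = 5,
    t: int = 400,
    noise_sd: float = 0.0,
    seed: int = 0,
    tr_seconds: float = 1.0,
) -> tuple[MultiSubjectDataset, list[np.ndarray], np.ndarray]:
    """Generate X_i = W_i* S* + noise with known ground truth.

    S* has zero-mean mutually orthogonal rows scaled so that each noise-free
    unit has exactly unit variance; W_i* are random equal-row-norm
    orthonormal bases (V must be a power of two). Returns
    (dataset, true transforms, true shared response).
    """
    rng = np.random.default_rng(seed)
    # zero-mean orthogonal rows, row norm sqrt(T * V / k) -> unit-variance units
    g = rng.standard_normal((t, k))
    g -= g.mean(axis=0)
    q, _ = np.linalg.qr(g)
    s_true = (q * np.sqrt(t * v / k)).T  # k x T
    ws, subs = [], []
    for i in range(n_subjects):
        w = _equal_row_norm_basis(v, k, rng)
        x = w @ s_true
        if noise_sd > 0:
            x = x + noise_sd * rng.standard_normal(x.shape)
        ws.append(w)
        subs.append(SubjectTimeSeries(x.T, tr_seconds, f"sub-{i:02d}"))
    return MultiSubjectDataset(subs, "time_aligned_only"), ws, s_true
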