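"""Intersubject correlation (ISC) and intersubject functional correlation.

ISC isolates the stimulus-driven component of brain activity by correlating
homologous units *across* subjects who received the same naturalistic
stimulus: idiosyncratic signal and noise are uncorrelated between brains and
average out.  ISFC extends the idea to all unit pairs, estimating
stimulus-locked functional networks; spatial ISC applies the same logic
across units within each timepoint.  Nonparametric nulls (phase
randomization, circular shift, subject bootstrap, sign permutation) provide
inference that respects the autocorrelation of the time series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
from scipy import stats

from .core import (
    DegenerateDataWarning,
    MultiSubjectDataset,
    ValidationError,
)

__all__ = [
    "ISCResult",
    "ISFCResult",
    "NullTestResult",
    "isc",
    "isfc",
    "spatial_isc",
    "sliding_isc",
    "isc_test",
    "fisher_mean",
]

Method = Literal["loo", "pairwise"]


@dataclass
class ISCResult:
    """Per-subject (loo) or per-pair (pairwise) unit-wise correlations."""

    values: np.ndarray  # (N, V) for loo; (N*(N-1)/2, V) for pairwise
    method: Method
    pair_index: list[tuple[int, int]] | None = None
    summary: np.ndarray | None = None  # optional V-length summary


@dataclass
class ISFCResult:
    matrices: np.ndarray  # (N or n_pairs, V, V)
    symmetrized: bool
    method: Method
    pair_index: list[tuple[int, int]] | None = None


@dataclass
class NullTestResult:
    """Observed statistic, permutation null, and add-one p / BH-FDR q values."""

    observed: np.ndarray
    null_samples: np.ndarray  # (B, V)
    p_values: np.ndarray
    q_values: np.ndarray
    method: str
    seed: int
    n_null: int


def fisher_mean(r: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean correlation via Fisher z (atanh), NaN-aware, back-transformed.

    atanh(+-1) is +-inf; tanh maps it back to +-1, so unanimous perfect
    correlations survive the round trip exactly.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(r)
        out = np.tanh(np.nanmean(z, axis=axis))
    return out


def _zscore_cols(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-score with population sd; returns (z, zero-variance mask)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    dead = sd == 0
    z = (x - mu) / np.where(dead, 1.0, sd)
    z[:, dead] = 0.0
    return z, dead


def _corr_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise Pearson correlation of two (T, V) arrays; NaN where a
    column of either input has zero variance."""
    t = a.shape[0]
    za, da = _zscore_cols(a)
    zb, db = _zscore_cols(b)
    r = (za * zb).sum(axis=0) / t
    r[da | db] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


def _check_dataset(dataset: MultiSubjectDataset) -> np.ndarray:
    if dataset.alignment_mode != "units_aligned":
        raise ValidationError("ISC requires a units_aligned dataset")
    if dataset.n_timepoints < 3:
        raise ValidationError("need T >= 3 for a non-degenerate correlation")
    return dataset.stack()  # (N, T, V)


def _isc_from_stack(x: np.ndarray, method: Method) -> tuple[np.ndarray, list | None]:
    n = x.shape[0]
    if method == "loo":
        total = x.sum(axis=0)
        rows = [_corr_cols(x[s], (total - x[s]) / (n - 1)) for s in range(n)]
        return np.stack(rows), None
    if method == "pairwise":
        pairs = list(combinations(range(n), 2))
        rows = [_corr_cols(x[i], x[j]) for i, j in pairs]
        return np.stack(rows), pairs
    raise ValidationError(f"unknown ISC method {method!r}")


def isc(
    dataset: MultiSubjectDataset,
    method: Method = "loo",
    summary: Literal["none", "mean_fisher_z", "median"] = "mean_fisher_z",
) -> ISCResult:
    """Intersubject correlation per unit.

    ``loo`` correlates each subject with the average of the rest; ``pairwise``
    correlates every subject pair (lexicographic order). Zero-variance series
    produce NaN entries, which summaries skip with a warning.
    """
    x = _check_dataset(dataset)
    values, pairs = _isc_from_stack(x, method)
    summ = None
    if summary != "none":
        n_nan = int(np.isnan(values).sum())
        if n_nan:
            warnings.warn(
                f"{n_nan} NaN correlation(s) excluded from the ISC summary",
                DegenerateDataWarning,
                stacklevel=2,
            )
        if summary == "mean_fisher_z":
            summ = fisher_mean(values, axis=0)
        elif summary == "median":
            summ = np.nanmedian(values, axis=0)
        else:
            raise ValidationError(f"unknown summary {summary!r}")
    return ISCResult(values, method, pairs, summ)


def isfc(
    dataset: MultiSubjectDataset,
    method: Method = "loo",
    symmetrize: bool = True,
) -> ISFCResult:
    """Intersubject functional correlation: unit-a-in-one-brain vs
    unit-b-in-other-brains, for every (a, b).

    The diagonal of the symmetrized leave-one-out ISFC matrix is exactly the
    leave-one-out ISC (symmetrization averages M with its transpose and the
    diagonal is a fixed point).
    """
    x = _check_dataset(dataset)
    n, t, _ = x.shape
    mats = []
    if method == "loo":
        total = x.sum(axis=0)
        for s in range(n):
            za, da = _zscore_cols(x[s])
            zb, db = _zscore_cols((total - x[s]) / (n - 1))
            m = za.T @ zb / t
            m[da, :] = np.nan
            m[:, db] = np.nan
            mats.append(np.clip(m, -1, 1))
        pairs = None
    elif method == "pairwise":
        pairs = list(combinations(range(n), 2))
        for i, j in pairs:
            za, da = _zscore_cols(x[i])
            zb, db = _zscore_cols(x[j])
            m = za.T @ zb / t
            m[da, :] = np.nan
            m[:, db] = np.nan
            mats.append(np.clip(m, -1, 1))
    else:
        raise ValidationError(f"unknown ISFC method {method!r}")
    out = np.stack(mats)
    if symmetrize:
        out = (out + out.transpose(0, 2, 1)) / 2
    return ISFCResult(out, symmetrize, method, pairs)


def spatial_isc(
    dataset: MultiSubjectDataset,
    pair_all_timepoints: bool = False,
) -> np.ndarray:
    """Leave-one-out spatial (pattern) ISC.

    For each timepoint, the correlation *across units* between one subject's
    spatial pattern and the average pattern of the others, Fisher-z averaged
    over subjects. With ``pair_all_timepoints`` every (t1, t2) combination is
    correlated, yielding a T x T matrix whose off-diagonal structure reveals
    recurring patterns.
    """
    x = _check_dataset(dataset)
    n, t, v = x.shape
    if v < 3:
        raise ValidationError("spatial ISC needs V >= 3")

    def _zrows(a: np.ndarray) -> np.ndarray:
        mu = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, np.nan, sd)
        return (a - mu) / sd

    total = x.sum(axis=0)
    rs = []
    for s in range(n):
        za = _zrows(x[s])
        zb = _zrows((total - x[s]) / (n - 1))
        if pair_all_timepoints:
            rs.append(np.clip(za @ zb.T / v, -1, 1))
        else:
            rs.append(np.clip((za * zb).sum(axis=1) / v, -1, 1))
    return fisher_mean(np.stack(rs), axis=0)


def sliding_isc(
    dataset: MultiSubjectDataset,
    window_tr: int,
    step_tr: int = 1,
    method: Method = "loo",
) -> np.ndarray:
    """Windowed ISC summary: rows are windows [w*step, w*step + window).

    Returns a (n_windows, V) matrix of Fisher-z mean ISC per window.
    """
    t = dataset.n_timepoints
    if not 3 <= window_tr <= t:
        raise ValidationError(f"window_tr must be in [3, T={t}], got {window_tr}")
    if step_tr < 1:
        raise ValidationError("step_tr must be >= 1")
    x = dataset.stack()
    n_windows = (t - window_tr) // step_tr + 1
    out = np.empty((n_windows, x.shape[2]))
    for w in range(n_windows):
        lo = w * step_tr
        values, _ = _isc_from_stack(x[:, lo : lo + window_tr, :], method)
        out[w] = fisher_mean(values, axis=0)
    return out


# ---------------------------------------------------------------------------
# Nonparametric tests


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fourier surrogate of each column of (T, V): amplitude spectrum kept,
    phases of non-DC/non-Nyquist bins replaced by iid uniform phases
    (conjugate symmetry implied by using the real FFT), so the surrogate is
    real with identical |FFT|."""
    t = x.shape[0]
    spec = np.fft.rfft(x, axis=0)
    nf = spec.shape[0]
    lo, hi = 1, nf - 1 if t % 2 == 0 else nf  # Nyquist bin exists iff T even
    phases = rng.uniform(0, 2 * np.pi, size=(hi - lo,) + x.shape[1:])
    spec[lo:hi] *= np.exp(1j * phases)
    return np.fft.irfft(spec, n=t, axis=0)


def _summary_stat(values: np.ndarray) -> np.ndarray:
    return fisher_mean(values, axis=0)


def isc_test(
    result: ISCResult,
    dataset: MultiSubjectDataset,
    method: Literal[
        "phase_randomization", "circular_shift", "subject_bootstrap", "sign_permutation"
    ] = "phase_randomization",
    n_null: int = 1000,
    seed: int = 0,
    tail: Literal["greater", "less", "two_sided"] = "greater",
) -> NullTestResult:
    """Nonparametric test of the unit-wise summary ISC.

    Surrogate methods (``phase_randomization``, ``circular_shift``) rebuild
    the summary ISC after disrupting temporal alignment while preserving,
    respectively, the amplitude spectrum or the autocorrelation of each
    series. ``subject_bootstrap`` and ``sign_permutation`` resample the
    per-subject Fisher-z leave-one-out values. p-values use the add-one rule
    p = (1 + #{null >= obs}) / (1 + B); q-values are Benjamini-Hochberg
    across units.
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    x = _check_dataset(dataset)
    n, t, v = x.shape
    rng = np.random.default_rng(seed)
    observed = _summary_stat(result.values)
    null = np.empty((n_null, v))

    if method in ("phase_randomization", "circular_shift"):
        for b in range(n_null):
            if method == "phase_randomization":
                surr = np.stack([phase_randomize(x[s], rng) for s in range(n)])
            else:
                shifts = rng.integers(0, t, size=n)
                surr = np.stack([np.roll(x[s], shifts[s], axis=0) for s in range(n)])
            values, _ = _isc_from_stack(surr, result.method)
            null[b] = _summary_stat(values)
    elif method in ("subject_bootstrap", "sign_permutation"):
        if result.method != "loo":
            raise ValidationError(f"{method} requires a leave-one-out ISCResult")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.arctanh(result.values)  # (N, V)
        if method == "subject_bootstrap":
            # bootstrap distribution re-centred at zero (shift method)
            zbar = np.nanmean(z, axis=0)
            for b in range(n_null):
                idx = rng.integers(0, n, size=n)
                null[b] = np.tanh(np.nanmean(z[idx], axis=0) - zbar)
        else:
            for b in range(n_null):
                signs = rng.choice([-1.0, 1.0], size=n)
                null[b] = np.tanh(np.nanmean(signs[:, None] * z, axis=0))
    else:
        raise ValidationError(f"unknown test method {method!r}")

    p_hi = (1 + (null >= observed[None, :]).sum(axis=0)) / (1 + n_null)
    p_lo = (1 + (null <= observed[None, :]).sum(axis=0)) / (1 + n_null)
    if tail == "greater":
        p = p_hi
    elif tail == "less":
        p = p_lo
    elif tail == "two_sided":
        p = np.minimum(1.0, 2 * np.minimum(p_hi, p_lo))
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    q = stats.false_discovery_control(p)
    return NullTestResult(observed, null, p, np.maximum(q, p), method, seed, n_null)


def make_shared_signal_dataset(
    n_subjects: int = 5,
    t: int = 2000,
    v: int = 1,
    noise_sd: float = 1.0,
    seed: int = 0,
    tr_seconds: float = 1.0,
) -> MultiSubjectDataset:
    """Shared-signal-plus-noise benchmark: x_i = s + noise_sd * n_i with s
    and n_i iid standard normal per unit.

    Closed forms for large T: pairwise ISC -> 1 / (1 + noise_sd^2) and
    leave-one-out ISC -> 1 / sqrt((1 + noise_sd^2)(1 + noise_sd^2/(N-1))).
    """
    from .core import SubjectTimeSeries

    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((t, v))
    subs = [
        SubjectTimeSeries(
            shared + noise_sd * rng.standard_normal((t, v)),
            tr_seconds,
            f"sub-{i:02d}",
        )
        for i in range(n_subjects)
    ]
    return MultiSubjectDataset(subs, "units_aligned")
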