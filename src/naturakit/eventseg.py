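"""Event segmentation with a left-to-right hidden Markov model.

A brain region responding to a continuous narrative is modelled as passing
through a fixed sequence of K discrete event states.  Three structural
assumptions define the chain: (1) at every TR the region either stays in
its current event or advances to the next; (2) it starts in the first event
and ends in the last; (3) each event k has a characteristic spatial pattern
m_k, and the observed pattern at a TR is that event's pattern plus isotropic
Gaussian noise.  Fitting alternates a constrained forward-backward pass
(E-step) with re-estimation of the event patterns and the shared emission
variance (M-step); both steps are exact, so the log-likelihood trace is
non-decreasing.

Numerics: the forward-backward recursions run in log space with
``logsumexp``; the start/end constraints enter as -inf log-prior mass on
disallowed states.  The stay probability defaults to 1 - K/T so that the
expected number of advances over the scan is about K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import SubjectTimeSeries, ValidationError

__all__ = [
    "EventSegModel",
    "BoundarySet",
    "eventseg_fit",
    "eventseg_apply",
    "eventseg_fit_shared",
    "boundaries",
    "boundary_match_test",
    "make_event_dataset",
]

NEG_INF = -np.inf


@dataclass
class EventSegModel:
    """Fitted left-to-right event model.

    ``event_patterns`` rows are z-scored across units for reporting;
    ``segments[t, k]`` is the posterior probability that TR t lies in
    event k.
    """

    K: int
    event_patterns: np.ndarray  # K x V
    segments: np.ndarray  # T x K
    sigma2: float
    loglik_trace: list[float]
    advance_prob: float


@dataclass
class BoundarySet:
    boundaries: list[int]
    K: int
    n_timepoints: int


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _emission_loglik(x: np.ndarray, patterns: np.ndarray, sigma2: float) -> np.ndarray:
    """(T, K) log N(x_t; m_k, sigma2 I) including the normalization constant
    (needed for a meaningful likelihood trace when sigma2 changes)."""
    v = x.shape[1]
    d2 = (
        (x**2).sum(axis=1)[:, None]
        - 2 * x @ patterns.T
        + (patterns**2).sum(axis=1)[None, :]
    )
    return -0.5 * d2 / sigma2 - 0.5 * v * np.log(2 * np.pi * sigma2)


def _forward_backward(
    log_b: np.ndarray, advance_prob: float
) -> tuple[np.ndarray, float]:
    """Posterior over events for a left-to-right chain conditioned on
    starting in event 0 and ending in event K-1.

    Returns (T x K posterior, total log-likelihood).
    """
    t, k = log_b.shape
    if not 0 < advance_prob < 1:
        if k == 1:
            return np.ones((t, 1)), float(log_b.sum())
        raise ValidationError(f"advance_prob must lie in (0, 1), got {advance_prob}")
    log_stay = np.log1p(-advance_prob)
    log_adv = np.log(advance_prob)

    log_alpha = np.full((t, k), NEG_INF)
    log_alpha[0, 0] = log_b[0, 0]
    for i in range(1, t):
        stay = log_alpha[i - 1] + log_stay
        adv = np.full(k, NEG_INF)
        adv[1:] = log_alpha[i - 1, :-1] + log_adv
        log_alpha[i] = log_b[i] + np.logaddexp(stay, adv)

    log_beta = np.full((t, k), NEG_INF)
    log_beta[t - 1, k - 1] = 0.0  # end-state constraint
    for i in range(t - 2, -1, -1):
        stay = log_stay + log_b[i + 1] + log_beta[i + 1]
        adv = np.full(k, NEG_INF)
        adv[:-1] = log_adv + log_b[i + 1, 1:] + log_beta[i + 1, 1:]
        log_beta[i] = np.logaddexp(stay, adv)

    loglik = float(log_alpha[t - 1, k - 1])
    if not np.isfinite(loglik):
        raise ValidationError(
            "zero-probability configuration (is K <= T and advance_prob sane?)"
        )
    log_gamma = log_alpha + log_beta
    log_gamma -= logsumexp(log_gamma, axis=1, keepdims=True)
    return np.exp(log_gamma), loglik


def _dp_segmentation(x: np.ndarray, k: int, max_exact_t: int = 1500) -> np.ndarray:
    """Optimal contiguous K-segmentation of (T, V) data by within-segment
    squared error, via dynamic programming; O(K T^2) time.

    For very long series the DP runs on a uniformly strided subsampling to
    bound memory, which is ample for an EM starting point.
    """
    t_orig = x.shape[0]
    stride = 1
    if t_orig > max_exact_t:
        stride = int(np.ceil(t_orig / max_exact_t))
        x = x[::stride]
    t = x.shape[0]
    if k >= t:
        return np.minimum((np.arange(t_orig) * k) // t_orig, k - 1)
    s1 = np.vstack([np.zeros(x.shape[1]), np.cumsum(x, axis=0)])  # (T+1, V)
    s2 = np.concatenate([[0.0], np.cumsum((x**2).sum(axis=1))])
    # cost[i, j] of segment [i, j), j > i
    lengths = np.arange(t + 1)[None, :] - np.arange(t + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = ((s1[None, :, :] - s1[:, None, :]) ** 2).sum(axis=2)
        cost = (s2[None, :] - s2[:, None]) - sq / lengths
    cost[lengths <= 0] = np.inf

    best = np.full((k, t + 1), np.inf)
    arg = np.zeros((k, t + 1), dtype=int)
    best[0] = cost[0]
    for seg in range(1, k):
        # candidate start i for a segment ending at j
        totals = best[seg - 1][:, None] + cost  # (i, j)
        arg[seg] = np.argmin(totals, axis=0)
        best[seg] = totals[arg[seg], np.arange(t + 1)]
    # backtrack
    bounds = []
    j = t
    for seg in range(k - 1, 0, -1):
        j = int(arg[seg, j])
        bounds.append(j)
    bounds = np.array(bounds[::-1])
    idx = np.searchsorted(bounds, np.arange(t), side="right")
    if stride > 1:
        idx = np.repeat(idx, stride)[:t_orig]
    return idx


def _prep(ts: SubjectTimeSeries) -> np.ndarray:
    # z-score each TR's pattern across units (assumption 3 concerns pattern
    # shape, not global amplitude)
    return _zscore_rows(ts.data)


def eventseg_fit(
    ts: SubjectTimeSeries,
    K: int,
    n_iter: int = 50,
    tol: float = 1e-6,
) -> EventSegModel:
    """Fit K event patterns and per-TR posteriors by EM-style alternation.

    Stops after ``n_iter`` iterations or when the log-likelihood improves by
    less than ``tol``.
    """
    t = ts.n_timepoints
    if K < 1:
        raise ValidationError("K must be >= 1")
    if K > t:
        raise ValidationError(f"K={K} exceeds T={t}")
    x = _prep(ts)
    v = x.shape[1]
    advance = K / t if K < t else 1.0 - 1.0 / (t + 1)
    if K == 1:
        patterns = x.mean(axis=0, keepdims=True)
        sigma2 = float(((x - patterns) ** 2).mean()) or 1.0
        ll = float(_emission_loglik(x, patterns, sigma2).sum())
        return EventSegModel(1, _zscore_rows(patterns), np.ones((t, 1)), sigma2, [ll], advance)

    # init: optimal least-squares K-segmentation (exact DP; the zero-noise
    # MAP of this chain), which keeps EM out of split/merge local optima
    idx = _dp_segmentation(x, K)
    patterns = np.stack([x[idx == k].mean(axis=0) for k in range(K)])
    sigma2 = float(((x - patterns[idx]) ** 2).mean()) or 1.0

    def em_step(patterns, sigma2, floor):
        log_b = _emission_loglik(x, patterns, max(sigma2, floor))
        gamma, ll = _forward_backward(log_b, advance)
        weights = gamma / gamma.sum(axis=0, keepdims=True)  # T x K
        new_patterns = weights.T @ x
        resid2 = (
            (x**2).sum(axis=1) @ gamma
            - 2 * np.einsum("tk,kt->k", gamma, new_patterns @ x.T)
            + gamma.sum(axis=0) * (new_patterns**2).sum(axis=1)
        ).sum()
        return new_patterns, max(float(resid2) / (t * v), 1e-12), gamma, ll

    for floor in 1.0 * 0.75 ** np.arange(15):  # warm start (not in the trace)
        patterns, sigma2, _, _ = em_step(patterns, sigma2, floor)

    trace: list[float] = []
    gamma = None
    for _ in range(n_iter):
        patterns, sigma2, gamma, ll = em_step(patterns, sigma2, 0.0)
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
    return EventSegModel(K, _zscore_rows(patterns), gamma, sigma2, trace, advance)


def eventseg_apply(
    patterns: np.ndarray,
    ts: SubjectTimeSeries,
    advance_prob: float | None = None,
    sigma2: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Infer event posteriors for new data under fixed event patterns.

    One constrained forward-backward pass; no re-estimation. Returns
    (T x K posterior, total log-likelihood).
    """
    patterns = np.asarray(patterns, float)
    if patterns.ndim != 2 or patterns.shape[1] != ts.n_units:
        raise ValidationError(
            f"patterns must be (K, V={ts.n_units}), got {patterns.shape}"
        )
    k, t = patterns.shape[0], ts.n_timepoints
    if advance_prob is None:
        advance_prob = k / t if k < t else 1.0 - 1.0 / (t + 1)
    x = _prep(ts)
    log_b = _emission_loglik(x, _zscore_rows(patterns), sigma2)
    return _forward_backward(log_b, advance_prob)


def eventseg_fit_shared(
    datasets: list[SubjectTimeSeries],
    K: int,
    n_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Fit one set of event patterns shared by several datasets.

    The datasets (e.g. different tellings of the same story, or perception
    vs recall) must share V but may differ in T; each gets its own
    T-dependent advance probability in the E-step, while the M-step pools
    posterior-weighted pattern sums across datasets. Returns the shared
    (K, V) z-scored patterns and the per-dataset posteriors.
    """
    if len(datasets) < 2:
        raise ValidationError("need >= 2 datasets")
    v0 = datasets[0].n_units
    if any(d.n_units != v0 for d in datasets):
        raise ValidationError("all datasets must share V")
    if any(K > d.n_timepoints for d in datasets):
        raise ValidationError("K exceeds the T of some dataset")
    xs = [_prep(d) for d in datasets]
    advances = [
        K / x.shape[0] if K < x.shape[0] else 1.0 - 1.0 / (x.shape[0] + 1) for x in xs
    ]
    # init: least-squares DP segmentation of each dataset, patterns pooled
    inits = [_dp_segmentation(x, K) for x in xs]
    patterns = np.mean(
        [np.stack([x[idx == k].mean(axis=0) for k in range(K)])
         for x, idx in zip(xs, inits)],
        axis=0,
    )
    sigma2 = float(
        np.mean([((x - patterns[idx]) ** 2).mean() for x, idx in zip(xs, inits)])
    ) or 1.0
    gammas: list[np.ndarray] = []
    prev_ll = None
    for _ in range(n_iter):
        gammas, lls = [], []
        for x, adv in zip(xs, advances):
            g, ll = _forward_backward(_emission_loglik(x, patterns, sigma2), adv)
            gammas.append(g)
            lls.append(ll)
        num = sum(g.T @ x for g, x in zip(gammas, xs))
        den = sum(g.sum(axis=0) for g in gammas)
        patterns = num / den[:, None]
        resid2 = sum(
            float(
                (x**2).sum(axis=1) @ g.sum(axis=1)
                - 2 * np.einsum("tk,kt->", g, patterns @ x.T)
                + g.sum(axis=0) @ (patterns**2).sum(axis=1)
            )
            for g, x in zip(gammas, xs)
        )
        n_obs = sum(x.size for x in xs)
        sigma2 = max(resid2 / n_obs, 1e-12)
        total = float(sum(lls))
        if prev_ll is not None and total - prev_ll < tol:
            break
        prev_ll = total
    return _zscore_rows(patterns), gammas


def boundaries(model_or_segments: EventSegModel | np.ndarray) -> BoundarySet:
    """Extract event boundaries: TRs where the MAP event index increments.

    Ties in the per-TR argmax break toward the lower event index.
    """
    if isinstance(model_or_segments, EventSegModel):
        seg = model_or_segments.segments
        k = model_or_segments.K
    else:
        seg = np.asarray(model_or_segments, float)
        k = seg.shape[1]
    map_idx = seg.argmax(axis=1)  # earliest (lowest event) tie-break
    bounds = [int(t) for t in range(1, len(map_idx)) if map_idx[t] > map_idx[t - 1]]
    return BoundarySet(bounds, k, seg.shape[0])


def boundary_match_test(
    model_bounds: BoundarySet,
    annotations: list[int],
    window_tr: int,
    n_null: int = 1000,
    seed: int = 0,
):
    """Permutation test of boundary agreement with annotations.

    Statistic: number of annotated boundaries with a model boundary within
    +-window_tr. Null: the same number of model boundaries placed uniformly
    at random (without replacement) among TRs 1..T-1. Add-one p-value.
    """
    from .isc import NullTestResult  # local import to avoid a cycle

    if window_tr < 0:
        raise ValidationError("window_tr must be >= 0")
    t = model_bounds.n_timepoints
    ann = np.asarray(sorted(annotations), int)
    if len(ann) and (ann.min() < 1 or ann.max() > t - 1):
        raise ValidationError("annotations must lie within [1, T-1]")

    def stat(bounds: np.ndarray) -> int:
        if len(bounds) == 0 or len(ann) == 0:
            return 0
        hits = np.abs(ann[:, None] - bounds[None, :]).min(axis=1) <= window_tr
        return int(hits.sum())

    obs_bounds = np.asarray(model_bounds.boundaries, int)
    observed = stat(obs_bounds)
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            stat(rng.choice(np.arange(1, t), size=len(obs_bounds), replace=False))
            for _ in range(n_null)
        ],
        dtype=float,
    )
    p = (1 + (null >= observed).sum()) / (1 + n_null)
    return NullTestResult(
        observed=np.array([float(observed)]),
        null_samples=null[:, None],
        p_values=np.array([p]),
        q_values=np.array([p]),
        method="boundary_permutation",
        seed=seed,
        n_null=n_null,
    )


def make_event_dataset(
    n_events: int = 10,
    t: int = 200,
    v: int = 30,
    noise_sd: float = 0.1,
    seed: int = 0,
    tr_seconds: float = 1.0,
) -> tuple[SubjectTimeSeries, np.ndarray, list[int]]:
    """Planted-event time series with known patterns and boundaries.

    Event mean patterns are iid N(0, 1) across units; event dwell times are
    drawn uniformly between 0.5 and 1.5 times the average length T/K and
    rescaled to sum to T; iid Gaussian noise of sd ``noise_sd`` is added per
    TR. Returns (data, true K x V patterns, true boundary TRs).
    """
    rng = np.random.default_rng(seed)
    if t < 2 * n_events:
        raise ValidationError("T too small for the requested events")
    u = rng.uniform(0.5, 1.5, size=n_events)
    lengths = np.maximum(1, np.floor(u / u.sum() * t).astype(int))
    # hand out the rounding remainder one TR at a time, longest first
    while lengths.sum() < t:
        lengths[np.argmax(u / lengths)] += 1
    assert lengths.sum() == t and (lengths >= 1).all()
    patterns = rng.standard_normal((n_events, v))
    idx = np.repeat(np.arange(n_events), lengths)
    data = patterns[idx] + noise_sd * rng.standard_normal((t, v))
    bounds = list(np.cumsum(lengths)[:-1].astype(int))
    return SubjectTimeSeries(data, tr_seconds, "planted"), patterns, bounds
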