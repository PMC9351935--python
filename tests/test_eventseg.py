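import itertools

import numpy as np
import pytest

from naturakit.core import SubjectTimeSeries, ValidationError
from naturakit.eventseg import (
    BoundarySet,
    _forward_backward,
    boundaries,
    boundary_match_test,
    eventseg_apply,
    eventseg_fit,
    eventseg_fit_shared,
    make_event_dataset,
)


def brute_force_posterior(log_b, advance):
    """Sum over every monotone start-to-end event path explicitly."""
    t, k = log_b.shape
    totals = np.zeros((t, k))
    z = 0.0
    for bounds in itertools.combinations(range(1, t), k - 1):
        idx = np.searchsorted(np.array(bounds), np.arange(t), side="right")
        logw = log_b[np.arange(t), idx].sum()
        logw += (k - 1) * np.log(advance) + (t - k) * np.log1p(-advance)
        w = np.exp(logw)
        z += w
        for tt in range(t):
            totals[tt, idx[tt]] += w
    return totals / z, np.log(z)


class TestForwardBackward:
    @pytest.mark.parametrize("trial", range(12))
    def test_matches_path_enumeration_oracle(self, trial):
        rng = np.random.default_rng(trial)
        t = int(rng.integers(3, 13))
        k = int(rng.integers(1, min(5, t) + 1))
        log_b = rng.normal(0, 2, size=(t, k))
        adv = float(rng.uniform(0.05, 0.9))
        post, ll = _forward_backward(log_b, adv)
        oracle, ll_oracle = brute_force_posterior(log_b, adv)
        np.testing.assert_allclose(post, oracle, atol=1e-10)
        assert ll == pytest.approx(ll_oracle, abs=1e-8)

    def test_rows_sum_to_one(self, rng):
        post, _ = _forward_backward(rng.normal(size=(40, 6)), 0.15)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_start_and_end_constraints(self, rng):
        post, _ = _forward_backward(rng.normal(size=(30, 4)), 0.2)
        assert post[0].argmax() == 0
        assert post[-1].argmax() == 3

    def test_expected_event_index_monotone(self, rng):
        post, _ = _forward_backward(rng.normal(size=(50, 5)), 0.1)
        expected = post @ np.arange(5)
        assert np.all(np.diff(expected) >= -1e-9)


class TestFit:
    def test_single_event_degenerate(self, rng):
        ts = SubjectTimeSeries(rng.standard_normal((30, 6)), 1.0)
        model = eventseg_fit(ts, K=1)
        np.testing.assert_array_equal(model.segments, np.ones((30, 1)))
        assert boundaries(model).boundaries == []

    def test_k_validation(self, rng):
        ts = SubjectTimeSeries(rng.standard_normal((10, 4)), 1.0)
        with pytest.raises(ValidationError):
            eventseg_fit(ts, K=0)
        with pytest.raises(ValidationError):
            eventseg_fit(ts, K=11)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_boundary_recovery(self, seed):
        ts, _, true_bounds = make_event_dataset(10, 200, 30, noise_sd=0.1, seed=seed)
        model = eventseg_fit(ts, K=10)
        got = boundaries(model).boundaries
        assert len(got) == 9
        assert max(abs(a - b) for a, b in zip(got, true_bounds)) <= 1

    def test_loglik_trace_ascends(self):
        ts, *_ = make_event_dataset(6, 120, 15, noise_sd=0.5, seed=3)
        model = eventseg_fit(ts, K=6)
        assert np.all(np.diff(model.loglik_trace) >= -1e-6)

    def test_duplicate_units_leave_map_unchanged(self):
        ts, *_ = make_event_dataset(5, 100, 12, noise_sd=0.2, seed=4)
        doubled = SubjectTimeSeries(np.hstack([ts.data, ts.data]), 1.0)
        m1 = eventseg_fit(ts, K=5)
        m2 = eventseg_fit(doubled, K=5)
        np.testing.assert_array_equal(
            m1.segments.argmax(axis=1), m2.segments.argmax(axis=1)
        )

    def test_cross_validated_k_selection(self):
        """Held-out log-likelihood, as a function of K, peaks at the true K
        (mode over seeded replicates)."""
        winners = []
        for seed in range(20):
            train, patterns, _ = make_event_dataset(8, 120, 20, 0.3, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            test = SubjectTimeSeries(
                train.data + 0.3 * rng.standard_normal(train.data.shape), 1.0
            )
            lls = {}
            for k in (4, 6, 8, 10, 12):
                model = eventseg_fit(train, K=k)
                # score under fixed patterns on the noisy replicate
                _, ll = eventseg_apply(
                    model.event_patterns, test, sigma2=model.sigma2
                )
                lls[k] = ll
            winners.append(max(lls, key=lls.get))
        values, counts = np.unique(winners, return_counts=True)
        assert values[counts.argmax()] == 8


class TestApply:
    def test_noise_free_blocks_recovered_exactly(self, rng):
        patterns = rng.standard_normal((3, 10))
        data = np.repeat(patterns, [8, 6, 6], axis=0)
        ts = SubjectTimeSeries(data, 1.0)
        post, _ = eventseg_apply(patterns, ts)
        np.testing.assert_array_equal(
            post.argmax(axis=1), np.repeat([0, 1, 2], [8, 6, 6])
        )
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_reversed_sequence_is_less_likely(self, rng):
        patterns = rng.standard_normal((3, 12))
        fwd = SubjectTimeSeries(np.repeat(patterns, 5, axis=0), 1.0)
        rev = SubjectTimeSeries(np.repeat(patterns[::-1], 5, axis=0), 1.0)
        _, ll_fwd = eventseg_apply(patterns, fwd)
        _, ll_rev = eventseg_apply(patterns, rev)
        assert ll_fwd > ll_rev

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValidationError):
            eventseg_apply(
                rng.standard_normal((3, 5)),
                SubjectTimeSeries(rng.standard_normal((20, 6)), 1.0),
            )


class TestFitShared:
    def test_common_patterns_different_dwell_times(self):
        rng = np.random.default_rng(3)
        patterns = rng.standard_normal((4, 20))
        d1 = SubjectTimeSeries(np.repeat(patterns, [10, 12, 8, 10], axis=0), 1.0)
        d2 = SubjectTimeSeries(np.repeat(patterns, [5, 6, 4, 5], axis=0), 1.0)
        shared, gammas = eventseg_fit_shared([d1, d2], K=4)
        from naturakit.eventseg import _zscore_rows

        truth = _zscore_rows(patterns)
        for k in range(4):
            assert np.corrcoef(shared[k], truth[k])[0, 1] > 0.999
        assert boundaries(gammas[0]).boundaries == [10, 22, 30]
        assert boundaries(gammas[1]).boundaries == [5, 11, 15]

    def test_duplicated_dataset_matches_single_fit(self):
        ts, *_ = make_event_dataset(5, 80, 20, 0.1, seed=9)
        shared, _ = eventseg_fit_shared([ts, ts], K=5)
        single = eventseg_fit(ts, K=5)
        np.testing.assert_allclose(shared, single.event_patterns, atol=1e-8)

    def test_compressed_recall_keeps_boundary_fractions(self):
        ts, *_ = make_event_dataset(5, 80, 20, 0.1, seed=9)
        halved = SubjectTimeSeries(ts.data[::2], 1.0)
        _, gammas = eventseg_fit_shared([ts, halved], K=5)
        f1 = [b / 80 for b in boundaries(gammas[0]).boundaries]
        f2 = [b / 40 for b in boundaries(gammas[1]).boundaries]
        assert max(abs(a - b) for a, b in zip(f1, f2)) < 0.05

    def test_unit_mismatch_rejected(self, rng):
        a = SubjectTimeSeries(rng.standard_normal((20, 5)), 1.0)
        b = SubjectTimeSeries(rng.standard_normal((20, 6)), 1.0)
        with pytest.raises(ValidationError):
            eventseg_fit_shared([a, b], K=3)


class TestBoundaries:
    def test_hard_blocks(self):
        seg = np.zeros((30, 3))
        seg[:10, 0] = seg[10:20, 1] = seg[20:, 2] = 1.0
        assert boundaries(seg).boundaries == [10, 20]


class TestBoundaryMatch:
    def test_perfect_match_statistic(self):
        bs = BoundarySet([10, 20, 30], K=4, n_timepoints=50)
        res = boundary_match_test(bs, [10, 20, 30], window_tr=0, n_null=99, seed=0)
        assert res.observed[0] == 3

    def test_add_one_rule(self):
        bs = BoundarySet([10, 20, 30], K=4, n_timepoints=300)
        res = boundary_match_test(bs, [10, 20, 30], window_tr=0, n_null=999, seed=1)
        assert res.p_values[0] == pytest.approx(1 / 1000)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        t, n_b = 300, 8
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            model_b = sorted(rng.choice(np.arange(1, t), n_b, replace=False))
            ann = sorted(rng.choice(np.arange(1, t), n_b, replace=False))
            bs = BoundarySet([int(b) for b in model_b], K=n_b + 1, n_timepoints=t)
            res = boundary_match_test(
                bs, [int(a) for a in ann], window_tr=3, n_null=99,
                seed=int(rng.integers(2**31)),
            )
            rejections += int(res.p_values[0] <= 0.05)
        rate = rejections / n_sim
        half = 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_negative_window_rejected(self):
        bs = BoundarySet([5], K=2, n_timepoints=20)
        with pytest.raises(ValidationError):
            boundary_match_test(bs, [5], window_tr=-1)
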