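"""Binarization, the Bernoulli-emission HMM, decoding and methylation
association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylandscape import (ChromatinStateModel, MarkBinaryMatrix, binarize,
                            decode, fit_hmm, log_likelihood,
                            state_composition, state_methylation)
from methylandscape.chromatin import binarize_tracks, posterior_probabilities
from methylandscape.errors import ConfigError, QCError


def _matrix(X, marks=None, chroms=None, window=200):
    X = np.asarray(X)
    marks = marks or [f"m{i}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=marks)
    frame.insert(0, "chrom", chroms if chroms is not None else "c")
    frame.insert(1, "start", np.arange(len(X)) * window)
    return MarkBinaryMatrix(frame=frame, marks=marks, window=window)


def _sample_hmm(rng, emission, transition, initial, T):
    S = len(initial)
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(S, p=initial)
    for t in range(1, T):
        states[t] = rng.choice(S, p=transition[states[t - 1]])
    X = (rng.random((T, emission.shape[1])) < emission[states]).astype(np.int8)
    return states, X


class TestBinarize:
    def test_zero_count_never_called(self):
        calls = binarize(np.array([0, 0, 50]), background=5.0)
        assert calls[0] == 0 and calls[1] == 0 and calls[2] == 1

    def test_threshold_matches_tail_summation_oracle(self):
        lam, p_thr = 5.0, 1e-4
        # brute-force smallest k with P(X >= k) < 1e-4 by direct summation
        k = 0
        from math import exp, factorial
        while 1.0 - sum(exp(-lam) * lam**j / factorial(j)
                        for j in range(k)) >= p_thr:
            k += 1
        counts = np.arange(0, 40)
        calls = binarize(counts, background=lam, p_threshold=p_thr)
        assert list(np.flatnonzero(calls)) == list(range(k, 40))

    def test_all_equal_counts_uniform_call(self):
        for c in (0, 3):
            calls = binarize(np.full(100, c), background=3.0)
            assert len(set(calls.tolist())) == 1

    def test_zero_coverage_is_qc_error(self):
        with pytest.raises(QCError):
            binarize(np.zeros(10))


class TestForwardLikelihood:
    def _enumeration_loglik(self, X, emission, transition, initial):
        """Brute-force sum over all state paths."""
        T, S = len(X), len(initial)
        total = 0.0
        for path in itertools.product(range(S), repeat=T):
            p = initial[path[0]]
            for t in range(1, T):
                p *= transition[path[t - 1], path[t]]
            for t, s in enumerate(path):
                e = emission[s]
                p *= np.prod(np.where(X[t] == 1, e, 1 - e))
            total += p
        return np.log(total)

    @pytest.mark.parametrize("T,S,M,seed", [(1, 2, 2, 0), (4, 2, 3, 1),
                                            (8, 2, 2, 2), (6, 3, 2, 3)])
    def test_forward_equals_exhaustive_path_sum(self, T, S, M, seed):
        rng = np.random.default_rng(seed)
        emission = rng.uniform(0.1, 0.9, size=(S, M))
        transition = rng.dirichlet(np.ones(S), size=S)
        initial = rng.dirichlet(np.ones(S))
        X = rng.integers(0, 2, size=(T, M))
        model = ChromatinStateModel(emission=emission, transition=transition,
                                    initial=initial,
                                    marks=[f"m{i}" for i in range(M)])
        got = log_likelihood(model, _matrix(X))
        expected = self._enumeration_loglik(X, emission, transition, initial)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_likelihood_sums_over_contigs(self):
        rng = np.random.default_rng(4)
        emission = rng.uniform(0.2, 0.8, size=(2, 2))
        transition = rng.dirichlet(np.ones(2), size=2)
        initial = np.array([0.5, 0.5])
        model = ChromatinStateModel(emission=emission, transition=transition,
                                    initial=initial, marks=["m0", "m1"])
        Xa, Xb = rng.integers(0, 2, (3, 2)), rng.integers(0, 2, (4, 2))
        joint = _matrix(np.vstack([Xa, Xb]), chroms=["a"] * 3 + ["b"] * 4)
        assert log_likelihood(model, joint) == pytest.approx(
            log_likelihood(model, _matrix(Xa)) + log_likelihood(model, _matrix(Xb)),
            abs=1e-12)


class TestFitHmm:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(500, 3))
        model = fit_hmm(_matrix(X), n_states=1, seed=0)
        np.testing.assert_allclose(model.emission[0], X.mean(axis=0), atol=1e-9)
        assert model.transition[0, 0] == pytest.approx(1.0)
        assert model.initial[0] == pytest.approx(1.0)

    def test_loglikelihood_trace_monotone(self):
        rng = np.random.default_rng(1)
        _, X = _sample_hmm(rng, np.array([[0.9, 0.1], [0.1, 0.9]]),
                           np.array([[0.9, 0.1], [0.1, 0.9]]),
                           np.array([0.5, 0.5]), 2000)
        model = fit_hmm(_matrix(X), n_states=2, seed=3)
        trace = np.array(model.log_likelihood_trace)
        assert len(trace) >= 2
        assert (np.diff(trace) >= -1e-6 * (1 + np.abs(trace[:-1]))).all()

    def test_decode_recovers_generating_labels(self):
        rng = np.random.default_rng(2)
        emission = np.array([[0.98, 0.02], [0.02, 0.98]])
        transition = np.array([[0.95, 0.05], [0.05, 0.95]])
        states, X = _sample_hmm(rng, emission, transition,
                                np.array([0.5, 0.5]), 5000)
        matrix = _matrix(X)
        model = fit_hmm(matrix, n_states=2, seed=0)
        track = decode(model, matrix)
        decoded = track.frame["state"].to_numpy() - 1
        acc = max((decoded == states).mean(), (decoded != states).mean())
        assert acc >= 0.95

    def test_fit_invariant_to_contig_order(self):
        rng = np.random.default_rng(6)
        Xa = rng.integers(0, 2, size=(300, 2))
        Xb = rng.integers(0, 2, size=(200, 2))
        ab = _matrix(np.vstack([Xa, Xb]), chroms=["a"] * 300 + ["b"] * 200)
        ba = _matrix(np.vstack([Xb, Xa]), chroms=["b"] * 200 + ["a"] * 300)
        ma = fit_hmm(ab, n_states=2, seed=4, max_iter=20)
        mb = fit_hmm(ba, n_states=2, seed=4, max_iter=20)
        np.testing.assert_allclose(ma.emission, mb.emission, atol=1e-8)
        np.testing.assert_allclose(ma.transition, mb.transition, atol=1e-8)

    def test_degenerate_configs_rejected(self):
        X = np.zeros((5, 2), dtype=int)
        with pytest.raises(ConfigError):
            fit_hmm(_matrix(X), n_states=10)
        with pytest.raises(ConfigError):
            fit_hmm(_matrix(X), n_states=0)


class TestDecode:
    def test_single_state_occupancy_one(self):
        model = ChromatinStateModel(
            emission=np.array([[0.5, 0.5]]), transition=np.array([[1.0]]),
            initial=np.array([1.0]), marks=["m0", "m1"])
        track = decode(model, _matrix(np.ones((10, 2), dtype=int)))
        assert (track.frame["state"] == 1).all()
        assert track.occupancy.tolist() == [1.0]

    def test_posteriors_sum_to_one_and_occupancy_normalizes(self):
        rng = np.random.default_rng(8)
        emission = rng.uniform(0.2, 0.8, (3, 2))
        transition = rng.dirichlet(np.ones(3), 3)
        model = ChromatinStateModel(emission=emission, transition=transition,
                                    initial=np.full(3, 1 / 3), marks=["m0", "m1"])
        matrix = _matrix(rng.integers(0, 2, (50, 2)))
        gamma = posterior_probabilities(model, matrix)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        assert decode(model, matrix).occupancy.sum() == pytest.approx(1.0)

    def test_mark_mismatch_rejected(self):
        model = ChromatinStateModel(
            emission=np.array([[0.5]]), transition=np.array([[1.0]]),
            initial=np.array([1.0]), marks=["H3K4me3"])
        with pytest.raises(ValueError, match="mark sets differ"):
            decode(model, _matrix(np.ones((3, 1), dtype=int), marks=["H3K9me2"]))


class TestBinarizeTracks:
    def test_wide_track_binarization_and_exclusion(self):
        rng = np.random.default_rng(10)
        frame = pd.DataFrame({
            "chrom": ["c"] * 50 + ["spike"] * 10,
            "start": list(range(0, 10_000, 200)) + list(range(0, 2000, 200)),
        })
        frame["end"] = frame["start"] + 200
        frame["m"] = rng.poisson(5.0, size=60)
        matrix = binarize_tracks(frame, exclude_contigs=["spike"])
        assert matrix.marks == ["m"]
        assert matrix.n_windows == 50
        assert matrix.window == 200


class TestMethylationAssociation:
    def _track(self, states, window=100):
        frame = pd.DataFrame({"chrom": "c",
                              "start": np.arange(len(states)) * window,
                              "state": states})
        from methylandscape.chromatin import StateTrack
        return StateTrack(frame=frame, window=window, n_states=max(states))

    def test_sites_split_between_states(self):
        track = self._track([1, 2])
        sites = pd.DataFrame({"chrom": "c", "pos": [10, 50, 150, 160],
                              "level": [0.0, 0.0, 1.0, 1.0]})
        tbl = state_methylation(track, sites)
        assert tbl.loc[1, "median"] == 0.0 and tbl.loc[2, "median"] == 1.0
        assert tbl["n"].tolist() == [2, 2]

    def test_state_without_sites_reported_empty(self):
        track = self._track([1, 2])
        sites = pd.DataFrame({"chrom": "c", "pos": [10], "level": [0.5]})
        tbl = state_methylation(track, sites)
        assert tbl.loc[2, "n"] == 0 and np.isnan(tbl.loc[2, "median"])

    def test_composition_single_state_indicator(self):
        track = self._track([3, 3, 3], window=100)
        comp = state_composition(track, {"s": {("c", 0)}}, bin_size=300)
        np.testing.assert_allclose(comp.loc["s"], [0, 0, 1.0])

    def test_composition_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        track = self._track(list(rng.integers(1, 5, size=60)), window=100)
        strata = {"a": {("c", 0), ("c", 1000)}, "b": {("c", 2000)}, "empty": set()}
        comp = state_composition(track, strata, bin_size=1000)
        assert comp.loc["a"].sum() == pytest.approx(1.0)
        assert comp.loc["b"].sum() == pytest.approx(1.0)
        assert comp.loc["empty"].isna().all()

    def test_incompatible_bin_and_window_rejected(self):
        track = self._track([1], window=300)
        with pytest.raises(ConfigError):
            state_composition(track, {"s": set()}, bin_size=1000)
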