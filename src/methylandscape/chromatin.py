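"""Chromatin-state segmentation from binarized histone-mark tracks.

A multivariate-Bernoulli hidden Markov model in the ChromHMM mold: each
genomic window carries a presence/absence call per histone mark; a hidden
state emits marks independently with per-state Bernoulli parameters
(the "emission profile"), and states follow a first-order Markov chain
along the genome with per-contig sequence resets.  Parameters are learned
by Baum-Welch EM with the scaled forward-backward recursions; decoding is
by posterior (forward-backward) argmax.

Binarization follows the standard Poisson-background rule: a window is
called present for a mark when the upper-tail probability of its read
count under a genome-wide background mean falls below a threshold
(default 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, NumericalError, QCError

EMISSION_FLOOR = 1e-6
TRANSITION_PSEUDOCOUNT = 1e-6


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

def binarize(counts, background: float | None = None,
             p_threshold: float = 1e-4) -> np.ndarray:
    """Poisson upper-tail presence calls for one mark's window counts.

    A window is 1 iff P(X >= count | lambda=background) < p_threshold.
    The background defaults to the genome-wide mean count.  A count of 0
    has tail probability 1 and is always 0.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("negative window counts")
    if background is None:
        background = float(counts.mean())
    if background <= 0:
        raise QCError("zero genome-wide coverage for mark; cannot binarize")
    tail = stats.poisson.sf(counts - 1, background)  # P(X >= count)
    return (tail < p_threshold).astype(np.int8)


@dataclass
class MarkBinaryMatrix:
    """Windows x marks presence/absence calls, contiguous per contig."""

    frame: pd.DataFrame  # chrom, start + one 0/1 column per mark
    marks: list[str]
    window: int

    def sequences(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (contig, T x M binary array) per contig, in frame order."""
        for chrom, g in self.frame.groupby("chrom", sort=False):
            yield chrom, g[self.marks].to_numpy(dtype=np.int8)

    @property
    def n_windows(self) -> int:
        return len(self.frame)


def binarize_tracks(track: pd.DataFrame, marks: Sequence[str] | None = None,
                    p_threshold: float = 1e-4,
                    background: Mapping[str, float] | None = None,
                    exclude_contigs: Sequence[str] = ()) -> MarkBinaryMatrix:
    """Binarize a wide windowed count track (chrom, start, end, mark columns)."""
    if marks is None:
        marks = [c for c in track.columns if c not in ("chrom", "start", "end")]
    track = track[~track["chrom"].isin(exclude_contigs)].reset_index(drop=True)
    window = int((track["end"] - track["start"]).max())
    frame = track[["chrom", "start"]].copy()
    for mark in marks:
        bg = background.get(mark) if background else None
        frame[mark] = binarize(track[mark].to_numpy(), background=bg,
                               p_threshold=p_threshold)
    return MarkBinaryMatrix(frame=frame, marks=list(marks), window=window)


# ---------------------------------------------------------------------------
# the HMM
# ---------------------------------------------------------------------------

@dataclass
class ChromatinStateModel:
    emission: np.ndarray  # (n_states, n_marks), Bernoulli P(mark present)
    transition: np.ndarray  # (n_states, n_states), row-stochastic
    initial: np.ndarray  # (n_states,)
    marks: list[str]
    log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.initial)

    def state_order_by_emission(self, mark: str) -> np.ndarray:
        """0-based state indices sorted by descending emission of one mark
        (the conventional display order, e.g. by H3K36me3)."""
        return np.argsort(-self.emission[:, self.marks.index(mark)], kind="stable")

    def to_frames(self) -> dict[str, pd.DataFrame]:
        states = [f"state_{i + 1}" for i in range(self.n_states)]
        return {
            "emission": pd.DataFrame(self.emission, index=states, columns=self.marks),
            "transition": pd.DataFrame(self.transition, index=states, columns=states),
            "initial": pd.DataFrame({"p": self.initial}, index=states),
        }


def _log_emission_matrix(X: np.ndarray, emission: np.ndarray) -> np.ndarray:
    """(T, S) log P(observation row | state) under independent Bernoullis."""
    e = np.clip(emission, EMISSION_FLOOR, 1.0 - EMISSION_FLOOR)
    return X @ np.log(e).T + (1 - X) @ np.log(1.0 - e).T


def _forward_backward(X: np.ndarray, emission: np.ndarray, transition: np.ndarray,
                      initial: np.ndarray, want_beta: bool = True):
    """Scaled forward(-backward) pass for one observation sequence.

    Returns (loglik, alpha_hat, beta_hat, b_scaled, c) where the scaled
    quantities follow the Rabiner conventions; beta_hat is None when
    ``want_beta`` is False.
    """
    logB = _log_emission_matrix(X, emission)
    m = logB.max(axis=1)
    b = np.exp(logB - m[:, None])  # row-rescaled emission likelihoods
    T, S = b.shape
    alpha = np.empty((T, S))
    c = np.empty(T)
    a = initial * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    if not np.all(np.isfinite(c)) or (c <= 0).any():
        raise NumericalError("non-finite forward scaling factor")
    loglik = float(np.log(c).sum() + m.sum())
    beta = None
    if want_beta:
        beta = np.empty((T, S))
        beta[-1] = 1.0
        for t in range(T - 2, -1, -1):
            beta[t] = (transition @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    return loglik, alpha, beta, b, c


def log_likelihood(model: ChromatinStateModel, matrix: MarkBinaryMatrix) -> float:
    """Total forward log-likelihood, summed over per-contig sequences."""
    _check_marks(model, matrix)
    total = 0.0
    for _, X in matrix.sequences():
        ll, *_ = _forward_backward(X, model.emission, model.transition,
                                   model.initial, want_beta=False)
        total += ll
    return total


def _check_marks(model: ChromatinStateModel, matrix: MarkBinaryMatrix) -> None:
    if model.marks != matrix.marks:
        raise ValueError(f"mark sets differ: model {model.marks} vs "
                         f"matrix {matrix.marks}")


def _em_iteration(sequences: list[np.ndarray], emission, transition, initial):
    """One E step + sufficient statistics. Returns (loglik, stats)."""
    S, M = emission.shape
    pi_acc = np.zeros(S)
    xi_acc = np.zeros((S, S))
    gamma_acc = np.zeros(S)
    gx_acc = np.zeros((S, M))
    total_ll = 0.0
    for X in sequences:
        ll, alpha, beta, b, c = _forward_backward(X, emission, transition, initial)
        total_ll += ll
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        pi_acc += gamma[0]
        gamma_acc += gamma.sum(axis=0)
        gx_acc += gamma.T @ X
        if len(X) > 1:
            w = b[1:] * beta[1:] / c[1:, None]
            xi_acc += transition * (alpha[:-1].T @ w)
    return total_ll, pi_acc, xi_acc, gamma_acc, gx_acc


def fit_hmm(matrix: MarkBinaryMatrix, n_states: int, seed: int = 0,
            max_iter: int = 100, tol: float = 1e-2,
            n_restarts: int = 1) -> ChromatinStateModel:
    """Baum-Welch fit of the Bernoulli-emission HMM.

    Emissions are initialized from seeded uniform(0.2, 0.8) draws and
    transitions uniformly; EM stops when the log-likelihood improves by
    less than ``tol`` or after ``max_iter`` iterations.  The log-likelihood
    is asserted non-decreasing every iteration (within round-off).  With
    ``n_restarts`` > 1 the best-likelihood fit is kept.  State labels are
    arbitrary (identifiable only up to permutation).
    """
    if n_states < 1:
        raise ConfigError("n_states must be >= 1")
    if matrix.n_windows == 0:
        raise ConfigError("empty binary matrix")
    if n_states > matrix.n_windows:
        raise ConfigError(f"n_states={n_states} exceeds {matrix.n_windows} windows")
    sequences = [X.astype(np.float64) for _, X in matrix.sequences()]
    M = len(matrix.marks)
    best: ChromatinStateModel | None = None
    root = np.random.SeedSequence([int(seed), 404])
    for child in root.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        emission = rng.uniform(0.2, 0.8, size=(n_states, M))
        transition = np.full((n_states, n_states), 1.0 / n_states)
        initial = np.full(n_states, 1.0 / n_states)
        trace: list[float] = []
        for it in range(max_iter):
            try:
                ll, pi_acc, xi_acc, gamma_acc, gx_acc = _em_iteration(
                    sequences, emission, transition, initial)
            except NumericalError as exc:
                raise NumericalError(f"EM iteration {it}: {exc}") from exc
            if not np.isfinite(ll):
                raise NumericalError(f"non-finite log-likelihood at iteration {it}")
            if trace and ll < trace[-1] - 1e-6 * (1.0 + abs(trace[-1])):
                raise NumericalError(
                    f"log-likelihood decreased at iteration {it}: "
                    f"{trace[-1]} -> {ll}")
            converged = bool(trace) and ll - trace[-1] < tol
            trace.append(ll)
            if converged:
                break
            initial = pi_acc / pi_acc.sum()
            xi = xi_acc + TRANSITION_PSEUDOCOUNT
            transition = xi / xi.sum(axis=1, keepdims=True)
            emission = np.clip(gx_acc / gamma_acc[:, None],
                               EMISSION_FLOOR, 1.0 - EMISSION_FLOOR)
        model = ChromatinStateModel(emission=emission, transition=transition,
                                    initial=initial, marks=list(matrix.marks),
                                    log_likelihood_trace=trace)
        if best is None or trace[-1] > best.log_likelihood_trace[-1]:
            best = model
    return best


# ---------------------------------------------------------------------------
# decoding and methylation association
# ---------------------------------------------------------------------------

@dataclass
class StateTrack:
    """Per-window decoded state labels (1-based) plus occupancy fractions."""

    frame: pd.DataFrame  # chrom, start, state
    window: int
    n_states: int

    @property
    def occupancy(self) -> np.ndarray:
        counts = np.bincount(self.frame["state"].to_numpy() - 1,
                             minlength=self.n_states)
        return counts / counts.sum()


def decode(model: ChromatinStateModel, matrix: MarkBinaryMatrix) -> StateTrack:
    """Posterior-argmax state labels per window (forward-backward).

    Ties break toward the lowest state index.  Posterior rows are checked
    to sum to 1.
    """
    _check_marks(model, matrix)
    states = []
    for _, X in matrix.sequences():
        _, alpha, beta, _, _ = _forward_backward(
            X.astype(np.float64), model.emission, model.transition, model.initial)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        if not np.allclose(gamma.sum(axis=1), 1.0):
            raise NumericalError("posterior rows do not normalize")
        states.append(np.argmax(gamma, axis=1) + 1)
    frame = matrix.frame[["chrom", "start"]].copy()
    frame["state"] = np.concatenate(states)
    return StateTrack(frame=frame, window=matrix.window, n_states=model.n_states)


def posterior_probabilities(model: ChromatinStateModel,
                            matrix: MarkBinaryMatrix) -> np.ndarray:
    """(n_windows, n_states) posterior state probabilities, rows summing to 1."""
    _check_marks(model, matrix)
    gammas = []
    for _, X in matrix.sequences():
        _, alpha, beta, _, _ = _forward_backward(
            X.astype(np.float64), model.emission, model.transition, model.initial)
        gamma = alpha * beta
        gammas.append(gamma / gamma.sum(axis=1, keepdims=True))
    return np.vstack(gammas)


def state_methylation(track: StateTrack, site_lvls: pd.DataFrame) -> pd.DataFrame:
    """Distribution summaries of per-site methylation within each state.

    ``site_lvls`` is the output of :func:`binning.site_levels` (chrom, pos,
    level).  Each site maps to the window containing its position and hence
    to exactly one state; states with no sites report n=0 and NaN summaries.
    """
    w = track.window
    sites = site_lvls.copy()
    sites["start"] = ((sites["pos"] - 1) // w) * w
    joined = sites.merge(track.frame, on=["chrom", "start"], how="inner")
    rows = []
    for s in range(1, track.n_states + 1):
        lv = joined.loc[joined["state"] == s, "level"]
        rows.append({
            "state": s, "n": len(lv),
            "median": float(lv.median()) if len(lv) else np.nan,
            "q1": float(lv.quantile(0.25)) if len(lv) else np.nan,
            "q3": float(lv.quantile(0.75)) if len(lv) else np.nan,
        })
    return pd.DataFrame(rows).set_index("state")


def state_composition(track: StateTrack, strata: Mapping[str, set],
                      bin_size: int = 10_000) -> pd.DataFrame:
    """Chromatin-state composition of each delta stratum's bins.

    Each row is a stratum; entries are the fraction of windows of each
    state among all windows falling inside the stratum's bins (rows sum to
    1; empty strata are NaN).  ``bin_size`` must be a multiple of the
    window size.
    """
    if bin_size % track.window != 0:
        raise ConfigError(
            f"bin_size {bin_size} is not a multiple of window {track.window}")
    frame = track.frame.copy()
    frame["bin"] = (frame["start"] // bin_size) * bin_size
    keys = pd.Series(list(zip(frame["chrom"], frame["bin"])), index=frame.index)
    rows = {}
    for label, bins in strata.items():
        sub = frame[keys.isin(bins)]
        if len(sub):
            counts = np.bincount(sub["state"].to_numpy() - 1,
                                 minlength=track.n_states).astype(float)
            rows[label] = counts / counts.sum()
        else:
            rows[label] = np.full(track.n_states, np.nan)
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"state_{i + 1}" for i in range(track.n_states)])
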