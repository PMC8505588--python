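"""Pairwise channel cross-correlation features.

For every unordered channel pair (i, j), i < j, of a trial, the full
cross-correlation sequence

    r_xy[l] = sum_t x[t] * y[t - l],   l in [-(N-1), N-1]

is reduced to three statistics — its maximum, mean and variance over lags —
and the triples are concatenated pair-major into one feature vector per
trial: 3 * C(14, 2) = 273 dimensions for the 14-channel montage.  Each
dimension is then min-max normalized to [0, 1] using statistics fitted on
training trials only, so evaluation never leaks test-fold information.

The raw (unnormalized-by-energy) correlation sum is used; an optional
coefficient mode dividing by the signal energies is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import fft as sfft

from eegauth.exceptions import EmptyInputError
from eegauth.preprocess import TrialSet


@dataclass(frozen=True)
class CrossCorrSequence:
    """Full cross-correlation of two length-N signals over all 2N-1 lags."""

    values: np.ndarray
    n: int

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-(self.n - 1), self.n)

    def at_lag(self, lag: int) -> float:
        if abs(lag) > self.n - 1:
            raise ValueError(f"lag {lag} outside [-(N-1), N-1]")
        return float(self.values[lag + self.n - 1])


def xcorr(x: np.ndarray, y: np.ndarray) -> CrossCorrSequence:
    """Cross-correlation of x with respect to y over the full lag range.

    Zero-padding semantics: signals are treated as zero outside [0, N).  The
    FFT-based implementation matches the direct double sum to numerical
    precision (this is asserted by the test suite against a brute-force
    oracle).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("xcorr expects 1-D signals")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("signals must have at least 2 samples")
    # r_xy[l] = sum_t x[t] y[t-l]; with numpy's correlate convention this is
    # correlate(x, y, "full") indexed so that entry l + (N-1) is lag l.
    values = np.correlate(x, y, mode="full")
    return CrossCorrSequence(values=values, n=x.size)


def channel_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Ordered list of unordered channel pairs (i, j), i < j."""
    return list(combinations(range(n_channels), 2))


def _pairwise_xcorr_stats(trials: np.ndarray) -> np.ndarray:
    """(max, mean, var) over lags of every pair's cross-correlation.

    ``trials`` is trial x channel x sample; returns trial x pair x 3.  All
    pair correlations of one trial are computed in a single batched FFT
    (circular correlation on a zero-padded length covering all 2N-1 linear
    lags), which matches the direct sum exactly up to floating-point error.
    """
    n_trials, n_channels, n = trials.shape
    pairs = channel_pairs(n_channels)
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    nfft = sfft.next_fast_len(2 * n - 1, real=True)

    out = np.empty((n_trials, len(pairs), 3))
    for t in range(n_trials):
        spectra = sfft.rfft(trials[t], nfft, axis=-1)
        cross = spectra[i_idx] * np.conj(spectra[j_idx])
        circ = sfft.irfft(cross, nfft, axis=-1)
        # circular index k holds lag k for k in [0, N) and lag k - nfft for
        # the top N-1 indices; assemble the linear sequence [-(N-1), N-1]
        seq = np.concatenate([circ[:, nfft - (n - 1):], circ[:, :n]], axis=1)
        out[t, :, 0] = seq.max(axis=1)
        out[t, :, 1] = seq.mean(axis=1)
        out[t, :, 2] = seq.var(axis=1)
    return out


def trial_pair_stats(
    trial: np.ndarray, pair_map: list[tuple[int, int]] | None = None
) -> np.ndarray:
    """Per-pair (max, mean, var) cross-correlation statistics of one trial.

    Returns an array of shape (n_pairs, 3) ordered like ``pair_map``
    (default: all unordered pairs in lexicographic order).
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be channel x sample")
    if trial.shape[0] < 2:
        raise ValueError("need at least 2 channels for pairwise statistics")
    stats = _pairwise_xcorr_stats(trial[None])[0]
    if pair_map is not None:
        default = channel_pairs(trial.shape[0])
        order = [default.index(p) for p in pair_map]
        stats = stats[order]
    return stats


@dataclass
class FeatureMatrix:
    """Per-trial feature vectors with provenance.

    ``X`` is trials x d with d = 3 * |pair_map|; columns are pair-major,
    (max, mean, var)-minor.  ``norm_params`` holds per-dimension (x_min,
    x_max) once a normalizer has been fitted; None for raw matrices.
    """

    X: np.ndarray
    labels: np.ndarray
    pair_map: list[tuple[int, int]]
    norm_params: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.shape[0] != self.labels.size:
            raise ValueError("one label per trial row required")
        if self.X.shape[1] != 3 * len(self.pair_map):
            raise ValueError("feature dimension must be 3 * number of pairs")

    def column_name(self, k: int) -> str:
        pair = self.pair_map[k // 3]
        stat = ("max", "mean", "var")[k % 3]
        return f"xc_{pair[0]}_{pair[1]}_{stat}"


def build_matrix(trialset: TrialSet) -> FeatureMatrix:
    """Raw (unnormalized) feature matrix for a trial set, one row per trial."""
    if trialset.n_trials == 0:
        raise EmptyInputError("trial set is empty")
    stats = _pairwise_xcorr_stats(trialset.trials)
    n_trials = stats.shape[0]
    return FeatureMatrix(
        X=stats.reshape(n_trials, -1),
        labels=np.repeat(trialset.subject_id, n_trials),
        pair_map=channel_pairs(trialset.trials.shape[1]),
    )


def concat_matrices(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack feature matrices row-wise (pair maps must agree)."""
    if not matrices:
        raise EmptyInputError("no feature matrices to concatenate")
    pair_map = matrices[0].pair_map
    if any(m.pair_map != pair_map for m in matrices):
        raise ValueError("pair maps differ between matrices")
    return FeatureMatrix(
        X=np.vstack([m.X for m in matrices]),
        labels=np.concatenate([m.labels for m in matrices]),
        pair_map=pair_map,
    )


def fit_normalizer(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension (x_min, x_max) of the training rows."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] == 0:
        raise EmptyInputError("X_train must be a non-empty 2-D matrix")
    return X_train.min(axis=0), X_train.max(axis=0)


def apply_normalizer(
    X: np.ndarray, norm_params: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Min-max map each dimension: (x - x_min) / (x_max - x_min).

    Training rows land in [0, 1] by construction; test rows may fall outside
    and are deliberately not clipped.  Constant dimensions (x_max == x_min)
    map to 0.
    """
    x_min, x_max = norm_params
    span = x_max - x_min
    safe = np.where(span == 0, 1.0, span)
    out = (np.asarray(X, dtype=float) - x_min) / safe
    out[:, span == 0] = 0.0
    return out
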