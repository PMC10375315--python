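"""Machinery for learning from skewed dose-response data.

Large drug screens are dominated by ineffective treatments (AUC near 1),
with sensitive outcomes (AUC near 0) orders of magnitude rarer. AUC values
are discretized into 12 equal bins over [0, 1.2]; smoothed inverse bin
frequencies drive both a multinomial weighted random sampler and a
double-weighted MSE loss that up-weights errors whenever the truth OR the
prediction falls in a rare bin. A standard binary focal loss supports the
synergy-classification variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

N_BINS = 12
BIN_RANGE = (0.0, 1.2)
BIN_WIDTH = (BIN_RANGE[1] - BIN_RANGE[0]) / N_BINS


def assign_bin(auc, warn: bool = True) -> np.ndarray | int:
    """Bin index 0..11 for AUC values over [0, 1.2].

    Bins are lower-closed / upper-open ([0.1*i, 0.1*(i+1))), the last bin
    closed at 1.2. Out-of-range values clamp to the end bins (logged;
    `warn=False` silences the log when binning raw model outputs inside a
    training loop); NaN raises.
    """
    arr = np.asarray(auc, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN AUC value cannot be binned")
    n_clamped = int(((arr < BIN_RANGE[0]) | (arr > BIN_RANGE[1])).sum())
    if n_clamped:
        logger.log(logging.WARNING if warn else logging.DEBUG,
                   "clamped %d AUC values outside [0, 1.2] to end bins",
                   n_clamped)
    # tiny shift guards against float error at the lower-closed boundaries
    # (e.g. 0.3/0.1 = 2.9999...96 must land in bin 3, not 2)
    idx = np.clip(np.floor(arr / BIN_WIDTH + 1e-9).astype(int), 0, N_BINS - 1)
    return int(idx) if np.isscalar(auc) or arr.ndim == 0 else idx


@dataclass
class BinWeights:
    """Smoothed inverse-frequency weights over the 12 AUC bins.

    f_i = c_i / sum(c), v_i = 1/(f_i + eps), w_i = v_i / sum(v). Rarer bins
    never receive smaller weight; eps -> infinity flattens the weights to
    uniform, eps = 0 (allowed only when every bin is occupied) gives pure
    inverse frequencies.
    """

    edges: np.ndarray  # 13 bin edges over [0, 1.2]
    counts: np.ndarray  # c_i
    frequencies: np.ndarray  # f_i
    smoothed_inverse: np.ndarray  # v_i
    weights: np.ndarray  # w_i, sums to 1
    epsilon: float

    def record_weights(self, aucs) -> np.ndarray:
        """Per-record sampling weight: the weight of each record's truth bin."""
        return self.weights[assign_bin(np.asarray(aucs, dtype=float))]


def smoothed_inverse_frequency(counts, epsilon: float) -> np.ndarray:
    """Normalized weights w_i from class counts: w_i prop. to 1/(f_i + eps)."""
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("no samples")
    if epsilon == 0 and (counts == 0).any():
        raise ValueError("epsilon = 0 with an empty class divides by zero")
    freqs = counts / counts.sum()
    v = 1.0 / (freqs + epsilon)
    return v / v.sum()


def compute_bin_weights(aucs, epsilon: float) -> BinWeights:
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    arr = np.asarray(aucs, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute bin weights from an empty sample")
    bins = assign_bin(arr)
    counts = np.bincount(bins, minlength=N_BINS).astype(float)
    if epsilon == 0 and (counts == 0).any():
        raise ValueError("epsilon = 0 with an empty bin divides by zero; "
                         "use a positive smoothing penalty")
    freqs = counts / counts.sum()
    v = 1.0 / (freqs + epsilon)
    w = smoothed_inverse_frequency(counts, epsilon)
    edges = np.linspace(BIN_RANGE[0], BIN_RANGE[1], N_BINS + 1)
    return BinWeights(edges=edges, counts=counts, frequencies=freqs,
                      smoothed_inverse=v, weights=w, epsilon=epsilon)


def sample_indices(sample_weights, n_draws: int | None,
                   rng: np.random.Generator) -> np.ndarray:
    """Multinomial weighted random sampling with replacement.

    `sample_weights` are per-record weights (typically the weight of each
    record's truth bin); `n_draws` defaults to the dataset size, so one
    resampled epoch has as many records as the original data.
    """
    w = np.asarray(sample_weights, dtype=float)
    if (w < 0).any():
        raise ValueError("negative sampling weights")
    total = w.sum()
    if total == 0:
        raise ValueError("all sampling weights are zero")
    if n_draws is None:
        n_draws = len(w)
    return rng.choice(len(w), size=n_draws, replace=True, p=w / total)


def double_weighted_mse(p, t, bw: BinWeights) -> float:
    """max(w_bin(p), w_bin(t)) * (p - t)^2, averaged over records.

    The max makes the penalty symmetric in prediction and truth: an error
    is up-weighted whenever either end of it sits in a rare bin.
    """
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.isnan(p).any() or np.isnan(t).any():
        raise ValueError("NaN in predictions or truths")
    wp = bw.weights[assign_bin(p)]
    wt = bw.weights[assign_bin(t)]
    return float(np.mean(np.maximum(wp, wt) * (p - t) ** 2))


_EPS = 1e-12


def focal_loss(prob, y, alpha: float = 0.4, gamma: float = 2.0) -> float:
    """Binary focal loss, mean over records.

    -alpha * (1-p)^gamma * log(p) for positives,
    -(1-alpha) * p^gamma * log(1-p) for negatives. gamma down-weights easy
    examples; alpha rebalances the classes. At gamma=0, alpha=0.5 this is
    half the binary cross-entropy. Probabilities exactly 0 or 1 are clamped
    by a tiny epsilon (logged).
    """
    p = np.asarray(prob, dtype=float)
    y = np.asarray(y, dtype=float)
    n_clamped = int(((p <= 0) | (p >= 1)).sum())
    if n_clamped:
        logger.warning("clamped %d probabilities at the {0,1} boundary",
                       n_clamped)
    p = np.clip(p, _EPS, 1 - _EPS)
    pos = -alpha * (1 - p) ** gamma * np.log(p)
    neg = -(1 - alpha) * p**gamma * np.log(1 - p)
    return float(np.mean(np.where(y == 1, pos, neg)))
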