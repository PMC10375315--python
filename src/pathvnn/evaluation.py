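"""Imbalance-aware evaluation of dose-response predictions.

Plain MSE and pooled correlations are dominated by the abundant
"no effect" bins, so this module provides their class-balanced
counterparts: the macroaverage MSE (mean of per-bin MSEs, so every AUC bin
counts equally regardless of its frequency), correlations computed on
repeated balanced resamples (equal draws per occupied bin), bin confusion
matrices, and the three cross-validation split schemes (random,
leave-cell-lines-out, leave-drugs-out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .imbalance import N_BINS, assign_bin


@dataclass
class EvalReport:
    mmse: float
    per_bin_mse: np.ndarray  # NaN for empty bins
    bin_counts: np.ndarray
    balanced_pearson: float | None = None
    balanced_pearson_sd: float | None = None
    balanced_spearman: float | None = None
    balanced_spearman_sd: float | None = None
    confusion: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "mmse": self.mmse,
            "per_bin_mse": [None if np.isnan(v) else float(v)
                            for v in self.per_bin_mse],
            "bin_counts": [int(c) for c in self.bin_counts],
        }
        for k in ("balanced_pearson", "balanced_pearson_sd",
                  "balanced_spearman", "balanced_spearman_sd"):
            v = getattr(self, k)
            if v is not None:
                d[k] = float(v)
        if self.confusion is not None:
            d["confusion"] = self.confusion.tolist()
        return d


def macro_mse(preds, truths) -> EvalReport:
    """Macroaverage MSE: the mean of per-bin MSEs over non-empty bins.

    Truth values are binned; each occupied bin contributes its own MSE with
    equal weight, so the measure is invariant to class frequencies and
    penalizes trivial majority-bin predictors.
    """
    p = np.asarray(preds, dtype=float)
    t = np.asarray(truths, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    bins = assign_bin(t)
    per_bin = np.full(N_BINS, np.nan)
    counts = np.bincount(bins, minlength=N_BINS)
    for i in range(N_BINS):
        mask = bins == i
        if mask.any():
            per_bin[i] = float(np.mean((p[mask] - t[mask]) ** 2))
    mmse = float(np.nanmean(per_bin))
    return EvalReport(mmse=mmse, per_bin_mse=per_bin, bin_counts=counts)


def balanced_correlation(
    preds,
    truths,
    n_per_class: int = 100,
    runs: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Pearson/Spearman on repeated class-balanced resamples.

    Each run draws `n_per_class` records from every occupied truth bin
    (with replacement when a bin is smaller than that) and computes both
    correlations; returns their means and standard deviations over runs.
    """
    if rng is None:
        rng = np.random.default_rng()
    p = np.asarray(preds, dtype=float)
    t = np.asarray(truths, dtype=float)
    bins = assign_bin(t)
    occupied = [np.flatnonzero(bins == i) for i in range(N_BINS)]
    occupied = [idx for idx in occupied if len(idx) > 0]
    if len(occupied) < 2:
        raise ValueError("balanced correlation needs at least 2 occupied bins")
    pearsons = np.empty(runs)
    spearmans = np.empty(runs)
    for r in range(runs):
        take = np.concatenate([
            rng.choice(idx, size=n_per_class, replace=True) for idx in occupied
        ])
        pearsons[r] = pearsonr(p[take], t[take]).statistic
        spearmans[r] = spearmanr(p[take], t[take]).statistic
    return {
        "pearson": float(np.mean(pearsons)),
        "pearson_sd": float(np.std(pearsons)),
        "spearman": float(np.mean(spearmans)),
        "spearman_sd": float(np.std(spearmans)),
    }


def bin_confusion(preds, truths) -> np.ndarray:
    """12x12 counts: entry (i, j) = truth-bin i predicted into bin j."""
    pb = assign_bin(np.asarray(preds, dtype=float))
    tb = assign_bin(np.asarray(truths, dtype=float))
    conf = np.zeros((N_BINS, N_BINS), dtype=int)
    np.add.at(conf, (tb, pb), 1)
    return conf


SPLIT_SCHEMES = ("random", "leave_cell_lines_out", "leave_drugs_out")


def split_folds(
    triplets: pd.DataFrame,
    scheme: str,
    k_folds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fold assignment (0..k_folds-1) per triplet row.

    `random` partitions the triplets; the leave-out schemes partition the
    cell (or drug) id set so no group id ever appears in two folds.
    """
    if scheme not in SPLIT_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SPLIT_SCHEMES}")
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    n = len(triplets)
    if scheme == "random":
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = np.arange(n) % k_folds
        return folds
    key = "cell_id" if scheme == "leave_cell_lines_out" else "drug_id"
    groups = np.asarray(sorted(triplets[key].unique()))
    if len(groups) < k_folds:
        raise ValueError(
            f"{len(groups)} unique {key} groups cannot fill {k_folds} folds"
        )
    gperm = rng.permutation(len(groups))
    gfold = np.empty(len(groups), dtype=int)
    gfold[gperm] = np.arange(len(groups)) % k_folds
    fold_of = dict(zip(groups, gfold))
    return triplets[key].map(fold_of).to_numpy(dtype=int)


def evaluate(preds, truths, n_per_class: int = 100, runs: int = 1000,
             rng: np.random.Generator | None = None) -> EvalReport:
    """Full report: MMSE, per-bin MSE, balanced correlations, confusion."""
    report = macro_mse(preds, truths)
    bc = balanced_correlation(preds, truths, n_per_class=n_per_class,
                              runs=runs, rng=rng)
    report.balanced_pearson = bc["pearson"]
    report.balanced_pearson_sd = bc["pearson_sd"]
    report.balanced_spearman = bc["spearman"]
    report.balanced_spearman_sd = bc["spearman_sd"]
    report.confusion = bin_confusion(preds, truths)
    return report
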