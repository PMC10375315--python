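"""Drug representation: fingerprint bits concatenated with molecular descriptors.

Each drug is a fixed-width vector of binary substructure-presence bits
(e.g. 881 PubChem-style fingerprint bits) followed by continuous
physicochemical/pharmacokinetic descriptors (e.g. 128 of them, giving the
default combined width of 1009). Descriptors are z-scored with statistics
learned on the training split only; fingerprints are never scaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DescriptorStats:
    """Per-column location/scale/impute statistics, fit on training rows."""

    columns: list[str]
    mean: np.ndarray
    std: np.ndarray
    median: np.ndarray


@dataclass
class DrugFeatureMatrix:
    F: pd.DataFrame  # drugs x fingerprint bits, binary
    V: pd.DataFrame  # drugs x descriptors, real

    @property
    def drugs(self) -> list[str]:
        return list(self.F.index)

    @property
    def width(self) -> int:
        return self.F.shape[1] + self.V.shape[1]

    def matrix(self) -> np.ndarray:
        """Combined drugs x (n_fp + n_desc) array, fingerprints first."""
        return np.concatenate([self.F.to_numpy(float), self.V.to_numpy(float)],
                              axis=1)

    def row(self, drug_id: str) -> np.ndarray:
        i = self.F.index.get_loc(drug_id)
        return self.matrix()[i]

    def validate(self) -> None:
        vals = self.F.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary fingerprint entry {vals[r, c]!r} for drug "
                f"{self.F.index[r]!r}, bit {self.F.columns[c]!r}"
            )
        if not self.F.index.equals(self.V.index):
            raise ValueError("fingerprint and descriptor drug sets differ")


def _read(path: str) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def load_drug_features(fingerprint_path: str,
                       descriptor_path: str) -> DrugFeatureMatrix:
    """Read fingerprint and descriptor tables keyed by drug id.

    Drugs missing from either file are excluded (logged). Descriptor columns
    that are entirely missing raise; partially missing values are left as NaN
    for `scale_descriptors` to impute from training rows. Column order is
    the file order and is deterministic across loads.
    """
    F = _read(fingerprint_path)
    V = _read(descriptor_path)
    common = F.index.intersection(V.index)
    n_excluded = (len(F.index) - len(common)) + (len(V.index) - len(common))
    if n_excluded:
        logger.warning("excluded %d drugs missing from one of the two files",
                       n_excluded)
    if len(common) == 0:
        raise ValueError("no drugs common to fingerprint and descriptor files")
    common = sorted(common)
    F, V = F.loc[common], V.loc[common]
    all_missing = V.columns[V.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(f"descriptor columns entirely missing: "
                         f"{list(all_missing)}")
    feats = DrugFeatureMatrix(F=F, V=V)
    feats.validate()
    return feats


def fit_descriptor_stats(V: pd.DataFrame,
                         train_drugs: list[str] | None = None) -> DescriptorStats:
    """Learn per-column mean/sd/median on the training drugs only."""
    rows = V if train_drugs is None else V.loc[train_drugs]
    return DescriptorStats(
        columns=list(V.columns),
        mean=rows.mean(axis=0, skipna=True).to_numpy(float),
        std=rows.std(axis=0, ddof=0, skipna=True).to_numpy(float),
        median=rows.median(axis=0, skipna=True).to_numpy(float),
    )


def scale_descriptors(V: pd.DataFrame, stats: DescriptorStats) -> pd.DataFrame:
    """z-score descriptor columns with training statistics.

    Missing values are imputed with the training-column median (logged);
    zero-variance columns map to 0. Raises if the column sets differ.
    """
    if list(V.columns) != stats.columns:
        raise ValueError("descriptor columns do not match the fitted statistics")
    X = V.to_numpy(float).copy()
    n_imputed = int(np.isnan(X).sum())
    if n_imputed:
        logger.warning("imputed %d missing descriptor values with training "
                       "medians", n_imputed)
        X = np.where(np.isnan(X), stats.median[None, :], X)
    sd = stats.std
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - stats.mean[None, :]) / sd[None, :]
    Z[:, sd == 0] = 0.0
    return pd.DataFrame(Z, index=V.index, columns=V.columns)
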