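"""Cell-line multiomics profiles and single-sample gene-set enrichment.

A cell line enters the model as three binary vectors (mutation,
amplification, deletion) plus a per-term normalized enrichment score (NES)
computed from its expression ranks with the Mann–Whitney–Wilcoxon gene-set
test: NES is the probability that a gene inside the set outranks a gene
outside it within that cell's expression profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ontology import OntologyLayout

logger = logging.getLogger(__name__)


class NESUndefinedError(ValueError):
    """NES requested for an empty gene set or an empty complement."""


def compute_nes(set_ranks: np.ndarray, m: int, n: int) -> float:
    """Mann–Whitney–Wilcoxon NES for one gene set in one sample.

    `set_ranks` are the ranks (1..m+n, midranks on ties) of the m in-set
    genes among all m+n genes. Returns NES = 1 - U/(mn) with
    U = mn + m(m+1)/2 - T, T the in-set rank sum: the probability that an
    in-set gene outranks an out-of-set gene (exact when there are no ties).
    """
    if m < 1 or n < 1:
        raise NESUndefinedError(f"NES undefined for m={m}, n={n}")
    t = float(np.sum(set_ranks))
    u = m * n + m * (m + 1) / 2.0 - t
    return 1.0 - u / (m * n)


def nes_matrix(
    E: pd.DataFrame,
    term_gene_index: dict[str, list[int]],
    undefined_value: float = 0.5,
) -> pd.DataFrame:
    """NES for every (cell, term): cells are rows of `E`, terms are keys of
    `term_gene_index` (column indices into `E`). Per-cell ranks are computed
    once and reused across terms. Terms with no in-set or no out-of-set
    genes get `undefined_value` (logged)."""
    X = E.to_numpy(dtype=float)
    n_cells, n_genes = X.shape
    ranks = rankdata(X, axis=1)  # midranks on ties
    terms = list(term_gene_index)
    out = np.empty((n_cells, len(terms)))
    n_undefined = 0
    for j, term in enumerate(terms):
        idx = term_gene_index[term]
        m = len(idx)
        n = n_genes - m
        if m == 0 or n == 0:
            out[:, j] = undefined_value
            n_undefined += 1
            continue
        t = ranks[:, idx].sum(axis=1)
        u = m * n + m * (m + 1) / 2.0 - t
        out[:, j] = 1.0 - u / (m * n)
    if n_undefined:
        logger.warning("NES undefined for %d terms (empty set or complement); "
                       "imputed %.2f", n_undefined, undefined_value)
    return pd.DataFrame(out, index=E.index, columns=terms)


@dataclass
class CohortData:
    """Binary omics matrices, expression, and per-term NES for a cell cohort.

    All matrices share the same cell index; M/A/D columns follow the layout's
    per-channel gene dictionaries, NES columns follow the layout term order.
    """

    M: pd.DataFrame
    A: pd.DataFrame
    D: pd.DataFrame
    E: pd.DataFrame
    NES: pd.DataFrame

    @property
    def cells(self) -> list[str]:
        return list(self.M.index)

    def validate(self) -> None:
        for name, mat in (("mutation", self.M), ("amplification", self.A),
                          ("deletion", self.D)):
            vals = mat.to_numpy()
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-binary value {vals[r, c]!r} in {name} matrix at "
                    f"cell {mat.index[r]!r}, gene {mat.columns[c]!r}"
                )
        if not ((self.NES.to_numpy() >= 0) & (self.NES.to_numpy() <= 1)).all():
            raise ValueError("NES entries outside [0, 1]")
        idx = self.M.index
        for mat in (self.A, self.D, self.E, self.NES):
            if not mat.index.equals(idx):
                raise ValueError("cell indices differ across matrices")
        if any(m.isna().to_numpy().any()
               for m in (self.M, self.A, self.D, self.E, self.NES)):
            raise ValueError("missing values after ingestion")


def _read_matrix(path: str) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def _align_channel(df: pd.DataFrame, gene_dict: dict[str, int],
                   channel: str) -> pd.DataFrame:
    known = [g for g in df.columns if g in gene_dict]
    dropped = df.shape[1] - len(known)
    if dropped:
        logger.warning("%s: dropped %d genes absent from the model layout",
                       channel, dropped)
    ordered = sorted(gene_dict, key=gene_dict.get)
    out = pd.DataFrame(0.0, index=df.index, columns=ordered)
    out.loc[:, known] = df[known]
    return out


def load_cohort(
    mutation_path: str,
    amplification_path: str,
    deletion_path: str,
    expression_path: str,
    layout: OntologyLayout,
) -> CohortData:
    """Read the four cells x genes matrices and derive the NES matrix.

    Genes are re-indexed to the layout's per-channel dictionaries (unknown
    genes dropped and counted, missing ones zero-filled for binary channels);
    cells are intersected across files, exclusions logged. Binary channels
    are validated strictly.
    """
    raw = {
        "mutation": _read_matrix(mutation_path),
        "amplification": _read_matrix(amplification_path),
        "deletion": _read_matrix(deletion_path),
        "expression": _read_matrix(expression_path),
    }
    common = raw["mutation"].index
    for df in raw.values():
        common = common.intersection(df.index)
    if len(common) == 0:
        raise ValueError("no cells common to all four omics files")
    for name, df in raw.items():
        excluded = len(df.index) - len(common)
        if excluded:
            logger.warning("%s: excluded %d cells absent from other files",
                           name, excluded)
    common = sorted(common)

    M = _align_channel(raw["mutation"].loc[common], layout.gene_dict["mutation"],
                       "mutation")
    A = _align_channel(raw["amplification"].loc[common],
                       layout.gene_dict["amplification"], "amplification")
    D = _align_channel(raw["deletion"].loc[common], layout.gene_dict["deletion"],
                       "deletion")
    expr_dict = layout.gene_dict["expression"]
    E = _align_channel(raw["expression"].loc[common], expr_dict, "expression")
    nes = nes_matrix(E, {t: layout.gene_index["expression"][t]
                         for t in layout.order})
    cohort = CohortData(M=M, A=A, D=D, E=E, NES=nes)
    cohort.validate()
    return cohort


def load_triplets(path: str) -> pd.DataFrame:
    """Read (cell_id, drug_id, auc) sensitivity triplets from TSV."""
    df = pd.read_csv(path, sep="\t")
    expected = ["cell_id", "drug_id", "auc"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"triplet file must have columns {expected}, "
                         f"got {list(df.columns[:3])}")
    if not np.isfinite(df["auc"]).all():
        raise ValueError("non-finite AUC values in triplet file")
    return df[expected]
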