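"""Ablation-based interpretability and drug-combination prioritization.

The relative improvement score (RIS) of an ontology term, for one
(cell, drug) prediction, compares how far the prediction moves when the
term's module is silenced (s_f) versus when all of its children are
silenced (s_cf): RIS = (s_cf - s_f) / (s_cf + s_f) in [-1, 1]. Positive
values mean the children carry more of the predictive signal than the
term's own integration. Top-RIS terms nominate combination partners:
drugs targeting genes of those terms, scored against validated synergy
data with a one-sided binomial enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .drug_features import DrugFeatureMatrix
from .model import Ablation, VisibleNetwork
from .ontology import OntologyLayout
from .profiles import CohortData


def _ris_from_deviations(s_f: float, s_cf: float) -> float:
    total = s_f + s_cf
    if total == 0:  # both ablations inert: uninformative term
        return 0.0
    return (s_cf - s_f) / total


def ris_scores(model: VisibleNetwork, cohort: CohortData,
               drugs: DrugFeatureMatrix, cell_id: str,
               drug_id: str) -> pd.DataFrame:
    """RIS for every retained term for one (cell, drug) prediction.

    Silencing a term zeroes its embedding and its NES pass-up before the
    parents consume them; the children ablation zeroes all child inputs of
    the term (for leaves, the term's gene inputs). One inference pass per
    ablation; the baseline is computed once.
    """
    layout = model.layout
    ci = cohort.M.index.get_loc(cell_id)
    M = cohort.M.to_numpy(float)[[ci]]
    A = cohort.A.to_numpy(float)[[ci]]
    D = cohort.D.to_numpy(float)[[ci]]
    NES = cohort.NES.to_numpy(float)[[ci]]
    dvec = drugs.row(drug_id)[None, :]
    base = float(model.predict(M, A, D, NES, dvec)[0])
    rows = []
    for term in layout.order:
        p_f = float(model.predict(M, A, D, NES, dvec,
                                  ablate=Ablation("term", term))[0])
        p_cf = float(model.predict(M, A, D, NES, dvec,
                                   ablate=Ablation("children", term))[0])
        s_f = abs(p_f - base)
        s_cf = abs(p_cf - base)
        rows.append({"cell_id": cell_id, "drug_id": drug_id, "term": term,
                     "p": base, "p_f": p_f, "p_cf": p_cf,
                     "s_f": s_f, "s_cf": s_cf,
                     "ris": _ris_from_deviations(s_f, s_cf)})
    return pd.DataFrame(rows)


def ris_scores_weight_zeroing(model: VisibleNetwork, cohort: CohortData,
                              drugs: DrugFeatureMatrix, cell_id: str,
                              drug_id: str) -> pd.DataFrame:
    """Reference RIS computed by literally zeroing stored parameters.

    Silencing a term zeroes its module's weights, biases and batch-norm
    scale/shift (so its embedding is exactly 0) plus the parents' weight
    columns that consume the term's NES; the children ablation does this
    for every child (gene-block weight columns for leaves). Slower than
    `ris_scores` but shares no masking code with it; used as an
    equivalence oracle in the tests.
    """
    layout = model.layout
    ci = cohort.M.index.get_loc(cell_id)
    M = cohort.M.to_numpy(float)[[ci]]
    A = cohort.A.to_numpy(float)[[ci]]
    D = cohort.D.to_numpy(float)[[ci]]
    NES = cohort.NES.to_numpy(float)[[ci]]
    dvec = drugs.row(drug_id)[None, :]
    base = float(model.predict(M, A, D, NES, dvec)[0])

    k = model.config.k

    def zero_module_output(m2, term):
        mod = m2.modules[term]
        mod.linear.W.data[:] = 0.0
        mod.linear.b.data[:] = 0.0
        mod.bn.gamma.data[:] = 0.0
        mod.bn.beta.data[:] = 0.0
        # parents' weight rows consuming this term's embedding + NES
        for parent, kids in layout.children.items():
            if term not in kids:
                continue
            span = m2._in_spans[parent]
            off = span["genes"] + 1
            for c in kids:
                if c == term:
                    m2.modules[parent].linear.W.data[off:off + k + 1, :] = 0.0
                off += k + 1

    def zero_gene_inputs(m2, term):
        span = m2._in_spans[term]
        m2.modules[term].linear.W.data[:span["genes"], :] = 0.0

    rows = []
    for term in layout.order:
        m_f = model.clone()
        zero_module_output(m_f, term)
        p_f = float(m_f.predict(M, A, D, NES, dvec)[0])
        m_cf = model.clone()
        kids = layout.children[term]
        if kids:
            for c in kids:
                zero_module_output(m_cf, c)
        else:
            zero_gene_inputs(m_cf, term)
        p_cf = float(m_cf.predict(M, A, D, NES, dvec)[0])
        s_f = abs(p_f - base)
        s_cf = abs(p_cf - base)
        rows.append({"cell_id": cell_id, "drug_id": drug_id, "term": term,
                     "p": base, "p_f": p_f, "p_cf": p_cf,
                     "s_f": s_f, "s_cf": s_cf,
                     "ris": _ris_from_deviations(s_f, s_cf)})
    return pd.DataFrame(rows)


def aggregate_ris(records: pd.DataFrame, by: str = "drug",
                  group_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Summarize RIS records per term within groups.

    `by` is 'drug', 'cell', or 'tissue_group' (the latter maps cell ids
    through `group_map`). Returns mean, sd and n per (group, term), sorted
    by group then descending mean RIS with ties broken by term id.
    """
    if records.empty:
        raise ValueError("no RIS records to aggregate")
    if by == "drug":
        key = records["drug_id"]
    elif by == "cell":
        key = records["cell_id"]
    elif by == "tissue_group":
        if group_map is None:
            raise ValueError("tissue_group aggregation needs a group_map")
        unknown = set(records["cell_id"]) - set(group_map)
        if unknown:
            raise KeyError(f"cells without a group: {sorted(unknown)[:5]}")
        key = records["cell_id"].map(group_map)
    else:
        raise ValueError(f"unknown grouping {by!r}")
    df = records.assign(group=key.to_numpy())
    out = (df.groupby(["group", "term"], sort=True)["ris"]
             .agg(mean="mean", sd="std", n="size").reset_index())
    out["sd"] = out["sd"].fillna(0.0)
    return out.sort_values(["group", "mean", "term"],
                           ascending=[True, False, True],
                           kind="mergesort").reset_index(drop=True)


def load_target_table(path: str) -> dict[str, set[str]]:
    """Drug -> target-gene sets from a two-column TSV (drug_id, gene)."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    out: dict[str, set[str]] = {}
    for drug, gene in df[cols].itertuples(index=False):
        out.setdefault(str(drug), set()).add(str(gene))
    return out


def candidate_combinations(
    ris_table: pd.DataFrame,
    layout: OntologyLayout,
    target_table: dict[str, set[str]],
    top_k: int = 5,
    leaves_only: bool = True,
    gene_channels: tuple = ("mutation", "amplification", "deletion",
                            "expression"),
) -> tuple[set[str], list[str]]:
    """Combination-partner candidates for one (cell, drug) RIS table.

    Takes the top_k terms by RIS (leaf terms by default), unions their
    annotated genes over the given channels, and returns every drug in the
    target table hitting at least one such gene — excluding the query drug.
    Returns (candidate set, selected terms).
    """
    if not target_table:
        raise ValueError("empty drug-target table")
    query_drugs = set(ris_table["drug_id"].unique())
    table = ris_table
    if leaves_only:
        leaves = set(layout.leaves())
        table = table[table["term"].isin(leaves)]
    top = (table.sort_values(["ris", "term"], ascending=[False, True],
                             kind="mergesort").head(top_k))
    terms = list(top["term"])
    genes: set[str] = set()
    for term in terms:
        for ch in gene_channels:
            genes |= set(layout.term_genes(ch, term))
    candidates = {d for d, targets in target_table.items()
                  if targets & genes and d not in query_drugs}
    return candidates, terms


@dataclass
class SynergyEnrichment:
    """Validated-synergy enrichment of a candidate set for one (cell, drug).

    TP/FP: candidates validated / not validated as synergistic with the
    query drug in that cell; S/NS: synergistic / non-synergistic partners
    among all tested combinations for the pair. precision = TP/(TP+FP) is
    compared against the baseline S/(S+NS) with a one-sided binomial test.
    """

    TP: int
    FP: int
    S: int
    NS: int
    precision: float | None
    baseline: float
    enrichment: float | None
    p_value: float | None


def synergy_enrichment(candidates: set[str],
                       validated: dict[str, int]) -> SynergyEnrichment:
    """Score a candidate set against validated partner labels.

    `validated` maps partner drug -> 1 (synergistic) / 0 (not) for the
    (cell, query-drug) pair. Candidates absent from the validated set are
    ignored. P(X >= TP | n = TP+FP, p = S/(S+NS)), one-sided greater.
    """
    if not validated:
        raise ValueError("no validated combinations for this pair")
    S = sum(1 for v in validated.values() if v == 1)
    NS = len(validated) - S
    baseline = S / (S + NS)
    scored = [d for d in candidates if d in validated]
    TP = sum(1 for d in scored if validated[d] == 1)
    FP = len(scored) - TP
    if TP + FP == 0:
        return SynergyEnrichment(TP=0, FP=0, S=S, NS=NS, precision=None,
                                 baseline=baseline, enrichment=None,
                                 p_value=None)
    precision = TP / (TP + FP)
    enrichment = precision / baseline if baseline > 0 else np.inf
    p = binomtest(TP, TP + FP, baseline, alternative="greater").pvalue
    return SynergyEnrichment(TP=TP, FP=FP, S=S, NS=NS, precision=precision,
                             baseline=baseline, enrichment=enrichment,
                             p_value=float(p))


def drug_branch_export(model: VisibleNetwork, drugs: DrugFeatureMatrix
                       ) -> pd.DataFrame:
    """Drug-branch embeddings for every drug (hook for external
    feature-attribution tools that operate on the drug branch alone)."""
    was = model.training
    model.train_mode(False)
    try:
        from ._autodiff import Tensor
        emb = model.drug_branch(Tensor(drugs.matrix())).data
    finally:
        model.train_mode(was)
    cols = [f"emb_{i}" for i in range(emb.shape[1])]
    return pd.DataFrame(emb, index=drugs.F.index, columns=cols)
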