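"""Structured synthetic inputs for end-to-end testing without downloads.

Emulates the shapes of real drug-screen data: a rooted ontology DAG with
several depth levels, sparse binary omics matrices, an expression matrix
whose ranks make the per-term enrichment score informative, a skewed AUC
distribution concentrated near 1 (the no-effect mode, with the most
sensitive bin rarer by a factor of ~50-100), and planted causal pathways:
designated ontology terms whose activity in a cell, combined with a drug
"mechanism" hitting those terms, lowers the AUC by a known effect size.
Synergy labels mark drug pairs hitting complementary causal terms in an
active cell. Everything is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drug_features import DrugFeatureMatrix
from .ontology import (OntologyGraph, OntologyLayout, TermAnnotation,
                       build_layout)
from .profiles import CohortData, nes_matrix


@dataclass
class SyntheticTruth:
    """Ground truth of a planted cohort: which terms are causal, which
    drugs hit them, and the generative parameters of the AUC model."""

    causal_terms: list[str]
    mechanism: dict[str, list[str]]      # drug -> causal terms it hits
    activity: pd.DataFrame | None = None  # cells x causal terms, 0/1
    beta: float = 0.35                    # AUC drop per hit causal pathway
    noise_sd: float = 0.03
    base_alpha: float = 25.0              # Beta params of the baseline AUC
    base_beta: float = 7.3
    seed: int = 0


# -- ontology -----------------------------------------------------------------


def generate_ontology(
    depth: int = 4,
    branching: int = 3,
    n_genes: int = 120,
    genes_per_term: int = 5,
    n_cross_edges: int = 0,
    seed: int = 0,
) -> tuple[OntologyGraph, TermAnnotation, dict[str, list[str]]]:
    """Complete tree ontology of `depth` levels (root included) with every
    leaf annotated by `genes_per_term` genes drawn from a shared universe.

    `n_cross_edges` adds extra child->ancestor is_a edges, turning the tree
    into a proper DAG for multi-parent wiring tests. Returns the graph, the
    per-channel annotation (all four channels share the leaf gene sets),
    and the leaf -> gene map.
    """
    if depth < 2 or branching < 1:
        raise ValueError("need depth >= 2 and branching >= 1")
    if genes_per_term > n_genes:
        raise ValueError("genes_per_term cannot exceed the gene universe")
    rng = np.random.default_rng(seed)
    levels: list[list[str]] = [["T:ROOT"]]
    edges: set[tuple[str, str]] = set()
    counter = 0
    for d in range(1, depth):
        level = []
        for parent in levels[d - 1]:
            for _ in range(branching):
                term = f"T:{counter:04d}"
                counter += 1
                level.append(term)
                edges.add((term, parent))
        levels.append(level)
    terms = {t for level in levels for t in level}
    if n_cross_edges:
        deep = [t for level in levels[2:] for t in level]
        shallow = levels[1]
        for _ in range(n_cross_edges):
            c = deep[rng.integers(len(deep))]
            p = shallow[rng.integers(len(shallow))]
            if (c, p) not in edges and c != p:
                edges.add((c, p))
    graph = OntologyGraph(terms=terms, edges=edges, root="T:ROOT")
    graph.validate()

    universe = [f"G{i:04d}" for i in range(n_genes)]
    leaves = levels[-1]
    leaf_genes = {
        leaf: sorted(rng.choice(universe, size=genes_per_term, replace=False))
        for leaf in leaves
    }
    channels = {
        ch: {leaf: set(genes) for leaf, genes in leaf_genes.items()}
        for ch in ("mutation", "amplification", "deletion", "expression")
    }
    ann = TermAnnotation(channels=channels,
                         universes={ch: list(universe) for ch in channels})
    return graph, ann, leaf_genes


def write_ontology_files(graph: OntologyGraph, ann: TermAnnotation,
                         out_dir: str) -> dict[str, str]:
    """Serialize the ontology to OBO and the annotations to GMT files,
    byte-identical across runs for the same inputs."""
    os.makedirs(out_dir, exist_ok=True)
    obo_path = os.path.join(out_dir, "ontology.obo")
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            for c, p in sorted(graph.edges):
                if c == term:
                    fh.write(f"is_a: {p} ! parent\n")
    paths = {"obo": obo_path}
    for ch, term_map in ann.channels.items():
        path = os.path.join(out_dir, f"annotation_{ch}.gmt")
        with open(path, "w") as fh:
            for term in sorted(term_map):
                genes = "\t".join(sorted(term_map[term]))
                fh.write(f"{term}\tsynthetic\t{genes}\n")
        paths[ch] = path
    return paths


# -- cohort -------------------------------------------------------------------


def default_truth(layout: OntologyLayout, n_causal: int, n_drugs: int,
                  rng: np.random.Generator, **kwargs) -> SyntheticTruth:
    """Pick causal leaf terms and assign each drug a mechanism of 1-2 of
    them (a fraction of drugs hit nothing and act as inert controls)."""
    leaves = layout.leaves()
    n_causal = min(n_causal, len(leaves))
    causal = sorted(rng.choice(leaves, size=n_causal, replace=False))
    mechanism: dict[str, list[str]] = {}
    for j in range(n_drugs):
        drug = f"D{j:03d}"
        if rng.random() < 0.2:  # inert drug
            mechanism[drug] = []
        else:
            n_hit = int(rng.integers(1, 3))
            mechanism[drug] = sorted(
                rng.choice(causal, size=min(n_hit, n_causal), replace=False))
    return SyntheticTruth(causal_terms=list(causal), mechanism=mechanism,
                          **kwargs)


def generate_cohort(
    layout: OntologyLayout,
    n_cells: int = 200,
    n_drugs: int = 40,
    n_causal: int = 6,
    n_fp_bits: int = 32,
    n_descriptors: int = 8,
    truth: SyntheticTruth | None = None,
    omics_density: float = 0.05,
    activity_rate: float = 0.3,
    expression_shift: float = 2.0,
    seed: int = 0,
) -> tuple[CohortData, DrugFeatureMatrix, pd.DataFrame, SyntheticTruth]:
    """Planted-signal cohort: omics + NES, drug features, AUC triplets.

    Each cell activates each causal term independently (rate
    `activity_rate`); active terms elevate the expression of their genes by
    `expression_shift` (so the term's NES rises) and switch on the term's
    mutation bits more often. AUC = clip(base - beta * (#hit active terms)
    + noise, 0, 1.2) with base ~ 1.2 * Beta(alpha, beta'), concentrated
    near 1 so the no-effect bin dominates and the sensitive bins are rare.
    Drug fingerprints carry one mechanism bit per causal term, making the
    drug branch learnable; remaining bits and all descriptors are noise.
    """
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = default_truth(layout, n_causal, n_drugs, rng, seed=seed)
    causal = truth.causal_terms
    cells = [f"C{i:03d}" for i in range(n_cells)]
    drugs = sorted(truth.mechanism)

    activity = pd.DataFrame(
        (rng.random((n_cells, len(causal))) < activity_rate).astype(int),
        index=cells, columns=causal)
    truth.activity = activity

    # omics: sparse Bernoulli background + mutation enrichment in active terms
    def genes_of(channel):
        return sorted(layout.gene_dict[channel], key=layout.gene_dict[channel].get)

    mats = {}
    for ch in ("mutation", "amplification", "deletion"):
        cols = genes_of(ch)
        mat = (rng.random((n_cells, len(cols))) < omics_density).astype(float)
        mats[ch] = pd.DataFrame(mat, index=cells, columns=cols)
    for term in causal:
        gidx = layout.gene_index["mutation"][term]
        active_cells = activity.index[activity[term] == 1]
        boost = (rng.random((len(active_cells), len(gidx))) < 0.6).astype(float)
        cols = [genes_of("mutation")[i] for i in gidx]
        mats["mutation"].loc[active_cells, cols] = np.maximum(
            mats["mutation"].loc[active_cells, cols].to_numpy(), boost)

    expr_cols = genes_of("expression")
    E = pd.DataFrame(rng.normal(size=(n_cells, len(expr_cols))),
                     index=cells, columns=expr_cols)
    for term in causal:
        gidx = layout.gene_index["expression"][term]
        cols = [expr_cols[i] for i in gidx]
        active_cells = activity.index[activity[term] == 1]
        E.loc[active_cells, cols] += expression_shift

    nes = nes_matrix(E, {t: layout.gene_index["expression"][t]
                         for t in layout.order})
    cohort = CohortData(M=mats["mutation"], A=mats["amplification"],
                        D=mats["deletion"], E=E, NES=nes)
    cohort.validate()

    # drug features: mechanism bits + noise bits + noise descriptors
    n_fp = max(n_fp_bits, len(causal))
    F = (rng.random((len(drugs), n_fp)) < 0.1).astype(int)
    for j, drug in enumerate(drugs):
        for t_i, term in enumerate(causal):
            F[j, t_i] = 1 if term in truth.mechanism[drug] else 0
    Fdf = pd.DataFrame(F, index=drugs,
                       columns=[f"bit{i:03d}" for i in range(n_fp)])
    V = pd.DataFrame(rng.normal(size=(len(drugs), n_descriptors)),
                     index=drugs,
                     columns=[f"desc{i:02d}" for i in range(n_descriptors)])
    V["desc00"] = [len(truth.mechanism[d]) for d in drugs]  # mild signal
    feats = DrugFeatureMatrix(F=Fdf, V=V)
    feats.validate()

    # AUC triplets over the full cell x drug grid
    rows = []
    act = activity.to_numpy()
    for j, drug in enumerate(drugs):
        hit_cols = [causal.index(t) for t in truth.mechanism[drug]]
        hits = act[:, hit_cols].sum(axis=1) if hit_cols else np.zeros(n_cells)
        base = 1.2 * rng.beta(truth.base_alpha, truth.base_beta, size=n_cells)
        auc = np.clip(base - truth.beta * hits
                      + rng.normal(0, truth.noise_sd, size=n_cells), 0.0, 1.2)
        for i, cell in enumerate(cells):
            rows.append((cell, drug, auc[i]))
    triplets = pd.DataFrame(rows, columns=["cell_id", "drug_id", "auc"])
    return cohort, feats, triplets, truth


def write_cohort_files(cohort: CohortData, feats: DrugFeatureMatrix,
                       triplets: pd.DataFrame, out_dir: str) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in (("mutation", cohort.M), ("amplification", cohort.A),
                     ("deletion", cohort.D), ("expression", cohort.E)):
        p = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(p, sep="\t")
        paths[name] = p
    for name, df in (("fingerprints", feats.F), ("descriptors", feats.V)):
        p = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(p, sep="\t")
        paths[name] = p
    p = os.path.join(out_dir, "triplets.tsv")
    triplets.to_csv(p, sep="\t", index=False)
    paths["triplets"] = p
    return paths


def target_table_from_truth(layout: OntologyLayout,
                            truth: SyntheticTruth) -> dict[str, set[str]]:
    """Drug -> target genes implied by the planted mechanisms (union of the
    mutation-channel genes of the causal terms each drug hits)."""
    table: dict[str, set[str]] = {}
    for drug, terms in truth.mechanism.items():
        genes: set[str] = set()
        for t in terms:
            genes |= set(layout.term_genes("mutation", t))
        if genes:
            table[drug] = genes
    return table


# -- synergy ------------------------------------------------------------------


def generate_synergy_labels(
    truth: SyntheticTruth,
    positive_rate: float = 0.10,
    label_noise: float = 0.02,
    n_pairs: int = 4000,
    seed: int = 0,
) -> pd.DataFrame:
    """(cell, drug_a, drug_b, label) pairs with planted complementarity.

    A pair is truly synergistic when the two drugs hit disjoint, non-empty
    causal-term sets that are both active in the cell. Pairs are sampled so
    positives make up ~`positive_rate` of the data (mirroring the strong
    class imbalance of real synergy screens), then labels are flipped with
    probability `label_noise`.
    """
    rng = np.random.default_rng(seed)
    activity = truth.activity
    if activity is None:
        raise ValueError("truth has no cell activity; generate a cohort first")
    cells = list(activity.index)
    drugs = sorted(truth.mechanism)

    def is_synergy(cell, da, db):
        ta, tb = set(truth.mechanism[da]), set(truth.mechanism[db])
        if not ta or not tb or (ta & tb):
            return 0
        row = activity.loc[cell]
        return int(all(row[t] == 1 for t in ta | tb))

    n_pos_target = int(round(n_pairs * positive_rate))
    positives, negatives = [], []
    seen = set()
    max_tries = 200 * n_pairs
    tries = 0
    while (len(positives) < n_pos_target
           or len(negatives) < n_pairs - n_pos_target) and tries < max_tries:
        tries += 1
        cell = cells[rng.integers(len(cells))]
        da, db = rng.choice(drugs, size=2, replace=False)
        da, db = sorted((da, db))
        key = (cell, da, db)
        if key in seen:
            continue
        lab = is_synergy(cell, da, db)
        if lab and len(positives) < n_pos_target:
            seen.add(key)
            positives.append((cell, da, db, 1))
        elif not lab and len(negatives) < n_pairs - n_pos_target:
            seen.add(key)
            negatives.append((cell, da, db, 0))
    rows = positives + negatives
    df = pd.DataFrame(rows, columns=["cell_id", "drug_a", "drug_b", "label"])
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))
                   ).reset_index(drop=True)
    flip = rng.random(len(df)) < label_noise
    df.loc[flip, "label"] = 1 - df.loc[flip, "label"]
    return df


# -- presets ------------------------------------------------------------------


def simulate_preset(preset: str, out_dir: str | None = None, seed: int = 0):
    """One-call generation of a complete synthetic study.

    Presets: 'tiny' (fast smoke), 'default' (~200 cells x 40 drugs,
    depth-4 ontology), 'synergy' (default cohort + synergy labels).
    Returns (layout, cohort, feats, triplets, truth[, synergy_pairs]).
    """
    if preset == "tiny":
        g, ann, _ = generate_ontology(depth=3, branching=2, n_genes=30,
                                      genes_per_term=4, seed=seed)
        layout = build_layout(g, ann, propagate=True)
        out = generate_cohort(layout, n_cells=30, n_drugs=8, n_causal=3,
                              n_fp_bits=16, n_descriptors=4, seed=seed)
    elif preset in ("default", "synergy"):
        g, ann, _ = generate_ontology(depth=4, branching=3, n_genes=120,
                                      genes_per_term=5, seed=seed)
        layout = build_layout(g, ann, propagate=True)
        out = generate_cohort(layout, n_cells=200, n_drugs=40, n_causal=6,
                              seed=seed)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    cohort, feats, triplets, truth = out
    result = [layout, cohort, feats, triplets, truth]
    if preset == "synergy":
        result.append(generate_synergy_labels(truth, seed=seed))
    if out_dir is not None:
        g2, ann2, _ = (generate_ontology(depth=3, branching=2, n_genes=30,
                                         genes_per_term=4, seed=seed)
                       if preset == "tiny" else
                       generate_ontology(depth=4, branching=3, n_genes=120,
                                         genes_per_term=5, seed=seed))
        write_ontology_files(g2, ann2, out_dir)
        write_cohort_files(cohort, feats, triplets, out_dir)
        if preset == "synergy":
            result[-1].to_csv(os.path.join(out_dir, "synergy_pairs.tsv"),
                              sep="\t", index=False)
    return tuple(result)
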