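"""The pathway-structured visible neural network and its training loop.

Every retained ontology term is a small module of k nonlinear units wired
to exactly the genes annotated to it (three binary omics blocks), its own
expression enrichment score (NES), and the embeddings + NES of its retained
children — nothing else. Module outputs flow up the hierarchy to the root,
whose embedding is combined with a drug embedding (fingerprints +
descriptors through a small dense branch) by a prediction head that outputs
the dose-response AUC. A Siamese twin-drug variant with a shared drug
branch and a logistic head supports synergy classification.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._autodiff import Adam, BatchNorm1d, Linear, Tensor, concat
from .drug_features import DrugFeatureMatrix
from .imbalance import (BinWeights, assign_bin, compute_bin_weights,
                        focal_loss, sample_indices,
                        smoothed_inverse_frequency)
from .ontology import OntologyLayout
from .profiles import CohortData


@dataclass
class ModelConfig:
    k: int = 6                      # hidden units per ontology module
    drug_layers: tuple = (100, 50, 6)
    head_hidden: int = 6
    learning_rate: float = 1e-5
    epochs: int = 300
    batch_size: int = 512
    split_fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    loss: str = "double_weighted_mse"   # double_weighted_mse | mse | focal
    epsilon: float = 80.0               # sampler/loss smoothing penalty
    focal_alpha: float = 0.4
    focal_gamma: float = 2.0
    bn_after_tanh: bool = True          # f = batchnorm(tanh(.)) vs tanh(batchnorm(.))
    root_nes_to_head: bool = False      # append the root term's NES to the head input

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if any(s < 1 for s in self.drug_layers) or self.head_hidden < 1:
            raise ValueError("layer sizes must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def synergy_config(**overrides) -> ModelConfig:
    """Defaults for the twin-drug synergy classifier (k=16, 50 epochs,
    focal loss, sampler smoothing epsilon=5)."""
    base = dict(k=16, epochs=50, loss="focal", epsilon=5.0)
    base.update(overrides)
    return ModelConfig(**base)


class _Module:
    """One ontology-term module: linear map over its wired inputs, then
    tanh and batch normalization (order configurable)."""

    def __init__(self, n_in: int, k: int, rng, bn_after_tanh: bool):
        self.linear = Linear(n_in, k, rng)
        self.bn = BatchNorm1d(k)
        self.bn_after_tanh = bn_after_tanh

    def __call__(self, x: Tensor) -> Tensor:
        z = self.linear(x)
        if self.bn_after_tanh:
            return self.bn(z.tanh())
        return self.bn(z).tanh()

    def parameters(self):
        return self.linear.parameters() + self.bn.parameters()


class _DrugBranch:
    def __init__(self, n_in: int, layers: tuple, rng, bn_after_tanh: bool):
        self.blocks = []
        prev = n_in
        for width in layers:
            self.blocks.append(_Module(prev, width, rng, bn_after_tanh))
            prev = width
        self.out_width = prev

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x

    def parameters(self):
        return [p for b in self.blocks for p in b.parameters()]


@dataclass
class Ablation:
    """Inference-time silencing instruction for the interpretability score.

    kind='term': zero the term's embedding and its NES pass-up to parents.
    kind='children': zero the child-embedding and child-NES inputs of the
    term (for a leaf, zero its gene-block inputs instead).
    """

    kind: str
    term: str


class VisibleNetwork:
    """Ontology-wired multiomics branch + drug branch + prediction head.

    `n_drug_branches` = 2 gives the Siamese synergy variant: one shared
    drug branch applied to both drugs, a head over cell + both drug
    embeddings, and a logistic output.
    """

    def __init__(self, layout: OntologyLayout, config: ModelConfig,
                 n_drug_features: int, n_drug_branches: int = 1):
        self.layout = layout
        self.config = config
        self.n_drug_features = n_drug_features
        self.n_drug_branches = n_drug_branches
        rng = np.random.default_rng(config.seed)
        k = config.k
        self.modules: dict[str, _Module] = {}
        self._in_spans: dict[str, dict] = {}
        for term in layout.order:
            nm = len(layout.gene_index["mutation"][term])
            na = len(layout.gene_index["amplification"][term])
            nd = len(layout.gene_index["deletion"][term])
            kids = layout.children[term]
            n_in = nm + na + nd + 1 + len(kids) * (k + 1)
            self._in_spans[term] = {"genes": nm + na + nd, "kids": kids}
            self.modules[term] = _Module(n_in, k, rng, config.bn_after_tanh)
        self.drug_branch = _DrugBranch(n_drug_features, config.drug_layers,
                                       rng, config.bn_after_tanh)
        head_in = (k + (1 if config.root_nes_to_head else 0)
                   + n_drug_branches * self.drug_branch.out_width)
        self.head_hidden = _Module(head_in, config.head_hidden, rng,
                                   config.bn_after_tanh)
        self.head_out = Linear(config.head_hidden, 1, rng)
        self.training = True

    # -- mode / parameter plumbing -------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = [p for m in self.modules.values() for p in m.parameters()]
        params += self.drug_branch.parameters()
        params += self.head_hidden.parameters() + self.head_out.parameters()
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train_mode(self, flag: bool = True) -> None:
        self.training = flag
        for m in list(self.modules.values()) + self.drug_branch.blocks + \
                [self.head_hidden]:
            m.bn.training = flag

    def clone(self) -> "VisibleNetwork":
        return copy.deepcopy(self)

    def state(self) -> list[np.ndarray]:
        arrs = [p.data.copy() for p in self.parameters()]
        for m in list(self.modules.values()) + self.drug_branch.blocks + \
                [self.head_hidden]:
            arrs += [m.bn.running_mean.copy(), m.bn.running_var.copy()]
        return arrs

    def load_state(self, arrs: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrs[: len(params)]):
            p.data = a.copy()
        rest = arrs[len(params):]
        mods = list(self.modules.values()) + self.drug_branch.blocks + \
            [self.head_hidden]
        for i, m in enumerate(mods):
            m.bn.running_mean = rest[2 * i].copy()
            m.bn.running_var = rest[2 * i + 1].copy()

    # -- forward --------------------------------------------------------------
    def cell_embedding(self, M: np.ndarray, A: np.ndarray, D: np.ndarray,
                       NES: np.ndarray, ablate: Ablation | None = None
                       ) -> tuple[Tensor, Tensor]:
        """Run the ontology branch; returns (root embedding, root NES column).

        Ablation zeroes the designated contributions before parents consume
        them (equivalent to zeroing the corresponding weights and biases)."""
        layout, k = self.layout, self.config.k
        term_col = {t: j for j, t in enumerate(layout.order)}
        embeddings: dict[str, Tensor] = {}
        nes_cols: dict[str, np.ndarray] = {}
        for term in layout.order:
            gi = layout.gene_index
            m_blk = M[:, gi["mutation"][term]]
            a_blk = A[:, gi["amplification"][term]]
            d_blk = D[:, gi["deletion"][term]]
            nes_blk = NES[:, [term_col[term]]]
            kids = self._in_spans[term]["kids"]
            if ablate is not None and ablate.kind == "children" and \
                    ablate.term == term and not kids:
                m_blk = np.zeros_like(m_blk)
                a_blk = np.zeros_like(a_blk)
                d_blk = np.zeros_like(d_blk)
            parts = [Tensor(np.concatenate([m_blk, a_blk, d_blk, nes_blk],
                                           axis=1))]
            for c in kids:
                e_c, n_c = embeddings[c], nes_cols[c]
                if ablate is not None and (
                    (ablate.kind == "term" and ablate.term == c)
                    or (ablate.kind == "children" and ablate.term == term)
                ):
                    e_c = e_c * 0.0
                    n_c = np.zeros_like(n_c)
                parts.append(e_c)
                parts.append(Tensor(n_c))
            x = parts[0] if len(parts) == 1 else concat(parts, axis=1)
            embeddings[term] = self.modules[term](x)
            nes_cols[term] = nes_blk
        root = layout.root
        e_root, n_root = embeddings[root], nes_cols[root]
        if ablate is not None and ablate.kind == "term" and ablate.term == root:
            e_root = e_root * 0.0
            n_root = np.zeros_like(n_root)
        return e_root, Tensor(n_root)

    def forward(self, M, A, D, NES, drug_feats, drug_feats_2=None,
                ablate: Ablation | None = None) -> Tensor:
        """Predicted AUC column (or synergy probability for the twin model)."""
        root_emb, root_nes = self.cell_embedding(M, A, D, NES, ablate=ablate)
        parts = [root_emb]
        if self.config.root_nes_to_head:
            parts.append(root_nes)
        parts.append(self.drug_branch(Tensor(drug_feats)))
        if self.n_drug_branches == 2:
            if drug_feats_2 is None:
                raise ValueError("the twin-drug model needs two drug vectors")
            parts.append(self.drug_branch(Tensor(drug_feats_2)))
        out = self.head_out(self.head_hidden(concat(parts, axis=1)))
        if self.n_drug_branches == 2:
            out = out.sigmoid()
        return out

    def predict(self, M, A, D, NES, drug_feats, drug_feats_2=None,
                ablate: Ablation | None = None) -> np.ndarray:
        """Inference-mode predictions (running batch-norm statistics)."""
        was_training = self.training
        self.train_mode(False)
        try:
            out = self.forward(M, A, D, NES, drug_feats, drug_feats_2,
                               ablate=ablate)
        finally:
            self.train_mode(was_training)
        return out.data[:, 0]


def expected_parameter_count(layout: OntologyLayout, config: ModelConfig,
                             n_drug_features: int,
                             n_drug_branches: int = 1) -> int:
    """Closed-form parameter count of the network implied by a layout.

    Each term module with g wired genes and r children has
    (g + 1 + r*(k+1))*k weights + k biases + 2k batch-norm parameters;
    the drug branch and head follow the same linear+batchnorm pattern."""
    k = config.k
    total = 0
    for term in layout.order:
        g = sum(len(layout.gene_index[ch][term])
                for ch in ("mutation", "amplification", "deletion"))
        r = len(layout.children[term])
        n_in = g + 1 + r * (k + 1)
        total += n_in * k + k + 2 * k
    prev = n_drug_features
    for width in config.drug_layers:
        total += prev * width + width + 2 * width
        prev = width
    head_in = (k + (1 if config.root_nes_to_head else 0)
               + n_drug_branches * prev)
    total += head_in * config.head_hidden + config.head_hidden \
        + 2 * config.head_hidden
    total += config.head_hidden * 1 + 1
    return total


def build_model(layout: OntologyLayout, config: ModelConfig,
                n_drug_features: int) -> VisibleNetwork:
    model = VisibleNetwork(layout, config, n_drug_features, n_drug_branches=1)
    assert model.n_parameters() == expected_parameter_count(
        layout, config, n_drug_features)
    return model


def build_synergy_model(layout: OntologyLayout, config: ModelConfig,
                        n_drug_features: int) -> VisibleNetwork:
    model = VisibleNetwork(layout, config, n_drug_features, n_drug_branches=2)
    assert model.n_parameters() == expected_parameter_count(
        layout, config, n_drug_features, n_drug_branches=2)
    return model


# -- checkpointing -------------------------------------------------------------


def save_checkpoint(model: VisibleNetwork, path: str) -> None:
    """Single-archive checkpoint: layout JSON + config + all arrays."""
    import dataclasses
    import json
    meta = {
        "layout": model.layout.to_json(),
        "config": dataclasses.asdict(model.config),
        "n_drug_features": model.n_drug_features,
        "n_drug_branches": model.n_drug_branches,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state())}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path: str) -> VisibleNetwork:
    import json
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[f"arr_{i}"] for i in range(len(z.files) - 1)]
    cfg_d = meta["config"]
    for key in ("drug_layers", "split_fractions"):
        cfg_d[key] = tuple(cfg_d[key])
    config = ModelConfig(**cfg_d)
    layout = OntologyLayout.from_json(meta["layout"])
    model = VisibleNetwork(layout, config, meta["n_drug_features"],
                           n_drug_branches=meta["n_drug_branches"])
    model.load_state(arrays)
    model.train_mode(False)
    return model


# -- training ------------------------------------------------------------------


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_mmse: list[float] = field(default_factory=list)
    best_epoch: int = -1


def split_triplets(n: int, fractions: tuple, rng: np.random.Generator):
    """Random train/test/validation index split."""
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_test = int(round(fractions[1] * n))
    train = perm[:n_train]
    test = perm[n_train:n_train + n_test]
    val = perm[n_train + n_test:]
    if len(train) == 0 or len(val) == 0:
        raise ValueError("empty split; dataset too small for the fractions")
    return train, test, val


class _Batcher:
    """Assembles per-batch input arrays from a cohort + drug table."""

    def __init__(self, cohort: CohortData, drugs: DrugFeatureMatrix,
                 triplets: pd.DataFrame, pair_cols=("cell_id", "drug_id")):
        self.Mm = cohort.M.to_numpy(float)
        self.Am = cohort.A.to_numpy(float)
        self.Dm = cohort.D.to_numpy(float)
        self.NESm = cohort.NES.to_numpy(float)
        self.drug_mat = drugs.matrix()
        cell_pos = {c: i for i, c in enumerate(cohort.M.index)}
        drug_pos = {d: i for i, d in enumerate(drugs.F.index)}
        unknown = [c for c in triplets[pair_cols[0]] if c not in cell_pos]
        unknown += [d for d in triplets[pair_cols[1]] if d not in drug_pos]
        if unknown:
            raise KeyError(f"unknown ids in triplets: {sorted(set(unknown))[:5]}")
        self.ci = triplets[pair_cols[0]].map(cell_pos).to_numpy(int)
        self.di = triplets[pair_cols[1]].map(drug_pos).to_numpy(int)
        self.di2 = None
        if len(pair_cols) == 3:
            self.di2 = triplets[pair_cols[2]].map(drug_pos).to_numpy(int)

    def batch(self, idx: np.ndarray):
        ci, di = self.ci[idx], self.di[idx]
        args = (self.Mm[ci], self.Am[ci], self.Dm[ci], self.NESm[ci],
                self.drug_mat[di])
        if self.di2 is not None:
            args = args + (self.drug_mat[self.di2[idx]],)
        return args


def _loss_tensor(pred: Tensor, truth: np.ndarray, config: ModelConfig,
                 bw: BinWeights | None) -> Tensor:
    t = truth[:, None]
    if config.loss == "mse":
        return ((pred - Tensor(t)) ** 2).mean()
    if config.loss == "double_weighted_mse":
        wp = bw.weights[assign_bin(pred.data[:, 0], warn=False)]
        wt = bw.weights[assign_bin(truth)]
        w = np.maximum(wp, wt)[:, None]  # piecewise-constant in p: no gradient
        return (Tensor(w) * (pred - Tensor(t)) ** 2).mean()
    if config.loss == "focal":
        eps = 1e-12
        a, g = config.focal_alpha, config.focal_gamma
        y = Tensor(t)
        p = pred * (1 - 2 * eps) + eps  # keep log() away from {0,1}
        pos = -a * ((1 - p) ** g) * p.log()
        neg = -(1 - a) * (p ** g) * (1 - p).log()
        return (y * pos + (1 - y) * neg).mean()
    raise ValueError(f"unknown loss {config.loss!r}")


def _eval_loss(pred: np.ndarray, truth: np.ndarray, config: ModelConfig,
               bw: BinWeights | None) -> float:
    from .imbalance import double_weighted_mse
    if config.loss == "mse":
        return float(np.mean((pred - truth) ** 2))
    if config.loss == "double_weighted_mse":
        return double_weighted_mse(pred, truth, bw)
    return focal_loss(pred, truth, config.focal_alpha, config.focal_gamma)


def train(model: VisibleNetwork, cohort: CohortData, drugs: DrugFeatureMatrix,
          triplets: pd.DataFrame, config: ModelConfig | None = None
          ) -> tuple[VisibleNetwork, TrainingHistory]:
    """Train on (cell, drug, auc) triplets with the weighted sampler.

    Splits the triplets per the config fractions, computes smoothed
    inverse-frequency bin weights on the training split, and each epoch
    draws a fresh multinomial resample of the training records (epoch
    length = training-set size). Returns the best-validation-loss snapshot
    and the per-epoch history. Fully reproducible from config.seed.
    """
    config = config or model.config
    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    tr_idx, _, val_idx = split_triplets(len(triplets), config.split_fractions,
                                        rng)
    aucs = triplets["auc"].to_numpy(float)
    bw = compute_bin_weights(aucs[tr_idx], config.epsilon) \
        if config.loss != "focal" else None
    batcher = _Batcher(cohort, drugs, triplets)
    record_w = bw.record_weights(aucs[tr_idx]) if bw is not None else None
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best_state, best_val = None, np.inf
    if config.epochs == 0:
        return model, history
    for epoch in range(config.epochs):
        if record_w is not None:
            order = tr_idx[sample_indices(record_w, None, rng)]
        else:
            order = tr_idx[rng.permutation(len(tr_idx))]
        model.train_mode(True)
        ep_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = model.forward(*batcher.batch(idx))
            loss = _loss_tensor(pred, aucs[idx], config, bw)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
        val_pred = predict_indices(model, batcher, val_idx)
        val_truth = aucs[val_idx]
        vloss = _eval_loss(val_pred, val_truth, config, bw)
        from .evaluation import macro_mse
        vmmse = macro_mse(val_pred, val_truth).mmse \
            if config.loss != "focal" else float("nan")
        history.train_loss.append(float(np.mean(ep_losses)))
        history.val_loss.append(vloss)
        history.val_mmse.append(vmmse)
        if vloss < best_val:
            best_val = vloss
            best_state = model.state()
            history.best_epoch = epoch
    if best_state is not None:
        model.load_state(best_state)
    return model, history


def predict_indices(model: VisibleNetwork, batcher: _Batcher,
                    idx: np.ndarray, chunk: int = 2048) -> np.ndarray:
    out = []
    for start in range(0, len(idx), chunk):
        out.append(model.predict(*batcher.batch(idx[start:start + chunk])))
    return np.concatenate(out) if out else np.empty(0)


def predict_batch(model: VisibleNetwork, cohort: CohortData,
                  drugs: DrugFeatureMatrix, pairs: pd.DataFrame) -> pd.DataFrame:
    """Inference over (cell_id, drug_id) pairs -> predicted_auc records."""
    if len(pairs) == 0:
        return pd.DataFrame(columns=["cell_id", "drug_id", "predicted_auc"])
    batcher = _Batcher(cohort, drugs, pairs)
    preds = predict_indices(model, batcher, np.arange(len(pairs)))
    out = pairs[["cell_id", "drug_id"]].copy()
    out["predicted_auc"] = preds
    return out


# -- synergy variant -----------------------------------------------------------


def augment_pair_orders(pairs: pd.DataFrame) -> pd.DataFrame:
    """Double the synergy dataset with both drug orders (the head
    concatenates the two drug embeddings, so order matters during
    training)."""
    swapped = pairs.rename(columns={"drug_a": "drug_b", "drug_b": "drug_a"})
    return pd.concat([pairs, swapped[pairs.columns]], ignore_index=True)


def train_synergy(model: VisibleNetwork, cohort: CohortData,
                  drugs: DrugFeatureMatrix, pairs: pd.DataFrame,
                  config: ModelConfig | None = None
                  ) -> tuple[VisibleNetwork, TrainingHistory]:
    """Train the twin-drug classifier on (cell_id, drug_a, drug_b, label).

    The dataset is doubled with both drug orders; the weighted sampler uses
    smoothed inverse class frequencies (label 0/1) and the focal loss
    handles the residual imbalance."""
    config = config or model.config
    rng = np.random.default_rng(config.seed)
    pairs = augment_pair_orders(pairs)
    labels = pairs["label"].to_numpy(float)
    history = TrainingHistory()
    tr_idx, _, val_idx = split_triplets(len(pairs), config.split_fractions, rng)
    counts = np.bincount(labels[tr_idx].astype(int), minlength=2).astype(float)
    class_w = smoothed_inverse_frequency(counts, config.epsilon)
    record_w = class_w[labels[tr_idx].astype(int)]
    batcher = _Batcher(cohort, drugs, pairs,
                       pair_cols=("cell_id", "drug_a", "drug_b"))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best_state, best_val = None, np.inf
    for epoch in range(config.epochs):
        order = tr_idx[sample_indices(record_w, None, rng)]
        model.train_mode(True)
        ep_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = model.forward(*batcher.batch(idx))
            loss = _loss_tensor(pred, labels[idx], config, None)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_losses.append(float(loss.data))
        val_pred = predict_indices(model, batcher, val_idx)
        vloss = _eval_loss(val_pred, labels[val_idx], config, None)
        history.train_loss.append(float(np.mean(ep_losses)))
        history.val_loss.append(vloss)
        history.val_mmse.append(float("nan"))
        if vloss < best_val:
            best_val = vloss
            best_state = model.state()
            history.best_epoch = epoch
    if best_state is not None:
        model.load_state(best_state)
    return model, history


def predict_synergy(model: VisibleNetwork, cohort: CohortData,
                    drugs: DrugFeatureMatrix, pairs: pd.DataFrame
                    ) -> pd.DataFrame:
    """Order-symmetrized synergy scores: the mean of both drug orders, so
    score(d1, d2) == score(d2, d1) exactly."""
    if len(pairs) == 0:
        return pd.DataFrame(columns=["cell_id", "drug_a", "drug_b",
                                     "synergy_score"])
    b1 = _Batcher(cohort, drugs, pairs, pair_cols=("cell_id", "drug_a",
                                                   "drug_b"))
    b2 = _Batcher(cohort, drugs, pairs, pair_cols=("cell_id", "drug_b",
                                                   "drug_a"))
    idx = np.arange(len(pairs))
    score = 0.5 * (predict_indices(model, b1, idx)
                   + predict_indices(model, b2, idx))
    out = pairs[["cell_id", "drug_a", "drug_b"]].copy()
    out["synergy_score"] = score
    return out
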