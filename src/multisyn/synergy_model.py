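"""The two-headed synergy network and its training loop.

Forward contract (per sample batch):

* drug branch (parameters shared by the two drugs):
  ``drugFeat_i = concat(FC_chem(descriptors_i), FC_graph(graph_embedding_i))``
* cell branch: ``cellFeat = FC_cell(expression)``; when the interaction
  branch is enabled, DDI features pass through ``FC_ddi`` and the cell
  features act as the attention query over them (key = value = DDI), the
  attended output being concatenated with the query —
  ``cell' = attention(cellFeat, ddiFeat)`` with twice the cell width;
* fusion: ``fused = concat(drugFeat1, drugFeat2, cell')``;
* per-task weighting: two attention blocks (query = key = value = fused)
  produce one representation per task, each concatenated with its input;
* task exchange: the cross-stitch subnetwork mixes the two representations;
* heads: a regression stack predicts the Loewe synergy score and a
  classification stack the three-class probabilities
  (antagonistic / additive / synergistic).

Training minimizes ``w_s * MSE(score) + w_c * CrossEntropy(3-class)`` plus
the weight/activity regularization of every FC stack, with AdamW, seeded
mini-batch shuffling, and (by default) z-scored regression targets whose
statistics come from the training rows only. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import AdamW, Linear, Tensor, concat, cross_entropy, relu
from .config import ModelConfig
from .neural_blocks import AttentionBlock, CrossStitchSubnetwork, FCSubnetwork

__all__ = ["FeatureDims", "SynergyBatch", "PredictionResult", "MultiSynModel",
           "assemble", "train", "predict"]


@dataclass(frozen=True)
class FeatureDims:
    """Input widths of the four feature families."""

    descriptor: int
    graph: int
    cell: int
    ddi: int = 0

    def __post_init__(self):
        if min(self.descriptor, self.graph, self.cell) <= 0:
            raise ValueError("descriptor/graph/cell dims must be positive")


@dataclass
class SynergyBatch:
    """Numeric model inputs for a batch of samples (one row per sample)."""

    desc1: np.ndarray
    desc2: np.ndarray
    graph1: np.ndarray
    graph2: np.ndarray
    cell: np.ndarray
    ddi: np.ndarray | None = None
    score: np.ndarray | None = None
    label: np.ndarray | None = None

    def __len__(self) -> int:
        return self.desc1.shape[0]

    def take(self, idx: np.ndarray) -> "SynergyBatch":
        pick = lambda a: None if a is None else a[idx]
        return SynergyBatch(self.desc1[idx], self.desc2[idx], self.graph1[idx],
                            self.graph2[idx], self.cell[idx], pick(self.ddi),
                            pick(self.score), pick(self.label))


@dataclass(frozen=True)
class PredictionResult:
    """Predicted Loewe scores and three-class probabilities."""

    scores: np.ndarray
    probs: np.ndarray

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.probs, axis=1)

    @property
    def synergistic_call(self) -> np.ndarray:
        from .data_pipeline import SYNERGISTIC
        return self.labels == SYNERGISTIC


class MultiSynModel:
    """Assembled synergy network; see the module docstring for the contract."""

    def __init__(self, config: ModelConfig, dims: FeatureDims, seed: int = 0):
        config = config.validated()
        self.config = config
        self.dims = dims
        rng = np.random.default_rng(seed)
        fc_kw = dict(dropout_rate=config.dropout, reg_weight=config.reg_weight,
                     reg_activity=config.reg_activity)

        self.fc_chem = FCSubnetwork(dims.descriptor, config.chem_widths, rng, **fc_kw)
        self.fc_graph = FCSubnetwork(dims.graph, config.graph_widths, rng, **fc_kw)
        self.fc_cell = FCSubnetwork(dims.cell, config.cell_widths, rng, **fc_kw)
        drug_dim = self.fc_chem.n_out + self.fc_graph.n_out

        if config.interaction_attention:
            if dims.ddi <= 0:
                raise ValueError("interaction attention enabled but ddi dim is 0")
            self.fc_ddi = FCSubnetwork(dims.ddi, config.ddi_widths, rng, **fc_kw)
            self.att_cell = AttentionBlock(
                self.fc_cell.n_out, self.fc_ddi.n_out, config.heads, rng,
                token_dim=config.token_dim, share_qkv=config.share_qkv,
                scaled=config.scaled_attention)
            cell_dim = 2 * self.fc_cell.n_out
        else:
            self.fc_ddi = None
            self.att_cell = None
            cell_dim = self.fc_cell.n_out

        self.fused_dim = 2 * drug_dim + cell_dim
        if config.feature_attention:
            mk = lambda: AttentionBlock(self.fused_dim, self.fused_dim,
                                        config.heads, rng,
                                        token_dim=config.token_dim,
                                        share_qkv=config.share_qkv,
                                        scaled=config.scaled_attention)
            self.att_task = (mk(), mk())
            self.task_dense = None
            task_dim = 2 * self.fused_dim
        else:
            # documented ablation: one rectified dense layer per task instead
            self.att_task = None
            self.task_dense = (Linear(self.fused_dim, self.fused_dim, rng),
                               Linear(self.fused_dim, self.fused_dim, rng))
            task_dim = self.fused_dim

        if config.cross_stitch:
            self.cross_stitch = CrossStitchSubnetwork(
                task_dim, rng, dense_width=config.cs_dense_width)
            head_in = self.cross_stitch.n_out
        else:
            self.cross_stitch = None
            head_in = task_dim

        self.head_reg = FCSubnetwork(head_in, config.pred_widths, rng, **fc_kw)
        self.head_cls = FCSubnetwork(head_in, config.pred_widths, rng, **fc_kw)
        self.out_reg = Linear(self.head_reg.n_out, 1, rng)
        self.out_cls = Linear(self.head_cls.n_out, 3, rng)

        self.trained = False
        # target standardization statistics (identity until fitted)
        self.y_mean = 0.0
        self.y_std = 1.0

    # -- forward -----------------------------------------------------------

    def _drug_branch(self, desc: Tensor, graph: Tensor, training, rng) -> Tensor:
        return concat([self.fc_chem(desc, training, rng),
                       self.fc_graph(graph, training, rng)], axis=-1)

    def forward(self, batch: SynergyBatch, training: bool = False,
                rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        """Raw regression output (standardized scale) and class logits."""
        d1 = self._drug_branch(Tensor(batch.desc1), Tensor(batch.graph1), training, rng)
        d2 = self._drug_branch(Tensor(batch.desc2), Tensor(batch.graph2), training, rng)
        cellf = self.fc_cell(Tensor(batch.cell), training, rng)
        if self.att_cell is not None:
            if batch.ddi is None:
                raise ValueError("model expects DDI features but batch has none")
            ddif = self.fc_ddi(Tensor(batch.ddi), training, rng)
            cellf = self.att_cell(cellf, ddif, ddif)
        fused = concat([d1, d2, cellf], axis=-1)
        if self.att_task is not None:
            t1 = self.att_task[0](fused, fused, fused)
            t2 = self.att_task[1](fused, fused, fused)
        else:
            t1 = relu(self.task_dense[0](fused))
            t2 = relu(self.task_dense[1](fused))
        if self.cross_stitch is not None:
            u1, u2 = self.cross_stitch(t1, t2)
        else:
            u1, u2 = t1, t2
        score = self.out_reg(self.head_reg(u1, training, rng))
        logits = self.out_cls(self.head_cls(u2, training, rng))
        return score, logits

    def penalty(self) -> Tensor:
        p = (self.fc_chem.penalty() + self.fc_graph.penalty()
             + self.fc_cell.penalty() + self.head_reg.penalty()
             + self.head_cls.penalty())
        if self.fc_ddi is not None:
            p = p + self.fc_ddi.penalty()
        return p

    def parameters(self) -> list[Tensor]:
        params = (self.fc_chem.parameters() + self.fc_graph.parameters()
                  + self.fc_cell.parameters())
        if self.fc_ddi is not None:
            params += self.fc_ddi.parameters() + self.att_cell.parameters()
        if self.att_task is not None:
            params += self.att_task[0].parameters() + self.att_task[1].parameters()
        else:
            params += [p for lin in self.task_dense for p in lin.parameters()]
        if self.cross_stitch is not None:
            params += self.cross_stitch.parameters()
        params += (self.head_reg.parameters() + self.head_cls.parameters()
                   + self.out_reg.parameters() + self.out_cls.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def assemble(config: ModelConfig, dims: FeatureDims, seed: int = 0) -> MultiSynModel:
    """Build the network for the given feature widths (seeded init)."""
    return MultiSynModel(config, dims, seed)


@dataclass
class TrainLog:
    """Per-epoch record of both task losses."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, **kw) -> None:
        self.epochs.append(dict(kw))


def train(model: MultiSynModel, data: SynergyBatch, config: ModelConfig | None = None,
          seed: int = 0) -> TrainLog:
    """Train in place with AdamW on the multi-task loss; returns the log."""
    config = config or model.config
    if len(data) == 0:
        raise ValueError("empty training dataset")
    if data.score is None or data.label is None:
        raise ValueError("training data needs score and label arrays")
    rng = np.random.default_rng(seed)
    if config.standardize_target and config.epochs > 0:
        model.y_mean = float(np.mean(data.score))
        model.y_std = float(np.std(data.score)) or 1.0
    y = ((data.score - model.y_mean) / model.y_std).reshape(-1, 1)

    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    log = TrainLog()
    n = len(data)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        tot_s = tot_c = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            sub = data.take(idx)
            opt.zero_grad()
            pred, logits = model.forward(sub, training=True, rng=rng)
            loss_s = (pred - Tensor(y[idx])).square().mean()
            loss_c = cross_entropy(logits, sub.label)
            loss = (config.loss_weight_score * loss_s
                    + config.loss_weight_class * loss_c
                    + model.penalty())
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: "
                    f"score={float(loss_s.data)}, class={float(loss_c.data)}"
                )
            loss.backward()
            opt.step()
            tot_s += float(loss_s.data) * len(idx)
            tot_c += float(loss_c.data) * len(idx)
        log.append(epoch=epoch, loss_score=tot_s / n, loss_class=tot_c / n)
    model.trained = config.epochs > 0 or model.trained
    return log


def predict(model: MultiSynModel, data: SynergyBatch) -> PredictionResult:
    """Deterministic evaluation-mode predictions on the Loewe scale."""
    raw, logits = model.forward(data, training=False)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    scores = raw.data.ravel() * model.y_std + model.y_mean
    return PredictionResult(scores, probs)
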