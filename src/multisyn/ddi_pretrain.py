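"""Drug–drug-interaction classifier pretraining.

Two parallel fully connected branches (one per drug, separate parameters)
encode the drugs' cleaned, normalized chemical descriptors; the branch
outputs are concatenated and passed through a post-concatenation stack ending
in a K-way softmax over interaction classes. After training, the activations
of the penultimate layer serve as drug-interaction features for the synergy
network (by default the last hidden layer of the post-concatenation stack; a
config switch selects the concatenated branch outputs instead).

Training uses a stratified 9:1 train/validation split, softmax cross-entropy
and AdamW. The validation report carries accuracy, precision, recall, Cohen's
kappa and F1 (macro-averaged over interaction classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
)
from sklearn.model_selection import train_test_split

from .autograd import AdamW, Linear, Tensor, concat, cross_entropy
from .config import ModelConfig
from .neural_blocks import FCSubnetwork

__all__ = ["DDIModel", "DDIReport", "train_ddi", "extract_ddi_features"]

POST_CONCAT_WIDTHS = [512, 256]


@dataclass
class DDIReport:
    """Validation-split report of a DDI training run."""

    metrics: dict[str, float]
    n_train: int
    n_val: int
    seed: int
    stratified: bool
    epoch_losses: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


class DDIModel:
    """Two drug branches, a post-concatenation stack and a K-way head."""

    def __init__(self, n_desc: int, n_classes: int, config: ModelConfig,
                 rng: np.random.Generator, post_widths: list[int] | None = None):
        if n_classes < 2:
            raise ValueError("need >= 2 interaction classes")
        self.n_desc = n_desc
        self.n_classes = n_classes
        self.penultimate_site = config.ddi_penultimate
        post_widths = list(post_widths or POST_CONCAT_WIDTHS)
        kw = dict(dropout_rate=config.dropout, reg_weight=config.reg_weight,
                  reg_activity=config.reg_activity)
        self.branch1 = FCSubnetwork(n_desc, config.ddi_widths, rng, **kw)
        self.branch2 = FCSubnetwork(n_desc, config.ddi_widths, rng, **kw)
        self.post = FCSubnetwork(2 * self.branch1.n_out, post_widths, rng, **kw)
        self.head = Linear(self.post.n_out, n_classes, rng)
        self.trained = False

    @property
    def penultimate_width(self) -> int:
        if self.penultimate_site == "post":
            return self.post.n_out
        return 2 * self.branch1.n_out

    def forward(self, d1: Tensor, d2: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Class logits for a batch of descriptor pairs."""
        h1 = self.branch1(d1, training, rng)
        h2 = self.branch2(d2, training, rng)
        h = self.post(concat([h1, h2], axis=-1), training, rng)
        return self.head(h)

    def penultimate(self, d1: Tensor, d2: Tensor) -> Tensor:
        """Interaction features: penultimate activations, no class head."""
        h1 = self.branch1(d1)
        h2 = self.branch2(d2)
        cat = concat([h1, h2], axis=-1)
        if self.penultimate_site == "branch":
            return cat
        return self.post(cat)

    def penalty(self) -> Tensor:
        return (self.branch1.penalty() + self.branch2.penalty()
                + self.post.penalty())

    def parameters(self) -> list[Tensor]:
        return (self.branch1.parameters() + self.branch2.parameters()
                + self.post.parameters() + self.head.parameters())


def _validate_dataset(data: pd.DataFrame, descriptors: pd.DataFrame) -> None:
    for col in ("drug1", "drug2", "label"):
        if col not in data.columns:
            raise ValueError(f"DDI table missing column {col!r}")
    known = set(descriptors.index)
    missing = sorted((set(data["drug1"]) | set(data["drug2"])) - known)
    if missing:
        raise ValueError(f"drugs without descriptor rows: {missing[:5]}")
    labels = np.sort(data["label"].unique())
    if labels[0] != 0 or not np.array_equal(labels, np.arange(len(labels))):
        raise ValueError("DDI class labels must be dense 0..K-1")


def train_ddi(data: pd.DataFrame, descriptors: pd.DataFrame, config: ModelConfig,
              seed: int = 0, epochs: int | None = None,
              post_widths: list[int] | None = None) -> tuple[DDIModel, DDIReport]:
    """Train the interaction classifier on (drug1, drug2, label) rows.

    ``descriptors`` must already be cleaned and tanh-normalized, indexed by
    drug id. The 9:1 split is stratified by class; classes with fewer than
    two samples fall back to a plain random split (recorded as a warning).
    """
    _validate_dataset(data, descriptors)
    rng = np.random.default_rng(seed)
    epochs = config.epochs if epochs is None else epochs
    n_classes = int(data["label"].max()) + 1

    x1 = descriptors.loc[data["drug1"]].to_numpy(dtype=float)
    x2 = descriptors.loc[data["drug2"]].to_numpy(dtype=float)
    y = data["label"].to_numpy(dtype=int)

    warnings: list[str] = []
    idx = np.arange(len(y))
    counts = np.bincount(y, minlength=n_classes)
    stratified = counts.min() >= 2 and len(y) >= 10
    if not stratified:
        warnings.append(
            "a class has <2 samples; falling back to an unstratified split"
        )
    tr, va = train_test_split(
        idx, test_size=0.1, random_state=seed,
        stratify=y if stratified else None,
    )

    model = DDIModel(x1.shape[1], n_classes, config, rng, post_widths)
    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    losses: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(tr)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            opt.zero_grad()
            logits = model.forward(Tensor(x1[batch]), Tensor(x2[batch]),
                                   training=True, rng=rng)
            loss = cross_entropy(logits, y[batch]) + model.penalty()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        losses.append(epoch_loss / len(order))
    model.trained = epochs > 0

    logits = model.forward(Tensor(x1[va]), Tensor(x2[va]))
    pred = np.argmax(logits.data, axis=1)
    avg = "macro"
    metrics = {
        "accuracy": float(accuracy_score(y[va], pred)),
        "precision": float(precision_score(y[va], pred, average=avg, zero_division=0)),
        "recall": float(recall_score(y[va], pred, average=avg, zero_division=0)),
        "kappa": float(cohen_kappa_score(y[va], pred)),
        "f1": float(f1_score(y[va], pred, average=avg, zero_division=0)),
    }
    report = DDIReport(metrics, len(tr), len(va), seed, stratified, losses, warnings)
    return model, report


def extract_ddi_features(model: DDIModel, drug1: np.ndarray, drug2: np.ndarray,
                         allow_untrained: bool = False) -> np.ndarray:
    """Penultimate-layer interaction features for descriptor pairs.

    Accepts single vectors or (B, n_desc) batches; returns matching shape
    with ``model.penultimate_width`` features. The two branches are distinct,
    so (d1, d2) and (d2, d1) generally map to different vectors.
    """
    if not model.trained and not allow_untrained:
        raise RuntimeError("DDI model is untrained; pass allow_untrained=True to override")
    d1 = np.atleast_2d(np.asarray(drug1, dtype=float))
    d2 = np.atleast_2d(np.asarray(drug2, dtype=float))
    if d1.shape[1] != model.n_desc or d2.shape[1] != model.n_desc:
        raise ValueError(
            f"descriptor length mismatch: got {d1.shape[1]}/{d2.shape[1]}, "
            f"expected {model.n_desc}"
        )
    out = model.penultimate(Tensor(d1), Tensor(d2)).data
    return out[0] if np.asarray(drug1).ndim == 1 else out
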