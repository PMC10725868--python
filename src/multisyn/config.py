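"""Model and experiment configuration.

`ModelConfig` defaults are the published global setting of the synergy
network: drug chemical subnetwork [1024, 512, 256], cell subnetwork
[512, 256, 128], DDI subnetwork [1024, 512, 256], graph subnetwork
[258, 128], prediction heads [128, 64], dropout 0.2, 4 attention heads,
AdamW with lr 1e-5 and weight decay 0.025, 1000 epochs, batch size 64.
`tiny()` returns a scaled-down configuration suited to minutes-scale CPU
experiments on synthetic data.

Ablation toggles mirror the documented component-removal variants:
``cross_stitch`` off routes the task-attention outputs straight to the
prediction heads; ``feature_attention`` off replaces the per-task attention
with one rectified dense layer per task; ``interaction_attention`` off drops
the DDI branch and the cell↔DDI attention; ``graph_view_I`` off excludes the
node-label view from the graph embedding.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, Field


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    chem_widths: list[int] = [1024, 512, 256]
    cell_widths: list[int] = [512, 256, 128]
    ddi_widths: list[int] = [1024, 512, 256]
    graph_widths: list[int] = [258, 128]
    pred_widths: list[int] = [128, 64]
    dropout: float = Field(0.2, ge=0.0, lt=1.0)
    heads: int = Field(4, ge=1)
    token_dim: int = Field(16, ge=1)
    lr: float = Field(1e-5, gt=0)
    weight_decay: float = Field(0.025, ge=0)
    epochs: int = Field(1000, ge=0)
    batch_size: int = Field(64, ge=1)
    loss_weight_score: float = 1.0
    loss_weight_class: float = 1.0
    reg_weight: float = Field(1e-4, ge=0)
    reg_activity: float = Field(1e-5, ge=0)
    cs_dense_width: Optional[int] = None  # None → same as cross-stitch input
    share_qkv: bool = False
    scaled_attention: bool = False
    standardize_target: bool = True
    ddi_penultimate: str = "post"  # "post" (post-concat stack) or "branch"
    # ablation toggles (True = component present)
    cross_stitch: bool = True
    feature_attention: bool = True
    interaction_attention: bool = True
    graph_view_I: bool = True

    def validated(self) -> "ModelConfig":
        for name in ("chem_widths", "cell_widths", "ddi_widths", "graph_widths",
                     "pred_widths"):
            if any(w <= 0 for w in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        if self.token_dim % self.heads:
            raise ValueError("token_dim must be divisible by the head count")
        if self.ddi_penultimate not in ("post", "branch"):
            raise ValueError("ddi_penultimate must be 'post' or 'branch'")
        return self

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Small CPU-friendly configuration for synthetic-data experiments."""
        base = dict(
            chem_widths=[32, 16], cell_widths=[32, 16], ddi_widths=[32, 16],
            graph_widths=[16, 8], pred_widths=[16, 8],
            heads=2, token_dim=8, lr=1e-3, weight_decay=1e-4,
            epochs=200, batch_size=64,
        )
        base.update(overrides)
        return cls(**base).validated()
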