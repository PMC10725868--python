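"""Feature matrix preparation: descriptor cleaning, tanh normalization and
landmark-gene panel selection.

Feature matrices are pandas DataFrames with entity ids in the index (drugs or
cell lines) and features as columns. Cleaning drops columns that contain any
non-numeric or missing value, then columns with zero population variance.
Normalization is the bounded "tanh estimator"

    z = 0.5 * (tanh(c * (x - mu) / sigma) + 1),    c = 0.01 by default,

with per-column mean/SD estimated on training rows only (constant columns get
sigma = 1), mapping every finite input strictly into (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "clean_descriptors",
    "Normalizer",
    "fit_normalizer",
    "apply_normalizer",
    "select_gene_panel",
    "load_gene_panel",
]


class EmptyFeatureError(ValueError):
    """All feature columns were removed (or no genes intersect the panel)."""


def clean_descriptors(raw: pd.DataFrame) -> pd.DataFrame:
    """Drop non-numeric / missing-valued columns, then zero-variance ones.

    Column order is otherwise preserved. Idempotent. Requires at least two
    rows so the variance filter is defined.
    """
    if len(raw) < 1:
        raise ValueError("descriptor matrix has no rows")
    if len(raw) < 2:
        raise ValueError("variance filter needs >= 2 rows")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    keep = [c for c in raw.columns if np.isfinite(numeric[c].to_numpy(dtype=float)).all()]
    cleaned = numeric[keep]
    var = cleaned.var(axis=0, ddof=0)
    cleaned = cleaned.loc[:, var > 0.0]
    if cleaned.shape[1] == 0:
        raise EmptyFeatureError("no descriptor columns survived cleaning")
    return cleaned.astype(float)


@dataclass
class Normalizer:
    """Fitted per-column tanh-norm statistics."""

    columns: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    c: float = 0.01
    fitted: bool = field(default=True)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "columns": list(self.columns),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "c": self.c,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "Normalizer":
        d = json.loads(Path(path).read_text())
        return cls(d["columns"], np.asarray(d["mu"]), np.asarray(d["sigma"]), d["c"])


def fit_normalizer(train: pd.DataFrame, c: float = 0.01) -> Normalizer:
    """Estimate per-column mean and population SD on training rows.

    Columns with zero spread get sigma = 1 so they map to a constant 0.5.
    """
    if len(train) < 2:
        raise ValueError("need >= 2 training rows to fit a normalizer")
    x = train.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=0)
    sigma = np.where(sigma == 0.0, 1.0, sigma)
    return Normalizer(list(train.columns), mu, sigma, c)


def apply_normalizer(x: pd.DataFrame, norm: Normalizer) -> pd.DataFrame:
    """Map features into (0, 1) with the fitted tanh-norm statistics."""
    if not norm.fitted:
        raise ValueError("normalizer is not fitted")
    if list(x.columns) != list(norm.columns):
        extra = sorted(set(x.columns) - set(norm.columns))
        missing = sorted(set(norm.columns) - set(x.columns))
        raise ValueError(f"column mismatch: extra={extra}, missing={missing}")
    z = 0.5 * (np.tanh(norm.c * (x.to_numpy(dtype=float) - norm.mu) / norm.sigma) + 1.0)
    return pd.DataFrame(z, index=x.index, columns=x.columns)


def select_gene_panel(expr: pd.DataFrame, panel: list[str]) -> pd.DataFrame:
    """Keep the expression columns that intersect the landmark panel.

    Columns come back in panel order; the intersection size is recorded in
    ``result.attrs["n_intersection"]``.
    """
    if len(panel) != len(set(panel)):
        raise ValueError("gene panel contains duplicates")
    have = set(expr.columns)
    kept = [g for g in panel if g in have]
    if not kept:
        raise EmptyFeatureError("no genes shared between expression matrix and panel")
    out = expr[kept].copy()
    out.attrs["n_intersection"] = len(kept)
    return out


def load_gene_panel(path: str | Path) -> list[str]:
    """Read a one-gene-per-line panel file."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln]
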