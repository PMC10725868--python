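"""Synergy dataset assembly and grouped five-fold cross-validation.

The raw screen table has one row per measurement: (drug1, drug2, cell line,
Loewe additivity score), possibly with replicate measurements of the same
unordered drug pair on the same cell line. The pipeline is:

1. ``aggregate_replicates`` — average replicate scores per unique
   (unordered drug pair, cell line);
2. ``assign_class_labels`` — Loewe score > 30 → synergistic, < 0 →
   antagonistic, the closed interval [0, 30] → additive;
3. ``augment_reversed_pairs`` — append a drug-swapped twin of every row
   (2n rows total) so the model sees both input orders;
4. ``split_folds`` — five folds grouped so that the scheme's entity
   (unordered pair / cell line / first drug / second drug) never spans folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES",
    "ANTAGONISTIC",
    "ADDITIVE",
    "SYNERGISTIC",
    "SCHEMES",
    "FoldSplit",
    "aggregate_replicates",
    "assign_class_labels",
    "augment_reversed_pairs",
    "split_folds",
]

ANTAGONISTIC, ADDITIVE, SYNERGISTIC = 0, 1, 2
CLASS_NAMES = ("antagonistic", "additive", "synergistic")
SCHEMES = ("pair", "cell", "drug1", "drug2")
N_FOLDS = 5

REQUIRED_COLUMNS = ("drug1", "drug2", "cell", "score")


def _check_columns(rows: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"synergy table missing columns {missing}")


def aggregate_replicates(rows: pd.DataFrame) -> pd.DataFrame:
    """One record per unique (unordered drug pair, cell line), mean score.

    (a, b) and (b, a) measurements of the same combination are replicates of
    one pair; the surviving row stores the pair in sorted order. Output rows
    are sorted by (drug1, drug2, cell) so the result is independent of the
    input row order.
    """
    _check_columns(rows)
    scores = pd.to_numeric(rows["score"], errors="raise")
    lo = rows[["drug1", "drug2"]].min(axis=1)
    hi = rows[["drug1", "drug2"]].max(axis=1)
    flat = pd.DataFrame({"drug1": lo, "drug2": hi, "cell": rows["cell"], "score": scores})
    out = (
        flat.groupby(["drug1", "drug2", "cell"], as_index=False, sort=True)["score"]
        .mean()
    )
    return out.reset_index(drop=True)


def assign_class_labels(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the three-class Loewe label.

    Thresholds: score > 30 synergistic, score < 0 antagonistic, the boundary
    values 0 and 30 fall in the additive class (closed interval).
    """
    _check_columns(records)
    scores = records["score"].to_numpy(dtype=float)
    labels = np.full(len(records), ADDITIVE, dtype=int)
    labels[scores > 30.0] = SYNERGISTIC
    labels[scores < 0.0] = ANTAGONISTIC
    out = records.copy()
    out["label"] = labels
    return out


def augment_reversed_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Append the drug-swapped twin of every row (exactly 2n rows).

    Each original row is immediately followed by its reversal; score, class
    and cell are untouched. A provenance flag guards against running the
    augmentation twice.
    """
    _check_columns(records)
    if records.attrs.get("augmented", False) or "is_reversed" in records.columns:
        raise ValueError("records are already reversal-augmented")
    fwd = records.copy().reset_index(drop=True)
    rev = fwd.copy()
    rev[["drug1", "drug2"]] = fwd[["drug2", "drug1"]].to_numpy()
    fwd["is_reversed"] = False
    rev["is_reversed"] = True
    interleaved = (
        pd.concat([fwd, rev])
        .sort_index(kind="stable")
        .reset_index(drop=True)
    )
    interleaved.attrs["augmented"] = True
    return interleaved


@dataclass(frozen=True)
class FoldSplit:
    """Fold assignment for one grouping scheme and seed."""

    scheme: str
    seed: int
    fold_of_sample: np.ndarray  # (n_samples,) ints in 0..4

    @property
    def n_folds(self) -> int:
        return N_FOLDS

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample != fold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": np.arange(len(self.fold_of_sample)),
            "fold": self.fold_of_sample,
            "scheme": self.scheme,
            "seed": self.seed,
        })


def _group_keys(records: pd.DataFrame, scheme: str) -> pd.Series:
    if scheme == "pair":
        lo = records[["drug1", "drug2"]].min(axis=1)
        hi = records[["drug1", "drug2"]].max(axis=1)
        return lo.astype(str) + "||" + hi.astype(str)
    if scheme == "cell":
        return records["cell"].astype(str)
    if scheme in ("drug1", "drug2"):
        return records[scheme].astype(str)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def split_folds(records: pd.DataFrame, scheme: str, seed: int) -> FoldSplit:
    """Grouped five-fold assignment.

    The distinct group entities of the scheme are shuffled with the seed and
    dealt round-robin into five folds, so fold sizes differ by at most one
    group and no entity spans folds. Under the pair scheme a row and its
    reversed twin share the unordered-pair key, hence the fold.
    """
    keys = _group_keys(records, scheme)
    entities = sorted(keys.unique())
    if len(entities) < N_FOLDS:
        raise ValueError(
            f"scheme {scheme!r} has {len(entities)} group entities; need >= {N_FOLDS}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entities))
    fold_of_entity = {entities[idx]: pos % N_FOLDS for pos, idx in enumerate(order)}
    folds = keys.map(fold_of_entity).to_numpy(dtype=int)
    return FoldSplit(scheme, seed, folds)
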