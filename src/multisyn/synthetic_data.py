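"""Seeded synthetic stand-ins for the four external inputs.

`generate_world` builds, from a single seed, a self-consistent miniature of
the data a synergy study consumes:

* a drug table mapping drug ids to valid SMILES drawn from a fixed bank of
  drug-like small molecules;
* a chemical-descriptor matrix with deliberately planted dirty columns (one
  non-numeric, one with missing values, one zero-variance) that the cleaning
  step must remove;
* a gene-expression matrix over a named gene panel, with a landmark panel
  file planted to intersect the matrix in exactly ``panel_overlap`` genes
  (875 by default, emulating the landmark-gene selection);
* a DDI pair table whose class is a linear rule on the two drugs'
  descriptors, so the interaction classifier is learnable;
* a replicated synergy table with planted additive structure,

      score = mu + a(drug1) + a(drug2) + b(cell) + gamma * I(pair) + eps,

  with drug effects a ~ N(0, drug_sd²), cell effects b ~ N(0, cell_sd²), a
  pair-specific interaction I ~ N(0, 1) scaled by gamma and replicate noise
  eps ~ N(0, noise_sd²). Replicates share everything but eps. The default
  scales span all three Loewe label regimes (< 0, [0, 30], > 30).

Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["WorldParams", "SyntheticWorld", "SMILES_BANK", "generate_world", "write_world"]

#: valid drug-like molecules (verified parseable); ids are assigned in order
SMILES_BANK: tuple[str, ...] = (
    "CCO", "CC(=O)O", "CC(=O)Oc1ccccc1C(=O)O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "c1ccccc1", "Cc1ccccc1", "Oc1ccccc1",
    "Nc1ccccc1", "Clc1ccccc1", "CCN(CC)CC", "CC(C)O", "CCCCCC", "C1CCCCC1",
    "C1CCOC1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "CC(=O)Nc1ccc(O)cc1",
    "OC(=O)c1ccccc1O", "CN1CCC[C@H]1c1cccnc1", "CC(N)Cc1ccccc1",
    "NCCc1ccc(O)c(O)c1", "OCC(O)CO", "CC(=O)NC1=CC=C(C=C1)O", "C1CCNCC1",
    "O=C(O)CCC(=O)O", "OC(=O)C(O)C(O)C(=O)O", "CCOC(=O)C", "CC(=O)C",
    "CCC(=O)O", "NC(=O)c1ccccc1", "COc1ccccc1", "CSc1ccccc1", "FC(F)(F)c1ccccc1",
    "O=S(=O)(N)c1ccccc1", "CC1=CC(=O)C=CC1=O", "Oc1ccc2ccccc2c1",
    "c1ccc2ncccc2c1", "c1ccc2[nH]ccc2c1", "OCCN1CCNCC1", "CN(C)CCCN",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1", "CN1CCN(CC1)c1ccccc1",
    "O=C1CCCN1", "O=C1NC(=O)NC(=O)C1", "NC1CCCCC1", "OC1CCCCC1",
    "N#Cc1ccccc1", "O=Cc1ccccc1",
)


@dataclass(frozen=True)
class WorldParams:
    """Generator settings; defaults are the package's study conditions."""

    n_drugs: int = 20
    n_cells: int = 10
    n_genes: int = 1200
    n_panel: int = 1000
    panel_overlap: int = 875
    n_descriptors: int = 24
    n_ddi_classes: int = 6
    n_ddi_pairs: int = 300
    #: minimum gap between the best and second-best class score of a pair;
    #: pairs closer to a class boundary are not emitted, so the planted
    #: classes are separable with a margin and genuinely learnable
    ddi_margin: float = 2.0
    n_synergy: int = 600
    replicate_frac: float = 0.3
    mu: float = 10.0
    drug_sd: float = 10.0
    cell_sd: float = 10.0
    gamma: float = 2.0
    noise_sd: float = 5.0

    def __post_init__(self):
        if min(self.n_drugs, self.n_cells, self.n_genes, self.n_ddi_classes,
               self.n_descriptors, self.n_synergy) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_drugs > len(SMILES_BANK):
            raise ValueError(f"at most {len(SMILES_BANK)} drugs available")
        if self.panel_overlap > min(self.n_panel, self.n_genes):
            raise ValueError("panel_overlap exceeds panel or gene count")


@dataclass
class SyntheticWorld:
    """All generated tables plus the planted ground-truth effects."""

    seed: int
    params: WorldParams
    drugs: pd.DataFrame        # index drug_id, column smiles
    descriptors: pd.DataFrame  # index drug_id, with planted dirty columns
    expression: pd.DataFrame   # index cell_id, gene columns
    gene_panel: list[str]
    ddi: pd.DataFrame          # drug1, drug2, label
    synergy: pd.DataFrame      # drug1, drug2, cell, score (replicated rows)
    drug_effects: dict[str, float] = field(repr=False, default_factory=dict)
    cell_effects: dict[str, float] = field(repr=False, default_factory=dict)


def generate_world(params: WorldParams | None = None, seed: int = 0) -> SyntheticWorld:
    params = params or WorldParams()
    rng = np.random.default_rng(seed)

    drug_ids = [f"D{i:03d}" for i in range(params.n_drugs)]
    cell_ids = [f"CL{i:02d}" for i in range(params.n_cells)]
    gene_ids = [f"G{i:04d}" for i in range(params.n_genes)]

    drugs = pd.DataFrame({"smiles": list(SMILES_BANK[: params.n_drugs])},
                         index=pd.Index(drug_ids, name="drug_id"))

    # descriptors: clean numeric block + planted dirty columns
    desc = rng.normal(size=(params.n_drugs, params.n_descriptors))
    columns = [f"desc_{j:02d}" for j in range(params.n_descriptors)]
    descriptors = pd.DataFrame(desc, index=drugs.index, columns=columns)
    descriptors["category"] = [f"cat{i % 3}" for i in range(params.n_drugs)]  # non-numeric
    missing = descriptors["desc_00"].copy().astype(object)
    missing.iloc[0] = None
    descriptors["desc_missing"] = missing
    descriptors["desc_const"] = 1.0  # zero variance

    # expression + landmark panel with planted intersection size
    expr = rng.normal(loc=5.0, scale=2.0, size=(params.n_cells, params.n_genes))
    expression = pd.DataFrame(expr, index=pd.Index(cell_ids, name="cell_id"),
                              columns=gene_ids)
    shared = list(rng.choice(gene_ids, size=params.panel_overlap, replace=False))
    extra = [f"GX{i:04d}" for i in range(params.n_panel - params.panel_overlap)]
    panel = shared + extra
    rng.shuffle(panel)

    # DDI pairs: class = argmax of K linear scores on concatenated
    # descriptors, keeping only pairs at least ddi_margin away from the
    # nearest class boundary
    w = rng.normal(size=(2 * params.n_descriptors, params.n_ddi_classes))
    all_pairs = [(i, j) for i in range(params.n_drugs)
                 for j in range(i + 1, params.n_drugs)]
    feats_all = np.hstack([desc[[i for i, _ in all_pairs]],
                           desc[[j for _, j in all_pairs]]])
    scores = feats_all @ w
    top2 = np.sort(scores, axis=1)[:, -2:]
    eligible = np.flatnonzero(top2[:, 1] - top2[:, 0] >= params.ddi_margin)
    n_pairs = min(params.n_ddi_pairs, len(eligible))
    chosen = np.sort(rng.choice(eligible, size=n_pairs, replace=False))
    pair_list = [all_pairs[k] for k in chosen]
    raw_labels = np.argmax(scores[chosen], axis=1)
    # re-index to dense 0..K'-1 in case a class never wins the argmax
    present = np.unique(raw_labels)
    dense = {c: k for k, c in enumerate(present)}
    ddi = pd.DataFrame({
        "drug1": [drug_ids[i] for i, _ in pair_list],
        "drug2": [drug_ids[j] for _, j in pair_list],
        "label": [dense[c] for c in raw_labels],
    })

    # synergy: additive planted structure with replicates
    a = rng.normal(scale=params.drug_sd, size=params.n_drugs)
    b = rng.normal(scale=params.cell_sd, size=params.n_cells)
    interaction: dict[tuple[int, int], float] = {}
    rows = []
    n_unique = max(1, int(round(params.n_synergy / (1 + params.replicate_frac))))
    for _ in range(n_unique):
        i, j = rng.choice(params.n_drugs, size=2, replace=False)
        c = int(rng.integers(params.n_cells))
        key = (min(i, j), max(i, j))
        if key not in interaction:
            interaction[key] = float(rng.normal())
        base = (params.mu + a[i] + a[j] + b[c]
                + params.gamma * interaction[key])
        n_rep = 2 if rng.random() < params.replicate_frac else 1
        for _ in range(n_rep):
            rows.append((drug_ids[i], drug_ids[j], cell_ids[c],
                         base + rng.normal(scale=params.noise_sd)))
    synergy = pd.DataFrame(rows, columns=["drug1", "drug2", "cell", "score"])

    return SyntheticWorld(
        seed=seed, params=params, drugs=drugs, descriptors=descriptors,
        expression=expression, gene_panel=panel, ddi=ddi, synergy=synergy,
        drug_effects={drug_ids[i]: float(a[i]) for i in range(params.n_drugs)},
        cell_effects={cell_ids[c]: float(b[c]) for c in range(params.n_cells)},
    )


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write the five fixture files in the schemas the readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": out / "drugs.csv",
        "descriptors": out / "descriptors.csv",
        "expression": out / "expression.csv",
        "gene_panel": out / "gene_panel.txt",
        "ddi": out / "ddi.csv",
        "synergy": out / "synergy.csv",
    }
    world.drugs.to_csv(paths["drugs"])
    world.descriptors.to_csv(paths["descriptors"])
    world.expression.to_csv(paths["expression"])
    paths["gene_panel"].write_text("\n".join(world.gene_panel) + "\n")
    world.ddi.to_csv(paths["ddi"], index=False)
    world.synergy.to_csv(paths["synergy"], index=False)
    return paths
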