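"""Featurization pipeline, end-to-end CV runner, checkpoints and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from typer.testing import CliRunner

import multisyn.data_pipeline as dp
from multisyn import checkpoint
from multisyn.cli import app
from multisyn.config import ModelConfig
from multisyn.experiment import ExperimentConfig, prepare_records, run_cv_experiment
from multisyn.pipeline import FeaturePipeline, GraphFeaturizer
from multisyn.synergy_model import assemble, predict
from multisyn.synthetic_data import WorldParams, generate_world, write_world

SMALL = WorldParams(n_drugs=8, n_cells=5, n_genes=60, n_panel=50,
                    panel_overlap=30, n_ddi_pairs=28, n_ddi_classes=3,
                    n_synergy=120)
GRAPH_DIMS = {"I": 16, "II": 32, "III": 16, "IV": 32}


@pytest.fixture(scope="module")
def small_world():
    return generate_world(SMALL, seed=5)


@pytest.fixture(scope="module")
def tiny_experiment():
    return ExperimentConfig(model=ModelConfig.tiny(epochs=2), ddi_epochs=2, seed=5)


class TestGraphFeaturizer:
    def test_embedding_width_and_determinism(self, small_world):
        feat = GraphFeaturizer(GRAPH_DIMS).fit(small_world.drugs["smiles"])
        mat = feat.embed_all(small_world.drugs["smiles"])
        assert mat.shape == (SMALL.n_drugs, feat.n_out)
        assert feat.n_out == sum(GRAPH_DIMS.values())
        mat2 = GraphFeaturizer(GRAPH_DIMS).fit(
            small_world.drugs["smiles"]).embed_all(small_world.drugs["smiles"])
        pd.testing.assert_frame_equal(mat, mat2)

    def test_view_I_excluded_when_disabled(self, small_world):
        feat = GraphFeaturizer(GRAPH_DIMS, include_view_I=False)
        feat.fit(small_world.drugs["smiles"])
        assert feat.n_out == GRAPH_DIMS["II"] + GRAPH_DIMS["III"] + GRAPH_DIMS["IV"]


class TestFeaturePipeline:
    def _fitted(self, world):
        records = prepare_records(world.synergy)
        cfg = ModelConfig.tiny(interaction_attention=False)
        pipe = FeaturePipeline(cfg, graph_dims=GRAPH_DIMS)
        pipe.fit(records, world.drugs, world.descriptors, world.expression,
                 world.gene_panel)
        return pipe, records

    def test_transform_matches_declared_dims(self, small_world):
        pipe, records = self._fitted(small_world)
        batch = pipe.transform(records.head(10))
        dims = pipe.feature_dims()
        assert batch.desc1.shape == (10, dims.descriptor)
        assert batch.graph1.shape == (10, dims.graph)
        assert batch.cell.shape == (10, dims.cell)
        assert batch.ddi is None

    def test_features_bounded_by_tanh_norm(self, small_world):
        pipe, records = self._fitted(small_world)
        batch = pipe.transform(records)
        for arr in (batch.desc1, batch.desc2, batch.graph1, batch.cell):
            assert (arr > 0).all() and (arr < 1).all()

    def test_planted_dirty_columns_removed(self, small_world):
        pipe, _ = self._fitted(small_world)
        assert "category" not in pipe.desc_columns_
        assert "desc_const" not in pipe.desc_columns_

    def test_unknown_entities_listed(self, small_world):
        pipe, records = self._fitted(small_world)
        bad = records.head(2).copy()
        bad.loc[bad.index[0], "drug1"] = "D999"
        with pytest.raises(KeyError, match="D999"):
            pipe.transform(bad)

    def test_statistics_come_from_training_rows_only(self, small_world):
        records = prepare_records(small_world.synergy)
        split = dp.split_folds(records, "cell", seed=0)
        tr = records.iloc[split.train_indices(0)]
        cfg = ModelConfig.tiny(interaction_attention=False)
        pipe = FeaturePipeline(cfg, graph_dims=GRAPH_DIMS)
        pipe.fit(tr, small_world.drugs, small_world.descriptors,
                 small_world.expression, small_world.gene_panel)
        train_cells = sorted(set(tr["cell"]))
        expr = small_world.expression.loc[train_cells, pipe.gene_columns_]
        np.testing.assert_allclose(pipe.expr_norm_.mu,
                                   expr.to_numpy().mean(axis=0), atol=1e-12)


class TestRunCV:
    def test_cell_scheme_one_cell_per_fold(self, small_world, tiny_experiment):
        cfg = tiny_experiment.model_copy(update={"scheme": "cell"})
        res = run_cv_experiment(
            small_world.synergy, small_world.drugs, small_world.descriptors,
            small_world.expression, small_world.gene_panel, small_world.ddi,
            config=cfg, graph_dims=GRAPH_DIMS)
        records = prepare_records(small_world.synergy)
        split = dp.split_folds(records, "cell", cfg.seed)
        for f in range(5):
            assert records.iloc[split.test_indices(f)]["cell"].nunique() == 1
        assert len(res.folds) == 5
        assert set(res.reports) >= {"mse", "rmse"}
        assert res.ddi_report is not None

    def test_rerun_is_deterministic(self, small_world, tiny_experiment):
        cfg = tiny_experiment.model_copy(update={"folds": [0]})
        kw = dict(config=cfg, graph_dims=GRAPH_DIMS)
        r1 = run_cv_experiment(small_world.synergy, small_world.drugs,
                               small_world.descriptors, small_world.expression,
                               small_world.gene_panel, small_world.ddi, **kw)
        r2 = run_cv_experiment(small_world.synergy, small_world.drugs,
                               small_world.descriptors, small_world.expression,
                               small_world.gene_panel, small_world.ddi, **kw)
        assert r1.folds[0].regression == r2.folds[0].regression
        assert r1.folds[0].classification == r2.folds[0].classification

    def test_artifacts_written(self, small_world, tiny_experiment, tmp_path):
        cfg = tiny_experiment.model_copy(
            update={"folds": [0], "out_dir": str(tmp_path / "run")})
        run_cv_experiment(small_world.synergy, small_world.drugs,
                          small_world.descriptors, small_world.expression,
                          small_world.gene_panel, small_world.ddi,
                          config=cfg, graph_dims=GRAPH_DIMS)
        out = tmp_path / "run"
        assert (out / "config.json").exists()
        assert (out / "fold_assignment.csv").exists()
        assert (out / "fold_metrics.json").exists()
        resolved = json.loads((out / "config.json").read_text())
        assert resolved["scheme"] == "pair" and resolved["seed"] == 5

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(Exception):
            ExperimentConfig(schemes="pair")

    def test_bad_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            ExperimentConfig(scheme="tissue").validated()


class TestCheckpoints:
    def test_synergy_model_round_trip(self, tmp_path, rng):
        from test_synergy_model import DIMS, make_batch
        cfg = ModelConfig.tiny()
        model = assemble(cfg, DIMS, seed=3)
        model.y_mean, model.y_std, model.trained = 4.2, 2.5, True
        checkpoint.save_synergy_model(model, tmp_path)
        loaded = checkpoint.load_synergy_model(tmp_path)
        batch = make_batch(rng, n=4)
        a, b = predict(model, batch), predict(loaded, batch)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_ddi_model_round_trip(self, tmp_path, rng):
        from multisyn.ddi_pretrain import DDIModel, extract_ddi_features
        cfg = ModelConfig.tiny()
        model = DDIModel(5, 3, cfg, np.random.default_rng(1), post_widths=[6])
        model.trained = True
        checkpoint.save_ddi_model(model, cfg, tmp_path)
        loaded = checkpoint.load_ddi_model(tmp_path)
        d1, d2 = rng.random((2, 5)), rng.random((2, 5))
        np.testing.assert_array_equal(
            extract_ddi_features(model, d1, d2),
            extract_ddi_features(loaded, d1, d2))


class TestCLI:
    def test_simulate_and_featurize(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "world"
        res = runner.invoke(app, ["simulate", "--seed", "3", "--out", str(out),
                                  "--n-drugs", "6", "--n-cells", "5",
                                  "--n-synergy", "40"])
        assert res.exit_code == 0, res.output
        assert (out / "synergy.csv").exists()
        res = runner.invoke(app, ["featurize", str(out / "drugs.csv"),
                                  "--out", str(tmp_path / "g.csv"),
                                  "--dims", "8,16,8,16"])
        assert res.exit_code == 0, res.output
        emb = pd.read_csv(tmp_path / "g.csv", index_col=0)
        assert emb.shape == (6, 48)
        vocab = json.loads((tmp_path / "g.vocab.json").read_text())
        assert vocab["dims"]["I"] == 8 and vocab["label_map"]

    def test_pretrain_ddi_command(self, tmp_path, small_world):
        runner = CliRunner()
        data = tmp_path / "w"
        write_world(small_world, data)
        res = runner.invoke(app, ["pretrain-ddi", str(data / "ddi.csv"),
                                  str(data / "descriptors.csv"),
                                  "--out", str(tmp_path / "ddi"),
                                  "--epochs", "1", "--seed", "0"])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "ddi" / "report.json").exists()
        assert (tmp_path / "ddi" / "ddi_params.npz").exists()

    def test_train_single_fold_command(self, tmp_path, small_world):
        runner = CliRunner()
        data = tmp_path / "w"
        write_world(small_world, data)
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "model:\n  chem_widths: [32, 16]\n  cell_widths: [32, 16]\n"
            "  ddi_widths: [32, 16]\n  graph_widths: [16, 8]\n"
            "  pred_widths: [16, 8]\n  heads: 2\n  token_dim: 8\n"
            "  lr: 0.001\n  weight_decay: 0.0001\n  epochs: 1\n"
            "  interaction_attention: false\n"
            "ddi_epochs: 1\n")
        res = runner.invoke(app, ["train", str(data), "--fold", "0",
                                  "--config", str(cfg),
                                  "--out", str(tmp_path / "run")])
        assert res.exit_code == 0, res.output
        assert "mse" in res.output
        assert (tmp_path / "run" / "fold_metrics.json").exists()
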