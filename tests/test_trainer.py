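"""Model assembly, batching invariance, gradient flow, ablation switches."""

import numpy as np
import pandas as pd
import pytest

from bsdti import SynthSpec, make_pairs
from bsdti.trainer import (ABLATION_FLAGS, DTIModel, ModelConfig, ablate,
                           build_batches, train_val_split)

from conftest import reduced_config


@pytest.fixture(scope="module")
def tiny_data():
    return make_pairs(SynthSpec(n_drugs=16, n_proteins=12, n_pairs=48,
                                label_noise=0.0, seed=13)).dataset


def tiny_config(**kw):
    base = dict(hidden_dim=16, protein_scales=(16, 8), decoder_hidden=32,
                head_hidden=32, decoder_heads=4, gat_layers=2,
                drug_tokens=4, batch_size=16, max_epochs=2, patience=5,
                seed=0, dtype="float64")
    base.update(kw)
    return ModelConfig(**base)


class TestConfig:
    def test_reference_defaults(self):
        cfg = ModelConfig()
        assert cfg.gat_layers == 3
        assert cfg.hidden_dim == 80
        assert cfg.drug_tokens == 8
        assert cfg.protein_scales == (1024, 512, 256, 128)
        assert cfg.top_k_percent == 30.0
        assert (cfg.decoder_layers, cfg.decoder_heads,
                cfg.decoder_hidden) == (3, 8, 256)
        assert cfg.cl_weight == 0.01
        assert cfg.lr == 0.001 and cfg.lr_decay_per_epoch == 0.10
        assert cfg.batch_size == 128

    def test_lr_schedule_multiplicative(self):
        from bsdti._nn import Adam
        from bsdti._tensor import Tensor

        opt = Adam({"w": Tensor(np.zeros(1), requires_grad=True)}, lr=0.001)
        opt.set_epoch(2)
        assert opt.lr == pytest.approx(0.00081)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(top_k_percent=0)
        with pytest.raises(ValueError):
            ModelConfig(ablation="bogus")

    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config(seed=7)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        again = ModelConfig.from_yaml(tmp_path / "cfg.yaml")
        assert again == cfg


class TestForwardAndPredict:
    def test_probabilities_within_unit_interval(self, tiny_data):
        model = DTIModel(tiny_config())
        df = model.predict(tiny_data)
        assert len(df) == len(tiny_data)
        assert ((df.probability > 0) & (df.probability < 1)).all()
        assert set(df.prediction) <= {0, 1}

    def test_empty_pair_list_gives_empty_table(self, tiny_data):
        model = DTIModel(tiny_config())
        df = model.predict(tiny_data.subset([]))
        assert len(df) == 0
        assert "probability" in df.columns

    def test_scores_invariant_to_batch_partition(self, tiny_data):
        """Same pairs scored with batch 1 vs batch 128 must agree."""
        model = DTIModel(tiny_config())
        a = model.predict(tiny_data)["probability"].to_numpy()
        model.cfg.batch_size = 1
        b = model.predict(tiny_data)["probability"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_forward_deterministic(self, tiny_data):
        pa = DTIModel(tiny_config()).predict(tiny_data)
        pb = DTIModel(tiny_config()).predict(tiny_data)
        np.testing.assert_array_equal(pa.probability.to_numpy(),
                                      pb.probability.to_numpy())

    def test_batches_cover_every_pair_once(self, tiny_data):
        cfg = tiny_config()
        batches = build_batches(tiny_data, range(len(tiny_data)),
                                cfg.batch_size, cfg)
        positions = np.concatenate([b.positions for b in batches])
        assert sorted(positions) == list(range(len(tiny_data)))


class TestGradientFlow:
    def test_one_step_changes_every_component(self, tiny_data):
        """After one optimizer step on a mixed batch, parameters of the
        extractor (GAT, pooling, selector score nets) and decoder all move."""
        from bsdti._nn import Adam

        cfg = tiny_config()
        model = DTIModel(cfg)
        params = model.parameters()
        before = {k: v.data.copy() for k, v in params.items()}
        batch = build_batches(tiny_data, range(16), 16, cfg)[0]
        out = model.forward_batch(batch)
        loss = model.loss(out, batch.y)
        opt = Adam(params, lr=1e-3)
        loss.backward()
        opt.step()
        moved = {k for k in params if not
                 np.array_equal(before[k], params[k].data)}
        for component in ("extractor.drug_msgn", "extractor.prot_msgn",
                          "extractor.selectors.0.ffd",
                          "extractor.prot_pools",
                          "decoder.layers", "decoder.head"):
            assert any(component in k for k in moved), \
                f"no parameter of {component} moved"


class TestTrainingLoop:
    def test_two_runs_same_seed_identical_history(self, tiny_data):
        tr, va = train_val_split(tiny_data, 0.25, 3)
        h1 = DTIModel(tiny_config()).fit(tr, va)
        h2 = DTIModel(tiny_config()).fit(tr, va)
        pd.testing.assert_frame_equal(h1, h2)

    def test_validation_needs_both_classes(self, tiny_data):
        labels = tiny_data.labels
        pos_only = tiny_data.subset(np.flatnonzero(labels == 1))
        with pytest.raises(ValueError, match="both classes"):
            DTIModel(tiny_config()).fit(tiny_data, pos_only)

    def test_divergence_aborts_with_diagnostic(self, tiny_data):
        tr, va = train_val_split(tiny_data, 0.25, 3)
        model = DTIModel(tiny_config(max_epochs=3))
        # corrupt one weight: the non-finite loss must abort, not propagate
        key = next(iter(model.parameters()))
        model.parameters()[key].data[...] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            model.fit(tr, va)

    def test_save_load_round_trip(self, tiny_data, tmp_path):
        model = DTIModel(tiny_config())
        a = model.predict(tiny_data)["probability"].to_numpy()
        model.save(tmp_path / "run")
        again = DTIModel.load(tmp_path / "run")
        b = again.predict(tiny_data)["probability"].to_numpy()
        np.testing.assert_array_equal(a, b)


class TestAblations:
    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError, match="unknown ablation"):
            ablate(tiny_config(), "definitely_not_a_flag")

    def test_no_cl_removes_complementary_term(self, tiny_data):
        cfg = tiny_config()
        model = ablate(cfg, "no_cl")
        batch = build_batches(tiny_data, range(16), 16, model.cfg)[0]
        out = model.forward_batch(batch)
        from bsdti.objective import bce_with_logits

        loss_no_aux = model.cfg.aux_pool_weight
        model.cfg.aux_pool_weight = 0.0
        loss = model.loss(out, batch.y)
        assert float(loss.data) == pytest.approx(
            float(bce_with_logits(out["logits"], batch.y).data))
        model.cfg.aux_pool_weight = loss_no_aux

    def test_no_topk_elects_every_token(self, tiny_data):
        model = ablate(tiny_config(), "no_topk")
        batch = build_batches(tiny_data, range(8), 8, model.cfg)[0]
        out = model.forward_batch(batch)
        for idx, scale in zip(out["indices"], batch.eff_scales):
            assert idx.shape[1] == scale

    def test_no_mmcmse_uses_single_scale(self, tiny_data):
        model = ablate(tiny_config(), "no_mmcmse")
        batch = build_batches(tiny_data, range(8), 8, model.cfg)[0]
        out = model.forward_batch(batch)
        assert len(out["indices"]) == 1

    def test_no_mmsid_replaces_decoder(self):
        model = ablate(tiny_config(), "no_mmsid")
        assert model.decoder is None
        assert hasattr(model, "pool_head")

    def test_every_flag_assembles_and_scores(self, tiny_data):
        for flag in ABLATION_FLAGS:
            model = ablate(tiny_config(), flag)
            df = model.predict(tiny_data.subset(range(6)))
            assert len(df) == 6
            assert np.isfinite(df.probability).all()
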