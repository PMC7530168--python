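import numpy as np
import pytest

from connectopred.models import (
    CNNSpec,
    DNNSpec,
    OutcomeModel,
    SklearnSpec,
    TLCNNSpec,
    TLDNNSpec,
    TrainConfig,
    build_baseline,
    build_model,
    pretrain_unsupervised,
)
from connectopred.simulate import GeneratorConfig, generate_cohort, generate_source_cohort


class TestBaselineGrids:
    def test_lr_grid_has_five_values(self):
        spec = build_baseline("lr")
        assert spec.grid == (1e-3, 1e-2, 1e-1, 1.0, 10.0)

    def test_svm_c_grid_has_seven_powers_of_two(self):
        spec = build_baseline("svm-linear")
        assert spec.grid == tuple(2.0 ** k for k in range(-3, 4))

    def test_dnn_hidden_widths(self):
        assert DNNSpec().units == (256, 64)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model("random-forest")

    def test_tlcnn_is_not_a_baseline(self):
        with pytest.raises(ValueError):
            build_baseline("tl-cnn")


class TestTLCNN:
    def test_backbone_frozen_through_training(self, tiny_fitted_tlcnn):
        assert (tiny_fitted_tlcnn.backbone.checksum()
                == tiny_fitted_tlcnn.backbone_checksum)

    def test_architecture_audit(self, tiny_fitted_tlcnn):
        assert tiny_fitted_tlcnn.n_backbone_conv_layers == 16
        assert len(tiny_fitted_tlcnn.head_conv_layers) == 2
        assert all(c.out_channels == 256
                   for c in tiny_fitted_tlcnn.head_conv_layers)

    def test_probabilities_in_unit_interval(self, tiny_fitted_tlcnn,
                                            planted_cohort):
        preds = tiny_fitted_tlcnn.predict(planted_cohort)
        assert len(preds) == len(planted_cohort)
        assert all(0.0 <= p.p <= 1.0 for p in preds)
        assert [p.subject_id for p in preds] == list(planted_cohort.ids)

    def test_prediction_is_pure_function(self, tiny_fitted_tlcnn,
                                         planted_cohort):
        from connectopred.connectome import Cohort, Subject

        s = planted_cohort[0]
        twin = Cohort((s, Subject("twin", s.connectome, s.score)))
        a = tiny_fitted_tlcnn.predict_values(twin)
        assert a[0] == a[1]

    def test_same_seed_reproduces_head_parameters(self, planted_cohort,
                                                  shared_backbone):
        def fit():
            spec = TLCNNSpec(train_config=TrainConfig(epochs=2, seed=5),
                             backbone=shared_backbone)
            return spec.fit(planted_cohort.subset(range(20)),
                            planted_cohort.subset(range(20, 28)))

        f1, f2 = fit(), fit()
        for p1, p2 in zip(f1.head.params, f2.head.params):
            assert np.array_equal(p1.value, p2.value)
        assert f1.history == f2.history

    def test_training_loss_decreases_on_separable_cohort(self,
                                                         tiny_fitted_tlcnn):
        losses = tiny_fitted_tlcnn.history["train_loss"]
        assert losses[-1] <= losses[0]

    def test_regression_outputs_are_finite_scores(self, planted_cohort,
                                                  shared_backbone):
        spec = TLCNNSpec(task="regression",
                         train_config=TrainConfig(epochs=2, seed=0),
                         backbone=shared_backbone)
        fitted = spec.fit(planted_cohort.subset(range(24)),
                          planted_cohort.subset(range(24, 32)))
        out = fitted.predict_values(planted_cohort.subset(range(32, 40)))
        assert np.all(np.isfinite(out))
        # on the score scale, not the standardized one
        assert 0 < out.mean() < 200

    def test_atlas_mismatch_rejected(self, tiny_fitted_tlcnn, planted_cohort,
                                     tmp_path):
        from connectopred.atlas import load_atlas
        from connectopred.connectome import Cohort, Connectome, Subject

        rows = [
            f"{r.index},{r.name},X{r.abbreviation},{r.lobe}"
            for r in planted_cohort.atlas.regions
        ]
        (tmp_path / "other.csv").write_text("\n".join(rows))
        other = load_atlas(tmp_path / "other.csv")
        s = planted_cohort[0]
        cohort2 = Cohort((Subject(s.id, Connectome(s.connectome.matrix, other),
                                  s.score),))
        with pytest.raises(ValueError, match="atlas"):
            tiny_fitted_tlcnn.predict_values(cohort2)


class TestVectorAndConvBaselines:
    @pytest.mark.parametrize("kind", ["lr", "svm-linear", "svm-rbf"])
    def test_sklearn_classifiers_emit_probabilities(self, kind, planted_cohort):
        spec = SklearnSpec(kind=kind)
        fitted = spec.fit(planted_cohort.subset(range(28)),
                          planted_cohort.subset(range(28, 36)))
        p = fitted.predict_values(planted_cohort.subset(range(36, 40)))
        assert np.all((0 <= p) & (p <= 1))

    def test_sklearn_regression_predicts_scores(self, planted_cohort):
        spec = SklearnSpec(kind="svm-linear", task="regression")
        fitted = spec.fit(planted_cohort.subset(range(28)),
                          planted_cohort.subset(range(28, 36)))
        out = fitted.predict_values(planted_cohort.subset(range(36, 40)))
        assert np.all(np.isfinite(out))

    def test_dnn_trains_and_predicts(self, planted_cohort):
        spec = DNNSpec(train_config=TrainConfig(epochs=3, seed=0))
        fitted = spec.fit(planted_cohort.subset(range(28)),
                          planted_cohort.subset(range(28, 36)))
        p = fitted.predict_values(planted_cohort.subset(range(36, 40)))
        assert np.all((0 <= p) & (p <= 1))
        assert len(fitted.history["train_loss"]) == 3

    def test_cnn_trains_on_matrices(self, planted_cohort):
        spec = CNNSpec(train_config=TrainConfig(epochs=1, seed=0, batch_size=8))
        fitted = spec.fit(planted_cohort.subset(range(12)),
                          planted_cohort.subset(range(12, 16)))
        p = fitted.predict_values(planted_cohort.subset(range(16, 20)))
        assert np.all((0 <= p) & (p <= 1))


@pytest.fixture(scope="module")
def source():
    return generate_source_cohort(40, seed=21)


class TestUnsupervisedPretraining:
    def test_reconstruction_loss_decreases(self, source):
        result = pretrain_unsupervised(source, epochs=8, seed=0)
        assert result["history"][-1] < result["history"][0]

    def test_deterministic_under_fixed_seed(self, source):
        a = pretrain_unsupervised(source, epochs=2, seed=3)
        b = pretrain_unsupervised(source, epochs=2, seed=3)
        for x, y in zip(a["params"], b["params"]):
            assert np.array_equal(x, y)

    def test_initialization_differs_from_random(self, source, planted_cohort):
        from connectopred.nn import checksum_params

        pre = pretrain_unsupervised(source, epochs=2, seed=0)
        tldnn = TLDNNSpec(source=source, pretrain_epochs=2,
                          train_config=TrainConfig(epochs=1, seed=0))
        fitted = tldnn.fit(planted_cohort.subset(range(20)),
                           planted_cohort.subset(range(20, 26)))
        assert fitted.kind == "tl-dnn"
        # a plain DNN with the same seed starts from different weights
        rng = np.random.default_rng(0)
        from connectopred.nn import Dense

        random_w1 = Dense(4005, 256, rng).weight.value
        assert checksum_params([pre["params"][0]]) != checksum_params([random_w1])

    def test_empty_source_rejected(self, planted_cohort):
        spec = TLDNNSpec(source=None)
        with pytest.raises(ValueError, match="source"):
            spec.fit(planted_cohort.subset(range(10)), None)


class TestOutcomeModelSurface:
    def test_fit_summary_and_predict(self, planted_cohort, shared_backbone):
        model = OutcomeModel(planted_cohort, kind="tl-cnn",
                             train_config=TrainConfig(epochs=2, seed=0),
                             backbone=shared_backbone)
        res = model.fit()
        text = res.summary()
        assert "tl-cnn" in text and "backbone conv layers: 16" in text
        preds = res.predict()
        assert len(preds) == len(planted_cohort)

    def test_sklearn_kind_summary(self, planted_cohort):
        res = OutcomeModel(planted_cohort, kind="lr").fit()
        assert "selected grid value" in res.summary()

    def test_history_plot_returns_axes(self, planted_cohort, shared_backbone):
        import matplotlib

        matplotlib.use("Agg")
        model = OutcomeModel(planted_cohort, kind="tl-cnn",
                             train_config=TrainConfig(epochs=2, seed=0),
                             backbone=shared_backbone)
        ax = model.fit().plot_history()
        assert ax.get_xlabel() == "epoch"
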