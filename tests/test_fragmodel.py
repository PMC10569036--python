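import numpy as np
import pytest
from scipy import stats

from turbofp import fragmodel
from turbofp.cli import _db_model_inputs
from turbofp.config import RunConfig
from turbofp.fragmodel import (
    HIDDEN_LAYERS,
    HIDDEN_WIDTH,
    build_model,
    evaluate_fragments,
    fit,
    predict,
    train,
)
from turbofp.synthdata import SimConfig, simulate_panel


@pytest.fixture(scope="module")
def small_training_set():
    """400 synthetic compounds: fingerprints from fragments via the
    rank-3 latent map with sigma=0.1 latent noise."""
    cfg = SimConfig(n_compounds=400, latent_noise_sd=0.1, seed=17)
    panel = simulate_panel(cfg)
    x, y, catalog, _ = _db_model_inputs(panel.reference_db(), RunConfig(), panel.isomers)
    return x, y, catalog


class TestBuildModel:
    def test_layer_audit(self):
        net = build_model(catalog_size=12, input_size=33, seed=0)
        # 10 ReLU hidden + 1 exponential hidden + 1 output = 12 weight mats
        assert net.n_layers == HIDDEN_LAYERS + 2
        assert all(w.shape[1] == HIDDEN_WIDTH for w in net.weights[:-1])
        assert net.weights[-1].shape == (HIDDEN_WIDTH, 12)
        spec = net.layer_spec()
        assert spec[0] == "input"
        assert sum(s.endswith("+relu") for s in spec) == 10
        assert sum(s.startswith("dropout") for s in spec) == 1
        assert sum(s.endswith("+exp") for s in spec) == 1
        assert spec[-1].endswith("+linear")

    def test_zero_input_forward_finite(self):
        net = build_model(catalog_size=7, input_size=20, seed=1)
        out = predict(net, np.zeros(20))
        assert out.shape == (1, 7)
        assert np.isfinite(out).all()
        assert (out >= 0).all()

    def test_same_seed_identical_weights(self):
        a = build_model(8, 15, seed=5)
        b = build_model(8, 15, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_model(0, 10)


class TestFitPredict:
    def test_fit_deterministic(self, rng):
        x = rng.normal(size=(80, 10))
        y = rng.poisson(1.0, size=(80, 4)).astype(float)
        nets = []
        for _ in range(2):
            net = build_model(4, 10, seed=3)
            fit(net, x, y, epochs=2, seed=3)
            nets.append(net)
        assert all(
            np.array_equal(w1, w2)
            for w1, w2 in zip(nets[0].weights, nets[1].weights)
        )

    def test_predict_nonnegative_and_deterministic(self, rng):
        net = build_model(4, 10, seed=0)
        x = rng.normal(size=(80, 10))
        y = rng.poisson(1.0, size=(80, 4)).astype(float)
        fit(net, x, y, epochs=2, seed=0)
        p1, p2 = predict(net, x), predict(net, x)
        assert np.array_equal(p1, p2)
        assert (p1 >= 0).all()

    def test_nan_input_directs_to_imputation(self):
        net = build_model(4, 10, seed=0)
        bad = np.full(10, np.nan)
        with pytest.raises(ValueError, match="imputation"):
            predict(net, bad)

    def test_offset_on_raw_fingerprint_does_not_change_prediction(self):
        """Standardization precedes the model, so an additive shift of the
        raw fingerprint (an ionization offset) leaves predictions alone."""
        from turbofp.fingerprint_stats import standardize
        from turbofp.partition import Fingerprint

        raw = {f"s{i}": v for i, v in enumerate([0.3, -1.0, 2.2, 0.9, 1.4])}
        shifted = {k: v - 0.8 for k, v in raw.items()}
        z1 = standardize(Fingerprint("c", raw)).vector(sorted(raw))
        z2 = standardize(Fingerprint("c", shifted)).vector(sorted(raw))
        net = build_model(3, 5, seed=2)
        assert predict(net, z1) == pytest.approx(predict(net, z2), abs=1e-6)


class TestEvaluateFragments:
    def test_identity(self):
        v = np.array([1.0, 0.0, 2.0, 3.0])
        m = evaluate_fragments(v, v)
        assert m["r2"] == pytest.approx(1.0)
        assert m["mae"] == pytest.approx(0.0)

    def test_constant_offset(self):
        true = np.array([1.0, 0.0, 2.0, 3.0])
        m = evaluate_fragments(true + 0.5, true)
        assert m["mae"] == pytest.approx(0.5)
        assert m["r2"] == pytest.approx(1.0)

    def test_zero_variance_r2_undefined(self):
        m = evaluate_fragments(np.ones(4), np.array([1.0, 2.0, 0.0, 1.0]))
        assert np.isnan(m["r2"])
        assert np.isfinite(m["mae"])

    def test_matches_straight_line_oracle(self, rng):
        # independent check of the metric arithmetic on random vectors
        for _ in range(5):
            t = rng.normal(size=12)
            p = rng.normal(size=12)
            m = evaluate_fragments(p, t)
            slope, intercept, r, *_ = stats.linregress(t, p)
            assert m["r2"] == pytest.approx(r**2, abs=1e-8)
            assert m["mae"] == pytest.approx(np.mean(np.abs(p - t)), abs=1e-12)


class TestTrainingRecovery:
    def test_loss_decreases_and_heldout_beats_baseline(self, small_training_set):
        x, y, catalog = small_training_set
        net, report = train(x, y, catalog, epochs=25, seed=7, folds=2)
        assert report.loss_history[-1] < report.loss_history[0]
        # no-information baseline: predict the training-mean count
        baseline = np.mean(np.abs(y - y.mean(axis=0)))
        assert report.mean_test_mae().mean() < baseline

    def test_noise_degrades_recovery_monotonically(self):
        """Held-out error grows with the latent noise in the generator."""
        maes = []
        for sigma in (0.0, 0.1, 0.3):
            per_seed = []
            for rep in range(3):
                cfg = SimConfig(
                    n_compounds=300, latent_noise_sd=sigma, seed=31 + rep
                )
                panel = simulate_panel(cfg)
                x, y, catalog, _ = _db_model_inputs(
                    panel.reference_db(), RunConfig(), panel.isomers
                )
                _, report = train(x, y, catalog, epochs=80, seed=5, folds=1)
                per_seed.append(report.mean_test_mae().mean())
            maes.append(np.mean(per_seed))
        assert maes[0] <= maes[1] <= maes[2]

    def test_train_rejects_tiny_datasets(self, rng):
        with pytest.raises(ValueError, match=">= 50"):
            train(rng.normal(size=(10, 5)), rng.normal(size=(10, 2)), ["a", "b"])


def test_model_roundtrip_via_directory(tmp_path, rng):
    net = build_model(4, 10, seed=0)
    x = rng.normal(size=(60, 10))
    y = rng.poisson(1.0, size=(60, 4)).astype(float)
    fit(net, x, y, epochs=2, seed=0)
    fragmodel.save_model(net, tmp_path / "m", catalog=list("abcd"))
    back, catalog = fragmodel.load_model(tmp_path / "m")
    assert catalog == list("abcd")
    assert predict(back, x) == pytest.approx(predict(net, x))
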