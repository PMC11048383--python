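"""VQC model: circuit structure, forward pass, decoding, training."""

import numpy as np
import pytest

from brainvqc import quantum as q
from brainvqc import vqc

from conftest import dense_unitary


def _rand_params(config, seed=0):
    rng = np.random.default_rng(seed)
    return vqc.VQCParams(
        angles=rng.uniform(-np.pi, np.pi, (config.n_blocks, 3, config.n_qubits)),
        head_scale=float(rng.uniform(0.2, 1.0)),
        head_offset=float(rng.uniform(-0.5, 0.5)),
    )


class TestCircuitStructure:
    def test_default_gate_counts(self):
        """17 qubits x 10 blocks: 17 data RYs, 510 trainable rotations, 160 CNOTs."""
        spec = vqc.build_circuit(vqc.VQCConfig(), x=np.zeros(17))
        rot_data = [g for g in spec.gates if g.kind == "RY" and g.angle is not None]
        trainable = [g for g in spec.gates if g.trainable]
        cnots = [g for g in spec.gates if g.kind == "CNOT"]
        assert len(rot_data) == 17
        assert len(trainable) == 510
        assert len(cnots) == 160

    def test_ring_adds_one_cnot_per_block(self):
        cfg = vqc.VQCConfig(n_qubits=4, n_blocks=2, entangler="ring")
        spec = vqc.build_circuit(cfg, x=np.zeros(4))
        cnots = [g for g in spec.gates if g.kind == "CNOT"]
        assert len(cnots) == 2 * 4  # (n-1) chain + 1 closing per block
        assert any(g.control == 3 and g.target == 0 for g in cnots)

    def test_zero_input_embedding_is_identity(self):
        cfg = vqc.VQCConfig(n_qubits=3, n_blocks=1)
        spec = vqc.build_circuit(cfg, x=np.zeros(3))
        data = [g for g in spec.gates[:3]]
        assert all(g.kind == "RY" and g.angle == 0.0 for g in data)

    def test_block_layer_order_rx_ry_rz(self):
        cfg = vqc.VQCConfig(n_qubits=2, n_blocks=1)
        spec = vqc.build_circuit(cfg, x=np.zeros(2))
        kinds = [g.kind for g in spec.gates if g.trainable]
        assert kinds == ["RX", "RX", "RY", "RY", "RZ", "RZ"]

    def test_zero_blocks_disallowed(self):
        with pytest.raises(ValueError, match="n_blocks"):
            vqc.VQCConfig(n_qubits=3, n_blocks=0)

    def test_dimension_mismatch_rejected(self):
        cfg = vqc.VQCConfig(n_qubits=3, n_blocks=1)
        with pytest.raises(q.CircuitError, match="expected 3 features"):
            vqc.build_circuit(cfg, x=np.zeros(4))


class TestForward:
    def test_identity_circuit_closed_form(self):
        """All angles 0, x = 0: the state stays |0...0>, so the summed-Z node
        reads n_qubits and the output is sigmoid(n_qubits)."""
        cfg = vqc.VQCConfig(n_qubits=17, n_blocks=1)
        params = vqc.VQCParams(np.zeros((1, 3, 17)), head_scale=1.0, head_offset=0.0)
        out = vqc.forward(cfg, params, np.zeros(17))
        assert out == pytest.approx(1.0 / (1.0 + np.exp(-17.0)), abs=1e-12)

    def test_zero_head_scale_ignores_input(self):
        cfg = vqc.VQCConfig(n_qubits=3, n_blocks=2)
        params = _rand_params(cfg)
        params = vqc.VQCParams(params.angles, head_scale=0.0, head_offset=0.3)
        rng = np.random.default_rng(3)
        outs = [vqc.forward(cfg, params, rng.uniform(0, 1, 3)) for _ in range(4)]
        assert np.allclose(outs, 1.0 / (1.0 + np.exp(-0.3)), atol=1e-12)

    def test_output_strictly_inside_unit_interval(self):
        cfg = vqc.VQCConfig(n_qubits=4, n_blocks=2)
        params = _rand_params(cfg, seed=5)
        rng = np.random.default_rng(6)
        for _ in range(5):
            out = vqc.forward(cfg, params, rng.uniform(0, 1, 4))
            assert 0.0 < out < 1.0

    def test_matches_dense_oracle_through_sigmoid(self):
        """2-qubit toy: the full model output equals dense kron evaluation."""
        cfg = vqc.VQCConfig(n_qubits=2, n_blocks=2)
        params = _rand_params(cfg, seed=7)
        x = np.array([0.21, 0.78])
        spec = vqc.build_circuit(cfg, x=x)
        flat = params.angles.reshape(-1)
        psi = dense_unitary(spec, flat) @ q.new_state(2)
        zsum = q.zsum_expectation(psi)
        expect = 1.0 / (1.0 + np.exp(-(params.head_scale * zsum + params.head_offset)))
        assert vqc.forward(cfg, params, x) == pytest.approx(expect, abs=1e-9)

    def test_measurement_head_permutation_invariance(self):
        """Relabeling every gate's wires by a qubit permutation leaves the
        summed-Z + sigmoid output unchanged: the measurement head has no
        preferred qubit."""
        cfg = vqc.VQCConfig(n_qubits=3, n_blocks=2, entangler="ring")
        params = _rand_params(cfg, seed=8)
        x = np.array([0.1, 0.5, 0.9])
        spec = vqc.build_circuit(cfg, x=x)
        flat = params.angles.reshape(-1)

        perm = {0: 2, 1: 0, 2: 1}
        relabeled = q.CircuitSpec(3, tuple(
            q.GateOp(g.kind, perm[g.target],
                     control=None if g.control is None else perm[g.control],
                     angle=g.angle, slot=g.slot, trainable=g.trainable)
            for g in spec.gates
        ))
        zsum = q.zsum_expectation(q.run_circuit(spec, flat))
        zsum_p = q.zsum_expectation(q.run_circuit(relabeled, flat))
        assert zsum_p == pytest.approx(zsum, abs=1e-10)
        # per-qubit expectations follow the same relabeling
        psi, psi_p = q.run_circuit(spec, flat), q.run_circuit(relabeled, flat)
        for qu in range(3):
            assert q.expectation_z(psi_p, perm[qu]) == pytest.approx(
                q.expectation_z(psi, qu), abs=1e-10)


class TestDecode:
    def test_regression_boundaries(self):
        codec = vqc.TargetCodec(task="regression", age_min=14.0, age_max=89.0)
        assert vqc.decode(codec, 0.0) == pytest.approx(14.0)
        assert vqc.decode(codec, 1.0) == pytest.approx(89.0)
        assert vqc.decode(codec, 0.5) == pytest.approx(51.5)

    def test_classification_tie_goes_to_male(self):
        codec = vqc.TargetCodec(task="classification")
        assert vqc.decode(codec, 0.5) == "M"
        assert vqc.decode(codec, 0.49999) == "F"

    def test_encode_decode_round_trip(self):
        codec = vqc.TargetCodec(task="regression", age_min=20.0, age_max=80.0)
        ages = np.array([20.0, 35.0, 80.0])
        assert np.allclose(vqc.decode(codec, codec.encode(ages)), ages)

    def test_unknown_label_rejected(self):
        codec = vqc.TargetCodec(task="classification")
        with pytest.raises(ValueError, match="labels outside"):
            codec.encode(np.array(["M", "X"]))


class TestTrainingGradients:
    @pytest.mark.parametrize("task", ["regression", "classification"])
    def test_loss_gradient_matches_parameter_shift_chain_rule(self, task):
        """The adjoint training gradient equals the parameter-shift circuit
        gradient pushed through the sigmoid + loss chain rule."""
        cfg = vqc.VQCConfig(n_qubits=3, n_blocks=1, task=task)
        params = _rand_params(cfg, seed=9)
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, (4, 3))
        y = rng.uniform(0.2, 0.8, 4) if task == "regression" else rng.integers(0, 2, 4).astype(float)
        template = vqc.build_circuit(cfg)
        _, grad_angles, grad_w, grad_b = vqc.batch_loss_grads(template, cfg, params, X, y)

        w, b = params.head_scale, params.head_offset
        flat = params.angles.reshape(-1)
        expected = np.zeros_like(flat)
        for i in range(len(X)):
            spec_i = vqc.build_circuit(cfg, x=X[i])
            zsum = q.zsum_expectation(q.run_circuit(spec_i, flat))
            f = 1.0 / (1.0 + np.exp(-(w * zsum + b)))
            if task == "regression":
                dlogit = 2.0 * (f - y[i]) * f * (1 - f) / len(X)
            else:
                dlogit = (f - y[i]) / len(X)
            for s in range(spec_i.n_slots):
                ps = q.parameter_shift_grad(spec_i, flat, None, s)
                expected[s] += dlogit * w * ps
        assert np.abs(grad_angles - expected).max() < 1e-6

    def test_gradient_matches_finite_differences_of_loss(self):
        cfg = vqc.VQCConfig(n_qubits=2, n_blocks=1, task="regression")
        params = _rand_params(cfg, seed=11)
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (3, 2))
        y = rng.uniform(0.2, 0.8, 3)
        template = vqc.build_circuit(cfg)

        def loss_at(flat_angles, w, b):
            p = vqc.VQCParams(flat_angles.reshape(params.angles.shape), w, b)
            loss, *_ = vqc.batch_loss_grads(template, cfg, p, X, y)
            return loss

        loss, grad_angles, grad_w, grad_b = vqc.batch_loss_grads(template, cfg, params, X, y)
        flat = params.angles.reshape(-1)
        h = 1e-6
        for j in range(len(flat)):
            up, dn = flat.copy(), flat.copy()
            up[j] += h
            dn[j] -= h
            fd = (loss_at(up, params.head_scale, params.head_offset)
                  - loss_at(dn, params.head_scale, params.head_offset)) / (2 * h)
            assert grad_angles[j] == pytest.approx(fd, abs=1e-6)
        fd_w = (loss_at(flat, params.head_scale + h, params.head_offset)
                - loss_at(flat, params.head_scale - h, params.head_offset)) / (2 * h)
        assert grad_w == pytest.approx(fd_w, abs=1e-6)


class TestTrainingLoop:
    def test_zero_epochs_returns_initial_params(self):
        cfg = vqc.VQCConfig(n_qubits=2, n_blocks=1, epochs=0, seed=1)
        rng = np.random.default_rng(cfg.seed)
        init = vqc.initial_params(cfg, rng)
        X = np.random.default_rng(2).uniform(0, 1, (10, 2))
        y = np.linspace(0.1, 0.9, 10)
        fitted, history = vqc.train(cfg, X, y, params=init.copy())
        assert history == []
        assert np.array_equal(fitted.angles, init.angles)

    def test_zero_learning_rate_changes_nothing(self):
        cfg = vqc.VQCConfig(n_qubits=2, n_blocks=1, epochs=3, learning_rate=0.0,
                            validation_fraction=0.0, seed=1)
        rng = np.random.default_rng(cfg.seed)
        init = vqc.initial_params(cfg, rng)
        X = np.random.default_rng(2).uniform(0, 1, (10, 2))
        y = np.linspace(0.1, 0.9, 10)
        fitted, history = vqc.train(cfg, X, y, params=init.copy())
        assert len(history) == 3
        assert np.allclose(fitted.angles, init.angles)
        assert fitted.head_scale == pytest.approx(init.head_scale)

    def test_training_is_deterministic_given_seed(self):
        cfg = vqc.VQCConfig(n_qubits=2, n_blocks=1, epochs=4, seed=3)
        X = np.random.default_rng(4).uniform(0, 1, (20, 2))
        y = np.linspace(0.1, 0.9, 20)
        p1, h1 = vqc.train(cfg, X, y)
        p2, h2 = vqc.train(cfg, X, y)
        assert h1 == h2
        assert np.array_equal(p1.angles, p2.angles)

    def test_convergence_on_noiseless_linear_target(self):
        """A 4-qubit VQC fits a linear-in-first-feature target to MSE < 0.01."""
        cfg = vqc.VQCConfig(n_qubits=4, n_blocks=2, epochs=150, seed=5,
                            validation_fraction=0.0)
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (200, 4))
        y = 0.15 + 0.7 * X[:, 0]  # already inside (0, 1)
        params, history = vqc.train(cfg, X, y)
        assert history[-1] < 0.01

    def test_nan_loss_aborts_with_diagnostic(self):
        cfg = vqc.VQCConfig(n_qubits=2, n_blocks=1, epochs=2, seed=1,
                            validation_fraction=0.0)
        X = np.random.default_rng(2).uniform(0, 1, (8, 2))
        y = np.full(8, np.nan)
        with pytest.raises(FloatingPointError, match="non-finite"):
            vqc.train(cfg, X, y)


class TestWrappers:
    def test_regressor_predictions_bounded_by_training_ages(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-3, 3, (60, 3))
        ages = rng.uniform(25, 75, 60)
        m = vqc.VQCRegressor(vqc.VQCConfig(n_qubits=3, n_blocks=1, epochs=5, seed=8))
        m.fit(X, ages)
        preds = m.predict(rng.uniform(-5, 5, (30, 3)))  # far outside train range
        assert preds.min() >= ages.min() and preds.max() <= ages.max()

    def test_classifier_returns_labels_and_probabilities(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(-1, 1, (40, 3))
        y = np.where(X[:, 0] > 0, "M", "F")
        m = vqc.VQCClassifier(vqc.VQCConfig(n_qubits=3, n_blocks=1, epochs=5, seed=10))
        m.fit(X, y)
        labels = m.predict(X)
        assert set(labels) <= {"M", "F"}
        proba = m.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        X = rng.uniform(-2, 2, (30, 2))
        ages = rng.uniform(20, 70, 30)
        m = vqc.VQCRegressor(vqc.VQCConfig(n_qubits=2, n_blocks=1, epochs=3, seed=12))
        m.fit(X, ages)
        dest = tmp_path / "vqc.json"
        m.save(dest)
        loaded = vqc.VQCRegressor.load(dest)
        assert np.allclose(loaded.predict(X), m.predict(X))

    def test_feature_count_mismatch_rejected(self):
        m = vqc.VQCRegressor(vqc.VQCConfig(n_qubits=3, n_blocks=1))
        with pytest.raises(ValueError, match="3 qubits"):
            m.fit(np.zeros((10, 5)), np.arange(10.0))
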