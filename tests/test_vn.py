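"""Variational network: layer identities, activation family, gradient
correctness against finite differences, determinism, training descent."""

import numpy as np
import pytest

from rhomap import phantom as ph
from rhomap.metrics import nrmse
from rhomap.operators import (
    ImageSequence,
    MultiCoilKSpace,
    adjoint,
    forward,
)
from rhomap.sampling import poisson_disk_mask
from rhomap.vn import (
    TrainConfig,
    VNLayer,
    VNParameters,
    activation_apply,
    fit_linear_activation,
    init_vn_parameters,
    train_vn,
    vn_forward,
    vn_layer,
    vn_loss_and_grads,
)


def _zero_params(M=3, nk=2, k=3, n_knots=31):
    layers = [
        VNLayer(
            np.zeros((nk, 2, k, k, 1)), np.zeros((nk, n_knots)), alpha=0.0
        )
        for _ in range(M)
    ]
    return VNParameters(layers, knot_range=1.0, n_knots=n_knots)


@pytest.fixture()
def vn_instance(tiny_problem):
    rng = np.random.default_rng(11)
    tsl = tiny_problem["tsl"]
    x = ImageSequence(
        rng.standard_normal((8, 8, 2)) + 1j * rng.standard_normal((8, 8, 2)), tsl
    )
    y = forward(x, tiny_problem["coils"], tiny_problem["mask"])
    return dict(
        yS=y, coils=tiny_problem["coils"], mask=tiny_problem["mask"], x=x, tsl=tsl
    )


class TestLayer:
    def test_identity_layer(self, vn_instance):
        layer = VNLayer(np.zeros((2, 2, 3, 3, 1)), np.zeros((2, 31)), alpha=0.0)
        x = vn_instance["x"]
        out = vn_layer(x, vn_instance["yS"], vn_instance["coils"],
                       vn_instance["mask"], layer)
        assert np.allclose(out.data, x.data)

    def test_data_consistency_vanishes_at_adjoint_full_sampling(self, vn_instance):
        # full sampling + normalized coils: residual y - FCx is zero at the
        # adjoint reconstruction, so a filter-free layer is the identity
        y_full = forward(vn_instance["x"], vn_instance["coils"])
        x0 = adjoint(y_full, vn_instance["coils"])
        layer = VNLayer(np.zeros((2, 2, 3, 3, 1)), np.zeros((2, 31)), alpha=1.0)
        out = vn_layer(x0, y_full, vn_instance["coils"], None, layer)
        assert np.abs(out.data - x0.data).max() < 1e-10

    def test_linear_activation_matches_tikhonov_gradient_step(self, vn_instance):
        # single identity filter with Phi'(u) = u reproduces one gradient
        # step of ||y - Ax||^2 + ||x||^2 (scaled): compare to hand-coded step
        knots = np.linspace(-1, 1, 31)
        sigma = 4.0 / 30
        w = fit_linear_activation(0.1, knots, sigma)
        filt = np.zeros((1, 2, 3, 3, 1))
        filt[0, 0, 1, 1, 0] = 1.0  # real-channel identity kernel
        layer = VNLayer(filt, w[None, :], alpha=0.5)
        x = vn_instance["x"]
        x_scaled = ImageSequence(0.3 * x.data / np.abs(x.data).max(), x.tsl)
        out = vn_layer(x_scaled, vn_instance["yS"], vn_instance["coils"],
                       vn_instance["mask"], layer)
        resid = vn_instance["yS"].data - forward(
            x_scaled, vn_instance["coils"], vn_instance["mask"]
        ).data
        dc = adjoint(
            MultiCoilKSpace(resid * vn_instance["mask"].pattern[..., None], x.tsl),
            vn_instance["coils"],
            vn_instance["mask"],
        ).data
        expected = x_scaled.data - 0.1 * x_scaled.data.real + 0.5 * dc
        assert np.abs(out.data - expected).max() < 2e-3  # RBF fit tolerance


class TestActivation:
    def test_zero_weights_zero_output(self):
        knots = np.linspace(-1, 1, 31)
        u = np.linspace(-2, 2, 100)
        out = activation_apply(u, np.zeros(31), knots, 2.0 / 30)
        assert np.all(out == 0)

    def test_approximates_linear_on_unit_interval(self):
        knots = np.linspace(-1, 1, 31)
        sigma = 4.0 / 30
        w = fit_linear_activation(1.0, knots, sigma)
        u = np.linspace(-1, 1, 501)
        out = activation_apply(u, w, knots, sigma)
        assert np.abs(out - u).max() < 1e-2

    def test_odd_weights_give_odd_function(self):
        knots = np.linspace(-1, 1, 31)
        sigma = 4.0 / 30
        rng = np.random.default_rng(0)
        w = rng.standard_normal(31)
        w = w - w[::-1]  # antisymmetric weight pattern
        u = np.linspace(-1, 1, 101)
        out = activation_apply(u, w, knots, sigma)
        assert np.abs(out + out[::-1]).max() < 1e-12

    def test_bounded_outside_knot_range(self):
        knots = np.linspace(-1, 1, 31)
        sigma = 4.0 / 30
        w = np.ones(31)
        inside = activation_apply(np.array([1.0]), w, knots, sigma)
        outside = activation_apply(np.array([50.0]), w, knots, sigma)
        assert np.isclose(inside, outside).all()


class TestForward:
    def test_zero_parameters_return_zero_filled_adjoint(self, vn_instance):
        params = _zero_params()
        out = vn_forward(vn_instance["yS"], vn_instance["coils"],
                         vn_instance["mask"], params)
        zf = adjoint(vn_instance["yS"], vn_instance["coils"], vn_instance["mask"])
        assert np.allclose(out.data, zf.data)

    def test_output_finite_for_random_parameters(self, vn_instance):
        params = init_vn_parameters(variant="st", preset=None, M=3, n_filters=4,
                                    ksize=3, seed=1)
        for layer in params.layers:
            layer.filters *= 50.0  # exaggerate: activations must stay bounded
        out = vn_forward(vn_instance["yS"], vn_instance["coils"],
                         vn_instance["mask"], params)
        assert np.all(np.isfinite(out.data))

    def test_deterministic(self, vn_instance):
        params = init_vn_parameters(variant="s", preset=None, M=2, n_filters=3,
                                    ksize=3, seed=2)
        a = vn_forward(vn_instance["yS"], vn_instance["coils"],
                       vn_instance["mask"], params).data
        b = vn_forward(vn_instance["yS"], vn_instance["coils"],
                       vn_instance["mask"], params).data
        assert np.array_equal(a, b)


class TestGradients:
    def test_backprop_matches_finite_differences(self, vn_instance):
        rng = np.random.default_rng(3)
        params = init_vn_parameters(variant="st", preset=None, M=2, n_filters=3,
                                    ksize=3, seed=4)
        x_ref = ImageSequence(
            rng.standard_normal((8, 8, 2)) + 1j * rng.standard_normal((8, 8, 2)),
            vn_instance["tsl"],
        )
        args = (vn_instance["yS"], vn_instance["coils"], vn_instance["mask"])
        loss0, grads = vn_loss_and_grads(*args, params, x_ref)

        def loss():
            out = vn_forward(*args, params)
            d = out.data - x_ref.data
            return float(np.vdot(d, d).real)

        assert np.isclose(loss0, loss())
        # directional derivatives: robust against tiny per-coordinate values
        eps = 1e-6
        for m in (0, 1):
            layer = params.layers[m]
            for attr in ("filters", "act_weights"):
                arr = getattr(layer, attr)
                g = grads[m][attr]
                v = rng.standard_normal(arr.shape)
                v /= np.linalg.norm(v)
                base = arr.copy()
                setattr(layer, attr, base + eps * v)
                lp = loss()
                setattr(layer, attr, base - eps * v)
                lm = loss()
                setattr(layer, attr, base)
                fd = (lp - lm) / (2 * eps)
                an = float(np.sum(g * v))
                assert abs(fd - an) / max(abs(fd), 1e-8) < 1e-4
            old = layer.alpha
            layer.alpha = old + eps
            lp = loss()
            layer.alpha = old - eps
            lm = loss()
            layer.alpha = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - grads[m]["alpha"]) / max(abs(fd), 1e-8) < 1e-4


class TestTraining:
    def test_epoch_invariant_enforced(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_vn([], TrainConfig(epochs=1, preset="desk"))

    def test_full_preset_hyperparameters(self):
        from rhomap.vn import PRESETS, preset_train_config

        p = PRESETS["full"]
        assert p["M"] == 10 and p["n_filters"] == 24 and p["ksize"] == 11
        cfg_s = preset_train_config("full", "s")
        cfg_st = preset_train_config("full", "st")
        assert cfg_s.epochs == 50 and cfg_s.learning_rate == 1e-3
        assert cfg_s.batch_size == 40 and cfg_st.batch_size == 20
        params = init_vn_parameters(variant="st", preset="full", seed=0)
        assert len(params.layers) == 10
        assert params.layers[0].filters.shape == (24, 2, 11, 11, 3)

    def test_desk_preset_training_substantially_reduces_loss(self):
        """Full desk-preset run (64 slices of 24x24x6 at AF 4, 30 epochs):
        training descends monotonically in trend and removes over 30% of
        the initial loss (the remainder is the noise/undersampling floor
        of the ground-truth-referenced objective)."""
        tsl = np.array([2.0, 4.0, 8.0, 15.0, 30.0, 55.0])
        tset = []
        for j in range(64):
            maps = ph.make_ground_truth(24, 24, seed=100 + j)
            xs = ph.synthesize_sequence(maps, tsl)
            coils = ph.make_coil_profile(24, 24, 4, seed=200 + j,
                                         image_for_phase=maps.c)
            y = forward(xs, coils)
            if j % 2 == 1:
                from rhomap.operators import add_noise

                y = add_noise(y, ph.snr_to_noise_sd(maps, 30.0), seed=300 + j)
            mask = poisson_disk_mask(24, 24, 6, 4.0, seed=400 + j)
            yS = MultiCoilKSpace(y.data * mask.pattern[..., None], tsl)
            tset.append((yS, coils, mask, xs))
        from rhomap.vn import preset_train_config

        cfg = preset_train_config("desk", "s", seed=0)
        _, info = train_vn(tset, cfg, variant="s")
        trace = info["train_loss"]
        assert trace[-1] < 0.7 * trace[0]
        assert trace[-1] <= trace.min() + 1e-9  # no terminal divergence

    def test_short_training_reduces_loss_and_is_deterministic(
        self, desk_training_suite
    ):
        tset = desk_training_suite[:8]
        cfg = TrainConfig(epochs=6, batch_size=4, seed=0, preset="desk")
        params_a, info_a = train_vn(tset, cfg, variant="s")
        assert info_a["train_loss"][-1] < info_a["train_loss"][0]
        cfg_b = TrainConfig(epochs=6, batch_size=4, seed=0, preset="desk")
        params_b, info_b = train_vn(tset, cfg_b, variant="s")
        assert np.array_equal(info_a["train_loss"], info_b["train_loss"])
        assert np.array_equal(
            params_a.layers[0].filters, params_b.layers[0].filters
        )
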