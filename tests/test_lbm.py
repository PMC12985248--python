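"""Lattice encoder contracts: positivity of the lifted state, exact per-site
mass/momentum conservation of the projected collision, permutation streaming,
moment readout and end-to-end differentiability."""

import numpy as np
import pytest

from hemodiff import autodiff as ad
from hemodiff.autodiff import Tensor
from hemodiff.lbm import LatticeConfig, LBMEncoder, collide_project, moments, stream

from conftest import numerical_gradient


@pytest.fixture
def encoder(rng):
    return LBMEncoder(LatticeConfig(), np.random.default_rng(5))


class TestLift:
    def test_zero_params_give_ln2_everywhere(self, encoder):
        encoder.lift_w.data[:] = 0.0
        encoder.lift_b.data[:] = 0.0
        F = encoder.lift(np.linspace(-1, 1, 32))
        assert np.allclose(F.data, np.log(2.0))

    def test_unit_weight_on_constant_two(self, encoder):
        encoder.lift_w.data[:] = 1.0
        encoder.lift_b.data[:] = 0.0
        F = encoder.lift(np.full(16, 2.0))
        assert np.allclose(F.data, np.log1p(np.exp(2.0)))
        assert np.isclose(F.data[0, 0, 0], 2.126928, atol=1e-6)

    def test_lift_strictly_positive_for_any_input(self, encoder, rng):
        F = encoder.lift(rng.standard_normal((4, 64)) * 50)
        assert F.data.min() > 0

    def test_three_lattice_channels(self, encoder):
        F = encoder.lift(np.zeros(32))
        assert F.shape == (1, 3, 32)


class TestCollision:
    def test_zero_mixing_is_identity(self, rng):
        cfg = LatticeConfig()
        F = Tensor(rng.random((2, 3, 16)))
        out = collide_project(F, Tensor(np.zeros((3, 3))), Tensor(np.zeros(3)), cfg)
        assert np.allclose(out.data, F.data)

    def test_exact_projection_conserves_mass_and_momentum(self, rng):
        """1000 random states and mixing params: per-site residual < 1e-6."""
        cfg = LatticeConfig()
        e = np.asarray(cfg.velocities, dtype=float)
        worst_mass = worst_mom = 0.0
        for _ in range(1000):
            F = rng.standard_normal((1, 3, 8))
            w = rng.standard_normal((3, 3))
            b = rng.standard_normal(3)
            out = collide_project(Tensor(F), Tensor(w), Tensor(b), cfg).data
            resid = out - F  # the projected residual C
            worst_mass = max(worst_mass, np.abs(resid.sum(axis=1)).max())
            worst_mom = max(worst_mom, np.abs((resid * e[None, :, None]).sum(axis=1)).max())
        assert worst_mass < 1e-6
        assert worst_mom < 1e-6

    def test_pure_mass_excess_fully_removed(self):
        """Uniform residual (δ, δ, δ) has Δm = 0 and is subtracted entirely."""
        cfg = LatticeConfig()
        F = Tensor(np.ones((1, 3, 4)))
        w = Tensor(np.zeros((3, 3)))
        b = Tensor(np.full(3, 0.7))  # constant residual per channel
        out = collide_project(F, w, b, cfg)
        assert np.allclose(out.data, F.data, atol=1e-12)

    def test_paper_literal_projection_leaves_momentum_residual(self, rng):
        """The alternative printed coefficient does not cancel Δm on D1Q3."""
        cfg = LatticeConfig(projection="paper_literal")
        e = np.asarray(cfg.velocities, dtype=float)
        F = rng.standard_normal((1, 3, 8))
        w = rng.standard_normal((3, 3))
        out = collide_project(Tensor(F), Tensor(w), Tensor(np.zeros(3)), cfg).data
        resid = out - F
        assert np.abs(resid.sum(axis=1)).max() < 1e-9  # mass still conserved
        assert np.abs((resid * e[None, :, None]).sum(axis=1)).max() > 1e-3

    def test_degenerate_velocity_set_rejected(self):
        with pytest.raises(ValueError):
            LatticeConfig(Q=1, velocities=(0,))


class TestStreaming:
    def test_stationary_channel_unchanged(self, rng):
        cfg = LatticeConfig()
        F = Tensor(rng.random((1, 3, 12)))
        out = stream(F, cfg)
        assert np.array_equal(out.data[:, 1], F.data[:, 1])

    def test_unit_advection_of_delta(self):
        cfg = LatticeConfig()
        F = np.zeros((1, 3, 8))
        F[0, 2, 3] = 1.0  # e=+1 channel
        out = stream(Tensor(F), cfg).data
        assert out[0, 2, 4] == 1.0 and out[0, 2].sum() == 1.0

    def test_wraparound_at_boundary(self):
        cfg = LatticeConfig()
        F = np.zeros((1, 3, 8))
        F[0, 0, 0] = 1.0  # e=-1 channel shifts left, wraps to the end
        out = stream(Tensor(F), cfg).data
        assert out[0, 0, 7] == 1.0

    def test_streaming_preserves_channel_sums_exactly(self, rng):
        cfg = LatticeConfig(stride=2)
        F = rng.random((3, 3, 32))
        out = stream(Tensor(F), cfg).data
        assert np.array_equal(out.sum(axis=-1), F.sum(axis=-1))


class TestMoments:
    def test_symmetric_distribution_has_zero_momentum(self):
        cfg = LatticeConfig()
        F = np.full((1, 3, 4), 0.9)
        h = moments(Tensor(F), cfg).data
        assert np.allclose(h[0, 0], 2.7)  # rho = 3a
        assert np.allclose(h[0, 1], 0.0)

    def test_single_backward_channel(self):
        cfg = LatticeConfig()
        F = np.zeros((1, 3, 4))
        F[0, 0] = 0.6  # e = -1
        h = moments(Tensor(F), cfg).data
        assert np.allclose(h[0, 0], 0.6)
        assert np.allclose(h[0, 1], -0.6)

    def test_zero_state_zero_moments(self):
        h = moments(Tensor(np.zeros((1, 3, 4))), LatticeConfig()).data
        assert not h.any()


class TestEncode:
    def test_zero_steps_reduces_to_lifted_moments(self, rng):
        enc = LBMEncoder(LatticeConfig(n_steps=0), np.random.default_rng(3))
        c = rng.standard_normal(32)
        h = enc(c).data
        expected = moments(enc.lift(c), enc.cfg).data
        assert np.array_equal(h, expected)

    def test_zero_collision_weights_reduce_to_lift_stream_moments(self, rng):
        enc = LBMEncoder(LatticeConfig(n_steps=2), np.random.default_rng(3))
        enc.mix_w.data[:] = 0.0
        enc.mix_b.data[:] = 0.0
        c = rng.standard_normal(16)
        F = enc.lift(c)
        for _ in range(2):
            F = stream(F, enc.cfg)
        assert np.allclose(enc(c).data, moments(F, enc.cfg).data)

    def test_encode_deterministic(self, rng):
        enc = LBMEncoder(rng=np.random.default_rng(8))
        c = rng.standard_normal((2, 24))
        assert np.array_equal(enc(c).data, enc(c).data)

    def test_global_mass_conserved_through_evolution(self, rng):
        """Projection + streaming leave the total mass of the lifted state."""
        enc = LBMEncoder(LatticeConfig(n_steps=5), np.random.default_rng(0))
        c = rng.standard_normal(40)
        F0 = enc.lift(c)
        h = enc(c).data
        assert np.isclose(h[0, 0].sum(), F0.data.sum(), rtol=1e-10)

    def test_encoder_gradients_match_finite_differences(self):
        """Autodiff vs central differences w.r.t. lift and collision params."""
        enc = LBMEncoder(LatticeConfig(n_steps=2), np.random.default_rng(4))
        c = np.random.default_rng(9).standard_normal(12)
        target = np.random.default_rng(10).standard_normal((1, 2, 12))

        def scalar_loss():
            return ((enc(c) - Tensor(target)) ** 2).mean()

        loss = scalar_loss()
        for p in enc.parameters():
            p.grad = None
        loss.backward()
        for p in enc.parameters():
            def f(arr, p=p):
                old = p.data.copy()
                p.data = arr
                val = scalar_loss().item()
                p.data = old
                return val

            num = numerical_gradient(f, p.data.copy())
            # mix_b has an exactly-zero gradient: the projection annihilates a
            # constant-per-channel residual; absolute tolerance covers the
            # finite-difference rounding noise there
            dev = np.max(np.abs(p.grad - num))
            assert dev < 1e-8 or dev / np.max(np.abs(num)) < 1e-4
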