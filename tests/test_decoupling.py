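"""Attention-gate, decoupling and correlation-module tests."""

import numpy as np
import pytest

from sheepface import decoupling as dc
from sheepface import nn


class TestEcaKernelSize:
    @pytest.mark.parametrize("channels,expected", [(256, 5), (2048, 7), (64, 3),
                                                   (32, 3), (512, 5), (1024, 5)])
    def test_hand_evaluated_rule(self, channels, expected):
        assert dc.eca_kernel_size(channels) == expected

    def test_always_odd_and_at_least_three(self):
        for c in range(2, 5000, 37):
            k = dc.eca_kernel_size(c)
            assert k % 2 == 1 and k >= 3

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            dc.eca_kernel_size(1)


@pytest.fixture()
def fmap(rng):
    return nn.Tensor(rng.normal(size=(3, 16, 4, 4)).astype(np.float32))


@pytest.fixture()
def ecbam_mod(rng):
    return dc.ECBAM(rng, channels=16)


class TestEcamGate:
    def test_zero_kernels_give_half_gate(self, rng, fmap):
        mod = dc.ECBAM(rng, 16)
        mod.conv_avg.data[:] = 0
        mod.conv_max.data[:] = 0
        gate = dc.ecam_gate(fmap, mod)
        assert np.allclose(gate.data, 0.5)

    def test_alpha_one_isolates_average_branch(self, rng, fmap):
        mod = dc.ECBAM(rng, 16)
        mod.alpha.data = np.array(1.0, dtype=np.float32)
        before = dc.ecam_gate(fmap, mod).data.copy()
        mod.conv_max.data[:] = 17.0  # perturbing the max branch is invisible
        after = dc.ecam_gate(fmap, mod).data
        assert np.array_equal(before, after)

    def test_equal_branches_make_alpha_irrelevant(self, rng):
        mod = dc.ECBAM(rng, 16)
        mod.conv_max.data = mod.conv_avg.data.copy()
        x = nn.Tensor(np.ones((2, 16, 3, 3), dtype=np.float32))  # GAP == GMP
        g1 = dc.ecam_gate(x, mod).data.copy()
        mod.alpha.data = np.array(0.123, dtype=np.float32)
        g2 = dc.ecam_gate(x, mod).data
        assert np.allclose(g1, g2, atol=1e-7)

    def test_gate_in_open_unit_interval(self, ecbam_mod, fmap):
        g = dc.ecam_gate(fmap, ecbam_mod).data
        assert np.all(g > 0) and np.all(g < 1)


class TestSamGate:
    def test_zero_conv_gives_uniform_half(self, rng, fmap):
        mod = dc.ECBAM(rng, 16)
        mod.spatial_conv.weight.data[:] = 0
        mod.spatial_conv.bias.data[:] = 0
        g = dc.sam_gate(fmap, mod).data
        assert np.allclose(g, 0.5)

    def test_spatially_constant_input_gives_constant_gate(self, rng):
        # constant away from the conv's zero-padding frame
        mod = dc.ECBAM(rng, 16)
        x = nn.Tensor(np.broadcast_to(
            np.arange(16, dtype=np.float32)[None, :, None, None],
            (1, 16, 11, 11)).copy())
        g = dc.sam_gate(x, mod).data[0, 0]
        inner = g[3:-3, 3:-3]
        assert np.allclose(inner, inner[0, 0], atol=1e-6)

    def test_translation_equivariance_with_wraparound(self, rng):
        # circular-shifting the input circular-shifts the gate, up to the
        # conv's zero-padding frame which we avoid by comparing the interior
        mod = dc.ECBAM(rng, 8, spatial_kernel=3)
        x = rng.normal(size=(1, 8, 12, 12)).astype(np.float32)
        g1 = dc.sam_gate(nn.Tensor(x), mod).data[0, 0]
        xs = np.roll(x, shift=(3, 3), axis=(2, 3))
        g2 = dc.sam_gate(nn.Tensor(xs), mod).data[0, 0]
        inner = np.s_[4:8, 4:8]
        assert np.allclose(np.roll(g1, (3, 3), axis=(0, 1))[inner], g2[inner],
                           atol=1e-5)


class TestEcbam:
    def test_zero_params_quarter_input(self, rng, fmap):
        mod = dc.ECBAM(rng, 16)
        for p in mod.parameters():
            p.data = np.zeros_like(p.data)
        out = dc.ecbam(fmap, mod)
        assert np.allclose(out.data, 0.25 * fmap.data, atol=1e-6)

    def test_attenuation_bound(self, ecbam_mod, fmap):
        out = dc.ecbam(fmap, ecbam_mod)
        assert np.all(np.abs(out.data) <= np.abs(fmap.data) + 1e-7)

    def test_cbam_variant_also_attenuates(self, rng, fmap):
        mod = dc.CBAM(rng, 16, reduction=4)
        out = mod(fmap)
        assert np.all(np.abs(out.data) <= np.abs(fmap.data) + 1e-7)


class TestDecouple:
    def test_conservation_identity_exact(self, rng, fmap):
        dec = dc.Decoupler(rng, embed_dim=16, age_dim=8, hidden=12)
        x = nn.Tensor(rng.normal(size=(3, 16)).astype(np.float32))
        bundle = dc.decouple(fmap, x, dec)
        assert np.array_equal(bundle.x.data, (bundle.x_id + bundle.r).data)

    def test_zero_residual_map_passes_embedding_through(self, rng, fmap):
        dec = dc.Decoupler(rng, embed_dim=16, age_dim=8, hidden=12)
        for layer in dec.mlp_res.layers:
            layer.weight.data[:] = 0
            layer.bias.data[:] = 0
        x = nn.Tensor(rng.normal(size=(3, 16)).astype(np.float32))
        bundle = dec(fmap, x)
        assert np.allclose(bundle.x_id.data, x.data)
        assert np.allclose(bundle.r.data, 0.0)

    def test_age_code_depends_on_map_not_embedding(self, rng, fmap):
        dec = dc.Decoupler(rng, embed_dim=16, age_dim=8, hidden=12)
        dec.eval()
        x1 = nn.Tensor(rng.normal(size=(3, 16)).astype(np.float32))
        x2 = nn.Tensor(rng.normal(size=(3, 16)).astype(np.float32))
        with nn.no_grad():
            b1 = dec(fmap, x1)
            b2 = dec(fmap, x2)
        assert np.array_equal(b1.x_age.data, b2.x_age.data)
        assert not np.allclose(b1.x_id.data, b2.x_id.data)

    def test_unknown_modes_rejected(self, rng):
        with pytest.raises(ValueError):
            dc.Decoupler(rng, 16, attention="sparkle")
        with pytest.raises(ValueError):
            dc.Decoupler(rng, 16, mode="subtracty")


class TestCorrModule:
    def test_projection_identity_case(self, rng):
        corr = dc.CorrModule(rng, id_dim=4, age_dim=4, hidden=4, n_pairs=1)
        # make phi the identity on the first coordinates and w = e1
        for mlp in (corr.phi_u, corr.phi_v):
            mlp.layers[0].weight.data = np.eye(4, dtype=np.float32) * 100.0
            mlp.layers[0].bias.data[:] = 0
            mlp.layers[1].weight.data = np.eye(4, dtype=np.float32) / 100.0
            mlp.layers[1].bias.data[:] = 0
        corr.w_u.data = np.array([[1.0], [0], [0], [0]], dtype=np.float32)
        corr.w_v.data = np.array([[1.0], [0], [0], [0]], dtype=np.float32)
        x = np.abs(rng.normal(size=(5, 4))).astype(np.float32)  # stay in relu range
        u, v = dc.kernel_projections(x, x, corr)
        assert np.allclose(u.data, x[:, 0], atol=1e-4)

    def test_scaling_w_scales_projection(self, rng):
        corr = dc.CorrModule(rng, 6, 6, hidden=5, n_pairs=1)
        x = rng.normal(size=(4, 6)).astype(np.float32)
        u1, _ = corr.projections(x, x)
        corr.w_u.data = corr.w_u.data * 3.0
        u2, _ = corr.projections(x, x)
        assert np.allclose(u2.data, 3.0 * u1.data, atol=1e-5)

    def test_deterministic(self, rng):
        corr = dc.CorrModule(rng, 6, 6, hidden=5)
        x = rng.normal(size=(4, 6)).astype(np.float32)
        y = rng.normal(size=(4, 6)).astype(np.float32)
        u1, v1 = corr.projections(x, y)
        u2, v2 = corr.projections(x, y)
        assert np.array_equal(u1.data, u2.data)
        assert np.array_equal(v1.data, v2.data)

    def test_batch_too_small_rejected(self, rng):
        corr = dc.CorrModule(rng, 6, 6)
        with pytest.raises(ValueError):
            corr.projections(np.zeros((1, 6), np.float32),
                             np.zeros((1, 6), np.float32))


class TestBatchCorrelation:
    def test_perfect_correlation(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        rho, flag = dc.batch_correlation(u, u)
        assert not flag
        assert float(rho.data) == pytest.approx(1.0, abs=1e-4)

    def test_perfect_anticorrelation(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        rho, _ = dc.batch_correlation(u, -u)
        assert float(rho.data) == pytest.approx(-1.0, abs=1e-4)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(42)
        u = rng.normal(size=10000)
        v = rng.normal(size=10000)
        rho, _ = dc.batch_correlation(u, v)
        assert abs(float(rho.data)) < 0.05

    def test_degenerate_batch_flagged_zero(self):
        rho, flag = dc.batch_correlation(np.ones(5), np.arange(5.0))
        assert flag and float(rho.data) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dc.batch_correlation(np.ones(4), np.ones(5))

    def test_bounded_by_one(self, rng):
        for _ in range(20):
            u = rng.normal(size=16)
            v = rng.normal(size=16)
            rho, _ = dc.batch_correlation(u, v)
            assert abs(float(rho.data)) <= 1.0 + 1e-6


class TestCorrelationLoss:
    @pytest.mark.parametrize("rho,expected", [(0.0, 0.0), (1.0, 1.0),
                                              (-1.0, 1.0), (0.3, 0.09)])
    def test_squared_value(self, rho, expected):
        assert dc.correlation_loss(rho) == pytest.approx(expected, abs=1e-12)

    def test_multi_pair_objective_in_unit_interval(self, rng):
        u = rng.normal(size=(32, 4)).astype(np.float32)
        v = rng.normal(size=(32, 4)).astype(np.float32)
        loss, max_abs = dc.correlation_objective(u, v)
        assert 0.0 <= float(loss.data) <= 1.0
        assert 0.0 <= max_abs <= 1.0 + 1e-6


class TestAdversarialDirections:
    def test_ascent_increases_and_descent_decreases_rho2(self, rng):
        # correlated Gaussian pair; small steps on the projections move the
        # squared correlation in the expected direction for each player
        n = 512
        z = rng.normal(size=n)
        x = np.column_stack([z + 0.1 * rng.normal(size=n),
                             rng.normal(size=n)]).astype(np.float32)
        y = np.column_stack([z + 0.1 * rng.normal(size=n),
                             rng.normal(size=n)]).astype(np.float32)
        corr = dc.CorrModule(rng, 2, 2, hidden=4, n_pairs=1)

        def rho2():
            u, v = corr.projections(x, y)
            loss, _ = dc.correlation_objective(u, v)
            return loss

        base = float(rho2().data)
        for p in corr.parameters():
            p.grad = None
        rho2().backward()
        lr = 1e-3
        for p in corr.parameters():
            if p.grad is not None:
                p.data = p.data + lr * p.grad  # ascent
        assert float(rho2().data) >= base - 1e-6

    def test_closed_form_solve_finds_planted_correlation(self, rng):
        n = 2000
        z = rng.normal(size=n)
        x = np.column_stack([z, rng.normal(size=n), rng.normal(size=n)])
        y = np.column_stack([rng.normal(size=n), z, rng.normal(size=n)])
        corr = dc.CorrModule(rng, 3, 3, hidden=8, n_pairs=2)
        corr.solve_projections(x.astype(np.float32), y.astype(np.float32))
        u, v = corr.projections(x.astype(np.float32), y.astype(np.float32))
        _, planted = dc.correlation_objective(u, v)

        y_null = rng.normal(size=y.shape)
        corr.solve_projections(x.astype(np.float32), y_null.astype(np.float32))
        u, v = corr.projections(x.astype(np.float32), y_null.astype(np.float32))
        _, null = dc.correlation_objective(u, v)
        # the random relu kernel maps attenuate the planted signal, but the
        # solver must still find far more correlation than on independent data
        assert planted > 0.5
        assert planted > null + 0.3
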