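import numpy as np
import pytest

from crossmp.autodiff import Tensor
from crossmp.model_core import (
    LatentEmbedding,
    LossWeights,
    ModelConfig,
    TranslationModel,
    bce_loss,
    kl_latent,
    nb_nll,
    total_loss,
)


def toy_config(**kw):
    defaults = dict(
        chromosome_blocks=[("chr1", 30), ("chr2", 20)],
        n_genes=25,
        n_sg_genes=10,
        gas_blocks=[("chr1", 15), ("chr2", 10)],
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def human_like_config():
    """22 autosome blocks, as in a human autosome-only peak matrix."""
    return ModelConfig(
        chromosome_blocks=[(f"chr{i}", 40) for i in range(1, 23)],
        n_genes=50,
        n_sg_genes=20,
        gas_blocks=[(f"chr{i}", 50) for i in range(1, 2)],
    )


def toy_model(cfg=None, seed=0):
    cfg = cfg or toy_config()
    m = TranslationModel(cfg, rng=np.random.default_rng(seed))
    m.set_training(False)
    return m


class TestArchitectureWidths:
    def test_human_autosome_concat_width_352(self):
        model = toy_model(human_like_config())
        x = np.random.default_rng(1).random((3, 22 * 40))
        z = model.encode_atac(x, "ATAC")
        assert z.shape == (3, 16)
        assert model.enc_atac._last_concat_width == 352
        assert model.dec_atac.expanded_dim == 352
        assert model.dec_atac.n_blocks == 22
        assert model.dec_rna.hidden_dim == 64

    def test_toy_two_block_concat_width(self):
        model = toy_model()
        x = np.zeros((4, 50))
        model.encode_atac(x, "ATAC")
        assert model.enc_atac._last_concat_width == 2 * 16

    def test_decoder_restores_per_chromosome_peak_counts(self):
        model = toy_model()
        z = LatentEmbedding(values=Tensor(np.zeros((4, 16))), source="ATAC+GAS")
        out = model.decode_atac(z)
        assert out.shape == (4, 50)  # 30 + 20
        assert np.all((out.data > 0) & (out.data < 1))

    def test_rna_decoder_two_heads_of_input_dimensionality(self):
        model = toy_model()
        z = LatentEmbedding(values=Tensor(np.zeros((5, 16))), source="RNA+SG")
        mean, disp = model.decode_rna(z)
        assert mean.shape == (5, 25) and disp.shape == (5, 25)
        assert np.all(mean.data > 0) and np.all(disp.data > 0)

    def test_zero_batch_passes(self):
        model = toy_model()
        z = model.encode_rna(np.zeros((0, 25)), "RNA")
        assert z.shape == (0, 16)

    def test_width_mismatch_rejected(self):
        model = toy_model()
        with pytest.raises(ValueError):
            model.encode_rna(np.zeros((2, 24)), "RNA")
        with pytest.raises(ValueError):
            model.encode_atac(np.zeros((2, 49)), "ATAC")

    def test_blocks_permutation_symmetry(self):
        # permuting peaks within one chromosome block together with the matching
        # rows of that block's first weight matrix leaves the output unchanged
        model = toy_model()
        rng = np.random.default_rng(2)
        x = (rng.random((6, 50)) < 0.3).astype(float)
        base = model.encode_atac(x, "ATAC").values.data
        perm = rng.permutation(30)  # within chr1 block
        x2 = x.copy()
        x2[:, :30] = x2[:, perm]
        model.enc_atac.block_encoders[0].fc1.weight.data = (
            model.enc_atac.block_encoders[0].fc1.weight.data[perm, :]
        )
        out = model.encode_atac(x2, "ATAC").values.data
        np.testing.assert_allclose(out, base, atol=1e-12)

    def test_inference_deterministic(self):
        model = toy_model()
        x = np.random.default_rng(3).random((7, 25))
        a = model.encode_rna(x, "RNA").values.data
        b = model.encode_rna(x, "RNA").values.data
        np.testing.assert_array_equal(a, b)

    def test_gas_encoder_routes_gene_blocks(self):
        model = toy_model()
        z = model.encode_atac(np.zeros((3, 25)), "GAS")  # 15 + 10 genes
        assert z.shape == (3, 16) and z.source == "GAS"


class TestMergeLatents:
    def test_zero_identity_and_commutativity(self):
        model = toy_model()
        rng = np.random.default_rng(4)
        a = LatentEmbedding(Tensor(rng.normal(size=(5, 16))), "ATAC")
        zeros = LatentEmbedding(Tensor(np.zeros((5, 16))), "GAS")
        merged = model.merge_latents(a, zeros)
        np.testing.assert_array_equal(merged.values.data, a.values.data)
        b = LatentEmbedding(Tensor(rng.normal(size=(5, 16))), "GAS")
        np.testing.assert_array_equal(
            model.merge_latents(a, b).values.data,
            model.merge_latents(b, a).values.data,
        )
        assert model.merge_latents(a, b).shape == (5, 16)

    def test_shape_mismatch_rejected(self):
        model = toy_model()
        a = LatentEmbedding(Tensor(np.zeros((5, 16))), "ATAC")
        b = LatentEmbedding(Tensor(np.zeros((4, 16))), "GAS")
        with pytest.raises(ValueError):
            model.merge_latents(a, b)


class TestNbNll:
    def test_zero_count_closed_form(self):
        # x=0: NLL = theta*log(1 + mu/theta); mu=1, theta=1 -> log 2
        val = nb_nll(np.zeros((1, 1)), np.ones((1, 1)), np.ones((1, 1)))
        assert float(val.data) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_poisson_limit(self):
        # theta -> inf: NLL -> mu - x log mu + lgamma(x+1); mu=1, x=1 -> 1
        val = nb_nll(np.ones((1, 1)), np.ones((1, 1)), np.full((1, 1), 1e8))
        assert float(val.data) == pytest.approx(1.0, abs=1e-4)

    def test_minimised_at_mean_equal_count(self):
        x = np.full((1, 1), 4.0)
        theta = np.full((1, 1), 2.0)
        grid = np.linspace(1.0, 8.0, 141)
        losses = [float(nb_nll(x, np.full((1, 1), m), theta).data) for m in grid]
        assert grid[int(np.argmin(losses))] == pytest.approx(4.0, abs=0.05)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_nll(np.ones((1, 1)), np.zeros((1, 1)), np.ones((1, 1)))
        with pytest.raises(ValueError):
            nb_nll(np.ones((1, 1)), np.ones((1, 1)), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            nb_nll(-np.ones((1, 1)), np.ones((1, 1)), np.ones((1, 1)))


class TestBceLoss:
    def test_closed_form_log2(self):
        val = bce_loss(np.ones((1, 1)), np.full((1, 1), 0.5))
        assert float(val.data) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_perfect_prediction_near_zero(self):
        y = np.array([[0.0, 1.0, 1.0]])
        val = bce_loss(y, np.clip(y, 1e-8, 1 - 1e-8))
        assert float(val.data) == pytest.approx(0.0, abs=1e-6)

    def test_confidently_wrong_is_large_but_finite(self):
        val = bce_loss(np.ones((1, 1)), np.full((1, 1), 1e-300))
        assert np.isfinite(val.data) and float(val.data) > 15

    def test_non_binary_targets_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.full((1, 1), 0.5), np.full((1, 1), 0.5))


class TestKlLatent:
    def test_identical_latents_zero(self):
        z = np.random.default_rng(5).normal(size=(6, 16))
        assert float(kl_latent(z, z.copy()).data) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a = rng.normal(size=(4, 8)) * rng.uniform(0.1, 3)
            b = rng.normal(size=(4, 8)) * rng.uniform(0.1, 3)
            assert float(kl_latent(a, b).data) >= -1e-12

    def test_softmax_shift_invariance(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
        base = float(kl_latent(a, b).data)
        shifted = float(kl_latent(a + 13.0, b - 4.0).data)
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_symmetrised_option(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
        sym = float(kl_latent(a, b, symmetric=True).data)
        expect = 0.5 * (float(kl_latent(a, b).data) + float(kl_latent(b, a).data))
        assert sym == pytest.approx(expect, abs=1e-12)


class TestTotalLoss:
    def _bundle(self, model, x_norm, x_sg, x_atac, x_gas):
        return model.forward(x_norm, x_sg, x_atac, x_gas)

    def test_breakdown_sums_to_total(self):
        model = toy_model()
        rng = np.random.default_rng(9)
        counts = rng.poisson(3.0, size=(6, 25)).astype(float)
        atac = (rng.random((6, 50)) < 0.2).astype(float)
        bundle, z_a, z_r = self._bundle(
            model, rng.normal(size=(6, 25)), rng.normal(size=(6, 10)), atac,
            rng.random((6, 25)),
        )
        w = LossWeights()
        total, breakdown = total_loss(bundle, counts, atac, z_a, z_r, w)
        expect = (
            breakdown["nb_rna_from_atac"]
            + breakdown["nb_rna_from_rna"]
            + w.w_bce * (breakdown["bce_atac_from_atac"] + breakdown["bce_atac_from_rna"])
            + w.w_kl * breakdown["kl_latent"]
        )
        assert float(total.data) == pytest.approx(expect, abs=1e-9)
        assert breakdown["total"] == pytest.approx(float(total.data), abs=1e-12)

    def test_zero_weights_leave_only_nb_terms(self):
        model = toy_model()
        rng = np.random.default_rng(10)
        counts = rng.poisson(3.0, size=(4, 25)).astype(float)
        atac = (rng.random((4, 50)) < 0.2).astype(float)
        bundle, z_a, z_r = self._bundle(
            model, rng.normal(size=(4, 25)), rng.normal(size=(4, 10)), atac,
            rng.random((4, 25)),
        )
        total, breakdown = total_loss(
            bundle, counts, atac, z_a, z_r, LossWeights(w_bce=0.0, w_kl=0.0)
        )
        assert float(total.data) == pytest.approx(
            breakdown["nb_rna_from_atac"] + breakdown["nb_rna_from_rna"], abs=1e-9
        )

    def test_perfect_predictions_leave_only_irreducible_nb(self):
        from crossmp.model_core import PredictionBundle

        rng = np.random.default_rng(11)
        counts = rng.integers(1, 6, size=(5, 8)).astype(float)
        atac = (rng.random((5, 12)) < 0.5).astype(float)
        theta = np.full_like(counts, 50.0)
        bundle = PredictionBundle(
            atac_from_atac=Tensor(np.clip(atac, 1e-8, 1 - 1e-8)),
            rna_from_atac=(Tensor(counts), Tensor(theta)),
            atac_from_rna=Tensor(np.clip(atac, 1e-8, 1 - 1e-8)),
            rna_from_rna=(Tensor(counts), Tensor(theta)),
        )
        z = rng.normal(size=(5, 16))
        total, breakdown = total_loss(bundle, counts, atac, z, z.copy(), LossWeights())
        assert breakdown["kl_latent"] == pytest.approx(0.0, abs=1e-12)
        assert breakdown["bce_atac_from_atac"] == pytest.approx(0.0, abs=1e-6)
        assert breakdown["bce_atac_from_rna"] == pytest.approx(0.0, abs=1e-6)
        irreducible = float(nb_nll(counts, counts, theta).data)
        assert breakdown["nb_rna_from_atac"] == pytest.approx(irreducible, abs=1e-12)

    def test_one_forward_call_yields_all_four_paths(self):
        model = toy_model()
        rng = np.random.default_rng(12)
        bundle, z_a, z_r = model.forward(
            rng.normal(size=(3, 25)), rng.normal(size=(3, 10)),
            (rng.random((3, 50)) < 0.2).astype(float), rng.random((3, 25)),
        )
        assert bundle.atac_from_atac.shape == (3, 50)
        assert bundle.atac_from_rna.shape == (3, 50)
        assert bundle.rna_from_atac[0].shape == (3, 25)
        assert bundle.rna_from_rna[1].shape == (3, 25)
        assert z_a.source == "ATAC+GAS" and z_r.source == "RNA+SG"


class TestMergeModeAlternative:
    def test_concat_project_keeps_latent_width(self):
        model = toy_model(toy_config(merge_mode="concat_project"))
        rng = np.random.default_rng(13)
        a = LatentEmbedding(Tensor(rng.normal(size=(4, 16))), "ATAC")
        b = LatentEmbedding(Tensor(rng.normal(size=(4, 16))), "GAS")
        assert model.merge_latents(a, b).shape == (4, 16)
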