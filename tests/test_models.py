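"""Generator layers, covariate embeddings, critic, and baseline bundles."""

import numpy as np
import pytest

import gexgan as gg
from gexgan import autodiff as ad
from gexgan.core_io import ValidationError
from gexgan.graphs import GeneGraph
from gexgan.models import (
    CovariateEmbedding,
    Critic,
    critic_forward,
    graphconv_layer,
    h2gcn_layer,
    h2gcn_readout,
    init_node_features,
)

from conftest import path_graph, empty_graph


class TestEmbeddingDim:
    @pytest.mark.parametrize("l,rule,expected", [
        (20, "l_plus_one", 21),
        (1, "l_plus_one", 2),
        (20, "sqrt_plus_one", 5),
        (9, "sqrt_plus_one", 4),
    ])
    def test_rules(self, l, rule, expected):
        assert gg.embedding_dim(l, rule) == expected

    def test_invalid_vocabulary_size(self):
        with pytest.raises(ValidationError):
            gg.embedding_dim(0)


class TestCovariateEmbedding:
    def make(self, rule="sqrt_plus_one"):
        vocab = {"tissue": ["liver", "lung", "heart", "brain"], "sex": ["F", "M"]}
        return CovariateEmbedding(vocab, np.random.default_rng(0), rule)

    def test_total_dimension_is_sum_of_blocks(self):
        emb = self.make()
        assert emb.m == gg.embedding_dim(4, "sqrt_plus_one") + gg.embedding_dim(2, "sqrt_plus_one")
        out = emb(np.array([[0, 1]]))
        assert out.shape == (1, emb.m)

    def test_lookup_is_deterministic(self):
        emb = self.make()
        a = emb(np.array([[2, 0]]))
        b = emb(np.array([[2, 0]]))
        np.testing.assert_array_equal(a.data, b.data)

    def test_changing_one_covariate_changes_only_its_slice(self):
        emb = self.make()
        d0 = emb.dims["tissue"]
        a = emb(np.array([[1, 0]])).data
        b = emb(np.array([[1, 1]])).data
        np.testing.assert_array_equal(a[:, :d0], b[:, :d0])
        assert not np.array_equal(a[:, d0:], b[:, d0:])

    def test_out_of_vocabulary_category_rejected(self):
        emb = self.make()
        with pytest.raises(ValidationError, match="sex"):
            emb.embed_values({"tissue": "liver", "sex": "unknown"})


class TestInitNodeFeatures:
    def test_zero_weight_returns_bias(self):
        W = ad.Tensor(np.zeros((3, 4)), requires_grad=True)
        b = ad.Tensor(np.array([1.0, -2.0, 0.5, 3.0]))
        for z in (np.zeros((1, 3)), np.ones((1, 3)) * 7):
            h0 = init_node_features(z, None, W, b)
            np.testing.assert_array_equal(h0.data, b.data[None, :])

    def test_hand_matrix_multiply(self):
        # 2 genes, latent dim 1, no covariates: W = [[1, -1]], z = [3] -> (3, -3)
        W = ad.Tensor(np.array([[1.0, -1.0]]))
        b = ad.Tensor(np.zeros(2))
        h0 = init_node_features(np.array([[3.0]]), None, W, b)
        np.testing.assert_array_equal(h0.data, [[3.0, -3.0]])

    def test_dimension_mismatch_raises(self):
        W = ad.Tensor(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            init_node_features(np.zeros((1, 5)), None, W, ad.Tensor(np.zeros(2)))


class TestGraphConvLayer:
    def test_empty_graph_reduces_to_self_term(self, rng):
        graph = empty_graph(4)
        h = rng.normal(size=(2, 4, 3))
        W1 = rng.normal(size=(3, 3))
        W2 = rng.normal(size=(3, 3))
        out = graphconv_layer(h, graph, W1, W2)
        np.testing.assert_allclose(out.data, h @ W1, atol=1e-12)

    def test_hand_computed_two_node_update(self):
        # single directed edge node1 -> node0, weight 1; h = (1, 2), W1 = W2 = 1
        graph = GeneGraph(["a", "b"], np.array([1]), np.array([0]), np.ones(1),
                          directed=True, signed=False)
        h = np.array([[[1.0], [2.0]]])
        out = graphconv_layer(h, graph, np.eye(1), np.eye(1))
        np.testing.assert_array_equal(out.data.ravel(), [3.0, 2.0])

    def test_weighted_contribution_scales_with_edge_weight(self):
        graph = GeneGraph(["a", "b"], np.array([1]), np.array([0]), np.array([-0.5]),
                          directed=True, signed=False)
        h = np.array([[[1.0], [2.0]]])
        out = graphconv_layer(h, graph, np.eye(1), np.eye(1))
        np.testing.assert_array_equal(out.data.ravel(), [0.0, 2.0])

    def test_permutation_equivariance(self, rng):
        n = 6
        src = np.array([0, 2, 3, 5])
        tgt = np.array([1, 4, 0, 2])
        w = rng.normal(size=4)
        graph = GeneGraph([f"g{i}" for i in range(n)], src, tgt, w, directed=True, signed=False)
        h = rng.normal(size=(1, n, 2))
        W1, W2 = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        out = graphconv_layer(h, graph, W1, W2).data

        perm = rng.permutation(n)
        inv = np.argsort(perm)
        permuted_graph = GeneGraph([f"g{perm[i]}" for i in range(n)][::1],
                                   inv[src], inv[tgt], w, directed=True, signed=False)
        out_perm = graphconv_layer(h[:, perm], permuted_graph, W1, W2).data
        np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-12)

    def test_mean_aggregator_divides_by_in_degree(self):
        graph = GeneGraph(["a", "b", "c"], np.array([1, 2]), np.array([0, 0]),
                          np.ones(2), directed=True, signed=False)
        h = np.array([[[0.0], [2.0], [4.0]]])
        summed = graphconv_layer(h, graph, np.zeros((1, 1)), np.eye(1), aggregator="sum")
        meaned = graphconv_layer(h, graph, np.zeros((1, 1)), np.eye(1), aggregator="mean")
        assert summed.data[0, 0, 0] == 6.0
        assert meaned.data[0, 0, 0] == 3.0


class TestH2GCNLayer:
    def test_path_graph_hand_example(self):
        # path a-b-c, h = (1, 0, 1): a's 1-hop block 0, 2-hop block 1
        graph = path_graph(3)
        h = np.array([[[1.0], [0.0], [1.0]]])
        out = h2gcn_layer(h, graph, np.eye(1), np.eye(1), "sym_sqrt_degree")
        assert out.shape == (1, 3, 2)
        np.testing.assert_allclose(out.data[0, 0], [0.0, 1.0], atol=1e-12)

    def test_no_length_two_paths_gives_zero_block(self, rng):
        graph = GeneGraph(["a", "b"], np.array([0]), np.array([1]), np.ones(1),
                          directed=False, signed=False)
        h = rng.normal(size=(1, 2, 3))
        out = h2gcn_layer(h, graph, np.eye(3), np.eye(3))
        np.testing.assert_array_equal(out.data[:, :, 3:], np.zeros((1, 2, 3)))

    def test_output_width_doubles(self, rng):
        graph = path_graph(4)
        h = rng.normal(size=(2, 4, 5))
        out = h2gcn_layer(h, graph, rng.normal(size=(5, 5)), rng.normal(size=(5, 5)))
        assert out.shape == (2, 4, 10)

    def test_ego_embedding_not_mixed_in(self, rng):
        """Perturbing a node's own feature leaves its output block unchanged."""
        graph = path_graph(3)
        h = rng.normal(size=(1, 3, 2))
        W1, W2 = rng.normal(size=(2, 2)), rng.normal(size=(2, 2))
        base = h2gcn_layer(h, graph, W1, W2).data
        h2 = h.copy()
        h2[0, 1] += 10.0
        bumped = h2gcn_layer(h2, graph, W1, W2).data
        np.testing.assert_allclose(bumped[0, 1], base[0, 1], atol=1e-12)

    def test_readout_width_bookkeeping_and_projection(self, rng):
        blocks = [rng.normal(size=(1, 3, w)) for w in (1, 2, 4)]
        W_c = rng.normal(size=(7, 1))
        y = h2gcn_readout(blocks, W_c)
        concat = np.concatenate(blocks, axis=-1)
        np.testing.assert_allclose(y.data, concat @ W_c, atol=1e-12)
        with pytest.raises(ValidationError):
            h2gcn_readout([], W_c)

    def test_single_intermediate_identity_projection(self):
        h0 = np.arange(3.0).reshape(1, 3, 1)
        y = h2gcn_readout([h0], np.eye(1))
        np.testing.assert_array_equal(y.data, h0)


class TestGeneratorForward:
    @pytest.mark.parametrize("family", ["graphconv", "h2gcn"])
    def test_output_length_codomain_determinism(self, tiny_bundle, family):
        spec = gg.GeneratorSpec(n_genes=20, layer_family=family, n_mp_layers=3,
                                output_activation="sigmoid")
        vocab = {k: list(v) for k, v in tiny_bundle.C.vocabularies.items()}
        bundle = gg.build_graph_model(tiny_bundle.graph, vocab, spec, seed=3)
        z = np.random.default_rng(0).standard_normal((4, spec.latent_dim))
        codes = tiny_bundle.C.code_matrix()[:4]
        out1 = bundle.generator.forward(z, codes).data
        out2 = bundle.generator.forward(z, codes).data
        assert out1.shape == (4, 20)
        assert np.all((out1 > 0) & (out1 < 1))
        np.testing.assert_array_equal(out1, out2)

    def test_empty_graph_generator_equals_dense_only_forward(self):
        """With no edges the graphconv generator is an MLP: message terms vanish."""
        graph = empty_graph(5)
        spec = gg.GeneratorSpec(n_genes=5, latent_dim=3, n_mp_layers=2,
                                node_feature_dim=4, output_activation="identity")
        bundle = gg.build_graph_model(graph, None, spec, seed=7)
        gen = bundle.generator
        z = np.random.default_rng(1).standard_normal((3, 3))
        out = gen.forward(z).data

        def leaky(x):
            return np.where(x > 0, x, 0.2 * x)

        h0 = leaky(z @ gen.init_layer.W.data + gen.init_layer.b.data)
        h = h0[:, :, None]
        h = leaky(h @ gen.W1[0].data)
        h = h @ gen.W1[1].data  # final layer: no inter-layer activation
        np.testing.assert_allclose(out, h[:, :, 0], atol=1e-12)

    def test_locality_of_message_passing(self):
        """With the self path zeroed, genes beyond graph distance L cannot reach a node."""
        graph = path_graph(6)
        spec = gg.GeneratorSpec(n_genes=6, latent_dim=2, n_mp_layers=2,
                                node_feature_dim=1, output_activation="identity")
        bundle = gg.build_graph_model(graph, None, spec, seed=0)
        gen = bundle.generator
        for W1 in gen.W1:
            W1.data[:] = 0.0  # disable self-path coupling
        rng = np.random.default_rng(4)
        h = rng.normal(size=(1, 6, 1))

        def run_layers(hin):
            out = ad.as_tensor(hin)
            for W1, W2 in zip(gen.W1, gen.W2):
                out = graphconv_layer(out, graph, W1, W2, operator=gen.operator)
            return out.data

        base = run_layers(h)
        far = h.copy()
        far[0, 5] += 100.0  # node 5 is at distance 5 > L = 2 from node 0
        bumped = run_layers(far)
        np.testing.assert_allclose(bumped[0, 0], base[0, 0], atol=1e-12)
        assert not np.allclose(bumped[0, 3], base[0, 3])  # distance 2: reachable


class TestCritic:
    def test_zero_final_layer_scores_zero(self, rng):
        critic = Critic(6, 0, np.random.default_rng(0))
        critic.mlp.layers[-1].W.data[:] = 0.0
        critic.mlp.layers[-1].b.data[:] = 0.0
        scores = critic_forward(critic, rng.normal(size=(5, 6)))
        np.testing.assert_array_equal(scores.data, np.zeros(5))

    def test_finite_for_large_inputs(self):
        critic = Critic(4, 0, np.random.default_rng(0))
        scores = critic_forward(critic, np.full((2, 4), 1e3))
        assert np.all(np.isfinite(scores.data))

    def test_conditioning_changes_score(self):
        critic = Critic(3, 2, np.random.default_rng(5))
        x = np.ones((1, 3))
        s1 = critic_forward(critic, x, np.array([[0.0, 0.0]])).data
        s2 = critic_forward(critic, x, np.array([[1.0, 0.0]])).data
        assert s1[0] != s2[0]

    def test_dimension_mismatch(self):
        critic = Critic(3, 0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            critic_forward(critic, np.ones((1, 4)))


class TestBaselines:
    def test_cvae_latent_dimension_fixed(self):
        bundle = gg.build_baseline("cvae", 10)
        assert bundle.generator.latent_dim == 64

    def test_wgan_gp_generator_output_length(self):
        bundle = gg.build_baseline("wgan_gp", 7)
        z = np.zeros((2, 64))
        assert bundle.generator.forward(z).shape == (2, 7)

    def test_unknown_kind(self):
        with pytest.raises(ValidationError):
            gg.build_baseline("diffusion", 5)

    def test_cvae_elbo_improves_on_gaussian_fixture(self):
        rng = np.random.default_rng(0)
        values = 0.5 + 0.1 * rng.standard_normal((64, 10))
        X = gg.ExpressionMatrix(values.clip(0, 1), [f"g{i}" for i in range(10)],
                                [f"s{i}" for i in range(64)], "minmax01")
        bundle = gg.build_baseline("cvae", 10, gene_ids=list(X.gene_ids))
        hist = gg.train_cvae(bundle, X, None, gg.TrainConfig(epochs=20, lr=1e-3, seed=0))
        smoothed = np.convolve(hist.critic_loss, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] < smoothed[0]


class TestCheckpointing:
    def test_save_load_reproduces_outputs(self, tmp_path, tiny_bundle):
        vocab = {k: list(v) for k, v in tiny_bundle.C.vocabularies.items()}
        spec = gg.GeneratorSpec(n_genes=20, n_mp_layers=2)
        bundle = gg.build_graph_model(tiny_bundle.graph, vocab, spec, seed=2)
        gg.save_model(bundle, tmp_path / "ckpt", graph=tiny_bundle.graph)
        back = gg.load_model(tmp_path / "ckpt")
        z = np.random.default_rng(0).standard_normal((3, spec.latent_dim))
        codes = tiny_bundle.C.code_matrix()[:3]
        np.testing.assert_array_equal(bundle.generator.forward(z, codes).data,
                                      back.generator.forward(z, codes).data)
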