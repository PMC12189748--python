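"""Generator architectures, covariate embeddings, and the Wasserstein critic.

The graph-informed generator maps a Gaussian latent vector, concatenated with
learned categorical-covariate embeddings, through a dense layer that assigns
one initial scalar per gene node, then refines these node features with L
rounds of message passing over the prior gene graph.  Two layer families are
provided:

* ``graphconv`` — 1-hop aggregation: h_i' = sigma(h_i W1 + sum_{j in N(i)} A_{j,i} h_j W2);
* ``h2gcn`` — heterophily-aware: separate degree-normalized 1-hop and 2-hop
  aggregates, concatenated ([agg1 || agg2]) without mixing in the ego
  embedding; a readout concatenates all intermediate representations and
  projects them to one value per gene.

The critic is a plain MLP emitting an unbounded scalar score (no terminal
squashing).  Baselines: fully connected GAN and WGAN-GP generators (two hidden
layers of 256, leaky ReLU) and a CVAE (one hidden layer of 256, latent 64).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .core_io import CovariateTable, ValidationError
from .graphs import GeneGraph, DENSE_LIMIT

LEAKY_SLOPE = 0.2


# ---------------------------------------------------------------------------
# covariate embeddings


def embedding_dim(l: int, rule: str = "l_plus_one") -> int:
    """Embedding dimension for a covariate with vocabulary size ``l``.

    ``l_plus_one`` is floor(l + 1); ``sqrt_plus_one`` is floor(sqrt(l)) + 1,
    the compact alternative (the literal rule makes embeddings larger than
    their vocabularies, which is unusual but kept as the default for fidelity).
    """
    if l < 1:
        raise ValidationError(f"vocabulary size must be >= 1, got {l}")
    if rule == "l_plus_one":
        return int(math.floor(l + 1))
    if rule == "sqrt_plus_one":
        return int(math.floor(math.sqrt(l))) + 1
    raise ValidationError(f"unknown embedding dimension rule {rule!r}")


class CovariateEmbedding:
    """Per-covariate learned embedding tables, concatenated in declaration order."""

    def __init__(self, vocabularies: dict[str, list[str]], rng, rule: str = "l_plus_one"):
        self.names = list(vocabularies)
        self.vocabularies = {k: list(v) for k, v in vocabularies.items()}
        self.rule = rule
        self.dims = {k: embedding_dim(len(v), rule) for k, v in self.vocabularies.items()}
        self.tables = {k: nn.Embedding(len(self.vocabularies[k]), self.dims[k], rng) for k in self.names}

    @property
    def m(self) -> int:
        return sum(self.dims.values())

    def __call__(self, codes: np.ndarray) -> Tensor:
        """(B, n_covariates) integer codes -> (B, m) embedding."""
        codes = np.atleast_2d(np.asarray(codes, dtype=np.intp))
        if codes.shape[1] != len(self.names):
            raise ValidationError(f"expected {len(self.names)} covariate codes, got {codes.shape[1]}")
        for j, name in enumerate(self.names):
            if codes[:, j].min(initial=0) < 0 or codes[:, j].max(initial=0) >= len(self.vocabularies[name]):
                raise ValidationError(f"code outside vocabulary for covariate {name!r}")
        blocks = [self.tables[name](codes[:, j]) for j, name in enumerate(self.names)]
        return ad.concat(blocks, axis=1)

    def embed_values(self, values: dict[str, str]) -> Tensor:
        """One category per covariate -> vector of length m."""
        codes = []
        for name in self.names:
            vocab = self.vocabularies[name]
            if values[name] not in vocab:
                raise ValidationError(f"value {values[name]!r} outside vocabulary of covariate {name!r}")
            codes.append(vocab.index(values[name]))
        return self(np.array([codes]))

    def parameters(self):
        return [p for name in self.names for p in self.tables[name].parameters()]


# ---------------------------------------------------------------------------
# message-passing operators derived from the prior graph


def _maybe_dense(S: sp.spmatrix, n: int):
    return np.asarray(S.todense()) if n <= DENSE_LIMIT else S.tocsr()


def graphconv_operator(graph: GeneGraph, aggregator: str = "sum", absolute: bool = False):
    """Mixing matrix S with S[i, j] = A[j, i]: aggregates in-neighbors of i."""
    if aggregator not in ("sum", "mean"):
        raise ValidationError(f"unknown aggregator {aggregator!r}")
    S = graph.adjacency(absolute=absolute).T.tocsr()
    if aggregator == "mean":
        indeg = np.asarray((S != 0).sum(axis=1)).ravel()
        scale = np.where(indeg > 0, 1.0 / np.maximum(indeg, 1), 0.0)
        S = sp.diags(scale) @ S
    return _maybe_dense(S, graph.n_genes)


def h2gcn_operators(graph: GeneGraph, normalization: str = "sym_sqrt_degree", absolute: bool = False):
    """Degree-normalized 1-hop and 2-hop mixing matrices (S1, S2).

    S1[i, j] = A[j, i] / norm(|N1(i)|, |N1(j)|) for 1-hop in-neighbors j;
    S2[i, k] = 1 / norm(|N2(i)|, |N2(k)|) for exact-distance-2 neighbors k
    (indicator weights: the prior assigns no weight to non-adjacent pairs).
    ``sym_sqrt_degree`` divides by sqrt(d_i * d_j); ``product_degree`` divides
    by d_i * d_j, the literal reading.
    """
    if normalization not in ("sym_sqrt_degree", "product_degree"):
        raise ValidationError(f"unknown normalization {normalization!r}")
    n = graph.n_genes
    A = graph.adjacency(absolute=absolute)  # A[j, i] = weight j -> i
    S1 = A.T.tocsr()
    B = (S1 != 0).astype(np.float64)  # B[i, j] = 1 iff j in N1(i)
    deg1 = np.asarray(B.sum(axis=1)).ravel()

    reach2 = (B @ B).tocsr()
    reach2.setdiag(0)
    reach2.eliminate_zeros()
    N2 = ((reach2 != 0).astype(np.float64) - (reach2 != 0).astype(np.float64).multiply(B != 0)).tocsr()
    N2.eliminate_zeros()
    deg2 = np.asarray((N2 != 0).sum(axis=1)).ravel()

    def normalize(S, deg):
        with np.errstate(divide="ignore"):
            if normalization == "sym_sqrt_degree":
                inv = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1)), 0.0)
            else:
                inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
        return sp.diags(inv) @ S @ sp.diags(inv)

    return _maybe_dense(normalize(S1, deg1), n), _maybe_dense(normalize(N2, deg2), n)


# ---------------------------------------------------------------------------
# functional layer operations (also used standalone in tests)


def init_node_features(z, c, W_I: Tensor, b_I: Tensor, activation=None) -> Tensor:
    """h0 = sigma(W_I v + b_I) with v = [z, c]; one scalar per gene node."""
    z = ad.as_tensor(z)
    parts = [z] if c is None else [z, ad.as_tensor(c)]
    v = ad.concat(parts, axis=-1) if len(parts) > 1 else parts[0]
    h0 = v @ W_I + b_I
    return activation(h0) if activation is not None else h0


def graphconv_layer(h, graph: GeneGraph, W1, W2, activation=None, aggregator: str = "sum",
                    operator=None) -> Tensor:
    """One GraphConv update: self term plus weighted 1-hop in-neighbor aggregate."""
    h = ad.as_tensor(h)
    S = graphconv_operator(graph, aggregator) if operator is None else operator
    out = h @ ad.as_tensor(W1) + ad.node_mix(S, h) @ ad.as_tensor(W2)
    return activation(out) if activation is not None else out


def h2gcn_layer(h, graph: GeneGraph, W1, W2, normalization: str = "sym_sqrt_degree",
                operators=None) -> Tensor:
    """One heterophily-aware update: [1-hop aggregate || 2-hop aggregate].

    The ego embedding is not mixed into either block; nodes with an empty
    neighborhood contribute a zero block.  Output width is doubled when W1 and
    W2 are square.
    """
    h = ad.as_tensor(h)
    S1, S2 = h2gcn_operators(graph, normalization) if operators is None else operators
    agg1 = ad.node_mix(S1, h @ ad.as_tensor(W1))
    agg2 = ad.node_mix(S2, h @ ad.as_tensor(W2))
    return ad.concat([agg1, agg2], axis=-1)


def h2gcn_readout(intermediates, W_c, f=None) -> Tensor:
    """Concatenate all intermediate node representations and project per node."""
    if not intermediates:
        raise ValidationError("h2gcn readout needs at least one intermediate representation")
    h_final = ad.concat([ad.as_tensor(h) for h in intermediates], axis=-1)
    y = h_final @ ad.as_tensor(W_c)
    return f(y) if f is not None else y


# ---------------------------------------------------------------------------
# generator / critic specs and modules


@dataclass
class GeneratorSpec:
    n_genes: int
    latent_dim: int = 64
    layer_family: str = "graphconv"  # or "h2gcn"
    n_mp_layers: int = 4
    node_feature_dim: int = 8
    output_activation: str = "sigmoid"  # or "identity"
    aggregator: str = "sum"
    h2gcn_normalization: str = "sym_sqrt_degree"
    abs_weights: bool = False
    leaky_slope: float = LEAKY_SLOPE

    def __post_init__(self):
        if self.n_mp_layers < 1:
            raise ValidationError("need at least one message-passing layer")
        if self.layer_family not in ("graphconv", "h2gcn"):
            raise ValidationError(f"unknown layer family {self.layer_family!r}")
        if self.output_activation not in ("sigmoid", "identity"):
            raise ValidationError(f"unknown output activation {self.output_activation!r}")


def _output_activation(name: str):
    return ad.sigmoid if name == "sigmoid" else None


class GraphGenerator:
    """Graph-informed generator: dense init, L message-passing layers, readout."""

    def __init__(self, spec: GeneratorSpec, graph: GeneGraph, embedding: CovariateEmbedding | None,
                 rng: np.random.Generator):
        if graph.n_genes != spec.n_genes:
            raise ValidationError("graph gene count does not match generator spec")
        self.spec = spec
        self.graph = graph
        self.embedding = embedding
        m = embedding.m if embedding is not None else 0
        self.init_layer = nn.Linear(spec.latent_dim + m, spec.n_genes, rng)
        p = spec.node_feature_dim
        L = spec.n_mp_layers
        if spec.layer_family == "graphconv":
            self.operator = graphconv_operator(graph, spec.aggregator, spec.abs_weights)
            dims = [1] + [p] * (L - 1) + [1] if L > 1 else [1, 1]
            self.W1 = [nn.parameter(nn.glorot(rng, a, b)) for a, b in zip(dims[:-1], dims[1:])]
            self.W2 = [nn.parameter(nn.glorot(rng, a, b)) for a, b in zip(dims[:-1], dims[1:])]
            self.W_c = None
        else:
            self.operators = h2gcn_operators(graph, spec.h2gcn_normalization, spec.abs_weights)
            widths = [1]
            for _ in range(L):
                widths.append(2 * widths[-1])
            self.W1 = [nn.parameter(nn.glorot(rng, w, w)) for w in widths[:-1]]
            self.W2 = [nn.parameter(nn.glorot(rng, w, w)) for w in widths[:-1]]
            self.W_c = nn.parameter(nn.glorot(rng, sum(widths), 1))

    def forward(self, z, codes=None) -> Tensor:
        """(B, latent_dim) noise + per-sample covariate codes -> (B, n_genes)."""
        z = ad.as_tensor(z)
        c = self.embedding(codes) if self.embedding is not None else None
        h0 = init_node_features(z, c, self.init_layer.W, self.init_layer.b,
                                activation=lambda t: ad.leaky_relu(t, self.spec.leaky_slope))
        B = h0.shape[0]
        h = ad.reshape(h0, (B, self.spec.n_genes, 1))
        if self.spec.layer_family == "graphconv":
            for t, (W1, W2) in enumerate(zip(self.W1, self.W2)):
                act = None if t == len(self.W1) - 1 else (lambda x: ad.leaky_relu(x, self.spec.leaky_slope))
                h = graphconv_layer(h, self.graph, W1, W2, activation=act, operator=self.operator)
            out = h
        else:
            intermediates = [h]
            for W1, W2 in zip(self.W1, self.W2):
                h = h2gcn_layer(h, self.graph, W1, W2, operators=self.operators)
                intermediates.append(h)
            out = h2gcn_readout(intermediates, self.W_c)
        out = ad.reshape(out, (B, self.spec.n_genes))
        act = _output_activation(self.spec.output_activation)
        return act(out) if act is not None else out

    def parameters(self):
        params = [] if self.embedding is None else self.embedding.parameters()
        params = params + self.init_layer.parameters() + self.W1 + self.W2
        if self.W_c is not None:
            params = params + [self.W_c]
        return params


class FCGenerator:
    """Fully connected baseline generator: two hidden layers of 256, leaky ReLU."""

    def __init__(self, n_genes: int, latent_dim: int, embedding: CovariateEmbedding | None,
                 rng, hidden=(256, 256), output_activation: str = "sigmoid"):
        self.embedding = embedding
        self.output_activation = output_activation
        m = embedding.m if embedding is not None else 0
        self.mlp = nn.MLP([latent_dim + m, *hidden, n_genes], rng, slope=LEAKY_SLOPE,
                          out_activation=_output_activation(output_activation))
        self.latent_dim = latent_dim
        self.n_genes = n_genes

    def forward(self, z, codes=None) -> Tensor:
        z = ad.as_tensor(z)
        if self.embedding is not None:
            z = ad.concat([z, self.embedding(codes)], axis=1)
        return self.mlp(z)

    def parameters(self):
        params = [] if self.embedding is None else self.embedding.parameters()
        return params + self.mlp.parameters()


@dataclass
class CriticSpec:
    input_dim: int
    hidden: tuple = (256, 256)
    leaky_slope: float = LEAKY_SLOPE


class Critic:
    """MLP critic emitting one unbounded score per sample."""

    def __init__(self, n_genes: int, cond_dim: int, rng, hidden=(256, 256)):
        self.spec = CriticSpec(n_genes + cond_dim, tuple(hidden))
        self.cond_dim = cond_dim
        self.mlp = nn.MLP([n_genes + cond_dim, *hidden, 1], rng, slope=LEAKY_SLOPE)

    def forward(self, x, c=None) -> Tensor:
        x = ad.as_tensor(x)
        if self.cond_dim:
            if c is None:
                raise ValidationError("critic is conditioned; covariate vector required")
            x = ad.concat([x, ad.as_tensor(c)], axis=1)
        elif c is not None and ad.as_tensor(c).shape[-1] != 0:
            raise ValidationError("critic is unconditioned; got a covariate vector")
        score = self.mlp(x)
        return ad.reshape(score, (score.shape[0],))

    def parameters(self):
        return self.mlp.parameters()


def generator_forward(generator, z, codes=None) -> Tensor:
    return generator.forward(z, codes)


def critic_forward(critic: Critic, x, c=None) -> Tensor:
    return critic.forward(x, c)


# ---------------------------------------------------------------------------
# CVAE baseline


class CVAE:
    """Conditional VAE: 1 hidden layer of 256 in encoder and decoder, latent 64."""

    def __init__(self, n_genes: int, embedding: CovariateEmbedding | None, rng,
                 latent_dim: int = 64, hidden: int = 256, output_activation: str = "sigmoid"):
        self.embedding = embedding
        m = embedding.m if embedding is not None else 0
        self.latent_dim = latent_dim
        self.n_genes = n_genes
        self.encoder = nn.MLP([n_genes + m, hidden, 2 * latent_dim], rng, slope=LEAKY_SLOPE)
        self.decoder = nn.MLP([latent_dim + m, hidden, n_genes], rng, slope=LEAKY_SLOPE,
                              out_activation=_output_activation(output_activation))

    def encode(self, x, codes=None):
        x = ad.as_tensor(x)
        if self.embedding is not None:
            x = ad.concat([x, self.embedding(codes)], axis=1)
        stats = self.encoder(x)
        mu = ad.getitem(stats, (slice(None), slice(0, self.latent_dim)))
        logvar = ad.getitem(stats, (slice(None), slice(self.latent_dim, 2 * self.latent_dim)))
        return mu, logvar

    def decode(self, zlat, codes=None) -> Tensor:
        zlat = ad.as_tensor(zlat)
        if self.embedding is not None:
            zlat = ad.concat([zlat, self.embedding(codes)], axis=1)
        return self.decoder(zlat)

    def forward(self, x, codes, eps) -> tuple[Tensor, Tensor, Tensor]:
        """Reparameterized pass; ``eps`` is externally drawn N(0,1) noise."""
        mu, logvar = self.encode(x, codes)
        zlat = mu + ad.exp(logvar * 0.5) * ad.as_tensor(eps)
        return self.decode(zlat, codes), mu, logvar

    def parameters(self):
        params = [] if self.embedding is None else self.embedding.parameters()
        return params + self.encoder.parameters() + self.decoder.parameters()


# ---------------------------------------------------------------------------
# model bundles and checkpointing


@dataclass
class ModelBundle:
    """A generator (+critic/encoder) with its conditioning and build metadata."""

    kind: str  # graph_wgan_gp | wgan_gp | gan | cvae
    generator: object
    critic: object | None
    embedding: CovariateEmbedding | None
    gene_ids: list[str]
    config: dict = field(default_factory=dict)

    def parameters(self):
        seen, out = set(), []
        modules = [self.generator] + ([self.critic] if self.critic is not None else [])
        for module in modules:
            for p in module.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out


def build_graph_model(graph: GeneGraph, vocabularies: dict[str, list[str]] | None,
                      spec: GeneratorSpec | None = None, seed: int = 0,
                      embedding_rule: str = "l_plus_one",
                      condition_critic: bool = True) -> ModelBundle:
    """Graph-informed WGAN-GP bundle; embeddings shared between generator and critic."""
    rng = np.random.default_rng(seed)
    spec = spec or GeneratorSpec(n_genes=graph.n_genes)
    embedding = CovariateEmbedding(vocabularies, rng, embedding_rule) if vocabularies else None
    generator = GraphGenerator(spec, graph, embedding, rng)
    cond_dim = embedding.m if (embedding is not None and condition_critic) else 0
    critic = Critic(graph.n_genes, cond_dim, rng)
    return ModelBundle(
        kind="graph_wgan_gp", generator=generator, critic=critic, embedding=embedding,
        gene_ids=list(graph.gene_ids),
        config={"seed": seed, "spec": asdict(spec), "embedding_rule": embedding_rule,
                "condition_critic": condition_critic,
                "vocabularies": vocabularies or {}},
    )


def build_baseline(kind: str, n_genes: int, vocabularies: dict[str, list[str]] | None = None,
                   latent_dim: int = 64, seed: int = 0, output_activation: str = "sigmoid",
                   embedding_rule: str = "l_plus_one", gene_ids: list[str] | None = None,
                   condition_critic: bool = True) -> ModelBundle:
    """Baseline bundles: 'gan', 'wgan_gp' (fully connected), or 'cvae'."""
    if kind not in ("gan", "wgan_gp", "cvae"):
        raise ValidationError(f"unknown baseline kind {kind!r}")
    rng = np.random.default_rng(seed)
    embedding = CovariateEmbedding(vocabularies, rng, embedding_rule) if vocabularies else None
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    config = {"seed": seed, "latent_dim": latent_dim, "output_activation": output_activation,
              "embedding_rule": embedding_rule, "condition_critic": condition_critic,
              "vocabularies": vocabularies or {}}
    if kind == "cvae":
        model = CVAE(n_genes, embedding, rng, latent_dim=64, output_activation=output_activation)
        return ModelBundle(kind, model, None, embedding, gene_ids, config)
    generator = FCGenerator(n_genes, latent_dim, embedding, rng, output_activation=output_activation)
    cond_dim = embedding.m if (embedding is not None and condition_critic) else 0
    critic = Critic(n_genes, cond_dim, rng)
    return ModelBundle(kind, generator, critic, embedding, gene_ids, config)


def sample_from(bundle: ModelBundle, n: int, codes: np.ndarray | None, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` synthetic expression rows (no gradient tracking)."""
    with ad.no_grad():
        if bundle.kind == "cvae":
            z = rng.standard_normal((n, bundle.generator.latent_dim))
            return bundle.generator.decode(z, codes).data
        z = rng.standard_normal((n, bundle.generator.latent_dim
                                 if isinstance(bundle.generator, FCGenerator)
                                 else bundle.generator.spec.latent_dim))
        return bundle.generator.forward(z, codes).data


def resample_codes(C: CovariateTable, n: int, rng: np.random.Generator) -> np.ndarray:
    """Resample covariate code rows from the empirical training distribution."""
    rows = rng.integers(0, len(C.sample_ids), size=n)
    return C.code_matrix()[rows]


def save_model(bundle: ModelBundle, directory, graph: GeneGraph | None = None) -> None:
    """Checkpoint = parameter archive + JSON spec sidecar (+ graph files)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params = bundle.parameters()
    np.savez(directory / "params.npz", **{f"p{i}": p.data for i, p in enumerate(params)})
    sidecar = {"kind": bundle.kind, "gene_ids": bundle.gene_ids, "config": bundle.config,
               "n_params": len(params)}
    (directory / "spec.json").write_text(json.dumps(sidecar, indent=1))
    if graph is not None:
        graph.save(directory / "graph_edges.tsv", directory / "graph_meta.json")


def load_model(directory) -> ModelBundle:
    directory = Path(directory)
    sidecar = json.loads((directory / "spec.json").read_text())
    config = sidecar["config"]
    vocab = config.get("vocabularies") or None
    if sidecar["kind"] == "graph_wgan_gp":
        graph = GeneGraph.load(directory / "graph_edges.tsv", directory / "graph_meta.json")
        spec = GeneratorSpec(**config["spec"])
        bundle = build_graph_model(graph, vocab, spec, seed=config["seed"],
                                   embedding_rule=config["embedding_rule"],
                                   condition_critic=config["condition_critic"])
    elif sidecar["kind"] == "cvae":
        bundle = build_baseline("cvae", len(sidecar["gene_ids"]), vocab, seed=config["seed"],
                                output_activation=config["output_activation"],
                                embedding_rule=config["embedding_rule"],
                                gene_ids=sidecar["gene_ids"])
    else:
        bundle = build_baseline(sidecar["kind"], len(sidecar["gene_ids"]), vocab,
                                latent_dim=config["latent_dim"], seed=config["seed"],
                                output_activation=config["output_activation"],
                                embedding_rule=config["embedding_rule"],
                                gene_ids=sidecar["gene_ids"],
                                condition_critic=config["condition_critic"])
    archive = np.load(directory / "params.npz")
    params = bundle.parameters()
    if len(params) != sidecar["n_params"]:
        raise ValidationError("checkpoint parameter count does not match rebuilt architecture")
    for i, p in enumerate(params):
        stored = archive[f"p{i}"]
        if stored.shape != p.data.shape:
            raise ValidationError(f"parameter {i} shape mismatch: {stored.shape} vs {p.data.shape}")
        p.data = stored.astype(np.float64)
    return bundle
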