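"""Seeded simulator for expression matrices with a planted regulatory graph.

The generative scheme is a linear-Gaussian structural equation model (SEM)
over a signed directed acyclic gene graph.  Regulator ("TF") genes sit
upstream; each edge carries a sign (+1 activation, -1 repression, drawn with
probability ``repression_prob``) and a latent magnitude drawn from
``edge_weight_range``.  Samples are drawn in topological order:

    x_j = mu[class(sample), j] + sum_{i in parents(j)} w_ij * x_i + eps_j

Class-conditional mean shifts (scale ``effect_size``) model tissue/condition
structure; covariates are categorical with configurable, possibly imbalanced
proportions, including an explicit MISSING class.  Exogenous (parentless)
genes receive intrinsic noise with sd ``driver_sd`` (default 1), while
downstream genes receive sd ``noise_sd``: regulators integrate many unmodeled
inputs, so their intrinsic variance is larger than the residual noise of the
genes they drive.  This separation is what makes strongly weighted edges
recoverable by correlation thresholding at low noise.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core_io import (
    MISSING,
    CovariateTable,
    ExpressionMatrix,
    NormalizationSpec,
    ValidationError,
    fit_normalizer,
    write_covariate_table,
    write_expression_table,
)
from .graphs import GeneGraph


@dataclass
class CovariateSpec:
    name: str
    categories: list[str]
    proportions: list[float]

    def __post_init__(self):
        if len(self.categories) != len(self.proportions):
            raise ValidationError("categories and proportions must align")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError(f"proportions of {self.name!r} must sum to 1")


@dataclass
class SimSpec:
    n_genes: int = 50
    n_tf: int = 10
    edge_prob: float = 0.03
    repression_prob: float = 0.25
    n_samples: int = 500
    covariates: list[CovariateSpec] = field(default_factory=list)
    effect_size: float = 0.5
    edge_weight_range: tuple[float, float] = (0.6, 0.95)
    noise_sd: float = 0.3
    driver_sd: float = 1.0
    max_in_degree: int | None = 1
    seed: int = 0

    def __post_init__(self):
        for p in (self.edge_prob, self.repression_prob):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")
        if self.n_tf > self.n_genes:
            raise ValidationError("n_tf cannot exceed n_genes")
        if self.noise_sd <= 0 or self.driver_sd <= 0:
            raise ValidationError("noise standard deviations must be positive")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1)


def simulate_grn(spec: SimSpec) -> GeneGraph:
    """Sample a signed directed acyclic regulatory graph.

    Admissible edges run from a regulator gene i (< n_tf) to any
    higher-indexed gene j, which guarantees acyclicity.  With the default
    in-degree cap of 1 each gene j draws at most one regulator, chosen
    uniformly among its admissible regulators, with the marginal per-pair
    edge probability kept at ``edge_prob`` (sparse, modular regulation; an
    uncapped Bernoulli-per-pair variant is available with
    ``max_in_degree=None``).  The cap keeps the variance of a regulated gene
    dominated by a single upstream driver, so strongly weighted edges remain
    recoverable by correlation thresholding.  The graph's weights are the
    signs (+1/-1); the latent SEM magnitudes are stored in
    ``meta['sem_weights']`` for downstream sampling and recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    sources, targets = [], []
    if spec.max_in_degree is None:
        for i in range(spec.n_tf):
            for j in range(i + 1, spec.n_genes):
                if rng.uniform() < spec.edge_prob:
                    sources.append(i)
                    targets.append(j)
    else:
        for j in range(1, spec.n_genes):
            n_regulators = min(j, spec.n_tf)
            count = min(spec.max_in_degree, rng.binomial(n_regulators, spec.edge_prob))
            for i in rng.choice(n_regulators, size=count, replace=False):
                sources.append(int(i))
                targets.append(j)
    n_edges = len(sources)
    signs = np.where(rng.uniform(size=n_edges) < spec.repression_prob, -1.0, 1.0)
    lo, hi = spec.edge_weight_range
    magnitudes = rng.uniform(lo, hi, size=n_edges)
    gene_ids = [f"TF{i:03d}" if i < spec.n_tf else f"G{i:03d}" for i in range(spec.n_genes)]
    return GeneGraph(
        gene_ids,
        np.array(sources, dtype=np.intp),
        np.array(targets, dtype=np.intp),
        signs,
        directed=True,
        signed=True,
        meta={"kind": "simulated_grn", "sem_weights": (signs * magnitudes).tolist(),
              "n_tf": spec.n_tf, "seed": spec.seed},
    )


def _sample_covariates(spec: SimSpec, rng: np.random.Generator) -> CovariateTable:
    sample_ids = [f"S{i:05d}" for i in range(spec.n_samples)]
    covariates = {}
    vocabularies = {}
    specs = spec.covariates or [CovariateSpec("condition", ["A", "B"], [0.5, 0.5])]
    for cov in specs:
        draws = rng.choice(len(cov.categories), size=spec.n_samples, p=cov.proportions)
        covariates[cov.name] = [cov.categories[d] for d in draws]
        vocabularies[cov.name] = list(cov.categories)
    return CovariateTable(sample_ids, covariates, vocabularies)


def simulate_expression(graph: GeneGraph, spec: SimSpec,
                        sample_seed: int | None = None) -> tuple[ExpressionMatrix, CovariateTable]:
    """Draw samples from the linear-Gaussian SEM defined by ``graph``.

    The population structure — the per-(class, gene) mean shifts of scale
    ``effect_size`` — is fixed by ``spec.seed``; covariate draws and residual
    noise come from ``sample_seed`` (default: derived from ``spec.seed``), so
    passing a different ``sample_seed`` yields an independent replicate from
    the *same* population.  Sampling proceeds gene by gene in topological
    order (the simulated graphs index parents below children).
    """
    structure_rng = np.random.default_rng(spec.seed + 1)
    rng = np.random.default_rng(spec.seed + 2 if sample_seed is None else sample_seed)
    weights = np.asarray(graph.meta.get("sem_weights", graph.weights), dtype=np.float64)
    # reject cyclic inputs: require a topological order
    order = _topological_order(graph)
    C = _sample_covariates(spec, rng)
    codes = C.code_matrix()
    # class index = mixed-radix code over the full vocabularies, so the mean
    # table is identical across replicates regardless of which combinations
    # happen to be realized
    sizes = [len(C.vocabularies[name]) for name in C.names]
    class_of = np.zeros(spec.n_samples, dtype=np.intp)
    for j, size in enumerate(sizes):
        class_of = class_of * size + codes[:, j]
    n_classes = int(np.prod(sizes))
    mu = structure_rng.normal(scale=spec.effect_size, size=(n_classes, spec.n_genes))

    parents: list[list[tuple[int, float]]] = [[] for _ in range(graph.n_genes)]
    for s, t, w in zip(graph.sources, graph.targets, weights):
        parents[t].append((int(s), float(w)))

    X = np.zeros((spec.n_samples, graph.n_genes))
    for j in order:
        sd = spec.driver_sd if not parents[j] else spec.noise_sd
        x = mu[class_of, j] + rng.normal(scale=sd, size=spec.n_samples)
        for i, w in parents[j]:
            x = x + w * X[:, i]
        X[:, j] = x
    Xm = ExpressionMatrix(X, list(graph.gene_ids), list(C.sample_ids), "raw")
    return Xm, C


def _topological_order(graph: GeneGraph) -> list[int]:
    n = graph.n_genes
    indeg = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for s, t in zip(graph.sources, graph.targets):
        indeg[t] += 1
        children[s].append(int(t))
    queue = [i for i in range(n) if indeg[i] == 0]
    order = []
    while queue:
        i = queue.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        raise ValidationError("the regulatory graph is cyclic; the SEM needs a DAG")
    return order


# ---------------------------------------------------------------------------
# ready-made fixtures


@dataclass
class FixtureBundle:
    spec: SimSpec
    graph: GeneGraph
    X_raw: ExpressionMatrix
    C: CovariateTable
    normalizer: NormalizationSpec
    train_idx: np.ndarray
    test_idx: np.ndarray


PROFILES = {
    # name: (n_genes, n_tf, n_samples, covariate spec, edge_prob)
    "tiny": SimSpec(
        n_genes=20, n_tf=5, n_samples=64, edge_prob=0.10,
        covariates=[CovariateSpec("condition", ["A", "B"], [0.5, 0.5])],
        seed=11,
    ),
    "small": SimSpec(
        n_genes=50, n_tf=10, n_samples=500, edge_prob=0.03,
        covariates=[CovariateSpec("condition", ["A", "B", MISSING], [0.6, 0.3, 0.1])],
        seed=12,
    ),
    "medium": SimSpec(
        n_genes=200, n_tf=20, n_samples=1000, edge_prob=0.02,
        covariates=[CovariateSpec("condition", ["A", "B", "C", "D", MISSING],
                                  [0.35, 0.25, 0.2, 0.12, 0.08])],
        seed=13,
    ),
}


def make_fixture(profile: str = "small", seed: int | None = None) -> FixtureBundle:
    """Simulate a complete study bundle: graph, expression, covariates, splits.

    Profiles: tiny = 20 genes x 64 samples (2 balanced classes); small = 50 x
    500 (3 classes, imbalanced, with a MISSING class); medium = 200 x 1000
    (5 classes).  A min-max normalizer is fitted on the training split; the
    70/30 split is deterministic under the profile seed.
    """
    if profile not in PROFILES:
        raise ValidationError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    spec = PROFILES[profile]
    if seed is not None:
        spec = SimSpec(**{**asdict(spec), "seed": seed,
                          "covariates": spec.covariates})
    graph = simulate_grn(spec)
    X, C = simulate_expression(graph, spec)
    rng = np.random.default_rng(spec.seed + 2)
    perm = rng.permutation(spec.n_samples)
    n_train = int(round(0.7 * spec.n_samples))
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    normalizer = fit_normalizer(X.subset_samples(train_idx), "minmax01")
    return FixtureBundle(spec, graph, X, C, normalizer, train_idx, test_idx)


def write_fixture(bundle: FixtureBundle, directory) -> None:
    """Write the bundle as TSVs + edge list + a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression_table(bundle.X_raw, directory / "expression.tsv")
    write_covariate_table(bundle.C, directory / "covariates.tsv")
    bundle.graph.save(directory / "graph_edges.tsv", directory / "graph_meta.json")
    (directory / "normalizer.json").write_text(bundle.normalizer.to_json())
    manifest = {
        "spec": json.loads(bundle.spec.to_json()),
        "train_idx": bundle.train_idx.tolist(),
        "test_idx": bundle.test_idx.tolist(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
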