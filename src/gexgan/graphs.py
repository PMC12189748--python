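"""Prior gene graphs: co-expression and signed regulatory networks.

Two conventions, matching how each graph type conditions the generator:

* co-expression graphs are undirected and weighted; an edge joins genes whose
  expression correlation clears a threshold, with the correlation (or its
  sign, if binarized) as the weight;
* regulatory graphs are directed and signed, weight +1 for activation and -1
  for repression, read from an edge-list file.  Regulation is not mirrored.

Graphs are stored as sparse edge lists; undirected edges are stored once with
``source < target`` and exposed symmetrically where needed.  Dense adjacency is
only materialized on demand and never for more than 2000 genes.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .core_io import ExpressionMatrix, ValidationError, ParseError

logger = logging.getLogger(__name__)

DENSE_LIMIT = 2000

_POSITIVE_TOKENS = {"+", "+1", "1", "activation", "activator", "positive"}
_NEGATIVE_TOKENS = {"-", "-1", "−", "−1", "repression", "repressor", "inhibition", "negative"}


@dataclass
class GeneGraph:
    """Sparse gene-gene graph aligned to an expression matrix's gene order."""

    gene_ids: list[str]
    sources: np.ndarray  # edge source indices
    targets: np.ndarray  # edge target indices
    weights: np.ndarray
    directed: bool
    signed: bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gene_ids = list(map(str, self.gene_ids))
        self.sources = np.asarray(self.sources, dtype=np.intp)
        self.targets = np.asarray(self.targets, dtype=np.intp)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        n = len(self.gene_ids)
        if self.sources.shape != self.targets.shape or self.sources.shape != self.weights.shape:
            raise ValidationError("edge arrays must have equal length")
        if self.n_edges and (
            self.sources.min() < 0 or self.sources.max() >= n or self.targets.min() < 0 or self.targets.max() >= n
        ):
            raise ValidationError("edge indices outside [0, n_genes)")
        if np.any(self.sources == self.targets):
            raise ValidationError("self-loops are not allowed")
        if self.signed and self.n_edges and not np.all(np.isin(self.weights, (-1.0, 1.0))):
            raise ValidationError("signed graph weights must be in {-1, +1}")
        if not self.directed and self.n_edges:
            # canonical storage: each undirected edge once, source < target
            lo = np.minimum(self.sources, self.targets)
            hi = np.maximum(self.sources, self.targets)
            order = np.lexsort((hi, lo))
            self.sources, self.targets, self.weights = lo[order], hi[order], self.weights[order]
            pairs = self.sources * n + self.targets
            if len(np.unique(pairs)) != len(pairs):
                raise ValidationError("duplicate undirected edges")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.sources)

    def symmetrized_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sources, targets, weights) with both directions for undirected graphs."""
        if self.directed:
            return self.sources, self.targets, self.weights
        return (
            np.concatenate([self.sources, self.targets]),
            np.concatenate([self.targets, self.sources]),
            np.concatenate([self.weights, self.weights]),
        )

    def adjacency(self, absolute: bool = False) -> sp.csr_matrix:
        """Sparse adjacency A with A[i, j] = weight of edge i -> j."""
        s, t, w = self.symmetrized_edges()
        if absolute:
            w = np.abs(w)
        return sp.csr_matrix((w, (s, t)), shape=(self.n_genes, self.n_genes))

    def in_neighbors(self, node: int) -> np.ndarray:
        s, t, _ = self.symmetrized_edges()
        return np.unique(s[t == node])

    def save(self, edge_path, meta_path=None) -> None:
        """Write the edge list as TSV (+ optional JSON meta sidecar)."""
        with open(edge_path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for s, t, w in zip(self.sources, self.targets, self.weights):
                fh.write(f"{self.gene_ids[s]}\t{self.gene_ids[t]}\t{w:.10g}\n")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump(
                    {
                        "gene_ids": self.gene_ids,
                        "directed": self.directed,
                        "signed": self.signed,
                        "meta": self.meta,
                    },
                    fh,
                    indent=1,
                )

    @classmethod
    def load(cls, edge_path, meta_path) -> "GeneGraph":
        with open(meta_path) as fh:
            info = json.load(fh)
        gene_ids = info["gene_ids"]
        lookup = {g: i for i, g in enumerate(gene_ids)}
        src, tgt, wts = [], [], []
        with open(edge_path) as fh:
            header = fh.readline()
            assert header.startswith("source")
            for line in fh:
                a, b, w = line.rstrip("\n").split("\t")
                src.append(lookup[a])
                tgt.append(lookup[b])
                wts.append(float(w))
        return cls(gene_ids, np.array(src, dtype=np.intp), np.array(tgt, dtype=np.intp),
                   np.array(wts), info["directed"], info["signed"], info.get("meta", {}))


# ---------------------------------------------------------------------------
# builders


def build_coexpression_graph(
    X: ExpressionMatrix, threshold: float, binarize: bool = False, meta: dict | None = None
) -> GeneGraph:
    """Threshold the absolute pairwise Pearson correlation into an undirected graph.

    Edge (i, j) is present iff |corr(g_i, g_j)| >= threshold; the weight is the
    correlation itself, or its sign if ``binarize``.  Correlation is computed
    on the matrix as given (normalize first if the generator trains in a
    normalized space).  Constant genes produce no edges.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    if X.n_samples < 3:
        raise ValidationError("need at least 3 samples to estimate correlations")
    sd = X.values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.values, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant genes -> no edges
    np.fill_diagonal(corr, 0.0)
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    iu, ju = np.triu_indices(X.n_genes, k=1)
    keep = np.abs(corr[iu, ju]) >= threshold
    weights = corr[iu[keep], ju[keep]]
    if binarize:
        weights = np.sign(weights)
    return GeneGraph(
        list(X.gene_ids),
        iu[keep],
        ju[keep],
        weights,
        directed=False,
        signed=bool(binarize),
        meta={"kind": "coexpression", "threshold": threshold, "binarize": binarize,
              "corr": "pearson", **(meta or {})},
    )


def build_tissue_graphs(
    X: ExpressionMatrix,
    tissue_labels,
    threshold: float,
    combine: str = "union_max_abs",
    binarize: bool = False,
):
    """Per-tissue co-expression graphs, optionally merged into one prior.

    ``combine='per_tissue'`` returns {tissue: GeneGraph}; ``'union_max_abs'``
    merges them, keeping per gene pair the weight of maximum absolute value
    (one prior for the single generator).  Tissue groups with fewer than 3
    samples are skipped with a warning.
    """
    if combine not in ("union_max_abs", "per_tissue"):
        raise ValidationError(f"unknown combine mode {combine!r}")
    labels = np.asarray([str(t) for t in tissue_labels])
    if len(labels) != X.n_samples:
        raise ValidationError("one tissue label per sample required")
    per_tissue: dict[str, GeneGraph] = {}
    for tissue in sorted(set(labels)):
        rows = np.flatnonzero(labels == tissue)
        if len(rows) < 3:
            warnings.warn(f"tissue {tissue!r} has {len(rows)} samples (<3); skipped", stacklevel=2)
            continue
        sub = X.subset_samples(rows)
        per_tissue[tissue] = build_coexpression_graph(
            sub, threshold, binarize=binarize, meta={"tissue": tissue}
        )
    if combine == "per_tissue":
        return per_tissue
    n = X.n_genes
    best: dict[int, float] = {}
    for g in per_tissue.values():
        for s, t, w in zip(g.sources, g.targets, g.weights):
            key = int(s) * n + int(t)
            if key not in best or abs(w) > abs(best[key]):
                best[key] = float(w)
    keys = np.array(sorted(best), dtype=np.intp)
    weights = np.array([best[k] for k in keys])
    return GeneGraph(
        list(X.gene_ids),
        keys // n,
        keys % n,
        weights,
        directed=False,
        signed=bool(binarize),
        meta={"kind": "coexpression_union_max_abs", "threshold": threshold,
              "tissues": sorted(per_tissue)},
    )


def load_regulatory_graph(path, gene_universe: list[str]) -> GeneGraph:
    """Load a signed directed regulatory edge list (regulator, target, sign).

    Sign tokens may be +/-, +1/-1, or activation/repression words.  Edges
    touching genes outside ``gene_universe`` are dropped and counted in meta.
    Contradictory duplicates (same ordered pair, both signs) keep the last
    occurrence, with a warning.
    """
    gene_universe = list(map(str, gene_universe))
    lookup = {g: i for i, g in enumerate(gene_universe)}
    edges: dict[tuple[int, int], float] = {}
    dropped = 0
    contradictions = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.lower().startswith(("source", "regulator", "tf"))):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            reg, tgt, sign_token = parts[0].strip(), parts[1].strip(), parts[2].strip().lower()
            if sign_token in _POSITIVE_TOKENS:
                sign = 1.0
            elif sign_token in _NEGATIVE_TOKENS:
                sign = -1.0
            else:
                raise ParseError(f"line {lineno}: unparseable sign token {parts[2]!r}")
            if reg not in lookup or tgt not in lookup:
                dropped += 1
                continue
            key = (lookup[reg], lookup[tgt])
            if key[0] == key[1]:
                dropped += 1
                continue
            if key in edges and edges[key] != sign:
                contradictions += 1
                warnings.warn(
                    f"contradictory regulatory edge {reg}->{tgt}; keeping the last sign", stacklevel=2
                )
            edges[key] = sign
    src = np.array([k[0] for k in edges], dtype=np.intp)
    tgt = np.array([k[1] for k in edges], dtype=np.intp)
    wts = np.array(list(edges.values()))
    return GeneGraph(
        gene_universe, src, tgt, wts, directed=True, signed=True,
        meta={"kind": "regulatory", "source_file": str(path), "dropped_edges": dropped,
              "contradictions": contradictions},
    )


# ---------------------------------------------------------------------------
# interrogation


def edge_homophily(graph: GeneGraph, node_values, similarity=None) -> float:
    """Mean similarity of connected node pairs, H(G) = (1/|E|) sum sim(j, k).

    ``similarity(a, b)`` must return values in [0, 1]; the default is the
    category-match indicator.  Computed over stored edges.
    """
    if graph.n_edges == 0:
        raise ValidationError("edge homophily is undefined on an empty edge set")
    if similarity is None:
        similarity = lambda a, b: 1.0 if a == b else 0.0  # noqa: E731
    values = list(node_values)
    sims = [similarity(values[s], values[t]) for s, t in zip(graph.sources, graph.targets)]
    if min(sims) < 0 or max(sims) > 1:
        raise ValidationError("similarity must return values in [0, 1]")
    return float(np.mean(sims))


def _in_neighbor_sets(graph: GeneGraph) -> list[set[int]]:
    s, t, _ = graph.symmetrized_edges()
    nbrs: list[set[int]] = [set() for _ in range(graph.n_genes)]
    for a, b in zip(s, t):
        nbrs[b].add(int(a))
    return nbrs


def two_hop_neighbors(graph: GeneGraph, node: int) -> set[int]:
    """Nodes at shortest-path distance exactly 2 from ``node``.

    Excludes the node itself and its 1-hop neighborhood.  For directed graphs
    the neighborhood orientation is incoming (regulators of regulators), since
    information flows source -> target in message passing.
    """
    if not 0 <= node < graph.n_genes:
        raise ValidationError(f"node index {node} outside [0, {graph.n_genes})")
    nbrs = _in_neighbor_sets(graph)
    one_hop = nbrs[node]
    two_hop: set[int] = set()
    for j in one_hop:
        two_hop |= nbrs[j]
    return two_hop - one_hop - {node}


def graph_density(graph: GeneGraph) -> float:
    """Percentage of possible gene pairs realized as edges (self-loops excluded)."""
    n = graph.n_genes
    if n < 2:
        raise ValidationError("density needs at least 2 genes")
    possible = n * (n - 1) if graph.directed else n * (n - 1) / 2
    return 100.0 * graph.n_edges / possible
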