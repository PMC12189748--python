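"""Expression-matrix and covariate containers, file I/O, normalization, filtering.

Expression data live in an :class:`ExpressionMatrix` (samples x genes, float64)
whose ``space_tag`` records which normalization has been applied.  Categorical
per-sample annotations live in a :class:`CovariateTable`; absent values are an
explicit ``MISSING`` category so that downstream conditioning and utility tests
can treat "unknown" as a first-class group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "MISSING"

RAW = "raw"
MINMAX01 = "minmax01"
LOG2_ZSCORE = "log2_zscore"


class ValidationError(ValueError):
    pass


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Samples x genes continuous expression with identifiers.

    Invariants: identifiers unique, shapes consistent, values finite, and
    ``space_tag == 'minmax01'`` implies values in [0, 1] up to 1e-9.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    space_tag: str = RAW

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D (samples x genes)")
        n_samples, n_genes = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {n_genes} columns")
        if len(self.sample_ids) != n_samples:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n_samples} rows")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {name} identifiers: {dupes[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values contain non-finite entries")
        if self.space_tag == MINMAX01:
            lo, hi = self.values.min(), self.values.max()
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValidationError(f"minmax01 matrix outside [0,1]: range ({lo}, {hi})")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, keep: list[int] | np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            self.values[keep], self.gene_ids, [self.sample_ids[i] for i in keep], self.space_tag
        )


@dataclass
class CovariateTable:
    """Per-sample categorical covariates with explicit vocabularies."""

    sample_ids: list[str]
    covariates: dict[str, list[str]]
    vocabularies: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.sample_ids = list(map(str, self.sample_ids))
        n = len(self.sample_ids)
        cleaned = {}
        for name, values in self.covariates.items():
            vals = [MISSING if (v is None or (isinstance(v, float) and np.isnan(v))) else str(v) for v in values]
            if len(vals) != n:
                raise ValidationError(f"covariate {name!r} has {len(vals)} values for {n} samples")
            cleaned[name] = vals
        self.covariates = cleaned
        if not self.vocabularies:
            self.vocabularies = {
                name: sorted(set(vals)) for name, vals in self.covariates.items()
            }
        for name, vals in self.covariates.items():
            vocab = set(self.vocabularies[name])
            bad = sorted(set(vals) - vocab)
            if bad:
                raise ValidationError(f"covariate {name!r} has values outside vocabulary: {bad[:5]}")

    @property
    def names(self) -> list[str]:
        return list(self.covariates)

    def codes(self, name: str) -> np.ndarray:
        """Integer codes of one covariate in vocabulary order."""
        lookup = {v: i for i, v in enumerate(self.vocabularies[name])}
        return np.array([lookup[v] for v in self.covariates[name]], dtype=np.intp)

    def code_matrix(self) -> np.ndarray:
        """(n_samples, n_covariates) integer code matrix, declaration order."""
        return np.stack([self.codes(name) for name in self.names], axis=1)

    def subset(self, keep) -> "CovariateTable":
        keep = np.asarray(keep)
        return CovariateTable(
            [self.sample_ids[i] for i in keep],
            {name: [vals[i] for i in keep] for name, vals in self.covariates.items()},
            dict(self.vocabularies),
        )


# ---------------------------------------------------------------------------
# file I/O


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_table(path, orientation: str = "samples_by_genes") -> ExpressionMatrix:
    """Read a delimited expression table into samples x genes orientation.

    The file must have one header row of column identifiers and one leading
    column of row identifiers; every body cell must be numeric.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False)
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(body.isna().values)
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"non-numeric cell {df.iloc[r, c]!r} at row {df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    values = body.values.astype(np.float64)
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if orientation == "genes_by_samples":
        values, rows, cols = values.T, cols, rows
    return ExpressionMatrix(values, gene_ids=cols, sample_ids=rows, space_tag=RAW)


def write_expression_table(X: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.gene_ids)
    df.to_csv(path, sep=_sep_for(path), float_format=float_format, index_label="sample_id")


def read_covariate_table(path, vocabularies: dict[str, list[str]] | None = None) -> CovariateTable:
    """Read a covariate table (sample_id column + one column per covariate)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str, keep_default_na=False)
    covariates = {}
    for col in df.columns:
        covariates[col] = [MISSING if v == "" else v for v in df[col]]
    return CovariateTable([str(i) for i in df.index], covariates, dict(vocabularies) if vocabularies else {})


def write_covariate_table(C: CovariateTable, path) -> None:
    df = pd.DataFrame(C.covariates, index=C.sample_ids)
    df.to_csv(path, sep=_sep_for(path), index_label="sample_id")


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizationSpec:
    """Per-gene normalization parameters fitted on training data.

    ``minmax01`` stores (min, max) per gene; ``log2_zscore`` stores the (mean,
    sd) of log2(x + pseudocount), with the population-sd convention (divide by
    n).  Degenerate genes (max == min, or sd == 0) are flagged and mapped to 0.
    """

    method: str
    gene_ids: list[str]
    param_a: np.ndarray  # min (minmax01) or mean (log2_zscore)
    param_b: np.ndarray  # max (minmax01) or sd (log2_zscore)
    pseudocount: float = 0.0

    @property
    def degenerate(self) -> np.ndarray:
        return self.param_b == self.param_a if self.method == MINMAX01 else self.param_b == 0.0

    def _index_for(self, gene_ids: list[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise ValidationError(f"genes not covered by normalizer: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=np.intp)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "gene_ids": self.gene_ids,
                "param_a": self.param_a.tolist(),
                "param_b": self.param_b.tolist(),
                "pseudocount": self.pseudocount,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationSpec":
        d = json.loads(text)
        return cls(
            d["method"], d["gene_ids"], np.asarray(d["param_a"]), np.asarray(d["param_b"]), d["pseudocount"]
        )


def fit_normalizer(X: ExpressionMatrix, method: str, pseudocount: float = 0.0) -> NormalizationSpec:
    """Fit per-gene normalization parameters on ``X`` (must be in raw space)."""
    if X.space_tag != RAW:
        raise ValidationError(f"normalizer must be fitted on raw data, got {X.space_tag!r}")
    if method == MINMAX01:
        return NormalizationSpec(method, list(X.gene_ids), X.values.min(axis=0), X.values.max(axis=0))
    if method == LOG2_ZSCORE:
        shifted = X.values + pseudocount
        if np.any(shifted <= 0):
            raise ValidationError(
                "log2_zscore requires positive values after adding the pseudocount; "
                f"minimum shifted value is {shifted.min()}"
            )
        logged = np.log2(shifted)
        mean = logged.mean(axis=0)
        sd = logged.std(axis=0)  # population convention (divide by n)
        return NormalizationSpec(method, list(X.gene_ids), mean, sd, pseudocount)
    raise ValidationError(f"unknown normalization method {method!r}")


def apply_normalizer(X: ExpressionMatrix, spec: NormalizationSpec, clip: bool = False) -> ExpressionMatrix:
    """Apply a fitted normalizer; degenerate genes map to 0.

    Values from samples outside the fitted range are not clipped unless
    ``clip`` is set (useful when post-processing generated samples).
    """
    idx = spec._index_for(X.gene_ids)
    a, b = spec.param_a[idx], spec.param_b[idx]
    degen = spec.degenerate[idx]
    if spec.method == MINMAX01:
        span = np.where(degen, 1.0, b - a)
        out = (X.values - a) / span
        out[:, degen] = 0.0
        if clip:
            out = np.clip(out, 0.0, 1.0)
        tag = MINMAX01 if (clip or (out.min() >= -1e-9 and out.max() <= 1 + 1e-9)) else RAW
        if tag == RAW:
            # out-of-range extrapolation: keep values, but the matrix no longer
            # satisfies the minmax01 invariant, so tag it raw-like.
            em = ExpressionMatrix(out, X.gene_ids, X.sample_ids, RAW)
            em.space_tag = MINMAX01 + "_unclipped"
            return em
        return ExpressionMatrix(out, X.gene_ids, X.sample_ids, tag)
    if spec.method == LOG2_ZSCORE:
        logged = np.log2(X.values + spec.pseudocount)
        sd = np.where(degen, 1.0, b)
        out = (logged - a) / sd
        out[:, degen] = 0.0
        return ExpressionMatrix(out, X.gene_ids, X.sample_ids, LOG2_ZSCORE)
    raise ValidationError(f"unknown normalization method {spec.method!r}")


def invert_normalizer(X: ExpressionMatrix, spec: NormalizationSpec) -> ExpressionMatrix:
    """Map normalized values back to raw space (degenerate genes to their constant)."""
    idx = spec._index_for(X.gene_ids)
    a, b = spec.param_a[idx], spec.param_b[idx]
    degen = spec.degenerate[idx]
    if spec.method == MINMAX01:
        out = X.values * (b - a) + a
        out[:, degen] = a[degen]
    elif spec.method == LOG2_ZSCORE:
        sd = np.where(degen, 1.0, b)
        out = np.exp2(X.values * sd + a) - spec.pseudocount
        out[:, degen] = np.exp2(a[degen]) - spec.pseudocount
    else:
        raise ValidationError(f"unknown normalization method {spec.method!r}")
    return ExpressionMatrix(out, X.gene_ids, X.sample_ids, RAW)


# ---------------------------------------------------------------------------
# greedy-sample filtering


def filter_greedy_samples(
    X: ExpressionMatrix, top_k: int = 10, max_fraction: float = 0.5
) -> tuple[ExpressionMatrix, dict]:
    """Remove samples dominated by a handful of genes.

    A sample is "greedy" when its ``top_k`` highest-expressed genes account for
    more than ``max_fraction`` of its total expression.  Requires raw-space,
    nonnegative values.  Returns the filtered matrix and a report listing
    removed sample ids with their top-k fractions.
    """
    if X.space_tag != RAW:
        raise ValidationError("greedy-sample filtering operates on raw expression")
    if np.any(X.values < 0):
        raise ValidationError("greedy-sample filtering requires nonnegative values")
    if not 0 < max_fraction < 1:
        raise ValidationError(f"max_fraction must be in (0,1), got {max_fraction}")
    top_k = min(int(top_k), X.n_genes)
    totals = X.values.sum(axis=1)
    sorted_desc = np.sort(X.values, axis=1)[:, ::-1]
    top_sums = sorted_desc[:, :top_k].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(totals > 0, top_sums / totals, 1.0)
    removed = fractions > max_fraction
    if removed.all():
        raise ValidationError(
            "greedy-sample filter removed every sample; raise max_fraction or top_k"
        )
    report = {
        "top_k": top_k,
        "max_fraction": max_fraction,
        "n_removed": int(removed.sum()),
        "removed": [
            {"sample_id": X.sample_ids[i], "fraction": float(fractions[i])}
            for i in np.flatnonzero(removed)
        ],
    }
    return X.subset_samples(np.flatnonzero(~removed)), report
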