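"""Metrics comparing a real and a synthetic expression matrix.

The suite mirrors the standard synthetic-transcriptomics validation stack:

* manifold precision/recall with t-th-nearest-neighbor sphere radii (t = 10)
  — precision is the fraction of synthetic points inside the real manifold,
  recall the fraction of real points inside the synthetic manifold; the
  high-precision/zero-recall corner is the mode-collapse signature;
* the correlation coefficient c(X, Xhat): Pearson correlation between the
  upper-triangle entries of the two gene-gene correlation matrices;
* detectability: F1 of classifiers trained to separate real from synthetic
  (chance level ~0.5 means indistinguishable), in the full feature space and
  in the space of the first 100 principal components of the real data;
* TSTR utility: train a label classifier on synthetic data, test on held-out
  real data, scored with balanced accuracy and macro-F1;
* per-gene two-sample Kolmogorov-Smirnov statistics with Benjamini-Hochberg
  adjustment, and the mean per-gene one-dimensional 2-Wasserstein distance.

Metrics operate in whatever space the inputs are given in; by convention this
is the normalized training space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, f1_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

from .core_io import ExpressionMatrix, ValidationError

DEFAULT_T = 10
DEFAULT_CLASSIFIERS = ("logistic_regression", "random_forest", "mlp")


def _as_array(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


def _make_classifier(name: str, seed: int):
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000, C=1.0, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(100,), early_stopping=True,
                             max_iter=300, random_state=seed)
    raise ValidationError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# unsupervised metrics


def manifold_radii(points: np.ndarray, t: int = DEFAULT_T) -> np.ndarray:
    """Distance of each point to its t-th nearest neighbor within the same set."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < t + 1:
        raise ValidationError(f"manifold estimate with t={t} needs at least {t + 1} points")
    nbrs = NearestNeighbors(n_neighbors=t + 1).fit(points)
    dist, _ = nbrs.kneighbors(points)
    return dist[:, t]  # column 0 is the point itself at distance 0


def _covered(queries: np.ndarray, reference: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """For each query, is it within radius(p) of at least one reference point p?"""
    covered = np.zeros(len(queries), dtype=bool)
    for chunk in range(0, len(reference), 512):
        ref = reference[chunk:chunk + 512]
        rad = radii[chunk:chunk + 512]
        d = np.linalg.norm(queries[:, None, :] - ref[None, :, :], axis=2)
        covered |= (d <= rad[None, :] + 1e-12).any(axis=1)
    return covered


def precision_recall(X_real, X_syn, t: int = DEFAULT_T) -> tuple[float, float]:
    """Manifold precision and recall with t-th nearest-neighbor sphere radii."""
    real, syn = _as_array(X_real), _as_array(X_syn)
    if real.shape[1] != syn.shape[1]:
        raise ValidationError("real and synthetic matrices must share the gene dimension")
    radii_real = manifold_radii(real, t)
    radii_syn = manifold_radii(syn, t)
    precision = float(_covered(syn, real, radii_real).mean())
    recall = float(_covered(real, syn, radii_syn).mean())
    return precision, recall


def _upper_triangle_correlations(values: np.ndarray, keep: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(values[:, keep], rowvar=False)
    iu = np.triu_indices(int(keep.sum()), k=1)
    return corr[iu]


def correlation_coefficient(X_real, X_syn) -> float:
    """Pearson correlation between the two upper-triangle gene-gene correlation vectors.

    Symmetric in its arguments and invariant to sample order; 1.0 when the two
    matrices share their pairwise correlation structure exactly.
    """
    real, syn = _as_array(X_real), _as_array(X_syn)
    if real.shape[1] != syn.shape[1] or real.shape[1] < 2:
        raise ValidationError("need matching gene dimensions with at least 2 genes")
    if min(len(real), len(syn)) < 3:
        raise ValidationError("need at least 3 samples per matrix")
    keep = (real.std(axis=0) > 0) & (syn.std(axis=0) > 0)
    if not keep.all():
        import warnings

        warnings.warn("constant genes dropped pairwise from the correlation coefficient",
                      stacklevel=2)
    if keep.sum() < 2:
        raise ValidationError("all gene pairs are degenerate; correlation coefficient undefined")
    a = _upper_triangle_correlations(real, keep)
    b = _upper_triangle_correlations(syn, keep)
    if a.std() == 0 or b.std() == 0:
        # single pair (2-gene system) or constant spread: centering is
        # degenerate, so compare the raw correlations by their normalized
        # product (+1 identical structure, -1 anti-structure)
        denom = np.sqrt((a * a).sum() * (b * b).sum())
        if denom == 0:
            raise ValidationError("all pairwise correlations are zero; coefficient undefined")
        return float((a * b).sum() / denom)
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    return float(np.mean(a * b))


# ---------------------------------------------------------------------------
# supervised metrics


def detectability(X_real, X_syn, classifiers=DEFAULT_CLASSIFIERS, space: str = "full",
                  n_components: int = 100, n_runs: int = 10, test_size: float = 0.3,
                  seed: int = 0) -> dict[str, float]:
    """Mean F1 of real-vs-synthetic classifiers over ``n_runs`` seeded splits.

    Real samples are labeled 1, synthetic 0; the split is stratified.  In
    ``space='pc'`` the principal components are fitted on the real training
    rows only and both sets are projected before classification.  Lower F1
    means less detectable synthetic data.
    """
    if space not in ("full", "pc"):
        raise ValidationError(f"unknown feature space {space!r}")
    real, syn = _as_array(X_real), _as_array(X_syn)
    if len(real) == 0 or len(syn) == 0:
        raise ValidationError("both sets must be nonempty")
    # canonicalize row order so the metric is invariant to input shuffling
    real = real[np.lexsort(real.T)]
    syn = syn[np.lexsort(syn.T)]
    X = np.vstack([real, syn])
    y = np.concatenate([np.ones(len(real)), np.zeros(len(syn))])
    scores: dict[str, list[float]] = {name: [] for name in classifiers}
    for run in range(n_runs):
        run_seed = seed + run
        X_train, X_test, y_train, y_test = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=run_seed
        )
        if space == "pc":
            real_train = X_train[y_train == 1]
            k = min(n_components, len(real_train) - 1, X.shape[1])
            pca = PCA(n_components=k, random_state=run_seed).fit(real_train)
            X_train, X_test = pca.transform(X_train), pca.transform(X_test)
        for name in classifiers:
            clf = _make_classifier(name, run_seed)
            clf.fit(X_train, y_train)
            scores[name].append(f1_score(y_test, clf.predict(X_test)))
    return {name: float(np.mean(vals)) for name, vals in scores.items()}


def tstr(X_syn, y_syn, X_real_test, y_real_test, classifiers=DEFAULT_CLASSIFIERS,
         seed: int = 0, n_runs: int = 1) -> dict[str, dict[str, float]]:
    """Train-on-Synthetic-Test-on-Real utility.

    Classifiers are fitted only on the synthetic data and scored on the real
    held-out set with balanced accuracy and macro-averaged F1 (every class
    weighted equally).  Real-set labels absent from the synthetic labels are
    reported under ``missing_classes``.
    """
    X_syn, X_real_test = _as_array(X_syn), _as_array(X_real_test)
    y_syn = np.asarray(y_syn)
    y_real_test = np.asarray(y_real_test)
    if len(np.unique(y_syn)) < 2:
        raise ValidationError("synthetic labels contain a single class; training is degenerate")
    missing = sorted(set(y_real_test.tolist()) - set(y_syn.tolist()))
    out: dict[str, dict[str, float]] = {}
    for name in classifiers:
        bal, mf1 = [], []
        for run in range(n_runs):
            clf = _make_classifier(name, seed + run)
            clf.fit(X_syn, y_syn)
            pred = clf.predict(X_real_test)
            bal.append(balanced_accuracy_score(y_real_test, pred))
            mf1.append(f1_score(y_real_test, pred, average="macro"))
        out[name] = {"balanced_accuracy": float(np.mean(bal)), "macro_f1": float(np.mean(mf1))}
    if missing:
        out["missing_classes"] = missing  # type: ignore[assignment]
    return out


# ---------------------------------------------------------------------------
# per-gene statistics


def ks_per_gene(X_real, X_syn, adjust: str = "benjamini_hochberg") -> dict[str, np.ndarray]:
    """Two-sample KS statistic, p-value, and adjusted p-value per gene."""
    real, syn = _as_array(X_real), _as_array(X_syn)
    if min(len(real), len(syn)) < 2:
        raise ValidationError("KS test needs at least 2 samples per set")
    stats_, ps = [], []
    for j in range(real.shape[1]):
        res = stats.ks_2samp(real[:, j], syn[:, j])
        stats_.append(res.statistic)
        ps.append(res.pvalue)
    ps = np.asarray(ps)
    if adjust == "benjamini_hochberg":
        adjusted = stats.false_discovery_control(ps, method="bh")
    elif adjust is None or adjust == "none":
        adjusted = ps
    else:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return {"statistic": np.asarray(stats_), "pvalue": ps, "pvalue_adjusted": adjusted}


def wasserstein_1d(u: np.ndarray, v: np.ndarray, order: int = 2) -> float:
    """p-Wasserstein distance between two one-dimensional empirical distributions.

    Quantile-matching formula: integrate |F^-1 - G^-1|^p over the merged
    quantile grid of the two samples.
    """
    u = np.sort(np.asarray(u, dtype=np.float64))
    v = np.sort(np.asarray(v, dtype=np.float64))
    if len(u) == 0 or len(v) == 0:
        raise ValidationError("empty sample in Wasserstein distance")
    qs = np.union1d(np.arange(1, len(u) + 1) / len(u), np.arange(1, len(v) + 1) / len(v))
    widths = np.diff(np.concatenate([[0.0], qs]))
    # F^-1(q) = u[ceil(q n) - 1]; the epsilon keeps exact grid points on their
    # own left-closed segment
    uq = u[np.clip(np.ceil(qs * len(u) - 1e-9).astype(int) - 1, 0, len(u) - 1)]
    vq = v[np.clip(np.ceil(qs * len(v) - 1e-9).astype(int) - 1, 0, len(v) - 1)]
    return float(np.sum(widths * np.abs(uq - vq) ** order) ** (1.0 / order))


def mean_gene_wasserstein(X_real, X_syn, order: int = 2) -> float:
    """Mean over genes of the 1-D p-Wasserstein distance between marginals."""
    real, syn = _as_array(X_real), _as_array(X_syn)
    return float(np.mean([wasserstein_1d(real[:, j], syn[:, j], order) for j in range(real.shape[1])]))


# ---------------------------------------------------------------------------
# the full report


@dataclass
class EvaluationReport:
    precision: float
    recall: float
    correlation_coefficient: float
    detectability_full: dict
    detectability_pc: dict
    tstr: dict | None
    ks_max_statistic: float
    ks_fraction_rejected: float
    mean_gene_wasserstein: float
    metadata: dict = field(default_factory=dict)
    per_gene: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["per_gene"] = {k: np.asarray(v).tolist() for k, v in self.per_gene.items()}
        return json.dumps(d, indent=1)

    def per_gene_tsv(self, path, gene_ids=None):
        ks = self.per_gene
        n = len(ks["statistic"])
        gene_ids = gene_ids or [f"g{i}" for i in range(n)]
        with open(path, "w") as fh:
            fh.write("gene_id\tks_statistic\tks_pvalue\tks_pvalue_adjusted\n")
            for i in range(n):
                fh.write(f"{gene_ids[i]}\t{ks['statistic'][i]:.6g}\t{ks['pvalue'][i]:.6g}"
                         f"\t{ks['pvalue_adjusted'][i]:.6g}\n")


def evaluate_all(X_real, X_syn, C_real=None, C_syn=None, label_covariate: str | None = None,
                 t: int = DEFAULT_T, n_runs: int = 10, seed: int = 0, alpha: float = 0.05,
                 classifiers=DEFAULT_CLASSIFIERS, test_size: float = 0.3) -> EvaluationReport:
    """Run the full metric suite with shared seeds and assemble a report.

    TSTR needs labels on both sides: ``label_covariate`` names the covariate
    used as the prediction target; when either covariate table is absent, the
    TSTR block is marked skipped and everything else still runs.
    """
    real, syn = _as_array(X_real), _as_array(X_syn)
    prec, rec = precision_recall(real, syn, t)
    corr = correlation_coefficient(real, syn)
    det_full = detectability(real, syn, classifiers, "full", n_runs=n_runs, seed=seed,
                             test_size=test_size)
    det_pc = detectability(real, syn, classifiers, "pc", n_runs=n_runs, seed=seed,
                           test_size=test_size)
    ks = ks_per_gene(real, syn)
    wd = mean_gene_wasserstein(real, syn)

    tstr_block = None
    if C_real is not None and C_syn is not None and label_covariate is not None:
        rng = np.random.default_rng(seed)
        y_real = np.asarray(C_real.covariates[label_covariate])
        y_syn = np.asarray(C_syn.covariates[label_covariate])
        test_idx = rng.choice(len(y_real), size=max(2, int(test_size * len(y_real))), replace=False)
        tstr_block = tstr(syn, y_syn, real[test_idx], y_real[test_idx], classifiers, seed=seed)
    elif label_covariate is not None:
        tstr_block = {"skipped": "synthetic or real covariates not provided"}

    return EvaluationReport(
        precision=prec,
        recall=rec,
        correlation_coefficient=corr,
        detectability_full=det_full,
        detectability_pc=det_pc,
        tstr=tstr_block,
        ks_max_statistic=float(ks["statistic"].max()),
        ks_fraction_rejected=float((ks["pvalue_adjusted"] < alpha).mean()),
        mean_gene_wasserstein=wd,
        metadata={"t": t, "n_runs": n_runs, "seed": seed, "alpha": alpha,
                  "classifiers": list(classifiers), "test_size": test_size,
                  "pc_components": 100},
        per_gene={k: v for k, v in ks.items()},
    )
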