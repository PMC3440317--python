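"""SVM training, cross-validation and evaluation.

The classifier is an RBF-kernel support vector machine over the tri-peptide
attribute encoding.  Cross-validation respects the similarity-aware folds
built by :mod:`tripitope.datasets`, and — to avoid information leakage — the
propensity table entering the encoding is recomputed from the training folds
only, inside every CV round (the background pool is a fixed external sample
and does not depend on the fold split).

Reported operating points follow the max-F convention: sensitivity and
precision are read off at the score threshold that maximises
F = 2*Sn*P/(Sn+P) on the test scores.  Confidence intervals are
mean +/- t(0.975, k-1) * sd/sqrt(k) over the k folds.

Feature vectors are L2-normalised before the kernel; see docs/methods.md for
the rationale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .datasets import EpitopeDataset
from .encoding import (
    EncodingConfig,
    PropensityTable,
    compute_propensity,
    encode_many,
    similarity_matrix,
    tripeptide_count_vector,
)
from .matrices import (
    DEFAULT_INDEX,
    SubsequencePattern,
    TriPeptideIndex,
    get_pattern,
    load_substitution_matrix,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SvmConfig:
    """SVM hyper-parameters.

    ``c`` is the soft-margin trade-off, ``g`` the RBF kernel width (gamma).
    ``p`` is accepted and recorded for configuration fidelity with
    epsilon-style SVM packages, but is not consumed by the classification
    backend.
    """

    c: float = 32.0
    g: float = 0.05
    p: float = 0.5

    def __post_init__(self) -> None:
        if min(self.c, self.g, self.p) <= 0:
            raise ValueError("c, g and p must all be positive")


def default_grid(include_reported_optimum: bool = True) -> list[SvmConfig]:
    """The standard hyper-parameter grid: c = 2^-10..2^-1, g = 2^-12..2^-3,
    p = 2^-5..2^-2 in powers of two, optionally extended with the
    (c=32, g=0.05, p=0.5) optimum."""
    grid = [
        SvmConfig(c=2.0**i, g=2.0**j, p=2.0**k)
        for i, j, k in product(range(-10, 0), range(-12, -2), range(-5, -1))
    ]
    if include_reported_optimum:
        grid.append(SvmConfig())
    return grid


@dataclass(frozen=True)
class EvalResult:
    """Metrics at the max-F operating point plus ranking quality."""

    sn: float
    p: float
    f: float
    auc: float
    threshold: float


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\tthreshold\n")
            for x, y, t in zip(self.fpr, self.tpr, self.thresholds, strict=True):
                fh.write(f"{x:.10g}\t{y:.10g}\t{t:.10g}\n")


def roc_and_max_f(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[RocCurve, EvalResult]:
    """ROC curve by threshold sweep over unique scores (ties grouped),
    trapezoidal AUC, and the max-F operating point.

    A peptide is called positive when its score is >= the threshold.  The
    trapezoidal AUC over the tie-grouped sweep equals the Mann-Whitney
    statistic (ties counted 1/2).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = (labels[order] == 1).astype(np.int64)
    # last index of every tie group
    cut = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([cut, [len(s) - 1]])
    tp = np.cumsum(y)[cut].astype(np.float64)
    fp = (cut + 1) - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s[cut]])
    auc = float(np.trapezoid(tpr, fpr))
    sn = tp / n_pos
    prec = tp / (tp + fp)
    with np.errstate(invalid="ignore"):
        f = np.where(sn + prec > 0, 2 * sn * prec / (sn + prec), 0.0)
    best = int(np.argmax(f))
    result = EvalResult(
        sn=float(sn[best]),
        p=float(prec[best]),
        f=float(f[best]),
        auc=auc,
        threshold=float(s[cut][best]),
    )
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc), result


# ---------------------------------------------------------------------------
# DeLong paired test for correlated ROC AUCs


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-instance structural components V10 (positives) and
    V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


def compare_roc(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> DelongResult:
    """Paired DeLong test for the difference between two ROC AUCs computed
    from two score sets on the same labeled instances.

    Returns a two-sided p-value.  When the variance of the AUC difference is
    (numerically) zero, the p-value is 1 for a zero difference and ``nan``
    (non-computable) otherwise.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("both score sets must cover the same labeled instances")
    auc_a, v10_a, v01_a = _delong_components(labels, scores_a)
    auc_b, v10_b, v01_b = _delong_components(labels, scores_b)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        if diff == 0:
            return DelongResult(auc_a=auc_a, auc_b=auc_b, z=0.0, p_value=1.0)
        logger.warning("DeLong variance is degenerate; p-value not computable")
        return DelongResult(auc_a=auc_a, auc_b=auc_b, z=np.nan, p_value=np.nan)
    z = diff / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return DelongResult(auc_a=auc_a, auc_b=auc_b, z=float(z), p_value=float(p))


# ---------------------------------------------------------------------------
# Training


def l2_normalize(x: np.ndarray) -> np.ndarray:
    """Row-wise unit-norm scaling (zero rows are left as zeros)."""
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    return np.divide(x, norms, out=np.zeros_like(x, dtype=np.float64),
                     where=norms > 0)


@dataclass
class TrainedModel:
    """A fitted SVM bundled with the complete encoding configuration needed
    to score new peptides identically."""

    svc: SVC
    config: SvmConfig
    matrix_name: str
    pattern_name: str
    mode: str
    propensity: PropensityTable | None
    length: int
    normalize: bool = True
    index: TriPeptideIndex = field(default_factory=lambda: DEFAULT_INDEX, repr=False)

    def encoding_config(self) -> EncodingConfig:
        return EncodingConfig(
            matrix=load_substitution_matrix(self.matrix_name),
            pattern=get_pattern(self.pattern_name),
            mode=self.mode,  # type: ignore[arg-type]
            propensity=self.propensity,
            index=self.index,
        )

    def score_peptides(self, peptides: Sequence[str]) -> np.ndarray:
        """Real-valued decision scores; positive means predicted epitope."""
        x = encode_many(peptides, self.encoding_config())
        if self.normalize:
            x = l2_normalize(x)
        return self.svc.decision_function(x)

    @property
    def dual_coefficients(self) -> np.ndarray:
        """Signed dual coefficients alpha_i * y_i of the support vectors."""
        return self.svc.dual_coef_.ravel()

    @property
    def support_vectors(self) -> np.ndarray:
        return self.svc.support_vectors_

    def save(self, path: str | Path) -> None:
        """Self-contained model archive (SVM, duals, encoding config,
        propensity table)."""
        joblib.dump(self, path, compress=False)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def train_model(
    peptides: Sequence[str],
    labels: np.ndarray,
    encoding: EncodingConfig,
    svm: SvmConfig = SvmConfig(),
    normalize: bool = True,
) -> TrainedModel:
    """Fit an RBF SVM on the encoded peptides.

    Raises on a degenerate single-class label vector.  The fit is
    deterministic given identical inputs.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training data contains a single class")
    if len(set(len(p) for p in peptides)) > 1:
        raise ValueError("training peptides must share one length")
    x = encode_many(peptides, encoding)
    if normalize:
        x = l2_normalize(x)
    svc = SVC(kernel="rbf", C=svm.c, gamma=svm.g, cache_size=512)
    svc.fit(x, labels)
    return TrainedModel(
        svc=svc,
        config=svm,
        matrix_name=encoding.matrix.name,
        pattern_name=encoding.pattern.name,
        mode=encoding.mode,
        propensity=encoding.propensity,
        length=len(peptides[0]),
        normalize=normalize,
        index=encoding.index,
    )


def attribute_weights(
    model: TrainedModel, index: TriPeptideIndex | None = None
) -> list[tuple[str, float]]:
    """Attribute weights w = sum_i alpha_i x_i over the support vectors,
    ranked by descending weight.

    This is the linear read-out of the dual solution; under the RBF kernel it
    is a linear proxy for attribute importance rather than an exact primal
    weight vector.
    """
    index = index or model.index
    w = model.dual_coefficients @ model.support_vectors
    order = np.argsort(-w, kind="stable")
    return [(index.tripeptide_at(int(i)), float(w[i])) for i in order]


def tendency_test(
    model: TrainedModel,
    pool_a: Sequence[str],
    pool_b: Sequence[str],
    top_ns: Sequence[int],
) -> dict[int, tuple[int, int]]:
    """Score two disjoint peptide pools together and report, for each N, how
    many of the top-N ranked peptides come from each pool.

    Ties are broken by stable input order (pool A first, then pool B).
    """
    total = len(pool_a) + len(pool_b)
    for n in top_ns:
        if n > total:
            raise ValueError(f"top-N {n} exceeds the pooled size {total}")
    scores = model.score_peptides(list(pool_a) + list(pool_b))
    is_a = np.arange(total) < len(pool_a)
    order = np.argsort(-scores, kind="stable")
    a_ranked = is_a[order]
    return {
        int(n): (int(a_ranked[:n].sum()), int(n - a_ranked[:n].sum()))
        for n in top_ns
    }


# ---------------------------------------------------------------------------
# Cross-validation


def mean_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Mean and t-distribution confidence half-width over CV folds."""
    v = np.asarray(values, dtype=np.float64)
    mean = float(v.mean())
    if len(v) < 2:
        return mean, float("nan")
    half = float(stats.t.ppf(0.5 + level / 2, len(v) - 1) * v.std(ddof=1)
                 / np.sqrt(len(v)))
    return mean, half


@dataclass
class CvResult:
    """Per-fold and pooled cross-validation outcome for one configuration."""

    config: SvmConfig
    fold_results: list[EvalResult]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray

    @property
    def mean_f(self) -> float:
        return float(np.mean([r.f for r in self.fold_results]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.fold_results]))

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name in ("sn", "p", "f", "auc"):
            mean, half = mean_ci([getattr(r, name) for r in self.fold_results])
            out[name] = mean
            out[f"{name}_ci"] = half
        return out


class _EncodedDataset:
    """Fold-independent encodings, shared across CV rounds and grid points."""

    def __init__(
        self,
        dataset: EpitopeDataset,
        matrix_name: str,
        pattern: SubsequencePattern | str,
        mode: str,
        index: TriPeptideIndex = DEFAULT_INDEX,
    ) -> None:
        self.dataset = dataset
        self.mode = mode
        self.index = index
        self.pattern = get_pattern(pattern)
        self.matrix = load_substitution_matrix(matrix_name)
        self.seqs = dataset.sequences()
        self.labels = dataset.labels()
        self.folds = dataset.folds()
        if mode == "propensity_only":
            self.base = np.stack(
                [tripeptide_count_vector(s, self.pattern, index) for s in self.seqs]
            )
        else:
            self.base = similarity_matrix(self.seqs, self.matrix, self.pattern, index)

    def features_for_fold(
        self, fold: int, background: Sequence[str], leak_free: bool,
        global_propensity: PropensityTable | None,
    ) -> tuple[np.ndarray, PropensityTable | None]:
        if self.mode == "similarity_only":
            return self.base, None
        if leak_free:
            train_pos = [
                p.seq
                for p, f in zip(self.dataset.positives, self.dataset.folds_pos,
                                strict=True)
                if f != fold
            ]
            prop = compute_propensity(train_pos, background, self.pattern,
                                      index=self.index)
        else:
            assert global_propensity is not None
            prop = global_propensity
        return self.base * prop.P[None, :], prop


def _rbf_gram_parts(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared-distance matrix building blocks (dot products, squared norms)."""
    sq = np.einsum("ij,ij->i", x, x)
    return x @ x.T, sq


def _squared_distances(g: np.ndarray, sq: np.ndarray) -> np.ndarray:
    d2 = sq[:, None] + sq[None, :] - 2.0 * g
    np.maximum(d2, 0.0, out=d2)
    return d2


def cross_validate(
    dataset: EpitopeDataset,
    background: Sequence[str],
    svm: SvmConfig = SvmConfig(),
    matrix_name: str = "blosum62",
    pattern: SubsequencePattern | str = "AAA",
    mode: str = "combined",
    leak_free_propensity: bool = True,
    normalize: bool = True,
    index: TriPeptideIndex = DEFAULT_INDEX,
) -> CvResult:
    """k-fold cross-validation over the dataset's similarity-aware folds.

    For every round the model is trained on k-1 folds and scored on the held
    out fold; in ``combined`` and ``propensity_only`` modes the propensity
    table is recomputed from the training folds' positives only (set
    ``leak_free_propensity=False`` to reproduce a global-table variant).
    """
    enc = _EncodedDataset(dataset, matrix_name, pattern, mode, index)
    results, = _run_cv(enc, background, [svm], leak_free_propensity, normalize)
    return results


def _run_cv(
    enc: _EncodedDataset,
    background: Sequence[str],
    grid: Sequence[SvmConfig],
    leak_free: bool,
    normalize: bool,
) -> list[CvResult]:
    """Shared CV engine: one pass over folds, evaluating every grid point.

    Kernels are precomputed from the (fold-specific) feature matrix once per
    fold; each (c, g) pair reuses the squared-distance matrix.
    """
    k = enc.dataset.n_folds
    labels = enc.labels
    folds = enc.folds
    global_prop = None
    if not leak_free and enc.mode != "similarity_only":
        global_prop = compute_propensity(
            [p.seq for p in enc.dataset.positives], background, enc.pattern,
            index=enc.index,
        )
    per_config_folds: list[list[EvalResult]] = [[] for _ in grid]
    per_config_scores: list[list[np.ndarray]] = [[] for _ in grid]
    pooled_labels: list[np.ndarray] = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        if len(set(labels[train].tolist())) < 2 or len(set(labels[test].tolist())) < 2:
            raise ValueError(f"fold {fold} is degenerate (single-class split)")
        x, _ = enc.features_for_fold(fold, background, leak_free, global_prop)
        if normalize:
            x = l2_normalize(x)
        gdot, sq = _rbf_gram_parts(x)
        d2 = _squared_distances(gdot, sq)
        d2_train = d2[np.ix_(train, train)]
        d2_test = d2[np.ix_(test, train)]
        pooled_labels.append(labels[test])
        gamma_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        for ci, cfg in enumerate(grid):
            if cfg.g not in gamma_cache:
                gamma_cache[cfg.g] = (
                    np.exp(-cfg.g * d2_train),
                    np.exp(-cfg.g * d2_test),
                )
            k_train, k_test = gamma_cache[cfg.g]
            svc = SVC(kernel="precomputed", C=cfg.c, cache_size=512)
            svc.fit(k_train, labels[train])
            scores = svc.decision_function(k_test)
            _, ev = roc_and_max_f(scores, labels[test])
            per_config_folds[ci].append(ev)
            per_config_scores[ci].append(scores)
    out = []
    y_pool = np.concatenate(pooled_labels)
    for cfg, fold_res, score_chunks in zip(
        grid, per_config_folds, per_config_scores, strict=True
    ):
        out.append(
            CvResult(
                config=cfg,
                fold_results=fold_res,
                pooled_scores=np.concatenate(score_chunks),
                pooled_labels=y_pool,
            )
        )
    return out


@dataclass
class GridSearchResult:
    best: CvResult
    all_results: list[CvResult]

    @property
    def best_config(self) -> SvmConfig:
        return self.best.config


def grid_search_cv(
    dataset: EpitopeDataset,
    background: Sequence[str],
    grid: Sequence[SvmConfig],
    matrix_name: str = "blosum62",
    pattern: SubsequencePattern | str = "AAA",
    mode: str = "combined",
    leak_free_propensity: bool = True,
    normalize: bool = True,
    index: TriPeptideIndex = DEFAULT_INDEX,
) -> GridSearchResult:
    """Evaluate every hyper-parameter triplet by k-fold CV and return the one
    with the largest mean max-F across test folds (ties: first in grid
    order)."""
    if not grid:
        raise ValueError("hyper-parameter grid is empty")
    enc = _EncodedDataset(dataset, matrix_name, pattern, mode, index)
    results = _run_cv(enc, background, list(grid), leak_free_propensity, normalize)
    best = max(range(len(results)), key=lambda i: (results[i].mean_f, -i))
    return GridSearchResult(best=results[best], all_results=results)


def fit_full_model(
    dataset: EpitopeDataset,
    background: Sequence[str],
    svm: SvmConfig = SvmConfig(),
    matrix_name: str = "blosum62",
    pattern: SubsequencePattern | str = "AAA",
    mode: str = "combined",
    normalize: bool = True,
    index: TriPeptideIndex = DEFAULT_INDEX,
) -> TrainedModel:
    """Train the deployable model on the whole dataset (propensity from all
    positives), as done for a prediction server after CV-based selection."""
    matrix = load_substitution_matrix(matrix_name)
    pattern = get_pattern(pattern)
    prop = None
    if mode != "similarity_only":
        prop = compute_propensity(
            [p.seq for p in dataset.positives], background, pattern, index=index
        )
    cfg = EncodingConfig(
        matrix=matrix, pattern=pattern, mode=mode,  # type: ignore[arg-type]
        propensity=prop, index=index,
    )
    return train_model(dataset.sequences(), dataset.labels(), cfg, svm, normalize)
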