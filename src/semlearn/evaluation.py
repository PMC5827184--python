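"""Quantitative and structural evaluation of learned semantic spaces.

The headline metric is balanced accuracy in a signal-detection framework:
for every probe word, every pair it forms with another probe is judged
"same category" when their similarity exceeds a threshold r; sweeping r
over a 0–1 grid (step 0.001), sensitivity and specificity are computed
per probe and averaged into a balanced accuracy, and the reported score
is the across-probe mean at the single threshold that maximizes it.
Balancing sensitivity and specificity removes the bias from the vast
majority of pairs being different-category.

Also here: per-word perplexity of a recurrent model on held-out text,
nearest neighbors, category-averaged similarity matrices with the
self-similarity diagonal removed, average-linkage hierarchical
clustering on 1 − similarity, and PCA of the representation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .corpus import InvalidConfigError
from .networks import LSTMWeights, SRNWeights, make_windows, window_nll
from .semspace import ProbeSet, RepresentationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class ThresholdGrid:
    """Similarity thresholds between 0.0 and 1.0 with step 0.001."""

    lower: float = 0.0
    upper: float = 1.0
    step: float = 0.001

    def values(self) -> np.ndarray:
        n = int(round((self.upper - self.lower) / self.step))
        grid = self.lower + self.step * np.arange(n + 1)
        if grid[0] < 0.0 or grid[-1] > 1.0 + 1e-12:
            raise InvalidConfigError("grid must lie within [0, 1]")
        return grid


@dataclass
class BalancedAccuracyReport:
    """Per-probe sensitivity/specificity across the grid plus the summary
    at the best (across-probe-mean-maximizing) threshold."""

    thresholds: np.ndarray
    probe_words: list[str]
    sensitivity: np.ndarray  # (n_probes, n_thresholds)
    specificity: np.ndarray  # (n_probes, n_thresholds)
    balanced_accuracy: np.ndarray  # (n_probes, n_thresholds)
    best_threshold: float
    best_index: int
    mean_balanced_accuracy: float
    per_probe_at_best: pd.Series = field(repr=False, default=None)
    per_category_at_best: pd.Series = field(repr=False, default=None)


def balanced_accuracy_sweep(
    s: SimilarityMatrix,
    probes: ProbeSet,
    grid: ThresholdGrid | None = None,
) -> BalancedAccuracyReport:
    """Signal-detection sweep of same-category classification.

    For a probe w and every other probe x: a hit is a same-category pair
    with S > r, a miss a same-category pair with S ≤ r, a false alarm a
    different-category pair with S > r, otherwise a correct rejection
    (ties S = r classify as "different").  Probes with no same-category
    partner are excluded with a warning.
    """
    if not s.is_square:
        raise InvalidConfigError("sweep needs a square probe-by-probe matrix")
    grid = grid or ThresholdGrid()
    thresholds = grid.values()
    words = s.row_words
    cats = np.array([probes.probes[w] for w in words])
    same = cats[:, None] == cats[None, :]
    np.fill_diagonal(same, False)
    usable = [i for i in range(len(words)) if same[i].any()]
    if len(usable) < len(words):
        logger.warning(
            "excluded %d probes with no same-category partner",
            len(words) - len(usable),
        )
    n_u, n_t = len(usable), thresholds.shape[0]
    sens = np.empty((n_u, n_t))
    spec = np.empty((n_u, n_t))
    off = ~np.eye(len(words), dtype=bool)
    for row, i in enumerate(usable):
        pos = np.sort(s.values[i, same[i]])
        neg = np.sort(s.values[i, off[i] & ~same[i]])
        # count(pos > r) via sorted search; ties S == r are "different"
        sens[row] = (
            pos.shape[0] - np.searchsorted(pos, thresholds, side="right")
        ) / pos.shape[0]
        spec[row] = np.searchsorted(neg, thresholds, side="right") / max(
            neg.shape[0], 1
        )
    ba = 0.5 * (sens + spec)
    mean_curve = ba.mean(axis=0)
    best = int(np.argmax(mean_curve))
    probe_words = [words[i] for i in usable]
    per_probe = pd.Series(ba[:, best], index=probe_words, name="balanced_accuracy")
    per_cat = per_probe.groupby(
        [probes.probes[w] for w in probe_words]
    ).mean()
    return BalancedAccuracyReport(
        thresholds=thresholds,
        probe_words=probe_words,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=ba,
        best_threshold=float(thresholds[best]),
        best_index=best,
        mean_balanced_accuracy=float(mean_curve[best]),
        per_probe_at_best=per_probe,
        per_category_at_best=per_cat,
    )


def perplexity(
    weights: SRNWeights | LSTMWeights,
    tokens: np.ndarray,
    pad_id: int,
    batch_size: int = 512,
) -> float:
    """exp(mean −ln p(word | its 7-token window)) over a token stream.

    Windows are built exactly as in training (left context padded with
    the boundary symbol at the stream start).  A perfect predictor scores
    1; a model uniform over k candidates scores k.
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.size == 0:
        raise InvalidConfigError("cannot score an empty test set")
    windows, targets = make_windows(tokens, pad_id)
    nll = np.empty(tokens.shape[0])
    for start in range(0, windows.shape[0], batch_size):
        nll[start:start + batch_size] = window_nll(
            weights,
            windows[start:start + batch_size],
            targets[start:start + batch_size],
        )
    return float(np.exp(nll.mean()))


def nearest_neighbors(
    s: SimilarityMatrix, word: str, k: int
) -> list[tuple[str, float]]:
    """Top-k most similar words, excluding the word itself; similarity ties
    break lexicographically."""
    if word not in s.row_words:
        raise KeyError(f"{word!r} not in similarity matrix")
    i = s.row_words.index(word)
    pairs = [
        (w, float(s.values[i, j]))
        for j, w in enumerate(s.col_words)
        if w != word and np.isfinite(s.values[i, j])
    ]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs[:max(k, 0)]


@dataclass
class CategorySimilarityMatrix:
    """Mean within/between-category similarity, clustering-ordered."""

    values: np.ndarray  # (K, K), in clustered order
    categories: list[str]  # clustered order
    linkage: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.categories,
                            columns=self.categories)


def category_similarity_matrix(
    s: SimilarityMatrix, probes: ProbeSet
) -> CategorySimilarityMatrix:
    """Average pairwise probe similarity within and between categories.

    The self-similarity diagonal of the probe matrix is removed before
    averaging; singleton categories get an undefined (NaN) within-cell.
    Rows/columns are reordered by hierarchical clustering of the
    category-level matrix.
    """
    if not s.is_square:
        raise InvalidConfigError("need a square probe-by-probe matrix")
    words = s.row_words
    cats = sorted({probes.probes[w] for w in words})
    members = {c: [i for i, w in enumerate(words) if probes.probes[w] == c]
               for c in cats}
    k = len(cats)
    mat = np.full((k, k), np.nan)
    vals = s.values.copy()
    np.fill_diagonal(vals, np.nan)  # remove self-similarities
    for a, ca in enumerate(cats):
        for b, cb in enumerate(cats):
            block = vals[np.ix_(members[ca], members[cb])]
            finite = block[np.isfinite(block)]
            if finite.size:
                mat[a, b] = finite.mean()
            elif a == b:
                logger.warning("singleton category %r: within-cell undefined", ca)
    order, linkage = _cluster_order(mat, cats)
    return CategorySimilarityMatrix(
        values=mat[np.ix_(order, order)],
        categories=[cats[i] for i in order],
        linkage=linkage,
    )


def _cluster_order(
    sim: np.ndarray, items: list[str]
) -> tuple[list[int], np.ndarray]:
    z = _linkage_from_similarity(sim)
    return list(hierarchy.leaves_list(z)), z


def _linkage_from_similarity(sim: np.ndarray) -> np.ndarray:
    dist = 1.0 - np.nan_to_num(sim, nan=0.0)
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


@dataclass
class Dendrogram:
    """Agglomerative merge tree over items, with deterministic leaf order."""

    items: list[str]
    linkage: np.ndarray
    leaf_order: list[str]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.items[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

        return walk(tree) + ";"


def hierarchical_cluster(s: SimilarityMatrix, items: list[str] | None = None) -> Dendrogram:
    """Average-linkage agglomerative clustering on distance 1 − S."""
    if not s.is_square:
        raise InvalidConfigError("need a square similarity matrix")
    items = items if items is not None else list(s.row_words)
    if len(items) < 2:
        raise InvalidConfigError("need at least 2 items to cluster")
    z = _linkage_from_similarity(s.values)
    order = hierarchy.leaves_list(z)
    return Dendrogram(
        items=items, linkage=z, leaf_order=[items[i] for i in order]
    )


@dataclass
class PCAReport:
    """Per-word component loadings and variance-explained fractions."""

    loadings: pd.DataFrame  # words x components
    variance_fractions: np.ndarray


def pca_loadings(
    reps: RepresentationMatrix, n_components: int | None = None
) -> PCAReport:
    """Principal components of the word-by-hidden-unit matrix.

    Rows are centered but not scaled (hidden units share one activation
    range).  Loadings are the projections of words onto the components.
    """
    sub = reps.defined_subset()
    if sub.matrix.shape[0] < 2:
        raise InvalidConfigError("need at least 2 defined rows for PCA")
    max_k = min(sub.matrix.shape[0] - 1, sub.matrix.shape[1])
    k = max_k if n_components is None else min(n_components, max_k)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(sub.matrix)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAReport(
        loadings=pd.DataFrame(scores, index=sub.words, columns=cols),
        variance_fractions=pca.explained_variance_ratio_,
    )
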