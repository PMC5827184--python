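"""Figures: dendrogram heatmaps, per-occurrence activation maps, t-SNE.

Plotting is a convenience layer over the evaluation outputs; nothing
downstream depends on it.  The t-SNE projection delegates to
scikit-learn and is not deterministic across runs.
"""

from __future__ import annotations

import numpy as np

from .evaluation import CategorySimilarityMatrix
from .semspace import ProbeSet, RepresentationMatrix


def plot_category_heatmap(cat: CategorySimilarityMatrix, ax=None):
    """Clustered heatmap of mean within/between-category similarity."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(cat.values, cmap="viridis")
    ax.set_xticks(range(len(cat.categories)))
    ax.set_xticklabels(cat.categories, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cat.categories)))
    ax.set_yticklabels(cat.categories, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="mean similarity")
    return ax


def plot_tsne(
    reps: RepresentationMatrix,
    probes: ProbeSet,
    seed: int | None = None,
    ax=None,
):
    """2-D t-SNE projection of probe representations, colored by category."""
    import matplotlib.pyplot as plt
    from sklearn.manifold import TSNE

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 8))
    sub = reps.defined_subset(sorted(set(probes.probes) & set(reps.words)))
    n = sub.matrix.shape[0]
    emb = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=min(30.0, max(2.0, (n - 1) / 3)),
        init="pca",
    ).fit_transform(sub.matrix)
    cats = sorted({probes.probes[w] for w in sub.words})
    for ci, cat in enumerate(cats):
        idx = [i for i, w in enumerate(sub.words) if probes.probes[w] == cat]
        ax.scatter(emb[idx, 0], emb[idx, 1], s=8, label=cat,
                   color=plt.cm.tab20(ci % 20))
        ax.annotate(cat, emb[idx].mean(axis=0), fontsize=8, weight="bold")
    return ax


def plot_occurrence_heatmap(states: np.ndarray, ax=None):
    """Per-occurrence hidden-state heatmap, rows clustered by similarity.

    Visual polysemy diagnostic: an unambiguous word's rows look alike,
    a polysemous word's rows split into distinct clusters.
    """
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    if states.shape[0] > 2:
        order = hierarchy.leaves_list(
            hierarchy.linkage(states, method="average")
        )
        states = states[order]
    ax.imshow(states, aspect="auto", cmap="coolwarm")
    ax.set_xlabel("hidden unit")
    ax.set_ylabel("occurrence")
    return ax
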