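"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from semlearn.corpus import Corpus, Document
from semlearn.networks import window_loss
from semlearn.synthetic import GeneratorConfig, generate_corpus, generate_lexicon


@pytest.fixture
def toy_corpus() -> Corpus:
    """Three tiny documents with out-of-order ages (sorted on construction)."""
    return Corpus(
        documents=[
            Document("d2", 18.0, [["you", "want", "milk", "?"],
                                  ["milk", "is", "good", "."]]),
            Document("d0", 6.0, [["hi", "baby", "!"], ["you", "like", "milk", "?"]]),
            Document("d1", 12.0, [["look", "a", "dog", "!"],
                                  ["the", "dog", "is", "big", "."]]),
        ]
    )


@pytest.fixture(scope="session")
def small_planted():
    """A small 2-category planted corpus for cheap end-to-end checks."""
    cfg = GeneratorConfig(
        n_categories=2,
        words_per_category=6,
        n_context_frames_per_category=4,
        n_documents=6,
        tokens_per_document=2000,
        seed=11,
    )
    lex = generate_lexicon(cfg)
    corpus, probes = generate_corpus(lex, cfg)
    return cfg, lex, corpus, probes


def finite_difference_grads(weights, window, eps: float = 1e-5):
    """Central-difference gradients of `window_loss` for every weight entry.

    The independent oracle for the backpropagation implementations: it
    only evaluates the forward loss.
    """
    grads = {}
    for name, arr in weights.params().items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp, _ = window_loss(weights, window)
            arr[idx] = orig - eps
            lm, _ = window_loss(weights, window)
            arr[idx] = orig
            g[idx] = (lp - lm) / (2.0 * eps)
        grads[name] = g
    return grads


def assert_grads_close(analytic, numeric, rtol: float = 1e-4):
    for name in numeric:
        a, n = analytic[name], numeric[name]
        tol = rtol * (np.abs(a) + np.abs(n)) + 1e-8
        assert np.all(np.abs(a - n) <= tol), f"gradient mismatch in {name}"


def brute_force_sweep(values: np.ndarray, cats: list[str], thresholds: np.ndarray):
    """Exhaustive per-probe signal-detection enumeration (pure loops).

    Independent oracle for `balanced_accuracy_sweep`: iterates every
    probe, partner, and threshold, counting hits/misses/FAs/CRs exactly
    as defined, and returns (mean curve, best threshold, best mean).
    """
    n = len(cats)
    curves = []
    for i in range(n):
        if not any(cats[j] == cats[i] for j in range(n) if j != i):
            continue
        row = []
        for r in thresholds:
            hits = misses = fas = crs = 0
            for j in range(n):
                if j == i:
                    continue
                same = cats[j] == cats[i]
                above = values[i, j] > r
                if same and above:
                    hits += 1
                elif same:
                    misses += 1
                elif above:
                    fas += 1
                else:
                    crs += 1
            sens = hits / (hits + misses)
            spec = crs / (crs + fas) if (crs + fas) else 0.0
            row.append(0.5 * (sens + spec))
        curves.append(row)
    mean_curve = np.mean(curves, axis=0)
    best = int(np.argmax(mean_curve))
    return mean_curve, thresholds[best], float(mean_curve[best])
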