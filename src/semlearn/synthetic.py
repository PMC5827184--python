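"""Synthetic child-directed-speech corpora with planted semantic structure.

The generator emulates the statistical properties of transcribed speech to
young children that matter for distributional learning experiments:
Zipfian word frequencies, short utterances terminated by punctuation
tokens, documents ordered by child age, and — the planted ground truth —
semantic categories realized as category-specific lexical frames in which
the member words are mutually substitutable.  Because the category
structure is planted, every downstream stage (training, representation
extraction, balanced-accuracy evaluation) can be tested end to end
without any corpus download, and a brute-force bag-of-contexts classifier
provides an oracle for how recoverable the structure is.

A *frame* is a small utterance template with one slot for a target word,
e.g. ``c3f1a _ c3f1b .``; all words of a category share the category's
frame pool, which is what makes them substitutable for a sequence
predictor.  ``frame_overlap`` shares frames across categories (blurring
category boundaries), ``polysemy_rate`` assigns some words to the frames
of two categories, and ``age_drift`` shifts each category's frame mixture
across document age.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus import Corpus, Document, InvalidConfigError, PUNCTUATION

SLOT = "_"


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults give an easy, clean corpus
    (10 categories of 8 words, disjoint frames) of ~200k tokens."""

    n_categories: int = 10
    words_per_category: int = 8
    n_context_frames_per_category: int = 10
    frame_overlap: float = 0.0
    zipf_exponent: float = 1.0
    n_documents: int = 32
    tokens_per_document: int = 6250
    polysemy_rate: float = 0.0
    age_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frame_overlap", "polysemy_rate", "age_drift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.words_per_category < 1:
            raise InvalidConfigError("words_per_category must be >= 1")
        if self.n_categories < 1:
            raise InvalidConfigError("n_categories must be >= 1")
        if self.zipf_exponent <= 0:
            raise InvalidConfigError("zipf_exponent must be positive")


@dataclass
class PlantedLexicon:
    """Ground truth: target words, their categories, and category frames."""

    target_words: dict[str, str]  # word -> category name
    frames: dict[str, list[tuple[str, ...]]]  # category -> templates with SLOT
    polysemous_words: dict[str, str] = field(default_factory=dict)  # word -> 2nd cat
    categories: list[str] = field(default_factory=list)

    def words_of(self, category: str) -> list[str]:
        return [w for w, c in self.target_words.items() if c == category]


def _category_names(n: int) -> list[str]:
    return [f"cat{i:02d}" for i in range(n)]


def _make_frame(rng: np.random.Generator, tag: str, j: int) -> tuple[str, ...]:
    """One utterance template: context words around a slot, then punctuation."""
    n_pre = int(rng.integers(1, 3))
    n_post = int(rng.integers(0, 3))
    pre = [f"{tag}f{j}p{k}" for k in range(n_pre)]
    post = [f"{tag}f{j}q{k}" for k in range(n_post)]
    punct = str(rng.choice([".", "!", "?"]))
    return tuple(pre + [SLOT] + post + [punct])


def generate_lexicon(config: GeneratorConfig) -> PlantedLexicon:
    """Build target words and category frame pools, deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    cats = _category_names(config.n_categories)
    target_words: dict[str, str] = {}
    for ci, cat in enumerate(cats):
        for wi in range(config.words_per_category):
            target_words[f"t{ci:02d}w{wi:02d}"] = cat

    shared = [
        _make_frame(rng, "sh", j)
        for j in range(config.n_context_frames_per_category)
    ]
    frames: dict[str, list[tuple[str, ...]]] = {}
    for ci, cat in enumerate(cats):
        pool = []
        for j in range(config.n_context_frames_per_category):
            if rng.random() < config.frame_overlap:
                pool.append(shared[j])
            else:
                pool.append(_make_frame(rng, f"c{ci:02d}", j))
        frames[cat] = pool

    poly: dict[str, str] = {}
    if config.polysemy_rate > 0 and config.n_categories > 1:
        words = list(target_words)
        n_poly = int(round(config.polysemy_rate * len(words)))
        for w in rng.choice(words, size=n_poly, replace=False):
            own = target_words[w]
            others = [c for c in cats if c != own]
            poly[str(w)] = str(rng.choice(others))
    return PlantedLexicon(
        target_words=target_words,
        frames=frames,
        polysemous_words=poly,
        categories=cats,
    )


def _instantiate(frame: tuple[str, ...], word: str) -> list[str]:
    return [word if tok == SLOT else tok for tok in frame]


def _frame_weights(
    n_frames: int, rel_age: float, age_drift: float
) -> np.ndarray:
    """Mixture over a category's frames at a relative age in [0, 1].

    Drift linearly interpolates between an early-half-biased and a
    late-half-biased mixture; at ``age_drift == 0`` the mixture is uniform
    and age-independent.
    """
    w = np.ones(n_frames)
    if age_drift > 0 and n_frames > 1:
        half = n_frames // 2
        early = np.ones(n_frames)
        early[half:] = 1.0 - age_drift
        late = np.ones(n_frames)
        late[:half] = 1.0 - age_drift
        w = (1.0 - rel_age) * early + rel_age * late
    return w / w.sum()


def generate_corpus(
    lexicon: PlantedLexicon, config: GeneratorConfig
) -> tuple[Corpus, dict[str, str]]:
    """Emit age-ordered documents plus the ground-truth probe map.

    Target-word unigram frequencies follow a Zipf law with the configured
    exponent; each utterance embeds one Zipf-sampled target word in a
    frame of its category (or, for polysemous words, of either of its two
    categories) and ends in a punctuation token.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    words = sorted(lexicon.target_words)
    ranks = rng.permutation(len(words)) + 1
    probs = ranks.astype(float) ** (-config.zipf_exponent)
    probs /= probs.sum()

    docs: list[Document] = []
    denom = max(config.n_documents - 1, 1)
    for d in range(config.n_documents):
        rel_age = d / denom
        utts: list[list[str]] = []
        n_tokens = 0
        while n_tokens < config.tokens_per_document:
            word = words[rng.choice(len(words), p=probs)]
            cat = lexicon.target_words[word]
            if word in lexicon.polysemous_words and rng.random() < 0.5:
                cat = lexicon.polysemous_words[word]
            pool = lexicon.frames[cat]
            weights = _frame_weights(len(pool), rel_age, config.age_drift)
            frame = pool[rng.choice(len(pool), p=weights)]
            utt = _instantiate(frame, word)
            utts.append(utt)
            n_tokens += len(utt)
        docs.append(
            Document(doc_id=f"doc{d:04d}", child_age_months=float(d), utterances=utts)
        )
    probes = dict(lexicon.target_words)
    return Corpus(documents=docs), probes


def inject_polysemy(
    corpus: Corpus,
    lexicon: PlantedLexicon,
    word: str,
    second_category: str,
    rate: float,
    seed: int = 0,
) -> Corpus:
    """Re-embed a fraction of a word's occurrences in another category's frames.

    A fraction ``rate`` of the utterances containing ``word`` is replaced
    with a freshly instantiated frame of ``second_category`` holding the
    same word, so the word's total occurrence count is unchanged.
    """
    if word not in lexicon.target_words:
        raise KeyError(f"{word!r} is not a target word")
    if second_category not in lexicon.frames:
        raise KeyError(f"unknown category {second_category!r}")
    if not 0.0 <= rate <= 1.0:
        raise InvalidConfigError(f"rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    occurrences = [
        (di, ui)
        for di, doc in enumerate(corpus)
        for ui, utt in enumerate(doc.utterances)
        if word in utt
    ]
    n_flip = int(round(rate * len(occurrences)))
    flip_idx = rng.choice(len(occurrences), size=n_flip, replace=False)
    flips = {occurrences[i] for i in flip_idx}
    pool = lexicon.frames[second_category]
    new_docs = []
    for di, doc in enumerate(corpus):
        utts = []
        for ui, utt in enumerate(doc.utterances):
            if (di, ui) in flips:
                frame = pool[rng.choice(len(pool))]
                utt = _instantiate(frame, word)
            utts.append(list(utt))
        new_docs.append(replace(doc, utterances=utts))
    return Corpus(documents=new_docs)


# ---------------------------------------------------------------------------
# recoverability oracle


def context_profiles(
    corpus: Corpus, words: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Bag-of-contexts count matrix: co-utterance tokens per target word.

    Punctuation tokens are excluded from the context inventory since they
    are shared across all categories by construction.
    """
    word_set = set(words)
    context_vocab: dict[str, int] = {}
    rows: dict[str, dict[int, int]] = {w: {} for w in words}
    for doc in corpus:
        for utt in doc.utterances:
            present = [t for t in utt if t in word_set]
            contexts = [
                t for t in utt if t not in word_set and t not in PUNCTUATION
            ]
            for w in present:
                for c in contexts:
                    j = context_vocab.setdefault(c, len(context_vocab))
                    rows[w][j] = rows[w].get(j, 0) + 1
    mat = np.zeros((len(words), len(context_vocab)))
    for i, w in enumerate(words):
        for j, cnt in rows[w].items():
            mat[i, j] = cnt
    return mat, sorted(context_vocab, key=context_vocab.get)


def bag_of_contexts_accuracy(corpus: Corpus, probes: dict[str, str]) -> float:
    """Nearest-centroid category accuracy from raw co-occurrence counts.

    The brute-force oracle downstream models are compared against: at zero
    overlap/polysemy/noise it recovers the planted categories perfectly.
    """
    words = sorted(probes)
    mat, _ = context_profiles(corpus, words)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = mat / norms
    cats = sorted(set(probes.values()))
    centroids = np.stack(
        [unit[[i for i, w in enumerate(words) if probes[w] == c]].mean(axis=0)
         for c in cats]
    )
    cnorm = np.linalg.norm(centroids, axis=1, keepdims=True)
    cnorm[cnorm == 0] = 1.0
    centroids = centroids / cnorm
    sims = unit @ centroids.T
    pred = np.argmax(sims, axis=1)
    truth = np.array([cats.index(probes[w]) for w in words])
    return float(np.mean(pred == truth))
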