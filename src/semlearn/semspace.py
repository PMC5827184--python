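"""Word representations and similarity structure from trained models.

For the recurrent models a word's representation is *contextual*: the
corpus is re-input to the trained model (weights frozen), the hidden
state at the end of every 7-token window is cached, and the word's vector
is the average of the final states over all windows whose last token is
that word.  For Skip-gram the representation is simply the word's
input-embedding row.  Similarity between two words is the Pearson
correlation of their representation vectors; agreement between two whole
semantic spaces (inter-model reliability) is the Pearson correlation of
their flattened probe-by-vocabulary similarity matrices, excluding
self-pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Vocabulary
from .networks import (
    LSTMWeights,
    SkipGramWeights,
    SRNWeights,
    final_hidden_states,
    make_anchor_windows,
)

logger = logging.getLogger(__name__)


@dataclass
class ProbeSet:
    """Evaluation words mapped to semantic categories."""

    probes: dict[str, str]
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.categories:
            self.categories = sorted(set(self.probes.values()))

    def __len__(self) -> int:
        return len(self.probes)

    def words(self) -> list[str]:
        return sorted(self.probes)

    def restricted_to(self, vocabulary_words) -> "ProbeSet":
        """Drop probes absent from the vocabulary, with a logged warning."""
        have = set(vocabulary_words)
        kept = {w: c for w, c in self.probes.items() if w in have}
        dropped = len(self.probes) - len(kept)
        if dropped:
            logger.warning("dropped %d probes absent from vocabulary", dropped)
        return ProbeSet(probes=kept)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeSet":
        probes: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            word, cat = line.split("\t")[:2]
            probes[word.lower()] = cat
        return cls(probes=probes)

    def to_tsv(self, path: str | Path) -> None:
        lines = [f"{w}\t{c}" for w, c in sorted(self.probes.items())]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RepresentationMatrix:
    """One vector per word plus the occurrence counts used in averaging.

    Rows with zero occurrences are undefined (NaN) and must be excluded
    from downstream similarity computations via ``defined``.
    """

    words: list[str]
    matrix: np.ndarray  # (n_words, H)
    occurrence_counts: np.ndarray  # (n_words,)
    source: str = "hidden-average"

    @property
    def defined(self) -> np.ndarray:
        return self.occurrence_counts > 0

    def row(self, word: str) -> np.ndarray:
        i = self.words.index(word)
        if self.occurrence_counts[i] == 0:
            raise KeyError(f"{word!r} has no defined representation")
        return self.matrix[i]

    def defined_subset(self, words=None) -> "RepresentationMatrix":
        wanted = self.words if words is None else list(words)
        idx = [
            self.words.index(w)
            for w in wanted
            if w in self.words and self.occurrence_counts[self.words.index(w)] > 0
        ]
        return RepresentationMatrix(
            words=[self.words[i] for i in idx],
            matrix=self.matrix[idx],
            occurrence_counts=self.occurrence_counts[idx],
            source=self.source,
        )


@dataclass
class SimilarityMatrix:
    """Pairwise Pearson correlations between word representations."""

    values: np.ndarray
    row_words: list[str]
    col_words: list[str]

    @property
    def is_square(self) -> bool:
        return self.row_words == self.col_words

    def get(self, w1: str, w2: str) -> float:
        return float(
            self.values[self.row_words.index(w1), self.col_words.index(w2)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_words, columns=self.col_words
        )


def extract_contextual_reps(
    weights: SRNWeights | LSTMWeights,
    tokens: np.ndarray,
    vocab: Vocabulary,
    pad_id: int | None = None,
    batch_size: int = 512,
) -> RepresentationMatrix:
    """Average final-step hidden states per word over a frozen model.

    The corpus stream is re-windowed exactly as in training; for each
    word the row is the mean of the hidden vectors at the last step of
    every window that *ends* in that word (the state that encodes the
    word in its context).  Words that never occur get an undefined row.
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    if pad_id is None:
        bid = vocab.boundary_id
        pad_id = bid if bid is not None else vocab.unknown_id
    windows = make_anchor_windows(tokens, pad_id)
    n_words = len(vocab)
    sums = np.zeros((n_words, weights.hidden_size))
    counts = np.zeros(n_words, dtype=np.int64)
    for start in range(0, windows.shape[0], batch_size):
        batch = windows[start:start + batch_size]
        states = final_hidden_states(weights, batch)
        last = batch[:, -1]
        np.add.at(sums, last, states)
        np.add.at(counts, last, 1)
    with np.errstate(invalid="ignore"):
        means = sums / counts[:, None]
    means[counts == 0] = np.nan
    return RepresentationMatrix(
        words=list(vocab.words),
        matrix=means,
        occurrence_counts=counts,
        source="hidden-average",
    )


def skipgram_reps(
    weights: SkipGramWeights, vocab: Vocabulary
) -> RepresentationMatrix:
    """A word's representation is its input-embedding row."""
    counts = np.ones(len(vocab), dtype=np.int64)
    return RepresentationMatrix(
        words=list(vocab.words),
        matrix=weights.w_in.copy(),
        occurrence_counts=counts,
        source="input-embedding",
    )


def _standardize_rows(mat: np.ndarray) -> np.ndarray:
    centered = mat - mat.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    zero = sd[:, 0] == 0
    if zero.any():
        warnings.warn("zero-variance representation rows yield undefined similarity")
    sd[zero] = np.nan
    return centered / sd


def similarity_matrix(
    reps: RepresentationMatrix,
    row_words: list[str],
    col_words: list[str] | None = None,
) -> SimilarityMatrix:
    """Pearson correlation of representation vectors, rows × columns.

    All requested words must have defined rows; zero-variance vectors
    produce NaN entries (flagged with a warning).
    """
    col_words = row_words if col_words is None else col_words
    idx = {w: i for i, w in enumerate(reps.words)}
    for w in set(row_words) | set(col_words):
        if w not in idx:
            raise KeyError(f"{w!r} has no representation row")
        if reps.occurrence_counts[idx[w]] == 0:
            raise KeyError(f"{w!r} has an undefined representation")
    h = reps.matrix.shape[1]
    zr = _standardize_rows(reps.matrix[[idx[w] for w in row_words]])
    zc = _standardize_rows(reps.matrix[[idx[w] for w in col_words]])
    values = np.clip(zr @ zc.T / h, -1.0, 1.0)
    return SimilarityMatrix(
        values=values, row_words=list(row_words), col_words=list(col_words)
    )


def model_reliability(s_a: SimilarityMatrix, s_b: SimilarityMatrix) -> float:
    """Pearson correlation of two flattened similarity matrices.

    Both matrices must share row and column word sets.  Entries whose row
    word equals the column word (self-similarities, identically 1) are
    excluded before correlating.
    """
    if s_a.row_words != s_b.row_words or s_a.col_words != s_b.col_words:
        raise ValueError("similarity matrices must share row/column words")
    keep = np.ones(s_a.values.shape, dtype=bool)
    col_index = {w: j for j, w in enumerate(s_a.col_words)}
    for i, w in enumerate(s_a.row_words):
        j = col_index.get(w)
        if j is not None:
            keep[i, j] = False
    a = s_a.values[keep]
    b = s_b.values[keep]
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
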