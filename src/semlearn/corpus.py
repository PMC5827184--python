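"""Corpus ingestion and preparation for child-directed speech.

Raw input is plain text, one utterance per line, one file per document,
with a TSV sidecar mapping document ids to the age (in months) of the
child being spoken to.  Preparation lower-cases and tokenizes utterances,
keeps sentence-boundary punctuation (``. ! , ?``) as standalone tokens,
regularizes spellings through an alias table, replaces proper names with
gender tokens (FNAME/MNAME), optionally splits productive noun/verb
suffixes off their stems, builds a frequency-capped vocabulary with an
UNKNOWN symbol, encodes documents as integer-id sequences, and slices the
age-ordered training stream into equal-size partitions for the
local-iteration training schedule.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentence-boundary punctuation kept in the corpus as standalone tokens.
PUNCTUATION = (".", "!", ",", "?")

UNKNOWN = "UNKNOWN"
#: Reserved symbol used to pad the left context of stream-initial windows.
BOUNDARY = "BOUNDARY"

#: Suffixes split off nouns and verbs, tried longest-first.  The split
#: form keeps the suffix as a token of its own, prefixed with "-".
MORPH_SUFFIXES = ("ies", "'s", "s'", "ing", "es", "ed", "ie", "s", "y")


class InvalidConfigError(ValueError):
    """A configuration value is outside its documented range."""


@dataclass
class Document:
    """One transcript: an ordered list of tokenized utterances."""

    doc_id: str
    child_age_months: float
    utterances: list[list[str]]

    @property
    def n_tokens(self) -> int:
        return sum(len(u) for u in self.utterances)

    def tokens(self) -> Iterator[str]:
        for utt in self.utterances:
            yield from utt


@dataclass
class Corpus:
    """Documents sorted non-decreasing by child age (ties by doc_id)."""

    documents: list[Document] = field(default_factory=list)
    ordering_key: str = "child_age_months"

    def __post_init__(self) -> None:
        self.documents = sorted(
            self.documents, key=lambda d: (d.child_age_months, d.doc_id)
        )

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(d.n_tokens for d in self.documents)

    def tokens(self) -> Iterator[str]:
        for doc in self.documents:
            yield from doc.tokens()


@dataclass
class Vocabulary:
    """Frequency-ranked word <-> id mapping with reserved symbols.

    The inventory holds at most ``size_limit`` symbols *including* the
    reserved ones, so a model built on it has input/output width equal to
    ``len(vocab)``.  ``frequencies[UNKNOWN]`` carries the total count of
    out-of-vocabulary tokens, so frequencies sum to the corpus token count.
    """

    words: list[str]
    ids: dict[str, int]
    frequencies: dict[str, int]
    unknown_symbol: str = UNKNOWN
    size_limit: int = 4096

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.ids

    @property
    def unknown_id(self) -> int:
        return self.ids[self.unknown_symbol]

    @property
    def boundary_id(self) -> int | None:
        return self.ids.get(BOUNDARY)

    def id_of(self, word: str) -> int:
        return self.ids.get(word, self.unknown_id)

    def decode(self, token_ids: Iterable[int]) -> list[str]:
        return [self.words[i] for i in token_ids]

    def to_json(self, path: str | Path) -> None:
        payload = {
            w: {"id": self.ids[w], "freq": int(self.frequencies.get(w, 0))}
            for w in self.words
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        payload = json.loads(Path(path).read_text())
        words = sorted(payload, key=lambda w: payload[w]["id"])
        ids = {w: payload[w]["id"] for w in words}
        freqs = {w: payload[w]["freq"] for w in words}
        return cls(words=words, ids=ids, frequencies=freqs, size_limit=len(words))


@dataclass
class PartitionSet:
    """Equal-length consecutive slices of the encoded training stream."""

    partitions: np.ndarray  # (n_partitions, tokens_per_partition) int array
    tokens_per_partition: int
    n_partitions: int
    n_dropped: int = 0

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.partitions)

    def concatenate(self) -> np.ndarray:
        return self.partitions.reshape(-1)


# ---------------------------------------------------------------------------
# tokenization and normalization


def normalize_and_tokenize(
    raw_text: str,
    aliases: Mapping[str, str] | None = None,
    names: Mapping[str, str] | None = None,
) -> list[str]:
    """Lower-case and tokenize one utterance line.

    Splits on whitespace, emits sentence-boundary punctuation as separate
    tokens, rewrites spelling variants through ``aliases`` and replaces
    proper names with FNAME/MNAME gender tokens via ``names`` (a map from
    lower-cased name to ``"female"``/``"male"``).  An empty line yields an
    empty token list.
    """
    aliases = aliases or {}
    names = names or {}
    tokens: list[str] = []
    for chunk in raw_text.lower().split():
        tokens.extend(_split_punctuation(chunk))
    out: list[str] = []
    for tok in tokens:
        tok = aliases.get(tok, tok)
        if tok in names:
            gender = names[tok].strip().lower()
            tok = "FNAME" if gender.startswith("f") else "MNAME"
        out.append(tok)
    return out


def _split_punctuation(chunk: str) -> list[str]:
    """Peel sentence-boundary punctuation off both ends of a chunk."""
    if chunk in PUNCTUATION:
        return [chunk]
    lead: list[str] = []
    trail: list[str] = []
    while chunk and chunk[0] in PUNCTUATION:
        lead.append(chunk[0])
        chunk = chunk[1:]
    while chunk and chunk[-1] in PUNCTUATION:
        trail.append(chunk[-1])
        chunk = chunk[:-1]
    middle = [chunk] if chunk else []
    return lead + middle + list(reversed(trail))


def morph_split(
    tokens: Sequence[str],
    stems: Iterable[str] | None = None,
    exceptions: Iterable[str] | None = None,
) -> list[str]:
    """Split productive noun/verb suffixes off their stems.

    Plural (-s, -es), possessive (-'s, -s'), diminutive (-ie, -y),
    past-tense (-ed) and progressive (-ing) endings are emitted as tokens
    of their own immediately after the stem.  A split is only made when
    the candidate stem occurs independently in ``stems`` (a lexicon of
    attested stem forms), so function words pass through unchanged.
    Tokens in ``exceptions`` are never split.
    """
    stem_set = set(stems) if stems is not None else set()
    except_set = set(exceptions) if exceptions is not None else set()
    out: list[str] = []
    for tok in tokens:
        out.extend(_split_token(tok, stem_set, except_set))
    return out


def _split_token(tok: str, stems: set[str], exceptions: set[str]) -> list[str]:
    if tok in exceptions or tok in stems:
        return [tok]
    for suffix in MORPH_SUFFIXES:
        if not tok.endswith(suffix):
            continue
        stem = tok[: -len(suffix)]
        if suffix == "ies":
            # babies -> baby + -s
            if stem + "y" in stems:
                return [stem + "y", "-s"]
            continue
        if len(stem) >= 2 and stem in stems:
            return [stem, "-" + suffix]
    return [tok]


# ---------------------------------------------------------------------------
# vocabulary and encoding


def build_vocabulary(
    corpus: Corpus,
    size_limit: int = 4096,
    extra_symbols: Sequence[str] = (UNKNOWN,),
) -> Vocabulary:
    """Keep the most frequent word types, reserving slots for symbols.

    ``extra_symbols`` (at minimum UNKNOWN) occupy inventory slots so a
    model built on the vocabulary has exactly ``size_limit`` input/output
    units.  Frequency ties are broken lexicographically for deterministic
    builds.
    """
    if size_limit < 2:
        raise InvalidConfigError(f"size_limit must be >= 2, got {size_limit}")
    if UNKNOWN not in extra_symbols:
        raise InvalidConfigError("extra_symbols must include UNKNOWN")
    counts = Counter(corpus.tokens())
    n_kept = size_limit - len(extra_symbols)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = ranked[:n_kept]
    words = [w for w, _ in kept]
    freqs = {w: c for w, c in kept}
    oov_mass = sum(c for _, c in ranked[n_kept:])
    for sym in extra_symbols:
        words.append(sym)
        freqs[sym] = oov_mass if sym == UNKNOWN else 0
    ids = {w: i for i, w in enumerate(words)}
    return Vocabulary(
        words=words, ids=ids, frequencies=freqs, size_limit=size_limit
    )


def encode_corpus(corpus: Corpus, vocab: Vocabulary) -> list[np.ndarray]:
    """Encode each document as one flat int-id array (OOV -> UNKNOWN id)."""
    encoded = []
    for doc in corpus:
        ids = np.fromiter(
            (vocab.id_of(t) for t in doc.tokens()),
            dtype=np.int64,
            count=doc.n_tokens,
        )
        encoded.append(ids)
    return encoded


def split_train_test(
    corpus: Corpus, test_fraction: float, seed: int
) -> tuple[Corpus, Corpus]:
    """Document-level random split; both halves keep age ordering."""
    if not 0.0 < test_fraction < 1.0:
        raise InvalidConfigError(
            f"test_fraction must lie in (0, 1), got {test_fraction}"
        )
    n = len(corpus)
    if n < 2:
        raise InvalidConfigError("need at least 2 documents to split")
    rng = np.random.default_rng(seed)
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    train_docs = [d for i, d in enumerate(corpus) if i not in test_idx]
    test_docs = [d for i, d in enumerate(corpus) if i in test_idx]
    return Corpus(documents=train_docs), Corpus(documents=test_docs)


def partition_corpus(encoded_train: np.ndarray, n_partitions: int) -> PartitionSet:
    """Slice the training stream into equal consecutive partitions.

    Partition size is ``floor(N / n_partitions)``; trailing remainder
    tokens are dropped and their count reported on the result.
    """
    if n_partitions <= 0:
        raise InvalidConfigError(f"n_partitions must be positive, got {n_partitions}")
    encoded_train = np.asarray(encoded_train)
    n = encoded_train.shape[0]
    if n < n_partitions:
        raise InvalidConfigError(
            f"cannot split {n} tokens into {n_partitions} partitions"
        )
    per = n // n_partitions
    used = per * n_partitions
    dropped = n - used
    if dropped:
        logger.info("partitioning dropped %d remainder tokens", dropped)
    parts = encoded_train[:used].reshape(n_partitions, per)
    return PartitionSet(
        partitions=parts,
        tokens_per_partition=per,
        n_partitions=n_partitions,
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# disk formats


def read_corpus_dir(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    names: Mapping[str, str] | None = None,
    stems: Iterable[str] | None = None,
    morph: bool = False,
) -> Corpus:
    """Read a directory of ``<doc_id>.txt`` files plus ``ages.tsv``.

    Each text file holds one utterance per line; ``ages.tsv`` maps
    ``doc_id<TAB>age_months``.  Tokenization/normalization (and optional
    morphological splitting against ``stems``) is applied on read.
    """
    path = Path(path)
    ages = read_tsv_map(path / "ages.tsv")
    docs = []
    for doc_id, age in ages.items():
        lines = (path / f"{doc_id}.txt").read_text().splitlines()
        utts = []
        for line in lines:
            toks = normalize_and_tokenize(line, aliases=aliases, names=names)
            if morph:
                toks = morph_split(toks, stems=stems)
            if toks:
                utts.append(toks)
        docs.append(
            Document(doc_id=doc_id, child_age_months=float(age), utterances=utts)
        )
    return Corpus(documents=docs)


def write_corpus_dir(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the plain-text + ages.tsv exchange format."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = []
    for doc in corpus:
        lines.append(f"{doc.doc_id}\t{doc.child_age_months:g}")
        text = "\n".join(" ".join(utt) for utt in doc.utterances)
        (path / f"{doc.doc_id}.txt").write_text(text + "\n")
    (path / "ages.tsv").write_text("\n".join(lines) + "\n")


def read_tsv_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV -> dict, skipping blank lines and # comments."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")[:2]
        out[key] = value
    return out


def save_encoded(path: str | Path, encoded: list[np.ndarray], ages: list[float]) -> None:
    """Persist encoded documents as an .npz with per-document arrays."""
    arrays = {f"doc_{i:05d}": arr for i, arr in enumerate(encoded)}
    arrays["ages"] = np.asarray(ages, dtype=float)
    np.savez_compressed(Path(path), **arrays)


def load_encoded(path: str | Path) -> tuple[list[np.ndarray], np.ndarray]:
    with np.load(Path(path)) as data:
        keys = sorted(k for k in data.files if k.startswith("doc_"))
        return [data[k] for k in keys], data["ages"]
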