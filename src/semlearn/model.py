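"""Model/Results interface over the functional training core.

Mirrors the fit-and-results convention of statistical modelling packages:
a model object is constructed from data (an encoded, partitioned corpus
and its vocabulary), ``fit()`` runs the training procedure and returns a
results object that carries the fitted weights, the training log, and the
downstream quantities (perplexity, contextual representations,
similarity matrices) as methods, plus a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import PartitionSet, Vocabulary, partition_corpus
from .evaluation import perplexity as _perplexity
from .networks import InitSpec, init_weights
from .semspace import (
    RepresentationMatrix,
    extract_contextual_reps,
    skipgram_reps,
)
from .training import (
    SkipGramTrainingConfig,
    TrainingConfig,
    train_recurrent,
    train_skipgram,
)


class RecurrentLanguageModel:
    """A next-word predictor (SRN or gated LSTM) over an encoded corpus.

    Parameters
    ----------
    partitions
        Equal-size partitions of the encoded training stream, in age
        order (see `semlearn.corpus.partition_corpus`).
    vocab
        The vocabulary the corpus was encoded with; its size fixes the
        input/output width of the network.
    arch
        ``"srn"`` or ``"lstm"``.

    Examples
    --------
    >>> model = RecurrentLanguageModel(parts, vocab, arch="srn")
    >>> res = model.fit(TrainingConfig(local_iterations=4, hidden_size=64))
    >>> res.perplexity(test_tokens)
    """

    def __init__(
        self,
        partitions: PartitionSet,
        vocab: Vocabulary,
        arch: str = "srn",
    ) -> None:
        if arch not in ("srn", "lstm"):
            raise ValueError(f"arch must be 'srn' or 'lstm', got {arch!r}")
        self.partitions = partitions
        self.vocab = vocab
        self.arch = arch
        bid = vocab.boundary_id
        self.pad_id = bid if bid is not None else vocab.unknown_id

    @classmethod
    def from_tokens(
        cls,
        tokens: np.ndarray,
        vocab: Vocabulary,
        n_partitions: int,
        arch: str = "srn",
    ) -> "RecurrentLanguageModel":
        return cls(partition_corpus(tokens, n_partitions), vocab, arch=arch)

    def fit(self, config: TrainingConfig) -> "RecurrentLMResults":
        weights, log = train_recurrent(
            self.arch,
            self.partitions,
            config,
            n_symbols=len(self.vocab),
            pad_id=self.pad_id,
        )
        return RecurrentLMResults(self, config, weights, log)

    def init_only(self, config: TrainingConfig) -> "RecurrentLMResults":
        """An untrained results object (weights at initialization)."""
        weights = init_weights(
            InitSpec(seed=config.seed), self.arch, len(self.vocab),
            config.hidden_size,
        )
        return RecurrentLMResults(self, config, weights, pd.DataFrame())


@dataclass
class RecurrentLMResults:
    """Fitted weights, training diagnostics, and evaluation entry points."""

    model: RecurrentLanguageModel
    config: TrainingConfig
    weights: object
    log: pd.DataFrame

    def perplexity(self, tokens: np.ndarray) -> float:
        """Per-word perplexity on a held-out encoded token stream."""
        return _perplexity(self.weights, tokens, self.model.pad_id)

    def representations(
        self, tokens: np.ndarray, batch_size: int = 512
    ) -> RepresentationMatrix:
        """Averaged contextual (hidden-state) representations per word."""
        return extract_contextual_reps(
            self.weights, tokens, self.model.vocab,
            pad_id=self.model.pad_id, batch_size=batch_size,
        )

    def summary(self) -> str:
        lines = [
            f"{self.model.arch.upper()} language model",
            "=" * 38,
            f"inventory (V):        {len(self.model.vocab)}",
            f"hidden units (H):     {self.config.hidden_size}",
            f"partitions:           {self.model.partitions.n_partitions}"
            f" x {self.model.partitions.tokens_per_partition} tokens",
            f"local iterations:     {self.config.local_iterations}",
            f"mini-batch size:      {self.config.mini_batch_size}",
            f"learning rate:        {self.config.learning_rate} (Adagrad)",
            f"seed:                 {self.config.seed}",
        ]
        if len(self.log):
            lines += [
                f"first-block loss:     {self.log['mean_loss'].iloc[0]:.4f}",
                f"final-block loss:     {self.log['mean_loss'].iloc[-1]:.4f}",
            ]
        else:
            lines.append("state:                untrained (initialization only)")
        return "\n".join(lines)


class SkipGramModel:
    """Skip-gram with negative sampling over an encoded token stream."""

    def __init__(self, tokens: np.ndarray, vocab: Vocabulary) -> None:
        self.tokens = np.asarray(tokens, dtype=np.int64)
        self.vocab = vocab

    def fit(self, config: SkipGramTrainingConfig) -> "SkipGramResults":
        weights, log = train_skipgram(self.tokens, config, len(self.vocab))
        return SkipGramResults(self, config, weights, log)


@dataclass
class SkipGramResults:
    model: SkipGramModel
    config: SkipGramTrainingConfig
    weights: object
    log: pd.DataFrame

    def representations(self) -> RepresentationMatrix:
        """Input-embedding rows as word representations."""
        return skipgram_reps(self.weights, self.model.vocab)

    def summary(self) -> str:
        lines = [
            "Skip-gram (negative sampling)",
            "=" * 38,
            f"inventory (V):        {len(self.model.vocab)}",
            f"embedding size (H):   {self.config.hidden_size}",
            f"window size:          ±{self.config.window_size}",
            f"epochs:               {self.config.n_epochs}",
            f"negatives per pair:   {self.config.k_negatives}",
            f"seed:                 {self.config.seed}",
        ]
        if len(self.log):
            lines.append(
                f"final-epoch loss:     {self.log['mean_loss'].iloc[-1]:.4f}"
            )
        return "\n".join(lines)
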