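"""Age-ordered local-iteration training with Adagrad.

Instead of epoch training (1,2,3,1,2,3,...), each age-ordered corpus
partition is repeated several times before moving to the next
(1,1,1,1,2,2,2,2,...), emulating day-by-day consolidation of linguistic
experience.  Weight updates use mini-batches of prediction windows: the
update reflects the *average* prediction error over the mini-batch, and
per-weight Adagrad scaling gives infrequently updated weights a larger
effective learning rate.  Adagrad accumulators are never reset between
partition blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .corpus import InvalidConfigError, PartitionSet
from .networks import (
    InitSpec,
    SkipGramWeights,
    batch_loss_and_grads,
    init_weights,
    make_windows,
    sample_negatives,
    sgns_batch_update,
    skipgram_pairs,
    unigram_noise,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Hyperparameters of the recurrent-model training loop.

    ``local_iterations`` (repetitions per partition before advancing) has
    no canonical value and must be set explicitly.
    """

    local_iterations: int
    learning_rate: float = 0.01
    mini_batch_size: int = 64
    adagrad_epsilon: float = 1e-8
    hidden_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning_rate must be positive")
        if self.mini_batch_size < 1:
            raise InvalidConfigError("mini_batch_size must be >= 1")
        if self.local_iterations < 1:
            raise InvalidConfigError("local_iterations must be >= 1")


def build_schedule(n_partitions: int, local_iterations: int) -> list[int]:
    """Block-repetition partition order, 1-based: (3, 4) ->
    [1,1,1,1,2,2,2,2,3,3,3,3]."""
    if n_partitions < 1 or local_iterations < 1:
        raise InvalidConfigError("n_partitions and local_iterations must be >= 1")
    return [p for p in range(1, n_partitions + 1) for _ in range(local_iterations)]


@dataclass
class AdagradState:
    """Per-weight accumulated squared gradients (non-decreasing)."""

    accumulators: dict[str, np.ndarray]
    step: int = 0


def init_adagrad(params: dict[str, np.ndarray]) -> AdagradState:
    return AdagradState(
        accumulators={k: np.zeros_like(v) for k, v in params.items()}
    )


def adagrad_update(
    state: AdagradState,
    params: dict[str, np.ndarray],
    gradients: dict[str, np.ndarray],
    learning_rate: float,
    epsilon: float = 1e-8,
) -> None:
    """In-place update: acc += g²; Δw = -lr · g / (sqrt(acc) + ε)."""
    for name, g in gradients.items():
        acc = state.accumulators[name]
        acc += g * g
        params[name] -= learning_rate * g / (np.sqrt(acc) + epsilon)
    state.step += 1


def train_recurrent(
    arch: str,
    partitions: PartitionSet,
    config: TrainingConfig,
    n_symbols: int,
    pad_id: int,
    checkpoint_callback: Callable[[int, object], None] | None = None,
) -> tuple[object, pd.DataFrame]:
    """Train an SRN or LSTM over the local-iteration schedule.

    Windows are presented in corpus order within each partition; gradients
    are averaged over ``mini_batch_size`` windows before each Adagrad
    update.  Returns the trained weights and a log with one row per
    partition block (step, partition, repetition, mean window loss).
    ``checkpoint_callback(block_index, weights)``, if given, runs at the
    end of every partition block.
    """
    if partitions.partitions.max() >= n_symbols or pad_id >= n_symbols:
        raise InvalidConfigError("corpus token ids exceed the model inventory")
    weights = init_weights(
        InitSpec(seed=config.seed), arch, n_symbols, config.hidden_size
    )
    params = weights.params()
    opt = init_adagrad(params)
    schedule = build_schedule(partitions.n_partitions, config.local_iterations)
    rows = []
    step = 0
    rep_counter: dict[int, int] = {}
    for block, part_no in enumerate(schedule):
        tokens = partitions.partitions[part_no - 1]
        windows, targets = make_windows(tokens, pad_id)
        losses = []
        for start in range(0, windows.shape[0], config.mini_batch_size):
            w_batch = windows[start:start + config.mini_batch_size]
            t_batch = targets[start:start + config.mini_batch_size]
            loss, grads = batch_loss_and_grads(weights, w_batch, t_batch)
            adagrad_update(
                opt, params, grads, config.learning_rate, config.adagrad_epsilon
            )
            losses.append(loss)
            step += 1
        rep_counter[part_no] = rep_counter.get(part_no, 0) + 1
        rows.append(
            {
                "step": step,
                "partition": part_no,
                "repetition": rep_counter[part_no],
                "mean_loss": float(np.mean(losses)),
            }
        )
        logger.debug(
            "%s block %d (partition %d): mean loss %.4f",
            arch, block, part_no, rows[-1]["mean_loss"],
        )
        if checkpoint_callback is not None:
            checkpoint_callback(block, weights)
    return weights, pd.DataFrame(rows)


@dataclass
class SkipGramTrainingConfig:
    """Skip-gram negative-sampling hyperparameters.

    Learning rate decays linearly from ``learning_rate`` to ``min_learning_rate``
    over training, the noise distribution is the unigram distribution
    raised to 0.75, and no frequent-word subsampling is applied.
    """

    n_epochs: int = 20
    window_size: int = 3
    k_negatives: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    noise_power: float = 0.75
    batch_size: int = 512
    hidden_size: int = 512
    seed: int = 0


def train_skipgram(
    tokens: np.ndarray,
    config: SkipGramTrainingConfig,
    n_symbols: int,
) -> tuple[SkipGramWeights, pd.DataFrame]:
    """Train Skip-gram with negative sampling over the token stream.

    Pairs are enumerated in corpus order each epoch; negatives are drawn
    from the smoothed unigram distribution, redrawn when they collide
    with the true context word.
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    weights = init_weights(
        InitSpec(seed=config.seed),
        "skipgram",
        n_symbols,
        config.hidden_size,
        window_size=config.window_size,
        n_epochs=config.n_epochs,
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    counts = np.bincount(tokens, minlength=n_symbols)
    noise = unigram_noise(counts, config.noise_power)
    pairs = np.fromiter(
        (x for pair in skipgram_pairs(tokens, config.window_size) for x in pair),
        dtype=np.int64,
    ).reshape(-1, 2)
    n_total = config.n_epochs * pairs.shape[0]
    rows = []
    seen = 0
    for epoch in range(config.n_epochs):
        losses = []
        for start in range(0, pairs.shape[0], config.batch_size):
            batch = pairs[start:start + config.batch_size]
            lr = config.learning_rate + (
                config.min_learning_rate - config.learning_rate
            ) * (seen / n_total)
            negs = sample_negatives(rng, noise, batch[:, 1], config.k_negatives)
            losses.append(
                sgns_batch_update(weights, batch[:, 0], batch[:, 1], negs, lr)
            )
            seen += batch.shape[0]
        rows.append({"epoch": epoch, "mean_loss": float(np.mean(losses))})
        logger.debug("skipgram epoch %d: mean loss %.4f", epoch, rows[-1]["mean_loss"])
    return weights, pd.DataFrame(rows)
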