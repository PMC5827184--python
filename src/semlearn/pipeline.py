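"""End-to-end orchestration: synth/prep → train replicates → extract → evaluate.

Stages communicate through files under one output directory so that each
stage can be re-run or resumed independently, and a manifest records the
configuration snapshot, per-stage seeds, and content hashes of the
artifacts so a re-run can be checked for bit-identical outputs.
Single-threaded execution under fixed seeds is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus import (
    BOUNDARY,
    UNKNOWN,
    Corpus,
    build_vocabulary,
    encode_corpus,
    load_encoded,
    partition_corpus,
    read_corpus_dir,
    save_encoded,
    split_train_test,
    write_corpus_dir,
    Vocabulary,
)
from .evaluation import (
    ThresholdGrid,
    balanced_accuracy_sweep,
    category_similarity_matrix,
    hierarchical_cluster,
    perplexity,
)
from .io import load_checkpoint, save_checkpoint
from .model import RecurrentLanguageModel, SkipGramModel
from .semspace import (
    ProbeSet,
    extract_contextual_reps,
    model_reliability,
    similarity_matrix,
    skipgram_reps,
)
from .synthetic import GeneratorConfig, generate_corpus, generate_lexicon
from .training import SkipGramTrainingConfig, TrainingConfig

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


# ---------------------------------------------------------------------------
# stages


def stage_synth(cfg: dict, out: Path) -> Path:
    """Generate a synthetic corpus in the corpus-prep input format."""
    gen = GeneratorConfig(**cfg)
    lexicon = generate_lexicon(gen)
    corpus, probes = generate_corpus(lexicon, gen)
    corpus_dir = out / "corpus"
    write_corpus_dir(corpus, corpus_dir)
    ProbeSet(probes=probes).to_tsv(out / "probes.tsv")
    return corpus_dir


def stage_prep(
    corpus_dir: Path,
    out: Path,
    vocab_size: int,
    n_partitions: int,
    test_fraction: float,
    seed: int,
) -> dict:
    """Tokenize, split, build vocabulary, encode, and partition."""
    out.mkdir(parents=True, exist_ok=True)
    corpus = read_corpus_dir(corpus_dir)
    train, test = split_train_test(corpus, test_fraction, seed)
    vocab = build_vocabulary(
        train, size_limit=vocab_size, extra_symbols=(UNKNOWN, BOUNDARY)
    )
    vocab.to_json(out / "vocab.json")
    enc_train = encode_corpus(train, vocab)
    enc_test = encode_corpus(test, vocab)
    save_encoded(out / "train.npz", enc_train,
                 [d.child_age_months for d in train])
    save_encoded(out / "test.npz", enc_test,
                 [d.child_age_months for d in test])
    stream = np.concatenate(enc_train)
    parts = partition_corpus(stream, n_partitions)
    meta = {
        "n_partitions": n_partitions,
        "tokens_per_partition": parts.tokens_per_partition,
        "n_dropped": parts.n_dropped,
        "n_train_tokens": int(stream.shape[0]),
        "n_test_tokens": int(sum(len(a) for a in enc_test)),
        "vocab_size": len(vocab),
    }
    (out / "prep.json").write_text(json.dumps(meta, indent=1))
    return meta


def _load_prep(prep_dir: Path) -> tuple[Vocabulary, np.ndarray, np.ndarray, dict]:
    vocab = Vocabulary.from_json(prep_dir / "vocab.json")
    train_docs, _ = load_encoded(prep_dir / "train.npz")
    test_docs, _ = load_encoded(prep_dir / "test.npz")
    meta = json.loads((prep_dir / "prep.json").read_text())
    return vocab, np.concatenate(train_docs), np.concatenate(test_docs), meta


def stage_train(
    prep_dir: Path,
    out: Path,
    arch: str,
    replicates: int,
    seed: int,
    resume: bool = False,
    **train_kwargs,
) -> list[Path]:
    """Train `replicates` models of one architecture, differing only by seed."""
    out.mkdir(parents=True, exist_ok=True)
    vocab, train_tokens, _, meta = _load_prep(prep_dir)
    paths = []
    for rep in range(replicates):
        ckpt = out / f"{arch}_{rep:02d}.h5"
        paths.append(ckpt)
        if resume and ckpt.exists():
            logger.info("resuming: %s already trained", ckpt.name)
            continue
        rep_seed = int(seed + 1000 * rep) % (2 ** 31)
        if arch == "skipgram":
            cfg = SkipGramTrainingConfig(seed=rep_seed, **train_kwargs)
            res = SkipGramModel(train_tokens, vocab).fit(cfg)
        else:
            cfg = TrainingConfig(seed=rep_seed, **train_kwargs)
            model = RecurrentLanguageModel.from_tokens(
                train_tokens, vocab, meta["n_partitions"], arch=arch
            )
            res = model.fit(cfg)
        res.log.to_csv(ckpt.with_suffix(".log.tsv"), sep="\t", index=False)
        save_checkpoint(ckpt, res.weights,
                        {"arch": arch, "seed": rep_seed, "config": vars(cfg)})
    return paths


def stage_extract(prep_dir: Path, checkpoint: Path, out: Path) -> Path:
    """Frozen-weight representation extraction for one checkpoint."""
    out.mkdir(parents=True, exist_ok=True)
    vocab, train_tokens, _, _ = _load_prep(prep_dir)
    weights, manifest = load_checkpoint(checkpoint)
    if manifest.get("arch") == "skipgram":
        reps = skipgram_reps(weights, vocab)
    else:
        reps = extract_contextual_reps(weights, train_tokens, vocab)
    path = out / (checkpoint.stem + "_reps.npz")
    np.savez_compressed(
        path,
        matrix=reps.matrix,
        counts=reps.occurrence_counts,
        words=np.array(reps.words),
        source=np.array(reps.source),
    )
    return path


def _load_reps(path: Path):
    from .semspace import RepresentationMatrix

    with np.load(path) as data:
        return RepresentationMatrix(
            words=[str(w) for w in data["words"]],
            matrix=data["matrix"],
            occurrence_counts=data["counts"],
            source=str(data["source"]),
        )


def stage_evaluate(
    prep_dir: Path,
    rep_paths: list[Path],
    probes_path: Path,
    out: Path,
    grid_step: float = 0.001,
    checkpoints: dict[str, Path] | None = None,
) -> pd.DataFrame:
    """Balanced accuracy, category structure, reliability, perplexity."""
    out.mkdir(parents=True, exist_ok=True)
    vocab, _, test_tokens, _ = _load_prep(prep_dir)
    probes = ProbeSet.from_tsv(probes_path).restricted_to(vocab.words)
    grid = ThresholdGrid(step=grid_step)
    all_reps = {p.stem.replace("_reps", ""): _load_reps(p) for p in rep_paths}

    summary_rows = []
    vocab_sims = {}
    for name, reps in all_reps.items():
        word_index = {w: i for i, w in enumerate(reps.words)}
        defined = [w for w in probes.words()
                   if w in word_index
                   and reps.occurrence_counts[word_index[w]] > 0]
        pset = ProbeSet(probes={w: probes.probes[w] for w in defined})
        s_pp = similarity_matrix(reps, defined)
        report = balanced_accuracy_sweep(s_pp, pset, grid)
        report.per_probe_at_best.to_csv(
            out / f"{name}_balanced_accuracy.tsv", sep="\t"
        )
        cat = category_similarity_matrix(s_pp, pset)
        cat.to_frame().to_csv(out / f"{name}_category_similarity.tsv", sep="\t")
        dend = hierarchical_cluster(s_pp)
        (out / f"{name}_dendrogram.nwk").write_text(dend.to_newick())
        cols = [w for i, w in enumerate(reps.words)
                if reps.occurrence_counts[i] > 0]
        vocab_sims[name] = similarity_matrix(reps, defined, cols)
        row = {
            "model": name,
            "mean_balanced_accuracy": report.mean_balanced_accuracy,
            "best_threshold": report.best_threshold,
            "n_probes": len(defined),
        }
        if checkpoints and name in checkpoints:
            weights, manifest = load_checkpoint(checkpoints[name])
            if manifest.get("arch") != "skipgram":
                pad = vocab.boundary_id
                row["test_perplexity"] = perplexity(
                    weights, test_tokens,
                    pad if pad is not None else vocab.unknown_id,
                )
        summary_rows.append(row)

    names = sorted(vocab_sims)
    rel_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = vocab_sims[a], vocab_sims[b]
            common_rows = [w for w in sa.row_words if w in set(sb.row_words)]
            common_cols = [w for w in sa.col_words if w in set(sb.col_words)]
            ra = _subset_sim(sa, common_rows, common_cols)
            rb = _subset_sim(sb, common_rows, common_cols)
            rel_rows.append(
                {"model_a": a, "model_b": b,
                 "reliability": model_reliability(ra, rb)}
            )
    pd.DataFrame(rel_rows).to_csv(out / "reliability.tsv", sep="\t", index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return summary


def _subset_sim(s, rows, cols):
    from .semspace import SimilarityMatrix

    ri = [s.row_words.index(w) for w in rows]
    ci = [s.col_words.index(w) for w in cols]
    return SimilarityMatrix(
        values=s.values[np.ix_(ri, ci)], row_words=rows, col_words=cols
    )


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 resume: bool = False) -> dict:
    """Execute synth → prep → train → extract → evaluate from one config.

    Returns the run manifest (also written to ``manifest.json``).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if "synthetic" in config:
        syn_cfg = dict(config["synthetic"])
        syn_cfg.setdefault("seed", seed)
        corpus_dir = stage_synth(syn_cfg, out)
    else:
        corpus_dir = Path(config["corpus_dir"])
    probes_path = (
        out / "probes.tsv" if "synthetic" in config
        else Path(config["probes"])
    )

    prep_cfg = config.get("prep", {})
    prep_dir = out / "prep"
    stage_prep(
        corpus_dir,
        prep_dir,
        vocab_size=int(prep_cfg.get("vocab_size", 4096)),
        n_partitions=int(prep_cfg.get("n_partitions", 256)),
        test_fraction=float(prep_cfg.get("test_fraction", 0.012)),
        seed=seed,
    )

    ckpt_dir = out / "checkpoints"
    checkpoints: dict[str, Path] = {}
    for arch_cfg in config.get("train", []):
        arch_cfg = dict(arch_cfg)
        arch = arch_cfg.pop("arch")
        replicates = int(arch_cfg.pop("replicates", 1))
        paths = stage_train(
            prep_dir, ckpt_dir, arch, replicates, seed,
            resume=resume, **arch_cfg,
        )
        for p in paths:
            checkpoints[p.stem] = p

    reps_dir = out / "reps"
    rep_paths = [stage_extract(prep_dir, p, reps_dir)
                 for p in checkpoints.values()]

    eval_cfg = config.get("evaluate", {})
    stage_evaluate(
        prep_dir, rep_paths, probes_path, out / "reports",
        grid_step=float(eval_cfg.get("grid_step", 0.001)),
        checkpoints=checkpoints,
    )

    artifacts = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
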