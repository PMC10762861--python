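"""End-to-end pipeline: simulate → build-dict → retrieve → train → link →
evaluate, with file artifacts in the documented formats.

Every stage is a plain function over paths so the CLI stays thin.  All
randomness flows from the pipeline seed; two runs with identical config and
seed produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as ev
from . import kb as kbio
from . import retrieval as rt
from .encoding import toy_dual_encoder
from .synth import SynthConfig, generate_corpus, generate_kb, train_dev_test_split
from .training import TrainingConfig, train

CHECKPOINT_VERSION = 1


@dataclass
class PipelineConfig:
    """Union of generator, retrieval, encoder and training settings."""

    seed: int = 0
    k: int = 64
    d: int = 32
    ctx_weight: float = 0.5
    max_len: int = 128
    dense_max_tokens: int = 50
    seen_fraction: float = 0.7
    use_dense: bool = False
    synth: SynthConfig = field(default_factory=SynthConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if self.k < 1 or self.d < 2 or not 0 < self.seen_fraction <= 1:
            raise ValueError("invalid pipeline configuration")

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj)
        kwargs = {}
        for section, sub_cls in (("synth", SynthConfig), ("training", TrainingConfig)):
            if section in obj:
                sub = obj.pop(section)
                unknown = set(sub) - {f.name for f in dataclasses.fields(sub_cls)}
                if unknown:
                    raise ValueError(f"unknown {section} keys: {sorted(unknown)}")
                for key in ("synonyms_per_entity", "head_range"):
                    if key in sub:
                        sub[key] = tuple(sub[key])
                kwargs[section] = sub_cls(**sub)
        unknown = set(obj) - {f.name for f in dataclasses.fields(cls)} - {"synth", "training"}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**obj, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = dataclasses.replace(
            self,
            seed=seed,
            synth=dataclasses.replace(self.synth, seed=seed),
            training=dataclasses.replace(self.training, seed=seed),
        )
        return cfg


def simulate(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a KB and split corpora; write JSONL artifacts and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kb = generate_kb(config.synth)
    corpus = generate_corpus(kb, config.synth)
    train_docs, dev_docs, test_docs = train_dev_test_split(
        corpus, config.seen_fraction, config.seed
    )
    paths = {
        "kb": out / "kb.jsonl",
        "train": out / "train.jsonl",
        "dev": out / "dev.jsonl",
        "test": out / "test.jsonl",
        "manifest": out / "manifest.json",
    }
    kbio.write_kb_jsonl(kb, paths["kb"])
    kbio.write_corpus(train_docs, paths["train"])
    kbio.write_corpus(dev_docs, paths["dev"])
    kbio.write_corpus(test_docs, paths["test"])
    manifest = {
        "seed": config.seed,
        "seen_fraction": config.seen_fraction,
        "synth": dataclasses.asdict(config.synth),
        "n_documents_generated": len(corpus),
        "split_sizes": {
            "train": len(train_docs),
            "dev": len(dev_docs),
            "test": len(test_docs),
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return paths


def build_dict(kb_path: str | Path, out_dir: str | Path) -> dict:
    """Build the synonym dictionary, persist the fitted tf-idf vectorizers,
    and return/write summary statistics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entities = kbio.read_kb_jsonl(kb_path)
    index = kbio.build_synonym_index(entities)
    char_vec = rt.fit_sparse(index.synonyms, mode="char_ngram")
    word_vec = rt.fit_sparse(index.synonyms, mode="word_unigram")
    char_vec.save(out / "tfidf_char.json")
    word_vec.save(out / "tfidf_word.json")
    stats = {
        "n_entities": len(index.entities),
        "n_synonyms": len(index),
        "n_ambiguous_synonyms": sum(1 for s in index.entries.values() if len(s) > 1),
    }
    (out / "dictionary_stats.json").write_text(json.dumps(stats, sort_keys=True, indent=1))
    return stats


def _corpus_mentions(docs: list[kbio.Document]) -> list[kbio.MentionAnnotation]:
    return [m for d in docs for m in d.mentions]


def retrieve(
    kb_path: str | Path,
    corpus_path: str | Path,
    out_tsv: str | Path,
    k: int = 64,
    config: PipelineConfig | None = None,
) -> dict[str, rt.CandidateList]:
    """Merged sparse candidates (char n-gram + word unigram tf-idf) per mention.

    With ``config.use_dense`` a dense toy-encoder list joins the merge."""
    entities = kbio.read_kb_jsonl(kb_path)
    index = kbio.build_synonym_index(entities)
    docs = kbio.read_corpus(corpus_path)
    mentions = _corpus_mentions(docs)

    char_vec = rt.fit_sparse(index.synonyms, mode="char_ngram")
    word_vec = rt.fit_sparse(index.synonyms, mode="word_unigram")
    char_matrix = char_vec.transform(index.synonyms)
    word_matrix = word_vec.transform(index.synonyms)
    dense_index = None
    if config is not None and config.use_dense:
        _, entity_enc = toy_dual_encoder(config.d, config.seed, ctx_weight=config.ctx_weight)
        dense_index = rt.DenseSynonymIndex(index, entity_enc, max_tokens=config.dense_max_tokens)

    merged: dict[str, rt.CandidateList] = {}
    for m in mentions:
        lists = [
            rt.retrieve_candidates(
                m.uid, index, rt.score_synonyms(m.surface, char_vec, char_matrix), k, "char"
            ),
            rt.retrieve_candidates(
                m.uid, index, rt.score_synonyms(m.surface, word_vec, word_matrix), k, "word"
            ),
        ]
        if dense_index is not None:
            lists.append(rt.dense_retrieve(m.uid, m.surface, dense_index, k))
        merged[m.uid] = rt.merge_candidate_lists(lists, k)
    rt.write_candidates_tsv([merged[m.uid] for m in mentions], out_tsv)
    return merged


def save_checkpoint(path: str | Path, result, config: PipelineConfig) -> None:
    obj = {
        "format_version": CHECKPOINT_VERSION,
        "d": config.d,
        "seed": config.seed,
        "ctx_weight": config.ctx_weight,
        "lam": result.radius_state.lam,
        "W_m": result.mention_encoder.W.tolist(),
        "W_e": result.entity_encoder.W.tolist(),
        "training": dataclasses.asdict(config.training),
    }
    Path(path).write_text(json.dumps(obj))


def load_checkpoint(path: str | Path):
    obj = json.loads(Path(path).read_text())
    if obj.get("format_version") != CHECKPOINT_VERSION:
        raise ValueError("unsupported checkpoint version")
    menc, eenc = toy_dual_encoder(obj["d"], obj["seed"], ctx_weight=obj["ctx_weight"])
    menc.W = np.asarray(obj["W_m"], dtype=float)
    eenc.W = np.asarray(obj["W_e"], dtype=float)
    return menc, eenc, obj


def train_stage(
    kb_path: str | Path,
    corpus_path: str | Path,
    candidates_tsv: str | Path,
    config: PipelineConfig,
    out_checkpoint: str | Path,
    log_tsv: str | Path | None = None,
):
    """Train the configured regime and persist encoder heads and λ."""
    entities = {e.entity_id: e for e in kbio.read_kb_jsonl(kb_path)}
    docs = kbio.read_corpus(corpus_path)
    candidates = rt.read_candidates_tsv(candidates_tsv)
    menc, eenc = toy_dual_encoder(config.d, config.seed, ctx_weight=config.ctx_weight)
    result = train(docs, entities, candidates, menc, eenc, config.training)
    save_checkpoint(out_checkpoint, result, config)
    if log_tsv is not None:
        with open(log_tsv, "w", encoding="utf-8") as fh:
            fh.write("epoch\tmean_loss\tlambda\tloss_evaluations\tskipped_clusters\n")
            for epoch, h in enumerate(result.history, start=1):
                fh.write(
                    f"{epoch}\t{h.mean_loss:.6f}\t{h.lam:.6f}\t"
                    f"{h.loss_evaluations}\t{h.skipped_clusters}\n"
                )
    return result


def link_stage(
    kb_path: str | Path,
    corpus_path: str | Path,
    candidates_tsv: str | Path,
    checkpoint_path: str | Path,
    out_predictions: str | Path,
) -> list[ev.LinkingResult]:
    """Re-rank candidates with the trained encoders; write predictions TSV."""
    entities = {e.entity_id: e for e in kbio.read_kb_jsonl(kb_path)}
    docs = kbio.read_corpus(corpus_path)
    candidates = rt.read_candidates_tsv(candidates_tsv)
    menc, eenc, obj = load_checkpoint(checkpoint_path)
    max_len = obj["training"].get("max_len", 128)
    results = ev.link_corpus(
        _corpus_mentions(docs), candidates, menc, entities, eenc, max_len=max_len
    )
    ev.write_predictions_tsv(results, out_predictions)
    return results


def evaluate_stage(
    predictions_tsv: str | Path,
    train_corpus_path: str | Path,
    out_metrics: str | Path,
) -> dict:
    """Compute Acc@1 plus the seen/unseen breakdown from a predictions file."""
    train_docs = kbio.read_corpus(train_corpus_path)
    train_ids = {m.gold_entity_id for d in train_docs for m in d.mentions}
    rows = []
    with open(predictions_tsv, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            uid, gold, predicted, _dist, _rank = line.rstrip("\n").split("\t")
            rows.append((uid, gold, None if predicted == "-" else predicted))
    if not rows:
        raise ValueError("empty predictions file")
    correct = [gold == pred for _, gold, pred in rows]
    seen_flags = [gold in train_ids for _, gold, _ in rows]
    n_seen = sum(seen_flags)
    n_unseen = len(rows) - n_seen
    metrics = {
        "n_mentions": len(rows),
        "acc_at_1": sum(correct) / len(rows),
        "acc_seen": (
            sum(c for c, s in zip(correct, seen_flags) if s) / n_seen if n_seen else None
        ),
        "acc_unseen": (
            sum(c for c, s in zip(correct, seen_flags) if not s) / n_unseen
            if n_unseen
            else None
        ),
        "unlinkable_count": sum(1 for _, _, p in rows if p is None),
    }
    Path(out_metrics).write_text(json.dumps(metrics, sort_keys=True, indent=1))
    return metrics


def run_full_pipeline(config: PipelineConfig, work_dir: str | Path) -> dict:
    """simulate → retrieve → train → link → evaluate on the dev split."""
    work = Path(work_dir)
    paths = simulate(config, work)
    build_dict(paths["kb"], work)
    retrieve(paths["kb"], paths["train"], work / "candidates_train.tsv", k=config.k, config=config)
    retrieve(paths["kb"], paths["dev"], work / "candidates_dev.tsv", k=config.k, config=config)
    train_stage(
        paths["kb"], paths["train"], work / "candidates_train.tsv", config,
        work / "checkpoint.json", work / "training_log.tsv",
    )
    link_stage(
        paths["kb"], paths["dev"], work / "candidates_dev.tsv",
        work / "checkpoint.json", work / "predictions.tsv",
    )
    return evaluate_stage(work / "predictions.tsv", paths["train"], work / "metrics.json")
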