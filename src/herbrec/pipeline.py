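"""End-to-end pipeline: co-occurrence -> autoencoders -> adversarial
refinement -> embedding assembly -> recommender -> top-K evaluation.

Every stage is seeded from the one global seed, and the run manifest
(config, seed, artifact hashes, metrics) fully determines every numeric
output: rerunning a manifest reproduces the metrics bit-identically.

Ablations replace the learned symptom and/or herb embedding table with a
seeded random table of the same shape, which isolates the contribution of
cross-domain learning while leaving every other stage untouched.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import corpus as corpus_mod
from .corpus import (ClinicalRecord, build_cooccurrence, build_vocabularies,
                     export_cooccurrence, split_records)
from .cross_domain import (AutoencoderConfig, CPMConfig, EmbeddingTable,
                           assemble_embeddings, latent_features,
                           padded_profiles, train_autoencoder, train_cpm,
                           write_embeddings_tsv)
from .evaluation import TopKReport, topk_metrics, write_reports
from .recommender import (HerbRecommender, RecommenderConfig, recommend,
                          save_model, train_recommender)
from .synthetic import CorpusSpec, generate_corpus, paper_profile_spec

logger = logging.getLogger("herbrec")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """One flat config for all stages; defaults are the tuned values
    (embedding dimension 500, 7/5-layer branches, no dropout, weight decay
    1e-3, Adam 1e-3, patience 20)."""

    records_path: str | None = None       # JSONL; None -> simulate corpus_spec
    out_dir: str = "herbrec-run"
    seed: int = 0
    corpus_scale: float = 0.01            # used only when simulating
    train_fraction: float = 0.8
    embedding_dim: int = 500
    ae_alpha: float = 1e-3
    ae_epochs: int = 300
    cpm_mu: float = 1.0
    cpm_lam: float = 1e-4
    cpm_hidden: int = 64
    cpm_lr: float = 1e-2
    cpm_epochs: int = 400
    mlp_s_depth: int = 7
    mlp_h_depth: int = 5
    out_width: int = 128
    dropout: float = 0.0
    lam: float = 1e-3
    lr: float = 1e-3
    patience: int = 20
    rec_epochs: int = 200
    batch_size: int = 64
    k_list: tuple[int, ...] = (5, 10, 20)
    ablate_symptom_embedding: bool = False
    ablate_herb_embedding: bool = False

    def __post_init__(self):
        if not self.k_list:
            raise ValueError("k_list must be nonempty")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "k_list" in raw:
        raw["k_list"] = tuple(raw["k_list"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _random_table(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    return rng.uniform(0.0, 1.0, size=shape)


def _features_by_term(vectors, refined_src, refined_tgt):
    src, tgt = {}, {}
    i_s = i_t = 0
    for v in vectors:
        if v.domain == "source":
            src[v.entity] = refined_src[i_s]; i_s += 1
        else:
            tgt[v.entity] = refined_tgt[i_t]; i_t += 1
    return src, tgt


def learn_embeddings(
    records: Sequence[ClinicalRecord], config: PipelineConfig,
) -> EmbeddingTable:
    """The cross-domain half of the pipeline: per-domain co-occurrence,
    one autoencoder per entity kind, adversarial refinement, union assembly."""
    symptom_vocab, herb_vocab = build_vocabularies(records)
    cooc_s = build_cooccurrence(records, symptom_vocab, herb_vocab, "source")
    cooc_t = build_cooccurrence(records, symptom_vocab, herb_vocab, "target")
    tables = {}
    for kind, union_terms in (("symptom", symptom_vocab.terms), ("herb", herb_vocab.terms)):
        t0 = time.perf_counter()
        vectors = padded_profiles(cooc_s, cooc_t, kind)
        ae_cfg = AutoencoderConfig(latent_dim=config.embedding_dim, alpha=config.ae_alpha,
                                   lr=config.lr, max_epochs=config.ae_epochs,
                                   patience=config.patience, seed=config.seed)
        params = train_autoencoder(vectors, ae_cfg)
        Y = np.stack([v.values for v in vectors])
        feats = latent_features(Y, params)
        is_src = np.array([v.domain == "source" for v in vectors])
        targets_src, targets_tgt = Y[is_src], Y[~is_src]
        cpm_cfg = CPMConfig(mu=config.cpm_mu, lam=config.cpm_lam, hidden=config.cpm_hidden,
                            lr=config.cpm_lr, max_epochs=config.cpm_epochs,
                            patience=config.patience, seed=config.seed + 1)
        ref_src, ref_tgt, _ = train_cpm(feats[is_src], feats[~is_src], cpm_cfg,
                                        source_targets=targets_src, target_targets=targets_tgt)
        src_map, tgt_map = _features_by_term(vectors, ref_src, ref_tgt)
        matrix, provenance = assemble_embeddings(src_map, tgt_map, union_terms)
        tables[kind] = (list(union_terms), matrix, provenance)
        logger.info("embeddings[%s]: %d terms, %.1fs", kind, len(union_terms),
                    time.perf_counter() - t0)
    (s_terms, E_s, s_prov), (h_terms, E_h, h_prov) = tables["symptom"], tables["herb"]
    return EmbeddingTable(s_terms, E_s, h_terms, E_h, s_prov, h_prov)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all artifacts under ``config.out_dir`` and
    return {"reports": per-domain TopKReports, "manifest": manifest dict}."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    # stage: input records
    if config.records_path is not None:
        records = corpus_mod.read_records_jsonl(config.records_path)
        stage_note = f"loaded {len(records)} records from {config.records_path}"
    else:
        spec = paper_profile_spec(scale=config.corpus_scale, seed=config.seed)
        records = generate_corpus(spec)
        stage_note = f"simulated {len(records)} records at scale {config.corpus_scale}"
    logger.info("records: %s", stage_note)
    if not records:
        raise RuntimeError("stage records: empty corpus")

    # stage: per-domain 8:2 split
    train, test = [], []
    for domain in ("source", "target"):
        dom_records = [r for r in records if r.domain == domain]
        if dom_records:
            tr, te = split_records(dom_records, config.train_fraction, config.seed)
            train.extend(tr); test.extend(te)
    if not train or not test:
        raise RuntimeError("stage split: a partition is empty")

    # stage: co-occurrence export (on training records)
    symptom_vocab, herb_vocab = build_vocabularies(records)
    artifacts: dict[str, Path] = {}
    for domain in ("source", "target"):
        cooc = build_cooccurrence(train, symptom_vocab, herb_vocab, domain)
        paths = export_cooccurrence(cooc, out, stem=f"cooccurrence-{domain}")
        artifacts.update({f"cooccurrence-{domain}-{k}": v for k, v in paths.items()})

    # stage: cross-domain embeddings (ablations swap in seeded random tables)
    table = learn_embeddings(train, config)
    rng = np.random.default_rng(config.seed + 7)
    if config.ablate_symptom_embedding:
        table = EmbeddingTable(table.symptom_terms, _random_table(rng, table.E_s.shape),
                               table.herb_terms, table.E_h,
                               ["random"] * len(table.symptom_terms), table.herb_provenance)
    if config.ablate_herb_embedding:
        table = EmbeddingTable(table.symptom_terms, table.E_s, table.herb_terms,
                               _random_table(rng, table.E_h.shape),
                               table.symptom_provenance, ["random"] * len(table.herb_terms))
    emb_s = out / "embeddings-symptoms.tsv"
    emb_h = out / "embeddings-herbs.tsv"
    write_embeddings_tsv(table.symptom_terms, table.E_s, emb_s)
    write_embeddings_tsv(table.herb_terms, table.E_h, emb_h)
    artifacts["embeddings-symptoms"] = emb_s
    artifacts["embeddings-herbs"] = emb_h

    # stage: recommender training
    rec_cfg = RecommenderConfig(
        d=table.d, mlp_s_depth=config.mlp_s_depth, mlp_h_depth=config.mlp_h_depth,
        out_width=config.out_width, dropout=config.dropout, lam=config.lam,
        lr=config.lr, max_epochs=config.rec_epochs, patience=config.patience,
        batch_size=config.batch_size, seed=config.seed + 13,
    )
    model = train_recommender(train, table, rec_cfg)
    ckpt = out / "model.json"
    save_model(model, ckpt)
    artifacts["model"] = ckpt

    # stage: evaluation per domain
    reports: dict[str, list[TopKReport]] = {}
    for domain in ("source", "target"):
        dom_test = [r for r in test if r.domain == domain]
        if not dom_test:
            continue
        preds_by_k = {k: [] for k in config.k_list}
        truths = [list(r.herbs) for r in dom_test]
        for rec in dom_test:
            try:
                ranked_herbs = recommend(model, rec.symptoms, max(config.k_list)).ranked_herbs
            except ValueError:
                # no symptom of this test record was seen in training
                ranked_herbs = []
            for k in config.k_list:
                preds_by_k[k].append(ranked_herbs[:k])
        reps = [topk_metrics(preds_by_k[k], truths, k) for k in config.k_list]
        reports[domain] = reps
        paths = write_reports(reps, out, model_name=f"herbrec-{domain}", stem=f"topk-{domain}")
        artifacts.update({f"topk-{domain}-{k}": v for k, v in paths.items()})

    # stage: manifest
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "n_records": len(records),
        "n_train": len(train),
        "n_test": len(test),
        "artifacts": {k: _sha256(p) for k, p in artifacts.items()},
        "metrics": {dom: [asdict(r) for r in reps] for dom, reps in reports.items()},
        "runtime_seconds": time.perf_counter() - t_start,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    logger.info("pipeline finished in %.1fs", manifest["runtime_seconds"])
    return {"reports": reports, "manifest": manifest, "model": model, "table": table}
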