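"""End-to-end experiment driver.

Runs the full workflow on a synthetic bundle (or user-supplied files):
vocabulary → skip-gram training → TF-IDF baseline → pair labeling →
cross-validated AUROC for both feature sources → cosine enrichment of
the interaction records → per-class accuracy table.  Every output file
is a deterministic function of the configuration and the global seed:
floating-point formatting is fixed and the run log carries no
timestamps, so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from . import cm_tfidf, corpus_io, enrichment, eval_classify, msg_trainer
from .corpus_io import EventClass, LabelResources, ReportCorpus, write_embeddings
from .eval_classify import CVResult, LabeledPairSet
from .msg_trainer import TrainParams
from .synthetic_data import Bundle, GenParams, generate, write_bundle

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a run needs; one global seed determines all randomness."""

    gen: GenParams = field(default_factory=GenParams)
    train: TrainParams = field(default_factory=TrainParams)
    pca_dim: int = 100
    folds: int = 10
    balance: bool = True
    l2_C: float = 1.0
    top_k: int = 20
    seed: int = 1
    skip_tfidf: bool = False
    # optional external inputs; when reports_path is set the generator is skipped
    reports_path: Optional[str] = None
    sider_path: Optional[str] = None
    toxicity_path: Optional[str] = None
    ddi_path: Optional[str] = None
    soc_path: Optional[str] = None
    classes_path: Optional[str] = None

    def resolved(self) -> "ExperimentConfig":
        """Propagate the global seed into the nested parameter blocks."""
        return dataclasses.replace(
            self,
            gen=dataclasses.replace(self.gen, seed=self.seed),
            train=dataclasses.replace(self.train, seed=self.seed + 1),
        )


# flat key=value config surface; unknown keys are rejected on load
_FLAT_KEYS: Dict[str, Tuple[str, type]] = {
    "dim": ("train.dim", int),
    "alpha": ("train.alpha0", float),
    "min_alpha": ("train.min_alpha", float),
    "epochs": ("train.epochs", int),
    "min_count": ("train.min_count", int),
    "n_classes": ("gen.n_classes", int),
    "drugs_per_class": ("gen.drugs_per_class", int),
    "background_drugs": ("gen.background_drugs", int),
    "reactions_per_class": ("gen.reactions_per_class", int),
    "background_reactions": ("gen.background_reactions", int),
    "n_reports": ("gen.n_reports", int),
    "signal": ("gen.signal", float),
    "noise_rate": ("gen.noise_rate", float),
    "background_report_rate": ("gen.background_report_rate", float),
    "ddis_per_class": ("gen.ddis_per_class", int),
    "background_ddis": ("gen.background_ddis", int),
    "toxicity_fraction": ("gen.toxicity_fraction", float),
    "pca_dim": ("pca_dim", int),
    "folds": ("folds", int),
    "balance": ("balance", lambda s: s in ("1", "true", "True", "yes")),
    "l2_C": ("l2_C", float),
    "top_k": ("top_k", int),
    "seed": ("seed", int),
    "skip_tfidf": ("skip_tfidf", lambda s: s in ("1", "true", "True", "yes")),
    "reports_path": ("reports_path", str),
    "sider_path": ("sider_path", str),
    "toxicity_path": ("toxicity_path", str),
    "ddi_path": ("ddi_path", str),
    "soc_path": ("soc_path", str),
    "classes_path": ("classes_path", str),
}


def load_config(path: str, overrides: Optional[Mapping[str, str]] = None) -> ExperimentConfig:
    """Parse a flat ``key = value`` config file; unknown keys are errors."""
    raw: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise corpus_io.ParseError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            raw[key] = val
    if overrides:
        raw.update(overrides)
    return config_from_flat(raw)


def config_from_flat(raw: Mapping[str, str]) -> ExperimentConfig:
    unknown = set(raw) - set(_FLAT_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    gen_kwargs: Dict[str, object] = {}
    train_kwargs: Dict[str, object] = {}
    top_kwargs: Dict[str, object] = {}
    for key, sval in raw.items():
        dest, conv = _FLAT_KEYS[key]
        val = conv(sval)
        if dest.startswith("gen."):
            gen_kwargs[dest[4:]] = val
        elif dest.startswith("train."):
            train_kwargs[dest[6:]] = val
        else:
            top_kwargs[dest] = val
    return ExperimentConfig(
        gen=GenParams(**gen_kwargs), train=TrainParams(**train_kwargs), **top_kwargs
    )


def dump_config(config: ExperimentConfig, path: str) -> None:
    inv: Dict[str, str] = {}
    for key, (dest, _) in _FLAT_KEYS.items():
        obj: object = config
        for part in dest.split("."):
            obj = getattr(obj, part)
        if obj is None:
            continue
        inv[key] = str(obj)
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(inv):
            fh.write(f"{key} = {inv[key]}\n")


@dataclass
class PipelineResult:
    """In-memory results of a run, mirroring the files on disk."""

    bundle: Optional[Bundle]
    corpus: ReportCorpus
    resources: LabelResources
    event_classes: List[EventClass]
    msg_vectors: Dict[str, np.ndarray]
    tfidf_vectors: Optional[Dict[str, np.ndarray]]
    cv_results: Dict[Tuple[str, str], CVResult]  # (class, source) -> result
    labelsets: Dict[str, LabeledPairSet]
    enrichments: Dict[str, List[enrichment.EnrichmentResult]]
    accuracy: enrichment.AccuracyTable
    out_dir: str


def _load_inputs(config: ExperimentConfig):
    if config.reports_path is None:
        bundle = generate(config.gen)
        return bundle, bundle.corpus, bundle.resources, bundle.event_classes
    corpus = corpus_io.read_reports(config.reports_path)
    resources = corpus_io.read_label_resources(
        config.sider_path, config.toxicity_path, config.ddi_path, config.soc_path
    )
    if config.classes_path is None:
        raise ValueError("classes_path is required when reports_path is given")
    classes = corpus_io.read_event_classes(config.classes_path)
    return None, corpus, resources, classes


def run_pipeline(config: ExperimentConfig, out_dir: str) -> PipelineResult:
    """Execute the full workflow and write all artifacts under ``out_dir``."""
    config = config.resolved()
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("msgddi")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: ExperimentConfig, out_dir: str) -> PipelineResult:
    dump_config(config, os.path.join(out_dir, "config_resolved.txt"))

    stage = "generate/load inputs"
    try:
        bundle, corpus, resources, event_classes = _load_inputs(config)
        if bundle is not None:
            write_bundle(bundle, os.path.join(out_dir, "bundle"))
        logger.info("corpus: %d reports", len(corpus))

        stage = "train MSG"
        model = msg_trainer.train(corpus, config.train)
        msg_vectors = model.embeddings()
        write_embeddings(msg_vectors, os.path.join(out_dir, "msg_embeddings.txt"))
        logger.info("MSG: %d tokens, dim %d", len(model.vocab), config.train.dim)

        stage = "build CM-TF-IDF"
        tfidf_vectors: Optional[Dict[str, np.ndarray]] = None
        if not config.skip_tfidf:
            matrix = cm_tfidf.build_matrix(corpus, model.vocab)
            k = min(config.pca_dim, len(matrix.terms), matrix.n_reports)
            reduced = cm_tfidf.reduce_pca(matrix, k)
            tfidf_vectors = reduced.vectors
            write_embeddings(tfidf_vectors, os.path.join(out_dir, "tfidf_features.txt"))
            logger.info("CM-TF-IDF: %d terms reduced to k=%d", len(matrix.terms), k)

        stage = "label pairs"
        vocab_drugs = set(model.vocab.drugs)
        ddi_drugs = {d for rec in resources.ddi_records for d in rec.pair}
        rdl = vocab_drugs & ddi_drugs if ddi_drugs else vocab_drugs
        pairs = eval_classify.candidate_pairs(corpus, rdl)
        logger.info("candidate pairs: %d (RDL size %d)", len(pairs), len(rdl))

        labelsets: Dict[str, LabeledPairSet] = {}
        cv_results: Dict[Tuple[str, str], CVResult] = {}
        sources: List[Tuple[str, Dict[str, np.ndarray]]] = [("MSG", msg_vectors)]
        if tfidf_vectors is not None:
            sources.append(("CM-TF-IDF", tfidf_vectors))

        stage = "cross-validate"
        for ec in event_classes:
            labelset = eval_classify.label_pairs(pairs, resources, ec)
            if config.balance:
                labelset = eval_classify.balance_negatives(labelset, seed=config.seed + 2)
            labelsets[ec.name] = labelset
            logger.info(
                "class %s: %d positives / %d negatives",
                ec.name,
                labelset.n_positive,
                labelset.n_negative,
            )
            for src_name, vectors in sources:
                feats = {
                    p: eval_classify.pair_features(vectors, p) for p in labelset.pairs
                }
                cv = eval_classify.crossval_auroc(
                    feats,
                    labelset,
                    n_folds=config.folds,
                    seed=config.seed + 3,
                    C=config.l2_C,
                )
                cv_results[(ec.name, src_name)] = cv
                logger.info(
                    "class %s / %s: mean AUROC %.4f", ec.name, src_name, cv.mean_auroc
                )
        _write_cv(cv_results, out_dir)

        stage = "enrichment"
        candidate_reactions = model.vocab.reactions
        # drugs: input vectors; reactions: target-side (path) embeddings —
        # the representation the trained model scores reactions with
        enrich_vectors = model.enrichment_vectors()
        write_embeddings(enrich_vectors, os.path.join(out_dir, "enrichment_vectors.txt"))
        enrichments: Dict[str, List[enrichment.EnrichmentResult]] = {}
        for ec in event_classes:
            results = []
            for rec in resources.ddi_records:
                if not any(kw in rec.description.lower() for kw in ec.keywords):
                    continue
                a, b = rec.pair
                if a not in enrich_vectors or b not in enrich_vectors:
                    continue
                results.append(
                    enrichment.enrich_pair(
                        enrich_vectors,
                        (a, b),
                        candidate_reactions,
                        resources.soc_map,
                        ec,
                        k=config.top_k,
                    )
                )
            enrichments[ec.name] = results
        table = enrichment.accuracy_table(enrichments)
        _write_enrichment(enrichments, table, out_dir)
        logger.info("pooled enrichment accuracy: %.6f", table.total_accuracy)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return PipelineResult(
        bundle=bundle,
        corpus=corpus,
        resources=resources,
        event_classes=event_classes,
        msg_vectors=msg_vectors,
        tfidf_vectors=tfidf_vectors,
        cv_results=cv_results,
        labelsets=labelsets,
        enrichments=enrichments,
        accuracy=table,
        out_dir=out_dir,
    )


def _write_cv(cv_results: Mapping[Tuple[str, str], CVResult], out_dir: str) -> None:
    with open(os.path.join(out_dir, "cv_results.tsv"), "w", encoding="utf-8") as fh:
        fh.write("class\tsource\tfold\tauroc\n")
        for (cls, src), cv in cv_results.items():
            for i, auc in enumerate(cv.auroc_per_fold, start=1):
                fh.write(f"{cls}\t{src}\t{i}\t{auc:.6f}\n")
            fh.write(f"{cls}\t{src}\tmean\t{cv.mean_auroc:.6f}\n")
    with open(os.path.join(out_dir, "roc_points.tsv"), "w", encoding="utf-8") as fh:
        fh.write("class\tsource\tfpr\ttpr\n")
        for (cls, src), cv in cv_results.items():
            for fpr, tpr in cv.roc_points:
                fh.write(f"{cls}\t{src}\t{fpr:.6f}\t{tpr:.6f}\n")


def _write_enrichment(
    enrichments: Mapping[str, List[enrichment.EnrichmentResult]],
    table: enrichment.AccuracyTable,
    out_dir: str,
) -> None:
    with open(os.path.join(out_dir, "enrichment.tsv"), "w", encoding="utf-8") as fh:
        fh.write("class\tdrug_a\tdrug_b\trank\treaction\tcosine\tvalid\n")
        for cls, results in enrichments.items():
            for res in results:
                for rank, (reaction, cos) in enumerate(res.ranked, start=1):
                    fh.write(
                        f"{cls}\t{res.pair[0]}\t{res.pair[1]}\t{rank}\t"
                        f"{reaction}\t{cos:.6f}\t{int(res.valid)}\n"
                    )
    with open(os.path.join(out_dir, "accuracy_table.tsv"), "w", encoding="utf-8") as fh:
        fh.write(table.format_tsv())
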