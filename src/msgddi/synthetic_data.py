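"""Synthetic adverse-event bundle with planted class structure.

The generator emulates the statistical shape of a preprocessed
spontaneous-report corpus: a handful of adverse-event classes, each
owning a pool of drugs and a pool of reactions that co-occur within
reports, diluted by background drugs/reactions and sampling noise.  It
emits every input file the pipeline consumes — report corpus, DDI
records, toxicity records, per-class drug lists, reaction-to-SOC map
and event-class definitions — in the exact formats of
:mod:`msgddi.corpus_io`, plus the ground truth behind them, so the full
pipeline is testable end to end without any external data.

Each report lists exactly two drugs (mirroring the two-drug filter
applied to real report corpora); a flag allows variable drug counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .corpus_io import (
    DDIRecord,
    EventClass,
    LabelResources,
    Report,
    ReportCorpus,
    write_ddi_records,
    write_drug_lists,
    write_event_classes,
    write_reports,
    write_soc_map,
    write_toxicity_records,
)

__all__ = ["GenParams", "GroundTruth", "Bundle", "generate", "write_bundle", "summarize"]

BACKGROUND_SOC = "Background disorders"


@dataclass(frozen=True)
class GenParams:
    """Knobs of the planted-structure generator.

    ``signal`` is the probability that each drug slot of a class report
    is filled from the class's own drug pool (otherwise a background
    drug); ``noise_rate`` is the per-reaction probability that a class
    reaction is replaced by a background one.
    ``background_report_rate`` is the fraction of reports with no class
    affiliation at all.
    """

    n_classes: int = 5
    drugs_per_class: int = 40
    background_drugs: int = 60
    reactions_per_class: int = 30
    background_reactions: int = 100
    n_reports: int = 2000
    signal: float = 0.8
    reactions_per_report: Tuple[int, int] = (2, 6)
    noise_rate: float = 0.1
    background_report_rate: float = 0.2
    ddis_per_class: int = 40
    background_ddis: int = 40
    toxicity_fraction: float = 0.5
    drugs_per_report: Tuple[int, int] = (2, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_classes",
            "drugs_per_class",
            "background_drugs",
            "reactions_per_class",
            "background_reactions",
            "n_reports",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("signal", "noise_rate", "background_report_rate", "toxicity_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.reactions_per_report
        if not (1 <= lo <= hi):
            raise ValueError("reactions_per_report must satisfy 1 <= lo <= hi")
        if hi > min(self.reactions_per_class, self.background_reactions):
            raise ValueError(
                "reactions_per_report upper bound exceeds a reaction pool size"
            )
        dlo, dhi = self.drugs_per_report
        if not (2 <= dlo <= dhi):
            raise ValueError("drugs_per_report must satisfy 2 <= lo <= hi")
        if dhi > min(self.drugs_per_class, self.background_drugs):
            raise ValueError("drugs_per_report upper bound exceeds a drug pool size")
        if self.drugs_per_class < 2:
            raise ValueError("need >= 2 drugs per class to form interacting pairs")
        max_pairs = self.drugs_per_class * (self.drugs_per_class - 1) // 2
        if self.ddis_per_class > max_pairs:
            raise ValueError(
                f"ddis_per_class={self.ddis_per_class} exceeds the "
                f"{max_pairs} distinct class-drug pairs"
            )
        max_bg_pairs = self.background_drugs * (self.background_drugs - 1) // 2
        if self.background_ddis > max_bg_pairs:
            raise ValueError(
                f"background_ddis={self.background_ddis} exceeds the "
                f"{max_bg_pairs} distinct background-drug pairs"
            )


@dataclass
class GroundTruth:
    """Planted assignments behind every emitted resource file."""

    drug_class: Dict[str, int]  # drug -> class index, -1 for background
    reaction_class: Dict[str, int]
    interacting_pairs: Dict[int, List[Tuple[str, str]]]  # class -> canonical pairs
    report_class: List[int] = field(default_factory=list)  # per report, -1 background


@dataclass
class Bundle:
    corpus: ReportCorpus
    resources: LabelResources
    event_classes: List[EventClass]
    truth: GroundTruth
    params: GenParams


def _class_name(c: int) -> str:
    return f"class{c}"


def _soc_label(c: int) -> str:
    return f"Class {c} disorders"


def _keyword(c: int) -> str:
    return f"class{c}tox"


def generate(params: GenParams) -> Bundle:
    """Draw a full input bundle, reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    P = params

    drug_pools = [
        [str(100_000 + c * 1000 + i) for i in range(P.drugs_per_class)]
        for c in range(P.n_classes)
    ]
    bg_drugs = [str(100_000 + P.n_classes * 1000 + i) for i in range(P.background_drugs)]
    reaction_pools = [
        [str(900_000 + c * 1000 + i) for i in range(P.reactions_per_class)]
        for c in range(P.n_classes)
    ]
    bg_reactions = [
        str(900_000 + P.n_classes * 1000 + i) for i in range(P.background_reactions)
    ]

    drug_class = {d: c for c, pool in enumerate(drug_pools) for d in pool}
    drug_class.update({d: -1 for d in bg_drugs})
    reaction_class = {r: c for c, pool in enumerate(reaction_pools) for r in pool}
    reaction_class.update({r: -1 for r in bg_reactions})

    def sample_drugs(c: int) -> List[str]:
        dlo, dhi = P.drugs_per_report
        n_drugs = int(rng.integers(dlo, dhi + 1))
        chosen: List[str] = []
        while len(chosen) < n_drugs:
            if c >= 0 and rng.random() < P.signal:
                pool = drug_pools[c]
            else:
                pool = bg_drugs
            d = pool[int(rng.integers(len(pool)))]
            if d not in chosen:
                chosen.append(d)
        return chosen

    def sample_reactions(c: int) -> List[str]:
        lo, hi = P.reactions_per_report
        m = int(rng.integers(lo, hi + 1))
        pool = reaction_pools[c] if c >= 0 else bg_reactions
        picked = [pool[i] for i in rng.choice(len(pool), size=m, replace=False)]
        if c >= 0 and P.noise_rate > 0:
            picked = [
                bg_reactions[int(rng.integers(len(bg_reactions)))]
                if rng.random() < P.noise_rate
                else r
                for r in picked
            ]
        return list(dict.fromkeys(picked))

    reports: List[Report] = []
    report_class: List[int] = []
    for _ in range(P.n_reports):
        c = -1 if rng.random() < P.background_report_rate else int(
            rng.integers(P.n_classes)
        )
        reports.append(Report(tuple(sample_drugs(c)), tuple(sample_reactions(c))))
        report_class.append(c)
    corpus = ReportCorpus(tuple(reports), source_path="<synthetic>")

    # --- label resources --------------------------------------------------
    sider_lists = {_class_name(c): frozenset(drug_pools[c]) for c in range(P.n_classes)}

    toxicity: List[Tuple[str, str]] = []
    for c in range(P.n_classes):
        n_tox = int(round(P.toxicity_fraction * P.drugs_per_class))
        idx = rng.choice(P.drugs_per_class, size=n_tox, replace=False)
        for i in sorted(idx):
            toxicity.append(
                (drug_pools[c][i], f"chronic exposure may cause {_keyword(c)} effects")
            )

    ddi_records: List[DDIRecord] = []
    interacting: Dict[int, List[Tuple[str, str]]] = {c: [] for c in range(P.n_classes)}
    for c in range(P.n_classes):
        pairs_seen: Dict[Tuple[str, str], None] = {}
        while len(pairs_seen) < P.ddis_per_class:
            i, j = rng.choice(P.drugs_per_class, size=2, replace=False)
            a, b = sorted((drug_pools[c][int(i)], drug_pools[c][int(j)]))
            pairs_seen.setdefault((a, b))
        for a, b in pairs_seen:
            interacting[c].append((a, b))
            ddi_records.append(
                DDIRecord(a, b, f"coadministration increases the risk of {_keyword(c)}")
            )
    bg_pairs: Dict[Tuple[str, str], None] = {}
    while len(bg_pairs) < P.background_ddis:
        i, j = rng.choice(P.background_drugs, size=2, replace=False)
        a, b = sorted((bg_drugs[int(i)], bg_drugs[int(j)]))
        bg_pairs.setdefault((a, b))
    for a, b in bg_pairs:
        ddi_records.append(DDIRecord(a, b, "no class-specific interaction noted"))

    soc_map = {r: _soc_label(c) for c, pool in enumerate(reaction_pools) for r in pool}
    soc_map.update({r: BACKGROUND_SOC for r in bg_reactions})

    event_classes = [
        EventClass(_class_name(c), (_keyword(c),), _soc_label(c))
        for c in range(P.n_classes)
    ]
    resources = LabelResources(
        sider_lists=sider_lists,
        toxicity_records=toxicity,
        ddi_records=ddi_records,
        soc_map=soc_map,
    )
    truth = GroundTruth(
        drug_class=drug_class,
        reaction_class=reaction_class,
        interacting_pairs=interacting,
        report_class=report_class,
    )
    return Bundle(corpus, resources, event_classes, truth, params)


def write_bundle(bundle: Bundle, out_dir: str) -> Dict[str, str]:
    """Write every bundle file in the standard formats; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "reports": os.path.join(out_dir, "reports.txt"),
        "ddi": os.path.join(out_dir, "ddi.tsv"),
        "toxicity": os.path.join(out_dir, "toxicity.tsv"),
        "sider": os.path.join(out_dir, "drug_lists.tsv"),
        "soc": os.path.join(out_dir, "soc_map.tsv"),
        "classes": os.path.join(out_dir, "event_classes.tsv"),
    }
    write_reports(bundle.corpus, paths["reports"])
    write_ddi_records(bundle.resources.ddi_records, paths["ddi"])
    write_toxicity_records(bundle.resources.toxicity_records, paths["toxicity"])
    write_drug_lists(bundle.resources.sider_lists, paths["sider"])
    write_soc_map(bundle.resources.soc_map, paths["soc"])
    write_event_classes(bundle.event_classes, paths["classes"])
    return paths


def summarize(bundle: Bundle) -> Dict[str, Dict[str, int]]:
    """Per-class positive-source counts (drug-list / toxicity / DDI layout).

    SIDER and Toxicity columns count drugs; the DDI column counts
    keyword-bearing interaction records, mirroring the usual reference
    tabulation of positive samples per source.
    """
    out: Dict[str, Dict[str, int]] = {}
    for ec in bundle.event_classes:
        tox = sum(
            1
            for _, text in bundle.resources.toxicity_records
            if any(kw in text.lower() for kw in ec.keywords)
        )
        ddi = sum(
            1
            for rec in bundle.resources.ddi_records
            if any(kw in rec.description.lower() for kw in ec.keywords)
        )
        out[ec.name] = {
            "SIDER": len(bundle.resources.sider_lists.get(ec.name, frozenset())),
            "Toxicity": tox,
            "DDI": ddi,
        }
    return out
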