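"""Readers and writers for every external file the pipeline touches.

The central artifact is the report corpus: one adverse-event report per
line, drug concept IDs left of a single ``|`` separator and reaction
concept IDs to its right, whitespace-delimited.  Concept IDs are opaque
token strings (typically numeric) and are matched exactly — no case
folding.  The remaining formats are small tab-separated tables: DDI
records, toxicity records, per-class drug lists, a reaction-to-SOC map
and event-class definitions.  Embeddings round-trip through a plain-text
format with a ``<n_tokens> <dim>`` header.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "Report",
    "ReportCorpus",
    "DDIRecord",
    "EventClass",
    "LabelResources",
    "read_reports",
    "write_reports",
    "read_ddi_records",
    "write_ddi_records",
    "read_toxicity_records",
    "write_toxicity_records",
    "read_drug_lists",
    "write_drug_lists",
    "read_soc_map",
    "write_soc_map",
    "read_event_classes",
    "write_event_classes",
    "read_label_resources",
    "write_embeddings",
    "read_embeddings",
]

#: decimal places used when serialising embedding coordinates
EMBEDDING_PRECISION = 6


class ParseError(ValueError):
    """Malformed input file; message carries file name and line number."""


def _dedup(tokens: Iterable[str]) -> Tuple[str, ...]:
    """Collapse duplicates preserving first-appearance order."""
    return tuple(dict.fromkeys(tokens))


@dataclass(frozen=True)
class Report:
    """One adverse-event record: the set of drugs and the set of reactions.

    Duplicate tokens within a side are collapsed (contexts are sets);
    the two sides must be disjoint.  A report may have an empty side, in
    which case it contributes no training pairs.
    """

    drugs: Tuple[str, ...]
    reactions: Tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", _dedup(self.drugs))
        object.__setattr__(self, "reactions", _dedup(self.reactions))
        overlap = set(self.drugs) & set(self.reactions)
        if overlap:
            raise ValueError(
                f"tokens listed as both drug and reaction: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class ReportCorpus:
    """An ordered sequence of reports, the training corpus D."""

    reports: Tuple[Report, ...]
    source_path: str = "<memory>"

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self.reports)

    def __getitem__(self, i: int) -> Report:
        return self.reports[i]


@dataclass(frozen=True)
class DDIRecord:
    """A known drug-drug interaction with its free-text description."""

    drug_a: str
    drug_b: str
    description: str

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError(f"self-interaction pair {self.drug_a!r}")

    @property
    def pair(self) -> Tuple[str, str]:
        """Canonical (sorted) form — DDI pairs are unordered."""
        return tuple(sorted((self.drug_a, self.drug_b)))  # type: ignore[return-value]

    @property
    def dedup_key(self) -> Tuple[Tuple[str, str], str]:
        return (self.pair, self.description.casefold())


@dataclass(frozen=True)
class EventClass:
    """An adverse-event class: a name, trigger keywords and the SOC gold label.

    ``soc_label`` is the MedDRA System Organ Class used as gold standard
    when validating enrichment (e.g. "Cardiac disorders" for
    cardiotoxicity).
    """

    name: str
    keywords: Tuple[str, ...]
    soc_label: str

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"event class {self.name!r} has no keywords")
        object.__setattr__(
            self, "keywords", tuple(k.lower() for k in self.keywords)
        )


@dataclass
class LabelResources:
    """The three positive-label sources plus the SOC map.

    ``soc_map`` may be partial: reactions missing from it simply never
    match a SOC label (they are not an error).
    """

    sider_lists: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    toxicity_records: List[Tuple[str, str]] = field(default_factory=list)
    ddi_records: List[DDIRecord] = field(default_factory=list)
    soc_map: Dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# report corpus
# ---------------------------------------------------------------------------

def read_reports(path: str | os.PathLike[str]) -> ReportCorpus:
    """Parse a pipe-delimited report corpus.

    Each non-blank line holds exactly one ``|``; drug IDs on the left,
    reaction IDs on the right, whitespace-separated.  Blank lines are
    skipped; an empty file yields an empty corpus.
    """
    reports: List[Report] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.count("|") != 1:
                raise ParseError(
                    f"{path}:{lineno}: expected exactly one '|' separator, "
                    f"found {line.count('|')}"
                )
            left, right = line.split("|")
            try:
                reports.append(Report(tuple(left.split()), tuple(right.split())))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return ReportCorpus(tuple(reports), source_path=str(path))


def write_reports(corpus: ReportCorpus, path: str | os.PathLike[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rep in corpus:
            fh.write(" ".join(rep.drugs) + " | " + " ".join(rep.reactions) + "\n")


# ---------------------------------------------------------------------------
# DDI records
# ---------------------------------------------------------------------------

def read_ddi_records(path: str | os.PathLike[str]) -> List[DDIRecord]:
    """Read TSV DDI records and deduplicate mirrored pairs.

    Two records naming the same unordered pair with case-insensitively
    equal descriptions carry the same knowledge and are collapsed to
    one; records with distinct descriptions are both kept.
    """
    seen: Dict[Tuple[Tuple[str, str], str], DDIRecord] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            a, b, desc = parts[0].strip(), parts[1].strip(), parts[2]
            if a == b:
                raise ParseError(f"{path}:{lineno}: self-interaction pair {a!r}")
            rec = DDIRecord(a, b, desc)
            seen.setdefault(rec.dedup_key, rec)
    return list(seen.values())


def write_ddi_records(records: Sequence[DDIRecord], path: str | os.PathLike[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.drug_a}\t{rec.drug_b}\t{rec.description}\n")


# ---------------------------------------------------------------------------
# label resources
# ---------------------------------------------------------------------------

def _read_tsv(path: str | os.PathLike[str], n_fields: int):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < n_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_fields} tab-separated fields, "
                    f"got {len(parts)}"
                )
            yield lineno, parts


def read_toxicity_records(path: str | os.PathLike[str]) -> List[Tuple[str, str]]:
    """TSV ``drug<TAB>description`` → list of (drug, text)."""
    return [(p[0].strip(), p[1]) for _, p in _read_tsv(path, 2)]


def write_toxicity_records(
    records: Sequence[Tuple[str, str]], path: str | os.PathLike[str]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for drug, text in records:
            fh.write(f"{drug}\t{text}\n")


def read_drug_lists(path: str | os.PathLike[str]) -> Dict[str, FrozenSet[str]]:
    """TSV ``class_name<TAB>drug_id`` → class → drug set (SIDER-style)."""
    lists: Dict[str, set] = {}
    for _, parts in _read_tsv(path, 2):
        lists.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return {k: frozenset(v) for k, v in lists.items()}


def write_drug_lists(
    lists: Mapping[str, Iterable[str]], path: str | os.PathLike[str]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cls in lists:
            for drug in sorted(lists[cls]):
                fh.write(f"{cls}\t{drug}\n")


def read_soc_map(path: str | os.PathLike[str]) -> Dict[str, str]:
    """TSV ``reaction_id<TAB>soc_label`` → reaction → SOC label."""
    return {p[0].strip(): p[1].strip() for _, p in _read_tsv(path, 2)}


def write_soc_map(soc_map: Mapping[str, str], path: str | os.PathLike[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid in soc_map:
            fh.write(f"{rid}\t{soc_map[rid]}\n")


def read_event_classes(path: str | os.PathLike[str]) -> List[EventClass]:
    """TSV ``class_name<TAB>soc_label<TAB>kw1,kw2,…`` → event classes."""
    classes = []
    for lineno, parts in _read_tsv(path, 3):
        keywords = tuple(k.strip() for k in parts[2].split(",") if k.strip())
        if not keywords:
            raise ParseError(f"{path}:{lineno}: event class with empty keyword list")
        classes.append(EventClass(parts[0].strip(), keywords, parts[1].strip()))
    return classes


def write_event_classes(
    classes: Sequence[EventClass], path: str | os.PathLike[str]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ec in classes:
            fh.write(f"{ec.name}\t{ec.soc_label}\t{','.join(ec.keywords)}\n")


def read_label_resources(
    sider_path: str | os.PathLike[str] | None,
    toxicity_path: str | os.PathLike[str] | None,
    ddi_path: str | os.PathLike[str] | None,
    soc_path: str | os.PathLike[str] | None,
) -> LabelResources:
    """Load all labeling resources; a missing file yields an empty resource.

    Unknown tokens are retained — filtering against the corpus vocabulary
    happens downstream.
    """
    res = LabelResources()
    if sider_path is not None and os.path.exists(sider_path):
        res.sider_lists = read_drug_lists(sider_path)
    elif sider_path is not None:
        logger.warning("drug-list file %s not found; SIDER lists empty", sider_path)
    if toxicity_path is not None and os.path.exists(toxicity_path):
        res.toxicity_records = read_toxicity_records(toxicity_path)
    elif toxicity_path is not None:
        logger.warning("toxicity file %s not found; toxicity records empty", toxicity_path)
    if ddi_path is not None and os.path.exists(ddi_path):
        res.ddi_records = read_ddi_records(ddi_path)
    elif ddi_path is not None:
        logger.warning("DDI file %s not found; DDI records empty", ddi_path)
    if soc_path is not None and os.path.exists(soc_path):
        res.soc_map = read_soc_map(soc_path)
    elif soc_path is not None:
        logger.warning("SOC map %s not found; SOC map empty", soc_path)
    return res


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def write_embeddings(
    vectors: Mapping[str, np.ndarray], path: str | os.PathLike[str], dim: int | None = None
) -> None:
    """Write token vectors as text: header ``<n_tokens> <dim>``, then one
    ``<token> <v1> … <vdim>`` line per token, 6-decimal precision."""
    tokens = list(vectors)
    if dim is None:
        if not tokens:
            raise ValueError("cannot infer dimension from an empty vector map")
        dim = len(vectors[tokens[0]])
    fmt = f"%.{EMBEDDING_PRECISION}f"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(tokens)} {dim}\n")
        for tok in tokens:
            vec = np.asarray(vectors[tok], dtype=float)
            if vec.shape != (dim,):
                raise ValueError(
                    f"vector for {tok!r} has shape {vec.shape}, expected ({dim},)"
                )
            fh.write(tok + " " + " ".join(fmt % x for x in vec) + "\n")


def read_embeddings(path: str | os.PathLike[str]) -> Dict[str, np.ndarray]:
    """Read the text embedding format back into a token → vector map."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}:1: malformed header {header!r}")
        n_tokens, dim = int(header[0]), int(header[1])
        vectors: Dict[str, np.ndarray] = {}
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.split()
            if not parts:
                continue
            if len(parts) != dim + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {dim} coordinates, got {len(parts) - 1}"
                )
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(vectors) != n_tokens:
        raise ParseError(
            f"{path}: header promises {n_tokens} tokens, file holds {len(vectors)}"
        )
    return vectors
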