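"""Gene sentences: ranked top-k gene symbols as the text view of a profile.

An expression profile — a spot, a single cell, or a bulk sample — is turned
into a "sentence": its most highly expressed gene symbols, ranked from high
to low and joined by single spaces.  Sentences are the transcriptomic input
to the text encoder.  Ranking is invariant under any strictly monotone
per-profile transform, so building sentences from raw or normalized counts
gives identical text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .st_io import InputError, SpotMatrix

logger = logging.getLogger("loki")

__all__ = [
    "GeneSentence",
    "SentenceCorpus",
    "normalize_counts",
    "build_sentence",
    "build_corpus",
    "profile_to_sentence",
    "marker_sentence",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
]


@dataclass(frozen=True)
class GeneSentence:
    """An ordered list of gene symbols and its space-joined text form."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise InputError("sentence contains duplicate gene symbols")
        for g in self.genes:
            if not g or any(c.isspace() for c in g):
                raise InputError(f"invalid gene symbol in sentence: {g!r}")

    @property
    def text(self) -> str:
        return " ".join(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SentenceCorpus:
    """Per-profile sentences with optional paired image-patch references."""

    records: list[tuple[str, GeneSentence, str | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise InputError("corpus record ids are not unique")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    @property
    def sentences(self) -> list[GeneSentence]:
        return [r[1] for r in self.records]


def normalize_counts(m: SpotMatrix, target_sum: float = 1e4) -> SpotMatrix:
    """Library-size normalize to ``target_sum`` per spot, then log1p.

    Profiles whose ``meta["units"]`` marks them as TPM or FPKM are returned
    unchanged: those units cannot be re-normalized to count space.
    """
    if str(m.meta.get("units", "")).upper() in {"TPM", "FPKM"}:
        return m
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise InputError(
            "zero-count spot(s) present; run qc_filter_spots before normalizing"
        )
    x = sp.csc_matrix(m.counts, dtype=float)
    x = x.multiply(target_sum / totals[None, :])
    x = sp.csr_matrix(x)
    x.data = np.log1p(x.data)
    return replace(m, counts=x, meta=dict(m.meta))


def _topk_by_value(values: np.ndarray, symbols: list[str], k: int) -> tuple[str, ...]:
    """Indices of the k largest strictly positive values; ties keep input order."""
    values = np.asarray(values, dtype=float).ravel()
    pos = np.flatnonzero(values > 0)
    if pos.size == 0:
        raise InputError("profile has no strictly positive expression value")
    # stable mergesort on -value preserves input order among ties
    order = pos[np.argsort(-values[pos], kind="stable")]
    return tuple(symbols[i] for i in order[:k])


def build_sentence(values, symbols: list[str], k: int = 50) -> GeneSentence:
    """Sentence of the ``k`` highest-expressed genes, descending.

    Ties are broken by ascending input gene order; zero-valued genes are
    never included, so the sentence may hold fewer than ``k`` symbols.
    """
    if len(symbols) != np.asarray(values).size:
        raise InputError("values and symbols differ in length")
    return GeneSentence(genes=_topk_by_value(np.asarray(values), symbols, k))


def build_corpus(
    m: SpotMatrix,
    k: int = 50,
    patches: dict[str, str] | None = None,
    deduplicate: bool = True,
) -> SentenceCorpus:
    """One sentence record per spot; exact duplicate (sentence, patch) pairs removed."""
    dense = m.to_dense()
    records: list[tuple[str, GeneSentence, str | None]] = []
    seen: set[tuple[str, str | None]] = set()
    for j, barcode in enumerate(m.barcodes):
        sent = build_sentence(dense[:, j], m.gene_ids, k=k)
        patch = patches.get(barcode) if patches else None
        key = (sent.text, patch)
        if deduplicate and key in seen:
            continue
        seen.add(key)
        records.append((barcode, sent, patch))
    dropped = m.n_spots - len(records)
    if dropped:
        logger.info("build_corpus: removed %d duplicate record(s)", dropped)
    return SentenceCorpus(records=records)


def profile_to_sentence(profile: pd.Series | pd.DataFrame, k: int = 50) -> GeneSentence:
    """Sentence for a bulk or pseudo-bulk gene/value profile.

    Uses the same top-k ranking rule as spot sentences.  ``profile`` is a
    Series indexed by gene symbol, or a two-column (gene, value) frame.
    """
    if isinstance(profile, pd.DataFrame):
        if profile.shape[1] != 2:
            raise InputError("profile frame must have exactly (gene, value) columns")
        profile = profile.set_index(profile.columns[0])[profile.columns[1]]
    values = profile.to_numpy(dtype=float)
    return GeneSentence(genes=_topk_by_value(values, list(profile.index), k))


def marker_sentence(markers: list[str]) -> GeneSentence:
    """Sentence from an ordered marker-gene list, keeping the given order.

    Duplicates are removed keeping the first occurrence.
    """
    if not markers:
        raise InputError("marker list is empty")
    seen: set[str] = set()
    ordered = [g for g in markers if not (g in seen or seen.add(g))]
    return GeneSentence(genes=tuple(ordered))


def write_corpus_jsonl(corpus: SentenceCorpus, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, sent, patch in corpus.records:
            fh.write(json.dumps({"id": rid, "sentence": sent.text, "patch": patch}) + "\n")


def read_corpus_jsonl(path: str | Path) -> SentenceCorpus:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        records.append(
            (obj["id"], GeneSentence(genes=tuple(obj["sentence"].split())), obj.get("patch"))
        )
    return SentenceCorpus(records=records)
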