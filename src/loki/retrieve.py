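"""Image-to-transcriptomics retrieval over an embedding bank.

A query image embedding is ranked against a bank of transcriptomic
embeddings by cosine similarity; retrieval quality is scored by Recall@K,
where K is a quantile of the bank (Recall@5% asks whether the ground-truth
entry ranks within the top 5% of candidates) and by the similarity between
the query image and the image paired with the retrieved transcriptomics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoder import cosine_similarity, cosine_similarity_matrix
from .st_io import InputError

__all__ = [
    "RetrievalBank",
    "RankedRetrieval",
    "retrieve_topk",
    "recall_at_k",
    "retrieval_similarity_report",
]


@dataclass
class RetrievalBank:
    """Candidate transcriptomic embeddings with unique entry ids."""

    embeddings: np.ndarray
    entry_ids: list[str]
    paired_image_embs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.embeddings = np.atleast_2d(np.asarray(self.embeddings, dtype=float))
        if self.embeddings.shape[0] == 0:
            raise InputError("retrieval bank is empty")
        if len(set(self.entry_ids)) != len(self.entry_ids):
            raise InputError("bank entry ids are not unique")
        if len(self.entry_ids) != self.embeddings.shape[0]:
            raise InputError("entry ids do not match embedding rows")
        if np.any(np.linalg.norm(self.embeddings, axis=1) == 0):
            raise InputError("bank contains zero embeddings")

    def __len__(self) -> int:
        return len(self.entry_ids)


@dataclass
class RankedRetrieval:
    """One query's candidates ordered by descending similarity."""

    entry_ids: list[str]
    scores: np.ndarray
    truth_id: str | None = None

    @property
    def truth_rank(self) -> int:
        """1-based rank of the ground-truth entry."""
        if self.truth_id is None:
            raise InputError("ranked retrieval has no ground-truth entry")
        return self.entry_ids.index(self.truth_id) + 1

    @property
    def truth_quantile(self) -> float:
        """Rank of the ground truth as a fraction of the bank size."""
        return self.truth_rank / len(self.entry_ids)


def retrieve_topk(
    query: np.ndarray,
    bank: RetrievalBank,
    k: int | None = None,
    truth_id: str | None = None,
) -> RankedRetrieval:
    """Top-k bank entries by cosine similarity to the query, descending.

    Ties are broken by bank insertion order (stable sort).
    """
    k = len(bank) if k is None else k
    if not 1 <= k <= len(bank):
        raise InputError(f"k={k} outside [1, {len(bank)}]")
    sims = cosine_similarity_matrix(np.atleast_2d(query), bank.embeddings).ravel()
    order = np.argsort(-sims, kind="stable")
    if truth_id is None:
        order = order[:k]  # with a known truth the full ranking is kept
    return RankedRetrieval(
        entry_ids=[bank.entry_ids[i] for i in order],
        scores=sims[order],
        truth_id=truth_id,
    )


def recall_at_k(results: list[RankedRetrieval], k: float) -> float:
    """Fraction of queries whose ground truth ranks within the top-K quantile."""
    if not 0 < k <= 1:
        raise InputError("K must be a fraction in (0, 1]")
    if not results:
        raise InputError("no retrieval results supplied")
    hits = 0
    for r in results:
        if r.truth_id is None:
            raise InputError("every result needs a ground-truth entry for Recall@K")
        if r.truth_quantile <= k:
            hits += 1
    return hits / len(results)


def retrieval_similarity_report(
    query_embs: np.ndarray,
    bank: RetrievalBank,
    query_image_embs: np.ndarray,
) -> pd.DataFrame:
    """Top-1 retrieval per query scored against the retrieved entry's paired image.

    The reported score is the cosine similarity between the query's image
    embedding and the paired image embedding of the retrieved transcriptomic
    entry; the summary statistic is the median (stored in ``attrs``).
    """
    if bank.paired_image_embs is None:
        raise InputError("bank entries carry no paired image embeddings")
    paired = np.atleast_2d(np.asarray(bank.paired_image_embs, dtype=float))
    valid = np.linalg.norm(paired, axis=1) > 0
    if not valid.all():
        logging.getLogger("loki").warning(
            "retrieval_similarity_report: excluding %d entries without paired images",
            int((~valid).sum()),
        )
    sub = RetrievalBank(
        embeddings=bank.embeddings[valid],
        entry_ids=[b for b, v in zip(bank.entry_ids, valid) if v],
        paired_image_embs=paired[valid],
    )
    query_embs = np.atleast_2d(query_embs)
    query_image_embs = np.atleast_2d(query_image_embs)
    rows = []
    for i in range(query_embs.shape[0]):
        top = retrieve_topk(query_embs[i], sub, k=1)
        j = sub.entry_ids.index(top.entry_ids[0])
        rows.append(
            {
                "query": str(i),
                "retrieved": top.entry_ids[0],
                "retrieval_score": float(top.scores[0]),
                "paired_image_similarity": cosine_similarity(
                    query_image_embs[i], sub.paired_image_embs[j]
                ),
            }
        )
    report = pd.DataFrame(rows).set_index("query")
    report.attrs["median_similarity"] = float(report["paired_image_similarity"].median())
    return report
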