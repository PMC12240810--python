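"""Zero-shot tissue annotation from reference embeddings and score fusion.

Tissue patches are scored against candidate tissue types by cosine
similarity in the shared embedding space; candidates come from bulk RNA-seq
profiles (top-k gene sentences) or ordered marker-gene lists.  Scores from
two independent models can be fused by per-image min-max normalization over
candidates followed by summation, and the predicted label is the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoder import cosine_similarity_matrix
from .metrics import classification_report
from .st_io import InputError

__all__ = [
    "ScoreTable",
    "similarity_map",
    "score_candidates",
    "zero_shot_classify",
    "fuse_scores",
    "evaluate_classification",
]


@dataclass
class ScoreTable:
    """Images-by-candidates similarity scores."""

    scores: np.ndarray
    image_ids: list[str]
    candidate_labels: list[str]

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if not np.isfinite(self.scores).all():
            raise InputError("score table contains non-finite values")
        if self.scores.shape != (len(self.image_ids), len(self.candidate_labels)):
            raise InputError("score table shape does not match ids/labels")
        if len(set(self.candidate_labels)) != len(self.candidate_labels):
            raise InputError("candidate labels are not unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.image_ids, columns=self.candidate_labels)


def similarity_map(patch_embs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-patch cosine similarity to one reference embedding.

    Higher similarity indicates greater presence of the reference tissue
    type at that patch; paired with spot coordinates this renders as a
    similarity heat map.
    """
    return cosine_similarity_matrix(patch_embs, ref[None, :]).ravel()


def score_candidates(
    patch_embs: np.ndarray,
    candidate_embs: np.ndarray,
    candidate_labels: list[str],
    image_ids: list[str] | None = None,
) -> ScoreTable:
    """Cosine-similarity score table of patches against candidate references."""
    patch_embs = np.atleast_2d(patch_embs)
    if image_ids is None:
        image_ids = [str(i) for i in range(patch_embs.shape[0])]
    return ScoreTable(
        scores=cosine_similarity_matrix(patch_embs, candidate_embs),
        image_ids=list(image_ids),
        candidate_labels=list(candidate_labels),
    )


def zero_shot_classify(table: ScoreTable) -> pd.Series:
    """Predicted label per image: highest-similarity candidate.

    Ties resolve to the first candidate in input order.
    """
    if len(table.candidate_labels) < 2:
        raise InputError("zero-shot classification needs at least 2 candidates")
    idx = table.scores.argmax(axis=1)  # argmax returns the first maximum
    return pd.Series(
        [table.candidate_labels[i] for i in idx], index=table.image_ids, name="label"
    )


def _minmax_rows(scores: np.ndarray) -> np.ndarray:
    lo = scores.min(axis=1, keepdims=True)
    hi = scores.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.full_like(scores, 0.5, dtype=float)
    ok = (span > 0).ravel()
    out[ok] = (scores[ok] - lo[ok]) / span[ok]
    return out


def fuse_scores(a: ScoreTable, b: ScoreTable) -> tuple[ScoreTable, pd.Series]:
    """Fuse two models' score tables by per-image min-max normalization + sum.

    Each table row is min-max normalized over its candidates, the normalized
    tables are summed, and the label with the highest combined score wins.
    A degenerate row (max == min) contributes a neutral 0.5 to every
    candidate, leaving the decision to the other model.
    """
    if a.image_ids != b.image_ids or a.candidate_labels != b.candidate_labels:
        raise InputError("fused tables must share images and candidate labels")
    combined = ScoreTable(
        scores=_minmax_rows(a.scores) + _minmax_rows(b.scores),
        image_ids=a.image_ids,
        candidate_labels=a.candidate_labels,
    )
    return combined, zero_shot_classify(combined)


def evaluate_classification(pred, truth) -> dict:
    """Precision, recall and frequency-weighted F1 for predicted labels."""
    report = classification_report(pred, truth)
    support = report["support"].to_numpy(dtype=float)
    weights = support / support.sum()
    return {
        "per_class": report,
        "precision": float((report["precision"] * weights).sum()),
        "recall": float((report["recall"] * weights).sum()),
        "weighted_f1": report.attrs["weighted_f1"],
    }
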