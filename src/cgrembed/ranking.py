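"""Ranking-fidelity evaluation of embeddings against alignment ground truth.

For an anchor q, the predicted ranking orders all other sequences by
descending cosine similarity of their embeddings to q's. It is scored
against the true (alignment-score) ranking by

* NDCG with relevance rel = n - true_rank + 1 evaluated at the predicted
  positions, discounted by 1/log(position + 1), normalized by the ideal
  (true-order) DCG; and
* the positional rank score at position p: the mean over anchors of
  exp(-|p - true rank of the item predicted at p|), an exponential penalty
  on rank displacement — 1.0 means position p is always exactly right.

Ties in predicted cosine are broken by ascending id, the same rule the
ground-truth ranking uses, so all rankings are reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import RankedRecord

__all__ = [
    "cosine_similarity",
    "predict_ranking",
    "RankingComparison",
    "compare_rankings",
    "dcg",
    "ndcg",
    "positional_rank_score",
    "evaluate_embeddings",
    "timed_transform",
    "CosineIndex",
]

_EPS = 1e-12


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expected two equal-length vectors")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _cosine_row(q: np.ndarray, E: np.ndarray) -> np.ndarray:
    qn = max(float(np.linalg.norm(q)), _EPS)
    en = np.maximum(np.linalg.norm(E, axis=1), _EPS)
    return (E @ q) / (qn * en)


def predict_ranking(
    q_emb: np.ndarray, candidate_ids: list[str], candidate_embs: np.ndarray
) -> list[str]:
    """Candidate ids by descending cosine to the anchor, ties by ascending id."""
    if len(candidate_ids) != len(candidate_embs):
        raise ValueError("ids and embeddings disagree in length")
    cos = _cosine_row(np.asarray(q_emb, float), np.asarray(candidate_embs, float))
    order = sorted(range(len(candidate_ids)), key=lambda i: (-cos[i], candidate_ids[i]))
    return [candidate_ids[i] for i in order]


@dataclass(frozen=True)
class RankingComparison:
    """True vs predicted order over the same id set for one anchor."""

    anchor_id: str
    true_order: tuple[str, ...]
    predicted_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.true_order) != set(self.predicted_order) or len(
            self.true_order
        ) != len(self.predicted_order):
            raise ValueError("orders must be permutations of the same id set")
        if len(self.true_order) == 0:
            raise ValueError("empty ranking")

    @property
    def n(self) -> int:
        return len(self.true_order)

    @property
    def relevances(self) -> np.ndarray:
        """rel at predicted position i: reversed true rank n - r + 1."""
        true_rank = {a: r for r, a in enumerate(self.true_order, start=1)}
        n = self.n
        return np.array([n - true_rank[a] + 1 for a in self.predicted_order], float)

    @property
    def true_position_of_predictions(self) -> np.ndarray:
        """1-based true rank of the item predicted at each position."""
        true_rank = {a: r for r, a in enumerate(self.true_order, start=1)}
        return np.array([true_rank[a] for a in self.predicted_order])


def compare_rankings(
    record: RankedRecord, candidate_ids: list[str], candidate_embs: np.ndarray,
    q_emb: np.ndarray,
) -> RankingComparison:
    """Build the comparison for one anchor from its embedding and candidates."""
    keep = [i for i, cid in enumerate(candidate_ids) if cid != record.anchor_id]
    ids = [candidate_ids[i] for i in keep]
    pred = predict_ranking(q_emb, ids, candidate_embs[keep])
    return RankingComparison(
        anchor_id=record.anchor_id,
        true_order=tuple(record.true_order),
        predicted_order=tuple(pred),
    )


def dcg(comparison: RankingComparison, log_base: float = 2.0) -> float:
    """Discounted cumulative gain of the predicted order."""
    rel = comparison.relevances
    i = np.arange(1, comparison.n + 1)
    return float((rel / (np.log(i + 1) / np.log(log_base))).sum())


def ndcg(comparison: RankingComparison, log_base: float = 2.0) -> float:
    """DCG normalized by the ideal (true-order) DCG; in (0, 1]."""
    ideal = RankingComparison(
        anchor_id=comparison.anchor_id,
        true_order=comparison.true_order,
        predicted_order=comparison.true_order,
    )
    return dcg(comparison, log_base) / dcg(ideal, log_base)


def positional_rank_score(
    comparisons: list[RankingComparison], p: int
) -> float:
    """Mean of exp(-|p - true rank of the position-p prediction|) over anchors."""
    if p < 1:
        raise ValueError("positions are 1-based")
    vals = []
    for c in comparisons:
        if p > c.n:
            raise ValueError(f"position {p} exceeds ranking size {c.n}")
        true_p = c.true_position_of_predictions[p - 1]
        vals.append(np.exp(-abs(p - true_p)))
    return float(np.mean(vals))


def timed_transform(embedder, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Embed a stack of images, returning (embeddings, seconds per item)."""
    t0 = time.perf_counter()
    E = embedder.transform(X)
    return E, (time.perf_counter() - t0) / max(len(X), 1)


def evaluate_embeddings(
    dataset: list[RankedRecord],
    ids: list[str],
    embeddings: np.ndarray,
    positions: tuple[int, ...] = (1, 2, 3),
) -> dict:
    """Score a full embedding table against ground-truth rankings.

    Returns per-anchor NDCG values plus aggregate mean/sd and positional rank
    scores at the requested positions.
    """
    row = {cid: i for i, cid in enumerate(ids)}
    comparisons = []
    for rec in dataset:
        q_emb = embeddings[row[rec.anchor_id]]
        comparisons.append(compare_rankings(rec, ids, embeddings, q_emb))
    scores = np.array([ndcg(c) for c in comparisons])
    out = {
        "ndcg_per_anchor": scores,
        "ndcg_mean": float(scores.mean()),
        "ndcg_sd": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
        "comparisons": comparisons,
    }
    for p in positions:
        if all(c.n >= p for c in comparisons):
            out[f"pos{p}"] = positional_rank_score(comparisons, p)
    return out


class CosineIndex:
    """Exact brute-force cosine retrieval over an embedding table."""

    def __init__(self, ids: list[str], embeddings: np.ndarray) -> None:
        if len(ids) != len(embeddings) or len(ids) == 0:
            raise ValueError("index needs one embedding per id")
        self.ids = list(ids)
        self.embeddings = np.asarray(embeddings, dtype=float)

    def query(self, q_emb: np.ndarray, top_k: int) -> list[tuple[str, float]]:
        if top_k > len(self.ids):
            import warnings

            warnings.warn("top_k exceeds index size; returning the full ranking")
            top_k = len(self.ids)
        cos = _cosine_row(np.asarray(q_emb, float), self.embeddings)
        order = sorted(range(len(self.ids)), key=lambda i: (-cos[i], self.ids[i]))
        return [(self.ids[i], float(cos[i])) for i in order[:top_k]]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), embeddings=self.embeddings)
        path.with_suffix(".ids.json").write_text(json.dumps(self.ids))

    @classmethod
    def load(cls, path: str | Path) -> "CosineIndex":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        ids = json.loads(path.with_suffix(".ids.json").read_text())
        return cls(ids, data["embeddings"])
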