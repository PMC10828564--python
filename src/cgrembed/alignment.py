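"""Needleman-Wunsch ground truth: pairwise scores, ranked records, splits.

The ground-truth similarity between two sequences is the optimal global
alignment score under a linear gap model: +1 per match, 0 per mismatch, -1
per gap position (opening and extension alike). Every sequence serves as an
anchor exactly once; its ranked record lists all other sequences by
descending score, ties broken by ascending id so rankings are reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from Bio import Align

__all__ = [
    "NwParams",
    "RankedRecord",
    "SplitSpec",
    "nw_score",
    "pairwise_scores",
    "build_ranked_record",
    "build_dataset",
    "split_anchors",
    "save_scores_tsv",
    "load_scores_tsv",
]


@dataclass(frozen=True)
class NwParams:
    """Global-alignment scoring: match / mismatch / per-position gap."""

    match: int = 1
    mismatch: int = 0
    gap: int = -1

    def __post_init__(self) -> None:
        if not (self.match > self.mismatch >= self.gap):
            raise ValueError("require match > mismatch >= gap")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap
        a.extend_gap_score = self.gap
        return a


@dataclass(frozen=True)
class RankedRecord:
    """Anchor q with all comparison sequences ordered by descending score."""

    anchor_id: str
    neighbors: tuple[tuple[str, float], ...]  # ((id, score), ...) descending

    def __post_init__(self) -> None:
        ids = [a for a, _ in self.neighbors]
        if self.anchor_id in ids:
            raise ValueError("anchor must not appear among its own neighbors")
        scores = [s for _, s in self.neighbors]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("neighbor scores must be non-increasing")

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def true_order(self) -> list[str]:
        return [a for a, _ in self.neighbors]

    def score_of(self, neighbor_id: str) -> float:
        for a, s in self.neighbors:
            if a == neighbor_id:
                return s
        raise KeyError(neighbor_id)


@dataclass(frozen=True)
class SplitSpec:
    """Random anchor-level train/test partition."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


def nw_score(a: str, b: str, params: NwParams | None = None) -> float:
    """Optimal global alignment score of two sequences.

    An empty sequence aligns all-gaps: score = gap * len(other).
    """
    params = params or NwParams()
    if not a or not b:
        return float(params.gap * (len(a) + len(b)))
    return float(params.aligner().score(a, b))


def pairwise_scores(
    records: list, params: NwParams | None = None
) -> dict[frozenset, float]:
    """Score each unordered pair once (the score is symmetric)."""
    params = params or NwParams()
    aligner = params.aligner()
    scores: dict[frozenset, float] = {}
    for r1, r2 in combinations(records, 2):
        scores[frozenset((r1.id, r2.id))] = float(aligner.score(r1.sequence, r2.sequence))
    return scores


def _rank_key(item: tuple[str, float]) -> tuple[float, str]:
    neighbor_id, score = item
    return (-score, neighbor_id)


def build_ranked_record(q, candidates: list, params: NwParams | None = None,
                        precomputed: dict[frozenset, float] | None = None) -> RankedRecord:
    """Rank candidates against anchor q by descending score, ties by id."""
    params = params or NwParams()
    scored = []
    for c in candidates:
        if c.id == q.id:
            raise ValueError("candidates must exclude the anchor")
        if precomputed is not None:
            s = precomputed[frozenset((q.id, c.id))]
        else:
            s = nw_score(q.sequence, c.sequence, params)
        scored.append((c.id, s))
    scored.sort(key=_rank_key)
    return RankedRecord(anchor_id=q.id, neighbors=tuple(scored))


def build_dataset(records: list, params: NwParams | None = None,
                  scores: dict[frozenset, float] | None = None) -> list[RankedRecord]:
    """One ranked record per input record; each pair scored exactly once."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    if scores is None:
        scores = pairwise_scores(records, params)
    out = []
    for q in records:
        cands = [r for r in records if r.id != q.id]
        out.append(build_ranked_record(q, cands, params, precomputed=scores))
    return out


def split_anchors(
    dataset: list[RankedRecord], spec: SplitSpec | None = None
) -> tuple[list[RankedRecord], list[RankedRecord]]:
    """Partition anchors into train/test; neighbor lists stay complete.

    Only the anchor role is split — a test anchor is still ranked against
    every other sequence, matching how the embedders are evaluated.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    n = len(dataset)
    n_train = int(round(n * spec.train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    perm = rng.permutation(n)
    train_idx = set(perm[:n_train].tolist())
    train = [rec for i, rec in enumerate(dataset) if i in train_idx]
    test = [rec for i, rec in enumerate(dataset) if i not in train_idx]
    return train, test


def save_scores_tsv(scores: dict[frozenset, float], path: str | Path) -> Path:
    """Persist the pair matrix as (id_a, id_b, score) rows, ids sorted."""
    path = Path(path)
    rows = sorted((tuple(sorted(pair)), s) for pair, s in scores.items())
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id_a", "id_b", "score"])
        for (a, b), s in rows:
            writer.writerow([a, b, s])
    return path


def load_scores_tsv(path: str | Path) -> dict[frozenset, float]:
    scores: dict[frozenset, float] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:3] != ["id_a", "id_b", "score"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for a, b, s in reader:
            scores[frozenset((a, b))] = float(s)
    return scores
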