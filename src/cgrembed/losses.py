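"""Triplet and ladder losses with their training-set constructions.

Triplet training uses hinge terms over (anchor, positive, negative) id
triples: for an anchor q, every ordered neighbor pair (a_i, a_j) with
strictly higher ground-truth score for a_i becomes a triplet — ties yield no
triplet. The loss pulls the positive inside the negative's squared euclidean
distance by a margin.

Ladder training ranks each anchor's neighbors into M contiguous similarity
tiers N_1..N_M and penalizes, tier by tier, any case where a more-similar
sample's embedding cosine to the anchor fails to exceed a less-similar
sample's cosine by the tier margin. Tier 1 treats the anchor itself as the
only positive (its self-cosine is identically 1). The final loss is the
beta-weighted sum of tier losses. Ground-truth alignment scores enter only
through tier construction; inside the loss, similarity is embedding cosine,
which keeps the loss differentiable in the network weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import RankedRecord

__all__ = [
    "Triplet",
    "TripletSet",
    "LadderGroups",
    "make_triplets",
    "make_ladder_groups",
    "triplet_loss",
    "triplet_loss_grad",
    "ladder_group_loss",
    "ladder_loss",
    "ladder_loss_grad",
    "default_margins",
    "default_betas",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Triplet:
    anchor: str
    positive: str
    negative: str


@dataclass(frozen=True)
class TripletSet:
    triplets: tuple[Triplet, ...]

    @property
    def n(self) -> int:
        return len(self.triplets)


@dataclass(frozen=True)
class LadderGroups:
    """Anchor q with neighbors partitioned into M descending-similarity tiers."""

    anchor_id: str
    groups: tuple[tuple[str, ...], ...]

    @property
    def m(self) -> int:
        return len(self.groups)


def make_triplets(
    record: RankedRecord, cap: int | None = None, seed: int = 0
) -> TripletSet:
    """All strict-order neighbor pairs of an anchor as triplets.

    For neighbors ranked i < j, (q, a_i, a_j) is a triplet iff s_i > s_j.
    With ``cap`` set, a seeded uniform subsample of at most ``cap`` triplets
    is returned.
    """
    if record.n < 2:
        raise ValueError("need at least two neighbors to form triplets")
    ids = [a for a, _ in record.neighbors]
    scores = np.array([s for _, s in record.neighbors])
    pos_idx, neg_idx = np.nonzero(scores[:, None] > scores[None, :])
    keep = pos_idx < neg_idx  # ranked list is descending, so strict pairs have i < j
    pos_idx, neg_idx = pos_idx[keep], neg_idx[keep]
    if cap is not None and len(pos_idx) > cap:
        choice = np.random.default_rng(seed).choice(len(pos_idx), cap, replace=False)
        choice.sort()
        pos_idx, neg_idx = pos_idx[choice], neg_idx[choice]
    triplets = tuple(
        Triplet(record.anchor_id, ids[i], ids[j]) for i, j in zip(pos_idx, neg_idx)
    )
    return TripletSet(triplets=triplets)


def make_ladder_groups(record: RankedRecord, m: int) -> LadderGroups:
    """Slice the descending neighbor list into M near-equal contiguous tiers.

    Sizes differ by at most one with the remainder given to the earliest
    tiers; a run of tied scores never straddles a boundary — the boundary is
    shifted forward so the whole run stays in the earlier tier.
    """
    n = record.n
    if m < 2:
        raise ValueError("need at least two groups")
    if n < m:
        raise ValueError(f"cannot split {n} neighbors into {m} groups")
    base, rem = divmod(n, m)
    sizes = [base + (1 if i < rem else 0) for i in range(m)]
    scores = [s for _, s in record.neighbors]
    bounds = list(np.cumsum(sizes)[:-1])
    for b in range(len(bounds)):
        cut = bounds[b]
        while cut < n and scores[cut] == scores[cut - 1]:
            cut += 1  # extend earlier tier over the tied run
        bounds[b] = cut
    bounds = [b for b in bounds if b < n]
    # tie extension may merge boundaries; drop duplicates to keep tiers nonempty
    cuts = [0] + sorted(set(bounds)) + [n]
    ids = [a for a, _ in record.neighbors]
    groups = tuple(tuple(ids[a:b]) for a, b in zip(cuts, cuts[1:]))
    return LadderGroups(anchor_id=record.anchor_id, groups=groups)


def triplet_loss(
    f_x: np.ndarray, f_pos: np.ndarray, f_neg: np.ndarray, alpha: float
) -> float:
    """Summed hinge [||f_x-f_pos||^2 - ||f_x-f_neg||^2 + alpha]_+ over a batch."""
    f_x, f_pos, f_neg = np.atleast_2d(f_x), np.atleast_2d(f_pos), np.atleast_2d(f_neg)
    if not (f_x.shape == f_pos.shape == f_neg.shape):
        raise ValueError("embedding dimension mismatch")
    d_pos = ((f_x - f_pos) ** 2).sum(axis=1)
    d_neg = ((f_x - f_neg) ** 2).sum(axis=1)
    return float(np.maximum(d_pos - d_neg + alpha, 0.0).sum())


def triplet_loss_grad(
    f_x: np.ndarray, f_pos: np.ndarray, f_neg: np.ndarray, alpha: float
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss plus gradients w.r.t. each embedding row."""
    f_x, f_pos, f_neg = np.atleast_2d(f_x), np.atleast_2d(f_pos), np.atleast_2d(f_neg)
    d_pos = ((f_x - f_pos) ** 2).sum(axis=1)
    d_neg = ((f_x - f_neg) ** 2).sum(axis=1)
    h = d_pos - d_neg + alpha
    active = (h > 0.0).astype(float)[:, None]
    g_x = 2.0 * (f_neg - f_pos) * active
    g_pos = 2.0 * (f_pos - f_x) * active
    g_neg = 2.0 * (f_x - f_neg) * active
    return float(np.maximum(h, 0.0).sum()), g_x, g_pos, g_neg


def _cosines(q: np.ndarray, X: np.ndarray) -> np.ndarray:
    qn = max(float(np.linalg.norm(q)), _EPS)
    xn = np.maximum(np.linalg.norm(X, axis=1), _EPS)
    return (X @ q) / (qn * xn)


def ladder_group_loss(
    q_emb: np.ndarray,
    group_embeddings: list[np.ndarray],
    i: int,
    alpha_i: float,
) -> float:
    """Tier-i hinge loss for one anchor.

    For i >= 2: sum over x+ in N_{i-1}, x- in N_{i..M} of
    [alpha_i - cos(q, x+) + cos(q, x-)]_+. For i = 1 the only positive is the
    anchor itself with cos(q, q) = 1, and the negatives are all of N_{1..M}.
    """
    m = len(group_embeddings)
    if not (1 <= i <= m):
        raise ValueError(f"group index {i} outside 1..{m}")
    if i == 1:
        pos_cos = np.array([1.0])
        neg_start = 0
    else:
        pos = group_embeddings[i - 2]
        if len(pos) == 0:
            return 0.0
        pos_cos = _cosines(q_emb, pos)
        neg_start = i - 1
    negs = [g for g in group_embeddings[neg_start:] if len(g)]
    if not negs:
        return 0.0
    neg_cos = _cosines(q_emb, np.vstack(negs))
    hinge = alpha_i - pos_cos[:, None] + neg_cos[None, :]
    return float(np.maximum(hinge, 0.0).sum())


def default_margins(m: int, step: float = 0.1) -> np.ndarray:
    """Non-decreasing tier margins alpha_i = step * i."""
    return step * np.arange(1, m + 1)


def default_betas(m: int) -> np.ndarray:
    return np.ones(m)


def ladder_loss(
    q_emb: np.ndarray,
    group_embeddings: list[np.ndarray],
    margins: np.ndarray,
    betas: np.ndarray,
) -> float:
    """Weighted sum of the M tier losses for one anchor."""
    m = len(group_embeddings)
    if len(margins) != m or len(betas) != m:
        raise ValueError("margins/betas must have one entry per group")
    return float(
        sum(
            betas[i - 1] * ladder_group_loss(q_emb, group_embeddings, i, margins[i - 1])
            for i in range(1, m + 1)
        )
    )


def ladder_loss_grad(
    q_emb: np.ndarray,
    group_embeddings: list[np.ndarray],
    margins: np.ndarray,
    betas: np.ndarray,
) -> tuple[float, np.ndarray, list[np.ndarray]]:
    """Ladder loss plus gradients w.r.t. the anchor and every group member.

    The gradient flows through the cosine terms only (the i=1 self-cosine is
    the constant 1).
    """
    m = len(group_embeddings)
    sizes = [len(g) for g in group_embeddings]
    X = np.vstack([g for g in group_embeddings if len(g)]) if sum(sizes) else np.zeros((0, q_emb.size))
    offsets = np.cumsum([0] + sizes)

    qn = max(float(np.linalg.norm(q_emb)), _EPS)
    xn = np.maximum(np.linalg.norm(X, axis=1), _EPS)
    cos = (X @ q_emb) / (qn * xn) if len(X) else np.zeros(0)

    # accumulate d(loss)/d(cos_t) for every candidate t
    dcos = np.zeros(len(X))
    total = 0.0
    for i in range(1, m + 1):
        beta, alpha = float(betas[i - 1]), float(margins[i - 1])
        if i == 1:
            pos_cos = np.array([1.0])
            pos_slice = slice(0, 0)
            neg_slice = slice(offsets[0], offsets[m])
        else:
            pos_slice = slice(offsets[i - 2], offsets[i - 1])
            neg_slice = slice(offsets[i - 1], offsets[m])
            pos_cos = cos[pos_slice]
        neg_cos = cos[neg_slice]
        if len(neg_cos) == 0 or len(pos_cos) == 0:
            continue
        hinge = alpha - pos_cos[:, None] + neg_cos[None, :]
        active = hinge > 0.0
        total += beta * float(np.maximum(hinge, 0.0).sum())
        if i >= 2:
            dcos[pos_slice] += -beta * active.sum(axis=1)
        dcos[neg_slice] += beta * active.sum(axis=0)

    # chain rule through cosine: for candidate x,
    #   d cos/d x = q/(|q||x|) - cos * x/|x|^2
    #   d cos/d q = x/(|q||x|) - cos * q/|q|^2
    g_q = np.zeros_like(q_emb, dtype=float)
    g_X = np.zeros_like(X, dtype=float)
    if len(X):
        g_X = dcos[:, None] * (q_emb[None, :] / (qn * xn[:, None]) - cos[:, None] * X / (xn[:, None] ** 2))
        g_q = (dcos[:, None] * (X / (qn * xn[:, None]) - (cos[:, None] / qn**2) * q_emb[None, :])).sum(axis=0)
    g_groups = [g_X[offsets[i]:offsets[i + 1]] for i in range(m)]
    return total, g_q, g_groups
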