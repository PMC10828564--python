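"""End-to-end desk-scale benchmark: all embedders vs alignment ground truth.

The benchmark generates the synthetic study conditions (8 families x 12
members, 300 nt ancestors, substitution tiers 0 to 0.25), computes the full
pairwise Needleman-Wunsch ground truth, encodes every sequence as a CGR
image, and scores each embedder's cosine rankings with NDCG and positional
rank scores — on all anchors and on the held-out 20% test anchors
separately. Neural embedders are trained on the 80% training anchors only.

Problem sizes here are the package's desk-scale defaults (96 sequences,
16x16 images, 8 conv filters, <=10 epochs); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import RankedRecord, SplitSpec, build_dataset, split_anchors
from .cgr import encode_records
from .embedders import (
    AHashEmbedder,
    FcgrEmbedder,
    PcaEmbedder,
    PHashEmbedder,
    WHashEmbedder,
)
from .ranking import evaluate_embeddings, timed_transform
from .siamese import SiameseEmbedder
from .simulate import FamilySpec, generate_dataset

__all__ = [
    "BenchmarkConfig",
    "BenchmarkData",
    "make_benchmark_data",
    "make_embedder",
    "run_benchmark",
    "dimension_sweep",
    "shuffled_baseline_ndcg",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = (
    "fcgr",
    "pca",
    "ahash",
    "phash",
    "whash",
    "cnn_triplet",
    "cnn_ladder",
)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Desk-scale study conditions for the end-to-end comparison."""

    family: FamilySpec = field(default_factory=FamilySpec)
    resolution: int = 16
    dim: int = 64
    train_fraction: float = 0.8
    epochs: int = 10
    n_filters: int = 8
    batch_candidates: int = 32
    learning_rate: float = 1e-3
    positions: tuple[int, ...] = (1, 2, 3)


@dataclass(frozen=True)
class BenchmarkData:
    """Everything derived from one seeded dataset draw."""

    ids: list[str]
    images: np.ndarray
    dataset: list[RankedRecord]
    train: list[RankedRecord]
    test: list[RankedRecord]


def make_benchmark_data(seed: int, config: BenchmarkConfig | None = None) -> BenchmarkData:
    """Generate sequences, ground truth and CGR images for one seed."""
    config = config or BenchmarkConfig()
    spec = FamilySpec(
        n_families=config.family.n_families,
        members_per_family=config.family.members_per_family,
        ancestor_length=config.family.ancestor_length,
        mutation_tiers=config.family.mutation_tiers,
        indel_rate=config.family.indel_rate,
        seed=seed,
    )
    records = generate_dataset(spec)
    dataset = build_dataset(records)
    train, test = split_anchors(
        dataset, SplitSpec(train_fraction=config.train_fraction, seed=seed)
    )
    ids, images = encode_records(records, resolution=config.resolution, normalize=True)
    return BenchmarkData(ids=ids, images=images, dataset=dataset, train=train, test=test)


def make_embedder(method: str, config: BenchmarkConfig, seed: int):
    """Instantiate one embedder by short name."""
    if method == "fcgr":
        return FcgrEmbedder()
    if method == "pca":
        return PcaEmbedder(dim=config.dim)
    if method == "ahash":
        return AHashEmbedder(dim=config.dim)
    if method == "phash":
        return PHashEmbedder(dim=config.dim)
    if method == "whash":
        return WHashEmbedder(dim=config.dim)
    if method in ("cnn_ladder", "cnn_triplet", "fcn_ladder", "fcn_triplet"):
        arch, loss = method.split("_")
        return SiameseEmbedder(
            architecture=arch,
            loss=loss,
            dim=config.dim,
            n_filters=config.n_filters,
            batch_candidates=config.batch_candidates,
            learning_rate=config.learning_rate,
            epochs=config.epochs,
            seed=seed,
        )
    raise ValueError(f"unknown method {method!r}")


def _fit_embedder(embedder, data: BenchmarkData):
    if isinstance(embedder, SiameseEmbedder):
        embedder.fit(data.images, data.train, ids=data.ids)
    elif isinstance(embedder, PcaEmbedder):
        train_ids = {r.anchor_id for r in data.train}
        rows = [i for i, cid in enumerate(data.ids) if cid in train_ids]
        # a requested dimension above the data rank is capped to full rank:
        # projecting onto every principal axis already retains everything
        n_pixels = data.images.shape[1] * data.images.shape[2]
        feasible = min(len(rows), n_pixels)
        if embedder.dim > feasible:
            embedder.set_params(dim=feasible)
        embedder.fit(data.images[rows])
    else:
        embedder.fit(data.images)
    return embedder


def run_benchmark(
    seed: int,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    config: BenchmarkConfig | None = None,
    data: BenchmarkData | None = None,
) -> pd.DataFrame:
    """Evaluate each method on one seeded dataset draw.

    Returns one row per (method, scope) with scope "full" (every anchor) or
    "test" (held-out anchors only), mean/sd NDCG, positional rank scores and
    mean per-sequence embedding time.
    """
    config = config or BenchmarkConfig()
    if data is None:
        data = make_benchmark_data(seed, config)
    rows = []
    for method in methods:
        embedder = _fit_embedder(make_embedder(method, config, seed), data)
        E, sec_per_item = timed_transform(embedder, data.images)
        for scope, subset in (("full", data.dataset), ("test", data.test)):
            res = evaluate_embeddings(subset, data.ids, E, positions=config.positions)
            row = {
                "method": method,
                "dim": E.shape[1],
                "seed": seed,
                "scope": scope,
                "ndcg_mean": res["ndcg_mean"],
                "ndcg_sd": res["ndcg_sd"],
                "embed_sec_per_seq": sec_per_item,
            }
            for p in config.positions:
                row[f"pos{p}"] = res.get(f"pos{p}", np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def dimension_sweep(
    seed: int,
    methods: tuple[str, ...] = ("pca", "ahash", "phash", "whash"),
    dims: tuple[int, ...] = (16, 64, 256),
    config: BenchmarkConfig | None = None,
    data: BenchmarkData | None = None,
) -> pd.DataFrame:
    """NDCG of the unparameterized embedders across embedding dimensions."""
    config = config or BenchmarkConfig()
    if data is None:
        data = make_benchmark_data(seed, config)
    rows = []
    for dim in dims:
        cfg = BenchmarkConfig(
            family=config.family,
            resolution=config.resolution,
            dim=dim,
            train_fraction=config.train_fraction,
            epochs=config.epochs,
            n_filters=config.n_filters,
            batch_candidates=config.batch_candidates,
            learning_rate=config.learning_rate,
            positions=config.positions,
        )
        for method in methods:
            embedder = _fit_embedder(make_embedder(method, cfg, seed), data)
            E = embedder.transform(data.images)
            res = evaluate_embeddings(data.dataset, data.ids, E, positions=())
            rows.append(
                {"method": method, "dim": dim, "seed": seed, "ndcg_mean": res["ndcg_mean"]}
            )
    return pd.DataFrame(rows)


def shuffled_baseline_ndcg(data: BenchmarkData, seed: int, n_draws: int = 20) -> float:
    """Mean NDCG of uniformly shuffled rankings — the chance floor.

    NDCG with reversed-rank relevance sits well above zero even for random
    orders; this is the reference level a hash at tiny dimension degrades to.
    """
    from .ranking import RankingComparison, ndcg

    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_draws):
        rec = data.dataset[rng.integers(len(data.dataset))]
        pred = list(rec.true_order)
        rng.shuffle(pred)
        vals.append(
            ndcg(
                RankingComparison(
                    anchor_id=rec.anchor_id,
                    true_order=tuple(rec.true_order),
                    predicted_order=tuple(pred),
                )
            )
        )
    return float(np.mean(vals))
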