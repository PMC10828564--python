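"""Siamese neural embedders trained on alignment-score rankings.

A single weight-shared network embeds CGR images into R^d; training pushes
the embedding cosine/distance structure toward the ground-truth alignment
ranking of each anchor, using either the triplet loss or the ladder loss.
Because the branches share one parameter set, "Siamese" is realized simply
by running every input through the same network instance.

Training is mini-batch per anchor: for each training anchor, a seeded sample
of its ranked candidates is embedded together with the anchor and one
gradient step is taken on the selected loss. A held-out slice of the
training anchors provides a validation loss for early stopping.

The recorded reference configuration uses 1024 conv filters and learning
rate 6e-7 (PAPER_PRESET); the default desk-scale configuration uses fewer
filters and an Adam step size that actually moves a small network within a
handful of epochs. See docs/methods.md.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alignment import RankedRecord
from .losses import (
    default_betas,
    default_margins,
    ladder_loss_grad,
    make_ladder_groups,
    make_triplets,
    triplet_loss_grad,
)
from .network import Adam, Network, build_network

__all__ = ["SiameseEmbedder", "PAPER_PRESET"]

# reference hyperparameters as published for the full-scale experiments
PAPER_PRESET = {
    "n_filters": 1024,
    "hidden": 512,
    "kernel": 5,
    "dropout": 0.2,
    "learning_rate": 6e-7,
}


class SiameseEmbedder(BaseEstimator, TransformerMixin):
    """CGR-image embedder trained with triplet or ladder loss.

    Parameters
    ----------
    architecture : "cnn" or "fcn"
        cnn: conv(kernel, n_filters, ReLU) -> overlapping max-pool ->
        dense hidden ReLU + dropout -> dense dim tanh.
        fcn: dense hidden ReLU + dropout -> dense dim ReLU.
    loss : "ladder" or "triplet"
    dim : embedding dimension d.
    n_groups, margins, betas : ladder tiers M, margins alpha_i (default
        0.1*i, non-decreasing) and weights beta_i (default 1).
    triplet_margin : alpha of the triplet hinge.
    triplet_cap : per-anchor cap on enumerated triplets (seeded subsample).
    batch_candidates : per-anchor candidate sample size for ladder steps.
    learning_rate, epochs, patience, val_fraction : Adam step size, epoch
        cap, early-stopping patience on validation loss, validation slice.
    seed : governs init, dropout, sampling and the validation split.
    """

    def __init__(
        self,
        architecture: str = "cnn",
        loss: str = "ladder",
        dim: int = 64,
        n_filters: int = 32,
        hidden: int = 512,
        kernel: int = 5,
        pool: int = 2,
        pool_stride: int = 1,
        dropout: float = 0.2,
        n_groups: int = 4,
        margins: tuple | None = None,
        betas: tuple | None = None,
        triplet_margin: float = 0.2,
        triplet_cap: int = 64,
        batch_candidates: int = 32,
        learning_rate: float = 1e-3,
        epochs: int = 10,
        patience: int = 3,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.architecture = architecture
        self.loss = loss
        self.dim = dim
        self.n_filters = n_filters
        self.hidden = hidden
        self.kernel = kernel
        self.pool = pool
        self.pool_stride = pool_stride
        self.dropout = dropout
        self.n_groups = n_groups
        self.margins = margins
        self.betas = betas
        self.triplet_margin = triplet_margin
        self.triplet_cap = triplet_cap
        self.batch_candidates = batch_candidates
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # ----------------------------------------------------------------- setup

    def _build(self, resolution: int) -> Network:
        return build_network(
            self.architecture,
            resolution,
            self.dim,
            n_filters=self.n_filters,
            kernel=self.kernel,
            pool=self.pool,
            pool_stride=self.pool_stride,
            hidden=self.hidden,
            dropout=self.dropout,
            seed=self.seed,
        )

    def initialize(self, resolution: int) -> "SiameseEmbedder":
        """Build the (untrained) network so transform() can be used as-is."""
        self.resolution_ = resolution
        self.network_ = self._build(resolution)
        self.history_ = {"train_loss": [], "val_loss": []}
        return self

    def _ladder_params(self):
        m = self.n_groups
        margins = np.asarray(self.margins, float) if self.margins is not None else default_margins(m)
        betas = np.asarray(self.betas, float) if self.betas is not None else default_betas(m)
        if len(margins) != m or len(betas) != m:
            raise ValueError("margins/betas must have n_groups entries")
        return margins, betas

    # -------------------------------------------------------------- training

    def fit(self, X, y: list[RankedRecord], ids: list[str] | None = None):
        """Train on ranked records.

        X is the (n, R, R) stack of CGR images of *all* sequences; ids gives
        the sequence id of each row (defaults to the union of ids appearing
        in y if omitted and X rows are in that order is required — passing
        ids explicitly is recommended). y holds the training anchors' ranked
        records; candidates may reference any row of X.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"expected (n, R, R) image stack, got {X.shape}")
        if not y:
            raise ValueError("no training anchors")
        if ids is None:
            raise ValueError("ids is required: one sequence id per row of X")
        if len(ids) != len(X):
            raise ValueError("ids and X disagree in length")
        if self.loss not in ("ladder", "triplet"):
            raise ValueError(f"unknown loss {self.loss!r}")
        row = {cid: i for i, cid in enumerate(ids)}
        self.initialize(X.shape[1])
        net = self.network_
        opt = Adam(net, lr=self.learning_rate)
        rng = np.random.default_rng([self.seed, 9173])

        # anchor-level validation slice for early stopping
        anchors = list(y)
        n_val = int(round(len(anchors) * self.val_fraction))
        perm = rng.permutation(len(anchors))
        val_set = [anchors[i] for i in perm[:n_val]]
        fit_set = [anchors[i] for i in perm[n_val:]] or anchors

        if self.loss == "ladder":
            margins, betas = self._ladder_params()
            structures = {
                rec.anchor_id: make_ladder_groups(rec, self.n_groups) for rec in anchors
            }
        else:
            structures = {
                rec.anchor_id: make_triplets(
                    rec, cap=self.triplet_cap, seed=int(rng.integers(2**31))
                )
                for rec in anchors
            }

        def anchor_step(rec: RankedRecord, train: bool) -> float:
            if self.loss == "ladder":
                groups = structures[rec.anchor_id].groups
                take = max(1, self.batch_candidates // len(groups))
                sampled = []
                for g in groups:
                    g = list(g)
                    if train and len(g) > take:
                        g = [g[k] for k in sorted(rng.choice(len(g), take, replace=False))]
                    sampled.append(g)
                batch_ids = [rec.anchor_id] + [cid for g in sampled for cid in g]
                emb = net.forward(X[[row[c] for c in batch_ids]], train=train)
                sizes = [len(g) for g in sampled]
                offs = np.concatenate([[1], 1 + np.cumsum(sizes)])
                group_embs = [emb[offs[i]:offs[i + 1]] for i in range(len(sizes))]
                loss, g_q, g_groups = ladder_loss_grad(emb[0], group_embs, margins, betas)
                n_terms = sum(len(g) for g in sampled) or 1
                if train:
                    grad = np.vstack([g_q[None, :]] + g_groups) / n_terms
                    net.backward(grad)
                    opt.step()
                return loss / n_terms
            # triplet
            tset = structures[rec.anchor_id].triplets
            if not tset:
                return 0.0
            uniq = [rec.anchor_id] + sorted(
                {t.positive for t in tset} | {t.negative for t in tset}
            )
            pos_of = {cid: k for k, cid in enumerate(uniq)}
            emb = net.forward(X[[row[c] for c in uniq]], train=train)
            ia = np.zeros(len(tset), dtype=int)
            ip = np.array([pos_of[t.positive] for t in tset])
            ineg = np.array([pos_of[t.negative] for t in tset])
            loss, g_x, g_p, g_n = triplet_loss_grad(
                emb[ia], emb[ip], emb[ineg], self.triplet_margin
            )
            if train:
                grad = np.zeros_like(emb)
                np.add.at(grad, ia, g_x)
                np.add.at(grad, ip, g_p)
                np.add.at(grad, ineg, g_n)
                net.backward(grad / len(tset))
                opt.step()
            return loss / len(tset)

        best_val = np.inf
        best_weights = net.get_weights()
        stall = 0
        for _epoch in range(self.epochs):
            order = rng.permutation(len(fit_set))
            losses = [anchor_step(fit_set[i], train=True) for i in order]
            train_loss = float(np.mean(losses))
            if not np.isfinite(train_loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {_epoch + 1}"
                )
            if val_set:
                val_loss = float(np.mean([anchor_step(r, train=False) for r in val_set]))
            else:
                val_loss = train_loss
            self.history_["train_loss"].append(train_loss)
            self.history_["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = net.get_weights()
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        net.set_weights(best_weights)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    # -------------------------------------------------------------- inference

    def transform(self, X, batch_size: int = 256):
        """Deterministic forward pass (dropout off), batched."""
        if not hasattr(self, "network_"):
            raise RuntimeError("embedder is neither fitted nor initialized")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != self.resolution_ or X.shape[2] != self.resolution_:
            raise ValueError(
                f"expected {self.resolution_}x{self.resolution_} images, got {X.shape[1:]}"
            )
        out = [
            self.network_.forward(X[i:i + batch_size], train=False)
            for i in range(0, len(X), batch_size)
        ]
        return np.vstack(out)

    def transform_timed(self, X) -> tuple[np.ndarray, list[float]]:
        """One-by-one embedding with a per-sequence wall-clock timing."""
        X = np.asarray(X, dtype=float)
        embs, times = [], []
        for img in X:
            t0 = time.perf_counter()
            embs.append(self.transform(img[None])[0])
            times.append(time.perf_counter() - t0)
        return np.stack(embs), times

    # ------------------------------------------------------------ persistence

    def save(self, path: str | Path) -> None:
        if not hasattr(self, "network_"):
            raise RuntimeError("nothing to save: embedder not fitted")
        path = Path(path)
        weights = self.network_.get_weights()
        named = {f"w{i:03d}": w for i, w in enumerate(weights)}
        named["__config__"] = np.frombuffer(
            json.dumps(
                {"params": self.get_params(), "resolution": self.resolution_}
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **named)

    @classmethod
    def load(cls, path: str | Path) -> "SiameseEmbedder":
        data = np.load(Path(path))
        meta = json.loads(bytes(data["__config__"]).decode())
        params = dict(meta["params"])
        for key in ("margins", "betas"):
            if params.get(key) is not None:
                params[key] = tuple(params[key])
        est = cls(**params)
        est.initialize(meta["resolution"])
        keys = sorted(k for k in data.files if k != "__config__")
        est.network_.set_weights([data[k] for k in keys])
        return est
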