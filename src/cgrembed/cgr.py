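"""Chaos game representation (CGR) of DNA sequences.

The chaos game maps a sequence over {A,C,G,T} into the unit square: a marker
starts at the center and, for each base, moves halfway toward that base's
corner. The visited points form a fractal point cloud whose density at
resolution 2^k encodes k-mer composition: the cell containing a point is
determined exactly by the last k bases consumed, so the rasterized count
grid at resolution 2^k (skipping the first k-1 warm-up points) is the k-mer
frequency matrix (FCGR).

Corner convention (configurable): A=(0,0), C=(0,1), G=(1,1), T=(1,0).
Pixel convention: pixels[row, col] with row = floor(y*R), col = floor(x*R),
half-open cells [i/R, (i+1)/R); chaos-game points never land on a cell
boundary at any dyadic resolution because the center start contributes an
odd dyadic offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DnaRecord

DEFAULT_VERTEX_MAP: dict[str, tuple[float, float]] = {
    "A": (0.0, 0.0),
    "C": (0.0, 1.0),
    "G": (1.0, 1.0),
    "T": (1.0, 0.0),
}

DEFAULT_RESOLUTION = 64

__all__ = [
    "CgrTrajectory",
    "CgrImage",
    "cgr_trajectory",
    "rasterize",
    "fcgr_matrix",
    "kmer_cell",
    "encode_records",
    "save_png",
    "DEFAULT_VERTEX_MAP",
    "DEFAULT_RESOLUTION",
]


@dataclass(frozen=True)
class CgrTrajectory:
    """Ordered chaos-game points p_1..p_L of one sequence."""

    points: np.ndarray  # (L, 2) float64, columns (x, y)
    vertex_map: dict[str, tuple[float, float]]
    sequence_id: str = ""

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CgrImage:
    """Rasterized CGR: a resolution x resolution non-negative grid."""

    pixels: np.ndarray
    resolution: int
    sequence_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.pixels.shape != (self.resolution, self.resolution):
            raise ValueError("pixel grid does not match resolution")


def _check_resolution(resolution: int) -> None:
    if resolution < 1 or (resolution & (resolution - 1)) != 0:
        raise ValueError(f"resolution must be a power of two, got {resolution}")


def cgr_trajectory(
    record: DnaRecord | str,
    vertex_map: dict[str, tuple[float, float]] | None = None,
) -> CgrTrajectory:
    """Run the chaos game: p_0 = center, p_i = (p_{i-1} + V(base_i)) / 2.

    Vectorized as a prefix recursion: p_i = sum_j V_j / 2^(i-j+1) + c / 2^i.
    """
    vm = DEFAULT_VERTEX_MAP if vertex_map is None else vertex_map
    seq = record.sequence if isinstance(record, DnaRecord) else record
    seq_id = record.id if isinstance(record, DnaRecord) else ""
    try:
        corners = np.array([vm[c] for c in seq], dtype=np.float64)
    except KeyError as exc:
        raise ValueError(f"cannot encode base {exc.args[0]!r}: not in vertex map") from exc
    length = len(seq)
    # weights: p_i = sum_{j<=i} V_j * 2^{j-i-1} + 0.5 * 2^{-i}
    # computed stably via the scaled cumulative sum s_i = sum V_j 2^j
    points = np.empty((length, 2))
    pos = np.array([0.5, 0.5])
    for i in range(length):
        pos = (pos + corners[i]) / 2.0
        points[i] = pos
    return CgrTrajectory(points=points, vertex_map=dict(vm), sequence_id=seq_id)


def rasterize(
    trajectory: CgrTrajectory,
    resolution: int = DEFAULT_RESOLUTION,
    *,
    normalize: bool = False,
    skip: int = 0,
) -> CgrImage:
    """Bin trajectory points into a resolution x resolution count grid.

    ``skip`` drops the leading points (used by :func:`fcgr_matrix` to discard
    the k-1 warm-up points that do not yet correspond to a full k-mer).
    Normalization divides by the maximum count, mapping pixels into [0, 1].
    """
    _check_resolution(resolution)
    pts = trajectory.points[skip:]
    cols = np.clip((pts[:, 0] * resolution).astype(np.intp), 0, resolution - 1)
    rows = np.clip((pts[:, 1] * resolution).astype(np.intp), 0, resolution - 1)
    grid = np.zeros((resolution, resolution), dtype=np.float64)
    np.add.at(grid, (rows, cols), 1.0)
    normalized = False
    if normalize:
        peak = grid.max()
        if peak > 0:
            grid /= peak
        normalized = True
    return CgrImage(
        pixels=grid,
        resolution=resolution,
        sequence_id=trajectory.sequence_id,
        normalized=normalized,
    )


def fcgr_matrix(
    record: DnaRecord | str,
    k: int,
    vertex_map: dict[str, tuple[float, float]] | None = None,
) -> CgrImage:
    """k-mer frequency matrix: 2^k x 2^k grid of k-mer counts.

    Equivalent to rasterizing the CGR trajectory at resolution 2^k and
    skipping the first k-1 points; total mass is L - k + 1.
    """
    seq = record.sequence if isinstance(record, DnaRecord) else record
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")
    traj = cgr_trajectory(record, vertex_map)
    return rasterize(traj, resolution=2**k, skip=k - 1)


def kmer_cell(
    kmer: str, vertex_map: dict[str, tuple[float, float]] | None = None
) -> tuple[int, int]:
    """(row, col) cell that k-mer occurrences occupy at resolution 2^len(kmer)."""
    traj = cgr_trajectory(kmer, vertex_map)
    res = 2 ** len(kmer)
    x, y = traj.points[-1]
    return int(y * res), int(x * res)


def encode_records(
    records: list[DnaRecord],
    resolution: int = DEFAULT_RESOLUTION,
    *,
    normalize: bool = True,
    vertex_map: dict[str, tuple[float, float]] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Encode records to a stacked image array.

    Returns (ids, X) with X of shape (n, resolution, resolution); normalized
    images are what the embedders consume.
    """
    ids = [r.id for r in records]
    X = np.stack(
        [
            rasterize(cgr_trajectory(r, vertex_map), resolution, normalize=normalize).pixels
            for r in records
        ]
    )
    return ids, X


def save_png(image: CgrImage, path: str) -> None:
    """Export for visual inspection (dark = dense)."""
    from PIL import Image

    arr = image.pixels
    peak = arr.max()
    scaled = (255 * (1.0 - arr / peak)).astype(np.uint8) if peak > 0 else np.full(
        arr.shape, 255, dtype=np.uint8
    )
    Image.fromarray(scaled, mode="L").save(path)
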