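"""Synthetic sequence families with graded, controllable similarity.

Each family descends from one random ancestor; member *r* carries iid
per-site substitutions at the rate of mutation tier *r* (optionally indels),
so within a family the ground-truth similarity to low-tier members is
stochastically higher than to high-tier members. This creates a known
ranking ladder for testing embedders end to end — it is a ranking testbed,
not an evolutionary model (no transition/transversion bias, no phylogeny).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DnaRecord

BASES = np.array(list("ACGT"))

__all__ = ["FamilySpec", "generate_family", "generate_dataset"]


def _default_tiers(members: int, max_rate: float = 0.25) -> tuple[float, ...]:
    """One strictly increasing tier per member rank, 0 .. max_rate."""
    return tuple(np.linspace(0.0, max_rate, members))


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic family dataset.

    mutation_tiers gives one per-site substitution probability per member
    rank and must be strictly increasing so the within-family similarity
    ladder is graded. Defaults emulate mid-length plasmid-like sequences:
    300 nt ancestors, substitution rates 0–0.25, no indels.
    """

    n_families: int = 8
    members_per_family: int = 12
    ancestor_length: int = 300
    mutation_tiers: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_tiers is None:
            object.__setattr__(
                self, "mutation_tiers", _default_tiers(self.members_per_family)
            )
        tiers = tuple(float(t) for t in self.mutation_tiers)
        object.__setattr__(self, "mutation_tiers", tiers)
        if self.n_families < 1 or self.members_per_family < 1:
            raise ValueError("n_families and members_per_family must be positive")
        if self.ancestor_length < 50:
            raise ValueError("ancestor_length must be >= 50")
        if len(tiers) != self.members_per_family:
            raise ValueError("need one mutation tier per member")
        if any(not (0.0 <= t < 1.0) for t in tiers):
            raise ValueError("mutation tiers must lie in [0, 1)")
        if any(b <= a for a, b in zip(tiers, tiers[1:])):
            raise ValueError("mutation tiers must be strictly increasing")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must lie in [0, 1)")


def _mutate(ancestor: np.ndarray, rate: float, indel_rate: float,
            rng: np.random.Generator) -> str:
    seq = ancestor.copy()
    hit = rng.random(seq.size) < rate
    if hit.any():
        # substitute to a uniformly chosen *different* base: shift by 1..3 in
        # base-index space, so the result is never the original base
        idx = np.searchsorted(BASES, seq[hit])
        shift = rng.integers(1, 4, size=hit.sum())
        seq[hit] = BASES[(idx + shift) % 4]
    if indel_rate > 0.0:
        out: list[str] = []
        for c in seq:
            u = rng.random()
            if u < indel_rate / 2:
                continue  # deletion
            out.append(c)
            if u >= 1.0 - indel_rate / 2:
                out.append(str(rng.choice(BASES)))  # insertion after site
        return "".join(out) if out else str(seq[0])
    return "".join(seq)


def generate_family(spec: FamilySpec, family_index: int) -> list[DnaRecord]:
    """Generate one family: ancestor plus tier-mutated members.

    Deterministic given (spec.seed, family_index). Member ids are
    ``f{family_index}m{rank}``; the group label is ``f{family_index}``.
    """
    rng = np.random.default_rng([spec.seed, family_index])
    ancestor = rng.choice(BASES, size=spec.ancestor_length)
    group = f"f{family_index}"
    records = []
    for rank, rate in enumerate(spec.mutation_tiers):
        seq = _mutate(ancestor, rate, spec.indel_rate, rng)
        records.append(DnaRecord(id=f"{group}m{rank}", sequence=seq, group=group))
    return records


def generate_dataset(spec: FamilySpec) -> list[DnaRecord]:
    """All families of the spec, concatenated in family order."""
    out: list[DnaRecord] = []
    for fam in range(spec.n_families):
        out.extend(generate_family(spec, fam))
    return out
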