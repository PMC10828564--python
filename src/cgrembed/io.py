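"""Sequence input/output and dataset-level filtering.

Records are plain DNA sequences over {A,C,G,T} tagged with a unique id and a
group label (e.g. the pathogen a plasmid was isolated from). FASTA headers
carry both, joined by a configurable delimiter: ``>id|group``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

__all__ = [
    "DnaRecord",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "filter_small_groups",
]


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class DnaRecord:
    """One DNA sequence with a unique id and a group label."""

    id: str
    sequence: str
    group: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-ACGT characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _clean_sequence(record_id: str, raw: str, ambiguity: str) -> str | None:
    """Upper-case and apply the ambiguity policy.

    Returns the cleaned sequence, or None when the record should be dropped.
    """
    seq = raw.upper()
    bad = [c for c in seq if c not in DNA_ALPHABET]
    if not bad:
        return seq
    if ambiguity == "drop-record":
        warnings.warn(
            f"record {record_id!r}: dropped ({len(bad)} non-ACGT characters)",
            stacklevel=3,
        )
        return None
    if ambiguity == "drop-character":
        warnings.warn(
            f"record {record_id!r}: removed {len(bad)} non-ACGT characters",
            stacklevel=3,
        )
        return "".join(c for c in seq if c in DNA_ALPHABET)
    raise ValueError(f"unknown ambiguity policy {ambiguity!r}")


def read_fasta(
    path: str | Path,
    *,
    delimiter: str = "|",
    ambiguity: str = "drop-character",
) -> list[DnaRecord]:
    """Read FASTA records with ``id<delimiter>group`` headers.

    Sequences are upper-cased. Characters outside {A,C,G,T} are handled per
    the ambiguity policy: ``drop-character`` removes them (with a warning),
    ``drop-record`` discards the whole record. A header with no delimiter
    yields an empty group label.
    """
    path = Path(path)
    records: list[DnaRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise FastaFormatError(f"{path}:1: expected '>' header, got {first.strip()!r}")
        handle.seek(0)
        for entry in SeqIO.parse(handle, "fasta"):
            rec_id, _, group = entry.description.partition(delimiter)
            rec_id = rec_id.strip()
            group = group.strip()
            if rec_id in seen:
                raise FastaFormatError(f"{path}: duplicate record id {rec_id!r}")
            seq = _clean_sequence(rec_id, str(entry.seq), ambiguity)
            if seq is None:
                continue
            if not seq:
                raise FastaFormatError(
                    f"{path}: record {rec_id!r} empty after removing ambiguous characters"
                )
            seen.add(rec_id)
            records.append(DnaRecord(id=rec_id, sequence=seq, group=group))
    if not records:
        raise FastaFormatError(f"{path}: no records")
    return records


def write_fasta(
    records: list[DnaRecord], path: str | Path, *, delimiter: str = "|"
) -> Path:
    """Write records as FASTA with ``id<delimiter>group`` headers.

    Round-trips through :func:`read_fasta`.
    """
    path = Path(path)
    entries = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}{delimiter}{r.group}", description="")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(entries, handle, "fasta-2line")
    return path


def filter_small_groups(
    records: list[DnaRecord], min_count: int = 10
) -> list[DnaRecord]:
    """Drop every record whose group has ``min_count`` or fewer members.

    Outlier removal for label groups too small to carry ranking signal: a
    group survives only when strictly more than ``min_count`` records share
    its label. Order is preserved; idempotent.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    sizes = Counter(r.group for r in records)
    return [r for r in records if sizes[r.group] > min_count]
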