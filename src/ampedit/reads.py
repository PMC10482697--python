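"""FASTQ input and overlap-based merging of paired-end amplicon reads.

Amplicon libraries sequenced 2 x 150 bp with an insert shorter than twice
the read length can be merged into a single full-length sequence from the
read overlap. :func:`merge_pair` does this with a maximum-matching overlap
search and a quality-aware consensus: at an overlap disagreement the base
with the higher Phred quality wins (ties go to read 1). Pre-merged
single-end input bypasses this step entirely.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "MergeParams",
    "MergeFailure",
    "FastqParseError",
    "read_fastq",
    "read_fastq_pairs",
    "merge_pair",
    "write_fastq",
]


class FastqParseError(ValueError):
    """Malformed FASTQ record; the message names the failing record index."""


@dataclass
class ReadRecord:
    """One sequencing read (or one merged read pair)."""

    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


@dataclass(frozen=True)
class MergeParams:
    """Overlap-merger settings: minimum overlap and mismatch tolerance."""

    min_overlap: int = 20
    max_mismatch_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 <= self.max_mismatch_frac < 0.5:
            raise ValueError("max_mismatch_frac must be in [0, 0.5)")


@dataclass(frozen=True)
class MergeFailure:
    """Returned (not raised) when no admissible overlap exists."""

    read_id: str
    reason: str


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a (optionally gzipped) Phred+33 FASTQ file.

    Yields records in file order; lowercase bases are uppercased. An empty
    file yields nothing. Malformed records raise :class:`FastqParseError`
    naming the 0-based record index.
    """
    index = 0
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"{path}: record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record {index}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            yield ReadRecord(
                id=title.split()[0] if title else f"read{index}",
                sequence=seq.upper(),
                qualities=tuple(ord(c) - 33 for c in qual),
            )
            index += 1


def read_fastq_pairs(
    path1: str | Path, path2: str | Path | None = None
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Yield read pairs from two files, or from one interleaved file."""
    if path2 is not None:
        it1, it2 = read_fastq(path1), read_fastq(path2)
        for r1 in it1:
            try:
                r2 = next(it2)
            except StopIteration:
                raise FastqParseError(f"{path2} has fewer reads than {path1}") from None
            yield r1, r2
        if next(it2, None) is not None:
            raise FastqParseError(f"{path2} has more reads than {path1}")
    else:
        it = read_fastq(path1)
        for r1 in it:
            r2 = next(it, None)
            if r2 is None:
                raise FastqParseError(f"{path1}: odd read count in interleaved input")
            yield r1, r2


def _revcomp_record(r: ReadRecord) -> ReadRecord:
    quals = tuple(reversed(r.qualities)) if r.qualities is not None else None
    return ReadRecord(r.id, reverse_complement(r.sequence), quals)


def merge_pair(
    r1: ReadRecord, r2: ReadRecord, params: MergeParams = MergeParams()
) -> ReadRecord | MergeFailure:
    """Merge a read pair into one consensus read via their 3' overlap.

    ``r2`` is reverse-complemented, then every overlap length
    ``k >= min_overlap`` is scored; among overlaps with mismatch fraction
    <= ``max_mismatch_frac`` the one with the most matching bases wins
    (ties: the longer overlap). A base involving N never counts as a
    match. Returns a :class:`MergeFailure` value when no admissible
    overlap exists; merged length is ``len(r1) + len(r2) - k``.
    """
    rc2 = _revcomp_record(r2)
    s1, s2 = r1.sequence, rc2.sequence
    q1 = r1.qualities or tuple([30] * len(s1))
    q2 = rc2.qualities or tuple([30] * len(s2))

    best_k, best_matches = 0, -1
    for k in range(min(len(s1), len(s2)), params.min_overlap - 1, -1):
        tail, head = s1[-k:], s2[:k]
        matches = sum(
            a == b and a != "N" for a, b in zip(tail, head)
        )
        if (k - matches) / k <= params.max_mismatch_frac and matches > best_matches:
            best_matches, best_k = matches, k
    if best_k == 0:
        return MergeFailure(r1.id, f"no overlap >= {params.min_overlap} bp within mismatch limit")

    k = best_k
    mid_seq: list[str] = []
    mid_qual: list[int] = []
    for i in range(k):
        a, b = s1[len(s1) - k + i], s2[i]
        qa, qb = q1[len(s1) - k + i], q2[i]
        if a == b:
            mid_seq.append(a)
            mid_qual.append(max(qa, qb))
        elif qb > qa:
            mid_seq.append(b)
            mid_qual.append(qb)
        else:  # tie -> read 1
            mid_seq.append(a)
            mid_qual.append(qa)
    seq = s1[: len(s1) - k] + "".join(mid_seq) + s2[k:]
    qual = q1[: len(s1) - k] + tuple(mid_qual) + q2[k:]
    return ReadRecord(r1.id, seq, qual)


def write_fastq(records: Iterator[ReadRecord] | list[ReadRecord], path: str | Path) -> int:
    """Write Phred+33 FASTQ; reads without qualities get Q40. Returns count."""
    n = 0
    with open(path, "w") as fh:
        for r in records:
            quals = r.qualities or tuple([40] * len(r.sequence))
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{''.join(chr(q + 33) for q in quals)}\n")
            n += 1
    return n
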