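"""Pairwise alignment of merged reads to the amplicon reference.

Alignment is semi-global (affine gap penalties, terminal gaps free at both
sequence ends, so length differences at the amplicon termini are not
penalised) with defaults match +5 / mismatch -4 / gap open -20 / gap
extend -1 per additional gapped base. N in a read scores 0 against any
base and never counts as a match.

From the gapped alignment this module extracts indel and substitution
calls in reference coordinates, canonicalises indels to their unique
leftmost placement (the normalisation convention used for variant
deduplication), and restricts calls to the quantification window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import Align
from Bio.Align import substitution_matrices

from .model import AmpliconSpec, quantification_window

__all__ = [
    "IndelCall",
    "AlignmentResult",
    "VariantCalls",
    "make_aligner",
    "global_align",
    "left_align_indel",
    "extract_variants",
    "indel_cigar",
]


@dataclass(frozen=True)
class IndelCall:
    """One insertion or deletion in reference coordinates.

    For a deletion, ``ref_start`` is the first deleted reference position.
    For an insertion, ``ref_start`` is the reference position *before
    which* ``inserted_seq`` is inserted. ``ref_start`` is canonical
    (left-aligned) after :func:`left_align_indel`. ``mh_length`` is the
    deletion-junction microhomology, filled by the classify module.
    """

    kind: str  # "deletion" | "insertion"
    ref_start: int
    length: int
    inserted_seq: str = ""
    mh_length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind == "insertion" and len(self.inserted_seq) != self.length:
            raise ValueError("insertion length must match inserted_seq")

    @property
    def ref_interval(self) -> tuple[int, int]:
        """Half-open reference interval; empty for insertions."""
        if self.kind == "deletion":
            return (self.ref_start, self.ref_start + self.length)
        return (self.ref_start, self.ref_start)


@dataclass
class AlignmentResult:
    """A gapped read-vs-reference alignment plus derived variant calls.

    ``identity`` is matches / aligned columns, where terminal-gap columns
    are excluded and a column involving N is never a match.
    """

    ref_aligned: str
    read_aligned: str
    score: float
    identity: float
    indels: list[IndelCall]
    substitutions: list[tuple[int, str]]  # (ref position, read base)
    ref_base_map: dict[int, str] = field(default_factory=dict, repr=False)


def make_aligner(
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -20.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    """Configured PairwiseAligner (affine gaps, free end gaps, ACGTN matrix)."""
    m = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = match if a == b else mismatch
    for x in "ACGTN":
        m["N", x] = 0.0
        m[x, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # renamed-attribute deprecation noise
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


_DEFAULT_ALIGNER = make_aligner()


def global_align(
    reference: str, read: str, aligner: Align.PairwiseAligner | None = None
) -> AlignmentResult:
    """Align ``read`` to ``reference`` and extract raw variant calls.

    The first optimal traceback is taken (deterministic for fixed inputs);
    indels are subsequently canonicalised by :func:`left_align_indel`, so
    co-optimal gap placements collapse to one representation.
    """
    if not reference or not read:
        raise ValueError("global_align requires non-empty sequences")
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(reference, read)[0]
    ref_aligned, read_aligned = str(aln[0]), str(aln[1])
    return _parse_alignment(reference, ref_aligned, read_aligned, float(aln.score))


def _parse_alignment(
    reference: str, ref_aligned: str, read_aligned: str, score: float
) -> AlignmentResult:
    ncol = len(ref_aligned)
    # terminal-gap columns: outside the first/last column where both rows
    # carry a base
    first = next((i for i in range(ncol) if ref_aligned[i] != "-" and read_aligned[i] != "-"), ncol)
    last = next(
        (i for i in range(ncol - 1, -1, -1) if ref_aligned[i] != "-" and read_aligned[i] != "-"),
        -1,
    )

    indels: list[IndelCall] = []
    substitutions: list[tuple[int, str]] = []
    base_map: dict[int, str] = {}
    matches = 0
    aligned_cols = 0  # all columns between first and last, gaps included
    ref_pos = 0
    del_start = del_len = 0
    ins_start = 0
    ins_seq: list[str] = []
    run_start_col = 0

    def flush() -> None:
        # a gap run is a real indel only if it lies wholly inside the
        # non-terminal region; terminal runs touch the alignment ends
        nonlocal del_len, ins_seq
        internal = first <= run_start_col <= last
        if del_len and internal:
            indels.append(left_align_indel(reference, IndelCall("deletion", del_start, del_len)))
        del_len = 0
        if ins_seq and internal:
            indels.append(
                left_align_indel(
                    reference,
                    IndelCall("insertion", ins_start, len(ins_seq), "".join(ins_seq)),
                )
            )
        ins_seq = []

    for i in range(ncol):
        a, b = ref_aligned[i], read_aligned[i]
        inside = first <= i <= last
        if inside:
            aligned_cols += 1
        if a != "-" and b != "-":
            flush()
            if inside:
                if a == b and a != "N":
                    matches += 1
                elif a != b and b != "N":
                    substitutions.append((ref_pos, b))
            base_map[ref_pos] = b
            ref_pos += 1
        elif b == "-":  # deletion in read
            if ins_seq:
                flush()
            if del_len == 0:
                del_start = ref_pos
                run_start_col = i
            del_len += 1
            if inside:
                base_map[ref_pos] = "-"
            ref_pos += 1
        else:  # a == "-": insertion in read
            if del_len:
                flush()
            if not ins_seq:
                ins_start = ref_pos
                run_start_col = i
            ins_seq.append(b)
    flush()  # trailing run starts after `last`, so it is dropped as terminal

    identity = matches / aligned_cols if aligned_cols else 0.0
    return AlignmentResult(
        ref_aligned=ref_aligned,
        read_aligned=read_aligned,
        score=score,
        identity=identity,
        indels=indels,
        substitutions=substitutions,
        ref_base_map=base_map,
    )


def left_align_indel(reference: str, indel: IndelCall) -> IndelCall:
    """Shift an indel to its unique leftmost equivalent placement.

    A deletion moves left while the base preceding it equals the last
    deleted base; an insertion moves left while the preceding reference
    base equals the last inserted base (rotating the inserted sequence).
    Idempotent; an already-canonical indel is returned unchanged.
    """
    if indel.kind == "deletion":
        s, L = indel.ref_start, indel.length
        if s + L > len(reference):
            raise ValueError("deletion exceeds reference bounds")
        while s > 0 and reference[s - 1] == reference[s + L - 1]:
            s -= 1
        return replace(indel, ref_start=s) if s != indel.ref_start else indel
    s, ins = indel.ref_start, indel.inserted_seq
    while s > 0 and reference[s - 1] == ins[-1]:
        ins = reference[s - 1] + ins[:-1]
        s -= 1
    if s == indel.ref_start:
        return indel
    return replace(indel, ref_start=s, inserted_seq=ins)


@dataclass
class VariantCalls:
    """Window-restricted calls from one read alignment."""

    in_window_indels: list[IndelCall]
    off_window_indels: int
    donor_present: tuple[bool, ...]
    substitutions: list[tuple[int, str]]


def _insertion_in_window(indel: IndelCall, window: frozenset[int]) -> bool:
    # an insertion sits between positions ref_start-1 and ref_start
    return indel.ref_start in window or (indel.ref_start - 1) in window


def extract_variants(alignment: AlignmentResult, spec: AmpliconSpec) -> VariantCalls:
    """Split indels by quantification window and score donor-edit presence.

    A deletion is in-window when its reference interval intersects the
    window; an insertion when either flanking position does. A donor edit
    is present iff the read base aligned to its position equals the donor
    alt base (a gap or unaligned position counts as absent). Non-donor
    substitutions are recorded but, being putative sequencing errors,
    never influence classification.
    """
    window = quantification_window(spec)
    in_window: list[IndelCall] = []
    off_window = 0
    for indel in alignment.indels:
        if indel.kind == "deletion":
            lo, hi = indel.ref_interval
            hit = any(p in window for p in range(lo, hi))
        else:
            hit = _insertion_in_window(indel, window)
        if hit:
            in_window.append(indel)
        else:
            off_window += 1
    donor_positions = {e.position for e in spec.donor_edits}
    donor_present = tuple(
        alignment.ref_base_map.get(e.position) == e.alt_base for e in spec.donor_edits
    )
    subs = [(p, b) for p, b in alignment.substitutions if p not in donor_positions]
    return VariantCalls(in_window, off_window, donor_present, subs)


def indel_cigar(indels: list[IndelCall]) -> str:
    """Compact descriptor like ``104D3;150I2:GG`` for per-read reports."""
    parts = []
    for x in indels:
        if x.kind == "deletion":
            parts.append(f"{x.ref_start}D{x.length}")
        else:
            parts.append(f"{x.ref_start}I{x.length}:{x.inserted_seq}")
    return ";".join(parts) if parts else "."
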