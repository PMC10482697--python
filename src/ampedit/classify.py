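"""Per-read editing-outcome classification.

Each retained read is assigned one category:

* ``WT`` — no indel in the quantification window, donor edit(s) absent;
* ``HDR`` — all donor substitutions present, no in-window indel, and
  high identity to the expected HDR allele;
* ``PARTIAL_HDR`` — a proper subset of (multiple) donor substitutions,
  no in-window indel;
* ``IMPERFECT_HDR`` — donor substitution(s) together with an in-window
  indel;
* ``MMEJ`` — insertion-free in-window indels whose maximum deletion-
  junction microhomology reaches the MMEJ threshold (default >= 2 bp);
* ``NHEJ`` — any other in-window indel (insertions, or deletions with
  sub-threshold microhomology);
* ``DISCARDED`` — identity below the retention threshold against both
  the wild-type and the HDR allele.

The microhomology of a deletion is the length of the sequence at one end
of the deletion that is identical to the undeleted sequence at the other
end; equivalently, the number of alternative placements of the same
deletion minus one. It is computed on the canonical left-aligned
placement as the match length of the right-side flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Align import PairwiseAligner

from .align import (
    AlignmentResult,
    IndelCall,
    VariantCalls,
    extract_variants,
    global_align,
)
from .model import AmpliconSpec, hdr_reference

CATEGORIES = ("WT", "HDR", "PARTIAL_HDR", "IMPERFECT_HDR", "NHEJ", "MMEJ")
ALL_CATEGORIES = CATEGORIES + ("DISCARDED",)

__all__ = ["OutcomeCall", "mh_length", "classify_read", "call_read", "CATEGORIES", "ALL_CATEGORIES"]


def mh_length(reference: str, del_start: int, del_len: int) -> int:
    """Deletion-junction microhomology of a left-aligned deletion.

    Returns the maximal ``k >= 0`` such that the first ``k`` deleted bases
    equal the first ``k`` bases retained after the deletion, i.e.
    ``reference[del_start : del_start + k] ==
    reference[del_start + del_len : del_start + del_len + k]``, bounded
    only by the reference end. This equals the number of equivalent
    placements of the deletion minus one, and may exceed the deletion
    length for contractions of tandem repeats.

    Raises ``ValueError`` if the deletion is out of bounds or not
    left-aligned (a left-shiftable deletion has no canonical junction).
    """
    if del_start < 0 or del_len < 1 or del_start + del_len > len(reference):
        raise ValueError("deletion outside reference bounds")
    if del_start > 0 and reference[del_start - 1] == reference[del_start + del_len - 1]:
        raise ValueError(
            f"deletion at {del_start}+{del_len} is not left-aligned canonical"
        )
    k = 0
    n = len(reference)
    while del_start + del_len + k < n and reference[del_start + k] == reference[del_start + del_len + k]:
        k += 1
    return k


@dataclass
class OutcomeCall:
    """Classification of one read, with the evidence behind it."""

    category: str
    identity_to_wt: float
    identity_to_hdr: float
    in_window_indels: list[IndelCall]
    donor_edits_present: int
    max_deletion_mh: int | None
    read_id: str = ""

    @property
    def has_insertion(self) -> bool:
        return any(x.kind == "insertion" for x in self.in_window_indels)

    @property
    def has_deletion(self) -> bool:
        return any(x.kind == "deletion" for x in self.in_window_indels)


def classify_read(
    aln_wt: AlignmentResult,
    aln_hdr: AlignmentResult | None,
    spec: AmpliconSpec,
    read_id: str = "",
) -> OutcomeCall:
    """Assign an outcome category from alignments to the WT and HDR alleles.

    ``aln_hdr`` may be None when the spec defines no donor edits (the two
    alleles coincide). Decision order: retention filter first, then the
    indel-free branch (HDR / PARTIAL_HDR / WT), then the indel branch
    (IMPERFECT_HDR / MMEJ / NHEJ).
    """
    t = spec.thresholds
    id_wt = aln_wt.identity
    id_hdr = aln_hdr.identity if aln_hdr is not None else id_wt

    variants = extract_variants(aln_wt, spec)
    indels = [
        replace(x, mh_length=mh_length(spec.reference, x.ref_start, x.length))
        if x.kind == "deletion"
        else x
        for x in variants.in_window_indels
    ]
    mh_values = [x.mh_length for x in indels if x.kind == "deletion"]
    max_mh: int | None = max(mh_values) if mh_values else None
    n_present = sum(variants.donor_present)
    n_edits = len(spec.donor_edits)

    if max(id_wt, id_hdr) < t.min_read_similarity:
        category = "DISCARDED"
    elif not indels:
        if n_edits and n_present == n_edits and id_hdr >= t.hdr_similarity:
            category = "HDR"
        elif 0 < n_present < n_edits:
            category = "PARTIAL_HDR"
        else:
            category = "WT"
    elif n_present > 0:
        category = "IMPERFECT_HDR"
    elif (
        not any(x.kind == "insertion" for x in indels)
        and max_mh is not None
        and max_mh >= t.mmej_min_mh
    ):
        category = "MMEJ"
    else:
        category = "NHEJ"

    return OutcomeCall(
        category=category,
        identity_to_wt=id_wt,
        identity_to_hdr=id_hdr,
        in_window_indels=indels,
        donor_edits_present=n_present,
        max_deletion_mh=max_mh,
        read_id=read_id,
    )


def call_read(
    read_sequence: str,
    spec: AmpliconSpec,
    aligner: PairwiseAligner | None = None,
    hdr_ref: str | None = None,
    read_id: str = "",
) -> OutcomeCall:
    """Convenience wrapper: align a read to both alleles and classify it."""
    aln_wt = global_align(spec.reference, read_sequence, aligner)
    aln_hdr = None
    if spec.donor_edits:
        if hdr_ref is None:
            hdr_ref = hdr_reference(spec)
        aln_hdr = global_align(hdr_ref, read_sequence, aligner)
    return classify_read(aln_wt, aln_hdr, spec, read_id=read_id)
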