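import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampedit import (
    AmpliconSpec,
    DonorEdit,
    IndelCall,
    extract_variants,
    global_align,
    left_align_indel,
)
from ampedit.simulate import make_reference

REF = make_reference(300, 0.5, seed=42)


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align(REF, REF)
        assert aln.identity == 1.0
        assert aln.indels == [] and aln.substitutions == []

    def test_single_deletion_recovered(self):
        read = REF[:100] + REF[103:]
        aln = global_align(REF, read)
        assert len(aln.indels) == 1
        d = aln.indels[0]
        assert d.kind == "deletion" and d.length == 3
        # canonical: equals the left-aligned placement of the constructed one
        assert d == left_align_indel(REF, IndelCall("deletion", 100, 3))

    def test_single_insertion_recovered(self):
        read = REF[:150] + "GG" + REF[150:]
        aln = global_align(REF, read)
        assert len(aln.indels) == 1
        ins = aln.indels[0]
        assert ins.kind == "insertion" and ins.length == 2
        assert ins == left_align_indel(REF, IndelCall("insertion", 150, 2, "GG"))

    def test_identity_drops_linearly_with_substitutions(self, rng):
        k = 12
        pos = rng.choice(len(REF), size=k, replace=False)
        read = list(REF)
        for p in pos:
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        aln = global_align(REF, "".join(read))
        assert aln.identity == pytest.approx(1 - k / len(REF))
        assert len(aln.substitutions) == k

    def test_read_substring_has_free_terminal_gaps(self):
        aln = global_align(REF, REF[50:250])
        assert aln.identity == 1.0
        assert aln.indels == []

    def test_n_never_counts_as_match(self):
        read = REF[:10] + "N" + REF[11:]
        aln = global_align(REF, read)
        assert aln.identity == pytest.approx(1 - 1 / len(REF))
        assert aln.substitutions == []  # N is not a substitution call

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align(REF, "")

    def test_random_single_indels_recovered_canonically(self, rng):
        """Reads built from one known indel yield exactly that call back."""
        for _ in range(300):
            L = int(rng.integers(1, 21))
            if rng.random() < 0.5:
                s = int(rng.integers(30, len(REF) - 30 - L))
                read = REF[:s] + REF[s + L :]
                expected = left_align_indel(REF, IndelCall("deletion", s, L))
            else:
                s = int(rng.integers(30, len(REF) - 30))
                ins = "".join(rng.choice(list("ACGT"), L))
                read = REF[:s] + ins + REF[s:]
                expected = left_align_indel(REF, IndelCall("insertion", s, L, ins))
            aln = global_align(REF, read)
            assert aln.indels == [expected], (s, L)

    def test_score_consistent_with_gapped_strings(self):
        read = REF[:80] + REF[86:200] + "TT" + REF[200:]
        aln = global_align(REF, read)
        score = 0.0
        in_gap = False
        for a, b in zip(aln.ref_aligned, aln.read_aligned):
            if a == "-" or b == "-":
                score += -1.0 if in_gap else -20.0
                in_gap = True
            else:
                in_gap = False
                if a == "N" or b == "N":
                    continue
                score += 5.0 if a == b else -4.0
        assert score == aln.score  # no terminal gaps in this construction


class TestLeftAlign:
    def test_shift_through_tandem_repeat(self):
        ref = "TTTAGCAGCTTT"
        out = left_align_indel(ref, IndelCall("deletion", 6, 3))
        assert out.ref_start == 3

    def test_already_canonical_unchanged(self):
        ref = "AAACCCGGGTTT"
        d = IndelCall("deletion", 3, 3)
        assert left_align_indel(ref, d) is d

    def test_idempotent(self):
        ref = "TTTAGCAGCTTT"
        once = left_align_indel(ref, IndelCall("deletion", 6, 3))
        assert left_align_indel(ref, once) == once

    def test_insertion_rotation(self):
        # inserting "A" after a run of A's slides to the run start
        ref = "GGGAAAATTTGGGGGGGGGGGGGGGGGGGGGGGGGGGGGG"
        out = left_align_indel(ref, IndelCall("insertion", 7, 1, "A"))
        assert out.ref_start == 3 and out.inserted_seq == "A"

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_idempotence_property(self, seed):
        r = np.random.default_rng(seed)
        ref = "".join(r.choice(list("ACGT"), 60))
        L = int(r.integers(1, 10))
        s = int(r.integers(1, 60 - L))
        once = left_align_indel(ref, IndelCall("deletion", s, L))
        assert left_align_indel(ref, once) == once
        # equivalence: deleting at either placement yields the same string
        assert ref[:s] + ref[s + L :] == ref[: once.ref_start] + ref[once.ref_start + L :]


@pytest.fixture(scope="module")
def win_spec():
    return AmpliconSpec(
        "t", REF, (150,), (DonorEdit(146, REF[146], "ACGT"["ACGT".index(REF[146]) - 1]),)
    )


class TestExtractVariants:

    def test_off_window_deletion_not_counted(self, win_spec):
        read = REF[:5] + REF[9:]  # deletion at 5..8, window is 130..169
        calls = extract_variants(global_align(REF, read), win_spec)
        assert calls.in_window_indels == [] and calls.off_window_indels == 1

    def test_donor_edit_presence(self, win_spec):
        alt = win_spec.donor_edits[0].alt_base
        read = REF[:146] + alt + REF[147:]
        calls = extract_variants(global_align(REF, read), win_spec)
        assert calls.donor_present == (True,)
        # the donor position is excluded from the generic substitution list
        assert calls.substitutions == []

    def test_deletion_spanning_window_edge_counts(self, win_spec):
        # window starts at 130; deletion 125..134 intersects it
        read = REF[:125] + REF[135:]
        calls = extract_variants(global_align(REF, read), win_spec)
        assert calls.off_window_indels == 0
        assert len(calls.in_window_indels) == 1
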