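import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ampedit import (
    AmpliconSpec,
    ClassifyThresholds,
    DonorEdit,
    call_read,
    hdr_reference,
    mh_length,
)
from ampedit.align import IndelCall, left_align_indel
from ampedit.simulate import make_reference


def mh_oracle(reference: str, del_start: int, del_len: int) -> int:
    """Placement-enumeration oracle: the number of same-length deletion
    windows producing the identical resulting sequence, minus one."""
    target = reference[:del_start] + reference[del_start + del_len :]
    count = sum(
        reference[:s] + reference[s + del_len :] == target
        for s in range(len(reference) - del_len + 1)
    )
    return count - 1


def random_canonical_deletion(r, ref_len_range=(100, 300), del_len_range=(1, 30)):
    n = int(r.integers(*ref_len_range))
    ref = "".join(r.choice(list("ACGT"), n))
    L = int(r.integers(del_len_range[0], del_len_range[1] + 1))
    s = int(r.integers(0, n - L))
    canon = left_align_indel(ref, IndelCall("deletion", s, L))
    return ref, canon.ref_start, L


class TestMhLength:
    def test_no_flanking_repeat(self):
        assert mh_length("AAACCCGGGTTT", 3, 3) == 0

    def test_tandem_repeat_contraction(self):
        # deleting one AGC from a 2x repeat: MH equals the repeat length,
        # and there are 4 equivalent placements of the same deletion
        assert mh_length("TTTAGCAGCTTT", 3, 3) == 3
        assert mh_oracle("TTTAGCAGCTTT", 3, 3) == 3

    def test_three_bp_flank_match(self):
        assert mh_length("CCATGTTTATGCC", 2, 6) == 3

    def test_non_canonical_input_rejected(self):
        # deletion at 6 shifts left through the AGC repeat
        with pytest.raises(ValueError, match="left-aligned"):
            mh_length("TTTAGCAGCTTT", 6, 3)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            mh_length("ACGTACGT" * 10, 75, 10)

    @given(st.integers(0, 10_000_000))
    @settings(max_examples=300, deadline=None)
    def test_equals_placement_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        ref, s, L = random_canonical_deletion(r)
        assert mh_length(ref, s, L) == mh_oracle(ref, s, L)

    def test_invariant_to_distant_bases(self, rng):
        for _ in range(50):
            ref, s, L = random_canonical_deletion(rng, (120, 200), (1, 15))
            mh = mh_length(ref, s, L)
            hi = min(len(ref), s + 2 * L + mh + 1)
            lo = max(0, s - 1)
            # scramble everything outside [lo, hi)
            scrambled = (
                "".join(rng.choice(list("ACGT"), lo)) + ref[lo:hi]
                + "".join(rng.choice(list("ACGT"), len(ref) - hi))
            )
            assert mh_length(scrambled, s, L) == mh


@pytest.fixture(scope="module")
def eng_spec():
    ref = make_reference(250, 0.5, seed=5)
    ref = ref[:119] + "CATTTG" + "ACG" + "CATCCG" + ref[134:]
    return AmpliconSpec("eng", ref, (125,), ())


class TestClassifyRead:

    def test_wildtype(self, eng_spec):
        assert call_read(eng_spec.reference, eng_spec).category == "WT"

    def test_hdr_read(self):
        ref = make_reference(250, 0.5, seed=6)
        spec = AmpliconSpec(
            "d", ref, (125,), (DonorEdit(121, ref[121], "ACGT"["ACGT".index(ref[121]) - 1]),)
        )
        assert call_read(hdr_reference(spec), spec).category == "HDR"

    def test_mh0_deletion_is_nhej_and_engineered_repeat_is_mmej(self):
        base = make_reference(250, 0.5, seed=7)
        # engineer: positions 120..134 = CAT TTG CAT then unique flank
        ref = base[:120] + "CATTTGCATGGAACC" + base[135:]
        spec = AmpliconSpec("eng", ref, (125,), ())
        # deletion of 126..131 ("CATGGA"? construct precisely): delete 6 bp
        # starting at 123 ("TTGCAT"): flanks CAT == CAT -> MH 3
        d_mmej = left_align_indel(ref, IndelCall("deletion", 123, 6))
        assert mh_length(ref, d_mmej.ref_start, 6) >= 2
        read = ref[: d_mmej.ref_start] + ref[d_mmej.ref_start + 6 :]
        assert call_read(read, spec).category == "MMEJ"
        # an MH-0 deletion at the same cut is NHEJ
        for s in range(118, 126):
            d = left_align_indel(ref, IndelCall("deletion", s, 4))
            if mh_length(ref, d.ref_start, 4) == 0:
                read = ref[: d.ref_start] + ref[d.ref_start + 4 :]
                assert call_read(read, spec).category == "NHEJ"
                break
        else:
            pytest.fail("no MH-0 deletion found near cut")

    def test_insertion_is_always_nhej(self, eng_spec):
        read = eng_spec.reference[:125] + "TTACG" + eng_spec.reference[125:]
        call = call_read(read, eng_spec)
        assert call.category == "NHEJ"
        assert call.has_insertion

    def test_donor_plus_indel_is_imperfect_hdr(self):
        ref = make_reference(250, 0.5, seed=8)
        spec = AmpliconSpec(
            "d", ref, (125,), (DonorEdit(110, ref[110], "ACGT"["ACGT".index(ref[110]) - 1]),)
        )
        h = hdr_reference(spec)
        read = h[:130] + h[132:]  # 2 bp deletion at the cut, donor intact
        assert call_read(read, spec).category == "IMPERFECT_HDR"

    def test_low_identity_discarded(self, eng_spec):
        ref = eng_spec.reference
        k = 88  # 88/250 = 35.2% mismatches -> identity 64.8%
        pos = np.linspace(0, 249, k, dtype=int)
        read = list(ref)
        for p in pos:
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        assert call_read("".join(read), eng_spec).category == "DISCARDED"

    def test_partial_hdr_with_two_donor_edits(self):
        ref = make_reference(250, 0.5, seed=9)
        edits = tuple(
            DonorEdit(p, ref[p], "ACGT"["ACGT".index(ref[p]) - 1]) for p in (118, 121)
        )
        spec = AmpliconSpec("d2", ref, (125,), edits)
        one = ref[:118] + edits[0].alt_base + ref[119:]
        assert call_read(one, spec).category == "PARTIAL_HDR"

    def test_raising_mmej_threshold_never_increases_mmej(self, errorfree_sim):
        from dataclasses import replace
        from ampedit.classify import classify_read
        from ampedit.align import global_align
        from ampedit import hdr_reference as hdrref

        spec = errorfree_sim.spec
        h = hdrref(spec)
        alns = [
            (global_align(spec.reference, r.sequence), global_align(h, r.sequence))
            for r in errorfree_sim.reads[:400]
        ]
        counts = []
        for thr in (1, 2, 3, 4, 5):
            s = replace(spec, thresholds=replace(spec.thresholds, mmej_min_mh=thr))
            n = sum(classify_read(a, b, s).category == "MMEJ" for a, b in alns)
            counts.append(n)
        assert counts == sorted(counts, reverse=True)
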