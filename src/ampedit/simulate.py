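"""Ground-truth-labelled synthetic data for every pipeline stage.

Reads are generated from configurable outcome proportions. Each category
is constructed so that it satisfies the classifier's own definition, and
MMEJ deletions are drawn from flanking repeats actually present in (or,
if necessary, engineered into) the reference and re-verified with the
microhomology statistic — the generator never trusts its own
construction. Deletion midpoints are centred on a randomly chosen cut
site with ±3 bp jitter, mimicking cut-proximal repair. Sequencing error
is substitution-only (no indel errors), so truth labels stay exact.

Droplet counts are drawn per droplet from Poisson occupancy at known
target/reference concentrations.

All randomness flows through a single seeded ``numpy.random.Generator``
(PCG64), so every artifact is bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .align import IndelCall, left_align_indel
from .classify import call_read, mh_length
from .ddpcr import DdpcrWell
from .model import AmpliconSpec, DonorEdit, hdr_reference, quantification_window
from .reads import ReadRecord

__all__ = [
    "ReadSimConfig",
    "ReadTruth",
    "WellTruth",
    "SimReads",
    "GenerationError",
    "make_reference",
    "example_spec",
    "simulate_reads",
    "simulate_droplets",
]

BASES = np.array(list("ACGT"))

DEFAULT_PROPORTIONS = {
    "WT": 0.05,
    "HDR": 0.60,
    "PARTIAL_HDR": 0.0,
    "IMPERFECT_HDR": 0.05,
    "NHEJ": 0.15,
    "MMEJ": 0.15,
}

CUT_JITTER = 3  # bp of jitter around the cut site for indel midpoints


class GenerationError(RuntimeError):
    """The requested outcome mix cannot be realised on this reference."""


@dataclass(frozen=True)
class ReadSimConfig:
    """Settings for the amplicon read simulator (seed is mandatory)."""

    spec: AmpliconSpec
    n_reads: int
    seed: int
    proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    del_len_range: tuple[int, int] = (1, 20)
    ins_len_range: tuple[int, int] = (1, 5)
    mmej_mh_range: tuple[int, int] = (2, 6)
    error_rate: float = 0.001
    paired_end: bool = False
    read_length: int = 150

    def __post_init__(self) -> None:
        props = dict(DEFAULT_PROPORTIONS, **self.proportions)
        unknown = set(props) - set(DEFAULT_PROPORTIONS)
        if unknown:
            raise ValueError(f"unknown outcome categories: {sorted(unknown)}")
        if any(v < 0 for v in props.values()) or abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("proportions must be >= 0 and sum to 1")
        if props["PARTIAL_HDR"] > 0 and len(self.spec.donor_edits) < 2:
            raise ValueError("PARTIAL_HDR requires >= 2 donor edits")
        if (props["HDR"] > 0 or props["IMPERFECT_HDR"] > 0) and not self.spec.donor_edits:
            raise ValueError("HDR outcomes require at least one donor edit")
        if self.mmej_mh_range[0] < self.spec.thresholds.mmej_min_mh:
            raise ValueError("mmej_mh_range must start at or above mmej_min_mh")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        object.__setattr__(self, "proportions", props)


@dataclass(frozen=True)
class ReadTruth:
    """Ground-truth label for one simulated read."""

    read_id: str
    category: str
    del_start: int | None = None
    del_len: int | None = None
    mh: int | None = None
    has_insertion: bool = False


@dataclass(frozen=True)
class WellTruth:
    """Ground truth for one simulated ddPCR well."""

    clone_id: str
    lambda_target: float
    lambda_ref: float


@dataclass
class SimReads:
    """Simulated reads (merged, and optionally as 2x150 pairs) + truth."""

    reads: list[ReadRecord]
    pairs: list[tuple[ReadRecord, ReadRecord]] | None
    truth: list[ReadTruth]
    spec: AmpliconSpec
    reference_modified: bool = False


def make_reference(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """Random reference sequence with the given expected GC content."""
    if length < 60:
        raise ValueError("reference length must be >= 60")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    return "".join(rng.choice(BASES, size=length, p=p))


def example_spec(
    seed: int = 0,
    length: int = 250,
    n_donor_edits: int = 1,
    name: str = "sim_amplicon",
) -> AmpliconSpec:
    """A ready-to-use single-cut experiment on a random reference.

    The cut sits mid-amplicon and the donor substitution(s) sit a few bp
    5' of it, inside the protospacer, acting as blocking mutations.
    """
    ref = make_reference(length, 0.5, seed)
    cut = length // 2
    edits = []
    for i in range(n_donor_edits):
        pos = cut - 4 - 3 * i
        ref_base = ref[pos]
        alt = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        edits.append(DonorEdit(pos, ref_base, alt))
    return AmpliconSpec(name=name, reference=ref, cut_sites=(cut,), donor_edits=tuple(edits))


# ---------------------------------------------------------------------------
# deletion candidates


@dataclass(frozen=True)
class _DelCandidate:
    start: int  # left-aligned canonical
    length: int
    mh: int


def _deletion_candidates(
    spec: AmpliconSpec, del_len_range: tuple[int, int]
) -> list[_DelCandidate]:
    """All cut-proximal, in-window, canonically placed deletions."""
    ref = spec.reference
    window = quantification_window(spec)
    seen: set[tuple[int, int]] = set()
    out: list[_DelCandidate] = []
    for cut in spec.cut_sites:
        for j in range(-CUT_JITTER, CUT_JITTER + 1):
            for L in range(del_len_range[0], del_len_range[1] + 1):
                s = cut + j - L // 2
                if s < 1 or s + L > len(ref) - 1:
                    continue
                canon = left_align_indel(ref, IndelCall("deletion", s, L))
                key = (canon.ref_start, L)
                if key in seen:
                    continue
                seen.add(key)
                if not any(p in window for p in range(canon.ref_start, canon.ref_start + L)):
                    continue
                out.append(_DelCandidate(canon.ref_start, L, mh_length(ref, canon.ref_start, L)))
    return out


def _engineer_mh_repeat(spec: AmpliconSpec, mh: int = 3, del_len: int = 6) -> AmpliconSpec:
    """Install a flanking repeat at the first cut site so an MMEJ deletion
    exists; used only when the supplied reference has none."""
    ref = list(spec.reference)
    c = spec.cut_sites[0]
    del_len = max(del_len, mh + 1)
    s = c - del_len // 2
    if s < 2 or s + del_len + mh > len(ref) - 2:
        raise GenerationError("reference too short to engineer an MMEJ repeat")
    for k in range(mh):
        ref[s + del_len + k] = ref[s + k]
    # cap the repeat at exactly mh so it cannot overshoot the target range
    if ref[s + del_len + mh] == ref[s + mh]:
        ref[s + del_len + mh] = "A" if ref[s + mh] != "A" else "C"
    # keep the construction left-aligned: break any accidental shiftability
    if ref[s - 1] == ref[s + del_len - 1]:
        ref[s - 1] = "A" if ref[s + del_len - 1] != "A" else "C"
    return spec.with_reference("".join(ref))


# ---------------------------------------------------------------------------
# read construction


def _donor_safe(c: _DelCandidate, donor_positions: list[int]) -> bool:
    # expanded by the equivalent-placement span + margin so the aligner
    # cannot slide the gap over a donor base
    lo = c.start - 2
    hi = c.start + c.length + c.mh + 2
    return not any(lo <= p < hi for p in donor_positions)


def _apply_deletion(seq: str, c: _DelCandidate) -> str:
    return seq[: c.start] + seq[c.start + c.length :]


def _random_insertion(
    rng: np.random.Generator,
    spec: AmpliconSpec,
    ins_len_range: tuple[int, int],
    donor_positions: list[int],
) -> tuple[int, str]:
    """An in-window insertion point and sequence, canonical placement kept
    clear of donor positions."""
    ref = spec.reference
    window = quantification_window(spec)
    for _ in range(200):
        cut = int(rng.choice(np.asarray(spec.cut_sites)))
        p = cut + int(rng.integers(-CUT_JITTER, CUT_JITTER + 1))
        L = int(rng.integers(ins_len_range[0], ins_len_range[1] + 1))
        seq = "".join(rng.choice(BASES, size=L))
        if not 1 <= p <= len(ref) - 1:
            continue
        canon = left_align_indel(ref, IndelCall("insertion", p, L, seq))
        if canon.ref_start not in window:
            continue
        # keep the equivalent-placement span (plus 1 bp margin) clear of
        # donor positions so the aligner cannot absorb a donor base into
        # the inserted gap
        if any(canon.ref_start - 2 <= d <= p + 1 for d in donor_positions):
            continue
        return p, seq
    raise GenerationError("could not place an in-window insertion")


def simulate_reads(config: ReadSimConfig) -> SimReads:
    """Draw reads from the configured outcome proportions, with truth.

    Category counts are multinomial; per-base substitution errors are
    applied after construction. If MMEJ reads are requested but the
    reference has no suitable cut-proximal flanking repeat, a repeat is
    engineered into the reference first and the returned spec (with
    ``reference_modified=True``) reflects that.
    """
    rng = np.random.default_rng(config.seed)
    spec = config.spec
    modified = False

    cands = _deletion_candidates(spec, config.del_len_range)
    lo_mh, hi_mh = config.mmej_mh_range
    mmej = [c for c in cands if lo_mh <= c.mh <= hi_mh]
    if config.proportions["MMEJ"] > 0 and not mmej:
        spec = _engineer_mh_repeat(spec, mh=lo_mh)
        modified = True
        cands = _deletion_candidates(spec, config.del_len_range)
        mmej = [c for c in cands if lo_mh <= c.mh <= hi_mh]
        if not mmej:
            raise GenerationError(
                "no MMEJ-compatible deletion exists even after engineering a repeat"
            )
    nhej_del = [c for c in cands if c.mh < spec.thresholds.mmej_min_mh]
    donor_pos = [e.position for e in spec.donor_edits]
    imperfect_del = [c for c in cands if _donor_safe(c, donor_pos)]

    ref = spec.reference
    hdr_ref = hdr_reference(spec)
    order = list(DEFAULT_PROPORTIONS)
    counts = rng.multinomial(config.n_reads, [config.proportions[k] for k in order])
    labels = np.repeat(np.arange(len(order)), counts)
    rng.shuffle(labels)

    reads: list[ReadRecord] = []
    truth: list[ReadTruth] = []
    for i, li in enumerate(labels):
        cat = order[int(li)]
        read_id = f"read{i:06d}"
        for attempt in range(20):
            del_c: _DelCandidate | None = None
            has_ins = False
            if cat == "WT":
                seq = ref
            elif cat == "HDR":
                seq = hdr_ref
            elif cat == "PARTIAL_HDR":
                k = int(rng.integers(1, len(spec.donor_edits)))
                subset = rng.choice(len(spec.donor_edits), size=k, replace=False)
                s = list(ref)
                for idx in subset:
                    e = spec.donor_edits[int(idx)]
                    s[e.position] = e.alt_base
                seq = "".join(s)
            elif cat == "MMEJ":
                del_c = mmej[int(rng.integers(len(mmej)))]
                seq = _apply_deletion(ref, del_c)
            elif cat == "NHEJ":
                use_ins = not nhej_del or rng.random() < 0.5
                if use_ins:
                    p, ins = _random_insertion(rng, spec, config.ins_len_range, donor_pos)
                    seq = ref[:p] + ins + ref[p:]
                    has_ins = True
                else:
                    del_c = nhej_del[int(rng.integers(len(nhej_del)))]
                    seq = _apply_deletion(ref, del_c)
            elif cat == "IMPERFECT_HDR":
                if not imperfect_del or rng.random() < 0.5:
                    p, ins = _random_insertion(rng, spec, config.ins_len_range, donor_pos)
                    seq = hdr_ref[:p] + ins + hdr_ref[p:]
                    has_ins = True
                else:
                    del_c = imperfect_del[int(rng.integers(len(imperfect_del)))]
                    seq = _apply_deletion(hdr_ref, del_c)
            else:  # pragma: no cover
                raise AssertionError(cat)

            if del_c is not None:
                # re-verify the construction against the classifier's own
                # microhomology definition rather than trusting it
                assert mh_length(ref, del_c.start, del_c.length) == del_c.mh
            if not has_ins or call_read(seq, spec, hdr_ref=hdr_ref).category == cat:
                break
            # rare: the random inserted bases allow a score-equivalent
            # alignment that absorbs a donor base; redraw the insertion
        else:
            raise GenerationError(f"could not construct an unambiguous {cat} read")
        seq = _apply_errors(rng, seq, config.error_rate)
        reads.append(ReadRecord(read_id, seq, tuple([40] * len(seq))))
        truth.append(
            ReadTruth(
                read_id=read_id,
                category=cat,
                del_start=del_c.start if del_c else None,
                del_len=del_c.length if del_c else None,
                mh=del_c.mh if del_c else None,
                has_insertion=has_ins,
            )
        )

    pairs = [_fragment(r, config.read_length) for r in reads] if config.paired_end else None
    return SimReads(reads=reads, pairs=pairs, truth=truth, spec=spec, reference_modified=modified)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in positions:
        p = int(p)
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[int(rng.integers(3))]
    return "".join(s)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _fragment(read: ReadRecord, read_length: int) -> tuple[ReadRecord, ReadRecord]:
    """Cut a merged amplicon into an overlapping 2 x ``read_length`` pair."""
    seq = read.sequence
    r1 = seq[:read_length]
    r2 = _revcomp(seq[-read_length:])
    q1 = tuple([40] * len(r1))
    q2 = tuple([40] * len(r2))
    return (
        ReadRecord(read.id, r1, q1),
        ReadRecord(read.id, r2, q2),
    )


def simulate_droplets(
    n_droplets: int,
    lambda_target: float,
    lambda_ref: float,
    seed: int | np.random.Generator,
    clone_id: str = "well1",
) -> tuple[DdpcrWell, WellTruth]:
    """Simulate one ddPCR well: per-droplet Poisson occupancy per channel.

    Negative droplets are those with zero molecules of the channel's
    template. ``seed`` may be an integer or an existing Generator (so
    many wells can share one stream).
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if lambda_target < 0 or lambda_ref < 0:
        raise ValueError("concentrations must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    neg_t = int((rng.poisson(lambda_target, n_droplets) == 0).sum())
    neg_r = int((rng.poisson(lambda_ref, n_droplets) == 0).sum())
    well = DdpcrWell(clone_id, n_droplets, neg_t, n_droplets, neg_r)
    return well, WellTruth(clone_id, lambda_target, lambda_ref)
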