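"""Droplet digital PCR: Poisson-corrected copy number with 95% CIs and
clone-level genotype / on-target-effect calls.

Template molecules are partitioned into ~20,000 droplets; with mean
occupancy lambda per droplet the fraction of negative (empty) droplets is
exp(-lambda), so lambda = -ln(negative/total). The diploid-normalised
copy number of the target locus is

    cn = 2 * lambda_target / lambda_reference

(the reference gene is assumed diploid). The 95% CI comes from the delta
method on the binomial negative fraction per channel, propagated on the
log-ratio scale — the standard construction for digital-PCR
concentration ratios.

A clone whose CI upper bound falls below ``loss_threshold`` (default
1.5, the midpoint between one and two copies) is flagged as a copy-number
loss, the signature of an unintended on-target event such as a large
deletion or rearrangement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .align import IndelCall, global_align
from .classify import OutcomeCall, call_read
from .model import AmpliconSpec

__all__ = [
    "DdpcrWell",
    "CopyNumberEstimate",
    "CloneRecord",
    "SaturationError",
    "poisson_lambda",
    "copy_number",
    "call_clone",
    "read_wells",
    "clone_table_header",
    "clone_table_row",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

LOW_DROPLET_WARNING = 1000


class SaturationError(ValueError):
    """All droplets positive: lambda is unbounded, the well is saturated."""


@dataclass(frozen=True)
class DdpcrWell:
    """Droplet counts for one well, target and reference channel."""

    clone_id: str
    target_total: int
    target_negative: int
    ref_total: int
    ref_negative: int

    def __post_init__(self) -> None:
        for total, neg, ch in (
            (self.target_total, self.target_negative, "target"),
            (self.ref_total, self.ref_negative, "reference"),
        ):
            if total < 1:
                raise ValueError(f"{self.clone_id}: {ch} droplet total must be >= 1")
            if not 0 <= neg <= total:
                raise ValueError(f"{self.clone_id}: {ch} negative count outside [0, total]")
            if total < LOW_DROPLET_WARNING:
                warnings.warn(
                    f"{self.clone_id}: only {total} {ch} droplets; "
                    f">= {LOW_DROPLET_WARNING} recommended",
                    stacklevel=2,
                )


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Diploid-normalised copy number with a 95% confidence interval."""

    lambda_target: float
    lambda_ref: float
    cn: float
    ci_low: float
    ci_high: float


def poisson_lambda(negative: int, total: int) -> tuple[float, float]:
    """Mean molecules per droplet and its standard error.

    ``lambda = -ln(p)`` with ``p = negative/total``;
    ``SE = sqrt((1 - p) / (total * p))`` by the delta method on the
    binomial negative fraction. ``negative == total`` gives (0, 0);
    ``negative == 0`` raises :class:`SaturationError`.
    """
    if total < 1:
        raise ValueError("total droplet count must be >= 1")
    if not 0 <= negative <= total:
        raise ValueError("negative count outside [0, total]")
    if negative == 0:
        raise SaturationError("no negative droplets: concentration unbounded")
    p = negative / total
    lam = -math.log(p)
    se = math.sqrt((1.0 - p) / (total * p))
    return lam, se


def copy_number(well: DdpcrWell) -> CopyNumberEstimate:
    """Poisson-corrected target/reference ratio times two, with 95% CI.

    The CI is log-normal on the ratio:
    ``SE(ln cn)^2 = SE(lt)^2/lt^2 + SE(lr)^2/lr^2`` and
    ``bounds = cn * exp(-+ 1.96 * SE(ln cn))``.
    """
    lt, se_t = poisson_lambda(well.target_negative, well.target_total)
    lr, se_r = poisson_lambda(well.ref_negative, well.ref_total)
    if lr == 0:
        raise ValueError(f"{well.clone_id}: reference channel empty, ratio undefined")
    cn = 2.0 * lt / lr
    if lt == 0:
        return CopyNumberEstimate(lt, lr, 0.0, 0.0, 0.0)
    se_log = math.sqrt((se_t / lt) ** 2 + (se_r / lr) ** 2)
    return CopyNumberEstimate(
        lambda_target=lt,
        lambda_ref=lr,
        cn=cn,
        ci_low=cn * math.exp(-Z_95 * se_log),
        ci_high=cn * math.exp(Z_95 * se_log),
    )


GENOTYPE_LABELS = {
    "WT": "WT",
    "HDR": "HDR",
    "PARTIAL_HDR": "HDR",
    "IMPERFECT_HDR": "HDR",
    "NHEJ": "EJ",
    "MMEJ": "EJ",
    "DISCARDED": "?",
}


@dataclass
class CloneRecord:
    """Genotype and copy-number call for a single cell-derived clone."""

    clone_id: str
    zygosity: str  # apparent_homozygous | apparent_heterozygous
    genotype: str  # e.g. "HDR/HDR", "HDR/WT", "HDR/EJ"
    pure_hdr: bool
    sequence_calls: list[OutcomeCall]
    cn_estimate: CopyNumberEstimate
    copy_loss: bool
    primer_site_indel: bool


def _overlaps(indel: IndelCall, intervals: Sequence[tuple[int, int]]) -> bool:
    lo, hi = indel.ref_interval
    if lo == hi:  # insertion: point between lo-1 and lo
        lo, hi = max(lo - 1, 0), lo + 1
    return any(lo < e and s < hi for s, e in intervals)


def call_clone(
    clone_id: str,
    sequences: Sequence[str],
    well: DdpcrWell,
    spec: AmpliconSpec,
    primer_intervals: Sequence[tuple[int, int]] = (),
    loss_threshold: float = 1.5,
) -> CloneRecord:
    """Combine target-site sequencing and ddPCR into a clone-level call.

    ``sequences`` are the 1 (apparent homozygous) or 2 (apparent
    heterozygous) predominant target-site sequences. The genotype string
    pools NHEJ and MMEJ as "EJ" and counts any read carrying the donor
    substitution as HDR; ``pure_hdr`` marks a homozygous clone whose
    single sequence is exclusively the intended substitution. The
    ``copy_loss`` flag fires when the CI upper bound is below
    ``loss_threshold``; ``primer_site_indel`` when any sequence has an
    indel overlapping a supplied primer/probe interval.
    """
    if not 1 <= len(sequences) <= 2:
        raise ValueError(
            f"{clone_id}: expected 1-2 predominant sequences, got {len(sequences)} "
            "(possible polyclonality)"
        )
    calls = [call_read(s, spec, read_id=f"{clone_id}.seq{i}") for i, s in enumerate(sequences)]
    zygosity = "apparent_homozygous" if len(sequences) == 1 else "apparent_heterozygous"
    labels = sorted(GENOTYPE_LABELS[c.category] for c in calls)
    genotype = "/".join(labels * 2 if len(labels) == 1 else labels)
    pure_hdr = len(calls) == 1 and calls[0].category == "HDR"

    cn = copy_number(well)
    primer_hit = False
    if primer_intervals:
        for seq in sequences:
            aln = global_align(spec.reference, seq)
            if any(_overlaps(x, primer_intervals) for x in aln.indels):
                primer_hit = True
                break

    return CloneRecord(
        clone_id=clone_id,
        zygosity=zygosity,
        genotype=genotype,
        pure_hdr=pure_hdr,
        sequence_calls=calls,
        cn_estimate=cn,
        copy_loss=cn.ci_high < loss_threshold,
        primer_site_indel=primer_hit,
    )


# ---------------------------------------------------------------------------
# tabular I/O

WELL_COLUMNS = ("clone_id", "target_total", "target_negative", "ref_total", "ref_negative")


def read_wells(path: str | Path) -> list[DdpcrWell]:
    """Read a TSV of droplet counts (header: clone_id, target_total,
    target_negative, ref_total, ref_negative)."""
    wells = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != WELL_COLUMNS:
            raise ValueError(f"{path}: expected columns {WELL_COLUMNS}, got {tuple(header)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(f)}")
            wells.append(DdpcrWell(f[0], int(f[1]), int(f[2]), int(f[3]), int(f[4])))
    return wells


def clone_table_header() -> str:
    return "\t".join(
        [
            "clone_id",
            "cn",
            "ci_low",
            "ci_high",
            "zygosity",
            "genotype",
            "pure_hdr",
            "copy_loss",
            "primer_site_indel",
        ]
    )


def clone_table_row(rec: CloneRecord) -> str:
    e = rec.cn_estimate
    return "\t".join(
        [
            rec.clone_id,
            f"{e.cn:.4f}",
            f"{e.ci_low:.4f}",
            f"{e.ci_high:.4f}",
            rec.zygosity,
            rec.genotype,
            str(int(rec.pure_hdr)),
            str(int(rec.copy_loss)),
            str(int(rec.primer_site_indel)),
        ]
    )
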