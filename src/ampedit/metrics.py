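"""Sample-level summaries: category fractions, outcome purity, the
deletion-microhomology spectrum, and replicate mean ± s.e.m.

Outcome purity is the fraction of all editing events (reads differing
from wild type) that are pure intended HDR:

    purity = HDR / (HDR + PARTIAL_HDR + IMPERFECT_HDR + NHEJ + MMEJ)

It is undefined (None) in an unedited sample. All fractions use retained
(non-discarded) reads as the denominator; discarded reads are reported
only as a count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .classify import CATEGORIES, OutcomeCall

__all__ = [
    "SampleSummary",
    "ReplicateSummary",
    "summarize",
    "mh_spectrum",
    "aggregate_replicates",
    "mean_sem",
    "summary_to_json",
    "summary_tsv_row",
]

DEFAULT_MH_BINS = (0, 1, 2, 3, 4)  # last bin is open-ended (>= 4)


def _bin_label(b: int, bins: Sequence[int]) -> str:
    return f">={b}" if b == bins[-1] else str(b)


@dataclass
class SampleSummary:
    """Aggregated outcome of one amplicon sample."""

    counts: dict[str, int]
    discarded: int
    retained: int
    fractions: dict[str, float]
    outcome_purity: float | None
    mh_spectrum: dict[str, float]
    mh_bins: tuple[int, ...] = DEFAULT_MH_BINS


def mh_spectrum(
    calls: Iterable[OutcomeCall], bins: Sequence[int] = DEFAULT_MH_BINS
) -> dict[str, float]:
    """Deletion frequencies by microhomology length.

    Each retained read carrying at least one in-window deletion
    contributes once, to the bin of its maximum deletion MH; the last bin
    is open-ended. Fractions are over retained reads.
    """
    bins = tuple(bins)
    counts = {_bin_label(b, bins): 0 for b in bins}
    retained = 0
    for c in calls:
        if c.category == "DISCARDED":
            continue
        retained += 1
        if c.max_deletion_mh is None:
            continue
        mh = min(c.max_deletion_mh, bins[-1])
        b = max(b for b in bins if b <= mh)
        counts[_bin_label(b, bins)] += 1
    if retained == 0:
        return {k: 0.0 for k in counts}
    return {k: v / retained for k, v in counts.items()}


def summarize(
    calls: Sequence[OutcomeCall],
    bins: Sequence[int] = DEFAULT_MH_BINS,
    purity_numerator: tuple[str, ...] = ("HDR",),
) -> SampleSummary:
    """Counts, fractions, outcome purity and MH spectrum for one sample.

    ``purity_numerator`` exposes the choice of which categories count as
    intended edits; the default is pure HDR only.
    """
    if not calls:
        raise ValueError("summarize requires at least one classified read")
    counts = {k: 0 for k in CATEGORIES}
    discarded = 0
    for c in calls:
        if c.category == "DISCARDED":
            discarded += 1
        else:
            counts[c.category] += 1
    retained = sum(counts.values())
    fractions = {
        k: (v / retained if retained else 0.0) for k, v in counts.items()
    }
    editing_events = sum(counts[k] for k in CATEGORIES if k != "WT")
    if editing_events:
        purity = sum(counts[k] for k in purity_numerator) / editing_events
    else:
        purity = None
    return SampleSummary(
        counts=counts,
        discarded=discarded,
        retained=retained,
        fractions=fractions,
        outcome_purity=purity,
        mh_spectrum=mh_spectrum(calls, bins),
        mh_bins=tuple(bins),
    )


def mean_sem(values: Sequence[float]) -> tuple[float, float | None]:
    """Mean and standard error of the mean (ddof=1); s.e.m. None for n=1."""
    n = len(values)
    if n == 0:
        raise ValueError("no values")
    mean = sum(values) / n
    if n == 1:
        return mean, None
    if all(v == values[0] for v in values):  # exactly zero, no rounding dust
        return values[0], 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n)


@dataclass
class ReplicateSummary:
    """Per-metric mean ± s.e.m. across biological replicates."""

    n: int
    metrics: dict[str, dict[str, float | None]]  # name -> {mean, sem}


def aggregate_replicates(summaries: Sequence[SampleSummary]) -> ReplicateSummary:
    """Mean and s.e.m. of each category fraction and of outcome purity.

    Purity is aggregated over the replicates where it is defined; its
    reported n may therefore be smaller.
    """
    if not summaries:
        raise ValueError("aggregate_replicates requires at least one summary")
    metrics: dict[str, dict[str, float | None]] = {}
    for k in CATEGORIES:
        mean, sem = mean_sem([s.fractions[k] for s in summaries])
        metrics[f"fraction_{k}"] = {"mean": mean, "sem": sem, "n": len(summaries)}
    pur = [s.outcome_purity for s in summaries if s.outcome_purity is not None]
    if pur:
        mean, sem = mean_sem(pur)
        metrics["outcome_purity"] = {"mean": mean, "sem": sem, "n": len(pur)}
    else:
        metrics["outcome_purity"] = {"mean": None, "sem": None, "n": 0}
    return ReplicateSummary(n=len(summaries), metrics=metrics)


# ---------------------------------------------------------------------------
# serialisation


def summary_to_json(summary: SampleSummary) -> str:
    """Canonical JSON document (stable key order, fixed float formatting)."""
    doc = {
        "counts": summary.counts,
        "discarded": summary.discarded,
        "retained": summary.retained,
        "fractions": summary.fractions,
        "outcome_purity": summary.outcome_purity,
        "mh_spectrum": summary.mh_spectrum,
    }
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def summary_from_json(text: str) -> SampleSummary:
    d = json.loads(text)
    return SampleSummary(
        counts=d["counts"],
        discarded=d["discarded"],
        retained=d["retained"],
        fractions=d["fractions"],
        outcome_purity=d["outcome_purity"],
        mh_spectrum=d["mh_spectrum"],
    )


def summary_tsv_row(summary: SampleSummary, name: str = "sample") -> str:
    """One-row TSV record (with header) for spreadsheets."""
    cols = ["sample", "retained", "discarded"]
    vals: list[str] = [name, str(summary.retained), str(summary.discarded)]
    for k in CATEGORIES:
        cols += [f"n_{k}", f"frac_{k}"]
        vals += [str(summary.counts[k]), f"{summary.fractions[k]:.6f}"]
    cols.append("outcome_purity")
    vals.append("NA" if summary.outcome_purity is None else f"{summary.outcome_purity:.6f}")
    for k, v in summary.mh_spectrum.items():
        cols.append(f"mh_{k}")
        vals.append(f"{v:.6f}")
    return "\t".join(cols) + "\n" + "\t".join(vals) + "\n"
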