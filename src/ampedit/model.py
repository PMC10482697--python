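"""Domain model for a CRISPR amplicon editing experiment.

Everything downstream (alignment, classification, metrics, simulation)
shares one coordinate frame, defined here:

* reference positions are 0-based;
* intervals are half-open ``[start, end)``;
* a cut site is a *between-base* offset: a blunt cut between reference
  positions ``c - 1`` and ``c`` is encoded as ``c``.

An :class:`AmpliconSpec` bundles the wild-type amplicon sequence, the cut
site(s) programmed by the gRNA(s), the substitution(s) carried by the DNA
donor, and the classification thresholds. From it the expected HDR allele
(:func:`hdr_reference`) and the quantification window around the cut sites
(:func:`quantification_window`) are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml

VALID_BASES = frozenset("ACGT")

__all__ = [
    "DonorEdit",
    "ClassifyThresholds",
    "AmpliconSpec",
    "SpecError",
    "hdr_reference",
    "quantification_window",
    "load_spec",
    "save_spec",
]


class SpecError(ValueError):
    """Raised when an experiment specification violates its invariants."""


@dataclass(frozen=True)
class DonorEdit:
    """A single-nucleotide substitution installed by the HDR donor.

    The donor substitution doubles as the blocking mutation that destroys
    the protospacer match and prevents re-cutting of edited alleles.
    """

    position: int  # 0-based index into the reference
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise SpecError(
                f"donor edit bases must be A/C/G/T, got "
                f"{self.ref_base!r}>{self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise SpecError(f"donor edit at {self.position} is not a substitution")
        if self.position < 0:
            raise SpecError(f"donor edit position {self.position} is negative")


@dataclass(frozen=True)
class ClassifyThresholds:
    """Filter and classification thresholds.

    min_read_similarity
        Reads below this alignment identity to both the wild-type and the
        HDR allele are discarded (default 0.70).
    hdr_similarity
        Minimum identity to the HDR allele for a pure HDR call
        (default 0.95).
    window_radius
        Half-width in bp of the quantification window around each cut site
        (default 20): only indels touching the window are scored.
    mmej_min_mh
        Minimum deletion-junction microhomology, in bp, for attributing a
        deletion to MMEJ rather than NHEJ (default 2).
    """

    min_read_similarity: float = 0.70
    hdr_similarity: float = 0.95
    window_radius: int = 20
    mmej_min_mh: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.min_read_similarity <= self.hdr_similarity <= 1):
            raise SpecError(
                "need 0 < min_read_similarity <= hdr_similarity <= 1, got "
                f"{self.min_read_similarity} / {self.hdr_similarity}"
            )
        if self.window_radius < 0:
            raise SpecError("window_radius must be >= 0")
        if self.mmej_min_mh < 1:
            raise SpecError("mmej_min_mh must be >= 1")


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference amplicon, cut sites, donor edits and thresholds."""

    name: str
    reference: str
    cut_sites: tuple[int, ...]
    donor_edits: tuple[DonorEdit, ...] = ()
    thresholds: ClassifyThresholds = field(default_factory=ClassifyThresholds)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cut_sites", tuple(self.cut_sites))
        object.__setattr__(self, "donor_edits", tuple(self.donor_edits))
        ref = self.reference
        if len(ref) < 40:
            raise SpecError(f"reference must be >= 40 bp, got {len(ref)}")
        if not set(ref) <= VALID_BASES:
            bad = sorted(set(ref) - VALID_BASES)
            raise SpecError(f"reference contains non-ACGT characters: {bad}")
        if not self.cut_sites:
            raise SpecError("at least one cut site is required")
        for c in self.cut_sites:
            if not 0 < c < len(ref):
                raise SpecError(f"cut site {c} outside (0, {len(ref)})")
        seen: set[int] = set()
        for e in self.donor_edits:
            if not 0 < e.position < len(ref) - 1:
                raise SpecError(f"donor edit position {e.position} not inside reference")
            if ref[e.position] != e.ref_base:
                raise SpecError(
                    f"donor edit ref_base {e.ref_base} does not match reference "
                    f"base {ref[e.position]} at {e.position}"
                )
            if e.position in seen:
                raise SpecError(f"duplicate donor edit at position {e.position}")
            seen.add(e.position)

    def with_reference(self, reference: str) -> "AmpliconSpec":
        """Copy of this spec with a different reference (re-validated)."""
        return replace(self, reference=reference)


def hdr_reference(spec: AmpliconSpec) -> str:
    """Expected HDR allele: the reference with every donor edit applied.

    Same length as the reference; the empty edit list returns the
    reference unchanged.
    """
    seq = list(spec.reference)
    for e in spec.donor_edits:
        seq[e.position] = e.alt_base
    return "".join(seq)


def quantification_window(spec: AmpliconSpec, window_radius: int | None = None) -> frozenset[int]:
    """Reference positions within ``window_radius`` of any cut site.

    The window for cut site ``c`` is ``[c - r, c + r)`` clipped to the
    reference; the result is the union over all cut sites, so overlapping
    windows merge. ``window_radius`` of 0 yields the empty set.
    """
    r = spec.thresholds.window_radius if window_radius is None else window_radius
    n = len(spec.reference)
    out: set[int] = set()
    for c in spec.cut_sites:
        out.update(range(max(0, c - r), min(n, c + r)))
    return frozenset(out)


# ---------------------------------------------------------------------------
# config file round-trip


def _spec_to_dict(spec: AmpliconSpec) -> dict:
    d: dict = {
        "name": spec.name,
        "reference": spec.reference,
        "cut_sites": list(spec.cut_sites),
    }
    if spec.donor_edits:
        d["donor_edits"] = [
            {"position": e.position, "ref": e.ref_base, "alt": e.alt_base}
            for e in spec.donor_edits
        ]
    t = spec.thresholds
    defaults = ClassifyThresholds()
    overrides = {
        k: getattr(t, k)
        for k in ("min_read_similarity", "hdr_similarity", "window_radius", "mmej_min_mh")
        if getattr(t, k) != getattr(defaults, k)
    }
    if overrides:
        d["thresholds"] = overrides
    return d


def spec_from_dict(d: dict) -> AmpliconSpec:
    try:
        edits = tuple(
            DonorEdit(int(e["position"]), str(e["ref"]).upper(), str(e["alt"]).upper())
            for e in d.get("donor_edits", [])
        )
        thresholds = ClassifyThresholds(**d.get("thresholds", {}))
        return AmpliconSpec(
            name=str(d["name"]),
            reference=str(d["reference"]).upper(),
            cut_sites=tuple(int(c) for c in d["cut_sites"]),
            donor_edits=edits,
            thresholds=thresholds,
        )
    except KeyError as exc:
        raise SpecError(f"experiment config missing required key: {exc}") from exc
    except TypeError as exc:
        raise SpecError(f"malformed experiment config: {exc}") from exc


def load_spec(path: str | Path) -> AmpliconSpec:
    """Load an experiment config (YAML key-value file)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise SpecError(f"{path}: experiment config must be a mapping")
    return spec_from_dict(d)


def save_spec(spec: AmpliconSpec, path: str | Path) -> None:
    """Write an experiment config; save -> load -> save is byte-identical."""
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=True, default_flow_style=False)
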