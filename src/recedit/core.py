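"""Domain types and the allele algebra.

Recursive Editing treats every edited sequence as a first-class allele: the
wildtype carries unit probability mass, and each predicted repair outcome
splits its parent's mass in proportion to the outcome's predicted frequency
(conditional on the indel channel; the HDR split is modelled separately in
:mod:`recedit.simulate`). This module defines those types and the three
primitive operations everything else builds on: applying an indel to a
sequence, left-aligning (canonicalising) deletions that are ambiguous because
of flanking microhomology, and measuring that microhomology.

Coordinates are 0-based, half-open throughout. An insertion with ``start=i``
places its bases *before* index ``i``; a deletion with ``start=s`` and
``length=d`` removes ``seq[s:s+d]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "DNA_ALPHABET",
    "revcomp",
    "SequenceWindow",
    "IndelOutcome",
    "Allele",
    "Substitution",
    "DonorSpec",
    "CoordinateError",
    "apply_to_seq",
    "apply_outcome",
    "canonicalize_deletion",
    "microhomology_length",
    "merge_alleles",
]

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """An indel's coordinates fall outside its target sequence."""


def _check_dna(seq: str, *, allow_n: bool = False) -> None:
    allowed = DNA_ALPHABET | {"N"} if allow_n else DNA_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")


@dataclass(frozen=True)
class SequenceWindow:
    """A genomic sequence excerpt.

    ``start`` is the 0-based offset of ``seq`` on ``contig_id`` (half-open),
    so window-local coordinate ``i`` maps to genomic ``start + i``. Windows
    used for design must be uppercase A/C/G/T and at least 30 nt; degenerate
    bases are only tolerated in background sequence used for off-target
    counting.
    """

    contig_id: str
    start: int
    seq: str
    origin_strand: str = "+"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence window")
        if self.seq != self.seq.upper():
            raise ValueError("sequence window must be uppercase")
        if self.origin_strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.origin_strand!r}")

    def validate_for_design(self) -> None:
        _check_dna(self.seq)
        if len(self.seq) < 30:
            raise ValueError(
                f"window of length {len(self.seq)} too short for design (need >= 30)"
            )

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass(frozen=True)
class IndelOutcome:
    """One predicted repair product: a deletion span or an inserted sequence.

    ``freq`` is the predicted frequency of this outcome among all indel
    (non-HDR) products of a single editing event.
    """

    kind: str  # "deletion" | "insertion"
    start: int
    length: int
    inserted_seq: str = ""
    freq: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"bad outcome kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("outcome length must be >= 1")
        if self.kind == "deletion" and self.inserted_seq:
            raise ValueError("deletion must not carry inserted_seq")
        if self.kind == "insertion" and len(self.inserted_seq) != self.length:
            raise ValueError("insertion length must equal |inserted_seq|")
        if not (0.0 < self.freq <= 1.0):
            raise ValueError(f"freq {self.freq} outside (0, 1]")
        if not self.label:
            sign = "-" if self.kind == "deletion" else "+"
            object.__setattr__(self, "label", f"{sign}{self.length} bp {self.kind[:3]}")

    @property
    def end(self) -> int:
        """End of the affected span in parent coordinates (== start for insertions)."""
        return self.start + self.length if self.kind == "deletion" else self.start


@dataclass(frozen=True)
class Allele:
    """A concrete sequence with its editing lineage and probability mass.

    ``mass`` is the product of conditional outcome frequencies along the
    lineage; the wildtype has mass 1 and level 0. Alleles are compared by
    sequence identity — two lineages converging on the same sequence are the
    same allele for targeting purposes (see :func:`merge_alleles`).
    """

    seq: str
    lineage: tuple = ()
    level: int = 0
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.level != len(self.lineage):
            raise ValueError("level must equal lineage length")
        if not (0.0 <= self.mass <= 1.0):
            raise ValueError(f"mass {self.mass} outside [0, 1]")


def apply_to_seq(seq: str, outcome: IndelOutcome) -> str:
    """Return ``seq`` with ``outcome`` applied; raises CoordinateError if out of range."""
    if outcome.kind == "deletion":
        if outcome.start < 0 or outcome.start + outcome.length > len(seq):
            raise CoordinateError(
                f"deletion [{outcome.start}, {outcome.start + outcome.length}) "
                f"outside sequence of length {len(seq)}"
            )
        return seq[: outcome.start] + seq[outcome.start + outcome.length :]
    if outcome.start < 0 or outcome.start > len(seq):
        raise CoordinateError(
            f"insertion anchor {outcome.start} outside sequence of length {len(seq)}"
        )
    return seq[: outcome.start] + outcome.inserted_seq + seq[outcome.start :]


def apply_outcome(allele: Allele, guide_id: str, outcome: IndelOutcome) -> Allele:
    """Child allele after ``guide_id`` induces ``outcome`` on ``allele``.

    The child's mass is ``parent.mass * outcome.freq`` (product rule along
    the lineage) and its level increments.
    """
    child_seq = apply_to_seq(allele.seq, outcome)
    return Allele(
        seq=child_seq,
        lineage=allele.lineage + ((guide_id, outcome),),
        level=allele.level + 1,
        mass=allele.mass * outcome.freq,
    )


def canonicalize_deletion(seq: str, outcome: IndelOutcome) -> IndelOutcome:
    """Leftmost-aligned representative of a deletion on ``seq``.

    Flanking microhomology makes equal-length deletions ambiguous: removing
    either copy of a repeat yields the identical child sequence. The
    canonical form is the unique leftmost start producing the same child;
    the operation is idempotent and leaves microhomology-free deletions
    unchanged.
    """
    if outcome.kind != "deletion":
        raise ValueError("canonicalize_deletion requires a deletion outcome")
    s, d = outcome.start, outcome.length
    if s < 0 or s + d > len(seq):
        raise CoordinateError(f"deletion [{s}, {s + d}) outside sequence of length {len(seq)}")
    while s > 0 and seq[s - 1] == seq[s + d - 1]:
        s -= 1
    if s == outcome.start:
        return outcome
    return replace(outcome, start=s)


def microhomology_length(seq: str, outcome: IndelOutcome) -> int:
    """Length of the exact repeat spanning a deletion's junction.

    Returns the largest ``m`` with ``seq[start + i] == seq[start + length + i]``
    for all ``i < m``. A deletion with microhomology ``m`` can slide right by
    up to ``m`` positions without changing the child sequence, which is what
    drives microhomology-mediated (alt-EJ) deletion classes.
    """
    if outcome.kind != "deletion":
        raise ValueError("microhomology_length requires a deletion outcome")
    s, d = outcome.start, outcome.length
    if s < 0 or s + d > len(seq):
        raise CoordinateError(f"deletion [{s}, {s + d}) outside sequence of length {len(seq)}")
    m = 0
    n = len(seq)
    while s + d + m < n and seq[s + m] == seq[s + d + m]:
        m += 1
    return m


def merge_alleles(alleles) -> list:
    """Merge alleles with identical sequences by summing mass.

    The representative keeps the lineage of the highest-mass contributor
    (ties: first encountered). Output is sorted by mass descending, then
    sequence, for determinism.
    """
    by_seq: dict[str, Allele] = {}
    summed: dict[str, float] = {}
    for a in alleles:
        if a.seq in by_seq:
            summed[a.seq] += a.mass
            if a.mass > by_seq[a.seq].mass:
                by_seq[a.seq] = a
        else:
            by_seq[a.seq] = a
            summed[a.seq] = a.mass
    merged = [replace(by_seq[s], mass=min(summed[s], 1.0)) for s in by_seq]
    merged.sort(key=lambda a: (-a.mass, a.seq))
    return merged


@dataclass(frozen=True)
class Substitution:
    """A replacement edit (position, ref, alt) — covers SNVs and block substitutions."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("substitution with ref == alt is malformed")

    @property
    def start(self) -> int:
        return self.position

    @property
    def end(self) -> int:
        return self.position + len(self.ref)

    def apply(self, seq: str) -> str:
        if seq[self.position : self.position + len(self.ref)] != self.ref:
            raise CoordinateError(
                f"reference mismatch at {self.position}: sequence has "
                f"{seq[self.position:self.position + len(self.ref)]!r}, edit says {self.ref!r}"
            )
        return seq[: self.position] + self.alt + seq[self.position + len(self.ref) :]


@dataclass(frozen=True)
class DonorSpec:
    """An HDR donor described by the edit it installs on the wildtype.

    Mirrors an ssODN design: homology arms of 40-50 nt around a small edit
    (default: a 3-bp insertion at the cut site). ``hdr_allele`` is derived —
    the wildtype window with the edit applied — and is what retargeting
    guides must never match.
    """

    edit: object  # IndelOutcome | Substitution
    hdr_allele: str
    homology_arm_length: int = 45

    @classmethod
    def from_edit(cls, wt_seq: str, edit, homology_arm_length: int = 45) -> "DonorSpec":
        if isinstance(edit, Substitution):
            hdr = edit.apply(wt_seq)
        else:
            hdr = apply_to_seq(wt_seq, edit)
        return cls(edit=edit, hdr_allele=hdr, homology_arm_length=homology_arm_length)

    @classmethod
    def from_substitution(
        cls, wt_seq: str, position: int, ref: str, alt: str, homology_arm_length: int = 45
    ) -> "DonorSpec":
        """Donor installing ``ref``→``alt`` at ``position`` (0-based) on the wildtype."""
        return cls.from_edit(wt_seq, Substitution(position, ref, alt), homology_arm_length)

    def arms(self, wt_seq: str) -> tuple[str, str]:
        """Homology arms flanking the edit on the wildtype window."""
        h = self.homology_arm_length
        left = wt_seq[max(0, self.edit.start - h) : self.edit.start]
        right = wt_seq[self.edit.end : self.edit.end + h]
        return left, right
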