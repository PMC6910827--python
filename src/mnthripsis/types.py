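"""Core domain types shared across the pipeline.

Coordinate convention: all internal coordinates are 0-based, half-open
``[start, end)`` in base pairs.  On-disk BED/BEDPE files use the same
convention; human-readable reports print 1-based inclusive positions.

Breakend sides follow the head/tail convention used for junction
orientation classes: ``tail`` means the retained (junction-adjacent)
sequence extends toward *lower* coordinates, ``head`` toward *higher*
coordinates.  Under this convention a simple deletion produces a
tail-head junction, a tandem duplication a head-tail junction, and an
inversion one head-head plus one tail-tail junction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

__all__ = [
    "ValidationError",
    "FormatError",
    "GenomicInterval",
    "SnpRecord",
    "CopyState",
    "CnaSegment",
    "Side",
    "Orientation",
    "Breakend",
    "Junction",
    "ReadPairCounts",
    "Verdict",
    "HaplotypeCall",
]

_CONTIG_RE = re.compile(r"^[ACGTN]+$")


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. BAF outside [0, 1])."""


class FormatError(ValueError):
    """A file cannot be parsed as the expected format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic span ``[start, end)`` on one chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class SnpRecord:
    """One genotyped SNP in one sample.

    ``genotype`` is an allele-count pair ``(n_A, n_B)`` so that disomic,
    trisomic and tetrasomic configurations (AB, AAB, AABB, ...) share one
    representation; ``None`` means missing.
    """

    chrom: str
    pos: int
    lrr: float
    baf: float
    genotype: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("SNP chromosome must be non-empty")
        if self.pos < 0:
            raise ValidationError(f"SNP position must be >= 0, got {self.pos}")
        if not (0.0 <= self.baf <= 1.0):
            raise ValidationError(f"BAF must lie in [0, 1], got {self.baf}")
        if self.lrr != self.lrr or self.lrr in (float("inf"), float("-inf")):
            raise ValidationError(f"LRR must be finite, got {self.lrr}")
        if self.genotype is not None:
            n_a, n_b = self.genotype
            if n_a < 0 or n_b < 0 or n_a + n_b < 1:
                raise ValidationError(
                    f"genotype counts must be non-negative with at least one allele, got {self.genotype}"
                )


class CopyState(str, Enum):
    LOSS = "loss"
    NEUTRAL = "neutral"
    GAIN = "gain"


@dataclass(frozen=True)
class CnaSegment:
    """A constant copy-number interval with its quantal value for one clone."""

    interval: GenomicInterval
    quantal: float
    clone_id: str
    state: Optional[CopyState] = None

    def __post_init__(self) -> None:
        if self.quantal <= 0:
            raise ValidationError(f"quantal value must be > 0, got {self.quantal}")
        if not self.clone_id:
            raise ValidationError("clone_id must be non-empty")


class Side(str, Enum):
    """Which direction the retained sequence extends from a breakend."""

    HEAD = "head"  # retained sequence toward higher coordinates
    TAIL = "tail"  # retained sequence toward lower coordinates


class Orientation(str, Enum):
    TAIL_HEAD = "tail_head"
    HEAD_TAIL = "head_tail"
    HEAD_HEAD = "head_head"
    TAIL_TAIL = "tail_tail"


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    side: Side

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("breakend chromosome must be non-empty")
        if self.pos < 0:
            raise ValidationError(f"breakend position must be >= 0, got {self.pos}")
        if not isinstance(self.side, Side):
            object.__setattr__(self, "side", Side(self.side))


def _sort_key(b: Breakend) -> Tuple[str, int, str]:
    # side breaks ties for the degenerate same-position case (e.g. a
    # foldback junction), keeping canonicalization a total order
    return (b.chrom, b.pos, b.side.value)


@dataclass(frozen=True)
class Junction:
    """Two breakends joined by a rearrangement, in canonical order.

    The orientation label is derived from the breakend sides after
    ordering by (chrom, pos): ``side(lower)-side(higher)``.
    """

    a: Breakend
    b: Breakend
    clone_id: str = ""
    name: str = ""
    contig: Optional[str] = None

    def __post_init__(self) -> None:
        if _sort_key(self.b) < _sort_key(self.a):
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)
        if self.contig is not None and not _CONTIG_RE.match(self.contig):
            raise ValidationError("junction contig must contain only ACGTN")

    @property
    def orientation(self) -> Orientation:
        return Orientation(f"{self.a.side.value}_{self.b.side.value}")

    @property
    def is_translocation(self) -> bool:
        return self.a.chrom != self.b.chrom

    @property
    def span(self) -> Optional[int]:
        """Genomic distance between breakends; None for translocations."""
        if self.is_translocation:
            return None
        return abs(self.b.pos - self.a.pos)


@dataclass(frozen=True)
class ReadPairCounts:
    """Allele counts at one phase-informative SNP supporting one junction.

    ``disc_*`` count read pairs discordant with the reference (supporting
    the junction); ``conc_*`` count concordant pairs, split by which
    homolog's allele they carry.
    """

    junction_id: str
    chrom: str
    snp_pos: int
    disc_transferred: int
    disc_endogenous: int
    conc_transferred: int
    conc_endogenous: int

    def __post_init__(self) -> None:
        for name in ("disc_transferred", "disc_endogenous", "conc_transferred", "conc_endogenous"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


class Verdict(str, Enum):
    TRANSFERRED = "transferred"
    ENDOGENOUS = "endogenous"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class HaplotypeCall:
    """Which homolog a CNA or junction affects, with the supporting evidence.

    ``n_support`` counts informative observations favoring the verdict out
    of ``n_total`` considered.
    """

    target: str
    verdict: Verdict
    n_support: int
    n_total: int
    detail: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.n_support <= self.n_total):
            raise ValidationError(
                f"need 0 <= n_support <= n_total, got {self.n_support}/{self.n_total}"
            )
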