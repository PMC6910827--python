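"""Synthetic trisomic genomes with a rearranged transferred homolog.

The generator emulates the signal structure of a microcell-mediated
chromosome transfer experiment: a diploid parental genome receives one
extra homolog of a distinct haplotype, and that transferred homolog is
then rearranged either by shattering (chromothripsis-like: fragmentation,
stochastic fragment loss, random reassembly) or by a replicative
mechanism (chromoanasynthesis-like: serial template switching producing
duplications/triplications with microhomology or templated insertions at
the junctions).  Every downstream input of the analysis pipeline — SNP
tables with BAF/LRR, binned quantal copy-number segments, breakpoint
junctions with assembled contigs, and per-SNP read-pair allele counts —
is rendered from a single ground truth that is retained for
parameter-recovery tests.

Microhomology and insertions are *planted* by editing the synthetic
reference so that the junction-adjacent bases on both reference sides are
identical for exactly the planted length; boundary bases are edited to
break any longer chance match, which makes the planted length the unique
ground truth.  Junctions that share a breakpoint with another junction
(possible under shattering) are left unedited and their ground-truth
lengths are *measured* from the final reference instead, so truth is
consistent by construction in every case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .types import (
    Breakend,
    CnaSegment,
    GenomicInterval,
    Junction,
    ReadPairCounts,
    Side,
    SnpRecord,
)

__all__ = [
    "GenomeSpec",
    "SnpSite",
    "ReferenceGenome",
    "RearrangementEvent",
    "TrueJunction",
    "SimulationTruth",
    "ReadPairCounts",
    "SimulationError",
    "simulate_reference",
    "simulate_shattering",
    "simulate_chromoanasynthesis",
    "simulate_junction_corpus",
    "simulate_cna_phasing_panel",
    "PhasingPanel",
    "truth_to_dict",
    "render_snp_profile",
    "render_quantal_segments",
    "render_junction_records",
    "render_readpair_counts",
    "junction_flanks",
    "measure_junction_ends",
]

_BASES = b"ACGT"
_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


class SimulationError(RuntimeError):
    """Simulation could not satisfy its own constraints."""


def _revcomp(seq: bytes) -> bytes:
    return seq.translate(_COMP)[::-1]


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GenomeSpec:
    """Shape of the toy genome: chromosome sizes, SNP density, trisomy."""

    chromosomes: Tuple[Tuple[str, int], ...] = (
        ("chr1", 10_000_000),
        ("chr2", 10_000_000),
        ("chr3", 10_000_000),
    )
    snp_density: float = 1 / 5000.0  # SNPs per bp
    informative_fraction: float = 0.3
    aneuploid_chrom: str = "chr2"
    aneuploid_copies: int = 3  # 3 = trisomic, 4 = tetrasomic

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if not (0 < self.informative_fraction <= 1):
            raise ValueError(
                "informative_fraction must lie in (0, 1]; with no informative "
                "SNPs the transferred haplotype is untestable"
            )
        if self.aneuploid_chrom not in names:
            raise ValueError(f"aneuploid_chrom {self.aneuploid_chrom!r} not in genome")
        if self.aneuploid_copies not in (3, 4):
            raise ValueError("aneuploid_copies must be 3 or 4")

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return dict(self.chromosomes)


@dataclass(frozen=True)
class SnpSite:
    """A SNP site with fixed parental and transferred-homolog alleles."""

    chrom: str
    pos: int
    parental_allele: str  # homozygous parental allele, "A" or "B"
    transferred_allele: str
    informative: bool  # transferred allele differs from parental


@dataclass
class ReferenceGenome:
    spec: GenomeSpec
    sequences: Dict[str, bytearray]
    snps: List[SnpSite]

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].decode()

    def snps_on(self, chrom: str) -> List[SnpSite]:
        return [s for s in self.snps if s.chrom == chrom]


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str  # fragment_deletion | fragment_retention | duplication | triplication | templated_insertion | inversion
    source: GenomicInterval
    dest_index: int = -1
    inverted: bool = False
    copies: int = 1


@dataclass
class TrueJunction:
    junction: Junction
    microhomology_len: int
    insertion: str = ""
    templated_source: Optional[GenomicInterval] = None
    planted: bool = True
    event_kind: str = ""

    @property
    def insertion_len(self) -> int:
        return len(self.insertion)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated clone."""

    genome: ReferenceGenome
    clone_id: str
    mechanism: str  # shattering | chromoanasynthesis | junction_corpus
    events: List[RearrangementEvent]
    # ordered fragments (interval, "+"/"-") of the rearranged transferred homolog
    derived_structure: List[Tuple[GenomicInterval, str]]
    # piecewise-constant profile over the aneuploid chromosome:
    # (interval, total copy number, transferred-homolog copy number)
    cn_profile: List[Tuple[GenomicInterval, int, int]]
    junctions: List[TrueJunction]

    @property
    def spec(self) -> GenomeSpec:
        return self.genome.spec

    def transferred_cn_at(self, chrom: str, pos: int) -> int:
        if chrom != self.spec.aneuploid_chrom:
            return 0
        for interval, _total, transferred in self.cn_profile:
            if interval.start <= pos < interval.end:
                return transferred
        return self.spec.aneuploid_copies - 2

    def total_cn_at(self, chrom: str, pos: int) -> int:
        if chrom != self.spec.aneuploid_chrom:
            return 2
        return 2 + self.transferred_cn_at(chrom, pos)

    def true_cnas(self) -> List[Tuple[GenomicInterval, int]]:
        """Maximal intervals whose total copy number deviates from the
        intact aneuploid baseline, with their total copy number."""
        baseline = self.spec.aneuploid_copies
        out: List[Tuple[GenomicInterval, int]] = []
        for interval, total, _ in self.cn_profile:
            if total != baseline:
                if out and out[-1][0].end == interval.start and out[-1][1] == total:
                    prev, _ = out.pop()
                    interval = GenomicInterval(interval.chrom, prev.start, interval.end)
                out.append((interval, total))
        return out


def truth_to_dict(truth: SimulationTruth) -> dict:
    """JSON-serializable ground-truth record (the simulator's truth file)."""
    return {
        "clone_id": truth.clone_id,
        "mechanism": truth.mechanism,
        "aneuploid_chrom": truth.spec.aneuploid_chrom,
        "aneuploid_copies": truth.spec.aneuploid_copies,
        "chromosomes": [[c, l] for c, l in truth.spec.chromosomes],
        "events": [
            {
                "kind": e.kind,
                "chrom": e.source.chrom,
                "start": e.source.start,
                "end": e.source.end,
                "dest_index": e.dest_index,
                "inverted": e.inverted,
                "copies": e.copies,
            }
            for e in truth.events
        ],
        "derived_structure": [
            [iv.chrom, iv.start, iv.end, ori] for iv, ori in truth.derived_structure
        ],
        "cn_profile": [
            [iv.chrom, iv.start, iv.end, total, transferred]
            for iv, total, transferred in truth.cn_profile
        ],
        "junctions": [
            {
                "name": tj.junction.name,
                "a": [tj.junction.a.chrom, tj.junction.a.pos, tj.junction.a.side.value],
                "b": [tj.junction.b.chrom, tj.junction.b.pos, tj.junction.b.side.value],
                "orientation": tj.junction.orientation.value,
                "microhomology_len": tj.microhomology_len,
                "insertion_len": tj.insertion_len,
                "insertion": tj.insertion,
                "templated_source": (
                    [tj.templated_source.chrom, tj.templated_source.start, tj.templated_source.end]
                    if tj.templated_source
                    else None
                ),
                "planted": tj.planted,
                "event_kind": tj.event_kind,
            }
            for tj in truth.junctions
        ],
    }


# ---------------------------------------------------------------------------
# reference simulation


def simulate_reference(spec: GenomeSpec, seed: Union[int, np.random.Generator]) -> ReferenceGenome:
    """Random reference plus parental/transferred alleles at SNP sites.

    SNPs are laid on a regular lattice at the requested density.  At
    informative sites the parental genotype is homozygous and the
    transferred homolog carries the other allele; at non-informative
    sites all three copies agree.  Chromosomes other than the aneuploid
    one have no transferred copy, so all their SNPs are non-informative.
    """
    rng = _rng(seed)
    spacing = max(1, round(1 / spec.snp_density))
    sequences: Dict[str, bytearray] = {}
    snps: List[SnpSite] = []
    for name, length in spec.chromosomes:
        seq = bytearray(bytes(np.frombuffer(_BASES, dtype=np.uint8)[
            rng.integers(0, 4, size=length)
        ]))
        sequences[name] = seq
        positions = np.arange(spacing // 2, length, spacing)
        if positions.size == 0:
            raise SimulationError(
                f"snp_density {spec.snp_density} yields zero SNPs on {name}"
            )
        parental = np.where(rng.random(positions.size) < 0.5, "A", "B")
        if name == spec.aneuploid_chrom:
            informative = rng.random(positions.size) < spec.informative_fraction
        else:
            informative = np.zeros(positions.size, dtype=bool)
        for pos, par, info in zip(positions, parental, informative):
            transferred = ("B" if par == "A" else "A") if info else par
            snps.append(SnpSite(name, int(pos), str(par), transferred, bool(info)))
    return ReferenceGenome(spec=spec, sequences=sequences, snps=snps)


# ---------------------------------------------------------------------------
# junction sequence contexts
#
# Contigs and flanks are always laid out with the junction's canonical
# first breakend (a) as the left side.  For a breakend used as the left
# side, "approach" is the derived sequence reading toward the junction
# and "beyond" its continuation past the breakend along the reference;
# used as the right side, "departure" reads away from the junction and
# "before" extends backward past the breakend.  A tail breakend keeps the
# reference strand; a head breakend on the left (or tail on the right)
# reads the reverse complement.


def _left_contexts(seq: bytearray, bend: Breakend, flank: int) -> Tuple[bytes, bytes]:
    p = bend.pos
    if bend.side == Side.TAIL:
        return bytes(seq[p - flank:p]), bytes(seq[p:p + flank])
    return _revcomp(bytes(seq[p:p + flank])), _revcomp(bytes(seq[p - flank:p]))


def _right_contexts(seq: bytearray, bend: Breakend, flank: int) -> Tuple[bytes, bytes]:
    p = bend.pos
    if bend.side == Side.HEAD:
        return bytes(seq[p:p + flank]), bytes(seq[p - flank:p])
    return _revcomp(bytes(seq[p - flank:p])), _revcomp(bytes(seq[p:p + flank]))


def junction_flanks(genome: ReferenceGenome, junction: Junction, flank_len: int) -> Tuple[str, str]:
    """Reference flanks of a junction, oriented as in its contig.

    Both flanks are ``2 * flank_len`` long with the breakend at the
    center: the left flank is the retained approach to breakend ``a``
    followed by the reference continuation beyond it, the right flank the
    reference upstream of breakend ``b`` followed by the retained
    departure.
    """
    approach, beyond = _left_contexts(genome.sequences[junction.a.chrom], junction.a, flank_len)
    departure, before = _right_contexts(genome.sequences[junction.b.chrom], junction.b, flank_len)
    return (approach + beyond).decode(), (before + departure).decode()


def _complement_byte(b: int) -> int:
    return bytes((b,)).translate(_COMP)[0]


class _EndEditor:
    """Read/write single derived-orientation bases around one breakend."""

    def __init__(self, seq: bytearray, bend: Breakend):
        self.seq = seq
        self.pos = bend.pos
        self.side = bend.side

    # offset j >= 0 counts bases past the breakend in derived reading
    # direction (beyond for a left breakend); offset -k counts retained
    # bases adjacent to the junction (approach[-k]).

    def _ref_index_left(self, j: int) -> Tuple[int, bool]:
        # left-side breakend: approach/beyond axis
        if self.side == Side.TAIL:
            return self.pos + j, False
        return self.pos - 1 - j, True

    def _ref_index_right(self, j: int) -> Tuple[int, bool]:
        # right-side breakend: departure axis (j >= 0 into retained side,
        # j < 0 into the "before" extension)
        if self.side == Side.HEAD:
            return self.pos + j, False
        return self.pos - 1 - j, True

    def get(self, j: int, as_left: bool) -> int:
        idx, comp = self._ref_index_left(j) if as_left else self._ref_index_right(j)
        b = self.seq[idx]
        return _complement_byte(b) if comp else b

    def set(self, j: int, value: int, as_left: bool) -> None:
        idx, comp = self._ref_index_left(j) if as_left else self._ref_index_right(j)
        self.seq[idx] = _complement_byte(value) if comp else value


def _different_base(rng: np.random.Generator, *avoid: int) -> int:
    choices = [b for b in _BASES if b not in avoid]
    return int(choices[rng.integers(0, len(choices))])


def _plant_features(
    genome: ReferenceGenome,
    tj: TrueJunction,
    rng: np.random.Generator,
) -> None:
    """Edit the reference so the junction's planted lengths are exact.

    For microhomology m, the first m reference bases beyond breakend a
    (derived orientation) are set equal to the first m retained bases of
    breakend b, and the flanking bases are forced to mismatch so neither
    the homology run nor a chance shift extends further.  For insertions
    the boundary bases are forced to mismatch the insertion ends.
    """
    jx = tj.junction
    left = _EndEditor(genome.sequences[jx.a.chrom], jx.a)
    right = _EndEditor(genome.sequences[jx.b.chrom], jx.b)
    m = tj.microhomology_len
    ins = tj.insertion.encode()
    if m > 0 and ins:
        raise SimulationError("a junction may plant homology or an insertion, not both")
    if not ins:
        # copy the homology bases into the (unretained) extension beyond a
        for j in range(m):
            left.set(j, right.get(j, as_left=False), as_left=True)
        # break rightward ambiguity at exactly m
        left.set(m, _different_base(rng, right.get(m, as_left=False)), as_left=True)
        # break leftward ambiguity entirely: base before b != last approach base
        right.set(-1, _different_base(rng, left.get(-1, as_left=True)), as_left=False)
    else:
        # insertion must not extend a match with either flank
        left.set(0, _different_base(rng, ins[0]), as_left=True)
        right.set(-1, _different_base(rng, ins[-1]), as_left=False)


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def anchored_junction_match(
    contig: str, left_flank: str, right_flank: str
) -> Tuple[int, int, int, int]:
    """Maximal exact anchors of a contig against breakend-centered flanks.

    Both flanks must be centered on their breakend (as
    :func:`junction_flanks` produces): the first half of the left flank
    is the retained approach, the second half the reference continuation
    beyond the breakend; mirrored for the right flank.  The contig's
    left anchor is the longest contig prefix equal to a suffix of the
    approach (so flanks may be longer than the contig's own flanks),
    extended across the breakend into the continuation; symmetrically on
    the right.

    Returns ``(anchor_left, anchor_right, ext_left, ext_right)`` where
    the anchors count retained bases only and the extensions include
    any match beyond the breakends.
    """
    n = len(contig)
    mid_l = len(left_flank) // 2
    approach, beyond = left_flank[:mid_l], left_flank[mid_l:]
    mid_r = len(right_flank) // 2
    before, departure = right_flank[:mid_r], right_flank[mid_r:]

    anchor_left = 0
    for f in range(min(mid_l, n), -1, -1):
        if f == 0 or contig[:f] == approach[mid_l - f:]:
            anchor_left = f
            break
    ext_left = anchor_left + _common_prefix_len(contig[anchor_left:], beyond)

    anchor_right = 0
    for f in range(min(mid_r, n), -1, -1):
        if f == 0 or contig[n - f:] == departure[:f]:
            anchor_right = f
            break
    rev_tail = contig[: n - anchor_right][::-1]
    ext_right = anchor_right + _common_prefix_len(rev_tail, before[::-1])
    return anchor_left, anchor_right, ext_left, ext_right


def measure_junction_ends(contig: str, left_flank: str, right_flank: str) -> Tuple[int, int]:
    """Measured (microhomology_len, insertion_len) by maximal anchored match.

    If the extended anchors overlap, the overlap is junction-shift
    ambiguity, i.e. microhomology; if they leave a gap, the gap is an
    insertion.  Flanks must be breakend-centered (see
    :func:`anchored_junction_match`).
    """
    _, _, ext_left, ext_right = anchored_junction_match(contig, left_flank, right_flank)
    overlap = ext_left + ext_right - len(contig)
    if overlap >= 0:
        return overlap, 0
    return 0, -overlap


# ---------------------------------------------------------------------------
# rearrangement mechanisms


def _junction_between(
    chrom: str,
    frag_out: Tuple[GenomicInterval, str],
    frag_in: Tuple[GenomicInterval, str],
    clone_id: str,
    name: str,
) -> Junction:
    iv_out, ori_out = frag_out
    iv_in, ori_in = frag_in
    out_end = (
        Breakend(chrom, iv_out.end, Side.TAIL)
        if ori_out == "+"
        else Breakend(chrom, iv_out.start, Side.HEAD)
    )
    in_end = (
        Breakend(chrom, iv_in.start, Side.HEAD)
        if ori_in == "+"
        else Breakend(chrom, iv_in.end, Side.TAIL)
    )
    return Junction(a=out_end, b=in_end, clone_id=clone_id, name=name)


def _profile_from_coverage(
    chrom: str,
    length: int,
    fragments: Sequence[GenomicInterval],
    copies: Sequence[int],
    baseline_extra: int = 0,
) -> List[Tuple[GenomicInterval, int, int]]:
    """Piecewise transferred-homolog coverage from fragment intervals.

    ``copies[i]`` is how many copies fragment i contributes (1 for a
    retained fragment, 2/3 for duplicated/triplicated source intervals);
    ``baseline_extra`` adds intact transferred copies beyond the first
    (1 for a tetrasomic line whose rearranged homolog is one of two
    transferred copies).
    """
    bounds = {0, length}
    for iv in fragments:
        bounds.add(iv.start)
        bounds.add(iv.end)
    edges = sorted(bounds)
    profile: List[Tuple[GenomicInterval, int, int]] = []
    for s, e in zip(edges[:-1], edges[1:]):
        cov = baseline_extra + sum(
            c for iv, c in zip(fragments, copies) if iv.start <= s and e <= iv.end
        )
        profile.append((GenomicInterval(chrom, s, e), 2 + cov, cov))
    # merge equal-coverage neighbours
    merged: List[Tuple[GenomicInterval, int, int]] = []
    for iv, total, cov in profile:
        if merged and merged[-1][1] == total and merged[-1][0].end == iv.start:
            prev = merged.pop()
            iv = GenomicInterval(chrom, prev[0].start, iv.end)
        merged.append((iv, total, cov))
    return merged


def _sample_breakpoints(
    rng: np.random.Generator, length: int, k: int, margin: int, min_sep: int
) -> np.ndarray:
    """k positions in [margin, length - margin], pairwise >= min_sep apart.

    Uses the standard spacing construction (uniforms over the free slack,
    shifted by the cumulative minimum gaps), which samples uniformly over
    valid configurations without rejection.
    """
    lo, hi = margin, length - margin
    slack = (hi - lo) - (k - 1) * min_sep
    if slack <= 0:
        raise SimulationError("chromosome too short for requested breakpoints")
    u = np.sort(rng.integers(0, slack, size=k))
    return lo + u + min_sep * np.arange(k)


def _plant_or_measure(
    genome: ReferenceGenome,
    true_junctions: List[TrueJunction],
    rng: np.random.Generator,
    flank_len: int,
) -> None:
    """Plant features where each breakpoint belongs to a single junction;
    otherwise leave the reference untouched and record measured lengths."""
    use_count: Dict[Tuple[str, int], int] = {}
    for tj in true_junctions:
        for bend in (tj.junction.a, tj.junction.b):
            key = (bend.chrom, bend.pos)
            use_count[key] = use_count.get(key, 0) + 1
    for tj in true_junctions:
        shared = any(
            use_count[(bend.chrom, bend.pos)] > 1 for bend in (tj.junction.a, tj.junction.b)
        )
        if shared:
            tj.planted = False
            tj.microhomology_len = 0
            tj.insertion = ""
            tj.templated_source = None
        else:
            _plant_features(genome, tj, rng)
    # ground truth for unplanted junctions is whatever the final reference
    # shows; planted junctions are verified to match their plan
    for tj in true_junctions:
        left, right = junction_flanks(genome, tj.junction, flank_len)
        contig = left[:flank_len] + tj.insertion + right[flank_len:]
        mh, ins_len = measure_junction_ends(contig, left, right)
        if tj.planted:
            if mh != tj.microhomology_len or ins_len != len(tj.insertion):
                raise SimulationError(
                    f"planted junction {tj.junction.name}: planned "
                    f"(mh={tj.microhomology_len}, ins={len(tj.insertion)}) "
                    f"but reference shows (mh={mh}, ins={ins_len})"
                )
        else:
            tj.microhomology_len = mh


_MARGIN = 2000  # breakpoints keep this distance from chromosome ends
_MIN_SEP = 5000  # floor on breakpoint separation, so flank windows never collide
# default minimum fragment size under shattering: real chromothripsis
# fragments span tens of kilobases to megabases, and it keeps every
# simulated CNA comfortably above the pipeline's 100 kb floor and the
# quantal bin size
_SHATTER_MIN_FRAGMENT = 200_000


def simulate_shattering(
    genome: ReferenceGenome,
    k_breakpoints: int,
    deletion_fraction: float,
    seed: Union[int, np.random.Generator],
    clone_id: str = "clone",
    microhomology_max: int = 5,
    insertion_max: int = 10,
    p_microhomology: float = 0.4,
    p_insertion: float = 0.2,
    shuffle: bool = True,
    flank_len: int = 300,
    max_retries: int = 50,
    min_fragment: int = _SHATTER_MIN_FRAGMENT,
) -> SimulationTruth:
    """Shatter the transferred homolog and reassemble the survivors.

    The homolog is cut at ``k_breakpoints`` random positions; each
    fragment is independently deleted with probability
    ``deletion_fraction``; the survivors are placed in uniformly random
    order with independent 50% inversion (unless ``shuffle`` is False,
    which keeps original order and orientation — the copy-neutral limit).
    Junction features (small microhomologies/insertions, as expected from
    end-joining repair) are planted where the reference permits.
    """
    if k_breakpoints < 1:
        raise ValueError("k_breakpoints must be >= 1")
    if not (0 <= deletion_fraction < 1):
        raise ValueError("deletion_fraction must lie in [0, 1)")
    rng = _rng(seed)
    chrom = genome.spec.aneuploid_chrom
    length = genome.spec.chrom_lengths[chrom]
    cuts = _sample_breakpoints(
        rng, length, k_breakpoints, max(_MARGIN, min_fragment), max(_MIN_SEP, min_fragment)
    )
    edges = [0, *map(int, cuts), length]
    fragments = [GenomicInterval(chrom, s, e) for s, e in zip(edges[:-1], edges[1:])]

    retained_mask = None
    for _ in range(max_retries):
        mask = rng.random(len(fragments)) >= deletion_fraction
        if mask.any():
            retained_mask = mask
            break
    if retained_mask is None:
        raise SimulationError("all fragments deleted after retry limit")

    retained = [f for f, keep in zip(fragments, retained_mask) if keep]
    # telomeric fragments, when retained, stay pinned at the derived ends
    # in original orientation: their chromosome-terminal breakends carry no
    # junction and no flanking sequence exists beyond them
    head_pin = retained[0] if retained[0].start == 0 else None
    tail_pin = retained[-1] if len(retained) > 1 and retained[-1].end == length else None
    interior = [f for f in retained if f is not head_pin and f is not tail_pin]
    if shuffle:
        order = rng.permutation(len(interior))
        orientations = np.where(rng.random(len(interior)) < 0.5, "-", "+")
    else:
        order = np.arange(len(interior))
        orientations = np.array(["+"] * len(interior))
    derived = [(interior[i], str(orientations[j])) for j, i in enumerate(order)]
    if head_pin is not None:
        derived.insert(0, (head_pin, "+"))
    if tail_pin is not None:
        derived.append((tail_pin, "+"))

    events: List[RearrangementEvent] = []
    dest_of = {id(frag): j for j, (frag, _) in enumerate(derived)}
    for frag, keep in zip(fragments, retained_mask):
        if keep:
            j = dest_of[id(frag)]
            events.append(
                RearrangementEvent(
                    kind="fragment_retention",
                    source=frag,
                    dest_index=j,
                    inverted=derived[j][1] == "-",
                )
            )
        else:
            events.append(RearrangementEvent(kind="fragment_deletion", source=frag))

    true_junctions: List[TrueJunction] = []
    for i in range(len(derived) - 1):
        jx = _junction_between(chrom, derived[i], derived[i + 1], clone_id, f"{clone_id}_j{i}")
        # skip restored original adjacencies (no junction actually exists)
        iv0, o0 = derived[i]
        iv1, o1 = derived[i + 1]
        if o0 == o1 == "+" and iv0.end == iv1.start:
            continue
        if o0 == o1 == "-" and iv1.end == iv0.start:
            continue
        kind = rng.random()
        if kind < p_microhomology and microhomology_max > 0:
            mh = int(rng.integers(1, microhomology_max + 1))
            ins = ""
        elif kind < p_microhomology + p_insertion and insertion_max > 0:
            mh = 0
            ins = _random_seq(rng, int(rng.integers(1, insertion_max + 1)))
        else:
            mh, ins = 0, ""
        true_junctions.append(
            TrueJunction(jx, microhomology_len=mh, insertion=ins, event_kind="shattering")
        )

    _plant_or_measure(genome, true_junctions, rng, flank_len)

    profile = _profile_from_coverage(
        chrom, length, retained, [1] * len(retained),
        baseline_extra=genome.spec.aneuploid_copies - 3,
    )
    return SimulationTruth(
        genome=genome,
        clone_id=clone_id,
        mechanism="shattering",
        events=events,
        derived_structure=derived,
        cn_profile=profile,
        junctions=true_junctions,
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(np.frombuffer(_BASES, dtype=np.uint8)[rng.integers(0, 4, size=n)]).decode()


def simulate_chromoanasynthesis(
    genome: ReferenceGenome,
    n_switches: int,
    seed: Union[int, np.random.Generator],
    clone_id: str = "clone",
    segment_size: Tuple[int, int] = (200_000, 1_000_000),
    microhomology_range: Tuple[int, int] = (1, 15),
    templated_range: Tuple[int, int] = (50, 200),
    p_templated: float = 0.3,
    flank_len: int = 300,
) -> SimulationTruth:
    """Replicative rearrangement: template switches create tandem
    duplications/triplications of transferred-homolog segments, with
    microhomology or templated insertions planted at the new junctions.

    With at least two switches the first two events are forced to be one
    duplication and one triplication so the copy-number profile shows
    more than two states — the signature distinguishing this mechanism
    from pure shattering.
    """
    if n_switches < 1:
        raise ValueError("n_switches must be >= 1")
    rng = _rng(seed)
    chrom = genome.spec.aneuploid_chrom
    length = genome.spec.chrom_lengths[chrom]

    # non-overlapping, well-separated source segments via the spacing construction
    sizes = rng.integers(segment_size[0], segment_size[1] + 1, size=n_switches)
    slack = (length - 2 * _MARGIN) - int(sizes.sum()) - (n_switches - 1) * _MIN_SEP
    if slack <= 0:
        raise SimulationError("could not place template-switch segments")
    u = np.sort(rng.integers(0, slack, size=n_switches))
    starts = _MARGIN + u + np.concatenate(([0], np.cumsum(sizes[:-1] + _MIN_SEP)))
    ends = starts + sizes

    copies = [1 + int(rng.random() < 0.3) for _ in range(n_switches)]
    if n_switches >= 2:
        copies[0], copies[1] = 1, 2  # one duplication, one triplication

    intervals = [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    events = [
        RearrangementEvent(
            kind="triplication" if c == 2 else "duplication",
            source=iv,
            dest_index=i,
            copies=c + 1,
        )
        for i, (iv, c) in enumerate(zip(intervals, copies))
    ]

    # derived structure: original chromosome with extra tandem copies
    derived: List[Tuple[GenomicInterval, str]] = []
    cursor = 0
    for iv, c in zip(intervals, copies):
        if iv.start > cursor:
            derived.append((GenomicInterval(chrom, cursor, iv.start), "+"))
        derived.append((iv, "+"))
        for _ in range(c):
            derived.append((iv, "+"))
        cursor = iv.end
    if cursor < length:
        derived.append((GenomicInterval(chrom, cursor, length), "+"))

    # one junction per distinct tandem adjacency (end -> start of the segment)
    true_junctions: List[TrueJunction] = []
    for i, (iv, c) in enumerate(zip(intervals, copies)):
        jx = Junction(
            a=Breakend(chrom, iv.end, Side.TAIL),
            b=Breakend(chrom, iv.start, Side.HEAD),
            clone_id=clone_id,
            name=f"{clone_id}_ts{i}",
        )
        if rng.random() < p_templated:
            ins_len = int(rng.integers(templated_range[0], templated_range[1] + 1))
            src, ins = _sample_template(rng, genome, chrom, ins_len, intervals)
            tj = TrueJunction(
                jx, 0, insertion=ins, templated_source=src, event_kind="template_switch"
            )
        else:
            mh = int(rng.integers(microhomology_range[0], microhomology_range[1] + 1))
            tj = TrueJunction(jx, mh, event_kind="template_switch")
        true_junctions.append(tj)

    _plant_or_measure(genome, true_junctions, rng, flank_len)

    profile = _profile_from_coverage(
        chrom,
        length,
        [GenomicInterval(chrom, 0, length), *intervals],
        [1, *copies],
        baseline_extra=genome.spec.aneuploid_copies - 3,
    )
    return SimulationTruth(
        genome=genome,
        clone_id=clone_id,
        mechanism="chromoanasynthesis",
        events=events,
        derived_structure=derived,
        cn_profile=profile,
        junctions=true_junctions,
    )


def _sample_template(
    rng: np.random.Generator,
    genome: ReferenceGenome,
    chrom: str,
    ins_len: int,
    forbidden: Sequence[GenomicInterval],
) -> Tuple[GenomicInterval, str]:
    """A templated-insertion source interval on the transferred homolog,
    away from every junction window so later edits cannot corrupt it."""
    length = genome.spec.chrom_lengths[chrom]
    seq = genome.sequences[chrom]
    for _ in range(200):
        s = int(rng.integers(_MARGIN, length - _MARGIN - ins_len))
        iv = GenomicInterval(chrom, s, s + ins_len)
        near_edit_zone = any(
            iv.start - _MIN_SEP < bound < iv.end + _MIN_SEP
            for f in forbidden
            for bound in (f.start, f.end)
        )
        if not near_edit_zone:
            return iv, bytes(seq[s:s + ins_len]).decode()
    raise SimulationError("could not place a templated-insertion source")


_EVENT_ORIENTATIONS = {
    "deletion": ["tail_head"],
    "tandem_duplication": ["head_tail"],
    "inversion": ["tail_tail", "head_head"],
}


def simulate_junction_corpus(
    genome: ReferenceGenome,
    n_junctions: int,
    seed: Union[int, np.random.Generator],
    clone_id: str = "corpus",
    microhomology_range: Tuple[int, int] = (0, 15),
    insertion_range: Tuple[int, int] = (1, 30),
    templated_range: Tuple[int, int] = (50, 200),
    p_blunt: float = 0.25,
    p_microhomology: float = 0.35,
    p_insertion: float = 0.25,
    flank_len: int = 300,
) -> SimulationTruth:
    """A corpus of isolated simple-event junctions for forensics tests.

    Each junction arises from one deletion, tandem duplication or
    inversion of a fresh, well-separated interval, so its orientation
    class is known from the event type and every junction can have its
    feature planted without interference.  Remaining probability mass
    (after blunt/microhomology/non-templated insertion) goes to templated
    insertions copied from the transferred homolog.
    """
    rng = _rng(seed)
    chrom = genome.spec.aneuploid_chrom
    length = genome.spec.chrom_lengths[chrom]
    kinds = ["deletion", "tandem_duplication", "inversion"]

    # count breakpoint pairs needed (inversions yield two junctions)
    events: List[RearrangementEvent] = []
    true_junctions: List[TrueJunction] = []
    n_events = n_junctions  # upper bound; inversions may overshoot by one
    pts = _sample_breakpoints(rng, length, 2 * n_events, _MARGIN, _MIN_SEP)
    source_intervals = [
        GenomicInterval(chrom, int(pts[i]), int(pts[i + 1])) for i in range(0, len(pts) - 1, 2)
    ]
    idx = 0
    while len(true_junctions) < n_junctions and idx < len(source_intervals):
        iv = source_intervals[idx]
        kind = kinds[int(rng.integers(0, 3))]
        idx += 1
        if kind == "deletion":
            jxs = [Junction(Breakend(chrom, iv.start, Side.TAIL), Breakend(chrom, iv.end, Side.HEAD))]
        elif kind == "tandem_duplication":
            jxs = [Junction(Breakend(chrom, iv.start, Side.HEAD), Breakend(chrom, iv.end, Side.TAIL))]
        else:
            jxs = [
                Junction(Breakend(chrom, iv.start, Side.TAIL), Breakend(chrom, iv.end, Side.TAIL)),
                Junction(Breakend(chrom, iv.start, Side.HEAD), Breakend(chrom, iv.end, Side.HEAD)),
            ]
        events.append(RearrangementEvent(kind=kind, source=iv))
        for jx in jxs:
            if len(true_junctions) >= n_junctions:
                break
            jx = Junction(jx.a, jx.b, clone_id=clone_id, name=f"{clone_id}_j{len(true_junctions)}")
            u = rng.random()
            if u < p_blunt:
                tj = TrueJunction(jx, 0, event_kind=kind)
            elif u < p_blunt + p_microhomology:
                mh = int(rng.integers(microhomology_range[0], microhomology_range[1] + 1))
                tj = TrueJunction(jx, mh, event_kind=kind)
            elif u < p_blunt + p_microhomology + p_insertion:
                ins = _random_seq(rng, int(rng.integers(insertion_range[0], insertion_range[1] + 1)))
                tj = TrueJunction(jx, 0, insertion=ins, event_kind=kind)
            else:
                ins_len = int(rng.integers(templated_range[0], templated_range[1] + 1))
                src, ins = _sample_template(rng, genome, chrom, ins_len, source_intervals)
                tj = TrueJunction(jx, 0, insertion=ins, templated_source=src, event_kind=kind)
            true_junctions.append(tj)
    if len(true_junctions) < n_junctions:
        raise SimulationError("could not place the requested number of junctions")

    # inversion junctions of one event share breakpoints only pairwise at
    # distinct positions (start vs end), so every breakpoint is used once
    # except when both inversion junctions were emitted: start and end each
    # appear in both junctions.  _plant_or_measure handles that case.
    _plant_or_measure(genome, true_junctions, rng, flank_len)

    base_tr = genome.spec.aneuploid_copies - 2
    profile = [(GenomicInterval(chrom, 0, length), 2 + base_tr, base_tr)]
    return SimulationTruth(
        genome=genome,
        clone_id=clone_id,
        mechanism="junction_corpus",
        events=events,
        derived_structure=[(GenomicInterval(chrom, 0, length), "+")],
        cn_profile=profile,
        junctions=true_junctions,
    )


def expected_orientations(event_kind: str) -> List[str]:
    """Junction orientation classes implied by a simple event type."""
    return _EVENT_ORIENTATIONS[event_kind]


# ---------------------------------------------------------------------------
# rendering


def _render_snp(
    snp: SnpSite,
    tr_cn: int,
    endo_cn: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> SnpRecord:
    n_b = (endo_cn if snp.parental_allele == "B" else 0) + (
        tr_cn if snp.transferred_allele == "B" else 0
    )
    total = endo_cn + tr_cn
    baf = n_b / total
    lrr = float(np.log2(total / 2))
    if noise_sd > 0:
        baf = float(np.clip(baf + rng.normal(0, noise_sd), 0, 1))
        lrr += float(rng.normal(0, noise_sd))
    return SnpRecord(snp.chrom, snp.pos, lrr, baf, (total - n_b, n_b))


def render_snp_profile(
    truth: SimulationTruth,
    noise_sd: float,
    seed: Union[int, np.random.Generator],
    parental_id: str = "parental",
    baseline_id: str = "baseline",
) -> Dict[str, List[SnpRecord]]:
    """SNP tables (BAF/LRR) for parental, baseline-trisomic and clone.

    Clone BAF at each SNP is the exact B-allele fraction over all copies
    under the local true copy configuration, plus truncated Gaussian
    noise clipped to [0, 1]; LRR is log2(total/2) plus the same noise.
    The parental table is rendered at uniform copy number 2; the
    baseline table is the aneuploid line before any rearrangement (the
    sample phase-informative SNPs are discovered against).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed)
    base_tr = truth.spec.aneuploid_copies - 2
    parental: List[SnpRecord] = []
    baseline: List[SnpRecord] = []
    clone: List[SnpRecord] = []
    for snp in truth.genome.snps:
        on_aneuploid = snp.chrom == truth.spec.aneuploid_chrom
        parental.append(_render_snp(snp, 0, 2, noise_sd, rng))
        baseline.append(
            _render_snp(snp, base_tr if on_aneuploid else 0, 2, noise_sd, rng)
        )
        tr_cn = truth.transferred_cn_at(snp.chrom, snp.pos)
        clone.append(_render_snp(snp, tr_cn, 2, noise_sd, rng))
    return {parental_id: parental, baseline_id: baseline, truth.clone_id: clone}


def render_quantal_segments(
    truth: SimulationTruth,
    bin_size: int,
    noise_sd: float,
    seed: Union[int, np.random.Generator],
    parental_id: Optional[str] = "parental",
) -> List[CnaSegment]:
    """Binned quantal copy-number segments for the clone (and parental).

    True copy-number boundaries are snapped to the nearest bin edge;
    each surviving segment's quantal value is its true total copy number
    plus Gaussian noise.  Non-aneuploid chromosomes render as single
    disomic segments; the parental sample is disomic everywhere.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    rng = _rng(seed)
    segments: List[CnaSegment] = []

    def noisy(cn: float) -> float:
        return float(cn + rng.normal(0, noise_sd)) if noise_sd > 0 else float(cn)

    aneuploid = truth.spec.aneuploid_chrom
    for chrom, length in truth.spec.chromosomes:
        if chrom != aneuploid:
            segments.append(
                CnaSegment(GenomicInterval(chrom, 0, length), noisy(2.0), truth.clone_id)
            )
            continue
        snapped: List[Tuple[int, int, int]] = []
        for iv, total, _ in truth.cn_profile:
            s = int(round(iv.start / bin_size)) * bin_size
            e = int(round(iv.end / bin_size)) * bin_size
            s, e = max(0, s), min(length, e)
            if e > s:
                snapped.append((s, e, total))
        # resolve snaps that collide: keep order, drop empties
        cleaned: List[Tuple[int, int, int]] = []
        cursor = 0
        for s, e, total in snapped:
            s = max(s, cursor)
            if e > s:
                cleaned.append((s, e, total))
                cursor = e
        for s, e, total in cleaned:
            segments.append(
                CnaSegment(GenomicInterval(aneuploid, s, e), noisy(total), truth.clone_id)
            )
    if parental_id is not None:
        for chrom, length in truth.spec.chromosomes:
            segments.append(
                CnaSegment(GenomicInterval(chrom, 0, length), noisy(2.0), parental_id)
            )
    segments.sort(key=lambda s: (s.clone_id, s.interval.chrom, s.interval.start))
    return segments


def render_junction_records(
    truth: SimulationTruth,
    flank_len: int = 300,
) -> List[Junction]:
    """Junction records with assembled contigs from the final reference.

    Each contig is the retained approach to breakend a, the planted
    insertion (if any), and the retained departure from breakend b, each
    flank ``flank_len`` bp.
    """
    max_feature = max(
        [tj.microhomology_len + len(tj.insertion) for tj in truth.junctions] or [0]
    )
    if flank_len <= max_feature:
        raise ValueError(
            f"flank_len {flank_len} must exceed max planted homology+insertion {max_feature}"
        )
    out = []
    for tj in truth.junctions:
        left, right = junction_flanks(truth.genome, tj.junction, flank_len)
        contig = left[:flank_len] + tj.insertion + right[flank_len:]
        jx = tj.junction
        out.append(Junction(jx.a, jx.b, clone_id=jx.clone_id, name=jx.name, contig=contig))
    return out


@dataclass
class PhasingPanel:
    """Evaluation panel for haplotype assignment: rendered SNP tables,
    CNA calls, and the true affected homolog of every CNA."""

    parental: List[SnpRecord]
    baseline: List[SnpRecord]
    clone: List[SnpRecord]
    cnas: List["CnaCallLike"]
    true_verdicts: List[str]  # "transferred" | "endogenous", parallel to cnas


# avoid a hard dependency cycle in type checking; at runtime these are
# mnthripsis.cna.CnaCall objects
CnaCallLike = object

_PANEL_EVENTS = ("del_transferred", "del_endogenous", "dup_transferred", "dup_endogenous")


def simulate_cna_phasing_panel(
    genome: ReferenceGenome,
    n_cnas: int,
    noise_sd: float,
    seed: Union[int, np.random.Generator],
    min_informative: int = 5,
    clone_id: str = "clone",
) -> PhasingPanel:
    """CNAs of known haplotype for benchmarking BAF-based assignment.

    Unlike the rearrangement simulators (where every event hits the
    transferred homolog by construction), this panel plants deletions
    and duplications on the transferred *and* the endogenous homologs in
    equal proportion, so both verdicts are exercised.  Each CNA interval
    covers at least ``min_informative`` phase-informative SNPs.  BAFs
    follow the genotype configurations: a transferred-copy deletion
    returns an informative SNP to parental homozygosity (AA/BB), an
    endogenous deletion leaves AB (0.5); a transferred duplication gives
    AABB (0.5), an endogenous one AAAB/ABBB (0.25/0.75).
    """
    from .cna import CnaCall  # local import: cna is a downstream module
    from .types import CopyState

    rng = _rng(seed)
    chrom = genome.spec.aneuploid_chrom
    snps_here = genome.snps_on(chrom)
    informative_positions = [s.pos for s in snps_here if s.informative]
    # group consecutive informative SNPs into disjoint CNA intervals
    chunks: List[Tuple[int, int]] = []
    i = 0
    while len(chunks) < n_cnas and i + min_informative <= len(informative_positions):
        size = min_informative + int(rng.integers(0, 3))
        j = min(i + size, len(informative_positions))
        if j - i >= min_informative:
            chunks.append((informative_positions[i] - 500, informative_positions[j - 1] + 500))
        i = j
    if len(chunks) < n_cnas:
        raise SimulationError(
            f"only {len(chunks)} CNA intervals with >= {min_informative} informative "
            f"SNPs fit on {chrom}; lower n_cnas or raise SNP density"
        )

    kinds = [_PANEL_EVENTS[k % 4] for k in range(n_cnas)]
    intervals = [GenomicInterval(chrom, s, e) for s, e in chunks]
    base_tr = genome.spec.aneuploid_copies - 2

    def copy_config(snp_chrom: str, pos: int, on_chrom: bool) -> Tuple[int, int]:
        # (transferred copies, endogenous copies) at this position
        tr, endo = (base_tr, 2) if on_chrom else (0, 2)
        for iv, kind in zip(intervals, kinds):
            if iv.contains(snp_chrom, pos):
                if kind == "del_transferred":
                    tr -= 1
                elif kind == "del_endogenous":
                    endo -= 1
                elif kind == "dup_transferred":
                    tr += 1
                else:
                    endo += 1
        return tr, endo

    parental: List[SnpRecord] = []
    baseline: List[SnpRecord] = []
    clone: List[SnpRecord] = []
    for snp in genome.snps:
        on_chrom = snp.chrom == chrom
        parental.append(_render_snp(snp, 0, 2, noise_sd, rng))
        baseline.append(
            _render_snp(snp, base_tr if on_chrom else 0, 2, noise_sd, rng)
        )
        tr, endo = copy_config(snp.chrom, snp.pos, on_chrom)
        clone.append(_render_snp(snp, tr, endo, noise_sd, rng))

    cnas = []
    verdicts = []
    for iv, kind in zip(intervals, kinds):
        total = 2 + base_tr + (1 if kind.startswith("dup") else -1)
        corrected = total - (genome.spec.aneuploid_copies - 2)
        state = CopyState.GAIN if kind.startswith("dup") else CopyState.LOSS
        cnas.append(CnaCall(iv, float(corrected), state, clone_id))
        verdicts.append("transferred" if kind.endswith("transferred") else "endogenous")
    return PhasingPanel(parental, baseline, clone, cnas, verdicts)


def render_readpair_counts(
    truth: SimulationTruth,
    coverage_mean: float,
    error_rate: float,
    seed: Union[int, np.random.Generator],
    window: int = 100_000,
) -> List[ReadPairCounts]:
    """Per-junction allele counts at nearby phase-informative SNPs.

    For each junction and each informative SNP within ``window`` of
    either breakend, Poisson(coverage_mean) discordant pairs are drawn;
    each carries the transferred allele (every simulated event lies on
    the transferred homolog) mislabeled with probability ``error_rate``.
    Concordant pairs are drawn one per copy present at the SNP.
    """
    if coverage_mean < 0:
        raise ValueError("coverage_mean must be >= 0")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = _rng(seed)
    informative = [s for s in truth.genome.snps if s.informative]
    counts: List[ReadPairCounts] = []
    for tj in truth.junctions:
        jx = tj.junction
        for snp in informative:
            near = any(
                bend.chrom == snp.chrom and abs(bend.pos - snp.pos) <= window
                for bend in (jx.a, jx.b)
            )
            if not near:
                continue
            n_disc = int(rng.poisson(coverage_mean))
            mislabeled = int(rng.binomial(n_disc, error_rate)) if n_disc else 0
            tr_cn = truth.transferred_cn_at(snp.chrom, snp.pos)
            copies = 2 + tr_cn
            n_conc = int(rng.poisson(coverage_mean * copies / 2))
            conc_from_transferred = int(rng.binomial(n_conc, tr_cn / copies)) if n_conc else 0
            counts.append(
                ReadPairCounts(
                    junction_id=jx.name,
                    chrom=snp.chrom,
                    snp_pos=snp.pos,
                    disc_transferred=n_disc - mislabeled,
                    disc_endogenous=mislabeled,
                    conc_transferred=conc_from_transferred,
                    conc_endogenous=n_conc - conc_from_transferred,
                )
            )
    return counts
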