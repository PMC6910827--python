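"""Copy-number aberration calling and uniqueness filtering.

Quantal segment values (~2 at disomy) are turned into loss/gain calls
with an aneuploid correction (subtract 1 on the trisomic chromosome so
its intact baseline reads as 2), consecutive same-state calls covering
more than 90% of their total span are merged, calls are held to a strict
100 kb size floor, and de novo ("unique") CNAs are isolated by requiring
less than 70% reciprocal overlap with every CNA of every sibling clone
and of the parental line.

All thresholds use strict inequalities: quantal < 1.5 is a loss,
> 2.5 a gain, length > 100 kb survives the floor, coverage > 0.90
merges, and reciprocal overlap < 0.70 keeps a call unique.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .types import CnaSegment, CopyState, GenomicInterval, ValidationError

__all__ = [
    "CnaCall",
    "call_quantal_states",
    "merge_consecutive",
    "filter_min_size",
    "reciprocal_overlap",
    "unique_cnas",
    "count_cnas_per_chromosome",
    "LOSS_THRESHOLD",
    "GAIN_THRESHOLD",
    "MIN_CNA_SIZE",
    "MERGE_COVERAGE",
    "UNIQUENESS_RO",
]

LOSS_THRESHOLD = 1.5
GAIN_THRESHOLD = 2.5
MIN_CNA_SIZE = 100_000
MERGE_COVERAGE = 0.90
UNIQUENESS_RO = 0.70


@dataclass(frozen=True)
class CnaCall:
    """A loss or gain call derived from one or more quantal segments."""

    interval: GenomicInterval
    corrected_quantal: float
    state: CopyState
    clone_id: str
    unique: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.state not in (CopyState.LOSS, CopyState.GAIN):
            raise ValidationError("CNA calls carry only loss or gain states")
        consistent = (
            self.corrected_quantal < LOSS_THRESHOLD
            if self.state == CopyState.LOSS
            else self.corrected_quantal > GAIN_THRESHOLD
        )
        if not consistent:
            raise ValidationError(
                f"state {self.state.value} inconsistent with corrected quantal "
                f"{self.corrected_quantal}"
            )

    @property
    def length(self) -> int:
        return self.interval.length


def call_quantal_states(
    segments: Sequence[CnaSegment],
    aneuploid_chrom: str,
    loss_threshold: float = LOSS_THRESHOLD,
    gain_threshold: float = GAIN_THRESHOLD,
    aneuploid_correction: float = 1.0,
) -> List[CnaCall]:
    """Assign loss/gain states to quantal segments; drop neutral ones.

    On the aneuploid chromosome the quantal value is first corrected by
    subtracting ``aneuploid_correction`` (1 for a trisomy; pass 2 for a
    tetrasomy) so its intact baseline is disomic-equivalent.  Both
    thresholds are strict.  Overlapping segments within one clone are a
    validation error.
    """
    _check_no_overlap(segments)
    calls: List[CnaCall] = []
    for seg in sorted(segments, key=lambda s: (s.clone_id, s.interval.chrom, s.interval.start)):
        corrected = seg.quantal
        if seg.interval.chrom == aneuploid_chrom:
            corrected -= aneuploid_correction
        if corrected < loss_threshold:
            state = CopyState.LOSS
        elif corrected > gain_threshold:
            state = CopyState.GAIN
        else:
            continue
        calls.append(CnaCall(seg.interval, corrected, state, seg.clone_id))
    return calls


def _check_no_overlap(segments: Sequence[CnaSegment]) -> None:
    by_clone_chrom: Dict[Tuple[str, str], List[GenomicInterval]] = {}
    for seg in segments:
        by_clone_chrom.setdefault((seg.clone_id, seg.interval.chrom), []).append(seg.interval)
    for (clone, chrom), intervals in by_clone_chrom.items():
        intervals.sort(key=lambda iv: iv.start)
        for prev, cur in zip(intervals[:-1], intervals[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"overlapping segments in clone {clone} on {chrom}: "
                    f"[{prev.start}, {prev.end}) and [{cur.start}, {cur.end})"
                )


def merge_consecutive(
    calls: Sequence[CnaCall],
    coverage_threshold: float = MERGE_COVERAGE,
) -> List[CnaCall]:
    """Merge runs of same-state calls densely covering their span.

    A run of >= 2 consecutive same-state, same-chromosome, same-clone
    calls is merged into one call spanning first start to last end when
    the summed segment lengths exceed ``coverage_threshold`` of that
    span (gaps count against coverage, strictly more than 90% by
    default).  Merging is greedy left-to-right, taking the longest
    qualifying extension each time, and is repeated to a fixpoint.  The
    merged quantal value is the length-weighted mean of the inputs.
    """
    groups: Dict[Tuple[str, str], List[CnaCall]] = {}
    for call in calls:
        groups.setdefault((call.clone_id, call.interval.chrom), []).append(call)
    out: List[CnaCall] = []
    for group in groups.values():
        group.sort(key=lambda c: c.interval.start)
        # split into maximal positional runs of identical state; a call of
        # the other state breaks the run even if it would be skipped over
        runs: List[List[CnaCall]] = []
        for call in group:
            if runs and runs[-1][-1].state == call.state:
                runs[-1].append(call)
            else:
                runs.append([call])
        for run in runs:
            while True:
                merged = _merge_pass(run, coverage_threshold)
                if merged == run:
                    break
                run = merged
            out.extend(run)
    out.sort(key=lambda c: (c.clone_id, c.interval.chrom, c.interval.start))
    return out


def _merge_pass(run: List[CnaCall], threshold: float) -> List[CnaCall]:
    out: List[CnaCall] = []
    i = 0
    while i < len(run):
        best_j = i
        for j in range(i + 1, len(run)):
            span = run[j].interval.end - run[i].interval.start
            covered = sum(c.interval.length for c in run[i:j + 1])
            if covered / span > threshold:
                best_j = j
        if best_j > i:
            members = run[i:best_j + 1]
            span_iv = GenomicInterval(
                members[0].interval.chrom,
                members[0].interval.start,
                members[-1].interval.end,
            )
            total_len = sum(c.interval.length for c in members)
            quantal = sum(c.corrected_quantal * c.interval.length for c in members) / total_len
            out.append(
                CnaCall(span_iv, quantal, members[0].state, members[0].clone_id)
            )
        else:
            out.append(run[i])
        i = best_j + 1
    return out


def filter_min_size(calls: Iterable[CnaCall], min_size: int = MIN_CNA_SIZE) -> List[CnaCall]:
    """Keep calls strictly longer than ``min_size`` (default 100 kb)."""
    return [c for c in calls if c.length > min_size]


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 across chromosomes."""
    ov = a.overlap_length(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def unique_cnas(
    calls_by_clone: Mapping[str, Sequence[CnaCall]],
    parental_calls: Sequence[CnaCall] = (),
    threshold: float = UNIQUENESS_RO,
) -> List[CnaCall]:
    """Annotate each call as unique (de novo) or shared.

    A call is unique iff its reciprocal overlap is strictly below
    ``threshold`` against every call of every *other* clone and every
    parental call; a call is never compared against calls of its own
    clone.  Shared calls are retained with ``unique=False``.
    """
    annotated: List[CnaCall] = []
    for clone, calls in calls_by_clone.items():
        others = [
            c for other, cs in calls_by_clone.items() if other != clone for c in cs
        ] + list(parental_calls)
        for call in calls:
            shared = any(
                reciprocal_overlap(call.interval, o.interval) >= threshold for o in others
            )
            annotated.append(replace(call, unique=not shared))
    annotated.sort(key=lambda c: (c.clone_id, c.interval.chrom, c.interval.start))
    return annotated


def write_calls(calls: Sequence[CnaCall], path) -> None:
    """Write CNA calls as BED5 + ``state corrected_quantal unique`` columns."""
    ordered = sorted(calls, key=lambda c: (c.clone_id, c.interval.chrom, c.interval.start))
    with open(path, "w") as fh:
        for c in ordered:
            unique = "." if c.unique is None else str(int(c.unique))
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.corrected_quantal:.6g}\t{c.clone_id}\t{c.state.value}\t{unique}\n"
            )


def read_calls(path) -> List[CnaCall]:
    calls: List[CnaCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise ValidationError(f"{path}: row {lineno}: expected 7 columns")
            calls.append(
                CnaCall(
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    float(f[3]),
                    CopyState(f[5]),
                    f[4],
                    unique=None if f[6] == "." else bool(int(f[6])),
                )
            )
    return calls


def count_cnas_per_chromosome(
    unique_calls: Iterable[CnaCall],
    aneuploid_chrom_by_clone: Mapping[str, str],
) -> Dict[str, object]:
    """Partition unique CNAs into aneuploid-chromosome vs elsewhere.

    ``aneuploid_chrom_by_clone`` maps each clone to its trisomic (or
    tetrasomic) chromosome.  Returns counts and the per-group size lists
    feeding the enrichment and size-comparison statistics.
    """
    n_aneuploid = 0
    n_other = 0
    sizes_aneuploid: List[int] = []
    sizes_other: List[int] = []
    for call in unique_calls:
        target = aneuploid_chrom_by_clone.get(call.clone_id)
        if call.interval.chrom == target:
            n_aneuploid += 1
            sizes_aneuploid.append(call.length)
        else:
            n_other += 1
            sizes_other.append(call.length)
    return {
        "n_aneuploid": n_aneuploid,
        "n_other": n_other,
        "sizes_aneuploid": sizes_aneuploid,
        "sizes_other": sizes_other,
    }
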