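"""Readers and writers for the pipeline's on-disk formats.

Formats (all plain text, tab-separated):

* SNP tables: header ``chrom pos lrr baf genotype``; genotype encoded as
  ``A:B`` allele counts (``2:1`` for AAB) or ``.`` for missing.
* Segment tables: headerless BED5-like ``chrom start end quantal clone_id``.
* Junctions: headerless BEDPE (10 standard columns) plus an optional 11th
  ``contig`` column; strand ``+`` maps to side ``tail`` (retained sequence
  to the left of the breakend) and ``-`` to ``head``.
* Reference: FASTA, via Biopython.

Coordinates on disk are 0-based half-open, matching the in-memory
convention.
"""

from __future__ import annotations

import sys
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    Breakend,
    CnaSegment,
    FormatError,
    GenomicInterval,
    Junction,
    ReadPairCounts,
    Side,
    SnpRecord,
    ValidationError,
)

__all__ = [
    "read_snp_table",
    "write_snp_table",
    "read_segments",
    "write_segments",
    "read_junctions",
    "write_junctions",
    "read_allele_counts",
    "write_allele_counts",
    "read_fasta",
    "write_fasta",
    "write_report",
]

PathLike = Union[str, Path]

_SNP_COLUMNS = ["chrom", "pos", "lrr", "baf", "genotype"]

_STRAND_TO_SIDE = {"+": Side.TAIL, "-": Side.HEAD}
_SIDE_TO_STRAND = {Side.TAIL: "+", Side.HEAD: "-"}


def _split_fields(line: str) -> List[str]:
    return line.rstrip("\n").split("\t")


def read_snp_table(path: PathLike) -> List[SnpRecord]:
    """Read a per-sample SNP table, sorted by (chrom, pos).

    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` (citing the row number) for rows violating
    SNP invariants such as BAF outside [0, 1].
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected header {_SNP_COLUMNS}")
        header = _split_fields(header_line)
        missing = [c for c in _SNP_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing} in header {header}")
        idx = {c: header.index(c) for c in _SNP_COLUMNS}
        records: List[SnpRecord] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split_fields(line)
            try:
                gt_text = fields[idx["genotype"]]
                if gt_text == ".":
                    genotype = None
                else:
                    n_a, n_b = gt_text.split(":")
                    genotype = (int(n_a), int(n_b))
                rec = SnpRecord(
                    chrom=fields[idx["chrom"]],
                    pos=int(fields[idx["pos"]]),
                    lrr=float(fields[idx["lrr"]]),
                    baf=float(fields[idx["baf"]]),
                    genotype=genotype,
                )
            except (ValidationError, ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: row {lineno}: {exc}") from exc
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_snp_table(records: Iterable[SnpRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SNP_COLUMNS) + "\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos)):
            gt = "." if r.genotype is None else f"{r.genotype[0]}:{r.genotype[1]}"
            fh.write(f"{r.chrom}\t{r.pos}\t{r.lrr:.6g}\t{r.baf:.6g}\t{gt}\n")


def read_segments(path: PathLike) -> List[CnaSegment]:
    """Read a BED5-like segment table, sorted by (clone, chrom, start)."""
    path = Path(path)
    segments: List[CnaSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_fields(line)
            if len(fields) < 5:
                raise FormatError(
                    f"{path}: row {lineno}: expected 5 columns "
                    f"(chrom start end quantal clone_id), got {len(fields)}"
                )
            try:
                seg = CnaSegment(
                    interval=GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    quantal=float(fields[3]),
                    clone_id=fields[4],
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}: row {lineno}: {exc}") from exc
            segments.append(seg)
    segments.sort(key=lambda s: (s.clone_id, s.interval.chrom, s.interval.start))
    return segments


def write_segments(segments: Iterable[CnaSegment], path: PathLike) -> None:
    ordered = sorted(segments, key=lambda s: (s.clone_id, s.interval.chrom, s.interval.start))
    with open(path, "w") as fh:
        for s in ordered:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.quantal:.6g}\t{s.clone_id}\n")


def read_junctions(path: PathLike) -> List[Junction]:
    """Read a BEDPE junction file (optional 11th ``contig`` column).

    Each breakend's position is taken as the BEDPE start coordinate;
    breakends are canonically ordered so the lower (chrom, pos) comes
    first, and the orientation label is derived from the strand-mapped
    sides.
    """
    path = Path(path)
    junctions: List[Junction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_fields(line)
            if len(fields) < 10:
                raise FormatError(
                    f"{path}: row {lineno}: expected >= 10 BEDPE columns, got {len(fields)}"
                )
            strand_a, strand_b = fields[8], fields[9]
            for strand in (strand_a, strand_b):
                if strand not in _STRAND_TO_SIDE:
                    raise FormatError(
                        f"{path}: row {lineno}: unknown strand symbol {strand!r}"
                    )
            contig = fields[10] if len(fields) > 10 and fields[10] not in (".", "") else None
            try:
                jx = Junction(
                    a=Breakend(fields[0], int(fields[1]), _STRAND_TO_SIDE[strand_a]),
                    b=Breakend(fields[3], int(fields[4]), _STRAND_TO_SIDE[strand_b]),
                    name=fields[6],
                    clone_id=fields[7] if fields[7] != "." else "",
                    contig=contig,
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}: row {lineno}: {exc}") from exc
            junctions.append(jx)
    junctions.sort(key=lambda j: (j.a.chrom, j.a.pos, j.b.chrom, j.b.pos, j.name))
    return junctions


def write_junctions(junctions: Iterable[Junction], path: PathLike) -> None:
    ordered = sorted(junctions, key=lambda j: (j.a.chrom, j.a.pos, j.b.chrom, j.b.pos, j.name))
    with open(path, "w") as fh:
        for j in ordered:
            contig = j.contig if j.contig is not None else "."
            clone = j.clone_id if j.clone_id else "."
            fh.write(
                "\t".join(
                    [
                        j.a.chrom, str(j.a.pos), str(j.a.pos + 1),
                        j.b.chrom, str(j.b.pos), str(j.b.pos + 1),
                        j.name or ".", clone,
                        _SIDE_TO_STRAND[j.a.side], _SIDE_TO_STRAND[j.b.side],
                        contig,
                    ]
                )
                + "\n"
            )


_RP_COLUMNS = [
    "junction_id", "chrom", "snp_pos",
    "disc_transferred", "disc_endogenous",
    "conc_transferred", "conc_endogenous",
]


def read_allele_counts(path: PathLike) -> List[ReadPairCounts]:
    """Read per-junction, per-SNP read-pair allele counts (TSV with header)."""
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected header {_RP_COLUMNS}")
        header = _split_fields(header_line)
        missing = [c for c in _RP_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        idx = {c: header.index(c) for c in _RP_COLUMNS}
        out: List[ReadPairCounts] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split_fields(line)
            try:
                out.append(
                    ReadPairCounts(
                        junction_id=fields[idx["junction_id"]],
                        chrom=fields[idx["chrom"]],
                        snp_pos=int(fields[idx["snp_pos"]]),
                        disc_transferred=int(fields[idx["disc_transferred"]]),
                        disc_endogenous=int(fields[idx["disc_endogenous"]]),
                        conc_transferred=int(fields[idx["conc_transferred"]]),
                        conc_endogenous=int(fields[idx["conc_endogenous"]]),
                    )
                )
            except (ValidationError, ValueError, IndexError) as exc:
                raise ValidationError(f"{path}: row {lineno}: {exc}") from exc
    return out


def write_allele_counts(counts: Iterable[ReadPairCounts], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_RP_COLUMNS) + "\n")
        for c in counts:
            fh.write(
                f"{c.junction_id}\t{c.chrom}\t{c.snp_pos}\t{c.disc_transferred}\t"
                f"{c.disc_endogenous}\t{c.conc_transferred}\t{c.conc_endogenous}\n"
            )


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_report(results: Mapping[str, object], out_dir: PathLike) -> List[Path]:
    """Write machine-readable tables plus a human-readable summary.

    ``results`` maps table names to lists of dict rows (written as TSV)
    or scalar summary values (collected into ``summary.txt``).  Output is
    byte-identical for identical inputs.  Positions in the summary are
    printed 1-based inclusive; the TSV tables keep 0-based half-open
    coordinates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    scalars: List[tuple] = []
    for name in sorted(results):
        value = results[name]
        if isinstance(value, list):
            table_path = out_dir / f"{name}.tsv"
            with open(table_path, "w") as fh:
                if value:
                    columns = list(value[0].keys())
                    fh.write("\t".join(columns) + "\n")
                    for row in value:
                        fh.write("\t".join(_format_cell(row[c]) for c in columns) + "\n")
                else:
                    fh.write("# no records\n")
            written.append(table_path)
        else:
            scalars.append((name, value))
    summary_path = out_dir / "summary.txt"
    with open(summary_path, "w") as fh:
        if not scalars and not written:
            fh.write("zero events\n")
        for name, value in scalars:
            fh.write(f"{name}: {_format_cell(value)}\n")
        for table_path in written:
            n_rows = sum(1 for line in open(table_path)) - 1
            fh.write(f"table {table_path.name}: {max(n_rows, 0)} rows\n")
    written.append(summary_path)
    return written


def _format_cell(value: object) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)
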