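"""File formats, gene models and coordinate arithmetic.

All internal coordinates are 1-based inclusive.  TSS-relative offsets are
signed: negative = upstream of the TSS, positive = downstream; the TSS base
itself is offset 0.  BED export converts to 0-based half-open.

Strand vocabulary is normalized to ``"forward"`` / ``"reverse"``; the common
aliases ``+/-/F/R`` are accepted on input.  Chromosome names are matched as
exact strings after whitespace trimming — no alias table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ParseError, ValidationError

FORWARD = "forward"
REVERSE = "reverse"

_STRAND_ALIASES = {
    "forward": FORWARD,
    "f": FORWARD,
    "+": FORWARD,
    "1": FORWARD,
    "reverse": REVERSE,
    "r": REVERSE,
    "-": REVERSE,
    "-1": REVERSE,
}


def normalize_strand(value: str) -> str:
    """Map a strand token (``+``, ``-``, ``F``, ``R``, ...) to the canonical vocabulary."""
    try:
        return _STRAND_ALIASES[str(value).strip().lower()]
    except KeyError:
        raise ValidationError(f"unrecognized strand value: {value!r}") from None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"interval start {self.start} > end {self.end} on {self.chromosome}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class ProbeTrack:
    """Ordered probe positions with per-replicate log2 enrichment values.

    ``positions`` is a 1-D int array of probe start coordinates (strictly
    increasing); ``values`` is a ``(n_probes, replicate_count)`` float array.
    """

    chromosome: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.positions.shape[0]:
            raise ValidationError(
                f"{self.chromosome}: {self.positions.shape[0]} positions but "
                f"{self.values.shape[0]} value rows"
            )
        if self.values.shape[1] < 1:
            raise ValidationError("replicate_count must be >= 1")
        diffs = np.diff(self.positions)
        if np.any(diffs == 0):
            pos = int(self.positions[np.argmin(diffs)])
            raise ValidationError(
                f"duplicate probe position {pos} on chromosome {self.chromosome}"
            )
        if np.any(diffs < 0):
            raise ValidationError(
                f"probe positions not sorted on chromosome {self.chromosome}"
            )

    @property
    def n_probes(self) -> int:
        return int(self.positions.shape[0])

    @property
    def replicate_count(self) -> int:
        return int(self.values.shape[1])

    def replicate_track(self, replicate: int) -> "ProbeTrack":
        """Single-replicate view of this track (values restricted to one column)."""
        return ProbeTrack(
            self.chromosome, self.positions.copy(), self.values[:, [replicate]].copy()
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinate record: TSS, start/stop codon and mRNA end.

    Invariant: coordinates are ordered along the direction of transcription,
    i.e. ``tss <= start_codon <= stop_codon <= mrna_end`` on the forward
    strand and the mirrored ordering on the reverse strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    tss: int
    start_codon: int
    stop_codon: int
    mrna_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "strand", normalize_strand(self.strand))
        coords = (self.tss, self.start_codon, self.stop_codon, self.mrna_end)
        if any(c < 1 for c in coords):
            raise ValidationError(f"{self.gene_id}: coordinates must be >= 1")
        ordered = coords if self.strand == FORWARD else coords[::-1]
        if list(ordered) != sorted(ordered):
            raise ValidationError(
                f"{self.gene_id}: coordinates not ordered along {self.strand} strand: {coords}"
            )


# ---------------------------------------------------------------------------
# coordinate arithmetic
# ---------------------------------------------------------------------------


def to_tss_relative(position: int, tss: int, strand: str) -> int:
    """Signed TSS-relative offset of a genomic position.

    Negative = upstream, positive = downstream, TSS base = 0.
    """
    strand = normalize_strand(strand)
    return position - tss if strand == FORWARD else tss - position


def from_tss_relative(offset: int, tss: int, strand: str) -> int:
    """Inverse of :func:`to_tss_relative`."""
    strand = normalize_strand(strand)
    return tss + offset if strand == FORWARD else tss - offset


def interval_length(interval: GenomicInterval) -> int:
    """Length in bp under the 1-based inclusive convention (end - start + 1)."""
    return interval.length


def promoter_interval(
    gene: GeneModel, length: int = 1000, chromosome_length: int | None = None
) -> GenomicInterval:
    """The ``length`` bp immediately upstream of the TSS (TSS base excluded).

    Clipped at chromosome bounds with a warning; a promoter with zero
    upstream room raises :class:`ValidationError`.
    """
    if length < 1:
        raise ValidationError("promoter length must be >= 1")
    if gene.strand == FORWARD:
        start, end = gene.tss - length, gene.tss - 1
        if end < 1:
            raise ValidationError(f"{gene.gene_id}: no upstream room for a promoter")
        if start < 1:
            warnings.warn(
                f"{gene.gene_id}: promoter clipped at chromosome start", stacklevel=2
            )
            start = 1
    else:
        start, end = gene.tss + 1, gene.tss + length
        if chromosome_length is not None:
            if start > chromosome_length:
                raise ValidationError(
                    f"{gene.gene_id}: no upstream room for a promoter"
                )
            if end > chromosome_length:
                warnings.warn(
                    f"{gene.gene_id}: promoter clipped at chromosome end", stacklevel=2
                )
                end = chromosome_length
    return GenomicInterval(gene.chromosome, start, end)


# ---------------------------------------------------------------------------
# probe tracks
# ---------------------------------------------------------------------------

PROBE_TRACK_HEADER = ("chrom", "position")


def read_probe_track(path, replicate_count: int = 3) -> dict[str, ProbeTrack]:
    """Read a tab-separated probe track file into per-chromosome tracks.

    Expected columns: ``chrom  position  rep1 .. repN`` with a header line.
    Probes are returned sorted by position; a duplicate position within a
    chromosome or a non-numeric value is an error naming the line.
    """
    if replicate_count < 1:
        raise ValidationError("replicate_count must be >= 1")
    per_chrom: dict[str, list[tuple[int, list[float]]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file, header expected")
        ncols = 2 + replicate_count
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncols:
                raise ParseError(
                    f"{path} line {lineno}: expected {ncols} tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom = fields[0].strip()
            try:
                pos = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path} line {lineno}: non-integer position {fields[1]!r}"
                ) from None
            try:
                vals = [float(v) for v in fields[2:]]
            except ValueError:
                raise ParseError(
                    f"{path} line {lineno}: non-numeric enrichment value in {fields[2:]}"
                ) from None
            per_chrom.setdefault(chrom, []).append((pos, vals))

    tracks: dict[str, ProbeTrack] = {}
    for chrom, rows in per_chrom.items():
        rows.sort(key=lambda r: r[0])
        positions = np.array([r[0] for r in rows], dtype=np.int64)
        dup = np.flatnonzero(np.diff(positions) == 0)
        if dup.size:
            raise ValidationError(
                f"{path}: duplicate position {int(positions[dup[0]])} on chromosome {chrom}"
            )
        values = np.array([r[1] for r in rows], dtype=float)
        tracks[chrom] = ProbeTrack(chrom, positions, values)
    return tracks


def write_probe_track(tracks: Mapping[str, ProbeTrack], path) -> None:
    """Write per-chromosome tracks as one tab-separated file (with header)."""
    first = next(iter(tracks.values()), None)
    reps = first.replicate_count if first is not None else 3
    with open(path, "w") as fh:
        cols = ["chrom", "position"] + [f"rep{i + 1}" for i in range(reps)]
        fh.write("\t".join(cols) + "\n")
        for chrom in sorted(tracks):
            tr = tracks[chrom]
            for pos, row in zip(tr.positions, tr.values):
                vals = "\t".join(repr(float(v)) for v in row)
                fh.write(f"{chrom}\t{int(pos)}\t{vals}\n")


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = (
    "gene_id",
    "chrom",
    "strand",
    "tss",
    "start_codon",
    "stop_codon",
    "mrna_end",
)


def read_gene_table(path) -> list[GeneModel]:
    """Read a tab-separated gene coordinate table (header required)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file, header expected")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path} line {lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                genes.append(
                    GeneModel(
                        gene_id=fields[0].strip(),
                        chromosome=fields[1].strip(),
                        strand=fields[2],
                        tss=int(fields[3]),
                        start_codon=int(fields[4]),
                        stop_codon=int(fields[5]),
                        mrna_end=int(fields[6]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path} line {lineno}: {exc}") from None
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chromosome}\t{g.strand}\t{g.tss}\t"
                f"{g.start_codon}\t{g.stop_codon}\t{g.mrna_end}\n"
            )


# ---------------------------------------------------------------------------
# region import/export
# ---------------------------------------------------------------------------


def write_regions_bed(regions, path) -> None:
    """Export called regions as BED6 (0-based half-open).

    name = region type, score = stringency * 100 rounded, strand = ".".
    Accepts any iterable of objects with ``chromosome``, ``interval``,
    ``type`` and ``stringency`` attributes, or bare :class:`GenomicInterval`.
    """
    with open(path, "w") as fh:
        for r in regions:
            if isinstance(r, GenomicInterval):
                chrom, start, end = r.chromosome, r.start, r.end
                name, score = "region", 0
            else:
                chrom = r.chromosome
                start, end = r.interval.start, r.interval.end
                name = r.type
                score = int(round(r.stringency * 100))
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score}\t.\n")


def read_intervals_bed(path) -> dict[str, list[GenomicInterval]]:
    """Read BED (>=3 columns) into per-chromosome 1-based inclusive intervals."""
    out: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: fewer than 3 BED columns")
            chrom = fields[0].strip()
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path} line {lineno}: non-integer coordinates") from None
            out.setdefault(chrom, []).append(GenomicInterval(chrom, start0 + 1, end0))
    for ivs in out.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return out


def write_intervals_tsv(intervals: Mapping[str, Sequence[GenomicInterval]], path) -> None:
    """Native 1-based inclusive interval TSV (chrom, start, end)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\n")
        for chrom in sorted(intervals):
            for iv in intervals[chrom]:
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\n")


def read_intervals_tsv(path) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: expected 3 fields")
            out.setdefault(fields[0], []).append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            )
    return out


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping (upper-cased)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
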