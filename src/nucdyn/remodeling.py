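"""Base-resolution comparison of control vs treated nucleosome region sets.

The comparison is a per-base partition of the union of both inputs:

- *depleted*  — bases occupied only in the control set,
- *enriched*  — bases occupied only in the treated set,
- *common*    — bases occupied in both.

Remodeled bases = total (union) bases - common bases.  Region type
(distinct/fuzzy) is pooled before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .io_annotation import GenomicInterval

IntervalMap = Mapping[str, Sequence[GenomicInterval]]


# ---------------------------------------------------------------------------
# interval set algebra (sorted, non-overlapping lists per chromosome)
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or adjacent intervals (one chromosome)."""
    if not intervals:
        return []
    chrom = intervals[0].chromosome
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [[ivs[0].start, ivs[0].end]]
    for iv in ivs[1:]:
        if iv.chromosome != chrom:
            raise ValidationError("merge_intervals: mixed chromosomes")
        if iv.start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [GenomicInterval(chrom, s, e) for s, e in merged]


def _check_disjoint(intervals: Sequence[GenomicInterval], label: str) -> None:
    prev_end = None
    for iv in sorted(intervals, key=lambda x: (x.start, x.end)):
        if prev_end is not None and iv.start <= prev_end:
            raise ValidationError(
                f"{label}: overlapping intervals on {iv.chromosome} "
                f"(merge inputs first)"
            )
        prev_end = iv.end


def _intersect(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval], chrom: str):
    out = []
    i = j = 0
    a = sorted(a, key=lambda iv: iv.start)
    b = sorted(b, key=lambda iv: iv.start)
    while i < len(a) and j < len(b):
        s = max(a[i].start, b[j].start)
        e = min(a[i].end, b[j].end)
        if s <= e:
            out.append(GenomicInterval(chrom, s, e))
        if a[i].end < b[j].end:
            i += 1
        else:
            j += 1
    return out


def _subtract(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval], chrom: str):
    """a minus b, both sorted and internally disjoint."""
    out = []
    b = sorted(b, key=lambda iv: iv.start)
    for iv in sorted(a, key=lambda iv: iv.start):
        cur_start = iv.start
        for cut in b:
            if cut.end < cur_start:
                continue
            if cut.start > iv.end:
                break
            if cut.start > cur_start:
                out.append(GenomicInterval(chrom, cur_start, cut.start - 1))
            cur_start = max(cur_start, cut.end + 1)
            if cur_start > iv.end:
                break
        if cur_start <= iv.end:
            out.append(GenomicInterval(chrom, cur_start, iv.end))
    return out


def total_bases(intervals: IntervalMap) -> int:
    return sum(iv.length for ivs in intervals.values() for iv in ivs)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------


@dataclass
class RemodelingPartition:
    """Disjoint base-level partition of the union of two region sets."""

    depleted: dict[str, list[GenomicInterval]]
    enriched: dict[str, list[GenomicInterval]]
    common: dict[str, list[GenomicInterval]]

    def bases(self, cls: str, chromosome: str | None = None) -> int:
        ivmap = getattr(self, cls)
        if chromosome is not None:
            return sum(iv.length for iv in ivmap.get(chromosome, []))
        return total_bases(ivmap)

    @property
    def remodeled_bases(self) -> int:
        """Total bases minus common bases (the accounting identity)."""
        return self.bases("depleted") + self.bases("enriched")

    @property
    def union_bases(self) -> int:
        return self.bases("depleted") + self.bases("enriched") + self.bases("common")

    @property
    def chromosomes(self) -> list[str]:
        return sorted(set(self.depleted) | set(self.enriched) | set(self.common))


def compare_conditions(
    regions_control: IntervalMap, regions_treated: IntervalMap
) -> RemodelingPartition:
    """Partition bases into depleted / enriched / common across two conditions.

    Each input must be internally non-overlapping per chromosome (merge
    first); otherwise a :class:`ValidationError` is raised.
    """
    for label, ivmap in (("control", regions_control), ("treated", regions_treated)):
        for chrom, ivs in ivmap.items():
            _check_disjoint(ivs, f"{label} regions on {chrom}")

    depleted: dict[str, list[GenomicInterval]] = {}
    enriched: dict[str, list[GenomicInterval]] = {}
    common: dict[str, list[GenomicInterval]] = {}
    for chrom in sorted(set(regions_control) | set(regions_treated)):
        a = list(regions_control.get(chrom, []))
        b = list(regions_treated.get(chrom, []))
        common[chrom] = _intersect(a, b, chrom)
        depleted[chrom] = _subtract(a, b, chrom)
        enriched[chrom] = _subtract(b, a, chrom)
    return RemodelingPartition(depleted=depleted, enriched=enriched, common=common)


def genome_remodeling_summary(
    partition: RemodelingPartition,
    genome_size: int | Mapping[str, int],
) -> pd.DataFrame:
    """Per-chromosome and genome-wide occupancy fractions (percent).

    Columns: ``pct_nor`` (union of both conditions), ``pct_common`` and
    ``pct_unique`` (= pct_nor - pct_common, the remodeled fraction).
    ``genome_size`` is either a total bp count or a per-chromosome mapping.
    """
    rows = []
    if isinstance(genome_size, Mapping):
        for chrom in partition.chromosomes:
            if chrom not in genome_size:
                raise ValidationError(f"no genome size for chromosome {chrom}")
            size = genome_size[chrom]
            if size <= 0:
                raise ValidationError(f"genome size for {chrom} must be > 0")
            union = sum(
                partition.bases(cls, chrom) for cls in ("depleted", "enriched", "common")
            )
            if union > size:
                raise ValidationError(
                    f"{chrom}: partition covers {union} bases > chromosome size {size}"
                )
            com = partition.bases("common", chrom)
            rows.append(
                {
                    "chrom": chrom,
                    "size": size,
                    "pct_nor": 100.0 * union / size,
                    "pct_common": 100.0 * com / size,
                    "pct_unique": 100.0 * (union - com) / size,
                }
            )
        total = sum(genome_size[c] for c in partition.chromosomes)
    else:
        total = int(genome_size)
    if total <= 0:
        raise ValidationError("genome_size must be > 0")
    union = partition.union_bases
    if union > total:
        raise ValidationError(
            f"partition covers {union} bases > genome size {total}"
        )
    com = partition.bases("common")
    rows.append(
        {
            "chrom": "genome",
            "size": total,
            "pct_nor": 100.0 * union / total,
            "pct_common": 100.0 * com / total,
            "pct_unique": 100.0 * (union - com) / total,
        }
    )
    return pd.DataFrame(rows)
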