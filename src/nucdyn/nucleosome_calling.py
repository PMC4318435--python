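"""Distinct/fuzzy nucleosome region calling from replicate probe tracks.

A probe qualifies at a stringency threshold iff its enrichment value is >=
the threshold in *every* replicate (equivalently: the per-probe replicate
minimum passes).  Maximal runs of >=4 consecutive qualifying probes become
regions; "consecutive" means adjacent in track order with a start-to-start
gap no larger than ``max_probe_gap`` (runs do not bridge tiling holes).

Each qualifying probe claims a pitch-wide tile ``[start, start+pitch-1]``,
so a region spans from the first qualifying probe start to the last
qualifying probe start plus ``probe_pitch - 1``.  At the native 35-bp pitch
a 4-probe run spans 140 bp and a 5-probe run 175 bp, which is the only
convention consistent with the distinct (131-161 bp) / fuzzy (>=161 bp)
classification bands.  The 131/161 boundary overlap is resolved half-open:
distinct = [131, 161), fuzzy = [161, inf).  Spans below 131 bp (possible
with irregular pitch) are discarded and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_annotation import GenomicInterval, ProbeTrack

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.0, -0.01, -0.1, -0.5, -1.0, -1.5, -2.0)

DISTINCT = "distinct"
FUZZY = "fuzzy"


@dataclass(frozen=True)
class StringencyConfig:
    """Thresholds and geometry for the region caller."""

    levels: tuple[float, ...] = DEFAULT_LEVELS
    min_run_distinct: int = 4
    distinct_min_span: int = 131
    distinct_max_span: int = 161  # exclusive; fuzzy = [161, inf)
    max_probe_gap: int = 50
    probe_pitch: int = 35

    def __post_init__(self) -> None:
        lv = tuple(float(x) for x in self.levels)
        if any(b >= a for a, b in zip(lv, lv[1:])):
            raise ValidationError("stringency levels must be strictly decreasing")
        if self.min_run_distinct < 1:
            raise ValidationError("min_run_distinct must be >= 1")
        if self.probe_pitch < 1:
            raise ValidationError("probe_pitch must be >= 1")
        object.__setattr__(self, "levels", lv)


@dataclass(frozen=True)
class NucleosomeRegion:
    """One called region at one stringency level in one condition."""

    chromosome: str
    interval: GenomicInterval
    type: str  # distinct | fuzzy
    condition: str
    stringency: float
    n_probes: int

    @property
    def span(self) -> int:
        return self.interval.length


def qualifying_mask(track: ProbeTrack, threshold: float) -> np.ndarray:
    """Boolean per-probe mask: min over replicates >= threshold (inclusive)."""
    return track.values.min(axis=1) >= threshold


def _runs(qualify: np.ndarray, positions: np.ndarray, max_gap: int):
    """Yield (i0, i1) index pairs of maximal qualifying runs, gap-broken."""
    n = len(qualify)
    i = 0
    while i < n:
        if not qualify[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and qualify[j + 1]
            and positions[j + 1] - positions[j] <= max_gap
        ):
            j += 1
        yield i, j
        i = j + 1


def call_regions(
    track: ProbeTrack,
    threshold: float,
    config: StringencyConfig = StringencyConfig(),
    condition: str = "control",
) -> list[NucleosomeRegion]:
    """Call distinct/fuzzy nucleosome regions on one chromosome track.

    Runs of fewer than ``min_run_distinct`` qualifying probes emit nothing.
    Returns regions in coordinate order; an empty track yields an empty list.
    """
    if track.n_probes == 0:
        return []
    qualify = qualifying_mask(track, threshold)
    regions: list[NucleosomeRegion] = []
    discarded_short = 0
    for i0, i1 in _runs(qualify, track.positions, config.max_probe_gap):
        n_probes = i1 - i0 + 1
        if n_probes < config.min_run_distinct:
            continue
        start = int(track.positions[i0])
        end = int(track.positions[i1]) + config.probe_pitch - 1
        span = end - start + 1
        if span < config.distinct_min_span:
            discarded_short += 1
            continue
        rtype = DISTINCT if span < config.distinct_max_span else FUZZY
        regions.append(
            NucleosomeRegion(
                chromosome=track.chromosome,
                interval=GenomicInterval(track.chromosome, start, end),
                type=rtype,
                condition=condition,
                stringency=float(threshold),
                n_probes=n_probes,
            )
        )
    if discarded_short:
        logger.info(
            "%s @%.3g: discarded %d run(s) spanning < %d bp",
            track.chromosome,
            threshold,
            discarded_short,
            config.distinct_min_span,
        )
    return regions


def call_regions_per_replicate(
    track: ProbeTrack,
    threshold: float,
    config: StringencyConfig = StringencyConfig(),
    condition: str = "control",
) -> list[list[NucleosomeRegion]]:
    """Call regions on each replicate alone (threshold on that replicate only)."""
    return [
        call_regions(track.replicate_track(r), threshold, config, condition)
        for r in range(track.replicate_count)
    ]


def stringency_sweep(
    tracks_by_condition: Mapping[str, Mapping[str, ProbeTrack]],
    config: StringencyConfig = StringencyConfig(),
) -> tuple[dict[tuple[float, str, str, str], list[NucleosomeRegion]], pd.DataFrame]:
    """Call regions for every (level, condition, type, chromosome) combination.

    Returns the keyed region sets plus a summary table of region counts and
    bases covered per key.  With 7 levels x 2 conditions x 2 types x 5
    chromosomes the table has 140 keyed datasets.
    """
    conditions = list(tracks_by_condition)
    if not conditions:
        raise ValidationError("no condition tracks supplied")
    chrom_sets = [set(tracks_by_condition[c]) for c in conditions]
    common = set.intersection(*chrom_sets)
    if not common:
        raise ValidationError("condition tracks cover disjoint chromosome sets")
    chromosomes = sorted(common)

    table: dict[tuple[float, str, str, str], list[NucleosomeRegion]] = {}
    rows = []
    for level in config.levels:
        for condition in conditions:
            for chrom in chromosomes:
                track = tracks_by_condition[condition][chrom]
                called = call_regions(track, level, config, condition)
                for rtype in (DISTINCT, FUZZY):
                    subset = [r for r in called if r.type == rtype]
                    table[(level, condition, rtype, chrom)] = subset
                    rows.append(
                        {
                            "level": level,
                            "condition": condition,
                            "type": rtype,
                            "chrom": chrom,
                            "n_regions": len(subset),
                            "bases": sum(r.span for r in subset),
                        }
                    )
    return table, pd.DataFrame(rows)


def coverage_per_nucleosome(
    chromosome_length: int,
    regions: Sequence[NucleosomeRegion | GenomicInterval],
    per_base: bool = False,
) -> float:
    """Chromosome length divided by the number of called regions (bp/nucleosome).

    With ``per_base=True``, divides by the total bases covered instead (the
    literal reading of the coverage text).  Zero regions yields +inf, flagged
    in the log.
    """
    if chromosome_length <= 0:
        raise ValidationError("chromosome_length must be > 0")
    if per_base:
        denom = sum(
            (r.length if isinstance(r, GenomicInterval) else r.span) for r in regions
        )
    else:
        denom = len(regions)
    if denom == 0:
        logger.warning("coverage_per_nucleosome: zero regions, returning +inf")
        return math.inf
    return chromosome_length / denom


def regions_to_intervals(
    regions: Sequence[NucleosomeRegion],
) -> dict[str, list[GenomicInterval]]:
    """Group region intervals by chromosome, coordinate-sorted (types pooled)."""
    out: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        out.setdefault(r.chromosome, []).append(r.interval)
    for ivs in out.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return out


def write_regions_tsv(regions: Sequence[NucleosomeRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tcondition\tstringency\tn_probes\n")
        for r in regions:
            fh.write(
                f"{r.chromosome}\t{r.interval.start}\t{r.interval.end}\t{r.type}\t"
                f"{r.condition}\t{r.stringency}\t{r.n_probes}\n"
            )


def read_regions_tsv(path) -> list[NucleosomeRegion]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            c, s, e, t, cond, strin, np_ = line.rstrip("\n").split("\t")
            out.append(
                NucleosomeRegion(
                    chromosome=c,
                    interval=GenomicInterval(c, int(s), int(e)),
                    type=t,
                    condition=cond,
                    stringency=float(strin),
                    n_probes=int(np_),
                )
            )
    return out
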