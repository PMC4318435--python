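"""TSS-anchored occupancy and remodeling profiles in 50-bp windows.

The +/-1000 bp span around each TSS is tiled into 40 windows of 50 bp.
Window labels are the conventional center-ish tags -975 ... -25, +25 ... +975;
a label L covers TSS-relative offsets [L-25, L+24], so -75 covers -100..-51
and +25 covers 0..49 (the TSS base, offset 0, sits in the first downstream
window).  A window scores 1 iff a single called region covers at least 25
*contiguous* bp inside it; split stretches do not add up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_classes import adjust_pvalues, two_sample_t
from .io_annotation import FORWARD, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

WINDOW_SIZE = 50
N_WINDOWS = 40
MIN_COVERED = 25
FLANK = 1000

#: window labels in ascending TSS-relative order (-975 ... -25, +25 ... +975)
WINDOW_LABELS: tuple[int, ...] = tuple(
    list(range(-975, 0, 50)) + list(range(25, 1000, 50))
)

IntervalMap = Mapping[str, Sequence[GenomicInterval]]


@dataclass
class OccupancyProfile:
    gene_id: str
    condition: str
    windows: np.ndarray  # 40 binary values, ordered as WINDOW_LABELS

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.int8)
        if self.windows.shape != (N_WINDOWS,):
            raise ValidationError("occupancy profile must have exactly 40 windows")
        if not np.isin(self.windows, (0, 1)).all():
            raise ValidationError("occupancy values must be 0/1")


def window_genomic_span(gene: GeneModel, label: int) -> tuple[int, int]:
    """Genomic (start, end) of the window with the given label for this gene."""
    rel_lo, rel_hi = label - 25, label + 24
    if gene.strand == FORWARD:
        return gene.tss + rel_lo, gene.tss + rel_hi
    return gene.tss - rel_hi, gene.tss - rel_lo


def window_occupancy(
    gene: GeneModel,
    regions: IntervalMap,
    condition: str = "control",
    chromosome_length: int | None = None,
) -> OccupancyProfile:
    """Binary 40-window occupancy profile for one gene.

    Windows falling (even partially) outside the chromosome are flagged
    absent (0).  Raises if the gene's chromosome has no entry in ``regions``.
    """
    if gene.chromosome not in regions:
        raise KeyError(f"no region set for chromosome {gene.chromosome}")
    chrom_regions = regions[gene.chromosome]
    occ = np.zeros(N_WINDOWS, dtype=np.int8)
    for w, label in enumerate(WINDOW_LABELS):
        gs, ge = window_genomic_span(gene, label)
        if gs < 1 or (chromosome_length is not None and ge > chromosome_length):
            continue  # clipped window: absent
        for iv in chrom_regions:
            ov = min(iv.end, ge) - max(iv.start, gs) + 1
            if ov >= MIN_COVERED:
                occ[w] = 1
                break
    return OccupancyProfile(gene.gene_id, condition, occ)


def filter_overlapping_genes(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Drop every gene whose +/-1000 bp TSS span overlaps another gene's span.

    Both members of an overlapping pair are removed.
    """
    spans = [
        GenomicInterval(g.chromosome, max(1, g.tss - FLANK), g.tss + FLANK)
        for g in genes
    ]
    bad = set()
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(spans):
        by_chrom.setdefault(s.chromosome, []).append(i)
    for idxs in by_chrom.values():
        idxs = sorted(idxs, key=lambda i: spans[i].start)
        for a, b in zip(idxs, idxs[1:]):
            if spans[a].overlaps(spans[b]):
                bad.add(a)
                bad.add(b)
    return [g for i, g in enumerate(genes) if i not in bad]


def occupancy_matrix(
    genes: Sequence[GeneModel],
    regions: IntervalMap,
    chromosome_length: int | None = None,
) -> np.ndarray:
    """(n_genes, 40) binary occupancy matrix (no overlap filtering)."""
    return np.array(
        [
            window_occupancy(g, regions, chromosome_length=chromosome_length).windows
            for g in genes
        ],
        dtype=np.int8,
    )


def group_coverage_profile(
    genes: Sequence[GeneModel],
    regions: IntervalMap,
    replicate_region_sets: Sequence[IntervalMap] | None = None,
    chromosome_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None, list[GeneModel]]:
    """Per-window mean occupancy for a gene group.

    Genes whose +/-1000 bp spans overlap another gene's span are removed
    before averaging.  Returns ``(consensus_means, per_replicate_means,
    kept_genes)`` where per-replicate means (shape ``(R, 40)``) are computed
    on each replicate region set when supplied, else None.
    """
    kept = filter_overlapping_genes(genes)
    if not kept:
        raise ValidationError("gene group empty after overlap filtering")
    consensus = occupancy_matrix(kept, regions, chromosome_length).mean(axis=0)
    per_rep = None
    if replicate_region_sets is not None:
        per_rep = np.array(
            [
                occupancy_matrix(kept, rset, chromosome_length).mean(axis=0)
                for rset in replicate_region_sets
            ]
        )
    return consensus, per_rep, kept


def remodeling_percent_profile(
    genes: Sequence[GeneModel],
    regions_control: IntervalMap,
    regions_treated: IntervalMap,
    chromosome_length: int | None = None,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Per-window depletion%% and enrichment%% across a gene group.

    For each window the denominator is the number of genes occupied under
    either condition; depletion%% counts 1->0 transitions, enrichment%%
    0->1.  Windows with zero denominator are reported NaN.
    """
    kept = genes if prefiltered else filter_overlapping_genes(genes)
    if not kept:
        raise ValidationError("gene group empty after overlap filtering")
    occ_c = occupancy_matrix(kept, regions_control, chromosome_length)
    occ_t = occupancy_matrix(kept, regions_treated, chromosome_length)
    either = ((occ_c == 1) | (occ_t == 1)).sum(axis=0).astype(float)
    dep = ((occ_c == 1) & (occ_t == 0)).sum(axis=0)
    enr = ((occ_c == 0) & (occ_t == 1)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dep_pct = np.where(either > 0, 100.0 * dep / either, np.nan)
        enr_pct = np.where(either > 0, 100.0 * enr / either, np.nan)
    if np.any(either == 0):
        logger.info(
            "remodeling_percent_profile: %d window(s) with zero denominator",
            int((either == 0).sum()),
        )
    return pd.DataFrame(
        {
            "window": WINDOW_LABELS,
            "denominator": either.astype(int),
            "depletion_pct": dep_pct,
            "enrichment_pct": enr_pct,
        }
    )


def window_significance(
    group_a: np.ndarray,
    group_b: np.ndarray,
    span_bp: int = 150,
    step_bp: int = 50,
    adjust_method: str = "bh",
) -> pd.DataFrame:
    """Sliding-block two-sample t-test between two groups of replicate profiles.

    ``group_a`` and ``group_b`` are ``(n_replicates, 40)`` arrays of
    per-replicate window values (occupancy means or remodeling percentages).
    Each test block pools ``span_bp / 50`` consecutive windows (default 3,
    i.e. one nucleosome-length 150-bp block) by per-replicate block means,
    sliding by ``step_bp``; p-values are multiplicity-adjusted.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != N_WINDOWS or b.shape[1] != N_WINDOWS:
        raise ValidationError("profiles must have 40 windows")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValidationError("window_significance requires >= 2 replicates per group")
    if span_bp % WINDOW_SIZE or step_bp % WINDOW_SIZE:
        raise ValidationError("span_bp and step_bp must be multiples of 50")
    block = span_bp // WINDOW_SIZE
    step = step_bp // WINDOW_SIZE

    rows = []
    for start in range(0, N_WINDOWS - block + 1, step):
        sl = slice(start, start + block)
        am = np.nanmean(a[:, sl], axis=1)
        bm = np.nanmean(b[:, sl], axis=1)
        t, p = two_sample_t(am, bm)
        rows.append(
            {
                "window_start": WINDOW_LABELS[start],
                "window_center": WINDOW_LABELS[start + block // 2],
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = adjust_pvalues(df["p"].to_numpy(), adjust_method)
    return df


def profiles_to_tsv(profile_means: Mapping[str, np.ndarray], path) -> None:
    """Write per-group window means as TSV (rows = windows, cols = groups)."""
    df = pd.DataFrame(dict(profile_means), index=list(WINDOW_LABELS))
    df.index.name = "window"
    df.to_csv(path, sep="\t")
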