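"""Motif frequency and enrichment statistics over promoter region classes.

Expected occurrence uses the local-composition formula

    E = (prod of per-base frequencies over the motif) / N * T

with N = motif length and T = counted bases.  The division by N is part of
the formula this tool reproduces and is kept deliberately;
``standard_expectation=True`` drops it for the textbook expectation.
Consequently the corrected
frequency observed/E of a motif over composition-random sequence converges
to N, not 1.

Motifs are counted on the given strand only, overlapping occurrences
included.  A trailing "/X" alternative (e.g. ``TGACG/C``) expands to both
final-base variants.  An occurrence straddling two region classes is
assigned to the class containing its 5'-most base.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

BASES = ("A", "C", "G", "T")

TOTAL_PROMOTER = "total_promoter"


def parse_motif(spec: str) -> list[str]:
    """Expand a motif spec like ``TGACG/C`` into equal-length variants."""
    parts = spec.strip().upper().split("/")
    core = parts[0]
    if not core or any(b not in BASES for b in core):
        raise ValidationError(f"motif must be over ACGT: {spec!r}")
    variants = [core]
    for alt in parts[1:]:
        if not alt or any(b not in BASES for b in alt):
            raise ValidationError(f"bad motif alternative in {spec!r}")
        if len(alt) >= len(core):
            raise ValidationError(f"alternative longer than motif in {spec!r}")
        variants.append(core[: len(core) - len(alt)] + alt)
    return variants


def base_frequencies(sequences: Iterable[str]) -> tuple[dict[str, float], int]:
    """Per-base frequency mapping F and counted-base total T (N bases excluded)."""
    counts = dict.fromkeys(BASES, 0)
    for seq in sequences:
        s = seq.upper()
        for b in BASES:
            counts[b] += s.count(b)
    t = sum(counts.values())
    if t == 0:
        raise ValidationError("base_frequencies: no countable bases")
    return {b: counts[b] / t for b in BASES}, t


def expected_occurrence(
    f: Mapping[str, float],
    t: int,
    motif: str,
    standard_expectation: bool = False,
) -> float:
    """Expected occurrence of ``motif`` under local composition (F, T)."""
    motif = motif.upper()
    if any(b not in BASES for b in motif):
        raise ValidationError(f"motif must be over ACGT: {motif!r}")
    prod = 1.0
    for b in motif:
        prod *= f[b]
    if standard_expectation:
        return prod * t
    return prod / len(motif) * t


def count_occurrences(sequences: Iterable[str], motif_spec: str) -> int:
    """Overlapping occurrences of the motif (any variant), given strand only."""
    variants = parse_motif(motif_spec)
    n = len(variants[0])
    total = 0
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - n + 1):
            if s[i : i + n] in variants:
                total += 1
    return total


def _wilson_interval(k: int, n: int) -> tuple[float, float]:
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass
class MotifStat:
    """Frequency statistics for one motif within one promoter region class."""

    motif: str
    region_class: str
    t: int
    f: dict[str, float]
    n: int
    expected: float
    observed: int
    corrected: float
    relative_corrected: float
    ci_low: float
    ci_high: float
    computable: bool = True


def _class_segments_bases(
    seq: str, segments: Sequence[tuple[int, int]]
) -> list[str]:
    out = []
    for s, e in segments:
        if s < 1 or e > len(seq) or s > e:
            raise ValidationError(
                f"segment ({s},{e}) outside promoter of length {len(seq)}"
            )
        out.append(seq[s - 1 : e])
    return out


def region_class_motif_stats(
    promoters: Mapping[str, str],
    region_classes: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]],
    motifs: Sequence[str],
    standard_expectation: bool = False,
) -> list[MotifStat]:
    """Per-(motif, class) statistics over a set of promoter sequences.

    ``region_classes`` maps class name -> {gene_id -> [(start, end), ...]}
    in 1-based promoter-local coordinates; classes must partition each
    promoter's bases.  The implicit ``total_promoter`` class is the whole
    promoter.  Corrected frequency = observed / expected with the class's
    own local composition; ``relative_corrected`` renormalizes by the
    total-promoter corrected frequency.  The 95% CI is a Wilson score
    interval on observed/T, rescaled to the corrected-frequency axis.
    """
    for gid, seq in promoters.items():
        covered = 0
        for cls in region_classes.values():
            for s, e in cls.get(gid, []):
                covered += e - s + 1
        if covered != len(seq):
            raise ValidationError(
                f"region classes do not partition promoter {gid}: "
                f"{covered} of {len(seq)} bases covered"
            )

    class_names = [TOTAL_PROMOTER] + list(region_classes)
    class_seqs: dict[str, list[str]] = {TOTAL_PROMOTER: list(promoters.values())}
    for cname, per_gene in region_classes.items():
        segs: list[str] = []
        for gid, seq in promoters.items():
            segs.extend(_class_segments_bases(seq, per_gene.get(gid, [])))
        class_seqs[cname] = segs

    # occurrence counting on the full promoter, assigned by 5'-most base
    def class_of_position(gid: str, pos: int) -> str:
        for cname, per_gene in region_classes.items():
            for s, e in per_gene.get(gid, []):
                if s <= pos <= e:
                    return cname
        return TOTAL_PROMOTER  # unreachable when classes partition

    stats: list[MotifStat] = []
    for motif_spec in motifs:
        variants = parse_motif(motif_spec)
        n = len(variants[0])
        observed: dict[str, int] = dict.fromkeys(class_names, 0)
        for gid, seq in promoters.items():
            s = seq.upper()
            for i in range(len(s) - n + 1):
                if s[i : i + n] in variants:
                    observed[TOTAL_PROMOTER] += 1
                    observed[class_of_position(gid, i + 1)] += 1

        per_class: dict[str, MotifStat] = {}
        for cname in class_names:
            seqs = class_seqs[cname]
            total_len = sum(len(x) for x in seqs)
            if total_len < n:
                per_class[cname] = MotifStat(
                    motif=motif_spec,
                    region_class=cname,
                    t=total_len,
                    f={},
                    n=n,
                    expected=float("nan"),
                    observed=observed[cname],
                    corrected=float("nan"),
                    relative_corrected=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    computable=False,
                )
                continue
            f, t = base_frequencies(seqs)
            e = expected_occurrence(f, t, variants[0], standard_expectation)
            obs = observed[cname]
            corrected = obs / e if e > 0 else float("nan")
            lo, hi = _wilson_interval(obs, t)
            scale = t / e if e > 0 else float("nan")
            per_class[cname] = MotifStat(
                motif=motif_spec,
                region_class=cname,
                t=t,
                f=f,
                n=n,
                expected=e,
                observed=obs,
                corrected=corrected,
                relative_corrected=float("nan"),
                ci_low=lo * scale,
                ci_high=hi * scale,
                computable=True,
            )
        ref = per_class[TOTAL_PROMOTER].corrected
        for st in per_class.values():
            if st.computable and ref > 0:
                st.relative_corrected = st.corrected / ref
                st.ci_low = st.ci_low / ref
                st.ci_high = st.ci_high / ref
            stats.append(st)
    return stats


def promoter_classes_from_partition(
    gene, partition, promoter_length: int = 1000
) -> dict[str, list[tuple[int, int]]]:
    """Map a base-level remodeling partition onto promoter-local coordinates.

    Local coordinate 1 is the farthest upstream base (5' end of the promoter
    read along the gene's strand); ``promoter_length`` is the TSS-adjacent
    kilobase.  Returns {'NOR': [...], 'remodeled': [...], 'NFR': [...]} with
    1-based inclusive local segments that partition the promoter: bases
    common to both conditions are NOR, bases unique to either are remodeled,
    the rest are NFR.
    """
    from .io_annotation import FORWARD, GenomicInterval, promoter_interval
    from .remodeling import _intersect, _subtract, merge_intervals

    prom = promoter_interval(gene, promoter_length)
    chrom = gene.chromosome

    def to_local(iv: GenomicInterval) -> tuple[int, int]:
        if gene.strand == FORWARD:
            lo = iv.start - prom.start + 1
            hi = iv.end - prom.start + 1
        else:
            lo = prom.end - iv.end + 1
            hi = prom.end - iv.start + 1
        return lo, hi

    out: dict[str, list[tuple[int, int]]] = {"NOR": [], "remodeled": [], "NFR": []}
    occupied: list[GenomicInterval] = []
    for cls, key in (("NOR", "common"),):
        for iv in getattr(partition, key).get(chrom, []):
            for piece in _intersect([iv], [prom], chrom):
                out[cls].append(to_local(piece))
                occupied.append(piece)
    remodeled_ivs = list(partition.depleted.get(chrom, [])) + list(
        partition.enriched.get(chrom, [])
    )
    for iv in remodeled_ivs:
        for piece in _intersect([iv], [prom], chrom):
            out["remodeled"].append(to_local(piece))
            occupied.append(piece)
    free = _subtract([prom], merge_intervals(occupied) if occupied else [], chrom)
    out["NFR"] = [to_local(piece) for piece in free]
    for cls in out:
        out[cls] = sorted(out[cls])
    return out


def motif_stats_to_frame(stats: Sequence[MotifStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motif": [s.motif for s in stats],
            "region_class": [s.region_class for s in stats],
            "T": [s.t for s in stats],
            "observed": [s.observed for s in stats],
            "expected": [s.expected for s in stats],
            "corrected": [s.corrected for s in stats],
            "relative_corrected": [s.relative_corrected for s in stats],
            "ci_low": [s.ci_low for s in stats],
            "ci_high": [s.ci_high for s in stats],
            "computable": [s.computable for s in stats],
        }
    )


# ---------------------------------------------------------------------------
# hexamer screens
# ---------------------------------------------------------------------------

ALL_HEXAMERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=6)
)


def _hexamer_counts(sequences: Sequence[str]) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    windows = 0
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - 5):
            h = s[i : i + 6]
            if all(b in BASES for b in h):
                counts[h] = counts.get(h, 0) + 1
                windows += 1
    return counts, windows


def hexamer_enrichment(
    target_seqs: Sequence[str],
    contrast_seqs: Sequence[str],
    background_seqs: Sequence[str],
    fold_min: float = 2.0,
    standard_expectation: bool = False,
) -> pd.DataFrame:
    """Observed/expected and lift screens over all 4096 hexamers.

    Two enrichment routes for each hexamer h, both target-vs-contrast:

    - OE: ``oe(h, set) = observed / E`` with E from that set's local
      composition; ``oe_ratio = oe(target) / oe(contrast)``.
    - Lift: hexamer frequency in a set relative to the background;
      ``lift_ratio = lift(target) / lift(contrast)``.

    A pseudocount of 1 is added to every observed count entering a ratio,
    so hexamers absent from a set stay defined.  ``passes`` requires both
    ratios >= ``fold_min``.
    """
    for name, seqs in (
        ("target", target_seqs),
        ("contrast", contrast_seqs),
        ("background", background_seqs),
    ):
        if not seqs or all(len(s) < 6 for s in seqs):
            raise ValidationError(f"hexamer_enrichment: empty {name} sequence set")

    sets = {}
    for name, seqs in (
        ("target", target_seqs),
        ("contrast", contrast_seqs),
        ("background", background_seqs),
    ):
        counts, windows = _hexamer_counts(seqs)
        f, t = base_frequencies(seqs)
        sets[name] = (counts, windows, f, t)

    rows = []
    for h in ALL_HEXAMERS:
        vals = {}
        for name, (counts, windows, f, t) in sets.items():
            c = counts.get(h, 0)
            e = expected_occurrence(f, t, h, standard_expectation)
            vals[f"obs_{name}"] = c
            vals[f"oe_{name}"] = (c + 1) / e if e > 0 else float("nan")
            vals[f"freq_{name}"] = (c + 1) / windows
        lift_target = vals["freq_target"] / vals["freq_background"]
        lift_contrast = vals["freq_contrast"] / vals["freq_background"]
        oe_ratio = vals["oe_target"] / vals["oe_contrast"]
        lift_ratio = lift_target / lift_contrast
        rows.append(
            {
                "hexamer": h,
                "obs_target": vals["obs_target"],
                "obs_contrast": vals["obs_contrast"],
                "obs_background": vals["obs_background"],
                "oe_target": vals["oe_target"],
                "oe_contrast": vals["oe_contrast"],
                "oe_background": vals["oe_background"],
                "oe_target_vs_background": vals["oe_target"] / vals["oe_background"],
                "oe_contrast_vs_background": vals["oe_contrast"] / vals["oe_background"],
                "oe_ratio": oe_ratio,
                "lift_target": lift_target,
                "lift_contrast": lift_contrast,
                "lift_ratio": lift_ratio,
                "passes": bool(oe_ratio >= fold_min and lift_ratio >= fold_min),
            }
        )
    return pd.DataFrame(rows)
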