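"""Synthetic dataset generator with planted ground truth.

Emits everything the pipeline consumes — probe tracks for two conditions,
a gene coordinate table, a long-format expression matrix for two genotypes
x two treatments, and promoter FASTA — together with a
:class:`TruthRecord` of what was planted, so every downstream stage can be
scored against a known answer.

Design of the plantings:

- probes tile each chromosome at a fixed pitch; planted nucleosome runs
  align to probe tiles, so the caller's tile convention recovers them
  exactly at zero noise;
- every gene gets a gene-body run (occupied in both conditions); induced
  (SI) genes get a promoter run (TSS-relative -200..-1) in the control
  condition only, repressed (SR) genes in the treated condition only, and
  constitutive/silent genes in both;
- alternating distinct (4-probe) and fuzzy (6-probe) intergenic runs are
  planted between genes in both conditions;
- expression is exactly additive for independent (NI) genes — the
  genotype x treatment interaction is zero by construction — while
  dependent (ND) genes lose their treatment response in the mutant;
- promoters of non-silent classes get W-box/TGA motifs planted inside
  truth nucleosome-free segments.

Noise is i.i.d. Gaussian on the log2 scale per probe per replicate
(a stand-in, not an array noise model).  A single seeded RNG with a fixed
draw order makes the whole dataset a pure function of the config.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import NucdynError, ValidationError
from .io_annotation import (
    FORWARD,
    REVERSE,
    GeneModel,
    GenomicInterval,
    ProbeTrack,
    write_fasta,
    write_gene_table,
    write_probe_track,
)

CONTROL = "control"
TREATED = "treated"
CONDITIONS = (CONTROL, TREATED)

CLASS_ORDER = ("SI", "SR", "CON", "SIL")

_MIN_GENE_SPACING = 2400
_MARGIN = 1500


class GenerationError(NucdynError):
    """Config asks for more planted structure than the chromosomes can hold."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 120_000
    probe_pitch: int = 35
    probe_length: int = 25
    replicate_count: int = 3
    noise_sd: float = 0.3
    nucleosome_signal_mean: float = 0.5
    background_mean: float = -3.0
    n_genes: int = 40
    group_fractions: dict[str, float] = field(
        default_factory=lambda: {"SI": 0.25, "SR": 0.25, "CON": 0.25, "SIL": 0.25}
    )
    nd_fraction: float = 0.5
    effect_size_log2fc: float = 3.0
    expression_noise_sd: float = 0.0
    expression_replicates: int = 3
    motif_plant_rate: float = 2.0  # planted motifs per kb of truth-NFR sequence
    promoter_length: int = 1000

    def __post_init__(self) -> None:
        if self.probe_pitch < 1:
            raise ValidationError("probe_pitch must be >= 1")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if self.replicate_count < 1:
            raise ValidationError("replicate_count must be >= 1")
        total = sum(self.group_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValidationError("group fractions must sum to <= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class TruthRecord:
    """Planted ground truth for one simulated dataset."""

    nucleosomes: dict[str, dict[str, list[GenomicInterval]]]
    gene_classes: dict[str, dict[str, str]]
    promoter_segments: dict[str, dict[str, list[tuple[int, int]]]]
    planted_motifs: list[tuple[str, int, str, str]]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for info in self.gene_classes.values():
            counts[info["sa_class"]] = counts.get(info["sa_class"], 0) + 1
        return counts

    def genes_in_class(self, sa_class: str, dependence: str | None = None) -> list[str]:
        out = []
        for gid, info in sorted(self.gene_classes.items()):
            if info["sa_class"] != sa_class:
                continue
            if dependence is not None and info.get("dependence") != dependence:
                continue
            out.append(gid)
        return out


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tracks: dict[str, dict[str, ProbeTrack]]  # condition -> chrom -> track
    genes: list[GeneModel]
    expression: pd.DataFrame
    promoters: dict[str, str]
    truth: TruthRecord
    chromosome_lengths: dict[str, int]

    def write(self, outdir) -> dict[str, str]:
        """Write every artifact as plain text; returns {filename: sha256}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_probe_track(self.tracks[CONTROL], outdir / "control.tsv")
        write_probe_track(self.tracks[TREATED], outdir / "treated.tsv")
        write_gene_table(self.genes, outdir / "genes.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        write_fasta(self.promoters, outdir / "promoters.fasta")
        with open(outdir / "chrom_sizes.tsv", "w") as fh:
            fh.write("chrom\tsize\n")
            for chrom in sorted(self.chromosome_lengths):
                fh.write(f"{chrom}\t{self.chromosome_lengths[chrom]}\n")
        self._write_truth(outdir)
        manifest = {}
        for f in sorted(outdir.iterdir()):
            if f.is_file():
                manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        return manifest

    def _write_truth(self, outdir: Path) -> None:
        with open(outdir / "truth_nucleosomes.tsv", "w") as fh:
            fh.write("condition\tchrom\tstart\tend\n")
            for cond in CONDITIONS:
                for chrom in sorted(self.truth.nucleosomes[cond]):
                    for iv in self.truth.nucleosomes[cond][chrom]:
                        fh.write(f"{cond}\t{chrom}\t{iv.start}\t{iv.end}\n")
        with open(outdir / "truth_classes.tsv", "w") as fh:
            fh.write("gene_id\tsa_class\tdependence\tsubclass\n")
            for gid in sorted(self.truth.gene_classes):
                info = self.truth.gene_classes[gid]
                fh.write(
                    f"{gid}\t{info['sa_class']}\t{info.get('dependence', '')}\t"
                    f"{info.get('subclass', '')}\n"
                )
        with open(outdir / "truth_motifs.tsv", "w") as fh:
            fh.write("gene_id\tposition\tmotif\tregion_class\n")
            for gid, pos, motif, cls in self.truth.planted_motifs:
                fh.write(f"{gid}\t{pos}\t{motif}\t{cls}\n")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _class_counts(n_genes: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of genes to classes."""
    exact = {c: fractions.get(c, 0.0) * n_genes for c in CLASS_ORDER}
    counts = {c: int(np.floor(exact[c])) for c in CLASS_ORDER}
    leftover = int(round(sum(exact.values()))) - sum(counts.values())
    by_frac = sorted(CLASS_ORDER, key=lambda c: exact[c] - counts[c], reverse=True)
    for c in by_frac[:leftover]:
        counts[c] += 1
    return counts


def _probe_index_range(
    ga: int, gb: int, pitch: int, n_probes: int
) -> tuple[int, int] | None:
    """Indices of probes whose tiles [pos, pos+pitch-1] intersect [ga, gb].

    Probe i starts at ``1 + i*pitch``.
    """
    i0 = int(np.ceil((ga - pitch) / pitch))
    i1 = (gb - 1) // pitch
    i0 = max(i0, 0)
    i1 = min(i1, n_probes - 1)
    if i1 < i0:
        return None
    return i0, i1


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete synthetic dataset from a config (pure in the seed)."""
    rng = np.random.default_rng(config.seed)
    pitch = config.probe_pitch
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chrom_length for c in chroms}

    # --- gene layout -------------------------------------------------------
    genes_per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(config.n_genes):
        genes_per_chrom[chroms[i % len(chroms)]] += 1
    for chrom, ng in genes_per_chrom.items():
        if ng == 0:
            continue
        spacing = (config.chrom_length - 2 * _MARGIN) // ng
        if spacing < _MIN_GENE_SPACING:
            raise GenerationError(
                f"{chrom}: {ng} genes need spacing >= {_MIN_GENE_SPACING} bp but "
                f"only {spacing} bp available; enlarge chrom_length or drop genes"
            )

    counts = _class_counts(config.n_genes, config.group_fractions)
    classes: list[str] = []
    for c in CLASS_ORDER:
        classes.extend([c] * counts[c])
    classes.extend(["OTHER"] * (config.n_genes - len(classes)))

    nd_rank: dict[str, int] = {"SI": 0, "SR": 0}
    genes: list[GeneModel] = []
    gene_truth: dict[str, dict[str, str]] = {}
    placed: dict[str, int] = {c: 0 for c in chroms}
    gene_meta: list[tuple[GeneModel, str, str | None]] = []
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        ng = genes_per_chrom[chrom]
        spacing = (config.chrom_length - 2 * _MARGIN) // ng
        k = placed[chrom]
        placed[chrom] += 1
        tss = _MARGIN + k * spacing + spacing // 2
        # snap the TSS to the probe grid so planted promoter runs tile cleanly
        tss = 1 + config.probe_pitch * round((tss - 1) / config.probe_pitch)
        strand = FORWARD if i % 2 == 0 else REVERSE
        d = 1 if strand == FORWARD else -1
        gene = GeneModel(
            gene_id=f"G{i + 1:04d}",
            chromosome=chrom,
            strand=strand,
            tss=tss,
            start_codon=tss + 120 * d,
            stop_codon=tss + 800 * d,
            mrna_end=tss + 1000 * d,
        )
        genes.append(gene)
        sa_class = classes[i]
        dependence = None
        if sa_class in ("SI", "SR"):
            n_cls = counts[sa_class]
            n_nd = int(round(config.nd_fraction * n_cls))
            dependence = "ND" if nd_rank[sa_class] < n_nd else "NI"
            nd_rank[sa_class] += 1
        gene_truth[gene.gene_id] = {
            "sa_class": sa_class,
            "dependence": dependence or "",
            "subclass": f"{sa_class}-{dependence}" if dependence else "",
        }
        gene_meta.append((gene, sa_class, dependence))

    # --- planted nucleosome intervals -------------------------------------
    n_probes = (config.chrom_length - pitch) // pitch + 1
    positions = {c: 1 + pitch * np.arange(n_probes, dtype=np.int64) for c in chroms}
    planted: dict[str, dict[str, list[tuple[int, int]]]] = {
        cond: {c: [] for c in chroms} for cond in CONDITIONS
    }

    def plant(cond: str, chrom: str, ga: int, gb: int, min_probes: int = 4) -> None:
        rng_idx = _probe_index_range(ga, gb, pitch, n_probes)
        if rng_idx is None or rng_idx[1] - rng_idx[0] + 1 < min_probes:
            raise GenerationError(
                f"cannot fit a {min_probes}-probe run over [{ga},{gb}] on {chrom}"
            )
        planted[cond][chrom].append(rng_idx)

    def plant_probes(cond: str, chrom: str, i0: int, n_run: int) -> None:
        i1 = i0 + n_run - 1
        if i0 < 0 or i1 >= n_probes:
            raise GenerationError(f"probe run [{i0},{i1}] outside {chrom}")
        planted[cond][chrom].append((i0, i1))

    def rel_span(gene: GeneModel, rel_lo: int, rel_hi: int) -> tuple[int, int]:
        if gene.strand == FORWARD:
            return gene.tss + rel_lo, gene.tss + rel_hi
        return gene.tss - rel_hi, gene.tss - rel_lo

    for gene, sa_class, _dep in gene_meta:
        body = rel_span(gene, 100, 500)
        plant(CONTROL, gene.chromosome, *body)
        plant(TREATED, gene.chromosome, *body)
        # tile-intersection over rel -205..-6 guarantees contiguous coverage
        # of the -175..-25 profile windows on either strand
        prom = rel_span(gene, -205, -6)
        if sa_class == "SI":
            plant(CONTROL, gene.chromosome, *prom)
        elif sa_class == "SR":
            plant(TREATED, gene.chromosome, *prom)
        else:
            plant(CONTROL, gene.chromosome, *prom)
            plant(TREATED, gene.chromosome, *prom)

    # intergenic runs, midway between consecutive genes on each chromosome:
    # exactly 4 probes (a distinct-width region) alternating with 6 (fuzzy)
    for chrom in chroms:
        tss_list = sorted(g.tss for g in genes if g.chromosome == chrom)
        for j, (a, b) in enumerate(zip(tss_list, tss_list[1:])):
            mid = (a + b) // 2
            n_run = 4 if j % 2 == 0 else 6
            i0 = round((mid - 1) / pitch) - n_run // 2
            run_start = 1 + pitch * i0
            run_end = 1 + pitch * (i0 + n_run - 1) + pitch - 1
            if run_start - a < 1050 or b - run_end < 1050:
                continue  # keep clear of the +/-1000 bp profile spans
            for cond in CONDITIONS:
                plant_probes(cond, chrom, i0, n_run)

    # --- probe values ------------------------------------------------------
    tracks: dict[str, dict[str, ProbeTrack]] = {}
    truth_nucs: dict[str, dict[str, list[GenomicInterval]]] = {}
    for cond in CONDITIONS:
        tracks[cond] = {}
        truth_nucs[cond] = {}
        for chrom in chroms:
            means = np.full(n_probes, config.background_mean)
            intervals = []
            merged: list[list[int]] = []
            for i0, i1 in sorted(set(planted[cond][chrom])):
                if merged and i0 <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], i1)
                else:
                    merged.append([i0, i1])
            for i0, i1 in merged:
                means[i0 : i1 + 1] = config.nucleosome_signal_mean
                intervals.append(
                    GenomicInterval(
                        chrom,
                        int(positions[chrom][i0]),
                        int(positions[chrom][i1]) + pitch - 1,
                    )
                )
            noise = rng.normal(0.0, 1.0, size=(n_probes, config.replicate_count))
            values = means[:, None] + config.noise_sd * noise
            tracks[cond][chrom] = ProbeTrack(chrom, positions[chrom].copy(), values)
            truth_nucs[cond][chrom] = intervals

    # --- expression --------------------------------------------------------
    r = config.expression_replicates
    eff = config.effect_size_log2fc
    rows = []
    for gene, sa_class, dep in gene_meta:
        if sa_class == "SIL":
            cells = np.full((2, 2), -1.0)
        elif sa_class == "CON":
            cells = np.full((2, 2), 5.0)
        elif sa_class == "SI":
            base = 1.0
            mut_eff = 0.0 if dep == "ND" else eff
            cells = np.array([[base, base + eff], [base, base + mut_eff]])
        elif sa_class == "SR":
            base = 4.0
            mut_eff = 0.0 if dep == "ND" else eff
            cells = np.array([[base, base - eff], [base, base - mut_eff]])
        else:  # OTHER: mildly responsive, never crosses any threshold
            cells = np.array([[1.5, 2.5], [1.5, 2.5]])
        noise = rng.normal(0.0, 1.0, size=(2, 2, r)) * config.expression_noise_sd
        for gi, geno in enumerate(("Col0", "npr1")):
            for ti, treat in enumerate(("control", "SA")):
                for rep in range(r):
                    rows.append(
                        {
                            "gene_id": gene.gene_id,
                            "genotype": geno,
                            "treatment": treat,
                            "replicate": rep + 1,
                            "value": cells[gi, ti] + noise[gi, ti, rep],
                        }
                    )
    expression = pd.DataFrame(rows)

    # --- promoters and motifs ----------------------------------------------
    plen = config.promoter_length
    promoters: dict[str, str] = {}
    promoter_segments: dict[str, dict[str, list[tuple[int, int]]]] = {}
    planted_motifs: list[tuple[str, int, str, str]] = []
    occupied_local = (plen - 200 + 1, plen)  # TSS-relative -200..-1
    for gene, sa_class, _dep in gene_meta:
        seq = "".join(rng.choice(list("ACGT"), size=plen))
        segs: dict[str, list[tuple[int, int]]] = {"NOR": [], "NFR": [], "remodeled": []}
        occ_class = "remodeled" if sa_class in ("SI", "SR") else "NOR"
        segs[occ_class].append(occupied_local)
        segs["NFR"].append((1, occupied_local[0] - 1))
        promoter_segments[gene.gene_id] = segs
        if sa_class != "SIL":
            nfr_len = occupied_local[0] - 1
            n_plant = max(1, int(round(config.motif_plant_rate * nfr_len / 1000.0)))
            chars = list(seq)
            for j in range(n_plant):
                motif = "TTGAC" if j % 2 == 0 else "TGACG"
                pos = int(rng.integers(1, nfr_len - len(motif) + 1))
                chars[pos - 1 : pos - 1 + len(motif)] = list(motif)
                planted_motifs.append((gene.gene_id, pos, motif, "NFR"))
            seq = "".join(chars)
        promoters[gene.gene_id] = seq

    truth = TruthRecord(
        nucleosomes=truth_nucs,
        gene_classes=gene_truth,
        promoter_segments=promoter_segments,
        planted_motifs=planted_motifs,
    )
    return SimulatedDataset(
        config=config,
        tracks=tracks,
        genes=genes,
        expression=expression,
        promoters=promoters,
        truth=truth,
        chromosome_lengths=chrom_lengths,
    )
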