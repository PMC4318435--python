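# nucdyn

Nucleosome positioning and remodeling analysis from tiling-array enrichment
tracks: stringency-based calling of distinct/fuzzy nucleosome regions,
base-resolution comparison of two conditions, TSS-anchored occupancy and
remodeling profiles stratified by expression class, and promoter motif
enrichment statistics — plus a synthetic-data generator with planted ground
truth so the whole pipeline is testable offline.

## Package layout

| module | purpose |
| --- | --- |
| `nucdyn.io_annotation` | probe-track/gene-table/BED/FASTA IO, 1-based coordinate arithmetic, strand-aware TSS-relative conversion |
| `nucdyn.synthetic_data` | seeded dataset simulator (tracks, genes, expression, promoters) with planted truth |
| `nucdyn.nucleosome_calling` | replicate-consistent run calling at seven stringency levels; distinct = 131–161 bp span, fuzzy ≥ 161 bp |
| `nucdyn.remodeling` | base-level depleted/enriched/common partition between conditions, genome fraction summaries |
| `nucdyn.tss_profiles` | 40×50-bp window occupancy over ±1000 bp from TSS (≥25 contiguous bp rule), group profiles, remodeling percentages, 150-bp block t-tests with FDR control |
| `nucdyn.expression_classes` | SI/SR/CON/SIL classification, per-gene two-way ANOVA, ND/NI dependence subclassing, BH/Storey q-values |
| `nucdyn.motif_enrichment` | local-composition expected occurrence, corrected motif frequencies per promoter region class with Wilson CIs, hexamer OE/lift screens |
| `nucdyn.cli` | `nucdyn` command-line pipeline |

Conventions: coordinates are 1-based inclusive internally (BED export is
0-based half-open); strand vocabulary is `forward`/`reverse` (aliases
`+,-,F,R` accepted); window label *L* covers TSS-relative offsets
[*L*−25, *L*+24], so −75 means −100…−51 and the TSS base sits in window +25.

Note on the expected-occurrence formula: `E = (∏F)/N · T` is implemented
with the division by the motif length N kept deliberately; the corrected
frequency of a motif over composition-random sequence therefore converges
to N rather than 1. Pass `standard_expectation=True` (CLI
`--standard-expectation`) for the textbook expectation.

## Command line

```bash
nucdyn simulate --seed 1 --out sim/                       # synthetic inputs + truth
nucdyn callnuc --control sim/control.tsv --treated sim/treated.tsv --out calls/
nucdyn remodel --control-regions c.bed --treated-regions t.bed \
               --genome-sizes sim/chrom_sizes.tsv --out remodel/
nucdyn classify --expr sim/expression.tsv --out groups.tsv
nucdyn profile --regions-control c.bed --regions-treated t.bed \
               --genes sim/genes.tsv --groups groups.tsv --out profiles/
nucdyn motifs --promoters sim/promoters.fasta --nor nor.bed --nfr nfr.bed \
              --remodeled rem.bed --out motif_stats.tsv
nucdyn hexamers --target sr.fa --contrast si.fa --background w.fa --out hex.tsv
nucdyn run-all --seed 1 --out run/                        # full pipeline + manifest
```

`run-all` chains every stage on a synthetic dataset and writes a
checksummed `run_manifest.json`; re-running with the same seed is
bit-identical.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes property tests (hypothesis) and independent oracles:
a per-position brute-force scan for the caller, a per-base membership scan
for the remodeling partition, an explicit sums-of-squares ANOVA oracle and
a brute-force Benjamini–Hochberg computation. `tests/test_acceptance.py`
holds the acceptance criteria (worked coordinate examples, the remodeling
accounting identity, sweep bookkeeping, oracle equivalences, seeded
parameter recovery and the motif suite).

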