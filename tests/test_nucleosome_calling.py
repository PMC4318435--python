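import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucdyn.errors import ValidationError
from nucdyn.io_annotation import GenomicInterval, ProbeTrack
from nucdyn.nucleosome_calling import (
    DEFAULT_LEVELS,
    StringencyConfig,
    call_regions,
    call_regions_per_replicate,
    coverage_per_nucleosome,
    stringency_sweep,
)
from tests.conftest import make_track

CFG = StringencyConfig()


# ---------------------------------------------------------------------------
# independent oracle: per-position scan, probe by probe, replicate by replicate
# ---------------------------------------------------------------------------


def oracle_base_set(track, threshold, cfg=CFG):
    """Brute-force base set: test every probe against every replicate, group
    qualifying probes into gap-limited runs, keep runs of >= 4 probes whose
    tile union spans >= the distinct minimum, and enumerate covered bases."""
    qualifies = []
    for i in range(track.n_probes):
        ok = True
        for r in range(track.replicate_count):
            if not track.values[i, r] >= threshold:
                ok = False
        qualifies.append(ok)
    bases = set()
    run = []
    runs = []
    for i in range(track.n_probes):
        if not qualifies[i]:
            if run:
                runs.append(run)
            run = []
            continue
        if run and track.positions[i] - track.positions[run[-1]] > cfg.max_probe_gap:
            runs.append(run)
            run = []
        run.append(i)
    if run:
        runs.append(run)
    for run in runs:
        if len(run) < cfg.min_run_distinct:
            continue
        start = int(track.positions[run[0]])
        end = int(track.positions[run[-1]]) + cfg.probe_pitch - 1
        if end - start + 1 < cfg.distinct_min_span:
            continue
        bases.update(range(start, end + 1))
    return bases


def called_base_set(regions):
    bases = set()
    for r in regions:
        bases.update(range(r.interval.start, r.interval.end + 1))
    return bases


def random_track(rng, max_probes=200):
    n = int(rng.integers(1, max_probes + 1))
    # irregular pitch incl. occasional large gaps that must break runs
    steps = rng.choice([35, 35, 35, 20, 51, 200], size=n - 1) if n > 1 else []
    positions = np.concatenate([[100], 100 + np.cumsum(steps)]).astype(np.int64)
    values = rng.normal(-0.5, 1.0, size=(n, 3))
    return ProbeTrack("chrN", positions, values)


class TestCallRegionsExamples:
    def test_four_probe_distinct(self):
        tr = make_track([1000, 1035, 1070, 1105], [0.1, 0.0, 0.5, 0.2])
        regions = call_regions(tr, 0.0, CFG)
        assert len(regions) == 1
        r = regions[0]
        assert (r.interval.start, r.interval.end) == (1000, 1139)
        assert r.span == 140
        assert r.type == "distinct"
        assert r.n_probes == 4
        # tile-arithmetic oracle
        assert called_base_set(regions) == oracle_base_set(tr, 0.0)

    def test_five_probe_fuzzy(self):
        tr = make_track([1000, 1035, 1070, 1105, 1140], [0.1, 0.0, 0.5, 0.2, 0.3])
        regions = call_regions(tr, 0.0, CFG)
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (1000, 1174)
        assert regions[0].span == 175
        assert regions[0].type == "fuzzy"

    def test_three_probes_no_region(self):
        tr = make_track([1000, 1035, 1070], [0.5, 0.5, 0.5])
        assert call_regions(tr, 0.0, CFG) == []

    def test_replicate_failure_breaks_run(self):
        # probe 2 passes in only 2 of 3 replicates
        values = np.full((4, 3), 0.5)
        values[1, 2] = -0.5
        tr = ProbeTrack("chr1", [1000, 1035, 1070, 1105], values)
        assert call_regions(tr, 0.0, CFG) == []

    def test_threshold_inclusive(self):
        tr = make_track([1000, 1035, 1070, 1105], [0.0, 0.0, 0.0, 0.0])
        assert len(call_regions(tr, 0.0, CFG)) == 1

    def test_gap_breaks_run(self):
        # 51 bp start-to-start gap between probes 2 and 3 exceeds max_probe_gap
        tr = make_track([1000, 1035, 1086, 1121], [0.5] * 4)
        assert call_regions(tr, 0.0, CFG) == []

    def test_empty_track(self):
        tr = ProbeTrack("chr1", np.array([], dtype=int), np.empty((0, 3)))
        assert call_regions(tr, 0.0, CFG) == []

    def test_short_span_discarded(self):
        # compressed pitch: 4 probes spanning < 131 bp emit nothing
        cfg = StringencyConfig(probe_pitch=20, max_probe_gap=50)
        tr = make_track([1000, 1020, 1040, 1060], [0.5] * 4)
        assert call_regions(tr, 0.0, cfg) == []


class TestCallRegionsProperties:
    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            tr = random_track(rng)
            thr = float(rng.choice(DEFAULT_LEVELS))
            assert called_base_set(call_regions(tr, thr, CFG)) == oracle_base_set(
                tr, thr
            )

    def test_monotonicity_across_levels(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            tr = random_track(rng)
            prev = None
            for level in DEFAULT_LEVELS:  # strictly decreasing
                bases = called_base_set(call_regions(tr, level, CFG))
                if prev is not None:
                    assert prev <= bases
                prev = bases

    def test_distinct_fuzzy_disjoint(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            tr = random_track(rng)
            regions = call_regions(tr, -0.5, CFG)
            distinct = called_base_set([r for r in regions if r.type == "distinct"])
            fuzzy = called_base_set([r for r in regions if r.type == "fuzzy"])
            assert not (distinct & fuzzy)

    def test_order_independence(self):
        rng = np.random.default_rng(99)
        tr = random_track(rng)
        perm = rng.permutation(tr.n_probes)
        order = np.argsort(tr.positions[perm], kind="mergesort")
        shuffled = ProbeTrack(
            "chrN", tr.positions[perm][order], tr.values[perm][order]
        )
        assert call_regions(shuffled, -0.5, CFG) == call_regions(tr, -0.5, CFG)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_hypothesis(self, seed):
        rng = np.random.default_rng(seed)
        tr = random_track(rng, max_probes=60)
        thr = float(rng.choice(DEFAULT_LEVELS))
        assert called_base_set(call_regions(tr, thr, CFG)) == oracle_base_set(tr, thr)

    def test_per_replicate_calls(self):
        values = np.full((4, 3), 0.5)
        values[0, 1] = -5.0  # replicate 2 fails at the first probe
        tr = ProbeTrack("chr1", [1000, 1035, 1070, 1105], values)
        per_rep = call_regions_per_replicate(tr, 0.0, CFG)
        assert len(per_rep) == 3
        assert len(per_rep[0]) == 1 and len(per_rep[2]) == 1
        assert per_rep[1] == []


class TestStringencySweep:
    def test_product_counts_small(self, track_factory):
        tracks = {
            "control": {"chr1": track_factory([100, 135, 170, 205], [0.5] * 4)},
            "treated": {"chr1": track_factory([100, 135, 170, 205], [-5.0] * 4)},
        }
        cfg = StringencyConfig(levels=(0.0,))
        table, summary = stringency_sweep(tracks, cfg)
        assert len(table) == 1 * 2 * 2 * 1  # level x condition x type x chrom
        assert summary.shape[0] == len(table)
        assert summary["n_regions"].sum() == 1

    def test_140_datasets(self, dataset):
        # 7 levels x 2 conditions x 2 types x 5 chromosomes
        from nucdyn.synthetic_data import SimulationConfig, simulate_dataset

        ds = simulate_dataset(SimulationConfig(seed=5, n_chromosomes=5, n_genes=10))
        table, summary = stringency_sweep(ds.tracks, CFG)
        assert len(table) == 140
        assert len(summary) == 140

    def test_disjoint_chromosomes_error(self, track_factory):
        tracks = {
            "control": {"chr1": track_factory([100], [0.0])},
            "treated": {"chr2": track_factory([100], [0.0])},
        }
        with pytest.raises(ValidationError):
            stringency_sweep(tracks, CFG)

    def test_distinct_only_plantings_leave_fuzzy_empty(self, track_factory):
        tr = track_factory([100, 135, 170, 205, 600, 635, 670, 705], [0.5] * 8)
        tracks = {"control": {"chr1": tr}, "treated": {"chr1": tr}}
        table, _ = stringency_sweep(tracks, StringencyConfig(levels=(0.0,)))
        for (level, cond, rtype, chrom), regions in table.items():
            if rtype == "fuzzy":
                assert regions == []
            else:
                assert len(regions) == 2


class TestCoveragePerNucleosome:
    def test_definition(self):
        regions = [GenomicInterval("chr1", i * 400 + 1, i * 400 + 140) for i in range(10)]
        assert coverage_per_nucleosome(10_000, regions) == 1000.0

    def test_genome_scale_arithmetic(self):
        regions = [
            GenomicInterval("chr1", i * 346 + 1, i * 346 + 140) for i in range(1000)
        ]
        assert coverage_per_nucleosome(346_000, regions) == 346.0

    def test_zero_regions_sentinel(self):
        assert math.isinf(coverage_per_nucleosome(1000, []))

    def test_per_base_variant(self):
        regions = [GenomicInterval("chr1", 1, 500)]
        assert coverage_per_nucleosome(1000, regions, per_base=True) == 2.0

    def test_invalid_length(self):
        with pytest.raises(ValidationError):
            coverage_per_nucleosome(0, [])
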