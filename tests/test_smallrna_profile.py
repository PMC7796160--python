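"""Profiling statistics must conserve read counts at every stage, recover
simulated truth within sampling bounds, and be invariant under rotation of
the circular consensus frame."""

import numpy as np
import pytest

from conftest import binomial_3sd
from satrna import satsim, smallrna_profile as sp
from satrna.errors import InvalidParameterError, NotComputableError
from satrna.preprocess import SmallRnaRead
from satrna.satsim import Hotspot, SimulationConfig
from satrna.tandem_mapper import Alignment, SatelliteConsensus, align_read, map_reads


def _aln(length, strand="sense", start=1, read_id="r", consensus="c"):
    return Alignment(read_id, consensus, strand, start, length, 0)


class TestClassifyBySize:
    @pytest.mark.parametrize(
        "length,ratio_cls,group_cls",
        [
            (20, "other", "siRNA"),
            (21, "siRNA", "siRNA"),
            (22, "siRNA", "siRNA"),
            (23, "other", "siRNA"),
            (24, "other", "other"),
            (26, "piRNA", "piRNA"),
            (28, "piRNA", "piRNA"),
            (30, "piRNA", "piRNA"),
            (31, "other", "piRNA"),
        ],
    )
    def test_window_boundaries_in_both_modes(self, length, ratio_cls, group_cls):
        assert sp.classify_by_size(length, "ratio") == ratio_cls
        assert sp.classify_by_size(length, "histogram-group") == group_cls


class TestSizeHistogram:
    def test_empty_input_gives_zero_histogram(self):
        hist = sp.size_histogram([])
        assert hist.total == 0

    def test_counts_partition_alignments(self):
        alns = [_aln(21), _aln(21, "antisense"), _aln(28), _aln(35)]
        hist = sp.size_histogram(alns)
        assert hist.total == 4
        assert hist.counts.loc[21, "sense"] == 1
        assert hist.counts.loc[21, "antisense"] == 1

    def test_simulated_modal_pirna_length_recovered(self, consensus_360):
        cfg = SimulationConfig(
            seed=3, n_reads=5000, class_mix={"siRNA": 0.0, "piRNA": 1.0, "other": 0.0}
        )
        reads, _ = satsim.simulate_small_rna_reads(cfg, consensus_360)
        alns, _ = map_reads(reads, consensus_360)
        hist = sp.size_histogram(alns)
        assert hist.counts.sum(axis=1).idxmax() == 28


class TestRatio:
    def test_arithmetic(self):
        hist = sp.size_histogram([_aln(28)] * 25 + [_aln(21)] * 10)
        assert sp.pirna_sirna_ratio(hist) == 2.5

    def test_zero_sirna_not_computable(self):
        with pytest.raises(NotComputableError):
            sp.pirna_sirna_ratio(sp.size_histogram([_aln(28)]))

    def test_simulated_ratio_recovered_within_sampling_error(self, consensus_360):
        mix = satsim.class_mix_for_ratio(6.0, other=0.0)
        cfg = SimulationConfig(seed=4, n_reads=50_000, class_mix=mix)
        reads, _ = satsim.simulate_small_rna_reads(cfg, consensus_360)
        alns, _ = map_reads(reads, consensus_360)
        ratio = sp.pirna_sirna_ratio(sp.size_histogram(alns))
        pi = sum(1 for a in alns if 26 <= a.read_length <= 30)
        si = sum(1 for a in alns if 21 <= a.read_length <= 22)
        sd = 6.0 * np.sqrt(1 / pi + 1 / si)  # delta-method SD of a count ratio
        assert abs(ratio - 6.0) < 3 * sd


class TestStrandFractions:
    def test_all_sense_dominant_one(self):
        f, dom = sp.strand_fractions([_aln(28)] * 5, "piRNA")
        assert (f, dom) == (1.0, 1.0)

    def test_80_20_split(self):
        alns = [_aln(28)] * 80 + [_aln(28, "antisense")] * 20
        assert sp.strand_fractions(alns, "piRNA") == (0.8, 0.8)

    def test_symmetric_simulation_not_dominant(self, consensus_360):
        cfg = SimulationConfig(
            seed=5,
            n_reads=10_000,
            class_mix={"siRNA": 1.0, "piRNA": 0.0, "other": 0.0},
            sense_fraction_sirna=0.5,
        )
        reads, _ = satsim.simulate_small_rna_reads(cfg, consensus_360)
        alns, _ = map_reads(reads, consensus_360)
        _, dom = sp.strand_fractions(alns, "siRNA")
        assert dom <= 0.52

    def test_no_reads_not_computable(self):
        with pytest.raises(NotComputableError):
            sp.strand_fractions([], "piRNA")


class TestPositionFrequencyMatrix:
    def test_rows_sum_to_one(self, consensus_360):
        cfg = SimulationConfig(seed=6, n_reads=2000)
        reads, _ = satsim.simulate_small_rna_reads(cfg, consensus_360)
        alns, _ = map_reads(reads, consensus_360)
        pfm = sp.position_frequency_matrix(alns, {r.id: r.sequence for r in reads}, 8)
        assert np.allclose(pfm.sum(axis=1), 1.0, atol=1e-9)

    def test_u1_bias_recovered(self, consensus_360):
        cfg = SimulationConfig(
            seed=7,
            n_reads=10_000,
            class_mix={"siRNA": 0.0, "piRNA": 1.0, "other": 0.0},
            u1_prob_pirna=0.9,
        )
        reads, _ = satsim.simulate_small_rna_reads(cfg, consensus_360)
        alns, _ = map_reads(reads, consensus_360)
        pfm = sp.position_frequency_matrix(alns, {r.id: r.sequence for r in reads}, 5)
        assert abs(pfm.loc[1, "U"] - 0.9) < binomial_3sd(0.9, len(alns))

    def test_uniform_reads_give_uniform_matrix(self):
        rng = np.random.default_rng(8)
        n = 4000
        reads = {f"r{i}": "".join(rng.choice(list("ACGT"), size=20)) for i in range(n)}
        alns = [_aln(20, read_id=f"r{i}") for i in range(n)]
        pfm = sp.position_frequency_matrix(alns, reads, 6)
        assert (np.abs(pfm.to_numpy() - 0.25) < binomial_3sd(0.25, n)).all()


class TestStartProfile:
    def test_profile_sums_to_strand_count(self, consensus_360):
        cfg = SimulationConfig(seed=9, n_reads=3000)
        reads, _ = satsim.simulate_small_rna_reads(cfg, consensus_360)
        alns, _ = map_reads(reads, consensus_360)
        prof = sp.positional_start_profile(alns, consensus_360, "piRNA", "sense")
        expected = sum(
            1
            for a in alns
            if a.strand == "sense" and sp.classify_by_size(a.read_length) == "piRNA"
        )
        assert prof.total == expected

    def test_single_hotspot_block_concentrates_starts(self, consensus_360):
        cfg = SimulationConfig(
            seed=10,
            n_reads=5000,
            class_mix={"siRNA": 0.0, "piRNA": 1.0, "other": 0.0},
            sense_fraction_pirna=1.0,
            hotspots=(Hotspot(30, 70, "sense", 1.0),),
            read_error_rate=0.0,
        )
        reads, _ = satsim.simulate_small_rna_reads(cfg, consensus_360)
        alns, _ = map_reads(reads, consensus_360)
        prof = sp.positional_start_profile(alns, consensus_360, "piRNA", "sense")
        assert prof.counts[29:70].sum() >= 0.95 * prof.total

    def test_junction_reads_report_positions_within_monomer(self, consensus_360):
        mono = consensus_360.monomer
        junction = mono[-10:] + mono[:11]
        read = SmallRnaRead("j", junction, "F" * 21)
        aln = align_read(read, consensus_360)
        prof = sp.positional_start_profile([aln], consensus_360, "siRNA", "sense")
        assert len(prof.counts) == 360
        assert prof.counts[350] == 1  # start 351, never > L


class TestDetectHotspots:
    def test_flat_profile_yields_no_regions(self):
        prof = sp.StartProfile("c", "piRNA", "sense", np.full(360, 5))
        assert sp.detect_hotspots(prof, min_fraction=2.0 * 5 / 360) == []

    def test_single_block_recovered_with_high_overlap(self, consensus_360):
        cfg = SimulationConfig(
            seed=11,
            n_reads=8000,
            class_mix={"siRNA": 0.0, "piRNA": 1.0, "other": 0.0},
            sense_fraction_pirna=1.0,
            hotspots=(Hotspot(30, 70, "sense", 1.0),),
        )
        reads, _ = satsim.simulate_small_rna_reads(cfg, consensus_360)
        alns, _ = map_reads(reads, consensus_360)
        prof = sp.positional_start_profile(alns, consensus_360, "piRNA", "sense")
        regions = sp.detect_hotspots(prof)
        assert len(regions) == 1
        region = regions[0]
        overlap = max(0, min(region.end, 70) - max(region.start, 30) + 1)
        assert overlap >= 0.9 * 41
        assert region.read_fraction > 0.95

    def test_two_disjoint_blocks_found_in_order(self, consensus_360):
        cfg = SimulationConfig(
            seed=12,
            n_reads=8000,
            class_mix={"siRNA": 0.0, "piRNA": 1.0, "other": 0.0},
            sense_fraction_pirna=1.0,
            hotspots=(Hotspot(30, 70, "sense", 1.0), Hotspot(220, 260, "sense", 1.0)),
        )
        reads, _ = satsim.simulate_small_rna_reads(cfg, consensus_360)
        alns, _ = map_reads(reads, consensus_360)
        prof = sp.positional_start_profile(alns, consensus_360, "piRNA", "sense")
        regions = sp.detect_hotspots(prof)
        assert len(regions) == 2
        assert regions[0].start < regions[1].start
        assert abs(regions[0].start - 30) <= 3 and abs(regions[1].end - 260) <= 3

    def test_wrapped_block_split_at_junction(self):
        counts = np.zeros(360, dtype=int)
        counts[340:] = 50
        counts[:20] = 50
        prof = sp.StartProfile("c", "piRNA", "sense", counts)
        regions = sp.detect_hotspots(prof)
        assert len(regions) == 2
        assert regions[0].start == 1 and regions[-1].end == 360
        assert sum(r.read_fraction for r in regions) == pytest.approx(1.0)


class TestCircularity:
    def test_rotation_shifts_profiles_and_preserves_summaries(self, monomer_360):
        r = 37
        cons = SatelliteConsensus("c", monomer_360)
        rotated = SatelliteConsensus("c", monomer_360[r:] + monomer_360[:r])
        cfg = SimulationConfig(seed=13, n_reads=3000, read_error_rate=0.0)
        reads, _ = satsim.simulate_small_rna_reads(cfg, cons)
        alns_orig, _ = map_reads(reads, cons)
        alns_rot, _ = map_reads(reads, rotated)
        ids = {a.read_id for a in alns_orig} & {a.read_id for a in alns_rot}
        sub_o = [a for a in alns_orig if a.read_id in ids]
        sub_r = [a for a in alns_rot if a.read_id in ids]
        assert sp.pirna_sirna_ratio(sp.size_histogram(sub_o)) == pytest.approx(
            sp.pirna_sirna_ratio(sp.size_histogram(sub_r))
        )
        assert sp.strand_fractions(sub_o, "piRNA") == sp.strand_fractions(sub_r, "piRNA")
        prof_o = sp.positional_start_profile(sub_o, cons, "piRNA", "sense")
        prof_r = sp.positional_start_profile(sub_r, rotated, "piRNA", "sense")
        assert np.array_equal(np.roll(prof_o.counts, -r), prof_r.counts)
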