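"""Normalized coverage: counting rules, normalization constraint, masking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from siqchip import (
    FragmentSet,
    TWO_ISLAND_CHROM_SIZES,
    build_normalized_coverage,
    build_siq_track,
    build_unit_coverage,
    check_normalization,
    mass_on_interval,
    two_island_fragments,
)
from conftest import random_fragments


def per_bp_oracle(fragments: FragmentSet, chrom_sizes, length_weighted=True):
    """Brute-force per-bp accumulation (the definition, one bp at a time)."""
    arrays = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    for frag in fragments:
        w = 1.0 / frag.length if length_weighted else 1.0
        for bp in range(frag.start, frag.stop):
            arrays[frag.chrom][bp] += w
    return arrays


def single_fragment(chrom="chr1", start=0, stop=10):
    return FragmentSet(pd.DataFrame([(chrom, start, stop)], columns=["chrom", "start", "stop"]))


class TestCountingRules:
    def test_one_fragment_length_weighted(self):
        track = build_normalized_coverage(single_fragment(), {"chr1": 20}, 1)
        v = track.values["chr1"]
        assert np.allclose(v[:10], 0.1) and np.all(v[10:] == 0)
        assert track.total() == pytest.approx(1.0, abs=1e-12)

    def test_one_fragment_unit(self):
        track = build_unit_coverage(single_fragment(), {"chr1": 20}, 1)
        assert np.allclose(track.values["chr1"][:10], 1.0)

    def test_unit_total_is_sum_of_lengths(self):
        rng = np.random.default_rng(4)
        sizes = {"chr1": 5000}
        fs = random_fragments(rng, sizes, 100)
        track = build_unit_coverage(fs, sizes, 1)
        assert track.total() == pytest.approx(fs.lengths.sum(), rel=1e-12)

    def test_fragment_beyond_chromosome_end_errors_unless_clipped(self):
        fs = single_fragment(stop=30)
        with pytest.raises(ValueError, match="beyond end"):
            build_normalized_coverage(fs, {"chr1": 20}, 1)
        clipped = build_normalized_coverage(fs, {"chr1": 20}, 1, clip=True)
        # clipped fragment keeps its original length weight
        assert clipped.total() == pytest.approx(20 / 30)


class TestTwoIslandFixture:
    """Two pile-up islands: equal unit-count peaks, unequal length-weighted."""

    def test_islands_disjoint(self):
        frame = two_island_fragments().frame
        left, right = frame.iloc[:3], frame.iloc[3:]
        assert left["stop"].max() <= right["start"].min()

    def test_unit_peaks_equal_length_weighted_ordered(self):
        frags = two_island_fragments()
        unit = build_unit_coverage(frags, TWO_ISLAND_CHROM_SIZES, 1).values["chr1"]
        lw = build_normalized_coverage(frags, TWO_ISLAND_CHROM_SIZES, 1).values["chr1"]
        mid = 45
        assert unit[:mid].max() == unit[mid:].max()
        assert lw[mid:].max() < lw[:mid].max()  # longer fragments -> lower peak

    def test_island_independence(self):
        """Fragments of one island never change bins of the other island."""
        frags = two_island_fragments()
        both = build_normalized_coverage(frags, TWO_ISLAND_CHROM_SIZES, 1).values["chr1"]
        left_only = build_normalized_coverage(
            FragmentSet(frags.frame.iloc[:3]), TWO_ISLAND_CHROM_SIZES, 1).values["chr1"]
        assert np.array_equal(both[:45], left_only[:45])


class TestNormalizationConstraint:
    @pytest.mark.parametrize("bin_size", [1, 10, 50])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sum_of_bins_equals_depth(self, bin_size, seed):
        rng = np.random.default_rng(seed)
        sizes = {"chr1": 3000, "chr2": 1700}
        fs = random_fragments(rng, sizes, 250)
        track = build_normalized_coverage(fs, sizes, bin_size)
        assert check_normalization(track) <= 1e-9

    def test_empty_track_residual_zero(self):
        empty = FragmentSet(pd.DataFrame(columns=["chrom", "start", "stop"]))
        track = build_normalized_coverage(empty, {"chr1": 100}, 1)
        assert check_normalization(track) == 0.0

    def test_unit_counting_violates_constraint(self):
        rng = np.random.default_rng(7)
        sizes = {"chr1": 2000}
        fs = random_fragments(rng, sizes, 50)
        track = build_unit_coverage(fs, sizes, 1)
        assert check_normalization(track) > 0

    @given(seed=st.integers(0, 1000), bin_size=st.sampled_from([1, 3, 10, 50]),
           n=st.integers(1, 150))
    def test_constraint_holds_for_arbitrary_sets(self, seed, bin_size, n):
        rng = np.random.default_rng(seed)
        sizes = {"chr1": 1500}
        fs = random_fragments(rng, sizes, n)
        track = build_normalized_coverage(fs, sizes, bin_size)
        assert check_normalization(track) <= 1e-9


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_binned_build_matches_per_bp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = {"chr1": 800, "chr2": 433}
        fs = random_fragments(rng, sizes, 120)
        per_bp = per_bp_oracle(fs, sizes)
        for bin_size in (1, 7, 25):
            track = build_normalized_coverage(fs, sizes, bin_size)
            for chrom, arr in per_bp.items():
                pad = (-len(arr)) % bin_size
                expected = np.pad(arr, (0, pad)).reshape(-1, bin_size).sum(axis=1)
                assert np.allclose(track.values[chrom], expected, rtol=1e-12, atol=1e-12)

    def test_rebinning_equals_direct_construction(self):
        rng = np.random.default_rng(9)
        sizes = {"chr1": 1000}
        fs = random_fragments(rng, sizes, 80)
        fine = build_normalized_coverage(fs, sizes, 1)
        direct = build_normalized_coverage(fs, sizes, 8)
        rebinned = fine.rebin(8)
        assert np.allclose(rebinned.values["chr1"], direct.values["chr1"], rtol=1e-12, atol=1e-12)
        assert rebinned.bin_size == direct.bin_size == 8


class TestSiqTrack:
    def test_identical_tracks_give_constant_alpha(self):
        rng = np.random.default_rng(10)
        sizes = {"chr1": 1000}
        f = build_normalized_coverage(random_fragments(rng, sizes, 60), sizes, 10)
        s = build_siq_track(f, f, alpha=0.05)
        finite = s.values["chr1"][np.isfinite(s.values["chr1"])]
        assert len(finite) > 0 and np.allclose(finite, 0.05)

    def test_zero_input_bins_masked_not_infinite(self):
        sizes = {"chr1": 40}
        f_ip = build_normalized_coverage(single_fragment(stop=10), sizes, 1)
        f_in = build_normalized_coverage(single_fragment(start=20, stop=30), sizes, 1)
        s = build_siq_track(f_ip, f_in, alpha=1.0)
        assert s.mask("chr1")[:20].all()  # IP-covered bins have no input -> masked
        assert np.isfinite(s.values["chr1"][20:30]).all()
        assert np.all(s.values["chr1"][20:30] == 0.0)

    def test_efficiency_above_one_warned_not_clamped(self):
        sizes = {"chr1": 20}
        f_ip = build_normalized_coverage(single_fragment(stop=10), sizes, 1)
        two_in = FragmentSet(pd.DataFrame(
            [("chr1", 0, 10), ("chr1", 10, 20)], columns=["chrom", "start", "stop"]))
        f_in = build_normalized_coverage(two_in, sizes, 1)
        with pytest.warns(UserWarning, match="efficiency > 1"):
            s = build_siq_track(f_ip, f_in, alpha=30.0)
        assert s.values["chr1"][0] == pytest.approx(30.0)  # alpha * 0.1 / 0.1

    def test_binning_mismatch_rejected(self):
        sizes = {"chr1": 100}
        a = build_normalized_coverage(single_fragment(), sizes, 1)
        b = build_normalized_coverage(single_fragment(), sizes, 2)
        with pytest.raises(ValueError, match="bin size"):
            build_siq_track(a, b, 1.0)


class TestMassProjection:
    def test_whole_genome_interval_returns_full_mass(self):
        rng = np.random.default_rng(11)
        sizes = {"chr1": 2000}
        fs = random_fragments(rng, sizes, 100)
        track = build_normalized_coverage(fs, sizes, 10)
        assert mass_on_interval(track, 42.0, ("chr1", 0, 2000)) == pytest.approx(42.0, rel=1e-9)

    def test_partition_masses_sum_to_total(self):
        rng = np.random.default_rng(12)
        sizes = {"chr1": 1777}
        fs = random_fragments(rng, sizes, 150)
        track = build_normalized_coverage(fs, sizes, 10)
        cuts = [0, 313, 700, 1001, 1777]  # deliberately not bin-aligned
        total = sum(mass_on_interval(track, 8.5, ("chr1", a, b))
                    for a, b in zip(cuts[:-1], cuts[1:]))
        assert total == pytest.approx(8.5, rel=1e-9)

    def test_single_fragment_inside_interval_carries_all_mass(self):
        track = build_normalized_coverage(single_fragment(start=5, stop=15), {"chr1": 100}, 1)
        assert mass_on_interval(track, 3.0, ("chr1", 0, 50)) == pytest.approx(3.0, rel=1e-12)

    def test_interval_outside_genome_rejected(self):
        track = build_normalized_coverage(single_fragment(), {"chr1": 100}, 1)
        with pytest.raises(ValueError, match="outside"):
            mass_on_interval(track, 1.0, ("chr1", 50, 200))
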