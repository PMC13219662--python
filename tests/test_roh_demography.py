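"""F_ROH, ROH ages, recent-Ne inversion, and the window-based caller."""

import numpy as np
import pytest

import loadscape as ls
from loadscape.roh_demography import (
    MB,
    ROHDemographyConfig,
    ROHInterval,
    call_roh_windows,
    froh,
    froh_expected,
    merge_roh_intervals,
    ne_from_froh,
    ne_trajectory,
    roh_age,
)


class TestRohAge:
    def test_printed_values(self):
        assert roh_age(1.0, 2.8) == pytest.approx(17.857, abs=1e-3)
        assert roh_age(5.0, 2.8) == pytest.approx(3.571, abs=1e-3)

    def test_doubling_length_halves_age(self):
        rng = np.random.default_rng(1)
        for length in rng.uniform(0.1, 80.0, size=20):
            assert roh_age(2 * length, 2.8) == pytest.approx(roh_age(length, 2.8) / 2)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            roh_age(0.0, 2.8)
        with pytest.raises(ValueError):
            roh_age(1.0, -1.0)


class TestNeFromFroh:
    def test_closed_form_points(self):
        assert ne_from_froh(0.5, 1) == pytest.approx(1.0)
        assert ne_from_froh(0.75, 2) == pytest.approx(1.0)

    def test_forward_inverse_roundtrip(self):
        """The survival-form round trip is exact to 1e-9 everywhere; the
        F-form agrees wherever F is representable away from 1."""
        from loadscape.roh_demography import froh_survival, ne_from_froh_survival

        for ne in (2.0, 10.0, 100.0, 1e4):
            for t in (1.0, 10.0, 100.0):
                s = froh_survival(ne, t)
                assert ne_from_froh_survival(s, t) == pytest.approx(ne, rel=1e-9)
                f = froh_expected(ne, t)
                if f < 0.999:  # away from the representability limit of 1 - F
                    assert ne_from_froh(f, t) == pytest.approx(ne, rel=1e-9)

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                ne_from_froh(bad, 10)


class TestFroh:
    def _config(self, genome=100 * MB, **kw):
        return ROHDemographyConfig(genome_length=genome, **kw)

    def test_half_genome(self):
        ivs = [ROHInterval("S", "chr01", 0, 50 * MB)]
        assert froh(ivs, self._config()) == pytest.approx(0.5)

    def test_short_tracts_below_cutoff(self):
        ivs = [ROHInterval("S", "chr01", i * MB, i * MB + MB // 2) for i in range(5)]
        assert froh(ivs, self._config()) == 0.0

    def test_posterior_threshold(self):
        ivs = [
            ROHInterval("S", "chr01", 0, 10 * MB, p_roh=0.95),
            ROHInterval("S", "chr01", 20 * MB, 30 * MB, p_roh=0.5),
        ]
        assert froh(ivs, self._config()) == pytest.approx(0.1)

    def test_monotone_in_min_length(self):
        rng = np.random.default_rng(8)
        ivs = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(MB, 3 * MB))
            length = int(rng.integers(MB // 4, 4 * MB))
            ivs.append(ROHInterval("S", "chr01", pos, pos + length))
            pos += length
        previous = 1.1
        for cutoff in (0, MB, 2 * MB, 4 * MB):
            value = froh(ivs, self._config(genome=pos + MB, min_roh_length=cutoff))
            assert value <= previous
            previous = value

    def test_interval_beyond_genome_is_error(self):
        ivs = [ROHInterval("S", "chr01", 0, 120 * MB)]
        cfg = self._config(chrom_lengths={"chr01": 100 * MB})
        with pytest.raises(ValueError, match="beyond"):
            froh(ivs, cfg)

    def test_mixed_samples_rejected(self):
        ivs = [
            ROHInterval("S1", "chr01", 0, 2 * MB),
            ROHInterval("S2", "chr01", 0, 2 * MB),
        ]
        with pytest.raises(ValueError, match="one sample"):
            froh(ivs, self._config())


class TestMergeIntervals:
    def test_merge_is_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(12)
        ivs = [
            ROHInterval("S", f"chr{rng.integers(1, 3)}", int(a), int(a) + int(l))
            for a, l in zip(
                rng.integers(0, 50 * MB, size=40), rng.integers(1, 5 * MB, size=40)
            )
        ]
        merged = merge_roh_intervals(ivs)
        assert merge_roh_intervals(merged) == merged
        shuffled = list(ivs)
        rng.shuffle(shuffled)
        total = sum(iv.length for iv in merge_roh_intervals(shuffled))
        assert total == sum(iv.length for iv in merged)


class TestWindowCaller:
    def test_zero_het_chromosome_is_one_roh(self):
        ivs = call_roh_windows({"chr01": []}, {"chr01": 10 * MB}, window_bp=MB)
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end) == (0, 10 * MB)

    def test_het_in_every_window_gives_no_roh(self):
        positions = np.arange(0, 10 * MB, 500_000)  # two hets per 1 Mb window
        ivs = call_roh_windows({"chr01": positions}, {"chr01": 10 * MB}, window_bp=MB)
        assert ivs == []

    def test_bad_window_is_error(self):
        with pytest.raises(ValueError):
            call_roh_windows({}, {"chr01": MB}, window_bp=0)

    def test_planted_tracts_recovered_within_one_window(self):
        """het rate 0 inside tracts, 1e-3 outside: the caller recovers each
        tract with boundary error at most one window."""
        rng = np.random.default_rng(21)
        window = 100_000
        genome = ls.simulate_froh_genome(
            0.4, 100 * MB, het_rate=1e-3, rng=rng
        )
        called = call_roh_windows(
            genome.het_positions, genome.chrom_lengths, window_bp=window
        )
        # symmetric difference between called and truth coverage is at most
        # one window per tract boundary
        length = genome.chrom_lengths["chr01"]
        cover_called = np.zeros(length // window, dtype=bool)
        cover_truth = np.zeros_like(cover_called)
        for iv in called:
            cover_called[iv.start // window : iv.end // window] = True
        for iv in genome.tracts:
            cover_truth[iv.start // window : iv.end // window] = True
        mismatch_windows = int((cover_called ^ cover_truth).sum())
        assert mismatch_windows <= 2 * len(genome.tracts)
        # and each sufficiently long truth tract is hit by exactly one called ROH
        for iv in (t for t in genome.tracts if t.length >= 4 * window):
            hits = [c for c in called if c.start < iv.end and c.end > iv.start]
            assert len(hits) == 1
            assert abs(hits[0].start - iv.start) <= window
            assert abs(hits[0].end - iv.end) <= window


class TestNeTrajectory:
    def test_composition_of_closed_forms(self):
        """A single 50-Mb ROH covering half the genome, in a bin whose
        representative length is 50 Mb, reproduces roh_age and ne_from_froh
        composed exactly."""
        cfg = ROHDemographyConfig(
            genome_length=100 * MB, length_bins=((25.0, 100.0),)
        )
        ivs = {"S1": [ROHInterval("S1", "chr01", 0, 50 * MB)]}
        traj = ne_trajectory(ivs, cfg)
        row = traj.iloc[0]
        assert row["length_rep_mb"] == pytest.approx(50.0)
        assert row["age_generations"] == pytest.approx(roh_age(50.0, 2.8))
        assert row["age_generations"] == pytest.approx(0.357, abs=1e-3)
        assert row["f_bin"] == pytest.approx(0.5)
        assert row["ne"] == pytest.approx(ne_from_froh(0.5, roh_age(50.0, 2.8)))

    def test_no_roh_means_all_bins_undetermined(self):
        cfg = ROHDemographyConfig(genome_length=100 * MB)
        traj = ne_trajectory({"S1": []}, cfg)
        assert traj["ne"].isna().all()

    def test_empty_bins_rejected(self):
        cfg = ROHDemographyConfig(genome_length=100 * MB, length_bins=())
        with pytest.raises(ValueError):
            ne_trajectory({"S1": []}, cfg)

    def test_age_decreases_with_length_and_years_scale(self):
        cfg = ROHDemographyConfig(genome_length=100 * MB)
        traj = ne_trajectory({"S1": []}, cfg)
        ages = traj["age_generations"].to_numpy()
        assert (np.diff(ages) < 0).all()
        assert np.allclose(traj["age_years"], ages * cfg.generation_time)
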