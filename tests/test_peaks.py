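"""Peak calling: standardization, sliding-window caller, consensus, subtraction."""

import numpy as np
import pytest

from telomap import (
    GenomeAssembly,
    GenomicInterval,
    IntervalSet,
    PeakCall,
    ProbeSignalTrack,
    SyntheticConfig,
    call_peaks,
    make_chip_replicates,
    make_genome,
    median_standardize,
    peaks_to_intervals,
    read_tracks,
    replicate_consensus,
    subtract_telomeric,
    telomere_windows,
    write_tracks,
)
from telomap.genome import GenomeError


def flat_track(rng, n_probes=5000, spacing=250, sd=1.0, rep="rep1", chrom="chr1"):
    starts = np.arange(n_probes, dtype=np.int64) * spacing
    return ProbeSignalTrack(
        chrom=np.full(n_probes, chrom, dtype=object),
        start=starts,
        end=starts + spacing,
        value=rng.normal(0, sd, n_probes),
        replicate_id=rep,
    )


class TestMedianStandardize:
    def test_identical_tracks_equal_standardized_input(self, rng):
        t = flat_track(rng)
        tracks = [
            ProbeSignalTrack(t.chrom, t.start, t.end, t.value.copy(), f"r{i}")
            for i in range(3)
        ]
        med = median_standardize(tracks)
        z = (t.value - t.value.mean()) / t.value.std(ddof=1)
        assert np.allclose(med.value, z)

    def test_median_of_three_distinct_values(self):
        base = dict(
            chrom=np.array(["c"] * 4, dtype=object),
            start=np.array([0, 10, 20, 30]),
            end=np.array([10, 20, 30, 40]),
        )
        # three tracks identical except one probe shifted; per-probe median
        vals = [np.array([0.0, 1.0, -1.0, 2.0]) for _ in range(3)]
        vals[0][1] = -3.0
        vals[2][1] = 5.0
        tracks = [ProbeSignalTrack(value=v, replicate_id=f"r{i}", **base) for i, v in enumerate(vals)]
        med = median_standardize(tracks)
        z1 = (vals[1] - vals[1].mean()) / vals[1].std(ddof=1)
        # track 1 holds the middle value at the disturbed probe only if its
        # standardized value is between the others; verify by brute force
        stack = np.vstack(
            [(v - v.mean()) / v.std(ddof=1) for v in vals]
        )
        assert np.allclose(med.value, np.sort(stack, axis=0)[1])
        assert med.value[0] == pytest.approx(np.median(stack[:, 0]))
        del z1

    def test_brute_force_oracle_random_tracks(self, rng):
        tracks = [flat_track(rng, n_probes=400, rep=f"r{i}") for i in range(3)]
        med = median_standardize(tracks)
        stack = np.vstack(
            [(t.value - t.value.mean()) / t.value.std(ddof=1) for t in tracks]
        )
        oracle = np.array(
            [sorted(stack[:, j])[1] for j in range(stack.shape[1])]
        )
        assert np.allclose(med.value, oracle)

    def test_grid_mismatch_and_zero_variance_rejected(self, rng):
        t1 = flat_track(rng)
        t2 = flat_track(rng, n_probes=4999)
        with pytest.raises(GenomeError):
            median_standardize([t1, t2])
        t3 = flat_track(rng)
        t3.value[:] = 1.0
        with pytest.raises(GenomeError):
            median_standardize([t1, t3])

    def test_track_tsv_round_trip(self, tmp_path, rng):
        tracks = [flat_track(rng, n_probes=50, rep=f"rep{i}") for i in range(2)]
        p = tmp_path / "tracks.tsv"
        write_tracks(tracks, p)
        back = read_tracks(p)
        assert len(back) == 2
        for a, b in zip(tracks, back):
            assert np.allclose(a.value, b.value)
            assert a.same_grid(b)


class TestCallPeaks:
    def test_planted_site_yields_one_covering_peak(self, rng):
        t = flat_track(rng, n_probes=4000)
        lo, hi = 2000 * 250, 2000 * 250 + 1000  # planted 1 kb site
        m = (t.start >= lo) & (t.end <= hi)
        t.value[m] += 5.0
        peaks = call_peaks(t, window_bp=500, step_bp=125, alpha=0.05)
        assert len(peaks) == 1
        assert peaks[0].interval.start <= lo and peaks[0].interval.end >= hi

    def test_mirrored_null_sd_consistency(self, rng):
        t = flat_track(rng, n_probes=20_000, sd=2.0)
        # windows of 2 probes: score sd = 2/sqrt(2)
        peaks = call_peaks(t, window_bp=500, step_bp=250, alpha=0.5)
        # estimate retrievable via the internal computation: recompute here
        starts = np.arange(0, int(t.end[-1]), 250)
        i0 = np.searchsorted(t.end, starts, side="right")
        i1 = np.searchsorted(t.start, np.minimum(starts + 500, t.end[-1]), "left")
        cs = np.concatenate([[0.0], np.cumsum(t.value)])
        keep = i1 > i0
        scores = (cs[i1[keep]] - cs[i0[keep]]) / (i1[keep] - i0[keep])
        neg = scores[scores < 0]
        est = np.sqrt(np.mean(neg**2))
        true_sd = scores.std()
        assert est == pytest.approx(true_sd, rel=0.05)
        del peaks

    def test_monotone_in_alpha(self, rng):
        t = flat_track(rng, n_probes=3000)
        t.value[1000:1008] += 4.0
        n_peaks = [
            len(call_peaks(t, alpha=a)) for a in (0.5, 0.1, 0.05, 0.01, 0.001)
        ]
        assert n_peaks == sorted(n_peaks, reverse=True)

    def test_all_positive_scores_error(self):
        t = ProbeSignalTrack(
            chrom=np.array(["c"] * 10, dtype=object),
            start=np.arange(10) * 100,
            end=np.arange(1, 11) * 100,
            value=np.full(10, 3.0),
        )
        with pytest.raises(GenomeError, match="null"):
            call_peaks(t, window_bp=200, step_bp=100)


class TestConsensus:
    def _peak(self, chrom, start, end, p=1e-4):
        return PeakCall(GenomicInterval(chrom, start, end), p)

    def test_three_of_five_retained_with_support(self):
        sets = [
            [self._peak("c", 100, 300)],
            [self._peak("c", 150, 350)],
            [self._peak("c", 90, 260)],
            [],
            [],
        ]
        out = replicate_consensus(sets, min_support=3)
        assert len(out) == 1
        assert out[0].support == 3
        assert (out[0].interval.start, out[0].interval.end) == (90, 350)

    def test_two_of_five_dropped(self):
        sets = [[self._peak("c", 100, 300)], [self._peak("c", 150, 350)], [], [], []]
        assert replicate_consensus(sets, min_support=3) == []

    def test_order_invariance(self, rng):
        sets = []
        for _ in range(5):
            peaks = []
            for _ in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, 5000))
                peaks.append(self._peak("c", s, s + int(rng.integers(50, 400))))
            sets.append(peaks)
        out1 = replicate_consensus(sets, 3)
        order = rng.permutation(5)
        out2 = replicate_consensus([sets[i] for i in order], 3)
        key = lambda pc: (pc.interval.chrom, pc.interval.start, pc.interval.end, pc.support)
        assert sorted(map(key, out1)) == sorted(map(key, out2))

    def test_brute_force_bitmap_oracle(self, rng):
        """Random jittered peak sets vs a base-level coverage oracle."""
        L = 3000
        for trial in range(25):
            trng = np.random.default_rng(1000 + trial)
            sets = []
            for _ in range(5):
                peaks = []
                for _ in range(int(trng.integers(0, 10))):
                    s = int(trng.integers(0, L - 60))
                    peaks.append(self._peak("c", s, s + int(trng.integers(10, 60))))
                sets.append(peaks)
            out = replicate_consensus(sets, 3)

            # oracle: boolean coverage, connected runs, per-replicate overlap
            cover = np.zeros(L + 1, dtype=bool)
            for peaks in sets:
                for pc in peaks:
                    cover[pc.interval.start : pc.interval.end] = True
            regions = []
            in_run = False
            for i in range(L + 1):
                if cover[i] and not in_run:
                    run_start, in_run = i, True
                elif not cover[i] and in_run:
                    regions.append((run_start, i))
                    in_run = False
            expected = []
            for rs, re in regions:
                support = sum(
                    any(pc.interval.start < re and pc.interval.end > rs for pc in peaks)
                    for peaks in sets
                )
                if support >= 3:
                    expected.append((rs, re, support))
            got = sorted(
                (pc.interval.start, pc.interval.end, pc.support) for pc in out
            )
            assert got == sorted(expected)


class TestSubtractTelomeric:
    def setup_method(self):
        self.asm = GenomeAssembly({"c": 100_000})
        self.tel = telomere_windows(self.asm, 15_000)

    def test_inside_removed_abutting_retained(self):
        peaks = [
            PeakCall(GenomicInterval("c", 1_000, 2_000), 1e-3),  # inside window
            PeakCall(GenomicInterval("c", 15_000, 16_000), 1e-3),  # abuts boundary
            PeakCall(GenomicInterval("c", 14_999, 16_000), 1e-3),  # 1 bp overlap
        ]
        kept = subtract_telomeric(peaks, self.tel)
        assert [(pc.interval.start, pc.interval.end) for pc in kept] == [(15_000, 16_000)]

    def test_membership_matches_brute_force(self, rng):
        peaks = []
        for _ in range(200):
            s = int(rng.integers(0, 99_000))
            peaks.append(PeakCall(GenomicInterval("c", s, s + int(rng.integers(1, 1000))), 0.01))
        kept = subtract_telomeric(peaks, self.tel)
        expected = [
            pc for pc in peaks
            if not (pc.interval.start < 15_000 or pc.interval.end > 85_000)
        ]
        assert [(p.interval.start, p.interval.end) for p in kept] == [
            (p.interval.start, p.interval.end) for p in expected
        ]


class TestEndToEndRecovery:
    def test_planted_sites_recovered_with_low_spurious_rate(self):
        """5-sigma peaks, 0.9 detection, 5 reps: >=90% recovery, <=5% spurious."""
        hits = 0
        total_sites = 0
        spurious = 0
        total_calls = 0
        for seed in range(8):
            cfg = SyntheticConfig(
                seed=seed, n_chrom=4, chrom_length_bp=100_000, n_ntbs=8,
                ntbs_margin_bp=25_000,
            )
            assembly, planted = make_genome(cfg)
            tracks = make_chip_replicates(assembly, planted, cfg)
            peaksets = [call_peaks(t) for t in tracks]
            consensus = replicate_consensus(peaksets, 3)
            ntbs = subtract_telomeric(consensus, telomere_windows(assembly, 15_000))
            called = peaks_to_intervals(ntbs)
            for iv in planted:
                total_sites += 1
                if any(iv.overlaps(c) for c in called):
                    hits += 1
            for c in called:
                total_calls += 1
                if not any(iv.overlaps(c) for iv in planted):
                    spurious += 1
        assert hits / total_sites >= 0.90
        assert spurious / max(total_calls, 1) <= 0.05
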