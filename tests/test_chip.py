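import numpy as np
import pandas as pd
import pytest

from irekit.chip import (
    RegionCountTable,
    call_differential_regions,
    classify_enhancer_states,
    conservation_window_mean,
    define_ires,
    region_counts,
    signal_matrix,
    SignalMatrix,
)
from irekit.intervals import GeneModel, GenomicInterval
from irekit.tracks import CoverageTrack


def make_table(counts, conditions, library_size=1_000_000):
    counts = np.asarray(counts)
    regions = [
        GenomicInterval("chr1", 1000 * i, 1000 * i + 500, name=f"r{i}")
        for i in range(counts.shape[0])
    ]
    meta = pd.DataFrame(
        {
            "condition": conditions,
            "replicate": list(range(1, len(conditions) + 1)),
            "library_size": library_size,
        },
        index=[f"s{i}" for i in range(len(conditions))],
    )
    return RegionCountTable(regions, counts, meta)


class TestRegionCounts:
    def test_constant_coverage_sums(self):
        track = CoverageTrack.zeros({"chr1": 1000}, fill=2.0)
        region = GenomicInterval("chr1", 100, 200)
        assert region_counts(track, [region])[0] == pytest.approx(200.0)

    def test_zero_track_and_linearity(self):
        track = CoverageTrack.zeros({"chr1": 1000})
        track.add(GenomicInterval("chr1", 0, 500), 1.0)
        r1 = GenomicInterval("chr1", 0, 100)
        r2 = GenomicInterval("chr1", 300, 400)
        both = GenomicInterval("chr1", 0, 100)
        c = region_counts(track, [r1, r2])
        assert c.sum() == pytest.approx(200.0)
        zero = CoverageTrack.zeros({"chr1": 1000})
        assert region_counts(zero, [r1, r2]).sum() == 0

    def test_out_of_bounds_clipped_with_warning(self):
        track = CoverageTrack.zeros({"chr1": 100}, fill=1.0)
        with pytest.warns(UserWarning, match="clipped"):
            c = region_counts(track, [GenomicInterval("chr1", 50, 200)])
        assert c[0] == pytest.approx(50.0)


class TestCallDifferentialRegions:
    def test_identical_conditions_give_no_ires(self, rng):
        base = rng.poisson(100, size=(50, 2))
        counts = np.hstack([base, base])
        table = make_table(counts, ["injured", "injured", "control", "control"])
        res = call_differential_regions(table, alpha=0.5)
        assert (res.table["call"] != "IRE").all()

    def test_scaling_injured_counts_never_decreases_log2fc(self, rng):
        counts = rng.poisson(80, size=(30, 4))
        table = make_table(counts, ["injured", "injured", "control", "control"])
        lfc1 = call_differential_regions(table).table["log2_fc"]
        boosted = counts.copy()
        boosted[:, :2] *= 3
        table2 = make_table(boosted, ["injured", "injured", "control", "control"])
        lfc2 = call_differential_regions(table2).table["log2_fc"]
        assert (lfc2 >= lfc1 - 1e-12).all()

    def test_invariant_to_global_library_rescale(self, rng):
        counts = rng.poisson(60, size=(40, 4))
        conds = ["injured", "injured", "control", "control"]
        r1 = call_differential_regions(make_table(counts, conds, 1_000_000))
        r2 = call_differential_regions(make_table(counts, conds, 5_000_000))
        assert np.allclose(r1.table["p_value"], r2.table["p_value"])
        assert np.allclose(r1.table["log2_fc"], r2.table["log2_fc"])

    def test_empty_library_errors(self):
        counts = np.array([[0, 5, 5, 5], [0, 5, 5, 5]])
        table = make_table(counts, ["injured", "injured", "control", "control"])
        with pytest.raises(ValueError, match="empty library"):
            call_differential_regions(table)

    def test_no_replicates_falls_back_to_poisson(self, rng):
        counts = rng.poisson(50, size=(20, 2))
        table = make_table(counts, ["injured", "control"])
        with pytest.warns(UserWarning, match="Poisson"):
            res = call_differential_regions(table)
        assert res.dispersion == 0.0

    def test_pvalue_criterion_used_for_zebrafish_style_rule(self, rng):
        counts = rng.poisson(50, size=(20, 4))
        table = make_table(counts, ["injured", "injured", "control", "control"])
        res = call_differential_regions(table, alpha=0.01, criterion="pvalue")
        assert res.criterion == "pvalue"


class TestDefineIres:
    def test_partition_and_promoter_exclusion(self):
        # TSS at 100: r0 (midpoint 250) is promoter-proximal, r2 (midpoint
        # 2 250) is distal; both r0 and r2 are up-called, r1 is flat
        genes = [GeneModel("g", "chr1", "+", 100)]
        counts = np.array(
            [[400, 420, 100, 110], [100, 105, 100, 98], [390, 410, 95, 105]]
        )
        table = make_table(counts, ["injured", "injured", "control", "control"])
        diff = call_differential_regions(table)
        assert list(diff.table["call"]) == ["IRE", "non-IRE", "IRE"]
        calls = define_ires(table.regions, diff, genes)
        assert list(calls) == ["excluded", "non-IRE", "IRE"]


class TestSignalMatrix:
    def test_constant_track_fills_matrix(self):
        track = CoverageTrack.zeros({"chr1": 20_000}, fill=3.0)
        anchors = [GenomicInterval("chr1", 9_000, 11_000)]
        m = signal_matrix(track, anchors, flank=1000, bin_width=100)
        assert m.values.shape == (1, 20)
        assert np.allclose(m.values, 3.0)

    def test_matches_naive_per_base_oracle(self, rng):
        arr = rng.random(50_000)
        track = CoverageTrack({"chr1": arr})
        anchors = [
            GenomicInterval("chr1", int(s), int(s) + 1000)
            for s in rng.integers(3000, 45_000, size=8)
        ]
        m = signal_matrix(track, anchors, flank=2000, bin_width=50)
        for i, a in enumerate(anchors):
            mid = a.midpoint
            for j in range(m.values.shape[1]):
                lo = mid - 2000 + j * 50
                expected = arr[lo : lo + 50].mean()
                assert m.values[i, j] == pytest.approx(expected)

    def test_minus_strand_tss_anchor_is_flipped(self):
        arr = np.zeros(10_000)
        arr[6_000:6_100] = 1.0  # downstream of TSS at 5 000 on + coordinates
        track = CoverageTrack({"chr1": arr})
        plus = signal_matrix(track, [GeneModel("p", "chr1", "+", 5_000)],
                             flank=2000, bin_width=100)
        minus = signal_matrix(track, [GeneModel("m", "chr1", "-", 5_000)],
                              flank=2000, bin_width=100)
        assert np.allclose(minus.values[0], plus.values[0][::-1])

    def test_planted_peak_profile_peaks_centrally(self):
        arr = np.zeros(30_000)
        center = 15_000
        ramp = np.concatenate([np.arange(500), np.arange(500)[::-1]])
        arr[center - 500 : center + 500] = ramp
        track = CoverageTrack({"chr1": arr})
        m = signal_matrix(track, [GenomicInterval("chr1", center - 50, center + 50)],
                          flank=5000, bin_width=100)
        prof = m.profile
        assert np.argmax(prof) in (len(prof) // 2 - 1, len(prof) // 2)

    def test_off_chromosome_zero_padded(self):
        track = CoverageTrack.zeros({"chr1": 3000}, fill=1.0)
        with pytest.warns(UserWarning, match="zero-padded"):
            m = signal_matrix(track, [GenomicInterval("chr1", 0, 100)],
                              flank=1000, bin_width=100)
        assert m.values[0, 0] == 0.0  # window ran past the chromosome start


class TestEnhancerStates:
    @staticmethod
    def _matrices(rng, n_per=30):
        def pop(ac, me3):
            return (np.full((n_per, 10), float(ac)) + rng.normal(0, 0.1, (n_per, 10)),
                    np.full((n_per, 10), float(me3)) + rng.normal(0, 0.1, (n_per, 10)))

        acs, me3s, truth = [], [], []
        for label, ac, me3 in [("poised", 1, 10), ("primed", 1, 1), ("active", 10, 1)]:
            a, m = pop(ac, me3)
            acs.append(a)
            me3s.append(m)
            truth += [label] * n_per
        ac = SignalMatrix(np.vstack(acs), "center", 500, 100)
        me3 = SignalMatrix(np.vstack(me3s), "center", 500, 100)
        return ac, me3, truth

    def test_recovers_constructed_states(self, rng):
        ac, me3, truth = self._matrices(rng)
        labels = classify_enhancer_states(ac, me3, seed=7)
        assert labels == truth

    def test_row_permutation_permutes_labels(self, rng):
        ac, me3, _ = self._matrices(rng)
        perm = rng.permutation(ac.values.shape[0])
        l1 = classify_enhancer_states(ac, me3, seed=7)
        l2 = classify_enhancer_states(
            SignalMatrix(ac.values[perm], "center", 500, 100),
            SignalMatrix(me3.values[perm], "center", 500, 100),
            seed=7,
        )
        assert l2 == [l1[i] for i in perm]

    def test_k_larger_than_n_errors(self):
        m = SignalMatrix(np.zeros((2, 4)), "center", 200, 100)
        with pytest.raises(ValueError):
            classify_enhancer_states(m, m, k=3)


class TestConservationWindowMean:
    def test_constant_and_half_missing(self):
        region = [GenomicInterval("chr1", 4_500, 5_500)]
        const = CoverageTrack.zeros({"chr1": 10_000}, fill=0.5)
        assert conservation_window_mean(const, region)[0] == pytest.approx(0.5)
        arr = np.full(10_000, np.nan)
        arr[4_500:5_000] = 1.0  # half the window defined
        half = CoverageTrack({"chr1": arr})
        assert conservation_window_mean(half, region)[0] == pytest.approx(1.0)

    def test_fully_missing_is_nan_not_zero(self):
        track = CoverageTrack({"chr1": np.full(10_000, np.nan)})
        out = conservation_window_mean(track, [GenomicInterval("chr1", 4000, 6000)])
        assert np.isnan(out[0])

    def test_linear_ramp_gives_midpoint_value(self):
        arr = np.arange(10_000, dtype=float) * 0.001
        track = CoverageTrack({"chr1": arr})
        region = [GenomicInterval("chr1", 4_000, 6_000)]  # midpoint 5 000
        # mean of the arithmetic sequence over [4500, 5500) is the value at
        # 4999.5, i.e. 4.9995
        got = conservation_window_mean(track, region, window=1000)[0]
        assert got == pytest.approx(4.9995)

    def test_odd_window_rejected(self):
        track = CoverageTrack.zeros({"chr1": 100})
        with pytest.raises(ValueError):
            conservation_window_mean(track, [], window=999)
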