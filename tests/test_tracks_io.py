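import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from termwindow.errors import TrackIOError, ValidationError
from termwindow.tracks_io import (
    CoverageTrack,
    GenomicRegion,
    anchored_vector,
    fold_enrichment,
    moving_average,
    read_bedgraph,
    region_mean,
    write_bedgraph,
)

from conftest import make_track, minus_unit, plus_unit


# -- bedGraph ---------------------------------------------------------------


class TestBedgraph:
    def test_single_interval(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chrI\t0\t10\t2\n")
        track = read_bedgraph(path, {"chrI": 50})
        assert np.all(track.data["chrI"][:10] == 2)
        assert np.all(track.data["chrI"][10:] == 0)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("")
        track = read_bedgraph(path, {"chrI": 100})
        assert np.all(track.data["chrI"] == 0)

    def test_round_trip_random(self, tmp_path, rng):
        values = rng.poisson(3.7, size=1000).astype(float) * 1.3
        track = make_track({"chrI": values})
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, path)
        back = read_bedgraph(path, {"chrI": 1000})
        np.testing.assert_array_equal(back.data["chrI"], values)

    def test_unknown_chromosome(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chrZ\t0\t10\t1\n")
        with pytest.raises(TrackIOError, match="chrZ"):
            read_bedgraph(path, {"chrI": 100})

    def test_conflicting_overlap(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chrI\t0\t10\t1\nchrI\t5\t15\t2\n")
        with pytest.raises(TrackIOError, match="conflicting"):
            read_bedgraph(path, {"chrI": 100})

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            make_track({"chrI": [-1.0, 2.0]})


# -- moving average ---------------------------------------------------------


class TestMovingAverage:
    def test_constant_fixed_point(self):
        for window in (1, 3, 220):
            out = moving_average(np.full(100, 7.5), window)
            np.testing.assert_allclose(out, 7.5)

    def test_impulse_window3(self):
        out = moving_average(np.array([0, 0, 0, 9, 0, 0, 0], dtype=float), 3)
        np.testing.assert_allclose(out, [0, 0, 3, 3, 3, 0, 0])

    def test_brute_force_oracle(self, rng):
        values = rng.random(2000) * 10
        window = 220
        expected = np.empty(2000)
        for i in range(2000):  # independent brute-force definition
            lo = max(i - (window - 1) // 2, 0)
            hi = min(i + window // 2 + 1, 2000)
            expected[i] = values[lo:hi].mean()
        np.testing.assert_allclose(moving_average(values, window), expected, atol=1e-9)

    def test_window_below_one_rejected(self):
        with pytest.raises(ValidationError):
            moving_average(np.ones(10), 0)

    @settings(max_examples=25, deadline=None)
    @given(
        values=st.lists(st.floats(0, 1e6), min_size=1, max_size=200),
        window=st.integers(1, 300),
    )
    def test_output_within_input_bounds(self, values, window):
        arr = np.asarray(values)
        out = moving_average(arr, window)
        assert len(out) == len(arr)
        assert out.min() >= arr.min() - 1e-6
        assert out.max() <= arr.max() + 1e-6


# -- anchored extraction ----------------------------------------------------


class TestAnchoredVector:
    def _ramp_track(self, n=10_000):
        return make_track({"chrI": np.arange(n, dtype=float)})

    def test_plus_strand_ramp(self):
        track = self._ramp_track()
        unit = plus_unit(start=50, mature_len=51)  # mature 3' end at 100
        vec = anchored_vector(track, unit, upstream=2, downstream=2, bin=1)
        np.testing.assert_array_equal(vec.values, [98, 99, 100, 101])
        np.testing.assert_array_equal(vec.positions, [-2, -1, 0, 1])

    def test_minus_strand_flip(self):
        track = self._ramp_track()
        unit = minus_unit(tss=199, mature_len=100, ext=50)  # mature 3' end at 100
        assert unit.anchor("mature_3p_end") == 100
        vec = anchored_vector(track, unit, upstream=2, downstream=2, bin=1)
        np.testing.assert_array_equal(vec.values, [102, 101, 100, 99])

    def test_edge_masking_and_direct_index_oracle(self, rng):
        values = rng.random(400)
        track = make_track({"chrI": values})
        unit = plus_unit(start=5, mature_len=1, ext=100)  # anchor at position 5
        vec = anchored_vector(track, unit, upstream=10, downstream=5, bin=1)
        assert not vec.mask[:5].any()  # genomic -5..-1 off-chromosome
        assert vec.mask[5:].all()
        expected = values[0:10]  # genomic 0..9 = rel -5..+4
        np.testing.assert_allclose(vec.values[5:], expected)

    def test_bin_means(self):
        track = make_track({"chrI": np.arange(100, dtype=float)})
        unit = plus_unit(start=10, mature_len=11)  # anchor at 20
        vec = anchored_vector(track, unit, upstream=4, downstream=4, bin=4)
        np.testing.assert_allclose(vec.values, [np.mean([16, 17, 18, 19]), np.mean([20, 21, 22, 23])])

    def test_missing_anchor_names_unit(self):
        from termwindow.annotation import TranscriptionUnit

        track = self._ramp_track(1000)
        unit = TranscriptionUnit(
            id="cut7", unit_class="CUT", chrom="chrI", start=100, end=400,
            strand="+", nbs_center=390,
        )
        with pytest.raises(ValidationError, match="cut7"):
            anchored_vector(track, unit, 10, 10, anchor_kind="mature_3p_end")

    def test_strand_symmetric_track_invariance(self, rng):
        """A track symmetric around the anchor gives the same vector on both strands."""
        anchor = 500
        half = rng.random(100)
        values = np.zeros(1001)
        values[anchor] = 5.0
        values[anchor + 1 : anchor + 101] = half
        values[anchor - 100 : anchor] = half[::-1]
        track = make_track({"chrI": values})
        up = plus_unit(start=anchor - 50, mature_len=51)
        down = minus_unit(tss=anchor + 99, mature_len=100)
        assert up.anchor() == down.anchor() == anchor
        v1 = anchored_vector(track, up, 80, 80, bin=1)
        v2 = anchored_vector(track, down, 80, 80, bin=1)
        np.testing.assert_allclose(v1.values, v2.values)


# -- region statistics ------------------------------------------------------


class TestRegionStats:
    def test_region_mean_constant(self):
        track = make_track({"chrI": np.full(100, 7.0)})
        assert region_mean(track, GenomicRegion("chrI", 10, 60)) == 7.0

    def test_region_mean_zero(self):
        track = make_track({"chrI": np.zeros(100)})
        assert region_mean(track, GenomicRegion("chrI", 0, 100)) == 0.0

    def test_region_mean_brute_force(self, rng):
        values = rng.random(500)
        track = make_track({"chrI": values})
        region = GenomicRegion("chrI", 37, 211)
        explicit = sum(values[i] for i in range(37, 211)) / (211 - 37)
        assert abs(region_mean(track, region) - explicit) < 1e-12

    def test_out_of_bounds(self):
        track = make_track({"chrI": np.zeros(100)})
        with pytest.raises(ValidationError):
            region_mean(track, GenomicRegion("chrI", 50, 200))

    def test_fold_enrichment_basic(self):
        values = np.concatenate([np.full(100, 50.0), np.full(100, 10.0)])
        track = make_track({"chrI": values})
        fe = fold_enrichment(track, GenomicRegion("chrI", 0, 100), GenomicRegion("chrI", 100, 200))
        assert fe.ratio == pytest.approx(5.0)

    def test_fold_enrichment_identity(self):
        track = make_track({"chrI": np.full(200, 3.0)})
        fe = fold_enrichment(track, GenomicRegion("chrI", 0, 100), GenomicRegion("chrI", 100, 200))
        assert fe.ratio == pytest.approx(1.0)

    def test_fold_enrichment_scale_invariance(self, rng):
        values = rng.random(300) + 0.1
        a = make_track({"chrI": values})
        b = make_track({"chrI": values * 17.3})
        q, bg = GenomicRegion("chrI", 0, 100), GenomicRegion("chrI", 200, 300)
        assert fold_enrichment(a, q, bg).ratio == pytest.approx(fold_enrichment(b, q, bg).ratio)

    def test_fold_enrichment_zero_background_guard(self):
        track = make_track({"chrI": np.zeros(200)})
        with pytest.raises(ValidationError):
            fold_enrichment(
                track, GenomicRegion("chrI", 0, 100), GenomicRegion("chrI", 100, 200),
                pseudocount=0.0,
            )

    def test_fold_enrichment_poisson_simulation(self, rng):
        """Planted 4x enrichment recovered within 3 SE at depth 100."""
        depth = 100.0
        lam = np.concatenate([np.full(500, 4 * depth), np.full(500, depth)])
        track = make_track({"chrI": rng.poisson(lam).astype(float)})
        fe = fold_enrichment(track, GenomicRegion("chrI", 0, 500), GenomicRegion("chrI", 500, 1000))
        # delta-method SE of the ratio of two Poisson-window means
        se = 4.0 * np.sqrt(1 / (500 * 4 * depth) + 1 / (500 * depth))
        assert abs(fe.ratio - 4.0) < 3 * se
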