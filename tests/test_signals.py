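import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallbench import signals
from fallbench.errors import ConfigError, DataError, FormatError
from fallbench.signals import (
    STANDARD_GRAVITY,
    DatasetDialect,
    ImuRecording,
    Window,
    load_recording,
    magnitude,
    median_filter3,
    min_sampling_rate_hz,
    preprocess,
    resample,
    sliding_windows,
    write_recording,
)


def make_rec(n=100, fs=50.0, A=None, G=None, **kw):
    t = np.arange(n) / fs
    if A is None:
        A = np.tile([0.0, 0.0, 1.0], (n, 1))
    if G is None:
        G = np.zeros((n, 3))
    return ImuRecording(t=t, A=A, G=G, fs=fs, **kw)


class TestImuRecording:
    def test_valid(self):
        rec = make_rec(10)
        assert len(rec) == 10
        assert rec.duration_s == pytest.approx(0.2)

    def test_nonuniform_times_rejected(self):
        t = np.arange(10) / 50.0
        t[5] += 1e-6
        with pytest.raises(DataError):
            ImuRecording(t=t, A=np.zeros((10, 3)), G=np.zeros((10, 3)), fs=50.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            ImuRecording(t=np.arange(5) / 50, A=np.zeros((4, 3)), G=np.zeros((5, 3)), fs=50.0)

    def test_nonfinite_rejected(self):
        A = np.zeros((5, 3))
        A[2, 1] = np.nan
        with pytest.raises(DataError):
            ImuRecording(t=np.arange(5) / 50, A=A, G=np.zeros((5, 3)), fs=50.0)


class TestLoadRecording:
    def _write_csv(self, path, n=7, header="time_s,ax_g,ay_g,az_g,gx_rads,gy_rads,gz_rads", scale=1.0, shuffle=False):
        rows = [header]
        ts = list(range(n))
        if shuffle:
            ts[2], ts[3] = ts[3], ts[2]
        for i, ti in enumerate(ts):
            rows.append(f"{ti / 50.0},{0.1 * i * scale},{0.0},{scale},0,0,0")
        path.write_text("\n".join(rows) + "\n")

    def test_generic_identity(self, tmp_path):
        p = tmp_path / "adl_walk.csv"
        self._write_csv(p)
        rec = load_recording(p, "generic")
        assert len(rec) == 7
        assert rec.A[3, 0] == pytest.approx(0.3)
        assert not rec.is_fall

    def test_ms2_unit_conversion(self, tmp_path):
        p = tmp_path / "fall_1.csv"
        self._write_csv(p, header="t,ax,ay,az,gx,gy,gz", scale=STANDARD_GRAVITY)
        dialect = DatasetDialect(
            name="custom",
            columns={"time": "t", "ax": "ax", "ay": "ay", "az": "az",
                     "gx": "gx", "gy": "gy", "gz": "gz"},
            acc_unit="ms2",
        )
        rec = load_recording(p, dialect)
        assert rec.A[0, 2] == pytest.approx(1.0)
        assert rec.is_fall  # file-name convention

    def test_shuffled_timestamps_data_error(self, tmp_path):
        p = tmp_path / "x.csv"
        self._write_csv(p, shuffle=True)
        with pytest.raises(DataError):
            load_recording(p, "generic")

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("time_s,ax_g,ay_g\n0,0,0\n")
        with pytest.raises(FormatError, match="az_g"):
            load_recording(p, "generic")

    def test_round_trip(self, tmp_path, fall):
        rec, _ = fall
        out = tmp_path / "fall_rt.csv"
        write_recording(rec, out)
        back = load_recording(out, "generic")
        np.testing.assert_allclose(back.A, rec.A, atol=1e-9)
        np.testing.assert_allclose(back.G, rec.G, atol=1e-9)
        np.testing.assert_allclose(back.t, rec.t, atol=1e-9)
        assert back.is_fall == rec.is_fall
        assert back.fs == rec.fs
        meta = json.loads((tmp_path / "fall_rt.csv.json").read_text())
        assert meta["fs"] == rec.fs


class TestResample:
    def test_2to1_decimation_length(self):
        rec = make_rec(1000, fs=100.0)
        out = resample(rec, 50.0)
        assert out.fs == 50.0
        assert len(out) == 500

    def test_4to1_umafall_style(self):
        rec = make_rec(1001, fs=200.0)
        out = resample(rec, 50.0)
        assert len(out) == int(np.ceil(1001 / 4))

    def test_constant_preserved(self):
        rec = make_rec(400, fs=100.0)
        out = resample(rec, 50.0)
        np.testing.assert_allclose(out.A[:, 2], 1.0, atol=1e-7)

    def test_upsample_requires_flag(self):
        rec = make_rec(100, fs=50.0)
        with pytest.raises(ConfigError):
            resample(rec, 100.0)
        out = resample(rec, 100.0, upsample=True)
        assert out.fs == 100.0

    def test_noninteger_ratio_linear(self):
        rec = make_rec(300, fs=60.0)
        out = resample(rec, 50.0)
        assert out.fs == 50.0
        assert abs(out.duration_s - rec.duration_s) <= 1.0 / 50.0

    def test_subsample_commutes_with_magnitude(self, rng):
        n = 200
        A = rng.normal(size=(n, 3))
        rec = make_rec(n, fs=100.0, A=A)
        sub = resample(rec, 50.0, method="subsample")
        np.testing.assert_allclose(magnitude(sub.A), magnitude(A)[::2], atol=0)


class TestMedianFilter3:
    def test_constant_fixed_point(self):
        rec = make_rec(20)
        out = median_filter3(rec)
        np.testing.assert_array_equal(out.A, rec.A)

    def test_spike_removed(self):
        A = np.zeros((3, 3))
        A[:, 0] = [1.0, 10.0, 1.0]
        rec = make_rec(3, A=A)
        np.testing.assert_array_equal(median_filter3(rec).A[:, 0], [1.0, 1.0, 1.0])

    def test_monotone_fixed_point(self):
        A = np.zeros((3, 3))
        A[:, 0] = [1.0, 2.0, 3.0]
        rec = make_rec(3, A=A)
        np.testing.assert_array_equal(median_filter3(rec).A[:, 0], [1.0, 2.0, 3.0])

    @given(st.lists(st.sampled_from([0.0, 1.0]), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_converges_to_root_signal_on_binary(self, bits):
        # window-3 medians are not one-pass idempotent on alternating
        # binary input, but repeated passes reach a fixed point fast
        A = np.zeros((len(bits), 3))
        A[:, 1] = bits
        rec = make_rec(len(bits), A=A)
        for _ in range(len(bits) // 2 + 1):
            nxt = median_filter3(rec)
            if np.array_equal(nxt.A, rec.A):
                break
            rec = nxt
        np.testing.assert_array_equal(median_filter3(rec).A, rec.A)

    def test_idempotent_on_runs(self):
        # binary signals without 1-sample oscillations are fixed points
        A = np.zeros((8, 3))
        A[:, 1] = [0, 0, 1, 1, 1, 0, 0, 0]
        rec = make_rec(8, A=A)
        once = median_filter3(rec)
        np.testing.assert_array_equal(once.A, median_filter3(once).A)


class TestMagnitude:
    @pytest.mark.parametrize(
        "v,expected",
        [((0, 0, 1), 1.0), ((0.6, 0.8, 0), 1.0), ((1, 1, 1), np.sqrt(3))],
    )
    def test_examples(self, v, expected):
        assert magnitude(np.array([v], dtype=float))[0] == pytest.approx(expected)

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.permutations([0, 1, 2]),
        st.lists(st.sampled_from([-1.0, 1.0]), min_size=3, max_size=3),
    )
    @settings(deadline=None, max_examples=200)
    def test_permutation_sign_invariance(self, v, perm, signs):
        v = np.array([v])
        w = v[:, perm] * np.array(signs)
        assert magnitude(v)[0] == magnitude(w)[0]


class TestSlidingWindows:
    def test_exact_fit(self):
        wins = sliding_windows(100, 1.0, 1.0, 50.0)
        assert wins[0] == Window(0, 50)
        assert wins == [Window(0, 50), Window(50, 100)]

    def test_half_second_stride(self):
        wins = sliding_windows(200, 2.0, 0.5, 50.0)
        assert [w.start for w in wins] == [0, 25, 50, 75, 100]
        assert len(wins) == 5

    def test_too_short_is_empty(self):
        assert sliding_windows(10, 2.0, 0.5, 50.0) == []


class TestPreprocess:
    def test_downsample_then_median(self):
        rec = make_rec(1000, fs=100.0)
        out = preprocess(rec)
        assert out.fs == 50.0
        assert len(out) == 500

    def test_low_rate_kept_native(self, caplog):
        rec = make_rec(100, fs=20.0)
        with caplog.at_level("WARNING"):
            out = preprocess(rec)
        assert out.fs == 20.0

    def test_nyquist_lower_bound(self):
        assert min_sampling_rate_hz(20.0) == 40.0
        with pytest.raises(ConfigError):
            min_sampling_rate_hz(0.0)
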