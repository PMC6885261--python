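"""Wavelet-packet decomposition, subband statistics and the feature table."""

import numpy as np
import pytest
import pywt

import emgkit as ek
from emgkit.errors import (
    ConfigurationError,
    DecompositionError,
    ReconstructionError,
    TableError,
)
from emgkit.io import Frame
from emgkit.wpd import frequency_order


def brute_force_wpd(x: np.ndarray, wavelet_name: str, level: int) -> list[np.ndarray]:
    """Independent oracle: explicit circular convolution with the analysis
    filter pair + dyadic downsampling (periodized transform), returning the
    terminal subbands in natural filter-bank order."""
    w = pywt.Wavelet(wavelet_name)
    lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)
    L = len(lo)

    def one_step(sig, filt):
        n = len(sig)
        return np.array(
            [
                sum(filt[m] * sig[(2 * k - m + L // 2) % n] for m in range(L))
                for k in range(n // 2)
            ]
        )

    nodes = [x]
    for _ in range(level):
        nodes = [branch for s in nodes for branch in (one_step(s, lo), one_step(s, hi))]
    return nodes


class TestDecompose:
    def test_terminal_shape_2048(self):
        subs = ek.wpd_decompose(np.random.default_rng(0).normal(size=2048))
        assert len(subs) == 16
        assert all(s.M == 128 for s in subs)
        assert [s.index for s in subs] == list(range(16))

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            f = rng.normal(size=2048)
            subs = ek.wpd_decompose(f)
            energy = sum(np.sum(s.coefficients**2) for s in subs)
            assert energy == pytest.approx(np.sum(f**2), rel=1e-10)

    def test_constant_frame_concentrates_in_lowest_band(self):
        subs = ek.wpd_decompose(np.ones(2048))
        assert all(np.max(np.abs(s.coefficients)) < 1e-10 for s in subs[1:])

    def test_haar_closed_form(self):
        cfg = ek.WpdConfig(wavelet_name="haar", level=1)
        approx, detail = ek.wpd_decompose(np.array([1.0, 1.0, -1.0, -1.0]), cfg)
        np.testing.assert_allclose(approx.coefficients, [np.sqrt(2), -np.sqrt(2)], atol=1e-12)
        np.testing.assert_allclose(detail.coefficients, [0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("wavelet", ["haar", "db2"])
    @pytest.mark.parametrize("length", [8, 16])
    @pytest.mark.parametrize("level", [1, 2])
    def test_matches_convolution_oracle(self, wavelet, length, level):
        rng = np.random.default_rng(42)
        cfg = ek.WpdConfig(wavelet_name=wavelet, level=level, ordering="natural")
        for _ in range(5):
            x = rng.normal(size=length)
            mine = ek.wpd_decompose(x, cfg)
            oracle = brute_force_wpd(x, wavelet, level)
            for got, want in zip(mine, oracle):
                np.testing.assert_allclose(got.coefficients, want, atol=1e-12)

    def test_frequency_order_matches_pywt(self):
        x = np.random.default_rng(3).normal(size=256)
        subs = ek.wpd_decompose(x, ek.WpdConfig(level=3))
        wp = pywt.WaveletPacket(x, "db4", mode="periodization", maxlevel=3)
        for mine, ref in zip(subs, wp.get_level(3, order="freq")):
            np.testing.assert_allclose(mine.coefficients, ref.data, atol=1e-12)

    def test_gray_code_permutation(self):
        assert frequency_order(1) == [0, 1]
        assert frequency_order(2) == [0, 1, 3, 2]

    def test_unknown_wavelet_rejected(self):
        with pytest.raises(ConfigurationError):
            ek.WpdConfig(wavelet_name="nosuchwavelet")

    def test_indivisible_length_rejected_in_periodic_mode(self):
        with pytest.raises(DecompositionError):
            ek.wpd_decompose(np.zeros(2050))

    def test_all_nodes_set_has_30_subbands(self):
        subs = ek.wpd_decompose(
            np.zeros(2048), ek.WpdConfig(subband_set="all_nodes")
        )
        assert len(subs) == 2 + 4 + 8 + 16


class TestReconstruct:
    def test_perfect_reconstruction_100_frames(self):
        rng = np.random.default_rng(5)
        cfg = ek.WpdConfig()
        worst = 0.0
        for _ in range(100):
            f = rng.normal(size=2048)
            rec = ek.wpd_reconstruct(ek.wpd_decompose(f, cfg), cfg)
            worst = max(worst, np.max(np.abs(rec - f)))
        assert worst < 1e-8

    def test_zero_subbands_give_zero_frame(self):
        subs = ek.wpd_decompose(np.zeros(2048))
        assert np.max(np.abs(ek.wpd_reconstruct(subs))) == 0.0

    def test_incomplete_set_rejected(self):
        subs = ek.wpd_decompose(np.random.default_rng(0).normal(size=2048))
        with pytest.raises(ReconstructionError):
            ek.wpd_reconstruct(subs[:-1])


class TestSubbandStats:
    def test_meanabs_and_avgpower(self):
        stats = ek.subband_stats(np.array([1.0, -2.0, 3.0]))
        assert stats["meanabs"] == pytest.approx(2.0)
        assert stats["avgpower"] == pytest.approx(14 / 3)

    def test_symmetric_sequence(self):
        stats = ek.subband_stats(np.array([-1.0, 1.0, -1.0, 1.0]))
        assert stats["std"] == pytest.approx(1.0)
        assert stats["skewness"] == pytest.approx(0.0, abs=1e-15)
        assert stats["kurtosis"] == pytest.approx(1.0)

    def test_degenerate_constant_subband(self, caplog):
        with caplog.at_level("WARNING"):
            stats = ek.subband_stats(np.array([5.0, 5.0, 5.0]))
        assert stats["std"] == 0.0
        assert stats["skewness"] == 0.0
        assert stats["kurtosis"] == 0.0

    def test_population_moments_match_scipy(self):
        from scipy import stats as sstats

        rng = np.random.default_rng(8)
        y = rng.normal(size=301)
        mine = ek.subband_stats(y)
        assert mine["std"] == pytest.approx(np.std(y))  # divisor M, no Bessel
        assert mine["skewness"] == pytest.approx(sstats.skew(y, bias=True))
        assert mine["kurtosis"] == pytest.approx(sstats.kurtosis(y, bias=True, fisher=False))


class TestAdjacentRatios:
    def test_identical_magnitudes_give_unit_ratio(self):
        subs = ek.wpd_decompose(np.random.default_rng(0).normal(size=2048))
        same = [subs[0], subs[0]]
        assert ek.adjacent_ratios(same)[0] == pytest.approx(1.0)

    def test_zero_numerator_and_denominator(self):
        a = ek.SubbandCoefficients(4, 0, np.zeros(4))
        b = ek.SubbandCoefficients(4, 1, np.array([1.0, 2.0, 3.0, 4.0]))
        assert ek.adjacent_ratios([a, b])[0] == 0.0
        assert ek.adjacent_ratios([b, a])[0] == 0.0  # zero denominator policy

    def test_count_is_subbands_minus_one(self):
        subs = ek.wpd_decompose(np.random.default_rng(1).normal(size=2048))
        assert len(ek.adjacent_ratios(subs)) == 15


class TestExtractFeatures:
    def _frames(self, n, length=2048, seed=0):
        rng = np.random.default_rng(seed)
        return [
            Frame(rng.normal(size=length), ek.CLASSES[i % 3], f"r{i}", 0)
            for i in range(n)
        ]

    def test_default_table_is_95_columns(self):
        table = ek.extract_features(self._frames(6))
        assert table.X.shape == (6, 95)
        assert table.feature_names[0] == "L4.S00.meanabs"
        assert table.feature_names[-1].endswith(".ratio")

    def test_row_matches_per_subband_computation(self):
        frames = self._frames(1)
        table = ek.extract_features(frames)
        subs = ek.wpd_decompose(frames[0].samples)
        stats = ek.subband_stats(subs[3])
        col = table.feature_names.index("L4.S03.meanabs")
        assert table.X[0, col] == pytest.approx(stats["meanabs"], rel=1e-12)
        ratios = ek.adjacent_ratios(subs)
        assert table.X[0, 80] == pytest.approx(ratios[0], rel=1e-12)

    def test_avgpower_times_m_sums_to_total_energy(self):
        frames = self._frames(3)
        table = ek.extract_features(frames)
        cols = [i for i, n in enumerate(table.feature_names) if n.endswith("avgpower")]
        for row, frame in zip(table.X[:, cols], frames):
            assert row.sum() * 128 == pytest.approx(np.sum(frame.samples**2), rel=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            x = rng.normal(size=256)
            c = rng.uniform(0.5, 5.0)
            cfg = ek.WpdConfig(level=2)
            base = ek.extract_features([Frame(x, "Normal", "r", 0)], cfg).X[0]
            scaled = ek.extract_features([Frame(c * x, "Normal", "r", 0)], cfg).X[0]
            names = ek.extract_features([Frame(x, "Normal", "r", 0)], cfg).feature_names
            for i, name in enumerate(names):
                if name.endswith(("meanabs", "std")):
                    assert scaled[i] == pytest.approx(c * base[i], rel=1e-9)
                elif name.endswith("avgpower"):
                    assert scaled[i] == pytest.approx(c**2 * base[i], rel=1e-9)
                else:  # skewness, kurtosis, ratios are scale-free
                    assert scaled[i] == pytest.approx(base[i], rel=1e-8, abs=1e-10)

    def test_zero_frame_gives_zero_row(self):
        table = ek.extract_features([Frame(np.zeros(2048), "Normal", "r", 0)])
        assert np.all(table.X == 0.0)

    def test_mixed_lengths_rejected(self):
        frames = self._frames(1) + self._frames(1, length=1024)
        with pytest.raises(TableError):
            ek.extract_features(frames)

    def test_all_nodes_gives_179_features(self):
        cfg = ek.WpdConfig(subband_set="all_nodes")
        table = ek.extract_features(self._frames(2), cfg)
        assert table.X.shape == (2, 5 * 30 + 29)

    def test_restricted_statistic_set(self):
        cfg = ek.WpdConfig(statistics=("meanabs", "avgpower"), include_ratios=False)
        table = ek.extract_features(self._frames(2), cfg)
        assert table.X.shape == (2, 32)


class TestFeatureTableIo:
    def _table(self):
        return ek.extract_features(
            [
                Frame(np.random.default_rng(i).normal(size=256), ek.CLASSES[i % 3], f"r{i}", 0)
                for i in range(6)
            ],
            ek.WpdConfig(level=2),
        )

    def test_csv_round_trip(self, tmp_path):
        table = self._table()
        path = ek.write_feature_table(table, tmp_path / "t.csv")
        back = ek.read_feature_table(path)
        np.testing.assert_array_equal(table.X, back.X)
        assert list(table.labels) == list(back.labels)
        assert table.feature_names == back.feature_names

    def test_arff_round_trip_and_header(self, tmp_path):
        table = self._table()
        path = ek.write_feature_table(table, tmp_path / "t.arff")
        text = path.read_text()
        assert text.startswith("@relation")
        assert "@attribute label {Normal,Myopathy,Neuropathy}" in text
        assert text.count("\n@data\n") == 1
        back = ek.read_feature_table(path)
        np.testing.assert_array_equal(table.X, back.X)
        assert back.class_labels == ek.CLASSES

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError):
            ek.write_feature_table(self._table(), tmp_path / "t.xyz")

    def test_missing_label_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(TableError):
            ek.read_feature_table(p)
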