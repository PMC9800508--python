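"""Moment descriptors: hand examples, a straight-line duplicate oracle, the
Parseval / circular-difference spectral identities, and scaling properties."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mdls import features as ft
from mdls.preprocess import segment_windows
from mdls.simulate import MultiChannelSignal

LAM = 0.1
EPS = 1e-12


# ---------------------------------------------------------------------------
# independent straight-line re-implementation (oracle)


def oracle_descriptors(x, lam=LAM, eps=EPS):
    x = np.asarray(x, dtype=float)
    N = len(x)
    m0 = np.sum(x**2)
    m2 = np.sum(np.diff(x) ** 2) / N
    m4 = np.sum(np.diff(x, 2) ** 2) / N
    m0n = m0**lam / lam if m0 > 0 else 0.0
    m2n = m2**lam / lam if m2 > 0 else 0.0
    m4n = m4**lam / lam if m4 > 0 else 0.0
    f1 = np.log(m0n + eps)
    f2 = np.log(abs(m0n - m2n) + eps)
    f3 = np.log(abs(m0n - m4n) + eps)
    f4 = np.log((m0n + eps) / ((abs(m0n - m2n) + eps) * (abs(m0n - m4n) + eps)))
    f5 = np.log(
        (np.sum(np.abs(np.diff(x, 2))) + eps) / (np.sum(np.abs(np.diff(x, 4))) + eps)
    )
    return np.array([f1, f2, f3, f4, f5])


class TestSpectralMoments:
    def test_constant_window(self):
        m = ft.spectral_moments(np.full(250, 3.0))
        assert m.m0 == pytest.approx(250 * 9.0)
        assert m.m2 == 0.0 and m.m4 == 0.0

    def test_alternating_hand_example(self):
        m = ft.spectral_moments(np.array([0.0, 1.0, 0.0, 1.0]))
        assert m.m0 == pytest.approx(2.0)
        assert m.m2 == pytest.approx(3.0 / 4.0)
        assert m.m4 == pytest.approx(2.0)

    def test_parseval_identity(self, rng):
        """Total time-domain power equals (1/N) * summed squared DFT magnitudes."""
        for _ in range(100):
            x = rng.normal(size=rng.integers(16, 512))
            m0 = ft.spectral_moments(x).m0
            spectral = np.sum(np.abs(np.fft.fft(x)) ** 2) / len(x)
            assert m0 == pytest.approx(spectral, rel=1e-9)

    def test_circular_m2_matches_dft_identity(self, rng):
        """With circular differences, the second moment equals
        sum_k |2 sin(pi k/N)|^2 P[k] / N with P[k] = |X[k]|^2 / N."""
        for _ in range(20):
            N = int(rng.integers(16, 256))
            x = rng.normal(size=N)
            dx = np.roll(x, -1) - x
            m2_circ = np.sum(dx**2) / N
            k = np.arange(N)
            P = np.abs(np.fft.fft(x)) ** 2 / N
            spectral = np.sum((2 * np.sin(np.pi * k / N)) ** 2 * P) / N
            assert m2_circ == pytest.approx(spectral, rel=1e-9)

    def test_m2_increases_with_high_frequency_content(self, rng):
        from mdls.preprocess import denoise

        for _ in range(10):
            x = rng.normal(size=2000)
            sig = MultiChannelSignal(x[:, None], 1000.0, (90.0,))
            low = denoise(sig, 50.0).samples[:, 0]
            assert ft.spectral_moments(x).m2 > ft.spectral_moments(low).m2

    def test_short_window_error(self):
        with pytest.raises(ValueError):
            ft.spectral_moments(np.array([1.0, 2.0]))


class TestNormalization:
    @pytest.mark.parametrize("raw,expected", [(1.0, 10.0), (0.0, 0.0), (1024.0, 20.0)])
    def test_power_law_values(self, raw, expected):
        m = ft.normalize_moments(ft.SpectralMoments(m0=raw, m2=raw, m4=raw), lam=0.1)
        assert m.m0n == pytest.approx(expected)

    def test_negative_moment_rejected(self):
        with pytest.raises(ValueError):
            ft.normalize_moments(ft.SpectralMoments(m0=-1.0, m2=0.0, m4=0.0))

    def test_lambda_must_be_positive(self):
        with pytest.raises(ValueError):
            ft.normalize_moments(ft.SpectralMoments(1.0, 1.0, 1.0), lam=0.0)


class TestDescriptors:
    def test_matches_straight_line_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=250)
            np.testing.assert_allclose(
                ft.window_descriptors(x), oracle_descriptors(x), rtol=1e-12, atol=1e-12
            )

    def test_constant_window_degeneracies(self):
        f = ft.window_descriptors(np.full(250, 2.0))
        assert f[1] == pytest.approx(f[0])  # f2 == f1
        assert f[2] == pytest.approx(f[0])  # f3 == f1
        assert f[3] == pytest.approx(-f[0])  # f4 == -f1
        assert f[4] == pytest.approx(0.0)  # f5 == 0

    def test_linear_ramp_f5_zero(self):
        f = ft.window_descriptors(np.arange(250.0))
        assert f[4] == pytest.approx(0.0)

    @given(log_a=st.floats(-2.0, 2.0))
    def test_scaling_shifts_f1_by_two_lambda_log_a(self, log_a):
        """x -> a*x multiplies m0 by a^2, so the normalized moment scales by
        a^(2 lam) and f1 shifts by 2*lam*log(a)."""
        a = np.exp(log_a)
        rng = np.random.default_rng(3)
        x = rng.normal(size=250)
        f = ft.window_descriptors(x)
        fa = ft.window_descriptors(a * x)
        assert fa[0] - f[0] == pytest.approx(2 * LAM * np.log(a), abs=1e-6)

    def test_constant_offset_changes_f1_not_f5(self, rng):
        x = rng.normal(size=250)
        f = ft.window_descriptors(x)
        fc = ft.window_descriptors(x + 5.0)
        assert fc[0] != pytest.approx(f[0])
        assert fc[4] == pytest.approx(f[4], abs=1e-9)

    def test_sparsity_sqrt_variant(self, rng):
        x = rng.normal(size=250)
        f_prod = ft.window_descriptors(x)
        f_sqrt = ft.window_descriptors(x, sparsity_sqrt=True)
        # only f4 differs, and log identities hold: f4_prod = f1 - f2 - f3
        np.testing.assert_allclose(f_prod[[0, 1, 2, 4]], f_sqrt[[0, 1, 2, 4]])
        assert f_prod[3] == pytest.approx(f_prod[0] - f_prod[1] - f_prod[2], abs=1e-9)
        assert f_sqrt[3] == pytest.approx(f_prod[0] - 0.5 * (f_prod[1] + f_prod[2]), abs=1e-9)

    def test_all_finite_on_zero_window(self):
        assert np.all(np.isfinite(ft.window_descriptors(np.zeros(250))))


class TestFeatureMatrix:
    def make_windows(self, n_channels, rng, label=None):
        x = rng.normal(size=(1000, n_channels))
        angles = tuple(float(10 * (i + 1)) for i in range(n_channels))
        sig = MultiChannelSignal(x, 1000.0, angles, label=label)
        return segment_windows(sig)

    def test_sixty_columns_for_twelve_channels(self, rng):
        fm = ft.build_feature_matrix(self.make_windows(12, rng))
        assert fm.n_features == 60
        assert fm.names[:6] == [
            "ch01_f1", "ch01_f2", "ch01_f3", "ch01_f4", "ch01_f5", "ch02_f1",
        ]

    def test_single_channel_gives_five(self, rng):
        assert ft.build_feature_matrix(self.make_windows(1, rng)).n_features == 5

    def test_channel_permutation_permutes_blocks(self, rng):
        x = rng.normal(size=(1000, 3))
        angles = (10.0, 20.0, 30.0)
        fm = ft.build_feature_matrix(
            segment_windows(MultiChannelSignal(x, 1000.0, angles))
        )
        perm = [2, 0, 1]
        fm_p = ft.build_feature_matrix(
            segment_windows(
                MultiChannelSignal(x[:, perm], 1000.0, tuple(angles[i] for i in perm))
            )
        )
        for new_c, old_c in enumerate(perm):
            np.testing.assert_allclose(
                fm_p.X[:, 5 * new_c : 5 * new_c + 5], fm.X[:, 5 * old_c : 5 * old_c + 5]
            )

    def test_labels_propagate(self, rng):
        fm = ft.build_feature_matrix(self.make_windows(2, rng, label=1))
        assert np.all(fm.y == 1)
        assert len(fm.y) == fm.n_windows

    def test_csv_round_trip(self, rng, tmp_path):
        fm = ft.build_feature_matrix(self.make_windows(2, rng, label=2))
        fm.to_csv(tmp_path / "f.csv")
        back = ft.FeatureMatrix.from_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back.X, fm.X)
        assert back.names == fm.names
        np.testing.assert_array_equal(back.y, fm.y)
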