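"""Metric-level tests: exact phase configurations, invariances, oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import signal as sg

from phasesleep.bands import ALPHA, BAND_NAMES
from phasesleep.connectivity import (
    METRICS,
    ConnectivityMatrix,
    CrossSpectrumSeries,
    ciplv,
    coh,
    connectivity_matrix,
    devectorize,
    feature_names,
    icoh,
    pli,
    plv,
    power_features,
    vectorize,
    wpli,
    _epoch_metric_matrices,
)
from phasesleep.preprocess import AnalyticEpoch

ALL_FUNCS = {"COH": coh, "iCOH": icoh, "PLV": plv, "ciPLV": ciplv,
             "PLI": pli, "wPLI": wpli}


def css_constant_lag(dphi, n=1000, a_i=1.0, a_j=1.0):
    return CrossSpectrumSeries.from_phase(np.full(n, dphi), a_i=a_i, a_j=a_j)


class TestExactPhaseConfigurations:
    """Closed-form values on constructed phase-difference series."""

    def test_identical_signals(self, rng):
        z = sg.hilbert(rng.standard_normal(1000))
        css = CrossSpectrumSeries.from_analytic(z, z)
        assert coh(css) == pytest.approx(1.0)
        assert plv(css) == pytest.approx(1.0)
        assert icoh(css) == pytest.approx(0.0, abs=1e-12)
        assert ciplv(css) == 0.0          # zero-lag coupling suppressed
        assert pli(css) == 0.0            # sign(0) = 0 convention
        assert wpli(css) == 0.0           # purely real cross-spectrum

    def test_quarter_cycle_lag(self):
        css = css_constant_lag(np.pi / 2)
        assert coh(css) == pytest.approx(1.0)
        assert icoh(css) == pytest.approx(1.0)   # +pi/2 lead -> +1
        assert plv(css) == pytest.approx(1.0)
        assert ciplv(css) == pytest.approx(1.0)
        assert pli(css) == pytest.approx(1.0)
        assert wpli(css) == pytest.approx(1.0)

    def test_antiphase(self):
        css = css_constant_lag(np.pi)
        assert icoh(css) == pytest.approx(0.0, abs=1e-12)
        assert coh(css) == pytest.approx(1.0)
        assert plv(css) == pytest.approx(1.0)

    def test_constant_lag_any_value_gives_plv_one(self):
        for dphi in (-2.0, 0.3, 1.2, 3.0):
            assert plv(css_constant_lag(dphi)) == pytest.approx(1.0)

    def test_uniform_four_phase_cancellation(self):
        dphi = np.repeat([0.0, np.pi / 2, np.pi, 3 * np.pi / 2], 250)
        css = CrossSpectrumSeries.from_phase(dphi)
        assert plv(css) == pytest.approx(0.0, abs=1e-12)

    def test_pli_sign_counting(self):
        dphi = np.concatenate([np.full(700, np.pi / 4), np.full(300, -np.pi / 4)])
        assert pli(CrossSpectrumSeries.from_phase(dphi)) == pytest.approx(0.4)

    def test_wpli_weighted_cancellation(self):
        # Im values {+2, -1, -1}: |mean| = 0 -> wPLI = 0 despite PLI != 0
        s_ij = np.array([1 + 2j, 1 - 1j, 1 - 1j], dtype=complex)
        css = CrossSpectrumSeries(s_ij=s_ij, s_ii=np.abs(s_ij),
                                  s_jj=np.abs(s_ij))
        assert wpli(css) == pytest.approx(0.0, abs=1e-12)


class TestStatisticalOracles:
    def test_plv_rayleigh_null(self, rng):
        """i.i.d. uniform phases: E[PLV] ~ sqrt(pi)/2 / sqrt(N)."""
        n = 400
        values = [
            plv(CrossSpectrumSeries.from_phase(rng.uniform(-np.pi, np.pi, n)))
            for _ in range(1000)
        ]
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
        assert np.mean(values) == pytest.approx(expected, rel=0.05)

    def test_ciplv_matches_brute_force_on_noisy_quarter_cycle(self, rng):
        dphi = np.pi / 2 + rng.normal(0, 0.1, 2000)
        css = CrossSpectrumSeries.from_phase(dphi)
        # independent brute-force evaluation of the definition
        e = np.exp(1j * dphi)
        expected = abs(np.mean(np.imag(e))) / np.sqrt(1 - np.mean(np.real(e)) ** 2)
        assert ciplv(css) == pytest.approx(expected, rel=1e-12)

    def test_wpli_less_variable_than_pli_near_zero_lag(self, rng):
        """Noise pushing samples across dphi = 0 hits PLI harder than wPLI.

        A true small lag perturbed by phase noise: samples crossing the
        zero border carry small |Im| and are down-weighted by wPLI, so its
        relative variance across epochs is lower than PLI's.
        """
        plis, wplis = [], []
        for _ in range(500):
            dphi = rng.normal(0.3, 0.5, 500)
            css = CrossSpectrumSeries.from_phase(dphi)
            plis.append(pli(css))
            wplis.append(wpli(css))
        plis, wplis = np.asarray(plis), np.asarray(wplis)
        rel_var_pli = plis.var() / plis.mean() ** 2
        rel_var_wpli = wplis.var() / wplis.mean() ** 2
        assert rel_var_wpli < rel_var_pli

    def test_coh_agrees_with_welch_band_average(self):
        from phasesleep.experiments import welch_coherence_deviation

        assert welch_coherence_deviation(seed=7) < 0.05


class TestPropertyBased:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        dphi=hnp.arrays(np.float64, st.integers(8, 200),
                        elements=st.floats(-np.pi, np.pi)),
        a=st.floats(0.1, 10.0),
    )
    def test_bounds_hold_for_arbitrary_phase_series(self, dphi, a):
        """Metric ranges hold for any phase-difference series and scale."""
        css = CrossSpectrumSeries.from_phase(dphi, a_i=a, a_j=1.0)
        assert 0.0 <= coh(css) <= 1.0 + 1e-12
        assert -1.0 - 1e-12 <= icoh(css) <= 1.0 + 1e-12
        for f in (plv, ciplv, pli, wpli):
            v = f(css)
            assert 0.0 <= v <= 1.0 + 1e-9, f.__name__
        assert abs(icoh(css)) <= coh(css) + 1e-12


class TestInvariances:
    def _random_css(self, rng, n=800):
        z1 = sg.hilbert(rng.standard_normal(n))
        z2 = sg.hilbert(rng.standard_normal(n))
        return z1, z2

    def test_bounds_and_icoh_dominated_by_coh(self, rng):
        for _ in range(25):
            z1, z2 = self._random_css(rng)
            css = CrossSpectrumSeries.from_analytic(z1, z2)
            for name in ("COH", "PLV", "ciPLV", "PLI", "wPLI"):
                v = ALL_FUNCS[name](css)
                assert 0.0 <= v <= 1.0, name
            assert abs(icoh(css)) <= coh(css) + 1e-12

    def test_amplitude_scale_invariance(self, rng):
        """All six metrics are invariant to positive rescaling of a channel."""
        z1, z2 = self._random_css(rng)
        base = CrossSpectrumSeries.from_analytic(z1, z2)
        scaled = CrossSpectrumSeries.from_analytic(3.7 * z1, z2)
        for name, func in ALL_FUNCS.items():
            assert func(scaled) == pytest.approx(func(base), rel=1e-9), name

    def test_plv_equals_coh_for_constant_amplitudes(self, rng):
        dphi = rng.uniform(-np.pi, np.pi, 1000)
        css = CrossSpectrumSeries.from_phase(dphi, a_i=2.0, a_j=0.5)
        assert plv(css) == pytest.approx(coh(css), rel=1e-12)

    def test_volume_conduction_discrimination(self):
        """Zero-lag mixtures: COH/PLV high; lag-sensitive metrics at null."""
        rng = np.random.default_rng(42)  # dedicated seed: null comparison
        n = 25000  # 100 s: long enough that the null envelope is tight
        fs = 250.0
        sos = sg.butter(4, [8, 12], btype="bandpass", fs=fs, output="sos")
        src = sg.sosfiltfilt(sos, rng.standard_normal(n))
        noise1 = sg.sosfiltfilt(sos, rng.standard_normal(n))
        noise2 = sg.sosfiltfilt(sos, rng.standard_normal(n))
        x1, x2 = src + 0.1 * noise1, 0.6 * src + 0.1 * noise2
        css = CrossSpectrumSeries.from_analytic(sg.hilbert(x1), sg.hilbert(x2))

        # Monte-Carlo null for lag-sensitive metrics on independent noise
        null = {"iCOH": [], "ciPLV": [], "PLI": [], "wPLI": []}
        for _ in range(200):
            a = sg.sosfiltfilt(sos, rng.standard_normal(n))
            b = sg.sosfiltfilt(sos, rng.standard_normal(n))
            c = CrossSpectrumSeries.from_analytic(sg.hilbert(a), sg.hilbert(b))
            for k in null:
                null[k].append(abs(ALL_FUNCS[k](c)))
        assert coh(css) > 0.9
        assert plv(css) > 0.9
        for k, vals in null.items():
            assert abs(ALL_FUNCS[k](css)) <= np.quantile(vals, 0.95), k


class TestMatrixAndVector:
    def _epoch(self, rng, n_ch, n_t=500, **meta):
        x = rng.standard_normal((n_ch, n_t))
        z = sg.hilbert(x, axis=1)
        return AnalyticEpoch(amplitude=np.abs(z), phase=np.angle(z),
                             band=ALPHA, fs=100.0, **meta)

    def test_pair_counts(self, rng):
        for n_ch, n_pairs in [(30, 435), (3, 3)]:
            mat = connectivity_matrix(self._epoch(rng, n_ch), "PLV")
            assert mat.n_pairs == n_pairs
            assert mat.pair_values().shape == (n_pairs,)

    def test_matrix_symmetric_with_nan_diagonal(self, rng):
        for metric in METRICS:
            mat = connectivity_matrix(self._epoch(rng, 5), metric).values
            assert np.all(np.isnan(np.diag(mat)))
            off = ~np.eye(5, dtype=bool)
            assert np.allclose(mat[off], mat.T[off])

    def test_vectorized_path_matches_scalar_functions(self, rng):
        z = sg.hilbert(rng.standard_normal((6, 800)), axis=1)
        mats = _epoch_metric_matrices(z, METRICS)
        for i in range(6):
            for j in range(i + 1, 6):
                css = CrossSpectrumSeries.from_analytic(z[i], z[j])
                for name, func in ALL_FUNCS.items():
                    expected = func(css)
                    if name == "iCOH":
                        assert mats[name][i, j] == pytest.approx(expected, abs=1e-10)
                    else:
                        assert mats[name][i, j] == pytest.approx(abs(expected), abs=1e-10)

    def test_channel_permutation_equivariance(self, rng):
        ep = self._epoch(rng, 5)
        perm = np.array([3, 1, 4, 0, 2])
        ep_p = AnalyticEpoch(amplitude=ep.amplitude[perm], phase=ep.phase[perm],
                             band=ALPHA, fs=100.0)
        m = connectivity_matrix(ep, "PLV").values
        m_p = connectivity_matrix(ep_p, "PLV").values
        assert np.allclose(m[np.ix_(perm, perm)], m_p, equal_nan=True)

    def _band_matrices(self, rng, n_ch):
        out = {}
        for band in BAND_NAMES:
            v = rng.uniform(0, 1, (n_ch, n_ch))
            v = (v + v.T) / 2
            np.fill_diagonal(v, np.nan)
            out[band] = ConnectivityMatrix(values=v, metric="PLV", band=band)
        return out

    def test_feature_vector_lengths(self, rng):
        assert vectorize(self._band_matrices(rng, 30)).coefficients.shape == (1740,)
        assert vectorize(self._band_matrices(rng, 3)).coefficients.shape == (12,)

    def test_vectorize_missing_band_rejected(self, rng):
        mats = self._band_matrices(rng, 4)
        del mats["beta"]
        with pytest.raises(ValueError, match="beta"):
            vectorize(mats)

    def test_devectorize_round_trip(self, rng):
        mats = self._band_matrices(rng, 7)
        vec = vectorize(mats)
        back = devectorize(vec, 7)
        for band in BAND_NAMES:
            iu = np.triu_indices(7, k=1)
            assert np.allclose(back[band][iu], mats[band].values[iu])

    def test_feature_names_order(self):
        names = feature_names(3, ("a", "b", "c"))
        assert names[:3] == ("delta_a-b", "delta_a-c", "delta_b-c")
        assert len(names) == 12

    def test_power_features(self, rng):
        epochs = {}
        for band in BAND_NAMES:
            amp = np.ones((30, 400))
            epochs[band] = AnalyticEpoch(amplitude=amp, phase=np.zeros_like(amp),
                                         band=ALPHA, fs=100.0)
        feats = power_features(epochs)
        assert feats.shape == (120,)
        # unit analytic amplitude -> A^2 feature exactly 1
        assert np.allclose(feats, 1.0)
        zero = {b: AnalyticEpoch(amplitude=np.zeros((2, 10)),
                                 phase=np.zeros((2, 10)), band=ALPHA, fs=100.0)
                for b in BAND_NAMES}
        assert np.allclose(power_features(zero), 0.0)
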