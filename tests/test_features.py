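import numpy as np
import pytest

from conftest import gaussian_pulse, make_waveform
from mngsort.features import (
    FEATURE_SETS,
    extract_all_feature_sets,
    extract_features,
    feat_raw,
    feat_simple,
    fit_pca,
)
from mngsort.preprocessing import ParameterError
from mngsort.spdf import (
    SPDF_FEATURE_NAMES,
    fundamental_points,
    fv3_vector,
    spdf_vector,
)


def triangle(peak_idx=30, base_half=5, amp=1.0, n=60):
    w = np.zeros(n)
    for i in range(n):
        d = abs(i - peak_idx)
        if d <= base_half:
            w[i] = amp * (1 - d / base_half)
    return w


class TestSimpleFeatures:
    def test_triangle_amplitude_and_width(self):
        # symmetric triangle, base width 10 -> half-max crossings 2.5 samples
        # either side of the peak
        w = make_waveform(triangle())
        a, width = feat_simple(w)
        assert a == pytest.approx(1.0)
        assert width == pytest.approx(5.0)

    @pytest.mark.parametrize("sigma", [2.0, 3.0, 5.0, 8.0])
    def test_gaussian_fwhm_closed_form(self, sigma):
        w = make_waveform(gaussian_pulse(sigma))
        a, width = feat_simple(w)
        assert a == pytest.approx(1.0)
        assert width == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma, abs=0.05)

    def test_all_negative_waveform_excluded(self):
        assert feat_simple(make_waveform(-gaussian_pulse(3.0))) is None

    def test_missing_half_crossing_excluded(self):
        # monotone ramp: no crossing to the right of the peak (at the edge)
        assert feat_simple(make_waveform(np.linspace(0, 1, 60))) is None


class TestFundamentalPoints:
    def test_strictly_negative_fd_undefined(self):
        w = make_waveform(np.zeros(60), fd=-np.ones(60), sd=np.zeros(60))
        assert not fundamental_points(w).defined

    def test_monotone_ramp_undefined(self):
        w = make_waveform(np.linspace(0, 1, 60))  # fd constant > 0
        assert not fundamental_points(w).defined

    def test_sin_fd_first_sign_change(self):
        fd = np.sin(2 * np.pi * np.arange(60) / 40 + 0.3)
        w = make_waveform(np.zeros(60), fd=fd, sd=np.zeros(60))
        fp = fundamental_points(w)
        # dense-scan oracle for the first sign change
        s = np.sign(fd)
        oracle = next(i + 1 for i in range(59) if s[i] != s[i + 1])
        assert fp.defined and fp.p1 == oracle

    def test_clean_spike_points_ordered(self):
        from mngsort.synthetic import MorphTemplate

        w = make_waveform(MorphTemplate(lam=0.3).aligned60())
        fp = fundamental_points(w)
        assert fp.defined
        # leading negative lobe: first fd zero-crossing sits at its trough,
        # before the rising flank; then steepest fall, then the trough after
        # the main peak
        assert fp.p1 <= fp.p2 < fp.p3 < fp.p4
        assert np.sign(w.fd[fp.p1 - 1]) != np.sign(w.fd[fp.p1])


class TestSpdfVector:
    def test_f8_mean_square_before_p1(self):
        # fd constant c over [0, P1) with P1 = 4 -> f8 = c^2
        c = 0.7
        fd = np.concatenate([np.full(4, c), np.full(56, -c)])
        w = make_waveform(np.zeros(60), fd=fd, sd=np.zeros(60))
        vec = spdf_vector(w)
        f8 = vec[SPDF_FEATURE_NAMES.index("f8")]
        assert f8 == pytest.approx(c**2)

    def test_fv3_extrema(self):
        fd = np.zeros(60)
        fd[10], fd[40] = 2.0, -1.0
        fd[20] = -0.5  # sign change so P1 is defined
        sd = np.zeros(60)
        sd[15], sd[45] = 1.5, -3.0
        w = make_waveform(np.zeros(60), fd=fd, sd=sd)
        np.testing.assert_allclose(fv3_vector(w), [2.0, 1.5, -3.0])
        vec = spdf_vector(w)
        for name, val in zip(("f14", "f18", "f19"), (2.0, 1.5, -3.0)):
            assert vec[SPDF_FEATURE_NAMES.index(name)] == val

    def test_fv3_scales_linearly(self, two_fiber_waveforms):
        w = two_fiber_waveforms[0]
        scaled = make_waveform(2.5 * w.samples, track=w.track)
        np.testing.assert_allclose(fv3_vector(scaled), 2.5 * fv3_vector(w),
                                   rtol=1e-12)

    def test_zero_waveform_excluded(self):
        assert spdf_vector(make_waveform(np.zeros(60))) is None

    def test_vector_has_23_finite_entries(self, two_fiber_waveforms):
        vec = spdf_vector(two_fiber_waveforms[0])
        assert vec.shape == (23,)
        assert np.all(np.isfinite(vec))


class TestFeatureMatrices:
    def test_spdf_sets_share_exclusion_mask(self, two_fiber_waveforms):
        ramp = make_waveform(np.linspace(0, 1, 60), track="Track1")
        ws = list(two_fiber_waveforms[:20]) + [ramp]
        m_raw = extract_features(ws, "SPDF_raw")
        m_fv3 = extract_features(ws, "SPDF_FV3")
        np.testing.assert_array_equal(m_raw.included, m_fv3.included)
        assert not m_raw.included[-1]

    def test_raw_set_never_excludes(self, two_fiber_waveforms):
        m = extract_features(two_fiber_waveforms, "W_raw")
        assert m.n_excluded == 0
        np.testing.assert_array_equal(m.X[0], two_fiber_waveforms[0].samples)

    @pytest.mark.parametrize("feature_set", FEATURE_SETS)
    def test_conservation(self, two_fiber_waveforms, feature_set):
        ws = list(two_fiber_waveforms)
        m = extract_features(ws, feature_set)
        assert len(m.X) + m.n_excluded == len(ws)
        assert len(m.labels) == len(m.X)

    def test_unknown_set_rejected(self, two_fiber_waveforms):
        with pytest.raises(ParameterError):
            extract_features(two_fiber_waveforms, "wavelets")

    def test_dimensions(self, two_fiber_waveforms):
        dims = {"simple": 2, "SPDF_FV3": 3, "SPDF_raw": 23,
                "W_2-PCA": 2, "W_3-PCA": 3, "W_raw": 60}
        mats = extract_all_feature_sets(two_fiber_waveforms)
        for fs, m in mats.items():
            assert m.X.shape[1] == dims[fs]


class TestPca:
    def test_collinear_data_single_component(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=60)
        X = np.outer(rng.normal(size=50), direction)
        model, scores = fit_pca(X, 2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        assert model.explained_variance_ratio[1] == pytest.approx(0.0, abs=1e-9)

    def test_isotropic_cloud_flat_spectrum(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 5))
        model, _ = fit_pca(X, 5)
        # eigenvalue oracle: all ratios near 1/5 within sampling error
        np.testing.assert_allclose(model.explained_variance_ratio, 0.2, atol=0.02)

    def test_scores_centered_and_ratios_sorted(self, two_fiber_waveforms):
        X = np.array([feat_raw(w) for w in two_fiber_waveforms])
        model, scores = fit_pca(X, 4)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-9)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1.0 + 1e-12

    def test_too_many_components_rejected(self):
        with pytest.raises(ParameterError):
            fit_pca(np.zeros((3, 60)), 3)
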