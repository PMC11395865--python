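import numpy as np
import pytest

from rapidwashout import phantom
from rapidwashout.preprocess import correct_bias, foreground_mask, normalize_means
from rapidwashout.volume import Volume

from conftest import dice


def _clean_small(small_layout):
    """Noise-free, bias-free phantom image on the small grid."""
    return phantom.generate(layout=small_layout, seed=0, bias_amplitude=0.0,
                            snr=1e9).early


def _quadratic_field(vol, lo=0.8, hi=1.2):
    """Smooth quadratic multiplicative field spanning [lo, hi]."""
    axes = [np.linspace(-1, 1, n) for n in vol.shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    q = 0.5 * X**2 + 0.3 * Y**2 - 0.4 * Z**2 + 0.2 * X
    q = (q - q.min()) / np.ptp(q)
    return lo + (hi - lo) * q


class TestBiasCorrection:
    def test_bias_free_input_nearly_unchanged(self):
        # homogeneous head with mild noise; N4 must leave it essentially alone
        from rapidwashout.phantom import PhantomLayout
        layout = PhantomLayout(shape=(48, 48, 40), spacing=(2.5, 2.5, 2.5),
                               head_semiaxes_mm=(42.0, 48.0, 38.0), lesions=[])
        vol = phantom.generate(layout=layout, seed=2, bias_amplitude=0.0,
                               snr=100.0).early
        fg = foreground_mask(vol)
        bc = correct_bias(vol, shrink=3, mask=fg)
        rel = np.abs(bc.corrected.data[fg] - vol.data[fg]) / vol.data[fg].mean()
        assert rel.max() < 0.02

    def test_known_field_cv_reduction(self, small_layout):
        clean = _clean_small(small_layout)
        field = _quadratic_field(clean)
        biased = clean.with_data(clean.data * field)
        fg = foreground_mask(biased)
        bc = correct_bias(biased, shrink=3, mask=fg)
        ratio_uncorr = biased.data[fg] / clean.data[fg]
        ratio_corr = bc.corrected.data[fg] / clean.data[fg]
        cv = lambda x: np.std(x) / np.mean(x)
        assert cv(ratio_corr) < 0.5 * cv(ratio_uncorr)
        assert (bc.field.data[fg] > 0).all()

    def test_shrink_1_and_3_agree(self, small_layout):
        clean = _clean_small(small_layout)
        field = _quadratic_field(clean)
        biased = clean.with_data(clean.data * field)
        fg = foreground_mask(biased)
        c1 = correct_bias(biased, shrink=1, mask=fg).corrected.data
        c3 = correct_bias(biased, shrink=3, mask=fg).corrected.data
        rms = np.sqrt(np.mean((c1[fg] - c3[fg]) ** 2)) / np.mean(c3[fg])
        assert rms < 0.05

    def test_idempotent_within_tolerance(self, small_layout):
        case = phantom.generate(layout=small_layout, seed=4, bias_amplitude=0.2)
        fg = foreground_mask(case.early)
        once = correct_bias(case.early, mask=fg)
        twice = correct_bias(once.corrected, mask=fg)
        rms = np.sqrt(np.mean((twice.corrected.data[fg] - once.corrected.data[fg]) ** 2))
        assert rms / np.mean(once.corrected.data[fg]) < 0.01

    def test_field_is_smooth(self, small_layout):
        case = phantom.generate(layout=small_layout, seed=5, bias_amplitude=0.2)
        bc = correct_bias(case.early)
        f = bc.field.data - bc.field.data.mean()
        # Hann window against spectral leakage of the non-periodic field
        win = np.ones(1)
        for ax, n in enumerate(f.shape):
            w = np.hanning(n).reshape([-1 if a == ax else 1 for a in range(3)])
            win = win * w
        spec = np.abs(np.fft.fftn(f * win)) ** 2
        freqs = [np.fft.fftfreq(n, d=s) for n, s in zip(f.shape, bc.field.spacing)]
        FX, FY, FZ = np.meshgrid(*freqs, indexing="ij")
        # energy above the finest B-spline control-grid scale (~15 mm) is tiny
        high = np.sqrt(FX**2 + FY**2 + FZ**2) > 1.0 / 15.0
        assert spec[high].sum() < 0.05 * spec.sum()

    def test_constant_image_returns_identity_field(self):
        vol = Volume(np.full((8, 8, 8), 7.0))
        bc = correct_bias(vol)
        assert bc.constant_input
        np.testing.assert_array_equal(bc.field.data, 1.0)
        np.testing.assert_array_equal(bc.corrected.data, vol.data)


class TestForegroundMask:
    def test_head_ellipsoid_recovered(self, default_case):
        mask = foreground_mask(default_case.early)
        assert dice(mask, default_case.truth.labels > 0) >= 0.95

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            foreground_mask(Volume(np.zeros((6, 6, 6))))

    def test_inverted_contrast_still_masks_head(self, default_case):
        inv = default_case.early.with_data(200.0 - default_case.early.data)
        mask = foreground_mask(inv)
        assert dice(mask, default_case.truth.labels > 0) >= 0.95


class TestNormalizeMeans:
    def test_stated_rule_exact(self):
        early = Volume(np.full((4, 4, 4), 200.0))
        late = Volume(np.full((4, 4, 4), 100.0))
        mask = np.ones((4, 4, 4), bool)
        e, l, (se, sl) = normalize_means(early, late, mask)
        assert (se, sl) == (0.75, 1.5)
        assert abs(e.data[mask].mean() - 150.0) < 1e-6
        assert abs(l.data[mask].mean() - 150.0) < 1e-6

    def test_identical_volumes_unit_scales(self, default_case):
        fg = default_case.truth.labels > 0
        _, _, scales = normalize_means(default_case.early, default_case.early, fg)
        assert scales == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equal_means_property(self, seed):
        rng = np.random.default_rng(seed)
        early = Volume(rng.uniform(10, 500, size=(8, 8, 8)))
        late = Volume(rng.uniform(5, 300, size=(8, 8, 8)))
        mask = rng.random((8, 8, 8)) > 0.4
        e, l, _ = normalize_means(early, late, mask)
        me, ml = e.data[mask].mean(), l.data[mask].mean()
        assert abs(me - ml) / me < 1e-6

    def test_zero_mean_rejected(self):
        early = Volume(np.ones((4, 4, 4)))
        late = Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            normalize_means(early, late, np.ones((4, 4, 4), bool))
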