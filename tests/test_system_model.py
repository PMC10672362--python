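"""Acquisition-system physics: ratios, PSFs, resampling plans."""

import itertools
import math
import warnings
from fractions import Fraction

import numpy as np
import pytest
from scipy.fft import fft
from scipy.signal.windows import hann

from octshot import speckle_sim as ss
from octshot import system_model as sm


# ---------------------------------------------------------------------------
# sampling resolution ratio
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "omega, delta, expected",
    [
        (8.28, 3.06, 3),  # bench system, chicken muscle / blueberry
        (18.0, 9.0, 2),  # retinal system
        (8.28, 8.0, 1),  # cucumber acquisition
        (4.14, 2.5, 2),  # chicken skin
        (30.0, 12.2, 2),  # catheter system
        (30.0, 24.4, 1),  # clinical catheter system
        (5.0, 5.0, 1),  # width equals pitch
        (1.0, 10.0, 1),  # floored at one
    ],
)
def test_sampling_resolution_ratio(omega, delta, expected):
    assert sm.sampling_resolution_ratio(omega, delta) == expected


@pytest.mark.parametrize("omega, delta", [(0.0, 1.0), (1.0, 0.0), (-2.0, 3.0)])
def test_sampling_resolution_ratio_rejects_nonpositive(omega, delta):
    with pytest.raises(sm.InvalidParameterError):
        sm.sampling_resolution_ratio(omega, delta)


def test_packaged_systems_reproduce_grain_sizes():
    expected = {
        "chicken": (3, 3),
        "chicken_skin": (2, 3),
        "cucumber": (1, 3),
        "retina": (2, 3),
        "cardiovascular_1": (2, 3),
        "cardiovascular_2": (1, 3),
    }
    assert set(sm.available_systems()) == set(expected)
    for name, (px, pz) in expected.items():
        spec = sm.load_system(name)
        assert (spec.px, spec.pz) == (px, pz)


def test_spec_validation():
    with pytest.raises(sm.InvalidParameterError):
        sm.OCTSystemSpec("bad", -1, 1, 1, 1, 10, 16)
    with pytest.raises(sm.InvalidParameterError):
        sm.OCTSystemSpec("bad", 1, 1, 1, 1, 32, 16)  # n_spectral > n_fft
    with pytest.raises(sm.InvalidParameterError):
        sm.OCTSystemSpec("bad", 1, 1, 1, 1, 10, 16, axial_range=100, n_axial_pixels=10)
    # consistent axial_range/n_axial_pixels is accepted
    sm.OCTSystemSpec("ok", 10.0, 1, 1, 1, 10, 16, axial_range=100, n_axial_pixels=10)


def test_spec_yaml_roundtrip(tmp_path, chicken_spec):
    path = tmp_path / "sys.yaml"
    chicken_spec.to_yaml(path)
    again = sm.OCTSystemSpec.from_yaml(path)
    assert again == chicken_spec


# ---------------------------------------------------------------------------
# PSFs
# ---------------------------------------------------------------------------


def test_lateral_psf_closed_form(chicken_spec):
    psf = sm.lateral_psf(chicken_spec, half_support=4)
    h = psf.half_support
    assert psf.samples[h] == 1.0
    expected_k1 = math.exp(-2.0 * 3.06**2 / 8.28**2)
    assert psf.samples[h + 1] == pytest.approx(expected_k1, rel=1e-12)
    np.testing.assert_allclose(psf.samples, psf.samples[::-1])


def test_lateral_psf_at_waist_over_sqrt2():
    # pitch chosen so the first off-center sample sits at x = omega/sqrt(2)
    spec = sm.OCTSystemSpec("t", 1.0, 8.28 / math.sqrt(2), 1.0, 8.28, 10, 16)
    psf = sm.lateral_psf(spec, half_support=2)
    assert psf.samples[psf.half_support + 1] == pytest.approx(math.exp(-1), rel=1e-12)


def test_axial_psf_symmetric_and_normalized(chicken_spec):
    psf = sm.axial_psf(chicken_spec)
    assert psf.samples.max() == 1.0
    np.testing.assert_allclose(psf.samples, psf.samples[::-1], atol=1e-12)
    # visible support lands in the 7-9 pixel range typical of these paddings
    assert 5 <= psf.samples.size <= 11


def test_axial_psf_fwhm_matches_oversampled_spectrum(chicken_spec):
    """Brute-force oracle: dense 16x oversampled window spectrum."""
    nh, nfft = chicken_spec.n_spectral, chicken_spec.n_fft
    over = 16
    padded = np.zeros(nfft * over)
    padded[:nh] = hann(nh, sym=True)
    dense = np.abs(fft(padded))
    dense /= dense.max()
    # FWHM in units of the original pixel grid (one pixel = `over` dense bins)
    peak = np.argmax(dense)
    assert peak == 0
    right = np.argmax(dense < 0.5)  # first dense bin below half max
    fwhm_oracle = 2 * right / over  # symmetric spectrum

    psf = sm.axial_psf(chicken_spec)
    h = psf.half_support
    # linear interpolation of the half-maximum crossing on the pixel grid
    k = np.argmax(psf.samples[h:] < 0.5)
    s0, s1 = psf.samples[h + k - 1], psf.samples[h + k]
    crossing = (k - 1) + (s0 - 0.5) / (s0 - s1)
    assert 2 * crossing == pytest.approx(fwhm_oracle, abs=0.1)


def test_axial_psf_padding_widens_main_lobe():
    """No zero padding gives the narrowest main lobe for a fixed n_fft."""
    def fwhm(n_spectral):
        spec = sm.OCTSystemSpec("t", 1, 1, 1, 1, n_spectral, 2048)
        s = sm.axial_psf(spec).samples
        h = s.size // 2
        k = np.argmax(s[h:] < 0.5)
        return 2 * ((k - 1) + (s[h + k - 1] - 0.5) / (s[h + k - 1] - s[h + k]))

    widths = [fwhm(n) for n in (2048, 1600, 1024, 512)]
    assert widths == sorted(widths)


def test_separable_psf_outer_product():
    impulse = sm.PSF1D(np.array([0.0, 1.0, 0.0]), "axial", 1.0)
    g = sm.PSF1D(np.array([0.25, 1.0, 0.25]), "lateral", 1.0)
    psf = sm.separable_psf(impulse, g)
    np.testing.assert_array_equal(psf.kernel[1], g.samples)
    assert psf.kernel[0].sum() == 0 and psf.kernel[2].sum() == 0

    both = sm.separable_psf(impulse, sm.PSF1D(np.array([0.0, 1.0, 0.0]), "lateral", 1.0))
    assert both.kernel.sum() == 1.0 and both.kernel[1, 1] == 1.0


def test_separable_psf_is_rank_one(chicken_spec):
    ax = sm.PSF1D(np.exp(-np.arange(-3, 4) ** 2 / 4.0), "axial", 1.0)
    la = sm.PSF1D(np.exp(-np.arange(-3, 4) ** 2 / 2.0), "lateral", 1.0)
    kernel = sm.separable_psf(ax, la).kernel
    s = np.linalg.svd(kernel, compute_uv=False)
    assert s[1] / s[0] < 1e-12


# ---------------------------------------------------------------------------
# resampling plans
# ---------------------------------------------------------------------------


def _lateral_plan(plans):
    return next(p for p in plans if p.axis == "lateral")


def test_plan_worked_examples():
    chicken = sm.load_system("chicken")
    skin = sm.load_system("chicken_skin")  # px = 2
    cucumber = sm.load_system("cucumber")  # px = 1
    retina = sm.load_system("retina")  # px = 2

    # chicken image (px 3) brought to a px=2 grid: lateral decimation by 4/3
    p = _lateral_plan(sm.plan_resampling(skin, chicken, applied_to="target"))
    assert p.factor == Fraction(4, 3) and p.direction == sm.Direction.DECIMATE

    # chicken image brought to a px=1 grid: lateral decimation by 8/3
    p = _lateral_plan(sm.plan_resampling(cucumber, chicken, applied_to="target"))
    assert p.factor == Fraction(8, 3) and p.direction == sm.Direction.DECIMATE

    # retina image (px 2) brought to a px=1 grid: lateral decimation by 2
    p = _lateral_plan(sm.plan_resampling(cucumber, retina, applied_to="target"))
    assert p.factor == Fraction(2, 1) and p.direction == sm.Direction.DECIMATE

    # identical systems: identity on both axes
    for p in sm.plan_resampling(chicken, chicken):
        assert p.direction == sm.Direction.IDENTITY and p.factor == 1


def test_plan_alignment_all_ordered_pairs():
    """After resampling, the moving image's integer ratio matches the other
    system's, for every ordered pair of packaged systems and both roles."""
    systems = [sm.load_system(n) for n in sm.available_systems()]
    for src, tgt in itertools.permutations(systems, 2):
        for applied_to in ("source", "target"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                plans = sm.plan_resampling(src, tgt, applied_to=applied_to)
            moving = src if applied_to == "source" else tgt
            counterpart = tgt if applied_to == "source" else src
            for p in plans:
                omega, delta = sm._axis_params(moving, p.axis)
                got = sm.sampling_resolution_ratio(omega, delta * float(p.factor))
                want = sm.sampling_resolution_ratio(
                    *sm._axis_params(counterpart, p.axis)
                )
                assert got == want, (src.name, tgt.name, applied_to, p)


def test_plan_round_trip_restores_ratio():
    """Adapting A -> B and then back lands on A's original integer ratio."""
    systems = [sm.load_system(n) for n in sm.available_systems()]
    for a, b in itertools.permutations(systems, 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forward = _lateral_plan(sm.plan_resampling(b, a, applied_to="target"))
            moved = sm.OCTSystemSpec(
                "moved",
                a.delta_z,
                a.delta_x * float(forward.factor),
                a.omega_z,
                a.omega_x,
                a.n_spectral,
                a.n_fft,
            )
            back = _lateral_plan(sm.plan_resampling(a, moved, applied_to="target"))
        final = moved.delta_x * float(back.factor)
        assert sm.sampling_resolution_ratio(a.omega_x, final) == a.px


def test_apply_identity_is_bit_exact(ramp_image):
    plan = sm.ResamplingPlan("lateral", Fraction(1), sm.Direction.IDENTITY, "target")
    out = sm.apply_resampling(ramp_image, plan)
    assert np.array_equal(out.values, ramp_image.values)
    assert out.pitches == ramp_image.pitches


def test_decimation_length_and_pitch():
    image = ss.LogImage(values=np.zeros((40, 300)), pitches=(6.0, 3.06))
    plan = sm.ResamplingPlan(
        "lateral", Fraction(8, 3), sm.Direction.DECIMATE, "target"
    )
    out = sm.apply_resampling(image, plan)
    assert out.shape == (40, 113)  # ceil(300 * 3 / 8)
    assert out.pitches[1] == pytest.approx(3.06 * 8 / 3)
    assert out.pitches[0] == 6.0


def test_decimate_interpolate_round_trip_on_bandlimited_image():
    x = np.linspace(0, 6 * np.pi, 256)
    z = np.linspace(0, 2 * np.pi, 64)
    values = np.sin(x)[None, :] + 0.5 * np.cos(z)[:, None]
    image = ss.LogImage(values=values, pitches=(1.0, 1.0))
    down = sm.apply_resampling(
        image, sm.ResamplingPlan("lateral", Fraction(2), sm.Direction.DECIMATE, "target")
    )
    up = sm.apply_resampling(
        down,
        sm.ResamplingPlan("lateral", Fraction(1, 2), sm.Direction.INTERPOLATE, "target"),
    )
    assert up.shape == image.shape
    interior = (slice(None), slice(20, -20))
    np.testing.assert_allclose(up.values[interior], image.values[interior], atol=0.02)
    assert up.pitches[1] == pytest.approx(1.0)


def test_short_output_warns():
    image = ss.LogImage(values=np.zeros((40, 40)))
    plan = sm.ResamplingPlan("lateral", Fraction(2), sm.Direction.DECIMATE, "target")
    with pytest.warns(UserWarning, match="too short"):
        sm.apply_resampling(image, plan)


# ---------------------------------------------------------------------------
# output regime
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "source, target, lateral_regime",
    [
        ((2, 3), (3, 3), sm.OutputRegime.DETAIL_ENHANCED_RISK),
        ((2, 3), (1, 3), sm.OutputRegime.BLURRED),
        ((2, 3), (2, 3), sm.OutputRegime.MATCHED),
    ],
)
def test_predict_output_regime(source, target, lateral_regime):
    s = sm.SamplingResolutionRatio(px=source[0], pz=source[1])
    t = sm.SamplingResolutionRatio(px=target[0], pz=target[1])
    regimes = sm.predict_output_regime(s, t)
    assert regimes["lateral"] == lateral_regime
    assert regimes["axial"] == sm.OutputRegime.MATCHED
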