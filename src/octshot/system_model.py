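"""OCT acquisition-system physics and sampling-resolution domain planning.

An OCT B-scan is acquired on a grid with axial/lateral sampling spaces
(``delta_z``, ``delta_x``, in µm per pixel) and blurred by a separable point
spread function: a Gaussian lateral profile with waist ``omega_x`` and an
axial profile given by the Fourier transform of a zero-padded Hanning window
(``n_spectral`` measured points padded to ``n_fft``).

The *sampling resolution ratio* along an axis — the PSF effective width over
the sampling space, rounded to the nearest integer and floored at one — is
the speckle grain size in pixels.  A patch despeckler learned on a source
system imprints the source grain size on its output, so deploying it on a
system with a different integer ratio calls for rational resampling of one
of the two images first.  :func:`plan_resampling` computes that plan and
:func:`apply_resampling` executes it with polyphase filtering.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np
import yaml
from scipy.fft import fft, fftshift
from scipy.signal import resample_poly
from scipy.signal.windows import hann

if TYPE_CHECKING:  # pragma: no cover
    from .speckle_sim import LogImage

__all__ = [
    "OCTSystemSpec",
    "PSF1D",
    "PSF2D",
    "SamplingResolutionRatio",
    "ResamplingPlan",
    "OutputRegime",
    "sampling_resolution_ratio",
    "lateral_psf",
    "axial_psf",
    "separable_psf",
    "system_psf",
    "system_ratio",
    "plan_resampling",
    "apply_resampling",
    "predict_output_regime",
    "load_system",
    "available_systems",
]


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OCTSystemSpec:
    """Physical parameters of one OCT acquisition system.

    Parameters
    ----------
    delta_z, delta_x:
        Axial / lateral sampling space in µm per pixel.
    omega_z, omega_x:
        Axial / lateral PSF effective widths in µm (``omega_x`` is the
        Gaussian beam waist).
    n_spectral, n_fft:
        Effective measured spectral points and total FFT points after
        zero padding; these shape the axial PSF.
    axial_range, n_axial_pixels:
        Optional imaging range (µm) and A-line pixel count; when both are
        given they must be consistent with ``delta_z``.
    """

    name: str
    delta_z: float
    delta_x: float
    omega_z: float
    omega_x: float
    n_spectral: int
    n_fft: int
    axial_range: Optional[float] = None
    n_axial_pixels: Optional[int] = None

    def __post_init__(self) -> None:
        for field in ("delta_z", "delta_x", "omega_z", "omega_x"):
            if not getattr(self, field) > 0:
                raise InvalidParameterError(f"{field} must be > 0")
        if self.n_spectral <= 0 or self.n_fft <= 0:
            raise InvalidParameterError("spectral point counts must be > 0")
        if self.n_spectral > self.n_fft:
            raise InvalidParameterError("n_spectral must not exceed n_fft")
        if self.axial_range is not None and self.n_axial_pixels is not None:
            implied = self.axial_range / self.n_axial_pixels
            if not math.isclose(implied, self.delta_z, rel_tol=1e-6):
                raise InvalidParameterError(
                    "delta_z inconsistent with axial_range / n_axial_pixels"
                )

    @property
    def fs_z(self) -> float:
        """Axial sampling rate, pixels per µm."""
        return 1.0 / self.delta_z

    @property
    def fs_x(self) -> float:
        """Lateral sampling rate, pixels per µm."""
        return 1.0 / self.delta_x

    @property
    def px(self) -> int:
        return sampling_resolution_ratio(self.omega_x, self.delta_x)

    @property
    def pz(self) -> int:
        return sampling_resolution_ratio(self.omega_z, self.delta_z)

    # -- YAML round trip ----------------------------------------------------

    _YAML_KEYS = {
        "delta_z": "delta_z_um",
        "delta_x": "delta_x_um",
        "omega_z": "omega_z_um",
        "omega_x": "omega_x_um",
        "n_spectral": "n_spectral",
        "n_fft": "n_fft",
    }

    @classmethod
    def from_yaml(cls, path) -> "OCTSystemSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, default_name=Path(path).stem)

    @classmethod
    def from_dict(cls, raw: dict, default_name: str = "unnamed") -> "OCTSystemSpec":
        kwargs = {"name": raw.get("name", default_name)}
        for attr, key in cls._YAML_KEYS.items():
            if key not in raw:
                raise InvalidParameterError(f"system file missing key {key!r}")
            kwargs[attr] = raw[key]
        if "axial_range_um" in raw:
            kwargs["axial_range"] = raw["axial_range_um"]
        if "n_axial_pixels" in raw:
            kwargs["n_axial_pixels"] = raw["n_axial_pixels"]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        raw = {"name": self.name}
        for attr, key in self._YAML_KEYS.items():
            raw[key] = getattr(self, attr)
        if self.axial_range is not None:
            raw["axial_range_um"] = self.axial_range
        if self.n_axial_pixels is not None:
            raw["n_axial_pixels"] = self.n_axial_pixels
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class PSF1D:
    """One axis of the separable PSF, sampled on the pixel grid.

    ``samples[k]`` is the amplitude at ``k - half_support`` pixels from the
    peak; the peak is normalized to one and the profile is symmetric.
    """

    samples: np.ndarray
    axis: str  # "axial" | "lateral"
    pixel_pitch: float  # µm / pixel

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size % 2 != 1:
            raise InvalidParameterError("PSF1D needs an odd-length 1D sample vector")
        if np.any(samples < 0) or not np.all(np.isfinite(samples)):
            raise InvalidParameterError("PSF samples must be finite and nonnegative")

    @property
    def half_support(self) -> int:
        return self.samples.size // 2


@dataclass(frozen=True)
class PSF2D:
    """Separable 2D PSF: outer product of the axial and lateral profiles."""

    kernel: np.ndarray  # (axial, lateral)
    pitches: tuple  # (µm/px axial, µm/px lateral)

    def __post_init__(self) -> None:
        kernel = np.asarray(self.kernel, dtype=float)
        object.__setattr__(self, "kernel", kernel)
        if kernel.ndim != 2:
            raise InvalidParameterError("PSF2D kernel must be 2D")


@dataclass(frozen=True)
class SamplingResolutionRatio:
    """Speckle grain size in pixels along each axis (>= 1)."""

    px: int
    pz: int

    def __post_init__(self) -> None:
        if self.px < 1 or self.pz < 1:
            raise InvalidParameterError("sampling resolution ratios must be >= 1")


class Direction(str, enum.Enum):
    DECIMATE = "decimate"
    INTERPOLATE = "interpolate"
    IDENTITY = "identity"


@dataclass(frozen=True)
class ResamplingPlan:
    """Rational resampling of one image axis.

    ``factor`` is the ratio of new to old pixel pitch: a factor above one
    coarsens the grid (decimation), below one refines it (interpolation).
    """

    axis: str  # "axial" | "lateral"
    factor: Fraction
    direction: Direction
    applied_to: str  # "source" | "target"
    kernel: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise InvalidParameterError("resampling factor must be positive")
        if (self.factor == 1) != (self.direction == Direction.IDENTITY):
            raise InvalidParameterError("identity direction iff factor == 1")


class OutputRegime(str, enum.Enum):
    MATCHED = "matched"
    DETAIL_ENHANCED_RISK = "detail_enhanced_risk"
    BLURRED = "blurred"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def sampling_resolution_ratio(omega: float, delta: float) -> int:
    """Integer pixels per speckle grain: round(omega/delta), floored at 1.

    Rounding is half-away-from-zero.
    """
    if not (omega > 0 and delta > 0):
        raise InvalidParameterError("omega and delta must be positive")
    return max(1, _round_half_away(omega / delta))


def lateral_psf(spec: OCTSystemSpec, half_support: Optional[int] = None) -> PSF1D:
    """Gaussian lateral profile exp(-2 x^2 / omega_x^2) on the pixel grid.

    When ``half_support`` is omitted it is chosen so the tails fall below
    1% of the peak.
    """
    if half_support is None:
        # exp(-2 x^2/w^2) = 0.01  =>  |x| = w * sqrt(ln(100)/2)
        reach = spec.omega_x * math.sqrt(math.log(100.0) / 2.0)
        half_support = max(1, math.ceil(reach / spec.delta_x))
    if half_support < 1:
        raise InvalidParameterError("half_support must be >= 1")
    k = np.arange(-half_support, half_support + 1)
    x = k * spec.delta_x
    samples = np.exp(-2.0 * x**2 / spec.omega_x**2)
    return PSF1D(samples=samples, axis="lateral", pixel_pitch=spec.delta_x)


def axial_psf(spec: OCTSystemSpec, truncate_threshold: float = 0.01) -> PSF1D:
    """Axial profile: magnitude FFT of a zero-padded Hanning window.

    A Hanning window of ``n_spectral`` points is zero padded to ``n_fft``
    points; the centered magnitude spectrum, peak-normalized, is the axial
    amplitude profile on the pixel grid.  Support is truncated to the
    contiguous region around the peak where the amplitude stays at or above
    ``truncate_threshold`` of the peak (default 1%, which yields the
    familiar 7–9 pixel visible range for typical spectral paddings).
    """
    if spec.n_spectral > spec.n_fft:
        raise InvalidParameterError("n_spectral must not exceed n_fft")
    window = hann(spec.n_spectral, sym=True)
    padded = np.zeros(spec.n_fft)
    padded[: spec.n_spectral] = window
    spectrum = np.abs(fftshift(fft(padded)))
    spectrum /= spectrum.max()
    center = int(np.argmax(spectrum))
    # symmetric contiguous support above threshold
    half = 0
    while (
        center + half + 1 < spectrum.size
        and center - half - 1 >= 0
        and spectrum[center + half + 1] >= truncate_threshold
        and spectrum[center - half - 1] >= truncate_threshold
    ):
        half += 1
    samples = spectrum[center - half : center + half + 1].copy()
    # enforce exact evenness (the magnitude spectrum of a real symmetric
    # window is even up to floating error)
    samples = 0.5 * (samples + samples[::-1])
    samples /= samples.max()
    return PSF1D(samples=samples, axis="axial", pixel_pitch=spec.delta_z)


def separable_psf(axial: PSF1D, lateral: PSF1D) -> PSF2D:
    """Rank-1 2D kernel: outer product of the axial and lateral profiles."""
    kernel = np.outer(axial.samples, lateral.samples)
    return PSF2D(kernel=kernel, pitches=(axial.pixel_pitch, lateral.pixel_pitch))


def system_psf(spec: OCTSystemSpec) -> PSF2D:
    """Convenience: the full separable PSF of a system."""
    return separable_psf(axial_psf(spec), lateral_psf(spec))


def system_ratio(spec: OCTSystemSpec) -> SamplingResolutionRatio:
    return SamplingResolutionRatio(px=spec.px, pz=spec.pz)


def _axis_params(spec: OCTSystemSpec, axis: str) -> tuple:
    if axis == "axial":
        return spec.omega_z, spec.delta_z
    return spec.omega_x, spec.delta_x


def _feasible_factor(
    omega: float, delta: float, p_desired: int, max_denominator: int
) -> Fraction:
    """Smallest fraction-denominator resampling factor achieving p_desired.

    The new pitch is ``delta * factor``; feasibility means
    round(omega / (delta*factor)) == p_desired.  Among feasible fractions
    with denominator <= max_denominator the one closest to the exact
    quotient (omega/delta)/p_desired wins; if none exists the denominator
    bound is escalated with a warning.
    """
    ratio = omega / delta
    ideal = ratio / p_desired
    # round-half-away bin: ratio' in [p-0.5, p+0.5); for p == 1 anything < 1.5
    # works because the ratio is floored at one.
    hi = ratio / (p_desired - 0.5) if p_desired > 1 else math.inf
    lo = ratio / (p_desired + 0.5)
    bound = max_denominator
    while True:
        candidates = []
        for den in range(1, bound + 1):
            n_lo = max(1, math.floor(lo * den))
            n_hi = (
                math.ceil(hi * den) + 1 if math.isfinite(hi) else n_lo + 4 * den
            )
            for num in range(n_lo, n_hi + 1):
                f = Fraction(num, den)
                if sampling_resolution_ratio(omega, delta * float(f)) == p_desired:
                    candidates.append(f)
        if candidates:
            return min(candidates, key=lambda f: (abs(float(f) - ideal), f.denominator))
        if bound > 64:  # pragma: no cover - degenerate specs only
            raise InvalidParameterError("no feasible rational resampling factor")
        bound += 1
        warnings.warn(
            f"no feasible factor with denominator <= {bound - 1}; "
            f"escalating to {bound}",
            stacklevel=2,
        )


def plan_resampling(
    source: OCTSystemSpec,
    target: OCTSystemSpec,
    applied_to: str = "target",
    max_denominator: int = 3,
) -> list:
    """Per-axis rational resampling aligning the two systems' grain sizes.

    The image belonging to ``applied_to`` is resampled so that its integer
    sampling-resolution ratio matches the counterpart system's on both
    axes.  Factors are exact fractions; a factor above one is a decimation
    (coarser grid), below one an interpolation.
    """
    if applied_to not in ("source", "target"):
        raise InvalidParameterError("applied_to must be 'source' or 'target'")
    if max_denominator < 1:
        raise InvalidParameterError("max_denominator must be >= 1")
    moving = source if applied_to == "source" else target
    counterpart = target if applied_to == "source" else source
    plans = []
    for axis in ("axial", "lateral"):
        omega, delta = _axis_params(moving, axis)
        p_desired = sampling_resolution_ratio(*_axis_params(counterpart, axis))
        p_moving = sampling_resolution_ratio(omega, delta)
        if p_moving == p_desired:
            plans.append(
                ResamplingPlan(axis, Fraction(1), Direction.IDENTITY, applied_to)
            )
            continue
        factor = _feasible_factor(omega, delta, p_desired, max_denominator)
        direction = Direction.DECIMATE if factor > 1 else Direction.INTERPOLATE
        plans.append(ResamplingPlan(axis, factor, direction, applied_to))
    return plans


def apply_resampling(
    image: "LogImage", plan: ResamplingPlan, min_length: int = 30
) -> "LogImage":
    """Polyphase rational resampling of one image axis.

    Decimation applies an anti-alias low-pass, interpolation a band-limited
    reconstruction (both via :func:`scipy.signal.resample_poly`); the pixel
    pitch metadata is scaled by the factor.  Output length is
    ``ceil(n * den / num)`` for a factor num/den.  An identity plan returns
    a bit-identical copy.
    """
    from .speckle_sim import LogImage  # local import avoids a cycle

    axis_index = 0 if plan.axis == "axial" else 1
    if plan.direction == Direction.IDENTITY:
        return dataclasses.replace(image, values=image.values.copy())
    up, down = plan.factor.denominator, plan.factor.numerator
    values = resample_poly(image.values, up, down, axis=axis_index, padtype="line")
    new_pitches = list(image.pitches)
    new_pitches[axis_index] = image.pitches[axis_index] * float(plan.factor)
    if values.shape[axis_index] < min_length:
        warnings.warn(
            f"resampled {plan.axis} length {values.shape[axis_index]} is below "
            f"{min_length}; too short to train an analysis-patch model",
            stacklevel=2,
        )
    return LogImage(
        values=values,
        pitches=tuple(new_pitches),
        dynamic_range=image.dynamic_range,
    )


def predict_output_regime(
    source: SamplingResolutionRatio, target: SamplingResolutionRatio
) -> dict:
    """Per-axis consequence of deploying a source-trained model on a target.

    The despeckled output inherits the *source* grain size: a source ratio
    below the target's risks artificially enhanced detail, above it the
    output is blurred along that axis.
    """

    def regime(s: int, t: int) -> OutputRegime:
        if s < t:
            return OutputRegime.DETAIL_ENHANCED_RISK
        if s > t:
            return OutputRegime.BLURRED
        return OutputRegime.MATCHED

    return {
        "axial": regime(source.pz, target.pz),
        "lateral": regime(source.px, target.px),
    }


# ---------------------------------------------------------------------------
# packaged system files
# ---------------------------------------------------------------------------


def available_systems() -> list:
    """Names of the packaged acquisition-system files."""
    base = resources.files("octshot") / "data" / "systems"
    return sorted(p.name[: -len(".yaml")] for p in base.iterdir() if p.name.endswith(".yaml"))


def load_system(name: str) -> OCTSystemSpec:
    """Load a packaged system by name (see :func:`available_systems`)."""
    base = resources.files("octshot") / "data" / "systems"
    path = base / f"{name}.yaml"
    if not path.is_file():
        raise InvalidParameterError(
            f"unknown system {name!r}; available: {available_systems()}"
        )
    raw = yaml.safe_load(path.read_text())
    return OCTSystemSpec.from_dict(raw, default_name=name)
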