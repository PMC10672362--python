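"""Physically grounded speckle simulation for coherent tomograms.

The simulator follows the standard random-phasor construction of coherent
imaging.  A phantom holds the nonnegative reflectivity magnitude ``a[m,n]``
of a tissue section; each speckle realization assigns every scatterer an
independent uniform phase, convolves the complex field with the system PSF,
and records the log-intensity tomogram

    Y = 10 log10 |(a e^{j phi}) * alpha|^2 .

Where the PSF covers many scatterers of comparable strength the intensity is
exponentially distributed (fully developed speckle, contrast std/mean = 1);
near sparse bright structure the speckle is only partially developed, with
no separate mechanism needed.  The matching clean tomogram is the incoherent
mean over phase realizations, available in closed form as

    X = 10 log10 (a^2 * |alpha|^2),

which is also the limit of angular compounding of many realizations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .system_model import (
    InvalidParameterError,
    OCTSystemSpec,
    PSF2D,
    system_psf,
)

__all__ = [
    "Phantom",
    "ComplexTomogram",
    "IntensityImage",
    "LogImage",
    "DB_FLOOR",
    "generate_phantom",
    "simulate_speckled_tomogram",
    "ground_truth_tomogram",
    "sample_speckle_intensity",
    "angular_compound",
    "make_pair",
    "db_to_linear",
    "linear_to_db",
]

#: Linear-intensity floor added inside the log, relative to unit mean
#: intensity; clips -inf for zero-intensity pixels.
DB_FLOOR = 1e-12


@dataclass(frozen=True)
class Phantom:
    """Ground-truth reflectivity magnitude on the acquisition grid."""

    amplitude: np.ndarray
    pitches: tuple = (1.0, 1.0)  # (µm/px axial, lateral)
    seed: int = 0

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        object.__setattr__(self, "amplitude", amp)
        if amp.ndim != 2:
            raise InvalidParameterError("phantom amplitude must be 2D")
        if not np.all(np.isfinite(amp)) or np.any(amp < 0):
            raise InvalidParameterError("phantom amplitude must be finite and >= 0")


@dataclass(frozen=True)
class ComplexTomogram:
    """Coherent field (phantom with random phases, convolved with the PSF)."""

    field: np.ndarray
    realization_seed: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.field, dtype=complex)
        object.__setattr__(self, "field", arr)
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("complex tomogram must be finite")


@dataclass(frozen=True)
class IntensityImage:
    """Linear-scale intensity image."""

    values: np.ndarray
    pitches: tuple = (1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if np.any(arr < 0):
            raise InvalidParameterError("intensities must be >= 0")


@dataclass(frozen=True)
class LogImage:
    """dB-scale tomogram, values = 10*log10(intensity)."""

    values: np.ndarray
    pitches: tuple = (1.0, 1.0)
    dynamic_range: Optional[tuple] = None  # (floor_dB, ceil_dB), display only

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 2:
            raise InvalidParameterError("LogImage values must be 2D")
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("LogImage values must be finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape


def linear_to_db(intensity: np.ndarray) -> np.ndarray:
    return 10.0 * np.log10(intensity + DB_FLOOR)


def db_to_linear(db: np.ndarray) -> np.ndarray:
    return 10.0 ** (np.asarray(db) / 10.0)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


def generate_phantom(
    rows: int,
    cols: int,
    seed: int = 0,
    style: str = "layered",
    pitches: tuple = (1.0, 1.0),
    n_layers: Optional[int] = None,
    texture_sigma: float = 0.2,
    level: float = 1.0,
) -> Phantom:
    """Deterministic synthetic reflectivity map.

    ``layered`` emulates the stratified structure of most OCT tissue:
    horizontally undulating strata of distinct mean reflectivity with
    multiplicative log-normal sub-resolution texture.  ``blobs`` gives
    smooth random clumps; ``constant`` a uniform ``level``.
    """
    if rows < 32 or cols < 32:
        raise InvalidParameterError("phantom must be at least 32x32")
    rng = np.random.default_rng(seed)
    if style == "constant":
        amp = np.full((rows, cols), float(level))
    elif style == "blobs":
        noise = rng.uniform(size=(rows, cols))
        amp = gaussian_filter(noise, sigma=max(2.0, rows / 32.0), mode="reflect")
        amp -= amp.min()
        amp /= max(amp.max(), 1e-12)
        amp = 0.1 + 0.9 * amp
        amp *= np.exp(rng.normal(0.0, texture_sigma, size=amp.shape))
    elif style == "layered":
        if n_layers is None:
            n_layers = int(rng.integers(4, 7))
        # strata mean amplitudes, shuffled log-spaced levels -> distinct layers
        levels = np.geomspace(0.15, 1.0, n_layers)
        rng.shuffle(levels)
        # undulating boundaries: evenly spaced base rows + smooth sinusoids
        base = np.linspace(0, rows, n_layers + 1)[1:-1]
        x = np.arange(cols)
        boundaries = []
        for b in base:
            amp_px = rng.uniform(1.0, 3.0)
            phase = rng.uniform(0, 2 * np.pi)
            period = rng.uniform(cols / 3.0, cols)
            boundaries.append(b + amp_px * np.sin(2 * np.pi * x / period + phase))
        boundaries = np.array(boundaries)  # (n_layers-1, cols)
        r = np.arange(rows)[:, None]
        layer_index = (r >= boundaries[:, None, :]).sum(axis=0)  # (rows, cols)
        amp = levels[layer_index]
        amp = amp * np.exp(rng.normal(0.0, texture_sigma, size=amp.shape))
    else:
        raise InvalidParameterError(f"unknown phantom style {style!r}")
    return Phantom(amplitude=amp, pitches=pitches, seed=seed)


# ---------------------------------------------------------------------------
# tomogram synthesis
# ---------------------------------------------------------------------------


def _convolve_same_reflect(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size convolution with reflected boundary (complex-safe)."""
    pad_a = kernel.shape[0] // 2
    pad_l = kernel.shape[1] // 2
    padded = np.pad(arr, ((pad_a, pad_a), (pad_l, pad_l)), mode="reflect")
    out = fftconvolve(padded, kernel, mode="same")
    return out[pad_a : pad_a + arr.shape[0], pad_l : pad_l + arr.shape[1]]


def _fine_kernel(kernel: np.ndarray, s: int) -> np.ndarray:
    """Kernel interpolated to a 1/s sub-pixel grid, power-matched.

    The scaling makes the sub-grid kernel power equal ``s^2`` times the
    pixel-grid power, so the incoherent expectation of an oversampled
    simulation matches the pixel-grid closed form exactly for flat
    reflectivity (and to quadrature accuracy otherwise).
    """
    from scipy.ndimage import zoom

    fine = zoom(kernel, s, order=3, mode="nearest")
    fine = np.clip(fine, 0.0, None)
    fine *= math.sqrt(s**2 * np.sum(kernel**2) / np.sum(fine**2))
    return fine


def simulate_speckled_tomogram(
    phantom: Phantom, psf: PSF2D, seed: int = 0, oversample: int = 3
) -> LogImage:
    """One coherent speckle realization of a phantom, as a dB tomogram.

    Each image pixel is populated with ``oversample x oversample``
    sub-resolution scatterers carrying the pixel's amplitude (split so the
    expected intensity is preserved) and i.i.d. phases uniform on
    [0, 2pi).  The complex scatterer field is convolved with the PSF
    amplitude kernel on the sub-pixel grid, sampled back at pixel centers,
    and returned as ``10 log10(|field|^2 + floor)``.

    Many independent phasors per resolution cell is what makes the
    fully developed interior exponential with unit contrast;
    ``oversample=1`` degenerates to one scatterer per pixel, which leaves
    the speckle slightly under-developed for narrow PSFs but makes the
    realization an exact pixel-grid convolution (useful for closed-form
    checks).
    """
    if psf.kernel.shape[0] > phantom.amplitude.shape[0] or psf.kernel.shape[
        1
    ] > phantom.amplitude.shape[1]:
        raise InvalidParameterError("PSF support exceeds phantom dimensions")
    if oversample < 1:
        raise InvalidParameterError("oversample must be >= 1")
    if not np.any(phantom.amplitude > 0):
        warnings.warn("all-zero phantom: tomogram sits at the dB floor", stacklevel=2)
    rng = np.random.default_rng(seed)
    s = int(oversample)
    if s == 1:
        amp = phantom.amplitude
        kernel = psf.kernel
    else:
        amp = np.repeat(np.repeat(phantom.amplitude, s, axis=0), s, axis=1) / s
        kernel = _fine_kernel(psf.kernel, s)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=amp.shape)
    field = amp * np.exp(1j * phases)
    coherent = _convolve_same_reflect(field, kernel.astype(complex))
    if s > 1:
        coherent = coherent[s // 2 :: s, s // 2 :: s]
    intensity = np.abs(coherent) ** 2
    return LogImage(values=linear_to_db(intensity), pitches=phantom.pitches)


def ground_truth_tomogram(phantom: Phantom, psf: PSF2D) -> LogImage:
    """Speckle-free tomogram: incoherent expectation over phase draws.

    With independent uniform phases the expected linear intensity is exactly
    ``a^2 * |alpha|^2``; no randomness is involved.
    """
    if psf.kernel.shape[0] > phantom.amplitude.shape[0] or psf.kernel.shape[
        1
    ] > phantom.amplitude.shape[1]:
        raise InvalidParameterError("PSF support exceeds phantom dimensions")
    intensity = _convolve_same_reflect(phantom.amplitude**2, psf.kernel**2)
    intensity = np.clip(intensity, 0.0, None)  # FFT round-off can dip below 0
    return LogImage(values=linear_to_db(intensity), pitches=phantom.pitches)


def sample_speckle_intensity(
    mean_intensity: float, n: int, seed: int = 0
) -> np.ndarray:
    """i.i.d. fully developed speckle intensities, density (1/x) exp(-y/x)."""
    if not mean_intensity > 0:
        raise InvalidParameterError("mean_intensity must be > 0")
    rng = np.random.default_rng(seed)
    return rng.exponential(scale=mean_intensity, size=int(n))


def angular_compound(realizations: list) -> LogImage:
    """Incoherent mean of speckle realizations, returned in dB.

    Each dB image is converted to linear intensity, averaged pixel-wise,
    and converted back; with many independent realizations this converges
    to the clean tomogram.
    """
    if len(realizations) == 0:
        raise InvalidParameterError("need at least one realization")
    shape = realizations[0].shape
    for img in realizations:
        if img.shape != shape:
            raise InvalidParameterError("realization shapes differ")
    stack = np.stack([db_to_linear(img.values) for img in realizations])
    mean = stack.mean(axis=0)
    return LogImage(
        values=linear_to_db(mean),
        pitches=realizations[0].pitches,
        dynamic_range=realizations[0].dynamic_range,
    )


def make_pair(
    spec: OCTSystemSpec,
    rows: int,
    cols: int,
    seed: int = 0,
    style: str = "layered",
    phantom_seed: Optional[int] = None,
) -> tuple:
    """One-shot training fixture: (speckled, clean) tomograms of one phantom.

    The PSF is built from the system spec; phantom pitches are taken from
    the spec so downstream domain planning sees the right grid.  ``seed``
    drives the speckle phases only; the phantom is controlled by
    ``phantom_seed`` (default 0), so different ``seed`` values share one
    phantom and hence one clean image.
    """
    psf = system_psf(spec)
    if phantom_seed is None:
        phantom_seed = 0
    phantom = generate_phantom(
        rows, cols, seed=phantom_seed, style=style, pitches=(spec.delta_z, spec.delta_x)
    )
    noisy = simulate_speckled_tomogram(phantom, psf, seed=seed)
    clean = ground_truth_tomogram(phantom, psf)
    return noisy, clean
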