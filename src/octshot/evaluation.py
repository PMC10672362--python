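"""Quality metrics and image I/O.

PSNR and SSIM are computed on a normalized [0,1] representation: both
images are mapped by the *reference* image's min–max affine and compared
with ``data_range=1``.  This pins down a convention the dB scale leaves
open — absolute scores depend on it, but method comparisons and gains do
not.  Tiled evaluation scores non-overlapping square tiles (default
256 x 256) and reports per-tile values plus their means.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from skimage.metrics import structural_similarity

from .patching import Normalization
from .speckle_sim import LogImage
from .system_model import InvalidParameterError

__all__ = [
    "MetricsReport",
    "PSNR_CAP_DB",
    "psnr",
    "ssim",
    "evaluate_tiles",
    "normalized_pair",
    "read_image",
    "write_image",
]

#: Sentinel reported instead of +inf for identical tiles.
PSNR_CAP_DB = 99.0


@dataclass
class MetricsReport:
    """Per-tile and mean PSNR/SSIM scores for one image pair."""

    psnr_db: list
    ssim: list
    tile: int
    n_tiles: int
    inputs: dict = field(default_factory=dict)

    @property
    def mean_psnr_db(self) -> float:
        return float(np.mean(self.psnr_db))

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim))

    def to_dict(self) -> dict:
        return {
            "schema": "octshot-metrics-1",
            "tile": self.tile,
            "n_tiles": self.n_tiles,
            "psnr_db": self.psnr_db,
            "ssim": self.ssim,
            "mean_psnr_db": self.mean_psnr_db,
            "mean_ssim": self.mean_ssim,
            "inputs": self.inputs,
        }


def _values(image) -> np.ndarray:
    return image.values if isinstance(image, LogImage) else np.asarray(image, float)


def normalized_pair(reference, test) -> tuple:
    """Map both images to [0,1] by the reference's min-max affine."""
    ref = _values(reference)
    tst = _values(test)
    if ref.shape != tst.shape:
        raise InvalidParameterError("reference and test shapes differ")
    norm = Normalization(float(ref.min()), float(ref.max()))
    return norm.apply(ref), norm.apply(tst)


def psnr(reference, test, data_range: float = 1.0, normalize: bool = True) -> float:
    """Peak signal-to-noise ratio, 10 log10(range^2 / MSE), in dB.

    With ``normalize=True`` (default) both images are first mapped by the
    reference's min-max and compared with ``data_range=1``; identical
    images return the cap sentinel instead of infinity.
    """
    if data_range <= 0:
        raise InvalidParameterError("data_range must be > 0")
    if normalize:
        ref, tst = normalized_pair(reference, test)
        data_range = 1.0
    else:
        ref, tst = _values(reference), _values(test)
        if ref.shape != tst.shape:
            raise InvalidParameterError("reference and test shapes differ")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(data_range**2 / mse))


def ssim(reference, test, normalize: bool = True) -> float:
    """Structural similarity with a Gaussian window (sigma 1.5), K1=0.01,
    K2=0.03, on the normalized [0,1] representation."""
    if normalize:
        ref, tst = normalized_pair(reference, test)
    else:
        ref, tst = _values(reference), _values(test)
        if ref.shape != tst.shape:
            raise InvalidParameterError("reference and test shapes differ")
    if min(ref.shape) < 7:
        raise InvalidParameterError("SSIM needs images of at least 7x7")
    return float(
        structural_similarity(
            ref,
            tst,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
        )
    )


def evaluate_tiles(
    reference, test, tile: int = 256, inputs: Optional[dict] = None
) -> MetricsReport:
    """Score non-overlapping tiles from the top-left corner.

    Remainder strips that do not fill a tile are excluded.  Images smaller
    than one tile fall back to a single whole-image tile with a warning.
    """
    ref, tst = normalized_pair(reference, test)
    rows, cols = ref.shape
    if rows < tile or cols < tile:
        warnings.warn(
            f"image {ref.shape} smaller than tile {tile}; scoring whole image",
            stacklevel=2,
        )
        tiles = [(slice(0, rows), slice(0, cols))]
    else:
        tiles = [
            (slice(r, r + tile), slice(c, c + tile))
            for r in range(0, rows - tile + 1, tile)
            for c in range(0, cols - tile + 1, tile)
        ]
    psnrs = [psnr(ref[t], tst[t], normalize=False) for t in tiles]
    ssims = [ssim(ref[t], tst[t], normalize=False) for t in tiles]
    return MetricsReport(
        psnr_db=psnrs,
        ssim=ssims,
        tile=tile,
        n_tiles=len(tiles),
        inputs=inputs or {},
    )


# ---------------------------------------------------------------------------
# image files
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: LogImage, path) -> None:
    """Write a tomogram: float32 TIFF or NPY (lossless dB), or 16-bit PNG
    after dynamic-range mapping; metadata goes to a JSON sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    meta = {"pitches": list(image.pitches), "dynamic_range": image.dynamic_range}
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.values.astype(np.float32))
    elif suffix == ".npy":
        np.save(path, image.values)
    elif suffix == ".png":
        import imageio.v3 as iio

        lo, hi = image.dynamic_range or (
            float(image.values.min()),
            float(image.values.max()),
        )
        scaled = np.clip((image.values - lo) / (hi - lo), 0.0, 1.0)
        iio.imwrite(path, (scaled * 65535.0 + 0.5).astype(np.uint16))
        meta["png_range_db"] = [lo, hi]
    else:
        raise InvalidParameterError(f"unsupported image format {suffix!r}")
    _sidecar_path(path).write_text(json.dumps(meta))


def read_image(path) -> LogImage:
    """Read a tomogram written by :func:`write_image` (TIFF/NPY/PNG)."""
    path = Path(path)
    if not path.exists():
        raise InvalidParameterError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if suffix in (".tif", ".tiff"):
        import tifffile

        values = np.asarray(tifffile.imread(path), dtype=float)
    elif suffix == ".npy":
        values = np.asarray(np.load(path), dtype=float)
    elif suffix == ".png":
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path), dtype=float) / 65535.0
        if "png_range_db" not in meta:
            raise InvalidParameterError(
                f"PNG tomogram {path} requires its JSON sidecar with png_range_db"
            )
        lo, hi = meta["png_range_db"]
        values = raw * (hi - lo) + lo
    else:
        raise InvalidParameterError(f"unsupported image format {suffix!r}")
    if values.ndim != 2:
        raise InvalidParameterError(f"expected a 2D tomogram, got shape {values.shape}")
    pitches = tuple(meta.get("pitches", (1.0, 1.0)))
    dr = meta.get("dynamic_range")
    return LogImage(values=values, pitches=pitches, dynamic_range=tuple(dr) if dr else None)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
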