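"""Analysis-patch datasets, sliding-window inference, overlap averaging.

An *analysis patch* is the ``Lt x Nx`` window of the noisy tomogram whose
contents predict the output at its anchor pixel: the patch's bottom row and
center column (more generally, the column ``nL`` from its left edge) sit on
the anchor.  Patch-to-pixel models predict the single anchor pixel;
patch-to-patch models predict the whole window, and overlapping window
predictions are combined by plain averaging.

Borders are handled by replicate padding so every pixel of the image yields
one training instance and one prediction — no silent cropping.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import h5py
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .speckle_sim import LogImage
from .system_model import InvalidParameterError

__all__ = [
    "AnalysisPatchConfig",
    "Normalization",
    "PatchDataset",
    "extract_analysis_patch",
    "build_dataset",
    "overlap_average_reconstruct",
    "iter_patches",
]


@dataclass(frozen=True)
class AnalysisPatchConfig:
    """Geometry of the analysis patch.

    ``Lt`` depth samples by ``Nx`` lateral columns, the anchor column
    ``nL`` columns from the left edge (``nL + nR = Nx - 1``); ``P`` is the
    output dimension per depth step: 1 for patch-to-pixel, ``Nx`` for
    patch-to-patch.
    """

    Lt: int = 15
    Nx: int = 15
    nL: Optional[int] = None
    nR: Optional[int] = None
    P: int = 1

    def __post_init__(self) -> None:
        if self.Lt < 1 or self.Nx < 1:
            raise InvalidParameterError("Lt and Nx must be >= 1")
        nL, nR = self.nL, self.nR
        if nL is None and nR is None:
            nL = (self.Nx - 1) // 2
            nR = self.Nx - 1 - nL
        elif nL is None:
            nL = self.Nx - 1 - nR
        elif nR is None:
            nR = self.Nx - 1 - nL
        object.__setattr__(self, "nL", nL)
        object.__setattr__(self, "nR", nR)
        if self.nL < 0 or self.nR < 0 or self.nL + self.nR != self.Nx - 1:
            raise InvalidParameterError("need nL + nR = Nx - 1 with nL, nR >= 0")
        if self.P not in (1, self.Nx):
            raise InvalidParameterError("P must be 1 (pixel) or Nx (patch)")


@dataclass(frozen=True)
class Normalization:
    """Affine dB -> [0,1] map fixed by a training image's min-max."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise InvalidParameterError("normalization needs hi > lo")

    @classmethod
    def from_image(cls, image: LogImage) -> "Normalization":
        return cls(float(image.values.min()), float(image.values.max()))

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.lo) / (self.hi - self.lo)

    def invert(self, values: np.ndarray) -> np.ndarray:
        return values * (self.hi - self.lo) + self.lo


@dataclass
class PatchDataset:
    """Aligned analysis patches, clean targets, and their anchors.

    ``inputs``: (m, Lt, Nx); ``targets``: (m, Lt) when P == 1 else
    (m, Lt, Nx); ``positions``: (m, 2) anchor (row, col).  Both inputs and
    targets are normalized by the *noisy* training image's dynamic range.
    """

    inputs: np.ndarray
    targets: np.ndarray
    positions: np.ndarray
    normalization: Normalization
    config: AnalysisPatchConfig

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("inputs", data=self.inputs)
            fh.create_dataset("targets", data=self.targets)
            fh.create_dataset("positions", data=self.positions)
            fh.attrs["norm_lo"] = self.normalization.lo
            fh.attrs["norm_hi"] = self.normalization.hi
            for key in ("Lt", "Nx", "nL", "nR", "P"):
                fh.attrs[key] = getattr(self.config, key)

    @classmethod
    def load(cls, path) -> "PatchDataset":
        with h5py.File(path, "r") as fh:
            cfg = AnalysisPatchConfig(
                Lt=int(fh.attrs["Lt"]),
                Nx=int(fh.attrs["Nx"]),
                nL=int(fh.attrs["nL"]),
                nR=int(fh.attrs["nR"]),
                P=int(fh.attrs["P"]),
            )
            return cls(
                inputs=fh["inputs"][()],
                targets=fh["targets"][()],
                positions=fh["positions"][()],
                normalization=Normalization(
                    float(fh.attrs["norm_lo"]), float(fh.attrs["norm_hi"])
                ),
                config=cfg,
            )


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------


def extract_analysis_patch(
    image: LogImage, i: int, j: int, cfg: AnalysisPatchConfig
) -> np.ndarray:
    """The ``Lt x Nx`` window anchored at pixel (i, j), replicate-padded.

    Rows ``i-(Lt-1) .. i`` and columns ``j-nL .. j+nR``; indices outside
    the image replicate the nearest edge pixel.
    """
    rows_n, cols_n = image.shape
    if not (0 <= i < rows_n and 0 <= j < cols_n):
        raise IndexError(f"anchor ({i}, {j}) outside image of shape {image.shape}")
    rows = np.clip(np.arange(i - cfg.Lt + 1, i + 1), 0, rows_n - 1)
    cols = np.clip(np.arange(j - cfg.nL, j + cfg.nR + 1), 0, cols_n - 1)
    return image.values[np.ix_(rows, cols)].copy()


def _padded_windows(values: np.ndarray, cfg: AnalysisPatchConfig) -> np.ndarray:
    """All anchored windows at once: out[i, j] == patch anchored at (i, j)."""
    padded = np.pad(values, ((cfg.Lt - 1, 0), (cfg.nL, cfg.nR)), mode="edge")
    return sliding_window_view(padded, (cfg.Lt, cfg.Nx))


def _region_slices(region, shape) -> tuple:
    if region is None:
        return slice(0, shape[0]), slice(0, shape[1])
    (r0, r1), (c0, c1) = region
    if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
        raise InvalidParameterError(f"region {region} outside image of shape {shape}")
    return slice(r0, r1), slice(c0, c1)


def build_dataset(
    noisy: LogImage,
    clean: LogImage,
    cfg: AnalysisPatchConfig,
    region=None,
) -> PatchDataset:
    """One training instance per pixel of ``region``.

    ``region`` is ``((row_start, row_stop), (col_start, col_stop))`` in
    0-based half-open convention, or ``None`` for the whole image.  Targets
    come from the clean image at the same anchors: the depth segment ending
    at the anchor when ``P == 1``, the full clean window when ``P == Nx``.
    """
    if noisy.shape != clean.shape:
        raise InvalidParameterError("noisy and clean shapes differ")
    rows, cols = _region_slices(region, noisy.shape)
    norm = Normalization.from_image(noisy)
    noisy01 = norm.apply(noisy.values)
    clean01 = norm.apply(clean.values)

    in_windows = _padded_windows(noisy01, cfg)[rows, cols]
    m_rows, m_cols = in_windows.shape[:2]
    inputs = in_windows.reshape(-1, cfg.Lt, cfg.Nx).astype(np.float32)

    tgt_windows = _padded_windows(clean01, cfg)[rows, cols]
    if cfg.P == 1:
        targets = tgt_windows[..., cfg.nL].reshape(-1, cfg.Lt).astype(np.float32)
    else:
        targets = tgt_windows.reshape(-1, cfg.Lt, cfg.Nx).astype(np.float32)

    rr, cc = np.meshgrid(
        np.arange(rows.start, rows.stop), np.arange(cols.start, cols.stop), indexing="ij"
    )
    positions = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return PatchDataset(
        inputs=inputs,
        targets=targets,
        positions=positions,
        normalization=norm,
        config=cfg,
    )


def iter_patches(
    image: LogImage, cfg: AnalysisPatchConfig, stride: tuple = (1, 1)
) -> tuple:
    """All inference windows of a (normalized) image at the given stride.

    Returns ``(patches, anchors)`` with patches of shape (m, Lt, Nx).
    """
    windows = _padded_windows(image.values, cfg)
    sr, sc = stride
    rows = np.arange(0, image.shape[0], sr)
    cols = np.arange(0, image.shape[1], sc)
    # always include the last row/column so coverage reaches the borders
    if rows[-1] != image.shape[0] - 1:
        rows = np.append(rows, image.shape[0] - 1)
    if cols[-1] != image.shape[1] - 1:
        cols = np.append(cols, image.shape[1] - 1)
    sub = windows[np.ix_(rows, cols)]
    patches = sub.reshape(-1, cfg.Lt, cfg.Nx)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    anchors = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return patches, anchors


def overlap_average_reconstruct(
    patch_predictions: np.ndarray,
    anchors: np.ndarray,
    shape: tuple,
    cfg: AnalysisPatchConfig,
    return_coverage: bool = False,
):
    """Average overlapping patch predictions into one image.

    Each patch entry (k, l) of the patch anchored at (i, j) votes for pixel
    ``(i - (Lt-1) + k, j - nL + l)``; votes falling outside the image (the
    replicate-padded part of border patches) are dropped.  Every covered
    pixel is the arithmetic mean of its votes; uncovered pixels are zero and
    reported via the coverage map.
    """
    patch_predictions = np.asarray(patch_predictions)
    if patch_predictions.size == 0:
        raise InvalidParameterError("empty prediction list")
    anchors = np.asarray(anchors)
    if np.any(anchors < 0) or np.any(anchors >= np.array(shape)):
        raise InvalidParameterError("anchors outside target shape")
    acc = np.zeros(shape, dtype=float)
    count = np.zeros(shape, dtype=np.int64)
    ai = anchors[:, 0]
    aj = anchors[:, 1]
    for k in range(cfg.Lt):
        for l in range(cfg.Nx):
            ri = ai - (cfg.Lt - 1) + k
            cj = aj - cfg.nL + l
            ok = (ri >= 0) & (ri < shape[0]) & (cj >= 0) & (cj < shape[1])
            np.add.at(acc, (ri[ok], cj[ok]), patch_predictions[ok, k, l])
            np.add.at(count, (ri[ok], cj[ok]), 1)
    covered = count > 0
    out = np.zeros(shape, dtype=float)
    out[covered] = acc[covered] / count[covered]
    if return_coverage:
        return out, count
    if not covered.all():
        import warnings

        warnings.warn("overlap averaging left uncovered pixels", stacklevel=2)
    return out
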