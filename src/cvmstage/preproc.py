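"""Image preprocessing operators: crop, resize, Sobel, local filters.

The staging task depends on vertebral outlines, not absolute gray levels, so
besides cropping and resizing the module implements three sliding-window
filters over a structuring element (square or disk): local mean, local
median, and local Shannon entropy

    H = -sum_n p_n ln p_n

computed from the histogram (configurable bin count) of intensities in each
pixel's neighbourhood. Entropy is maximal for a uniform histogram, so the
filter responds to neighbourhoods that mix several gray populations --
edges and texture -- while being insensitive to the local mean level.

All operators accept 2-D float or integer arrays and return float64 images,
except :func:`crop` and :func:`resize` which preserve the input dtype where
possible.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import disk as _disk
from skimage.transform import resize as _sk_resize


class PipelineError(RuntimeError):
    """A preprocessing step failed; the message names the step."""


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Structuring element for the local filters.

    ``shape`` is ``"square"`` (side = ``radius_or_side``) or ``"disk"``
    (radius = ``radius_or_side``); ``border_policy`` is ``"reflect"`` or
    ``"constant"`` (zero padding).
    """

    shape: str = "square"
    radius_or_side: int = 9
    border_policy: str = "reflect"

    def __post_init__(self) -> None:
        if self.shape not in ("square", "disk"):
            raise ValueError(f"unknown window shape {self.shape!r}")
        if self.border_policy not in ("reflect", "constant"):
            raise ValueError(f"unknown border policy {self.border_policy!r}")
        if self.radius_or_side < 1:
            raise ValueError("window must span at least one pixel")
        if self.footprint().sum() < 2:
            raise ValueError("window must cover >= 2 pixels")

    def footprint(self) -> np.ndarray:
        if self.shape == "square":
            return np.ones((self.radius_or_side, self.radius_or_side), dtype=bool)
        return _disk(self.radius_or_side).astype(bool)

    @property
    def ndimage_mode(self) -> str:
        return {"reflect": "reflect", "constant": "constant"}[self.border_policy]


def crop(image: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    """Crop to ``roi = (row, col, height, width)``; values copied unchanged."""
    r, c, h, w = roi
    if r < 0 or c < 0 or h <= 0 or w <= 0 or r + h > image.shape[0] \
            or c + w > image.shape[1]:
        raise ValueError(f"roi {roi} outside image bounds {image.shape}")
    return image[r:r + h, c:c + w].copy()


def center_roi(image: np.ndarray, side: int) -> tuple[int, int, int, int]:
    """Centered square ROI of the given side."""
    r = (image.shape[0] - side) // 2
    c = (image.shape[1] - side) // 2
    return (r, c, side, side)


def resize(image: np.ndarray, side: int, *, order: int | None = None) -> np.ndarray:
    """Resize to ``side x side``.

    Downscaling uses area-weighted (anti-aliased) interpolation by default to
    avoid aliasing of the thin body rims; ``order=0`` gives nearest-neighbour.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    if image.shape == (side, side) and (order is None or order == 0):
        return image.copy()
    anti_alias = side < min(image.shape)
    out = _sk_resize(
        image.astype(np.float64), (side, side),
        order=1 if order is None else order,
        anti_aliasing=anti_alias if order != 0 else False,
        mode="reflect", preserve_range=True,
    )
    return out


def sobel_magnitude(image: np.ndarray) -> np.ndarray:
    """Gradient magnitude from the classic 3x3 Sobel kernels.

    Uses the unnormalised kernels [[1,0,-1],[2,0,-2],[1,0,-1]] (and its
    transpose) with reflected borders; output is sqrt(gx^2 + gy^2) >= 0.
    """
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    img = image.astype(np.float64)
    kx = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=np.float64)
    gx = ndi.convolve(img, kx, mode="reflect")
    gy = ndi.convolve(img, kx.T, mode="reflect")
    return np.hypot(gx, gy)


def _quantize(image: np.ndarray, bins: int,
              value_range: tuple[float, float] | None) -> np.ndarray:
    """Map intensities to integer bin indices 0..bins-1."""
    img = image.astype(np.float64)
    if value_range is None:
        lo, hi = float(img.min()), float(img.max())
    else:
        lo, hi = value_range
    if hi <= lo:  # constant image: everything in one bin
        return np.zeros(image.shape, dtype=np.intp)
    idx = np.floor((img - lo) / (hi - lo) * bins).astype(np.intp)
    return np.clip(idx, 0, bins - 1)


def _box_counts(mask: np.ndarray, side: int, mode: str) -> np.ndarray:
    """Count of True pixels in the side x side window around each pixel."""
    return ndi.uniform_filter(mask.astype(np.float64), size=side,
                              mode=mode) * (side * side)


def local_entropy(
    image: np.ndarray,
    window: WindowSpec | None = None,
    bins: int = 256,
    *,
    value_range: tuple[float, float] | None = None,
    base: float = math.e,
) -> np.ndarray:
    """Local Shannon entropy of the windowed intensity histogram.

    Each output pixel is ``-sum_n p_n log p_n`` over the histogram (with
    ``bins`` equal-width bins spanning ``value_range``, by default the image's
    own range) of the intensities inside the structuring element centered
    there. Natural log by default (values in [0, ln bins]); pass
    ``base=2`` for bits.
    """
    window = window or WindowSpec()
    if bins < 2:
        raise ValueError("bins must be >= 2")
    idx = _quantize(image, bins, value_range)
    fp = window.footprint()
    n_win = int(fp.sum())
    mode = window.ndimage_mode
    square = window.shape == "square"

    # Accumulate sum of c*ln(c) over per-bin window counts c, visiting only
    # bins that occur in the image; H = ln(n) - (1/n) * sum c ln c.
    c_lnc = np.zeros(image.shape, dtype=np.float64)
    counts_total = np.zeros(image.shape, dtype=np.float64)
    for b in np.unique(idx):
        mask = idx == b
        if square:
            c = _box_counts(mask, window.radius_or_side, mode)
        else:
            c = ndi.correlate(mask.astype(np.float64), fp.astype(np.float64),
                              mode=mode)
        c = np.clip(np.rint(c), 0, None)
        counts_total += c
        nz = c > 0
        c_lnc[nz] += c[nz] * np.log(c[nz])

    # With constant border policy the window may contain padding pixels that
    # belong to no bin; entropy uses the actual in-window histogram mass.
    n_eff = counts_total if window.border_policy == "constant" else float(n_win)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.log(n_eff) - c_lnc / n_eff
    h = np.where(counts_total > 0, h, 0.0)
    h = np.clip(h, 0.0, None)
    if base != math.e:
        h = h / math.log(base)
    return h


def local_mean(image: np.ndarray, window: WindowSpec | None = None) -> np.ndarray:
    """Sliding-window mean over the structuring element."""
    window = window or WindowSpec()
    fp = window.footprint().astype(np.float64)
    return ndi.correlate(image.astype(np.float64), fp / fp.sum(),
                         mode=window.ndimage_mode)


def local_median(image: np.ndarray, window: WindowSpec | None = None) -> np.ndarray:
    """Sliding-window median over the structuring element."""
    window = window or WindowSpec()
    return ndi.median_filter(image.astype(np.float64),
                             footprint=window.footprint(),
                             mode=window.ndimage_mode).astype(np.float64)


# ---------------------------------------------------------------------------
# Pipelines

@dataclasses.dataclass(frozen=True)
class PreprocStep:
    """One named step with keyword parameters, e.g. ``crop`` with ``side``."""

    name: str
    params: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class PreprocSpec:
    """Ordered list of preprocessing steps.

    Step names and parameters:

    - ``crop``: ``roi=(r, c, h, w)`` or ``side`` (centered square);
    - ``resize``: ``side``;
    - ``sobel``: no parameters;
    - ``mean`` / ``median``: ``window`` (dict or :class:`WindowSpec`);
    - ``entropy``: ``window``, ``bins``, optional ``value_range``.
    """

    steps: tuple[PreprocStep, ...] = ()

    @classmethod
    def from_list(cls, raw: Iterable) -> "PreprocSpec":
        steps = []
        for item in raw:
            if isinstance(item, PreprocStep):
                steps.append(item)
            elif isinstance(item, str):
                steps.append(PreprocStep(item))
            else:
                d = dict(item)
                steps.append(PreprocStep(d.pop("name"), d))
        return cls(tuple(steps))


def _window_from(params) -> WindowSpec:
    w = params.get("window")
    if w is None:
        return WindowSpec()
    if isinstance(w, WindowSpec):
        return w
    return WindowSpec(**w)


def apply_pipeline(
    image: np.ndarray, spec: PreprocSpec | Sequence
) -> tuple[np.ndarray, list[str]]:
    """Apply the steps in order; returns (image, provenance record).

    A failing step raises :class:`PipelineError` naming the step.
    """
    if not isinstance(spec, PreprocSpec):
        spec = PreprocSpec.from_list(spec)
    out = image
    provenance: list[str] = []
    for i, step in enumerate(spec.steps):
        try:
            p = step.params
            if step.name == "crop":
                roi = p.get("roi") or center_roi(out, p["side"])
                out = crop(out, tuple(roi))
            elif step.name == "resize":
                out = resize(out, p["side"], order=p.get("order"))
            elif step.name == "sobel":
                out = sobel_magnitude(out)
            elif step.name == "mean":
                out = local_mean(out, _window_from(p))
            elif step.name == "median":
                out = local_median(out, _window_from(p))
            elif step.name == "entropy":
                out = local_entropy(out, _window_from(p),
                                    bins=p.get("bins", 256),
                                    value_range=p.get("value_range"))
            else:
                raise ValueError(f"unknown step {step.name!r}")
        except Exception as exc:
            raise PipelineError(
                f"step {i} ({step.name}) failed: {exc}"
            ) from exc
        provenance.append(f"{step.name}({step.params})")
    return out, provenance


def entropy_preprocess_batch(
    images: np.ndarray,
    window: WindowSpec | None = None,
    bins: int = 64,
    value_range: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Entropy-filter a stack of images in [0, 1] and rescale to [0, 1].

    Convenience used by the training pipeline: each image is replaced by its
    local entropy (fixed bin grid over ``value_range`` so the mapping is
    identical across images) divided by ln(bins).
    """
    window = window or WindowSpec("square", 7)
    out = np.empty_like(images, dtype=np.float32)
    scale = 1.0 / math.log(bins)
    for i in range(images.shape[0]):
        out[i] = (local_entropy(images[i], window, bins,
                                value_range=value_range) * scale)
    return out
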