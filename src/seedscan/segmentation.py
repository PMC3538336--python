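"""Batch thresholding and 8-connected component extraction.

The batch protocol: an optimal threshold is computed for every image in a
scanning batch by Otsu's criterion; images with too little foreground give
no usable threshold and are skipped; the mean of the usable per-image
thresholds is then applied to binarize every image in the batch. Seeds are
dark objects on a light background, so a pixel is foreground when its
intensity falls strictly below the threshold. Potential seeds are the
maximal 8-connected components of the binarized image.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .image_io import RasterImage

__all__ = [
    "ThresholdSet",
    "BinaryMask",
    "Component",
    "otsu_threshold",
    "batch_threshold",
    "binarize",
    "label_components",
]

logger = logging.getLogger(__name__)

#: 3x3 structuring element: diagonal neighbors connect (8-connectivity).
_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-image Otsu thresholds and their batch mean.

    ``per_image`` maps image_id to the threshold, or ``None`` where Otsu's
    criterion was undefined (single-intensity histogram). ``batch_mean``
    is the arithmetic mean of the defined values and is the single
    threshold applied to the whole batch.
    """

    per_image: Mapping[str, float | None]
    batch_mean: float

    def to_json(self, path: str | Path) -> None:
        """Store the threshold set as a JSON sidecar for later reuse."""
        payload = {"per_image": dict(self.per_image), "batch_mean": self.batch_mean}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        payload = json.loads(Path(path).read_text())
        return cls(per_image=payload["per_image"], batch_mean=payload["batch_mean"])


@dataclass(frozen=True)
class BinaryMask:
    """Foreground mask with the same shape as its source image."""

    mask: np.ndarray  # bool, (H, W)
    image_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class Component:
    """One maximal 8-connected foreground component.

    ``coords`` is an (n, 2) integer array of (row, col) pixel positions;
    ``touches_border`` flags components clipped by the image edge, which
    downstream filtering may exclude as truncated seeds.
    """

    label: int
    coords: np.ndarray
    touches_border: bool

    def __post_init__(self) -> None:
        c = np.asarray(self.coords)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] == 0:
            raise ValueError("coords must be a non-empty (n, 2) array")
        object.__setattr__(self, "coords", c)

    @property
    def size(self) -> int:
        return self.coords.shape[0]

    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.coords}


def otsu_threshold(image: RasterImage | np.ndarray) -> int | None:
    """Otsu's threshold: maximize between-class variance of the histogram.

    Every candidate cut ``t`` in 1..255 splits the 256-bin intensity
    histogram into the classes ``[0, t)`` and ``[t, 255]``; the returned
    integer maximizes the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2``. Ties take the lowest threshold (smaller
    foreground). Returns ``None`` when the histogram occupies a single bin,
    where no split is possible — an image with very few seeds may hit this.
    """
    pixels = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    hist = np.bincount(pixels.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        return None
    total = hist.sum()
    # cum0[t] = mass/moment of intensities < t, for cuts t = 1..255
    w0 = np.cumsum(hist)[:-1] / total
    m0 = np.cumsum(hist * np.arange(256))[:-1] / total
    mu_t = m0[-1] + hist[255] * 255 / total
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(255)
    sigma_b[valid] = (mu_t * w0[valid] - m0[valid]) ** 2 / (w0[valid] * w1[valid])
    return int(np.argmax(sigma_b)) + 1


def batch_threshold(
    thresholds: Mapping[str, float | None] | Iterable[float | None],
) -> ThresholdSet:
    """Average the defined per-image thresholds into a batch threshold.

    Undefined entries (``None``) are excluded from the mean and logged.
    Raises :class:`ValueError` when no image produced a usable threshold,
    in which case a manual threshold must be supplied.
    """
    if isinstance(thresholds, Mapping):
        per_image = dict(thresholds)
    else:
        per_image = {f"image_{i}": t for i, t in enumerate(thresholds)}
    defined = [float(t) for t in per_image.values() if t is not None]
    n_undef = len(per_image) - len(defined)
    if not defined:
        raise ValueError(
            "no image yielded a usable Otsu threshold; supply a manual threshold"
        )
    if n_undef:
        logger.warning(
            "%d image(s) had an undefined Otsu threshold; excluded from batch mean",
            n_undef,
        )
    return ThresholdSet(per_image=per_image, batch_mean=float(np.mean(defined)))


def binarize(
    image: RasterImage, threshold: float, dark_foreground: bool = True
) -> BinaryMask:
    """Split an image into foreground and background at a threshold.

    With the default polarity, foreground is intensity strictly below the
    threshold (dark seeds on a light background); ``dark_foreground=False``
    inverts this for light objects on dark media.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    if dark_foreground:
        mask = image.pixels < threshold
    else:
        mask = image.pixels > threshold
    return BinaryMask(mask=mask, image_id=image.image_id)


def label_components(mask: BinaryMask) -> list[Component]:
    """Extract maximal 8-connected foreground components.

    Labels are assigned in row-major order of each component's first
    pixel; an empty mask yields an empty list.
    """
    labeled, n = ndimage.label(mask.mask, structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    flat = labeled.ravel()
    fg_idx = np.flatnonzero(flat)
    labels_at = flat[fg_idx]
    # first raster occurrence of each label -> row-major ordering
    uniq, first_idx = np.unique(labels_at, return_index=True)
    order = uniq[np.argsort(first_idx, kind="stable")]
    rank = np.empty(n + 1, dtype=np.int64)
    rank[order] = np.arange(1, n + 1)

    h, w = mask.mask.shape
    sort_ix = np.argsort(rank[labels_at], kind="stable")
    sorted_idx = fg_idx[sort_ix]
    counts = np.bincount(rank[labels_at], minlength=n + 1)[1:]
    splits = np.cumsum(counts)[:-1]
    components: list[Component] = []
    for i, idx in enumerate(np.split(sorted_idx, splits), start=1):
        rows, cols = np.divmod(idx, w)
        touches = bool(
            (rows == 0).any()
            or (rows == h - 1).any()
            or (cols == 0).any()
            or (cols == w - 1).any()
        )
        components.append(
            Component(
                label=i,
                coords=np.column_stack([rows, cols]),
                touches_border=touches,
            )
        )
    return components
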