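"""Per-pixel multiscale filter-bank features.

Every pixel is described by four rotation-invariant scalar filter
responses -- Gaussian gradient magnitude, Laplacian of Gaussian, and the
minimum and maximum eigenvalues of the smoothed structure tensor --
computed at several scales on each colour channel.  With the defaults
(5 scales x 3 channels x 4 filters) that is 60 features per pixel, the
covariates of the density regression.

The structure tensor uses an inner (gradient) scale of sigma/2 and an
outer (tensor smoothing) scale of sigma, the usual two-scale convention.
All filtering uses reflect boundary handling so features are defined up to
the image edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

FILTER_NAMES = ("gradient_magnitude", "laplacian_of_gaussian",
                "structure_tensor_min_eig", "structure_tensor_max_eig")

_MODE = "reflect"


@dataclass(frozen=True)
class FeatureConfig:
    scales: Tuple[float, ...] = (0.8, 1.6, 3.2, 6.4, 12.8)
    channels: Tuple[str, ...] = ("red", "green", "blue")

    def __post_init__(self) -> None:
        if not self.scales or not self.channels:
            raise ValueError("need at least one scale and one channel")
        if any(s <= 0 for s in self.scales):
            raise ValueError(f"scales must be positive, got {self.scales}")
        if list(self.scales) != sorted(set(self.scales)):
            raise ValueError(f"scales must be strictly increasing, got {self.scales}")

    @property
    def n_features(self) -> int:
        return len(self.channels) * len(self.scales) * len(FILTER_NAMES)

    def feature_names(self) -> List[str]:
        return [f"{ch}/sigma={s:g}/{f}"
                for ch in self.channels for s in self.scales for f in FILTER_NAMES]


@dataclass
class FeatureStack:
    """H x W x F array of filter responses plus their names."""

    values: np.ndarray
    feature_names: List[str] = field(default_factory=list)

    @property
    def image_shape(self) -> Tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def as_matrix(self) -> np.ndarray:
        """Flatten to (H*W, F) row-major, the regression design matrix."""
        h, w, f = self.values.shape
        return self.values.reshape(h * w, f)


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Scale integer images to [0, 1]; pass floats through unchanged."""
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    if image.dtype == np.uint16:
        return image.astype(np.float64) / 65535.0
    return image.astype(np.float64)


def _second_derivative(channel: np.ndarray, sigma: float, axis: int) -> np.ndarray:
    """d^2/dx_axis^2 of the sigma-smoothed image, with exactly zero DC.

    Composing two first-derivative Gaussian kernels (each at sigma/sqrt(2),
    so the total smoothing is sigma per axis) instead of sampling the
    second-derivative kernel directly: first-derivative kernels are exactly
    antisymmetric, so constant images produce exactly zero response, which
    the directly sampled second-derivative kernel does not guarantee at
    small sigma.
    """
    s = sigma / np.sqrt(2.0)
    d = ndimage.gaussian_filter1d(channel, s, axis=axis, order=1, mode=_MODE)
    d = ndimage.gaussian_filter1d(d, s, axis=axis, order=1, mode=_MODE)
    return ndimage.gaussian_filter1d(d, sigma, axis=1 - axis, order=0, mode=_MODE)


def _channel_features(channel: np.ndarray, sigma: float) -> List[np.ndarray]:
    gr = ndimage.gaussian_filter(channel, sigma, order=(1, 0), mode=_MODE)
    gc = ndimage.gaussian_filter(channel, sigma, order=(0, 1), mode=_MODE)
    gradmag = np.hypot(gr, gc)

    log = _second_derivative(channel, sigma, 0) + _second_derivative(channel, sigma, 1)

    # Structure tensor: gradients at inner scale sigma/2, products smoothed
    # at outer scale sigma.  Eigenvalues of the 2x2 symmetric tensor in
    # closed form; the tensor is PSD so the min eigenvalue is clipped at 0
    # only to absorb floating-point round-off.
    inner = sigma / 2.0
    dr = ndimage.gaussian_filter(channel, inner, order=(1, 0), mode=_MODE)
    dc = ndimage.gaussian_filter(channel, inner, order=(0, 1), mode=_MODE)
    a_rr = ndimage.gaussian_filter(dr * dr, sigma, mode=_MODE)
    a_rc = ndimage.gaussian_filter(dr * dc, sigma, mode=_MODE)
    a_cc = ndimage.gaussian_filter(dc * dc, sigma, mode=_MODE)
    mean = 0.5 * (a_rr + a_cc)
    root = np.sqrt((0.5 * (a_rr - a_cc)) ** 2 + a_rc ** 2)
    eig_min = np.maximum(mean - root, 0.0)
    eig_max = mean + root
    return [gradmag, log, eig_min, eig_max]


def compute_feature_stack(image: np.ndarray, cfg: FeatureConfig | None = None,
                          dtype=np.float64) -> FeatureStack:
    """Compute the full multiscale descriptor for one image.

    ``image`` is 2-D (grayscale, replicated across the configured channels)
    or H x W x 3.  Integer inputs are scaled to [0, 1] first.  ``dtype``
    controls the storage type of the stack; computation is float64.
    """
    cfg = cfg or FeatureConfig()
    image = np.asarray(image)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    if image.ndim == 2:
        channels = [normalize_intensity(image)] * len(cfg.channels)
    elif image.ndim == 3 and image.shape[2] == len(cfg.channels):
        norm = normalize_intensity(image)
        channels = [norm[:, :, i] for i in range(norm.shape[2])]
    else:
        raise ValueError(
            f"expected 2-D image or {len(cfg.channels)}-channel image, "
            f"got shape {image.shape}")

    planes: List[np.ndarray] = []
    for ch in channels:
        for sigma in cfg.scales:
            planes.extend(_channel_features(ch, sigma))
    stack = np.stack(planes, axis=-1).astype(dtype, copy=False)
    return FeatureStack(values=stack, feature_names=cfg.feature_names())
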