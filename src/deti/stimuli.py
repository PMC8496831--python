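"""Stimulus calibration and image statistics.

Covers circular windowing, RMS-contrast calibration, linear edge
ramping, angular-distance matrices between images, state-space stimulus
sampling, and amplitude-spectrum slope estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import config
from .exceptions import ArgumentError, DegenerateInputError

__all__ = [
    "WindowSpec",
    "CalibratedImage",
    "StimulusSet",
    "build_window_mask",
    "rms_calibrate",
    "apply_edge_ramp",
    "angular_distance_matrix",
    "sample_stimulus_set",
    "amplitude_spectrum_slope",
]


@dataclass(frozen=True)
class WindowSpec:
    """Circular-window definition on a square pixel grid.

    The default convention (``center_offset``/``radius_offset`` of 0.5
    with a strict-interior rule) is frozen in :mod:`deti.config`; for a
    512-px grid with a 512-px diameter it yields 206,643 visible pixels.
    """

    image_size: int
    diameter: float
    center: tuple[float, float] | None = None
    inclusion_rule: str = config.WINDOW_CONVENTION["inclusion_rule"]
    ramp_width: int = 0
    radius_offset: float = config.WINDOW_CONVENTION["radius_offset"]

    def __post_init__(self) -> None:
        if self.image_size < 2:
            raise ArgumentError(f"image_size must be >= 2, got {self.image_size}")
        if self.diameter <= 0:
            raise ArgumentError(f"diameter must be positive, got {self.diameter}")
        if self.inclusion_rule not in ("strict_interior", "inclusive"):
            raise ArgumentError(f"unknown inclusion_rule {self.inclusion_rule!r}")
        if self.ramp_width < 0:
            raise ArgumentError("ramp_width must be >= 0")

    @property
    def effective_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        c = (self.image_size - 1) / 2 + config.WINDOW_CONVENTION["center_offset"]
        return (c, c)

    @property
    def radius(self) -> float:
        return self.diameter / 2 + self.radius_offset


def build_window_mask(spec: WindowSpec) -> tuple[np.ndarray, int]:
    """Return the boolean visibility mask and its pixel count."""
    n = spec.image_size
    cy, cx = spec.effective_center
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dist = np.hypot(yy - cy, xx - cx)
    if spec.inclusion_rule == "strict_interior":
        mask = dist < spec.radius
    else:
        mask = dist <= spec.radius
    return mask, int(mask.sum())


@dataclass
class CalibratedImage:
    """Windowed image with fixed in-mask RMS contrast and mean luminance."""

    values: np.ndarray
    mask: np.ndarray
    rms_target: float
    mean_luminance: float = config.DEFAULT_MEAN_LUMINANCE

    @property
    def visible(self) -> np.ndarray:
        """In-mask pixel values as a flat array."""
        return self.values[self.mask]


@dataclass
class StimulusSet:
    """A collection of calibrated images sharing one window."""

    images: list[CalibratedImage]
    ids: list[str]
    window: WindowSpec
    degrees_per_pixel: float = config.DEFAULT_DEGREES_PER_PIXEL
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.images) != len(self.ids):
            raise ArgumentError("images and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ArgumentError("ids must be unique")
        if self.mask is None:
            self.mask, _ = build_window_mask(self.window)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_size(self) -> int:
        return self.window.image_size

    @property
    def n_visible(self) -> int:
        return int(self.mask.sum())


def rms_calibrate(
    image: np.ndarray,
    mask: np.ndarray,
    rms_target: float = config.DEFAULT_RMS_TARGET,
    mean_luminance: float = config.DEFAULT_MEAN_LUMINANCE,
) -> CalibratedImage:
    """Scale an image so its in-mask RMS contrast equals ``rms_target``.

    The in-mask pixel array I is transformed as::

        I_zm   = I - mean(I)
        I_sc   = 0.5 * I_zm / max|I_zm|
        RMS_sc = 2 * sqrt(sum(I_sc**2) / (Y - 1))        # Y = visible count
        S_rms  = 2 * rms_target / RMS_sc
        out    = 127 * (I_sc * S_rms) + mean_luminance

    All statistics use in-mask pixels only.  Out-of-mask pixels are set
    to ``mean_luminance``.  The operation is idempotent and invariant to
    positive rescaling of the input.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ArgumentError("image and mask shapes differ")
    vals = image[mask]
    y = vals.size
    if y < 2:
        raise ArgumentError("mask must contain at least 2 pixels")
    i_zm = vals - vals.mean()
    peak = np.abs(i_zm).max()
    if peak == 0:
        raise DegenerateInputError("constant in-mask image cannot be calibrated")
    i_sc = 0.5 * i_zm / peak
    rms_sc = 2.0 * np.sqrt(np.sum(i_sc**2) / (y - 1))
    s_rms = 2.0 * rms_target / rms_sc
    calibrated = 127.0 * (i_sc * s_rms) + mean_luminance

    out = np.full_like(image, float(mean_luminance))
    out[mask] = calibrated
    return CalibratedImage(out, mask, rms_target, mean_luminance)


def apply_edge_ramp(image: CalibratedImage, ramp_width: int, window: WindowSpec) -> np.ndarray:
    """Linearly ramp luminance to the mean across the window boundary.

    The ramp spans ``ramp_width`` pixels inward from the window radius;
    pixels outside the window are set to the mean luminance.
    """
    if ramp_width < 0:
        raise ArgumentError("ramp_width must be >= 0")
    if ramp_width > window.radius:
        raise ArgumentError(
            f"ramp_width {ramp_width} exceeds window radius {window.radius}"
        )
    n = window.image_size
    cy, cx = window.effective_center
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dist = np.hypot(yy - cy, xx - cx)
    mean = image.mean_luminance
    if ramp_width == 0:
        weight = image.mask.astype(float)
    else:
        weight = np.clip((window.radius - dist) / ramp_width, 0.0, 1.0)
        weight[~image.mask] = 0.0
    return weight * image.values + (1.0 - weight) * mean


def angular_distance_matrix(arrays: Sequence[np.ndarray]) -> np.ndarray:
    """Pairwise angular distances (degrees) between zero-mean vectors."""
    stack = np.asarray([np.asarray(a, dtype=float).ravel() for a in arrays])
    norms = np.linalg.norm(stack, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError("zero-norm vector in angular distance input")
    unit = stack / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos))
    np.fill_diagonal(theta, 0.0)
    return 0.5 * (theta + theta.T)


def _default_embedding(distance_matrix: np.ndarray, embed_dim: int, seed: int) -> np.ndarray:
    """t-SNE on a precomputed distance matrix, falling back to classical
    MDS when the set is too small for a sensible perplexity."""
    n = distance_matrix.shape[0]
    perplexity = min(30.0, (n - 1) / 3.0)
    if perplexity >= 2.0:
        from sklearn.manifold import TSNE

        tsne = TSNE(
            n_components=embed_dim,
            metric="precomputed",
            init="random",
            perplexity=perplexity,
            random_state=seed,
        )
        return tsne.fit_transform(distance_matrix)
    # classical MDS via double-centered Gram eigendecomposition
    d2 = distance_matrix**2
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1][:embed_dim]
    return v[:, order] * np.sqrt(np.clip(w[order], 0, None))


def sample_stimulus_set(
    distance_matrix: np.ndarray,
    ids: Sequence[str],
    n_select: int,
    embed_dim: int = 3,
    seed: int = 0,
    embedding: Callable[[np.ndarray, int, int], np.ndarray] | None = None,
) -> list[str]:
    """Select ``n_select`` items spread uniformly over a low-dimensional
    embedding of the distance matrix.

    The embedding is pluggable (default: t-SNE / classical-MDS
    fallback).  Uniform coverage is implemented as seeded k-means
    binning of the embedded points into ``n_select`` cells, selecting
    the medoid of each cell.
    """
    distance_matrix = np.asarray(distance_matrix, dtype=float)
    n = distance_matrix.shape[0]
    if len(ids) != n:
        raise ArgumentError("ids length must match distance matrix")
    if n_select > n:
        raise ArgumentError(f"n_select {n_select} exceeds set size {n}")
    if n_select == n:
        return list(ids)
    embed_fn = embedding or _default_embedding
    coords = np.asarray(embed_fn(distance_matrix, embed_dim, seed), dtype=float)

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_select, n_init=10, random_state=seed)
    labels = km.fit_predict(coords)
    selected: list[int] = []
    for cell in range(n_select):
        members = np.flatnonzero(labels == cell)
        dist_to_centroid = np.linalg.norm(
            coords[members] - km.cluster_centers_[cell], axis=1
        )
        selected.append(int(members[np.argmin(dist_to_centroid)]))
    return [ids[i] for i in sorted(selected)]


def amplitude_spectrum_slope(image: np.ndarray) -> float:
    """Least-squares slope of log amplitude vs log spatial frequency.

    Uses orientation-averaged Fourier amplitude in log-spaced radial
    bins (cycles/image), DC excluded, fit over
    [2 cycles/image, 0.9 * Nyquist].
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ArgumentError("image must be square")
    if np.ptp(image) == 0:
        raise DegenerateInputError("constant image has no amplitude spectrum")
    n = image.shape[0]
    amp = np.abs(np.fft.fft2(image - image.mean()))
    freq = np.fft.fftfreq(n) * n  # cycles/image
    fy, fx = np.meshgrid(freq, freq, indexing="ij")
    radius = np.hypot(fy, fx)

    cfg = config.SLOPE_FIT
    f_lo = cfg["f_min_cyc_per_image"]
    f_hi = (n / 2) * cfg["nyquist_fraction"]
    edges = np.geomspace(f_lo, f_hi, cfg["n_bins"] + 1)
    log_f, log_a = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (radius >= lo) & (radius < hi)
        if not sel.any():
            continue
        mean_amp = amp[sel].mean()
        if mean_amp <= 0:
            continue
        log_f.append(np.log10(np.sqrt(lo * hi)))
        log_a.append(np.log10(mean_amp))
    if len(log_f) < 2:
        raise DegenerateInputError("not enough radial bins for slope fit")
    slope, _ = np.polyfit(log_f, log_a, 1)
    return float(slope)
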