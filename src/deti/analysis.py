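"""Downstream statistics on tag maps.

Everything here consumes integer tag arrays (0 = untagged, k = encoder
k over visible pixels) or encoder-probability tensors derived from
them: per-encoder probabilities, electrode dominance counts, spatial
tag histograms and their doubly-normalized marginals, the
log10 HSF/LSF probability ratio, per-timestep state-space PCA, the
time-time ratio-similarity matrix, nine-window local analyses,
between-window encoder covariation, paired permutation contrasts and
bubbles-style image reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from . import config
from .encoders import EncoderSpace, LogGaborSpec
from .exceptions import ArgumentError, DegenerateInputError

__all__ = [
    "LocalWindowLayout",
    "TimeTimeResult",
    "encoder_probability",
    "sf_groups",
    "electrode_dominance",
    "tag_histograms",
    "marginal_profile",
    "sf_ratio",
    "build_statespace_matrix",
    "statespace_pca",
    "ratio_regression",
    "timetime_regression",
    "window_probabilities",
    "local_window_analysis",
    "window_covariation",
    "group_contrast_test",
    "percentile_ci",
    "patch_diameter_px",
    "reconstruct_image",
]


def encoder_probability(tags: np.ndarray, n_encoders: int) -> np.ndarray:
    """Tagged-pixel count per encoder divided by the visible-pixel count.

    Works over arbitrary leading axes; the last axis is pixels.  The
    untagged mass is 1 minus the sum over encoders.
    """
    tags = np.asarray(tags)
    flat = tags.reshape(-1, tags.shape[-1])
    out = np.empty((flat.shape[0], n_encoders))
    for i, row in enumerate(flat):
        counts = np.bincount(row, minlength=n_encoders + 1)[1 : n_encoders + 1]
        out[i] = counts / row.size
    return out.reshape(tags.shape[:-1] + (n_encoders,))


def sf_groups(peaks: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean LSF / HSF membership per encoder (1 cpd in neither)."""
    peaks = np.asarray(peaks, dtype=float)
    lsf = np.isin(peaks, config.LSF_PEAKS)
    hsf = np.isin(peaks, config.HSF_PEAKS)
    return lsf, hsf


def electrode_dominance(
    tags: np.ndarray, n_encoders: int, peaks: Sequence[float] | None = None
) -> dict:
    """Per timestep, assign each electrode its modal (most prevalent)
    tag and count electrodes per encoder.

    ``tags`` is [electrodes, timesteps, pixels].  Untagged pixels are
    excluded from the mode; fully empty maps yield no assignment.
    """
    tags = np.asarray(tags)
    if tags.ndim != 3:
        raise ArgumentError("tags must be [electrodes, timesteps, pixels]")
    n_e, n_s, _ = tags.shape
    counts = np.zeros((n_s, n_encoders), dtype=int)
    for e in range(n_e):
        for s in range(n_s):
            c = np.bincount(tags[e, s], minlength=n_encoders + 1)[1:]
            if c.sum() == 0:
                continue
            counts[s, int(np.argmax(c))] += 1
    result = {"counts": counts}
    if peaks is not None:
        lsf, hsf = sf_groups(peaks)
        result["lsf_counts"] = counts[:, lsf].sum(axis=1)
        result["hsf_counts"] = counts[:, hsf].sum(axis=1)
    return result


def tag_histograms(tags: np.ndarray, n_encoders: int) -> np.ndarray:
    """Sum binary per-encoder indicator maps over all leading axes.

    ``tags`` is [..., pixels]; result is [encoders, pixels] with the
    counting identity that the histograms at a pixel sum to the number
    of maps tagging it.
    """
    tags = np.asarray(tags).reshape(-1, np.asarray(tags).shape[-1])
    hist = np.zeros((n_encoders, tags.shape[1]), dtype=int)
    for k in range(1, n_encoders + 1):
        hist[k - 1] = (tags == k).sum(axis=0)
    return hist


def _minmax(x: np.ndarray, axis: int) -> np.ndarray:
    """Scale to [0, 1] along ``axis``; all-zero slices stay zero."""
    peak = x.max(axis=axis, keepdims=True)
    return np.divide(x, peak, out=np.zeros_like(x, dtype=float), where=peak > 0)


def marginal_profile(
    hist_series: np.ndarray,
    pixel_index: np.ndarray,
    image_size: int,
    mask: np.ndarray,
    axis: str = "row",
    group: str = "LSF",
    peaks: Sequence[float] | None = None,
) -> np.ndarray:
    """Doubly-normalized spatial marginal of grouped tag histograms.

    ``hist_series`` is [timesteps, encoders, pixels].  Encoders in the
    requested SF group are summed, scattered back into image space, and
    averaged along the requested axis over in-mask pixels only.  Each
    position's trace is then min-max normalized over time, and each
    time column min-max normalized again.  Returns [positions,
    timesteps].
    """
    hist_series = np.asarray(hist_series, dtype=float)
    if hist_series.ndim != 3:
        raise ArgumentError("hist_series must be [timesteps, encoders, pixels]")
    n_s, n_k, n_p = hist_series.shape
    if n_s < 1:
        raise ArgumentError("need at least one timestep")
    peaks = peaks if peaks is not None else list(config.DEFAULT_SF_BANK)
    lsf, hsf = sf_groups(peaks)
    members = lsf if group.upper() == "LSF" else hsf
    grouped = hist_series[:, members, :].sum(axis=1)  # [timesteps, pixels]

    rows, cols = pixel_index[:, 0], pixel_index[:, 1]
    pos = rows if axis == "row" else cols
    profile = np.zeros((image_size, n_s))
    pixel_count = np.bincount(pos, minlength=image_size).astype(float)
    for s in range(n_s):
        sums = np.bincount(pos, weights=grouped[s], minlength=image_size)
        np.divide(sums, pixel_count, out=profile[:, s], where=pixel_count > 0)

    profile = _minmax(profile, axis=1)  # each position's trace over time
    profile = _minmax(profile, axis=0)  # then within each time column
    return profile


def sf_ratio(
    prob: np.ndarray,
    peaks: Sequence[float] | None = None,
    epsilon: float | None = None,
    visible_count: int | None = None,
) -> np.ndarray:
    """log10 of summed HSF probability over summed LSF probability.

    The 1 cpd encoder belongs to neither group.  ``epsilon`` defaults to
    one pixel's worth of probability (1/visible_count) to guard zeros.
    """
    prob = np.asarray(prob, dtype=float)
    peaks = peaks if peaks is not None else list(config.DEFAULT_SF_BANK)
    if epsilon is None:
        if visible_count is None:
            raise ArgumentError("provide epsilon or visible_count")
        epsilon = 1.0 / visible_count
    lsf, hsf = sf_groups(peaks)
    hsf_sum = prob[..., hsf].sum(axis=-1)
    lsf_sum = prob[..., lsf].sum(axis=-1)
    return np.log10((hsf_sum + epsilon) / (lsf_sum + epsilon))


def build_statespace_matrix(prob: np.ndarray) -> np.ndarray:
    """[electrodes, encoders, images] -> [electrodes*encoders, images]."""
    prob = np.asarray(prob, dtype=float)
    if prob.ndim != 3:
        raise ArgumentError("prob must be [electrodes, encoders, images]")
    return prob.reshape(-1, prob.shape[2])


def statespace_pca(matrix: np.ndarray, n_pcs: int = 2) -> dict:
    """PCA of a [rows, images] probability matrix with rows as
    observations and images as variables.  Each image gets coordinates
    on the first two PCs (eigenvector entries scaled by the singular
    values); degenerate (rank < 2) input is flagged."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ArgumentError("matrix must be 2-D [rows, images]")
    centered = m - m.mean(axis=0, keepdims=True)
    u, s_vals, vt = np.linalg.svd(centered, full_matrices=False)
    var = s_vals**2
    total = var.sum()
    coords = vt[:n_pcs].T * s_vals[:n_pcs]
    degenerate = total == 0 or (var[1] / total < 1e-12 if var.size > 1 else True)
    return {
        "coords": coords,
        "var_explained": var[:n_pcs] / total if total > 0 else np.zeros(n_pcs),
        "degenerate": bool(degenerate),
    }


def ratio_regression(coords: np.ndarray, ratio: np.ndarray) -> float:
    """Adjusted R-squared of the SF ratio predicting the two PC
    coordinates jointly (pooled sum of squares over both responses)."""
    coords = np.asarray(coords, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    n = ratio.size
    if coords.shape[0] != n:
        raise ArgumentError("coords and ratio lengths differ")
    if np.ptp(ratio) == 0:
        raise DegenerateInputError("constant ratio cannot predict coordinates")
    x = np.column_stack([np.ones(n), ratio])
    beta, *_ = np.linalg.lstsq(x, coords, rcond=None)
    resid = coords - x @ beta
    sse = float((resid**2).sum())
    sst = float(((coords - coords.mean(axis=0)) ** 2).sum())
    if sst == 0:
        return 0.0
    r2 = 1.0 - sse / sst
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


@dataclass
class TimeTimeResult:
    """Time-time R2 matrix with its top-percentile contour."""

    r2: np.ndarray  # [timesteps, timesteps]
    contour: np.ndarray  # boolean mask of the top-fraction R2 values
    flagged_steps: np.ndarray  # timesteps with constant ratios
    threshold: float


def timetime_regression(
    ratios: np.ndarray, top_fraction: float = 0.12
) -> TimeTimeResult:
    """Squared correlation of per-image SF ratios between all timestep
    pairs.  ``ratios`` is [images, timesteps].  Constant-ratio timesteps
    get a zero row/column and are flagged.  The contour marks the top
    ``top_fraction`` of values computed over the upper triangle
    (diagonal included)."""
    r = np.asarray(ratios, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2 or r.shape[0] < 3:
        raise ArgumentError("ratios must be [images >= 3, timesteps >= 2]")
    n_s = r.shape[1]
    std = r.std(axis=0)
    flagged = np.flatnonzero(std == 0)
    safe = np.where(std > 0, std, 1.0)
    z = (r - r.mean(axis=0)) / safe
    corr = (z.T @ z) / r.shape[0]
    r2 = corr**2
    r2[flagged, :] = 0.0
    r2[:, flagged] = 0.0
    np.fill_diagonal(r2, 1.0)
    r2[flagged, flagged] = 1.0

    iu = np.triu_indices(n_s)
    threshold = float(np.quantile(r2[iu], 1.0 - top_fraction))
    contour = r2 >= threshold
    return TimeTimeResult(r2=r2, contour=contour, flagged_steps=flagged, threshold=threshold)


@dataclass
class LocalWindowLayout:
    """One central circular window plus eight on a surrounding ring.

    Default geometry (for 512-px stimuli): 128-px window diameter,
    190-px center-to-outer ring radius, 8 equally spaced ring angles.
    """

    image_size: int
    window_diameter: float = 128.0
    ring_radius: float = 190.0
    n_ring: int = 8
    center: tuple[float, float] | None = None

    def centers(self) -> list[tuple[float, float]]:
        if self.center is not None:
            cy, cx = self.center
        else:
            cy = cx = (self.image_size - 1) / 2 + 0.5
        out = [(cy, cx)]
        for i in range(self.n_ring):
            ang = 2 * np.pi * i / self.n_ring
            out.append((cy + self.ring_radius * np.sin(ang), cx + self.ring_radius * np.cos(ang)))
        return out

    def window_pixel_sets(
        self, mask: np.ndarray, pixel_index: np.ndarray
    ) -> list[np.ndarray]:
        """Indices (into the visible-pixel ordering) per window.

        Windows are congruent by construction: each is the same set of
        integer offsets around its center.  Raises if any window pixel
        falls outside the stimulus mask.
        """
        radius = self.window_diameter / 2
        r_int = int(np.ceil(radius))
        oy, ox = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
        inside = np.hypot(oy, ox) < radius
        offsets = np.column_stack([oy[inside], ox[inside]])

        lookup = -np.ones(mask.shape, dtype=np.int64)
        lookup[tuple(pixel_index.T)] = np.arange(pixel_index.shape[0])

        sets = []
        for cy, cx in self.centers():
            rows = np.round(cy + offsets[:, 0]).astype(int)
            cols = np.round(cx + offsets[:, 1]).astype(int)
            if (
                rows.min() < 0
                or cols.min() < 0
                or rows.max() >= mask.shape[0]
                or cols.max() >= mask.shape[1]
            ):
                raise ArgumentError("local window extends beyond the image grid")
            idx = lookup[rows, cols]
            if (idx < 0).any():
                raise ArgumentError("local window extends outside the stimulus mask")
            sets.append(idx)
        return sets


def window_probabilities(
    tags: np.ndarray, window_pixels: np.ndarray, n_encoders: int
) -> np.ndarray:
    """Encoder probabilities restricted to one window's pixel subset."""
    return encoder_probability(np.asarray(tags)[..., window_pixels], n_encoders)


def local_window_analysis(
    tags: np.ndarray,
    layout: LocalWindowLayout,
    mask: np.ndarray,
    pixel_index: np.ndarray,
    n_encoders: int,
    peaks: Sequence[float] | None = None,
    with_timetime: bool = False,
) -> list[dict]:
    """Per-window SF-ratio series (and optional time-time matrices).

    ``tags`` is [images, timesteps, pixels] (image-specific maps).
    Returns one dict per window with keys ``prob`` [images, timesteps,
    encoders], ``ratio`` [images, timesteps] and optionally
    ``timetime``.
    """
    sets = layout.window_pixel_sets(mask, pixel_index)
    results = []
    for idx in sets:
        prob = window_probabilities(tags, idx, n_encoders)
        ratio = sf_ratio(prob, peaks, visible_count=idx.size)
        entry = {"prob": prob, "ratio": ratio, "n_pixels": int(idx.size)}
        if with_timetime:
            entry["timetime"] = timetime_regression(ratio)
        results.append(entry)
    return results


def window_covariation(
    encoder_space: EncoderSpace,
    layout: LocalWindowLayout,
    peaks: Sequence[float] | None = None,
) -> dict[str, np.ndarray]:
    """Between-window encoder covariation: R2 of encoder responses at
    corresponding pixel positions across images, averaged over pixels
    then over encoders within each SF group.  Returns 9x9 matrices for
    LSF and HSF."""
    idx_sets = layout.window_pixel_sets(encoder_space.mask, encoder_space.pixel_index)
    sizes = {s.size for s in idx_sets}
    if len(sizes) != 1:
        raise ArgumentError("windows must be congruent (equal pixel counts)")
    peaks = peaks if peaks is not None else [s.f_peak for s in encoder_space.bank]
    lsf, hsf = sf_groups(peaks)
    n_w = len(idx_sets)
    n_k = encoder_space.n_encoders
    per_encoder = np.zeros((n_k, n_w, n_w))
    for k in range(n_k):
        # [window, image, pixel-in-window], z-scored across images
        vals = np.stack([encoder_space.values[k][:, idx] for idx in idx_sets])
        vals = vals - vals.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(vals, axis=1)
        norms = np.where(norms > 0, norms, 1.0)
        unit = vals / norms[:, None, :]
        # pairwise per-pixel correlation, averaged over pixels
        r = np.einsum("anp,bnp->abp", unit, unit)
        per_encoder[k] = (r**2).mean(axis=2)
    return {
        "LSF": per_encoder[lsf].mean(axis=0),
        "HSF": per_encoder[hsf].mean(axis=0),
        "per_encoder": per_encoder,
    }


def group_contrast_test(
    series_a: np.ndarray,
    series_b: np.ndarray,
    n_perms: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Paired t per timestep with max-statistic permutation correction.

    ``series_a``/``series_b`` are [participants, timesteps].  The null
    is built by randomly sign-flipping each participant's paired
    difference; the corrected p at each timestep is the proportion of
    permutation max-|t| values at or above the observed |t|.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ArgumentError("series must be matching [participants, timesteps]")
    n_p = a.shape[0]
    if n_p < 3:
        raise DegenerateInputError("need at least 3 participants")
    diff = a - b

    def _paired_t(d: np.ndarray) -> np.ndarray:
        mean = d.mean(axis=0)
        sem = d.std(axis=0, ddof=1) / np.sqrt(n_p)
        return np.divide(mean, sem, out=np.zeros_like(mean), where=sem > 0)

    t_obs = _paired_t(diff)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perms)
    for i in range(n_perms):
        signs = rng.choice([-1.0, 1.0], size=n_p)
        null_max[i] = np.abs(_paired_t(diff * signs[:, None])).max()
    p_corr = (null_max[None, :] >= np.abs(t_obs)[:, None]).mean(axis=1)
    return {"t": t_obs, "p": p_corr, "significant": p_corr < alpha}


def percentile_ci(
    data: np.ndarray, axis: int = 0, level: float = 95.0
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile confidence interval over participants; collapses to
    the point estimate when there is a single participant."""
    data = np.asarray(data, dtype=float)
    half = (100.0 - level) / 2.0
    lo = np.percentile(data, half, axis=axis)
    hi = np.percentile(data, 100.0 - half, axis=axis)
    return lo, hi


def patch_diameter_px(f_peak_cpd: float, degrees_per_pixel: float) -> float:
    """Reconstruction patch diameter: 1.5 periods of the encoder SF."""
    return 1.5 / (f_peak_cpd * degrees_per_pixel)


def _gaussian_patch(diameter: float) -> np.ndarray:
    """Unit-sum Gaussian kernel spanning the given diameter."""
    size = max(3, int(np.ceil(diameter)))
    if size % 2 == 0:
        size += 1
    sigma = diameter / 4.0
    ax = np.arange(size) - size // 2
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    g = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
    return g / g.sum()


def reconstruct_image(
    histograms: np.ndarray,
    bank: Sequence[LogGaborSpec],
    filtered_stack: np.ndarray,
    pixel_index: np.ndarray,
    image_size: int,
    degrees_per_pixel: float,
) -> np.ndarray:
    """Bubbles-style reconstruction from per-pixel encoder histograms.

    At each visible pixel the encoder with the highest electrode sum is
    selected; a Gaussian-weighted patch (1.5 periods of the encoder's
    SF across, unit-sum Gaussian) of that encoder's filtered image,
    centered at the pixel, is accumulated into the output.  Implemented
    per encoder as ``filtered * conv(selection_indicator, gaussian)``,
    which is algebraically identical to direct patch accumulation.
    """
    histograms = np.asarray(histograms, dtype=float)
    n_k = histograms.shape[0]
    if len(bank) != n_k or filtered_stack.shape[0] != n_k:
        raise ArgumentError("histograms, bank and filtered stack disagree")
    selected = np.argmax(histograms, axis=0)
    has_votes = histograms.sum(axis=0) > 0

    out = np.zeros((image_size, image_size))
    for k in range(n_k):
        pick = has_votes & (selected == k)
        if not pick.any():
            continue
        indicator = np.zeros((image_size, image_size))
        coords = pixel_index[pick]
        indicator[coords[:, 0], coords[:, 1]] = 1.0
        kernel = _gaussian_patch(patch_diameter_px(bank[k].f_peak, degrees_per_pixel))
        weight = _signal.fftconvolve(indicator, kernel, mode="same")
        out += filtered_stack[k] * weight
    return out
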