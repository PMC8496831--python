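"""Seeded generators for synthetic stimuli, ground-truth preference
fields and forward-modeled VEPs, plus recovery scoring.

The forward model follows the pipeline's own linking assumption: each
electrode's evoked response is a time-weighted sum of standardized
per-pixel log encoder power at that electrode's preferred encoders,
plus white Gaussian noise.  Because the generators are seeded and fully
synthetic, every pipeline stage can be validated end-to-end without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config
from .encoders import EncoderSpace, default_sf_bank
from .exceptions import ArgumentError
from .stimuli import CalibratedImage, StimulusSet, WindowSpec, build_window_mask, rms_calibrate
from .veps import EpochSet, VEPTensor, average_trials, pc_window_centers

__all__ = [
    "SynthConfig",
    "GroundTruthField",
    "synth_images",
    "synth_ground_truth",
    "synth_veps",
    "recovery_score",
]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for the synthetic pipeline (seed is mandatory)."""

    seed: int
    n_images: int = 40
    image_size: int = 128
    n_electrodes: int = 8
    n_trials: int = 1
    sample_rate: float = 1000.0
    pre_ms: float = 99.0
    post_ms: float = 300.0
    slope_range: tuple[float, float] = (-2.0, -0.5)
    #: timestep index at which preferences switch from the LSF to the
    #: HSF field (None = static preferences)
    switch_step: int | None = None
    #: encoder indices (1-based) used by the preference fields; spaced
    #: bands keep neighboring-band confusions out of recovery tests
    preference_bands: tuple[int, ...] = (1, 3, 5, 7)
    #: number of eccentricity rings mapped onto the bands (0 = uniform
    #: preference per electrode)
    eccentricity_rings: int = 2
    #: number of radial image zones with independently drawn spectral
    #: slopes (1 = one global slope per image).  Matching this to
    #: ``eccentricity_rings`` makes per-pixel preferences recoverable:
    #: with a single global slope, log power at every pixel is driven by
    #: the same image statistic and pixels are not separable.
    n_slope_zones: int = 1
    #: std (ln units) of independent per-band spectral gain jitter
    #: applied in disjoint log-frequency annuli around the encoder
    #: peaks.  With 0, all encoder responses are monotone functions of
    #: the one spectral slope and band identity is not recoverable from
    #: pixel responses; recovery tests therefore set this > 0.
    band_gain_sigma: float = 0.0
    #: texture mode: when > 0, images are sums of per-band noise
    #: carriers modulated by smooth random spatial envelopes on an
    #: envelope_cells x envelope_cells grid.  This gives images many
    #: independent local factors (bands x cells instead of a handful of
    #: global spectral factors), which keeps false-positive snowballs
    #: small in permutation-null runs.
    envelope_cells: int = 0
    envelope_sigma: float = 1.0
    #: subtract the cross-encoder mean from the standardized responses
    #: before mixing (divisive-normalization analog).  Off by default:
    #: the winner-take-all step compares squared correlations, and the
    #: anticorrelations this introduces in other bands can compete with
    #: the generating band.
    center_across_encoders: bool = False
    noise_sigma: float = 0.0
    step_ms: float = 5.0
    half_window_ms: float = 20.0
    #: half-width (samples) of the unit-peak temporal kernel.  Keep it
    #: below the step spacing: overlapping kernels from static
    #: preferences sum to a time-constant plateau that the windowed
    #: PCA's column centering removes entirely.
    kernel_half_samples: int = 2
    degrees_per_pixel: float = config.DEFAULT_DEGREES_PER_PIXEL

    def __post_init__(self) -> None:
        lo, hi = self.slope_range
        if not (-2.5 <= lo <= hi <= 0.0):
            raise ArgumentError("slope_range must lie within [-2.5, 0]")
        for name in ("n_images", "image_size", "n_electrodes", "n_trials"):
            if getattr(self, name) <= 0:
                raise ArgumentError(f"{name} must be positive")


@dataclass
class GroundTruthField:
    """Per-(electrode, pixel, timestep) preferred encoder (1-based)."""

    preferred_encoder: np.ndarray  # [electrodes, pixels, timesteps] int
    spatial_weight: np.ndarray  # [pixels]
    temporal_kernel: np.ndarray  # unit peak
    noise_sigma: float
    step_centers: np.ndarray  # sample indices of the PCA window centers


def _band_annuli(n: int, degrees_per_pixel: float) -> list[np.ndarray]:
    """Disjoint log-frequency annuli with boundaries at the geometric
    midpoints between the default encoder peaks."""
    peaks = np.array([s.f_peak for s in default_sf_bank()])
    bounds = np.concatenate([[1e-9], np.sqrt(peaks[:-1] * peaks[1:]), [1e9]])
    freq = np.fft.fftfreq(n)
    fy, fx = np.meshgrid(freq, freq, indexing="ij")
    f_cpd = np.hypot(fy, fx) / degrees_per_pixel
    return [(f_cpd >= lo) & (f_cpd < hi) for lo, hi in zip(bounds[:-1], bounds[1:])]


def _power_law_noise(
    rng: np.random.Generator,
    n: int,
    slope: float,
    band_gains: np.ndarray | None = None,
    annuli: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Unit-variance phase-randomized noise with amplitude ~ f**slope,
    optionally multiplied by exp(gain) within each band annulus."""
    freq = np.fft.fftfreq(n) * n
    fy, fx = np.meshgrid(freq, freq, indexing="ij")
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0
    amplitude = radius**slope
    if band_gains is not None:
        for g, ann in zip(band_gains, annuli):
            amplitude[ann] *= np.exp(g)
    amplitude[0, 0] = 0.0
    white = np.fft.fft2(rng.standard_normal((n, n)))
    phase = white / np.maximum(np.abs(white), np.finfo(float).tiny)
    img = np.real(np.fft.ifft2(amplitude * phase))
    return img / img.std()


def _zone_masks(n: int, n_zones: int, mask: np.ndarray) -> list[np.ndarray]:
    """Radial zones (inner disc to outer ring) partitioning the window,
    eccentricity-normalized the same way as the preference fields."""
    c = (n - 1) / 2 + 0.5
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    ecc = np.hypot(yy - c, xx - c)
    ecc = ecc / max(ecc[mask].max(), 1.0)
    ring = np.minimum((ecc * n_zones).astype(int), n_zones - 1)
    return [ring == z for z in range(n_zones)]


def _texture_image(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    """One texture-mode image: per-band annulus-limited noise carriers,
    each modulated by a smooth lognormal spatial envelope, with band
    weights following a drawn spectral slope."""
    from scipy import ndimage

    n = cfg.image_size
    annuli = _band_annuli(n, cfg.degrees_per_pixel)
    peaks = np.array([s.f_peak for s in default_sf_bank()])
    slope = rng.uniform(*cfg.slope_range)
    weights = peaks ** (slope + 1.0)  # band std ~ f**(slope+1) for ~f**slope amplitude
    cells = cfg.envelope_cells
    img = np.zeros((n, n))
    for w, ann in zip(weights, annuli):
        spectrum = np.fft.fft2(rng.standard_normal((n, n)))
        spectrum[~ann] = 0.0
        carrier = np.real(np.fft.ifft2(spectrum))
        sd = carrier.std()
        if sd == 0:
            continue
        grid = rng.standard_normal((cells, cells))
        env = np.exp(
            cfg.envelope_sigma * ndimage.zoom(grid, n / cells, order=1)[:n, :n]
        )
        img += w * env * (carrier / sd)
    return img


def synth_images(cfg: SynthConfig) -> StimulusSet:
    """Phase-randomized noise images with amplitude ~ f**slope, slopes
    uniform over ``slope_range``, calibrated to the standard RMS
    contrast and mean luminance.

    With ``n_slope_zones > 1`` each radial zone of each image gets an
    independently drawn slope (zone layout matches the ground-truth
    eccentricity rings), giving pixels spatially local spectral content.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_size
    window = WindowSpec(image_size=n, diameter=float(n))
    mask, _ = build_window_mask(window)

    if cfg.envelope_cells > 0:
        images = [
            rms_calibrate(_texture_image(rng, cfg), mask) for _ in range(cfg.n_images)
        ]
        ids = [f"synth-{i:03d}" for i in range(cfg.n_images)]
        return StimulusSet(
            images, ids, window, degrees_per_pixel=cfg.degrees_per_pixel, mask=mask
        )

    annuli = (
        _band_annuli(n, cfg.degrees_per_pixel) if cfg.band_gain_sigma > 0 else None
    )

    def _one() -> np.ndarray:
        slope = rng.uniform(*cfg.slope_range)
        gains = (
            rng.normal(0.0, cfg.band_gain_sigma, len(annuli))
            if annuli is not None
            else None
        )
        return _power_law_noise(rng, n, slope, gains, annuli)

    images: list[CalibratedImage] = []
    if cfg.n_slope_zones <= 1:
        for _ in range(cfg.n_images):
            images.append(rms_calibrate(_one(), mask))
    else:
        zones = _zone_masks(n, cfg.n_slope_zones, mask)
        for _ in range(cfg.n_images):
            img = np.zeros((n, n))
            for zone in zones:
                img[zone] = _one()[zone]
            images.append(rms_calibrate(img, mask))
    ids = [f"synth-{i:03d}" for i in range(cfg.n_images)]
    return StimulusSet(
        images, ids, window, degrees_per_pixel=cfg.degrees_per_pixel, mask=mask
    )


def _preference_field(
    cfg: SynthConfig, pixel_index: np.ndarray, mask_shape: tuple[int, int], shift: int
) -> np.ndarray:
    """Eccentricity-banded encoder preference per (electrode, pixel).

    Center pixels prefer the highest band, peripheral pixels the lowest
    (HSF-center / LSF-periphery); electrodes rotate the band assignment
    by one position each.  ``shift`` moves all assignments along the
    band list (coarse-to-fine scheduling)."""
    bands = np.sort(np.asarray(cfg.preference_bands, dtype=int))
    n_b = bands.size
    cy = cx = (mask_shape[0] - 1) / 2 + 0.5
    ecc = np.hypot(pixel_index[:, 0] - cy, pixel_index[:, 1] - cx)
    ecc = ecc / max(ecc.max(), 1.0)

    if cfg.eccentricity_rings <= 0:
        ring = np.zeros(pixel_index.shape[0], dtype=int)
        n_rings = 1
    else:
        n_rings = cfg.eccentricity_rings
        ring = np.minimum((ecc * n_rings).astype(int), n_rings - 1)
    if n_b < n_rings:
        raise ArgumentError("need at least as many preference bands as rings")

    # each electrode uses a contiguous slice of the band list, higher
    # band toward the center (HSF-center / LSF-periphery); the schedule
    # shift slides the slice along the list (clipped at the ends)
    base = n_rings - 1 - ring  # 0 (periphery) .. n_rings-1 (center)
    max_start = n_b - n_rings
    field = np.empty((cfg.n_electrodes, pixel_index.shape[0]), dtype=np.int16)
    for e in range(cfg.n_electrodes):
        start = int(np.clip((e % (max_start + 1)) + shift, 0, max_start))
        field[e] = bands[start + base]
    return field


def synth_ground_truth(cfg: SynthConfig, n_visible: int, pixel_index: np.ndarray) -> GroundTruthField:
    """Build the preference field and schedule for a synthetic run.

    Deterministic given the config (the seed fixes electrode offsets
    implicitly through the config fields).  When ``switch_step`` is
    set, preferences before that PCA step use the low-shift (LSF
    leaning) field and steps at/after it the high-shift (HSF leaning)
    field; otherwise the field is static.
    """
    n_samples = int(round((cfg.pre_ms + cfg.post_ms) * cfg.sample_rate / 1000.0))
    centers, _, _ = pc_window_centers(
        n_samples, cfg.sample_rate, cfg.pre_ms, cfg.step_ms, cfg.half_window_ms
    )
    n_steps = centers.size
    shape = (cfg.image_size, cfg.image_size)
    early = _preference_field(cfg, pixel_index, shape, shift=-1)
    late = _preference_field(cfg, pixel_index, shape, shift=+1)

    pref = np.empty((cfg.n_electrodes, n_visible, n_steps), dtype=np.int16)
    for s in range(n_steps):
        if cfg.switch_step is None:
            pref[:, :, s] = _preference_field(cfg, pixel_index, shape, shift=0)
        else:
            pref[:, :, s] = early if s < cfg.switch_step else late

    weight = np.full(n_visible, 1.0 / n_visible)
    half = cfg.kernel_half_samples
    kernel = np.hanning(2 * half + 3)[1:-1]  # unit peak, zero at the ends
    return GroundTruthField(
        preferred_encoder=pref,
        spatial_weight=weight,
        temporal_kernel=kernel,
        noise_sigma=cfg.noise_sigma,
        step_centers=centers,
    )


def synth_veps(
    encoder_space: EncoderSpace, truth: GroundTruthField, cfg: SynthConfig
) -> tuple[EpochSet, VEPTensor]:
    """Forward-model epochs from the ground-truth preference field.

    The deterministic per-electrode signal at PCA-step s is the
    spatially weighted mean of standardized log power at each pixel's
    preferred encoder, spread over time by the unit-peak kernel
    centered on that step; trials add i.i.d. Gaussian noise.
    """
    n_k, n_i, n_p = encoder_space.values.shape
    if truth.preferred_encoder.shape[1] != n_p:
        raise ArgumentError("ground-truth field does not match encoder space pixels")
    if truth.preferred_encoder.max() > n_k or truth.preferred_encoder.min() < 1:
        raise ArgumentError("preferred encoder index out of bank range")

    # standardize per (encoder, pixel) across images
    v = encoder_space.values
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    z = (v - mu) / np.where(sd > 0, sd, 1.0)
    if cfg.center_across_encoders:
        z = z - z.mean(axis=0, keepdims=True)

    n_samples = int(round((cfg.pre_ms + cfg.post_ms) * cfg.sample_rate / 1000.0))
    centers = truth.step_centers
    kernel = truth.temporal_kernel
    half = (kernel.size - 1) // 2

    signal = np.zeros((cfg.n_electrodes, n_samples, n_i))
    amp_cache: dict[bytes, np.ndarray] = {}
    pixel_arange = np.arange(n_p)
    for e in range(cfg.n_electrodes):
        for s, c in enumerate(centers):
            pref = truth.preferred_encoder[e, :, s]  # [pixels], 1-based
            key = pref.tobytes()
            amp = amp_cache.get(key)
            if amp is None:
                amp = np.einsum(
                    "p,ip->i", truth.spatial_weight, z[pref - 1, :, pixel_arange].T
                )
                # unit variance so no preference field dominates PC1
                # merely through its spectral-band energy
                sd = amp.std()
                amp = amp / sd if sd > 0 else amp
                amp_cache[key] = amp
            lo = max(0, c - half)
            hi = min(n_samples, c + half + 1)
            signal[e, lo:hi, :] += kernel[lo - (c - half) : hi - (c - half), None] * amp[None, :]

    rng = np.random.default_rng(cfg.seed + 1)
    n_trials_total = cfg.n_trials * n_i
    data = np.empty((n_trials_total, cfg.n_electrodes, n_samples))
    image_ids = np.empty(n_trials_total, dtype=int)
    t = 0
    for i in range(n_i):
        for _ in range(cfg.n_trials):
            noise = (
                rng.standard_normal((cfg.n_electrodes, n_samples)) * cfg.noise_sigma
                if cfg.noise_sigma > 0
                else 0.0
            )
            data[t] = signal[:, :, i] + noise
            image_ids[t] = i
            t += 1
    epochs = EpochSet(data, cfg.sample_rate, (cfg.pre_ms, cfg.post_ms), image_ids)
    veps = average_trials(epochs, image_ids=list(range(n_i)))
    return epochs, veps


def recovery_score(
    tags: np.ndarray,
    truth_pref: np.ndarray,
    n_encoders: int,
) -> dict:
    """Agreement between estimated tags and ground-truth preferences.

    Both arrays are flat over (whatever leading axes) x pixels with the
    same shape; only tagged (nonzero) pixels are scored.  Reports exact
    agreement, near agreement (within +-1 encoder), a confusion table
    indexed [true, tagged] and the 1/n_encoders chance level.  An empty
    estimate yields ``agreement=None``.
    """
    tags = np.asarray(tags).ravel()
    truth_pref = np.asarray(truth_pref).ravel()
    if tags.shape != truth_pref.shape:
        raise ArgumentError("tag and truth shapes differ")
    scored = tags > 0
    n_tagged = int(scored.sum())
    confusion = np.zeros((n_encoders, n_encoders), dtype=int)
    if n_tagged == 0:
        return {
            "agreement": None,
            "near_agreement": None,
            "n_tagged": 0,
            "confusion": confusion,
            "chance": 1.0 / n_encoders,
        }
    est = tags[scored]
    tru = truth_pref[scored]
    np.add.at(confusion, (tru - 1, est - 1), 1)
    return {
        "agreement": float((est == tru).mean()),
        "near_agreement": float((np.abs(est - tru) <= 1).mean()),
        "n_tagged": n_tagged,
        "confusion": confusion,
        "chance": 1.0 / n_encoders,
    }
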