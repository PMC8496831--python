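"""VEP preprocessing and time-resolved first-principal-component series.

Epochs are filtered (zero-phase Butterworth), artifact-rejected,
average-referenced and baseline-corrected, then trial-averaged into a
per-image VEP tensor.  A sliding-window PCA over images then yields, at
each electrode and 5-ms step, the first eigenvector of the
image-by-image covariance of the windowed potentials: one loading per
image, the neural response axis that everything downstream is regressed
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from . import config
from .exceptions import ArgumentError, DegenerateInputError

__all__ = [
    "EpochSet",
    "VEPTensor",
    "PCSeries",
    "PreprocessConfig",
    "preprocess_epochs",
    "average_trials",
    "pc_window_centers",
    "timeresolved_pc1",
]


@dataclass
class EpochSet:
    """Trial epochs: data [trials, electrodes, samples] in microvolts."""

    data: np.ndarray
    sample_rate: float
    epoch_window_ms: tuple[float, float]  # (pre, post) around onset
    image_ids: np.ndarray  # one id per trial
    electrode_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.image_ids = np.asarray(self.image_ids)
        if self.data.ndim != 3:
            raise ArgumentError("epoch data must be [trials, electrodes, samples]")
        if self.image_ids.shape[0] != self.data.shape[0]:
            raise ArgumentError("one image id required per trial")
        pre, post = self.epoch_window_ms
        expected = int(round((pre + post) * self.sample_rate / 1000.0))
        if self.data.shape[2] != expected:
            raise ArgumentError(
                f"samples {self.data.shape[2]} inconsistent with window "
                f"({pre}+{post}) ms at {self.sample_rate} Hz (expected {expected})"
            )

    @property
    def onset_sample(self) -> int:
        return int(round(self.epoch_window_ms[0] * self.sample_rate / 1000.0))


@dataclass
class VEPTensor:
    """Trial-averaged potentials: data [electrodes, samples, images]."""

    data: np.ndarray
    sample_rate: float
    epoch_window_ms: tuple[float, float]
    image_ids: Sequence
    trial_counts: np.ndarray | None = None
    electrode_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ArgumentError("VEP data must be [electrodes, samples, images]")
        if self.data.shape[2] != len(self.image_ids):
            raise ArgumentError("image axis must match image_ids")

    @property
    def onset_sample(self) -> int:
        return int(round(self.epoch_window_ms[0] * self.sample_rate / 1000.0))

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[1]
        return np.arange(n) / self.sample_rate * 1000.0 - self.epoch_window_ms[0]


@dataclass
class PCSeries:
    """First-PC image loadings per (electrode, timestep)."""

    loadings: np.ndarray  # [electrodes, steps, images], unit norm per slice
    var_explained: np.ndarray  # [electrodes, steps, n_pcs]
    step_centers_ms: np.ndarray
    step_ms: float = 5.0
    half_window_ms: float = 20.0
    skipped_steps: list = field(default_factory=list)


@dataclass(frozen=True)
class PreprocessConfig:
    highpass_hz: float = 0.1
    lowpass_hz: float = 45.0
    reject_uv: float = 100.0
    baseline_ms: float = 99.0
    highpass_order: int = config.FILTER_DESIGN["highpass_order"]
    lowpass_order: int = config.FILTER_DESIGN["lowpass_order"]


def preprocess_epochs(
    epochs: EpochSet, cfg: PreprocessConfig | None = None
) -> tuple[EpochSet, dict]:
    """Filter, artifact-reject, re-reference and baseline epochs.

    Order of operations: zero-phase high-pass, zero-phase low-pass,
    amplitude/transient rejection (trial dropped when any sample or
    sample-to-sample step exceeds the threshold), average re-reference
    across electrodes, baseline subtraction of the mean over the final
    ``baseline_ms`` before onset.  Returns the cleaned epochs and a
    rejection report.
    """
    cfg = cfg or PreprocessConfig()
    rate = epochs.sample_rate
    if cfg.lowpass_hz >= rate / 2:
        raise ArgumentError("lowpass cutoff at or above Nyquist")

    data = epochs.data
    sos_hp = signal.butter(
        cfg.highpass_order, cfg.highpass_hz, "highpass", fs=rate, output="sos"
    )
    sos_lp = signal.butter(
        cfg.lowpass_order, cfg.lowpass_hz, "lowpass", fs=rate, output="sos"
    )
    data = signal.sosfiltfilt(sos_hp, data, axis=2)
    data = signal.sosfiltfilt(sos_lp, data, axis=2)

    amp_bad = np.abs(data).max(axis=(1, 2)) > cfg.reject_uv
    trans_bad = np.abs(np.diff(data, axis=2)).max(axis=(1, 2)) > cfg.reject_uv
    keep = ~(amp_bad | trans_bad)

    surviving_ids = epochs.image_ids[keep]
    for img in np.unique(epochs.image_ids):
        if img not in surviving_ids:
            raise DegenerateInputError(
                f"all trials rejected for image {img!r}"
            )

    data = data[keep]
    data = data - data.mean(axis=1, keepdims=True)  # average reference

    onset = epochs.onset_sample
    nb = int(round(cfg.baseline_ms * rate / 1000.0))
    baseline = data[:, :, onset - nb : onset].mean(axis=2, keepdims=True)
    data = data - baseline

    report = {
        "n_trials_in": int(epochs.data.shape[0]),
        "n_trials_kept": int(keep.sum()),
        "dropped_fraction": float(1.0 - keep.mean()),
        "dropped_amplitude": int(amp_bad.sum()),
        "dropped_transient": int((trans_bad & ~amp_bad).sum()),
    }
    cleaned = EpochSet(
        data,
        epochs.sample_rate,
        epochs.epoch_window_ms,
        surviving_ids,
        epochs.electrode_ids,
    )
    return cleaned, report


def average_trials(epochs: EpochSet, image_ids: Sequence | None = None) -> VEPTensor:
    """Average epochs across trials per image -> [electrodes, samples, images]."""
    ids = list(image_ids) if image_ids is not None else sorted(
        np.unique(epochs.image_ids).tolist()
    )
    n_e, n_s = epochs.data.shape[1], epochs.data.shape[2]
    out = np.empty((n_e, n_s, len(ids)))
    counts = np.zeros(len(ids), dtype=int)
    for j, img in enumerate(ids):
        sel = epochs.image_ids == img
        if not sel.any():
            raise DegenerateInputError(f"no surviving trials for image {img!r}")
        counts[j] = int(sel.sum())
        out[:, :, j] = epochs.data[sel].mean(axis=0)
    return VEPTensor(
        out,
        epochs.sample_rate,
        epochs.epoch_window_ms,
        ids,
        trial_counts=counts,
        electrode_ids=epochs.electrode_ids,
    )


def pc_window_centers(
    n_samples: int,
    sample_rate: float,
    pre_ms: float,
    step_ms: float = 5.0,
    half_window_ms: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Valid window-center sample indices for the sliding PCA.

    Centers start at stimulus onset and advance in ``step_ms`` steps;
    centers whose full +-``half_window_ms`` window would be truncated at
    either epoch edge are excluded.  Returns (center sample indices,
    center times in ms, half-window in samples).
    """
    hw = int(round(half_window_ms * sample_rate / 1000.0))
    step = max(1, int(round(step_ms * sample_rate / 1000.0)))
    onset = int(round(pre_ms * sample_rate / 1000.0))
    centers = []
    for c in range(onset, n_samples, step):
        if c - hw >= 0 and c + hw < n_samples:
            centers.append(c)
    centers = np.asarray(centers, dtype=int)
    times = centers / sample_rate * 1000.0 - pre_ms
    return centers, times, hw


def timeresolved_pc1(
    veps: VEPTensor, step_ms: float = 5.0, half_window_ms: float = 20.0, n_pcs: int = 5
) -> PCSeries:
    """Sliding-window PCA over images at each electrode.

    At each step the [window samples, images] matrix is column-centered
    and the first eigenvector of its image-by-image covariance taken as
    the loading vector (unit norm, one entry per image).  Sign is
    canonicalized so each loading vector correlates non-negatively with
    the projection of the data onto the mean window profile; downstream
    R-squared statistics are sign-invariant regardless.
    """
    n_e, n_s, n_i = veps.data.shape
    centers, times, hw = pc_window_centers(
        n_s, veps.sample_rate, veps.epoch_window_ms[0], step_ms, half_window_ms
    )
    if centers.size == 0:
        raise ArgumentError("no window center fits within the epoch")
    n_pcs = min(n_pcs, n_i)
    loadings = np.zeros((n_e, centers.size, n_i))
    var_exp = np.zeros((n_e, centers.size, n_pcs))
    for e in range(n_e):
        for s, c in enumerate(centers):
            x = veps.data[e, c - hw : c + hw + 1, :]
            xc = x - x.mean(axis=0, keepdims=True)
            cov = xc.T @ xc / max(xc.shape[0] - 1, 1)
            w, v = np.linalg.eigh(cov)
            order = np.argsort(w)[::-1]
            w = np.clip(w[order], 0.0, None)
            total = w.sum()
            if total > 0:
                var_exp[e, s] = w[:n_pcs] / total
            vec = v[:, order[0]]
            profile = x.mean(axis=1)
            proj = profile @ x  # per-image projection onto mean profile
            proj = proj - proj.mean()
            if vec @ proj < 0:
                vec = -vec
            loadings[e, s] = vec
    return PCSeries(
        loadings=loadings,
        var_explained=var_exp,
        step_centers_ms=times,
        step_ms=step_ms,
        half_window_ms=half_window_ms,
    )
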