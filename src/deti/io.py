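"""HDF5 persistence for the pipeline containers."""

from __future__ import annotations

import h5py
import numpy as np

from .encoders import EncoderSpace, LogGaborSpec
from .stimuli import CalibratedImage, StimulusSet, WindowSpec
from .veps import PCSeries, VEPTensor

__all__ = [
    "save_stimuli",
    "load_stimuli",
    "save_encoder_space",
    "load_encoder_space",
    "save_veps",
    "load_veps",
    "save_pc_series",
    "load_pc_series",
    "save_tags",
    "load_tags",
]


def save_stimuli(path: str, stimuli: StimulusSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "images", data=np.stack([im.values for im in stimuli.images]), dtype="f4"
        )
        f.create_dataset("mask", data=stimuli.mask.astype("u1"))
        f.create_dataset("ids", data=np.array(stimuli.ids, dtype="S"))
        f.attrs["rms_target"] = stimuli.images[0].rms_target
        f.attrs["mean_luminance"] = stimuli.images[0].mean_luminance
        f.attrs["degrees_per_pixel"] = stimuli.degrees_per_pixel
        w = stimuli.window
        f.attrs["image_size"] = w.image_size
        f.attrs["diameter"] = w.diameter
        f.attrs["inclusion_rule"] = w.inclusion_rule
        f.attrs["radius_offset"] = w.radius_offset
        f.attrs["ramp_width"] = w.ramp_width


def load_stimuli(path: str) -> StimulusSet:
    with h5py.File(path, "r") as f:
        values = f["images"][...].astype(float)
        mask = f["mask"][...].astype(bool)
        ids = [s.decode() for s in f["ids"][...]]
        window = WindowSpec(
            image_size=int(f.attrs["image_size"]),
            diameter=float(f.attrs["diameter"]),
            inclusion_rule=str(f.attrs["inclusion_rule"]),
            radius_offset=float(f.attrs["radius_offset"]),
            ramp_width=int(f.attrs["ramp_width"]),
        )
        images = [
            CalibratedImage(
                v, mask, float(f.attrs["rms_target"]), float(f.attrs["mean_luminance"])
            )
            for v in values
        ]
        return StimulusSet(
            images, ids, window, float(f.attrs["degrees_per_pixel"]), mask=mask
        )


def save_encoder_space(path: str, space: EncoderSpace) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("logpower", data=space.values, dtype="f4")
        f.create_dataset("pixel_index", data=space.pixel_index, dtype="i4")
        f.create_dataset("floor", data=space.floor)
        f.create_dataset("mask", data=space.mask.astype("u1"))
        f.attrs["degrees_per_pixel"] = space.degrees_per_pixel
        f.attrs["f_peak"] = [s.f_peak for s in space.bank]
        f.attrs["bandwidth_octaves"] = [s.bandwidth_octaves for s in space.bank]
        f.attrs["orientation_center"] = [
            -1.0 if s.isotropic else float(s.orientation_center) for s in space.bank
        ]
        f.attrs["orientation_sigma"] = [s.orientation_sigma for s in space.bank]


def load_encoder_space(path: str) -> EncoderSpace:
    with h5py.File(path, "r") as f:
        bank = []
        for fp, bw, oc, osig in zip(
            f.attrs["f_peak"],
            f.attrs["bandwidth_octaves"],
            f.attrs["orientation_center"],
            f.attrs["orientation_sigma"],
        ):
            center = "isotropic" if oc < 0 else float(oc)
            bank.append(LogGaborSpec(float(fp), float(bw), center, float(osig)))
        return EncoderSpace(
            values=f["logpower"][...].astype(float),
            bank=bank,
            pixel_index=f["pixel_index"][...],
            floor=f["floor"][...],
            mask=f["mask"][...].astype(bool),
            degrees_per_pixel=float(f.attrs["degrees_per_pixel"]),
        )


def save_veps(path: str, veps: VEPTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("veps", data=veps.data, dtype="f8")
        f.attrs["sample_rate"] = veps.sample_rate
        f.attrs["pre_ms"] = veps.epoch_window_ms[0]
        f.attrs["post_ms"] = veps.epoch_window_ms[1]
        f.create_dataset("image_ids", data=np.array([str(i) for i in veps.image_ids], dtype="S"))
        if veps.trial_counts is not None:
            f.create_dataset("trial_counts", data=veps.trial_counts)


def load_veps(path: str) -> VEPTensor:
    with h5py.File(path, "r") as f:
        counts = f["trial_counts"][...] if "trial_counts" in f else None
        return VEPTensor(
            f["veps"][...],
            float(f.attrs["sample_rate"]),
            (float(f.attrs["pre_ms"]), float(f.attrs["post_ms"])),
            [s.decode() for s in f["image_ids"][...]],
            trial_counts=counts,
        )


def save_pc_series(path: str, series: PCSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("loadings", data=series.loadings, dtype="f8")
        f.create_dataset("var_explained", data=series.var_explained, dtype="f8")
        f.create_dataset("step_centers_ms", data=series.step_centers_ms)
        f.attrs["step_ms"] = series.step_ms
        f.attrs["half_window_ms"] = series.half_window_ms


def load_pc_series(path: str) -> PCSeries:
    with h5py.File(path, "r") as f:
        return PCSeries(
            loadings=f["loadings"][...],
            var_explained=f["var_explained"][...],
            step_centers_ms=f["step_centers_ms"][...],
            step_ms=float(f.attrs["step_ms"]),
            half_window_ms=float(f.attrs["half_window_ms"]),
        )


def save_tags(path: str, tags: np.ndarray, n_encoders: int, q: float, variant: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("tags", data=np.asarray(tags), dtype="u1")
        f.attrs["n_encoders"] = n_encoders
        f.attrs["q"] = q
        f.attrs["variant"] = variant


def load_tags(path: str) -> tuple[np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        meta = {
            "n_encoders": int(f.attrs["n_encoders"]),
            "q": float(f.attrs["q"]),
            "variant": str(f.attrs["variant"]),
        }
        return f["tags"][...].astype(np.int16), meta
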