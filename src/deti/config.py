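"""Frozen package-wide conventions and defaults.

The circular-window lattice convention was calibrated once against the
known visible-pixel count for a 512-px image with a 512-px diameter
window (206,643 pixels) and is frozen here; see ``WINDOW_CONVENTION``.
"""

# Circular window lattice convention (calibrated, do not change):
# pixel centers at integer coordinates, window center at
# ((N-1)/2 + center_offset, (N-1)/2 + center_offset), pixels included
# when distance < diameter/2 + radius_offset (strict interior).
WINDOW_CONVENTION = {
    "center_offset": 0.5,
    "radius_offset": 0.5,
    "inclusion_rule": "strict_interior",
}

#: RMS contrast target used for stimulus calibration.
DEFAULT_RMS_TARGET = 0.20

#: Mean pixel luminance (display units) restored after calibration.
DEFAULT_MEAN_LUMINANCE = 127.0

#: Degrees of visual angle subtended by one pixel.
DEFAULT_DEGREES_PER_PIXEL = 0.0382

#: Spatial-frequency encoder bank: peak (cpd) -> FWHH bandwidth (octaves).
DEFAULT_SF_BANK = {
    0.25: 2.3,
    0.50: 2.3,
    0.75: 2.0,
    1.00: 2.0,
    2.00: 1.75,
    4.00: 1.5,
    8.00: 1.0,
}

#: Orientation bank centers in degrees (8 orientations tiling 180 deg).
DEFAULT_ORIENTATION_CENTERS = tuple(22.5 * i for i in range(8))

#: Encoder peak-SF groups (cpd).  1 cpd belongs to neither group.
LSF_PEAKS = (0.25, 0.50, 0.75)
HSF_PEAKS = (2.0, 4.0, 8.0)

#: Radial-bin settings for the amplitude-spectrum slope estimate:
#: log-spaced bins over [2 cycles/image, 0.9 * Nyquist].
SLOPE_FIT = {"n_bins": 20, "f_min_cyc_per_image": 2.0, "nyquist_fraction": 0.9}

#: Zero-phase Butterworth orders used by the epoch preprocessor.
FILTER_DESIGN = {"highpass_order": 2, "lowpass_order": 4}

#: Relative log-power floor applied per encoder when building encoder space.
LOG_POWER_FLOOR_REL = 1e-12
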