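"""Two-regime telomere length quantification.

Telomere tracts above the optical resolution are measured from the spatial
extent of their red signal (pixels x kb-per-pixel); sub-resolution tracts,
down to ~100 bp, are measured from the integrated red fluorescence
intensity divided by the fitted per-kb yield.  Both conversion constants
are derived by least-squares regression through the origin on segments of
known length: zero telomere implies zero signal, and an additive offset
could produce negative lengths.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import yaml

from .errors import CalibrationError
from .simulate import RedSegment


@dataclasses.dataclass(frozen=True)
class QuantCalibration:
    """Fitted optical-stretch and fluorescence-yield constants.

    ``resolution_floor_kb`` is the extent below which the intensity regime
    is used.  Diagnostics carry the standard error of each slope and the
    number of calibration points.
    """

    kb_per_pixel: float
    intensity_per_kb: float
    resolution_floor_kb: float = 1.5
    kb_per_pixel_se: float = float("nan")
    intensity_per_kb_se: float = float("nan")
    n_points: int = 0

    def __post_init__(self):
        if self.kb_per_pixel <= 0 or self.intensity_per_kb <= 0:
            raise CalibrationError("calibration constants must be > 0")


class TelomereMeasurement(NamedTuple):
    kb: float
    mode: str  # "extent" or "intensity"
    qc_flags: tuple[str, ...] = ()


def _origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y = s*x through the origin, with its SE."""
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        raise CalibrationError("degenerate calibration abscissa")
    s = float(np.sum(x * y)) / sxx
    resid = y - s * x
    dof = max(x.size - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return s, se


def calibrate(
    red_segments_with_known_kb: Sequence[tuple[float, float, float]],
    resolution_floor_kb: float = 1.5,
) -> QuantCalibration:
    """Fit conversion constants from (extent_px, intensity, true_kb) points.

    Requires at least 10 points spanning at least one decade of true
    length.  The pixel slope is fitted on points whose true length exceeds
    the resolution floor (below it the extent is dominated by the point
    spread, not the tract).
    """
    pts = np.asarray(list(red_segments_with_known_kb), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 10 or pts.shape[1] != 3:
        raise CalibrationError("need at least 10 (extent_px, intensity, kb) points")
    extent_px, intensity, true_kb = pts.T
    if np.any(true_kb <= 0):
        raise CalibrationError("true lengths must be positive")
    if true_kb.max() / true_kb.min() < 10.0:
        raise CalibrationError(
            "calibration points must span at least one decade of true length"
        )
    above = true_kb >= resolution_floor_kb
    if np.count_nonzero(above) < 2:
        raise CalibrationError("no calibration points above the resolution floor")
    kbpp, kbpp_se = _origin_slope(extent_px[above], true_kb[above])
    ipk, ipk_se = _origin_slope(true_kb, intensity)
    return QuantCalibration(
        kb_per_pixel=kbpp,
        intensity_per_kb=ipk,
        resolution_floor_kb=resolution_floor_kb,
        kb_per_pixel_se=kbpp_se,
        intensity_per_kb_se=ipk_se,
        n_points=int(pts.shape[0]),
    )


def measure_px(extent_px: float, intensity: float,
               calib: QuantCalibration) -> TelomereMeasurement:
    """Length (kb) of a red segment given its raw pixel extent and intensity."""
    extent_kb = extent_px * calib.kb_per_pixel
    if extent_px >= calib.resolution_floor_kb / calib.kb_per_pixel:
        return TelomereMeasurement(max(extent_kb, 0.0), "extent")
    if intensity <= 0:
        return TelomereMeasurement(0.0, "intensity", ("zero_intensity",))
    return TelomereMeasurement(max(intensity / calib.intensity_per_kb, 0.0),
                               "intensity")


def measure_telomere(segment: RedSegment, calib: QuantCalibration,
                     px_scale_kb: float | None = None) -> TelomereMeasurement:
    """Measure a molecule's red segment.

    Molecule red segments are stored in kb under the nominal instrument
    stretch; ``px_scale_kb`` is that nominal kb-per-pixel (defaults to the
    calibrated value) and converts the stored extent back to pixels before
    the calibrated conversion is applied.
    """
    scale = px_scale_kb if px_scale_kb is not None else calib.kb_per_pixel
    extent_px = max(segment.end_kb - segment.start_kb, 0.0) / scale
    return measure_px(extent_px, segment.intensity, calib)


def write_calibration(calib: QuantCalibration, path) -> None:
    data = dataclasses.asdict(calib)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_calibration(path) -> QuantCalibration:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return QuantCalibration(**data)
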