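"""Arterial input function: LV detection, extraction, arrival, conditioning.

The AIF — contrast concentration over time in the LV blood pool (or aortic
root) — is the input of the convolution model that all quantification
rests on.  It is sampled either from a dedicated low-resolution short-TS
series (dual-sequence) or from a diluted pre-bolus acquisition
(dual-bolus); both paths end in a plasma-concentration curve on the
myocardial time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .preprocess import DynamicSeries
from .signal import QuantConfig

__all__ = [
    "ConcentrationCurve",
    "ArrivalEstimate",
    "detect_lv",
    "extract_aif",
    "detect_arrival",
    "to_plasma",
    "assemble_dual_bolus",
]


class AifError(ValueError):
    pass


@dataclass
class ConcentrationCurve:
    """Contrast concentration (or signal) versus time for blood or tissue."""

    times: np.ndarray  # s, ascending (may be non-uniform)
    values: np.ndarray  # mmol/L once converted, a.u. before
    role: Literal["aif_blood", "aif_plasma", "tissue"] = "aif_blood"
    arrival_index: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise AifError("times and values must be matching 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise AifError("times must be strictly ascending")
        if not np.all(np.isfinite(self.values)):
            raise AifError("curve values must be finite")

    def __len__(self) -> int:
        return self.times.size

    def crop(self, start: int, stop: int) -> "ConcentrationCurve":
        return replace(
            self,
            times=self.times[start:stop],
            values=self.values[start:stop],
            arrival_index=None,
        )


@dataclass(frozen=True)
class ArrivalEstimate:
    index: int
    time: float  # s
    method: Literal["triangle", "upslope_line"]
    confidence: float  # peak-to-baseline-noise ratio


def detect_lv(
    series: DynamicSeries,
    erosion_px: int = 1,
    sd_threshold: float | None = None,
) -> np.ndarray:
    """Locate the LV blood pool from the temporal dynamics of the series.

    A standard-deviation map of the SR signal-time curves highlights
    enhancing regions; connected candidates above an Otsu threshold are
    ranked by earliest arrival and peak amplitude (the LV enhances first
    and brightest, before the myocardium).  The winning region is eroded
    to exclude papillary muscles and partial-volume pixels at the
    endocardial border.
    """
    sr = series.sr_frames().frames
    sd_map = sr.std(axis=0)
    if np.ptp(sd_map) == 0:
        raise AifError("no LV candidate: series has no temporal dynamics")
    thr = threshold_otsu(sd_map) if sd_threshold is None else sd_threshold
    candidates = sd_map > thr
    if not candidates.any():
        raise AifError("no LV candidate above SD threshold")
    labels, n = ndimage.label(candidates)
    best_score, best = -np.inf, None
    for lab in range(1, n + 1):
        region = labels == lab
        if region.sum() < 4:
            continue
        curve = sr[:, region].mean(axis=1)
        peak = float(curve.max())
        if peak <= 0:
            continue
        # earlier half-peak crossing and higher amplitude both score up
        above = np.flatnonzero(curve >= 0.5 * peak)
        t_half = int(above[0]) if above.size else sr.shape[0]
        score = peak / (1.0 + t_half)
        if score > best_score:
            best_score, best = score, region
    if best is None:
        raise AifError("no LV candidate of sufficient size")
    eroded = ndimage.binary_erosion(best, iterations=erosion_px)
    if not eroded.any():
        raise AifError("LV candidate vanished under erosion")
    return eroded


def extract_aif(
    series: DynamicSeries,
    mask: np.ndarray,
    contamination_check: bool = True,
    contamination_spread: float = 3.0,
) -> tuple[ConcentrationCurve, dict]:
    """Mean signal over the blood-pool mask, per SR frame.

    PD frames are excluded from the curve (they feed the conversion
    upstream).  A simple contamination detector compares per-pixel curves
    inside the mask with the mask-mean curve: low median correlation or a
    wide spread of peak times indicates that non-blood tissue (e.g.
    myocardium) leaked into the mask.  Returns the curve and a QC dict.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise AifError("empty AIF mask")
    sr = series.sr_frames()
    pix = sr.frames[:, mask]  # (T, n_pix)
    curve = pix.mean(axis=1)
    qc: dict = {"n_pixels": int(mask.sum()), "contaminated": False}
    if contamination_check and mask.sum() >= 3 and np.ptp(curve) > 0:
        peak_times = pix.argmax(axis=0)
        spread = float(np.percentile(peak_times, 90) - np.percentile(peak_times, 10))
        qc["peak_time_spread"] = spread
        # blood-pool pixels peak together; tissue admixture delays a tail
        if spread > contamination_spread:
            qc["contaminated"] = True
    return (
        ConcentrationCurve(times=sr.sr_times_s(), values=curve, role="aif_blood"),
        qc,
    )


def _triangle_foot(values: np.ndarray, peak: int) -> int:
    """Point of maximal perpendicular distance from the chord to the curve.

    The chord runs from the first sample to the peak; the foot of the
    upslope is the sample below the chord that is farthest from it.
    """
    x = np.arange(peak + 1, dtype=float)
    y = values[: peak + 1]
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return 0
    # signed distance; the pre-bolus foot lies below the chord
    dist = (dy * (x - x[0]) - dx * (y - y[0])) / norm
    return int(np.argmax(dist))


def detect_arrival(
    curve: ConcentrationCurve,
    method: Literal["triangle", "upslope_line"] = "triangle",
    min_peak_snr: float = 3.0,
) -> ArrivalEstimate:
    """Detect the tracer arrival (foot of the upslope) on a curve.

    ``triangle``: maximal perpendicular distance from the first-sample-to-
    peak chord to the curve marks the foot.  ``upslope_line``: a line is
    fitted to the steep upslope segment (20-80% of peak) and intersected
    with zero.  Both return the index of the first sample at or after the
    foot.  The curve must be baseline-corrected.
    """
    v = curve.values
    if v.size < 5:
        raise AifError("need at least 5 samples for arrival detection")
    peak = int(np.argmax(v))
    baseline_sd = float(np.std(v[: max(2, peak // 3)])) if peak >= 2 else float(np.std(v))
    peak_val = float(v[peak])
    if peak_val <= 0 or peak_val < min_peak_snr * max(baseline_sd, 1e-12) or peak == 0:
        raise AifError("no bolus detected: curve is flat or too noisy")

    if method == "triangle":
        idx = _triangle_foot(v, peak)
        # foot marks the last pre-bolus sample; arrival is at/after it
        while idx < peak and v[idx] <= 0:
            idx += 1
    elif method == "upslope_line":
        # fit the line over samples bracketing the 20-80% band of the
        # upslope (the band itself may hold < 2 samples at RR sampling)
        lo, hi = 0.2 * peak_val, 0.8 * peak_val
        below = np.flatnonzero(v[:peak] <= lo)
        i_lo = int(below[-1]) if below.size else 0
        above = np.flatnonzero(v[: peak + 1] >= hi)
        i_hi = int(above[0]) if above.size else peak
        if i_hi <= i_lo:
            i_hi = min(i_lo + 1, peak)
        seg = np.arange(i_lo, i_hi + 1)
        slope, intercept = np.polyfit(curve.times[seg], v[seg], 1)
        if slope <= 0:
            raise AifError("no bolus detected: non-positive upslope")
        t0 = -intercept / slope
        # first sample strictly after the zero crossing (the foot itself
        # is the last pre-contrast instant)
        idx = int(np.searchsorted(curve.times, t0, side="right"))
    else:
        raise AifError(f"unknown arrival method {method!r}")
    idx = int(np.clip(idx, 0, v.size - 1))
    conf = peak_val / max(baseline_sd, 1e-12)
    return ArrivalEstimate(
        index=idx, time=float(curve.times[idx]), method=method, confidence=conf
    )


def to_plasma(curve: ConcentrationCurve, config: QuantConfig) -> ConcentrationCurve:
    """Blood-to-plasma conversion: divide by (1 - hematocrit)."""
    if curve.role != "aif_blood":
        raise AifError(f"expected an aif_blood curve, got role {curve.role!r}")
    return replace(
        curve, values=curve.values / (1.0 - config.hematocrit), role="aif_plasma"
    )


def assemble_dual_bolus(
    prebolus_aif: ConcentrationCurve,
    main_lv_curve: ConcentrationCurve,
    dilution: float = 0.10,
) -> ConcentrationCurve:
    """Build a quantification AIF from a diluted pre-bolus acquisition.

    The pre-bolus AIF (acquired with the same sequence, so free of
    saturation) is scaled by ``1/dilution`` and time-shifted so that its
    arrival coincides with the main-bolus arrival seen in the LV signal of
    the myocardial series.  The result is resampled onto the main study's
    time grid.
    """
    if not 0.0 < dilution < 1.0:
        raise AifError("dilution must be in (0, 1) exclusive")
    pre_arr = detect_arrival(prebolus_aif)
    main_arr = detect_arrival(main_lv_curve)
    dt = main_lv_curve.times[main_arr.index] - prebolus_aif.times[pre_arr.index]
    shifted_times = prebolus_aif.times + dt
    values = np.interp(
        main_lv_curve.times, shifted_times, prebolus_aif.values / dilution,
        left=0.0, right=prebolus_aif.values[-1] / dilution,
    )
    return ConcentrationCurve(
        times=main_lv_curve.times.copy(),
        values=values,
        role=prebolus_aif.role,
        arrival_index=main_arr.index,
    )
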