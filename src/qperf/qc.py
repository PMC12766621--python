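"""Quality control of perfusion studies, curves and maps.

Each check mirrors one item of the review checklist a reader would apply
manually: RR regularity, AIF shape and SNR, baseline enhancement,
residual motion, map/raw shape agreement and per-segment fit failures.
Every flag carries the frame/pixel locus and the rule that raised it, so
the report is reviewable.  The numeric thresholds are configuration
values (logged in the report), not clinical constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .aif import ConcentrationCurve

__all__ = ["QCFlag", "QCThresholds", "QCReport", "rr_check", "aif_qc", "study_qc"]


@dataclass(frozen=True)
class QCFlag:
    rule: str
    locus: str  # e.g. "frame 12", "segment 3", "curve"
    critical: bool = False
    detail: str = ""


@dataclass(frozen=True)
class QCThresholds:
    """Tunable QC thresholds; defaults are pipeline choices, logged in reports."""

    rr_missed_factor: float = 1.75  # interval > factor x running median
    aif_flat_top_tol: float = 0.01  # samples within 1% of peak count as flat
    aif_flat_top_run: int = 3  # consecutive flat samples -> saturation
    aif_min_snr: float = 10.0  # peak / baseline SD
    residual_motion_px: float = 1.0  # max post-registration displacement
    baseline_enhancement_ratio: float = 1.3  # LV/myo pre-contrast ratio
    segment_failure_fraction: float = 0.20  # failed pixels -> exclude segment
    wall_thickness_rel_tol: float = 0.35


@dataclass
class QCReport:
    rr_flags: list[QCFlag] = field(default_factory=list)
    aif_metrics: dict = field(default_factory=dict)
    aif_flags: list[QCFlag] = field(default_factory=list)
    image_flags: list[QCFlag] = field(default_factory=list)
    map_flags: list[QCFlag] = field(default_factory=list)
    segment_exclusions: list[int] = field(default_factory=list)
    unverifiable: list[str] = field(default_factory=list)
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def all_flags(self) -> list[QCFlag]:
        return self.rr_flags + self.aif_flags + self.image_flags + self.map_flags

    @property
    def overall(self) -> str:
        if any(f.critical for f in self.all_flags):
            return "fail"
        if self.all_flags or self.segment_exclusions:
            return "review"
        return "pass"

    def to_json(self) -> str:
        d = asdict(self)
        d["overall"] = self.overall
        return json.dumps(d, indent=2, default=str)

    def to_text(self) -> str:
        lines = [f"QC report: {self.overall.upper()}"]
        for group, flags in (
            ("RR", self.rr_flags),
            ("AIF", self.aif_flags),
            ("images", self.image_flags),
            ("maps", self.map_flags),
        ):
            for f in flags:
                crit = " [CRITICAL]" if f.critical else ""
                lines.append(f"  {group}: {f.rule} @ {f.locus}{crit} {f.detail}")
        if self.segment_exclusions:
            lines.append(f"  segments excluded: {self.segment_exclusions}")
        for item in self.unverifiable:
            lines.append(f"  unverifiable: {item}")
        if len(lines) == 1:
            lines.append("  no flags")
        return "\n".join(lines)


def rr_check(
    trigger_times: Sequence[float],
    upslope_window: tuple[float, float] | None = None,
    thresholds: QCThresholds | None = None,
) -> list[QCFlag]:
    """Flag missed/irregular beats from the trigger-time sequence.

    An RR interval exceeding ``rr_missed_factor`` times the running
    median is a missed beat; it is critical when it falls inside the
    supplied upslope window (ms) of the AIF or myocardial curve, where a
    missing sample corrupts quantification.
    """
    th = thresholds or QCThresholds()
    t = np.asarray(trigger_times, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 trigger times")
    rr = np.diff(t)
    flags: list[QCFlag] = []
    for i, interval in enumerate(rr):
        lo = max(0, i - 5)
        window = np.concatenate([rr[lo:i], rr[i + 1 : i + 6]])
        med = float(np.median(window)) if window.size else float(np.median(rr))
        if interval > th.rr_missed_factor * med:
            critical = False
            if upslope_window is not None:
                critical = upslope_window[0] <= t[i + 1] <= upslope_window[1]
            flags.append(
                QCFlag(
                    rule="missed beat",
                    locus=f"frame {i + 1}",
                    critical=critical,
                    detail=f"RR {interval:.0f} ms vs median {med:.0f} ms",
                )
            )
    return flags


def aif_qc(
    curve: ConcentrationCurve, thresholds: QCThresholds | None = None
) -> tuple[dict, list[QCFlag]]:
    """AIF shape metrics: smoothness, flat-top saturation, SNR.

    The AIF should be a single peaked curve without apparent saturation;
    smoothness is 1 minus the fraction of total variation left in the
    residual after a quadratic Savitzky-Golay filter, which preserves a
    genuine bolus peak while isolating sample-to-sample noise (a smooth
    curve scores near 1).  A run of near-peak samples within
    ``aif_flat_top_tol`` of the peak marks saturation; peak-to-
    baseline-SD below ``aif_min_snr`` marks low SNR.
    """
    th = thresholds or QCThresholds()
    v = curve.values
    flags: list[QCFlag] = []
    peak_idx = int(np.argmax(v))
    peak = float(v[peak_idx])
    n_base = max(3, peak_idx // 3)
    baseline_sd = float(np.std(v[:n_base])) if peak_idx >= 3 else float(np.std(v))

    from scipy.signal import savgol_filter

    window = min(7, v.size if v.size % 2 else v.size - 1)
    smooth = savgol_filter(v, window, polyorder=4) if window >= 7 else v
    tv_total = float(np.abs(np.diff(v)).sum())
    tv_resid = float(np.abs(np.diff(v - smooth)).sum())
    smoothness = 1.0 - tv_resid / tv_total if tv_total > 0 else 1.0

    near_peak = v >= (1.0 - th.aif_flat_top_tol) * peak
    run = max_run = 0
    for flag in near_peak:
        run = run + 1 if flag else 0
        max_run = max(max_run, run)
    saturated = max_run >= th.aif_flat_top_run
    snr = peak / baseline_sd if baseline_sd > 0 else float("inf")

    if saturated:
        flags.append(
            QCFlag(
                rule="AIF saturation (flat top)",
                locus=f"frames near {peak_idx}",
                critical=True,
                detail=f"{max_run} samples within {th.aif_flat_top_tol:.0%} of peak",
            )
        )
    if snr < th.aif_min_snr:
        flags.append(
            QCFlag(rule="low AIF SNR", locus="curve", detail=f"SNR {snr:.1f}")
        )
    metrics = {
        "peak": peak,
        "peak_index": peak_idx,
        "peak_to_baseline_sd": snr,
        "smoothness": smoothness,
        "saturation": saturated,
    }
    return metrics, flags


def study_qc(
    *,
    trigger_times: Sequence[float] | None = None,
    aif_curve: ConcentrationCurve | None = None,
    aif_upslope_ms: tuple[float, float] | None = None,
    pre_contrast_frames: np.ndarray | None = None,  # (n, H, W) SR baseline frames
    lv_mask: np.ndarray | None = None,
    myo_mask: np.ndarray | None = None,
    residual_displacements: np.ndarray | None = None,  # (T, 2) px
    parameter_map=None,
    segments=None,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Assemble the full QC report from whichever pipeline outputs exist.

    Checks: RR regularity; AIF shape; baseline blood-pool enhancement
    (remnant contrast from a previous injection); residual post-
    registration motion; map-vs-mask wall-thickness agreement; and
    per-segment fit-failure fractions (segments above the threshold are
    marked for exclusion).  Missing inputs yield 'unverifiable' entries,
    not errors.
    """
    th = thresholds or QCThresholds()
    report = QCReport(thresholds=th)

    if trigger_times is not None:
        report.rr_flags = rr_check(trigger_times, aif_upslope_ms, th)
    else:
        report.unverifiable.append("RR intervals")

    if aif_curve is not None:
        report.aif_metrics, report.aif_flags = aif_qc(aif_curve, th)
    else:
        report.unverifiable.append("AIF curve")

    if pre_contrast_frames is not None and lv_mask is not None and myo_mask is not None:
        base = np.asarray(pre_contrast_frames, dtype=float).mean(axis=0)
        lv_mean = float(base[lv_mask].mean())
        myo_mean = float(base[myo_mask].mean())
        if myo_mean > 0 and lv_mean / myo_mean > th.baseline_enhancement_ratio:
            report.image_flags.append(
                QCFlag(
                    rule="baseline blood-pool enhancement (remnant contrast)",
                    locus="pre-contrast frames",
                    detail=f"LV/myo ratio {lv_mean / myo_mean:.2f}",
                )
            )
    else:
        report.unverifiable.append("baseline enhancement")

    if residual_displacements is not None:
        disp = np.linalg.norm(np.asarray(residual_displacements, float), axis=1)
        worst = int(np.argmax(disp))
        if disp[worst] > th.residual_motion_px:
            report.image_flags.append(
                QCFlag(
                    rule="residual motion",
                    locus=f"frame {worst}",
                    detail=f"{disp[worst]:.2f} px after registration",
                )
            )
    else:
        report.unverifiable.append("residual motion")

    if parameter_map is not None:
        failed = parameter_map.qc_flags.get("failed")
        if myo_mask is not None:
            map_valid = parameter_map.mask & np.isfinite(parameter_map.mbf)
            t_map = _mean_thickness(map_valid)
            t_raw = _mean_thickness(myo_mask)
            if t_raw > 0 and abs(t_map - t_raw) / t_raw > th.wall_thickness_rel_tol:
                report.map_flags.append(
                    QCFlag(
                        rule="map/raw wall-thickness mismatch",
                        locus="map",
                        detail=f"map {t_map:.1f} px vs raw {t_raw:.1f} px",
                    )
                )
        if failed is not None and segments is not None:
            seg_list = segments if isinstance(segments, (list, tuple)) else [segments]
            for seg in seg_list:
                for sid in seg.segment_ids:
                    sel = (seg.labels == sid) & parameter_map.mask
                    if sel.any() and failed[sel].mean() > th.segment_failure_fraction:
                        report.segment_exclusions.append(int(sid))
                        report.map_flags.append(
                            QCFlag(
                                rule="segment fit-failure fraction",
                                locus=f"segment {sid}",
                                detail=f"{failed[sel].mean():.0%} failed pixels",
                            )
                        )
    else:
        report.unverifiable.append("parameter map")

    return report


def _mean_thickness(mask: np.ndarray) -> float:
    """Mean radial thickness (px) of an annular mask, via area/perimeter midline."""
    if not mask.any():
        return 0.0
    # distance transform peaks at half thickness along the midline
    dist = ndimage.distance_transform_edt(mask)
    return float(2.0 * dist[mask].mean())
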