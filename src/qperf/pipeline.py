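"""End-to-end orchestration: images -> concentration -> AIF -> maps -> QC.

The stage order is register -> coil-correct -> convert to concentration
-> baseline-correct -> AIF extraction -> pixel-wise kinetic fitting ->
maps and QC.  Every stage's parameters are logged in the result, and a
fixed seed makes the whole run reproducible (the pipeline itself is
deterministic; randomness only enters through the phantom).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import __version__
from .aif import ConcentrationCurve, detect_arrival, detect_lv, to_plasma
from .kinetics import KineticsError
from .maps import ParameterMap, SegmentModel, aha16_segment, compute_mpr, quantify_pixelwise
from .phantom import StudyBundle
from .preprocess import DynamicSeries, baseline_correct, coil_correct, register_translation
from .qc import QCReport, QCThresholds, study_qc
from .signal import QuantConfig, build_dictionary, si_to_concentration


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineResult:
    aif_blood: ConcentrationCurve
    aif_plasma: ConcentrationCurve
    times: np.ndarray  # s, SR frames
    conc_slices: list[np.ndarray]  # converted, baseline-corrected stacks
    masks: list[np.ndarray]
    maps: list[ParameterMap]
    segments: list[SegmentModel]
    qc: QCReport
    log: dict = field(default_factory=dict)


def _convert_series(
    series: DynamicSeries,
    config: QuantConfig,
    register: bool,
) -> tuple[np.ndarray, DynamicSeries, np.ndarray, np.ndarray]:
    """register -> coil QC field -> concentration stack (not yet baselined)."""
    displacements = np.zeros((series.n_frames, 2))
    if register:
        reg = register_translation(series)
        series = reg.corrected
        displacements = reg.displacements
    _, bias = coil_correct(series, method="pixelwise")
    pd_ref = series.pd_frames().mean(axis=0)
    dictionary = build_dictionary(series.seq)
    conc, clamped = si_to_concentration(series, pd_ref, config, dictionary)
    return conc, series, displacements, clamped


def run_pipeline(
    study: StudyBundle,
    model: Literal["fermi", "2cxm", "patlak", "tikhonov"] = "fermi",
    config: QuantConfig | None = None,
    slices: Sequence[int] | None = None,
    register: bool = True,
    max_delay_samples: int = 3,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
    **fit_kw,
) -> PipelineResult:
    """Run the full quantification pipeline on one (stress or rest) study.

    Myocardial masks come from the study's ground truth when present
    (phantom studies); otherwise a crude enhancement-based annulus is
    derived and flagged as approximate.
    """
    config = config or study.config or QuantConfig()
    slices = list(range(len(study.myocardial_series))) if slices is None else list(slices)
    log: dict = {
        "version": __version__,
        "model": model,
        "seed": seed,
        "register": register,
        "slices": slices,
    }

    # ---- AIF branch (dual-sequence low-resolution series) -------------
    aif_series = study.aif_series
    aif_conc, aif_series_reg, aif_disp, aif_clamped = _convert_series(
        aif_series, config, register
    )
    lv_mask = detect_lv(aif_series_reg)
    curve_vals = aif_conc[:, lv_mask].mean(axis=1)
    times = aif_series_reg.sr_times_s()
    prov = curve_vals - curve_vals[:3].mean()
    arrival = detect_arrival(
        ConcentrationCurve(times=times, values=prov, role="aif_blood")
    )
    pre = list(range(max(arrival.index - 1, 1)))
    aif_blood = ConcentrationCurve(
        times=times,
        values=np.asarray(baseline_correct(curve_vals, pre)),
        role="aif_blood",
        arrival_index=arrival.index,
    )
    aif_plasma = to_plasma(aif_blood, config)
    aif_plasma.arrival_index = arrival.index
    log["aif"] = {"arrival_index": arrival.index, "n_lv_pixels": int(lv_mask.sum())}

    # ---- myocardial slices --------------------------------------------
    conc_slices, masks, pmaps, segments = [], [], [], []
    residual_disp = None
    levels = {0: "base", 1: "mid"}
    gt = study.ground_truth
    for s in slices:
        series = study.myocardial_series[s]
        conc, series_reg, disp, clamped = _convert_series(series, config, register)
        conc = np.asarray(baseline_correct(conc, pre))
        if gt and "slice_truth" in gt:
            mask = gt["slice_truth"][s]["myo"]
            approx_mask = False
        elif gt and "myo_mask" in gt and s == 0:
            mask = gt["myo_mask"]
            approx_mask = False
        else:
            mask = _auto_myo_mask(conc)
            approx_mask = True
        pmap = quantify_pixelwise(
            conc,
            times,
            mask,
            aif_plasma,
            model=model,
            config=config,
            max_delay_samples=max_delay_samples,
            **fit_kw,
        )
        pmap.qc_flags["approximate_mask"] = approx_mask
        pmap.qc_flags["si_clamped_pixels"] = int(np.asarray(clamped).sum())
        level = levels.get(s, "apex" if s == len(study.myocardial_series) - 1 else "mid")
        center = _mask_center(mask)
        rv = (center[0] - 1.5 * _mask_radius(mask), center[1])
        segments.append(aha16_segment(mask, center, rv, level))
        conc_slices.append(conc)
        masks.append(mask)
        pmaps.append(pmap)
        if s == slices[0]:
            residual_disp = disp if not register else np.zeros_like(disp)

    # ---- QC -------------------------------------------------------------
    first = study.myocardial_series[slices[0]]
    sr_idx = first.sr_indices
    n_pre = max(len(pre), 1)
    upslope_ms = (
        first.trigger_times[sr_idx[arrival.index]],
        first.trigger_times[sr_idx[min(int(np.argmax(aif_blood.values)), len(sr_idx) - 1)]],
    )
    qc = study_qc(
        trigger_times=first.trigger_times,
        aif_curve=aif_blood,
        aif_upslope_ms=upslope_ms,
        pre_contrast_frames=conc_slices[0][:n_pre] if conc_slices else None,
        lv_mask=_downproject(gt, "lv_mask", masks[0].shape) if gt else None,
        myo_mask=masks[0],
        residual_displacements=residual_disp,
        parameter_map=pmaps[0],
        segments=segments[0],
        thresholds=thresholds,
    )
    return PipelineResult(
        aif_blood=aif_blood,
        aif_plasma=aif_plasma,
        times=times,
        conc_slices=conc_slices,
        masks=masks,
        maps=pmaps,
        segments=segments,
        qc=qc,
        log=log,
    )


def _downproject(gt: dict, key: str, shape) -> np.ndarray | None:
    m = gt.get(key)
    if m is None or m.shape != tuple(shape):
        slice_truth = gt.get("slice_truth")
        if slice_truth:
            return slice_truth[0]["lv"]
        return None
    return m


def _mask_center(mask: np.ndarray) -> tuple[float, float]:
    idx = np.nonzero(mask)
    return float(idx[0].mean()), float(idx[1].mean())


def _mask_radius(mask: np.ndarray) -> float:
    c = _mask_center(mask)
    idx = np.nonzero(mask)
    return float(np.hypot(idx[0] - c[0], idx[1] - c[1]).mean())


def _auto_myo_mask(conc: np.ndarray) -> np.ndarray:
    """Crude enhancement-based annulus when no segmentation is supplied."""
    from scipy import ndimage
    from skimage.filters import threshold_otsu

    peak = conc.max(axis=0)
    finite = np.isfinite(peak)
    if not finite.any():
        raise PipelineError("no finite concentration values for auto-masking")
    vals = peak[finite]
    thr = threshold_otsu(vals) if np.ptp(vals) > 0 else 0.0
    bright = np.where(finite, peak, 0.0) > thr  # LV and strongly enhancing
    labels, n = ndimage.label(bright)
    if n == 0:
        raise PipelineError("auto myocardial mask failed: no enhancement")
    sizes = ndimage.sum(bright, labels, range(1, n + 1))
    lv = labels == (1 + int(np.argmax(sizes)))
    ring = ndimage.binary_dilation(lv, iterations=6) & ~ndimage.binary_dilation(
        lv, iterations=2
    )
    moderate = np.where(finite, peak, 0.0) > 0.05 * vals.max()
    return ring & moderate


def run_stress_rest(
    stress: StudyBundle,
    rest: StudyBundle,
    rest_floor: float = 0.1,
    **kw,
) -> tuple[PipelineResult, PipelineResult, list[ParameterMap]]:
    """Quantify a stress/rest pair and derive pixel-wise MPR maps."""
    res_stress = run_pipeline(stress, **kw)
    res_rest = run_pipeline(rest, **kw)
    mpr_maps = [
        compute_mpr(s, r, rest_floor=rest_floor)
        for s, r in zip(res_stress.maps, res_rest.maps)
    ]
    return res_stress, res_rest, mpr_maps


def run_from_config(cfg: dict, out_dir: str | Path) -> PipelineResult:
    """Config-driven entry point used by the command line.

    Config keys: ``input`` (path), ``format`` (``dicom``/``archive``),
    ``acquisition`` (must be 2d), ``model``, ``seed``, ``slices``,
    ``register``.  Outputs (maps, bullseye CSV, QC JSON, log) are written
    under ``out_dir``.
    """
    import json

    import pandas as pd

    if cfg.get("acquisition", "2d").lower() != "2d":
        raise PipelineError(
            "unsupported input: only 2D multi-slice acquisitions are supported"
        )
    from .io import load_archive, read_study

    fmt = cfg.get("format", "archive")
    if fmt == "archive":
        study = load_archive(cfg["input"])
    elif fmt == "dicom":
        study = read_study(cfg["input"])
    else:
        raise PipelineError(f"unknown input format {fmt!r}")

    result = run_pipeline(
        study,
        model=cfg.get("model", "fermi"),
        slices=cfg.get("slices"),
        register=bool(cfg.get("register", True)),
        seed=int(cfg.get("seed", 0)),
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, pmap in enumerate(result.maps):
        np.save(out / f"mbf_slice{i}.npy", pmap.mbf)
        np.save(out / f"arrival_slice{i}.npy", pmap.arrival)
    rows = []
    for seg, pmap in zip(result.segments, result.maps):
        for sid in seg.segment_ids:
            sel = (seg.labels == sid) & pmap.mask
            vals = pmap.mbf[sel]
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "segment": int(sid),
                    "level": seg.level,
                    "mean_mbf": float(vals.mean()) if vals.size else np.nan,
                    "n_pixels": int(sel.sum()),
                    "excluded": int(sid) in result.qc.segment_exclusions,
                }
            )
    pd.DataFrame(rows).to_csv(out / "bullseye.csv", index=False)
    (out / "qc.json").write_text(result.qc.to_json())
    (out / "log.json").write_text(json.dumps(result.log, indent=2, default=str))
    return result
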