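"""Reading and writing perfusion studies: DICOM series and phantom archives.

Studies travel as one DICOM file per frame with the sequence parameters
needed for Bloch-based conversion (TS, TD, lines to k-space centre,
saturation efficiency, frame role) carried in a documented private block,
since they have no standard DICOM fields.  The phantom additionally
writes a self-describing archive (arrays + JSON sidecar) that preserves
ground truth losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .phantom import StudyBundle
from .preprocess import DynamicSeries
from .signal import SequenceParams

__all__ = [
    "PrivateTagMap",
    "write_study",
    "read_study",
    "save_archive",
    "load_archive",
    "write_parameter_map_dicom",
]


class StudyIOError(ValueError):
    pass


_PRIVATE_FIELDS = {
    "TS": 0x01,
    "TD": 0x02,
    "lines_to_center": 0x03,
    "frame_role": 0x04,
    "saturation_efficiency": 0x05,
    "series_role": 0x06,
    "pd_flip_angle": 0x07,
    "agent_name": 0x08,
    "acquisition_window": 0x09,
    "readout": 0x0A,
}


@dataclass(frozen=True)
class PrivateTagMap:
    """Where each non-standard sequence parameter lives in the DICOM header.

    ``elements`` maps field names to byte offsets inside the private
    block owned by ``creator`` in ``group``; vendor dialects are handled
    by supplying a different map.  Standard parameters (flip angle, TR,
    TE, trigger time, pixel spacing) always use their standard tags.
    """

    creator: str = "QPERF"
    group: int = 0x0011
    elements: dict = field(default_factory=lambda: dict(_PRIVATE_FIELDS))


def _quantize(frame: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo = float(frame.min())
    hi = float(frame.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    q = np.round((frame - lo) / slope).astype(np.uint16)
    return q, slope, lo


def _frame_dataset(
    frame: np.ndarray,
    series: DynamicSeries,
    index: int,
    series_number: int,
    tagmap: PrivateTagMap,
    study_uid: str,
    series_uid: str,
) -> pydicom.dataset.FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.dataset.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "MR"
    ds.SeriesNumber = series_number
    ds.InstanceNumber = index + 1
    ds.SeriesDescription = f"qperf {series.seq.role}"
    ds.Rows, ds.Columns = frame.shape
    ds.PixelSpacing = [str(series.pixel_spacing[0]), str(series.pixel_spacing[1])]
    ds.SliceLocation = str(series.slice_location)
    ds.SliceThickness = "8"
    ds.TriggerTime = f"{series.trigger_times[index]:.6g}"
    ds.FlipAngle = f"{series.seq.flip_angle:.6g}"
    ds.RepetitionTime = f"{series.seq.TR:.6g}"
    te = series.seq.TE if np.isscalar(series.seq.TE) else series.seq.TE[0]
    ds.EchoTime = f"{te:.6g}"

    q, slope, intercept = _quantize(frame)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = f"{intercept:.10g}"
    ds.PixelData = q.tobytes()

    block = ds.private_block(tagmap.group, tagmap.creator, create=True)
    e = tagmap.elements
    block.add_new(e["TS"], "DS", f"{series.seq.TS:.6g}")
    block.add_new(e["TD"], "DS", f"{series.seq.TD:.6g}")
    block.add_new(e["lines_to_center"], "IS", str(series.seq.lines_to_center))
    block.add_new(e["frame_role"], "CS", series.frame_roles[index])
    block.add_new(
        e["saturation_efficiency"], "DS", f"{series.seq.saturation_efficiency:.6g}"
    )
    block.add_new(e["series_role"], "LO", series.seq.role)
    block.add_new(e["pd_flip_angle"], "DS", f"{series.seq.pd_flip_angle:.6g}")
    block.add_new(e["acquisition_window"], "DS", f"{series.seq.acquisition_window:.6g}")
    block.add_new(e["readout"], "LO", series.seq.readout)
    return ds


def write_study(
    bundle: StudyBundle, path: str | Path, tagmap: PrivateTagMap | None = None
) -> Path:
    """Write a study as per-frame DICOM files under ``path``."""
    tagmap = tagmap or PrivateTagMap()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid(entropy_srcs=["qperf-study"])
    all_series = list(bundle.myocardial_series) + [bundle.aif_series]
    for s_num, series in enumerate(all_series, start=1):
        series_uid = generate_uid(entropy_srcs=[f"qperf-series-{s_num}"])
        for i in range(series.n_frames):
            ds = _frame_dataset(
                series.frames[i], series, i, s_num, tagmap, study_uid, series_uid
            )
            ds.save_as(path / f"series{s_num:02d}_frame{i:03d}.dcm",
                       enforce_file_format=True)
    (path / "condition.json").write_text(json.dumps({"condition": bundle.condition}))
    return path


def _seq_from_dataset(ds: Dataset, tagmap: PrivateTagMap) -> tuple[SequenceParams, str]:
    try:
        block = ds.private_block(tagmap.group, tagmap.creator)
    except KeyError as exc:
        raise StudyIOError(
            f"private block {tagmap.creator!r} in group {tagmap.group:#06x} missing"
        ) from exc
    e = tagmap.elements

    def need(name, tag_offset, cast=float):
        if tag_offset not in block:
            raise StudyIOError(
                f"required parameter {name!r} missing "
                f"(private tag ({tagmap.group:#06x}, xx{tag_offset:02X}))"
            )
        return cast(block[tag_offset].value)

    for std in ("FlipAngle", "RepetitionTime", "EchoTime", "TriggerTime"):
        if std not in ds:
            raise StudyIOError(f"required standard field {std} missing")
    role = need("series_role", e["series_role"], str)
    seq = SequenceParams(
        flip_angle=float(ds.FlipAngle),
        TR=float(ds.RepetitionTime),
        TE=float(ds.EchoTime),
        TS=need("TS", e["TS"]),
        TD=need("TD", e["TD"]),
        lines_to_center=need("lines_to_center", e["lines_to_center"], int),
        readout=need("readout", e["readout"], str),
        acquisition_window=need("acquisition_window", e["acquisition_window"]),
        role=role,
        saturation_efficiency=need(
            "saturation_efficiency", e["saturation_efficiency"]
        ),
        pd_flip_angle=need("pd_flip_angle", e["pd_flip_angle"]),
    )
    frame_role = need("frame_role", e["frame_role"], str)
    return seq, frame_role


def read_study(path: str | Path, tagmap: PrivateTagMap | None = None) -> StudyBundle:
    """Read a per-frame DICOM study directory back into a StudyBundle.

    Files are grouped by series and time-ordered by trigger time, so the
    on-disk file order is irrelevant.  PD frames are identified by the
    explicit frame-role tag.  Any required parameter that cannot be
    resolved raises an error naming the field and tag.
    """
    tagmap = tagmap or PrivateTagMap()
    path = Path(path)
    files = sorted(path.glob("*.dcm"))
    if not files:
        raise StudyIOError(f"no DICOM files under {path}")
    by_series: dict[int, list] = {}
    for f in files:
        ds = pydicom.dcmread(f)
        by_series.setdefault(int(ds.SeriesNumber), []).append(ds)

    myo, aif = [], None
    for s_num in sorted(by_series):
        datasets = by_series[s_num]
        order = np.argsort([float(d.TriggerTime) for d in datasets])
        datasets = [datasets[i] for i in order]
        seq, _ = _seq_from_dataset(datasets[0], tagmap)
        frames, triggers, roles = [], [], []
        for d in datasets:
            _, frame_role = _seq_from_dataset(d, tagmap)
            arr = d.pixel_array.astype(float)
            arr = arr * float(d.RescaleSlope) + float(d.RescaleIntercept)
            frames.append(arr)
            triggers.append(float(d.TriggerTime))
            roles.append(frame_role)
        series = DynamicSeries(
            frames=np.stack(frames),
            trigger_times=np.asarray(triggers),
            frame_roles=tuple(roles),
            seq=seq,
            pixel_spacing=(
                float(datasets[0].PixelSpacing[0]),
                float(datasets[0].PixelSpacing[1]),
            ),
            slice_location=float(datasets[0].SliceLocation),
        )
        if seq.role == "AIF":
            aif = series
        else:
            myo.append(series)
    if aif is None:
        raise StudyIOError("study has no AIF series")
    condition = "rest"
    cond_file = path / "condition.json"
    if cond_file.exists():
        condition = json.loads(cond_file.read_text()).get("condition", "rest")
    return StudyBundle(
        myocardial_series=myo, aif_series=aif, ground_truth={}, condition=condition
    )


# ---------------------------------------------------------------------------
# lossless phantom archive (arrays + JSON sidecar)
# ---------------------------------------------------------------------------

def _seq_to_dict(seq: SequenceParams) -> dict:
    d = asdict(seq)
    if isinstance(d["TE"], tuple):
        d["TE"] = list(d["TE"])
    return d


def save_archive(bundle: StudyBundle, path: str | Path) -> Path:
    """Self-describing archive: npz arrays plus a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    meta: dict = {"condition": bundle.condition, "series": []}
    for i, s in enumerate(list(bundle.myocardial_series) + [bundle.aif_series]):
        key = f"series{i}"
        arrays[f"{key}_frames"] = s.frames
        arrays[f"{key}_triggers"] = s.trigger_times
        meta["series"].append(
            {
                "key": key,
                "roles": list(s.frame_roles),
                "seq": _seq_to_dict(s.seq),
                "pixel_spacing": list(s.pixel_spacing),
                "slice_location": s.slice_location,
            }
        )
    gt = bundle.ground_truth
    if gt:
        for name in ("lv_mask", "myo_mask", "fp_map", "sr_times", "motion", "bias"):
            if name in gt:
                arrays[f"gt_{name}"] = np.asarray(gt[name], dtype=float)
        arrays["gt_aif_times"] = gt["aif_blood"].times
        arrays["gt_aif_values"] = gt["aif_blood"].values
        meta["ground_truth"] = {
            "aif_arrival_s": gt.get("aif_arrival_s"),
            "tissue_arrival_s": gt.get("tissue_arrival_s"),
        }
    np.savez_compressed(path / "arrays.npz", **arrays)
    (path / "study.json").write_text(json.dumps(meta, indent=2))
    return path


def load_archive(path: str | Path) -> StudyBundle:
    path = Path(path)
    meta = json.loads((path / "study.json").read_text())
    arrays = np.load(path / "arrays.npz")
    series_list = []
    for entry in meta["series"]:
        seq_d = dict(entry["seq"])
        if isinstance(seq_d.get("TE"), list):
            seq_d["TE"] = tuple(seq_d["TE"])
        series_list.append(
            DynamicSeries(
                frames=arrays[f"{entry['key']}_frames"],
                trigger_times=arrays[f"{entry['key']}_triggers"],
                frame_roles=tuple(entry["roles"]),
                seq=SequenceParams(**seq_d),
                pixel_spacing=tuple(entry["pixel_spacing"]),
                slice_location=entry["slice_location"],
            )
        )
    aif = next(s for s in series_list if s.seq.role == "AIF")
    myo = [s for s in series_list if s.seq.role != "AIF"]
    gt: dict = {}
    if "gt_lv_mask" in arrays:
        from .aif import ConcentrationCurve

        gt = {
            "lv_mask": arrays["gt_lv_mask"].astype(bool),
            "myo_mask": arrays["gt_myo_mask"].astype(bool),
            "fp_map": arrays["gt_fp_map"],
            "sr_times": arrays["gt_sr_times"],
            "aif_blood": ConcentrationCurve(
                times=arrays["gt_aif_times"],
                values=arrays["gt_aif_values"],
                role="aif_blood",
            ),
        }
        gt.update(meta.get("ground_truth", {}))
    return StudyBundle(
        myocardial_series=myo,
        aif_series=aif,
        ground_truth=gt,
        condition=meta["condition"],
    )


def write_parameter_map_dicom(
    values: np.ndarray, path: str | Path, description: str = "qperf MBF map"
) -> Path:
    """Export a parameter map as a DICOM secondary-capture image."""
    path = Path(path)
    arr = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = pydicom.dataset.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.Modality = "OT"
    ds.SeriesDescription = description
    ds.Rows, ds.Columns = arr.shape
    q, slope, intercept = _quantize(arr)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = f"{intercept:.10g}"
    ds.PixelData = q.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path
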