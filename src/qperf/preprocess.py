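"""Frame alignment, coil-bias correction, baseline nulling and filtering.

The pipeline order is configurable but defaults to
register -> coil-correct -> baseline-correct, with spatial filtering off.
Temporal filtering is deliberately not implemented: it distorts the
first-pass dynamics that quantification depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .signal import SequenceParams

__all__ = [
    "DynamicSeries",
    "RegistrationResult",
    "register_translation",
    "coil_correct",
    "baseline_correct",
    "spatial_filter",
]


class PreprocessError(ValueError):
    pass


@dataclass
class DynamicSeries:
    """A time-ordered stack of 2D frames from one slice position.

    ``frame_roles`` distinguishes the proton-density lead-in frames (``PD``,
    acquired without saturation at low flip angle) from the
    saturation-recovery frames (``SR``) that carry the contrast dynamics.
    """

    frames: np.ndarray  # (T, H, W)
    trigger_times: np.ndarray  # ms, strictly increasing
    frame_roles: tuple[str, ...]  # 'PD' | 'SR'
    seq: SequenceParams
    pixel_spacing: tuple[float, float] = (2.5, 2.5)  # mm
    slice_location: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.trigger_times = np.asarray(self.trigger_times, dtype=float)
        self.frame_roles = tuple(self.frame_roles)
        if self.frames.ndim != 3:
            raise PreprocessError("frames must be a (T, H, W) stack")
        n = self.frames.shape[0]
        if self.trigger_times.shape != (n,) or len(self.frame_roles) != n:
            raise PreprocessError("frames, trigger_times and frame_roles disagree")
        if np.any(np.diff(self.trigger_times) <= 0):
            raise PreprocessError("trigger_times must be strictly increasing")
        bad = set(self.frame_roles) - {"PD", "SR"}
        if bad:
            raise PreprocessError(f"unknown frame roles {bad}")

    # -- views ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def pd_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.frame_roles) == "PD")

    @property
    def sr_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.frame_roles) == "SR")

    def pd_frames(self) -> np.ndarray:
        return self.frames[self.pd_indices]

    def sr_frames(self) -> "DynamicSeries":
        """Sub-series containing only the SR frames."""
        idx = self.sr_indices
        return replace(
            self,
            frames=self.frames[idx],
            trigger_times=self.trigger_times[idx],
            frame_roles=tuple("SR" for _ in idx),
        )

    def sr_times_s(self) -> np.ndarray:
        """SR frame times in seconds, zeroed at the first SR frame."""
        t = self.trigger_times[self.sr_indices]
        return (t - t[0]) / 1000.0

    def with_frames(self, frames: np.ndarray) -> "DynamicSeries":
        return replace(self, frames=np.asarray(frames, dtype=float))


@dataclass
class RegistrationResult:
    displacements: np.ndarray  # (T, 2) row/col shifts applied
    corrected: DynamicSeries
    flags: tuple[int, ...]  # indices of frames with degenerate content


def _shift_frame(frame: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Subpixel translation via the Fourier shift theorem."""
    if shift == (0.0, 0.0):
        return frame
    return np.real(
        np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(frame), shift))
    )


def _highpass(frame: np.ndarray, sigma: float = 3.0) -> np.ndarray:
    hp = frame - ndimage.gaussian_filter(frame, sigma)
    sd = hp.std()
    return hp / sd if sd > 0 else hp


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask] - a[mask].mean()
    bv = b[mask] - b[mask].mean()
    denom = np.sqrt((av * av).sum() * (bv * bv).sum())
    return float((av * bv).sum() / denom) if denom > 0 else 0.0


def register_translation(
    series: DynamicSeries,
    reference: int | None = None,
    upsample_factor: int = 50,
    dynamic_sd_fraction: float = 0.05,
    max_shift: int = 8,
) -> RegistrationResult:
    """Estimate and correct in-plane translation of every frame.

    Contrast passage makes naive inter-frame correlation lock onto the
    enhancing blood pool, so registration is driven by the static
    anatomy: pixels whose temporal SD exceeds ``dynamic_sd_fraction`` of
    the maximum are masked out, and the integer shift of each frame
    (PD frames included) is found by exhaustive normalized
    cross-correlation of the static content over ``+-max_shift`` pixels.
    A subpixel refinement — phase correlation of high-passed frames after
    integer alignment — is accepted only when it stays below one pixel.
    The default reference is the middle SR frame.  Frames with
    (near-)constant content cannot be registered; they get a zero
    displacement and are flagged.
    """
    if series.n_frames < 2:
        raise PreprocessError("need at least two frames to register")
    if reference is None:
        sr = series.sr_indices
        reference = int(sr[len(sr) // 2]) if sr.size else series.n_frames // 2
    ref = series.frames[reference]
    if np.ptp(ref) == 0:
        raise PreprocessError("reference frame is constant")

    # contrast dynamics live in the SR frames; PD frames only differ in
    # global brightness and would mark the whole body as dynamic
    sr_idx = series.sr_indices
    sd_map = series.frames[sr_idx if sr_idx.size >= 2 else slice(None)].std(axis=0)
    dynamic = sd_map > dynamic_sd_fraction * sd_map.max()
    static = ~ndimage.binary_dilation(dynamic, iterations=2)
    if static.sum() < 0.05 * static.size:  # nearly everything enhances
        static = np.ones_like(static)
    # keep a margin so rolled-in content never enters the comparison
    r = max_shift
    valid = np.zeros_like(static)
    valid[r:-r, r:-r] = static[r:-r, r:-r]
    if not valid.any():
        valid = static
    ref_hp = _highpass(ref)
    shifts_grid = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]

    disps = np.zeros((series.n_frames, 2))
    flags: list[int] = []
    out = np.empty_like(series.frames)
    for i, frame in enumerate(series.frames):
        if np.ptp(frame) == 0:
            flags.append(i)
            out[i] = frame
            continue
        scores = [
            _ncc(ref, np.roll(frame, (dy, dx), axis=(0, 1)), valid)
            for dy, dx in shifts_grid
        ]
        shift = np.array(shifts_grid[int(np.argmax(scores))], dtype=float)
        if upsample_factor > 1:
            aligned = _shift_frame(frame, tuple(shift))
            refine, _, _ = phase_cross_correlation(
                ref_hp,
                _highpass(aligned),
                upsample_factor=upsample_factor,
                normalization="phase",
            )
            mag = float(np.hypot(*refine))
            # sub-resolution refinements are numerical noise; shifts that
            # disagree with the robust integer estimate by >= 1 px are
            # correlation failures -- keep the integer answer either way
            if 0.1 <= mag < 1.0:
                shift = shift + refine
        disps[i] = shift
        out[i] = _shift_frame(frame, tuple(shift))
    return RegistrationResult(
        displacements=disps,
        corrected=series.with_frames(out),
        flags=tuple(flags),
    )


def _poly2_design(h: int, w: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy / max(h - 1, 1) - 0.5).ravel()
    x = (xx / max(w - 1, 1) - 0.5).ravel()
    return np.column_stack([np.ones_like(x), x, y, x * y, x**2, y**2])


def coil_correct(
    series: DynamicSeries,
    method: Literal["surface_fit", "pixelwise"] = "surface_fit",
    mask_fraction: float = 0.10,
    smooth_sigma: float = 2.0,
) -> tuple[DynamicSeries, np.ndarray]:
    """Estimate the coil sensitivity field from the PD frames and divide it out.

    ``surface_fit`` fits a quadratic 2D polynomial surface to the mean PD
    image and divides every frame by the surface normalized to unit mean
    inside the body mask (threshold at ``mask_fraction`` of the PD
    maximum).  The fit itself uses only the brightest tissue class
    (Otsu-separated): mixing tissue classes with different proton density
    into one polynomial fit would fold anatomy into the bias estimate.
    ``pixelwise`` divides by the smoothed mean PD image itself — simpler
    and robust when PD and perfusion frames are well aligned.  Returns
    the corrected series and the bias field for QC.
    """
    pd = series.pd_frames()
    if pd.size == 0:
        raise PreprocessError("series has no PD frames")
    pd_mean = pd.mean(axis=0)
    if np.all(pd_mean == 0):
        raise PreprocessError("PD frames are identically zero")
    h, w = pd_mean.shape
    mask = pd_mean > mask_fraction * pd_mean.max()

    if method == "surface_fit":
        if np.ptp(pd_mean) > 0:
            from skimage.filters import threshold_otsu

            fit_mask = pd_mean > threshold_otsu(pd_mean)
        else:
            fit_mask = mask
        design = _poly2_design(h, w)
        rows = design[fit_mask.ravel()]
        vals = pd_mean[fit_mask]
        coeffs, *_ = np.linalg.lstsq(rows, vals, rcond=None)
        # one robustifying pass: drop gross outliers (e.g. stray pixels of
        # another tissue class that crossed the threshold) and refit
        resid = vals - rows @ coeffs
        keep = np.abs(resid) <= 3.0 * max(np.std(resid), 1e-12)
        if keep.sum() >= 6 and not keep.all():
            coeffs, *_ = np.linalg.lstsq(rows[keep], vals[keep], rcond=None)
        bias = (design @ coeffs).reshape(h, w)
    elif method == "pixelwise":
        bias = ndimage.gaussian_filter(pd_mean, smooth_sigma)
    else:
        raise PreprocessError(f"unknown coil correction method {method!r}")

    bias = bias / bias[mask].mean()
    bias = np.where(bias <= 1e-6, np.nan, bias)
    corrected = series.frames / bias[None]
    corrected = np.nan_to_num(corrected, nan=0.0)
    return series.with_frames(corrected), np.nan_to_num(bias, nan=1.0)


def baseline_correct(obj, pre_contrast: Sequence[int]):
    """Null the pre-contrast baseline by subtracting its mean.

    ``obj`` may be a :class:`DynamicSeries` (indices refer to SR frames;
    PD frames are untouched), a plain array of curves with time on the
    first axis, or a ``ConcentrationCurve``.  Applicable
    both before and after conversion to concentration, which also removes
    any remnant contrast from a previous injection.
    """
    idx = np.asarray(list(pre_contrast), dtype=int)
    if idx.size == 0:
        raise PreprocessError("empty pre-contrast frame set")

    if isinstance(obj, DynamicSeries):
        sr = obj.sr_indices
        base = obj.frames[sr[idx]].mean(axis=0)
        out = obj.frames.copy()
        out[sr] = out[sr] - base[None]
        return obj.with_frames(out)

    from .aif import ConcentrationCurve

    if isinstance(obj, ConcentrationCurve):
        base = float(np.mean(obj.values[idx]))
        return replace(obj, values=obj.values - base)

    arr = np.asarray(obj, dtype=float)
    return arr - arr[idx].mean(axis=0)


def spatial_filter(
    series: DynamicSeries,
    kernel: Literal["none", "gaussian", "median"] = "none",
    width: float = 1.0,
) -> DynamicSeries:
    """Optional in-plane smoothing of the high-resolution myocardial frames.

    Refused for AIF series: filtering the AIF blunts its peak and biases
    flow estimates.  Applied to all frames including PD.  Default is no
    filtering; use only when SNR is insufficient for fitting.
    """
    if series.seq.role == "AIF":
        raise PreprocessError("spatial filtering of the AIF series is not allowed")
    if kernel == "none":
        return series
    if kernel == "gaussian":
        out = np.stack([ndimage.gaussian_filter(f, width) for f in series.frames])
    elif kernel == "median":
        size = int(width)
        if size < 2:
            raise PreprocessError("median width must be >= 2 pixels")
        out = np.stack([ndimage.median_filter(f, size=size) for f in series.frames])
    else:
        raise PreprocessError(f"unknown kernel {kernel!r}")
    return series.with_frames(out)
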