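"""Digital first-pass perfusion phantom with known ground truth.

The phantom emulates a dual-sequence stress/rest perfusion study: a
gamma-variate arterial bolus in the LV blood pool, myocardial tissue
responses generated by convolving the AIF with a chosen residue model,
saturation-recovery signal rendering through the Bloch recursion
(reproducing the nonlinear signal-concentration relationship), coil
bias, PD-weighted lead-in frames, pre-contrast baseline offset,
Rician-like noise, in-plane respiratory translation, and an irregular RR
schedule.  Every rendered study carries its complete ground truth, so
each downstream stage of the pipeline can be tested without patient
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .aif import ConcentrationCurve
from .kinetics import (
    KineticParams,
    causal_convolve,
    fermi_irf,
    residue_2cxm,
    residue_one_compartment,
)
from .preprocess import DynamicSeries
from .signal import QuantConfig, SequenceParams, sr_gre_signal, sr_signal

__all__ = [
    "GammaVariateAif",
    "SectorKinetics",
    "PhantomSpec",
    "StudyBundle",
    "generate_aif",
    "forward_tissue",
    "render_study",
    "stress_rest_pair",
    "default_myo_sequence",
    "default_aif_sequence",
]


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class GammaVariateAif:
    """Gamma-variate bolus: peaked, causal, with optional recirculation.

    CA(t) = amplitude * (s/(alpha*beta))^alpha * exp(alpha - s/beta),
    s = t - onset, zero before onset; the mode is at onset + alpha*beta.
    Recirculation is a delayed, scaled copy of the first pass.
    """

    amplitude: float = 4.0  # mmol/L at the peak (stress-like bolus)
    onset: float = 8.0  # s
    alpha: float = 3.0
    beta: float = 1.5  # s
    recirc_fraction: float = 0.15
    recirc_delay: float = 25.0  # s


def generate_aif(shape: GammaVariateAif, times: Sequence[float]) -> ConcentrationCurve:
    """Evaluate the gamma-variate AIF on a (possibly non-uniform) time grid."""
    if shape.alpha <= 0 or shape.beta <= 0:
        raise PhantomError("gamma-variate alpha and beta must be positive")
    t = np.asarray(times, dtype=float)

    def first_pass(tt: np.ndarray) -> np.ndarray:
        s = tt - shape.onset
        out = np.zeros_like(s)
        pos = s > 0
        x = s[pos] / (shape.alpha * shape.beta)
        out[pos] = shape.amplitude * x**shape.alpha * np.exp(
            shape.alpha * (1.0 - x)
        )
        return out

    values = first_pass(t)
    if shape.recirc_fraction > 0:
        values = values + shape.recirc_fraction * first_pass(t - shape.recirc_delay)
    return ConcentrationCurve(times=t, values=values, role="aif_blood")


def forward_tissue(
    aif: ConcentrationCurve,
    params: KineticParams,
    model: Literal["2cxm", "one_compartment", "fermi", "kety_tofts"] = "2cxm",
    times: Sequence[float] | None = None,
    oversample: int = 16,
) -> ConcentrationCurve:
    """Tissue concentration C_myo(t) = F_p (R ⊛ C_aif)(t) for a residue model.

    The convolution is evaluated on a fine uniform grid and resampled to
    the AIF's (possibly non-uniform) time grid.
    """
    params.validate()
    t = aif.times if times is None else np.asarray(times, dtype=float)
    if times is not None and not np.array_equal(t, aif.times):
        raise PhantomError("tissue times must match the AIF time grid")
    ca = aif.values

    if model == "2cxm":
        irf = lambda lag: (params.F_p / 60.0) * residue_2cxm(
            lag, params.F_p, params.v_p, params.v_e, params.PS
        )
    elif model == "one_compartment":
        irf = lambda lag: (params.F_p / 60.0) * residue_one_compartment(
            lag, params.F_p, params.v_p
        )
    elif model == "fermi":
        irf = lambda lag: fermi_irf(
            lag, params.fermi_A, params.fermi_mu, params.fermi_k, params.fermi_offset
        ) / 60.0
    elif model == "kety_tofts":
        # extended Tofts: v_p C_a + K_trans exp(-k_ep t) ⊛ C_a
        if params.v_e <= 0:
            raise PhantomError("kety_tofts requires v_e > 0")
        kep = params.K_trans / 60.0 / params.v_e
        conv = causal_convolve(
            t, lambda lag: (params.K_trans / 60.0) * np.exp(-kep * lag), ca, oversample
        )
        return ConcentrationCurve(times=t, values=conv + params.v_p * ca, role="tissue")
    else:
        raise PhantomError(f"unknown forward model {model!r}")

    values = causal_convolve(t, irf, ca, oversample)
    return ConcentrationCurve(times=t, values=values, role="tissue")


@dataclass(frozen=True)
class SectorKinetics:
    """Angular sector of the myocardial annulus with its own kinetics."""

    name: str
    start_deg: float  # measured counter-clockwise from the +x (image col) axis
    end_deg: float
    params: KineticParams


def _default_rest_params() -> KineticParams:
    return KineticParams(F_p=1.0, v_p=0.08, v_e=0.2, PS=0.5, v=0.28)


@dataclass
class PhantomSpec:
    """Complete description of one synthetic perfusion study.

    Geometry is in pixels on ``matrix``; the LV blood pool is a disk
    centred in the myocardial annulus.  ``region_kinetics`` carves the
    annulus into angular sectors with individual kinetics; the remainder
    of the annulus uses ``base_kinetics``.
    """

    matrix: tuple[int, int] = (96, 96)
    n_slices: int = 3
    center: tuple[float, float] | None = None  # defaults to matrix centre
    lv_radius: float = 11.0
    inner_radius: float = 15.0
    outer_radius: float = 25.0
    base_kinetics: KineticParams = field(default_factory=_default_rest_params)
    region_kinetics: tuple[SectorKinetics, ...] = ()
    kinetic_model: str = "2cxm"
    aif_shape: GammaVariateAif = field(default_factory=GammaVariateAif)
    tissue_arrival_delay: float = 1.0  # s between LV and myocardial arrival
    n_pd_frames: int = 3
    n_frames: int = 60  # total frames incl. PD lead-in
    rr_ms: float = 1000.0
    rr_schedule: tuple[float, ...] | None = None  # explicit RR intervals, ms
    noise_sd: float = 0.0  # fraction of the PD signal level
    coil_bias_coeffs: tuple[float, ...] = (1.0, 0.15, -0.10, 0.05, -0.08, 0.06)
    baseline_offset: float = 0.0  # a.u. added to every frame
    motion_amplitude: float = 0.0  # px, sinusoidal respiratory translation
    motion_period: float = 4.0  # s
    motion: tuple[tuple[float, float], ...] | None = None  # explicit per-frame
    background_m0: float = 0.5
    background_t1: float = 800.0
    background_texture: float = 0.3  # fractional smooth M0 texture (chest-wall-like)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inner_radius < self.outer_radius:
            raise PhantomError("inner radius must be below outer radius")
        if not 1 <= self.n_pd_frames <= 4:
            raise PhantomError("n_pd_frames must lie in [1, 4]")
        if self.lv_radius >= self.inner_radius:
            raise PhantomError("LV disk must fit inside the annulus")
        self.base_kinetics.validate()
        for sector in self.region_kinetics:
            sector.params.validate()

    def rr_intervals(self) -> np.ndarray:
        if self.rr_schedule is not None:
            rr = np.asarray(self.rr_schedule, dtype=float)
            if rr.size != self.n_frames - 1:
                raise PhantomError("rr_schedule must have n_frames - 1 intervals")
            return rr
        return np.full(self.n_frames - 1, self.rr_ms)

    def trigger_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.rr_intervals())])


@dataclass
class StudyBundle:
    """One rendered study: image series plus complete ground truth."""

    myocardial_series: list[DynamicSeries]
    aif_series: DynamicSeries
    ground_truth: dict
    condition: Literal["stress", "rest"] = "rest"
    spec: PhantomSpec | None = None
    config: QuantConfig | None = None


def default_myo_sequence(**overrides) -> SequenceParams:
    base = dict(
        flip_angle=12.0, TR=2.5, TE=1.2, TS=102.5, TD=5.0, lines_to_center=40,
        readout="GRE", acquisition_window=100.0, role="myocardial",
    )
    base.update(overrides)
    return SequenceParams(**base)


def default_aif_sequence(**overrides) -> SequenceParams:
    base = dict(
        flip_angle=8.0, TR=1.8, TE=0.7, TS=23.4, TD=5.0, lines_to_center=11,
        readout="GRE", acquisition_window=40.0, role="AIF",
    )
    base.update(overrides)
    return SequenceParams(**base)


def _geometry_masks(
    shape: tuple[int, int],
    center: tuple[float, float],
    lv_radius: float,
    inner: float,
    outer: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - center[0], xx - center[1])
    theta = np.rad2deg(np.arctan2(yy - center[0], xx - center[1])) % 360.0
    lv = r <= lv_radius
    myo = (r >= inner) & (r <= outer)
    return lv, myo, theta


def _coil_bias(shape: tuple[int, int], coeffs: Sequence[float]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx / max(w - 1, 1) - 0.5
    y = yy / max(h - 1, 1) - 0.5
    c = list(coeffs) + [0.0] * (6 - len(coeffs))
    bias = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * x**2 + c[5] * y**2
    if np.any(bias <= 0):
        raise PhantomError("coil bias field must stay positive")
    return bias


def _motion_schedule(spec: PhantomSpec, times_s: np.ndarray) -> np.ndarray:
    if spec.motion is not None:
        mot = np.asarray(spec.motion, dtype=float)
        if mot.shape != (spec.n_frames, 2):
            raise PhantomError("explicit motion must be (n_frames, 2)")
        return mot
    if spec.motion_amplitude == 0.0:
        return np.zeros((spec.n_frames, 2))
    phase = 2.0 * np.pi * times_s / spec.motion_period
    return np.column_stack(
        [spec.motion_amplitude * np.sin(phase), 0.6 * spec.motion_amplitude * np.cos(phase)]
    )


def _translate(frame: np.ndarray, shift: np.ndarray) -> np.ndarray:
    if not np.any(shift):
        return frame
    return np.real(
        np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(frame), tuple(shift)))
    )


def render_study(
    spec: PhantomSpec,
    seq_myo: SequenceParams | None = None,
    seq_aif: SequenceParams | None = None,
    config: QuantConfig | None = None,
    condition: Literal["stress", "rest"] = "rest",
    noncompliant: bool = False,
    aif_downsample: int = 2,
) -> StudyBundle:
    """Render a dual-sequence study from the phantom specification.

    The first ``n_pd_frames`` frames are PD-weighted (no saturation, low
    flip); subsequent frames are SR frames rendered through the Bloch
    recursion from the ground-truth concentration fields.  Coil bias
    multiplies all frames including PD; baseline offset, Rician-like
    noise and per-frame translation are then applied.  A fixed seed gives
    byte-identical output.  Sequence parameters violating the protocol
    bounds (myocardial TS <= 130 ms, AIF TS < 30 ms) are refused unless
    ``noncompliant`` is set (useful for validator tests).
    """
    seq_myo = seq_myo or default_myo_sequence()
    seq_aif = seq_aif or default_aif_sequence()
    config = config or QuantConfig()
    if not noncompliant:
        if seq_myo.TS > 130.0:
            raise PhantomError("myocardial TS exceeds 130 ms (set noncompliant=True)")
        if seq_aif.TS >= 30.0:
            raise PhantomError("AIF TS must be < 30 ms (set noncompliant=True)")
    h, w = spec.matrix
    if spec.outer_radius > min(h, w) / 2.0:
        raise PhantomError("annulus geometry exceeds the matrix")
    center = spec.center or ((h - 1) / 2.0, (w - 1) / 2.0)
    rng = np.random.default_rng(spec.seed)

    triggers = spec.trigger_times()
    times_s = triggers / 1000.0
    roles = tuple(
        "PD" if i < spec.n_pd_frames else "SR" for i in range(spec.n_frames)
    )
    sr_mask = np.array([r == "SR" for r in roles])
    sr_times = times_s[sr_mask] - times_s[sr_mask][0]

    # ground-truth concentration curves
    aif_curve = generate_aif(spec.aif_shape, sr_times)
    delayed = ConcentrationCurve(
        times=sr_times,
        values=np.interp(sr_times - spec.tissue_arrival_delay, sr_times,
                         aif_curve.values, left=0.0),
        role="aif_blood",
    )
    plasma = replace(
        delayed, values=delayed.values / (1.0 - config.hematocrit), role="aif_plasma"
    )
    region_curves = {
        "base": forward_tissue(plasma, spec.base_kinetics, spec.kinetic_model)
    }
    for sector in spec.region_kinetics:
        region_curves[sector.name] = forward_tissue(
            plasma, sector.params, spec.kinetic_model
        )

    bias = _coil_bias((h, w), spec.coil_bias_coeffs)
    motion = _motion_schedule(spec, times_s)

    def render_series(shape, seq, scale):
        ctr = (center[0] * scale, center[1] * scale)
        lv, myo, theta = _geometry_masks(
            shape, ctr, spec.lv_radius * scale,
            spec.inner_radius * scale, spec.outer_radius * scale,
        )
        b = _coil_bias(shape, spec.coil_bias_coeffs)
        m0 = np.full(shape, spec.background_m0)
        if spec.background_texture > 0:
            # smooth anatomical-like texture outside the heart; gives the
            # registration static structure to lock onto, as a chest does
            tex_rng = np.random.default_rng(spec.seed + 7919)
            tex = ndimage.gaussian_filter(tex_rng.standard_normal(shape), 3.0)
            tex = tex / max(tex.std(), 1e-12)
            m0 *= np.clip(1.0 + spec.background_texture * tex, 0.2, None)
        m0[lv] = 1.0
        m0[myo] = 1.0
        t1_0 = np.full(shape, spec.background_t1)
        t1_0[lv] = config.T1_0_blood
        t1_0[myo] = config.T1_0_myo

        # per-pixel sector labels
        sector_of = np.full(shape, "base", dtype=object)
        for sector in spec.region_kinetics:
            span = (theta - sector.start_deg) % 360.0
            width = (sector.end_deg - sector.start_deg) % 360.0
            sel = myo & (span < width)
            sector_of[sel] = sector.name

        ca_fields = np.zeros((sr_mask.sum(), *shape))
        ca_fields[:, lv] = delayed.values[:, None]
        for name, curve in region_curves.items():
            sel = myo & (sector_of == name)
            ca_fields[:, sel] = curve.values[:, None]

        pd_signal = m0 * np.sin(np.deg2rad(seq.pd_flip_angle))
        frames = np.empty((spec.n_frames, *shape))
        k_sr = 0
        for i in range(spec.n_frames):
            if roles[i] == "PD":
                clean = pd_signal.copy()
            else:
                # per-pixel baseline T1: 1/T1 = 1/T1_0 + r1*CA
                t1 = 1000.0 / (1000.0 / t1_0 + config.agent.r1 * ca_fields[k_sr])
                if seq.readout == "GRE":
                    clean = sr_gre_signal(t1, seq) * m0
                else:
                    clean = np.vectorize(lambda x: sr_signal(x, seq))(t1) * m0
                k_sr += 1
            frame = clean * b + spec.baseline_offset
            if spec.noise_sd > 0:
                sd = spec.noise_sd * pd_signal.max()
                frame = np.hypot(frame + rng.normal(0, sd, shape),
                                 rng.normal(0, sd, shape))
            frame = _translate(frame, motion[i] * scale)
            frames[i] = frame
        series = DynamicSeries(
            frames=frames, trigger_times=triggers, frame_roles=roles, seq=seq,
        )
        truth_masks = {"lv": lv, "myo": myo, "sector_of": sector_of, "bias": b,
                       "ca_fields": ca_fields}
        return series, truth_masks

    myo_series = []
    slice_truth = []
    for s in range(spec.n_slices):
        shrink = 1.0 - 0.15 * s / max(spec.n_slices - 1, 1)  # apex smaller
        ser, tm = render_series((h, w), seq_myo, shrink)
        ser = replace(ser, slice_location=10.0 * s)
        myo_series.append(ser)
        slice_truth.append(tm)

    aif_shape_px = (h // aif_downsample, w // aif_downsample)
    aif_series, aif_truth = render_series(aif_shape_px, seq_aif, 1.0 / aif_downsample)

    # per-region kinetic truth maps on the base slice
    fp_map = np.full((h, w), np.nan)
    lv0, myo0 = slice_truth[0]["lv"], slice_truth[0]["myo"]
    sector0 = slice_truth[0]["sector_of"]
    fp_map[myo0] = spec.base_kinetics.F_p
    for sector in spec.region_kinetics:
        fp_map[myo0 & (sector0 == sector.name)] = sector.params.F_p

    ground_truth = {
        "aif_blood": aif_curve,
        "tissue_input_blood": delayed,
        "tissue_input_plasma": plasma,
        "region_curves": region_curves,
        "sr_times": sr_times,
        "lv_mask": lv0,
        "myo_mask": myo0,
        "sector_of": sector0,
        "fp_map": fp_map,
        "slice_truth": slice_truth,
        "aif_truth": aif_truth,
        "bias": bias,
        "motion": motion,
        "aif_arrival_s": spec.aif_shape.onset,
        "tissue_arrival_s": spec.aif_shape.onset + spec.tissue_arrival_delay,
        "base_kinetics": spec.base_kinetics,
    }
    return StudyBundle(
        myocardial_series=myo_series,
        aif_series=aif_series,
        ground_truth=ground_truth,
        condition=condition,
        spec=spec,
        config=config,
    )


def stress_rest_pair(
    spec: PhantomSpec | None = None,
    mpr: float = 3.0,
    config: QuantConfig | None = None,
    **render_kw,
) -> tuple[StudyBundle, StudyBundle]:
    """Matched stress/rest studies whose true MBF ratio is ``mpr``.

    The stress study scales every sector's plasma flow by ``mpr`` while
    keeping volumes and permeability fixed.
    """
    spec = spec or PhantomSpec()
    rest = render_study(spec, config=config, condition="rest", **render_kw)

    def scale(p: KineticParams) -> KineticParams:
        return replace(p, F_p=p.F_p * mpr)

    stress_spec = replace(
        spec,
        base_kinetics=scale(spec.base_kinetics),
        region_kinetics=tuple(
            replace(s, params=scale(s.params)) for s in spec.region_kinetics
        ),
    )
    stress = render_study(stress_spec, config=config, condition="stress", **render_kw)
    return stress, rest
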