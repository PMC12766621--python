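"""Saturation-recovery signal modelling and signal-to-concentration conversion.

First-pass perfusion imaging uses a saturation-recovery (SR) prepared
readout: a 90-degree saturation pulse resets longitudinal magnetization
every heartbeat, and the image is acquired while magnetization recovers
with the tissue T1.  Gadolinium shortens T1 in proportion to its
concentration,

    1/T1 = 1/T1_0 + r1 * CA,

so converting measured signal back to concentration requires an accurate
forward model of the SR readout.  This module provides that model as a
pulse-by-pulse Bloch recursion (GRE and bSSFP readouts), dictionary-based
inversion of the signal-T1 relationship, the relaxivity conversion to
concentration, and multi-echo T2* correction of high-concentration blood
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SequenceParams",
    "ContrastAgent",
    "QuantConfig",
    "SignalDictionary",
    "sr_gre_signal",
    "sr_bssfp_signal",
    "sr_signal",
    "build_dictionary",
    "si_to_concentration",
    "concentration_from_t1",
    "t1_from_concentration",
    "t2star_correct",
]


class SignalModelError(ValueError):
    """Invalid physical parameter or non-invertible signal model."""


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of one SR-prepared dynamic sequence.

    Timing convention: ``TS`` is measured from the saturation pulse to the
    acquisition of the k-space centre line, ``TD`` from saturation to the
    first readout RF pulse, so ``TS = TD + (lines_to_center - 1) * TR``
    up to rounding of one TR.
    """

    flip_angle: float  # degrees
    TR: float  # ms
    TE: float | tuple[float, ...]  # ms, scalar or per-echo
    TS: float  # ms, saturation to k-space centre
    TD: float  # ms, saturation to first readout pulse
    lines_to_center: int
    readout: Literal["GRE", "bSSFP"] = "GRE"
    acquisition_window: float = 100.0  # ms
    dynamic_interval: float | tuple[float, ...] = 1000.0  # ms
    role: Literal["myocardial", "AIF"] = "myocardial"
    saturation_efficiency: float = 1.0
    T2: float = 45.0  # ms, used by the bSSFP recursion only
    pd_flip_angle: float = 5.0  # degrees, lead-in PD frames

    def __post_init__(self) -> None:
        if self.TR <= 0:
            raise SignalModelError(f"TR must be positive, got {self.TR}")
        if self.TD < 0 or self.TS < self.TD:
            raise SignalModelError("require TS >= TD >= 0")
        if self.lines_to_center < 1:
            raise SignalModelError("lines_to_center must be >= 1")
        implied = self.TD + (self.lines_to_center - 1) * self.TR
        if abs(implied - self.TS) > self.TR + 1e-9:
            raise SignalModelError(
                f"TS={self.TS} inconsistent with TD + (lines_to_center-1)*TR"
                f" = {implied} (beyond one TR of rounding)"
            )
        if not 0.0 <= self.saturation_efficiency <= 1.0:
            raise SignalModelError("saturation_efficiency must be in [0, 1]")


@dataclass(frozen=True)
class ContrastAgent:
    """Gadolinium-based contrast agent relaxivities (L mmol^-1 s^-1)."""

    name: str = "gadobutrol"
    r1: float = 4.5
    r2_star: float | None = None

    def __post_init__(self) -> None:
        if self.r1 <= 0:
            raise SignalModelError("r1 must be positive")


@dataclass(frozen=True)
class QuantConfig:
    """Population-level constants for quantification.

    Fixed baseline T1 values are preferred over per-patient measurement to
    simplify the protocol; defaults are 3T-like and overridable.
    """

    T1_0_blood: float = 1600.0  # ms
    T1_0_myo: float = 1200.0  # ms
    hematocrit: float = 0.42
    tissue_density: float = 1.05  # g/mL
    agent: ContrastAgent = field(default_factory=ContrastAgent)
    report_blood_flow: bool = True  # MBF = F_p/(1-Hct) when True

    def __post_init__(self) -> None:
        if not 0.0 < self.hematocrit < 1.0:
            raise SignalModelError("hematocrit must be in (0, 1)")
        if self.T1_0_blood <= 0 or self.T1_0_myo <= 0:
            raise SignalModelError("baseline T1 values must be positive")
        if self.tissue_density <= 0:
            raise SignalModelError("tissue density must be positive")

    def t1_0(self, role: str) -> float:
        return self.T1_0_blood if role == "AIF" else self.T1_0_myo


def sr_gre_signal(T1: float, seq: SequenceParams, M0: float = 1.0) -> float:
    """Magnitude signal of an SR-prepared spoiled-GRE readout at the centre line.

    The longitudinal magnetization is iterated pulse by pulse: saturation
    (scaled by the configured efficiency), free recovery over ``TD``, then
    ``lines_to_center`` excitations separated by ``TR``, each tipping the
    current Mz by the flip angle.  The returned value is the transverse
    magnitude generated by the centre-line pulse.
    """
    T1 = np.asarray(T1, dtype=float)
    if np.any(T1 <= 0):
        raise SignalModelError("T1 must be positive")
    alpha = np.deg2rad(seq.flip_angle)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    mz = (1.0 - seq.saturation_efficiency) * M0
    mz = M0 + (mz - M0) * np.exp(-seq.TD / T1)
    e_tr = np.exp(-seq.TR / T1)
    for _ in range(seq.lines_to_center - 1):
        mz = mz * cos_a
        mz = M0 + (mz - M0) * e_tr
    sig = np.abs(mz * sin_a)
    return float(sig) if np.isscalar(sig) or sig.ndim == 0 else sig


def sr_bssfp_signal(T1: float, seq: SequenceParams, M0: float = 1.0) -> float:
    """SR-prepared bSSFP centre-line signal via a combined T1/T2 recursion.

    On-resonance balanced readout with alternating RF phase: each TR the
    magnetization vector is rotated by +/- flip about x, then relaxes (T2 on
    the transverse component, T1 on the longitudinal).  Off-resonance and
    slice-profile effects are not modelled.
    """
    if T1 <= 0:
        raise SignalModelError("T1 must be positive")
    alpha = np.deg2rad(seq.flip_angle)
    e1, e2 = np.exp(-seq.TR / T1), np.exp(-seq.TR / seq.T2)
    my, mz = 0.0, (1.0 - seq.saturation_efficiency) * M0
    mz = M0 + (mz - M0) * np.exp(-seq.TD / T1)
    # alpha/2 - TR/2 catalyzation onto the alternating steady-state path
    half = alpha / 2.0
    my, mz = my * np.cos(half) + mz * np.sin(half), mz * np.cos(half) - my * np.sin(half)
    my *= np.exp(-seq.TR / 2.0 / seq.T2)
    mz = M0 + (mz - M0) * np.exp(-seq.TR / 2.0 / T1)
    sign = -1.0
    signal = 0.0
    for _ in range(seq.lines_to_center):
        a = sign * alpha
        my, mz = my * np.cos(a) + mz * np.sin(a), mz * np.cos(a) - my * np.sin(a)
        signal = abs(my)
        my *= e2
        mz = M0 + (mz - M0) * e1
        sign = -sign
    return float(signal)


def sr_signal(T1: float, seq: SequenceParams, M0: float = 1.0) -> float:
    """Dispatch to the GRE or bSSFP recursion according to ``seq.readout``."""
    if seq.readout == "GRE":
        return sr_gre_signal(T1, seq, M0)
    if seq.readout == "bSSFP":
        return sr_bssfp_signal(T1, seq, M0)
    raise SignalModelError(f"unknown readout {seq.readout!r}")


@dataclass(frozen=True)
class SignalDictionary:
    """Pre-computed signal-vs-T1 lookup for one sequence, with inversion.

    ``signal_grid`` must be strictly decreasing in T1, which makes the
    inversion unambiguous; construction fails otherwise rather than
    inverting silently.
    """

    T1_grid: np.ndarray  # ms, ascending
    signal_grid: np.ndarray  # a.u., strictly decreasing
    seq: SequenceParams
    M0_reference: float = 1.0

    @property
    def step(self) -> float:
        return float(np.diff(self.T1_grid).max())

    def signal(self, T1: np.ndarray) -> np.ndarray:
        """Interpolate the forward model on the grid."""
        return np.interp(T1, self.T1_grid, self.signal_grid)

    def invert(self, signal: np.ndarray, return_flags: bool = False):
        """Map normalized signal back to T1 (ms) by linear interpolation.

        Signals outside the tabulated range are clamped to the nearest grid
        end and flagged; they are never extrapolated.
        """
        s = np.asarray(signal, dtype=float)
        lo, hi = self.signal_grid[-1], self.signal_grid[0]
        clamped = (s < lo) | (s > hi)
        s_c = np.clip(s, lo, hi)
        # interp wants ascending x: traverse the dictionary in reverse
        t1 = np.interp(s_c, self.signal_grid[::-1], self.T1_grid[::-1])
        if return_flags:
            return t1, clamped
        return t1


def build_dictionary(
    seq: SequenceParams,
    T1_range: tuple[float, float] = (50.0, 3000.0),
    step: float = 1.0,
    M0: float = 1.0,
) -> SignalDictionary:
    """Tabulate the Bloch-simulated signal over a T1 grid.

    Raises if the resulting signal is not strictly monotone decreasing in
    T1 (possible for pathological bSSFP settings), because inversion would
    then be ambiguous.
    """
    lo, hi = T1_range
    if not (0.0 < lo < hi <= 5000.0):
        raise SignalModelError("T1 range must satisfy 0 < lo < hi <= 5000 ms")
    if step <= 0:
        raise SignalModelError("step must be positive")
    grid = np.arange(lo, hi + step / 2.0, step)
    if seq.readout == "GRE":  # the GRE recursion is vectorized over T1
        sig = np.asarray(sr_gre_signal(grid, seq, M0))
    else:
        sig = np.array([sr_signal(t1, seq, M0) for t1 in grid])
    if not np.all(np.diff(sig) < 0):
        raise SignalModelError(
            "signal is not strictly decreasing in T1 over the grid; "
            "dictionary inversion would be ambiguous"
        )
    return SignalDictionary(T1_grid=grid, signal_grid=sig, seq=seq, M0_reference=M0)


def concentration_from_t1(T1: np.ndarray, T1_0: float, r1: float) -> np.ndarray:
    """Relaxivity conversion CA = (1/T1 - 1/T1_0)/r1, T1 in ms, CA in mmol/L."""
    T1 = np.asarray(T1, dtype=float)
    return (1000.0 / T1 - 1000.0 / T1_0) / r1


def t1_from_concentration(CA: np.ndarray, T1_0: float, r1: float) -> np.ndarray:
    """Inverse of :func:`concentration_from_t1` (returns T1 in ms)."""
    CA = np.asarray(CA, dtype=float)
    return 1000.0 / (1000.0 / T1_0 + r1 * CA)


def si_to_concentration(
    series,
    pd_reference: np.ndarray,
    config: QuantConfig,
    dictionary: SignalDictionary,
    m0_mode: Literal["pixelwise", "surface"] = "pixelwise",
):
    """Convert an SR image series to contrast-agent concentration maps.

    Per pixel and frame the signal is normalized by an M0 map derived from
    the PD reference (``PD / sin(pd_flip_angle)``), inverted through the
    dictionary to T1(t), and mapped to concentration with the relaxivity
    equation using the fixed baseline T1 for the series role.  Because the
    PD frames see the same coil sensitivity as the SR frames, the pixelwise
    normalization cancels coil bias.

    Returns ``(conc, clamp_flags)``: concentration array (frames x H x W,
    mmol/L, SR frames only) and a boolean array marking pixels whose signal
    fell outside the dictionary range (clamped, recorded for QC — never
    silently extrapolated).  Negative baseline concentrations are retained
    for downstream baseline correction rather than clipped.
    """
    from .preprocess import DynamicSeries  # cycle-free at runtime

    assert isinstance(series, DynamicSeries)
    pd_ref = np.asarray(pd_reference, dtype=float)
    if np.all(pd_ref <= 0):
        raise SignalModelError("PD reference is non-positive everywhere")
    seq = series.seq
    m0 = pd_ref / np.sin(np.deg2rad(seq.pd_flip_angle))
    if m0_mode == "surface":
        # low-order smooth M0 surface: robust to PD noise, blurs edges
        from scipy.ndimage import gaussian_filter

        m0 = gaussian_filter(m0, sigma=3.0)
    m0 = np.where(m0 <= 0, np.nan, m0)

    sr = series.sr_frames()
    norm = sr.frames / (m0[None] * dictionary.M0_reference)
    t1, clamped = dictionary.invert(norm, return_flags=True)
    conc = concentration_from_t1(t1, config.t1_0(seq.role), config.agent.r1)
    conc = np.where(np.isnan(m0)[None], np.nan, conc)
    return conc, clamped


def t2star_correct(
    signals: Sequence[float], TEs: Sequence[float]
) -> tuple[float, float, bool]:
    """Fit S(TE) = S0 * exp(-TE/T2*) by log-linear least squares.

    Returns ``(S0, T2star, decay_flag)``.  With two echoes the fit is
    exact.  A non-decaying signal (no measurable T2* loss) is reported as
    ``T2star = inf`` with ``decay_flag = False`` and ``S0`` set to the mean
    signal.
    """
    s = np.asarray(signals, dtype=float)
    te = np.asarray(TEs, dtype=float)
    if s.size < 2 or te.size != s.size:
        raise SignalModelError("need >= 2 echoes with matching TE list")
    if len(np.unique(te)) != te.size:
        raise SignalModelError("echo times must be distinct")
    if np.any(s <= 0):
        raise SignalModelError("signals must be positive for log-linear fit")
    slope, intercept = np.polyfit(te, np.log(s), 1)
    if slope >= 0:
        return float(s.mean()), float("inf"), False
    return float(np.exp(intercept)), float(-1.0 / slope), True
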