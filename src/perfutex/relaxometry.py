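"""Variable-flip-angle T1 mapping and signal-to-concentration conversion.

The dynamic signal of a spoiled gradient echo at steady state is

    S = M0 * sin(a) * (1 - E) / (1 - E * cos(a)),    E = exp(-TR / T1).

Baseline T1 (T10) is estimated from a multi-flip-angle acquisition via the
linearised relation S/sin(a) = E * S/tan(a) + M0 * (1 - E).  Contrast
concentration follows from the change in longitudinal relaxation rate,

    C(t) = (1/T1(t) - 1/T1(0)) / r1,

either through the first-order (linear) reduction

    C(t) = (S(t) - S0) / (S0 * r1 * T10)

or by exact inversion of the SPGR equation for T1(t).  The linear form is
the package default because it is what commercial perfusion software
commonly applies, but note it is only proportional to the exact answer:
even as C -> 0 it differs by the protocol-dependent sensitivity factor
TR*E*(1-cos a) / [(1-E)(1-E cos a) * T10] (about 0.85 at TR = 3.9 ms,
a = 12 deg, T10 = 1 s), and it saturates further at high enhancement.
Because the same bias affects tissue and artery it largely cancels in the
kinetic-parameter ratios; use ``method="exact"`` for quantitatively
accurate concentrations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams
from .errors import DimensionError, InvalidInputError

__all__ = [
    "DynamicSeries",
    "FlipAngleSeries",
    "T1Map",
    "ConcentrationSeries",
    "spgr_signal",
    "vfa_t1_fit",
    "signal_to_concentration_linear",
    "signal_to_concentration_exact",
    "signal_to_concentration",
]


@dataclass
class DynamicSeries:
    """4D dynamic signal grid (x, y, z, t) with its acquisition timing."""

    signal: np.ndarray
    times: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.ndim != 4:
            raise DimensionError("signal must be 4D (x, y, z, t)")
        if self.times.ndim != 1 or self.times.size != self.signal.shape[-1]:
            raise DimensionError("time axis length must match the signal grid")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("times must be strictly increasing")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class FlipAngleSeries:
    """One 3D volume per flip angle of the baseline T1 acquisition."""

    volumes: list[np.ndarray]
    flip_angles: list[float]

    def __post_init__(self) -> None:
        self.volumes = [np.asarray(v, dtype=float) for v in self.volumes]
        if len(self.volumes) != len(self.flip_angles):
            raise InvalidInputError("need exactly one volume per flip angle")
        if len(set(self.flip_angles)) < 2:
            raise InvalidInputError("need at least two distinct flip angles")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise DimensionError("all flip-angle volumes must share a grid")


@dataclass
class T1Map:
    """Voxelwise longitudinal relaxation time and equilibrium signal.

    ``t1`` is in seconds and NaN where the fit was rejected; ``valid`` marks
    voxels with a physically meaningful estimate.
    """

    t1: np.ndarray
    m0: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.t1.shape != self.m0.shape or self.t1.shape != self.valid.shape:
            raise DimensionError("t1, m0 and valid grids must be congruent")


@dataclass
class ConcentrationSeries:
    """Tissue contrast concentration over time, mmol/L."""

    conc: np.ndarray
    times: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.ndim != 4:
            raise DimensionError("conc must be 4D (x, y, z, t)")
        if self.times.size != self.conc.shape[-1]:
            raise DimensionError("time axis length must match the grid")
        if self.valid is None:
            self.valid = np.ones(self.conc.shape[:3], dtype=bool)


def spgr_signal(m0, t1, params: AcquisitionParams, flip_angle: float | None = None):
    """Steady-state spoiled-gradient-echo signal.

    Parameters are broadcast; ``flip_angle`` (degrees) defaults to the
    dynamic flip angle of ``params``.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise InvalidInputError("t1 must be positive")
    alpha = np.deg2rad(params.flip_angle_dynamic if flip_angle is None else flip_angle)
    e1 = np.exp(-params.repetition_time / t1)
    return np.asarray(m0) * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


def vfa_t1_fit(fa_series: FlipAngleSeries, params: AcquisitionParams) -> T1Map:
    """Fit T1 and M0 per voxel from a variable-flip-angle series.

    Uses the linearised SPGR relation: regressing S/sin(a) on S/tan(a)
    across angles gives slope E = exp(-TR/T1) and intercept M0*(1-E).
    Voxels whose slope falls outside (0, 1) — including all-zero voxels —
    are flagged invalid rather than raising.
    """
    if len(fa_series.flip_angles) < 2:
        raise InvalidInputError("need at least two flip angles")
    alphas = np.deg2rad(np.asarray(fa_series.flip_angles, dtype=float))
    stack = np.stack(fa_series.volumes, axis=0)  # (n_angles, x, y, z)
    y = stack / np.sin(alphas)[:, None, None, None]
    x = stack / np.tan(alphas)[:, None, None, None]

    n = len(alphas)
    sx, sy = x.sum(0), y.sum(0)
    sxy, sxx = (x * y).sum(0), (x * x).sum(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sxx - sx * sx
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
        valid = np.isfinite(slope) & (slope > 0) & (slope < 1) & (intercept > 0)
        t1 = np.where(valid, -params.repetition_time / np.log(slope), np.nan)
        m0 = np.where(valid, intercept / (1.0 - slope), np.nan)
    return T1Map(t1=t1, m0=m0, valid=valid)


def _baseline_signal(dyn: DynamicSeries) -> np.ndarray:
    nb = dyn.params.n_baseline
    return dyn.signal[..., :nb].mean(axis=-1)


def signal_to_concentration_linear(
    dyn: DynamicSeries,
    t10: T1Map,
    params: AcquisitionParams | None = None,
    clip_negative: bool = False,
) -> ConcentrationSeries:
    """Linear (first-order) signal-to-concentration conversion.

    C(t) = (S(t) - S0) / (S0 * r1 * T10) with S0 the mean of the
    pre-contrast frames.  Negative concentrations from noise are retained
    unless ``clip_negative`` is set, so that baseline noise statistics stay
    unbiased.
    """
    params = params or dyn.params
    if t10.t1.shape != dyn.shape3d:
        raise DimensionError("T1 map grid does not match the dynamic series")
    s0 = _baseline_signal(dyn)
    valid = t10.valid & (s0 != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = (dyn.signal - s0[..., None]) / (
            s0[..., None] * params.relaxivity_r1 * t10.t1[..., None]
        )
    conc[~valid] = np.nan
    if clip_negative:
        conc = np.clip(conc, 0.0, None)
    return ConcentrationSeries(conc=conc, times=dyn.times, valid=valid)


def signal_to_concentration_exact(
    dyn: DynamicSeries,
    t10: T1Map,
    params: AcquisitionParams | None = None,
    clip_negative: bool = False,
) -> ConcentrationSeries:
    """Exact SPGR inversion for T1(t), then C(t) = (1/T1(t) - 1/T10) / r1.

    The implied equilibrium term M0*sin(a) is recovered from the baseline
    signal and T10, so the inversion needs no separate M0 input.  Signal
    ratios outside the invertible range (E outside (0, 1)) are flagged
    invalid per voxel/time via NaN.
    """
    params = params or dyn.params
    if t10.t1.shape != dyn.shape3d:
        raise DimensionError("T1 map grid does not match the dynamic series")
    alpha = np.deg2rad(params.flip_angle_dynamic)
    cos_a = np.cos(alpha)
    s0 = _baseline_signal(dyn)
    with np.errstate(divide="ignore", invalid="ignore"):
        e0 = np.exp(-params.repetition_time / t10.t1)
        # amplitude m = M0*sin(a), inferred from the baseline SPGR signal
        m = s0 * (1.0 - e0 * cos_a) / (1.0 - e0)
        s = dyn.signal / m[..., None]
        e_t = (1.0 - s) / (1.0 - s * cos_a)
        invertible = (e_t > 0) & (e_t < 1)
        r1_t = np.where(invertible, -np.log(e_t) / params.repetition_time, np.nan)
        conc = (r1_t - 1.0 / t10.t1[..., None]) / params.relaxivity_r1
    valid = t10.valid & (s0 != 0)
    conc[~valid] = np.nan
    if clip_negative:
        conc = np.clip(conc, 0.0, None)
    return ConcentrationSeries(conc=conc, times=dyn.times, valid=valid)


def signal_to_concentration(
    dyn: DynamicSeries,
    t10: T1Map,
    params: AcquisitionParams | None = None,
    method: str = "linear",
    clip_negative: bool = False,
) -> ConcentrationSeries:
    """Dispatch between the linear and exact conversion methods."""
    if method == "linear":
        return signal_to_concentration_linear(dyn, t10, params, clip_negative)
    if method == "exact":
        return signal_to_concentration_exact(dyn, t10, params, clip_negative)
    raise InvalidInputError(f"unknown conversion method {method!r}")
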