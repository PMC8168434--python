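"""Voxelwise extended Tofts model fitting.

The extended Tofts model describes tissue contrast concentration as

    C(t) = vp * Cp(t) + Ktrans * int_0^t Cp(tau) exp(-kep (t - tau)) dtau

with Ktrans the plasma-to-interstitium transfer constant (min^-1), kep the
back-flux rate constant (min^-1), vp the plasma volume fraction and
ve = Ktrans / kep the extravascular extracellular volume fraction.  Fits are
bounded nonlinear least squares in (Ktrans, kep, vp), initialised from the
linear matrix formulation of the same equations; time integration is done
in minutes internally so parameters come out in min^-1 as conventionally
reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .aif import AifCurve
from .errors import DimensionError, InvalidInputError

__all__ = ["PkMaps", "FitBounds", "tofts_forward", "tofts_forward_many", "fit_voxel", "fit_map"]

#: parameter bounds enforced by the solver: Ktrans [0, 5] /min, kep (0, 10] /min,
#: vp [0, 0.5]
LOWER = np.array([0.0, 1e-6, 0.0])
UPPER = np.array([5.0, 10.0, 0.5])


@dataclass
class PkMaps:
    """Voxelwise kinetic parameter maps (NaN outside the fitted region)."""

    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    fit_ok: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.ktrans, self.kep, self.ve, self.vp, self.fit_ok)}
        if len(shapes) != 1:
            raise DimensionError("all parameter maps must share a grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ktrans.shape

    def roi_means(self, mask: np.ndarray) -> dict[str, float]:
        """ROI means of the four parameters over fit_ok voxels inside mask."""
        sel = np.asarray(mask, dtype=bool) & self.fit_ok
        if not sel.any():
            raise InvalidInputError("no successfully fitted voxels inside mask")
        return {
            "ktrans": float(self.ktrans[sel].mean()),
            "kep": float(self.kep[sel].mean()),
            "ve": float(self.ve[sel].mean()),
            "vp": float(self.vp[sel].mean()),
        }


def _exp_conv(kep_min: np.ndarray, cp: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    """Causal trapezoidal convolution int_0^t cp(tau) e^{-kep (t-tau)} dtau.

    ``kep_min`` has shape (V,), the result (V, T).  Times in minutes.
    """
    nt = t_min.size
    out = np.zeros((kep_min.size, nt))
    for i in range(1, nt):
        w = np.exp(-np.outer(kep_min, t_min[i] - t_min[: i + 1]))
        out[:, i] = np.trapezoid(cp[: i + 1] * w, t_min[: i + 1], axis=1)
    return out


def tofts_forward_many(
    ktrans: np.ndarray,
    kep: np.ndarray,
    vp: np.ndarray,
    aif: AifCurve,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised forward model for V voxels; returns a (V, T) array."""
    ktrans = np.atleast_1d(np.asarray(ktrans, dtype=float))
    kep = np.atleast_1d(np.asarray(kep, dtype=float))
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    if np.any(ktrans < 0) or np.any(kep < 0) or np.any(vp < 0):
        raise InvalidInputError("kinetic parameters must be non-negative")
    if np.any((ktrans > 0) & (kep <= 0)):
        raise InvalidInputError("kep must be positive wherever ktrans > 0")
    t = aif.times if times is None else np.asarray(times, dtype=float)
    t_min = t / 60.0
    conv = _exp_conv(np.where(kep > 0, kep, 1.0), aif.cp, t_min)
    conv[kep <= 0] = 0.0
    return vp[:, None] * aif.cp[None, :] + ktrans[:, None] * conv


def tofts_forward(
    ktrans: float,
    kep: float,
    vp: float,
    aif: AifCurve,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Extended Tofts concentration curve for one voxel.

    Rate constants are per minute; ``times`` (seconds) defaults to the AIF
    sampling grid.
    """
    return tofts_forward_many(ktrans, kep, vp, aif, times)[0]


def _linear_init(ct: np.ndarray, cp: np.ndarray, t_min: np.ndarray) -> np.ndarray:
    """Linear least-squares formulation of the extended Tofts equations.

    Integrating the ODE form gives
        C(t) = (Ktrans + kep*vp) int Cp - kep int C + vp Cp,
    a linear system in (b1, b2, b3) = (Ktrans + kep*vp, kep, vp).
    """
    from scipy.integrate import cumulative_trapezoid

    icp = cumulative_trapezoid(cp, t_min, initial=0.0)
    ict = cumulative_trapezoid(ct, t_min, initial=0.0)
    a = np.column_stack([icp, -ict, cp])
    b, *_ = np.linalg.lstsq(a, ct, rcond=None)
    kep0 = b[1]
    vp0 = b[2]
    ktrans0 = b[0] - kep0 * vp0
    x0 = np.array([ktrans0, kep0, vp0])
    # clamp to the interior of the bounds
    return np.clip(x0, LOWER + 1e-4, UPPER - 1e-4)


@dataclass
class FitBounds:
    lower: np.ndarray = field(default_factory=lambda: LOWER.copy())
    upper: np.ndarray = field(default_factory=lambda: UPPER.copy())


def fit_voxel(
    ct: np.ndarray,
    aif: AifCurve,
    times: np.ndarray | None = None,
    linear_only: bool = False,
) -> tuple[float, float, float, float, bool]:
    """Fit (Ktrans, kep, ve, vp) to one concentration curve.

    Returns ``(ktrans, kep, ve, vp, fit_ok)``.  All-zero input is the
    degenerate no-uptake case and returns Ktrans = 0 with fit_ok True;
    non-finite input, solver failure, or a solution pinned at an upper
    bound yields fit_ok False.  ``linear_only`` skips the nonlinear
    refinement (fast mode).
    """
    ct = np.asarray(ct, dtype=float)
    t = aif.times if times is None else np.asarray(times, dtype=float)
    if ct.size < 10:
        raise InvalidInputError("need at least 10 timepoints to fit")
    if not np.all(np.isfinite(ct)):
        return (np.nan, np.nan, np.nan, np.nan, False)
    if np.allclose(ct, 0.0):
        # no uptake: Ktrans, ve, vp are zero; kep is unidentifiable and
        # reported as 1.0 by convention so that ve == ktrans/kep holds
        return (0.0, 1.0, 0.0, 0.0, True)
    t_min = t / 60.0
    x0 = _linear_init(ct, aif.cp, t_min)
    if linear_only:
        ktrans, kep, vp = x0
        return (float(ktrans), float(kep), float(ktrans / kep), float(vp), True)

    def resid(x: np.ndarray) -> np.ndarray:
        return tofts_forward_many(x[0], x[1], x[2], aif, t)[0] - ct

    try:
        sol = least_squares(resid, x0, bounds=(LOWER, UPPER), method="trf", xtol=1e-12, ftol=1e-12)
    except Exception:
        return (np.nan, np.nan, np.nan, np.nan, False)
    ktrans, kep, vp = sol.x
    at_upper = bool(np.any(np.isclose(sol.x, UPPER, rtol=0, atol=1e-9)))
    fit_ok = bool(sol.success) and not at_upper
    return (float(ktrans), float(kep), float(ktrans / kep), float(vp), fit_ok)


def fit_map(
    conc,
    mask: np.ndarray,
    aif: AifCurve,
    linear_only: bool = False,
) -> PkMaps:
    """Apply :func:`fit_voxel` to every voxel of ``mask``.

    ``conc`` is a :class:`~perfutex.relaxometry.ConcentrationSeries`.  Maps
    are NaN outside the mask; a per-map ``fit_ok`` grid records failures.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != conc.conc.shape[:3]:
        raise DimensionError("mask grid does not match the concentration grid")
    if not mask.any():
        raise InvalidInputError("lesion mask is empty")
    shape = mask.shape
    maps = {k: np.full(shape, np.nan) for k in ("ktrans", "kep", "ve", "vp")}
    fit_ok = np.zeros(shape, dtype=bool)
    n_failed = 0
    for idx in np.argwhere(mask):
        i, j, k = idx
        ct = conc.conc[i, j, k, :]
        ktrans, kep, ve, vp, ok = fit_voxel(ct, aif, conc.times, linear_only=linear_only)
        maps["ktrans"][i, j, k] = ktrans
        maps["kep"][i, j, k] = kep
        maps["ve"][i, j, k] = ve
        maps["vp"][i, j, k] = vp
        fit_ok[i, j, k] = ok
        n_failed += not ok
    result = PkMaps(fit_ok=fit_ok, **maps)
    result.n_failed = n_failed  # fit log: count of voxels that did not converge
    return result
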