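"""Synthetic DCE-MRI phantom cohorts with known ground-truth kinetics.

The generator emulates a two-visit (pre/post treatment) esophageal-tumor
DCE study with two response classes, CR (complete response) and PR
(partial response).  Per-lesion mean kinetic parameters are drawn from
truncated normal distributions whose moments are the published group
means +/- SDs of the study population at each visit; voxels vary around the
lesion mean through a spatially correlated multiplicative heterogeneity
field whose smoothness and variance differ by class, so PR lesions carry
more co-occurrence entropy than CR lesions, matching the direction seen in
patients.

Everything is deterministic given a seed: the same seed reproduces the
same cohort voxel-for-voxel.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm

from .acquisition import AcquisitionParams
from .aif import AifCurve
from .errors import DimensionError, InvalidInputError
from .pkfit import PkMaps, tofts_forward_many
from .relaxometry import DynamicSeries, FlipAngleSeries, T1Map, spgr_signal

__all__ = [
    "CLASS_MOMENTS",
    "HETEROGENEITY",
    "GroundTruthLesion",
    "make_population_aif",
    "make_lesion",
    "forward_signal",
    "make_cohort",
    "ellipsoid_mask",
]

#: group means and SDs of the lesion-level kinetic parameters, by visit and
#: response class (Ktrans and kep in min^-1, ve and vp fractions)
CLASS_MOMENTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "pre": {
        "CR": {"ktrans": (0.454, 0.213), "ve": (0.388, 0.107), "vp": (0.008, 0.006)},
        "PR": {"ktrans": (0.444, 0.162), "ve": (0.352, 0.057), "vp": (0.011, 0.020)},
    },
    "post": {
        "CR": {"ktrans": (0.117, 0.065), "ve": (0.130, 0.094), "vp": (0.003, 0.003)},
        "PR": {"ktrans": (0.299, 0.231), "ve": (0.322, 0.204), "vp": (0.004, 0.008)},
    },
}

#: spatial-heterogeneity roughness by visit and class.  Each lesion draws a
#: roughness weight w ~ Beta(a, b) that mixes a smooth and a fine-grained
#: correlated Gaussian field.  Before treatment the classes share one
#: distribution (pre-treatment texture does not separate responders);
#: after treatment responding (CR) lesions stay predominantly smooth while
#: non-responding (PR) lesions roughen, giving a standardized
#: co-occurrence-entropy separation of about one pooled SD, as in patients,
#: with entropy increasing under treatment in both classes.
HETEROGENEITY: dict[str, dict[str, tuple[float, float]]] = {
    "pre": {"CR": (1.5, 6.0), "PR": (1.5, 6.0)},
    "post": {"CR": (2.0, 4.0), "PR": (4.0, 2.0)},
}
FIELD_CV = 0.3       # in-mask coefficient of variation of the field
SMOOTH_SIGMA = 2.5   # voxels, the smooth component
ROUGH_SIGMA = 0.45   # voxels, the fine-grained component

#: baseline longitudinal relaxation times, seconds (typical 3 T values)
T10_TISSUE = 1.0
T10_BLOOD = 1.6

# population AIF constants: a recirculating biexponential washout (classic
# plasma-clearance amplitudes in (mmol/L) per (mmol/kg) of dose, decay rates
# in min^-1) under a gamma-variate first-pass bolus.  The bolus is kept
# broad enough that the 6 s dynamic sampling resolves it (trapezoidal area
# agrees with fine-grid quadrature to < 1%).
AIF_WASHOUT_A = (3.99, 4.78)     # amplitudes, (mmol/L) / (mmol/kg)
AIF_WASHOUT_M = (0.144, 0.0111)  # decay rates, min^-1
AIF_BOLUS_PEAK = 4.5             # first-pass bolus amplitude, mmol/L
AIF_BOLUS_TP = 0.6               # time-to-peak of the bolus term, min
AIF_RISE_TAU = 0.12              # washout upslope time constant, min


@dataclass
class GroundTruthLesion:
    """A lesion with known voxelwise kinetics and its response class."""

    pk: PkMaps
    mask: np.ndarray
    class_label: str
    seed: int
    true_means: dict[str, float]


def make_population_aif(
    params: AcquisitionParams,
    times: np.ndarray,
    onset: float | None = None,
) -> AifCurve:
    """Closed-form population arterial input function.

    Zero before ``onset`` (default: end of the pre-contrast frames), then a
    first-pass bolus peak riding on a biexponential washout, all scaled by
    the injected dose.  Values are finite and non-negative everywhere.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise InvalidInputError("times must be nondecreasing")
    onset = params.bolus_onset if onset is None else float(onset)
    if not 0 <= onset <= times.max():
        raise InvalidInputError("onset must lie within the sampled interval")
    tau = np.maximum(times - onset, 0.0) / 60.0  # minutes post injection
    washout = params.dose * sum(
        a * np.exp(-m * tau) for a, m in zip(AIF_WASHOUT_A, AIF_WASHOUT_M)
    )
    bolus = AIF_BOLUS_PEAK * (tau / AIF_BOLUS_TP) ** 2 * np.exp(
        2.0 * (1.0 - tau / AIF_BOLUS_TP)
    )
    rise = 1.0 - np.exp(-((tau / AIF_RISE_TAU) ** 2))
    cp = bolus + washout * rise
    cp[times < onset] = 0.0
    return AifCurve(times=times, cp=cp)


def ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float] | None = None,
    radii: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Boolean ellipsoid inscribed in ``shape`` (default: the full grid)."""
    if center is None:
        center = tuple((n - 1) / 2.0 for n in shape)
    if radii is None:
        radii = tuple(n / 2.0 - 0.25 for n in shape)
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def _trunc_normal(rng, mean, sd, lower, upper, size=None):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _heterogeneity_field(rng, shape, mask, w: float, cv: float) -> np.ndarray:
    """Multiplicative field, mean ~1 with coefficient of variation cv in-mask.

    ``w`` in [0, 1] mixes a smooth and a fine-grained spatially correlated
    Gaussian field; higher w gives a rougher map and higher co-occurrence
    entropy.
    """

    def unit(sigma: float) -> np.ndarray:
        g = gaussian_filter(rng.standard_normal(shape), sigma)
        inside = g[mask]
        return (g - inside.mean()) / max(inside.std(), 1e-12)

    f = (1.0 - w) * unit(SMOOTH_SIGMA) + w * unit(ROUGH_SIGMA)
    inside = f[mask]
    f = (f - inside.mean()) / max(inside.std(), 1e-12)
    return np.clip(1.0 + cv * f, 0.05, None)


def make_lesion(
    class_label: str,
    shape: tuple[int, int, int] = (11, 11, 7),
    seed: int = 0,
    visit: str = "post",
) -> GroundTruthLesion:
    """Generate one ground-truth lesion of the given response class.

    The lesion-level mean of each kinetic parameter is drawn from a
    truncated normal with the class/visit group moments (Ktrans > 0,
    ve in (0, 1)); voxels are the lesion mean modulated by the class's
    spatially correlated heterogeneity field.  kep is Ktrans/ve.
    """
    if class_label not in ("CR", "PR"):
        raise InvalidInputError(f"unknown class label {class_label!r}")
    if visit not in CLASS_MOMENTS:
        raise InvalidInputError(f"unknown visit {visit!r}")
    if any(n < 3 for n in shape):
        raise InvalidInputError("lesion grid must be at least 3x3x3")
    rng = np.random.default_rng(seed)
    moments = CLASS_MOMENTS[visit][class_label]
    mu_kt = _trunc_normal(rng, *moments["ktrans"], 1e-3, 5.0)
    mu_ve = _trunc_normal(rng, *moments["ve"], 5e-3, 0.95)
    mu_vp = _trunc_normal(rng, *moments["vp"], 1e-4, 0.2)
    mask = ellipsoid_mask(shape)

    w = float(rng.beta(*HETEROGENEITY[visit][class_label]))
    cv = FIELD_CV
    f_kt = _heterogeneity_field(rng, shape, mask, w, cv)
    f_ve = _heterogeneity_field(rng, shape, mask, w, cv)

    ktrans = np.full(shape, np.nan)
    ve = np.full(shape, np.nan)
    vp = np.full(shape, np.nan)
    ktrans[mask] = np.clip(mu_kt * f_kt[mask], 1e-4, 5.0)
    ve[mask] = np.clip(mu_ve * f_ve[mask], 1e-3, 0.999)
    vp[mask] = np.clip(
        mu_vp * _heterogeneity_field(rng, shape, mask, w, cv)[mask], 0.0, 0.5
    )
    kep = ktrans / ve
    pk = PkMaps(ktrans=ktrans, kep=kep, ve=ve, vp=vp, fit_ok=mask.copy())
    true_means = {"ktrans": float(mu_kt), "ve": float(mu_ve), "vp": float(mu_vp)}
    return GroundTruthLesion(
        pk=pk, mask=mask, class_label=class_label, seed=seed, true_means=true_means
    )


def make_lesion_table(
    n_cr: int,
    n_pr: int,
    seed: int = 0,
    lesion_shape: tuple[int, int, int] = (11, 11, 7),
    texture_config=None,
) -> "pd.DataFrame":
    """Fast cohort at the feature level: ground-truth maps -> texture -> table.

    Generates both visits for every patient, computes ROI means and the
    co-occurrence texture of the true Ktrans map, and returns the wide
    pre/post/change feature table.  This skips signal synthesis and
    refitting, so it carries the class effect sizes without estimation
    noise; use :func:`make_cohort` plus the estimation chain for the full
    image-level round trip.
    """
    from .features import LesionRecord, build_table
    from .texture import TextureConfig, lesion_texture

    texture_config = texture_config or TextureConfig()
    root = np.random.SeedSequence(seed)
    records = []
    labels = ["CR"] * n_cr + ["PR"] * n_pr
    for pidx, label in enumerate(labels):
        pid = f"P{pidx:03d}"
        for vidx, visit in enumerate(("pre", "post")):
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(pidx, vidx))
            lesion_seed = int(child.generate_state(1)[0] % (2**31))
            lesion = make_lesion(label, lesion_shape, seed=lesion_seed, visit=visit)
            tex = lesion_texture(lesion.pk.ktrans, lesion.mask, texture_config)
            records.append(
                LesionRecord(
                    patient_id=pid,
                    visit=visit,
                    group=label,
                    means=lesion.pk.roi_means(lesion.mask),
                    texture=tex,
                    n_voxels=int(lesion.mask.sum()),
                )
            )
    return build_table(records)


def forward_signal(
    lesion: GroundTruthLesion,
    aif: AifCurve,
    t10_map: T1Map,
    params: AcquisitionParams,
    extra_conc: np.ndarray | None = None,
) -> DynamicSeries:
    """Simulate the dynamic SPGR signal of a lesion.

    Per voxel: extended Tofts convolution of the AIF gives C(t); then
    1/T1(t) = 1/T1(0) + r1 C(t); then the steady-state SPGR signal at the
    dynamic flip angle.  Voxels outside the lesion mask take no contrast
    unless ``extra_conc`` (a 4D concentration grid, e.g. for a blood
    region) supplies it.  Baseline frames equal the pre-contrast signal
    because the AIF is zero before the bolus.
    """
    mask = lesion.mask
    if t10_map.t1.shape != mask.shape:
        raise DimensionError("T1 map grid does not match the lesion grid")
    times = aif.times
    conc = np.zeros(mask.shape + (times.size,))
    if extra_conc is not None:
        if extra_conc.shape != conc.shape:
            raise DimensionError("extra_conc grid does not match")
        conc += extra_conc
    if mask.any():
        conc[mask] = tofts_forward_many(
            lesion.pk.ktrans[mask], lesion.pk.kep[mask], lesion.pk.vp[mask], aif
        )
    r1_t = 1.0 / t10_map.t1[..., None] + params.relaxivity_r1 * conc
    signal = spgr_signal(t10_map.m0[..., None], 1.0 / r1_t, params)
    return DynamicSeries(signal=signal, times=times, params=params)


def _vfa_series(t10: T1Map, params: AcquisitionParams) -> list[np.ndarray]:
    return [
        spgr_signal(t10.m0, t10.t1, params, flip_angle=a) for a in params.flip_angles_t1
    ]


def make_cohort(
    n_cr: int,
    n_pr: int,
    noise_sd: float | None = None,
    seed: int = 0,
    out_dir: str | Path = ".",
    params: AcquisitionParams | None = None,
    vol_shape: tuple[int, int, int] = (20, 20, 10),
    lesion_shape: tuple[int, int, int] = (11, 11, 7),
) -> pd.DataFrame:
    """Write a full synthetic cohort (two visits per patient) to disk.

    Per patient and visit the generator writes a 4D dynamic NIfTI, a 4D
    multi-flip-angle baseline NIfTI (angles along the 4th axis), lesion and
    aorta masks, and appends a manifest row with the true lesion-mean
    parameters.  ``noise_sd`` is additive Gaussian noise in signal units
    (default: 2% of the mean pre-contrast lesion signal).  Returns the
    manifest, which is also written as ``manifest.csv``.
    """
    import nibabel as nib

    if n_cr < 1 or n_pr < 1:
        raise InvalidInputError("need at least one patient per class")
    params = params or AcquisitionParams()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    times = params.times
    aif = make_population_aif(params, times)
    affine = np.diag([1.2, 1.2, 5.0, 1.0])

    # fixed scene geometry: lesion ellipsoid in the left half, aorta column right
    lesion_origin = (2, 2, 1)
    aorta = np.zeros(vol_shape, dtype=bool)
    aorta[vol_shape[0] - 4 : vol_shape[0] - 1, vol_shape[1] - 4 : vol_shape[1] - 1, :] = True

    t10 = np.full(vol_shape, T10_TISSUE)
    t10[aorta] = T10_BLOOD
    m0 = np.full(vol_shape, 1000.0)
    t10_map = T1Map(t1=t10, m0=m0, valid=np.ones(vol_shape, dtype=bool))
    blood_conc = np.zeros(vol_shape + (times.size,))
    blood_conc[aorta] = aif.cp * (1.0 - params.hematocrit)

    root = np.random.SeedSequence(seed)
    rows = []
    labels = ["CR"] * n_cr + ["PR"] * n_pr
    for pidx, label in enumerate(labels):
        pid = f"{label}{pidx + 1:03d}" if label == "CR" else f"{label}{pidx - n_cr + 1:03d}"
        for visit in ("pre", "post"):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(pidx, 0 if visit == "pre" else 1)
            )
            lesion_seed = int(child.generate_state(1)[0] % (2**31))
            small = make_lesion(label, lesion_shape, seed=lesion_seed, visit=visit)
            # embed the lesion in the full volume
            mask = np.zeros(vol_shape, dtype=bool)
            sl = tuple(
                slice(o, o + n) for o, n in zip(lesion_origin, lesion_shape)
            )
            mask[sl] = small.mask
            pk_full = {}
            for name in ("ktrans", "kep", "ve", "vp"):
                grid = np.full(vol_shape, np.nan)
                grid[sl] = getattr(small.pk, name)
                pk_full[name] = grid
            embedded = GroundTruthLesion(
                pk=PkMaps(fit_ok=mask.copy(), **pk_full),
                mask=mask,
                class_label=label,
                seed=lesion_seed,
                true_means=small.true_means,
            )
            dyn = forward_signal(embedded, aif, t10_map, params, extra_conc=blood_conc)
            vfa = _vfa_series(t10_map, params)

            rng = np.random.default_rng(lesion_seed + 1)
            if noise_sd is None:
                sd = 0.02 * dyn.signal[mask][:, : params.n_baseline].mean()
            else:
                sd = noise_sd
            signal = dyn.signal + (rng.standard_normal(dyn.signal.shape) * sd if sd > 0 else 0.0)
            vfa_stack = np.stack(vfa, axis=-1)
            if sd > 0:
                vfa_stack = vfa_stack + rng.standard_normal(vfa_stack.shape) * sd

            prefix = out / f"{pid}_{visit}"
            paths = {
                "dynamic_path": f"{prefix}_dyn.nii.gz",
                "vfa_path": f"{prefix}_vfa.nii.gz",
                "lesion_mask_path": f"{prefix}_lesion.nii.gz",
                "aorta_mask_path": f"{prefix}_aorta.nii.gz",
            }
            nib.save(nib.Nifti1Image(signal, affine), paths["dynamic_path"])
            nib.save(nib.Nifti1Image(vfa_stack, affine), paths["vfa_path"])
            nib.save(
                nib.Nifti1Image(mask.astype(np.uint8), affine), paths["lesion_mask_path"]
            )
            nib.save(
                nib.Nifti1Image(aorta.astype(np.uint8), affine), paths["aorta_mask_path"]
            )
            rows.append(
                {
                    "patient_id": pid,
                    "class": label,
                    "visit": visit,
                    **{k: str(Path(v).name) for k, v in paths.items()},
                    "true_ktrans_mean": small.true_means["ktrans"],
                    "true_ve_mean": small.true_means["ve"],
                    "true_vp_mean": small.true_means["vp"],
                    "lesion_seed": lesion_seed,
                    "noise_sd": sd,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    aif.to_csv(out / "population_aif.csv")
    return manifest
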