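"""Volume I/O, masks and run configuration.

All image data travel as NIfTI-1; masks must share their image's grid and
affine (within a small tolerance) because no resampling is performed — the
per-visit volumes are assumed intrinsically co-registered.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .acquisition import AcquisitionParams
from .errors import DimensionError, InvalidInputError
from .texture import TextureConfig

AFFINE_TOL = 1e-4


@dataclass
class Volume:
    data: np.ndarray
    affine: np.ndarray
    path: str | None = None


@dataclass
class RoiMask:
    """Boolean region mask with a provenance label (lesion | aorta)."""

    data: np.ndarray
    label: str = "lesion"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DimensionError("mask must be 3D")


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume, preserving data and affine geometry."""
    img = nib.load(str(path))
    return Volume(
        data=np.asarray(img.dataobj, dtype=float),
        affine=np.asarray(img.affine),
        path=str(path),
    )


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def read_mask(path: str | Path, image: Volume, label: str = "lesion") -> RoiMask:
    """Read a mask and verify it is congruent with its image."""
    vol = read_volume(path)
    if vol.data.shape != image.data.shape[:3]:
        raise DimensionError(
            f"mask {path} shape {vol.data.shape} does not match image "
            f"{image.path} shape {image.data.shape[:3]}"
        )
    if not np.allclose(vol.affine, image.affine, atol=AFFINE_TOL):
        raise DimensionError(f"mask {path} and image {image.path} affines differ")
    return RoiMask(data=vol.data > 0, label=label, affine=vol.affine)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "perfutex_out"
    seed: int = 0
    n_cr: int = 16
    n_pr: int = 16
    noise_sd: float | None = None
    vol_shape: tuple[int, int, int] = (20, 20, 10)
    lesion_shape: tuple[int, int, int] = (11, 11, 7)
    conversion_method: str = "linear"
    hematocrit_correction: bool = True
    linear_fit_only: bool = False
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    texture: TextureConfig = field(default_factory=TextureConfig)
    alpha: float = 0.05
    rho_threshold: float = 0.6
    positive_class: str = "CR"

    def __post_init__(self) -> None:
        self.vol_shape = tuple(self.vol_shape)
        self.lesion_shape = tuple(self.lesion_shape)
        if any(v < l for v, l in zip(self.vol_shape, self.lesion_shape)):
            raise InvalidInputError("lesion_shape must fit inside vol_shape")
        if self.conversion_method not in ("linear", "exact"):
            raise InvalidInputError("conversion_method must be 'linear' or 'exact'")
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")
        if not 0 < self.rho_threshold <= 1:
            raise InvalidInputError("rho_threshold must be in (0, 1]")
        if self.positive_class not in ("CR", "PR"):
            raise InvalidInputError("positive_class must be CR or PR")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        acq = AcquisitionParams(**raw.pop("acquisition", {}))
        tex = TextureConfig(**raw.pop("texture", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(acquisition=acq, texture=tex, **raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["acquisition"]["flip_angles_t1"] = list(
            payload["acquisition"]["flip_angles_t1"]
        )
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
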