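"""3D gray-level co-occurrence matrix (GLCM) and Haralick-type features.

A lesion's parameter map is quantized to ``n_levels`` equal-width gray
levels inside the mask, co-occurrences are counted over the 13 unique 3D
direction offsets at a given voxel distance (pooled into a single matrix,
symmetric by default), and seven scalar features are derived:

    energy              sum p^2
    entropy             -sum p log2 p          (0 log 0 = 0)
    inertia (contrast)  sum (i - j)^2 p
    correlation         sum (i - mu_i)(j - mu_j) p / (sigma_i sigma_j)
    cluster shade       sum (i + j - mu_i - mu_j)^3 p
    cluster prominence  sum (i + j - mu_i - mu_j)^4 p
    IDM (homogeneity)   sum p / (1 + (i - j)^2)

Entropy uses log base 2 by default (bits); the base is configurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "OFFSETS_3D",
    "Glcm",
    "TextureFeatures",
    "TextureConfig",
    "quantize",
    "glcm_3d",
    "texture_features",
    "lesion_texture",
]

#: the 13 unique direction offsets of the 26-connected 3D neighbourhood
#: (one of each antipodal pair)
OFFSETS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass
class Glcm:
    """Normalized co-occurrence probability matrix over gray levels 1..n."""

    p: np.ndarray
    n_levels: int
    offsets: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.p.shape != (self.n_levels, self.n_levels):
            raise InvalidInputError("GLCM must be n_levels x n_levels")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-9:
            raise InvalidInputError("GLCM entries must be non-negative and sum to 1")


@dataclass
class TextureFeatures:
    energy: float
    entropy: float
    inertia: float
    correlation: float
    cluster_shade: float
    cluster_prominence: float
    idm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "energy": self.energy,
            "entropy": self.entropy,
            "inertia": self.inertia,
            "correlation": self.correlation,
            "cluster_shade": self.cluster_shade,
            "cluster_prominence": self.cluster_prominence,
            "idm": self.idm,
        }


@dataclass
class TextureConfig:
    """Texture-stage settings: gray levels, offset distance, source map."""

    n_levels: int = 32
    distance: int = 1
    symmetric: bool = True
    source_map: str = "ktrans"
    log_base: float = 2.0


def quantize(values: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width min-max binning of in-mask values into levels 1..n_levels.

    Levels are 0 outside the mask.  The binning is invariant to affine
    rescaling of the input; a constant map quantizes to a single level 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("mask is empty")
    if n_levels < 2:
        raise InvalidInputError("n_levels must be >= 2")
    v = np.asarray(values, dtype=float)
    if v.ndim != 3 or v.shape != mask.shape:
        raise InvalidInputError("values must be a 3D grid congruent with the mask")
    inside = v[mask]
    if not np.all(np.isfinite(inside)):
        raise InvalidInputError("non-finite values inside mask")
    vmin, vmax = inside.min(), inside.max()
    q = np.zeros(v.shape, dtype=np.int32)
    if vmax == vmin:
        q[mask] = 1
        return q
    width = (vmax - vmin) / n_levels
    levels = np.floor((inside - vmin) / width).astype(np.int32) + 1
    q[mask] = np.clip(levels, 1, n_levels)
    return q


def glcm_3d(
    q: np.ndarray,
    mask: np.ndarray,
    distance: int = 1,
    symmetric: bool = True,
    n_levels: int | None = None,
) -> Glcm:
    """Pooled 3D GLCM over the 13 direction offsets at ``distance``.

    Only voxel pairs with both ends inside the mask contribute; symmetric
    mode adds the transposed counts before normalization.
    """
    mask = np.asarray(mask, dtype=bool)
    q = np.asarray(q)
    if q.ndim != 3 or q.shape != mask.shape:
        raise InvalidInputError("quantized grid must be 3D and congruent with the mask")
    if distance < 1:
        raise InvalidInputError("distance must be >= 1")
    if mask.sum() < 2:
        raise InvalidInputError("mask must contain at least 2 voxels")
    if n_levels is None:
        n_levels = int(q[mask].max())
    counts = np.zeros((n_levels, n_levels), dtype=float)
    for off in OFFSETS_3D:
        dx, dy, dz = (distance * o for o in off)
        src = _shift_slices(q.shape, dx, dy, dz)
        dst = _shift_slices(q.shape, -dx, -dy, -dz)
        pair_ok = mask[src] & mask[dst]
        a = q[src][pair_ok] - 1
        b = q[dst][pair_ok] - 1
        np.add.at(counts, (a, b), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise InvalidInputError("no co-occurring voxel pairs inside the mask")
    return Glcm(p=counts / total, n_levels=n_levels, offsets=OFFSETS_3D)


def _shift_slices(shape, dx: int, dy: int, dz: int) -> tuple[slice, slice, slice]:
    """Slices selecting voxels whose neighbour at (dx,dy,dz) stays in-grid."""

    def ax(n: int, d: int) -> slice:
        if d >= 0:
            return slice(0, n - d)
        return slice(-d, n)

    return (ax(shape[0], dx), ax(shape[1], dy), ax(shape[2], dz))


def texture_features(g: Glcm, log_base: float = 2.0) -> TextureFeatures:
    """The seven scalar co-occurrence features of a GLCM.

    Correlation is NaN (missing) when either marginal is degenerate
    (sigma = 0), e.g. for a constant region.
    """
    p = g.p
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise InvalidInputError("GLCM must be normalized")
    n = g.n_levels
    i = np.arange(1, n + 1)[:, None].astype(float)
    j = np.arange(1, n + 1)[None, :].astype(float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    lv = np.arange(1, n + 1, dtype=float)
    mu_i = float(lv @ pi)
    mu_j = float(lv @ pj)
    var_i = float(((lv - mu_i) ** 2) @ pi)
    var_j = float(((lv - mu_j) ** 2) @ pj)

    energy = float((p**2).sum())
    nz = p > 0
    entropy = float(-(p[nz] * (np.log(p[nz]) / np.log(log_base))).sum())
    inertia = float(((i - j) ** 2 * p).sum())
    sig = np.sqrt(var_i * var_j)
    if sig > 0:
        correlation = float((((i - mu_i) * (j - mu_j) * p).sum()) / sig)
    else:
        correlation = float("nan")
    dev = i + j - mu_i - mu_j
    cluster_shade = float((dev**3 * p).sum())
    cluster_prominence = float((dev**4 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    return TextureFeatures(
        energy=energy,
        entropy=entropy,
        inertia=inertia,
        correlation=correlation,
        cluster_shade=cluster_shade,
        cluster_prominence=cluster_prominence,
        idm=idm,
    )


def lesion_texture(
    values: np.ndarray,
    mask: np.ndarray,
    config: TextureConfig | None = None,
) -> TextureFeatures:
    """Quantize -> 3D GLCM -> features for one lesion map."""
    config = config or TextureConfig()
    q = quantize(values, mask, config.n_levels)
    g = glcm_3d(
        q,
        mask,
        distance=config.distance,
        symmetric=config.symmetric,
        n_levels=config.n_levels,
    )
    return texture_features(g, log_base=config.log_base)
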