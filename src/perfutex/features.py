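"""Per-lesion aggregation into the pre/post/change feature table.

Each patient contributes one lesion at two visits (pre- and
post-treatment).  ROI means of the four kinetic parameters and the seven
co-occurrence texture features are collected per visit, then pivoted into a
wide table with ``<feature>_pre``, ``<feature>_post`` and
``<feature>_change`` columns, where change = post - pre exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingVisitError
from .pkfit import PkMaps
from .texture import TextureFeatures

__all__ = ["PK_FEATURES", "TEXTURE_FEATURES", "ALL_FEATURES", "LesionRecord",
           "summarize_lesion", "build_table"]

log = logging.getLogger(__name__)

PK_FEATURES = ("ktrans", "kep", "ve", "vp")
TEXTURE_FEATURES = (
    "energy", "entropy", "inertia", "correlation",
    "cluster_shade", "cluster_prominence", "idm",
)
ALL_FEATURES = PK_FEATURES + TEXTURE_FEATURES


@dataclass
class LesionRecord:
    """One lesion at one visit: ROI means plus texture features."""

    patient_id: str
    visit: str       # "pre" or "post"
    group: str       # "CR" or "PR"
    means: dict[str, float]
    texture: TextureFeatures
    n_voxels: int = 0

    def as_row(self) -> dict[str, float | str]:
        return {
            "patient_id": self.patient_id,
            "visit": self.visit,
            "group": self.group,
            **self.means,
            **self.texture.as_dict(),
        }


def summarize_lesion(
    pk: PkMaps,
    tex: TextureFeatures,
    mask: np.ndarray,
    meta: dict[str, str],
) -> LesionRecord:
    """ROI means over successfully fitted voxels, plus the texture features.

    ``meta`` must carry ``patient_id``, ``visit`` and ``group``.  Voxels
    with ``fit_ok`` False are excluded from every mean; a lesion with no
    usable voxel raises an error naming it.
    """
    mask = np.asarray(mask, dtype=bool)
    sel = mask & pk.fit_ok
    if not sel.any():
        raise InvalidInputError(
            f"lesion {meta.get('patient_id')}/{meta.get('visit')}: "
            "no successfully fitted voxels"
        )
    means = pk.roi_means(mask)
    record = LesionRecord(
        patient_id=str(meta["patient_id"]),
        visit=str(meta["visit"]),
        group=str(meta["group"]),
        means=means,
        texture=tex,
        n_voxels=int(sel.sum()),
    )
    log.debug("lesion %s/%s: %d voxels", record.patient_id, record.visit, record.n_voxels)
    return record


def build_table(records: list[LesionRecord]) -> pd.DataFrame:
    """Pivot per-visit records into the wide pre/post/change feature table.

    Patients missing either visit are excluded with a warning; a patient
    whose group label differs between visits is an error.
    """
    if not records:
        raise InvalidInputError("no lesion records")
    long = pd.DataFrame([r.as_row() for r in records])
    features = [c for c in long.columns if c not in ("patient_id", "visit", "group")]

    groups = long.groupby("patient_id")["group"].nunique()
    if (groups > 1).any():
        bad = groups[groups > 1].index.tolist()
        raise InvalidInputError(f"inconsistent group labels for patients: {bad}")

    visit_counts = long.pivot_table(
        index="patient_id", columns="visit", values=features[0], aggfunc="count"
    )
    complete = visit_counts.reindex(columns=["pre", "post"]).notna().all(axis=1)
    dropped = complete.index[~complete].tolist()
    if dropped:
        log.warning("excluding patients with a missing visit: %s", dropped)
    keep = complete.index[complete]
    if len(keep) == 0:
        raise MissingVisitError(f"no patient has both visits (dropped: {dropped})")

    wide = long[long["patient_id"].isin(keep)].pivot(
        index="patient_id", columns="visit", values=features
    )
    out = pd.DataFrame(index=wide.index)
    for f in features:
        out[f"{f}_pre"] = wide[(f, "pre")]
        out[f"{f}_post"] = wide[(f, "post")]
        out[f"{f}_change"] = wide[(f, "post")] - wide[(f, "pre")]
    out["group"] = long.drop_duplicates("patient_id").set_index("patient_id")["group"]
    return out.reset_index()
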