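"""Structure-mask morphology: PTV-based truncation, length, volume, Dice.

The rectum is an open-ended organ, so observers disagree most about its
superior/inferior limits.  Truncating the contour to the cranio-caudal
extent of the PTV (optionally plus a margin) removes exactly that source
of variation; these operations quantify what truncation changes.

Slice membership is decided by the slice-centre z coordinate against the
closed interval ``[ptv_inferior - margin, ptv_superior + margin]`` — exact
on the lattice for any dz.  Cranio-caudal length is the occupied-slice span
(count × dz) rather than a coordinate difference, so a single-slice organ
has length dz, not zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .grids import StructureMask, require_same_grid

log = logging.getLogger(__name__)

__all__ = [
    "MorphologySummary",
    "truncate_to_ptv",
    "structure_length",
    "structure_volume",
    "dice",
    "morphology_table",
]


@dataclass
class MorphologySummary:
    """Length/volume of a structure, plus pairwise Dice where applicable."""

    length_cm: float
    volume_cc: float
    dice: float | None = None

    def __post_init__(self) -> None:
        if self.length_cm < 0 or self.volume_cc < 0:
            raise GeometryError("length and volume must be non-negative")
        if self.dice is not None and not (0.0 <= self.dice <= 1.0):
            raise GeometryError("Dice coefficient must lie in [0, 1]")


def truncate_to_ptv(
    organ: StructureMask, ptv: StructureMask, margin_cm: float = 0.0
) -> StructureMask:
    """Restrict ``organ`` to slices within ``margin_cm`` of the PTV z-extent.

    In-plane voxels are untouched; only whole slices are dropped.  An empty
    result is permitted (the caller excludes such patients downstream) but
    is flagged with a warning.
    """
    require_same_grid(organ, ptv, "truncate_to_ptv")
    if margin_cm < 0:
        raise GeometryError(f"margin_cm must be >= 0, got {margin_cm}")
    ptv_slices = ptv.occupied_slices()
    if ptv_slices.size == 0:
        raise GeometryError("PTV is empty; cannot define a truncation extent")

    z = organ.slice_centers_z()
    z_inf = organ.origin[2] + organ.spacing[2] * ptv_slices[0]
    z_sup = organ.origin[2] + organ.spacing[2] * ptv_slices[-1]
    keep = (z >= z_inf - margin_cm) & (z <= z_sup + margin_cm)

    occ = organ.occupancy.copy()
    occ[:, :, ~keep] = False
    out = StructureMask(
        organ.origin.copy(), organ.spacing.copy(), occ,
        name=f"{organ.name}_ptv{margin_cm:g}",
    )
    if out.is_empty():
        log.warning(
            "truncation of %r to PTV +/- %g cm left no occupied voxels", organ.name, margin_cm
        )
    return out


def structure_length(organ: StructureMask) -> float:
    """Cranio-caudal extent: occupied-slice span × dz (cm)."""
    occ = organ.occupied_slices()
    if occ.size == 0:
        raise GeometryError(f"structure {organ.name!r} is empty; length undefined")
    return float((occ[-1] - occ[0] + 1) * organ.spacing[2])


def structure_volume(organ: StructureMask) -> float:
    """Occupied-voxel count × voxel volume (cc); 0 for an empty mask."""
    return organ.voxel_count() * organ.voxel_volume_cc


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|)."""
    require_same_grid(a, b, "dice")
    na, nb = a.voxel_count(), b.voxel_count()
    if na + nb == 0:
        raise GeometryError("Dice undefined: both masks are empty")
    inter = int(np.count_nonzero(a.occupancy & b.occupancy))
    return 2.0 * inter / (na + nb)


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(x)),
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


def morphology_table(
    pairs: dict[str, list[tuple[StructureMask, StructureMask]]],
) -> pd.DataFrame:
    """Cohort morphology summary for (original, reviewed) mask pairs.

    ``pairs`` maps a rectum-definition label (e.g. ``"whole"``,
    ``"ptv2cm"``, ``"ptv0cm"``) to a list of per-patient mask pairs.
    Returns one row per definition with median/IQR of length, volume,
    their reviewed-minus-original differences, and Dice.  Patients whose
    mask is empty under a definition are skipped for that definition.
    """
    rows = []
    for definition, mask_pairs in pairs.items():
        lo, lr, vo, vr, dsc = [], [], [], [], []
        skipped = 0
        for orig, rev in mask_pairs:
            if orig.is_empty() or rev.is_empty():
                skipped += 1
                continue
            lo.append(structure_length(orig))
            lr.append(structure_length(rev))
            vo.append(structure_volume(orig))
            vr.append(structure_volume(rev))
            dsc.append(dice(orig, rev))
        if skipped:
            log.info("morphology_table: %d empty-mask patients skipped for %r", skipped, definition)
        if not lo:
            continue
        lo, lr = np.asarray(lo), np.asarray(lr)
        vo, vr = np.asarray(vo), np.asarray(vr)
        row: dict[str, float | str | int] = {"definition": definition, "n": len(lo)}
        for label, arr in [
            ("length_original_cm", lo),
            ("length_reviewed_cm", lr),
            ("length_diff_cm", lr - lo),
            ("volume_original_cc", vo),
            ("volume_reviewed_cc", vr),
            ("volume_diff_cc", vr - vo),
            ("dice", np.asarray(dsc)),
        ]:
            med, q1, q3 = _median_iqr(arr)
            row[f"{label}_median"] = med
            row[f"{label}_q1"] = q1
            row[f"{label}_q3"] = q3
        rows.append(row)
    return pd.DataFrame(rows)
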