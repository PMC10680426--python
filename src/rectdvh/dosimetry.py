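"""Cumulative DVH computation and EQD2 harmonisation of dose levels.

A cumulative dose-volume histogram (DVH) gives, at each dose level D, the
volume of a structure receiving at least D — as a percentage of the
structure (relative) or in cc (absolute).  Dose levels of interest are
defined on the 74 Gy / 37 fraction regimen (2 Gy per fraction) and mapped
onto hypofractionated regimens so that they are iso-effective under the
linear-quadratic model:

    EQD2(D, n) = D * (D/n + α/β) / (2 + α/β)

with α/β = 3 Gy for late rectal effects.  Rather than transforming the dose
grid voxelwise, each query level is converted to the physical dose that is
EQD2-equivalent for the patient's fractionation — the physical DVH is left
untouched.  Mapped levels are written V30*, ..., V74*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DosimetryError
from .grids import DoseGrid, StructureMask, require_same_grid
from .regimens import Arm

log = logging.getLogger(__name__)

__all__ = [
    "DVH",
    "DoseLevelSet",
    "REFERENCE_LEVELS_7",
    "REFERENCE_LEVELS_6",
    "ALPHA_BETA_LATE_RECTUM",
    "compute_dvh",
    "eqd2",
    "physical_dose_for_eqd2",
    "dose_levels_for_arm",
    "volume_at_dose",
    "mean_dvh",
]

#: Reference dose levels (Gy at 2 Gy/Fr).  The 7-level set, including 65 Gy,
#: is the modelling default; the 6-level set is the constraint-style list.
REFERENCE_LEVELS_7: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 65.0, 70.0, 74.0)
REFERENCE_LEVELS_6: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 70.0, 74.0)

#: α/β (Gy) representing late rectal toxicity.
ALPHA_BETA_LATE_RECTUM: float = 3.0


@dataclass
class DVH:
    """Cumulative DVH sampled at ascending dose edges.

    ``cum_rel[i]`` is the % of the structure receiving >= ``dose_edges[i]``;
    ``cum_abs`` the same in cc.  ``cum_rel[0]`` is exactly 100 (edges start
    at 0 Gy and dose is non-negative).
    """

    dose_edges: np.ndarray
    cum_rel: np.ndarray
    cum_abs: np.ndarray
    total_volume_cc: float

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.cum_rel = np.asarray(self.cum_rel, dtype=float)
        self.cum_abs = np.asarray(self.cum_abs, dtype=float)
        if np.any(np.diff(self.dose_edges) <= 0):
            raise DosimetryError("dose_edges must be strictly ascending")
        if np.any(np.diff(self.cum_rel) > 1e-12) or np.any(np.diff(self.cum_abs) > 1e-12):
            raise DosimetryError("cumulative DVH must be non-increasing")

    @property
    def max_dose(self) -> float:
        return float(self.dose_edges[-1])


def compute_dvh(dose: DoseGrid, organ: StructureMask, bin_width: float = 0.1) -> DVH:
    """Cumulative histogram of voxel doses inside ``organ``.

    Edges run from 0 Gy to just past the maximum organ dose in steps of
    ``bin_width``; cumulative values are exact counts at each edge (voxels
    with dose >= edge), so no binning error enters at the edges themselves.
    """
    require_same_grid(organ, dose, "compute_dvh")
    if organ.is_empty():
        raise DosimetryError(f"cannot compute DVH of empty structure {organ.name!r}")
    if bin_width <= 0:
        raise DosimetryError("bin_width must be positive")

    doses = np.sort(dose.dose[organ.occupancy])
    n = doses.size
    n_bins = int(math.ceil(doses[-1] / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    # voxels with dose >= edge, via binary search on the sorted doses
    count_ge = n - np.searchsorted(doses, edges, side="left")
    total_volume = n * organ.voxel_volume_cc
    return DVH(
        dose_edges=edges,
        cum_rel=100.0 * count_ge / n,
        cum_abs=count_ge * organ.voxel_volume_cc,
        total_volume_cc=total_volume,
    )


def eqd2(total_dose_gy: float, n_fractions: float, alpha_beta_gy: float = ALPHA_BETA_LATE_RECTUM) -> float:
    """Equivalent dose in 2 Gy fractions of ``total_dose_gy`` given in ``n_fractions``."""
    if total_dose_gy <= 0 or n_fractions <= 0 or alpha_beta_gy <= 0:
        raise DosimetryError("eqd2 requires strictly positive inputs")
    d_per_fr = total_dose_gy / n_fractions
    return total_dose_gy * (d_per_fr + alpha_beta_gy) / (2.0 + alpha_beta_gy)


def physical_dose_for_eqd2(
    target_eqd2_gy: float, n_fractions: float, alpha_beta_gy: float = ALPHA_BETA_LATE_RECTUM
) -> float:
    """Physical dose D (Gy) in ``n_fractions`` whose EQD2 equals the target.

    Positive root of D²/n + αβ·D = E·(2+αβ), written in the cancellation-free
    form 2c / (αβ + sqrt(αβ² + 4c/n)) with c = E·(2+αβ).
    """
    if target_eqd2_gy <= 0 or n_fractions <= 0 or alpha_beta_gy <= 0:
        raise DosimetryError("physical_dose_for_eqd2 requires strictly positive inputs")
    c = target_eqd2_gy * (2.0 + alpha_beta_gy)
    return 2.0 * c / (alpha_beta_gy + math.sqrt(alpha_beta_gy**2 + 4.0 * c / n_fractions))


@dataclass
class DoseLevelSet:
    """Reference dose levels and their physical equivalents for one regimen."""

    reference_levels_gy: tuple[float, ...]
    alpha_beta_gy: float
    arm_n_fractions: int
    mapped_levels_gy: tuple[float, ...]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mapped_levels_gy) <= 0):
            raise DosimetryError("mapped dose levels must be strictly increasing")


def dose_levels_for_arm(
    reference_levels: tuple[float, ...],
    arm: Arm,
    alpha_beta_gy: float = ALPHA_BETA_LATE_RECTUM,
) -> DoseLevelSet:
    """Map the 2 Gy/Fr reference levels onto a regimen's physical doses.

    The 37-fraction arm is the reference (2 Gy/Fr is the EQD2 fixed point)
    and returns the levels unchanged; hypofractionated arms get the
    EQD2-equivalent physical dose per level.
    """
    if not isinstance(arm, Arm):
        raise ConfigError(f"unknown arm {arm!r}; expected one of {[a.label for a in Arm]}")
    if arm is Arm.FR37:
        mapped = tuple(float(v) for v in reference_levels)
    else:
        mapped = tuple(
            physical_dose_for_eqd2(v, arm.n_fractions, alpha_beta_gy) for v in reference_levels
        )
    return DoseLevelSet(
        reference_levels_gy=tuple(float(v) for v in reference_levels),
        alpha_beta_gy=alpha_beta_gy,
        arm_n_fractions=arm.n_fractions,
        mapped_levels_gy=mapped,
    )


def volume_at_dose(dvh: DVH, dose_gy: float, mode: str = "relative") -> float:
    """Volume receiving >= ``dose_gy``, linearly interpolated between edges.

    ``mode`` is ``"relative"`` (%) or ``"absolute"`` (cc).  Queries above the
    last edge return 0 (nothing receives more than the maximum dose).
    """
    if mode not in ("relative", "absolute"):
        raise DosimetryError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    if dose_gy < 0:
        raise DosimetryError("query dose must be non-negative")
    curve = dvh.cum_rel if mode == "relative" else dvh.cum_abs
    if dose_gy > dvh.max_dose:
        log.debug("volume_at_dose: %g Gy above max edge %g Gy, returning 0", dose_gy, dvh.max_dose)
        return 0.0
    return float(np.interp(dose_gy, dvh.dose_edges, curve))


def mean_dvh(
    dvhs: list[DVH], levels_gy: tuple[float, ...] | list[float], mode: str = "relative"
) -> np.ndarray:
    """Arithmetic mean of volume-at-dose across patients at each level."""
    if len(dvhs) == 0:
        raise DosimetryError("mean_dvh requires at least one DVH")
    vals = np.array([[volume_at_dose(d, lv, mode) for lv in levels_gy] for d in dvhs])
    return vals.mean(axis=0)
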