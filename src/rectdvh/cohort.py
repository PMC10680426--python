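"""Synthetic cohort generation: geometry, dose, contours, and toxicity.

Every downstream stage of the pipeline is exercised on cohorts generated
here, since real trial plans and toxicity records are not public.  A
patient is:

* a rectum modelled as a stack of filled circles along z (dz 0.5 cm,
  in-plane 0.2 cm by default) — coarse, but DVH behaviour on this lattice
  matches what the analysis needs;
* a PTV box abutting (and slightly overlapping) the anterior rectal wall,
  spanning most of the rectum's cranio-caudal extent but leaving
  uninvolved rectum inferiorly and superiorly;
* a dose field equal to the arm's prescription inside the PTV, decaying
  exponentially with Euclidean distance from the PTV surface outside it;
* a "reviewed" contour obtained by re-drawing the superior/inferior
  borders with the empirical border-change rates (43% superior, 32%
  inferior), extension copying the terminal slice cross-section;
* late toxicity per symptom drawn from a logistic model on the patient's
  true whole-rectum relative dose-bin covariates, with G2+ events nested
  inside G1+ events via a single latent uniform draw.

One root RNG seed is split into per-patient substreams
(``SeedSequence.spawn``), so cohorts are bitwise reproducible and
independent of generation order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import distance_transform_edt
from scipy.special import expit

from .dosimetry import REFERENCE_LEVELS_7, compute_dvh, dose_levels_for_arm, volume_at_dose
from .endpoints import LATE_VISIT_MONTHS, SYMPTOMS
from .errors import ConfigError, GeometryError, SimulationError
from .grids import DoseGrid, StructureMask
from .regimens import Arm

log = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "SyntheticPatient",
    "generate_cohort",
    "build_dose_field",
    "perturb_borders",
    "simulate_toxicity",
    "sample_covariates",
    "cohort_toxicity_table",
    "save_cohort",
    "load_cohort",
    "load_config",
    "save_config",
]

# fixed anatomical constants of the generator (cm)
_PTV_HALFWIDTH_X = 2.0       # lateral half-extent of the PTV box
_PTV_AP_EXTENT = 6.0         # anterior-posterior PTV extent
_GRID_PAD_Z = 2.0            # z headroom for border extensions
_RECTUM_BELOW_PTV = (1.0, 0.4)   # mean/SD of rectum extending below the PTV
_PTV_OVERLAP_DEPTH = (0.4, 0.1)  # mean/SD of PTV reach into the anterior wall
_COVARIATE_JITTER_SD = 0.05      # per-level lognormal jitter in the profile sampler


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Distributions are (mean, SD) in cm.  ``toxicity_coefficients`` is the
    intercept plus 7 slopes on the relative-volume dose-bin covariates
    (fractions in [0, 1]); per-symptom intercept shifts spread event rates
    across the five symptoms, and ``g2_severity_offset`` (logit units) sets
    how much rarer intervention-requiring (G2) events are than G1 events.
    """

    n_patients: int = 100
    arm_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    grid_spacing: tuple[float, float, float] = (0.2, 0.2, 0.5)
    rectum_length_dist: tuple[float, float] = (9.5, 1.5)
    rectum_radius_dist: tuple[float, float] = (1.5, 0.15)
    ptv_extent_dist: tuple[float, float] = (7.0, 0.8)
    border_shift_prob_sup: float = 0.43
    border_shift_prob_inf: float = 0.32
    border_shift_slices: tuple[int, int] = (1, 3)
    dose_falloff_scale: float = 2.0
    toxicity_coefficients: tuple[float, ...] = (-2.2, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 8.0)
    symptom_intercept_shifts: dict[str, float] = field(
        default_factory=lambda: {
            "frequency": 0.4,
            "bleeding": 0.0,
            "proctitis": 0.2,
            "sphincter_control": -0.9,
            "stricture_ulcer": -2.4,
        }
    )
    g2_severity_offset: float = 1.4
    followup_completion_prob: float = 0.85
    baseline_g1plus_prob: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError(f"n_patients must be >= 0, got {self.n_patients}")
        w = np.asarray(self.arm_weights, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ConfigError(f"arm_weights must be 3 non-negative values summing to 1, got {self.arm_weights}")
        if any(s <= 0 for s in self.grid_spacing):
            raise ConfigError(f"grid_spacing must be strictly positive, got {self.grid_spacing}")
        for name in ("rectum_length_dist", "rectum_radius_dist", "ptv_extent_dist"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ConfigError(f"{name} must have positive mean and SD >= 0, got {(mean, sd)}")
        for name in ("border_shift_prob_sup", "border_shift_prob_inf",
                     "followup_completion_prob", "baseline_g1plus_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.border_shift_slices
        if lo < 0 or hi < lo:
            raise ConfigError(f"border_shift_slices must be 0 <= min <= max, got {self.border_shift_slices}")
        if self.dose_falloff_scale <= 0:
            raise ConfigError(f"dose_falloff_scale must be positive, got {self.dose_falloff_scale}")
        if len(self.toxicity_coefficients) != 8:
            raise ConfigError("toxicity_coefficients must be intercept + 7 slopes")
        unknown = set(self.symptom_intercept_shifts) - set(SYMPTOMS)
        if unknown:
            raise ConfigError(f"symptom_intercept_shifts has unknown symptoms {sorted(unknown)}")


@dataclass
class SyntheticPatient:
    """One simulated trial patient (all masks share the dose grid lattice)."""

    patient_id: str
    arm: Arm
    dose: DoseGrid
    rectum_original: StructureMask
    rectum_reviewed: StructureMask
    ptv: StructureMask
    true_covariates: np.ndarray          # 7 whole-rectum relative volumes, fractions
    toxicity: pd.DataFrame               # long format: endpoint_name, visit_month, grade


# ---------------------------------------------------------------------------
# Dose field
# ---------------------------------------------------------------------------

def build_dose_field(
    ptv: StructureMask, prescription_gy: float, falloff_scale_cm: float
) -> DoseGrid:
    """Prescription dose inside the PTV, exponential falloff outside.

    ``dose(v) = prescription * exp(-dist(v, PTV) / falloff_scale)`` with
    Euclidean distance in cm — monotone in distance, strictly positive,
    never above prescription.
    """
    if ptv.is_empty():
        raise GeometryError("cannot build a dose field around an empty PTV")
    if prescription_gy <= 0 or falloff_scale_cm <= 0:
        raise GeometryError("prescription and falloff scale must be positive")
    dist = distance_transform_edt(~ptv.occupancy, sampling=tuple(ptv.spacing))
    dose = prescription_gy * np.exp(-dist / falloff_scale_cm)
    return DoseGrid(ptv.origin.copy(), ptv.spacing.copy(), dose)


# ---------------------------------------------------------------------------
# Border perturbation ("reviewed" contour)
# ---------------------------------------------------------------------------

def _shift_border(occ: np.ndarray, border: str, k: int, name: str) -> None:
    """Extend (k > 0) or remove (k < 0) |k| slices at one border, in place."""
    occupied = np.nonzero(occ.any(axis=(0, 1)))[0]
    lo, hi = int(occupied[0]), int(occupied[-1])
    nz = occ.shape[2]
    if k > 0:  # extension copies the terminal slice cross-section
        if border == "sup":
            end, stop = hi, min(hi + k, nz - 1)
            new = range(hi + 1, stop + 1)
        else:
            end, stop = lo, max(lo - k, 0)
            new = range(stop, lo)
        if len(new) < k:
            log.warning("border extension of %r clipped at the grid edge", name)
        template = occ[:, :, end].copy()
        for s in new:
            occ[:, :, s] = template
    elif k < 0:  # removal deletes slices, clamped to leave >= 1 slice
        n_slices = hi - lo + 1
        remove = min(-k, n_slices - 1)
        if remove < -k:
            log.warning("border removal would empty %r; clamped to 1 remaining slice", name)
        if border == "sup":
            occ[:, :, hi - remove + 1 : hi + 1] = False
        else:
            occ[:, :, lo : lo + remove] = False


def perturb_borders(
    mask: StructureMask,
    prob_sup: float,
    prob_inf: float,
    shift_range: tuple[int, int],
    rng: np.random.Generator,
    direction: int | None = None,
) -> StructureMask:
    """Interobserver-style re-draw of the superior/inferior borders.

    With probability ``prob_sup`` the superior border is shifted by a
    magnitude drawn uniformly from ``shift_range`` slices (inclusive),
    extension or removal equally likely (or forced via ``direction`` = +1 /
    -1); the inferior border analogously.  Extension copies the terminal
    slice's cross-section — an observer extending the same tube.  The
    result is never empty: removals are clamped to leave one slice.
    """
    if mask.is_empty():
        raise GeometryError("cannot perturb an empty structure")
    lo, hi = shift_range
    if lo < 0 or hi < lo:
        raise ConfigError(f"shift_range must satisfy 0 <= min <= max, got {shift_range}")
    out = mask.copy(name=f"{mask.name}_reviewed")
    for border, prob in (("sup", prob_sup), ("inf", prob_inf)):
        if rng.random() >= prob:
            continue
        magnitude = int(rng.integers(lo, hi + 1))
        sign = int(direction) if direction is not None else (1 if rng.random() < 0.5 else -1)
        if magnitude:
            _shift_border(out.occupancy, border, sign * magnitude, mask.name)
    return out


# ---------------------------------------------------------------------------
# Toxicity simulation
# ---------------------------------------------------------------------------

def simulate_toxicity(
    covariates: np.ndarray,
    coefficients: tuple[float, ...] | np.ndarray,
    followup_completion_prob: float,
    baseline_g1plus_prob: float,
    rng: np.random.Generator,
    g2_severity_offset: float = 1.4,
) -> list[dict]:
    """Visit-level grades for one symptom of one patient.

    The G1+ event probability is exactly ``expit(intercept + sum(beta*x))``
    and the G2+ probability ``expit(lp - g2_severity_offset)``; a single
    latent uniform draw makes G2+ events a subset of G1+ events.  Each of
    the 7 late visits is completed independently; when an event occurs,
    one uniformly chosen visit is forced to be completed and records the
    maximum grade, so the record always reflects the drawn event.
    Non-event patients never show an above-threshold grade.
    """
    x = np.asarray(covariates, dtype=float)
    coefs = np.asarray(coefficients, dtype=float)
    if x.shape != (7,) or not np.isfinite(x).all():
        raise SimulationError("expected 7 finite covariates")
    lp = float(coefs[0] + coefs[1:] @ x)
    if not math.isfinite(lp):
        raise SimulationError("non-finite linear predictor")
    p_g1 = expit(lp)
    p_g2 = expit(lp - g2_severity_offset)

    u = rng.random()
    max_grade = 2 if u < p_g2 else (1 if u < p_g1 else 0)
    baseline_grade = 1 if rng.random() < baseline_g1plus_prob else 0

    completed = rng.random(len(LATE_VISIT_MONTHS)) < followup_completion_prob
    grades = np.full(len(LATE_VISIT_MONTHS), np.nan)
    if max_grade >= 1:
        event_visit = int(rng.integers(0, len(LATE_VISIT_MONTHS)))
        completed[event_visit] = True
        grades[completed] = rng.integers(0, max_grade + 1, size=int(completed.sum()))
        grades[event_visit] = max_grade
    else:
        grades[completed] = 0.0

    rows = [{"visit_month": 0, "grade": float(baseline_grade)}]
    rows.extend(
        {"visit_month": month, "grade": float(g) if not np.isnan(g) else np.nan}
        for month, g in zip(LATE_VISIT_MONTHS, grades)
    )
    return rows


# ---------------------------------------------------------------------------
# Patient geometry and cohort assembly
# ---------------------------------------------------------------------------

def _draw_geometry(config: CohortConfig, rng: np.random.Generator) -> dict[str, float]:
    def clipped_normal(mean_sd, lo, hi):
        mean, sd = mean_sd
        return float(np.clip(rng.normal(mean, sd), lo, hi))

    return {
        "length": clipped_normal(config.rectum_length_dist, 5.0, 15.0),
        "radius": clipped_normal(config.rectum_radius_dist, 1.0, 2.0),
        "ptv_extent": clipped_normal(config.ptv_extent_dist, 4.0, 10.0),
        "below_ptv": clipped_normal(_RECTUM_BELOW_PTV, 0.0, 2.5),
        "overlap": clipped_normal(_PTV_OVERLAP_DEPTH, 0.1, 0.8),
    }


def _build_patient_masks(
    geo: dict[str, float], spacing: tuple[float, float, float]
) -> tuple[StructureMask, StructureMask]:
    dx, dy, dz = spacing
    ptv_inf = geo["below_ptv"]
    ptv_sup = ptv_inf + geo["ptv_extent"]
    z_min = -_GRID_PAD_Z
    z_max = max(geo["length"], ptv_sup) + _GRID_PAD_Z

    xs = np.arange(-2.0, 2.0 + dx / 2, dx)
    ys = np.arange(-2.0, 3.0 + dy / 2, dy)
    zs = np.arange(z_min, z_max + dz / 2, dz)
    origin = np.array([xs[0], ys[0], zs[0]])

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    disk = X**2 + Y**2 <= geo["radius"] ** 2
    rectum_z = (zs >= 0.0) & (zs <= geo["length"])
    rectum_occ = disk[:, :, None] & rectum_z[None, None, :]

    y_post = geo["radius"] - geo["overlap"]
    ptv_inplane = (np.abs(X) <= _PTV_HALFWIDTH_X) & (Y >= y_post) & (Y <= y_post + _PTV_AP_EXTENT)
    ptv_z = (zs >= ptv_inf) & (zs <= ptv_sup)
    ptv_occ = ptv_inplane[:, :, None] & ptv_z[None, None, :]

    rectum = StructureMask(origin, np.asarray(spacing), rectum_occ, name="rectum_original")
    ptv = StructureMask(origin.copy(), np.asarray(spacing), ptv_occ, name="ptv")
    return rectum, ptv


def _generate_patient(
    index: int, config: CohortConfig, rng: np.random.Generator
) -> SyntheticPatient:
    arm = list(Arm)[int(rng.choice(3, p=np.asarray(config.arm_weights, float)))]
    geo = _draw_geometry(config, rng)
    rectum, ptv = _build_patient_masks(geo, config.grid_spacing)
    dose = build_dose_field(ptv, arm.prescription_gy, config.dose_falloff_scale)
    reviewed = perturb_borders(
        rectum,
        config.border_shift_prob_sup,
        config.border_shift_prob_inf,
        config.border_shift_slices,
        rng,
    )

    dvh = compute_dvh(dose, rectum)
    levels = dose_levels_for_arm(REFERENCE_LEVELS_7, arm).mapped_levels_gy
    covariates = np.array(
        [volume_at_dose(dvh, lv, "relative") / 100.0 for lv in levels]
    )

    tox_rows = []
    for symptom in SYMPTOMS:
        coefs = np.asarray(config.toxicity_coefficients, dtype=float).copy()
        coefs[0] += config.symptom_intercept_shifts.get(symptom, 0.0)
        for row in simulate_toxicity(
            covariates,
            coefs,
            config.followup_completion_prob,
            config.baseline_g1plus_prob,
            rng,
            config.g2_severity_offset,
        ):
            tox_rows.append({"endpoint_name": symptom, **row})

    pid = f"P{index:06d}"
    toxicity = pd.DataFrame(tox_rows)
    toxicity.insert(0, "patient_id", pid)
    return SyntheticPatient(
        patient_id=pid,
        arm=arm,
        dose=dose,
        rectum_original=rectum,
        rectum_reviewed=reviewed,
        ptv=ptv,
        true_covariates=covariates,
        toxicity=toxicity,
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate a cohort; deterministic given ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    patients = []
    for i, child in enumerate(root.spawn(config.n_patients)):
        patients.append(_generate_patient(i, config, np.random.default_rng(child)))
    log.info(
        "generated %d patients (arms: %s)",
        len(patients),
        {a.label: sum(p.arm is a for p in patients) for a in Arm},
    )
    return patients


def cohort_toxicity_table(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Long-format toxicity records of a whole cohort."""
    if not patients:
        return pd.DataFrame(columns=["patient_id", "endpoint_name", "visit_month", "grade"])
    return pd.concat([p.toxicity for p in patients], ignore_index=True)


# ---------------------------------------------------------------------------
# Fast covariate sampler for large-n statistical harnesses
# ---------------------------------------------------------------------------

def _segment_fraction(depth: np.ndarray, radius: float) -> np.ndarray:
    """Area fraction of a disc within ``depth`` of its edge (circular segment)."""
    t = np.clip(depth, 0.0, 2.0 * radius)
    theta = 2.0 * np.arccos(np.clip(1.0 - t / radius, -1.0, 1.0))
    return (theta - np.sin(theta)) / (2.0 * np.pi)


def sample_covariates(
    n: int,
    config: CohortConfig | None = None,
    rng: np.random.Generator | int | None = None,
    arm: Arm = Arm.FR37,
) -> np.ndarray:
    """Draw (n, 7) relative-volume covariates from the slice-profile model.

    A semi-analytic mirror of the voxel generator: the same geometry
    distributions, with per-slice dose coverage computed from the circular
    cross-section and the exponential falloff instead of a voxel lattice,
    plus small per-level lognormal jitter standing in for residual
    contouring/planning variability.  Used by calibration and recovery
    harnesses where hundreds of thousands of patients are needed.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(rng)
    levels = np.asarray(dose_levels_for_arm(REFERENCE_LEVELS_7, arm).mapped_levels_gy)
    prescription = arm.prescription_gy
    s = config.dose_falloff_scale
    dz = config.grid_spacing[2]

    out = np.zeros((n, 7))
    for i in range(n):
        geo = _draw_geometry(config, rng)
        z = np.arange(dz / 2, geo["length"], dz)
        ptv_inf, ptv_sup = geo["below_ptv"], geo["below_ptv"] + geo["ptv_extent"]
        da = np.maximum(0.0, np.maximum(ptv_inf - z, z - ptv_sup))
        with np.errstate(divide="ignore"):
            budget = s * np.log(prescription / levels)   # depth budget per level
        t_max = geo["overlap"] + budget[None, :] - da[:, None]
        frac = _segment_fraction(t_max, geo["radius"])
        v = frac.mean(axis=0)
        v[levels > prescription] = 0.0
        v *= np.exp(rng.normal(0.0, _COVARIATE_JITTER_SD, size=7))
        out[i] = np.clip(v, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Config and cohort I/O
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {
    "arm_weights", "grid_spacing", "rectum_length_dist", "rectum_radius_dist",
    "ptv_extent_dist", "border_shift_slices", "toxicity_coefficients",
}


def load_config(path) -> CohortConfig:
    """Read a cohort config from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a key-value mapping")
    known = {f.name for f in fields(CohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    return CohortConfig(**raw)


def save_config(config: CohortConfig, path) -> None:
    data = {}
    for f in fields(CohortConfig):
        v = getattr(config, f.name)
        data[f.name] = list(v) if isinstance(v, tuple) else v
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def save_cohort(patients: list[SyntheticPatient], outdir, seed: int | None = None) -> None:
    """Write manifest CSV, per-patient compressed array containers, and the
    long-format toxicity CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "arrays").mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(
        {"patient_id": [p.patient_id for p in patients],
         "arm": [p.arm.label for p in patients],
         "seed": seed if seed is not None else "",}
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    cohort_toxicity_table(patients).to_csv(outdir / "toxicity.csv", index=False)
    for p in patients:
        np.savez_compressed(
            outdir / "arrays" / f"{p.patient_id}.npz",
            origin=p.dose.origin,
            spacing=p.dose.spacing,
            dose=p.dose.dose,
            rectum_original=p.rectum_original.occupancy,
            rectum_reviewed=p.rectum_reviewed.occupancy,
            ptv=p.ptv.occupancy,
            true_covariates=p.true_covariates,
            arm=p.arm.name,
        )


def load_cohort(outdir) -> list[SyntheticPatient]:
    from pathlib import Path

    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    toxicity = pd.read_csv(outdir / "toxicity.csv")
    patients = []
    for pid in manifest["patient_id"]:
        with np.load(outdir / "arrays" / f"{pid}.npz") as z:
            origin, spacing = z["origin"], z["spacing"]
            arm = Arm[str(z["arm"])]
            patients.append(
                SyntheticPatient(
                    patient_id=pid,
                    arm=arm,
                    dose=DoseGrid(origin, spacing, z["dose"]),
                    rectum_original=StructureMask(origin, spacing, z["rectum_original"], "rectum_original"),
                    rectum_reviewed=StructureMask(origin, spacing, z["rectum_reviewed"], "rectum_original_reviewed"),
                    ptv=StructureMask(origin, spacing, z["ptv"], "ptv"),
                    true_covariates=z["true_covariates"],
                    toxicity=toxicity[toxicity["patient_id"] == pid].reset_index(drop=True),
                )
            )
    return patients
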