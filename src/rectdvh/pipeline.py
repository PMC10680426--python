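"""End-to-end orchestration of the four definition-comparison hypotheses.

Given a synthetic cohort (or a user-supplied covariate/outcome table), the
pipeline runs: geometry (PTV truncations, morphology, Dice) → dosimetry
(DVHs, EQD2-mapped dose levels, covariate extraction) → endpoint
derivation → statistics (logistic fits, bootstrap, DeLong, per-level
Wilcoxon) and writes the result tables.  The four primary hypotheses each
compare the standard-of-care definition (whole rectum, original contour,
relative volumes) against an alternative:

    original_whole_rel  vs  reviewed_whole_rel    (contour review)
    original_whole_rel  vs  original_whole_abs    (absolute volumes)
    original_whole_rel  vs  original_ptv2_rel     (truncation, PTV ± 2 cm)
    original_whole_rel  vs  original_ptv0_rel     (truncation, PTV ± 0 cm)

Everything is deterministic given the master seed; per-(endpoint,
comparison) RNG substreams make endpoint results independent of execution
order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import endpoints as ep
from .cohort import CohortConfig, SyntheticPatient, cohort_toxicity_table, generate_cohort
from .dosimetry import (
    REFERENCE_LEVELS_6,
    REFERENCE_LEVELS_7,
    compute_dvh,
    dose_levels_for_arm,
    volume_at_dose,
)
from .errors import ConfigError, RectdvhError
from .geometry import morphology_table, truncate_to_ptv
from .regimens import Arm
from .stats import EXPLORATORY_ALPHA, compare_definitions, significance_policy, wilcoxon_signed_rank

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ComparisonReport", "run_pipeline", "exclusion_accounting",
           "DEFAULT_COMPARISONS", "DEFINITIONS"]

#: rectal-DVH definition labels usable in comparisons
DEFINITIONS = (
    "original_whole_rel",
    "reviewed_whole_rel",
    "original_whole_abs",
    "original_ptv2_rel",
    "original_ptv0_rel",
)

#: the four primary hypotheses, standard of care first
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("original_whole_rel", "reviewed_whole_rel"),
    ("original_whole_rel", "original_whole_abs"),
    ("original_whole_rel", "original_ptv2_rel"),
    ("original_whole_rel", "original_ptv0_rel"),
)


@dataclass
class RunConfig:
    """One pipeline run: cohort source, hypotheses, and statistical settings."""

    cohort_config: CohortConfig | None = None
    covariates_csv: str | Path | None = None
    outcomes_csv: str | Path | None = None
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS
    endpoints: tuple[str, ...] = tuple(lab for lab, _, _ in ep.ENDPOINT_LABELS)
    B: int = 2000
    seed: int = 0
    arm_filter: str = "all"
    outdir: str | Path | None = None
    n_levels: int = 7
    threshold_rule: str = "youden"

    def __post_init__(self) -> None:
        if not self.comparisons or not self.endpoints:
            raise ConfigError("at least one comparison and one endpoint must be selected")
        known = set(DEFINITIONS)
        for a, b in self.comparisons:
            if a not in known or b not in known:
                raise ConfigError(f"unknown definition in comparison ({a}, {b})")
        known_ep = {lab for lab, _, _ in ep.ENDPOINT_LABELS}
        bad = set(self.endpoints) - known_ep
        if bad:
            raise ConfigError(f"unknown endpoints: {sorted(bad)}")
        if self.n_levels not in (6, 7):
            raise ConfigError(f"n_levels must be 6 or 7, got {self.n_levels}")
        if self.cohort_config is None and self.covariates_csv is None:
            raise ConfigError("either cohort_config or covariates_csv must be given")

    @property
    def reference_levels(self) -> tuple[float, ...]:
        return REFERENCE_LEVELS_7 if self.n_levels == 7 else REFERENCE_LEVELS_6


@dataclass
class ComparisonReport:
    """All pipeline outputs for one run."""

    morphology: pd.DataFrame
    dose_levels: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    wilcoxon: pd.DataFrame
    comparisons: pd.DataFrame
    consort: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _level_columns(levels: tuple[float, ...]) -> list[str]:
    return [f"V{lv:g}*" for lv in levels]


# ---------------------------------------------------------------------------
# Covariate extraction from a voxel cohort
# ---------------------------------------------------------------------------

def _extract_covariates(
    patients: list[SyntheticPatient], reference_levels: tuple[float, ...]
) -> tuple[pd.DataFrame, set[str]]:
    """Long covariate table and the set of patients with an empty truncation."""
    cols = _level_columns(reference_levels)
    rows = []
    structure_excluded: set[str] = set()
    for p in patients:
        mapped = dose_levels_for_arm(reference_levels, p.arm).mapped_levels_gy
        masks = {
            "original_whole": p.rectum_original,
            "reviewed_whole": p.rectum_reviewed,
            "original_ptv0": truncate_to_ptv(p.rectum_original, p.ptv, 0.0),
            "original_ptv2": truncate_to_ptv(p.rectum_original, p.ptv, 2.0),
        }
        if any(m.is_empty() for m in masks.values()):
            structure_excluded.add(p.patient_id)
            log.info("patient %s excluded: empty structure after truncation", p.patient_id)
            continue
        for struct_label, mask in masks.items():
            dvh = compute_dvh(p.dose, mask)
            for mode in ("relative", "absolute"):
                if mode == "absolute" and struct_label not in ("original_whole", "reviewed_whole"):
                    continue
                vals = [volume_at_dose(dvh, lv, mode) for lv in mapped]
                rows.append(
                    {"patient_id": p.patient_id, "arm": p.arm.label,
                     "definition": f"{struct_label}_{'rel' if mode == 'relative' else 'abs'}",
                     **dict(zip(cols, vals))}
                )
    return pd.DataFrame(rows), structure_excluded


def _dose_level_table(reference_levels: tuple[float, ...]) -> pd.DataFrame:
    rows = []
    for arm in Arm:
        mapped = dose_levels_for_arm(reference_levels, arm).mapped_levels_gy
        for ref, phys in zip(reference_levels, mapped):
            rows.append({"arm": arm.label, "reference_level_gy": ref,
                         "physical_dose_gy": round(phys, 4)})
    return pd.DataFrame(rows)


def _wilcoxon_table(cov: pd.DataFrame, levels: tuple[float, ...]) -> pd.DataFrame:
    """Per-dose-level paired Wilcoxon: original vs reviewed, both modes."""
    cols = _level_columns(levels)
    rows = []
    for mode in ("rel", "abs"):
        a = cov[cov["definition"] == f"original_whole_{mode}"].set_index("patient_id")
        b = cov[cov["definition"] == f"reviewed_whole_{mode}"].set_index("patient_id")
        common = a.index.intersection(b.index)
        if len(common) == 0:
            continue
        for ref, col in zip(levels, cols):
            p = wilcoxon_signed_rank(a.loc[common, col].to_numpy(),
                                     b.loc[common, col].to_numpy())
            rows.append({"mode": mode, "level": col, "n": len(common), "wilcoxon_p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["significant_exploratory"] = significance_policy(
            out["wilcoxon_p"].to_numpy(), "exploratory_dose_levels"
        )
    return out


# ---------------------------------------------------------------------------
# CONSORT-style exclusion accounting
# ---------------------------------------------------------------------------

def exclusion_accounting(
    total_n: int, structure_excluded: set[str], outcomes: pd.DataFrame,
    endpoint_labels: tuple[str, ...],
) -> pd.DataFrame:
    """Per-endpoint counts at each exclusion stage; rows sum to the cohort total."""
    rows = []
    for label in endpoint_labels:
        statuses = outcomes[label] if label in outcomes else pd.Series(dtype=object)
        in_struct = statuses.index.difference(list(structure_excluded))
        s = statuses.loc[in_struct]
        analyzed = int(((s == ep.STATUS_CASE) | (s == ep.STATUS_CONTROL)).sum())
        row = {
            "endpoint": label,
            "cohort_total": total_n,
            "excluded_structures": len(structure_excluded),
            "excluded_baseline": int((s == ep.STATUS_EXCL_BASELINE).sum()),
            "excluded_insufficient_followup": int((s == ep.STATUS_EXCL_FOLLOWUP).sum()),
            "analyzed": analyzed,
        }
        assert (
            row["excluded_structures"] + row["excluded_baseline"]
            + row["excluded_insufficient_followup"] + row["analyzed"] == total_n
        ), "exclusion counts must partition the cohort"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Main entry point
# ---------------------------------------------------------------------------

def _load_csv_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    cov = pd.read_csv(config.covariates_csv)
    if config.outcomes_csv is None:
        raise ConfigError("covariates_csv mode requires outcomes_csv")
    out = pd.read_csv(config.outcomes_csv).set_index("patient_id")
    required = {"patient_id", "definition"}
    if not required <= set(cov.columns):
        raise ConfigError(f"covariates CSV must contain columns {sorted(required)}")
    return cov, out


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Execute the full comparison pipeline; deterministic given config.seed."""
    meta: dict = {"seed": config.seed, "B": config.B, "threshold_rule": config.threshold_rule,
                  "n_levels": config.n_levels, "arm_filter": config.arm_filter}

    if config.cohort_config is not None:
        patients = generate_cohort(config.cohort_config)
        if config.arm_filter != "all":
            arm = Arm.parse(config.arm_filter)
            patients = [p for p in patients if p.arm is arm]
            log.info("arm filter %s: %d patients retained", arm.label, len(patients))
        total_n = len(patients)
        morphology = morphology_table({
            "whole": [(p.rectum_original, p.rectum_reviewed) for p in patients],
            "ptv2cm": [
                (truncate_to_ptv(p.rectum_original, p.ptv, 2.0),
                 truncate_to_ptv(p.rectum_reviewed, p.ptv, 2.0))
                for p in patients
            ],
            "ptv0cm": [
                (truncate_to_ptv(p.rectum_original, p.ptv, 0.0),
                 truncate_to_ptv(p.rectum_reviewed, p.ptv, 0.0))
                for p in patients
            ],
        })
        covariates, structure_excluded = _extract_covariates(patients, config.reference_levels)
        outcomes = ep.build_outcome_table(cohort_toxicity_table(patients))
        wilcoxon = _wilcoxon_table(covariates, config.reference_levels)
    else:
        covariates, outcomes = _load_csv_inputs(config)
        if config.arm_filter != "all":
            arm = Arm.parse(config.arm_filter)
            covariates = covariates[covariates["arm"] == arm.label]
        total_n = outcomes.shape[0]
        structure_excluded = set()
        morphology = pd.DataFrame()
        wilcoxon = _wilcoxon_table(covariates, config.reference_levels) if not covariates.empty else pd.DataFrame()

    dose_levels = _dose_level_table(config.reference_levels)
    consort = exclusion_accounting(total_n, structure_excluded, outcomes, config.endpoints)

    cols = _level_columns(config.reference_levels)
    wide = {
        d: covariates[covariates["definition"] == d].set_index("patient_id")[cols]
        for d in DEFINITIONS
        if (covariates["definition"] == d).any()
    } if not covariates.empty else {}

    # RNG substreams are keyed on global endpoint/definition identity so a
    # model's results do not depend on which other endpoints were selected
    all_endpoints = [lab for lab, _, _ in ep.ENDPOINT_LABELS]

    comp_rows = []
    for label in config.endpoints:
        e_idx = all_endpoints.index(label)
        if label not in outcomes.columns:
            log.warning("endpoint %s missing from outcomes; skipped", label)
            continue
        status = outcomes[label]
        usable = status[(status == ep.STATUS_CASE) | (status == ep.STATUS_CONTROL)]
        usable = usable[~usable.index.isin(structure_excluded)]
        for label_a, label_b in config.comparisons:
            row: dict = {"endpoint": label, "definition_a": label_a, "definition_b": label_b}
            if label_a not in wide or label_b not in wide:
                row.update({"n": 0, "note": "covariates unavailable"})
                comp_rows.append(row)
                continue
            ids = usable.index.intersection(wide[label_a].index).intersection(wide[label_b].index)
            y = (usable.loc[ids] == ep.STATUS_CASE).to_numpy().astype(float)
            if ids.size == 0 or y.sum() == 0 or y.sum() == y.size:
                row.update({"n": int(ids.size), "note": "degenerate stratum; model skipped"})
                log.warning("endpoint %s / %s vs %s: degenerate stratum (n=%d)",
                            label, label_a, label_b, ids.size)
                comp_rows.append(row)
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.seed, e_idx, DEFINITIONS.index(label_a), DEFINITIONS.index(label_b)]
                )
            )
            mc = compare_definitions(
                wide[label_a].loc[ids].to_numpy(),
                wide[label_b].loc[ids].to_numpy(),
                y,
                label_a,
                label_b,
                B=config.B,
                rng=rng,
                threshold_rule=config.threshold_rule,
            )
            for side, perf in (("a", mc.performance_a), ("b", mc.performance_b)):
                row[f"auc_{side}"] = perf.auc
                row[f"auc_ci_lo_{side}"] = perf.auc_ci[0] if perf.auc_ci else math.nan
                row[f"auc_ci_hi_{side}"] = perf.auc_ci[1] if perf.auc_ci else math.nan
                row[f"sens632_{side}"] = perf.sens632
                row[f"spec632_{side}"] = perf.spec632
                row[f"ppv632_{side}"] = perf.ppv632
                row[f"npv632_{side}"] = perf.npv632
            row.update({"n": mc.n, "delong_z": mc.delong_z, "delong_p": mc.delong_p,
                        "significant_primary": mc.significant_primary, "note": ""})
            comp_rows.append(row)

    comparisons = pd.DataFrame(comp_rows)
    report = ComparisonReport(
        morphology=morphology,
        dose_levels=dose_levels,
        covariates=covariates,
        outcomes=outcomes,
        wilcoxon=wilcoxon,
        comparisons=comparisons,
        consort=consort,
        metadata=meta,
    )
    if config.outdir is not None:
        _write_report(report, Path(config.outdir))
    return report


def _write_report(report: ComparisonReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = "".join(f"# {k}: {v}\n" for k, v in report.metadata.items())
    for name, df in [
        ("morphology.csv", report.morphology),
        ("dose_levels.csv", report.dose_levels),
        ("covariates.csv", report.covariates),
        ("wilcoxon.csv", report.wilcoxon),
        ("comparisons.csv", report.comparisons),
    ]:
        with open(outdir / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    report.outcomes.to_csv(outdir / "outcomes.csv")
    with open(outdir / "consort.txt", "w") as fh:
        fh.write(header)
        fh.write(report.consort.to_string(index=False))
        fh.write("\n")
    log.info("report written to %s", outdir)
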