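"""Simulation harnesses that check the statistical machinery's calibration.

These are the package's own self-validation experiments: type-I error of
the paired DeLong test under a simulated null, Wald-interval coverage of
the logistic fitter at large n, percentile-bootstrap CI coverage for a
prespecified score, and the lattice-exact DVH/truncation invariants on a
voxel cohort.  They are exercised by the test suite and by the
reproduction script at fixed problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .cohort import SyntheticPatient, sample_covariates
from .dosimetry import REFERENCE_LEVELS_7, compute_dvh, dose_levels_for_arm, volume_at_dose
from .geometry import truncate_to_ptv
from .stats import bootstrap_performance, delong_paired, fit_logistic

__all__ = [
    "delong_type1_rate",
    "logistic_recovery_coverage",
    "bootstrap_null_coverage",
    "dvh_invariant_violations",
]


def delong_type1_rate(
    n: int = 200,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    effect: float = 1.2,
    noise_sd: float = 0.6,
) -> float:
    """Rejection rate of the paired DeLong test under a simulated null.

    Each repetition draws one underlying dosimetric signal, generates the
    outcome from a logistic model on it, and compares two equally noisy
    derivatives of the same signal — so the two AUCs share one true value
    and any rejection at level ``alpha`` is a false positive.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    done = 0
    while done < reps:
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-1.0 + effect * x)).astype(float)
        if y.sum() in (0, n):
            continue
        scores_a = x + noise_sd * rng.normal(size=n)
        scores_b = x + noise_sd * rng.normal(size=n)
        _, _, _, p = delong_paired(scores_a, scores_b, y)
        rejections += p < alpha
        done += 1
    return rejections / reps


def logistic_recovery_coverage(
    n_reps: int = 20,
    n: int = 20_000,
    seed: int = 0,
    coefficients: tuple[float, ...] = (-2.2, 0.0, 0.0, 2.0, 0.0, 0.0, 0.0, 8.0),
) -> float:
    """Pooled 95% Wald-interval coverage of known logistic coefficients.

    Covariates come from the fast slice-profile sampler (same geometry
    distributions as the voxel generator); outcomes are Bernoulli with the
    known coefficients.  Returns the fraction of (repetition, coefficient)
    pairs whose true value lies inside the fitted 95% Wald interval.
    """
    beta = np.asarray(coefficients, dtype=float)
    root = np.random.SeedSequence(seed)
    covered = 0
    total = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        X = sample_covariates(n, rng=rng)
        y = (rng.random(n) < expit(beta[0] + X @ beta[1:])).astype(float)
        fit = fit_logistic(X, y)
        se = np.sqrt(np.diag(fit.covariance))
        inside = np.abs(fit.coefficients - beta) <= 1.959963984540054 * se
        covered += int(inside.sum())
        total += inside.size
    return covered / total


class _FixedScore:
    """A prespecified scoring rule: the first covariate IS the score.

    Removes refitting optimism so that bootstrap CI coverage of the true
    AUC can be assessed; a refitted model's apparent AUC is biased upward
    and its CI is not expected to cover the null value.
    """

    converged = True

    def __init__(self, X: np.ndarray, y: np.ndarray) -> None:
        self.fitted_prob = X[:, 0]

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        return X[:, 0]


def bootstrap_null_coverage(
    reps: int = 100,
    n: int = 500,
    B: int = 500,
    seed: int = 0,
    prevalence: float = 0.3,
) -> float:
    """Fraction of null-signal repetitions whose 95% bootstrap AUC CI covers 0.5."""
    root = np.random.SeedSequence(seed)
    covered = 0
    for child in root.spawn(reps):
        rng = np.random.default_rng(child)
        X = rng.normal(size=(n, 1))
        y = (rng.random(n) < prevalence).astype(float)
        if y.sum() in (0, n):
            continue
        perf = bootstrap_performance(X, y, B=B, rng=rng, fit_fn=_FixedScore)
        lo, hi = perf.auc_ci
        covered += lo <= 0.5 <= hi
    return covered / reps


@dataclass
class DvhInvariantReport:
    n_patients: int
    normalization_violations: int = 0
    monotonicity_violations: int = 0
    unit_link_violations: int = 0
    nesting_violations: int = 0
    relative_direction_violations: int = 0
    absolute_direction_violations: int = 0

    @property
    def total_violations(self) -> int:
        return (self.normalization_violations + self.monotonicity_violations
                + self.unit_link_violations + self.nesting_violations
                + self.relative_direction_violations + self.absolute_direction_violations)


def dvh_invariant_violations(patients: list[SyntheticPatient]) -> DvhInvariantReport:
    """Count violations of the lattice-exact DVH and truncation invariants.

    Per patient: cumulative-DVH normalization (100% at 0 Gy), monotone
    non-increase, the relative/absolute unit link, voxelwise truncation
    nesting (PTV±0 ⊆ PTV±2 ⊆ whole), and the truncation direction at the
    top dose bin (relative volume non-decreasing, absolute non-increasing
    when cold rectum is removed).
    """
    report = DvhInvariantReport(n_patients=len(patients))
    tol = 1e-9
    for p in patients:
        whole = compute_dvh(p.dose, p.rectum_original)
        if whole.cum_rel[0] != 100.0:
            report.normalization_violations += 1
        if np.any(np.diff(whole.cum_rel) > tol) or np.any(np.diff(whole.cum_abs) > tol):
            report.monotonicity_violations += 1
        if not np.allclose(whole.cum_abs, whole.cum_rel * whole.total_volume_cc / 100.0,
                           rtol=1e-9, atol=1e-9):
            report.unit_link_violations += 1

        t0 = truncate_to_ptv(p.rectum_original, p.ptv, 0.0)
        t2 = truncate_to_ptv(p.rectum_original, p.ptv, 2.0)
        if np.any(t0.occupancy & ~t2.occupancy) or np.any(t2.occupancy & ~p.rectum_original.occupancy):
            report.nesting_violations += 1
        if t0.is_empty():
            continue
        mapped = dose_levels_for_arm(REFERENCE_LEVELS_7, p.arm).mapped_levels_gy
        trunc = compute_dvh(p.dose, t0)
        v_top = mapped[-1]
        if volume_at_dose(trunc, v_top) < volume_at_dose(whole, v_top) - tol:
            report.relative_direction_violations += 1
        if any(
            volume_at_dose(trunc, lv, "absolute") > volume_at_dose(whole, lv, "absolute") + tol
            for lv in mapped
        ):
            report.absolute_direction_violations += 1
    return report
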