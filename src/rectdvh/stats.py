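"""Statistical engine: logistic NTCP models and paired model comparison.

The toxicity models are plain logistic regressions of a binary endpoint on
the 7 dose-bin covariates (V30*..V74*), fitted by iteratively reweighted
least squares.  Model discrimination is the ROC AUC; two rectal-DVH
definitions fitted to the same patients are compared with the DeLong
paired test, which estimates the covariance of the two correlated AUCs
nonparametrically from midrank structural components.  Confidence
intervals come from stratified bootstrap resampling (cases and controls
resampled separately, preserving counts), and operating-point metrics
(sensitivity, specificity, PPV, NPV) from the .632 bootstrap:

    metric_632 = 0.368 * apparent + 0.632 * mean(out-of-bag)

Significance policy: the model comparisons form a family of 32 primary
tests (8 endpoints x 4 hypotheses) interpreted at the Bonferroni-corrected
0.0015 level; per-dose-level volume comparisons are exploratory at 0.0001.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtr
from scipy.stats import rankdata

from .errors import ModelError

log = logging.getLogger(__name__)

__all__ = [
    "LogisticFit",
    "PerformanceEstimate",
    "ModelComparison",
    "fit_logistic",
    "auc",
    "delong_paired",
    "delong_variance_single",
    "bootstrap_auc_ci",
    "estimate_632",
    "combine_632",
    "bootstrap_performance",
    "dichotomize",
    "wilcoxon_signed_rank",
    "significance_policy",
    "bonferroni_threshold",
    "compare_definitions",
    "PRIMARY_ALPHA",
    "EXPLORATORY_ALPHA",
]

#: Bonferroni-corrected threshold for the 32 primary model comparisons
#: (0.05/32 = 0.0015625, floored at 4 decimals).
PRIMARY_ALPHA: float = 0.0015
#: Threshold for exploratory per-dose-level comparisons.
EXPLORATORY_ALPHA: float = 0.0001

_ETA_CLIP = 35.0  # keeps expit strictly inside (0, 1) in float64


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: intercept + one slope per covariate."""

    coefficients: np.ndarray          # (p+1,), intercept first
    covariance: np.ndarray            # (p+1, p+1)
    converged: bool
    linear_predictor: np.ndarray      # (n,)
    fitted_prob: np.ndarray           # (n,), strictly inside (0, 1)
    loglik: float
    n_iter: int
    dropped_columns: tuple[int, ...] = ()  # zero-variance covariates, slope fixed at 0

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        eta = self.coefficients[0] + X @ self.coefficients[1:]
        return expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def _validate_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ModelError("covariates must be n x p with matching n outcomes")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ModelError("non-finite covariates or outcomes")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ModelError("outcomes must be binary 0/1")
    if classes.size < 2:
        raise ModelError("one-class outcome: both cases and controls are required")
    return X, y


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Fit a logistic model by IRLS.

    Convergence is declared when the maximum absolute coefficient change
    falls below ``tol``; after ``max_iter`` iterations the fit is returned
    with ``converged=False`` and a diagnostic logged (non-convergence in
    well-posed problems almost always signals separation).  Zero-variance
    covariates are dropped from the design (their slope is exactly 0) so a
    degenerate per-arm dose bin cannot make the normal equations singular.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if n <= p + 1:
        raise ModelError(f"need more observations than parameters ({n} rows, {p} covariates)")

    keep = np.ptp(X, axis=0) > 0
    dropped = tuple(int(i) for i in np.nonzero(~keep)[0])
    if dropped:
        log.debug("fit_logistic: dropping zero-variance covariate columns %s", dropped)
    Xd = np.column_stack([np.ones(n), X[:, keep]])
    k = Xd.shape[1]

    beta = np.zeros(k)
    pbar = y.mean()
    beta[0] = math.log(pbar / (1.0 - pbar))

    converged = False
    it = 0
    xtwx = np.eye(k)
    for it in range(1, max_iter + 1):
        eta = np.clip(Xd @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        z = eta + (y - mu) / w
        xw = Xd * w[:, None]
        xtwx = xw.T @ Xd
        xtwz = xw.T @ z
        try:
            beta_new = np.linalg.solve(xtwx, xtwz)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(xtwx, xtwz, rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    if not converged:
        log.warning(
            "fit_logistic: no convergence in %d iterations (max |beta| = %.3g); "
            "possible separation", max_iter, float(np.max(np.abs(beta))),
        )

    eta = np.clip(Xd @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    loglik = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))
    cov_d = np.linalg.pinv(xtwx)
    cov_d = 0.5 * (cov_d + cov_d.T)

    # embed back into full (p+1) parameter space, dropped slopes pinned at 0
    coef = np.zeros(p + 1)
    cov = np.zeros((p + 1, p + 1))
    full_idx = np.concatenate([[0], 1 + np.nonzero(keep)[0]])
    coef[full_idx] = beta
    cov[np.ix_(full_idx, full_idx)] = cov_d

    return LogisticFit(
        coefficients=coef,
        covariance=cov,
        converged=converged,
        linear_predictor=eta,
        fitted_prob=mu,
        loglik=loglik,
        n_iter=it,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# AUC and the DeLong paired comparison
# ---------------------------------------------------------------------------

def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(float)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if cases.size == 0 or controls.size == 0:
        raise ModelError("AUC requires both cases and controls")
    return cases, controls


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling: P(case > control) + P(=)/2."""
    cases, controls = _split_scores(scores, labels)
    m, n = cases.size, controls.size
    ranks = rankdata(np.concatenate([cases, controls]))
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_components(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-case (V10) and per-control (V01) structural components."""
    cases, controls = _split_scores(scores, labels)
    m, n = cases.size, controls.size
    tz = rankdata(np.concatenate([cases, controls]))
    tx = rankdata(cases)
    ty = rankdata(controls)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    a = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return a, v10, v01


def delong_variance_single(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance estimate of a single AUC."""
    _, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_paired(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two score vectors on the same subjects.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.  A
    zero variance of the AUC difference (e.g. identical scores) yields
    ``z = 0, p = 1`` by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ModelError("paired comparison requires scores on the same subjects")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var_diff = float(s[0, 0] + s[1, 1] - 2.0 * s[0, 1])
    if var_diff <= 1e-16:
        log.debug("delong_paired: zero variance of AUC difference; p = 1 by convention")
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * (1.0 - ndtr(abs(z)))
    return auc_a, auc_b, float(z), float(p)


# ---------------------------------------------------------------------------
# Operating point and confusion metrics
# ---------------------------------------------------------------------------

def dichotomize(probabilities: np.ndarray, labels: np.ndarray, rule: str = "youden") -> float:
    """Classification threshold on the fitting data.

    ``"youden"`` maximises J = sensitivity + specificity - 1 over the
    observed probabilities (subjects with prob >= threshold are called
    positive); ties are broken toward the lower threshold.  ``"fixed05"``
    returns 0.5.
    """
    if rule == "fixed05":
        return 0.5
    if rule != "youden":
        raise ModelError(f"unknown threshold rule {rule!r}")
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not y.any() or y.all():
        raise ModelError("threshold selection requires both classes")
    n1 = int(y.sum())
    n0 = y.size - n1
    # single descending sweep: at threshold = each unique prob, everything
    # with prob >= threshold is called positive
    order = np.argsort(-probs, kind="stable")
    sorted_probs = probs[order]
    tp = np.cumsum(y[order])
    fp = np.cumsum(~y[order])
    is_last = np.r_[sorted_probs[1:] != sorted_probs[:-1], True]  # one entry per unique value
    # J = tp/n1 - fp/n0, compared in exact integer arithmetic so ties are real ties
    j_scaled = tp[is_last].astype(np.int64) * n0 - fp[is_last].astype(np.int64) * n1
    best = np.nonzero(j_scaled == j_scaled.max())[0][-1]  # lowest threshold among ties
    return float(sorted_probs[is_last][best])


def _confusion_metrics(y: np.ndarray, positive: np.ndarray) -> dict[str, float]:
    """sens/spec/ppv/npv; NaN where the denominator class is absent."""
    y = np.asarray(y).astype(bool)
    positive = np.asarray(positive).astype(bool)
    tp = int((positive & y).sum())
    fn = int((~positive & y).sum())
    tn = int((~positive & ~y).sum())
    fp = int((positive & ~y).sum())
    return {
        "sens": tp / (tp + fn) if (tp + fn) else math.nan,
        "spec": tn / (tn + fp) if (tn + fp) else math.nan,
        "ppv": tp / (tp + fp) if (tp + fp) else math.nan,
        "npv": tn / (tn + fn) if (tn + fn) else math.nan,
    }


# ---------------------------------------------------------------------------
# Bootstrap: AUC CI and .632 operating-point estimates
# ---------------------------------------------------------------------------

@dataclass
class PerformanceEstimate:
    """Bootstrap summary of one fitted model."""

    auc: float
    auc_ci: tuple[float, float] | None
    sens632: float
    spec632: float
    ppv632: float
    npv632: float
    n_bootstrap: int
    threshold: float
    n_skipped: int = 0
    ci_contains_point: bool | None = None


def combine_632(apparent: float, oob_mean: float) -> float:
    """The .632 blend: 0.368 x apparent + 0.632 x mean out-of-bag."""
    return 0.368 * apparent + 0.632 * oob_mean


def _stratified_resample(case_idx, control_idx, rng) -> np.ndarray:
    take_cases = rng.integers(0, case_idx.size, case_idx.size)
    take_controls = rng.integers(0, control_idx.size, control_idx.size)
    return np.concatenate([case_idx[take_cases], control_idx[take_controls]])


def bootstrap_performance(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 2000,
    rng: np.random.Generator | int | None = None,
    threshold_rule: str = "youden",
    fit_fn=fit_logistic,
) -> PerformanceEstimate:
    """Stratified-bootstrap AUC CI plus .632 sens/spec/PPV/NPV in one loop.

    Cases and controls are resampled with replacement separately,
    preserving the original class counts.  The AUC point estimate is the
    full-sample fit; its CI is the 2.5th/97.5th centile of the per-resample
    (refit, re-evaluated on the resample) AUCs.  Each .632 metric combines
    the apparent full-sample value with the mean out-of-bag value over the
    replicates where it is defined.  Non-converged resample fits are
    skipped and counted.
    """
    X, y = _validate_xy(X, y)
    rng = np.random.default_rng(rng)
    full = fit_fn(X, y)
    auc_point = auc(full.fitted_prob, y)
    thr = dichotomize(full.fitted_prob, y, threshold_rule)
    apparent = _confusion_metrics(y, full.fitted_prob >= thr)

    case_idx = np.nonzero(y == 1)[0]
    control_idx = np.nonzero(y == 0)[0]
    boot_aucs: list[float] = []
    oob: dict[str, list[float]] = {k: [] for k in apparent}
    n_skipped = 0

    for _ in range(B):
        idx = _stratified_resample(case_idx, control_idx, rng)
        try:
            fit = fit_fn(X[idx], y[idx])
        except (ModelError, np.linalg.LinAlgError):
            n_skipped += 1
            continue
        if not fit.converged:
            n_skipped += 1
            continue
        boot_aucs.append(auc(fit.fitted_prob, y[idx]))
        out_idx = np.setdiff1d(np.arange(y.size), idx, assume_unique=False)
        if out_idx.size == 0:
            continue
        t = dichotomize(fit.fitted_prob, y[idx], threshold_rule)
        prob_oob = fit.predict_prob(X[out_idx])
        metrics = _confusion_metrics(y[out_idx], prob_oob >= t)
        for k, v in metrics.items():
            if not math.isnan(v):
                oob[k].append(v)

    if B and n_skipped > 0.05 * B:
        log.warning("bootstrap: %d/%d resamples skipped", n_skipped, B)

    if boot_aucs:
        lo, hi = np.percentile(boot_aucs, [2.5, 97.5])
        ci: tuple[float, float] | None = (float(lo), float(hi))
        contains = bool(lo <= auc_point <= hi)
        if not contains:
            log.warning("bootstrap AUC CI (%.3f, %.3f) excludes point estimate %.3f", lo, hi, auc_point)
    else:
        ci = None
        contains = None
        if B:
            log.warning("bootstrap: no usable resamples; CI undefined")

    def comb(key: str) -> float:
        if math.isnan(apparent[key]) or not oob[key]:
            return math.nan
        return combine_632(apparent[key], float(np.mean(oob[key])))

    return PerformanceEstimate(
        auc=auc_point,
        auc_ci=ci,
        sens632=comb("sens"),
        spec632=comb("spec"),
        ppv632=comb("ppv"),
        npv632=comb("npv"),
        n_bootstrap=len(boot_aucs),
        threshold=thr,
        n_skipped=n_skipped,
        ci_contains_point=contains,
    )


def bootstrap_auc_ci(
    X, y, fit_fn=fit_logistic, B: int = 2000, seed=None, threshold_rule: str = "youden"
) -> PerformanceEstimate:
    """AUC point estimate with stratified-bootstrap percentile CI."""
    return bootstrap_performance(X, y, B=B, rng=seed, threshold_rule=threshold_rule, fit_fn=fit_fn)


def estimate_632(
    X, y, fit_fn=fit_logistic, threshold_rule: str = "youden", B: int = 2000, seed=None
) -> dict[str, float]:
    """.632-bootstrap sensitivity/specificity/PPV/NPV of the fitted model."""
    perf = bootstrap_performance(X, y, B=B, rng=seed, threshold_rule=threshold_rule, fit_fn=fit_fn)
    return {
        "sens632": perf.sens632,
        "spec632": perf.spec632,
        "ppv632": perf.ppv632,
        "npv632": perf.npv632,
    }


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 25


def _wilcoxon_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p by enumeration of the 2^n sign assignments.

    Midranks are doubled so tied half-ranks become integers; the null
    distribution of the doubled positive-rank sum is built by dynamic
    programming (subset-sum convolution), equivalent to full enumeration.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        upd = dist.copy()
        upd[r:] += dist[: total + 1 - r]
        dist = upd
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(paired_a: np.ndarray, paired_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; ties in |difference| get midranks.  The
    null distribution is enumerated exactly for n <= 25 and approximated
    by a tie- and continuity-corrected normal otherwise.  All-zero
    differences give p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ModelError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        log.info("wilcoxon_signed_rank: all differences zero; p = 1")
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= _EXACT_N_MAX:
        return _wilcoxon_exact_p(w_plus, ranks)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mean
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
    return float(2.0 * (1.0 - ndtr(abs(z))))


# ---------------------------------------------------------------------------
# Multiple-testing policy
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 32, decimals: int = 4) -> float:
    """Bonferroni-corrected level, floored at ``decimals`` decimal places."""
    scale = 10.0**decimals
    return math.floor(alpha / n_tests * scale) / scale


def significance_policy(p_values: np.ndarray, family: str) -> np.ndarray:
    """Significance flags: primary comparisons at 0.0015, exploratory at 0.0001."""
    thresholds = {
        "primary_model_comparisons": PRIMARY_ALPHA,
        "exploratory_dose_levels": EXPLORATORY_ALPHA,
    }
    if family not in thresholds:
        raise ModelError(f"unknown test family {family!r}; expected one of {sorted(thresholds)}")
    return np.asarray(p_values, dtype=float) < thresholds[family]


# ---------------------------------------------------------------------------
# Paired definition comparison (one table row)
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Paired comparison of two rectal-DVH definitions on one endpoint."""

    label_a: str
    label_b: str
    n: int
    performance_a: PerformanceEstimate
    performance_b: PerformanceEstimate
    delong_z: float
    delong_p: float
    significant_primary: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.delong_p <= 1.0):
            raise ModelError("DeLong p-value outside [0, 1]")
        self.significant_primary = bool(self.delong_p < PRIMARY_ALPHA)


def compare_definitions(
    X_a: np.ndarray,
    X_b: np.ndarray,
    y: np.ndarray,
    label_a: str,
    label_b: str,
    B: int = 2000,
    rng: np.random.Generator | int | None = None,
    threshold_rule: str = "youden",
) -> ModelComparison:
    """Fit both definitions on the same subjects, DeLong-compare the AUCs,
    and bootstrap each model's performance estimates."""
    rng = np.random.default_rng(rng)
    fit_a = fit_logistic(np.asarray(X_a, float), y)
    fit_b = fit_logistic(np.asarray(X_b, float), y)
    _, _, z, p = delong_paired(fit_a.fitted_prob, fit_b.fitted_prob, np.asarray(y))
    perf_a = bootstrap_performance(X_a, y, B=B, rng=rng, threshold_rule=threshold_rule)
    perf_b = bootstrap_performance(X_b, y, B=B, rng=rng, threshold_rule=threshold_rule)
    return ModelComparison(
        label_a=label_a,
        label_b=label_b,
        n=int(np.asarray(y).size),
        performance_a=perf_a,
        performance_b=perf_b,
        delong_z=z,
        delong_p=p,
    )
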