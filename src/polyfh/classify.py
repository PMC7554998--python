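"""Threshold derivation and ROC analysis.

Thresholds come from the control (population) score distribution, either as
empirical percentiles (75th/90th/95th, linear-interpolation "type 7"
quantiles) or as the ROC-optimal point maximizing Youden's J = sens + spec − 1.
Classification is ``score > threshold`` (strict) by default.

The AUC is computed twice on every curve — trapezoid rule over the swept
operating points and the Mann-Whitney placement identity
AUC = U/(n₁·n₀) with half-credit for ties — and the two must agree to 1e-10;
disagreement raises, as it would indicate a sweep bug.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .model import (
    ConfigError,
    CutoffReport,
    InsufficientDataError,
    RocCurve,
)

PERCENTILE_CUTOFFS = {"p75": 75.0, "p90": 90.0, "p95": 95.0}
MIN_CONTROLS = 20


def _clean(scores) -> np.ndarray:
    arr = np.asarray(scores, dtype=float)
    return arr[np.isfinite(arr)]


def percentile_cutoff(control_scores, q: float, min_n: int = MIN_CONTROLS) -> float:
    """Empirical ``q``-th percentile of the control scores (type-7 quantile)."""
    arr = _clean(control_scores)
    if len(arr) < min_n:
        raise InsufficientDataError(
            f"percentile cutoff needs at least {min_n} controls, got {len(arr)}"
        )
    if not (0.0 < q < 100.0):
        raise ConfigError(f"percentile must lie in (0, 100), got {q}")
    return float(np.quantile(arr, q / 100.0))


def proportion_above(scores, threshold: float, strict: bool = True) -> tuple[int, float]:
    """(count, proportion) of scores above a threshold, missing scores excluded
    from both numerator and denominator."""
    arr = _clean(scores)
    if arr.size == 0:
        raise InsufficientDataError("no non-missing scores")
    count = int((arr > threshold).sum() if strict else (arr >= threshold).sum())
    return count, count / arr.size


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def roc_curve(
    case_scores,
    control_scores,
    panel_name: str | None = None,
) -> RocCurve:
    """Empirical ROC of case vs control under the rule ``score > t``.

    Thresholds sweep the midpoints between adjacent distinct pooled scores
    plus sentinels below/above the observed range, so every achievable
    operating point appears exactly once.
    """
    case = _clean(case_scores)
    control = _clean(control_scores)
    if case.size == 0 or control.size == 0:
        raise InsufficientDataError("both case and control scores required")
    pooled = np.concatenate([case, control])
    uniq = np.unique(pooled)
    degenerate = uniq.size == 1
    if uniq.size > 1:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    else:
        thresholds = np.array([uniq[0] - 1.0, uniq[0] + 1.0])
    case_sorted = np.sort(case)
    control_sorted = np.sort(control)
    # Operating points are defined by the unique score values, not by
    # comparisons against the midpoint thresholds: a midpoint between two
    # adjacent near-equal floats can collide with one of them and misplace a
    # sample.  Point k (k >= 1) is the rule "score > uniq[k-1]".
    cum_case = np.searchsorted(case_sorted, uniq, side="right") / case.size
    cum_control = np.searchsorted(control_sorted, uniq, side="right") / control.size
    sens = np.concatenate([[1.0], 1.0 - cum_case])
    spec = np.concatenate([[0.0], cum_control])
    # trapezoid AUC over (1 - spec, sens); fpr is decreasing along thresholds
    fpr = 1.0 - spec
    auc_trap = float(np.trapezoid(sens[::-1], fpr[::-1]))
    # Mann-Whitney identity with tie correction
    ranks = _midrank(pooled)
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    auc_mw = float(u / (case.size * control.size))
    if abs(auc_trap - auc_mw) > 1e-10:
        raise AssertionError(
            f"ROC internal cross-check failed: trapezoid {auc_trap} vs "
            f"Mann-Whitney {auc_mw}"
        )
    return RocCurve(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc_trap,
        n_case=int(case.size),
        n_control=int(control.size),
        degenerate=degenerate,
        panel_name=panel_name,
        case_scores=case,
        control_scores=control,
    )


def youden_optimal(roc: RocCurve) -> CutoffReport:
    """Threshold maximizing Youden's J; ties resolved toward the higher
    threshold (higher specificity)."""
    j = roc.sens + roc.spec - 1.0
    best = np.flatnonzero(j == j.max())[-1]
    return CutoffReport(
        panel_name=roc.panel_name or "",
        cutoff_type="youden",
        threshold=float(roc.thresholds[best]),
        sens=float(roc.sens[best]),
        spec=float(roc.spec[best]),
        youden_j=float(j[best]),
    )


# ---------------------------------------------------------------------------
# correlated-AUC comparison (DeLong-type)


def _placements(case: np.ndarray, control: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus case/control placement values (structural components)."""
    m, n = case.size, control.size
    all_ranks = _midrank(np.concatenate([case, control]))
    case_ranks = _midrank(case)
    control_ranks = _midrank(control)
    v10 = (all_ranks[:m] - case_ranks) / n                     # per-case
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m            # per-control
    auc = float(v10.mean())
    return auc, v10, v01


def compare_auc(roc_a: RocCurve, roc_b: RocCurve, paired: bool = True) -> dict:
    """Two-sided comparison of two AUCs via placement-value (DeLong) covariance.

    Paired mode requires the two curves to be built from scores of the same
    samples in the same order; unpaired mode treats them as independent.
    """
    for roc in (roc_a, roc_b):
        if roc.case_scores is None or roc.control_scores is None:
            raise ConfigError("RocCurve lacks raw scores needed for comparison")
    a_auc, a10, a01 = _placements(roc_a.case_scores, roc_a.control_scores)
    b_auc, b10, b01 = _placements(roc_b.case_scores, roc_b.control_scores)
    if paired:
        if roc_a.n_case != roc_b.n_case or roc_a.n_control != roc_b.n_control:
            raise ConfigError("paired AUC comparison requires matching sample sizes")
        m, n = roc_a.n_case, roc_a.n_control
        s10 = np.cov(np.vstack([a10, b10]), ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.vstack([a01, b01]), ddof=1) if n > 1 else np.zeros((2, 2))
        s = s10 / m + s01 / n
        var = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    else:
        var = (
            np.var(a10, ddof=1) / roc_a.n_case + np.var(a01, ddof=1) / roc_a.n_control
            + np.var(b10, ddof=1) / roc_b.n_case + np.var(b01, ddof=1) / roc_b.n_control
        )
    diff = a_auc - b_auc
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / math.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return {
        "auc_a": a_auc,
        "auc_b": b_auc,
        "delta": diff,
        "z": float(z),
        "p_value": p,
        "paired": paired,
    }


# ---------------------------------------------------------------------------
# full panel × cutoff suite


def panel_cutoff_suite(
    scores: Mapping[str, Mapping[str, Sequence[float]]],
    cutoffs: Sequence[str] = ("p75", "p90", "p95", "youden"),
    control_group: str = "EUR",
    case_group: str = "FH_Mneg",
    strict: bool = True,
) -> list[CutoffReport]:
    """Cross every panel with every cutoff type.

    ``scores[panel][group]`` are per-sample wGS values.  Percentile cutoffs
    are derived from the control group; the Youden cutoff from the
    case-vs-control ROC.  Each report carries the count and proportion above
    threshold for every group present.
    """
    reports: list[CutoffReport] = []
    for panel, by_group in scores.items():
        if control_group not in by_group:
            raise ConfigError(f"panel {panel}: control group {control_group!r} missing")
        control = _clean(by_group[control_group])
        for cutoff in cutoffs:
            if cutoff in PERCENTILE_CUTOFFS:
                threshold = percentile_cutoff(control, PERCENTILE_CUTOFFS[cutoff])
                report = CutoffReport(panel_name=panel, cutoff_type=cutoff,
                                      threshold=threshold)
                if case_group in by_group:
                    _, report.sens = proportion_above(
                        by_group[case_group], threshold, strict
                    )
                    above_ctrl, _ = proportion_above(control, threshold, strict)
                    report.spec = 1.0 - above_ctrl / control.size
            elif cutoff == "youden":
                if case_group not in by_group:
                    raise ConfigError(
                        f"panel {panel}: case group {case_group!r} required for Youden"
                    )
                roc = roc_curve(by_group[case_group], control, panel_name=panel)
                report = youden_optimal(roc)
                report.cutoff_type = "youden"
            else:
                raise ConfigError(f"unknown cutoff type {cutoff!r}")
            for group, vals in by_group.items():
                count, prop = proportion_above(vals, report.threshold, strict)
                report.n_above[group] = count
                report.n_total[group] = int(_clean(vals).size)
                report.proportion_above[group] = prop
            reports.append(report)
    return reports
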