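"""Statistical battery: HWE, allele-frequency association, stepwise logistic
panel refinement, group score comparisons, trend and adjusted associations.

Conventions
-----------
* chi-square tests are Pearson without continuity correction; Fisher's exact
  (or the exact HWE test) replaces them whenever any expected cell count is
  below 5;
* two-group comparisons are gated on Shapiro-Wilk normality at α = 0.05 per
  group: Welch's t-test when both pass, Wilcoxon-Mann-Whitney otherwise;
  more than two groups use ANOVA / Kruskal-Wallis plus pairwise post-hocs;
* raw p-values are reported throughout (no multiplicity correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
import statsmodels.api as sm

from .model import (
    AssocResult,
    ConfigError,
    GenotypeMatrix,
    HweResult,
    InsufficientDataError,
    ParameterError,
)

# ---------------------------------------------------------------------------
# Hardy-Weinberg


def _hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact HWE test (conditional on allele counts, two-sided by probability
    mass): p = Σ P(n_het') over heterozygote counts no more probable than the
    observed one."""
    n = n0 + n1 + n2
    n_a = 2 * n0 + n1  # copies of the allele counted in n2? orientation-free
    het_values = np.arange(n1 % 2, min(n_a, 2 * n - n_a) + 1, 2)
    # log P(n_het) ∝ n_het·log2 − log(n_hom_a!) − log(n_het!) − log(n_hom_b!)
    hom_a = (n_a - het_values) // 2
    hom_b = n - hom_a - het_values
    logp = (
        het_values * math.log(2.0)
        - gammaln(hom_a + 1)
        - gammaln(het_values + 1)
        - gammaln(hom_b + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    observed = probs[list(het_values).index(n1)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def hwe_test(
    genotype_counts: tuple[int, int, int],
    rsid: str | None = None,
    group: str | None = None,
) -> HweResult:
    """Test genotype counts (n0, n1, n2) against Hardy-Weinberg proportions.

    Chi-square goodness of fit with 1 df against expectations from the
    observed allele frequency; switches to the exact conditional test when
    any expected count is below 5.
    """
    n0, n1, n2 = (int(c) for c in genotype_counts)
    if min(n0, n1, n2) < 0:
        raise ParameterError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise InsufficientDataError("HWE test needs at least one genotype")
    p = (2 * n0 + n1) / (2 * n)
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n0, n1, n2], dtype=float)
    if p in (0.0, 1.0):
        # monomorphic: trivially in HWE
        return HweResult(rsid, group, 0.0, 1.0, (n0, n1, n2), method="chi2")
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum((observed - expected) ** 2 / expected))
    if expected.min() < 5:
        return HweResult(rsid, group, chi2, _hwe_exact_p(n0, n1, n2),
                         (n0, n1, n2), method="exact")
    return HweResult(rsid, group, chi2, float(sps.chi2.sf(chi2, df=1)),
                     (n0, n1, n2), method="chi2")


# ---------------------------------------------------------------------------
# allele-frequency case-control test


@dataclass(frozen=True)
class FreqTestResult:
    chi2: float | None
    p_value: float
    method: str            # chi2 | fisher
    table: tuple[tuple[int, int], tuple[int, int]]


def allele_freq_test(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> FreqTestResult:
    """Compare effect-allele counts between two groups on the 2×2 allele table.

    ``counts_x`` is (effect-allele copies, other-allele copies).  Pearson
    chi-square without continuity correction; Fisher's exact two-sided test
    when any expected cell is below 5.
    """
    table = np.array([counts_a, counts_b], dtype=float)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise InsufficientDataError("allele table has an empty margin")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    tbl = ((int(counts_a[0]), int(counts_a[1])), (int(counts_b[0]), int(counts_b[1])))
    if expected.min() < 5 or table.min() == 0:
        _, p = sps.fisher_exact(table, alternative="two-sided")
        return FreqTestResult(chi2=None, p_value=float(p), method="fisher", table=tbl)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return FreqTestResult(chi2=float(chi2), p_value=float(p), method="chi2", table=tbl)


def allele_counts(dosages: np.ndarray) -> tuple[int, int]:
    """(effect, other) allele copies from a dosage vector, ignoring missing."""
    d = dosages[np.isfinite(dosages)]
    eff = int(d.sum())
    return eff, int(2 * d.size - eff)


# ---------------------------------------------------------------------------
# stepwise logistic regression

_SEPARATION_COEF = 15.0


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            return None
    if not np.all(np.isfinite(res.params)):
        return None
    return res


@dataclass
class StepwiseResult:
    selected: list[AssocResult]
    order: list[str] = field(default_factory=list)
    criterion: str = "p"
    separation: bool = False


def stepwise_logistic(
    dosages: GenotypeMatrix | pd.DataFrame,
    labels: Sequence[int] | np.ndarray,
    criterion: str = "p",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    direction: str = "both",
    max_steps: int = 100,
) -> StepwiseResult:
    """Bidirectional stepwise selection on the additive-dosage logistic model.

    ``criterion='p'`` enters the candidate with the smallest Wald p below
    ``p_enter`` and removes any retained term whose Wald p exceeds
    ``p_remove``; ``criterion='aic'`` adds/drops whichever move lowers the
    AIC most.  Samples with a missing dosage at any candidate are dropped.
    Quasi-separation is flagged on the result, never silently ignored.
    """
    if criterion not in ("p", "aic"):
        raise ConfigError(f"unknown stepwise criterion {criterion!r}")
    if direction not in ("forward", "backward", "both"):
        raise ConfigError(f"unknown stepwise direction {direction!r}")
    X = dosages.to_frame() if isinstance(dosages, GenotypeMatrix) else pd.DataFrame(dosages)
    if X.shape[1] < 2:
        raise ConfigError("stepwise selection needs at least 2 candidates")
    y = np.asarray(labels, dtype=float)
    if len(y) != len(X):
        raise ConfigError("labels length does not match dosage rows")
    keep = np.isfinite(X.to_numpy()).all(axis=1) & np.isfinite(y)
    X, y = X.loc[keep].reset_index(drop=True), y[keep]
    if len(set(y)) < 2:
        raise InsufficientDataError("both case and control labels required")

    candidates = list(X.columns)
    included: list[str] = [] if direction != "backward" else list(candidates)
    order: list[str] = []
    separation = False

    def fit(cols: list[str]):
        return _fit_logit(X[cols] if cols else X[[]], y)

    for _ in range(max_steps):
        changed = False
        # forward step
        if direction in ("forward", "both"):
            best_col, best_score = None, None
            for col in candidates:
                if col in included:
                    continue
                res = fit(included + [col])
                if res is None:
                    continue
                if criterion == "p":
                    score = res.pvalues[col]
                    ok = score < p_enter
                else:
                    base = fit(included)
                    score = res.aic
                    ok = base is not None and res.aic < base.aic - 1e-9
                if ok and (best_score is None or score < best_score):
                    best_col, best_score = col, score
            if best_col is not None:
                included.append(best_col)
                order.append(best_col)
                changed = True
        # backward step
        if direction in ("backward", "both") and included:
            res = fit(included)
            if res is not None:
                if criterion == "p":
                    pvals = res.pvalues[included]
                    worst = pvals.idxmax()
                    if pvals[worst] > p_remove:
                        included.remove(worst)
                        changed = True
                else:
                    for col in list(included):
                        alt = fit([c for c in included if c != col])
                        if alt is not None and alt.aic < res.aic - 1e-9:
                            included.remove(col)
                            changed = True
                            break
        if not changed:
            break

    selected: list[AssocResult] = []
    if included:
        res = fit(included)
        if res is None:
            raise InsufficientDataError("final stepwise model failed to converge")
        for col in included:
            b = float(res.params[col])
            se = float(res.bse[col])
            note = ""
            if abs(b) > _SEPARATION_COEF or not math.isfinite(se):
                note = "possible separation"
                separation = True
            selected.append(
                AssocResult(
                    rsid=str(col),
                    odds_ratio=math.exp(b),
                    ci95=(math.exp(b - 1.96 * se), math.exp(b + 1.96 * se)),
                    p_value=float(res.pvalues[col]),
                    note=note,
                )
            )
        selected.sort(key=lambda r: r.p_value)
    return StepwiseResult(selected=selected, order=order, criterion=criterion,
                          separation=separation)


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    test: str             # t | wilcoxon
    statistic: float
    p_value: float


@dataclass
class GroupCompareReport:
    groups: list[str]
    moments: dict[str, dict[str, float]]     # group -> mean/sd/n/normal_p
    omnibus_test: str | None                 # anova | kruskal (k > 2 only)
    omnibus_p: float | None
    pairwise: list[PairwiseTest]

    def pairwise_p(self, a: str, b: str) -> float:
        for t in self.pairwise:
            if {t.group_a, t.group_b} == {a, b}:
                return t.p_value
        raise KeyError((a, b))


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(x) == 0 or len(x) < 3:
        return False
    return bool(sps.shapiro(x).pvalue >= alpha)


def _two_sample(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> PairwiseTest:
    if np.ptp(np.concatenate([a, b])) == 0:
        # fully tied data: no evidence of a location difference
        return PairwiseTest("", "", "wilcoxon", 0.0, 1.0)
    if _is_normal(a, alpha) and _is_normal(b, alpha):
        res = sps.ttest_ind(a, b, equal_var=False)
        return PairwiseTest("", "", "t", float(res.statistic), float(res.pvalue))
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return PairwiseTest("", "", "wilcoxon", float(res.statistic), float(res.pvalue))


def group_compare(
    scores_by_group: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]] | None = None,
    alpha_normality: float = 0.05,
) -> GroupCompareReport:
    """Compare score distributions between groups.

    Two groups: Welch t-test if both pass the Shapiro-Wilk gate, otherwise
    Wilcoxon-Mann-Whitney.  More than two: ANOVA when every group passes,
    otherwise Kruskal-Wallis, followed by the two-sample logic pairwise
    (over ``pairs`` when given, else all pairs).
    """
    clean = {
        g: np.asarray(x, dtype=float)[np.isfinite(np.asarray(x, dtype=float))]
        for g, x in scores_by_group.items()
    }
    if len(clean) < 2:
        raise InsufficientDataError("need at least two groups")
    for g, x in clean.items():
        if len(x) < 2:
            raise InsufficientDataError(f"group {g!r} has fewer than 2 observations")
    groups = list(clean)
    moments = {
        g: {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "n": int(len(x)),
            "normal": _is_normal(x, alpha_normality),
        }
        for g, x in clean.items()
    }
    omnibus_test = omnibus_p = None
    if len(groups) > 2:
        samples = [clean[g] for g in groups]
        if all(moments[g]["normal"] for g in groups):
            omnibus_test = "anova"
            omnibus_p = float(sps.f_oneway(*samples).pvalue)
        else:
            omnibus_test = "kruskal"
            if np.ptp(np.concatenate(samples)) == 0:
                omnibus_p = 1.0
            else:
                omnibus_p = float(sps.kruskal(*samples).pvalue)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    pairwise = []
    for a, b in pairs:
        t = _two_sample(clean[a], clean[b], alpha_normality)
        pairwise.append(PairwiseTest(a, b, t.test, t.statistic, t.p_value))
    return GroupCompareReport(groups=groups, moments=moments,
                              omnibus_test=omnibus_test, omnibus_p=omnibus_p,
                              pairwise=pairwise)


# ---------------------------------------------------------------------------
# Cochran-Armitage trend test


def cochran_armitage(
    trend_table: Sequence[tuple[int, int]],
    scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Trend in a proportion across ordered categories.

    ``trend_table`` holds (n_positive, n_negative) per ordered category;
    ``scores`` default to 1..K.  Returns (z, two-sided p) with the exact
    permutation mean/variance (hypergeometric) standardisation, so the
    statistic is invariant to affine re-scoring.
    """
    table = np.asarray(trend_table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ConfigError("trend table must be K rows of (n_positive, n_negative)")
    k = table.shape[0]
    if k < 2:
        raise InsufficientDataError("trend test needs at least 2 ordered categories")
    s = np.asarray(scores, dtype=float) if scores is not None else np.arange(1.0, k + 1)
    if len(s) != k:
        raise ConfigError("scores length must match number of categories")
    pos = table[:, 0]
    n_k = table.sum(axis=1)
    n = n_k.sum()
    a = pos.sum()
    if n < 2 or a == 0 or a == n:
        raise InsufficientDataError("degenerate trend table")
    s_bar = (n_k * s).sum() / n
    t_stat = (s * pos).sum()
    mean = a * s_bar
    var = a * (n - a) / (n * (n - 1)) * ((n_k * s**2).sum() - n * s_bar**2)
    if var <= 0:
        return 0.0, 1.0
    z = float((t_stat - mean) / math.sqrt(var))
    return z, float(2 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# age/sex-adjusted association of a DLCN component with the score


@dataclass(frozen=True)
class AdjustedAssocResult:
    coefficient: float        # logit slope per score unit
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    separation: bool = False


def adjusted_component_assoc(
    wgs: Sequence[float],
    component: Sequence[int],
    age: Sequence[float],
    sex: Sequence[str],
) -> AdjustedAssocResult:
    """Logistic model: component ~ wGS + age + sex (sex coded M=1, F=0)."""
    df = pd.DataFrame(
        {
            "wgs": np.asarray(wgs, dtype=float),
            "age": np.asarray(age, dtype=float),
            "sex": [1.0 if s == "M" else 0.0 for s in sex],
        }
    )
    y = np.asarray(component, dtype=float)
    keep = np.isfinite(df.to_numpy()).all(axis=1) & np.isfinite(y)
    df, y = df.loc[keep].reset_index(drop=True), y[keep]
    if len(set(y)) < 2:
        raise InsufficientDataError("component must take both values")
    res = _fit_logit(df, y)
    if res is None:
        raise InsufficientDataError("adjusted logistic model failed to converge")
    b = float(res.params["wgs"])
    se = float(res.bse["wgs"])
    sep = abs(b) > _SEPARATION_COEF or not math.isfinite(se)
    return AdjustedAssocResult(
        coefficient=b,
        odds_ratio=math.exp(b),
        ci95=(math.exp(b - 1.96 * se), math.exp(b + 1.96 * se)),
        p_value=float(res.pvalues["wgs"]),
        n=int(len(y)),
        separation=sep,
    )
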