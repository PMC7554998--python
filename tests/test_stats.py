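"""HWE, allele association, stepwise refinement, group comparison, trend tests."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import polyfh
from polyfh.model import ConfigError, InsufficientDataError
from polyfh.simulate import simulate_genotypes_hwe
from polyfh.stats import (
    AdjustedAssocResult,
    _fit_logit,
    adjusted_component_assoc,
    allele_counts,
    allele_freq_test,
    cochran_armitage,
    group_compare,
    hwe_test,
    stepwise_logistic,
)


def hwe_exact_enumeration(n0, n1, n2):
    """Independent exact-HWE oracle in rational arithmetic.

    Conditional on allele counts, P(n_het) ∝ multinomial(n; n0,n1,n2)·2^n1;
    two-sided p sums probabilities not exceeding the observed one.
    """
    n = n0 + n1 + n2
    na = 2 * n0 + n1
    probs = {}
    for het in range(n1 % 2, min(na, 2 * n - na) + 1, 2):
        ha = (na - het) // 2
        hb = n - ha - het
        probs[het] = Fraction(
            math.factorial(n) * 2**het,
            math.factorial(ha) * math.factorial(het) * math.factorial(hb),
        )
    total = sum(probs.values())
    obs = probs[n1]
    return float(sum(p for p in probs.values() if p <= obs) / total)


class TestHwe:
    def test_perfect_hwe(self):
        res = hwe_test((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "chi2"

    def test_total_heterozygote_deficit(self):
        # n=100, allele freq 0.5 -> expected (25, 50, 25)
        res = hwe_test((50, 0, 50))
        assert res.chi2 == pytest.approx(100.0)

    def test_textbook_formula(self, rng):
        for _ in range(20):
            counts = tuple(int(c) for c in rng.integers(5, 200, size=3))
            n = sum(counts)
            p = (2 * counts[0] + counts[1]) / (2 * n)
            expected = (n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2)
            chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
            assert hwe_test(counts).chi2 == pytest.approx(chi2, abs=1e-10)

    @pytest.mark.parametrize("counts", [(4, 1, 0), (3, 2, 1), (8, 1, 1), (0, 1, 4)])
    def test_exact_path_matches_enumeration(self, counts):
        res = hwe_test(counts)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(hwe_exact_enumeration(*counts), abs=1e-9)

    def test_exact_enumeration_all_small_totals(self):
        # every genotype configuration with total <= 20 and expected < 5 path
        for n0 in range(0, 8):
            for n1 in range(0, 8):
                for n2 in range(0, 8):
                    if n0 + n1 + n2 < 1 or (n0 + n2 == 0 and n1 == 0):
                        continue
                    res = hwe_test((n0, n1, n2))
                    if res.method == "exact":
                        assert res.p_value == pytest.approx(
                            hwe_exact_enumeration(n0, n1, n2), abs=1e-9
                        )
                    assert 0.0 <= res.p_value <= 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(InsufficientDataError):
            hwe_test((0, 0, 0))


class TestAlleleFreqTest:
    def test_identical_frequencies(self):
        res = allele_freq_test((500, 500), (500, 500))
        assert res.method == "chi2"
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_path_enumeration(self):
        # table ((10,0),(0,10)): hypergeometric two-sided p = 2/C(20,10)
        res = allele_freq_test((10, 0), (0, 10))
        assert res.method == "fisher"
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_empty_margin_rejected(self):
        with pytest.raises(InsufficientDataError):
            allele_freq_test((0, 0), (5, 5))

    def test_power_at_study_size(self, sim_config):
        # the largest configured shift (rs4299376: 0.31 -> 0.42) should be
        # detected at study-scale n in most seeds
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            eur = simulate_genotypes_hwe(503, {"rs4299376": 0.31}, seed=seed)
            mneg = simulate_genotypes_hwe(420, {"rs4299376": 0.42}, seed=50_000 + seed)
            res = allele_freq_test(
                allele_counts(mneg.column("rs4299376")),
                allele_counts(eur.column("rs4299376")),
            )
            hits += res.p_value < 0.05
        assert hits >= 0.8 * n_seeds


class TestStepwise:
    def _simulate(self, seed, n=2000, n_null=9, beta=math.log(1.5), freq=0.3):
        rng = np.random.default_rng(seed)
        cols = {f"snp{j}": rng.binomial(2, freq, size=n).astype(float)
                for j in range(n_null)}
        causal = rng.binomial(2, freq, size=n).astype(float)
        cols["causal"] = causal
        logit = -0.6 + beta * causal
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return pd.DataFrame(cols), y

    def test_recovers_causal_snp(self):
        X, y = self._simulate(seed=1)
        res = stepwise_logistic(X, y)
        assert "causal" in [r.rsid for r in res.selected]

    def test_null_data_empty_selection(self):
        # perfectly balanced null: dosage identical across classes
        X = pd.DataFrame({"a": [0, 1, 2, 0, 1, 2.0], "b": [2, 1, 0, 2, 1, 0.0]})
        y = [0, 0, 0, 1, 1, 1]
        res = stepwise_logistic(X, y)
        assert res.selected == []

    def test_wald_ci_brackets_or(self):
        X, y = self._simulate(seed=2)
        res = stepwise_logistic(X, y)
        for r in res.selected:
            lo, hi = r.ci95
            assert lo <= r.odds_ratio <= hi
            assert r.odds_ratio > 0

    def test_aic_criterion_also_recovers(self):
        X, y = self._simulate(seed=3)
        res = stepwise_logistic(X, y, criterion="aic")
        assert "causal" in [r.rsid for r in res.selected]

    def test_needs_two_candidates(self):
        with pytest.raises(ConfigError):
            stepwise_logistic(pd.DataFrame({"a": [0.0, 1]}), [0, 1])

    def test_score_equations_at_convergence(self):
        X, y = self._simulate(seed=4, n=500, n_null=3)
        res = _fit_logit(X, np.asarray(y, dtype=float))
        grad = res.model.score(res.params)
        assert np.linalg.norm(grad) < 1e-6

    def test_single_binary_predictor_matches_cross_product(self, rng):
        x = rng.integers(0, 2, size=400).astype(float)
        y = (rng.random(400) < np.where(x > 0, 0.6, 0.4)).astype(float)
        res = _fit_logit(pd.DataFrame({"x": x}), y)
        n11 = ((x == 1) & (y == 1)).sum()
        n10 = ((x == 1) & (y == 0)).sum()
        n01 = ((x == 0) & (y == 1)).sum()
        n00 = ((x == 0) & (y == 0)).sum()
        assert math.exp(res.params["x"]) == pytest.approx(
            (n11 * n00) / (n10 * n01), rel=1e-6
        )


class TestGroupCompare:
    def test_identical_constant_groups(self):
        rep = group_compare({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert rep.pairwise[0].p_value == 1.0

    def test_gaussian_groups_use_t(self, rng):
        rep = group_compare({
            "a": rng.normal(0, 1, 200), "b": rng.normal(0, 1, 200)
        })
        assert rep.pairwise[0].test == "t"

    def test_skewed_groups_use_wilcoxon(self, rng):
        rep = group_compare({
            "a": rng.exponential(1, 200), "b": rng.exponential(1, 200)
        })
        assert rep.pairwise[0].test == "wilcoxon"

    def test_three_null_groups_calibrated(self):
        low = 0
        n_seeds = 30
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            rep = group_compare({
                g: r.normal(0, 1, 80) for g in ("a", "b", "c")
            })
            assert rep.omnibus_test in ("anova", "kruskal")
            low += rep.omnibus_p < 0.05
        assert low <= 7

    def test_moments_reported(self, rng):
        x = rng.normal(5, 2, 300)
        rep = group_compare({"a": x, "b": rng.normal(0, 1, 50)})
        assert rep.moments["a"]["mean"] == pytest.approx(x.mean())
        assert rep.moments["a"]["sd"] == pytest.approx(x.std(ddof=1))
        assert rep.moments["a"]["n"] == 300


class TestCochranArmitage:
    def test_flat_proportions(self):
        table = [(10, 90)] * 5
        z, p = cochran_armitage(table)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_increasing_trend_detected(self, rng):
        props = (0.1, 0.3, 0.5, 0.7, 0.9)
        table = [(int(50 * q), 50 - int(50 * q)) for q in props]
        z, p = cochran_armitage(table)
        assert z > 0
        assert p < 1e-6

    def test_affine_invariance(self):
        table = [(5, 45), (12, 38), (20, 30), (26, 24)]
        z1, p1 = cochran_armitage(table, scores=[1, 2, 3, 4])
        z2, p2 = cochran_armitage(table, scores=[10, 30, 50, 70])
        assert z1 == pytest.approx(z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_k2_reduces_to_chi2(self):
        # z^2 = chi2_pearson * (N-1)/N for a 2x2 table
        table = [(30, 70), (50, 50)]
        z, _ = cochran_armitage(table)
        chi2 = sps.chi2_contingency(np.array(table), correction=False)[0]
        n = sum(sum(row) for row in table)
        assert z**2 == pytest.approx(chi2 * (n - 1) / n, rel=1e-12)

    def test_single_category_rejected(self):
        with pytest.raises(InsufficientDataError):
            cochran_armitage([(10, 20)])

    def test_matches_permutation_null(self, rng):
        # exact permutation null sampled via multivariate hypergeometric
        table = [(14, 36), (20, 30), (22, 28), (28, 22), (31, 19)]
        z, p_asym = cochran_armitage(table)
        n_k = np.array([sum(row) for row in table])
        a = sum(row[0] for row in table)
        scores = np.arange(1, 6)
        draws = sps.multivariate_hypergeom.rvs(
            m=n_k, n=a, size=100_000, random_state=np.random.default_rng(0)
        )
        t_obs = (scores * np.array([row[0] for row in table])).sum()
        t_null = draws @ scores
        mean = t_null.mean()
        p_perm = np.mean(np.abs(t_null - mean) >= abs(t_obs - mean) - 1e-9)
        assert p_asym == pytest.approx(p_perm, abs=0.01)


class TestAdjustedAssoc:
    def _simulate(self, seed, slope, n=600, confound=False):
        rng = np.random.default_rng(seed)
        wgs = rng.normal(0.8, 0.2, n)
        age = rng.normal(45, 12, n)
        sex = np.where(rng.random(n) < 0.5, "M", "F")
        logit = -0.2 + slope * (wgs - 0.8)
        if confound:
            # component depends on age only; age correlated with the score
            age = age + 20 * (wgs - 0.8)
            logit = -0.2 + 0.05 * (age - 45)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return wgs, y, age, sex

    def test_null_coefficient_near_zero(self):
        hits = 0
        for seed in range(20):
            wgs, y, age, sex = self._simulate(seed, slope=0.0)
            res = adjusted_component_assoc(wgs, y, age, sex)
            lo, hi = res.ci95
            hits += lo <= 1.0 <= hi
        assert hits >= 17  # 95% CI covers the null OR in most seeds

    def test_negative_dependence_sign_recovered(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            wgs, y, age, sex = self._simulate(seed, slope=-2.0)
            res = adjusted_component_assoc(wgs, y, age, sex)
            hits += res.coefficient < 0
        assert hits >= 0.95 * n_seeds

    def test_confounding_absorbed_by_adjustment(self):
        cover = 0
        for seed in range(20):
            wgs, y, age, sex = self._simulate(seed, slope=0.0, confound=True)
            res = adjusted_component_assoc(wgs, y, age, sex)
            lo, hi = res.ci95
            cover += lo <= 1.0 <= hi
        assert cover >= 16

    def test_returns_result_type(self, rng):
        wgs, y, age, sex = self._simulate(0, slope=1.0)
        assert isinstance(adjusted_component_assoc(wgs, y, age, sex),
                          AdjustedAssocResult)
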