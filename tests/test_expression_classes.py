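import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nucdyn.errors import ValidationError
from nucdyn.expression_classes import (
    AnovaResult,
    adjust_pvalues,
    anova_two_way,
    classify_baseline,
    classify_genes,
    classify_npr1_dependence,
    classify_sa_response,
    two_sample_t,
)
from nucdyn.synthetic_data import SimulationConfig, simulate_dataset


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_anova(values):
    """Explicit sums-of-squares decomposition with plain Python loops."""
    g, t, r = values.shape
    grand = values.mean()
    ss_total = sum(
        (values[i, j, k] - grand) ** 2
        for i in range(g)
        for j in range(t)
        for k in range(r)
    )
    ss_a = sum(
        t * r * (values[i].mean() - grand) ** 2 for i in range(g)
    )
    ss_b = sum(
        g * r * (values[:, j].mean() - grand) ** 2 for j in range(t)
    )
    ss_cells = sum(
        r * (values[i, j].mean() - grand) ** 2 for i in range(g) for j in range(t)
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells
    df_err = g * t * (r - 1)
    out = {}
    for name, ss in (("genotype", ss_a), ("treatment", ss_b), ("interaction", ss_ab)):
        f = ss / (ss_err / df_err)
        out[name] = (f, sps.f.sf(f, 1, df_err))
    out["ss"] = (ss_a, ss_b, ss_ab, ss_err, ss_total)
    return out


def oracle_bh(pvalues):
    """Brute-force Benjamini-Hochberg: q_i = min over p_(j) >= p_i of p_(j)*m/j."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        q[i] = best
    return np.array(q)


class TestAnova:
    def test_additive_interaction_zero(self):
        values = np.array([[[0, 1], [2, 3]], [[1, 2], [3, 4]]], dtype=float)
        res = anova_two_way(values)
        # cell means 0.5, 2.5, 1.5, 3.5: 0.5 - 2.5 - 1.5 + 3.5 = 0
        assert res.f_interaction == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence_100_random_designs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            r = int(rng.integers(2, 6))
            values = rng.normal(size=(2, 2, r))
            res = anova_two_way(values)
            orc = oracle_anova(values)
            assert res.f_genotype == pytest.approx(orc["genotype"][0], abs=1e-9)
            assert res.p_genotype == pytest.approx(orc["genotype"][1], abs=1e-9)
            assert res.f_treatment == pytest.approx(orc["treatment"][0], abs=1e-9)
            assert res.p_treatment == pytest.approx(orc["treatment"][1], abs=1e-9)
            assert res.f_interaction == pytest.approx(orc["interaction"][0], abs=1e-9)
            assert res.p_interaction == pytest.approx(orc["interaction"][1], abs=1e-9)

    def test_statsmodels_equivalence(self):
        import pandas as pd
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(3)
        values = rng.normal(size=(2, 2, 4))
        rows = [
            {"g": g, "t": t, "y": values[g, t, k]}
            for g in range(2)
            for t in range(2)
            for k in range(4)
        ]
        df = pd.DataFrame(rows)
        tab = anova_lm(ols("y ~ C(g) * C(t)", data=df).fit(), typ=2)
        res = anova_two_way(values)
        assert res.f_genotype == pytest.approx(tab.loc["C(g)", "F"], abs=1e-9)
        assert res.f_treatment == pytest.approx(tab.loc["C(t)", "F"], abs=1e-9)
        assert res.f_interaction == pytest.approx(tab.loc["C(g):C(t)", "F"], abs=1e-9)

    def test_ss_conservation(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            values = rng.normal(size=(2, 2, 3))
            res = anova_two_way(values)
            ss_total = float(((values - values.mean()) ** 2).sum())
            assert (
                res.ss_genotype + res.ss_treatment + res.ss_interaction + res.ss_error
            ) == pytest.approx(ss_total, rel=1e-9)

    def test_all_identical_degenerate(self):
        res = anova_two_way(np.full((2, 2, 3), 2.5))
        assert res.degenerate
        assert res.f_genotype == 0.0 and res.p_genotype == 1.0

    def test_degenerate_with_effect(self):
        values = np.zeros((2, 2, 3))
        values[:, 1, :] = 4.0  # exact treatment effect, no noise
        res = anova_two_way(values)
        assert res.degenerate
        assert res.p_treatment < 1e-300
        assert res.p_interaction == 1.0

    def test_requires_two_replicates(self):
        with pytest.raises(ValidationError):
            anova_two_way(np.zeros((2, 2, 1)))


class TestAdjustPvalues:
    def test_bh_worked_example(self):
        q = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_vs_bruteforce_random(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.allclose(adjust_pvalues(p, "bh"), oracle_bh(p), atol=1e-12)

    def test_equal_ps_equal_qs(self):
        q = adjust_pvalues([0.2, 0.2, 0.2], "bh")
        assert len(set(np.round(q, 12))) == 1

    def test_single_p(self):
        assert adjust_pvalues([0.03], "bh")[0] == pytest.approx(0.03)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(31)
        for method in ("bh", "storey"):
            p = rng.uniform(size=30)
            q = adjust_pvalues(p, method)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)

    def test_bh_q_geq_p(self):
        rng = np.random.default_rng(37)
        p = rng.uniform(size=25)
        assert np.all(adjust_pvalues(p, "bh") >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bh_hypothesis(self, p):
        assert np.allclose(adjust_pvalues(p, "bh"), oracle_bh(p), atol=1e-12)


class TestClassificationRules:
    def test_si(self):
        assert classify_sa_response(2.5, 0.01) == "SI"

    def test_sr_inclusive_boundary(self):
        assert classify_sa_response(-2.0, 0.04) == "SR"

    def test_insignificant_none(self):
        assert classify_sa_response(3.0, 0.2) is None

    def test_si_inclusive_boundary(self):
        assert classify_sa_response(2.0, 0.05) == "SI"

    def test_baseline_sil(self):
        assert classify_baseline([-0.2] * 6) == "SIL"

    def test_baseline_con(self):
        assert classify_baseline([5.1] * 6) == "CON"

    def test_baseline_inconsistent(self):
        assert classify_baseline([-0.2, 0.4, -0.1, 0.2, 0.3, -0.3]) is None

    def _anova(self, p_int):
        return AnovaResult(
            f_genotype=1, p_genotype=0.5, f_treatment=50, p_treatment=1e-5,
            f_interaction=1, p_interaction=p_int, df_error=8,
            ss_genotype=0, ss_treatment=0, ss_interaction=0, ss_error=1,
        )

    def test_si_nd(self):
        assert classify_npr1_dependence(self._anova(5e-5), 0.01, 2.4) == "SI-ND"

    def test_sr_ni(self):
        assert classify_npr1_dependence(self._anova(0.5), 0.01, -2.2) == "SR-NI"

    def test_gap_unclassified(self):
        assert classify_npr1_dependence(self._anova(0.01), 0.01, 2.4) == "unclassified"

    def test_not_regulated_unclassified(self):
        assert classify_npr1_dependence(self._anova(5e-5), 0.2, 2.4) == "unclassified"

    def test_genotype_term_option(self):
        # p_genotype = 0.5 >= 0.1 -> NI under the genotype term
        a = self._anova(5e-5)
        assert (
            classify_npr1_dependence(a, 0.01, 2.4, dependence_term="genotype")
            == "SI-NI"
        )
        assert classify_npr1_dependence(a, 0.01, 2.4) == "SI-ND"


class TestTwoSampleT:
    def test_derived_closed_form(self):
        a = np.array([0.89, 0.90, 0.91])
        b = np.array([0.09, 0.10, 0.11])
        t, p = two_sample_t(a, b)
        # closed form: pooled sd = 0.01, se = 0.01*sqrt(2/3)
        se = 0.01 * np.sqrt(2 / 3)
        assert t == pytest.approx(0.8 / se, rel=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(0.8 / se, 4), rel=1e-9)
        assert p < 1e-6

    def test_identical_groups(self):
        assert two_sample_t([1, 1, 1], [1, 1, 1]) == (0.0, 1.0)

    def test_zero_variance_unequal_means(self):
        t, p = two_sample_t([1, 1, 1], [2, 2, 2])
        assert p == pytest.approx(np.finfo(float).tiny)


class TestClassifyGenes:
    def test_truth_recovery_noise_free(self):
        ds = simulate_dataset(SimulationConfig(seed=23, n_genes=24))
        result = classify_genes(ds.expression).set_index("gene_id")
        for gid, info in ds.truth.gene_classes.items():
            row = result.loc[gid]
            expected = info["sa_class"] if info["sa_class"] != "OTHER" else "none"
            assert row["class"] == expected
            expected_sub = info["subclass"] or "unclassified"
            assert row["subclass"] == expected_sub

    def test_class_disjointness(self):
        ds = simulate_dataset(SimulationConfig(seed=29, n_genes=16))
        result = classify_genes(ds.expression)
        both = result[result["sa_class"].notna() & result["baseline_class"].notna()]
        assert both.empty

    def test_unbalanced_design_rejected(self):
        ds = simulate_dataset(SimulationConfig(seed=2, n_genes=4))
        expr = ds.expression.drop(index=0)
        with pytest.raises(ValidationError):
            classify_genes(expr)
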