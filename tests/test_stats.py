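"""Holm-Bonferroni arithmetic and the comparison decision tree."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from atheroflow.stats import compare_groups, holm_bonferroni
from atheroflow.synthetic import make_cohort


class TestHolm:
    def test_worked_example(self):
        assert holm_bonferroni([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_properties_and_statsmodels_agreement(self, pvals):
        adj = holm_bonferroni(pvals)
        p = np.asarray(pvals)
        m = len(p)
        assert np.all(adj >= p - 1e-15)            # never below raw
        assert np.all(adj <= np.minimum(1, m * p) + 1e-12)  # never above Bonferroni
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # order-preserving
        ref = multipletests(p, method="holm")[1]
        assert adj == pytest.approx(ref, abs=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])
        with pytest.raises(ValueError):
            holm_bonferroni([])


def paired_cohort(shift=0.0, seed=0, n=10):
    rng = np.random.default_rng(seed)
    base = rng.normal(10, 2, n)
    rows = []
    for i in range(n):
        rows.append({"mouse": f"m{i}", "group": "pre", "region": "upstream",
                     "week": -1, "measurement": "x", "value": base[i]})
        rows.append({"mouse": f"m{i}", "group": "post", "region": "upstream",
                     "week": 9, "measurement": "x",
                     "value": base[i] + shift + rng.normal(0, 1)})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(42)
        cohort = make_cohort({"9U": 10.0, "9D": 10.0}, sd=2.0, n_per_group=12, seed=42)
        res = compare_groups(cohort, families={"f": [("9U", "9D")]})
        assert all(r.p_adjusted > 0.05 for r in res)

    def test_strong_shift_detected_with_high_power(self):
        hits = 0
        for seed in range(200):
            cohort = make_cohort({"9U": 10.0, "9D": 10.0 + 2 * 3.0}, sd=3.0,
                                 n_per_group=10, seed=seed)
            res = compare_groups(cohort, families={"f": [("9U", "9D")]})
            pairwise = [r for r in res if r.contrast != "omnibus"]
            hits += pairwise[0].significant
        assert hits / 200 > 0.9

    def test_parametric_branch_with_omnibus(self):
        cohort = make_cohort({"9U": 10.0, "9A": 8.0, "9D": 5.0}, sd=1.5,
                             n_per_group=10, seed=3)
        res = compare_groups(
            cohort, families={"f": [("9U", "9A"), ("9U", "9D"), ("9A", "9D")]})
        omni = [r for r in res if r.contrast == "omnibus"]
        assert omni and omni[0].test == "Welch ANOVA"
        pairwise = [r for r in res if r.contrast != "omnibus"]
        assert all("t" in r.test for r in pairwise)
        # Holm within the family: adjusted >= raw, monotone in rank order
        raws = np.array([r.p_raw for r in pairwise])
        adjs = np.array([r.p_adjusted for r in pairwise])
        assert np.all(adjs >= raws)
        assert adjs == pytest.approx(holm_bonferroni(raws))

    def test_nonnormal_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(5)
        rows = []
        for g in ("9U", "9D"):
            for i, v in enumerate(rng.exponential(1.0, 15) ** 3):
                rows.append({"mouse": f"{g}{i}", "group": g, "region": "u",
                             "week": 9, "measurement": "x", "value": v})
        cohort = pd.DataFrame(rows)
        res = compare_groups(cohort, families={"f": [("9U", "9D")]})
        assert res[0].test == "Mann-Whitney U"

    def test_unequal_variances_route_to_welch_t(self):
        rng = np.random.default_rng(8)
        rows = []
        for g, sd in (("9U", 0.5), ("9D", 6.0)):
            for i, v in enumerate(rng.normal(10, sd, 12)):
                rows.append({"mouse": f"{g}{i}", "group": g, "region": "u",
                             "week": 9, "measurement": "x", "value": v})
        res = compare_groups(pd.DataFrame(rows), families={"f": [("9U", "9D")]})
        assert res[0].test == "Welch t"

    def test_paired_branch_uses_paired_tests(self):
        res = compare_groups(paired_cohort(shift=3.0, seed=1), design="paired",
                             families={"f": [("post", "pre")]})
        assert res[0].test in ("paired t", "Wilcoxon signed-rank")
        assert res[0].significant

    def test_paired_missing_mouse_rejected(self):
        cohort = paired_cohort(seed=2).iloc[:-1]  # drop one post measurement
        with pytest.raises(ValueError, match="every mouse"):
            compare_groups(cohort, design="paired", families={"f": [("post", "pre")]})

    def test_one_tailed_direction(self):
        cohort = make_cohort({"9U": 12.0, "9D": 8.0}, sd=1.0, n_per_group=10, seed=9)
        hi = compare_groups(cohort, tails="one", families={"f": [("9U", "9D")]})
        lo = compare_groups(cohort, tails="one", families={"f": [("9D", "9U")]})
        assert hi[0].p_raw < 0.05 < lo[0].p_raw

    def test_families_must_be_declared(self):
        cohort = make_cohort({"9U": 1.0, "9D": 1.0}, sd=1.0, n_per_group=5)
        with pytest.raises(ValueError, match="families"):
            compare_groups(cohort)

    def test_small_groups_rejected(self):
        cohort = make_cohort({"9U": 1.0, "9D": 1.0}, sd=1.0, n_per_group=3)
        res = compare_groups(cohort, families={"f": [("9U", "9D")]})  # n=3 ok
        cohort = cohort.iloc[:-1]
        with pytest.raises(ValueError, match="at least 3"):
            compare_groups(cohort, families={"f": [("9U", "9D")]})
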