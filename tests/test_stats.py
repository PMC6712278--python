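"""Composition tables, five-way ANOVA vs an RSS oracle, BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gusmap.stats import (
    DesignError,
    anova_with_bh,
    bh_correct,
    composition_by_sample,
    five_way_anova,
)
from gusmap.synth import CompositionDesign, make_metadata_and_assignments

from .oracles import anova_type2_oracle, bh_flags_bruteforce


def assignments_frame(rows):
    return pd.DataFrame(rows, columns=["protein_id", "sample_id", "category"])


class TestComposition:
    def test_single_sample_single_category(self):
        df = assignments_frame(
            [(f"p{i}", "S1", "L1") for i in range(5)]
        )
        comp = composition_by_sample(df, categories=["L1", "L2", "NL"])
        by_cat = comp.set_index("category")["proportion"]
        assert by_cat["L1"] == 1.0
        assert by_cat["L2"] == 0.0 and by_cat["NL"] == 0.0

    def test_hand_computed_three_sample_table(self):
        # counts per sample over (A, B, C): S1 2/1/1, S2 0/4/0, S3 1/1/2
        rows = (
            [(f"p{i}", "S1", c) for i, c in enumerate("AABC")]
            + [(f"q{i}", "S2", "B") for i in range(4)]
            + [(f"r{i}", "S3", c) for i, c in enumerate("ABCC")]
        )
        comp = composition_by_sample(assignments_frame(rows))
        pivot = comp.pivot(index="sample_id", columns="category", values="proportion")
        assert pivot.loc["S1"].tolist() == [0.5, 0.25, 0.25]
        assert pivot.loc["S2"].tolist() == [0.0, 1.0, 0.0]
        assert pivot.loc["S3"].tolist() == [0.25, 0.25, 0.5]

    def test_proportions_sum_to_one_on_random_input(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"p{i}", f"S{rng.integers(6)}", "ABCD"[rng.integers(4)])
            for i in range(300)
        ]
        comp = composition_by_sample(assignments_frame(rows))
        sums = comp.groupby("sample_id")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_unclassified_rows_excluded_with_warning_when_sample_empty(self):
        rows = [("p1", "S1", "A"), ("p2", "S2", None)]
        with pytest.warns(UserWarning, match="S2"):
            comp = composition_by_sample(assignments_frame(rows))
        assert set(comp["sample_id"]) == {"S1"}


class TestFiveWayAnova:
    @staticmethod
    def _design(rng_seed=0, n=40, effects=None):
        design = CompositionDesign(n_samples=n, effects=effects or {})
        return make_metadata_and_assignments(design, rng_seed)

    def test_constant_response_gives_f_zero_p_one(self):
        meta, _ = self._design()
        comp = pd.DataFrame(
            {"sample_id": meta["sample_id"], "category": "A", "proportion": 0.25}
        )
        for r in five_way_anova(comp, meta, "A"):
            assert r.F == 0.0 and r.p == 1.0

    def test_two_level_factor_equals_squared_t_statistic(self):
        # one varying two-level factor, others constant (dropped): the
        # one-way F equals the square of the pooled two-sample t statistic
        rng = np.random.default_rng(1)
        n = 20
        meta = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "strain": ["X"] * n, "provider": ["P"] * n, "location": ["L"] * n,
            "sex": ["F"] * n, "diet": ["LF"] * (n // 2) + ["HF"] * (n // 2),
        })
        y = rng.normal(0.3, 0.05, size=n)
        y[n // 2 :] += 0.04
        comp = pd.DataFrame(
            {"sample_id": meta["sample_id"], "category": "A", "proportion": y}
        )
        with pytest.warns(UserWarning):
            results = five_way_anova(comp, meta, "A")
        (diet,) = [r for r in results if r.factor == "diet"]
        g1, g2 = y[: n // 2], y[n // 2 :]
        sp2 = ((g1.var(ddof=1) + g2.var(ddof=1)) / 2)
        t = (g2.mean() - g1.mean()) / np.sqrt(sp2 * 2 / (n // 2))
        assert diet.F == pytest.approx(t**2, rel=1e-9)

    def test_f_matches_rss_oracle_on_random_designs(self):
        rng = np.random.default_rng(2)
        for trial in range(25):
            meta, assign = self._design(rng_seed=100 + trial, n=40)
            comp = composition_by_sample(assign)
            results = five_way_anova(comp, meta, "NL")
            merged = comp[comp["category"] == "NL"].merge(meta, on="sample_id")
            oracle = anova_type2_oracle(
                merged["proportion"].to_numpy(),
                {f: merged[f].to_numpy()
                 for f in ("strain", "provider", "location", "sex", "diet")},
            )
            for r in results:
                F_exp, p_exp = oracle[r.factor]
                assert r.F == pytest.approx(F_exp, rel=1e-6), r.factor
                assert r.p == pytest.approx(p_exp, rel=1e-6, abs=1e-12)

    def test_aliased_design_raises_naming_factors(self):
        n = 12
        meta = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "strain": ["A", "B"] * (n // 2),
            "provider": ["p1", "p2"] * (n // 2),  # perfectly aliased with strain
            "location": ["l1"] * (n // 2) + ["l2"] * (n // 2),
            "sex": ["F", "M"] * (n // 2),
            "diet": ["LF"] * (n // 2) + ["HF"] * (n // 2),
        })
        rng = np.random.default_rng(3)
        comp = pd.DataFrame({
            "sample_id": meta["sample_id"], "category": "A",
            "proportion": rng.uniform(size=n),
        })
        with pytest.raises(DesignError, match="strain|provider"):
            five_way_anova(comp, meta, "A")

    def test_unknown_sample_rejected(self):
        meta, assign = self._design()
        comp = composition_by_sample(assign)
        comp.loc[0, "sample_id"] = "GHOST"
        with pytest.raises(ValueError, match="GHOST"):
            five_way_anova(comp, meta, comp["category"].iloc[0])


class TestBH:
    def test_all_ones_nothing_significant(self):
        assert not bh_correct([1.0, 1.0, 1.0]).any()

    def test_hand_worked_example(self):
        # p=(0.001, 0.2, 0.9), q=0.05: only k=1 satisfies p(k) <= k*q/3
        flags = bh_correct([0.001, 0.2, 0.9], fdr=0.05)
        assert flags.tolist() == [True, False, False]

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_correct([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_correct([-0.1])

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            m = rng.integers(1, 30)
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            assert np.array_equal(bh_correct(p), bh_flags_bruteforce(p))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_flags_are_monotone_in_p(self, pvals):
        flags = bh_correct(pvals)
        if flags.any():
            threshold = max(p for p, f in zip(pvals, flags) if f)
            for p, f in zip(pvals, flags):
                if p <= threshold:
                    assert f


def test_planted_diet_effect_flagged_and_sex_not():
    design = CompositionDesign(
        n_samples=40, effects={"diet": {"HF": {"NL": 0.15, "L2": -0.15}}}
    )
    meta, assign = make_metadata_and_assignments(design, 12)
    comp = composition_by_sample(assign)
    table = anova_with_bh(comp, meta)
    sig = table[table["significant"]]
    assert {("NL", "diet"), ("L2", "diet")} <= set(
        zip(sig["response"], sig["factor"])
    )
    assert not table[(table["factor"] == "sex")]["significant"].any()
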