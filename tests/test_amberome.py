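"""Pulldown enrichment preprocessing and statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ipass.amberome import (
    LfqMatrix,
    attach_contexts,
    enrichment_test,
    filter_min_valid,
    impute_missing,
    normalize_to_proteome,
    perseus_style_de,
    sorte_enrichment,
    stop_codon_summary,
)
from ipass.contexts import SequenceContext
from ipass.synth import gen_lfq_experiment


def _matrix(values: dict, groups: dict) -> LfqMatrix:
    data = pd.DataFrame(values).T
    data.columns = list(groups)
    design = pd.DataFrame(
        [
            {"sample": s, "group": g, "replicate": r}
            for s, (g, r) in groups.items()
        ]
    ).set_index("sample")
    return LfqMatrix(data=data, design=design)


GROUPS_2x2 = {
    "pt1": ("pulldown_treated", 1),
    "pt2": ("pulldown_treated", 2),
    "pc1": ("pulldown_control", 1),
    "pc2": ("pulldown_control", 2),
}


class TestFilterMinValid:
    def test_kept_dropped_and_identity(self):
        nan = np.nan
        groups = {
            "pt1": ("pulldown_treated", 1),
            "pt2": ("pulldown_treated", 2),
            "pt3": ("pulldown_treated", 3),
            "pc1": ("pulldown_control", 1),
            "pc2": ("pulldown_control", 2),
            "pc3": ("pulldown_control", 3),
        }
        m = _matrix(
            {
                "full_one_group": [20, 21, 22, nan, nan, nan],  # kept
                "sparse": [20, nan, nan, nan, 21, nan],  # dropped
                "complete": [20, 21, 22, 23, 24, 25],  # kept
            },
            groups,
        )
        filtered, dropped = filter_min_valid(m, min_per_group=2)
        assert dropped == ["sparse"]
        assert list(filtered.data.index) == ["full_one_group", "complete"]
        # all-complete matrix passes unchanged
        complete = _matrix({"a": [1, 2, 3, 4, 5, 6], "b": [2] * 6}, groups)
        out, dropped = filter_min_valid(complete)
        assert dropped == [] and out.data.equals(complete.data)


class TestImputeMissing:
    def test_no_missing_is_identity_and_deterministic(self):
        m = _matrix({"a": [20.0, 21, 22, 23], "b": [25.0, 24, 23, 22]}, GROUPS_2x2)
        out = impute_missing(m, seed=1)
        pd.testing.assert_frame_equal(out.data, m.data)
        nanm = _matrix(
            {"a": [20.0, np.nan, 22, 23], "b": [25.0, 24, 23, 22], "c": [21.0, 22, 23, 24]},
            GROUPS_2x2,
        )
        o1 = impute_missing(nanm, seed=42)
        o2 = impute_missing(nanm, seed=42)
        pd.testing.assert_frame_equal(o1.data, o2.data)
        assert not o1.data.equals(impute_missing(nanm, seed=43).data)
        # observed cells untouched
        assert o1.data.loc["a", "pt1"] == 20.0

    def test_downshifted_distribution_monte_carlo(self):
        # column with observed mean 20, sd 1 and 1e5 missing cells:
        # imputed values should center on 20 - 1.8 = 18.2 with sd 0.2
        n = 100_000
        col = np.full(n + 3, np.nan)
        col[:3] = [19.0, 20.0, 21.0]  # mean 20, sample sd 1
        groups = {"pt1": ("pulldown_treated", 1), "pt2": ("pulldown_treated", 2)}
        m = _matrix(
            {f"P{i}": [col[i], 20.0] for i in range(n + 3)},
            groups,
        )
        out = impute_missing(m, width=0.2, downshift=1.8, seed=0)
        imputed = out.data["pt1"].to_numpy()[3:]
        se_mean = 0.2 / np.sqrt(n)
        assert abs(imputed.mean() - 18.2) < 3 * se_mean
        assert abs(imputed.std(ddof=1) - 0.2) < 3 * 0.2 / np.sqrt(2 * n)

    def test_column_with_single_value_errors(self):
        m = _matrix({"a": [20.0, np.nan, 22, 23], "b": [np.nan, np.nan, np.nan, 22]}, GROUPS_2x2)
        with pytest.raises(ValueError, match="< 2 observed"):
            impute_missing(m, seed=0)


FULL_DESIGN = {
    f"{g}{r}": (grp, r)
    for g, grp in [
        ("pt", "pulldown_treated"),
        ("pc", "pulldown_control"),
        ("ft", "proteome_treated"),
        ("fc", "proteome_control"),
    ]
    for r in (1, 2)
}


class TestNormalizeToProteome:
    def test_direct_subtraction(self):
        m = _matrix(
            {"P1": [25.0, 25, 20, 20, 20.0, 20, 20, 20]},
            FULL_DESIGN,
        )
        norm = normalize_to_proteome(m)
        assert norm["treated"].loc["P1"].tolist() == [5.0, 5.0]
        assert norm["control"].loc["P1"].tolist() == [0.0, 0.0]

    def test_oracle_random_matrix(self):
        rng = np.random.default_rng(0)
        vals = {f"P{i}": rng.normal(25, 3, 8).tolist() for i in range(20)}
        m = _matrix(vals, FULL_DESIGN)
        norm = normalize_to_proteome(m)
        for pid, row in vals.items():  # independent cell-by-cell subtraction
            assert norm["treated"].loc[pid, 1] == pytest.approx(row[0] - row[4])
            assert norm["treated"].loc[pid, 2] == pytest.approx(row[1] - row[5])
            assert norm["control"].loc[pid, 1] == pytest.approx(row[2] - row[6])

    def test_invariant_to_shared_per_replicate_constant(self):
        rng = np.random.default_rng(1)
        vals = {f"P{i}": rng.normal(25, 3, 8).tolist() for i in range(5)}
        m = _matrix(vals, FULL_DESIGN)
        shifted = m.data.copy()
        shifted["pt1"] += 7.0  # same constant to a pulldown and its matched
        shifted["ft1"] += 7.0  # proteome replicate: abundance-independence
        m2 = LfqMatrix(data=shifted, design=m.design)
        for line in ("treated", "control"):
            pd.testing.assert_frame_equal(
                normalize_to_proteome(m)[line], normalize_to_proteome(m2)[line]
            )

    def test_unpaired_replicate_errors(self):
        design = dict(FULL_DESIGN)
        design.pop("ft2")
        m = _matrix({"P1": [1.0] * 7}, design)
        with pytest.raises(ValueError, match="unpaired"):
            normalize_to_proteome(m)


class TestEnrichmentTest:
    def _frames(self, treated, control):
        t = pd.DataFrame({i: [v] for i, v in enumerate(treated)}, index=["P1"])
        c = pd.DataFrame({i: [v] for i, v in enumerate(control)}, index=["P1"])
        return t, c

    def test_identical_groups(self):
        res = enrichment_test(*self._frames([1.0, 2, 3], [1.0, 2, 3]))
        assert res.loc["P1", "mean_lfc"] == 0.0
        assert res.loc["P1", "p_value"] == pytest.approx(1.0)

    def test_textbook_pooled_t(self):
        # treated {5,6,7} vs control {0,1,2}: sp2 = 1, t = 5/sqrt(2/3), df = 4
        res = enrichment_test(*self._frames([5.0, 6, 7], [0.0, 1, 2]))
        t_expected = 5.0 / np.sqrt(2.0 / 3.0)
        p_expected = 2 * stats.t.sf(t_expected, df=4)
        assert res.loc["P1", "t"] == pytest.approx(t_expected)
        assert res.loc["P1", "p_value"] == pytest.approx(p_expected)
        assert res.loc["P1", "mean_lfc"] == pytest.approx(5.0)
        # agrees with scipy's implementation
        sp = stats.ttest_ind([5.0, 6, 7], [0.0, 1, 2], equal_var=True)
        assert res.loc["P1", "p_value"] == pytest.approx(sp.pvalue)

    def test_label_swap_negates_lfc_preserves_p(self):
        t, c = self._frames([5.0, 6, 7], [0.0, 1, 3])
        a = enrichment_test(t, c)
        b = enrichment_test(c, t)
        assert a.loc["P1", "mean_lfc"] == -b.loc["P1", "mean_lfc"]
        assert a.loc["P1", "p_value"] == pytest.approx(b.loc["P1", "p_value"])

    def test_zero_variance_unequal_means_flagged(self):
        res = enrichment_test(*self._frames([2.0, 2, 2], [0.0, 0, 0]))
        assert res.loc["P1", "p_value"] == 0.0
        assert bool(res.loc["P1", "zero_variance"])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(0)
        n = 10_000
        t = pd.DataFrame(rng.normal(size=(n, 4)))
        c = pd.DataFrame(rng.normal(size=(n, 4)))
        res = enrichment_test(t, c)
        ks = stats.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01


class TestPerseusStyleDe:
    def _null(self, n=200, reps=3, seed=0):
        rng = np.random.default_rng(seed)
        return (
            pd.DataFrame(rng.normal(size=(n, reps))),
            pd.DataFrame(rng.normal(size=(n, reps))),
        )

    def test_identical_groups_nothing_significant(self):
        t, _ = self._null()
        res = perseus_style_de(t, t.copy(), n_perm=50, seed=1)
        assert res["significant"].sum() == 0

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(5)
        n = 200
        t = pd.DataFrame(rng.normal(scale=0.3, size=(n, 3)))
        c = pd.DataFrame(rng.normal(scale=0.3, size=(n, 3)))
        t.iloc[:10] += 4.0  # planted 4 log2-unit shift in 10 proteins
        res = perseus_style_de(t, c, s0=1.0, fdr=0.05, n_perm=100, seed=2)
        assert res["significant"].iloc[:10].all()
        assert res["significant"].iloc[10:].sum() <= 1

    def test_s0_limit_kills_statistic(self):
        t, c = self._null(seed=3)
        res = perseus_style_de(t, c, s0=1e9, n_perm=20, seed=0)
        assert np.abs(res["d"]).max() < 1e-6

    def test_null_fdr_bound(self):
        t, c = self._null(n=2000, reps=4, seed=7)
        res = perseus_style_de(t, c, fdr=0.05, n_perm=100, seed=0)
        rate = res["significant"].mean()
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(res))

    def test_too_few_permutations(self):
        t, c = self._null(reps=2)
        with pytest.raises(ValueError, match="exact enumeration"):
            perseus_style_de(t, c)

    def test_incomplete_matrix_rejected(self):
        t, c = self._null()
        t.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputed"):
            perseus_style_de(t, c)


class TestAttachContexts:
    CTX_A = SequenceContext("AAAAAA", "UAG", "CCCCCC")
    CTX_B = SequenceContext("GGGGGG", "UAG", "CCCCCC")

    def _records(self):
        return pd.DataFrame(
            {
                "mean_lfc": [3.0, 2.5, 0.1, 0.0, 1.0],
                "p_value": [0.001, 0.005, 0.5, 0.9, 0.02],
            },
            index=[f"P{i}" for i in range(1, 6)],
        )

    def test_join_and_partition(self):
        contexts = [("P1", self.CTX_A), ("P2", self.CTX_B), ("P3", self.CTX_A)]
        parts = attach_contexts(self._records(), contexts)
        assert len(parts["enriched"]) == 2  # P1, P2 at p < 0.01
        assert len(parts["background"]) == 1  # P3
        assert set(parts["unresolved"].index) == {"P4", "P5"}

    def test_isoforms_two_distinct_contexts_two_rows(self):
        contexts = [("P1", self.CTX_A), ("P1", self.CTX_B), ("P1", self.CTX_A)]
        parts = attach_contexts(self._records(), contexts)
        assert len(parts["enriched"]) == 2

    def test_empty_contexts(self):
        parts = attach_contexts(self._records(), [])
        assert parts["enriched"].empty and parts["background"].empty
        assert len(parts["unresolved"]) == 5

    def test_conflicting_stop_codons_error(self):
        contexts = [
            ("P1", self.CTX_A),
            ("P1", SequenceContext("AAAAAA", "UGA", "CCCCCC")),
        ]
        with pytest.raises(ValueError, match="conflicting stop"):
            attach_contexts(self._records(), contexts)

    def test_p_exactly_at_cutoff_is_background(self):
        recs = pd.DataFrame(
            {"mean_lfc": [1.0], "p_value": [0.01]}, index=["P1"]
        )
        parts = attach_contexts(recs, [("P1", self.CTX_A)])
        assert parts["background"].shape[0] == 1


class TestStopCodonSummary:
    def test_known_composition(self):
        recs = pd.DataFrame(
            {
                "stop": ["UAG"] * 6 + ["UAA"] * 2 + ["UGA"] * 2,
                "enriched": [True] * 6 + [False] * 4,
                "mean_lfc": [2.0] * 6 + [0.0] * 4,
            }
        )
        summ = stop_codon_summary(recs).set_index(["fraction", "stop"])
        assert summ.loc[("enriched", "UAG"), "count"] == 6
        assert summ.loc[("enriched", "UAG"), "proportion"] == 1.0
        for frac in ("enriched", "background"):
            assert summ.loc[frac]["proportion"].sum() == pytest.approx(1.0)

    def test_all_amber(self):
        recs = pd.DataFrame(
            {"stop": ["UAG"] * 5, "enriched": [True] * 5, "mean_lfc": [1.0] * 5}
        )
        summ = stop_codon_summary(recs)
        row = summ[(summ["fraction"] == "enriched")].iloc[0]
        assert row["proportion"] == 1.0


def test_full_sorte_branch_on_synthetic_experiment():
    m, truth = gen_lfq_experiment(
        n_proteins=300, n_reps=4, frac_amber_enriched=0.1, effect_lfc=3.0, seed=4
    )
    res = sorte_enrichment(m)
    joined = res.join(truth)
    # proteins with too many low-abundance dropouts cannot be tested;
    # among the testable ones recall is high, false positives near nominal
    tested = joined["p_value"].notna()
    planted = joined["enriched_truth"]
    assert joined.loc[planted & tested, "enriched"].mean() >= 0.9
    assert joined.loc[~planted & tested, "enriched"].mean() <= 0.05
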