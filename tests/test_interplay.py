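"""Effect scores, TOST equivalence and IUT interplay classification."""

import math

import numpy as np
import pandas as pd
import pytest

from adjinterplay import (
    SimulationConfig,
    classify_gene,
    classify_table,
    compute_effect_scores,
    effect_contrast,
    generate_dataset,
    summarize_categories,
)
from adjinterplay.interplay import (
    DEFAULT_CATEGORIES,
    MIRROR_MAP,
    UNCLASSIFIED,
    Statement,
    mirror_category,
)
from adjinterplay.interplay import test_equivalence as equivalence_test
from adjinterplay.linear_model import test_contrast as contrast_test
from _oracles import brute_classify_gene, tost_p
from conftest import fitted, make_dataset


def _fit_only(expr, design):
    from adjinterplay import align, fit_cell_means

    return fit_cell_means(*align(expr, design))


class TestEffectScores:
    def test_equal_condition_means_give_zero(self):
        expr, design = make_dataset(
            {"g1": (0.0, 0.0, 0.0), "g2": (0.0, 0.0, 0.0)}, sigma=0.0
        )
        fit = _fit_only(expr, design)
        scores = compute_effect_scores(fit, "2h")
        assert (scores.loc["g1"] == 0.0).all()

    def test_forced_arithmetic(self):
        # cell means PBS=8, MPL=9, QS21=8.5, AS01=11
        expr, design = make_dataset(
            {"g1": (1.0, 0.5, 3.0), "g2": (0.0, 0.0, 0.0)}, sigma=0.0
        )
        fit = _fit_only(expr, design)
        scores = compute_effect_scores(fit, "2h")
        assert scores.loc["g1", "theta_M"] == pytest.approx(1.0)
        assert scores.loc["g1", "theta_Q"] == pytest.approx(0.5)
        assert scores.loc["g1", "theta_A"] == pytest.approx(3.0)

    def test_matches_contrast_estimates(self, small_sim):
        fit, prior = small_sim["fit"], small_sim["prior"]
        scores = compute_effect_scores(fit, "4h")
        for theta, name in (("theta_M", "M"), ("theta_Q", "Q"),
                            ("theta_A", "A")):
            res = contrast_test(fit, prior, effect_contrast(name, "4h"))
            np.testing.assert_allclose(scores[theta], res["estimate"])

    def test_missing_condition_is_error(self, small_sim):
        with pytest.raises(ValueError, match="absent"):
            compute_effect_scores(small_sim["fit"], "17h")


class TestEquivalence:
    def test_estimate_at_margin_never_equivalent(self):
        # an effect sitting exactly on the margin has one one-sided p = 0.5,
        # so TOST can never declare equivalence at alpha = 0.05
        expr, design = make_dataset(
            {"edge": (1.0, 0.0, 0.0), "bg": (0.0, 0.0, 0.0)},
            sigma=0.0, n_rep=6,
        )
        # deterministic within-cell spread that leaves cell means exact
        data = expr.data.copy()
        bump = np.tile([-0.1, 0.0, 0.1], 8)
        for g in data.index:
            data.loc[g] = data.loc[g].to_numpy() + bump
        from adjinterplay import ExpressionMatrix

        fit, prior = fitted(ExpressionMatrix(data), design)
        res = equivalence_test(fit, prior, effect_contrast("M", "2h"))
        assert res.loc["edge", "estimate"] == pytest.approx(1.0)
        assert res.loc["edge", "p"] >= 0.5

    def test_tiny_se_with_null_estimate_gives_tiny_p(self):
        expr, design = make_dataset(
            {f"g{i}": (0.0, 0.0, 0.0) for i in range(5)},
            sigma=1e-4, n_rep=12,
        )
        fit, prior = fitted(expr, design)
        res = equivalence_test(fit, prior, effect_contrast("M", "2h"))
        assert (res["p"] < 1e-10).all()

    def test_matches_independent_t_cdf(self, small_sim):
        """TOST p equals the independently evaluated Student-t tail."""
        fit, prior = small_sim["fit"], small_sim["prior"]
        res = equivalence_test(fit, prior, effect_contrast("D", "6h"),
                               margin=1.0)
        expected = [
            tost_p(row.estimate, row.se, row.df_total, 1.0)
            for row in res.itertuples()
        ]
        np.testing.assert_allclose(res["p"], expected, rtol=1e-12)
        assert ((res["p"] >= 0) & (res["p"] <= 1)).all()

    def test_margin_must_be_positive(self, small_sim):
        with pytest.raises(ValueError, match="margin"):
            equivalence_test(
                small_sim["fit"], small_sim["prior"],
                effect_contrast("M", "2h"), margin=0.0,
            )


NOISE_FREE_CASES = [
    ((0.0, 0.0, 3.0), "emergence"),
    ((2.0, 0.0, 2.0), "irrelevance_of_QS21"),
    ((0.0, 2.0, 2.0), "irrelevance_of_MPL"),
    ((1.5, 1.5, 3.0), "additivity"),
    ((1.5, 1.5, 5.0), "synergy"),
    ((1.5, 1.5, 1.5), "antagonism"),
    ((3.0, 0.0, 4.5), "potentiation_by_QS21"),
    ((3.0, 0.0, 1.5), "inhibition_by_QS21"),
    ((0.0, 3.0, 4.5), "potentiation_by_MPL"),
    ((0.0, 3.0, 1.5), "inhibition_by_MPL"),
]


class TestClassify:
    @pytest.mark.parametrize("theta,expected", NOISE_FREE_CASES)
    def test_noise_free_definitions(self, theta, expected):
        thetas = {"target": theta}
        thetas.update({f"bg{i}": (0.0, 0.0, 0.0) for i in range(9)})
        expr, design = make_dataset(thetas, sigma=1e-3, n_rep=6, seed=1)
        fit, prior = fitted(expr, design)
        call = classify_gene("target", "2h", fit, prior)
        assert call.category == expected
        assert call.iut_p < 0.05

    def test_iut_p_is_max_of_components(self, small_sim):
        """The assigned category's IUT p equals the max of its component
        elementary p-values, recomputed from the call record."""
        fit, prior = small_sim["fit"], small_sim["prior"]
        table = classify_table(fit, prior, "2h")
        by_name = {d.name: d for d in DEFAULT_CATEGORIES}
        checked = 0
        for row in table.itertuples():
            if row.category == UNCLASSIFIED:
                continue
            parts = []
            for s in by_name[row.category].statements:
                cols = [
                    f"p_diff_{c}" if s.kind != "equivalence" else f"p_eq_{c}"
                    for c in s.contrasts
                ]
                vals = [getattr(row, c) for c in cols]
                parts.append(min(vals))
            assert row.iut_p == pytest.approx(max(parts), rel=1e-12)
            checked += 1
        assert checked > 50

    def test_matches_brute_force_enumeration(self):
        """Vectorised classification equals a first-principles IUT
        enumeration over all ten categories, gene by gene."""
        cfg = SimulationConfig(n_genes=150, seed=21, times=("2h",))
        expr, design, _ = generate_dataset(cfg)
        fit, prior = fitted(expr, design)
        table = classify_table(fit, prior, "2h").set_index("gene")
        post = prior.posterior_var(fit)
        df_total = prior.total_df(fit)
        for gene in fit.gene_ids:
            cell_means = {
                cond: fit.coef.loc[gene, (cond, "2h")]
                for cond in ("PBS", "MPL", "QS21", "AS01")
            }
            expected, expected_p = brute_classify_gene(
                cell_means, n_rep=3, s_post=post[gene], df_total=df_total
            )
            assert table.loc[gene, "category"] == expected, gene
            if expected != UNCLASSIFIED:
                assert table.loc[gene, "iut_p"] == pytest.approx(
                    expected_p, rel=1e-9
                )

    def test_unknown_gene_is_error(self, small_sim):
        with pytest.raises(KeyError, match="nope"):
            classify_gene("nope", "2h", small_sim["fit"],
                          small_sim["prior"])

    def test_null_genes_rarely_claim_an_effect(self):
        """IUT level control: among genuinely null genes the rate of
        assignment to any effect-asserting category stays near alpha.
        (A null gene genuinely satisfies the irrelevance equivalences,
        so those assignments are correct rejections, not errors.)"""
        from adjinterplay.interplay import EFFECT_ASSERTING_CATEGORIES

        cfg = SimulationConfig(n_genes=2000, proportions={}, seed=33,
                               times=("2h",))
        expr, design, _ = generate_dataset(cfg)
        fit, prior = fitted(expr, design)
        table = classify_table(fit, prior, "2h")
        rate = table["category"].isin(EFFECT_ASSERTING_CATEGORIES).mean()
        assert rate <= 0.05 + 2.576 * math.sqrt(0.05 * 0.95 / 2000)

    def test_label_symmetry_under_mpl_qs21_swap(self):
        """Swapping the MPL and QS-21 input columns mirrors the sided
        categories and fixes the symmetric ones."""
        cfg = SimulationConfig(n_genes=300, seed=8, times=("2h",))
        expr, design, _ = generate_dataset(cfg)
        fit, prior = fitted(expr, design)
        calls = classify_table(fit, prior, "2h").set_index("gene")

        swapped_design = design.data.copy()
        swapped_design["condition"] = swapped_design["condition"].map(
            {"PBS": "PBS", "MPL": "QS21", "QS21": "MPL", "AS01": "AS01"}
        )
        from adjinterplay import DesignTable

        fit2, prior2 = fitted(expr, DesignTable(swapped_design))
        calls2 = classify_table(fit2, prior2, "2h").set_index("gene")
        mirrored = calls["category"].map(mirror_category)
        assert (calls2["category"] == mirrored).all()

    def test_statement_kind_validation(self):
        with pytest.raises(ValueError, match="kind"):
            Statement(kind="mystery", contrasts=("M",))
        with pytest.raises(ValueError, match="one contrast"):
            Statement(kind="difference", contrasts=("M", "Q"))


class TestSummary:
    def test_zero_degs_gives_empty_total(self, small_sim):
        empty = classify_table(
            small_sim["fit"], small_sim["prior"], "2h", genes=[]
        )
        summary = summarize_categories(empty)
        assert len(summary) == 0 or (summary["total_degs"] == 0).all()

    def test_planted_counts_and_fraction_normalisation(self):
        thetas = {}
        for i in range(10):
            for j, (theta, _) in enumerate(NOISE_FREE_CASES):
                thetas[f"g{j}_{i}"] = theta
        expr, design = make_dataset(thetas, sigma=1e-3, n_rep=6, seed=4)
        fit, prior = fitted(expr, design)
        calls = classify_table(fit, prior, "2h")
        summary = summarize_categories(calls).set_index("category")
        for _, expected in NOISE_FREE_CASES:
            assert summary.loc[expected, "count"] == 10
        assert summary["fraction"].sum() == pytest.approx(1.0)
        assert summary["count"].sum() == len(calls)

    def test_mirror_map_is_involutive(self):
        for a, b in MIRROR_MAP.items():
            assert MIRROR_MAP[b] == a
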