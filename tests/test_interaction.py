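import numpy as np
import pandas as pd
import pytest

from chemoshift.errors import EmptyCellError, FractionError
from chemoshift.interaction import (
    InteractionFit,
    InteractionModel,
    fit_all,
    fit_gene_model,
    rank_and_select,
)
from chemoshift.io import ExpressionMatrix, SampleDesign

from conftest import make_design, matrix_from_cell_means


def diff_of_diffs(cell_means):
    """Independent oracle: e = (alt drug - alt ctrl) - (ref drug - ref ctrl)."""
    return (cell_means[("drug", "CSC")] - cell_means[("control", "CSC")]) - (
        cell_means[("drug", "NT")] - cell_means[("control", "NT")]
    )


class TestFitGeneModel:
    def test_hand_solved_cell_means(self, design2):
        cells = {("control", "NT"): 1.0, ("drug", "NT"): 3.0,
                 ("control", "CSC"): 1.0, ("drug", "CSC"): 2.0}
        m = matrix_from_cell_means(cells, design2)
        fit = fit_gene_model(m.data.iloc[0], design2)
        assert fit.mu == pytest.approx(1.0, abs=1e-12)
        assert fit.d == pytest.approx(2.0, abs=1e-12)
        assert fit.c == pytest.approx(0.0, abs=1e-12)
        assert fit.e == pytest.approx(-1.0, abs=1e-12)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-12)
        assert fit.n_obs == 8

    def test_constant_gene_all_effects_zero(self, design2):
        fit = fit_gene_model([5.0] * 8, design2)
        assert (fit.mu, fit.d, fit.c, fit.e) == pytest.approx((5.0, 0, 0, 0), abs=1e-12)

    def test_additive_cells_have_zero_interaction(self, design2):
        cells = {("control", "NT"): 1.0, ("drug", "NT"): 2.0,
                 ("control", "CSC"): 3.0, ("drug", "CSC"): 4.0}
        m = matrix_from_cell_means(cells, design2)
        assert fit_gene_model(m.data.iloc[0], design2).e == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_alt_phenotype_response_raises_e(self, design2):
        cells = {("control", "NT"): 0.0, ("drug", "NT"): 1.0,
                 ("control", "CSC"): 0.0, ("drug", "CSC"): 2.5}
        m = matrix_from_cell_means(cells, design2)
        assert fit_gene_model(m.data.iloc[0], design2).e > 0

    def test_residual_sd_from_n_minus_4_dof(self, design2):
        # two replicates per cell offset by +/-1: RSS = 8, dof = 4
        cells = {k: 0.0 for k in design2.cells()}
        noise = np.tile([1.0, -1.0], 4)[None, :]
        m = matrix_from_cell_means(cells, design2, noise=noise)
        fit = fit_gene_model(m.data.iloc[0], design2)
        assert fit.resid_sd == pytest.approx(np.sqrt(8 / 4))

    def test_empty_cell_raises(self):
        table = pd.DataFrame(
            {"treatment": ["ctrl", "ctrl", "drug", "drug"],
             "phenotype": ["NT", "NT", "NT", "CSC"],
             "replicate": [1, 2, 1, 1]},
            index=pd.Index(["a", "b", "c", "d"], name="sample"),
        )
        design = SampleDesign(table)
        with pytest.raises(EmptyCellError):
            fit_gene_model([1.0, 2.0, 3.0, 4.0], design)


class TestFitAll:
    def test_matches_per_gene_fit_and_order(self, design2):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(6, 8)),
                          index=[f"g{i}" for i in range(6)],
                          columns=design2.sample_ids)
        matrix = ExpressionMatrix(df)
        fits = fit_all(matrix, design2)
        assert [f.gene for f in fits] == list(df.index)
        for gene, fit in zip(df.index, fits):
            single = fit_gene_model(df.loc[gene], design2, gene=gene)
            for attr in ("mu", "d", "c", "e", "resid_sd"):
                assert getattr(fit, attr) == pytest.approx(getattr(single, attr), abs=1e-10)

    def test_column_permutation_invariance(self, design2):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(4, 8)),
                          index=[f"g{i}" for i in range(4)],
                          columns=design2.sample_ids)
        fits = fit_all(ExpressionMatrix(df), design2)
        perm = rng.permutation(8)
        df_perm = df.iloc[:, perm]
        design_perm = SampleDesign(design2.table.loc[df_perm.columns],
                                   treatment_levels=design2.treatment_levels,
                                   phenotype_levels=design2.phenotype_levels)
        fits_perm = fit_all(ExpressionMatrix(df_perm), design_perm)
        for a, b in zip(fits, fits_perm):
            assert a.e == pytest.approx(b.e, abs=1e-12)
            assert a.mu == pytest.approx(b.mu, abs=1e-12)

    @pytest.mark.parametrize("reps", [2, 3, 5])
    def test_interaction_equals_difference_of_differences(self, reps):
        """OLS e must coincide with the cell-mean contrast on balanced designs."""
        design = make_design(reps_per_cell=reps)
        rng = np.random.default_rng(100 + reps)
        for _ in range(30):
            values = rng.normal(0, 1, len(design.sample_ids))
            fit = fit_gene_model(values, design)
            cells = design.cells()
            series = pd.Series(values, index=design.sample_ids)
            means = {k: series[v].mean() for k, v in cells.items()}
            assert fit.e == pytest.approx(diff_of_diffs(means), abs=1e-10)

    def test_noiseless_planted_parameters_recovered(self, design2):
        mu, d, c, e = 7.0, 1.2, -0.4, -0.6
        treated, alt = design2.indicator_arrays(design2.sample_ids)
        values = mu + d * treated + c * alt + e * treated * alt
        fit = fit_gene_model(values, design2)
        assert (fit.mu, fit.d, fit.c, fit.e) == pytest.approx((mu, d, c, e), abs=1e-12)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-10)


def fits_with_e(e_values, prefix="g"):
    return [InteractionFit(f"{prefix}{i:03d}", 0, 0, 0, e, 0, 8)
            for i, e in enumerate(e_values)]


class TestRankAndSelect:
    def test_five_percent_tails_of_100(self):
        sel = rank_and_select(fits_with_e(np.linspace(-1, 1, 100)), fraction=0.05)
        assert len(sel.top_genes) == len(sel.bottom_genes) == 5
        assert len(sel.responsive) == 10
        assert sel.top_genes[0] == "g099"  # largest e first
        assert sel.bottom_genes[0] == "g000"  # smallest e first

    def test_floor_with_minimum_one(self):
        sel = rank_and_select(fits_with_e(np.linspace(-1, 1, 30)), fraction=0.05)
        assert len(sel.top_genes) == len(sel.bottom_genes) == 1

    def test_all_ties_filled_by_identifier_and_disjoint(self):
        sel = rank_and_select(fits_with_e([0.0] * 40), fraction=0.05)
        assert sel.top_genes == ("g000", "g001")
        assert sel.bottom_genes == ("g002", "g003")
        assert not set(sel.top_genes) & set(sel.bottom_genes)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        fits = fits_with_e(rng.normal(size=60))
        sel = rank_and_select(fits, 0.1)
        shuffled = list(fits)
        rng.shuffle(shuffled)
        sel2 = rank_and_select(shuffled, 0.1)
        assert sel.top_genes == sel2.top_genes
        assert sel.bottom_genes == sel2.bottom_genes

    @pytest.mark.parametrize("fraction", [0.0, 0.5, -0.1, 1.0])
    def test_fraction_domain(self, fraction):
        with pytest.raises(FractionError):
            rank_and_select(fits_with_e([1.0, 2.0, 3.0]), fraction)


class TestModelResultsSurface:
    def test_results_frame_and_summary(self, design2):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(20, 8)),
                          index=[f"g{i}" for i in range(20)],
                          columns=design2.sample_ids)
        results = InteractionModel.from_dataframe(df, design2).fit()
        frame = results.to_frame()
        assert list(frame.columns) == ["mu", "d", "c", "e", "resid_sd", "n_obs"]
        assert len(frame) == 20
        assert "genes: 20" in results.summary()
        sel = results.select_responsive(0.1)
        assert len(sel.top_genes) == 2
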