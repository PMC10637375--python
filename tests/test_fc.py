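"""The three fractional-contribution estimators and their aggregation."""

import numpy as np
import pytest

from gabafc import (
    ExpressionMatrix,
    aggregate_fc,
    fc1_cell,
    fc1_dataset,
    fc2_dataset,
    fc3_dataset,
    summarize_dataset,
)
from gabafc.errors import EstimationError, IntegrityError, PreconditionError
from tests.conftest import make_count_matrix


def panel_matrix(values, panel, unit="UMI"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        dataset_id="d",
        cell_ids=[f"c{i}" for i in range(values.shape[0])],
        gene_symbols=panel.genes,
        values=values,
        unit=unit,
    )


def vec(panel, **counts):
    x = np.zeros(19)
    for g, v in counts.items():
        x[panel.genes.index(g)] = v
    return x


class TestFC1Cell:
    def test_symmetric_split(self, panel):
        p = fc1_cell(vec(panel, GABRA1=5, GABRB2=5), panel)
        assert p.defined
        assert p.fc["GABRA1"] == pytest.approx(50.0)
        assert p.fc["GABRB2"] == pytest.approx(50.0)

    def test_one_to_three_split(self, panel):
        p = fc1_cell(vec(panel, GABRA1=1, GABRB2=3), panel)
        assert p.fc["GABRA1"] == pytest.approx(25.0)
        assert p.fc["GABRB2"] == pytest.approx(75.0)

    def test_all_zero_undefined(self, panel):
        p = fc1_cell(np.zeros(19), panel)
        assert not p.defined
        assert p.fc == {}


class TestFC1Dataset:
    def test_two_point_sample_sd(self, panel):
        m = panel_matrix(
            [vec(panel, GABRA1=7), vec(panel, GABRA2=3)], panel
        )
        s = fc1_dataset(m, panel)
        assert s.table.loc["GABRA1", "fc1_mean"] == pytest.approx(50.0)
        assert s.table.loc["GABRA2", "fc1_mean"] == pytest.approx(50.0)
        # two points at 100 and 0: sample SD = sqrt(2 * 50^2 / 1)
        assert s.table.loc["GABRA1", "fc1_sd"] == pytest.approx(
            70.71067811865476, abs=1e-9
        )

    def test_single_defined_cell_sd_is_nan(self, panel):
        m = panel_matrix([vec(panel, GABRA1=4, GABRB1=4)], panel)
        s = fc1_dataset(m, panel)
        assert s.n_cells_defined == 1
        assert np.isnan(s.table["fc1_sd"]).all()
        assert np.isnan(s.table["fc1_se"]).all()

    def test_zero_defined_cells_is_estimation_error(self, panel):
        with pytest.raises(EstimationError):
            fc1_dataset(panel_matrix(np.zeros((3, 19)), panel), panel)

    def test_panel_silent_cells_excluded_from_averaging(self, panel):
        rows = [vec(panel, GABRA1=10), np.zeros(19)]
        s = fc1_dataset(panel_matrix(rows, panel), panel)
        assert s.n_cells_total == 2
        assert s.n_cells_defined == 1
        assert s.table.loc["GABRA1", "fc1_mean"] == pytest.approx(100.0)

    def test_matches_loop_oracle(self, rng, panel):
        m = make_count_matrix(rng, n_cells=500)
        s = fc1_dataset(m, panel)
        sums = {g: [] for g in panel.genes}
        for i in range(m.n_cells):
            total = sum(m.values[i, m.gene_index(g)] for g in panel.genes)
            if total <= 0:
                continue
            for g in panel.genes:
                sums[g].append(100 * m.values[i, m.gene_index(g)] / total)
        for g in panel.genes:
            arr = np.array(sums[g])
            assert s.table.loc[g, "fc1_mean"] == pytest.approx(
                arr.mean(), abs=1e-10
            )
            assert s.table.loc[g, "fc1_sd"] == pytest.approx(
                arr.std(ddof=1), abs=1e-10
            )

    def test_depth_invariance(self, rng, panel):
        m = make_count_matrix(rng, n_cells=40)
        scales = rng.uniform(0.1, 5.0, size=40)
        scaled = ExpressionMatrix(
            "d", m.cell_ids, m.gene_symbols, m.values * scales[:, None], "FPKM"
        )
        a, b = fc1_dataset(m, panel), fc1_dataset(scaled, panel)
        np.testing.assert_allclose(
            a.table["fc1_mean"], b.table["fc1_mean"], atol=1e-9
        )


class TestFC2:
    def test_single_expressed_gene_takes_all(self, panel):
        m = panel_matrix([vec(panel, GABRE=3), vec(panel, GABRE=1)], panel)
        s = fc2_dataset(m, panel)
        assert s.table.loc["GABRE", "fc2"] == pytest.approx(100.0)
        assert s.table.drop("GABRE")["fc2"].sum() == 0

    def test_uniform_pooled_totals(self, panel):
        m = panel_matrix([np.ones(19)], panel)
        s = fc2_dataset(m, panel)
        np.testing.assert_allclose(s.table["fc2"], 100 / 19, atol=1e-12)

    def test_sums_to_100_and_matches_pooled_oracle(self, rng, panel):
        m = make_count_matrix(rng, n_cells=60)
        s = fc2_dataset(m, panel)
        assert s.table["fc2"].sum() == pytest.approx(100.0, abs=1e-9)
        for g in panel.genes:
            pooled_g = sum(m.values[i, m.gene_index(g)] for i in range(60))
            pooled_all = sum(
                m.values[i, m.gene_index(h)]
                for i in range(60) for h in panel.genes
            )
            assert s.table.loc[g, "fc2"] == pytest.approx(
                100 * pooled_g / pooled_all, abs=1e-10
            )

    def test_fc2_is_depth_weighted_unlike_fc1(self, panel):
        # two cells, same composition ratios but 10x depth difference
        m = panel_matrix(
            [vec(panel, GABRA1=1, GABRB2=1), vec(panel, GABRA1=0, GABRB2=20)],
            panel,
        )
        s1, s2 = fc1_dataset(m, panel), fc2_dataset(m, panel)
        assert s1.table.loc["GABRA1", "fc1_mean"] == pytest.approx(25.0)
        # FC2 pools counts: 1 / 22 for GABRA1
        assert s2.table.loc["GABRA1", "fc2"] == pytest.approx(100 / 22)


class TestFC3:
    def test_detection_fraction(self, panel):
        rows = [vec(panel, GABRG2=i + 1) for i in range(4)] + [np.zeros(19)] * 6
        s = fc3_dataset(panel_matrix(rows, panel), panel)
        assert s.table.loc["GABRG2", "fc3"] == pytest.approx(40.0)

    def test_absent_gene_scores_zero(self, panel):
        s = fc3_dataset(panel_matrix([vec(panel, GABRA1=1)], panel), panel)
        assert s.table.loc["GABRR3", "fc3"] == 0.0

    def test_denominator_includes_panel_silent_cells(self, panel):
        rows = [vec(panel, GABRA1=1), np.zeros(19), np.zeros(19), np.zeros(19)]
        s = fc3_dataset(panel_matrix(rows, panel), panel)
        assert s.table.loc["GABRA1", "fc3"] == pytest.approx(25.0)

    def test_empty_matrix_refused(self, panel):
        with pytest.raises(PreconditionError):
            fc3_dataset(panel_matrix(np.zeros((0, 19)), panel), panel)


class TestAggregate:
    def test_identical_summaries_have_zero_se(self, rng, panel):
        m = make_count_matrix(rng, n_cells=30)
        s1 = summarize_dataset(m, panel)
        m2 = ExpressionMatrix("d2", m.cell_ids, m.gene_symbols,
                              m.values.copy(), "UMI")
        s2 = summarize_dataset(m2, panel)
        agg = aggregate_fc([s1, s2], statistic="fc2")
        np.testing.assert_allclose(agg.grand_se, 0.0, atol=1e-12)
        np.testing.assert_allclose(agg.grand_mean, s1.table["fc2"], atol=1e-12)

    def test_single_dataset_se_is_nan(self, rng, panel):
        s = summarize_dataset(make_count_matrix(rng, n_cells=30), panel)
        agg = aggregate_fc([s])
        assert np.isnan(agg.grand_se).all()
        np.testing.assert_allclose(agg.grand_mean, s.table["fc1_mean"])

    def test_grand_mean_is_unweighted_dataset_mean(self, rng, panel):
        summaries = [
            summarize_dataset(
                make_count_matrix(rng, n_cells=20 + 10 * i,
                                  dataset_id=f"d{i}"),
                panel,
            )
            for i in range(8)
        ]
        agg = aggregate_fc(summaries, statistic="fc2")
        expected = np.mean([s.table["fc2"].to_numpy() for s in summaries], axis=0)
        np.testing.assert_allclose(agg.grand_mean, expected, atol=1e-12)

    def test_mixed_panels_refused(self, rng, panel):
        s1 = summarize_dataset(make_count_matrix(rng, dataset_id="a"), panel)
        s2 = summarize_dataset(make_count_matrix(rng, dataset_id="b"), panel)
        s2.table = s2.table.iloc[::-1]
        with pytest.raises(IntegrityError):
            aggregate_fc([s1, s2])


def test_gene_column_permutation_permutes_fc(rng, panel):
    m = make_count_matrix(rng, n_cells=25)
    perm = rng.permutation(19)
    permuted = ExpressionMatrix(
        "d", m.cell_ids,
        [panel.genes[j] for j in perm] + m.gene_symbols[19:],
        np.hstack([m.values[:, perm], m.values[:, 19:]]),
        "UMI",
    )
    a = summarize_dataset(m, panel).table
    b = summarize_dataset(permuted, panel).table
    np.testing.assert_allclose(a["fc2"], b["fc2"], atol=1e-12)
    np.testing.assert_allclose(a["fc1_mean"], b["fc1_mean"], atol=1e-12)
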