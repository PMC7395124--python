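"""All-pairs coupling, combined chemical shifts, correlation and filtering."""

import numpy as np
import pandas as pd
import pytest

from allonet import (
    CouplingMatrix,
    PropagationConfig,
    ShiftTable,
    chesca_correlation,
    combined_chemical_shift,
    compute_aci,
    correlation_tpr,
    gaussian_filter_matrix,
    make_network,
    pairwise_aci,
    symmetrized,
)


def _shift_table(rows):
    return ShiftTable(pd.DataFrame(rows, columns=["residue", "variant", "H_ppm", "N_ppm"]))


class TestPairwiseAci:
    def test_no_edges_gives_identity(self):
        net = make_network([], n=4)
        mat = pairwise_aci(net, n_rounds=50, seed=0)
        assert np.array_equal(mat.values, np.eye(4))

    def test_two_node_symmetric_edge(self):
        p = 0.45
        net = make_network([(0, 1, p)])
        mat = pairwise_aci(net, n_rounds=10_000, seed=1)
        bound = 4 * np.sqrt(p * (1 - p) / 10_000)
        assert abs(mat.values[0, 1] - p) < bound
        assert abs(mat.values[1, 0] - p) < bound

    def test_tree_rows_match_edge_products(self):
        net = make_network([(0, 1, 0.8), (1, 2, 0.5), (1, 3, 0.4)])
        mat = pairwise_aci(net, n_rounds=10_000, seed=2)
        expected_0 = np.array([1.0, 0.8, 0.4, 0.32])
        bound = 4 * np.sqrt(expected_0 * (1 - expected_0) / 10_000) + 1e-9
        assert np.all(np.abs(mat.values[0] - expected_0) < bound)

    def test_row_equals_single_source_profile_at_same_seed(self):
        net = make_network([(0, 1, 0.6), (1, 2, 0.5)])
        mat = pairwise_aci(net, n_rounds=500, seed=9)
        profile = compute_aci(net, PropagationConfig(source=(1,), n_rounds=500, seed=9))
        assert np.array_equal(mat.values[1], profile.aci)

    def test_symmetrized_variant_flagged(self):
        net = make_network([(0, 1, 0.6)])
        mat = pairwise_aci(net, n_rounds=200, seed=0)
        sym = symmetrized(mat)
        assert np.allclose(sym.values, sym.values.T)
        assert sym.metadata["symmetrized"] is True
        assert mat.metadata["symmetrized"] is False


class TestCombinedChemicalShift:
    def test_direct_formula(self):
        table = _shift_table([(5, "wt", 8.0, 120.0)])
        ccs = combined_chemical_shift(table)
        assert ccs.loc[5, "wt"] == pytest.approx(26.0)

    def test_zero_nitrogen_reduces_to_proton_shift(self):
        table = _shift_table([(1, "wt", 7.5, 0.0)])
        assert combined_chemical_shift(table).loc[1, "wt"] == pytest.approx(7.5)

    def test_linearity(self):
        rows = [(1, "wt", 8.0, 118.0), (1, "m1", 8.1, 119.0)]
        base = combined_chemical_shift(_shift_table(rows))
        scaled_rows = [(r, v, 2 * h, 2 * n) for r, v, h, n in rows]
        scaled = combined_chemical_shift(_shift_table(scaled_rows))
        assert np.allclose(scaled.to_numpy(), 2 * base.to_numpy())

    def test_incomplete_residue_dropped_with_warning(self, caplog):
        rows = [(1, "wt", 8.0, 118.0), (1, "m1", 8.1, 119.0),
                (2, "wt", 7.9, 117.0)]  # residue 2 missing in m1
        with caplog.at_level("WARNING", logger="allonet.correlation_map"):
            ccs = combined_chemical_shift(_shift_table(rows))
        assert list(ccs.index) == [1]
        assert "dropping" in caplog.text

    def test_wildtype_substitution_keeps_residue(self):
        rows = [(1, "wt", 8.0, 118.0), (1, "m1", 8.1, 119.0),
                (2, "wt", 7.9, 117.0)]
        ccs = combined_chemical_shift(_shift_table(rows), substitute_variant="wt")
        assert list(ccs.index) == [1, 2]
        assert ccs.loc[2, "m1"] == ccs.loc[2, "wt"]


class TestChescaCorrelation:
    def test_identical_vectors_correlate_fully(self):
        ccs = pd.DataFrame({"v1": [1.0, 1.0], "v2": [2.0, 2.0], "v3": [3.0, 3.0]},
                           index=[10, 11])
        mat = chesca_correlation(ccs)
        assert mat.values[0, 1] == pytest.approx(1.0)

    def test_anticorrelation_is_absolute(self):
        ccs = pd.DataFrame({"v1": [1.0, 3.0], "v2": [2.0, 2.0], "v3": [3.0, 1.0]},
                           index=[10, 11])
        assert chesca_correlation(ccs).values[0, 1] == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(3)
        ccs = pd.DataFrame(rng.normal(size=(6, 5)),
                           index=range(6), columns=[f"v{i}" for i in range(5)])
        mat = chesca_correlation(ccs).values
        x = ccs.to_numpy()
        for i in range(6):
            for j in range(6):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert mat[i, j] == pytest.approx(abs(r), abs=1e-12)

    def test_too_few_variants_rejected(self):
        ccs = pd.DataFrame({"v1": [1.0, 2.0], "v2": [2.0, 1.0]}, index=[1, 2])
        with pytest.raises(ValueError):
            chesca_correlation(ccs)

    def test_zero_variance_residue_flagged_missing(self):
        ccs = pd.DataFrame({"v1": [1.0, 5.0], "v2": [2.0, 5.0], "v3": [3.0, 5.0]},
                           index=[1, 2])
        mat = chesca_correlation(ccs)
        assert mat.metadata["flat_residues"] == [2]
        assert np.isnan(mat.values[1]).all()
        assert np.isnan(mat.values[:, 1]).all()


class TestGaussianFilter:
    def test_tiny_sigma_is_identity(self):
        rng = np.random.default_rng(4)
        mat = CouplingMatrix(values=rng.uniform(size=(6, 6)), kind="chesca")
        out = gaussian_filter_matrix(mat, sigma=1e-6)
        assert np.allclose(out.values, mat.values, atol=1e-9)

    def test_constant_matrix_unchanged(self):
        mat = CouplingMatrix(values=np.full((7, 7), 0.42), kind="chesca")
        out = gaussian_filter_matrix(mat, sigma=1.5)
        assert np.allclose(out.values, 0.42, atol=1e-12)

    def test_single_spike_matches_discrete_kernel(self):
        n = 13
        values = np.zeros((n, n))
        values[6, 6] = 1.0
        out = gaussian_filter_matrix(CouplingMatrix(values=values, kind="chesca"),
                                     sigma=1.0).values
        # independent closed form: normalized discrete Gaussian, radius 4
        d = np.arange(-4, 5)
        k = np.exp(-d**2 / 2.0)
        k /= k.sum()
        for di in range(-2, 3):
            for dj in range(-2, 3):
                assert out[6 + di, 6 + dj] == pytest.approx(k[4 + di] * k[4 + dj], abs=1e-9)

    def test_values_stay_within_input_range(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.2, 0.8, size=(9, 9))
        out = gaussian_filter_matrix(CouplingMatrix(values=values, kind="chesca"), 2.0)
        assert out.values.min() >= values.min() - 1e-12
        assert out.values.max() <= values.max() + 1e-12

    def test_missing_cells_excluded_and_preserved(self):
        values = np.full((8, 8), 0.5)
        values[2, 3] = values[3, 2] = np.nan
        out = gaussian_filter_matrix(CouplingMatrix(values=values, kind="chesca"), 1.0)
        present = np.isfinite(values)
        # renormalisation over present cells keeps a constant matrix constant
        assert np.allclose(out.values[present], 0.5, atol=1e-12)
        assert np.isnan(out.values[2, 3]) and np.isnan(out.values[3, 2])

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(size=(8, 8))
        sym = 0.5 * (a + a.T)
        out = gaussian_filter_matrix(CouplingMatrix(values=sym, kind="chesca"), 1.0)
        assert np.allclose(out.values, out.values.T, atol=1e-12)


class TestCorrelationTpr:
    def _mats(self, pred, ref, labels):
        return (CouplingMatrix(values=np.asarray(pred, float), kind="predicted_aci",
                               labels=list(labels)),
                CouplingMatrix(values=np.asarray(ref, float), kind="chesca",
                               labels=list(labels)))

    def test_perfect_prediction(self):
        ref = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.7], [0.8, 0.7, 1.0]])
        pred, refm = self._mats(ref, ref, [1, 5, 9])
        assert correlation_tpr(pred, refm, n_top=3) == 1.0

    def test_reference_below_threshold(self):
        pred = np.array([[1.0, 0.9], [0.9, 1.0]])
        ref = np.array([[1.0, 0.2], [0.2, 1.0]])
        p, r = self._mats(pred, ref, [1, 5])
        assert correlation_tpr(p, r, n_top=1) == 0.0

    def test_hand_counted_toy(self):
        labels = [1, 4, 7, 10]  # no adjacent labels
        pred = np.zeros((4, 4))
        ref = np.zeros((4, 4))
        # predicted ranking of the 6 unordered pairs
        pairs = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
                 (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.4}
        hits = {(0, 1): 0.9, (0, 2): 0.1, (0, 3): 0.6,
                (1, 2): 0.2, (1, 3): 0.8, (2, 3): 0.9}
        for (i, j), v in pairs.items():
            pred[i, j] = pred[j, i] = v
        for (i, j), v in hits.items():
            ref[i, j] = ref[j, i] = v
        p, r = self._mats(pred, ref, labels)
        # top-4 by prediction: (0,1)T, (0,2)F, (0,3)T, (1,2)F -> 2/4
        assert correlation_tpr(p, r, n_top=4) == pytest.approx(0.5)
        assert correlation_tpr(p, r, n_top=6) == pytest.approx(4 / 6)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(7)
        labels = list(range(0, 20, 2))
        a = rng.uniform(size=(10, 10))
        pred_vals = 0.5 * (a + a.T)
        ref_vals = 0.5 * (rng.uniform(size=(10, 10)) + 0.2)
        ref_vals = 0.5 * (ref_vals + ref_vals.T)
        p1, r = self._mats(pred_vals, ref_vals, labels)
        p2, _ = self._mats(np.sqrt(pred_vals), ref_vals, labels)
        for k in (1, 5, 10, 20):
            assert correlation_tpr(p1, r, k) == correlation_tpr(p2, r, k)

    def test_adjacent_pairs_excluded_by_default(self):
        labels = [1, 2, 5]
        pred = np.ones((3, 3))
        ref = np.zeros((3, 3))
        ref[0, 1] = ref[1, 0] = 0.9  # adjacent pair (1,2) would be the only hit
        p, r = self._mats(pred, ref, labels)
        assert correlation_tpr(p, r, n_top=2) == 0.0
        assert correlation_tpr(p, r, n_top=3, exclude_adjacent=False) == pytest.approx(1 / 3)

    def test_too_few_pairs_rejected(self):
        p, r = self._mats(np.ones((2, 2)), np.ones((2, 2)), [1, 5])
        with pytest.raises(ValueError):
            correlation_tpr(p, r, n_top=5)

    def test_missing_reference_pairs_removed(self):
        labels = [1, 4, 7]
        pred = np.ones((3, 3))
        ref = np.full((3, 3), np.nan)
        ref[0, 1] = ref[1, 0] = 0.9
        p, r = self._mats(pred, ref, labels)
        assert correlation_tpr(p, r, n_top=1) == 1.0
        with pytest.raises(ValueError):
            correlation_tpr(p, r, n_top=2)
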