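"""Marker discovery: filtering, correlation, clustering, selection, paired tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import plasmaqc as pq
from oracle_utils import bh_oracle, paired_t_p_oracle, spearman_oracle


def matrix_from(values, index=None, columns=None):
    df = pd.DataFrame(values, index=index, columns=columns)
    df.index = df.index.astype(str)
    df.columns = [f"S{j + 1}" for j in range(df.shape[1])] if columns is None else df.columns
    return pq.ProteinMatrix(df)


class TestMissingnessFilter:
    def test_strict_exceed_rule(self):
        # missing fractions 0, 0.25, 0.50, 0.75 across four samples
        rows = np.array(
            [
                [1.0, 1.0, 1.0, 1.0],
                [np.nan, 1.0, 1.0, 1.0],
                [np.nan, np.nan, 1.0, 1.0],
                [np.nan, np.nan, np.nan, 1.0],
            ]
        )
        m = matrix_from(rows, index=["A", "B", "C", "D"])
        assert pq.filter_by_missingness(m, 0.5).protein_ids == ["A", "B", "C"]
        assert pq.filter_by_missingness(m, 1.0).protein_ids == ["A", "B", "C", "D"]
        assert pq.filter_by_missingness(m, 0.0).protein_ids == ["A"]

    def test_samples_unchanged(self, small_sim):
        m = small_sim[0]
        assert pq.filter_by_missingness(m).sample_ids == m.sample_ids

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            pq.filter_by_missingness(pq.ProteinMatrix(pd.DataFrame()))


class TestSpearman:
    @pytest.mark.parametrize(
        "values,gradient,expected",
        [
            ([1.0, 2.0, 3.0], [10, 20, 30], 1.0),
            ([1.0, 2.0, 3.0], [30, 20, 10], -1.0),
            ([1.0, 3.0, 2.0, 4.0], [1, 2, 3, 4], 0.8),
        ],
    )
    def test_known_values(self, values, gradient, expected):
        m = matrix_from([values], index=["A"])
        (profile,) = pq.spearman_with_gradient(m, gradient)
        assert profile.rho == pytest.approx(expected)
        assert profile.n_pairs == len(values)

    def test_pairwise_complete_and_undefined(self):
        rows = [[1.0, np.nan, 2.0, 3.0, 4.0], [np.nan, np.nan, np.nan, 1.0, 2.0]]
        m = matrix_from(rows, index=["A", "B"])
        a, b = pq.spearman_with_gradient(m, [1, 2, 3, 4, 5])
        assert a.n_pairs == 4 and a.rho == pytest.approx(1.0)
        assert b.n_pairs == 2 and not b.defined

    def test_constant_gradient_rejected(self):
        m = matrix_from([[1.0, 2.0, 3.0]], index=["A"])
        with pytest.raises(ValueError, match="constant"):
            pq.spearman_with_gradient(m, [5, 5, 5])

    @given(
        st.integers(3, 8).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 5), min_size=n, max_size=n),
                st.lists(st.integers(0, 5), min_size=n, max_size=n),
            )
        )
    )
    def test_matches_rank_pearson_oracle(self, xy):
        x, g = xy
        if len(set(x)) < 2 or len(set(g)) < 2:
            return
        m = matrix_from([np.asarray(x, dtype=float) + 1.0], index=["A"])
        (profile,) = pq.spearman_with_gradient(m, g)
        assert profile.rho == pytest.approx(spearman_oracle(x, g), abs=1e-12)


class TestFuzzyCMeans:
    @staticmethod
    def trend_matrix(seed=0):
        rng = np.random.default_rng(seed)
        levels = np.repeat(np.arange(5.0), 2)  # 5 levels, duplicate samples
        rising = np.array([lv + 1.0 for lv in levels])
        rows = []
        for i in range(20):
            direction = rising if i < 10 else rising[::-1]
            rows.append(direction * (1 + 0.01 * rng.standard_normal(len(levels))) * (i + 1))
        m = matrix_from(np.array(rows), index=[f"P{i:02d}" for i in range(20)])
        return m, levels

    def test_two_archetypes_separate(self):
        m, levels = self.trend_matrix()
        result = pq.fuzzy_cmeans_cluster(m, levels, n_clusters=2, seed=1)
        top = result.membership.to_numpy().argmax(axis=1)
        assert (result.membership.max(axis=1) >= 0.9).all()
        assert len(set(top[:10])) == 1 and len(set(top[10:])) == 1
        assert top[0] != top[10]

    def test_memberships_row_normalized(self, small_sim):
        m, meta, _ = small_sim
        levels = [x.gradient_value for x in meta]
        result = pq.fuzzy_cmeans_cluster(pq.filter_by_missingness(m), levels, n_clusters=4, seed=2)
        sums = result.membership.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_centroids_zero_mean(self):
        m, levels = self.trend_matrix()
        result = pq.fuzzy_cmeans_cluster(m, levels, n_clusters=2, seed=1)
        assert np.allclose(result.cluster_centroids.mean(axis=1), 0.0, atol=1e-6)

    def test_same_seed_identical(self):
        m, levels = self.trend_matrix()
        a = pq.fuzzy_cmeans_cluster(m, levels, n_clusters=3, seed=5)
        b = pq.fuzzy_cmeans_cluster(m, levels, n_clusters=3, seed=5)
        pd.testing.assert_frame_equal(a.membership, b.membership)

    def test_too_many_clusters(self):
        m, levels = self.trend_matrix()
        with pytest.raises(ValueError, match="exceeds"):
            pq.fuzzy_cmeans_cluster(m, levels, n_clusters=50)


class TestMarkerSelection:
    def test_recovers_planted_markers(self, dilution_sim):
        m, meta, truth = dilution_sim
        filtered = pq.filter_by_missingness(m)
        gradient = {x.sample_id: x.gradient_value for x in meta}
        panel = pq.select_contamination_markers(filtered, gradient)
        assert len(panel) == 30
        planted = set(truth.planted_marker_ids)
        assert all(p in planted for p in panel.marker_ids)

    def test_panel_equals_pool_sorted_by_abundance(self):
        # five perfectly rising proteins with distinct abundances
        base = np.array([[1, 2, 3, 4.0]])
        rows = np.vstack([base * scale for scale in (3, 1, 5, 2, 4)])
        m = matrix_from(rows, index=["A", "B", "C", "D", "E"])
        panel = pq.select_contamination_markers(
            m, [1, 2, 3, 4], correlation_pool=5, panel_size=5
        )
        assert list(panel.marker_ids) == ["C", "E", "A", "D", "B"]

    def test_tie_breaks_lexicographic(self):
        rows = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        m = matrix_from(rows, index=["B", "A", "Z"])
        panel = pq.select_contamination_markers(m, [1, 2, 3], correlation_pool=3, panel_size=2)
        # Z wins on abundance; A and B tie on rho and abundance -> A
        assert list(panel.marker_ids) == ["Z", "A"]

    def test_too_few_proteins(self):
        m = matrix_from(np.array([[1.0, 2.0, 3.0]]), index=["A"])
        with pytest.raises(ValueError, match="panel"):
            pq.select_contamination_markers(m, [1, 2, 3], panel_size=5)

    def test_invariance_to_sample_permutation_and_scaling(self, small_sim):
        m, meta, _ = small_sim
        filtered = pq.filter_by_missingness(m)
        gradient = {x.sample_id: x.gradient_value for x in meta}
        panel = pq.select_contamination_markers(filtered, gradient, 60, 20)
        perm = list(np.random.default_rng(0).permutation(filtered.sample_ids))
        m2 = pq.ProteinMatrix(filtered.intensities[perm] * 7.5)
        panel2 = pq.select_contamination_markers(m2, gradient, 60, 20)
        # rank-based rho ignores sample order; a global rescale shifts all
        # abundances identically, so the selection is unchanged
        assert panel2 == panel


class TestIndependentProteins:
    def test_signed_threshold_rules(self):
        rows = np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 5.0],  # rho = 1 -> excluded
                [5.0, 4.0, 3.0, 2.0, 1.0],  # rho = -1 -> included (signed rule)
                [30.0, 10.0, 20.0, 40.0, 50.0],  # rho = 0.7 exactly -> excluded (strict)
                [2.0, 1.0, 3.0, 2.5, 1.5],  # weak association -> included
            ]
        )
        m = matrix_from(rows, index=["UP", "DOWN", "EDGE", "FLAT"])
        out = pq.select_independent_proteins(m, [1, 2, 3, 4, 5])
        assert "UP" not in out and "EDGE" not in out
        assert "DOWN" in out and "FLAT" in out

    def test_requires_presence_at_zero_contamination(self, noiseless_sim):
        m, meta, truth = noiseless_sim
        gradient = {x.sample_id: x.gradient_value for x in meta}
        out = set(pq.select_independent_proteins(m, gradient))
        # planted markers correlate perfectly -> excluded
        assert not out & set(truth.planted_marker_ids)
        # contamination-independent proteins are all recovered
        assert set(truth.independent_ids) <= out


class TestPairedT:
    def test_known_value(self):
        # d = (1, 2, 3): t = 3.4641 on 2 df
        assert pq.paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0742, abs=2e-4)

    def test_identical_pairs_give_one(self):
        assert pq.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_symmetry(self):
        x, y = [1.0, 4.0, 2.0, 6.0], [0.5, 5.0, 1.0, 4.0]
        assert pq.paired_t_test(x, y) == pytest.approx(pq.paired_t_test(y, x))

    def test_matches_t_cdf_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = rng.integers(2, 9)
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert pq.paired_t_test(x, y) == pytest.approx(paired_t_p_oracle(x, y), abs=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            pq.paired_t_test([1.0], [2.0])


class TestBHAdjust:
    def test_hand_stepped_example(self):
        assert np.allclose(pq.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_equal(self):
        assert pq.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(pq.bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pq.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    def test_matches_stepup_oracle(self, p):
        adjusted = pq.bh_adjust(p)
        assert np.allclose(adjusted, bh_oracle(p), atol=1e-12)
        assert (adjusted >= np.asarray(p) - 1e-12).all() and (adjusted <= 1.0).all()


class TestCoagulationSelection:
    def test_noiseless_survivors_are_planted(self):
        m, meta, truth = pq.simulate_paired_plasma_serum(
            n_donors=6, n_proteins=200, n_coag_planted=40, coag_fold=8.0, noise_cv=0.0, seed=6
        )
        pairing = pq.pairing_from_metadata(meta)
        table = pq.coagulation_differential(m, m, pairing)
        survivors = table[(table["fold_change"] > 5) & (table["adj_p"] < 0.05)]
        assert set(survivors["protein_id"]) == set(truth.planted_marker_ids)
        panel = pq.select_coagulation_markers(m, m, pairing)
        assert len(panel) == 20
        assert set(panel.marker_ids) <= set(truth.planted_marker_ids)
        # the panel is the 20 most abundant survivors
        top = survivors.sort_values(
            ["mean_abundance", "protein_id"], ascending=[False, True]
        ).head(20)
        assert list(panel.marker_ids) == list(top["protein_id"])

    @staticmethod
    def paired_matrices(fold_x):
        donors = ["D1", "D2", "D3"]
        serum = pd.DataFrame(
            {f"{d}_serum": [100.0, 50.0] for d in donors}, index=["X", "Y"]
        )
        plasma = pd.DataFrame(
            {f"{d}_plasma": [100.0 * fold_x, 50.0 * 8] for d in donors}, index=["X", "Y"]
        )
        both = pq.ProteinMatrix(pd.concat([plasma, serum], axis=1))
        pairing = {d: {"plasma": [f"{d}_plasma"], "serum": [f"{d}_serum"]} for d in donors}
        return both, pairing

    def test_fold_exactly_five_excluded(self):
        m, pairing = self.paired_matrices(fold_x=5.0)
        with pytest.warns(UserWarning, match="only 1"):
            panel = pq.select_coagulation_markers(m, m, pairing)
        assert list(panel.marker_ids) == ["Y"]

    def test_no_survivors_is_an_error(self):
        m, pairing = self.paired_matrices(fold_x=1.0)
        m2, _ = self.paired_matrices(fold_x=1.0)
        # make Y also non-differential
        flat = pq.ProteinMatrix(m.intensities.copy())
        flat.intensities.loc["Y"] = 50.0
        with pytest.warns(UserWarning, match="no protein passed"):
            with pytest.raises(ValueError, match="cannot build a panel"):
                pq.select_coagulation_markers(flat, flat, pairing)

    def test_empty_pairing_rejected(self, paired_sim):
        m, _, _ = paired_sim
        with pytest.raises(ValueError, match="no paired donors"):
            pq.coagulation_differential(m, m, {})
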