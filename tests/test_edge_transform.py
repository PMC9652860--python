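"""The z-score-product transform, its algebraic identities, Pearson utilities
and the differential-correlation screen."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import edgeqnet as eq
from edgeqnet.errors import (
    DegenerateInputError,
    DegenerateMoleculeError,
    DegenerateStateError,
    MissingMoleculeError,
)
from conftest import random_cohort_pair


def _single_state_cohort(kin_col, sub_col):
    n = len(kin_col)
    protein = eq.CohortMatrix(
        [f"S{i}" for i in range(n)], ["K"], np.asarray(kin_col, float).reshape(-1, 1),
        np.ones(n, dtype=int), "protein",
    )
    phospho = eq.CohortMatrix(
        [f"S{i}" for i in range(n)], ["G_S1"], np.asarray(sub_col, float).reshape(-1, 1),
        np.ones(n, dtype=int), "phosphosite",
    )
    edge = eq.KinaseSubstrateEdge("K→G_S1", "K", "G_S1")
    return protein, phospho, [edge]


class TestStateStats:
    def test_textbook_mean_and_sample_sd(self):
        protein, _, _ = _single_state_cohort([1.0, 2.0, 3.0], [0, 1, 2])
        stats = eq.state_stats(protein)
        assert stats.mu("K", 1) == pytest.approx(2.0)
        assert stats.sigma("K", 1) == pytest.approx(1.0)  # ddof=1

    def test_two_state_values(self):
        # state 1: [1,3] → μ=2, σ=√2 ; state 2: [10,14] → μ=12, σ=√8
        protein = eq.CohortMatrix(
            ["a", "b", "c", "d"], ["K"],
            np.array([[1.0], [3.0], [10.0], [14.0]]),
            np.array([1, 1, 2, 2]), "protein",
        )
        stats = eq.state_stats(protein)
        assert stats.mu("K", 1) == pytest.approx(2.0)
        assert stats.sigma("K", 1) == pytest.approx(np.sqrt(2.0))
        assert stats.mu("K", 2) == pytest.approx(12.0)
        assert stats.sigma("K", 2) == pytest.approx(np.sqrt(8.0))

    def test_constant_molecule_flagged(self, caplog):
        protein = eq.CohortMatrix(
            ["a", "b", "c"], ["K"], np.array([[5.0], [5.0], [5.0]]),
            np.array([1, 1, 1]), "protein",
        )
        with caplog.at_level("WARNING"):
            stats = eq.state_stats(protein)
        assert stats.constant == {"K"}
        assert stats.sigma("K", 1) == 0.0

    def test_single_sample_state_rejected(self):
        protein = eq.CohortMatrix(
            ["a", "b", "c"], ["K"], np.array([[1.0], [2.0], [3.0]]),
            np.array([1, 1, 2]), "protein",
        )
        with pytest.raises(DegenerateStateError):
            eq.state_stats(protein)


class TestEdgeStrength:
    def test_collinear_columns_give_squared_z(self):
        # kinase [1,2,3], substrate [2,4,6]: z = [−1,0,1] each → products [1,0,1]
        protein, phospho, edges = _single_state_cohort([1, 2, 3], [2, 4, 6])
        matrix = eq.edge_strength(protein, phospho, edges)
        assert matrix.column("K→G_S1") == pytest.approx([1.0, 0.0, 1.0])

    def test_kinase_at_state_mean_annihilates_edge(self, rng):
        kin = np.array([1.0, 2.0, 3.0, 2.0])  # last sample at the mean
        sub = rng.normal(size=4)
        protein, phospho, edges = _single_state_cohort(kin, sub)
        matrix = eq.edge_strength(protein, phospho, edges)
        assert matrix.column("K→G_S1")[3] == 0.0

    def test_within_state_sum_equals_nk_minus_1_times_r(self, rng):
        """Σ_j strength[j] over a state = (n_k − 1)·r — brute-force oracle."""
        protein, phospho, edges = random_cohort_pair(rng, 20, 3, 3, min_per_state=4)
        matrix = eq.edge_strength(protein, phospho, edges)
        for e in edges:
            for k in (1, 2):
                mask = protein.state_mask(k)
                lhs = matrix.column(e.edge_id)[mask].sum()
                r = np.corrcoef(
                    protein.column(e.kinase_molecule)[mask],
                    phospho.column(e.substrate_molecule)[mask],
                )[0, 1]
                assert lhs == pytest.approx((mask.sum() - 1) * r, abs=1e-10)

    def test_zero_sigma_molecule_raises(self):
        protein, phospho, edges = _single_state_cohort([1, 1, 1], [2, 4, 6])
        with pytest.raises(DegenerateMoleculeError) as exc:
            eq.edge_strength(protein, phospho, edges)
        assert exc.value.molecule_id == "K"

    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance_of_positive_rescaling(self, a, b):
        rng = np.random.default_rng(5)
        protein, phospho, edges = random_cohort_pair(rng, 12, 2, 2, min_per_state=4)
        base = eq.edge_strength(protein, phospho, edges).strengths
        scaled = eq.CohortMatrix(
            protein.sample_ids, protein.molecule_ids,
            a * protein.values + b, protein.states, "protein",
        )
        again = eq.edge_strength(scaled, phospho, edges).strengths
        assert np.allclose(again, base, atol=1e-10)

    def test_negative_scaling_flips_sign_exactly(self, rng):
        protein, phospho, edges = random_cohort_pair(rng, 12, 2, 2, min_per_state=4)
        base = eq.edge_strength(protein, phospho, edges).strengths
        flipped = eq.CohortMatrix(
            protein.sample_ids, protein.molecule_ids,
            -protein.values, protein.states, "protein",
        )
        again = eq.edge_strength(flipped, phospho, edges).strengths
        assert np.array_equal(again, -base)


class TestTransformNewSample:
    @pytest.fixture()
    def reference(self, rng):
        protein, phospho, edges = random_cohort_pair(rng, 16, 2, 2, min_per_state=6)
        return protein, phospho, edges, eq.reference_stats(protein, phospho)

    def test_patient_at_state_means_maps_to_zero(self, reference):
        protein, phospho, edges, stats = reference
        patient = eq.PatientProfile(
            "new", 1,
            {m: stats.protein.mu(m, 1) for m in protein.molecule_ids},
            {m: stats.phospho.mu(m, 1) for m in phospho.molecule_ids},
        )
        vec = eq.transform_new_sample(patient, stats, edges)
        assert np.array_equal(vec, np.zeros(len(edges)))

    def test_one_and_two_sigma_above_mean_gives_strength_two(self, reference):
        protein, phospho, edges, stats = reference
        patient = eq.PatientProfile(
            "new", 2,
            {m: stats.protein.mu(m, 2) + stats.protein.sigma(m, 2)
             for m in protein.molecule_ids},
            {m: stats.phospho.mu(m, 2) + 2 * stats.phospho.sigma(m, 2)
             for m in phospho.molecule_ids},
        )
        vec = eq.transform_new_sample(patient, stats, edges)
        assert vec == pytest.approx(np.full(len(edges), 2.0))

    def test_training_sample_reproduces_its_row(self, reference):
        protein, phospho, edges, stats = reference
        j = 3
        patient = eq.PatientProfile(
            protein.sample_ids[j], int(protein.states[j]),
            {m: float(protein.column(m)[j]) for m in protein.molecule_ids},
            {m: float(phospho.column(m)[j]) for m in phospho.molecule_ids},
        )
        vec = eq.transform_new_sample(patient, stats, edges)
        row = eq.edge_strength(protein, phospho, edges).strengths[j]
        assert vec == pytest.approx(row, abs=1e-12)

    def test_missing_molecule_listed(self, reference):
        protein, phospho, edges, stats = reference
        patient = eq.PatientProfile("new", 1, {}, {})
        with pytest.raises(MissingMoleculeError) as exc:
            eq.transform_new_sample(patient, stats, edges)
        assert edges[0].kinase_molecule in exc.value.missing

    def test_unknown_state_rejected(self, reference):
        protein, phospho, edges, stats = reference
        one_state = eq.CohortMatrix(
            protein.sample_ids, protein.molecule_ids, protein.values,
            np.ones(len(protein.sample_ids), dtype=int), "protein",
        )
        one_state_ph = eq.CohortMatrix(
            phospho.sample_ids, phospho.molecule_ids, phospho.values,
            np.ones(len(phospho.sample_ids), dtype=int), "phosphosite",
        )
        stats1 = eq.reference_stats(one_state, one_state_ph)
        patient = eq.PatientProfile(
            "new", 2,
            {m: 0.0 for m in protein.molecule_ids},
            {m: 0.0 for m in phospho.molecule_ids},
        )
        with pytest.raises(DegenerateStateError):
            eq.transform_new_sample(patient, stats1, edges)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = eq.pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_perfect_anticorrelation(self):
        x = np.arange(8.0)
        r, _ = eq.pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            eq.pearson(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            eq.pearson(np.array([1.0, 2.0]), np.array([3.0, 4.0]))

    def test_p_value_matches_permutation_null(self, rng):
        """t-based p agrees with an independent 20k-permutation null."""
        n, B = 20, 20_000
        x, y = rng.normal(size=n), rng.normal(size=n)
        r_obs, p_t = eq.pearson(x, y)
        xc = x - x.mean()
        perms = rng.permuted(np.tile(y, (B, 1)), axis=1)
        yc = perms - perms.mean(axis=1, keepdims=True)
        r_perm = (yc @ xc) / (
            np.linalg.norm(xc) * np.linalg.norm(yc, axis=1)
        )
        p_perm = np.mean(np.abs(r_perm) >= abs(r_obs))
        se = np.sqrt(p_perm * (1 - p_perm) / B)
        assert abs(p_t - p_perm) <= 4 * se


def _pair_with_exact_r(rng, n, r):
    """Construct (x, y) whose empirical Pearson correlation is exactly r."""
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
    ec = e - e.mean() - (e - e.mean()) @ xc * xc
    ec /= np.linalg.norm(ec)
    y = r * xc + np.sqrt(1 - r * r) * ec
    return x, y


class TestDcpScreen:
    def _cohort_from_pairs(self, xy1, xy2):
        x = np.concatenate([xy1[0], xy2[0]])
        y = np.concatenate([xy1[1], xy2[1]])
        n1, n2 = len(xy1[0]), len(xy2[0])
        states = np.array([1] * n1 + [2] * n2)
        ids = [f"S{i}" for i in range(n1 + n2)]
        protein = eq.CohortMatrix(ids, ["K"], x.reshape(-1, 1), states, "protein")
        phospho = eq.CohortMatrix(ids, ["G_S1"], y.reshape(-1, 1), states, "phosphosite")
        return protein, phospho

    def test_constructed_differential_pair_selected(self, rng):
        protein, phospho = self._cohort_from_pairs(
            _pair_with_exact_r(rng, 15, 0.95), _pair_with_exact_r(rng, 15, -0.95)
        )
        res = eq.dcp_screen(protein, phospho, [("K", "G_S1")], min_abs_delta=1.0)
        row = res.table.iloc[0]
        assert row["r_state1"] == pytest.approx(0.95, abs=1e-12)
        assert row["r_state2"] == pytest.approx(-0.95, abs=1e-12)
        assert row["delta"] == pytest.approx(1.9, abs=1e-12)
        assert bool(row["selected"])
        assert res.selected_pairs == [("K", "G_S1")]

    def test_equal_correlations_never_selected(self, rng):
        protein, phospho = self._cohort_from_pairs(
            _pair_with_exact_r(rng, 12, 0.6), _pair_with_exact_r(rng, 12, 0.6)
        )
        res = eq.dcp_screen(protein, phospho, [("K", "G_S1")], min_abs_delta=1e-9)
        assert res.table.iloc[0]["delta"] == pytest.approx(0.0, abs=1e-12)
        assert not bool(res.table.iloc[0]["selected"])

    def test_vacuous_thresholds_select_everything(self, rng):
        protein, phospho, edges = random_cohort_pair(rng, 16, 2, 2, min_per_state=6)
        res = eq.dcp_screen(protein, phospho, edges, min_abs_delta=0.0, alpha_level=1.0)
        assert res.table["selected"].all()

    def test_degenerate_column_reported_unselected(self, rng, caplog):
        n = 12
        states = np.array([1] * 6 + [2] * 6)
        ids = [f"S{i}" for i in range(n)]
        protein = eq.CohortMatrix(ids, ["K"], np.ones((n, 1)), states, "protein")
        phospho = eq.CohortMatrix(
            ids, ["G_S1"], rng.normal(size=(n, 1)), states, "phosphosite"
        )
        with caplog.at_level("WARNING"):
            res = eq.dcp_screen(protein, phospho, [("K", "G_S1")])
        row = res.table.iloc[0]
        assert not bool(row["selected"]) and np.isnan(row["delta"])

    def test_small_state_rejected(self, rng):
        protein, phospho = self._cohort_from_pairs(
            _pair_with_exact_r(rng, 3, 0.5), _pair_with_exact_r(rng, 8, 0.5)
        )
        with pytest.raises(DegenerateStateError):
            eq.dcp_screen(protein, phospho, [("K", "G_S1")])


class TestFisherZ:
    def test_identical_correlations_give_p_one(self):
        assert eq.edge_transform.fisher_z_test(0.4, 20, 0.4, 25) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        from scipy import stats as sps

        r1, n1, r2, n2 = 0.8, 18, 0.1, 22
        z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
        assert eq.edge_transform.fisher_z_test(r1, n1, r2, n2) == pytest.approx(
            2 * sps.norm.sf(abs(z)), rel=1e-12
        )
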