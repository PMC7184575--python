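"""Marker QC, imputation, the Fisher allelic filter and the GRM."""

import numpy as np
import pytest
from scipy import stats

from mkgblup import (
    MarkerMatrix,
    compute_grm,
    filter_markers,
    fisher_allelic_filter,
    impute_markers,
)
from mkgblup.genotype import GenotypeDataError


def _planted_matrix(rng, n_lines=10, n_markers=1000, n_low_maf=100, n_over_missing=50):
    """Common markers plus disjoint planted below-MAF and over-missing sets."""
    dosage = 2.0 * (rng.random((n_lines, n_markers)) < 0.5)
    missing = np.zeros((n_lines, n_markers), dtype=bool)
    # below-MAF markers: exactly zero alternate alleles
    dosage[:, :n_low_maf] = 0.0
    # over-missing markers: 9/10 lines missing (0.9 > 0.8)
    missing[: n_lines - 1, n_low_maf : n_low_maf + n_over_missing] = True
    # make sure the remainder passes MAF: force a balanced column
    bulk = slice(n_low_maf + n_over_missing, n_markers)
    dosage[: n_lines // 2, bulk] = 0.0
    dosage[n_lines // 2 :, bulk] = 2.0
    return MarkerMatrix(
        line_ids=[f"L{i}" for i in range(n_lines)],
        marker_ids=[f"M{j}" for j in range(n_markers)],
        dosage=dosage,
        missing=missing,
    )


class TestFilterMarkers:
    def test_planted_counts(self):
        m = _planted_matrix(np.random.default_rng(0))
        out = filter_markers(m, max_missing=0.80, min_maf=0.05)
        assert out.n_markers == 850
        assert out.qc_counts == {
            "removed_missing": 50,
            "removed_maf": 100,
            "retained": 850,
        }

    def test_over_missing_marker_removed(self):
        dosage = np.zeros((10, 2))
        dosage[:5, 0] = 2.0
        dosage[:5, 1] = 2.0
        missing = np.zeros((10, 2), dtype=bool)
        missing[:9, 1] = True  # 0.9 > 0.8
        m = MarkerMatrix([f"L{i}" for i in range(10)], ["keep", "drop"], dosage, missing)
        out = filter_markers(m)
        assert out.marker_ids == ["keep"]

    def test_maf_half_retained_and_boundary_ties_kept(self):
        # MAF exactly 0.5 and ties exactly at the thresholds survive
        dosage = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]] * 5)
        m = MarkerMatrix([f"L{i}" for i in range(20)], ["a", "b"], dosage)
        out = filter_markers(m, min_maf=0.5)
        assert out.n_markers == 2

    def test_all_removed_raises(self):
        m = MarkerMatrix(["x", "y"], ["m"], np.zeros((2, 1)))
        with pytest.raises(GenotypeDataError):
            filter_markers(m)

    def test_order_preserved(self):
        m = _planted_matrix(np.random.default_rng(1))
        out = filter_markers(m)
        surviving = [mid for mid in m.marker_ids if mid in set(out.marker_ids)]
        assert out.marker_ids == surviving


class TestImputeMarkers:
    def test_identity_when_complete(self, tiny_markers):
        complete = tiny_markers.subset_markers(np.array([0, 1]))
        out = impute_markers(complete)
        np.testing.assert_array_equal(out.dosage, complete.dosage)

    def test_column_mean_value(self):
        dosage = np.array([[0.0], [2.0], [2.0], [2.0], [0.0]])
        missing = np.array([[False], [False], [False], [False], [True]])
        m = MarkerMatrix(list("abcde"), ["m"], dosage, missing)
        out = impute_markers(m, "column_mean")
        assert out.dosage[4, 0] == pytest.approx(1.5)
        assert not out.missing.any()

    def test_random_masking_recovers_column_means(self, rng):
        dosage = 2.0 * (rng.random((40, 30)) < 0.4)
        missing = rng.random((40, 30)) < 0.05
        m = MarkerMatrix(
            [f"L{i}" for i in range(40)], [f"M{j}" for j in range(30)], dosage, missing
        )
        out = impute_markers(m, "column_mean")
        for j in range(30):
            obs = dosage[~missing[:, j], j]
            imputed = out.dosage[missing[:, j], j]
            if imputed.size:
                np.testing.assert_allclose(imputed, obs.mean())

    def test_major_allele_gives_integer_dosage(self, rng):
        dosage = np.array([[0.0], [0.0], [2.0]])
        missing = np.array([[False], [False], [True]])
        missing[2, 0] = True
        m = MarkerMatrix(list("abc"), ["m"], dosage, missing)
        out = impute_markers(m, "major_allele")
        assert out.dosage[2, 0] == 0.0


class TestFisherFilter:
    def test_complementary_alleles_retained(self):
        # 25 ref-only and 25 alt-only inbreds: alleles perfectly dependent
        dosage = np.concatenate([np.zeros(25), np.full(25, 2.0)])[:, None]
        m = MarkerMatrix([f"L{i}" for i in range(50)], ["m"], dosage)
        # oracle: exact hypergeometric P for the 2x2 table [[0,25],[25,0]]
        p = stats.fisher_exact([[0, 25], [25, 0]])[1]
        assert p < 0.001
        out = fisher_allelic_filter(m)
        assert out.marker_ids == ["m"]

    def test_independent_alleles_rejected_at_alpha_rate(self):
        # alleles present independently with prob 0.5 each: retention ~ alpha
        rng = np.random.default_rng(5)
        n_markers, n_lines = 2000, 50
        ref = rng.random((n_lines, n_markers)) < 0.5
        alt = rng.random((n_lines, n_markers)) < 0.5
        # dosage: both -> 1 (het), ref only -> 0, alt only -> 2, neither -> missing
        dosage = np.where(ref & alt, 1.0, np.where(alt, 2.0, 0.0))
        missing = ~(ref | alt)
        m = MarkerMatrix(
            [f"L{i}" for i in range(n_lines)],
            [f"M{j}" for j in range(n_markers)],
            dosage,
            missing,
        )
        try:
            out = fisher_allelic_filter(m, alpha=0.001)
            retained = out.n_markers
        except GenotypeDataError:
            retained = 0
        assert retained / n_markers < 0.01  # ~ alpha, generous margin

    def test_monomorphic_marker_removed(self):
        dosage = np.column_stack([np.zeros(30), np.concatenate([np.zeros(15), np.full(15, 2.0)])])
        m = MarkerMatrix([f"L{i}" for i in range(30)], ["mono", "seg"], dosage)
        out = fisher_allelic_filter(m)
        assert "mono" not in out.marker_ids


class TestGrm:
    def test_two_line_hand_oracle(self):
        m = MarkerMatrix(["l1", "l2"], ["m1", "m2"], np.array([[0.0, 0.0], [2.0, 2.0]]))
        G = compute_grm(m).matrix
        np.testing.assert_allclose(G, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)

    def test_trace_identity_and_symmetry(self, rng):
        dosage = 2.0 * (rng.random((30, 200)) < rng.uniform(0.1, 0.5, 200))
        keep = dosage.std(axis=0) > 0
        m = MarkerMatrix(
            [f"L{i}" for i in range(30)],
            [f"M{j}" for j in np.flatnonzero(keep)],
            dosage[:, keep],
        )
        G = compute_grm(m).matrix
        assert np.allclose(G, G.T)
        assert np.trace(G) / 30 == pytest.approx(1.0)

    def test_family_structure_reflected(self):
        rng = np.random.default_rng(11)
        fam_freq = rng.random((2, 2000)) * 0.8 + 0.1
        fam = np.repeat([0, 1], 100)
        p_line = np.clip(fam_freq[fam] + rng.normal(0, 0.05, (200, 2000)), 0.01, 0.99)
        dosage = 2.0 * (rng.random((200, 2000)) < p_line)
        keep = dosage.std(axis=0) > 0
        m = MarkerMatrix(
            [f"L{i}" for i in range(200)],
            [f"M{j}" for j in np.flatnonzero(keep)],
            dosage[:, keep],
        )
        G = compute_grm(m).matrix
        off = ~np.eye(200, dtype=bool)
        same_fam = (fam[:, None] == fam[None, :]) & off
        assert G[same_fam].mean() > G[~same_fam & off].mean()

    def test_marker_duplication_invariance(self, rng):
        dosage = 2.0 * (rng.random((20, 50)) < 0.5)
        keep = dosage.std(axis=0) > 0
        dosage = dosage[:, keep]
        ids = [f"M{j}" for j in range(dosage.shape[1])]
        m1 = MarkerMatrix([f"L{i}" for i in range(20)], ids, dosage)
        m2 = MarkerMatrix(
            [f"L{i}" for i in range(20)],
            ids + [f"{i}dup" for i in ids],
            np.hstack([dosage, dosage]),
        )
        np.testing.assert_allclose(compute_grm(m1).matrix, compute_grm(m2).matrix, atol=1e-10)

    def test_zero_variance_column_rejected(self):
        m = MarkerMatrix(["a", "b"], ["m1", "m2"], np.array([[0.0, 2.0], [0.0, 0.0]]))
        with pytest.raises(GenotypeDataError, match="m1"):
            compute_grm(m)

    def test_line_permutation_equivariance(self, rng):
        dosage = 2.0 * (rng.random((15, 60)) < 0.5)
        keep = dosage.std(axis=0) > 0
        dosage = dosage[:, keep]
        lines = [f"L{i}" for i in range(15)]
        ids = [f"M{j}" for j in range(dosage.shape[1])]
        perm = rng.permutation(15)
        G1 = compute_grm(MarkerMatrix(lines, ids, dosage)).matrix
        G2 = compute_grm(
            MarkerMatrix([lines[i] for i in perm], ids, dosage[perm])
        ).matrix
        np.testing.assert_allclose(G2, G1[np.ix_(perm, perm)], atol=1e-12)


class TestRoundTrips:
    def test_csv_round_trip(self, tiny_markers, tmp_path):
        path = tmp_path / "m.csv"
        tiny_markers.to_csv(path)
        back = MarkerMatrix.from_csv(path)
        assert back.line_ids == tiny_markers.line_ids
        assert back.marker_ids == tiny_markers.marker_ids
        np.testing.assert_array_equal(back.missing, tiny_markers.missing)
        obs = ~tiny_markers.missing
        np.testing.assert_allclose(back.dosage[obs], tiny_markers.dosage[obs])

    def test_vcf_round_trip(self, tiny_markers, tmp_path):
        path = tmp_path / "m.vcf"
        tiny_markers.to_vcf(path)
        back = MarkerMatrix.from_vcf(path)
        assert back.line_ids == tiny_markers.line_ids
        np.testing.assert_array_equal(back.missing, tiny_markers.missing)
        obs = ~tiny_markers.missing
        np.testing.assert_allclose(back.dosage[obs], tiny_markers.dosage[obs])

    def test_filter_impute_grm_deterministic(self, rng):
        dosage = 2.0 * (rng.random((25, 120)) < 0.4)
        missing = rng.random((25, 120)) < 0.1
        m = MarkerMatrix(
            [f"L{i}" for i in range(25)], [f"M{j}" for j in range(120)], dosage, missing
        )
        g1 = compute_grm(impute_markers(filter_markers(m))).matrix
        g2 = compute_grm(impute_markers(filter_markers(m))).matrix
        np.testing.assert_array_equal(g1, g2)
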