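"""Relationship matrices: hand values, brute-force oracle, parameterization identities."""

import numpy as np
import pytest

import varkin as vk
from varkin.kernels import RelationshipMatrix

from conftest import genotypes_from_codes


# ---------------------------------------------------------------- oracle
def brute_force_kernels(codes, approach):
    """Per-locus summation oracle for G, D and the aa-epistatic kernel.

    Written independently of the matrix-algebra path: explicit Python loops
    over individuals and loci, frequencies by direct counting.
    """
    codes = np.asarray(codes)
    n, m = codes.shape
    p = [(sum(codes[:, j]) / (2.0 * n)) for j in range(m)]
    p0 = [(codes[:, j] == 0).sum() / n for j in range(m)]
    p1 = [(codes[:, j] == 1).sum() / n for j in range(m)]
    p2 = [(codes[:, j] == 2).sum() / n for j in range(m)]

    ha = [[codes[i, j] - 2 * p[j] for j in range(m)] for i in range(n)]
    hd = []
    for i in range(n):
        row = []
        for j in range(m):
            if approach == "hwe":
                vals = {
                    0: -2 * p[j] ** 2,
                    1: 2 * p[j] * (1 - p[j]),
                    2: -2 * (1 - p[j]) ** 2,
                }
            else:
                den = p0[j] + p2[j] - (p0[j] - p2[j]) ** 2
                if den <= 1e-12:
                    vals = {0: 0.0, 1: 0.0, 2: 0.0}
                else:
                    vals = {
                        0: -2 * p1[j] * p2[j] / den,
                        1: 4 * p0[j] * p2[j] / den,
                        2: -2 * p0[j] * p1[j] / den,
                    }
            row.append(vals[codes[i, j]])
        hd.append(row)

    def cross(h):
        return [
            [sum(h[i][j] * h[k][j] for j in range(m)) for k in range(n)]
            for i in range(n)
        ]

    GG, DD = cross(ha), cross(hd)
    if approach == "noia":
        g_den = sum(GG[i][i] for i in range(n)) / n
        d_den = sum(DD[i][i] for i in range(n)) / n
    else:
        g_den = 2 * sum(pj * (1 - pj) for pj in p)
        d_den = 4 * sum((pj * (1 - pj)) ** 2 for pj in p)
    G = np.array(GG) / g_den
    D = np.array(DD) / d_den if d_den > 0 else None
    E = G * G
    if approach == "noia":
        E = E / (np.trace(E) / n)
    return G, D, E


@pytest.mark.parametrize("approach", ["noia", "hwe"])
@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_kernels_match_bruteforce_oracle(approach, seed):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(3, 7), rng.integers(2, 5)
    # rejection-sample a panel where every locus is polymorphic with hets
    while True:
        codes = rng.integers(0, 3, (n, m))
        if all(len(set(codes[:, j])) >= 2 and (codes[:, j] == 1).any() for j in range(m)):
            break
    g = genotypes_from_codes(codes)
    stats = vk.locus_stats(g)
    G = vk.build_grm(vk.additive_contrasts(g, stats), stats, approach)
    D = vk.build_drm(vk.dominance_contrasts(g, stats, approach), stats, approach)
    E = vk.build_epistatic(G, G, approach)
    Gb, Db, Eb = brute_force_kernels(codes, approach)
    np.testing.assert_allclose(G.values, Gb, atol=1e-10)
    np.testing.assert_allclose(D.values, Db, atol=1e-10)
    np.testing.assert_allclose(E.values, Eb, atol=1e-10)


# ------------------------------------------------------------- contrasts
class TestAdditiveContrasts:
    def test_hand_column(self, hwe_locus):
        h = vk.additive_contrasts(hwe_locus)
        np.testing.assert_allclose(h.values.ravel(), [-1, 0, 0, 1])

    def test_allele_flip_negates(self, hwe_locus):
        flipped = genotypes_from_codes((2 - hwe_locus.codes).tolist())
        a = vk.additive_contrasts(hwe_locus).values
        b = vk.additive_contrasts(flipped).values
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_columns_centered(self):
        rng = np.random.default_rng(5)
        g = genotypes_from_codes(rng.integers(0, 3, (25, 7)))
        h = vk.additive_contrasts(g)
        np.testing.assert_allclose(h.values.mean(axis=0), 0.0, atol=1e-12)


class TestDominanceContrasts:
    def test_exact_hwe_sample_noia_equals_hwe(self, hwe_locus):
        noia = vk.dominance_contrasts(hwe_locus, approach="noia")
        hwe = vk.dominance_contrasts(hwe_locus, approach="hwe")
        np.testing.assert_allclose(noia.values.ravel(), [-0.5, 0.5, 0.5, -0.5])
        np.testing.assert_allclose(noia.values, hwe.values, atol=1e-12)

    def test_no_heterozygotes_gives_zero_column(self):
        g = genotypes_from_codes([[0], [0], [2], [2]])
        noia = vk.dominance_contrasts(g, approach="noia")
        np.testing.assert_allclose(noia.values, 0.0)

    def test_noia_orthogonal_to_additive(self):
        rng = np.random.default_rng(6)
        g = genotypes_from_codes(rng.integers(0, 3, (40, 12)))
        stats = vk.locus_stats(g)
        ha = vk.additive_contrasts(g, stats).values
        hd = vk.dominance_contrasts(g, stats, "noia").values
        np.testing.assert_allclose((ha * hd).sum(axis=0), 0.0, atol=1e-9)


# ---------------------------------------------------------------- kernels
class TestBuildGrm:
    def test_hwe_sample_hand_values(self, hwe_locus):
        stats = vk.locus_stats(hwe_locus)
        ha = vk.additive_contrasts(hwe_locus, stats)
        G = vk.build_grm(ha, stats, "noia")
        np.testing.assert_allclose(np.diag(G.values), [2, 0, 0, 2])
        assert G.values[0, 3] == pytest.approx(-2.0)
        assert G.scale_denominator == pytest.approx(0.5)
        Gh = vk.build_grm(ha, stats, "hwe")
        np.testing.assert_allclose(G.values, Gh.values, atol=1e-12)

    def test_non_hwe_sample_scalings_differ(self):
        g = genotypes_from_codes([[0], [0], [2], [2]])
        stats = vk.locus_stats(g)
        ha = vk.additive_contrasts(g, stats)
        G_noia = vk.build_grm(ha, stats, "noia")
        G_hwe = vk.build_grm(ha, stats, "hwe")
        np.testing.assert_allclose(np.diag(G_noia.values), 1.0)
        np.testing.assert_allclose(np.diag(G_hwe.values), 2.0)

    def test_noia_trace_mean_one(self):
        rng = np.random.default_rng(7)
        g = genotypes_from_codes(rng.integers(0, 3, (30, 15)))
        stats = vk.locus_stats(g)
        G = vk.build_grm(vk.additive_contrasts(g, stats), stats, "noia")
        assert np.trace(G.values) / G.n == pytest.approx(1.0)

    def test_hwe_is_scalar_multiple_of_noia(self):
        rng = np.random.default_rng(8)
        g = genotypes_from_codes(rng.integers(0, 3, (25, 10)))
        stats = vk.locus_stats(g)
        ha = vk.additive_contrasts(g, stats)
        G_noia = vk.build_grm(ha, stats, "noia").values
        G_hwe = vk.build_grm(ha, stats, "hwe").values
        ratio = G_hwe[G_noia != 0] / G_noia[G_noia != 0]
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-10)

    def test_monomorphic_panel_rejected(self):
        g = genotypes_from_codes([[2], [2], [2]])
        stats = vk.locus_stats(g)
        with pytest.raises(ValueError, match="monomorphic"):
            vk.build_grm(vk.additive_contrasts(g, stats), stats, "noia")


class TestBuildDrm:
    def test_hwe_sample_hand_values(self, hwe_locus):
        stats = vk.locus_stats(hwe_locus)
        hd = vk.dominance_contrasts(hwe_locus, stats, "noia")
        D = vk.build_drm(hd, stats, "noia")
        np.testing.assert_allclose(np.diag(D.values), 1.0)
        # like contrasts attract, unlike repel: h_d = (−.5, .5, .5, −.5)
        assert D.values[0, 3] > 0 and D.values[1, 2] > 0
        assert D.values[0, 1] < 0 and D.values[2, 3] < 0
        assert D.values.sum() == pytest.approx(0.0, abs=1e-8)

    def test_exact_hwe_sample_d_matrices_equal(self):
        # two loci, both with genotype counts in exact HWE proportions
        g = genotypes_from_codes(
            [[0, 0], [1, 1], [1, 1], [2, 2], [0, 1], [1, 0], [1, 2], [2, 1]]
        )
        stats = vk.locus_stats(g)
        D_noia = vk.build_drm(vk.dominance_contrasts(g, stats, "noia"), stats, "noia")
        D_hwe = vk.build_drm(vk.dominance_contrasts(g, stats, "hwe"), stats, "hwe")
        np.testing.assert_allclose(D_noia.values, D_hwe.values, atol=1e-9)

    def test_zero_divisor_error_names_cause(self):
        g = genotypes_from_codes([[0], [0], [2], [2]])
        stats = vk.locus_stats(g)
        hd = vk.dominance_contrasts(g, stats, "noia")
        with pytest.raises(ValueError, match="heterozygotes"):
            vk.build_drm(hd, stats, "noia")


class TestEpistatic:
    def _rm(self, vals):
        return RelationshipMatrix(np.asarray(vals, float), "additive", "noia")

    def test_hadamard_hand_values(self):
        G = self._rm([[1, 0.5], [0.5, 1]])
        E = vk.build_epistatic(G, G, "noia")
        np.testing.assert_allclose(E.values, [[1, 0.25], [0.25, 1]])
        assert E.component == "epistatic_aa"

    def test_noia_scaling_cancels_kernel_scale(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(6, 6))
        G = self._rm(A @ A.T)
        cG = self._rm(3.7 * G.values)
        e1 = vk.build_epistatic(G, G, "noia").values
        e2 = vk.build_epistatic(cG, cG, "noia").values
        np.testing.assert_allclose(e1, e2, rtol=1e-10)

    def test_identity_fixed_point(self):
        eye = self._rm(np.eye(4))
        for approach in ("noia", "hwe"):
            np.testing.assert_allclose(
                vk.build_epistatic(eye, eye, approach).values, np.eye(4)
            )

    def test_component_mapping(self):
        G = self._rm(np.eye(3))
        D = RelationshipMatrix(np.eye(3), "dominance", "noia")
        assert vk.build_epistatic(G, D, "noia").component == "epistatic_ad"
        assert vk.build_epistatic(D, D, "noia").component == "epistatic_dd"

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            vk.build_epistatic(self._rm(np.eye(3)), self._rm(np.eye(4)), "noia")


class TestLegarraFactor:
    def test_hand_values(self):
        assert vk.legarra_factor(np.array([[2.0, 0], [0, 2.0]])) == pytest.approx(1.0)
        assert vk.legarra_factor(np.eye(3)) == pytest.approx(2 / 3)

    def test_noia_grm_factor_is_one(self):
        rng = np.random.default_rng(10)
        g = genotypes_from_codes(rng.integers(0, 3, (30, 20)))
        stats = vk.locus_stats(g)
        G = vk.build_grm(vk.additive_contrasts(g, stats), stats, "noia")
        assert vk.legarra_factor(G) == pytest.approx(1.0, abs=1e-8)


# ------------------------------------------------------------ invariances
@pytest.mark.parametrize("approach", ["noia", "hwe"])
def test_kernels_invariant_to_allele_flip(approach):
    rng = np.random.default_rng(11)
    codes = rng.integers(0, 3, (20, 9))
    flipped = codes.copy()
    flipped[:, ::2] = 2 - flipped[:, ::2]
    out = []
    for c in (codes, flipped):
        g = genotypes_from_codes(c)
        stats = vk.locus_stats(g)
        G = vk.build_grm(vk.additive_contrasts(g, stats), stats, approach)
        D = vk.build_drm(vk.dominance_contrasts(g, stats, approach), stats, approach)
        out.append((G.values, D.values))
    np.testing.assert_allclose(out[0][0], out[1][0], atol=1e-10)
    np.testing.assert_allclose(out[0][1], out[1][1], atol=1e-10)


@pytest.mark.parametrize("approach", ["noia", "hwe"])
def test_kernels_symmetric_and_psd(approach, desk_dataset):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kernels, _ = vk.prepare_kernels(desk_dataset.genotypes, approach, seed=5)
    for mat in kernels.values():
        np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-10)
        evals = np.linalg.eigvalsh(mat.values)
        assert evals.min() >= -1e-8


# ---------------------------------------------------------------- pedigree
class TestPedigreeNumerator:
    def test_full_sibs(self):
        import pandas as pd

        ped = pd.DataFrame(
            {"id": ["s", "d", "o1", "o2"],
             "sire": [None, None, "s", "s"],
             "dam": [None, None, "d", "d"]}
        )
        A = vk.pedigree_numerator(ped)
        np.testing.assert_allclose(np.diag(A.values), 1.0)
        assert A.values[2, 3] == pytest.approx(0.5)

    def test_half_sibs(self):
        import pandas as pd

        ped = pd.DataFrame(
            {"id": ["s", "d1", "d2", "o1", "o2"],
             "sire": [None, None, None, "s", "s"],
             "dam": [None, None, None, "d1", "d2"]}
        )
        A = vk.pedigree_numerator(ped)
        assert A.values[3, 4] == pytest.approx(0.25)

    def test_unsorted_input_and_cycle_detection(self):
        import pandas as pd

        ped = pd.DataFrame(
            {"id": ["o1", "s", "d"], "sire": ["s", None, None], "dam": ["d", None, None]}
        )
        A = vk.pedigree_numerator(ped)
        assert A.ids == ["o1", "s", "d"]
        assert A.values[0, 1] == pytest.approx(0.5)
        cyc = pd.DataFrame({"id": ["a", "b"], "sire": ["b", "a"], "dam": [None, None]})
        with pytest.raises(ValueError, match="cycle"):
            vk.pedigree_numerator(cyc)
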