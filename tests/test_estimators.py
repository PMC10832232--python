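"""Inbreeding estimators and relationship matrices."""

import numpy as np
import pandas as pd
import pytest

from idstrat.data_io import (
    MISSING,
    AlleleFrequencySet,
    GenotypeMatrix,
    build_pedigree,
)
from idstrat.estimators import (
    annual_trend,
    build_relationship_matrix,
    f_grm,
    f_het,
    f_ped,
    f_uni,
    inbreeding_table,
    relationship_matrix_pedigree,
    _fped_slow,
)
from idstrat.simulate import gene_drop_ibd_probability


def _gm(dosages, morgan=None):
    dosages = np.asarray(dosages)
    n, L = dosages.shape
    return GenotypeMatrix(
        dosages,
        [f"i{k}" for k in range(n)],
        pd.DataFrame(
            {
                "chrom": "1",
                "snp_id": [f"s{i}" for i in range(L)],
                "morgan": morgan if morgan is not None else np.linspace(0, 0.5, L),
                "bp": np.arange(1, L + 1),
                "a1": "A",
                "a2": "B",
            }
        ),
    )


def _random_pedigree(rng, n_founders=6, n_extra=20):
    ids = [f"f{k}" for k in range(n_founders)]
    sires = ["0"] * n_founders
    dams = ["0"] * n_founders
    years = [0] * n_founders
    for k in range(n_extra):
        a, b = rng.choice(len(ids), size=2, replace=False)
        ids.append(f"x{k}")
        sires.append(ids[a])
        dams.append(ids[b])
        years.append(max(years[a], years[b]) + 1)
    return build_pedigree(ids, sires, dams, years)


FULL_SIB_PED = build_pedigree(
    ["A", "B", "C", "D", "E"],
    ["0", "0", "A", "A", "C"],
    ["0", "0", "B", "B", "D"],
    [1, 1, 2, 2, 3],
)


class TestPedigreeF:
    def test_textbook_values(self):
        assert f_ped(FULL_SIB_PED)[-1] == pytest.approx(0.25)
        half = build_pedigree(
            ["A", "B", "C", "S1", "S2", "E"],
            ["0", "0", "0", "A", "A", "S1"],
            ["0", "0", "0", "B", "C", "S2"],
            [1, 1, 1, 2, 2, 3],
        )
        assert f_ped(half)[-1] == pytest.approx(0.125)
        trio = build_pedigree(
            ["A", "B", "C"], ["0", "0", "A"], ["0", "0", "B"], [1, 1, 2]
        )
        np.testing.assert_allclose(f_ped(trio), 0.0)

    def test_matches_tabular_method_on_random_pedigrees(self):
        for seed in (1, 2, 3):
            ped = _random_pedigree(np.random.default_rng(seed))
            np.testing.assert_allclose(f_ped(ped), _fped_slow(ped), atol=1e-12)

    def test_matches_gene_drop_oracle(self):
        """Meuwissen-Luo F equals Monte-Carlo identity-by-descent frequency."""
        ped = _random_pedigree(np.random.default_rng(4), n_founders=4, n_extra=8)
        n_drops = 100_000
        mc = gene_drop_ibd_probability(ped, n_drops, seed=10)
        exact = f_ped(ped)
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n_drops)
        assert np.all(np.abs(mc - exact) < 3 * se + 5e-4)


class TestMarkerEstimators:
    def test_f_het_extremes(self):
        af = AlleleFrequencySet(np.full(6, 0.5), "sample")
        all_het = _gm(np.ones((1, 6), dtype=int))
        assert f_het(all_het, af)[0] == pytest.approx(-1.0)
        all_hom = _gm(np.full((1, 6), 2, dtype=int))
        assert f_het(all_hom, af)[0] == pytest.approx(1.0)

    def test_f_het_hand_evaluated(self):
        p = np.array([0.5, 0.5, 0.25, 0.1])
        geno = np.array([[2, 1, 0, 2]])  # hom, het, hom, hom
        e_hom = np.sum(1 - 2 * p * (1 - p))
        expected = (3 - e_hom) / (4 - e_hom)
        got = f_het(_gm(geno), AlleleFrequencySet(p, "sample"))[0]
        assert got == pytest.approx(expected)

    @pytest.mark.parametrize("x, expected", [(1, -1.0), (2, 1.0)])
    def test_f_uni_single_snp(self, x, expected):
        g = _gm(np.array([[x]]))
        af = AlleleFrequencySet(np.array([0.5]), "sample")
        assert f_uni(g, af)[0] == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.1, 0.25, 0.5, 0.8])
    def test_f_uni_and_f_grm2_unbiased_under_hwe(self, p):
        """Expectation over Hardy-Weinberg genotypes is zero, by enumeration."""
        weights = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        af = AlleleFrequencySet(np.array([p]), "sample")
        vals_uni = [f_uni(_gm([[x]]), af)[0] for x in (0, 1, 2)]
        vals_g2 = [f_grm(_gm([[x]]), af, rule=2)[0] for x in (0, 1, 2)]
        assert float(weights @ vals_uni) == pytest.approx(0.0, abs=1e-12)
        assert float(weights @ vals_g2) == pytest.approx(0.0, abs=1e-12)

    def test_f_grm_hand_values(self):
        af = AlleleFrequencySet(np.array([0.5]), "sample")
        assert f_grm(_gm([[2]]), af, rule=1)[0] == pytest.approx(1.0)
        # dosage equal to 2p everywhere -> -1 under both rules
        af2 = AlleleFrequencySet(np.array([0.5, 0.5]), "sample")
        g = _gm([[1, 1]])
        assert f_grm(g, af2, rule=1)[0] == pytest.approx(-1.0)
        assert f_grm(g, af2, rule=2)[0] == pytest.approx(-1.0)

    def test_f_grm_rules_coincide_at_half_frequency(self):
        rng = np.random.default_rng(8)
        g = _gm(rng.integers(0, 3, size=(15, 20)))
        af = AlleleFrequencySet(np.full(20, 0.5), "sample")
        np.testing.assert_allclose(f_grm(g, af, 1), f_grm(g, af, 2))

    def test_monomorphic_marker_rejected(self):
        af = AlleleFrequencySet(np.array([0.0, 0.5]), "sample")
        with pytest.raises(ValueError, match="monomorphic"):
            f_uni(_gm([[0, 1]]), af)

    def test_missing_data_uses_individual_denominators(self):
        p = np.array([0.3, 0.4, 0.2])
        af = AlleleFrequencySet(p, "sample")
        full = _gm([[2, 1, 0]])
        part = _gm([[2, 1, MISSING]])
        exp_part = f_uni(_gm([[2, 1]]), AlleleFrequencySet(p[:2], "sample"))[0]
        assert f_uni(part, af)[0] == pytest.approx(exp_part)
        assert f_uni(part, af)[0] != pytest.approx(f_uni(full, af)[0])


class TestRelationshipMatrices:
    def test_trio_pedigree_matrix(self):
        trio = build_pedigree(
            ["A", "B", "C"], ["0", "0", "A"], ["0", "0", "B"], [1, 1, 2]
        )
        A = relationship_matrix_pedigree(trio)
        np.testing.assert_allclose(
            A, [[1, 0, 0.5], [0, 1, 0.5], [0.5, 0.5, 1]]
        )

    def test_half_freq_similarity_diagonal_all_homozygous(self):
        g = _gm(np.array([[2, 0, 2, 0], [1, 1, 1, 1]]))
        G = build_relationship_matrix("half_freq_similarity", g=g)
        assert G[0, 0] == pytest.approx(2.0)
        assert G[1, 1] == pytest.approx(0.0)

    def test_vanraden1_diagonal_matches_f_grm1(self):
        rng = np.random.default_rng(9)
        g = _gm(rng.integers(0, 3, size=(12, 30)))
        p = np.clip(compute_af(g), 0.05, 0.95)
        af = AlleleFrequencySet(p, "sample")
        G = build_relationship_matrix("vanraden1", g=g, af=af)
        np.testing.assert_allclose(np.diag(G) - 1.0, f_grm(g, af, 1), atol=1e-12)

    def test_vanraden2_against_direct_formula(self):
        rng = np.random.default_rng(10)
        g = _gm(rng.integers(0, 3, size=(6, 12)))
        p = np.clip(compute_af(g), 0.05, 0.95)
        af = AlleleFrequencySet(p, "sample")
        G = build_relationship_matrix("vanraden2", g=g, af=af)
        z = g.dosages - 2 * p
        expect = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                expect[i, j] = np.mean(z[i] * z[j] / (2 * p * (1 - p)))
        np.testing.assert_allclose(G, expect, atol=1e-12)


def compute_af(g):
    return g.dosages.mean(axis=0) / 2.0


class TestAnnualTrend:
    def _table(self, ped, values):
        return pd.DataFrame({"f_ped": values}, index=pd.Index(ped.ids, name="id"))

    def test_constant_f_gives_zero_slope(self):
        ped = build_pedigree(
            ["a", "b", "c"], ["0"] * 3, ["0"] * 3, [2011, 2012, 2013]
        )
        out = annual_trend(self._table(ped, [0.02, 0.02, 0.02]), ped)
        assert out["slope_per_year"][0] == pytest.approx(0.0)

    def test_exact_line(self):
        ped = build_pedigree(
            ["a", "b", "c"], ["0"] * 3, ["0"] * 3, [2011, 2012, 2013]
        )
        out = annual_trend(self._table(ped, [0.02, 0.03, 0.04]), ped)
        assert out["slope_per_year"][0] == pytest.approx(0.01)
        assert out["slope_percent"][0] == pytest.approx(1.0)

    def test_single_year_errors(self):
        ped = build_pedigree(["a", "b"], ["0"] * 2, ["0"] * 2, [2011, 2011])
        with pytest.raises(ValueError, match="two distinct"):
            annual_trend(self._table(ped, [0.1, 0.2]), ped)

    def test_shrinking_population_has_positive_trend(self, small_analysis):
        """Inbreeding accumulates as the breeding population shrinks, so both
        the pedigree and the HBD estimator show a positive slope by birth year."""
        pop = small_analysis["pop"]
        g = small_analysis["genotypes"]
        tab = inbreeding_table(
            g, small_analysis["founder_af"], ped=pop.pedigree,
            f_hbd=small_analysis["dec_founder"].f_hbd,
        )
        out = annual_trend(tab, pop.pedigree).set_index("estimator")
        assert out.loc["f_ped", "slope_per_year"] > 0
        assert out.loc["f_hbd", "slope_per_year"] > 0
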