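"""Heritabilities, EBV correlations and selection responses."""

import numpy as np
import pandas as pd
import pytest

from bubalus import genpar, refdata, reml, simdata
from bubalus.genpar import (
    correlated_response,
    correlation_matrices,
    direct_response,
    genetic_correlation_ebv,
    heritabilities,
    phenotypic_correlation,
    response_matrix,
)
from bubalus.reml import AnimalModelSpec, VarianceComponents, blup_ebv, em_reml


def _vc(sa, sm, se, cov=None):
    vc = VarianceComponents(sa, sm, se)
    vc.cov = cov
    return vc


class TestHeritabilities:
    def test_published_body_weight_row(self):
        h = heritabilities(_vc(260.172, 503.610, 16.163))
        assert round(h.h2_direct, 3) == 0.334
        assert round(h.h2_maternal, 3) == 0.646
        assert round(h.h2_total, 3) == 0.656

    def test_published_wither_height_row(self):
        h = heritabilities(_vc(10.391, 0.002, 11.139))
        assert round(h.h2_direct, 3) == 0.483
        assert round(h.h2_maternal, 3) == 0.000
        assert round(h.h2_total, 3) == 0.483

    def test_zero_maternal_total_equals_direct(self):
        h = heritabilities(_vc(4.0, 0.0, 6.0))
        assert h.h2_total == h.h2_direct

    def test_total_at_least_direct_when_maternal_positive(self):
        h = heritabilities(_vc(3.0, 2.0, 5.0))
        assert h.h2_total > h.h2_direct

    def test_nonpositive_phenotypic_variance_errors(self):
        with pytest.raises(ValueError):
            heritabilities(_vc(0.0, 0.0, 0.0))

    def test_delta_se_matches_numeric_differentiation(self):
        """Delta-method SE of h2 agrees with a numeric-gradient oracle."""
        sa, sm, se = 3.0, 1.0, 6.0
        cov = np.array([
            [0.30, -0.05, -0.02],
            [-0.05, 0.20, -0.03],
            [-0.02, -0.03, 0.25],
        ])
        h = heritabilities(_vc(sa, sm, se, cov))

        def h2a(th):
            return th[0] / th.sum()

        eps = 1e-7
        th0 = np.array([sa, sm, se])
        g = np.array([
            (h2a(th0 + eps * np.eye(3)[i]) - h2a(th0 - eps * np.eye(3)[i]))
            / (2 * eps)
            for i in range(3)
        ])
        se_num = np.sqrt(g @ cov @ g)
        assert h.se_direct == pytest.approx(se_num, abs=1e-6)


class TestEbvCorrelation:
    def test_proportional_ebvs_give_unity(self):
        x = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("abcd"))
        assert genetic_correlation_ebv(x, 2 * x).r == pytest.approx(1.0)

    def test_negated_ebvs_give_minus_one(self):
        x = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("abcd"))
        assert genetic_correlation_ebv(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        x = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        z = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            res = genetic_correlation_ebv(x, z)
        assert not res.defined

    def test_common_animal_alignment(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = pd.Series([8.0, 6.0, 4.0], index=list("bcd"))
        res = genetic_correlation_ebv(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(-1.0)

    def test_bivariate_simulation_recovers_genetic_correlation(self):
        """True-component BLUP EBVs recover rG = 0.8 within +-0.1."""
        comp = pd.DataFrame(
            {"sigma2_a": [5.0, 5.0], "sigma2_m": [0.0, 0.0],
             "sigma2_e": [5.0, 5.0]},
            index=["T1", "T2"],
        )
        rG = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]],
                          index=["T1", "T2"], columns=["T1", "T2"])
        means = pd.Series([100.0, 50.0], index=["T1", "T2"])
        estimates = []
        for seed in range(20):
            cfg = simdata.SimConfig(
                n_sires=20, n_dams=250, n_calves=1000, n_farms=5,
                calves_per_dam=4, traits=("T1", "T2"),
                true_components=comp, true_rG=rG, means=means,
                fixed_effect_contrasts={}, farm_sd_frac=0.0,
                snp_loci={}, seed=seed,
            )
            ped = simdata.simulate_pedigree(cfg)
            pheno, _ = simdata.simulate_phenotypes(ped, cfg)
            data = pheno.reset_index()
            ebvs = {}
            for t in ("T1", "T2"):
                spec = AnimalModelSpec(t, ped, (), include_maternal=False)
                ebvs[t] = blup_ebv(
                    data[["animal", t]], spec, (5.0, 5.0)
                )["ebv_direct"]
            recorded = data["animal"]
            estimates.append(
                genetic_correlation_ebv(
                    ebvs["T1"].loc[recorded], ebvs["T2"].loc[recorded]
                ).r
            )
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.1)


class TestPhenotypicCorrelation:
    def test_identical_vectors(self):
        x = pd.Series(np.arange(5.0))
        assert phenotypic_correlation(x, x).r == pytest.approx(1.0)

    def test_orthogonal_residual_pair_is_zero(self):
        rng = np.random.default_rng(0)
        x = pd.Series(rng.normal(0, 1, 50))
        y = pd.Series(rng.normal(0, 1, 50))
        y_orth = y - np.polyval(np.polyfit(x, y, 1), x)
        assert abs(phenotypic_correlation(x, y_orth).r) < 1e-12

    def test_matches_hand_computed_sums(self):
        """Ten-pair table against the explicit sum formula."""
        x = pd.Series([2.0, 4, 5, 5, 6, 7, 8, 8, 9, 10])
        y = pd.Series([1.0, 3, 3, 5, 6, 6, 7, 9, 9, 12])
        n = 10
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        sxx = (x**2).sum() - x.sum() ** 2 / n
        syy = (y**2).sum() - y.sum() ** 2 / n
        r_hand = sxy / np.sqrt(sxx * syy)
        res = phenotypic_correlation(x, y)
        assert res.r == pytest.approx(r_hand, abs=1e-12)
        from scipy import stats as st

        t = r_hand * np.sqrt((n - 2) / (1 - r_hand**2))
        assert res.p == pytest.approx(2 * st.t.sf(abs(t), n - 2), abs=1e-12)

    def test_pairwise_complete_deletion(self):
        x = pd.Series([1.0, 2, np.nan, 4, 5])
        y = pd.Series([2.0, 4, 6, np.nan, 10])
        assert phenotypic_correlation(x, y).n == 3


class TestResponses:
    def test_published_direct_responses(self):
        assert direct_response(0.334, 779.945) == pytest.approx(
            9.3278, abs=5e-4
        )
        assert direct_response(0.483, 21.534) == pytest.approx(
            2.2413, abs=5e-4
        )

    def test_zero_heritability_zero_response(self):
        assert direct_response(0.0, 100.0) == 0.0

    def test_published_correlated_responses(self):
        assert correlated_response(0.88, 0.435, 0.334) == pytest.approx(
            1.0043, abs=5e-4
        )
        assert correlated_response(0.71, 0.334, 0.0001) == pytest.approx(
            41.0328, abs=5e-4
        )

    def test_zero_genetic_correlation_zero_response(self):
        assert correlated_response(0.0, 0.5, 0.5) == 0.0

    def test_zero_responding_heritability_errors(self):
        with pytest.raises(ValueError, match="unbounded"):
            correlated_response(0.7, 0.3, 0.0)

    def test_reciprocal_product_identity(self):
        """CR(j->i) * CR(i->j) = rG^2 exactly."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            rg = rng.uniform(-1, 1)
            h2j = rng.uniform(0.05, 0.95)
            h2i = rng.uniform(0.05, 0.95)
            prod = correlated_response(rg, h2j, h2i) * correlated_response(
                rg, h2i, h2j
            )
            assert prod == pytest.approx(rg**2, abs=1e-12)

    def test_matrix_orientation_row_is_selected_trait(self):
        h2s = {"A": 0.483, "B": 0.334}
        sp2 = {"A": 21.534, "B": 779.945}
        rg = pd.DataFrame([[1.0, 0.78], [0.78, 1.0]],
                          index=["A", "B"], columns=["A", "B"])
        M = response_matrix(h2s, sp2, rg)
        # selecting on A (row) for response in B: rG * h_A / h_B
        assert M.loc["A", "B"] == pytest.approx(
            0.78 * np.sqrt(0.483 / 0.334), abs=1e-9
        )
        assert M.loc["B", "A"] == pytest.approx(
            0.78 * np.sqrt(0.334 / 0.483), abs=1e-9
        )
        assert M.loc["A", "A"] == pytest.approx(0.483 * np.sqrt(21.534))

    def test_single_trait_matrix_is_direct_response(self):
        M = response_matrix({"X": 0.4}, {"X": 25.0},
                            pd.DataFrame([[1.0]], index=["X"], columns=["X"]))
        assert M.shape == (1, 1)
        assert M.loc["X", "X"] == pytest.approx(0.4 * 5.0)

    def test_identity_rg_gives_zero_off_diagonals(self):
        h2s = {"A": 0.4, "B": 0.4}
        sp2 = {"A": 1.0, "B": 1.0}
        rg = pd.DataFrame(np.eye(2), index=["A", "B"], columns=["A", "B"])
        M = response_matrix(h2s, sp2, rg)
        assert M.loc["A", "B"] == 0.0 and M.loc["B", "A"] == 0.0


class TestCorrelationMatrices:
    def test_combined_layout_genetic_upper_phenotypic_lower(self):
        """3-trait fixture: genetic above, phenotypic below the diagonal."""
        rng = np.random.default_rng(6)
        idx = [f"a{i}" for i in range(30)]
        base = rng.normal(0, 1, 30)
        ebvs = {
            "X": pd.Series(base, index=idx),
            "Y": pd.Series(base + rng.normal(0, 0.5, 30), index=idx),
            "Z": pd.Series(rng.normal(0, 1, 30), index=idx),
        }
        adj = pd.DataFrame(
            rng.normal(0, 1, (30, 3)), index=idx, columns=["X", "Y", "Z"]
        )
        cm = correlation_matrices(ebvs, adj)
        combined = cm.combined()
        for i, t in enumerate(cm.traits):
            for j, u in enumerate(cm.traits):
                if i < j:
                    assert combined.loc[t, u] == cm.genetic.loc[t, u]
                elif i > j:
                    assert combined.loc[t, u] == cm.phenotypic.loc[t, u]
        assert np.allclose(cm.genetic, cm.genetic.T)
        assert ((cm.genetic.to_numpy() >= -1) & (cm.genetic.to_numpy() <= 1)).all()


class TestEndToEndRecovery:
    def test_reml_and_ebv_recover_genetic_correlation(self):
        """Full chain at reduced scale: simulate two correlated traits,
        estimate components by EM-REML, predict EBVs at the estimates,
        and recover rG = 0.8 within +-0.1 (mean over 8 seeds, n=600)."""
        comp = pd.DataFrame(
            {"sigma2_a": [6.0, 6.0], "sigma2_m": [0.0, 0.0],
             "sigma2_e": [6.0, 6.0]},
            index=["T1", "T2"],
        )
        rG = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]],
                          index=["T1", "T2"], columns=["T1", "T2"])
        means = pd.Series([100.0, 50.0], index=["T1", "T2"])
        estimates = []
        for seed in range(8):
            cfg = simdata.SimConfig(
                n_sires=15, n_dams=150, n_calves=600, n_farms=5,
                calves_per_dam=4, traits=("T1", "T2"),
                true_components=comp, true_rG=rG, means=means,
                fixed_effect_contrasts={}, farm_sd_frac=0.0,
                snp_loci={}, seed=100 + seed,
            )
            ped = simdata.simulate_pedigree(cfg)
            pheno, _ = simdata.simulate_phenotypes(ped, cfg)
            data = pheno.reset_index()
            ebvs = {}
            for t in ("T1", "T2"):
                spec = AnimalModelSpec(t, ped, (), include_maternal=False)
                vc = em_reml(data[["animal", t]], spec, tol=1e-4,
                             max_iter=200, accelerate=True)
                ebvs[t] = blup_ebv(data[["animal", t]], spec, vc)[
                    "ebv_direct"
                ]
            recorded = data["animal"]
            estimates.append(
                genetic_correlation_ebv(
                    ebvs["T1"].loc[recorded], ebvs["T2"].loc[recorded]
                ).r
            )
        assert np.mean(estimates) == pytest.approx(0.8, abs=0.1)
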