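"""Animal-model REML and BLUP against direct-inversion oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from bubalus import pedigree as ped_mod
from bubalus import reml
from bubalus.pedigree import relationship_matrix
from bubalus.reml import (
    AnimalModelSpec,
    NonIdentifiableWarning,
    blup_ebv,
    build_mme,
    em_reml,
    restricted_loglik,
    se_from_information,
    solve_mme,
)

from ._oracles import gls_blup, reml_loglik_v


def _vmats(ped, data, maternal):
    """Full-A quantities for the V-inversion oracles."""
    A = relationship_matrix(ped)
    pos = {a: i for i, a in enumerate(A.ids)}
    rec_pos = [pos[a] for a in data["animal"]]
    dam_pos = None
    if maternal:
        dams = {a: d for a, s, d in ped.entries}
        dam_pos = [pos[dams[a]] for a in data["animal"]]
    return A.values, rec_pos, dam_pos


class TestMMEAgainstGLS:
    def test_solution_equals_direct_v_inversion(self, six_record_model):
        """MME fixed effects and BLUPs equal the GLS formulas."""
        ped, data, spec = six_record_model
        theta = (4.0, 2.0, 6.0)
        A, rec_pos, dam_pos = _vmats(ped, data, maternal=True)
        X = np.column_stack(
            [np.ones(6), np.where(data.sex == "f", 1.0, -1.0)]
        )
        beta, a_hat, m_hat = gls_blup(
            A, rec_pos, X, data.y.to_numpy(), theta[0], theta[2],
            dam_pos, theta[1],
        )
        mme = build_mme(data, spec, theta)
        sol = solve_mme(mme)
        assert sol[mme.slices["a"]] == pytest.approx(a_hat, abs=1e-8)
        assert sol[mme.slices["m"]] == pytest.approx(m_hat, abs=1e-8)
        fitted_or = X @ beta
        Xp = np.column_stack(
            [np.ones(6), np.where(data.sex == "f", 1.0, -1.0)]
        )
        assert Xp @ sol[mme.slices["beta"]] == pytest.approx(
            fitted_or, abs=1e-8
        )

    def test_no_maternal_model_matches_oracle(self, six_record_model):
        ped, data, _ = six_record_model
        spec = AnimalModelSpec("y", ped, ("sex",), include_maternal=False)
        A, rec_pos, _ = _vmats(ped, data, maternal=False)
        X = np.column_stack(
            [np.ones(6), np.where(data.sex == "f", 1.0, -1.0)]
        )
        _, a_hat, _ = gls_blup(A, rec_pos, X, data.y.to_numpy(), 3.0, 5.0)
        mme = build_mme(data, spec, (3.0, 5.0))
        sol = solve_mme(mme)
        assert sol[mme.slices["a"]] == pytest.approx(a_hat, abs=1e-8)

    def test_loglik_identity_mme_vs_direct_v(self, six_record_model):
        """The determinant identity: marginal form equals direct V form."""
        ped, data, spec = six_record_model
        theta = (4.0, 2.0, 6.0)
        A, rec_pos, dam_pos = _vmats(ped, data, maternal=True)
        X = np.column_stack(
            [np.ones(6), np.where(data.sex == "f", 1.0, -1.0)]
        )
        ll_v = reml_loglik_v(A, rec_pos, X, data.y.to_numpy(), theta, dam_pos)
        assert restricted_loglik(data, spec, theta) == pytest.approx(
            ll_v, abs=1e-9
        )

    def test_both_genetic_variances_zero_error(self, six_record_model):
        ped, data, spec = six_record_model
        with pytest.raises(ValueError, match="nothing to predict"):
            build_mme(data, spec, (0.0, 0.0, 5.0))


class TestBlupProperties:
    def test_record_at_fitted_mean_gives_zero_ebv(self):
        ped = ped_mod.pedigree_from_records(
            [("A", None, None), ("B", None, None)]
        )
        data = pd.DataFrame({"animal": ["A", "B"], "y": [10.0, 10.0]})
        spec = AnimalModelSpec("y", ped, (), include_maternal=False)
        ebv = blup_ebv(data, spec, (2.0, 3.0))
        assert ebv["ebv_direct"].to_numpy() == pytest.approx([0.0, 0.0])

    def test_unrecorded_offspring_gets_parent_average(self):
        ped = ped_mod.pedigree_from_records([
            ("S", None, None), ("D", None, None), ("C", "S", "D"),
        ])
        rng = np.random.default_rng(1)
        data = pd.DataFrame({
            "animal": ["S", "D"], "y": rng.normal(50, 3, 2),
        })
        spec = AnimalModelSpec("y", ped, (), include_maternal=False)
        ebv = blup_ebv(data, spec, (4.0, 2.0))["ebv_direct"]
        assert ebv["C"] == pytest.approx((ebv["S"] + ebv["D"]) / 2, abs=1e-10)

    def test_pev_bounded_by_additive_variance(self, six_record_model):
        ped, data, spec = six_record_model
        sa2 = 4.0
        ebv = blup_ebv(data, spec, (sa2, 2.0, 6.0))
        A = relationship_matrix(ped)
        for animal in A.ids:
            assert 0 <= ebv.loc[animal, "pev_direct"] <= sa2 * A.loc(
                animal, animal
            ) + 1e-9

    def test_single_record_accuracy_matches_theory(self):
        """corr(true BV, EBV) ~ sqrt(h2) for unrelated recorded animals."""
        h2, n = 0.5, 1000
        sa2, se2 = h2 * 10, (1 - h2) * 10
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            ids = [f"a{i}" for i in range(n)]
            ped = ped_mod.pedigree_from_records(
                [(a, None, None) for a in ids]
            )
            a_true = rng.normal(0, np.sqrt(sa2), n)
            y = 50 + a_true + rng.normal(0, np.sqrt(se2), n)
            data = pd.DataFrame({"animal": ids, "y": y})
            spec = AnimalModelSpec("y", ped, (), include_maternal=False)
            ebv = blup_ebv(data, spec, (sa2, se2))["ebv_direct"]
            accs.append(np.corrcoef(a_true, ebv.loc[ids])[0, 1])
        assert np.mean(accs) == pytest.approx(np.sqrt(h2), abs=0.05)


def _numeric_reml(ped, data, X_cols, maternal, start):
    """Brute-force restricted-likelihood search via direct V inversion."""
    A, rec_pos, dam_pos = _vmats(ped, data, maternal)
    dam_pos = dam_pos if maternal else None
    X = X_cols
    y = data.iloc[:, data.columns.get_loc("y")].to_numpy()

    def nll(logth):
        return -reml_loglik_v(A, rec_pos, X, y, np.exp(logth), dam_pos)

    res = minimize(
        nll, np.log(start), method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=4000),
    )
    return np.exp(res.x), -res.fun


def _signal_data(ped, animals, rng, sd_a, sd_m, sd_e, mu):
    """Phenotypes drawn from the animal model itself (interior optimum)."""
    A = relationship_matrix(ped)
    pos = {a: i for i, a in enumerate(A.ids)}
    L = np.linalg.cholesky(A.values + 1e-10 * np.eye(len(A.ids)))
    a = L @ rng.normal(0, sd_a, len(A.ids))
    y = mu + a[[pos[x] for x in animals]]
    if sd_m > 0:
        m = L @ rng.normal(0, sd_m, len(A.ids))
        dams = {x: d for x, s, d in ped.entries}
        y = y + m[[pos[dams[x]] for x in animals]]
    return pd.DataFrame(
        {"animal": animals, "y": y + rng.normal(0, sd_e, len(animals))}
    )


class TestEmRemlOracle:
    def test_eight_record_no_maternal_matches_grid_search(self):
        """EM optimum equals the numeric V-inversion REML optimum."""
        ped = ped_mod.pedigree_from_records([
            ("S1", None, None), ("S2", None, None),
            ("D1", None, None), ("D2", None, None),
            ("C1", "S1", "D1"), ("C2", "S1", "D1"), ("C3", "S1", "D2"),
            ("C4", "S2", "D2"), ("C5", "S2", "D1"), ("C6", "S2", "D2"),
            ("C7", "S1", "D1"), ("C8", "S2", "D2"),
        ])
        animals = [f"C{i}" for i in range(1, 9)]
        data = _signal_data(
            ped, animals, np.random.default_rng(9), 2.0, 0.0, 1.4, 30.0
        )
        spec = AnimalModelSpec("y", ped, (), include_maternal=False)
        vc = em_reml(data, spec, tol=1e-12, max_iter=20000,
                     loglik_tol=1e-14, accelerate=True)
        oracle, ll_or = _numeric_reml(
            ped, data, np.ones((8, 1)), False,
            [vc.sigma2_a + 0.1, vc.sigma2_e + 0.1],
        )
        assert vc.sigma2_a == pytest.approx(oracle[0], rel=1e-4)
        assert vc.sigma2_e == pytest.approx(oracle[1], rel=1e-4)
        assert vc.loglik == pytest.approx(ll_or, abs=1e-6)

    def test_twelve_record_maternal_matches_grid_search(self):
        ped_entries = [("S1", None, None), ("S2", None, None)]
        ped_entries += [(f"D{i}", None, None) for i in range(1, 5)]
        k = 0
        animals = []
        for d in range(1, 5):
            for _ in range(3):
                k += 1
                a = f"C{k}"
                ped_entries.append((a, f"S{1 + (k % 2)}", f"D{d}"))
                animals.append(a)
        ped = ped_mod.pedigree_from_records(ped_entries)
        data = _signal_data(
            ped, animals, np.random.default_rng(9), 2.0, 1.5, 1.0, 100.0
        )
        spec = AnimalModelSpec("y", ped, (), include_maternal=True)
        vc = em_reml(data, spec, tol=1e-12, max_iter=40000,
                     loglik_tol=1e-14, accelerate=True)
        oracle, ll_or = _numeric_reml(
            ped, data, np.ones((12, 1)), True,
            [vc.sigma2_a + 0.1, vc.sigma2_m + 0.1, vc.sigma2_e + 0.1],
        )
        assert vc.loglik == pytest.approx(ll_or, abs=1e-5)
        for est, orc in zip(
            (vc.sigma2_a, vc.sigma2_m, vc.sigma2_e), oracle
        ):
            assert est == pytest.approx(orc, rel=1e-4, abs=1e-8)


class TestEmBehaviour:
    def test_loglik_monotone_on_fixture(self, six_record_model):
        ped, data, spec = six_record_model
        vc = em_reml(data, spec, tol=1e-10, max_iter=3000)
        h = np.asarray(vc.loglik_history)
        assert np.all(np.diff(h) >= -1e-7 * (1 + np.abs(h[:-1])))

    def test_loglik_monotone_on_random_simulations(self):
        """EM never decreases the restricted likelihood (20 random herds)."""
        from .conftest import small_herd

        for seed in range(20):
            herd = small_herd(seed=seed, n_calves=40, n_dams=20,
                              calves_per_dam=2, n_sires=4)
            spec = AnimalModelSpec(
                "WH", herd.pedigree, ("sex",), include_maternal=True
            )
            vc = em_reml(herd.phenotypes.reset_index(), spec,
                         tol=1e-6, max_iter=200, accelerate=True)
            h = np.asarray(vc.loglik_history)
            assert np.all(np.diff(h) >= -1e-7 * (1 + np.abs(h[:-1]))), seed

    def test_unlinked_records_warn_non_identifiable(self):
        ids = [f"u{i}" for i in range(10)]
        ped = ped_mod.pedigree_from_records([(a, None, None) for a in ids])
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"animal": ids, "y": rng.normal(0, 1, 10)})
        spec = AnimalModelSpec("y", ped, (), include_maternal=False)
        with pytest.warns(NonIdentifiableWarning):
            em_reml(data, spec, tol=1e-6, max_iter=50)

    def test_scale_equivariance(self, six_record_model):
        """Scaling y by c scales components by c^2 and leaves h2 fixed."""
        ped, data, spec = six_record_model
        vc1 = em_reml(data, spec, tol=1e-9, max_iter=4000)
        c = 3.7
        data2 = data.assign(y=data.y * c)
        vc2 = em_reml(data2, spec, tol=1e-9, max_iter=4000)
        assert vc2.sigma2_a == pytest.approx(vc1.sigma2_a * c**2, rel=1e-3,
                                             abs=1e-8)
        assert vc2.sigma2_e == pytest.approx(vc1.sigma2_e * c**2, rel=1e-3,
                                             abs=1e-8)
        h1 = vc1.sigma2_a / vc1.sigma2_p
        h2 = vc2.sigma2_a / vc2.sigma2_p
        assert h1 == pytest.approx(h2, abs=1e-4)

    def test_record_order_invariance(self, six_record_model):
        ped, data, spec = six_record_model
        vc1 = em_reml(data, spec, tol=1e-9, max_iter=4000)
        shuffled = data.sample(frac=1.0, random_state=4)
        vc2 = em_reml(shuffled, spec, tol=1e-9, max_iter=4000)
        assert vc1.sigma2_a == pytest.approx(vc2.sigma2_a, rel=1e-6, abs=1e-10)
        assert vc1.loglik == pytest.approx(vc2.loglik, abs=1e-8)

    def test_component_sum_is_sigma2_p(self, six_record_model):
        ped, data, spec = six_record_model
        vc = em_reml(data, spec, tol=1e-8, max_iter=2000)
        assert vc.sigma2_p == vc.sigma2_a + vc.sigma2_m + vc.sigma2_e

    def test_maternal_off_matches_reduced_model_likelihood(
        self, six_record_model
    ):
        """sigma2_m -> 0 in the maternal model recovers the reduced model."""
        ped, data, spec = six_record_model
        red = AnimalModelSpec("y", ped, ("sex",), include_maternal=False)
        ll_red = restricted_loglik(data, red, (3.0, 5.0))
        ll_full = restricted_loglik(data, spec, (3.0, 1e-12, 5.0))
        assert ll_full == pytest.approx(ll_red, abs=1e-6)

    def test_unknown_dam_gets_dummy_founder(self):
        ped = ped_mod.pedigree_from_records([
            ("S", None, None), ("C1", "S", None), ("C2", "S", None),
        ])
        data = pd.DataFrame({
            "animal": ["C1", "C2"], "y": [1.0, 2.0],
        })
        spec = AnimalModelSpec("y", ped, (), include_maternal=True)
        with pytest.warns(UserWarning, match="dummy founder"):
            mme = build_mme(data, spec, (1.0, 1.0, 1.0))
        assert any(i.startswith("__dummy_dam_") for i in mme.ids)


class TestStandardErrors:
    def test_diagonal_information_inverse_sqrt(self):
        assert se_from_information(np.diag([100.0, 400.0])) == pytest.approx(
            [0.1, 0.05]
        )

    def test_boundary_component_reports_zero_se(self):
        """A variance pinned at zero is flagged and gets SE 0."""
        ids = [f"a{i}" for i in range(30)]
        ped = ped_mod.pedigree_from_records(
            [("S", None, None)] + [(a, "S", None) for a in ids]
        )
        rng = np.random.default_rng(8)
        # pure-noise trait: additive variance collapses toward zero
        data = pd.DataFrame({"animal": ids, "y": rng.normal(0, 1, 30)})
        spec = AnimalModelSpec("y", ped, (), include_maternal=False)
        vc = em_reml(data, spec, tol=1e-8, max_iter=5000)
        if vc.boundary["sigma2_a"]:
            assert vc.se_a == 0.0
        else:  # noise can leave a small positive estimate; SEs stay finite
            assert np.isfinite(vc.se_a)
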