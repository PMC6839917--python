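"""Chi-square fitting, NNLS weights, minimal ensemble search, Keq."""
import numpy as np
import pytest

from saxstate.ensemble import (
    chi_square,
    classify_members,
    equilibrium_constant,
    fit_weights,
    minimal_ensemble_search,
    relative_activity,
)
from saxstate.errors import DataError, FitError, GridError
from saxstate.profiles import SaxsProfile
from saxstate.scattering import debye_profile, default_q_grid

from conftest import toy_model


def _curves(seed=0, n_q=101):
    """Two distinct smooth toy curves on the default grid."""
    q = np.linspace(0.01, 0.4, n_q)
    a = 100.0 * np.exp(-(q**2) * 30.0**2 / 3.0)
    b = 100.0 * np.exp(-(q**2) * 45.0**2 / 3.0) * (1.0 + 0.3 * np.sin(8 * q))
    return q, a, b


class TestChiSquare:
    def test_identical_curves(self):
        q, a, _ = _curves()
        exp = SaxsProfile(q=q, intensity=a, sigma=np.ones_like(a))
        theo = SaxsProfile(q=q, intensity=a)
        chi2, c = chi_square(exp, theo)
        assert chi2 == pytest.approx(0.0, abs=1e-18)
        assert c == pytest.approx(1.0)

    def test_scale_invariance(self):
        q, a, _ = _curves()
        exp = SaxsProfile(q=q, intensity=5.0 * a, sigma=np.ones_like(a))
        theo = SaxsProfile(q=q, intensity=a)
        chi2, c = chi_square(exp, theo)
        assert chi2 == pytest.approx(0.0, abs=1e-15)
        assert c == pytest.approx(5.0)

    def test_reduced_chi2_near_unity_for_matching_noise(self):
        """Reduced chi^2 of pure noise residuals follows its chi^2 law.

        With N = 100 points the reduced statistic has mean 1 and sd
        sqrt(2/99) ~ 0.14, so the central band [0.7, 1.4] (about -2.1 to
        +2.8 sd) holds for ~98% of replicates; the mean over 100 seeded
        replicates pins the distribution's location.
        """
        q, a, _ = _curves(n_q=100)
        sigma = 0.02 * a
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            exp = SaxsProfile(q=q, intensity=a + rng.normal(0, sigma), sigma=sigma)
            chi2, _ = chi_square(exp, SaxsProfile(q=q, intensity=a))
            vals.append(chi2)
        in_band = sum(0.7 <= v <= 1.4 for v in vals)
        assert in_band >= 92
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_nonoverlapping_grids_rejected(self):
        q, a, _ = _curves()
        exp = SaxsProfile(q=q, intensity=a, sigma=np.ones_like(a))
        theo = SaxsProfile(q=q + 1.0, intensity=a)
        with pytest.raises(GridError):
            chi_square(exp, theo)

    def test_nonpositive_sigma_rejected(self):
        q, a, _ = _curves()
        sigma = np.ones_like(a)
        sigma[3] = 0.0
        exp = SaxsProfile(q=q, intensity=a, sigma=sigma)
        with pytest.raises(DataError):
            chi_square(exp, SaxsProfile(q=q, intensity=a))


class TestFitWeights:
    def test_single_member_identity(self):
        q, a, _ = _curves()
        exp = SaxsProfile(q=q, intensity=a, sigma=0.01 * a)
        fit = fit_weights(exp, [SaxsProfile(q=q, intensity=a, label="m0")])
        assert fit.weights[0] == pytest.approx(1.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("w_true", [(0.6, 0.4), (0.72, 0.28), (0.9, 0.1)])
    def test_noiseless_mixture_recovered_vs_grid_oracle(self, w_true):
        from oracles import simplex_grid_weights

        q, a, b = _curves()
        mix = w_true[0] * a + w_true[1] * b
        sigma = 0.01 * mix
        exp = SaxsProfile(q=q, intensity=mix, sigma=sigma)
        members = [
            SaxsProfile(q=q, intensity=a, label="a"),
            SaxsProfile(q=q, intensity=b, label="b"),
        ]
        fit = fit_weights(exp, members)
        got = dict(zip(fit.member_ids, fit.weights))
        assert got["a"] == pytest.approx(w_true[0], abs=1e-6)
        assert got["b"] == pytest.approx(w_true[1], abs=1e-6)
        oracle_w, _ = simplex_grid_weights(
            mix, sigma, np.column_stack([a, b]), step=0.001
        )
        assert got["a"] == pytest.approx(oracle_w[0], abs=1e-3)

    def test_three_member_fit_matches_grid_oracle(self):
        from oracles import simplex_grid_weights

        q, a, b = _curves()
        c = 80.0 * np.exp(-(q**2) * 20.0**2 / 3.0)
        mix = 0.5 * a + 0.3 * b + 0.2 * c
        sigma = 0.01 * mix
        exp = SaxsProfile(q=q, intensity=mix, sigma=sigma)
        members = [
            SaxsProfile(q=q, intensity=x, label=lab)
            for x, lab in ((a, "a"), (b, "b"), (c, "c"))
        ]
        fit = fit_weights(exp, members)
        oracle_w, _ = simplex_grid_weights(
            mix, sigma, np.column_stack([a, b, c]), step=0.001
        )
        got = dict(zip(fit.member_ids, fit.weights))
        for lab, k in (("a", 0), ("b", 1), ("c", 2)):
            assert got[lab] == pytest.approx(oracle_w[k], abs=1.5e-3)

    def test_four_member_fit_matches_coarser_grid_oracle(self):
        from oracles import simplex_grid_weights

        q, a, b = _curves()
        c = 80.0 * np.exp(-(q**2) * 20.0**2 / 3.0)
        d = 60.0 * np.exp(-(q**2) * 55.0**2 / 3.0) * (1.0 + 0.2 * np.cos(10 * q))
        mix = 0.4 * a + 0.3 * b + 0.2 * c + 0.1 * d
        sigma = 0.01 * mix
        exp = SaxsProfile(q=q, intensity=mix, sigma=sigma)
        members = [
            SaxsProfile(q=q, intensity=x, label=lab)
            for x, lab in ((a, "a"), (b, "b"), (c, "c"), (d, "d"))
        ]
        fit = fit_weights(exp, members)
        oracle_w, _ = simplex_grid_weights(
            mix, sigma, np.column_stack([a, b, c, d]), step=0.005
        )
        got = dict(zip(fit.member_ids, fit.weights))
        for lab, k in (("a", 0), ("b", 1), ("c", 2), ("d", 3)):
            assert got[lab] == pytest.approx(oracle_w[k], abs=0.005)

    def test_duplicate_members_weight_sum_well_defined(self):
        q, a, b = _curves()
        mix = 0.7 * a + 0.3 * b
        exp = SaxsProfile(q=q, intensity=mix, sigma=0.01 * mix)
        fit_dup = fit_weights(
            exp,
            [
                SaxsProfile(q=q, intensity=a, label="a1"),
                SaxsProfile(q=q, intensity=a, label="a2"),
                SaxsProfile(q=q, intensity=b, label="b"),
            ],
        )
        dup_sum = fit_dup.weight_of("a1") + fit_dup.weight_of("a2")
        assert dup_sum == pytest.approx(0.7, abs=1e-6)

    def test_weights_sum_to_one_exactly(self):
        q, a, b = _curves()
        mix = 0.55 * a + 0.45 * b
        exp = SaxsProfile(q=q, intensity=mix, sigma=0.01 * mix)
        fit = fit_weights(
            exp,
            [SaxsProfile(q=q, intensity=a), SaxsProfile(q=q, intensity=b)],
        )
        assert abs(float(np.sum(fit.weights)) - 1.0) <= 1e-9


class TestMinimalEnsembleSearch:
    def _pool_profiles(self, n_decoys=6):
        rng = np.random.default_rng(11)
        q = default_q_grid()
        profs = []
        for k in range(n_decoys + 2):
            m = toy_model(
                rng.normal(scale=rng.uniform(8, 16), size=(40, 3)),
                model_id=f"m{k}",
            )
            profs.append(debye_profile(m, q, label=f"m{k}"))
        return q, profs

    def test_single_source_selects_one_state(self):
        q, profs = self._pool_profiles()
        truth = profs[0].intensity
        exp = SaxsProfile(q=q, intensity=truth, sigma=0.01 * truth)
        res = minimal_ensemble_search(exp, profs, max_states=3)
        assert res.selected_n == 1
        assert res.selected.member_ids[0] == "m0"
        assert res.selected.weights[0] == pytest.approx(1.0)

    def test_two_state_mixture_recovered(self):
        q, profs = self._pool_profiles()
        mix = 0.72 * profs[0].intensity + 0.28 * profs[1].intensity
        exp = SaxsProfile(q=q, intensity=mix, sigma=0.005 * mix)
        res = minimal_ensemble_search(exp, profs, max_states=3)
        assert res.selected_n == 2
        got = dict(zip(res.selected.member_ids, res.selected.weights))
        assert got["m0"] == pytest.approx(0.72, abs=1e-3)
        assert got["m1"] == pytest.approx(0.28, abs=1e-3)

    def test_chi2_non_increasing_in_n(self):
        q, profs = self._pool_profiles()
        rng = np.random.default_rng(3)
        mix = 0.5 * profs[2].intensity + 0.5 * profs[3].intensity
        sigma = 0.02 * mix
        exp = SaxsProfile(q=q, intensity=mix + rng.normal(0, sigma), sigma=sigma)
        res = minimal_ensemble_search(exp, profs, max_states=4)
        chis = [res.per_n[n].chi2 for n in sorted(res.per_n)]
        assert all(c2 <= c1 + 1e-12 for c1, c2 in zip(chis, chis[1:]))

    def test_stochastic_branch_requires_seed_and_finds_mixture(self):
        from saxstate.errors import ConfigError
        import saxstate.ensemble as ens

        q, profs = self._pool_profiles(n_decoys=18)
        mix = 0.6 * profs[0].intensity + 0.4 * profs[5].intensity
        exp = SaxsProfile(q=q, intensity=mix, sigma=0.01 * mix)
        old = ens.ENUMERATION_LIMIT
        ens.ENUMERATION_LIMIT = 50  # force the stochastic path
        try:
            with pytest.raises(ConfigError):
                minimal_ensemble_search(exp, profs, max_states=2)
            res = minimal_ensemble_search(
                exp, profs, max_states=2, seed=1, n_restarts=300
            )
        finally:
            ens.ENUMERATION_LIMIT = old
        got = dict(zip(res.selected.member_ids, res.selected.weights))
        assert got.get("m0", 0.0) == pytest.approx(0.6, abs=0.01)
        assert got.get("m5", 0.0) == pytest.approx(0.4, abs=0.01)


class TestKeqAndActivity:
    def _fit(self, w_compact, w_extended):
        from saxstate.ensemble import EnsembleFit

        return EnsembleFit(
            member_ids=("compact", "extended"),
            weights=np.array([w_compact, w_extended]),
            scale=1.0,
            chi2=0.0,
        )

    def test_two_state_split_gives_printed_keq(self):
        fit = self._fit(0.72, 0.28)
        keq = equilibrium_constant(fit, extended_ids={"extended"})
        assert keq == pytest.approx(0.389, abs=0.001)
        assert round(keq, 2) == 0.39

    def test_equal_weights_unity(self):
        fit = self._fit(0.5, 0.5)
        assert equilibrium_constant(fit, {"extended"}) == pytest.approx(1.0)

    def test_all_extended_flags_infinity(self):
        fit = self._fit(0.0, 1.0)
        assert equilibrium_constant(fit, {"extended"}) == float("inf")

    def test_partial_activity_fraction(self):
        assert relative_activity(309.0, 1988.0) == pytest.approx(15.54, abs=0.01)
        # the partially activated enzyme runs at ~15% of the maximal rate
        assert int(relative_activity(309.0, 1988.0)) == 15

    def test_maximal_and_zero_rates(self):
        assert relative_activity(1988.0, 1988.0) == pytest.approx(100.0)
        assert relative_activity(0.0, 1988.0) == 0.0

    def test_nonpositive_maximum_rejected(self):
        with pytest.raises(DataError):
            relative_activity(10.0, 0.0)


class TestClassifyMembers:
    def test_members_assigned_to_nearest_reference(self, small_bent, small_extended):
        from saxstate.sampling import sample_conformers, sgc_default_protocol

        proto = sgc_default_protocol(small_bent, n_samples_per_stage=4,
                                     max_angle=10.0, seed=1)
        pool = sample_conformers(small_bent, proto)
        members = {c.member_id: c.model for c in pool}
        members["bent"] = small_bent
        refs = {"compact": small_bent, "extended": small_extended}
        got = classify_members(members, refs)
        # mildly perturbed copies of the bent model stay classified compact
        assert got["bent"] == "compact"
        assert all(v == "compact" for v in got.values())
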