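"""Closed-form Gaussian propagation against numeric and Monte-Carlo oracles."""

import numpy as np
import pytest

from ri2md.materials import WATER, default_table
from ri2md.mixture import ComponentSpec, binary_effective_alpha, binary_effective_theta
from ri2md.uncertainty import (
    InhomogeneityParams,
    binary_partials,
    combine_uncertainties,
    delta_eff_single,
    delta_eff_total,
    delta_phi1,
    mean_effective,
    mixture_spread,
    propagate,
)


@pytest.fixture(scope="module")
def protein():
    return ComponentSpec.from_material(default_table()["trunk_protein"], WATER)


@pytest.fixture(scope="module")
def lipid():
    return ComponentSpec.from_material(default_table()["triolein"], WATER)


class TestElementary:
    def test_combine(self):
        assert combine_uncertainties(3.0, 4.0) == pytest.approx(5.0)
        assert combine_uncertainties(0.0, 2.0) == 2.0
        assert combine_uncertainties(4.0, 3.0) == combine_uncertainties(3.0, 4.0)
        with pytest.raises(ValueError):
            combine_uncertainties(-1.0, 1.0)

    def test_mixture_spread_single_component(self):
        assert mixture_spread([(0.7, 0.01)], [1.0]) == (pytest.approx(0.7), pytest.approx(0.01))

    def test_mixture_spread_two_deltas(self):
        # equal-weight mixture of two point masses: sd = half the separation
        mean, sd = mixture_spread([(0.7, 0.0), (1.1, 0.0)], [0.5, 0.5])
        assert mean == pytest.approx(0.9)
        assert sd == pytest.approx(0.2)

    def test_spread_maximised_at_half(self):
        grid = np.linspace(0.05, 0.95, 19)
        sds = [mixture_spread([(0.7, 0.0), (1.1, 0.0)], [1 - x, x])[1] for x in grid]
        assert grid[int(np.argmax(sds))] == pytest.approx(0.5)

    def test_delta_eff_single(self):
        assert delta_eff_single(0.5, 1) == 0.5
        assert delta_eff_single(0.009, 81) == pytest.approx(0.001)

    def test_delta_eff_single_matches_mc(self):
        # MC oracle: sd of the mass-averaged PSV over Ns iid draws
        rng = np.random.default_rng(3)
        mu, sd, Ns, reps = 0.734, 0.009, 49, 10_000
        draws = rng.normal(mu, sd, (reps, Ns))
        theta_eff = Ns / (1.0 / draws).sum(axis=1)
        assert np.std(theta_eff) == pytest.approx(delta_eff_single(sd, Ns), rel=0.05)


class TestPartials:
    def test_equal_psv_gives_zero(self, protein):
        twin = ComponentSpec("twin", alpha=0.10, theta=protein.theta)
        dth, _ = binary_partials(0.4, protein, twin)
        assert dth == pytest.approx(0.0, abs=1e-15)

    def test_sign_of_theta_partial(self, protein, lipid):
        for x in (0.1, 0.5, 0.9):
            dth, _ = binary_partials(x, protein, lipid)
            assert dth > 0  # lipid PSV exceeds the protein PSV

    @pytest.mark.parametrize("x", [0.1, 0.3, 0.7])
    def test_against_finite_differences(self, protein, lipid, x):
        h = 1e-6
        dth, dal = binary_partials(x, protein, lipid)
        fd_th = (
            binary_effective_theta(x + h, protein.theta, lipid.theta)
            - binary_effective_theta(x - h, protein.theta, lipid.theta)
        ) / (2 * h)
        a, b = (protein.alpha, protein.theta), (lipid.alpha, lipid.theta)
        fd_al = (binary_effective_alpha(x + h, a, b) - binary_effective_alpha(x - h, a, b)) / (2 * h)
        assert dth == pytest.approx(fd_th, rel=1e-6)
        assert dal == pytest.approx(fd_al, rel=1e-6)


class TestDeltaEffTotal:
    def test_reduces_to_single_spread_without_composition_noise(self, protein, lipid):
        params = InhomogeneityParams(phi1_mean=0.9, x_lip_mean=0.5, d_x_lip=0.0, N0=10_000)
        s_th, s_al = delta_eff_total(params, protein, lipid)
        ns = params.n_solute
        th0 = mixture_spread(
            [(protein.theta, protein.d_theta), (lipid.theta, lipid.d_theta)], [0.5, 0.5]
        )[1]
        assert s_th == pytest.approx(delta_eff_single(th0, ns), rel=1e-12)

    def test_plateau_at_large_n0(self, protein, lipid):
        dth, _ = binary_partials(0.5, protein, lipid)
        big = InhomogeneityParams(phi1_mean=0.9, x_lip_mean=0.5, d_x_lip=0.1, N0=10**9)
        s_th, _ = delta_eff_total(big, protein, lipid)
        assert s_th == pytest.approx(abs(dth) * 0.1, rel=1e-3)


class TestDeltaPhi1:
    def test_binomial_identity(self, protein):
        # with a delta-distributed PSV the binomial proportion sd is exact
        exact = ComponentSpec("p", alpha=0.197, theta=0.734)
        params = InhomogeneityParams(phi1_mean=0.9, N0=10_000, ns_model="binomial")
        val = delta_phi1(params, exact, exact)
        assert val == pytest.approx(np.sqrt(0.9 * 0.1 / 10_000), rel=1e-9)

    def test_homogeneous_limit_vanishes(self, protein, lipid):
        params = InhomogeneityParams(
            phi1_mean=0.9, x_lip_mean=0.5, N0=10**12, ns_model="mass_fluctuation"
        )
        assert delta_phi1(params, protein, lipid) == pytest.approx(0.0, abs=1e-5)

    def test_mass_fluctuation_plateau(self, protein):
        exact = ComponentSpec("p", alpha=0.197, theta=0.734)
        params = InhomogeneityParams(
            phi1_mean=0.9, d_ms_rel=0.05, N0=10**12, ns_model="mass_fluctuation"
        )
        assert delta_phi1(params, exact, exact) == pytest.approx(0.1 * 0.05, rel=1e-3)

    def test_fixed_model_has_no_count_noise(self, protein, lipid):
        params = InhomogeneityParams(phi1_mean=0.9, x_lip_mean=0.5, N0=1000, ns_model="fixed")
        assert delta_phi1(params, protein, lipid) == 0.0


class TestPropagate:
    def test_totals_are_rss_of_components(self, protein, lipid):
        params = InhomogeneityParams(
            phi1_mean=0.9, x_lip_mean=0.5, d_x_lip=0.1, d_ms_rel=0.05, N0=10_000
        )
        prop = propagate(params, protein, lipid)
        for total_name, parts in prop.components.items():
            total = getattr(prop, total_name)
            assert total == pytest.approx(np.sqrt(sum(v**2 for v in parts.values())), abs=1e-12)
            assert all(v >= 0 for v in parts.values())

    def test_all_zero_inputs_give_zero(self):
        exact = ComponentSpec("p", alpha=0.197, theta=0.734)
        params = InhomogeneityParams(phi1_mean=0.9, N0=10**12, ns_model="fixed")
        prop = propagate(params, exact, exact)
        assert prop.d_n == pytest.approx(0.0, abs=1e-7)
        assert prop.d_rho == pytest.approx(0.0, abs=1e-7)

    def test_n_partials_match_finite_differences(self, protein, lipid):
        # dn/dbeta of n = n1 + (1-phi1) alpha_eff/theta_eff
        x, phi1 = 0.3, 0.85
        alpha_eff, theta_eff = mean_effective(x, protein, lipid)
        n_of = lambda p, a, t: WATER.n1 + (1 - p) * a / t
        h = 1e-7
        fd_phi1 = (n_of(phi1 + h, alpha_eff, theta_eff) - n_of(phi1 - h, alpha_eff, theta_eff)) / (2 * h)
        fd_alpha = (n_of(phi1, alpha_eff + h, theta_eff) - n_of(phi1, alpha_eff - h, theta_eff)) / (2 * h)
        fd_theta = (n_of(phi1, alpha_eff, theta_eff + h) - n_of(phi1, alpha_eff, theta_eff - h)) / (2 * h)
        from ri2md.uncertainty import _n_partials

        params = InhomogeneityParams(phi1_mean=phi1, x_lip_mean=x, N0=1000)
        dn_dphi1, dn_dalpha, dn_dtheta = _n_partials(params, protein, lipid, WATER)
        assert dn_dphi1 == pytest.approx(fd_phi1, rel=1e-6)
        assert dn_dalpha == pytest.approx(fd_alpha, rel=1e-6)
        assert dn_dtheta == pytest.approx(fd_theta, rel=1e-6)

    def test_decoupled_composition_insensitive_to_phi1(self, protein, lipid):
        from ri2md.mixture import decoupling_fraction

        x_star = decoupling_fraction(protein.theta, lipid.theta, WATER.rho1)
        exact_p = ComponentSpec("p", alpha=protein.alpha, theta=protein.theta)
        exact_l = ComponentSpec("l", alpha=lipid.alpha, theta=lipid.theta)
        params = InhomogeneityParams(
            phi1_mean=0.9, x_lip_mean=x_star, N0=10**9, ns_model="binomial"
        )
        prop = propagate(params, exact_p, exact_l)
        # theta_eff = 1/rho1: density noise from phi1 counting vanishes
        assert prop.components["d_rho"]["phi1"] == pytest.approx(0.0, abs=1e-12)

    def test_scaling_law_inverse_sqrt_n0(self, protein, lipid):
        # with no inhomogeneity every sd falls by 2 per 4x voxelinos
        vals = {}
        for n0 in (10**3, 4 * 10**3, 16 * 10**3):
            params = InhomogeneityParams(
                phi1_mean=0.9, x_lip_mean=0.5, N0=n0, ns_model="mass_fluctuation"
            )
            p = propagate(params, protein, lipid)
            vals[n0] = np.array([p.d_theta_eff, p.d_alpha_eff, p.d_phi1, p.d_n, p.d_rho])
        assert np.allclose(vals[10**3] / vals[4 * 10**3], 2.0, rtol=0.01)
        assert np.allclose(vals[4 * 10**3] / vals[16 * 10**3], 2.0, rtol=0.01)

    def test_plateau_with_mass_inhomogeneity(self, protein, lipid):
        big, huge = (
            propagate(
                InhomogeneityParams(
                    phi1_mean=0.9, x_lip_mean=0.5, d_ms_rel=0.05, N0=n0,
                    ns_model="mass_fluctuation",
                ),
                protein,
                lipid,
            )
            for n0 in (10**7, 10**9)
        )
        assert big.d_n == pytest.approx(huge.d_n, rel=1e-2)
        assert huge.d_n > 0 and huge.d_rho > 0

    def test_validation(self):
        with pytest.raises(ValueError):
            InhomogeneityParams(phi1_mean=1.2)
        with pytest.raises(ValueError):
            InhomogeneityParams(phi1_mean=0.9, N0=0)
        with pytest.raises(ValueError):
            InhomogeneityParams(phi1_mean=0.9, ns_model="poisson")
        with pytest.raises(ValueError):
            InhomogeneityParams(phi1_mean=0.9999, N0=100)


class TestMonteCarloAgreement:
    """Closed forms versus the per-voxelino simulator (scaled-down grid)."""

    @pytest.mark.parametrize("x_lip,d_x_lip", [(0.0, 0.0), (0.5, 0.0)])
    def test_effective_and_phi1_sds_match_mc(self, protein, lipid, x_lip, d_x_lip):
        from ri2md.voxel_mc import MixtureSpec, simulate

        n0 = 2000
        params = InhomogeneityParams(
            phi1_mean=0.9, x_lip_mean=x_lip, d_x_lip=d_x_lip, N0=n0,
            ns_model="mass_fluctuation",
        )
        prop = propagate(params, protein, lipid)
        spec = MixtureSpec(
            components=[protein, lipid],
            weights=[1.0 - x_lip, x_lip],
            phi1_mean=0.9,
            x_sd=d_x_lip,
            N0=n0,
            Nv=4000,
            ns_model="mass_fluctuation",
        )
        ens = simulate(spec, seed=42)
        assert prop.d_phi1 == pytest.approx(np.std(ens.phi1), rel=0.10)
        assert prop.d_n == pytest.approx(np.std(ens.n), rel=0.10)
        assert prop.d_rho == pytest.approx(np.std(ens.rho), rel=0.10)
        if x_lip > 0:
            assert prop.d_theta_eff == pytest.approx(np.std(ens.theta_eff), rel=0.10)
            assert prop.d_alpha_eff == pytest.approx(np.std(ens.alpha_eff), rel=0.10)
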