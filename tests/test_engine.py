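"""Forward/back rates, equilibrium deuteration and uptake kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hdxmix import (
    DomainError,
    SolventCondition,
    default_reference_set,
    equilibrium_deuteration,
    extended_tilde_rates,
    ion_state,
    mixture_rate,
    observed_rate,
    residue_profile,
    tilde_rates,
    uptake_curve,
    weighted_rates,
)

PHI = 10.0**0.08  # kHH/kDH for PDLA


def kint_at(cond, refset):
    tf, tb = tilde_rates(ion_state(cond), refset, temperature=cond.temperature)
    kf, kb = weighted_rates(cond.x, tf, tb)
    return mixture_rate(kf, kb)


class TestTildeRates:
    def test_pure_h2o_terms(self, pdla, neutral_h2o):
        s = ion_state(neutral_h2o)
        rs = pdla.at_temperature(298.15)
        tf, tb = tilde_rates(s, rs)
        assert tf == pytest.approx(rs.kHH * s.conc_OH)
        assert tb == pytest.approx(rs.kDH * s.conc_OH)

    def test_pure_d2o_terms(self, pdla, neutral_d2o):
        s = ion_state(neutral_d2o)
        rs = pdla.at_temperature(298.15)
        tf, tb = tilde_rates(s, rs)
        assert tf == pytest.approx(rs.kHD * s.conc_OD)
        assert tb == pytest.approx(rs.kDD * s.conc_OD)

    @pytest.mark.parametrize("x", [0.1, 0.5, 0.9])
    def test_forward_back_ratio_is_phi(self, pdla, x):
        """k~_forw/k~_back collapses to kHH/kDH at any composition."""
        s = ion_state(SolventCondition.from_ph_read(7.0, x, 298.15))
        tf, tb = tilde_rates(s, pdla, temperature=298.15)
        assert tf / tb == pytest.approx(PHI, rel=1e-12)

    def test_phi_invariant_over_grid(self, pdla):
        """Ratio independent of x, pH* and T on a 10x5x5 grid."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for x in np.linspace(0.05, 0.95, 10):
                for ph in np.linspace(5.0, 9.0, 5):
                    for temp in np.linspace(278.15, 323.15, 5):
                        s = ion_state(SolventCondition.from_ph_read(ph, x, temp))
                        tf, tb = tilde_rates(s, pdla, temperature=temp)
                        assert tf / tb == pytest.approx(PHI, rel=1e-9)


class TestWeightedRates:
    def test_endpoints(self):
        assert weighted_rates(0.0, 3.0, 5.0) == (0.0, 5.0)
        assert weighted_rates(1.0, 3.0, 5.0) == (3.0, 0.0)

    def test_half(self):
        kf, kb = weighted_rates(0.5, 3.0, 5.0)
        assert (kf, kb) == (1.5, 2.5)

    def test_domain(self):
        with pytest.raises(DomainError):
            weighted_rates(1.2, 1.0, 1.0)


class TestEquilibriumDeuteration:
    def test_endpoint_limits(self):
        assert equilibrium_deuteration(0.0, 1.0) == 0.0
        assert equilibrium_deuteration(1.0, 0.0) == 1.0

    def test_pdla_half_mixture(self, pdla):
        s = ion_state(SolventCondition.from_ph_read(7.0, 0.5, 298.15))
        tf, tb = tilde_rates(s, pdla, temperature=298.15)
        kf, kb = weighted_rates(0.5, tf, tb)
        assert equilibrium_deuteration(kf, kb) == pytest.approx(0.545922, abs=1e-5)

    def test_both_zero_rejected(self):
        with pytest.raises(DomainError):
            equilibrium_deuteration(0.0, 0.0)

    @given(x=st.floats(0.001, 0.999))
    def test_closed_form_and_enrichment(self, pdla, x):
        """d_eq = x*phi/(x*phi + 1 - x) and exceeds the solvent fraction."""
        s = ion_state(SolventCondition.from_ph_read(7.0, x, 298.15))
        tf, tb = tilde_rates(s, pdla, temperature=298.15)
        kf, kb = weighted_rates(x, tf, tb)
        d_eq = equilibrium_deuteration(kf, kb)
        assert d_eq == pytest.approx(x * PHI / (x * PHI + 1.0 - x), rel=1e-10)
        assert d_eq > x


class TestMixtureRateScenarios:
    def test_fixed_ph_read_decreasing(self, pdla):
        xs = np.linspace(0.0, 1.0, 11)
        ks = [kint_at(SolventCondition.from_ph_read(7.0, x, 298.15), pdla) for x in xs]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_fixed_pl_decreasing_more_steeply(self, pdla):
        xs = np.linspace(0.0, 1.0, 11)
        ks_pl = [kint_at(SolventCondition.from_pl(7.43, x, 298.15), pdla) for x in xs]
        ks_ph = [kint_at(SolventCondition.from_ph_read(7.0, x, 298.15), pdla) for x in xs]
        assert all(a > b for a, b in zip(ks_pl, ks_pl[1:]))
        assert ks_pl[0] / ks_pl[-1] > ks_ph[0] / ks_ph[-1]

    def test_fixed_pol_increasing(self, pdla):
        xs = np.linspace(0.0, 1.0, 11)
        ks = [kint_at(SolventCondition.from_pol(7.43, x, 298.15), pdla) for x in xs]
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_fixed_pol_endpoint_ratio(self, pdla):
        """At fixed catalyst concentration, D2O is 10^0.18 ~ 1.5x faster."""
        hi = kint_at(SolventCondition.from_pol(7.0, 1.0, 298.15), pdla)
        lo = kint_at(SolventCondition.from_pol(7.0, 0.0, 298.15), pdla)
        assert hi / lo == pytest.approx(10.0**0.18, rel=1e-10)

    def test_pure_solvent_recovery(self, pdla):
        """x=1 recovers kHD[OD-]; x=0 back rate recovers kDH[OH-]."""
        rs = pdla.at_temperature(298.15)
        s1 = ion_state(SolventCondition.from_ph_read(7.0, 1.0, 298.15))
        assert kint_at(SolventCondition.from_ph_read(7.0, 1.0, 298.15), pdla) == pytest.approx(
            rs.kHD * s1.conc_OD, rel=1e-12
        )
        s0 = ion_state(SolventCondition.from_ph_read(7.0, 0.0, 298.15))
        assert kint_at(SolventCondition.from_ph_read(7.0, 0.0, 298.15), pdla) == pytest.approx(
            rs.kDH * s0.conc_OH, rel=1e-12
        )


class TestUptakeCurve:
    def test_initial_condition_and_plateau(self):
        c = uptake_curve(0.1, 0.9, 2.0, [0.0, 1e6])
        assert c.d_values[0] == pytest.approx(0.1)
        assert c.d_values[-1] == pytest.approx(0.9)

    def test_half_life(self):
        k = 0.37
        c = uptake_curve(0.0, 0.8, k, [math.log(2.0) / k])
        assert c.d_values[0] == pytest.approx(0.4)

    def test_satisfies_relaxation_ode(self):
        """dD/dt = k_forw (1-D) - k_back D, checked by central differences."""
        kf, kb = 1.3, 0.7
        k = kf + kb
        d_eq = kf / k
        t = np.linspace(0.0, 3.0, 3001)
        c = uptake_curve(0.05, d_eq, k, t)
        dt = t[1] - t[0]
        deriv = np.gradient(c.d_values, dt)
        rhs = kf * (1.0 - c.d_values) - kb * c.d_values
        assert np.allclose(deriv[1:-1], rhs[1:-1], rtol=1e-4, atol=1e-6)

    def test_monotone_toward_equilibrium_and_bounded(self):
        c = uptake_curve(0.0, 0.85, 1.0, np.linspace(0, 10, 100))
        assert np.all(np.diff(c.d_values) > 0)
        assert np.all((c.d_values >= 0) & (c.d_values <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(DomainError):
            uptake_curve(0.0, 0.5, 1.0, [-1.0])


class TestObservedRate:
    @pytest.mark.parametrize("p,expected", [(0.0, 1.0), (1.0, 0.5), (9.0, 0.1)])
    def test_protection_scaling(self, p, expected):
        assert observed_rate(1.0, p) == pytest.approx(expected)

    def test_monotone_decreasing_in_protection(self):
        ks = [observed_rate(1.0, p) for p in (0.0, 1.0, 10.0, 1e6)]
        assert all(a > b for a, b in zip(ks, ks[1:]))
        assert ks[-1] < 1e-5

    def test_negative_protection_rejected(self):
        with pytest.raises(DomainError):
            observed_rate(1.0, -0.1)


class TestResidueProfile:
    def test_polyalanine_interior_rates_equal(self, neutral_d2o):
        rows = residue_profile("AAAAAAA", neutral_d2o)
        interior = [r.k_int_mix for r in rows if r.index in (3, 4, 5, 6)]
        assert all(k == pytest.approx(interior[0], rel=1e-12) for k in interior)

    def test_rows_align_with_sequence(self, neutral_d2o):
        rows = residue_profile("PEPTIDE", neutral_d2o)
        assert [r.index for r in rows] == list(range(1, 8))
        assert [r.residue for r in rows] == list("PEPTIDE")
        assert rows[0].flag == "n-terminus"
        assert rows[2].flag == "proline"
        assert all(math.isnan(rows[i].k_int_mix) for i in (0, 2))
        assert all(r.flag == "" for r in rows if r.index in (2, 4, 5, 6, 7))

    def test_dipeptide_pure_d2o_hand_computation(self, pdla, factor_table, neutral_d2o):
        """'AA' at x=1, pH*=7, 25 degC equals kHD * B * [OD-].

        Independent hand computation: log kHD(25 C) = 10.18 +
        (17/R)(1/293.15-1/298.15)/ln10; B carries the terminal
        corrections (residue 2 is both second and last); pOL follows
        from pKw(1) = pKw_H2O(25 C) + 0.8620 and pL = 7.431.
        """
        import hdxmix

        rows = residue_profile("AA", neutral_d2o, pdla)
        log_khd_25 = 10.18 + (17.0 / 1.9872036e-3) * (
            1.0 / 293.15 - 1.0 / 298.15
        ) / math.log(10.0)
        b = 10.0 ** (factor_table.lam("NT") + factor_table.rho("CT"))
        pkw_mix = hdxmix.pkw_water(298.15) + 0.8620
        pol = pkw_mix - 7.0 * (1.0 + 0.8620 / hdxmix.pkw_water(298.15))
        expected = 10.0**log_khd_25 * b * 10.0 ** (-pol)
        assert rows[1].k_int_mix == pytest.approx(expected, rel=1e-9)
        assert rows[1].k_backward == 0.0

    def test_equilibrium_deuteration_in_profile(self, neutral_d2o):
        rows = residue_profile("AAAA", neutral_d2o)
        for r in rows[1:]:
            assert r.d_eq == pytest.approx(1.0)  # pure D2O: full deuteration

    def test_empty_sequence_rejected(self, neutral_d2o):
        from hdxmix import InputError

        with pytest.raises(InputError):
            residue_profile("", neutral_d2o)


class TestExtendedRates:
    def test_reduces_to_base_only(self, pdla):
        s = ion_state(SolventCondition.from_ph_read(7.0, 0.5, 298.15))
        base = tilde_rates(s, pdla, temperature=298.15)
        ext = extended_tilde_rates(s, 0.5, pdla, temperature=298.15)
        assert ext == base

    def test_water_term_adds_everywhere(self, pdla):
        from hdxmix import ReferenceRateSet

        water = ReferenceRateSet(
            log_kHH=-6.0, log_kDH=-6.3, log_kHD=-6.1, log_kDD=-6.4, standard="water"
        )
        for x in (0.0, 0.5, 1.0):
            cond = SolventCondition.from_ph_read(7.0, x, 298.15)
            s = ion_state(cond)
            tf0, tb0 = tilde_rates(s, pdla, temperature=298.15)
            tf1, tb1 = extended_tilde_rates(
                s, x, pdla, refset_water=water, temperature=298.15
            )
            assert tf1 > tf0 and tb1 > tb0

    def test_acid_term_uses_lyonium_pool(self, pdla):
        from hdxmix import ReferenceRateSet

        acid = ReferenceRateSet(
            log_kHH=1.6, log_kDH=1.4, log_kHD=1.7, log_kDD=1.5, standard="acid"
        )
        x = 0.25
        s = ion_state(SolventCondition.from_ph_read(7.0, x, 298.15))
        tf0, tb0 = tilde_rates(s, pdla, temperature=298.15)
        tf1, tb1 = extended_tilde_rates(s, x, pdla, refset_acid=acid, temperature=298.15)
        conc_l = 10.0 ** (-s.pL)
        ra = acid.at_temperature(298.15)
        assert tf1 - tf0 == pytest.approx(
            ra.kHH * (1 - x) * conc_l + ra.kHD * x * conc_l, rel=1e-10
        )
        assert tb1 - tb0 == pytest.approx(
            ra.kDH * (1 - x) * conc_l + ra.kDD * x * conc_l, rel=1e-10
        )
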