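"""Closed-form bind-and-gate conversions: examples, inverses, error domains."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from etachan import core
from etachan.core import (
    ActivationConstants,
    CRCParameters,
    DomainError,
    EnergyProfile,
    binding_energy,
    coupling_constant,
    ec50_from_constants,
    efficacy_lambda,
    efficiency,
    efficiency_from_kd,
    eta_from_slope,
    gating_constant_from_po,
    kd_from_energy,
    kdc_from_ec50,
    kdo_from_cycle,
    po_curve,
    po_from_gating_constant,
    predict_crc,
    profile_sems_from_kd,
    slope_from_eta,
)


class TestGatingConstant:
    @pytest.mark.parametrize(
        "po,expected", [(0.5, 1.0), (0.96, 24.0), (0.60, 1.5)]
    )
    def test_examples(self, po, expected):
        assert gating_constant_from_po(po) == pytest.approx(expected)
        assert po_from_gating_constant(expected) == pytest.approx(po)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5, float("nan")])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            gating_constant_from_po(bad)


def _po_half_max_bisection(ec50_guess_range, kdc, l2):
    """Independent oracle: numeric root of PO(A) = POmax/2."""
    pomax = l2 / (1.0 + l2)
    return brentq(
        lambda a: po_curve(a, kdc, l2) - pomax / 2.0, *ec50_guess_range, xtol=1e-30, rtol=1e-14
    )


class TestKdcEc50:
    def test_tabulated_inversion(self):
        # BzTMA: EC50 = 1070 uM, POmax = 0.60 -> KdC ~ 930 uM
        kdc = kdc_from_ec50(1070e-6, gating_constant_from_po(0.60))
        assert kdc * 1e6 == pytest.approx(931.8, abs=0.1)
        assert kdc * 1e6 == pytest.approx(930.0, abs=9.3)  # printed precision

    def test_weak_gating_limit(self):
        # L2 -> 0: KdC/EC50 -> 1/(1 + sqrt 2)
        assert kdc_from_ec50(1.0, 1e-12) == pytest.approx(1 / (1 + math.sqrt(2)), rel=1e-6)

    def test_against_bisection_example(self):
        kdc = kdc_from_ec50(110e-6, 4.0)
        assert kdc * 1e6 == pytest.approx(159.5, abs=0.1)
        ec50 = _po_half_max_bisection((1e-9, 1e-1), kdc, 4.0)
        assert ec50 == pytest.approx(110e-6, rel=1e-9)

    @pytest.mark.parametrize("l2", [1e-4, 1e-2, 1.0, 1e2, 1e4])
    def test_bisection_oracle_grid(self, l2):
        kdc = 150e-6
        ec50 = ec50_from_constants(kdc, l2)
        ec50_oracle = _po_half_max_bisection((kdc * 1e-8, kdc * 1e4), kdc, l2)
        assert ec50 == pytest.approx(ec50_oracle, rel=1e-9)
        assert kdc_from_ec50(ec50, l2) == pytest.approx(kdc, rel=1e-9)

    def test_domain(self):
        with pytest.raises(DomainError):
            kdc_from_ec50(-1e-6, 2.0)
        with pytest.raises(DomainError):
            kdc_from_ec50(1e-6, 0.0)


class TestCycle:
    def test_ach_kdo(self):
        # KdC = 174 uM with L2 = 26.64 and wild-type L0 gives KdO ~ 29 nM
        kdo = kdo_from_cycle(174e-6, 26.64, 7.4e-7)
        assert kdo * 1e9 == pytest.approx(29.0, rel=0.01)

    def test_identity_and_hand_value(self):
        assert kdo_from_cycle(1e-4, 3.3e-7, 3.3e-7) == pytest.approx(1e-4)
        assert kdo_from_cycle(100e-6, 1.0, 1e-6) == pytest.approx(100e-9)

    def test_inverse_agonism_allowed(self):
        assert kdo_from_cycle(1e-4, 1e-7, 1e-6) > 1e-4  # c < 1 -> KdO > KdC

    def test_cycle_closure(self):
        for kdc, kdo, l0 in [(1e-4, 1e-7, 5e-7), (1e-3, 1e-3, 1e-6), (1e-6, 1e-8, 1e-5)]:
            ac = ActivationConstants.from_kd(kdc, kdo, l0)
            assert kdo_from_cycle(ac.KdC, ac.L2, ac.L0) == pytest.approx(kdo, rel=1e-9)

    def test_inconsistent_constants_rejected(self):
        # c = 1000 so the cycle demands L2 = L0 * 1e6 = 1.0; L2 = 2 violates it
        ActivationConstants(L0=1e-6, L2=1.0, KdC=1e-4, KdO=1e-7)
        with pytest.raises(DomainError):
            ActivationConstants(L0=1e-6, L2=2.0, KdC=1e-4, KdO=1e-7)


class TestCoupling:
    @pytest.mark.parametrize(
        "kdc,kdo,expected",
        [(90e-6, 140e-9, 642.9), (1e-4, 1e-4, 1.0), (138e-6, 900e-9, 153.3)],
    )
    def test_examples(self, kdc, kdo, expected):
        assert coupling_constant(kdc, kdo) == pytest.approx(expected, abs=0.1)


class TestEnergies:
    def test_ach_values(self):
        assert binding_energy(174e-6) == pytest.approx(-5.11, abs=0.005)
        assert binding_energy(29e-9) == pytest.approx(-10.24, abs=0.005)
        assert binding_energy(1.0) == 0.0

    def test_round_trip(self):
        for kd in [1e-9, 1e-6, 1e-3, 0.5]:
            assert kd_from_energy(binding_energy(kd)) == pytest.approx(kd, rel=1e-9)

    def test_efficiency_examples(self):
        assert efficiency(-5.11, -10.24) == pytest.approx(0.501, abs=0.001)
        assert efficiency(0.0, -10.0) == 1.0
        assert efficiency_from_kd(90e-6, 140e-9) == pytest.approx(0.41, abs=0.005)

    def test_efficiency_matches_kd_form_exactly(self):
        kdc, kdo = 3.3e-5, 8.8e-8
        via_energy = efficiency(binding_energy(kdc), binding_energy(kdo))
        assert efficiency_from_kd(kdc, kdo) == pytest.approx(via_energy, abs=1e-12)

    def test_efficiency_rt_and_base_invariant(self):
        kdc, kdo = 2e-4, 5e-8
        e1 = efficiency(binding_energy(kdc, RT=0.59), binding_energy(kdo, RT=0.59))
        e2 = efficiency(binding_energy(kdc, RT=0.616), binding_energy(kdo, RT=0.616))
        e3 = 1.0 - math.log10(kdc) / math.log10(kdo)
        assert e1 == pytest.approx(e2, abs=1e-12)
        assert e1 == pytest.approx(e3, abs=1e-12)

    def test_efficacy(self):
        assert efficacy_lambda(-10.24, -5.11) == pytest.approx(-5.13)
        assert efficacy_lambda(-3.3, -3.3) == 0.0
        # lambda = -RT ln c
        c = 643.0
        lam = -0.59 * math.log(c)
        assert lam == pytest.approx(-3.815, abs=0.005)
        kdo = 90e-6 / c
        assert efficacy_lambda(binding_energy(kdo), binding_energy(90e-6)) == pytest.approx(
            lam, rel=1e-9
        )

    def test_efficiency_domain(self):
        with pytest.raises(DomainError):
            efficiency(-5.0, 0.0)
        with pytest.raises(DomainError):
            efficiency_from_kd(1e-4, 1.0)


class TestSlopeEta:
    @pytest.mark.parametrize("m,eta", [(2.0, 0.5), (2.545, 0.55996)])
    def test_forward(self, m, eta):
        assert eta_from_slope(m) == pytest.approx(eta, abs=1e-4)

    def test_inverse(self):
        assert slope_from_eta(0.41) == pytest.approx(1.3898, abs=1e-3)
        for eta in [0.1, 0.41, 0.51, 0.9]:
            assert eta_from_slope(slope_from_eta(eta)) == pytest.approx(eta, rel=1e-12)

    def test_domain(self):
        with pytest.raises(DomainError):
            eta_from_slope(0.0)
        with pytest.raises(DomainError):
            eta_from_slope(-1.0)


class TestPoCurve:
    def test_limits(self):
        assert po_curve(0.0, 1e-4, 24.0) == 0.0
        assert po_curve(1e2, 1e-4, 24.0) == pytest.approx(24 / 25, rel=1e-4)

    def test_half_max_consistency(self):
        kdc, l2 = 1e-4, 7.0
        a = ec50_from_constants(kdc, l2)
        assert po_curve(a, kdc, l2) == pytest.approx(0.5 * l2 / (1 + l2), rel=1e-12)

    def test_monotone(self):
        a = np.logspace(-8, -1, 60)
        po = po_curve(a, 1e-4, 5.0)
        assert np.all(np.diff(po) > 0)

    def test_one_site(self):
        # x L1 / (1 + x + x L1) at x = 1: L1/(2 + L1)
        assert po_curve(1e-4, 1e-4, 3.0, n_sites=1) == pytest.approx(3 / 5)

    def test_bad_sites(self):
        with pytest.raises(DomainError):
            po_curve(1e-5, 1e-4, 2.0, n_sites=3)


class TestPredictCRC:
    def test_ach_pomax(self):
        p = predict_crc(174e-6, 29e-9, 7.4e-7)
        assert p.POmax == pytest.approx(0.96, abs=0.005)

    def test_ec50_against_numeric_half_max(self):
        p = predict_crc(174e-6, 29e-9, 7.4e-7)
        assert p.EC50 * 1e6 == pytest.approx(40.0, abs=0.1)
        l2 = 7.4e-7 * (174e-6 / 29e-9) ** 2
        oracle = _po_half_max_bisection((1e-9, 1e-1), 174e-6, l2)
        assert p.EC50 == pytest.approx(oracle, rel=1e-9)

    def test_no_coupling(self):
        p = predict_crc(1e-4, 1e-4, 1e-6)
        assert p.POmax == pytest.approx(p.POmin, rel=1e-9)

    @pytest.mark.parametrize("l2", [1e-3, 0.1, 10.0, 1e3])
    def test_round_trip_through_inversion(self, l2):
        l0, kdc = 5.2e-7, 1e-4
        kdo = kdc / math.sqrt(l2 / l0)
        p = predict_crc(kdc, kdo, l0)
        l2_back = gating_constant_from_po(p.POmax)
        kdc_back = kdc_from_ec50(p.EC50, l2_back)
        kdo_back = kdo_from_cycle(kdc_back, l2_back, l0)
        assert l2_back == pytest.approx(l2, rel=1e-7)
        assert kdc_back == pytest.approx(kdc, rel=1e-7)
        assert kdo_back == pytest.approx(kdo, rel=1e-7)


class TestSemPropagation:
    def test_linear_map(self):
        # dG_LA = RT ln KdC: sem = RT * sem_KdC / KdC (pure scaling)
        out = profile_sems_from_kd(1e-4, 1e-7, 5e-6, 0.0)
        assert out["dG_LA"] == pytest.approx(0.59 * 5e-6 / 1e-4, rel=1e-12)
        assert out["dG_HA"] == 0.0

    def test_zero_in_zero_out(self):
        out = profile_sems_from_kd(9e-5, 1.4e-7, 0.0, 0.0)
        assert all(v == 0.0 for v in out.values())

    def test_eta_sem_vs_bootstrap(self, rng):
        # tabulated pair: KdC = 90 +- 7 uM, KdO = 140 +- 10 nM
        kdc, kdo, s_kdc, s_kdo = 90e-6, 140e-9, 7e-6, 10e-9
        sem = profile_sems_from_kd(kdc, kdo, s_kdc, s_kdo)["eta"]
        assert sem == pytest.approx(0.006, abs=0.001)
        draws_c = rng.normal(kdc, s_kdc, 10_000)
        draws_o = rng.normal(kdo, s_kdo, 10_000)
        keep = (draws_c > 0) & (draws_o > 0)
        etas = 1.0 - np.log(draws_c[keep]) / np.log(draws_o[keep])
        assert sem == pytest.approx(etas.std(), rel=0.15)


class TestDomainTypes:
    def test_crc_parameters_validation(self):
        with pytest.raises(DomainError):
            CRCParameters(EC50=1e-4, POmax=1.2)
        with pytest.raises(DomainError):
            CRCParameters(EC50=1e-4, POmax=0.3, POmin=0.5)

    def test_energy_profile_from_kd(self):
        ep = EnergyProfile.from_kd(174e-6, 29e-9)
        assert ep.lam == pytest.approx(ep.dG_HA - ep.dG_LA)
        assert ep.eta == pytest.approx(1 - ep.dG_LA / ep.dG_HA, abs=1e-12)
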