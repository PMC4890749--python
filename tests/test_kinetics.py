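"""Exchange-rate expressions, occupancy and experiment-design arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from hdx_allomap.kinetics import (
    BindingKinetics,
    ExchangeSite,
    MixComponent,
    MixDesign,
    fractional_occupancy,
    ligand_protein_ratio,
    limiting_rate,
    mix_concentrations,
    observed_exchange_rate,
    saturation_check,
)
from hdx_allomap.units import format_ratio, parse_concentration

rates = st.floats(1e-4, 1e4)
concs = st.floats(1e-12, 1e-1)


class TestBindingKinetics:
    def test_kd_filled_from_rates(self):
        kin = BindingKinetics(k_on=1e6, k_off=0.3)
        assert kin.K_D == pytest.approx(3e-7)

    def test_kon_filled_from_kd_and_koff(self):
        kin = BindingKinetics(k_off=0.3, K_D=3e-7)
        assert kin.k_on == pytest.approx(1e6)

    def test_inconsistent_triplet_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            BindingKinetics(k_on=1e6, k_off=0.3, K_D=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k_off"):
            BindingKinetics(k_off=-1.0)

    def test_site_cannot_be_occluded_and_allosteric(self):
        with pytest.raises(ValueError):
            ExchangeSite(1, k_ex=1.0, occluded=True, allosteric_factor=0.5)


class TestObservedExchangeRate:
    def test_no_ligand_reduces_to_koff(self):
        kin = BindingKinetics(k_off=0.3, k_on=1e6, ligand_conc=0.0)
        assert observed_exchange_rate(kin, k_ex=1.0) == pytest.approx(0.3)

    def test_hand_arithmetic(self):
        # k_on*[L] = 20 min^-1, k_ex = 1 -> 0.3/21
        kin = BindingKinetics(k_off=0.3, k_on=1e6, ligand_conc=2e-5)
        assert observed_exchange_rate(kin, 1.0) == pytest.approx(0.3 / 21.0)
        assert observed_exchange_rate(kin, 1.0) == pytest.approx(1.4286e-2, rel=1e-3)

    def test_nonpositive_parameters_named_in_error(self):
        with pytest.raises(ValueError, match="k_ex"):
            observed_exchange_rate(BindingKinetics(k_off=0.3), k_ex=0.0)
        with pytest.raises(ValueError, match="k_off"):
            observed_exchange_rate(BindingKinetics(), k_ex=1.0)

    @settings(max_examples=200, derandomize=True)
    @given(k_off=rates, k_on=st.floats(1e2, 1e9), lig=concs, k_ex=rates)
    def test_bounded_by_koff_and_decreasing_in_ligand(self, k_off, k_on, lig, k_ex):
        kin = BindingKinetics(k_off=k_off, k_on=k_on, ligand_conc=lig)
        k_obs = observed_exchange_rate(kin, k_ex)
        assert 0.0 < k_obs <= k_off
        more = BindingKinetics(k_off=k_off, k_on=k_on, ligand_conc=lig * 2)
        assert observed_exchange_rate(more, k_ex) < k_obs

    def test_converges_to_limiting_rate_in_excess(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            k_ex = 10.0 ** rng.uniform(-2, 2)
            ratio = 10.0 ** rng.uniform(2, 5)  # k_on*[L]/k_ex >= 100
            lig = 10.0 ** rng.uniform(-6, -2)
            k_on = ratio * k_ex / lig
            k_off = 10.0 ** rng.uniform(-3, 1)
            kin = BindingKinetics(k_off=k_off, k_on=k_on, ligand_conc=lig)
            full = observed_exchange_rate(kin, k_ex)
            limit = limiting_rate(kin.K_D, k_ex, lig)
            assert abs(full - limit) / limit < 1e-2


class TestLimitingRate:
    def test_infinitely_tight_binder_never_exchanges(self):
        assert limiting_rate(0.0, 1.0, 1e-5) == 0.0

    @pytest.mark.parametrize("K_D,lig,expected", [
        (1.9e-8, 2e-5, 9.5e-4),    # tight natural inhibitor at 20 uM
        (5.7e-4, 5e-3, 0.114),     # weak fragment at 5 mM
    ])
    def test_hand_arithmetic(self, K_D, lig, expected):
        assert limiting_rate(K_D, 1.0, lig) == pytest.approx(expected)

    def test_zero_ligand_is_domain_error(self):
        with pytest.raises(ValueError):
            limiting_rate(1e-8, 1.0, 0.0)


class TestFractionalOccupancy:
    def test_no_ligand_no_complex(self):
        assert fractional_occupancy(1e-6, 1e-6, 0.0) == 0.0

    def test_stoichiometric_titration_limit(self):
        assert fractional_occupancy(1e-15, 1e-6, 2e-6) == pytest.approx(1.0)

    def test_tight_inhibitor_near_saturation(self):
        occ = fractional_occupancy(1.9e-8, 3.3e-6, 2e-5)
        assert occ == pytest.approx(0.9989, abs=1e-3)

    def test_matches_bisection_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            K_D = 10.0 ** rng.uniform(-9, -3)
            P = 10.0 ** rng.uniform(-7, -4)
            L = 10.0 ** rng.uniform(-8, -2)

            def balance(x):
                return (P - x) * (L - x) - K_D * x

            x = brentq(balance, 0.0, min(P, L), xtol=1e-18, rtol=1e-15)
            assert fractional_occupancy(K_D, P, L) == pytest.approx(
                x / P, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(K_D=concs, P=st.floats(1e-9, 1e-3), l1=concs, l2=concs)
    def test_monotone_in_ligand(self, K_D, P, l1, l2):
        lo, hi = sorted((l1, l2))
        assert fractional_occupancy(K_D, P, lo) <= \
            fractional_occupancy(K_D, P, hi) + 1e-12


class TestMixDesign:
    def test_published_quench_mix(self):
        # 1 uL of 100 uM protein + 27 uL of 99.9% D2O buffer + 2 uL DMSO
        design = MixDesign([
            MixComponent(1.0, 100e-6, 0.0),
            MixComponent(27.0, 0.0, 0.999),
            MixComponent(2.0, 0.0, 0.0),
        ])
        concs_out, d2o = mix_concentrations(design)
        assert concs_out[0] * 1e6 == pytest.approx(3.3, abs=0.05)
        assert d2o == pytest.approx(0.90, abs=0.005)

    def test_single_component_identity(self):
        concs_out, d2o = mix_concentrations(
            MixDesign([MixComponent(5.0, 1e-6, 0.5)]))
        assert concs_out == [pytest.approx(1e-6)]
        assert d2o == pytest.approx(0.5)

    def test_equal_volume_average(self):
        concs_out, _ = mix_concentrations(MixDesign(
            [MixComponent(10, 10e-6, 0), MixComponent(10, 0, 0)]))
        assert concs_out[0] == pytest.approx(5e-6)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            mix_concentrations(MixDesign([]))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0.1, 100), st.floats(0, 1e-3)),
                    min_size=1, max_size=6))
    def test_mass_conservation(self, comps):
        design = MixDesign([MixComponent(v, c) for v, c in comps])
        concs_out, _ = mix_concentrations(design)
        total_mass = sum(v * c for v, c in comps)
        assert sum(c * design.total_volume_ul for c in concs_out) == \
            pytest.approx(total_mass)


class TestRatios:
    def test_published_renderings(self):
        protein = 100e-6 / 30.0  # 3.33 uM after the quench dilution
        assert format_ratio(ligand_protein_ratio(20e-6, protein)) == "6:1"
        assert format_ratio(ligand_protein_ratio(5e-3, protein)) == "1500:1"

    def test_equal_concentrations(self):
        assert ligand_protein_ratio(3.3e-6, 3.3e-6) == 1.0

    def test_zero_protein_rejected(self):
        with pytest.raises(ValueError):
            ligand_protein_ratio(1e-6, 0.0)


class TestSaturationCheck:
    def test_tight_inhibitor_is_saturating(self):
        # k_on*[L]/k_ex = 200 with K_D = 19 nM at 20 uM
        kin = BindingKinetics(K_D=19e-9, k_on=1e7, ligand_conc=2e-5,
                              protein_conc=3.3e-6)
        verdict = saturation_check(kin, k_ex=1.0)
        assert verdict.scenario == "saturating"
        assert verdict.kinetic_ratio == pytest.approx(200.0)
        assert verdict.occupancy > 0.99

    def test_no_ligand(self):
        kin = BindingKinetics(K_D=19e-9, protein_conc=3.3e-6, ligand_conc=0.0)
        verdict = saturation_check(kin, k_ex=1.0)
        assert verdict.scenario == "no-binding"
        assert verdict.occupancy == 0.0

    def test_slow_off_complex(self):
        kin = BindingKinetics(k_off=1e-3, K_D=1e-10, ligand_conc=1e-4,
                              protein_conc=1e-6)
        verdict = saturation_check(kin, k_ex=1.0)
        assert verdict.scenario == "slow-off"
        assert "not dissociate" in verdict.note

    def test_intermediate_regime(self):
        kin = BindingKinetics(k_off=0.3, K_D=1e-6, ligand_conc=1e-6,
                              protein_conc=1e-6)
        verdict = saturation_check(kin, k_ex=1.0)
        assert verdict.scenario == "intermediate"


class TestUnits:
    @pytest.mark.parametrize("text,molar", [
        ("20 uM", 2e-5), ("5mM", 5e-3), ("19 nM", 1.9e-8),
        ("0.5 M", 0.5), ("3.3 µM", 3.3e-6), ("1e-7", 1e-7),
    ])
    def test_concentration_parsing(self, text, molar):
        assert parse_concentration(text) == pytest.approx(molar)

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_concentration("fast")
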