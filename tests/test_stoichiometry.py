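"""The hepatocyte reaction-network stoichiometry and its conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sinusim.processes import (HEPATIC_STOICHIOMETRY, hepatic_derivatives,
                               hepatic_stoichiometric_matrix)
from sinusim.state import HEP_SPECIES

# Frozen rate-equation table: species -> {process: coefficient}.  This is
# the authoritative set of linear combinations defining d(state)/dt.
RATE_EQUATIONS = {
    "glucose_c": {"glucokinase": -1, "g6pase": 1, "glucose_uptake": 1},
    "g6p": {"glucokinase": 1, "g6pase": -1, "glycogen_phosphorylase": 1,
            "glycogen_synthase": -1, "gluconeogenesis2": 1, "glycolysis1": -1},
    "glycogen": {"glycogen_synthase": 1, "glycogen_phosphorylase": -1},
    "g3p_gadp": {"gluconeogenesis1": 1, "gluconeogenesis2": -2,
                 "glycolysis1": 2, "glycolysis2": -1, "glycerol_kinase": 1,
                 "tg_synthesis": -1},
    "pyr_lac": {"lactate_exchange": 1, "gluconeogenesis1": -1,
                "glycolysis2": 1, "pdh": -1},
    "acetyl_coa": {"pdh": 1, "lipogenesis": -8, "beta_oxidation": 8,
                   "atp_synthesis": -1},
    "ffa_c": {"ffa_uptake": 1, "lipolysis": 3, "tg_synthesis": -3,
              "lipogenesis": 1, "beta_oxidation": -1},
    "tg_c": {"tg_exchange": 1, "tg_synthesis": 1, "lipolysis": -1},
    "glycerol_c": {"glycerol_exchange": 1, "glycerol_kinase": -1,
                   "lipolysis": 1},
    "atp": {"atp_synthesis": 12, "adenylate_kinase": -1,
            "gluconeogenesis1": -2, "glycolysis1": -1, "glycolysis2": 3.25,
            "glucokinase": -1, "ndk_g": -1, "ndk_u": -1, "atp_use": -1,
            "beta_oxidation": -2, "lipogenesis": -7, "glycerol_kinase": -1,
            "pdh": 2.5, "tg_synthesis": -3},
    "adp": {"atp_synthesis": -12, "adenylate_kinase": 2,
            "gluconeogenesis1": 2, "glycolysis1": 1, "glycolysis2": -3.25,
            "glucokinase": 1, "ndk_g": 1, "ndk_u": 1, "atp_use": 1,
            "lipogenesis": 7, "glycerol_kinase": 1, "beta_oxidation": 1,
            "pdh": -2.5},
    "amp": {"adenylate_kinase": -1, "beta_oxidation": 1, "tg_synthesis": 3},
    "pi": {"atp_synthesis": -12, "glycogen_phosphorylase": -1, "g6pase": 1,
           "glycogen_synthase": 2, "glycolysis2": -2.25,
           "gluconeogenesis1": 2, "gluconeogenesis2": 1, "pi_regulation": -1,
           "atp_use": 1, "lipogenesis": 7, "beta_oxidation": 1, "pdh": -2.5,
           "tg_synthesis": 7},
    "utp": {"ndk_u": 1, "glycogen_synthase": -1},
    "udp": {"ndk_u": -1, "glycogen_synthase": 1},
    "gtp": {"ndk_g": 1, "gluconeogenesis1": -1},
    "gdp": {"ndk_g": -1, "gluconeogenesis1": 1},
}


class TestRateEquationTable:
    def test_stoichiometry_reproduces_rate_equations_exactly(self):
        """Column-by-column identity with the frozen rate-equation table,
        including the fractional coefficients 3.25, 2.25, 2.5 and 12."""
        for species, combo in RATE_EQUATIONS.items():
            for process, coef in combo.items():
                assert HEPATIC_STOICHIOMETRY[process].get(species, 0) == coef, \
                    f"{process} -> {species}"
        # and no spurious extra hepatic entries anywhere
        for process, stoich in HEPATIC_STOICHIOMETRY.items():
            for species, coef in stoich.items():
                if species in HEP_SPECIES:
                    assert RATE_EQUATIONS[species].get(process, 0) == coef, \
                        f"unexpected {process} -> {species}"

    def test_all_processes_present(self):
        assert len(HEPATIC_STOICHIOMETRY) == 25


class TestConservation:
    @pytest.mark.parametrize("pool", [("atp", "adp", "amp"),
                                      ("utp", "udp"), ("gtp", "gdp")])
    def test_nucleotide_moiety_columns_sum_to_zero(self, pool):
        S = hepatic_stoichiometric_matrix()
        rows = [HEP_SPECIES.index(s) for s in pool]
        assert np.allclose(S[rows].sum(axis=0), 0.0)

    @given(st.lists(st.floats(0, 100), min_size=25, max_size=25))
    @settings(max_examples=50, deadline=None)
    def test_pools_conserved_for_any_rate_vector(self, rates_list):
        rates = dict(zip(HEPATIC_STOICHIOMETRY, rates_list))
        d = hepatic_derivatives(rates)
        idx = {s: HEP_SPECIES.index(s) for s in HEP_SPECIES}
        assert d[idx["atp"]] + d[idx["adp"]] + d[idx["amp"]] == \
            pytest.approx(0.0, abs=1e-9)
        assert d[idx["utp"]] + d[idx["udp"]] == pytest.approx(0.0, abs=1e-9)
        assert d[idx["gtp"]] + d[idx["gdp"]] == pytest.approx(0.0, abs=1e-9)

    def test_carbon_bookkeeping(self):
        """Triglyceride synthesis moves 3*16+3 = 51 carbons into one TG;
        lipogenesis packs 8 2-carbon acetyl units per 16-carbon FFA and
        beta-oxidation is its reverse."""
        tsyn = HEPATIC_STOICHIOMETRY["tg_synthesis"]
        carbons_in = -tsyn["ffa_c"] * 16 + -tsyn["g3p_gadp"] * 3
        assert carbons_in == 51 == tsyn["tg_c"] * 51
        lgen = HEPATIC_STOICHIOMETRY["lipogenesis"]
        assert -lgen["acetyl_coa"] * 2 == lgen["ffa_c"] * 16
        boxi = HEPATIC_STOICHIOMETRY["beta_oxidation"]
        assert boxi["acetyl_coa"] * 2 == -boxi["ffa_c"] * 16


class TestHepaticDerivatives:
    def test_zero_rates_give_zero_derivatives(self):
        d = hepatic_derivatives({n: 0.0 for n in HEPATIC_STOICHIOMETRY})
        assert np.all(d == 0)

    def test_pure_lipogenesis_column(self):
        rates = {n: 0.0 for n in HEPATIC_STOICHIOMETRY}
        rates["lipogenesis"] = 1.0
        d = hepatic_derivatives(rates)
        get = lambda s: d[HEP_SPECIES.index(s)]
        assert get("acetyl_coa") == -8
        assert get("ffa_c") == 1
        assert get("atp") == -7
        assert get("adp") == 7
        assert get("pi") == 7

    def test_missing_rate_raises(self):
        with pytest.raises(KeyError):
            hepatic_derivatives({"glucokinase": 1.0})
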