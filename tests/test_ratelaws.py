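"""Hill factors and hormone-effect transforms."""

import pytest
from hypothesis import given, settings, strategies as st

from sinusim.processes import effective_hormones
from sinusim.ratelaws import RateTerm, TermKind, hill_term, term_from_config


class TestHillTerm:
    def test_half_saturation_point(self):
        assert hill_term(2.0, 2.0, 2.0) == pytest.approx(0.5)

    def test_boundaries_at_zero(self):
        assert hill_term(0.0, 1.0, 2.0, "activation") == 0.0
        assert hill_term(0.0, 1.0, 2.0, "inhibition") == 1.0

    def test_two_K_activation(self):
        # (2K)^2 / (K^2 + (2K)^2) = 4/5
        assert hill_term(2.0, 1.0, 2.0) == pytest.approx(0.8)

    @given(c=st.floats(0, 1e6), K=st.floats(1e-3, 1e6),
           n=st.floats(0.5, 4.0))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_complementary(self, c, K, n):
        a = hill_term(c, K, n, "activation")
        i = hill_term(c, K, n, "inhibition")
        assert 0.0 <= a <= 1.0
        assert a + i == pytest.approx(1.0, abs=1e-12)

    @given(K=st.floats(1e-3, 1e3), n=st.floats(0.5, 4.0),
           c1=st.floats(0, 1e4), c2=st.floats(0, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_substrate(self, K, n, c1, c2):
        lo, hi = sorted((c1, c2))
        assert hill_term(lo, K, n) <= hill_term(hi, K, n) + 1e-15

    @pytest.mark.parametrize("K,n", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0),
                                     (1.0, -2.0)])
    def test_invalid_constants_rejected(self, K, n):
        with pytest.raises(ValueError):
            hill_term(1.0, K, n)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_term(-1.0, 1.0, 1.0)


class TestRateTerm:
    def test_hormone_factor_shape(self):
        t = RateTerm(TermKind.INSULIN_ACT, None, K=0.1, n=1.0, base=0.2,
                     amp=0.8)
        assert t.evaluate(insulin_eff=0.0) == pytest.approx(0.2)
        assert t.evaluate(insulin_eff=0.1) == pytest.approx(0.6)
        assert t.evaluate(insulin_eff=1e9) == pytest.approx(1.0, rel=1e-6)

    def test_config_round_trip(self):
        t = term_from_config({"kind": "inh", "species": "acetyl_coa",
                              "K": 250.0, "n": 2})
        assert t.kind == TermKind.INHIBITION
        assert t.evaluate(250.0) == pytest.approx(0.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            term_from_config({"kind": "banana", "K": 1.0})


class TestEffectiveHormones:
    def test_identity_when_metabolically_healthy(self):
        ins, gln = effective_hormones(0.5, 0.05, k_ir=1.0, srebp1c=False,
                                      process="glucokinase")
        assert ins == pytest.approx(0.5)
        assert gln == pytest.approx(0.05)

    def test_severe_insulin_resistance_scales_detection(self):
        ins, _ = effective_hormones(0.5, 0.05, k_ir=0.015, srebp1c=False,
                                    process="glucokinase")
        assert ins == pytest.approx(0.0075)

    def test_srebp_clamp_overrides_resistance_for_lipogenic_processes(self):
        ins, _ = effective_hormones(0.1, 0.05, k_ir=0.015, srebp1c=True,
                                    process="lipogenesis")
        assert ins == pytest.approx(1.0)
        ins, _ = effective_hormones(0.1, 0.05, k_ir=0.015, srebp1c=True,
                                    process="tg_synthesis")
        assert ins == pytest.approx(1.0)

    def test_srebp_clamp_spares_non_lipogenic_processes(self):
        ins, _ = effective_hormones(0.1, 0.05, k_ir=0.015, srebp1c=True,
                                    process="beta_oxidation")
        assert ins == pytest.approx(0.0015)

    def test_glucagon_unaffected_by_resistance(self):
        _, gln = effective_hormones(0.1, 0.07, k_ir=0.015, srebp1c=False,
                                    process="g6pase")
        assert gln == pytest.approx(0.07)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_k_ir_rejected(self, bad):
        with pytest.raises(ValueError):
            effective_hormones(0.1, 0.05, k_ir=bad, srebp1c=False,
                               process="glucokinase")
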