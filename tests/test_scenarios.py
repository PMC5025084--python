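"""Scenario presets, diet composition and the feeding waveform."""

import numpy as np
import pytest

from sinusim.scenarios import (K_IR_SEVERE, K_IR_DEVELOPING, Scenario,
                               feeding_input, make_scenario)


class TestFeedingWaveform:
    def test_trough_between_meals(self):
        assert feeding_input(0.0, 10.0) == 0.0
        assert feeding_input(4.0, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_peak_mid_cycle(self):
        assert feeding_input(2.0, 10.0) == pytest.approx(10.0)

    def test_period_is_four_hours(self):
        t = np.linspace(0, 4, 97)
        a = [feeding_input(ti, 1.0) for ti in t]
        b = [feeding_input(ti + 4.0, 1.0) for ti in t]
        assert np.allclose(a, b)

    def test_cycle_mean_is_5_16(self):
        t = np.linspace(0, 4, 400001)
        mean = np.mean([feeding_input(ti, 1.0) for ti in t[:-1]])
        assert mean == pytest.approx(5.0 / 16.0, abs=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            feeding_input(1.0, -1.0)


class TestPresets:
    def test_metabolically_healthy_is_identity(self):
        s = make_scenario("MH")
        assert s.k_ir == 1.0
        assert not s.srebp1c
        assert s.glucose_input_multiplier == 1.0
        assert s.ffa_input_multiplier == 1.0

    def test_insulin_resistance_levels(self):
        assert make_scenario("developing_IR").k_ir == K_IR_DEVELOPING == 0.05
        assert make_scenario("severe_IR").k_ir == K_IR_SEVERE == 0.015
        assert not make_scenario("severe_IR").srebp1c

    def test_nafld_combines_severe_ir_and_srebp(self):
        s = make_scenario("NAFLD")
        assert s.k_ir == K_IR_SEVERE
        assert s.srebp1c

    def test_high_fat_multiplier(self):
        assert make_scenario("high_fat").ffa_input_multiplier == 1.125

    @pytest.mark.parametrize("level,mult", [("raised", 1.05), ("high", 1.125),
                                            ("very_high", 1.25)])
    @pytest.mark.parametrize("kind", ["fat", "carb"])
    def test_diet_ladder(self, level, mult, kind):
        s = make_scenario(f"{level}_{kind}")
        if kind == "fat":
            assert s.ffa_input_multiplier == mult
            assert s.glucose_input_multiplier == 1.0
        else:
            assert s.glucose_input_multiplier == mult
            assert s.ffa_input_multiplier == 1.0

    @pytest.mark.parametrize("base,k_ir,srebp",
                             [("MH", 1.0, False),
                              ("developing_IR", 0.05, False),
                              ("severe_IR", 0.015, False),
                              ("NAFLD", 0.015, True)])
    @pytest.mark.parametrize("diet", ["raised_fat", "high_fat",
                                      "very_high_fat", "high_carb",
                                      "very_high_carb"])
    def test_composition_is_orthogonal(self, base, k_ir, srebp, diet):
        """Disease state and diet combine freely without interference."""
        s = make_scenario(f"{base}+{diet}")
        assert s.k_ir == k_ir
        assert s.srebp1c == srebp
        ref = make_scenario(diet)
        assert s.ffa_input_multiplier == ref.ffa_input_multiplier
        assert s.glucose_input_multiplier == ref.glucose_input_multiplier
        # peak input rates are diet-independent (multipliers carry the diet)
        assert s.v_input_glucose == ref.v_input_glucose

    def test_constant_baseline_uses_stored_inputs(self):
        s = make_scenario("constant_baseline",
                          baseline_inputs={"glucose": 2.5, "ffa": 0.34},
                          body_volume_l=10.0)
        assert s.waveform == "constant"
        assert s.v_input_glucose == pytest.approx(25.0)
        assert s.v_input_ffa == pytest.approx(3.4)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            make_scenario("keto")

    def test_invalid_k_ir_rejected(self):
        with pytest.raises(ValueError):
            Scenario(name="x", k_ir=0.0)
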