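"""Feeding, diet and disease scenarios.

A scenario bundles the insulin-resistance constant K_IR, the SREBP-1c
over-expression flag, diet multipliers and the feeding waveform.  The
moderate diet delivers 78.1 g of carbohydrate and 22.2 g of lipid per
4-hour sin^6 feeding cycle; raised/high/very-high diets scale one input
by +5%, +12.5% and +25%.  Developing and severe insulin resistance
correspond to K_IR = 0.05 and 0.015; the NAFLD scenario combines severe
resistance with the SREBP-1c clamp on lipogenesis and triglyceride
synthesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .params import FeedingParams

#: Mean of sin^6 over one period.
SIN6_MEAN = 5.0 / 16.0

K_IR_DEVELOPING = 0.05
K_IR_SEVERE = 0.015

_DIET_MULTIPLIERS = {
    "moderate": 1.0,
    "raised": 1.05,
    "high": 1.125,
    "very_high": 1.25,
    "low": 0.875,
}


def feeding_input(t_hours: float, v_input: float,
                  cycle_hours: float = 4.0) -> float:
    """Spiked feeding input v_input * sin^6(pi * t / cycle) (period = cycle).

    The cycle mean of sin^6 is 5/16, so one cycle delivers
    v_input * 5/16 * cycle_hours (in hour * rate units).
    """
    if v_input < 0:
        raise ValueError(f"v_input must be >= 0, got {v_input}")
    if t_hours < 0:
        raise ValueError(f"t must be >= 0, got {t_hours}")
    return v_input * math.sin(math.pi * t_hours / cycle_hours) ** 6


@dataclass(frozen=True)
class Scenario:
    """A declarative simulation condition.

    ``v_input_glucose``/``v_input_ffa`` are peak input rates in umol/s
    for the cyclic waveform, or the constant rates for the constant
    waveform.  Multipliers scale the inputs relative to the moderate diet.
    """

    name: str
    k_ir: float = 1.0
    srebp1c: bool = False
    glucose_input_multiplier: float = 1.0
    ffa_input_multiplier: float = 1.0
    waveform: str = "cyclic"            # 'cyclic' | 'constant'
    v_input_glucose: float = 0.0        # umol/s (peak for cyclic)
    v_input_ffa: float = 0.0
    cycle_hours: float = 4.0

    def __post_init__(self):
        if not 0.0 < self.k_ir <= 1.0:
            raise ValueError(f"K_IR must be in (0, 1], got {self.k_ir}")
        if self.glucose_input_multiplier <= 0 or self.ffa_input_multiplier <= 0:
            raise ValueError("diet multipliers must be positive")
        if self.waveform not in ("cyclic", "constant"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    @classmethod
    def metabolically_healthy(cls, feeding: FeedingParams | None = None) -> "Scenario":
        return make_scenario("MH", feeding=feeding)


def _cyclic_base(name: str, feeding: FeedingParams) -> Scenario:
    vg, vf = feeding.peak_rates_umol_per_s()
    return Scenario(name=name, waveform="cyclic", v_input_glucose=vg,
                    v_input_ffa=vf, cycle_hours=feeding.cycle_hours)


def make_scenario(preset: str, feeding: FeedingParams | None = None,
                  baseline_inputs: dict | None = None,
                  body_volume_l: float = 10.0) -> Scenario:
    """Build a scenario from a preset name.

    Base presets: ``MH``, ``developing_IR``, ``severe_IR``, ``NAFLD``
    (severe IR + SREBP-1c) and ``constant_baseline`` (the solved
    constant-input state used by the rate-constant sensitivity protocol).
    Diet variants append ``+<level>_<fat|carb>``, e.g.
    ``severe_IR+high_fat`` or ``MH+very_high_carb``; a bare diet name
    such as ``high_fat`` applies to the healthy base.
    """
    feeding = feeding or FeedingParams()
    parts = preset.split("+")
    base = parts[0]
    diets = parts[1:]
    known_bases = {"MH", "developing_IR", "severe_IR", "NAFLD",
                   "constant_baseline"}
    if base not in known_bases:
        # bare diet name -> healthy base
        diets = [base] + diets
        base = "MH"

    if base == "constant_baseline":
        if diets:
            raise ValueError("diet variants do not apply to the constant baseline")
        inputs = baseline_inputs or {}
        return Scenario(name=preset, waveform="constant",
                        v_input_glucose=inputs.get("glucose", 0.0) * body_volume_l,
                        v_input_ffa=inputs.get("ffa", 0.0) * body_volume_l,
                        cycle_hours=feeding.cycle_hours)

    scen = _cyclic_base(preset, feeding)
    if base == "developing_IR":
        scen = replace(scen, k_ir=K_IR_DEVELOPING)
    elif base == "severe_IR":
        scen = replace(scen, k_ir=K_IR_SEVERE)
    elif base == "NAFLD":
        scen = replace(scen, k_ir=K_IR_SEVERE, srebp1c=True)

    for diet in diets:
        try:
            level, kind = diet.rsplit("_", 1)
            mult = _DIET_MULTIPLIERS[level]
        except (ValueError, KeyError):
            raise ValueError(f"unknown preset component {diet!r}") from None
        if kind == "fat":
            scen = replace(scen, ffa_input_multiplier=mult)
        elif kind == "carb":
            scen = replace(scen, glucose_input_multiplier=mult)
        else:
            raise ValueError(f"unknown diet kind {kind!r}")
    return scen
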