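"""State containers and the flat-vector layout used by the integrator.

The full model state is one 1-D float vector:

    y = [ body blood (8) |
          compartment 1: blood (8), hepatocyte (17) |
          ...
          compartment N: blood (8), hepatocyte (17) ]

Hepatocyte species follow the order of the model's rate-equation table;
pooled species (triose phosphates, pyruvate/lactate) are single states.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

#: Hepatocyte species (uM), in canonical order.
HEP_SPECIES = (
    "glucose_c", "g6p", "glycogen", "g3p_gadp", "pyr_lac", "acetyl_coa",
    "ffa_c", "tg_c", "glycerol_c",
    "atp", "adp", "amp", "pi", "utp", "udp", "gtp", "gdp",
)

#: Blood species; metabolites in uM, hormones in nM, oxygen in mmHg.
BLOOD_SPECIES = (
    "glucose_b", "lactate_b", "ffa_b", "tg_b", "glycerol_b",
    "insulin", "glucagon", "oxygen",
)

N_HEP = len(HEP_SPECIES)      # 17
N_BLOOD = len(BLOOD_SPECIES)  # 8
N_PER_COMP = N_BLOOD + N_HEP  # 25

HEP_INDEX = {name: i for i, name in enumerate(HEP_SPECIES)}
BLOOD_INDEX = {name: i for i, name in enumerate(BLOOD_SPECIES)}

#: Species codes used in stoichiometries and rate laws: hepatocyte species
#: are 0..16, local-blood (or body-pool) species are 17..24.
SPECIES_CODE = dict(HEP_INDEX)
SPECIES_CODE.update({name: N_HEP + i for name, i in BLOOD_INDEX.items()})
CODE_SPECIES = {v: k for k, v in SPECIES_CODE.items()}


def n_states(n_compartments: int) -> int:
    return N_BLOOD + n_compartments * N_PER_COMP


def body_slice() -> slice:
    return slice(0, N_BLOOD)


def blood_slice(i: int) -> slice:
    """Blood state of sinusoid compartment ``i`` (0-based)."""
    base = N_BLOOD + i * N_PER_COMP
    return slice(base, base + N_BLOOD)


def hep_slice(i: int) -> slice:
    """Hepatocyte state of sinusoid compartment ``i`` (0-based)."""
    base = N_BLOOD + i * N_PER_COMP + N_BLOOD
    return slice(base, base + N_HEP)


def _nonneg(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if v < 0:
            raise ValueError(f"{f.name} must be >= 0, got {v}")


@dataclass
class HepatocyteState:
    """Intracellular species of one sinusoid compartment (uM).

    ``glycogen`` is in glucose-equivalent uM; ``ffa_c`` is palmitate
    equivalent; ``g3p_gadp`` and ``pyr_lac`` are pooled species.
    """

    glucose_c: float
    g6p: float
    glycogen: float
    g3p_gadp: float
    pyr_lac: float
    acetyl_coa: float
    ffa_c: float
    tg_c: float
    glycerol_c: float
    atp: float
    adp: float
    amp: float
    pi: float
    utp: float
    udp: float
    gtp: float
    gdp: float

    def __post_init__(self):
        _nonneg(self)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in HEP_SPECIES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "HepatocyteState":
        return cls(**{n: float(a[i]) for i, n in enumerate(HEP_SPECIES)})

    @property
    def adenine_pool(self) -> float:
        return self.atp + self.adp + self.amp

    @property
    def uridine_pool(self) -> float:
        return self.utp + self.udp

    @property
    def guanine_pool(self) -> float:
        return self.gtp + self.gdp


@dataclass
class BloodState:
    """Plasma species of one compartment or of the systemic pool."""

    glucose_b: float
    lactate_b: float
    ffa_b: float
    tg_b: float
    glycerol_b: float
    insulin: float
    glucagon: float
    oxygen: float

    def __post_init__(self):
        _nonneg(self)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BLOOD_SPECIES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "BloodState":
        return cls(**{n: float(a[i]) for i, n in enumerate(BLOOD_SPECIES)})
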