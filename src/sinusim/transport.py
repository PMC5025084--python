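"""Sinusoid assembly: plug-flow advection, body compartment, oracles.

Blood enters the chain of well-mixed sinusoid compartments from the
systemic pool, flows periportal -> pericentral, and drains back into the
pool, where it meets the pancreas, adipose tissue, gut, muscle and the
feeding inputs.  Insulin and glucagon are degraded at a constant
fractional rate per compartment and oxygen is consumed at a constant
(zero-order) rate, so both admit closed-form steady-state profiles that
serve as verification oracles for the transport scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams, load_params
from .processes import (INSULIN_RECEPTION_KN, GLUCAGON_RECEPTION_KN)
from .state import (BLOOD_SPECIES, BLOOD_INDEX, N_BLOOD, blood_slice,
                    body_slice, hep_slice, n_states, HEP_SPECIES)
from .zonation import build_zonation_profile


@dataclass
class BodyCompartment:
    """Systemic pool: blood state plus the non-hepatic physiology."""

    volume_l: float
    params: ModelParams

    def process_rates(self, blood: dict[str, float], k_ir: float = 1.0) -> dict[str, float]:
        """Net rates of the body processes (uM/s, pool basis)."""
        out = {}
        for name, proc in self.params.body_processes.items():
            ins_eff = k_ir * blood.get("insulin", 0.0)
            out[name] = proc.net_rate(blood, 1.0, ins_eff,
                                      blood.get("glucagon", 0.0))
        return out


class SinusoidModel:
    """The assembled zonated model: N hepatic compartments plus the body.

    Thin wrapper around a :class:`~sinusim.params.ModelParams` adding the
    derived per-compartment structure (zonation multipliers, hormone
    reception profiles, degradation rates, oxygen handling) and the
    default initial state.
    """

    def __init__(self, params: ModelParams | None = None):
        self.params = params if params is not None else load_params()
        phys = self.params.physiology
        n = phys.n_compartments
        if phys.blood_flow_l_per_s <= 0:
            raise ValueError("blood flow must be positive")
        self.n_compartments = n
        self.flow = phys.blood_flow_l_per_s
        self.compartment_blood_volume = phys.compartment_blood_volume_l
        self.compartment_hep_volume = phys.compartment_hepatocyte_volume_l
        self.body_volume = phys.body_volume_l
        self.hepatocyte_blood_ratio = phys.hepatocyte_blood_ratio
        self.zonation = {name: build_zonation_profile(proc.k_n, n)
                         for name, proc in self.params.processes.items()}
        self.insulin_reception = build_zonation_profile(
            INSULIN_RECEPTION_KN, n).multipliers
        self.glucagon_reception = build_zonation_profile(
            GLUCAGON_RECEPTION_KN, n).multipliers
        self.insulin_degradation = phys.hormone_degradation_per_s(
            phys.insulin_survival_per_compartment)
        self.glucagon_degradation = phys.hormone_degradation_per_s(
            phys.glucagon_survival_per_compartment)
        self.oxygen_consumption = phys.oxygen_consumption_mmhg_per_s()
        self.oxygen_body_input = phys.oxygen_body_input_mmhg_per_s()
        self.body = BodyCompartment(volume_l=self.body_volume,
                                    params=self.params)

    # -- initial state -----------------------------------------------------
    def initial_state(self) -> np.ndarray:
        """Reference initial state: uniform metabolites, graded hormones
        and oxygen at their steady sinusoidal profiles."""
        ref = self.params.reference_state
        phys = self.params.physiology
        n = self.n_compartments
        y = np.zeros(n_states(n))
        body = y[body_slice()]
        for name, idx in BLOOD_INDEX.items():
            if name == "oxygen":
                body[idx] = phys.oxygen_inlet_mmhg
            else:
                body[idx] = ref.get(name, 0.0)
        f_ins = phys.insulin_survival_per_compartment
        f_gln = phys.glucagon_survival_per_compartment
        o2 = gradient_oracle(phys.oxygen_inlet_mmhg, "zero-order",
                             (phys.oxygen_inlet_mmhg - phys.oxygen_outlet_mmhg) / n,
                             n)
        ins = gradient_oracle(ref.get("insulin", 0.0), "first-order", f_ins, n)
        gln = gradient_oracle(ref.get("glucagon", 0.0), "first-order", f_gln, n)
        for i in range(n):
            bl = y[blood_slice(i)]
            for name, idx in BLOOD_INDEX.items():
                bl[idx] = ref.get(name, 0.0)
            bl[BLOOD_INDEX["insulin"]] = ins[i]
            bl[BLOOD_INDEX["glucagon"]] = gln[i]
            bl[BLOOD_INDEX["oxygen"]] = o2[i]
            hp = y[hep_slice(i)]
            for j, name in enumerate(HEP_SPECIES):
                hp[j] = ref.get(name, 0.0)
        return y

    def pancreas_rates(self, glucose_body_um: float) -> tuple[float, float]:
        """(insulin, glucagon) secretion in nM/s for a systemic glucose level.

        Insulin secretion rises sigmoidally with glucose, glucagon falls;
        both are bounded by their basal and maximal rates.
        """
        if glucose_body_um < 0:
            raise ValueError("glucose must be >= 0")
        pk = self.params.pancreas
        return (pk.insulin_secretion(glucose_body_um),
                pk.glucagon_secretion(glucose_body_um))


def advection_derivatives(blood_states: np.ndarray, body_state: np.ndarray,
                          flow: float, compartment_volume: float,
                          body_volume: float) -> tuple[np.ndarray, np.ndarray]:
    """Plug-flow advection terms for all transported blood species.

    ``blood_states`` is (N, n_species) ordered periportal->pericentral.
    Compartment 1 is fed by the body pool; compartment N drains into it.
    Returns (d(blood)/dt per compartment, d(body)/dt).
    """
    if flow <= 0:
        raise ValueError("flow must be positive")
    n = blood_states.shape[0]
    if n < 2:
        raise ValueError("need at least 2 compartments")
    d = np.zeros_like(blood_states)
    q_over_v = flow / compartment_volume
    for i in range(n):
        upstream = body_state if i == 0 else blood_states[i - 1]
        d[i] = q_over_v * (upstream - blood_states[i])
    d_body = flow / body_volume * (blood_states[-1] - body_state)
    return d, d_body


def gradient_oracle(c_in: float, mode: str, rate: float, n: int) -> np.ndarray:
    """Closed-form steady-state sinusoidal profile for a degraded species.

    ``zero-order``: compartment i carries c_in - i*rate (rate = drop per
    compartment); ``first-order``: c_in * f^i with per-compartment
    survival fraction f = rate.  These are the exact steady states of the
    advection chain and are used to verify the simulated oxygen and
    hormone gradients.
    """
    if c_in < 0:
        raise ValueError("inlet concentration must be >= 0")
    i = np.arange(1, n + 1, dtype=float)
    if mode == "zero-order":
        prof = c_in - i * rate
        if np.any(prof < 0):
            raise ValueError(
                "zero-order consumption would drive the concentration "
                "negative; inconsistent rate parameter")
        return prof
    if mode == "first-order":
        return c_in * rate ** i
    raise ValueError(f"unknown mode {mode!r}")


def body_derivatives(model: SinusoidModel, body_blood: dict[str, float],
                     t_hours: float = 0.0, scenario=None) -> dict[str, float]:
    """Reference-path derivatives of the body pool from its own processes.

    Includes adipose lipogenesis/lipolysis, gut triglyceride synthesis,
    muscle consumption, pancreatic secretion, hormone clearance, oxygen
    input and the feeding inputs.  Advective exchange with the sinusoid
    is handled separately.
    """
    from .scenarios import Scenario, feeding_input
    scen = scenario if scenario is not None else Scenario.metabolically_healthy()
    d = {name: 0.0 for name in BLOOD_SPECIES}
    rates = model.body.process_rates(body_blood, k_ir=scen.k_ir)
    for name, proc in model.params.body_processes.items():
        for sp, coef in proc.stoichiometry.items():
            d[sp] += coef * rates[name]
    ins_sec, gln_sec = model.pancreas_rates(body_blood["glucose_b"])
    phys = model.params.physiology
    d["insulin"] += ins_sec - phys.body_insulin_clearance_per_s * body_blood["insulin"]
    d["glucagon"] += gln_sec - phys.body_glucagon_clearance_per_s * body_blood["glucagon"]
    d["oxygen"] += model.oxygen_body_input
    if scen.waveform == "cyclic":
        g_in = feeding_input(t_hours, scen.v_input_glucose, scen.cycle_hours)
        f_in = feeding_input(t_hours, scen.v_input_ffa, scen.cycle_hours)
    else:
        g_in, f_in = scen.v_input_glucose, scen.v_input_ffa
    d["glucose_b"] += scen.glucose_input_multiplier * g_in / model.body_volume
    d["ffa_b"] += scen.ffa_input_multiplier * f_in / model.body_volume
    return d
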