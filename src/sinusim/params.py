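"""Parameter file handling.

The whole model is configured from one hierarchical YAML document:
physiology (volumes, flow, oxygen gradient, hormone handling), one block
per hepatic/body process (base rate constant, zonation constant and the
Hill terms of its rate law), pancreatic secretion, feeding composition
and the stored constant-input baseline.  The file shipped in
``sinusim/data/default_params.yaml`` is the calibrated reference set.
"""

from __future__ import annotations

import copy
import importlib.resources as resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import units
from .processes import (ProcessDefinition, build_body_processes,
                        build_processes)


@dataclass
class PhysiologyParams:
    """Geometry, flow and systemic parameters of the sinusoid model."""

    n_compartments: int = 8
    hepatocyte_volume_l: float = 1.5      # total, all compartments
    sinusoid_blood_volume_l: float = 0.2  # total, all compartments
    body_volume_l: float = 10.0           # systemic distribution volume
    blood_flow_l_per_s: float = 0.024
    oxygen_inlet_mmhg: float = 65.0
    oxygen_outlet_mmhg: float = 35.0
    insulin_survival_per_compartment: float = 0.928
    glucagon_survival_per_compartment: float = 0.968
    body_insulin_clearance_per_s: float = 2.0e-3
    body_glucagon_clearance_per_s: float = 1.5e-3
    srebp_clamp_nm: float = 1.0

    @property
    def compartment_blood_volume_l(self) -> float:
        return self.sinusoid_blood_volume_l / self.n_compartments

    @property
    def compartment_hepatocyte_volume_l(self) -> float:
        return self.hepatocyte_volume_l / self.n_compartments

    @property
    def hepatocyte_blood_ratio(self) -> float:
        """Volume ratio scaling cellular rates into local blood rates."""
        return self.hepatocyte_volume_l / self.sinusoid_blood_volume_l

    @property
    def transit_time_s(self) -> float:
        return self.sinusoid_blood_volume_l / self.blood_flow_l_per_s

    def oxygen_consumption_mmhg_per_s(self) -> float:
        """Zero-order per-compartment consumption fixing the 65->35 drop."""
        drop = (self.oxygen_inlet_mmhg - self.oxygen_outlet_mmhg) \
            / self.n_compartments
        return drop * self.blood_flow_l_per_s / self.compartment_blood_volume_l

    def oxygen_body_input_mmhg_per_s(self) -> float:
        """Constant systemic oxygen input restoring the inlet tension."""
        return self.blood_flow_l_per_s \
            * (self.oxygen_inlet_mmhg - self.oxygen_outlet_mmhg) \
            / self.body_volume_l

    def hormone_degradation_per_s(self, survival: float) -> float:
        """First-order sinusoidal degradation rate from a per-compartment
        survival fraction (steady state c_i/c_{i-1} = survival)."""
        q_over_v = self.blood_flow_l_per_s / self.compartment_blood_volume_l
        return q_over_v * (1.0 / survival - 1.0)


@dataclass
class PancreasParams:
    """Sigmoidal glucose-dependent hormone secretion (nM/s, body basis)."""

    insulin_vmax: float
    insulin_K: float
    insulin_n: float
    insulin_basal: float
    glucagon_vmax: float
    glucagon_K: float
    glucagon_n: float
    glucagon_basal: float

    def insulin_secretion(self, glucose_um: float) -> float:
        x = (max(glucose_um, 0.0) / self.insulin_K) ** self.insulin_n
        return self.insulin_basal + self.insulin_vmax * x / (1.0 + x)

    def glucagon_secretion(self, glucose_um: float) -> float:
        x = (max(glucose_um, 0.0) / self.glucagon_K) ** self.glucagon_n
        return self.glucagon_basal + self.glucagon_vmax / (1.0 + x)


@dataclass
class FeedingParams:
    carb_g_per_cycle: float = 78.1
    lipid_g_per_cycle: float = 22.2
    cycle_hours: float = 4.0

    def peak_rates_umol_per_s(self) -> tuple[float, float]:
        """Peak glucose and FFA input rates of the sin^6 waveform.

        The cycle mean of sin^6 is 5/16, so the peak rate delivering a
        target molar amount per cycle is total / (5/16 * cycle seconds).
        """
        seconds = self.cycle_hours * 3600.0
        denom = (5.0 / 16.0) * seconds
        g = units.grams_to_umol(self.carb_g_per_cycle, units.GLUCOSE_MOLAR_MASS)
        f = units.grams_to_umol(self.lipid_g_per_cycle, units.FFA_MOLAR_MASS)
        return g / denom, f / denom


@dataclass
class ModelParams:
    """Everything needed to assemble a :class:`~sinusim.transport.SinusoidModel`."""

    physiology: PhysiologyParams
    pancreas: PancreasParams
    feeding: FeedingParams
    processes: dict[str, ProcessDefinition]
    body_processes: dict[str, ProcessDefinition]
    baseline_inputs: dict[str, float]
    conversion: dict[str, float]
    reference_state: dict[str, float] = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    def copy(self) -> "ModelParams":
        return load_params_dict(copy.deepcopy(self.raw))


def default_params_path() -> Path:
    return Path(resources.files("sinusim") / "data" / "default_params.yaml")


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load a parameter file (the shipped calibrated defaults if None)."""
    p = Path(path) if path is not None else default_params_path()
    with open(p) as fh:
        doc = yaml.safe_load(fh)
    return load_params_dict(doc)


def load_params_dict(doc: dict) -> ModelParams:
    phys = PhysiologyParams(**doc.get("physiology", {}))
    pk = doc["pancreas"]
    pancreas = PancreasParams(
        insulin_vmax=pk["insulin"]["vmax"], insulin_K=pk["insulin"]["K"],
        insulin_n=pk["insulin"]["n"], insulin_basal=pk["insulin"]["basal"],
        glucagon_vmax=pk["glucagon"]["vmax"], glucagon_K=pk["glucagon"]["K"],
        glucagon_n=pk["glucagon"]["n"], glucagon_basal=pk["glucagon"]["basal"])
    feeding = FeedingParams(**doc.get("feeding", {}))
    processes = build_processes(doc["processes"])
    body = build_body_processes(doc["body_processes"])
    return ModelParams(
        physiology=phys, pancreas=pancreas, feeding=feeding,
        processes=processes, body_processes=body,
        baseline_inputs=dict(doc.get("baseline_constant_inputs", {})),
        conversion=dict(doc.get("conversion", {})),
        reference_state=dict(doc.get("reference_state", {})),
        raw=doc)


def save_params(params_doc: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_doc, fh, sort_keys=False)


def state_files_dir() -> Path:
    return Path(resources.files("sinusim") / "data" / "states")


def load_reference_state(name: str) -> np.ndarray | None:
    """Load a stored near-equilibrium state vector for a scenario, if any."""
    import json
    f = state_files_dir() / f"{name}.json"
    if not f.exists():
        return None
    with open(f) as fh:
        return np.asarray(json.load(fh)["y"], dtype=float)


def save_reference_state(name: str, y: np.ndarray, meta: dict | None = None) -> None:
    import json
    d = state_files_dir()
    d.mkdir(parents=True, exist_ok=True)
    doc = {"y": [float(v) for v in y]}
    if meta:
        doc["meta"] = meta
    with open(d / f"{name}.json", "w") as fh:
        json.dump(doc, fh)
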