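"""Local sensitivity protocols.

Two one-at-a-time sweeps quantify how inter-individual variation in
hepatic enzyme activity shapes steatosis:

* the *rate sweep* perturbs each hepatic base rate constant by +-10%
  from the constant-input baseline steady state and reports the change
  in cellular/plasma FFA and triglyceride after 36 hours;
* the *zonation sweep* perturbs each lipid-relevant zonation constant by
  +-0.2 under the NAFLD feeding scenario, re-equilibrates the feeding
  cycle, and reports the periportal:pericentral (compartment 1 :
  compartment 8) triglyceride ratio together with the normalised
  pericentral-minus-periportal response statistic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import _part_paths, get_param, set_param
from .engine import Engine, IntegrationError, run_to_cycle_equilibrium
from .params import ModelParams, load_params_dict
from .scenarios import make_scenario
from .state import BLOOD_INDEX, blood_slice, body_slice, hep_slice, HEP_SPECIES
from .transport import SinusoidModel

#: Hepatic processes swept in the rate protocol, with report labels.
RATE_SWEEP_PROCESSES = {
    "beta_oxidation": "β-oxidation",
    "atp_synthesis": "ATP Synthesis",
    "glycolysis1": "Glycolysis 1 (G6P to G3P)",
    "gluconeogenesis2": "Gluconeogenesis 2 (G3P to G6P)",
    "glycolysis2": "Glycolysis 2 (G3P to Pyr)",
    "gluconeogenesis1": "Gluconeogenesis 1 (Pyr to G3P)",
    "pdh": "Pyruvate Dehydrogenase",
    "tg_exchange": "VLDL Synthesis and Release",
    "tg_synthesis": "Triglyceride Synthesis",
    "ffa_uptake": "FFA Uptake",
    "lipogenesis": "Lipogenesis",
    "glucokinase": "Glucokinase",
    "g6pase": "G6Pase",
    "lipolysis": "Lipolysis",
    "glycogen_synthase": "Glycogen Synthase",
    "glucose_uptake": "Glucose Uptake",
    "glycogen_phosphorylase": "Glycogen Phosphorylase",
}

#: Processes swept in the zonation protocol (lipid metabolism).
ZONATION_SWEEP_PROCESSES = {
    "ffa_uptake": "Fatty Acid Uptake",
    "tg_exchange": "Triglyceride Release as VLDL",
    "pdh": "Acetyl-CoA Synthesis",
    "beta_oxidation": "β-oxidation",
    "glycolysis1": "Glycolysis 1 (G6P -> GADP)",
    "lipogenesis": "Lipogenesis",
    "gluconeogenesis2": "Gluconeogenesis (GADP -> G6P)",
    "gluconeogenesis1": "Gluconeogenesis 1 (Pyr -> GADP)",
    "glycolysis2": "Glycolysis 2 (GADP -> Pyr)",
    "tg_synthesis": "Triglyceride Synthesis",
    "glucokinase": "Glucokinase",
    "g6pase": "G6Pase",
    "lipolysis": "Lipolysis",
}


@dataclass
class SensitivityReport:
    """Tabular outcome of one sweep protocol."""

    kind: str                  # 'rate' | 'zonation'
    delta: float
    table: pd.DataFrame
    baseline: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _scaled_doc(params: ModelParams, process: str, factor: float) -> dict:
    """Copy of the raw document with every vb of one process scaled."""
    doc = copy.deepcopy(params.raw)
    paths = _part_paths(doc)
    for part_name, path in paths.items():
        if part_name == process or part_name.startswith(process + "::"):
            set_param(doc, path, float(get_param(doc, path)) * factor)
    return doc


def _kn_doc(params: ModelParams, process: str, dk: float) -> dict | None:
    """Copy of the raw document with one zonation constant shifted by dk.

    Returns None when the shifted constant would leave the admissible
    range |k_n| < 1 (which would give a negative rate constant).
    """
    from .processes import ZONATION_RATIOS
    from .zonation import kn_from_ratio
    doc = copy.deepcopy(params.raw)
    base = params.processes[process].k_n
    new = base + dk
    if abs(new) >= 1:
        return None
    doc["processes"][process]["kn"] = float(new)
    return doc


def _lipid_state(y: np.ndarray, n: int) -> dict[str, float]:
    ffa_i = HEP_SPECIES.index("ffa_c")
    tg_i = HEP_SPECIES.index("tg_c")
    return {
        "ffa_c": float(np.mean([y[hep_slice(i)][ffa_i] for i in range(n)])),
        "tg_c": float(np.mean([y[hep_slice(i)][tg_i] for i in range(n)])),
        "ffa_b": float(y[body_slice()][BLOOD_INDEX["ffa_b"]]),
        "tg_b": float(y[body_slice()][BLOOD_INDEX["tg_b"]]),
    }


def _run_36h(doc: dict, y0: np.ndarray, horizon_s: float, dt: float) -> dict:
    p = load_params_dict(doc)
    model = SinusoidModel(p)
    scen = make_scenario("constant_baseline", baseline_inputs=p.baseline_inputs,
                         body_volume_l=model.body_volume)
    eng = Engine(model, scen)
    res = eng.run(np.array(y0, dtype=float), 0.0, horizon_s, dt,
                  sample_every=10 ** 9)
    return _lipid_state(res.end_state, model.n_compartments)


def rate_sweep(params: ModelParams, baseline_state: np.ndarray,
               delta: float = 0.10, horizon_h: float = 36.0,
               dt: float = 0.2, processes: list[str] | None = None,
               drift_tolerance: float = 1e-3) -> SensitivityReport:
    """±delta rate-constant sweep from the constant-input steady state.

    Each hepatic process is run twice (v_b x (1+delta) and x (1-delta))
    for ``horizon_h`` hours from the same initial state; the report holds
    the change (at the horizon, not time-averaged) of cellular and plasma
    FFA and triglyceride relative to the unperturbed control.  Aborts if
    the provided baseline drifts by more than ``drift_tolerance``
    (relative) over a one-hour control run.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    names = processes or list(RATE_SWEEP_PROCESSES)
    horizon_s = horizon_h * 3600.0
    # steady-state guard
    ctrl_1h = _run_36h(params.raw, baseline_state, 3600.0, dt)
    base0 = _lipid_state(np.asarray(baseline_state),
                         params.physiology.n_compartments)
    drift = max(abs(ctrl_1h[k] - base0[k]) / (abs(base0[k]) + 1e-9)
                for k in base0)
    if drift > drift_tolerance:
        raise IntegrationError(
            f"baseline is not at steady state (relative drift {drift:.2e} "
            f"over 1 h control run exceeds {drift_tolerance})")
    control = _run_36h(params.raw, baseline_state, horizon_s, dt)
    rows = []
    for name in names:
        row = {"process": RATE_SWEEP_PROCESSES.get(name, name),
               "process_key": name}
        for sign, label in ((+1, "increased"), (-1, "reduced")):
            out = _run_36h(_scaled_doc(params, name, 1.0 + sign * delta),
                           baseline_state, horizon_s, dt)
            row[f"d_ffa_c_{label}"] = out["ffa_c"] - control["ffa_c"]
            row[f"d_tg_c_{label}"] = out["tg_c"] - control["tg_c"]
            row[f"d_ffa_b_{label}"] = out["ffa_b"] - control["ffa_b"]
            row[f"d_tg_b_{label}"] = out["tg_b"] - control["tg_b"]
        rows.append(row)
    table = pd.DataFrame(rows)
    return SensitivityReport(kind="rate", delta=delta, table=table,
                             baseline=control)


def zonation_sweep(params: ModelParams, delta: float = 0.2,
                   scenario_preset: str = "NAFLD", tol: float = 2e-4,
                   dt: float = 0.2, max_cycles: int = 400,
                   y0: np.ndarray | None = None,
                   processes: list[str] | None = None) -> SensitivityReport:
    """±delta zonation-constant sweep at feeding-cycle equilibrium.

    For each lipid-relevant process the zonation constant is shifted by
    ±delta, the NAFLD feeding cycle is re-equilibrated, and the
    compartment-1 : compartment-8 cycle-average triglyceride ratio is
    reported along with (ΔTG_pc - ΔTG_pp)/TG_av between the two shifted
    runs.  A shift that would leave |k_n| < 1 is skipped with a warning
    row.
    """
    names = processes or list(ZONATION_SWEEP_PROCESSES)
    tg_i = HEP_SPECIES.index("tg_c")

    def equilibrium_tg(doc) -> np.ndarray:
        p = load_params_dict(doc)
        model = SinusoidModel(p)
        scen = make_scenario(scenario_preset, feeding=p.feeding,
                             baseline_inputs=p.baseline_inputs,
                             body_volume_l=model.body_volume)
        res = run_to_cycle_equilibrium(model, scen, tol=tol, dt=dt,
                                       equilibration_dt=dt,
                                       max_cycles=max_cycles, y0=y0)
        return res.hep_avg("tg_c")

    base_tg = equilibrium_tg(params.raw)
    base_ratio = float(base_tg[-1] / base_tg[0])
    rows = []
    for name in names:
        row = {"process": ZONATION_SWEEP_PROCESSES.get(name, name),
               "process_key": name, "baseline_ratio": base_ratio}
        shifted = {}
        for sign, label in ((+1, "more_periportal"), (-1, "more_pericentral")):
            doc = _kn_doc(params, name, sign * delta)
            if doc is None:
                row[f"ratio_{label}"] = np.nan
                row["warning"] = "|kn +- delta| >= 1; skipped"
                continue
            tg = equilibrium_tg(doc)
            shifted[sign] = tg
            row[f"ratio_{label}"] = float(tg[-1] / tg[0])
        if +1 in shifted and -1 in shifted:
            tg_av = float(np.mean(base_tg))
            d_pc = shifted[-1][-1] - shifted[+1][-1]
            d_pp = shifted[-1][0] - shifted[+1][0]
            row["normalized_pc_pp_difference"] = float((d_pc - d_pp) / tg_av)
        rows.append(row)
    table = pd.DataFrame(rows)
    return SensitivityReport(kind="zonation", delta=delta, table=table,
                             baseline={"ratio": base_ratio,
                                       "tg_profile": base_tg})
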