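"""Flattening of the process network into kernel-ready arrays.

The compiled integrator consumes the model as flat CSR-style arrays:
one row per unidirectional process part, with its stoichiometry, rate-law
terms and per-compartment zonation multipliers.  Sinusoidal hormone
degradation and oxygen consumption are appended as blood-basis parts so
the kernel treats them uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ratelaws import TermKind
from .state import SPECIES_CODE, N_HEP


@dataclass
class PackedNetwork:
    """Arrays mirroring the process network for the compiled kernel."""

    # hepatic + sinusoid-blood parts
    part_names: list[str]
    part_process: np.ndarray      # lumped process index per part
    part_sign: np.ndarray
    process_names: list[str]
    vb: np.ndarray
    basis: np.ndarray             # 0 = hepatocyte basis, 1 = blood basis
    srebp: np.ndarray
    m: np.ndarray                 # (P, N) zonation multipliers
    s_ptr: np.ndarray
    s_idx: np.ndarray
    s_coef: np.ndarray
    t_ptr: np.ndarray
    t_kind: np.ndarray
    t_sp: np.ndarray
    t_K: np.ndarray
    t_n: np.ndarray
    t_base: np.ndarray
    t_amp: np.ndarray
    # body parts
    body_part_names: list[str]
    body_part_process: np.ndarray
    body_part_sign: np.ndarray
    body_process_names: list[str]
    b_vb: np.ndarray
    bs_ptr: np.ndarray
    bs_idx: np.ndarray
    bs_coef: np.ndarray
    bt_ptr: np.ndarray
    bt_kind: np.ndarray
    bt_sp: np.ndarray
    bt_K: np.ndarray
    bt_n: np.ndarray
    bt_base: np.ndarray
    bt_amp: np.ndarray

    def kernel_args(self) -> tuple:
        return (self.vb, self.basis, self.srebp, self.m,
                self.s_ptr, self.s_idx, self.s_coef,
                self.t_ptr, self.t_kind, self.t_sp, self.t_K, self.t_n,
                self.t_base, self.t_amp,
                self.b_vb,
                self.bs_ptr, self.bs_idx, self.bs_coef,
                self.bt_ptr, self.bt_kind, self.bt_sp, self.bt_K, self.bt_n,
                self.bt_base, self.bt_amp)


def _pack_parts(entries, species_offset: int = 0):
    """entries: list of (part_name, proc_idx, sign, vb, basis, srebp, terms, stoich)."""
    names, proc_idx, signs, vbs, bases, srebps = [], [], [], [], [], []
    s_ptr, s_idx, s_coef = [0], [], []
    t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp = [0], [], [], [], [], [], []
    for (name, pi, sign, vb, basis, srebp, terms, stoich) in entries:
        names.append(name)
        proc_idx.append(pi)
        signs.append(sign)
        vbs.append(vb)
        bases.append(basis)
        srebps.append(srebp)
        for sp, coef in stoich.items():
            s_idx.append(SPECIES_CODE[sp] - species_offset)
            s_coef.append(coef)
        s_ptr.append(len(s_idx))
        for t in terms:
            t_kind.append(int(t.kind))
            t_sp.append(-1 if t.species is None
                        else SPECIES_CODE[t.species] - species_offset)
            t_K.append(t.K)
            t_n.append(t.n)
            t_base.append(t.base)
            t_amp.append(t.amp)
        t_ptr.append(len(t_kind))
    return (names, np.array(proc_idx, dtype=np.int64),
            np.array(signs, dtype=np.float64),
            np.array(vbs, dtype=np.float64),
            np.array(bases, dtype=np.int64),
            np.array(srebps, dtype=np.int64),
            np.array(s_ptr, dtype=np.int64), np.array(s_idx, dtype=np.int64),
            np.array(s_coef, dtype=np.float64),
            np.array(t_ptr, dtype=np.int64), np.array(t_kind, dtype=np.int64),
            np.array(t_sp, dtype=np.int64), np.array(t_K, dtype=np.float64),
            np.array(t_n, dtype=np.float64), np.array(t_base, dtype=np.float64),
            np.array(t_amp, dtype=np.float64))


def pack_network(model) -> PackedNetwork:
    """Flatten a :class:`~sinusim.transport.SinusoidModel` for the kernel."""
    from .ratelaws import RateTerm

    n = model.n_compartments
    entries = []
    m_rows = []
    process_names = list(model.params.processes)
    for pi, (pname, proc) in enumerate(model.params.processes.items()):
        mult = model.zonation[pname].multipliers
        for part in proc.parts:
            entries.append((part.name, pi, part.sign, part.vb, 0,
                            int(proc.srebp_target), part.terms,
                            part.stoichiometry))
            m_rows.append(mult)

    # sinusoid blood housekeeping: first-order hormone degradation and
    # zero-order oxygen consumption
    house = [
        ("insulin_degradation", model.insulin_degradation,
         (RateTerm(TermKind.LINEAR, "insulin", 1.0, 1.0),), {"insulin": -1.0}),
        ("glucagon_degradation", model.glucagon_degradation,
         (RateTerm(TermKind.LINEAR, "glucagon", 1.0, 1.0),), {"glucagon": -1.0}),
        ("oxygen_consumption", model.oxygen_consumption, (), {"oxygen": -1.0}),
    ]
    for name, vb, terms, stoich in house:
        process_names.append(name)
        entries.append((name, len(process_names) - 1, 1.0, vb, 1, 0, terms,
                        stoich))
        m_rows.append(np.ones(n))

    (names, proc_idx, signs, vbs, bases, srebps, s_ptr, s_idx, s_coef,
     t_ptr, t_kind, t_sp, t_K, t_n, t_base, t_amp) = _pack_parts(entries)

    bentries = []
    body_process_names = list(model.params.body_processes)
    for pi, (pname, proc) in enumerate(model.params.body_processes.items()):
        for part in proc.parts:
            bentries.append((part.name, pi, part.sign, part.vb, 2, 0,
                             part.terms, part.stoichiometry))
    (bnames, bproc_idx, bsigns, bvbs, _, _, bs_ptr, bs_idx, bs_coef,
     bt_ptr, bt_kind, bt_sp, bt_K, bt_n, bt_base, bt_amp) = _pack_parts(
        bentries, species_offset=N_HEP)

    return PackedNetwork(
        part_names=names, part_process=proc_idx, part_sign=signs,
        process_names=process_names, vb=vbs, basis=bases, srebp=srebps,
        m=np.ascontiguousarray(np.vstack(m_rows)),
        s_ptr=s_ptr, s_idx=s_idx, s_coef=s_coef,
        t_ptr=t_ptr, t_kind=t_kind, t_sp=t_sp, t_K=t_K, t_n=t_n,
        t_base=t_base, t_amp=t_amp,
        body_part_names=bnames, body_part_process=bproc_idx,
        body_part_sign=bsigns, body_process_names=body_process_names,
        b_vb=bvbs, bs_ptr=bs_ptr, bs_idx=bs_idx, bs_coef=bs_coef,
        bt_ptr=bt_ptr, bt_kind=bt_kind, bt_sp=bt_sp, bt_K=bt_K, bt_n=bt_n,
        bt_base=bt_base, bt_amp=bt_amp)


def phys_vector(model) -> np.ndarray:
    pk = model.params.pancreas
    phys = model.params.physiology
    return np.array([
        float(model.n_compartments),
        model.flow,
        model.compartment_blood_volume,
        model.compartment_hep_volume,
        model.body_volume,
        model.hepatocyte_blood_ratio,
        pk.insulin_vmax, pk.insulin_K, pk.insulin_n, pk.insulin_basal,
        pk.glucagon_vmax, pk.glucagon_K, pk.glucagon_n, pk.glucagon_basal,
        phys.body_insulin_clearance_per_s,
        phys.body_glucagon_clearance_per_s,
        model.oxygen_body_input,
        phys.srebp_clamp_nm,
    ])


def scenario_vector(scen) -> np.ndarray:
    return np.array([
        scen.k_ir,
        1.0 if scen.srebp1c else 0.0,
        scen.v_input_glucose,
        scen.v_input_ffa,
        1.0 if scen.waveform == "cyclic" else 0.0,
        scen.cycle_hours * 3600.0,
        scen.glucose_input_multiplier,
        scen.ffa_input_multiplier,
    ])
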