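"""Process definitions: stoichiometry and zonated rate laws.

The hepatic reaction network couples glycogen storage, two-stage
glycolysis/gluconeogenesis, pyruvate oxidation, de novo lipogenesis,
beta-oxidation, triglyceride cycling and the nucleotide machinery of one
hepatocyte compartment.  Stoichiometries are fixed; rate constants,
zonation constants and Hill terms come from the parameter file.

Reversible processes (the membrane transports, adenylate kinase and the
inorganic-phosphate regulator) are represented internally as pairs of
saturable unidirectional parts; the public, lumped process exposes their
signed net rate and the canonical stoichiometry of its forward direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ratelaws import RateTerm, TermKind, term_from_config
from .state import HEP_SPECIES, BLOOD_SPECIES, N_HEP, SPECIES_CODE
from .zonation import kn_from_ratio

# ---------------------------------------------------------------------------
# Stoichiometry of the hepatic processes (forward direction).
# Coefficients are signed per mole of process turnover; blood-side species
# are volume-rescaled during assembly.  Fractional ATP coefficients lump
# the indirect NADH-derived phosphorylations into a single step.
# ---------------------------------------------------------------------------
HEPATIC_STOICHIOMETRY: dict[str, dict[str, float]] = {
    "glucose_uptake":        {"glucose_b": -1, "glucose_c": 1},
    "glucokinase":           {"glucose_c": -1, "atp": -1, "g6p": 1, "adp": 1},
    "g6pase":                {"g6p": -1, "glucose_c": 1, "pi": 1},
    "glycogen_synthase":     {"g6p": -1, "utp": -1, "glycogen": 1, "udp": 1, "pi": 2},
    "glycogen_phosphorylase": {"glycogen": -1, "pi": -1, "g6p": 1},
    "glycolysis1":           {"g6p": -1, "atp": -1, "g3p_gadp": 2, "adp": 1},
    "glycolysis2":           {"g3p_gadp": -1, "pyr_lac": 1,
                              "atp": 3.25, "adp": -3.25, "pi": -2.25},
    "gluconeogenesis1":      {"pyr_lac": -1, "g3p_gadp": 1, "atp": -2, "adp": 2,
                              "gtp": -1, "gdp": 1, "pi": 2},
    "gluconeogenesis2":      {"g3p_gadp": -2, "g6p": 1, "pi": 1},
    "pdh":                   {"pyr_lac": -1, "acetyl_coa": 1,
                              "atp": 2.5, "adp": -2.5, "pi": -2.5},
    "beta_oxidation":        {"ffa_c": -1, "acetyl_coa": 8, "atp": -2,
                              "adp": 1, "amp": 1, "pi": 1},
    "atp_synthesis":         {"acetyl_coa": -1, "adp": -12, "pi": -12, "atp": 12},
    "ndk_g":                 {"gdp": -1, "atp": -1, "gtp": 1, "adp": 1},
    "ndk_u":                 {"udp": -1, "atp": -1, "utp": 1, "adp": 1},
    "adenylate_kinase":      {"atp": -1, "amp": -1, "adp": 2},
    "atp_use":               {"atp": -1, "adp": 1, "pi": 1},
    "pi_regulation":         {"pi": -1},
    "lipogenesis":           {"acetyl_coa": -8, "atp": -7, "ffa_c": 1,
                              "adp": 7, "pi": 7},
    "tg_synthesis":          {"ffa_c": -3, "g3p_gadp": -1, "atp": -3,
                              "tg_c": 1, "amp": 3, "pi": 7},
    "lipolysis":             {"tg_c": -1, "glycerol_c": 1, "ffa_c": 3},
    "glycerol_kinase":       {"glycerol_c": -1, "atp": -1, "g3p_gadp": 1, "adp": 1},
    "lactate_exchange":      {"lactate_b": -1, "pyr_lac": 1},
    "ffa_uptake":            {"ffa_b": -1, "ffa_c": 1},
    "tg_exchange":           {"tg_b": -1, "tg_c": 1},
    "glycerol_exchange":     {"glycerol_b": -1, "glycerol_c": 1},
}

#: Sinusoid blood-side housekeeping (hormone degradation, oxygen use).
BLOOD_STOICHIOMETRY: dict[str, dict[str, float]] = {
    "insulin_degradation":  {"insulin": -1},
    "glucagon_degradation": {"glucagon": -1},
    "oxygen_consumption":   {"oxygen": -1},
}

#: Systemic (body-pool) processes; glucose in, FFA out of adipose de novo
#: synthesis, plasma-TG turnover through adipose lipolysis and gut
#: re-esterification, and bulk consumption by muscle and other tissues.
BODY_STOICHIOMETRY: dict[str, dict[str, float]] = {
    "adipose_lipogenesis":  {"glucose_b": -4, "ffa_b": 1},
    "adipose_lipolysis":    {"tg_b": -1, "ffa_b": 3, "glycerol_b": 1},
    "gut_tg_synthesis":     {"ffa_b": -3, "glycerol_b": -1, "tg_b": 1},
    "glucose_consumption":  {"glucose_b": -1},
    "ffa_consumption":      {"ffa_b": -1},
    # closure terms: peripheral lactate/glycerol turnover
    "lactate_production":   {"glucose_b": -0.5, "lactate_b": 1},
    "lactate_consumption":  {"lactate_b": -1},
    "glycerol_consumption": {"glycerol_b": -1},
}

#: Periportal:pericentral rate-constant ratios of the hepatic processes.
ZONATION_RATIOS: dict[str, tuple[float, float]] = {
    "glucose_uptake": (1, 1),
    "glucokinase": (1, 2.5),
    "g6pase": (1.9, 1),
    "glycogen_synthase": (3, 1),
    "glycogen_phosphorylase": (1, 1),
    "glycolysis1": (1, 1),
    "glycolysis2": (1, 2.1),
    "gluconeogenesis1": (2.4, 1),
    "gluconeogenesis2": (1.75, 1),
    "pdh": (1, 1),
    "beta_oxidation": (1.6, 1),
    "atp_synthesis": (1.5, 1),
    "ndk_g": (1, 1),
    "ndk_u": (1, 1),
    "adenylate_kinase": (1, 1),
    "atp_use": (1, 1),
    "pi_regulation": (1, 1),
    "lipogenesis": (1, 1.6),
    "tg_synthesis": (1, 1),
    "lipolysis": (1, 1),
    "glycerol_kinase": (1, 1),
    "lactate_exchange": (1, 1),
    "ffa_uptake": (1.5, 1),
    "tg_exchange": (1, 1),
    "glycerol_exchange": (1, 1),
}

#: Hormone reception varies along the sinusoid as well: insulin reception
#: is pericentral-dominant (1:1.35), glucagon periportal (1.35:1).
INSULIN_RECEPTION_KN = kn_from_ratio(1, 1.35)
GLUCAGON_RECEPTION_KN = kn_from_ratio(1.35, 1)

#: Processes whose insulin stimulation is clamped by SREBP-1c
#: over-expression in the NAFLD scenario.
SREBP_TARGETS = ("lipogenesis", "tg_synthesis")

_VALID_SPECIES = set(HEP_SPECIES) | set(BLOOD_SPECIES)


@dataclass(frozen=True)
class ProcessPart:
    """One unidirectional component of a (possibly reversible) process."""

    name: str
    sign: float                       # +1 forward, -1 backward
    vb: float                         # base rate constant, uM/s
    terms: tuple[RateTerm, ...]
    stoichiometry: dict[str, float]   # signed, already includes `sign`
    basis: str = "hep"                # 'hep' | 'blood' | 'body'

    def rate(self, concentrations: dict[str, float], m_i: float = 1.0,
             insulin_eff: float = 0.0, glucagon_eff: float = 0.0) -> float:
        """Evaluate v_b * m_i * prod(factors) for given concentrations."""
        r = self.vb * m_i
        for t in self.terms:
            if t.species is not None:
                try:
                    c = concentrations[t.species]
                except KeyError as e:
                    raise KeyError(
                        f"rate law of {self.name} references unknown species "
                        f"{t.species!r}") from e
            else:
                c = None
            r *= t.evaluate(c, insulin_eff=insulin_eff,
                            glucagon_eff=glucagon_eff,
                            oxygen=concentrations.get("oxygen", 0.0))
        return r


@dataclass
class ProcessDefinition:
    """A named model process: stoichiometry plus a zonated Hill rate law.

    Reversible processes carry two or more :class:`ProcessPart`s whose
    net signed rate is the reported process rate.
    """

    name: str
    stoichiometry: dict[str, float]
    k_n: float
    parts: list[ProcessPart]
    basis: str = "hep"
    srebp_target: bool = False
    reversible: bool = False
    oxygen_K: float | None = None

    def __post_init__(self):
        if abs(self.k_n) >= 1:
            raise ValueError(f"{self.name}: |k_n| must be < 1, got {self.k_n}")
        for s in self.stoichiometry:
            if s not in _VALID_SPECIES:
                raise ValueError(f"{self.name}: unknown species {s!r}")

    @property
    def vb(self) -> float:
        """Base rate constant of the forward (dominant) part."""
        return self.parts[0].vb

    def net_rate(self, concentrations: dict[str, float], m_i: float = 1.0,
                 insulin_eff: float = 0.0, glucagon_eff: float = 0.0) -> float:
        return sum(p.sign * p.rate(concentrations, m_i, insulin_eff,
                                   glucagon_eff) for p in self.parts)

    def scale_vb(self, factor: float) -> None:
        """Multiply every part's base rate constant (sensitivity sweeps)."""
        self.parts = [ProcessPart(p.name, p.sign, p.vb * factor, p.terms,
                                  p.stoichiometry, p.basis)
                      for p in self.parts]


def effective_hormones(insulin: float, glucagon: float, k_ir: float,
                       srebp1c: bool, process: "ProcessDefinition | str",
                       reception_multiplier_insulin: float = 1.0,
                       reception_multiplier_glucagon: float = 1.0,
                       srebp_clamp_nm: float = 1.0) -> tuple[float, float]:
    """Hormone concentrations as sensed by one hepatic process.

    Insulin resistance scales the detected insulin by ``k_ir`` (< 1 in
    disease); SREBP-1c over-expression clamps the insulin seen by
    lipogenesis and triglyceride synthesis to a high constant level
    (1 nM by default) regardless of resistance.  Glucagon detection is
    unaffected by insulin resistance.  Receptor zonation enters as
    per-compartment multipliers on the sensed concentrations.
    """
    if not 0.0 < k_ir <= 1.0:
        raise ValueError(f"K_IR must be in (0, 1], got {k_ir}")
    if insulin < 0 or glucagon < 0:
        raise ValueError("hormone concentrations must be >= 0")
    name = process.name if isinstance(process, ProcessDefinition) else process
    if srebp1c and name in SREBP_TARGETS:
        insulin_eff = srebp_clamp_nm
    else:
        insulin_eff = k_ir * insulin * reception_multiplier_insulin
    return insulin_eff, glucagon * reception_multiplier_glucagon


def process_rate(process: ProcessDefinition, hep, blood,
                 compartment_multiplier: float = 1.0, k_ir: float = 1.0,
                 srebp1c: bool = False,
                 reception_multiplier_insulin: float = 1.0,
                 reception_multiplier_glucagon: float = 1.0) -> float:
    """Net rate of a process for given hepatocyte and blood states (uM/s).

    This is the readable reference path used by the verification suite;
    production simulations evaluate the identical law in the compiled
    kernel.
    """
    conc = {}
    if hep is not None:
        conc.update({n: getattr(hep, n) for n in HEP_SPECIES})
    if blood is not None:
        conc.update({n: getattr(blood, n) for n in BLOOD_SPECIES})
    ins_eff, gln_eff = effective_hormones(
        conc.get("insulin", 0.0), conc.get("glucagon", 0.0), k_ir, srebp1c,
        process, reception_multiplier_insulin, reception_multiplier_glucagon)
    return process.net_rate(conc, compartment_multiplier, ins_eff, gln_eff)


def hepatic_stoichiometric_matrix(names: list[str] | None = None) -> np.ndarray:
    """The 17 x P signed stoichiometric matrix of the hepatocyte network."""
    if names is None:
        names = list(HEPATIC_STOICHIOMETRY)
    S = np.zeros((N_HEP, len(names)))
    for j, name in enumerate(names):
        for sp, coef in HEPATIC_STOICHIOMETRY[name].items():
            i = SPECIES_CODE[sp]
            if i < N_HEP:
                S[i, j] = coef
    return S


def hepatic_derivatives(rates: dict[str, float]) -> np.ndarray:
    """d(hepatocyte state)/dt from a full set of net process rates (uM/s).

    Raises
    ------
    KeyError
        If any hepatic process rate is missing.
    """
    missing = [n for n in HEPATIC_STOICHIOMETRY if n not in rates]
    if missing:
        raise KeyError(f"missing process rates: {missing}")
    names = list(HEPATIC_STOICHIOMETRY)
    S = hepatic_stoichiometric_matrix(names)
    r = np.array([rates[n] for n in names])
    return S @ r


def _parts_from_config(name: str, cfg: dict, stoich: dict[str, float],
                       basis: str) -> tuple[list[ProcessPart], bool]:
    def mk(suffix: str, sign: float, sub: dict) -> ProcessPart:
        terms = tuple(term_from_config(t) for t in sub.get("terms", []))
        st = {s: sign * c for s, c in stoich.items()}
        return ProcessPart(name=f"{name}{suffix}", sign=sign,
                           vb=float(sub["vb"]), terms=terms,
                           stoichiometry=st, basis=basis)

    if "parts" in cfg:
        parts = [mk(f"::{p['id']}", float(p.get("sign", 1)), p)
                 for p in cfg["parts"]]
        reversible = any(p.sign < 0 for p in parts)
    elif "forward" in cfg:
        parts = [mk("::fwd", 1.0, cfg["forward"]),
                 mk("::bwd", -1.0, cfg["backward"])]
        reversible = True
    else:
        parts = [mk("", 1.0, cfg)]
        reversible = False
    return parts, reversible


def build_processes(process_cfg: dict) -> dict[str, ProcessDefinition]:
    """Construct the full hepatic process set from the parameter file."""
    out: dict[str, ProcessDefinition] = {}
    for name, stoich in HEPATIC_STOICHIOMETRY.items():
        if name not in process_cfg:
            raise ValueError(f"parameter file missing process {name!r}")
        cfg = process_cfg[name]
        pp, pc = ZONATION_RATIOS[name]
        k_n = float(cfg.get("kn", kn_from_ratio(pp, pc)))
        parts, reversible = _parts_from_config(name, cfg, stoich, "hep")
        ox = [t for p in parts for t in p.terms if t.kind == TermKind.OXYGEN]
        out[name] = ProcessDefinition(
            name=name, stoichiometry=dict(stoich), k_n=k_n, parts=parts,
            basis="hep", srebp_target=name in SREBP_TARGETS,
            reversible=reversible, oxygen_K=ox[0].K if ox else None)
    return out


def build_body_processes(body_cfg: dict) -> dict[str, ProcessDefinition]:
    out: dict[str, ProcessDefinition] = {}
    for name, stoich in BODY_STOICHIOMETRY.items():
        if name not in body_cfg:
            raise ValueError(f"parameter file missing body process {name!r}")
        parts, reversible = _parts_from_config(name, body_cfg[name], stoich,
                                               "body")
        out[name] = ProcessDefinition(name=name, stoichiometry=dict(stoich),
                                      k_n=0.0, parts=parts, basis="body",
                                      reversible=reversible)
    return out
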