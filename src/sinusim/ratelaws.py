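"""Hill-form rate laws.

Every process rate in the model is a product

    R = v_b * m_i * prod(factors)

where ``v_b`` is the zone-independent base rate constant, ``m_i`` the
zonation multiplier for compartment ``i`` and each factor is a
dimensionless Hill term in [0, 1] (or, for hormone factors, an affine
map ``base + amp * hill`` of one).  Substrate dependences, allosteric
modifiers, hormone sensitivities and the oxygen dependence of oxidative
phosphorylation all share this form.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum


class TermKind(IntEnum):
    """Factor kinds; integer values are shared with the compiled kernel."""

    SUBSTRATE = 0        # hill activation on a substrate species
    ACTIVATION = 1       # allosteric activation
    INHIBITION = 2       # allosteric inhibition
    LINEAR = 3           # c / K (first-order removal)
    INSULIN_ACT = 4      # base + amp * act(insulin_eff)
    INSULIN_INH = 5      # base + amp * inh(insulin_eff)
    GLUCAGON_ACT = 6
    GLUCAGON_INH = 7
    OXYGEN = 8           # hill activation on local oxygen tension


HORMONE_KINDS = (TermKind.INSULIN_ACT, TermKind.INSULIN_INH,
                 TermKind.GLUCAGON_ACT, TermKind.GLUCAGON_INH)
INSULIN_KINDS = (TermKind.INSULIN_ACT, TermKind.INSULIN_INH)


def hill_term(c: float, K: float, n: float, mode: str = "activation") -> float:
    """Dimensionless Hill factor in [0, 1].

    ``activation`` returns c^n / (K^n + c^n); ``inhibition`` returns
    K^n / (K^n + c^n).

    Parameters
    ----------
    c : concentration (>= 0)
    K : half-saturation constant (> 0)
    n : Hill exponent (> 0)
    """
    if K <= 0 or n <= 0:
        raise ValueError(f"Hill constants must be positive (K={K}, n={n})")
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    cn = (c / K) ** n
    if mode == "activation":
        return cn / (1.0 + cn)
    if mode == "inhibition":
        return 1.0 / (1.0 + cn)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class RateTerm:
    """One multiplicative factor of a process rate law.

    ``species`` is the sensed species name for concentration-dependent
    kinds and ``None`` for hormone/oxygen kinds (which sense the local
    effective hormone or oxygen).  ``base``/``amp`` shape hormone factors
    as ``base + amp * hill``; they are fixed at 0/1 for plain Hill terms.
    """

    kind: TermKind
    species: str | None
    K: float
    n: float
    base: float = 0.0
    amp: float = 1.0

    def __post_init__(self):
        if self.K <= 0 or self.n <= 0:
            raise ValueError(f"invalid Hill constants in term {self}")
        if self.base < 0 or self.amp < 0:
            raise ValueError("hormone factor base/amp must be >= 0")

    def evaluate(self, c: float | None = None, insulin_eff: float = 0.0,
                 glucagon_eff: float = 0.0, oxygen: float = 0.0) -> float:
        k = self.kind
        if k in (TermKind.SUBSTRATE, TermKind.ACTIVATION):
            return hill_term(c, self.K, self.n, "activation")
        if k == TermKind.INHIBITION:
            return hill_term(c, self.K, self.n, "inhibition")
        if k == TermKind.LINEAR:
            return c / self.K
        if k == TermKind.INSULIN_ACT:
            return self.base + self.amp * hill_term(insulin_eff, self.K, self.n)
        if k == TermKind.INSULIN_INH:
            return self.base + self.amp * hill_term(insulin_eff, self.K, self.n,
                                                    "inhibition")
        if k == TermKind.GLUCAGON_ACT:
            return self.base + self.amp * hill_term(glucagon_eff, self.K, self.n)
        if k == TermKind.GLUCAGON_INH:
            return self.base + self.amp * hill_term(glucagon_eff, self.K, self.n,
                                                    "inhibition")
        if k == TermKind.OXYGEN:
            return hill_term(oxygen, self.K, self.n)
        raise ValueError(f"unknown term kind {k}")


_KIND_NAMES = {
    "sub": TermKind.SUBSTRATE,
    "act": TermKind.ACTIVATION,
    "inh": TermKind.INHIBITION,
    "linear": TermKind.LINEAR,
    "insulin_act": TermKind.INSULIN_ACT,
    "insulin_inh": TermKind.INSULIN_INH,
    "glucagon_act": TermKind.GLUCAGON_ACT,
    "glucagon_inh": TermKind.GLUCAGON_INH,
    "oxygen": TermKind.OXYGEN,
}


def term_from_config(cfg: dict) -> RateTerm:
    """Build a :class:`RateTerm` from one parameter-file entry."""
    try:
        kind = _KIND_NAMES[cfg["kind"]]
    except KeyError as e:
        raise ValueError(f"unknown rate-law term kind in {cfg}") from e
    return RateTerm(kind=kind, species=cfg.get("species"),
                    K=float(cfg["K"]), n=float(cfg.get("n", 1.0)),
                    base=float(cfg.get("base", 0.0)),
                    amp=float(cfg.get("amp", 1.0)))
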