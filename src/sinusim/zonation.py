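"""Zonation of enzyme expression along the porto-central axis.

Hepatocyte enzyme activity varies continuously from the periportal inlet
(compartment 1) to the pericentral outlet (compartment N).  Each process
carries a dimensionless zonation constant ``k_n``; the zone-independent
base rate constant ``v_b`` is scaled in compartment ``i`` by

    m_i = 1 + k_n * x_i,        x_i = 1 - 2*(i-1)/(N-1)

so that ``x`` runs linearly from +1 (periportal) to -1 (pericentral).
Positive ``k_n`` means periportal expression.  The endpoint activity ratio
is (1+k_n)/(1-k_n) and the sinusoid mean of ``m_i`` is exactly 1, i.e.
``v_b`` is the sinusoid-average rate constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def kn_from_ratio(pp: float, pc: float) -> float:
    """Zonation constant reproducing a periportal:pericentral activity ratio.

    ``pp:pc`` is the ratio of endpoint rate constants, e.g. glucokinase is
    quoted as 1:2.5 (pericentral-dominant) giving ``k_n`` = -3/7.
    """
    if pp <= 0 or pc <= 0:
        raise ValueError("ratio components must be positive")
    return (pp - pc) / (pp + pc)


def zonation_positions(n_compartments: int) -> np.ndarray:
    """Axial coordinate x_i, +1 at the periportal end, -1 pericentral."""
    if n_compartments < 2:
        raise ValueError("need at least 2 compartments")
    return 1.0 - 2.0 * np.arange(n_compartments) / (n_compartments - 1)


@dataclass(frozen=True)
class ZonationProfile:
    """Per-compartment multipliers applied to a base rate constant."""

    k_n: float
    n_compartments: int
    multipliers: np.ndarray = field(repr=False)

    @property
    def endpoint_ratio(self) -> float:
        """Periportal / pericentral multiplier (m_1 / m_N)."""
        return self.multipliers[0] / self.multipliers[-1]


def build_zonation_profile(k_n: float, n_compartments: int) -> ZonationProfile:
    """Construct the linear zonation gradient for one process.

    Raises
    ------
    ValueError
        If ``abs(k_n) >= 1`` (which would produce a non-positive rate
        constant at one end of the sinusoid) or ``n_compartments < 2``.
    """
    if abs(k_n) >= 1:
        raise ValueError(f"|k_n| must be < 1, got {k_n} (negative multiplier)")
    x = zonation_positions(n_compartments)
    return ZonationProfile(k_n=float(k_n), n_compartments=n_compartments,
                           multipliers=1.0 + k_n * x)
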