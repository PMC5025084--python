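"""Pure-Python reference right-hand side built from the object layer.

Assembles the full model derivative from the public pieces --
``process_rate`` over the lumped process definitions, the Table-style
stoichiometries, ``advection_derivatives`` and ``body_derivatives`` --
with no shared code with the compiled kernel.  Used to cross-validate
the kernel on arbitrary states.
"""

import numpy as np

from sinusim.processes import process_rate
from sinusim.state import (BLOOD_INDEX, BLOOD_SPECIES, HEP_SPECIES,
                           SPECIES_CODE, N_HEP, blood_slice, body_slice,
                           hep_slice)
from sinusim.transport import advection_derivatives, body_derivatives


def reference_rhs(model, scenario, t_s, y):
    n = model.n_compartments
    dy = np.zeros_like(y)

    # systemic pool: body processes, pancreas, clearance, feeding, oxygen
    body = {name: y[body_slice()][i] for name, i in BLOOD_INDEX.items()}
    d_body = body_derivatives(model, body, t_hours=t_s / 3600.0,
                              scenario=scenario)
    for name, i in BLOOD_INDEX.items():
        dy[i] += d_body[name]

    # advection
    blood = np.array([y[blood_slice(i)] for i in range(n)])
    d_adv, d_adv_body = advection_derivatives(
        blood, y[body_slice()], model.flow, model.compartment_blood_volume,
        model.body_volume)
    dy[body_slice()] += d_adv_body
    for i in range(n):
        dy[blood_slice(i)] += d_adv[i]

    # hepatic processes
    rho = model.hepatocyte_blood_ratio
    for i in range(n):
        from sinusim.state import HepatocyteState, BloodState
        hep = HepatocyteState.from_array(y[hep_slice(i)])
        bl = BloodState.from_array(y[blood_slice(i)])
        h0 = hep_slice(i).start
        b0 = blood_slice(i).start
        for name, proc in model.params.processes.items():
            m_i = model.zonation[name].multipliers[i]
            r = process_rate(
                proc, hep, bl, m_i, k_ir=scenario.k_ir,
                srebp1c=scenario.srebp1c,
                reception_multiplier_insulin=model.insulin_reception[i],
                reception_multiplier_glucagon=model.glucagon_reception[i])
            for sp, coef in proc.stoichiometry.items():
                code = SPECIES_CODE[sp]
                if code < N_HEP:
                    dy[h0 + code] += coef * r
                else:
                    dy[b0 + code - N_HEP] += coef * r * rho
        # blood-side housekeeping
        dy[b0 + BLOOD_INDEX["insulin"]] -= \
            model.insulin_degradation * bl.insulin
        dy[b0 + BLOOD_INDEX["glucagon"]] -= \
            model.glucagon_degradation * bl.glucagon
        dy[b0 + BLOOD_INDEX["oxygen"]] -= model.oxygen_consumption
    return dy
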