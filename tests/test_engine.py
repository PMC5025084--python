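"""Integrator properties: fixed points, convergence order, guards."""

import numpy as np
import pytest

from sinusim.engine import Engine, IntegrationError, integrate
from sinusim.params import load_reference_state
from sinusim.scenarios import make_scenario
from sinusim.state import hep_slice


def _scenario(model, preset):
    return make_scenario(preset, feeding=model.params.feeding,
                         baseline_inputs=model.params.baseline_inputs,
                         body_volume_l=model.params.physiology.body_volume_l)


@pytest.fixture(scope="module")
def baseline(model):
    y = load_reference_state("constant_baseline")
    if y is None:
        pytest.skip("no stored baseline state")
    return y


class TestFixedPoint:
    def test_steady_state_is_invariant(self, model, baseline):
        """At the calibrated constant-input fixed point the state does not
        move over any horizon."""
        scen = _scenario(model, "constant_baseline")
        res = integrate(model, scen, dt=0.2, horizon_s=1800.0, y0=baseline)
        assert np.max(np.abs(res.end_state - baseline)
                      / (np.abs(baseline) + 1e-9)) < 1e-9


class TestConvergence:
    def test_fourth_order_error_decay(self, model):
        """Richardson check on a genuine transient: halving dt shrinks the
        endpoint error by ~2^4."""
        scen = _scenario(model, "MH")  # cyclic forcing => transient
        y0 = model.initial_state()     # off-equilibrium start
        horizon = 300.0
        ref = integrate(model, scen, dt=0.0125, horizon_s=horizon, y0=y0,
                        t0=5400.0)
        errs = []
        for dt in (0.4, 0.2, 0.1):
            res = integrate(model, scen, dt=dt, horizon_s=horizon, y0=y0,
                            t0=5400.0)
            errs.append(np.max(np.abs(res.end_state - ref.end_state)
                               / (np.abs(ref.end_state) + 1e-9)))
        order1 = np.log2(errs[0] / errs[1])
        order2 = np.log2(errs[1] / errs[2])
        assert order1 > 3.5
        assert order2 > 3.5

    def test_stable_at_reference_and_coarse_steps(self, model, baseline):
        """The reference configuration stays finite and positive for
        dt up to 0.4 s."""
        scen = _scenario(model, "MH")
        for dt in (0.05, 0.4):
            res = integrate(model, scen, dt=dt, horizon_s=600.0, y0=baseline)
            assert np.all(np.isfinite(res.end_state))
            assert np.all(res.end_state >= 0)


class TestGuards:
    def test_invalid_dt_rejected(self, model):
        with pytest.raises(ValueError):
            integrate(model, _scenario(model, "MH"), dt=0.0)

    def test_cycle_equilibrium_requires_cyclic_waveform(self, model):
        from sinusim.engine import run_to_cycle_equilibrium
        with pytest.raises(ValueError):
            run_to_cycle_equilibrium(model, _scenario(model,
                                                      "constant_baseline"))

    def test_blowup_reports_offending_species(self, model, baseline):
        """A pathological parameter set aborts with a diagnostic naming the
        first species driven negative, instead of clipping silently."""
        import copy
        from sinusim.params import load_params_dict
        from sinusim.transport import SinusoidModel
        doc = copy.deepcopy(model.params.raw)
        # absurd glucokinase activity forces hepatic glucose through zero
        doc["processes"]["glucokinase"]["vb"] = 1e9
        bad = SinusoidModel(load_params_dict(doc))
        with pytest.raises(IntegrationError, match=r"glucose|g6p|atp"):
            integrate(bad, _scenario(bad, "MH"), dt=0.4, horizon_s=120.0,
                      y0=baseline)


class TestResultViews:
    def test_averages_and_views_consistent(self, model, baseline):
        scen = _scenario(model, "constant_baseline")
        res = integrate(model, scen, dt=0.2, horizon_s=300.0, y0=baseline)
        atp = res.hep_avg("atp")
        assert atp.shape == (model.n_compartments,)
        # at the fixed point, the average equals the state itself
        for i in range(model.n_compartments):
            assert atp[i] == pytest.approx(
                baseline[hep_slice(i)][9], rel=1e-9)
        frame = res.to_frame()
        assert {"time_s", "compartment", "species", "value"} == \
            set(frame.columns)
        assert (frame["compartment"] == 0).any()  # body rows present
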