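"""Cable integration: passive oracles, stability, and determinism."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

import dendgate as dg
from dendgate.morphology import SiteAddress
from dendgate.stimuli import StepCurrentSpec, StimulusProtocol


def passive_steady_state_oracle(grid, inj_node, inj_na):
    """Direct sparse solve of the passive steady-state linear system.

    G v = b with G the (leak + axial) conductance matrix in uS and b the
    injected currents in nA plus leak * E_L; independent of the time-stepping
    engine.
    """
    n = grid.n_nodes
    rows, cols, vals = [], [], []
    diag = grid.g_leak_us.copy()
    for i in range(1, n):
        p = grid.parent[i]
        g = grid.g_axial_us[i]
        diag[i] += g
        diag[p] += g
        rows += [i, p]
        cols += [p, i]
        vals += [-g, -g]
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    G = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    b = grid.g_leak_us * grid.e_leak
    b[inj_node] += inj_na
    return spla.spsolve(G.tocsc(), b)


class TestPassiveLimit:
    def test_rest_is_flat(self, passive_cell, probes):
        spec = dg.SimulationSpec(duration=100.0, probes=probes)
        rec = dg.simulate(passive_cell, StimulusProtocol(), spec)
        for (label, qty), series in rec.series.items():
            if qty == "V":
                assert np.all(np.abs(series + 70.0) < 0.01), label

    def test_steady_state_matches_linear_solve(self, passive_cell, probes):
        grid = passive_cell.grid
        node = grid.node_index(SiteAddress("soma", 0.5))
        v_direct = passive_steady_state_oracle(grid, node, 0.1)
        proto = StimulusProtocol([StepCurrentSpec(
            amplitude_na=0.1, duration_ms=400.0, onset_ms=0.0)])
        spec = dg.SimulationSpec(duration=400.0, probes=probes)
        rec = dg.simulate(passive_cell, proto, spec)
        for label, site, qty in probes:
            if qty != "V":
                continue
            idx = grid.node_index(site)
            assert rec.get(label, "V")[-1] == pytest.approx(
                v_direct[idx], rel=1e-3), label

    def test_charge_conservation_subthreshold(self, passive_cell, probes):
        """Injected charge accounting over a subthreshold step (< 1%)."""
        grid = passive_cell.grid
        amp, dur = 0.05, 30.0
        all_v = [(f"n{i}", grid.site_of(i), "V")
                 for i in range(0, grid.n_nodes, 1)]
        proto = StimulusProtocol([StepCurrentSpec(
            amplitude_na=amp, duration_ms=dur, onset_ms=0.0)])
        spec = dg.SimulationSpec(duration=dur, probes=all_v)
        rec = dg.simulate(passive_cell, proto, spec)
        q_in = amp * dur  # nA*ms = pC
        q_mem = 0.0       # capacitive + leaked charge
        for i in range(grid.n_nodes):
            v = rec.get(f"n{i}", "V")
            q_mem += grid.c_nf[i] * (v[-1] - v[0])
            q_mem += grid.g_leak_us[i] * np.trapezoid(v - grid.e_leak, rec.t)
        assert q_mem == pytest.approx(q_in, rel=0.01)


class TestActive:
    def test_somatic_spike_latency(self, control_step):
        """Somatic spike peaks roughly 2.5 ms after stimulation onset."""
        v = control_step.get("soma", "V")
        t_peak = control_step.t[int(np.argmax(v))] - 10.0
        assert 2.0 <= t_peak <= 3.0
        assert v.max() - v[0] > 80.0

    def test_determinism(self, cell, probes):
        spec = dg.SimulationSpec(duration=30.0, probes=probes)
        a = dg.simulate(cell, dg.make_somatic_step(t0=10.0), spec)
        b = dg.simulate(cell, dg.make_somatic_step(t0=10.0), spec)
        for key in a.series:
            assert np.array_equal(a.series[key], b.series[key])

    def test_dt_refinement_stability(self, cell, probes):
        """Halving dt changes bAP peak amplitudes by < 2% at all probes."""
        amps = {}
        for dt in (0.1, 0.05):
            spec = dg.SimulationSpec(duration=30.0, dt=dt, probes=probes)
            rec = dg.simulate(cell, dg.make_somatic_step(t0=10.0), spec)
            amps[dt] = {lbl: rec.get(lbl, "V").max() - rec.get(lbl, "V")[0]
                        for lbl in ("soma", "oblique", "basal")}
        for lbl in amps[0.1]:
            assert amps[0.05][lbl] == pytest.approx(amps[0.1][lbl], rel=0.02)

    def test_recording_frame_layout(self, control_step):
        df = control_step.to_frame()
        assert set(df.columns) == {"time_ms", "probe", "quantity", "value"}
        assert df.value.notna().all()
        assert control_step.meta["protocol_hash"]

    def test_invalid_spec_rejected(self, probes):
        with pytest.raises(ValueError):
            dg.SimulationSpec(duration=10.0, dt=-0.1)
        with pytest.raises(ValueError):
            dg.SimulationSpec(duration=10.0,
                              probes=[("x", SiteAddress("soma", 0.5), "Q")])
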