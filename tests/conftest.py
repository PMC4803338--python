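import numpy as np
import pytest

import dendgate as dg


@pytest.fixture(scope="session")
def cell():
    """The default calibrated pyramidal cell (shared across tests)."""
    return dg.build_neuron()


@pytest.fixture(scope="session")
def morph(cell):
    return cell.morph


@pytest.fixture(scope="session")
def probes(morph):
    return dg.standard_probes(morph)


@pytest.fixture(scope="session")
def control_step(cell, probes):
    """Uninhibited somatic-step recording (the bAP control trial)."""
    spec = dg.SimulationSpec(duration=50.0, probes=probes)
    return dg.simulate(cell, dg.make_somatic_step(t0=10.0), spec)


@pytest.fixture(scope="session")
def passive_cell(cell):
    """Same cell with every active conductance removed (pure cable)."""
    dens = cell.dens.scaled(gna1=0.0, gna2=0.0, gkdr=0.0, gka=0.0,
                            gcah=0.0, gcal=0.0, gkca=0.0)
    return cell.with_densities(dens)


def run_step_with_inhibition(cell, probes, g_ns, location_um=90.0,
                             onset_rel=2.0, kind="apical", duration=50.0):
    proto = dg.make_somatic_step(t0=10.0)
    if g_ns > 0:
        proto.add(dg.inhibitory_synapse(cell.morph, location_um, g_ns,
                                        onset=10.0 + onset_rel, kind=kind))
    spec = dg.SimulationSpec(duration=duration, probes=probes)
    return dg.simulate(cell, proto, spec)
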