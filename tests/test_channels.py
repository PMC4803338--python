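"""Channel kinetics, density profiles, and the current-summation surface."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendgate.cable import discretize
from dendgate.channels import (ChannelDensityParams, GATE_EXPONENTS,
                               KineticParams, assemble_channel_distribution,
                               gating_steady_states, gating_time_constants,
                               ka_density, membrane_current, na_gates)
from dendgate.morphology import SiteAddress, build_simplified_pyramidal


class TestKaDensity:
    def test_somatic_value(self):
        assert ka_density(0.0) == pytest.approx(0.029)

    def test_linear_law_midpoint(self):
        # five-fold increase over 500 um: at 250 um the density is
        # 0.029 * (1 + 4 * 250/500)
        assert ka_density(250.0) == pytest.approx(0.087)

    def test_clamped_variant(self):
        p = ChannelDensityParams(ka_clamp=True)
        assert ka_density(600.0, p) == pytest.approx(ka_density(500.0, p))

    def test_default_continues_gradient(self):
        assert ka_density(600.0) > ka_density(500.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            ka_density(-1.0)


@pytest.fixture(scope="module")
def dist(morph):
    grid = discretize(morph)
    return grid, assemble_channel_distribution(grid)


class TestDistribution:

    def test_zone_cah_threefold(self, dist):
        grid, d = dist
        sel = (np.array([grid.morph.sections[s].stype
                         for s in grid.section]) == "apical") & \
            (grid.dist_um >= 500) & (grid.dist_um <= 750)
        assert np.allclose(d.gcah[sel], 0.00045)
        assert np.all(d.gcal[sel] == 0.005)

    def test_soma_twofold(self, dist):
        grid, d = dist
        i = grid.node_index(SiteAddress("soma", 0.5))
        assert d.gkca[i] == pytest.approx(0.0005)
        assert d.gcah[i] == pytest.approx(0.0003)

    def test_axon_split_populations(self, dist):
        grid, d = dist
        i = grid.node_index(SiteAddress("axon", 0.5))
        assert d.gna1[i] + d.gna2[i] == pytest.approx(0.6)
        assert d.gna1[i] == pytest.approx(0.3)
        # half the axonal channels are shifted -10 mV relative to the rest
        assert d.shift2[i] - d.shift1[i] == -10.0
        assert d.gcal[i] == 0.0 and d.gkca[i] == 0.0

    def test_dendritic_shift_and_basal_ka(self, dist):
        grid, d = dist
        ob = grid.node_index(grid.morph.resolve_um("oblique", 250.0))
        assert d.shift1[ob] == 5.0
        ba = grid.node_index(grid.morph.resolve_um("basal", 75.0))
        assert d.gka[ba] == pytest.approx(0.029)


class TestGating:
    @pytest.mark.parametrize("v", np.linspace(-120, 60, 37))
    def test_steady_states_bounded(self, v):
        for name, x in gating_steady_states(float(v)).items():
            assert 0.0 <= x <= 1.0, name

    @pytest.mark.parametrize("v", [-90, -60, -30, 0, 30])
    def test_time_constants_positive(self, v):
        for name, tau in gating_time_constants(float(v)).items():
            assert tau > 0.0, name

    def test_voltage_shift_composition(self):
        kp = KineticParams()
        for v in np.linspace(-80, 0, 17):
            m_sh, _, _, _ = na_gates(float(v), 5.0, kp.qt_na, kp.na_tha,
                                     kp.na_hvhalf)
            m_un, _, _, _ = na_gates(float(v) - 5.0, 0.0, kp.qt_na,
                                     kp.na_tha, kp.na_hvhalf)
            assert m_sh == pytest.approx(m_un, rel=1e-12)


class TestMembraneCurrent:
    def test_kdr_zero_at_reversal(self):
        out = membrane_current(-80.0, {"kdr_n": 0.7}, {"kdr": 0.01})
        assert out["kdr"] == 0.0

    def test_only_leak_with_closed_gates(self):
        gates = {"na_m": 0.0, "na_h": 0.0, "kdr_n": 0.0}
        out = membrane_current(-50.0, gates, {"na": 0.009, "kdr": 0.01})
        assert out["na"] == 0.0 and out["kdr"] == 0.0
        assert out["leak"] == pytest.approx((-50.0 + 70.0) / 40000.0)

    @given(st.floats(-90, 30), st.floats(0, 1), st.floats(0, 1),
           st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_against_term_by_term_oracle(self, v, m, h, n):
        gates = {"na_m": m, "na_h": h, "kdr_n": n}
        dens = {"na": 0.009, "kdr": 0.01}
        out = membrane_current(v, gates, dens)
        # independent summation with explicit exponents and reversals
        assert out["na"] == pytest.approx(0.009 * m**3 * h * (v - 60.0))
        assert out["kdr"] == pytest.approx(0.01 * n * (v + 80.0))

    def test_gate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            membrane_current(-50.0, {"kdr_n": 1.5}, {"kdr": 0.01})
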