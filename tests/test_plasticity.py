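"""STDP rule, pairing protocol, and learning windows."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dendgate as dg
from dendgate.plasticity import (STDPRule, accumulate_weight,
                                 learning_window, run_pairing_protocol,
                                 stdp_delta)
from dendgate.stimuli import inhibitory_synapse


class TestRule:
    def test_depression_at_zero(self):
        # Dt = 0 falls on the depression branch: -A_minus
        assert stdp_delta(0.0) == pytest.approx(-0.00106)

    def test_potentiation_at_one_tau(self):
        assert stdp_delta(20.0) == pytest.approx(0.001 * np.e ** -1)

    def test_vanishes_at_infinity(self):
        assert stdp_delta(1e4) == pytest.approx(0.0, abs=1e-12)
        assert stdp_delta(-1e4) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-200, 200))
    @settings(max_examples=200, deadline=None)
    def test_matches_independent_formula(self, dt):
        """Piecewise re-evaluation of the printed exponential window."""
        expected = np.where(dt <= 0, -0.00106 * np.exp(dt / 20.0),
                            0.001 * np.exp(-dt / 20.0))
        assert stdp_delta(dt) == pytest.approx(float(expected), rel=1e-12)

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            STDPRule(a_plus=-1.0)
        with pytest.raises(ValueError):
            STDPRule(w_min=1.0, w_max=0.5)


class TestAccumulation:
    @given(st.lists(st.floats(-0.05, 0.05), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_bounds_never_violated(self, dws):
        rule = STDPRule()
        w = 1e-6
        for dw in dws:
            w = accumulate_weight(dw, 1, rule, w_init=w)
            assert rule.w_min <= w <= rule.w_max

    def test_linearity_in_unclipped_regime(self):
        rule = STDPRule()
        dw = 1e-4  # small positive fraction, no bound reached over 50 steps
        w0 = 5e-5
        for n in (1, 7, 50):
            w = accumulate_weight(dw, n, rule, w_init=w0)
            assert w - w0 == pytest.approx(n * dw * rule.w_max)

    def test_depression_clips_at_floor(self):
        rule = STDPRule()
        w = accumulate_weight(-0.00106, 100, rule, w_init=1e-6)
        assert w == rule.w_min


@pytest.fixture(scope="module")
def ob_window(cell):
    """Uninhibited oblique window on a coarse grid (shared)."""
    return learning_window(cell, "oblique", np.array([-10.0, -5.0, 5.0, 10.0]))


class TestPairing:
    def test_unknown_site_rejected(self, cell):
        with pytest.raises(KeyError):
            run_pairing_protocol(cell, "axon_hillock", 5.0)

    def test_oblique_window_is_asymmetric(self, ob_window):
        """Classical STDP: potentiation for post-after-pre, depression for
        pre-after-post."""
        signs = np.sign(ob_window.dw_norm)
        assert np.all(signs == np.sign(ob_window.dt_ms))
        assert np.max(np.abs(ob_window.dw_norm)) == pytest.approx(1.0)

    def test_proximal_inhibition_flattens_oblique(self, cell):
        inh = inhibitory_synapse(cell.morph, 90.0, 50.0, onset=1.5)
        win = learning_window(cell, "oblique", np.array([-5.0, 5.0]), inh)
        assert np.all(win.dw_norm == 0.0)

    def test_distal_window_nonnegative(self, cell):
        win = learning_window(cell, "distal", np.array([-15.0, 0.0, 5.0]))
        assert np.all(win.dw_norm >= 0.0)
        assert np.any(win.dw_norm > 0.0)

    def test_distal_inhibition_flattens_distal(self, cell):
        inh = inhibitory_synapse(cell.morph, 460.0, 50.0, onset=1.5)
        win = learning_window(cell, "distal", np.array([0.0, 5.0]), inh)
        assert np.all(win.dw_norm == 0.0)


class TestCalciumScan:
    def test_bimodal_without_and_low_with_inhibition(self, cell):
        grid = np.array([-20.0, -10.0, 0.0, 5.0, 20.0])
        free = dg.plasticity.distal_calcium_scan(cell, grid)
        vals = free.ca_peak_mM.to_numpy()
        assert vals.max() > 0.5 and vals.min() < 0.25  # two separated modes
        inh = inhibitory_synapse(cell.morph, 460.0, 50.0, onset=1.5)
        gated = dg.plasticity.distal_calcium_scan(cell, grid, inh)
        assert np.all(gated.ca_peak_mM < 0.5)

    def test_zero_distal_drive_stays_low(self, cell):
        import dendgate.plasticity as pl
        old = pl.PLASTIC_SYNAPSES["distal"]
        pl.PLASTIC_SYNAPSES["distal"] = (old[0], old[1], old[2], 0.0)
        try:
            df = pl.distal_calcium_scan(cell, np.array([0.0]))
        finally:
            pl.PLASTIC_SYNAPSES["distal"] = old
        assert np.all(df.ca_peak_mM < 0.5)
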