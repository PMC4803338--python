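"""Synapse waveforms and protocol builders."""

import numpy as np
import pytest

import dendgate as dg
from dendgate.morphology import SiteAddress
from dendgate.stimuli import (Exp2SynSpec, ExpSynSpec, StimulusProtocol,
                              exp2_waveform, exp_waveform,
                              make_distributed_excitation,
                              make_frequency_drive, make_inhibitory_train,
                              make_jittered_inhibition)


def _inh(onsets=(5.0,), g=10.0):
    return Exp2SynSpec(SiteAddress("apic_trunk0", 0.9), 0.5, 5.0, g, -73.0,
                       onsets=onsets)


class TestWaveforms:
    def test_zero_at_onset_and_before(self):
        t = np.arange(0, 30, 0.01)
        g = exp2_waveform(t, _inh(onsets=(5.0,)))
        assert np.all(g[t < 5.0] == 0.0)
        assert g[np.searchsorted(t, 5.0)] == pytest.approx(0.0, abs=1e-9)

    def test_peak_normalization_and_time(self):
        spec = _inh()
        tp = spec.peak_time
        # closed form: tp = tr*td/(td-tr) * ln(td/tr)
        assert tp == pytest.approx(0.5 * 5 / 4.5 * np.log(10.0))
        t = np.arange(0, 60, 0.0005)
        g = exp2_waveform(t, spec)
        assert g.max() == pytest.approx(10.0 * 1e-3, rel=1e-6)
        assert t[np.argmax(g)] - 5.0 == pytest.approx(tp, abs=1e-3)

    def test_decays_to_zero(self):
        g = exp2_waveform(np.array([500.0]), _inh(onsets=(0.0,)))
        assert g[0] == pytest.approx(0.0, abs=1e-12)

    def test_superposition(self):
        t = np.arange(0, 50, 0.01)
        one = exp2_waveform(t, _inh(onsets=(5.0,)))
        three = exp2_waveform(t, _inh(onsets=(5.0, 5.0, 5.0)))
        assert np.allclose(three, 3 * one)

    def test_nonnegative(self):
        t = np.arange(0, 100, 0.05)
        g = exp2_waveform(t, _inh(onsets=(1.0, 7.0, 20.0)))
        assert np.all(g >= 0.0)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            Exp2SynSpec(SiteAddress("soma", 0.5), 5.0, 0.5, 1.0, 0.0)

    def test_exp_waveform_peaks_at_onset(self):
        t = np.arange(0, 20, 0.01)
        g = exp_waveform(t, ExpSynSpec(SiteAddress("soma", 0.5),
                                       g_max_ns=8.0, onsets=(3.0,)))
        assert g.max() == pytest.approx(8e-3)
        assert t[np.argmax(g)] == pytest.approx(3.0)


class TestBuilders:
    def test_distributed_defaults(self, morph):
        syns = make_distributed_excitation(morph)
        assert len(syns) == 8
        assert all(s.g_max_ns == pytest.approx(2.5) for s in syns)
        soma = SiteAddress("soma", 0.5)
        dists = sorted(morph.path_distance(soma, s.site) for s in syns)
        assert dists[0] == pytest.approx(140.0, abs=2.0)
        assert dists[-1] == pytest.approx(420.0, abs=3.0)

    def test_distributed_single_synapse_midpoint(self, morph):
        (syn,) = make_distributed_excitation(morph, n=1)
        soma = SiteAddress("soma", 0.5)
        assert morph.path_distance(soma, syn.site) == pytest.approx(280.0,
                                                                    abs=3.0)
        assert syn.g_max_ns == pytest.approx(20.0)

    def test_inhibitory_train_spacing(self, morph):
        syn = make_inhibitory_train(morph, 4, 75.0, 70.0,
                                    morph.resolve_um("basal", 100.0), 10.0)
        onsets = np.array(syn.onsets)
        assert len(onsets) == 4
        assert np.allclose(np.diff(onsets), 1000.0 / 75.0)
        assert syn.e_rev == -73.0

    def test_train_single_pulse(self, morph):
        syn = make_inhibitory_train(morph, 1, 75.0, 50.0,
                                    morph.resolve_um("apical", 90.0), 12.0)
        assert syn.onsets == (12.0,)

    def test_jitter_zero_sigma_colocated(self, morph):
        syns = make_jittered_inhibition(morph, 25, 0.0, 0.0, seed=1)
        soma = SiteAddress("soma", 0.5)
        assert len(syns) == 25
        for s in syns:
            assert morph.path_distance(soma, s.site) == pytest.approx(90.0)
            assert s.onsets == (12.0,)
            assert s.g_max_ns == 1.0

    def test_jitter_truncated_to_trunk(self, morph):
        syns = make_jittered_inhibition(morph, 200, 80.0, 1.0, seed=3)
        assert all(s.site.section in ("apic_trunk0", "apic_trunk1")
                   for s in syns)

    def test_jitter_deterministic(self, morph):
        a = make_jittered_inhibition(morph, 10, 20.0, 0.5, seed=42)
        b = make_jittered_inhibition(morph, 10, 20.0, 0.5, seed=42)
        assert a == b

    def test_frequency_drive_cycle_count(self):
        proto = make_frequency_drive(90.0, 600.0)
        assert len(proto.events) == 54

    def test_frequency_drive_rejects_zero(self):
        with pytest.raises(ValueError):
            make_frequency_drive(0.0)

    def test_frequency_drive_interval(self):
        p80 = make_frequency_drive(80.0, 600.0)
        p70 = make_frequency_drive(70.0, 600.0)
        d80 = p80.events[1].onset_ms - p80.events[0].onset_ms
        d70 = p70.events[1].onset_ms - p70.events[0].onset_ms
        assert d80 == pytest.approx(12.5)
        assert d70 == pytest.approx(1000 / 70)
        assert p80.events[0].amplitude_na == p70.events[0].amplitude_na

    def test_bac_zero_conductance_is_bare_step(self, morph):
        a = dg.make_bac_pairing(morph, 5.0, 0.0, t0=10.0)
        b = dg.make_somatic_step(t0=10.0)
        assert a.events == b.events

    def test_protocol_roundtrip(self, morph):
        proto = dg.make_bac_pairing(morph, 5.0, 8.0, t0=10.0)
        proto.add(_inh())
        back = StimulusProtocol.from_dict(proto.to_dict())
        assert back.events == proto.events
        assert back.t_stim == proto.t_stim
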