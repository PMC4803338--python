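"""Morphology construction, path metric, and SWC round-trips."""

import math

import numpy as np
import pytest

from dendgate.morphology import (Morphology, PassiveParams, Section,
                                 SiteAddress, build_simplified_pyramidal,
                                 export_swc, import_swc, path_distance)


class TestBuild:
    def test_trunk_split(self, morph):
        assert morph["apic_trunk0"].length == 100.0
        assert morph["apic_trunk0"].nseg == 19
        assert morph["apic_trunk1"].length == 400.0
        assert morph["apic_trunk1"].nseg == 73
        total = morph["apic_trunk0"].length + morph["apic_trunk1"].length
        assert total == 500.0

    def test_daughter_diameter_rule(self, morph):
        assert morph["tuft_a"].diameter == pytest.approx(2.0 * 2 / 3)
        assert morph["tuft_a_a"].diameter == pytest.approx(2.0 * 4 / 9)
        assert morph["basal_a"].diameter == pytest.approx(1.0 * 2 / 3)

    def test_empty_overrides_identical(self):
        a = build_simplified_pyramidal({})
        b = build_simplified_pyramidal()
        sa = [(s.name, s.length, s.diameter, s.nseg, s.parent)
              for s in a.sections.values()]
        sb = [(s.name, s.length, s.diameter, s.nseg, s.parent)
              for s in b.sections.values()]
        assert sa == sb

    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError):
            build_simplified_pyramidal({"no_such_parameter": 1.0})

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_simplified_pyramidal({"trunk_diam": -1.0})

    def test_single_root_and_attachments(self, morph):
        roots = [s for s in morph.sections.values() if s.parent is None]
        assert [s.name for s in roots] == ["soma"]
        assert morph["axon"].parent == "soma"
        assert morph["basal"].parent == "soma"

    def test_membrane_area(self, morph):
        for s in morph.sections.values():
            assert s.area == pytest.approx(math.pi * s.diameter * s.length)

    def test_passive_defaults(self, morph):
        p = morph.passive
        assert (p.cm, p.ra, p.rm, p.e_leak) == (0.75, 150.0, 40000.0, -70.0)


class TestPathDistance:
    def test_soma_to_oblique_junction(self, morph):
        d = path_distance(morph, SiteAddress("soma", 0.5),
                          SiteAddress("apic_trunk0", 1.0))
        assert d == pytest.approx(100.0)

    def test_self_distance_zero(self, morph):
        site = SiteAddress("oblique", 0.3)
        assert path_distance(morph, site, site) == 0.0

    def test_triangle_equality_along_path(self, morph):
        a = SiteAddress("soma", 0.5)
        b = SiteAddress("apic_trunk1", 0.4)
        c = SiteAddress("tuft_a", 0.8)
        dab = path_distance(morph, a, b)
        dbc = path_distance(morph, b, c)
        dac = path_distance(morph, a, c)
        assert dac == pytest.approx(dab + dbc)

    def test_against_graph_oracle(self, morph):
        """Random site pairs agree with a brute-force edge walk (networkx)."""
        import networkx as nx
        g = nx.Graph()
        for s in morph.sections.values():
            g.add_edge((s.name, 0.0), (s.name, 1.0), weight=s.metric_length)
            if s.parent is not None:
                p = morph.sections[s.parent]
                # attach child 0-end at the parent fraction point
                g.add_edge((s.name, 0.0), (s.parent, "@", s.parent_x),
                           weight=0.0)
                g.add_edge((s.parent, "@", s.parent_x), (s.parent, 0.0),
                           weight=s.parent_x * p.metric_length)
                g.add_edge((s.parent, "@", s.parent_x), (s.parent, 1.0),
                           weight=(1 - s.parent_x) * p.metric_length)
        rng = np.random.default_rng(7)
        names = list(morph.sections)
        for _ in range(25):
            sa, sb = rng.choice(names, 2)
            xa, xb = rng.random(), rng.random()
            a, b = SiteAddress(sa, xa), SiteAddress(sb, xb)
            g.add_edge(("A",), (sa, 0.0),
                       weight=xa * morph.sections[sa].metric_length)
            g.add_edge(("A",), (sa, 1.0),
                       weight=(1 - xa) * morph.sections[sa].metric_length)
            g.add_edge(("B",), (sb, 0.0),
                       weight=xb * morph.sections[sb].metric_length)
            g.add_edge(("B",), (sb, 1.0),
                       weight=(1 - xb) * morph.sections[sb].metric_length)
            expected = nx.shortest_path_length(g, ("A",), ("B",),
                                               weight="weight")
            if sa == sb:
                expected = abs(xa - xb) * morph.sections[sa].metric_length
            assert path_distance(morph, a, b) == pytest.approx(expected,
                                                               abs=1e-9)
            g.remove_node(("A",))
            g.remove_node(("B",))

    def test_resolve_um_convention(self, morph):
        site = morph.resolve_um("apical", 90.0)
        assert site.section == "apic_trunk0"
        assert site.x == pytest.approx(0.9)
        obl = morph.resolve_um("oblique", 370.0)
        assert obl.section == "oblique"
        assert obl.x == pytest.approx(0.9)

    def test_unresolvable_address(self, morph):
        with pytest.raises(KeyError):
            morph.resolve(SiteAddress("nowhere", 0.5))
        with pytest.raises(ValueError):
            morph.resolve_um("apical", 5000.0)


class TestSWC:
    def test_radius_and_root_convention(self, morph):
        text = export_swc(morph)
        rows = [l.split() for l in text.splitlines()
                if l and not l.startswith("#")]
        # root soma: parent -1, radius = diameter/2
        root = rows[0]
        assert root[6] == "-1"
        assert float(root[5]) == pytest.approx(18.5 / 2)
        diam_halves = {s.diameter / 2 for s in morph.sections.values()}
        for r in rows[1:]:
            rad = float(r[5])
            assert any(abs(rad - d) < 1e-3 for d in diam_halves)

    def test_roundtrip_path_distances(self, morph):
        """Export -> import preserves the path-distance matrix to 0.1 um."""
        back = import_swc(export_swc(morph))
        # distances between a set of landmark points, via the um resolver on
        # the original and tip-to-root walks on the reimport
        landmarks = [("soma", 0.5), ("apic_trunk0", 1.0),
                     ("apic_trunk1", 1.0), ("oblique", 1.0), ("basal", 1.0)]
        # map original landmark -> reimported node by matching coordinates of
        # total distance from root
        orig_root = SiteAddress("soma", 0.5)
        back_root = SiteAddress(back.root, 0.5)
        orig_d = []
        for sec, x in landmarks:
            orig_d.append(morph.path_distance(orig_root,
                                              SiteAddress(sec, x)))
        # every original section end must exist at the same distance in the
        # reimport: compare sorted distance multisets of all section 1-ends
        def tip_dists(m, root):
            return sorted(m.path_distance(root, SiteAddress(name, 1.0))
                          for name in m.sections)
        a = tip_dists(morph, orig_root)
        b = tip_dists(back, back_root)
        assert len(a) == len(b)
        assert np.allclose(a, b, atol=0.1)
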