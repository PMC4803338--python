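"""Spatial discretization of a morphology into cable nodes.

Each section is split into ``nseg`` iso-potential nodes at the segment
centers (the usual compartmental convention).  Nodes are numbered in a
depth-first order starting at the soma so that ``parent[i] < i`` for every
non-root node; the branched implicit solve in the engine relies on this
(Hines) ordering.

Unit conventions used throughout the package:

==========  =======
quantity    unit
==========  =======
voltage     mV
time        ms
capacitance nF
conductance uS
current     nA
length      um
==========  =======

With these, ``C dV/dt`` (nF*mV/ms) and ``g*V`` (uS*mV) are both in nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .morphology import Morphology, SiteAddress

__all__ = ["CableGrid", "discretize"]


@dataclass
class CableGrid:
    """Per-node arrays describing the discretized tree.

    Attributes
    ----------
    section : list of section name per node
    x : fractional position of each node center along its section
    dist_um : path distance of each node from the soma (um)
    area_cm2 : membrane area of each node (cm^2)
    c_nf : membrane capacitance per node (nF)
    g_leak_us : leak conductance per node (uS)
    parent : index of the parent node (-1 for the root)
    g_axial_us : axial conductance linking each node to its parent (uS)
    e_leak : leak reversal (mV)
    """

    morph: Morphology
    section: list
    x: np.ndarray
    dist_um: np.ndarray
    area_cm2: np.ndarray
    c_nf: np.ndarray
    g_leak_us: np.ndarray
    parent: np.ndarray
    g_axial_us: np.ndarray
    e_leak: float

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def node_index(self, site: SiteAddress) -> int:
        """Index of the node whose segment contains ``site``."""
        sec = self.morph.sections[site.section]
        first = self._sec_first[site.section]
        k = min(int(site.x * sec.nseg), sec.nseg - 1)
        return first + k

    def nodes_of(self, name: str) -> np.ndarray:
        """All node indices belonging to one section, in proximal order."""
        first = self._sec_first[name]
        return np.arange(first, first + self.morph.sections[name].nseg)

    def site_of(self, index: int) -> SiteAddress:
        return SiteAddress(self.section[index], float(self.x[index]))


def _half_axial_ohm(morph: Morphology, name: str, length_um: float) -> float:
    """Axial resistance (Ohm) of ``length_um`` of the named section."""
    sec = morph.sections[name]
    r_cm = sec.diameter / 2.0 * 1e-4
    area = math.pi * r_cm * r_cm
    return morph.passive.ra * (length_um * 1e-4) / area


def discretize(morph: Morphology) -> CableGrid:
    """Build the node grid, Hines-ordered, with axial couplings in uS."""
    p = morph.passive
    order: list[str] = []

    def dfs(name: str) -> None:
        order.append(name)
        for kid in sorted(morph.children(name)):
            dfs(kid)

    dfs(morph.root)

    section: list[str] = []
    xs: list[float] = []
    parents: list[int] = []
    g_ax: list[float] = []
    areas: list[float] = []
    dists: list[float] = []
    sec_first: dict[str, int] = {}
    soma_site = SiteAddress(morph.root, 0.5)

    for name in order:
        sec = morph.sections[name]
        first = len(section)
        sec_first[name] = first
        seg_len = sec.length / sec.nseg
        seg_area = sec.area / sec.nseg * 1e-8  # um^2 -> cm^2
        half_r = _half_axial_ohm(morph, name, seg_len / 2.0)
        for k in range(sec.nseg):
            x = (k + 0.5) / sec.nseg
            section.append(name)
            xs.append(x)
            areas.append(seg_area)
            dists.append(morph.path_distance(soma_site, SiteAddress(name, x)))
            if k > 0:
                parents.append(first + k - 1)
                g_ax.append(1e6 / (2.0 * half_r))  # two half-segments in series
            elif sec.parent is None:
                parents.append(-1)
                g_ax.append(0.0)
            else:
                # child half-segment + parent resistance from the parent node
                # center to the attachment point
                psec = morph.sections[sec.parent]
                pfirst = sec_first[sec.parent]
                pk = min(int(sec.parent_x * psec.nseg), psec.nseg - 1)
                p_center = (pk + 0.5) / psec.nseg
                p_len = abs(sec.parent_x - p_center) * psec.length
                r = half_r + _half_axial_ohm(morph, sec.parent, p_len)
                parents.append(pfirst + pk)
                g_ax.append(1e6 / r)

    area_arr = np.asarray(areas)
    grid = CableGrid(
        morph=morph,
        section=section,
        x=np.asarray(xs),
        dist_um=np.asarray(dists),
        area_cm2=area_arr,
        c_nf=p.cm * area_arr * 1e3,          # uF/cm^2 * cm^2 -> nF
        g_leak_us=area_arr / p.rm * 1e6,     # S -> uS
        parent=np.asarray(parents, dtype=np.int64),
        g_axial_us=np.asarray(g_ax),
        e_leak=p.e_leak,
    )
    grid._sec_first = sec_first  # type: ignore[attr-defined]
    return grid
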