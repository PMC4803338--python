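"""Simplified pyramidal-cell morphology: a branched tree of cylindrical cables.

The default cell consists of an axon initial segment, a cylindrical soma, an
apical trunk of total length 500 um that splits at 100 um into a proximal and a
distal compartment (an oblique dendrite joins at the split), apical tuft
branches beyond 500 um, and a basal tree.  First-order daughter branches have
2/3 of the diameter of their mother; second-order branches are present to
avoid sealed-end boundary artifacts but carry no probes or synapses.

All dimensions are micrometres.  Path distances follow the convention of the
experimental literature: the soma is treated as a point, so "90 um from the
soma" means 90 um of dendritic cable measured from the somatic origin of the
tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "SiteAddress",
    "PassiveParams",
    "build_simplified_pyramidal",
    "path_distance",
    "export_swc",
    "import_swc",
]

#: SWC structure-type codes.
_SWC_TYPES = {"soma": 1, "axon": 2, "basal": 3, "apical": 4}
_SWC_TYPES_INV = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}


@dataclass
class PassiveParams:
    """Passive cable parameters shared by every section.

    cm    : specific membrane capacitance, uF/cm^2
    ra    : axial resistivity, Ohm*cm
    rm    : specific membrane resistance, Ohm*cm^2
    e_leak: leak reversal potential, mV
    """

    cm: float = 0.75
    ra: float = 150.0
    rm: float = 40_000.0
    e_leak: float = -70.0


@dataclass
class Section:
    """One unbranched cylindrical cable.

    ``parent_x`` is the attachment position on the parent (fraction of parent
    length); children of the soma attach at its poles but, because the soma is
    a point in the path metric, the attachment fraction carries no distance.
    """

    name: str
    length: float
    diameter: float
    nseg: int
    stype: str = "apical"
    parent: str | None = None
    parent_x: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"section {self.name}: length must be > 0")
        if self.diameter <= 0:
            raise ValueError(f"section {self.name}: diameter must be > 0")
        if self.nseg < 1:
            raise ValueError(f"section {self.name}: nseg must be >= 1")
        if not 0.0 <= self.parent_x <= 1.0:
            raise ValueError(f"section {self.name}: parent_x outside [0, 1]")
        if self.stype not in _SWC_TYPES:
            raise ValueError(f"section {self.name}: unknown type {self.stype!r}")

    @property
    def metric_length(self) -> float:
        """Length contributed to path distances (0 for the point-like soma)."""
        return 0.0 if self.stype == "soma" else self.length

    @property
    def area(self) -> float:
        """Lateral membrane area in um^2 (pi * d * L)."""
        return math.pi * self.diameter * self.length


@dataclass(frozen=True)
class SiteAddress:
    """A point on the tree: a named section plus a fraction along it."""

    section: str
    x: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 1.0:
            raise ValueError(f"site fraction {self.x} outside [0, 1]")


class Morphology:
    """A rooted tree of :class:`Section` objects plus passive parameters."""

    def __init__(self, passive: PassiveParams | None = None) -> None:
        self.sections: dict[str, Section] = {}
        self.passive = passive or PassiveParams()
        self._root: str | None = None

    # -- construction ------------------------------------------------------

    def add(self, section: Section) -> Section:
        if section.name in self.sections:
            raise ValueError(f"duplicate section name {section.name!r}")
        if section.parent is None:
            if self._root is not None:
                raise ValueError("tree already has a root")
            self._root = section.name
        elif section.parent not in self.sections:
            raise ValueError(f"unknown parent {section.parent!r}")
        self.sections[section.name] = section
        return section

    @property
    def root(self) -> str:
        if self._root is None:
            raise ValueError("empty morphology")
        return self._root

    def __getitem__(self, name: str) -> Section:
        return self.sections[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sections

    def children(self, name: str) -> list[str]:
        return [s.name for s in self.sections.values() if s.parent == name]

    def ancestors(self, name: str) -> list[str]:
        """Chain of section names from ``name`` up to and including the root."""
        chain = [name]
        while self.sections[chain[-1]].parent is not None:
            chain.append(self.sections[chain[-1]].parent)  # type: ignore[arg-type]
        return chain

    # -- spatial queries ---------------------------------------------------

    def resolve(self, site: SiteAddress) -> SiteAddress:
        if site.section not in self.sections:
            raise KeyError(f"no section named {site.section!r}")
        return site

    def path_distance(self, a: SiteAddress, b: SiteAddress) -> float:
        """Length of the unique tree path between two points, in um."""
        a, b = self.resolve(a), self.resolve(b)
        if a.section == b.section:
            return abs(a.x - b.x) * self.sections[a.section].metric_length
        anc_a, anc_b = self.ancestors(a.section), self.ancestors(b.section)
        common = set(anc_a) & set(anc_b)
        lca = next(s for s in anc_a if s in common)

        def climb(site: SiteAddress) -> tuple[float, float]:
            """Walk up to the LCA; return (distance walked, arrival fraction)."""
            sec, x, dist = site.section, site.x, 0.0
            while sec != lca:
                s = self.sections[sec]
                dist += x * s.metric_length
                sec, x = s.parent, s.parent_x  # type: ignore[assignment]
            return dist, x

        da, xa = climb(a)
        db, xb = climb(b)
        return da + db + abs(xa - xb) * self.sections[lca].metric_length

    def resolve_um(self, kind: str, distance: float) -> SiteAddress:
        """Resolve a "``distance`` um from the soma" address.

        ``kind`` selects the path: ``"apical"`` follows the trunk and, beyond
        500 um, continues into the main tuft branch; ``"oblique"`` turns into
        the oblique dendrite at the 100 um junction; ``"basal"`` follows the
        basal main shaft and its first daughter.  This matches the common
        usage where "90 um from the soma" lies on the apical trunk.
        """
        paths = {
            "apical": ["apic_trunk0", "apic_trunk1", "tuft_a", "tuft_a_a"],
            "oblique": ["apic_trunk0", "oblique", "oblique2_a"],
            "basal": ["basal", "basal_a", "basal_a_a"],
        }
        if kind not in paths:
            raise KeyError(f"unknown path kind {kind!r}")
        if distance < 0:
            raise ValueError("distance must be >= 0")
        remaining = distance
        for name in paths[kind]:
            if name not in self.sections:
                continue
            sec = self.sections[name]
            if remaining <= sec.metric_length:
                return SiteAddress(name, remaining / sec.metric_length)
            remaining -= sec.metric_length
        raise ValueError(f"{distance} um exceeds the {kind} path")


# -- default cell ----------------------------------------------------------

#: Documented override keys for :func:`build_simplified_pyramidal` and their
#: default values (lengths/diameters in um).
DEFAULT_GEOMETRY = {
    "soma_diam": 18.5,
    "soma_len": 18.5,
    "axon_diam": 2.0,
    "axon_len": 3.0,
    "trunk_diam": 2.0,
    "trunk_prox_len": 100.0,
    "trunk_dist_len": 400.0,
    "trunk_prox_nseg": 19,
    "trunk_dist_nseg": 73,
    "branch_len": 300.0,
    "branch_nseg": 91,
    "basal_diam": 1.0,
    "basal_len": 150.0,
    "basal_nseg": 91,
    "daughter_ratio": 2.0 / 3.0,
    "cm": 0.75,
    "ra": 150.0,
    "rm": 40_000.0,
    "e_leak": -70.0,
}


def build_simplified_pyramidal(overrides: dict | None = None) -> Morphology:
    """Construct the default simplified pyramidal cell.

    Geometry: axon 2 x 3 um; soma 18.5 x 18.5 um; apical trunk 2 um diameter,
    split into 100 um (nseg 19) and 400 um (nseg 73) compartments at the
    oblique junction; oblique and tuft branches 300 um (nseg 91) with daughter
    diameters 2/3 of the mother; basal shaft 1 um diameter, basal branches
    150 um.  ``overrides`` may replace any key of :data:`DEFAULT_GEOMETRY`.
    """
    p = dict(DEFAULT_GEOMETRY)
    if overrides:
        unknown = set(overrides) - set(p)
        if unknown:
            raise KeyError(f"unknown morphology parameter(s): {sorted(unknown)}")
        p.update(overrides)
    for key, val in p.items():
        if key.endswith(("_diam", "_len")) or key in ("cm", "ra", "rm"):
            if val <= 0:
                raise ValueError(f"{key} must be > 0")

    r = p["daughter_ratio"]
    m = Morphology(PassiveParams(p["cm"], p["ra"], p["rm"], p["e_leak"]))
    m.add(Section("soma", p["soma_len"], p["soma_diam"], 1, "soma"))
    m.add(Section("axon", p["axon_len"], p["axon_diam"], 1, "axon",
                  parent="soma", parent_x=0.0))
    m.add(Section("apic_trunk0", p["trunk_prox_len"], p["trunk_diam"],
                  p["trunk_prox_nseg"], "apical", parent="soma", parent_x=1.0))
    m.add(Section("apic_trunk1", p["trunk_dist_len"], p["trunk_diam"],
                  p["trunk_dist_nseg"], "apical", parent="apic_trunk0"))
    # oblique pathway: first-order branch at the 100 um junction
    m.add(Section("oblique", p["branch_len"], p["trunk_diam"] * r,
                  p["branch_nseg"], "apical", parent="apic_trunk0"))
    for suffix in ("a", "b"):
        m.add(Section(f"oblique2_{suffix}", p["branch_len"],
                      p["trunk_diam"] * r * r, p["branch_nseg"], "apical",
                      parent="oblique"))
    # apical tuft: two first-order branches at 500 um, each with two daughters
    for suffix in ("a", "b"):
        m.add(Section(f"tuft_{suffix}", p["branch_len"], p["trunk_diam"] * r,
                      p["branch_nseg"], "apical", parent="apic_trunk1"))
        for sub in ("a", "b"):
            m.add(Section(f"tuft_{suffix}_{sub}", p["branch_len"],
                          p["trunk_diam"] * r * r, p["branch_nseg"], "apical",
                          parent=f"tuft_{suffix}"))
    # basal tree
    m.add(Section("basal", p["basal_len"], p["basal_diam"], p["basal_nseg"],
                  "basal", parent="soma", parent_x=0.0))
    for suffix in ("a", "b"):
        m.add(Section(f"basal_{suffix}", p["basal_len"], p["basal_diam"] * r,
                      p["basal_nseg"], "basal", parent="basal"))
        for sub in ("a", "b"):
            m.add(Section(f"basal_{suffix}_{sub}", p["basal_len"],
                          p["basal_diam"] * r * r, p["basal_nseg"], "basal",
                          parent=f"basal_{suffix}"))
    return m


def path_distance(morph: Morphology, a: SiteAddress, b: SiteAddress) -> float:
    """Module-level convenience wrapper around :meth:`Morphology.path_distance`."""
    return morph.path_distance(a, b)


# -- SWC export / import ---------------------------------------------------

_BRANCH_ANGLE = math.radians(35.0)


def _layout(morph: Morphology) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Synthesize straight-line 2-D coordinates (z = 0) for every section.

    The coordinates carry no physics (the model is a 1-D cable); they only
    give SWC viewers a plausible planar rendering.  Apical sections grow in
    +y, basal and axonal sections in -y, siblings fan out by a fixed angle.
    """
    coords: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    directions: dict[str, float] = {}

    def place(name: str, origin: np.ndarray, angle: float) -> None:
        sec = morph.sections[name]
        end = origin + sec.length * np.array(
            [math.sin(angle), math.cos(angle), 0.0])
        coords[name] = (origin, end)
        directions[name] = angle
        kids = morph.children(name)
        spread = _BRANCH_ANGLE if len(kids) > 1 else 0.0
        for i, kid in enumerate(kids):
            off = (i - (len(kids) - 1) / 2.0) * 2 * spread
            kx = morph.sections[kid].parent_x
            start = origin + kx * (end - origin)
            place(kid, start, angle + off)

    root = morph.root
    origin = np.zeros(3)
    coords[root] = (origin, origin)  # point soma
    for kid in morph.children(root):
        sec = morph.sections[kid]
        if sec.stype == "apical":
            base_angle = 0.0
        elif sec.stype == "axon":
            base_angle = math.pi + math.radians(20.0)
        else:
            base_angle = math.pi
        place(kid, origin.copy(), base_angle)
    return coords


def export_swc(morph: Morphology) -> str:
    """Serialize to standard 7-column SWC text.

    The soma becomes a single sample of radius diameter/2 with parent -1.
    Every other section contributes a proximal sample (at its attachment
    point) and a distal sample, so the inter-sample distance reproduces the
    section length exactly and a re-import round-trips path distances.
    """
    coords = _layout(morph)
    rows: list[str] = ["# id type x y z radius parent",
                       "# exported by dendgate (synthetic planar layout)"]
    ids: dict[str, int] = {}
    next_id = 1
    root = morph.root
    rs = morph.sections[root].diameter / 2.0
    rows.append(f"1 {_SWC_TYPES[morph.sections[root].stype]} 0.0 0.0 0.0 {rs:.4f} -1")
    ids[root] = 1
    next_id = 2
    # topological order (parents first)
    order = [s for s in morph.sections if s != root]
    order.sort(key=lambda n: len(morph.ancestors(n)))
    for name in order:
        sec = morph.sections[name]
        start, end = coords[name]
        t = _SWC_TYPES[sec.stype]
        radius = sec.diameter / 2.0
        pid = ids[sec.parent]  # distal sample of the parent (or soma sample)
        rows.append(f"{next_id} {t} {start[0]:.4f} {start[1]:.4f} {start[2]:.4f} "
                    f"{radius:.4f} {pid}")
        rows.append(f"{next_id + 1} {t} {end[0]:.4f} {end[1]:.4f} {end[2]:.4f} "
                    f"{radius:.4f} {next_id}")
        ids[name] = next_id + 1
        next_id += 2
    return "\n".join(rows) + "\n"


def import_swc(text: str, passive: PassiveParams | None = None) -> Morphology:
    """Rebuild a :class:`Morphology` from SWC text.

    Each non-soma sample becomes one section whose length is the distance to
    its parent sample; zero-length connector samples (proximal duplicates) are
    merged away.  Discretization is not stored in SWC, so imported sections
    get nseg = 1; geometry and path distances are preserved.
    """
    samples: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC row: {line!r}")
        sid, stype = int(parts[0]), int(parts[1])
        xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        samples[sid] = (stype, xyz, float(parts[5]), int(parts[6]))

    m = Morphology(passive)
    # map sample id -> section name it terminates in (or attaches to)
    owner: dict[int, str] = {}
    for sid in sorted(samples):
        stype, xyz, radius, pid = samples[sid]
        kind = _SWC_TYPES_INV.get(stype, "apical")
        if pid == -1:
            name = "soma" if kind == "soma" else f"root{sid}"
            m.add(Section(name, 2 * radius, 2 * radius, 1, kind))
            owner[sid] = name
            continue
        length = float(np.linalg.norm(xyz - samples[pid][1]))
        if length < 1e-9:
            owner[sid] = owner[pid]  # connector sample: merge into parent
            continue
        name = f"swc{sid}"
        m.add(Section(name, length, 2 * radius, 1, kind,
                      parent=owner[pid], parent_x=1.0))
        owner[sid] = name
    return m
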