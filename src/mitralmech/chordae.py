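"""Chordae-tendineae network model, rupture scenarios, and statics.

The mitral chordae apparatus is represented as a network of tension-only
truss members (chords) running from the two papillary-muscle (PM) tips —
anterolateral (APM) and posteromedial (PPM) — to insertion points on the
ventricular surface of the two leaflets.  Chords are classified into five
groups by insertion zone:

* ``AML_marginal`` / ``AML_strut`` — anterior leaflet free edge / thick strut
  chords;
* ``PML_marginal`` / ``PML_intermediate`` / ``PML_basal`` — posterior leaflet
  free edge, rough zone, and base.

The posterior leaflet is divided into the three scallops P1 (anterolateral),
P2 (central) and P3 (posteromedial).  Rupture scenarios remove named subsets
of chords: isolated single-scallop prolapse removes the marginal and
intermediate chords of one scallop; "partial" double-scallop prolapse adds
the adjacent half of a second scallop; "total" double-scallop prolapse adds
the basal chords of both scallops.

The equilibrium solver finds nodal positions at which every free node is in
force balance under prescribed insertion loads, with segment tensions given
by the incompressible Ogden chordal law (zero in compression).  Geometry is
in millimetres (annulus plane z = 0, ventricle at z < 0), forces in newtons,
pressures converted at 1 mmHg = 133.322 Pa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constitutive import OgdenParams, ogden_chord_force
from .errors import (
    ConvergenceError,
    NetworkSpecError,
    ScenarioError,
    SingularityError,
    UndefinedQuantityError,
    ValidationError,
)

__all__ = [
    "GROUPS",
    "SCALLOPS",
    "SCENARIO_NAMES",
    "MMHG_TO_MPA",
    "Node",
    "Segment",
    "ChordaeNetwork",
    "NetworkSpec",
    "RuptureScenario",
    "LoadCase",
    "TensionSolution",
    "default_table_spec",
    "build_network",
    "scenario_segments",
    "loads_from_pressure",
    "solve_static_tensions",
    "pm_reactions",
    "group_force",
    "pm_force_distribution",
    "compare_scenarios",
]

GROUPS = (
    "AML_marginal",
    "AML_strut",
    "PML_marginal",
    "PML_intermediate",
    "PML_basal",
)
SCALLOPS = ("P1", "P2", "P3", "AML")
PMS = ("APM", "PPM")
SCENARIO_NAMES = (
    "control",
    "isolated_P3",
    "isolated_P1",
    "partial_P2P1",
    "isolated_P2",
    "partial_P2P3",
    "total_P2P3",
    "total_P2P1",
)

MMHG_TO_MPA = 133.322e-6  # 1 mmHg in MPa (= N/mm^2)

# Posterior leaflet angular sectors (degrees, annulus-plane polar angle).
# P1 borders the anterolateral commissure, P3 the posteromedial one.
_PML_SPAN = (100.0, 260.0)
_SCALLOP_EDGES = {"P1": (100.0, 153.3333), "P2": (153.3333, 206.6667), "P3": (206.6667, 260.0)}


@dataclass
class Node:
    id: str
    xyz: np.ndarray  # mm
    role: str  # pm_origin | branch | insertion
    anchor: str  # APM | PPM | leaflet

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)
        if self.role not in ("pm_origin", "branch", "insertion"):
            raise ValidationError(f"unknown node role {self.role!r}")
        if self.anchor not in ("APM", "PPM", "leaflet"):
            raise ValidationError(f"unknown node anchor {self.anchor!r}")


@dataclass
class Segment:
    id: str
    n1: str
    n2: str
    group: str
    scallop: str
    area0: float  # mm^2
    rest_length: float  # mm
    pm: str  # APM | PPM (source papillary muscle)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown chordae group {self.group!r}")
        if self.scallop not in SCALLOPS:
            raise ValidationError(f"unknown scallop {self.scallop!r}")
        if self.pm not in PMS:
            raise ValidationError(f"unknown pm source {self.pm!r}")
        if not self.rest_length > 0:
            raise ValidationError("rest_length must be positive")
        if not self.area0 > 0:
            raise ValidationError("area0 must be positive")


@dataclass
class ChordaeNetwork:
    """Nodes, segments and chord paths of the chordal apparatus.

    ``chord_paths`` maps a chord id to the ordered list of segment ids from
    the PM origin to the leaflet insertion (at most 10 segments per chord).
    """

    nodes: dict[str, Node]
    segments: dict[str, Segment]
    chord_paths: dict[str, list[str]]

    def __post_init__(self) -> None:
        for seg in self.segments.values():
            if seg.n1 not in self.nodes or seg.n2 not in self.nodes:
                raise ValidationError(f"segment {seg.id} references unknown node")
        for cid, path in self.chord_paths.items():
            if len(path) > 10:
                raise ValidationError(f"chord {cid} has more than 10 segments")
            for sid in path:
                if sid not in self.segments:
                    raise ValidationError(f"chord {cid} references unknown segment {sid}")

    # -- queries ---------------------------------------------------------

    def pm_origin_nodes(self) -> list[str]:
        return [nid for nid, n in self.nodes.items() if n.role == "pm_origin"]

    def insertion_nodes(self) -> list[str]:
        return [nid for nid, n in self.nodes.items() if n.role == "insertion"]

    def chord_group(self, chord_id: str) -> str:
        return self.segments[self.chord_paths[chord_id][0]].group

    def chord_pm(self, chord_id: str) -> str:
        return self.segments[self.chord_paths[chord_id][0]].pm

    def chord_insertion_node(self, chord_id: str) -> str:
        last = self.segments[self.chord_paths[chord_id][-1]]
        return last.n2

    def chord_origin_node(self, chord_id: str) -> str:
        first = self.segments[self.chord_paths[chord_id][0]]
        return first.n1

    def insertion_counts(self) -> dict[tuple[str, str], int]:
        """Number of leaflet insertions per (group, pm)."""
        out: dict[tuple[str, str], int] = {}
        for cid in self.chord_paths:
            key = (self.chord_group(cid), self.chord_pm(cid))
            out[key] = out.get(key, 0) + 1
        return out

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        data = {
            "nodes": [
                {
                    "id": n.id,
                    "xyz_mm": [float(v) for v in n.xyz],
                    "role": n.role,
                    "anchor": n.anchor,
                }
                for n in self.nodes.values()
            ],
            "segments": [
                {
                    "id": s.id,
                    "n1": s.n1,
                    "n2": s.n2,
                    "group": s.group,
                    "scallop": s.scallop,
                    "area0_mm2": s.area0,
                    "rest_length_mm": s.rest_length,
                    "pm": s.pm,
                }
                for s in self.segments.values()
            ],
            "chords": [
                {"id": cid, "segments": list(path)}
                for cid, path in self.chord_paths.items()
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(data, indent=1))
        return data

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "ChordaeNetwork":
        data = source if isinstance(source, dict) else json.loads(Path(source).read_text())
        nodes = {
            d["id"]: Node(d["id"], np.array(d["xyz_mm"]), d["role"], d["anchor"])
            for d in data["nodes"]
        }
        segments = {
            d["id"]: Segment(
                d["id"], d["n1"], d["n2"], d["group"], d["scallop"],
                float(d["area0_mm2"]), float(d["rest_length_mm"]), d["pm"],
            )
            for d in data["segments"]
        }
        chords = {d["id"]: list(d["segments"]) for d in data["chords"]}
        return cls(nodes, segments, chords)


@dataclass(frozen=True)
class NetworkSpec:
    """Counts and geometry parameters for the idealized chordal apparatus.

    ``origin_counts`` maps (pm, leaflet) to the number of PM-tip chordae
    origins; ``insertion_counts`` maps (group, pm) to the number of leaflet
    insertions.  The default reproduces the reference apparatus: 17 origins
    total and group areas 0.71 / 2.05 / 0.38 mm^2 for basal+intermediate /
    strut / marginal chordae.
    """

    origin_counts: Mapping[tuple[str, str], int]
    insertion_counts: Mapping[tuple[str, str], int]
    areas_mm2: Mapping[str, float] = field(
        default_factory=lambda: {
            "AML_marginal": 0.38,
            "AML_strut": 2.05,
            "PML_marginal": 0.38,
            "PML_intermediate": 0.71,
            "PML_basal": 0.71,
        }
    )
    annulus_semi_axis_cc_mm: float = 19.0  # commissural semi-axis (x)
    annulus_semi_axis_ap_mm: float = 15.0  # anteroposterior semi-axis (y)
    pm_depth_mm: float = 22.0
    pm_radius_mm: float = 12.0
    target_segment_length_mm: float = 1.5
    jitter_mm: float = 0.0

    def __post_init__(self) -> None:
        for k, v in {**self.origin_counts, **self.insertion_counts}.items():
            if v < 0:
                raise NetworkSpecError(f"negative count for {k}")
        for pm in PMS:
            for leaflet in ("AML", "PML"):
                n_or = self.origin_counts.get((pm, leaflet), 0)
                n_ins = sum(
                    n
                    for (g, p), n in self.insertion_counts.items()
                    if p == pm and g.startswith(leaflet)
                )
                if 0 < n_ins < n_or:
                    raise NetworkSpecError(
                        f"{pm}/{leaflet}: {n_ins} insertions cannot occupy "
                        f"{n_or} origins without branch sharing"
                    )


def default_table_spec(**overrides) -> NetworkSpec:
    """The reference chordal topology: 17 PM-tip origins (APM 5+4, PPM 3+5)
    and per-group insertion counts (AML marginal 8/6, AML strut 3/4, PML
    marginal 7/6, PML intermediate 7/1, PML basal 5/6 for APM/PPM)."""
    return NetworkSpec(
        origin_counts={
            ("APM", "AML"): 5,
            ("PPM", "AML"): 3,
            ("APM", "PML"): 4,
            ("PPM", "PML"): 5,
        },
        insertion_counts={
            ("AML_marginal", "APM"): 8,
            ("AML_marginal", "PPM"): 6,
            ("AML_strut", "APM"): 3,
            ("AML_strut", "PPM"): 4,
            ("PML_marginal", "APM"): 7,
            ("PML_marginal", "PPM"): 6,
            ("PML_intermediate", "APM"): 7,
            ("PML_intermediate", "PPM"): 1,
            ("PML_basal", "APM"): 5,
            ("PML_basal", "PPM"): 6,
        },
        **overrides,
    )


@dataclass(frozen=True)
class RuptureScenario:
    """A named set of removed (ruptured) chordae segments."""

    name: str
    removed_segments: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "removed_segments", frozenset(self.removed_segments))
        if self.name == "control" and self.removed_segments:
            raise ScenarioError("control scenario must remove nothing")


@dataclass
class LoadCase:
    """Static load on the chordal apparatus.

    ``insertion_loads`` are 3-vectors in newtons applied at insertion nodes
    (the leaflet pull transmitted down each chord); ``pm_displacements``
    optionally move the PM tips (mm) between diastolic and systolic
    positions.
    """

    transmitral_pressure: float  # mmHg
    insertion_loads: dict[str, np.ndarray]
    pm_displacements: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.transmitral_pressure < 0:
            raise ValidationError("pressure must be non-negative")
        self.insertion_loads = {
            k: np.asarray(v, dtype=float).reshape(3)
            for k, v in self.insertion_loads.items()
        }
        if self.pm_displacements is not None:
            self.pm_displacements = {
                k: np.asarray(v, dtype=float).reshape(3)
                for k, v in self.pm_displacements.items()
            }

    def validate_against(self, network: ChordaeNetwork) -> None:
        for nid in self.insertion_loads:
            node = network.nodes.get(nid)
            if node is None or node.role != "insertion":
                raise ValidationError(f"load applied at non-insertion node {nid!r}")


@dataclass
class TensionSolution:
    """Converged segment tensions (N, >= 0) and free-node displacements (mm)."""

    segment_tensions: dict[str, float]
    node_displacements: dict[str, np.ndarray]
    converged: bool
    residual: float
    slack_chords: tuple[str, ...] = ()

    def to_frame(self, network: ChordaeNetwork) -> pd.DataFrame:
        rows = []
        for sid, t in self.segment_tensions.items():
            s = network.segments[sid]
            rows.append(
                {"segment_id": sid, "group": s.group, "scallop": s.scallop,
                 "pm": s.pm, "tension_N": t}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry generation
# ---------------------------------------------------------------------------


def _annulus_point(phi_deg: float, spec: NetworkSpec, radial_frac: float, z: float) -> np.ndarray:
    phi = np.radians(phi_deg)
    r = 1.0 / np.sqrt(
        (np.cos(phi) / spec.annulus_semi_axis_cc_mm) ** 2
        + (np.sin(phi) / spec.annulus_semi_axis_ap_mm) ** 2
    )
    return np.array([radial_frac * r * np.cos(phi), radial_frac * r * np.sin(phi), z])


# radial position (fraction of local annulus radius) and depth of each
# insertion zone: marginal chords insert at the free edge (innermost,
# hanging below the annulus plane), basal chords near the leaflet base.
_ZONE_GEOM = {
    "AML_marginal": (0.45, -3.0),
    "AML_strut": (0.62, -2.0),
    "PML_marginal": (0.50, -3.0),
    "PML_intermediate": (0.68, -1.5),
    "PML_basal": (0.88, -0.5),
}

# angular span of insertions served by each PM, per leaflet (degrees)
_PM_SPANS = {
    ("APM", "PML"): (102.0, 180.0),
    ("PPM", "PML"): (180.0, 258.0),
    ("APM", "AML"): (10.0, 95.0),
    ("PPM", "AML"): (265.0, 350.0),
}


def _scallop_of(phi_deg: float) -> str:
    phi = phi_deg % 360.0
    for name, (lo, hi) in _SCALLOP_EDGES.items():
        if lo <= phi < hi:
            return name
    return "AML"


def build_network(
    spec: NetworkSpec | None = None, seed: int = 0
) -> ChordaeNetwork:
    """Construct an idealized chordal apparatus from a count specification.

    The annulus is a D-shaped (elliptical) curve in the z = 0 plane with the
    ventricle at z < 0; the two PM tips sit below the commissures.  Each
    insertion is connected to a PM-tip origin of its leaflet (origins are
    shared round-robin, emulating chordae fanning out from each PM head)
    by a polyline chord subdivided into at most 10 segments near the
    target segment length.  Deterministic for a fixed seed.
    """
    spec = spec or default_table_spec()
    rng = np.random.default_rng(seed)
    nodes: dict[str, Node] = {}
    segments: dict[str, Segment] = {}
    chords: dict[str, list[str]] = {}

    pm_tip = {
        "APM": _annulus_point(115.0, spec, spec.pm_radius_mm / spec.annulus_semi_axis_cc_mm, 0.0),
        "PPM": _annulus_point(245.0, spec, spec.pm_radius_mm / spec.annulus_semi_axis_cc_mm, 0.0),
    }
    for pm in PMS:
        pm_tip[pm][2] = -spec.pm_depth_mm

    # PM-tip origin nodes, one ring of points per (pm, leaflet)
    origins: dict[tuple[str, str], list[str]] = {}
    for (pm, leaflet), n_or in sorted(spec.origin_counts.items()):
        ids = []
        for j in range(n_or):
            nid = f"{pm}_{leaflet}_origin{j}"
            # small deterministic spread of origins over the PM tip
            ang = 2 * np.pi * j / max(n_or, 1)
            offset = 1.2 * np.array([np.cos(ang), np.sin(ang), 0.1 * j])
            nodes[nid] = Node(nid, pm_tip[pm] + offset, "pm_origin", pm)
            ids.append(nid)
        origins[(pm, leaflet)] = ids

    for (group, pm), n_ins in sorted(spec.insertion_counts.items()):
        if n_ins == 0:
            continue
        leaflet = "AML" if group.startswith("AML") else "PML"
        origin_ids = origins.get((pm, leaflet), [])
        if not origin_ids:
            raise NetworkSpecError(f"no origins for {pm}/{leaflet} but insertions requested")
        lo, hi = _PM_SPANS[(pm, leaflet)]
        radial_frac, z_ins = _ZONE_GEOM[group]
        phis = np.linspace(lo, hi, n_ins + 2)[1:-1]  # interior, avoids commissures
        for j, phi in enumerate(phis):
            ins_id = f"{group}_{pm}_ins{j}"
            p_ins = _annulus_point(float(phi), spec, radial_frac, z_ins)
            scallop = _scallop_of(float(phi)) if leaflet == "PML" else "AML"
            nodes[ins_id] = Node(ins_id, p_ins, "insertion", "leaflet")
            origin_id = origin_ids[j % len(origin_ids)]
            p0 = nodes[origin_id].xyz
            length = float(np.linalg.norm(p_ins - p0))
            n_seg = int(min(max(2, round(length / spec.target_segment_length_mm)), 10))
            cid = f"chord_{group}_{pm}_{j}"
            path: list[str] = []
            prev = origin_id
            for k in range(1, n_seg + 1):
                frac = k / n_seg
                p = p0 + frac * (p_ins - p0)
                if k < n_seg:
                    bid = f"{cid}_b{k}"
                    if spec.jitter_mm > 0:
                        p = p + rng.normal(scale=spec.jitter_mm, size=3)
                    nodes[bid] = Node(bid, p, "branch", "leaflet")
                    nxt = bid
                else:
                    nxt = ins_id
                sid = f"{cid}_s{k}"
                rest = float(np.linalg.norm(nodes[nxt].xyz - nodes[prev].xyz))
                segments[sid] = Segment(
                    sid, prev, nxt, group, scallop, spec.areas_mm2[group], rest, pm
                )
                path.append(sid)
                prev = nxt
            chords[cid] = path

    return ChordaeNetwork(nodes, segments, chords)


# ---------------------------------------------------------------------------
# rupture scenarios
# ---------------------------------------------------------------------------

_ALIAS = {"P2/P3": "total_P2P3", "P2/P1": "total_P2P1"}


def _chord_phi(network: ChordaeNetwork, chord_id: str) -> float:
    p = network.nodes[network.chord_insertion_node(chord_id)].xyz
    return float(np.degrees(np.arctan2(p[1], p[0])) % 360.0)


def _chords_matching(
    network: ChordaeNetwork,
    groups: Iterable[str],
    scallop: str,
    half: str | None = None,
) -> set[str]:
    """Chords of the given groups inserting on a scallop (optionally only
    the half adjacent to the named neighbouring scallop)."""
    lo, hi = _SCALLOP_EDGES[scallop]
    mid = 0.5 * (lo + hi)
    out: set[str] = set()
    for cid in network.chord_paths:
        seg0 = network.segments[network.chord_paths[cid][0]]
        if seg0.group not in groups or seg0.scallop != scallop:
            continue
        if half is not None:
            phi = _chord_phi(network, cid)
            lo2, hi2 = _SCALLOP_EDGES[half]
            toward_neighbor = (phi >= mid) if hi2 >= hi else (phi <= mid)
            if not toward_neighbor:
                continue
        out.add(cid)
    return out


def scenario_segments(network: ChordaeNetwork, name: str) -> RuptureScenario:
    """Removed-segment set for a named rupture scenario.

    ``isolated_X`` ruptures every PML marginal and intermediate chord of
    scallop X; ``partial_P2Y`` adds the P2-adjacent half of scallop Y;
    ``total_P2Y`` adds the basal chords of P2 and Y.
    """
    name = _ALIAS.get(name, name)
    if name not in SCENARIO_NAMES:
        raise ScenarioError(f"unknown scenario {name!r}; valid: {SCENARIO_NAMES}")
    mi = ("PML_marginal", "PML_intermediate")
    chords: set[str] = set()
    if name == "control":
        pass
    elif name.startswith("isolated_"):
        chords = _chords_matching(network, mi, name.removeprefix("isolated_"))
    else:
        other = "P1" if name.endswith("P2P1") else "P3"
        chords = _chords_matching(network, mi, "P2")
        chords |= _chords_matching(network, mi, other, half="P2")
        if name.startswith("total_"):
            chords |= _chords_matching(network, ("PML_basal",), "P2")
            chords |= _chords_matching(network, ("PML_basal",), other)
    removed = frozenset(
        sid for cid in chords for sid in network.chord_paths[cid]
    )
    return RuptureScenario(name=name, removed_segments=removed)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def loads_from_pressure(
    network: ChordaeNetwork,
    pressure_mmhg: float = 120.0,
    tributary_area_mm2: float | Mapping[str, float] = 20.0,
    scenario: RuptureScenario | None = None,
) -> LoadCase:
    """Insertion loads from a peak-systolic transmitral pressure.

    Each insertion node receives force = pressure x its tributary leaflet
    area, directed along its chord (origin to insertion) — the direction in
    which a pressurized leaflet pulls its chord taut.  ``tributary_area_mm2``
    is a scalar or an insertion-node-id map.  Insertions whose chords are
    fully removed in ``scenario`` receive no load.
    """
    removed = scenario.removed_segments if scenario else frozenset()
    p_mpa = pressure_mmhg * MMHG_TO_MPA
    loads: dict[str, np.ndarray] = {}
    for cid, path in network.chord_paths.items():
        if all(sid in removed for sid in path):
            continue
        ins = network.chord_insertion_node(cid)
        org = network.chord_origin_node(cid)
        d = network.nodes[ins].xyz - network.nodes[org].xyz
        d = d / np.linalg.norm(d)
        area = (
            tributary_area_mm2.get(ins, 0.0)
            if isinstance(tributary_area_mm2, Mapping)
            else float(tributary_area_mm2)
        )
        loads[ins] = loads.get(ins, np.zeros(3)) + p_mpa * area * d
    return LoadCase(transmitral_pressure=pressure_mmhg, insertion_loads=loads)


# ---------------------------------------------------------------------------
# equilibrium solver
# ---------------------------------------------------------------------------


def _tension_and_modulus(
    stretch: float, ogden: OgdenParams, area0: float
) -> tuple[float, float]:
    """Tension T(stretch) and tangent dT/dstretch of a tension-only chord."""
    if stretch <= 1.0:
        return 0.0, 0.0
    T = ogden_chord_force(stretch, ogden, area0)
    lam = stretch
    dP = sum(
        (2.0 * mu / a)
        * ((a - 1.0) * lam ** (a - 2.0) + (a / 2.0 + 1.0) * lam ** (-a / 2.0 - 2.0))
        for mu, a in ogden.terms
    )
    return T, area0 * dP


def _tension_modulus_at_unity(ogden: OgdenParams, area0: float) -> float:
    return area0 * sum(
        (2.0 * mu / a) * ((a - 1.0) + (a / 2.0 + 1.0)) for mu, a in ogden.terms
    )


def solve_static_tensions(
    network: ChordaeNetwork,
    scenario: RuptureScenario,
    load: LoadCase,
    ogden: OgdenParams,
    *,
    tol: float = 1e-8,
    max_iter: int = 50,
    n_load_steps: int = 10,
    max_step_mm: float = 1.0,
) -> TensionSolution:
    """Quasi-static nodal equilibrium of the tension-only chordal truss.

    Newton's method with incremental load stepping; PM-origin nodes are
    fixed (or displaced per the load case), all other nodes are free.
    Removed segments carry no force.  Insertion nodes disconnected from
    every PM by the rupture are reported as slack chords and excluded from
    the system.  Converges when the free-node residual falls below
    ``tol`` x total applied load.
    """
    load.validate_against(network)
    removed = scenario.removed_segments
    for sid in removed:
        if sid not in network.segments:
            raise ScenarioError(f"scenario removes unknown segment {sid!r}")
    active = [s for sid, s in network.segments.items() if sid not in removed]

    # connectivity to a PM origin over active segments
    import collections

    adj: dict[str, list[str]] = collections.defaultdict(list)
    for s in active:
        adj[s.n1].append(s.n2)
        adj[s.n2].append(s.n1)
    anchored: set[str] = set()
    stack = list(network.pm_origin_nodes())
    while stack:
        n = stack.pop()
        if n in anchored:
            continue
        anchored.add(n)
        stack.extend(adj[n])

    slack_chords = tuple(
        sorted(
            cid
            for cid in network.chord_paths
            if network.chord_insertion_node(cid) not in anchored
        )
    )
    active = [s for s in active if s.n1 in anchored and s.n2 in anchored]

    free = sorted(
        n for n in anchored if network.nodes[n].role != "pm_origin"
    )
    index = {nid: i for i, nid in enumerate(free)}
    n_dof = 3 * len(free)

    X0 = {nid: network.nodes[nid].xyz.copy() for nid in network.nodes}
    pm_disp = load.pm_displacements or {}

    ext_full = np.zeros(n_dof)
    for nid, f in load.insertion_loads.items():
        if nid in index:
            ext_full[3 * index[nid] : 3 * index[nid] + 3] = f
    total_load = float(np.sum(np.abs(ext_full))) or 1.0

    def positions(u: np.ndarray, scale: float) -> dict[str, np.ndarray]:
        pos = {}
        for nid in anchored:
            node = network.nodes[nid]
            if node.role == "pm_origin":
                d = pm_disp.get(node.anchor, np.zeros(3))
                pos[nid] = X0[nid] + scale * d
            else:
                i = index[nid]
                pos[nid] = X0[nid] + u[3 * i : 3 * i + 3]
        return pos

    def assemble(u: np.ndarray, scale: float):
        pos = positions(u, scale)
        R = scale * ext_full.copy()
        K = np.zeros((n_dof, n_dof))
        tensions: dict[str, float] = {}
        for s in active:
            xa, xb = pos[s.n1], pos[s.n2]
            dvec = xb - xa
            ell = float(np.linalg.norm(dvec))
            d = dvec / ell
            lam = ell / s.rest_length
            T, dT = _tension_and_modulus(lam, ogden, s.area0)
            tensions[s.id] = T
            # At lam = 1 (the stress-free start) the one-sided tangent is the
            # tension-side modulus; truly slack chords keep a small fictitious
            # axial stiffness so Newton stays well-posed. The residual always
            # uses the true (zero) tension, so equilibrium is unaffected.
            k_unity = _tension_modulus_at_unity(ogden, s.area0)
            if lam > 1.0:
                k_ax = max(dT, 1e-6 * k_unity) / s.rest_length
            elif lam >= 1.0 - 1e-9:
                k_ax = k_unity / s.rest_length
            else:
                k_ax = 1e-3 * k_unity / s.rest_length
            k_geo = T / ell
            D = np.outer(d, d)
            Ke = k_ax * D + k_geo * (np.eye(3) - D)
            # transverse regularizer: keeps straight stress-free polylines
            # non-singular; vanishes relative to real stiffness once loaded
            Ke = Ke + 1e-8 * k_ax * np.eye(3)
            fa = T * d  # force on node a, pulls toward b
            ia = index.get(s.n1)
            ib = index.get(s.n2)
            if ia is not None:
                R[3 * ia : 3 * ia + 3] += fa
                K[3 * ia : 3 * ia + 3, 3 * ia : 3 * ia + 3] += Ke
            if ib is not None:
                R[3 * ib : 3 * ib + 3] -= fa
                K[3 * ib : 3 * ib + 3, 3 * ib : 3 * ib + 3] += Ke
            if ia is not None and ib is not None:
                K[3 * ia : 3 * ia + 3, 3 * ib : 3 * ib + 3] -= Ke
                K[3 * ib : 3 * ib + 3, 3 * ia : 3 * ia + 3] -= Ke
        return R, K, tensions

    u = np.zeros(n_dof)
    history: list[float] = []
    tensions: dict[str, float] = {}
    if n_dof > 0:
        for step in range(1, n_load_steps + 1):
            scale = step / n_load_steps
            for it in range(max_iter):
                R, K, tensions = assemble(u, scale)
                rnorm = float(np.linalg.norm(R))
                history.append(rnorm)
                if rnorm <= tol * total_load:
                    break
                try:
                    du = np.linalg.solve(K, R)
                except np.linalg.LinAlgError:
                    diag = np.array(
                        [np.linalg.norm(K[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]) for i in range(len(free))]
                    )
                    raise SingularityError(free[int(np.argmin(diag))]) from None
                if not np.all(np.isfinite(du)):
                    raise ConvergenceError(
                        f"non-finite Newton update at load step {step}", history
                    )
                # trust-region style cap: slack (regularized) directions can
                # produce arbitrarily long updates during large rotations
                nodal = du.reshape(-1, 3)
                worst = float(np.linalg.norm(nodal, axis=1).max())
                if worst > max_step_mm:
                    du = du * (max_step_mm / worst)
                u = u + du
            else:
                raise ConvergenceError(
                    f"no convergence in {max_iter} iterations at load step "
                    f"{step}/{n_load_steps} (residual {history[-1]:.3e} N)",
                    history,
                )
        R, _, tensions = assemble(u, 1.0)
        residual = float(np.linalg.norm(R))
    else:
        residual = 0.0

    seg_t = {sid: 0.0 for sid in network.segments}
    seg_t.update({sid: float(t) for sid, t in tensions.items()})
    for sid in removed:
        seg_t[sid] = 0.0

    disp = {nid: np.zeros(3) for nid in network.nodes}
    for nid, i in index.items():
        disp[nid] = u[3 * i : 3 * i + 3].copy()
    return TensionSolution(
        segment_tensions=seg_t,
        node_displacements=disp,
        converged=True,
        residual=residual,
        slack_chords=slack_chords,
    )


def pm_reactions(
    network: ChordaeNetwork, solution: TensionSolution
) -> dict[str, np.ndarray]:
    """Support reaction (N) at each papillary muscle.

    The chords pull each fixed origin node toward the leaflets; the reaction
    is the equal-and-opposite force the PM must supply, so for a converged
    solution the reactions sum to minus the applied insertion loads.
    """
    pos = {
        nid: network.nodes[nid].xyz + solution.node_displacements.get(nid, np.zeros(3))
        for nid in network.nodes
    }
    out = {pm: np.zeros(3) for pm in PMS}
    for s in network.segments.values():
        T = solution.segment_tensions.get(s.id, 0.0)
        if T == 0.0:
            continue
        for end, other in ((s.n1, s.n2), (s.n2, s.n1)):
            node = network.nodes[end]
            if node.role == "pm_origin":
                d = pos[other] - pos[end]
                out[node.anchor] = out[node.anchor] - T * d / np.linalg.norm(d)
    return out


def group_force(
    network: ChordaeNetwork,
    solution: TensionSolution,
    group: str,
    pm_source: str | None = None,
) -> tuple[np.ndarray, float]:
    """Net force vector and magnitude (N) carried by a chordae group.

    Sums, over every chord of the group (optionally restricted to one PM),
    the tension of its origin-adjacent segment times the unit segment
    direction (pointing from the PM origin toward the leaflet) in the
    deformed configuration.
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown chordae group {group!r}")
    pos = {
        nid: network.nodes[nid].xyz + solution.node_displacements.get(nid, np.zeros(3))
        for nid in network.nodes
    }
    total = np.zeros(3)
    for cid, path in network.chord_paths.items():
        s0 = network.segments[path[0]]
        if s0.group != group or (pm_source is not None and s0.pm != pm_source):
            continue
        T = solution.segment_tensions.get(s0.id, 0.0)
        if T == 0.0:
            continue
        d = pos[s0.n2] - pos[s0.n1]
        total = total + T * d / np.linalg.norm(d)
    return total, float(np.linalg.norm(total))


def pm_force_distribution(
    network: ChordaeNetwork, solution: TensionSolution
) -> pd.DataFrame:
    """Percentage of each PM's total chordal tension carried per group.

    Returns a (PM x group) table of percentages; each PM row sums to 100.
    """
    sums: dict[str, dict[str, float]] = {}
    for cid, path in network.chord_paths.items():
        s0 = network.segments[path[0]]
        sums.setdefault(s0.pm, {g: 0.0 for g in GROUPS})
        sums[s0.pm][s0.group] += solution.segment_tensions.get(s0.id, 0.0)
    rows = {}
    for pm in (p for p in PMS if p in sums):
        total = sum(sums[pm].values())
        if total <= 0:
            raise UndefinedQuantityError(
                f"all chords from {pm} are slack; force distribution undefined"
            )
        rows[pm] = {g: 100.0 * sums[pm][g] / total for g in GROUPS}
    return pd.DataFrame.from_dict(rows, orient="index")[list(GROUPS)]


def compare_scenarios(
    network: ChordaeNetwork,
    scenarios: Sequence[RuptureScenario],
    load: LoadCase,
    ogden: OgdenParams,
    **solver_kwargs,
) -> pd.DataFrame:
    """Group-force magnitudes per scenario and percent change vs. control.

    Each scenario is solved under loads restricted to its surviving chords
    (a ruptured chord no longer transmits leaflet load).
    """
    names = [sc.name for sc in scenarios]
    if "control" not in names:
        raise ScenarioError("scenario list must include the control")
    rows: dict[str, dict[str, float]] = {}
    for sc in scenarios:
        if sc.removed_segments:
            # ruptured chords no longer transmit leaflet load: drop loads at
            # insertions whose every chord is removed
            keep = {
                network.chord_insertion_node(cid)
                for cid, path in network.chord_paths.items()
                if not all(sid in sc.removed_segments for sid in path)
            }
            case = LoadCase(
                transmitral_pressure=load.transmitral_pressure,
                insertion_loads={
                    n: f for n, f in load.insertion_loads.items() if n in keep
                },
                pm_displacements=load.pm_displacements,
            )
        else:
            case = load
        sol = solve_static_tensions(network, sc, case, ogden, **solver_kwargs)
        rows[sc.name] = {
            g: group_force(network, sol, g)[1] for g in GROUPS
        }
    df = pd.DataFrame.from_dict(rows, orient="index")[list(GROUPS)]
    ctrl = df.loc["control"]
    for g in GROUPS:
        base = ctrl[g]
        df[f"{g}_pct_change"] = (
            100.0 * (df[g] - base) / base if base > 0 else np.nan
        )
    return df
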