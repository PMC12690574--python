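"""Synthetic receptors and programmed multicopy trajectories.

Every stage of the pipeline is testable without an MD engine or any
download: a coarse bead "protein" (backbone + sidechain bead per residue,
on a sphere, with concave pockets at controlled anchor directions), a
four-atom polar fragment, and kinematic trajectories in which each ligand
copy follows a programmed schedule of binding/unbinding events with
seeded noise.  The ground truth (residence times, contact residues, best
site) is derived analytically from the event schedule alone, so the
pipeline's output can be checked against values the trajectory generator
never computes through the pipeline's own code paths.

The trajectories are kinematic (programmed positions plus noise), not
dynamical; descriptors that need energetics use the assigned toy charges
and Lennard-Jones parameters, so the energy ordering between programmed
"tight" and "loose" binding is controlled by placement distance and
charge magnitudes.  A small decorative set of waters and counterions is
included to exercise solvent stripping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_io import (
    AtomRecord,
    Frame,
    GenerationError,
    Topology,
    Trajectory,
    ValidationError,
)

#: Toy Lennard-Jones parameters (epsilon kcal/mol, rmin/2 Å) by element.
TOY_LJ = {"C": (0.1094, 1.9080), "N": (0.1700, 1.8240),
          "O": (0.2100, 1.6612), "H": (0.0157, 0.6000),
          "S": (0.2500, 2.0000), "NA": (0.0874, 1.3690)}

#: Fragment template: name, element, offset from the central atom (Å),
#: partial charge.  The central N carries the repulsive-centre flag (N99);
#: the N-H vector points along -z so a bound pose directs the hydrogen at
#: the pocket's central acceptor bead.
LIGAND_TEMPLATE = [
    ("N1", "N", np.array([0.0, 0.0, 0.0]), -0.20),
    ("H1", "H", np.array([0.0, 0.0, -1.0]), 0.35),
    ("C1", "C", np.array([1.4, 0.0, 0.3]), 0.10),
    ("O1", "O", np.array([-1.2, 0.6, 0.3]), -0.25),
]

_POCKET_ANCHORS = np.array([
    [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, -1.0, 0.0],
])


@dataclass
class BindingEvent:
    """One programmed interval of a copy's schedule.

    ``site`` is a pocket index or None for unbound; ``mean_distance`` is
    the distance (Å) of the ligand's central atom from the pocket's
    central bead, jittered per frame by ``jitter``.
    """

    site: int | None
    start_ns: float
    end_ns: float
    mean_distance: float = 2.9
    jitter: float = 0.1


@dataclass
class FixtureSpec:
    """Full description of a synthetic multicopy study."""

    seed: int = 0
    n_residues: int = 48
    n_pockets: int = 2
    pocket_size: int = 5
    n_copies: int = 3
    n_replicates: int = 4
    frame_interval_ns: float = 2.0
    production_length_ns: float = 400.0
    sphere_radius: float = 12.0
    events: dict[int, list[BindingEvent]] = field(default_factory=dict)
    replicate_events: dict[tuple[int, int], list[BindingEvent]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pockets > len(_POCKET_ANCHORS):
            raise ValidationError(
                f"at most {len(_POCKET_ANCHORS)} pockets supported")
        if self.n_residues < 2 * self.pocket_size * self.n_pockets:
            raise GenerationError(
                "n_residues must be at least twice the total pocket size")
        for events in list(self.events.values()) + \
                list(self.replicate_events.values()):
            times = sorted((e.start_ns, e.end_ns) for e in events)
            for (s1, e1), (s2, _) in zip(times, times[1:]):
                if s2 < e1:
                    raise ValidationError("events overlap in time")
            for e in events:
                if e.site is not None and not (0 <= e.site < self.n_pockets):
                    raise GenerationError(f"event references unknown pocket "
                                          f"{e.site}")

    def schedule(self, replicate: int, copy_id: int) -> list[BindingEvent]:
        if (replicate, copy_id) in self.replicate_events:
            return self.replicate_events[(replicate, copy_id)]
        return self.events.get(copy_id, [])

    def frame_times(self) -> np.ndarray:
        n = int(round(self.production_length_ns / self.frame_interval_ns)) + 1
        return np.arange(n) * self.frame_interval_ns


def dominant_site_spec(seed: int = 0, **overrides) -> FixtureSpec:
    """A study with a programmed dominant site (pocket 0): long residence,
    tight placement and every replicate reactive there; pocket 1 hosts a
    shorter, looser binder in half the replicates only."""
    spec = FixtureSpec(seed=seed, **overrides)
    length = spec.production_length_ns
    spec.events = {
        1: [BindingEvent(None, 0.0, 0.25 * length, 0, 0),
            BindingEvent(0, 0.25 * length, length, 2.9, 0.1)],
        2: [BindingEvent(0, 0.625 * length, length, 3.1, 0.1)],
        3: [BindingEvent(1, 0.85 * length, length, 4.1, 0.15)],
    }
    # copy 3 finds the weak site in the first half of the replicates only
    for rep in range(spec.n_replicates // 2 + 1, spec.n_replicates + 1):
        spec.replicate_events[(rep, 3)] = []
    for copy in range(4, spec.n_copies + 1):
        spec.events[copy] = []          # extra copies stay in solution
    return spec


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Analytic expectations derived from the spec alone."""

    true_rt_ns: dict[tuple[int, int], float]
    true_site: dict[tuple[int, int], int | None]
    true_contacts: dict[int, frozenset]
    true_best_site: int | None
    pocket_residue_ids: dict[int, list[int]]


def _bound_indicator(spec: FixtureSpec, replicate: int,
                     copy_id: int) -> np.ndarray:
    times = spec.frame_times()
    bound = np.zeros(len(times), dtype=bool)
    for event in spec.schedule(replicate, copy_id):
        if event.site is not None:
            bound |= (times >= event.start_ns - 1e-9) & \
                     (times <= event.end_ns + 1e-9)
    return bound


def _analytic_rt(times: np.ndarray, bound: np.ndarray,
                 fraction: float = 0.90) -> float:
    """Reference residence time by exhaustive suffix-window scan (O(n²));
    intentionally independent of the pipeline's O(n) implementation."""
    n = len(times)
    if not bound[-1]:
        return 0.0
    best = 0.0
    for start in range(n):
        window = bound[start:]
        if window.sum() / len(window) >= fraction:
            best = max(best, float(times[-1] - times[start]))
    return best


def ground_truth(spec: FixtureSpec,
                 rt_fraction: float = 0.90) -> GroundTruth:
    """Derive the fixture's expected analysis outcome from its schedule."""
    times = spec.frame_times()
    rt: dict[tuple[int, int], float] = {}
    site: dict[tuple[int, int], int | None] = {}
    site_total_rt: dict[int, float] = {}
    for rep in range(1, spec.n_replicates + 1):
        for copy in range(1, spec.n_copies + 1):
            bound = _bound_indicator(spec, rep, copy)
            rt[(rep, copy)] = _analytic_rt(times, bound, rt_fraction)
            final_site = None
            for event in spec.schedule(rep, copy):
                if event.site is not None and \
                        event.end_ns >= spec.production_length_ns - 1e-9:
                    final_site = event.site
            site[(rep, copy)] = final_site
            if final_site is not None and rt[(rep, copy)] > 0:
                site_total_rt[final_site] = (site_total_rt.get(final_site, 0.0)
                                             + rt[(rep, copy)])
    best = max(site_total_rt, key=site_total_rt.get) if site_total_rt else None

    pockets = _pocket_layout(spec)
    contacts = {}
    pocket_ids = {}
    for p, residues in enumerate(pockets):
        pocket_ids[p] = [rid for rid, _ in residues]
        contacts[p] = frozenset(("A", rid, name) for rid, name in residues)
    return GroundTruth(true_rt_ns=rt, true_site=site, true_contacts=contacts,
                       true_best_site=best, pocket_residue_ids=pocket_ids)


# ---------------------------------------------------------------------------
# Receptor construction
# ---------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rad = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rad * np.cos(phi), rad * np.sin(phi), z])


def _pocket_layout(spec: FixtureSpec) -> list[list[tuple[int, str]]]:
    """Residue ids (1-based) and names of each pocket, deterministic."""
    pockets = []
    for p in range(spec.n_pockets):
        first = p * spec.pocket_size + 1
        pockets.append([(first + k, "GLY" if k else "SER")
                        for k in range(spec.pocket_size)])
    return pockets


def _orthonormal_tangents(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, helper)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(normal, t1)


@dataclass
class ReceptorFixture:
    topology: Topology
    frame: Frame
    pocket_centers: np.ndarray          # central bead position per pocket
    pocket_normals: np.ndarray          # outward unit normal per pocket
    pocket_residue_ids: dict[int, list[int]]


def make_toy_receptor(spec: FixtureSpec) -> ReceptorFixture:
    """Build the bead receptor: one backbone (CA) and one sidechain (CB)
    bead per residue on a sphere, with each pocket's residues arranged as
    a concave ring (central acceptor bead + ring) indented into the
    surface around its anchor direction.

    Deterministic for a given spec; pocket residues lie within 6 Å of the
    pocket centroid and distinct pockets are separated by about twice the
    sphere radius.
    """
    R = spec.sphere_radius
    n_res = spec.n_residues
    pockets = _pocket_layout(spec)
    pocket_ids = {rid for pocket in pockets for rid, _ in pocket}

    directions = _fibonacci_directions(n_res)
    # keep generic residues away from the pocket anchors
    anchors = _POCKET_ANCHORS[:spec.n_pockets]
    generic_dirs = [d for d in directions
                    if all(np.dot(d, a) < 0.85 for a in anchors)]
    if len(generic_dirs) < n_res - len(pocket_ids):
        raise GenerationError("infeasible geometry: too few surface slots")

    atoms: list[AtomRecord] = []
    kinds: list[str] = []
    coords: list[np.ndarray] = []
    serial = 0
    gi = 0
    pocket_centers = np.zeros((spec.n_pockets, 3))
    pocket_normals = anchors.copy().astype(float)

    def add_atom(name: str, element: str, rid: int, resname: str,
                 charge: float, pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        eps, rmin = TOY_LJ[element]
        atoms.append(AtomRecord(serial=serial, name=name, element=element,
                                residue_name=resname, residue_id=rid,
                                chain_or_copy="A", charge=charge,
                                lj_epsilon=eps, lj_rmin_half=rmin))
        kinds.append("receptor")
        coords.append(pos)

    sidechain_cycle = ["C", "O", "N"]
    for rid in range(1, n_res + 1):
        pocket_of = next((p for p, pk in enumerate(pockets)
                          if any(r == rid for r, _ in pk)), None)
        resname = "GLY"
        if pocket_of is not None:
            k = rid - pockets[pocket_of][0][0]
            normal = anchors[pocket_of]
            t1, t2 = _orthonormal_tangents(normal)
            base = normal * (R - 1.0)
            if k == 0:
                # central acceptor bead of the pocket
                ca = base - normal * 1.5
                cb = base
                element, charge, resname = "O", -0.30, "SER"
            else:
                angle = 2.0 * math.pi * (k - 1) / (spec.pocket_size - 1)
                ring = base + 3.0 * (math.cos(angle) * t1
                                     + math.sin(angle) * t2)
                ca = ring - normal * 1.5
                cb = ring
                element, charge = "C", 0.05
            if k == 0:
                pocket_centers[pocket_of] = cb
            add_atom("CA", "C", rid, resname, 0.0, ca)
            add_atom("CB", element, rid, resname, charge, cb)
        else:
            d = generic_dirs[gi]
            gi += 1
            element = sidechain_cycle[rid % 3]
            charge = {"C": 0.05, "O": -0.25, "N": -0.20}[element]
            add_atom("CA", "C", rid, "GLY", 0.0, R * d)
            add_atom("CB", element, rid, "GLY", charge, (R + 1.6) * d)

    topology = Topology(atoms=atoms, molecule_kinds=kinds, n_ligand_copies=0)
    frame = Frame(time_ns=0.0, coordinates=np.asarray(coords))
    return ReceptorFixture(topology=topology, frame=frame,
                           pocket_centers=pocket_centers,
                           pocket_normals=pocket_normals,
                           pocket_residue_ids={p: [r for r, _ in pk]
                                               for p, pk in enumerate(pockets)})


# ---------------------------------------------------------------------------
# Ligand copies, solvent and trajectory assembly
# ---------------------------------------------------------------------------

def _ligand_atoms(copy_id: int, first_serial: int,
                  residue_id: int) -> list[AtomRecord]:
    out = []
    for k, (name, element, _, charge) in enumerate(LIGAND_TEMPLATE):
        eps, rmin = TOY_LJ[element]
        out.append(AtomRecord(
            serial=first_serial + k, name=name, element=element,
            residue_name="LIG", residue_id=residue_id,
            chain_or_copy=str(copy_id), charge=charge,
            lj_epsilon=eps, lj_rmin_half=rmin,
            is_repulsive_center=(name == "N1"),
            amber_type="N99" if name == "N1" else None))
    return out


def _ligand_coords(center: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Template coordinates placed with the central atom at ``center`` and
    the template -z axis (the N-H direction) along ``-normal``."""
    t1, t2 = _orthonormal_tangents(normal)
    rot = np.column_stack([t1, t2, normal])     # maps template z to normal
    offsets = np.asarray([off for _, _, off, _ in LIGAND_TEMPLATE])
    return center + offsets @ rot.T


def make_programmed_trajectory(receptor: ReceptorFixture, spec: FixtureSpec,
                               replicate: int = 1) -> Trajectory:
    """Kinematic multicopy trajectory for one replicate.

    Bound events place each copy's central atom ``mean_distance`` ±
    ``jitter`` outward of the named pocket's central bead (hydrogen
    pointing into the pocket); unbound stretches park the copy on a
    per-copy random far orbit (> 12 Å from every receptor atom).  All
    noise comes from the seeded generator; the schedule itself is exact.
    """
    rng = np.random.default_rng([spec.seed, replicate])
    times = spec.frame_times()
    n_frames = len(times)
    R = spec.sphere_radius

    rec_topo = receptor.topology
    atoms = [replace(a) for a in rec_topo.atoms]
    kinds = list(rec_topo.molecule_kinds)
    serial = len(atoms)
    next_rid = max(a.residue_id for a in atoms) + 1

    lig_slices = []
    for copy in range(1, spec.n_copies + 1):
        lig = _ligand_atoms(copy, serial + 1, next_rid)
        atoms.extend(lig)
        kinds.extend(["ligand"] * len(lig))
        lig_slices.append(slice(serial, serial + len(lig)))
        serial += len(lig)
        next_rid += 1

    n_waters, n_ions = 8, 2
    solvent_dirs = _fibonacci_directions(n_waters + n_ions)
    solvent_base = []
    for k in range(n_waters):
        serial += 1
        eps, rmin = TOY_LJ["O"]
        atoms.append(AtomRecord(serial=serial, name="O", element="O",
                                residue_name="WAT", residue_id=next_rid,
                                chain_or_copy="W", charge=-0.8,
                                lj_epsilon=eps, lj_rmin_half=rmin))
        kinds.append("water")
        solvent_base.append(solvent_dirs[k] * (R + 45.0))
        next_rid += 1
    for k in range(n_ions):
        serial += 1
        eps, rmin = TOY_LJ["NA"]
        atoms.append(AtomRecord(serial=serial, name="NA", element="NA",
                                residue_name="NA", residue_id=next_rid,
                                chain_or_copy="I", charge=1.0,
                                lj_epsilon=eps, lj_rmin_half=rmin))
        kinds.append("ion")
        solvent_base.append(solvent_dirs[n_waters + k] * (R + 55.0))
        next_rid += 1
    solvent_base = np.asarray(solvent_base)

    topology = Topology(atoms=atoms, molecule_kinds=kinds,
                        n_ligand_copies=spec.n_copies)
    n_atoms = len(atoms)
    n_rec = len(rec_topo)

    # per-copy far-orbit direction for unbound stretches, away from pockets
    orbit_dirs = []
    for copy in range(spec.n_copies):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        orbit_dirs.append(d)

    frames = []
    for fi, t in enumerate(times):
        coords = np.empty((n_atoms, 3))
        coords[:n_rec] = receptor.frame.coordinates
        for copy in range(1, spec.n_copies + 1):
            event = None
            for ev in spec.schedule(replicate, copy):
                if ev.site is not None and \
                        ev.start_ns - 1e-9 <= t <= ev.end_ns + 1e-9:
                    event = ev
            sl = lig_slices[copy - 1]
            if event is None:
                center = orbit_dirs[copy - 1] * (R + 30.0) \
                    + rng.normal(0.0, 0.5, 3)
                normal = orbit_dirs[copy - 1]
            else:
                normal = receptor.pocket_normals[event.site]
                t1, t2 = _orthonormal_tangents(normal)
                d = event.mean_distance + rng.uniform(-event.jitter,
                                                      event.jitter)
                lateral = rng.uniform(-0.3, 0.3, 2)
                center = (receptor.pocket_centers[event.site]
                          + normal * d + lateral[0] * t1 + lateral[1] * t2)
            coords[sl] = _ligand_coords(center, normal)
        coords[n_rec + 4 * spec.n_copies:] = \
            solvent_base + rng.normal(0.0, 0.2, solvent_base.shape)
        frames.append(Frame(time_ns=float(t), coordinates=coords))
    return Trajectory(topology=topology, frames=frames)


def make_study(spec: FixtureSpec) -> tuple[ReceptorFixture,
                                           list[tuple[int, Trajectory]],
                                           GroundTruth]:
    """Receptor + one programmed multicopy trajectory per replicate +
    analytic ground truth."""
    receptor = make_toy_receptor(spec)
    replicates = [(rep, make_programmed_trajectory(receptor, spec, rep))
                  for rep in range(1, spec.n_replicates + 1)]
    return receptor, replicates, ground_truth(spec)


# ---------------------------------------------------------------------------
# Random energy test systems
# ---------------------------------------------------------------------------

def make_energy_test_system(n_rec: int, n_lig: int, seed: int = 0,
                            min_separation: float = 1.6
                            ) -> tuple[Topology, Frame]:
    """Random receptor/ligand point system with physical-range charges and
    LJ parameters and no overlapping atoms; used for brute-force oracle
    equivalence tests."""
    if n_rec < 1 or n_lig < 1:
        raise ValidationError("need at least one atom per group")
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    while len(coords) < n_rec + n_lig:
        cand = rng.uniform(-8.0, 8.0, 3)
        if all(np.linalg.norm(cand - c) > min_separation for c in coords):
            coords.append(cand)
    atoms = []
    kinds = []
    elements = ["C", "N", "O", "S"]
    for i in range(n_rec + n_lig):
        is_lig = i >= n_rec
        atoms.append(AtomRecord(
            serial=i + 1, name=f"X{i + 1}",
            element=elements[rng.integers(len(elements))],
            residue_name="LIG" if is_lig else "GLY",
            residue_id=1000 if is_lig else i + 1,
            chain_or_copy="1" if is_lig else "A",
            charge=float(rng.uniform(-0.5, 0.5)),
            lj_epsilon=float(rng.uniform(0.05, 0.3)),
            lj_rmin_half=float(rng.uniform(1.2, 2.0))))
        kinds.append("ligand" if is_lig else "receptor")
    topology = Topology(atoms=atoms, molecule_kinds=kinds, n_ligand_copies=1)
    return topology, Frame(time_ns=0.0, coordinates=np.asarray(coords))
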