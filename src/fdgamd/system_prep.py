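"""Multicopy simulation-system preparation.

Covers the geometric half of the fragment-dissolved workflow: orienting
receptor and fragment along their principal axes (to minimise rotational
bias and shrink the solvation box), tiling a pre-equilibrated ligand box
around the receptor with a solvation shell, whole-molecule clash pruning,
injection of the anti-aggregation repulsive Lennard-Jones term between the
designated central atoms of the ligand copies, and the system-size-derived
GaMD equilibration step schedule

    ntave     = 4 * N_atoms
    ntcmdprep = 2 * ntave
    ntebprep  = 2 * ntave
    ntcmd     = 5 * ntave

where ntave is the update interval of the running potential-energy
statistics, ntcmdprep/ntebprep the conventional-MD and boost preparation
step counts, and ntcmd the total conventional-MD steps used to estimate
the initial boost parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .model_io import (
    AtomRecord,
    DegeneracyError,
    Frame,
    PlacementError,
    SelectionError,
    Topology,
    Trajectory,
    UnsupportedElementError,
    ValidationError,
    logger,
)

REPULSIVE_ELEMENTS = ("C", "N", "O", "S")


# ---------------------------------------------------------------------------
# GaMD equilibration schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilSchedule:
    """GaMD equilibration step counts derived from the system atom count."""

    n_atoms: int
    ntave: int
    ntcmdprep: int
    ntebprep: int
    ntcmd: int


def gamd_equilibration_schedule(n_atoms: int) -> EquilSchedule:
    """Compute the GaMD step schedule from the total atom count.

    Pure integer arithmetic: ntave = 4*N, ntcmdprep = ntebprep = 2*ntave,
    ntcmd = 5*ntave.
    """
    n_atoms = int(n_atoms)
    if n_atoms < 1:
        raise ValidationError(f"n_atoms must be >= 1, got {n_atoms}")
    ntave = 4 * n_atoms
    return EquilSchedule(n_atoms=n_atoms, ntave=ntave, ntcmdprep=2 * ntave,
                         ntebprep=2 * ntave, ntcmd=5 * ntave)


# ---------------------------------------------------------------------------
# Principal-axis alignment
# ---------------------------------------------------------------------------

def principal_axes(coordinates: np.ndarray, masses: np.ndarray,
                   degeneracy_tol: float = 1e-8) -> np.ndarray:
    """Mass-weighted principal axes of a point cloud, ordered by descending
    spatial extent.

    Returns a (3, 3) array whose *rows* are orthonormal axis vectors
    (eigenvectors of the mass-weighted covariance tensor about the centre
    of mass) forming a right-handed frame.  The sign of each of the first
    two axes is fixed so its largest-magnitude component is positive; the
    third is their cross product.  Raises :class:`DegeneracyError` for
    fewer than three points or a collinear set.  Near-degenerate spectra
    (relative eigenvalue gap below ``degeneracy_tol``) fall back to the
    same deterministic sign convention.
    """
    coords = np.asarray(coordinates, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError("coordinates must be (n, 3)")
    if coords.shape[0] < 3:
        raise DegeneracyError("principal axes need at least 3 points")
    com = np.average(coords, axis=0, weights=masses)
    centered = coords - com
    cov = (centered * masses[:, None]).T @ centered / masses.sum()
    evals, evecs = np.linalg.eigh(cov)      # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    axes = evecs[:, order].T                # rows = axes, descending extent
    if evals[0] <= 0 or evals[1] / evals[0] < 1e-12:
        raise DegeneracyError("point set is collinear (or a single point)")
    gaps = np.diff(evals[::-1])
    if np.any(np.abs(gaps) < degeneracy_tol * max(evals[0], 1e-30)):
        logger.debug("near-degenerate inertia spectrum; deterministic "
                     "sign convention applied")
    for i in range(2):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])    # right-handed by construction
    return axes


def align_to_principal_axes(frame: Frame, topology: Topology
                            ) -> tuple[Frame, np.ndarray]:
    """Rotate a frame so its principal axes coincide with x, y, z (longest
    extent on x) and its centre of mass sits at the origin.

    Returns the rotated frame and the applied rotation matrix R (rows =
    principal axes; ``x' = R @ (x - com)``).  Rigid: all pairwise
    distances are preserved.
    """
    masses = topology.masses
    axes = principal_axes(frame.coordinates, masses)
    com = np.average(frame.coordinates, axis=0, weights=masses)
    rotated = (frame.coordinates - com) @ axes.T
    return Frame(time_ns=frame.time_ns, coordinates=rotated,
                 box_lengths=frame.box_lengths), axes


# ---------------------------------------------------------------------------
# Multicopy box assembly
# ---------------------------------------------------------------------------

@dataclass
class PrepReport:
    """Summary of a multicopy box assembly."""

    n_copies_placed: int
    n_molecules_removed_clash: int
    final_box_lengths: np.ndarray
    rotation_applied: dict[str, np.ndarray]
    n_tiles: tuple[int, int, int] = (1, 1, 1)
    n_waters_placed: int = 0


def _molecule_groups(topology: Topology) -> list[np.ndarray]:
    """Group template atoms into whole molecules by (kind, chain, res_id)."""
    groups: dict[tuple, list[int]] = {}
    for i, (atom, kind) in enumerate(zip(topology.atoms,
                                         topology.molecule_kinds)):
        key = (kind, atom.chain_or_copy, atom.residue_id)
        groups.setdefault(key, []).append(i)
    return [np.asarray(v, dtype=int) for v in groups.values()]


def tiling_counts(receptor_extent: np.ndarray, shell: float,
                  box_lengths: np.ndarray) -> tuple[int, int, int]:
    """Per-axis replication counts of the minimal lattice covering the
    receptor extent plus ``shell`` on every side."""
    needed = np.asarray(receptor_extent, dtype=float) + 2.0 * shell
    return tuple(int(np.ceil(needed[k] / box_lengths[k])) for k in range(3))


def assemble_multicopy_box(receptor_frame: Frame, receptor_topology: Topology,
                           template_frame: Frame, template_topology: Topology,
                           shell: float = 20.0, clash: float = 1.0,
                           align: bool = True,
                           ) -> tuple[Frame, Topology, PrepReport]:
    """Solvate the receptor with replicas of a pre-equilibrated ligand box.

    The template box (ligand copies + waters) is replicated verbatim on the
    minimal rectangular lattice covering the receptor extent plus ``shell``
    Å on all sides, centred on the receptor centre of mass.  Every template
    molecule with any atom strictly closer than ``clash`` Å to any receptor
    atom is removed whole (molecule-atomic pruning; never partial).  Ligand
    copies in the combined system are renumbered 1..N.
    """
    if len(template_topology) == 0:
        raise ValidationError("empty template box")
    if template_frame.box_lengths is None:
        raise ValidationError("template box lengths are required")
    box = np.asarray(template_frame.box_lengths, dtype=float)
    if np.any(box <= 0):
        raise ValidationError("template box lengths must be positive")

    rotations: dict[str, np.ndarray] = {"ligand_box": np.eye(3)}
    if align:
        receptor_frame, rot = align_to_principal_axes(receptor_frame,
                                                      receptor_topology)
        rotations["receptor"] = rot
    else:
        rotations["receptor"] = np.eye(3)

    rec = receptor_frame.coordinates
    extent = rec.max(axis=0) - rec.min(axis=0)
    if np.any(box > extent + 2 * shell):
        raise PlacementError(
            f"template box {box} larger than the target region "
            f"{extent + 2 * shell} (receptor extent + 2*shell)")
    n_tiles = tiling_counts(extent, shell, box)
    com = np.average(rec, axis=0, weights=receptor_topology.masses)
    origin = com - np.asarray(n_tiles) * box / 2.0

    tree = cKDTree(rec)
    groups = _molecule_groups(template_topology)
    tcoords = template_frame.coordinates

    kept_coords: list[np.ndarray] = []
    kept_groups: list[tuple[np.ndarray, str]] = []  # (atom indices, kind)
    n_removed = 0
    for ix in range(n_tiles[0]):
        for iy in range(n_tiles[1]):
            for iz in range(n_tiles[2]):
                offset = origin + np.array([ix, iy, iz]) * box
                shifted = tcoords + offset
                for grp in groups:
                    kind = template_topology.molecule_kinds[grp[0]]
                    dmin, _ = tree.query(shifted[grp], k=1)
                    if np.min(dmin) < clash:
                        n_removed += 1
                        continue
                    kept_coords.append(shifted[grp])
                    kept_groups.append((grp, kind))

    atoms: list[AtomRecord] = []
    kinds: list[str] = []
    coords: list[np.ndarray] = [rec]
    serial = 0
    for atom in receptor_topology.atoms:
        serial += 1
        atoms.append(replace(atom, serial=serial))
        kinds.append("receptor")

    n_copies = 0
    max_res = max((a.residue_id for a in receptor_topology.atoms), default=0)
    next_res = max_res + 1
    n_waters = 0
    for (grp, kind), grp_coords in zip(kept_groups, kept_coords):
        if kind == "ligand":
            n_copies += 1
            label = str(n_copies)
        else:
            label = template_topology.atoms[grp[0]].chain_or_copy
            if kind == "water":
                n_waters += 1
        for i in grp:
            serial += 1
            atoms.append(replace(template_topology.atoms[i], serial=serial,
                                 residue_id=next_res, chain_or_copy=label))
            kinds.append(kind)
        next_res += 1
        coords.append(grp_coords)

    topology = Topology(atoms=atoms, molecule_kinds=kinds,
                        n_ligand_copies=n_copies)
    frame = Frame(time_ns=receptor_frame.time_ns,
                  coordinates=np.concatenate(coords, axis=0),
                  box_lengths=np.asarray(n_tiles) * box)
    report = PrepReport(
        n_copies_placed=n_copies,
        n_molecules_removed_clash=n_removed,
        final_box_lengths=np.asarray(n_tiles) * box,
        rotation_applied=rotations,
        n_tiles=n_tiles,
        n_waters_placed=n_waters,
    )
    return frame, topology, report


# ---------------------------------------------------------------------------
# Repulsive central-atom term
# ---------------------------------------------------------------------------

def default_central_atom(topology: Topology, frame: Frame,
                         copy_id: int) -> str:
    """Heuristic central-atom choice for one ligand copy: the heteroatom
    (non-C, non-H; else a carbon) nearest the copy's unweighted centroid."""
    idx = topology.ligand_copy_indices(copy_id)
    if idx.size == 0:
        raise SelectionError(f"no atoms for ligand copy {copy_id}")
    coords = frame.coordinates[idx]
    centroid = coords.mean(axis=0)
    dist = np.linalg.norm(coords - centroid, axis=1)
    hetero = [k for k, i in enumerate(idx)
              if topology.atoms[i].element.upper() not in ("C", "H")]
    pool = hetero if hetero else [k for k, i in enumerate(idx)
                                  if topology.atoms[i].element.upper() == "C"]
    if not pool:
        raise SelectionError(f"ligand copy {copy_id} has no C/N/O/S atom")
    best = min(pool, key=lambda k: dist[k])
    return topology.atoms[idx[best]].name


def inject_repulsive_term(topology: Topology,
                          central_atom_name: str | None = None,
                          frame: Frame | None = None) -> Topology:
    """Flag the central atom of every ligand copy as a repulsive centre.

    The named atom in each copy is marked ``is_repulsive_center`` and
    retyped C99/N99/O99/S99 according to its element.  Pair interactions
    between two repulsive centres then use only the r^-12 repulsive
    Lennard-Jones branch (the attractive r^-6 coefficient is zeroed in the
    energy routines); all other interactions are unchanged.  When no name
    is given, the heuristic of :func:`default_central_atom` is applied
    (requires a frame).
    """
    if topology.n_ligand_copies < 1:
        raise SelectionError("topology has no ligand copies")
    atoms = [replace(a) for a in topology.atoms]
    new = Topology(atoms=atoms, molecule_kinds=list(topology.molecule_kinds),
                   n_ligand_copies=topology.n_ligand_copies)
    for copy_id in new.copy_ids():
        name = central_atom_name
        if name is None:
            if frame is None:
                raise SelectionError(
                    "central-atom heuristic needs coordinates; supply a frame "
                    "or an explicit atom name")
            name = default_central_atom(new, frame, copy_id)
        idx = [i for i in new.ligand_copy_indices(copy_id)
               if new.atoms[i].name == name]
        if len(idx) != 1:
            raise SelectionError(
                f"central atom {name!r} matched {len(idx)} atoms in ligand "
                f"copy {copy_id} (need exactly 1)")
        atom = new.atoms[idx[0]]
        element = atom.element.upper()
        if element not in REPULSIVE_ELEMENTS:
            raise UnsupportedElementError(
                f"central atom element {element!r} outside C/N/O/S")
        atom.is_repulsive_center = True
        atom.amber_type = f"{element}99"
    new._cache.clear()
    return new
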