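"""Data model and I/O for multicopy protein--fragment systems.

The in-memory containers are deliberately small: an :class:`AtomRecord` per
atom (identity + nonbonded parameters), a :class:`Topology` (ordered atoms,
molecule kinds, ligand-copy labels), time-stamped :class:`Frame` coordinate
sets, and a :class:`Trajectory` bundling both.  Structures travel as PDB
(single- or multi-MODEL, parsed/written through biotite); nonbonded
parameters travel as a JSON sidecar because force-field topology generation
is outside this package's scope.

Units are fixed package-wide in the AMBER convention: coordinates in Å,
energies in kcal/mol, charges in elementary units, masses in amu, and the
Coulomb constant ``COULOMB_CONSTANT`` = 332.0637 kcal·Å/(mol·e²).
Lennard-Jones parameters are stored as (epsilon, rmin/2) and combined by
Lorentz-Berthelot rules.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger("fdgamd")

# ---------------------------------------------------------------------------
# Package-wide physical constants (AMBER conventions)
# ---------------------------------------------------------------------------

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0637

#: Solvent (water) dielectric used by the generalized-Born model.
SOLVENT_DIELECTRIC = 78.5

#: Default atomic masses (amu) by element symbol.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "ZN": 65.38, "F": 18.998, "BR": 79.904,
}

#: Residue names recognised as water / monoatomic ions when classifying
#: molecule kinds from a bare PDB.
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "T3P"}
ION_RESNAMES = {"NA", "CL", "K", "MG", "ZN", "CA2", "NA+", "CL-", "CIO"}

#: Default residue names treated as the fragment/ligand species.
LIGAND_RESNAMES = {"LIG", "UNL", "UNK", "MOL", "FRG"}


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class FdgamdError(Exception):
    """Base class for all package errors."""


class ParseError(FdgamdError):
    """A file could not be parsed (message names the offending line)."""


class StructureError(FdgamdError):
    """Structurally inconsistent input (e.g. unequal MODEL atom counts)."""


class ParamLookupError(FdgamdError):
    """Parameter sidecar does not cover the topology."""


class ConfigError(FdgamdError):
    """Unknown configuration key."""


class ValidationError(FdgamdError):
    """A value violates a documented invariant."""


class DomainError(FdgamdError):
    """Mathematical-domain violation (non-finite input, U_max <= U_min, ...)."""


class DegeneracyError(FdgamdError):
    """Degenerate geometry (collinear point set and the like)."""


class SelectionError(FdgamdError):
    """An atom selection matched nothing (or not exactly one atom)."""


class PlacementError(FdgamdError):
    """Box assembly could not place the template."""


class UnsupportedElementError(FdgamdError):
    """Element outside the supported C/N/O/S set for repulsive typing."""


class SingularityError(FdgamdError):
    """Overlapping atoms made a pairwise energy singular."""


class GenerationError(FdgamdError):
    """A synthetic fixture could not be generated from its spec."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom: identity, labels and nonbonded parameters.

    ``chain_or_copy`` holds the receptor chain identifier for protein atoms
    and the ligand copy index (as a string) for fragment atoms.
    ``is_repulsive_center`` marks the single central atom per ligand copy
    that carries the anti-aggregation repulsive Lennard-Jones term; such an
    atom is retyped C99/N99/O99/S99 in ``amber_type`` according to element.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_or_copy: str = "A"
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 1.5
    is_repulsive_center: bool = False
    mass: float = 0.0
    amber_type: str | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0.0:
            self.mass = ELEMENT_MASSES.get(self.element.upper(), 12.011)
        self.validate()

    def validate(self) -> None:
        if self.lj_epsilon < 0:
            raise ValidationError(
                f"atom {self.serial} ({self.name}): lj_epsilon must be >= 0, "
                f"got {self.lj_epsilon}")
        if self.lj_rmin_half <= 0:
            raise ValidationError(
                f"atom {self.serial} ({self.name}): lj_rmin_half must be > 0")
        if self.mass <= 0:
            raise ValidationError(f"atom {self.serial}: mass must be > 0")


MOLECULE_KINDS = ("receptor", "ligand", "water", "ion")


@dataclass
class Topology:
    """Ordered atom list plus per-atom molecule kind and ligand-copy labels.

    Atom ordering is stable across every frame of a trajectory.  Ligand
    atoms carry a copy label in ``1..n_ligand_copies`` (stored in each
    atom's ``chain_or_copy``).
    """

    atoms: list[AtomRecord]
    molecule_kinds: list[str]
    n_ligand_copies: int = 0

    def __post_init__(self) -> None:
        if len(self.atoms) != len(self.molecule_kinds):
            raise ValidationError("molecule_kinds must match atom count")
        for kind in self.molecule_kinds:
            if kind not in MOLECULE_KINDS:
                raise ValidationError(f"unknown molecule kind {kind!r}")
        for atom, kind in zip(self.atoms, self.molecule_kinds):
            if kind == "ligand":
                try:
                    copy = int(atom.chain_or_copy)
                except ValueError:
                    raise ValidationError(
                        f"ligand atom {atom.serial} lacks an integer copy label")
                if not (1 <= copy <= max(self.n_ligand_copies, 1)):
                    raise ValidationError(
                        f"ligand atom {atom.serial} copy label {copy} outside "
                        f"[1, {self.n_ligand_copies}]")
        self._cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.atoms)

    # -- cached per-atom arrays (invalidated by rebuilding the Topology) ----

    def _array(self, key: str, getter) -> np.ndarray:
        if key not in self._cache:
            self._cache[key] = np.asarray([getter(a) for a in self.atoms])
        return self._cache[key]

    @property
    def charges(self) -> np.ndarray:
        return self._array("charges", lambda a: a.charge)

    @property
    def lj_epsilons(self) -> np.ndarray:
        return self._array("eps", lambda a: a.lj_epsilon)

    @property
    def lj_rmin_halves(self) -> np.ndarray:
        return self._array("rmin", lambda a: a.lj_rmin_half)

    @property
    def masses(self) -> np.ndarray:
        return self._array("mass", lambda a: a.mass)

    @property
    def repulsive_flags(self) -> np.ndarray:
        return self._array("rep", lambda a: a.is_repulsive_center).astype(bool)

    @property
    def kinds(self) -> np.ndarray:
        if "kinds" not in self._cache:
            self._cache["kinds"] = np.asarray(self.molecule_kinds)
        return self._cache["kinds"]

    def indices_of_kind(self, kind: str) -> np.ndarray:
        return np.flatnonzero(self.kinds == kind)

    def ligand_copy_indices(self, copy_id: int) -> np.ndarray:
        idx = [i for i, (a, k) in enumerate(zip(self.atoms, self.molecule_kinds))
               if k == "ligand" and int(a.chain_or_copy) == copy_id]
        return np.asarray(idx, dtype=int)

    def copy_ids(self) -> list[int]:
        seen: list[int] = []
        for atom, kind in zip(self.atoms, self.molecule_kinds):
            if kind == "ligand":
                cid = int(atom.chain_or_copy)
                if cid not in seen:
                    seen.append(cid)
        return seen


@dataclass
class Frame:
    """Time-stamped coordinate set (Å) for every topology atom."""

    time_ns: float
    coordinates: np.ndarray
    box_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValidationError("coordinates must be an (n, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValidationError("coordinates must be finite")
        if self.time_ns < 0:
            raise ValidationError("time_ns must be non-negative")
        if self.box_lengths is not None:
            self.box_lengths = np.asarray(self.box_lengths, dtype=float)


@dataclass
class Trajectory:
    """Topology + ordered frames with strictly increasing time stamps."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise StructureError(
                    f"frame {i} has {fr.coordinates.shape[0]} atoms, "
                    f"topology has {n}")
        times = [fr.time_ns for fr in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([fr.time_ns for fr in self.frames])

    def coordinate_stack(self) -> np.ndarray:
        return np.stack([fr.coordinates for fr in self.frames])


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Every tunable of the analysis protocol, with its protocol default.

    Defaults encode the published protocol constants: the 15 Å ligand-box
    margin and 20 Å solvation shell, 1 Å clash pruning, the 5 Å
    central-atom interaction screen with 90 % occupancy, the 50 ns
    residence-time cutoff, 4.5 Å residue contacts merged at Jaccard
    J > 0.35, hydrogen bonds over the last 20 ns retained above 45 %
    occupancy, 10 ns stability blocks, and four 400 ns replicates.
    """

    box_margin_dmin: float = 15.0
    solvation_shell: float = 20.0
    clash_cutoff: float = 1.0
    interaction_cutoff: float = 5.0
    rt_occupancy_fraction: float = 0.90
    rt_cutoff_ns: float = 50.0
    contact_cutoff: float = 4.5
    jaccard_threshold: float = 0.35
    hbond_window_ns: float = 20.0
    hbond_occupancy_min: float = 0.45
    hbond_distance_cutoff: float = 3.0
    hbond_angle_min_deg: float = 135.0
    stability_block_ns: float = 10.0
    stability_sd_scale: float = 2.0
    n_replicates: int = 4
    production_length_ns: float = 400.0

    def __post_init__(self) -> None:
        positive = ("box_margin_dmin", "solvation_shell", "clash_cutoff",
                    "interaction_cutoff", "rt_cutoff_ns", "contact_cutoff",
                    "hbond_window_ns", "hbond_distance_cutoff",
                    "stability_block_ns", "production_length_ns")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("rt_occupancy_fraction", "hbond_occupancy_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if not (0 <= self.jaccard_threshold <= 1):
            raise ValidationError(
                f"jaccard_threshold must be in [0, 1], got {self.jaccard_threshold}")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.stability_sd_scale <= 0:
            raise ValidationError("stability_sd_scale must be > 0")


_CONFIG_FIELDS = {f.name for f in fields(AnalysisConfig)}


def load_config(overrides: Mapping[str, object] | None = None,
                path: str | Path | None = None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from defaults, a YAML/JSON file and
    explicit overrides (in that precedence order).

    Raises :class:`ConfigError` for unknown keys and
    :class:`ValidationError` when a value violates a config invariant.
    """
    merged: dict[str, object] = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        merged.update(data)
    if overrides:
        merged.update(overrides)
    unknown = sorted(set(merged) - _CONFIG_FIELDS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    return AnalysisConfig(**merged)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# PDB reading / writing (through biotite)
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: Path) -> None:
    """Scan ATOM/HETATM records and report unparsable coordinate fields by
    line number, before handing the file to the structure parser."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(
                    f"{path}:{lineno}: ATOM record shorter than the "
                    "coordinate fields")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: unparsable {what} coordinate "
                        f"field {line[lo:hi]!r}")


def classify_molecule_kind(residue_name: str,
                           ligand_resnames: set[str] | None = None) -> str:
    resname = residue_name.strip().upper()
    ligand = ligand_resnames or LIGAND_RESNAMES
    if resname in WATER_RESNAMES:
        return "water"
    if resname in ION_RESNAMES:
        return "ion"
    if resname in ligand:
        return "ligand"
    return "receptor"


def read_structure(path: str | Path, format: str = "pdb",
                   frame_interval: float = 1.0,
                   ligand_resnames: Iterable[str] | None = None) -> Trajectory:
    """Read a single- or multi-MODEL PDB file into a :class:`Trajectory`.

    One frame per MODEL block (a single frame when the file has none);
    frame time stamps are ``i * frame_interval`` (the PDB format carries no
    time, so the interval is caller-supplied; the default of one time unit
    per frame is only a placeholder and analyses requiring real times must
    override it).  Ligand copies are numbered in order of first appearance
    of each distinct ligand residue.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)

    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None, extra_fields=["atom_id", "charge"])
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise StructureError(
            f"{path}: inconsistent MODEL blocks ({exc})") from exc

    ligset = {r.upper() for r in ligand_resnames} if ligand_resnames else None
    atoms: list[AtomRecord] = []
    kinds: list[str] = []
    copy_of_residue: dict[tuple[str, int], int] = {}
    for i in range(stack.array_length()):
        resname = str(stack.res_name[i])
        kind = classify_molecule_kind(resname, ligset)
        element = str(stack.element[i]) or "C"
        label = str(stack.chain_id[i])
        if kind == "ligand":
            key = (str(stack.chain_id[i]), int(stack.res_id[i]))
            if key not in copy_of_residue:
                copy_of_residue[key] = len(copy_of_residue) + 1
            label = str(copy_of_residue[key])
        atoms.append(AtomRecord(
            serial=int(stack.atom_id[i]) if "atom_id" in stack.get_annotation_categories() else i + 1,
            name=str(stack.atom_name[i]),
            element=element,
            residue_name=resname,
            residue_id=int(stack.res_id[i]),
            chain_or_copy=label,
        ))
        kinds.append(kind)

    topology = Topology(atoms=atoms, molecule_kinds=kinds,
                        n_ligand_copies=len(copy_of_residue))
    frames = [Frame(time_ns=i * frame_interval, coordinates=stack.coord[i])
              for i in range(stack.stack_depth())]
    return Trajectory(topology=topology, frames=frames)


def write_structure(trajectory: Trajectory, path: str | Path) -> None:
    """Write a :class:`Trajectory` as a (multi-MODEL) PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    topo = trajectory.topology
    n = len(topo)
    stack = struc.AtomArrayStack(len(trajectory.frames), n)
    stack.coord = trajectory.coordinate_stack()
    stack.set_annotation("chain_id", np.asarray(
        [a.chain_or_copy if k != "ligand" else "L"
         for a, k in zip(topo.atoms, topo.molecule_kinds)], dtype="U4"))
    stack.set_annotation("res_id", np.asarray(
        [a.residue_id for a in topo.atoms], dtype=int))
    stack.set_annotation("res_name", np.asarray(
        [a.residue_name for a in topo.atoms], dtype="U5"))
    stack.set_annotation("atom_name", np.asarray(
        [a.name for a in topo.atoms], dtype="U6"))
    stack.set_annotation("element", np.asarray(
        [a.element.upper() for a in topo.atoms], dtype="U2"))
    stack.set_annotation("hetero", np.asarray(
        [k != "receptor" for k in topo.molecule_kinds], dtype=bool))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# JSON parameter sidecar
# ---------------------------------------------------------------------------

def read_params(topology: Topology, path: str | Path) -> Topology:
    """Update topology atoms in place from a JSON parameter sidecar.

    Schema: ``{"atoms": [{"residue_name": .., "name": .., "charge": ..,
    "lj_epsilon": .., "lj_rmin_half": .., "element"?, "mass"?,
    "is_repulsive_center"?, "serial"?}, ...]}``.  Atoms are matched by
    ``serial`` when given, otherwise by ``(residue_name, name)``.  Every
    topology atom must be covered; unmatched atoms raise
    :class:`ParamLookupError` listing the offenders.
    """
    data = json.loads(Path(path).read_text())
    entries = data["atoms"] if isinstance(data, dict) else data

    by_serial: dict[int, dict] = {}
    by_key: dict[tuple[str, str], dict] = {}
    for entry in entries:
        eps = entry.get("lj_epsilon", 0.0)
        if eps < 0:
            raise ValidationError(
                f"sidecar entry {entry.get('name')}: negative lj_epsilon {eps}")
        if "serial" in entry:
            by_serial[int(entry["serial"])] = entry
        if "residue_name" in entry and "name" in entry:
            by_key[(entry["residue_name"], entry["name"])] = entry

    missing: list[str] = []
    for atom in topology.atoms:
        entry = by_serial.get(atom.serial) or by_key.get(
            (atom.residue_name, atom.name))
        if entry is None:
            missing.append(f"{atom.residue_name}/{atom.name} (serial {atom.serial})")
            continue
        atom.charge = float(entry.get("charge", atom.charge))
        atom.lj_epsilon = float(entry.get("lj_epsilon", atom.lj_epsilon))
        atom.lj_rmin_half = float(entry.get("lj_rmin_half", atom.lj_rmin_half))
        if "element" in entry:
            atom.element = str(entry["element"])
        if "mass" in entry:
            atom.mass = float(entry["mass"])
        if "is_repulsive_center" in entry:
            atom.is_repulsive_center = bool(entry["is_repulsive_center"])
        if "amber_type" in entry:
            atom.amber_type = str(entry["amber_type"])
        atom.validate()
        if not all(math.isfinite(v) for v in
                   (atom.charge, atom.lj_epsilon, atom.lj_rmin_half)):
            raise ValidationError(f"non-finite parameter for atom {atom.serial}")
    if missing:
        raise ParamLookupError(
            "sidecar does not cover topology atoms: " + ", ".join(missing))
    topology._cache.clear()
    return topology


def write_params(topology: Topology, path: str | Path) -> None:
    """Write the topology's nonbonded parameters as a JSON sidecar."""
    entries = [{
        "serial": a.serial,
        "residue_name": a.residue_name,
        "name": a.name,
        "element": a.element,
        "charge": a.charge,
        "lj_epsilon": a.lj_epsilon,
        "lj_rmin_half": a.lj_rmin_half,
        "mass": a.mass,
        "is_repulsive_center": a.is_repulsive_center,
        **({"amber_type": a.amber_type} if a.amber_type else {}),
    } for a in topology.atoms]
    Path(path).write_text(json.dumps({"atoms": entries}, indent=1))


def retime(trajectory: Trajectory, frame_interval_ns: float) -> Trajectory:
    """Return the same trajectory with frame times ``i * frame_interval_ns``."""
    if frame_interval_ns <= 0:
        raise ValidationError("frame_interval_ns must be > 0")
    frames = [replace(fr, time_ns=i * frame_interval_ns)
              for i, fr in enumerate(trajectory.frames)]
    return Trajectory(topology=trajectory.topology, frames=frames)
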