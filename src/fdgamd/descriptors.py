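"""Per-trajectory descriptor battery.

For each reactive ligand--receptor trajectory the analysis computes:

* intermolecular nonbonded energy E_inter = E_vdW + E_elec (all
  receptor--ligand atom pairs, no cutoff, vacuum dielectric 1, AMBER
  Lorentz-Berthelot combination of (epsilon, rmin/2) parameters);
* an MM/GBSA end-point binding free energy under the one-trajectory
  approximation (complex, receptor and ligand evaluated on the same
  frames, so every intramolecular term cancels exactly and dE_intra = 0):

      dG_bind = E_inter + dG_GB + dG_SA        (-T*dS omitted as a
                                                declared constant)

  with the polar term from a generalized-Born model (HCT pairwise
  descreening effective radii + Still interpolation, interior dielectric
  1, solvent 78.5) and the nonpolar term gamma * SASA with
  gamma = 0.0072 kcal/(mol*Å²);
* a 10 ns-block stability filter on the dG time series;
* the ligand's solvent exposure: SASA of the ligand inside the complex as
  a percentage of the same conformation's free SASA (Shrake-Rupley
  numerical surface, deterministic Fibonacci point grid);
* hydrogen-bond occupancies over the last 20 ns (heavy-atom D···A
  distance <= 3.0 Å and D-H···A angle >= 135°), retained above 45 %
  occupancy.

The estimator deliberately has no bonded-energy code path: under the
one-trajectory scheme intramolecular contributions can never enter the
binding energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_io import (
    COULOMB_CONSTANT,
    SOLVENT_DIELECTRIC,
    DomainError,
    Frame,
    SingularityError,
    Topology,
    ValidationError,
    logger,
)
from .trajectory_ops import LigandCopyTrajectory, ResidenceRecord

#: Nonpolar solvation coefficient gamma, kcal/(mol*Å²), zero offset.
SA_GAMMA = 0.0072

#: mbondi-style intrinsic GB radii (Å) by element, and the dielectric
#: offset subtracted before descreening.
MBONDI_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.5, "S": 1.8,
                "P": 1.85, "F": 1.47, "CL": 1.7, "BR": 1.85, "NA": 1.868,
                "K": 2.658}
GB_OFFSET = 0.09

#: HCT descreening scale factors by element.
HCT_SCREEN = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.96}
HCT_SCREEN_DEFAULT = 0.80

#: van der Waals radii (Å) for SASA, by element.
SASA_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8,
              "P": 1.8, "F": 1.47, "CL": 1.75, "BR": 1.85}


# ---------------------------------------------------------------------------
# Report containers
# ---------------------------------------------------------------------------

@dataclass
class EnergyReport:
    """Energy decomposition of one frame (kcal/mol).

    ``de_intra`` is identically zero under the one-trajectory
    approximation and ``tds_term`` is a declared omitted constant.
    """

    e_vdw: float
    e_elec: float
    dg_gb: float = 0.0
    dg_sa: float = 0.0
    de_intra: float = 0.0
    tds_term: str = "omitted-constant"

    @property
    def e_inter(self) -> float:
        return self.e_vdw + self.e_elec

    @property
    def dg_solv(self) -> float:
        return self.dg_gb + self.dg_sa

    @property
    def dg_bind_mmgbsa(self) -> float:
        return self.e_inter + self.de_intra + self.dg_gb + self.dg_sa


@dataclass
class SASAReport:
    sasa_ligand_complexed: float
    sasa_ligand_free: float
    percent_exposed: float


@dataclass
class HBondReport:
    """Donor--acceptor pairs with their occupancy over the evaluation
    window; ``retained`` holds those above the occupancy threshold."""

    pairs: list[tuple[int, int, int, float]]   # (donor, hydrogen, acceptor, occ)
    n_retained: int
    window_start_ns: float
    window_end_ns: float

    @property
    def retained(self) -> list[tuple[int, int, int, float]]:
        return [p for p in self.pairs if p in self._retained_set]

    def __post_init__(self) -> None:
        self._retained_set = set()


# ---------------------------------------------------------------------------
# Nonbonded intermolecular energy
# ---------------------------------------------------------------------------

def lj_pair_energy(eps_i: float, rmin_half_i: float, eps_j: float,
                   rmin_half_j: float, r: float,
                   repulsive_only: bool = False) -> float:
    """Lennard-Jones pair energy from AMBER (epsilon, rmin/2) parameters.

    E = A/r^12 - B/r^6 with A = eps*rmin^12 and B = 2*eps*rmin^6 after
    Lorentz-Berthelot combination; ``repulsive_only`` zeroes B (the
    anti-aggregation interaction between two repulsive centres).
    """
    if r <= 0:
        raise SingularityError("pair distance must be > 0")
    eps = math.sqrt(eps_i * eps_j)
    rmin = rmin_half_i + rmin_half_j
    a = eps * rmin ** 12
    b = 0.0 if repulsive_only else 2.0 * eps * rmin ** 6
    return a / r ** 12 - b / r ** 6


def nonbonded_inter_energy(frame: Frame, topology: Topology,
                           group_a: np.ndarray | None = None,
                           group_b: np.ndarray | None = None,
                           ) -> EnergyReport:
    """Receptor--ligand nonbonded interaction energy of one frame.

    Sums LJ and Coulomb (q_i q_j * 332.0637 / r) over all pairs between
    the two atom groups (defaults: receptor vs all ligand atoms), with no
    cutoff and vacuum dielectric.  Pairs of two repulsive centres use the
    purely repulsive branch.  Overlapping atoms (r < 1e-6 Å) raise
    :class:`SingularityError` naming the pair.
    """
    if group_a is None:
        group_a = topology.indices_of_kind("receptor")
    if group_b is None:
        group_b = topology.indices_of_kind("ligand")
    coords = frame.coordinates
    diff = coords[group_a][:, None, :] - coords[group_b][None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if np.any(r < 1e-6):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        a, b = topology.atoms[group_a[i]], topology.atoms[group_b[j]]
        raise SingularityError(
            f"overlapping atoms: serial {a.serial} ({a.name}) and "
            f"serial {b.serial} ({b.name}) at r = {r[i, j]:.2e} Å")

    q = topology.charges
    eps = np.sqrt(np.outer(topology.lj_epsilons[group_a],
                           topology.lj_epsilons[group_b]))
    rmin = (topology.lj_rmin_halves[group_a][:, None]
            + topology.lj_rmin_halves[group_b][None, :])
    ratio6 = (rmin / r) ** 6
    rep_pair = np.outer(topology.repulsive_flags[group_a],
                        topology.repulsive_flags[group_b])
    attract = np.where(rep_pair, 0.0, 2.0 * eps * ratio6)
    e_vdw = float(np.sum(eps * ratio6 ** 2 - attract))
    e_elec = float(COULOMB_CONSTANT
                   * np.sum(np.outer(q[group_a], q[group_b]) / r))
    return EnergyReport(e_vdw=e_vdw, e_elec=e_elec)


# ---------------------------------------------------------------------------
# Generalized Born polar solvation
# ---------------------------------------------------------------------------

def hct_effective_radii(coords: np.ndarray, intrinsic_radii: np.ndarray,
                        screens: np.ndarray | None = None) -> np.ndarray:
    """HCT pairwise-descreening effective Born radii.

    ``intrinsic_radii`` are the dielectric-offset radii rho_i; each
    neighbour j descreens with scaled radius s_j*rho_j through the
    standard HCT integral; 1/R_i = 1/rho_i - sum_j I_ij.  A lone atom's
    effective radius equals its intrinsic radius exactly.
    """
    rho = np.asarray(intrinsic_radii, dtype=float)
    if np.any(rho <= 0):
        raise DomainError("intrinsic radii must be > 0")
    n = len(rho)
    if screens is None:
        screens = np.full(n, HCT_SCREEN_DEFAULT)
    if n == 1:
        return rho.copy()
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    eye = np.eye(n, dtype=bool)
    r_safe = np.where(eye, 1.0, r)          # placeholder; masked out below
    sj = (screens * rho)[None, :]           # scaled neighbour radii
    u = r_safe + sj
    lo = np.maximum(np.abs(r_safe - sj), rho[:, None])
    # contributes only off-diagonal and when the neighbour sphere is not
    # fully buried inside atom i
    mask = (~eye) & (rho[:, None] < u)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (1.0 / lo - 1.0 / u
                + 0.25 * (r_safe - sj * sj / r_safe)
                * (1.0 / u ** 2 - 1.0 / lo ** 2)
                + 0.5 / r_safe * np.log(lo / u))
    integral = 0.5 * np.where(mask, term, 0.0).sum(axis=1)
    inv = 1.0 / rho - integral
    # descreening cannot push the radius negative; clamp generously
    inv = np.maximum(inv, 1.0 / (50.0 * rho))
    return 1.0 / inv


def gb_polar_energy(coords: np.ndarray, charges: np.ndarray,
                    intrinsic_radii: np.ndarray,
                    screens: np.ndarray | None = None,
                    solvent_dielectric: float = SOLVENT_DIELECTRIC) -> float:
    """Generalized-Born polar solvation energy (kcal/mol).

    Still interpolation f_GB = sqrt(r² + R_i R_j exp(-r²/(4 R_i R_j)))
    over all pairs including self terms (f_ii = R_i); interior dielectric
    1.  Reduces to the Born formula -1/2 (1 - 1/eps_w) k_e q²/rho for a
    single ion and is additive at large separation.
    """
    charges = np.asarray(charges, dtype=float)
    coords = np.asarray(coords, dtype=float)
    radii = hct_effective_radii(coords, intrinsic_radii, screens)
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.sum(diff * diff, axis=2)
    rirj = np.outer(radii, radii)
    f_gb = np.sqrt(r2 + rirj * np.exp(-r2 / (4.0 * rirj)))
    qq = np.outer(charges, charges)
    prefac = -0.5 * (1.0 - 1.0 / solvent_dielectric) * COULOMB_CONSTANT
    return float(prefac * np.sum(qq / f_gb))


def gb_intrinsic_radii(topology: Topology,
                       indices: np.ndarray | None = None) -> np.ndarray:
    """mbondi-style intrinsic radii (element lookup minus the 0.09 Å
    dielectric offset) for the selected atoms."""
    atoms = topology.atoms if indices is None else [topology.atoms[i]
                                                    for i in indices]
    return np.asarray([MBONDI_RADII.get(a.element.upper(), 1.5) - GB_OFFSET
                       for a in atoms])


def gb_screens(topology: Topology,
               indices: np.ndarray | None = None) -> np.ndarray:
    atoms = topology.atoms if indices is None else [topology.atoms[i]
                                                    for i in indices]
    return np.asarray([HCT_SCREEN.get(a.element.upper(), HCT_SCREEN_DEFAULT)
                       for a in atoms])


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set."""
    k = np.arange(n_points, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    rad = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rad * np.cos(phi), rad * np.sin(phi), z])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley numerical solvent-accessible surface area (Å²).

    Returns the per-atom SASA; deterministic for fixed ``n_points``
    (Fibonacci point grid).  A numerical approximation to the analytic
    (Connolly/molsurf) surface, accurate to ~2 % on a sphere at the
    default point count.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise DomainError("SASA radii must be > 0")
    n = len(radii)
    sphere = _fibonacci_sphere(n_points)
    expanded = radii + probe
    out = np.zeros(n)
    if n == 1:
        return np.array([4.0 * math.pi * expanded[0] ** 2])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    for i in range(n):
        neighbors = np.flatnonzero(
            (dist[i] < expanded[i] + expanded) & (np.arange(n) != i))
        area_i = 4.0 * math.pi * expanded[i] ** 2
        if neighbors.size == 0:
            out[i] = area_i
            continue
        pts = coords[i] + expanded[i] * sphere
        d = np.linalg.norm(pts[:, None, :] - coords[neighbors][None, :, :],
                           axis=2)
        exposed = np.all(d >= expanded[neighbors][None, :], axis=1)
        out[i] = area_i * np.count_nonzero(exposed) / n_points
    return out


def sasa_radii(topology: Topology,
               indices: np.ndarray | None = None) -> np.ndarray:
    atoms = topology.atoms if indices is None else [topology.atoms[i]
                                                    for i in indices]
    missing = [a.name for a in atoms if a.element.upper() not in SASA_RADII]
    if missing:
        raise KeyError(f"no SASA radius for atoms: {', '.join(missing)}")
    return np.asarray([SASA_RADII[a.element.upper()] for a in atoms])


def sa_nonpolar_energy(sasa_total: float, gamma: float = SA_GAMMA) -> float:
    """Nonpolar solvation term dG_SA = gamma * SASA (zero offset)."""
    if sasa_total < 0:
        raise DomainError("SASA must be >= 0")
    return gamma * sasa_total


def percent_exposed(frame: Frame, topology: Topology,
                    probe: float = 1.4, n_points: int = 960) -> SASAReport:
    """Ligand solvent exposure: SASA of the ligand atoms inside the complex
    as a percentage of the free ligand's SASA (same conformation)."""
    lig = topology.indices_of_kind("ligand")
    all_idx = np.concatenate([topology.indices_of_kind("receptor"), lig])
    radii_all = sasa_radii(topology, all_idx)
    per_atom = sasa(frame.coordinates[all_idx], radii_all, probe, n_points)
    lig_mask = np.isin(all_idx, lig)
    complexed = float(per_atom[lig_mask].sum())
    free = float(sasa(frame.coordinates[lig], sasa_radii(topology, lig),
                      probe, n_points).sum())
    if free <= 0:
        raise DomainError("free ligand SASA is zero (degenerate input)")
    return SASAReport(sasa_ligand_complexed=complexed, sasa_ligand_free=free,
                      percent_exposed=100.0 * complexed / free)


# ---------------------------------------------------------------------------
# MM/GBSA binding energy (one-trajectory approximation)
# ---------------------------------------------------------------------------

def mmgbsa_frame(frame: Frame, topology: Topology,
                 sasa_points: int = 240) -> EnergyReport:
    """Full MM/GBSA decomposition of one frame.

    dG_GB and dG_SA are complex-minus-parts differences evaluated on the
    same coordinates (one-trajectory scheme), so intramolecular MM terms
    cancel identically and never appear.
    """
    rec = topology.indices_of_kind("receptor")
    lig = topology.indices_of_kind("ligand")
    report = nonbonded_inter_energy(frame, topology, rec, lig)

    both = np.concatenate([rec, lig])
    coords = frame.coordinates
    radii = gb_intrinsic_radii(topology, both)
    screens = gb_screens(topology, both)
    q = topology.charges
    nrec = len(rec)
    gb_complex = gb_polar_energy(coords[both], q[both], radii, screens)
    gb_rec = gb_polar_energy(coords[rec], q[rec], radii[:nrec], screens[:nrec])
    gb_lig = gb_polar_energy(coords[lig], q[lig], radii[nrec:], screens[nrec:])

    sr = sasa_radii(topology, both)
    sasa_complex = sasa(coords[both], sr, n_points=sasa_points).sum()
    sasa_rec = sasa(coords[rec], sr[:nrec], n_points=sasa_points).sum()
    sasa_lig = sasa(coords[lig], sr[nrec:], n_points=sasa_points).sum()

    report.dg_gb = gb_complex - gb_rec - gb_lig
    report.dg_sa = (sa_nonpolar_energy(float(sasa_complex))
                    - sa_nonpolar_energy(float(sasa_rec))
                    - sa_nonpolar_energy(float(sasa_lig)))
    return report


def mmgbsa_binding(traj: LigandCopyTrajectory,
                   frame_indices: np.ndarray | list[int] | None = None,
                   sasa_points: int = 240,
                   ) -> tuple[list[EnergyReport], float]:
    """Per-frame MM/GBSA reports and their window average (kcal/mol)."""
    if frame_indices is None:
        frame_indices = range(len(traj.frames))
    reports = [mmgbsa_frame(traj.frames[i], traj.topology, sasa_points)
               for i in frame_indices]
    if not reports:
        raise ValidationError("empty MM/GBSA evaluation window")
    return reports, float(np.mean([r.dg_bind_mmgbsa for r in reports]))


# ---------------------------------------------------------------------------
# Stability filter
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    keep: bool
    evaluable: bool
    block_means: np.ndarray
    overall_mean: float
    block_sd: float


def stability_filter(times_ns: np.ndarray, dg_series: np.ndarray,
                     block_ns: float = 10.0,
                     scale: float = 2.0) -> StabilityReport:
    """Block-stability screen of a binding-energy time series.

    The series is cut into consecutive ``block_ns`` blocks; a trajectory
    is discarded when any block mean deviates from the overall mean of
    block means by strictly more than ``scale`` sample standard deviations
    of the block means.  Series spanning fewer than two blocks are flagged
    not evaluable and kept with a warning.
    """
    times_ns = np.asarray(times_ns, dtype=float)
    dg_series = np.asarray(dg_series, dtype=float)
    if len(times_ns) != len(dg_series):
        raise ValidationError("times and series length mismatch")
    block_idx = np.floor((times_ns - times_ns[0]) / block_ns).astype(int)
    blocks = np.unique(block_idx)       # only populated blocks
    n_blocks = len(blocks)
    if n_blocks < 2:
        logger.warning("stability filter: series spans < 2 blocks; "
                       "not evaluable, kept")
        return StabilityReport(keep=True, evaluable=False,
                               block_means=np.asarray([]),
                               overall_mean=float(np.mean(dg_series))
                               if len(dg_series) else math.nan,
                               block_sd=math.nan)
    means = np.asarray([dg_series[block_idx == b].mean() for b in blocks])
    overall = float(means.mean())
    sd = float(means.std(ddof=1))
    deviation = np.abs(means - overall)
    keep = bool(np.all(deviation <= scale * sd + 1e-12))
    return StabilityReport(keep=keep, evaluable=True, block_means=means,
                           overall_mean=overall, block_sd=sd)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

POLAR_ELEMENTS = ("N", "O")


def _donor_hydrogens(topology: Topology, coords: np.ndarray,
                     bond_cutoff: float = 1.25) -> list[tuple[int, int]]:
    """Infer (donor heavy atom, hydrogen) pairs by distance: an H within
    ``bond_cutoff`` Å of a polar heavy atom is treated as bonded to it."""
    h_idx = [i for i, a in enumerate(topology.atoms)
             if a.element.upper() == "H"]
    heavy = [i for i, a in enumerate(topology.atoms)
             if a.element.upper() in POLAR_ELEMENTS]
    pairs = []
    for h in h_idx:
        for d in heavy:
            if np.linalg.norm(coords[h] - coords[d]) <= bond_cutoff:
                pairs.append((d, h))
                break
    return pairs


def hydrogen_bonds(traj: LigandCopyTrajectory, window_ns: float = 20.0,
                   distance_cutoff: float = 3.0, angle_min_deg: float = 135.0,
                   occupancy_min: float = 0.45) -> HBondReport:
    """Intermolecular hydrogen-bond occupancies over the final window.

    Donors are polar heavy atoms (N/O) with an attached hydrogen (inferred
    geometrically from the first window frame); acceptors are polar heavy
    atoms.  A bond exists in a frame when the heavy-atom D···A distance is
    <= ``distance_cutoff`` and the D-H···A angle >= ``angle_min_deg``.
    Pairs with occupancy strictly above ``occupancy_min`` are retained.
    """
    times = traj.times
    t_end = float(times[-1])
    window = np.flatnonzero(times >= t_end - window_ns)
    topo = traj.topology
    kinds = topo.kinds
    first = traj.frames[window[0]].coordinates
    donors = _donor_hydrogens(topo, first)
    acceptors = [i for i, a in enumerate(topo.atoms)
                 if a.element.upper() in POLAR_ELEMENTS]
    candidates = [(d, h, a) for d, h in donors for a in acceptors
                  if a != d and kinds[a] != kinds[d]]
    if not candidates:
        return HBondReport(pairs=[], n_retained=0,
                           window_start_ns=float(times[window[0]]),
                           window_end_ns=t_end)

    counts = np.zeros(len(candidates), dtype=int)
    cos_min = math.cos(math.radians(angle_min_deg))
    for fi in window:
        coords = traj.frames[fi].coordinates
        for ci, (d, h, a) in enumerate(candidates):
            da = coords[a] - coords[d]
            if np.dot(da, da) > distance_cutoff ** 2:
                continue
            hd = coords[d] - coords[h]
            ha = coords[a] - coords[h]
            denom = np.linalg.norm(hd) * np.linalg.norm(ha)
            if denom <= 0:
                continue
            cos_angle = float(np.dot(hd, ha) / denom)
            # angle(D-H...A) >= angle_min  <=>  cos(angle) <= cos(angle_min)
            if cos_angle <= cos_min:
                counts[ci] += 1

    occ = counts / len(window)
    pairs = [(d, h, a, float(o)) for (d, h, a), o in zip(candidates, occ)]
    retained = [p for p in pairs if p[3] > occupancy_min]
    report = HBondReport(pairs=pairs, n_retained=len(retained),
                         window_start_ns=float(times[window[0]]),
                         window_end_ns=t_end)
    report._retained_set = set(retained)
    return report


# ---------------------------------------------------------------------------
# Full per-trajectory descriptor record
# ---------------------------------------------------------------------------

@dataclass
class DescriptorRecord:
    """Complete descriptor battery for one per-ligand trajectory."""

    source_replicate: int
    copy_id: int
    rt_ns: float
    bound_fraction: float
    final_distance: float
    e_vdw_rt_avg: float = math.nan
    e_elec_rt_avg: float = math.nan
    e_inter_rt_avg: float = math.nan
    e_inter_rt_best: float = math.nan
    e_inter_last20_avg: float = math.nan
    mmgbsa_rt_avg: float = math.nan
    mmgbsa_rt_best: float = math.nan
    mmgbsa_last20_avg: float = math.nan
    sasa_percent_last: float = math.nan
    sasa_percent_rt_avg: float = math.nan
    n_hbonds: int = 0
    hbond_occupancies: list[float] = field(default_factory=list)
    stability_keep: bool = True
    stability_evaluable: bool = False
    site_id: int | None = None


def _window_frames(times: np.ndarray, start_ns: float, end_ns: float,
                   max_frames: int,
                   keep: np.ndarray | None = None) -> np.ndarray:
    """Frame indices inside [start, end], optionally restricted by a
    boolean mask, evenly subsampled to at most ``max_frames`` (always
    keeping the last frame)."""
    in_window = (times >= start_ns - 1e-9) & (times <= end_ns + 1e-9)
    if keep is not None:
        in_window &= keep
    idx = np.flatnonzero(in_window)
    if idx.size > max_frames:
        picks = np.unique(np.round(
            np.linspace(0, idx.size - 1, max_frames)).astype(int))
        idx = idx[picks]
    return idx


def compute_descriptors(traj: LigandCopyTrajectory,
                        residence: ResidenceRecord,
                        config=None, max_window_frames: int = 25,
                        sasa_points: int = 240) -> DescriptorRecord:
    """Evaluate the full descriptor battery for one reactive trajectory.

    Energy and SASA averages over the RT window (and the last 20 ns) are
    evaluated on an even subsample of at most ``max_window_frames`` frames
    to bound the cost of the O(n²) GB/SASA kernels.
    """
    from .model_io import AnalysisConfig
    from .trajectory_ops import distance_series
    cfg = config or AnalysisConfig()
    times = traj.times
    t_end = float(times[-1])

    record = DescriptorRecord(
        source_replicate=traj.source_replicate, copy_id=traj.copy_id,
        rt_ns=residence.rt_ns, bound_fraction=residence.bound_fraction,
        final_distance=residence.final_distance)

    # RT-window descriptors are evaluated on the *bound* frames of the
    # residence window: the 90 %-occupancy rule lets the window reach into
    # unbound stretches, whose near-zero energies would otherwise dilute
    # the averages and trip the stability screen by construction.
    rt_idx = _window_frames(times, residence.window_start_ns, t_end,
                            max_window_frames,
                            keep=distance_series(traj) < cfg.interaction_cutoff)
    last20_idx = _window_frames(times, t_end - cfg.hbond_window_ns, t_end,
                                max_window_frames)

    rec_idx = traj.receptor_indices()
    lig_idx = traj.ligand_indices()
    e_rt = [nonbonded_inter_energy(traj.frames[i], traj.topology,
                                   rec_idx, lig_idx) for i in rt_idx]
    record.e_vdw_rt_avg = float(np.mean([r.e_vdw for r in e_rt]))
    record.e_elec_rt_avg = float(np.mean([r.e_elec for r in e_rt]))
    record.e_inter_rt_avg = float(np.mean([r.e_inter for r in e_rt]))
    record.e_inter_rt_best = float(np.min([r.e_inter for r in e_rt]))
    e_last = [nonbonded_inter_energy(traj.frames[i], traj.topology,
                                     rec_idx, lig_idx) for i in last20_idx]
    record.e_inter_last20_avg = float(np.mean([r.e_inter for r in e_last]))

    gb_rt, record.mmgbsa_rt_avg = mmgbsa_binding(traj, rt_idx, sasa_points)
    record.mmgbsa_rt_best = float(np.min([r.dg_bind_mmgbsa for r in gb_rt]))
    _, record.mmgbsa_last20_avg = mmgbsa_binding(traj, last20_idx, sasa_points)

    stability = stability_filter(times[rt_idx],
                                 np.asarray([r.dg_bind_mmgbsa for r in gb_rt]),
                                 block_ns=cfg.stability_block_ns,
                                 scale=cfg.stability_sd_scale)
    record.stability_keep = stability.keep
    record.stability_evaluable = stability.evaluable

    record.sasa_percent_last = percent_exposed(
        traj.frames[-1], traj.topology, n_points=sasa_points).percent_exposed
    sasa_vals = [percent_exposed(traj.frames[i], traj.topology,
                                 n_points=sasa_points).percent_exposed
                 for i in rt_idx]
    record.sasa_percent_rt_avg = float(np.mean(sasa_vals))

    hb = hydrogen_bonds(traj, window_ns=cfg.hbond_window_ns,
                        distance_cutoff=cfg.hbond_distance_cutoff,
                        angle_min_deg=cfg.hbond_angle_min_deg,
                        occupancy_min=cfg.hbond_occupancy_min)
    record.n_hbonds = hb.n_retained
    record.hbond_occupancies = [p[3] for p in hb.pairs]
    return record
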