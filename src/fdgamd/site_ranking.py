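"""Binding-site definition, Jaccard clustering, aggregation and consensus.

Each reactive trajectory contributes a *contact set*: the protein residues
with any atom strictly closer than 4.5 Å to the ligand in the trajectory's
final frame.  Contact sets are merged into binding sites by greedy
sequential clustering on the Jaccard index

    J(A, B) = |A ∩ B| / |A ∪ B|

joining an existing site when J against its canonical (running-union)
residue set is strictly greater than 0.35, else founding a new site.

Per site, descriptors are aggregated across replicates: "best" is the most
favourable member value (max RT, min energies, min %SASA, max H-bonds) and
"averaged" is the sum over the site's reactive-trajectory values divided by
the number of independent replicates (explicitly *not* by the member
count), so sites found in few replicates are penalised.  A consensus vote
then gives one vote per ranked descriptor column to the site holding the
most favourable value; the most-voted site is the predicted binding site,
with vote ties broken by lower averaged MM/GBSA, then lower averaged
E_inter (reported as tie-broken).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorRecord
from .model_io import AnalysisConfig, ValidationError, logger
from .trajectory_ops import LigandCopyTrajectory

Residue = tuple[str, int, str]      # (chain, residue_id, residue_name)


@dataclass
class ContactSet:
    """Residue contact fingerprint of one reactive trajectory."""

    residues: frozenset[Residue]
    source: tuple[int, int]          # (replicate, copy_id)
    frame_used: float                # time_ns of the frame


@dataclass
class BindingSiteCluster:
    site_id: int
    canonical_residues: frozenset[Residue]
    members: list[tuple[int, int, ContactSet, DescriptorRecord]] = field(
        default_factory=list)


# ---------------------------------------------------------------------------
# Contacts and Jaccard
# ---------------------------------------------------------------------------

def contact_residues(traj: LigandCopyTrajectory, cutoff: float = 4.5,
                     frame_index: int = -1) -> ContactSet:
    """Protein residues with any atom strictly closer than ``cutoff`` Å to
    any ligand atom in the selected frame (default: last)."""
    topo = traj.topology
    coords = traj.frames[frame_index].coordinates
    rec_idx = traj.receptor_indices()
    lig_idx = traj.ligand_indices()
    diff = coords[rec_idx][:, None, :] - coords[lig_idx][None, :, :]
    dmin = np.min(np.linalg.norm(diff, axis=2), axis=1)
    residues = set()
    for i, d in zip(rec_idx, dmin):
        if d < cutoff:
            atom = topo.atoms[i]
            residues.add((atom.chain_or_copy, atom.residue_id,
                          atom.residue_name))
    if not residues:
        logger.warning("empty contact set for replicate %d copy %d "
                       "(reactive trajectory)", traj.source_replicate,
                       traj.copy_id)
    return ContactSet(residues=frozenset(residues),
                      source=(traj.source_replicate, traj.copy_id),
                      frame_used=float(traj.times[frame_index]))


def contact_residues_windowed(traj: LigandCopyTrajectory,
                              window_start_ns: float, cutoff: float = 4.5,
                              presence: float = 0.5) -> ContactSet:
    """Alternative contact mode: residues present in at least ``presence``
    of the frames of the residence window."""
    times = traj.times
    idx = np.flatnonzero(times >= window_start_ns - 1e-9)
    counts: dict[Residue, int] = {}
    for fi in idx:
        cs = contact_residues(traj, cutoff, int(fi))
        for res in cs.residues:
            counts[res] = counts.get(res, 0) + 1
    kept = frozenset(r for r, c in counts.items() if c / len(idx) >= presence)
    return ContactSet(residues=kept,
                      source=(traj.source_replicate, traj.copy_id),
                      frame_used=float(times[-1]))


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B|, with J(∅, ∅) = 0 by convention."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


# ---------------------------------------------------------------------------
# Greedy site assignment
# ---------------------------------------------------------------------------

def assign_sites(entries: list[tuple[ContactSet, DescriptorRecord]],
                 threshold: float = 0.35) -> list[BindingSiteCluster]:
    """Greedy sequential clustering of contact sets into binding sites.

    Entries are processed in deterministic (replicate, copy_id) order;
    each joins the existing cluster with the highest Jaccard index against
    the cluster's canonical set, provided J is strictly greater than
    ``threshold``; otherwise it founds a new cluster.  The canonical set
    is updated to the running union after each join.
    """
    if not (0 <= threshold <= 1):
        raise ValidationError("threshold must be in [0, 1]")
    ordered = sorted(entries, key=lambda e: e[0].source)
    clusters: list[BindingSiteCluster] = []
    for cset, record in ordered:
        best, best_j = None, threshold
        for cluster in clusters:
            j = jaccard(cset.residues, cluster.canonical_residues)
            if j > best_j:
                best, best_j = cluster, j
        if best is None:
            best = BindingSiteCluster(site_id=len(clusters) + 1,
                                      canonical_residues=cset.residues)
            clusters.append(best)
        else:
            best.canonical_residues = best.canonical_residues | cset.residues
        best.members.append((cset.source[0], cset.source[1], cset, record))
        record.site_id = best.site_id
    return clusters


# ---------------------------------------------------------------------------
# Aggregation and consensus vote
# ---------------------------------------------------------------------------

#: Ranked descriptor columns: (name, most-favourable direction).
VOTE_COLUMNS: list[tuple[str, str]] = [
    ("n_reactive", "max"),
    ("best_rt_ns", "max"),
    ("best_e_inter_rt", "min"),
    ("avg_e_inter_rt", "min"),
    ("best_mmgbsa_rt", "min"),
    ("avg_mmgbsa_rt", "min"),
    ("avg_mmgbsa_last20", "min"),
    ("sasa_percent_last", "min"),
    ("max_hbonds", "max"),
]


@dataclass
class RankingRow:
    site_id: int
    n_members: int
    n_reactive: int                 # distinct replicates represented
    best_rt_ns: float
    best_e_inter_rt: float
    avg_e_inter_rt: float
    avg_e_inter_last20: float
    best_mmgbsa_rt: float
    avg_mmgbsa_rt: float
    avg_mmgbsa_last20: float
    sasa_percent_last: float
    sasa_percent_rt_avg: float
    max_hbonds: int
    residues: frozenset[Residue] = frozenset()
    votes: int = 0


def _replicate_average(values: list[float], n_replicates: int) -> float:
    """Protocol averaging rule: sum of reactive values / replicate count."""
    finite = [v for v in values if math.isfinite(v)]
    return sum(finite) / n_replicates


def aggregate(clusters: list[BindingSiteCluster],
              n_replicates: int) -> list[RankingRow]:
    """One :class:`RankingRow` per binding site.

    ``n_reactive`` counts distinct replicates contributing at least one
    reactive trajectory (capped at the replicate count by construction).
    Members with a missing (NaN) descriptor are excluded from that column
    with a logged warning.
    """
    rows = []
    for cluster in clusters:
        if not cluster.members:
            raise ValidationError(f"site {cluster.site_id} has no members")
        records = [m[3] for m in cluster.members]
        for rec in records:
            bad = [name for name in ("e_inter_rt_avg", "mmgbsa_rt_avg")
                   if not math.isfinite(getattr(rec, name))]
            if bad:
                logger.warning("site %d: replicate %d copy %d missing %s; "
                               "excluded from those columns",
                               cluster.site_id, rec.source_replicate,
                               rec.copy_id, ",".join(bad))
        replicates = {m[0] for m in cluster.members}
        rows.append(RankingRow(
            site_id=cluster.site_id,
            n_members=len(cluster.members),
            n_reactive=len(replicates),
            best_rt_ns=max(r.rt_ns for r in records),
            best_e_inter_rt=min(r.e_inter_rt_best for r in records),
            avg_e_inter_rt=_replicate_average(
                [r.e_inter_rt_avg for r in records], n_replicates),
            avg_e_inter_last20=_replicate_average(
                [r.e_inter_last20_avg for r in records], n_replicates),
            best_mmgbsa_rt=min(r.mmgbsa_rt_best for r in records),
            avg_mmgbsa_rt=_replicate_average(
                [r.mmgbsa_rt_avg for r in records], n_replicates),
            avg_mmgbsa_last20=_replicate_average(
                [r.mmgbsa_last20_avg for r in records], n_replicates),
            sasa_percent_last=min(r.sasa_percent_last for r in records),
            sasa_percent_rt_avg=_replicate_average(
                [r.sasa_percent_rt_avg for r in records], n_replicates),
            max_hbonds=max(r.n_hbonds for r in records),
            residues=cluster.canonical_residues,
        ))
    return rows


@dataclass
class ConsensusResult:
    rows: list[RankingRow]          # sorted by votes (descending)
    selected_site_id: int
    tie_broken: bool


def consensus_vote(rows: list[RankingRow]) -> ConsensusResult:
    """Per-descriptor best-value vote and final site selection.

    Each ranked column gives one vote to the site holding its most
    favourable value (ties on a column give one vote to every tied site).
    The selected site is the vote argmax; exact vote ties are broken by
    lower averaged MM/GBSA (RT window), then lower averaged E_inter, and
    flagged as tie-broken.
    """
    if not rows:
        raise ValidationError("consensus vote needs at least one site")
    for row in rows:
        row.votes = 0
    for column, direction in VOTE_COLUMNS:
        values = [getattr(r, column) for r in rows]
        finite = [(v, r) for v, r in zip(values, rows) if math.isfinite(v)]
        if not finite:
            continue
        best = max(v for v, _ in finite) if direction == "max" else \
            min(v for v, _ in finite)
        for v, r in finite:
            if v == best:
                r.votes += 1

    top_votes = max(r.votes for r in rows)
    leaders = [r for r in rows if r.votes == top_votes]
    tie_broken = len(leaders) > 1
    selected = min(leaders, key=lambda r: (r.avg_mmgbsa_rt, r.avg_e_inter_rt,
                                           r.site_id))
    ordered = sorted(rows, key=lambda r: (-r.votes, r.avg_mmgbsa_rt,
                                          r.avg_e_inter_rt, r.site_id))
    return ConsensusResult(rows=ordered, selected_site_id=selected.site_id,
                           tie_broken=tie_broken)


def ranking_table(rows: list[RankingRow]) -> pd.DataFrame:
    """Per-site ranking as a DataFrame (one RankingRow per line)."""
    return pd.DataFrame([{
        "site_id": r.site_id,
        "n_reactive": r.n_reactive,
        "best_rt_ns": r.best_rt_ns,
        "best_e_inter_rt": r.best_e_inter_rt,
        "avg_e_inter_rt": r.avg_e_inter_rt,
        "avg_e_inter_last20": r.avg_e_inter_last20,
        "best_mmgbsa_rt": r.best_mmgbsa_rt,
        "avg_mmgbsa_rt": r.avg_mmgbsa_rt,
        "avg_mmgbsa_last20": r.avg_mmgbsa_last20,
        "sasa_percent_last": r.sasa_percent_last,
        "sasa_percent_rt_avg": r.sasa_percent_rt_avg,
        "max_hbonds": r.max_hbonds,
        "votes": r.votes,
        "residues": ";".join(f"{c}:{i}:{n}" for c, i, n in sorted(r.residues)),
    } for r in rows])


# ---------------------------------------------------------------------------
# End-to-end analysis of a replicate set
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    records: list[DescriptorRecord]
    clusters: list[BindingSiteCluster]
    rows: list[RankingRow]
    consensus: ConsensusResult | None
    n_trajectories: int
    n_reactive: int
    #: residence record per (replicate, copy) passing the final-frame screen
    residences: dict = field(default_factory=dict)


def analyze_multicopy(replicate_trajectories, config: AnalysisConfig | None = None,
                      max_window_frames: int = 25,
                      sasa_points: int = 240) -> AnalysisResult:
    """Run the full per-ligand analysis over a set of replicate
    multicopy trajectories.

    ``replicate_trajectories`` is an iterable of (replicate_id,
    multicopy :class:`~fdgamd.model_io.Trajectory`) pairs with real (ns)
    frame times.  Steps: strip & split -> final-frame 5 Å screen -> RT ->
    reactive filter -> descriptor battery -> contact sets -> Jaccard site
    assignment -> aggregation -> consensus vote.
    """
    from .descriptors import compute_descriptors
    from .trajectory_ops import (end_screen, reactive_filter, residence_time,
                                 strip_and_split)

    cfg = config or AnalysisConfig()
    screened = []
    residences: dict[tuple[int, int], object] = {}
    n_total = 0
    for replicate_id, mc_traj in replicate_trajectories:
        for lig_traj in strip_and_split(mc_traj, replicate_id):
            n_total += 1
            if not end_screen(lig_traj, cfg.interaction_cutoff):
                continue
            residence = residence_time(lig_traj, cfg.interaction_cutoff,
                                       cfg.rt_occupancy_fraction)
            residences[(replicate_id, lig_traj.copy_id)] = residence
            screened.append((lig_traj, residence))
    reactive = reactive_filter(screened, cfg.rt_cutoff_ns)

    records: list[DescriptorRecord] = []
    entries: list[tuple[ContactSet, DescriptorRecord]] = []
    for lig_traj, residence in reactive:
        record = compute_descriptors(lig_traj, residence, cfg,
                                     max_window_frames, sasa_points)
        if record.stability_evaluable and not record.stability_keep:
            logger.info("replicate %d copy %d discarded by stability filter",
                        lig_traj.source_replicate, lig_traj.copy_id)
            continue
        records.append(record)
        entries.append((contact_residues(lig_traj, cfg.contact_cutoff),
                        record))

    clusters = assign_sites(entries, cfg.jaccard_threshold)
    rows = aggregate(clusters, cfg.n_replicates) if clusters else []
    consensus = consensus_vote(rows) if rows else None
    return AnalysisResult(records=records, clusters=clusters, rows=rows,
                          consensus=consensus, n_trajectories=n_total,
                          n_reactive=len(reactive), residences=residences)
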