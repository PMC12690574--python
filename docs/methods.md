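# Methods

This note documents the models and procedures implemented in `fdgamd`,
the defaults and units they use, the design decisions taken where the
protocol leaves room, and what the synthetic fixtures do and do not
emulate.

## Units and conventions

All coordinates are in Å, energies in kcal/mol, charges in elementary
units, masses in amu. Lennard-Jones parameters are stored as
(ε, r_min/2) and combined with Lorentz–Berthelot rules
(r_min,ij = r_min,i/2 + r_min,j/2; ε_ij = √(ε_i ε_j)). The Coulomb
constant is fixed at 332.0637 kcal·Å/(mol·e²), the GB solvent
dielectric at 78.5, the interior dielectric at 1. PDB files carry no
time information, so every analysis entry point that needs residence
times requires an explicit frame interval in ns.

## System preparation

* **Principal axes.** Axes are eigenvectors of the mass-weighted
  covariance (gyration) tensor about the centre of mass, ordered by
  descending extent. Signs are fixed deterministically (largest
  component of each of the first two axes positive; the third is their
  cross product, guaranteeing a right-handed frame). Collinear point
  sets raise a degeneracy error; near-degenerate spectra (relative
  eigenvalue gap < 1e-8) keep the same deterministic convention so
  symmetric fragments always align identically.
* **Box tiling.** The ligand template box is replicated verbatim on the
  minimal rectangular lattice covering the receptor extent plus the
  solvation shell (20 Å default) on every side, centred on the receptor
  centre of mass. Partial edge boxes are included. The tiling origin and
  edge handling are package choices; the shell is measured from the
  per-axis bounding extent of the receptor. A template box larger than
  the target region is rejected.
* **Clash pruning** removes template molecules *whole* when any atom is
  strictly closer than 1 Å (default) to a receptor atom; pruning is
  order-independent by construction. No water re-equilibration is
  performed — the template is assumed pre-equilibrated.
* **Repulsive term.** The designated central atom of each ligand copy
  (explicit name, or the heuristic: the non-C/non-H heteroatom nearest
  the copy's unweighted centroid, falling back to carbon) is flagged and
  retyped `<element>99` for element in {C, N, O, S}. Pairs of two
  flagged atoms interact through the r⁻¹² branch only; all other pairs
  are untouched, so a system with fewer than two flagged atoms has
  exactly unchanged energy.
* **GaMD schedule.** `ntave = 4·N_atoms`, `ntcmdprep = ntebprep =
  2·ntave`, `ntcmd = 5·ntave`, in integer arithmetic.

## GaMD boost

`ΔU = ½k(E−U)²` below the threshold and zero above it; `k = k₀/(U_max −
U_min)` with `k₀ ∈ [0, 1]`. The default threshold convention is the
lower bound `E = U_max` (configurable). The boosted force is the
unboosted force scaled by `1 − k(E−U)` for `U < E`; with `E ≤ U_min +
1/k` the smoothed potential is non-decreasing wherever the original is,
which is the usual GaMD smoothness condition. Running potential
statistics use Welford's online algorithm; the standard deviation is
flagged undefined below two samples. No k₀ update formula is
implemented beyond capping at 1 — adaptive optimization is left to the
MD engine. Reweighting of boosted observables is out of scope.

**Double-well demonstrator.** Overdamped Langevin dynamics on
`U(x) = h(x²−1)²` in reduced units, Euler–Maruyama with friction and
mass absorbed into the step size. The step size defaults to
`min(0.01, 1/(16h))`, keeping `dt·U''` below the Euler stability bound
across the well region. A preparation phase of 20 % of the requested
steps (minimum 10) runs unboosted to collect `U_max/U_min`; both
production runs then share one pre-drawn noise sequence, so `k₀ = 0`
reproduces the unboosted trajectory bit for bit. Crossings of `x = 0`
are counted with a ±0.25 hysteresis band to suppress barrier-top
chatter. With the defaults (h = 8 kcal/mol, kT = 0.6, 2·10⁵ steps) the
unboosted walker essentially never crosses while the k₀ = 1 walker
crosses tens of times — the point is the inequality, not a specific
count.

## Per-ligand analysis

* **Stripping/splitting** removes waters and ions and emits one
  receptor + single-copy trajectory per fragment copy; receptor atoms
  and frame times are identical across outputs.
* **Distance screen.** All screens use the minimum distance between the
  copy's flagged central atom and any protein atom (an any-ligand-atom
  mode exists for sensitivity checks). The final-frame screen discards
  strictly greater than 5 Å; 5.0 Å exactly is kept. No periodic-image
  correction is applied by default (stripped trajectories are assumed
  imaged).
* **Residence time** is the longest window *ending at the final frame*
  whose fraction of bound frames (distance < 5 Å) is at least 0.90;
  RT = 0 when the final frame is unbound. End-anchoring matches the
  final-frame screen; note that the 90 % rule lets the window extend up
  to RT/9 into a preceding unbound stretch, so RT can exceed the length
  of the last contiguous bound run. This is the central interpretive
  decision of the implementation and is applied consistently in the
  fixture ground truth. The reactive cutoff keeps RT ≥ 50 ns.
* **Energies.** E_inter sums Lennard-Jones and Coulomb over all
  receptor–ligand pairs with no cutoff in vacuum (ε = 1). MM/GBSA uses
  the one-trajectory approximation: complex, receptor and ligand are
  evaluated on the same coordinates, so intramolecular terms cancel
  identically — the estimator has no bonded-energy code path at all,
  and the entropy term is a declared omitted constant. The GB polar
  term uses HCT pairwise-descreening effective radii (mbondi-style
  element radii minus a 0.09 Å offset, element screening factors) with
  Still's interpolation; exact numeric parity with any specific engine
  is a non-goal — the contracts are the Born single-ion limit, large-
  separation additivity, non-positivity and q² scaling. The nonpolar
  term is γ·SASA with γ = 0.0072 kcal/(mol·Å²) and zero offset.
* **SASA** is Shrake–Rupley with a deterministic Fibonacci point grid
  (960 points default, 2 % sphere accuracy; the pipeline uses 240
  points per atom as a speed/accuracy compromise). Ligand exposure is
  reported as 100 · SASA(ligand in complex)/SASA(ligand alone, same
  conformation), at the last snapshot and averaged over the residence
  window.
* **RT-window descriptors are evaluated on the bound frames of the
  residence window**, evenly subsampled to at most 25 frames to bound
  the O(n²) GB/SASA cost. Including the unbound lead admitted by the
  90 % rule would dilute the averages with near-zero energies and make
  the stability screen reject every mid-simulation binder by
  construction, which cannot be the protocol's intent.
* **Stability filter.** The MM/GBSA series is cut into 10 ns blocks
  (populated blocks only); a trajectory is discarded when any block
  mean deviates from the mean of block means by strictly more than 2.0
  (configurable) sample standard deviations of the block means. Series
  spanning fewer than two blocks are flagged not evaluable and kept.
  With subsampled frames a block may hold a single frame, making the
  filter act as an outlier screen; a small fraction of genuinely stable
  trajectories can be rejected by noise, which the consensus tolerates.
* **Hydrogen bonds** are evaluated over the last 20 ns: donors are
  polar heavy atoms (N/O) with a hydrogen within 1.25 Å (inferred from
  the first window frame), acceptors are polar heavy atoms of the other
  molecule; a bond exists when the D···A distance is ≤ 3.0 Å and the
  D–H···A angle ≥ 135°. Pairs are retained above 45 % occupancy
  (strictly greater).

## Site definition, aggregation, consensus

Contact sets are the receptor residues with any atom strictly closer
than 4.5 Å to any ligand atom in the trajectory's final frame (a
windowed mode keeps residues present in ≥ 50 % of residence-window
frames). Sets are clustered greedily in (replicate, copy) order: a set
joins the existing cluster with the highest Jaccard index against the
cluster's running-union canonical set when J > 0.35 strictly, else
founds a new cluster. The greedy-with-union rule is a deterministic
choice; reordering the input can change the clustering, which is why
the order is fixed.

Per site: `n_reactive` counts distinct replicates (maximum = replicate
count); "best" takes the most favourable member value; "averaged"
divides the sum of reactive-trajectory values by the *number of
replicates*, not the member count, deliberately penalising sites found
in few replicates. Nine columns are voted on — n_reactive, best RT,
best and averaged E_inter (residence window), best and averaged MM/GBSA
(residence window), averaged MM/GBSA (last 20 ns), % SASA (last
snapshot), max H-bonds — one vote each, ties on a column voting for
every tied site. The most-voted site wins; exact vote ties are broken
by lower averaged MM/GBSA, then lower averaged E_inter, and reported as
tie-broken.

## Synthetic fixtures

The toy receptor is a bead protein: one backbone and one sidechain bead
per residue on a 12 Å sphere (quasi-uniform Fibonacci placement),
with each pocket built as a concave ring — a central acceptor bead
indented 1 Å below the surface plus a 3 Å ring — around an anchor
direction; two requested pockets sit ≥ 20 Å apart. The fragment is four
atoms (central N99 with an H aimed into the pocket, one C, one O) with
toy GAFF-like LJ parameters and small partial charges. Trajectories are
*kinematic*: each copy follows its programmed event schedule (bound:
central atom placed `mean_distance` ± `jitter` outward of the pocket's
central bead; unbound: parked on a far orbit > 12 Å away), with all
noise drawn from a generator seeded by (spec seed, replicate). Defaults
mirror the study conditions: 4 replicates × 400 ns, with a 2 ns frame
interval (the saving interval is not prescribed by the protocol; 2 ns
gives 201 frames per replicate, enough to resolve every screen at
tractable cost). A handful of far-away waters and ions exercise the
stripping stage.

Ground truth is derived from the schedule alone: residence times by an
independent exhaustive suffix-window scan of the ideal bound indicator,
sites from the final bound event, contacts from the programmed pocket
lists, and the best site as the one accumulating the most reactive
residence time. The `dominant_site_spec` study programs pocket 0 as
tight (2.9–3.1 Å placement, long RTs, every replicate) and pocket 1 as
loose (4.1 Å, short RT, half the replicates), so the true consensus
winner is unambiguous.

What the fixtures do **not** emulate: real protein geometry and
chemistry, force-field-quality energetics, actual binding/unbinding
kinetics, solvent effects beyond the implicit model, and periodic
boundary artefacts. Passing the end-to-end recovery therefore shows the
*pipeline logic* (screens, windows, clustering, aggregation, voting) is
correct on data with known truth — not that the descriptors would rank
real binding sites correctly.

## Numerical choices and degenerate inputs

Overlapping atoms (r < 1e-6 Å) raise a singularity error naming the
pair; zero free-ligand SASA is a degenerate-input error; empty polar
atom sets yield an empty hydrogen-bond report rather than an error;
clusters cannot be empty by construction. HCT descreening is clamped so
an effective radius never exceeds 50× the intrinsic radius. Boundary
semantics are literal throughout: "greater than 5 Å" discards strictly
greater, "at least 50 ns" keeps equality, "J > 0.35" at exactly 0.35
founds a new site, "greater than 45 %" at exactly 0.45 is not retained.

## Known limitations

* MM/GBSA values are toy-parameterised descriptors here; no claim of
  engine-level parity (igb flavours, surface definitions) is made.
* The boost demonstrator is one-dimensional and overdamped; it
  illustrates barrier-crossing acceleration, not molecular kinetics.
* The greedy site clustering is order-dependent by design; a different
  deterministic order could merge sites differently near the Jaccard
  threshold.
* Binary MD trajectory formats are supported only through external
  readers adapting into the `Trajectory` container; the native format
  is multi-model PDB.
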