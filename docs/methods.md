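# Methods

This note records the models, conventions and design choices behind
`hydronet`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate model

An `Ensemble` is an ordered list of frames sharing one non-water atom table;
the water complement may differ per frame, which is how solvent
identity-exchange appears in multi-MODEL PDB trajectories.  Residue and atom
numbering from the input is preserved verbatim — author numbering in
deposited structures is meaningful (e.g. Cu ions numbered in the 3000s) and
renumbering would silently break cross-references.  The sampling period
defaults to 2 ps per frame, the convention of the trajectories this package
was built to analyse; times are `t0 + k·frame_interval`.

Waters are handled oxygen-only throughout.  Trajectory frames converted to a
three-site water model may or may not carry hydrogens and crystal structures
never do; keying every water analysis on the oxygen makes both input classes
uniform.  The water residue-name set ({HOH, WAT, TIP3, SOL}) is
configurable.  Altloc handling keeps the highest-occupancy copy, ties
breaking toward the earliest altloc letter (deterministic).  Reading is
backed by gemmi; writing is a fixed-column formatter that guarantees the
3-decimal round trip the tests rely on.

## Superposition

Kabsch least squares via SVD of the weighted covariance matrix, with the
reflection corrected by flipping the smallest singular vector, so the
rotation is always proper.  Rank-deficient (collinear) point sets and sets
of fewer than three atoms are rejected rather than silently fitted.  The
default fit selection is the protein backbone (N, CA, C, O) excluding
waters, ligand and metals: those are the analytes, and fitting on them would
absorb exactly the motion being measured.  The reference is frame 0 by
default; an external reference model (e.g. a crystal structure) can be
supplied, which is also how recovered site centroids can be expressed in a
structure's own frame.

## Interaction criteria

All criteria are distance-based on heavy atoms; with hydrogens unavailable
in general no angle term is defensible, and published distance tables for
systems of this kind span 2.45–3.5 Å for hydrogen bonds.

| interaction | criterion | default |
|---|---|---|
| hydrogen bond | donor–acceptor heavy-atom distance | ≤ 3.5 Å |
| salt bridge | Asp/Glu carboxylate O to Lys NZ / Arg NE,NH1,NH2 (His optional) | ≤ 4.0 Å |
| metal coordination | metal to N/O/S (water O included) | ≤ 3.0 Å |
| T-shaped π-stack | ring-centroid distance and inter-plane angle | 4.0–7.0 Å, 60–120° |

The salt-bridge and π windows are field-standard values, exposed in the
config.  Intra-residue pairs and 1-2/1-3 pairs across the peptide bond are
excluded from hydrogen bonds.  Polar atoms of residues outside the built-in
donor/acceptor table (ligands, cofactors) default to donor-and-acceptor,
since their protonation is not modelled; the table is overridable.

Occupation frequency of a key is `100 · n_present / n_total` over the
analysed frame range (default: all frames).  Whether O.F. is counted at
atom level or residue level (Asp OD1 *or* OD2) is an explicit grouping
choice of the caller (`pair_key` vs `residue_pair_key`); published tables
usually group by residue, so the pipeline default does.

## Conserved-water sites

Superposed water oxygens are paired to sites with a 1.8 Å cutoff.  Single
superposition-pairing generalizes to many frames as greedy leader
clustering: waters are processed frame by frame; each joins the nearest
existing site whose current centroid is within the cutoff (at most one
water per site per frame — the nearer wins and the displaced water is
re-queued) or seeds a new site.  A second pass freezes the pass-1 centroids
and re-assigns every water against them; the final centroid is the mean of
the retained members.  The algorithm is O(waters × sites), fully
deterministic for a fixed frame order, and every assignment is auditable
(member distance at assignment time is recorded).  Sites are labelled
WS1, WS2, … by descending occupancy, not discovery order, so labels are
stable under re-analysis.

Site O.F. counts *site* occupancy — any water id — because identity
exchange at a conserved position is expected and is itself reported (the
distinct ids per site).  Conservation classes are conserved ≥ 90 %,
semi-conserved ≥ 60 %, transient below; the literature calls ~100 % sites
conserved and ~85 % sites semi-conserved without fixing thresholds, so
these two are package conventions and are config-exposed.  Sites under 10 %
occupancy are dropped from reports by default.  A binding-site mode
restricts the analysis to waters within 6 Å of a selection, evaluated per
frame.

## Recognition paths

Nodes: ligand polar atoms (individually), protein residues (side chains
collapsed — published path notations mix backbone adjacency and side-chain
contacts at residue level), water sites, metal ions.  Node ids omit the
chain (monomeric systems); `ASP1025`, `CU3047`, `SRO:N1`, `WS2`.  Edges:
hydrogen bonds (salt bridges folded in), covalent adjacency between
sequence-consecutive residues, metal coordination.  Every non-covalent edge
must reach an occupancy floor (default 50 %, the lowest O.F. published
tables still treat as stabilizing); this applies to coordination edges too,
so a contact grazed in a stray frame cannot wire a spurious shortcut.  A
detected contact between sequence-adjacent residues never replaces their
covalent edge.

The search is breadth-first minimal-hop to any target; among equal-hop
paths the maximal minimum-edge-occupancy wins, then the lexicographically
smallest node sequence — the literature asserts paths without defining a
search, and minimal hops with deterministic tie-breaks is the
least-assumptive formalization.  "No path" is a `None` result, distinct
from argument errors.  Path strings render hydrogen bonds as `…` and
covalent/coordination steps as `-`, except that steps through a water site
always render as `…`, matching how water-mediated routes are written in
the field.

## Trajectory metrics

RMSD is computed per frame against a reference frame after alignment (no
re-fitting inside the metric).  RMSF per residue is
`sqrt(mean_f |r - <r>|²)` per atom, averaged over the residue's selected
atoms.  The snapshot report maps requested times to the nearest frame (ties
to the earlier frame) and prints the tracked distance at each snapshot plus
the whole-trajectory O.F.; snapshot cells equal direct distance measurement
bit for bit.

## Synthetic generator

`make_scaffold` realizes a roster of residue-like groups from coarse
templates: geometry is plausible, not chemically exact — these are test
scaffolds whose point is *known* truth, not force-field realism.  Pair
constraints pin exact atom–atom distances; a triad constraint embeds three
pairwise distances exactly (triangle construction), which is how the
acidic-triad template geometry (6.08/4.05/7.11 Å) is built and verified.

`simulate_trajectory` adds, per frame: per-residue Gaussian noise (default
σ = 0.05 Å for the rigid scaffold; per-residue overrides for planted
mobility); Bernoulli-toggled interactions whose partner atom is placed at
the on-distance (0.5 Å inside the detection cutoff) or off-distance
(0.5 Å outside) along a fixed direction, so detector truth is unambiguous;
Bernoulli-occupied water sites with jitter radius 0.4 Å (< half the link
cutoff, so a site never splits) and water residue ids rotating every 10
frames among 4 identities; finally a random global rigid motion (rotation
≤ 15°, translation ≤ 3 Å per axis) so that skipping superposition visibly
destroys site clustering — the packaged negative control measures exactly
this inflation.

The packaged benchmark plants three amine-proximal sites at occupancies
{1.0, 0.85, 0.5} with centroid separations ≥ 4.5 Å, a bridging site on the
Glu1032–Cu axis, and the two recognition routes (direct through the
Cys–His copper pair; water-bridged through Met–Glu).  The three groups
coordinated to the hub copper are laid out 120° apart so no pair of them
falls inside the hydrogen-bond cutoff by construction.  Because residue
orientations are still random, each candidate scaffold is verified on a
noiseless frame — the detectors must recover exactly the planted topology —
and re-drawn deterministically from the seed otherwise; an unrealizable
request raises a placement error rather than returning ambiguous truth.

What passing these benchmarks shows: the pipeline recovers planted site
counts, occupancies (binomial-limited: SE ≈ 1.1 % at 1000 frames for
p = 0.85), per-residue mobility (√3·σ at large frame counts) and path
topology, deterministically.  What it does not show: behaviour on real
force-field water dynamics (correlated motions, partial occupancies off
lattice, protein conformational change), crowded solvation shells where
sites approach the link cutoff, or hydrogen-position-dependent criteria —
all outside the generator's model.

## Numerical and determinism notes

All randomness flows from one recorded integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical ensembles
and byte-identical CSV payloads.  Every output file embeds the config hash
(SHA-256 of the canonical config JSON, truncated).  Problem sizes used by
the shipped checks — 1000 frames for occupancy recovery, 500 for RMSF,
300 for the negative control, 200 random models / 100 random graphs for
oracle agreement — were chosen so binomial and fitting errors sit well
inside the asserted tolerances.

Known limitations: no explicit-hydrogen criteria, no energy scoring, no
density-grid water placement, no mmCIF writing, binary trajectory formats
(DCD/XTC) not included; residue nodes assume a monomeric chain id scheme.
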