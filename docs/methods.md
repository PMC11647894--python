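# Methods

## Scope and model

`cellenergy` analyzes the nonbonded energetics of finite cellulose
nanocrystals.  It does **not** minimize structures and carries no bonded
force-field terms (bonds, angles, dihedrals): it evaluates Coulomb and
12-6 Lennard-Jones pair sums on structures that are either ingested from
PDB files (e.g. externally energy-minimized crystals) or generated from
packaged idealized templates.  Consequently the package can reproduce any
quantity that is a pure nonbonded pair sum — pairwise bond energies, group
interaction energies, interchain decompositions, bulk-energy slopes of a
given structure series — but "total intrachain" or "overall" crystal
energies that include bonded terms are out of scope by design.

Electrostatics uses the GLYCAM convention `E = (18.2223 q_i)(18.2223 q_j)/r`
(kcal/mol, charges in e, r in Å) with vacuum permittivity, no cutoff and no
periodic images.  This is deliberate: the crystals are finite, every
interior glucose unit is exactly neutral, and terminal units are
neutralized (below), so all unit–unit interactions are multipole-like and
absolutely convergent; a cutoff or Ewald treatment would only distort the
finite-size extrapolation.  The Lennard-Jones term uses
`R_min = (R_i + R_j)/2` with per-atom radii `R_i` (twice the AMBER `R*`)
and the geometric-mean well depth; its minimum is exactly −ε at R_min,
which the tests assert.

## Force-field tables and variants

The packaged table `data/glycam06_cellulose.params` carries the GLYCAM06
cellulose partial charges and Lennard-Jones parameters per atom *name*
(externally sourced parameter data).  Only the non-neutral atoms carry
charge; all aliphatic hydrogens are zero, so a central glucose unit sums to
exactly 0 e.  The four near-neutral charge groups used in hydrogen-bond
scoring are C2-O2-H (+0.029 e), C3-O3-H (+0.007 e), C6-O6-H (+0.018 e) and
the five-atom ring group {O4, C1, O5, C5, C4} (−0.054 e).

The `GLYCAM06_OSMOr14_TIP5P` variant multiplies Lennard-Jones well depths
by 0.94.  Which types are exempt from that rescaling is not enumerated in
the literature description ("most ε parameters"); the default applies it to
*all* carbohydrate atom types with an empty, configurable exempt list.
Charges and radii never differ between variants, so every electrostatic
result is variant-independent.

Hydroxyl hydrogens have ε = 0 (GLYCAM convention); their radius column is a
nominal placeholder that cannot enter any energy because the geometric-mean
well depth vanishes.

**Terminal units.**  Chain termini carry an extra hydroxyl (O1–H at the
reducing end, O4–H at the non-reducing end) whose atoms are not part of the
neutral central-unit charge set; the packaged table assigns them O4-like
and hydroxyl-H-like charges, leaving each terminal unit with a small net
charge.  `neutralize_termini` removes this excess by spreading it equally
over all hydrogen atoms of the terminal unit — mimicking the neutralization
that surrounding solvent would provide — and is idempotent (residual excess
below 1e-12 e is left untouched).  Interior units are never modified.

## Crystal templates (synthetic)

The packaged unit-cell templates use the published fiber-diffraction
lattice constants of cellulose Iβ (a = 7.784 Å, b = 8.201 Å, c = 10.38 Å,
γ = 96.5°) and cellulose II (a = 8.10 Å, b = 9.03 Å, c = 10.31 Å,
γ = 117.1°), with the chain axis along c.  The *atomic* coordinates are
synthetic: an idealized chair-ring glucose geometry, optimized under
restraints (ideal bond lengths/angles, 2₁ screw closure of the glycosidic
linkage, clash avoidance) rather than the experimental coordinates, which
are not redistributed here.  Chain setting angles and the center-chain
axial offset were chosen once to maximize interchain contact distances on
the lattice; cellulose II center chains are antiparallel, Iβ chains all
parallel, and origin/center chains alternate exactly as on the real
lattices.

These templates give structurally correct topology (chain counts,
parities, directions, habit, hydrogen-bearing hydroxyls) and sensible but
*unminimized* packing.  Absolute interchain energies of built crystals are
therefore not comparable to energies of minimized structures — a few
contacts sit on the repulsive Lennard-Jones wall — and no test or
acceptance quantity depends on template coordinates.  Quantitative
energetics in the tests always comes from fixtures placed at prescribed
geometry or from ingested structures.

Crystal habit: chains occupy the `n_chains` lattice sites (corner "origin"
and face-center "center" positions) closest to the lattice anchor,
deterministically ordered; an explicit rows×cols block can be requested
instead.  Central-chain selection picks the `n` chains nearest the lateral
centroid (ties broken by chain id), a reasoned stand-in for the visually
outlined central-chain sets of published figures.

PDB I/O goes through gemmi with standard columns (3-decimal coordinates,
so round-trips preserve coordinates to 1e-3 Å and energies to roughly
0.01 kcal/mol on hydrogen-bond scales).  Chain ids use the 62-character
alphanumeric alphabet; beyond 62 chains a two-character id is stored in the
segment-id columns (73–76) and transparently restored on read.

## Energy decomposition

The per-chain interchain energy is ½ Σ (atoms of the chain × atoms of all
*other* chains of the whole crystal — not only the selected subset).
Intrachain nonbonded sums exclude covalent 1-2 and 1-3 pairs and include
1-4 and beyond at full strength (GLYCAM applies no 1-4 scaling); the
exclusion set is derived from the glucose bond topology including the
glycosidic link.  Decomposition totals are validated against an
independent O(N²) plain-Python unique-pair oracle on toy crystals.

Reported totals aggregate per-chain values as the mean by default (the
energy of a typical selected chain) or the sum; the choice is recorded in
the result object.

## Bulk-energy extraction

Per-chain energies are linear in the degree of polymerization dp to high
accuracy; `fit_bulk_energy` performs *unweighted* ordinary least squares of
per-chain energy vs dp.  The slope is the bulk energy per glucose unit, the
intercept the chain-end term, and the slope standard error comes from the
standard OLS formula (undefined and flagged NaN for two-point fits).
Replica sets are summarized by mean and standard error of the mean
(sample standard deviation / √n).  Monte-Carlo tests (1000 seeded noisy
series, σ = 0.2 kcal/mol) confirm unbiased slope recovery; on exactly
linear data the generating slope is recovered to 1e-10 relative.

## Hydrogen bonds

Detection: donors are the hydroxyl oxygens O2/O3/O6 with their hydrogen
present; acceptors are O2/O3/O5/O6 of any *other* glucose unit (the
nearest real hydrogen bonds span adjacent units, so same-unit contacts are
excluded).  A bond is kept when d(H···O) ≤ 3.0 Å and the O–H···O angle
(measured at H) is ≥ 115°.  These defaults are configurable and echoed in
every report; they are wide enough to admit the weak branch bond of
cellulose Iβ (d_HO near 3 Å, angle near 120°) while excluding ordinary
nonbonded contacts.  One donor H may match several acceptors; each match
is a separate record (branched bonds), and loosening the criterion can
only add records (a tested invariant).

Scoring modes (`OH_O`, `COH_O`, `COH_COX`) are full group–group pair sums
with no exclusions across groups; the vdW component uses the same group
pairs as the electrostatic one.  Mode nesting is exact by additivity:
`COH_COX` = `COH_O` + (donor triple × remaining acceptor-group atoms).

Per-glucose aggregation attributes each bond to its donor unit, sums per
chain parity (origin/center), divides by the number of distinct donor
units of that parity (or an explicit per-parity unit count), and averages
the two parities.  The hydrogen-bond share of the interchain
electrostatics is reported as an integer percentage of the bulk
electrostatic interchain energy per glucose unit.

## Synthetic fixtures

The three printed geometry numbers (d_HO, d_OO, angle) of a hydrogen bond
fully determine the O–H···O triangle — including the implied O–H bond
length — but leave the donor carbon position underdetermined by one cone
angle (C–O–H, default 109.5°) and one dihedral about the O–H axis (default
180°, anti to the acceptor, in plane).  `make_hbond_fixture` exposes both;
the tests show that for every published bond geometry a chemically
plausible placement reproduces the published donor-group energy within its
printed spread, and that a *fixed* placement cannot (the weak branch bonds
need an out-of-plane carbon).  Out-of-plane freedom of the hydrogen itself
is fixed to zero, since the printed numbers cannot constrain it.

`make_group_pair_fixture` embeds two atom groups so as to realize a full
cross-distance matrix (deterministic seeded least squares, residual below
1e-6 Å required); it is the bridge from published pairwise energies to 3D
fixtures, since distances follow from pair energies by inverting the
Coulomb formula.

Toy crystals are square lattices of straight chains with a configurable
per-residue atom motif (default: a neutral two-atom dipole with
Lennard-Jones parameters) and ship with a brute-force energy ledger from
an independent O(N²) loop.  They emulate the size scaling and
decomposition bookkeeping of real crystals but none of their chemistry; a
passing toy-crystal test validates the pair-sum machinery, not the force
field or geometry.

## Problem sizes and determinism

The test-suite and the acceptance script run on deliberately small
problems: toy crystals of ≤ a few hundred atoms, built crystals of 6–8
chains and dp ≤ 5, two-body systems, and 1000-seed Monte-Carlo fits —
every check completes in seconds.  The pipeline defaults mirror the
reference study conditions (52 chains; dp 6, 8, 10, 12; 30 central chains)
and take a few minutes at full size.  All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); identical
configuration and seeds give byte-identical JSON reports.

## Known limitations

- No minimization and no bonded terms: absolute energies of the packaged
  idealized crystals are dominated by unrelaxed contacts; the package's
  quantitative claims concern pair sums at given geometry and the fitting/
  aggregation machinery.
- The ε-rescaling exempt list and the exact published hydrogen-bond
  criterion thresholds are not enumerated in the literature; both are
  explicit, configurable parameters here.
- Chain-parity classification of ingested structures is geometric
  (direction sign, axial stagger clustering) and labels structures it
  cannot cluster cleanly as `unclassified` rather than guessing; the
  origin/center naming of a recovered family is conventional (family of
  the first chain = origin).
- Hydrogen positions are taken as given; there is no hydrogen placement or
  optimization.
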