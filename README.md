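# cellenergy

Energy decomposition and hydrogen-bond scoring for cellulose Iβ and
cellulose II nanocrystals.

Natural cellulose crystallizes as cellulose Iβ, with all chains parallel,
yet the recrystallized polymorph cellulose II — with antiparallel neighbor
chains — is the thermodynamically favored form.  Understanding why requires
separating the interchain energetics of the two crystals into electrostatic
and van der Waals contributions and asking how much of the electrostatics
the hydrogen bonds actually carry.  `cellenergy` provides the analysis
toolchain for that question: it builds or ingests nanocrystal structures,
decomposes their nonbonded energies chain by chain, extrapolates bulk
energies per glucose unit from finite-size series, and scores hydrogen
bonds with a group-based multipole description.  It is aimed at
computational carbohydrate scientists who have (or want to generate)
crystal structures and need reproducible per-glucose energetics.

## Model

All energies are pairwise nonbonded terms with GLYCAM-style parameters.
For atoms *i*, *j* with partial charges *qᵢ*, *qⱼ* (units of *e*) at
distance *r* (Å):

- **Electrostatics** — bare Coulomb, `E = Q_i Q_j / r` with
  `Q = 18.2223 q`, in kcal/mol; no cutoff, no periodic images, relative
  permittivity 1.  Glucose units are neutral, so unit–unit electrostatics
  is short-ranged (multipole-like) even though atom–atom terms are not.
- **van der Waals** — 12-6 Lennard-Jones,
  `E = ε[(R_min/r)¹² − 2(R_min/r)⁶]`, with `R_min = (Rᵢ + Rⱼ)/2` and
  `ε = √(εᵢ εⱼ)`.  Two parameter variants are shipped: `GLYCAM06` and
  `GLYCAM06_OSMOr14_TIP5P`, in which the well depths are rescaled by 0.94
  (a recalibration to osmotic pressures of carbohydrate solutions).
- **Interchain energy of a chain** — half the pairwise sum between the
  chain's atoms and all atoms of every other chain (the ½ compensates
  pair double-counting when averaging over chains).  **Intrachain**
  nonbonded sums exclude covalent 1-2/1-3 pairs.
- **Bulk energy per glucose unit** — the slope of per-chain energy versus
  chain length (degree of polymerization), fitted by ordinary least
  squares over crystals of increasing chain length; the intercept absorbs
  chain-end effects.
- **Hydrogen bonds** — detected by a distance/angle criterion
  (default d(H···O) ≤ 3.0 Å, O–H···O angle ≥ 115°) and scored three ways:
  donor OH vs acceptor O (`OH_O`, the naive dipole picture), donor C–O–H
  vs acceptor O (`COH_O`), and donor C–O–H vs the acceptor's near-neutral
  group (`COH_COX`: the acceptor's own C–O–H, or {O4, C1, O5, C5, C4} for
  the ring oxygen O5).  The last mode treats the bond as an interaction of
  two near-neutral multipoles, in the spirit of the classical CO/NH
  dipole treatment of protein backbone hydrogen bonds.

## Worked example

Score the strong interchain hydrogen bond of cellulose Iβ (O6–H donating
to O3) at its average geometry, using a synthetic fixture placed exactly at
that geometry:

```python
import cellenergy as ce
from cellenergy.synthdata import make_hbond_fixture

pc = make_hbond_fixture("O6", "O3", d_HO=1.77, d_OO=2.72, angle=162.0)
hb = ce.detect_hbonds(pc)[0]
for mode in ("OH_O", "COH_O", "COH_COX"):
    e = ce.hbond_energy(pc, hb, mode)
    print(f"{mode:8s} electrostatic = {e.electrostatic:7.1f} kcal/mol")
```

prints

```
OH_O     electrostatic =     3.2 kcal/mol
COH_O    electrostatic =   -14.9 kcal/mol
COH_COX  electrostatic =    -7.6 kcal/mol
```

The naive two-atom picture (`OH_O`) is *repulsive* (+3.2): the O–O
repulsion of the heavily charged oxygens beats the H···O attraction.
Including the donor carbon (`COH_O`) gives a strong attraction, −14.9
kcal/mol, but that exceeds the entire interchain electrostatic energy per
glucose unit and so overestimates the bond.  The full group–group multipole
energy (`COH_COX`), −7.6 kcal/mol here, is the physically consistent
hydrogen-bond strength: summed over the interchain bonds it accounts for
roughly 70% (Iβ) and 75% (II) of the bulk interchain electrostatics.

A full pipeline run — build both polymorphs over several chain lengths,
fit bulk energies, tabulate hydrogen bonds — is one command:

```sh
cellenergy report --out-dir report        # JSON + markdown reports
cellenergy build --form Ibeta --chains 52 --dp 6 --out crystal.pdb
cellenergy hbonds --pdb crystal.pdb --out hbonds.csv
```

Idealized crystals come from packaged synthetic unit-cell templates
(experimental lattice constants, idealized atom geometry); absolute
energies of such unminimized structures are not comparable to
minimized-structure results — see `docs/methods.md`.

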