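"""Nonbonded force-field parameters for cellulose crystals.

The package scores crystal energetics with GLYCAM-style nonbonded terms:
per-atom partial charges (elementary charge units) for the Coulomb sum and
per-atom Lennard-Jones radii/well depths combined by the arithmetic/geometric
rules.  Two force-field variants are supported: plain ``GLYCAM06`` and the
osmotic-pressure recalibrated ``GLYCAM06_OSMOr14_TIP5P`` variant, in which
the Lennard-Jones well depths are rescaled by 0.94.

A central glucose unit is electrically neutral; chain-terminal units carry a
small excess charge from their extra hydroxyl atoms, which
:func:`neutralize_termini` removes by spreading the excess over the terminal
residue's hydrogens (mimicking the neutralization a surrounding solvent would
provide in a vacuum electrostatics calculation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AtomTypeParams",
    "ForceFieldVariant",
    "ChargeGroup",
    "GLYCAM06",
    "GLYCAM06_OSMO",
    "CHARGE_GROUPS",
    "load_forcefield",
    "assign_parameters",
    "neutralize_termini",
    "normalize_atom_name",
    "ParameterizedCrystal",
    "GLUCOSE_BONDS",
]

#: default epsilon rescaling of the osmotic-pressure recalibrated variant
OSMO_EPSILON_SCALE = 0.94


@dataclass(frozen=True)
class AtomTypeParams:
    """Nonbonded parameters of one named cellulose atom.

    ``vdw_radius`` is the per-atom R_i entering the arithmetic combination
    rule R_min = (R_i + R_j)/2 of the 12-6 potential (twice the AMBER R*).
    """

    atom_name: str
    partial_charge: float  # e
    vdw_radius: float  # Angstrom
    epsilon: float  # kcal/mol

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")
        if self.vdw_radius <= 0:
            raise ValueError(
                f"non-positive vdW radius for atom {self.atom_name!r}: "
                f"{self.vdw_radius}"
            )
        if self.epsilon < 0:
            raise ValueError(
                f"negative epsilon for atom {self.atom_name!r}: {self.epsilon}"
            )


@dataclass(frozen=True)
class ForceFieldVariant:
    """A named variant of the nonbonded parameter set.

    ``epsilon_scale`` multiplies the Lennard-Jones well depth of every atom
    type whose name is not in ``exempt_types``; partial charges are never
    touched by a variant switch.
    """

    name: str
    epsilon_scale: float = 1.0
    exempt_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.epsilon_scale <= 0:
            raise ValueError("epsilon_scale must be positive")


GLYCAM06 = ForceFieldVariant("GLYCAM06", 1.0)
#: well depths rescaled by 0.94 (fit to osmotic pressures of carbohydrate
#: solutions); no atom type is exempted by default because the recalibration
#: is described as applying to essentially all carbohydrate types.
GLYCAM06_OSMO = ForceFieldVariant("GLYCAM06_OSMOr14_TIP5P", OSMO_EPSILON_SCALE)

_VARIANTS = {v.name: v for v in (GLYCAM06, GLYCAM06_OSMO)}


def variant_by_name(name: str) -> ForceFieldVariant:
    try:
        return _VARIANTS[name]
    except KeyError:
        raise ValueError(
            f"unknown force-field variant {name!r}; "
            f"known: {sorted(_VARIANTS)}"
        ) from None


@dataclass(frozen=True)
class ChargeGroup:
    """A near-neutral group of cellulose atoms used in hydrogen-bond scoring.

    The three hydroxyl groups are C-O-H triples; the ring-oxygen acceptor O5
    is represented by the five remaining charged atoms {O4, C1, O5, C5, C4}.
    """

    label: str
    member_atom_names: tuple[str, ...]
    net_charge: float  # e


CHARGE_GROUPS: dict[str, ChargeGroup] = {
    "C2O2H": ChargeGroup("C2O2H", ("C2", "O2", "HO2"), 0.029),
    "C3O3H": ChargeGroup("C3O3H", ("C3", "O3", "HO3"), 0.007),
    "C6O6H": ChargeGroup("C6O6H", ("C6", "O6", "HO6"), 0.018),
    "O5-group": ChargeGroup("O5-group", ("O4", "C1", "O5", "C5", "C4"), -0.054),
}

#: hydroxyl oxygen -> (bound carbon, hydroxyl hydrogen)
HYDROXYL_TRIPLES = {"O2": ("C2", "HO2"), "O3": ("C3", "HO3"), "O6": ("C6", "HO6")}

#: acceptor oxygen -> charge-group label used in COH-COX scoring
ACCEPTOR_GROUP_OF = {"O2": "C2O2H", "O3": "C3O3H", "O6": "C6O6H", "O5": "O5-group"}

# covalent topology of one glucose unit (interior atoms); used for the
# intrachain 1-2/1-3 exclusions and for hydrogen-bond donor lookup
GLUCOSE_BONDS: tuple[tuple[str, str], ...] = (
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"),
    ("C5", "O5"), ("O5", "C1"),
    ("C2", "O2"), ("O2", "HO2"),
    ("C3", "O3"), ("O3", "HO3"),
    ("C4", "O4"),
    ("C5", "C6"), ("C6", "O6"), ("O6", "HO6"),
    ("C1", "H1"), ("C2", "H2"), ("C3", "H3"), ("C4", "H4"), ("C5", "H5"),
    ("C6", "H61"), ("C6", "H62"),
    # terminal decorations (present only on end residues)
    ("C1", "O1"), ("O1", "HO1"), ("O4", "HO4"),
)

#: bond linking consecutive glucose units i -> i+1 along a chain
GLYCOSIDIC_BOND = ("C1", "O4")


def normalize_atom_name(name: str) -> str:
    """Map PDB-style spellings (``H_O2``, ``HO2``, `` O3 ``) to table names."""
    return name.strip().replace("_", "").upper()


def _packaged_table_path() -> Path:
    return Path(resources.files("cellenergy").joinpath("data/glycam06_cellulose.params"))


def load_forcefield(
    variant: ForceFieldVariant | str = GLYCAM06,
    table_source: str | Path | None = None,
) -> dict[str, AtomTypeParams]:
    """Read a parameter table and apply the variant's epsilon rescaling.

    Parameters
    ----------
    variant
        Force-field variant (or its name).  The Lennard-Jones well depth of
        every non-exempt atom type is multiplied by ``variant.epsilon_scale``;
        charges and radii are identical between variants.
    table_source
        Plain-text table with one row per atom name
        (``name charge radius epsilon``).  Defaults to the packaged
        GLYCAM06-style cellulose table.
    """
    if isinstance(variant, str):
        variant = variant_by_name(variant)
    path = Path(table_source) if table_source is not None else _packaged_table_path()
    params: dict[str, AtomTypeParams] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        name = normalize_atom_name(parts[0])
        charge, radius, eps = map(float, parts[1:])
        if radius <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive radius for {name!r}")
        if name not in variant.exempt_types:
            eps *= variant.epsilon_scale
        params[name] = AtomTypeParams(name, charge, radius, eps)
    if not params:
        raise ValueError(f"no parameters found in {path}")
    return params


class ParameterizedCrystal:
    """A crystal with per-atom nonbonded parameters in flat numpy arrays.

    The flat atom order follows the crystal traversal order
    (chain -> glucose unit -> atom).  ``bonds`` holds covalent bonds as pairs
    of flat indices; the 1-2 and 1-3 exclusion set for intrachain sums is
    derived from it lazily.
    """

    def __init__(
        self,
        crystal,
        names: list[str],
        coords: np.ndarray,
        charges: np.ndarray,
        radii: np.ndarray,
        epsilons: np.ndarray,
        chain_index: np.ndarray,
        residue_index: np.ndarray,
        bonds: list[tuple[int, int]],
    ) -> None:
        n = len(names)
        coords = np.asarray(coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.crystal = crystal
        self.names = names
        self.coords = coords
        self.charges = np.asarray(charges, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.epsilons = np.asarray(epsilons, dtype=float)
        self.chain_index = np.asarray(chain_index, dtype=int)
        self.residue_index = np.asarray(residue_index, dtype=int)
        self.bonds = list(bonds)
        self._excluded: set[tuple[int, int]] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.crystal.chains]

    def atoms_of_chain(self, ci: int) -> np.ndarray:
        return np.nonzero(self.chain_index == ci)[0]

    def atoms_of_residue(self, ri: int) -> np.ndarray:
        return np.nonzero(self.residue_index == ri)[0]

    def excluded_pairs(self) -> set[tuple[int, int]]:
        """Atom pairs at covalent graph distance 1 or 2 (1-2 and 1-3)."""
        if self._excluded is None:
            adj: dict[int, set[int]] = {}
            for i, j in self.bonds:
                adj.setdefault(i, set()).add(j)
                adj.setdefault(j, set()).add(i)
            excl: set[tuple[int, int]] = set()
            for i, nbrs in adj.items():
                for j in nbrs:
                    excl.add((min(i, j), max(i, j)))
                    for k in adj.get(j, ()):
                        if k != i:
                            excl.add((min(i, k), max(i, k)))
            self._excluded = excl
        return self._excluded

    def copy(self) -> "ParameterizedCrystal":
        new = copy.copy(self)
        new.charges = self.charges.copy()
        new._excluded = self._excluded
        return new

    def residue_net_charge(self, ri: int) -> float:
        return float(self.charges[self.atoms_of_residue(ri)].sum())


def assign_parameters(crystal, ff: Mapping[str, AtomTypeParams]) -> ParameterizedCrystal:
    """Attach charges and Lennard-Jones parameters to every atom of a crystal.

    Raises a :class:`ValueError` naming the residue and atom if any atom name
    cannot be resolved in the parameter mapping.
    """
    names: list[str] = []
    coords: list[np.ndarray] = []
    charges: list[float] = []
    radii: list[float] = []
    epsilons: list[float] = []
    chain_index: list[int] = []
    residue_index: list[int] = []
    bonds: list[tuple[int, int]] = []

    ri = -1
    for ci, chain in enumerate(crystal.chains):
        prev_local: dict[str, int] | None = None
        for unit in chain.units:
            ri += 1
            local: dict[str, int] = {}
            for atom in unit.atoms:
                nm = normalize_atom_name(atom.name)
                if nm not in ff:
                    raise ValueError(
                        f"no force-field parameters for atom {atom.name!r} in "
                        f"chain {chain.chain_id!r} residue {unit.index_in_chain}"
                    )
                p = ff[nm]
                local[nm] = len(names)
                names.append(nm)
                coords.append(np.asarray(atom.xyz, dtype=float))
                charges.append(p.partial_charge)
                radii.append(p.vdw_radius)
                epsilons.append(p.epsilon)
                chain_index.append(ci)
                residue_index.append(ri)
            for a, b in GLUCOSE_BONDS:
                if a in local and b in local:
                    bonds.append((local[a], local[b]))
            if prev_local is not None:
                a, b = GLYCOSIDIC_BOND
                if a in prev_local and b in local:
                    bonds.append((prev_local[a], local[b]))
            prev_local = local

    pc = ParameterizedCrystal(
        crystal,
        names,
        np.array(coords).reshape(len(names), 3) if names else np.zeros((0, 3)),
        np.array(charges),
        np.array(radii),
        np.array(epsilons),
        np.array(chain_index, dtype=int),
        np.array(residue_index, dtype=int),
        bonds,
    )
    return pc


def _terminal_residue_ids(pc: ParameterizedCrystal) -> list[int]:
    out = []
    ri = -1
    for chain in pc.crystal.chains:
        first = ri + 1
        ri += len(chain.units)
        if len(chain.units) == 1:
            out.append(first)
        else:
            out.extend([first, ri])
    return out


def neutralize_termini(pc: ParameterizedCrystal) -> ParameterizedCrystal:
    """Return a copy in which every terminal glucose unit is neutral.

    The excess charge of each chain-terminal residue is spread equally over
    the hydrogen atoms of that residue; interior residues are untouched.
    Idempotent: applying it twice changes nothing.
    """
    new = pc.copy()
    for ri in _terminal_residue_ids(pc):
        idx = pc.atoms_of_residue(ri)
        excess = float(new.charges[idx].sum())
        h_idx = [i for i in idx if new.names[i].startswith("H")]
        if not h_idx:
            raise ValueError(
                f"terminal residue {ri} has no hydrogen atoms to adjust"
            )
        if abs(excess) > 1e-12:  # fixed point: already-neutral termini untouched
            new.charges[h_idx] -= excess / len(h_idx)
    return new


def central_unit_names() -> tuple[str, ...]:
    """Atom names of an interior (central) glucose unit."""
    return (
        "C1", "C2", "C3", "C4", "C5", "C6",
        "O2", "O3", "O4", "O5", "O6",
        "H1", "H2", "H3", "H4", "H5", "H61", "H62",
        "HO2", "HO3", "HO6",
    )
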