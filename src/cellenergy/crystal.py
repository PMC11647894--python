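"""Cellulose nanocrystal structures: build, read, write, select.

A :class:`Crystal` is a hierarchy of chains -> glucose units -> atoms.
Idealized nanocrystals of the two polymorphs are generated from packaged
unit-cell templates: cellulose Ibeta (all chains parallel, origin and center
chains staggered along the chain axis) and cellulose II (center chains
antiparallel to origin chains).  The templates carry experimentally
determined lattice constants but synthetic idealized atomic geometry; they
are meant for method development and testing, not as substitutes for
energy-minimized structures, which can be ingested from PDB files instead.

Chain ids use the 62-character alphanumeric alphabet; crystals with more
than 62 chains fall back to a two-character id scheme stored in the PDB
segment-id columns (73-76), which :func:`read_pdb` transparently undoes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "GlucoseUnit",
    "Chain",
    "Crystal",
    "UnitCellTemplate",
    "load_template",
    "build_crystal",
    "read_pdb",
    "write_pdb",
    "select_central_chains",
    "classify_chain_parity",
]

_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

_TEMPLATE_FILES = {
    "Ibeta": "template_ibeta_synthetic.yaml",
    "II": "template_cellulose_ii_synthetic.yaml",
}

_OH, _CO = 0.96, 1.43
_COH_ANGLE = 108.5  # deg


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass
class GlucoseUnit:
    index_in_chain: int  # 1-based
    chain_id: str
    atoms: list[Atom]
    is_terminal: bool = False
    is_reducing_end: bool = False

    def centroid(self) -> np.ndarray:
        return np.mean([a.xyz for a in self.atoms], axis=0)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass
class Chain:
    chain_id: str
    units: list[GlucoseUnit]
    parity: str | None = None  # "origin" | "center" | None
    direction: np.ndarray | None = None  # unit vector along the chain axis

    @property
    def dp(self) -> int:
        return len(self.units)

    def axis_direction(self) -> np.ndarray:
        """Unit vector from the first toward the last glucose unit."""
        if self.direction is not None:
            return self.direction
        if self.dp < 2:
            return np.array([0.0, 0.0, 1.0])
        v = self.units[-1].centroid() - self.units[0].centroid()
        return v / np.linalg.norm(v)


@dataclass
class Crystal:
    form: str | None
    chains: list[Chain]
    cell_template: "UnitCellTemplate | None" = None

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(u.atoms) for c in self.chains for u in c.units)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


@dataclass
class UnitCellTemplate:
    """Packaged unit-cell description of one cellulose polymorph.

    ``residue_local`` holds the synthetic idealized coordinates of one
    glucose unit in the chain-local frame (chain axis along z); chain sites
    place rotated/flipped copies of that residue on the lattice.
    """

    form: str
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    symmetry_ops: list[str]
    chain_sites: dict
    atom_names: list[str]
    atom_elements: list[str]
    residue_local: np.ndarray  # (n_atoms, 3) Cartesian, chain axis = z
    provenance: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("lattice constants must be positive")

    def cell_matrix(self) -> np.ndarray:
        """Columns are the a, b, c cell vectors (c is the chain axis, +z)."""
        g = np.radians(self.gamma)
        return np.array(
            [
                [self.a, self.b * np.cos(g), 0.0],
                [0.0, self.b * np.sin(g), 0.0],
                [0.0, 0.0, self.c],
            ]
        )

    def fractional_asymmetric_unit(self) -> np.ndarray:
        """Residue coordinates of the origin site in fractional units."""
        site = self.chain_sites["origin"]
        X = _place_site_residue(self.residue_local, site, 0.0)
        return np.linalg.solve(self.cell_matrix(), X.T).T

    def symmetry_closed(self) -> bool:
        """Check the op set is closed under composition modulo lattice."""
        ops = [gemmi.Op(s) for s in self.symmetry_ops]
        trips = {op.triplet() for op in ops}

        def canonical(op: gemmi.Op) -> str:
            w = [t % op.DEN for t in op.tran]
            res = gemmi.Op()
            res.rot = op.rot
            res.tran = w
            return res.triplet()

        for p in ops:
            for q in ops:
                if canonical(p * q) not in {canonical(o) for o in ops}:
                    return False
        return True


def _rotz(deg: float) -> np.ndarray:
    t = np.radians(deg)
    return np.array(
        [[np.cos(t), -np.sin(t), 0.0], [np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )


def _place_site_residue(X: np.ndarray, site: dict, z_extent_shift: float) -> np.ndarray:
    P = X @ _rotz(site["rotation_deg"]).T
    if site.get("flip"):
        P = P @ np.diag([1.0, -1.0, -1.0])
        P = P + np.array([0.0, 0.0, z_extent_shift])
    return P


def load_template(form: str) -> UnitCellTemplate:
    if form not in _TEMPLATE_FILES:
        raise ValueError(
            f"unknown crystal form {form!r}; known: {sorted(_TEMPLATE_FILES)}"
        )
    path = resources.files("cellenergy").joinpath("data", _TEMPLATE_FILES[form])
    doc = yaml.safe_load(path.read_text())
    cell = doc["cell"]
    return UnitCellTemplate(
        form=doc["form"],
        a=cell["a"], b=cell["b"], c=cell["c"],
        alpha=cell["alpha"], beta=cell["beta"], gamma=cell["gamma"],
        symmetry_ops=list(doc["symmetry_ops"]),
        chain_sites=doc["chain_sites"],
        atom_names=[r["name"] for r in doc["residue_atoms"]],
        atom_elements=[r["element"] for r in doc["residue_atoms"]],
        residue_local=np.array([r["xyz"] for r in doc["residue_atoms"]], dtype=float),
        provenance=doc.get("provenance", ""),
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _hydroxyl_h(o: np.ndarray, bonded: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Place a hydroxyl hydrogen on oxygen ``o`` bonded to atom ``bonded``."""
    u = _unit(bonded - o)
    r = ref - o
    perp = r - np.dot(r, u) * u
    perp = _unit(perp) if np.linalg.norm(perp) > 1e-8 else _unit(np.cross(u, [1.0, 0, 0]))
    t = np.radians(_COH_ANGLE)
    return o + _OH * (np.cos(t) * u + np.sin(t) * perp)


def _build_chain_local(tpl: UnitCellTemplate, dp: int) -> list[dict[str, np.ndarray]]:
    """Raw screw-stacked residues (k = chemical index 0..dp-1) plus terminal
    decorations, in the unrotated chain-local frame."""
    X = tpl.residue_local
    names = tpl.atom_names
    idx = {n: i for i, n in enumerate(names)}
    chalf = tpl.c / 2.0

    def residue_raw(k: int) -> np.ndarray:
        Y = X.copy()
        if k % 2:
            Y[:, 0] *= -1
            Y[:, 1] *= -1
        Y[:, 2] += k * chalf
        return Y

    residues = []
    for k in range(dp):
        R = residue_raw(k)
        atoms = {n: R[idx[n]] for n in names}
        residues.append(atoms)
    # non-reducing end (k=0): O4 gains a hydroxyl hydrogen
    prev_c1 = residue_raw(-1)[idx["C1"]]
    o4 = residues[0]["O4"]
    residues[0]["HO4"] = _hydroxyl_h(o4, residues[0]["C4"], prev_c1)
    # reducing end (k=dp-1): C1 gains the anomeric hydroxyl O1-HO1
    nxt_o4 = residue_raw(dp)[idx["O4"]]
    c1 = residues[-1]["C1"]
    o1 = c1 + _CO * _unit(nxt_o4 - c1)
    residues[-1]["O1"] = o1
    residues[-1]["HO1"] = _hydroxyl_h(o1, c1, residues[-1]["O5"])
    return residues


def _candidate_sites(tpl: UnitCellTemplate, n_needed: int):
    """Lattice chain sites sorted deterministically by compactness."""
    M2 = tpl.cell_matrix()[:2, :2]
    m = 1
    while (2 * m + 1) ** 2 * 2 < 4 * n_needed:
        m += 1
    m += 1
    anchor = M2 @ np.array([0.25, 0.25])
    sites = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for stype, (du, dv) in (("origin", (0.0, 0.0)), ("center", (0.5, 0.5))):
                uv = np.array([i + du, j + dv])
                pos = M2 @ uv
                d = np.linalg.norm(pos - anchor)
                sites.append((round(d, 6), i, j, stype, pos))
    sites.sort(key=lambda s: (s[0], s[1], s[2], s[3]))
    return sites[:n_needed]


def _chain_id(k: int) -> tuple[str, str]:
    """(pdb chain char, full id). Two-character ids beyond 62 chains."""
    if k < len(_CHAIN_ALPHABET):
        c = _CHAIN_ALPHABET[k]
        return c, c
    hi, lo = divmod(k - len(_CHAIN_ALPHABET), len(_CHAIN_ALPHABET))
    if hi >= len(_CHAIN_ALPHABET):
        raise ValueError("too many chains for the two-character id scheme")
    return _CHAIN_ALPHABET[hi], _CHAIN_ALPHABET[hi] + _CHAIN_ALPHABET[lo]


def build_crystal(
    form: str,
    n_chains: int,
    dp: int,
    rows: int | None = None,
    cols: int | None = None,
) -> Crystal:
    """Build an idealized nanocrystal of ``n_chains`` chains of ``dp`` units.

    By default the chain habit is the compact set of lattice sites closest to
    the lattice anchor (roughly rectangular cross-section); an explicit
    ``rows x cols`` block of unit cells may be requested instead, in which
    case ``n_chains`` must equal ``2 * rows * cols``.
    """
    tpl = load_template(form)
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if dp < 2:
        raise ValueError("dp must be >= 2 (no glucose chain otherwise)")

    if (rows is None) != (cols is None):
        raise ValueError("rows and cols must be given together")
    if rows is not None:
        if n_chains != 2 * rows * cols:
            raise ValueError("n_chains must equal 2*rows*cols")
        M2 = tpl.cell_matrix()[:2, :2]
        sites = []
        for i in range(cols):
            for j in range(rows):
                for stype, (du, dv) in (("origin", (0.0, 0.0)), ("center", (0.5, 0.5))):
                    uv = np.array([i + du, j + dv])
                    sites.append((0.0, i, j, stype, M2 @ uv))
    else:
        sites = _candidate_sites(tpl, n_chains)

    chalf = tpl.c / 2.0
    chains: list[Chain] = []
    serial = 0
    for k, (_, i, j, stype, lateral) in enumerate(sites):
        site = tpl.chain_sites[stype]
        residues = _build_chain_local(tpl, dp)
        R = _rotz(site["rotation_deg"])
        flip = bool(site.get("flip"))
        zshift = (dp - 1) * chalf if flip else 0.0
        zoff = site["z_offset_frac"] * tpl.c
        _, cid = _chain_id(k)
        units: list[GlucoseUnit] = []
        for ridx, atoms in enumerate(residues):
            alist: list[Atom] = []
            for name, p in atoms.items():
                q = R @ p
                if flip:
                    q = np.array([q[0], -q[1], -q[2] + zshift])
                q = q + np.array([lateral[0], lateral[1], zoff])
                serial += 1
                alist.append(Atom(serial, name, "H" if name.startswith("H") else name[0], q))
            units.append(
                GlucoseUnit(
                    index_in_chain=ridx + 1,
                    chain_id=cid,
                    atoms=alist,
                    is_terminal=(ridx == 0 or ridx == dp - 1),
                    is_reducing_end=(ridx == dp - 1),
                )
            )
        direction = np.array([0.0, 0.0, -1.0 if flip else 1.0])
        chains.append(Chain(cid, units, parity=stype, direction=direction))
    return Crystal(form=form, chains=chains, cell_template=tpl)


# ---------------------------------------------------------------- PDB I/O


def _validate_pdb_text(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
            raise ValueError(
                f"{path}:{lineno}: truncated {line[:6].strip()} record"
            )


def read_pdb(path: str | Path) -> Crystal:
    """Read a crystal from a PDB file (chains -> residues -> atoms).

    Chain identity is the segment id when present (two-character overflow
    scheme used by :func:`write_pdb`), else the chain id column.
    """
    path = Path(path)
    _validate_pdb_text(path)
    st = gemmi.read_structure(str(path))
    if not len(st) or not len(st[0]):
        raise ValueError(f"{path}: no atoms parsed from PDB file")
    model = st[0]
    chains: dict[str, list[GlucoseUnit]] = {}
    for ch in model:
        for res in ch:
            cid = res.segment if res.segment else ch.name
            atoms = [
                Atom(a.serial, a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in res
            ]
            chains.setdefault(cid, []).append(
                GlucoseUnit(res.seqid.num, cid, atoms)
            )
    out: list[Chain] = []
    for cid, units in chains.items():
        units.sort(key=lambda u: u.index_in_chain)
        for u in units:
            u.is_terminal = u is units[0] or u is units[-1]
        if units:
            units[-1].is_reducing_end = True
        out.append(Chain(cid, units))
    out.sort(key=lambda c: c.chain_id)
    return Crystal(form=None, chains=out)


def write_pdb(crystal: Crystal, path: str | Path) -> None:
    """Write a crystal to PDB (standard columns, 3-decimal coordinates)."""
    st = gemmi.Structure()
    st.name = crystal.form or "cellulose"
    tpl = crystal.cell_template
    if tpl is not None:
        st.cell = gemmi.UnitCell(tpl.a, tpl.b, tpl.c, tpl.alpha, tpl.beta, tpl.gamma)
    model = gemmi.Model("1")
    for k, chain in enumerate(crystal.chains):
        cchar, cid = _chain_id(k)
        g = gemmi.Chain(cchar)
        for unit in chain.units:
            res = gemmi.Residue()
            res.name = "BGC"
            res.seqid = gemmi.SeqId(unit.index_in_chain, " ")
            if cid != cchar or len(chain.chain_id) > 1:
                res.segment = chain.chain_id if len(chain.chain_id) <= 4 else cid
            for a in unit.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = 1.0
                res.add_atom(ga)
            g.add_residue(res)
        model.add_chain(g)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ------------------------------------------------- selection and parity


def _lateral_positions(crystal: Crystal) -> tuple[np.ndarray, np.ndarray]:
    dirs = np.array([c.axis_direction() for c in crystal.chains])
    ref = dirs[0]
    mean_dir = _unit((dirs * np.sign(dirs @ ref)[:, None]).mean(axis=0))
    cents = np.array(
        [np.mean([u.centroid() for u in c.units], axis=0) for c in crystal.chains]
    )
    lateral = cents - np.outer(cents @ mean_dir, mean_dir)
    return lateral, mean_dir


def select_central_chains(crystal: Crystal, n_central: int) -> list[str]:
    """Ids of the ``n_central`` chains nearest the crystal's lateral centroid.

    Distances are measured in the plane perpendicular to the mean chain axis;
    ties are broken by chain id.  The result is independent of the order in
    which chains are stored.
    """
    if n_central > crystal.n_chains:
        raise ValueError(
            f"n_central={n_central} exceeds number of chains {crystal.n_chains}"
        )
    if n_central == 0:
        return []
    lateral, _ = _lateral_positions(crystal)
    center = lateral.mean(axis=0)
    d = np.linalg.norm(lateral - center, axis=1)
    order = sorted(
        range(crystal.n_chains), key=lambda i: (round(d[i], 6), crystal.chains[i].chain_id)
    )
    return sorted(crystal.chains[i].chain_id for i in order[:n_central])


def classify_chain_parity(crystal: Crystal) -> dict[str, str]:
    """Label every chain ``origin`` or ``center`` (or ``unclassified``).

    Built crystals carry template parities, which are returned directly.  For
    ingested structures the two chain families are recovered geometrically:
    antiparallel chain directions split the families directly (cellulose II
    packing); for all-parallel crystals the axial stagger of the chains
    relative to the screw repeat is clustered into two groups (cellulose
    Ibeta packing).  The family of the first chain (by storage order) is
    labelled ``origin``.  If the geometry supports no clean two-family
    clustering the chains are labelled ``unclassified`` rather than guessed.
    """
    if all(c.parity in ("origin", "center") for c in crystal.chains):
        return {c.chain_id: c.parity for c in crystal.chains}
    if crystal.n_chains == 1:
        return {crystal.chains[0].chain_id: "origin"}

    dirs = np.array([c.axis_direction() for c in crystal.chains])
    ref = dirs[0]
    dots = dirs @ ref
    if np.any(dots < -0.5):
        labels = {}
        for c, dt in zip(crystal.chains, dots):
            if abs(dt) < 0.5:
                labels[c.chain_id] = "unclassified"
            else:
                labels[c.chain_id] = "origin" if dt > 0 else "center"
        return labels

    # parallel family: cluster axial phase of the first glucose unit
    _, mean_dir = _lateral_positions(crystal)
    spacings = []
    for c in crystal.chains:
        cents = [u.centroid() @ mean_dir for u in c.units]
        if len(cents) > 1:
            spacings.extend(np.diff(sorted(cents)))
    if not spacings:
        return {c.chain_id: "unclassified" for c in crystal.chains}
    h = float(np.mean(spacings))  # screw repeat (c/2)
    t0 = min(u.centroid() @ mean_dir for u in crystal.chains[0].units)
    phases = np.array(
        [
            (min(u.centroid() @ mean_dir for u in c.units) - t0) % h
            for c in crystal.chains
        ]
    )

    def circ_dist(x, y):
        d = np.abs(x - y) % h
        return np.minimum(d, h - d)

    # two-means on the circle, seeded by chain 0 and its farthest chain
    c0 = phases[0]
    c1 = phases[np.argmax(circ_dist(phases, c0))]
    for _ in range(16):
        d0, d1 = circ_dist(phases, c0), circ_dist(phases, c1)
        lab = d0 <= d1
        if lab.all() or (~lab).all():
            break
        c0 = _circular_mean(phases[lab], h)
        c1 = _circular_mean(phases[~lab], h)
    sep = circ_dist(np.array([c0]), np.array([c1]))[0]
    if sep < h / 6:  # single family
        return {c.chain_id: "origin" for c in crystal.chains}
    spread0 = circ_dist(phases[lab], c0).max(initial=0.0)
    spread1 = circ_dist(phases[~lab], c1).max(initial=0.0)
    if max(spread0, spread1) > sep / 3:
        return {c.chain_id: "unclassified" for c in crystal.chains}
    return {
        c.chain_id: ("origin" if is0 else "center")
        for c, is0 in zip(crystal.chains, lab)
    }


def _circular_mean(x: np.ndarray, period: float) -> float:
    ang = 2 * np.pi * x / period
    return float(
        (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) % (2 * np.pi))
        * period
        / (2 * np.pi)
    )
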