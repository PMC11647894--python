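"""Synthetic inputs with analytically known answers.

Everything the test-suite needs that a real study would take from minimized
crystal structures is generated here instead: two-body systems whose
Coulomb/Lennard-Jones energies follow from closed forms, single hydrogen
bonds placed at prescribed geometry, toy crystals of point-charge chains
shipped with an independently computed brute-force energy ledger, and noisy
linear chain-length series with known slope.  Identical parameters and seed
always produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .bulk import SizeSeries
from .crystal import Atom, Chain, Crystal, GlucoseUnit
from .forcefield import (
    HYDROXYL_TRIPLES,
    AtomTypeParams,
    ParameterizedCrystal,
    load_forcefield,
)

__all__ = [
    "make_two_body",
    "make_hbond_fixture",
    "make_group_pair_fixture",
    "make_toy_crystal",
    "make_size_series",
    "ToyLedger",
]

_O5_GROUP_ORDER = ("O4", "C1", "O5", "C5", "C4")


def _assemble(
    chain_atoms: list[list[tuple[str, np.ndarray]]],
    charges: list[float],
    radii: list[float],
    epsilons: list[float],
    bonds: list[tuple[int, int]],
    form: str | None = None,
) -> ParameterizedCrystal:
    """Build a ParameterizedCrystal from per-chain (name, xyz) lists.

    Each chain holds a single glucose-unit record; parameters are given as
    flat lists in traversal order.
    """
    chains = []
    names: list[str] = []
    coords: list[np.ndarray] = []
    chain_index: list[int] = []
    residue_index: list[int] = []
    serial = 0
    for ci, atoms in enumerate(chain_atoms):
        alist = []
        for name, xyz in atoms:
            serial += 1
            alist.append(Atom(serial, name, "H" if name.startswith("H") else name[0], xyz))
            names.append(name)
            coords.append(np.asarray(xyz, float))
            chain_index.append(ci)
            residue_index.append(ci)
        cid = chr(ord("A") + ci)
        unit = GlucoseUnit(1, cid, alist, is_terminal=True)
        chains.append(Chain(cid, [unit]))
    crystal = Crystal(form=form, chains=chains)
    return ParameterizedCrystal(
        crystal,
        names,
        np.array(coords),
        np.array(charges, float),
        np.array(radii, float),
        np.array(epsilons, float),
        np.array(chain_index),
        np.array(residue_index),
        bonds,
    )


def make_two_body(
    q1: float,
    q2: float,
    r: float,
    lj1: AtomTypeParams | None = None,
    lj2: AtomTypeParams | None = None,
) -> ParameterizedCrystal:
    """Two point atoms at distance ``r``, one per chain.

    Energies are analytic: Coulomb = 18.2223^2 q1 q2 / r plus, when LJ
    parameters are supplied, the 12-6 term with combined R_min and epsilon.
    """
    if r <= 0:
        raise ValueError("separation r must be positive")
    p1 = lj1 or AtomTypeParams("X1", q1, 1.0, 0.0)
    p2 = lj2 or AtomTypeParams("X2", q2, 1.0, 0.0)
    return _assemble(
        [
            [("X1", np.zeros(3))],
            [("X2", np.array([r, 0.0, 0.0]))],
        ],
        charges=[q1, q2],
        radii=[p1.vdw_radius, p2.vdw_radius],
        epsilons=[p1.epsilon, p2.epsilon],
        bonds=[],
    )


def _hbond_positions(
    d_HO: float, d_OO: float, angle: float, theta_COH: float, dihedral: float
) -> dict[str, np.ndarray]:
    """Donor O/H/C and acceptor O positions realizing the printed geometry.

    Donor O sits at the origin and the acceptor O on +x.  The O-H bond
    length is *derived* from (d_HO, d_OO, angle) -- the three values fix the
    O-H-O triangle completely -- and the donor carbon is placed at the C-O-H
    angle ``theta_COH`` with the given dihedral about the O-H axis (180 deg
    = anti to the acceptor, in plane).
    """
    th = np.radians(angle)
    c = np.cos(th)
    disc = d_HO * d_HO * c * c - d_HO * d_HO + d_OO * d_OO
    if disc < 0:
        raise ValueError(
            f"unsatisfiable hydrogen-bond geometry: d_HO={d_HO}, d_OO={d_OO}, "
            f"angle={angle}"
        )
    d_OH = d_HO * c + np.sqrt(disc)
    if d_OH <= 0:
        raise ValueError("unsatisfiable hydrogen-bond geometry (non-positive O-H)")
    Od = np.zeros(3)
    Oa = np.array([d_OO, 0.0, 0.0])
    # angle at the donor O between O->H and O->Oa
    cosg = (d_OH**2 + d_OO**2 - d_HO**2) / (2 * d_OH * d_OO)
    cosg = np.clip(cosg, -1.0, 1.0)
    sing = np.sqrt(1 - cosg * cosg)
    if sing < 1e-7:  # exactly collinear O-H···O
        sing, cosg = 0.0, np.sign(cosg) or 1.0
    H = d_OH * np.array([cosg, sing, 0.0])
    # donor C on the cone about the O-H axis
    u = H / np.linalg.norm(H)
    x_axis = np.array([1.0, 0.0, 0.0])
    p = x_axis - np.dot(x_axis, u) * u  # in-plane unit toward the acceptor
    norm_p = np.linalg.norm(p)
    if norm_p < 1e-9:  # collinear O-H···O: any perpendicular will do
        p = np.array([0.0, 1.0, 0.0])
    else:
        p = p / norm_p
    w = np.cross(u, p)
    tC = np.radians(theta_COH)
    ph = np.radians(dihedral)
    cdir = np.cos(tC) * u + np.sin(tC) * (np.cos(ph) * p + np.sin(ph) * w)
    C = Od + 1.43 * cdir
    return {"Od": Od, "H": H, "C": C, "Oa": Oa}


def make_hbond_fixture(
    donor: str,
    acceptor: str,
    d_HO: float,
    d_OO: float,
    angle: float,
    theta_COH: float = 109.5,
    dihedral: float = 180.0,
    ff=None,
) -> ParameterizedCrystal:
    """One donor hydroxyl triple and one acceptor group at exact geometry.

    ``donor`` is a hydroxyl oxygen name (O2/O3/O6); ``acceptor`` an acceptor
    oxygen name (O2/O3/O5/O6).  Donor and acceptor live on different chains.
    The acceptor's companion atoms (its C-O-H triple, or the five-atom ring
    group for O5) are placed at idealized positions pointing away from the
    donor; their exact placement is a synthetic choice, since the three
    geometry numbers fix only the O-H···O triangle.

    Charges and Lennard-Jones parameters come from the packaged GLYCAM06
    table unless ``ff`` is given.
    """
    if donor not in HYDROXYL_TRIPLES:
        raise ValueError(f"donor must be a hydroxyl oxygen, got {donor!r}")
    if acceptor not in ("O2", "O3", "O5", "O6"):
        raise ValueError(f"unknown acceptor oxygen {acceptor!r}")
    ff = ff or load_forcefield()
    pos = _hbond_positions(d_HO, d_OO, angle, theta_COH, dihedral)
    cname, hname = HYDROXYL_TRIPLES[donor]
    donor_atoms = [(cname, pos["C"]), (donor, pos["Od"]), (hname, pos["H"])]

    away = np.array([1.0, 0.0, 0.0])  # acceptor side, pointing away from donor
    Oa = pos["Oa"]
    acc_atoms: list[tuple[str, np.ndarray]]
    if acceptor == "O5":
        # idealized five-atom ring fragment {O4, C1, O5, C5, C4}
        c1 = Oa + 1.43 * _rot_xy(away, +56.0)
        c5 = Oa + 1.43 * _rot_xy(away, -56.0)
        c4 = c5 + 1.525 * _rot_xy(away, -112.0)
        o4 = c4 + 1.43 * _rot_xy(away, -56.0)
        acc_atoms = [("O4", o4), ("C1", c1), ("O5", Oa), ("C5", c5), ("C4", c4)]
        acc_bondnames = [("O5", "C1"), ("O5", "C5"), ("C5", "C4"), ("C4", "O4")]
    else:
        ac, ah = HYDROXYL_TRIPLES[acceptor]
        c = Oa + 1.43 * _rot_xy(away, +55.0)
        h = Oa + 0.96 * _rot_xy(away, -65.0)
        acc_atoms = [(ac, c), (acceptor, Oa), (ah, h)]
        acc_bondnames = [(acceptor, ac), (acceptor, ah)]

    atoms = [donor_atoms, acc_atoms]
    names = [n for grp in atoms for n, _ in grp]
    missing = [n for n in names if n not in ff]
    if missing:
        raise ValueError(f"no parameters for fixture atoms: {missing}")
    charges = [ff[n].partial_charge for n in names]
    radii = [ff[n].vdw_radius for n in names]
    epsilons = [ff[n].epsilon for n in names]
    bonds = [(0, 1), (1, 2)]  # donor C-O, O-H
    base = len(donor_atoms)
    name_to_idx = {n: base + i for i, (n, _) in enumerate(acc_atoms)}
    bonds += [(name_to_idx[a], name_to_idx[b]) for a, b in acc_bondnames]
    return _assemble(atoms, charges, radii, epsilons, bonds)


def _rot_xy(v: np.ndarray, deg: float) -> np.ndarray:
    t = np.radians(deg)
    R = np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])
    return R @ v


def make_group_pair_fixture(
    donor_names: list[str],
    acceptor_names: list[str],
    cross_distances: np.ndarray,
    ff=None,
    seed: int = 0,
    tol: float = 1e-6,
) -> ParameterizedCrystal:
    """Embed two atom groups realizing a prescribed cross-distance matrix.

    ``cross_distances[i, j]`` is the wanted distance between donor atom i and
    acceptor atom j.  Positions are found by deterministic (seeded)
    least-squares embedding; a residual above ``tol`` raises, since it means
    the distances admit no 3D realization.
    """
    D = np.asarray(cross_distances, float)
    nd, na = len(donor_names), len(acceptor_names)
    if D.shape != (nd, na):
        raise ValueError("cross_distances shape must be (len(donor), len(acceptor))")
    ff = ff or load_forcefield()

    def resid(x):
        p = x.reshape(nd + na, 3)
        diff = p[:nd, None, :] - p[None, nd:, :]
        return (np.sqrt((diff**2).sum(axis=2)) - D).ravel()

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(24):
        x0 = rng.normal(scale=2.0, size=3 * (nd + na))
        sol = least_squares(resid, x0, xtol=1e-15, ftol=1e-15)
        err = float(np.abs(sol.fun).max())
        if best is None or err < best[0]:
            best = (err, sol.x)
        if err < tol:
            break
    err, x = best
    if err > tol:
        raise ValueError(
            f"cross-distance matrix admits no 3D embedding (residual {err:.2e})"
        )
    P = x.reshape(nd + na, 3)
    atoms = [
        [(n, P[i]) for i, n in enumerate(donor_names)],
        [(n, P[nd + j]) for j, n in enumerate(acceptor_names)],
    ]
    names = donor_names + acceptor_names
    return _assemble(
        atoms,
        charges=[ff[n].partial_charge for n in names],
        radii=[ff[n].vdw_radius for n in names],
        epsilons=[ff[n].epsilon for n in names],
        bonds=[],
    )


@dataclass
class ToyLedger:
    """Ground-truth energies of a toy crystal from the brute-force oracle."""

    interchain_electrostatic: float  # sum over unique interchain pairs
    interchain_vdw: float
    per_chain_interchain_electrostatic: dict[str, float]
    per_chain_interchain_vdw: dict[str, float]
    intrachain_electrostatic: dict[str, float]  # with 1-2/1-3 exclusions
    intrachain_vdw: dict[str, float]


_DEFAULT_MOTIF = (
    # (name, offset(A), charge(e), radius(A), epsilon(kcal/mol))
    ("TP", (0.00, 0.00, 0.00), 0.30, 3.0, 0.10),
    ("TM", (0.55, 0.00, 0.45), -0.30, 2.6, 0.05),
)


def make_toy_crystal(
    n_chains: int,
    dp: int,
    lattice_spacing: float = 4.0,
    motif=_DEFAULT_MOTIF,
    residue_spacing: float = 2.5,
) -> tuple[ParameterizedCrystal, ToyLedger]:
    """Toy lattice of straight point-atom chains plus a brute-force ledger.

    Chains sit on a square grid of ``lattice_spacing`` in the xy plane and
    run along z with one motif copy per residue.  Atoms within a residue are
    bonded sequentially and residues are linked first-to-last, so the
    crystal exercises the 1-2/1-3 intrachain exclusions.  The ledger is
    computed by an independent O(N^2) Python loop over unique atom pairs.
    """
    if n_chains < 1 or dp < 1:
        raise ValueError("need at least one chain and one residue")
    motif = list(motif)
    side = int(np.ceil(np.sqrt(n_chains)))
    chain_atoms: list[list[tuple[str, np.ndarray]]] = []
    chains: list[Chain] = []
    names: list[str] = []
    coords: list[np.ndarray] = []
    charges: list[float] = []
    radii: list[float] = []
    epsilons: list[float] = []
    chain_index: list[int] = []
    residue_index: list[int] = []
    bonds: list[tuple[int, int]] = []
    serial = 0
    ri = -1
    for ci in range(n_chains):
        gx, gy = divmod(ci, side)
        base = np.array([gx * lattice_spacing, gy * lattice_spacing, 0.0])
        cid = _toy_chain_id(ci)
        units = []
        prev_last = None
        for k in range(dp):
            ri += 1
            alist = []
            first_idx = None
            for m, (nm, off, q, rad, eps) in enumerate(motif):
                serial += 1
                xyz = base + np.asarray(off, float) + np.array([0, 0, k * residue_spacing])
                alist.append(Atom(serial, nm, nm[0], xyz))
                idx = len(names)
                names.append(nm)
                coords.append(xyz)
                charges.append(q)
                radii.append(rad)
                epsilons.append(eps)
                chain_index.append(ci)
                residue_index.append(ri)
                if m > 0:
                    bonds.append((idx - 1, idx))
                if first_idx is None:
                    first_idx = idx
            if prev_last is not None:
                bonds.append((prev_last, first_idx))
            prev_last = len(names) - 1
            units.append(GlucoseUnit(k + 1, cid, alist, is_terminal=k in (0, dp - 1)))
        chains.append(Chain(cid, units, direction=np.array([0.0, 0.0, 1.0])))
    crystal = Crystal(form=None, chains=chains)
    pc = ParameterizedCrystal(
        crystal, names, np.array(coords), np.array(charges), np.array(radii),
        np.array(epsilons), np.array(chain_index), np.array(residue_index), bonds,
    )
    # overlap sanity: distinct chains must not interpenetrate
    if n_chains > 1:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if chain_index[i] != chain_index[j]:
                    if np.linalg.norm(np.array(coords[i]) - np.array(coords[j])) < 0.5:
                        raise ValueError("overlapping chains in toy crystal")
    return pc, _brute_force_ledger(pc)


def _toy_chain_id(ci: int) -> str:
    alpha = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if ci < 26:
        return alpha[ci]
    return alpha[ci // 26 - 1] + alpha[ci % 26]


def _brute_force_ledger(pc: ParameterizedCrystal) -> ToyLedger:
    """Independent O(N^2) unique-pair sum (plain Python, no vectorization)."""
    from math import sqrt

    # independent 1-2/1-3 set via explicit two-step neighbor walk
    nbr: dict[int, set[int]] = {}
    for a, b in pc.bonds:
        nbr.setdefault(a, set()).add(b)
        nbr.setdefault(b, set()).add(a)
    excluded = set()
    for a in nbr:
        reach = set(nbr[a])
        for b in nbr[a]:
            reach |= nbr.get(b, set())
        reach.discard(a)
        for b in reach:
            excluded.add((min(a, b), max(a, b)))

    K = 18.2223**2
    ids = pc.chain_ids
    inter_e = inter_v = 0.0
    pce = {cid: 0.0 for cid in ids}
    pcv = {cid: 0.0 for cid in ids}
    intra_e = {cid: 0.0 for cid in ids}
    intra_v = {cid: 0.0 for cid in ids}
    n = pc.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            dx = pc.coords[i] - pc.coords[j]
            r = sqrt(dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2)
            e = K * pc.charges[i] * pc.charges[j] / r
            rmin = 0.5 * (pc.radii[i] + pc.radii[j])
            eps = sqrt(pc.epsilons[i] * pc.epsilons[j])
            x6 = (rmin / r) ** 6
            v = eps * (x6 * x6 - 2 * x6)
            ci, cj = pc.chain_index[i], pc.chain_index[j]
            if ci != cj:
                inter_e += e
                inter_v += v
                for c in (ci, cj):
                    pce[ids[c]] += 0.5 * e
                    pcv[ids[c]] += 0.5 * v
            elif (i, j) not in excluded:
                intra_e[ids[ci]] += e
                intra_v[ids[ci]] += v
    return ToyLedger(inter_e, inter_v, pce, pcv, intra_e, intra_v)


def make_size_series(
    slope: float,
    intercept: float,
    noise_sd: float,
    dp_list: list[int],
    seed: int = 0,
    term: str = "synthetic",
) -> SizeSeries:
    """Linear per-chain energy series with optional Gaussian noise."""
    if not dp_list:
        raise ValueError("dp_list must be nonempty")
    rng = np.random.default_rng(seed)
    dp = np.asarray(sorted(dp_list), float)
    y = slope * dp + intercept
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=len(dp))
    return SizeSeries([int(v) for v in dp], [float(v) for v in y], term=term)
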