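"""Hydrogen-bond detection and group-based (multipole) energy scoring.

Hydrogen bonds are identified with a distance- and angle-based geometric
criterion (hydroxyl donors O2/O3/O6; acceptors O2/O3/O5/O6) and scored in
three electrostatic/vdW modes of increasing physical realism:

``OH_O``
    donor O and H versus the acceptor O alone -- the naive dipole picture.
    For cellulose this picture fails: the O-O repulsion between the heavily
    charged oxygens exceeds the H···O attraction.
``COH_O``
    the full donor C-O-H triple versus the acceptor O.  Attractive, but it
    systematically overestimates hydrogen-bond strengths.
``COH_COX``
    the donor C-O-H triple versus the acceptor's near-neutral atom group
    (the acceptor's own C-O-H triple for hydroxyl acceptors; the five-atom
    {O4, C1, O5, C5, C4} group for the ring oxygen O5).  Both groups are
    nearly neutral, so this is a multipole-multipole energy, analogous to
    the classical CO/NH dipole treatment of protein backbone hydrogen bonds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energetics import group_interaction_energy
from .forcefield import (
    ACCEPTOR_GROUP_OF,
    CHARGE_GROUPS,
    HYDROXYL_TRIPLES,
    ParameterizedCrystal,
)

__all__ = [
    "HBond",
    "HBondEnergy",
    "HBondCriteria",
    "detect_hbonds",
    "hbond_geometry",
    "hbond_energy",
    "aggregate_per_glucose",
    "fraction_of_interchain_electrostatics",
]

MODES = ("OH_O", "COH_O", "COH_COX")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criterion: H···O distance cap and O-H···O angle floor.

    The defaults (3.0 A, 115 deg) are wide enough to admit the weak branch
    bond of cellulose Ibeta (d_HO near 3 A, angle near 120 deg) while
    excluding ordinary nonbonded contacts.
    """

    max_d_HO: float = 3.0
    min_angle: float = 115.0


@dataclass
class HBond:
    """One detected hydrogen bond (atom references are flat indices)."""

    donor_O: int
    donor_H: int
    donor_C: int
    acceptor_O: int
    acceptor_group: str  # ChargeGroup label
    d_HO: float
    d_OO: float
    angle: float  # deg, at H
    scope: str  # "intra" | "inter"
    class_label: str
    donor_chain: str
    donor_residue: int  # global residue index
    donor_parity: str | None = None


@dataclass
class HBondEnergy:
    mode: str
    electrostatic: float
    vdw: float


def hbond_geometry(
    donor_O_xyz: np.ndarray, donor_H_xyz: np.ndarray, acceptor_O_xyz: np.ndarray
) -> tuple[float, float, float]:
    """(d_HO, d_OO, angle): H···O_acc and O_don···O_acc distances in A and
    the O_don-H···O_acc angle in degrees, measured at the hydrogen."""
    dO = np.asarray(donor_O_xyz, float)
    h = np.asarray(donor_H_xyz, float)
    aO = np.asarray(acceptor_O_xyz, float)
    d_HO = float(np.linalg.norm(aO - h))
    d_OO = float(np.linalg.norm(aO - dO))
    u = dO - h
    v = aO - h
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise ValueError("coincident atoms in hydrogen-bond geometry")
    # atan2 form is well conditioned near 0 and 180 degrees
    ang = np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))
    return d_HO, d_OO, float(np.degrees(ang))


def _residue_atom_map(pc: ParameterizedCrystal, ri: int) -> dict[str, int]:
    return {pc.names[i]: i for i in pc.atoms_of_residue(ri)}


def detect_hbonds(
    pc: ParameterizedCrystal,
    criteria: HBondCriteria = HBondCriteria(),
    parity_labels: dict[str, str] | None = None,
) -> list[HBond]:
    """Detect hydrogen bonds satisfying the geometric criterion.

    Donors are the hydroxyl oxygens O2/O3/O6 (their H must be present in the
    structure); acceptors are O2/O3/O5/O6 of any *other* glucose unit.  One
    donor H may satisfy the criterion with several acceptors (branched
    bonds); each match is reported as its own record.  Ordering is
    deterministic: (donor chain, donor residue, donor O name, acceptor).
    """
    donor_names = set(HYDROXYL_TRIPLES)
    acceptor_names = set(ACCEPTOR_GROUP_OF)
    if not any(n.startswith("HO") for n in pc.names):
        raise ValueError(
            "structure carries no hydroxyl hydrogens; hydrogen-bond detection "
            "needs a hydrogen-bearing input"
        )
    chain_ids = pc.chain_ids

    residues = sorted(set(pc.residue_index.tolist()))
    maps = {ri: _residue_atom_map(pc, ri) for ri in residues}
    acceptors = [
        (ri, nm, i)
        for ri in residues
        for nm, i in maps[ri].items()
        if nm in acceptor_names
    ]
    acc_xyz = np.array([pc.coords[i] for _, _, i in acceptors])

    out: list[HBond] = []
    for ri in residues:
        amap = maps[ri]
        for oname in sorted(donor_names):
            if oname not in amap:
                continue
            cname, hname = HYDROXYL_TRIPLES[oname]
            if hname not in amap or cname not in amap:
                continue
            iO, iH, iC = amap[oname], amap[hname], amap[cname]
            d = np.linalg.norm(acc_xyz - pc.coords[iH], axis=1)
            for (arj, anm, ai), d_HO in zip(acceptors, d):
                if arj == ri or d_HO > criteria.max_d_HO:
                    continue
                d_HO, d_OO, ang = hbond_geometry(
                    pc.coords[iO], pc.coords[iH], pc.coords[ai]
                )
                if ang < criteria.min_angle or d_HO >= d_OO:
                    continue
                dchain = chain_ids[pc.chain_index[iO]]
                achain = chain_ids[pc.chain_index[ai]]
                scope = "intra" if dchain == achain else "inter"
                parity = None
                if parity_labels is not None:
                    parity = parity_labels.get(dchain)
                label = f"{oname}H···{anm} {scope}"
                out.append(
                    HBond(
                        donor_O=iO, donor_H=iH, donor_C=iC, acceptor_O=ai,
                        acceptor_group=ACCEPTOR_GROUP_OF[anm],
                        d_HO=d_HO, d_OO=d_OO, angle=ang, scope=scope,
                        class_label=label, donor_chain=dchain,
                        donor_residue=ri, donor_parity=parity,
                    )
                )
    out.sort(
        key=lambda h: (
            h.donor_chain,
            h.donor_residue,
            pc.names[h.donor_O],
            pc.names[h.acceptor_O],
            h.acceptor_O,
        )
    )
    return out


def hbond_energy(pc: ParameterizedCrystal, hb: HBond, mode: str) -> HBondEnergy:
    """Score one hydrogen bond in the requested mode (see module docstring)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; known: {MODES}")
    if mode == "OH_O":
        donor = [hb.donor_O, hb.donor_H]
    else:
        donor = [hb.donor_C, hb.donor_O, hb.donor_H]
    if mode in ("OH_O", "COH_O"):
        acceptor = [hb.acceptor_O]
    else:
        group = CHARGE_GROUPS[hb.acceptor_group]
        amap = _residue_atom_map(pc, int(pc.residue_index[hb.acceptor_O]))
        acceptor = []
        for nm in group.member_atom_names:
            if nm not in amap:
                raise ValueError(
                    f"acceptor group {group.label} member {nm!r} missing from "
                    f"residue {pc.residue_index[hb.acceptor_O]}"
                )
            acceptor.append(amap[nm])
    elec, vdw = group_interaction_energy(pc, donor, acceptor)
    return HBondEnergy(mode=mode, electrostatic=elec, vdw=vdw)


def aggregate_per_glucose(
    pc: ParameterizedCrystal | None,
    hbonds: list[HBond],
    scope: str,
    mode: str,
    energies: list[HBondEnergy] | None = None,
    component: str = "electrostatic",
    n_glucose_per_parity: dict[str, int] | None = None,
) -> float:
    """Per-glucose hydrogen-bond energy, averaged over chain parities.

    Bonds of the requested scope are attributed to their donor glucose unit;
    for each chain parity the bond energies are summed and divided by the
    number of distinct donor units of that parity (or by an explicit per-
    parity glucose count), and the origin- and center-chain per-glucose sums
    are averaged.  Every bond must carry a parity label.
    """
    sel = [h for h in hbonds if h.scope == scope]
    if not sel:
        return 0.0
    if energies is None:
        if pc is None:
            raise ValueError("need either precomputed energies or a structure")
        energies_sel = [hbond_energy(pc, h, mode) for h in sel]
    else:
        if len(energies) != len(hbonds):
            raise ValueError("energies must align with hbonds")
        energies_sel = [
            e for h, e in zip(hbonds, energies) if h.scope == scope
        ]
    sums: dict[str, float] = {}
    donors: dict[str, set[int]] = {}
    for h, e in zip(sel, energies_sel):
        if h.donor_parity not in ("origin", "center"):
            raise ValueError(
                f"hydrogen bond {h.class_label!r} lacks a chain parity label"
            )
        val = e.electrostatic if component == "electrostatic" else e.vdw
        sums[h.donor_parity] = sums.get(h.donor_parity, 0.0) + val
        donors.setdefault(h.donor_parity, set()).add(h.donor_residue)
    per_parity = []
    for parity, s in sorted(sums.items()):
        if n_glucose_per_parity is not None:
            n = n_glucose_per_parity[parity]
        else:
            n = len(donors[parity])
        per_parity.append(s / n)
    return float(np.mean(per_parity))


def fraction_of_interchain_electrostatics(
    hbond_per_glucose: float, bulk_elec_per_glucose: float
) -> int:
    """Hydrogen-bond share of the interchain electrostatics, in percent.

    Both inputs are per-glucose energies in kcal/mol; with both negative
    (attractive) the result is a positive integer percentage.
    """
    if bulk_elec_per_glucose == 0:
        raise ValueError("bulk electrostatic energy is zero")
    return int(round(100.0 * hbond_per_glucose / bulk_elec_per_glucose))
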