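"""Pairwise nonbonded energies and their interchain/intrachain decomposition.

Electrostatics is the bare Coulomb interaction of GLYCAM partial charges,

    E_elec(i, j) = (18.2223 q_i) (18.2223 q_j) / r_ij   [kcal/mol, r in A],

with no distance cutoff, no periodic images and relative permittivity 1:
the crystals analyzed here are finite and built from neutral glucose units,
whose mutual electrostatic interactions are short-ranged (multipole-like)
compared with bare atomic Coulomb terms.  The van der Waals interaction is
the 12-6 Lennard-Jones potential

    E_vdW(i, j) = eps [ (R_min/r)^12 - 2 (R_min/r)^6 ],

with R_min = (R_i + R_j)/2 and eps = sqrt(eps_i eps_j); its minimum is
exactly -eps at r = R_min.

The interchain energy of a chain is half the sum of its pairwise energies
with all atoms of every other chain (the half compensates the double
counting of pairs when averaging over chains).  Intrachain sums exclude
covalent 1-2 and 1-3 pairs; 1-4 and more distant pairs enter at full
strength (GLYCAM applies no 1-4 nonbonded scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import AtomTypeParams, ParameterizedCrystal

__all__ = [
    "COULOMB_PREFACTOR",
    "coulomb_energy",
    "lj_energy",
    "group_interaction_energy",
    "interchain_energy",
    "intrachain_nonbonded_energy",
    "EnergyBreakdown",
]

#: (18.2223)^2 -- converts q_i q_j / r [e^2/A] to kcal/mol
COULOMB_PREFACTOR = 18.2223**2


def coulomb_energy(q_i: float, q_j: float, r: float) -> float:
    """Coulomb energy (kcal/mol) of two partial charges (e) at distance r (A)."""
    if r <= 0:
        raise ValueError(f"interatomic distance must be positive, got {r}")
    return COULOMB_PREFACTOR * q_i * q_j / r


def lj_energy(params_i: AtomTypeParams, params_j: AtomTypeParams, r: float) -> float:
    """12-6 Lennard-Jones energy (kcal/mol) at distance r (A).

    R_min is the arithmetic mean of the two atomic radii, the well depth the
    geometric mean of the two atomic well depths.
    """
    if r <= 0:
        raise ValueError(f"interatomic distance must be positive, got {r}")
    rmin = 0.5 * (params_i.vdw_radius + params_j.vdw_radius)
    eps = np.sqrt(params_i.epsilon * params_j.epsilon)
    x = (rmin / r) ** 6
    return eps * (x * x - 2.0 * x)


def _pair_energies_blocks(
    pc: ParameterizedCrystal, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[float, float]:
    """Vectorized sums of Coulomb and LJ energies over the a x b pair block."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        return 0.0, 0.0
    d = pc.coords[idx_a][:, None, :] - pc.coords[idx_b][None, :, :]
    r = np.sqrt((d * d).sum(axis=2))
    if np.any(r <= 1e-9):
        raise ValueError("coincident atoms in pair-energy evaluation")
    elec = COULOMB_PREFACTOR * np.outer(pc.charges[idx_a], pc.charges[idx_b]) / r
    rmin = 0.5 * (pc.radii[idx_a][:, None] + pc.radii[idx_b][None, :])
    eps = np.sqrt(np.outer(pc.epsilons[idx_a], pc.epsilons[idx_b]))
    x = (rmin / r) ** 6
    vdw = eps * (x * x - 2.0 * x)
    return float(elec.sum()), float(vdw.sum())


def group_interaction_energy(
    pc: ParameterizedCrystal, group_a, group_b
) -> tuple[float, float]:
    """(electrostatic, vdW) energy between two disjoint atom groups.

    Full double sum over a x b atom pairs; no exclusions apply across groups.
    Groups are flat atom indices into ``pc``.
    """
    a = np.asarray(list(group_a), dtype=int)
    b = np.asarray(list(group_b), dtype=int)
    if len(np.intersect1d(a, b)) > 0:
        raise ValueError("groups overlap; group interaction requires disjoint groups")
    return _pair_energies_blocks(pc, a, b)


@dataclass
class EnergyBreakdown:
    """Electrostatic and vdW totals of one scope, with per-chain detail.

    ``electrostatic`` / ``vdw`` aggregate the per-chain values either as the
    mean (default; the per-chain energy of a typical selected chain) or the
    sum, recorded in ``aggregate``.  ``per_glucose`` divides the aggregate by
    the chain length.
    """

    scope: str  # "interchain" | "intrachain"
    electrostatic: float
    vdw: float
    per_chain_electrostatic: dict[str, float]
    per_chain_vdw: dict[str, float]
    aggregate: str = "mean"
    per_glucose_electrostatic: float | None = None
    per_glucose_vdw: float | None = None

    @property
    def total(self) -> float:
        return self.electrostatic + self.vdw


def _aggregate(values: dict[str, float], how: str) -> float:
    v = np.array(list(values.values()))
    if how == "mean":
        return float(v.mean()) if len(v) else 0.0
    if how == "sum":
        return float(v.sum())
    raise ValueError(f"unknown aggregate {how!r}")


def interchain_energy(
    pc: ParameterizedCrystal,
    chain_subset: list[str] | None = None,
    aggregate: str = "mean",
) -> EnergyBreakdown:
    """Interchain energy of each chain in ``chain_subset``.

    The per-chain value is half the pairwise sum between the chain's atoms
    and the atoms of *all* other chains of the crystal (not restricted to
    the subset); the factor 1/2 compensates double counting of pairs when
    the per-chain values are averaged or summed over chains.
    """
    ids = pc.chain_ids
    if chain_subset is None:
        chain_subset = ids
    if not chain_subset:
        raise ValueError("chain_subset must be nonempty")
    missing = set(chain_subset) - set(ids)
    if missing:
        raise ValueError(f"unknown chain ids: {sorted(missing)}")
    pce, pcv = {}, {}
    all_idx = np.arange(pc.n_atoms)
    for cid in chain_subset:
        ci = ids.index(cid)
        mine = pc.atoms_of_chain(ci)
        others = all_idx[pc.chain_index != ci]
        e, v = _pair_energies_blocks(pc, mine, others)
        pce[cid] = 0.5 * e
        pcv[cid] = 0.5 * v
    dp = max((len(c.units) for c in pc.crystal.chains), default=0)
    e_tot, v_tot = _aggregate(pce, aggregate), _aggregate(pcv, aggregate)
    return EnergyBreakdown(
        scope="interchain",
        electrostatic=e_tot,
        vdw=v_tot,
        per_chain_electrostatic=pce,
        per_chain_vdw=pcv,
        aggregate=aggregate,
        per_glucose_electrostatic=e_tot / dp if dp else None,
        per_glucose_vdw=v_tot / dp if dp else None,
    )


def intrachain_nonbonded_energy(
    pc: ParameterizedCrystal,
    chain_subset: list[str] | None = None,
    aggregate: str = "mean",
) -> EnergyBreakdown:
    """Nonbonded energy within each chain (1-2 and 1-3 pairs excluded).

    This is the *nonbonded* part of the intrachain energy only; bonded
    (bond/angle/dihedral) contributions are outside the scope of this
    package.
    """
    ids = pc.chain_ids
    if chain_subset is None:
        chain_subset = ids
    if not chain_subset:
        raise ValueError("chain_subset must be nonempty")
    excl = pc.excluded_pairs()
    pce, pcv = {}, {}
    for cid in chain_subset:
        ci = ids.index(cid)
        idx = pc.atoms_of_chain(ci)
        d = pc.coords[idx][:, None, :] - pc.coords[idx][None, :, :]
        r = np.sqrt((d * d).sum(axis=2))
        iu, ju = np.triu_indices(len(idx), k=1)
        rr = r[iu, ju]
        if np.any(rr <= 1e-9):
            raise ValueError("coincident atoms within a chain")
        keep = np.array(
            [
                (min(a, b), max(a, b)) not in excl
                for a, b in zip(idx[iu], idx[ju])
            ]
        )
        qq = pc.charges[idx][iu] * pc.charges[idx][ju]
        elec = COULOMB_PREFACTOR * qq / rr
        rmin = 0.5 * (pc.radii[idx][iu] + pc.radii[idx][ju])
        eps = np.sqrt(pc.epsilons[idx][iu] * pc.epsilons[idx][ju])
        x = (rmin / rr) ** 6
        vdw = eps * (x * x - 2.0 * x)
        pce[cid] = float(elec[keep].sum())
        pcv[cid] = float(vdw[keep].sum())
    dp = max((len(c.units) for c in pc.crystal.chains), default=0)
    e_tot, v_tot = _aggregate(pce, aggregate), _aggregate(pcv, aggregate)
    return EnergyBreakdown(
        scope="intrachain",
        electrostatic=e_tot,
        vdw=v_tot,
        per_chain_electrostatic=pce,
        per_chain_vdw=pcv,
        aggregate=aggregate,
        per_glucose_electrostatic=e_tot / dp if dp else None,
        per_glucose_vdw=v_tot / dp if dp else None,
    )
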