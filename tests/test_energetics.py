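"""Pair potentials, group sums, and the interchain/intrachain decomposition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cellenergy as ce
from cellenergy.forcefield import AtomTypeParams, central_unit_names
from cellenergy.synthdata import make_toy_crystal, make_two_body


class TestCoulomb:
    @given(
        q1=st.floats(-1, 1), q2=st.floats(-1, 1),
        r=st.floats(0.5, 50), alpha=st.floats(0.5, 4),
    )
    def test_symmetry_and_inverse_r_scaling(self, q1, q2, r, alpha):
        assert ce.coulomb_energy(q1, q2, r) == pytest.approx(
            ce.coulomb_energy(q2, q1, r), rel=1e-15, abs=1e-300
        )
        assert ce.coulomb_energy(q1, q2, alpha * r) == pytest.approx(
            ce.coulomb_energy(q1, q2, r) / alpha
        )

    def test_zero_charge(self):
        assert ce.coulomb_energy(0.0, -0.7, 1.8) == 0.0

    def test_nonpositive_distance_raises(self):
        with pytest.raises(ValueError):
            ce.coulomb_energy(0.1, 0.1, 0.0)
        with pytest.raises(ValueError):
            ce.coulomb_energy(0.1, 0.1, -1.0)


class TestLennardJones:
    O = AtomTypeParams("O3", -0.709, 3.442, 0.2104)
    C = AtomTypeParams("C3", 0.284, 3.816, 0.1094)

    def test_minimum_location_and_depth_exact(self):
        rmin = 0.5 * (self.O.vdw_radius + self.C.vdw_radius)
        eps = np.sqrt(self.O.epsilon * self.C.epsilon)
        assert ce.lj_energy(self.O, self.C, rmin) == pytest.approx(-eps, rel=1e-14)
        # it is a strict minimum
        for dr in (-1e-4, 1e-4):
            assert ce.lj_energy(self.O, self.C, rmin + dr) > -eps

    def test_repulsive_inside_contact(self):
        # two hydroxyl oxygens at a typical hydrogen-bond O-O distance sit
        # well inside their combined vdW radius and repel
        assert ce.lj_energy(self.O, self.O, 2.72) > 0

    def test_long_range_decay(self):
        rmin = 0.5 * (self.O.vdw_radius + self.C.vdw_radius)
        eps = np.sqrt(self.O.epsilon * self.C.epsilon)
        assert abs(ce.lj_energy(self.O, self.C, 10 * rmin)) < 1e-5 * eps

    def test_nonpositive_distance_raises(self):
        with pytest.raises(ValueError):
            ce.lj_energy(self.O, self.C, 0.0)


class TestGroupInteraction:
    def test_matches_pairwise_double_sum(self, ff):
        rng = np.random.default_rng(3)
        names = ["C6", "O6", "HO6", "C3", "O3", "HO3"]
        from cellenergy.synthdata import _assemble

        coords = rng.uniform(-3, 3, size=(6, 3))
        coords[3:] += 8.0  # keep groups apart
        pc = _assemble(
            [[(n, coords[i]) for i, n in enumerate(names[:3])],
             [(n, coords[3 + i]) for i, n in enumerate(names[3:])]],
            charges=[ff[n].partial_charge for n in names],
            radii=[ff[n].vdw_radius for n in names],
            epsilons=[ff[n].epsilon for n in names],
            bonds=[],
        )
        elec, vdw = ce.group_interaction_energy(pc, [0, 1, 2], [3, 4, 5])
        e_ref = v_ref = 0.0
        for i in range(3):
            for j in range(3, 6):
                r = float(np.linalg.norm(pc.coords[i] - pc.coords[j]))
                e_ref += ce.coulomb_energy(pc.charges[i], pc.charges[j], r)
                pi = AtomTypeParams(names[i], pc.charges[i], pc.radii[i], pc.epsilons[i])
                pj = AtomTypeParams(names[j], pc.charges[j], pc.radii[j], pc.epsilons[j])
                v_ref += ce.lj_energy(pi, pj, r)
        assert elec == pytest.approx(e_ref, rel=1e-12)
        assert vdw == pytest.approx(v_ref, rel=1e-12)

    def test_overlapping_groups_raise(self):
        pc = make_two_body(0.1, -0.1, 3.0)
        with pytest.raises(ValueError, match="overlap"):
            ce.group_interaction_energy(pc, [0], [0, 1])

    def test_zero_charges_zero_electrostatics(self):
        pc = make_two_body(0.0, 0.0, 3.0)
        elec, _ = ce.group_interaction_energy(pc, [0], [1])
        assert elec == 0.0


class TestDecomposition:
    def test_single_chain_interchain_zero(self):
        pc, _ = make_toy_crystal(1, 4)
        br = ce.interchain_energy(pc)
        assert br.electrostatic == 0.0
        assert br.vdw == 0.0

    def test_matches_brute_force_ledger(self):
        pc, ledger = make_toy_crystal(3, 4)
        br = ce.interchain_energy(pc, aggregate="sum")
        # summed per-chain halves equal the unique-pair total
        assert br.electrostatic == pytest.approx(
            ledger.interchain_electrostatic, rel=1e-10
        )
        assert br.vdw == pytest.approx(ledger.interchain_vdw, rel=1e-10)
        for cid, v in ledger.per_chain_interchain_electrostatic.items():
            assert br.per_chain_electrostatic[cid] == pytest.approx(v, rel=1e-9)

    def test_identical_chains_symmetric(self):
        pc, _ = make_toy_crystal(2, 5)
        br = ce.interchain_energy(pc)
        vals = list(br.per_chain_electrostatic.values())
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)

    def test_intrachain_exclusions(self):
        # a two-atom bonded chain has no nonbonded intrachain pairs
        pc, _ = make_toy_crystal(1, 1)
        br = ce.intrachain_nonbonded_energy(pc)
        assert br.electrostatic == 0.0 and br.vdw == 0.0

    def test_intrachain_matches_ledger(self):
        pc, ledger = make_toy_crystal(2, 4)
        br = ce.intrachain_nonbonded_energy(pc)
        for cid, v in ledger.intrachain_electrostatic.items():
            assert br.per_chain_electrostatic[cid] == pytest.approx(v, rel=1e-9)
        for cid, v in ledger.intrachain_vdw.items():
            assert br.per_chain_vdw[cid] == pytest.approx(v, rel=1e-9)

    def test_chargefree_chain_is_vdw_only(self):
        motif = (("TA", (0, 0, 0), 0.0, 3.0, 0.1), ("TB", (0.6, 0, 0.5), 0.0, 2.8, 0.05))
        pc, _ = make_toy_crystal(1, 4, motif=motif)
        br = ce.intrachain_nonbonded_energy(pc)
        assert br.electrostatic == 0.0
        assert br.vdw != 0.0

    def test_totals_equal_per_chain_aggregate(self):
        pc, _ = make_toy_crystal(4, 3)
        for agg, fn in (("mean", np.mean), ("sum", np.sum)):
            br = ce.interchain_energy(pc, aggregate=agg)
            assert br.electrostatic == pytest.approx(
                float(fn(list(br.per_chain_electrostatic.values()))), rel=1e-12
            )

    def test_unknown_chain_subset(self):
        pc, _ = make_toy_crystal(2, 2)
        with pytest.raises(ValueError, match="unknown chain"):
            ce.interchain_energy(pc, ["Z"])


class TestNeutralGroupShortRange:
    def test_neutral_glucose_pair_interaction_is_multipole_like(self, ff):
        """Two neutral glucose charge sets interact much faster-decaying than
        Coulomb: doubling the separation cuts the energy by far more than 2."""
        from cellenergy.crystal import load_template
        from cellenergy.synthdata import _assemble

        tpl = load_template("Ibeta")
        names = [n for n in tpl.atom_names]
        X = tpl.residue_local

        def energy_at(d):
            pc = _assemble(
                [[(n, X[i]) for i, n in enumerate(names)],
                 [(n, X[i] + np.array([d, 0, 0])) for i, n in enumerate(names)]],
                charges=[ff[n].partial_charge for n in names] * 2,
                radii=[ff[n].vdw_radius for n in names] * 2,
                epsilons=[0.0] * (2 * len(names)),
                bonds=[],
            )
            e, _ = ce.group_interaction_energy(
                pc, range(len(names)), range(len(names), 2 * len(names))
            )
            return e

        energies = [energy_at(d) for d in (12.0, 24.0, 48.0)]
        for e1, e2 in zip(energies, energies[1:]):
            assert abs(e2) < abs(e1) / 4  # faster than 1/r^2; dipoles give 1/8
        # |E| * d^3 stays bounded (multipole series leads with dipole-dipole)
        vals = [abs(e) * d**3 for e, d in zip(energies, (12.0, 24.0, 48.0))]
        assert max(vals) < 10 * max(vals[0], 1e-12)
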