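"""Nonbonded energies: closed forms, decomposition, oracle equivalence, π–π."""

import itertools

import numpy as np
import pytest

from oligostate.energetics import (
    AtomParameters,
    COULOMB_KCAL_A,
    default_parameters,
    iie,
    pair_energy,
    pipi_interactions,
    read_parameters,
    total_energy,
    write_parameters,
)
from oligostate.synthetic import AssemblyScript, Event, build_peptide, generate
from oligostate.topology import SystemTopology, TrajectoryFrame


def _params(q, sigma=0.3, eps=0.0):
    n = len(q)
    return AtomParameters(np.asarray(q, float), np.full(n, sigma), np.full(n, eps))


class TestPairEnergy:
    def test_point_charges_at_one_nanometre(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[1.0, 0, 0]])
        e = pair_energy(a, b, _params([1.0]), _params([-1.0]))
        assert e.ele == pytest.approx(-COULOMB_KCAL_A / 10.0, abs=1e-9)
        assert e.ele == pytest.approx(-33.206, abs=5e-4)
        assert e.vdw == 0.0

    def test_lj_minimum_is_minus_epsilon(self):
        sigma, eps = 0.34, 0.25
        r = sigma * 2 ** (1 / 6)
        a = np.array([[0.0, 0, 0]])
        b = np.array([[r, 0, 0]])
        e = pair_energy(a, b, _params([0.0], sigma, eps), _params([0.0], sigma, eps))
        assert e.vdw == pytest.approx(-eps, abs=1e-12)
        assert e.ele == 0.0

    def test_groups_beyond_cutoff_are_zero(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3)) + np.array([3.0, 0, 0])
        pa = _params([1.0, -0.5, 0.2], eps=0.1)
        pb = _params([0.3, 0.3, -0.6], eps=0.1)
        e = pair_energy(a + np.random.default_rng(0).normal(0, 0.05, (3, 3)),
                        b, pa, pb, cutoff_nm=1.0)
        assert e.vdw == 0.0 and e.ele == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, (4, 3))
        b = rng.uniform(2, 3, (5, 3))
        pa = AtomParameters(rng.normal(0, 0.3, 4), rng.uniform(0.2, 0.4, 4),
                            rng.uniform(0, 0.3, 4))
        pb = AtomParameters(rng.normal(0, 0.3, 5), rng.uniform(0.2, 0.4, 5),
                            rng.uniform(0, 0.3, 5))
        e1 = pair_energy(a, b, pa, pb)
        e2 = pair_energy(b, a, pb, pa)
        assert e1.vdw == pytest.approx(e2.vdw, rel=1e-12)
        assert e1.ele == pytest.approx(e2.ele, rel=1e-12)

    def test_overlapping_atoms_rejected(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[0.005, 0, 0]])
        with pytest.raises(ValueError, match="overlap"):
            pair_energy(a, b, _params([0.0]), _params([0.0]))


class TestIIE:
    def test_separated_peptides_zero_with_cutoff(self, wt_system):
        top, frames, _ = wt_system
        e = iie(top, frames[0], cutoff_nm=1.0)
        assert e.vdw == 0.0 and e.ele == 0.0

    def test_decomposition_sums_to_total(self, sheet_trajectory):
        _, top, frames, _ = sheet_trajectory
        e = iie(top, frames[-1])
        assert e.total == pytest.approx(e.vdw + e.ele, abs=1e-12)

    def test_matches_difference_form_oracle(self, sheet_trajectory):
        """IIE as the sum of inter-peptide pair energies equals
        E_complex - sum_i E_i computed by a brute-force total-energy
        routine (intra-peptide terms cancel exactly)."""
        _, top, frames, _ = sheet_trajectory
        params = default_parameters(top)
        for fr in (frames[0], frames[-1]):
            direct = iie(top, fr, params)
            e_complex = total_energy(fr.coordinates, params)
            vdw_diff = e_complex.vdw
            ele_diff = e_complex.ele
            for p in range(top.n_peptides):
                idx = top.peptide_atom_indices(p)
                mono = total_energy(fr.coordinates[idx], params.subset(idx))
                vdw_diff -= mono.vdw
                ele_diff -= mono.ele
            assert direct.vdw == pytest.approx(vdw_diff, abs=1e-9)
            assert direct.ele == pytest.approx(ele_diff, abs=1e-9)

    def test_docked_complementary_charges_attract(self):
        # two 2-atom "peptides" with +/- charges facing each other
        from oligostate.topology import PeptideTopology, Residue

        coords = np.array(
            [[0.0, 0, 0], [0.3, 0, 0], [0.8, 0, 0], [1.1, 0, 0]]
        )
        peptides = []
        for p in range(2):
            idx = np.arange(2 * p, 2 * p + 2)
            res = Residue("UNK", ("A", "B"), ("C", "C"), idx)
            peptides.append(PeptideTopology([res]))
        top = SystemTopology(peptides, 4)
        params = AtomParameters(np.array([1.0, -1.0, 1.0, -1.0]),
                                np.full(4, 0.2), np.zeros(4))
        e = iie(top, TrajectoryFrame(0, 0.0, coords), params)
        assert e.ele < 0

    def test_single_peptide_rejected(self, wt_monomer):
        top, xyz = wt_monomer
        with pytest.raises(ValueError, match="two peptides"):
            iie(top, TrajectoryFrame(0, 0.0, xyz))


class TestPiPi:
    def test_wt_type_counts(self, wt_system):
        top, frames, _ = wt_system
        pp = pipi_interactions(top, frames[:1])
        intra = [p for p in pp if p.intra]
        inter = [p for p in pp if not p.intra]
        assert len(intra) == 1 and intra[0].pair_type == "F4-F5"
        assert len(inter) == 3
        assert {p.pair_type for p in inter} == {"F4-F4", "F4-F5", "F5-F5"}

    def test_mutant_type_counts(self, mutant_system):
        top, frames, _ = mutant_system
        pp = pipi_interactions(top, frames[:1])
        intra = [p for p in pp if p.intra]
        inter = [p for p in pp if not p.intra]
        assert len(intra) == 6
        assert len(inter) == 10

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_type_counts_follow_combinatorics(self, k):
        # intra = C(k,2), inter = C(k+1,2) for k Phe per peptide
        seq = list("LVLVLVL")
        positions = [0, 3, 5, 6][:k]
        for i in positions:
            seq[i] = "F"
        seq = "".join(seq)
        s = AssemblyScript(events=[], duration_ps=20.0, sequence=seq, seed=0)
        top, frames, _ = generate(s)
        pp = pipi_interactions(top, frames[:1])
        n_intra = sum(p.intra for p in pp)
        n_inter = sum(not p.intra for p in pp)
        assert n_intra == k * (k - 1) // 2
        assert n_inter == (k + 1) * k // 2

    def test_no_rings_gives_empty_list(self):
        s = AssemblyScript(events=[], duration_ps=20.0, sequence="KLVALAE", seed=0)
        top, frames, _ = generate(s)
        assert pipi_interactions(top, frames[:1]) == []

    def test_weak_interactions_have_zero_population(self, wt_system):
        top, frames, _ = wt_system  # fully separated monomers
        pp = pipi_interactions(top, frames[:2])
        inter = [p for p in pp if not p.intra]
        for p in inter:
            assert p.population_pct(-1.0) == 0.0

    def test_population_monotone_in_threshold(self, sheet_trajectory):
        _, top, frames, _ = sheet_trajectory
        pp = pipi_interactions(top, frames[::10])
        for p in pp:
            pops = [p.population_pct(th) for th in (-0.01, -0.5, -1.0, -2.0)]
            assert all(a >= b for a, b in zip(pops, pops[1:]))

    def test_stacked_rings_populate(self):
        """Two face-to-face rings near LJ-contact distance score a strongly
        favourable energy, so the population at the default threshold is
        100% while a far-apart pair scores 0%."""
        pep, xyz = build_peptide("F", "coil")
        top_xyz = np.concatenate([xyz, xyz + np.array([0.0, 0.0, 0.9])])
        from oligostate.topology import PeptideTopology, Residue, SystemTopology

        peptides = []
        for p in range(2):
            shift = p * xyz.shape[0]
            res0 = pep.residues[0]
            res = Residue(res0.name, res0.atom_names, res0.elements,
                          res0.atom_indices + shift)
            pt = PeptideTopology([res])
            pt.backbone_index_map[0] = tuple(i + shift
                                             for i in pep.backbone_index_map[0])
            peptides.append(pt)
        top = SystemTopology(peptides, 2 * xyz.shape[0])
        ring_a = top.peptides[0].ring_atom_indices(0)
        ring_b = top.peptides[1].ring_atom_indices(0)
        coords = top_xyz.copy()
        # translate peptide B so its ring is stacked 0.19 nm above ring A
        offset = (coords[ring_a].mean(axis=0) + np.array([0.0, 0.0, 0.19])
                  - coords[ring_b].mean(axis=0))
        coords[xyz.shape[0]:] += offset
        params = AtomParameters(np.zeros(top.atom_count),
                                np.full(top.atom_count, 0.17),
                                np.full(top.atom_count, 0.11))
        pp = pipi_interactions(top, [TrajectoryFrame(0, 0.0, coords)], params)
        inter = [p for p in pp if not p.intra]
        assert len(inter) == 1
        assert inter[0].energies[0] < -1.0
        assert inter[0].population_pct(-1.0) == 100.0


class TestParameterIO:
    def test_round_trip(self, tmp_path, wt_system):
        top, _, _ = wt_system
        params = default_parameters(top)
        path = str(tmp_path / "params.tsv")
        write_parameters(params, path)
        back = read_parameters(path)
        np.testing.assert_allclose(back.charge_e, params.charge_e, atol=1e-6)
        np.testing.assert_allclose(back.sigma_nm, params.sigma_nm, atol=1e-6)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            AtomParameters(np.zeros(2), np.array([0.3, 0.0]), np.zeros(2))

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError, match="epsilon"):
            AtomParameters(np.zeros(2), np.full(2, 0.3), np.array([0.1, -0.1]))
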