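"""Generator contracts: backbone construction, placement, scripted assembly."""

import numpy as np
import pytest

from oligostate.metrics import min_distance
from oligostate.oligomers import detect_oligomers
from oligostate.secondary import measure_dihedrals
from oligostate.synthetic import (
    AssemblyScript,
    BackboneSpec,
    CONFORMER_DIHEDRALS,
    Event,
    build_backbone,
    build_peptide,
    canonical_script,
    generate,
    place_initial,
    tetrahedron_vertices,
)
from oligostate.topology import SystemTopology, TrajectoryFrame


def _measure(pep, xyz):
    top = SystemTopology([pep], xyz.shape[0])
    return measure_dihedrals(top, TrajectoryFrame(0, 0.0, xyz), 0)


class TestBuildBackbone:
    @pytest.mark.parametrize("phi,psi", [(-139.0, 135.0), (-57.0, -47.0),
                                         (-75.0, 145.0), (-100.0, 60.0)])
    def test_requested_dihedrals_are_realized(self, phi, psi):
        pep, xyz = build_backbone("KLVFFAE", BackboneSpec.uniform(7, phi, psi))
        prof = _measure(pep, xyz)
        np.testing.assert_allclose(prof.phi[1:], phi, atol=1e-3)
        np.testing.assert_allclose(prof.psi[:-1], psi, atol=1e-3)

    def test_two_residue_chain_has_no_complete_pair(self):
        pep, xyz = build_backbone("KL", BackboneSpec.uniform(2, -139.0, 135.0))
        prof = _measure(pep, xyz)
        # phi undefined at residue 0, psi undefined at residue 1: no residue
        # carries a complete (phi, psi) pair
        assert not any(prof.defined(i) for i in range(2))

    def test_alpha_helix_geometry(self):
        # i,i+4 CA-CA distance of an ideal alpha helix is about 0.62 nm
        pep, xyz = build_peptide("KLVFFAE", "helix")
        ca = xyz[pep.ca_indices()]
        d = [np.linalg.norm(ca[i + 4] - ca[i]) for i in range(3)]
        np.testing.assert_allclose(d, 0.62, atol=0.05)

    def test_beta_strand_rise(self):
        pep, xyz = build_peptide("KLVFFAE", "beta")
        ca = xyz[pep.ca_indices()]
        e2e = np.linalg.norm(ca[-1] - ca[0])
        assert abs(e2e - 2.1) / 2.1 < 0.10  # ~0.35 nm rise per residue

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_backbone("", BackboneSpec.uniform(0, -139.0, 135.0))

    def test_nonfinite_angles_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            build_backbone("KL", BackboneSpec(phi_deg=(float("nan"), -139.0),
                                              psi_deg=(135.0, 135.0)))

    def test_phe_gets_hexagonal_ring(self):
        pep, xyz = build_peptide("KLVFFAE", "beta")
        for pos in pep.phe_positions():
            ring = xyz[pep.ring_atom_indices(pos)]
            assert ring.shape == (6, 3)
            center = ring.mean(axis=0)
            # regular hexagon: all sites at one circumradius (= edge)
            np.testing.assert_allclose(
                np.linalg.norm(ring - center, axis=1), 0.139, atol=1e-9
            )
            ca = xyz[pep.backbone_index_map[pos][1]]
            np.testing.assert_allclose(np.linalg.norm(center - ca), 0.35, atol=1e-9)


class TestPlaceInitial:
    def test_tetrahedron_centroid_distances(self):
        pep, xyz = build_peptide("KLVFFAE", "coil")
        coords, min_d = place_initial([xyz.copy() for _ in range(4)], 3.5)
        n = xyz.shape[0]
        centers = [coords[p * n:(p + 1) * n].mean(axis=0) for p in range(4)]
        dists = [np.linalg.norm(centers[i] - centers[j])
                 for i in range(4) for j in range(i + 1, 4)]
        np.testing.assert_allclose(dists, 3.5, atol=1e-9)
        assert min_d > 2.0  # minimum inter-peptide atom distance

    def test_min_distance_matches_brute_force(self):
        pep, xyz = build_peptide("KLVFFAE", "helix")
        coords, min_d = place_initial([xyz.copy() for _ in range(4)], 10.0)
        n = xyz.shape[0]
        groups = [coords[p * n:(p + 1) * n] for p in range(4)]
        brute = min(
            np.linalg.norm(a - b)
            for i in range(4) for j in range(i + 1, 4)
            for a in groups[i] for b in groups[j]
        )
        assert min_d == pytest.approx(brute, abs=1e-12)
        assert min_d > 8.0

    def test_zero_edge_rejected(self):
        pep, xyz = build_peptide("KLVFFAE", "coil")
        with pytest.raises(ValueError):
            place_initial([xyz.copy() for _ in range(4)], 0.0)

    def test_wrong_count_rejected(self):
        pep, xyz = build_peptide("KLVFFAE", "coil")
        with pytest.raises(ValueError, match="4 peptides"):
            place_initial([xyz.copy() for _ in range(3)], 3.5)


class TestScriptValidation:
    def test_dissociate_unassociated_pair_rejected(self):
        s = AssemblyScript(events=[Event(10.0, "dissociate", 0, 1)],
                           duration_ps=100.0)
        with pytest.raises(ValueError, match="never associated"):
            s.validate()

    def test_registry_requires_beta(self):
        s = AssemblyScript(
            events=[Event(5.0, "associate", 0, 1),
                    Event(10.0, "set_registry", 0, 1, value="parallel")],
            duration_ps=100.0,
        )
        with pytest.raises(ValueError, match="beta"):
            s.validate()

    def test_event_outside_duration_rejected(self):
        s = AssemblyScript(events=[Event(500.0, "associate", 0, 1)],
                           duration_ps=100.0)
        with pytest.raises(ValueError, match="outside"):
            s.validate()

    def test_self_association_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            Event(5.0, "associate", 1, 1)


class TestGenerate:
    def test_frame_cadence_and_count(self):
        s = AssemblyScript(events=[], duration_ps=1000.0, save_interval_ps=10.0)
        _, frames, labels = generate(s)
        assert len(frames) == 100
        assert frames[-1].time_ps == 990.0
        assert labels.n_frames == 100

    def test_empty_script_keeps_four_monomers(self):
        s = AssemblyScript(events=[], duration_ps=1000.0)
        _, frames, labels = generate(s)
        assert all(lab == "I" for lab in labels.state_labels)
        assert len({tuple(row) for row in labels.components}) == 1

    def test_association_docks_below_quarter_nanometre(self):
        s = AssemblyScript(events=[Event(50.0, "associate", 0, 1)],
                          duration_ps=100.0)
        top, frames, _ = generate(s)
        fr = frames[-1]
        d = min_distance(fr.coordinates[top.peptide_atom_indices(0)],
                         fr.coordinates[top.peptide_atom_indices(1)])
        assert d <= 0.25
        assert d > 0.05

    def test_beta_pair_at_requested_ca_spacing(self, sheet_trajectory):
        _, top, frames, _ = sheet_trajectory
        fr = frames[-1]
        ca0 = fr.coordinates[top.peptides[0].ca_indices()]
        ca1 = fr.coordinates[top.peptides[1].ca_indices()]
        # antiparallel neighbours: aligned residue-wise distance ~ spacing
        mean_aligned = np.mean(np.linalg.norm(ca0 - ca1[::-1], axis=1))
        assert 0.45 < mean_aligned < 0.55
        d = min_distance(fr.coordinates[top.peptide_atom_indices(0)],
                         fr.coordinates[top.peptide_atom_indices(1)])
        assert d <= 0.25

    def test_same_seed_bit_identical(self):
        s1 = canonical_script(200.0, 700.0, 1500.0, noise_sigma_nm=0.02, seed=7, duration_ps=2000.0)
        s2 = canonical_script(200.0, 700.0, 1500.0, noise_sigma_nm=0.02, seed=7, duration_ps=2000.0)
        _, f1, _ = generate(s1)
        _, f2, _ = generate(s2)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_different_seed_same_labels_different_noise(self):
        s1 = canonical_script(200.0, 700.0, 1500.0, noise_sigma_nm=0.02, seed=7, duration_ps=2000.0)
        s2 = canonical_script(200.0, 700.0, 1500.0, noise_sigma_nm=0.02, seed=8, duration_ps=2000.0)
        _, f1, l1 = generate(s1)
        _, f2, l2 = generate(s2)
        assert l1.state_labels == l2.state_labels
        np.testing.assert_array_equal(l1.components, l2.components)
        assert not np.array_equal(f1[-1].coordinates, f2[-1].coordinates)

    def test_scripted_sizes_reach_2_3_4_at_event_times(self, stepwise_trajectory):
        script, _, _, labels = stepwise_trajectory
        sizes = labels.largest_sizes()
        dt = script.save_interval_ps
        for size, t in [(2, 2000.0), (3, 7000.0), (4, 18000.0)]:
            first = np.nonzero(sizes >= size)[0][0] * dt
            assert first == t

    def test_noise_recovery_degrades_monotonically(self):
        recov = []
        for sigma in (0.0, 0.02, 0.15, 0.4):
            s = canonical_script(200.0, 700.0, 1800.0, noise_sigma_nm=sigma,
                                 seed=5, duration_ps=3000.0)
            top, frames, labels = generate(s)
            ok = 0
            for f, fr in enumerate(frames):
                part = detect_oligomers(top, fr)
                gt = {}
                for p, c in enumerate(labels.components[f]):
                    gt.setdefault(c, []).append(p)
                ok += {frozenset(v) for v in gt.values()} == \
                      {frozenset(c) for c in part.components}
            recov.append(ok / len(frames))
        assert recov[0] == 1.0
        assert recov[1] >= 0.99
        assert all(a >= b for a, b in zip(recov, recov[1:]))

    def test_dihedral_recovery_on_noiseless_frames(self, sheet_trajectory):
        _, top, frames, labels = sheet_trajectory
        fr = frames[-1]
        for p in range(4):
            prof = measure_dihedrals(top, fr, p)
            phi, psi = CONFORMER_DIHEDRALS["beta"]
            np.testing.assert_allclose(prof.phi[1:], phi, atol=1e-3)
            np.testing.assert_allclose(prof.psi[:-1], psi, atol=1e-3)


class TestTetrahedron:
    def test_vertices_equidistant(self):
        v = tetrahedron_vertices(3.5)
        d = [np.linalg.norm(v[i] - v[j]) for i in range(4) for j in range(i + 1, 4)]
        np.testing.assert_allclose(d, 3.5, atol=1e-12)
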