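"""Shared fixtures: built peptide systems and small scripted trajectories."""

import numpy as np
import pytest

from oligostate.synthetic import (
    AssemblyScript,
    Event,
    build_peptide,
    canonical_script,
    generate,
)
from oligostate.topology import SystemTopology, TrajectoryFrame

WT_SEQUENCE = "KLVFFAE"
MUTANT_SEQUENCE = "FLVFFAF"


@pytest.fixture(scope="session")
def wt_monomer():
    """Single wild-type peptide, β conformer, canonical orientation."""
    pep, xyz = build_peptide(WT_SEQUENCE, "beta")
    top = SystemTopology(peptides=[pep], atom_count=xyz.shape[0])
    return top, xyz


@pytest.fixture(scope="session")
def wt_system():
    """Four wild-type peptides, all-coil, initial tetrahedral frame."""
    script = AssemblyScript(events=[], duration_ps=50.0, noise_sigma_nm=0.0,
                            seed=0, sequence=WT_SEQUENCE)
    top, frames, labels = generate(script)
    return top, frames, labels


@pytest.fixture(scope="session")
def mutant_system():
    script = AssemblyScript(events=[], duration_ps=20.0, noise_sigma_nm=0.0,
                            seed=0, sequence=MUTANT_SEQUENCE)
    top, frames, labels = generate(script)
    return top, frames, labels


@pytest.fixture(scope="session")
def stepwise_trajectory():
    """Noiseless canonical stepwise assembly (dimer 2 ns, trimer 7 ns,
    tetramer 18 ns; 10 ps cadence, 30 ns)."""
    script = canonical_script(noise_sigma_nm=0.0, seed=1)
    top, frames, labels = generate(script)
    return script, top, frames, labels


@pytest.fixture(scope="session")
def sheet_trajectory():
    """Short trajectory ending in an all-antiparallel tetramer sheet."""
    events = [
        Event(100.0, "set_conformation", 0, value="beta"),
        Event(100.0, "set_conformation", 1, value="beta"),
        Event(100.0, "set_conformation", 2, value="beta"),
        Event(100.0, "set_conformation", 3, value="beta"),
        Event(200.0, "associate", 0, 1),
        Event(200.0, "set_registry", 0, 1, value="antiparallel"),
        Event(300.0, "associate", 1, 2),
        Event(300.0, "set_registry", 1, 2, value="antiparallel"),
        Event(400.0, "associate", 2, 3),
        Event(400.0, "set_registry", 2, 3, value="antiparallel"),
    ]
    script = AssemblyScript(events=events, duration_ps=500.0,
                            noise_sigma_nm=0.0, seed=2)
    top, frames, labels = generate(script)
    return script, top, frames, labels


def random_point_frame(rng, n_peptides=4, atoms_per_peptide=8, box_nm=3.0):
    """A SystemTopology + frame of random point clouds (one 'residue' per
    peptide), for geometric oracle tests."""
    from oligostate.topology import PeptideTopology, Residue

    peptides = []
    coords = []
    idx = 0
    for p in range(n_peptides):
        atom_idx = np.arange(idx, idx + atoms_per_peptide)
        idx += atoms_per_peptide
        res = Residue(name="UNK",
                      atom_names=tuple(f"X{i}" for i in range(atoms_per_peptide)),
                      elements=("C",) * atoms_per_peptide,
                      atom_indices=atom_idx)
        peptides.append(PeptideTopology(residues=[res]))
        center = rng.uniform(0, box_nm, size=3)
        coords.append(center + rng.normal(0, 0.3, size=(atoms_per_peptide, 3)))
    top = SystemTopology(peptides=peptides, atom_count=idx)
    frame = TrajectoryFrame(0, 0.0, np.concatenate(coords))
    return top, frame
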