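"""Domain types for peptide systems and trajectories.

The analysis operates on small multi-peptide systems (canonically four
heptapeptides such as Aβ16–22, sequence KLVFFAE, optionally capped with
ACE/NME).  Coordinates are stored in nanometres throughout; file readers
convert from Ångström where the on-disk format requires it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Residue",
    "PeptideTopology",
    "SystemTopology",
    "TrajectoryFrame",
    "AnalysisWindow",
    "GroundTruthLabels",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "CAP_RESIDUES",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: residue names treated as terminal capping groups (kept as atoms,
#: excluded from residue-level indexing)
CAP_RESIDUES = frozenset({"ACE", "NME", "NHE"})


class TopologyError(ValueError):
    """Raised for malformed or inconsistent topology input."""


@dataclass(frozen=True)
class Residue:
    """One residue: a named group of atoms with global atom indices."""

    name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    atom_indices: np.ndarray  # global, into the system coordinate array
    is_cap: bool = False

    def __post_init__(self) -> None:
        if len(self.atom_names) != len(self.atom_indices):
            raise TopologyError(
                f"residue {self.name}: {len(self.atom_names)} atom names vs "
                f"{len(self.atom_indices)} indices"
            )


@dataclass
class PeptideTopology:
    """A single peptide chain.

    ``residues`` includes capping groups; ``backbone_index_map`` maps each
    *non-cap* residue position to the global indices of its N, CA, C atoms
    and is required for dihedral-based analyses.
    """

    residues: list[Residue]
    backbone_index_map: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def noncap_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_cap]

    @property
    def n_residues(self) -> int:
        """Number of residues excluding caps."""
        return len(self.noncap_residues)

    @property
    def sequence(self) -> str:
        out = []
        for r in self.noncap_residues:
            if len(r.name) == 1:
                out.append(r.name)
            else:
                out.append(THREE_TO_ONE.get(r.name.upper(), "X"))
        return "".join(out)

    @property
    def atom_indices(self) -> np.ndarray:
        if not self.residues:
            return np.empty(0, dtype=int)
        return np.concatenate([r.atom_indices for r in self.residues])

    def ca_indices(self) -> np.ndarray:
        """Global CA indices for the non-cap residues, in sequence order."""
        return np.array(
            [self.backbone_index_map[i][1] for i in range(self.n_residues)],
            dtype=int,
        )

    def phe_positions(self) -> list[int]:
        """0-based non-cap residue positions holding phenylalanine."""
        return [
            i for i, r in enumerate(self.noncap_residues)
            if r.name.upper() in ("PHE", "F")
        ]

    def ring_atom_indices(self, residue_pos: int) -> np.ndarray:
        """Global indices of the aromatic-ring atoms of a Phe residue."""
        res = self.noncap_residues[residue_pos]
        ring_names = {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}
        mask = [name in ring_names for name in res.atom_names]
        idx = res.atom_indices[np.asarray(mask, bool)]
        if idx.size == 0:
            raise TopologyError(
                f"residue {res.name}@{residue_pos} has no aromatic ring atoms"
            )
        return idx


@dataclass
class SystemTopology:
    """All peptides of one simulation system."""

    peptides: list[PeptideTopology]
    atom_count: int
    parameter_set: object | None = None  # AtomParameters, resolved lazily

    def __post_init__(self) -> None:
        if not self.peptides:
            raise TopologyError("topology contains zero peptides")
        seen = np.zeros(self.atom_count, dtype=bool)
        for p, pep in enumerate(self.peptides):
            idx = pep.atom_indices
            if idx.size and (idx.min() < 0 or idx.max() >= self.atom_count):
                raise TopologyError(f"peptide {p}: atom index out of range")
            if seen[idx].any():
                raise TopologyError(f"peptide {p}: atom assigned to two peptides")
            seen[idx] = True
        if not seen.all():
            raise TopologyError("some atoms belong to no peptide")

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def peptide_atom_indices(self, p: int) -> np.ndarray:
        return self.peptides[p].atom_indices

    def atom_names(self) -> list[str]:
        names = [""] * self.atom_count
        for pep in self.peptides:
            for res in pep.residues:
                for name, i in zip(res.atom_names, res.atom_indices):
                    names[int(i)] = name
        return names

    def elements(self) -> list[str]:
        elems = [""] * self.atom_count
        for pep in self.peptides:
            for res in pep.residues:
                for el, i in zip(res.elements, res.atom_indices):
                    elems[int(i)] = el
        return elems


@dataclass(frozen=True)
class TrajectoryFrame:
    """One snapshot: per-atom coordinates (nm) at a time point (ps)."""

    frame_index: int
    time_ps: float
    coordinates: np.ndarray  # (n_atoms, 3), nm

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"coordinates must be (n, 3); got {c.shape}")
        object.__setattr__(self, "coordinates", c)

    def check(self, topology: SystemTopology) -> None:
        if self.coordinates.shape[0] != topology.atom_count:
            raise ValueError(
                f"frame {self.frame_index}: {self.coordinates.shape[0]} atoms, "
                f"topology has {topology.atom_count}"
            )


@dataclass(frozen=True)
class AnalysisWindow:
    """Inclusive frame range used for window-averaged statistics."""

    first_frame: int
    last_frame: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.first_frame > self.last_frame:
            raise ValueError(
                f"window first_frame {self.first_frame} > last_frame {self.last_frame}"
            )
        if self.first_frame < 0:
            raise ValueError("window first_frame must be >= 0")

    def validate(self, n_frames: int) -> None:
        if self.last_frame >= n_frames:
            raise ValueError(
                f"window [{self.first_frame}, {self.last_frame}] exceeds "
                f"trajectory length {n_frames}"
            )

    def slice(self) -> slice:
        return slice(self.first_frame, self.last_frame + 1)

    def n_frames(self) -> int:
        return self.last_frame - self.first_frame + 1


@dataclass
class GroundTruthLabels:
    """Scripted per-frame ground truth accompanying a synthetic trajectory.

    components[f][p] is the oligomer (cluster) id of peptide p at frame f;
    conformations[f][p] in {"coil", "beta", "helix"}; state_labels[f] is the
    scripted I..X oligomerization-state label; sheet_classes[f] the sheet
    class of the largest sheet ("-" when none); orientations[f][p] the strand
    sign (+1/-1, 0 for non-beta peptides) used for registry bookkeeping.
    """

    components: np.ndarray        # (n_frames, n_peptides) int
    conformations: list[list[str]]
    state_labels: list[str]
    sheet_classes: list[str]
    orientations: np.ndarray      # (n_frames, n_peptides) int
    time_ps: np.ndarray           # (n_frames,)

    def __post_init__(self) -> None:
        n = len(self.state_labels)
        for name, obj in [
            ("components", self.components),
            ("conformations", self.conformations),
            ("sheet_classes", self.sheet_classes),
            ("orientations", self.orientations),
            ("time_ps", self.time_ps),
        ]:
            if len(obj) != n:
                raise ValueError(f"labels field {name} has length {len(obj)} != {n}")

    @property
    def n_frames(self) -> int:
        return len(self.state_labels)

    def largest_sizes(self) -> np.ndarray:
        out = np.empty(self.n_frames, dtype=int)
        for f in range(self.n_frames):
            _, counts = np.unique(self.components[f], return_counts=True)
            out[f] = counts.max()
        return out


def iter_frames(frames: Sequence[TrajectoryFrame]) -> Iterator[TrajectoryFrame]:
    yield from frames
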