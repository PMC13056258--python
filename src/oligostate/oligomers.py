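"""Oligomer detection, β-sheet topology, and the 10-state classifier.

Two peptides are "in contact" when their minimum atom–atom distance is
≤ 0.3 nm; oligomers are the connected components of the resulting contact
graph, which realizes the chained dimer→trimer→tetramer definitions (a
trimer is a dimer plus a third peptide in contact with either member, and
so on).  β-sheets are built from strand pairing: maximal runs of ≥ 2
consecutive β residues pair when their optimally aligned Cα distances
average ≤ 0.55 nm, with parallel/antiparallel orientation from the sign
of the dot product of the strand direction vectors.  Sheets of 2–4
peptides fall into eight classes (pBS2, apBS2, pBS3, apBS3, mBS3, pBS4,
apBS4, mBS4).  The per-frame system state (I–X) combines the largest
oligomer size with the number of sheet-participating peptides inside it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import min_distance
from .topology import SystemTopology, TrajectoryFrame

__all__ = [
    "OligomerPartition",
    "Strand",
    "SheetAssembly",
    "SystemState",
    "detect_oligomers",
    "detect_sheets",
    "classify_state",
    "state_label_for",
    "sheet_class_for",
    "STATE_LABELS",
    "SHEET_CLASSES",
    "enumerate_states",
    "enumerate_sheet_classes",
]

logger = logging.getLogger(__name__)

STATE_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")
SHEET_CLASSES = ("pBS2", "apBS2", "pBS3", "apBS3", "mBS3", "pBS4", "apBS4", "mBS4")


@dataclass
class OligomerPartition:
    """Connected-component decomposition of the peptide contact graph."""

    frame_index: int
    edges: list[tuple[int, int]]
    components: list[list[int]]

    @property
    def largest_size(self) -> int:
        return max(len(c) for c in self.components)

    def component_of(self) -> np.ndarray:
        n = sum(len(c) for c in self.components)
        out = np.empty(n, dtype=int)
        for cid, comp in enumerate(self.components):
            for p in comp:
                out[p] = cid
        return out

    def sizes_by_peptide(self) -> np.ndarray:
        n = sum(len(c) for c in self.components)
        out = np.empty(n, dtype=int)
        for comp in self.components:
            for p in comp:
                out[p] = len(comp)
        return out


@dataclass(frozen=True)
class Strand:
    """A maximal run of consecutive β residues within one peptide."""

    peptide: int
    first_residue: int
    last_residue: int  # inclusive

    @property
    def n_residues(self) -> int:
        return self.last_residue - self.first_residue + 1


@dataclass
class SheetAssembly:
    """Strand-pairing graph and per-sheet class assignment for one frame."""

    strands: list[Strand]
    pairing: list[tuple[int, int, float, str]]  # (strand_a, strand_b, mean CA dist, orientation)
    sheets: list[list[int]]  # connected strand-index sets, size >= 2
    sheet_classes: list[str]
    rejected_pairs: list[tuple[int, int]] = field(default_factory=list)

    def peptides_in_sheets(self) -> set[int]:
        out: set[int] = set()
        for sheet in self.sheets:
            for s in sheet:
                out.add(self.strands[s].peptide)
        return out

    def sheet_peptides(self, sheet_idx: int) -> set[int]:
        return {self.strands[s].peptide for s in self.sheets[sheet_idx]}


@dataclass(frozen=True)
class SystemState:
    """The I–X oligomerization-state label of one frame."""

    label: str
    largest_size: int
    n_sheet_peptides: int


def detect_oligomers(
    topology: SystemTopology, frame: TrajectoryFrame, cutoff_nm: float = 0.3
) -> OligomerPartition:
    """Contact-graph connected components at the given atom-distance cutoff."""
    n = topology.n_peptides
    groups = [frame.coordinates[topology.peptide_atom_indices(p)] for p in range(n)]
    edges: list[tuple[int, int]] = []
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if min_distance(groups[i], groups[j]) <= cutoff_nm:
                edges.append((i, j))
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, list[int]] = {}
    for p in range(n):
        comps.setdefault(find(p), []).append(p)
    components = [sorted(c) for c in sorted(comps.values(), key=lambda c: c[0])]
    return OligomerPartition(frame.frame_index, edges, components)


def _strands_from_labels(ss_labels: list[list[str]], min_len: int = 2) -> list[Strand]:
    strands = []
    for p, labels in enumerate(ss_labels):
        start = None
        for i, lab in enumerate(labels + ["_"]):
            if lab == "beta":
                if start is None:
                    start = i
            else:
                if start is not None and i - start >= min_len:
                    strands.append(Strand(p, start, i - 1))
                start = None
    return strands


def _pair_strands(
    ca_a: np.ndarray, ca_b: np.ndarray, cutoff_nm: float
) -> tuple[float, str] | None:
    """Best mean aligned Cα distance over register shifts −2..+2 and both
    senses of alignment; returns (mean distance, orientation) or None."""
    dir_a = ca_a[-1] - ca_a[0]
    dir_b = ca_b[-1] - ca_b[0]
    na = np.linalg.norm(dir_a)
    nb = np.linalg.norm(dir_b)
    if na < 1e-9 or nb < 1e-9:
        return None
    cosang = float(np.dot(dir_a, dir_b) / (na * nb))
    if abs(cosang) < 0.1:
        return None  # near-perpendicular: no defined registry
    orientation = "parallel" if cosang > 0 else "antiparallel"
    cb = ca_b if orientation == "parallel" else ca_b[::-1]
    best = np.inf
    for shift in range(-2, 3):
        dists = []
        for ia in range(len(ca_a)):
            ib = ia + shift
            if 0 <= ib < len(cb):
                dists.append(np.linalg.norm(ca_a[ia] - cb[ib]))
        if len(dists) >= 2:
            best = min(best, float(np.mean(dists)))
    if best <= cutoff_nm:
        return best, orientation
    return None


def detect_sheets(
    topology: SystemTopology,
    frame: TrajectoryFrame,
    ss_labels: list[list[str]],
    pair_cutoff_nm: float = 0.55,
) -> SheetAssembly:
    """Strand pairing and sheet classification for one frame.

    ``ss_labels[p][i]`` is the secondary-structure label of residue i of
    peptide p ("beta"/"helix"/"turn"/"coil").
    """
    strands = _strands_from_labels(ss_labels)
    pairing: list[tuple[int, int, float, str]] = []
    rejected: list[tuple[int, int]] = []
    cas = []
    for s in strands:
        ca_idx = topology.peptides[s.peptide].ca_indices()[
            s.first_residue:s.last_residue + 1
        ]
        cas.append(frame.coordinates[ca_idx])

    for a, b in itertools.combinations(range(len(strands)), 2):
        if strands[a].peptide == strands[b].peptide:
            continue
        dir_ok = _pair_strands(cas[a], cas[b], pair_cutoff_nm)
        if dir_ok is None:
            # distinguish rejection cause for the log only
            da = cas[a][-1] - cas[a][0]
            db = cas[b][-1] - cas[b][0]
            denom = np.linalg.norm(da) * np.linalg.norm(db)
            if denom > 0 and abs(float(np.dot(da, db)) / denom) < 0.1:
                rejected.append((a, b))
                logger.debug(
                    "strand pair (%d, %d) rejected: near-perpendicular", a, b
                )
            continue
        mean_d, orientation = dir_ok
        pairing.append((a, b, mean_d, orientation))

    # sheets: connected components of the pairing graph
    parent = list(range(len(strands)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _, _ in pairing:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for s in range(len(strands)):
        groups.setdefault(find(s), []).append(s)
    sheets = [sorted(g) for g in groups.values() if len(g) >= 2]
    sheets.sort(key=lambda g: g[0])

    classes = []
    for sheet in sheets:
        members = set(sheet)
        orientations = {o for a, b, _, o in pairing if a in members and b in members}
        n_pep = len({strands[s].peptide for s in sheet})
        classes.append(sheet_class_for(n_pep, orientations))
    return SheetAssembly(strands=strands, pairing=pairing, sheets=sheets,
                         sheet_classes=classes, rejected_pairs=rejected)


def sheet_class_for(n_peptides: int, orientations: set[str]) -> str:
    """Class name from sheet size and the mix of pairing orientations."""
    if n_peptides < 2 or n_peptides > 4:
        raise ValueError(f"sheet of {n_peptides} peptides has no class")
    if not orientations:
        raise ValueError("sheet with no oriented pairings")
    if len(orientations) > 1:
        if n_peptides == 2:
            raise ValueError("a two-strand sheet cannot be mixed")
        prefix = "m"
    else:
        prefix = "p" if "parallel" in orientations else "ap"
    return f"{prefix}BS{n_peptides}"


def state_label_for(largest_size: int, n_sheet_peptides: int) -> str:
    """Map (largest oligomer size, sheet-participating peptides) to I–X.

    A lone β-conformation peptide is not a sheet, so the "no sheet"
    states (II, IV, VII) absorb sheet counts of 0 or 1.
    """
    if largest_size == 1:
        return "I"
    if largest_size == 2:
        return "II" if n_sheet_peptides < 2 else "III"
    if largest_size == 3:
        return {0: "IV", 1: "IV", 2: "V", 3: "VI"}[min(n_sheet_peptides, 3)]
    if largest_size == 4:
        return {0: "VII", 1: "VII", 2: "VIII", 3: "IX", 4: "X"}[min(n_sheet_peptides, 4)]
    raise ValueError(f"unsupported oligomer size {largest_size}")


def classify_state(partition: OligomerPartition, sheets: SheetAssembly) -> SystemState:
    """Per-frame I–X label; sheet peptides counted inside the largest oligomer.

    When several components tie for largest, the most sheet-rich one
    defines the state (the taxonomy is about the oligomer achieved).
    """
    largest = partition.largest_size
    sheet_peps = sheets.peptides_in_sheets()
    n_sheet = 0
    for comp in partition.components:
        if len(comp) == largest:
            n_sheet = max(n_sheet, len(sheet_peps & set(comp)))
    return SystemState(
        label=state_label_for(largest, n_sheet),
        largest_size=largest,
        n_sheet_peptides=n_sheet,
    )


def enumerate_states() -> list[tuple[int, int, str]]:
    """All admissible (largest size, sheet-peptide count) pairs with labels.

    Sheet participation requires pairing, so a size-s oligomer admits
    sheet counts {0, 2, 3, …, s}; a count of exactly 1 is geometrically
    impossible.  The enumeration yields exactly ten distinct labels.
    """
    out = []
    for size in (1, 2, 3, 4):
        for n_sheet in range(size + 1):
            if n_sheet == 1:
                continue  # a single strand is not a sheet
            out.append((size, n_sheet, state_label_for(size, n_sheet)))
    return out


def enumerate_sheet_classes() -> list[str]:
    """All achievable sheet classes (size 2–4 × orientation mixes)."""
    out = []
    for n_pep in (2, 3, 4):
        mixes = [{"parallel"}, {"antiparallel"}]
        if n_pep > 2:
            mixes.append({"parallel", "antiparallel"})
        for mix in mixes:
            out.append(sheet_class_for(n_pep, mix))
    return out
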