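"""Readers and writers for topologies, trajectories, labels, and run config.

Formats
-------
* topology: PDB (coordinates in Å on disk, converted to nm in memory),
  peptides delimited by chain identifier with a TER-record fallback;
* coordinates: multi-frame XYZ (text; the comment line carries the frame
  time as ``t= <ps> ps``; coordinates in nm) or binary DCD (Å, read via
  mdtraj when installed);
* ground-truth labels: tab-separated table, one row per (frame, peptide);
* run configuration: YAML mapping with strict key validation.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
import yaml

from .topology import (
    CAP_RESIDUES,
    GroundTruthLabels,
    PeptideTopology,
    Residue,
    SystemTopology,
    TopologyError,
    TrajectoryFrame,
)

__all__ = [
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_labels",
    "write_labels",
    "RunConfig",
    "load_config",
    "ConfigError",
    "n_frames_for",
    "BOLTZMANN_KCAL",
]

#: Boltzmann constant in kcal mol^-1 K^-1
BOLTZMANN_KCAL = 0.0019872

_BACKBONE = ("N", "CA", "C")


# ---------------------------------------------------------------------------
# PDB topology
# ---------------------------------------------------------------------------

def _element_for(atom_name: str) -> str:
    name = atom_name.strip()
    for el in ("CL", "NA"):  # two-letter ions, unlikely here but harmless
        if name.upper() == el:
            return el.capitalize()
    return name[0].upper() if name else "X"


def _build_peptide(res_groups: list[tuple[str, list[tuple[str, str, int]]]]) -> PeptideTopology:
    """res_groups: list of (res_name, [(atom_name, element, global_index)])."""
    residues: list[Residue] = []
    for res_name, atoms in res_groups:
        is_cap = res_name.upper() in CAP_RESIDUES
        residues.append(
            Residue(
                name=res_name,
                atom_names=tuple(a for a, _, _ in atoms),
                elements=tuple(e for _, e, _ in atoms),
                atom_indices=np.array([i for _, _, i in atoms], dtype=int),
                is_cap=is_cap,
            )
        )
    pep = PeptideTopology(residues=residues)
    for pos, res in enumerate(pep.noncap_residues):
        found = {}
        for name, idx in zip(res.atom_names, res.atom_indices):
            if name in _BACKBONE:
                found[name] = int(idx)
        if len(found) == 3:
            pep.backbone_index_map[pos] = (found["N"], found["CA"], found["C"])
        elif len(found) >= 2:
            missing = sorted(set(_BACKBONE) - set(found))
            raise TopologyError(
                f"residue {res.name} (position {pos}) is missing backbone "
                f"atom(s) {missing}"
            )
        # zero or one backbone atom: residue is usable for distances only
    return pep


def read_topology(path: str) -> tuple[SystemTopology, np.ndarray]:
    """Read a PDB file into a :class:`SystemTopology` plus coordinates (nm).

    Peptides are delimited by chain identifier; if the file uses a single
    (or blank) chain id, TER records are used instead.  Residues named ACE
    or NME are flagged as caps and excluded from residue-level indexing.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)

    # line-level parse: biotite's PDBFile does not expose TER placement,
    # which we need for the chain-delimitation fallback
    atoms: list[tuple[str, str, str, int, float, float, float, bool]] = []
    # (atom_name, res_name, chain_id, res_seq, x, y, z, after_ter_break)
    pending_break = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "TER":
                pending_break = True
            elif rec in ("ATOM", "HETATM"):
                atom_name = line[12:16].strip()
                res_name = line[17:20].strip()
                chain_id = line[21:22].strip()
                res_seq = int(line[22:26])
                x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
                atoms.append(
                    (atom_name, res_name, chain_id, res_seq, x, y, z, pending_break)
                )
                pending_break = False
    if not atoms:
        raise TopologyError(f"{path}: no ATOM records (zero peptides)")

    chain_ids = {a[2] for a in atoms}
    use_chains = len(chain_ids) > 1

    # split into peptides
    peptide_atoms: list[list[tuple[str, str, str, int, float, float, float, bool]]] = []
    current: list = []
    for a in atoms:
        boundary = False
        if current:
            if use_chains:
                boundary = a[2] != current[-1][2]
            else:
                boundary = a[7]  # follows a TER record
        if boundary:
            peptide_atoms.append(current)
            current = []
        current.append(a)
    if current:
        peptide_atoms.append(current)

    coords = np.array([[a[4], a[5], a[6]] for a in atoms], dtype=float) / 10.0  # Å→nm

    peptides: list[PeptideTopology] = []
    gidx = 0
    for chain in peptide_atoms:
        res_groups: list[tuple[str, list[tuple[str, str, int]]]] = []
        last_key = None
        for a in chain:
            key = (a[3], a[1])  # res_seq, res_name
            if key != last_key:
                res_groups.append((a[1], []))
                last_key = key
            res_groups[-1][1].append((a[0], _element_for(a[0]), gidx))
            gidx += 1
        peptides.append(_build_peptide(res_groups))

    top = SystemTopology(peptides=peptides, atom_count=len(atoms))
    return top, coords


def write_topology(topology: SystemTopology, coordinates_nm: np.ndarray, path: str) -> None:
    """Write a single-model PDB (Å) with one chain per peptide and TER records."""
    coords = np.asarray(coordinates_nm, dtype=float) * 10.0  # nm→Å
    if coords.shape != (topology.atom_count, 3):
        raise ValueError(
            f"coordinates shape {coords.shape} != ({topology.atom_count}, 3)"
        )
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    lines: list[str] = []
    serial = 1
    for p, pep in enumerate(topology.peptides):
        chain = chain_letters[p % len(chain_letters)]
        res_seq = 0
        for res in pep.residues:
            res_seq += 1
            rname = res.name if len(res.name) > 1 else _one_to_three_safe(res.name)
            for name, el, i in zip(res.atom_names, res.elements, res.atom_indices):
                x, y, z = coords[int(i)]
                aligned = f" {name:<3s}" if len(name) < 4 else name[:4]
                lines.append(
                    f"ATOM  {serial:>5d} {aligned}{'':1s}{rname:>3s} {chain}"
                    f"{res_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}      {rname:>3s} {chain}{res_seq:>4d}")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _one_to_three_safe(code: str) -> str:
    from .topology import ONE_TO_THREE

    return ONE_TO_THREE.get(code.upper(), "UNK")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory(frames: list[TrajectoryFrame], path: str) -> None:
    """Write frames as multi-frame XYZ (nm; comment line ``t= <ps> ps``)."""
    with open(path, "w") as fh:
        for fr in frames:
            n = fr.coordinates.shape[0]
            fh.write(f"{n}\n")
            fh.write(f"t= {fr.time_ps:.4f} ps\n")
            for x, y, z in fr.coordinates:
                fh.write(f"X {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory(
    topology: SystemTopology, path: str, save_interval_ps: float = 10.0
) -> list[TrajectoryFrame]:
    """Read a multi-frame XYZ or DCD coordinate series.

    Times are assigned as ``frame_index * save_interval_ps`` (uniform
    cadence is required by downstream kinetics).  XYZ coordinates are in
    nm per this package's dialect; DCD files are in Å and converted.
    """
    if path.endswith(".dcd"):
        return _read_dcd(topology, path, save_interval_ps)
    frames: list[TrajectoryFrame] = []
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header.strip():
                if header == "" or not header.strip():
                    break
            try:
                n = int(header.strip())
            except ValueError as exc:
                raise ValueError(f"frame {idx}: bad atom-count line {header!r}") from exc
            if n != topology.atom_count:
                raise ValueError(
                    f"frame {idx}: atom count {n} != topology {topology.atom_count}"
                )
            fh.readline()  # comment / time line (informational)
            rows = np.empty((n, 3), dtype=float)
            for i in range(n):
                line = fh.readline()
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"frame {idx}: truncated at atom {i}")
                rows[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            frames.append(
                TrajectoryFrame(frame_index=idx, time_ps=idx * save_interval_ps,
                                coordinates=rows)
            )
            idx += 1
    return frames


def _read_dcd(
    topology: SystemTopology, path: str, save_interval_ps: float
) -> list[TrajectoryFrame]:
    try:
        from mdtraj.formats import DCDTrajectoryFile
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading DCD requires mdtraj") from exc
    with DCDTrajectoryFile(path) as fh:
        xyz, _, _ = fh.read()
    xyz = np.asarray(xyz, dtype=float) / 10.0  # Å→nm
    frames = []
    for idx, coords in enumerate(xyz):
        if coords.shape[0] != topology.atom_count:
            raise ValueError(
                f"frame {idx}: atom count {coords.shape[0]} != "
                f"topology {topology.atom_count}"
            )
        frames.append(TrajectoryFrame(idx, idx * save_interval_ps, coords))
    return frames


def n_frames_for(duration_ps: float, save_interval_ps: float) -> int:
    """Number of saved snapshots for a run of ``duration_ps`` at fixed cadence.

    Matches the convention of saving one snapshot per interval (a 500 ns run
    saved every 10 ps yields 50,000 snapshots; times run 0 .. (n-1)*dt).
    """
    if save_interval_ps <= 0:
        raise ValueError("save_interval_ps must be positive")
    n = int(round(duration_ps / save_interval_ps))
    if n <= 0:
        raise ValueError("duration shorter than one save interval")
    return n


# ---------------------------------------------------------------------------
# ground-truth labels
# ---------------------------------------------------------------------------

def write_labels(labels: GroundTruthLabels, path: str) -> None:
    cols = "frame\ttime_ps\tpeptide_id\tcomponent\tconformation\torientation\tstate_label\tsheet_class"
    with open(path, "w") as fh:
        fh.write(cols + "\n")
        n_pep = labels.components.shape[1]
        for f in range(labels.n_frames):
            for p in range(n_pep):
                fh.write(
                    f"{f}\t{labels.time_ps[f]:.4f}\t{p}\t{labels.components[f, p]}"
                    f"\t{labels.conformations[f][p]}\t{labels.orientations[f, p]}"
                    f"\t{labels.state_labels[f]}\t{labels.sheet_classes[f]}\n"
                )


def read_labels(path: str) -> GroundTruthLabels:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    n_frames = df["frame"].nunique()
    n_pep = df["peptide_id"].nunique()
    df = df.sort_values(["frame", "peptide_id"])
    components = df["component"].to_numpy().reshape(n_frames, n_pep)
    orientations = df["orientation"].to_numpy().reshape(n_frames, n_pep)
    conf = df["conformation"].astype(str).to_numpy().reshape(n_frames, n_pep)
    per_frame = df.drop_duplicates("frame")
    return GroundTruthLabels(
        components=components.astype(int),
        conformations=[list(row) for row in conf],
        state_labels=per_frame["state_label"].astype(str).tolist(),
        sheet_classes=per_frame["sheet_class"].astype(str).tolist(),
        orientations=orientations.astype(int),
        time_ps=per_frame["time_ps"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with field defaults.

    Distances in nm, energies in kcal/mol, temperature in K.
    """

    temperature_K: float = 310.0
    peptide_contact_cutoff_nm: float = 0.3
    residue_contact_cutoff_nm: float = 0.45
    pipi_threshold_kcal: float = -1.0
    sheet_pair_cutoff_nm: float = 0.55
    energy_cutoff_nm: float | None = None
    sasa_probe_nm: float = 0.14
    sasa_n_points: int = 960
    fel_bin_width_nm: float = 0.1
    save_interval_ps: float = 10.0
    mass_weighted_centroids: bool = False

    @property
    def kBT(self) -> float:
        """Thermal energy kB*T in kcal/mol."""
        return BOLTZMANN_KCAL * self.temperature_K

    def validate(self) -> None:
        bad: list[str] = []
        if self.temperature_K <= 0:
            bad.append("temperature_K")
        for key in (
            "peptide_contact_cutoff_nm",
            "residue_contact_cutoff_nm",
            "sheet_pair_cutoff_nm",
            "sasa_probe_nm",
            "fel_bin_width_nm",
            "save_interval_ps",
        ):
            if getattr(self, key) is not None and getattr(self, key) <= 0:
                bad.append(key)
        if self.energy_cutoff_nm is not None and self.energy_cutoff_nm <= 0:
            bad.append("energy_cutoff_nm")
        if self.sasa_n_points < 32:
            bad.append("sasa_n_points")
        if bad:
            raise ConfigError(f"invalid configuration value(s) for: {', '.join(bad)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path: str | None = None) -> RunConfig:
    """Load a YAML run configuration; missing keys take defaults.

    Unknown keys are rejected so typos cannot silently fall back to a
    default threshold.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        data = raw
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
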