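"""On-disk representations used throughout the pipeline.

Cα-resolution structures travel as PDB ATOM records (read and written through
biotite); metadynamics hills and collective-variable trajectories use small
whitespace-delimited dialects with ``#`` comments; tabular results are
tab-separated with a header.  Every reader validates the type invariants and
rejects malformed records with a line-numbered error instead of coercing.

Units: coordinates in Å, energies in kcal/mol, times in ps.  Residue
numbering is 1-based.  A missing chain id defaults to ``'A'``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class FormatError(ValueError):
    """Raised when an on-disk record violates the format or a type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Structure:
    """Cα-only structure with per-residue domain labels.

    Attributes
    ----------
    residue_index : (N,) int array, 1-based, strictly increasing per chain
    residue_name : (N,) array of 3-letter codes
    chain_id : (N,) array of single characters
    domain_label : (N,) array of string tags (e.g. ``"CC1a1"`` / ``"CAD"``)
    positions : (N, 3) float array, Å
    """

    residue_index: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    domain_label: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.residue_index)
        if self.positions.shape != (n, 3):
            raise FormatError(f"positions shape {self.positions.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("non-finite coordinates")
        for cid in np.unique(self.chain_id):
            idx = self.residue_index[self.chain_id == cid]
            if np.any(np.diff(idx) <= 0):
                raise FormatError(
                    f"residue indices not strictly increasing in chain {cid!r}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.residue_index)

    def atom_indices(self, residues) -> np.ndarray:
        """Positional indices of the given 1-based residue numbers."""
        residues = np.atleast_1d(np.asarray(residues))
        mask = np.isin(self.residue_index, residues)
        return np.flatnonzero(mask)

    def domain_residues(self, label: str) -> np.ndarray:
        return self.residue_index[self.domain_label == label]

    def with_positions(self, positions: np.ndarray) -> "Structure":
        return replace(self, positions=np.asarray(positions, float))


@dataclass(frozen=True)
class Trajectory:
    """Ordered coordinate frames congruent with a :class:`Structure`."""

    structure: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    dt: float  # ps
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[1] != self.structure.n_atoms:
            raise FormatError(
                f"frames shape {self.frames.shape} incongruent with "
                f"{self.structure.n_atoms}-atom structure"
            )
        if not self.dt > 0:
            raise FormatError("dt must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True)
class HillsSeries:
    """Deposited metadynamics Gaussians (well-tempered heights).

    Columns: deposition step, center in the distance CV (Å), center in the
    contact CV, widths (σ) in both dimensions, and the already-tempered
    height in kcal/mol.
    """

    step: np.ndarray
    center_d: np.ndarray
    center_nc: np.ndarray
    width_d: np.ndarray
    width_nc: np.ndarray
    height: np.ndarray

    def __post_init__(self) -> None:
        if len(self.step) and np.any(np.diff(self.step) <= 0):
            raise FormatError("hill steps not strictly increasing")
        if np.any(self.width_d <= 0) or np.any(self.width_nc <= 0):
            raise FormatError("hill widths must be > 0")
        if np.any(self.height <= 0):
            raise FormatError("hill heights must be > 0")

    def __len__(self) -> int:
        return len(self.step)


@dataclass(frozen=True)
class CVTrajectory:
    """Time series of the two collective variables, optionally weighted."""

    time: np.ndarray  # ps
    d_com: np.ndarray  # Å
    n_contacts: np.ndarray
    weights: np.ndarray | None = None  # normalized, optional

    def __post_init__(self) -> None:
        if len(self.time) > 1 and np.any(np.diff(self.time) <= 0):
            raise FormatError("CV trajectory times not strictly increasing")
        if np.any(self.d_com <= 0):
            raise FormatError("d_com must be > 0")
        if np.any(self.n_contacts < 0):
            raise FormatError("n_contacts must be >= 0")
        if self.weights is not None:
            if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
                raise FormatError("weights must be non-negative and sum to 1")

    def __len__(self) -> int:
        return len(self.time)


# ---------------------------------------------------------------------------
# structures (PDB)
# ---------------------------------------------------------------------------

def read_structure(path, domain_map: dict[str, str] | None = None) -> Structure:
    """Read the Cα atoms of a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path : str or Path
        PDB-format text file.
    domain_map : dict, optional
        Maps domain labels to 1-based residue ranges given as ``"start-end"``
        strings (e.g. ``{"CC1a1": "235-270", "CAD": "350-435"}``).  Residues
        outside every range get the label ``""``.

    Raises
    ------
    FormatError
        On a malformed ATOM line (named by line number) or when the file
        contains no Cα atoms.
    """
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:  # locate the offending line for the error message
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                        int(line[22:26])
                    except (ValueError, IndexError):
                        raise FormatError(
                            f"{path}: malformed ATOM line {lineno}: {line.rstrip()!r}"
                        ) from exc
        raise FormatError(f"{path}: unreadable PDB file: {exc}") from exc

    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise FormatError(f"{path}: no Cα atoms")

    chain = np.asarray(ca.chain_id, dtype="U4")
    chain[chain == ""] = "A"
    labels = _labels_from_map(ca.res_id, domain_map)
    return Structure(
        residue_index=np.asarray(ca.res_id, int),
        residue_name=np.asarray(ca.res_name, dtype="U3"),
        chain_id=chain,
        domain_label=labels,
        positions=np.asarray(ca.coord, float),
    )


def parse_residue_range(spec) -> np.ndarray:
    """Expand ``"start-end"`` (or an iterable of ints) to residue numbers."""
    if isinstance(spec, str):
        lo, hi = (int(x) for x in spec.split("-"))
        if hi < lo:
            raise FormatError(f"bad residue range {spec!r}")
        return np.arange(lo, hi + 1)
    return np.asarray(list(spec), int)


def _labels_from_map(res_id, domain_map) -> np.ndarray:
    labels = np.full(len(res_id), "", dtype="U32")
    if domain_map:
        for label, rng in domain_map.items():
            labels[np.isin(res_id, parse_residue_range(rng))] = label
    return labels


def write_structure(structure: Structure, path) -> None:
    """Write a Cα-only Structure as PDB ATOM records."""
    arr = struc.AtomArray(structure.n_atoms)
    arr.coord = np.asarray(structure.positions, float)
    arr.chain_id = structure.chain_id
    arr.res_id = structure.residue_index
    arr.res_name = structure.residue_name
    arr.atom_name = np.full(structure.n_atoms, "CA")
    arr.element = np.full(structure.n_atoms, "C")
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-MODEL PDB file."""
    arr = struc.AtomArrayStack(traj.n_frames, traj.structure.n_atoms)
    arr.coord = np.asarray(traj.frames, float)
    arr.chain_id = traj.structure.chain_id
    arr.res_id = traj.structure.residue_index
    arr.res_name = traj.structure.residue_name
    arr.atom_name = np.full(traj.structure.n_atoms, "CA")
    arr.element = np.full(traj.structure.n_atoms, "C")
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_trajectory(path, structure_or_map=None, dt: float = 1.0) -> Trajectory:
    """Read a multi-MODEL PDB file into a :class:`Trajectory`.

    ``structure_or_map`` may be a :class:`Structure` (atom congruence is taken
    from it) or a domain map applied to the file's own first model.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    ca = stack[..., stack.atom_name == "CA"]
    if ca.array_length() == 0:
        raise FormatError(f"{path}: no Cα atoms")
    if isinstance(structure_or_map, Structure):
        structure = structure_or_map
    else:
        chain = np.asarray(ca.chain_id, dtype="U4")
        chain[chain == ""] = "A"
        structure = Structure(
            residue_index=np.asarray(ca.res_id, int),
            residue_name=np.asarray(ca.res_name, dtype="U3"),
            chain_id=chain,
            domain_label=_labels_from_map(ca.res_id, structure_or_map),
            positions=np.asarray(ca.coord[0], float),
        )
    return Trajectory(structure=structure, frames=np.asarray(ca.coord, float), dt=dt)


# ---------------------------------------------------------------------------
# hills and CV-trajectory dialects
# ---------------------------------------------------------------------------

_HILLS_COLS = ("step", "center_d", "center_nc", "width_d", "width_nc", "height")


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_hills(path) -> HillsSeries:
    """Read a hills file: columns step, center_d, center_nc, σ_d, σ_n, height."""
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 6:
            raise FormatError(
                f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
            )
        try:
            rows.append([float(x) for x in fields])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric field in {line!r}") from None
    data = np.asarray(rows, float).reshape(-1, 6)
    return HillsSeries(
        step=data[:, 0].astype(int),
        center_d=data[:, 1], center_nc=data[:, 2],
        width_d=data[:, 3], width_nc=data[:, 4], height=data[:, 5],
    )


def write_hills(hills: HillsSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + " ".join(_HILLS_COLS) + "\n")
        for k in range(len(hills)):
            fh.write(
                f"{hills.step[k]:d} {hills.center_d[k]:.9g} {hills.center_nc[k]:.9g} "
                f"{hills.width_d[k]:.9g} {hills.width_nc[k]:.9g} {hills.height[k]:.9g}\n"
            )


def read_cv_traj(path) -> CVTrajectory:
    """Read a CV trajectory: columns time (ps), d_com (Å), n_contacts[, weight]."""
    rows = []
    ncol = None
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) not in (3, 4):
            raise FormatError(
                f"{path}:{lineno}: expected 3 or 4 columns, got {len(fields)}"
            )
        if ncol is None:
            ncol = len(fields)
        elif len(fields) != ncol:
            raise FormatError(f"{path}:{lineno}: inconsistent column count")
        try:
            rows.append([float(x) for x in fields])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric field in {line!r}") from None
    data = np.asarray(rows, float).reshape(-1, ncol or 3)
    if len(data) and np.any(np.diff(data[:, 0]) == 0):
        raise FormatError(f"{path}: duplicate times in CV trajectory")
    return CVTrajectory(
        time=data[:, 0], d_com=data[:, 1], n_contacts=data[:, 2],
        weights=data[:, 3] if (ncol == 4) else None,
    )


def write_cv_traj(cv: CVTrajectory, path) -> None:
    cols = "time_ps d_com_A n_contacts" + (" weight" if cv.weights is not None else "")
    with open(path, "w") as fh:
        fh.write(f"# {cols}\n")
        for k in range(len(cv)):
            row = f"{cv.time[k]:.9g} {cv.d_com[k]:.12g} {cv.n_contacts[k]:.12g}"
            if cv.weights is not None:
                row += f" {cv.weights[k]:.12g}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# tables and JSON reports
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path) -> None:
    """Write a results table as TSV with header."""
    frame.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json_report(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
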