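"""Structure and trajectory I/O.

Reading goes through MDAnalysis (single- and multi-model PDB, and DCD/XTC
with a PDB topology); everything downstream sees a uniform labelled-
coordinate view (:class:`LabeledStructure`, :class:`Trajectory`).  All
outputs are single- or multi-model PDB written with a fixed-column emitter
so that reruns are byte-identical.

Atom ordering is never permuted by any operation in this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import (
    AtomCountMismatchError,
    EmptyTrajectoryError,
    FrameIndexError,
    LigandNotFoundError,
    StructureParseError,
)

logger = logging.getLogger(__name__)

#: Standard atomic weights (u) for the elements that occur in protein/ligand
#: PDB files.  Used for residue centre-of-mass weighting; deterministic
#: regardless of what the reader guessed.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}

#: Residue names treated as amino acids (standard 20 plus common
#: protonation/disulfide variants).
AMINO_ACIDS: frozenset[str] = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX", "ASH", "GLH", "LYN",
})

BACKBONE_NAMES: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

_TWO_LETTER = frozenset({"CL", "BR", "FE", "ZN", "MG", "NA", "SE", "MN",
                         "CU", "CO", "NI"})


def guess_element(atom_name: str, resname: str) -> str:
    """Best-effort element symbol for files without an element column."""
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    if not stripped:
        raise StructureParseError(f"cannot infer element for atom {atom_name!r}")
    if resname.upper() not in AMINO_ACIDS and stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    return stripped[0]


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError as exc:
        raise StructureParseError(f"no mass tabulated for element {element!r}") from exc


@dataclass
class LabeledStructure:
    """Atoms with residue identity, role flags and (optionally) coordinates.

    All per-atom arrays share the same length and ordering; ``coords`` may be
    ``None`` when the structure serves purely as a topology.
    """

    chain: np.ndarray          # str per atom
    resid: np.ndarray          # int per atom (author numbering)
    resname: np.ndarray       # str per atom
    atom_name: np.ndarray     # str per atom
    element: np.ndarray       # str per atom
    mass: np.ndarray          # u, per atom
    is_hydrogen: np.ndarray   # bool per atom
    is_backbone: np.ndarray   # bool per atom
    is_ligand: np.ndarray     # bool per atom
    coords: np.ndarray | None = None  # (n_atoms, 3) Å
    ligand_resname: str | None = None
    source: str = ""
    _residue_keys: list[tuple[str, int, str]] = field(default=None, repr=False)  # type: ignore[assignment]
    _residue_atoms: dict[tuple[str, int, str], np.ndarray] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        for arr in (self.chain, self.resid, self.resname, self.element,
                    self.mass, self.is_hydrogen, self.is_backbone, self.is_ligand):
            if len(arr) != n:
                raise StructureParseError("per-atom arrays have inconsistent lengths")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise StructureParseError("coords must be (n_atoms, 3)")
            if not np.all(np.isfinite(self.coords)):
                raise StructureParseError("non-finite coordinates")
        keys: list[tuple[str, int, str]] = []
        atoms: dict[tuple[str, int, str], list[int]] = {}
        for i in range(n):
            key = (str(self.chain[i]), int(self.resid[i]), str(self.resname[i]))
            if key not in atoms:
                atoms[key] = []
                keys.append(key)
            atoms[key].append(i)
        object.__setattr__(self, "_residue_keys", keys)
        object.__setattr__(
            self, "_residue_atoms",
            {k: np.asarray(v, dtype=int) for k, v in atoms.items()},
        )

    # -- basic views -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Residue keys ``(chain, resid, resname)`` in file order."""
        return list(self._residue_keys)

    def residue_atom_indices(self, key: tuple[str, int, str]) -> np.ndarray:
        return self._residue_atoms[key]

    @property
    def is_protein(self) -> np.ndarray:
        return np.isin(self.resname, list(AMINO_ACIDS)) & ~self.is_ligand

    @property
    def heavy(self) -> np.ndarray:
        return ~self.is_hydrogen

    def ligand_atom_indices(self, heavy_only: bool = True) -> np.ndarray:
        mask = self.is_ligand
        if heavy_only:
            mask = mask & self.heavy
        return np.flatnonzero(mask)

    def with_coords(self, coords: np.ndarray) -> "LabeledStructure":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class Trajectory:
    """A topology plus one coordinate set per frame (Å)."""

    topology: LabeledStructure
    frames: np.ndarray                 # (F, n_atoms, 3)
    frame_interval: float | None = None  # ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureParseError("frames must be (F, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise EmptyTrajectoryError("trajectory has zero frames")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise AtomCountMismatchError(
                f"topology has {self.topology.n_atoms} atoms but frames have "
                f"{self.frames.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, index: int) -> LabeledStructure:
        if not 0 <= index < self.n_frames:
            raise FrameIndexError(f"frame index {index} out of range 0..{self.n_frames - 1}")
        return self.topology.with_coords(self.frames[index])


# ---------------------------------------------------------------------------
# Reading (MDAnalysis)
# ---------------------------------------------------------------------------

def _universe(*paths: str):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(*paths)
        except Exception as exc:  # noqa: BLE001 - normalise reader errors
            msg = str(exc)
            if "atoms" in msg.lower() and ("match" in msg.lower() or "mismatch" in msg.lower()):
                raise AtomCountMismatchError(msg) from exc
            raise StructureParseError(f"cannot parse {paths}: {exc}") from exc


def _labeled_from_universe(u, ligand_resname: str | None, source: str) -> LabeledStructure:
    atoms = u.atoms
    n = len(atoms)
    if n == 0:
        raise StructureParseError(f"{source}: no atoms")

    names = np.asarray([a.name for a in atoms], dtype=object)
    resnames = np.asarray([a.resname for a in atoms], dtype=object)
    resids = np.asarray([a.resid for a in atoms], dtype=int)
    try:
        chains = np.asarray([c if c.strip() else "A" for c in atoms.chainIDs], dtype=object)
    except Exception:  # noqa: BLE001 - chainIDs absent on some topologies
        try:
            chains = np.asarray([s if s.strip() else "A" for s in atoms.segids], dtype=object)
        except Exception:  # noqa: BLE001
            chains = np.asarray(["A"] * n, dtype=object)

    try:
        elements = np.asarray(
            [e.upper() if e.strip() else guess_element(nm, rn)
             for e, nm, rn in zip(atoms.elements, names, resnames)],
            dtype=object,
        )
    except Exception:  # noqa: BLE001 - no element column
        elements = np.asarray(
            [guess_element(nm, rn) for nm, rn in zip(names, resnames)], dtype=object
        )

    masses = np.asarray([mass_of(e) for e in elements], dtype=float)
    is_h = np.asarray([e in ("H", "D") for e in elements], dtype=bool)
    is_lig = np.zeros(n, dtype=bool)
    if ligand_resname is not None:
        is_lig = np.asarray([rn == ligand_resname for rn in resnames], dtype=bool)
        if not is_lig.any():
            raise LigandNotFoundError(
                f"{source}: no residue named {ligand_resname!r}"
            )
    is_aa = np.asarray([rn in AMINO_ACIDS for rn in resnames], dtype=bool)
    is_bb = np.asarray([nm in BACKBONE_NAMES for nm in names], dtype=bool)
    is_bb = is_bb & is_aa & ~is_h & ~is_lig

    # keep the first altloc only: MDAnalysis exposes all altlocs as separate
    # atoms sharing (chain, resid, resname, name); drop every repeat
    keep = np.ones(n, dtype=bool)
    seen: set[tuple] = set()
    for i in range(n):
        ident = (chains[i], resids[i], resnames[i], names[i])
        if ident in seen:
            keep[i] = False
            logger.warning("dropping duplicate/altloc atom %s", ident)
        else:
            seen.add(ident)

    coords = atoms.positions.astype(float)
    sel = np.flatnonzero(keep)
    return LabeledStructure(
        chain=chains[sel], resid=resids[sel], resname=resnames[sel],
        atom_name=names[sel], element=elements[sel], mass=masses[sel],
        is_hydrogen=is_h[sel], is_backbone=is_bb[sel], is_ligand=is_lig[sel],
        coords=coords[sel], ligand_resname=ligand_resname, source=source,
    )


def read_structure(path: str | Path, ligand_residue_name: str | None = None) -> LabeledStructure:
    """Read a single-model PDB into a :class:`LabeledStructure`.

    Parameters
    ----------
    path:
        PDB file; for multi-model files the first model is used.
    ligand_residue_name:
        Residue name identifying ligand atoms.  If given and no atom
        matches, :class:`LigandNotFoundError` is raised.
    """
    u = _universe(str(path))
    return _labeled_from_universe(u, ligand_residue_name, source=str(path))


def read_trajectory(
    topology_path: str | Path,
    traj_path: str | Path | None = None,
    ligand_residue_name: str | None = None,
) -> Trajectory:
    """Read a trajectory (multi-model PDB, or PDB topology + DCD/XTC).

    Frames are returned in file order; an atom-count mismatch between
    topology and trajectory raises :class:`AtomCountMismatchError`.
    """
    if traj_path is None:
        u = _universe(str(topology_path))
    else:
        u = _universe(str(topology_path), str(traj_path))
    topo = _labeled_from_universe(u, ligand_residue_name, source=str(topology_path))
    if topo.n_atoms != len(u.atoms):
        raise StructureParseError(
            "altloc filtering changed the atom count; trajectories with "
            "alternate locations are not supported"
        )
    n_frames = len(u.trajectory)
    if n_frames < 1:
        raise EmptyTrajectoryError(f"{topology_path}: zero frames")
    frames = np.empty((n_frames, topo.n_atoms, 3), dtype=float)
    for i, _ts in enumerate(u.trajectory):
        frames[i] = u.atoms.positions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDB readers guess dt and warn
        dt = getattr(u.trajectory, "dt", None)
    topo_no_coords = replace(topo, coords=None)
    return Trajectory(topology=topo_no_coords, frames=frames,
                      frame_interval=float(dt) if dt else None)


# ---------------------------------------------------------------------------
# Writing (fixed-column PDB emitter)
# ---------------------------------------------------------------------------

def _atom_line(serial: int, name: str, resname: str, chain: str,
               resid: int, xyz: np.ndarray, element: str) -> str:
    if len(name) < 4:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"ATOM  {serial:5d} {name_field}{'':1s}{resname:<4s}{chain[:1]}{resid:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{element:>2s}\n"
    )


def write_pdb(
    path: str | Path,
    structure: LabeledStructure,
    frames: np.ndarray | None = None,
    remarks: Sequence[str] = (),
) -> Path:
    """Write a single- or multi-model PDB preserving atom order."""
    path = Path(path)
    if frames is None:
        if structure.coords is None:
            raise StructureParseError("structure has no coordinates to write")
        frames = structure.coords[None, :, :]
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    multi = frames.shape[0] > 1
    with path.open("w") as fh:
        for rem in remarks:
            fh.write(f"REMARK   1 {rem}\n")
        for m, coords in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(structure.n_atoms):
                fh.write(_atom_line(
                    (i % 99999) + 1, str(structure.atom_name[i]),
                    str(structure.resname[i]), str(structure.chain[i]),
                    int(structure.resid[i]), coords[i], str(structure.element[i]),
                ))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def write_representatives(
    traj: Trajectory,
    frame_indices: Sequence[int],
    out_dir: str | Path,
) -> list[Path]:
    """Write one single-model PDB per representative frame.

    Files are named ``representative_<cluster>.pdb`` in the order given
    (index position = cluster label); each records its source frame index
    in a REMARK.  Out-of-range indices raise :class:`FrameIndexError`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for idx in frame_indices:
        if not 0 <= int(idx) < traj.n_frames:
            raise FrameIndexError(
                f"frame index {idx} out of range 0..{traj.n_frames - 1}"
            )
    paths = []
    for label, idx in enumerate(frame_indices):
        p = out_dir / f"representative_{label:02d}.pdb"
        write_pdb(
            p, traj.topology, frames=traj.frames[int(idx)],
            remarks=[f"CLUSTER {label} SOURCE FRAME {int(idx)}"],
        )
        paths.append(p)
    return paths
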