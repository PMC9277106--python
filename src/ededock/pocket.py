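"""Binding-pocket definition and featurization.

The pocket is defined once, on the static reference complex, as every
protein residue whose side chain comes within a cutoff (default 3 Å) of any
ligand heavy atom.  Each trajectory frame is then rigidly superposed onto
the reference over the Cα atoms of a configurable residue range (the rigid
core, e.g. the 7TM bundle of a GPCR), and the mass-weighted centre of mass
of each pocket residue is collected, giving one 3m-dimensional feature
vector per frame.

Distances are plain Euclidean with no periodic imaging: frames are assumed
whole.  Hydrogens are excluded from both the contact rule and the centres
of mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    AlignmentAtomsError,
    EmptyPocketError,
    LigandNotFoundError,
    MissingPocketResidueError,
)
from .io import LabeledStructure, Trajectory

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class PocketDefinition:
    """The residue set selected by the contact rule, plus its parameters."""

    residue_keys: tuple[ResidueKey, ...]
    contact_cutoff: float  # Å
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.residue_keys) == 0:
            raise EmptyPocketError("pocket has no residues")
        if len(set(self.residue_keys)) != len(self.residue_keys):
            raise ValueError("duplicate pocket residues")

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)


@dataclass
class FeatureMatrix:
    """Frames × (3m) matrix of pocket-residue centres of mass, Å."""

    values: np.ndarray
    residue_order: tuple[ResidueKey, ...]
    alignment_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3 * len(self.residue_order):
            raise ValueError("feature matrix must be F x (3 * n_residues)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def column_names(self) -> list[str]:
        return [
            f"{c}:{r}:{n}:{ax}"
            for (c, r, n) in self.residue_order
            for ax in ("x", "y", "z")
        ]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.values, columns=self.column_names).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        keys: list[ResidueKey] = []
        for col in df.columns[::3]:
            chain, resnum, resname, _ax = col.split(":")
            keys.append((chain, int(resnum), resname))
        return cls(values=df.to_numpy(float), residue_order=tuple(keys))


# ---------------------------------------------------------------------------
# Contact rule
# ---------------------------------------------------------------------------

def _contact_atom_indices(struct: LabeledStructure, key: ResidueKey) -> np.ndarray:
    """Side-chain heavy atoms of a residue; Cα substitutes for glycine."""
    idx = struct.residue_atom_indices(key)
    side = idx[~struct.is_backbone[idx] & struct.heavy[idx]]
    if side.size == 0:
        ca = idx[struct.atom_name[idx] == "CA"]
        if ca.size:
            logger.info("residue %s has no side-chain heavy atoms; using CA", key)
        return ca
    return side


def select_pocket(ref: LabeledStructure, cutoff: float = 3.0) -> PocketDefinition:
    """Select pocket residues by the side-chain/ligand contact rule.

    A residue is included iff the minimum distance between any of its
    side-chain heavy atoms and any ligand heavy atom is ≤ ``cutoff`` Å.
    """
    lig_idx = ref.ligand_atom_indices(heavy_only=True)
    if lig_idx.size == 0:
        raise LigandNotFoundError("reference structure has no ligand heavy atoms")
    lig_xyz = ref.coords[lig_idx]

    selected: list[ResidueKey] = []
    protein = ref.is_protein
    for key in ref.residue_keys:
        idx = ref.residue_atom_indices(key)
        if not protein[idx].any():
            continue
        contact_idx = _contact_atom_indices(ref, key)
        if contact_idx.size == 0:
            continue
        dmin = cdist(ref.coords[contact_idx], lig_xyz).min()
        if dmin <= cutoff:
            selected.append(key)
    if not selected:
        raise EmptyPocketError(
            f"no residue within {cutoff} Å of the ligand; try a larger cutoff"
        )
    selected.sort(key=lambda k: (k[0], k[1]))
    return PocketDefinition(tuple(selected), contact_cutoff=float(cutoff),
                            source=ref.source)


# ---------------------------------------------------------------------------
# Rigid superposition (Kabsch)
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with ``mobile @ R.T + t`` the fitted
    coordinates.  Proper rotation enforced (no reflection).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if P.shape[0] < 3:
        raise AlignmentAtomsError(f"need >= 3 alignment atoms, got {P.shape[0]}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(((fitted - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def _alignment_indices(
    struct: LabeledStructure, align_range: tuple[int, int] | None
) -> dict[tuple[str, int], int]:
    """Map (chain, resid) -> index of the residue's Cα atom."""
    out: dict[tuple[str, int], int] = {}
    for i in np.flatnonzero((struct.atom_name == "CA") & struct.is_protein):
        resid = int(struct.resid[i])
        if align_range is not None and not align_range[0] <= resid <= align_range[1]:
            continue
        out.setdefault((str(struct.chain[i]), resid), int(i))
    return out


def superpose(
    frame: np.ndarray,
    topology: LabeledStructure,
    ref: LabeledStructure,
    align_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, float, tuple[np.ndarray, np.ndarray]]:
    """Superpose a frame onto the reference over shared Cα atoms.

    The frame (coordinates over ``topology``) is moved; the reference
    defines the lab frame.  Returns the transformed full-atom coordinates,
    the post-fit Cα RMSD, and the rigid transform ``(R, t)``.
    """
    frame = np.asarray(frame, dtype=float)
    f_ca = _alignment_indices(topology, align_range)
    r_ca = _alignment_indices(ref, align_range)
    shared = sorted(set(f_ca) & set(r_ca))
    if len(shared) < 3:
        raise AlignmentAtomsError(
            f"only {len(shared)} shared C-alpha atoms in alignment range {align_range}"
        )
    P = frame[[f_ca[k] for k in shared]]
    Q = ref.coords[[r_ca[k] for k in shared]]
    R, t, rmsd = kabsch(P, Q)
    return frame @ R.T + t, rmsd, (R, t)


# ---------------------------------------------------------------------------
# Centre-of-mass features
# ---------------------------------------------------------------------------

def _com_indices(struct: LabeledStructure, key: ResidueKey, mode: str) -> np.ndarray:
    idx = struct.residue_atom_indices(key)
    if mode == "residue":
        sel = idx[struct.heavy[idx]]
    elif mode == "sidechain":
        sel = _contact_atom_indices(struct, key)
    else:
        raise ValueError(f"unknown COM mode {mode!r}")
    if sel.size == 0:
        raise MissingPocketResidueError(f"residue {key} has no heavy atoms")
    return sel


def residue_com(coords: np.ndarray, struct: LabeledStructure,
                key: ResidueKey, mode: str = "residue") -> np.ndarray:
    idx = _com_indices(struct, key, mode)
    w = struct.mass[idx]
    return (coords[idx] * w[:, None]).sum(axis=0) / w.sum()


def extract_features(
    traj: Trajectory,
    pocket: PocketDefinition,
    ref: LabeledStructure,
    align_range: tuple[int, int] | None = None,
    com_mode: str = "residue",
) -> FeatureMatrix:
    """Superpose every frame on the reference and collect pocket-residue COMs.

    Row f of the result holds the m concatenated (x, y, z) centre-of-mass
    triplets of the pocket residues in pocket order.
    """
    topo = traj.topology
    available = set(topo.residue_keys)
    for key in pocket.residue_keys:
        if key not in available:
            raise MissingPocketResidueError(
                f"pocket residue {key} not present in trajectory topology"
            )
    com_idx = [_com_indices(topo, key, com_mode) for key in pocket.residue_keys]
    weights = [topo.mass[idx] for idx in com_idx]

    F = traj.n_frames
    out = np.empty((F, 3 * pocket.n_residues), dtype=float)
    for f in range(F):
        fitted, _rmsd, _tr = superpose(traj.frames[f], topo, ref, align_range)
        for j, (idx, w) in enumerate(zip(com_idx, weights)):
            out[f, 3 * j:3 * j + 3] = (fitted[idx] * w[:, None]).sum(axis=0) / w.sum()
    return FeatureMatrix(out, residue_order=pocket.residue_keys,
                         alignment_range=align_range)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class PocketFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer: reference complex in, per-frame pocket COM features out.

    ``fit`` takes the static reference receptor–ligand complex (a
    :class:`~ededock.io.LabeledStructure` with ligand atoms flagged) and
    applies the contact rule; ``transform`` takes a
    :class:`~ededock.io.Trajectory` and returns the F × 3m feature matrix.

    Parameters
    ----------
    contact_cutoff : float, default 3.0
        Side-chain heavy-atom to ligand heavy-atom distance cutoff, Å.
    align_range : (int, int) or None, default None
        Inclusive author-numbering residue interval used for the Cα
        superposition; ``None`` aligns on the full chain.
    com_mode : {"residue", "sidechain"}, default "residue"
        Whether residue centres of mass use all heavy atoms or side-chain
        heavy atoms only.
    """

    def __init__(self, contact_cutoff: float = 3.0,
                 align_range: tuple[int, int] | None = None,
                 com_mode: str = "residue"):
        self.contact_cutoff = contact_cutoff
        self.align_range = align_range
        self.com_mode = com_mode

    def fit(self, X: LabeledStructure, y=None) -> "PocketFeaturizer":
        self.reference_ = X
        self.pocket_ = select_pocket(X, cutoff=self.contact_cutoff)
        self.n_features_out_ = 3 * self.pocket_.n_residues
        return self

    def transform(self, X: Trajectory) -> np.ndarray:
        return self.featurize(X).values

    def featurize(self, traj: Trajectory) -> FeatureMatrix:
        """Like :meth:`transform` but returns the labelled FeatureMatrix."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "pocket_")
        return extract_features(traj, self.pocket_, self.reference_,
                                align_range=self.align_range,
                                com_mode=self.com_mode)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "pocket_")
        names = [
            f"{c}:{r}:{n}:{ax}"
            for (c, r, n) in self.pocket_.residue_keys
            for ax in ("x", "y", "z")
        ]
        return np.asarray(names, dtype=object)
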