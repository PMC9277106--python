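"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: toy receptor–ligand
complexes with exactly-controlled contact distances, multi-state pocket
trajectories (Gaussian fluctuation around k distinct conformations with
specified populations, emulating a metastable binding pocket), and docking
score tables with specified per-conformation affinities and noise.  All
artifacts are written in the same formats the readers consume (PDB, CSV),
so the I/O paths are exercised identically to real data.

The generators make no attempt at force-field realism: bond geometry is
schematic, and pocket motion is isotropic Gaussian noise around rigid state
centres rather than correlated protein dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import InfeasibleGeometryError
from .io import LabeledStructure, Trajectory, mass_of, write_pdb
from .scoring import ScoreTable, ensemble_score, ThermalContext

import logging

logger = logging.getLogger(__name__)


@dataclass
class StateSpec:
    """One metastable pocket conformation of a synthetic trajectory."""

    state_id: int
    population: float
    pocket_com_centers: np.ndarray       # (m, 3) Å
    fluctuation_sigma: float = 0.25      # Å, isotropic
    true_dg_bind: np.ndarray | None = None  # per-compound, kcal/mol

    def __post_init__(self) -> None:
        self.pocket_com_centers = np.asarray(self.pocket_com_centers, dtype=float)
        if self.fluctuation_sigma < 0:
            raise ValueError("fluctuation_sigma must be non-negative")


def _check_states(states: list[StateSpec]) -> None:
    pops = np.array([s.population for s in states])
    if not np.isclose(pops.sum(), 1.0, atol=1e-9):
        raise ValueError("state populations must sum to 1")
    m = states[0].pocket_com_centers.shape[0]
    if any(s.pocket_com_centers.shape != (m, 3) for s in states):
        raise ValueError("all states must share the pocket residue count")


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _structure(chain, resid, resname, names, elements, coords,
               is_backbone, is_ligand, ligand_resname=None, source="synthetic"):
    n = len(names)
    elements = np.asarray(elements, dtype=object)
    return LabeledStructure(
        chain=np.asarray(chain, dtype=object),
        resid=np.asarray(resid, dtype=int),
        resname=np.asarray(resname, dtype=object),
        atom_name=np.asarray(names, dtype=object),
        element=elements,
        mass=np.asarray([mass_of(e) for e in elements], dtype=float),
        is_hydrogen=np.asarray([e in ("H", "D") for e in elements], dtype=bool),
        is_backbone=np.asarray(is_backbone, dtype=bool),
        is_ligand=np.asarray(is_ligand, dtype=bool),
        coords=np.asarray(coords, dtype=float) if coords is not None else None,
        ligand_resname=ligand_resname,
        source=source,
    )


# ---------------------------------------------------------------------------
# Toy complex with exact contact distances
# ---------------------------------------------------------------------------

def make_toy_complex(
    n_residues: int,
    ligand_atoms: int,
    contact_distances,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> LabeledStructure:
    """A fake peptide + ligand with exact side-chain–ligand distances.

    Residue j's single side-chain heavy atom (CB) is placed so that its
    minimum distance to any ligand heavy atom equals ``contact_distances[j]``
    exactly, enabling sharp pocket-selection tests.  Backbone atoms sit
    farther out and never enter the contact rule.
    """
    if n_residues < 1 or ligand_atoms < 1:
        raise InfeasibleGeometryError("need at least one residue and one ligand atom")
    dists = np.asarray(contact_distances, dtype=float)
    if dists.shape != (n_residues,):
        raise InfeasibleGeometryError("contact_distances must have one entry per residue")
    if np.any(dists <= 0):
        raise InfeasibleGeometryError("contact distances must be positive")

    rng = np.random.default_rng(seed)
    lig_xyz = rng.uniform(-1.0, 1.0, size=(ligand_atoms, 3))
    dirs = _fibonacci_directions(n_residues)

    chain, resid, resname, names, elements, coords = [], [], [], [], [], []
    is_bb, is_lig = [], []

    for j in range(n_residues):
        u = dirs[j]
        # anchor = ligand atom with max projection on u: for any other ligand
        # atom b, |CB−b| >= d, so the minimum contact distance is exactly d
        anchor = lig_xyz[int(np.argmax(lig_xyz @ u))]
        cb = anchor + dists[j] * u
        ca = anchor + (dists[j] + 1.53) * u
        perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        bb = {"N": ca + 1.46 * perp, "CA": ca,
              "C": ca - 1.52 * perp, "O": ca - 1.52 * perp + 1.23 * u}
        for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            chain.append("A"); resid.append(j + 1); resname.append("ALA")
            names.append(nm); elements.append(el); coords.append(bb[nm])
            is_bb.append(True); is_lig.append(False)
        chain.append("A"); resid.append(j + 1); resname.append("ALA")
        names.append("CB"); elements.append("C"); coords.append(cb)
        is_bb.append(False); is_lig.append(False)

    for a in range(ligand_atoms):
        chain.append("L"); resid.append(900); resname.append("LIG")
        names.append(f"C{a + 1}"); elements.append("C"); coords.append(lig_xyz[a])
        is_bb.append(False); is_lig.append(True)

    struct = _structure(chain, resid, resname, names, elements, coords,
                        is_bb, is_lig, ligand_resname="LIG")
    if out_path is not None:
        write_pdb(out_path, struct, remarks=["SYNTHETIC TOY COMPLEX"])
    return struct


# ---------------------------------------------------------------------------
# Multi-state trajectory
# ---------------------------------------------------------------------------

CORE_RESID_START = 101  # author numbering of the rigid alignment core


def _pocket_topology(m: int, n_core: int, seed: int):
    """Topology: m 2-atom pocket residues + a rigid n_core-residue CA core.

    Pocket residue j has atoms CA/CB (equal carbon masses) offset ±o/2 from
    the residue COM, so the whole-residue COM equals the sampled point
    exactly.  Core residues carry N/CA/C/O at fixed positions.
    """
    rng = np.random.default_rng(seed)
    offsets = rng.normal(size=(m, 3))
    offsets /= np.linalg.norm(offsets, axis=1, keepdims=True)
    offsets *= 0.77  # half a C–C bond

    chain, resid, resname, names, elements = [], [], [], [], []
    is_bb, is_lig = [], []
    for j in range(m):
        for nm, bb in (("CA", True), ("CB", False)):
            chain.append("A"); resid.append(j + 1); resname.append("ALA")
            names.append(nm); elements.append("C")
            is_bb.append(bb); is_lig.append(False)

    theta = 2 * np.pi * np.arange(n_core) / n_core
    core_xyz = []
    for t in range(n_core):
        ca = np.array([25.0 * np.cos(theta[t]), 25.0 * np.sin(theta[t]),
                       3.0 * np.sin(3 * theta[t])])
        for nm, el, off in (("N", "N", [-1.4, 0, 0]), ("CA", "C", [0, 0, 0]),
                            ("C", "C", [1.4, 0, 0]), ("O", "O", [1.4, 1.2, 0])):
            chain.append("A"); resid.append(CORE_RESID_START + t)
            resname.append("GLY"); names.append(nm); elements.append(el)
            is_bb.append(True); is_lig.append(False)
            core_xyz.append(ca + np.asarray(off, dtype=float))
    core_xyz = np.asarray(core_xyz)

    topo = _structure(chain, resid, resname, names, elements, None,
                      is_bb, is_lig)
    return topo, offsets, core_xyz


def _frame_coords(com: np.ndarray, offsets: np.ndarray,
                  core_xyz: np.ndarray) -> np.ndarray:
    m = com.shape[0]
    pocket = np.empty((2 * m, 3))
    pocket[0::2] = com - offsets / 2.0  # CA
    pocket[1::2] = com + offsets / 2.0  # CB
    return np.vstack([pocket, core_xyz])


def make_state_trajectory(
    states: list[StateSpec],
    n_frames: int,
    seed: int = 0,
    rigid_jitter: bool = False,
    n_core: int = 8,
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory hopping i.i.d. between metastable pocket states.

    Each frame's state is drawn from the state populations; the pocket
    residue COMs are the state centres plus isotropic Gaussian noise; a
    rigid alignment core is held fixed (and, with ``rigid_jitter``, the
    whole frame is additionally rotated/translated at random — motion the
    superposition stage must undo).  Returns the trajectory and the
    ground-truth state label per frame.
    """
    _check_states(states)
    if n_frames < len(states):
        raise ValueError("need at least one frame per state")
    m = states[0].pocket_com_centers.shape[0]
    topo, offsets, core_xyz = _pocket_topology(m, n_core, seed=seed + 1)

    rng = np.random.default_rng(seed)
    # separate stream so the pocket noise is identical with and without jitter
    jitter_rng = np.random.default_rng(seed + 90_001)
    pops = np.array([s.population for s in states])
    labels = rng.choice(len(states), size=n_frames, p=pops)
    frames = np.empty((n_frames, topo.n_atoms, 3))
    for f in range(n_frames):
        s = states[labels[f]]
        com = s.pocket_com_centers + rng.normal(
            scale=s.fluctuation_sigma, size=(m, 3))
        xyz = _frame_coords(com, offsets, core_xyz)
        if rigid_jitter:
            R = Rotation.random(rng=jitter_rng).as_matrix()
            t = jitter_rng.uniform(-10.0, 10.0, size=3)
            xyz = xyz @ R.T + t
        frames[f] = xyz
    return Trajectory(topology=topo, frames=frames), labels


def make_reference_complex(
    states: list[StateSpec], seed: int = 0, n_core: int = 8,
    contact_distance: float = 1.5,
) -> LabeledStructure:
    """Static reference complex matching a state trajectory's topology.

    The receptor adopts state 0's noiseless geometry; one ligand atom is
    placed ``contact_distance`` Å from each pocket residue's CB so that the
    3 Å contact rule selects exactly the pocket residues.
    """
    _check_states(states)
    m = states[0].pocket_com_centers.shape[0]
    topo, offsets, core_xyz = _pocket_topology(m, n_core, seed=seed + 1)
    xyz = _frame_coords(states[0].pocket_com_centers, offsets, core_xyz)

    pocket_center = states[0].pocket_com_centers.mean(axis=0)
    cb = xyz[1:2 * m:2]
    to_center = pocket_center - cb
    norms = np.linalg.norm(to_center, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    lig_xyz = cb + contact_distance * to_center / norms

    chain = list(topo.chain) + ["L"] * m
    resid = list(topo.resid) + [900] * m
    resname = list(topo.resname) + ["LIG"] * m
    names = list(topo.atom_name) + [f"C{a + 1}" for a in range(m)]
    elements = list(topo.element) + ["C"] * m
    is_bb = list(topo.is_backbone) + [False] * m
    is_lig = [False] * topo.n_atoms + [True] * m
    coords = np.vstack([xyz, lig_xyz])
    return _structure(chain, resid, resname, names, elements, coords,
                      is_bb, is_lig, ligand_resname="LIG")


# ---------------------------------------------------------------------------
# Docking-score tables
# ---------------------------------------------------------------------------

def make_score_table(
    states: list[StateSpec],
    n_compounds: int,
    noise_sigma: float = 0.25,
    missing_rate: float = 0.0,
    seed: int = 0,
    ctx: ThermalContext = ThermalContext(),
    affinity_range: tuple[float, float] = (-12.0, -4.0),
) -> tuple[ScoreTable, np.ndarray, np.ndarray]:
    """Noisy per-conformation docking scores with known ensemble truth.

    Returns ``(table, true_ensemble_scores, dg_conf)`` where the truth is
    computed from the noiseless affinities and the generative state
    populations.  Every compound keeps at least one observed score.
    """
    _check_states(states)
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_states = len(states)

    true = np.empty((n_compounds, n_states))
    for i, s in enumerate(states):
        if s.true_dg_bind is not None:
            if len(s.true_dg_bind) != n_compounds:
                raise ValueError("true_dg_bind length mismatch")
            true[:, i] = s.true_dg_bind
        else:
            true[:, i] = rng.uniform(*affinity_range, size=n_compounds)

    pops = np.array([s.population for s in states])
    dg_conf = -np.log(pops / pops.max())

    noisy = true + rng.normal(scale=noise_sigma, size=true.shape)
    if missing_rate > 0:
        mask = rng.random(size=true.shape) < missing_rate
        for c in range(n_compounds):
            while mask[c].all():  # a compound must keep >= 1 score
                logger.info("regenerating all-missing mask for compound %d", c)
                mask[c] = rng.random(size=n_states) < missing_rate
        noisy = noisy.copy()
        noisy[mask] = np.nan

    table = ScoreTable(
        compound_ids=[f"CPD{c:05d}" for c in range(n_compounds)],
        conformation_ids=[f"S{i}" for i in range(n_states)],
        dg_bind=noisy,
    )
    true_scores = np.array([
        ensemble_score(true[c], dg_conf, ctx)[0] for c in range(n_compounds)
    ])
    return table, true_scores, dg_conf


def make_activity_labels(
    compound_ids, true_scores, strong_cutoff: float = -10.0,
    medium_cutoff: float = -9.0,
) -> dict[str, str]:
    """Map true ensemble scores onto strong/medium/weak activity classes."""
    labels = {}
    for cid, s in zip(compound_ids, true_scores):
        if s <= strong_cutoff:
            labels[cid] = "strong"
        elif s <= medium_cutoff:
            labels[cid] = "medium"
        else:
            labels[cid] = "weak"
    return labels


# ---------------------------------------------------------------------------
# Documented preset: a 4-state, 12-residue pocket
# ---------------------------------------------------------------------------

@dataclass
class PresetBundle:
    states: list[StateSpec]
    reference: LabeledStructure
    trajectory: Trajectory
    state_labels: np.ndarray
    align_range: tuple[int, int]


def four_state_preset(
    seed: int = 0,
    n_frames: int = 5000,
    m_residues: int = 12,
    populations: tuple[float, ...] = (0.5, 0.3, 0.15, 0.05),
    sigma: float = 0.25,
    separation_sigmas: float = 20.0,
    rigid_jitter: bool = False,
) -> PresetBundle:
    """A GPCR-pocket-like fixture: 4 metastable states, 12 pocket residues.

    State centres are at least ``separation_sigmas`` fluctuation widths
    apart, so the states are unambiguous and clustering should recover the
    generative populations.
    """
    rng = np.random.default_rng(seed)
    base = _fibonacci_directions(m_residues) * 8.0
    scale = separation_sigmas * sigma
    states = []
    for i, p in enumerate(populations):
        delta = rng.normal(size=(m_residues, 3))
        delta /= np.linalg.norm(delta.ravel())
        centers = base + (0.0 if i == 0 else scale * delta * np.sqrt(m_residues))
        states.append(StateSpec(state_id=i, population=p,
                                pocket_com_centers=centers,
                                fluctuation_sigma=sigma))
    flat = np.array([s.pocket_com_centers.ravel() for s in states])
    d = np.linalg.norm(flat[:, None, :] - flat[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < separation_sigmas * sigma:
        raise InfeasibleGeometryError("state centres are too close; reseed")

    traj, labels = make_state_trajectory(states, n_frames, seed=seed,
                                         rigid_jitter=rigid_jitter)
    reference = make_reference_complex(states, seed=seed)
    n_core = 8
    return PresetBundle(
        states=states, reference=reference, trajectory=traj,
        state_labels=labels,
        align_range=(CORE_RESID_START, CORE_RESID_START + n_core - 1),
    )
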