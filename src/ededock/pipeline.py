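"""End-to-end pipeline: pocket → features → PCA → clusters → representatives
→ (optional) ensemble scoring → (optional) evaluation.

Every stage's output is persisted in plain text (PDB/CSV/YAML/JSON) so the
pipeline can be resumed at any seam — in particular between representative
selection and scoring, where docking happens in an external engine.  A run
manifest records the configuration, seed, package version, input checksums
and every file written; reruns with the same inputs and seed are
byte-identical (manifests carry no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterEnsemble, KMeansConformations, inertia_report, select_representatives
from .decomposition import EssentialDynamics, ProjectedTrajectory
from .exceptions import ConfigError, EdedError
from .io import read_structure, read_trajectory, write_representatives
from .pocket import FeatureMatrix, PocketDefinition, PocketFeaturizer
from .scoring import (
    BoltzmannEnsembleScorer,
    ScoreTable,
    evaluate_screen,
    results_to_frame,
    screen_summary,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; numeric fields are validated up front."""

    reference: str | None = None
    ligand_resname: str | None = None
    trajectory: str | None = None
    topology: str | None = None        # only for binary trajectories
    scores: str | None = None
    labels: str | None = None
    out_dir: str = "eded_out"
    contact_cutoff: float = 3.0        # Å
    align_range: tuple[int, int] | None = None
    com_mode: str = "residue"
    variance_threshold: float = 0.90
    max_pcs: int | None = 15
    k: int = 4
    seed: int = 0
    restarts: int = 10
    temperature: float = 300.0         # K
    triage_cutoff: float = -9.0        # kcal/mol
    energy_mode: str = "populations"
    representative_metric: str = "pc"
    top_fraction: float = 0.025
    active_classes: tuple[str, ...] = ("strong", "medium")

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise ConfigError("contact_cutoff must be positive")
        if not 0 < self.variance_threshold <= 1:
            raise ConfigError("variance_threshold must be in (0, 1]")
        if self.max_pcs is not None and self.max_pcs < 1:
            raise ConfigError("max_pcs must be >= 1")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.restarts < 1:
            raise ConfigError("restarts must be >= 1")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")
        if not np.isfinite(self.triage_cutoff):
            raise ConfigError("triage_cutoff must be finite")
        if not 0 < self.top_fraction <= 1:
            raise ConfigError("top_fraction must be in (0, 1]")
        if self.com_mode not in ("residue", "sidechain"):
            raise ConfigError("com_mode must be 'residue' or 'sidechain'")
        if self.representative_metric not in ("pc", "cartesian"):
            raise ConfigError("representative_metric must be 'pc' or 'cartesian'")
        if self.align_range is not None:
            self.align_range = (int(self.align_range[0]), int(self.align_range[1]))
            if self.align_range[0] > self.align_range[1]:
                raise ConfigError("align_range must be (low, high)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "align_range" in raw and raw["align_range"] is not None:
            raw["align_range"] = tuple(raw["align_range"])
        if "active_classes" in raw:
            raw["active_classes"] = tuple(raw["active_classes"])
        return cls(**raw)


# -- small persistence helpers -------------------------------------------------

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def pocket_to_yaml(pocket: PocketDefinition, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "contact_cutoff": pocket.contact_cutoff,
        "source": pocket.source,
        "residues": [[c, int(r), n] for (c, r, n) in pocket.residue_keys],
    }
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def pocket_from_yaml(path: str | Path) -> PocketDefinition:
    data = yaml.safe_load(Path(path).read_text())
    return PocketDefinition(
        residue_keys=tuple((c, int(r), n) for c, r, n in data["residues"]),
        contact_cutoff=float(data["contact_cutoff"]),
        source=data.get("source", ""),
    )


def ensemble_to_yaml(ens: ClusterEnsemble, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "k": int(ens.k),
        "seed": None if ens.seed is None else int(ens.seed),
        "populations": [float(p) for p in ens.populations],
        "dg_conf_kT": [float(g) for g in ens.dg_conf],
        "representative_frames": (
            None if ens.representative_frames is None
            else [int(i) for i in ens.representative_frames]
        ),
        "centers": [[float(x) for x in c] for c in ens.centers],
    }
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def ensemble_from_yaml(path: str | Path, assignments: np.ndarray | None = None) -> ClusterEnsemble:
    data = yaml.safe_load(Path(path).read_text())
    reps = data.get("representative_frames")
    return ClusterEnsemble(
        k=int(data["k"]),
        assignments=(np.asarray(assignments, dtype=int)
                     if assignments is not None else np.zeros(0, dtype=int)),
        centers=np.asarray(data["centers"], dtype=float),
        populations=np.asarray(data["populations"], dtype=float),
        dg_conf=np.asarray(data["dg_conf_kT"], dtype=float),
        representative_frames=None if reps is None else np.asarray(reps, dtype=int),
        seed=data.get("seed"),
    )


# -- the pipeline ---------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage the config has inputs for; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "inputs": {},
        "outputs": {},
    }

    def _stage(name):
        def wrap(exc):
            raise EdedError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    if config.reference is None or config.trajectory is None:
        raise ConfigError("pipeline needs at least 'reference' and 'trajectory'")
    for key in ("reference", "trajectory", "topology", "scores", "labels"):
        p = getattr(config, key)
        if p is not None:
            if not Path(p).exists():
                raise ConfigError(f"stage {key!r}: input file {p} does not exist")
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(p)}

    # pocket + features
    try:
        ref = read_structure(config.reference, config.ligand_resname)
        if config.topology is not None:
            traj = read_trajectory(config.topology, config.trajectory)
        else:
            traj = read_trajectory(config.trajectory)
        feat = PocketFeaturizer(contact_cutoff=config.contact_cutoff,
                                align_range=config.align_range,
                                com_mode=config.com_mode).fit(ref)
        features = feat.featurize(traj)
    except EdedError as exc:
        _stage("features")(exc)
    manifest["outputs"]["pocket"] = str(pocket_to_yaml(feat.pocket_, out / "pocket.yaml"))
    manifest["outputs"]["features"] = str(features.to_csv(out / "features.csv"))

    # PCA
    try:
        ed = EssentialDynamics(variance_threshold=config.variance_threshold,
                               max_pcs=config.max_pcs).fit(features)
        proj = ProjectedTrajectory(scores=ed.transform(features), model=ed)
    except EdedError as exc:
        _stage("reduce")(exc)
    manifest["outputs"]["ed_model"] = str(ed.to_dir(out / "ed_model"))
    proj_df = pd.DataFrame(
        proj.scores, columns=[f"pc{i + 1}" for i in range(proj.scores.shape[1])]
    )
    proj_df.to_csv(out / "projections.csv", index=False)
    manifest["outputs"]["projections"] = str(out / "projections.csv")

    # clustering + representatives
    try:
        km = KMeansConformations(n_clusters=config.k,
                                 random_state=config.seed,
                                 n_init=config.restarts,
                                 energy_mode=config.energy_mode).fit(proj)
        ens = km.to_ensemble(seed=config.seed)
        if config.representative_metric == "cartesian":
            reps = select_representatives(proj, ens, metric="cartesian",
                                          features=features.values, model=ed)
            ens.representative_frames = reps
    except EdedError as exc:
        _stage("cluster")(exc)
    pd.DataFrame({"frame": np.arange(traj.n_frames),
                  "cluster": ens.assignments}).to_csv(
        out / "assignments.csv", index=False)
    manifest["outputs"]["assignments"] = str(out / "assignments.csv")
    manifest["outputs"]["ensemble"] = str(ensemble_to_yaml(ens, out / "ensemble.yaml"))
    elbow = inertia_report(proj, range(1, min(9, traj.n_frames + 1)),
                           seed=config.seed, restarts=config.restarts)
    elbow.to_csv(out / "inertia_vs_k.csv", index=False)
    manifest["outputs"]["inertia_vs_k"] = str(out / "inertia_vs_k.csv")

    rep_paths = write_representatives(traj, ens.representative_frames,
                                      out / "representatives")
    manifest["outputs"]["representatives"] = [str(p) for p in rep_paths]

    # scoring (optional: docking happens externally between select and score)
    if config.scores is not None:
        try:
            table = ScoreTable.from_csv(config.scores)
            scorer = BoltzmannEnsembleScorer(
                temperature=config.temperature,
                triage_cutoff=config.triage_cutoff).fit(ens)
            results = scorer.score_compounds(table)
        except EdedError as exc:
            _stage("score")(exc)
        ranked = results_to_frame(results).sort_values(
            ["ensemble_dg_bind", "compound_id"], kind="stable")
        ranked.to_csv(out / "ranked.csv", index=False)
        manifest["outputs"]["ranked"] = str(out / "ranked.csv")
        summary = screen_summary(results, top_fraction=config.top_fraction)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["outputs"]["summary"] = str(out / "summary.json")

        if config.labels is not None:
            try:
                lab = pd.read_csv(config.labels)
                labels = dict(zip(lab["compound_id"].astype(str), lab["class"]))
                ev = evaluate_screen(results, labels,
                                     cutoff=config.triage_cutoff,
                                     active_classes=config.active_classes)
            except EdedError as exc:
                _stage("evaluate")(exc)
            (out / "evaluation.json").write_text(
                json.dumps(ev, indent=2, sort_keys=True))
            manifest["outputs"]["evaluation"] = str(out / "evaluation.json")
    elif config.labels is not None:
        raise ConfigError("stage 'evaluate': labels given but no scores file")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
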