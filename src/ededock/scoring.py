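"""Boltzmann-weighted ensemble docking scores.

A compound docked against an ensemble of n receptor conformations gets a
single ensemble binding score

    ensemble ΔG_bind = kT · ln( Σᵢ e^(−ΔG_conf,i) /
                                Σᵢ e^(−ΔG_conf,i − ΔG_bind,i / kT) )

where ΔG_conf,i is the relative free energy of conformation i (kT units,
0 for the reference/most-populated state) and ΔG_bind,i the docking score
against that conformation (kcal/mol, more negative = better).  This equals
kT·ln(P_unbound/P_bound) over the conformational ensemble: the numerator is
the apo (unbound) partition over all n states and the denominator the bound
partition.  High-energy states are automatically discounted, so rare
conformations with spuriously good docking scores do not dominate the
result.  With all ΔG_conf = 0 this reduces to the equal-weighting form
kT·ln(n / Σ e^(−ΔG_bind,i/kT)); with n = 1 it is the raw docking score.

Both partitions are evaluated with max-shifted log-sum-exp, so scores in
[−50, 50] kcal/mol and ΔG_conf up to hundreds of kT are safe.

A docking pose missing for conformation i (NaN in the score table) is
treated as no binding to that state: its term is dropped from the bound
partition but kept in the unbound one, and the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .clustering import ClusterEnsemble
from .exceptions import (
    AllScoresMissingError,
    EmptyResultsError,
    ReferenceEnergyError,
    UnlabeledCompoundError,
)

#: Gas constant in kcal/(mol·K).
GAS_CONSTANT_KCAL = 0.0019872041

#: Default activity classes counted as experimentally active.
DEFAULT_ACTIVE_CLASSES = frozenset({"strong", "medium"})


@dataclass(frozen=True)
class ThermalContext:
    """Temperature and the derived thermal energy kT (kcal/mol)."""

    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        return GAS_CONSTANT_KCAL * self.temperature


@dataclass
class ScoreTable:
    """Compound × conformation docking scores, kcal/mol (NaN = missing pose)."""

    compound_ids: list[str]
    conformation_ids: list[str]
    dg_bind: np.ndarray  # (n_compounds, n_conformations)

    def __post_init__(self) -> None:
        self.dg_bind = np.asarray(self.dg_bind, dtype=float)
        if self.dg_bind.shape != (len(self.compound_ids), len(self.conformation_ids)):
            raise ValueError("score matrix shape mismatch")
        missing_all = ~np.isfinite(self.dg_bind).any(axis=1)
        if missing_all.any():
            bad = [self.compound_ids[i] for i in np.flatnonzero(missing_all)]
            raise AllScoresMissingError(f"compounds with no scores: {bad}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path)
        if df.columns[0] != "compound_id":
            raise ValueError("first column of a score table must be 'compound_id'")
        return cls(
            compound_ids=[str(c) for c in df["compound_id"]],
            conformation_ids=[str(c) for c in df.columns[1:]],
            dg_bind=df.iloc[:, 1:].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.dg_bind, columns=self.conformation_ids)
        df.insert(0, "compound_id", self.compound_ids)
        df.to_csv(path, index=False)
        return path


@dataclass
class EnsembleResult:
    """Ensemble score and bound-partition breakdown for one compound."""

    compound_id: str
    ensemble_dg_bind: float              # kcal/mol
    contributions: np.ndarray            # fraction of bound partition per conformation
    n_conformations_used: int
    has_missing: bool = False
    triage_pass: bool | None = None
    rank: int | None = None


# ---------------------------------------------------------------------------
# Core score (the partition-ratio form, log-sum-exp stable)
# ---------------------------------------------------------------------------

def _validate_dg_conf(dg_conf: np.ndarray) -> np.ndarray:
    dg_conf = np.asarray(dg_conf, dtype=float)
    if dg_conf.ndim != 1 or dg_conf.size < 1:
        raise ValueError("dg_conf must be a non-empty 1-D array")
    if not np.isclose(dg_conf.min(), 0.0, atol=1e-9):
        raise ReferenceEnergyError(
            f"reference conformation must have dg_conf = 0 (min is {dg_conf.min()})"
        )
    return dg_conf


def ensemble_score(
    dg_bind_row: np.ndarray,
    dg_conf: np.ndarray,
    ctx: ThermalContext = ThermalContext(),
) -> tuple[float, np.ndarray]:
    """Ensemble binding score of one compound, with per-state contributions.

    Parameters
    ----------
    dg_bind_row : (n,) docking scores, kcal/mol; NaN marks a missing pose.
    dg_conf : (n,) relative conformational free energies, kT; min must be 0.

    Returns
    -------
    (score, contributions) — score in kcal/mol; contributions are the
    normalised bound-partition weights (0 at missing poses, summing to 1).
    """
    dg_conf = _validate_dg_conf(dg_conf)
    row = np.asarray(dg_bind_row, dtype=float)
    if row.shape != dg_conf.shape:
        raise ValueError("dg_bind row and dg_conf length mismatch")
    used = np.isfinite(row)
    if not used.any():
        raise AllScoresMissingError("no docking score for any conformation")
    kT = ctx.kT
    log_unbound = logsumexp(-dg_conf)                       # over all n states
    log_terms = -dg_conf[used] - row[used] / kT             # bound partition
    log_bound = logsumexp(log_terms)
    score = float(kT * (log_unbound - log_bound))
    contributions = np.zeros_like(row)
    contributions[used] = np.exp(log_terms - log_bound)
    return score, contributions


def equal_weight_score(
    dg_bind_row: np.ndarray, ctx: ThermalContext = ThermalContext()
) -> float:
    """Equal-likelihood limit: kT·ln( n / Σ e^(−ΔG_bind,i/kT) )."""
    row = np.asarray(dg_bind_row, dtype=float)
    used = np.isfinite(row)
    if not used.any():
        raise AllScoresMissingError("no docking score for any conformation")
    kT = ctx.kT
    n = row.size
    return float(kT * (np.log(n) - logsumexp(-row[used] / kT)))


# ---------------------------------------------------------------------------
# Screening-level operations
# ---------------------------------------------------------------------------

def score_table(
    table: ScoreTable,
    dg_conf: np.ndarray,
    ctx: ThermalContext = ThermalContext(),
    cutoff: float | None = None,
) -> list[EnsembleResult]:
    """Score every compound in a table; optionally apply the triage cutoff."""
    dg_conf = _validate_dg_conf(dg_conf)
    if len(dg_conf) != len(table.conformation_ids):
        raise ValueError("dg_conf length does not match table conformations")
    results = []
    for cid, row in zip(table.compound_ids, table.dg_bind):
        s, contrib = ensemble_score(row, dg_conf, ctx)
        used = int(np.isfinite(row).sum())
        results.append(EnsembleResult(
            compound_id=cid, ensemble_dg_bind=s, contributions=contrib,
            n_conformations_used=used, has_missing=used < row.size,
            triage_pass=None if cutoff is None else bool(s <= cutoff),
        ))
    order = np.argsort([r.ensemble_dg_bind for r in results], kind="stable")
    for rank, i in enumerate(order, start=1):
        results[i].rank = rank
    return results


def triage(
    results: Sequence[EnsembleResult], cutoff: float = -9.0
) -> tuple[list[EnsembleResult], list[EnsembleResult]]:
    """Partition into (predicted active, predicted inactive) at the cutoff.

    A compound is predicted active iff its ensemble score ≤ cutoff (the
    boundary counts as active); each partition is sorted by ascending score.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    ordered = sorted(results, key=lambda r: r.ensemble_dg_bind)
    actives = [r for r in ordered if r.ensemble_dg_bind <= cutoff]
    inactives = [r for r in ordered if r.ensemble_dg_bind > cutoff]
    for r in actives:
        r.triage_pass = True
    for r in inactives:
        r.triage_pass = False
    return actives, inactives


def evaluate_screen(
    results: Sequence[EnsembleResult],
    labels: Mapping[str, str],
    cutoff: float = -9.0,
    active_classes: Iterable[str] = DEFAULT_ACTIVE_CLASSES,
) -> dict:
    """Confusion counts and rates of the triage against activity classes.

    ``accuracy = (TP+TN)/total``, ``FNR = FN/(FN+TP)``, ``FPR = FP/(FP+TN)``;
    a rate whose denominator is zero is reported as None (undefined), not 0.
    """
    active_classes = set(active_classes)
    tp = fp = tn = fn = 0
    for r in results:
        if r.compound_id not in labels:
            raise UnlabeledCompoundError(f"no activity label for {r.compound_id!r}")
        truth = labels[r.compound_id] in active_classes
        pred = r.ensemble_dg_bind <= cutoff
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    total = tp + fp + tn + fn
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": (tp + tn) / total if total else None,
        "fnr": fn / (fn + tp) if (fn + tp) else None,
        "fpr": fp / (fp + tn) if (fp + tn) else None,
    }


def screen_summary(
    results: Sequence[EnsembleResult], top_fraction: float = 0.025
) -> dict:
    """Summary statistics of the best-scoring fraction of the screen.

    Selects the best ⌈top_fraction·N⌉ compounds by ascending ensemble score.
    """
    if not results:
        raise EmptyResultsError("no results to summarise")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    scores = np.sort([r.ensemble_dg_bind for r in results])
    n_top = int(np.ceil(top_fraction * scores.size))
    top = scores[:n_top]
    return {
        "n_total": int(scores.size), "n_top": int(n_top),
        "mean": float(top.mean()), "median": float(np.median(top)),
        "std": float(top.std(ddof=0)), "best": float(top.min()),
        "worst": float(top.max()),
    }


def results_to_frame(results: Sequence[EnsembleResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "compound_id": r.compound_id,
            "ensemble_dg_bind": r.ensemble_dg_bind,
            "n_conformations_used": r.n_conformations_used,
            "has_missing": r.has_missing,
            "rank": r.rank,
            "triage_pass": r.triage_pass,
        }
        for j, c in enumerate(r.contributions):
            row[f"contribution_{j}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class BoltzmannEnsembleScorer(BaseEstimator):
    """Scores compounds against a fitted conformational ensemble.

    ``fit`` takes a :class:`~ededock.clustering.ClusterEnsemble`, a fitted
    :class:`~ededock.clustering.KMeansConformations`, or a raw ΔG_conf
    vector (kT); ``decision_function`` returns ensemble scores
    for a :class:`ScoreTable` and ``predict`` the triage decisions.

    Parameters
    ----------
    temperature : float, default 300.0 — K, sets kT for unit conversion.
    triage_cutoff : float, default −9.0 — kcal/mol; scores ≤ cutoff are
        predicted active.
    """

    def __init__(self, temperature: float = 300.0, triage_cutoff: float = -9.0):
        self.temperature = temperature
        self.triage_cutoff = triage_cutoff

    def fit(self, X, y=None) -> "BoltzmannEnsembleScorer":
        if isinstance(X, ClusterEnsemble):
            dg_conf = X.dg_conf
        elif hasattr(X, "dg_conf_"):  # a fitted KMeansConformations
            dg_conf = X.dg_conf_
        else:
            dg_conf = np.asarray(X, dtype=float)
        self.dg_conf_ = _validate_dg_conf(dg_conf)
        self.ctx_ = ThermalContext(temperature=self.temperature)
        return self

    def score_compounds(self, table: ScoreTable) -> list[EnsembleResult]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "dg_conf_")
        return score_table(table, self.dg_conf_, self.ctx_,
                           cutoff=self.triage_cutoff)

    def decision_function(self, table: ScoreTable) -> np.ndarray:
        return np.asarray(
            [r.ensemble_dg_bind for r in self.score_compounds(table)]
        )

    def predict(self, table: ScoreTable) -> np.ndarray:
        return self.decision_function(table) <= self.triage_cutoff
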