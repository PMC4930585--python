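"""Similarity-based multi drug-target predictor.

Guilt-by-association scoring: a drug D is scored against a target T by the
maximum similarity between D and the drugs known to bind T, always
excluding D itself from the binder set (leave-one-out). The retained
maximum defines the score, and the binder realizing it is kept as the
"origin" drug, so every candidate can be traced back to the known
interaction that generated its signal. Known drug-target pairs therefore
receive honest (non-trivial) scores and can serve as positives in ROC
evaluation, while every unknown combination is an explicit candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import AssociationTable
from .similarity import SimilarityMatrix

__all__ = [
    "ScoredCandidate",
    "score_pair_loo",
    "score_all",
    "threshold_candidates",
    "DrugTargetModel",
    "DrugTargetResults",
]

#: Candidate-selection threshold on the similarity score.
DEFAULT_SCORE_THRESHOLD = 0.75


@dataclass(frozen=True)
class ScoredCandidate:
    """One drug-target combination with its leave-one-out maximum score.

    ``score`` is NA when the target has no binder other than the drug
    itself; ``origin_drug`` is the binder realizing the maximum (ties broken
    lexicographically); ``known`` flags membership in the reference standard.
    """

    drug_id: str
    target_id: str
    score: Optional[float]
    origin_drug: Optional[str]
    known: bool


def score_pair_loo(
    drug: str,
    target: str,
    sim: SimilarityMatrix,
    assoc: AssociationTable,
) -> ScoredCandidate:
    """Leave-one-out maximum-similarity score of one drug against one target."""
    i = sim.index_of(drug)  # raises if drug missing from the matrix
    binders = sorted(assoc.drugs_of(target) - {drug})
    known = (drug, target) in assoc.edge_set()
    if not binders:
        return ScoredCandidate(drug, target, None, None, known)
    scores = np.array([sim.values[i, sim.index_of(b)] for b in binders])
    j = int(np.argmax(scores))  # first max -> lexicographically smallest binder
    return ScoredCandidate(drug, target, float(scores[j]), binders[j], known)


def score_all(sim: SimilarityMatrix, assoc: AssociationTable) -> pd.DataFrame:
    """Score every drug x target combination.

    Produces exactly ``n_drugs * n_targets`` rows (drugs taken from the
    similarity matrix, targets from the association table), each carrying
    the leave-one-out maximum score, origin drug and known flag. Rows are
    sorted by (drug_id, target_id) for determinism.
    """
    if len(assoc) == 0:
        raise ValueError("association table is empty")
    missing = set(assoc.drugs) - set(sim.drug_ids)
    if missing:
        raise ValueError(f"drugs absent from similarity matrix: {sorted(missing)[:5]}")

    drugs = list(sim.drug_ids)
    n = len(drugs)
    drug_pos = {d: i for i, d in enumerate(drugs)}
    targets = sorted(set(assoc.edges["entity_id"]))
    known_pairs = assoc.edge_set()

    frames = []
    for target in targets:
        binders = sorted(assoc.drugs_of(target))
        bidx = np.array([drug_pos[b] for b in binders], dtype=int)
        V = sim.values[:, bidx].copy()
        # leave-one-out: a binder never scores against itself
        for col, b in enumerate(binders):
            V[drug_pos[b], col] = -1.0
        arg = V.argmax(axis=1)
        best = V[np.arange(n), arg]
        origin = np.array(binders, dtype=object)[arg]
        score = np.where(best < 0, np.nan, best)
        origin = np.where(best < 0, None, origin)
        frames.append(
            pd.DataFrame(
                {
                    "drug_id": drugs,
                    "target_id": target,
                    "score": score,
                    "origin_drug": origin,
                    "known": [(d, target) in known_pairs for d in drugs],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["drug_id", "target_id"], kind="stable").reset_index(drop=True)
    return out


def threshold_candidates(
    table: pd.DataFrame, min_score: float = DEFAULT_SCORE_THRESHOLD
) -> pd.DataFrame:
    """Keep candidates with score >= ``min_score`` (inclusive); NA-scored
    rows are dropped."""
    mask = table["score"].notna() & (table["score"] >= min_score)
    return table[mask].reset_index(drop=True)


class DrugTargetModel:
    """Similarity-based drug-target predictor (leave-one-out maximum score).

    Parameters
    ----------
    sim : SimilarityMatrix
        Drug-drug similarity; must cover every drug in ``assoc``.
    assoc : AssociationTable
        Known drug-target interactions (the reference standard).

    Examples
    --------
    >>> model = DrugTargetModel(sim, dt)     # doctest: +SKIP
    >>> res = model.fit()                    # doctest: +SKIP
    >>> res.candidates.head()                # doctest: +SKIP
    >>> strong = res.threshold(0.75)         # doctest: +SKIP
    """

    def __init__(self, sim: SimilarityMatrix, assoc: AssociationTable):
        if assoc.kind != "drug_target":
            raise ValueError("assoc must be a drug_target table")
        self.sim = sim
        self.assoc = assoc

    def fit(self) -> "DrugTargetResults":
        candidates = score_all(self.sim, self.assoc)
        return DrugTargetResults(self, candidates)


class DrugTargetResults:
    """Fitted candidate table plus evaluation helpers."""

    def __init__(self, model: DrugTargetModel, candidates: pd.DataFrame):
        self.model = model
        self.candidates = candidates

    @property
    def n_combinations(self) -> int:
        return len(self.candidates)

    def threshold(self, min_score: float = DEFAULT_SCORE_THRESHOLD) -> pd.DataFrame:
        return threshold_candidates(self.candidates, min_score)

    def auroc(self) -> float:
        from .evaluation import RankedLabels, auroc

        return auroc(RankedLabels.from_candidates(self.candidates))

    def per_target_auroc(self) -> pd.DataFrame:
        from .evaluation import per_target_auroc

        return per_target_auroc(self.candidates)

    def summary(self) -> str:
        c = self.candidates
        n_drugs = c["drug_id"].nunique()
        n_targets = c["target_id"].nunique()
        known = int(c["known"].sum())
        lines = [
            "Drug-target predictor (leave-one-out max similarity)",
            "====================================================",
            f"drugs                  {n_drugs:>9d}",
            f"targets                {n_targets:>9d}",
            f"combinations scored    {len(c):>9d}",
            f"known positives        {known:>9d}",
            f"candidates >= 0.75     {len(self.threshold()):>9d}",
        ]
        try:
            lines.append(f"global AUROC           {self.auroc():>9.3f}")
        except ValueError:
            lines.append("global AUROC                  NA")
        return "\n".join(lines)
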