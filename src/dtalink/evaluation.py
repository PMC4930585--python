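"""Evaluation protocols for the drug-target predictor.

Labels: known associations in the reference standard are the positives and
every other drug-target combination is a negative (no negative sampling).
Performance is summarized by the AUROC (rank statistic: the probability a
random positive outscores a random negative, ties counting one half),
precision in the top-k of the ranked candidate list, and the enrichment
factor at k, i.e. precision@k over the global prevalence of positives
(EF = 1 is random performance; EF at full depth is exactly 1).

Two validation designs are provided: hold-out (a random fraction of known
edges moved to a test set, the model rebuilt on the rest) and
leave-class-out (all edges of the drugs in one therapeutic class removed,
probing whether a class can be recovered with no close neighbors in
training). Per-target AUROCs assess each individual target model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import AssociationTable, DrugCatalog
from .similarity import SimilarityMatrix

__all__ = [
    "RankedLabels",
    "SplitSpec",
    "EvaluationReport",
    "auroc",
    "precision_at_k",
    "ef_at_k",
    "make_split",
    "evaluate_model",
    "per_target_auroc",
]

DEFAULT_KS = (10, 50, 100, 500, 1000)


@dataclass
class RankedLabels:
    """Scores with binary labels, sorted by the deterministic decision rule:
    score descending, then drug_id, then target_id."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and of equal length")
        if not np.all(np.isin(self.labels, [0, 1])):
            raise ValueError("labels must be 0/1")

    @classmethod
    def from_candidates(
        cls,
        table: pd.DataFrame,
        label_col: str = "known",
        score_col: str = "score",
    ) -> "RankedLabels":
        """Rank a candidate table; NA-scored rows are excluded."""
        t = table[table[score_col].notna()]
        sort_cols = [score_col] + [c for c in ("drug_id", "target_id") if c in t.columns]
        t = t.sort_values(
            sort_cols, ascending=[False] + [True] * (len(sort_cols) - 1), kind="stable"
        )
        return cls(t[score_col].to_numpy(), t[label_col].astype(int).to_numpy())

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())


@dataclass(frozen=True)
class SplitSpec:
    """Validation split: ``holdout`` moves a random fraction of the known
    edges to the test set; ``leave_class_out`` moves every edge of the drugs
    carrying ``class_label``."""

    mode: str  # "holdout" | "leave_class_out"
    fraction: Optional[float] = None
    class_label: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("holdout", "leave_class_out"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "holdout":
            if self.fraction is None or not (0 < self.fraction < 1):
                raise ValueError("holdout requires a fraction in (0, 1)")
        elif self.class_label is None:
            raise ValueError("leave_class_out requires a class_label")


def auroc(ranked: RankedLabels) -> float:
    """Area under the ROC curve as the normalized Mann-Whitney statistic;
    tied scores contribute half a concordance."""
    if ranked.labels.min() == ranked.labels.max():
        raise ValueError("AUROC needs at least one positive and one negative")
    return float(roc_auc_score(ranked.labels, ranked.scores))


def precision_at_k(ranked: RankedLabels, k: int) -> float:
    """Fraction of positives among the top k of the ranked list."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k={k} out of range 1..{len(ranked)}")
    return float(ranked.labels[:k].mean())


def ef_at_k(ranked: RankedLabels, k: int) -> float:
    """Enrichment factor at depth k: precision@k over global prevalence."""
    prev = ranked.prevalence
    if prev == 0:
        raise ValueError("enrichment factor undefined at zero prevalence")
    return precision_at_k(ranked, k) / prev


def roc_curve_points(ranked: RankedLabels) -> pd.DataFrame:
    """(fpr, tpr) points of the ROC curve for external plotting."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(ranked.labels, ranked.scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def make_split(
    assoc: AssociationTable,
    spec: SplitSpec,
    catalog: Optional[DrugCatalog] = None,
) -> tuple[AssociationTable, set[tuple[str, str]]]:
    """Split known edges into a training table and a test edge set.

    Hold-out picks ``round(fraction * n_edges)`` edges uniformly at random
    (reproducible per seed); leave-class-out removes all edges of the drugs
    carrying the class label. Train and test are disjoint and their union is
    the input edge set.
    """
    edges = assoc.edges.reset_index(drop=True)
    if spec.mode == "holdout":
        rng = np.random.default_rng(spec.seed)
        n_test = int(round(spec.fraction * len(edges)))
        if n_test == 0 or n_test == len(edges):
            raise ValueError("fraction produces an empty train or test set")
        idx = rng.permutation(len(edges))
        test_idx = np.sort(idx[:n_test])
    else:
        if catalog is None:
            raise ValueError("leave_class_out requires a drug catalog with classes")
        class_drugs = set(catalog.drugs_in_class(spec.class_label))
        if not class_drugs:
            raise ValueError(f"class {spec.class_label!r} covers no drugs")
        mask = edges["drug_id"].isin(class_drugs)
        if not mask.any():
            raise ValueError(f"class {spec.class_label!r} has no edges")
        if mask.all():
            raise ValueError("split leaves an empty training set")
        test_idx = np.flatnonzero(mask.to_numpy())
    test_edges = set(
        zip(edges.loc[test_idx, "drug_id"], edges.loc[test_idx, "entity_id"])
    )
    train = AssociationTable(assoc.kind, edges.drop(index=test_idx))
    return train, test_edges


def evaluate_model(
    train: AssociationTable,
    test_edges: set[tuple[str, str]],
    sim: SimilarityMatrix,
    ks: Sequence[int] = DEFAULT_KS,
) -> "EvaluationReport":
    """Rescore all combinations using training edges only and evaluate on
    the held-out edges.

    Training edges are removed from the ranked list entirely (neither
    positives nor negatives at test time); held-out edges are the positives
    and all remaining unknown combinations the negatives.
    """
    from .drug_target import score_all

    if len(train) == 0:
        raise ValueError("empty training table")
    if not test_edges:
        raise ValueError("empty test edge set")
    cand = score_all(sim, train)
    cand = cand[~cand["known"]].copy()
    key = list(zip(cand["drug_id"], cand["target_id"]))
    cand["label"] = [int(k in test_edges) for k in key]
    ranked = RankedLabels.from_candidates(cand, label_col="label")
    ks_used = [k for k in ks if 1 <= k <= len(ranked)]
    return EvaluationReport(
        auroc=auroc(ranked),
        precision_at={k: precision_at_k(ranked, k) for k in ks_used},
        ef_at={k: ef_at_k(ranked, k) for k in ks_used},
        n_ranked=len(ranked),
        n_test=len(test_edges),
    )


@dataclass
class EvaluationReport:
    auroc: float
    precision_at: dict[int, float]
    ef_at: dict[int, float]
    n_ranked: int
    n_test: int

    def summary(self) -> str:
        lines = [
            "Hold-out evaluation",
            "===================",
            f"ranked combinations  {self.n_ranked:>9d}",
            f"test positives       {self.n_test:>9d}",
            f"AUROC                {self.auroc:>9.3f}",
        ]
        for k in self.precision_at:
            lines.append(
                f"top {k:>5d}: precision {self.precision_at[k]:6.3f}   EF {self.ef_at[k]:8.2f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": "auroc", "k": np.nan, "value": self.auroc}]
        rows += [{"metric": "precision", "k": k, "value": v} for k, v in self.precision_at.items()]
        rows += [{"metric": "ef", "k": k, "value": v} for k, v in self.ef_at.items()]
        return pd.DataFrame(rows)


def per_target_auroc(candidates: pd.DataFrame) -> pd.DataFrame:
    """AUROC of each individual target model within its own drug ranking.

    Targets without at least one positive and one negative among the
    non-NA-scored drugs are reported as NA.
    """
    rows = []
    for target, grp in candidates.groupby("target_id", sort=True):
        g = grp[grp["score"].notna()]
        n_binders = int(grp["known"].sum())
        labels = g["known"].astype(int).to_numpy()
        if len(g) == 0 or labels.min() == labels.max():
            value = np.nan
        else:
            value = float(roc_auc_score(labels, g["score"].to_numpy()))
        rows.append({"target_id": target, "n_binders": n_binders, "auroc": value})
    return pd.DataFrame(rows)
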