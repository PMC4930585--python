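"""Drug-target-ADE linkage and bidirectional leveraging.

Linkage intersects the two predictors on the shared target: every
drug-target candidate above the score threshold is joined with every
selected target-ADE signal of that target, producing drug-target-ADE
triples. Each drug-target anchor thus carries a set of predicted adverse
effects, and each drug-ADE anchor (from an external drug-ADE predictor) a
set of predicted targets.

Leveraging tests those predicted sets against the orthogonal reference
standard with the same 2x2 machinery as the scan. For a drug-target anchor:
TP = predicted adverse effects corroborated in the drug-ADE reference for
the drug, FP = predicted but not corroborated, FN = in the reference but
not predicted, TN = neither, over the post-filter ADE universe. EF, the
one-sided Fisher p and q-values (one family per leveraging run) then
re-rank the anchors, so corroboration by an independent data source - not
the similarity score alone - drives the final ordering. The mirrored
computation re-ranks drug-ADE anchors against the drug-target reference.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .enrichment import _ef_vec, _fisher_vec, qvalues
from .io import AssociationTable

__all__ = [
    "link_triples",
    "leverage_drug_targets",
    "leverage_drug_ades",
    "select_leveraged",
    "rank_leveraged",
    "PhenotypeLeverage",
    "TargetLeverage",
    "LeverageResults",
]


def link_triples(
    dt_candidates: pd.DataFrame, ta_selected: pd.DataFrame
) -> pd.DataFrame:
    """Cross-join thresholded drug-target candidates with selected
    target-ADE signals on the target.

    Returns one row per (drug, target, ade) with the candidate score and the
    signal's EF and q; ``attrs["n_distinct_pairs"]`` reports the number of
    distinct drug-target anchors that received at least one adverse effect.
    """
    if dt_candidates.empty or ta_selected.empty:
        out = pd.DataFrame(
            columns=["drug_id", "target_id", "ade_id", "dt_score", "ta_ef", "ta_q"]
        )
        out.attrs["n_distinct_pairs"] = 0
        return out
    left = dt_candidates[["drug_id", "target_id", "score"]].rename(
        columns={"score": "dt_score"}
    )
    right = ta_selected[["target_id", "ade_id", "ef", "q"]].rename(
        columns={"ef": "ta_ef", "q": "ta_q"}
    )
    out = left.merge(right, on="target_id", how="inner")
    out = out[["drug_id", "target_id", "ade_id", "dt_score", "ta_ef", "ta_q"]]
    out = out.sort_values(["drug_id", "target_id", "ade_id"], kind="stable").reset_index(
        drop=True
    )
    out.attrs["n_distinct_pairs"] = len(out[["drug_id", "target_id"]].drop_duplicates())
    return out


def _leverage(
    anchors: pd.DataFrame,  # columns: anchor cols..., "predicted" (entity id)
    anchor_cols: list[str],
    reference: AssociationTable,
    universe: set[str],
    qvalue_method: str = "bh",
) -> pd.DataFrame:
    """Shared contingency machinery for both leveraging directions.

    ``anchors`` holds one row per (anchor, predicted entity); the predicted
    set of an anchor is tested against ``reference`` restricted to the
    entity ``universe``. Duplicate (anchor, entity) rows are collapsed, so
    the computation is idempotent under repeated triples.
    """
    if not universe:
        raise ValueError("empty entity universe")
    N = len(universe)
    anchors = anchors.drop_duplicates(subset=anchor_cols + ["predicted"])
    anchors = anchors[anchors["predicted"].isin(universe)]
    if anchors.empty:
        return pd.DataFrame(
            columns=anchor_cols + ["tp", "fp", "fn", "tn", "ef", "p", "q"]
        )

    ref_sets: dict[str, set[str]] = {}
    for drug, grp in reference.edges.groupby("drug_id"):
        ref_sets[drug] = set(grp["entity_id"]) & universe

    rows = []
    missing: set[str] = set()
    for key, grp in anchors.groupby(anchor_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        drug = key[0]
        predicted = set(grp["predicted"])
        if drug not in ref_sets:
            missing.add(drug)
        known = ref_sets.get(drug, set())
        tp = len(predicted & known)
        rows.append(
            dict(zip(anchor_cols, key))
            | {
                "tp": tp,
                "fp": len(predicted) - tp,
                "fn": len(known) - tp,
                "tn": N - len(predicted | known),
            }
        )
    if missing:
        warnings.warn(
            f"{len(missing)} drugs absent from the reference standard; "
            "treated as having no known associations"
        )
    out = pd.DataFrame(rows)
    tp = out["tp"].to_numpy()
    sel = (out["tp"] + out["fp"]).to_numpy()
    pos = (out["tp"] + out["fn"]).to_numpy()
    out["ef"] = _ef_vec(tp, sel, pos, N)
    out["p"] = _fisher_vec(tp, sel, pos, N)
    out["q"] = qvalues(out["p"], method=qvalue_method)
    return out.reset_index(drop=True)


def leverage_drug_targets(
    triples: pd.DataFrame,
    drug_ade_reference: AssociationTable,
    ade_universe: Optional[set[str]] = None,
    qvalue_method: str = "bh",
) -> pd.DataFrame:
    """Re-score drug-target anchors by how well their predicted adverse
    effects are corroborated in the drug-ADE reference standard.

    ``ade_universe`` defaults to the ADEs present in the reference (it
    should be the post-filter ADE set of the scan that produced the
    triples' target-ADE signals).
    """
    if ade_universe is None:
        ade_universe = set(drug_ade_reference.entities)
    anchors = triples.rename(columns={"ade_id": "predicted"})[
        ["drug_id", "target_id", "predicted"]
    ]
    return _leverage(
        anchors, ["drug_id", "target_id"], drug_ade_reference, ade_universe, qvalue_method
    )


def leverage_drug_ades(
    da_candidates: pd.DataFrame,
    ta_selected: pd.DataFrame,
    drug_target_reference: AssociationTable,
    target_universe: Optional[set[str]] = None,
    qvalue_method: str = "bh",
) -> pd.DataFrame:
    """Re-score drug-ADE anchors by how well the targets implicated in the
    adverse effect are validated in the drug-target reference standard.

    ``da_candidates`` comes from an external drug-ADE predictor already
    thresholded on its score (columns drug_id, ade_id[, score]). Anchors
    whose adverse effect has no selected target signal make no prediction
    and are dropped.
    """
    if target_universe is None:
        target_universe = set(drug_target_reference.entities)
    merged = da_candidates[["drug_id", "ade_id"]].merge(
        ta_selected[["target_id", "ade_id"]], on="ade_id", how="inner"
    )
    anchors = merged.rename(columns={"target_id": "predicted"})[
        ["drug_id", "ade_id", "predicted"]
    ]
    return _leverage(
        anchors, ["drug_id", "ade_id"], drug_target_reference, target_universe, qvalue_method
    )


def select_leveraged(
    candidates: pd.DataFrame, min_ef: float = 1.0, max_q: float = 0.05
) -> pd.DataFrame:
    """Final leveraged selection: EF strictly above ``min_ef`` and q
    strictly below ``max_q``."""
    if candidates.empty:
        return candidates
    mask = (candidates["ef"] > min_ef) & (candidates["q"] < max_q)
    return candidates[mask].reset_index(drop=True)


def rank_leveraged(candidates: pd.DataFrame) -> pd.DataFrame:
    """Deterministic ranking of leveraged anchors: EF descending, q
    ascending, then lexicographic anchor ids."""
    anchor_cols = [c for c in candidates.columns if c.endswith("_id")]
    return candidates.sort_values(
        ["ef", "q"] + anchor_cols,
        ascending=[False, True] + [True] * len(anchor_cols),
        kind="stable",
    ).reset_index(drop=True)


class PhenotypeLeverage:
    """Leverage drug-target candidates with phenotype (drug-ADE) data.

    Parameters
    ----------
    triples : DataFrame from :func:`link_triples`.
    drug_ade_reference : AssociationTable
        The drug-ADE reference standard used for corroboration.
    ade_universe : set of str, optional
        TN universe; defaults to the reference's ADE set.
    """

    def __init__(
        self,
        triples: pd.DataFrame,
        drug_ade_reference: AssociationTable,
        ade_universe: Optional[set[str]] = None,
    ):
        self.triples = triples
        self.reference = drug_ade_reference
        self.universe = ade_universe

    def fit(self, qvalue_method: str = "bh") -> "LeverageResults":
        table = leverage_drug_targets(
            self.triples, self.reference, self.universe, qvalue_method
        )
        return LeverageResults(table, anchor_cols=["drug_id", "target_id"])


class TargetLeverage:
    """Leverage drug-ADE candidates with target (drug-target) data."""

    def __init__(
        self,
        da_candidates: pd.DataFrame,
        ta_selected: pd.DataFrame,
        drug_target_reference: AssociationTable,
        target_universe: Optional[set[str]] = None,
    ):
        self.da_candidates = da_candidates
        self.ta_selected = ta_selected
        self.reference = drug_target_reference
        self.universe = target_universe

    def fit(self, qvalue_method: str = "bh") -> "LeverageResults":
        table = leverage_drug_ades(
            self.da_candidates,
            self.ta_selected,
            self.reference,
            self.universe,
            qvalue_method,
        )
        return LeverageResults(table, anchor_cols=["drug_id", "ade_id"])


class LeverageResults:
    """Leveraged anchors with contingency counts, EF, p and q."""

    def __init__(self, table: pd.DataFrame, anchor_cols: list[str]):
        self.table = table
        self.anchor_cols = anchor_cols

    def select(self, min_ef: float = 1.0, max_q: float = 0.05) -> pd.DataFrame:
        return select_leveraged(self.table, min_ef, max_q)

    def rank(self) -> pd.DataFrame:
        return rank_leveraged(self.table)

    def summary(self) -> str:
        t = self.table
        sel = self.select()
        lines = [
            f"Leveraged anchors ({' x '.join(self.anchor_cols)})",
            "=" * 40,
            f"anchors tested         {len(t):>8d}",
            f"selected (EF>1, q<0.05) {len(sel):>7d}",
        ]
        if len(t):
            lines.append(f"median EF | max EF     {t['ef'].median():8.3g} | {t['ef'].max():.3g}")
        return "\n".join(lines)
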