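"""2x2 enrichment engine and the target-adverse-effect scan.

For a target T and adverse effect E over a universe of N drugs, the 2x2
contingency table counts drugs associated with both (TP), only the target
(FP), only the adverse effect (FN), and neither (TN). The enrichment factor

    EF = [TP / (TP + FP)] / [(TP + FN) / N]

is the precision of "drugs binding T" at retrieving "drugs with E" divided
by the background prevalence of E, i.e. the precision a random drug sample
would achieve; EF = 1 means no enrichment. Significance is the one-sided
Fisher exact test in the enrichment direction (hypergeometric upper tail
with margins fixed), and multiplicity over a scan is handled with q-values
(Benjamini-Hochberg, optionally with a Storey pi0 estimate at lambda = 0.5).

The full scan over all target x ADE pairs is vectorized: TP counts for
every pair come from one indicator-matrix product, and the hypergeometric
tail is evaluated array-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AssociationTable

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "build_contingency",
    "enrichment_factor",
    "fisher_exact_greater",
    "qvalues",
    "pairwise_enrichment_scan",
    "select_associations",
    "TargetAdeModel",
    "TargetAdeResults",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts tp, fp, fn, tn over a drug universe of size tp+fp+fn+tn."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.n == 0:
            raise ValueError("contingency table over an empty universe")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EnrichmentResult:
    ef: float
    p_value: float
    q_value: float = float("nan")


def build_contingency(set_a: set, set_b: set, universe: set) -> ContingencyTable:
    """2x2 table for membership in ``set_a`` (e.g. binds target) vs
    ``set_b`` (e.g. has adverse effect) over ``universe``."""
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    tp = len(set_a & set_b)
    return ContingencyTable(
        tp=tp,
        fp=len(set_a) - tp,
        fn=len(set_b) - tp,
        tn=len(universe) - len(set_a | set_b),
    )


def enrichment_factor(ct: ContingencyTable) -> float:
    """Observed precision over background prevalence.

    Returns 0.0 when tp == 0 and +inf when prevalence is 0 with tp > 0
    (cannot occur for a well-formed table). Undefined (error) when the
    "selected" margin tp+fp is empty.
    """
    sel = ct.tp + ct.fp
    if sel == 0:
        raise ValueError("enrichment factor undefined: tp + fp == 0")
    if ct.tp == 0:
        return 0.0
    prevalence = (ct.tp + ct.fn) / ct.n
    if prevalence == 0:
        return float("inf")
    return (ct.tp / sel) / prevalence


def fisher_exact_greater(ct: ContingencyTable) -> float:
    """One-sided Fisher exact p-value in the enrichment direction:
    P(X >= tp) under the hypergeometric with all margins fixed."""
    N = ct.n
    K = ct.tp + ct.fn  # drugs with the effect
    n = ct.tp + ct.fp  # drugs selected (bind the target)
    return float(hypergeom.sf(ct.tp - 1, N, K, n))


def _fisher_vec(tp: np.ndarray, row: np.ndarray, col: np.ndarray, N: int) -> np.ndarray:
    """Vectorized one-sided Fisher p for tables with common universe N.

    ``row`` = tp+fp (selected margin), ``col`` = tp+fn (effect margin).
    """
    return hypergeom.sf(tp - 1, N, col, row)


def _ef_vec(tp: np.ndarray, row: np.ndarray, col: np.ndarray, N: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ef = (tp / row) / (col / N)
    ef = np.where(tp == 0, 0.0, ef)
    return ef


def qvalues(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """FDR q-values for a family of p-values, in input order.

    method "bh": Benjamini-Hochberg step-up adjusted p-values.
    method "storey": q_i = pi0_hat * bh_i with pi0_hat = min(1,
    #{p > 0.5} / (0.5 m)), the Storey null-proportion estimate at a fixed
    lambda = 0.5 (no smoother).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return bh
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
        return np.minimum(pi0 * bh, 1.0)
    raise ValueError(f"unknown q-value method {method!r}")


def pairwise_enrichment_scan(
    assoc_a: AssociationTable,
    assoc_b: AssociationTable,
    universe: Optional[set[str]] = None,
    qvalue_method: str = "bh",
) -> pd.DataFrame:
    """Enrichment of every (entity_a, entity_b) pair over a shared drug
    universe: one row per pair of the full cross-product, with tp/fp/fn/tn,
    EF, one-sided Fisher p and q-values computed jointly across the scan.

    ``assoc_a`` is conventionally the drug-target table and ``assoc_b`` the
    drug-ADE table; both should already be degree-filtered. The universe
    defaults to drugs present in both tables.
    """
    drugs_a, drugs_b = set(assoc_a.drugs), set(assoc_b.drugs)
    if universe is None:
        universe = drugs_a & drugs_b
    if not drugs_a & drugs_b:
        raise ValueError("drug universes of the two tables are disjoint")
    if not universe:
        raise ValueError("empty drug universe")
    drugs = sorted(universe)
    drug_idx = {d: i for i, d in enumerate(drugs)}
    N = len(drugs)

    def indicator(assoc: AssociationTable) -> tuple[np.ndarray, list[str]]:
        ents = sorted(set(assoc.edges["entity_id"]))
        eidx = {e: j for j, e in enumerate(ents)}
        M = np.zeros((N, len(ents)), dtype=np.int32)
        sub = assoc.edges[assoc.edges["drug_id"].isin(drug_idx)]
        M[
            sub["drug_id"].map(drug_idx).to_numpy(),
            sub["entity_id"].map(eidx).to_numpy(),
        ] = 1
        return M, ents

    A, ents_a = indicator(assoc_a)
    B, ents_b = indicator(assoc_b)
    if not ents_a or not ents_b:
        raise ValueError("no entities left to scan")

    tp = (A.T @ B).astype(np.int64)  # (n_a, n_b)
    deg_a = A.sum(axis=0).astype(np.int64)  # tp + fp per entity_a
    deg_b = B.sum(axis=0).astype(np.int64)  # tp + fn per entity_b
    row = np.broadcast_to(deg_a[:, None], tp.shape)
    col = np.broadcast_to(deg_b[None, :], tp.shape)

    tp_f = tp.ravel()
    row_f = row.ravel()
    col_f = col.ravel()
    ef = _ef_vec(tp_f, row_f, col_f, N)
    p = _fisher_vec(tp_f, row_f, col_f, N)
    q = qvalues(p, method=qvalue_method)

    n_a, n_b = len(ents_a), len(ents_b)
    out = pd.DataFrame(
        {
            "target_id": np.repeat(np.array(ents_a, dtype=object), n_b),
            "ade_id": np.tile(np.array(ents_b, dtype=object), n_a),
            "tp": tp_f,
            "fp": row_f - tp_f,
            "fn": col_f - tp_f,
            "tn": N - row_f - col_f + tp_f,
            "ef": ef,
            "p": p,
            "q": q,
        }
    )
    out.attrs["n_universe"] = N
    return out


def select_associations(
    results: pd.DataFrame,
    min_ef: float = 5.0,
    max_q: float = 0.05,
    min_common: int = 3,
) -> pd.DataFrame:
    """Signal selection: EF strictly above ``min_ef``, q strictly below
    ``max_q``, and at least ``min_common`` drugs shared (tp)."""
    mask = (results["ef"] > min_ef) & (results["q"] < max_q) & (results["tp"] >= min_common)
    return results[mask].reset_index(drop=True)


class TargetAdeModel:
    """Target-adverse-effect enrichment model.

    Couples a drug-target table with a drug-ADE table on their shared drug
    universe, applies the minimum-support filter (entities with fewer than
    ``min_drugs`` drugs are dropped, single pass), and scans every
    target x ADE pair for overrepresentation.

    Parameters
    ----------
    drug_target, drug_ade : AssociationTable
    min_drugs : int
        Minimum distinct drugs per target and per ADE (default 5).
        Pass 0 to disable (e.g. when the inputs are pre-filtered).

    Examples
    --------
    >>> model = TargetAdeModel(dt, da)            # doctest: +SKIP
    >>> res = model.fit(qvalue_method="bh")       # doctest: +SKIP
    >>> hits = res.select(min_ef=5, max_q=0.05, min_common=3)  # doctest: +SKIP
    """

    def __init__(
        self,
        drug_target: AssociationTable,
        drug_ade: AssociationTable,
        min_drugs: int = 5,
    ):
        universe = set(drug_target.drugs) & set(drug_ade.drugs)
        if not universe:
            raise ValueError("no drugs shared between the two tables")
        dt = drug_target.restrict_drugs(universe)
        da = drug_ade.restrict_drugs(universe)
        if min_drugs > 1:
            from .io import apply_min_degree_filter

            dt = apply_min_degree_filter(dt, min_drugs)
            da = apply_min_degree_filter(da, min_drugs)
        self.drug_target = dt
        self.drug_ade = da
        self.universe = universe
        self.min_drugs = min_drugs

    def fit(self, qvalue_method: str = "bh") -> "TargetAdeResults":
        table = pairwise_enrichment_scan(
            self.drug_target, self.drug_ade, self.universe, qvalue_method
        )
        return TargetAdeResults(self, table)


class TargetAdeResults:
    """Scan results: one row per target x ADE pair with counts, EF, p, q."""

    def __init__(self, model: TargetAdeModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def select(
        self, min_ef: float = 5.0, max_q: float = 0.05, min_common: int = 3
    ) -> pd.DataFrame:
        return select_associations(self.table, min_ef, max_q, min_common)

    def summary(self) -> str:
        t = self.table
        sel = self.select()
        lines = [
            "Target-ADE enrichment scan",
            "==========================",
            f"drug universe          {len(self.model.universe):>8d}",
            f"targets                {t['target_id'].nunique():>8d}",
            f"adverse effects        {t['ade_id'].nunique():>8d}",
            f"pairs scanned          {self.n_pairs:>8d}",
            f"selected (EF>5, q<0.05, tp>=3) {len(sel):>8d}",
            f"median EF | max EF     {t['ef'].median():8.3g} | {t['ef'].max():.3g}",
            f"fraction q < 0.05      {float((t['q'] < 0.05).mean()):8.4f}",
        ]
        return "\n".join(lines)
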