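"""Tabular input/output and reference-standard construction filters.

All files are tab-separated UTF-8 with a header row. The similarity matrix
dialect has the drug id in the first column and one column per drug;
association tables have columns ``drug_id``, ``entity_id`` plus optional
metadata. Reference-standard filters mirror common chemogenomics practice:
drop poorly specified or low-potency activity records (IC50/EC50/Ki above a
cutoff, threshold-only reports), collapse repeated assays of one drug-target
pair into a single edge, and keep only entities supported by a minimum
number of distinct drugs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .similarity import SimilarityMatrix

__all__ = [
    "DrugCatalog",
    "ActivityRecord",
    "AssociationTable",
    "read_similarity_matrix",
    "read_associations",
    "read_smiles",
    "filter_activity_records",
    "apply_min_degree_filter",
    "write_table",
]

#: Assay comment labels treated as "not well specified" and dropped.
DEFAULT_EXCLUDED_LABELS = frozenset(
    {"not determined", "not active", "not tested", "no inhibition",
     "potential missing data"}
)

#: Potency cutoff in micromolar; records weaker than this are dropped.
DEFAULT_MAX_POTENCY_UM = 50.0


def _normalize_id(raw: str) -> str:
    return str(raw).strip().casefold()


@dataclass
class DrugCatalog:
    """Registry of drugs with optional SMILES and ATC class labels.

    Drug ids are normalized (trimmed, case-folded) and must be unique.
    """

    drug_ids: list[str]
    smiles: Optional[dict[str, str]] = None
    atc_codes: Optional[dict[str, list[str]]] = None

    def __post_init__(self) -> None:
        self.drug_ids = [_normalize_id(d) for d in self.drug_ids]
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids in catalog after normalization")
        if self.smiles is not None:
            self.smiles = {_normalize_id(k): v for k, v in self.smiles.items()}
        if self.atc_codes is not None:
            self.atc_codes = {_normalize_id(k): list(v) for k, v in self.atc_codes.items()}

    def __contains__(self, drug_id: str) -> bool:
        return _normalize_id(drug_id) in set(self.drug_ids)

    def drugs_in_class(self, atc_class: str) -> list[str]:
        if self.atc_codes is None:
            return []
        return [d for d in self.drug_ids if atc_class in self.atc_codes.get(d, [])]


@dataclass(frozen=True)
class ActivityRecord:
    """One raw bioactivity measurement for a drug against a target.

    ``value`` is the reported potency in micromolar (``None`` when the assay
    reported no number); ``relation`` qualifies it (``=``, ``>``, ``<``,
    ``>=``, ``<=`` or ``unspecified``) and is only meaningful together with a
    value. ``comment_label`` carries free-text assay annotations such as
    "not determined".
    """

    drug_id: str
    target_id: str
    measure: str = "other"  # IC50 | EC50 | Ki | other
    relation: str = "unspecified"
    value: Optional[float] = None
    comment_label: str = ""


class AssociationTable:
    """A bipartite edge set: drugs x targets or drugs x adverse effects.

    Edges are deduplicated (drug_id, entity_id) pairs. Optional per-edge
    metadata columns are carried alongside.
    """

    VALID_KINDS = ("drug_target", "drug_ade")

    def __init__(self, kind: str, edges: pd.DataFrame):
        if kind not in self.VALID_KINDS:
            raise ValueError(f"kind must be one of {self.VALID_KINDS}, got {kind!r}")
        if not {"drug_id", "entity_id"}.issubset(edges.columns):
            raise ValueError("edges need columns drug_id, entity_id")
        edges = edges.copy()
        edges["drug_id"] = edges["drug_id"].map(_normalize_id)
        edges["entity_id"] = edges["entity_id"].astype(str).str.strip()
        edges = edges.drop_duplicates(subset=["drug_id", "entity_id"], keep="first")
        overlap = set(edges["drug_id"]) & set(edges["entity_id"])
        if overlap:
            raise ValueError(f"drug and entity id namespaces overlap: {sorted(overlap)[:5]}")
        self.kind = kind
        self.edges = edges.reset_index(drop=True)

    @classmethod
    def from_pairs(cls, kind: str, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        df = pd.DataFrame(list(pairs), columns=["drug_id", "entity_id"])
        return cls(kind, df)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.edges["drug_id"].unique())

    @property
    def entities(self) -> list[str]:
        return sorted(self.edges["entity_id"].unique())

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["drug_id"], self.edges["entity_id"]))

    def drugs_of(self, entity_id: str) -> set[str]:
        mask = self.edges["entity_id"] == entity_id
        return set(self.edges.loc[mask, "drug_id"])

    def entities_of(self, drug_id: str) -> set[str]:
        mask = self.edges["drug_id"] == _normalize_id(drug_id)
        return set(self.edges.loc[mask, "entity_id"])

    def entity_degree(self) -> pd.Series:
        return self.edges.groupby("entity_id")["drug_id"].nunique()

    def restrict_drugs(self, drugs: Iterable[str]) -> "AssociationTable":
        keep = {_normalize_id(d) for d in drugs}
        return AssociationTable(self.kind, self.edges[self.edges["drug_id"].isin(keep)])


def read_similarity_matrix(
    path: str | Path,
    policy: str = "max",
    catalog: Optional[DrugCatalog] = None,
) -> SimilarityMatrix:
    """Read a square drug x drug similarity matrix from TSV.

    Parameters
    ----------
    policy : {"max", "mean", "strict"}
        How to symmetrize asymmetric cells (pairwise alignment scores need
        not be symmetric): keep the larger, average, or refuse beyond 1e-9.
    catalog : DrugCatalog, optional
        If given, every matrix id must exist in the catalog.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    row_ids = [_normalize_id(i) for i in df.index]
    col_ids = [_normalize_id(c) for c in df.columns]
    if row_ids != col_ids:
        raise ValueError("similarity matrix is not square: row/column ids differ")
    values = df.to_numpy(dtype=float)
    tol = 1e-9
    if np.any(values < -tol) or np.any(values > 1 + tol):
        bad = values[(values < -tol) | (values > 1 + tol)]
        raise ValueError(f"similarity value out of range [0, 1]: {bad.flat[0]}")
    if catalog is not None:
        unknown = [d for d in row_ids if d not in set(catalog.drug_ids)]
        if unknown:
            raise ValueError(f"drug ids not in catalog: {unknown}")
    if policy == "max":
        values = np.maximum(values, values.T)
    elif policy == "mean":
        values = (values + values.T) / 2.0
    elif policy == "strict":
        if not np.allclose(values, values.T, atol=tol):
            raise ValueError("matrix is asymmetric and policy is 'strict'")
    else:
        raise ValueError(f"unknown symmetrization policy {policy!r}")
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(row_ids, values)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=sim.drug_ids, columns=sim.drug_ids)
    df.index.name = "drug_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_associations(path: str | Path, kind: str) -> AssociationTable:
    """Read a drug-entity edge list from a two-or-more column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (drug_id, entity_id)")
    df = df.rename(columns={df.columns[0]: "drug_id", df.columns[1]: "entity_id"})
    bad = df.index[df["drug_id"].isna() | df["entity_id"].isna()]
    if len(bad):
        # +2: one for the header, one for 1-based line numbers
        raise ValueError(f"{path}: malformed row at line {bad[0] + 2}")
    if df.empty:
        raise ValueError(f"{path}: no edges")
    return AssociationTable(kind, df)


def read_smiles(path: str | Path) -> dict[str, str]:
    """Read a (drug_id, smiles) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("SMILES file needs columns drug_id, smiles")
    return {_normalize_id(r.iloc[0]): str(r.iloc[1]) for _, r in df.iterrows()}


def filter_activity_records(
    records: Iterable[ActivityRecord],
    max_potency_uM: float = DEFAULT_MAX_POTENCY_UM,
    excluded_labels: frozenset[str] | set[str] = DEFAULT_EXCLUDED_LABELS,
) -> AssociationTable:
    """Build the drug-target reference standard from raw activity records.

    Applies, in order: drop records whose comment label matches the excluded
    set (case-insensitive); drop threshold-only potencies (relation ``>`` or
    ``>=`` - "greater than X" reports carry no usable number); drop records
    with potency above ``max_potency_uM``; then collapse surviving records of
    one (drug, target) pair into a single edge, keeping the lowest-potency
    record's assay details as representative metadata. Negative potencies are
    rejected with a warning, not fatally.
    """
    excluded = {lbl.casefold() for lbl in excluded_labels}
    rows = []
    for rec in records:
        if rec.comment_label and rec.comment_label.strip().casefold() in excluded:
            continue
        if rec.value is not None and rec.value < 0:
            warnings.warn(
                f"negative potency {rec.value} for ({rec.drug_id}, {rec.target_id}); "
                "record skipped"
            )
            continue
        if rec.relation in (">", ">="):
            continue
        if rec.value is not None and rec.value > max_potency_uM:
            continue
        rows.append(
            {
                "drug_id": _normalize_id(rec.drug_id),
                "entity_id": rec.target_id.strip(),
                "measure": rec.measure,
                "relation": rec.relation,
                "value": np.inf if rec.value is None else rec.value,
            }
        )
    if not rows:
        return AssociationTable.from_pairs("drug_target", [])
    df = pd.DataFrame(rows)
    df = df.sort_values(["drug_id", "entity_id", "value"], kind="stable")
    df = df.drop_duplicates(subset=["drug_id", "entity_id"], keep="first")
    df["value"] = df["value"].replace(np.inf, np.nan)
    return AssociationTable("drug_target", df.reset_index(drop=True))


def apply_min_degree_filter(assoc: AssociationTable, min_drugs: int = 5) -> AssociationTable:
    """Drop entities (targets or ADEs) supported by fewer than ``min_drugs``
    distinct drugs, with all their edges.

    Single-pass: degrees are taken on the input table and the filter is not
    re-applied after removals.
    """
    if len(assoc) == 0:
        raise ValueError("association table is empty")
    deg = assoc.entity_degree()
    keep = set(deg.index[deg >= min_drugs])
    return AssociationTable(assoc.kind, assoc.edges[assoc.edges["entity_id"].isin(keep)])


def write_table(rows: pd.DataFrame | AssociationTable, path: str | Path) -> None:
    """Write a result table (or association table) as TSV.

    Stable column order, header always present, floats at 6 significant
    digits so repeated runs are byte-identical.
    """
    df = rows.edges if isinstance(rows, AssociationTable) else rows
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
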