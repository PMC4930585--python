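"""Seeded synthetic datasets with the coupled structure the pipeline assumes.

The generator emulates two bipartite networks tied together by a planted
causal map. Drug-target edges are i.i.d. Bernoulli. A set of planted
target -> adverse-effect links defines the mechanism of toxicity: each
binder of a causal target shows the linked adverse effect with penetrance
``penetrance``; on top of that, spurious drug-ADE edges appear at
``background_ade_rate``. Drug-drug similarity directly instantiates the
guilt-by-association premise: pairs sharing at least one target draw their
similarity from a high Beta distribution, all other pairs from a low one,
so signal strength is a single knob (the gap between the two means).

ATC-like drug classes are assigned from the target-sharing graph (connected
components, chunked to a maximum class size) so that leave-class-out
validation removes genuinely similar neighbors, not a random subset.

Default parameters define the strong-signal reference condition:
500 drugs x 100 targets x 150 adverse effects, drug-target edge probability
0.02 (about 10 binders per target, comfortably above the minimum-support
filter of 5), 60 planted causal links with penetrance 0.8, background ADE
rate 0.02, similarity Beta(4, 1) (mean 0.8) for target-sharing pairs versus
Beta(1, 4) (mean 0.2) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import AssociationTable, DrugCatalog
from .similarity import SimilarityMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "null_permute",
    "strong_signal_config",
    "null_calibration_config",
    "small_fixture_config",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the coupled synthetic data-generating process."""

    n_drugs: int = 500
    n_targets: int = 100
    n_ades: int = 150
    p_edge_dt: float = 0.02
    n_causal_links: int = 60
    penetrance: float = 0.8
    background_ade_rate: float = 0.02
    sim_high: tuple[float, float] = (4.0, 1.0)  # Beta(a, b), mean 0.8
    sim_low: tuple[float, float] = (1.0, 4.0)  # Beta(a, b), mean 0.2
    class_size_cap: int = 25
    min_causal_binders: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_edge_dt", "penetrance", "background_ade_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if min(self.n_drugs, self.n_targets, self.n_ades) < 1:
            raise ValueError("network dimensions must be positive")
        mean_high = self.sim_high[0] / sum(self.sim_high)
        mean_low = self.sim_low[0] / sum(self.sim_low)
        if self.p_edge_dt > 0 and mean_high < mean_low:
            raise ValueError("sim_high mean must be >= sim_low mean")


def strong_signal_config(seed: int = 0) -> SyntheticConfig:
    """The strong-signal reference condition (the class defaults)."""
    return SyntheticConfig(seed=seed)


def null_calibration_config(seed: int = 0) -> SyntheticConfig:
    """Dense, signal-free condition for null calibration of the scan.

    100 targets x 100 ADEs give exactly 10,000 scanned pairs; entity degrees
    around 50 of 500 drugs keep the discrete one-sided Fisher p-value close
    to uniform (sparser margins make it visibly conservative).
    """
    return SyntheticConfig(
        n_drugs=500,
        n_targets=100,
        n_ades=100,
        p_edge_dt=0.1,
        n_causal_links=0,
        penetrance=0.0,
        background_ade_rate=0.1,
        seed=seed,
    )


def small_fixture_config(seed: int = 0) -> SyntheticConfig:
    """Small dataset (50 drugs x 20 targets x 30 ADEs) for fast tests."""
    return SyntheticConfig(
        n_drugs=50,
        n_targets=20,
        n_ades=30,
        p_edge_dt=0.15,
        n_causal_links=10,
        penetrance=0.8,
        background_ade_rate=0.05,
        class_size_cap=10,
        seed=seed,
    )


@dataclass
class SyntheticDataset:
    """Generated networks plus the planted ground truth."""

    catalog: DrugCatalog
    sim: SimilarityMatrix
    dt: AssociationTable
    da: AssociationTable
    causal_pairs: list[tuple[str, str]]
    true_dt_edges: set[tuple[str, str]] = field(default_factory=set)
    config: Optional[SyntheticConfig] = None


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset from the configured process; reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    drugs = _ids("d", config.n_drugs)
    targets = _ids("t", config.n_targets)
    ades = _ids("e", config.n_ades)

    dt_mat = rng.random((config.n_drugs, config.n_targets)) < config.p_edge_dt
    if not dt_mat.any():
        raise ValueError("configuration produced zero drug-target edges")

    # plant causal target->ADE links on targets with enough binders so the
    # pairs survive the minimum-support filter
    degree = dt_mat.sum(axis=0)
    eligible = np.flatnonzero(degree >= config.min_causal_binders)
    causal_pairs_idx: list[tuple[int, int]] = []
    if config.n_causal_links > 0:
        if len(eligible) == 0:
            raise ValueError("no target has enough binders to plant causal links")
        n_slots = len(eligible) * config.n_ades
        n_links = min(config.n_causal_links, n_slots)
        flat = rng.choice(n_slots, size=n_links, replace=False)
        causal_pairs_idx = [
            (int(eligible[f // config.n_ades]), int(f % config.n_ades)) for f in flat
        ]

    da_mat = rng.random((config.n_drugs, config.n_ades)) < config.background_ade_rate
    for t_idx, e_idx in causal_pairs_idx:
        binders = np.flatnonzero(dt_mat[:, t_idx])
        shows = rng.random(len(binders)) < config.penetrance
        da_mat[binders[shows], e_idx] = True

    # similarity conditional on target sharing
    share = (dt_mat.astype(np.int32) @ dt_mat.T.astype(np.int32)) > 0
    high = rng.beta(*config.sim_high, size=(config.n_drugs, config.n_drugs))
    low = rng.beta(*config.sim_low, size=(config.n_drugs, config.n_drugs))
    values = np.where(share, high, low)
    values = np.triu(values, k=1)
    values = values + values.T
    np.fill_diagonal(values, 1.0)
    sim = SimilarityMatrix(drugs, values)

    # ATC-like classes: connected components of the target-sharing graph,
    # chunked to the class-size cap
    adj = csr_matrix(share & ~np.eye(config.n_drugs, dtype=bool))
    _, comp = connected_components(adj, directed=False)
    atc: dict[str, list[str]] = {}
    label = 0
    for c in np.unique(comp):
        members = np.flatnonzero(comp == c)
        for start in range(0, len(members), config.class_size_cap):
            label += 1
            for m in members[start : start + config.class_size_cap]:
                atc[drugs[m]] = [f"atc{label:03d}"]
    catalog = DrugCatalog(drug_ids=drugs, atc_codes=atc)

    di, ti = np.nonzero(dt_mat)
    dt = AssociationTable(
        "drug_target",
        pd.DataFrame({"drug_id": [drugs[i] for i in di], "entity_id": [targets[j] for j in ti]}),
    )
    di, ei = np.nonzero(da_mat)
    da = AssociationTable(
        "drug_ade",
        pd.DataFrame({"drug_id": [drugs[i] for i in di], "entity_id": [ades[j] for j in ei]}),
    )
    return SyntheticDataset(
        catalog=catalog,
        sim=sim,
        dt=dt,
        da=da,
        causal_pairs=sorted((targets[t], ades[e]) for t, e in causal_pairs_idx),
        true_dt_edges=dt.edge_set(),
        config=config,
    )


def random_bipartite(
    kind: str,
    drugs: list[str],
    entities: list[str],
    degree_range: tuple[int, int] = (5, 30),
    seed: int = 0,
) -> AssociationTable:
    """Random edge table where every entity gets a uniform number of
    distinct drugs in ``degree_range`` (inclusive), guaranteeing the
    minimum-support filter is satisfied by construction."""
    rng = np.random.default_rng(seed)
    lo, hi = degree_range
    pairs: list[tuple[str, str]] = []
    for ent in entities:
        k = int(rng.integers(lo, hi + 1))
        for i in rng.choice(len(drugs), size=k, replace=False):
            pairs.append((drugs[i], ent))
    return AssociationTable.from_pairs(kind, pairs)


def null_permute(ds: SyntheticDataset, seed: int) -> SyntheticDataset:
    """Permute the drug labels of the drug-ADE table.

    Destroys the target-ADE coupling while preserving every drug's ADE
    degree sequence (each drug's ADE set is reassigned wholesale to another
    drug). Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    drugs = list(ds.catalog.drug_ids)
    perm = rng.permutation(len(drugs))
    mapping = {drugs[i]: drugs[perm[i]] for i in range(len(drugs))}
    edges = ds.da.edges.copy()
    edges["drug_id"] = edges["drug_id"].map(mapping)
    return replace(ds, da=AssociationTable("drug_ade", edges), causal_pairs=[])
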