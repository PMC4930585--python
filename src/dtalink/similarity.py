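"""Drug-drug similarity: the pharmacophoric overlap normalization, the
Tanimoto coefficient, and the :class:`SimilarityMatrix` container.

3D pharmacophoric similarity between two aligned molecules A and B is the
overlap volume of matched feature types normalized by the larger
self-overlap,

    Sim(A, B) = O(A, B) / max(O(A, A), O(B, B)),

which maps raw overlap volumes onto [0, 1] (1 = maximum similarity).
Conformer generation and shape alignment are external: this module turns
precomputed overlap volumes into scores, validates full matrices, and can
build a 2D Tanimoto matrix from binary fingerprints as an alternative
similarity backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "normalize_overlap",
    "tanimoto",
    "matrix_from_fingerprints",
    "maccs_fingerprints",
]

_TOL = 1e-9


@dataclass
class SimilarityMatrix:
    """Symmetric drug x drug similarity scores in [0, 1] with unit diagonal.

    Parameters
    ----------
    drug_ids : list of str
        Row/column labels, order defines the array layout.
    values : ndarray of shape (n, n)
        Scores; must be symmetric, within [0, 1] and 1 on the diagonal.
    """

    drug_ids: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.drug_ids = [str(d) for d in self.drug_ids]
        n = len(self.drug_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} drug ids"
            )
        if len(set(self.drug_ids)) != n:
            raise ValueError("duplicate drug ids in similarity matrix")
        self.validate()
        self._index = {d: i for i, d in enumerate(self.drug_ids)}

    def validate(self) -> None:
        v = self.values
        if v.size == 0:
            raise ValueError("empty similarity matrix")
        if np.any(v < -_TOL) or np.any(v > 1 + _TOL):
            bad = v[(v < -_TOL) | (v > 1 + _TOL)]
            raise ValueError(f"similarity values out of [0, 1]: e.g. {bad.flat[0]}")
        if not np.allclose(v, v.T, atol=_TOL):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=_TOL):
            raise ValueError("similarity matrix diagonal is not 1")
        # clamp numeric dust so downstream code sees exact bounds
        np.clip(v, 0.0, 1.0, out=v)
        np.fill_diagonal(v, 1.0)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def index_of(self, drug_id: str) -> int:
        try:
            return self._index[drug_id]
        except KeyError:
            raise KeyError(f"drug {drug_id!r} not in similarity matrix") from None

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def subset(self, drug_ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.index_of(d) for d in drug_ids]
        return SimilarityMatrix(list(drug_ids), self.values[np.ix_(idx, idx)])


def normalize_overlap(o_ab: float, o_aa: float, o_bb: float) -> float:
    """Normalize a pairwise overlap volume into a similarity score.

    ``Sim(A, B) = O(A, B) / max(O(A, A), O(B, B))`` where ``O(A, B)`` is the
    overlap of matched pharmacophoric sites between the aligned pair and the
    denominator is the larger self-overlap, so the score lies in [0, 1].

    Raises
    ------
    ValueError
        If a self-overlap is non-positive, the pair overlap is negative, or
        the pair overlap exceeds the larger self-overlap (score would exceed 1).
    """
    if o_aa <= 0 or o_bb <= 0:
        raise ValueError("self-overlap must be positive")
    if o_ab < 0:
        raise ValueError("pair overlap must be nonnegative")
    denom = max(o_aa, o_bb)
    if o_ab > denom * (1 + _TOL):
        raise ValueError(
            f"pair overlap {o_ab} exceeds max self-overlap {denom}; score would be > 1"
        )
    return min(o_ab / denom, 1.0)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| between two binary fingerprints."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fingerprints must be 1-D and of equal length")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("both fingerprints are all-zero; Tanimoto undefined")
    return int(np.logical_and(a, b).sum()) / union


def matrix_from_fingerprints(fps: Mapping[str, np.ndarray]) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix over a fingerprint set.

    Parameters
    ----------
    fps : mapping drug_id -> binary bit vector (equal lengths, >= 1 set bit).
    """
    if len(fps) < 2:
        raise ValueError("need at least 2 drugs to build a similarity matrix")
    ids = list(fps.keys())
    mat = np.array([np.asarray(fps[d], dtype=bool) for d in ids])
    if mat.ndim != 2:
        raise ValueError("fingerprints must all have the same length")
    counts = mat.sum(axis=1)
    if np.any(counts == 0):
        empty = [ids[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"all-zero fingerprints for: {empty}")
    inter = (mat.astype(np.int64) @ mat.T.astype(np.int64)).astype(float)
    union = counts[:, None] + counts[None, :] - inter
    values = inter / union
    return SimilarityMatrix(ids, values)


def maccs_fingerprints(smiles: Mapping[str, str]) -> dict[str, np.ndarray]:
    """MACCS-key fingerprints from SMILES via RDKit (optional dependency)."""
    try:
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys
    except ImportError as exc:  # pragma: no cover - depends on extra
        raise ImportError(
            "rdkit is required for MACCS fingerprints; install dtalink[chem]"
        ) from exc
    out: dict[str, np.ndarray] = {}
    for drug_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {drug_id!r}: {smi!r}")
        fp = MACCSkeys.GenMACCSKeys(mol)
        out[drug_id] = np.array([fp.GetBit(i) for i in range(fp.GetNumBits())], dtype=bool)
    return out
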