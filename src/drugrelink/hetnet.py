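"""Drug-disease heterogeneous network assembly.

The heterogeneous adjacency stacks the drug similarity block M_r, the
disease similarity block M_d and the binary association block M_rd:

    M_h = [[M_r,    M_rd],
           [M_rd.T, M_d ]]            A = M_h + I

Drugs occupy the first N_r rows, diseases the remaining N_d.  A is
degree-normalized symmetrically (D^-1/2 A D^-1/2) with weighted degrees, and
the initial node feature matrix places the associations off-diagonal:

    X0 = [[0,      M_rd],
          [M_rd.T, 0   ]]

so each node's input feature vector is its association profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "AssociationMatrix",
    "HeterogeneousNetwork",
    "build_association_matrix",
    "build_heterogeneous_network",
    "mask_test_edges",
]


@dataclass
class AssociationMatrix:
    """Binary drug x disease association matrix with id orderings."""

    drug_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValueError(
                f"association shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.disease_ids)} diseases"
            )
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("association matrix must be binary")

    @property
    def positives(self) -> list[tuple[str, str]]:
        return [
            (self.drug_ids[i], self.disease_ids[j])
            for i, j in zip(*np.nonzero(self.values))
        ]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.drug_ids), list(self.disease_ids), self.values.copy())


@dataclass
class HeterogeneousNetwork:
    drug_ids: list[str]
    disease_ids: list[str]
    m_h: np.ndarray
    a: np.ndarray = field(init=False)
    degree: np.ndarray = field(init=False)
    a_norm: np.ndarray = field(init=False)
    x0: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.drug_ids) + len(self.disease_ids)
        if self.m_h.shape != (n, n):
            raise ValueError(f"m_h shape {self.m_h.shape}, expected ({n}, {n})")
        if not np.allclose(self.m_h, self.m_h.T, atol=1e-10):
            raise ValueError("m_h is not symmetric")
        self.a = self.m_h + np.eye(n)
        deg = self.a.sum(axis=1)
        assert (deg >= 1.0 - 1e-12).all(), "self-loops guarantee degree >= 1"
        self.degree = np.diag(deg)
        d_inv_sqrt = 1.0 / np.sqrt(deg)
        self.a_norm = self.a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
        nr = len(self.drug_ids)
        m_rd = self.m_h[:nr, nr:]
        x0 = np.zeros_like(self.m_h)
        x0[:nr, nr:] = m_rd
        x0[nr:, :nr] = m_rd.T
        self.x0 = x0

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.drug_ids) + len(self.disease_ids)


def build_association_matrix(
    pairs: list[tuple[str, str]],
    drug_ids: list[str],
    disease_ids: list[str],
) -> AssociationMatrix:
    """Binary matrix with entry (i, j) = 1 iff the pair appears; duplicates collapse."""
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    disease_index = {d: j for j, d in enumerate(disease_ids)}
    if len(drug_index) != len(drug_ids):
        raise ValueError("duplicate drug ids")
    if len(disease_index) != len(disease_ids):
        raise ValueError("duplicate disease ids")
    m = np.zeros((len(drug_ids), len(disease_ids)))
    for r, d in pairs:
        if r not in drug_index:
            raise KeyError(f"unknown drug id {r!r} in association pairs")
        if d not in disease_index:
            raise KeyError(f"unknown disease id {d!r} in association pairs")
        m[drug_index[r], disease_index[d]] = 1.0
    return AssociationMatrix(list(drug_ids), list(disease_ids), m)


def build_heterogeneous_network(
    m_r: SimilarityMatrix,
    m_d: SimilarityMatrix,
    m_rd: AssociationMatrix,
) -> HeterogeneousNetwork:
    """Assemble M_h, A = M_h + I, degrees, normalized adjacency and X0.

    Similarity blocks keep their continuous weights; degrees are weighted
    row sums of A.
    """
    if m_r.ids != m_rd.drug_ids:
        raise ValueError("drug id ordering mismatch between drug similarity and associations")
    if m_d.ids != m_rd.disease_ids:
        raise ValueError("disease id ordering mismatch between disease similarity and associations")
    nr, nd = len(m_r.ids), len(m_d.ids)
    m_h = np.zeros((nr + nd, nr + nd))
    m_h[:nr, :nr] = m_r.values
    m_h[nr:, nr:] = m_d.values
    m_h[:nr, nr:] = m_rd.values
    m_h[nr:, :nr] = m_rd.values.T
    return HeterogeneousNetwork(list(m_r.ids), list(m_d.ids), m_h)


def mask_test_edges(
    m_rd: AssociationMatrix,
    held_out: list[tuple[str, str]],
) -> AssociationMatrix:
    """Zero out held-out positives in a copy (leakage control for evaluation).

    Masking an entry that is already 0 raises: that signals fold bookkeeping
    gone wrong.
    """
    out = m_rd.copy()
    drug_index = {d: i for i, d in enumerate(out.drug_ids)}
    disease_index = {d: j for j, d in enumerate(out.disease_ids)}
    for r, d in held_out:
        i, j = drug_index[r], disease_index[d]
        if out.values[i, j] != 1.0:
            raise ValueError(f"cannot mask pair ({r!r}, {d!r}): not a known association")
        out.values[i, j] = 0.0
    return out
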