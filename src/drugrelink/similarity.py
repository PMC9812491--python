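"""Drug and disease similarity computation.

Drug similarity is the Jaccard index between per-drug feature sets (chemical
substructures, target-protein domains, or gene annotations).  Disease
similarity is DAG-based semantic similarity in the Wang style: each disease
carries a directed acyclic graph of ancestor terms (MeSH-tree like), every
ancestor contributes semantically with a decay factor ``delta`` per edge, and
two diseases are similar in proportion to the contributions of their shared
ancestor terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "DrugFeatureSet",
    "DiseaseDAG",
    "SemanticProfile",
    "SimilarityMatrix",
    "jaccard_similarity",
    "drug_similarity_matrix",
    "semantic_profile",
    "disease_semantic_similarity",
    "disease_similarity_matrix",
    "fuse_drug_similarities",
]

FEATURE_KINDS = ("che", "dom", "anno")


@dataclass
class DrugFeatureSet:
    """A drug's feature set of one kind (che / dom / anno)."""

    drug_id: str
    kind: str
    features: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}")
        self.features = frozenset(self.features)


@dataclass
class DiseaseDAG:
    """The ancestor DAG of one disease.

    ``nodes`` is the ancestor closure of ``disease_id`` (the disease itself
    included); ``edges`` are (child, parent) pairs.  ``delta`` is the semantic
    contribution decay per edge, in (0, 1].
    """

    disease_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    delta: float = 0.5

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        self.edges = frozenset((str(c), str(p)) for c, p in self.edges)
        if not 0.0 < self.delta <= 1.0:
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        if self.disease_id not in self.nodes:
            raise ValueError(f"disease {self.disease_id!r} missing from its own DAG nodes")
        for c, p in self.edges:
            if c not in self.nodes or p not in self.nodes:
                raise ValueError(f"edge ({c!r}, {p!r}) references a term outside the node set")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class SemanticProfile:
    """Per-term semantic contributions D_d(s) and their sum DV(d)."""

    disease_id: str
    contributions: dict[str, float]
    semantic_value: float = field(init=False)

    def __post_init__(self) -> None:
        if self.contributions.get(self.disease_id) != 1.0:
            raise ValueError("the disease's own contribution must be exactly 1")
        for term, v in self.contributions.items():
            if not 0.0 < v <= 1.0:
                raise ValueError(f"contribution of {term!r} out of (0, 1]: {v}")
        self.semantic_value = float(sum(self.contributions.values()))


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with an explicit id ordering."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} does not match {n} ids")
        self.validate()

    def validate(self, atol: float = 1e-12) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("similarity matrix diagonal is not 1")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("similarity values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)


def jaccard_similarity(a, b) -> float:
    """Jaccard index |a∩b| / |a∪b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def _check_unique(order: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in order:
        if x in seen:
            raise ValueError(f"duplicate {what} id {x!r} in ordering")
        seen.add(x)


def drug_similarity_matrix(features: dict[str, set[str]], drug_order: list[str]) -> SimilarityMatrix:
    """Pairwise Jaccard similarity over ``drug_order``.

    Drugs missing from ``features`` are treated as having an empty feature
    set.  The diagonal is forced to 1 regardless of emptiness.
    """
    _check_unique(drug_order, "drug")
    sets = [frozenset(features.get(d, ())) for d in drug_order]
    n = len(drug_order)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = jaccard_similarity(sets[i], sets[j])
    return SimilarityMatrix(list(drug_order), m)


def semantic_profile(dag: DiseaseDAG) -> SemanticProfile:
    """Semantic contribution of every term in a disease's ancestor DAG.

    The disease itself contributes 1; any other term s contributes
    ``delta * max(contribution of children of s)``, i.e. contributions decay
    by ``delta`` along the best (shortest, under decay) upward path from the
    disease.  Terms are processed in topological order so each child is
    finished before its parents.
    """
    g = dag.to_networkx()
    try:
        topo = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cyc = nx.find_cycle(g)
        raise ValueError(f"disease DAG for {dag.disease_id!r} contains a cycle through edge {cyc[0][:2]}") from None

    contrib: dict[str, float] = {dag.disease_id: 1.0}
    for s in topo:  # children precede parents (edges point child -> parent)
        if s == dag.disease_id:
            continue
        children = [c for c, _ in g.in_edges(s)]
        best = max((contrib[c] for c in children if c in contrib), default=None)
        if best is None:
            raise ValueError(f"term {s!r} is not reachable from disease {dag.disease_id!r}")
        contrib[s] = dag.delta * best
    return SemanticProfile(dag.disease_id, contrib)


def disease_semantic_similarity(p1: SemanticProfile, p2: SemanticProfile) -> float:
    """Shared-ancestor similarity: Σ_{s∈V1∩V2}(D1(s)+D2(s)) / (DV1+DV2)."""
    shared = p1.contributions.keys() & p2.contributions.keys()
    if not shared:
        return 0.0
    num = sum(p1.contributions[s] + p2.contributions[s] for s in shared)
    return num / (p1.semantic_value + p2.semantic_value)


def disease_similarity_matrix(dags: dict[str, DiseaseDAG], order: list[str]) -> SimilarityMatrix:
    """Pairwise semantic similarity over ``order``.

    Diseases with no DAG entry get an identity row (self-similarity 1, zero
    elsewhere) so matrix shapes stay aligned with the association table.
    """
    _check_unique(order, "disease")
    deltas = {dag.delta for dag in dags.values()}
    if len(deltas) > 1:
        raise ValueError(f"inconsistent delta across disease DAGs: {sorted(deltas)}")
    profiles = {d: semantic_profile(dags[d]) for d in order if d in dags}
    n = len(order)
    m = np.eye(n)
    for i in range(n):
        pi = profiles.get(order[i])
        if pi is None:
            continue
        for j in range(i + 1, n):
            pj = profiles.get(order[j])
            if pj is None:
                continue
            m[i, j] = m[j, i] = disease_semantic_similarity(pi, pj)
    return SimilarityMatrix(list(order), m)


def fuse_drug_similarities(mats: list[SimilarityMatrix], mode: str = "mean"):
    """Combine per-feature-kind drug similarity matrices.

    mode="mean": element-wise arithmetic mean with the diagonal re-forced to
    1 — the single-network pathway.  mode="per_network": the list is passed
    through unchanged for pipelines that embed each similarity network
    separately.
    """
    if not mats:
        raise ValueError("need at least one similarity matrix")
    ref = mats[0].ids
    for m in mats[1:]:
        for pos, (a, b) in enumerate(zip(ref, m.ids)):
            if a != b:
                raise ValueError(f"id ordering mismatch at position {pos}: {a!r} vs {b!r}")
        if len(m.ids) != len(ref):
            raise ValueError("id ordering length mismatch")
    if mode == "per_network":
        return list(mats)
    if mode != "mean":
        raise ValueError(f"unknown fusion mode {mode!r}")
    fused = np.mean([m.values for m in mats], axis=0)
    np.fill_diagonal(fused, 1.0)
    return SimilarityMatrix(list(ref), fused)
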