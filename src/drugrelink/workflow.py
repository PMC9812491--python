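"""Glue from input files to similarity matrices and trained models.

This is the high-level path the CLI drives: read feature / DAG / association
tables, compute per-kind drug similarities and the disease semantic
similarity, fuse, and hand off to the network builder, encoder and
classifier.
"""

from __future__ import annotations

from pathlib import Path

from . import io
from .evaluation import LabelledPairSet, sample_negatives
from .hetnet import build_association_matrix, build_heterogeneous_network
from .pair_cnn import CNNConfig, train_classifier
from .similarity import (
    FEATURE_KINDS,
    SimilarityMatrix,
    disease_similarity_matrix,
    drug_similarity_matrix,
    fuse_drug_similarities,
)
from .vgae import VGAEConfig, train_vgae

__all__ = ["load_inputs", "build_similarities", "train_full_model"]


def load_inputs(data_dir, delta: float = 0.5, kinds=FEATURE_KINDS):
    """Read feature, DAG and association tables from a dataset directory.

    Orderings are the sorted union of ids seen in any input so matrices stay
    aligned with the association table.
    """
    data_dir = Path(data_dir)
    features = {}
    for kind in kinds:
        p = data_dir / f"features_{kind}.tsv"
        if not p.exists():
            raise FileNotFoundError(f"missing feature file {p}")
        features[kind] = io.read_feature_file(p)
    dags = io.read_dag_file(data_dir / "disease_dags.tsv", delta=delta)
    positives = io.read_associations(data_dir / "associations.tsv")
    drug_ids = sorted({r for r, _ in positives} | {d for f in features.values() for d in f})
    disease_ids = sorted({d for _, d in positives} | set(dags))
    return features, dags, positives, drug_ids, disease_ids


def build_similarities(features, dags, drug_ids, disease_ids, fusion_mode: str = "mean"):
    """Per-kind drug similarities (fused per ``fusion_mode``) and disease similarity."""
    per_kind = [drug_similarity_matrix(features[k], drug_ids) for k in features]
    m_r = fuse_drug_similarities(per_kind, mode=fusion_mode)
    m_d = disease_similarity_matrix(dags, disease_ids)
    return m_r, m_d, per_kind


def train_full_model(
    m_r: SimilarityMatrix,
    m_d: SimilarityMatrix,
    positives,
    vgae_config: VGAEConfig | None = None,
    cnn_config: CNNConfig | None = None,
    seed: int = 0,
):
    """Train encoder and classifier on all known associations.

    Negatives for the classifier are sampled 1:1 from unobserved pairs.
    Returns (embeddings, cnn params, association matrix, traces).
    """
    drug_ids, disease_ids = m_r.ids, m_d.ids
    m_rd = build_association_matrix(positives, drug_ids, disease_ids)
    net = build_heterogeneous_network(m_r, m_d, m_rd)
    _, emb, vgae_trace = train_vgae(net, vgae_config, seed=seed)
    negatives = sample_negatives(m_rd, len(positives), seed=seed)
    pairset = LabelledPairSet(list(positives), negatives)
    pairs = pairset.positives + pairset.negatives
    labels = [1] * len(pairset.positives) + [0] * len(pairset.negatives)
    params, cnn_trace = train_classifier(
        emb, pairs, labels, drug_ids, disease_ids, cnn_config, seed=seed + 1)
    return emb, params, m_rd, {"vgae": vgae_trace, "cnn": cnn_trace}
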