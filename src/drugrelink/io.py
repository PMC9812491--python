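"""Delimited-text readers and writers for every artifact the pipeline touches.

All formats are plain TSV with a header row: drug feature memberships
(drug_id, feature_id), disease DAG edge lists (disease_id, child, parent —
a row (d, d, d) declares a singleton DAG), drug-disease association tables
(drug_id, disease_id), similarity matrices (ids as header row and first
column), node embeddings, pair predictions and metrics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hetnet import HeterogeneousNetwork
from .pair_cnn import PairPrediction
from .similarity import DiseaseDAG, SimilarityMatrix
from .vgae import NodeEmbeddings

__all__ = [
    "read_feature_file", "write_feature_file",
    "read_dag_file", "write_dag_file",
    "read_associations", "write_associations",
    "read_similarity_matrix", "write_similarity_matrix",
    "write_embeddings", "read_embeddings",
    "write_predictions", "write_metrics", "write_edge_list",
    "write_json", "read_json",
]

_SEP = "\t"


def read_feature_file(path) -> dict[str, set[str]]:
    """drug_id -> feature set from a two-column membership table."""
    df = pd.read_csv(path, sep=_SEP, dtype=str)
    if list(df.columns[:2]) != ["drug_id", "feature_id"]:
        raise ValueError(f"{path}: expected columns drug_id, feature_id, got {list(df.columns)}")
    out: dict[str, set[str]] = {}
    for drug, feat in zip(df["drug_id"], df["feature_id"]):
        out.setdefault(drug, set())
        if not pd.isna(feat):
            out[drug].add(feat)
    return out


def write_feature_file(features: dict[str, set[str]], path) -> None:
    rows = [(d, f) for d in sorted(features) for f in sorted(features[d])]
    pd.DataFrame(rows, columns=["drug_id", "feature_id"]).to_csv(path, sep=_SEP, index=False)


def read_dag_file(path, delta: float = 0.5) -> dict[str, DiseaseDAG]:
    """disease_id -> DiseaseDAG from a (disease_id, child, parent) edge list."""
    df = pd.read_csv(path, sep=_SEP, dtype=str)
    if list(df.columns[:3]) != ["disease_id", "child", "parent"]:
        raise ValueError(f"{path}: expected columns disease_id, child, parent")
    dags: dict[str, DiseaseDAG] = {}
    for disease, grp in df.groupby("disease_id", sort=True):
        nodes = {disease}
        edges = set()
        for c, p in zip(grp["child"], grp["parent"]):
            if c == disease and p == disease:
                continue  # singleton declaration
            nodes.update((c, p))
            edges.add((c, p))
        dags[disease] = DiseaseDAG(disease, frozenset(nodes), frozenset(edges), delta)
    return dags


def write_dag_file(dags: dict[str, DiseaseDAG], path) -> None:
    rows = []
    for d in sorted(dags):
        dag = dags[d]
        if dag.edges:
            rows += [(d, c, p) for c, p in sorted(dag.edges)]
        else:
            rows.append((d, d, d))
    pd.DataFrame(rows, columns=["disease_id", "child", "parent"]).to_csv(path, sep=_SEP, index=False)


def read_associations(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep=_SEP, dtype=str)
    if list(df.columns[:2]) != ["drug_id", "disease_id"]:
        raise ValueError(f"{path}: expected columns drug_id, disease_id")
    return list(dict.fromkeys(zip(df["drug_id"], df["disease_id"])))


def write_associations(pairs: list[tuple[str, str]], path) -> None:
    pd.DataFrame(pairs, columns=["drug_id", "disease_id"]).to_csv(path, sep=_SEP, index=False)


def read_similarity_matrix(path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep=_SEP, index_col=0)
    ids = [str(c) for c in df.columns]
    return SimilarityMatrix(ids, df.to_numpy(dtype=float))


def write_similarity_matrix(m: SimilarityMatrix, path) -> None:
    pd.DataFrame(m.values, index=m.ids, columns=m.ids).to_csv(path, sep=_SEP)


def write_embeddings(emb: NodeEmbeddings, drug_ids, disease_ids, path) -> None:
    d1 = emb.x2.shape[1]
    cols = ["node_id", "node_type"] + [f"v{i}" for i in range(d1)]
    rows = [
        [nid, typ, *emb.x2[k]]
        for k, (nid, typ) in enumerate(
            [(d, "drug") for d in drug_ids] + [(d, "disease") for d in disease_ids]
        )
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_SEP, index=False, float_format="%.10g")


def read_embeddings(path) -> tuple[NodeEmbeddings, list[str], list[str]]:
    df = pd.read_csv(path, sep=_SEP, dtype={"node_id": str})
    drugs = df[df["node_type"] == "drug"]
    diseases = df[df["node_type"] == "disease"]
    vec_cols = [c for c in df.columns if c.startswith("v")]
    x2 = np.vstack([drugs[vec_cols].to_numpy(float), diseases[vec_cols].to_numpy(float)])
    emb = NodeEmbeddings(x2, len(drugs), len(diseases))
    return emb, list(drugs["node_id"]), list(diseases["node_id"])


def write_predictions(preds: list[PairPrediction], path, sort: bool = False) -> None:
    if sort:
        preds = sorted(preds, key=lambda p: (-p.probability, p.drug_id, p.disease_id))
    rows = [(p.drug_id, p.disease_id, f"{p.probability:.10g}",
             "" if p.label is None else p.label) for p in preds]
    pd.DataFrame(rows, columns=["drug_id", "disease_id", "probability", "label"]).to_csv(
        path, sep=_SEP, index=False)


def write_metrics(report: dict[str, float], path) -> None:
    pd.DataFrame([report]).to_csv(path, sep=_SEP, index=False, float_format="%.10g")


def write_edge_list(net: HeterogeneousNetwork, path) -> None:
    """Heterogeneous network as (node_u, node_v, weight, edge_type) rows."""
    nr = net.n_drugs
    names = list(net.drug_ids) + list(net.disease_ids)
    rows = []
    for i in range(net.n_nodes):
        for j in range(i + 1, net.n_nodes):
            w = net.m_h[i, j]
            if w == 0:
                continue
            kind = ("drug-drug" if j < nr else
                    "disease-disease" if i >= nr else "drug-disease")
            rows.append((names[i], names[j], f"{w:.10g}", kind))
    pd.DataFrame(rows, columns=["node_u", "node_v", "weight", "edge_type"]).to_csv(
        path, sep=_SEP, index=False)


def save_cnn_params(params, path) -> None:
    """Single-file model snapshot (npz) with a format version field."""
    import json as _json
    from dataclasses import asdict

    from .pair_cnn import CNNConfig  # noqa: F401  (format owner)

    arrays = {"format_version": np.array(1)}
    for i, (w, b) in enumerate(params.conv):
        arrays[f"conv{i}_w"], arrays[f"conv{i}_b"] = w, b
    for i, (w, b) in enumerate(params.fc):
        arrays[f"fc{i}_w"], arrays[f"fc{i}_b"] = w, b
    arrays["out_w"], arrays["out_b"] = params.out
    arrays["config_json"] = np.array(_json.dumps(asdict(params.config)))
    np.savez(path, **arrays)


def load_cnn_params(path):
    import json as _json

    from .pair_cnn import CNNConfig, CNNParams

    with np.load(path, allow_pickle=False) as z:
        if int(z["format_version"]) != 1:
            raise ValueError(f"unsupported model format version {z['format_version']}")
        raw = _json.loads(str(z["config_json"]))
        config = CNNConfig(**{k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                              if isinstance(v, list) else v for k, v in raw.items()})
        conv, fc, i = [], [], 0
        while f"conv{i}_w" in z:
            conv.append((z[f"conv{i}_w"], z[f"conv{i}_b"]))
            i += 1
        i = 0
        while f"fc{i}_w" in z:
            fc.append((z[f"fc{i}_w"], z[f"fc{i}_b"]))
            i += 1
        return CNNParams(conv, fc, (z["out_w"], z["out_b"]), config)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
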