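"""Synthetic drug-disease data with planted, recoverable cluster structure.

The generator emulates the three inputs the pipeline consumes — per-kind
drug feature sets, disease ancestor DAGs, and a drug-disease association
table — with a shared latent clustering: drugs and diseases are assigned
round-robin to ``n_clusters`` groups; drugs of a cluster share most of a
per-kind signature feature set (plus noise features); diseases of a cluster
hang off a shared ancestor term ladder (so same-cluster diseases score high
under DAG semantic similarity); and associations are Bernoulli(p_in) for
matched drug/disease clusters and Bernoulli(p_out) otherwise.

Because the signal lives jointly in all three feature kinds, dropping a
kind degrades the drug similarity signal, which is what feature-ablation
experiments measure on this data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .similarity import FEATURE_KINDS, DiseaseDAG

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "write_dataset", "read_dataset"]


@dataclass
class SyntheticConfig:
    n_drugs: int = 100
    n_diseases: int = 80
    n_clusters: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    feature_pool: int = 300  # features per kind; signatures are disjoint slices of it
    signature_size: int = 30
    feature_overlap: float = 0.8  # fraction of the signature each member drug carries
    n_noise_features: int = 6  # extra features drawn from the whole pool per drug
    dag_depth: int = 4
    delta: float = 0.5
    # With >= 3 clusters, each feature kind shares one adjacent cluster pair's
    # signature, so no single kind resolves every cluster but the three kinds
    # jointly do — feature-subset ablations then measurably degrade
    # performance instead of removing redundant information.
    kind_confusion: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_drugs < self.n_clusters or self.n_diseases < self.n_clusters:
            raise ValueError("need at least one drug and one disease per cluster")
        if self.n_clusters * self.signature_size > self.feature_pool:
            raise ValueError("feature pool too small for disjoint cluster signatures")
        if not 0.0 < self.feature_overlap <= 1.0:
            raise ValueError("feature_overlap must be in (0, 1]")


@dataclass
class SyntheticDataset:
    features: dict[str, dict[str, set[str]]]  # kind -> drug -> feature set
    dags: dict[str, DiseaseDAG]
    associations: list[tuple[str, str]]
    drug_ids: list[str]
    disease_ids: list[str]
    truth: dict[str, int]  # node id -> planted cluster
    config: SyntheticConfig = field(repr=False)


def _cluster_of(index: int, n_clusters: int) -> int:
    return index % n_clusters


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a fully seeded dataset; resample associations (tiny instances
    only) until the realized within-cluster rate exceeds the between rate."""
    rng = np.random.default_rng(config.seed)
    drugs = [f"R{i:04d}" for i in range(config.n_drugs)]
    diseases = [f"D{j:04d}" for j in range(config.n_diseases)]
    truth = {d: _cluster_of(i, config.n_clusters) for i, d in enumerate(drugs)}
    truth.update({d: _cluster_of(j, config.n_clusters) for j, d in enumerate(diseases)})

    # per-kind disjoint group signatures from a permuted pool; a "group" is a
    # cluster, except that kind k may merge one adjacent cluster pair
    features: dict[str, dict[str, set[str]]] = {}
    n_sig = round(config.feature_overlap * config.signature_size)
    for ki, kind in enumerate(FEATURE_KINDS):
        group_of = list(range(config.n_clusters))
        if config.kind_confusion and config.n_clusters >= 3:
            a, b = ki % config.n_clusters, (ki + 1) % config.n_clusters
            group_of[b] = group_of[a]
        # relabel groups densely
        relabel: dict[int, int] = {}
        group_of = [relabel.setdefault(g, len(relabel)) for g in group_of]
        pool = [f"{kind}_{p:05d}" for p in rng.permutation(config.feature_pool)]
        group_sigs = [
            pool[g * config.signature_size : (g + 1) * config.signature_size]
            for g in range(len(relabel))
        ]
        signatures = [group_sigs[group_of[c]] for c in range(config.n_clusters)]
        kind_features: dict[str, set[str]] = {}
        for i, drug in enumerate(drugs):
            sig = signatures[truth[drug]]
            own = rng.choice(len(sig), size=n_sig, replace=False)
            noise = rng.choice(config.feature_pool, size=config.n_noise_features, replace=False)
            kind_features[drug] = {sig[s] for s in own} | {pool[s] for s in noise}
        features[kind] = kind_features

    # per-cluster ancestor term ladders under one shared root
    dags: dict[str, DiseaseDAG] = {}
    for j, disease in enumerate(diseases):
        c = truth[disease]
        depth = int(rng.integers(1, config.dag_depth + 1))
        ladder = [f"T{c}_{k}" for k in range(depth)]  # T{c}_0 is just under the root
        nodes = {disease, "ROOT", *ladder}
        edges = {(disease, ladder[-1]), (ladder[0], "ROOT")}
        edges.update((ladder[k], ladder[k - 1]) for k in range(1, depth))
        dags[disease] = DiseaseDAG(disease, frozenset(nodes), frozenset(edges), config.delta)

    # associations: planted block pattern
    for attempt in range(20):
        pairs = []
        within = between = within_n = between_n = 0
        for i, r in enumerate(drugs):
            for j, d in enumerate(diseases):
                matched = truth[r] == truth[d]
                p = config.p_in if matched else config.p_out
                hit = rng.random() < p
                if matched:
                    within += hit
                    within_n += 1
                else:
                    between += hit
                    between_n += 1
                if hit:
                    pairs.append((r, d))
            # noqa: loop body intentionally dense — one Bernoulli per cell
        ok_rate = (between_n == 0) or (within / max(within_n, 1) > between / between_n)
        if pairs and ok_rate:
            break
    else:
        raise RuntimeError("could not realize a dataset with within > between association rate")

    return SyntheticDataset(features, dags, pairs, drugs, diseases, truth, config)


def write_dataset(ds: SyntheticDataset, directory) -> dict[str, str]:
    """Emit the exact file formats the readers consume, plus truth and manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for kind in FEATURE_KINDS:
        p = directory / f"features_{kind}.tsv"
        # include feature-less drugs as empty-set rows is unnecessary: readers
        # default missing drugs to empty sets
        io.write_feature_file(ds.features[kind], p)
        paths[f"features_{kind}"] = str(p)
    io.write_dag_file(ds.dags, directory / "disease_dags.tsv")
    paths["dags"] = str(directory / "disease_dags.tsv")
    io.write_associations(ds.associations, directory / "associations.tsv")
    paths["associations"] = str(directory / "associations.tsv")

    import pandas as pd

    truth_rows = [(d, "drug", ds.truth[d]) for d in ds.drug_ids] + [
        (d, "disease", ds.truth[d]) for d in ds.disease_ids
    ]
    pd.DataFrame(truth_rows, columns=["node_id", "node_type", "cluster"]).to_csv(
        directory / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(directory / "truth.tsv")
    io.write_json({"config": asdict(ds.config)}, directory / "manifest.json")
    paths["manifest"] = str(directory / "manifest.json")
    return paths


def read_dataset(directory, delta: float = 0.5):
    """Round-trip reader returning (features-by-kind, dags, associations)."""
    directory = Path(directory)
    features = {
        kind: io.read_feature_file(directory / f"features_{kind}.tsv")
        for kind in FEATURE_KINDS
    }
    dags = io.read_dag_file(directory / "disease_dags.tsv", delta=delta)
    associations = io.read_associations(directory / "associations.tsv")
    return features, dags, associations
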