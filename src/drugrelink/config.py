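"""Run configuration and the association degree filter."""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .evaluation import PipelineConfig
from .pair_cnn import CNNConfig
from .vgae import VGAEConfig

__all__ = ["RunConfig", "degree_filter", "load_config", "synthetic_profile"]


def synthetic_profile(mask_test: bool = True, seed: int = 0) -> PipelineConfig:
    """Training profile sized for the bundled synthetic benchmarks.

    The library defaults mirror the dimensions used on database-scale
    networks (hundreds of drugs/diseases, tens of thousands of pairs); on
    the ~180-node synthetic benchmarks those are oversized.  This profile
    (encoder 64/32, 60 epochs; classifier with 8 base filters and a
    256/256/128 head, 25 epochs) trains stably in seconds per fold on one
    CPU and is what the bundled evaluation scripts use.
    """
    return PipelineConfig(
        vgae=VGAEConfig(d0=64, d1=32, epochs=60),
        cnn=CNNConfig(n_conv=8, fc_sizes=(256, 256, 128), epochs=25),
        mask_test=mask_test,
    )


@dataclass
class RunConfig:
    """Everything a full run needs: inputs, model settings, protocol knobs."""

    data_dir: str = "."
    fusion_mode: str = "mean"  # or per_network
    delta: float = 0.5
    vgae: VGAEConfig = field(default_factory=VGAEConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    k_folds: int = 5
    threshold: float = 0.5
    seed: int = 0
    mask_test: bool = True
    kinds: tuple[str, ...] = ("che", "dom", "anno")  # feature-subset ablations

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(vgae=self.vgae, cnn=self.cnn, k_folds=self.k_folds,
                              threshold=self.threshold, mask_test=self.mask_test)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    vgae = VGAEConfig(**raw.pop("vgae", {}))
    def tuplify(v):
        return tuple(tuplify(x) for x in v) if isinstance(v, list) else v

    cnn = CNNConfig(**{k: tuplify(v) for k, v in raw.pop("cnn", {}).items()})
    if "kinds" in raw:
        raw["kinds"] = tuple(raw["kinds"])
    return RunConfig(vgae=vgae, cnn=cnn, **raw)


def degree_filter(
    associations: list[tuple[str, str]],
    min_drug_degree: int = 10,
    min_disease_degree: int = 10,
    fixed_point: bool = True,
) -> list[tuple[str, str]]:
    """Keep drugs/diseases whose degree is strictly greater than the threshold.

    With ``fixed_point`` (default) the screen is iterated until stable, since
    removing one side's nodes can drop the other side below threshold; one
    pass reproduces a single screening sweep.
    """
    pairs = list(dict.fromkeys(associations))
    while True:
        drug_deg = Counter(r for r, _ in pairs)
        disease_deg = Counter(d for _, d in pairs)
        kept = [
            (r, d) for r, d in pairs
            if drug_deg[r] > min_drug_degree and disease_deg[d] > min_disease_degree
        ]
        if len(kept) == len(pairs) or not fixed_point:
            return kept
        pairs = kept
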