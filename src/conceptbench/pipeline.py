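"""End-to-end orchestration: world -> hierarchy -> features -> benchmark.

This is the programmatic equivalent of running the CLI stages in sequence,
with the reference desk-scale configuration as default: a 32x32 world of 30
base and 10 novel categories with 200 exemplars each, a three-stage
hierarchy trained for up to 20 epochs, and the factorial benchmark over
training sizes {2, 4, 8, 16, 32} with 20 splits per cell.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .elastic_net import ElasticNetConfig
from .fewshot import ProtocolConfig, run_benchmark
from .hierarchy import (
    HierarchyConfig,
    TrainedHierarchy,
    combine_feature_sets,
    extract_features,
    train_hierarchy,
    TAPS,
)
from .synthetic_world import ImageDataset, World, WorldConfig, build_world, generate_dataset

__all__ = [
    "reference_world_config",
    "reference_hierarchy_config",
    "build_datasets",
    "train_reference_hierarchy",
    "extract_feature_sets",
    "run_experiment",
]


def reference_world_config(seed: int = 7, **overrides) -> WorldConfig:
    return replace(WorldConfig(), seed=seed, **overrides) if overrides else WorldConfig(seed=seed)


def reference_hierarchy_config(
    world_config: WorldConfig, seed: int | None = None, **overrides
) -> HierarchyConfig:
    return HierarchyConfig(
        input_size=world_config.image_size,
        concept_width=world_config.n_base_categories,
        seed=world_config.seed if seed is None else seed,
        **overrides,
    )


def build_datasets(config: WorldConfig) -> tuple[World, dict[str, ImageDataset]]:
    world = build_world(config)
    datasets = {role: generate_dataset(world, role) for role in ("base-train", "base-val", "novel")}
    return world, datasets


def train_reference_hierarchy(
    datasets: dict[str, ImageDataset], config: HierarchyConfig, verbose: bool = False
) -> TrainedHierarchy:
    return train_hierarchy(datasets["base-train"], datasets["base-val"], config, verbose=verbose)


def extract_feature_sets(model: TrainedHierarchy, novel: ImageDataset):
    """All five benchmark feature sets for the novel images."""
    sets = {tap: extract_features(model, novel, tap) for tap in TAPS}
    sets["Generic1+Conceptual"] = combine_feature_sets(sets["Generic1"], sets["Conceptual"])
    return sets


def run_experiment(
    seed: int = 7,
    world_overrides: dict | None = None,
    hierarchy_overrides: dict | None = None,
    protocol: ProtocolConfig | None = None,
    classifier: ElasticNetConfig | None = None,
    verbose: bool = False,
) -> dict:
    """Run the whole reference experiment; returns every intermediate object.

    The benchmark master seed defaults to the world seed so one integer
    reproduces the entire run.
    """
    wc = reference_world_config(seed, **(world_overrides or {}))
    hc = reference_hierarchy_config(wc, **(hierarchy_overrides or {}))
    protocol = protocol or ProtocolConfig(master_seed=seed)
    classifier = classifier or ElasticNetConfig()
    world, datasets = build_datasets(wc)
    model = train_reference_hierarchy(datasets, hc, verbose=verbose)
    features = extract_feature_sets(model, datasets["novel"])
    results = run_benchmark(features, protocol, classifier)
    return {
        "world": world,
        "datasets": datasets,
        "model": model,
        "features": features,
        "results": results,
        "configs": {
            "world": wc,
            "hierarchy": hc,
            "protocol": protocol,
            "classifier": classifier,
        },
    }
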