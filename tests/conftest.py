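import numpy as np
import pytest

from conceptbench.elastic_net import ElasticNetConfig
from conceptbench.fewshot import ProtocolConfig, run_benchmark
from conceptbench.hierarchy import FeatureMatrix, HierarchyConfig, train_hierarchy
from conceptbench.pipeline import (
    build_datasets,
    extract_feature_sets,
    reference_hierarchy_config,
    reference_world_config,
)
from conceptbench.synthetic_world import WorldConfig, build_world, generate_dataset


@pytest.fixture(scope="session")
def tiny_world_config():
    """A miniature world: fast to generate, enough structure to learn from."""
    return WorldConfig(
        n_base_categories=6,
        n_novel_categories=4,
        exemplars_per_category=24,
        val_exemplars_per_base_category=6,
        image_size=16,
        part_dictionary_size=8,
        parts_per_category=2,
        translation_jitter=2.0,
        scale_jitter=(0.8, 1.2),
        rotation_jitter=15.0,
        clutter_density=0.5,
        noise_sd=0.05,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_world_config):
    return build_world(tiny_world_config)


@pytest.fixture(scope="session")
def tiny_datasets(tiny_world):
    return {
        role: generate_dataset(tiny_world, role)
        for role in ("base-train", "base-val", "novel")
    }


@pytest.fixture(scope="session")
def tiny_model(tiny_datasets):
    config = HierarchyConfig(
        input_size=16, stage_widths=(8, 12, 16), concept_width=6, epochs=8, seed=3
    )
    return train_hierarchy(tiny_datasets["base-train"], tiny_datasets["base-val"], config)


def make_gaussian_features(
    n_categories: int = 8,
    per_category: int = 30,
    dim: int = 12,
    separation: float = 2.0,
    seed: int = 0,
    tap: str = "Generic1",
) -> FeatureMatrix:
    """Synthetic stand-in features: one Gaussian cloud per category.

    Used wherever the benchmark machinery is under test and the hierarchy
    itself is irrelevant.
    """
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, separation, (n_categories, dim))
    values, labels, ids = [], [], []
    for c in range(n_categories):
        values.append(centers[c] + rng.normal(0, 1.0, (per_category, dim)))
        labels += [f"novel{c:03d}"] * per_category
        ids += [f"novel{c:03d}/{i:04d}" for i in range(per_category)]
    return FeatureMatrix(
        values=np.concatenate(values), image_ids=ids, labels=labels, tap=tap
    )


@pytest.fixture(scope="session")
def reference_run():
    """The full desk-scale reference experiment (seed 7): world, training,
    extraction, and benchmark. Shared across the expensive end-to-end tests."""
    wc = reference_world_config(7)
    world, datasets = build_datasets(wc)
    model = train_hierarchy(
        datasets["base-train"], datasets["base-val"], reference_hierarchy_config(wc)
    )
    features = extract_feature_sets(model, datasets["novel"])
    protocol = ProtocolConfig(master_seed=7)
    results = run_benchmark(features, protocol, ElasticNetConfig())
    return {
        "world": world,
        "datasets": datasets,
        "model": model,
        "features": features,
        "protocol": protocol,
        "results": results,
    }
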