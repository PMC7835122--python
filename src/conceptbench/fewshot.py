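"""The factorial few-shot benchmark: one-vs-all learning of novel categories.

For every combination of (feature set x novel category x training-set size x
random split) a balanced tiny training set is sampled — half positives from
the target category, half negatives drawn from the other novel categories —
an elastic-net logistic classifier is fit on it, and its decisions on
held-out positives and freshly sampled negatives are tallied into confusion
counts and a d' score.

Two design choices carry the statistics downstream: the same splits (image
ids) are reused for every feature set, so feature-set comparisons are paired
within each cell; and each cell derives its own seed from a stable hash of
(master_seed, category, n_total, split_index), so adding a size or category
never perturbs the randomness of other cells.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import elastic_net
from .elastic_net import ElasticNetConfig
from .hierarchy import FeatureMatrix
from .sdt import ConfusionCounts, dprime

__all__ = [
    "ProtocolConfig",
    "SplitSpec",
    "cell_seed",
    "make_splits",
    "run_benchmark",
    "write_results",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "feature_set",
    "category",
    "n_pos",
    "split_index",
    "hits",
    "misses",
    "false_alarms",
    "correct_rejections",
    "dprime",
    "solver_converged",
    "config_fingerprint",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Factorial design of the benchmark.

    ``training_sizes`` are *total* training-set sizes, evenly split between
    positives and negatives, so every entry must be even and >= 2.
    ``n_test_positives=None`` means "all held-out positives of the category";
    ``negatives_per_test=None`` means "as many negatives as test positives"
    (a balanced test set, so hit and false-alarm rates are equally well
    estimated).
    """

    training_sizes: tuple[int, ...] = (2, 4, 8, 16, 32)
    n_splits: int = 20
    n_test_positives: int | None = None
    negatives_per_test: int | None = None
    master_seed: int = 0
    dprime_correction: str = "clamp"

    def __post_init__(self) -> None:
        for n in self.training_sizes:
            if n < 2 or n % 2 != 0:
                raise ValueError(f"training sizes must be even and >= 2, got {n}")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """One few-shot train/test split for one (category, size, split) cell."""

    category: str
    n_total: int
    split_index: int
    train_pos_ids: tuple[str, ...]
    train_neg_ids: tuple[str, ...]
    test_pos_ids: tuple[str, ...]
    test_neg_ids: tuple[str, ...]
    cell_seed: int

    def __post_init__(self) -> None:
        if len(self.train_pos_ids) != len(self.train_neg_ids):
            raise ValueError("training set must be balanced")
        train = set(self.train_pos_ids) | set(self.train_neg_ids)
        test = set(self.test_pos_ids) | set(self.test_neg_ids)
        if train & test:
            raise ValueError("train and test ids overlap")


def cell_seed(master_seed: int, category: str, n_total: int, split_index: int) -> int:
    """Stable per-cell seed from a SHA-256 hash of the cell coordinates."""
    key = f"{master_seed}|{category}|{n_total}|{split_index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big")


def make_splits(
    novel_features: FeatureMatrix,
    category: str,
    n_total: int,
    n_splits: int,
    master_seed: int,
    n_test_positives: int | None = None,
    negatives_per_test: int | None = None,
) -> list[SplitSpec]:
    """Sample the train/test splits for one (category, size) cell.

    Training positives are drawn from the target category and negatives from
    all other categories, both without replacement. Test positives are every
    held-out positive of the category (optionally capped); test negatives are
    sampled from the other categories, disjoint from the training negatives.
    """
    labels = np.asarray(novel_features.labels)
    ids = np.asarray(novel_features.image_ids)
    pos_ids = ids[labels == category]
    neg_ids = ids[labels != category]
    if pos_ids.size == 0:
        raise ValueError(f"category {category!r} not present in the novel feature matrix")
    n_half = n_total // 2
    if n_half >= pos_ids.size:
        raise ValueError(
            f"category {category!r}: {n_half} training positives requested but only "
            f"{pos_ids.size} exemplars exist (test positives would be empty)"
        )
    splits = []
    for si in range(n_splits):
        seed = cell_seed(master_seed, category, n_total, si)
        rng = np.random.default_rng(seed)
        train_pos = rng.choice(pos_ids, size=n_half, replace=False)
        train_neg = rng.choice(neg_ids, size=n_half, replace=False)
        test_pos = np.setdiff1d(pos_ids, train_pos, assume_unique=True)
        if n_test_positives is not None and n_test_positives < test_pos.size:
            test_pos = rng.choice(test_pos, size=n_test_positives, replace=False)
        held_neg = np.setdiff1d(neg_ids, train_neg, assume_unique=True)
        n_test_neg = negatives_per_test if negatives_per_test is not None else test_pos.size
        if n_test_neg > held_neg.size:
            raise ValueError(
                f"category {category!r}: {n_test_neg} test negatives requested but only "
                f"{held_neg.size} remain"
            )
        test_neg = rng.choice(held_neg, size=n_test_neg, replace=False)
        splits.append(
            SplitSpec(
                category=category,
                n_total=n_total,
                split_index=si,
                train_pos_ids=tuple(train_pos),
                train_neg_ids=tuple(train_neg),
                test_pos_ids=tuple(test_pos),
                test_neg_ids=tuple(test_neg),
                cell_seed=seed,
            )
        )
    return splits


def _config_fingerprint(protocol: ProtocolConfig, classifier: ElasticNetConfig) -> str:
    blob = json.dumps({"protocol": asdict(protocol), "classifier": asdict(classifier)},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_benchmark(
    features_by_set: dict[str, FeatureMatrix],
    protocol: ProtocolConfig,
    classifier: ElasticNetConfig | None = None,
) -> pd.DataFrame:
    """Run the full factorial benchmark and return the long-format results.

    All feature matrices must cover the same images in the same order —
    the comparison across feature sets is paired, cell by cell, on identical
    splits. One row per (feature_set, category, size, split) with confusion
    counts, d', and a convergence flag; identical master_seed reproduces the
    table exactly.
    """
    classifier = classifier or ElasticNetConfig()
    sets = list(features_by_set)
    ref = features_by_set[sets[0]]
    for name in sets[1:]:
        if features_by_set[name].image_ids != ref.image_ids:
            raise ValueError(
                f"feature set {name!r} covers different images than {sets[0]!r}; "
                "paired comparison requires identical coverage"
            )
    categories = sorted(set(ref.labels))
    fingerprint = _config_fingerprint(protocol, classifier)
    row_index = {iid: k for k, iid in enumerate(ref.image_ids)}

    # splits are sampled once per cell and shared across feature sets
    all_splits = [
        split
        for category in categories
        for n_total in protocol.training_sizes
        for split in make_splits(
            ref,
            category,
            n_total,
            protocol.n_splits,
            protocol.master_seed,
            protocol.n_test_positives,
            protocol.negatives_per_test,
        )
    ]

    rows = []
    for set_name in sets:
        fm = features_by_set[set_name]
        for sp in all_splits:
            tr_idx = [row_index[i] for i in sp.train_pos_ids + sp.train_neg_ids]
            y = np.array([1.0] * len(sp.train_pos_ids) + [-1.0] * len(sp.train_neg_ids))
            model = elastic_net.fit(fm.values[tr_idx], y, classifier)
            te_pos = [row_index[i] for i in sp.test_pos_ids]
            te_neg = [row_index[i] for i in sp.test_neg_ids]
            pos_dec, _ = elastic_net.decide(model, fm.values[te_pos])
            neg_dec, _ = elastic_net.decide(model, fm.values[te_neg])
            counts = ConfusionCounts(
                hits=int(pos_dec.sum()),
                misses=int((~pos_dec).sum()),
                false_alarms=int(neg_dec.sum()),
                correct_rejections=int((~neg_dec).sum()),
            )
            rows.append(
                {
                    "feature_set": set_name,
                    "category": sp.category,
                    "n_pos": sp.n_total // 2,
                    "split_index": sp.split_index,
                    "hits": counts.hits,
                    "misses": counts.misses,
                    "false_alarms": counts.false_alarms,
                    "correct_rejections": counts.correct_rejections,
                    "dprime": dprime(counts, protocol.dprime_correction),
                    "solver_converged": model.converged,
                    "config_fingerprint": fingerprint,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(
    results: pd.DataFrame,
    out_path: str | Path,
    manifest: dict | None = None,
) -> Path:
    """Write the results TSV (and an optional JSON run manifest alongside)."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_path, sep="\t", index=False, float_format="%.10g")
    if manifest is not None:
        Path(str(out_path) + ".manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return out_path
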