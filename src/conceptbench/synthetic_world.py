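"""Seeded synthetic category worlds for few-shot concept-learning experiments.

The generator emulates the structure the benchmark needs from a natural image
collection: a set of "base" categories on which a visual hierarchy is first
trained, plus a disjoint set of "novel" categories that are never seen during
that training but *share visual parts* with the base categories — the way a
car wheel shares structure with a bicycle wheel. Every category is a fixed
arrangement of a few part stamps drawn from one shared part dictionary;
exemplars of a category vary in part position, scale and rotation, carry
clutter parts sampled from the same dictionary, and are corrupted by pixel
noise. Identical (config, seed) reproduces a bit-identical world and
datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "WorldConfig",
    "CategorySpec",
    "ImageDataset",
    "World",
    "build_world",
    "render_exemplar",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "ROLES",
]

ROLES = ("base-train", "base-val", "novel")
_ROLE_CODE = {"base-train": 1, "base-val": 2, "novel": 3}


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world.

    Geometry jitters are the per-exemplar variability controls: every part is
    translated by up to ``translation_jitter`` pixels (uniform per axis),
    scaled by a factor drawn uniformly from ``scale_jitter``, and rotated by
    up to ``rotation_jitter`` degrees. ``clutter_density`` is the expected
    number of distractor parts per image (Poisson), drawn from the same part
    dictionary so that negatives are genuinely confusable with positives.
    ``noise_sd`` is the standard deviation of additive Gaussian pixel noise
    in [0, 1] intensity units.
    """

    n_base_categories: int = 30
    n_novel_categories: int = 10
    exemplars_per_category: int = 200
    val_exemplars_per_base_category: int = 25
    image_size: int = 32
    part_dictionary_size: int = 12
    parts_per_category: int = 3
    translation_jitter: float = 4.0
    scale_jitter: tuple[float, float] = (0.75, 1.25)
    rotation_jitter: float = 25.0
    clutter_density: float = 1.5
    noise_sd: float = 0.08
    seed: int = 7

    def __post_init__(self) -> None:
        counts = {
            "n_base_categories": self.n_base_categories,
            "n_novel_categories": self.n_novel_categories,
            "exemplars_per_category": self.exemplars_per_category,
            "val_exemplars_per_base_category": self.val_exemplars_per_base_category,
            "image_size": self.image_size,
            "part_dictionary_size": self.part_dictionary_size,
            "parts_per_category": self.parts_per_category,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.parts_per_category > self.part_dictionary_size:
            raise ValueError(
                f"parts_per_category ({self.parts_per_category}) exceeds "
                f"part_dictionary_size ({self.part_dictionary_size})"
            )
        if self.val_exemplars_per_base_category >= self.exemplars_per_category:
            raise ValueError(
                "val_exemplars_per_base_category must be < exemplars_per_category"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.translation_jitter < 0 or self.rotation_jitter < 0:
            raise ValueError("jitters must be >= 0")
        lo, hi = self.scale_jitter
        if not (0 < lo <= hi):
            raise ValueError(f"scale_jitter must satisfy 0 < lo <= hi, got {self.scale_jitter}")


@dataclass(frozen=True)
class CategorySpec:
    """A category = an ordered arrangement of part-dictionary entries.

    ``layout`` holds one (x, y, scale) triple per part, with positions in
    unit-canvas coordinates [0, 1]^2 and a canonical (pre-jitter) scale.
    """

    label: str
    part_ids: tuple[int, ...]
    layout: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.part_ids) != len(self.layout):
            raise ValueError("one layout entry per part required")
        for x, y, s in self.layout:
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise ValueError("canonical positions must lie in the unit canvas")
            if s <= 0:
                raise ValueError("canonical scale must be positive")


@dataclass
class ImageDataset:
    """A labelled stack of grayscale images for one role of the experiment."""

    images: np.ndarray  # (n, size, size) float32 in [0, 1]
    labels: list[str]
    image_ids: list[str]
    role: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not (len(self.labels) == len(self.image_ids) == self.images.shape[0]):
            raise ValueError("images, labels and image_ids must agree in length")

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def label_set(self) -> set[str]:
        return set(self.labels)


@dataclass
class World:
    config: WorldConfig
    parts: np.ndarray  # (dictionary_size, stamp, stamp) float32 in [0, 1]
    base_specs: list[CategorySpec]
    novel_specs: list[CategorySpec]

    def spec_by_label(self, label: str) -> CategorySpec:
        for spec in self.base_specs + self.novel_specs:
            if spec.label == label:
                return spec
        raise KeyError(label)


# ---------------------------------------------------------------------------
# part dictionary

def _stamp_size(image_size: int) -> int:
    s = max(7, image_size // 3)
    return s + 1 - s % 2  # odd, so stamps have a center pixel


def _make_stamp(kind: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """One procedurally generated shape stamp in [0, 1].

    Cycles through blob / bar / corner / ring / cross / spoke motifs with
    randomized proportions, so even two stamps of the same kind differ.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    c = (size - 1) / 2.0
    r = np.hypot(xx - c, yy - c)
    theta = np.arctan2(yy - c, xx - c)
    img = np.zeros((size, size))
    kind = kind % 6
    if kind == 0:  # anisotropic gaussian blob
        sx = rng.uniform(0.15, 0.3) * size
        sy = rng.uniform(0.15, 0.3) * size
        img = np.exp(-(((xx - c) / sx) ** 2 + ((yy - c) / sy) ** 2))
    elif kind == 1:  # bar
        w = rng.uniform(0.1, 0.2) * size
        img = (np.abs(yy - c) < w).astype(float)
    elif kind == 2:  # corner (two orthogonal half-bars)
        w = rng.uniform(0.08, 0.16) * size
        img = (((np.abs(yy - c) < w) & (xx >= c)) | ((np.abs(xx - c) < w) & (yy >= c))).astype(
            float
        )
    elif kind == 3:  # ring
        r0 = rng.uniform(0.25, 0.4) * size
        w = rng.uniform(0.06, 0.12) * size
        img = (np.abs(r - r0) < w).astype(float)
    elif kind == 4:  # cross
        w = rng.uniform(0.08, 0.15) * size
        img = ((np.abs(yy - c) < w) | (np.abs(xx - c) < w)).astype(float)
    else:  # spokes
        n_spokes = rng.integers(3, 6)
        phase = rng.uniform(0, 2 * np.pi)
        img = ((np.cos(n_spokes * (theta + phase)) > 0.55) & (r < 0.45 * size)).astype(float)
    img *= rng.uniform(0.7, 1.0)  # per-part peak intensity
    # soften edges slightly so downstream convolutions see gradients
    img = ndimage.gaussian_filter(img, sigma=0.5)
    peak = img.max()
    return (img / peak if peak > 0 else img).astype(np.float32)


# ---------------------------------------------------------------------------
# world construction

def build_world(config: WorldConfig) -> World:
    """Build the shared part dictionary and the base/novel category specs.

    Each category samples ``parts_per_category`` distinct parts from the one
    shared dictionary (with replacement *across* categories), so base and
    novel categories overlap in parts with nonzero expectation — the premise
    that novel concepts can be described in terms of previously learned ones.
    Base and novel labels are disjoint by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    s = _stamp_size(config.image_size)
    parts = np.stack(
        [_make_stamp(k, s, rng) for k in range(config.part_dictionary_size)]
    )

    def make_specs(prefix: str, n: int) -> list[CategorySpec]:
        specs = []
        for i in range(n):
            ids = tuple(
                int(j)
                for j in rng.choice(
                    config.part_dictionary_size, size=config.parts_per_category, replace=False
                )
            )
            layout = tuple(
                (float(rng.uniform(0.2, 0.8)), float(rng.uniform(0.2, 0.8)), 1.0)
                for _ in ids
            )
            specs.append(CategorySpec(label=f"{prefix}{i:03d}", part_ids=ids, layout=layout))
        return specs

    base = make_specs("base", config.n_base_categories)
    novel = make_specs("novel", config.n_novel_categories)
    return World(config=config, parts=parts, base_specs=base, novel_specs=novel)


# ---------------------------------------------------------------------------
# rendering

def _place(canvas: np.ndarray, stamp: np.ndarray, cx: float, cy: float) -> None:
    """Max-composite ``stamp`` onto ``canvas`` centered at (cx, cy), clipping
    whatever falls outside the border (parts can be partially cropped out)."""
    size = canvas.shape[0]
    h, w = stamp.shape
    top = int(round(cy - h / 2.0))
    left = int(round(cx - w / 2.0))
    y0, y1 = max(top, 0), min(top + h, size)
    x0, x1 = max(left, 0), min(left + w, size)
    if y0 >= y1 or x0 >= x1:
        return
    sub = stamp[y0 - top : y1 - top, x0 - left : x1 - left]
    np.maximum(canvas[y0:y1, x0:x1], sub, out=canvas[y0:y1, x0:x1])


def _transform_stamp(
    stamp: np.ndarray, scale: float, angle_deg: float
) -> np.ndarray:
    out = stamp
    if angle_deg != 0.0:
        out = ndimage.rotate(out, angle_deg, reshape=True, order=1, prefilter=False)
    if scale != 1.0:
        out = ndimage.zoom(out, scale, order=1, prefilter=False)
        if out.size == 0:
            out = np.zeros((1, 1), dtype=stamp.dtype)
    return np.clip(out, 0.0, 1.0)


def render_exemplar(
    world: World, spec: CategorySpec, rng: np.random.Generator
) -> np.ndarray:
    """Render one exemplar of a category.

    Each part is stamped at its canonical position perturbed by a uniform
    translation of up to ``translation_jitter`` pixels per axis, scaled by a
    factor drawn from ``scale_jitter`` and rotated by up to
    ``rotation_jitter`` degrees; Poisson-many clutter parts land uniformly on
    the canvas; Gaussian pixel noise is added and the image clipped to [0, 1].
    With all jitters, clutter and noise at zero the rendering is the
    deterministic canonical image of the category.
    """
    cfg = world.config
    size = cfg.image_size
    canvas = np.zeros((size, size), dtype=np.float32)

    for part_id, (ux, uy, base_scale) in zip(spec.part_ids, spec.layout):
        dx = rng.uniform(-cfg.translation_jitter, cfg.translation_jitter)
        dy = rng.uniform(-cfg.translation_jitter, cfg.translation_jitter)
        scale = base_scale * rng.uniform(*cfg.scale_jitter)
        angle = rng.uniform(-cfg.rotation_jitter, cfg.rotation_jitter)
        stamp = _transform_stamp(world.parts[part_id], scale, angle)
        _place(canvas, stamp, ux * size + dx, uy * size + dy)

    n_clutter = rng.poisson(cfg.clutter_density)
    for _ in range(n_clutter):
        part_id = int(rng.integers(cfg.part_dictionary_size))
        scale = rng.uniform(*cfg.scale_jitter)
        angle = rng.uniform(-cfg.rotation_jitter, cfg.rotation_jitter)
        stamp = _transform_stamp(world.parts[part_id], scale, angle)
        _place(canvas, stamp, rng.uniform(0, size), rng.uniform(0, size))

    if cfg.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, cfg.noise_sd, canvas.shape).astype(np.float32)
    return np.clip(canvas, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset generation

def _exemplar_rng(seed: int, category_index: int, exemplar_index: int) -> np.random.Generator:
    # random-access seeding: any single exemplar is reproducible on its own
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), 1 + category_index, exemplar_index])
    )


def generate_dataset(world: World, role: str) -> ImageDataset:
    """Generate the image dataset for one role.

    Every base category owns a stream of ``exemplars_per_category`` exemplar
    slots; base-train takes the first ``exemplars - val_exemplars`` slots and
    base-val the remaining ones, so the two roles partition the stream and
    never share an image. Novel categories use all their slots. Each slot is
    seeded by (world seed, category index, slot index), so any role — and any
    single image — regenerates identically in isolation.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    cfg = world.config
    n_train = cfg.exemplars_per_category - cfg.val_exemplars_per_base_category

    if role == "novel":
        specs = world.novel_specs
        cat_offset = cfg.n_base_categories
        slots = range(cfg.exemplars_per_category)
    else:
        specs = world.base_specs
        cat_offset = 0
        slots = range(n_train) if role == "base-train" else range(n_train, cfg.exemplars_per_category)

    images, labels, ids = [], [], []
    for ci, spec in enumerate(specs):
        for ei in slots:
            rng = _exemplar_rng(cfg.seed, cat_offset + ci, ei)
            images.append(render_exemplar(world, spec, rng))
            labels.append(spec.label)
            ids.append(f"{spec.label}/{ei:04d}")
    return ImageDataset(
        images=np.stack(images),
        labels=labels,
        image_ids=ids,
        role=role,
        provenance={"world_seed": cfg.seed, "role_code": _ROLE_CODE[role]},
    )


def expected_dataset_sizes(
    n_base: int, n_novel: int, exemplars: int, val_exemplars: int
) -> dict[str, int]:
    """Image counts per role implied by the train/validation partition:
    each base category sets aside ``val_exemplars`` of its ``exemplars``
    for validation and trains on the rest; novel categories keep all."""
    if not 0 < val_exemplars < exemplars:
        raise ValueError("need 0 < val_exemplars < exemplars")
    return {
        "base-train": n_base * (exemplars - val_exemplars),
        "base-val": n_base * val_exemplars,
        "novel": n_novel * exemplars,
    }


# ---------------------------------------------------------------------------
# on-disk formats: PNG-per-image + manifest CSV + config JSON (manifest is
# the source of truth); an .npz pack is accepted for speed.

def save_dataset(dataset: ImageDataset, out_dir: str | Path, config: WorldConfig,
                 packed: bool = False) -> Path:
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["path,image_id,label,role"]
    if packed:
        pack = out / f"{dataset.role}.npz"
        np.savez_compressed(
            pack,
            images=dataset.images,
            labels=np.asarray(dataset.labels),
            image_ids=np.asarray(dataset.image_ids),
        )
        for iid, lab in zip(dataset.image_ids, dataset.labels):
            rows.append(f"{pack.name},{iid},{lab},{dataset.role}")
    else:
        for img, iid, lab in zip(dataset.images, dataset.image_ids, dataset.labels):
            rel = Path(dataset.role) / f"{iid}.png"
            path = out / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            iio.imwrite(path, (np.clip(img, 0, 1) * 255).astype(np.uint8))
            rows.append(f"{rel},{iid},{lab},{dataset.role}")
    manifest = out / f"manifest_{dataset.role}.csv"
    manifest.write_text("\n".join(rows) + "\n")
    (out / "world_config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")
    return manifest


def load_dataset(out_dir: str | Path, role: str) -> ImageDataset:
    import imageio.v3 as iio

    out = Path(out_dir)
    manifest = out / f"manifest_{role}.csv"
    lines = manifest.read_text().strip().splitlines()[1:]
    images, labels, ids = [], [], []
    pack_cache: dict[str, dict] = {}
    for line in lines:
        path, iid, lab, _ = line.split(",")
        if path.endswith(".npz"):
            if path not in pack_cache:
                with np.load(out / path) as z:
                    pack_cache[path] = {
                        "images": z["images"],
                        "index": {i: k for k, i in enumerate(z["image_ids"])},
                    }
            pack = pack_cache[path]
            images.append(pack["images"][pack["index"][iid]])
        else:
            images.append(iio.imread(out / path).astype(np.float32) / 255.0)
        labels.append(lab)
        ids.append(iid)
    return ImageDataset(
        images=np.stack(images), labels=labels, image_ids=ids, role=role,
        provenance={"loaded_from": str(out)},
    )
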