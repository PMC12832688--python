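"""Image ingestion, preprocessing, splitting, and a synthetic radiograph
generator.

The generator renders simplified frontal chest phantoms: a bright thorax
background carrying two darker elliptical lung fields, with the pneumonia
class adding blurred bright opacity blobs confined to the lung fields,
plus additive Gaussian pixel noise.  Everything is driven by a single
seed, so datasets are byte-reproducible, and each pneumonia image keeps
its ground-truth opacity mask for interpretability checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

LABELS = ("normal", "pneumonia")

__all__ = [
    "LABELS",
    "ImageRecord",
    "SplitSpec",
    "SyntheticSpec",
    "preprocess",
    "stratified_split",
    "generate_synthetic",
    "lung_mask",
    "load_directory",
    "write_dataset",
]


@dataclass
class ImageRecord:
    """One labeled radiograph: 8-bit grayscale pixels plus an optional
    ground-truth opacity mask (synthetic images only)."""

    identifier: str
    pixels: np.ndarray  # (H, W) uint8
    label: str
    opacity_mask: np.ndarray | None = None  # (H, W) bool

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test split specification.

    Exactly one of ``ratios`` (default 0.8/0.1/0.1) or explicit ``counts``
    is active; ``counts`` exists to reproduce printed set sizes verbatim.
    """

    ratios: tuple[float, float, float] | None = (0.8, 0.1, 0.1)
    counts: tuple[int, int, int] | None = None
    seed: int = 42
    stratified: bool = True

    def __post_init__(self) -> None:
        if (self.ratios is None) == (self.counts is None):
            raise ValueError("exactly one of ratios or counts must be set")
        if self.ratios is not None and abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")

    def sizes(self, n: int) -> tuple[int, int, int]:
        if self.counts is not None:
            if sum(self.counts) != n:
                raise ValueError(f"counts {self.counts} do not sum to n={n}")
            return tuple(self.counts)
        return _largest_remainder(np.asarray(self.ratios) * n, n)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic chest-radiograph phantom.

    Geometry is in coordinates relative to the image side; intensities on
    the 8-bit scale.  The base phantom (thorax + lung fields) is
    deterministic; per-image variation comes from the noise field and,
    for the pneumonia class, the opacity blobs.
    """

    n_normal: int = 200
    n_pneumonia: int = 200
    image_size: int = 224
    # (center_x, center_y, axis_x, axis_y) per lung, relative to image side
    lung_ellipses: tuple[tuple[float, float, float, float], ...] = (
        (0.33, 0.52, 0.16, 0.30),
        (0.67, 0.52, 0.16, 0.30),
    )
    background_intensity: float = 200.0
    lung_darkening: float = 80.0
    opacity_count: tuple[int, int] = (1, 3)  # inclusive range per image
    opacity_intensity: float = 45.0
    # consolidation-scale opacities (segmental, not nodular): radii in
    # pixels at the reference 224 resolution
    opacity_radius: tuple[float, float] = (12.0, 30.0)
    opacity_sigma: float = 4.0  # Gaussian blur, pixels
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_normal, self.n_pneumonia) < 1:
            raise ValueError("class sizes must be positive")
        for cx, cy, ax, ay in self.lung_ellipses:
            if ax <= 0 or ay <= 0:
                raise ValueError(f"degenerate lung ellipse axes ({ax}, {ay})")
        if self.opacity_count[0] > self.opacity_count[1] or self.opacity_count[0] < 1:
            raise ValueError("opacity_count must be a nonempty positive range")


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(record: ImageRecord, target: int = 224) -> np.ndarray:
    """Resize (bilinear) to target x target, convert to grayscale, scale to
    [0, 1], and replicate to 3 identical channels."""
    px = np.asarray(record.pixels)
    if px.size == 0:
        raise IOError(f"empty image for record {record.identifier!r}")
    if px.ndim == 3:  # RGB -> luminance
        px = px[..., 0] * 0.299 + px[..., 1] * 0.587 + px[..., 2] * 0.114
    img = Image.fromarray(px.astype(np.float32), mode="F")
    if img.size != (target, target):
        img = img.resize((target, target), Image.BILINEAR)
    gray = np.asarray(img, dtype=np.float32) / 255.0
    return np.repeat(gray[:, :, None], 3, axis=2)


def stack_images(records: list[ImageRecord], target: int = 224) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess a record list into (X, y) arrays; y encodes pneumonia as 1."""
    x = np.stack([preprocess(r, target) for r in records])
    y = np.array([1.0 if r.label == "pneumonia" else 0.0 for r in records], dtype=np.float32)
    return x, y


# ---------------------------------------------------------------------------
# stratified splitting


def _largest_remainder(quota: np.ndarray, total: int) -> tuple[int, ...]:
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    # hand out the shortfall to the largest fractional remainders
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return tuple(int(v) for v in base)


def stratified_split(
    labels, spec: SplitSpec | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split indices into disjoint train/val/test sets.

    Per-class allocation uses largest-remainder rounding so class
    proportions in every set deviate from exact proportionality by less
    than one item.  Identical seeds give identical index sets.
    """
    spec = spec or SplitSpec()
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("cannot split an empty label list")
    sizes = spec.sizes(n)
    rng = np.random.default_rng(spec.seed)

    if not spec.stratified:
        perm = rng.permutation(n)
        a, b = sizes[0], sizes[0] + sizes[1]
        return np.sort(perm[:a]), np.sort(perm[a:b]), np.sort(perm[b:])

    classes = sorted(set(labels.tolist()))
    pools = {}
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls!r} has no members")
        pools[cls] = list(rng.permutation(idx))

    splits = []
    for size in sizes[:-1]:
        remaining = {cls: len(p) for cls, p in pools.items()}
        rem_total = sum(remaining.values())
        quota = np.array([remaining[cls] * size / rem_total for cls in classes])
        take = _largest_remainder(quota, size)
        chosen: list[int] = []
        for cls, k in zip(classes, take):
            chosen += [pools[cls].pop() for _ in range(k)]
        splits.append(np.sort(np.array(chosen, dtype=int)))
    last = np.sort(np.array([i for p in pools.values() for i in p], dtype=int))
    splits.append(last)
    return tuple(splits)


# ---------------------------------------------------------------------------
# synthetic phantom generator


def lung_mask(spec: SyntheticSpec) -> np.ndarray:
    """Boolean union of the two elliptical lung fields."""
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s] / s
    mask = np.zeros((s, s), dtype=bool)
    for cx, cy, ax, ay in spec.lung_ellipses:
        mask |= ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    return mask


def _base_phantom(spec: SyntheticSpec, mask: np.ndarray) -> np.ndarray:
    base = np.full((spec.image_size, spec.image_size), spec.background_intensity)
    base[mask] -= spec.lung_darkening
    # soften lung-field borders a touch so edges are not a single hard step
    return gaussian_filter(base, sigma=spec.image_size / 112.0)

def generate_synthetic(spec: SyntheticSpec | None = None) -> list[ImageRecord]:
    """Render the synthetic dataset: ``n_normal`` normals followed by
    ``n_pneumonia`` pneumonia phantoms, fully determined by ``spec.seed``.

    Pneumonia records carry their ground-truth opacity mask."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    mask = lung_mask(spec)
    base = _base_phantom(spec, mask)
    lung_idx = np.flatnonzero(mask.ravel())
    scale = spec.image_size / 224.0
    records: list[ImageRecord] = []

    def finalize(img: np.ndarray) -> np.ndarray:
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        return np.clip(img, 0, 255).astype(np.uint8)

    for i in range(spec.n_normal):
        records.append(ImageRecord(f"normal_{i:04d}", finalize(base.copy()), "normal"))

    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    for i in range(spec.n_pneumonia):
        blobs = np.zeros((s, s))
        k = int(rng.integers(spec.opacity_count[0], spec.opacity_count[1] + 1))
        for _ in range(k):
            flat = int(rng.choice(lung_idx))
            cy, cx = divmod(flat, s)
            r = rng.uniform(*spec.opacity_radius) * scale
            blobs[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = 1.0
        blobs = gaussian_filter(blobs, sigma=spec.opacity_sigma * scale)
        blobs *= mask  # opacities exist only inside the lung fields
        img = base + spec.opacity_intensity * blobs
        gt = blobs > 0.2
        records.append(ImageRecord(f"pneumonia_{i:04d}", finalize(img), "pneumonia",
                                   opacity_mask=gt))
    return records


# ---------------------------------------------------------------------------
# directory IO (class-per-folder layout, Kaggle convention)


def load_directory(root) -> list[ImageRecord]:
    """Read a class-per-folder image tree into records, lexicographically
    ordered.  Folder names (case-insensitive) must be the known labels."""
    root = Path(root)
    if not root.is_dir():
        raise IOError(f"dataset root {root} is not a directory")
    records: list[ImageRecord] = []
    subdirs = sorted(p for p in root.iterdir() if p.is_dir())
    for sub in subdirs:
        label = sub.name.lower()
        if label not in LABELS:
            raise ValueError(
                f"unknown class directory {sub.name!r}; expected one of {list(LABELS)}")
        for path in sorted(sub.iterdir()):
            if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            try:
                img = Image.open(path)
                px = np.asarray(img.convert("L"), dtype=np.uint8)
            except Exception as exc:  # noqa: BLE001 - surface the file identity
                raise IOError(f"unreadable image {path}: {exc}") from exc
            records.append(ImageRecord(str(path.relative_to(root)), px, label))
    if not records:
        warnings.warn(f"no images found under {root}", stacklevel=2)
    return records


def write_dataset(records: list[ImageRecord], root, manifest: str = "manifest.csv") -> Path:
    """Write records as PNGs in class-per-folder layout plus a CSV manifest
    (identifier, label).  Returns the manifest path."""
    import pandas as pd

    root = Path(root)
    rows = []
    for rec in records:
        sub = root / rec.label.upper()
        sub.mkdir(parents=True, exist_ok=True)
        fname = f"{rec.identifier.replace('/', '_')}.png"
        Image.fromarray(rec.pixels).save(sub / fname)
        rows.append({"identifier": f"{rec.label.upper()}/{fname}", "label": rec.label})
    manifest_path = root / manifest
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
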