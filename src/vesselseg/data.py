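"""Dataset loading, preprocessing, augmentation and patch extraction.

Supported directory layouts (all rasters read with imageio; TIFF/GIF/PNG/
JPEG accepted):

``drive``
    root/images, root/1st_manual, optional root/mask and root/2nd_manual;
    files paired by the leading digits of the stem.  Records are sorted by
    id; the first 20 form the training split, the rest the test split.
``chase``
    all files in one directory: ``<stem>.jpg`` images with
    ``<stem>_1stHO.png`` / ``<stem>_2ndHO.png`` annotations.  First 20
    train, last 8 test.
``flat``
    root/images, root/labels, optional root/masks and root/labels2, paired
    by identical stem (the layout the synthetic generator writes).  Splits
    are given explicitly or default to all-train.

Preprocessing follows the training protocol: per-image min-max scaling to
[0,1], grayscale conversion X = 0.299 R + 0.578 G + 0.114 B, geometric
augmentation applied identically to image and labels, then random
extraction of 64x64 patches (4000 by default).  Full-image inference pads
reflectively to the next multiple of 8 and crops back afterwards.

Coordinates are 0-based, row-major, top-left origin; patch extents are
half-open.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

GRAY_COEFFS = (0.299, 0.578, 0.114)  # R, G, B
RASTER_EXTS = (".tif", ".tiff", ".gif", ".png", ".jpg", ".jpeg", ".bmp", ".ppm")


@dataclass
class FundusRecord:
    """One sample: image, binary vessel label, optional FOV mask and
    second-observer label."""

    id: str
    image: np.ndarray  # (H,W) gray in [0,1] or (H,W,3) RGB in [0,1]
    label: np.ndarray  # (H,W) binary {0,1}
    fov: np.ndarray | None = None
    label2: np.ndarray | None = None

    def __post_init__(self) -> None:
        hw = self.image.shape[:2]
        for name in ("label", "fov", "label2"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if arr.shape != hw:
                raise ValueError(f"{self.id}: {name} shape {arr.shape} != image {hw}")
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"{self.id}: {name} is not binary (values {vals[:8]})")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class Dataset:
    records: list[FundusRecord]
    train_ids: list[str]
    test_ids: list[str]

    def _subset(self, ids: list[str]) -> list[FundusRecord]:
        by_id = {r.id: r for r in self.records}
        return [by_id[i] for i in ids]

    @property
    def train(self) -> list[FundusRecord]:
        return self._subset(self.train_ids)

    @property
    def test(self) -> list[FundusRecord]:
        return self._subset(self.test_ids)


@dataclass
class Patch:
    image: np.ndarray  # (size,size) gray in [0,1]
    label: np.ndarray  # (size,size) binary
    source_id: str
    top_left: tuple[int, int]


@dataclass
class PatchSet:
    patches: list[Patch]
    seed: int

    def __len__(self) -> int:
        return len(self.patches)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack to (n,1,size,size) images and (n,size,size) labels."""
        imgs = np.stack([p.image for p in self.patches])[:, None]
        labels = np.stack([p.label for p in self.patches])
        return imgs, labels


# ---------------------------------------------------------------------------
# elementary transforms
# ---------------------------------------------------------------------------


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """Grayscale conversion X = 0.299 R + 0.578 G + 0.114 B.

    Input must carry three channels on the last axis with values in [0,1].
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim < 1 or rgb.shape[-1] != 3:
        raise ValueError(f"expected 3 channels on the last axis, got shape {rgb.shape}")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    return GRAY_COEFFS[0] * r + GRAY_COEFFS[1] * g + GRAY_COEFFS[2] * b


def normalize01(img: np.ndarray) -> np.ndarray:
    """Per-image min-max scaling to [0,1] (constant images map to 0)."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def preprocess_image(image: np.ndarray) -> np.ndarray:
    """Min-max normalise, then convert RGB to gray; returns (H,W) in [0,1]."""
    if image.ndim == 3:
        image = to_gray(normalize01(image))
    else:
        image = normalize01(image)
    return np.clip(image, 0.0, 1.0)


def pad_for_inference(gray: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflection-pad (bottom/right) to the next multiples of 8.

    Returns the padded raster and the original (H, W) as the crop spec;
    ``padded[:H, :W]`` restores the input exactly.
    """
    gray = np.asarray(gray)
    h, w = gray.shape[-2:]
    ph, pw = (-h) % 8, (-w) % 8
    if ph or pw:
        pad = [(0, 0)] * (gray.ndim - 2) + [(0, ph), (0, pw)]
        gray = np.pad(gray, pad, mode="reflect")
    return gray, (h, w)


def crop_to(padded: np.ndarray, spec: tuple[int, int]) -> np.ndarray:
    h, w = spec
    return padded[..., :h, :w]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _apply_geom(arr: np.ndarray, op: str, shift: tuple[int, int] = (0, 0)) -> np.ndarray:
    if op == "identity":
        return arr
    if op == "hflip":
        return arr[..., :, ::-1].copy()
    if op == "vflip":
        return arr[..., ::-1, :].copy()
    if op.startswith("rot"):
        k = int(op[3:]) // 90
        return np.rot90(arr, k=k, axes=(-2, -1)).copy()
    if op == "translate":
        dy, dx = shift
        h, w = arr.shape[-2:]
        pad = [(0, 0)] * (arr.ndim - 2) + [(abs(dy), abs(dy)), (abs(dx), abs(dx))]
        big = np.pad(arr, pad, mode="reflect")
        y0, x0 = abs(dy) - dy, abs(dx) - dx
        return big[..., y0 : y0 + h, x0 : x0 + w].copy()
    raise ValueError(f"unknown transform {op!r}")


@dataclass
class AugmentConfig:
    flips: bool = True
    rotations: tuple[int, ...] = (90, 180, 270)
    n_translations: int = 2
    max_shift: int = 16


def augment(records: list[FundusRecord], config: AugmentConfig | None = None,
            seed: int = 0) -> list[FundusRecord]:
    """Expand a record list with geometric copies.

    Default per record: identity, horizontal flip, vertical flip, rotations
    by 90/180/270 degrees and two random integer-pixel translations with
    reflection padding (8 records out per record in).  The identical
    transform is applied to image, label, FOV mask and second-observer
    label, so the pairs stay registered.  Deterministic given ``seed``.
    """
    config = config if config is not None else AugmentConfig()
    rng = np.random.default_rng(seed)
    ops: list[tuple[str, tuple[int, int]]] = [("identity", (0, 0))]
    if config.flips:
        ops += [("hflip", (0, 0)), ("vflip", (0, 0))]
    ops += [(f"rot{a}", (0, 0)) for a in config.rotations]
    out: list[FundusRecord] = []
    for rec in records:
        rec_ops = list(ops)
        for _ in range(config.n_translations):
            dy, dx = rng.integers(-config.max_shift, config.max_shift + 1, size=2)
            rec_ops.append(("translate", (int(dy), int(dx))))
        for j, (op, shift) in enumerate(rec_ops):
            if op == "identity":
                out.append(rec)
                continue
            out.append(
                replace(
                    rec,
                    id=f"{rec.id}~{op}{j}",
                    image=_apply_geom(rec.image, op, shift),
                    label=_apply_geom(rec.label, op, shift),
                    fov=None if rec.fov is None else _apply_geom(rec.fov, op, shift),
                    label2=None if rec.label2 is None else _apply_geom(rec.label2, op, shift),
                )
            )
    return out


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------


def extract_patches(records: list[FundusRecord], n: int = 4000, size: int = 64,
                    seed: int = 0, fov_centers_only: bool = False) -> PatchSet:
    """Randomly crop ``n`` image/label patches of ``size`` x ``size``.

    Source record and top-left position are drawn uniformly (seeded).
    Records smaller than the patch are skipped with a warning; with no
    eligible record at all this is an error.  Images are preprocessed
    (normalised + grayscale) before cropping.
    """
    rng = np.random.default_rng(seed)
    eligible = []
    for rec in records:
        h, w = rec.shape
        if h < size or w < size:
            warnings.warn(f"record {rec.id} ({h}x{w}) smaller than patch {size}; skipped")
            continue
        eligible.append(rec)
    if not eligible:
        raise ValueError(f"no record is at least {size}x{size}")
    grays = [preprocess_image(rec.image) for rec in eligible]
    patches: list[Patch] = []
    attempts = 0
    while len(patches) < n:
        attempts += 1
        if attempts > 100 * max(n, 1):
            raise RuntimeError("patch sampling stalled (no valid FOV-centred placements?)")
        k = int(rng.integers(len(eligible)))
        rec, gray = eligible[k], grays[k]
        h, w = rec.shape
        y = int(rng.integers(h - size + 1))
        x = int(rng.integers(w - size + 1))
        if fov_centers_only and rec.fov is not None:
            if not rec.fov[y + size // 2, x + size // 2]:
                continue
        patches.append(
            Patch(
                image=gray[y : y + size, x : x + size].copy(),
                label=rec.label[y : y + size, x : x + size].astype(np.int64),
                source_id=rec.id,
                top_left=(y, x),
            )
        )
    return PatchSet(patches=patches, seed=seed)


# ---------------------------------------------------------------------------
# dataset loading
# ---------------------------------------------------------------------------


def _read_raster(path: Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - depends on file content
        raise OSError(f"cannot read raster {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max if arr.max() > 1 else arr.astype(np.float64)
    return arr.astype(np.float64)


def _read_binary(path: Path) -> np.ndarray:
    arr = _read_raster(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return (arr >= 0.5).astype(np.int64)


def _index_by_stem(folder: Path, key) -> dict[str, Path]:
    out: dict[str, Path] = {}
    if not folder.is_dir():
        return out
    for p in sorted(folder.iterdir()):
        if p.suffix.lower() in RASTER_EXTS:
            k = key(p.stem)
            if k is not None:
                out[k] = p
    return out


def _numeric_key(stem: str) -> str | None:
    m = re.match(r"(\d+)", stem)
    return m.group(1) if m else stem


def load_dataset(root, layout: str = "flat",
                 train_ids: list[str] | None = None,
                 test_ids: list[str] | None = None) -> Dataset:
    """Read a dataset directory into paired records with a train/test split.

    See the module docstring for the three layouts.  Unpaired images or
    labels raise with an explicit listing of the orphans.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    layout = layout.lower()
    if layout == "drive":
        images = _index_by_stem(root / "images", _numeric_key)
        labels = _index_by_stem(root / "1st_manual", _numeric_key)
        fovs = _index_by_stem(root / "mask", _numeric_key)
        labels2 = _index_by_stem(root / "2nd_manual", _numeric_key)
        n_train = 20
    elif layout == "chase":
        all_files = _index_by_stem(root, lambda s: s)
        images = {k: v for k, v in all_files.items() if not k.endswith(("_1stHO", "_2ndHO"))}
        labels = {k[: -len("_1stHO")]: v for k, v in all_files.items() if k.endswith("_1stHO")}
        labels2 = {k[: -len("_2ndHO")]: v for k, v in all_files.items() if k.endswith("_2ndHO")}
        fovs = {}
        n_train = 20
    elif layout == "flat":
        images = _index_by_stem(root / "images", lambda s: s)
        labels = _index_by_stem(root / "labels", lambda s: s)
        fovs = _index_by_stem(root / "masks", lambda s: s)
        labels2 = _index_by_stem(root / "labels2", lambda s: s)
        n_train = None
    else:
        raise ValueError(f"unknown layout {layout!r}; expected drive, chase or flat")

    orphans = sorted(set(images) ^ set(labels))
    if orphans:
        raise ValueError(f"unpaired image/label stems in {root}: {orphans}")
    if not images:
        raise ValueError(f"no image/label pairs found under {root} (layout {layout})")

    records = []
    for k in sorted(images):
        records.append(
            FundusRecord(
                id=k,
                image=_read_raster(images[k]),
                label=_read_binary(labels[k]),
                fov=_read_binary(fovs[k]) if k in fovs else None,
                label2=_read_binary(labels2[k]) if k in labels2 else None,
            )
        )
    ids = [r.id for r in records]
    if train_ids is not None or test_ids is not None:
        train = list(train_ids or [])
        test = list(test_ids or [])
    elif n_train is not None:
        train, test = ids[:n_train], ids[n_train:]
    else:
        train, test = ids, []
    missing = [i for i in train + test if i not in set(ids)]
    if missing:
        raise ValueError(f"split references unknown record ids: {missing}")
    return Dataset(records=records, train_ids=train, test_ids=test)


def write_flat_dataset(root, records: list[FundusRecord]) -> None:
    """Write records to the flat layout (images/, labels/, masks/, labels2/)."""
    root = Path(root)
    for sub in ("images", "labels"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    for rec in records:
        img = rec.image
        if img.ndim == 2:
            img8 = np.clip(img * 255, 0, 255).astype(np.uint8)
        else:
            img8 = np.clip(img * 255, 0, 255).astype(np.uint8)
        iio.imwrite(root / "images" / f"{rec.id}.png", img8)
        iio.imwrite(root / "labels" / f"{rec.id}.png", (rec.label * 255).astype(np.uint8))
        if rec.fov is not None:
            (root / "masks").mkdir(exist_ok=True)
            iio.imwrite(root / "masks" / f"{rec.id}.png", (rec.fov * 255).astype(np.uint8))
        if rec.label2 is not None:
            (root / "labels2").mkdir(exist_ok=True)
            iio.imwrite(root / "labels2" / f"{rec.id}.png", (rec.label2 * 255).astype(np.uint8))
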