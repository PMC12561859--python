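"""Dataset handling: manifests, mask IO, side normalization, splitting.

Images arrive as pre-cropped single-eye periocular photographs.  Right-side
images are mirrored about the vertical axis so that every sample shares
left-periocular framing (medial side = image-left); masks flip together with
the image.  The manifest CSV links each sample id to its image, iris mask
and eyebrow mask, with optional ground-truth landmark columns.

Splitting is image-level by default with an optional patient-grouped mode
that keeps all of a patient's samples in one split.  Allocation is
floor-based on the requested ratios with remainders going to the training
split; a positive test ratio is guaranteed at least one item.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .geometry import BinaryMask, as_mask_array

SPLITS = ("train", "val", "test")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class DatasetItem:
    id: str
    side: str
    image_path: Path
    iris_mask_path: Path
    brow_mask_path: Path
    split: str = "unassigned"
    patient: str | None = None
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test ratios (must sum to 1) with deterministic shuffling."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    group_by: str = "none"  # 'none' | 'patient'

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"split ratios must sum to 1, got {self.ratios}")
        if any(r < 0 for r in self.ratios):
            raise ConfigurationError("split ratios must be non-negative")
        if self.group_by not in ("none", "patient"):
            raise ConfigurationError(
                f"group_by must be 'none' or 'patient', got {self.group_by!r}")


# ---------------------------------------------------------------------------
# Side normalization
# ---------------------------------------------------------------------------

def normalize_side(image: np.ndarray, masks, side: str):
    """Mirror right-side inputs to left-periocular framing.

    ``masks`` is a sequence of binary masks flipped consistently with the
    image; left-side inputs pass through unchanged.
    """
    if side not in ("left", "right"):
        raise InputError(f"side must be 'left' or 'right', got {side!r}")
    if side == "left":
        return image, list(masks)
    flipped_image = np.ascontiguousarray(np.asarray(image)[:, ::-1])
    flipped_masks = [np.ascontiguousarray(as_mask_array(m)[:, ::-1])
                     for m in masks]
    return flipped_image, flipped_masks


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def _allocate(n: int, ratios) -> tuple[int, int, int]:
    n_train = int(n * ratios[0])
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train += n - n_train - n_val - n_test  # remainders to train
    if n_test == 0 and ratios[2] > 0 and n_train > 1:
        n_train -= 1
        n_test += 1
    return n_train, n_val, n_test


def split_dataset(items: list[DatasetItem],
                  spec: SplitSpec | None = None) -> list[DatasetItem]:
    """Assign each item to train/val/test; deterministic for a fixed seed.

    With ``group_by='patient'`` whole patient groups are allocated so no
    patient spans splits (counts then match the ratios only approximately).
    """
    spec = spec or SplitSpec()
    if spec.group_by == "none" and len(items) < 3:
        raise InputError("need at least 3 items to split")
    rng = np.random.default_rng(spec.seed)

    if spec.group_by == "none":
        n_train, n_val, n_test = _allocate(len(items), spec.ratios)
        if min(n_train, n_val, n_test) == 0:
            warnings.warn("degenerate split: at least one subset is empty",
                          stacklevel=2)
        order = rng.permutation(len(items))
        for rank, idx in enumerate(order):
            if rank < n_train:
                items[idx].split = "train"
            elif rank < n_train + n_val:
                items[idx].split = "val"
            else:
                items[idx].split = "test"
        return items

    groups: dict[str, list[DatasetItem]] = {}
    for it in items:
        if it.patient is None:
            raise InputError(
                f"item {it.id} has no patient id; grouped split impossible")
        groups.setdefault(it.patient, []).append(it)
    if len(groups) < 3:
        raise InputError("need at least 3 patient groups for a grouped split")
    keys = sorted(groups)
    rng.shuffle(keys)
    n = len(items)
    targets = dict(zip(SPLITS, _allocate(n, spec.ratios)))
    filled = {s: 0 for s in SPLITS}
    # fill test and val first so small splits are not starved by large groups
    for key in keys:
        size = len(groups[key])
        deficits = {s: targets[s] - filled[s] for s in ("test", "val", "train")}
        dest = max(deficits, key=lambda s: deficits[s])
        if deficits[dest] <= 0:
            dest = "train"
        for it in groups[key]:
            it.split = dest
        filled[dest] += size
    return items


# ---------------------------------------------------------------------------
# Manifest and mask IO
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("id", "side", "image_path", "iris_mask_path",
                     "brow_mask_path")


def load_manifest(path, check_files: bool = True) -> list[DatasetItem]:
    """Read a manifest CSV; paths resolve relative to the manifest's folder."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"manifest {path} lacks columns {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise InputError(f"duplicate manifest ids: {dupes[:5]}")
    root = path.parent
    items = []
    for _, row in df.iterrows():
        item = DatasetItem(
            id=str(row["id"]),
            side=str(row["side"]),
            image_path=root / str(row["image_path"]),
            iris_mask_path=root / str(row["iris_mask_path"]),
            brow_mask_path=root / str(row["brow_mask_path"]),
            split=str(row["split"]) if "split" in df.columns else "unassigned",
            patient=str(row["patient"]) if "patient" in df.columns else None,
            extras={k: row[k] for k in df.columns
                    if k not in _REQUIRED_COLUMNS + ("split", "patient")},
        )
        if check_files:
            for p in (item.image_path, item.iris_mask_path, item.brow_mask_path):
                if not Path(p).exists():
                    raise InputError(f"manifest references missing file: {p}")
        items.append(item)
    return items


def save_manifest(items: list[DatasetItem], path) -> None:
    root = Path(path).parent
    rows = []
    for it in items:
        rows.append({
            "id": it.id, "side": it.side,
            "image_path": _relativize(it.image_path, root),
            "iris_mask_path": _relativize(it.iris_mask_path, root),
            "brow_mask_path": _relativize(it.brow_mask_path, root),
            "split": it.split,
            **({"patient": it.patient} if it.patient is not None else {}),
            **it.extras,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def _relativize(p: Path, root: Path) -> str:
    try:
        return str(Path(p).relative_to(root))
    except ValueError:
        return str(p)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise InputError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # non-image content
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def read_mask(path, class_label: str = "iris") -> BinaryMask:
    """Read a mask PNG; any nonzero value counts as foreground."""
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise InputError(f"mask {path} is not 2-D (shape {arr.shape})")
    return BinaryMask(grid=arr != 0, class_label=class_label)


def write_mask(mask, path) -> None:
    """Write a binary mask as an 8-bit 0/255 PNG."""
    arr = as_mask_array(mask)
    iio.imwrite(Path(path), arr.astype(np.uint8) * 255)


def save_report(report, path) -> None:
    """Write an ErrorReport: CSV table, or JSON (with exclusion counts)
    when the path ends in ``.json``."""
    path = Path(path)
    if path.suffix == ".json":
        import json
        payload = {
            "per_landmark": report.per_landmark.reset_index()
                                  .to_dict(orient="records"),
            "overall_rmse_mm": report.overall_rmse_mm,
            "overall_mape_pct": report.overall_mape_pct,
            "brow_subgroup_mape_pct": report.brow_subgroup_mape_pct,
            "brow_subgroup_rmse_mm": report.brow_subgroup_rmse_mm,
            "excluded": report.excluded,
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        report.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# Training-array assembly
# ---------------------------------------------------------------------------

def load_training_arrays(items: list[DatasetItem], task: str):
    """Assemble (X, Y) model arrays for one task from dataset items.

    ``task`` is 'iris' or 'brow'.  Images are side-normalized, resized to
    the model grid and scaled to [0, 1]; masks are nearest-neighbor
    downscaled.  Returns X (N, 3, 64, 64) float32, Y (N, 1, 64, 64) float32.
    """
    from .model import downscale_mask, preprocess_image

    if task not in ("iris", "brow"):
        raise InputError(f"task must be 'iris' or 'brow', got {task!r}")
    xs, ys = [], []
    for it in items:
        image = read_image(it.image_path)
        mask_path = it.iris_mask_path if task == "iris" else it.brow_mask_path
        mask = read_mask(mask_path, class_label=task).grid
        image, (mask,) = normalize_side(image, [mask], it.side)
        xs.append(preprocess_image(image)[0])
        ys.append(downscale_mask(mask)[None].astype(np.float32))
    if not xs:
        raise InputError("no items to assemble arrays from")
    return np.stack(xs), np.stack(ys)
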