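"""Datasets and manifest I/O.

A :class:`DomainDataset` holds either feature vectors (N, d) or RGB
images (N, H, W, 3) for one domain, with optional integer grade labels.
Two manifest flavours share the path/grade/domain CSV schema used by the
CLI: image manifests reference PNG/JPEG files on disk, feature manifests
carry the vectors inline as ``f0..f{d-1}`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingLabelError

#: grades {0,1} are non-referable, {2,3,4} referable
REFERABLE_THRESHOLD = 2


def referable(grades: np.ndarray) -> np.ndarray:
    """Map ICDR grades 0-4 to the binary referable flag."""
    return (np.asarray(grades) >= REFERABLE_THRESHOLD).astype(int)


@dataclass
class DomainDataset:
    """Samples from one domain: features or images, with optional labels."""

    X: np.ndarray
    y: np.ndarray | None
    domain: str
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X)
        if self.X.size == 0:
            raise InvalidInputError(f"domain {self.domain!r}: empty data")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if len(self.y) != len(self.X):
                raise InvalidInputError(
                    f"domain {self.domain!r}: {len(self.X)} samples but {len(self.y)} labels"
                )
        if not self.ids:
            self.ids = [f"{self.domain}:{i}" for i in range(len(self.X))]

    def __len__(self) -> int:
        return len(self.X)

    @property
    def kind(self) -> str:
        return "image" if self.X.ndim == 4 else "feature"

    @property
    def labeled(self) -> bool:
        return self.y is not None

    def require_labels(self) -> np.ndarray:
        if self.y is None:
            raise MissingLabelError(f"domain {self.domain!r} has no labels")
        return self.y

    def unlabeled(self) -> "DomainDataset":
        """A copy with labels hidden (for adaptation inputs)."""
        return DomainDataset(self.X, None, self.domain, list(self.ids))


def write_feature_manifest(data: DomainDataset, path: str | Path) -> None:
    d = data.X.shape[1]
    df = pd.DataFrame(data.X, columns=[f"f{i}" for i in range(d)])
    df.insert(0, "id", data.ids)
    df["grade"] = data.y if data.y is not None else ""
    df["domain"] = data.domain
    df.to_csv(path, index=False)


def read_feature_manifest(path: str | Path) -> DomainDataset:
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if not feat_cols:
        raise InvalidInputError(f"{path}: no feature columns f0..fd found")
    feat_cols.sort(key=lambda c: int(c[1:]))
    X = df[feat_cols].to_numpy(dtype=np.float64)
    grades = df["grade"] if "grade" in df else pd.Series([np.nan] * len(df))
    y = None if grades.isna().all() else grades.to_numpy(dtype=int)
    domain = str(df["domain"].iloc[0]) if "domain" in df else "unknown"
    ids = [str(v) for v in df["id"]] if "id" in df else []
    return DomainDataset(X, y, domain, ids)


def write_image_manifest(rows: list[dict], path: str | Path) -> None:
    """rows: dicts with keys path, grade (int or ''), domain."""
    pd.DataFrame(rows, columns=["path", "grade", "domain"]).to_csv(path, index=False)


def read_image_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"path", "domain"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def load_image_dataset(manifest_path: str | Path) -> DomainDataset:
    """Load all images referenced by a manifest into one array dataset."""
    from PIL import Image

    df = read_image_manifest(manifest_path)
    base = Path(manifest_path).parent
    imgs, ids = [], []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        imgs.append(np.asarray(Image.open(p).convert("RGB")))
        ids.append(str(row["path"]))
    shapes = {im.shape for im in imgs}
    if len(shapes) > 1:
        raise InvalidInputError(f"images have mixed shapes {shapes}; preprocess first")
    grades = df["grade"] if "grade" in df else pd.Series([np.nan] * len(df))
    y = None if grades.isna().all() else grades.to_numpy(dtype=int)
    domain = str(df["domain"].iloc[0])
    return DomainDataset(np.stack(imgs), y, domain, ids)


def load_dataset(manifest_path: str | Path) -> DomainDataset:
    """Dispatch on manifest schema: feature columns inline vs image paths."""
    head = pd.read_csv(manifest_path, nrows=1)
    if "path" in head.columns:
        return load_image_dataset(manifest_path)
    return read_feature_manifest(manifest_path)
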