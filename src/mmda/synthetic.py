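"""Synthetic multi-domain benchmarks with known labels and controlled shift.

Two tiers: Gaussian feature-vector domains (fast, exercises every
adaptation stage) and small procedurally rendered fundus-like images
(a bright disc on black ground with grade-dependent bright/dark spots,
shifted between domains by global brightness/tint/blur).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import DomainDataset, referable, write_feature_manifest, write_image_manifest
from .errors import InvalidParameterError, ShapeError

DEFAULT_SHIFT_MAGNITUDES = (0.5, 1.0, 2.0)
DEFAULT_LESION_RANGES = {0: (0, 0), 1: (1, 2), 2: (3, 5), 3: (6, 9), 4: (10, 14)}


@dataclass
class FeatureDomainSpec:
    class_means: np.ndarray  # (K, d)
    cov_scale: float = 1.0
    shift_offset: np.ndarray | None = None  # (d,), added to every mean
    rotation_angle: float = 0.0  # radians, in the plane of the first two coords
    n_per_class: int = 100
    seed: int = 0
    name: str = "domain"

    def __post_init__(self):
        self.class_means = np.asarray(self.class_means, dtype=np.float64)
        if self.class_means.ndim != 2 or self.class_means.shape[1] < 2:
            raise InvalidParameterError("class_means must be (K, d) with d >= 2")
        if self.n_per_class < 1:
            raise InvalidParameterError("n_per_class must be >= 1")
        if self.shift_offset is None:
            self.shift_offset = np.zeros(self.class_means.shape[1])
        self.shift_offset = np.asarray(self.shift_offset, dtype=np.float64)

    @property
    def k(self) -> int:
        return self.class_means.shape[0]

    @property
    def d(self) -> int:
        return self.class_means.shape[1]

    def effective_means(self) -> np.ndarray:
        means = self.class_means.copy()
        if self.rotation_angle:
            c, s = np.cos(self.rotation_angle), np.sin(self.rotation_angle)
            rot = means[:, :2] @ np.array([[c, s], [-s, c]])
            means[:, :2] = rot
        return means + self.shift_offset


@dataclass
class ImageDomainSpec:
    side: int = 32
    disc_radius_frac: float = 0.42
    lesion_ranges: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LESION_RANGES)
    )
    brightness: float = 1.0
    tint: tuple[float, float, float] = (0.0, 0.0, 0.0)
    blur_sigma: float = 0.0
    n_per_class: int = 20
    seed: int = 0
    name: str = "imgdomain"

    def __post_init__(self):
        if self.side < 16:
            raise InvalidParameterError("side must be >= 16")
        counts = [self.lesion_ranges[g][1] for g in sorted(self.lesion_ranges)]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise InvalidParameterError("lesion counts must grow monotonically with grade")


@dataclass
class MultiDomainBenchmark:
    """n labeled source domains plus one target with held-out labels."""

    sources: list[DomainDataset]
    target: DomainDataset  # labels hidden
    target_labels: np.ndarray
    shift_magnitudes: list[float] = field(default_factory=list)

    @property
    def n_sources(self) -> int:
        return len(self.sources)


def _sample_feature_domain(spec: FeatureDomainSpec) -> DomainDataset:
    rng = np.random.default_rng(spec.seed)
    means = spec.effective_means()
    xs, ys = [], []
    for cls in range(spec.k):
        xs.append(rng.normal(means[cls], spec.cov_scale, size=(spec.n_per_class, spec.d)))
        ys.append(np.full(spec.n_per_class, cls))
    return DomainDataset(np.concatenate(xs), np.concatenate(ys), spec.name)


def make_feature_domains(
    specs: list[FeatureDomainSpec], target_spec: FeatureDomainSpec
) -> MultiDomainBenchmark:
    d, k = target_spec.d, target_spec.k
    for s in specs:
        if s.d != d or s.k != k:
            raise ShapeError(f"spec {s.name!r} has (d={s.d}, K={s.k}), expected ({d}, {k})")
    sources = [_sample_feature_domain(s) for s in specs]
    tgt = _sample_feature_domain(target_spec)
    mags = [float(np.linalg.norm(s.shift_offset)) for s in specs]
    return MultiDomainBenchmark(sources, tgt.unlabeled(), tgt.y.copy(), mags)


def default_feature_benchmark(
    seed: int = 0,
    d: int = 16,
    k: int = 2,
    n_per_class: int = 200,
    shift_magnitudes: tuple[float, ...] = DEFAULT_SHIFT_MAGNITUDES,
    cov_scale: float = 0.5,
    class_sep: float = 2.0,
    angle_scale: float = 0.6,
    matched_source: bool = False,
    matched_index: int = 0,
) -> MultiDomainBenchmark:
    """The desk-scale benchmark: 3 shifted Gaussian sources + 1 target.

    Each domain's shift magnitude drives two effects: a rotation of the
    class-mean axis (magnitude x ``angle_scale`` radians, with signs
    +,-,- across the sources so they fan out) and an offset in a random
    direction orthogonal to the class axis. The rotation is the part a
    normalizing encoder cannot undo, so far sources genuinely mislead a
    uniform source ensemble on the target. The target sits
    ``shift_magnitudes[1]`` beyond source 0 along the rotation, making
    source 0 the closest domain. With ``matched_source`` the target
    instead reuses source ``matched_index``'s shift exactly (same
    distribution, fresh draw).
    """
    rng = np.random.default_rng(seed)
    means = np.zeros((k, d))
    axis = np.zeros(d)
    axis[0] = 1.0
    offsets = np.linspace(-class_sep / 2.0, class_sep / 2.0, k)
    for cls in range(k):
        means[cls] = offsets[cls] * axis

    def ortho_dir() -> np.ndarray:
        v = rng.normal(size=d)
        v[:2] = 0.0  # keep clear of the rotation plane
        v /= np.linalg.norm(v)
        return v

    angle_signs = [1.0, -1.0, -1.0]
    dirs = [ortho_dir() for _ in shift_magnitudes]
    specs = [
        FeatureDomainSpec(
            class_means=means,
            cov_scale=cov_scale,
            shift_offset=mag * dirs[i],
            rotation_angle=angle_signs[i % 3] * mag * angle_scale,
            n_per_class=n_per_class,
            seed=seed * 1000 + 17 * (i + 1),
            name=f"source{i}",
        )
        for i, mag in enumerate(shift_magnitudes)
    ]
    if matched_source:
        target_offset = specs[matched_index].shift_offset.copy()
        target_angle = specs[matched_index].rotation_angle
    else:
        target_offset = specs[0].shift_offset + shift_magnitudes[1] * dirs[0]
        target_angle = specs[0].rotation_angle + shift_magnitudes[1] * angle_scale
    target_spec = FeatureDomainSpec(
        class_means=means,
        cov_scale=cov_scale,
        shift_offset=target_offset,
        rotation_angle=target_angle,
        n_per_class=n_per_class,
        seed=seed * 1000 + 997,
        name="target",
    )
    return make_feature_domains(specs, target_spec)


def _render_fundus(
    spec: ImageDomainSpec, grade: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """One disc-on-black image with grade-dependent lesion spots."""
    side = spec.side
    img = np.zeros((side, side, 3), dtype=np.float64)
    center = (side - 1) / 2.0 + rng.uniform(-1.0, 1.0, size=2)
    radius = spec.disc_radius_frac * side
    yy, xx = np.mgrid[0:side, 0:side]
    disc = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    base = np.array([175.0, 95.0, 45.0])  # retina-like orange
    img[disc] = base
    lo, hi = spec.lesion_ranges[grade]
    n_spots = int(rng.integers(lo, hi + 1))
    inside = np.argwhere(disc)
    for s in range(n_spots):
        cy, cx = inside[rng.integers(0, len(inside))]
        r_spot = rng.uniform(1.0, 2.5)
        spot = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_spot**2
        if s % 3 == 2:  # dark hemorrhage-like spot
            img[spot & disc] = np.array([60.0, 15.0, 15.0])
        else:  # bright exudate-like spot
            img[spot & disc] = np.array([235.0, 220.0, 130.0])
    img *= spec.brightness
    img += np.asarray(spec.tint)
    if spec.blur_sigma > 0:
        for ch in range(3):
            img[:, :, ch] = gaussian_filter(img[:, :, ch], spec.blur_sigma, mode="reflect")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), n_spots


def _sample_image_domain(spec: ImageDomainSpec) -> tuple[DomainDataset, list[int]]:
    rng = np.random.default_rng(spec.seed)
    imgs, ys, spot_counts = [], [], []
    for grade in sorted(spec.lesion_ranges):
        for _ in range(spec.n_per_class):
            img, n_spots = _render_fundus(spec, grade, rng)
            imgs.append(img)
            ys.append(grade)
            spot_counts.append(n_spots)
    return DomainDataset(np.stack(imgs), np.array(ys), spec.name), spot_counts


def make_image_domains(
    specs: list[ImageDomainSpec], target_spec: ImageDomainSpec
) -> MultiDomainBenchmark:
    sources = [_sample_image_domain(s)[0] for s in specs]
    tgt, _ = _sample_image_domain(target_spec)
    return MultiDomainBenchmark(sources, tgt.unlabeled(), tgt.y.copy(), [])


def default_image_benchmark(seed: int = 0, n_per_class: int = 15, side: int = 32) -> MultiDomainBenchmark:
    """3 image sources + 1 target, shifted by brightness/tint/blur."""
    shifts = [
        dict(brightness=1.0, tint=(0.0, 0.0, 0.0), blur_sigma=0.0),
        dict(brightness=0.8, tint=(10.0, 0.0, -10.0), blur_sigma=0.4),
        dict(brightness=1.25, tint=(-15.0, 5.0, 15.0), blur_sigma=0.8),
    ]
    specs = [
        ImageDomainSpec(
            side=side, n_per_class=n_per_class, seed=seed * 1000 + 31 * (i + 1),
            name=f"imgsource{i}", **kw,
        )
        for i, kw in enumerate(shifts)
    ]
    target_spec = ImageDomainSpec(
        side=side, brightness=0.9, tint=(5.0, -5.0, 0.0), blur_sigma=0.5,
        n_per_class=n_per_class, seed=seed * 1000 + 499, name="imgtarget",
    )
    return make_image_domains(specs, target_spec)


def write_benchmark(bench: MultiDomainBenchmark, out_dir: str | Path) -> dict[str, Path]:
    """Persist a benchmark as manifests (feature CSVs, or PNGs + CSV)."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    labeled_target = DomainDataset(
        bench.target.X, bench.target_labels, bench.target.domain, list(bench.target.ids)
    )
    for ds in [*bench.sources, labeled_target]:
        key = "target" if ds.domain == labeled_target.domain else ds.domain
        if ds.kind == "feature":
            p = out_dir / f"{ds.domain}.csv"
            write_feature_manifest(ds, p)
        else:
            img_dir = out_dir / ds.domain
            img_dir.mkdir(exist_ok=True)
            rows = []
            for i, (img, grade) in enumerate(zip(ds.X, ds.y)):
                name = f"{i:04d}.png"
                Image.fromarray(img).save(img_dir / name)
                rows.append({"path": name, "grade": int(grade), "domain": ds.domain})
            p = img_dir / "manifest.csv"
            write_image_manifest(rows, p)
        paths[key] = p
    return paths


def referable_labels(grades: np.ndarray) -> np.ndarray:
    return referable(grades)
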