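"""Synthetic fundus photographs with ground-truth lesion annotations.

Emulates the appearance cues that matter for parapapillary-atrophy (PPA)
segmentation: a bright, roughly circular optic disc; an adjacent crescent
of atrophy of intermediate brightness whose maximal radial width is a
controllable fraction of the papilla diameter; dark curved vessels
radiating from the disc; a tessellated ("leopard") speckle texture; and a
global blur imitating the soft boundaries of myopic fundi. Every sample
carries its lesion mask, boundary (edge) map, disc mask and geometry, so
the whole training/evaluation pipeline is testable without clinical data.

The module also houses dataset splitting (seeded permutation at an exact
integer ratio) and the lesion-size rule: a lesion whose radial extent
beyond the disc rim is at most one third of the papilla diameter is
"small", otherwise "large".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter
from scipy.spatial import ConvexHull
from skimage.draw import bezier_curve

__all__ = [
    "SynthParams", "FundusSample", "generate_sample", "mask_to_edge",
    "split_dataset", "classify_lesion_size", "measure_papilla_diameter",
    "write_dataset", "load_manifest",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    ``ppa_width_fraction_range`` is the maximal radial width of the
    atrophy crescent as a fraction of the papilla diameter (2x the disc
    radius); ``crescent_angular_span`` is the angular extent of the
    crescent in degrees (0 produces an empty lesion).
    """

    canvas_size: int = 352
    disc_radius_range: tuple[float, float] = (28.0, 44.0)
    ppa_width_fraction_range: tuple[float, float] = (0.12, 0.75)
    crescent_angular_span: float = 200.0
    vessel_count: int = 7
    speckle_strength: float = 0.08
    blur_sigma: float = 1.2
    seed: int = 0
    color: bool = False

    def __post_init__(self):
        if self.canvas_size < 64:
            raise ValueError("canvas_size must be >= 64")
        for name in ("disc_radius_range", "ppa_width_fraction_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is degenerate: {lo} > {hi}")
        lo, hi = self.ppa_width_fraction_range
        if not (0.0 < lo <= 1.5 and hi <= 1.5):
            raise ValueError(
                "ppa_width_fraction_range must lie within (0, 1.5]")
        if self.disc_radius_range[0] <= 0:
            raise ValueError("disc_radius_range must be positive")
        if not 0.0 <= self.crescent_angular_span <= 360.0:
            raise ValueError("crescent_angular_span must be in [0, 360]")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        if self.speckle_strength < 0:
            raise ValueError("speckle_strength must be >= 0")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass
class FundusSample:
    """One image with its ground truth and disc geometry.

    ``mask`` marks the atrophy ring outside the disc (never overlapping
    ``disc_mask``); ``edge`` is the 1-pixel inner boundary of ``mask``;
    ``ppa_width`` is the realised maximal radial extent of the atrophy
    beyond the disc rim in pixels.
    """

    image: np.ndarray
    mask: np.ndarray
    edge: np.ndarray
    disc_mask: np.ndarray
    papilla_diameter: float
    ppa_width: float

    def validate(self) -> "FundusSample":
        shapes = {a.shape[:2] for a in (self.image, self.mask, self.edge,
                                        self.disc_mask)}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent grid shapes: {shapes}")
        if np.any(self.mask.astype(bool) & self.disc_mask.astype(bool)):
            raise ValueError("atrophy mask overlaps the disc")
        if np.any(self.edge.astype(bool) & ~self.mask.astype(bool)):
            raise ValueError("edge pixels outside the mask")
        if self.papilla_diameter <= 0:
            raise ValueError("papilla_diameter must be positive")
        return self


def mask_to_edge(mask: np.ndarray, thickness: int = 1) -> np.ndarray:
    """Inner morphological boundary: mask minus its erosion.

    Erosion uses the 3x3 cross structuring element iterated ``thickness``
    times (a city-block ball of radius ``thickness``), with the outside of
    the grid treated as background, so a mask touching the border keeps a
    boundary there. The result is a subset of the mask.
    """
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must be binary")
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    m = mask.astype(bool)
    eroded = binary_erosion(m, structure=_CROSS, iterations=thickness,
                            border_value=0)
    return (m & ~eroded).astype(np.uint8)


def split_dataset(n: int, ratio_train: int, ratio_test: int, seed: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded permutation split at an exact integer ratio.

    |train| = round(n * ratio_train / (ratio_train + ratio_test)) with
    half-up rounding; train and test are disjoint, sorted, and cover
    0..n-1.
    """
    if ratio_train < 1 or ratio_test < 1:
        raise ValueError("split ratios must be positive integers")
    if n < ratio_train + ratio_test:
        raise ValueError(
            f"need at least {ratio_train + ratio_test} samples, got {n}")
    n_train = int(np.floor(n * ratio_train / (ratio_train + ratio_test) + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def measure_papilla_diameter(disc_mask: np.ndarray) -> float:
    """Maximal chord of the disc mask (exact, via its convex hull)."""
    pts = np.argwhere(np.asarray(disc_mask, dtype=bool))
    if len(pts) == 0:
        raise ValueError("disc mask is empty")
    if len(pts) == 1:
        return 1.0
    hull_pts = pts[ConvexHull(pts).vertices] if len(pts) > 3 else pts
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def classify_lesion_size(sample: FundusSample) -> str:
    """"small" iff the radial PPA extent is <= one third of the papilla
    diameter; an empty lesion is small."""
    if not np.any(sample.disc_mask):
        raise ValueError("disc mask is empty")
    pd_ = sample.papilla_diameter
    if pd_ is None or pd_ <= 0:
        pd_ = measure_papilla_diameter(sample.disc_mask)
    return "small" if sample.ppa_width <= pd_ / 3.0 else "large"


def _radial_extent(mask: np.ndarray, cy: float, cx: float,
                   disc_radius: float) -> float:
    """Maximal distance of a mask pixel beyond the disc rim."""
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return 0.0
    r = np.sqrt((ys - cy) ** 2 + (xs - cx) ** 2)
    return float(max(0.0, r.max() - disc_radius))


def generate_sample(params: SynthParams | None = None,
                    seed: int | None = None) -> FundusSample:
    """Generate one fundus-like sample; identical (params, seed) pairs
    reproduce bit-identical results."""
    params = params or SynthParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    s = params.canvas_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)

    # disc geometry: keep disc + widest possible crescent inside the canvas
    r_d = rng.uniform(*params.disc_radius_range)
    frac = rng.uniform(*params.ppa_width_fraction_range)
    w_max = frac * 2.0 * r_d
    margin = r_d + w_max + 4.0
    lo = min(margin, s / 2.0)
    cy = rng.uniform(lo, s - lo) if s - lo > lo else s / 2.0
    cx = rng.uniform(lo, s - lo) if s - lo > lo else s / 2.0

    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    theta = np.arctan2(yy - cy, xx - cx)
    disc_mask = (r <= r_d).astype(np.uint8)

    # crescent: radial width tapers cosinusoidally to 0 at the span edges
    span = np.deg2rad(params.crescent_angular_span)
    theta0 = rng.uniform(-np.pi, np.pi)
    dtheta = np.angle(np.exp(1j * (theta - theta0)))
    if span > 0:
        taper = np.cos(np.clip(dtheta / span, -0.5, 0.5) * np.pi)
        width = w_max * np.sqrt(np.clip(taper, 0.0, 1.0))
        inside = np.abs(dtheta) <= span / 2.0
        mask = ((r > r_d) & (r <= r_d + width) & inside).astype(np.uint8)
    else:
        mask = np.zeros((s, s), dtype=np.uint8)
    edge = mask_to_edge(mask, 1)

    # ---- rendering ------------------------------------------------------
    image = np.full((s, s), 0.32, dtype=np.float32)
    # mild radial vignette
    rc = np.sqrt((yy - s / 2) ** 2 + (xx - s / 2) ** 2) / (s / 2)
    image -= 0.10 * rc ** 2
    # leopard-fundus speckle: band-passed noise
    if params.speckle_strength > 0:
        noise = rng.standard_normal((s, s)).astype(np.float32)
        speckle = gaussian_filter(noise, 3.0) - gaussian_filter(noise, 9.0)
        sd = speckle.std()
        if sd > 0:
            image += params.speckle_strength * speckle / sd
    # vessels: dark quadratic curves leaving the disc centre
    vessel = np.zeros((s, s), dtype=bool)
    for _ in range(params.vessel_count):
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.4, 0.9) * s / 2
        y1 = cy + np.sin(ang) * length * 0.5 + rng.normal(0, s * 0.05)
        x1 = cx + np.cos(ang) * length * 0.5 + rng.normal(0, s * 0.05)
        y2 = cy + np.sin(ang) * length
        x2 = cx + np.cos(ang) * length
        pts = [int(np.clip(v, 0, s - 1)) for v in (cy, cx, y1, x1, y2, x2)]
        rr, cc = bezier_curve(pts[0], pts[1], pts[2], pts[3], pts[4], pts[5],
                              weight=1.0, shape=(s, s))
        vessel[rr, cc] = True
    if params.vessel_count:
        vessel = binary_dilation(vessel, iterations=1)
    image[vessel] -= 0.15
    # atrophy: brighter than background, darker than disc
    image[mask.astype(bool)] = 0.62 + 0.04 * rng.standard_normal()
    image[disc_mask.astype(bool)] = 0.92
    if params.blur_sigma > 0:
        image = gaussian_filter(image, params.blur_sigma)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    if params.color:
        # fundus-like tint: strong red, medium green, weak blue
        image = np.stack([np.clip(image * 1.15, 0, 1), image * 0.75,
                          image * 0.45], axis=-1).astype(np.float32)

    sample = FundusSample(
        image=image, mask=mask, edge=edge, disc_mask=disc_mask,
        papilla_diameter=2.0 * r_d,
        ppa_width=_radial_extent(mask, cy, cx, r_d),
    )
    return sample.validate()


# ---------------------------------------------------------------------------
# dataset writing / loading
# ---------------------------------------------------------------------------

def _save_png(path: Path, arr: np.ndarray, binary: bool) -> None:
    if binary:
        img = Image.fromarray((np.asarray(arr) * 255).astype(np.uint8))
    elif arr.ndim == 3:
        img = Image.fromarray(
            np.clip(arr * 255, 0, 255).astype(np.uint8), mode="RGB")
    else:
        img = Image.fromarray(
            np.clip(arr * 255, 0, 255).astype(np.uint8), mode="L")
    img.save(path)


def write_dataset(out_dir, n: int, params: SynthParams | None = None,
                  seed: int = 0, ratio: tuple[int, int] = (4, 1)
                  ) -> pd.DataFrame:
    """Generate ``n`` samples, write PNGs and the manifest CSV.

    The manifest has columns id, image_path, mask_path, edge_path,
    disc_path, papilla_diameter, ppa_width, size_class, split; paths are
    relative to the manifest location.
    """
    params = params or SynthParams()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "edges").mkdir(exist_ok=True)
    (out / "discs").mkdir(exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sample_seeds = ss.generate_state(n) % (2 ** 31)
    train_idx, _ = split_dataset(n, ratio[0], ratio[1],
                                 seed=int(ss.generate_state(n + 1)[-1] % (2 ** 31)))
    train_set = set(int(i) for i in train_idx)
    rows = []
    for i in range(n):
        smp = generate_sample(params, seed=int(sample_seeds[i]))
        sid = f"{i:05d}"
        paths = {
            "image_path": f"images/{sid}.png",
            "mask_path": f"masks/{sid}.png",
            "edge_path": f"edges/{sid}.png",
            "disc_path": f"discs/{sid}.png",
        }
        _save_png(out / paths["image_path"], smp.image, binary=False)
        _save_png(out / paths["mask_path"], smp.mask, binary=True)
        _save_png(out / paths["edge_path"], smp.edge, binary=True)
        _save_png(out / paths["disc_path"], smp.disc_mask, binary=True)
        rows.append({
            "id": sid, **paths,
            "papilla_diameter": smp.papilla_diameter,
            "ppa_width": smp.ppa_width,
            "size_class": classify_lesion_size(smp),
            "split": "train" if i in train_set else "test",
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest(manifest_path) -> pd.DataFrame:
    """Read a manifest CSV and make its paths absolute."""
    path = Path(manifest_path)
    df = pd.read_csv(path, dtype={"id": str})
    missing = []
    for col in ("image_path", "mask_path", "edge_path", "disc_path"):
        if col in df.columns:
            df[col] = [str((path.parent / p)) for p in df[col]]
            missing += [p for p in df[col] if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            f"{len(missing)} manifest files missing, e.g. {missing[:3]}")
    return df


def load_png(path, binary: bool) -> np.ndarray:
    img = Image.open(path)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    if binary:
        return (arr > 0.5).astype(np.uint8)
    return arr
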