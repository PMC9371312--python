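"""Synthetic breast-ultrasound phantom generator.

A breast-ultrasound B-mode frame is approximated as three horizontal tissue
bands — a bright skin/subcutaneous-fat band at the top, a mid-intensity
mammary-gland band, and a darker muscle region with periodic bright rib-like
echoes below — because that layered anatomy is where the anatomical prior of
the network comes from: lesions occur inside the gland band. An optional
single hypoechoic lesion is placed fully inside the gland band; benign lesions
are smooth ellipses while malignant lesions are irregular star polygons with
radial jitter, giving the classifier a learnable morphology signal. The clean
image is blurred and corrupted with unit-mean multiplicative gamma speckle so
layer contrast is preserved in expectation.

Every sample is a deterministic function of ``(cfg.seed, index)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon


class PhantomConfigError(ValueError):
    """Raised when a PhantomConfig violates its invariants."""


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise parameters of the phantom population.

    Defaults are the desk-scale study conditions: 64x64 frames, a 15% skin/fat
    band over a 35% gland band, a lesion in half the images (half of those
    malignant), lesion radii 5-9 px, lesion intensity 0.25 below the gland
    background, and gamma speckle with standard deviation 0.15.
    """

    image_height: int = 64
    image_width: int = 64
    skin_band_fraction: float = 0.15
    gland_band_fraction: float = 0.35
    lesion_probability: float = 0.5
    malignant_fraction: float = 0.5
    lesion_radius_range: Tuple[int, int] = (5, 9)
    speckle_strength: float = 0.15
    contrast_lesion: float = -0.25
    seed: int = 0
    binary_labels: bool = True  # normal-vs-lesion; False: normal/benign/malignant

    def __post_init__(self):
        self.validate()

    @property
    def skin_rows(self) -> int:
        return int(round(self.skin_band_fraction * self.image_height))

    @property
    def gland_rows(self) -> Tuple[int, int]:
        """Half-open row interval [start, stop) of the gland band."""
        start = self.skin_rows
        stop = start + int(round(self.gland_band_fraction * self.image_height))
        return start, stop

    def validate(self) -> None:
        if not (0.05 <= self.skin_band_fraction <= 0.25):
            raise PhantomConfigError(
                f"skin_band_fraction {self.skin_band_fraction} outside [0.05, 0.25]")
        if not (0.2 <= self.gland_band_fraction <= 0.5):
            raise PhantomConfigError(
                f"gland_band_fraction {self.gland_band_fraction} outside [0.2, 0.5]")
        if self.skin_band_fraction + self.gland_band_fraction >= 1.0:
            raise PhantomConfigError("skin + gland fractions must be < 1")
        if not (0.0 <= self.lesion_probability <= 1.0):
            raise PhantomConfigError("lesion_probability must lie in [0, 1]")
        if not (0.0 <= self.malignant_fraction <= 1.0):
            raise PhantomConfigError("malignant_fraction must lie in [0, 1]")
        rmin, rmax = self.lesion_radius_range
        if not (0 < rmin <= rmax):
            raise PhantomConfigError("lesion_radius_range must satisfy 0 < min <= max")
        start, stop = self.gland_rows
        if rmax >= (stop - start):
            raise PhantomConfigError(
                f"max lesion radius {rmax} must be smaller than the gland band "
                f"height ({stop - start} px)")
        if not (-1.0 <= self.contrast_lesion < 0.0):
            raise PhantomConfigError("contrast_lesion must lie in [-1, 0)")
        if self.speckle_strength < 0:
            raise PhantomConfigError("speckle_strength must be >= 0")


@dataclass
class PhantomSample:
    """One phantom frame with its ground truth.

    coarse_mask labels: 0 background, 1 mammary gland, 2 lesion.
    class_label: 0 normal; in binary mode 1 = lesion, otherwise 1 = benign,
    2 = malignant. ``meta`` keeps the pre-speckle ("clean") image and the
    lesion geometry; it is not persisted by :func:`write_dataset`.
    """

    image: np.ndarray
    coarse_mask: np.ndarray
    lesion_mask: np.ndarray
    class_label: int
    seed: int
    meta: dict = field(default_factory=dict)


# layer mean intensities of the clean image
_SKIN_LEVEL = 0.72
_GLAND_LEVEL = 0.50
_MUSCLE_LEVEL = 0.28
_RIB_GAIN = 0.22


def _sample_seed(cfg_seed: int, index: int) -> int:
    """Deterministic per-sample seed below 2**31."""
    ss = np.random.SeedSequence([int(cfg_seed), int(index)])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


def _benign_footprint(rng, cfg: PhantomConfig):
    rmin, rmax = cfg.lesion_radius_range
    a = rng.uniform(rmin, rmax)                    # semi-major axis
    ratio = rng.uniform(0.6, 1.0)
    b = max(a * ratio, float(rmin))                # keep both axes >= rmin
    theta = rng.uniform(0.0, np.pi)
    t = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    xs = x * np.cos(theta) - y * np.sin(theta)
    ys = x * np.sin(theta) + y * np.cos(theta)
    return ys, xs, max(a, b)


def _malignant_footprint(rng, cfg: PhantomConfig):
    rmin, rmax = cfg.lesion_radius_range
    R = rng.uniform(max(rmin, 0.6 * rmax), rmax)
    n_spikes = int(rng.integers(7, 13))
    angles = np.linspace(0.0, 2 * np.pi, 2 * n_spikes, endpoint=False)
    angles = angles + rng.uniform(-0.3, 0.3, size=angles.shape) * np.pi / n_spikes
    radii = np.empty_like(angles)
    radii[0::2] = R * rng.uniform(0.8, 1.0, size=n_spikes)   # spike tips
    radii[1::2] = R * rng.uniform(0.45, 0.6, size=n_spikes)  # valleys
    ys = radii * np.sin(angles)
    xs = radii * np.cos(angles)
    return ys, xs, R


def generate_phantom(cfg: PhantomConfig, index: int) -> PhantomSample:
    """Generate the ``index``-th phantom of the population defined by ``cfg``."""
    cfg.validate()
    seed = _sample_seed(cfg.seed, index)
    rng = np.random.default_rng(seed)

    H, W = cfg.image_height, cfg.image_width
    g_start, g_stop = cfg.gland_rows

    rows = np.arange(H)[:, None]
    clean = np.full((H, W), _MUSCLE_LEVEL, dtype=np.float64)
    clean[rows[:, 0] < g_stop] = _GLAND_LEVEL
    clean[rows[:, 0] < g_start] = _SKIN_LEVEL
    # small per-sample layer-level jitter so the population is not degenerate
    clean[rows[:, 0] < g_start] += rng.uniform(-0.03, 0.03)
    clean[(rows[:, 0] >= g_start) & (rows[:, 0] < g_stop)] += rng.uniform(-0.03, 0.03)
    clean[rows[:, 0] >= g_stop] += rng.uniform(-0.03, 0.03)

    # periodic rib-like bright blobs in the muscle layer
    muscle_depth = (g_stop + H) // 2
    period = max(W // 3, 8)
    phase = rng.uniform(0, period)
    cols = np.arange(W)[None, :]
    for cx in np.arange(phase, W, period):
        blob = _RIB_GAIN * np.exp(-(((cols - cx) / 4.0) ** 2
                                    + ((rows - muscle_depth) / 2.5) ** 2))
        clean += np.where(rows >= g_stop, blob, 0.0)

    coarse = np.zeros((H, W), dtype=np.uint8)
    coarse[g_start:g_stop, :] = 1
    lesion_mask = np.zeros((H, W), dtype=np.uint8)

    has_lesion = rng.uniform() < cfg.lesion_probability
    malignant = bool(rng.uniform() < cfg.malignant_fraction)
    meta = {"index": int(index), "malignant": None}

    if has_lesion:
        ys, xs, reach = (_malignant_footprint(rng, cfg) if malignant
                         else _benign_footprint(rng, cfg))
        margin = int(np.ceil(reach)) + 1
        lo, hi = g_start + margin, g_stop - margin
        cy = rng.uniform(lo, hi) if hi > lo else 0.5 * (g_start + g_stop)
        cx = rng.uniform(margin, W - margin)
        rr, cc = draw_polygon(ys + cy, xs + cx, shape=(H, W))
        lesion_mask[rr, cc] = 1
        # clip to the gland band (margins should already guarantee this)
        lesion_mask[:g_start, :] = 0
        lesion_mask[g_stop:, :] = 0
        coarse[lesion_mask == 1] = 2
        clean = clean + cfg.contrast_lesion * (lesion_mask == 1)
        meta["malignant"] = malignant
        meta["center"] = (float(cy), float(cx))

    clean = ndimage.gaussian_filter(clean, sigma=1.2)
    clean = np.clip(clean, 0.0, 1.0)
    meta["clean"] = clean.copy()

    if cfg.speckle_strength > 0:
        s2 = cfg.speckle_strength ** 2
        speckle = rng.gamma(shape=1.0 / s2, scale=s2, size=(H, W))
    else:
        speckle = np.ones((H, W))
    image = np.clip(clean * speckle, 0.0, 1.0)

    if not has_lesion:
        label = 0
    elif cfg.binary_labels:
        label = 1
    else:
        label = 2 if malignant else 1
    return PhantomSample(image=image, coarse_mask=coarse,
                         lesion_mask=lesion_mask, class_label=label,
                         seed=seed, meta=meta)


def generate_dataset(cfg: PhantomConfig, n: int, start_index: int = 0
                     ) -> List[PhantomSample]:
    return [generate_phantom(cfg, start_index + i) for i in range(n)]


def write_dataset(samples: List[PhantomSample], out_dir) -> Path:
    """Write images/masks as 8-bit grayscale PNGs plus a CSV manifest.

    Files per sample i: ``sample_{i:05d}.png`` (image), ``*_coarse.png``
    (labels 0/1/2) and ``*_lesion.png`` (0/255). Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    rows = []
    for i, s in enumerate(samples):
        stem = f"sample_{i:05d}"
        try:
            iio.imwrite(out_dir / f"{stem}.png",
                        np.round(s.image * 255).astype(np.uint8))
            iio.imwrite(out_dir / f"{stem}_coarse.png",
                        s.coarse_mask.astype(np.uint8))
            iio.imwrite(out_dir / f"{stem}_lesion.png",
                        (s.lesion_mask * 255).astype(np.uint8))
        except OSError as exc:
            raise OSError(f"failed writing phantom files for {out_dir / stem}: {exc}")
        rows.append({"filename": f"{stem}.png", "class_label": s.class_label,
                     "seed": s.seed})
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["filename", "class_label", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def read_dataset(manifest) -> List[PhantomSample]:
    """Inverse of :func:`write_dataset` up to 8-bit intensity quantization."""
    manifest = Path(manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    base = manifest.parent
    samples = []
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                set(reader.fieldnames) < {"filename", "class_label", "seed"}:
            raise ValueError(f"malformed manifest {manifest}: "
                             f"header {reader.fieldnames}")
        for row in reader:
            stem = Path(row["filename"]).stem
            paths = {k: base / f"{stem}{suffix}.png"
                     for k, suffix in [("image", ""), ("coarse", "_coarse"),
                                       ("lesion", "_lesion")]}
            for p in paths.values():
                if not p.exists():
                    raise FileNotFoundError(f"dataset file missing: {p}")
            image = np.asarray(iio.imread(paths["image"]), dtype=np.float64) / 255.0
            coarse = np.asarray(iio.imread(paths["coarse"]), dtype=np.uint8)
            lesion = np.asarray(iio.imread(paths["lesion"]), dtype=np.uint8)
            bad = set(np.unique(coarse)) - {0, 1, 2}
            if bad:
                raise ValueError(f"coarse mask {paths['coarse']} has labels {bad} "
                                 "outside {0, 1, 2}")
            if set(np.unique(lesion)) - {0, 255}:
                raise ValueError(f"lesion mask {paths['lesion']} has values "
                                 "outside {0, 255}")
            samples.append(PhantomSample(
                image=image, coarse_mask=coarse,
                lesion_mask=(lesion > 0).astype(np.uint8),
                class_label=int(row["class_label"]),
                seed=int(row["seed"])))
    return samples
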