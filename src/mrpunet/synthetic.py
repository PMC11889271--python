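"""Seeded generator of dermoscopy-like image/mask pairs.

Real dermoscopy collections (ISIC, PH2, HAM10000) confront a segmenter with
lesions of varying size, irregular borders, non-uniform colour, low contrast
against the surrounding skin, and occluding artifacts — hairs, air bubbles,
vessels, and the black circular frame of some capture devices.  This module
emulates that phenomenology with fully parameterised, analytically checkable
geometry so the rest of the package can be exercised without any download:

* the lesion is a star-convex region ``radius(theta) = r(theta) * (1 +
  irregularity * smooth_noise(theta))`` around a rotated ellipse, so the
  expected area is known in closed form when the irregularity is zero;
* the ground-truth mask is captured *before* artifacts are painted — hair,
  bubbles and vessels occlude the image but are not lesion;
* everything is driven by one ``numpy`` Generator seeded from
  ``LesionParams.seed``, so a given parameter set is byte-reproducible.

No attempt is made at photorealism; the generator's purpose is a controlled
test bed, not a stand-in for clinical data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw

__all__ = ["LesionParams", "ImageSample", "generate_lesion_image",
           "generate_dataset"]

_DARK_PIGMENT = np.array([62.0, 36.0, 30.0])  # deep melanin tone


@dataclass
class LesionParams:
    """Controls for one synthetic sample.

    ``lesion_radius_range`` is a (min, max) fraction of the image side; the
    drawn ellipse semi-axes are sampled from it.  ``border_irregularity`` is
    the amplitude of smooth radial noise on the boundary (0 = exact ellipse).
    ``lesion_skin_contrast`` in (0, 1] scales the colour distance between
    lesion and skin (low values emulate the hard low-contrast cases).
    Artifact counts are exact, not stochastic.
    """

    image_size: int = 96
    lesion_radius_range: Tuple[float, float] = (0.12, 0.38)
    border_irregularity: float = 0.25
    lesion_skin_contrast: float = 0.45
    color_jitter: float = 0.10
    n_hairs: int = 6
    n_bubbles: int = 2
    vessel_density: float = 0.5
    black_border_width: int = 0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_radius_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError(f"radius range must lie within (0, 0.5): {(lo, hi)}")
        if self.lesion_skin_contrast <= 0 or self.lesion_skin_contrast > 1:
            raise ValueError("lesion_skin_contrast must be in (0, 1]")
        if self.border_irregularity < 0 or self.color_jitter < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class ImageSample:
    image: np.ndarray   # H x W x 3 uint8
    mask: np.ndarray    # H x W, {0, 1}
    params: LesionParams
    id: str = ""


def _smooth_periodic_noise(rng: np.random.Generator, theta: np.ndarray,
                           n_harmonics: int = 5) -> np.ndarray:
    """Random low-frequency periodic signal normalised to max |.| = 1."""
    out = np.zeros_like(theta)
    for k in range(2, 2 + n_harmonics):
        amp = rng.uniform(0.2, 1.0) / k
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.sin(k * theta + phase)
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def _bezier_stroke(rng: np.random.Generator, size: int, thickness: int) -> np.ndarray:
    """Boolean mask of one random quadratic Bezier stroke across the image."""
    pts = rng.integers(0, size, size=(3, 2))
    rr, cc = draw.bezier_curve(pts[0, 0], pts[0, 1], pts[1, 0], pts[1, 1],
                               pts[2, 0], pts[2, 1], weight=1.0, shape=(size, size))
    stroke = np.zeros((size, size), dtype=bool)
    stroke[rr, cc] = True
    if thickness > 1:
        stroke = ndimage.binary_dilation(stroke, iterations=thickness - 1)
    return stroke


def generate_lesion_image(params: LesionParams) -> ImageSample:
    """Render one image/mask pair. Deterministic for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    S = params.image_size

    # skin background: warm tone with gentle large-scale shading
    skin = np.array([205.0, 165.0, 144.0]) + rng.uniform(-14, 14, size=3)
    image = np.ones((S, S, 3)) * skin
    shading = ndimage.gaussian_filter(rng.normal(0, 1, (S, S)), sigma=S / 4)
    image += 8.0 * shading[..., None]

    # lesion geometry: rotated ellipse with smooth radial perturbation
    lo, hi = params.lesion_radius_range
    a = rng.uniform(lo, hi) * S
    b = rng.uniform(lo, hi) * S
    angle = rng.uniform(0, np.pi)
    r_cap = max(a, b) * (1.0 + params.border_irregularity)
    margin = min(S / 2 - 1, r_cap + 2)
    cy = S / 2 + rng.uniform(-1, 1) * (S / 2 - margin)
    cx = S / 2 + rng.uniform(-1, 1) * (S / 2 - margin)

    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r_ell = (a * b) / np.sqrt((b * np.cos(theta - angle)) ** 2
                              + (a * np.sin(theta - angle)) ** 2)
    if params.border_irregularity > 0:
        r = r_ell * (1.0 + params.border_irregularity
                     * _smooth_periodic_noise(rng, theta))
    else:
        r = r_ell
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    rr, cc = draw.polygon(rows, cols, shape=(S, S))
    mask = np.zeros((S, S), dtype=np.uint8)
    mask[rr, cc] = 1

    # lesion fill: pigment pulled toward a dark tone by the contrast knob,
    # with smooth within-lesion colour variation
    lesion_color = skin - params.lesion_skin_contrast * (skin - _DARK_PIGMENT)
    jitter = np.stack([ndimage.gaussian_filter(rng.normal(0, 1, (S, S)), sigma=S / 10)
                       for _ in range(3)], axis=-1)
    lesion_px = lesion_color + params.color_jitter * 80.0 * jitter
    image[mask == 1] = lesion_px[mask == 1]

    # ---- occluding artifacts (image only; the mask is already frozen) ----
    for _ in range(params.n_hairs):
        stroke = _bezier_stroke(rng, S, thickness=rng.integers(1, 3))
        shade = rng.uniform(20, 70)
        image[stroke] = image[stroke] * 0.25 + shade * 0.75

    for _ in range(params.n_bubbles):
        br = rng.integers(max(2, S // 40), max(3, S // 12))
        by = rng.integers(br, S - br)
        bx = rng.integers(br, S - br)
        ry, rx = draw.circle_perimeter(by, bx, br, shape=(S, S))
        ring = np.zeros((S, S), dtype=bool)
        ring[ry, rx] = True
        ring = ndimage.binary_dilation(ring)
        image[ring] = np.minimum(image[ring] + 70.0, 255.0)
        dy, dx = draw.disk((by, bx), br, shape=(S, S))
        image[dy, dx] += 12.0

    n_vessels = int(round(params.vessel_density * 4))
    for _ in range(n_vessels):
        stroke = _bezier_stroke(rng, S, thickness=1)
        image[stroke] = image[stroke] * 0.6 + np.array([170.0, 60.0, 60.0]) * 0.4

    if params.black_border_width > 0:
        w = params.black_border_width
        image[:w], image[-w:], image[:, :w], image[:, -w:] = 0, 0, 0, 0

    image = np.clip(image, 0, 255).astype(np.uint8)
    return ImageSample(image=image, mask=mask, params=params)


def _stratified_split(areas: np.ndarray, test_fraction: float,
                      rng: np.random.Generator) -> List[str]:
    """train/test assignment stratified by lesion-size tercile."""
    n = len(areas)
    order = np.argsort(areas, kind="stable")
    terciles = np.array_split(order, 3)
    split = np.array(["train"] * n, dtype=object)
    for idx in terciles:
        idx = np.array(idx)
        n_test = int(round(len(idx) * test_fraction))
        chosen = rng.choice(idx, size=n_test, replace=False)
        split[chosen] = "test"
    return list(split)


def generate_dataset(n: int, out_dir, seed: int = 0,
                     base_params: Optional[LesionParams] = None,
                     test_fraction: float = 0.25) -> pd.DataFrame:
    """Write ``n`` PNG image/mask pairs plus a manifest CSV to ``out_dir``.

    Per-sample parameters are drawn around ``base_params``: contrast, border
    irregularity and artifact counts vary between samples so the dataset
    spans the challenge taxonomy (small/large lesions, low contrast, hair,
    bubbles, black borders).  Returns the manifest as a DataFrame; also
    written to ``out_dir / "manifest.csv"``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = base_params if base_params is not None else LesionParams()
    rng = np.random.default_rng(seed)

    samples, rows = [], []
    for i in range(n):
        sample_seed = int(rng.integers(0, 2**31 - 1))
        prng = np.random.default_rng(sample_seed + 1)
        p = replace(
            base,
            lesion_skin_contrast=float(np.clip(
                base.lesion_skin_contrast * prng.uniform(0.55, 1.3), 0.05, 1.0)),
            border_irregularity=float(base.border_irregularity * prng.uniform(0.4, 1.4)),
            n_hairs=int(prng.integers(0, base.n_hairs + 1)),
            n_bubbles=int(prng.integers(0, base.n_bubbles + 1)),
            vessel_density=float(base.vessel_density * prng.uniform(0, 1.5)),
            black_border_width=(int(base.image_size // 16) if prng.random() < 0.2
                                else 0),
            seed=sample_seed,
        )
        sample = generate_lesion_image(p)
        sample.id = f"syn{i:04d}"
        samples.append(sample)

    areas = np.array([s.mask.sum() for s in samples])
    splits = _stratified_split(areas, test_fraction, rng)

    for sample, split in zip(samples, splits):
        img_path = out_dir / f"{sample.id}.png"
        mask_path = out_dir / f"{sample.id}_mask.png"
        iio.imwrite(img_path, sample.image)
        iio.imwrite(mask_path, (sample.mask * 255).astype(np.uint8))
        rows.append({
            "id": sample.id,
            "image_path": img_path.name,
            "mask_path": mask_path.name,
            "split": split,
            "seed": sample.params.seed,
            "params_json": json.dumps(asdict(sample.params)),
        })

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
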