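"""Seeded generator of vial-like images with exact egg ground truth.

Emulates the visual challenges of photographing fly-food surfaces: bright
ellipsoidal eggs of roughly uniform size and variable orientation, partial
clustering and overlap, two background classes (pale translucent defined
medium vs darker opaque yeast-based medium with speckle texture), and
surface artefacts -- bubbles, specular streaks and marks near the vial
base.  Every image is fully determined by its seed, and the returned dot
annotation lists the rounded ellipse centres, so the generator doubles as
a ground-truth source for every other module's tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .annotations import CSV_SUFFIX, DotAnnotation, write_dots_csv

MEDIA = ("translucent", "opaque")


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic vial photograph.

    Egg axes are half-axis ranges in pixels; defaults give eggs roughly
    8-14 px long and 3-5 px wide, the scale of real eggs in webcam vial
    photographs.  ``cluster_fraction`` is the share of eggs deliberately
    placed within one egg length of an already placed egg.
    """

    image_shape: Tuple[int, int] = (600, 600)
    n_eggs: int = 100
    egg_major_range: Tuple[float, float] = (4.0, 7.0)   # half-axes: 8-14 px long
    egg_minor_range: Tuple[float, float] = (1.5, 2.5)   # 3-5 px wide
    cluster_fraction: float = 0.3
    medium: str = "translucent"
    n_bubbles: int = 4
    n_streaks: int = 2
    n_base_marks: int = 3
    noise_sigma: float = 0.012
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_eggs < 0:
            raise ValueError("n_eggs must be >= 0")
        if self.medium not in MEDIA:
            raise ValueError(f"medium must be one of {MEDIA}, got {self.medium!r}")
        if not (0.0 <= self.cluster_fraction <= 1.0):
            raise ValueError("cluster_fraction must lie in [0, 1]")
        for lo, hi in (self.egg_major_range, self.egg_minor_range):
            if lo <= 0 or hi < lo:
                raise ValueError("egg axis ranges must be positive with lo <= hi")
        if self.egg_major_range[0] < self.egg_minor_range[1]:
            raise ValueError("major half-axis range must sit above the minor range")


def _vial_geometry(shape: Tuple[int, int]) -> Tuple[float, float, float]:
    h, w = shape
    return (h - 1) / 2.0, (w - 1) / 2.0, 0.46 * min(h, w)


def _background(p: SceneParams, rng: np.random.Generator) -> np.ndarray:
    h, w = p.image_shape
    cr, cc, radius = _vial_geometry(p.image_shape)
    rr, cc_grid = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - cr, cc_grid - cc) / radius
    inside = dist <= 1.0

    img = np.empty((h, w, 3), dtype=np.float64)
    from scipy import ndimage
    # radial illumination falloff toward the vial wall
    shade = 1.0 - 0.25 * np.clip(dist, 0.0, 1.0) ** 2
    # low-frequency mottle shared by both media
    mottle = ndimage.gaussian_filter(rng.standard_normal((h, w)), 6.0)
    mottle /= max(np.abs(mottle).max(), 1e-9)
    if p.medium == "translucent":
        # pale, smooth defined medium: eggs stand out cleanly
        base = np.array([0.72, 0.70, 0.66])
        field = shade * (1.0 + 0.03 * mottle)
        img[:] = base[None, None, :] * field[:, :, None]
    else:
        # yeast-based medium: rough, egg-scale speckle partly obscures eggs
        base = np.array([0.62, 0.50, 0.30])
        speckle = ndimage.gaussian_filter(rng.standard_normal((h, w)), 1.3)
        speckle /= max(np.abs(speckle).max(), 1e-9)
        field = shade * (1.0 + 0.06 * mottle + 0.25 * speckle)
        img[:] = base[None, None, :] * field[:, :, None]
        # bright yeast grains: small egg-coloured blobs acting as confusers
        n_grains = max(1, int(0.0008 * h * w))
        grain_color = np.array([0.90, 0.87, 0.80])
        for _ in range(n_grains):
            ang, rad = rng.uniform(0, 2 * np.pi), radius * np.sqrt(rng.random())
            gr, gc = cr + rad * np.sin(ang), cc + rad * np.cos(ang)
            size = rng.uniform(1.2, 3.2)
            _draw_ellipse(img, gr, gc, size, size * rng.uniform(0.6, 1.0),
                          rng.uniform(0, np.pi),
                          grain_color * rng.uniform(0.8, 1.0), softness=1.2)
    img[~inside] = np.array([0.10, 0.10, 0.11])  # dark bench around the vial
    return img


def _place_centres(p: SceneParams, rng: np.random.Generator) -> np.ndarray:
    cr, cc, radius = _vial_geometry(p.image_shape)
    placeable = 0.92 * radius
    mean_egg_area = (np.pi * np.mean(p.egg_major_range) * np.mean(p.egg_minor_range))
    if p.n_eggs * mean_egg_area > 0.5 * np.pi * placeable ** 2:
        raise ValueError(
            f"cannot place {p.n_eggs} eggs: total egg area exceeds half the "
            "vial surface")
    centres: List[Tuple[float, float]] = []
    egg_len = 2.0 * np.mean(p.egg_major_range)
    for k in range(p.n_eggs):
        clustered = centres and rng.random() < p.cluster_fraction
        for _ in range(1000):
            if clustered:
                ar, ac = centres[rng.integers(len(centres))]
                ang = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(0.3, 1.0) * egg_len
                r, c = ar + dist * np.sin(ang), ac + dist * np.cos(ang)
            else:
                ang = rng.uniform(0, 2 * np.pi)
                rad = placeable * np.sqrt(rng.random())
                r, c = cr + rad * np.sin(ang), cc + rad * np.cos(ang)
            if np.hypot(r - cr, c - cc) <= placeable:
                centres.append((r, c))
                break
        else:
            raise ValueError(f"failed to place egg {k} after 1000 attempts")
    return np.array(centres, dtype=np.float64).reshape(-1, 2)


def _draw_ellipse(img: np.ndarray, r0: float, c0: float, a: float, b: float,
                  theta: float, color: np.ndarray, softness: float = 0.9) -> None:
    """Alpha-composite one anti-aliased filled ellipse onto ``img``."""
    h, w = img.shape[:2]
    pad = int(np.ceil(a + softness)) + 1
    rlo, rhi = max(0, int(r0) - pad), min(h, int(r0) + pad + 1)
    clo, chi = max(0, int(c0) - pad), min(w, int(c0) + pad + 1)
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    # signed distance proxy from the ellipse boundary, in pixels
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    dist_px = (q - 1.0) * b
    alpha = np.clip(0.5 - dist_px / softness, 0.0, 1.0)
    # slight interior highlight toward the centre
    highlight = 1.0 + 0.10 * np.clip(1.0 - q, 0.0, 1.0)
    patch = img[rlo:rhi, clo:chi]
    patch[:] = (patch * (1.0 - alpha[..., None])
                + alpha[..., None] * (color[None, None, :] * highlight[..., None]))


def _draw_artefacts(img: np.ndarray, p: SceneParams, rng: np.random.Generator) -> None:
    h, w = p.image_shape
    cr, cc, radius = _vial_geometry(p.image_shape)
    rr, cc_grid = np.mgrid[0:h, 0:w]
    # bubbles: dark discs with a thin bright rim, as light refracts at the edge
    for _ in range(p.n_bubbles):
        ang, rad = rng.uniform(0, 2 * np.pi), rng.uniform(0, 0.85) * radius
        br, bc = cr + rad * np.sin(ang), cc + rad * np.cos(ang)
        rb = rng.uniform(3.0, 9.0)
        d = np.hypot(rr - br, cc_grid - bc)
        inner = np.clip(1.0 - d / rb, 0.0, 1.0)
        rim = np.exp(-((d - rb) ** 2) / (2 * 0.8 ** 2))
        img *= (1.0 - 0.35 * inner ** 0.7)[..., None]
        img += 0.18 * rim[..., None]
    # specular streaks: elongated soft bright lines on the vial glass
    for _ in range(p.n_streaks):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.55, 0.95) * radius
        sr, sc = cr + rad * np.sin(ang), cc + rad * np.cos(ang)
        direction = ang + np.pi / 2 + rng.uniform(-0.3, 0.3)
        du, dv = np.sin(direction), np.cos(direction)
        t = (rr - sr) * du + (cc_grid - sc) * dv
        n = -(rr - sr) * dv + (cc_grid - sc) * du
        length = rng.uniform(25.0, 70.0)
        streak = np.exp(-(n ** 2) / (2 * 2.8 ** 2)) * np.exp(-(t ** 2) / (2 * (length / 2) ** 2))
        img += 0.14 * streak[..., None]
    # marks on the vial base: dark arcs hugging the periphery
    for _ in range(p.n_base_marks):
        ang0 = rng.uniform(0, 2 * np.pi)
        arc = rng.uniform(0.15, 0.5)
        rad = rng.uniform(0.96, 1.02) * radius
        d = np.hypot(rr - cr, cc_grid - cc)
        theta = np.arctan2(rr - cr, cc_grid - cc)
        dtheta = np.angle(np.exp(1j * (theta - ang0)))
        band = np.exp(-((d - rad) ** 2) / (2 * 2.0 ** 2)) * (np.abs(dtheta) < arc / 2)
        img *= (1.0 - 0.45 * band)[..., None]


def generate_vial_image(p: SceneParams) -> Tuple[np.ndarray, DotAnnotation]:
    """Render one vial photograph; returns (uint8 RGB image, annotation)."""
    rng = np.random.default_rng(p.seed)
    img = _background(p, rng)
    centres = _place_centres(p, rng)
    egg_color = np.array([0.93, 0.91, 0.86])
    # eggs on yeast paste are often partially buried: wider visibility jitter
    jitter_range = (0.85, 1.05) if p.medium == "translucent" else (0.35, 0.90)
    for r0, c0 in centres:
        a = rng.uniform(*p.egg_major_range)
        b = rng.uniform(*p.egg_minor_range)
        theta = rng.uniform(0, np.pi)
        jitter = rng.uniform(*jitter_range)
        _draw_ellipse(img, r0, c0, a, b, theta, egg_color * jitter)
    _draw_artefacts(img, p, rng)
    if p.medium == "opaque":
        # surface roughness sits on top of everything, eggs included
        from scipy import ndimage
        rough = ndimage.gaussian_filter(
            rng.standard_normal(p.image_shape), 1.5)
        rough /= max(np.abs(rough).max(), 1e-9)
        img *= (1.0 + 0.20 * rough)[..., None]
    if p.noise_sigma > 0:
        img += rng.normal(0.0, p.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    out = (img * 255.0 + 0.5).astype(np.uint8)

    h, w = p.image_shape
    dots = [(int(np.clip(round(r), 0, h - 1)), int(np.clip(round(c), 0, w - 1)))
            for r, c in centres]
    return out, DotAnnotation(image_id=f"synthetic_seed{p.seed}", dots=dots)


def generate_dataset(n_images: int,
                     count_range: Tuple[int, int] = (15, 410),
                     p_template: Optional[SceneParams] = None,
                     master_seed: Optional[int] = None,
                     out_dir=None):
    """Generate a dataset of vial images whose counts span ``count_range``.

    Counts are evenly spaced across the range (the way evaluation datasets
    are assembled to cover low through high laying densities).  Per-image
    seeds derive from ``master_seed``; the manifest records image id, count
    and seed so any image can be regenerated in isolation.

    Returns ``(scenes, manifest)`` where ``scenes`` is a list of
    ``(image, annotation)`` and ``manifest`` a DataFrame.  With ``out_dir``
    set, PNGs, companion ``_dots.csv`` files and ``manifest.csv`` are
    written there as well.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    template = p_template or SceneParams()
    counts = np.linspace(count_range[0], count_range[1], n_images).round().astype(int)
    seeds = np.random.SeedSequence(master_seed).generate_state(n_images)
    scenes = []
    rows = []
    for i, (count, seed) in enumerate(zip(counts, seeds)):
        params = replace(template, n_eggs=int(count), seed=int(seed))
        img, ann = generate_vial_image(params)
        image_id = f"vial_{i:03d}"
        ann.image_id = image_id
        scenes.append((img, ann))
        rows.append({"image": image_id, "count": int(count), "seed": int(seed),
                     "medium": template.medium})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (img, ann), row in zip(scenes, rows):
            iio.imwrite(out_dir / f"{row['image']}.png", img)
            write_dots_csv(ann, out_dir / f"{row['image']}{CSV_SUFFIX}")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return scenes, manifest
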