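"""Seeded generation of H&E-like synthetic tiles and annotated images.

Real H&E histology shows purple-stained cell nuclei (hematoxylin) on a
pink cytoplasm/stroma background (eosin). Malignancy manifests in a
handful of morphological cues: more nuclei per unit area, larger nuclei,
darker nuclear staining (hyperchromasia), greater variability of nuclear
size, and irregular nuclear contours. The generator renders colored
elliptical "nuclei" on an eosin-like background with each of those cues
exposed as an independent, continuous control, so descriptor and
classifier behavior can be probed without any external dataset.

The tiles are surrogates for testing the machinery, not simulations of
real stain statistics; see the methods note for what passing tests on
them do and do not establish.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SyntheticTileSpec",
    "AnnotatedImage",
    "LabeledPatch",
    "generate_tile",
    "benign_preset",
    "malignant_preset",
    "generate_annotated_image",
    "label_patches",
    "noise_tile",
    "texture_pool",
]

#: base chromatin color ramp: light purple (hyperchromasia=0) to very dark
_NUCLEUS_LIGHT = np.array([150.0, 115.0, 185.0])
_NUCLEUS_DARK = np.array([45.0, 18.0, 80.0])


@dataclass(frozen=True)
class SyntheticTileSpec:
    """Controls for one generated tile.

    nucleus_density is the expected number of nuclei per 10^4 px^2
    (a Poisson intensity); hyperchromasia in [0, 1] darkens nuclei;
    contour_irregularity in [0, 1] is the relative amplitude of the
    angular boundary perturbation.
    """

    size: tuple[int, int] = (150, 150)
    nucleus_density: float = 4.0
    nucleus_radius_mean: float = 4.0
    nucleus_radius_std: float = 0.8
    hyperchromasia: float = 0.35
    contour_irregularity: float = 0.15
    background_rgb: tuple[int, int, int] = (236, 200, 212)
    seed: int = 0

    def __post_init__(self):
        if self.size[0] < 1 or self.size[1] < 1:
            raise ValueError(f"degenerate tile size {self.size}")
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.nucleus_radius_mean <= 0:
            raise ValueError("nucleus_radius_mean must be > 0")
        for name in ("hyperchromasia", "contour_irregularity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class AnnotatedImage:
    """An RGB image with a binary per-pixel malignancy mask."""

    pixels: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must equal image shape")


@dataclass(frozen=True)
class LabeledPatch:
    """One grid patch with its label (+1 malignant / -1 benign) and offset."""

    pixels: np.ndarray
    label: int
    offset: tuple[int, int]


def _render_nucleus(img: np.ndarray, rng: np.random.Generator,
                    spec: SyntheticTileSpec) -> None:
    h, w = img.shape[:2]
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    r0 = max(rng.normal(spec.nucleus_radius_mean, spec.nucleus_radius_std), 1.0)
    aspect = rng.uniform(0.7, 1.0)
    theta0 = rng.uniform(0, np.pi)
    # angular boundary perturbation: low-order harmonics, amplitude set by
    # contour_irregularity (relative to the radius)
    n_harm = 4
    amp = spec.contour_irregularity * rng.normal(0, 0.5, n_harm) / np.sqrt(n_harm)
    phase = rng.uniform(0, 2 * np.pi, n_harm)

    pad = int(np.ceil(r0 * (1.0 + spec.contour_irregularity) / aspect)) + 2
    y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, h)
    x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    # rotate into the ellipse frame and squash the minor axis
    c, s = np.cos(theta0), np.sin(theta0)
    u = c * dx + s * dy
    v = (-s * dx + c * dy) / aspect
    dist = np.hypot(u, v)
    ang = np.arctan2(v, u)
    r_theta = r0 * (1.0 + sum(a * np.cos((k + 2) * ang + p)
                              for k, (a, p) in enumerate(zip(amp, phase))))
    r_theta = np.maximum(r_theta, 0.5)
    alpha = np.clip(r_theta - dist + 0.5, 0.0, 1.0)  # ~1px soft edge

    darkness = np.clip(spec.hyperchromasia + rng.normal(0, 0.05), 0.0, 1.0)
    color = _NUCLEUS_LIGHT + darkness * (_NUCLEUS_DARK - _NUCLEUS_LIGHT)
    region = img[y0:y1, x0:x1]
    region[:] = alpha[..., None] * color + (1.0 - alpha[..., None]) * region


def generate_tile(spec: SyntheticTileSpec) -> np.ndarray:
    """Render one 8-bit RGB tile from a spec; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_rgb
    # gentle eosin texture: low-frequency mottling + pixel noise
    yy, xx = np.mgrid[0:h, 0:w]
    phase = rng.uniform(0, 2 * np.pi, 4)
    mottle = (np.sin(2 * np.pi * yy / max(h, 1) * 1.7 + phase[0])
              * np.sin(2 * np.pi * xx / max(w, 1) * 1.3 + phase[1])
              + np.sin(2 * np.pi * (yy + xx) / max(h + w, 1) * 2.1 + phase[2]))
    img += (4.0 * mottle)[..., None]
    img += rng.normal(0, 3.0, size=img.shape)

    n_nuclei = rng.poisson(spec.nucleus_density * h * w / 1e4)
    for _ in range(n_nuclei):
        _render_nucleus(img, rng, spec)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def benign_preset(size: tuple[int, int] = (150, 150), seed: int = 0) -> SyntheticTileSpec:
    """Benign surrogate: sparse, light, regular round nuclei."""
    return SyntheticTileSpec(size=size, seed=seed)


def malignant_preset(size: tuple[int, int] = (150, 150), seed: int = 0) -> SyntheticTileSpec:
    """Malignant surrogate: 3x the nuclear density, +0.3 hyperchromasia,
    2x the radius spread, +0.4 contour irregularity over the benign preset."""
    b = benign_preset(size=size, seed=seed)
    return replace(
        b,
        nucleus_density=b.nucleus_density * 3.0,
        hyperchromasia=b.hyperchromasia + 0.3,
        nucleus_radius_std=b.nucleus_radius_std * 2.0,
        contour_irregularity=b.contour_irregularity + 0.4,
    )


def generate_annotated_image(
    size: tuple[int, int],
    malignant_region: tuple[int, int, int, int] | None,
    seed: int = 0,
    benign_spec: SyntheticTileSpec | None = None,
    malignant_spec: SyntheticTileSpec | None = None,
) -> AnnotatedImage:
    """Benign texture everywhere, malignant texture inside a rectangle.

    ``malignant_region`` is ``(row, col, height, width)``; None or zero
    area means a fully benign image with an all-zero mask.
    """
    h, w = size
    bspec = replace(benign_spec or benign_preset(), size=size, seed=seed)
    mspec = replace(malignant_spec or malignant_preset(), size=size, seed=seed + 1)
    pixels = generate_tile(bspec)
    mask = np.zeros((h, w), dtype=bool)
    if malignant_region is not None:
        r, c, rh, rw = malignant_region
        if r < 0 or c < 0 or r + rh > h or c + rw > w:
            raise ValueError(f"region {malignant_region} outside image {size}")
        if rh > 0 and rw > 0:
            mal = generate_tile(mspec)
            pixels = pixels.copy()
            pixels[r:r + rh, c:c + rw] = mal[r:r + rh, c:c + rw]
            mask[r:r + rh, c:c + rw] = True
    return AnnotatedImage(pixels=pixels, mask=mask)


def label_patches(
    annotated: AnnotatedImage,
    patch_size: int,
    positive_threshold: float = 0.8,
    negative_purity: float = 0.0,
) -> list[LabeledPatch]:
    """Disjoint grid tiling with the strict labeling rule.

    A patch is +1 when strictly more than ``positive_threshold`` of its
    pixels are malignant, -1 when its malignant fraction is <=
    ``negative_purity`` (default: devoid, exactly 0), and discarded
    otherwise. Partial boundary patches that do not fit the grid are not
    produced.
    """
    if not 0 < positive_threshold <= 1:
        raise ValueError("positive_threshold must lie in (0, 1]")
    if negative_purity < 0 or negative_purity >= positive_threshold:
        raise ValueError("negative_purity must lie in [0, positive_threshold)")
    h, w = annotated.mask.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch size {patch_size} exceeds image {h}x{w}")
    out: list[LabeledPatch] = []
    for r in range(0, h - patch_size + 1, patch_size):
        for c in range(0, w - patch_size + 1, patch_size):
            frac = annotated.mask[r:r + patch_size, c:c + patch_size].mean()
            if frac > positive_threshold:
                label = 1
            elif frac <= negative_purity:
                label = -1
            else:
                continue
            out.append(LabeledPatch(
                pixels=annotated.pixels[r:r + patch_size, c:c + patch_size],
                label=label, offset=(r, c)))
    return out


def noise_tile(size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform 8-bit RGB noise tile (background-class instances)."""
    return rng.integers(0, 256, size=(*size, 3), dtype=np.uint8)


def texture_pool(n: int, size: tuple[int, int] = (150, 150),
                 seed: int = 0) -> list[np.ndarray]:
    """Surrogate non-tissue texture images (oriented sinusoidal gratings
    plus noise), standing in for a generic texture dataset."""
    rng = np.random.default_rng(seed)
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    pool = []
    for _ in range(n):
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(0.05, 0.4)
        phase = rng.uniform(0, 2 * np.pi)
        base = rng.uniform(60, 200, size=3)
        contrast = rng.uniform(20, 55)
        grating = np.sin(freq * (np.cos(theta) * xx + np.sin(theta) * yy) + phase)
        img = base[None, None, :] + contrast * grating[..., None]
        img += rng.normal(0, 8.0, size=img.shape)
        pool.append(np.clip(np.round(img), 0, 255).astype(np.uint8))
    return pool
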