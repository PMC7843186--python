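"""Synthetic multi-contrast brain phantoms.

Every other stage of the package is testable offline because this module
emits small 2-D "slices" that mimic the contrast behaviour of the four
standard MRI sequences: peritumoral edema is bright on the FLAIR- and
T2-like channels, the enhancing core is prominent on the T1ce-like
channel, and necrosis is dark on T1/T1ce. Labels follow the usual
five-class taxonomy::

    0 background, 1 normal tissue, 2 edema, 3 enhancing core, 4 necrosis

and the composite regions nest: ET (class 3) ⊆ TC (3 ∪ 4) ⊆ WT (2 ∪ 3 ∪ 4).

The geometry is deliberately simple — an elliptical brain with nested,
angularly perturbed tumor blobs — because the contrast relations, not
anatomy, are what downstream code depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CHANNEL_NAMES",
    "CLASS_NAMES",
    "TumorConfig",
    "Phantom",
    "RegionMasks",
    "PhantomGeometryError",
    "generate_phantom",
    "add_noise",
    "region_masks",
]

CHANNEL_NAMES = ("flair", "t1", "t1ce", "t2")
CLASS_NAMES = ("background", "normal", "edema", "enhancing_core", "necrosis")

# Mean 8-bit intensity of each tissue class on each channel. Rows follow
# CLASS_NAMES, columns CHANNEL_NAMES. Chosen so that edema > normal on
# flair/t2 by a wide margin and enhancing core is the brightest tissue
# on t1ce, with necrosis dark on t1/t1ce.
_CLASS_MEANS = np.array(
    [
        #  flair  t1   t1ce  t2
        [10.0, 10.0, 10.0, 10.0],   # background
        [90.0, 120.0, 110.0, 100.0],  # normal
        [185.0, 90.0, 100.0, 175.0],  # edema
        [140.0, 150.0, 210.0, 130.0],  # enhancing core
        [120.0, 70.0, 60.0, 145.0],   # necrosis
    ]
)


class PhantomGeometryError(ValueError):
    """Raised when the requested tumor cannot fit inside the brain mask."""


@dataclass(frozen=True)
class TumorConfig:
    """Geometry and contrast parameters of the simulated tumor.

    Fractions are areas relative to the brain ellipse and must nest:
    necrosis_frac < core_frac < edema_frac, each in (0, 1) with total < 1.
    ``contrast_margin`` is the guaranteed mean-intensity gap (8-bit units)
    between edema and normal tissue on the flair/t2-like channels.
    """

    edema_frac: float = 0.14
    core_frac: float = 0.055
    necrosis_frac: float = 0.02
    texture_sigma: float = 5.0
    boundary_wobble: float = 0.15
    contrast_margin: float = 40.0

    def validate(self) -> None:
        fracs = (self.edema_frac, self.core_frac, self.necrosis_frac)
        if not all(0.0 < f < 1.0 for f in fracs):
            raise ValueError("tumor fractions must lie in (0, 1)")
        if sum(fracs) >= 1.0:
            raise ValueError("tumor fractions must sum to < 1")
        if not self.necrosis_frac < self.core_frac < self.edema_frac:
            raise ValueError("fractions must nest: necrosis < core < edema")


@dataclass(frozen=True)
class RegionMasks:
    """The three nested evaluation regions (boolean masks)."""

    wt: np.ndarray  # whole tumor: edema ∪ enhancing core ∪ necrosis
    tc: np.ndarray  # tumor core: enhancing core ∪ necrosis
    et: np.ndarray  # enhancing tumor: enhancing core only


@dataclass(frozen=True)
class Phantom:
    """A clean multi-contrast slice with its ground-truth label map."""

    channels: np.ndarray  # (4, H, W) uint8, order CHANNEL_NAMES
    labels: np.ndarray    # (H, W) uint8 in {0..4}
    seed: int
    config: TumorConfig = field(default_factory=TumorConfig)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[CHANNEL_NAMES.index(name)]


def _blob_mask(
    dist: np.ndarray, theta: np.ndarray, radius: float, profile: np.ndarray
) -> np.ndarray:
    # profile is a periodic angular modulation sampled on a fixed grid
    ang_idx = ((theta + np.pi) / (2 * np.pi) * (len(profile) - 1)).astype(int)
    return dist <= radius * profile[ang_idx]


def generate_phantom(
    seed: int,
    height: int = 128,
    width: int = 128,
    tumor_config: TumorConfig | None = None,
) -> Phantom:
    """Generate one deterministic phantom slice.

    The same ``(seed, height, width, tumor_config)`` always yields a
    bit-identical phantom. Raises :class:`PhantomGeometryError` when the
    requested tumor cannot be placed inside the brain ellipse and
    ``ValueError`` on out-of-range sizes or fractions.
    """
    if height < 32 or width < 32:
        raise ValueError("phantom must be at least 32x32")
    cfg = tumor_config or TumorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ay, ax = 0.42 * height, 0.45 * width
    brain = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    brain_area = float(brain.sum())

    # nested tumor radii from the requested area fractions
    r_edema = np.sqrt(cfg.edema_frac * brain_area / np.pi)
    r_core = np.sqrt(cfg.core_frac * brain_area / np.pi)
    r_nec = np.sqrt(cfg.necrosis_frac * brain_area / np.pi)
    max_extent = r_edema * (1.0 + cfg.boundary_wobble)
    if max_extent >= min(ay, ax):
        raise PhantomGeometryError(
            "tumor does not fit inside the brain mask; reduce edema_frac"
        )

    # tumor center: seeded offset from the brain center, constrained so
    # the outermost (wobbled) edema boundary stays inside the ellipse
    margin_y = ay - max_extent
    margin_x = ax - max_extent
    tcy = cy + rng.uniform(-0.6, 0.6) * margin_y
    tcx = cx + rng.uniform(-0.6, 0.6) * margin_x

    dist = np.hypot(yy - tcy, xx - tcx)
    theta = np.arctan2(yy - tcy, xx - tcx)
    # one smooth angular profile shared by all three compartments so the
    # blobs nest exactly (radii strictly decrease)
    n_ang = 360
    ang = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    profile = np.ones(n_ang)
    for k in range(2, 6):
        profile += cfg.boundary_wobble / 4.0 * (
            rng.normal() * np.cos(k * ang) + rng.normal() * np.sin(k * ang)
        )
    profile = np.clip(profile, 1.0 - cfg.boundary_wobble, 1.0 + cfg.boundary_wobble)

    edema_blob = _blob_mask(dist, theta, r_edema, profile) & brain
    core_blob = _blob_mask(dist, theta, r_core, profile) & brain
    nec_blob = _blob_mask(dist, theta, r_nec, profile) & brain

    labels = np.zeros((height, width), dtype=np.uint8)
    labels[brain] = 1
    labels[edema_blob] = 2
    labels[core_blob] = 3
    labels[nec_blob] = 4

    present = set(np.unique(labels).tolist())
    if present != {0, 1, 2, 3, 4}:
        raise PhantomGeometryError(
            f"degenerate phantom: classes {sorted({0, 1, 2, 3, 4} - present)} empty"
        )

    channels = np.empty((4, height, width), dtype=np.uint8)
    for c in range(4):
        img = _CLASS_MEANS[labels, c]
        # smooth intra-class texture; blur shrinks the white-noise std so
        # rescale it back to texture_sigma
        tex = gaussian_filter(rng.normal(0.0, 1.0, size=img.shape), sigma=2.0)
        std = tex.std()
        if std > 0:
            tex *= cfg.texture_sigma / std
        channels[c] = np.clip(np.rint(img + tex), 0, 255).astype(np.uint8)

    return Phantom(channels=channels, labels=labels, seed=seed, config=cfg)


def add_noise(
    image: np.ndarray, model: str, level: float, seed: int
) -> np.ndarray:
    """Add seeded noise to one intensity plane, clipped to [0, 255].

    Models: ``gaussian`` (additive, sigma = level), ``rician``
    (magnitude of the signal plus a complex Gaussian, the standard MRI
    magnitude-noise model, sigma = level), ``salt_pepper`` (level =
    fraction of pixels forced to 0 or 255). ``level = 0`` returns the
    input values unchanged. Output is float64.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    img = np.asarray(image, dtype=float)
    if level == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        out = img + rng.normal(0.0, level, size=img.shape)
    elif model == "rician":
        n1 = rng.normal(0.0, level, size=img.shape)
        n2 = rng.normal(0.0, level, size=img.shape)
        out = np.hypot(img + n1, n2)
    elif model == "salt_pepper":
        out = img.copy()
        hit = rng.random(img.shape) < level
        salt = rng.random(img.shape) < 0.5
        out[hit & salt] = 255.0
        out[hit & ~salt] = 0.0
    else:
        raise ValueError(f"unknown noise model: {model!r}")
    return np.clip(out, 0.0, 255.0)


def region_masks(labels: np.ndarray) -> RegionMasks:
    """Composite evaluation masks from a five-class label map.

    By definition ET ⊆ TC ⊆ WT for any valid label map.
    """
    lab = np.asarray(labels)
    if lab.size and not np.isin(lab, [0, 1, 2, 3, 4]).all():
        raise ValueError("labels must be in {0,...,4}")
    return RegionMasks(
        wt=np.isin(lab, [2, 3, 4]),
        tc=np.isin(lab, [3, 4]),
        et=lab == 3,
    )
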