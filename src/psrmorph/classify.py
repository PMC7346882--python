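"""Per-pixel tissue classification of PSR-stained sections.

Picrosirius Red renders collagen fibres red against orange/yellow
counterstained myocytes; unstained structures (fat vacuoles, vessel lumens,
slide background) appear near-white.  Classification therefore proceeds in
two passes:

1. :func:`classify_pixels` — colour-band thresholds in HSV (or RGB) space
   assign every pixel a provisional label in {background, collagen, myocyte}.
   Near-white pixels are all provisionally *background*; fat cannot be told
   apart from background by colour alone.
2. :func:`detect_fat` — morphological pass: enclosed (non border-connected)
   background components of plausible adipocyte size and solidity are
   relabelled *fat*.

The exact colour thresholds used by commercial analysis software are not
published, so the defaults here are calibrated on the synthetic fixtures and
real-slide use requires explicit user calibration (see ``ColorBands``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import morphology

__all__ = [
    "Label",
    "TISSUE_LABELS",
    "ANALYZABLE_LABELS",
    "SlideImage",
    "ClassMap",
    "ColorBands",
    "HSVBand",
    "FatMorphParams",
    "classify_pixels",
    "detect_fat",
]


class Label(IntEnum):
    """Pixel classes. ``EXCLUDED_*`` are produced by vessel exclusion."""

    BACKGROUND = 0
    COLLAGEN = 1
    FAT = 2
    MYOCYTE = 3
    EXCLUDED_LUMEN = 4
    EXCLUDED_PERIVASCULAR = 5


#: Labels counted as tissue (fat is tissue; lumens and background are not).
TISSUE_LABELS = (Label.COLLAGEN, Label.FAT, Label.MYOCYTE)
#: Tissue labels that enter composition percentages (excluded_* do not).
ANALYZABLE_LABELS = TISSUE_LABELS


@dataclass
class SlideImage:
    """A calibrated RGB section image.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` uint8 RGB array.
    um_per_px:
        Pixel size in micrometres per pixel.
    epicardial_boundary:
        Optional ``(H, W)`` boolean mask marking the epicardial surface of
        the tissue (used by the equal-area epi/endo partition).  ``None``
        for septal samples, which have no epicardial surface.
    """

    pixels: np.ndarray
    um_per_px: float
    epicardial_boundary: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"slide image must be (H, W, 3) RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValueError("slide image is empty")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ClassMap:
    """Per-pixel label field over the image grid.

    Every pixel carries exactly one :class:`Label`; the labels partition the
    image at every pipeline stage (pixel accounting is conserved).
    """

    labels: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ValueError("label field must be 2-D")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")

    def copy(self) -> "ClassMap":
        return ClassMap(self.labels.copy(), self.um_per_px)

    def counts(self) -> dict[Label, int]:
        """Pixel count per label (zero for absent labels)."""
        c = np.bincount(self.labels.ravel(), minlength=len(Label))
        return {lab: int(c[lab]) for lab in Label}

    @property
    def px_area_um2(self) -> float:
        return self.um_per_px**2

    def mask(self, *labels: Label) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=bool)
        for lab in labels:
            out |= self.labels == lab
        return out


@dataclass(frozen=True)
class HSVBand:
    """Inclusion ranges in HSV. Hue is circular in [0, 1): ``hue=(0.9, 0.06)``
    wraps through red. ``None`` bounds mean unconstrained."""

    hue: tuple[float, float] | None = None
    sat: tuple[float, float] | None = None
    val: tuple[float, float] | None = None

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        out = np.ones(h.shape, dtype=bool)
        if self.hue is not None:
            lo, hi = self.hue
            if lo <= hi:
                out &= (h >= lo) & (h <= hi)
            else:  # wrap-around band (red straddles hue 0)
                out &= (h >= lo) | (h <= hi)
        if self.sat is not None:
            out &= (s >= self.sat[0]) & (s <= self.sat[1])
        if self.val is not None:
            out &= (v >= self.val[0]) & (v <= self.val[1])
        return out


def _hsv_embed(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Embed HSV into the colour cone (s*cos, s*sin, v) so that hue distance
    is circular and hue is meaningless at zero saturation."""
    ang = 2.0 * np.pi * h
    return np.stack([s * np.cos(ang), s * np.sin(ang), v], axis=-1)


@dataclass
class ColorBands:
    """Per-class colour inclusion bands plus overlap-resolution priority.

    ``centers`` are HSV class centres used to assign pixels that fall in no
    band (nearest centre in the colour-cone embedding); the map must
    partition the image, so no pixel may stay unlabelled.

    Defaults were tuned on the synthetic fixtures; they are NOT the unpublished
    vendor thresholds, and real slides need user calibration.
    """

    bands: dict[Label, HSVBand] = field(
        default_factory=lambda: {
            Label.BACKGROUND: HSVBand(sat=(0.0, 0.25), val=(0.72, 1.0)),
            Label.COLLAGEN: HSVBand(hue=(0.88, 0.055), sat=(0.25, 1.0)),
            Label.MYOCYTE: HSVBand(hue=(0.055, 0.30), sat=(0.25, 1.0)),
        }
    )
    priority: tuple[Label, ...] = (Label.BACKGROUND, Label.COLLAGEN, Label.MYOCYTE)
    centers: dict[Label, tuple[float, float, float]] = field(
        default_factory=lambda: {
            Label.BACKGROUND: (0.0, 0.02, 0.96),
            Label.COLLAGEN: (0.99, 0.80, 0.70),
            Label.MYOCYTE: (0.098, 0.74, 0.90),
        }
    )

    def __post_init__(self) -> None:
        if sorted(self.priority) != sorted(self.bands):
            raise ValueError("priority must be a permutation of the banded classes")
        if set(self.centers) != set(self.bands):
            raise ValueError("centers must cover exactly the banded classes")

    def nearest_center(self, hsv: np.ndarray) -> np.ndarray:
        """Label array assigning each pixel its nearest class centre."""
        pts = _hsv_embed(hsv[..., 0], hsv[..., 1], hsv[..., 2])
        labs = list(self.centers)
        ctr = np.array(
            [_hsv_embed(*map(np.asarray, self.centers[lab])) for lab in labs]
        )
        d2 = ((pts[..., None, :] - ctr) ** 2).sum(axis=-1)
        idx = np.argmin(d2, axis=-1)
        lut = np.array([int(lab) for lab in labs], dtype=np.uint8)
        return lut[idx]


def classify_pixels(img: SlideImage, bands: ColorBands | None = None) -> ClassMap:
    """Assign every pixel a provisional label by colour-band thresholds.

    Near-white pixels become ``BACKGROUND`` (fat is resolved later by
    :func:`detect_fat`), red-band pixels ``COLLAGEN`` and orange/yellow
    pixels ``MYOCYTE``.  Band overlaps resolve by ``bands.priority``; pixels
    in no band are assigned their nearest band centre so the label field
    partitions the image.  Deterministic and idempotent for fixed bands.
    """
    bands = bands if bands is not None else ColorBands()
    hsv = skcolor.rgb2hsv(img.pixels)
    labels = np.full(img.shape, 255, dtype=np.uint8)  # 255 = not yet assigned
    unassigned = np.ones(img.shape, dtype=bool)
    for lab in bands.priority:
        hit = bands.bands[lab].contains(hsv) & unassigned
        labels[hit] = int(lab)
        unassigned &= ~hit
    if unassigned.any():
        fallback = bands.nearest_center(hsv)
        labels[unassigned] = fallback[unassigned]
    return ClassMap(labels, img.um_per_px)


@dataclass(frozen=True)
class FatMorphParams:
    """Morphological filter for adipocyte vacuoles.

    Areas are physical (µm²) so the filter is calibration-aware.  The
    defaults match the synthetic fixtures (vacuole radii ≈ 5–9 µm) and keep
    a clear gap below the vessel-lumen area floor so fat and lumens never
    compete; real slides need values sized to actual adipocytes.
    """

    min_area_um2: float = 40.0
    max_area_um2: float = 320.0
    min_solidity: float = 0.85
    closing_radius_px: int = 1

    def __post_init__(self) -> None:
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")
        if not 0.0 < self.min_solidity <= 1.0:
            raise ValueError("min_solidity must be in (0, 1]")
        if self.closing_radius_px < 0:
            raise ValueError("closing_radius_px must be >= 0")


def _component_solidity(comp: np.ndarray, closing_radius_px: int) -> float:
    """Solidity (area / convex-hull area) of a component after closing."""
    if closing_radius_px > 0:
        pad = closing_radius_px + 1
        comp = np.pad(comp, pad)
        comp = ndi.binary_closing(comp, structure=morphology.disk(closing_radius_px))
    filled = ndi.binary_fill_holes(comp)
    hull = morphology.convex_hull_image(filled)
    hull_area = hull.sum()
    if hull_area == 0:
        return 0.0
    return float(filled.sum() / hull_area)


def detect_fat(cmap: ClassMap, params: FatMorphParams | None = None) -> ClassMap:
    """Relabel enclosed near-white vacuoles as fat.

    Fat shares colour with background, so the disambiguator is geometric:
    a background-labelled connected component is relabelled ``FAT`` iff it

    - does not touch the image border (border-connected white stays
      background),
    - has area within ``[min_area_um2, max_area_um2]``, and
    - has solidity ≥ ``min_solidity`` after morphological closing.

    Zero detected fat is a valid outcome.  Only the original component
    pixels are relabelled, so pixel accounting is conserved.
    """
    params = params if params is not None else FatMorphParams()
    out = cmap.copy()
    bg = out.labels == Label.BACKGROUND
    lab_img, n = ndi.label(bg)
    if n == 0:
        return out
    border = np.zeros(bg.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(lab_img[border & bg]))
    px_area = cmap.px_area_um2
    objects = ndi.find_objects(lab_img)
    for comp_id, sl in enumerate(objects, start=1):
        if comp_id in border_ids or sl is None:
            continue
        comp = lab_img[sl] == comp_id
        area_um2 = comp.sum() * px_area
        if not params.min_area_um2 <= area_um2 <= params.max_area_um2:
            continue
        if _component_solidity(comp, params.closing_radius_px) < params.min_solidity:
            continue
        region = out.labels[sl]
        region[comp] = int(Label.FAT)
    return out
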