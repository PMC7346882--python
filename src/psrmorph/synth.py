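"""Synthetic PSR-like slides and clustered study tables with known truth.

No slide images are publicly deposited for normal-heart PSR morphometry, so
every downstream stage of this package is exercised against synthetic data
with exact ground truth:

* :func:`generate_slide` draws a PSR-like section — red collagen fibres on
  an orange/yellow myocyte background, enclosed white fat vacuoles,
  elliptical vessel lumens wrapped in red perivascular collagen cuffs, and
  near-white slide background — and returns the image together with the
  per-pixel truth masks and realized component fractions.
* :func:`generate_study` draws a long-format composition table of
  log-normally distributed percentages with a shared per-heart random
  intercept, location/region fixed effects and optional covariate effects,
  mirroring the clustered structure of a multi-site cadaveric study.

All randomness flows from a single seed; identical specs give bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage as ndi
from skimage import morphology

from .classify import Label, SlideImage

__all__ = [
    "SlideSpec",
    "GroundTruth",
    "StudySpec",
    "generate_slide",
    "generate_study",
    "reference_log_means",
    "save_slide_bundle",
    "PackingError",
]

#: RGB colour centres per class (collagen: strong red; myocyte:
#: orange-yellow; unstained structures: near-white).
COLOR_CENTERS: dict[Label, tuple[int, int, int]] = {
    Label.BACKGROUND: (246, 244, 242),
    Label.COLLAGEN: (178, 34, 48),
    Label.FAT: (246, 244, 242),
    Label.MYOCYTE: (235, 158, 58),
}

#: Collagen-free gap (px) kept between perivascular cuffs and interstitial
#: collagen so cuffs are distinct structures in the fixtures.
CUFF_MOAT_PX = 2


class PackingError(RuntimeError):
    """Requested fractions/geometry are unattainable (e.g. vacuole packing
    limit reached); raised instead of silently truncating."""


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide.

    ``collagen_frac`` and ``fat_frac`` are target proportions of analyzable
    tissue (tissue excluding the perivascular cuffs); realized fractions are
    reported in :class:`GroundTruth` and may differ slightly from the target
    because placement is discrete.
    """

    width_px: int = 512
    height_px: int = 512
    um_per_px: float = 1.0
    collagen_frac: float = 0.10
    fat_frac: float = 0.05
    n_vessels: int = 3
    vessel_lumen_radius_px: tuple[float, float] = (15.0, 24.0)
    perivascular_cuff_px: int = 6
    fat_vacuole_radius_px: tuple[float, float] = (5.0, 9.0)
    epicardial_side: str = "top"
    curvature_px: float = 0.0
    margin_px: int = 24
    color_sd: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("slide must be at least 64x64 px")
        if not 0.0 < self.collagen_frac < 1.0:
            raise ValueError("collagen_frac must be in (0, 1)")
        if not 0.0 <= self.fat_frac < 1.0:
            raise ValueError("fat_frac must be in [0, 1)")
        if self.collagen_frac + self.fat_frac >= 1.0:
            raise ValueError("collagen_frac + fat_frac must be < 1")
        for lo, hi in (self.vessel_lumen_radius_px, self.fat_vacuole_radius_px):
            if not 0 < lo <= hi:
                raise ValueError("radius ranges must satisfy 0 < lo <= hi")
        if self.n_vessels < 0 or self.perivascular_cuff_px <= 0:
            raise ValueError("n_vessels >= 0 and cuff thickness > 0 required")
        if self.epicardial_side not in {"top", "bottom", "left", "right"}:
            raise ValueError("epicardial_side must be top/bottom/left/right")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")


@dataclass
class GroundTruth:
    """Exact per-pixel truth for a generated slide.

    ``class_mask`` uses the provisional classes a colour classifier should
    recover: cuff pixels are collagen-class and lumen pixels are
    background-class.  ``true_fracs`` are realized pixel-count proportions
    of **analyzable** tissue (tissue minus perivascular cuff) and sum to 1
    over collagen/fat/myocyte.
    """

    class_mask: np.ndarray
    lumen_mask: np.ndarray
    perivascular_mask: np.ndarray
    true_fracs: dict[str, float]


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dy, dx = rr - cy, cc - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _orient(arr: np.ndarray, side: str) -> np.ndarray:
    """Map canonical frame (epicardium on top) to the requested side.
    Works for (H, W) masks and (H, W, 3) images alike."""
    if side == "top":
        return arr
    if side == "bottom":
        return arr[::-1].copy()
    swapped = np.swapaxes(arr, 0, 1)
    if side == "left":
        return swapped.copy()
    return swapped[:, ::-1].copy()  # right


def generate_slide(spec: SlideSpec) -> tuple[SlideImage, GroundTruth]:
    """Generate one PSR-like slide with exact ground truth.

    Geometry is drawn in a canonical frame with the epicardial surface on
    top, then re-oriented to ``spec.epicardial_side``.  Fat vacuoles are
    always enclosed by tissue, and vessels keep a collagen-free moat so
    every cuff is a complete, distinct structure.

    Raises
    ------
    PackingError
        If the requested vacuole area cannot be placed (packing limit) or
        the collagen target exceeds the available interstitium.
    """
    rng = np.random.default_rng(spec.rng_seed)
    # canonical frame dimensions (transpose for left/right at the end)
    if spec.epicardial_side in ("top", "bottom"):
        h, w = spec.height_px, spec.width_px
    else:
        h, w = spec.width_px, spec.height_px
    m = spec.margin_px

    # --- tissue slab (epicardial edge on top, optionally curved) ---
    tissue = np.zeros((h, w), dtype=bool)
    cols = np.arange(w)
    if spec.curvature_px:
        phase = rng.uniform(0, 2 * np.pi)
        top = m + spec.curvature_px * 0.5 * (
            1 + np.sin(2 * np.pi * cols / max(w - 1, 1) + phase)
        )
    else:
        top = np.full(w, float(m))
    top = np.clip(np.round(top).astype(int), 1, h - 2 * m)
    for c in range(m, w - m):
        tissue[top[c] : h - m, c] = True

    # epicardial boundary: topmost tissue pixel per column
    boundary = np.zeros((h, w), dtype=bool)
    for c in range(m, w - m):
        boundary[top[c], c] = True

    # --- vessels: elliptical lumens with collagen cuffs ---
    lumen = np.zeros((h, w), dtype=bool)
    cuff = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, clearance radius)
    cuff_px = spec.perivascular_cuff_px
    for _ in range(spec.n_vessels):
        ok = False
        for _attempt in range(300):
            a = rng.uniform(*spec.vessel_lumen_radius_px)
            b = a * rng.uniform(0.60, 0.95)
            theta = rng.uniform(0, np.pi)
            clearance = a + cuff_px + CUFF_MOAT_PX + 2
            lo_r = int(np.max(top)) + clearance
            hi_r = h - m - clearance
            lo_c, hi_c = m + clearance, w - m - clearance
            if lo_r >= hi_r or lo_c >= hi_c:
                continue
            cy, cx = rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)
            if any(
                np.hypot(cy - py, cx - px) < clearance + pr + 2
                for py, px, pr in placed
            ):
                continue
            ell = _ellipse_mask((h, w), cy, cx, a, b, theta)
            lumen |= ell
            cuff |= ndi.binary_dilation(ell, structure=morphology.disk(cuff_px)) & ~ell
            placed.append((cy, cx, clearance))
            ok = True
            break
        if not ok:
            raise PackingError(
                f"could not place vessel {len(placed) + 1}/{spec.n_vessels}; "
                "slide too small or too crowded"
            )
    cuff &= tissue & ~lumen
    tissue_solid = tissue & ~lumen  # lumens are holes (background-class)
    analyzable = tissue_solid & ~cuff
    n_analyzable = int(analyzable.sum())

    # --- fat vacuoles: enclosed white discs, never touching border/vessels ---
    fat = np.zeros((h, w), dtype=bool)
    vessel_keepout = ndi.binary_dilation(
        lumen | cuff, structure=morphology.disk(CUFF_MOAT_PX)
    )
    target_fat = int(round(spec.fat_frac * n_analyzable))
    r_lo, r_hi = spec.fat_vacuole_radius_px
    min_disc = np.pi * r_lo**2
    attempts = 0
    while target_fat - fat.sum() > 0.5 * min_disc:
        attempts += 1
        if attempts > 4000:
            raise PackingError(
                "fat vacuole packing limit reached before the requested "
                f"fat fraction {spec.fat_frac} was attained"
            )
        remaining = target_fat - int(fat.sum())
        r = min(rng.uniform(r_lo, r_hi), max(r_lo, np.sqrt(remaining / np.pi)))
        gap = r + 2
        lo_r = int(np.max(top)) + gap
        if lo_r >= h - m - gap or m + gap >= w - m - gap:
            raise PackingError("slide too small for requested fat vacuoles")
        cy = rng.uniform(lo_r, h - m - gap)
        cx = rng.uniform(m + gap, w - m - gap)
        # work in a local window around the candidate disc for speed
        rad = int(np.ceil(r)) + 3
        r0, c0 = int(cy) - rad, int(cx) - rad
        r1, c1 = int(cy) + rad + 1, int(cx) + rad + 1
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            continue
        win = (slice(r0, r1), slice(c0, c1))
        rr_w, cc_w = np.ogrid[r0:r1, c0:c1]
        d2 = (rr_w - cy) ** 2 + (cc_w - cx) ** 2
        disc = d2 <= r**2
        halo = d2 <= (r + 2) ** 2  # keep vacuoles separate
        if (halo & (vessel_keepout[win] | fat[win])).any():
            continue
        if (disc & ~tissue_solid[win]).any():
            continue
        fat[win] |= disc

    # --- interstitial collagen: smooth noise field thresholded to the
    # exact target count over the eligible interstitium ---
    target_col = int(round(spec.collagen_frac * n_analyzable))
    eligible = analyzable & ~fat & ~vessel_keepout
    n_eligible = int(eligible.sum())
    if target_col > n_eligible:
        raise PackingError(
            f"collagen target {target_col} px exceeds eligible interstitium "
            f"({n_eligible} px)"
        )
    field_img = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma=3.0)
    collagen = np.zeros((h, w), dtype=bool)
    if target_col > 0:
        elig_idx = np.flatnonzero(eligible.ravel())
        order = np.argsort(field_img.ravel()[elig_idx], kind="stable")[::-1]
        chosen = elig_idx[order[:target_col]]
        collagen.ravel()[chosen] = True

    myocyte = analyzable & ~fat & ~collagen

    # --- truth masks and realized fractions ---
    class_mask = np.full((h, w), int(Label.BACKGROUND), dtype=np.uint8)
    class_mask[cuff | collagen] = int(Label.COLLAGEN)
    class_mask[fat] = int(Label.FAT)
    class_mask[myocyte] = int(Label.MYOCYTE)
    n_col, n_fat = int(collagen.sum()), int(fat.sum())
    true_fracs = {
        "collagen": n_col / n_analyzable,
        "fat": n_fat / n_analyzable,
        "myocyte": (n_analyzable - n_col - n_fat) / n_analyzable,
    }

    # --- render RGB with per-class Gaussian colour noise ---
    img = np.empty((h, w, 3), dtype=float)
    for lab, center in COLOR_CENTERS.items():
        mask = class_mask == int(lab)
        img[mask] = center
    img += rng.normal(0.0, spec.color_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    side = spec.epicardial_side
    slide = SlideImage(
        pixels=_orient(img, side),
        um_per_px=spec.um_per_px,
        epicardial_boundary=_orient(boundary, side),
    )
    truth = GroundTruth(
        class_mask=_orient(class_mask, side),
        lumen_mask=_orient(lumen, side),
        perivascular_mask=_orient(cuff, side),
        true_fracs=true_fracs,
    )
    return slide, truth


# ---------------------------------------------------------------------------
# Clustered study tables
# ---------------------------------------------------------------------------

def reference_log_means(
    components: tuple[str, ...] = ("collagen", "fat", "myocyte"),
) -> dict[tuple[str, str, str], float]:
    """Log-scale cell means from published normal-myocardium reference
    geometric means (% of tissue area, total region per location)."""
    ref = {
        "collagen": {"RV": 15.2, "IVS": 8.6, "LV": 9.5},
        "fat": {"RV": 12.3, "IVS": 1.5, "LV": 4.7},
        "myocyte": {"RV": 65.9, "IVS": 88.6, "LV": 81.2},
    }
    out: dict[tuple[str, str, str], float] = {}
    for comp in components:
        for loc, gm in ref[comp].items():
            out[(loc, "total", comp)] = float(np.log(gm))
    return out


@dataclass
class StudySpec:
    """Parameters of a simulated clustered study.

    ``fixed_log_means`` maps ``(location, region, component)`` to the
    log-scale cell mean.  Each heart receives one random intercept shared by
    all of its rows (log-scale SD ``heart_sd``); rows add independent
    residual noise (``residual_sd``).  Demographic covariates default to
    the study population this package models: mostly male decedents,
    age ≈ 32 ± 10 years, BMI ≈ 29 ± 7.  The number of female hearts is
    fixed at ``round(female_prob * n_hearts)`` (clamped to [1, n−1]) and
    shuffled across hearts, mirroring a fixed autopsy-series composition.
    """

    n_hearts: int = 29
    fixed_log_means: dict[tuple[str, str, str], float] = field(
        default_factory=reference_log_means
    )
    heart_sd: float = 0.3
    residual_sd: float = 0.2
    covariate_effects: dict[str, float] | None = None
    female_prob: float = 4 / 29
    age_mean: float = 32.1
    age_sd: float = 9.9
    bmi_mean: float = 28.7
    bmi_sd: float = 7.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hearts < 2:
            raise ValueError("n_hearts must be >= 2")
        if self.heart_sd < 0 or self.residual_sd < 0:
            raise ValueError("heart_sd and residual_sd must be >= 0")
        if not self.fixed_log_means:
            raise ValueError("fixed_log_means must be non-empty")
        if self.covariate_effects is not None and not set(
            self.covariate_effects
        ) <= {"sex", "age", "bmi"}:
            raise ValueError("covariate_effects keys must be among sex/age/bmi")


def generate_study(spec: StudySpec) -> pd.DataFrame:
    """Simulate a long-format composition table.

    One row per (heart, location, region, component) cell listed in
    ``fixed_log_means``; ``value_pct = exp(cell mean + covariate effects +
    heart intercept + residual)``.  Covariate effects apply to sex coded
    F=1 and to age/BMI centred at their population means, so cell means stay
    interpretable as reference-population geometric means.
    """
    rng = np.random.default_rng(spec.rng_seed)
    eff = spec.covariate_effects or {}
    # fixed sex composition (like a real autopsy series), shuffled across
    # hearts, so the sex covariate is never accidentally constant
    n_female = int(round(spec.female_prob * spec.n_hearts))
    n_female = min(max(n_female, 1), spec.n_hearts - 1)
    females = np.zeros(spec.n_hearts, dtype=bool)
    females[:n_female] = True
    rng.shuffle(females)
    rows: list[dict] = []
    for i in range(spec.n_hearts):
        heart_id = f"H{i + 1:03d}"
        female = bool(females[i])
        age = rng.normal(spec.age_mean, spec.age_sd)
        bmi = rng.normal(spec.bmi_mean, spec.bmi_sd)
        intercept = rng.normal(0.0, spec.heart_sd) if spec.heart_sd > 0 else 0.0
        shift = (
            eff.get("sex", 0.0) * float(female)
            + eff.get("age", 0.0) * (age - spec.age_mean)
            + eff.get("bmi", 0.0) * (bmi - spec.bmi_mean)
        )
        for (loc, region, comp), mu in spec.fixed_log_means.items():
            resid = rng.normal(0.0, spec.residual_sd) if spec.residual_sd > 0 else 0.0
            rows.append(
                {
                    "heart_id": heart_id,
                    "location": loc,
                    "region": region,
                    "component": comp,
                    "value_pct": float(np.exp(mu + shift + intercept + resid)),
                    "sex": "F" if female else "M",
                    "age": float(age),
                    "bmi": float(bmi),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def save_slide_bundle(
    out_dir: str | Path,
    name: str,
    slide: SlideImage,
    truth: GroundTruth,
    image_format: str = "tiff",
) -> dict[str, Path]:
    """Write a slide as 8-bit RGB TIFF (or PNG), label/boundary masks as
    single-channel PNGs, and the ground truth as a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if image_format == "tiff":
        paths["image"] = out_dir / f"{name}.tiff"
        tifffile.imwrite(paths["image"], slide.pixels, photometric="rgb")
    elif image_format == "png":
        paths["image"] = out_dir / f"{name}.png"
        Image.fromarray(slide.pixels).save(paths["image"])
    else:
        raise ValueError("image_format must be 'tiff' or 'png'")
    paths["class_mask"] = out_dir / f"{name}_class_mask.png"
    Image.fromarray(truth.class_mask, mode="L").save(paths["class_mask"])
    for key in ("lumen_mask", "perivascular_mask"):
        paths[key] = out_dir / f"{name}_{key}.png"
        arr = (getattr(truth, key).astype(np.uint8)) * 255
        Image.fromarray(arr, mode="L").save(paths[key])
    if slide.epicardial_boundary is not None:
        paths["boundary"] = out_dir / f"{name}_boundary.png"
        arr = slide.epicardial_boundary.astype(np.uint8) * 255
        Image.fromarray(arr, mode="L").save(paths["boundary"])
    paths["truth"] = out_dir / f"{name}_truth.json"
    meta = {
        "um_per_px": slide.um_per_px,
        "true_fracs": truth.true_fracs,
        "label_legend": {lab.name.lower(): int(lab) for lab in Label},
    }
    paths["truth"].write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths
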