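"""Ellipse fitting, the elliptical shape score, lumen detection and
perivascular exclusion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from psrmorph import (
    ExclusionParams,
    Label,
    classify_pixels,
    detect_fat,
    detect_lumens,
    elliptical_score,
    exclude_perivascular,
    fit_ellipse,
)

from conftest import toy_map


# ---------------------------------------------------------------------------
# Independent brute-force IoU oracle
# ---------------------------------------------------------------------------

def iou_with_moment_ellipse(region: np.ndarray) -> float:
    """Brute-force oracle: covariance eigen-decomposition via numpy.linalg,
    per-pixel point-in-ellipse tests over an explicit window."""
    rr, cc = np.nonzero(region)
    cy, cx = rr.mean(), cc.mean()
    cov = np.cov(np.stack([cc - cx, rr - cy]), bias=True)
    evals, evecs = np.linalg.eigh(cov)
    a, b = 2 * np.sqrt(evals[1]), 2 * np.sqrt(evals[0])
    major = evecs[:, 1]  # (x, y) of the major axis
    pad = int(np.ceil(a)) + 3
    pts_region = set(zip(rr.tolist(), cc.tolist()))
    pts_ellipse = set()
    for r in range(int(rr.min()) - pad, int(rr.max()) + pad + 1):
        for c in range(int(cc.min()) - pad, int(cc.max()) + pad + 1):
            dx, dy = c - cx, r - cy
            u = dx * major[0] + dy * major[1]
            v = -dx * major[1] + dy * major[0]
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                pts_ellipse.add((r, c))
    inter = len(pts_region & pts_ellipse)
    union = len(pts_region | pts_ellipse)
    return inter / union


def make_region(kind: str) -> np.ndarray:
    """Constructed test regions: ellipses, rectangles, L-shapes, notched
    disks at several sizes/orientations."""
    rng_shape = (101, 101)
    rr, cc = np.mgrid[: rng_shape[0], : rng_shape[1]]
    cy = cx = 50
    name, *args = kind.split(":")
    m = np.zeros(rng_shape, dtype=bool)
    if name == "ellipse":
        a, b, deg = (float(x) for x in args)
        t = np.deg2rad(deg)
        u = (cc - cx) * np.cos(t) + (rr - cy) * np.sin(t)
        v = -(cc - cx) * np.sin(t) + (rr - cy) * np.cos(t)
        m = (u / a) ** 2 + (v / b) ** 2 <= 1
    elif name == "rect":
        w, h = (int(x) for x in args)
        m[cy - h // 2 : cy + (h + 1) // 2, cx - w // 2 : cx + (w + 1) // 2] = True
    elif name == "L":
        arm, thick = (int(x) for x in args)
        m[cy : cy + thick, cx : cx + arm] = True
        m[cy : cy + arm, cx : cx + thick] = True
    elif name == "notched_disk":
        r = float(args[0])
        m = (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
        m[(rr >= cy) & (cc >= cx)] = False  # remove one quadrant
    else:
        raise ValueError(kind)
    return m


ORACLE_REGIONS = (
    [f"ellipse:{a}:{b}:{deg}" for a, b, deg in
     [(30, 15, 0), (30, 15, 30), (25, 25, 0), (20, 8, 60), (35, 12, 120),
      (15, 10, 45), (28, 22, 75), (18, 6, 150)]]
    + [f"rect:{w}:{h}" for w, h in [(40, 10), (20, 20), (48, 6), (30, 18)]]
    + [f"L:{arm}:{t}" for arm, t in [(40, 3), (30, 5), (45, 8), (25, 4)]]
    + [f"notched_disk:{r}" for r in (15, 20, 28, 34)]
)


class TestFitEllipse:
    def test_disk_recovers_radius(self):
        m = make_region("ellipse:20:20:0")
        ell = fit_ellipse(m)
        assert ell.semi_major == pytest.approx(20, rel=0.02)
        assert ell.semi_minor == pytest.approx(20, rel=0.02)

    def test_rectangle_closed_form_moments(self):
        # uniform w x h rectangle: semi-axes 2*sqrt((n^2-1)/12)
        ell = fit_ellipse(make_region("rect:40:10"))
        assert ell.orientation == pytest.approx(0.0, abs=1e-6)
        assert ell.semi_major / ell.semi_minor == pytest.approx(4.0, rel=0.05)
        assert ell.semi_major == pytest.approx(2 * np.sqrt((40**2 - 1) / 12), rel=1e-6)

    @pytest.mark.parametrize("deg", [20, 55, 110, 160])
    def test_rotation_equivariance(self, deg):
        base = fit_ellipse(make_region("ellipse:30:15:0"))
        rot = fit_ellipse(make_region(f"ellipse:30:15:{deg}"))
        delta = (np.rad2deg(rot.orientation - base.orientation)) % 180
        assert min(delta, 180 - delta) == pytest.approx(deg % 180, abs=2.0) or (
            min(delta, 180 - delta) == pytest.approx(180 - deg % 180, abs=2.0)
        )

    def test_degenerate_region_raises(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4, 2:9] = True  # collinear
        with pytest.raises(ValueError):
            fit_ellipse(m)
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((5, 5), dtype=bool))


class TestEllipticalScore:
    def test_filled_ellipse_scores_high(self):
        assert elliptical_score(make_region("ellipse:30:15:0")) >= 0.95

    def test_thin_L_rejected(self):
        assert elliptical_score(make_region("L:40:3")) < 0.4

    def test_degenerate_scores_zero(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4, 2:9] = True
        assert elliptical_score(m) == 0.0

    @pytest.mark.parametrize("kind", ORACLE_REGIONS)
    def test_matches_brute_force_oracle(self, kind):
        m = make_region(kind)
        assert elliptical_score(m) == pytest.approx(
            iou_with_moment_ellipse(m), abs=1e-9
        )

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(
        dr=st.integers(-30, 120),
        dc=st.integers(-30, 120),
        k=st.integers(0, 3),
        a=st.integers(8, 26),
        b=st.integers(5, 18),
    )
    def test_translation_and_rot90_invariance(self, dr, dc, k, a, b):
        a, b = max(a, b), min(a, b)
        m = make_region(f"ellipse:{a}:{b}:20")
        s0 = elliptical_score(m)
        rr, cc = np.nonzero(np.rot90(m, k))
        coords = np.stack([rr + dr + 200, cc + dc + 200], axis=1).astype(float)
        assert elliptical_score(coords) == pytest.approx(s0, abs=1e-12)


class TestDetectLumens:
    def test_no_enclosed_background_empty(self):
        lab = np.full((32, 32), int(Label.MYOCYTE))
        lab[0, :] = int(Label.BACKGROUND)
        assert detect_lumens(toy_map(lab)) == []

    def test_generator_lumens_all_accepted(self, rv_slide, rv_classified):
        _, truth = rv_slide
        n_true = ndi.label(truth.lumen_mask)[1]
        cands = detect_lumens(rv_classified)
        accepted = [c for c in cands if c.accepted]
        assert len(accepted) == n_true

    def test_five_lumens_among_fifty_vacuoles(self):
        from psrmorph import SlideSpec, generate_slide

        spec = SlideSpec(
            width_px=900, height_px=900, collagen_frac=0.08, fat_frac=0.02,
            n_vessels=5, fat_vacuole_radius_px=(8.0, 8.0), rng_seed=41,
        )
        slide, truth = generate_slide(spec)
        cmap = detect_fat(classify_pixels(slide))
        accepted = [c for c in detect_lumens(cmap) if c.accepted]
        assert len(accepted) == 5

    def test_threshold_semantics_and_monotonicity(self):
        # notched disk scores below 1; acceptance flips exactly at >= cut
        m = make_region("notched_disk:20")
        s = elliptical_score(m)
        assert 0 < s < 1
        lab = np.full((101, 101), int(Label.MYOCYTE))
        lab[m] = int(Label.BACKGROUND)
        cmap = toy_map(lab)
        low = detect_lumens(cmap, ExclusionParams(score_threshold=s - 1e-6,
                                                  min_lumen_area_um2=10))
        at = detect_lumens(cmap, ExclusionParams(score_threshold=min(s, 1.0),
                                                 min_lumen_area_um2=10))
        hi = detect_lumens(cmap, ExclusionParams(score_threshold=min(s + 1e-6, 1.0),
                                                 min_lumen_area_um2=10))
        assert low[0].accepted and at[0].accepted and not hi[0].accepted
        n_acc = [sum(c.accepted for c in cands) for cands in (low, at, hi)]
        assert n_acc == sorted(n_acc, reverse=True)

    def test_candidates_sorted_by_centroid(self, rv_classified):
        cands = detect_lumens(rv_classified)
        cents = [c.centroid for c in cands]
        assert cents == sorted(cents)


class TestExcludePerivascular:
    def test_lumen_without_collagen_only_lumen_excluded(self):
        lab = np.full((64, 64), int(Label.MYOCYTE))
        rr, cc = np.mgrid[:64, :64]
        lumen = (rr - 32) ** 2 + (cc - 32) ** 2 <= 12**2
        lab[lumen] = int(Label.BACKGROUND)
        cmap = toy_map(lab)
        cands = detect_lumens(cmap, ExclusionParams(min_lumen_area_um2=10))
        out = exclude_perivascular(cmap, cands, ExclusionParams(min_lumen_area_um2=10))
        assert (out.labels == Label.EXCLUDED_LUMEN).sum() == lumen.sum()
        assert (out.labels == Label.EXCLUDED_PERIVASCULAR).sum() == 0

    def test_cuff_removed_with_little_collateral(self, rv_slide, rv_classified):
        _, truth = rv_slide
        cands = detect_lumens(rv_classified)
        out = exclude_perivascular(rv_classified, cands)
        excl = out.labels == Label.EXCLUDED_PERIVASCULAR
        cuff = truth.perivascular_mask
        assert (excl & cuff).sum() / cuff.sum() >= 0.95
        non_cuff_col = (truth.class_mask == Label.COLLAGEN) & ~cuff
        assert (excl & non_cuff_col).sum() / non_cuff_col.sum() < 0.01

    def test_myocyte_and_fat_counts_never_change(self, rv_classified):
        cands = detect_lumens(rv_classified)
        out = exclude_perivascular(rv_classified, cands)
        before = rv_classified.counts()
        after = out.counts()
        assert after[Label.MYOCYTE] == before[Label.MYOCYTE]
        assert after[Label.FAT] == before[Label.FAT]
        assert sum(after.values()) == sum(before.values())

    def test_rejected_candidates_left_alone(self, rv_classified):
        cands = detect_lumens(rv_classified)
        for c in cands:
            c.accepted = False
        out = exclude_perivascular(rv_classified, cands)
        assert np.array_equal(out.labels, rv_classified.labels)

    def test_overlapping_reaches_union_exclusively(self):
        # two adjacent lumens sharing a collagen bridge
        lab = np.full((80, 140), int(Label.MYOCYTE))
        rr, cc = np.mgrid[:80, :140]
        l1 = (rr - 40) ** 2 + (cc - 45) ** 2 <= 12**2
        l2 = (rr - 40) ** 2 + (cc - 95) ** 2 <= 12**2
        bridge = (np.abs(rr - 40) <= 3) & (cc >= 45) & (cc <= 95)
        lab[bridge] = int(Label.COLLAGEN)
        lab[l1 | l2] = int(Label.BACKGROUND)
        cmap = toy_map(lab)
        cands = detect_lumens(cmap, ExclusionParams(min_lumen_area_um2=10))
        assert sum(c.accepted for c in cands) == 2
        out = exclude_perivascular(cmap, cands, ExclusionParams(min_lumen_area_um2=10))
        counts = out.counts()
        assert sum(counts.values()) == out.labels.size  # labels stay exclusive
        assert counts[Label.EXCLUDED_LUMEN] == int((l1 | l2).sum())
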