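"""Equal-area epicardial/endocardial partition and composition records.

Free-wall tissue is split 50:50 by area into an epicardial and an
endocardial half: every analyzable-tissue pixel gets a Euclidean distance
to the annotated epicardial surface, pixels are ranked by that distance,
and the ranking is cut at the median so each half holds half the tissue
area (whole distance strata are never split, so the halves can differ by at
most one stratum).  Septal samples have no epicardial surface and carry a
``whole_only`` mask.

Composition percentages denominate **analyzable** tissue: collagen + fat +
myocyte pixels, with excluded lumen and perivascular pixels removed from
both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage as ndi

from .classify import ANALYZABLE_LABELS, ClassMap, Label

__all__ = [
    "RegionMask",
    "CompositionRecord",
    "LOCATION_GROUPS",
    "partition_epi_endo",
    "compute_composition",
    "pool_records",
    "records_to_frame",
]

#: Sampled-location labels and the analysis group each belongs to.  The
#: right ventricular free-wall samples (and the outflow tract) are pooled
#: into a single RV quantity before percentages are computed.
LOCATION_GROUPS: dict[str, str] = {
    "RVOT": "RV",
    "RV": "RV",
    "RV_ant": "RV",
    "RV_lat": "RV",
    "RV_post": "RV",
    "IVS": "IVS",
    "IVS_ant": "IVS",
    "IVS_post": "IVS",
    "LV": "LV",
    "LV_ant": "LV",
    "LV_post": "LV",
}

REGION_NONE = 0
REGION_EPI = 1
REGION_ENDO = 2


@dataclass
class RegionMask:
    """Per-pixel region labels: 0 none, 1 epicardial, 2 endocardial.

    ``whole_only`` is True for septal samples (no epicardial surface); the
    label field is then all zero and only the total region is quantified.
    """

    labels: np.ndarray
    whole_only: bool
    provenance: str = "equal_area_distance_rank"


def partition_epi_endo(
    cmap: ClassMap, epicardial_boundary: np.ndarray | None
) -> RegionMask:
    """Split analyzable tissue into equal-area epi/endo halves.

    Distances are Euclidean (exact distance transform, pixel centres) from
    the boundary mask.  The cut distance is the whole-stratum threshold that
    brings the epicardial half closest to 50% of tissue area; pixels at
    distance ≤ cut are epicardial.  Deterministic and bit-reproducible.

    Passing ``epicardial_boundary=None`` yields a ``whole_only`` mask (the
    septal case).  An empty boundary mask for a free-wall sample raises.
    """
    tissue = cmap.mask(*ANALYZABLE_LABELS)
    if not tissue.any():
        raise ValueError("no analyzable tissue to partition")
    if epicardial_boundary is None:
        return RegionMask(
            labels=np.zeros(cmap.labels.shape, dtype=np.uint8),
            whole_only=True,
            provenance="whole_only",
        )
    boundary = np.asarray(epicardial_boundary, dtype=bool)
    if boundary.shape != cmap.labels.shape:
        raise ValueError("boundary mask shape does not match the label field")
    if not boundary.any():
        raise ValueError("epicardial boundary annotation is empty")
    dist = ndi.distance_transform_edt(~boundary)
    tvals = dist[tissue]
    n = tvals.size
    # whole-stratum cut closest to an exact 50:50 area split
    uniq, counts = np.unique(tvals, return_counts=True)
    cum = np.cumsum(counts)
    cut_idx = int(np.argmin(np.abs(cum - n / 2.0)))
    cut = uniq[cut_idx]
    labels = np.zeros(cmap.labels.shape, dtype=np.uint8)
    labels[tissue & (dist <= cut)] = REGION_EPI
    labels[tissue & (dist > cut)] = REGION_ENDO
    return RegionMask(labels=labels, whole_only=False)


@dataclass
class CompositionRecord:
    """Composition of one (heart, location, region) sample.

    Percentages are of analyzable tissue area and sum to 100; raw pixel
    counts are retained so samples can be pooled (RV free-wall merging)
    without re-reading images.
    """

    heart_id: str
    location: str
    region: str
    collagen_pct: float
    fat_pct: float
    myocyte_pct: float
    tissue_area_mm2: float
    collagen_px: int = 0
    fat_px: int = 0
    myocyte_px: int = 0
    um_per_px: float = float("nan")

    @property
    def group(self) -> str:
        """Analysis group (RV / IVS / LV) for this sampled location."""
        return LOCATION_GROUPS.get(self.location, self.location)


def _record_from_counts(
    heart_id: str,
    location: str,
    region: str,
    n_col: int,
    n_fat: int,
    n_myo: int,
    um_per_px: float,
) -> CompositionRecord:
    total = n_col + n_fat + n_myo
    if total == 0:
        raise ValueError(
            f"zero analyzable tissue for {heart_id}/{location}/{region}"
        )
    area_mm2 = total * um_per_px**2 * 1e-6
    return CompositionRecord(
        heart_id=heart_id,
        location=location,
        region=region,
        collagen_pct=100.0 * n_col / total,
        fat_pct=100.0 * n_fat / total,
        myocyte_pct=100.0 * n_myo / total,
        tissue_area_mm2=area_mm2,
        collagen_px=n_col,
        fat_px=n_fat,
        myocyte_px=n_myo,
        um_per_px=um_per_px,
    )


def compute_composition(
    cmap: ClassMap,
    regions: RegionMask | None,
    heart_id: str,
    location: str,
) -> list[CompositionRecord]:
    """Composition records for the total region, plus epi/endo if split.

    The map must be finalized (fat detected, perivascular excluded):
    percentages are ``100 × class pixels / analyzable pixels`` where
    analyzable tissue excludes ``EXCLUDED_LUMEN`` and
    ``EXCLUDED_PERIVASCULAR``.  Raises on zero analyzable tissue.
    """
    lab = cmap.labels

    def counts_in(mask: np.ndarray | None) -> tuple[int, int, int]:
        if mask is None:
            sel = lab
        else:
            sel = lab[mask]
        return (
            int((sel == Label.COLLAGEN).sum()),
            int((sel == Label.FAT).sum()),
            int((sel == Label.MYOCYTE).sum()),
        )

    out = [
        _record_from_counts(
            heart_id, location, "total", *counts_in(None), cmap.um_per_px
        )
    ]
    if regions is not None and not regions.whole_only:
        for name, code in (("epicardial", REGION_EPI), ("endocardial", REGION_ENDO)):
            out.append(
                _record_from_counts(
                    heart_id,
                    location,
                    name,
                    *counts_in(regions.labels == code),
                    cmap.um_per_px,
                )
            )
    return out


def pool_records(
    records: Iterable[CompositionRecord],
    location: str | None = None,
) -> CompositionRecord:
    """Merge samples by pooling pixel counts before computing percentages.

    Used to combine the right-ventricular free-wall samples into one RV
    record; the pooled percentage equals the area-weighted mean of the
    inputs.  All records must share heart, region and pixel size.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no records to pool")
    hearts = {r.heart_id for r in recs}
    regions_ = {r.region for r in recs}
    sizes = {r.um_per_px for r in recs}
    if len(hearts) != 1 or len(regions_) != 1 or len(sizes) != 1:
        raise ValueError("pooled records must share heart_id, region and um_per_px")
    loc = location if location is not None else recs[0].group
    return _record_from_counts(
        recs[0].heart_id,
        loc,
        recs[0].region,
        sum(r.collagen_px for r in recs),
        sum(r.fat_px for r in recs),
        sum(r.myocyte_px for r in recs),
        recs[0].um_per_px,
    )


def records_to_frame(
    records: Iterable[CompositionRecord],
    covariates: Mapping[str, Mapping[str, object]] | None = None,
) -> "pd.DataFrame":
    """Long-format table (one row per record × component) in the shared CSV
    schema: heart_id, location, region, component, value_pct, sex, age, bmi."""
    import pandas as pd

    rows = []
    for r in records:
        cov = (covariates or {}).get(r.heart_id, {})
        for comp, pct in (
            ("collagen", r.collagen_pct),
            ("fat", r.fat_pct),
            ("myocyte", r.myocyte_pct),
        ):
            rows.append(
                {
                    "heart_id": r.heart_id,
                    "location": r.location,
                    "region": r.region,
                    "component": comp,
                    "value_pct": pct,
                    "sex": cov.get("sex", ""),
                    "age": cov.get("age", np.nan),
                    "bmi": cov.get("bmi", np.nan),
                }
            )
    return pd.DataFrame(rows)
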