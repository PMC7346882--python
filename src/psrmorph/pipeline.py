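"""End-to-end orchestration: slide → labels → exclusion → composition → stats.

The pipeline is deterministic: a config hash and the seed are recorded in
every report, per-stage pixel accounting is checked for conservation, and
re-running with identical config and seed produces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synth
from .classify import (
    ClassMap,
    ColorBands,
    FatMorphParams,
    HSVBand,
    Label,
    SlideImage,
    classify_pixels,
    detect_fat,
)
from .regions import (
    LOCATION_GROUPS,
    CompositionRecord,
    RegionMask,
    compute_composition,
    partition_epi_endo,
    pool_records,
    records_to_frame,
)
from .stats import (
    ModelFit,
    RatioEstimate,
    cell_name,
    contrast_ratio,
    covariate_tests,
    fit_multilevel,
    predict_geometric_means,
)
from .vessels import ExclusionParams, LumenCandidate, detect_lumens, exclude_perivascular

__all__ = [
    "PipelineConfig",
    "SlideInput",
    "SlideResult",
    "PipelineResult",
    "process_slide",
    "run_pipeline",
    "make_fixtures",
]

#: Provenance metadata of the histology protocol this pipeline models
#: (stored in reports only; it does not affect computation).
PROTOCOL_METADATA = {
    "stain": "Picrosirius Red",
    "section_thickness_um": 5.0,
    "scan_magnification": "20x",
}


def _band_to_dict(b: HSVBand) -> dict:
    return {
        k: list(v)
        for k, v in (("hue", b.hue), ("sat", b.sat), ("val", b.val))
        if v is not None
    }


def _band_from_dict(d: dict) -> HSVBand:
    return HSVBand(
        hue=tuple(d["hue"]) if "hue" in d else None,
        sat=tuple(d["sat"]) if "sat" in d else None,
        val=tuple(d["val"]) if "val" in d else None,
    )


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one serialisable object.

    The config round-trips through YAML unchanged, and its canonical-JSON
    SHA-256 hash stamps every output so runs with different settings never
    masquerade as each other.
    """

    um_per_px: float = 1.0
    color_bands: ColorBands = field(default_factory=ColorBands)
    fat_params: FatMorphParams = field(default_factory=FatMorphParams)
    exclusion_params: ExclusionParams = field(default_factory=ExclusionParams)
    location_groups: dict[str, str] = field(
        default_factory=lambda: dict(LOCATION_GROUPS)
    )
    covariates: list[str] = field(default_factory=list)
    zero_policy: str = "halfmin"
    rng_seed: int = 0
    metadata: dict = field(default_factory=lambda: dict(PROTOCOL_METADATA))

    def __post_init__(self) -> None:
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")
        if self.zero_policy not in {"halfmin", "fail"}:
            raise ValueError("zero_policy must be 'halfmin' or 'fail'")
        # owned parameter types validate themselves on construction

    def to_dict(self) -> dict:
        return {
            "um_per_px": self.um_per_px,
            "color_bands": {
                "bands": {
                    lab.name.lower(): _band_to_dict(b)
                    for lab, b in self.color_bands.bands.items()
                },
                "priority": [lab.name.lower() for lab in self.color_bands.priority],
                "centers": {
                    lab.name.lower(): list(c)
                    for lab, c in self.color_bands.centers.items()
                },
            },
            "fat_params": dataclasses.asdict(self.fat_params),
            "exclusion_params": dataclasses.asdict(self.exclusion_params),
            "location_groups": dict(self.location_groups),
            "covariates": list(self.covariates),
            "zero_policy": self.zero_policy,
            "rng_seed": self.rng_seed,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "color_bands" in d:
            cb = d["color_bands"]
            lab = {name.lower(): m for name, m in Label.__members__.items()}
            d["color_bands"] = ColorBands(
                bands={lab[k]: _band_from_dict(v) for k, v in cb["bands"].items()},
                priority=tuple(lab[k] for k in cb["priority"]),
                centers={lab[k]: tuple(v) for k, v in cb["centers"].items()},
            )
        if "fat_params" in d:
            d["fat_params"] = FatMorphParams(**d["fat_params"])
        if "exclusion_params" in d:
            d["exclusion_params"] = ExclusionParams(**d["exclusion_params"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SlideInput:
    """One slide plus its identity and (optional) epicardial annotation."""

    slide: SlideImage
    heart_id: str
    location: str
    septal: bool = False
    covariates: dict = field(default_factory=dict)


@dataclass
class SlideResult:
    class_map: ClassMap
    region_mask: RegionMask
    records: list[CompositionRecord]
    lumens: list[LumenCandidate]
    accounting: dict


@dataclass
class PipelineResult:
    composition: pd.DataFrame
    analysis_table: pd.DataFrame
    predictions: pd.DataFrame
    ratios: list[RatioEstimate]
    fits: dict[str, ModelFit]
    report: dict


def _accounting(stage: str, cmap: ClassMap) -> dict:
    counts = {lab.name.lower(): n for lab, n in cmap.counts().items()}
    counts["stage"] = stage
    counts["total"] = int(cmap.labels.size)
    return counts


def process_slide(inp: SlideInput, config: PipelineConfig) -> SlideResult:
    """Run one slide through classification, fat detection, vessel
    exclusion, regional partition and composition; pixel accounting is
    verified to be conserved after every stage."""
    stages = []
    cmap = classify_pixels(inp.slide, config.color_bands)
    stages.append(_accounting("classify", cmap))
    cmap = detect_fat(cmap, config.fat_params)
    stages.append(_accounting("detect_fat", cmap))
    lumens = detect_lumens(cmap, config.exclusion_params)
    cmap = exclude_perivascular(cmap, lumens, config.exclusion_params)
    stages.append(_accounting("exclude_perivascular", cmap))
    for st in stages:
        assert (
            sum(st[lab.name.lower()] for lab in Label) == st["total"]
        ), f"pixel accounting broken at stage {st['stage']}"

    if inp.septal:
        region_mask = partition_epi_endo(cmap, None)
    else:
        if inp.slide.epicardial_boundary is None:
            raise ValueError(
                f"free-wall slide {inp.heart_id}/{inp.location} has no "
                "epicardial boundary annotation"
            )
        region_mask = partition_epi_endo(cmap, inp.slide.epicardial_boundary)
    records = compute_composition(cmap, region_mask, inp.heart_id, inp.location)
    return SlideResult(
        class_map=cmap,
        region_mask=region_mask,
        records=records,
        lumens=lumens,
        accounting={"slide": f"{inp.heart_id}/{inp.location}", "stages": stages},
    )


def _pool_rv(records: list[CompositionRecord], groups: dict[str, str]) -> list[
    CompositionRecord
]:
    """Merge each heart's RV free-wall samples (pixel-count pooling) into a
    single RV record per region; other locations pass through."""
    rv_free = {"RV", "RV_ant", "RV_lat", "RV_post"}
    out: list[CompositionRecord] = []
    buckets: dict[tuple[str, str], list[CompositionRecord]] = {}
    for r in records:
        if r.location in rv_free:
            buckets.setdefault((r.heart_id, r.region), []).append(r)
        else:
            out.append(r)
    for (_, _), recs in sorted(buckets.items()):
        out.append(pool_records(recs, location="RV"))
    return out


def _default_ratio_pairs(cells: list[str]) -> list[tuple[str, str]]:
    """Location contrasts within each region, plus epi-vs-endo within each
    location, in a fixed preferred order."""
    pairs = []
    parsed = [tuple(c.split("|", 1)) for c in cells]
    regions = sorted({r for _, r in parsed})
    pref = ["RV", "IVS", "LV"]
    for region in regions:
        locs = [l for l, r in parsed if r == region]
        locs = [l for l in pref if l in locs] + sorted(set(locs) - set(pref))
        for i in range(len(locs)):
            for j in range(i + 1, len(locs)):
                pairs.append((cell_name(locs[i], region), cell_name(locs[j], region)))
    locs = sorted({l for l, _ in parsed})
    for loc in locs:
        a, b = cell_name(loc, "epicardial"), cell_name(loc, "endocardial")
        if a in cells and b in cells:
            pairs.append((a, b))
    return pairs


def run_pipeline(
    config: PipelineConfig,
    slides: Sequence[SlideInput],
    components: tuple[str, ...] = ("collagen", "fat", "myocyte"),
) -> PipelineResult:
    """Process a slide set end-to-end and fit the per-component models.

    RV free-wall samples are pooled per heart before percentages enter the
    analysis; sampled locations are mapped to their analysis group
    (RV/IVS/LV) in the model table.  Statistics are skipped (empty outputs)
    when fewer than two hearts are available.
    """
    slide_results = []
    all_records: list[CompositionRecord] = []
    for inp in slides:
        res = process_slide(inp, config)
        slide_results.append(res)
        all_records.extend(res.records)
    pooled = _pool_rv(all_records, config.location_groups)

    covmap = {s.heart_id: s.covariates for s in slides if s.covariates}
    composition = records_to_frame(pooled, covariates=covmap)
    analysis = composition.copy()
    analysis["location"] = analysis["location"].map(
        lambda l: config.location_groups.get(l, l)
    )

    fits: dict[str, ModelFit] = {}
    predictions = pd.DataFrame()
    ratios: list[RatioEstimate] = []
    if analysis["heart_id"].nunique() >= 2:
        pred_frames = []
        for comp in components:
            fit = fit_multilevel(
                analysis,
                comp,
                covariates=config.covariates or None,
                zero_policy=config.zero_policy,
            )
            fits[comp] = fit
            pred_frames.append(predict_geometric_means(fit))
            for a, b in _default_ratio_pairs(fit.cells):
                ratios.append(contrast_ratio(fit, a, b))
        predictions = pd.concat(pred_frames, ignore_index=True)

    report = {
        "config_hash": config.config_hash,
        "seed": config.rng_seed,
        "metadata": dict(config.metadata),
        "n_slides": len(slides),
        "accounting": [r.accounting for r in slide_results],
        "lumen_candidates": [
            {
                "slide": r.accounting["slide"],
                "centroid": list(c.centroid),
                "area_px": c.area_px,
                "elliptical_score": c.elliptical_score,
                "accepted": c.accepted,
            }
            for r in slide_results
            for c in r.lumens
        ],
    }
    return PipelineResult(
        composition=composition,
        analysis_table=analysis,
        predictions=predictions,
        ratios=ratios,
        fits=fits,
        report=report,
    )


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def make_fixtures(
    seed: int,
    out_dir: str | Path,
    n_hearts: int = 3,
    slide_px: int = 384,
) -> dict:
    """Write the documented synthetic fixture set used by the test suite.

    Per heart: an RV free-wall slide (vessels + fat), a septal slide (no
    fat, no boundary) and an LV slide; plus a simulated 29-heart study
    table at the reference cell means.  Returns a manifest of SHA-256
    checksums, also written as ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict[str, str] = {}
    plan = {"RV": (0.15, 0.12, 3), "IVS": (0.09, 0.0, 2), "LV": (0.10, 0.05, 2)}
    for i in range(n_hearts):
        heart = f"H{i + 1:03d}"
        for loc, (col, fat, nves) in plan.items():
            spec = synth.SlideSpec(
                width_px=slide_px,
                height_px=slide_px,
                collagen_frac=col,
                fat_frac=fat,
                n_vessels=nves,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
            slide, truth = synth.generate_slide(spec)
            if loc == "IVS":
                slide.epicardial_boundary = None
            paths = synth.save_slide_bundle(out_dir, f"{heart}__{loc}", slide, truth)
            for p in paths.values():
                manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    study = synth.generate_study(
        synth.StudySpec(rng_seed=int(rng.integers(0, 2**31 - 1)))
    )
    study_path = out_dir / "study.csv"
    study.to_csv(study_path, index=False)
    manifest[study_path.name] = hashlib.sha256(study_path.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
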