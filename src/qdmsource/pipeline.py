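"""End-to-end workflow: phantom (or loaded maps) -> registration ->
detection + inversion -> provenance classification -> statistics.

Every stage is importable on its own; this module wires them together the
way the study processed each field of view, and writes the run's tables,
config snapshot and summary beside each other so a run is reproducible from
its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .classify import SourceRecord, classify, match_sources, records_to_frame
from .detect import detect_and_fit, noise_floor_survey
from .phantom import AcquisitionPair, PhantomConfig, make_phantom
from .physics import Direction, SensorGeometry
from .registration import estimate_transform
from .stats import (
    binomial_tissue_test,
    fisher_mean,
    contains_direction,
    fov_geometry,
    size_depth_report,
)


@dataclass
class RunConfig:
    """Serializable snapshot of everything a pipeline run depends on."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    k_mad: float = 5.0
    min_sep_px: int = 10
    window_px: int = 41
    match_tol_um: float = 5.0
    sensor_tol_um: float = 5.0
    depth_min_um: float = 1.0
    direction_rule_deg: float = 90.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["applied_field"] = {
            "dec": self.phantom.applied_field.declination,
            "inc": self.phantom.applied_field.inclination,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        af = ph.pop("applied_field", None)
        if isinstance(af, dict):
            ph["applied_field"] = Direction(af["dec"], af["inc"])
        for key in ("moment_range", "depth_range", "artifact_standoff_range",
                    "transform_rotation"):
            if key in ph and isinstance(ph[key], list):
                ph[key] = tuple(ph[key])
        return cls(phantom=PhantomConfig(**ph), **d)


@dataclass
class PipelineResult:
    pair: AcquisitionPair
    transform: "object"
    fits1: list
    fits2: list
    records: list[SourceRecord]
    sources_table: pd.DataFrame
    stats: dict


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full chain on a phantom generated from ``cfg``.

    When ``outdir`` is given, writes the phantom, fits tables, sources
    table, transform and a JSON summary there (never overwriting silently:
    existing files raise).
    """
    phantom_cfg = dataclasses.replace(cfg.phantom, seed=cfg.seed)
    pair = make_phantom(phantom_cfg)
    geom = phantom_cfg.geometry()
    applied = phantom_cfg.applied_field

    transform = estimate_transform(
        pair.fiducials1,
        pair.fiducials2,
        center=(
            geom.n_cols * geom.pixel_size / 2.0,
            geom.n_rows * geom.pixel_size / 2.0,
        ),
    )

    fits1 = detect_and_fit(
        pair.map1, geom, applied_field=applied,
        k_mad=cfg.k_mad, min_sep_px=cfg.min_sep_px, window_px=cfg.window_px,
    )
    fits2 = detect_and_fit(
        pair.map2, geom, applied_field=applied,
        k_mad=cfg.k_mad, min_sep_px=cfg.min_sep_px, window_px=cfg.window_px,
    )

    records = match_sources(
        [f for _, f in fits1],
        [f for _, f in fits2],
        transform,
        tol=cfg.match_tol_um,
        sensor_tol=cfg.sensor_tol_um,
    )
    classify(
        records,
        applied_field=applied,
        t=transform,
        depth_min=cfg.depth_min_um,
        direction_rule=cfg.direction_rule_deg,
        sensor_tol=cfg.sensor_tol_um,
        tol=cfg.match_tol_um,
        tissue_mask=pair.tissue_mask,
        geom=geom,
    )
    table = records_to_frame(records)
    stats = summarize_run(records, pair, geom)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("sources.csv", "fits1.csv", "fits2.csv", "summary.json"):
            if (outdir / name).exists():
                raise FileExistsError(f"refusing to overwrite {outdir / name}")
        qio.write_acquisition_pair(outdir / "phantom", pair)
        qio.write_fits(outdir / "fits1.csv", fits1, 1)
        qio.write_fits(outdir / "fits2.csv", fits2, 2)
        qio.write_sources(outdir / "sources.csv", records)
        qio.write_transform(outdir / "estimated_transform.json", transform)
        qio.write_config(outdir / "run_config.yaml", cfg.to_dict())
        (outdir / "summary.json").write_text(json.dumps(stats, indent=2, sort_keys=True))

    return PipelineResult(
        pair=pair, transform=transform, fits1=fits1, fits2=fits2,
        records=records, sources_table=table, stats=stats,
    )


def summarize_run(
    records: list[SourceRecord], pair: AcquisitionPair, geom: SensorGeometry
) -> dict:
    """Downstream statistics over one classified run."""
    applied = pair.config.applied_field
    labels = [r.label for r in records]
    bona = [r for r in records if r.label == "bona_fide"]
    out: dict = {
        "n_records": len(records),
        "label_counts": {lab: labels.count(lab) for lab in sorted(set(labels))},
        "fov": fov_geometry(geom),
    }

    if len(bona) >= 3:
        fr = fisher_mean([r.mean_direction for r in bona])
        out["fisher"] = {
            "n": fr.n,
            "mean_dec": fr.mean.declination if fr.mean else None,
            "mean_inc": fr.mean.inclination if fr.mean else None,
            "resultant_R": fr.resultant_R,
            "kappa": fr.kappa,
            "alpha95_deg": fr.alpha95,
            "contains_applied_field": bool(contains_direction(fr, applied))
            if np.isfinite(fr.alpha95)
            else None,
        }

    with_tissue = [r for r in bona if r.in_tissue is not None]
    if with_tissue:
        k = sum(1 for r in with_tissue if r.in_tissue)
        tissue_area = float(pair.tissue_mask.mean()) * out["fov"]["area_mm2"]
        bt = binomial_tissue_test(
            k, len(with_tissue), tissue_area, out["fov"]["area_mm2"]
        )
        out["binomial_tissue_test"] = {
            "k": bt.k, "n": bt.n, "p0": bt.p0, "p_value": bt.p_value,
        }

    table, summary = size_depth_report(records)
    out["size_depth_summary"] = summary

    all_fits = [r.fit1 for r in records if r.fit1] + [
        r.fit2 for r in records if r.fit2
    ]
    if all_fits:
        out["noise_floor"] = {
            k: v
            for k, v in noise_floor_survey(
                all_fits, n_smallest=min(147, len(all_fits))
            ).items()
            if k in ("n", "median", "mode_bin", "min")
        }
    return out


def score_against_truth(
    records: list[SourceRecord], pair: AcquisitionPair, tol_um: float = 5.0
) -> dict:
    """Confusion matrix of assigned labels against phantom ground truth.

    Each truth source is matched to the nearest record (sample frame,
    within ``tol_um``); expected labels are sample -> bona_fide,
    artifact -> artifact, contaminant -> contamination. Truth sources with
    no record count as misses.
    """
    expected = {"sample": "bona_fide", "artifact": "artifact", "contaminant": "contamination"}
    rec_xy = np.array([r.sample_frame_xy for r in records]).reshape(-1, 2)
    confusion: dict = {}
    n_correct = 0
    rows = []
    for ps in pair.truth:
        if ps.role == "artifact":
            # artifacts live in the sensor frame == acq-1 sample frame here
            xy = np.asarray(ps.sensor_xy_1)
        else:
            xy = np.array([ps.source.x, ps.source.y])
        if len(rec_xy):
            d = np.linalg.norm(rec_xy - xy, axis=1)
            i = int(np.argmin(d))
            got = records[i].label if d[i] <= tol_um else "missed"
        else:
            got = "missed"
        want = expected[ps.role]
        confusion[(want, got)] = confusion.get((want, got), 0) + 1
        n_correct += got == want
        rows.append({"role": ps.role, "expected": want, "assigned": got})
    return {
        "n_truth": len(pair.truth),
        "n_correct": n_correct,
        "accuracy": n_correct / len(pair.truth) if pair.truth else float("nan"),
        "confusion": {f"{w}->{g}": c for (w, g), c in sorted(confusion.items())},
        "per_source": rows,
    }
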