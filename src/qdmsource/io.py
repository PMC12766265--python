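"""Readers and writers for maps, tables and run artifacts.

Field maps travel as 32-bit float single-channel TIFF (or a plain-text
matrix when the path ends in ``.txt``) with a JSON sidecar carrying pixel
size, component, frame and acquisition metadata; tables are CSV with
documented headers; transforms and configs are JSON/YAML. All coordinates
in files are µm in the acquisition-1 sensor frame unless a frame tag says
otherwise; pixel (0, 0) is the top-left pixel center, 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classify import records_to_frame
from .detect import Candidate, DipoleFit
from .phantom import AcquisitionPair, PhantomSource
from .physics import FieldMap
from .registration import RigidTransform2D


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_fieldmap(path, fmap: FieldMap) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, fmap.values.astype(np.float32))
    elif path.suffix == ".txt":
        np.savetxt(path, fmap.values)
    else:
        raise ValueError(f"unsupported map format: {path.suffix}")
    sidecar = {
        "pixel_size_um": fmap.pixel_size,
        "component": fmap.component,
        "frame": fmap.frame,
        "units": "tesla",
        **_jsonable(fmap.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_fieldmap(path) -> FieldMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path).astype(float)
    elif path.suffix == ".txt":
        values = np.loadtxt(path)
    else:
        raise ValueError(f"unsupported map format: {path.suffix}")
    meta = json.loads(_sidecar_path(path).read_text())
    return FieldMap(
        values=values,
        pixel_size=meta.pop("pixel_size_um"),
        component=meta.pop("component", "bz"),
        frame=meta.pop("frame", "sensor"),
        metadata=meta,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_transform(path, t: RigidTransform2D) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(t.to_dict(), indent=2, sort_keys=True))
    return path


def read_transform(path) -> RigidTransform2D:
    return RigidTransform2D.from_dict(json.loads(Path(path).read_text()))


def write_fiducials(path, fiducials: np.ndarray, acquisition_id: int) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "id": np.arange(len(fiducials)),
            "acquisition": acquisition_id,
            "x_um": fiducials[:, 0] if len(fiducials) else [],
            "y_um": fiducials[:, 1] if len(fiducials) else [],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_fiducials(path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("id")
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


def write_truth(path, truth: list[PhantomSource]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for ps in truth:
        rows.append(
            {
                "role": ps.role,
                "host": ps.host,
                "x_um": ps.source.x,
                "y_um": ps.source.y,
                "standoff_um": ps.source.standoff,
                "mx_Am2": ps.source.moment.mx,
                "my_Am2": ps.source.moment.my,
                "mz_Am2": ps.source.moment.mz,
                "appears_in": "+".join(str(a) for a in ps.appears_in),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "role", "host", "x_um", "y_um", "standoff_um",
            "mx_Am2", "my_Am2", "mz_Am2", "appears_in",
        ],
    ).to_csv(path, index=False)
    return path


def fits_to_frame(
    pairs: list[tuple[Candidate, DipoleFit]], acquisition_id: int
) -> pd.DataFrame:
    rows = []
    for i, (cand, fit) in enumerate(pairs):
        d = fit.direction
        rows.append(
            {
                "acquisition_id": acquisition_id,
                "candidate_id": i,
                "x_um": fit.x,
                "y_um": fit.y,
                "fitted_distance_um": fit.fitted_distance,
                "depth_um": fit.depth,
                "moment_Am2": fit.moment_magnitude,
                "mx_Am2": fit.moment.mx,
                "my_Am2": fit.moment.my,
                "mz_Am2": fit.moment.mz,
                "dec_deg": d.declination,
                "inc_deg": d.inclination,
                "residual_rms_T": fit.residual_rms,
                "r2": fit.r_squared,
                "converged": fit.converged,
                "snr": cand.snr,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "acquisition_id", "candidate_id", "x_um", "y_um",
            "fitted_distance_um", "depth_um", "moment_Am2",
            "mx_Am2", "my_Am2", "mz_Am2", "dec_deg", "inc_deg",
            "residual_rms_T", "r2", "converged", "snr",
        ],
    )


def write_fits(path, pairs, acquisition_id: int) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fits_to_frame(pairs, acquisition_id).to_csv(path, index=False)
    return path


def write_sources(path, records) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False)
    return path


def write_acquisition_pair(outdir, pair: AcquisitionPair, fmt: str = "tif") -> dict:
    """Serialize a phantom: two maps + sidecars, fiducial CSVs, truth CSV,
    true transform JSON and tissue mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map1": write_fieldmap(outdir / f"map1.{fmt}", pair.map1),
        "map2": write_fieldmap(outdir / f"map2.{fmt}", pair.map2),
        "fiducials1": write_fiducials(outdir / "fiducials1.csv", pair.fiducials1, 1),
        "fiducials2": write_fiducials(outdir / "fiducials2.csv", pair.fiducials2, 2),
        "truth": write_truth(outdir / "truth.csv", pair.truth),
        "transform": write_transform(outdir / "true_transform.json", pair.true_transform),
    }
    mask_path = outdir / "tissue_mask.txt"
    np.savetxt(mask_path, pair.tissue_mask.astype(np.uint8), fmt="%d")
    paths["tissue_mask"] = mask_path
    return paths


def write_config(path, cfg: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_jsonable(cfg), sort_keys=True))
    return path


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
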