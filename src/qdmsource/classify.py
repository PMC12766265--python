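"""Provenance classification of fitted sources across duplicate acquisitions.

The duplicate-acquisition design separates three source populations by how
their positions behave under the rigid motion between the two maps:

* a **bona fide** in-sample source occupies the same *sample-frame* position
  in both maps, lies deeper than the NV-layer correction (so it is inside
  the sample, not on a surface) and is magnetized consistently with the
  in-plane field applied before imaging;
* a **diamond artifact** travels with the sensor, so its *sensor-frame*
  position is unchanged between the maps;
* **contamination** (or noise) appears in only one acquisition, or sits at
  a surface (depth at or above the sample surface).

Label priority is artifact > contamination > bona_fide: a sensor-frame
colocated pair is an artifact regardless of its depth or direction, a
singleton or surface-depth record is contamination, and only records
passing every bona-fide criterion receive that label. Pairs failing the
direction rule alone, pairs whose two depth estimates disagree by more than
2 µm, and everything else fall through to ``ambiguous`` — as does every
paired record when the inter-acquisition motion is too small to tell the
two frames apart (below 3x the co-location tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import DipoleFit
from .physics import Direction, MomentVector, vector_to_direction
from .registration import RigidTransform2D


@dataclass
class SourceRecord:
    """One physical source hypothesis assembled from fits in the two maps."""

    source_id: int
    fit1: DipoleFit | None
    fit2: DipoleFit | None  # moment components rotated into the acq-1 frame
    sample_frame_xy: tuple[float, float]
    sensor_frame_shift: float | None  # µm between the raw sensor positions
    sample_frame_dist: float | None  # µm between the aligned positions
    label: str = "ambiguous"
    criteria: dict = field(default_factory=dict)
    in_tissue: bool | None = None

    @property
    def paired(self) -> bool:
        return self.fit1 is not None and self.fit2 is not None

    @property
    def mean_depth(self) -> float:
        depths = [f.depth for f in (self.fit1, self.fit2) if f is not None]
        return float(np.mean(depths))

    @property
    def mean_direction(self) -> Direction:
        vecs = [
            f.moment.as_array() / f.moment_magnitude
            for f in (self.fit1, self.fit2)
            if f is not None and f.moment_magnitude > 0
        ]
        return vector_to_direction(np.sum(vecs, axis=0))


def _mutual_nn_pairs(pos_a: np.ndarray, pos_b: np.ndarray, tol: float):
    """Indices (i, j) of mutual nearest neighbors within ``tol``."""
    if len(pos_a) == 0 or len(pos_b) == 0:
        return []
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    pairs = []
    for i in range(len(pos_a)):
        j = int(np.argmin(d[i]))
        if d[i, j] <= tol and int(np.argmin(d[:, j])) == i:
            pairs.append((i, j))
    return pairs


def _rotate_fit_moment(fit: DipoleFit, t: RigidTransform2D) -> DipoleFit:
    """Express an acquisition-2 fit's moment in acquisition-1 axes (the
    sample rotates with the rigid motion; in-plane components follow R)."""
    R = t.matrix()
    mxy = R @ np.array([fit.moment.mx, fit.moment.my])
    from dataclasses import replace

    return replace(fit, moment=MomentVector(float(mxy[0]), float(mxy[1]), fit.moment.mz))


def match_sources(
    fits1: list[DipoleFit],
    fits2: list[DipoleFit],
    t: RigidTransform2D,
    tol: float = 5.0,
    sensor_tol: float = 5.0,
) -> list[SourceRecord]:
    """Pair fits across the duplicate maps and assemble source records.

    Fits are first paired by mutual nearest neighbor in the *sample frame*
    (acquisition-2 positions pushed through ``t``), accepting pairs within
    ``tol`` µm — these are the in-sample source hypotheses. Remaining fits
    are then paired by mutual nearest neighbor in the raw *sensor frame*
    within ``sensor_tol`` — pairs that ignored the sample motion, i.e.
    diamond-artifact hypotheses. Whatever is left becomes a singleton
    record. Acquisition-2 moments are rotated into acquisition-1 axes.
    """
    p1 = np.array([[f.x, f.y] for f in fits1], dtype=float).reshape(-1, 2)
    p2_raw = np.array([[f.x, f.y] for f in fits2], dtype=float).reshape(-1, 2)
    p2_aligned = t.apply(p2_raw) if len(p2_raw) else p2_raw

    records: list[SourceRecord] = []
    used1: set[int] = set()
    used2: set[int] = set()
    sid = 0

    for i, j in _mutual_nn_pairs(p1, p2_aligned, tol):
        used1.add(i)
        used2.add(j)
        mid = 0.5 * (p1[i] + p2_aligned[j])
        records.append(
            SourceRecord(
                source_id=sid,
                fit1=fits1[i],
                fit2=_rotate_fit_moment(fits2[j], t),
                sample_frame_xy=tuple(mid),
                sensor_frame_shift=float(np.linalg.norm(p1[i] - p2_raw[j])),
                sample_frame_dist=float(np.linalg.norm(p1[i] - p2_aligned[j])),
                criteria={"colocated_sample_frame": True, "colocated_sensor_frame": False},
            )
        )
        sid += 1

    rest1 = [i for i in range(len(fits1)) if i not in used1]
    rest2 = [j for j in range(len(fits2)) if j not in used2]
    if rest1 and rest2:
        q1 = p1[rest1]
        q2 = p2_raw[rest2]
        for a, b in _mutual_nn_pairs(q1, q2, sensor_tol):
            i, j = rest1[a], rest2[b]
            used1.add(i)
            used2.add(j)
            records.append(
                SourceRecord(
                    source_id=sid,
                    fit1=fits1[i],
                    # a sensor-frame pair shares one sensor position; that is
                    # the meaningful coordinate to report for it
                    fit2=_rotate_fit_moment(fits2[j], t),
                    sample_frame_xy=tuple(0.5 * (p1[i] + p2_raw[j])),
                    sensor_frame_shift=float(np.linalg.norm(p1[i] - p2_raw[j])),
                    sample_frame_dist=float(np.linalg.norm(p1[i] - p2_aligned[j])),
                    criteria={
                        "colocated_sample_frame": False,
                        "colocated_sensor_frame": True,
                    },
                )
            )
            sid += 1

    for i in range(len(fits1)):
        if i not in used1:
            records.append(
                SourceRecord(
                    source_id=sid,
                    fit1=fits1[i],
                    fit2=None,
                    sample_frame_xy=tuple(p1[i]),
                    sensor_frame_shift=None,
                    sample_frame_dist=None,
                    criteria={
                        "colocated_sample_frame": False,
                        "colocated_sensor_frame": False,
                    },
                )
            )
            sid += 1
    for j in range(len(fits2)):
        if j not in used2:
            records.append(
                SourceRecord(
                    source_id=sid,
                    fit1=None,
                    fit2=_rotate_fit_moment(fits2[j], t),
                    sample_frame_xy=tuple(p2_aligned[j]),
                    sensor_frame_shift=None,
                    sample_frame_dist=None,
                    criteria={
                        "colocated_sample_frame": False,
                        "colocated_sensor_frame": False,
                    },
                )
            )
            sid += 1
    return records


def classify(
    records: list[SourceRecord],
    applied_field: Direction,
    t: RigidTransform2D,
    depth_min: float = 1.0,
    direction_rule: float = 90.0,
    sensor_tol: float = 5.0,
    tol: float = 5.0,
    tissue_mask: np.ndarray | None = None,
    geom=None,
    depth_disagreement_max: float = 2.0,
) -> list[SourceRecord]:
    """Assign a provenance label to every record (in place, also returned).

    Rules, in priority order (see module docstring for rationale):
    transform too small -> paired records ambiguous; sensor-frame colocated
    -> artifact; singleton or mean depth <= ``depth_min`` -> contamination;
    sample-frame colocated, deep, direction within ``direction_rule``
    degrees of the applied field, depths consistent -> bona_fide; otherwise
    ambiguous.
    """
    frames_distinguishable = t.translation_magnitude >= 3.0 * tol

    for rec in records:
        c = rec.criteria
        c["depth_ok"] = rec.mean_depth > depth_min
        if rec.fit1 is not None or rec.fit2 is not None:
            angle = rec.mean_direction.angle_to(applied_field)
            c["direction_ok"] = angle < direction_rule
            c["direction_angle_deg"] = angle
        depths = [f.depth for f in (rec.fit1, rec.fit2) if f is not None]
        depth_consistent = (
            len(depths) < 2 or abs(depths[0] - depths[1]) <= depth_disagreement_max
        )
        c["depth_consistent"] = depth_consistent
        c["frames_distinguishable"] = frames_distinguishable

        if tissue_mask is not None and geom is not None:
            row, col = geom.xy_to_rowcol(*rec.sample_frame_xy)
            r, cix = int(round(float(row))), int(round(float(col)))
            if 0 <= r < tissue_mask.shape[0] and 0 <= cix < tissue_mask.shape[1]:
                rec.in_tissue = bool(tissue_mask[r, cix])
            else:
                rec.in_tissue = False
        c["in_tissue"] = rec.in_tissue

        sensor_coloc = (
            rec.paired
            and rec.sensor_frame_shift is not None
            and rec.sensor_frame_shift <= sensor_tol
            and c.get("colocated_sensor_frame", False)
        )
        if rec.paired and not frames_distinguishable:
            rec.label = "ambiguous"
        elif sensor_coloc:
            rec.label = "artifact"
        elif not rec.paired or not c["depth_ok"]:
            rec.label = "contamination"
        elif c["colocated_sample_frame"] and c["direction_ok"] and depth_consistent:
            rec.label = "bona_fide"
        else:
            rec.label = "ambiguous"
    return records


def deduplicate_records(
    record_sets: list[list[SourceRecord]], tol: float = 5.0
) -> list[list[int]]:
    """Cluster records from repeat map pairs of the same field of view.

    A source detected in several map pairs of one FOV is one physical
    source; records within ``tol`` µm (sample frame) across sets are grouped
    greedily. Returns clusters as lists of (set_index, record_index) pairs
    flattened to a global index order.
    """
    flat = [
        (si, ri, np.asarray(rec.sample_frame_xy))
        for si, recs in enumerate(record_sets)
        for ri, rec in enumerate(recs)
    ]
    clusters: list[list[int]] = []
    centers: list[np.ndarray] = []
    assignments: list[list[tuple[int, int]]] = []
    for gi, (si, ri, xy) in enumerate(flat):
        placed = False
        for ci, ctr in enumerate(centers):
            if np.linalg.norm(xy - ctr) <= tol:
                members = assignments[ci]
                if all(m[0] != si for m in members):  # one record per set
                    members.append((si, ri))
                    pts = [flat_xy for s, r, flat_xy in flat if (s, r) in members]
                    centers[ci] = np.mean(pts, axis=0)
                    clusters[ci].append(gi)
                    placed = True
                    break
        if not placed:
            clusters.append([gi])
            centers.append(xy.astype(float))
            assignments.append([(si, ri)])
    return [assignments[i] for i in range(len(assignments))]


_SOURCES_COLUMNS = [
    "source_id", "label", "x_um", "y_um", "sensor_frame_shift_um",
    "sample_frame_dist_um", "in_tissue",
    "depth1_um", "moment1_Am2", "dec1_deg", "inc1_deg", "r2_1",
    "depth2_um", "moment2_Am2", "dec2_deg", "inc2_deg", "r2_2",
    "mean_depth_um",
]


def records_to_frame(records: list[SourceRecord]) -> pd.DataFrame:
    """Flatten records into the sources table (header kept even if empty)."""
    if not records:
        return pd.DataFrame(columns=_SOURCES_COLUMNS)
    rows = []
    for rec in records:
        row = {
            "source_id": rec.source_id,
            "label": rec.label,
            "x_um": rec.sample_frame_xy[0],
            "y_um": rec.sample_frame_xy[1],
            "sensor_frame_shift_um": rec.sensor_frame_shift,
            "sample_frame_dist_um": rec.sample_frame_dist,
            "in_tissue": rec.in_tissue,
        }
        for i, fit in ((1, rec.fit1), (2, rec.fit2)):
            if fit is None:
                row.update(
                    {
                        f"depth{i}_um": np.nan,
                        f"moment{i}_Am2": np.nan,
                        f"dec{i}_deg": np.nan,
                        f"inc{i}_deg": np.nan,
                        f"r2_{i}": np.nan,
                    }
                )
            else:
                d = fit.direction
                row.update(
                    {
                        f"depth{i}_um": fit.depth,
                        f"moment{i}_Am2": fit.moment_magnitude,
                        f"dec{i}_deg": d.declination,
                        f"inc{i}_deg": d.inclination,
                        f"r2_{i}": fit.r_squared,
                    }
                )
        row["mean_depth_um"] = rec.mean_depth
        for k, v in rec.criteria.items():
            row[f"crit_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
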