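"""Downstream statistics: Fisher directional statistics, binomial
tissue-preference tests, particle sizing reports and the TEM-probability
worked example.

Fisher (1953) statistics treat unit directions as draws from a spherical
analogue of the normal distribution concentrated about a mean direction with
precision parameter kappa. From n unit vectors with resultant length R the
maximum-likelihood style estimates are

    kappa_hat = (n - 1) / (n - R)
    alpha95   = arccos( 1 - (n - R)/R * ((1/0.05)^(1/(n-1)) - 1) )

where alpha95 is the half-angle of the 95% confidence cone about the mean
direction. The confidence region is implemented as this circular cone; the
containment test checks the angular distance of a candidate direction against
alpha95.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .physics import (
    Direction,
    SensorGeometry,
    diameter_to_moment,
    direction_to_vector,
    moment_to_diameter,
    vector_to_direction,
)


# ---------------------------------------------------------------------------
# Fisher statistics


@dataclass(frozen=True)
class FisherResult:
    mean: Direction | None
    n: int
    resultant_R: float
    kappa: float
    alpha95: float  # degrees; NaN when undefined (n < 3 or R ~ 0)

    @property
    def mean_defined(self) -> bool:
        return self.mean is not None


def fisher_mean(directions: list[Direction]) -> FisherResult:
    """Mean direction, resultant length, kappa and the 95% confidence cone."""
    n = len(directions)
    if n == 0:
        raise ValueError("need at least one direction")
    vecs = np.array([direction_to_vector(d) for d in directions])
    resultant = vecs.sum(axis=0)
    R = float(np.linalg.norm(resultant))
    if R < 1e-12:
        return FisherResult(mean=None, n=n, resultant_R=R, kappa=0.0, alpha95=float("nan"))
    mean = vector_to_direction(resultant)
    kappa = float("inf") if np.isclose(R, n) else (n - 1) / (n - R)
    if n < 3:
        a95 = float("nan")
    else:
        cosa = 1.0 - ((n - R) / R) * ((1.0 / 0.05) ** (1.0 / (n - 1)) - 1.0)
        a95 = float(np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0)))) if cosa >= -1.0 else 180.0
    return FisherResult(mean=mean, n=n, resultant_R=R, kappa=kappa, alpha95=a95)


def contains_direction(fr: FisherResult, d: Direction) -> bool:
    """True iff ``d`` lies inside the 95% confidence cone of ``fr``."""
    if fr.mean is None or not np.isfinite(fr.alpha95):
        raise ValueError("confidence cone undefined (n < 3 or zero resultant)")
    return fr.mean.angle_to(d) <= fr.alpha95


def sample_fisher_directions(
    mean: Direction, kappa: float, n: int, rng: np.random.Generator
) -> list[Direction]:
    """Draw n unit directions from a Fisher distribution about ``mean``.

    Uses the standard inversion for the polar angle about the mean
    (w = 1 + log(u + (1-u) e^{-2 kappa}) / kappa) and a uniform azimuth,
    then rotates the draws onto the mean direction.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    u = rng.random(n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), w])
    mu = direction_to_vector(mean)
    # orthonormal basis with e3 = mu
    helper = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    basis = np.column_stack([e1, e2, mu])
    world = local @ basis.T
    return [vector_to_direction(v) for v in world]


# ---------------------------------------------------------------------------
# binomial tissue-preference test


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    p0: float
    p_value: float


def binomial_tissue_test(
    k: int, n: int, tissue_area: float, fov_area: float
) -> BinomialTestResult:
    """Exact one-tailed right-sided binomial test for tissue preference.

    Under the null that sources land uniformly over the field of view, the
    probability that any one source falls in tissue is the area ratio
    p0 = tissue_area / fov_area; the p-value is P(X >= k) for
    X ~ Binomial(n, p0).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < tissue_area <= fov_area:
        raise ValueError("need 0 < tissue_area <= fov_area")
    p0 = tissue_area / fov_area
    if n == 0:
        p_value = 1.0
    else:
        p_value = float(sps.binomtest(k, n, p0, alternative="greater").pvalue)
    return BinomialTestResult(k=k, n=n, p0=p0, p_value=p_value)


# ---------------------------------------------------------------------------
# geometry and worked example


def fov_geometry(geom: SensorGeometry) -> dict:
    """Physical size of the field of view in mm / mm^2."""
    w = geom.n_cols * geom.pixel_size * 1e-3
    h = geom.n_rows * geom.pixel_size * 1e-3
    return {"width_mm": w, "height_mm": h, "area_mm2": w * h}


def tem_detection_probability(
    specific_moment: float = 1e-6,
    d_nm: float = 50.0,
    image_area_um2: float = 100.0,
    section_thickness_nm: float = 100.0,
    tissue_density: float = 1000.0,
    ms: float = 4.8e5,
) -> dict:
    """Expected number of magnetite particles in a single TEM image.

    Assumes the bulk specific moment of brain tissue (A m^2 per kg, default
    the literature maximum 1e-6) is carried entirely by identical spheres of
    diameter ``d_nm``, homogeneously distributed at ``tissue_density``. The
    result is the expected particle count inside one imaged volume
    (image area x section thickness) and its reciprocal ("1 in N chance" to
    catch a particle in one micrograph).
    """
    if min(specific_moment, d_nm, image_area_um2, section_thickness_nm, tissue_density, ms) < 0:
        raise ValueError("all inputs must be >= 0")
    per_particle = diameter_to_moment(d_nm, ms)
    density = specific_moment * tissue_density / per_particle  # particles / m^3
    volume = image_area_um2 * 1e-12 * section_thickness_nm * 1e-9  # m^3
    expected = density * volume
    return {
        "expected_count": expected,
        "one_in_N": float("inf") if expected == 0 else 1.0 / expected,
    }


# ---------------------------------------------------------------------------
# sizing report


def size_depth_report(
    records, cluster_diameter_nm: float = 300.0, ms: float = 4.8e5
) -> tuple[pd.DataFrame, dict]:
    """Per-source, per-image particle diameter and depth table plus summary.

    Converts each fit's moment magnitude to an equivalent magnetite sphere
    diameter. Sources whose implied diameter exceeds
    ``cluster_diameter_nm`` are flagged as probable clusters of smaller
    particles rather than single crystals. Summary reports the diameter
    range over bona fide sources.
    """
    rows = []
    for rec in records:
        for image, fit in ((1, rec.fit1), (2, rec.fit2)):
            if fit is None:
                continue
            d = moment_to_diameter(fit.moment_magnitude, ms)
            rows.append(
                {
                    "source_id": rec.source_id,
                    "label": rec.label,
                    "image": image,
                    "moment_Am2": fit.moment_magnitude,
                    "diameter_nm": d,
                    "depth_um": fit.depth,
                    "probable_cluster": d > cluster_diameter_nm,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "source_id",
            "label",
            "image",
            "moment_Am2",
            "diameter_nm",
            "depth_um",
            "probable_cluster",
        ],
    )
    bona = table[table["label"] == "bona_fide"] if len(table) else table
    summary = {
        "n_sources": int(table["source_id"].nunique()) if len(table) else 0,
        "n_bona_fide": int(bona["source_id"].nunique()) if len(table) else 0,
        "diameter_min_nm": float(bona["diameter_nm"].min()) if len(bona) else float("nan"),
        "diameter_max_nm": float(bona["diameter_nm"].max()) if len(bona) else float("nan"),
        "n_probable_clusters": int(
            table.loc[table["probable_cluster"], "source_id"].nunique()
        )
        if len(table)
        else 0,
    }
    return table, summary
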