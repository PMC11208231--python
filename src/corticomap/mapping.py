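"""Cortical motor map features: center of gravity and map area.

The motor map of a muscle is the set of stimulation sites (in template,
MNI-like, coordinates) at which TMS evoked an accepted MEP, each weighted by
its peak-to-peak amplitude Vi.  Two scalar features summarise it:

* the center of gravity (CoG), the amplitude-weighted centroid
  ``(sum(Vi*Xi)/sum(Vi), sum(Vi*Yi)/sum(Vi), sum(Vi*Zi)/sum(Vi))``, and
* the cortical area (mm^2), the planar extent of the MEP-positive sites.

Axis convention: X is medio-lateral (larger |X| = more lateral), Y is
posterior-anterior, Z vertical.  Stimulation targets the hemisphere
contralateral to the (most) painful side, so a cohort mixes hemispheres;
before group analysis maps are mirrored onto a common canonical side (the
left, X < 0, so "more lateral" = more negative X).

Area is computed on the best-fit plane through the 3-D site cloud
(principal-axes projection).  The default estimator is the alpha-shape area
(union of Delaunay triangles with circumradius <= alpha, default 15 mm),
which tolerates non-convex maps; the convex hull is available as an
alternative and is the alpha -> infinity limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .mep import MepRecord

__all__ = [
    "MapSite",
    "MotorMap",
    "DegenerateMapWarning",
    "MUSCLES",
    "compute_cog",
    "compute_area",
    "summarize_map",
    "mirror_hemisphere",
    "maps_to_frame",
]

MUSCLES = (
    "longissimus_L3",
    "longissimus_L5",
    "obliquus_externus",
    "obliquus_internus",
)

DEFAULT_ALPHA_MM = 15.0


class DegenerateMapWarning(UserWarning):
    """Fewer than three non-collinear sites: area reported as 0."""


@dataclass(frozen=True)
class MapSite:
    """One MEP-positive stimulation site: coordinates (mm) and amplitude Vi (uV)."""

    coords: tuple[float, float, float]
    amplitude: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("MapSite coordinates must be finite")
        if self.amplitude <= 0:
            raise ValueError("MapSite amplitude must be positive")


@dataclass
class MotorMap:
    """Per-muscle map summary.  ``cog`` is None when no MEPs were elicited."""

    muscle: str
    sites: list[MapSite]
    cog: np.ndarray | None
    area_mm2: float
    n_sites: int
    flags: list[str] = field(default_factory=list)

    @property
    def missing(self) -> bool:
        return self.cog is None


def compute_cog(sites: Sequence[MapSite]) -> np.ndarray:
    """Amplitude-weighted centroid of the site coordinates, per axis."""
    if len(sites) == 0:
        raise ValueError("compute_cog requires at least one site")
    coords = np.array([s.coords for s in sites], dtype=float)
    weights = np.array([s.amplitude for s in sites], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("compute_cog requires positive total amplitude")
    return coords.T @ weights / total


def _project_to_plane(coords: np.ndarray) -> np.ndarray:
    """Project 3-D sites onto their best-fit plane via centered SVD."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:2].T


def _alpha_shape_area(pts: np.ndarray, alpha: float) -> float:
    """Sum of Delaunay-triangle areas with circumradius <= alpha."""
    tri = Delaunay(pts)
    a = pts[tri.simplices[:, 0]]
    b = pts[tri.simplices[:, 1]]
    c = pts[tri.simplices[:, 2]]
    ab = np.linalg.norm(b - a, axis=1)
    bc = np.linalg.norm(c - b, axis=1)
    ca = np.linalg.norm(a - c, axis=1)
    u, v = b - a, c - a
    area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = ab * bc * ca / (2.0 * area2)
    keep = (area2 > 0) & (circumradius <= alpha)
    return float(area2[keep].sum() / 2.0)


def compute_area(
    sites: Sequence[MapSite],
    method: Literal["alpha_shape", "convex_hull"] = "alpha_shape",
    alpha: float = DEFAULT_ALPHA_MM,
) -> float:
    """Planar map area in mm^2 on the best-fit plane of the site cloud.

    Degenerate inputs (fewer than 3 sites, or collinear sites) give area 0
    with a :class:`DegenerateMapWarning` rather than an exception, so the
    map remains reportable (the CoG is still defined).
    """
    if method not in ("alpha_shape", "convex_hull"):
        raise ValueError(f"unknown area method {method!r}")
    if alpha <= 0:
        raise ValueError("alpha must be positive (mm)")
    coords = np.array([s.coords for s in sites], dtype=float).reshape(-1, 3)
    if coords.shape[0] < 3:
        warnings.warn("fewer than 3 sites; area set to 0", DegenerateMapWarning)
        return 0.0
    flat = _project_to_plane(coords)
    try:
        if method == "convex_hull":
            return float(ConvexHull(flat).volume)  # 2-D "volume" is the area
        return _alpha_shape_area(flat, alpha)
    except QhullError:
        warnings.warn("collinear/degenerate sites; area set to 0", DegenerateMapWarning)
        return 0.0


def mirror_hemisphere(
    coords: np.ndarray, hemisphere: str, onto: str = "left"
) -> np.ndarray:
    """Mirror coordinates from ``hemisphere`` onto the canonical side.

    Flips the medio-lateral axis (X -> -X) when the stimulated hemisphere
    differs from ``onto``; |X| (laterality), Y and Z are preserved, so
    pooled cohorts share one sign convention.
    """
    coords = np.asarray(coords, dtype=float)
    for name, value in (("hemisphere", hemisphere), ("onto", onto)):
        if value not in ("left", "right"):
            raise ValueError(f"{name} must be 'left' or 'right', got {value!r}")
    if hemisphere != onto:
        flipped = coords.copy()
        flipped[..., 0] *= -1.0
        return flipped
    return coords


def summarize_map(
    muscle: str,
    meps: Sequence[MepRecord],
    coords_by_stim: pd.DataFrame,
    method: Literal["alpha_shape", "convex_hull"] = "alpha_shape",
    alpha: float = DEFAULT_ALPHA_MM,
) -> MotorMap:
    """Join retained MEPs to stimulation coordinates and summarise the map.

    ``coords_by_stim`` must be indexed by (or contain a column) ``stim_id``
    with columns x/y/z in mm.  A session with zero accepted MEPs yields a
    map flagged ``no_meps`` whose features are missing outcomes downstream.
    """
    df = coords_by_stim
    if "stim_id" in df.columns:
        df = df.set_index("stim_id")
    sites: list[MapSite] = []
    for r in meps:
        if not r.accepted:
            continue
        if r.stim_id not in df.index:
            raise KeyError(f"stimulation {r.stim_id} has no coordinates")
        row = df.loc[r.stim_id]
        sites.append(MapSite((float(row["x"]), float(row["y"]), float(row["z"])), r.peak_to_peak))
    if not sites:
        return MotorMap(muscle, [], cog=None, area_mm2=np.nan, n_sites=0, flags=["no_meps"])
    cog = compute_cog(sites)
    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DegenerateMapWarning)
        area = compute_area(sites, method=method, alpha=alpha)
        if any(issubclass(w.category, DegenerateMapWarning) for w in caught):
            flags.append("degenerate_area")
    return MotorMap(muscle, sites, cog=cog, area_mm2=area, n_sites=len(sites), flags=flags)


def maps_to_frame(maps: dict[str, dict[str, MotorMap]]) -> pd.DataFrame:
    """Nested {subject: {muscle: MotorMap}} as the per-subject map table."""
    rows = []
    for subject, by_muscle in maps.items():
        for muscle, m in by_muscle.items():
            rows.append(
                {
                    "subject": subject,
                    "muscle": muscle,
                    "cog_x": np.nan if m.missing else m.cog[0],
                    "cog_y": np.nan if m.missing else m.cog[1],
                    "cog_z": np.nan if m.missing else m.cog[2],
                    "area_mm2": m.area_mm2,
                    "n_sites": m.n_sites,
                    "flags": ";".join(m.flags),
                }
            )
    return pd.DataFrame(rows)
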