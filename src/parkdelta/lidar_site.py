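"""Site characterisation and barrier porosity from classified point clouds.

Each monitoring site is profiled from an airborne-lidar point cloud
classified into ground / vegetation / building: within a disc around
the sensor the per-class footprint area and mean height above ground
are computed on a regular grid, and the distance and class of the
nearest road polyline are measured.  The roadside vegetation barrier's
porosity is proxied by its volumetric point density: for every point
the number of neighbours inside a small sphere is converted to
points/m³ and histogrammed; a higher modal density means a denser,
less porous stand.

Clouds are read from 4-column x,y,z,class delimited text.  Numeric
classes follow the LAS convention (2 = ground, 3/4/5 = vegetation,
6 = building, anything else = other); text labels are accepted as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely import wkt as shapely_wkt
from shapely.geometry import Point

from parkdelta.errors import ConfigurationError, InsufficientDataError

CLASSES = ("ground", "vegetation", "building", "other")

_LAS_CODE_MAP = {2: "ground", 3: "vegetation", 4: "vegetation",
                 5: "vegetation", 6: "building"}


@dataclass
class PointCloud:
    """Classified points in projected metric coordinates."""

    xyz: np.ndarray = field(repr=False)       # (n, 3) float
    classes: np.ndarray = field(repr=False)   # (n,) str from CLASSES

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.classes = np.asarray(self.classes, dtype=object)
        if not np.isfinite(self.xyz).all():
            raise ConfigurationError("point cloud contains non-finite coordinates")
        bad = set(self.classes) - set(CLASSES)
        if bad:
            raise ConfigurationError(f"unknown point classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.xyz)

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.xyz[mask], self.classes[mask])


@dataclass(frozen=True)
class SiteProfile:
    vegetation_area: float        # m²
    mean_crown_height: float      # m, over occupied vegetation cells
    building_area: float          # m²
    mean_building_height: float   # m
    radius: float
    cell: float


@dataclass
class DensityProfile:
    """Histogram of per-point volumetric density (points/m³)."""

    radius: float
    bin_edges: np.ndarray
    counts: np.ndarray
    densities: np.ndarray = field(repr=False)

    @property
    def modal_density(self) -> float:
        """Centre of the most populated histogram bin."""
        k = int(np.argmax(self.counts))
        return float((self.bin_edges[k] + self.bin_edges[k + 1]) / 2.0)


def map_las_classes(codes) -> np.ndarray:
    """Numeric LAS classification codes to the package's class labels."""
    return np.array([_LAS_CODE_MAP.get(int(c), "other") for c in codes], dtype=object)


def read_cloud_text(path, *, sep: str = ",") -> PointCloud:
    """Read an x,y,z,class delimited text cloud (header optional).

    The class column may hold LAS numeric codes or the text labels
    ground/vegetation/building/other.
    """
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str,
                     skip_blank_lines=True)
    # tolerate a header row
    try:
        float(df.iloc[0, 0])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    if df.shape[1] < 4:
        raise ConfigurationError("cloud text needs 4 columns: x,y,z,class")
    xyz = df.iloc[:, :3].astype(float).to_numpy()
    cls_raw = df.iloc[:, 3].str.strip()
    if cls_raw.str.fullmatch(r"-?\d+").all():
        classes = map_las_classes(cls_raw.astype(int))
    else:
        classes = cls_raw.to_numpy(dtype=object)
    return PointCloud(xyz, classes)


def read_roads_wkt(path) -> list[tuple[object, str]]:
    """Road polylines from a two-column text file: WKT;class (``;``-separated)."""
    roads = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            geom_txt, _, cls = line.rpartition(";")
            roads.append((shapely_wkt.loads(geom_txt.strip()), cls.strip()))
    if not roads:
        raise ConfigurationError(f"no road polylines in {path}")
    return roads


# ---------------------------------------------------------------------------

def clip(cloud: PointCloud, center=None, radius: float | None = None,
         polygon=None) -> PointCloud:
    """Points within a horizontal disc or a polygon (x–y only)."""
    if len(cloud) == 0:
        return cloud
    if polygon is not None:
        from shapely import points as shapely_points, contains

        pts = shapely_points(cloud.xyz[:, 0], cloud.xyz[:, 1])
        mask = contains(polygon.buffer(1e-9), pts)
        return cloud.subset(mask)
    if center is None or radius is None:
        raise ConfigurationError("clip needs either polygon or center+radius")
    d2 = ((cloud.xyz[:, :2] - np.asarray(center, dtype=float)) ** 2).sum(axis=1)
    return cloud.subset(d2 <= radius**2)


def site_profile(cloud: PointCloud, center, radius: float = 50.0,
                 cell: float = 1.0) -> SiteProfile:
    """Class areas and mean heights within a disc around the sensor.

    The disc is gridded at ``cell`` metres; a class occupies a cell when
    at least one of its points falls there, so class area = occupied
    cells × cell².  Heights are the per-cell maximum z of the class
    minus the ground reference (minimum ground-class elevation within
    the disc — sites are locally flat), averaged over occupied cells.
    """
    disc = clip(cloud, center=center, radius=radius)
    ground = disc.xyz[disc.classes == "ground"]
    if len(ground) == 0:
        raise InsufficientDataError("no ground reference points within the disc")
    z0 = float(ground[:, 2].min())

    def class_stats(name: str) -> tuple[float, float]:
        pts = disc.xyz[disc.classes == name]
        if len(pts) == 0:
            return 0.0, 0.0
        ij = np.floor((pts[:, :2] - np.asarray(center, dtype=float)) / cell).astype(int)
        cells: dict[tuple[int, int], float] = {}
        for (i, j), z in zip(map(tuple, ij), pts[:, 2]):
            key = (i, j)
            if key not in cells or z > cells[key]:
                cells[key] = z
        heights = np.array(list(cells.values())) - z0
        return len(cells) * cell * cell, float(heights.mean())

    veg_area, veg_h = class_stats("vegetation")
    bld_area, bld_h = class_stats("building")
    return SiteProfile(
        vegetation_area=veg_area,
        mean_crown_height=veg_h,
        building_area=bld_area,
        mean_building_height=bld_h,
        radius=radius,
        cell=cell,
    )


def nearest_road(point, roads: list[tuple[object, str]]) -> tuple[float, str]:
    """Distance (m) and class of the closest road polyline."""
    if not roads:
        raise ConfigurationError("empty road set")
    p = Point(point)
    best = min(roads, key=lambda rc: p.distance(rc[0]))
    return float(p.distance(best[0])), best[1]


# ---------------------------------------------------------------------------

def neighbor_counts(cloud: PointCloud, radius: float) -> np.ndarray:
    """Per-point neighbour count within a sphere, self excluded (k-d tree)."""
    tree = cKDTree(cloud.xyz)
    counts = tree.query_ball_point(cloud.xyz, r=radius, return_length=True)
    return np.asarray(counts, dtype=int) - 1  # query includes the point itself


def neighbor_counts_bruteforce(cloud: PointCloud, radius: float) -> np.ndarray:
    """Reference O(n²) neighbour count; any accelerated index must match it."""
    xyz = cloud.xyz
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= radius**2
    return within.sum(axis=1) - 1


def density_profile(cloud: PointCloud, neighborhood_radius: float = 1.0,
                    bins=30) -> DensityProfile:
    """Histogram of spherical-neighbourhood volumetric point density.

    Each point's neighbour count inside the sphere is divided by the
    sphere volume (4/3·π·r³) to give points/m³.  ``bins`` is either a
    bin count (edges from the data range) or explicit edges, which two
    profiles must share to be comparable.
    """
    if len(cloud) < 2:
        raise InsufficientDataError("density profile needs at least 2 points")
    counts = neighbor_counts(cloud, neighborhood_radius)
    volume = 4.0 / 3.0 * np.pi * neighborhood_radius**3
    densities = counts / volume
    hist, edges = np.histogram(densities, bins=bins)
    return DensityProfile(
        radius=neighborhood_radius,
        bin_edges=edges,
        counts=hist,
        densities=densities,
    )


def compare_barriers(profile_a: DensityProfile, profile_b: DensityProfile,
                     labels=("A", "B")) -> dict:
    """Porosity ordering of two barriers measured with identical bins.

    Higher modal volumetric density ⇒ denser stand ⇒ less porous.
    """
    if profile_a.radius != profile_b.radius or not np.array_equal(
        profile_a.bin_edges, profile_b.bin_edges
    ):
        raise ConfigurationError("profiles use different radii or bins")
    ma, mb = profile_a.modal_density, profile_b.modal_density
    if ma > mb:
        less_porous = labels[0]
    elif mb > ma:
        less_porous = labels[1]
    else:
        less_porous = None  # tie
    return {
        "modal_density": {labels[0]: ma, labels[1]: mb},
        "less_porous": less_porous,
        "tie": less_porous is None,
    }
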