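"""Per-triad predictor construction: geography, climate velocity, tree times.

Species ranges are sets of equal-area grid cells (a gridded stand-in for
polygon range maps: distances, areas, overlaps and centroids are all the
analysis needs).  Climate-change velocity follows the classic
temporal-rate-over-spatial-gradient definition: |dT/dt| / |grad T|, with
dT taken between the present and the Last Glacial Maximum (21,000 years
before present) so the result is in km/yr.

The assembled predictor table carries both raw and transformed columns.
Transformations mirror the modeling conventions: absolute values for
latitude, climate velocity and the introgression Z-score, then natural logs
of every variable except gene-tree discordance; geographic distance is
logged as ln(km + 1) so that sympatric pairs (distance 0) stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .introgression import DResult
from .trees import RootedTree, Triad, node_age, is_ultrametric, TreeValidationError

__all__ = [
    "GriddedRange",
    "ClimateGrid",
    "LGM_YEARS",
    "EARTH_RADIUS_KM",
    "MIN_GRADIENT",
    "haversine",
    "range_distance",
    "range_summary",
    "climate_velocity",
    "triad_times",
    "assemble_predictor_table",
    "load_ranges",
    "read_esri_ascii",
    "write_esri_ascii",
]

EARTH_RADIUS_KM = 6371.0
#: Years between the present and the Last Glacial Maximum.
LGM_YEARS = 21_000.0
#: Floor on the spatial temperature gradient (degC/km) to avoid division blow-up.
MIN_GRADIENT = 1e-6


@dataclass(frozen=True)
class GriddedRange:
    """A species range as a set of equal-area grid cells."""

    species: str
    cells: frozenset[str]
    centroids: Mapping[str, tuple[float, float]]  # cell_id -> (lat, lon)
    cell_area: float  # km^2, identical across cells on an equal-area grid

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError(f"{self.species}: empty range")
        missing = self.cells - set(self.centroids)
        if missing:
            raise ValueError(f"{self.species}: cells without centroids: {sorted(missing)}")

    @property
    def area(self) -> float:
        return len(self.cells) * self.cell_area

    @property
    def centroid(self) -> tuple[float, float]:
        pts = np.array([self.centroids[c] for c in sorted(self.cells)])
        lat, lon = pts.mean(axis=0)
        return float(lat), float(lon)

    def coords(self) -> np.ndarray:
        return np.array([self.centroids[c] for c in sorted(self.cells)])


def load_ranges(
    ranges_tsv: str, grid_tsv: str
) -> dict[str, GriddedRange]:
    """Read species->cell memberships plus the grid table.

    ``ranges_tsv`` has columns (species, cell_id); ``grid_tsv`` has columns
    (cell_id, lat, lon, area_km2).
    """
    grid = pd.read_csv(grid_tsv, sep="\t").set_index("cell_id")
    centroids = {c: (float(r["lat"]), float(r["lon"])) for c, r in grid.iterrows()}
    area = float(grid["area_km2"].iloc[0])
    memb = pd.read_csv(ranges_tsv, sep="\t")
    unknown = set(memb["cell_id"]) - set(grid.index)
    if unknown:
        raise ValueError(f"range cells not in grid: {sorted(unknown)[:5]}")
    out = {}
    for sp, sub in memb.groupby("species"):
        out[sp] = GriddedRange(
            species=sp,
            cells=frozenset(sub["cell_id"]),
            centroids=centroids,
            cell_area=area,
        )
    return out


def haversine(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance (km) between two (lat, lon) points in degrees."""
    for lat, lon in (a, b):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    la1, lo1, la2, lo2 = map(math.radians, (*a, *b))
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _pairwise_haversine(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    la1 = np.radians(x[:, 0])[:, None]
    lo1 = np.radians(x[:, 1])[:, None]
    la2 = np.radians(y[:, 0])[None, :]
    lo2 = np.radians(y[:, 1])[None, :]
    h = (
        np.sin((la2 - la1) / 2) ** 2
        + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def range_distance(r1: GriddedRange, r2: GriddedRange) -> float:
    """Closest edge-to-edge distance (km); 0 for overlapping or shared-cell ranges."""
    if r1.cells & r2.cells:
        return 0.0
    return float(_pairwise_haversine(r1.coords(), r2.coords()).min())


def range_summary(
    r1: GriddedRange, r2: GriddedRange
) -> tuple[float, float, float]:
    """(mean range size km^2, overlap km^2, mean absolute centroid latitude deg)."""
    mean_size = (r1.area + r2.area) / 2.0
    overlap = len(r1.cells & r2.cells) * r1.cell_area
    mean_abs_lat = (abs(r1.centroid[0]) + abs(r2.centroid[0])) / 2.0
    return mean_size, overlap, mean_abs_lat


@dataclass
class ClimateGrid:
    """Rectangular temperature grids for the present and the LGM.

    ``t_present`` and ``t_lgm`` are 2D arrays (NaN = missing);
    ``cell_ids`` is a parallel 2D object array naming each cell;
    ``spacing_km`` is the cell-to-cell distance on the equal-area grid.
    """

    t_present: np.ndarray
    t_lgm: np.ndarray
    cell_ids: np.ndarray
    spacing_km: float

    def __post_init__(self) -> None:
        if self.t_present.shape != self.t_lgm.shape or self.t_present.shape != self.cell_ids.shape:
            raise ValueError("present/LGM/cell_id grids must share a shape")
        if self.spacing_km <= 0:
            raise ValueError("spacing must be positive")


def climate_velocity(grid: ClimateGrid) -> tuple[dict[str, float], set[str]]:
    """Climate-change velocity (km/yr) per grid cell since the LGM.

    velocity = |T_present - T_LGM| / 21,000 yr  /  |grad T_present|

    where the spatial gradient is the Euclidean norm of central differences
    (one-sided on edges) in degC/km.  Gradients below ``MIN_GRADIENT`` are
    capped there; cells so capped are returned in the second element.
    Cells missing either epoch are skipped.
    """
    tp, tl = grid.t_present, grid.t_lgm
    if tp.shape[0] < 3 or tp.shape[1] < 3:
        raise ValueError("need at least a 3x3 grid for spatial gradients")
    gy, gx = np.gradient(tp, grid.spacing_km)
    gradient = np.sqrt(gx**2 + gy**2)
    capped_mask = gradient < MIN_GRADIENT
    gradient = np.maximum(gradient, MIN_GRADIENT)
    rate = np.abs(tp - tl) / LGM_YEARS  # degC / yr
    vel = rate / gradient  # km / yr
    out: dict[str, float] = {}
    capped: set[str] = set()
    for (i, j), cid in np.ndenumerate(grid.cell_ids):
        if math.isnan(tp[i, j]) or math.isnan(tl[i, j]) or math.isnan(vel[i, j]):
            continue
        out[str(cid)] = float(vel[i, j])
        if capped_mask[i, j]:
            capped.add(str(cid))
    return out, capped


def triad_times(tree: RootedTree, triad: Triad) -> tuple[float, float]:
    """(divergence time, internode length) in the tree's time units.

    The divergence time of the hybridizing pair is the triad's crown age:
    whichever pair the sign of D implicates (P2, P3 for positive, P1, P3
    for negative), its MRCA is the triad crown on an exclusive triad.  The
    internode is crown age minus sister-pair age.
    """
    if not is_ultrametric(tree):
        raise TreeValidationError("triad times require a dated (ultrametric) tree")
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = {triad.p1, triad.p2, triad.p3} - labels
    if missing:
        raise ValueError(f"triad species missing from tree: {sorted(missing)}")
    taxa = tree.taxon_namespace
    mrca_all = tree.mrca(taxa=[taxa.get_taxon(s) for s in triad.species])
    mrca_pair = tree.mrca(taxa=[taxa.get_taxon(s) for s in (triad.p1, triad.p2)])
    crown = node_age(tree, mrca_all)
    sister = node_age(tree, mrca_pair)
    return crown, crown - sister


def mean_velocity_over_ranges(
    r1: GriddedRange, r2: GriddedRange, velocity: Mapping[str, float]
) -> float:
    """Mean per-cell climate velocity over the union of the two ranges."""
    cells = sorted(r1.cells | r2.cells)
    vals = [velocity[c] for c in cells if c in velocity]
    return float(np.mean(vals)) if vals else math.nan


RAW_COLUMNS = [
    "z_signal",
    "geo_distance",
    "range_overlap",
    "mean_range_size",
    "mean_abs_centroid_latitude",
    "mean_climate_velocity",
    "divergence_time",
    "internode",
    "discordance",
]


def assemble_predictor_table(
    dresults: Mapping[str, DResult],
    triads: Sequence[Triad],
    ranges: Mapping[str, GriddedRange],
    velocity: Mapping[str, float],
    tree: RootedTree,
    discordance: Mapping[str, float],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the per-triad predictor table (raw and log-transformed columns).

    ``dresults`` and ``discordance`` are keyed by triad id; ``discordance``
    holds the gene-tree discordance ratio at the node subtending the sister
    pair.  Rows lacking any ingredient, or with a nonpositive value where a
    log is required, are returned separately with a reason.  Transformed
    columns are prefixed ``log_``; ``introgression_binary`` is 1 when the
    triad's two-sided p-value is below *alpha*.
    """
    rows, dropped = [], []

    def drop(tid: str, reason: str) -> None:
        dropped.append({"triad_id": tid, "reason": reason})

    for triad in triads:
        tid = triad.triad_id
        dres = dresults.get(tid)
        if dres is None or math.isnan(dres.z):
            drop(tid, "no D-statistic result")
            continue
        if triad.p1 not in ranges or triad.p2 not in ranges:
            drop(tid, "missing range data for sister pair")
            continue
        if tid not in discordance or math.isnan(discordance[tid]):
            drop(tid, "missing sister-node discordance")
            continue
        r1, r2 = ranges[triad.p1], ranges[triad.p2]
        dist = range_distance(r1, r2)
        mean_size, overlap, mean_abs_lat = range_summary(r1, r2)
        vel = mean_velocity_over_ranges(r1, r2, velocity)
        if math.isnan(vel):
            drop(tid, "no climate velocity over the pair's ranges")
            continue
        divergence, internode = triad_times(tree, triad)
        raw = {
            "triad_id": tid,
            "z_signal": abs(dres.z),
            "introgression_binary": int(dres.p < alpha),
            "geo_distance": dist,
            "range_overlap": overlap,
            "mean_range_size": mean_size,
            "mean_abs_centroid_latitude": mean_abs_lat,
            "mean_climate_velocity": abs(vel),
            "divergence_time": divergence,
            "internode": internode,
            "discordance": discordance[tid],
        }
        bad = [
            c
            for c in RAW_COLUMNS
            if c not in ("geo_distance", "range_overlap", "discordance")
            and raw[c] <= 0
        ]
        if bad:
            drop(tid, f"nonpositive value where log required: {bad}")
            continue
        for c in RAW_COLUMNS:
            if c == "discordance":
                continue
            if c == "geo_distance":
                raw["log_geo_distance"] = math.log(raw[c] + 1.0)
            elif c == "range_overlap":
                raw["log_range_overlap"] = math.log(raw[c] + 1.0) if raw[c] >= 0 else math.nan
            else:
                raw[f"log_{c}"] = math.log(raw[c])
        rows.append(raw)
    table = pd.DataFrame(rows)
    report = pd.DataFrame(dropped, columns=["triad_id", "reason"])
    return table, report


def read_esri_ascii(path: str) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII raster; returns (array, header) with NODATA as NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    arr = np.loadtxt(lines[n_header:])
    arr = np.atleast_2d(arr)
    if "nodata_value" in header:
        arr = np.where(arr == header["nodata_value"], np.nan, arr)
    expect = (int(header["nrows"]), int(header["ncols"]))
    if arr.shape != expect:
        raise ValueError(f"{path}: grid shape {arr.shape} != header {expect}")
    return arr, header


def write_esri_ascii(
    path: str,
    arr: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata: float = -9999.0,
) -> None:
    nrows, ncols = arr.shape
    body = np.where(np.isnan(arr), nodata, arr)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\nxllcorner {xllcorner}\n"
            f"yllcorner {yllcorner}\ncellsize {cellsize}\nNODATA_value {nodata}\n"
        )
        for row in body:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def climate_grid_from_rasters(
    present_path: str, lgm_path: str, spacing_km: float, cell_prefix: str = "c"
) -> ClimateGrid:
    """Build a ClimateGrid from a pair of ESRI ASCII rasters.

    Cells are named ``{prefix}{row}_{col}`` in array order (row 0 = top).
    """
    tp, hp = read_esri_ascii(present_path)
    tl, hl = read_esri_ascii(lgm_path)
    if tp.shape != tl.shape:
        raise ValueError("present and LGM rasters differ in shape")
    ids = np.empty(tp.shape, dtype=object)
    for (i, j), _ in np.ndenumerate(ids):
        ids[i, j] = f"{cell_prefix}{i}_{j}"
    return ClimateGrid(tp, tl, ids, spacing_km)
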