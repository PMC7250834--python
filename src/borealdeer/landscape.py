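"""Landscape composition around camera sites at multiple buffer radii.

Covariates come in two kinds: percent cover of raster landcover classes
(cell-centre-in-circle rule) and density of linear features (km of clipped
polyline per km^2 of buffer).  Rasters are integer class grids in a
projected metric CRS, read and written as ESRI ASCII grids; linear
features and sites travel as GeoJSON in the same CRS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, mapping, shape
from shapely.ops import unary_union

__all__ = [
    "LandscapeRaster",
    "LinearFeatures",
    "SiteCovariateTable",
    "extract_covariates",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_lines_geojson",
    "write_lines_geojson",
    "read_sites_geojson",
    "write_sites_geojson",
    "default_radii",
]

LINE_CLASSES = ("road", "OHV trail", "seismic line")


def default_radii(n: int = 20, lo: float = 250.0, hi: float = 5000.0) -> np.ndarray:
    """Default scale-of-effect radii: 20 values, 250 m to 5000 m, 250-m step."""
    return np.linspace(lo, hi, n)


@dataclass
class LandscapeRaster:
    """Classified landcover grid in projected metre coordinates.

    ``data`` is (nrows, ncols) with row 0 at the *top* (north), as in ESRI
    ASCII grids; ``origin`` is the lower-left corner (xll, yll).
    """

    data: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=int)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        codes = set(np.unique(self.data).tolist())
        missing = codes - set(self.legend)
        if missing:
            raise ValueError(f"raster codes missing from legend: {sorted(missing)}")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        nr, nc = self.data.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nc * self.cell_size, y0 + nr * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row, top-down) centres."""
        nr, nc = self.data.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ytop = y0 + nr * self.cell_size
        ys = ytop - (np.arange(nr) + 0.5) * self.cell_size
        return xs, ys


@dataclass
class LinearFeatures:
    """Polyline features (roads, OHV trails, seismic lines) in metres."""

    features: list[tuple[str, LineString]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cls, geom in self.features:
            if len(geom.coords) < 2:
                raise ValueError("line with fewer than 2 vertices")
            if not np.all(np.isfinite(np.asarray(geom.coords))):
                raise ValueError("non-finite line coordinates")

    def classes(self) -> list[str]:
        return sorted({c for c, _ in self.features})

    def total_length(self, cls: str | None = None) -> float:
        return sum(g.length for c, g in self.features if cls is None or c == cls)


@dataclass
class SiteCovariateTable:
    """Tidy site x radius x variable table of landscape summaries."""

    data: pd.DataFrame  # columns: site_id, radius_m, variable, value
    kinds: dict[str, str]  # variable -> "percent" | "density"
    standardized: bool = False
    scaling: pd.DataFrame | None = None  # variable, mean, sd used when standardized

    def radii(self) -> np.ndarray:
        return np.sort(self.data["radius_m"].unique())

    def variables(self) -> list[str]:
        return sorted(self.data["variable"].unique())

    def wide(self, radius: float) -> pd.DataFrame:
        """site x variable matrix at one radius (sites as index)."""
        sub = self.data[np.isclose(self.data["radius_m"], radius)]
        if sub.empty:
            raise KeyError(f"radius {radius} not present in table")
        return sub.pivot(index="site_id", columns="variable", values="value")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kinds: dict[str, str] | None = None) -> "SiteCovariateTable":
        df = pd.read_csv(path)
        need = {"site_id", "radius_m", "variable", "value"}
        if not need.issubset(df.columns):
            raise ValueError(f"covariate CSV must have columns {sorted(need)}")
        if kinds is None:
            kinds = {v: ("density" if v.startswith("density_") else "percent") for v in df["variable"].unique()}
        return cls(data=df, kinds=kinds)


def extract_covariates(
    raster: LandscapeRaster,
    lines: LinearFeatures,
    sites: pd.DataFrame,
    radii,
) -> SiteCovariateTable:
    """Summarise landscape composition in circular buffers around sites.

    Per raster class: percent of buffer area covered, by the cell-centre
    rule (a cell belongs to the buffer if its centre is within the radius).
    Per line class: clipped length / buffer area, in km/km^2.  Buffers
    extending past the raster edge are computed on the available cells with
    a warning, against the full circle's cell count.

    ``sites`` needs columns site_id, x, y.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size < 1 or np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    xs, ys = raster.cell_centers()
    xmin, ymin, xmax, ymax = raster.extent
    rmax = radii[-1]
    rows = []
    class_codes = sorted(raster.legend)
    # one merged geometry per line class: a single GEOS intersection per buffer
    merged_lines = {
        cls: unary_union([g for c, g in lines.features if c == cls]) for cls in lines.classes()
    }
    for _, site in sites.iterrows():
        sx, sy, sid = float(site["x"]), float(site["y"]), site["site_id"]
        if sx - rmax < xmin or sx + rmax > xmax or sy - rmax < ymin or sy + rmax > ymax:
            warnings.warn(
                f"site {sid}: buffer at {rmax:.0f} m exits the raster; "
                "percent cover computed on available cells",
                stacklevel=2,
            )
        dx2 = (xs - sx) ** 2
        dy2 = (ys - sy) ** 2
        # distance^2 from every cell centre, windowed to the largest buffer
        ci = np.where(dx2 <= rmax**2)[0]
        ri = np.where(dy2 <= rmax**2)[0]
        d2 = dy2[ri][:, None] + dx2[ci][None, :]
        vals = raster.data[np.ix_(ri, ci)]
        pt = Point(sx, sy)
        for r in radii:
            inside = d2 <= r * r
            n_in = int(inside.sum())
            if n_in == 0:
                for code in class_codes:
                    rows.append((sid, r, f"pct_{raster.legend[code]}", np.nan))
            else:
                v = vals[inside]
                counts = np.bincount(v, minlength=max(class_codes) + 1)
                for code in class_codes:
                    rows.append(
                        (sid, r, f"pct_{raster.legend[code]}", 100.0 * counts[code] / n_in)
                    )
            circle = pt.buffer(r, quad_segs=64)
            area_km2 = np.pi * (r / 1000.0) ** 2
            for cls, geom in merged_lines.items():
                clipped_m = geom.intersection(circle).length
                rows.append((sid, r, f"density_{cls}", (clipped_m / 1000.0) / area_km2))
    df = pd.DataFrame(rows, columns=["site_id", "radius_m", "variable", "value"])
    kinds = {f"pct_{name}": "percent" for name in raster.legend.values()}
    kinds.update({f"density_{cls}": "density" for cls in lines.classes()})
    return SiteCovariateTable(data=df, kinds=kinds)


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid, GeoJSON lines and sites


def write_ascii_grid(raster: LandscapeRaster, path, legend_path=None) -> None:
    """Write an ESRI ASCII grid (plus optional JSON legend side-car)."""
    nr, nc = raster.data.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {raster.origin[0]!r}\n")
        fh.write(f"yllcorner {raster.origin[1]!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write("NODATA_value -9999\n")
        for row in raster.data:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
    if legend_path is not None:
        with open(legend_path, "w") as fh:
            json.dump({str(k): v for k, v in raster.legend.items()}, fh, indent=1)


def read_ascii_grid(path, legend: dict[int, str] | None = None, legend_path=None) -> LandscapeRaster:
    """Read an ESRI ASCII grid; the legend comes from a mapping or side-car."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines_ = fh.read().split("\n")
    i = 0
    while i < len(lines_):
        parts = lines_[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key}")
    body = " ".join(lines_[i:]).split()
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if len(body) != nr * nc:
        raise ValueError(f"{path}: expected {nr * nc} cells, found {len(body)}")
    data = np.array(body, dtype=int).reshape(nr, nc)
    if legend is None:
        if legend_path is not None:
            with open(legend_path) as fh:
                legend = {int(k): v for k, v in json.load(fh).items()}
        else:
            legend = {int(c): f"class_{int(c)}" for c in np.unique(data)}
    return LandscapeRaster(
        data=data,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        legend=legend,
    )


def write_lines_geojson(lines: LinearFeatures, path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"class": cls}, "geometry": mapping(geom)}
            for cls, geom in lines.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_lines_geojson(path) -> LinearFeatures:
    with open(path) as fh:
        fc = json.load(fh)
    feats = []
    for f in fc.get("features", []):
        geom = shape(f["geometry"])
        if not isinstance(geom, LineString):
            raise ValueError(f"{path}: expected LineString geometries")
        feats.append((f["properties"].get("class", "road"), geom))
    return LinearFeatures(features=feats)


def write_sites_geojson(sites: pd.DataFrame, path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"site_id": str(row["site_id"])},
                "geometry": {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
            }
            for _, row in sites.iterrows()
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_sites_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for f in fc.get("features", []):
        x, y = f["geometry"]["coordinates"][:2]
        rows.append((f["properties"]["site_id"], float(x), float(y)))
    return pd.DataFrame(rows, columns=["site_id", "x", "y"])
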