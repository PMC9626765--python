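"""Inverse-distance-weighted interpolation over a lon/lat grid.

The interpolator predicts a concentration at an arbitrary point as the
weighted mean of the k nearest samples, with weights d^(-p) on the
great-circle (haversine) distance d.  It is an exact interpolator: a query
coincident with a sample (within ``eps_m`` metres) returns that sample's
value (mean over coincident ties), and every prediction is a convex
combination of sample values, hence bounded by the sample min and max.

Defaults p = 2 and k = 12 follow common GIS practice.  Surfaces are
node-centred regular grids; export is ESRI ASCII grid (.asc), which
requires square cells — ``GridSpec.square`` derives the latitude extent
from the longitude spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neighbors import BallTree

from .errors import EmptyGroupError, GrainRiskError, ParameterError
from .io_config import SampleRecord

EARTH_RADIUS_M = 6_371_008.8
NODATA_DEFAULT = -9999.0


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


@dataclass(frozen=True)
class GridSpec:
    """Node-centred regular lon/lat grid."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ParameterError("grid bounds must satisfy max > min on both axes")
        if self.n_cols < 2 or self.n_rows < 2:
            raise ParameterError("grid needs at least 2 columns and 2 rows")

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / (self.n_cols - 1)

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / (self.n_rows - 1)

    def lons(self) -> np.ndarray:
        return np.linspace(self.lon_min, self.lon_max, self.n_cols)

    def lats(self) -> np.ndarray:
        """Latitudes north-first (row 0 of a surface is the northern edge)."""
        return np.linspace(self.lat_max, self.lat_min, self.n_rows)

    @classmethod
    def square(cls, lon_min: float, lon_max: float, lat_min: float,
               n_cols: int, n_rows: int) -> "GridSpec":
        """Grid with equal lon/lat node spacing (ASCII-grid compatible).

        The latitude extent is derived from the longitude spacing, growing
        north from ``lat_min``.
        """
        dlon = (lon_max - lon_min) / (n_cols - 1)
        return cls(lon_min=lon_min, lon_max=lon_max, lat_min=lat_min,
                   lat_max=lat_min + dlon * (n_rows - 1),
                   n_cols=n_cols, n_rows=n_rows)


@dataclass
class Surface:
    """A raster of interpolated values; row 0 is the northernmost row."""

    spec: GridSpec
    values: np.ndarray
    element: str = ""
    crop: str = ""
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ParameterError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )


class IDWInterpolator(RegressorMixin, BaseEstimator):
    """Inverse-distance-weighted regressor on geographic coordinates.

    Parameters
    ----------
    power : float
        Distance decay exponent p (> 0); weights are d^(-p).
    n_neighbors : int
        Number of nearest samples contributing to each prediction
        (capped at the training size).
    eps_m : float
        Coincidence radius in metres: queries within this distance of a
        sample return the (mean) sample value exactly.
    """

    def __init__(self, power: float = 2.0, n_neighbors: int = 12,
                 eps_m: float = 1.0):
        self.power = power
        self.n_neighbors = n_neighbors
        self.eps_m = eps_m

    def fit(self, X, y):
        """Store samples. X is (n, 2) columns lon, lat; y the values."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ParameterError("X must be (n_samples, 2): lon, lat")
        if X.shape[0] == 0:
            raise EmptyGroupError("IDW needs at least one sample")
        if y.shape[0] != X.shape[0]:
            raise ParameterError("X and y length mismatch")
        if self.power <= 0:
            raise ParameterError(f"power must be positive, got {self.power}")
        if self.n_neighbors < 1:
            raise ParameterError("n_neighbors must be >= 1")
        self.X_ = X
        self.y_ = y
        # BallTree haversine metric expects (lat, lon) in radians
        self.tree_ = BallTree(np.radians(X[:, ::-1]), metric="haversine")
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not hasattr(self, "tree_"):
            raise GrainRiskError("IDWInterpolator is not fitted")
        k = min(self.n_neighbors, self.X_.shape[0])
        dist_rad, idx = self.tree_.query(np.radians(X[:, ::-1]), k=k)
        dist_m = dist_rad * EARTH_RADIUS_M
        z = self.y_[idx]
        with np.errstate(divide="ignore", over="ignore"):
            w = dist_m ** (-self.power)
        with np.errstate(invalid="ignore", over="ignore"):
            out = (w * z).sum(axis=1) / w.sum(axis=1)
        # exact at (near-)coincident points: mean over ties within eps_m
        coincident = dist_m < self.eps_m
        for i in np.nonzero(coincident.any(axis=1))[0]:
            out[i] = z[i][coincident[i]].mean()
        return out


def _fit_from_records(samples: Sequence[SampleRecord], element: str,
                      power: float, k: int) -> IDWInterpolator:
    if not samples:
        raise EmptyGroupError("IDW needs at least one sample")
    X = np.array([(r.lon, r.lat) for r in samples])
    y = np.array([r.concentration(element) for r in samples])
    return IDWInterpolator(power=power, n_neighbors=k).fit(X, y)


def idw_predict(point: tuple[float, float], samples: Sequence[SampleRecord],
                element: str, power: float = 2.0, k: int = 12) -> float:
    """Interpolated concentration at one (lon, lat) point."""
    est = _fit_from_records(samples, element, power, k)
    return float(est.predict(np.array([point]))[0])


def interpolate_surface(samples: Sequence[SampleRecord], element: str,
                        spec: GridSpec, power: float = 2.0,
                        k: int = 12, crop: str = "") -> Surface:
    """IDW prediction at every grid node."""
    est = _fit_from_records(samples, element, power, k)
    lon_grid, lat_grid = np.meshgrid(spec.lons(), spec.lats())
    pts = np.column_stack([lon_grid.ravel(), lat_grid.ravel()])
    values = est.predict(pts).reshape(spec.n_rows, spec.n_cols)
    return Surface(spec=spec, values=values, element=element, crop=crop)


def exceedance_surface(surface: Surface, limit: float) -> Surface:
    """0/1 indicator surface: 1 where the value strictly exceeds the limit."""
    vals = surface.values
    out = np.where(np.isnan(vals), np.nan, (vals > limit).astype(float))
    return Surface(spec=surface.spec, values=out,
                   element=surface.element, crop=surface.crop,
                   nodata=surface.nodata)


def write_ascii_grid(surface: Surface, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc), north row first, 6 significant digits.

    Requires square cells: the lon and lat node spacings must agree to 1
    part in 1e6 (use :meth:`GridSpec.square`).
    """
    spec = surface.spec
    cellsize = spec.dlon
    if abs(spec.dlat - cellsize) > 1e-6 * cellsize:
        raise ParameterError(
            f"ASCII grid requires square cells; dlon={spec.dlon!r} "
            f"dlat={spec.dlat!r} differ"
        )
    vals = np.where(np.isnan(surface.values), surface.nodata, surface.values)
    lines = [
        f"ncols {spec.n_cols}",
        f"nrows {spec.n_rows}",
        f"xllcorner {spec.lon_min - cellsize / 2:.10g}",
        f"yllcorner {spec.lat_min - cellsize / 2:.10g}",
        f"cellsize {cellsize:.10g}",
        f"NODATA_value {surface.nodata:.10g}",
    ]
    for row in vals:
        lines.append(" ".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path) -> Surface:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    text = Path(path).read_text().strip().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GrainRiskError(f"ASCII grid header missing {key}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cellsize = header["cellsize"]
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    values = np.loadtxt(text[data_start:], ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise GrainRiskError(
            f"ASCII grid body {values.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    lon_min = header["xllcorner"] + cellsize / 2
    lat_min = header["yllcorner"] + cellsize / 2
    spec = GridSpec(
        lon_min=lon_min,
        lon_max=lon_min + cellsize * (n_cols - 1),
        lat_min=lat_min,
        lat_max=lat_min + cellsize * (n_rows - 1),
        n_cols=n_cols,
        n_rows=n_rows,
    )
    values = np.where(values == nodata, np.nan, values)
    return Surface(spec=spec, values=values, nodata=nodata)


def plot_surface(surface: Surface, path: str | Path, title: str = "") -> None:
    """Optional PNG heat map of a surface (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = surface.spec
    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(
        surface.values,
        extent=(spec.lon_min, spec.lon_max, spec.lat_min, spec.lat_max),
        origin="upper",
        aspect="auto",
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label="mg/kg")
    ax.set_xlabel("longitude (deg E)")
    ax.set_ylabel("latitude (deg N)")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
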