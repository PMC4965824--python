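"""3D facies classification and predictive biomass mapping.

The two stratigraphic surfaces that bound the biogeochemical facies —
the Hanford-Ringold contact (top of the oxidized facies) and the redox
transition — are interpolated from well-log picks by inverse distance
weighting. Combining the surfaces classifies a regular 3D grid into
facies, and per-facies biomass statistics (log10 16S copies per gram,
computed from sample metadata) are then painted onto the grid either
deterministically (facies mean) or stochastically (normal draws in
log10 space).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FACIES_CODES, SampleMetadata, ValidationError, WellLog

#: Integer facies codes used on grids.
EXCLUDED = "hanford_excluded"
GRID_FACIES = (EXCLUDED, "oxidized", "transition", "reduced")


@dataclass(frozen=True)
class Surface:
    """Inverse-distance-weighted elevation surface.

    Exact at its control points: evaluating at a control (x, y) returns
    that point's elevation regardless of the power parameter.
    """

    points: np.ndarray  # (n, 3) of x, y, elevation
    power: float = 2.0

    def __call__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shape = np.broadcast(x, y).shape
        xf = np.broadcast_to(x, shape).ravel()
        yf = np.broadcast_to(y, shape).ravel()
        px, py, pz = self.points.T
        d2 = (xf[:, None] - px[None, :]) ** 2 + (yf[:, None] - py[None, :]) ** 2
        out = np.empty(len(xf))
        at_point = d2 <= 1e-24
        hit = at_point.any(axis=1)
        if hit.any():
            out[hit] = pz[np.argmax(at_point[hit], axis=1)]
        free = ~hit
        if free.any():
            w = d2[free] ** (-self.power / 2.0)
            out[free] = (w @ pz) / w.sum(axis=1)
        return out.reshape(shape) if shape else float(out[0])


def idw_surface(control_points: Sequence[Sequence[float]], power: float = 2.0) -> Surface:
    """Build an IDW surface from (x, y, elevation) control points."""
    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 1:
        raise ValidationError("control points must be an (n, 3) array of x, y, z")
    xy = pts[:, :2]
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.allclose(xy[i], xy[j]) and pts[i, 2] != pts[j, 2]:
                raise ValidationError(
                    f"duplicate plan position {tuple(xy[i])} with different elevations"
                )
    return Surface(points=pts, power=float(power))


def surfaces_from_well_logs(
    logs: Sequence[WellLog], power: float = 2.0
) -> tuple[Surface, Surface]:
    """Contact and transition surfaces interpolated from well logs."""
    contact = idw_surface([(w.x_m, w.y_m, w.hr_contact_elev_m) for w in logs], power)
    transition = idw_surface([(w.x_m, w.y_m, w.transition_elev_m) for w in logs], power)
    return contact, transition


@dataclass(frozen=True)
class GridSpec:
    """Regular 3D grid; cells are addressed by their centers."""

    x0: float
    x1: float
    y0: float
    y1: float
    z0: float
    z1: float
    dx: float
    dy: float
    dz: float

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0 and self.z1 > self.z0):
            raise ValidationError("grid extents must be increasing")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValidationError("grid resolutions must be positive")

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xc = np.arange(self.x0 + self.dx / 2, self.x1, self.dx)
        yc = np.arange(self.y0 + self.dy / 2, self.y1, self.dy)
        zc = np.arange(self.z0 + self.dz / 2, self.z1, self.dz)
        return xc, yc, zc


@dataclass
class FaciesGrid:
    """Facies codes (and optionally log10 biomass) on a regular grid.

    ``facies`` holds indices into GRID_FACIES with shape (nx, ny, nz);
    ``log10_copies_per_g`` is NaN wherever the facies is excluded.
    """

    spec: GridSpec
    facies: np.ndarray
    log10_copies_per_g: np.ndarray | None = None

    def facies_names(self) -> np.ndarray:
        return np.asarray(GRID_FACIES, dtype=object)[self.facies]

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.facies == k).sum()) for k, name in enumerate(GRID_FACIES)
        }

    def to_frame(self) -> pd.DataFrame:
        xc, yc, zc = self.spec.centers()
        X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
        biomass = (
            self.log10_copies_per_g
            if self.log10_copies_per_g is not None
            else np.full(self.facies.shape, np.nan)
        )
        return pd.DataFrame(
            {
                "x": X.ravel(),
                "y": Y.ravel(),
                "z": Z.ravel(),
                "facies": self.facies_names().ravel(),
                "log10_copies_per_g": biomass.ravel(),
            }
        )


def classify_facies(
    grid_spec: GridSpec,
    contact_surface: Surface,
    transition_surface: Surface,
    band_halfwidth: float = 0.25,
) -> FaciesGrid:
    """Classify every grid cell into a biogeochemical facies.

    With contact elevation C(x,y), transition elevation T(x,y) and band
    half-width h: cells above C are excluded (coarse formation above the
    unconformity, outside the facies model); cells within h of T are
    transition; cells between the band and C are oxidized; cells below
    the band are reduced. The partition is exhaustive and exclusive; the
    band takes precedence where it reaches the contact.
    """
    if band_halfwidth < 0:
        raise ValidationError("band halfwidth must be >= 0")
    xc, yc, zc = grid_spec.centers()
    X, Y = np.meshgrid(xc, yc, indexing="ij")
    C = contact_surface(X, Y)
    T = transition_surface(X, Y)
    bad = C <= T
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"surfaces cross at (x={X[i, j]:.2f}, y={Y[i, j]:.2f}): "
            f"contact {C[i, j]:.3f} <= transition {T[i, j]:.3f}"
        )
    Z = zc[None, None, :]
    C3 = C[:, :, None]
    T3 = T[:, :, None]
    codes = np.empty((len(xc), len(yc), len(zc)), dtype=np.int8)
    codes[:] = GRID_FACIES.index("reduced")
    codes[np.abs(Z - T3) <= band_halfwidth] = GRID_FACIES.index("transition")
    codes[(Z > T3 + band_halfwidth) & (Z <= C3)] = GRID_FACIES.index("oxidized")
    codes[Z > C3] = GRID_FACIES.index(EXCLUDED)
    return FaciesGrid(spec=grid_spec, facies=codes)


def per_facies_biomass_stats(metadata: SampleMetadata) -> dict[str, tuple[float, float]]:
    """Mean and sd of log10(copies per gram) within each facies."""
    copies = metadata.env("copies_per_g")
    if (copies <= 0).any():
        raise ValidationError("copies_per_g must be positive to take log10")
    log10 = np.log10(copies.to_numpy(dtype=float))
    facies = metadata.facies().to_numpy()
    out = {}
    for code in FACIES_CODES:
        vals = log10[facies == code]
        if len(vals) == 0:
            raise ValidationError(f"no samples in facies {code!r}")
        out[code] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    return out


def assign_biomass(
    grid: FaciesGrid,
    per_facies_stats: dict[str, tuple[float, float]],
    mode: str = "deterministic",
    seed: int = 0,
) -> FaciesGrid:
    """Paint per-cell log10 biomass from per-facies statistics.

    Deterministic mode writes each facies' mean; stochastic mode draws
    cells independently from Normal(mean, sd) in log10 space. Excluded
    cells carry no value.
    """
    missing = [c for c in FACIES_CODES if c not in per_facies_stats]
    if missing:
        raise ValidationError(f"missing facies statistics for {missing}")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    biomass = np.full(grid.facies.shape, np.nan)
    for code in FACIES_CODES:
        mask = grid.facies == GRID_FACIES.index(code)
        mean, sd = per_facies_stats[code]
        if mode == "deterministic":
            biomass[mask] = mean
        else:
            biomass[mask] = rng.normal(mean, sd, size=int(mask.sum()))
    return FaciesGrid(spec=grid.spec, facies=grid.facies,
                      log10_copies_per_g=biomass)


def check_vertical_ordering(grid: FaciesGrid) -> None:
    """Assert oxidized above transition above reduced in every column."""
    order = {"hanford_excluded": 3, "oxidized": 2, "transition": 1, "reduced": 0}
    ranks = np.vectorize(order.get)(grid.facies_names())
    # z ascends along the last axis, so ranks must be non-decreasing with z
    if not (np.diff(ranks, axis=2) >= 0).all():
        raise AssertionError("facies vertical ordering violated")


def map_pipeline(
    well_logs: Sequence[WellLog],
    metadata: SampleMetadata,
    grid_spec: GridSpec,
    band_halfwidth: float = 0.25,
    power: float = 2.0,
    mode: str = "deterministic",
    seed: int = 0,
    out_path=None,
) -> FaciesGrid:
    """End-to-end facies/biomass map from well logs and sample metadata."""
    contact, transition = surfaces_from_well_logs(well_logs, power=power)
    grid = classify_facies(grid_spec, contact, transition, band_halfwidth)
    stats = per_facies_biomass_stats(metadata)
    grid = assign_biomass(grid, stats, mode=mode, seed=seed)
    check_vertical_ordering(grid)
    if out_path is not None:
        from .io import write_grid

        write_grid(grid.to_frame(), out_path)
    return grid
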