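"""Per-species equal-area projection for range-metric computation.

Range statistics (convex-hull area, grid-cell occupancy) must be computed
in km², so longitude/latitude points are projected with a Lambert
cylindrical equal-area projection recentred on each species' own points:
the central meridian is the mean longitude and the standard parallel the
mean latitude of the inputs. Recentring keeps areal distortion small over
the extent of a single species' range while remaining exactly equal-area
everywhere.

Forward equations (spherical, radius R in km):

    x = R * cos(phi_s) * (lambda - lambda_0)
    y = R * sin(phi)   / cos(phi_s)

with angles in radians. The Jacobian of (x, y) with respect to spherical
surface area is identically 1, so planar areas in (x, y) are true areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088

# Standard parallels very close to the poles make cos(phi_s) -> 0 and the
# projection numerically useless; clamp well short of that.
_MAX_STANDARD_PARALLEL = 89.0


@dataclass(frozen=True)
class ProjectionContext:
    """Cylindrical equal-area projection recentred on a species' points.

    Parameters
    ----------
    central_meridian
        Longitude of the projection centre, degrees.
    standard_parallel
        Latitude of true scale, degrees; clamped to ±89°.
    """

    central_meridian: float
    standard_parallel: float

    def __post_init__(self):
        clamped = float(
            np.clip(self.standard_parallel, -_MAX_STANDARD_PARALLEL, _MAX_STANDARD_PARALLEL)
        )
        object.__setattr__(self, "standard_parallel", clamped)
        object.__setattr__(self, "central_meridian", float(self.central_meridian))

    @classmethod
    def from_points(cls, lons, lats) -> "ProjectionContext":
        """Build a context from the arithmetic means of the input coordinates."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        if lons.size == 0:
            return cls(0.0, 0.0)
        return cls(float(lons.mean()), float(lats.mean()))

    def forward(self, lons, lats) -> tuple[np.ndarray, np.ndarray]:
        """Project lon/lat degrees to (x, y) in km."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        cos_sp = np.cos(np.radians(self.standard_parallel))
        # wrap the meridian offset into [-180, 180) so ranges near the
        # antimeridian do not explode in x
        dlon = (lons - self.central_meridian + 180.0) % 360.0 - 180.0
        x = EARTH_RADIUS_KM * cos_sp * np.radians(dlon)
        y = EARTH_RADIUS_KM * np.sin(np.radians(lats)) / cos_sp
        return x, y

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Back-project (x, y) km to lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        cos_sp = np.cos(np.radians(self.standard_parallel))
        lon = self.central_meridian + np.degrees(x / (EARTH_RADIUS_KM * cos_sp))
        sin_lat = np.clip(y * cos_sp / EARTH_RADIUS_KM, -1.0, 1.0)
        lat = np.degrees(np.arcsin(sin_lat))
        lon = (lon + 180.0) % 360.0 - 180.0
        return lon, lat
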