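"""Crypt basal-membrane geometry.

The crypt surface is the union of a hemispherical bottom cap (radius ``R``,
centred at the origin, occupying ``z < 0``) and a cylinder of the same radius
for ``z >= 0``; the crypt axis is ``+z`` (bottom pole at ``(0, 0, -R)``,
villus direction up).  The axial position ``P`` of a point is the geodesic
(meridian-arc) distance from the bottom pole, in cell radii:

* on the cap, ``P = R * theta`` where ``theta`` is the polar angle from the
  downward axis;
* on the cylinder, ``P = R * pi/2 + z``.

With ``R = 4`` the cap equator sits at ``P = 2π ≈ 6.28`` and successive cell
rows at the crypt bottom are labelled by ``P ≈ 1, 2, 3, …``.
"""

from __future__ import annotations

import numpy as np

from .params import GeometryParams

__all__ = [
    "CryptSurface",
    "axial_position",
    "project_to_surface",
    "has_substrate_contact",
]


class CryptSurface:
    """Fixed cylinder + hemispherical-cap basal membrane."""

    def __init__(self, params: GeometryParams | None = None):
        self.params = params or GeometryParams()
        self.R = float(self.params.cap_radius)
        self.exit_position = float(self.params.exit_position)
        #: deterministic fallback directions for degenerate projections
        self._cap_fallback = np.array([0.0, 0.0, -1.0])
        self._cyl_fallback = np.array([1.0, 0.0, 0.0])

    # ------------------------------------------------------------------
    def axial_position(self, points: np.ndarray) -> np.ndarray:
        """Geodesic distance P from the bottom pole, in cell radii.

        Off-surface points are first projected onto the surface.
        Accepts a single point ``(3,)`` or an array ``(N, 3)``.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q = self._project(pts)
        z = q[:, 2]
        P = np.empty(len(q))
        on_cap = z < 0
        if on_cap.any():
            # polar angle from the downward axis: cos(theta) = -z / R
            c = np.clip(-z[on_cap] / self.R, -1.0, 1.0)
            P[on_cap] = self.R * np.arccos(c)
        if (~on_cap).any():
            P[~on_cap] = self.R * np.pi / 2.0 + z[~on_cap]
        if np.asarray(points).ndim == 1:
            return float(P[0])
        return P

    def axial_position_on_surface(self, points: np.ndarray) -> np.ndarray:
        """P for points already lying on the surface (skips projection)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z = pts[:, 2]
        cap = z < 0
        P = np.empty(len(pts))
        P[cap] = self.R * np.arccos(np.clip(-z[cap] / self.R, -1.0, 1.0))
        P[~cap] = self.R * np.pi / 2.0 + z[~cap]
        return P

    # ------------------------------------------------------------------
    def project_to_surface(self, points: np.ndarray) -> np.ndarray:
        """Nearest point on the surface; idempotent for surface points."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        q = self._project(np.atleast_2d(pts))
        return q[0] if single else q

    def _project(self, pts: np.ndarray) -> np.ndarray:
        q = np.array(pts, dtype=float, copy=True)
        z = pts[:, 2]
        cap = z < 0
        # hemisphere: radial projection from the sphere centre (origin)
        if cap.any():
            p = pts[cap]
            norm = np.linalg.norm(p, axis=1)
            bad = norm < 1e-12
            if bad.any():
                p = p.copy()
                p[bad] = self._cap_fallback
                norm = np.linalg.norm(p, axis=1)
            q[cap] = p * (self.R / norm)[:, None]
        # cylinder: clamp radial coordinate, keep height
        cyl = ~cap
        if cyl.any():
            p = pts[cyl]
            rho = np.hypot(p[:, 0], p[:, 1])
            bad = rho < 1e-12
            out = p.copy()
            if bad.any():
                out[bad, 0] = self.R * self._cyl_fallback[0]
                out[bad, 1] = self.R * self._cyl_fallback[1]
            good = ~bad
            scale = self.R / rho[good]
            out[good, 0] = p[good, 0] * scale
            out[good, 1] = p[good, 1] * scale
            q[cyl] = out
        return q

    # ------------------------------------------------------------------
    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance from each point to its surface projection."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q = self._project(pts)
        d = np.linalg.norm(pts - q, axis=1)
        if np.asarray(points).ndim == 1:
            return float(d[0])
        return d

    # ------------------------------------------------------------------
    def normals(self, points: np.ndarray) -> np.ndarray:
        """Outward surface normal at the projection of each point."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q = self._project(pts)
        n = np.empty_like(q)
        cap = q[:, 2] < 0
        n[cap] = q[cap] / self.R
        if (~cap).any():
            p = q[~cap]
            rho = np.hypot(p[:, 0], p[:, 1])
            rho = np.where(rho < 1e-12, 1.0, rho)
            n[~cap, 0] = p[:, 0] / rho
            n[~cap, 1] = p[:, 1] / rho
            n[~cap, 2] = 0.0
        return n

    def meridian_up(self, points: np.ndarray) -> np.ndarray:
        """Unit tangent along the meridian toward increasing P.

        Zero at the bottom pole, where the direction is undefined.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q = self._project(pts)
        t = np.zeros_like(q)
        cap = q[:, 2] < 0
        if cap.any():
            n = q[cap] / self.R
            zhat = np.array([0.0, 0.0, 1.0])
            raw = zhat[None, :] - n * n[:, 2:3]
            norm = np.linalg.norm(raw, axis=1)
            ok = norm > 1e-9
            raw[ok] /= norm[ok, None]
            raw[~ok] = 0.0  # at/near the pole
            t[cap] = raw
        t[~cap] = np.array([0.0, 0.0, 1.0])
        if np.asarray(points).ndim == 1:
            return t[0]
        return t

    def tangent_basis(self, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal tangent basis (e1, e2) at the projection of *point*."""
        n = self.normals(point[None, :])[0]
        ref = np.array([0.0, 0.0, 1.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(n, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2


# ---------------------------------------------------------------------------
# functional wrappers


def axial_position(point: np.ndarray, surface: CryptSurface):
    return surface.axial_position(point)


def project_to_surface(point: np.ndarray, surface: CryptSurface):
    return surface.project_to_surface(point)


def has_substrate_contact(cell, surface: CryptSurface, tolerance: float = 0.1):
    """True iff the cell centre lies within ``radius + tolerance`` of the
    surface (boundary inclusive)."""
    d = surface.surface_distance(np.asarray(cell.position, dtype=float))
    return bool(d <= cell.radius + tolerance + 1e-12)
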