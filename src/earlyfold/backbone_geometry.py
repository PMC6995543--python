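"""Backbone torsion angles, peptide-plane aperture angles and the
pentapeptide radius of curvature.

These are the geometric primitives behind the elliptical early-stage path:
ln(R) of a five-residue fragment is a second-degree polynomial in the
aperture angle V between adjacent peptide-bond planes, and the (phi, psi)
points of fragments lying on that idealized relationship trace an ellipse
on the Ramachandran map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, NoDihedralsError
from .structure_io import DomainStructure

_EPS = 1e-12


def _wrap_deg(x: float) -> float:
    """Wrap an angle into (-180, 180]."""
    w = ((x + 180.0) % 360.0) - 180.0
    if w <= -180.0:
        w = 180.0
    return w


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of four points, degrees in (-180, 180].

    IUPAC sign convention: cis = 0, trans = 180; positive for a clockwise
    rotation of the far bond when sighting down p2->p3.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise DegenerateGeometryError("zero-length bond vector")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("collinear atoms: torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = -float(np.dot(m1, n2))
    return _wrap_deg(np.degrees(np.arctan2(y, x)))


@dataclass
class DihedralSeries:
    """Per-residue phi/psi in degrees; NaN marks undefined positions."""

    phi: np.ndarray
    psi: np.ndarray

    def defined(self) -> np.ndarray:
        """Boolean mask of residues with both angles defined."""
        return ~(np.isnan(self.phi) | np.isnan(self.psi))


def _consecutive(domain: DomainStructure, i: int, j: int) -> bool:
    """True if residues i..j (0-based) are complete and sequence-contiguous."""
    res = domain.residues
    for k in range(i, j + 1):
        if k < 0 or k >= len(res) or not res[k].complete:
            return False
    return all(res[k + 1].seq_num - res[k].seq_num == 1 for k in range(i, j))


def compute_dihedrals(domain: DomainStructure) -> DihedralSeries:
    """Phi/psi for every residue of a domain.

    phi(i) uses C(i-1), N(i), CA(i), C(i); psi(i) uses N(i), CA(i), C(i),
    N(i+1).  An angle is undefined (NaN) wherever a needed atom is missing
    or the chain is broken.
    """
    n = len(domain)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    res = domain.residues
    for i in range(n):
        if i > 0 and _consecutive(domain, i - 1, i):
            phi[i] = dihedral(
                res[i - 1].coords_C, res[i].coords_N, res[i].coords_CA, res[i].coords_C
            )
        if i < n - 1 and _consecutive(domain, i, i + 1):
            psi[i] = dihedral(
                res[i].coords_N, res[i].coords_CA, res[i].coords_C, res[i + 1].coords_N
            )
    if np.all(np.isnan(phi)) and np.all(np.isnan(psi)):
        raise NoDihedralsError(f"no dihedrals computable for {domain.id}")
    return DihedralSeries(phi=phi, psi=psi)


def _peptide_plane_normal(res_a, res_b) -> np.ndarray:
    """Unit normal of the peptide-bond plane CA(a)-C(a)-N(b)."""
    v1 = res_a.coords_C - res_a.coords_CA
    v2 = res_b.coords_N - res_a.coords_C
    nvec = np.cross(v1, v2)
    norm = np.linalg.norm(nvec)
    if norm < _EPS:
        raise DegenerateGeometryError("degenerate peptide plane")
    return nvec / norm


def aperture_angle(domain: DomainStructure, i: int) -> float:
    """Angle V between peptide-bond planes i->i+1 and i+1->i+2, degrees.

    ``i`` is the 1-based residue index of the first residue.  The result is
    folded into [0, 180] (the relationship ln(R) = f(V) carries no sign).
    """
    k = i - 1
    if not _consecutive(domain, k, k + 2):
        raise DegenerateGeometryError(
            f"undefined aperture at residue {i}: missing atoms or chain break"
        )
    res = domain.residues
    n1 = _peptide_plane_normal(res[k], res[k + 1])
    n2 = _peptide_plane_normal(res[k + 1], res[k + 2])
    c = float(np.clip(np.dot(n1, n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def _circle_fit_2d(xy: np.ndarray) -> tuple[float, float]:
    """Algebraic least-squares circle fit; returns (radius, rms residual).

    Exact for points lying on a circle.  Raises on collinear input.
    """
    x, y = xy[:, 0], xy[:, 1]
    centered = xy - xy.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] < _EPS or s[1] < 1e-9 * s[0]:
        raise DegenerateGeometryError("collinear projection")
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    rhs = x * x + y * y
    sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise DegenerateGeometryError("circle fit collapsed")
    r = float(np.sqrt(r2))
    resid = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - r) ** 2)))
    return r, resid


def curvature_radius(ca_coords) -> float:
    """Radius of curvature of 5 consecutive CA positions, in Angstrom.

    The points are projected onto the plane orthogonal to one of their
    principal axes and fitted with a least-squares circle; among the three
    principal-axis projections the one with the smallest circle residual
    wins.  This is exact both for coplanar circular arcs (projecting out
    the plane normal) and for ideal helices (projecting out the helix
    axis).  Collinear traces return +inf.
    """
    pts = np.asarray(ca_coords, dtype=float)
    if pts.shape != (5, 3):
        raise ValueError("curvature_radius expects exactly 5 CA coordinates")
    for a in range(5):
        for b in range(a + 1, 5):
            if np.linalg.norm(pts[a] - pts[b]) < 1e-9:
                raise DegenerateGeometryError("duplicate CA points")
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9 * max(s[0], _EPS):
        return float("inf")
    axes = list(vt)
    # Second differences are perpendicular to the axis of a uniform helix
    # and coplanar with a circular arc: their smallest singular direction
    # is the best projection axis for both ideal cases.
    second = np.diff(pts, n=2, axis=0)
    if np.linalg.norm(second) > _EPS:
        _, s2, vt2 = np.linalg.svd(second)
        axes.append(vt2[-1])
    best_r, best_resid = float("inf"), float("inf")
    for axis in axes:
        helper = np.eye(3)[int(np.argmin(np.abs(axis)))]
        b1 = np.cross(axis, helper)
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(axis, b1)
        proj = centered @ np.column_stack([b1, b2])
        try:
            r, resid = _circle_fit_2d(proj)
        except DegenerateGeometryError:
            continue
        if resid < best_resid:
            best_r, best_resid = r, resid
    return best_r


@dataclass
class CurvaturePoint:
    """One pentapeptide observation feeding the ellipse derivation."""

    lnR: float
    V: float
    phi: float | None = None
    psi: float | None = None


@dataclass
class PolynomialFit:
    a: float
    b: float
    c: float
    rms: float

    def __call__(self, v):
        return self.a * np.asarray(v) ** 2 + self.b * np.asarray(v) + self.c


def lnR_polynomial_fit(points: list[CurvaturePoint]) -> PolynomialFit:
    """Least-squares fit of lnR = a V^2 + b V + c over finite points."""
    usable = [p for p in points if np.isfinite(p.lnR)]
    vs = np.array([p.V for p in usable])
    ys = np.array([p.lnR for p in usable])
    if len(usable) < 3 or len(np.unique(np.round(vs, 12))) < 3:
        raise ValueError("underdetermined: need >= 3 points with distinct V")
    coeffs = np.polyfit(vs, ys, 2)
    resid = ys - np.polyval(coeffs, vs)
    return PolynomialFit(*map(float, coeffs), rms=float(np.sqrt(np.mean(resid**2))))


def curvature_profile(domain: DomainStructure) -> list[CurvaturePoint]:
    """All pentapeptide (lnR, V) observations of a domain.

    Each window of five consecutive complete residues contributes one
    point: R from the five CA positions, V from the central pair of
    peptide planes, and the central residue's (phi, psi) for the ellipse
    fit downstream.
    """
    series = compute_dihedrals(domain)
    res = domain.residues
    out: list[CurvaturePoint] = []
    for i in range(len(res) - 4):
        if not _consecutive(domain, i, i + 4):
            continue
        r = curvature_radius(np.array([res[k].coords_CA for k in range(i, i + 5)]))
        v = aperture_angle(domain, i + 2)
        mid = i + 2
        phi = series.phi[mid] if not np.isnan(series.phi[mid]) else None
        psi = series.psi[mid] if not np.isnan(series.psi[mid]) else None
        out.append(
            CurvaturePoint(
                lnR=float(np.log(r)) if np.isfinite(r) else float("inf"),
                V=v,
                phi=phi,
                psi=psi,
            )
        )
    return out
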