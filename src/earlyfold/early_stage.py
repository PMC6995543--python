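"""Early-stage encoding: projection of (phi, psi) onto the elliptical
path, the parametric angle t, the 1-degree t histogram, and the seven
structural codes A-G.

The early-stage model assumes the first folding step is decided by
backbone preferences alone: every observed (phi, psi) pair is replaced by
its nearest point (phi_e, psi_e) on an elliptical path across the
Ramachandran map, summarized by the parametric angle t measured clockwise
from an anchor in the lower-right quadrant, and discretized into one of
seven letters by fixed integer intervals of t.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import minimize_scalar

from .backbone_geometry import compute_dihedrals, curvature_profile, lnR_polynomial_fit
from .errors import (
    CannotDeriveEllipseError,
    NoMaximaError,
    NotEllipticalError,
    NotOnEllipseError,
)
from .structure_io import DomainStructure

__all__ = [
    "EllipseSpec",
    "CodeIntervalTable",
    "EarlyStageAssignment",
    "THistogram",
    "default_code_table",
    "default_ellipse",
    "project_to_ellipse",
    "t_angle",
    "assign_code",
    "encode_domain",
    "build_t_histogram",
    "find_local_maxima",
    "derive_ellipse",
    "fit_ellipse",
]


def _wrap_deg(x):
    w = (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(w <= -180.0, 180.0, w)


@dataclass(frozen=True)
class EllipseSpec:
    """Parametric early-stage path on the (phi, psi) plane.

    ``center`` and semi-axis lengths are in degrees; ``tilt`` rotates the
    major axis counterclockwise from the phi axis.  ``t_zero_anchor`` is
    the on-ellipse point where t = 0; t always increases clockwise in the
    standard Ramachandran axes.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    tilt: float
    t_zero_anchor: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self):
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")
        if self.t_zero_anchor is None:
            object.__setattr__(self, "t_zero_anchor", self._max_phi_point())
        anchor = np.asarray(self.t_zero_anchor, dtype=float)
        if abs(self.implicit(anchor)) > 1e-9:
            raise ValueError("t_zero_anchor does not lie on the ellipse")
        if not (anchor[0] > 0 and anchor[1] < 0):
            raise ValueError(
                "t_zero_anchor must lie in the lower-right quadrant (phi > 0, psi < 0)"
            )

    # -- parametric machinery -------------------------------------------------
    def _rot(self) -> np.ndarray:
        th = np.radians(self.tilt)
        c, s = np.cos(th), np.sin(th)
        return np.array([[c, -s], [s, c]])

    def point_at_param(self, u_deg):
        """Ellipse point at parametric angle u (counterclockwise, degrees)."""
        u = np.radians(np.asarray(u_deg, dtype=float))
        a, b = self.semi_axes
        local = np.stack([a * np.cos(u), b * np.sin(u)], axis=-1)
        return local @ self._rot().T + np.asarray(self.center)

    def param_of_point(self, point) -> float:
        p = (np.asarray(point, dtype=float) - np.asarray(self.center)) @ self._rot()
        a, b = self.semi_axes
        return float(np.degrees(np.arctan2(p[1] / b, p[0] / a)) % 360.0)

    def implicit(self, point) -> float:
        """(x'/a)^2 + (y'/b)^2 - 1 in the ellipse's own frame."""
        p = (np.asarray(point, dtype=float) - np.asarray(self.center)) @ self._rot()
        a, b = self.semi_axes
        return float((p[0] / a) ** 2 + (p[1] / b) ** 2 - 1.0)

    def _max_phi_point(self) -> tuple[float, float]:
        a, b = self.semi_axes
        th = np.radians(self.tilt)
        u_star = np.arctan2(-b * np.sin(th), a * np.cos(th))
        return tuple(self.point_at_param(np.degrees(u_star)))

    @property
    def anchor_param(self) -> float:
        return self.param_of_point(self.t_zero_anchor)

    def t_from_param(self, u_deg):
        """Clockwise t of the parametric angle u (u runs counterclockwise)."""
        return (self.anchor_param - np.asarray(u_deg, dtype=float)) % 360.0

    def param_from_t(self, t_deg):
        return (self.anchor_param - np.asarray(t_deg, dtype=float)) % 360.0

    def point_at_t(self, t_deg):
        return self.point_at_param(self.param_from_t(t_deg))

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "center": list(map(float, self.center)),
            "semi_axes": list(map(float, self.semi_axes)),
            "tilt": float(self.tilt),
            "t_zero_anchor": list(map(float, self.t_zero_anchor)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseSpec":
        return cls(
            center=tuple(d["center"]),
            semi_axes=tuple(d["semi_axes"]),
            tilt=float(d["tilt"]),
            t_zero_anchor=tuple(d["t_zero_anchor"]) if "t_zero_anchor" in d else None,
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "EllipseSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Integer t intervals of the seven structural codes (inclusive bounds).
DEFAULT_CODE_INTERVALS = [
    ("A", 0, 50),
    ("B", 51, 85),
    ("C", 86, 110),
    ("D", 111, 150),
    ("E", 151, 193),
    ("F", 194, 225),
    ("G", 226, 359),
]


@dataclass(frozen=True)
class CodeIntervalTable:
    """Maps integer degrees of t onto structural-code letters."""

    entries: tuple = tuple(DEFAULT_CODE_INTERVALS)

    def __post_init__(self):
        covered = np.zeros(360, dtype=bool)
        for _, lo, hi in self.entries:
            if not (0 <= lo <= hi <= 359):
                raise ValueError("interval bounds must lie in 0..359")
            if covered[lo : hi + 1].any():
                raise ValueError("overlapping code intervals")
            covered[lo : hi + 1] = True
        if not covered.all():
            raise ValueError("code intervals do not cover 0..359")

    @functools.cached_property
    def lookup(self) -> np.ndarray:
        out = np.empty(360, dtype="<U1")
        for code, lo, hi in self.entries:
            out[lo : hi + 1] = code
        return out

    @property
    def codes(self) -> list[str]:
        return [c for c, _, _ in self.entries]


def default_code_table() -> CodeIntervalTable:
    return CodeIntervalTable()


def assign_code(t: float, table: CodeIntervalTable | None = None) -> str:
    """Structural code of a t angle: the interval containing floor(t).

    The interval table is integer and inclusive on both ends, so real t
    values fall in half-open bins [from, to+1).  Out-of-range t is wrapped
    modulo 360 first.
    """
    if table is None:
        table = default_code_table()
    t = float(t)
    if np.isnan(t):
        raise ValueError("undefined t")
    return str(table.lookup[int(np.floor(t % 360.0))])


@dataclass
class ProjectionResult:
    phi_e: float
    psi_e: float
    t: float
    distance: float


def project_to_ellipse(phi: float, psi: float, e: EllipseSpec) -> ProjectionResult:
    """Nearest ellipse point to (phi, psi) in the degrees-Euclidean metric.

    Inputs are wrapped into (-180, 180] first; the ellipse is interior to
    that square, so no torus wrapping is applied to the distance itself.
    A coarse 0.5-degree parametric scan brackets every local minimum of
    the distance, each is refined by bounded scalar minimization, and ties
    (e.g. the exact center) break toward the smaller t.
    """
    p = np.array([float(_wrap_deg(phi)), float(_wrap_deg(psi))])
    grid = np.arange(0.0, 360.0, 0.5)
    pts = e.point_at_param(grid)
    d2 = np.sum((pts - p) ** 2, axis=1)

    # local minima of the periodic coarse profile
    left = np.roll(d2, 1)
    right = np.roll(d2, -1)
    cand = np.where((d2 <= left) & (d2 <= right))[0]
    if cand.size == 0:
        cand = np.array([int(np.argmin(d2))])

    def f(u):
        q = e.point_at_param(u)
        return float(np.sum((q - p) ** 2))

    refined: list[tuple[float, float]] = []
    for idx in cand:
        u0 = grid[idx]
        res = minimize_scalar(
            f, bounds=(u0 - 0.75, u0 + 0.75), method="bounded",
            options={"xatol": 1e-12},
        )
        refined.append((float(res.fun), float(res.x % 360.0)))
    best = min(r[0] for r in refined)
    # ties broken to the smaller t
    winners = [u for d, u in refined if d <= best + 1e-9]
    t_best = min(float(e.t_from_param(u)) for u in winners)
    u_best = float(e.param_from_t(t_best))
    q = e.point_at_param(u_best)
    return ProjectionResult(
        phi_e=float(q[0]), psi_e=float(q[1]),
        t=t_best % 360.0, distance=float(np.sqrt(f(u_best))),
    )


def t_angle(point, e: EllipseSpec, tol: float = 1e-6) -> float:
    """Parametric t of an on-ellipse point (clockwise from the anchor)."""
    if abs(e.implicit(point)) > tol:
        raise NotOnEllipseError(f"point {point} not on ellipse (tol {tol})")
    return float(e.t_from_param(e.param_of_point(point)))


@dataclass
class EarlyStageAssignment:
    """Per-residue early-stage encoding of one domain."""

    indices: list[int]
    aa: str
    phi: np.ndarray
    psi: np.ndarray
    phi_e: np.ndarray
    psi_e: np.ndarray
    t: np.ndarray
    codes: list[str | None]

    @property
    def code_string(self) -> str:
        return "".join(c if c is not None else "-" for c in self.codes)

    def defined_ts(self) -> np.ndarray:
        return self.t[~np.isnan(self.t)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "index": self.indices,
                "aa": list(self.aa),
                "phi": self.phi,
                "psi": self.psi,
                "phi_e": self.phi_e,
                "psi_e": self.psi_e,
                "t": self.t,
                "code": [c if c is not None else "-" for c in self.codes],
            }
        )


def encode_domain(
    domain: DomainStructure,
    e: EllipseSpec | None = None,
    table: CodeIntervalTable | None = None,
) -> EarlyStageAssignment:
    """Project every residue's (phi, psi) onto the path and assign codes.

    Residues lacking phi or psi (termini, chain breaks, incomplete
    backbones) stay undefined.
    """
    if e is None:
        e = default_ellipse()
    if table is None:
        table = default_code_table()
    series = compute_dihedrals(domain)
    n = len(domain)
    phi_e = np.full(n, np.nan)
    psi_e = np.full(n, np.nan)
    ts = np.full(n, np.nan)
    codes: list[str | None] = [None] * n
    for i in range(n):
        if np.isnan(series.phi[i]) or np.isnan(series.psi[i]):
            continue
        proj = project_to_ellipse(series.phi[i], series.psi[i], e)
        phi_e[i], psi_e[i], ts[i] = proj.phi_e, proj.psi_e, proj.t
        codes[i] = assign_code(proj.t, table)
    return EarlyStageAssignment(
        indices=[r.index for r in domain.residues],
        aa=domain.sequence,
        phi=series.phi,
        psi=series.psi,
        phi_e=phi_e,
        psi_e=psi_e,
        t=ts,
        codes=codes,
    )


@dataclass
class THistogram:
    """360-bin histogram of t angles; bin i covers [i, i+1) degrees."""

    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_t_histogram(ts) -> THistogram:
    ts = np.asarray(ts, dtype=float)
    if ts.size and ((ts < 0).any() or (ts >= 360).any()):
        raise ValueError("t values must lie in [0, 360)")
    counts = np.bincount(np.floor(ts).astype(int), minlength=360) if ts.size else (
        np.zeros(360, dtype=int)
    )
    return THistogram(counts=counts.astype(int))


@dataclass
class PeakSet:
    maxima: list[int]
    boundaries: list[int]

    @property
    def count(self) -> int:
        return len(self.maxima)


def find_local_maxima(
    h: THistogram, smoothing_window: int = 5, min_prominence: float = 0.02
) -> PeakSet:
    """Local maxima of the circularly smoothed histogram.

    ``min_prominence`` is a fraction of the smoothed histogram's dynamic
    range; bumps less prominent than that (counting noise on a flat
    baseline) are ignored.  Interval boundaries are proposed at the
    minimum between each pair of adjacent maxima (circular order).  A
    flat histogram has no maxima.
    """
    from scipy.signal import find_peaks

    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    counts = h.counts.astype(float)
    if counts.size == 0:
        raise NoMaximaError("empty histogram")
    kernel = np.ones(smoothing_window) / smoothing_window
    pad = smoothing_window // 2
    padded = np.concatenate([counts[-pad:], counts, counts[:pad]]) if pad else counts
    smooth = np.convolve(padded, kernel, mode="valid")
    if np.ptp(smooth) < 1e-12:
        raise NoMaximaError("flat histogram: no maxima")
    n = smooth.size
    # circular peak finding: search the middle copy of a tripled array
    tripled = np.concatenate([smooth, smooth, smooth])
    peaks, _ = find_peaks(tripled, prominence=min_prominence * np.ptp(smooth))
    maxima = sorted({int(p - n) for p in peaks if n <= p < 2 * n})
    if not maxima:
        raise NoMaximaError("no local maxima found")
    boundaries = []
    for a, b in zip(maxima, maxima[1:] + [maxima[0] + n]):
        if b - a < 2:
            continue
        arc = np.arange(a + 1, b) % n
        boundaries.append(int(arc[np.argmin(smooth[arc])]))
    return PeakSet(maxima=maxima, boundaries=boundaries)


# -- ellipse fitting ----------------------------------------------------------

def _fit_conic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct least-squares ellipse-constrained conic fit (Halir-Flusser).

    Returns conic coefficients (A, B, C, D, E, F) of
    A x^2 + B xy + C y^2 + D x + E y + F = 0 with B^2 - 4AC < 0.
    """
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    t_mat = -np.linalg.solve(s3, s2.T)
    m = s1 + s2 @ t_mat
    m = np.array([m[2] / 2, -m[1], m[0] / 2])
    eigval, eigvec = np.linalg.eig(m)
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    a1 = eigvec[:, np.real(cond) > 0]
    if a1.shape[1] == 0:
        raise NotEllipticalError("conic fit did not yield an ellipse")
    a1 = np.real(a1[:, 0])
    a2 = t_mat @ a1
    return np.concatenate([a1, a2])


def _conic_to_spec(coef: np.ndarray) -> EllipseSpec:
    a, b, c, d, e, f = (float(v) for v in coef)
    disc = b * b - 4 * a * c
    if disc >= 0:
        raise NotEllipticalError("conic is not an ellipse")
    m = np.array([[a, b / 2], [b / 2, c]])
    center = np.linalg.solve(2 * m, [-d, -e])
    fc = (
        a * center[0] ** 2
        + b * center[0] * center[1]
        + c * center[1] ** 2
        + d * center[0]
        + e * center[1]
        + f
    )
    eigval, eigvec = np.linalg.eigh(m)
    axes = np.sqrt(-fc / eigval)
    order = np.argsort(axes)[::-1]
    axes = axes[order]
    major_dir = eigvec[:, order[0]]
    tilt = float(np.degrees(np.arctan2(major_dir[1], major_dir[0])) % 180.0)
    return EllipseSpec(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(axes[0]), float(axes[1])),
        tilt=tilt,
    )


def fit_ellipse(phi, psi) -> EllipseSpec:
    """Algebraic least-squares ellipse fit to (phi, psi) points.

    The t = 0 anchor defaults to the point of maximal phi (in the
    lower-right quadrant for paths tilted like the Ramachandran ellipse).
    """
    x = np.asarray(phi, dtype=float)
    y = np.asarray(psi, dtype=float)
    if x.size < 5:
        raise CannotDeriveEllipseError("need at least 5 points for a conic fit")
    return _conic_to_spec(_fit_conic(x, y))


def derive_ellipse(
    corpus: list[DomainStructure],
    residual_band: float = 1.0,
    min_points: int = 50,
) -> EllipseSpec:
    """Derive the elliptical path from a corpus of domain structures.

    Every pentapeptide contributes an (lnR, V) observation; a quadratic
    lnR = f(V) is fitted; fragments within ``residual_band`` of the fit
    are the "relaxed" ones, and their central (phi, psi) points receive an
    algebraic ellipse fit.
    """
    points = []
    for dom in corpus:
        points.extend(curvature_profile(dom))
    usable = [
        p for p in points if np.isfinite(p.lnR) and p.phi is not None and p.psi is not None
    ]
    if len(usable) < min_points:
        raise CannotDeriveEllipseError(
            f"cannot derive ellipse: only {len(usable)} usable pentapeptides"
        )
    poly = lnR_polynomial_fit([p for p in usable])
    selected = [p for p in usable if abs(p.lnR - poly(p.V)) <= residual_band]
    if len(selected) < min_points:
        raise CannotDeriveEllipseError(
            f"cannot derive ellipse: only {len(selected)} on-path points "
            f"within residual band {residual_band}"
        )
    return fit_ellipse([p.phi for p in selected], [p.psi for p in selected])


#: Fixed seed of the packaged synthetic calibration corpus.
_CALIBRATION_SEED = 70_001


@functools.lru_cache(maxsize=1)
def default_ellipse() -> EllipseSpec:
    """The packaged default path, derived from a synthetic calibration corpus.

    Sixty backbones are built from torsions jittered around a canonical
    elliptical path through the main Ramachandran basins, and
    :func:`derive_ellipse` is run on them.  Real-data work should derive
    or supply its own :class:`EllipseSpec`.
    """
    from .synthetic_data import build_backbone

    truth = EllipseSpec(center=(0.0, 0.0), semi_axes=(130.0, 70.0), tilt=120.0)
    rng = np.random.default_rng(_CALIBRATION_SEED)
    corpus = []
    for _ in range(60):
        u = rng.uniform(0.0, 360.0, size=50)
        pts = truth.point_at_param(u) + rng.normal(0.0, 3.0, size=(50, 2))
        torsions = np.asarray(_wrap_deg(pts))
        corpus.append(build_backbone(torsions))
    return derive_ellipse(corpus, residual_band=1.5)


def export_encoding(assignment: EarlyStageAssignment, path: str | Path) -> None:
    """Write a per-domain encoding as TSV."""
    assignment.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def save_code_table(table: CodeIntervalTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([list(e) for e in table.entries], fh)


def load_code_table(path: str | Path) -> CodeIntervalTable:
    with open(path) as fh:
        entries = json.load(fh)
    return CodeIntervalTable(entries=tuple(tuple(e) for e in entries))
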