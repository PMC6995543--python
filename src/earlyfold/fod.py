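"""Fuzzy-oil-drop hydrophobicity model: theoretical (T), observed (O) and
uniform (R_u) densities, the Kullback-Leibler based RD statistic, the
iterative worst-residue trimming classifier, and the run filter.

The model posits that a globular domain concentrates hydrophobicity in a
centric 3D Gaussian core (T).  The observed density (O) aggregates
pairwise hydrophobic interactions inside a distance cutoff.  RD compares
the O-T divergence to the sum of the O-T and O-R_u divergences; below 0.5
the structure is compliant with the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import rel_entr

from .errors import (
    DegenerateSpreadError,
    UnboundedDivergenceError,
    ZeroHydrophobicityError,
)
from .structure_io import AA_ALPHABET, DomainStructure

#: Default inter-residue interaction cutoff, Angstrom.
DEFAULT_CUTOFF = 9.0

#: Default compliance threshold on RD.
RD_THRESHOLD = 0.5

# Kyte-Doolittle hydropathy, min-max scaled to [0, 1].  Packaged stand-in
# only: the screening results in this package are always computed with
# explicitly supplied (synthetic) scales.
_KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class HydrophobicityScale:
    """Intrinsic (self) hydrophobicity Hr per amino acid, dimensionless >= 0."""

    values: dict

    def __post_init__(self):
        missing = set(AA_ALPHABET) - set(self.values)
        if missing:
            raise ValueError(f"scale missing letters: {sorted(missing)}")
        for aa, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"invalid hydrophobicity {v!r} for {aa}")

    def __getitem__(self, aa: str) -> float:
        if aa not in self.values:
            raise KeyError(f"unknown amino acid {aa!r}")
        return float(self.values[aa])

    @classmethod
    def kyte_doolittle_normalized(cls) -> "HydrophobicityScale":
        lo, hi = min(_KD.values()), max(_KD.values())
        return cls({aa: (v - lo) / (hi - lo) for aa, v in _KD.items()})

    @classmethod
    def rank_scale(cls) -> "HydrophobicityScale":
        """Synthetic rank scale 0/19 .. 19/19 over the alphabet in order."""
        return cls({aa: i / 19.0 for i, aa in enumerate(AA_ALPHABET)})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("aa\tHr\n")
            for aa in AA_ALPHABET:
                fh.write(f"{aa}\t{self.values[aa]:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HydrophobicityScale":
        vals = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                aa, v = line.split()
                vals[aa] = float(v)
        return cls(vals)


def default_scale() -> HydrophobicityScale:
    return HydrophobicityScale.kyte_doolittle_normalized()


def effective_positions(
    domain: DomainStructure, mode: str = "CA"
) -> tuple[np.ndarray, list[int]]:
    """One interaction point per residue plus the kept residue indices.

    Only the CA mode is available on backbone-only records; incomplete
    residues are skipped (with a warning) and excluded from N downstream.
    """
    if mode != "CA":
        raise ValueError(
            f"effective-position mode {mode!r} not available on backbone-only records"
        )
    pts, kept = [], []
    for r in domain.residues:
        if not r.complete:
            continue
        pts.append(r.coords_CA)
        kept.append(r.index)
    if not pts:
        raise ValueError(f"no complete residues in {domain.id}")
    if len(kept) < len(domain):
        warnings.warn(
            f"{domain.id}: skipped {len(domain) - len(kept)} incomplete residues",
            stacklevel=2,
        )
    return np.array(pts, dtype=float), kept


def theoretical_distribution(points) -> np.ndarray:
    """Centric 3D Gaussian density evaluated at each effective position.

    Points are centered on their mean and rotated to principal axes; the
    per-axis sigma follows the three-sigma rule (max |coordinate| / 3).
    Axes with no spread contribute nothing.  Normalized to sum 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    centered = pts - pts.mean(axis=0)
    if np.abs(centered).max() < 1e-9:
        raise DegenerateSpreadError("all points coincident")
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    coords = centered @ vecs
    sigma = np.abs(coords).max(axis=0) / 3.0
    logt = np.zeros(len(pts))
    for k in range(3):
        if sigma[k] > 1e-9:
            logt -= coords[:, k] ** 2 / (2.0 * sigma[k] ** 2)
    t = np.exp(logt)
    return t / t.sum()


def contact_kernel(x) -> np.ndarray:
    """Sigmoid contact polynomial g(x) = 1 - (7x^2 - 9x^4 + 5x^6 - x^8)/2.

    g(0) = 1, g(1) = 0; zero beyond x = 1 (x is distance over cutoff).
    """
    x = np.asarray(x, dtype=float)
    inside = x <= 1.0
    x2 = np.where(inside, x, 0.0) ** 2
    g = 1.0 - 0.5 * (7 * x2 - 9 * x2**2 + 5 * x2**3 - x2**4)
    return np.where(inside, g, 0.0)


def observed_distribution(
    points, aas, scale: HydrophobicityScale, cutoff_c: float = DEFAULT_CUTOFF
) -> np.ndarray:
    """Observed hydrophobicity density collected from pairwise contacts.

    O_i sums (Hr_i + Hr_j) * g(r_ij / c) over all partners within the
    cutoff, the self term j = i included (g(0) = 1); normalized to sum 1.
    """
    pts = np.asarray(points, dtype=float)
    h = np.array([scale[a] for a in aas], dtype=float)
    if len(h) != len(pts):
        raise ValueError("points and amino acids not aligned")
    if h.sum() <= 0:
        raise ZeroHydrophobicityError("all intrinsic hydrophobicities are zero")
    g = contact_kernel(cdist(pts, pts) / cutoff_c)
    o = (g * (h[:, None] + h[None, :])).sum(axis=1)
    return o / o.sum()


def uniform_reference(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def kl_divergence(p, q, base: float = 2.0) -> float:
    """Kullback-Leibler divergence sum p_i log(p_i / q_i), default in bits."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    if np.any((p > 0) & (q <= 0)):
        raise UnboundedDivergenceError("P > 0 where Q = 0")
    return float(rel_entr(p, q).sum() / np.log(base))


def compute_rd(o, t, r_u, base: float = 2.0) -> float:
    """RD = D(O|T) / (D(O|T) + D(O|R_u)), dimensionless in [0, 1]."""
    d_ot = kl_divergence(o, t, base)
    d_or = kl_divergence(o, r_u, base)
    if d_ot + d_or == 0.0:
        warnings.warn("O, T and R_u coincide; RD defined as 0", stacklevel=2)
        return 0.0
    return d_ot / (d_ot + d_or)


@dataclass
class FODProfile:
    """Full fuzzy-oil-drop evaluation of one domain."""

    domain_id: str
    indices: list[int]
    aa: list[str]
    T: np.ndarray
    O: np.ndarray
    R_u: np.ndarray
    d_ot: float
    d_or: float
    rd: float

    @property
    def compliant(self) -> bool:
        return self.rd < RD_THRESHOLD

    def to_json(self, path: str | Path) -> None:
        payload = {
            "id": self.domain_id,
            "N": len(self.indices),
            "D_OT": self.d_ot,
            "D_OR": self.d_or,
            "RD": self.rd,
            "residues": [
                {"index": i, "aa": a, "T": float(t), "O": float(o)}
                for i, a, t, o in zip(self.indices, self.aa, self.T, self.O)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def fod_profile(
    domain: DomainStructure,
    scale: HydrophobicityScale | None = None,
    cutoff_c: float = DEFAULT_CUTOFF,
    aa_override: list[str] | None = None,
) -> FODProfile:
    """Evaluate T, O, R_u and RD on a domain's effective positions."""
    if scale is None:
        scale = default_scale()
    pts, kept = effective_positions(domain)
    by_index = {r.index: r.aa for r in domain.residues}
    aas = aa_override if aa_override is not None else [by_index[i] for i in kept]
    t = theoretical_distribution(pts)
    o = observed_distribution(pts, aas, scale, cutoff_c)
    r_u = uniform_reference(len(pts))
    d_ot = kl_divergence(o, t)
    d_or = kl_divergence(o, r_u)
    rd = compute_rd(o, t, r_u)
    return FODProfile(
        domain_id=domain.id, indices=kept, aa=list(aas),
        T=t, O=o, R_u=r_u, d_ot=d_ot, d_or=d_or, rd=rd,
    )


@dataclass
class ComplianceStatus:
    """Per-residue compliance labels from the trimming classifier.

    ``labels`` aligns with the domain's residues: 'C' retained
    (compliant), 'N' removed (noncompliant), None for residues excluded
    from the evaluation (incomplete backbone).
    """

    domain_id: str
    labels: list[str | None]
    original_rd: float
    final_rd: float
    removal_order: list[int] = field(default_factory=list)
    never_compliant: bool = False

    @property
    def origin_compliant(self) -> bool:
        return self.original_rd < RD_THRESHOLD

    @property
    def status_string(self) -> str:
        return "".join(l if l is not None else "-" for l in self.labels)


def trim_classify(
    domain: DomainStructure,
    scale: HydrophobicityScale | None = None,
    threshold: float = RD_THRESHOLD,
    cutoff_c: float = DEFAULT_CUTOFF,
    trim_metric: str = "abs",
    min_residues: int = 5,
    aa_override: list[str] | None = None,
) -> ComplianceStatus:
    """Iteratively remove the worst residue until RD drops below threshold.

    Each iteration re-evaluates T (Gaussian re-centred and re-scaled on
    the retained subset) and O, then removes the residue with the largest
    |T - O| discrepancy (``trim_metric='signed'`` uses the observed excess
    O - T instead); ties break to the lowest residue index.  If the
    retained set would shrink below ``min_residues`` without passing,
    every position is labelled noncompliant and the never-compliant flag
    is raised.
    """
    if scale is None:
        scale = default_scale()
    if trim_metric not in ("abs", "signed"):
        raise ValueError("trim_metric must be 'abs' or 'signed'")
    pts_all, kept = effective_positions(domain)
    by_index = {r.index: r.aa for r in domain.residues}
    aas_all = aa_override if aa_override is not None else [by_index[i] for i in kept]
    retained = list(range(len(kept)))
    removal_order: list[int] = []
    original_rd: float | None = None
    final_rd = float("nan")
    while True:
        pts = pts_all[retained]
        aas = [aas_all[k] for k in retained]
        t = theoretical_distribution(pts)
        o = observed_distribution(pts, aas, scale, cutoff_c)
        rd = compute_rd(o, t, uniform_reference(len(retained)))
        if original_rd is None:
            original_rd = rd
        if rd < threshold:
            final_rd = rd
            break
        if len(retained) - 1 < min_residues:
            # never reached compliance; everything counts as noncompliant
            removal_order.extend(kept[k] for k in retained)
            retained = []
            labels: list[str | None] = [None] * len(domain)
            pos = {r.index: j for j, r in enumerate(domain.residues)}
            for idx in kept:
                labels[pos[idx]] = "N"
            return ComplianceStatus(
                domain_id=domain.id,
                labels=labels,
                original_rd=original_rd,
                final_rd=rd,
                removal_order=removal_order,
                never_compliant=True,
            )
        metric = np.abs(t - o) if trim_metric == "abs" else (o - t)
        worst = retained[int(np.argmax(metric))]  # argmax ties -> lowest index
        removal_order.append(kept[worst])
        retained.remove(worst)
    removed = set(removal_order)
    labels = [None] * len(domain)
    pos = {r.index: j for j, r in enumerate(domain.residues)}
    for idx in kept:
        labels[pos[idx]] = "N" if idx in removed else "C"
    return ComplianceStatus(
        domain_id=domain.id,
        labels=labels,
        original_rd=original_rd,
        final_rd=final_rd,
        removal_order=removal_order,
    )


def status_runs(labels, min_len: int = 4) -> list[tuple[str, int, int]]:
    """Maximal constant-label runs of length >= min_len, 1-based inclusive.

    ``labels`` is a string over {C, N, -} or a list with None breaks; runs
    never span an undefined position.
    """
    if not isinstance(labels, str):
        labels = "".join(l if l is not None else "-" for l in labels)
    runs = []
    start = 0
    n = len(labels)
    while start < n:
        ch = labels[start]
        end = start
        while end + 1 < n and labels[end + 1] == ch:
            end += 1
        if ch in ("C", "N") and end - start + 1 >= min_len:
            runs.append((ch, start + 1, end + 1))
        start = end + 1
    return runs


def hydrophobicity_profile_export(sequence: str, scale: HydrophobicityScale) -> np.ndarray:
    """Per-position intrinsic hydrophobicity of a sequence (for plotting)."""
    for aa in sequence:
        if aa not in AA_ALPHABET:
            raise ValueError(f"unknown amino acid {aa!r}")
    return np.array([scale[aa] for aa in sequence])
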