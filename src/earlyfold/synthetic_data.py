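"""Synthetic inputs with the statistical structure the analysis assumes.

Four generators cover the pipeline end to end without any external data:
torsion sampling from Ramachandran basin mixtures, backbone
reconstruction from internal coordinates, globular clouds with planted
(or anti-planted) hydrophobic cores for the fuzzy-oil-drop stage, and
paired window corpora with planted tetrapeptide code-frequency contrasts
for the correlation screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contingency import CODE_ALPHABET, N_CODE4, code4_unrank
from .fod import HydrophobicityScale, theoretical_distribution
from .structure_io import AA_ALPHABET, DomainStructure, ResidueRecord

# Ideal backbone internal coordinates (Angstrom, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA_TRANS = 180.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _wrap_deg(x):
    w = (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0
    return np.where(w <= -180.0, 180.0, w)


@dataclass(frozen=True)
class TorsionMixtureSpec:
    """Gaussian mixture over (phi, psi) emulating Ramachandran basins."""

    components: tuple  # of (mean_phi, mean_psi, sd, weight)
    omega: float = OMEGA_TRANS

    def __post_init__(self):
        weights = [w for *_, w in self.components]
        if not weights or any(w <= 0 for w in weights):
            raise ValueError("component weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")

    @classmethod
    def default_basins(cls) -> "TorsionMixtureSpec":
        """Right-handed helix, beta, polyproline II and left-handed helix."""
        return cls(
            components=(
                (-63.0, -43.0, 10.0, 0.40),
                (-120.0, 130.0, 15.0, 0.30),
                (-75.0, 150.0, 10.0, 0.20),
                (60.0, 45.0, 10.0, 0.10),
            )
        )


def sample_torsions(spec: TorsionMixtureSpec, n: int, seed=0) -> np.ndarray:
    """n i.i.d. (phi, psi) draws from the mixture, wrapped into (-180, 180].

    Noise is Gaussian on each angle independently (adequate far from the
    +-180 seam); the same seed always reproduces the same draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    weights = np.array([w for *_, w in spec.components])
    means = np.array([(p, s) for p, s, _, _ in spec.components])
    sds = np.array([sd for _, _, sd, _ in spec.components])
    comp = rng.choice(len(weights), size=n, p=weights)
    draws = means[comp] + rng.normal(size=(n, 2)) * sds[comp, None]
    return np.asarray(_wrap_deg(draws))


def _place_atom(a, b, c, length: float, angle_deg: float, torsion_deg: float):
    """Next atom position from three predecessors and internal coordinates.

    The returned point d satisfies |cd| = length, angle(b, c, d) =
    angle_deg and dihedral(a, b, c, d) = torsion_deg.
    """
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(theta),
            length * np.sin(theta) * np.cos(chi),
            length * np.sin(theta) * np.sin(chi),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_backbone(
    torsions, omega: float = OMEGA_TRANS, aa_seq: str | None = None,
    domain_id: str = "synthetic",
) -> DomainStructure:
    """Chain extension from (phi, psi) pairs with ideal bond geometry.

    ``torsions[i] = (phi_i, psi_i)``; phi of the first residue and psi of
    the last are ignored (they do not determine any atom), matching what
    ``compute_dihedrals`` can recover.
    """
    torsions = np.atleast_2d(np.asarray(torsions, dtype=float))
    n = len(torsions)
    if n < 1:
        raise ValueError("need at least one torsion pair")
    if aa_seq is None:
        aa_seq = "A" * n
    if len(aa_seq) != n:
        raise ValueError("aa_seq not aligned with torsions")

    coords = np.zeros((n, 3, 3))  # residue, atom (N, CA, C), xyz
    coords[0, 0] = [0.0, 0.0, 0.0]
    coords[0, 1] = [BOND_N_CA, 0.0, 0.0]
    theta = np.radians(ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    for i in range(n - 1):
        n_next = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2],
            BOND_C_N, ANGLE_CA_C_N, torsions[i, 1],
        )
        ca_next = _place_atom(
            coords[i, 1], coords[i, 2], n_next, BOND_N_CA, ANGLE_C_N_CA, omega
        )
        c_next = _place_atom(
            coords[i, 2], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C,
            torsions[i + 1, 0],
        )
        coords[i + 1] = [n_next, ca_next, c_next]

    residues = [
        ResidueRecord(
            index=i + 1,
            aa=aa_seq[i],
            coords_N=coords[i, 0].copy(),
            coords_CA=coords[i, 1].copy(),
            coords_C=coords[i, 2].copy(),
            complete=True,
        )
        for i in range(n)
    ]
    return DomainStructure(id=domain_id, residues=residues)


# -- fuzzy-oil-drop cases -----------------------------------------------------

#: Per-axis spread of the synthetic globular CA cloud, Angstrom.  Chosen
#: to give a 60-residue cloud the radius of gyration of a small globular
#: domain (about 11 A) with a dense contact network under the 9 A cutoff.
FOD_CLOUD_SIGMA = (7.0, 6.0, 5.0)


@dataclass
class FodCase:
    domain: DomainStructure
    scale: HydrophobicityScale
    aa_seq: str
    planted_noncore: list[int] = field(default_factory=list)


def _cloud_domain(n: int, rng: np.random.Generator, domain_id: str) -> DomainStructure:
    pts = rng.normal(size=(n, 3)) * np.array(FOD_CLOUD_SIGMA)
    residues = []
    for i in range(n):
        ca = pts[i]
        residues.append(
            ResidueRecord(
                index=i + 1,
                aa="A",
                coords_N=ca + np.array([-1.2, -0.4, 0.0]),
                coords_CA=ca.copy(),
                coords_C=ca + np.array([1.2, -0.4, 0.0]),
                complete=True,
            )
        )
    return DomainStructure(id=domain_id, residues=residues)


def _rank_assign(t_density: np.ndarray, scale: HydrophobicityScale, invert: bool) -> str:
    """Assign letters so Hr tracks (or anti-tracks) the Gaussian density."""
    letters = sorted(AA_ALPHABET, key=lambda a: scale[a], reverse=not invert)
    n = len(t_density)
    order = np.argsort(-t_density)  # most central first
    aa = [""] * n
    for rank, idx in enumerate(order):
        aa[idx] = letters[min(19, rank * 20 // n)]
    return "".join(aa)


def make_fod_case(
    compliant: bool, n: int = 60, seed=0, scale: HydrophobicityScale | None = None
) -> FodCase:
    """A globular CA cloud whose sequence follows or violates the core.

    The compliant case rank-matches intrinsic hydrophobicity to the
    centric Gaussian density (hydrophobic inside); the noncompliant case
    anti-matches it (hydrophobic outside).
    """
    if n < 20:
        raise ValueError("need n >= 20 for a meaningful core")
    rng = _rng(seed)
    if scale is None:
        scale = HydrophobicityScale.rank_scale()
    tag = "compliant" if compliant else "anticore"
    domain = _cloud_domain(n, rng, f"fodcase_{tag}_{seed}")
    t = theoretical_distribution(domain.ca_coords())
    aa = _rank_assign(t, scale, invert=not compliant)
    for rec, letter in zip(domain.residues, aa):
        rec.aa = letter
    return FodCase(domain=domain, scale=scale, aa_seq=aa)


def make_trim_case(n: int = 60, k: int = 14, seed=0) -> FodCase:
    """Compliant core with k residues' hydrophobicity rank inverted.

    The inversions hit the most central residues (largest theoretical
    density), where swapping hydrophobic for hydrophilic perturbs the
    core hardest; the planted positions are the ground truth for the
    trimming classifier, whose removals should concentrate on them.
    """
    rng = _rng(seed)
    scale = HydrophobicityScale.rank_scale()
    case = make_fod_case(True, n=n, seed=rng, scale=scale)
    letters = sorted(AA_ALPHABET, key=lambda a: scale[a])
    rank_of = {a: i for i, a in enumerate(letters)}
    t = theoretical_distribution(case.domain.ca_coords())
    planted = sorted(np.argsort(-t)[:k].tolist())
    aa = list(case.aa_seq)
    for i in planted:
        aa[i] = letters[19 - rank_of[aa[i]]]
    case.aa_seq = "".join(aa)
    for rec, letter in zip(case.domain.residues, aa):
        rec.aa = letter
    case.planted_noncore = [i + 1 for i in planted]
    return case


# -- planted window corpora ---------------------------------------------------


@dataclass(frozen=True)
class PlantedCorpusSpec:
    """Conditions of a paired corpus with planted code-frequency contrast.

    Null tetrapeptides share one code4 profile between classes; signal
    tetrapeptides use a rank-reversed profile in the noncompliant class,
    which makes their population correlation negative by construction.
    ``signal_effect`` in (0, 1] blends toward the reversed profile.
    """

    n_domains_compliant: int = 3200
    n_domains_noncompliant: int = 800
    windows_per_domain: int = 20
    n_null_tetrapeptides: int = 50
    signal_tetrapeptides: tuple = ("DKAG", "FVRL", "LFDD")
    signal_effect: float = 1.0
    dirichlet_alpha: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for s in self.signal_tetrapeptides:
            if len(s) != 4 or any(c not in AA_ALPHABET for c in s):
                raise ValueError(f"invalid signal tetrapeptide {s!r}")
        if not 0.0 < self.signal_effect <= 1.0:
            raise ValueError("signal_effect must be in (0, 1]")


@dataclass
class CorpusDomain:
    """One synthetic domain already encoded: sequence, codes, statuses."""

    aa_seq: str
    code_seq: str
    statuses: str
    origin_compliant: bool


@dataclass
class PlantedCorpus:
    spec: PlantedCorpusSpec
    compliant: list[CorpusDomain]
    noncompliant: list[CorpusDomain]
    null_tetrapeptides: list[str]
    signal_tetrapeptides: list[str]


def _rank_reversed(p: np.ndarray) -> np.ndarray:
    """Reassign probabilities so the largest cell gets the smallest mass."""
    order = np.argsort(p, kind="stable")
    q = np.empty_like(p)
    q[order] = p[order[::-1]]
    return q


def _pack_domains(
    windows: list[tuple[str, str]], per_domain: int, status_char: str,
    origin_compliant: bool,
) -> list[CorpusDomain]:
    """Join 4-residue windows into chains with undefined-code spacers.

    The spacer (X residue, '-' code) guarantees no window straddles two
    planted blocks when the corpus is re-cut by ``extract_windows``.
    """
    domains = []
    for start in range(0, len(windows), per_domain):
        chunk = windows[start : start + per_domain]
        if not chunk:
            continue
        aa = "X".join(w[0] for w in chunk)
        codes = "-".join(w[1] for w in chunk)
        domains.append(
            CorpusDomain(
                aa_seq=aa,
                code_seq=codes,
                statuses=status_char * len(aa),
                origin_compliant=origin_compliant,
            )
        )
    return domains


def make_planted_corpus(spec: PlantedCorpusSpec) -> PlantedCorpus:
    """Two window corpora with the requested planted contrast.

    Returns domains of (aa_seq, code_seq, statuses) ready for
    ``contingency.extract_windows``; byte-identical for equal specs.
    """
    rng = _rng(spec.seed)
    signals = list(spec.signal_tetrapeptides)
    nulls: list[str] = []
    seen = set(signals)
    while len(nulls) < spec.n_null_tetrapeptides:
        cand = "".join(rng.choice(list(AA_ALPHABET), size=4))
        if cand not in seen:
            nulls.append(cand)
            seen.add(cand)
    pool = signals + nulls

    profiles = {}
    for seq in pool:
        p = rng.dirichlet(np.full(N_CODE4, spec.dirichlet_alpha))
        q = p
        if seq in signals:
            rev = _rank_reversed(p)
            q = spec.signal_effect * rev + (1.0 - spec.signal_effect) * p
            q = q / q.sum()
        profiles[seq] = (p, q)

    out = {}
    for class_name, n_domains, which in (
        ("compliant", spec.n_domains_compliant, 0),
        ("noncompliant", spec.n_domains_noncompliant, 1),
    ):
        total = n_domains * spec.windows_per_domain
        seq_counts = rng.multinomial(total, np.full(len(pool), 1.0 / len(pool)))
        windows: list[tuple[str, str]] = []
        for seq, count in zip(pool, seq_counts):
            if count == 0:
                continue
            cell_counts = rng.multinomial(count, profiles[seq][which])
            for rank in np.nonzero(cell_counts)[0]:
                code = code4_unrank(int(rank))
                windows.extend([(seq, code)] * int(cell_counts[rank]))
        perm = rng.permutation(len(windows))
        windows = [windows[i] for i in perm]
        out[class_name] = _pack_domains(
            windows, spec.windows_per_domain,
            "C" if class_name == "compliant" else "N",
            origin_compliant=(class_name == "compliant"),
        )
    return PlantedCorpus(
        spec=spec,
        compliant=out["compliant"],
        noncompliant=out["noncompliant"],
        null_tetrapeptides=nulls,
        signal_tetrapeptides=signals,
    )
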