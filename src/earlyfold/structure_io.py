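"""Read, write and slice protein domain structures in PDB format.

Only the backbone atoms N, CA and C are retained: the whole analysis
(torsion angles, curvature, hydrophobicity densities over effective
positions) runs on the backbone trace.  Parsing and serialization go
through :mod:`gemmi`; this module only maps gemmi objects onto the
package's light-weight residue records.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import (
    ChainNotFoundError,
    EmptyDomainError,
    NoBackboneError,
    TooShortError,
)

#: Minimum number of residues any analysis operation will accept
#: (pentapeptide curvature windows and 4-residue sliding windows).
MIN_RESIDUES = 5

#: The 20-letter amino-acid alphabet in lexicographic order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


@dataclass
class ResidueRecord:
    """One chain position with its backbone geometry.

    ``index`` is the 1-based position within the (possibly sliced) domain;
    ``seq_num`` keeps the author residue number used by range configs.
    ``complete`` is true iff all three backbone atoms are present; no
    geometry operation may consume an incomplete residue.
    """

    index: int
    aa: str
    coords_N: np.ndarray | None
    coords_CA: np.ndarray | None
    coords_C: np.ndarray | None
    complete: bool
    seq_num: int = 0
    icode: str = ""

    def __post_init__(self) -> None:
        if self.seq_num == 0:
            self.seq_num = self.index


@dataclass
class DomainStructure:
    """An ordered run of residues analysed as one folding unit."""

    id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) CA coordinates of complete residues, in chain order."""
        return np.array([r.coords_CA for r in self.residues if r.complete])


@dataclass(frozen=True)
class DomainRange:
    """One entry of a domain-range configuration (inclusive bounds)."""

    file: str
    chain: str
    start: int
    end: int
    domain_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"range start {self.start} > end {self.end} for {self.domain_id}"
            )


@dataclass
class DomainRangeConfig:
    entries: list[DomainRange]

    def __post_init__(self) -> None:
        by_chain: dict[tuple[str, str], list[DomainRange]] = {}
        for e in self.entries:
            by_chain.setdefault((e.file, e.chain), []).append(e)
        for (f, c), group in by_chain.items():
            group = sorted(group, key=lambda e: e.start)
            for prev, cur in zip(group, group[1:]):
                if cur.start <= prev.end:
                    raise ValueError(
                        f"overlapping ranges {prev.domain_id} and "
                        f"{cur.domain_id} on {f} chain {c}"
                    )


def require_analysable(domain: DomainStructure) -> None:
    """Raise :class:`TooShortError` for domains below :data:`MIN_RESIDUES`."""
    if len(domain) < MIN_RESIDUES:
        raise TooShortError(
            f"domain {domain.id} too short: {len(domain)} < {MIN_RESIDUES}"
        )


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    one = info.one_letter_code.upper()
    # gemmi reports lowercase for nonstandard residues; .upper() maps them
    # to the parent amino acid (e.g. MSE -> M).  Anything outside the
    # 20-letter alphabet stays X.
    return one if one in AA_ALPHABET else "X"


def read_structure(path: str | Path, chain: str) -> DomainStructure:
    """Read one chain of a PDB file into a :class:`DomainStructure`.

    Altloc handling keeps blank or 'A' locations; residues are ordered by
    (sequence number, insertion code); nonstandard residues are mapped to
    their parent amino acid where tabulated, else to X.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    model = st[0]
    gchain = model.find_chain(chain)
    if gchain is None:
        raise ChainNotFoundError(f"chain {chain!r} not found in {path}")

    records: list[ResidueRecord] = []
    for res in gchain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and not info.is_amino_acid():
            continue
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.altloc not in ("\0", "", "A"):
                continue
            if atom.name in ("N", "CA", "C") and atom.name not in atoms:
                atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
        records.append(
            ResidueRecord(
                index=0,
                aa=_one_letter(res.name),
                coords_N=atoms.get("N"),
                coords_CA=atoms.get("CA"),
                coords_C=atoms.get("C"),
                complete=all(k in atoms for k in ("N", "CA", "C")),
                seq_num=res.seqid.num,
                icode=res.seqid.icode.strip(),
            )
        )
    records.sort(key=lambda r: (r.seq_num, r.icode))
    for i, rec in enumerate(records, start=1):
        rec.index = i
    if not any(r.complete for r in records):
        raise NoBackboneError(f"no complete backbone residue in {path} chain {chain}")
    return DomainStructure(id=f"{path.stem}_{chain}", residues=records)


def slice_domain(chain: DomainStructure, rng: DomainRange) -> DomainStructure:
    """Extract residues with sequence numbers in [start, end], renumbered from 1."""
    picked = [r for r in chain.residues if rng.start <= r.seq_num <= rng.end]
    if not picked:
        raise EmptyDomainError(
            f"empty domain: range {rng.start}-{rng.end} selects nothing in {chain.id}"
        )
    out = []
    for i, r in enumerate(picked, start=1):
        out.append(
            ResidueRecord(
                index=i,
                aa=r.aa,
                coords_N=None if r.coords_N is None else r.coords_N.copy(),
                coords_CA=None if r.coords_CA is None else r.coords_CA.copy(),
                coords_C=None if r.coords_C is None else r.coords_C.copy(),
                complete=r.complete,
                seq_num=i,
            )
        )
    return DomainStructure(id=rng.domain_id, residues=out)


def write_structure(domain: DomainStructure, path: str | Path) -> None:
    """Serialize a domain as PDB ATOM records (N, CA, C per residue)."""
    if len(domain) == 0:
        raise ValueError("cannot serialize an empty domain")
    for r in domain.residues:
        if not r.complete:
            raise ValueError(
                f"cannot serialize: residue {r.index} of {domain.id} is incomplete"
            )
    st = gemmi.Structure()
    st.name = domain.id[:4] if domain.id else "XXXX"
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for r in domain.residues:
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(r.aa, "UNK")
        res.seqid = gemmi.SeqId(r.index, " ")
        for name, xyz, elem in (
            ("N", r.coords_N, "N"),
            ("CA", r.coords_CA, "C"),
            ("C", r.coords_C, "C"),
        ):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.write_pdb(str(path))


def load_range_config(path: str | Path) -> DomainRangeConfig:
    """Read a TSV with columns file, chain, start, end, domain_id."""
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries.append(
                DomainRange(
                    file=row["file"],
                    chain=row["chain"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    domain_id=row["domain_id"],
                )
            )
    return DomainRangeConfig(entries=entries)


def save_range_config(config: DomainRangeConfig, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["file", "chain", "start", "end", "domain_id"])
        for e in config.entries:
            writer.writerow([e.file, e.chain, e.start, e.end, e.domain_id])
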