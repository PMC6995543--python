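"""Sequence-structure contingency tables over 4-residue windows and the
correlation-significance screen between the compliant and noncompliant
corpora.

The table is logically 160,000 columns (20^4 amino-acid tetrapeptides) by
2,401 rows (7^4 structural-code tetrads).  For every column (fixed
sequence) and every row (fixed code tetrad) a Pearson correlation between
the compliant and noncompliant count vectors is tested with the
large-sample statistic z = r sqrt(n-2)/sqrt(1-r^2) against the critical
value 1.96 (two-sided, alpha = 0.05).  Tetrapeptides whose correlation is
significantly negative take opposite structural forms in the two corpora.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .errors import UndefinedCorrelationError
from .fod import status_runs
from .structure_io import AA_ALPHABET

CODE_ALPHABET = "ABCDEFG"
N_SEQ4 = len(AA_ALPHABET) ** 4  # 160,000 sequence columns
N_CODE4 = len(CODE_ALPHABET) ** 4  # 2,401 structural-code rows

WINDOW = 4

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_CODE_INDEX = {c: i for i, c in enumerate(CODE_ALPHABET)}


def seq4_rank(seq4: str) -> int:
    """Lexicographic rank of an amino-acid 4-mer in [0, 160000)."""
    if len(seq4) != 4 or any(c not in _AA_INDEX for c in seq4):
        raise ValueError(f"invalid sequence 4-mer {seq4!r}")
    r = 0
    for c in seq4:
        r = r * 20 + _AA_INDEX[c]
    return r


def seq4_unrank(rank: int) -> str:
    if not 0 <= rank < N_SEQ4:
        raise ValueError(f"sequence rank out of range: {rank}")
    out = []
    for _ in range(4):
        rank, rem = divmod(rank, 20)
        out.append(AA_ALPHABET[rem])
    return "".join(reversed(out))


def code4_rank(code4: str) -> int:
    """Lexicographic rank of a structural-code 4-mer in [0, 2401)."""
    if len(code4) != 4 or any(c not in _CODE_INDEX for c in code4):
        raise ValueError(f"invalid code 4-mer {code4!r}")
    r = 0
    for c in code4:
        r = r * 7 + _CODE_INDEX[c]
    return r


def code4_unrank(rank: int) -> str:
    if not 0 <= rank < N_CODE4:
        raise ValueError(f"code rank out of range: {rank}")
    out = []
    for _ in range(4):
        rank, rem = divmod(rank, 7)
        out.append(CODE_ALPHABET[rem])
    return "".join(reversed(out))


@dataclass(frozen=True)
class WindowPair:
    seq4: str
    code4: str
    label: str  # "compliant" | "noncompliant"

    def __post_init__(self):
        seq4_rank(self.seq4)
        code4_rank(self.code4)
        if self.label not in ("compliant", "noncompliant"):
            raise ValueError(f"invalid label {self.label!r}")


def extract_windows(
    aa_seq: str,
    code_seq: str,
    statuses: str | None = None,
    origin_compliant: bool = True,
    min_run: int = 4,
) -> list[WindowPair]:
    """Slide a 4-position window and emit labelled sequence-structure pairs.

    For an originally-compliant domain every window with four defined
    codes and no X residue goes to the compliant set.  For an
    originally-noncompliant domain a window must additionally lie entirely
    inside one qualifying status run (length >= ``min_run``) and inherits
    that run's label; windows straddling runs are dropped.
    """
    if len(aa_seq) != len(code_seq):
        raise ValueError("aa_seq and code_seq are not aligned")
    n = len(aa_seq)
    if n < WINDOW:
        return []
    runs = None
    if not origin_compliant:
        if statuses is None:
            raise ValueError("statuses required for noncompliant-origin domains")
        if len(statuses) != n:
            raise ValueError("statuses not aligned with sequence")
        runs = status_runs(statuses, min_len=min_run)
    out: list[WindowPair] = []
    for i in range(n - WINDOW + 1):
        seq4 = aa_seq[i : i + WINDOW]
        code4 = code_seq[i : i + WINDOW]
        if any(c not in _CODE_INDEX for c in code4):
            continue
        if any(a not in _AA_INDEX for a in seq4):
            continue
        if origin_compliant:
            label = "compliant"
        else:
            label = None
            for run_label, start, end in runs:
                if start <= i + 1 and i + WINDOW <= end:
                    label = "compliant" if run_label == "C" else "noncompliant"
                    break
            if label is None:
                continue
        out.append(WindowPair(seq4=seq4, code4=code4, label=label))
    return out


@dataclass
class ContingencyTable:
    """Sparse (seq4, code4) count table with fixed logical capacity."""

    label: str
    counts: dict = field(default_factory=dict)
    total: float = 0.0
    scale_factor: float = 1.0

    n_columns = N_SEQ4
    n_rows = N_CODE4

    def add(self, seq4: str, code4: str, weight: float = 1.0) -> None:
        seq4_rank(seq4)
        code4_rank(code4)
        self.counts[(seq4, code4)] = self.counts.get((seq4, code4), 0.0) + weight
        self.total += weight

    def column_vector(self, seq4: str) -> np.ndarray:
        """Dense length-2401 vector of one column, canonical code4 order."""
        seq4_rank(seq4)
        v = np.zeros(N_CODE4)
        for (s, c), w in self.counts.items():
            if s == seq4:
                v[code4_rank(c)] = w
        return v

    def row_vector(self, code4: str) -> np.ndarray:
        """Dense length-160000 vector of one row, canonical seq4 order."""
        code4_rank(code4)
        v = np.zeros(N_SEQ4)
        for (s, c), w in self.counts.items():
            if c == code4:
                v[seq4_rank(s)] = w
        return v

    def occupied_columns(self) -> set:
        return {s for s, _ in self.counts}

    def occupied_rows(self) -> set:
        return {c for _, c in self.counts}

    def by_column(self) -> dict:
        out: dict = {}
        for (s, c), w in self.counts.items():
            out.setdefault(s, {})[c] = w
        return out

    def by_row(self) -> dict:
        out: dict = {}
        for (s, c), w in self.counts.items():
            out.setdefault(c, {})[s] = w
        return out

    def copy(self) -> "ContingencyTable":
        return ContingencyTable(
            label=self.label,
            counts=dict(self.counts),
            total=self.total,
            scale_factor=self.scale_factor,
        )

    # -- persistence ----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("seq4\tcode4\tcount\n")
            for (s, c) in sorted(self.counts):
                fh.write(f"{s}\t{c}\t{self.counts[(s, c)]:.9g}\n")
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "label": self.label,
                    "total": self.total,
                    "scale_factor": self.scale_factor,
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContingencyTable":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar) as fh:
            meta = json.load(fh)
        table = cls(label=meta["label"], scale_factor=meta["scale_factor"])
        with open(path) as fh:
            next(fh)
            for line in fh:
                s, c, w = line.split()
                table.counts[(s, c)] = float(w)
        table.total = sum(table.counts.values())
        if not math.isclose(table.total, meta["total"], rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("sidecar total does not match counts")
        return table


def build_table(pairs: list[WindowPair], label: str) -> ContingencyTable:
    """Aggregate window pairs into a contingency table."""
    table = ContingencyTable(label=label)
    for p in pairs:
        if p.label != label:
            raise ValueError(f"pair labelled {p.label!r} fed to {label!r} table")
        table.add(p.seq4, p.code4)
    return table


def scale_table(
    small: ContingencyTable, large: ContingencyTable
) -> tuple[ContingencyTable, float]:
    """Scale the smaller table's counts by the size ratio of the two sets.

    Counts remain real-valued; the factor is recorded on the copy.
    """
    if small.total <= 0 or large.total <= 0:
        raise ValueError("empty set: both tables need positive totals")
    if small.total > large.total:
        raise ValueError("first argument must be the smaller-total table")
    factor = large.total / small.total
    scaled = small.copy()
    scaled.counts = {k: w * factor for k, w in scaled.counts.items()}
    scaled.total = small.total * factor
    scaled.scale_factor = small.scale_factor * factor
    return scaled, factor


def scale_smaller(
    a: ContingencyTable, b: ContingencyTable
) -> tuple[ContingencyTable, ContingencyTable, float]:
    """Return (a, b) with whichever has the smaller total scaled up."""
    if a.total <= b.total:
        scaled, factor = scale_table(a, b)
        return scaled, b, factor
    scaled, factor = scale_table(b, a)
    return a, scaled, factor


def pearson_r(x, y) -> float:
    """Product-moment correlation; raises on constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def large_sample_critical(alpha: float = 0.05) -> float:
    """Two-sided standard-normal critical value at the given alpha."""
    return float(norm.ppf(1.0 - alpha / 2.0))


def significance(
    r: float, n: int, alpha: float = 0.05, critical: float = 1.96
) -> tuple[float, bool]:
    """z = r sqrt(n-2)/sqrt(1-r^2) against the large-sample critical value."""
    if n < 3:
        raise ValueError("insufficient n for a significance test")
    if abs(r) >= 1.0:
        return math.copysign(math.inf, r), True
    z = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return z, abs(z) >= critical


@dataclass(frozen=True)
class CorrelationRecord:
    key: str
    r: float
    z_stat: float
    n: int
    significant: bool
    sign: str  # "positive" | "negative" | "none"


def _sparse_pearson(
    xs: dict, ys: dict, n_cells: int, cells: str
) -> tuple[float, int]:
    """Pearson r between two sparse nonnegative vectors of dimension n_cells.

    ``cells='all'`` uses every canonical cell (zeros included);
    ``cells='joint_nonzero'`` restricts to cells nonzero in both vectors.
    """
    if cells == "joint_nonzero":
        keys = sorted(set(xs) & set(ys))
        n = len(keys)
        if n < 3:
            raise UndefinedCorrelationError("fewer than 3 jointly nonzero cells")
        x = np.array([xs[k] for k in keys])
        y = np.array([ys[k] for k in keys])
        return pearson_r(x, y), n
    n = n_cells
    sx = sum(xs.values())
    sy = sum(ys.values())
    sxx = sum(v * v for v in xs.values())
    syy = sum(v * v for v in ys.values())
    sxy = sum(xs[k] * ys.get(k, 0.0) for k in xs)
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        raise UndefinedCorrelationError("constant vector")
    return float((n * sxy - sx * sy) / math.sqrt(vx * vy)), n


def correlation_screen(
    compliant: ContingencyTable,
    noncompliant: ContingencyTable,
    mode: str = "columns",
    alpha: float = 0.05,
    critical: float = 1.96,
    cells: str = "all",
) -> list[CorrelationRecord]:
    """Correlate the two tables column-by-column or row-by-row.

    One record per key occupied in at least one table, sorted by key.
    Keys whose correlation is undefined (constant or empty vector) are
    flagged sign='none', not significant.
    """
    if mode not in ("columns", "rows"):
        raise ValueError("mode must be 'columns' or 'rows'")
    if cells not in ("all", "joint_nonzero"):
        raise ValueError("cells must be 'all' or 'joint_nonzero'")
    if not compliant.counts and not noncompliant.counts:
        raise ValueError("nothing to screen: both tables empty")
    if mode == "columns":
        ga, gb = compliant.by_column(), noncompliant.by_column()
        n_cells = N_CODE4
    else:
        ga, gb = compliant.by_row(), noncompliant.by_row()
        n_cells = N_SEQ4
    records = []
    for key in sorted(set(ga) | set(gb)):
        xs = ga.get(key, {})
        ys = gb.get(key, {})
        try:
            r, n = _sparse_pearson(xs, ys, n_cells, cells)
            z, sig = significance(r, n, alpha=alpha, critical=critical)
            sign = "positive" if r > 0 else ("negative" if r < 0 else "none")
        except UndefinedCorrelationError:
            r, z, n, sig, sign = float("nan"), float("nan"), n_cells, False, "none"
        records.append(
            CorrelationRecord(key=key, r=r, z_stat=z, n=n, significant=sig, sign=sign)
        )
    return records


def negative_significant(records: list[CorrelationRecord]) -> list[CorrelationRecord]:
    """Significantly negative keys, sorted — the report of interest."""
    return sorted(
        (r for r in records if r.significant and r.sign == "negative"),
        key=lambda r: r.key,
    )


def export_screen(records: list[CorrelationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tr\tz\tn\tsignificant\tsign\n")
        for rec in records:
            fh.write(
                f"{rec.key}\t{rec.r:.6f}\t{rec.z_stat:.4f}\t{rec.n}\t"
                f"{int(rec.significant)}\t{rec.sign}\n"
            )
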