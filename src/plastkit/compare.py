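"""Whole-plastome comparison.

Inverted-repeat (quadripartite) boundary detection, pairwise substitution
and indel distances on alignments, MISA-style SSR discovery and cross-genome
SSR polymorphism.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Plastome, revcomp, validate_sequence

UNAMBIGUOUS = frozenset("ACGT")
GAP = "-"

# MISA-style thresholds: mononucleotide runs must be longer than five
# nucleotides; di-/trinucleotide repeats need >= 4 units; tetra- to
# hexanucleotide repeats need >= 3 units.
MONO_MIN_LENGTH = 6
MIN_UNITS = {2: 4, 3: 4, 4: 3, 5: 3, 6: 3}


# ---------------------------------------------------------------------------
# inverted repeats


@dataclass(frozen=True)
class QuadripartiteStructure:
    """Result of inverted-repeat detection on a linearised plastome.

    All intervals are 0-based half-open. When no inverted repeat of at
    least ``min_ir`` exists, ``has_ir`` is False and only ``lsc_pieces``
    (the whole sequence) is populated.
    """

    has_ir: bool
    ira: tuple[int, int] | None = None
    irb: tuple[int, int] | None = None
    ssc: tuple[int, int] | None = None
    lsc: tuple[int, int] | None = None
    #: the long single-copy region as linear pieces (it may wrap the origin)
    lsc_pieces: tuple[tuple[int, int], ...] = ()

    @property
    def ir_length(self) -> int:
        return 0 if self.ira is None else self.ira[1] - self.ira[0]

    def as_boundaries(self) -> dict[str, tuple[int, int]]:
        """Boundary dict for :class:`Plastome`; requires a contiguous LSC."""
        if not self.has_ir or self.lsc is None:
            raise ValueError("quadripartite boundaries require a contiguous LSC")
        return {"LSC": self.lsc, "IRa": self.ira, "SSC": self.ssc, "IRb": self.irb}


def _window_hashes(codes: np.ndarray, length: int, base: int, mod: int) -> np.ndarray:
    """Polynomial rolling hashes of every window of ``length`` (vectorised)."""
    n = codes.size
    if length > n:
        return np.empty(0, dtype=object)
    # python ints: no overflow concerns at 61-bit modulus
    power = pow(base, length - 1, mod)
    out = [0] * (n - length + 1)
    c = codes.tolist()
    h = 0
    for i in range(length):
        h = (h * base + c[i]) % mod
    out[0] = h
    for i in range(1, n - length + 1):
        h = ((h - c[i - 1] * power) % mod * base + c[i + length - 1]) % mod
        out[i] = h
    return np.array(out, dtype=object)


def _best_disjoint_pair(seq: str, rc: str, length: int) -> tuple[int, int] | None:
    """Leftmost pair of disjoint intervals (a_start, b_start) with
    seq[a:a+L] == revcomp(seq[b:b+L]), or None."""
    n = len(seq)
    mod = (1 << 61) - 1
    base = 1_000_003
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    rcodes = np.frombuffer(rc.encode(), dtype=np.uint8)
    fwd = _window_hashes(codes, length, base, mod)
    rev = _window_hashes(rcodes, length, base, mod)
    table: dict[int, list[int]] = {}
    for i, h in enumerate(fwd):
        table.setdefault(h, []).append(i)
    best: tuple[int, int] | None = None
    for j, h in enumerate(rev):
        hits = table.get(h)
        if not hits:
            continue
        # rc window j corresponds to seq interval [n-j-L, n-j)
        b = n - j - length
        for a in hits:
            lo, hi = (a, b) if a <= b else (b, a)
            if lo + length > hi:  # overlapping
                continue
            if seq[a:a + length] != rc[j:j + length]:  # hash collision
                continue
            cand = (lo, hi)
            if best is None or cand < best:
                best = cand
    return best


def find_inverted_repeats(sequence: str | Plastome, min_ir: int = 1000) -> QuadripartiteStructure:
    """Detect the quadripartite structure of a linearised plastome.

    Finds the longest pair of disjoint intervals whose sequences are exact
    reverse complements (leftmost-start pair on ties), labels the leftmost
    IRa, and derives SSC (the shorter single-copy stretch) and LSC. With no
    inverted repeat of at least ``min_ir``, a single-copy-only structure is
    reported.
    """
    if isinstance(sequence, Plastome):
        sequence = sequence.sequence
    seq = validate_sequence(sequence)
    n = len(seq)
    if n < 4 * min_ir:
        raise ValueError(f"sequence length {n} is below 4 x min_ir ({4 * min_ir})")
    rc = revcomp(seq)
    if _best_disjoint_pair(seq, rc, min_ir) is None:
        return QuadripartiteStructure(has_ir=False, lsc_pieces=((0, n),))
    lo, hi = min_ir, n // 2
    while lo < hi:  # largest L with a disjoint reverse-complement pair
        mid = (lo + hi + 1) // 2
        if _best_disjoint_pair(seq, rc, mid) is not None:
            lo = mid
        else:
            hi = mid - 1
    length = lo
    a, b = _best_disjoint_pair(seq, rc, length)
    ira, irb = (a, a + length), (b, b + length)
    inner = (ira[1], irb[0])
    outer = tuple(p for p in ((0, ira[0]), (irb[1], n)) if p[1] > p[0])
    inner_len = inner[1] - inner[0]
    outer_len = sum(e - s for s, e in outer)
    if inner_len <= outer_len:
        ssc = inner
        lsc = outer[0] if len(outer) == 1 else None
        pieces = outer
    else:
        ssc = outer[0] if len(outer) == 1 else None
        lsc = inner
        pieces = (inner,)
    return QuadripartiteStructure(True, ira, irb, ssc, lsc, pieces)


# ---------------------------------------------------------------------------
# alignment distances


def _check_pair(a: str, b: str) -> tuple[str, str]:
    if len(a) != len(b):
        raise ValueError(f"aligned rows differ in length ({len(a)} vs {len(b)})")
    return a.upper(), b.upper()


def count_substitutions(a: str, b: str) -> int:
    """Substitution count between two aligned rows.

    Counts columns where both rows carry unambiguous, non-gap bases that
    differ; gap and N/ambiguity columns are skipped (snp-dists semantics).
    """
    a, b = _check_pair(a, b)
    return sum(
        1 for x, y in zip(a, b)
        if x != y and x in UNAMBIGUOUS and y in UNAMBIGUOUS
    )


def count_indels(a: str, b: str, model: str = "indelblock") -> int:
    """Indel distance between two aligned rows.

    model="indel" counts columns gapped in exactly one row; "indelblock"
    counts maximal runs of such columns (one event per contiguous gap).
    """
    a, b = _check_pair(a, b)
    if model not in ("indel", "indelblock"):
        raise ValueError(f"unknown indel model {model!r}")
    flags = [(x == GAP) != (y == GAP) for x, y in zip(a, b)]
    if model == "indel":
        return sum(flags)
    return sum(1 for prev, cur in zip([False] + flags, flags) if cur and not prev)


def distance_matrices(
    rows: dict[str, str], indel_model: str = "indelblock"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric substitution and indel count matrices over aligned genomes."""
    ids = list(rows)
    subs = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    indels = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, x in enumerate(ids):
        for y in ids[i + 1:]:
            s = count_substitutions(rows[x], rows[y])
            d = count_indels(rows[x], rows[y], indel_model)
            subs.loc[x, y] = subs.loc[y, x] = s
            indels.loc[x, y] = indels.loc[y, x] = d
    return subs, indels


# ---------------------------------------------------------------------------
# SSRs


@dataclass(frozen=True)
class SSRLocus:
    """A maximal simple-sequence-repeat locus.

    ``unit`` is the observed leftmost phase; ``canonical_unit`` its
    lexicographically smallest rotation (used to group homologous loci).
    """

    genome_id: str
    start: int  # 0-based
    unit: str
    unit_length: int
    unit_count: int

    @property
    def total_length(self) -> int:
        return self.unit_length * self.unit_count

    @property
    def end(self) -> int:
        return self.start + self.total_length

    @property
    def canonical_unit(self) -> str:
        u = self.unit
        return min(u[i:] + u[:i] for i in range(len(u)))


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def _true_runs(mask: np.ndarray):
    """(start, length) of maximal runs of True."""
    if mask.size == 0:
        return
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        yield int(s), int(e - s)


def find_ssrs(obj: str | Plastome, genome_id: str = "") -> list[SSRLocus]:
    """Maximal tandem repeats of 1-6 bp units meeting the length thresholds.

    Loci whose unit is itself periodic (ATAT = 2 x AT) are reported at the
    smallest unit length only. Runs containing N are broken at the N. The
    scan is linear (no origin-spanning repeats).
    """
    if isinstance(obj, Plastome):
        seq, gid = obj.sequence, obj.id
    else:
        seq, gid = validate_sequence(obj), genome_id
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = arr != ord("N")
    loci: list[SSRLocus] = []
    for u in range(1, 7):
        if n < 2 * u:
            break
        eq = (arr[:-u] == arr[u:]) & valid[:-u] & valid[u:]
        for s, m in _true_runs(eq):
            units = (m + u) // u  # full units in the periodic span of m+u bases
            if u == 1:
                if units < MONO_MIN_LENGTH:
                    continue
            elif units < MIN_UNITS[u]:
                continue
            unit = seq[s:s + u]
            if not _is_primitive(unit):
                continue
            loci.append(SSRLocus(gid, s, unit, u, units))
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def ssr_table(loci: list[SSRLocus]) -> pd.DataFrame:
    """SSR loci as a table (start emitted 1-based)."""
    return pd.DataFrame(
        {
            "genome": [l.genome_id for l in loci],
            "start": [l.start + 1 for l in loci],
            "unit": [l.unit for l in loci],
            "unit_length": [l.unit_length for l in loci],
            "unit_count": [l.unit_count for l in loci],
            "total_length": [l.total_length for l in loci],
        }
    )


# ---------------------------------------------------------------------------
# SSR polymorphism across genomes


def _column_of(ungapped_pos: np.ndarray, row: str) -> np.ndarray:
    """Map ungapped positions of a row to alignment columns."""
    cols = np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord(GAP))
    return cols[ungapped_pos]


def ssr_polymorphism(
    loci_by_genome: dict[str, list[SSRLocus]], alignment: dict[str, str]
) -> pd.DataFrame:
    """Group homologous SSR loci via alignment coordinates and flag variation.

    Returns one row per homologous locus group with per-genome unit counts
    (NaN where the locus is absent), a ``variable`` flag (unit counts differ
    or locus absent in some genome) and a ``mononucleotide`` flag: mono loci
    are prone to within-individual heteroplasmy and are excluded from the
    recommended-marker list (filter on ``mononucleotide == False``).
    """
    genomes = list(alignment)
    records = []
    for g in genomes:
        row = alignment[g]
        for loc in loci_by_genome.get(g, []):
            pos = np.array([loc.start, loc.end - 1])
            cols = _column_of(pos, row)
            records.append((g, loc, int(cols[0]), int(cols[1]) + 1))
    records.sort(key=lambda r: r[2])
    groups: list[dict] = []
    for g, loc, c0, c1 in records:
        placed = False
        for grp in groups:
            if (
                grp["unit_length"] == loc.unit_length
                and grp["unit"] == loc.canonical_unit
                and c0 < grp["col_end"]
                and c1 > grp["col_start"]
            ):
                grp["col_start"] = min(grp["col_start"], c0)
                grp["col_end"] = max(grp["col_end"], c1)
                grp["counts"][g] = loc.unit_count
                placed = True
                break
        if not placed:
            groups.append(
                {
                    "unit": loc.canonical_unit,
                    "unit_length": loc.unit_length,
                    "col_start": c0,
                    "col_end": c1,
                    "counts": {g: loc.unit_count},
                }
            )
    rows = []
    for i, grp in enumerate(groups):
        counts = {g: grp["counts"].get(g) for g in genomes}
        present = [c for c in counts.values() if c is not None]
        variable = len(set(present)) > 1 or len(present) < len(genomes)
        rows.append(
            {
                "group": i,
                "unit": grp["unit"],
                "unit_length": grp["unit_length"],
                "column_start": grp["col_start"] + 1,  # 1-based
                **{f"count_{g}": counts[g] for g in genomes},
                "variable": variable,
                "mononucleotide": grp["unit_length"] == 1,
            }
        )
    return pd.DataFrame(rows)


def variable_ssr_positions(poly: pd.DataFrame) -> pd.DataFrame:
    """Recommended variable markers: non-mononucleotide variable loci."""
    if poly.empty:
        return poly
    return poly[poly["variable"] & ~poly["mononucleotide"]].reset_index(drop=True)
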