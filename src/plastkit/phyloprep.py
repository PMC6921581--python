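"""Phylogenetic input preparation.

IRa removal from whole-plastome alignments, homopolymer masking outside
coding sequence, codon-aware CDS concatenation with partition export, and
simple indel coding (Simmons & Ochoterena 2000) of gap characters. Tree
inference itself is out of scope; writers emit FASTA / relaxed PHYLIP,
RAxML-style partition text and a NEXUS with the binary indel partition.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GeneFeature, Plastome

GAP = "-"


def _ref_columns(row: str) -> np.ndarray:
    """Alignment column of every ungapped position of a row."""
    return np.flatnonzero(np.frombuffer(row.encode(), dtype=np.uint8) != ord(GAP))


@dataclass
class MaskedAlignment:
    """An alignment plus a column mask with provenance.

    ``masked_columns`` indexes columns of ``rows`` (the original alignment);
    ``without_masked()`` drops them. The mask log records (column, row,
    reason) triples so the operation is fully reconstructible.
    """

    rows: dict[str, str]
    masked_columns: list[int] = field(default_factory=list)
    log: list[tuple[int, str, str]] = field(default_factory=list)
    provenance: str = ""

    def without_masked(self) -> dict[str, str]:
        drop = set(self.masked_columns)
        return {
            g: "".join(c for i, c in enumerate(s) if i not in drop)
            for g, s in self.rows.items()
        }

    def mask_log_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"column": c + 1, "row": r, "reason": why} for c, r, why in self.log]
        )


def remove_ira(
    alignment: dict[str, str], ira: tuple[int, int] | None, reference: str
) -> tuple[dict[str, str], np.ndarray]:
    """Cut the columns of the IRa interval (reference coordinates) from a
    whole-plastome alignment.

    Returns the trimmed alignment and the kept-column indices (into the
    input alignment) for coordinate mapping. Gap-only columns of the
    reference that fall between the first and last IRa column are removed
    with it.
    """
    if ira is None:
        raise ValueError("IRa boundaries are required to cut the alignment")
    ref = alignment[reference]
    cols = _ref_columns(ref)
    start, end = ira
    c0, c1 = int(cols[start]), int(cols[end - 1]) + 1
    n = len(ref)
    keep = np.concatenate([np.arange(0, c0), np.arange(c1, n)])
    out = {g: "".join(s[i] for i in keep) for g, s in alignment.items()}
    return out, keep


def mask_homopolymers(
    alignment: dict[str, str],
    cds_features: list[GeneFeature] | None = None,
    reference: str | None = None,
    max_run: int = 5,
) -> MaskedAlignment:
    """Mask columns belonging to mononucleotide runs longer than ``max_run``.

    Run length is measured on the ungapped sequence of each row; the union
    of implicated columns over rows is masked (rows may disagree on run
    length). Masking is restricted to non-coding sequence: columns mapping
    to a reference CDS position are exempt when ``cds_features`` and
    ``reference`` are given.
    """
    masked: set[int] = set()
    log: list[tuple[int, str, str]] = []
    for g, row in alignment.items():
        cols = _ref_columns(row)
        seq = row.replace(GAP, "")
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i > max_run and seq[i] != "N":
                for k in range(i, j):
                    c = int(cols[k])
                    if c not in masked:
                        log.append((c, g, f"homopolymer {seq[i]}x{j - i}"))
                    masked.add(c)
            i = j
    if cds_features is not None and reference is not None:
        refcols = _ref_columns(alignment[reference])
        cds_cols: set[int] = set()
        for f in cds_features:
            for a, b in f.exons:
                cds_cols.update(int(c) for c in refcols[a:b])
        masked -= cds_cols
        log = [(c, g, why) for c, g, why in log if c not in cds_cols]
    return MaskedAlignment(
        rows=dict(alignment),
        masked_columns=sorted(masked),
        log=sorted(log),
    )


# ---------------------------------------------------------------------------
# simple indel coding


@dataclass
class IndelCharacterMatrix:
    """Binary characters from simple indel coding.

    One character per distinct gap block (identical start and end columns);
    states: '1' the taxon has exactly that block, '0' it has nucleotides
    across the block's span, '?' its gap strictly contains the span
    (inapplicable).
    """

    taxa: list[str]
    blocks: list[tuple[int, int]]  # 0-based half-open column intervals
    states: dict[str, str]  # taxon -> string over {0,1,?}

    @property
    def n_characters(self) -> int:
        return len(self.blocks)


def _gap_blocks(row: str) -> list[tuple[int, int]]:
    blocks = []
    i = 0
    n = len(row)
    while i < n:
        if row[i] == GAP:
            j = i
            while j < n and row[j] == GAP:
                j += 1
            blocks.append((i, j))
            i = j
        else:
            i += 1
    return blocks


def simple_indel_coding(alignment: dict[str, str]) -> IndelCharacterMatrix:
    """Code each distinct gap block of the alignment as a binary character
    (Simmons & Ochoterena 2000, "simple" variant).

    Two gaps are the same character iff their start and end columns are
    identical. A taxon scores 1 for its own blocks, ? where a longer gap of
    its strictly contains another taxon's block, and 0 otherwise (including
    partially overlapping gaps, which are distinct events under simple
    coding).
    """
    taxa = list(alignment)
    per_taxon = {t: _gap_blocks(alignment[t]) for t in taxa}
    blocks = sorted({b for bl in per_taxon.values() for b in bl})
    states: dict[str, str] = {}
    for t in taxa:
        own = set(per_taxon[t])
        chars = []
        for b in blocks:
            if b in own:
                chars.append("1")
            elif any(
                g[0] <= b[0] and b[1] <= g[1] and g != b for g in per_taxon[t]
            ):
                chars.append("?")
            else:
                chars.append("0")
        states[t] = "".join(chars)
    return IndelCharacterMatrix(taxa=taxa, blocks=blocks, states=states)


# ---------------------------------------------------------------------------
# CDS concatenation


@dataclass
class Supermatrix:
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (name, start, end) 0-based half-open
    missing_genes: list[tuple[str, str]] = field(default_factory=list)  # (genome, gene)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))


def concatenate_cds(genomes: dict[str, Plastome]) -> Supermatrix:
    """Concatenate unique protein-coding genes into a codon-aware supermatrix.

    Genes are taken once per IR-duplicated copy and concatenated in
    alphabetical order of gene name (the documented fixed order). A gene
    absent from a genome is filled with '?' and logged. Gene lengths must
    agree across the genomes that carry them (the operation concatenates,
    it does not align).
    """
    gene_names = sorted({f.name for p in genomes.values() for f in p.cds_features()})
    pieces: dict[str, list[str]] = {g: [] for g in genomes}
    partitions: list[tuple[str, int, int]] = []
    missing: list[tuple[str, str]] = []
    offset = 0
    for gene in gene_names:
        seqs: dict[str, str] = {}
        for g, p in genomes.items():
            try:
                seqs[g] = p.feature(gene).extract(p.sequence)
            except KeyError:
                seqs[g] = ""
        lengths = {len(s) for s in seqs.values() if s}
        if len(lengths) != 1:
            raise ValueError(
                f"gene {gene}: CDS lengths differ across genomes ({sorted(lengths)}); "
                "align per-gene before concatenation"
            )
        (L,) = lengths
        for g in genomes:
            if seqs[g]:
                pieces[g].append(seqs[g])
            else:
                pieces[g].append("?" * L)
                missing.append((g, gene))
        partitions.append((gene, offset, offset + L))
        offset += L
    return Supermatrix(
        rows={g: "".join(p) for g, p in pieces.items()},
        partitions=partitions,
        missing_genes=missing,
    )


# ---------------------------------------------------------------------------
# writers


def write_fasta_alignment(rows: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for g, s in rows.items():
            fh.write(f">{g}\n{s}\n")


def write_phylip(rows: dict[str, str], path) -> None:
    """Relaxed PHYLIP (names of any length, space-separated)."""
    n = len(rows)
    L = len(next(iter(rows.values())))
    with open(path, "w") as fh:
        fh.write(f" {n} {L}\n")
        for g, s in rows.items():
            fh.write(f"{g}  {s}\n")


def write_raxml_partitions(partitions, path, indel_characters: int = 0) -> None:
    """RAxML-style partition file; column ranges are 1-based inclusive."""
    with open(path, "w") as fh:
        for name, a, b in partitions:
            fh.write(f"DNA, {name} = {a + 1}-{b}\n")
        if indel_characters:
            last = partitions[-1][2] if partitions else 0
            fh.write(f"BIN, indels = {last + 1}-{last + indel_characters}\n")


def write_nexus(
    rows: dict[str, str], path, indels: IndelCharacterMatrix | None = None
) -> None:
    """NEXUS with a DNA matrix and an optional binary indel partition
    (datatype=mixed, MrBayes style; binary symbols 0/1, missing ?)."""
    taxa = list(rows)
    dna_len = len(next(iter(rows.values())))
    bin_len = indels.n_characters if indels is not None else 0
    total = dna_len + bin_len
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"  dimensions ntax={len(taxa)} nchar={total};\n")
        if bin_len:
            fh.write(
                "  format datatype=mixed(DNA:1-%d,restriction:%d-%d) gap=- missing=?;\n"
                % (dna_len, dna_len + 1, total)
            )
        else:
            fh.write("  format datatype=DNA gap=- missing=?;\n")
        fh.write("  matrix\n")
        for t in taxa:
            extra = indels.states[t] if bin_len else ""
            fh.write(f"  {t}  {rows[t]}{extra}\n")
        fh.write("  ;\nend;\n")
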