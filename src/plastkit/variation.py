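"""Protein-coding variation across aligned plastomes.

Segregating-site classification (synonymous vs non-synonymous, DnaSP-style
semantics), per-gene summaries, and pairwise Ka/Ks by the Nei-Gojobori
(1986) counting method with Jukes-Cantor correction.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

UNAMBIGUOUS = frozenset("ACGT")

#: NCBI translation table 11 (bacterial / plant plastid)
PLASTID_TABLE_ID = 11


def _code(table_id: int) -> tuple[dict[str, str], set[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(tbl.forward_table)
    stops = set(tbl.stop_codons)
    return fwd, stops


def translate_codon(codon: str, table_id: int = PLASTID_TABLE_ID) -> str:
    fwd, stops = _code(table_id)
    if codon in stops:
        return "*"
    return fwd[codon]


@dataclass(frozen=True)
class SegregatingSite:
    """One variable nucleotide position in an in-frame gene alignment."""

    gene: str
    column: int  # 0-based position in the (gap-codon-stripped) alignment
    codon_index: int  # 0-based
    codon_position: int  # 1..3
    alleles: tuple[tuple[str, str], ...]  # (genome, base)
    synonymous: bool
    creates_stop: bool


@dataclass
class SiteClassification:
    sites: list[SegregatingSite]
    excluded_codons: int  # codons skipped due to gaps/N in any genome


def classify_segregating_sites(
    alignment: dict[str, str], gene: str, table_id: int = PLASTID_TABLE_ID
) -> SiteClassification:
    """Classify segregating sites in an in-frame gene alignment.

    A site segregates if at least two distinct unambiguous bases occur
    across the aligned genomes. It is non-synonymous if any observed allele
    changes the encoded amino acid relative to any other allele in its codon
    context, each genome's other two codon positions held at their own
    states. Codons containing gaps or N in any genome are excluded (tallied
    in ``excluded_codons``). Alleles creating a premature stop are flagged.
    """
    rows = {g: s.upper() for g, s in alignment.items()}
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"gene {gene}: aligned rows differ in length")
    (length,) = lengths
    if length % 3 != 0:
        raise ValueError(f"gene {gene}: alignment length {length} not divisible by 3")
    fwd, stops = _code(table_id)

    def aa(codon: str) -> str:
        return "*" if codon in stops else fwd[codon]

    genomes = list(rows)
    n_codons = length // 3
    sites: list[SegregatingSite] = []
    excluded = 0
    for ci in range(n_codons):
        codons = {g: rows[g][3 * ci:3 * ci + 3] for g in genomes}
        if any(set(c) - UNAMBIGUOUS for c in codons.values()):
            excluded += 1
            continue
        for p in range(3):
            bases = {g: codons[g][p] for g in genomes}
            observed = set(bases.values())
            if len(observed) < 2:
                continue
            nonsyn = False
            stop_flag = False
            for g, h in itertools.combinations(genomes, 2):
                if bases[g] == bases[h]:
                    continue
                for src, other in ((g, h), (h, g)):
                    c0 = codons[src]
                    c1 = c0[:p] + bases[other] + c0[p + 1:]
                    if aa(c0) != aa(c1):
                        nonsyn = True
                    if (aa(c1) == "*" or aa(c0) == "*") and ci < n_codons - 1:
                        stop_flag = True
            sites.append(
                SegregatingSite(
                    gene=gene,
                    column=3 * ci + p,
                    codon_index=ci,
                    codon_position=p + 1,
                    alleles=tuple(sorted(bases.items())),
                    synonymous=not nonsyn,
                    creates_stop=stop_flag,
                )
            )
    return SiteClassification(sites, excluded)


def summarize_genes(
    sites_by_gene: dict[str, list[SegregatingSite]], genes: list[str]
) -> pd.DataFrame:
    """Partition genes into identical / synonymous-only / has-nonsynonymous.

    ``genes`` must list every unique protein-coding gene under comparison
    (IR duplicates once); genes without sites are classed "identical".
    """
    rows = []
    for g in genes:
        sites = sites_by_gene.get(g, [])
        n_syn = sum(1 for s in sites if s.synonymous)
        n_non = sum(1 for s in sites if not s.synonymous)
        if n_syn == n_non == 0:
            cls = "identical"
        elif n_non == 0:
            cls = "synonymous_only"
        else:
            cls = "has_nonsynonymous"
        rows.append({"gene": g, "synonymous_sites": n_syn,
                     "nonsynonymous_sites": n_non, "class": cls})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks


@dataclass
class KaKsResult:
    """Pairwise Ka/Ks by NG86 counting with Jukes-Cantor correction.

    ``ka_ks`` is None when Ks = 0 (undefined ratio). ``undefined_correction``
    flags pN or pS >= 3/4 where the Jukes-Cantor transform does not exist;
    the uncorrected proportions are always reported.
    """

    gene: str
    pair: tuple[str, str]
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    ka_ks: float | None
    excluded_codons: int
    undefined_correction: bool = False


def _codon_sites(codon: str, fwd, stops) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to or from a stop codon count as
    non-synonymous.
    """
    def aa(c):
        return "*" if c in stops else fwd[c]
    syn = 0.0
    a0 = aa(codon)
    for p in range(3):
        s = 0
        for b in "ACGT":
            if b == codon[p]:
                continue
            c1 = codon[:p] + b + codon[p + 1:]
            if aa(c1) == a0 and a0 != "*":
                s += 1
        syn += s / 3.0
    return syn, 3.0 - syn


def _pathway_diffs(c1: str, c2: str, fwd, stops) -> tuple[float, float]:
    """Synonymous/non-synonymous differences between two codons, averaged
    over all minimal mutational pathways with equal weights; pathways passing
    through a stop codon are excluded (all pathways used if none survive)."""
    def aa(c):
        return "*" if c in stops else fwd[c]
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        steps = []
        through_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            steps.append((cur, nxt))
            if aa(nxt) == "*" and nxt != c2:
                through_stop = True
            cur = nxt
        paths.append((through_stop, steps))
    usable = [steps for stop, steps in paths if not stop] or [s for _, s in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if aa(a) == aa(b) and aa(a) != "*":
                syn += 1
            else:
                nonsyn += 1
    k = len(usable)
    return syn / k, nonsyn / k


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - 4.0 * p / 3.0)


def kaks_pairwise(
    seq1: str,
    seq2: str,
    gene: str = "",
    pair: tuple[str, str] = ("seq1", "seq2"),
    table_id: int = PLASTID_TABLE_ID,
    jc_correction: bool = True,
) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks between two aligned in-frame sequences.

    Codons containing gaps, N or a stop in either sequence are excluded from
    both site and difference counts. Set ``jc_correction=False`` for the raw
    proportions pN/pS (both variants are of interest because the exact
    DnaSP setting behind published matrices is rarely stated).
    """
    s1, s2 = seq1.upper(), seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    if len(s1) % 3:
        raise ValueError(f"gene {gene or '<pair>'}: length not divisible by 3")
    fwd, stops = _code(table_id)
    S = N = Sd = Nd = 0.0
    excluded = 0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i:i + 3], s2[i:i + 3]
        if set(c1) - UNAMBIGUOUS or set(c2) - UNAMBIGUOUS or c1 in stops or c2 in stops:
            excluded += 1
            continue
        s_1, n_1 = _codon_sites(c1, fwd, stops)
        s_2, n_2 = _codon_sites(c2, fwd, stops)
        S += (s_1 + s_2) / 2.0
        N += (n_1 + n_2) / 2.0
        sd, nd = _pathway_diffs(c1, c2, fwd, stops)
        Sd += sd
        Nd += nd
    if S == 0 and N == 0:
        raise ValueError(f"gene {gene or '<pair>'}: no analysable codons")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    if jc_correction:
        ks, ka = _jc(ps), _jc(pn)
        undefined = (ks is None and ps > 0) or (ka is None and pn > 0)
    else:
        ks, ka = ps, pn
        undefined = False
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(
        gene=gene, pair=pair, syn_sites=S, nonsyn_sites=N,
        syn_diffs=Sd, nonsyn_diffs=Nd, ps=ps, pn=pn,
        ks=ks, ka=ka, ka_ks=ratio, excluded_codons=excluded,
        undefined_correction=undefined,
    )


def kaks_matrix(
    gene_alignment: dict[str, str], gene: str = "", **kwargs
) -> pd.DataFrame:
    """All pairwise Ka/Ks results for one gene alignment, one row per pair."""
    ids = list(gene_alignment)
    rows = []
    for a, b in itertools.combinations(ids, 2):
        r = kaks_pairwise(gene_alignment[a], gene_alignment[b], gene=gene,
                          pair=(a, b), **kwargs)
        nan = float("nan")
        rows.append({"gene": gene, "genome_a": a, "genome_b": b,
                     "ka": nan if r.ka is None else r.ka,
                     "ks": nan if r.ks is None else r.ks,
                     "ka_ks": nan if r.ka_ks is None else r.ka_ks,
                     "syn_sites": r.syn_sites, "nonsyn_sites": r.nonsyn_sites,
                     "syn_diffs": r.syn_diffs, "nonsyn_diffs": r.nonsyn_diffs})
    return pd.DataFrame(rows)
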