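"""Synthetic study generator with fully recorded ground truth.

Builds a toy quadripartite plastome (LSC + IRa + SSC + IRb with IRa the
exact reverse complement of IRb), derives haplotypes with planted
substitutions, indels and SSR-unit variation, constructs a mitochondrial
genome carrying diverged plastid-like inserts, and simulates stranded
paired-end RNA-seq reads from sense and antisense transcripts with planted
per-site C-to-U editing fractions across three female and three
hermaphrodite individuals per haplotype. Every planted feature is recorded
in final coordinates so each downstream stage can be checked against truth.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import compare
from .compare import SSRLocus, find_ssrs
from .model import GeneFeature, Plastome, revcomp
from .quant import ReadAlignmentSet

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is infeasible."""


_CODE2ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return bytes(_CODE2ASCII[np.asarray(codes, dtype=np.uint8)]).decode()


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# configuration and ground-truth records


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults mirror a gynodioecious-plant study design at toy scale: a 30 kb
    quadripartite plastome, two haplotypes separated by planted
    substitutions and indels, diverged plastid-like inserts in the
    mitochondrial genome, and dUTP-type stranded paired-end RNA-seq from
    three female (F) and three hermaphrodite (H) individuals per haplotype
    at a mean per-base depth of 500.
    """

    seed: int = 0
    plastome_length: int = 30_000
    ir_length: int = 4_000
    ssc_length: int | None = None  # default: a fifth of the single-copy space
    gc: float = 0.36
    n_genes: int = 14
    gene_length_range: tuple[int, int] = (300, 900)  # CDS length, bp
    intron_genes: float = 0.2
    intron_length_range: tuple[int, int] = (80, 160)
    n_haplotypes: int = 2
    n_substitutions: int = 50
    n_indels: int = 10
    indel_length_range: tuple[int, int] = (1, 8)
    ssr_variation: bool = True  # one indel alters a planted SSR's unit count
    #: planted SSR loci as (unit, unit_count); positions chosen automatically
    ssr_spec: tuple[tuple[str, int], ...] = (
        ("A", 8), ("T", 7), ("AT", 5), ("AAG", 4), ("AAAT", 3)
    )
    #: None -> two inserts placed automatically (one intergenic, one
    #: overlapping a gene tail), both at 2% divergence
    mtpt_spec: tuple[tuple[int, int, float], ...] | None = None
    mtpt_divergence: float = 0.02
    mito_length: int = 20_000
    editing_spec: tuple["EditingSpecSite", ...] | None = None
    n_antisense: int = 2
    antisense_length_range: tuple[int, int] = (160, 280)
    antisense_expression: float = 1.0
    sexes: tuple[str, ...] = ("F", "F", "F", "H", "H", "H")
    read_length: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    #: transcripts extend this far past the annotated gene span (UTRs), so
    #: coverage is flat across the coding sequence including start codons
    utr_length: int = 120
    depth: float = 500.0
    error_rate: float = 0.002
    mito_read_fraction: float = 0.05
    strandedness: str = "fr-firststrand"
    #: sd (log2) of per-transcript, per-individual expression noise
    expression_noise_sd: float = 0.1
    #: gene -> fold change applied to hermaphrodite individuals (empty: null)
    sex_fold_changes: dict[str, float] = field(default_factory=dict)
    #: relative expression per gene; None -> a fixed 0.5x..3x gradient
    expression: dict[str, float] | None = None

    def validate(self) -> None:
        if self.ir_length < 1000:
            raise ConfigurationError("ir_length must be >= 1000")
        single_copy = self.plastome_length - 2 * self.ir_length
        if single_copy < 4000:
            raise ConfigurationError(
                "plastome_length - 2*ir_length leaves too little single-copy "
                f"space ({single_copy} bp)"
            )
        if self.strandedness not in ("fr-firststrand", "fr-secondstrand"):
            raise ConfigurationError(
                f"unknown strandedness {self.strandedness!r}"
            )
        if not 0 <= self.error_rate < 0.05:
            raise ConfigurationError("error_rate must be in [0, 0.05)")


@dataclass
class EditingSpecSite:
    """A planted C-to-U editing site (coordinates of one plastome)."""

    position: int
    strand: str
    context: str  # gene name, "antisense" or "intergenic"
    rates: dict[str, float]  # haplotype id -> true editing fraction

    def rate_for(self, haplotype: str) -> float:
        return self.rates.get(haplotype, 0.0)


@dataclass
class AntisenseSpec:
    start: int
    end: int
    strand: str
    expression: float
    present_in: tuple[str, ...]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class MTPTInsert:
    """A plastid interval copied (with divergence markers) into the
    mitochondrial genome."""

    plastid_start: int
    plastid_end: int
    mito_start: int
    mito_end: int
    divergence: float
    #: (plastid position, plastome base, diverged base)
    markers: tuple[tuple[int, str, str], ...]

    @property
    def plastid_interval(self) -> tuple[int, int]:
        return (self.plastid_start, self.plastid_end)

    @property
    def size(self) -> int:
        return self.plastid_end - self.plastid_start


@dataclass
class MitoGenome:
    id: str
    sequence: str
    inserts: list[MTPTInsert]


@dataclass
class PairDiff:
    """Planted differences between a derived haplotype and the base genome."""

    base_id: str
    derived_id: str
    substitutions: list[tuple[int, str, str, int]]  # base pos, ref, alt, derived pos
    insertions: list[tuple[int, str, int]]  # base pos (before), seq, derived pos
    deletions: list[tuple[int, int, str]]  # base interval + deleted seq
    alignment: tuple[str, str]  # (base row, derived row)

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    @property
    def n_indels(self) -> int:
        return len(self.insertions) + len(self.deletions)


@dataclass
class GroundTruth:
    """Everything planted into one haplotype, in final coordinates."""

    genome_id: str
    ssrs: list[SSRLocus]
    expression: dict[str, float]
    editing_sites: list[EditingSpecSite]
    antisense: list[AntisenseSpec]
    mtpt_intervals: list[tuple[int, int, float]]
    diff: PairDiff | None = None  # vs the base haplotype; None for the base
    reserve: tuple[int, int] | None = None  # intergenic block hosting inserts


# ---------------------------------------------------------------------------
# plastome construction helpers


class _GenomeBuilder:
    """Mutable code-array genome with IR mirroring."""

    def __init__(self, codes: np.ndarray, ira: tuple[int, int], irb: tuple[int, int]):
        self.codes = codes
        self.ira = ira
        self.irb = irb

    def set_base(self, p: int, code: int) -> None:
        self.codes[p] = code
        a0, a1 = self.ira
        b0, b1 = self.irb
        if a0 <= p < a1:
            self.codes[b0 + (a1 - 1 - p)] = 3 - code
        elif b0 <= p < b1:
            self.codes[a0 + (b1 - 1 - p)] = 3 - code

    def seq(self) -> str:
        return _decode(self.codes)


def _covered(locus: SSRLocus, intervals: list[tuple[int, int]]) -> bool:
    return any(locus.start >= s and locus.end <= e for s, e in intervals)


def _break_ssrs(
    gb: _GenomeBuilder,
    rng: np.random.Generator,
    planted: list[tuple[int, int]],
    protected: set[int] | None = None,
    cds_codons: dict[int, tuple[str, tuple[int, int, int]]] | None = None,
    max_rounds: int = 300,
) -> None:
    """Mutate single bases until no SSR outside the planted intervals remains.

    ``protected`` positions are never touched. ``cds_codons`` maps genome
    positions inside coding sequence to (strand, codon genome positions in
    transcript order); mutations there must not create a stop codon.
    """
    protected = protected or set()
    for _ in range(max_rounds):
        extra = [
            l for l in find_ssrs(gb.seq())
            if not _covered(l, planted)
        ]
        if not extra:
            return
        locus = extra[0]
        fixed = False
        order = list(range(locus.start, locus.end))
        mid = locus.start + locus.total_length // 2
        order.sort(key=lambda p: abs(p - mid))
        for p in order:
            if p in protected or p <= 0 or p >= len(gb.codes) - 1:
                continue
            cur = int(gb.codes[p])
            neighbours = {int(gb.codes[p - 1]), int(gb.codes[p + 1]), cur}
            options = [b for b in range(4) if b not in neighbours]
            if not options:
                options = [b for b in range(4) if b != cur]
            if cds_codons is not None and p in cds_codons:
                strand, cpos = cds_codons[p]
                ok_options = []
                for b in options:
                    codes = [b if q == p else int(gb.codes[q]) for q in cpos]
                    if strand == "-":
                        codes = [3 - c for c in codes]
                    codon = "".join(_BASES[c] for c in codes)
                    if codon not in _STOPS:
                        ok_options.append(b)
                options = ok_options
            if options:
                gb.set_base(p, int(rng.choice(options)))
                fixed = True
                break
        if not fixed:
            raise ConfigurationError(
                f"cannot break spurious SSR at {locus.start} without touching "
                "protected positions"
            )
    raise ConfigurationError("SSR cleaning did not converge")


def _write_transcript_codon(
    gb: _GenomeBuilder, feature: GeneFeature, codon_index: int, codon: str
) -> None:
    tpos = feature.transcript_positions()
    for k, base in enumerate(codon):
        p = tpos[3 * codon_index + k]
        code = "ACGT".index(base)
        if feature.strand == "-":
            code = 3 - code
        gb.set_base(p, code)


def _transcript_codon_map(
    feature: GeneFeature,
) -> dict[int, tuple[str, tuple[int, int, int]]]:
    """genome position -> (strand, its codon's genome positions in
    transcript order), for stop-safe mutation inside coding sequence."""
    out: dict[int, tuple[str, tuple[int, int, int]]] = {}
    tpos = feature.transcript_positions()
    for ci in range(len(tpos) // 3):
        triple = tuple(tpos[3 * ci:3 * ci + 3])
        for p in triple:
            out[p] = (feature.strand, triple)
    return out


# default editing plan: (codon, edited codon position 1..3, rates-or-float)
# covering high/intermediate/low rates, a silent edit, a premature-stop edit,
# an edited start codon, a haplotype-private site and an alternative-trigger
# low-rate site, mirroring the variety of the emulated study.
_DEFAULT_EDIT_PLAN = [
    ("TCA", 2, 0.95, "nonsyn"),
    ("TCA", 2, 0.90, "nonsyn"),
    ("TCA", 2, 0.80, "nonsyn"),
    ("CAT", 1, 0.70, "nonsyn"),
    ("TCA", 2, 0.50, "nonsyn"),
    ("GTC", 3, 0.40, "silent"),
    ("CAA", 1, 0.10, "stop"),
    ("ACG", 2, 0.15, "start"),
    ("TCA", 2, "private", "nonsyn"),  # 0 in haplotype A, 6% elsewhere
    ("TCA", 2, 0.02, "low"),
]


def make_plastome(config: SimulationConfig) -> tuple[Plastome, GroundTruth]:
    """Build the base haplotype ("A") with all planted features recorded.

    The genome is laid out LSC + IRa + SSC + IRb; genes, SSR loci, editing
    sites and the intergenic reserve hosting MTPT source intervals all live
    in the single-copy regions. Byte-identical output for equal seeds.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    L, ir = config.plastome_length, config.ir_length
    single = L - 2 * ir
    ssc = config.ssc_length if config.ssc_length is not None else single // 5
    lsc = single - ssc
    if min(lsc, ssc) < 1500:
        raise ConfigurationError("LSC/SSC too short; adjust ssc_length or ir_length")
    ira_iv = (lsc, lsc + ir)
    irb_iv = (lsc + ir + ssc, L)

    p = np.array([(1 - config.gc) / 2, config.gc / 2,
                  config.gc / 2, (1 - config.gc) / 2])
    fwd = rng.choice(4, size=lsc + ir + ssc, p=p).astype(np.uint8)
    codes = np.concatenate([fwd, (3 - fwd[lsc:lsc + ir])[::-1].astype(np.uint8)])
    gb = _GenomeBuilder(codes, ira_iv, irb_iv)

    _break_ssrs(gb, rng, planted=[])

    # --- plant SSR loci in the early LSC, well before the gene space
    ssr_zone_start = 120
    planted_ssrs: list[SSRLocus] = []
    cursor = ssr_zone_start
    for unit, count in config.ssr_spec:
        total = len(unit) * count
        start = cursor
        for k in range(total):
            gb.set_base(start + k, "ACGT".index(unit[k % len(unit)]))
        # flanks must not extend the repeat period
        u = len(unit)
        left_bad = {int(gb.codes[start + u - 1])}
        opts = [b for b in range(4) if b not in left_bad | {int(gb.codes[start - 2])}]
        gb.set_base(start - 1, int(rng.choice(opts)))
        right_bad = {int(gb.codes[start + total - u])}
        opts = [b for b in range(4)
                if b not in right_bad | {int(gb.codes[start + total + 1])}]
        gb.set_base(start + total, int(rng.choice(opts)))
        planted_ssrs.append(SSRLocus("A", start, unit, u, count))
        cursor = start + total + int(rng.integers(25, 60))
    ssr_intervals = [(l.start, l.end) for l in planted_ssrs]
    _break_ssrs(gb, rng, planted=ssr_intervals)

    # --- gene placement (single-copy regions, after the SSR zone)
    gene_space_start = cursor + 40
    zones = [(gene_space_start, lsc - 150), (lsc + ir + 150, lsc + ir + ssc - 150)]
    n = config.n_genes
    lo, hi = config.gene_length_range
    cds_lens = (rng.integers(lo // 3, hi // 3 + 1, size=n) * 3).astype(int)
    intron_flags = rng.random(n) < config.intron_genes
    ilo, ihi = config.intron_length_range
    reserve_len = 1800
    reserve_after = max(1, n // 3)  # the gene whose tail the second insert covers
    features: list[GeneFeature] = []
    reserve: tuple[int, int] | None = None
    zone_i, cur = 0, zones[0][0]
    for gi in range(n):
        glen = int(cds_lens[gi]) + 6  # + start & stop codons
        ilen = int(rng.integers(ilo, ihi + 1)) if intron_flags[gi] else 0
        span = glen + ilen
        placed = False
        while zone_i < len(zones):
            zs, ze = zones[zone_i]
            cur = max(cur, zs)
            if cur + span <= ze:
                placed = True
                break
            zone_i += 1
            cur = zones[zone_i][0] if zone_i < len(zones) else 0
        if not placed:
            raise ConfigurationError(
                f"gene {gi + 1} of {n} (span {span} bp) does not fit in the "
                "single-copy regions; reduce n_genes or gene_length_range"
            )
        start, strand = cur, "+-"[gi % 2]
        name = f"g{gi + 1:02d}"
        cds = "ATG" + "".join(
            rng.choice(_NONSTOP_CODONS) for _ in range(int(cds_lens[gi]) // 3)
        ) + "TAA"
        if ilen:
            cut = int(rng.integers(len(cds) // 4, 3 * len(cds) // 4))
            genomic = cds[:cut] + _decode(rng.choice(4, size=ilen).astype(np.uint8)) \
                + cds[cut:]
            if strand == "+":
                exons = ((start, start + cut), (start + cut + ilen, start + span))
                intron_iv = (start + cut, start + cut + ilen)
            else:
                exons = ((start, start + span - cut - ilen),
                         (start + span - cut, start + span))
                intron_iv = (start + span - cut - ilen, start + span - cut)
        else:
            genomic = cds
            exons = ((start, start + span),)
            intron_iv = None
        write = revcomp(genomic) if strand == "-" else genomic
        for k, b in enumerate(write):
            gb.set_base(start + k, "ACGT".index(b))
        features.append(GeneFeature(name, "CDS", strand, exons))
        if intron_iv:
            features.append(
                GeneFeature(f"{name}_intron", "intron", strand, (intron_iv,))
            )
        cur = start + span + int(rng.integers(60, 140))
        if gi == reserve_after:
            reserve = (cur, cur + reserve_len)
            cur += reserve_len

    if reserve is None:
        raise ConfigurationError("too few genes to host the intergenic reserve")
    genes = [f for f in features if f.ftype == "CDS"]
    mtpt_gene = genes[reserve_after]

    # --- editing sites
    hap_ids = [chr(ord("A") + i) for i in range(config.n_haplotypes)]
    editing: list[EditingSpecSite] = []
    if config.editing_spec is None:
        eligible = [g for g in genes if g.name != mtpt_gene.name]
        start_gene = eligible[-1]  # dedicated host for the edited start codon
        rest = [g for g in eligible if g.name != start_gene.name]
        per_gene_count: dict[str, int] = {}
        gi = 0
        for codon, cp, rate, kind in _DEFAULT_EDIT_PLAN:
            if kind == "start":
                g, ci = start_gene, 0
                idx = features.index(g)
                features[idx] = replace(g, edited_start_or_stop=True)
            else:
                g = rest[gi % len(rest)]
                gi += 1
                k = per_gene_count.get(g.name, 0)
                n_codons = g.length // 3
                # mid-gene, where fragment coverage is flat
                ci = max(1, min(n_codons // 2 - 3 * k, n_codons - 2))
            per_gene_count[g.name] = per_gene_count.get(g.name, 0) + 1
            _write_transcript_codon(gb, g, ci, codon)
            pos = g.transcript_positions()[3 * ci + (cp - 1)]
            if rate == "private":
                rates = {h: (0.0 if h == "A" else 0.06) for h in hap_ids}
            else:
                rates = {h: float(rate) for h in hap_ids}
            editing.append(EditingSpecSite(pos, g.strand, g.name, rates))
        genes = [f for f in features if f.ftype == "CDS"]
    else:
        editing = [replace(s) for s in config.editing_spec]

    # --- antisense transcripts (opposite strand, inside a gene's span)
    antisense: list[AntisenseSpec] = []
    hosts = [g for g in genes
             if g.name != mtpt_gene.name and g.end - g.start >= 320]
    alo, ahi = config.antisense_length_range
    for ai in range(config.n_antisense):
        g = hosts[(ai * 2 + 1) % len(hosts)]
        span = g.end - g.start
        length = int(min(int(rng.integers(alo, ahi + 1)), span - 40))
        start = g.start + 20
        strand = "-" if g.strand == "+" else "+"
        present = tuple(hap_ids) if ai == 0 else ("A",)
        antisense.append(
            AntisenseSpec(start, start + length, strand,
                          config.antisense_expression, present)
        )
    # one intergenic (antisense-borne) editing site in the first antisense RNA
    if config.editing_spec is None and antisense:
        a = antisense[0]
        centre = (a.start + a.end) // 2
        # a C on the transcribed strand: genome C for '+', genome G for '-'
        want = 1 if a.strand == "+" else 2
        pos_found = None
        for off in range((a.end - a.start) // 2 - 10):
            for pos in (centre + off, centre - off):
                if int(gb.codes[pos]) == want:
                    pos_found = pos
                    break
            if pos_found is not None:
                break
        if pos_found is not None:
            editing.append(
                EditingSpecSite(pos_found, a.strand, "antisense",
                                {h: 0.85 for h in hap_ids})
            )

    # --- clean SSRs created by gene/codon writes, protecting planted bases
    protected: set[int] = set()
    for s in editing:
        protected.update(range(s.position - 1, s.position + 2))
    cds_codons: dict[int, tuple[str, tuple[int, int, int]]] = {}
    for g in genes:
        tpos = g.transcript_positions()
        protected.update(tpos[:3])
        protected.update(tpos[-3:])
        cds_codons.update(_transcript_codon_map(g))
    _break_ssrs(gb, rng, planted=ssr_intervals, protected=protected,
                cds_codons=cds_codons)

    # --- MTPT source intervals
    if config.mtpt_spec is not None:
        mtpt = [tuple(t) for t in config.mtpt_spec]
    else:
        d = config.mtpt_divergence
        i2 = (mtpt_gene.end - 300, mtpt_gene.end - 300 + 1018, d)
        i1 = (reserve[0] + 1100, reserve[0] + 1100 + 377, d)
        if i1[1] > reserve[1] or i2[1] > reserve[1] + 300:
            raise ConfigurationError("reserve too small for MTPT intervals")
        mtpt = [i2, i1]

    expression = dict(config.expression) if config.expression else {
        g.name: float(0.5 * (3.0 / 0.5) ** (i / max(len(genes) - 1, 1)))
        for i, g in enumerate(genes)
    }

    seq = gb.seq()
    boundaries = {"LSC": (0, lsc), "IRa": ira_iv, "SSC": (lsc + ir, lsc + ir + ssc),
                  "IRb": irb_iv}
    plastome = Plastome("A", seq, features, boundaries)
    plastome.check_boundaries()

    found = {(l.start, l.unit, l.unit_count) for l in find_ssrs(plastome)}
    want = {(l.start, l.unit, l.unit_count) for l in planted_ssrs}
    if found != want:
        raise RuntimeError("internal error: planted SSR set not clean")

    truth = GroundTruth(
        genome_id="A",
        ssrs=planted_ssrs,
        expression=expression,
        editing_sites=editing,
        antisense=antisense,
        mtpt_intervals=mtpt,
        reserve=reserve,
    )
    return plastome, truth


# ---------------------------------------------------------------------------
# haplotype derivation


def _apply_events(base_seq: str, events: list[tuple]) -> tuple[str, str, str, np.ndarray]:
    """Apply sorted (kind, pos, payload) events to the base sequence.

    Returns (derived sequence, aligned base row, aligned derived row,
    offset array) where offset[p] added to p maps base coordinates at or
    after each event to derived coordinates.
    """
    L = len(base_seq)
    row_a: list[str] = []
    row_b: list[str] = []
    delta = np.zeros(L + 1, dtype=np.int64)
    cur = 0
    for ev in events:
        kind, p = ev[0], ev[1]
        row_a.append(base_seq[cur:p])
        row_b.append(base_seq[cur:p])
        if kind == "sub":
            row_a.append(base_seq[p])
            row_b.append(ev[2])
            cur = p + 1
        elif kind == "del":
            ln = ev[2]
            row_a.append(base_seq[p:p + ln])
            row_b.append("-" * ln)
            delta[p + ln] -= ln
            cur = p + ln
        elif kind == "ins":
            seq_ins = ev[2]
            row_a.append("-" * len(seq_ins))
            row_b.append(seq_ins)
            delta[p] += len(seq_ins)
            cur = p
    row_a.append(base_seq[cur:])
    row_b.append(base_seq[cur:])
    aln_a = "".join(row_a)
    aln_b = "".join(row_b)
    derived = aln_b.replace("-", "")
    offsets = np.cumsum(delta)
    return derived, aln_a, aln_b, offsets


def derive_haplotype(
    base: Plastome,
    base_truth: GroundTruth,
    derived_id: str,
    n_substitutions: int,
    n_indels: int,
    seed,
    indel_length_range: tuple[int, int] = (1, 8),
    ssr_variation: bool = True,
) -> tuple[Plastome, GroundTruth]:
    """Derive a haplotype by planting substitutions and indels.

    Substitutions may fall inside coding sequence (creating segregating
    sites) but avoid the IRs, planted SSR loci, editing-site codons and
    gene start/stop codons; indels are intergenic. When ``ssr_variation``
    is set, the first indel inserts one repeat unit into a planted
    multi-nucleotide SSR, so the derived haplotype shows SSR length
    polymorphism. The pairwise distance of the returned alignment equals
    (n_substitutions, n_indels) exactly under the indelblock model.
    """
    rng = np.random.default_rng([seed] if np.isscalar(seed) else list(seed))
    seq = base.sequence
    L = len(seq)
    genes = [f for f in base.features if f.ftype == "CDS"]
    ira = base.boundaries["IRa"]
    irb = base.boundaries["IRb"]

    forbidden = np.zeros(L, dtype=bool)
    forbidden[ira[0]:ira[1]] = True
    forbidden[irb[0]:irb[1]] = True
    forbidden[:60] = forbidden[-60:] = True
    for l in base_truth.ssrs:
        forbidden[max(l.start - 8, 0):l.end + 8] = True
    for s in base_truth.editing_sites:
        forbidden[max(s.position - 4, 0):s.position + 5] = True
    for g in genes:
        tpos = g.transcript_positions()
        for p in tpos[:3] + tpos[-3:]:
            forbidden[p] = True

    in_gene = np.zeros(L, dtype=bool)
    for f in base.features:
        in_gene[max(f.start - 5, 0):f.end + 5] = True
    for a in base_truth.antisense:
        in_gene[max(a.start - 5, 0):a.end + 5] = True

    sub_pool = np.flatnonzero(~forbidden)
    indel_pool = np.flatnonzero(~forbidden & ~in_gene)
    if sub_pool.size < 4 * n_substitutions or indel_pool.size < 20 * n_indels:
        raise ConfigurationError(
            "requested substitutions/indels exceed the available positions"
        )

    ilo, ihi = indel_length_range
    target_ssr = next(
        (l for l in base_truth.ssrs if l.unit_length >= 2), None
    ) if ssr_variation and n_indels > 0 else None

    for attempt in range(30):
        sub_pos = np.sort(rng.choice(sub_pool, size=n_substitutions, replace=False))
        events: list[tuple] = []
        ok = True
        for p in sub_pos.tolist():
            ref = seq[p]
            alt = _BASES[int(rng.choice([b for b in range(4) if _BASES[b] != ref]))]
            events.append(("sub", p, alt))
        blocked = set(sub_pos.tolist())
        indels: list[tuple] = []
        if target_ssr is not None:
            indels.append(("ins", target_ssr.start, target_ssr.unit))
        tries = 0
        while len(indels) < n_indels and tries < 2000:
            tries += 1
            p = int(rng.choice(indel_pool))
            ln = int(rng.integers(ilo, ihi + 1))
            kind = "del" if rng.random() < 0.5 else "ins"
            iv = (p, p + ln) if kind == "del" else (p, p + 1)
            clash = any(
                iv[0] - 3 < q[1] and iv[1] + 3 > q[0]
                for q in [((e[1], e[1] + e[2]) if e[0] == "del" else (e[1], e[1] + 1))
                          for e in indels]
            ) or any(iv[0] - 2 <= q <= iv[1] + 2 for q in blocked)
            if clash or (kind == "del" and in_gene[p:p + ln].any()):
                continue
            if kind == "del":
                indels.append(("del", p, ln))
            else:
                ins_seq = _decode(rng.choice(4, size=ln).astype(np.uint8))
                indels.append(("ins", p, ins_seq))
        if len(indels) < n_indels:
            ok = False
        if ok:
            events.extend(indels)
            events.sort(key=lambda e: (e[1], 0 if e[0] == "ins" else 1))
            derived_seq, aln_a, aln_b, offsets = _apply_events(seq, events)

            def mapper(p, offsets=offsets):
                return int(p + offsets[p])

            # verify planted distances and SSR cleanliness
            if compare.count_substitutions(aln_a, aln_b) != n_substitutions:
                ok = False
            if ok and compare.count_indels(aln_a, aln_b, "indelblock") != n_indels:
                ok = False
            if ok:
                expected = set()
                for l in base_truth.ssrs:
                    count = l.unit_count
                    start = mapper(l.start)
                    if target_ssr is not None and l.start == target_ssr.start:
                        count += 1
                        start -= l.unit_length  # inserted unit sits before it
                    expected.add((start, l.unit, count))
                found = {
                    (l.start, l.unit, l.unit_count)
                    for l in find_ssrs(derived_seq)
                }
                if found != expected:
                    ok = False
        if ok:
            break
    else:
        raise RuntimeError("could not place haplotype edits cleanly")

    features = [f.shift(mapper) for f in base.features]
    boundaries = {k: (mapper(a), mapper(b)) for k, (a, b) in base.boundaries.items()}
    derived = Plastome(derived_id, derived_seq, features, boundaries)
    derived.check_boundaries()

    subs = []
    insertions = []
    deletions = []
    for ev in events:
        if ev[0] == "sub":
            p = ev[1]
            subs.append((p, seq[p], ev[2], mapper(p)))
        elif ev[0] == "ins":
            insertions.append((ev[1], ev[2], mapper(ev[1])))
        else:
            deletions.append((ev[1], ev[1] + ev[2], seq[ev[1]:ev[1] + ev[2]]))
    diff = PairDiff(base.id, derived_id, subs, insertions, deletions, (aln_a, aln_b))

    d_ssrs = []
    for l in base_truth.ssrs:
        count = l.unit_count
        start = mapper(l.start)
        if target_ssr is not None and l.start == target_ssr.start:
            count += 1
            start -= l.unit_length
        d_ssrs.append(SSRLocus(derived_id, start, l.unit, l.unit_length, count))
    d_edit = [
        EditingSpecSite(mapper(s.position), s.strand, s.context, dict(s.rates))
        for s in base_truth.editing_sites
    ]
    d_anti = [
        AntisenseSpec(mapper(a.start), mapper(a.end), a.strand,
                      a.expression, a.present_in)
        for a in base_truth.antisense
    ]
    d_mtpt = [(mapper(a), mapper(b), d) for a, b, d in base_truth.mtpt_intervals]
    truth = GroundTruth(
        genome_id=derived_id,
        ssrs=d_ssrs,
        expression=dict(base_truth.expression),
        editing_sites=d_edit,
        antisense=d_anti,
        mtpt_intervals=d_mtpt,
        diff=diff,
        reserve=None if base_truth.reserve is None
        else (mapper(base_truth.reserve[0]), mapper(base_truth.reserve[1])),
    )
    return derived, truth


# ---------------------------------------------------------------------------
# mitochondrial genome with plastid-like inserts


def make_mito_with_inserts(
    plastome: Plastome,
    mtpt_spec: list[tuple[int, int, float]],
    seed,
    mito_length: int = 20_000,
    mito_id: str | None = None,
) -> MitoGenome:
    """Build a mitochondrial genome carrying diverged copies of plastid
    intervals.

    Each insert copies the named plastid interval and substitutes a fraction
    of positions (the divergence markers, recorded in plastid coordinates).
    Marker substitutions never mimic a candidate C-to-U editing observation
    (no C->T or G->A changes): a diverged base indistinguishable from
    editing is invisible to any read filter by construction, so planting it
    would make the recorded truth unrecoverable in principle.
    """
    rng = np.random.default_rng([seed] if np.isscalar(seed) else list(seed))
    for a, b, d in mtpt_spec:
        if not (0.005 <= d <= 0.05):
            raise ConfigurationError(
                f"insert divergence {d} outside the supported range [0.005, 0.05]"
            )
        if not (0 <= a < b <= len(plastome.sequence)):
            raise ConfigurationError(f"insert interval ({a}, {b}) out of range")
    background = rng.choice(4, size=mito_length, p=[0.29, 0.21, 0.21, 0.29])
    background = background.astype(np.uint8)
    pieces: list[np.ndarray] = []
    inserts: list[MTPTInsert] = []
    n = len(mtpt_spec)
    step = mito_length // (n + 1) if n else mito_length
    cursor = 0
    out_len = 0
    for i, (a, b, d) in enumerate(mtpt_spec):
        at = step * (i + 1)
        pieces.append(background[cursor:at])
        out_len += at - cursor
        seg = _encode(plastome.sequence[a:b]).copy()
        k = int(round(d * (b - a)))
        marker_off = np.sort(rng.choice(b - a, size=k, replace=False))
        markers = []
        for off in marker_off.tolist():
            ref = int(seg[off])
            banned = {ref}
            if ref == 1:  # C: a C->T change would mimic plus-strand editing
                banned.add(3)
            if ref == 2:  # G: a G->A change would mimic minus-strand editing
                banned.add(0)
            alt = int(rng.choice([x for x in range(4) if x not in banned]))
            seg[off] = alt
            markers.append((a + off, _BASES[ref], _BASES[alt]))
        inserts.append(
            MTPTInsert(a, b, out_len, out_len + (b - a), d, tuple(markers))
        )
        pieces.append(seg)
        out_len += b - a
        cursor = at
    pieces.append(background[cursor:])
    sequence = _decode(np.concatenate(pieces))
    return MitoGenome(mito_id or f"{plastome.id}-mt", sequence, inserts)


# ---------------------------------------------------------------------------
# read simulation


def _flags_for(transcript_strand: str, strandedness: str) -> tuple[int, int]:
    """(flag of the left-mapped read, flag of the right-mapped read)."""
    # dUTP / fr-firststrand: read2 carries the transcript orientation
    plus = (163, 83)   # left: read2 forward, right: read1 reverse
    minus = (99, 147)  # left: read1 forward, right: read2 reverse
    if strandedness == "fr-secondstrand":
        plus, minus = minus, plus
    return plus if transcript_strand == "+" else minus


def simulate_reads(
    plastome: Plastome,
    truth: GroundTruth,
    mito: MitoGenome,
    config: SimulationConfig,
    seed,
    individuals: list[tuple[str, str]] | None = None,
) -> dict[str, ReadAlignmentSet]:
    """Simulate stranded paired-end RNA-seq for every individual of one
    haplotype, emitted pre-aligned at true positions.

    Transcripts are the unspliced gene spans plus the antisense intervals
    present in this haplotype; a configurable fraction of reads originates
    from the diverged mitochondrial insert copies (aligned at the
    homologous plastid coordinates, carrying the divergence markers).
    Editing is applied per RNA fragment as Bernoulli(true rate), so both
    mates of an edited fragment agree. Returns one ReadAlignmentSet per
    individual, key "<hap>_<sex><replicate>".
    """
    hap = plastome.id
    if individuals is None:
        counts: dict[str, int] = {}
        individuals = []
        for s in config.sexes:
            counts[s] = counts.get(s, 0) + 1
            individuals.append((f"{hap}_{s}{counts[s]}", s))
    genome_codes = _encode(plastome.sequence)
    RL = config.read_length
    genes = plastome.cds_features()
    transcripts: list[tuple[int, int, str, float, str, int]] = []
    utr = config.utr_length
    for g in genes:
        expr = truth.expression.get(g.name, 1.0)
        transcripts.append(
            (max(0, g.start - utr), min(len(plastome.sequence), g.end + utr),
             g.strand, expr, g.name, -1)
        )
    for a in truth.antisense:
        if hap in a.present_in:
            transcripts.append((a.start, a.end, a.strand, a.expression,
                                "antisense", -1))
    for j, ins in enumerate(mito.inserts):
        transcripts.append(
            (ins.plastid_start, ins.plastid_end, "+",
             config.mito_read_fraction, "mito", j)
        )

    # warn once for editing sites no transcript covers
    for s in truth.editing_sites:
        covered = any(
            t[0] <= s.position < t[1] and t[2] == s.strand and t[5] < 0
            for t in transcripts
        )
        if not covered:
            warnings.warn(
                f"editing site at {s.position}{s.strand} is not covered by any "
                "transcript; skipped", stacklevel=2
            )

    out: dict[str, ReadAlignmentSet] = {}
    base_entropy = [seed] if np.isscalar(seed) else list(seed)
    for idx, (ind_id, sex) in enumerate(individuals):
        rng = np.random.default_rng(base_entropy + [idx])
        starts_l: list[np.ndarray] = []
        flens_l: list[np.ndarray] = []
        strands_l: list[np.ndarray] = []
        origin_l: list[np.ndarray] = []
        for (ts, te, strand, expr, name, ins_j) in transcripts:
            span = te - ts
            if span < RL:
                continue
            e = expr
            if ins_j < 0 and name != "antisense" and sex == "H":
                e *= config.sex_fold_changes.get(name, 1.0)
            e *= 2.0 ** rng.normal(0.0, config.expression_noise_sd)
            lam = e * config.depth * span / (2.0 * RL)
            nf = int(rng.poisson(lam))
            if nf == 0:
                continue
            # short transcripts fragment shorter, else 2 x RL sequencing of
            # near-full-length fragments would leave a mid-transcript hole
            fmean = min(config.fragment_mean, 0.75 * span)
            flen = np.clip(
                np.rint(rng.normal(fmean, config.fragment_sd, nf)),
                RL, span
            ).astype(np.int64)
            start = ts + (rng.random(nf) * (span - flen + 1)).astype(np.int64)
            starts_l.append(start)
            flens_l.append(flen)
            strands_l.append(np.full(nf, 1 if strand == "+" else 0, dtype=np.int8))
            origin_l.append(np.full(nf, ins_j, dtype=np.int64))
        fstart = np.concatenate(starts_l)
        flen = np.concatenate(flens_l)
        fstrand = np.concatenate(strands_l)
        forigin = np.concatenate(origin_l)
        F = fstart.size
        left = fstart
        right = fstart + flen - RL
        pos_all = np.concatenate([left, right])  # reads 0..F-1 left, F..2F-1 right
        codes = genome_codes[pos_all[:, None] + np.arange(RL)[None, :]].copy()

        # diverged bases on mitochondrial-origin reads
        for j, ins in enumerate(mito.inserts):
            rows = np.flatnonzero(np.concatenate([forigin == j] * 2))
            if rows.size == 0:
                continue
            for mpos, _ref, alt in ins.markers:
                col = mpos - pos_all[rows]
                hit = rows[(col >= 0) & (col < RL)]
                codes[hit, mpos - pos_all[hit]] = _BASES.index(alt)

        # planted editing, per fragment
        for s in truth.editing_sites:
            r = s.rate_for(hap)
            if r <= 0:
                continue
            want = 1 if s.strand == "+" else 0
            covered = (
                (fstrand == want) & (forigin < 0)
                & (fstart <= s.position) & (s.position < fstart + flen)
            )
            edited = covered & (rng.random(F) < r)
            if not edited.any():
                continue
            new_code = 3 if s.strand == "+" else 0  # C->T forward, G->A reverse
            rows = np.flatnonzero(np.concatenate([edited] * 2))
            col = s.position - pos_all[rows]
            hit = rows[(col >= 0) & (col < RL)]
            codes[hit, s.position - pos_all[hit]] = new_code

        # uniform sequencing errors
        err = rng.random(codes.shape) < config.error_rate
        n_err = int(err.sum())
        if n_err:
            codes[err] = (codes[err] + rng.integers(1, 4, n_err)) % 4

        left_flag = np.where(fstrand == 1, *(
            _flags_for("+", config.strandedness)[0],
            _flags_for("-", config.strandedness)[0],
        ))
        right_flag = np.where(fstrand == 1, *(
            _flags_for("+", config.strandedness)[1],
            _flags_for("-", config.strandedness)[1],
        ))
        flags = np.concatenate([left_flag, right_flag]).astype(np.int64)
        mpos = np.concatenate([right, left])
        tlen = np.concatenate([flen, -flen])
        origin_tag = np.where(forigin >= 0, "mt", "pt")
        qnames = [
            f"{ind_id}:{origin_tag[i]}:{i}" for i in range(F)
        ]
        qname = qnames + qnames
        big = bytes(_CODE2ASCII[codes.reshape(-1)]).decode()
        seqs = [big[i * RL:(i + 1) * RL] for i in range(2 * F)]
        qual = "I" * RL
        out[ind_id] = ReadAlignmentSet(
            individual=ind_id,
            reference_id=hap,
            reference_length=len(plastome.sequence),
            qname=qname,
            flag=flags,
            pos=pos_all.astype(np.int64),
            cigar=[f"{RL}M"] * (2 * F),
            seq=seqs,
            qual=[qual] * (2 * F),
            mpos=mpos.astype(np.int64),
            tlen=tlen.astype(np.int64),
        )
    return out


# ---------------------------------------------------------------------------
# multiple alignment of planted haplotypes and study orchestration


def build_msa(base: Plastome, diffs: dict[str, PairDiff]) -> dict[str, str]:
    """Exact multiple alignment of the base and derived haplotypes from the
    planted event records (valid because indels of different haplotypes do
    not overlap by construction)."""
    seq = base.sequence
    L = len(seq)
    haps = list(diffs)
    subs = {h: {p: alt for p, _r, alt, _d in diffs[h].substitutions} for h in haps}
    dels = {h: set() for h in haps}
    for h in haps:
        for a, b, _s in diffs[h].deletions:
            dels[h].update(range(a, b))
    ins_at: dict[int, list[tuple[str, str]]] = {}
    for h in haps:
        for p, s, _d in diffs[h].insertions:
            ins_at.setdefault(p, []).append((h, s))
    rows = {base.id: [], **{h: [] for h in haps}}
    for p in range(L + 1):
        for h_ins, s in sorted(ins_at.get(p, [])):
            rows[base.id].append("-" * len(s))
            for h in haps:
                rows[h].append(s if h == h_ins else "-" * len(s))
        if p == L:
            break
        c = seq[p]
        rows[base.id].append(c)
        for h in haps:
            if p in dels[h]:
                rows[h].append("-")
            else:
                rows[h].append(subs[h].get(p, c))
    return {k: "".join(v) for k, v in rows.items()}


@dataclass
class StudyData:
    """A complete synthetic study: genomes, truths, mito genomes and reads."""

    config: SimulationConfig
    plastomes: dict[str, Plastome]
    truths: dict[str, GroundTruth]
    mitos: dict[str, MitoGenome]
    reads: dict[str, ReadAlignmentSet]  # individual id -> alignments
    msa: dict[str, str]

    def individuals_of(self, haplotype: str) -> list[str]:
        return [i for i in self.reads if i.startswith(f"{haplotype}_")]

    @staticmethod
    def sex_of(individual: str) -> str:
        return individual.split("_")[1][0]

    @staticmethod
    def haplotype_of(individual: str) -> str:
        return individual.split("_")[0]


def simulate_study(config: SimulationConfig, with_reads: bool = True) -> StudyData:
    """Run the full generator: base plastome, derived haplotypes, per-
    haplotype mitochondrial genomes, and (optionally) reads for all
    individuals of every haplotype."""
    base, base_truth = make_plastome(config)
    plastomes = {"A": base}
    truths = {"A": base_truth}
    for i in range(1, config.n_haplotypes):
        hid = chr(ord("A") + i)
        p, t = derive_haplotype(
            base, base_truth, hid, config.n_substitutions, config.n_indels,
            seed=[config.seed, 7, i],
            indel_length_range=config.indel_length_range,
            ssr_variation=config.ssr_variation,
        )
        plastomes[hid] = p
        truths[hid] = t
    mitos = {
        h: make_mito_with_inserts(
            plastomes[h], list(truths[h].mtpt_intervals), seed=[config.seed, 11, i],
            mito_length=config.mito_length,
        )
        for i, h in enumerate(plastomes)
    }
    reads: dict[str, ReadAlignmentSet] = {}
    if with_reads:
        for i, h in enumerate(plastomes):
            reads.update(
                simulate_reads(
                    plastomes[h], truths[h], mitos[h], config,
                    seed=[config.seed, 23, i],
                )
            )
    msa = build_msa(base, {h: truths[h].diff for h in plastomes if h != "A"})
    return StudyData(config, plastomes, truths, mitos, reads, msa)
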