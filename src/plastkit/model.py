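"""Shared domain types for plastid genome and transcriptome analysis.

Coordinates are 0-based half-open everywhere inside the package; writers
emit 1-based inclusive coordinates (GFF3/TSV convention) and say so in a
header comment.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC bases accepted in genome sequences; other ambiguity codes are
#: rejected at load with a clear error.
ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sequence(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(
            f"{name} contains unsupported characters {sorted(bad)}; "
            "only A, C, G, T and N are accepted (other ambiguity codes are rejected)"
        )
    return seq


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature on a plastome.

    exons are 0-based half-open intervals in genome coordinates, ordered by
    genome position regardless of strand.
    """

    name: str
    ftype: str  # CDS | tRNA | rRNA | intron | IGS
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    phase: int = 0
    #: flagged for genes whose start/stop codon is completed by RNA editing
    edited_start_or_stop: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("feature needs at least one exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Total exonic length."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def extract(self, genome: str) -> str:
        """Spliced feature sequence, 5'->3' on the transcript strand."""
        s = "".join(genome[a:b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s

    def transcript_positions(self) -> list[int]:
        """Genome coordinates of exonic bases in transcript (5'->3') order."""
        pos = [p for a, b in self.exons for p in range(a, b)]
        return pos[::-1] if self.strand == "-" else pos

    def shift(self, mapper) -> "GeneFeature":
        """Return a copy with coordinates run through ``mapper(pos)``."""
        exons = tuple((mapper(a), mapper(b)) for a, b in self.exons)
        return replace(self, exons=exons)


@dataclass
class Plastome:
    """An annotated (linearised) plastid genome.

    boundaries maps region names LSC/SSC/IRa/IRb to 0-based half-open
    intervals partitioning the sequence; it may be None for genomes whose
    quadripartite structure has not been determined.
    """

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    boundaries: dict[str, tuple[int, int]] | None = None

    def __post_init__(self):
        self.sequence = validate_sequence(self.sequence, f"genome {self.id}")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r} in genome {self.id}")

    def cds_features(self) -> list[GeneFeature]:
        """Unique protein-coding genes (IR duplicates collapsed by name)."""
        seen: dict[str, GeneFeature] = {}
        for f in self.features:
            if f.ftype == "CDS" and f.name not in seen:
                seen[f.name] = f
        return list(seen.values())

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def check_boundaries(self) -> None:
        """Assert boundary invariants: partition + IRa == revcomp(IRb)."""
        if self.boundaries is None:
            return
        ivs = sorted(self.boundaries.values())
        if ivs[0][0] != 0 or ivs[-1][1] != len(self.sequence):
            raise ValueError("boundaries do not span the genome")
        for (a, b), (c, d) in zip(ivs, ivs[1:]):
            if b != c:
                raise ValueError("boundaries do not partition the genome")
        ira = self.boundaries.get("IRa")
        irb = self.boundaries.get("IRb")
        if ira and irb:
            sa = self.sequence[ira[0]:ira[1]]
            sb = self.sequence[irb[0]:irb[1]]
            if sa != revcomp(sb):
                raise ValueError("IRa is not the reverse complement of IRb")
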