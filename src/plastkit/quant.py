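"""Strand-specific transcript quantification.

Read-pair strand separation by SAM flags, filtering of reads that likely
originate from plastid-like inserts in the mitochondrial genome (MTPT),
CIGAR-aware per-base depth of coverage, per-feature TPM, antisense-transcript
detection and between-group expression comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GeneFeature, Plastome

FPAIRED, FPROPER, FUNMAP, FMUNMAP = 0x1, 0x2, 0x4, 0x8
FREVERSE, FMREVERSE, FREAD1, FREAD2 = 0x10, 0x20, 0x40, 0x80

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_bases(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4 (treated as no-call)."""
    return _BASE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@dataclass
class ReadAlignmentSet:
    """Aligned paired-end reads of one individual against one reference.

    A thin columnar container over SAM records (0-based positions). Reads
    with a uniform ``<L>M`` CIGAR take vectorised fast paths throughout;
    arbitrary CIGARs are handled by per-read fallbacks.
    """

    individual: str
    reference_id: str
    reference_length: int
    qname: list[str] = field(default_factory=list)
    flag: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    pos: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    cigar: list[str] = field(default_factory=list)
    seq: list[str] = field(default_factory=list)
    qual: list[str] | None = None
    mpos: np.ndarray | None = None
    tlen: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.qname)

    # -- structure helpers -------------------------------------------------

    @property
    def uniform_read_length(self) -> int | None:
        """Read length if every CIGAR is a plain ``<L>M`` of equal L."""
        if not self.cigar:
            return None
        L = len(self.seq[0])
        tag = f"{L}M"
        if all(c == tag for c in self.cigar):
            return L
        return None

    def seq_codes(self) -> np.ndarray:
        """(n_reads, L) base-code matrix; uniform read sets only."""
        L = self.uniform_read_length
        if L is None:
            raise ValueError("seq_codes requires uniform all-M reads")
        raw = np.frombuffer("".join(self.seq).upper().encode(), dtype=np.uint8)
        return _BASE_CODE[raw].reshape(len(self), L)

    def qual_codes(self) -> np.ndarray | None:
        if self.qual is None:
            return None
        L = self.uniform_read_length
        raw = np.frombuffer("".join(self.qual).encode(), dtype=np.uint8)
        return (raw - 33).reshape(len(self), L)

    def subset(self, index: np.ndarray) -> "ReadAlignmentSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        take = index.tolist()
        return ReadAlignmentSet(
            individual=self.individual,
            reference_id=self.reference_id,
            reference_length=self.reference_length,
            qname=[self.qname[i] for i in take],
            flag=self.flag[index],
            pos=self.pos[index],
            cigar=[self.cigar[i] for i in take],
            seq=[self.seq[i] for i in take],
            qual=None if self.qual is None else [self.qual[i] for i in take],
            mpos=None if self.mpos is None else self.mpos[index],
            tlen=None if self.tlen is None else self.tlen[index],
        )

    # -- SAM round trip ----------------------------------------------------

    def to_sam(self, path) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": self.reference_id, "LN": int(self.reference_length)}],
            "RG": [{"ID": self.individual, "SM": self.individual}],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i in range(len(self)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = self.qname[i]
                a.flag = int(self.flag[i])
                a.reference_id = 0
                a.reference_start = int(self.pos[i])
                a.mapping_quality = 60
                a.cigarstring = self.cigar[i]
                a.query_sequence = self.seq[i]
                if self.qual is not None:
                    a.query_qualities = pysam.qualitystring_to_array(self.qual[i])
                if self.mpos is not None:
                    a.next_reference_id = 0
                    a.next_reference_start = int(self.mpos[i])
                if self.tlen is not None:
                    a.template_length = int(self.tlen[i])
                a.set_tag("RG", self.individual)
                out.write(a)

    @classmethod
    def from_sam(cls, path, individual: str | None = None) -> "ReadAlignmentSet":
        with pysam.AlignmentFile(str(path), "r") as fh:
            ref = fh.references[0]
            rlen = fh.lengths[0]
            qname, flag, pos, cigar, seq, qual, mpos, tlen = [], [], [], [], [], [], [], []
            for a in fh:
                qname.append(a.query_name)
                flag.append(a.flag)
                pos.append(a.reference_start)
                cigar.append(a.cigarstring or "")
                seq.append(a.query_sequence or "")
                qual.append(
                    pysam.qualities_to_qualitystring(a.query_qualities)
                    if a.query_qualities is not None else ""
                )
                mpos.append(a.next_reference_start)
                tlen.append(a.template_length)
        return cls(
            individual=individual or "sample",
            reference_id=ref,
            reference_length=rlen,
            qname=qname,
            flag=np.array(flag, dtype=np.int64),
            pos=np.array(pos, dtype=np.int64),
            cigar=cigar,
            seq=seq,
            qual=qual if any(qual) else None,
            mpos=np.array(mpos, dtype=np.int64),
            tlen=np.array(tlen, dtype=np.int64),
        )


# ---------------------------------------------------------------------------
# strand separation


@dataclass
class StrandSeparation:
    plus: ReadAlignmentSet
    minus: ReadAlignmentSet
    unassigned: ReadAlignmentSet
    reasons: list[str]  # one per unassigned read


def separate_strands(
    ras: ReadAlignmentSet, convention: str = "fr-firststrand"
) -> StrandSeparation:
    """Assign each properly-paired read to the transcriptional strand implied
    by its SAM flags under the configured library convention.

    "fr-firststrand" is the dUTP convention: the second read of a pair has
    the orientation of the transcript (so read 1 mapping reverse means a
    plus-strand fragment). "fr-secondstrand" is the inverse. The partition
    plus/minus/unassigned is exhaustive and disjoint; improperly paired or
    flag-inconsistent records go to unassigned with a reason code.
    """
    if convention not in ("fr-firststrand", "fr-secondstrand"):
        raise ValueError(f"unknown library convention {convention!r}")
    f = ras.flag
    paired = (f & FPAIRED) > 0
    proper = (f & FPROPER) > 0
    mapped = (f & (FUNMAP | FMUNMAP)) == 0
    r1 = (f & FREAD1) > 0
    r2 = (f & FREAD2) > 0
    rev = (f & FREVERSE) > 0
    valid = paired & proper & mapped & (r1 ^ r2)
    # dUTP: read1 reverse -> '+'; read2 forward -> '+'
    plus_mask = valid & ((r1 & rev) | (r2 & ~rev))
    if convention == "fr-secondstrand":
        plus_mask = valid & ~((r1 & rev) | (r2 & ~rev))
    minus_mask = valid & ~plus_mask
    un_mask = ~valid
    reasons = []
    for i in np.flatnonzero(un_mask):
        fi = int(f[i])
        if not (fi & FPAIRED):
            reasons.append("unpaired")
        elif not (fi & FPROPER):
            reasons.append("not_proper_pair")
        elif fi & (FUNMAP | FMUNMAP):
            reasons.append("unmapped_mate")
        else:
            reasons.append("inconsistent_read1_read2_flags")
    return StrandSeparation(
        plus=ras.subset(plus_mask),
        minus=ras.subset(minus_mask),
        unassigned=ras.subset(un_mask),
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# MTPT filtering


def _read_mismatches_slow(ras, i, ref_codes):
    """(ref_pos, ref_code, read_code) mismatch triples for one read (any CIGAR)."""
    out = []
    rpos = int(ras.pos[i])
    qpos = 0
    seq = encode_bases(ras.seq[i])
    for n, op in _cigar_ops(ras.cigar[i]):
        if op in "M=X":
            for k in range(n):
                rc, qc = int(ref_codes[rpos + k]), int(seq[qpos + k])
                if rc != qc and rc < 4 and qc < 4:
                    out.append((rpos + k, rc, qc))
            rpos += n
            qpos += n
        elif op in "DN":
            rpos += n
        elif op in "IS":
            qpos += n
    return out


def _cigar_ops(cigar: str):
    n = ""
    for c in cigar:
        if c.isdigit():
            n += c
        else:
            yield int(n), c
            n = ""


def filter_mtpt_reads(
    ras: ReadAlignmentSet,
    inserts: list[tuple[int, int]],
    reference: str,
    strand: str,
) -> tuple[ReadAlignmentSet, ReadAlignmentSet]:
    """Remove reads that plausibly originate from plastid-like mitochondrial
    inserts (MTPT) rather than the plastome.

    ``inserts`` are plastid-coordinate intervals homologous to mitochondrial
    inserts (0-based half-open). A read overlapping any interval is discarded
    iff it carries at least one mismatch to the plastid reference that is not
    a candidate C-to-U editing observation for its strand assignment (C->T on
    '+', G->A on '-'); reads outside the intervals are untouched. Returns
    (retained, discarded).
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    for iv in inserts:
        if len(iv) < 2 or iv[1] <= iv[0]:
            raise ValueError(f"malformed insert interval {iv!r}")
    if len(ras) == 0:
        return ras, ras.subset(np.zeros(0, dtype=int))
    ref_codes = encode_bases(reference)
    L = ras.uniform_read_length
    cand_ref, cand_read = (1, 3) if strand == "+" else (2, 0)  # C->T or G->A
    if L is not None:
        ends = ras.pos + L
        overlap = np.zeros(len(ras), dtype=bool)
        for s, e in ((iv[0], iv[1]) for iv in inserts):
            overlap |= (ras.pos < e) & (ends > s)
        discard = np.zeros(len(ras), dtype=bool)
        idx = np.flatnonzero(overlap)
        if idx.size:
            sub = ras.subset(idx)
            codes = sub.seq_codes()
            positions = sub.pos[:, None] + np.arange(L)[None, :]
            refm = ref_codes[positions]
            mism = (codes != refm) & (codes < 4) & (refm < 4)
            noncand = mism & ~((refm == cand_ref) & (codes == cand_read))
            discard[idx] = noncand.any(axis=1)
    else:
        discard = np.zeros(len(ras), dtype=bool)
        for i in range(len(ras)):
            span = _read_span(ras, i)
            if not any(span[0] < e and span[1] > s for s, e in
                       ((iv[0], iv[1]) for iv in inserts)):
                continue
            for _, rc, qc in _read_mismatches_slow(ras, i, ref_codes):
                if not (rc == cand_ref and qc == cand_read):
                    discard[i] = True
                    break
    return ras.subset(~discard), ras.subset(discard)


def _read_span(ras, i) -> tuple[int, int]:
    rpos = int(ras.pos[i])
    end = rpos
    for n, op in _cigar_ops(ras.cigar[i]):
        if op in "M=XDN":
            end += n
    return rpos, end


# ---------------------------------------------------------------------------
# coverage and TPM


def depth_of_coverage(ras: ReadAlignmentSet) -> np.ndarray:
    """Per-base aligned depth over the reference (CIGAR-aware).

    M/=/X operations contribute depth; D and N consume reference without
    adding depth; I and S consume only the query. Reads running past the
    reference end raise (circular wrap must be resolved upstream).
    """
    depth = np.zeros(ras.reference_length, dtype=np.int64)
    if len(ras) == 0:
        return depth
    L = ras.uniform_read_length
    if L is not None:
        if int(ras.pos.max()) + L > ras.reference_length:
            raise ValueError("read extends beyond reference end")
        positions = (ras.pos[:, None] + np.arange(L)[None, :]).ravel()
        depth += np.bincount(positions, minlength=ras.reference_length)
        return depth
    for i in range(len(ras)):
        rpos = int(ras.pos[i])
        for n, op in _cigar_ops(ras.cigar[i]):
            if op in "M=X":
                if rpos + n > ras.reference_length:
                    raise ValueError("read extends beyond reference end")
                depth[rpos:rpos + n] += 1
                rpos += n
            elif op in "DN":
                rpos += n
    return depth


def feature_mean_depth(depth: np.ndarray, feature: GeneFeature) -> float:
    """Per-base depth averaged over the exonic length of a feature."""
    total = sum(int(depth[a:b].sum()) for a, b in feature.exons)
    return total / feature.length


def compute_tpm(mean_depths: pd.Series) -> pd.Series:
    """TPM from per-feature mean depths.

    Mean per-base depth is already length-normalised, so it is the feature's
    abundance rate; TPM rescales rates to sum to one million.
    """
    rates = mean_depths.astype(float)
    if (rates < 0).any():
        raise ValueError("negative mean depths")
    total = rates.sum()
    if total == 0:
        raise ValueError("all-zero coverage: TPM undefined")
    return rates / total * 1e6


@dataclass
class CoverageProfile:
    """Strand-specific coverage and per-feature abundance for one individual."""

    individual: str
    depth_plus: np.ndarray
    depth_minus: np.ndarray
    features: pd.DataFrame  # feature, strand, length, mean_depth, tpm


def coverage_profile(
    plus: ReadAlignmentSet,
    minus: ReadAlignmentSet,
    plastome: Plastome,
    feature_types: tuple[str, ...] = ("CDS",),
) -> CoverageProfile:
    """Per-base strand-specific depth plus per-feature mean depth and TPM.

    Each feature is quantified on its own (sense) strand. rRNA and tRNA are
    excluded by default via ``feature_types`` because library preparation
    biases their coverage.
    """
    dp = depth_of_coverage(plus)
    dm = depth_of_coverage(minus)
    feats = [f for f in plastome.features if f.ftype in feature_types]
    # unique by name (IR duplicates once)
    seen = {}
    for f in feats:
        seen.setdefault(f.name, f)
    feats = list(seen.values())
    rows = []
    for f in feats:
        depth = dp if f.strand == "+" else dm
        rows.append(
            {"feature": f.name, "strand": f.strand, "length": f.length,
             "mean_depth": feature_mean_depth(depth, f)}
        )
    tbl = pd.DataFrame(rows)
    if not tbl.empty:
        tbl["tpm"] = compute_tpm(tbl.set_index("feature")["mean_depth"]).values
    return CoverageProfile(plus.individual, dp, dm, tbl)


# ---------------------------------------------------------------------------
# antisense detection


@dataclass(frozen=True)
class AntisenseCall:
    """A putative antisense transcript: sustained coverage opposite annotation."""

    start: int  # 0-based half-open
    end: int
    strand: str
    mean_depth: float
    overlapped_features: tuple[str, ...]  # features on the opposite strand

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_antisense(
    profile: CoverageProfile,
    plastome: Plastome,
    min_length: int = 100,
    floor: float | str = "auto",
) -> list[AntisenseCall]:
    """Call antisense transcripts as maximal intervals of strand-specific
    depth at or above ``floor`` and longer than ``min_length``, located
    opposite annotated features.

    floor="auto" uses the minimum per-feature mean depth among the
    quantified protein-coding genes of the same sample (the published
    fixed-depth equivalent is a manual floor of a few hundred). Positions
    covered by a same-strand feature are excluded so sense transcription is
    never called antisense.
    """
    if floor == "auto":
        if profile.features.empty:
            raise ValueError("auto floor requires quantified protein-coding genes")
        floor_value = float(profile.features["mean_depth"].min())
    else:
        floor_value = float(floor)
    n = len(plastome.sequence)
    calls: list[AntisenseCall] = []
    for strand, depth in (("+", profile.depth_plus), ("-", profile.depth_minus)):
        blocked = np.zeros(n, dtype=bool)
        for f in plastome.features:
            if f.strand == strand:
                blocked[f.start:f.end] = True
        ok = (depth >= floor_value) & ~blocked
        # maximal runs of ok
        padded = np.concatenate(([False], ok, [False])).astype(np.int8)
        d = np.diff(padded)
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            if e - s <= min_length:
                continue
            opp = tuple(
                f.name for f in plastome.features
                if f.strand != strand and f.start < e and f.end > s
            )
            if not opp:
                continue
            calls.append(AntisenseCall(int(s), int(e), strand,
                                       float(depth[s:e].mean()), opp))
    return calls


def antisense_presence(
    calls_by_sample: dict[str, list[AntisenseCall]], groups: dict[str, str]
) -> pd.DataFrame:
    """Presence/absence of merged antisense intervals per group.

    Calls from all samples are merged by overlap on the same strand; a group
    is marked present if any of its samples contributed a call.
    """
    events = []
    for sample, calls in calls_by_sample.items():
        for c in calls:
            events.append((c.strand, c.start, c.end, groups[sample]))
    events.sort()
    merged: list[dict] = []
    for strand, s, e, grp in events:
        for m in merged:
            if m["strand"] == strand and s < m["end"] and e > m["start"]:
                m["start"] = min(m["start"], s)
                m["end"] = max(m["end"], e)
                m["groups"].add(grp)
                break
        else:
            merged.append({"strand": strand, "start": s, "end": e, "groups": {grp}})
    all_groups = sorted(set(groups.values()))
    rows = []
    for m in merged:
        rows.append(
            {"strand": m["strand"], "start": m["start"] + 1, "end": m["end"],
             **{g: g in m["groups"] for g in all_groups}}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison


def compare_groups(
    tpm: pd.DataFrame,
    groups: dict[str, str],
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature two-group comparison of expression.

    Welch's t-test on log2(TPM + pseudocount) per feature, Benjamini-Hochberg
    adjusted across features. ``tpm`` is features x samples; ``groups`` maps
    sample to group label (exactly two groups, each with >= 2 replicates).
    Returns estimate (log2 fold change), raw and adjusted p-values and a
    significance flag at FDR ``alpha``.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a_cols = [s for s in tpm.columns if groups.get(s) == labels[0]]
    b_cols = [s for s in tpm.columns if groups.get(s) == labels[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 replicates")
    la = np.log2(tpm[a_cols].to_numpy(dtype=float) + pseudocount)
    lb = np.log2(tpm[b_cols].to_numpy(dtype=float) + pseudocount)
    est = la.mean(axis=1) - lb.mean(axis=1)
    t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    rej, padj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "feature": tpm.index,
            "log2_fold_change": est,
            "t": t,
            "p_value": p,
            "p_adjusted": padj,
            "significant": rej,
        }
    ).set_index("feature")
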