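"""C-to-U RNA editing discovery and quantification.

Builds strand-specific pileups from aligned reads, scans every reference C
on the transcribed strand (observed as C->T on '+', G->A on '-'), estimates
per-individual editing rates as T/(C+T) of high-quality bases, applies the
reporting thresholds, annotates codon effects and classifies cross-taxon
conservation states.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Plastome, revcomp
from .quant import ReadAlignmentSet, _cigar_ops, encode_bases
from .variation import PLASTID_TABLE_ID, translate_codon


@dataclass(frozen=True)
class ThresholdPolicy:
    """Reporting thresholds for editing sites.

    A site is reported when, in at least one individual, depth >= min_depth
    and (rate >= min_rate or edited bases >= min_edited) — the published
    "5 % (or 10 edited nucleotides)" alternative trigger with a 200-read
    coverage floor. Bases below min_baseq are excluded from allele counts
    but still contribute to depth.
    """

    min_rate: float = 0.05
    min_edited: int = 10
    min_depth: int = 200
    min_baseq: int = 20

    def __post_init__(self):
        if min(self.min_rate, self.min_edited, self.min_depth, self.min_baseq) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class Pileup:
    """Per-position base counts on one strand of one individual.

    counts is (L, 4) over A/C/G/T of bases passing the quality floor; depth
    additionally includes aligned low-quality and N bases.
    """

    counts: np.ndarray
    depth: np.ndarray

    @property
    def length(self) -> int:
        return self.depth.size


def build_pileup(
    ras: ReadAlignmentSet, reference: str, min_baseq: int = 20
) -> Pileup:
    """CIGAR-aware base counting against the reference for one strand-set."""
    L_ref = len(reference)
    if ras.reference_length != L_ref:
        raise ValueError(
            f"reference length mismatch: reads say {ras.reference_length}, "
            f"sequence has {L_ref}"
        )
    counts = np.zeros((L_ref, 4), dtype=np.int64)
    depth = np.zeros(L_ref, dtype=np.int64)
    if len(ras) == 0:
        return Pileup(counts, depth)
    L = ras.uniform_read_length
    if L is not None:
        codes = ras.seq_codes()
        positions = ras.pos[:, None] + np.arange(L)[None, :]
        quals = ras.qual_codes()
        ok = np.ones_like(codes, dtype=bool) if quals is None else quals >= min_baseq
        ok &= codes < 4
        flatpos = positions.ravel()
        depth += np.bincount(flatpos, minlength=L_ref)
        keep = ok.ravel()
        key = flatpos[keep] * 4 + codes.ravel()[keep].astype(np.int64)
        counts += np.bincount(key, minlength=L_ref * 4).reshape(L_ref, 4)
        return Pileup(counts, depth)
    for i in range(len(ras)):
        rpos = int(ras.pos[i])
        qpos = 0
        seq = encode_bases(ras.seq[i])
        q = None if ras.qual is None else np.frombuffer(
            ras.qual[i].encode(), dtype=np.uint8) - 33
        for n, op in _cigar_ops(ras.cigar[i]):
            if op in "M=X":
                for k in range(n):
                    depth[rpos + k] += 1
                    c = int(seq[qpos + k])
                    if c < 4 and (q is None or q[qpos + k] >= min_baseq):
                        counts[rpos + k, c] += 1
                rpos += n
                qpos += n
            elif op in "DN":
                rpos += n
            elif op in "IS":
                qpos += n
    return Pileup(counts, depth)


# ---------------------------------------------------------------------------
# site calling


_A, _C, _G, _T = 0, 1, 2, 3


@dataclass
class EditingCallResult:
    """Candidate editing sites with per-individual rates.

    sites: one row per (position, strand) with the reporting decision;
    per_individual: tidy counts with one row per site x individual.
    Positions are 0-based internally.
    """

    sites: pd.DataFrame
    per_individual: pd.DataFrame


def call_editing_sites(
    pileups: dict[str, dict[str, Pileup]],
    reference: str,
    policy: ThresholdPolicy = ThresholdPolicy(),
    plastome: Plastome | None = None,
    exclude_types: tuple[str, ...] = ("tRNA", "rRNA"),
) -> EditingCallResult:
    """Scan every reference C on each transcribed strand for C-to-U editing.

    ``pileups`` maps individual -> {'+': Pileup, '-': Pileup}. The editing
    rate is T/(C+T) on the plus strand and, equivalently on complemented
    counts, A/(G+A) on the minus strand. A site is reported if at least one
    individual passes the policy; sites that fail everywhere but show at
    least one edited base in every individual are kept in a below-threshold
    annex (``below_threshold`` flag). Positions inside rRNA/tRNA annotation
    are excluded (biased coverage).
    """
    ref_codes = encode_bases(reference)
    individuals = list(pileups)
    masked = np.zeros(len(reference), dtype=bool)
    if plastome is not None:
        for f in plastome.features:
            if f.ftype in exclude_types:
                masked[f.start:f.end] = True

    site_rows = []
    indiv_rows = []
    for strand, ref_base, un_code, ed_code in (
        ("+", _C, _C, _T), ("-", _G, _G, _A)
    ):
        cand = np.flatnonzero((ref_codes == ref_base) & ~masked)
        if cand.size == 0:
            continue
        un = np.zeros((len(individuals), cand.size), dtype=np.int64)
        ed = np.zeros_like(un)
        dp = np.zeros_like(un)
        for k, ind in enumerate(individuals):
            p = pileups[ind][strand]
            un[k] = p.counts[cand, un_code]
            ed[k] = p.counts[cand, ed_code]
            dp[k] = p.depth[cand]
        tot = un + ed
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(tot > 0, ed / np.maximum(tot, 1), np.nan)
        passes = (dp >= policy.min_depth) & (
            (rate >= policy.min_rate) | (ed >= policy.min_edited)
        )
        edited_any = ed > 0
        reported = passes.any(axis=0) & edited_any.any(axis=0)
        # annex: consistently edited in every individual, at a pooled rate
        # clearly above the sequencing-error background, yet never passing
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = ed.sum(axis=0) / np.maximum(tot.sum(axis=0), 1)
        annex = (~reported) & edited_any.all(axis=0) & (pooled >= 0.01)
        for j in np.flatnonzero(reported | annex):
            pos = int(cand[j])
            site_rows.append(
                {
                    "position": pos,
                    "strand": strand,
                    "reported": bool(reported[j]),
                    "below_threshold": bool(annex[j]),
                    "mean_rate": float(np.nanmean(rate[:, j])),
                }
            )
            for k, ind in enumerate(individuals):
                indiv_rows.append(
                    {
                        "position": pos,
                        "strand": strand,
                        "individual": ind,
                        "edited": int(ed[k, j]),
                        "unedited": int(un[k, j]),
                        "depth": int(dp[k, j]),
                        "rate": float(rate[k, j]) if tot[k, j] > 0 else np.nan,
                    }
                )
    sites = pd.DataFrame(
        site_rows,
        columns=["position", "strand", "reported", "below_threshold", "mean_rate"],
    ).sort_values(["position", "strand"]).reset_index(drop=True)
    per_ind = pd.DataFrame(
        indiv_rows,
        columns=["position", "strand", "individual", "edited", "unedited",
                 "depth", "rate"],
    )
    return EditingCallResult(sites, per_ind)


# ---------------------------------------------------------------------------
# effect annotation


@dataclass(frozen=True)
class EffectAnnotation:
    context: str  # gene name, "<gene>_intron", or "intergenic"
    category: str  # nonsynonymous | silent | start_created | stop_created | noncoding
    label: str
    codon_index: int | None = None
    codon_position: int | None = None
    codon_before: str | None = None
    codon_after: str | None = None


def annotate_effect(
    position: int,
    strand: str,
    plastome: Plastome,
    table_id: int = PLASTID_TABLE_ID,
) -> EffectAnnotation:
    """Codon effect of a C-to-U edit at a genomic position.

    For CDS sites reports the codon before/after with amino acids in the
    style "TCA (S) => TTA (L)", flagging start-codon creation (edited
    ACG -> ATG at the first codon) and premature stop creation. Sites in
    introns or intergenic space are labelled non-coding.
    """
    for f in plastome.features:
        if f.ftype != "CDS" or f.strand != strand:
            continue
        if not (f.start <= position < f.end):
            continue
        tpos = f.transcript_positions()
        try:
            i = tpos.index(position)
        except ValueError:
            return EffectAnnotation(f"{f.name}_intron", "noncoding", "intron")
        ci, cp = divmod(i, 3)
        codon_positions = tpos[3 * ci:3 * ci + 3]
        if len(codon_positions) < 3:
            raise ValueError(
                f"position {position}: codon spans past the exon map of {f.name}"
            )
        bases = [plastome.sequence[p] for p in codon_positions]
        if f.strand == "-":
            bases = [revcomp(b) for b in bases]
        before = "".join(bases)
        if before[cp] != "C":
            raise ValueError(
                f"position {position} is {before[cp]} on the transcribed strand, "
                "not a C-to-U candidate"
            )
        after = before[:cp] + "T" + before[cp + 1:]
        aa_b = translate_codon(before, table_id)
        aa_a = translate_codon(after, table_id)
        if ci == 0 and after == "ATG":
            category = "start_created"
            label = f"{before}({aa_b}) => ATG (Start)"
        elif aa_a == "*":
            category = "stop_created"
            label = f"{before}({aa_b}) => {after}(Stop)"
        elif aa_a == aa_b:
            category = "silent"
            label = f"Silent {before} ({aa_b}) => {after} ({aa_a})"
        else:
            category = "nonsynonymous"
            label = f"{before} ({aa_b}) => {after} ({aa_a})"
        return EffectAnnotation(f.name, category, label, ci, cp + 1, before, after)
    for f in plastome.features:
        if f.ftype == "intron" and f.start <= position < f.end:
            return EffectAnnotation(f.name, "noncoding", "intron")
    return EffectAnnotation("intergenic", "noncoding", "intergenic")


# ---------------------------------------------------------------------------
# cross-taxon conservation


CONSERVATION_STATES = ("Edit", "T", "C", "C?", "NA")


def classify_conservation(
    ortho_alignment: dict[str, str] | None,
    focal: str,
    focal_position: int,
    edit_lists: dict[str, set[int]] | None = None,
) -> dict[str, str]:
    """Conservation state of an edited position across taxa.

    ``ortho_alignment`` is a gapped orthologous alignment (transcript
    orientation) containing the focal taxon; ``focal_position`` is the
    ungapped position of the edited C in the focal row. Per taxon: "T" for a
    genomic T at the homologous column; "Edit" for a genomic C present in
    that taxon's known-edit list (ungapped coordinates); "C" for a genomic C
    known unedited (taxon has an edit list not containing the position);
    "C?" for a genomic C with no editing information; "NA" when the column
    is gapped. Any other base is reported literally. Passing None (e.g. an
    unalignable intergenic site) yields no states — callers mark all taxa NA.
    """
    if ortho_alignment is None:
        return {}
    edit_lists = edit_lists or {}
    focal_row = ortho_alignment[focal]
    cols = [i for i, c in enumerate(focal_row) if c != "-"]
    col = cols[focal_position]
    out: dict[str, str] = {}
    for taxon, row in ortho_alignment.items():
        if taxon == focal:
            continue
        c = row[col].upper()
        if c == "-":
            out[taxon] = "NA"
        elif c == "T":
            out[taxon] = "T"
        elif c == "C":
            if taxon in edit_lists:
                upos = sum(1 for x in row[:col] if x != "-")
                out[taxon] = "Edit" if upos in edit_lists[taxon] else "C"
            else:
                out[taxon] = "C?"
        else:
            out[taxon] = c
    return out


# ---------------------------------------------------------------------------
# group comparison


def compare_editing(
    per_individual: pd.DataFrame,
    groups: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-site comparison of editing between two groups (sexes or haplotypes).

    Pools edited/unedited counts within each group for an exact
    two-proportion (Fisher) test, reports per-group mean +/- SD of individual rates, and adjusts
    p-values by Benjamini-Hochberg across sites. Sites where either group
    has no individual with a defined rate are skipped (flagged in the
    returned frame's ``skipped`` column is absent — they are simply not
    returned; the count is available via attrs['n_skipped']).
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    df = per_individual.copy()
    df["group"] = df["individual"].map(groups)
    df = df.dropna(subset=["group"])
    rows = []
    skipped = 0
    for (pos, strand), sub in df.groupby(["position", "strand"]):
        by = {g: sub[sub["group"] == g] for g in labels}
        if any(b["rate"].notna().sum() < 2 for b in by.values()):
            skipped += 1
            continue
        pooled_ed = [int(by[g]["edited"].sum()) for g in labels]
        pooled_tot = [int((by[g]["edited"] + by[g]["unedited"]).sum()) for g in labels]
        if pooled_ed[0] == pooled_ed[1] and pooled_tot[0] == pooled_tot[1]:
            p = 1.0
        elif sum(pooled_ed) == 0 or sum(pooled_ed) == sum(pooled_tot):
            p = 1.0
        else:
            table = [
                [pooled_ed[0], pooled_tot[0] - pooled_ed[0]],
                [pooled_ed[1], pooled_tot[1] - pooled_ed[1]],
            ]
            _, p = stats.fisher_exact(table)
        rows.append(
            {
                "position": pos,
                "strand": strand,
                f"rate_{labels[0]}": by[labels[0]]["rate"].mean(),
                f"sd_{labels[0]}": by[labels[0]]["rate"].std(),
                f"rate_{labels[1]}": by[labels[1]]["rate"].mean(),
                f"sd_{labels[1]}": by[labels[1]]["rate"].std(),
                "pooled_rate_diff": pooled_ed[0] / max(pooled_tot[0], 1)
                - pooled_ed[1] / max(pooled_tot[1], 1),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        rej, padj, _, _ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
        out["p_adjusted"] = padj
        out["significant"] = rej
    out.attrs["n_skipped"] = skipped
    return out
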