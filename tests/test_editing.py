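"""Pileup construction, editing-site calling, effect annotation,
conservation classification and group comparison."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import make_read_set
from plastkit.editing import (
    Pileup,
    ThresholdPolicy,
    annotate_effect,
    build_pileup,
    call_editing_sites,
    classify_conservation,
    compare_editing,
)
from plastkit.model import GeneFeature, Plastome

REF = "AACCGGTTAACCGGTTAACC"  # 20 bp


# ---------------------------------------------------------------------------
# pileup


def test_uniform_c_column_counts():
    ras = make_read_set([(0, "10M", REF[:10])] * 10, reference_length=20)
    p = build_pileup(ras, REF)
    assert p.counts[2, 1] == 10  # C at position 2
    assert p.depth[2] == 10


def test_mixed_c_t_column():
    reads = [(0, "10M", REF[:10])] * 7
    edited = REF[:2] + "T" + REF[3:10]
    reads += [(0, "10M", edited)] * 3
    p = build_pileup(make_read_set(reads, reference_length=20), REF)
    assert p.counts[2, 1] == 7 and p.counts[2, 3] == 3
    assert p.depth[2] == 10


def _brute_force_pileup(ras, ref_len):
    """Per-read CIGAR walk with a dict, written independently."""
    import re

    counts = {}
    depth = {}
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i in range(len(ras)):
        pos, q = int(ras.pos[i]), 0
        for n, op in re.findall(r"(\d+)([MIDNSX=])", ras.cigar[i]):
            n = int(n)
            if op in "M=X":
                for k in range(n):
                    depth[pos + k] = depth.get(pos + k, 0) + 1
                    b = ras.seq[i][q + k]
                    if b in code:
                        key = (pos + k, code[b])
                        counts[key] = counts.get(key, 0) + 1
                pos += n
                q += n
            elif op in "DN":
                pos += n
            elif op in "IS":
                q += n
    c = np.zeros((ref_len, 4), dtype=int)
    d = np.zeros(ref_len, dtype=int)
    for (p, b), v in counts.items():
        c[p, b] = v
    for p, v in depth.items():
        d[p] = v
    return c, d


def test_pileup_matches_per_read_scan_on_hand_built_sam():
    ras = make_read_set(
        [
            (0, "8M", REF[:8]),
            (2, "3M2D5M", REF[2:5] + REF[7:12]),  # deletion spans positions 5-6
            (4, "4M1I4M", REF[4:8] + "A" + REF[8:12]),
            (6, "2S6M", "GG" + REF[6:12]),
            (1, "8M", "T" * 8),
        ],
        reference_length=20,
    )
    p = build_pileup(ras, REF)
    bc, bd = _brute_force_pileup(ras, 20)
    assert (p.counts == bc).all()
    assert (p.depth == bd).all()


def test_deleted_positions_contribute_no_base_counts():
    ras = make_read_set([(0, "3M2D5M", REF[:3] + REF[5:10])] * 5,
                        reference_length=20)
    p = build_pileup(ras, REF)
    assert p.counts[3].sum() == 0 and p.counts[4].sum() == 0
    assert p.depth[3] == 0


def test_low_quality_bases_excluded_from_counts_but_in_depth():
    quals = ["I" * 5 + "#" + "I" * 4]  # one Q2 base at offset 5
    ras = make_read_set([(0, "10M", REF[:10])], reference_length=20,
                        quals=quals)
    p = build_pileup(ras, REF, min_baseq=20)
    assert p.counts[5].sum() == 0
    assert p.depth[5] == 1


def test_reference_length_mismatch_raises():
    ras = make_read_set([(0, "4M", "ACGT")], reference_length=50)
    with pytest.raises(ValueError):
        build_pileup(ras, REF)


# ---------------------------------------------------------------------------
# site calling


def _pileup_pair(ref_len, plus=None, minus=None):
    def mk(spec):
        counts = np.zeros((ref_len, 4), dtype=np.int64)
        depth = np.zeros(ref_len, dtype=np.int64)
        for pos, acgt in (spec or {}).items():
            counts[pos] = acgt
            depth[pos] = sum(acgt)
        return Pileup(counts, depth)

    return {"+": mk(plus), "-": mk(minus)}


def test_high_rate_site_reported():
    ref = "A" * 10 + "C" + "A" * 9
    pl = {"x": _pileup_pair(20, plus={10: (0, 7, 0, 93)})}
    # depth 100 < 200: not reported; at depth 500 it is
    res = call_editing_sites(pl, ref, ThresholdPolicy(min_depth=100))
    assert res.sites.iloc[0]["reported"]
    assert res.per_individual.iloc[0]["rate"] == pytest.approx(0.93)


def test_alternative_trigger_ten_edited_bases():
    ref = "C" + "A" * 19
    pl = {"x": _pileup_pair(20, plus={0: (0, 490, 0, 10)})}
    res = call_editing_sites(pl, ref, ThresholdPolicy())
    row = res.sites.iloc[0]
    assert row["reported"]  # rate 0.02 < 5% but 10 edited bases
    assert res.per_individual.iloc[0]["rate"] == pytest.approx(0.02)


def test_minus_strand_site_uses_complemented_counts():
    ref = "A" * 5 + "G" + "A" * 14
    pl = {"x": _pileup_pair(20, minus={5: (180, 0, 420, 0)})}  # A=180 G=420
    res = call_editing_sites(pl, ref, ThresholdPolicy())
    row = res.sites.iloc[0]
    assert row["strand"] == "-"
    assert res.per_individual.iloc[0]["rate"] == pytest.approx(0.3)


def test_reference_t_positions_never_emitted():
    rng = np.random.default_rng(2)
    ref = "".join(rng.choice(list("ACGT"), 50))
    counts_plus = {i: tuple(rng.integers(0, 300, 4)) for i in range(50)}
    pl = {"x": _pileup_pair(50, plus=counts_plus, minus=counts_plus)}
    res = call_editing_sites(pl, ref, ThresholdPolicy(min_depth=1, min_rate=0.0))
    for r in res.sites.itertuples():
        base = ref[r.position]
        assert base == ("C" if r.strand == "+" else "G")


def test_raising_min_depth_never_adds_sites():
    rng = np.random.default_rng(3)
    ref = "".join(rng.choice(list("ACGT"), 80))
    counts = {i: tuple(rng.integers(0, 200, 4)) for i in range(80)}
    pl = {"x": _pileup_pair(80, plus=counts)}
    prev = None
    for d in (50, 150, 400, 1000):
        res = call_editing_sites(pl, ref, ThresholdPolicy(min_depth=d))
        got = {(r.position, r.strand)
               for r in res.sites[res.sites.reported].itertuples()}
        if prev is not None:
            assert got <= prev
        prev = got


def test_zero_c_plus_t_recorded_as_missing():
    ref = "C" + "A" * 19
    pl = {
        "x": _pileup_pair(20, plus={0: (0, 400, 0, 100)}),
        "y": _pileup_pair(20, plus={0: (300, 0, 0, 0)}),  # A-only pileup
    }
    res = call_editing_sites(pl, ref, ThresholdPolicy())
    y = res.per_individual.query("individual == 'y'").iloc[0]
    assert np.isnan(y["rate"])


# ---------------------------------------------------------------------------
# effect annotation


def _toy_plastome():
    #        g+: ATG TCA GTC CAA TAA  at 0..14   (plus strand)
    #        g-: revcomp(ATG ACG CAT TAA) at 20..31 (minus strand)
    plus_gene = "ATGTCAGTCCAATAA"
    minus_gene = "ATGACGCATTAA"
    from plastkit.model import revcomp

    seq = plus_gene + "AAAAA" + revcomp(minus_gene) + "GGGGG"
    feats = [
        GeneFeature("gp", "CDS", "+", ((0, 15),)),
        GeneFeature("gm", "CDS", "-", ((20, 32),)),
    ]
    return Plastome("toy", seq, feats)


def test_tca_edit_is_serine_to_leucine():
    p = _toy_plastome()
    eff = annotate_effect(4, "+", p)  # TCA, codon 2, position 2
    assert eff.category == "nonsynonymous"
    assert eff.label == "TCA (S) => TTA (L)"


def test_gtc_third_position_is_silent():
    p = _toy_plastome()
    eff = annotate_effect(8, "+", p)  # GTC -> GTT
    assert eff.category == "silent"
    assert "GTC (V) => GTT (V)" in eff.label


def test_caa_edit_creates_stop():
    p = _toy_plastome()
    eff = annotate_effect(9, "+", p)  # CAA -> TAA
    assert eff.category == "stop_created"
    assert "(Stop)" in eff.label


def test_acg_codon_on_minus_strand_gene():
    p = _toy_plastome()
    # gm codon 2 is ACG; its C is genome G on the plus strand
    tpos = p.feature("gm").transcript_positions()
    pos = tpos[4]  # codon 2, position 2
    eff = annotate_effect(pos, "-", p)
    assert eff.codon_before == "ACG"
    assert eff.codon_after == "ATG"
    assert eff.category == "nonsynonymous"  # T -> M mid-gene


def test_start_codon_creation_flagged():
    from plastkit.model import revcomp

    seq = "ACGTCAGTCCAATAA" + "A" * 10
    p = Plastome("toy", seq, [GeneFeature("g", "CDS", "+", ((0, 15),),
                                          edited_start_or_stop=True)])
    eff = annotate_effect(1, "+", p)
    assert eff.category == "start_created"
    assert "ATG (Start)" in eff.label


def test_non_candidate_position_rejected():
    p = _toy_plastome()
    with pytest.raises(ValueError):
        annotate_effect(0, "+", p)  # A, not C


def test_intergenic_and_intron_context():
    p = _toy_plastome()
    assert annotate_effect(16, "+", p).context == "intergenic"


# ---------------------------------------------------------------------------
# conservation


def test_conservation_states():
    aln = {
        "focal":  "ATGTCA",
        "tax_t":  "ATGTTA",   # T at the edited position
        "tax_e":  "ATGTCA",   # C, known edited
        "tax_c":  "ATGTCA",   # C, known unedited
        "tax_q":  "ATGTCA",   # C, no information
        "tax_na": "ATGT-A",   # gapped column
    }
    states = classify_conservation(
        aln, "focal", 4,
        edit_lists={"tax_e": {4}, "tax_c": set()},
    )
    assert states == {"tax_t": "T", "tax_e": "Edit", "tax_c": "C",
                      "tax_q": "C?", "tax_na": "NA"}


def test_unalignable_site_returns_no_states():
    assert classify_conservation(None, "f", 0) == {}


def test_gap_shifted_coordinates_use_taxon_own_positions():
    aln = {"focal": "AT--GTCA", "other": "ATCCGTCA"}
    states = classify_conservation(aln, "focal", 4, {"other": {6}})
    assert states == {"other": "Edit"}


# ---------------------------------------------------------------------------
# group comparison


def _per_individual(rows):
    return pd.DataFrame(
        rows, columns=["position", "strand", "individual", "edited",
                       "unedited", "depth", "rate"]
    )


def test_identical_pooled_counts_not_significant():
    rows = []
    for ind, grp in [("a1", "F"), ("a2", "F"), ("b1", "H"), ("b2", "H")]:
        rows.append((100, "+", ind, 50, 50, 100, 0.5))
    res = compare_editing(_per_individual(rows),
                          {"a1": "F", "a2": "F", "b1": "H", "b2": "H"})
    assert res.iloc[0]["p_value"] == 1.0
    assert not res.iloc[0]["significant"]


def test_zero_versus_six_percent_at_high_depth_detected():
    rows = []
    for i in range(6):
        rows.append((100, "+", f"k{i}", 0, 1000, 1000, 0.0))
        rows.append((100, "+", f"v{i}", 60, 940, 1000, 0.06))
    groups = {f"k{i}": "KRA" for i in range(6)}
    groups.update({f"v{i}": "KOV" for i in range(6)})
    res = compare_editing(_per_individual(rows), groups)
    assert res.iloc[0]["significant"]
    assert res.iloc[0]["rate_KOV"] == pytest.approx(0.06)


def test_sites_without_defined_rates_in_a_group_are_skipped():
    rows = [
        (5, "+", "a1", 10, 90, 100, 0.1),
        (5, "+", "a2", 12, 88, 100, 0.12),
        (5, "+", "b1", 11, 89, 100, np.nan),
        (5, "+", "b2", 9, 91, 100, np.nan),
    ]
    res = compare_editing(_per_individual(rows),
                          {"a1": "F", "a2": "F", "b1": "H", "b2": "H"})
    assert res.empty
    assert res.attrs["n_skipped"] == 1
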