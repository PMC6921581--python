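"""Phylogenetic input preparation: IRa removal, masking, indel coding,
CDS concatenation."""
from __future__ import annotations

import numpy as np
import pytest

from plastkit.model import GeneFeature, Plastome
from plastkit.phyloprep import (
    concatenate_cds,
    mask_homopolymers,
    remove_ira,
    simple_indel_coding,
    write_nexus,
    write_phylip,
    write_raxml_partitions,
)


# ---------------------------------------------------------------------------
# IRa removal


def test_remove_ira_outside_alignment_is_noop_like():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), size=30))
    aln = {"r": seq, "s": seq}
    out, kept = remove_ira(aln, (25, 28), "r")
    assert len(out["r"]) == 27
    assert out["r"] == seq[:25] + seq[28:]


def test_remove_ira_columns_10_to_20_of_30_leaves_19():
    seq = "A" * 30
    aln = {"r": seq.replace("A", "C", 1)}  # any content
    aln = {"r": "ACGT" * 7 + "AC", "s": "ACGT" * 7 + "AC"}
    out, kept = remove_ira(aln, (9, 20), "r")  # columns 10..20, 1-based
    assert len(out["r"]) == 19
    assert list(kept) == list(range(9)) + list(range(20, 30))


def test_remove_ira_takes_reference_gap_columns_with_it():
    aln = {"r": "AAA---TTTGGG", "s": "AAACCCTTTGGG"}
    out, _ = remove_ira(aln, (2, 7), "r")  # spans the gap block
    assert out["r"] == "AAGG"
    assert out["s"] == "AAGG"


def test_remove_ira_requires_boundaries():
    with pytest.raises(ValueError):
        remove_ira({"r": "ACGT"}, None, "r")


def test_synthetic_alignment_shrinks_by_planted_ir_length(small_study):
    base = small_study.plastomes["A"]
    ira = base.boundaries["IRa"]
    out, _ = remove_ira(small_study.msa, ira, "A")
    ncol = len(small_study.msa["A"])
    # no haplotype edits fall inside the IRs, so exactly IR-length columns go
    assert len(out["A"]) == ncol - (ira[1] - ira[0])


# ---------------------------------------------------------------------------
# homopolymer masking


def test_homopolymer_longer_than_five_masked_outside_cds():
    aln = {"r": "GGAAAAAAGG", "s": "GGAAAAAAGG"}
    masked = mask_homopolymers(aln)
    assert masked.masked_columns == [2, 3, 4, 5, 6, 7]


def test_homopolymer_of_exactly_five_not_masked():
    aln = {"r": "GGAAAAAGGG", "s": "GGAAAAAGGG"}
    assert mask_homopolymers(aln).masked_columns == []


def test_homopolymer_inside_cds_is_exempt():
    aln = {"r": "GGAAAAAAGG", "s": "GGAAAAAAGG"}
    cds = [GeneFeature("g", "CDS", "+", ((0, 10),))]
    masked = mask_homopolymers(aln, cds, "r")
    assert masked.masked_columns == []


def test_mask_union_over_rows_and_run_length_on_ungapped_sequence():
    # the run is split by a gap in row s but not in row r
    aln = {"r": "GGAAAAAAGG", "s": "GGAAA-AAGG"}
    masked = mask_homopolymers(aln)
    # row r implicates its 6-run's columns; s has runs of 3 and 2 only
    assert masked.masked_columns == [2, 3, 4, 5, 6, 7]


def test_masking_preserves_unmasked_columns():
    aln = {"r": "GGAAAAAAGGTT", "s": "CCAAAAAAGGTT"}
    masked = mask_homopolymers(aln)
    kept = masked.without_masked()
    drop = set(masked.masked_columns)
    for g in aln:
        assert kept[g] == "".join(
            c for i, c in enumerate(aln[g]) if i not in drop)


# ---------------------------------------------------------------------------
# simple indel coding


def test_single_shared_block():
    m = simple_indel_coding({"a": "A--T", "b": "ACGT", "c": "ACGT"})
    assert m.blocks == [(1, 3)]
    assert m.states == {"a": "1", "b": "0", "c": "0"}


def test_nested_gap_scores_question_mark():
    m = simple_indel_coding({"a": "A---T", "b": "A--GT"})
    assert m.blocks == [(1, 3), (1, 4)]
    # a's gap (1,4) strictly contains b's block (1,3) -> '?'
    assert m.states["a"] == "?1"
    assert m.states["b"] == "10"


def test_gap_free_alignment_yields_no_characters():
    m = simple_indel_coding({"a": "ACGT", "b": "ACGT"})
    assert m.n_characters == 0


def _brute_force_sic(aln: dict[str, str]):
    """Re-derivation of the simple-coding rules, written independently."""
    def blocks_of(row):
        out, i = [], 0
        while i < len(row):
            if row[i] == "-":
                j = i
                while j < len(row) and row[j] == "-":
                    j += 1
                out.append((i, j))
                i = j
            else:
                i += 1
        return out

    per = {t: blocks_of(r) for t, r in aln.items()}
    chars = sorted({b for bs in per.values() for b in bs})
    states = {}
    for t, row in aln.items():
        s = []
        for c in chars:
            if c in per[t]:
                s.append("1")
            else:
                container = [
                    g for g in per[t] if g[0] <= c[0] and c[1] <= g[1]
                ]
                s.append("?" if container else "0")
        states[t] = "".join(s)
    return chars, states


@pytest.mark.parametrize("seed", range(6))
def test_indel_coding_matches_brute_force_on_random_alignments(seed):
    rng = np.random.default_rng(seed)
    taxa = {}
    for t in "abcde":
        row = list("".join(rng.choice(list("ACGT"), size=60)))
        for _ in range(4):  # plant gap runs
            start = int(rng.integers(0, 55))
            ln = int(rng.integers(1, 6))
            row[start:start + ln] = "-" * min(ln, 60 - start)
        taxa[t] = "".join(row)
    m = simple_indel_coding(taxa)
    blocks, states = _brute_force_sic(taxa)
    assert m.blocks == blocks
    assert m.states == states


# ---------------------------------------------------------------------------
# CDS concatenation


def _toy_genomes():
    rng = np.random.default_rng(9)
    g1 = "ATGGCTGCTGCTGCTGCTGCTGCTGGGTAA"  # 30 bp
    g2 = "ATG" + "GCT" * 18 + "TAA"  # 60 bp
    def genome(gid, second_gene=True):
        spacer = "".join(rng.choice(list("ACGT"), 10))
        seq = g1 + spacer + (g2 if second_gene else "")
        feats = [GeneFeature("geneA", "CDS", "+", ((0, 30),))]
        if second_gene:
            feats.append(GeneFeature("geneB", "CDS", "+", ((40, 100),)))
        return Plastome(gid, seq, feats)
    return genome


def test_concatenation_partitions_and_length():
    mk = _toy_genomes()
    sm = concatenate_cds({"x": mk("x"), "y": mk("y")})
    assert sm.length == 90
    assert sm.partitions == [("geneA", 0, 30), ("geneB", 30, 90)]
    assert not sm.missing_genes


def test_missing_gene_filled_with_question_marks():
    mk = _toy_genomes()
    sm = concatenate_cds({"x": mk("x"), "y": mk("y", second_gene=False)})
    assert sm.rows["y"][30:] == "?" * 60
    assert ("y", "geneB") in sm.missing_genes


def test_writers_produce_readable_files(tmp_path, small_study):
    sm = concatenate_cds(small_study.plastomes)
    assert len(sm.partitions) == small_study.config.n_genes
    write_phylip(sm.rows, tmp_path / "m.phy")
    write_raxml_partitions(sm.partitions, tmp_path / "p.txt", indel_characters=3)
    aln = {"a": "AC-T", "b": "ACGT"}
    m = simple_indel_coding(aln)
    write_nexus(aln, tmp_path / "m.nex", m)
    head = (tmp_path / "m.phy").read_text().splitlines()[0].split()
    assert head == [str(len(sm.rows)), str(sm.length)]
    ptxt = (tmp_path / "p.txt").read_text()
    assert f"BIN, indels = {sm.partitions[-1][2] + 1}-" in ptxt
    nex = (tmp_path / "m.nex").read_text()
    assert "datatype=mixed(DNA:1-4,restriction:5-5)" in nex
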