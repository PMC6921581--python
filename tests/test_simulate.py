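"""The synthetic-data generator: determinism, invariants, planted truth."""
from __future__ import annotations

import numpy as np
import pytest

from plastkit.model import revcomp
from plastkit.quant import separate_strands
from plastkit.simulate import (
    ConfigurationError,
    SimulationConfig,
    derive_haplotype,
    make_mito_with_inserts,
    make_plastome,
    simulate_reads,
)


def test_same_seed_gives_byte_identical_genomes():
    a1, _ = make_plastome(SimulationConfig(seed=7))
    a2, _ = make_plastome(SimulationConfig(seed=7))
    assert a1.sequence == a2.sequence
    assert a1.features == a2.features


def test_same_seed_gives_identical_reads(small_config, small_study):
    from plastkit.simulate import simulate_study

    again = simulate_study(small_config)
    r1 = small_study.reads["A_F1"]
    r2 = again.reads["A_F1"]
    assert r1.seq == r2.seq
    assert (r1.pos == r2.pos).all()


def test_quadripartite_invariants(small_study):
    for p in small_study.plastomes.values():
        p.check_boundaries()  # partition + IRa == revcomp(IRb)
        lsc = p.boundaries["LSC"]
        ssc = p.boundaries["SSC"]
        ira = p.boundaries["IRa"]
        assert (lsc[1] - lsc[0]) > (ssc[1] - ssc[0])
        assert ira[1] - ira[0] >= 1000


def test_planted_length_arithmetic():
    cfg = SimulationConfig(seed=3, plastome_length=30000, ir_length=4000)
    p, _ = make_plastome(cfg)
    b = p.boundaries
    lsc = b["LSC"][1] - b["LSC"][0]
    ssc = b["SSC"][1] - b["SSC"][0]
    assert lsc + ssc == 22000
    assert p.sequence[slice(*b["IRa"])] == revcomp(p.sequence[slice(*b["IRb"])])


def test_infeasible_gene_load_raises_named_error():
    cfg = SimulationConfig(seed=0, plastome_length=14000, ir_length=2500,
                           n_genes=40, gene_length_range=(600, 900))
    with pytest.raises(ConfigurationError, match="does not fit"):
        make_plastome(cfg)


def test_short_ir_rejected():
    with pytest.raises(ConfigurationError, match="ir_length"):
        SimulationConfig(ir_length=500).validate()


def test_editing_positions_are_reference_c_on_transcribed_strand(small_study):
    for h, p in small_study.plastomes.items():
        for s in small_study.truths[h].editing_sites:
            base = p.sequence[s.position]
            assert base == ("C" if s.strand == "+" else "G")


def test_zero_edit_derivation_is_identity(small_study):
    base = small_study.plastomes["A"]
    truth = small_study.truths["A"]
    d, t = derive_haplotype(base, truth, "Z", 0, 0, seed=5,
                            ssr_variation=False)
    assert d.sequence == base.sequence
    assert t.diff.n_substitutions == 0 and t.diff.n_indels == 0


def test_derived_truth_positions_match_derived_genome(small_study):
    d = small_study.plastomes["B"]
    t = small_study.truths["B"]
    for s in t.editing_sites:
        assert d.sequence[s.position] == ("C" if s.strand == "+" else "G")
    for l in t.ssrs:
        assert d.sequence[l.start:l.end] == (l.unit * l.unit_count)


def test_mito_divergence_marker_arithmetic(small_study):
    base = small_study.plastomes["A"]
    mito = make_mito_with_inserts(base, [(1000, 2000, 0.02)], seed=1)
    (ins,) = mito.inserts
    assert len(ins.markers) == 20
    assert ins.size == 1000
    # mito carries the diverged copy
    seg = mito.sequence[ins.mito_start:ins.mito_end]
    plast = base.sequence[1000:2000]
    mismatches = sum(1 for a, b in zip(seg, plast) if a != b)
    assert mismatches == 20


def test_insert_of_377_nt(small_study):
    base = small_study.plastomes["A"]
    mito = make_mito_with_inserts(base, [(100, 477, 0.02)], seed=2)
    assert mito.inserts[0].size == 377


def test_empty_insert_spec_gives_plain_mito(small_study):
    base = small_study.plastomes["A"]
    mito = make_mito_with_inserts(base, [], seed=3)
    assert mito.inserts == []


def test_out_of_range_divergence_rejected(small_study):
    base = small_study.plastomes["A"]
    with pytest.raises(ConfigurationError):
        make_mito_with_inserts(base, [(0, 500, 0.2)], seed=1)


def test_read_conservation_per_individual(small_study):
    for ind, ras in small_study.reads.items():
        sep = separate_strands(ras)
        assert len(sep.plus) + len(sep.minus) + len(sep.unassigned) == len(ras)
        assert len(sep.unassigned) == 0  # generator emits proper pairs only


def test_mate_records_are_consistent(small_study):
    ras = small_study.reads["B_H2"]
    by_name: dict[str, list[int]] = {}
    for i, q in enumerate(ras.qname):
        by_name.setdefault(q, []).append(i)
    for q, idx in list(by_name.items())[:500]:
        assert len(idx) == 2
        i, j = idx
        assert ras.mpos[i] == ras.pos[j]
        assert ras.mpos[j] == ras.pos[i]
        assert ras.tlen[i] == -ras.tlen[j]
        r1 = bool(ras.flag[i] & 0x40) + bool(ras.flag[j] & 0x40)
        assert r1 == 1  # exactly one read1 per pair


def test_zero_rate_site_shows_only_error_level_t(small_study):
    # haplotype A's private-site rate is 0: T fraction stays at error level
    from plastkit.editing import build_pileup

    truth = small_study.truths["A"]
    site = next(s for s in truth.editing_sites if s.rate_for("A") == 0.0)
    p = small_study.plastomes["A"]
    ed = un = 0
    for ind in ["A_F1", "A_F2", "A_F3"]:
        sep = separate_strands(small_study.reads[ind])
        strand_reads = sep.plus if site.strand == "+" else sep.minus
        pu = build_pileup(strand_reads, p.sequence)
        e_code, u_code = (3, 1) if site.strand == "+" else (0, 2)
        ed += pu.counts[site.position, e_code]
        un += pu.counts[site.position, u_code]
    rate = ed / max(ed + un, 1)
    assert rate < 3 * small_study.config.error_rate


def test_high_rate_site_within_binomial_noise(small_study):
    from plastkit.editing import build_pileup

    truth = small_study.truths["A"]
    site = max(truth.editing_sites, key=lambda s: s.rate_for("A"))
    r = site.rate_for("A")
    p = small_study.plastomes["A"]
    ed = un = 0
    for ind in small_study.individuals_of("A"):
        sep = separate_strands(small_study.reads[ind])
        strand_reads = sep.plus if site.strand == "+" else sep.minus
        pu = build_pileup(strand_reads, p.sequence)
        e_code, u_code = (3, 1) if site.strand == "+" else (0, 2)
        ed += pu.counts[site.position, e_code]
        un += pu.counts[site.position, u_code]
    n = ed + un
    est = ed / n
    assert abs(est - r) < 3 * np.sqrt(r * (1 - r) / n) + 3 * small_study.config.error_rate


def test_antisense_absent_interval_has_no_coverage():
    cfg = SimulationConfig(seed=13, depth=40.0, antisense_expression=0.0,
                           n_haplotypes=1, mito_read_fraction=0.0)
    from plastkit.simulate import simulate_study
    from plastkit.quant import depth_of_coverage

    study = simulate_study(cfg)
    spec = study.truths["A"].antisense[0]
    sep = separate_strands(study.reads["A_F1"])
    reads = sep.plus if spec.strand == "+" else sep.minus
    depth = depth_of_coverage(reads)
    assert depth[spec.start:spec.end].max() == 0


def test_uncovered_editing_site_warns(small_study):
    from plastkit.simulate import EditingSpecSite

    base = small_study.plastomes["A"]
    truth = small_study.truths["A"]
    cfg = small_study.config
    # a candidate C far from any transcript
    reserve = truth.reserve
    pos = next(
        i for i in range(reserve[0] + 1150, reserve[1])
        if base.sequence[i] == "C"
    )
    import dataclasses

    t2 = dataclasses.replace(
        truth, editing_sites=[EditingSpecSite(pos, "+", "intergenic", {"A": 0.5})]
    )
    mito = small_study.mitos["A"]
    with pytest.warns(UserWarning, match="not covered"):
        simulate_reads(base, t2, mito, dataclasses.replace(cfg, depth=5.0),
                       seed=1, individuals=[("A_F1", "F")])
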