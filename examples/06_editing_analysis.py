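"""C-to-U editing: site discovery, rates, codon effects, haplotype
comparison and cross-taxon conservation states.
"""
from plastkit import editing, quant
from plastkit.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=1))

per_hap = {}
for h, p in study.plastomes.items():
    inserts = [(a, b) for a, b, _ in study.truths[h].mtpt_intervals]
    pileups = {}
    for ind in study.individuals_of(h):
        sep = quant.separate_strands(study.reads[ind])
        plus, _ = quant.filter_mtpt_reads(sep.plus, inserts, p.sequence, "+")
        minus, _ = quant.filter_mtpt_reads(sep.minus, inserts, p.sequence, "-")
        pileups[ind] = {"+": editing.build_pileup(plus, p.sequence),
                        "-": editing.build_pileup(minus, p.sequence)}
    res = editing.call_editing_sites(pileups, p.sequence,
                                     editing.ThresholdPolicy(), p)
    per_hap[h] = res
    print(f"haplotype {h}: {int(res.sites.reported.sum())} sites pass the "
          "thresholds (rate >= 5% or >= 10 edited bases, depth >= 200)")
    for r in res.sites[res.sites.reported].itertuples():
        eff = editing.annotate_effect(int(r.position), r.strand, p)
        print(f"  {r.position + 1}{r.strand}  rate {r.mean_rate:.2f}  "
              f"{eff.context}: {eff.label}")

# sexes within one haplotype: planted rates are sex-independent
sexes = {i: study.sex_of(i) for i in study.individuals_of("A")}
cmp_sex = editing.compare_editing(per_hap["A"].per_individual, sexes)
print("sites significant between F and H:",
      int(cmp_sex["significant"].sum()) if not cmp_sex.empty else 0)

# conservation against a toy ortholog panel: a taxon with genomic T, one
# with a known edit, one with no information
aln = {"focal": "ATGTCA", "species_t": "ATGTTA", "species_e": "ATGTCA",
       "species_q": "ATGTCA"}
states = editing.classify_conservation(aln, "focal", 4,
                                       edit_lists={"species_e": {4}})
print("conservation states:", states)
# "T": the edit is hard-coded in that genome; "Edit": edited there too;
# "C?": a C with no editing information.
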