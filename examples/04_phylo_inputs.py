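"""Prepare phylogenetic inputs: IRa removal, homopolymer masking, CDS
concatenation and simple indel coding.

The emitted FASTA/PHYLIP/partition/NEXUS files feed external tree software;
no tree inference happens here.
"""
from pathlib import Path

from plastkit import phyloprep
from plastkit.simulate import SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(seed=1), with_reads=False)
base = study.plastomes["A"]

trimmed, _ = phyloprep.remove_ira(study.msa, base.boundaries["IRa"], "A")
print(f"alignment columns: {len(study.msa['A'])} -> {len(trimmed['A'])} "
      "after cutting IRa (one repeat copy would otherwise count twice)")

masked = phyloprep.mask_homopolymers(trimmed, base.cds_features(), "A")
print(f"masked {len(masked.masked_columns)} homopolymer columns "
      "(runs > 5 nt outside coding sequence are uninformative)")

rows = masked.without_masked()
indels = phyloprep.simple_indel_coding(rows)
print(f"simple indel coding: {indels.n_characters} binary characters")
print({t: s for t, s in indels.states.items()})

sm = phyloprep.concatenate_cds(study.plastomes)
print(f"CDS supermatrix: {len(sm.rows)} taxa x {sm.length} columns, "
      f"{len(sm.partitions)} gene partitions")

out = Path("scratch/phylo_inputs")
out.mkdir(parents=True, exist_ok=True)
phyloprep.write_phylip(sm.rows, out / "cds.phy")
phyloprep.write_raxml_partitions(sm.partitions, out / "cds_partitions.txt")
phyloprep.write_nexus(rows, out / "whole_plastome.nex", indels)
print(f"wrote tree-software inputs to {out}/")
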