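# Methods

`plastkit` implements a comparative analysis of plastid (chloroplast)
genomes and their strand-specific transcriptomes, of the kind used to ask
whether cytoplasmic male sterility in a gynodioecious species leaves any
footprint in plastid gene expression or RNA editing. This note documents
the models and procedures, the parameters that matter, what the synthetic
data generator does and does not emulate, and the numerical choices made
where the design was open.

## Genome-level analyses

**Quadripartite structure.** A plastome typically comprises a long and a
short single-copy region (LSC, SSC) separated by two inverted repeats
(IRa, IRb) that are exact reverse complements. `find_inverted_repeats`
finds the longest pair of disjoint intervals whose sequences are exact
reverse complements, using rolling-hash window matching inside a binary
search over the repeat length (O(n log n) expected). Ties break to the
leftmost-start pair; the leftmost interval is labelled IRa. The shorter
single-copy stretch between/around the IRs is the SSC. Mismatch-tolerant
repeat detection is out of scope: assembled plastomes have identical IR
copies, and the synthetic generator plants them identically.

**Distances.** Substitution distances count alignment columns where both
rows carry unambiguous, differing bases (gap and N columns skipped), the
convention of SNP-distance tools. Indel distances come in two models:
`indel` counts columns gapped in exactly one row; `indelblock` counts
maximal runs of such columns, i.e. one event per contiguous gap. Both are
reported because published per-pair indel counts rarely state the model;
`indelblock <= indel` entrywise is asserted as an invariant.

**SSRs.** Microsatellites of unit length 1–6 are found with the
thresholds common in plastome surveys: mononucleotide runs longer than
five bases, at least four units for di- and trinucleotides, at least three
for tetra- to hexanucleotides. The scanner marks maximal periodic runs
(positions where `s[i] == s[i+u]`), reports full units only, skips units
that are themselves periodic (so `ATATAT` is a dinucleotide, never a
tetranucleotide), and breaks runs at N. A brute-force O(n²) tandem scanner
re-derived from the same thresholds serves as the test oracle.
Cross-genome SSR polymorphism groups homologous loci through alignment
columns and flags unit-count differences; mononucleotide loci are reported
but excluded from the recommended marker list, because within-individual
heteroplasmy makes their lengths unstable.

**Coding variation.** A site segregates when at least two distinct
unambiguous bases occur across the aligned genomes. It is non-synonymous
if swapping any observed allele into any genome's codon context changes
the encoded amino acid (NCBI translation table 11); alleles creating a
premature stop are flagged. Codons containing gaps or N in any genome are
excluded and tallied. Pairwise Ka/Ks uses Nei–Gojobori (1986) counting:
per-codon synonymous site fractions over the three possible changes at
each position (changes to stops count as non-synonymous), differences
averaged over all minimal mutational pathways with equal weights,
pathways through stop codons excluded, and a Jukes–Cantor correction
(undefined when p ≥ 3/4; the uncorrected proportions are always
reported). The test oracle enumerates pathways recursively and must agree
to 1e-9.

**Phylogenetic inputs.** Preparation follows common practice for
plastome phylogenies: one IR copy (IRa) is cut from the whole-genome
alignment (otherwise the repeat counts twice); mononucleotide runs longer
than five bases, measured on each row's ungapped sequence, are masked in
non-coding sequence only, taking the union of implicated columns across
rows (conservative — exactly the non-informative signal goes); protein
coding genes are concatenated once per IR duplicate, in alphabetical
order, with missing genes filled with `?`. Gap characters are coded by
the "simple" variant of Simmons & Ochoterena: one binary character per
distinct gap block (identical start and end columns), state 1 for the
block itself, `?` when a taxon's longer gap strictly contains the block,
0 otherwise. Writers emit FASTA, relaxed PHYLIP, RAxML-style partitions
and a NEXUS with a mixed DNA + restriction matrix; tree inference itself
is external.

## Transcriptome-level analyses

**Strand separation.** Fragments are assigned to the transcribed strand
from read-pair SAM flags. The default library convention is
`fr-firststrand` (dUTP: read 2 carries the transcript orientation);
`fr-secondstrand` inverts the rule. The real libraries' convention is not
derivable from the consumed alignments, so it is a configuration choice
with no fidelity claim. Improperly paired or flag-inconsistent records go
to an `unassigned` bin with reason codes; the partition is exhaustive.

**MTPT filtering.** Plastid DNA inserted into the mitochondrial genome
(MTPT) yields transcripts that masquerade as plastid reads. Given the
plastid-coordinate intervals homologous to such inserts, a read
overlapping an interval is discarded iff it carries at least one mismatch
to the plastid reference that is not a candidate editing observation
(C→T on the plus strand, G→A on the minus strand); reads outside the
intervals are untouched. The filter is deliberately aggressive inside the
intervals — a genuine plastid read with a sequencing error there is lost
— and blind to diverged copies whose only differences look like editing;
both properties are inherent to the published rule, and the generator's
recovery bounds (≥95% of marker-carrying mitochondrial reads discarded,
≤1% of genuine reads lost) are checked in the acceptance tests.

**Coverage and TPM.** Depth of coverage counts aligned bases per
reference position and strand (CIGAR-aware: M/=/X add depth, D/N consume
reference without depth). Per-feature mean depth over exonic length is
already length-normalised, so TPM is simply that rate rescaled to sum to
10⁶ across quantified features per sample. rRNA and tRNA are excluded
from quantification by default (library preparation biases their
coverage).

**Antisense transcripts.** Maximal intervals of strand-specific depth at
or above a floor, longer than 100 nt, on the strand opposite annotated
features, with same-strand feature positions excluded so sense
transcription is never called antisense. The floor defaults to the
minimum per-feature mean depth among the sample's protein-coding genes
("auto"), matching the published rationale for a fixed floor of a few
hundred reads; a manual numeric floor is supported. Presence/absence per
haplotype comes from overlap-merging calls across samples.

**Editing sites.** Every reference C on each transcribed strand is a
candidate (plus strand: C with T observations; minus strand: genomic G
with A observations — the same event on complemented counts). The
per-individual editing rate is T/(C+T) of bases passing a quality floor
(default Q20); bases below the floor count toward depth but not alleles.
A site is reported when at least one individual has depth ≥ 200 and
(rate ≥ 5% or ≥ 10 edited bases). Sites failing everywhere but edited in
every individual at a pooled rate ≥ 1% are kept in a below-threshold
annex; the 1% guard exists because at depths of several hundred reads,
"at least one edited base in every individual" is routinely met by
sequencing error alone. No variant-caller pre-screen is used: the
exhaustive pileup scan is strictly more sensitive and the thresholds are
applied identically downstream. Codon effects are annotated from the exon
map (labels like `TCA (S) => TTA (L)`, with start-creation for edited ACG
start codons and premature-stop creation flagged). Cross-taxon
conservation states per taxon are `T` (edit hard-coded in DNA), `Edit`
(genomic C, position in that taxon's known-edit list), `C` (known
unedited), `C?` (no information), `NA` (gapped/unalignable); intergenic
sites are `NA` throughout, as they cannot be aligned reliably across taxa.

**Group comparisons.** Expression: Welch's t-test on log2(TPM + 1) per
feature, Benjamini–Hochberg across features at FDR 0.05 — the
smallest-assumption choice for 3-vs-3 designs; the test is pluggable.
Editing: Fisher's exact test on the pooled edited/unedited counts of the
two groups, BH across sites, with per-individual mean ± SD reported. An
exact test is used because several genuine sites have low edited counts,
where the normal-approximation two-proportion z-test is anti-conservative
(the null simulations in the test suite exercise exactly this). Pooling
treats reads as independent; mate pairs double-count a site only when the
fragment is shorter than twice the read length, which is rare under the
default fragment model.

## The synthetic data generator

The generator emulates the study design the package targets: a
quadripartite plastome (default 30 kb — desk-scale rather than the ~151 kb
of real plastomes — with 4 kb IRs), 14 genes on alternating strands
(20% with one intron), five planted SSR loci, two haplotypes separated by
50 substitutions and 10 indel events (one of which inserts a repeat unit
into a planted SSR, creating length polymorphism), a mitochondrial genome
carrying two diverged plastid inserts (2% divergence; one intergenic, one
overlapping a gene tail), and stranded paired-end 2×100 nt reads at mean
depth 500 for three female and three hermaphrodite individuals per
haplotype. Planted editing sites cover the biological variety of
interest: high/intermediate/low rates, a silent edit, a premature-stop
edit at 10%, an edited ACG start codon at 15%, a haplotype-private site
(0% vs 6%), a below-rate-threshold 2% site, and one site on an antisense
transcript. All planted features are recorded in final coordinates, and
the same seed yields byte-identical output.

Deliberate modelling choices:

- **Background hygiene.** Random sequence is iteratively cleaned of
  spurious SSRs (and re-cleaned after gene and codon writes, without
  creating stop codons), so planted-SSR recovery can be tested as set
  equality rather than supersets.
- **Divergence markers avoid the editing signature.** Marker
  substitutions in mitochondrial insert copies never use C→T or G→A: a
  diverged base indistinguishable from editing is invisible to the filter
  by the rule's own definition, so planting one would make the recorded
  truth unrecoverable in principle. Real MTPT divergence includes such
  changes; the filter's corresponding blind spot is exercised separately
  by direct unit tests.
- **Transcripts carry 120 nt UTRs** beyond the annotated gene span, so
  coverage is flat across coding sequence including start codons — without
  this, an edited start codon could never reach the 200-read floor.
- **Short transcripts fragment shorter** (fragment mean shrinks to 0.75×
  span below the global 300 nt mean): sequencing 2×100 nt ends of
  near-full-length fragments would otherwise leave a mid-transcript
  coverage hole on short antisense RNAs.
- **Editing is applied per RNA fragment** (Bernoulli at the true rate),
  so mates agree, as they would for a single molecule.
- **Sequencing error** is a uniform 0.2% per-base substitution; no indel
  errors, soft clips or multimapping, because alignment consumption — not
  mapping — is in scope. Reads are emitted pre-aligned at true positions.
- **Gene expression** follows a fixed 0.5×–3× gradient (so an "auto"
  antisense floor is meaningful) with per-individual log-normal noise
  (sd 0.1 log2); sex effects default to none (the null design) and are
  configurable per gene.

What passing on synthetic data does **not** show: robustness to mapping
artefacts (multimapping in the IRs, soft-clipped splice junctions),
heteroplasmy beyond SSR length variation, rRNA/tRNA coverage bias, UTR
boundaries estimated from data, or real inter-species divergence in the
conservation panel. Real-accession numbers therefore cannot be reproduced
desk-scale; the package's claims on real data are limited to implementing
the published rules faithfully.

## Numerical and interface conventions

Coordinates are 0-based half-open in memory; every emitted table is
1-based inclusive and says so in a header comment (bedGraph and BED keep
their native 0-based convention). Ambiguity codes other than N are
rejected at load. TPM sums are exact to floating tolerance. Determinism:
all randomness flows from `numpy.random.default_rng` seeded from a single
integer; pipeline reruns with the same configuration produce
byte-identical outputs (checksummed in the run manifest).

## Problem sizes

The default study (two haplotypes × six individuals at depth 500 over a
30 kb plastome, ≈ 0.5 M read pairs total) runs the full pipeline in well
under a minute; the test suite's null-behaviour check repeats a reduced
single-haplotype study (depth 80) across 20 seeds. These sizes are the
package's chosen desk-scale defaults; all of them are configuration, not
constants.
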