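# Methods

`dinomfrs` reconstructs the expressed MHC class I allele repertoire of an
individual from paired-end RNA-Seq reads.  MHC class I loci are multigenic
(1–4 expressed genes per haplotype in ruminants) and extremely polymorphic,
and reference databases for most species are far from complete, so standard
read-to-reference genotyping misses divergent alleles.  The pipeline
combines a *permissive* alignment of reads to a curated allele database
with a *stringent* de novo reassembly of the read subsets that align
imperfectly, iterating as newly assembled alleles are added to the
database.

All sequences are the exon 2 – exon 3 region of the class I transcript
(nominally 549 bp), which encodes the α1/α2 domains forming the
antigen-binding groove and carries nearly all allelic variation.

## The discovery loop

For one individual, per round:

1. **Map** every read pair against every database allele with a
   seed-and-extend aligner (exact 19-mer seeds, banded affine-gap local
   extension, soft clips charged per clipped end).  Two scoring regimes
   are used: DISCOVERY (match +1, mismatch −4, band 100, clip 5) is
   permissive enough that reads from an unknown allele align to their
   closest known relative; VERIFY (match +2, mismatch −5, band 30,
   clip 2) is used once at the end so dissimilar fragments no longer
   co-map.  A pair is *proper* when both mates align to the same allele on
   opposite strands with an implied fragment length in [read length,
   1000] bp; otherwise the pair score is charged an unpaired penalty (17).
   Records are emitted for **every** allele tying the best pair score, so
   reads from conserved segments count toward every tied allele's pileup.
   When only one mate of a pair aligns to the winning allele, the other
   mate is *rescued*: placed full-length and gapless at the
   mismatch-minimizing diagonal and accepted on identity (≥ 65 % over
   ≥ 40 bp — random sequence peaks near 39 %).  Rescue is what keeps
   mates that fall inside highly divergent windows in the alignment,
   which the extraction step depends on.
2. **Call** per-allele pileups.  An allele is *present* when coverage is
   complete (depth ≥ 5 at every position) with no mismatched consensus
   column and no heterogeneous column.  A column is heterogeneous when
   the runner-up base has count ≥ 10 and frequency ≥ 0.05; the frequency
   floor sits ~30× above the sequencing-error expectation but below the
   ~9 % minority that a lowest-tier allele contributes when its reads
   stack on a highest-tier reference.
3. **Candidates.**  A pileup that is not a present known allele, stacks
   more than 500 reads over a contiguous covered span longer than
   400 bp, and shows at least one mismatched or heterogeneous column is
   a novel-allele candidate.
4. **Extract and reassemble.**  Proper-pair reads of all candidates of
   the round are pooled (orientation-normalized to their reference's
   forward strand), positionally subsampled (one pair per (start, mate,
   edit-distance class) bucket; up to three near the reference ends;
   mates whose alignment contains an indel are dropped as out of
   register), and reassembled by greedy overlap-layout-consensus under
   stringent gates: overlap ≥ 40 bp, identity ≥ 99 %, overlap score
   3·matches − 5·mismatches ≥ 120, contig support ≥ 20 reads.
   Mismatches are counted over mutually *confirmed* columns (≥ 2 reads
   and a ≥ 70 % majority); a single-read growth frontier is provisional,
   so one error base cannot permanently wall off a junction, while
   divergent alleles still refuse to merge anywhere their confirmed
   consensus differs.  Short (≤ 5 bp) provisional overhangs next to deep
   columns are trimmed from final contigs.
5. **Augment.**  Contigs whose best local alignment to some database
   allele covers ≥ 95 % of that allele's length are provisionally named
   (`LfL2001`, `LfL2002`, …; identical contigs share one name) and added
   to the working database.  The loop repeats (up to 5 rounds) until a
   round adds nothing.
6. **Verify.**  A final VERIFY mapping against the individual-complete
   database confirms each allele: complete mismatch-free coverage *and*
   both terminal 30 bp windows covered by reads belonging to proper
   pairs (orphaned reads do not count toward the ends, guarding against
   recombination artifacts).  Expression is binned from the read count
   at the marker column (full-CDS position 260): < 1000 low, 1000–5000
   middle, > 5000 high.  Only verified novel alleles propagate into the
   shared database returned for the next individual.

## Coordinates

The trimmed region is anchored at full-CDS position 74 (`cds_offset`
73), so the marker column 260 is local position 187 and the first
complete codon (local position 3) is residue 26 of the precursor.  The
frame is validated against the anchor that CDS 256–264 (the CAGATACAA
motif) encodes residues 86–88 (QIQ).  Both values follow from pure codon
arithmetic: `aa = ceil(nt / 3)`.

## Annotation

Confirmed alleles are characterized by: percent identity to the closest
database allele (global alignment, +1/−1/−1; identity = matches /
alignment columns); translation (stops as `*`, ambiguity as `X`);
classical vs putative non-classical grouping by single-linkage clustering
of the 31 antigen-contact residues (Hamming ≤ 3 links; clusters of ≥ 3
alleles with within-cluster contact diversity ≤ 3 are labeled putative
non-classical — low groove diversity is the hallmark of non-classical
genes); a gene-conversion screen (identical flanks ≥ 200 bp around a
core ≥ 50 bp diverging ≥ 10 %); and window diversity statistics (mean
and maximum pairwise substitution counts over a CDS window).  The
31-position contact set shipped with the package
(`data/contact_positions_synthetic.tsv`) is a synthetic stand-in
curation composed from canonical class I peptide-binding-groove residues
plus every group-diagnostic contact residue the annotation uses; pocket
labels are approximate.

Genomic placement of an RNA-derived allele splits it at the nominal
exon 2/exon 3 boundary (position 272 of the trimmed region) and aligns
each exon separately (infix alignment, both strands) against genomic
contigs; hit pairs on one strand, colinear, with an intron-sized gap
(50–5000 bp) are reported with 1-based forward-strand coordinates, and
reverse-orientation hits print start > end per exon.

## The synthetic-data generator

The generator is the package's study-condition authority; its defaults
*are* the conditions the tests run under.

* **Alleles.**  A random 549 bp ancestral sequence is diversified by
  seeded substitutions (hypervariable windows at local 150–280 and
  380–480 get double weight).  Known alleles mutate from the ancestor at
  half a pairwise rate drawn from 5–15 %; novel alleles derive from a
  randomly chosen known parent at a sampled pairwise rate.  One novel
  allele carries the 9 bp CAGATACAA marker motif at CDS 256–264 and is
  checked to differ there in ≥ 4/9 positions from every other allele.
* **Divergence guarantees.**  Every allele pair differs at ≥ 4 positions
  in every 100 bp window and shares no identical run > 60 bp, mirroring
  the observed polymorphism density of real class I allele sets (mean
  18.5 differences per 120 bp window); this is what makes single reads
  allele-informative and lets stringent overlap assembly separate
  mixtures without chimeras.  Every novel allele is *locally coherent*
  with its parent — each 100 bp window is ≥ 2 differences closer to the
  parent than to any other allele — encoding the biological premise that
  novel alleles are point-mutation derivatives of one allelic lineage;
  recent inter-lineage recombinants (gene-conversion products) violate
  this and are a known limitation of reference-anchored discovery.
* **Reads.**  2×100 bp (or 125/150) pairs; fragment length normal(300,
  50) truncated to [read length, min(600, region length)]; fragments may
  overhang the trimmed region (the transcript continues on both sides)
  with mates truncated at the region boundary, which yields the uniform
  terminal coverage real RNA-Seq shows; per-base substitution errors at
  0.3 % and single-base indels at a tenth of that; constant Q35
  qualities.  Per allele, fragments are drawn until the number of reads
  covering the marker column reaches the allele's tier target
  (low 650, middle 2600, high 6200 — each ≥ 20 % away from the
  1000/5000 bin boundaries).  The first three carried alleles span the
  three tiers; extras alternate low/middle (individuals typically
  express one allele highly).  A truth table records every pair's source
  allele, fragment coordinates, marker coverage and error counts.
* **Not modeled:** positional coverage bias, PCR duplicates,
  splice-junction reads, base-quality variation.  Passing tests
  therefore demonstrate the method's behavior under idealized error and
  sampling models, not robustness to library artifacts.

## Problem sizes and numerical choices

The end-to-end recovery check runs 20 seeded simulations of 4–6 alleles
(1–3 novel), each ~20–60 k read pairs, through the full loop; smaller
fixtures drive the per-module tests.  The aligner skips its dynamic
program when the best gapless diagonal score provably dominates any
gapped alternative (gap open 6, extend 1 means a d-diagonal deviation
costs ≥ 6 + d), and shrinks the explored band accordingly — these are
exact bounds, not heuristics, and the aligner is tested for score
equality against an independent unbanded dynamic program.  Assembly
ties break by higher overlap score, then longer overlap, then smallest
member read id; consensus ties resolve toward the reference base (in
pileups) or the alphabetically first base (in contigs).  All randomness
flows from one integer seed through numpy's PCG64 generator; identical
seeds give byte-identical FASTQ/FASTA outputs.

## Known limitations

* Co-expressed alleles sharing identical runs longer than a read cannot
  be separated by overlap assembly; the generator's divergence floor
  reflects typical class I pairs, not recent recombinants.
* The candidate rule (> 500 reads over > 400 bp) can miss a weakly
  expressed novel allele whose reads scatter across several references
  in sub-threshold pieces; local parental coherence makes this rare in
  simulation but real patchwork alleles could still be missed.
* Expression bins count reads at one marker column and inherit its
  allele-specificity; alleles identical around the marker would share
  counts.
* The spliced-alignment, quality-aware, and duplicate-marking features
  of production mappers are out of scope.
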