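# Methods

`fgdpipe` implements an ORFeome-centred comparative-genomics pipeline for
bacterial genomes: all-vs-all protein similarity condensed into a
functional genome distribution (FGD) distance matrix with UPGMA
clustering, E-value-threshold mining of core/shared/specific gene sets,
detection of strain-specific chromosomal regions from whole-genome
nucleotide comparison, and deposited-annotation genome statistics. A
pangenome simulator with full ground-truth bookkeeping makes every stage
testable without any external data.

## Alignment engine

Protein comparisons use Smith–Waterman local alignment with affine gaps
(BLAST convention: a gap of length *L* costs `gap_open + L*gap_extend`),
BLOSUM62 with open 11 / extend 1 by default. Traceback tie-breaks are
fixed (diagonal > up > left, smallest-coordinate maximum cell) so
alignments are byte-reproducible. Raw scores *S* are normalised with the
Karlin–Altschul formulae

    S' = (λS − ln K) / ln 2          E = m·n·2^(−S')

using the published gapped parameters λ = 0.267, K = 0.041 for
BLOSUM62 11/1. The search space `m·n` uses raw sequence lengths (query
length × summed subject ORFeome length); the finite-size length
adjustment applied by NCBI BLAST is deliberately omitted, so absolute
E-values run somewhat conservative (larger), but all operations in this
package consume E-values through user-chosen cutoffs, whose semantics
are preserved. Composition-based statistics and SEG masking are not
implemented. For match/mismatch (nucleotide) schemes an exact ungapped λ
solver (`karlin_lambda`) is provided; the default +1/−2 scheme carries
λ = 1.28, K = 0.46.

The all-vs-all search is seeded: exact k-mers (default word length 4)
shared between query and subject nominate candidate diagonals, which are
clustered and extended with a banded Smith–Waterman (half-width 40).
Because banding only removes paths, the reported score is always a lower
bound on the exact score, and equals it whenever the optimal alignment
stays inside the band of a seed — verified in the test suite against
both a brute-force DP oracle and Biopython's independent C aligner.

## FGD distance

Each ORF's affinity to a target genome is its best bit score into that
genome divided by its self-alignment bit score, clamped to [0, 1]; hits
with E-value above the affinity ceiling (default 1e−5) are discarded.
The genome–genome distance in distance units (du) is

    d(A,B) = 1 − (mean_a affinity(a→B) + mean_b affinity(b→A)) / 2 .

This self-normalised bidirectional best-hit ratio is this package's own
operationalisation of "level and quality of amino-acid similarity": it
is symmetric, bounded, 0 for identical ORFeomes and 1 for ORFeomes with
no qualifying cross-hits. The exact formula used by the original FGD
software is unpublished, so the affinity function is a pluggable
strategy (`build_matrix(affinity=...)`) and results should be read as an
interpretation, not a re-implementation. Pipeline ORFeomes include
pseudogenes with deposited translations by default (annotation-style ORF
counting treats pseudogenes as ORFs, and one hit table then serves both
FGD and gene-set mining); set `include_pseudo_in_orfeome: false` to
exclude them.

Clustering is classical UPGMA: merge the closest pair, new height =
distance/2, cluster distances updated by member-count-weighted
arithmetic means (equivalent to the unweighted mean over leaf pairs,
verified against an exhaustive merge-order oracle and SciPy average
linkage). Ties merge the lexicographically smallest pair of leaf-label
sets; Newick output rounds branch lengths to six decimals. Because
distances enter UPGMA only through their ordering, topology recovery
requires FGD distance to be a monotone transform of an ultrametric — a
property the simulator's clock-like trees satisfy and the tests exploit.

## Gene-set mining

Presence of a reference ORF in genome *G* means best hit E-value ≤
`e_present`; absence means no hit at `e_absent`. All judgments are
one-directional from the reference ORF (a reciprocal-best-hit refinement
exists but is off by default) and a single qualifying hit suffices —
paralogous families are not collapsed. Core genes require presence in
every genome of the set; group-specific genes require presence across
the in-group and absence from every out-group genome; strain-specific is
the one-genome in-group case. Shared fraction is the percentage of
reference ORFs with a hit in at least one genome of the other group.
Default cutoffs follow common practice for these analyses: core 1e−60,
shared 1e−10, specific 1e−10 (all configurable; the bundled demo config
uses core 1e−20 because its synthetic genes are shorter and its
divergences deeper than a real genus-wide panel).

## Strain-specific regions

Nucleotide comparison is megablast-like: exact 16-mer anchors (anchors
occurring > 50 times in the reference are skipped as repeats), ungapped
X-drop extension (X = 100) on both strands, greedy removal of blocks ≥
90 % contained in a higher-scoring kept block. Blocks must reach E ≤
1e−3 under the Karlin–Altschul statistics for the two-replicon search
space; without this filter, bare 16-bp chance matches (E ≈ 1 at
genome scale) shred the coverage complement. Specific regions are the
literal complement of the block union, kept when strictly longer than
`min_region_len` (default 50 bp); no merging across covered gaps is
performed (a merge option exists but is off by default). Regions absent
from multiple queries are intersected per base. ORFs map into a region
when the overlap covers ≥ `min_overlap_frac` (default 0.5) of the ORF;
regions whose gap is ≤ `locus_gap_bp` (default 5 000) share a locus.
Headline ORF-per-region and locus counts are sensitive to both knobs. A
locus (or, with `level="region"`, each region) is flagged as
transposase-flanked when a feature whose product matches the
configurable lexicon ("transposase", case-insensitive, pseudogenes
included) lies within `window_bp` (default 1 000) of a boundary.

Boundary precision is limited by local divergence: the reported block
end is the running-score maximum of the ungapped extension, which can
fall tens of bases short of the true homology boundary once pairwise
nucleotide divergence exceeds ~15–20 %. Region comparison is therefore
meaningful between closely related strains (a few per cent divergence),
which is also how the bundled simulation plants its islands.

## Pangenome simulator

The generator defines the study conditions for all end-to-end tests.
Gene families are born on a user-supplied tree (branch lengths =
expected substitutions/site): core families at the root, clade-specific
families at their clade's ancestor, strain-specific families at single
leaves. Ancestral proteins are i.i.d. draws from BLOSUM62 background
frequencies (first residue M); along each branch every site substitutes
with probability `1 − exp(−t)` and the replacement is drawn from the
BLOSUM62-implied conditional distribution `P(b|a) ∝ p_b·2^(S_ab/2)` over
the 19 other residues. This site-wise Poisson model controls expected
identity — the only quantity the pipeline senses — but has no rate
matrix, no rate heterogeneity, and no within-gene indels. Codons follow
their amino acid: a substituted site receives a fresh uniform synonymous
codon, an untouched site keeps its ancestral codon, so nucleotide
identity tracks protein identity (uniform codon usage; GC content is not
controlled). Intergenic spacers are ancestral random DNA evolved with
the same per-site model. Genomes are collinear: one shuffled backbone
order shared by all genomes, genes absent from a genome simply omitted.

Islands are contiguous blocks of novel single-genome genes (optionally
bracketed by transposase-annotated genes) inserted at junctions whose
backbone neighbour is a core gene and at least two slots apart, so both
island boundaries abut universally shared sequence and flank flags stay
attributable to their own island. Pseudogenisation rewrites one codon in
the second half of a gene to TAA and truncates the deposited
translation, leaving coordinates and most of the sequence intact — hits
into pseudogenes therefore remain strong, as in real decayed genes.
Conserved rRNA operon and tRNA loci (identical across genomes) exercise
the statistics stage. Everything is driven by one `numpy` generator, so
output is byte-identical for a fixed seed.

The bundled demonstration config uses an ultrametric 5-genome tree
`(((A:0.02,B:0.02):0.04,C:0.06):0.09,(D:0.12,E:0.12):0.03)` — a tight
strain pair diverging from a third strain inside one clade, with a
two-genome outgroup — 40 core families, 6 + 5 clade-specific, 14
strain-specific genes, four islands (three transposase-flanked), 5 %
pseudogenes, 3 rRNA operons and 8 tRNAs, ~60 genes per genome (mean gene
length 200 codons). These sizes keep a full pipeline run within seconds
while leaving every recovery statistic well-determined. What passing
tests show is recovery of planted structure under this idealised model;
they do not exercise real-data complications such as rearrangement,
horizontal transfer of shared families, codon bias, indels within genes,
or annotation error.

## Genome statistics

GC% is computed over unambiguous bases. ORF count is CDS plus pseudogene
features. Coding density is the **sum** of ORF lengths over replicon
length — overlapping ORFs count twice — matching the usual genome-table
arithmetic (mean gene length × ORF count / genome length); a union-based
density would differ. rRNA features with inter-feature gaps ≤
`rrna_gap_bp` (default 2 000, the scale of 16S–23S–5S spacing) cluster
into one operon. Coordinates are 1-based inclusive externally
(GenBank/GFF3) and 0-based half-open in interval arithmetic; the
converters in `genome_io` are the only translation points. Features
wrapping a circular origin are stored as `start > end`, split into two
intervals for interval math, and counted once as ORFs.

## Degenerate inputs and numerical choices

Empty sequences alignments return zero-score hits with empty spans; a
genome with no features yields zero counts, not errors; a single-genome
core query returns the whole ORFeome (vacuous universal quantifier).
E-values underflow to 0.0 beyond ~2 650 raw score units, which only
strengthens cutoff decisions. Distance matrices are validated
(symmetry, zero diagonal, [0, 1] range) on construction. All tie-breaks
(hit ordering, UPGMA merges, feature ordering) are lexicographic so
reruns are byte-identical; the pipeline manifest records SHA-256
checksums of every artifact.

## Known limitations

- The FGD affinity formula is this package's definition (see above);
  absolute du values are not comparable to other FGD implementations.
- E-values lack BLAST's length adjustment and composition-based
  statistics; compare cutoffs within this package only.
- The nucleotide comparator is ungapped; long indel-free homologous
  stretches are assumed between strains, and boundary precision
  degrades with divergence.
- The simulator omits recombination, gene conversion, shared mobile
  elements, rate heterogeneity and realistic codon usage.
- Reciprocal-best-hit filtering, orthology clustering and synteny-aware
  analyses are intentionally out of scope.
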