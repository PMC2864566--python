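# Methods

This note records the models, conventions and design choices behind
`unipseudo`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic benchmarks do
and do not demonstrate.

## The comparative model of gene loss

A unitary pseudogene is only observable relative to a reference
species that retains the functional ortholog. The package therefore
frames discovery as a screen over reference proteins with no assigned
query ortholog (an InParanoid-style pairwise table is the input
contract). Absence of orthology has two explanations with opposite
polarity — a gain on the reference lineage or a loss on the query
lineage — and the genome separates them: a gained gene has no homologous
query locus at all, while a lost gene leaves an alignable locus bearing
coding-sequence disruptions. Processed (retrotransposed) copies and
members of tandem gene families mimic losses and are removed on
structural and family evidence rather than by sequence identity alone.

## Protein-to-genome mapping

The mapper is a deliberately small translated search with the same
contract as BLAT's translated mode: exact amino-acid 5-mer seeds
against all six reading frames, chained per strand by dynamic
programming under an intron-sized gap bound (50 kb). The chain score is
covered protein residues minus 0.01 per nt of genomic span in excess of
the protein's own length. The span penalty matters: tandem paralogs sit
a few hundred bp apart, and without it a chimeric chain across two
paralogous loci can tie a compact single-locus chain. Coverage ≥ 0.5
of the protein gates "alignable"; chaining tolerates the genome lagging
the protein by up to 60 nt so that planted deletions do not break
colinearity. These thresholds are exposed as parameters.

## Exon-guided frameshift-aware alignment

Because the reference gene model is always in hand, alignment is
per-exon rather than a free gene-prediction HMM. Each reference exon's
protein segment is aligned glocally (protein fully accounted for,
genomic ends free) against the candidate window near its expected
position, with BLOSUM62 codon-to-residue scores, affine gaps
(open 11, extend 1) that consume whole codons or whole residues, and
frameshift transitions consuming 1–2 extra nt at penalty 20. An exon
whose in-slice alignment is weak (< 0.8 of its self-score) is retried
against the whole window — this is what lets an intronless processed
copy align contiguously instead of being forced into the reference
exon layout. An exon with no positive-score alignment anywhere is
missing (feeding truncation calls). The aligner requires codon-aligned
(phase-0) exon boundaries, which the generator guarantees; phase-1/2
introns are a known limitation.

Disruption calls and their coordinate conventions:

- premature stop: an in-frame stop strictly before the final codon,
  reported at the leftmost base of the stop codon. Stops within the
  last 10 codons are tolerated (stop-codon drift near the terminus),
  a configurable threshold.
- frameshift: any exon block whose net indel length is not a multiple
  of 3; reported at the insertion-point coordinate of the slip
  junction. Frameshift placement is only defined up to alignment
  equivalence, so the generator plants indels only at junctions where
  the optimal alignment is unique (see below).
- splice site: an inferred intron (gap ≥ 20 nt between consecutive
  exon blocks) whose donor is not GT or acceptor not AG, reported at
  the leftmost base of the dinucleotide. GC donors are reported with a
  minor-site flag rather than silently accepted.
- truncation: missing leading/trailing exons.

Structure similarity is 0.5 · protein coverage + 0.5 · fraction of
reference introns recovered (inferred intron length within ±10 bp of
the reference length), pass at ≥ 0.6. A full-coverage intronless copy
of a spliced gene scores exactly 0.5 and fails, which is how processed
pseudogenes are excluded without a dedicated stage. Scores within 0.05
of the threshold are flagged as needing review, standing in for the
manual-annotation step of a curated workflow.

## The locus cascade

Candidates with disruptions are clustered into loci by single-linkage
overlap (same chromosome and strand, ≥ 1 bp). A locus inherits the
best evidence class among its contributing reference genes
(named gene > spliced cDNA > unspliced cDNA > predicted); loci
supported only by unspliced or merely predicted annotation are dropped,
since an intronless "gene" is more plausibly itself a processed copy
and predictions cannot anchor a loss claim. Tandem-family loci
(family of ≥ 2 members with ≥ 2 members within 10 kb in the reference)
are reported separately: ortholog/paralog relationships inside tandem
clusters are unreliable, so their "unitary" status is not defensible.
Synteny requires, on each side, that at least one of the k = 3 nearest
reference flanking genes has its query ortholog on the same chromosome
and the same side of the locus; a contig edge passes vacuously. Loci
whose transcripts carry the functional state at every disruption they
span are classified polymorphic — the genomic sequence and the mRNA
were effectively sampled from different alleles.

## Dating

Ancestral sequences come from per-site Fitch parsimony with
deterministic tie-breaking (prefer the parent's state, then the
alphabetical minimum), which attains the parsimony count. Branch-wise
K_A and K_S use Nei–Gojobori (1986): fractional synonymous site counts
per codon (mutations to stops counted as nonsynonymous — the NG86/MEGA
convention, byte-compatible with Biopython's implementation, which the
test suite uses as an independent cross-check), equal-weight pathway
averaging for multi-hit codons, and the Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p). Codon columns containing a stop or gap in
either sequence are excluded; proportions ≥ 3/4 are flagged saturated.

Dollo parsimony places a disruption on the stem of the minimal clade
containing every species that carries it: a disruptive mutation arises
once and is never cleanly reverted. An "absent" species inside that
clade makes the pattern homoplasic and is flagged, not silently
resolved. Missing data are uninformative.

The nonfunctionalization time assumes K_A accumulates at ω̄·r_S before
inactivation and at r_S after, giving
K_A1 = r_S1·[ω̄·(T − T_N) + T_N] and hence
T_N = T·(ω₁ − ω̄)/(1 − ω̄), clamped to [0, T] with a flag when
clamping occurred and a caution flag when fewer than four species
inform the background. ω̄ defaults to the unweighted mean of defined
branch ω over non-focal branches; an external constrained ratio
(e.g. a genome-wide median such as 0.12 for human–mouse) can be
supplied instead. Estimates from a single gene are noisy — at 5,000
codons and primate-scale divergence the per-replicate spread is about
±1 MY — and the recovery benchmark therefore evaluates the mean over
50 replicates.

## Population genetics

The HWE test is a chi-square goodness of fit of the three genotype
classes to p̂², 2p̂q̂, q̂². The default degrees of freedom are 2 (three
classes minus one); the conventional df = 1 (one further degree for
the estimated allele frequency) is available as `standard1`, and it is
the calibrated choice — the type-I-error benchmark uses it. F_ST is
Nei's G_ST-style (H_T − H_S)/H_T with unweighted population means;
subdivisions are summarized by the unweighted mean of member
frequencies. Populations are clustered by UPGMA on the pairwise F_ST
matrix and the dendrogram is cut at the largest gap between successive
merge heights. The permutation test shuffles population labels across
the two subdivisions (sizes preserved), p = (1 + #{F ≥ obs})/(1 + n);
when fewer than 20 distinct assignments exist they are enumerated
exactly. Note the resolution limit: with two groups of sizes (a, b)
the smallest achievable p is of order 1/C(a+b, a), so small panels
cannot produce small p-values no matter how strong the signal.

## Enrichment

Annotations are closed under is_a ancestors (true-path rule) before
testing. Each term carried by at least one study gene is tested with
the hypergeometric upper tail — identical to one-sided Fisher on the
2×2 table — and Benjamini–Hochberg adjustment runs across the tested
terms. Propagation means a planted leaf-term enrichment also surfaces
its ancestors, which is correct behavior, not leakage.

## The synthetic data and what it shows

The genome generator writes multi-exon genes (2–5 exons of 45–150 nt
in whole codons, introns 60–200 nt with canonical GT..AG, 300 nt
intergenic spacers, ~30% minus-strand) so that any non-GT..AG junction
or ORF break in the query is a planted event. Background divergence is
substitution-only and ORF-preserving (stop-creating and
splice-dinucleotide substitutions are skipped), so intact orthologs
stay intact at any rate and the planted disruptions are the only
signal. Tandem families are near-copies at ~94% nt identity, in the
range of real tandem receptor families. Fates are planted by count or
by explicit assignment; deletions/gains replace the locus with random
sequence; processed copies insert a stop-bearing intronless CDS copy
near the chromosome end.

Frameshift planting enforces detectability by construction: a cut must
have junction-distinct flanking bases, strictly dominate codon-shifted
and exon-boundary-slide alternative alignments under the actual scoring
scheme, and finally pass a direct run of the exon DP confirming the
slip lands at the recorded junction. This is the generator guaranteeing
its stated contract — planted truth equals detectable truth — because
indel positions are only well-defined up to alignment equivalence.

The codon-phylogeny simulator evolves codons with Poisson substitution
attempts (default 0.0011 per site per MY, primate-like), accepting
synonymous changes and accepting nonsynonymous ones with probability ω;
mutations to stops are rejected to keep sequences analyzable. Because
NG86 counts stop-adjacent opportunities as nonsynonymous sites, pure
rejection would bias measured neutral ω to ~0.95; synonymous acceptance
is therefore damped per codon by (reachable nonsynonymous)/(all
nonsynonymous) neighbors, which makes the realized K_A/K_S equal ω in
expectation. Genotypes are multinomial draws under
(p² + Fpq, 2pq(1 − F), q² + Fpq); annotation sets plant one leaf term
at an exact fold over background.

What passing these benchmarks shows: the machinery is internally
correct — planted events are recovered exactly, estimators hit their
algebraic identities and recover planted parameters within quantified
error, and test statistics are calibrated under their nulls. What it
does not show: robustness to the messiness of real genomes — assembly
gaps and errors, phase-1/2 introns, alternative splicing, segmental
duplications, alignment ambiguity at high divergence, annotation noise
— nor the manual curation that a production survey of a real genome
would still require.

## Numerical and determinism notes

Every generator is a pure function of (seed, parameters); sub-streams
derive from a single integer seed via numpy's seeding of
`default_rng([seed, stream])`. All ordering is made deterministic
(lexicographic tie-breaks in screens, label order in clustering,
alphabetical tie-breaks in Fitch), so repeated runs are byte-identical.
Scores and penalties are integers in floating point; traceback
preference order (plain codon, then slips; match, then protein gap,
then genome gap) fixes the reported coordinates among equal-scoring
paths.
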