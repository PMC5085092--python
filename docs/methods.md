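# Methods

`prgtyper` infers diploid HLA-style genotypes at G group resolution by
building a population reference graph (PRG) of known allele sequences,
mapping paired-end short reads directly to the graph, and evaluating a
likelihood over all pairs of candidate alleles. This note documents
the model, the numerical choices, and what the synthetic experiments
do and do not demonstrate.

## The graph model

A PRG here is a leveled directed acyclic graph. Levels correspond to
columns of a merged multiple sequence alignment; each level carries one
edge per distinct character observed in that column, so alleles that
agree at a column share the edge and the graph is *fully collapsed*:
there is one node per level boundary, and any per-level choice of edge
labels is a valid source-to-sink path. This models potential
recombination between known alleles; the cost is that the graph also
contains recombinant paths no input allele follows, which is acceptable
because genotyping is performed against the catalogued allele
genotypes, not against free graph paths.

Two label conventions matter throughout:

* `-` is a **graph-encoded gap**: a known deletion allele. It is
  traversed free of charge and consumes no read base. It is *not* an
  alignment error.
* `N` is a literal wildcard base (used for the inter-gene spacers). It
  matches any read base at match score during extension, but no walk
  containing `N` is entered into the k-mer index (exact seeding over
  {A,C,G,T} could never hit it).

### Merging tiered alignments

Allele databases are tiered: many alleles are known only over the
exons, fewer over the full gene, and fewer still as regional haplotypes
with flanking non-genic padding. Each tier is a rectangular gapped
alignment. The merge locates each inner (higher-resolution) block
inside the outer alignment through the alleles shared between tiers:
for each shared allele, the first and last non-gap columns of its inner
row enter the sets P_L and P_R, and the consensus region is
[G_L, G_R] = [max P_L, min P_R]. The inner alignment restricted to the
consensus columns becomes a segment of the gene; the outer sequence of
every allele left and right of the consensus region is re-aligned into
flank segments. With several exon blocks the rule is applied block by
block, left to right; embedding the merged gene into the regional tier
applies the same rule once more, treating the gene alignment
(restricted to the alleles that span every segment) as the inner block.

Outer-only alleles have no inner row, so their boundary is derived from
the shared alleles' boundaries in outer-alignment columns (max of the
left boundaries, min of the right, mirroring the consensus rule), and
their middle substring is threaded through the consensus block by
global alignment against the block's column consensus. A substring
that would need an insertion relative to the block is a construction
error; multiple substring occurrences are resolved leftmost and logged.

Characters of inner-only alleles that fall outside the consensus region
are necessarily dropped from the graph; the merge records them and
warns. The synthetic generator avoids the situation (shared alleles
are kept gap-free at block edges), so the reconstruction invariant —
every input record is reproduced exactly by its path fragments — holds
everywhere in the shipped experiments.

Flank re-alignment uses a built-in progressive aligner (pairwise global
alignment, match +1 / mismatch −1 / gap −2, guide order = input order)
so that no external aligner binary is required; any callable satisfying
the same contract can be substituted.

### Allele paths and G groups

An allele known only over the exons has no representation in intron or
padding segments, so allele paths are stored as contiguous *fragments*
(one per exon block for exon-only alleles, a single fragment for
genomic and regional alleles). The peptide-binding site (PBS) is the
set of levels annotated as exon 2 and 3 for a class I locus and exon 2
for class II. Alleles with identical PBS genotype strings (including
gap characters) form one G group, named after the lexicographically
smallest member with a `G` suffix; all genotyping is at this
resolution.

## Read filtering

Graph alignment is the expensive step, so read pairs are pre-screened
with two k-mer criteria (k = 31 by default, matching the coverage
quality metric):

* **positive selection** — the fraction of the pair's pooled k-mers
  (both mates, strand-canonicalized membership) present in the graph
  index must strictly exceed 0.30;
* **negative selection** — at least one mate must carry a k-mer that is
  in the graph but not in the background set (k-mers of reference
  sequence outside the PRG, closed under reverse complement), or at
  least one mate's background k-mer fraction must be strictly below
  0.45.

Discarded pairs carry a reason code (`too_short`,
`positive_selection`, `negative_selection`) for auditability. An
optional per-base Phred floor can mask low-quality k-mers; it is off by
default. The k-mer index enumerates *every* gap-skipping k-character
walk; in variant-dense PBS windows this is combinatorial, and a guard
aborts with a diagnostic if a single window exceeds 2×10⁶ walks
(clustered variation at the default study conditions can legitimately
reach the 10⁵–10⁶ range).

## Read-to-graph alignment

Alignment is seed-and-extend. Seeds are maximal exact matches found by
looking up every read k-mer in the index and chaining hits whose read
offsets and graph walks are both successive; both strands are searched
and matches shorter than the index k are dropped. Each seed is
extended leftward and rightward by banded affine-gap dynamic
programming over the leveled graph, with three states per (level
boundary, read position): match/mismatch, read insertion, read
deletion. Graph gap edges propagate all states at zero cost. Scores
are base-quality aware: match log(1−ε), mismatch log(ε/3) with ε the
Phred error probability floored at 10⁻⁴.

Scoring constants (natural log units, all configurable): gap open
ln 0.01 ≈ −4.605, gap extend ln 0.1 ≈ −2.303, per-base soft-clip
penalty ln 0.25 ≈ −1.386, improper-pair penalty −13.8, score-drop
termination 25. These magnitudes are comparable to mainstream short-
read mappers; correctness is established against an exhaustive oracle
rather than by matching any particular tool. The band is a window of
`band_pad` (48) levels beyond the read span; the score-drop rule
terminates extension early (clipping the remainder) only when clipping
is enabled.

Candidate alignments of the two mates are combined by Cartesian
product. A proper pair (opposite strands, forward/reverse orientation)
adds the log density of a normal insert-size model, measured in graph
levels between the outermost aligned levels; any other configuration
receives the flat improper-pair penalty. Pair log likelihoods are
softmax-normalized into a posterior; the maximum-likelihood pair is
selected (ties broken by lowest level, then lexicographic walk) and
treated as fixed downstream. The mapping quality is the selected
pair's posterior; the per-position quality of a base is the posterior
mass of candidate pairs that place that base at the same level.
A pair whose either mate yields no seeded candidate is recorded
unmapped and excluded from genotyping.

### Validation against an exhaustive oracle

`prgtyper.bruteforce` enumerates all source-to-sink path sequences of a
small graph and scores the read against each with a plain
sequence-to-sequence fitting alignment under identical scoring. On
random graphs with a bounded path count, the unbanded, unclipped graph
DP must reproduce the best path-by-path score exactly (within 1e−9);
this is asserted over hundreds of random instances in the test suite
and recomputed by the acceptance script. The oracle shares no code
with the production DP.

## Genotype likelihood

Let R be the read pairs whose fixed ML alignment overlaps the PBS of a
locus. For a read r and candidate allele a:

    L(r | a)       = ∏ over overlapping PBS columns of score(g_r, g_a)
    L(r | (a1,a2)) = ½ L(r | a1) + ½ L(r | a2)
    L(R | (a1,a2)) = ∏_r L(r | (a1,a2))

where g_r is the read residue (base + quality, or a read gap) and g_a
the allele's genotype at that column; score is match/mismatch as above,
a flat gap-open penalty for read-base-vs-allele-gap and
read-gap-vs-allele-base, zero for gap-vs-gap, and match for an `N`
allele base. All products are computed in log space. The likelihood
over all unordered allele pairs (including homozygous) is normalized to
a posterior (log-sum-exp).

Calling is two-step: allele 1 maximizes the marginal probability of
occurring at least once (a homozygous pair contributes once), reported
as Q1; allele 2 maximizes the absolute pair posterior among pairs
containing allele 1, reported as Q2. Ties break lexicographically.
Note Q1 ≥ Q2 is not implied by these definitions.

Two auxiliary metrics accompany each call:

* **allele k-mer coverage** — the fraction of the called G group
  representative's 31-mers (per path fragment, strand-canonicalized)
  observed among the kept reads' 31-mers;
* **unaccounted columns** — the number of PBS pileup columns (minimum
  depth 5, from the fixed ML alignments) where some residue reaches
  within-column frequency ≥ 0.2 yet matches neither called allele.
  Residual high-frequency evidence signals a call that fails to explain
  the data.

## The synthetic data generator

The generator emulates the structure of a curated HLA-like database
rather than any particular organism's sequence content. Per locus it
plants variants against an explicit column coordinate system, so the
tiered MSAs are exact by construction (true homology; no aligner in the
loop) and every read's origin is recorded.

Default study conditions: 3 loci (classes I, II, I) × 10 alleles, of
which 4 have genomic and 2 regional-haplotype records (tier identifiers
nest, guaranteeing shared alleles); exons of 90/210/210 bp with 120 bp
introns, 60 bp UTRs and 500 bp padding; per-allele substitution rate
0.02 in PBS exons (pairwise PBS divergence ≈ 4%, comfortably above the
2% floor the recovery experiments assume) and 0.005 elsewhere; small
indels (≤ 4 bp) planted away from block edges — 0.5 per genomic-tier
allele in the non-coding gene body, plus one coding-exon indel event
per locus (coding indels are rare in curated allele alignments, and a
fully-enumerated k-mer index makes stacked coding indels exponentially
costly); locus ancestors diverged at rate 0.15 from a common root. Reads: 2×100 bp,
normal fragment length 350 ± 50, per-base error 0.002 with quality
strings encoding exactly that rate, 30× total diploid coverage
(fragments per haplotype = cov/2 · L / (2·read length)). Every output
is byte-reproducible from the integer seed. Distinct PBS genotypes are
enforced (each allele founds its own G group) unless PBS divergence is
zero or a planted paralogous exon freezes the whole PBS.

What the generator does **not** model: real IMGT allele-frequency
spectra, gene conversion mosaics, long structural variation, sequencing
quality-score miscalibration, GC-dependent coverage bias, or DRB3/DRB4
copy-number variation. Passing the recovery experiments therefore
demonstrates the correctness of the machinery under honest noise, not
field performance on real whole-genome data.

## Experiment scales and numerical tolerances

The shipped experiments use desk-scale problem sizes chosen so the
whole suite runs in minutes on one CPU: parameter recovery uses 20
simulated diploid samples per coverage (30× and 20×) over 3 loci × 10 G
groups (~840 read pairs per sample); aligner-oracle validation uses 200
random graphs with ≤ 2⁷ paths and reads of 30–120 bp; reconstruction is
checked on the toy fixture plus 100 random databases. Posterior
normalization is exact to 1e−9 (log-sum-exp); homozygous collapse and
pair symmetry hold to machine precision by construction and are
asserted exactly. DP traceback matches cell values with a 1e−6
tolerance because the vectorized forward recurrences and the
incremental candidate expressions may differ by float re-association;
equal-scoring branches are interchangeable and reported scores always
come from the forward pass.

## Known limitations

* Exon-only alleles contribute no intron information; reads bridging an
  exon/intron boundary are scored against the intron alleles present in
  the graph, which can slightly favour genomic-tier alleles of the same
  G group (harmless at G group resolution).
* The filter's "modified criteria" for read sets with many low-quality
  positions are represented only by the configurable thresholds and the
  optional per-base quality floor.
* Genotyping assigns each read by its fixed ML alignment; there is no
  cross-locus reassignment or joint haplotype reconstruction.
* Novel alleles are not detected: evidence from an allele absent from
  the database surfaces only indirectly, in the unaccounted-columns
  metric.
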