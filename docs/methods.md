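# Methods

This note documents the models and numerical choices behind `bcrpipe`: what
each stage computes, which parameters matter, what the simulator does and
does not emulate, and where the design was genuinely open.

## Preprocessing model

Reads carry a 5′ or 3′ amplicon primer followed by a UMI of 8 or 12 nt.
Primer identification scans offsets 0–4 at the read start and accepts ≤2
mismatches; two distinct primers tying at the best mismatch count drop the
read (logged), since the UMI length would be ambiguous.  Mixed-length UMIs
are standardized by truncation to their 8-nt prefix; the 5′ and 3′ prefixes
concatenate into a 16-nt signature identifying one cDNA molecule.

The mean-quality filter keeps reads with arithmetic mean Phred ≥ 20
(inclusive boundary).  We read the rule as *keep* good reads — the
keep-if-≥20 convention of standard amplicon preprocessors — because
discarding reads above the threshold would invert the filter's purpose.

UMI consensus is a per-position majority vote weighted by summed Phred
scores; an exact tie yields `N`.  Positions covered by fewer than half the
members are trimmed from the 3′ end.  Members deviating from the group's
length mode by more than 10 nt are split off and dropped.  A group whose
members still disagree with the consensus at >10% of positions is treated
as a UMI collision and split by complete linkage at 10% identity distance;
this path requires a consensus of ≥30 nt so that the per-position tie rule,
not the collision heuristic, governs short degenerate cases.  Collisions
are vanishingly rare at the simulator's UMI lengths (4^16 signatures) but
the path is exercised by tests.

Paired-end assembly reverse-complements the 3′ consensus and takes the
maximal-scoring ungapped suffix/prefix overlap (score = matches −
mismatches) of length ≥10 with mismatch rate ≤0.2; overlap disagreements
resolve toward the base with the larger quality sum.  A 20-nt exact seed is
tried first purely as a fast path; when it fails the full overlap scan runs.

Isotype and subtype are called by the best ungapped constant-stub match
within 2 mismatches at the 3′ end; a tie between subtypes of one isotype
keeps the isotype with subtype "ambiguous", a tie across isotypes leaves
the sequence unassigned (excluded downstream, counted).

Collapse merges exact-duplicate nucleotide sequences of identical
isotype/subtype, summing distinct UMI signatures (`umi_count`) and tracking
the maximum reads-per-UMI.  The default retention rule is
`max_reads_per_umi ≥ 2`, which removes sequences supported only by single
reads (the main vehicle for sequencing-error artifacts).  The
`min_reads_per_umi=1` view ("all unique reads") is retained for the
constant-threshold comparisons and mAb matching, which deliberately cast a
wider net.

Read-pair accounting is conserved across every stage
(`pairs_in = retained + Σ dropped`) and asserted on every run.

## Annotation model

V genes are assigned by semi-global pairwise alignment (match +1, mismatch
−1, linear gap −4, terminal gaps free) of each germline V against the
query; J genes likewise against the query segment downstream of the V; ties
break lexicographically by gene name.  D calls are best-effort — longest
exact substring (≥5 nt) of the inter-V–J segment — and are never used for
clonal partitioning.  A k-mer prescreen limits which V genes are aligned;
it is a pure performance device (all genes are aligned when inconclusive)
and tests compare scores against an exhaustive dynamic-programming oracle.
Queries with best V identity <0.6 are unannotatable and excluded with a
logged count.

Region bounds (FWR1–FWR4, CDR1–2) are germline intervals projected through
the alignment trace.  The junction runs from the conserved V-end cysteine
codon through the J tryptophan codon, both carried as per-gene anchors in
the reference sidecar; CDRH3 is the junction minus its boundary codons.
When terminal mismatches push an anchor just outside the aligned span, its
position is extrapolated from the nearest aligned column (at most 12 nt
away) — valid because that neighbourhood is ungapped; anchors further from
any aligned column are unresolved and the sequence is excluded from
junction-dependent analyses.

SHM is `100 × mismatched / aligned columns` over the V segment, excluding
the junction (everything from the Cys codon onward) and excluding indel
columns from numerator and denominator.  The J segment is not included in
the denominator; the choice is applied identically to real and simulated
data, and keeps SHM exactly recoverable from the simulator's planted
mutation positions.  SHM is always measured against the provided germline
reference; novel-allele inference is out of scope.

Kabat numbering is not implemented as a general numbering engine: the
reference sidecar carries a fixed per-gene position map with the two
positions the persistence analysis needs (codon 12 on the V, the residue-136
boundary on the J).

## Clonal inference

Sequences partition by (V gene, J gene, junction length); allele suffixes
are collapsed to gene level first, because allele-level partitioning
fragments clones under SHM.  Within a partition the distance is normalized
Hamming distance on the junction; unequal lengths never meet, so the
distance is always defined.

The per-sample threshold is the density minimum between the two highest
local maxima of a Gaussian KDE over the distance-to-nearest multiset.  The
KDE uses Silverman bandwidth over *unique* values weighted by their counts,
so the estimate depends only on the empirical distribution (duplicating
every observation changes nothing).  Unimodal densities, or fewer than 50
finite distances, fall back to the constant 0.12.  Clustering is
single-linkage: an edge joins sequences at distance ≤ threshold and clones
are connected components (union-find, oracle-tested).  Clone ids hash the
sorted member ids and are stable across runs and row orders.

The cross-sample constant threshold is the median of per-sample optimized
thresholds (mean of the middle two for even counts) rounded half-up to an
integer percent; the bundled published per-replicate values yield 12%.  In
constant-threshold mode (mAb matching) the distance region switches from
the junction to the CDRH3, matching the convention that the 12% mismatch
allowance is stated on the CDRH3; both modes share the same machinery and
the region is a parameter.

## Longitudinal analyses

Persistence: sequences are trimmed to the Kabat-12..136 core and matched by
exact nucleotide identity across *all* queried samples.  Matching is
isotype-agnostic, but isotypes are recorded and a consensus reported;
"mutated" means mean SHM strictly >1%.  The UMI signatures supporting a
persistent core must be pairwise disjoint across samples; a shared
signature flags the core as contamination-suspect and excludes it from
headline counts.

mAb matching annotates each mAb heavy chain through the same aligner,
appends it to the all-unique-reads repertoire, clusters at the constant
threshold, and reports per mAb whether it co-clustered with ≥1 repertoire
sequence, with how many, and in which clone.

Lineages are minimum spanning trees over {germline ∪ unique member
sequences} under Hamming distance on the aligned V(D)J region, rooted at
the germline, with Kruskal edges sorted deterministically.  This is an
oracle-checkable approximation of maximum-parsimony lineage programs: it
preserves germline rooting, branching structure and mutational-step edge
labels.  Multi-step edges keep their count; intermediate haplotypes are
realized only when an actual member sequence lies between two nodes (the
MST then routes through it automatically) — no unobserved intermediate
sequences are fabricated.  Identical member sequences merge into one node
with the isotype set union and summed UMI read counts.  The germline
rearrangement is rebuilt from the clone's V/J calls over the aligned span,
keeping observed junction-interior nucleotides where no germline template
exists (N regions and D edges), which slightly *underestimates* root-edge
lengths and is the standard compromise absent a D-aware germline.

The immunodominance grid is a 2-D histogram of clones over log10 read
abundance × linear mean SHM, with matched mAb clones overlaid as labeled
points; cell counts sum to the clone count.

## Statistics

Sequence-level condition aggregates are unweighted means of per-sample
values rounded to one decimal (this convention reproduces the published
0.7 / 2.2 / 6.0 percent aggregates from the bundled per-replicate rows);
count-weighted means exist behind a flag but are not the default.
Clone-level SHM averages each clone's mean member SHM.  The RDI subsamples
both repertoires to a common depth without replacement, log2(1+x)-transforms
per-gene counts and takes the Euclidean distance, averaged over iterations;
the subsampling stream of each repertoire is derived from its own contents,
so the score is symmetric in its arguments by construction.  SHM
distribution comparisons use Welch's t with Holm–Šidák adjustment.

## Simulator: what it emulates, and what it does not

Defaults encode the two compartments the pipeline is meant to contrast:

| parameter | naïve (PBMC-like) | memory (stimulated-like) |
|---|---|---|
| isotype profile | 92% IgM | 70% IgG1, 84% IgG total |
| SHM per site | 0.0075 | 0.055 |
| clone sizes (power law) | α=3.5, max 5 | α=2.0, max 50 |
| transcripts per cell (mean) | 1.5 | 3 |
| reads per transcript (mean) | 3 | 9 |

The naïve profile keeps IgM above 90% with 0.5–1% SHM and near-singleton
clones; the memory profile puts IgG1 at the head of a class-switched,
4–7%-SHM, expansion-skewed repertoire, with a ≥3× transcript/read output
per cell reflecting activation-driven transcriptional up-regulation.
Junctional diversity uses uniform 0–5 nt trims and uniform 0–10 nt
N-insertions per join — enough junction-length spread for realistic
partitioning; no biological trimming model is claimed.  SHM is
substitution-only and uniform over the V(D)J, making the SHM oracle exact;
clones are star-shaped (every member mutates independently from the naïve
ancestor).  Lineage-structure tests therefore use separately scripted
stepwise fixtures, not simulator clones, for chain topology.  Qualities are
two-valued (Q37, error positions Q20) so the mean-quality filter behaves
predictably.  Timepoint plans copy planted persistent cells — generated as
singleton clones so each contributes one distinct core — identically into
every sample, while UMIs are always drawn fresh per sample from a shared
exclusion set.

Consequences for interpretation: passing tests demonstrate correctness of
the pipeline's algorithms against planted truth, not robustness to
features the generator lacks — indels (in reads or SHM), PCR chimeras and
jackpot amplification, biased gene usage, within-clone phylogenetic
structure, light chains, or non-uniform quality profiles.

## Problem sizes and determinism

The benchmark experiments run at fixed sizes chosen to give stable
statistics: 2,000 cells for the noise-free round trip, 500 planted clones
(≈1,400 cells) for clone recovery, 3×400 cells with 50 planted persistent
sequences, 600 cells for mAb spiking, and 2×2,500 cells for the
compartment-enrichment comparison.  Enrichment measurements are compared
against the *planted* expectation computed from the truth table (which
cells carry ≥2 reads per UMI), removing per-seed sampling wobble from the
comparison while leaving the pipeline's measurement untouched.  Every
source of randomness derives from a single integer seed; reruns are
byte-identical, including FASTQ and rearrangement tables.

## Known limitations

- The aligner is a simplified two-segment (V then J) semi-global aligner;
  it does not model transcript leaders, truncated reads starting inside V,
  or inverted orientations.
- D-gene calls are exact-substring heuristics, reported but never load-bearing.
- The constant-threshold and optimized-threshold modes share one distance
  implementation; whether published per-sample thresholds were computed on
  the junction or the CDRH3 is not documented, so the region is explicit
  and configurable.
- RDI depth/iterations have no published values; defaults (depth 100,
  100 iterations) are declared, and RDI scores are not compared against
  published values.
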