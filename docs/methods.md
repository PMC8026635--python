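# Methods

This note documents the models and procedures implemented in `plasphage`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not
establish.

## Problem setting

A temperate phage can lysogenize its host either by integrating into the
chromosome or by being maintained as a low-copy plasmid (a *plasmid
prophage*). In public sequence databases such molecules are routinely
deposited as ordinary plasmids. The pipeline screens a collection of
plasmid sequences for phage signatures, clusters the selected genomes by
shared protein content, and classifies each one as a putative active
plasmid prophage, a degenerated (remnant) prophage, a putative virulent
phage, or a non-phage plasmid.

## Pairwise alignment and homology statistics

All pairwise alignment is exact affine-gap dynamic programming
(Needleman–Wunsch / Smith–Waterman via Biopython's `PairwiseAligner`),
not a seeded heuristic: at desk scale exact DP is affordable and removes a
heuristic dependency. Protein scoring uses BLOSUM62 with gap open −11 and
extend −1; nucleotide scoring uses +1/−2 with gaps −5/−2. `gap_open` is
the score of the first gap column (a length-g gap scores
`open + (g−1)·extend`). Raw scores map to bit scores via the gapped
Karlin–Altschul parameters λ = 0.267, K = 0.041 (BLOSUM62 −11/−1), and
E = m·n·2^(−bits). Identity is counted over all alignment columns
including gaps; coverage is the aligned span over the full sequence
length, per sequence. When several alignments are co-optimal, the first
alignment reported by the aligner is used — a fixed, deterministic choice;
scores and therefore all thresholded decisions are unaffected.

Full-genome global alignment at 15–500 kbp does not fit a dense DP matrix,
so genome-scale comparisons use a banded affine-gap DP (numpy) with band
width `2·|Δlength| + 32`. The banded score is exact whenever the optimal
path stays inside the band, which holds for the near-identical,
substitution-dominated pairs that the 99%-identity deduplication must
discriminate; the band assumption is checked against the dense DP in the
test suite on sequences with indels.

## Greedy identity/coverage clustering

Deduplication (99% identity / 99% coverage, global) and marker-family
clustering (20% identity / 80% coverage, local) share one greedy
incremental algorithm: sequences are visited longest-first (ties by
identifier) and join the first cluster whose *representative* they match
at the thresholds, with coverage enforced on both sequences; otherwise
they found a new cluster. The representative is therefore always the
longest member. Protein families cluster in local mode and genome dedup in
global mode — the choice is not dictated by anything upstream and is the
natural pairing of marker domains (local) versus whole-replicon identity
(global).

Two prefilters accelerate the quadratic scan without changing results:
an exact length-ratio bound (global identity can never exceed
shorter/longer), and k-mer screens (k = 8 nucleotide / k = 4 protein;
k = 16 integer-encoded containment for genome-scale sequences). A pair at
identity ≥ t must contain an exact-match run of ≈ t/(1−t) columns, so a
shared k-mer is guaranteed only when t ≥ k/(k+1); below that threshold the
k-mer screens disengage automatically and the scan is exhaustive.

## Marker profiles

For each marker family the reference set is clustered (20%/80%), clusters
with ≥ 10 members are aligned and the largest becomes the profile's
training alignment. The MSA is center-star: the center maximises the
summed pairwise local score, all members are globally aligned to it, and
the pairwise alignments merge under once-a-gap-always-a-gap. For
same-length family members diverged by substitutions this reproduces the
column-exact alignment; externally produced MSAs (aligned FASTA or
Stockholm) are accepted as an alternative input.

Profiles are Krogh-style: match states = columns with > 50% residues;
emissions and transitions are Laplace(+1)-smoothed counts; insert states
emit the background (uniform 1/20) distribution; transition groups are
M→{M,I,D}, I→{M,I}, D→{M,D} (the rare I↔D events in an MSA are routed
through the modelled states). Search is a local log-odds Viterbi in bits:
free entry into and exit from any match state, flanking residues score
zero against the background, delete chains carry their transition costs.
`match_state_coverage` is the span of match states visited (including
deletions) over M — this is what the terminase-truncation rule reads.

Joint (full-path) Viterbi and Forward recursions are implemented
separately and validated against exhaustive state-path enumeration to
1e-9 in log space; the search DP is validated against its own path
enumerator. The production search kernel is numba-compiled.

**Acceptance rule.** Default is a bit-score threshold of 25 bits — far
above anything unrelated sequences reach against these profiles (hundreds
of bits separate true family members from background) and low enough to
retain 70%-length truncated markers. Optionally a Gumbel null is fitted by
method of moments to ≥ 100 (default 500) background-shuffled decoys with
lengths resampled from the training lengths; then
E(s) = database_size · P_Gumbel(S ≥ s) with database size = number of
proteins searched in the run, and the default cutoff is E ≤ 1e-2 (the
survey practice used per-species cutoffs in the 1e-1…1e-3 range; a single
configurable cutoff replaces that).

## Genome screen

Genomes of 15–500 kbp (bounds inclusive — the published range gives no
bracket semantics) pass the size filter. Every protein is searched against
every profile; a genome is selected iff it has qualifying hits for **all**
required markers, by default terminase *and* major capsid protein. The
marker table records the best hit per genome per marker for all profiles.
When both annotation (GFF3 / protein FASTA) and the nucleotide genome are
available, annotated CDSs take precedence; a six-frame ORF scan
(ATG-initiated, ≥ 50 aa, optional GTG/TTG starts of translation table 11)
is the fallback. Rotating a circular genome so the terminase gene leads is
provided as a reporting-time convenience, not a screening step.

## Orthology and grouping

All inter-genome protein pairs are aligned locally; hits require
E ≤ 1e-5 and query coverage ≥ 0.75 (directional — a gene fragment covers
its query but a full-length gene does not cover a fragment, which is what
keeps split/truncated copies out of the main clusters). BBH: p and q are a
pair iff each is the other's best-scoring hit in the partner genome (ties:
higher coverage, then smaller identifier). COGtriangles: a triangle is
three pairwise-BBH proteins from three distinct genomes; triangles merge
iff they share a BBH **edge** (merging on shared vertices over-merges and
is rejected); proteins in no triangle become singleton clusters, which
still occupy pangenome columns because they are genome-specific markers in
the network. In-paralog pre-collapsing is omitted; the generator avoids
intra-genome paralogs by default (a flag plants them to document
behaviour).

Grouping replaces the survey's semi-manual judgment with an explicit
testable rule: similarity = shared clusters / min(cluster counts), edges
at ≥ 0.5, groups = connected components ordered by size then smallest
member. Min-normalisation (not Jaccard) keeps gene-poor degenerated
prophages grouped with their intact relatives. Genomic-characteristic
tie-breaking (length, tRNAs, synteny) is out of scope. The 0.5 default
cleanly separates the regimes that matter here: co-group genomes share
essentially their whole repertoire (sim ≈ 0.9–1.0) while genomes related
only through the universal marker families sit near 6/16 ≈ 0.38.

## Classifier

Feature extraction reads the marker hits plus gene layout:

| parameter | default | rationale |
|---|---|---|
| `tmp_min_aa` | 900 aa | between observed split TMP fragments (≤ ~790 aa) and intact TMPs (1200–2200 aa) |
| `terminase_min_profile_cov` | 0.80 | a truncated terminase covers ≲ 0.70 of match states; intact copies ≳ 0.95 |
| `adapter_max_aa` / window | 150 aa / 2 genes | the partitioning adapter is a small DNA-binding protein immediately downstream of the motor, same strand |
| `serine_small_max_aa` / `serine_large_min_aa` | 250 / 400 aa | ~200-aa serine recombinases act as resolvases/invertases; ≥ 400 aa ones as integrases |
| `tmp_window_genes` | 3 | split-TMP fragments are adjacent or near-adjacent CDSs |

The cascade (first match wins): **R1** missing terminase or MCP →
non-phage plasmid; **R2** signature present but no partitioning motor and
no recombinase of either family → putative virulent phage (a phage with no
plasmid-maintenance machinery has no way to persist as a plasmid);
**R3** truncated terminase or split TMP → putative degenerated plasmid
prophage; **R4** otherwise → putative active plasmid prophage. Morphotype:
myovirus-like iff a tail sheath is found, else siphovirus-like iff a TMP
is present, else undetermined. A split gene is *always* called degenerated
— stop codons that might stem from sequencing error are not
second-guessed. R2 keys on motor-or-recombinase absence only (not on the
adapter), mirroring how virulent-phage candidates are argued from the
absence of partitioning genes and recombinases. Whether a prophage could
also integrate is not inferred.

## Synthetic worlds

The generator's defaults are the stated benchmark, not a tuning knob:
40 genomes (12 active / 6 degenerated / 2 virulent-like / 20 non-phage),
3 groups of 5 (each group mixing active and degenerated members, as real
groups do), family divergence 0.2 (≈ 64% pairwise identity — comfortably
detectable yet far from trivial), genome lengths 15–120 kbp, intergenic
spacers ~120 bp, 12 members per marker family, 3 duplicate pairs (one
exact, two at 99.5% identity) and 2 decoy pairs at 98% identity that must
*not* deduplicate. Marker ancestors are drawn i.i.d. from a uniform
residue background; members substitute each position at the divergence
rate with a uniformly random different residue, so expected pairwise
identity has the closed form (1−d)² + d²/19 used in the tests. Genes are
reverse-translated with uniform synonymous-codon choice (all downstream
analysis is protein-level), motors/recombinases cycle per group and
singleton, adapters sit immediately downstream of their motor on the same
strand, and the last group also carries a tail sheath so both morphotypes
occur. Degenerated genomes alternate between a TMP split by a planted
in-frame stop near the midpoint and a terminase truncated to 70%.
Near-duplicate and decoy mutations avoid start/stop codons and never
create in-frame stops, so every emitted CDS still translates to its
protein record exactly.

What the generator does **not** emulate: realistic phage gene order and
operon structure, codon usage, indel/recombination evolution, intra-genome
paralogs (unless asked), contamination, or annotation errors. A green
end-to-end test therefore establishes that the machinery is correct and
the thresholds are mutually consistent on a clean, stated world — not that
the defaults are optimal for real survey data.

## Numerical and determinism notes

- All randomness flows from one seed through `numpy.random.SeedSequence`
  children; reruns with an identical config are byte-identical (verified
  by hashing the whole output tree).
- Probability sums are validated to 1e-9; DP oracle comparisons use 1e-9
  absolute tolerance in log space.
- Deterministic tie-breaks everywhere: lexicographic identifiers for
  cluster founding and BBH ties, smallest-member ordering for cluster and
  group ids.
- Degenerate inputs: empty sequences, missing required profiles, CDSs
  outside their genome, and sub-minimum decoy counts raise `ValueError`
  with the offending field named; an all-negative local alignment returns
  the empty alignment with raw score 0.

## Known limitations

- The banded global aligner is exact only within its band; for genuinely
  indel-rich genome pairs near the identity threshold the dense DP (or a
  wider band) must be requested explicitly.
- Circular rotation is recorded but not exploited: two rotations of the
  same plasmid do not deduplicate (rotation-invariant alignment is out of
  scope).
- E-value calibration extrapolates a moment-fitted Gumbel into its tail;
  calibrated cutoffs below ~1e-4 per sequence should not be over-read.
- The grouping threshold was chosen on the synthetic world's geometry; on
  real data it is a starting point, not a validated constant.
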