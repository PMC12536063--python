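# Methods

## Problem setting

A B-cell clone is identified by its rearranged IGH VDJ sequence: one
germline V, D and J segment joined with non-templated N nucleotides on
either side of a (usually truncated) D insert, plus somatic hypermutation
(SHM) accumulated in the V region after antigen exposure. With 150 bp
reads no single read spans a full rearrangement, so the library design
uses three nested forward primers in the V framework regions (FR1, FR2,
FR3) — optionally a leader primer for cDNA — against a common reverse
anchor at the 3′ end. The pipeline reconstructs each rearrangement by
integrating the overlapping amplicons around a germline scaffold rather
than assembling de novo: the clonal dominance typical of CLL makes a
consensus-per-V–J-pairing strategy both simpler and self-correcting for
sequencing/PCR errors.

## Pipeline model and assumptions

**Assignment.** Reads are aligned locally (match +1, mismatch −2, gap
open −4, extend −1) against every V and J allele in both orientations;
hits below a score floor of 40 are discarded. The floor is set so a
150 bp read at ≤5 % divergence always passes while random sequence
essentially never does. Ties between alleles resolve by higher percent
identity, then lexicographic allele name, making results deterministic.
One physical molecule has one orientation, so both segment hits of a read
are taken from the better-scoring orientation; a score ≥ 100 cannot arise
from the wrong orientation of a 150 bp read and short-circuits the
second-strand scan.

**Linkage.** A V–J pairing requires at least `min_link_reads = 3` read
units (a unit is a mate pair, or a single junction-spanning read)
carrying both hits; the threshold suppresses singleton chimeras while
keeping a 2 % clone detectable at a depth of ~1000 read pairs. Units with
only a V (or only a J) hit are attached to the unambiguous pairing of
their allele — ambiguity (equal linking support) drops the unit rather
than guessing. Fragment-of-origin labels come from the forward mate only:
the reverse read starts wherever the molecule ends and would otherwise
absorb a spurious label from whatever FR offset it happens to overlap.

**Consensus.** Reads of a pairing are expressed in the coordinates of the
concatenated V–[N×gap]–J reference (`gap_len = 30` N characters standing
in for the junction/D region; the exact width is immaterial because the
junction is assembled from reads). Each reference column takes the
majority base among covering reads, requiring depth ≥ 2; columns below
that depth, or ties involving the reference base, keep the reference
(other ties resolve alphabetically). Junction length varies between
clones, so per-column voting cannot represent it: reads whose V alignment
reaches the V 3′ end and whose J alignment starts at the J 5′ end (2 nt
slack for alignment clipping) each nominate a full junction string, and
the most frequent string wins (ties: longer, then lexicographic). Depth
inside the junction is the number of nominating reads.

**Identity and mutational status.** SHM load is the percent identity of
the consensus V portion to its germline allele over a pairwise local
alignment — identity = 100·matches/aligned columns, junction and J
excluded, mirroring how V-region identity is conventionally reported.
Status is a pure threshold function: UM at ≥ 98.0 %, borderline in
[97.0, 98.0), MM below 97.0. The borderline band is reported both as its
own label and as an MM-with-note free-text field, since downstream
consumers differ in which representation they expect. Both thresholds are
config keys (`um_threshold`, `borderline_floor`). An identity below 60 %
flags the rearrangement as an artifact candidate instead of erroring.

**CDR3 and D.** The CDR3 runs from the conserved second cysteine of the V
(Cys104) to the J-region tryptophan (Trp118), inclusive. Cys104 is
located on the germline allele (last in-frame TGT/TGC within the final
36 nt) and mapped through the V alignment onto the consensus; if the
mapping fails, the fallback is the lastmost Cys codon encoded in the
final 36 nt of the consensus V. The reading frame follows from the anchor
position; the translated consensus is scanned downstream for the first
W-G-x-G, whose W is Trp118. No motif-satisfying frame, or a stop codon in
the anchored frame, reports the junction as unproductive — an outcome,
not an error. Full IMGT gapped numbering is deliberately not implemented;
the alignment-anchor approximation is exact whenever the 3′ end of V is
covered, which the FR3 amplicon guarantees by design. D inference aligns
the junction insert against all D alleles and reports the best hit with a
contiguous match run ≥ 8 nt at ≥ 80 % identity; both values are invented
operating points (exposed in config) chosen so random N-nucleotide runs
essentially never qualify while a D core truncated by up to 5 nt per side
usually does.

**Artifact filtering.** Nonspecific V mapping can split one rearrangement
across sibling V alleles or genes. Merging is done in descending
read-count order (largest absorbs): first between alleles of the same V
gene, then across V genes, whenever the two consensuses share ≥ 95 %
identity. Identity here is computed with an end-gap-free *global*
(overlap) alignment, counting internal gaps and mismatches — a local
alignment would score two genuinely distinct clones that share a germline
V allele as 100 % identical over the V segment. For the same reason both
passes require an identical J allele: the artifact mechanism is
mis-mapping of the V, not a different recombination. A second stage
absorbs rearrangements supported by a single fragment class or with an
FR3 read share ≥ 92 % into the largest rearrangement with equal V family
and CDR3; the 92 % share is interpreted per-rearrangement (that
rearrangement's FR3 reads over its total reads), the most consistent
reading of the rule, and is configurable. Lacking a matching major, the
rearrangement is kept and flagged `low-support`. Read counts are
conserved exactly through the filter, and re-running it is a no-op.

**Clonality.** Clones below 0.1 % of IGH-assigned reads are removed;
percentages are sorted descending and consecutive ratios
pct_i/pct_{i+1} computed. MAX_DIFF is the maximum ratio; ties take the
earliest (most abundant) position, the conservative choice for N. A
sample with a single surviving rearrangement has no consecutive pair;
its MAX_DIFF is defined as the infinite sentinel and the sample is
1CLONE (near-100 % clones require this case). The classifier is a KNN
(k = 3, Euclidean) on standardized per-sample features. The feature
vector — log₁₀ MAX_DIFF (capped at 10⁴ so the sentinel stays finite) and
the top-clone percentage — is a design choice where the design was open;
it is configurable and logged. Training uses a stratified random split
with a small training fraction (0.25, mirroring a
train-on-few/test-on-many validation protocol) plus stratified 10-fold
cross-validated F1-micro/F1-macro. MAX_DIFF values between the validated
polyclonal maximum (3.77) and clonal minimum (8.19) are flagged
`near_threshold` in reports, since no rule arbitrates that interval.

**Group statistics.** Pairwise MAX_DIFF comparisons use a two-sided
Mann-Whitney U test: exact permutation enumeration (valid under ties) for
pooled sizes ≤ 20, the normal approximation with tie correction above,
with Bonferroni correction over the number of pairwise comparisons.
Confusion and concordance arithmetic (sensitivity = 100·TP/(TP+FN),
specificity = 100·TN/(TN+FP)) is done in exact rational arithmetic and
rounded only for the report.

## The synthetic-data generator

The simulator provides every input the pipeline needs, so all testing
runs offline and from a single seed.

- **Germline**: a synthetic stand-in for a real germline export —
  realistic IMGT-style allele names over random coding sequences. Every
  V allele (294 nt) ends with TGT-GCG-AGA, fixing the Cys104 codon; every
  J allele is a 9–15 nt prefix plus a W-G-Q-G-encoding core, fixing
  Trp118. Sequences being random, inter-allele identities are far below
  real germline similarities (see limitations).
- **Rearrangements**: V/D/J drawn uniformly, D truncated 0–5 nt per end,
  N1/N2 of 0–10 nt, SHM as independent per-base substitutions. The last
  9 nt of V (the Cys anchor codon region) are spared from SHM so the
  ground-truth CDR3 stays well defined; with default rates this removes
  ~3 % of mutable positions. Productive junctions are enforced by frame
  padding and resampling junctions that create stops or a premature
  W-G-x-G inside the CDR3.
- **Profiles**: polyclonal profiles are near-flat with a planted maximum
  consecutive ratio uniform on [1.5, 3.7] (the validated polyclonal range
  being 1.50–3.77); single-clone profiles have a dominant/next ratio
  log-uniform on [8.3, 900] (validated clonal minimum 8.19); two-clone
  profiles have a mutual ratio uniform on [1.05, 3.5] and a second/third
  ratio log-uniform on [8.3, 400]. The top background clone is floored at
  0.25 % of the total so the dominant gap is measured against a clone
  that survives the 0.1 % filter.
- **Reads**: each amplicon's fragment runs from its V-offset (defaults
  leader 0, FR1 ≈ 0.25·|V|, FR2 ≈ 0.5·|V|, FR3 ≈ 0.75·|V|) to the 3′
  end; R1 reads the 5′ end, R2 the reverse complement of the 3′ end,
  150 bp each, split in equal thirds across amplicons (the real multiplex
  proportions are unknown; equal is the declared assumption).
  Substitution errors are i.i.d.; qualities are constant with an optional
  Phred-2 tail to exercise trimming. Primer sequences themselves are not
  modelled — they are irrelevant to the algorithmics under test.

What passing tests therefore show: correct reconstruction, annotation and
classification under substitution noise, realistic abundance structure,
and partial-amplicon coverage. What they do not show: robustness to
primer-binding bias and chimeric PCR products, to indel sequencing
errors (an optional concern; the default error model is
substitution-only, the dominant Illumina class), to highly similar
germline alleles (real IGHV siblings differ by a few bases, synthetic
ones by ~75 %; the ≥ 95 %-identity merge rule is exercised with
constructed near-identical consensuses instead), or to RNA expression
bias.

## Problem sizes and runtime choices

Simulated samples in the test suite use 120–600 read pairs and 1–5
clones; SHM-recovery runs use the leader-inclusive design so the whole V
region is covered (with FR-only designs, mutations 5′ of the FR1 primer
are invisible — reproducing the known blind spot of FR1-anchored assays —
and measured identity is correspondingly higher than the simulated rate).
The classifier experiment uses 90 profiles (60 clonal, 30 polyclonal),
which is fully separable in feature space and reaches held-out accuracy
1.0. The exact Mann-Whitney enumeration is restricted to pooled n ≤ 20
(≤ 184 756 splits).

## Known limitations

- Clones are keyed by V–J allele pair: two co-existing clones with the
  same V and J alleles but different junctions collapse into one
  consensus. The simulator assigns distinct pairs per clone accordingly.
- Subclonal SHM heterogeneity is not phased; quantifying SHM in
  subclones would need higher coverage and UMIs.
- No correction for amplification bias; clonal percentages are read
  shares, not cell fractions.
- IMGT unique numbering is approximated by alignment anchoring (exact
  for 3′-covered V regions, undefined for consensuses missing Cys104).
- Samples failing the read-support QC (major clone ≤ 1000 reads for the
  clonal track; < 1000 trimmed reads for the polyclonal track) are
  reported with reasons, not silently dropped.
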