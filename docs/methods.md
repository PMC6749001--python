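# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `lineagesv`, in the order the pipeline runs them.

## Coordinate conventions

All in-memory coordinates are 0-based half-open (BED convention). BED
emission is verbatim; the VCF writer adds the 1-based anchor base at the
write boundary and the reader removes it. SVs and enhancers are strandless
intervals — no procedure in the package depends on strand. Soft-masked
(lowercase) bases are uppercased on read; repeat-aware logic uses explicit
interval annotation, never letter case.

Insertions are anchored at a single reference position; for overlap
arithmetic their interval is widened to `[pos, pos + length)` so the
length-reciprocal overlap rule treats all SV types uniformly. In the
partner-genome frame a deletion's locus is a zero-width point (the missing
sequence has no coordinates there); such points are widened to 1 bp only
inside any-overlap intersection tests.

## The synthetic clade

**What it emulates.** The simulator generates the statistical structure the
comparative analysis assumes: a fixed catarrhine topology
`(((((human, chimp), gorilla), orangutan)[, gibbon]), macaque), marmoset`
with SV events (DEL/INS; DUP/INV supported but default 0, matching the
restriction of lineage inference to the two dominant SV types) and
substitutions planted per branch. Branch lengths are irrelevant because the
inference uses presence/absence patterns, not rates — a branch is fully
described by its event counts, length distributions and substitution rate.

**Ancestral genome.** Random sequence at a target GC (default 0.41) with
planted repeats: copies of three SINE-like (300 bp) and two LINE-like
(1.5 kb / 6 kb) monomers tiled at random non-overlapping positions to a
target coverage (default 0.5). Each copy is independently mutated at 5 %
per base and reverse-complemented half the time. The divergence matters:
identical copies would make repeat regions anchorless, whereas real repeat
families are a few to tens of percent diverged and remain locally
alignable; 5 % keeps most 31-mers unique while preserving >90 % identity
between copies.

**Event placement.** Default counts are 60 ape-ancestor events (45 DEL /
15 INS, matching the ~80:20 deletion:insertion skew observed in ape-specific
SV catalogues), 40 macaque-branch events (25/15) and 20 per ape tip (12/8).
Lengths are log-normal with medians 319 bp (DEL) and 231 bp (INS), log-sigma
1.0, floor 50 bp — the observed medians of assembly-based SV catalogues.
Placements are globally disjoint with a 500 bp buffer and a 2 kb margin from
chromosome ends. Global (not merely per-lineage-path) disjointness is the
package's choice: it keeps macaque-frame truth projection exact and
guarantees at most one event between any pair of alignment anchors, at the
cost of not modelling recurrent or overlapping mutation — which the
downstream model does not attempt to resolve anyway.

**Substitutions** (default 0.002 per base per branch) are drawn once per
branch and shared by all tips below it, applied to the ancestral backbone
(inserted sequences are not further mutated — a simplification that only
matters for within-insert divergence, which no stage measures).

**Truth projection.** Truth coordinates are projected onto the macaque tip
genome, the analysis reference frame, by accumulating the signed length
shifts of macaque-branch events. Polarity is ape-centric: a DEL truth on
`ape_ancestor` means macaque and marmoset retain the sequence and all apes
lack it; a macaque-branch event appears to a macaque-frame caller with the
opposite type (`TruthSV.expected_call_type`).

**What the simulator does not emulate:** read-level errors and coverage
(assemblies are taken as given), recurrent mutation, segmental duplications
and translocations, population polymorphism beyond the genotype-table
abstraction, GC-biased repeat landscapes, and assembly collapse in long
repeats. Passing the recovery suites therefore shows the *inference logic*
is sound under clean and moderately diverged assemblies, not that the
pipeline is robust to real assembly artefacts.

## Alignment layer: anchors and chains

The pairwise comparison layer is a self-contained unique-k-mer anchor
engine, not a wrapped aligner — keeping the artifact desk-scale and every
step inspectable.

* **Anchors** are k-mers (default k = 31, odd, canonical-form counting)
  occurring exactly once in each of the two genomes; orientation is
  recorded from the strands of the two canonical occurrences.
* **Chains**: per (ref chromosome, query chromosome, orientation) block,
  the maximum-cardinality colinear subset of anchors is taken (longest
  increasing subsequence on query position, O(n log n) patience sorting,
  with a fast path when the block is already colinear), then split at
  adjacent-anchor gaps > 100 kb. A cleaning pass removes anchors whose
  ref/query offset is not shared with a neighbouring anchor: orthologous
  regions produce runs of constant offset, while a k-mer accidentally
  unique in two non-orthologous repeat copies is an offset singleton that
  would otherwise corrupt the gap arithmetic between its neighbours.
* **Calls**: for adjacent anchors, `d = (query gap) − (ref gap)`;
  `d ≥ 50` is an insertion in the query, `d ≤ −50` a deletion. Anchors may
  overlap on the shorter side at a junction (breakpoint micro-homology):
  the junction is then pulled back so the event ends at the right anchor.
  Otherwise the junction is refined by a mismatch-tolerant extension from
  the left anchor that scores +1 per match and −4 per mismatch and takes
  the maximal-scoring prefix — it walks through isolated substitutions but
  stops decisively at the transition into unrelated sequence (~25 % chance
  agreement). On divergence-free input this reduces to the exact common
  prefix and breakpoints are exact. Inversions are expressed as '−'
  orientation chains and deliberately not called.

The reverse-direction calls of a genome pair are projected into the forward
(macaque) frame by their own anchors with types swapped (`swap_frame`), and
forward calls without a reciprocal-overlap, type-matched reverse partner
are dropped (`bidirectional_concordance`) — a monotone filter that removes
direction-specific artefacts.

## ASSV inference and outgroup polarization

A candidate survives `intersect_across_apes` only if every ape comparison
contains a > 50 % reciprocal-overlap, type-matched partner (the reciprocal
threshold for the cross-ape step is taken equal to the published-set
matching threshold; it is a parameter). The representative record comes
from the human comparison, because human-frame coordinates are the ones
downstream annotation uses; a second human assembly (a GRCh38 stand-in
derived by planting private SVs) is matched in the macaque frame to attach
independent human coordinates, flagging candidates absent from it.

Outgroup classification compares, at each candidate locus, the inter-anchor
span in the outgroup against the two alleles. The homology map is built
once per outgroup from the genome-wide anchor chains; for a locus the
nearest usable anchors within 1 kb on each side must co-locate on one
outgroup chromosome in order. With `Δ = (outgroup span) − (macaque span)`
and L the SV length:

| call type | Δ ≈ 0 | Δ ≈ −L | Δ ≈ +L |
|---|---|---|---|
| DEL | high-confident (ape-derived) | false (macaque-lineage gain) | — |
| INS | high-confident (ape-derived) | — | false (macaque-lineage loss) |

Tolerance is ±10 % of L (minimum 10 bp); anything intermediate, any locus
whose flanks cannot be co-located, and any locus with flank identity below
0.85 is *uncertain*. The identity prefilter credits the located anchors
(exact 31-mer matches) and measures ungapped identity over the flank
windows, excluding 50 bp adjacent to the junction — reported breakpoints
may sit anywhere within junction micro-homology, and without the pad the
windows would straddle the junction and count unrelated sequence as
mismatch. The 0.85 floor and ±10 % span tolerance operationalise the
qualitative "completely aligned / partially aligned" distinction of manual
curation; both are exposed as parameters.

The same span logic against a gibbon genome separates ape-wide variants
(gibbon carries the derived allele → ASSV) from great-ape-specific ones
(gibbon macaque-like → GASSV); with no gibbon supplied every high-confident
call is uncertain at this second level.

## Gap closure and assembly QC

A gap is a maximal run of ≥ 2 N (the strictest reading of "more than one
N"; the run length is a parameter, so ≥ 1 is available). For closure, up to
5 kb of flank on each side is located on the assembly through the anchor
machinery, treating the flank as a miniature genome; a flank maps when its
best chain's merged anchor footprint exceeds 2.5 kb, and two distinct loci
with equal best footprint fail as ambiguous (failing is conservative; the
alternative of picking one is not defensible without mapping qualities).
LC is the rightmost assembly coordinate reached by the upstream flank and
RC the leftmost of the downstream flank, each refined by the same
mismatch-tolerant junction extension so LC/RC land on the junction even
when the last *unique* anchor stops short of it (a repeat bordering the
gap). The gap is closed iff both flanks map to one assembly chromosome in
'+' orientation with LC < RC and no N in `[LC, RC)`; the closed length is
RC − LC. A flank that fails to map (or maps ambiguously) gives
`flank_fail`; mapped but inconsistent flanks (different chromosomes,
orientation, or RC ≤ LC) give `unclosed` — the behaviour when only one
flank maps is not standardised anywhere, and emitting `unclosed` is this
package's conservative choice.

QV is the exact formula `−10·log₁₀(variants per base)`, reported unrounded
and nearest-integer rounded, with zero variants flagged as infinite rather
than inventing a pseudocount. N50 is the standard "length L such that
segments ≥ L sum to at least half the total"; contigs are scaffold
segments split at N runs ≥ 2.

## SV set statistics

Reciprocal overlap is strict (`overlap > t·len(a)` **and** `> t·len(b)`,
default t = 0.5), symmetric and threshold-monotone. Callset matching is
greedy one-to-one in decreasing overlap fraction, ties broken by smaller
start then smaller id — deterministic and order-independent. Window
densities use non-overlapping tiling windows (default 500 kb), counting an
SV in the window containing its start; the last partial window is kept.
Subtelomeric enrichment compares SV density (by start position) in the
terminal margins (default 5 Mb) against the remainder; the null redraws
each SV's start uniformly on its own chromosome and the p-value uses the
add-one estimator `p = (1 + #{fold* ≥ fold}) / (1 + n_perm)`, which is
never zero — an extreme observation is reported as a bound, not as p = 0.
Chromosomes shorter than twice the margin are wholly subtelomeric and are
flagged rather than silently skewing the denominator.

Genotype summaries: *invalidated* = no usable genotype in any individual;
*present* = ≥ 1 alt allele anywhere; *fixed* = homozygous-alt in every
individual (the stricter of the two defensible readings; the carrier-based
alternative is available via `fixed_rule="carrier_all"`); *polymorphic* =
present and not fixed. Percentages of present/invalidated are over all
SVs, fixed/polymorphic over present SVs, to two decimals.

## Differential enhancers

Counts are tested on the log₂(count + 1) scale — the transform is stated
because it is a genuine free choice; log stabilises the multiplicative
noise the simulator (and ChIP-seq practice) implies. The test is the
pooled-variance Student t by default: the chimpanzee group has two
replicates and Welch degrees of freedom are unstable at n = 2 (Welch via
`equal_var=False`). Zero-variance identical groups give p = 1. The ADE
criterion is the raw compound rule — macaque–human p < 0.05 and
macaque–chimp p < 0.05 with equal direction signs, human–chimp p > 0.05 —
with no multiple-testing correction, because the criterion itself is the
screen; a BH-adjusted mode exists but is off by default. Fold change is
log₂ of (mean human + mean chimp)/2 over mean macaque on raw means with a
+1 pseudocount. Under the all-null simulation (CV 0.15, 3/2/3 samples) the
empirical ADE rate is below 0.01 — much stricter than 0.05² because the
two significant tests share the macaque samples and the third test must
*fail*.

ASSV×ADE intersection is any-overlap (≥ 1 bp) in the human frame. Gene
annotation assigns an SV to every gene whose interval ± 5 kb it overlaps.
The cortical-layer comparison is a two-tailed paired t across matched
sections (the study design pairs 16 neocortical layers plus adjacent white
matter, 17 sections).

## Enrichment

The permutation null draws equal-sized SV subsets uniformly without
replacement from the full SV universe and recounts *distinct* trait genes
hit (gene ± 5 kb); distinct genes, not SV–gene pairs, is the primary
statistic (a pair-count mode exists). Desk-scale default is 10,000
iterations with `n_iter` exposed so larger counts are reachable; the
add-one estimator bounds p below by 1/(n_iter + 1). Fisher's exact test on
{in subset} × {hits trait gene} is computed alongside; the two agree in
rank across planted enrichment levels but are not numerically
interchangeable (the permutation statistic saturates when few genes
remain unhit). Both are reported; the permutation p is the primary number
because it is the procedure actually described by the resampling model.

## Pipeline and reproducibility

`run_pipeline` executes simulate → gap closure/QC → pairwise calling →
concordance → cross-ape intersection → human overlay → outgroup
classification → truth evaluation → set statistics → genotype summary →
ADE calling → enrichment. Every stochastic stage draws from a named
substream spawned from the single top-level seed (`SeedSequence.spawn`),
so identical configurations give byte-identical reports and single stages
can be re-run reproducibly. The resolved configuration and all stage seeds
are embedded in the report.

Default problem sizes — a 2 × 1 Mb genome, 180 SV events, 12 gaps, 2000
enhancers, 2000 permutation iterations — are chosen so a full run completes
in well under a minute on one CPU while leaving every stage statistically
non-trivial (≥ 40 events per evaluated class, ≥ 100 planted enhancers per
direction).

## Evaluation

`evaluate_assv_calls` matches calls to truth by chromosome, expected call
type, length within 10 %, and anchor position within k + 20 bp (breakpoint
representations may shift within junction micro-homology). Sensitivity is
the fraction of ape-ancestor truths recovered as high-confident;
macaque-branch truths with any matching call have "reached the
intersection stage" and are correctly handled when classified false;
precision is the fraction of high-confident calls matching an ape-ancestor
truth. On the default substitution-free conditions all three are 1.0; with
substitutions at 0.002 they are ≥ 0.95 by construction of the robustness
margins above (and 1.0 for sensitivity and false-classification on the
seeds exercised in the tests).

## Known limitations

* The caller reports DEL/INS only; duplications are called as insertions
  of the duplicated sequence and inversions are not called.
* Anchors require exact 31-mer uniqueness; regions whose repeat copies are
  younger (less diverged) than ~1 substitution per k bases are anchorless
  and events inside them are invisible. Real centromeric/satellite arrays
  are far beyond this regime.
* The outgroup classifier assumes the outgroup assembly is locally
  complete; assembly gaps in the outgroup produce *uncertain*, never
  *false*, mirroring the conservative direction of manual curation.
* The enhancer model tests per-enhancer counts independently; co-regulated
  enhancer correlation structure is not simulated.
* With two chimpanzee replicates the t test has 3 pooled degrees of
  freedom in the macaque–chimp comparison; power there is the limiting
  factor of the compound criterion, as the detection-rate calibration
  shows.
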