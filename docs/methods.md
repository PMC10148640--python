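# Methods

This note documents the models, rules and numerical choices behind
`termipep`, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data model

The original study material — public transcriptome and genome read
archives — is external and large, so every quantitative property of the
pipeline is demonstrated on synthetic read sets whose generating process is
known and exported.

**Gene catalog.** A catalog always contains 17 named genes: the seven
insulin-like peptides (gonadulin, IGF, the dilp7 ortholog, and the four
sirps atirpin, birpin, cirpin, brovirpin), seven CNS neuropeptides (AKH,
neuroparsin, SIFamide, SMYamide, allatostatin A, hansolin, CNMamide) and
three structural proteins (vitellogenin, a hexamerin, the vitellogenin
receptor), plus optional anonymous extras per category. IGF, atirpin,
brovirpin and AKH carry the peripheral-expression flag the normaliser
consults. Coding sequences are uniform random ACGT, rejection-sampled so
every pair stays below 60 % global identity (identity = 1 − Levenshtein /
max length, computed with edlib; up to 60 redraws per gene before a
`CatalogError`). Random sequences at these lengths sit near 48 % identity,
so rejection is rare; the bound guarantees that read-to-gene assignment
has a unique right answer except where a shared region is planted on
purpose. Neuropeptide/ilp CDS are 150–360 nt and structural-protein CDS
1800–3600 nt (≥ 5× the longest neuropeptide CDS), so 3′-bias undercounting
is visible on the long genes. Each generator draws from a seed stream
namespaced by generator kind, so a catalog and a read set built from the
same master seed never replay each other's random bytes.

**Transcriptome read sets.** Each spot picks a gene with probability
proportional to its programmed abundance λ (multiplied by the caste's
structural load for protein-category genes), then a fragment start `p`
with weight `((p+1)/ℓ)^bias` over the transcript (CDS + random 3′ UTR of
the annotated length). The power law is a one-parameter stand-in for the
3′ enrichment that polyA selection plus random mRNA breakage produces;
bias 0 is uniform and the default 1.5 gives a clear but not degenerate
skew. Reads are emitted on a random strand (unstranded library) with
independent per-base substitution errors (no indels — the matcher is
ungapped; error rate capped at 5 %). Optionally paired: a 5′ mate plus the
reverse-complemented adjacent fragment. A `dup_rate` fraction of spots are
re-emissions of earlier spots, under fresh spot ids by default (the
PCR-duplicate analog that spot-id deduplication cannot and should not
remove) or under the original id to exercise deduplication. Truth records
per-gene original counts, per-spot origins and fragment starts, and
duplicate provenance; `matchable_truth_counts` derives from it the counts
a CDS matcher can possibly see (fragments overlapping the CDS by at least
the match length), which is the correct exact-recovery reference — the gap
between true and matchable counts *is* the 3′-bias artefact being
modelled.

**Genome read sets.** Uniform shotgun reads over supplied contigs at a
target mean coverage, random strand, with the embedded-gene map passed
into truth. What the simulator does not model: base qualities, adapters,
indels, splice isoforms, coverage biases. Passing tests therefore
demonstrate the pipeline's logic, not robustness to platform-specific
artefacts of real archives.

## Spot counting

A gene's count is the number of distinct spot ids with at least one read
matching its CDS. Match semantics (implemented twice — k-mer index in the
package, exhaustive all-diagonal scan in the test oracle — and asserted
exactly equal): a read matches iff some ungapped alignment window of
length ≥ `min_match` has mismatch fraction ≤ `max_mismatch_frac` and
contains ≥ `k` consecutive exact matches, on either strand. Defaults
k = 15, min_match = 40, max_mismatch_frac = 0.05: simulated 100 nt reads
at 1 % error are recovered while sub-60 %-identity decoys have no chance
(a qualifying window requires a shared 15-mer). Non-ACGT characters never
match, including to themselves. A spot matching two genes increments both;
no best-hit resolution is attempted, mirroring query-by-query counting.
Counting one spot once per gene regardless of how many of its reads hit is
a deliberate resolution of an ambiguity in result-row deduplication.

For strongly expressed genes, `count_spots_sampled` counts only the first
N spots in file order and scales by `N_total / N`; file order (not a
random sample) matches how subsampled counting is done on archives, and
the unit is spots rather than file lines because line counts are
format-fragile.

The batched counting path turns every read position into an integer k-mer
code, prescreens against the sorted index codes with one `searchsorted`,
and verifies only unique (read, gene, strand, diagonal) candidates; a
perfect-overlap string comparison short-circuits the windowed check. These
are pure optimisations; the per-read `match_read` path and the test oracle
pin the semantics.

## Normalisation

Two measures per sample: spots-per-million `m_g = 1e6·c_g/N_total`, and
the neuropeptide fraction `f_g = c_g / Σ_{h∈D} c_h`, where D is all
neuropeptide- and ilp-category genes minus an exclusion set E. E contains
the peripheral genes whose share of the *raw* neuropeptide total exceeds
τ = 0.25 — the threshold and the raw-total basis are package decisions
(recorded in output metadata); the exclusion exists because a sample rich
in peripheral tissue can load the denominator with IGF/atirpin/brovirpin/
AKH counts that say nothing about CNS expression. The fraction is computed
per sample, never over a pooled comparison set. If the denominator is
zero, fractions are flagged undefined rather than invented.

Caste tables take group means over replicates, assign castes to
highest/intermediate/lowest by single-linkage gaps ≥ 1 in log₂-mean space
(at most two cuts), and report the fold difference as the mean of the
highest group's caste means over the lowest group's, with a pseudocount
added to both. The pseudocount default 0.5 is count-scale (it keeps
fold tables total-ordered when a group mean is zero); fraction-scale
tables should pass 0, in which case a zero group mean flags the fold
undefined instead. Correlations are Spearman: archive counts are
heavy-tailed and the relationships of interest are monotone claims.

QC flags are reproducible functions of counts alone: a deep library with
none of the four brain/corpus-cardiacum markers (neuroparsin, AKH,
SIFamide, SMYamide) is mislabeled or not a head/whole-body sample; high
brovirpin plus vitellogenin receptor is an ovary signature; counts for a
gene absent from the species indicate contamination.

## Rank-sum testing and calibration

The exact two-sided p is the share of all C(n₁+n₂, n₁) relabelings with
|W − E₀[W]| at least the observed value, E₀[W] = n₁(N+1)/2, mid-ranks for
ties. The distribution of W over the observed mid-rank multiset is
computed by a subset-sum recursion on doubled mid-ranks — identical to
literal enumeration (the tests check this against an itertools walk at
small n) but feasible at n₁ = n₂ = 15, where the smallest achievable
two-sided p is 2/C(30,15). Two-sided was chosen because the direction of
caste differences varies by gene. The large-sample fallback uses the
normal approximation with tie-corrected variance and a 0.5 continuity
correction.

Null calibration draws both groups i.i.d. Uniform(0,1) (any continuous law
is rank-equivalent) and counts strictly `p < α` per batch, following the
screening rule's phrasing. Note a discreteness consequence the idealised
"m·α expected false positives" argument glosses over: at n₁ = n₂ = 15 the
largest attainable level below 0.05 is 0.04533, so 100 null tests average
≈ 4.53 significant results, not 5.00; and p = 1 itself is attainable
(whenever W lands adjacent to E₀), so α = 1 does not flag every test. The
multiplicity report computes E = m·α exactly, applies the informal rule
(p between 0.02 and α is "ignored" as consistent with chance), and adds
Benjamini–Hochberg q-values as the principled alternative.

## Gene-loss calling

The query protein region (a receptor transmembrane region, supplied by the
caller — no TM prediction is done) is cut at its coding-exon boundaries so
no search query straddles an intron; pieces under 8 aa are merged with a
neighbour. Each piece is searched against all six reading frames of every
read (stop codons truncate frames) with exact 4-aa seeds extended
ungapped under BLOSUM62 to the maximal-score alignment containing the
seed. Raw scores are converted to bit scores with the standard ungapped
Karlin–Altschul parameters (λ = 0.267, K = 0.041); hits need ≥ 25 bits
over ≥ 10 aa. The thresholds were validated against a shuffled-read null:
random 100 nt reads top out near 20 bits against a 180 aa query, while
45 %-identity paralog fragments land above 25.

Every hit is re-scored against each member of a paralog panel (which must
include the query itself) and supports the query only if the query is its
unique best assignment — ties support nobody, which makes the verdict
independent of panel order. Verdicts: *present* if ≥ 50 % of pieces are
supported; *absent* if no piece is supported **and** the estimated mean
coverage (from control single-copy sequences, `estimate_depth`) is ≥ 5 —
below that, finding nothing proves nothing and the verdict is *ambiguous*.
High-identity hits truncated by in-frame stops raise a pseudogene hint;
distinguishing pseudogene from clean loss is otherwise out of scope.

## Precursor annotation

Convertase sites: maximal runs of K/R, longest-match — runs of ≥ 4 are one
tetrabasic site, runs of 2–3 contribute one dibasic site at their
rightmost KR/RR/KK pair (RK alone is not a site); cleavage is C-terminal
to the motif. The signal region is the first 19-aa Kyte–Doolittle window
with mean hydropathy ≥ 1.6 within the N-terminal 35 residues; a window
starting after residue 5 hints at an uncleaved signal anchor. This is an
explicit heuristic, not a predictor, and is labelled approximate.

Chains: the mature sequence is segmented at cleavage sites; the B chain is
the first cysteine-containing segment, the A chain the last segment with
≥ 4 cysteines (the last four are taken as the framework when more are
present — relevant for the no-cleavage-site, single-segment IGF-like
layout). `cys2_cys3_gap` counts residues strictly between the 2nd and 3rd
framework cysteines ("CXXXC" → 3). Class: gap 3 → IGF-like/atirpin-like,
gap 4 → other-sirp, anything else unclassifiable — deviations are
surfaced, never guessed. Processing hint: *constitutive* when no dibasic
site lies between the B and A chains. `make_ilp_precursors` builds seven
synthetic precursors with this designed architecture (gap 3 for IGF and
atirpin, without dibasic linkers; gap 4 with KR linkers for the rest);
they are stand-ins for real precursor sequences, which are not bundled.

## Problem sizes and determinism

The quantitative test suite uses: 200 replicates × 100 tests for the null
calibration (the acceptance script uses 1000 replicates to pin the mean to
±0.05); 50 seeded instances up to 2000 spots for counter/oracle
equivalence; 100 seeded two-caste experiments at 6000 spots for the
dilution contrast (geometric means of per-gene ratios, which are
log-symmetric at sparse counts); 100 seeds × 3 castes × 3 replicates at
5000 neuropeptide spots for fold recovery of programmed 17× and 5×
differences (expression programs are total-compensated so a fraction-based
fold equals the programmed ratio); 50 seeds at coverage 10 for the
no-false-loss property. All generators and tests are pure functions of
their seeds; the pipeline manifest records the master seed, the config and
SHA-256 checksums of every output, and a rerun under the same config is
bit-identical.

## Known limitations

Ungapped matching cannot follow indel sequencing errors or splice
junctions; the identity constraint makes cross-gene assignment trivial
compared with real paralog families (the planted-shared-region and
LGR-panel constructions probe the interesting cases directly); the signal
heuristic is cruder than dedicated predictors; fold grouping with a log₂
gap threshold of 1 is sensitive to programs whose caste means sit exactly
one doubling apart; and the normalisation argument assumes neuropeptide
expression is CNS-dominated, which is exactly why the peripheral exclusion
rule exists.
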