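# Methods

This note documents the models and procedures behind each pipeline stage,
the tunable parameters that matter, what the synthetic data emulate (and do
not), and the numerical choices made where the design was genuinely open.

## Profile HMMs and domain identification

The identification engine is a compact Plan-7-style profile HMM. Match
states M_1..M_L carry 20-way emissions; insert states sit between matches;
delete states are silent. Local (domain-anywhere) matching comes from
flanking self-looping states N and C that emit background residues with
loop probability l/(l+2) for a length-l target, uniform entry B→M_k with
probability 1/L, and a constant per-match exit probability
(`p_exit = 0.05`) to E, with M_L→E and D_L→E certain. The reported bit
score is log2 P(seq|model) − log2 P(seq|null) where the null emits l
background residues with a geometric length term; because N/C and the null
share the background, the dynamic programs run in log-odds space. Forward
and Viterbi are exact over this model — forward agrees with explicit path
enumeration to < 1e-9 bits on toy profiles — and run in log space without
underflow for sequences up to at least 5,000 residues.

Profiles are trained from seed alignments: columns with ≥ 50% residue
occupancy (`match_fraction`) become match states; emissions, transitions
and the background get Laplace pseudocounts (1.0). The background defaults
to the training-set residue frequencies; for short motif profiles (the
33-aa PPD below) the training composition is far too small and biased to
act as a null — its use produced ~15-bit spreads in null scores and
seed-to-seed instability — so motif profiles use the standard amino acid
composition instead (`build_profile(..., background=...)`).

E-values use a Gumbel null fitted to forward scores of 1,000 random
sequences whose lengths *and* residue frequencies are resampled from the
database about to be scanned (`calibrate_for_database`); E(s) =
db_size × P(S ≥ s). The fit matches the empirical 50th and 95th
percentiles rather than maximizing likelihood: the length-mixture null is
not exactly Gumbel, and a maximum-likelihood fit drifts off the median —
the one point of the curve with a sharp operational meaning (E at the null
median must be about db/2). Matching quantiles pins the median by
construction and keeps tail E-values monotone and order-of-magnitude
accurate (a 300-decoy scan at E ≤ 1.0 yields a handful of hits).

Scanning applies one E-value per sequence (the cutoff of the original
searches was per search, not per domain), takes the best Viterbi envelope,
masks it, and rescans for further domains; hits whose best path covers
fewer than 60% of the match columns are flagged `partial`. At planted
divergence 0.3, recall is 1.0 on 500-protein proteomes and envelope overlap
with the planted truth exceeds Jaccard 0.95.

## Pairwise alignment and homology search

Local and global alignment are exact affine-gap Smith–Waterman /
Needleman–Wunsch (Bio.Align.PairwiseAligner) with the classic BLASTP
scoring (BLOSUM62, gap open 11, extend 1; a length-k gap costs 11 + k).
Identity is identical columns over aligned columns; coverage is
query-relative, matching the coverage rules that are always phrased on the
query. Karlin–Altschul (K, λ) are estimated once per scoring scheme from a
Gumbel fit to local scores of 10,000 random length-150 pairs; E =
K·m·n·exp(−λs). These E-values gate screens that are always followed by a
stronger verification step (domain rescan, identity/coverage thresholds),
so order-of-magnitude calibration suffices.

The progressive multiple aligner builds a UPGMA guide tree on pairwise
(1 − identity) and merges groups by profile–profile dynamic programming
under a column-decomposable sum-of-pairs score (residue/residue from the
matrix, residue/gap −8, gap/gap 0; deterministic diagonal-first
tie-breaking). It recovers the exhaustive three-sequence optimum on
unambiguous cases; it is a heuristic, as all progressive aligners are.

## JTT distances, trees and subfamily assignment

Evolutionary distances maximize the likelihood of the published JTT
replacement model (exchangeabilities and frequencies frozen in `_jtt.py`;
rate matrix normalized to one expected substitution per site per unit
time, transition matrices via spectral decomposition). The optimizer is a
64-point geometric grid bracket followed by bounded Brent refinement; the
returned likelihood dominates a 1,000-point grid. Distances cap at 10
substitutions/site with a saturation flag. Parameter recovery at t = 0.3
over 10,000 sites is within 5%.

Trees are neighbor-joining (scikit-bio) on these distances — a
deterministic, desk-scale substitute for ML/Bayesian tree search;
subfamily classification depends on clade membership, not branch-length
fine structure, and NJ is exact on additive matrices (verified against a
15-topology minimum-evolution enumeration on 5 taxa). Negative branch
lengths are clamped to zero and counted. Bootstrap resamples columns with
replacement; supports are the fraction of replicate trees containing each
original bipartition.

A query domain sequence is assigned a subfamily by joining a labeled
reference panel in one NJ tree and taking the label of its smallest
enclosing reference group: among all bipartition sides that contain the
query and at least one reference, all sides of minimal size are pooled and
their reference labels must agree, otherwise the query stays `unassigned`
(this resolves exact ties conservatively). When N- and C-terminal domains
disagree, the N-terminal call is kept and the conflict flagged. On
synthetic panels with 2× between/within divergence (0.3 vs 0.15),
assignment is 100% correct.

## Duplication mechanisms

The tandem verdict is the conjunction of: child coverage ≥ 0.30 in a local
alignment at E ≤ 0.01, identity ≥ 0.70, rank distance ≤ 10 and midpoint
bp distance within the genome-size window (100 kb under 200 Mb, else
350 kb). "Ten genes apart" is implemented as |rank difference| ≤ 10 (the
intervening-gene reading is ambiguous); bp distance is
midpoint-to-midpoint; genes on different chromosomes fail the proximity
rule rather than erroring. The verdict equals brute-force predicate
evaluation on 10,000 random pairs.

Collinear blocks come from sparse DP chaining of anchor pairs (score 1 per
anchor, linear gap penalty 0.01 per rank, max gap 10 gene ranks, both
orientations, greedy best-chain extraction); chains under 5 pairs are
discarded. The chain score matches exhaustive increasing-subsequence
enumeration on ≤10 anchors and is translation-invariant. Mobile-element
relations are pure interval arithmetic on 1-based inclusive coordinates
with 50 kb flanks: `contained` ⊂, `partial` overlap, `flank_only` within
the window, else `none`.

## Expression

FPKM is counts × 1e9 / (length × mapped total); with totals equal to
per-sample sums, Σ_g fpkm·length = 1e9 exactly. Heat-map values are log2
with zeros masked as "no expression". A gene is tissue-preferred when its
top tissue exceeds every other tissue ≥ 2-fold on linear means and every
Welch t-test on log2(x+1) values is significant at α = 0.05; testing on
the log scale follows the survey convention of analyzing log2-transformed
abundances and stabilizes count variance at n = 3 (power ≈ 1.0 at fold 8,
dispersion 0.05, versus ≈ 0.90 on the raw scale). Welch rather than the
pooled-variance test is the conservative choice at three replicates. Ties
at the top are not called; silent-everywhere genes are excluded;
single-replicate tissues cannot support a call. No multiple-testing
correction by default (Benjamini–Hochberg available). Duplicate pairs are
diverged when any tissue shows a ≥2-fold significant difference or a
expressed/silent specificity change.

## Ka/Ks (NG86)

Site counts are fractional per codon position with changes to stop codons
excluded from the denominator, so N + S = 3 per codon identically;
differences average over all minimal substitution pathways that avoid
stops (all pathways if every one is blocked); pN and pS get the
Jukes–Cantor correction, with saturation flagged at p ≥ 0.75 and the ratio
flagged undefined at Ks = 0. Gapped codons are dropped pairwise; internal
stops are errors. The implementation matches hand-counted single- and
double-difference oracles exactly and an independent implementation
(Biopython's experimental NG86, which differs in its stop-site convention)
within a few percent. On codon pairs evolved at a known dN/dS (uniform
proposals; synonymous accepted, nonsynonymous accepted with probability
ω, stops rejected), the estimator recovers ω within 15% at 1,000 codons.

## PPD screen and HGT rules

PPD discovery scans IDS proteins with the C-terminal-domain profile at
E ≤ 100, keeps one best envelope per protein, discards envelopes outside
0.6–1.5× the expected 33-aa motif length, and deduplicates by exact string
equality (near-duplicate clustering deliberately not applied). The unique
seeds are aligned (trivially when equal-length) into a dedicated PPD
profile used to report per-set hit fractions; percentages are exact
rational arithmetic rounded half-up to one decimal (the convention that
makes 20,113/22,375 print as 89.9). Conserved-column analysis returns the
columns whose non-gap residues agree at a threshold (default 100%),
optionally within a row subset, which exposes subset-only conservation.

The HGT screen is a two-stage rule engine: candidate stage (any plant
alignment with query coverage ≥ 0.70 at E ≤ 0.01) and verdict stage (best
plant hit identity > 0.80 and coverage > 0.70, high-similarity hits in ≥ 2
plant species — the minimal reading of "multiple" — and no other-bacteria
homolog above 50% identity). The verdict equals brute-force evaluation of
the four predicates by construction and by test.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed). Proteomes plant domain
instances sampled from the profile consensus with per-site substitutions
drawn from the match-column distributions; decoys and flanks are uniform
1/20 background (the configurable null-model default); linkers are 10–50
aa, keeping envelopes separable. Genome layouts plant tandem arrays
satisfying every rule, controls violating exactly one named rule, ≥5-pair
collinear blocks and LTR-like elements at chosen relations. Expression is
negative-binomial (variance μ + φμ²; Poisson at φ→0) with 3 replicates,
baseline 100 counts, fold 8 for preferred genes and dispersion 0.05 —
values chosen once as representative of a moderately deep RNA-Seq
experiment. The IDS consensus embeds one fixed degenerate copy of a
C-terminal-domain window (33 aa mutated once at rate 0.8), so that IDS
proteins share a mutually conserved PPD that the C-terminal profile sees
only at relaxed E-values — the regime in which the motif is defined —
while the PPD profile built from discovered seeds finds essentially all
IDS proteins and almost no decoys.

These data are idealized: no alternative isoforms or fragmented gene
models, no compositional heterogeneity along real proteins, no correlated
expression between tissues, no alignment uncertainty in the codon pairs,
and domain divergence that is i.i.d. per site. Passing tests therefore
demonstrate the correctness of the rules and the calibration of the
statistics under their stated assumptions, not performance on any
particular genome release.

## Problem sizes

The test suite and the acceptance script use 500-protein proteomes,
1,000-sequence calibration nulls, 150–300-protein IDS/decoy panels,
1,000-gene null and 300-gene power expression simulations, 1,000-codon
Ka/Ks pairs, and ≤10-anchor enumeration oracles — sizes at which every
oracle is exact or tightly converged while the whole pipeline remains
desk-scale.
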