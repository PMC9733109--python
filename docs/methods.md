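# Methods

This note documents the statistical conventions, models, and design choices
behind `competab`, and what the synthetic-data validation does and does not
establish.

## Statistics kernel

**Exact binomial.** Two-sided p-values use the *minlike* convention: the sum
of the probabilities of all outcomes no more likely than the observed one.
For a 12:1 split this gives p = 0.0034; conventions that double the smaller
tail give the same value here but differ in general.

**Proportion tests.** `prop_test_cc` is the one-sample chi-square test with
Yates continuity correction, `(|k − n p₀| − ½)² / (n p₀ (1 − p₀))`, the
correction truncated at the absolute deviation. One-sided p-values halve the
chi-square tail on the observed side. `prop_test_two_sample` is the
two-sample analogue on a 2×2 table. For sired-offspring counts the report
shows three variants — one-sample corrected, exact binomial, and the
"mirrored" two-sample test of k/n vs (n−k)/n — because published analyses of
such counts are frequently the mirrored two-vector form of R's `prop.test`
(for counts 11 vs 5 the three give p = 0.21, 0.21, and 0.077 two-sided;
they agree in the strongly lopsided cases).

**Rank tests.** The rank-sum statistic is reported as `min(U, nm − U)` and
the signed-rank statistic as the positive-rank sum V, both matching R's
`wilcox.test` output. Exact null distributions are used for small untied
samples (rank-sum: both ≤ 20; signed-rank: ≤ 25 nonzero pairs), otherwise
the tie-corrected, continuity-corrected normal approximation. Zero paired
differences are dropped and counted. The Friedman statistic includes the
standard tie correction (midranks); a table whose blocks are all fully tied
carries no information and returns statistic 0, p = 1 rather than 0/0.

**Ordination.** `pca_counts` drops behavior columns contributing ≤ the
configured fraction (default 5%) of all events, converts rows to
proportions, centers columns, and eigendecomposes the covariance; component
signs are fixed by making each component's largest-magnitude loading
positive, so results are reproducible across platforms. Bray–Curtis
dissimilarity is computed on raw counts: `Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ)`.

**Permutation tests.** All permutation p-values use
`(1 + #{T_perm ≥ T_obs}) / (n_perm + 1)` with a single explicit integer seed
(default 1234) recorded in the result, so any p-value is reproducible
bit-for-bit. ANOSIM uses `R = (mean between-group rank − mean within-group
rank) / (M/2)`, M = n(n−1)/2, shuffling group labels. The Mantel test
correlates the upper triangles and shuffles rows and columns of the second
matrix simultaneously. PERMANOVA log(x+1)-transforms and column-standardizes
the response, takes Euclidean distances, Gower-centers −½D², and partitions
the total sum of squared distances *sequentially* (Type I) over the
predictor terms in the order given, permuting raw rows; collinear terms are
dropped with a warning. The log/standardize/Euclidean default mirrors how
multivariate behavioral metrics spanning orders of magnitude (latencies in
seconds vs counts) are normally prepared for an Adonis-style analysis; pass
`transform=False` to supply your own scaling.

## Encounter scoring

Conflicts are maximal runs of offensive/defensive events with inter-event
gaps ≤ `gap_s` (default 15 s, one location-scan interval); neutral behaviors
never open or extend a bout. This gap rule is an explicit operationalization
of live conflict scoring — the one free parameter is the gap. A bout is
decided iff exactly one dyad member shows defensive behavior (both-defensive
bouts are conservatively undecided), the winner being the other member.
Dominance within a dyad requires a two-sided exact binomial p < α (default
0.05) *and* a majority of decided conflicts; both session days are pooled.
The behavior→class map is a JSON config, not code; the packaged default
classifies attack/chase/fight/bite/box/tail-rattle as offensive,
flight/escape-to-water/submissive-posture as defensive, and
cleaning/sniffing/vocalization as neutral (vocalization is kept neutral even
though losers tend to vocalize more — reclassify via config if desired).

Cage use is summarized as per-individual shares of 15-s scans over
{home, neutral, foreign, tube, water/escape}. Friedman tests ask whether the
three main cages are used equally (overall and per population); the three
pairwise signed-rank comparisons are Bonferroni-corrected with m = 3;
foreign-cage use is compared between populations pairing the two members of
each dyad.

## Enclosure tracking

Occupancy inference is deliberately conservative and fully deterministic:

* `[t_open, first read]` is assigned to the home arena — animals are born
  and raised there before the connections open;
* consecutive same-side reads (any tube) pin the interval to that arena;
* opposite-side consecutive reads leave the interval *unassigned* and count
  exactly one passage. An odd number of crossings must have occurred; one is
  the minimum-evidence count, which makes the passage count robust to missed
  antenna reads (it never double-counts a crossing whose paired read was
  lost);
* `[last read, t_end]` follows the last read's side.

The intervals tile `[t_open, t_end]` exactly per tag (time conservation),
and with perfect detection the passage count equals the true number of
crossings, with arena-time error bounded by the true tube dwell. Tags never
read are excluded from metrics, mirroring how untracked transponders drop
out of an enclosure analysis. Touch latency is the first read minus
`t_open`; cross latency the first foreign-side read minus the first read
(missing, never infinite, if the mouse never reached the foreign side —
such mice are excluded pairwise from latency comparisons). "Session" is not
a standard quantity; here it is a maximal run of reads at one antenna with
internal gaps ≤ 10 s (configurable) and is flagged as an interpretation.
Rooms are processed independently.

## Population assignment and parentage

Founders are labeled by population in this design, so assignment is
*supervised*: founder allele counts (additive pseudocount 0.5 on the union
allele support, so every observed allele has positive frequency in both
panels) give two frequency panels, and each individual's admixture
proportion q toward population A maximizes
`Σ_alleles log(q f_A + (1−q) f_B)`, alleles treated independently across the
13 loci. The optimum is located on a 0.001 grid and refined by bounded
scalar minimization. Classes: pure-A at q ≥ 0.9, pure-B at q ≤ 0.1, mixed
otherwise (thresholds configurable; they are a convention, not an estimate).
Individuals typed at fewer than 6 loci are unassigned; identical panels
leave the likelihood flat and the result is tie-broken to q = 0.5 and
flagged uninformative. A supervised MLE keeps the stage deterministic and
desk-scale where an unsupervised MCMC clustering would add nothing, founders
being known.

The parentage LOD is a single-parent likelihood ratio per locus:
`log₁₀ [((1−ε)·T(g_o|g_c, f) + ε·P_HWE(g_o|f)) / P_HWE(g_o|f)]`, where T is
Mendelian transmission of one allele from the candidate with the other drawn
from the room-pooled frequencies f, and ε (default 0.01) is a genotyping
error escape: mismatching loci are penalized smoothly rather than hard
excluded, and at ε = 0 a single Mendelian-impossible locus yields −∞ (hard
exclusion). Missing loci are skipped. Candidates are all transpondered
adults of the relevant sex in the room — no conception-window filtering.
Per sex, candidates are ranked by LOD (ties broken by id) and the parent's
population background is accepted only when the top two candidates share a
population; otherwise it is undetermined. Missing genotypes propagate as
unassigned/excluded, never imputed.

## Synthetic-data generators

All generators fan a root seed out to per-unit streams with
`SeedSequence.spawn` in unit order, so enlarging a cohort never perturbs
earlier units, and identical seeds give byte-identical outputs.

**Dyads.** Per 10-min session, bout count ~ Poisson(21.3) (the observed 638
conflicts over 15 dyads × 2 days), decided with probability 0.42
(271/638), the dyad's dominant winning a decided bout with probability 0.95
(the observed winner share is 265/271 ≈ 0.98; 0.95 keeps a realistic
minority of upsets), and the CB-like member dominant with probability 10/13.
Bout events are role-specific multinomials with intra-bout gaps below the
segmentation default; bouts are spaced more than one gap apart so
segmentation can recover them exactly. Location scans follow a per-role
Markov chain over the six compartments at 15-s ticks (losers avoid the
foreign cage).

**Enclosure.** Each mouse is an independent continuous-time Markov chain
over {home arena, tube, foreign arena}: exponential waits to the first tube
approach and between tube entries, an exponential tube dwell, a crossing
probability per tube visit, and a (shorter) exponential sojourn when in the
foreign arena. Every true antenna pass is detected with probability 0.9 by
default (reflecting that roughly a tenth of time was unassignable in
practice). The CB-like/MC-like presets encode ordered contrasts only —
shorter latencies, more crossings, longer foreign sojourns for CB-like —
not fitted magnitudes. Movement is memoryless by construction; this is the
simplest model producing the metric structure the analysis consumes, not a
claim about mice. There is no social interaction between simulated mice.

**Pedigree.** Per-locus allele frequencies follow a Balding–Nichols draw
around a uniform-Dirichlet ancestral frequency; because each population
diverges independently, the Balding–Nichols parameter is set to
`F' = 2·fst/(1+fst)` so the expected *pairwise* Gst between the two
populations equals the configured target (default 0.15, a realistic
divergence for recently separated commensal populations). Defaults: 13
loci, 14 alleles per locus (typical polymorphism of microsatellite panels,
which are selected for diversity), 25 founders per population, Mendelian
offspring from pure and mixed matings, then per-allele genotyping error
(1%, replacement by a random allele) and per-locus missingness (1%) applied
last. Truth records every offspring's parents and class.

**What passing tests do and do not show.** The generators reproduce the
statistical *structure* the analyses assume — Poisson bouts, memoryless
movement, Hardy–Weinberg founders — not the dependence structure of real
recordings (social conflict dynamics, diurnal rhythm, antenna burst reads,
linked loci, inbreeding). Recovery rates measured on them are best-case
calibrations of the inference code, not field performance estimates.

## Validation problem sizes

The test suite and acceptance script use desk-scale problem sizes chosen to
make Monte-Carlo error small relative to the asserted margins: 20 mice ×
72 h for occupancy-oracle equivalence; 200 null replicates (n = 16, 199
permutations) for type-I calibration of ANOSIM/Mantel/PERMANOVA, and 200
even-dominance dyads for the winner call; three independent 50+50-founder
cohorts with 42 F1 offspring each for assignment/parentage recovery. The
calibration checks accept when the rejection count is consistent with a
Binomial(n, 0.05) draw at the 95% level.

## Known limitations

* The per-dyad exact binomial cannot reach p < 0.001 for totals below 11;
  published tables sometimes print "< 0.001" for such splits, which no
  binomial convention reproduces (the dominance calls themselves all hold
  at α = 0.05).
* The occupancy rule undercounts passages when detection failures hide an
  even number of return crossings between two observed same-side reads;
  this is the price of a deterministic, conservative rule.
* The admixture MLE treats alleles as independent draws (no
  linkage/inbreeding) and is supervised — it cannot discover population
  structure beyond the two labeled panels.
* Single-parent (not trio) parentage likelihoods; no sibship
  reconstruction, null-allele, or mutation modeling.
* No generalized linear or mixed models; count-regression modeling of
  conflict outcomes is out of scope by design, replaced with exact and
  permutation tests.
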