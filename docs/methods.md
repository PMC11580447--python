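# Methods

This note records the models, estimators, numerical choices and known
limitations behind `aureomine`, in the order the pipeline runs them.

## Profile HMM and glocal scoring

The model is a classic match/insert/delete profile (begin, match
states `M_1..M_L`, insert states `I_0..I_L`, delete states `D_1..D_L`,
end), with the transition set {M→M, M→I, M→D, I→M, I→I, D→M, D→D} —
no I↔D transitions.  It is estimated from a seed alignment:

* **Match columns.** A column is a match state when its gap fraction is
  *strictly* below the occupancy threshold (default 0.5).  A column at
  exactly the threshold is an insert column; the strict rule is a
  documented tie-break, not a convention-free choice.
* **Emissions.** `(counts + w·background) / (n + w)` with a single
  pseudocount weight `w` (default 1.0) and a packaged amino-acid
  background (Robinson–Robinson frequencies).  A single-parameter
  background mixture was chosen over Dirichlet mixtures for determinism
  and testability at toy scale; it is the main respect in which the
  model is simpler than a production `hmmbuild` profile (no entropy
  weighting, no effective-sequence-number downweighting).
* **Transitions.** Counted from each row's observed state path and
  Laplace-smoothed (+1) over the transitions the architecture allows at
  each node; at the last node the "next match" target is the end state
  and M→D/D→D are structurally zero.

Scoring is **glocal** — whole model against whole sequence — because
the targets are complete small proteins and a hit is only meaningful
when homology spans the whole peptide.  The forward recursion sums over
all paths in log2-odds space against the i.i.d. background null, so the
score is directly a bit score; Viterbi maximizes with a fixed
M < D < I predecessor priority, making the reported path the
lexicographically first optimum.  `X` emits the background probability
in both model and null (odds 1, zero bits).  Both scorers are verified
against brute-force enumeration of all glocal paths on toy models
(M ≤ 3, sequences ≤ 4) at 1e-9 log-space tolerance; the batched scorer
groups sequences by length and carries the batch as a trailing numpy
axis (the delete chain is the only per-node sequential sweep).

## E-value calibration

E-values come from a Gumbel survival law fitted to forward scores of
null sequences drawn from the database composition,
`E = N · (1 − exp(−exp(−λ(s − µ))))`.  Each null sequence receives its
own composition from a Dirichlet around the smoothed background
(concentration 50), matching the decoy generator, because real short
proteins are compositionally overdispersed and a fixed-composition null
understates score variance.

The fit is **censored**: a maximum-likelihood exponential rate on the
exceedances over the upper quantile of the null sample
(`tail_fraction` defaulting to 2.5%, widened when necessary so at least
~20 exceedances remain), converted to Gumbel form via
`µ = u + ln(tail_fraction)/λ`.  Measured on 5×10⁴ null
scores, the glocal forward null is lighter-tailed than Gumbel through
its bulk — a whole-sample moments fit (`fit_gumbel_moments`, retained
as an option and verified on genuine Gumbel samples) overestimates the
10⁻⁴ tail quantile by ~20 bits and would make every E-value grossly
conservative.  The far tail is close to exponential (~7.5 bits per
decade beyond the 99th percentile), which the censored fit tracks to
within one to two bits; the residual extrapolation bias is mildly
conservative (true E-values slightly below reported ones).  Pushing the
anchor quantile deeper reduces that bias but inflates estimator
variance roughly in proportion; at the default null sample sizes the
two effects are comparable, so the anchor stays at the 2.5% tail.  The
whole calibration stands in for an external search engine's
significance machinery and is deliberately swappable.

Calibration uses a single sequence length (the median of the filtered
database); E-values for sequences far from that length are
correspondingly approximate.  This matters little here because planted
signal sits tens of bits above the null.

## Iterative search

Round 1: filter the database to proteins strictly under `max_len`
(default 100) residues, build the model from the seed alignment,
calibrate, score, keep `E < 1e-5`.  Round 2: project the round-1 hits
onto the model's match columns via their Viterbi paths (deletes become
gaps; insert-emitted residues are dropped — the trimmed-alignment
convention), project the seed rows the same way, rebuild, recalibrate
and rescore.  Hits are reported once with the round of first discovery
and that round's score and E-value.  Recalibration can in principle
shift borderline E-values between rounds; the monotonicity the tests
assert therefore uses well-separated planted scores.

## Alignment and percent identity

Needleman–Wunsch with affine gaps (first gap residue `gap_open` = −10,
each further residue `gap_extend` = −1, BLOSUM62) and a deterministic
traceback tie-break: diagonal > up > left.  Percent identity divides
identical columns by **all** alignment columns, gaps included —
the convention under which 14 shared residues in a 52-column alignment
give 26.92 → 26.9%, and 9/14 gives 64.29%, the network threshold.
Values carry 0.01 precision internally and display at one decimal.

The multiple alignment is star-progressive: the center is the sequence
with the highest summed pairwise score, all others align to it, and
pairwise gaps merge under "once a gap, always a gap".  This replaces a
heuristic aligner on purpose: the procedure is fully specified and
oracle-testable, which a muscle run is not.

## Networks, clustering, phylogeny

The similarity network keeps an edge when pid is strictly greater than
the threshold (default 64.29%), so singletons are exactly peptides with
≤ 64.29% identity to everything else.  Components are labeled by size
descending, then smallest member id.  Greedy clustering processes
sequences longest-first (ties by id); each sequence joins the first
representative at ≥ the identity threshold (default 0.90) else founds a
cluster — the CD-HIT procedure without its word-filter heuristics,
which are unnecessary when exact pids are cheap.

The tree is Saitou–Nei neighbor joining on `d = 1 − pid/100`, with the
smallest-(i,j) tie-break on the Q criterion and negative branch
estimates clamped to zero with the deficit moved to the sister branch
(the pair sum is preserved).  On additive matrices NJ recovers the
generating tree exactly (tested to 1e-9 against random 4–8 taxon trees
and cross-checked against scikit-bio's implementation).  NJ replaces
maximum-likelihood inference deliberately: the tree's role is clade
grouping of cluster representatives, and a distance method is exactly
reproducible.  Outgroup rooting splits the outgroup's pendant branch at
its midpoint.  An optional column bootstrap is out of scope; no support
values are reported.

## Peptide properties

GRAVY is the mean Kyte–Doolittle hydropathy; molecular weight sums
average (not monoisotopic) residue masses plus one water (18.0153 Da),
matching kDa-level reporting.  Net charge is the Henderson–Hasselbalch
sum on the EMBOSS pK set (N-term 8.6, C-term 3.6, K 10.8, R 12.5,
H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1), packaged as data and swappable;
the summary table reports charge at pH 7.0, a documented assumption.
The charge curve is strictly decreasing in pH, so the isoelectric point
is the unique bisection root on [0, 14] (interval shrunk to 1e-6 pH so
the charge at the root is well under 1e-3).  A consequence worth noting:
for a peptide with no ionizable side chains the pH-7 charge is slightly
*negative* (≈ −0.024), because the C-terminus (pK 3.6) is more fully
ionized there than the N-terminus (pK 8.6) is protonated.  `X` is
rejected in all property calculations — a single unknown residue
poisons every downstream number.  Dose conversion is
`µM = 1000 · (µg/mL) / Da`, reported at one decimal: 100 µg/mL at
6.3 kDa is 15.9 µM.

Group contrasts use the tie-corrected Kruskal–Wallis H with a
chi-square p (df = groups − 1; scipy's implementation behind the module
surface).  The degenerate all-identical input returns H = 0, p = 1.  At
very small samples (e.g. 4 + 4) the chi-square p is an approximation;
the tests compare it against a 10⁵-permutation oracle and accept the
~0.01–0.02 discrepancy that approximation carries at that size.

## Synthetic data: what it emulates, and what it does not

The generator plants peptide families by substituting exactly
`round(fraction × length)` positions of a seed, chosen uniformly
without replacement except that at most one tryptophan position is
touched whenever the requested count permits — the conserved
tryptophans are what the profile keys on (the default designed seed is
52 aa, strongly cationic, W at positions 21, 32 and 45).  When the
count forces it (e.g. fraction 1), the minimum extra tryptophans are
substituted so the realized Hamming distance always equals the
requested count.  Replacement residues come from a K/R-enriched
background and always differ from the original.  Decoys are i.i.d.
within a per-sequence Dirichlet-drawn composition: homology-free by
construction, hence a proper score null.  Default study conditions:
two families at distances 0.1 and 0.3, ten members each, 200 decoys of
length 40–120 (straddling the 100-residue cutoff so the length filter
always has work); families alternate phyla so the rank test always has
two non-empty groups.  Operon archetypes cover a single core gene with
transport/membrane/regulator neighbors, tandem multi-core operons (2–8
copies inside one window), a contig truncated < 2 kb after the core
gene, and transport+regulator on the strand opposite the core.

What passing tests on this data do **not** show: recovery rates against
real catalogs (real homologs are not uniform substitution clouds, real
decoys are not i.i.d., and real databases are 10⁶–10⁹ sequences, which
moves E-value thresholds); realistic intergenic structure or gene
calling; taxonomy beyond a two-phylum label.  The synthetic results
validate the machinery, not the biology.

## BGC classification

Roles are keyword matches on product strings (packaged, overridable)
with fixed precedence core > transport > membrane > regulator > repair
> hypothetical > other; mined core genes get the core role by identity,
not text.  The neighborhood window is ±5 kb around the merged core-gene
span — characterized operons of this family fit in 5 kb — clipped to
contig bounds; `contig_edge` records that clipping occurred.  Core
genes closer than the merge distance (default: the window) chain into
one cluster, which is how tandem multi-core operons are counted once.
`opposite_strand_machinery` is raised when any transport or regulator
feature sits on a strand opposite every core gene.  The
`functional_operon` flag is the conjunction transport ∧ (membrane ∨
regulator) — a structural summary, never a biological claim.

## Pipeline determinism and problem sizes

One integer seed drives every random draw (simulation, calibration
nulls); identical config + seed reproduces every output file byte for
byte (the run log with timings is excluded from that guarantee).  The
shipped test and acceptance workloads use 10⁴-sequence null databases,
20 replicate calibrations, 10⁴-decoy recovery experiments,
10⁵-permutation rank-test oracles and 50 BGC replicates per archetype —
sizes chosen so the full suite completes in a few minutes on one CPU
while keeping every statistical check at meaningful resolution.
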