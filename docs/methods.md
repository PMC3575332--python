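# Methods

## Data model

A genotype matrix holds three-state calls (heterozygous-like,
homozygous-like, missing) for markers x individuals, with a linkage-group
label and a dense 0-based order rank per marker. Missing is first-class:
it is never conflated with a homozygous call, and every operation either
handles it explicitly or refuses to run (binning, for instance, demands an
imputed matrix). Surface dialects — JoinMap CP codes `lm/ll/nn/np/--` and
the simplified `a/h/-` alphabet — are normalised to the internal states at
I/O time.

Phase encoding collapses call + phase into `{1, 0, -1}`: heterozygous on a
phase `1-` marker and homozygous on a phase `0-` marker both mean the same
parental homolog and encode +1; the opposite pairings encode −1; missing
encodes 0. Flipping a marker's phase negates its non-missing encoded
values, and every downstream statistic is either equivariant (imputation)
or invariant (two-point r after folding, χ²) under that flip.

When no phase column accompanies the input, phases are inferred greedily
along the given order: the first marker of each group is assigned `1-`,
and each later marker takes the phase that best agrees with the most
recent informative marker, majority-voted over individuals (ties keep
`1-`). With markers correctly ordered, adjacent-marker recombination is
rare, so non-recombinant individuals dominate the vote. This is a
deliberate stand-in for phases taken from an external mapping run; the
matrix I/O accepts an explicit phase column whenever one exists.

## The imputation core

Per individual and linkage group, on the encoded vector:

1. **Compress.** Zeros are removed; an index map remembers original
   positions. Vectors whose missing fraction exceeds `max_missing`
   (default 0.70) are passed through untouched and flagged, preserving
   matrix shape; so are vectors with no calls at all.
2. **Detect.** The zero-free vector is correlated with the antisymmetric
   sign mask `(-1,...,-1, 0, +1,...,+1)` of half-width `E`. The mask
   weights approximate the first derivative; the sign choice makes a clean
   phase transition score exactly `2E`, leaving an error run of length `c`
   at score `2c` — below the default threshold `T = E` whenever
   `c <= E/2`. Any position with `|conv| > T` (strictly) is above
   threshold; contiguous same-sign runs collapse to one edge placed
   between `m` and `m+1`, `m` the leftmost position attaining the run's
   maximum (a clean edge yields a two-wide plateau, making this exact; the
   leftmost rule is the deterministic tie-break). Windows overrunning the
   vector ends are zeroed: a truncated antisymmetric window scores
   non-zero even on constant input, so no edge is detectable within `E`
   positions of either end and terminal blocks absorb those positions.
   Vectors shorter than the mask have no interior positions, detect no
   edges, and are flagged `short_window`.
3. **Fill.** Each block between consecutive edges is set to the majority
   sign of its original values; an exact tie takes the block's first
   (leftmost) entry — deterministic and sign-symmetric. Adjacent blocks
   that end up equal are merged and the separating edge dropped, which
   removes spurious double edges from error clusters.

Passes 2–3 iterate on the compressed vector until a fixed point (hard cap
20 iterations; 3 suffice in practice). A single pass is not idempotent —
`[1,-1,-1,1]` at `E=1` takes three passes to stabilise — and idempotence
is the property callers should be able to rely on: re-imputing an imputed
matrix must change nothing. On clean data one pass already is the fixed
point, so the iteration leaves all simple cases untouched.

Finally the corrected vector is expanded to original coordinates: each
formerly-missing position takes its nearest non-missing neighbour's
corrected value, equidistant ties to the left. This places an inferred
crossover at the proximal end of a missing run — the conservative choice,
as extending the preceding block is the assumption that no recombination
occurred where data are absent. Leading/trailing missing runs take the
first/last corrected value.

Reported edges carry the pair of adjacent informative positions they fall
between, in original order-rank coordinates, with the transition sign and
the detection score.

### Parameters

| parameter     | meaning                                              | default |
|---------------|------------------------------------------------------|---------|
| `E`           | mask half-width; max expected consecutive errors     | 5       |
| `T`           | edge threshold, strict: abs(conv) > T                | `E`     |
| `max_missing` | per-vector missing fraction above which it is skipped| 0.70    |

Larger `E` detects edges more reliably but locates them less precisely
near errors, and leaves runs of up to `floor(E/2)` consecutive wrong calls
correctable. `E = 5` suits matrices with a couple of percent error; `T`
below `E` trades error tolerance for sensitivity to short blocks.

### Guarantees and their hypotheses

The exhaustive suite verifies, for `E <= 3` and every vector of length
<= 16 in the qualifying class, that the output equals brute-force
minimum-Hamming piecewise-constant segmentation at the true edge count.
Qualifying means: crossovers at least `E+1` positions from the ends and
separated by more than `2E+1`; error runs of length at most `floor(E/2)`,
separated from each other *and from every crossover* by more than `2E+1`.
Both separations are necessary, not conservative: a run of `c` errors with
`2c > E` fires spurious edges, and an error inside a crossover's detection
window degrades the convolution plateau enough to shift or erase the edge
(counterexample: length 6, `E=2`, crossover after position 2, error at
position 0). Outside the qualifying class the algorithm still runs and is
idempotent and sign-symmetric; it simply carries no optimality guarantee.

## Map statistics

* **Recombination accounting** counts sign changes between consecutive
  non-missing entries; per-individual totals sum over groups.
  `percent_reduction` reports `100*(before-after)/before` to one decimal.
* **Binning** groups markers with byte-identical call vectors; bins are
  ordered by first appearance along the map and the first member is the
  representative.
* **Two-point linkage**: r̂ = recombinants / informative meioses (both
  calls present), folded to [0, 0.5] by adopting the complementary phase
  when the raw fraction exceeds 0.5 (recorded on the result — standard
  testcross practice, and it makes grouping phase-agnostic). LOD is the
  closed-form likelihood ratio at the MLE,
  `R*log10(r/0.5) + (n-R)*log10((1-r)/0.5)`, which reduces to
  `n*log10(2)` at r̂ = 0. Pairs with no informative meioses are flagged
  undefined rather than given a value.
* **Grouping** joins markers with LOD >= `min_lod` (default 7.0) and
  r̂ <= `max_r` (default 0.35) and takes connected components
  (single linkage). Raising the LOD threshold can only split, never merge.
  Note the ceiling `n*log10(2)`: below 24 individuals no pair can reach
  LOD 7.
* **Kosambi distances** `d = 25*ln((1+2r)/(1-2r))`; map length is the sum
  over consecutive bins along the given order. This sequential two-point
  construction approximates multipoint regression mapping; it is unbiased
  to first order and its sampling noise on `n` meioses is roughly
  `sqrt(100^2 * (L/100) / n)` cM for a group of length `L` — about 11 cM
  for 87.6 cM at n = 71, which is the band the tests assert.
* **Distortion scan**: per marker, `chi2 = (a-b)^2/(a+b)` on the two
  testcross class counts (df = 1 against 1:1), p-values from the χ²
  survival function, flags at the fixed critical values 3.841 / 6.635 /
  10.828. Raw statistics are plotted against fixed thresholds with no
  multiple-testing correction, matching how distortion scans are usually
  read along a map; an FDR column would be a trivial addition but is
  deliberately off.
* **Greedy ordering** (nearest-neighbour chaining from the closest bin
  pair, ties to lower ids) is provided so synthetic end-to-end runs need
  no external ordering tool. It recovers the true order or its reversal on
  clean data and is documented as a heuristic, nothing more.

## The simulator

`simulate_clean` draws, per gamete and linkage group, a
Poisson(`L`/100) crossover count with breakpoints uniform on (0, L) — a
no-interference model. Distances are later expressed in Kosambi cM, which
assumes partial interference; at the simulated group lengths (roughly
0.5–0.9 Morgans) the mismatch in expected map length is small, and it is
accepted for simplicity. Marker positions are uniform; each individual's
encoded vector is the starting phase (fair coin) cut at the breakpoints;
marker phases are random so the observed call matrix exercises both
encodings. Two crossovers falling in the same marker interval cancel and
are invisible by construction — the truth set records drawn breakpoints,
and the tests account for within-interval parity when comparing counts.

`degrade` draws a per-individual missing rate from a Beta distribution
parameterised by mean (0.36) and standard deviation (0.10), emulating the
strong between-individual variance of sequencing depth without modelling
reads; cells drop independently at that rate, then surviving calls flip
between the two testcross classes with probability 0.02. Missing and
error masks are disjoint and recorded. Defaults — 71 individuals, seven
groups at lengths 87.6/46.4/73.6/78.5/53.1/68.4/55.1 cM, 500 markers per
group — reproduce the data shape of the GBS raspberry progeny the package
is modelled on; the true per-call error rate of such data is unknown (only
its symptom, inflated perceived recombination, is observable), so 2% is an
exposed parameter, not a claim.

What the simulator does *not* emulate: marker misordering (the core
assumes the given order), read-depth-correlated call bias within an
individual, clustered errors from paralogous loci, segregation distortion,
and AB×AB markers. Passing recovery tests therefore demonstrate the
algorithm under its own assumptions — correctly ordered markers,
independent symmetric errors — not robustness to ordering mistakes or
systematic miscalls.

## Validation scale

The fixed-seed recovery suite runs the full study shape (71 x 3500 cells)
in under a second, so no scaling-down was needed there; exhaustive oracle
checks stop at vector length 16 and `E <= 3`, where brute-force
segmentation enumeration is still cheap and which already covers every
qualitative regime (0–2 crossovers, 0–3 isolated errors, truncated
windows). Grouping tests use 60 markers per group; pairwise two-point
matrices grow quadratically in markers and 420 markers exercise the
clustering fully.
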