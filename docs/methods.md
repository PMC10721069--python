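# Methods

## Model and estimators

A duplex ddPCR well partitions template into `D` droplets (default
20,000) of volume `V` (default 0.85 nL, the QX200 average; configurable
because instruments differ). Occupancy is Poisson with mean `λ`
copies/droplet; concentration on the instrument scale is
`λ / (V in µL)`, so the 5000 copies/µL ceiling of the QX200 reader
corresponds to `λ = 4.25`. Each molecule is independently one of
three species: 5'-only (probability `p_CMV`), 3'-only (`p_polyA`), or
intact (`1 − p_CMV − p_polyA`). The four droplet-category
probabilities follow in closed form:

* negative: `e^{−λ}`
* target-1-only: `e^{−λ(1−p_CMV)} − e^{−λ}`
* target-2-only: `e^{−λ(1−p_polyA)} − e^{−λ}`
* double-positive: the complement.

**Poisson-multinomial estimator.** `λ` is estimated from the negative
fraction. Each observed single-positive fraction `s` is equated to
the truncated series `Σ_{k=1..k_max} Pois(k; λ) p^k`, a polynomial in
`p` with non-negative coefficients, hence strictly increasing on
[0, 1]: the root is unique and found by bisection (tolerance 1e-12 in
`p`, iteration cap 200). The default truncation depth `k_max = 20`
covers the whole dynamic range: at `λ = 4.25`, `P(K > 20) ≈ 5.4e-9`.
The untruncated series sums to `e^{−λ(1−p)} − e^{−λ}`, giving the
closed form `p = 1 + ln(s + e^{−λ})/λ`; this is kept as an
independent oracle for the solver (they agree to < 1e-6 in `p`
everywhere in the working range), not as the production path.
Integrity is `(1 − p_CMV − p_polyA) × 100`, never clamped — a
0%-integrity sample legitimately produces small negative estimates at
finite droplet counts, and clamping would bias dilution-series means.

**Comparators.** The simple percentage (double positives over total
positives; a concentration-ratio variant Poisson-corrects each
positive category separately) is exact only in the dilute limit; on
exact expected counts it increases monotonically with `λ` for any
partially intact sample. The linkage concentration is implemented as
the molecular-species decomposition
`λ_linked = λ_t1 + λ_t2 − λ_total` (per-channel λ's from each
channel's negative fraction), which matches the verbal definition of
linkage — double positives in excess of chance co-localization —
exactly under the Poisson partition model; the instrument vendor's
proprietary computation may differ in low-count edge cases. On exact
expected counts with symmetric partials, average-linkage integrity
equals `200 p_full / (1 + p_full)` and therefore always overestimates
partially intact samples; the compensated variant additionally scores
100% for a sample whose molecules all carry a single target. Both
pathologies are reported as-is, not corrected.

**NA rule.** The strict rule (default) declares the
Poisson-multinomial estimate NA when any of the four category counts
is zero, mirroring the published analysis app's behaviour on raw
exports. A relaxed mode requires only a nonzero negative count: a
zero single-positive fraction then solves to `p = 0`, so a perfectly
intact well evaluates to exactly 100%. The relaxed mode exists
because a model-faithful simulation of a 100%-intact sample produces
*no* single positives in any well — a configuration real wet-lab data
never achieve — and the strict rule would discard the entire sample.
Simulation-based validation therefore runs relaxed; instrument data
default to strict.

## Synthetic-data generator

The simulator draws wells from exactly the model above: two stock
populations (an intact-like and a fragmented-like stock, each a
species mixture parameterised by an integrity fraction and a 5'/3'
split of its partial molecules) mixed at molecule fractions, diluted
over a concentration grid, with a fixed droplet count per well. Two
sampling modes are statistically identical and tested as such: one
multinomial draw over the four category probabilities (fast default)
and a per-molecule mode that draws Poisson occupancies and assigns
each molecule a species. Seeding is hierarchical:
`SeedSequence([master_seed, well_index])` with sample-major well
ordering, so any single well is reproducible in isolation.

Built-in designs emulate two validation studies: a plasmid study
(expected integrities {0, 8, 18, 29, 43, 60, 82, 100}% from mixing a
fully intact with a fully fragmented, symmetric-partial stock; 12
dilutions at {8, 16, 31, 63, 125, 250, 500, 1000, 2000, 3000, 4000,
5000} copies/µL; 2 replicates) and an rAAV study (a heterogeneous
84%-intact stock mixed with a 0%-intact, 5'-only stock to
{0, 5, 10, 21, 42, 63, 84}%; 4 dilutions geometrically spaced over
62–498 copies/µL, i.e. {62, 124, 249, 498}; 6 replicate experiments).
The partial split of the heterogeneous stock is a free parameter
(default 0.5); expected integrities depend only on the intact
fractions. Wells are simulated at exactly the nominal concentration —
no pipetting-error model — so the simulator exercises estimator
behaviour, not laboratory variability: passing simulation-based checks
demonstrates correctness of the statistical inversion, not robustness
to amplification bias, droplet-volume variation, rain/ambiguous
droplets, or cross-channel bleed, none of which are modelled.

## Validation arithmetic

Per sample: the per-dilution means across replicates form the
dilution-series estimates; their mean, RSD (sample standard deviation,
n−1 denominator — the convention of validation statistics; the
population-SD alternative would shrink RSDs by √((n−1)/n)), and
recovery (100 × mean/expected) are flagged against the pre-defined
acceptance criteria RSD < 20% and recovery 80–120%. Per (sample,
replicate): the replicate-average recovery feeds overall accuracy
(grand mean) and intermediate precision (RSD of those recoveries).
Samples with 0% expected integrity have undefined recovery, are marked
NC, and are excluded from the accuracy/precision footer.

Linearity of calculated vs expected integrity is fit by feasible
generalized least squares: OLS first, then a compound-symmetry
correlation (observations sharing an experimental-replicate label are
equicorrelated) with the correlation estimated from residual
cross-products, clipped to [0, 0.99]. Independence reduces to OLS.
The reported pseudo-R² is 1 − RSS/TSS on the observation scale; other
definitions (likelihood-ratio based) exist but this one is
scale-interpretable and reduces to ordinary R² under independence.
The compound-symmetry choice is an assumption, not an identity — any
structure that models shared per-experiment shifts would serve.

## Numerical choices and degenerate inputs

* Bisection rather than a generic polynomial solver: monotonicity
  guarantees bracketing convergence and avoids complex roots; 200
  iterations of interval halving reach the 1e-12 tolerance with margin.
* A single-positive fraction exactly at the feasibility bound
  `1 − e^{−λ}` maps to `p = 1` (an all-one-species population); a few
  ulps of slack absorb roundoff in exactly-at-the-bound inputs.
  Fractions beyond that raise an infeasibility error.
* Zero negative droplets raise a saturation error (concentration above
  the dynamic range); per-channel saturation names the channel.
* Count containers accept non-negative reals so that exact expected
  counts can be pushed through the estimators when verifying
  identities; instrument data are integers.
* Presentation rounds integrity to 1 decimal place; all internal
  computation is full precision, and annotated CSVs carry both a
  rounded and a full-precision column.

## Problem sizes

The simulation-based checks run the full plasmid design (192 wells of
20,000 droplets), a 1e6-droplet well for the consistency check, and
2e6-droplet wells for frequency checks — all complete in seconds. The
acceptance script runs the complete plasmid study (168 nonzero-integrity
wells after excluding the 0% sample, whose recovery is undefined).

## Known limitations

* Integrity uncertainty intervals are not computed.
* Only duplex (two-target) assays are modelled; no higher-order
  multiplexing.
* The simulator does not model upstream droplet gating/thresholding;
  category counts are taken as given.
* The GLS pseudo-R² and the compound-symmetry structure are
  conventions; alternatives would give slightly different linearity
  summaries.
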