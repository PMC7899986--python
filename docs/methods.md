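# Methods

## Colour-vision model

**Spectra.** All curves live on the 300–650 nm window, the range over
which the flower reflectances were measured at 10 nm resolution; every
integral uses the trapezoidal rule on that 10 nm grid. Negative
reflectance readings (instrument noise around dark samples) are clipped
to 0 on input with a warning; values above 1 are retained, since a glossy
petal can exceed a pressed-powder white standard.

**Illuminant.** Midday open-sky illumination is represented by the CIE
D65 relative spectral power distribution (canonical 10 nm table, shipped
as packaged data), converted to relative photon flux by multiplying each
value by its wavelength — receptors count photons, not energy — and
normalized to 1 at 550 nm. Physical constants are dropped because they
cancel in the von Kries ratio.

**Receptor sensitivities.** The honeybee UV/B/G curves are built from a
rhodopsin (A1) absorbance template parameterized only by λmax
(Govardovskii-style α band in x = λmax/λ plus a Gaussian β band), with
defaults λmax = 344, 436, 544 nm. A template was chosen over digitized
measured curves so the package is reproducible from a formula; λmax is
configurable because the exact curves used in any given study are rarely
recoverable. Each curve is tabulated at 1 nm and normalized to exactly 1
at its λmax.

**Adaptation and the hexagon.** Quantum catches are normalized by the
catch from a flat 10% reflectance achromatic background (von Kries
adaptation), so the background itself always yields P = 1, E = P/(P+1) =
0.5, and the hexagon origin — this fixed point is asserted end-to-end in
the tests. Hexagon coordinates follow the standard layout (UV lower-left,
G lower-right, B top): x = (√3/2)(E_G − E_UV), y = E_B − (E_UV + E_G)/2.
Green contrast is defined as |E_G − 0.5|; the recorded contrast tables
are consistent with this definition but were not printed with a formula.

**Recorded colour data as fixtures.** The per-sample contrasts and the
21-pair distance/probability matrix are consumed as stored records: the
raw spectra behind them were published only as figure curves, so the
pipeline never claims to regenerate them. Their mutual consistency is
tested instead (|c_a − c_b| ≤ d(a,b) ≤ c_a + c_b against the background
origin, with a 0.005 slack for 3-d.p. rounding of the published values).
The two tables disagree on the category labels of orchids 5 and 6; the
package keys everything on sample/part labels and carries category
metadata verbatim without reconciliation.

## Psychometric discrimination function

The published curve's parameters live in prior experimental work and are
not printed, so the package calibrates its own: a four-parameter logistic
reduced to three by pinning the lower asymptote at 0.5, chance level
under absolute conditioning:

    P(d) = 0.5 + (A − 0.5) / (1 + exp(−(d − d0)/s))

Least squares (scipy `curve_fit`, bounded: A ∈ [0.5, 1], d0, s > 0) from
5 jittered restarts under a fixed seed; the best-RMSE fit is kept. On the
packaged 21-pair calibration this converges to A = 0.8415, d0 = 0.0856,
s = 0.0071 with RMSE 0.0056, well under the 0.02 acceptance bound, and
its above/below-0.70 verdict agrees with the recorded probability for
every calibration pair. A fit whose asymptote collapses to chance, or
whose curve is flat over the calibration range, is flagged `degenerate`.
The discrimination threshold is strict (> 0.70, "exceeds"), and class
fractions are reported as whole percents, matching the conventions of the
field reports this reproduces.

Comparison classes: sepal–sepal and labellum–labellum between different
flowers, sepal-vs-labellum within a flower, sepal-vs-labellum across
flowers. Same-part pairs within one flower (replicate measurements) are
excluded.

## Reproductive statistics

- **χ² family.** Pearson χ², *no* Yates continuity correction — required
  to reproduce the published statistics (22.0, 7.8, 4.460, 19.346, 17.8).
  Expected-count-below-5 situations warn but do not block, since the
  source tables violate the rule themselves. Note the per-patch fruit
  goodness-of-fit (χ² = 17.8, df = 4) has an exact p of 0.0013; the
  source rounded this to "< 0.001".
- **`chisq_on_values`.** Σ(v − v̄)²/v̄ applied to percentage-success
  values reproduces a published statistic (8.6 from the printed 1-d.p.
  percentages) but is not a valid count-based test; it emits a
  methodological warning on every call.
- **Association measures** use standard definitions (V² = χ²/(N·(min(r,c)−1));
  Pearson on raw codes; Spearman on midranks; τ-b with tie correction;
  Goodman–Kruskal τ as proportional reduction in error predicting outcome
  from code) and are verified against a brute-force oracle that
  enumerates all small 2×2 tables and recomputes each definition from
  first principles. The association values printed in the original field
  report could not be reconstructed from the published margins under any
  ordering tried and are not asserted.
- **Success rates** report both conventions found in field tables: the
  pooled percentage (100·Σfruits/Σflowers) and the mean of yearly
  percentages ± SE (sd/√n years; for two years this equals the
  half-range).
- **Capsule summaries** exclude grazed/moldy/lost crosses from per-cell
  denominators but count the overall rate over all crosses performed (the
  convention of the source summary). The published per-cell percentages
  imply 71 capsules while the text says 70 of 91; the packaged cross
  fixture follows the per-cell table and its file documents that the
  allocation of failed crosses to cells is synthetic.

**Records fixtures.** The packaged tagged-plant records are expanded from
the published count tables. Only the category and patch *margins* were
published, never their joint distribution, so the expander fills the
joint table with a deterministic northwest-corner rule. Every statistic
the package computes from these records depends only on the margins;
joint category×patch statistics must not be read off the expansion.

## Marker and sequence diversity

- **Dominant markers.** Band frequency f per locus; null-allele
  q = √(1 − f) under HWE (the square-root estimator; Lynch–Milligan bias
  correction is out of scope). H_e = 2pq, N_e = 1/(p² + q²),
  I = −(p ln p + q ln q) with 0·ln 0 = 0, uH_e = H_e·2N/(2N − 1); means
  ± SE over loci.
- **AMOVA φ_PT.** Two-level (within/among populations) on squared
  Euclidean band-vector distances (= band-difference counts for 0/1
  data). SS from pairwise distances, df among = k − 1, df within = N − k,
  variance components by the standard moment estimators with
  n0 = (N − Σn_i²/N)/(k − 1); φ_PT = σ²_among/(σ²_among + σ²_within),
  not truncated at 0. Permutation p = (#{φ_perm ≥ φ_obs} + 1)/(n + 1)
  with 999 label permutations by default, seeded.
- **Jukes–Cantor.** d = −(3/4)·ln(1 − (4/3)·p̂) with p̂ from
  pairwise-deleted sites (complete deletion by flag); p̂ ≥ 0.75
  (saturation) and zero-overlap pairs are reported as NaN rather than
  guessed.
- **Diversity partition.** d_S = mean of within-group mean distances,
  d_T = mean over all pairs, coefficient = (d_T − d_S)/d_T (Nei-style;
  no formula was published for the original coefficient). SE by
  bootstrapping alignment sites (default 500 replicates, seeded) when
  the alignment is available.

## Synthetic generators

The generators' defaults are the observed study conditions, fixed once:
category probabilities (0.21, 0.26, 0.30, 0.15, 0.08); patch
probabilities = the monitored-cohort flower distribution (35, 24, 10, 16,
49)/134; per-patch fruiting probabilities (11/35, 6/24, 1/10, 1/16,
2/49), which pool to the observed 15.7% fruit set. Spectra are baseline +
sigmoid long-pass edge (~400 nm, the UV-absorbing yellow-green tepal
signature) + Gaussian red/UV bumps + Gaussian noise, clipped to [0, 1.2].

The marker generator's calibration is analytic: individuals are
Bernoulli(p_pop) draws, so the within-population variance component is
E[p(1−p)] = p̄(1−p̄) − Var(p) and the total is exactly p̄(1−p̄); drawing
population frequencies with Var(p) = t·p̄(1−p̄) therefore gives expected
φ_PT = t. Clipping to [0.01, 0.99] makes the mapping approximate at
extreme frequencies; recovery of a 0.085 target to ±0.03 over 20 matrices
(2 populations × 30 individuals, 100 loci, 999 permutations) is asserted
in the tests. Alignments evolve under JC on a star topology: tip branches
d_within/2, root-to-group branches (d_between − d_within)/2, so expected
tip-to-tip distances equal the targets; JC-estimator recovery at length
10,000 is asserted to ±0.01 of a 0.10 target.

What the generators do **not** emulate: spatial autocorrelation of
patches, year effects beyond independent draws, linkage between loci,
rate variation across sites, indels. Passing recovery tests therefore
shows estimator correctness under the stated model, not robustness to
real-data violations of it.

## Problem sizes and determinism

All fixture-based reproductions are desk-scale (< 1 s each). Simulation
tests use 2×30 individuals × 100 loci for AMOVA recovery, alignments of
10,000 sites for distance recovery, and 10,000 plant-years for rate
recovery — sizes at which the binomial/moment noise is comfortably inside
the asserted tolerances. Every stochastic stage (fit restarts, AMOVA
permutations, bootstrap, generators) draws from `numpy.random.default_rng`
with an explicit seed, and rerunning the pipeline with the same config
produces byte-identical output tables (asserted in the CLI tests).

## Known limitations

- The hexagon model is a trichromat model; no receptor-noise (ΔS) space,
  no tetrachromats, no illuminant estimation.
- The psychometric calibration is a reconstruction from 21 published
  pairs, not the original authors' fitted function; its parameters should
  be re-fit for any other observer or conditioning regime.
- Dominant-marker allele frequencies assume HWE within populations.
- Two-level AMOVA only; no hierarchical (region/population) designs.
- `chisq_on_values` exists for comparability with historical reports and
  should not be used for inference.
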