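# polmorph

Analysis toolkit for colour-polymorphic, deceptively pollinated orchid
populations. It was built around the conservation question posed by the
Tawny Spider-orchid (*Caladenia fulva*) at Deep Lead, Victoria — a small
endangered population with five flower-colour categories, no confirmed
pollinator, and a recovery plan that needs to know whether the colour
variants differ in pollination success, whether a hymenopteran pollinator
could even tell them apart, and whether they are genetically one
interbreeding population.

The package bundles the three computational strands such a study needs,
each usable on its own data or on built-in synthetic generators:

1. **Bee colour vision** (`polmorph.spectra`, `polmorph.hexagon`,
   `polmorph.discrimination`). Flower reflectance spectra R(λ) on
   300–650 nm are combined with a D65 photon-flux illuminant I(λ) and
   honeybee UV/B/G sensitivity curves S_i(λ) (rhodopsin template, λmax
   344/436/544 nm) into von Kries-adapted quantum catches

       P_i = ∫ I S_i R dλ / ∫ I S_i R_b dλ

   against a 10% achromatic background R_b, then into hexagon excitations
   E_i = P_i/(P_i+1) and loci x = (√3/2)(E_G − E_UV),
   y = E_B − (E_UV + E_G)/2. Colour contrast is distance from the origin,
   green contrast |E_G − 0.5|. A logistic psychometric function
   P(d) = 0.5 + (A − 0.5)/(1 + e^−(d−d0)/s), calibrated on recorded
   (distance, probability) pairs, classifies pairs of colours against the
   70% discrimination threshold.

2. **Reproductive success** (`polmorph.repro`). Contingency-table χ²
   (Pearson, no continuity correction), goodness-of-fit tests, OLS
   regression of fruit number on flower number, association measures
   (Cramér's V², Pearson r, Spearman ρ, Kendall τ-b, Goodman–Kruskal τ),
   fruiting success rates with per-year SEs, Kruskal–Wallis tests on seed
   viability, and capsule-formation summaries for artificial crosses.

3. **Molecular diversity** (`polmorph.markers`). Dominant-marker (ISSR)
   allele frequencies under HWE (q = √(1 − band frequency)), per-locus
   N_e, I, H_e, uH_e, two-level AMOVA φ_PT with a label-permutation test,
   Jukes–Cantor sequence distances with pairwise deletion, and
   within/among-group diversity with a Nei-style coefficient of
   differentiation (d_T − d_S)/d_T.

`polmorph.datasets` ships the published field summaries (flowering and
fruiting count tables, colour contrasts, the 21-pair discrimination
calibration) as machine-readable fixtures; `polmorph.synthetic` generates
flower-like spectra, multi-year plant records, marker matrices with a
controlled φ_PT, and JC-evolved alignments.

## Worked example

```sh
$ polmorph vision --out out/
psychometric fit: A=0.8415 d0=0.0856 s=0.0071 rmse=0.0056
threshold summaries (packaged calibration distances, theta=0.7):
  sepal-sepal: 2/3 above = 67%
  labellum-labellum: 4/6 above = 67%
  within-flower: 2/3 above = 67%
  cross-flower: 7/9 above = 78%
```

The fitted curve rises from chance (0.5) to an asymptote of 0.84 around a
hexagon distance of 0.086 — i.e. a bee discriminates two flower colours
reliably once their loci are ≳0.09 hexagon units apart. Two thirds of
sepal pairs and labellum pairs from different plants, and 78% of
sepal-vs-labellum comparisons across plants, exceed the 70% threshold:
the colour variation used to classify flowers by eye is usually visible
to a hymenopteran pollinator too.

```sh
$ polmorph repro --out out/
category x year heterogeneity: chi2=22.0 df=8 p=0.005
category regression: fruits = 0.2119 x flowers + -1.4783 (R^2 = 0.9562)
patch regression: fruits = 0.0933 x flowers + 1.6996 (R^2 = 0.1125)
overall fruiting success: 15.7%
...
```

Fruit number tracks flower number closely across colour categories
(R² = 0.96: no category is disproportionately successful) but not across
patches (R² = 0.11: where a plant grows matters more than what colour it
is). Overall natural fruit set is 15.7% (21 of 134 plants).

Other subcommands: `polmorph markers --matrix FILE --perms 999 --seed 1`,
`polmorph seqdist --fasta FILE`, `polmorph simulate
spectra|records|markers|sequences --seed N --out DIR`, and `polmorph all
--config run.yaml` for the full pipeline with a hashed, rerun-identical
report bundle.

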