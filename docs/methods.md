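# Methods

## Scope and model

`seedwebs` infers weighted bipartite food webs between weed-seed genera and
carabid ground-beetle species from ecological census data plus body-size
traits. The core assumption is frequency-dependent prey selection without
switching: a carabid's diet composition is proportional to each seed's risk
index times its availability, and the risk index r = E/h (per-item energy
over a per-item interaction-cost index) is independent of density. h lumps
handling time, innate preference and any other cost into one quantity, so
it is comparable only within a single feeding experiment — the reason the
cost regression carries a study intercept.

The inference chain per field is deterministic given the inputs:

1. **Traits.** Carabid body length = geometric mean of the reported
   min/max (mm); dry mass from ln M = −3.4 + 2.6 ln L (mg). Feeding guild
   from taxonomy: Harpalini and Zabrini → granivore; Sphodrini, Trechini
   and the genera *Pterostichus*, *Poecilus*, *Agonum* → omnivore; all
   others → carnivore (a total function; an explicit override table wins
   over the rule because taxonomic authorities differ). Seeds are
   aggregated to genus (counts summed, trait values an unweighted mean
   over member species); genera without an energy value get the
   cross-genus mean 18.77 kJ/g.
2. **Densities.** Seed density D_i is the season-summed viable seed-rain
   count — a relative density; every downstream quantity that normalizes
   over D is invariant to a common scale factor (asserted by property
   tests). Pitfall counts are activity-densities; D_j = n_j·M_j^β with
   β = −0.51 (single trap, 21 °C) removes the body-size component of
   activity. β is configurable within the published temperature range
   [−0.55, −0.45]; values outside require an explicit override flag.
3. **Costs and risk.** ln h from the regression below; r = E_i/h.
4. **Diet.** F_ij normalizes r·D over the seed taxa present in the field
   with D_i > 0 (bottom-up assumption: seeds absent from the field never
   enter a diet). The daily requirement E_j = guild rate × M_j uses the
   literature rates 0.51 / 0.18 / 0.00 mg seed per mg body mass per day.
   C_ij = F_ij·E_j / Σ_i(F_ij·E_i) converts the budget into seed counts
   and conserves it exactly: Σ_i C_ij·E_i = E_j.
5. **Web.** I_ij = C_ij·D_j; P_i = Σ_j I_ij / D_i. Carabids whose diet is
   empty are dropped from the matrix (logged); webs with no seeds, no
   carabids or no positive flow are flagged empty and excluded from
   summaries.

## The interaction-cost regression

Response: ln h derived from cafeteria data via h = E_i/x_i, with
x_i = 0.5·(seeds offered)/CT50 where only half-removal times are
published. Design: intercept, M_i^⅓, ln M_j and their product. Case
weights w = M_i^−1/3 damp the influence of the few very large seeds.
Defaults are the published estimates (−14.2177, 8.739, 1.720, −1.278),
stored at full precision and never rounded before exponentiation.

The study effect defaults to a random intercept. Because the standard
mixed-model routines available do not accept case weights, the weighted
random-intercept fit is a profiled REML generalized least squares written
here directly: per study block V = diag(1/w) + λ11ᵀ, inverted by the
Woodbury identity; the REML criterion is minimized over ln λ by bounded
scalar search; study offsets are the usual shrinkage predictions
λ·1ᵀV⁻¹r. The unweighted case is cross-checked against an independent
mixed-model implementation in the test suite. With one study, or if the
scalar search fails, the fit degrades to fixed sum-to-zero study
intercepts (or no study term) with a logged warning. Reported standard
errors are plug-in (λ treated as known), the usual REML convention;
simulation shows 95% CI coverage of 0.90–0.96 for all four coefficients
at 3 studies × 40 records.

Predictions for seed masses above 8.9 mg — the largest seed in the source
trials — are allowed but raise an `ExtrapolationWarning` (threshold
configurable).

Two notational readings of the diet-frequency denominator circulate (sum
over seeds vs sum over consumers); the per-carabid normalization (sum over
seeds i for each j) is implemented, matching the verbal definition
"proportion in the diet per carabid species."

## Units and the two intake modes

The feeding rates are mass-based while the risk index is energy-based, so
the C_ij denominator admits two dimensionally consistent readings. In
`energy` mode (default) the chain runs in kJ: E_j = rate·M_j·ē/1000 with ē
a reference energy density, by default the fixed 18.77 kJ/g (chosen for
cross-field comparability; a flag switches to the field's
abundance-weighted mean), and per-seed values are E_i. In `mass` mode the
chain runs in mg (per-seed value M_i, E_j = rate·M_j) and needs no energy
data. Both conserve their own budget; the mode is recorded in outputs.
With a single seed taxon the modes coincide (the density cancels), which
the single-link oracle test exploits. All rates are per day; season totals
are a user-side multiplication, never applied implicitly.

## Network metrics

No single definition of weighted connectance is universal, so the
flow-entropy (effective-links) form is used: for flow matrix b,
H_N = exp(Σ_j (b·j/b··)·H(column j)) is the flow-weighted effective number
of resources per consumer, H_P the analogue over rows; linkage density
LD = (H_N + H_P)/2 and C_w = LD/S. Binary connectance (links/possible
links) is always reported alongside so users can recompute against other
conventions. Carnivores are excluded from S by default — they cannot hold
seed links and would deflate C_w artifactually — with a config flag to
retain them; the reported `network_size` always counts all census taxa.
A single-link web has C_w = 1/2. An all-zero matrix has no defined
connectance and raises.

## Synthetic data

The generator emulates a multi-field arable survey: per-field Bernoulli
occupancy from regional species pools, log-normal abundances rounded to
integers with floor 1, log-normal seed masses (median ≈ 0.6 mg, σ = 1 on
the log scale, spanning roughly 0.05–10 mg), carabid lengths (median
≈ 7.8 mm → masses ≈ 2–40 mg), energy densities centred on 18.77 kJ/g with
25% missing, and a 0.30/0.40/0.30 granivore/omnivore/carnivore guild mix.
Pool sizes (30 seed genera, 40 carabid species) and occupancies (0.28,
0.22) put the median per-field network size near 17 nodes, the scale of
real arable assemblages. Cafeteria data are generated by inverting the
cost model: ln h = prediction + study offset (N(0, 0.5²) across studies)
+ N(0, 0.3²) noise, x = E/h, defaults 3 studies × 40 records.

All randomness flows through numpy PCG64 generators keyed on
(rng_seed, purpose tag, field index), so every artefact is reproducible
from a single integer and fields are independent of how many are drawn.

What the generator does **not** emulate: spatial trap layout, seasonality,
crop-type covariates, abundance–trait correlations, and taxonomic
structure in who co-occurs. Passing tests therefore demonstrate internal
correctness and qualitative behaviour (e.g. smaller seeds attract higher
predation pressure), not field-data realism.

## Numerical choices and limitations

- Floats in CSV outputs use 9 significant digits; reruns are
  byte-identical. The run manifest records config, input SHA-256 digests,
  package version, seed and warnings (its timestamp is the one
  intentionally non-reproducible field).
- Diet normalization tolerance 1e-12 and energy-budget closure 1e-9
  (relative) are asserted, not enforced — the algebra is exact up to
  floating point.
- The cube root is the real root of a positive mass; masses are validated
  positive at the boundary.
- Problem sizes in the test and acceptance runs (200 synthetic fields, 200
  recovery replicates, 1,000 random diets) were chosen as the package's
  own simulation scale; they complete in seconds.
- Limitations: no prey switching or density-dependent risk, no
  invertebrate alternate prey, no intraguild interference, genus-level
  seeds only, and the printed cost-model coefficients are taken as
  authoritative since the digitized source trials are not shipped.
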