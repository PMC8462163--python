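# seedwebs

Quantitative (weighted) ecological networks need interaction strengths, but
predation events — a ground beetle eating a weed seed at the soil surface —
are brief, cryptic and rarely sampled. `seedwebs` infers weighted bipartite
seed–carabid food webs from data that *are* routinely collected: seed-rain
counts, pitfall-trap counts, and body-size traits. It is aimed at
agroecologists and network ecologists who have census data but no direct
feeding observations.

## The model

For seed taxon *i* (dry mass *M_i* mg, per-seed energy *E_i* kJ) and carabid
species *j* (dry mass *M_j* mg from the length allometry
ln *M_j* = −3.4 + 2.6 ln *L*), a per-individual **interaction cost index**
*h_ij* — handling time, innate preference and other costs lumped together —
is predicted from a regression fitted to published cafeteria (seed-choice)
experiments:

```
ln h_ij = −14.2177 + 8.739·M_i^⅓ + 1.720·ln M_j − 1.278·M_i^⅓·ln M_j
```

The chain to a web is then:

| quantity | formula | meaning |
|---|---|---|
| risk index | *r_ij* = *E_i* / *h_ij* | per-item profitability |
| diet frequency | *F_ij* = *r_ij·D_i* / Σ_i *r_ij·D_i* | frequency-dependent prey choice, no switching |
| intake | *C_ij* = *F_ij·E_j* / Σ_i(*F_ij·E_i*) | seeds eaten per individual per day; *E_j* = guild rate × *M_j* with rates 0.51 (granivore), 0.18 (omnivore), 0.00 (carnivore) mg·mg⁻¹·day⁻¹ |
| interaction strength | *I_ij* = *C_ij·D_j* | population-level flow; *D_j* = *n_j·M_j*^−0.51 corrects pitfall activity-density |
| predation pressure | *P_i* = Σ_j *I_ij* / *D_i* | expected per-seed predation intensity |

Webs get quantitative (flow-entropy) and binary connectance metrics. The
cost regression can be re-fitted from new cafeteria data
(`InteractionCostModel.fit()`, weighted by 1/*M_i*^⅓ with the source study
as a random intercept), and a synthetic-data module generates censuses,
trait tables and cafeteria trials with known ground truth.

## Worked example

```python
import seedwebs as sw
from seedwebs.synth import fixture_community

seed_traits, carabid_traits, census = fixture_community()
web = sw.build_web(census,
                   sw.build_seed_table(seed_traits),
                   sw.build_carabid_table(carabid_traits))
print(web.I.round(3))
print(web.P.round(4))
print({k: round(v, 3) for k, v in web.metrics.items()})
```

prints

```
carabid      Harpalus rufipes  Nebria brevicollis  Pterostichus melanarius
seed
Chenopodium            18.673                 0.0                    5.084
Poa                    49.871                 0.0                   12.606
Viciafaba               0.544                 0.0                    0.188
seed
Chenopodium    0.1980
Poa            0.2083
Viciafaba      0.0488
dtype: float64
{'network_size': 6, 'weighted_connectance': 0.354, 'binary_connectance': 1.0, 'total_flow': 86.966}
```

The granivore (Harpalus) carries the largest flows and the carnivore
(Nebria) none; the small, per-item-cheap seeds (Poa at 0.3 mg, Chenopodium
at 0.7 mg) absorb far more predation per seed (P ≈ 0.20/day) than the
4 mg Vicia (P ≈ 0.05/day).

The same pipeline is scriptable from the shell:

```
seedwebs fixtures --out demo/in
seedwebs infer demo/in/census.csv demo/in/seed_traits.csv demo/in/carabid_traits.csv --out demo/out
seedwebs simulate --seed 42 --out demo/synth      # synthetic survey + cafeteria data
seedwebs fit-cost demo/synth/cafeteria.csv --out demo/coefs.yaml
```

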