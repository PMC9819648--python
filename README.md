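# parkaccess

Spatial-accessibility modelling of urban parks with floating catchment
area (FCA) methods, for health-geography and urban-planning analyses of
how fairly green space is distributed across a city.

The core is the two-step floating catchment area family with three
extensions applied on top of each other:

1. **2SFCA** — each park *j* gets a supply–demand ratio over the
   residential areas *k* inside its travel-cost catchment (threshold
   *t₀*), then each residential area *i* sums the ratios of the parks it
   can reach:

   R_j = S_j / Σ_{k: t_kj ≤ t₀} D_k,  A_i = Σ_{j: t_ij ≤ t₀} R_j

   with S the park size and D the population.

2. **Gaussian decay (G2SFCA)** — all-or-nothing catchment membership is
   replaced by a truncated Gaussian kernel

   G(t) = (e^{−(1/2)(t/t₀)²} − e^{−1/2}) / (1 − e^{−1/2}),  t ≤ t₀

   (0 beyond t₀), so nearby parks count more than barely reachable ones.

3. **Supply competition and mode compositing (SCM-G2SFCA)** — a park
   quality score W_j (e.g. a 0–5 crowd-sourced rating) multiplies the
   capacity in step 1, expressing competition between more and less
   attractive parks; the two catchment steps run once per travel mode
   (driving, public transport, riding, walking) on mode-specific
   travel-time matrices, and the composite accessibility is the
   share-weighted sum A_i = Σ_n W_{Mn} · A_{i,Mn} over the daily
   travel-mode split.

Downstream, the package aggregates accessibility to administrative zones
by population-weighted means and classifies spatial clusters with local
Moran's I (LISA: HH/LL clusters, HL/LH outliers, permutation inference).
A seeded synthetic-city generator produces complete test scenarios — 902
residential areas, 31 parks with a deliberately south-skewed park layout,
17 zones, four calibrated mode speed models — so the whole pipeline runs
end-to-end without any proprietary navigation data.

## Worked example

```python
from parkaccess import (
    DecaySpec, ModeMix, ScenarioConfig,
    generate_city, generate_mode_costs, run_scm_g2sfca,
    build_weights, local_moran,
)

city = generate_city(ScenarioConfig(seed=42))
costs = generate_mode_costs(city)                      # 4 OD time matrices
result = run_scm_g2sfca(
    city.demand, city.supply, costs,
    DecaySpec(kind="gaussian", threshold=39.0),        # 39-minute catchment
    ModeMix.default(),                                 # 25.7/43.2/8.6/22.5 %
)
A = result.combined.values                             # per-site accessibility
print(round(A.min(), 2), round(A.max(), 2), round(A.mean(), 2))

w = build_weights(city.demand, scheme="knn", k=8)
lisa = local_moran(A, w, n_perm=999, seed=7)
print(lisa.counts().to_dict())
```

prints

```
1.57 23.08 7.24
{'not significant': 535, 'HH': 185, 'LL': 181, 'LH': 1}
```

The combined accessibility (park capacity × quality per decay-weighted
resident, summed over reachable parks and averaged over travel modes)
ranges from 1.57 to 23.08 across the 902 synthetic residential areas.
The LISA classification finds a large HH cluster (high-accessibility
sites surrounded by high ones) in the park-rich south of the city and an
LL cluster in the park-poor north — the equity gradient the generator is
designed to emulate.

The same pipeline is scriptable from the shell:

```sh
parkaccess simulate --seed 42 --out city/
parkaccess compute --demand city/demand.csv --supply city/supply.csv \
    --od city/od_driving.csv --od city/od_transit.csv \
    --od city/od_riding.csv --od city/od_walking.csv \
    --out-access access.csv --out-ratios ratios.csv
parkaccess aggregate --demand city/demand.csv --access access.csv --out zones.csv
parkaccess lisa --demand city/demand.csv --access access.csv --seed 7 --out lisa.csv
```

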