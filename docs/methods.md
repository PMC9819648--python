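# Methods

## Model

The package computes place-based spatial accessibility of urban parks
with the two-step floating catchment area (2SFCA) family. Both steps use
the same travel-cost threshold t₀ and the same decay kernel G:

* step 1 (per park j): R_j = S_j·W_j / Σ_{k: t_kj ≤ t₀} D_k·G(t_kj) —
  quality-weighted capacity per decay-weighted resident in the park's
  catchment;
* step 2 (per residential area i): A_i = Σ_{j: t_ij ≤ t₀} R_j·G(t_ij).

Kernels: `gaussian`, the truncated Gaussian
G(t) = (e^{−(1/2)(t/t₀)²} − e^{−1/2})/(1 − e^{−1/2}) with G(0)=1 and
G(t₀)=0, continuous and strictly decreasing on [0, t₀]; or `indicator`,
plain catchment membership (1 iff t ≤ t₀, boundary inclusive). With the
indicator kernel and W_j ≡ 1 the model reduces exactly to the classic
2SFCA; with the Gaussian kernel and W_j ≡ 1 it is the standard G2SFCA.

The multimodal composite runs both steps independently per travel mode
on that mode's origin–destination time matrix and combines per-mode
fields convexly: A_i = Σ_n W_{Mn}·A_{i,Mn}, where W_{Mn} are daily-trip
shares. The default split is the Chengdu main-urban-area survey split —
driving 25.7%, public transport 43.2%, riding 8.6%, walking 22.5%.

Model assumptions worth keeping in mind: demand is fixed at residential
centroids (no trip chaining, no demand elasticity); supply capacity is
the park area times a raw quality score; each mode's accessibility is
computed as if all trips used that mode, and the composite mixes fields,
not route choices per trip.

### Identities the implementation guarantees

* Conservation: when every park's catchment contains positive
  decay-weighted population, Σ_i D_i·A_i = Σ_j S_j·W_j exactly (the
  decay terms cancel between the two steps). Checked to 1e-9 relative
  in the tests.
* Homogeneity: scaling all W_j by c scales every A_i by c; scaling all
  D_k by c scales every A_i by 1/c. Because of this, quality scores are
  used raw: any normalization is a transparent global rescaling, and a
  min–max rescaling option belongs in user preprocessing, not the engine.
* A demand site with no reachable park gets A_i exactly 0; a park with
  an empty catchment gets R_j = 0 (with a logged warning) rather than a
  division error, so isolated parks contribute nothing.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| threshold t₀ | 39 | min | average daily travel time reported for Chengdu |
| decay kind | gaussian | — | smooth within-catchment differentiation |
| mode shares | 25.7/43.2/8.6/22.5 | % | Chengdu daily-travel mode split |
| use_weights | on | — | quality-weighted supply competition is the point of the model |
| walking speed | 4.154 | km/h | calibrated so 2.7 km ≈ 39 min |
| riding speed | 10.77 | km/h | calibrated so 7 km ≈ 39 min |
| driving speed | 30 | km/h | urban average; covers the 13×10 km extent inside 39 min |
| transit line speed | 35 | km/h | metro/bus in-vehicle speed; access legs at walking speed |
| LISA weights | knn, k=8, row-standardized | — | standard LISA practice for point supports |
| LISA inference | 999 conditional permutations, two-tailed, α=0.05 | — | standard practice; seed required |

Mode shares are renormalized to sum to 1 at load, with a warning if they
deviate by more than 1e-6. Costs are minutes throughout (or coordinate
units for the Euclidean baseline); coordinates are planar projected
meters — the engine does no geographic (lat/lon) math.

## Travel-cost models

Real route-planned travel times are replaced by kinematic models: time =
fixed overhead + 60·d/v over the straight-line distance d. Public
transport adds corridor polylines ridden at line speed, with walk access
to the nearest point on the corridor (shapely nearest-point projection)
and the boarding overhead charged on the ride option only; each trip
takes the minimum over pure walking and the per-corridor ride options,
so transit is never slower than walking. All default overheads are 0,
which keeps the pointwise mode ordering walking ≥ riding ≥ driving exact
at all ranges. Matrices are demand→supply only; no return trips,
congestion, timetables or network shortest paths.

## Spatial statistics

Zone values are population-weighted means Σ D_i A_i / Σ D_i over each
zone's sites; a zone with zero total population is reported as missing.

Global Moran's I follows the textbook form (n/S₀)·Σ w_ij z_i z_j / Σ z²;
local Moran's I is I_i = (z_i/m₂)·Σ_j w_ij z_j with m₂ = Σz²/n, so under
row-standardized weights Σ_i I_i = n·I holds identically (verified to
1e-9). Inference is conditional permutation: site i's value stays fixed,
the other n−1 values are permuted (a single seeded table of permutations
shared across sites, applied in sorted-site_id order, making p-values
reproducible and independent of input row order), and the pseudo p-value
is (#{|I_perm| ≥ |I_obs|}+1)/(n_perm+1), which can never be exactly zero.
Significant sites are labelled by Moran-scatter quadrant (HH/LL clusters,
HL/LH outliers); constant fields are labelled entirely "not significant"
with a warning. knn ties are broken by site_id order for determinism.

## Synthetic scenario generator

The generator emulates a mid-sized Chinese urban district at study
scale: a 13×10 km extent, 902 residential areas uniform in space with
log-normal populations (median 1000, σ=0.8 — totals around 1.2 M,
census-scale), 31 parks with log-normal areas (median 5 ha, σ=1.1) and
uniform quality scores in [3.5, 5.0] on a 0–5 rating scale, 17 zones as
a rectangular 4-row grid with (4,4,4,5) columns, and 3 jittered transit
corridors crossing the extent. Its key structural feature is an uneven
park layout: parks are assigned largest-first to the southern band
(southern 40% of the extent) until that band holds 70% of total park
area. This reproduces the qualitative pattern the model family is
designed to expose — high accessibility in the south, low in the north —
and with the default configuration the south band's population-weighted
mean combined accessibility exceeds the north band's in every tested
seed, with LISA finding HH sites in the south and LL sites in the north.

What the generator does **not** emulate: real street networks and routed
travel times, census disaggregation to building footprints, true
sub-district polygon geometry, or any empirical accessibility magnitude.
Passing tests therefore demonstrate the correctness of the formulas and
the qualitative spatial behaviour, not agreement with any particular
city's measured accessibility values.

All randomness flows from one `numpy` Generator seeded by the scenario
config; identical configs give byte-identical fixture bundles.

## Numerical choices

* Accumulation order is fixed (sites sorted by id) for deterministic
  floating-point results.
* Catchment membership is boundary-inclusive (t = t₀ is inside);
  immaterial for the Gaussian kernel, observable for the indicator.
* Unreachable pairs are +inf sentinels; pairs missing from an OD file are
  read as unreachable, never as zero minutes.
* Serialized floats carry 12 significant digits, making writer/reader
  round-trips lossless to ~5e-12 relative and output files reproducible
  byte-for-byte.
* Test and acceptance problem sizes: random engine checks at ≤50×10
  sites, permutation checks at n=100 and the full 902-site default city;
  these sizes make every identity measurable at tight tolerance while
  the whole suite runs in seconds.

## Known limitations

* Fixed catchment radius: no variable/dynamic-radius variants (V2SFCA,
  D2SFCA), no Huff/3SFCA selection probabilities.
* The quality score enters linearly and raw; there is no evidence-based
  calibration of how ratings trade off against area.
* Kinematic travel times ignore congestion and network topology; the
  transit model allows at most one corridor per trip (no transfers).
* LISA p-values are pseudo p-values from conditional permutation and
  inherit the usual multiple-testing caveats across sites.
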