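"""Independent brute-force oracles used to cross-check the implementation.

These are literal double-loop transcriptions of the model formulas, written
before the vectorized engine and kept free of any package internals beyond
the plain site dataclasses.  They are intentionally slow and simple.
"""

import math

import numpy as np


def gaussian_kernel(t, t0):
    if t > t0:
        return 0.0
    e = math.exp(-0.5)
    return (math.exp(-0.5 * (t / t0) ** 2) - e) / (1.0 - e)


def indicator_kernel(t, t0):
    return 1.0 if t <= t0 else 0.0


def fca_oracle(demand, supply, cost, t0, kind="gaussian", use_weights=True):
    """Two catchment steps as explicit loops.

    ``demand``/``supply`` are site lists sorted by id; ``cost`` is the
    aligned (n_demand, n_supply) array.  Returns (R by supply id, A by
    demand id) as dicts.
    """
    g = gaussian_kernel if kind == "gaussian" else indicator_kernel
    R = {}
    for j, park in enumerate(supply):
        denom = 0.0
        for i, res in enumerate(demand):
            if cost[i, j] <= t0:
                denom += res.population * g(cost[i, j], t0)
        numer = park.supply_scale * (park.weight if use_weights else 1.0)
        R[park.site_id] = numer / denom if denom > 0 else 0.0
    A = {}
    for i, res in enumerate(demand):
        total = 0.0
        for j, park in enumerate(supply):
            if cost[i, j] <= t0:
                total += R[park.site_id] * g(cost[i, j], t0)
        A[res.site_id] = total
    return R, A


def global_moran_oracle(z, w_dense):
    """Textbook global Moran's I from a dense weight matrix."""
    z = np.asarray(z, float)
    n = len(z)
    zc = z - z.mean()
    s0 = w_dense.sum()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += w_dense[i, j] * zc[i] * zc[j]
    return n / s0 * num / (zc @ zc)


def local_moran_oracle(z, w_dense):
    """Per-site local Moran statistics from a dense weight matrix."""
    z = np.asarray(z, float)
    n = len(z)
    zc = z - z.mean()
    m2 = (zc @ zc) / n
    out = np.zeros(n)
    for i in range(n):
        lag = 0.0
        for j in range(n):
            lag += w_dense[i, j] * zc[j]
        out[i] = zc[i] / m2 * lag
    return out


def random_instance(rng, n_demand, n_supply, t0, reachable=True):
    """A random small scenario: sites plus an aligned cost matrix.

    With ``reachable`` every cost lies safely inside the threshold so all
    catchments are nonempty; otherwise ~30% of pairs fall outside it.
    """
    from parkaccess import DemandSite, SupplySite

    demand = [
        DemandSite(
            site_id=f"d{i:03d}",
            x=float(rng.uniform(0, 1000)),
            y=float(rng.uniform(0, 1000)),
            population=float(rng.uniform(10, 500)),
        )
        for i in range(n_demand)
    ]
    supply = [
        SupplySite(
            site_id=f"s{j:03d}",
            x=float(rng.uniform(0, 1000)),
            y=float(rng.uniform(0, 1000)),
            supply_scale=float(rng.uniform(1, 50)),
            weight=float(rng.uniform(0.5, 5)),
        )
        for j in range(n_supply)
    ]
    if reachable:
        cost = rng.uniform(0, 0.95 * t0, size=(n_demand, n_supply))
    else:
        cost = rng.uniform(0, 1.4 * t0, size=(n_demand, n_supply))
    return demand, supply, cost
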