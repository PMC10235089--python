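"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities with naive O(n^2) enumeration,
plain-loop statistics or direct likelihood optimization, sharing no
code with the implementation paths they check.
"""

import numpy as np
from scipy.optimize import minimize

from phenotil.cellmap import COLOR_COLS, HARALICK_STATS, MORPH_COLS


def brute_force_til_features(cell_map, radii, til_id):
    """Naive re-enumeration of the full contextual vector of one TIL."""
    cells = cell_map.cells
    me = cells[cells.cell_id == til_id].iloc[0]
    out = []
    for r in radii:
        neigh = []
        for _, row in cells.iterrows():
            if row.cell_id == til_id:
                continue
            d = np.sqrt((row.x - me.x) ** 2 + (row.y - me.y) ** 2)
            if d <= r:
                neigh.append((d, row))
        til = [(d, row) for d, row in neigh if row["class"] == "TIL"]
        non = [(d, row) for d, row in neigh if row["class"] == "nonTIL"]
        n_t, n_n = len(til), len(non)
        disc_mm2 = np.pi * r**2 * (cell_map.microns_per_pixel / 1000.0) ** 2
        out += [n_t, n_n, n_t + n_n,
                n_t / (n_t + n_n) if (n_t + n_n) else 0.0,
                n_t / disc_mm2, n_n / disc_mm2]

        def stats(vals, which):
            if not vals:
                return [0.0] * len(which)
            v = np.asarray(vals, float)
            table = {"mean": v.mean(), "std": v.std(), "min": v.min(), "max": v.max()}
            return [table[s] for s in which]

        full = ("mean", "std", "min", "max")
        for grp in (til, non):
            out += stats([d for d, _ in grp], full)
        for col in MORPH_COLS:
            for grp in (til, non):
                out += stats([row[col] for _, row in grp], full)
        for col in COLOR_COLS:
            for grp in (til, non):
                out += stats([row[col] for _, row in grp], ("mean", "std", "max"))
        for stat in HARALICK_STATS:
            for grp in (til, non):
                out += stats([row[f"har_{stat}"] for _, row in grp], ("mean",))
    return np.asarray(out)


def breslow_cox_fit(X, time, event):
    """Unpenalized Cox fit by direct Breslow partial-likelihood optimization."""
    X = np.asarray(X, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)

    def negll(beta):
        eta = X @ beta
        ll = 0.0
        for i in np.where(e == 1)[0]:
            risk = t >= t[i]
            ll += eta[i] - np.log(np.exp(eta[risk]).sum())
        return -ll

    res = minimize(negll, np.zeros(X.shape[1]), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    return res.x


def manual_logrank(t1, e1, t2, e2):
    """Observed-minus-expected log-rank chi-square, computed by hand."""
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O1 = E1 = V = 0.0
    for tt in times:
        n1 = (t1 >= tt).sum()
        n2 = (t2 >= tt).sum()
        d1 = ((t1 == tt) & (e1 == 1)).sum()
        d2 = ((t2 == tt) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        if n < 2:
            continue
        O1 += d1
        E1 += d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O1 - E1) ** 2 / V


def union_find_components(coords, radius):
    """Connected components of the radius graph via explicit union-find."""
    n = len(coords)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= radius:
                parent[find(i)] = find(j)
    return np.asarray([find(i) for i in range(n)])
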