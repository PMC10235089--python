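"""Gene expression association with TIL niches and gene-set enrichment.

Genes are correlated (Pearson) with per-patient niche counts and with
the survival risk score; "activation genes" for a target are those
whose absolute correlation exceeds half the maximum absolute
correlation over genes.  Selected genes are tested for
over-representation in user-supplied gene sets (GMT format) with a
one-sided hypergeometric test and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def correlate_expression(expr: pd.DataFrame, targets: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of every gene against every target column.

    Parameters
    ----------
    expr
        Genes x patients expression matrix.
    targets
        Patients x targets (e.g. the 8 niche counts plus the OSRS);
        patient order must match ``expr`` columns.

    Returns
    -------
    (r, missing)
        ``r``: genes x targets correlation matrix; entries where the
        gene or the target has zero variance are NaN and marked True in
        the boolean ``missing`` frame.
    """
    if expr.shape[1] != targets.shape[0]:
        raise ValueError("expr columns and target rows must align (patients)")
    X = expr.to_numpy(float)
    Y = targets.to_numpy(float)
    xs = X.std(axis=1)
    ys = Y.std(axis=0)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    n = X.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Yc) / (n * np.outer(xs, ys))
    missing = np.isnan(r) | (xs[:, None] == 0) | (ys[None, :] == 0)
    r = np.where(missing, np.nan, np.clip(r, -1.0, 1.0))
    rdf = pd.DataFrame(r, index=expr.index, columns=targets.columns)
    return rdf, pd.DataFrame(missing, index=expr.index, columns=targets.columns)


def select_activation_genes(corr: pd.DataFrame) -> dict[str, list[str]]:
    """Half-of-maximum selection rule, per target.

    For each target the threshold is 0.5 times the maximum absolute
    correlation over genes; genes strictly above the threshold are
    selected (all-zero targets select nothing).
    """
    out: dict[str, list[str]] = {}
    for col in corr.columns:
        a = corr[col].abs()
        mx = a.max(skipna=True)
        if not np.isfinite(mx) or mx == 0:
            out[col] = []
            continue
        out[col] = list(corr.index[a > 0.5 * mx])
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: one tab-separated ``name<TAB>desc<TAB>genes...`` per line."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def enrich(selected: set[str] | list[str], gene_sets: dict[str, set[str]],
           universe: list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each gene set.

    The p-value is P(X >= k) for k overlap genes drawn s times from a
    universe of U genes containing m set members; q-values are
    Benjamini-Hochberg across sets.

    Returns a DataFrame sorted by p with columns gene_set, k, m, s, U,
    p, q.
    """
    uni = set(universe)
    sel = set(selected) & uni
    U, s = len(uni), len(sel)
    rows = []
    for name, genes in gene_sets.items():
        members = genes & uni
        m = len(members)
        k = len(sel & members)
        p = float(hypergeom.sf(k - 1, U, m, s)) if m else 1.0
        rows.append({"gene_set": name, "k": k, "m": m, "s": s, "U": U, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        df["q"] = []
    return df
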