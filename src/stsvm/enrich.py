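"""Hypergeometric enrichment of a signature against gene sets.

The universe defaults to the features actually present on the analysis
network/dataset, since that is the population the signature was drawn from;
callers studying array-wide enrichment can pass a larger universe.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_enrich(
    signature: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: Iterable[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of signature overlap with each gene set.

    For a universe of N features, a gene set of size m (after intersection
    with the universe) and a signature of size n, the p-value is
    P[X >= k] for the observed overlap k, X ~ Hypergeom(N, m, n).
    ``correction`` is "bonferroni" or "bh", applied over the sets tested.
    Rows are sorted by adjusted p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not signature <= universe:
        raise ValueError("signature must be a subset of the universe")
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    n_univ = len(universe)
    sig = signature & universe
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        m = len(members)
        k = len(members & sig)
        # P[X >= k]; sf(k-1) so that k = 0 gives exactly 1
        p = float(hypergeom.sf(k - 1, n_univ, m, len(sig)))
        p = min(max(p, 0.0), 1.0)
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": m,
                "signature_size": len(sig),
                "universe_size": n_univ,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["p_adj"] = []
        return df
    method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
    df["p_adj"] = multipletests(df["p"].to_numpy(), method=method)[1]
    return df.sort_values(["p_adj", "p", "set"]).reset_index(drop=True)
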