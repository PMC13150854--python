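"""Hierarchical bin-map over-representation analysis.

A bin map assigns genes to nodes of a hierarchical functional ontology
(paths like ``"metabolism.cell_wall.degradation"``). For a gene list drawn
from a universe, each bin truncated to a requested depth is tested for
over-representation with a one-sided hypergeometric upper-tail test, and
p-values are Benjamini-Hochberg adjusted across the tested bins. The choice
of test is explicit in the output (``test`` column).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = ["read_bin_map", "truncate_bins", "enrich", "top_bins"]

DELIMITER = "."


def read_bin_map(path) -> dict:
    """Read ``gene_id<TAB>bin_path`` rows into gene -> [paths]. A gene may
    map to several bins."""
    out = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
            gene, path_ = parts
            if not path_:
                raise DataError(f"{path}:{i}: empty bin path")
            out.setdefault(gene, []).append(path_)
    return out


def truncate_bins(bin_map: dict, level: int) -> dict:
    """Gene -> set of bin paths cut to ``level`` components."""
    if level < 1:
        raise DataError("bin level must be >= 1")
    return {
        g: {DELIMITER.join(p.split(DELIMITER)[:level]) for p in paths}
        for g, paths in bin_map.items()
    }


def enrich(list_genes, universe_genes, bin_map, level=2) -> pd.DataFrame:
    """Over-representation of each level-``level`` bin in ``list_genes``.

    Columns of the result: bin, k (hits in list), n (list size), K (hits in
    universe), N (universe size), p (hypergeometric upper tail,
    ``P[X >= k]``), fdr (BH-adjusted), test. Sorted by p then bin name.
    """
    universe = set(universe_genes)
    query = set(list_genes)
    stray = sorted(query - universe)
    if stray:
        raise DataError(f"genes not in universe: {stray[:10]}" +
                        (" ..." if len(stray) > 10 else ""))
    trunc = truncate_bins(bin_map, level)
    bins = {}
    for gene in universe:
        for b in trunc.get(gene, ()):
            bins.setdefault(b, set()).add(gene)
    N, n = len(universe), len(query)
    rows = []
    for b in sorted(bins):
        members = bins[b]
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"bin": b, "k": k, "n": n, "K": K, "N": N, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "bin"], kind="stable").reset_index(drop=True)
    else:
        df["fdr"] = []
    df["test"] = "hypergeometric"
    return df


def top_bins(results: pd.DataFrame, k=10) -> pd.DataFrame:
    """The ``k`` most significant bins (results are already p-sorted)."""
    return results.head(k).reset_index(drop=True)
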