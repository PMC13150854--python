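"""Subgenome binding-bias tests.

For each homoeologous chromosome group (one chromosome per subgenome), the
observed peak count per subgenome is compared with the count expected if
binding sites fell in proportion to chromosome size: the expected count of a
chromosome is the group's total peak count times its share of the group's
total length. Departure is measured with a chi-square goodness-of-fit test
(df = #subgenomes - 1). A pooled genome-wide variant aggregates all groups
by subgenome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "SubgenomeBiasResult",
    "count_peaks_by_chromosome",
    "expected_counts",
    "chi_square_bias",
    "group_bias_tests",
    "pooled_subgenome_test",
]


@dataclass(frozen=True)
class SubgenomeBiasResult:
    group: int | str
    subgenomes: tuple
    observed: tuple
    expected: tuple
    chi2: float
    df: int
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def count_peaks_by_chromosome(peaks, layout):
    """Tally peaks per (group, subgenome); exhaustive over the layout, so
    cells with no peaks are explicit zeros.

    ``peaks`` may be Peak or ReproduciblePeak objects (anything with a
    ``chrom``). A peak on a chromosome absent from the layout is an error.
    """
    counts = {(c.group, c.subgenome): 0 for c in layout}
    unknown = set()
    for p in peaks:
        if p.chrom not in layout:
            unknown.add(p.chrom)
            continue
        c = layout[p.chrom]
        counts[(c.group, c.subgenome)] += 1
    if unknown:
        raise DataError(f"peaks on unknown chromosomes: {sorted(unknown)}")
    df = pd.DataFrame(
        [(g, s, n) for (g, s), n in counts.items()],
        columns=["group", "subgenome", "observed"],
    )
    return df.sort_values(["group", "subgenome"], kind="stable").reset_index(drop=True)


def expected_counts(observed, layout, group):
    """Size-proportional expected counts for one chromosome group.

    ``observed`` maps subgenome -> count (dict or Series). Expected counts
    are real-valued and conserve the group total exactly.
    """
    chroms = layout.group_chromosomes(group)
    if not chroms:
        raise DataError(f"no chromosomes in group {group}")
    total_len = sum(c.length for c in chroms)
    if total_len <= 0:
        raise DataError(f"group {group} has zero total length")
    total_obs = float(sum(observed[c.subgenome] for c in chroms))
    return np.array([total_obs * c.length / total_len for c in chroms])


def chi_square_bias(observed, expected, group="all", subgenomes=(), alpha=0.05):
    """Goodness-of-fit chi-square of observed vs expected counts.

    chi2 = sum (O - E)^2 / E with df = k - 1; p from the chi-square survival
    function. Zero expected cells are rejected (pool categories first).
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise DataError("observed and expected must align")
    if np.any(exp <= 0):
        raise DataError("expected count of zero; pool subgenomes before testing")
    chi2, p = stats.chisquare(obs, exp)
    return SubgenomeBiasResult(
        group=group,
        subgenomes=tuple(subgenomes),
        observed=tuple(obs),
        expected=tuple(exp),
        chi2=float(chi2),
        df=obs.size - 1,
        p_value=float(p),
        alpha=alpha,
    )


def group_bias_tests(peaks, layout, alpha=0.05, bonferroni=False):
    """Run the per-group bias test over every homoeologous chromosome group.

    The tests are reported uncorrected by default; ``bonferroni=True``
    additionally multiplies p-values by the number of groups (capped at 1)
    for a family-wise view.
    """
    tab = count_peaks_by_chromosome(peaks, layout)
    results = []
    n_groups = len(layout.groups)
    for group in layout.groups:
        chroms = layout.group_chromosomes(group)
        obs = {
            r.subgenome: r.observed
            for r in tab[tab["group"] == group].itertuples()
        }
        exp = expected_counts(obs, layout, group)
        obs_vec = [obs[c.subgenome] for c in chroms]
        res = chi_square_bias(
            obs_vec, exp, group=group,
            subgenomes=[c.subgenome for c in chroms], alpha=alpha,
        )
        if bonferroni:
            res = SubgenomeBiasResult(
                group=res.group,
                subgenomes=res.subgenomes,
                observed=res.observed,
                expected=res.expected,
                chi2=res.chi2,
                df=res.df,
                p_value=min(1.0, res.p_value * n_groups),
                alpha=alpha,
            )
        results.append(res)
    return results


def pooled_subgenome_test(peaks, layout, alpha=0.05):
    """Genome-wide test: peaks pooled by subgenome across all groups,
    expected from total subgenome length."""
    tab = count_peaks_by_chromosome(peaks, layout)
    by_sub = tab.groupby("subgenome", sort=True)["observed"].sum()
    lengths = {}
    for c in layout:
        lengths[c.subgenome] = lengths.get(c.subgenome, 0) + c.length
    subs = list(by_sub.index)
    total_len = sum(lengths[s] for s in subs)
    total_obs = float(by_sub.sum())
    exp = np.array([total_obs * lengths[s] / total_len for s in subs])
    return chi_square_bias(by_sub.to_numpy(), exp, group="pooled",
                           subgenomes=subs, alpha=alpha)


def results_table(results) -> pd.DataFrame:
    """Flatten bias results to one row per (group, subgenome)."""
    rows = []
    for r in results:
        for s, o, e in zip(r.subgenomes, r.observed, r.expected):
            rows.append(
                {
                    "group": r.group,
                    "subgenome": s,
                    "observed": int(o),
                    "expected": e,
                    "chi2": r.chi2,
                    "df": r.df,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)
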