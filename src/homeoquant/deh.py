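"""Differentially expressed homeolog (DEH) calling.

A homeolog group is a DEH between two conditions iff

1. its expression changes significantly in at least one subgenome
   (FDR-adjusted q <= alpha_de, default 0.05), and
2. its homeolog expression *ratio* shifts significantly: a two-sided
   Fisher's exact test on the replicate-combined read counts has
   p < alpha_ratio (default 0.05) with fold change >= fc_min (default 2).

For three subgenomes the ratio is tested with three contrasts (A vs BD,
B vs AD, D vs AB) at the Bonferroni-corrected threshold alpha_ratio / 3.
No further FDR correction is applied to the Fisher p-values.

The per-subgenome differential-expression filter is pluggable: supply
DESeq2 (or other) q-values via ``method="external"``, or use the built-in
test — an exact conditional binomial test of condition-1 counts against the
library-size-ratio null on replicate-summed counts, Benjamini-Hochberg
adjusted across genes within each subgenome.

Fold change of the ratio shift is the symmetrized odds ratio of the 2x2
table, ``max(OR, 1/OR)``, with a Haldane 0.5 continuity correction applied
when any cell is zero (which covers zero margins and keeps the estimate
finite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(slots=True)
class DehResult:
    group_id: str
    de_qvalues: dict[str, float]
    fisher_p: dict[str, float]
    fold_change: dict[str, float]
    is_deh: bool
    contrasts: tuple[str, ...] = field(default_factory=tuple)


def _replicate_sums(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum a (sample, subgenome) count table over samples -> group x subgenome."""
    return counts.T.groupby(level="subgenome").sum().T


def de_filter(
    counts_c1: pd.DataFrame,
    counts_c2: pd.DataFrame,
    method: str = "builtin",
    external_q: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-subgenome differential-expression q-values (groups x subgenomes).

    ``external`` passes a user q-value table (e.g. from DESeq2) through
    unchanged; ``builtin`` requires at least two replicates per condition.
    """
    if method == "external":
        if external_q is None:
            raise ValueError("external mode requires a q-value table")
        return external_q

    if method != "builtin":
        raise ValueError(f"unknown DE filter method {method!r}")
    for name, c in (("condition 1", counts_c1), ("condition 2", counts_c2)):
        n_reps = c.columns.get_level_values("sample").nunique()
        if n_reps < 2:
            raise ValueError(
                f"builtin DE filter needs >=2 replicates in {name} "
                f"(got {n_reps}); supply external q-values instead"
            )

    sums1 = _replicate_sums(counts_c1)
    sums2 = _replicate_sums(counts_c2)
    subs = sums1.columns
    qvals = pd.DataFrame(index=sums1.index, columns=subs, dtype=float)
    for sub in subs:
        n1 = sums1[sub].round().astype(int)
        n2 = sums2[sub].reindex(sums1.index).fillna(0).round().astype(int)
        lib1, lib2 = int(n1.sum()), int(n2.sum())
        null_p = lib1 / (lib1 + lib2) if lib1 + lib2 > 0 else 0.5
        pvals = np.ones(len(n1))
        for i, (a, b) in enumerate(zip(n1.values, n2.values)):
            if a + b > 0:
                pvals[i] = stats.binomtest(int(a), int(a + b), null_p).pvalue
        qvals[sub] = multipletests(pvals, method="fdr_bh")[1]
    return qvals


def fisher_ratio_test(
    focal_c1: float, rest_c1: float, focal_c2: float, rest_c2: float
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 ratio table.

    Table layout: ``[[focal_c1, rest_c1], [focal_c2, rest_c2]]`` with counts
    combined across replicates.  Returns ``(p, fold_change)``.
    """
    cells = [round(focal_c1), round(rest_c1), round(focal_c2), round(rest_c2)]
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    a, b, c, d = cells
    if a + b + c + d == 0:
        return 1.0, 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c)
    return float(p), float(max(odds, 1.0 / odds))


def call_deh(
    de_q: dict[str, float],
    fisher_results: dict[str, tuple[float, float]],
    ploidy: int,
    alpha_de: float = 0.05,
    alpha_ratio: float = 0.05,
    fc_min: float = 2.0,
    group_id: str = "",
) -> DehResult:
    """Combine the DE filter and ratio tests into a DEH call for one group."""
    expected = 1 if ploidy == 2 else 3
    if len(fisher_results) != expected:
        raise ValueError(
            f"ploidy {ploidy} expects {expected} ratio contrast(s), got "
            f"{sorted(fisher_results)}"
        )
    threshold = alpha_ratio if ploidy == 2 else alpha_ratio / 3.0
    de_ok = min(de_q.values()) <= alpha_de
    ratio_ok = any(
        p < threshold and fc >= fc_min for p, fc in fisher_results.values()
    )
    return DehResult(
        group_id=group_id,
        de_qvalues=dict(de_q),
        fisher_p={k: p for k, (p, _) in fisher_results.items()},
        fold_change={k: fc for k, (_, fc) in fisher_results.items()},
        is_deh=bool(de_ok and ratio_ok),
        contrasts=tuple(fisher_results),
    )


def call_deh_table(
    counts_c1: pd.DataFrame,
    counts_c2: pd.DataFrame,
    de_q: pd.DataFrame | None = None,
    alpha_de: float = 0.05,
    alpha_ratio: float = 0.05,
    fc_min: float = 2.0,
) -> pd.DataFrame:
    """DEH calls for every group of a two-condition count table pair.

    ``de_q`` defaults to the builtin DE filter.  Contrasts are the focal
    subgenome versus the combined rest (one contrast for two subgenomes,
    three for three).
    """
    if de_q is None:
        de_q = de_filter(counts_c1, counts_c2)
    sums1 = _replicate_sums(counts_c1)
    sums2 = _replicate_sums(counts_c2).reindex(sums1.index).fillna(0)
    subs = list(sums1.columns)
    ploidy = len(subs)
    rows = []
    for gid in sums1.index:
        fisher = {}
        for focal in subs if ploidy == 3 else subs[:1]:
            rest = [s for s in subs if s != focal]
            name = f"{focal}_vs_{''.join(rest)}"
            fisher[name] = fisher_ratio_test(
                sums1.loc[gid, focal],
                sums1.loc[gid, rest].sum(),
                sums2.loc[gid, focal],
                sums2.loc[gid, rest].sum(),
            )
        res = call_deh(
            de_q.loc[gid].to_dict(),
            fisher,
            ploidy,
            alpha_de,
            alpha_ratio,
            fc_min,
            group_id=gid,
        )
        row = {"group_id": gid, "is_deh": res.is_deh}
        for s in subs:
            row[f"q:{s}"] = res.de_qvalues[s]
        for k in res.contrasts:
            row[f"p:{k}"] = res.fisher_p[k]
            row[f"fc:{k}"] = res.fold_change[k]
        rows.append(row)
    return pd.DataFrame(rows).set_index("group_id")


def deh_overlap(results_by_method: dict[str, set]) -> dict:
    """Pairwise DEH intersections and per-method support fractions.

    A method's DEH is *supported* when at least one other method also calls
    it; the support fraction is supported / total for that method.
    """
    if len(results_by_method) < 2:
        raise ValueError("overlap needs at least two result sets")
    methods = sorted(results_by_method)
    pairwise = {}
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1 :]:
            pairwise[f"{m1}|{m2}"] = len(
                results_by_method[m1] & results_by_method[m2]
            )
    supported = {}
    for m in methods:
        others = set().union(
            *(results_by_method[o] for o in methods if o != m)
        )
        mine = results_by_method[m]
        supported[m] = (
            len(mine & others) / len(mine) if mine else float("nan")
        )
    return {"pairwise_intersection": pairwise, "supported_fraction": supported}
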