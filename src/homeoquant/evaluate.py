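"""Ground-truth and cross-method evaluation.

Classification error is the proportion of reads assigned to the *wrong*
subgenome; COMMON and UNKNOWN labels never enter the numerator, and the
denominator is an explicit mode because published summaries switch between
mapped reads, classified reads and quantified reads.

Method concordance uses the root-mean-square distance

    RMSD = sqrt( sum_i (x_i - y_i)^2 / n )

and the squared sample correlation r^2; pairs with an undefined proportion
(zero-total groups) are dropped pairwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import COMMON, UNKNOWN


@dataclass(slots=True)
class ErrorReport:
    denominator: str
    n_denominator: int
    n_wrong: int
    error_pct: float
    error_by_direction: dict[str, float] = field(default_factory=dict)
    mapped_pct: float = float("nan")
    classified_pct: float = float("nan")


def classification_error(
    classifications,
    truth: dict[str, str],
    denominator: str = "classified",
    quantified_ids: set | None = None,
    n_total_reads: int | None = None,
) -> ErrorReport:
    """Per-direction misclassification rates against a truth table.

    ``denominator`` is ``mapped`` (all fragments with an alignment, i.e.
    everything classified_sample saw), ``classified`` (fragments assigned a
    subgenome) or ``quantified`` (fragments in ``quantified_ids``).
    """
    if not truth:
        raise ValueError("empty truth table")
    n_mapped = len(classifications)
    classified = {
        rid: rc
        for rid, rc in classifications.items()
        if rc.label not in (COMMON, UNKNOWN)
    }
    if denominator == "mapped":
        denom_ids = set(classifications)
    elif denominator == "classified":
        denom_ids = set(classified)
    elif denominator == "quantified":
        if quantified_ids is None:
            raise ValueError("quantified mode needs quantified_ids")
        denom_ids = set(quantified_ids)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")

    n_denom = len(denom_ids)
    wrong_by_dir: dict[str, int] = {}
    n_wrong = 0
    for rid, rc in classified.items():
        if rid not in denom_ids:
            continue
        true_sub = truth[rid]
        if rc.label != true_sub:
            key = f"{true_sub}->{rc.label}"
            wrong_by_dir[key] = wrong_by_dir.get(key, 0) + 1
            n_wrong += 1
    return ErrorReport(
        denominator=denominator,
        n_denominator=n_denom,
        n_wrong=n_wrong,
        error_pct=100.0 * n_wrong / n_denom if n_denom else float("nan"),
        error_by_direction={
            k: 100.0 * v / n_denom for k, v in sorted(wrong_by_dir.items())
        },
        mapped_pct=(
            100.0 * n_mapped / n_total_reads
            if n_total_reads
            else float("nan")
        ),
        classified_pct=100.0 * len(classified) / n_mapped if n_mapped else 0.0,
    )


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def rmsd(x, y) -> float:
    """Root-mean-square distance between two vectors (NA pairs dropped)."""
    x, y = _complete_pairs(x, y)
    if x.size == 0:
        return math.nan
    return float(np.sqrt(np.mean((x - y) ** 2)))


def r_squared(x, y) -> float:
    """Squared sample correlation (NA pairs dropped; NaN on zero variance)."""
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise ValueError("r_squared needs at least 3 complete pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        warnings.warn("zero variance in r_squared input; returning NaN")
        return math.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def stratified_concordance(
    ratio_tables: dict[str, pd.Series],
    total_counts: pd.Series,
    low_max: float = 100,
    high_min: float = 200,
) -> dict:
    """Pairwise RMSD matrices for low- and high-expression strata.

    Groups with total count <= ``low_max`` form the low stratum, groups with
    total count > ``high_min`` the high stratum.  Also reports a paired
    t-test across the per-pair RMSDs of the two strata.
    """
    if len(ratio_tables) < 2:
        raise ValueError("need ratio tables from at least two methods")
    methods = sorted(ratio_tables)
    shared = ratio_tables[methods[0]].index
    for m in methods[1:]:
        shared = shared.intersection(ratio_tables[m].index)
    counts = total_counts.reindex(shared)
    strata = {
        "low": shared[counts <= low_max],
        "high": shared[counts > high_min],
    }
    out = {}
    pair_rmsds = {"low": [], "high": []}
    for name, idx in strata.items():
        mat = pd.DataFrame(np.nan, index=methods, columns=methods)
        for m1, m2 in itertools.combinations(methods, 2):
            val = (
                rmsd(ratio_tables[m1].reindex(idx), ratio_tables[m2].reindex(idx))
                if len(idx)
                else math.nan
            )
            mat.loc[m1, m2] = mat.loc[m2, m1] = val
            pair_rmsds[name].append(val)
        out[name] = mat
    low, high = np.array(pair_rmsds["low"]), np.array(pair_rmsds["high"])
    ok = ~(np.isnan(low) | np.isnan(high))
    if ok.sum() >= 2:
        out["paired_t_p"] = float(stats.ttest_rel(low[ok], high[ok]).pvalue)
    else:
        out["paired_t_p"] = math.nan
    return out
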