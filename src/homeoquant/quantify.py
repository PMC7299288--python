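"""Per-homeolog read counting and expression-proportion tables.

Counting follows transcript-level featureCounts semantics: a fragment
increments the count of the homeolog member on its assigned subgenome iff
one of its mates overlaps that transcript's exons by at least one base;
fragments overlapping more than one feature on the assigned subgenome are
dropped, as are UNKNOWN fragments.  COMMON fragments are held aside and can
optionally be distributed across subgenomes in proportion to the classified
base counts (:func:`distribute_common`), which makes counts real-valued.

The homeolog expression proportion p-hat of a group is the focal subgenome's
count over the total across all subgenome copies (NA when the total is 0).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import HomeologCatalog
from .model import COMMON, UNKNOWN, SubgenomeAlignment, TranscriptModel


class _ExonIndex:
    """Per-contig sorted exon intervals -> transcript ids."""

    def __init__(self, models: Iterable[TranscriptModel]):
        per_contig: dict[str, list[tuple[int, int, str]]] = {}
        for m in models:
            for s, e in m.exons:
                per_contig.setdefault(m.contig, []).append((s, e, m.transcript_id))
        self._contigs = {}
        for contig, ivs in per_contig.items():
            ivs.sort()
            self._contigs[contig] = (
                np.array([s for s, _, _ in ivs], dtype=np.int64),
                np.array([e for _, e, _ in ivs], dtype=np.int64),
                [t for _, _, t in ivs],
            )

    def overlapping(self, contig: str, start: int, end: int) -> set[str]:
        entry = self._contigs.get(contig)
        if entry is None:
            return set()
        starts, ends, tids = entry
        hi = int(np.searchsorted(starts, end, side="left"))
        return {tids[i] for i in range(hi) if ends[i] > start}


def count_reads(
    classifications,
    alignments_by_subgenome: dict[str, Iterable[SubgenomeAlignment]],
    transcript_models: Iterable[TranscriptModel],
    catalog: HomeologCatalog,
    sample: str,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Count classified fragments per homeolog group and subgenome.

    Returns ``(base_counts, common_counts, tally)`` for one sample:
    base_counts has columns ``(sample, subgenome)``, common_counts is a
    per-group series of COMMON fragments awaiting distribution.
    """
    index = _ExonIndex(transcript_models)
    frag_alns: dict[str, dict[str, list[SubgenomeAlignment]]] = {}
    for sub, alns in alignments_by_subgenome.items():
        for aln in alns:
            if aln.is_secondary:
                continue
            frag_alns.setdefault(aln.read_id, {}).setdefault(sub, []).append(aln)

    subs = catalog.subgenomes
    group_ids = [g.group_id for g in catalog.groups]
    base = pd.DataFrame(
        0.0,
        index=group_ids,
        columns=pd.MultiIndex.from_product(
            [[sample], subs], names=["sample", "subgenome"]
        ),
    )
    common = pd.Series(0.0, index=group_ids)
    tally = {"counted": 0, "common": 0, "ambiguous": 0, "dropped": 0,
             "non_homeolog": 0}

    def fragment_features(read_id, sub):
        feats: set[str] = set()
        for aln in frag_alns.get(read_id, {}).get(sub, []):
            feats |= index.overlapping(aln.contig, aln.pos, aln.reference_end)
        return feats

    for read_id, rc in classifications.items():
        if rc.label == UNKNOWN:
            tally["dropped"] += 1
            continue
        if rc.label == COMMON:
            # resolve the group via any subgenome's overlap; members of one
            # group share the group id so any consistent hit works
            groups = set()
            for sub in subs:
                for tid in fragment_features(read_id, sub):
                    g = catalog.by_transcript.get(tid)
                    if g is not None:
                        groups.add(g.group_id)
            if len(groups) == 1:
                common[next(iter(groups))] += 1
                tally["common"] += 1
            else:
                tally["ambiguous" if groups else "non_homeolog"] += 1
            continue
        feats = fragment_features(read_id, rc.label)
        if not feats:
            tally["dropped"] += 1
            continue
        if len(feats) > 1:
            tally["ambiguous"] += 1  # featureCounts default: drop multi-feature
            continue
        tid = next(iter(feats))
        g = catalog.by_transcript.get(tid)
        if g is None:
            tally["non_homeolog"] += 1
            continue
        if g.members.get(rc.label) != tid:
            raise ValueError(
                f"fragment {read_id} assigned to {rc.label} but overlaps "
                f"{tid}, the {g.group_id} member of another subgenome"
            )
        base.loc[g.group_id, (sample, rc.label)] += 1
        tally["counted"] += 1
    return base, common, tally


def distribute_common(
    base_counts: pd.DataFrame, common_counts: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Split COMMON fragments across subgenomes proportionally to base counts.

    ``common_counts`` is per group (Series, applied to every sample column
    group) or per group x sample (DataFrame).  Groups with all-zero base
    counts split equally.  Conservation: the output total equals base total
    plus common total.
    """
    if (base_counts.values < 0).any():
        raise ValueError("negative base counts")
    out = base_counts.astype(float).copy()
    samples = base_counts.columns.get_level_values("sample").unique()
    for sample in samples:
        block = base_counts[sample]
        if isinstance(common_counts, pd.Series):
            extra = common_counts.reindex(block.index).fillna(0.0)
        else:
            extra = common_counts[sample].reindex(block.index).fillna(0.0)
        if (np.asarray(extra) < 0).any():
            raise ValueError("negative common counts")
        totals = block.sum(axis=1)
        nsub = block.shape[1]
        weights = block.div(totals.where(totals > 0), axis=0)
        weights = weights.fillna(1.0 / nsub)
        for sub in block.columns:
            out[(sample, sub)] = block[sub] + extra * weights[sub]
    return out


def phat(counts_row: pd.Series | dict, focal: str) -> float:
    """Focal-subgenome proportion of a single group's counts (NA if empty)."""
    if isinstance(counts_row, dict):
        counts_row = pd.Series(counts_row)
    total = float(counts_row.sum())
    if total <= 0:
        return math.nan
    return float(counts_row[focal]) / total


def ratio_table(counts: pd.DataFrame, focal: str) -> pd.DataFrame:
    """Per-group, per-sample p-hat for the focal subgenome."""
    samples = counts.columns.get_level_values("sample").unique()
    out = {}
    for sample in samples:
        block = counts[sample]
        totals = block.sum(axis=1)
        out[sample] = (block[focal] / totals.where(totals > 0)).astype(float)
    return pd.DataFrame(out)


def expressed_homeologs(
    counts: pd.DataFrame, min_reads: float = 1, n_catalog: int | None = None
) -> dict[str, float]:
    """Percent of catalog groups with more than ``min_reads`` in any sample.

    Note the strict inequality: a group with exactly ``min_reads`` reads is
    not called expressed.
    """
    if counts.shape[0] == 0:
        raise ValueError("empty count table / catalog")
    n_total = n_catalog if n_catalog is not None else counts.shape[0]
    subs = counts.columns.get_level_values("subgenome").unique()
    out = {}
    for sub in subs:
        block = counts.xs(sub, axis=1, level="subgenome")
        expressed = (block.max(axis=1) > min_reads).sum()
        out[sub] = 100.0 * float(expressed) / n_total
    return out
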